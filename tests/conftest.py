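import warnings

import numpy as np
import pytest

import zfmask as z
from zfmask import ica_pipeline as ica
from zfmask import response_classification as rc

IMAGING_RATE_HZ = 7.1
IMAGING_FOV = (40, 30)


@pytest.fixture(scope="session")
def behavior_schedule():
    return z.make_schedule("behavior_cycles", 10, seed=1)


@pytest.fixture(scope="session")
def imaging_run():
    """One small end-to-end imaging run shared by decomposition and
    classification tests: a randomized blue/red pulse schedule, five
    planted sources (one per response class) at SNR 10, decomposed and
    classified."""
    seed = 3
    sch = z.make_schedule("imaging_random", 4, seed=seed)
    sources = z.default_source_bank(IMAGING_FOV, jitter_px=2, seed=seed)
    T = sch.n_samples(IMAGING_RATE_HZ)
    movie, masks, classes = z.simulate_calcium_movie(
        sch, sources, (T, *IMAGING_FOV), noise_sd=0.1, rate_hz=IMAGING_RATE_HZ,
        seed=seed,
    )
    pca = ica.pca_reduce(movie, 8)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        decomp = ica.spatial_ica(pca, seed=seed)
    rois = ica.segment_rois(decomp)
    bank = rc.build_templates(sch, IMAGING_RATE_HZ)
    cls = rc.classify_components(decomp, bank)
    return {
        "schedule": sch,
        "sources": sources,
        "movie": movie,
        "masks": masks,
        "classes": classes,
        "pca": pca,
        "decomp": decomp,
        "rois": rois,
        "bank": bank,
        "classification": cls,
        "rate_hz": IMAGING_RATE_HZ,
        "fov": IMAGING_FOV,
    }
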