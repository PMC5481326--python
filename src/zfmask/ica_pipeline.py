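"""Movie decomposition: PCA dimension reduction, spatiotemporal ICA,
ROI segmentation and trace extraction.

The decomposition follows the cell-sorting approach standard for calcium
imaging: PCA on the mean-subtracted pixel-time matrix, then fixed-point
ICA on the whitened, mu-weighted concatenation of the spatial and
temporal views (mu = 0 purely spatial, 1 purely temporal).  The ICA
contrast is skewness-based, matching the positive-going, sparse character
of calcium signals.  ROIs are the above-threshold connected components of
the sign-oriented spatial maps.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy import stats
from skimage import measure

DEFAULT_N_PCS = 30
DEFAULT_Z_THRESHOLD = 2.0
DEFAULT_MIN_PIXELS = 10


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PCAResult:
    """Top-k principal components of a movie's pixel-time matrix.

    ``scores`` (T x k) are the temporal courses, ``loadings`` (k x Y*X)
    the unit-norm spatial eigenimages; ``variance_explained`` holds each
    retained PC's fraction of total variance.
    """

    scores: np.ndarray
    loadings: np.ndarray
    variance_explained: np.ndarray
    mean_image: np.ndarray
    frame_shape: tuple[int, int]

    @property
    def k(self) -> int:
        return self.loadings.shape[0]

    def spatial_images(self) -> np.ndarray:
        return self.loadings.reshape(self.k, *self.frame_shape)

    def reconstruct(self) -> np.ndarray:
        T = self.scores.shape[0]
        flat = self.scores @ self.loadings + self.mean_image.ravel()[None, :]
        return flat.reshape(T, *self.frame_shape)


def _skew_orient(spatial: np.ndarray, temporal: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Flip component signs so each spatial map has positive skewness.

    Calcium sources are bright blobs on a flat background, so the correct
    orientation is positively skewed in space; a near-symmetric map falls
    back to the temporal skewness.
    """
    spatial = spatial.copy()
    temporal = temporal.copy()
    for i in range(spatial.shape[0]):
        s = stats.skew(spatial[i])
        if abs(s) < 1e-12:
            s = stats.skew(temporal[:, i] if temporal.ndim == 2 else temporal[i])
        if s < 0:
            spatial[i] *= -1
            if temporal.ndim == 2:
                temporal[:, i] *= -1
            else:
                temporal[i] *= -1
    return spatial, temporal


def pca_reduce(movie: np.ndarray, k: int) -> PCAResult:
    """Reduce a T x Y x X movie to its top-k principal components.

    Deterministic up to sign; signs are fixed by the positive-skew rule.
    Raises on a rank-deficient request (k beyond the number of non-trivial
    components, e.g. any k on an all-constant movie).
    """
    movie = np.asarray(movie, dtype=float)
    if movie.ndim != 3:
        raise ValueError("movie must be T x Y x X")
    if not np.all(np.isfinite(movie)):
        raise ValueError("movie contains non-finite values")
    T, Y, X = movie.shape
    if not 1 <= k <= min(T, Y * X):
        raise ValueError(f"k must be in [1, {min(T, Y * X)}]")
    Xmat = movie.reshape(T, Y * X)
    mean_image = Xmat.mean(axis=0)
    Xc = Xmat - mean_image[None, :]
    # eigendecomposition on the smaller Gram side (movies are usually
    # long and narrow, so this beats a full SVD by a wide margin)
    if Y * X <= T:
        G = Xc.T @ Xc
        vals, vecs = np.linalg.eigh(G)
        vals = np.clip(vals[::-1], 0.0, None)
        vecs = vecs[:, ::-1]
        s = np.sqrt(vals)
        total = float(vals.sum())
        if total <= 0 or s[k - 1] <= 1e-12 * s[0]:
            raise ValueError("movie rank below requested k (zero-variance input?)")
        loadings = vecs[:, :k].T
        scores = Xc @ vecs[:, :k]
    else:
        G = Xc @ Xc.T
        vals, vecs = np.linalg.eigh(G)
        vals = np.clip(vals[::-1], 0.0, None)
        vecs = vecs[:, ::-1]
        s = np.sqrt(vals)
        total = float(vals.sum())
        if total <= 0 or s[k - 1] <= 1e-12 * s[0]:
            raise ValueError("movie rank below requested k (zero-variance input?)")
        U = vecs[:, :k]
        scores = U * s[:k]
        loadings = (Xc.T @ U / s[:k]).T
    ve = vals[:k] / total
    loadings, scores = _skew_orient(loadings, scores)
    return PCAResult(
        scores=scores,
        loadings=loadings,
        variance_explained=ve,
        mean_image=mean_image.reshape(Y, X),
        frame_shape=(Y, X),
    )


# ---------------------------------------------------------------------------
# Spatiotemporal ICA
# ---------------------------------------------------------------------------

@dataclass
class ICADecomposition:
    """Paired spatial maps (k x Y*X) and temporal signals (k x T)."""

    spatial_maps: np.ndarray
    temporal_signals: np.ndarray
    retained_pcs: int
    variance_explained: np.ndarray
    mu: float
    frame_shape: tuple[int, int]
    converged: bool = True
    n_iter: int = 0
    seed: int | None = None

    @property
    def k(self) -> int:
        return self.spatial_maps.shape[0]

    def spatial_images(self) -> np.ndarray:
        return self.spatial_maps.reshape(self.k, *self.frame_shape)

    def save(self, maps_tiff: str | Path, meta_json: str | Path) -> None:
        tifffile.imwrite(str(maps_tiff), self.spatial_images().astype(np.float32))
        Path(meta_json).write_text(
            json.dumps(
                {
                    "k": self.k,
                    "retained_pcs": self.retained_pcs,
                    "mu": self.mu,
                    "seed": self.seed,
                    "converged": self.converged,
                    "n_iter": self.n_iter,
                    "variance_explained": list(map(float, self.variance_explained)),
                },
                indent=1,
            )
        )


def _fixed_point_ica(
    Z: np.ndarray, rng: np.random.Generator, max_iter: int, tol: float
) -> tuple[np.ndarray, bool, int]:
    """Symmetric fixed-point ICA with a skewness contrast (G(u) = u^3/3).

    ``Z`` is k x m, whitened (identity row covariance).  Returns the
    orthogonal unmixing matrix W maximizing the skewness of W @ Z.
    """
    k, m = Z.shape

    def _sym_decorrelate(W):
        vals, vecs = np.linalg.eigh(W @ W.T)
        return vecs @ np.diag(vals**-0.5) @ vecs.T @ W

    W = _sym_decorrelate(rng.standard_normal((k, k)))
    for it in range(1, max_iter + 1):
        Y = W @ Z
        # g(u) = u^2, g'(u) = 2u
        W_new = (Y**2) @ Z.T / m - 2.0 * np.mean(Y, axis=1)[:, None] * W
        W_new = _sym_decorrelate(W_new)
        delta = np.max(np.abs(np.abs(np.sum(W_new * W, axis=1)) - 1.0))
        W = W_new
        if delta < tol:
            return W, True, it
    return W, False, max_iter


def spatial_ica(
    pca: PCAResult,
    n_components: int | None = None,
    mu: float = 0.0,
    seed: int | None = 0,
    max_iter: int = 500,
    tol: float = 1e-6,
) -> ICADecomposition:
    """Unmix PCA components by ICA on the mu-weighted spatiotemporal view.

    mu = 0 runs purely spatial ICA (the default: footprints of distinct
    cells are close to spatially independent), mu = 1 purely temporal;
    intermediate values concatenate the whitened spatial and temporal
    views with weights (1 - mu) and mu.  Components are ordered by
    decreasing temporal-signal skewness and sign-fixed by the
    positive-skew rule.  Non-convergence returns the best iterate flagged
    ``converged=False``.
    """
    if not 0.0 <= mu <= 1.0:
        raise ValueError("mu must lie in [0, 1]")
    k = pca.k if n_components is None else int(n_components)
    if not 1 <= k <= pca.k:
        raise ValueError("n_components must be in [1, retained PCs]")

    spatial = pca.loadings[:k]  # k x P, orthonormal rows
    temporal = pca.scores[:, :k].T  # k x T

    def _whiten_rows(M):
        Mc = M - M.mean(axis=1, keepdims=True)
        sd = Mc.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        return Mc / sd

    views = []
    if mu < 1.0:
        views.append((1.0 - mu) * _whiten_rows(spatial))
    if mu > 0.0:
        views.append(mu * _whiten_rows(temporal))
    Z = np.concatenate(views, axis=1)
    # joint whitening so the unmixing search stays on the orthogonal group
    C = Z @ Z.T / Z.shape[1]
    vals, vecs = np.linalg.eigh(C)
    vals = np.clip(vals, 1e-12, None)
    white = vecs @ np.diag(vals**-0.5) @ vecs.T
    Zw = white @ Z

    rng = np.random.default_rng(seed)
    W, converged, n_iter = _fixed_point_ica(Zw, rng, max_iter, tol)
    if not converged:
        warnings.warn(
            f"ICA did not converge in {max_iter} iterations; returning best iterate",
            stacklevel=2,
        )
    M = W @ white
    maps = M @ spatial
    signals = M @ temporal
    signals = signals - signals.mean(axis=1, keepdims=True)
    maps, signals = _skew_orient(maps, signals)
    order = np.argsort(-stats.skew(signals, axis=1))
    return ICADecomposition(
        spatial_maps=maps[order],
        temporal_signals=signals[order],
        retained_pcs=pca.k,
        variance_explained=pca.variance_explained,
        mu=mu,
        frame_shape=pca.frame_shape,
        converged=converged,
        n_iter=n_iter,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# ROI segmentation and traces
# ---------------------------------------------------------------------------

@dataclass
class ROISet:
    """Disjoint labelled ROIs with the component each came from."""

    label_image: np.ndarray  # Y x X int, 0 = background
    provenance: dict[int, int] = field(default_factory=dict)  # label -> component

    @property
    def n_rois(self) -> int:
        return len(self.provenance)

    def pixels(self, label: int) -> np.ndarray:
        return np.argwhere(self.label_image == label)

    def save(self, label_tiff: str | Path) -> None:
        tifffile.imwrite(str(label_tiff), self.label_image.astype(np.int32))


def segment_rois(
    decomp: ICADecomposition,
    z_threshold: float = DEFAULT_Z_THRESHOLD,
    min_pixels: int = DEFAULT_MIN_PIXELS,
) -> ROISet:
    """Threshold each spatial map at mean + z*SD and keep large components.

    Pixels already claimed by an earlier (higher-skew) component are not
    reassigned, so labels stay disjoint.  An empty result is returned with
    a warning when no map has a qualifying component.
    """
    Y, X = decomp.frame_shape
    label_image = np.zeros((Y, X), dtype=np.int32)
    provenance: dict[int, int] = {}
    next_label = 1
    for ci, flat_map in enumerate(decomp.spatial_maps):
        img = flat_map.reshape(Y, X)
        thr = img.mean() + z_threshold * img.std()
        mask = (img > thr) & (label_image == 0)
        if not mask.any():
            continue
        comp_labels = measure.label(mask, connectivity=2)
        for region in measure.regionprops(comp_labels):
            if region.area < min_pixels:
                continue
            label_image[comp_labels == region.label] = next_label
            provenance[next_label] = ci
            next_label += 1
    if not provenance:
        warnings.warn("no pixels passed the ROI threshold in any map", stacklevel=2)
    return ROISet(label_image=label_image, provenance=provenance)


def roi_traces(movie: np.ndarray, rois: ROISet) -> pd.DataFrame:
    """Spatially averaged, z-scored trace per ROI (time x ROI columns)."""
    movie = np.asarray(movie, dtype=float)
    T = movie.shape[0]
    if rois.label_image.shape != movie.shape[1:]:
        raise ValueError("ROI label image does not match movie frame shape")
    flat = movie.reshape(T, -1)
    labels_flat = rois.label_image.ravel()
    out = {}
    for label in sorted(rois.provenance):
        idx = np.flatnonzero(labels_flat == label)
        trace = flat[:, idx].mean(axis=1)
        sd = trace.std()
        if sd == 0:
            warnings.warn(f"ROI {label} has a zero-variance trace", stacklevel=2)
            out[f"roi{label:03d}"] = np.zeros(T)
        else:
            out[f"roi{label:03d}"] = (trace - trace.mean()) / sd
    return pd.DataFrame(out)
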