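"""Oracle and property tests for the behavioral statistics battery."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

import zfmask.behavior_stats as bs
from zfmask import make_schedule
from zfmask.trajectories import TrajectorySet

RATE = 5.0


def _traj(depth):
    return TrajectorySet(depth=np.asarray(depth, dtype=float), rate_hz=RATE)


# ---------------------------------------------------------------------------
# Epoch metrics and occurrence
# ---------------------------------------------------------------------------

def _piecewise_fish(climbs):
    """Depth trace for 10 cycles: dives 4.0 cm -> stays, then climbs to 1.0
    within the light epoch when climbs[cycle] is True, else stays at 4.0."""
    n = int(60 * RATE)
    segs = []
    for do_climb in climbs:
        segs.append(np.full(n, 4.0))  # dark epoch: parked deep
        if do_climb:
            half = np.linspace(4.0, 1.0, n // 2)
            segs.append(np.concatenate([half, np.full(n - n // 2, 1.0)]))
        else:
            segs.append(np.full(n, 4.0))
    return np.concatenate(segs)


def test_noiseless_dive_speed():
    """A linear 2.5 -> 4.5 cm descent in the first 20 s of a dark epoch
    gives a dive speed of exactly 0.1 cm/s."""
    sch = make_schedule("behavior_cycles", 1, seed=0)
    n = int(60 * RATE)
    down = np.concatenate([np.linspace(2.5, 4.5, int(20 * RATE) + 1),
                           np.full(n - int(20 * RATE) - 1, 4.5)])
    trace = np.concatenate([down, np.full(n, 4.5)])
    m = bs.epoch_metrics(_traj(trace[None, :]), sch)
    off = m[m.phase == "off"].iloc[0]
    assert off.initial_speed_cm_s == pytest.approx(0.1, abs=1e-9)
    assert off.final_position_cm == pytest.approx(4.5)


def test_constant_depth_has_zero_speed_and_no_crossings():
    sch = make_schedule("behavior_cycles", 2, seed=0)
    m = bs.epoch_metrics(_traj(np.full((3, int(240 * RATE)), 3.3)), sch)
    assert (m.initial_speed_cm_s == 0).all()
    assert not m.reached_half.any()
    assert m.time_to_half_s.isna().all()


def test_twelve_fish_ten_cycles_gives_120_events_per_direction():
    sch = make_schedule("behavior_cycles", 10, seed=0)
    depth = np.full((12, int(1200 * RATE)), 2.0)
    m = bs.epoch_metrics(_traj(depth), sch)
    assert bs.occurrence_rate(m, "on")[1] == 120
    assert bs.occurrence_rate(m, "off")[1] == 120


def test_occurrence_counts_constructed_crossings():
    """12 fish x 10 cycles built so that exactly 72 climbs cross half-depth."""
    pattern = np.zeros((12, 10), dtype=bool)
    pattern.ravel()[:72] = True
    sch = make_schedule("behavior_cycles", 10, seed=0)
    depth = np.stack([_piecewise_fish(row) for row in pattern])
    m = bs.epoch_metrics(_traj(depth), sch)
    assert bs.occurrence_rate(m, "on") == (72, 120)
    assert bs.occurrence_rate(m, "off") == (0, 120)


def test_epoch_metrics_validation():
    sch = make_schedule("behavior_cycles", 2, seed=0)
    with pytest.raises(ValueError, match="duration"):
        bs.epoch_metrics(_traj(np.zeros((1, 100))), sch)
    short = make_schedule("behavior_cycles", 1, seed=0, epoch_duration_s=10.0)
    with pytest.raises(ValueError, match="20 s"):
        bs.epoch_metrics(_traj(np.zeros((1, 100))), short)


# ---------------------------------------------------------------------------
# Correlation matrices
# ---------------------------------------------------------------------------

def test_identical_traces_correlate_perfectly():
    base = np.sin(np.linspace(0, 20, 500))
    R = bs.pairwise_correlation(_traj(np.tile(base, (4, 1))))
    assert np.allclose(R.offdiag_values(), 1.0)


def test_mirror_trace_correlates_minus_one():
    base = 2.5 + np.sin(np.linspace(0, 20, 500))
    R = bs.pairwise_correlation(_traj(np.stack([base, 5.0 - base])))
    assert R.R[0, 1] == pytest.approx(-1.0)


def test_shared_drive_gives_signal_fraction_correlation():
    """With shared signal and independent noise of equal variance, pairwise
    r concentrates at sigma_s^2 / (sigma_s^2 + sigma_n^2) = 0.5."""
    rng = np.random.default_rng(0)
    shared = rng.standard_normal(6000)
    depth = 2.5 + 0.3 * (shared[None, :] + rng.standard_normal((12, 6000)))
    R = bs.pairwise_correlation(_traj(np.clip(depth, 0, 5)))
    assert np.median(R.offdiag_values()) == pytest.approx(0.5, abs=0.05)


def test_zero_variance_trace_excluded_with_warning():
    rng = np.random.default_rng(1)
    depth = np.vstack([rng.random((3, 200)), np.full(200, 2.0)])
    with pytest.warns(UserWarning, match="zero-variance"):
        R = bs.pairwise_correlation(_traj(depth))
    assert np.isnan(R.R[3, 0])
    assert R.offdiag_values().size == 3  # only the 3 valid pairs remain


# ---------------------------------------------------------------------------
# Jennrich test
# ---------------------------------------------------------------------------

def _random_corr(p, n, rng):
    return np.corrcoef(rng.standard_normal((p, n)))


def test_jennrich_equal_matrices_give_zero():
    R = _random_corr(5, 300, np.random.default_rng(0))
    res = bs.jennrich_test(R, 400, R, 400)
    assert res.chi2 == pytest.approx(0.0, abs=1e-10)
    assert res.p == pytest.approx(1.0)


def test_jennrich_df_formula():
    rng = np.random.default_rng(1)
    res = bs.jennrich_test(_random_corr(12, 500, rng), 500,
                           _random_corr(12, 500, rng), 500)
    assert res.df == 66


def test_jennrich_two_by_two_oracle():
    """p = 2, r1 = 0.5, r2 = 0, n1 = n2 = 100: the scalar closed form of
    the statistic evaluates to 128/9 = 14.2222."""
    R1 = np.array([[1.0, 0.5], [0.5, 1.0]])
    R2 = np.eye(2)
    res = bs.jennrich_test(R1, 100, R2, 100)
    assert res.chi2 == pytest.approx(14.222222222, abs=1e-8)
    assert res.df == 1


def test_jennrich_symmetry_and_positivity():
    rng = np.random.default_rng(2)
    A, B = _random_corr(6, 200, rng), _random_corr(6, 200, rng)
    r1 = bs.jennrich_test(A, 150, B, 250)
    r2 = bs.jennrich_test(B, 250, A, 150)
    assert r1.chi2 == pytest.approx(r2.chi2)
    assert r1.chi2 > 0


def test_jennrich_validation():
    rng = np.random.default_rng(3)
    A = _random_corr(5, 100, rng)
    with pytest.raises(ValueError):
        bs.jennrich_test(A, 4, A, 100)  # n <= p
    with pytest.raises(ValueError):
        bs.jennrich_test(A, 100, _random_corr(4, 100, rng), 100)


# ---------------------------------------------------------------------------
# Mann-Whitney
# ---------------------------------------------------------------------------

def test_complete_separation():
    res = bs.mann_whitney([1, 2], [3, 4], tail="two")
    assert res.U == 0
    assert res.rank_biserial == pytest.approx(1.0)


@pytest.mark.parametrize(
    "U,n1,n2,expected",
    [(28, 12, 12, 0.61), (66, 12, 12, 0.083), (4, 24, 16, 0.98),
     (119, 29, 27, 0.70), (261, 29, 28, 0.36)],
)
def test_rank_biserial_identity(U, n1, n2, expected):
    assert bs.rank_biserial(U, n1, n2) == pytest.approx(expected, abs=0.005)


def _brute_force_p(x, y, tail):
    allv = np.concatenate([x, y])
    ranks = sps.rankdata(allv)
    n1 = len(x)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    Us = np.array([
        ranks[list(comb)].sum() - n1 * (n1 + 1) / 2
        for comb in itertools.combinations(range(len(allv)), n1)
    ])
    p_greater = np.mean(Us >= u_obs)
    p_less = np.mean(Us <= u_obs)
    if tail == "one":
        return min(p_greater, p_less)
    return min(1.0, 2 * min(p_greater, p_less))


@pytest.mark.parametrize("tail", ["one", "two"])
def test_exact_p_matches_enumeration(tail):
    """Exact p equals brute-force enumeration over all labelings."""
    rng = np.random.default_rng(4)
    for _ in range(20):
        n1 = int(rng.integers(2, 7))
        n2 = int(rng.integers(2, 13 - n1))
        pool = rng.permutation(np.arange(1.0, n1 + n2 + 1))
        x, y = pool[:n1], pool[n1:]
        res = bs.mann_whitney(x, y, tail=tail)
        assert res.p == pytest.approx(_brute_force_p(x, y, tail), abs=1e-12)


@given(
    x=st.lists(st.floats(-100, 100, allow_nan=False), min_size=2, max_size=10),
    y=st.lists(st.floats(-100, 100, allow_nan=False), min_size=2, max_size=10),
)
@settings(max_examples=50, deadline=None)
def test_swap_invariance_and_u_complement(x, y):
    """Effect size is symmetric in the samples and U + U' = n1*n2."""
    from hypothesis import assume

    assume(len(set(x) | set(y)) > 1)
    a = bs.mann_whitney(x, y, tail="two")
    b = bs.mann_whitney(y, x, tail="two")
    assert a.rank_biserial == pytest.approx(b.rank_biserial, abs=1e-12)
    assert a.U == pytest.approx(b.U)
    assert a.p == pytest.approx(b.p, abs=1e-12)


def test_empty_sample_rejected():
    with pytest.raises(ValueError):
        bs.mann_whitney([], [1, 2])


# ---------------------------------------------------------------------------
# Kruskal-Wallis and Bonferroni
# ---------------------------------------------------------------------------

def test_kruskal_identical_groups_give_zero():
    res = bs.kruskal_wallis([[1, 2, 3], [1, 2, 3], [1, 2, 3]])
    assert res.H == pytest.approx(0.0)
    assert res.df == 2


def test_kruskal_hand_ranked_oracle():
    """{1,2},{3,4},{5,6}: H = 12/(6*7) * (9/2 + 49/2 + 121/2) - 3*7 = 32/7."""
    res = bs.kruskal_wallis([[1, 2], [3, 4], [5, 6]])
    assert res.H == pytest.approx(32.0 / 7.0, abs=1e-10)
    assert res.df == 2


def test_kruskal_rejects_empty_group():
    with pytest.raises(ValueError):
        bs.kruskal_wallis([[1, 2], []])


@pytest.mark.parametrize(
    "alpha,n,expected", [(0.05, 3, 0.0167), (0.05, 1, 0.05), (0.01, 4, 0.0025)]
)
def test_bonferroni(alpha, n, expected):
    assert bs.bonferroni(alpha, n) == expected


def test_bonferroni_rejects_bad_input():
    with pytest.raises(ValueError):
        bs.bonferroni(0.05, 0)


# ---------------------------------------------------------------------------
# Photometry
# ---------------------------------------------------------------------------

def test_photon_intensity_oracle_values():
    """Direct evaluation of I = (P/A)/(hc/lambda) for the three
    photon-matched settings: all near 1.54e15 photons/cm^2/s."""
    assert bs.photon_intensity(650, 470) == pytest.approx(1.538e15, rel=1e-3)
    assert bs.photon_intensity(465, 660) == pytest.approx(1.545e15, rel=1e-3)


def test_photon_intensity_linearity_and_inverse():
    base = bs.photon_intensity(100, 500)
    assert bs.photon_intensity(200, 500) == pytest.approx(2 * base, rel=1e-12)
    # I * E / (P/A) == 1 to machine precision
    from scipy import constants
    E = constants.h * constants.c / 500e-9
    assert base * E / (100e-6) == pytest.approx(1.0, rel=1e-12)


@given(lam=st.floats(300, 800), power=st.floats(1, 10000))
@settings(max_examples=50, deadline=None)
def test_photon_intensity_monotone_in_wavelength(lam, power):
    assert bs.photon_intensity(power, lam * 1.01) > bs.photon_intensity(power, lam)


def test_photon_intensity_rejects_nonpositive():
    with pytest.raises(ValueError):
        bs.photon_intensity(0, 470)


# ---------------------------------------------------------------------------
# Confidence bands and normality
# ---------------------------------------------------------------------------

def test_ci_band_identical_traces_is_degenerate():
    depth = np.tile(np.linspace(1, 4, 100), (5, 1))
    mean, half = bs.mean_ci_band(_traj(depth))
    assert np.allclose(half, 0.0)
    np.testing.assert_allclose(mean, depth[0])


def test_ci_band_closed_form():
    """Depths 1..12 at a single time point: 95% half-width is
    t(0.975, 11) * sd / sqrt(12) = 2.291."""
    depth = np.arange(1.0, 13.0)[:, None]
    _, half = bs.mean_ci_band(_traj(depth), confidence=0.95)
    assert half[0] == pytest.approx(2.291, abs=0.005)


def test_ci_band_zero_confidence_collapses():
    depth = np.random.default_rng(0).random((4, 50))
    mean, half = bs.mean_ci_band(_traj(depth), confidence=0.0)
    assert np.allclose(half, 0.0)
    with pytest.raises(ValueError):
        bs.mean_ci_band(_traj(depth[:1]))


def test_shapiro_p_uniform_under_normality():
    """Under H0 the Shapiro-Wilk p-value is uniform: a KS test over seeded
    normal replicates must not reject uniformity."""
    rng = np.random.default_rng(7)
    ps = [bs.normality_check(rng.standard_normal(80))[1] for _ in range(300)]
    assert sps.kstest(ps, "uniform").pvalue > 0.01


def test_shapiro_detects_bimodality():
    rng = np.random.default_rng(8)
    rejected = 0
    for _ in range(100):
        sample = np.concatenate([rng.normal(-4, 1, 25), rng.normal(4, 1, 25)])
        rejected += bs.normality_check(sample)[1] < 0.05
    assert rejected >= 95


def test_shapiro_validation():
    with pytest.raises(ValueError):
        bs.normality_check([1.0, 2.0])
    with pytest.raises(ValueError):
        bs.normality_check(np.full(10, 3.0))
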