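"""Statistics for the vertical-migration assay.

Covers the full battery applied to depth trajectories: epoch-aligned
initial speeds and final positions, half-depth occurrence rates and
times, inter-individual Pearson correlation matrices, the Jennrich
chi-square test of correlation-matrix equality, Mann-Whitney U with
rank-biserial effect size, Kruskal-Wallis with Bonferroni-corrected
follow-ups, t-based confidence bands, Shapiro-Wilk normality checks and
photon-flux conversion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .schedule import StimulusSchedule, photon_intensity  # noqa: F401 (re-export)
from .trajectories import HALF_DEPTH_CM, TrajectorySet

ANALYSIS_WINDOW_S = 20.0


# ---------------------------------------------------------------------------
# Epoch-aligned kinematics
# ---------------------------------------------------------------------------

def epoch_metrics(traj: TrajectorySet, schedule: StimulusSchedule) -> pd.DataFrame:
    """Per fish x epoch kinematic metrics.

    For every epoch: the signed initial speed over the first 20 s (net
    displacement / 20 s, positive when moving in the epoch-congruent
    direction — up during light, down during darkness), the mean depth
    over the last 20 s, and whether/when the fish crossed the 2.5 cm
    half-depth mark in the congruent direction.

    Returns a DataFrame with columns ``fish, cycle, phase, channel,
    initial_speed_cm_s, final_position_cm, reached_half, time_to_half_s``
    (``time_to_half_s`` is NaN when the half mark was not reached;
    censoring at the epoch duration).
    """
    rate = traj.rate_hz
    n_win = int(round(ANALYSIS_WINDOW_S * rate))
    if abs(traj.duration_s - schedule.total_duration_s) > 1.0 / rate + 1e-9:
        raise ValueError(
            f"trajectory duration {traj.duration_s:.1f}s does not match "
            f"schedule {schedule.total_duration_s:.1f}s"
        )
    rows = []
    cycle = {"on": 0, "off": 0}
    for ep in schedule.epochs:
        if ep.duration_s < ANALYSIS_WINDOW_S:
            raise ValueError("epoch shorter than the 20 s analysis window")
        phase = "on" if ep.is_light else "off"
        cycle[phase] += 1
        i0 = int(round(ep.start_s * rate))
        i1 = min(int(round(ep.end_s * rate)), traj.n_samples)
        sign = -1.0 if ep.is_light else 1.0  # congruent: up in light, down in dark
        for f in range(traj.n_fish):
            d = traj.depth[f, i0:i1]
            speed = sign * (d[n_win] - d[0]) / ANALYSIS_WINDOW_S
            final = float(np.mean(d[-n_win:]))
            crossed = sign * (d - HALF_DEPTH_CM)
            # first sample strictly past the half mark after starting short of it
            hit = np.flatnonzero((crossed[1:] >= 0) & (crossed[:-1] < 0)) + 1
            reached = hit.size > 0
            rows.append(
                {
                    "fish": traj.ids[f],
                    "cycle": cycle[phase],
                    "phase": phase,
                    "channel": ep.channel,
                    "initial_speed_cm_s": float(speed),
                    "final_position_cm": final,
                    "reached_half": bool(reached),
                    "time_to_half_s": float(hit[0] / rate) if reached else np.nan,
                }
            )
    return pd.DataFrame(rows)


def occurrence_rate(metrics: pd.DataFrame, phase: str | None = None) -> tuple[int, int]:
    """(occurrences, total) of half-depth crossings, per direction.

    ``phase`` is ``"on"`` (climbs) or ``"off"`` (dives); None pools both.
    The total is n_fish x n_cycles for the selected direction.
    """
    if metrics.empty:
        raise ValueError("empty metrics")
    sub = metrics if phase is None else metrics[metrics["phase"] == phase]
    return int(sub["reached_half"].sum()), int(len(sub))


# ---------------------------------------------------------------------------
# Correlation matrices and the Jennrich test
# ---------------------------------------------------------------------------

@dataclass
class CorrelationMatrix:
    """p x p Pearson matrix over fish, with the sample size that built it."""

    R: np.ndarray
    n_samples: int
    label: str = ""

    def __post_init__(self) -> None:
        self.R = np.asarray(self.R, dtype=float)
        if self.R.ndim != 2 or self.R.shape[0] != self.R.shape[1]:
            raise ValueError("R must be square")

    @property
    def p(self) -> int:
        return self.R.shape[0]

    def offdiag_values(self) -> np.ndarray:
        """Upper-triangle coefficients — the sample used in group tests."""
        iu = np.triu_indices(self.p, k=1)
        vals = self.R[iu]
        return vals[~np.isnan(vals)]

    def to_csv(self, path, ids=None) -> None:
        ids = ids or [f"fish{i:02d}" for i in range(self.p)]
        pd.DataFrame(self.R, index=ids, columns=ids).to_csv(path)


def pairwise_correlation(trajset: TrajectorySet, label: str = "") -> CorrelationMatrix:
    """Pearson r of depth traces for every fish pair over the full recording."""
    if trajset.n_fish < 2:
        raise ValueError("need at least two fish")
    depth = trajset.depth
    sd = depth.std(axis=1)
    flat = np.flatnonzero(sd == 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        R = np.corrcoef(depth)
    if flat.size:
        warnings.warn(
            f"{flat.size} zero-variance trace(s); their pairs are undefined "
            "and excluded",
            stacklevel=2,
        )
        R[flat, :] = np.nan
        R[:, flat] = np.nan
    np.fill_diagonal(R, 1.0)
    return CorrelationMatrix(R=R, n_samples=trajset.n_samples, label=label)


@dataclass
class JennrichResult:
    chi2: float
    df: int
    p: float


def jennrich_test(
    R1: CorrelationMatrix | np.ndarray,
    n1: int,
    R2: CorrelationMatrix | np.ndarray,
    n2: int,
) -> JennrichResult:
    """Jennrich (1970) chi-square test of equality of two correlation matrices.

    With c = n1 n2 / (n1 + n2), pooled matrix R̄ = (n1 R1 + n2 R2)/(n1+n2)
    and Z = sqrt(c) R̄⁻¹ (R1 − R2):

        chi2 = tr(Z²)/2 − dg(Z)ᵀ S⁻¹ dg(Z),   S_ij = δ_ij + r̄_ij r̄^ij,

    where r̄^ij are the entries of R̄⁻¹.  df = p(p−1)/2.  The sample sizes
    are the number of observations (here: time samples) behind each
    matrix; temporal autocorrelation inflates the effective n, so a
    decimated sample count may be passed instead.
    """
    A = R1.R if isinstance(R1, CorrelationMatrix) else np.asarray(R1, dtype=float)
    B = R2.R if isinstance(R2, CorrelationMatrix) else np.asarray(R2, dtype=float)
    if A.shape != B.shape or A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("correlation matrices must be square and same shape")
    p = A.shape[0]
    if n1 <= p or n2 <= p:
        raise ValueError("sample sizes must exceed the matrix dimension")
    c = n1 * n2 / (n1 + n2)
    Rbar = (n1 * A + n2 * B) / (n1 + n2)
    try:
        Rinv = np.linalg.inv(Rbar)
    except np.linalg.LinAlgError as e:
        raise ValueError("pooled correlation matrix is singular") from e
    Z = np.sqrt(c) * Rinv @ (A - B)
    S = np.eye(p) + Rbar * Rinv
    dg = np.diag(Z)
    chi2 = 0.5 * np.trace(Z @ Z) - dg @ np.linalg.solve(S, dg)
    chi2 = float(max(chi2, 0.0))
    df = p * (p - 1) // 2
    return JennrichResult(chi2=chi2, df=df, p=float(stats.chi2.sf(chi2, df)))


# ---------------------------------------------------------------------------
# Rank tests
# ---------------------------------------------------------------------------

@dataclass
class MannWhitneyResult:
    U: float
    tail: str
    p: float
    rank_biserial: float
    n1: int
    n2: int


def rank_biserial(U: float, n1: int, n2: int) -> float:
    """Effect-size magnitude |1 − 2U/(n1 n2)| for a Mann-Whitney U."""
    if n1 < 1 or n2 < 1:
        raise ValueError("group sizes must be >= 1")
    return abs(1.0 - 2.0 * U / (n1 * n2))


def mann_whitney(x, y, tail: str = "two") -> MannWhitneyResult:
    """Mann-Whitney U test reporting U = min(U_x, U_y).

    Exact p by enumeration when n1 + n2 <= 20 with no ties; otherwise the
    tie-corrected normal approximation with continuity correction.  A
    one-tailed p is taken in the direction favored by the data.  The
    rank-biserial effect size is reported as a magnitude.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("empty sample")
    if tail not in ("one", "two"):
        raise ValueError("tail must be 'one' or 'two'")
    n1, n2 = x.size, y.size
    ties = np.unique(np.concatenate([x, y])).size < n1 + n2
    method = "exact" if (n1 + n2 <= 20 and not ties) else "asymptotic"
    res_g = stats.mannwhitneyu(x, y, alternative="greater", method=method)
    U_x = float(res_g.statistic)
    U_y = n1 * n2 - U_x
    if tail == "two":
        p = float(stats.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue)
    else:
        p_less = float(stats.mannwhitneyu(x, y, alternative="less", method=method).pvalue)
        p = min(float(res_g.pvalue), p_less)
    return MannWhitneyResult(
        U=min(U_x, U_y),
        tail=tail,
        p=p,
        rank_biserial=rank_biserial(min(U_x, U_y), n1, n2),
        n1=n1,
        n2=n2,
    )


@dataclass
class KruskalWallisResult:
    H: float
    df: int
    p: float


def kruskal_wallis(groups: list) -> KruskalWallisResult:
    """Tie-corrected Kruskal-Wallis H over >= 2 groups."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise ValueError("empty group")
    H, p = stats.kruskal(*arrays)
    return KruskalWallisResult(H=float(H), df=len(groups) - 1, p=float(p))


def bonferroni(alpha: float, n_hypotheses: int) -> float:
    """Per-hypothesis level alpha/n, reported at 4 decimals (0.05/3 -> 0.0167)."""
    if n_hypotheses < 1:
        raise ValueError("n_hypotheses must be >= 1")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    return round(alpha / n_hypotheses, 4)


# ---------------------------------------------------------------------------
# Bands and checks
# ---------------------------------------------------------------------------

def mean_ci_band(
    trajset: TrajectorySet, confidence: float = 0.95
) -> tuple[np.ndarray, np.ndarray]:
    """Across-fish mean depth and t-interval half-width at each time point."""
    if trajset.n_fish < 2:
        raise ValueError("confidence band needs at least two fish")
    n = trajset.n_fish
    mean = trajset.depth.mean(axis=0)
    if confidence <= 0:
        return mean, np.zeros_like(mean)
    tcrit = stats.t.ppf(1 - (1 - confidence) / 2, df=n - 1)
    half = tcrit * trajset.depth.std(axis=0, ddof=1) / np.sqrt(n)
    return mean, half


def normality_check(sample) -> tuple[float, float]:
    """Shapiro-Wilk W and p; rejects constant or out-of-range samples."""
    x = np.asarray(sample, dtype=float)
    if not 3 <= x.size <= 5000:
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    if np.ptp(x) == 0:
        raise ValueError("constant sample has no defined normality statistic")
    W, p = stats.shapiro(x)
    return float(W), float(p)
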