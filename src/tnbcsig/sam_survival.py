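"""Supervised prognostic discovery: moderated Cox score statistics with a
permutation null (the survival mode of Significance Analysis of Microarrays).

For probeset g with expression x and survival data (time, event), let t_k be
the distinct event times, D_k the deaths at t_k (d_k = |D_k|) and R_k the
risk set (Breslow tie handling).  The score statistic components are

    r = sum_k [ sum_{i in D_k} x_i  -  d_k * mean(x, R_k) ]
    s = sqrt( sum_k (d_k/|R_k|) * sum_{i in R_k} (x_i - mean(x, R_k))^2 )

and the moderated statistic is d = r / (s + s0), where the fudge factor s0
stabilizes scores of low-variance probesets.  For a binary tie-free covariate
r/s is exactly the log-rank Z statistic.

Significance calling compares the sorted observed d against the expected
order statistics dbar from B permutations of the (time, event) pairs; a band
half-width delta defines the called set, and the median number of permuted
scores beyond the cuts, scaled by the null-proportion estimate pi0, gives
the median false discovery rate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expression_io import ExpressionMatrix

logger = logging.getLogger(__name__)


@dataclass
class SurvivalVector:
    """Follow-up aligned to the sample order of an expression matrix."""

    time: np.ndarray
    event: np.ndarray

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        if self.time.shape != self.event.shape:
            raise ValueError("time and event must have equal length")
        if (self.time < 0).any():
            raise ValueError("negative survival times")
        if not np.isin(self.event, (0, 1)).all():
            raise ValueError("event indicators must be 0/1")
        if self.event.sum() < 1:
            raise ValueError("at least one event is required")

    def __len__(self) -> int:
        return len(self.time)


@dataclass
class Signature:
    """Ordered probesets with SAM-score weights and prognostic direction.

    POOR probesets carry positive weight (d > 0), GOOD negative; the risk
    score of a sample is the weighted sum of its expression values.
    """

    probeset_ids: list[str]
    weights: np.ndarray
    directions: list[str]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if not np.isfinite(self.weights).all():
            raise ValueError("signature weights must be finite")
        for w, direction in zip(self.weights, self.directions):
            if (direction == "POOR") != (w > 0):
                raise ValueError("direction inconsistent with weight sign")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "probeset_id": self.probeset_ids,
                "weight": self.weights,
                "direction": self.directions,
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, provenance: dict | None = None) -> "Signature":
        return cls(
            frame["probeset_id"].astype(str).tolist(),
            frame["weight"].to_numpy(dtype=float),
            frame["direction"].astype(str).tolist(),
            provenance or {},
        )

    def __len__(self) -> int:
        return len(self.probeset_ids)


@dataclass
class SamResult:
    """Observed scores, fudge factor, permutation null and pi0 estimate."""

    probeset_ids: list[str]
    r: np.ndarray
    s: np.ndarray
    d: np.ndarray
    s0: float
    null_order_stats: np.ndarray  # B x G, each row sorted ascending
    dbar: np.ndarray              # expected order statistics
    pi0: float

    def scores_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"r": self.r, "s": self.s, "d": self.d}, index=self.probeset_ids
        )

    def delta_table(self, deltas) -> pd.DataFrame:
        rows = []
        for delta in deltas:
            poor, good, fdr = select_by_delta(self, delta)
            rows.append(
                (delta, len(poor), len(good), np.nan if fdr is None else fdr)
            )
        return pd.DataFrame(rows, columns=["delta", "n_poor", "n_good", "median_FDR"])


# ---------------------------------------------------------------------------
# score computation
# ---------------------------------------------------------------------------

def cox_scores(X: np.ndarray, surv: SurvivalVector) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized (r, s) for every row of ``X`` (probesets x samples)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = X.shape[1]
    if n != len(surv):
        raise ValueError("expression and survival lengths differ")

    order = np.argsort(surv.time, kind="mergesort")
    t = surv.time[order]
    e = surv.event[order]
    # row-centring leaves r and the risk-set variances unchanged but avoids
    # catastrophic cancellation in the suffix sum-of-squares
    Xs = X[:, order] - X.mean(axis=1, keepdims=True)

    # suffix sums: risk set at time t_k is every sample with index >= start_k
    suff = np.cumsum(Xs[:, ::-1], axis=1)[:, ::-1]
    suff_sq = np.cumsum((Xs**2)[:, ::-1], axis=1)[:, ::-1]

    event_idx = np.flatnonzero(e == 1)
    event_times = t[event_idx]
    # first occurrence of each distinct event time in the sorted order
    distinct, first_pos = np.unique(event_times, return_index=True)
    starts = np.searchsorted(t, distinct, side="left")
    d_k = np.diff(np.append(first_pos, len(event_times)))  # deaths per time

    n_k = n - starts                       # risk-set sizes
    mean_k = suff[:, starts] / n_k         # G x K risk-set means
    ss_k = suff_sq[:, starts] - n_k * mean_k**2
    ss_k = np.maximum(ss_k, 0.0)           # guard tiny negative round-off

    # sum of x over deaths at each distinct time
    death_x = Xs[:, event_idx]
    bounds = np.append(first_pos, len(event_times))
    death_sums = np.add.reduceat(death_x, bounds[:-1], axis=1)

    r = (death_sums - d_k * mean_k).sum(axis=1)
    s = np.sqrt(((d_k / n_k) * ss_k).sum(axis=1))
    return r, s


def cox_score_stats(x: np.ndarray, surv: SurvivalVector) -> tuple[float, float]:
    """(r, s) for a single probeset's expression vector."""
    x = np.asarray(x, dtype=float)
    if not np.isfinite(x).all():
        raise ValueError("expression must be finite")
    r, s = cox_scores(x[None, :], surv)
    return float(r[0]), float(s[0])


def estimate_s0(
    r: np.ndarray,
    s: np.ndarray,
    override: float | None = None,
    n_bins: int = 100,
) -> float:
    """Fudge factor by the Tusher/Chu coefficient-of-variation criterion.

    Candidates are the percentiles {0, 5, ..., 100} of the s distribution;
    for each, d = r/(s+cand) is split into ``n_bins`` s-quantile bins and
    the candidate minimizing the coefficient of variation of the per-bin
    median absolute deviations is chosen.  ``override`` short-circuits the
    search (config-provided fixed value).
    """
    if override is not None:
        return float(override)
    r = np.asarray(r, dtype=float)
    s = np.asarray(s, dtype=float)
    if np.ptp(s) == 0:
        logger.info("estimate_s0: all s identical; returning that value")
        return float(s[0])

    percentiles = np.arange(0, 101, 5)
    candidates = np.percentile(s, percentiles)
    n_bins = min(n_bins, max(2, len(s) // 5))
    edges = np.quantile(s, np.linspace(0, 1, n_bins + 1))
    bin_idx = np.clip(np.searchsorted(edges, s, side="right") - 1, 0, n_bins - 1)

    best_cv, best_s0 = np.inf, candidates[0]
    for cand in candidates:
        d = r / (s + cand)
        mads = np.array(
            [
                _mad(d[bin_idx == b])
                for b in range(n_bins)
                if np.any(bin_idx == b)
            ]
        )
        mean = mads.mean()
        cv = np.inf if mean == 0 else mads.std(ddof=1) / mean
        if cv < best_cv - 1e-12:
            best_cv, best_s0 = cv, cand
    return float(best_s0)


def _mad(x: np.ndarray) -> float:
    return 1.4826 * float(np.median(np.abs(x - np.median(x))))


def permutation_null(
    m: ExpressionMatrix | np.ndarray,
    surv: SurvivalVector,
    s0: float,
    B: int = 100,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """B permutations of the (time, event) pairs against the expression columns.

    Each permutation recomputes d with the ORIGINAL s0 and sorts the vector;
    returns (null_order_stats: B x G, dbar = column means).
    """
    if B < 10:
        raise ValueError("B must be >= 10")
    if rng is None:
        if seed is None:
            raise ValueError("a seed (or rng) is required; no silent clock seeding")
        rng = np.random.default_rng(seed)
    X = m.values.to_numpy(dtype=float) if isinstance(m, ExpressionMatrix) else np.asarray(m, float)
    n = X.shape[1]
    null = np.empty((B, X.shape[0]))
    for b in range(B):
        perm = rng.permutation(n)
        surv_b = SurvivalVector(surv.time[perm], surv.event[perm])
        r_b, s_b = cox_scores(X, surv_b)
        null[b] = np.sort(r_b / (s_b + s0))
    return null, null.mean(axis=0)


def run_sam(
    m: ExpressionMatrix,
    surv: SurvivalVector,
    B: int = 100,
    seed: int | None = None,
    s0_override: float | None = None,
) -> SamResult:
    """Full observed-score + permutation-null computation."""
    X = m.values.to_numpy(dtype=float)
    r, s = cox_scores(X, surv)
    s0 = estimate_s0(r, s, override=s0_override)
    d = r / (s + s0)
    null, dbar = permutation_null(X, surv, s0, B=B, seed=seed)
    pi0 = estimate_pi0(d, null)
    return SamResult(m.probeset_ids, r, s, d, s0, null, dbar, pi0)


def estimate_pi0(d: np.ndarray, null_order_stats: np.ndarray) -> float:
    """pi0 = min(1, #{null d in (q25, q75) of observed d} / (0.5 * G * B))."""
    q25, q75 = np.quantile(d, [0.25, 0.75])
    B, G = null_order_stats.shape
    inside = np.count_nonzero((null_order_stats > q25) & (null_order_stats < q75))
    return min(1.0, inside / (0.5 * G * B))


# ---------------------------------------------------------------------------
# delta-band calling
# ---------------------------------------------------------------------------

def _sorted_observed(result: SamResult) -> tuple[np.ndarray, np.ndarray]:
    """Observed d sorted ascending, ties broken by probeset id."""
    order = np.lexsort((np.asarray(result.probeset_ids, dtype=object), result.d))
    return result.d[order], order


def select_by_delta(
    result: SamResult, delta: float
) -> tuple[set[str], set[str], float | None]:
    """SAM's monotone band rule at half-width ``delta``.

    Walking the sorted observed d against dbar from the middle outward, the
    first upper index with d_(i) - dbar_(i) >= delta sets the POOR cut; the
    symmetric lower walk sets the GOOD cut.  The median FDR is pi0 times the
    median over permutations of null scores beyond the cuts, divided by the
    number called (None when nothing is called), capped at 1.
    """
    if delta <= 0:
        raise ValueError("delta must be > 0")
    d_sorted, order = _sorted_observed(result)
    dbar = result.dbar
    G = len(d_sorted)
    ids = np.asarray(result.probeset_ids, dtype=object)[order]

    mid = int(np.searchsorted(dbar, 0.0, side="left"))

    cut_up = np.inf
    for i in range(mid, G):
        if d_sorted[i] - dbar[i] >= delta:
            cut_up = d_sorted[i]
            break
    cut_low = -np.inf
    for i in range(min(mid, G - 1), -1, -1):
        if d_sorted[i] - dbar[i] <= -delta:
            cut_low = d_sorted[i]
            break

    poor = set(ids[d_sorted >= cut_up]) if np.isfinite(cut_up) else set()
    good = set(ids[d_sorted <= cut_low]) if np.isfinite(cut_low) else set()

    n_called = len(poor) + len(good)
    if n_called == 0:
        return poor, good, None
    null = result.null_order_stats
    beyond = (null >= cut_up).sum(axis=1) + (null <= cut_low).sum(axis=1)
    fdr = min(1.0, result.pi0 * float(np.median(beyond)) / n_called)
    return poor, good, fdr


def build_signature(result: SamResult, delta: float) -> Signature:
    """Signature of all probesets called at ``delta``, weighted by d."""
    poor, good, fdr = select_by_delta(result, delta)
    called = poor | good
    if not called:
        raise ValueError(
            f"no probesets called at delta={delta}; try a smaller delta"
        )
    frame = result.scores_frame().loc[sorted(called)]
    frame = frame.sort_values("d", ascending=False, kind="mergesort")
    return Signature(
        probeset_ids=list(frame.index),
        weights=frame["d"].to_numpy(),
        directions=["POOR" if v > 0 else "GOOD" for v in frame["d"]],
        provenance={"delta": delta, "median_FDR": fdr, "s0": result.s0},
    )
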