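"""Cohort harmonization for pooled multi-dataset expression studies.

Four concerns live here:

* a per-dataset comparability metric C used to rank datasets by how close
  their per-gene means sit to the pooled means (in pooled-SD units);
* partition of datasets into finding/validation cohorts by that metric;
* triple-negative receptor calling from bimodal mRNA expression of ESR1,
  PGR and ERBB2 (two-component Gaussian mixtures with a density-crossing
  cutpoint);
* a per-probeset Kruskal-Wallis dataset-bias score with threshold filtering
  (preset cutoffs 75 and 150).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.mixture import GaussianMixture

from .expression_io import ExpressionMatrix

logger = logging.getLogger(__name__)

#: Named Kruskal-Wallis bias cutoffs used in the stability analyses.
BIAS_CUTOFF_PRESETS = {"strict": 75.0, "lenient": 150.0}


@dataclass
class ComparabilityReport:
    """Per-dataset comparability metric, sorted ascending (lower = better)."""

    table: pd.DataFrame  # columns: dataset_id, C, n_samples, rank
    n_probesets_used: int
    n_probesets_excluded: int


@dataclass
class ReceptorCalls:
    """Per-sample receptor statuses and the triple-negative flag."""

    table: pd.DataFrame  # index sample_id; esr1/pgr/erbb2 status + triple_negative
    cutpoints: dict[str, float]
    fallback_used: dict[str, bool]


def comparability_metric(m: ExpressionMatrix) -> ComparabilityReport:
    """Compute C_d = (1/G) * sum_g ((mu_gd - mu_g) / sigma_g)^2 per dataset.

    mu_g and sigma_g are the pooled mean/SD over all samples; probesets with
    zero pooled SD are excluded (logged).  Lower C means the dataset's gene
    means track the pooled cohort more closely.
    """
    labels = m.dataset_labels
    datasets = sorted(labels.unique())
    if len(datasets) < 2:
        raise ValueError("comparability metric needs >= 2 datasets")

    vals = m.values.to_numpy(dtype=float)
    mu = vals.mean(axis=1)
    sigma = vals.std(axis=1, ddof=1)
    keep = sigma > 0
    n_excluded = int((~keep).sum())
    if n_excluded:
        logger.info("comparability_metric: excluded %d zero-variance probesets", n_excluded)
    vals = vals[keep]
    mu = mu[keep]
    sigma = sigma[keep]
    G = vals.shape[0]
    if G == 0:
        raise ValueError("no probesets with positive variance")

    rows = []
    for d in datasets:
        mask = (labels == d).to_numpy()
        n_d = int(mask.sum())
        if n_d < 2:
            warnings.warn(f"dataset {d} has a single sample; mean still defined")
        mu_d = vals[:, mask].mean(axis=1)
        C = float(np.mean(((mu_d - mu) / sigma) ** 2))
        rows.append((d, C, n_d))

    table = pd.DataFrame(rows, columns=["dataset_id", "C", "n_samples"])
    table = table.sort_values(["C", "dataset_id"], kind="mergesort").reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    return ComparabilityReport(table, G, n_excluded)


def partition_by_comparability(
    report: ComparabilityReport,
    threshold: float | None = None,
    top_k: int | None = None,
) -> tuple[list[str], list[str]]:
    """Split datasets into (finding, validation) by exactly one rule.

    ``threshold``: finding = datasets with C <= threshold.
    ``top_k``: finding = the k datasets with lowest C (ties broken by
    lexicographic dataset_id, which the sorted report already encodes).
    """
    if (threshold is None) == (top_k is None):
        raise ValueError("specify exactly one of threshold / top_k")
    table = report.table
    if top_k is not None:
        if top_k > len(table):
            raise ValueError(f"top_k={top_k} exceeds {len(table)} datasets")
        finding = table["dataset_id"].iloc[:top_k].tolist()
    else:
        finding = table.loc[table["C"] <= threshold, "dataset_id"].tolist()
    validation = [d for d in table["dataset_id"] if d not in finding]
    if not validation:
        warnings.warn("validation set is empty: every dataset passed the rule")
    return finding, validation


def _density_crossing(gm: GaussianMixture) -> float:
    """Cutpoint where the two weighted component densities cross, searched
    on a fine grid between the component means."""
    means = gm.means_.ravel()
    order = np.argsort(means)
    lo, hi = means[order]
    if hi - lo < 1e-12:
        return float(lo)
    grid = np.linspace(lo, hi, 2001)
    resp = gm.predict_proba(grid.reshape(-1, 1))
    # responsibility of the lower-mean component drops below 0.5 at the crossing
    low_resp = resp[:, order[0]]
    idx = np.argmax(low_resp < 0.5)
    return float(grid[idx])


def call_receptor_status(
    m: ExpressionMatrix,
    probe_map: Mapping[str, Sequence[str]],
    fallback_cutpoints: Mapping[str, float] | None = None,
    random_state: int = 0,
) -> ReceptorCalls:
    """Call ESR1/PGR/ERBB2 status from bimodal mRNA expression.

    For each receptor gene the (mean, if several probesets) expression pooled
    over all samples is fitted with a two-component Gaussian mixture; the
    cutpoint is the density crossing between the components and samples below
    it are called negative.  If the fit is degenerate (component means closer
    than half the pooled SD) a configured fixed cutpoint is used instead,
    with a warning.  ``triple_negative`` is true iff all three are negative.
    """
    required = {"ESR1", "PGR", "ERBB2"}
    if not required <= set(probe_map):
        raise ValueError(f"probe_map must cover {sorted(required)}")
    fallback_cutpoints = dict(fallback_cutpoints or {})

    statuses = {}
    cutpoints: dict[str, float] = {}
    fallback_used: dict[str, bool] = {}
    for gene in ("ESR1", "PGR", "ERBB2"):
        probes = [p for p in probe_map[gene] if p in m.values.index]
        if not probes:
            raise ValueError(f"no probesets for {gene} present in matrix")
        expr = m.values.loc[probes].mean(axis=0).to_numpy(dtype=float)
        col = expr.reshape(-1, 1)
        gm = GaussianMixture(n_components=2, n_init=5, random_state=random_state)
        gm.fit(col)
        delta_means = abs(float(np.diff(gm.means_.ravel())[0]))
        pooled_sd = float(expr.std(ddof=1))
        # degenerate when components are indistinguishable or the two-
        # component model does not beat a single Gaussian (no bimodality)
        one = GaussianMixture(n_components=1, random_state=random_state).fit(col)
        degenerate = delta_means < 0.5 * pooled_sd or gm.bic(col) >= one.bic(col)
        if degenerate:
            cut = float(fallback_cutpoints.get(gene, np.median(expr)))
            warnings.warn(
                f"{gene}: mixture fit degenerate "
                f"(|dmean|={delta_means:.3g}, SD={pooled_sd:.3g}); "
                f"using fixed cutpoint {cut:.3g}"
            )
            fallback_used[gene] = True
        else:
            cut = _density_crossing(gm)
            fallback_used[gene] = False
        cutpoints[gene] = cut
        statuses[gene.lower() + "_status"] = np.where(expr < cut, "negative", "positive")

    table = pd.DataFrame(statuses, index=m.values.columns)
    table["triple_negative"] = (table == "negative").all(axis=1)
    return ReceptorCalls(table, cutpoints, fallback_used)


def kruskal_wallis_bias(m: ExpressionMatrix) -> pd.DataFrame:
    """Tie-corrected Kruskal-Wallis H of each probeset across dataset labels.

    A probeset constant across all samples gets H = 0 by convention.
    Returns a DataFrame indexed by probeset_id with column ``H``.
    """
    labels = m.dataset_labels.to_numpy()
    datasets = np.unique(labels)
    if len(datasets) < 2:
        raise ValueError("bias assessment needs >= 2 datasets")
    groups_masks = [labels == d for d in datasets]
    vals = m.values.to_numpy(dtype=float)
    H = np.empty(vals.shape[0])
    for i, row in enumerate(vals):
        if np.ptp(row) == 0:  # total tie: H = 0 by convention
            H[i] = 0.0
            continue
        groups = [row[mask] for mask in groups_masks]
        H[i] = stats.kruskal(*groups).statistic
    return pd.DataFrame({"H": H}, index=m.values.index)


def filter_probesets_by_bias(bias: pd.DataFrame, cutoff: float) -> set[str]:
    """Retain probesets with H strictly below ``cutoff``.

    ``cutoff`` may be a number or one of the preset names in
    :data:`BIAS_CUTOFF_PRESETS` ("strict" = 75, "lenient" = 150).
    """
    if isinstance(cutoff, str):
        cutoff = BIAS_CUTOFF_PRESETS[cutoff]
    if cutoff < 0:
        raise ValueError("cutoff must be >= 0")
    return set(bias.index[bias["H"] < cutoff])
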