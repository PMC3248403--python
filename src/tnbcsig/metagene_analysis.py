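"""Metagene scoring, probeset-to-metagene classification, and hierarchical
clustering of score vectors.

A metagene score is the arithmetic mean of its member probesets' expression
per sample.  Signature probesets are assigned to the metagene they correlate
with most strongly (largest |Pearson r|) when that correlation reaches a
cutoff (0.2 by default, 0.3 for the stringent variant), else "unclassified".
Score vectors (signatures, metagenes, external comparator scores) are
clustered by average linkage on correlation distance.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .expression_io import ExpressionMatrix

logger = logging.getLogger(__name__)

ASSIGNMENT_CUTOFFS = {"main": 0.2, "stringent": 0.3}


def metagene_score(
    m: ExpressionMatrix, mg: Mapping[str, Sequence[str]]
) -> pd.DataFrame:
    """Per-sample mean member expression for each metagene (metagene x sample).

    Members absent from the matrix are dropped (logged); a metagene with no
    present member is an error.
    """
    rows = {}
    for name, members in mg.items():
        present = [p for p in members if p in m.values.index]
        n_missing = len(members) - len(present)
        if not present:
            raise ValueError(f"metagene {name!r} has no probesets in the matrix")
        if n_missing:
            logger.info("metagene %s: dropped %d missing member(s)", name, n_missing)
        rows[name] = m.values.loc[present].mean(axis=0)
    return pd.DataFrame(rows).T


def assign_to_metagenes(
    m: ExpressionMatrix,
    probesets: Sequence[str],
    mg_scores: pd.DataFrame,
    cutoff: float = 0.2,
) -> pd.DataFrame:
    """Assign each probeset to its best-correlated metagene.

    Per probeset, Pearson correlations against every metagene score vector
    are computed; the probeset is assigned to the metagene with the largest
    |r| when |r| >= cutoff, else "unclassified".  Zero-variance probesets are
    unclassified with ``zero_variance`` flagged.  The full correlation vector
    is returned alongside the call (signed r is recorded; ranking uses |r|).
    """
    if not 0 < cutoff < 1:
        raise ValueError("cutoff must be in (0, 1)")
    sample_ids = mg_scores.columns
    X = m.values.loc[list(probesets), sample_ids].to_numpy(dtype=float)
    M = mg_scores.to_numpy(dtype=float)

    Xc = X - X.mean(axis=1, keepdims=True)
    Mc = M - M.mean(axis=1, keepdims=True)
    x_sd = np.sqrt((Xc**2).sum(axis=1))
    m_sd = np.sqrt((Mc**2).sum(axis=1))
    zero_var = x_sd == 0
    x_sd_safe = np.where(zero_var, 1.0, x_sd)
    corr = (Xc @ Mc.T) / np.outer(x_sd_safe, m_sd)
    corr[zero_var, :] = np.nan

    names = list(mg_scores.index)
    best_idx = np.nanargmax(np.where(zero_var[:, None], -np.inf, np.abs(corr)), axis=1)
    best_r = corr[np.arange(len(probesets)), best_idx]
    assigned = [
        "unclassified"
        if zero_var[i] or abs(best_r[i]) < cutoff
        else names[best_idx[i]]
        for i in range(len(probesets))
    ]
    out = pd.DataFrame(
        corr, index=list(probesets), columns=[f"r_{n}" for n in names]
    )
    out.insert(0, "best_metagene", assigned)
    out.insert(1, "best_r", best_r)
    out.insert(2, "zero_variance", zero_var)
    return out


def cluster_scores(
    score_matrix: pd.DataFrame, absolute: bool = True
) -> tuple[list[str], np.ndarray]:
    """Average-linkage clustering of named score vectors.

    Distance is 1 - |Pearson r| (``absolute=False`` uses 1 - r).  Rows are
    pre-sorted lexicographically by name so equal-distance merges resolve
    deterministically.  Returns (names in clustering order, scipy linkage
    matrix).
    """
    if score_matrix.shape[0] < 2:
        raise ValueError("need >= 2 score vectors")
    score_matrix = score_matrix.sort_index(kind="mergesort")
    vals = score_matrix.to_numpy(dtype=float)
    sds = vals.std(axis=1)
    if (sds == 0).any():
        bad = score_matrix.index[sds == 0].tolist()
        raise ValueError(f"zero-variance score vector(s): {bad}")
    corr = np.corrcoef(vals)
    dist = 1.0 - (np.abs(corr) if absolute else corr)
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2, 0.0, None)
    Z = linkage(squareform(dist, checks=False), method="average")
    return list(score_matrix.index), Z
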