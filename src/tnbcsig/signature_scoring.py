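"""Compound-covariate risk scores and quartile-based risk stratification.

The risk score of a sample is the sum of its expression values over the
signature probesets, each weighted by the probeset's SAM score.  Samples
above the cohort's 75th score percentile form the high-risk group (the
"highest quartile" cutoff); an externally supplied cutoff can be applied
instead for portability experiments.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from .expression_io import ExpressionMatrix
from .sam_survival import Signature

logger = logging.getLogger(__name__)

QUARTILE_LABELS = ("Q1", "Q2", "Q3", "Q4")


def compound_score(m: ExpressionMatrix, sig: Signature) -> pd.Series:
    """Per-sample weighted expression sum over the signature probesets.

    Signature probesets absent from the matrix are dropped with a warning;
    zero overlap is an error.
    """
    present = [p in m.values.index for p in sig.probeset_ids]
    n_missing = len(present) - sum(present)
    if sum(present) == 0:
        raise ValueError("no signature probesets present in the matrix")
    if n_missing:
        warnings.warn(f"{n_missing} signature probeset(s) missing from matrix; dropped")
        logger.info("compound_score: dropped %d missing probesets", n_missing)
    ids = [p for p, ok in zip(sig.probeset_ids, present) if ok]
    w = sig.weights[np.asarray(present)]
    scores = w @ m.values.loc[ids].to_numpy(dtype=float)
    return pd.Series(scores, index=m.values.columns, name="score")


def quartile_stratify(
    scores: pd.Series, external_cutoff: float | None = None
) -> pd.DataFrame:
    """Quartile labels and the high-risk flag for a score vector.

    Self mode (default) computes quartile boundaries within the given cohort
    and flags score > 75th percentile as high risk; external mode applies the
    supplied cutoff for the high-risk flag (quartile labels still computed
    within-cohort).  Ties at a boundary go to the LOWER group (strict >).
    """
    vals = scores.to_numpy(dtype=float)
    if np.ptp(vals) == 0:
        raise ValueError("all scores identical; no stratification possible")
    if external_cutoff is None and len(vals) < 8:
        raise ValueError("self mode needs n >= 8")

    q25, q50, q75 = np.quantile(vals, [0.25, 0.50, 0.75])
    labels = np.select(
        [vals <= q25, vals <= q50, vals <= q75],
        ["Q1", "Q2", "Q3"],
        default="Q4",
    )
    cutoff = q75 if external_cutoff is None else float(external_cutoff)
    high = vals > cutoff
    if external_cutoff is not None and not high.any():
        warnings.warn("external cutoff leaves zero high-risk samples")
    return pd.DataFrame(
        {"score": vals, "quartile": labels, "high_risk": high}, index=scores.index
    )
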