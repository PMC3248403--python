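"""ROC analysis of pathological-complete-response prediction.

AUC is computed by the Mann-Whitney formulation (ties count 1/2), with the
Hanley-McNeil normal-approximation confidence interval and a two-sided test
against AUC = 0.5.  The combined predictor is the parameter-free sum of
z-standardized scores: z(immune metagene) - z(risk signature) - the risk
signature predicts NON-response, so it enters negated for pCR prediction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass
class RocResult:
    auc: float
    ci_low: float
    ci_high: float
    p_value: float
    n_positive: int
    n_negative: int


def roc_auc(score: np.ndarray, label: np.ndarray) -> RocResult:
    """AUC of ``score`` for predicting binary ``label`` (1 = positive)."""
    score = np.asarray(score, dtype=float)
    label = np.asarray(label, dtype=int)
    if not np.isin(label, (0, 1)).all():
        raise ValueError("labels must be 0/1")
    pos = score[label == 1]
    neg = score[label == 0]
    n1, n0 = len(pos), len(neg)
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")

    # Mann-Whitney U via mid-ranks: ties count 1/2
    ranks = stats.rankdata(score)
    u = ranks[label == 1].sum() - n1 * (n1 + 1) / 2
    auc = float(u / (n1 * n0))

    q1 = auc / (2 - auc)
    q2 = 2 * auc**2 / (1 + auc)
    var = (auc * (1 - auc) + (n1 - 1) * (q1 - auc**2) + (n0 - 1) * (q2 - auc**2)) / (
        n1 * n0
    )
    se = float(np.sqrt(max(var, 0.0)))
    zcrit = stats.norm.ppf(0.975)
    ci_low = max(0.0, auc - zcrit * se)
    ci_high = min(1.0, auc + zcrit * se)
    if se == 0:
        p = 0.0 if auc != 0.5 else 1.0
    else:
        p = float(2 * stats.norm.sf(abs(auc - 0.5) / se))
    return RocResult(auc, ci_low, ci_high, p, n1, n0)


def combine_predictors(
    bcell_score: np.ndarray,
    sig_score: np.ndarray,
    weights: tuple[float, float] = (1.0, -1.0),
) -> np.ndarray:
    """Linear combination of z-standardized immune and risk scores.

    The default weights (+1, -1) add the standardized immune score and
    subtract the standardized risk score (high risk predicts non-response);
    alternative weights are exposed for sensitivity analysis.
    """
    b = np.asarray(bcell_score, dtype=float)
    s = np.asarray(sig_score, dtype=float)
    if b.shape != s.shape:
        raise ValueError("score vectors must be aligned")
    if b.std() == 0 or s.std() == 0:
        raise ValueError("zero variance in an input score")
    zb = (b - b.mean()) / b.std()
    zs = (s - s.mean()) / s.std()
    return weights[0] * zb + weights[1] * zs
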