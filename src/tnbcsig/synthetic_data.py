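"""Synthetic multi-dataset expression cohorts with known structure.

The generator emulates the statistical features a pooled microarray survival
study rests on, each with recorded ground truth:

* several datasets with dataset-specific additive batch shifts on a
  designated biased probeset subset (shift magnitude in SD units);
* latent co-expression factors ("metagenes") loading on member probesets;
* a prognostic co-expression program: the designated prognostic probesets
  share a latent factor, and the hazard is exponential with rate
  lambda0 * exp(sum_j beta_j * x_j) over those probesets.  In the default
  "factor" mode beta_j = log_hr / n_prognostic, i.e. log-HR ``log_hr`` per
  unit of the mean expression of the prognostic set;
* bimodal receptor-gene expression (two-component Gaussian mixtures) for
  ESR1/PGR/ERBB2 with stored component labels;
* logistic pCR outcomes driven by an immune factor, with the intercept
  solved so the marginal pCR rate matches a configured target.

Expression is generated directly on the normalized log2-like scale (unit
noise variance), so the pipeline's normalization steps are optional on
synthetic data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special

from .expression_io import ExpressionMatrix, SampleRecord


@dataclass
class FactorSpec:
    """One latent co-expression factor and the probesets it loads on."""

    name: str
    members: list[int]          # probeset indices < n_probesets
    loading: float = 1.0


@dataclass
class GeneratorConfig:
    """Study conditions for one synthetic cohort.

    Defaults are the package's standard end-to-end scenario: 5 datasets of 80
    samples, 2000 probesets, three biological factors of 30 probesets, 50
    batch-biased probesets shifted by 2 SD, a 50-probeset prognostic program
    with log-HR 0.8 per unit of its mean expression, ~45% events under
    uniform accrual censoring, a 27% marginal pCR rate driven by the immune
    factor, and bimodal receptor genes.
    """

    n_datasets: int = 5
    samples_per_dataset: int = 80
    n_probesets: int = 2000
    factors: list[FactorSpec] = field(
        default_factory=lambda: [
            FactorSpec("immune", list(range(0, 30))),
            FactorSpec("proliferation", list(range(30, 60))),
            FactorSpec("stroma", list(range(60, 90))),
        ]
    )
    prognostic_probesets: list[int] = field(default_factory=lambda: list(range(100, 150)))
    prognostic_loading: float = 1.0
    log_hr: float = 0.8
    prognostic_mode: str = "factor"  # "factor" | "independent"
    biased_probesets: list[int] = field(default_factory=lambda: list(range(200, 250)))
    batch_shift_sd: float = 2.0
    baseline_hazard: float = 0.0085      # events per month
    censor_min_months: float = 12.0
    censor_max_months: float = 120.0
    rfs_fraction_datasets: float = 0.6   # leading datasets use RFS, rest DMFS
    receptor_probesets: dict = field(
        default_factory=lambda: {"ESR1": 1990, "PGR": 1991, "ERBB2": 1992}
    )
    receptor_neg_props: dict = field(
        default_factory=lambda: {"ESR1": 0.30, "PGR": 0.40, "ERBB2": 0.85}
    )
    receptor_means: tuple[float, float] = (-1.5, 1.5)  # (negative, positive)
    receptor_sd: float = 0.6
    pcr_rate: float = 0.27
    pcr_coef: float = 0.8
    pcr_factor: str = "immune"
    seed: int = 17

    def validate(self) -> None:
        G = self.n_probesets
        listed = (
            [i for f in self.factors for i in f.members]
            + self.prognostic_probesets
            + self.biased_probesets
            + list(self.receptor_probesets.values())
        )
        if listed and (min(listed) < 0 or max(listed) >= G):
            raise ValueError("probeset indices must lie in [0, n_probesets)")
        for prop in self.receptor_neg_props.values():
            if not 0 <= prop <= 1:
                raise ValueError("mixture proportions must be in [0, 1]")
        if not 0 <= self.pcr_rate <= 1:
            raise ValueError("pcr_rate must be in [0, 1]")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline hazard must be > 0")
        if self.censor_max_months <= self.censor_min_months:
            raise ValueError("censoring window is empty")
        if self.prognostic_mode not in ("factor", "independent"):
            raise ValueError("prognostic_mode must be 'factor' or 'independent'")
        names = [f.name for f in self.factors]
        if len(set(names)) != len(names):
            raise ValueError("factor names must be unique")
        if self.prognostic_probesets and self.pcr_factor not in names + ["prognostic"]:
            if self.pcr_factor not in names:
                raise ValueError(f"unknown pcr_factor {self.pcr_factor!r}")


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    factor_scores: pd.DataFrame          # factor x sample latent values
    biased_probesets: list[str]
    prognostic_probesets: list[str]
    prognostic_betas: pd.Series          # per-probeset hazard coefficient
    linear_predictor: pd.Series          # per-sample true log relative hazard
    receptor_labels: pd.DataFrame        # per-sample true component (0=neg,1=pos)
    pcr_probability: pd.Series


def pcr_intercept_for_rate(rate: float, coef: float) -> float:
    """Intercept a with E[sigmoid(a + coef*F)] = rate for F ~ N(0, 1).

    Gauss-Hermite quadrature over the factor distribution; reduces to
    logit(rate) when coef = 0.
    """
    if coef == 0:
        return float(special.logit(rate))
    nodes, weights = np.polynomial.hermite_e.hermegauss(64)
    weights = weights / weights.sum()

    def marginal(a: float) -> float:
        return float(weights @ special.expit(a + coef * nodes)) - rate

    return float(optimize.brentq(marginal, -20, 20))


def _probeset_ids(G: int) -> list[str]:
    return [f"PS{i:05d}_at" for i in range(G)]


def _sample_ids(cfg: GeneratorConfig) -> tuple[list[str], list[str]]:
    samples, labels = [], []
    for d in range(cfg.n_datasets):
        for j in range(cfg.samples_per_dataset):
            samples.append(f"D{d:02d}_S{j:03d}")
            labels.append(f"D{d:02d}")
    return samples, labels


def generate_cohort(
    cfg: GeneratorConfig | None = None, seed: int | None = None
) -> tuple[ExpressionMatrix, list[SampleRecord], GroundTruth]:
    """Generate one cohort; bit-reproducible from the seed.

    ``seed`` overrides ``cfg.seed`` when given.
    """
    cfg = cfg or GeneratorConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)

    G = cfg.n_probesets
    n = cfg.n_datasets * cfg.samples_per_dataset
    probe_ids = _probeset_ids(G)
    sample_ids, labels = _sample_ids(cfg)
    dataset_of = np.repeat(np.arange(cfg.n_datasets), cfg.samples_per_dataset)

    X = rng.standard_normal((G, n))

    # latent biological factors
    factor_rows = {}
    for f in cfg.factors:
        F = rng.standard_normal(n)
        X[f.members] += f.loading * F
        factor_rows[f.name] = F

    # prognostic co-expression program
    betas = np.zeros(G)
    if cfg.prognostic_probesets:
        Fp = rng.standard_normal(n)
        X[cfg.prognostic_probesets] += cfg.prognostic_loading * Fp
        factor_rows["prognostic"] = Fp
        if cfg.prognostic_mode == "factor":
            betas[cfg.prognostic_probesets] = cfg.log_hr / len(cfg.prognostic_probesets)
        else:
            betas[cfg.prognostic_probesets] = cfg.log_hr

    # dataset batch shifts on the biased subset: per-probeset random
    # permutation (and sign) of a centred pattern with population SD exactly
    # equal to the configured shift magnitude
    if cfg.biased_probesets and cfg.n_datasets > 1:
        base = np.arange(cfg.n_datasets, dtype=float)
        base = (base - base.mean()) / base.std()
        for g in cfg.biased_probesets:
            pattern = cfg.batch_shift_sd * rng.choice([-1.0, 1.0]) * rng.permutation(base)
            X[g] += pattern[dataset_of]

    # receptor genes: overwrite with two-component mixtures
    mu_neg, mu_pos = cfg.receptor_means
    receptor_labels = {}
    for gene, idx in cfg.receptor_probesets.items():
        comp = (rng.random(n) >= cfg.receptor_neg_props[gene]).astype(int)  # 1 = positive
        X[idx] = np.where(comp == 1, mu_pos, mu_neg) + cfg.receptor_sd * rng.standard_normal(n)
        receptor_labels[gene] = comp
        betas[idx] = 0.0

    # survival: exponential PH model on the prognostic linear predictor
    lp = betas @ X
    rate = cfg.baseline_hazard * np.exp(lp)
    T = rng.exponential(1.0 / rate)
    C = rng.uniform(cfg.censor_min_months, cfg.censor_max_months, size=n)
    time = np.minimum(T, C)
    event = (T <= C).astype(int)
    # avoid zero-time events (invariant: event implies time > 0)
    time = np.maximum(time, 1e-3)

    n_rfs_datasets = int(round(cfg.rfs_fraction_datasets * cfg.n_datasets))
    endpoint_of_dataset = [
        "RFS" if d < n_rfs_datasets else "DMFS" for d in range(cfg.n_datasets)
    ]

    # pCR from a logistic model on the designated immune factor
    if cfg.pcr_factor in factor_rows:
        F_immune = factor_rows[cfg.pcr_factor]
    else:
        F_immune = np.zeros(n)
    intercept = pcr_intercept_for_rate(cfg.pcr_rate, cfg.pcr_coef)
    p_pcr = special.expit(intercept + cfg.pcr_coef * F_immune)
    pcr = (rng.random(n) < p_pcr).astype(int)

    # clinical covariate classes (marginals typical of a TN cohort,
    # independent of outcome by construction)
    age = np.where(rng.random(n) < 0.5, ">50", "<=50")
    size = np.where(rng.random(n) < 0.6, ">2cm", "<=2cm")
    node = np.where(rng.random(n) < 0.3, "LNP", "LNN")
    grade = np.where(rng.random(n) < 0.74, "G3", "G1&2")

    records = [
        SampleRecord(
            sample_id=sample_ids[i],
            dataset_id=labels[i],
            endpoint_type=endpoint_of_dataset[dataset_of[i]],
            time=float(time[i]),
            event=int(event[i]),
            age_class=str(age[i]),
            size_class=str(size[i]),
            node_class=str(node[i]),
            grade_class=str(grade[i]),
            pcr=int(pcr[i]),
        )
        for i in range(n)
    ]

    matrix = ExpressionMatrix(
        pd.DataFrame(X, index=probe_ids, columns=sample_ids),
        pd.Series(labels, index=sample_ids),
    )
    truth = GroundTruth(
        factor_scores=pd.DataFrame(factor_rows, index=sample_ids).T,
        biased_probesets=[probe_ids[i] for i in cfg.biased_probesets],
        prognostic_probesets=[probe_ids[i] for i in cfg.prognostic_probesets],
        prognostic_betas=pd.Series(betas, index=probe_ids),
        linear_predictor=pd.Series(lp, index=sample_ids),
        receptor_labels=pd.DataFrame(receptor_labels, index=sample_ids),
        pcr_probability=pd.Series(p_pcr, index=sample_ids),
    )
    return matrix, records, truth


def true_dichotomized_hr(
    cfg: GeneratorConfig, n_samples: int = 20000, seed: int = 0
) -> float:
    """Large-sample Cox HR of the top-quartile indicator of the TRUE risk score.

    This is the generator's ground-truth value that a dichotomized compound
    score should recover; computed by simulating one large cohort and fitting
    the oracle indicator.
    """
    from .survival_stats import EfsRecord, cox_fit

    big = replace(
        cfg,
        samples_per_dataset=int(np.ceil(n_samples / cfg.n_datasets)),
        seed=seed,
    )
    _, records, truth = generate_cohort(big)
    lp = truth.linear_predictor
    high = (lp > lp.quantile(0.75)).astype(float)
    efs = [
        EfsRecord(r.sample_id, min(r.time, 120.0), r.event if r.time <= 120 else 0, r.endpoint_type)
        for r in records
    ]
    cov = pd.DataFrame({"high_risk": high})
    return float(cox_fit(efs, cov).hazard_ratio("high_risk"))


# ---------------------------------------------------------------------------
# recovery reporting
# ---------------------------------------------------------------------------

def _sens_spec(truth_set: set, called_set: set, universe: set) -> tuple[float | None, float]:
    tp = len(truth_set & called_set)
    fp = len(called_set - truth_set)
    fn = len(truth_set - called_set)
    tn = len(universe - truth_set - called_set)
    sens = None if not truth_set else tp / (tp + fn)
    spec = 1.0 if (tn + fp) == 0 else tn / (tn + fp)
    return sens, spec


def recovery_report(
    truth: GroundTruth,
    all_probesets: Sequence[str],
    sam_called: set[str] | None = None,
    kw_removed: set[str] | None = None,
    receptor_calls: pd.DataFrame | None = None,
    estimated_hr: float | None = None,
    true_hr: float | None = None,
    combined_auc: float | None = None,
    oracle_auc: float | None = None,
) -> dict:
    """Sensitivity/specificity/bias summary per pipeline stage.

    Every section is optional; supplied outputs must share ids with the
    ground truth.  A sensitivity whose truth set is empty is reported as
    None (undefined), not 0.
    """
    universe = set(all_probesets)
    report: dict = {}

    if sam_called is not None:
        if not sam_called <= universe:
            raise ValueError("SAM calls contain unknown probeset ids")
        sens, spec = _sens_spec(set(truth.prognostic_probesets), sam_called, universe)
        report["prognostic"] = {
            "sensitivity": sens,
            "specificity": spec,
            "n_called": len(sam_called),
        }

    if kw_removed is not None:
        if not kw_removed <= universe:
            raise ValueError("bias-filter output contains unknown probeset ids")
        sens, spec = _sens_spec(set(truth.biased_probesets), kw_removed, universe)
        report["bias_filter"] = {"sensitivity": sens, "specificity": spec}

    if receptor_calls is not None:
        acc = {}
        for gene in truth.receptor_labels.columns:
            col = gene.lower() + "_status"
            if col not in receptor_calls.columns:
                raise ValueError(f"receptor calls lack column {col}")
            called_pos = (receptor_calls[col] == "positive").astype(int)
            truth_pos = truth.receptor_labels[gene].reindex(called_pos.index)
            if truth_pos.isna().any():
                raise ValueError("receptor calls and truth have mismatched samples")
            acc[gene] = float((called_pos == truth_pos).mean())
        report["receptor_accuracy"] = acc

    if estimated_hr is not None:
        report["hazard_ratio"] = {
            "estimated": estimated_hr,
            "true": true_hr,
            "log_bias": None
            if true_hr is None
            else float(np.log(estimated_hr) - np.log(true_hr)),
        }

    if combined_auc is not None:
        report["response_auc"] = {"combined": combined_auc, "oracle": oracle_auc}

    return report
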