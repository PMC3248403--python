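import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from tnbcsig.cohort_assembly import (
    call_receptor_status,
    comparability_metric,
    filter_probesets_by_bias,
    kruskal_wallis_bias,
    partition_by_comparability,
)
from tnbcsig.synthetic_data import GeneratorConfig, generate_cohort

from conftest import make_matrix


def brute_force_C(values, labels):
    """Direct per-gene loop over the comparability formula."""
    mu = values.mean(axis=1)
    sigma = values.std(axis=1, ddof=1)
    out = {}
    for d in sorted(set(labels)):
        cols = [j for j, l in enumerate(labels) if l == d]
        acc = 0.0
        for g in range(values.shape[0]):
            mu_gd = values[g, cols].mean()
            acc += ((mu_gd - mu[g]) / sigma[g]) ** 2
        out[d] = acc / values.shape[0]
    return out


class TestComparabilityMetric:
    def test_matches_brute_force_on_toy(self):
        vals = np.array(
            [[1.0, 2.0, 3.0, 7.0], [4.0, 0.0, 2.0, 2.0], [1.0, 1.0, 5.0, 3.0]]
        )
        labels = ["A", "A", "B", "B"]
        m = make_matrix(vals, labels)
        report = comparability_metric(m)
        expected = brute_force_C(vals, labels)
        for _, row in report.table.iterrows():
            assert row["C"] == pytest.approx(expected[row["dataset_id"]], rel=1e-12)

    def test_equal_means_give_zero(self):
        # both dataset means equal the global mean for every gene
        vals = np.array([[1.0, 3.0, 1.0, 3.0], [5.0, 2.0, 5.0, 2.0]])
        m = make_matrix(vals, ["A", "A", "B", "B"])
        report = comparability_metric(m)
        assert np.allclose(report.table["C"], 0.0)

    def test_invariant_to_gene_permutation_and_global_affine(self):
        rng = np.random.default_rng(5)
        vals = rng.normal(size=(20, 12))
        labels = ["A"] * 4 + ["B"] * 4 + ["C"] * 4
        base = comparability_metric(make_matrix(vals, labels)).table
        perm = comparability_metric(
            make_matrix(vals[rng.permutation(20)], labels)
        ).table
        affine = comparability_metric(make_matrix(2.5 * vals - 7.0, labels)).table
        pd.testing.assert_frame_equal(base, perm)
        pd.testing.assert_frame_equal(base, affine)

    def test_single_dataset_errors(self):
        m = make_matrix(np.random.default_rng(0).normal(size=(5, 4)), ["A"] * 4)
        with pytest.raises(ValueError, match="2 datasets"):
            comparability_metric(m)


class TestPartition:
    @staticmethod
    def report_from(c_values):
        table = pd.DataFrame(
            {
                "dataset_id": list(c_values),
                "C": list(c_values.values()),
                "n_samples": 10,
            }
        ).sort_values(["C", "dataset_id"]).reset_index(drop=True)
        table["rank"] = np.arange(1, len(table) + 1)
        from tnbcsig.cohort_assembly import ComparabilityReport

        return ComparabilityReport(table, 100, 0)

    def test_partition_is_exhaustive_and_disjoint(self):
        report = self.report_from({"a": 0.01, "b": 0.05, "c": 0.02})
        finding, validation = partition_by_comparability(report, top_k=2)
        assert finding == ["a", "c"]
        assert validation == ["b"]
        assert set(finding) | set(validation) == {"a", "b", "c"}
        assert set(finding) & set(validation) == set()

    def test_threshold_rule_and_empty_validation_warns(self):
        report = self.report_from({"a": 0.01, "b": 0.02})
        with pytest.warns(UserWarning, match="empty"):
            finding, validation = partition_by_comparability(report, threshold=0.5)
        assert finding == ["a", "b"] and validation == []

    def test_tie_broken_lexicographically(self):
        report = self.report_from({"zed": 0.02, "abe": 0.02, "mid": 0.01})
        finding, _ = partition_by_comparability(report, top_k=2)
        assert finding == ["mid", "abe"]

    def test_top_k_exceeding_datasets_errors(self):
        report = self.report_from({"a": 0.01})
        with pytest.raises(ValueError):
            partition_by_comparability(report, top_k=5)

    def test_exactly_one_rule_required(self):
        report = self.report_from({"a": 0.01, "b": 0.02})
        with pytest.raises(ValueError):
            partition_by_comparability(report, top_k=1, threshold=0.5)


class TestReceptorCalling:
    def test_bimodal_genes_recover_generating_components(self, default_cohort):
        matrix, _, truth = default_cohort
        cfg = GeneratorConfig()
        probe_map = {
            g: [matrix.probeset_ids[i]] for g, i in cfg.receptor_probesets.items()
        }
        calls = call_receptor_status(matrix, probe_map)
        for gene in ("ESR1", "PGR", "ERBB2"):
            called_pos = (calls.table[gene.lower() + "_status"] == "positive").astype(int)
            acc = (called_pos.to_numpy() == truth.receptor_labels[gene].to_numpy()).mean()
            assert acc >= 0.99
        # triple negative consistency with its definition
        tn = (calls.table[["esr1_status", "pgr_status", "erbb2_status"]] == "negative").all(axis=1)
        assert (calls.table["triple_negative"] == tn).all()

    def test_positive_esr1_vetoes_triple_negative(self):
        rng = np.random.default_rng(2)
        n = 200
        esr1 = np.concatenate([rng.normal(-2, 0.4, n // 2), rng.normal(2, 0.4, n // 2)])
        low = rng.normal(-2, 0.4, n)  # all negative
        m = make_matrix(np.vstack([esr1, low, low]), ["A"] * (n // 2) + ["B"] * (n - n // 2))
        calls = call_receptor_status(
            m, {"ESR1": ["p0"], "PGR": ["p1"], "ERBB2": ["p2"]},
            fallback_cutpoints={"PGR": 0.0, "ERBB2": 0.0},
        )
        pos = calls.table["esr1_status"] == "positive"
        assert pos.any()
        assert not calls.table.loc[pos, "triple_negative"].any()

    def test_unimodal_gene_falls_back_with_warning(self):
        rng = np.random.default_rng(3)
        uni = rng.normal(0, 1, 300)  # no bimodality: mixture fit degenerate
        bim = np.concatenate([rng.normal(-2, 0.3, 150), rng.normal(2, 0.3, 150)])
        m = make_matrix(np.vstack([uni, bim, bim]), ["A"] * 300)
        with pytest.warns(UserWarning, match="ESR1"):
            calls = call_receptor_status(
                m,
                {"ESR1": ["p0"], "PGR": ["p1"], "ERBB2": ["p2"]},
                fallback_cutpoints={"ESR1": 0.0},
            )
        assert calls.fallback_used["ESR1"]
        assert calls.cutpoints["ESR1"] == 0.0


def hand_kruskal_wallis(groups):
    """Textbook tie-corrected rank-sum formula."""
    pooled = np.concatenate(groups)
    ranks = stats.rankdata(pooled)
    N = len(pooled)
    offsets = np.cumsum([0] + [len(g) for g in groups[:-1]])
    H = 0.0
    for off, g in zip(offsets, groups):
        rbar = ranks[off : off + len(g)].mean()
        H += len(g) * (rbar - (N + 1) / 2) ** 2
    H *= 12 / (N * (N + 1))
    _, counts = np.unique(pooled, return_counts=True)
    tie = 1 - ((counts**3 - counts).sum() / (N**3 - N))
    return H / tie


class TestKruskalWallisBias:
    def test_constant_probeset_has_zero_H(self):
        m = make_matrix([[3.0] * 6, [1, 2, 3, 4, 5, 6]], ["A"] * 3 + ["B"] * 3)
        table = kruskal_wallis_bias(m)
        assert table.loc["p0", "H"] == 0.0

    def test_matches_hand_rank_formula(self):
        g1 = np.array([1.2, 3.4, 2.2])
        g2 = np.array([5.5, 4.4, 3.4])  # one cross-group tie
        m = make_matrix([np.concatenate([g1, g2])], ["A"] * 3 + ["B"] * 3)
        table = kruskal_wallis_bias(m)
        assert table.loc["p0", "H"] == pytest.approx(hand_kruskal_wallis([g1, g2]), abs=1e-12)

    def test_fully_segregated_shift_approaches_maximum(self):
        rng = np.random.default_rng(7)
        base = rng.normal(size=40)
        shifted = np.concatenate([base[:20], base[20:] + 10])
        m = make_matrix([shifted], ["A"] * 20 + ["B"] * 20)
        H = kruskal_wallis_bias(m).loc["p0", "H"]
        # maximum H for two groups of 20 with fully segregated ranks
        hmax = hand_kruskal_wallis([np.arange(20.0), np.arange(20.0) + 20])
        assert H == pytest.approx(hmax, rel=0.01)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        row = rng.normal(size=12)
        labels = ["A"] * 4 + ["B"] * 4 + ["C"] * 4
        h1 = kruskal_wallis_bias(make_matrix([row], labels)).iloc[0, 0]
        h2 = kruskal_wallis_bias(make_matrix([np.exp(row)], labels)).iloc[0, 0]
        assert h1 == pytest.approx(h2, abs=1e-10)


class TestBiasFilter:
    def test_infinite_cutoff_keeps_all_and_zero_keeps_none(self):
        table = pd.DataFrame({"H": [0.0, 10.0, 200.0]}, index=["a", "b", "c"])
        assert filter_probesets_by_bias(table, np.inf) == {"a", "b", "c"}
        assert filter_probesets_by_bias(table, 0.0) == set()

    def test_planted_batch_bias_detected_at_presets(self, default_cohort):
        matrix, _, truth = default_cohort
        table = kruskal_wallis_bias(matrix)
        planted = set(truth.biased_probesets)
        universe = set(matrix.probeset_ids)
        for cutoff in (75.0, 150.0):
            removed = universe - filter_probesets_by_bias(table, cutoff)
            tp = len(removed & planted)
            fp = len(removed - planted)
            sens = tp / len(planted)
            spec = 1 - fp / (len(universe) - len(planted))
            assert sens >= 0.95, f"sensitivity {sens} at cutoff {cutoff}"
            assert spec >= 0.95, f"specificity {spec} at cutoff {cutoff}"
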