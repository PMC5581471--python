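import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from fflnet.exprfilter import (
    EdgeRule,
    ThresholdPolicy,
    bh_adjust,
    critical_r,
    extract_significant_ffls,
    one_tailed_p,
    pearson_r,
    results_to_frame,
    significant_pairs,
)
from fflnet.ffl import FFL, FFLCategory
from fflnet.io import EdgeType, ExpressionMatrix, RegulatoryEdge


def bh_brute_force(p):
    """Independent step-up BH: q_(i) = min_{j>=i} min(1, m p_(j) / j)."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q_sorted = np.minimum(1.0, p[order] * m / np.arange(1, m + 1))
    for i in range(m - 2, -1, -1):
        q_sorted[i] = min(q_sorted[i], q_sorted[i + 1])
    out = np.empty(m)
    out[order] = q_sorted
    return out


class TestPearson:
    def test_identical_vectors_give_one(self):
        r, n, reason = pearson_r(np.array([1.0, 2, 3, 4]), np.array([1.0, 2, 3, 4]))
        assert r == pytest.approx(1.0)
        assert n == 4 and reason is None

    def test_hand_computed_example(self):
        # cov = 3, var_x = 2, var_y = 42/9 -> r = 3 / sqrt(2 * 42/9)
        r, n, _ = pearson_r(np.array([1.0, 2, 3]), np.array([1.0, 2, 4]))
        assert r == pytest.approx(3 / np.sqrt(2 * 42 / 9), abs=1e-12)
        assert round(r, 4) == 0.9820

    def test_constant_vector_flagged(self):
        r, n, reason = pearson_r(np.array([1.0, 1, 1]), np.array([1.0, 2, 3]))
        assert np.isnan(r) and reason == "zero variance"

    def test_missing_values_dropped_pairwise(self):
        x = np.array([1.0, 2, np.nan, 4, 5])
        y = np.array([2.0, 4, 6, np.nan, 10])
        r, n, reason = pearson_r(x, y)
        assert n == 3 and r == pytest.approx(1.0)

    def test_too_few_samples_flagged(self):
        r, n, reason = pearson_r(np.array([1.0, 2]), np.array([2.0, 1]))
        assert reason == "n<3"

    def test_agrees_with_scipy_on_random_vectors(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            x, y = rng.standard_normal((2, 50))
            r, n, _ = pearson_r(x, y)
            assert r == pytest.approx(stats.pearsonr(x, y).statistic, abs=1e-12)


class TestOneTailedP:
    def test_zero_correlation_gives_half(self):
        assert one_tailed_p(0.0, 100, "observed-sign") == pytest.approx(0.5)
        assert one_tailed_p(0.0, 100, "negative") == pytest.approx(0.5)

    def test_published_thresholds_sit_at_p_001(self):
        # |r| = 0.1432 at the mRNA sample size n = 264 and r = -0.1492 at
        # the miRNA-overlap size n = 243 are both right at p = 0.010
        assert one_tailed_p(0.1432, 264, "observed-sign") == pytest.approx(0.010, abs=5e-4)
        assert one_tailed_p(-0.1492, 243, "negative") == pytest.approx(0.010, abs=5e-4)

    def test_agrees_with_scipy_one_tailed(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            x, y = rng.standard_normal((2, 40))
            r = stats.pearsonr(x, y).statistic
            assert one_tailed_p(r, 40, "negative") == pytest.approx(
                stats.pearsonr(x, y, alternative="less").pvalue, rel=1e-9
            )

    def test_decreasing_in_magnitude_and_n(self):
        ps = [one_tailed_p(r, 50, "observed-sign") for r in (0.1, 0.2, 0.4, 0.8)]
        assert ps == sorted(ps, reverse=True)
        pn = [one_tailed_p(0.3, n, "observed-sign") for n in (10, 50, 200)]
        assert pn == sorted(pn, reverse=True)

    def test_perfect_correlation_underflows_not_zero(self):
        p = one_tailed_p(-1.0, 10, "negative")
        assert 0 < p < 1e-300

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            one_tailed_p(0.5, 2, "negative")


class TestCriticalR:
    def test_reproduces_published_cutoffs(self):
        assert round(critical_r(264), 2) == 0.14
        assert round(critical_r(243), 2) == 0.15

    def test_is_the_boundary_of_significance(self):
        for n in (50, 243, 264, 500):
            rc = critical_r(n)
            assert one_tailed_p(rc, n, "observed-sign") == pytest.approx(0.01, rel=1e-6)
            assert one_tailed_p(rc * 1.01, n, "observed-sign") < 0.01
            assert one_tailed_p(rc * 0.99, n, "observed-sign") > 0.01


class TestBH:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.03]) == pytest.approx([0.03])

    def test_hand_computed_ladder(self):
        assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_all_equal_stay_equal(self):
        assert bh_adjust([0.2, 0.2, 0.2, 0.2]) == pytest.approx([0.2] * 4)

    def test_empty_and_invalid(self):
        assert bh_adjust([]).size == 0
        with pytest.raises(ValueError):
            bh_adjust([0.0, 0.5])

    @given(st.lists(st.floats(1e-12, 1.0), min_size=1, max_size=200))
    def test_matches_brute_force_step_up(self, pvals):
        assert bh_adjust(pvals) == pytest.approx(bh_brute_force(pvals), abs=1e-12)


def _matrices(n=60, r=-0.9, seed=0):
    """Tiny study: hsa-miR-1 ~ G1 at correlation ~r, G2/T1 independent."""
    rng = np.random.default_rng(seed)
    samples = [f"S{i}" for i in range(n)]
    f = rng.standard_normal(n)
    b = np.sqrt(abs(r))
    mir = b * np.sign(r) * f + np.sqrt(1 - b * b) * rng.standard_normal(n)
    g1 = b * f + np.sqrt(1 - b * b) * rng.standard_normal(n)
    mrna = ExpressionMatrix(
        pd.DataFrame(
            np.vstack([g1, rng.standard_normal((2, n))]),
            index=["G1", "G2", "T1"],
            columns=samples,
        ),
        assay="MRNA",
    )
    mirna = ExpressionMatrix(
        pd.DataFrame([mir], index=["hsa-miR-1"], columns=samples), assay="MIRNA"
    )
    return mrna, mirna


class TestSignificantPairs:
    def test_planted_negative_edge_significant_decoy_not(self):
        mrna, mirna = _matrices()
        planted = RegulatoryEdge("hsa-miR-1", "G1", EdgeType.MIRNA_GENE)
        decoy = RegulatoryEdge("hsa-miR-1", "G2", EdgeType.MIRNA_GENE)
        results = {r.edge.key: r for r in significant_pairs([planted, decoy], mrna, mirna)}
        assert results[planted.key].significant
        assert results[planted.key].r < -0.5
        assert not results[decoy.key].significant

    def test_unmeasured_endpoint_reported_not_significant(self):
        mrna, mirna = _matrices()
        edge = RegulatoryEdge("hsa-miR-99", "G1", EdgeType.MIRNA_GENE)
        ok = RegulatoryEdge("hsa-miR-1", "G1", EdgeType.MIRNA_GENE)
        res = significant_pairs([edge, ok], mrna, mirna)
        by_key = {r.edge.key: r for r in res}
        assert by_key[edge.key].reason == "unmeasured"
        assert not by_key[edge.key].significant

    def test_all_unmeasured_is_error(self):
        mrna, mirna = _matrices()
        edge = RegulatoryEdge("hsa-miR-99", "GX", EdgeType.MIRNA_GENE)
        with pytest.raises(ValueError, match="no candidate edge"):
            significant_pairs([edge], mrna, mirna)

    def test_q_at_least_p(self):
        mrna, mirna = _matrices()
        edges = [
            RegulatoryEdge("hsa-miR-1", g, EdgeType.MIRNA_GENE) for g in ("G1", "G2")
        ] + [RegulatoryEdge("T1", "G1", EdgeType.TF_GENE)]
        for r in significant_pairs(edges, mrna, mirna):
            assert r.q >= r.p_one_tailed - 1e-15

    def test_positive_r_fails_repression_rule_but_not_tf_rule(self):
        mrna, mirna = _matrices(r=+0.9)  # miRNA-G1 strongly *positive*
        # force-construct: positive correlation on a repressive edge type
        edge = RegulatoryEdge("hsa-miR-1", "G1", EdgeType.MIRNA_GENE)
        (res,) = [
            r for r in significant_pairs([edge], mrna, mirna) if r.edge.key == edge.key
        ]
        assert res.r > 0.5 and not res.significant

    def test_report_frame_layout(self):
        mrna, mirna = _matrices()
        res = significant_pairs(
            [RegulatoryEdge("hsa-miR-1", "G1", EdgeType.MIRNA_GENE)], mrna, mirna
        )
        df = results_to_frame(res)
        assert list(df.columns) == [
            "source", "target", "edge_type", "r", "n", "p", "q", "significant", "reason",
        ]


class TestExtractSignificantFFLs:
    def _ffl_and_results(self, sig_flags):
        edges = (
            RegulatoryEdge("m1", "T1", EdgeType.MIRNA_TF),
            RegulatoryEdge("m1", "g1", EdgeType.MIRNA_GENE),
            RegulatoryEdge("T1", "g1", EdgeType.TF_GENE),
        )
        f = FFL("m1", "T1", "g1", FFLCategory.MIRNA_FFL, edges)
        from fflnet.exprfilter import CorrelationResult

        results = [
            CorrelationResult(e, -0.5, 100, 0.001, 0.002, s)
            for e, s in zip(edges, sig_flags)
        ]
        return f, results

    def test_all_edges_significant_kept(self):
        f, res = self._ffl_and_results([True, True, True])
        assert extract_significant_ffls([f], res) == [f]

    def test_one_failing_edge_drops_the_motif(self):
        f, res = self._ffl_and_results([True, True, False])
        assert extract_significant_ffls([f], res) == []

    def test_stricter_policy_never_adds_ffls(self):
        from fflnet.synth import SimulationConfig, simulate_expression, simulate_regulome
        from fflnet.ffl import enumerate_ffls

        cfg = SimulationConfig(seed=9)
        edges, truth = simulate_regulome(cfg)
        mrna, mirna = simulate_expression(truth, cfg)
        ffls = enumerate_ffls(edges)
        loose = significant_pairs(edges, mrna, mirna, ThresholdPolicy())
        strict_rules = {
            t: EdgeRule(min_abs_r=0.45, sign=r.sign, alpha=1e-4)
            for t, r in ThresholdPolicy().rules.items()
        }
        strict = significant_pairs(edges, mrna, mirna, ThresholdPolicy(rules=strict_rules))
        kept_loose = {f.triple for f in extract_significant_ffls(ffls, loose)}
        kept_strict = {f.triple for f in extract_significant_ffls(ffls, strict)}
        assert kept_strict <= kept_loose
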