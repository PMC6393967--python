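"""d-measure closed forms, log-sum oracle, and branch classification."""

import math

import numpy as np
import pytest

import stokeshift as ss
from stokeshift.epistasis import (
    DMeasureParams,
    ScoringError,
    branch_epistasis_logsum,
    classify_branches,
    d_measure,
    d_weight_matrix,
    nonconservation_weight,
    percentile_ranks,
)


class TestClosedForms:
    def test_nc_at_zero_rate_is_half(self):
        assert nonconservation_weight(0.0) == pytest.approx(0.5, abs=1e-15)

    def test_nc_values(self):
        assert nonconservation_weight(0.01) == pytest.approx(
            1 / (1 + math.e**2), rel=1e-12
        )
        assert nonconservation_weight(0.05) == pytest.approx(
            1 / (1 + math.e**10), rel=1e-12
        )

    def test_d_maximal(self):
        assert d_measure(1.0, 1.0, 0.0) == pytest.approx(1.0, abs=1e-15)

    def test_d_zero_support(self):
        assert d_measure(0.0, 0.9, 0.0) == 0.0
        assert d_measure(0.0, 0.9, 0.5) == 0.0

    def test_d_composition(self):
        assert d_measure(0.5, 0.4, 0.01) == pytest.approx(
            0.5 * 0.4 * 2 / (1 + math.e**2), rel=1e-12
        )

    def test_point_mass_rare_substitution_logsum_value(self):
        # parent A, child R, RF = 0.01: L = ln(2 * NC(0.01)) ~ -1.4337
        val = math.log(d_measure(1.0, 1.0, 0.01))
        assert val == pytest.approx(math.log(2 / (1 + math.e**2)), rel=1e-12)
        assert val == pytest.approx(-1.4337, abs=5e-4)

    def test_pp_square_variant(self):
        p = DMeasureParams(pp_square_variant=True)
        assert d_measure(0.5, 0.4, 0.0, p) == pytest.approx(0.5 * 0.16 * 0.5)

    def test_d_monotonicity_small_sample(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            pa, pb = rng.random(2)
            rf = rng.random() * 0.05
            eps = 1e-4
            base = d_measure(pa, pb, rf)
            assert d_measure(min(pa + eps, 1.0), pb, rf) >= base
            assert d_measure(pa, min(pb + eps, 1.0), rf) >= base
            assert d_measure(pa, pb, rf + eps) <= base


class TestBranchLogsum:
    def test_identical_point_masses_error(self, jtt):
        pp = np.zeros((1, 20))
        pp[0, 0] = 1.0
        with pytest.raises(ScoringError, match="zero"):
            branch_epistasis_logsum(pp, pp.copy(), jtt)

    def test_matches_naive_triple_loop(self, jtt):
        rng = np.random.default_rng(3)
        parent = rng.dirichlet(np.full(20, 0.5), size=50)
        child = rng.dirichlet(np.full(20, 0.5), size=50)
        fast = branch_epistasis_logsum(parent, child, jtt)
        q = jtt.q
        total = 0.0
        for s in range(50):
            for a in range(20):
                for b in range(20):
                    if a == b:
                        continue
                    total += d_measure(parent[s, a], child[s, b], max(q[a, b], 0.0))
        assert fast == pytest.approx(math.log(total), abs=1e-12)

    def test_weight_matrix_range(self, jtt):
        w = d_weight_matrix(jtt)
        off = w[~np.eye(20, dtype=bool)]
        assert np.all(off > 0) and np.all(off <= 1.0)
        assert np.all(np.diag(w) == 0)

    def test_shift_branch_scores_above_median(self, jtt, gamma6):
        from conftest import shift_replicate

        rep = shift_replicate(5, jtt, gamma6)
        df = rep["epistasis"]
        target_score = df.set_index("child").loc[rep["target"], "score"]
        assert target_score > df["score"].median()
        assert np.isfinite(df["score"]).all()


class TestClassification:
    def test_four_distinct_scores_one_per_quartile(self):
        scores = {("r", f"n{i}"): float(i) for i in range(4)}
        df = classify_branches(scores)
        assert sorted(df["quartile"]) == ["Q1", "Q2", "Q3", "Q4"]

    def test_all_equal_scores_collapse_to_q2_unflagged(self):
        scores = {("r", f"n{i}"): 1.5 for i in range(6)}
        df = classify_branches(scores, flag_percentile=95)
        assert set(df["quartile"]) == {"Q2"}
        assert not df["flag"].any()

    def test_top_ranks_flagged_at_95(self):
        scores = {("r", f"n{i:03d}"): float(i + 1) for i in range(100)}
        df = classify_branches(scores, flag_percentile=95).set_index("child")
        flagged = {c for c in df.index if df.loc[c, "flag"]}
        # Hazen percentile of score k out of 1..100 is k - 0.5
        assert flagged == {f"n{i:03d}" for i in range(95, 100)}

    def test_percentile_ranks_midpoint_ties(self):
        pct = percentile_ranks(np.array([1.0, 1.0, 2.0, 3.0]))
        assert pct[0] == pct[1] == pytest.approx(25.0)

    def test_too_few_branches_rejected(self):
        with pytest.raises(ScoringError):
            classify_branches({("r", "a"): 1.0})


def test_leaf_branch_scoring_optional(jtt, gamma6):
    tree = ss.simulate_yule_tree(6, seed=13)
    aln, _ = ss.simulate_evolution(tree, jtt, gamma6, 50, seed=13)
    prof = ss.marginal_posteriors(aln, tree, jtt, gamma6)
    inner_only = ss.score_tree_epistasis(prof, tree, jtt)
    with_leaves = ss.score_tree_epistasis(
        prof, tree, jtt, include_leaf_branches=True, aln=aln
    )
    assert set(inner_only) < set(with_leaves)
    assert len(with_leaves) == len(tree.branches())
    for b, v in inner_only.items():
        assert with_leaves[b] == pytest.approx(v)
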