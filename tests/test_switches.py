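"""Isoform ratios, sqrt-JSD properties, divergence tests, switch criteria."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import jensenshannon

from ersplice.switches import (
    classify_switch,
    dsg_test,
    isoform_ratio,
    jsd_sqrt,
    promoter_switch_test,
    switch_set_logic,
)


class TestIsoformRatio:
    @pytest.mark.parametrize("iso, gene, expected", [
        (5, 20, 25.0), (0, 20, 0.0), (20, 20, 100.0),
    ])
    def test_values(self, iso, gene, expected):
        assert isoform_ratio(iso, gene) == pytest.approx(expected)

    def test_zero_gene_fpkm_undefined(self):
        assert isoform_ratio(0.0, 0.0) is None

    def test_isoform_exceeding_gene_rejected(self):
        with pytest.raises(ValueError):
            isoform_ratio(25, 20)


class TestJsdSqrt:
    def test_identity_is_zero(self):
        assert jsd_sqrt([0.3, 0.7], [0.3, 0.7]) == 0.0

    def test_disjoint_support_is_one(self):
        assert jsd_sqrt([1.0, 0.0], [0.0, 1.0]) == pytest.approx(1.0)

    def test_half_versus_point_mass(self):
        # H(0.75,0.25) - 0.5*H(0.5,0.5) = 0.311278...; sqrt = 0.557923...
        assert jsd_sqrt([0.5, 0.5], [1.0, 0.0]) == pytest.approx(0.5579, abs=1e-3)

    def test_flip_of_dominant_isoform(self):
        assert jsd_sqrt([0.9, 0.1], [0.1, 0.9]) == pytest.approx(0.729, abs=1e-3)

    def test_matches_independent_implementation_on_random_simplex(self, rng):
        for _ in range(200):
            k = int(rng.integers(2, 6))
            p = rng.dirichlet(np.ones(k))
            q = rng.dirichlet(np.ones(k))
            assert jsd_sqrt(p, q) == pytest.approx(
                jensenshannon(p, q, base=2), abs=1e-9)

    def test_metric_properties_on_random_triples(self, rng):
        for _ in range(200):
            k = int(rng.integers(2, 5))
            p, q, r = (rng.dirichlet(np.ones(k)) for _ in range(3))
            dpq, dqr, dpr = jsd_sqrt(p, q), jsd_sqrt(q, r), jsd_sqrt(p, r)
            assert dpq == pytest.approx(jsd_sqrt(q, p))
            assert dpr <= dpq + dqr + 1e-12
            assert 0.0 <= dpq <= 1.0

    def test_unnormalized_input_rejected(self):
        with pytest.raises(ValueError):
            jsd_sqrt([0.5, 0.4], [0.5, 0.5])


class TestPromoterSwitchTest:
    def test_identical_abundances_give_zero_statistic(self, rng):
        counts = np.array([[400, 410, 395], [100, 105, 98]])
        res = promoter_switch_test(counts, counts, n_perm=199, rng=rng)
        assert res.statistic == pytest.approx(0.0, abs=0.02)
        assert res.p > 0.5

    def test_single_group_not_testable(self, rng):
        one = np.array([[500, 480, 510]])
        assert promoter_switch_test(one, one, rng=rng) is None

    def test_planted_dominant_flip_is_significant(self, rng):
        # dominant promoter share 0.8 -> 0.2 across conditions, 3 reps
        hits = 0
        trials = 30
        for _ in range(trials):
            tot = rng.poisson(500, size=6)
            veh = np.array([rng.binomial(tot[:3], 0.8),
                            tot[:3] - rng.binomial(tot[:3], 0.8)])
            veh = np.vstack([veh[0], tot[:3] - veh[0]])
            e2_top = rng.binomial(tot[3:], 0.2)
            e2 = np.vstack([e2_top, tot[3:] - e2_top])
            res = promoter_switch_test(veh, e2, n_perm=199, rng=rng)
            if res.p <= 0.01:
                hits += 1
        assert hits / trials >= 0.9

    def test_null_monte_carlo_p_is_calibrated(self, rng):
        # stable usage: the fraction of p <= 0.05 stays near 0.05
        ps = []
        for _ in range(300):
            tot = rng.poisson(400, size=6)
            top = rng.binomial(tot, 0.6)
            veh = np.vstack([top[:3], tot[:3] - top[:3]])
            e2 = np.vstack([top[3:], tot[3:] - top[3:]])
            res = promoter_switch_test(veh, e2, n_perm=99, rng=rng,
                                       randomized=True)
            ps.append(res.p)
        frac = np.mean(np.asarray(ps) <= 0.05)
        assert frac <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / len(ps))


class TestDsgTest:
    def test_unchanged_proportions_give_zero_statistic(self, rng):
        counts = np.array([[300, 290, 310], [300, 310, 295], [50, 55, 48]])
        res = dsg_test(counts, counts, ["TSS01", "TSS01", "TSS02"],
                       n_perm=99, rng=rng)
        assert res.statistic == pytest.approx(0.0, abs=0.03)

    def test_no_multi_isoform_group_not_testable(self, rng):
        counts = np.array([[100, 90, 110], [40, 50, 45]])
        assert dsg_test(counts, counts, ["TSS01", "TSS02"], rng=rng) is None

    def test_within_group_flip_is_recovered(self, rng):
        # 2-isoform promoter group flipping 0.9/0.1 -> 0.1/0.9 at depth 500
        tot = rng.poisson(500, size=6)
        top_v = rng.binomial(tot[:3], 0.9)
        top_e = rng.binomial(tot[3:], 0.1)
        veh = np.vstack([top_v, tot[:3] - top_v])
        e2 = np.vstack([top_e, tot[3:] - top_e])
        res = dsg_test(veh, e2, ["TSS01", "TSS01"], n_perm=199, rng=rng)
        assert res.statistic == pytest.approx(0.729, abs=0.08)
        assert res.p <= 0.01


class TestClassifySwitch:
    LINES = ("wt", "ct_erb", "nt_erb")

    def ratios(self, per_isoform):
        rows = []
        for iso, dr in per_isoform.items():
            for line, val in zip(self.LINES, dr):
                rows.append(dict(isoform_id=iso, cell_line=line, dratio=val))
        return pd.DataFrame(rows)

    def test_constructed_pass_satisfies_all_criteria(self):
        # isoform A: +15 in wt, -12/-14 in the ERbeta+ lines; A significant
        # in wt; one splicing event in ct -> all four criteria hold
        ratios = self.ratios({"A": (15, -12, -14), "B": (-15, 12, 14)})
        call = classify_switch(
            "g", ratios,
            {"wt": {"A": True}}, {"ct_erb": True},
        )
        assert (call.criterion_i, call.criterion_ii,
                call.criterion_iii, call.criterion_iv) == (True,) * 4
        assert call.passes

    def test_inconsistent_erb_direction_fails_criterion_iii(self):
        ratios = self.ratios({"A": (15, -12, 3), "B": (-15, 12, -3)})
        call = classify_switch("g", ratios, {"wt": {"A": True}},
                               {"ct_erb": True})
        assert not call.criterion_iii
        assert not call.passes

    def test_small_ratio_changes_fail_criterion_i(self):
        ratios = self.ratios({"A": (8, -8, -8), "B": (-8, 8, 8)})
        call = classify_switch("g", ratios, {"wt": {"A": True}},
                               {"ct_erb": True})
        assert not call.criterion_i

    def test_relaxing_threshold_is_monotone(self):
        ratios = self.ratios({"A": (8, -8, -8), "B": (-8, 8, 8)})
        strict = classify_switch("g", ratios, {"wt": {"A": True}},
                                 {"ct_erb": True}, ratio_points=10)
        relaxed = classify_switch("g", ratios, {"wt": {"A": True}},
                                  {"ct_erb": True}, ratio_points=5)
        assert not strict.passes and relaxed.passes

    def test_missing_line_rejected(self):
        ratios = self.ratios({"A": (15, -12, -14)}).query(
            "cell_line != 'nt_erb'")
        with pytest.raises(ValueError):
            classify_switch("g", ratios, {}, {})


class TestSwitchSetLogic:
    def tables(self, sig):
        return {
            line: pd.DataFrame(dict(gene_id=list("abc"),
                                    significant=flags))
            for line, flags in sig.items()
        }

    def test_lost_and_specific_sets(self):
        res = switch_set_logic(self.tables({
            "wt": [True, False, True],
            "ct_erb": [False, True, True],
            "nt_erb": [False, True, False],
        }))
        assert res["lost"] == {"a"}
        assert res["erb_specific"] == {"b"}
        # 'c' significant in wt and ct only -> neither set
        assert "c" not in res["lost"] | res["erb_specific"]

    def test_universe_mismatch_rejected(self):
        tabs = self.tables({
            "wt": [True, False, True],
            "ct_erb": [False, True, True],
            "nt_erb": [False, True, False],
        })
        tabs["nt_erb"] = tabs["nt_erb"].iloc[:2]
        with pytest.raises(ValueError):
            switch_set_logic(tabs)
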