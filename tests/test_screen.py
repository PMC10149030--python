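"""Silencing screen, hypermethylation calls, targetability and panels."""

import itertools

import numpy as np
import pandas as pd
import pytest

from epipanel.screen import (anticorrelation_screen, call_hypermethylation,
                             greedy_panel, panel_coverage, promoter_summary,
                             targetable_matrix)


def _ann(tumors, normals):
    idx = list(tumors) + list(normals)
    return pd.DataFrame(
        {"tissue": ["tumor"] * len(tumors) + ["normal"] * len(normals),
         "matched_pair_id": [None] * len(idx),
         "subtype_label": ["unknown"] * len(idx)},
        index=pd.Index(idx, name="sample_id"))


class TestPromoterSummary:
    def test_single_probe_identity_and_mean(self):
        meth = pd.DataFrame([[0.2, 0.6], [0.4, 0.8], [0.5, 0.5]],
                            index=["p1", "p2", "p3"], columns=["s1", "s2"])
        pm = pd.DataFrame({"probe_id": ["p1", "p2", "p3"],
                           "gene_id": ["gA", "gA", "gB"]})
        summ = promoter_summary(meth, pm)
        assert summ.loc["gA", "s1"] == pytest.approx(0.3)
        assert summ.loc["gB", "s1"] == pytest.approx(0.5)  # identity
        summ_max = promoter_summary(meth, pm, method="max")
        assert summ_max.loc["gA", "s1"] == pytest.approx(0.4)

    def test_missing_probes_excluded_pairwise(self):
        meth = pd.DataFrame([[0.2, np.nan], [np.nan, np.nan]],
                            index=["p1", "p2"], columns=["s1", "s2"])
        pm = pd.DataFrame({"probe_id": ["p1", "p2"], "gene_id": ["gA", "gA"]})
        summ = promoter_summary(meth, pm)
        assert summ.loc["gA", "s1"] == pytest.approx(0.2)
        assert np.isnan(summ.loc["gA", "s2"])


class TestAnticorrelationScreen:
    def test_perfect_monotone_anticorrelation(self):
        tumors = [f"t{i}" for i in range(12)]
        normals = ["n1", "n2", "n3"]
        ann = _ann(tumors, normals)
        rng = np.random.default_rng(0)
        beta = pd.DataFrame(
            [np.concatenate([np.linspace(0.1, 0.9, 12), [0.1, 0.1, 0.1]])],
            index=["gA"], columns=tumors + normals)
        expr = pd.DataFrame(
            [np.concatenate([np.linspace(12, 1, 12), [12.0, 11.0, 13.0]])],
            index=["gA"], columns=tumors + normals)
        res = anticorrelation_screen(expr, beta, ann)
        assert res.loc["gA", "rho"] == pytest.approx(-1.0)
        assert res.loc["gA", "candidate"]

    def test_constant_gene_excluded(self):
        tumors = [f"t{i}" for i in range(12)]
        normals = ["n1", "n2", "n3"]
        ann = _ann(tumors, normals)
        beta = pd.DataFrame([[0.5] * 15], index=["gA"],
                            columns=tumors + normals)
        rng = np.random.default_rng(1)
        expr = pd.DataFrame([rng.normal(size=15)], index=["gA"],
                            columns=tumors + normals)
        res = anticorrelation_screen(expr, beta, ann)
        assert not res.loc["gA", "evaluable"]
        assert not res.loc["gA", "candidate"]

    def test_minimum_cohort_sizes_enforced(self):
        ann = _ann(["t1", "t2"], ["n1", "n2", "n3"])
        df = pd.DataFrame([[0.1] * 5], index=["g"], columns=ann.index)
        with pytest.raises(ValueError, match="10 tumors"):
            anticorrelation_screen(df, df, ann)


class TestHypermethylationCalls:
    def _inputs(self):
        meth = pd.DataFrame(
            {"t1": [0.8, 0.3], "t2": [0.6, 0.3], "t3": [0.2, 0.7],
             "n1": [0.5, 0.4], "n2": [0.6, 0.2]},
            index=["p1", "p2"])
        pm = pd.DataFrame({"probe_id": ["p1", "p2"], "gene_id": ["gA", "gA"]})
        return meth, pm

    def test_any_probe_rule_and_strict_boundary(self):
        meth, pm = self._inputs()
        calls = call_hypermethylation(meth, pm, ["n1", "n2"],
                                      ["t1", "t2", "t3"])
        assert bool(calls.loc["gA", "t1"])        # 0.8 > 0.6
        assert not bool(calls.loc["gA", "t2"])    # exactly equal: NOT hyper
        assert bool(calls.loc["gA", "t3"])        # probe 2: 0.7 > 0.4

    def test_summary_rule_can_differ(self):
        meth, pm = self._inputs()
        any_rule = call_hypermethylation(meth, pm, ["n1", "n2"],
                                         ["t1", "t2", "t3"])
        summary = call_hypermethylation(meth, pm, ["n1", "n2"],
                                        ["t1", "t2", "t3"], rule="summary")
        # t3: probe-level call true, but mean (0.45) <= normal max mean (0.45)
        assert bool(any_rule.loc["gA", "t3"])
        assert not bool(summary.loc["gA", "t3"])

    def test_normals_never_exceed_their_own_maximum(self, small_cohort):
        bundle, _ = small_cohort
        normals = bundle.normals
        calls = call_hypermethylation(bundle.methylation, bundle.promoter_map,
                                      normals, normals)
        assert not calls.fillna(False).to_numpy().any()

    def test_missing_probe_gives_missing_call(self):
        meth = pd.DataFrame({"t1": [np.nan], "n1": [0.4]}, index=["p1"])
        pm = pd.DataFrame({"probe_id": ["p1"], "gene_id": ["gA"]})
        calls = call_hypermethylation(meth, pm, ["n1"], ["t1"])
        assert pd.isna(calls.loc["gA", "t1"])


class TestTargetability:
    def test_loss_excluded_and_combinations(self):
        hyper = pd.DataFrame([[True, True, False]], index=["g"],
                             columns=["s1", "s2", "s3"]).astype("boolean")
        cnv = pd.DataFrame([[-1.0, 1.0, 0.0]], index=["g"],
                           columns=["s1", "s2", "s3"])
        tm = targetable_matrix(hyper, cnv)
        assert not tm.targetable.loc["g", "s1"]   # hyper but loss
        assert tm.targetable.loc["g", "s2"]       # hyper, gain
        assert not tm.targetable.loc["g", "s3"]   # no hyper
        assert (tm.targetable.to_numpy() <= (
            tm.hypermethylated.fillna(False).to_numpy()
            & tm.no_loss.to_numpy())).all()

    def test_missing_cnv_treated_as_no_loss_with_flag(self):
        hyper = pd.DataFrame([[True]], index=["g"], columns=["s1"])
        cnv = pd.DataFrame([[np.nan]], index=["g"], columns=["s1"])
        tm = targetable_matrix(hyper, cnv)
        assert tm.targetable.loc["g", "s1"]
        assert tm.missing_cnv_flagged == 1


def _random_targetable(rng, n_genes, n_tumors, p=0.3):
    mat = rng.uniform(size=(n_genes, n_tumors)) < p
    return pd.DataFrame(mat, index=[f"g{i}" for i in range(n_genes)],
                        columns=[f"t{j}" for j in range(n_tumors)])


class TestPanelCoverage:
    def _groups(self, targetable):
        n = targetable.shape[1]
        return pd.Series((["A"] * (n // 2)) + (["B"] * (n - n // 2)),
                         index=targetable.columns)

    def test_hand_enumeration(self):
        t = pd.DataFrame(
            [[1, 0, 0, 0], [0, 1, 1, 0], [0, 0, 0, 0]],
            index=["g1", "g2", "g3"],
            columns=["s1", "s2", "s3", "s4"]).astype(bool)
        groups = pd.Series(["A"] * 4, index=t.columns)
        cov = panel_coverage(t, groups, ["g1", "g2"])
        assert cov.overall_pct == pytest.approx(75.0)

    def test_empty_panel_and_full_panel(self, rng):
        t = _random_targetable(rng, 6, 20)
        groups = self._groups(t)
        assert panel_coverage(t, groups, []).overall_pct == 0.0
        full = panel_coverage(t, groups, list(t.index))
        any_pct = 100.0 * t.any(axis=0).mean()
        assert full.overall_pct == pytest.approx(any_pct)

    def test_panel_at_least_best_single_gene(self, rng):
        for _ in range(20):
            t = _random_targetable(rng, 8, 25)
            cov = panel_coverage(t, self._groups(t), list(t.index[:4]))
            assert cov.overall_pct >= max(cov.gene_pct.values()) - 1e-9

    def test_empty_group_flagged_nan(self):
        t = pd.DataFrame([[True]], index=["g"], columns=["s1"])
        groups = pd.Series([np.nan], index=["s1"])
        cov = panel_coverage(t, groups, ["g"])
        assert cov.group_pct == {}

    def test_monotone_in_panel(self, rng):
        for _ in range(20):
            t = _random_targetable(rng, 8, 30)
            groups = self._groups(t)
            panel = list(rng.choice(t.index, size=3, replace=False))
            extra = [g for g in t.index if g not in panel][0]
            before = panel_coverage(t, groups, panel)
            after = panel_coverage(t, groups, panel + [extra])
            assert after.overall_pct >= before.overall_pct - 1e-12
            for g in before.group_pct:
                assert after.group_pct[g] >= before.group_pct[g] - 1e-12

    def test_matches_exhaustive_enumeration(self, rng):
        for _ in range(100):
            t = _random_targetable(rng, rng.integers(2, 7),
                                   rng.integers(3, 15))
            panel = list(rng.choice(t.index,
                                    size=rng.integers(1, len(t.index) + 1),
                                    replace=False))
            cov = panel_coverage(t, self._groups(t), panel)
            covered = sum(
                any(t.loc[g, s] for g in panel) for s in t.columns)
            assert cov.overall_pct == pytest.approx(
                100.0 * covered / t.shape[1])


class TestGreedyPanel:
    def test_single_covering_gene(self):
        t = pd.DataFrame([[1, 1, 1], [1, 0, 0]], index=["g1", "g2"],
                         columns=["s1", "s2", "s3"]).astype(bool)
        groups = pd.Series(["A"] * 3, index=t.columns)
        panel, traj = greedy_panel(t, groups, max_size=3)
        assert panel == ["g1"]
        assert traj["overall_pct"].iloc[-1] == 100.0

    def test_disjoint_blocks_exactly_optimal(self):
        # each gene covers a distinct tumor block -> greedy == optimum
        t = pd.DataFrame(np.kron(np.eye(4), np.ones((1, 3))),
                         index=[f"g{i}" for i in range(4)],
                         columns=[f"s{j}" for j in range(12)]).astype(bool)
        groups = pd.Series(["A"] * 12, index=t.columns)
        panel, traj = greedy_panel(t, groups, max_size=2)
        assert traj["overall_pct"].iloc[-1] == pytest.approx(100 * 6 / 12)

    def test_trajectory_nondecreasing_and_bounded(self, rng):
        t = _random_targetable(rng, 10, 30)
        groups = pd.Series(["A"] * 15 + ["B"] * 15, index=t.columns)
        panel, traj = greedy_panel(t, groups, max_size=4)
        assert len(panel) <= 4
        assert (np.diff(traj["overall_pct"]) >= -1e-12).all()

    def test_beats_1_minus_1_over_e_bound(self, rng):
        """Greedy coverage >= (1 - 1/e) of the exhaustive optimum for the
        same panel size on random instances."""
        bound = 1 - 1 / np.e
        for _ in range(10):
            t = _random_targetable(rng, 8, 20, p=0.25)
            groups = pd.Series(["A"] * 20, index=t.columns)
            k = 3
            panel, traj = greedy_panel(t, groups, max_size=k)
            best = max(
                panel_coverage(t, groups, list(sub)).overall_pct
                for sub in itertools.combinations(t.index, min(k, len(t.index))))
            assert traj["overall_pct"].iloc[-1] >= bound * best - 1e-9

    def test_lexicographic_tie_break(self):
        t = pd.DataFrame([[1, 0], [1, 0]], index=["gB", "gA"],
                         columns=["s1", "s2"]).astype(bool)
        groups = pd.Series(["A", "A"], index=t.columns)
        panel, _ = greedy_panel(t, groups, max_size=1)
        assert panel == ["gA"]
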