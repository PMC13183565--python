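import numpy as np
import pandas as pd
import pytest
from skbio import DistanceMatrix

from codami import microbiome as mb


class TestRetainResolve:
    def test_toy_walkthrough(self, toy_table):
        res = mb.retain_resolve(toy_table, prevalence_min=0.5,
                                abundance_min=0.05, glom_rank="genus")
        assert set(res.table.taxa) == {"A", "B", "genus:GenusCD", mb.OTHER_ID}
        # per-sample totals conserved exactly
        pd.testing.assert_series_equal(res.table.counts.sum(axis=0),
                                       toy_table.counts.sum(axis=0))
        assert res.audit.initial == 5
        assert res.audit.retained_round1 == 2
        assert res.audit.glommed_candidates == 2  # GenusCD + GenusE
        assert res.audit.retained_round2 == 1
        assert res.audit.other_merged == 1
        # every input taxon assigned to exactly one output row
        assert res.assignment.to_dict() == {
            "A": "A", "B": "B", "C": "genus:GenusCD", "D": "genus:GenusCD",
            "E": mb.OTHER_ID}

    def test_zero_thresholds_keep_everything(self, toy_table):
        res = mb.retain_resolve(toy_table, prevalence_min=0.0, abundance_min=0.0)
        assert res.audit.other_merged == 0
        assert res.audit.retained_round1 == 5

    def test_mass_conservation_on_simulated_data(self, micro_table):
        res = mb.retain_resolve(micro_table)
        pd.testing.assert_series_equal(res.table.counts.sum(axis=0),
                                       micro_table.counts.sum(axis=0))
        assert (res.audit.retained_round1 + res.audit.retained_round2
                + res.audit.other_merged) == res.audit.glommed_candidates + res.audit.retained_round1
        assert res.assignment.notna().all()

    def test_unknown_rank_and_empty_table(self, toy_table):
        with pytest.raises(ValueError, match="unknown rank"):
            mb.retain_resolve(toy_table, glom_rank="clade")


class TestAlphaDiversity:
    def test_uniform_and_singleton_examples(self, toy_table):
        counts = pd.DataFrame({"s": [10, 10, 10, 10]}, index=list("wxyz"))
        lineage = pd.Series({t: ";".join(["L"] * 7) for t in "wxyz"})
        meta = pd.DataFrame({"timepoint": ["P7"], "age": [7.0], "sex": ["F"]},
                            index=["s"])
        table = mb.TaxaCountTable(counts, lineage, meta)
        assert mb.alpha_diversity(table, "shannon")["s"] == pytest.approx(np.log(4))
        assert mb.alpha_diversity(table, "inv_simpson")["s"] == pytest.approx(4.0)
        assert mb.alpha_diversity(table, "richness")["s"] == 4

        counts.loc[:, "s"] = [30, 0, 0, 0]
        single = mb.TaxaCountTable(counts, lineage, meta)
        assert mb.alpha_diversity(single, "shannon")["s"] == pytest.approx(0.0)
        assert mb.alpha_diversity(single, "inv_simpson")["s"] == pytest.approx(1.0)
        assert mb.alpha_diversity(single, "richness")["s"] == 1

    def test_shannon_bounded_by_log_richness(self, micro_table):
        sh = mb.alpha_diversity(micro_table, "shannon")
        rich = mb.alpha_diversity(micro_table, "richness")
        assert (sh <= np.log(rich) + 1e-12).all()

    def test_trend_constant_values(self, micro_table):
        const = pd.Series(3.0, index=micro_table.samples)
        out = mb.test_alpha_trend(const, micro_table.metadata)
        assert (out["F"] == 0).all()
        assert (out["p"] == 1).all()

    def test_trend_coefficients_match_normal_equations(self, micro_table):
        rng = np.random.default_rng(0)
        y = pd.Series(rng.normal(size=len(micro_table.samples)),
                      index=micro_table.samples)
        import statsmodels.formula.api as smf

        df = micro_table.metadata.copy()
        df["y"] = y
        fit = smf.ols("y ~ C(timepoint) + C(sex)", data=df).fit()
        X = fit.model.exog
        beta_oracle = np.linalg.inv(X.T @ X) @ X.T @ fit.model.endog
        np.testing.assert_allclose(fit.params.to_numpy(), beta_oracle, atol=1e-8)
        out = mb.test_alpha_trend(y, micro_table.metadata)
        assert set(out.index) == {"timepoint", "sex"}

    def test_trend_detects_planted_timepoint_effect(self):
        """Power > 0.9 for a 2-sd monotone timepoint effect at study n."""
        rng = np.random.default_rng(7)
        hits = 0
        n_rep = 60
        meta = pd.DataFrame({
            "timepoint": np.repeat(["P7", "P14", "P24", "8W"], 12),
            "age": np.repeat([7.0, 14.0, 24.0, 56.0], 12),
            "sex": ["F", "M"] * 24,
        }, index=[f"s{i}" for i in range(48)])
        meta["timepoint"] = pd.Categorical(meta["timepoint"],
                                           ["P7", "P14", "P24", "8W"], ordered=True)
        effect = np.repeat([0.0, 2 / 3, 4 / 3, 2.0], 12)  # 2 sd span
        for _ in range(n_rep):
            y = pd.Series(effect + rng.normal(size=48), index=meta.index)
            out = mb.test_alpha_trend(y, meta)
            hits += out.loc["timepoint", "p"] < 0.01
        assert hits / n_rep > 0.9


class TestBetaDistance:
    def test_identical_samples_give_zero(self, micro_table):
        for metric in mb.BETA_METRICS:
            d = mb.beta_distance(micro_table, metric)
            assert d[micro_table.samples[0], micro_table.samples[0]] == 0.0

    def test_disjoint_supports(self):
        counts = pd.DataFrame({"s1": [5, 5, 0, 0], "s2": [0, 0, 7, 3]},
                              index=list("abcd"))
        lineage = pd.Series({t: ";".join(["L"] * 7) for t in "abcd"})
        meta = pd.DataFrame({"timepoint": ["P7", "P7"], "age": [7.0, 7.0],
                             "sex": ["F", "M"]}, index=["s1", "s2"])
        table = mb.TaxaCountTable(counts, lineage, meta)
        assert mb.beta_distance(table, "jaccard")["s1", "s2"] == 1.0
        assert mb.beta_distance(table, "bray_curtis")["s1", "s2"] == 1.0

    def test_bray_curtis_hand_value(self):
        counts = pd.DataFrame({"s1": [50, 50, 0], "s2": [25, 25, 50]},
                              index=list("abc"))
        lineage = pd.Series({t: ";".join(["L"] * 7) for t in "abc"})
        meta = pd.DataFrame({"timepoint": ["P7", "P7"], "age": [7.0, 7.0],
                             "sex": ["F", "M"]}, index=["s1", "s2"])
        table = mb.TaxaCountTable(counts, lineage, meta)
        assert mb.beta_distance(table, "bray_curtis")["s1", "s2"] == pytest.approx(0.5)


class TestPcoa:
    def test_collinear_points_recovered_on_first_axis(self):
        xs = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        D = np.abs(xs[:, None] - xs[None, :])
        dm = DistanceMatrix(D, ids=list("abcde"))
        coords, eigvals = mb.pcoa(dm, k=2)
        r = np.corrcoef(coords["PC1"], xs)[0, 1]
        assert abs(r) == pytest.approx(1.0, abs=1e-10)

    def test_euclidean_distances_reproduced_exactly(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(7, 3))
        from scipy.spatial.distance import pdist, squareform

        dm = DistanceMatrix(squareform(pdist(pts)), ids=[str(i) for i in range(7)])
        coords, eigvals = mb.pcoa(dm, k=6)
        rec = squareform(pdist(coords.to_numpy()))
        np.testing.assert_allclose(rec, dm.data, atol=1e-8)
        diffs = np.diff(eigvals.to_numpy())
        assert (diffs <= 1e-9).all()


class TestPermanova:
    @staticmethod
    def _dm(points, ids):
        from scipy.spatial.distance import pdist, squareform

        return DistanceMatrix(squareform(pdist(points)), ids=ids)

    def test_maximal_separation_gives_minimal_p(self):
        pts = np.array([[0, 0]] * 8 + [[100, 100]] * 8, dtype=float)
        pts += np.random.default_rng(0).normal(0, 1e-6, pts.shape)
        ids = [f"s{i}" for i in range(16)]
        groups = pd.Series(["a"] * 8 + ["b"] * 8, index=ids)
        res = mb.permanova(self._dm(pts, ids), groups, n_perm=199, seed=1)
        assert res.p == pytest.approx(1 / 200)
        assert 0 <= res.R2 <= 1

    def test_pseudo_f_matches_brute_force(self):
        rng = np.random.default_rng(5)
        pts = rng.normal(size=(6, 2))
        ids = [f"s{i}" for i in range(6)]
        groups = pd.Series(["a", "a", "a", "b", "b", "b"], index=ids)
        dm = self._dm(pts, ids)
        res = mb.permanova(dm, groups, n_perm=99, seed=0)
        # oracle: direct Anderson partition of squared distances
        d2 = dm.data**2
        n, a = 6, 2
        sst = d2[np.triu_indices(6, 1)].sum() / n
        ssw = 0.0
        for g in ("a", "b"):
            idx = np.flatnonzero(groups.to_numpy() == g)
            sub = d2[np.ix_(idx, idx)]
            ssw += sub[np.triu_indices(3, 1)].sum() / 3
        f_oracle = ((sst - ssw) / (a - 1)) / (ssw / (n - a))
        assert res.pseudo_F == pytest.approx(f_oracle, rel=1e-12)

    def test_statistic_matches_skbio(self, micro_table):
        dist = mb.beta_distance(micro_table, "bray_curtis")
        ours = mb.permanova(dist, micro_table.metadata["timepoint"],
                            n_perm=99, seed=0)
        import skbio.stats.distance as skd

        theirs = skd.permanova(dist, micro_table.metadata["timepoint"].astype(str),
                               permutations=0)
        assert ours.pseudo_F == pytest.approx(theirs["test statistic"], rel=1e-9)

    def test_p_invariant_to_sample_order(self, micro_table):
        dist = mb.beta_distance(micro_table, "bray_curtis")
        res1 = mb.permanova(dist, micro_table.metadata["timepoint"],
                            n_perm=199, seed=3)
        order = list(reversed(list(dist.ids)))
        res2 = mb.permanova(dist.filter(order),
                            micro_table.metadata["timepoint"].loc[order],
                            n_perm=199, seed=3)
        assert res1.pseudo_F == pytest.approx(res2.pseudo_F, rel=1e-9)

    def test_small_n_perm_warns(self, micro_table):
        dist = mb.beta_distance(micro_table, "jaccard")
        with pytest.warns(UserWarning, match="n_perm"):
            mb.permanova(dist, micro_table.metadata["timepoint"], n_perm=20, seed=0)
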