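import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix

from codami import coda, integrate
from codami.simulate import (
    Coupling,
    RECOVERY_PAIRS,
    coupled_config,
    null_config,
    simulate_coupled,
)


def _euclid_dm(points, ids):
    return DistanceMatrix(squareform(pdist(points)), ids=ids)


class TestMantel:
    def test_self_comparison(self):
        rng = np.random.default_rng(0)
        D = _euclid_dm(rng.normal(size=(12, 3)), [f"s{i}" for i in range(12)])
        res = integrate.mantel(D, D, n_perm=199, seed=1)
        assert res.r == pytest.approx(1.0)
        assert res.p == pytest.approx(1 / 200)

    def test_matches_skbio_without_strata(self):
        rng = np.random.default_rng(1)
        ids = [f"s{i}" for i in range(15)]
        D1 = _euclid_dm(rng.normal(size=(15, 2)), ids)
        D2 = _euclid_dm(rng.normal(size=(15, 2)), ids)
        ours = integrate.mantel(D1, D2, n_perm=99, seed=0)
        from skbio.stats.distance import mantel as skbio_mantel

        r_skbio, _, _ = skbio_mantel(D1, D2, permutations=0)
        assert ours.r == pytest.approx(r_skbio, abs=1e-10)

    def test_singleton_strata_freeze_the_permutation(self):
        """With one sample per stratum no exchange is possible, so every
        permuted r equals the observed r and p is 1."""
        rng = np.random.default_rng(2)
        ids = [f"s{i}" for i in range(10)]
        D1 = _euclid_dm(rng.normal(size=(10, 2)), ids)
        D2 = _euclid_dm(rng.normal(size=(10, 2)), ids)
        strata = pd.Series(range(10), index=ids)
        res = integrate.mantel(D1, D2, n_perm=99, strata=strata, seed=3)
        assert res.p == 1.0

    def test_calibration_under_independence(self):
        rng = np.random.default_rng(4)
        ids = [f"s{i}" for i in range(20)]
        ps = []
        for rep in range(150):
            D1 = _euclid_dm(rng.normal(size=(20, 3)), ids)
            D2 = _euclid_dm(rng.normal(size=(20, 3)), ids)
            ps.append(integrate.mantel(D1, D2, n_perm=99, seed=rep).p)
        assert 0.03 <= np.mean(np.array(ps) < 0.05) <= 0.07 or \
            abs(np.mean(ps) - 0.5) < 0.06

    def test_mismatched_samples_rejected(self):
        rng = np.random.default_rng(5)
        D1 = _euclid_dm(rng.normal(size=(5, 2)), list("abcde"))
        D2 = _euclid_dm(rng.normal(size=(5, 2)), list("abcdf"))
        with pytest.raises(ValueError, match="different samples"):
            integrate.mantel(D1, D2)


class TestProportionality:
    def test_identity_and_antiproportional_limits(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=30)
        df = pd.DataFrame({"a": x, "b": x, "c": -x})
        rho = integrate.proportionality_rho(df)
        assert rho.loc["a", "b"] == pytest.approx(1.0)
        assert rho.loc["a", "c"] == pytest.approx(-1.0)
        assert rho.loc["a", "a"] == 1.0

    def test_matches_brute_force_formula(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.normal(size=(6, 5)), columns=list("abcde"))
        rho = integrate.proportionality_rho(df)
        for i in "abcde":
            for j in "abcde":
                expected = 1 - np.var(df[i] - df[j], ddof=1) / (
                    np.var(df[i], ddof=1) + np.var(df[j], ddof=1))
                assert rho.loc[i, j] == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_feature_reported_missing(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [5.0, 5.0, 5.0]})
        rho = integrate.proportionality_rho(df)
        assert np.isnan(rho.loc["a", "b"])
        assert np.isnan(rho.loc["b", "b"])


class TestUpdateCutoffs:
    def test_noise_has_high_fdr_at_low_cutoffs(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.normal(size=(40, 12)))
        df.columns = [f"f{i}" for i in range(12)]
        curve = integrate.update_cutoffs(df, n_perm=100, seed=1)
        low = curve.table[curve.table["cutoff"] <= 0.15]
        assert (low["fdr"] > 0.6).all()
        assert low["fdr"].iloc[0] > 0.9

    def test_fdr_curve_nonincreasing_after_clipping(self):
        mi, gt, _ = simulate_coupled(coupled_config(seed=3))
        clr_m = coda.clr(coda.replace_zeros(mi.relative_abundance()))
        clr_i = coda.uss_transform(gt, standardize=False)
        curve = integrate.update_cutoffs(pd.concat([clr_m, clr_i], axis=1),
                                         n_perm=100, seed=0)
        fdr = curve.table["fdr"].to_numpy()
        # ignore flagged (zero-observed) tail entries
        ok = ~curve.table["flagged"].to_numpy()
        assert (np.diff(fdr[ok]) <= 1e-9).all()

    def test_planted_couplings_reach_low_fdr_below_0p6(self):
        mi, gt, _ = simulate_coupled(coupled_config(seed=6))
        clr_m = coda.clr(coda.replace_zeros(mi.relative_abundance()))
        clr_i = coda.uss_transform(gt, standardize=False)
        curve = integrate.update_cutoffs(pd.concat([clr_m, clr_i], axis=1),
                                         n_perm=100, seed=0)
        c = curve.cutoff_for(0.05)
        assert c is not None and c <= 0.6


class TestSpearmanNetwork:
    def test_rank_invariance_under_monotone_transform(self):
        rng = np.random.default_rng(0)
        a = pd.DataFrame({"x": rng.normal(size=25)})
        b = pd.DataFrame({"y": a["x"] * 2 + rng.normal(0, 0.1, 25)})
        e1 = integrate.spearman_clr_network(a, b, r_min=0.5, fdr_max=0.05,
                                            n_boot=20, seed=0)
        e2 = integrate.spearman_clr_network(np.exp(a), b, r_min=0.5,
                                            fdr_max=0.05, n_boot=20, seed=0)
        assert e1.loc[0, "weight"] == pytest.approx(e2.loc[0, "weight"])

    def test_hand_computed_rank_correlation(self):
        a = pd.DataFrame({"x": [3.0, 1.0, 4.0, 1.5, 5.0]})
        b = pd.DataFrame({"y": [2.0, 0.5, 3.5, 1.0, 9.0]})
        # ranks x: 3 1 4 2 5; y: 3 1 4 2 5 -> perfect rank agreement
        e = integrate.spearman_clr_network(a, b, r_min=0.5, fdr_max=0.9,
                                           n_boot=10, seed=0,
                                           influence_screen=False)
        assert e.loc[0, "weight"] == pytest.approx(1.0)

    def test_anticoupled_pair_recovered_with_negative_sign(self):
        cfg = null_config(
            seed=90001,
            coupling_spec=(Coupling("Bacteroides_sp2",
                                    "CD45/CD3+CD19-/CD8+CD4-", -1.5),),
            baseline_overrides={"Bacteroides_sp2": 1.5})
        mi, gt, _ = simulate_coupled(cfg)
        clr_m = coda.clr(coda.replace_zeros(mi.relative_abundance()))
        clr_i = coda.uss_transform(gt, standardize=False)
        edges = integrate.spearman_clr_network(clr_m, clr_i, n_boot=50, seed=0)
        hit = edges[((edges.source == "Bacteroides_sp2")
                     & (edges.target == "CD45/CD3+CD19-/CD8+CD4-"))
                    | ((edges.target == "Bacteroides_sp2")
                       & (edges.source == "CD45/CD3+CD19-/CD8+CD4-"))]
        assert len(hit) == 1
        assert hit.iloc[0]["sign"] == -1
        assert hit.iloc[0]["bootstrap_support"] > 0.8


class TestBuildNetwork:
    def test_empty_edges_with_declared_nodes(self):
        nodes = pd.DataFrame({"type": ["taxon", "immune_cell"]},
                             index=["t1", "c1"])
        G = integrate.build_network(pd.DataFrame(columns=["source", "target",
                                                          "weight"]), nodes)
        assert set(G.nodes) == {"t1", "c1"}
        assert G.number_of_edges() == 0

    def test_edge_count_matches_threshold_passers(self):
        mi, gt, _ = simulate_coupled(coupled_config(seed=4))
        clr_m = coda.clr(coda.replace_zeros(mi.relative_abundance()))
        clr_i = coda.uss_transform(gt, standardize=False)
        edges = integrate.rho_edges(clr_m, clr_i, rho_min=0.45)
        G = integrate.build_network(edges)
        assert G.number_of_edges() == len(edges)

    def test_duplicate_conflicting_edge_rejected(self):
        edges = pd.DataFrame([
            {"source": "a", "target": "b", "weight": 0.7},
            {"source": "b", "target": "a", "weight": 0.9},
        ])
        with pytest.raises(ValueError, match="conflicting"):
            integrate.build_network(edges)

    def test_undeclared_feature_rejected(self):
        nodes = pd.DataFrame({"type": ["taxon"]}, index=["a"])
        edges = pd.DataFrame([{"source": "a", "target": "ghost", "weight": 0.7}])
        with pytest.raises(ValueError, match="undeclared"):
            integrate.build_network(edges, nodes)


class TestCoupledRecovery:
    def test_planted_pairs_recovered_at_rho_cutoff(self):
        """>=4 of 5 planted pairs recovered per run on average."""
        recovered = []
        for s in range(15):
            mi, gt, _ = simulate_coupled(coupled_config(seed=80000 + s))
            clr_m = coda.clr(coda.replace_zeros(mi.relative_abundance()))
            clr_i = coda.uss_transform(gt, standardize=False)
            rho = integrate.proportionality_rho(pd.concat([clr_m, clr_i], axis=1))
            recovered.append(sum(rho.loc[t, n] > 0.45 for t, n in RECOVERY_PAIRS))
        assert np.mean(recovered) >= 4

    def test_zero_loading_yields_no_excess_cross_edges(self):
        cross_counts = []
        for s in range(10):
            cfg = null_config(
                seed=95000 + s,
                coupling_spec=tuple(Coupling(t, n, 0.0) for t, n in RECOVERY_PAIRS))
            mi, gt, _ = simulate_coupled(cfg)
            clr_m = coda.clr(coda.replace_zeros(mi.relative_abundance()))
            clr_i = coda.uss_transform(gt, standardize=False)
            edges = integrate.rho_edges(clr_m, clr_i, rho_min=0.45)
            cross = edges[edges.source_type != edges.target_type]
            cross_counts.append(len(cross))
        n_pairs = 48 * 9  # taxa × immune features
        assert np.mean(cross_counts) / n_pairs < 0.02
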