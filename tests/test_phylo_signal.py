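"""PGLS, diet residualization and local phylogenetic signal (LIPA)."""

import numpy as np
import pandas as pd
import pytest
from skbio import TreeNode

import phylosym as ps
from phylosym.phylo_signal import local_morans_i, phylo_proximity_weights


def star_tree(n, depth=1.0):
    newick = "(" + ",".join(f"t{i}:{depth}" for i in range(n)) + ")root;"
    return TreeNode.read([newick])


class TestBrownianCovariance:
    def test_star_tree_diagonal(self):
        cov = ps.brownian_covariance(star_tree(5, depth=2.0))
        assert np.allclose(cov.to_numpy(), 2.0 * np.eye(5))

    def test_sister_pair_shares_stem(self):
        tree = TreeNode.read(["((a:1.0,b:1.0)ab:0.5,c:1.5)root;"])
        cov = ps.brownian_covariance(tree)
        assert cov.loc["a", "b"] == pytest.approx(0.5)
        assert cov.loc["a", "c"] == 0.0
        assert cov.loc["a", "a"] == pytest.approx(1.5)

    def test_matches_mrca_depth_oracle(self):
        tree, _ = ps.simulate_host_tree(5, seed=3)
        cov = ps.brownian_covariance(tree)
        tips = list(cov.index)
        for a in tips:
            for b in tips:
                ta = [t for t in tree.tips() if t.name == a][0]
                if a == b:
                    expected = tree.distance(ta)
                else:
                    tb = [t for t in tree.tips() if t.name == b][0]
                    mrca = tree.lowest_common_ancestor([a, b])
                    expected = tree.distance(mrca)
                assert cov.loc[a, b] == pytest.approx(expected, abs=1e-9)


class TestPgls:
    def test_star_tree_reduces_to_ols(self):
        tree = star_tree(12)
        rng = np.random.default_rng(0)
        species = [f"t{i}" for i in range(12)]
        y = pd.Series(rng.normal(size=12), index=species)
        x = pd.DataFrame({"x": rng.normal(size=12)}, index=species)
        res = ps.pgls_fit(tree, y, x)
        design = np.column_stack([np.ones(12), x["x"]])
        ols = np.linalg.lstsq(design, y.to_numpy(), rcond=None)[0]
        assert np.allclose(res.coefficients.to_numpy(), ols, atol=1e-10)

    def test_three_tip_closed_form(self):
        tree = TreeNode.read(["((a:1.0,b:1.0)ab:1.0,c:2.0)root;"])
        species = ["a", "b", "c"]
        y = pd.Series([1.0, 2.0, 4.0], index=species)
        x = pd.DataFrame({"x": [0.0, 1.0, 2.0]}, index=species)
        res = ps.pgls_fit(tree, y, x)
        # direct GLS arithmetic: b = (X'C^-1X)^-1 X'C^-1 y
        c = np.array([[2.0, 1.0, 0.0], [1.0, 2.0, 0.0], [0.0, 0.0, 2.0]])
        design = np.column_stack([np.ones(3), x["x"]])
        ci = np.linalg.inv(c)
        beta = np.linalg.solve(design.T @ ci @ design,
                               design.T @ ci @ y.to_numpy())
        assert np.allclose(res.coefficients.to_numpy(), beta, atol=1e-10)

    def test_intercept_shift_only_changes_intercept(self):
        tree, _ = ps.simulate_host_tree(10, seed=1)
        species = [t.name for t in tree.tips()]
        rng = np.random.default_rng(2)
        y = pd.Series(rng.normal(size=10), index=species)
        x = pd.DataFrame({"x": rng.normal(size=10)}, index=species)
        a = ps.pgls_fit(tree, y, x)
        b = ps.pgls_fit(tree, y + 5.0, x)
        assert b.coefficients["intercept"] == pytest.approx(
            a.coefficients["intercept"] + 5.0)
        assert b.coefficients["x"] == pytest.approx(a.coefficients["x"])

    def test_rank_deficient_design_rejected(self):
        tree = star_tree(5)
        species = [f"t{i}" for i in range(5)]
        y = pd.Series(np.arange(5.0), index=species)
        x = pd.DataFrame({"x1": np.ones(5), "x2": np.ones(5)}, index=species)
        with pytest.raises(ValueError, match="rank"):
            ps.pgls_fit(tree, y, x)


class TestPglsScreen:
    def test_five_pcs_give_five_results(self, small_synthetic):
        sub = small_synthetic
        species = [t.name for t in sub.host_tree.tips()]
        rng = np.random.default_rng(3)
        pcs = pd.DataFrame(rng.normal(size=(len(species), 5)),
                           index=species,
                           columns=[f"PC{i+1}" for i in range(5)])
        design = pd.DataFrame({"x": rng.normal(size=len(species))},
                              index=species)
        fam = ps.pgls_screen(sub.host_tree, pcs, design)
        assert len(fam.results) == 5
        assert len(fam.adjusted_p) == 5

    def test_noise_responses_rarely_significant(self):
        tree, _ = ps.simulate_host_tree(20, seed=4)
        species = [t.name for t in tree.tips()]
        rng = np.random.default_rng(5)
        responses = pd.DataFrame(rng.normal(size=(20, 30)), index=species)
        responses.columns = [f"r{i}" for i in range(30)]
        design = pd.DataFrame(
            {"x": rng.integers(0, 2, size=20).astype(float)}, index=species)
        fam = ps.pgls_screen(tree, responses, design)
        assert (fam.adjusted_p < 0.05).sum() <= 2

    def test_planted_diet_otus_rank_first(self):
        # strong diet-guild OTUs should get the smallest adjusted p
        cfg = ps.SimulationConfig(
            n_species=30, extra_sample_mean=0.0, n_heritable=0,
            n_diet_guild=5, diet_log_odds=5.0, diet_intercept=-3.0,
            n_cospeciating=0, n_consortium=0, n_noise=20,
            noise_p_range=(0.2, 0.5), depth=400, seed=6)
        ds = ps.simulate_dataset(cfg)
        pres = ds.table.presence().astype(float)
        sp = ds.metadata.host_species
        pres.index = [sp[s] for s in pres.index]
        keep = pres.columns[(pres.var(axis=0) > 0)]
        design = pd.get_dummies(
            ds.metadata.data["diet_general"], drop_first=True).astype(float)
        design.index = [sp[s] for s in design.index]
        fam = ps.pgls_screen(ds.host_tree, pres[keep], design)
        ranked = fam.adjusted_p.sort_values()
        top = set(ranked.index[:5])
        planted = {o for o in ranked.index if o.startswith("diet")}
        assert len(top & planted) >= 3


class TestRegressOutDiet:
    def _design(self, species, rng):
        return pd.DataFrame({"h": rng.integers(0, 2, len(species)).astype(float)},
                            index=species)

    def test_null_diet_residuals_centered(self):
        rng = np.random.default_rng(7)
        species = [f"sp{i}" for i in range(40)]
        pres = pd.DataFrame({"otu1": rng.integers(0, 2, 40)}, index=species)
        design = pd.DataFrame({"h": np.zeros(40) + rng.normal(0, 1e-8, 40)},
                              index=species)
        res = ps.regress_out_diet(pres, design)
        # no diet effect: deviance residual signs follow centered presence
        signs = np.sign(res.residuals["otu1"].to_numpy())
        expected = np.sign(pres["otu1"].to_numpy() - pres["otu1"].mean())
        assert (signs == expected).all()

    def test_perfect_separation_fallback(self):
        species = [f"sp{i}" for i in range(20)]
        h = np.array([1.0] * 10 + [0.0] * 10)
        pres = pd.DataFrame({"otu1": (h == 1).astype(int)}, index=species)
        design = pd.DataFrame({"h": h}, index=species)
        res = ps.regress_out_diet(pres, design)
        assert "otu1" in res.fallback

    def test_constant_otus_skipped(self):
        species = [f"sp{i}" for i in range(10)]
        pres = pd.DataFrame({"all1": np.ones(10, dtype=int),
                             "all0": np.zeros(10, dtype=int)}, index=species)
        design = pd.DataFrame({"h": np.arange(10.0)}, index=species)
        res = ps.regress_out_diet(pres, design)
        assert set(res.skipped) == {"all1", "all0"}

    def test_matches_irls_oracle(self):
        # independent IRLS implementation of the binomial GLM
        rng = np.random.default_rng(8)
        species = [f"sp{i}" for i in range(60)]
        x = rng.normal(size=60)
        p = 1 / (1 + np.exp(-(0.3 + 0.8 * x)))
        y = (rng.random(60) < p).astype(int)
        pres = pd.DataFrame({"otu1": y}, index=species)
        design = pd.DataFrame({"x": x}, index=species)
        res = ps.regress_out_diet(pres, design)

        beta = np.zeros(2)
        design_m = np.column_stack([np.ones(60), x])
        for _ in range(100):
            eta = design_m @ beta
            mu = 1 / (1 + np.exp(-eta))
            w = mu * (1 - mu)
            z = eta + (y - mu) / w
            wls = np.linalg.solve(design_m.T @ (w[:, None] * design_m),
                                  design_m.T @ (w * z))
            if np.max(np.abs(wls - beta)) < 1e-12:
                beta = wls
                break
            beta = wls
        mu = 1 / (1 + np.exp(-(design_m @ beta)))
        with np.errstate(divide="ignore", invalid="ignore"):
            dev = 2 * (y * np.log(np.where(y == 1, 1 / mu, 1.0))
                       + (1 - y) * np.log(np.where(y == 0, 1 / (1 - mu), 1.0)))
        expected = np.sign(y - mu) * np.sqrt(dev)
        assert np.allclose(res.residuals["otu1"].to_numpy(), expected,
                           atol=1e-8)


class TestLipa:
    def test_clade_indicator_positive_in_clade(self):
        tree = TreeNode.read([
            "(((a:1,b:1):1,(c:1,d:1):1):1,((e:1,f:1):1,(g:1,h:1):1):1)root;"])
        trait = pd.Series([1.0, 1.0, 1.0, 1.0, 0.0, 0.0, 0.0, 0.0],
                          index=list("abcdefgh"))
        res = ps.lipa(tree, trait, n_perm=199, seed=0)
        assert (res.loc[list("abcd"), "I"] > 0).all()

    def test_matches_formula_oracle(self):
        tree, _ = ps.simulate_host_tree(8, seed=10)
        tips = [t.name for t in tree.tips()]
        rng = np.random.default_rng(11)
        trait = pd.Series(rng.normal(size=8), index=tips)
        res = ps.lipa(tree, trait, n_perm=9, seed=1)
        w = phylo_proximity_weights(tree, tips=tips).to_numpy()
        x = trait.to_numpy()
        z = x - x.mean()
        m2 = (z ** 2).sum() / 8
        expected = (z / m2) * (w @ z)
        assert np.allclose(res["I"].to_numpy(), expected, atol=1e-12)

    def test_affine_invariance(self):
        tree, _ = ps.simulate_host_tree(10, seed=12)
        tips = [t.name for t in tree.tips()]
        rng = np.random.default_rng(13)
        trait = pd.Series(rng.normal(size=10), index=tips)
        a = ps.lipa(tree, trait, n_perm=99, seed=2)
        b = ps.lipa(tree, 3.0 * trait + 7.0, n_perm=99, seed=2)
        assert np.allclose(a["I"], b["I"], atol=1e-10)
        assert np.allclose(a["p"], b["p"])

    def test_mean_local_equals_global_moran(self):
        tree, _ = ps.simulate_host_tree(12, seed=14)
        tips = [t.name for t in tree.tips()]
        rng = np.random.default_rng(15)
        x = rng.normal(size=12)
        w = phylo_proximity_weights(tree, tips=tips).to_numpy()
        local = local_morans_i(x, w)
        z = x - x.mean()
        global_i = (12 / w.sum()) * (z @ w @ z) / (z @ z)
        assert local.mean() == pytest.approx(global_i, abs=1e-12)

    def test_constant_trait_rejected(self):
        tree, _ = ps.simulate_host_tree(5, seed=16)
        tips = [t.name for t in tree.tips()]
        with pytest.raises(ValueError, match="constant"):
            ps.lipa(tree, pd.Series(np.ones(5), index=tips), n_perm=9, seed=0)


class TestLipaScreen:
    def test_zero_variance_residuals_excluded(self):
        tree, _ = ps.simulate_host_tree(8, seed=17)
        tips = [t.name for t in tree.tips()]
        rng = np.random.default_rng(18)
        resid = pd.DataFrame({
            "good": rng.normal(size=8),
            "flat": np.zeros(8),
        }, index=tips)
        res = ps.lipa_screen(tree, resid, n_perm=99, seed=3)
        assert res.excluded == ["flat"]
        assert list(res.p_values.columns) == ["good"]

    def test_all_noise_cell_rejection_near_alpha(self):
        tree, _ = ps.simulate_host_tree(15, seed=19)
        tips = [t.name for t in tree.tips()]
        rng = np.random.default_rng(20)
        resid = pd.DataFrame(rng.normal(size=(15, 60)), index=tips,
                             columns=[f"o{i}" for i in range(60)])
        res = ps.lipa_screen(tree, resid, n_perm=99, seed=4)
        frac = res.significant.to_numpy().mean()
        assert 0.01 < frac < 0.10
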