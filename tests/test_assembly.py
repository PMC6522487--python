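"""MPD/MNTD SES, co-occurrence, network structure and IndVal."""

from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import pytest
from skbio import DistanceMatrix

import phylosym as ps
from phylosym.predictors import patristic_distance
from tests.conftest import make_metadata


def presence_frame(rows, samples, otus):
    return pd.DataFrame(rows, index=samples, columns=otus)


@pytest.fixture
def microbe_setup():
    tree, _ = ps.simulate_host_tree(5, seed=30)
    d = patristic_distance(tree)
    return d, list(d.ids)


class TestMpdMntd:
    def test_two_otus_equal_metrics(self, microbe_setup):
        d, otus = microbe_setup
        pres = presence_frame([[1, 1, 0, 0, 0]], ["s"], otus)
        mpd = ps.mpd_mntd(pres, d, "mpd")["s"]
        mntd = ps.mpd_mntd(pres, d, "mntd")["s"]
        assert mpd == pytest.approx(d[otus[0], otus[1]])
        assert mntd == pytest.approx(mpd)

    def test_full_pool_mpd_is_grand_mean(self, microbe_setup):
        d, otus = microbe_setup
        pres = presence_frame([[1] * 5], ["s"], otus)
        tril = np.tril_indices(5, k=-1)
        assert ps.mpd_mntd(pres, d, "mpd")["s"] == pytest.approx(
            d.data[tril].mean())

    def test_matches_enumeration_oracle(self, microbe_setup):
        d, otus = microbe_setup
        pres = presence_frame([[1, 0, 1, 1, 0]], ["s"], otus)
        idx = [0, 2, 3]
        pair_mean = np.mean([d.data[i, j]
                             for i, j in combinations(idx, 2)])
        nearest = np.mean([min(d.data[i, j] for j in idx if j != i)
                           for i in idx])
        assert ps.mpd_mntd(pres, d, "mpd")["s"] == pytest.approx(pair_mean)
        assert ps.mpd_mntd(pres, d, "mntd")["s"] == pytest.approx(nearest)

    def test_single_otu_sample_is_nan(self, microbe_setup):
        d, otus = microbe_setup
        pres = presence_frame([[1, 0, 0, 0, 0]], ["s"], otus)
        assert np.isnan(ps.mpd_mntd(pres, d, "mpd")["s"])


class TestSes:
    def test_full_pool_sample_flagged(self, microbe_setup):
        d, otus = microbe_setup
        pres = presence_frame([[1] * 5], ["s"], otus)
        res = ps.ses(pres, d, metric="mpd", n_perm=49, seed=0)
        assert "s" in res.flagged
        assert np.isnan(res.ses["s"])

    def test_null_communities_centered(self):
        tree, _ = ps.simulate_host_tree(14, seed=31)
        d = patristic_distance(tree)
        otus = list(d.ids)
        rng = np.random.default_rng(1)
        rows = []
        for _ in range(60):
            k = rng.integers(3, 7)
            row = np.zeros(14, dtype=int)
            row[rng.choice(14, size=k, replace=False)] = 1
            rows.append(row)
        pres = presence_frame(rows, [f"s{i}" for i in range(60)], otus)
        res = ps.ses(pres, d, metric="mpd", n_perm=99, seed=2)
        assert abs(np.nanmean(res.ses)) < 0.3
        rej = np.nanmean(res.p.to_numpy() <= 0.05)
        assert rej < 0.15

    def test_clade_confined_community_clustered(self):
        # community restricted to one of two deep clades
        from skbio import TreeNode
        tree = TreeNode.read([
            "(((a:1,b:1):1,(c:1,d:1):1):5,((e:1,f:1):1,(g:1,h:1):1):5)root;"])
        d = tree.tip_tip_distances()
        otus = list(d.ids)
        row = [1 if o in set("abcd") else 0 for o in otus]
        pres = presence_frame([row], ["s"], otus)
        res = ps.ses(pres, d, metric="mpd", n_perm=199, seed=3)
        assert res.ses["s"] < -1.0

    def test_branch_length_scaling_invariant(self, microbe_setup):
        d, otus = microbe_setup
        pres = presence_frame([[1, 1, 0, 1, 0], [0, 1, 1, 1, 0]],
                              ["s1", "s2"], otus)
        res1 = ps.ses(pres, d, metric="mntd", n_perm=99, seed=4)
        d10 = DistanceMatrix(10.0 * d.data, ids=list(d.ids))
        res2 = ps.ses(pres, d10, metric="mntd", n_perm=99, seed=4)
        assert np.allclose(res1.ses.dropna(), res2.ses.dropna(), atol=1e-10)


def cooccur_oracle(n, n1, n2):
    """Exact distribution of the co-occurrence count by enumeration."""
    probs = {}
    for j in range(max(0, n1 + n2 - n), min(n1, n2) + 1):
        probs[j] = (comb(n, j) * comb(n - j, n2 - j) * comb(n - n2, n1 - j)
                    / (comb(n, n1) * comb(n, n2)))
    return probs


class TestCooccur:
    def test_worked_example_p3(self):
        # N=5, both OTUs in 3 samples, all 3 shared
        pres = presence_frame(
            [[1, 1], [1, 1], [1, 1], [0, 0], [0, 0]],
            [f"s{i}" for i in range(5)], ["a", "b"])
        pairs = ps.cooccur_pairs(pres, min_expected=0.0)
        row = pairs.iloc[0]
        assert row["p_gt"] == pytest.approx(0.1)

    def test_ubiquitous_partner_forces_cooccurrence(self):
        pres = presence_frame(
            [[1, 1], [1, 0], [1, 1], [1, 0]],
            [f"s{i}" for i in range(4)], ["everywhere", "b"])
        pairs = ps.cooccur_pairs(pres, min_expected=0.0)
        row = pairs.iloc[0]
        assert row["p_lt"] == pytest.approx(1.0)
        assert row["p_gt"] == pytest.approx(1.0)

    @pytest.mark.parametrize("n,n1,n2", [(5, 3, 3), (8, 4, 6), (12, 5, 7)])
    def test_matches_enumeration_oracle(self, n, n1, n2):
        oracle = cooccur_oracle(n, n1, n2)
        assert sum(oracle.values()) == pytest.approx(1.0, abs=1e-12)
        rows = np.zeros((n, 2), dtype=int)
        rows[:n1, 0] = 1
        rows[n - n2:, 1] = 1
        obs = int((rows[:, 0] & rows[:, 1]).sum())
        pres = presence_frame(rows, [f"s{i}" for i in range(n)], ["a", "b"])
        pairs = ps.cooccur_pairs(pres, min_expected=0.0)
        row = pairs.iloc[0]
        p_lt = sum(v for j, v in oracle.items() if j <= obs)
        p_gt = sum(v for j, v in oracle.items() if j >= obs)
        assert row["p_lt"] == pytest.approx(p_lt, abs=1e-12)
        assert row["p_gt"] == pytest.approx(p_gt, abs=1e-12)

    def test_min_expected_excludes_rare_pairs(self):
        rows = np.zeros((20, 2), dtype=int)
        rows[0, 0] = 1
        rows[1, 1] = 1
        pres = presence_frame(rows, [f"s{i}" for i in range(20)], ["a", "b"])
        assert len(ps.cooccur_pairs(pres, min_expected=1.0)) == 0


class TestNetwork:
    def _pairs_from_edges(self, edges, sign="positive"):
        rows = []
        for a, b in edges:
            rows.append({"otu_a": a, "otu_b": b, "n_a": 5, "n_b": 5,
                         "observed": 5, "expected": 2.0,
                         "p_lt": 1.0 if sign == "positive" else 0.001,
                         "p_gt": 0.001 if sign == "positive" else 1.0})
        return pd.DataFrame(rows)

    def test_two_cliques_two_subnetworks_density_one(self):
        clique1 = list(combinations(["a", "b", "c", "d"], 2))
        clique2 = list(combinations(["w", "x", "y", "z"], 2))
        net = ps.build_network(self._pairs_from_edges(clique1 + clique2))
        assert net.subnetworks.nunique() == 2
        assert (net.density == 1.0).all()
        assert set(net.subnetworks[["a", "b", "c", "d"]]) != \
            set(net.subnetworks[["w", "x", "y", "z"]])

    def test_path_betweenness_closed_form(self):
        net = ps.build_network(self._pairs_from_edges([("A", "B"), ("B", "C")]))
        assert net.betweenness["B"] == pytest.approx(1.0)
        assert net.betweenness["A"] == 0.0

    def test_betweenness_matches_brute_force(self):
        rng = np.random.default_rng(5)
        nodes = [f"n{i}" for i in range(12)]
        edges = [(a, b) for a, b in combinations(nodes, 2)
                 if rng.random() < 0.25]
        net = ps.build_network(self._pairs_from_edges(edges))
        import networkx as nx
        g = nx.Graph(edges)
        expected = nx.betweenness_centrality(g, normalized=False)
        for node, val in expected.items():
            if node in net.betweenness.index:
                assert net.betweenness[node] == pytest.approx(val)

    def test_planted_blocks_recovered(self):
        cfg = ps.SimulationConfig(
            n_species=40, extra_sample_mean=1.0, n_heritable=0,
            n_diet_guild=0, n_cospeciating=0, n_consortium=16,
            consortium_blocks=2, n_noise=40, noise_p_range=(0.05, 0.3),
            depth=400, seed=700)
        ds = ps.simulate_dataset(cfg)
        f = ps.filter_by_prevalence(ds.table, 0.05)
        pairs = ps.cooccur_pairs(f.presence().astype(int))
        net = ps.build_network(pairs)
        blocks = {}
        for otu, row in ds.truth.iterrows():
            if row["class"] == "consortium":
                blocks.setdefault(row["detail"], []).append(otu)
        labels = []
        for members, otus in blocks.items():
            found = [o for o in otus if o in net.subnetworks.index]
            assert len(found) >= len(otus) * 0.75
            labels.append(net.subnetworks[found].mode().iloc[0])
        assert labels[0] != labels[1]


class TestSubnetworkPrevalence:
    def test_ubiquitous_subnetwork_prevalence_one(self):
        pres = presence_frame(np.ones((6, 4), dtype=int),
                              [f"s{i}" for i in range(6)],
                              ["a", "b", "c", "d"])
        meta = make_metadata([f"s{i}" for i in range(6)],
                             ["sp1", "sp1", "sp2", "sp2", "sp3", "sp3"],
                             diets=["herbivore", "herbivore", "omnivore",
                                    "omnivore", "carnivore", "carnivore"])
        pairs = ps.cooccur_pairs(pres, min_expected=0.0)
        net = ps.build_network(
            pd.DataFrame([{"otu_a": "a", "otu_b": "b", "n_a": 6, "n_b": 6,
                           "observed": 6, "expected": 6.0, "p_lt": 1.0,
                           "p_gt": 0.001}]))
        out = ps.subnetwork_prevalence(net, pres, meta, grouping="diet")
        assert (out["prevalence"]["prevalence"] == 1.0).all()
        assert (out["kruskal_wallis"]["p"].dropna() >= 0.99).all()

    def test_planted_herbivore_consortium_ranks_highest(self):
        rng = np.random.default_rng(6)
        samples = [f"s{i}" for i in range(30)]
        species = [f"sp{i // 2}" for i in range(30)]
        diets = ["herbivore" if i < 10 else
                 ("omnivore" if i < 20 else "carnivore") for i in range(30)]
        herb = np.array([d == "herbivore" for d in diets])
        col_a = np.where(herb, 1, (rng.random(30) < 0.1).astype(int))
        col_b = np.where(herb, 1, (rng.random(30) < 0.1).astype(int))
        pres = presence_frame(np.column_stack([col_a, col_b]),
                              samples, ["a", "b"])
        meta = make_metadata(samples, species, diets=diets)
        net = ps.build_network(
            pd.DataFrame([{"otu_a": "a", "otu_b": "b", "n_a": 10, "n_b": 10,
                           "observed": 10, "expected": 3.0, "p_lt": 1.0,
                           "p_gt": 0.001}]))
        out = ps.subnetwork_prevalence(net, pres, meta, grouping="diet")
        prev = out["prevalence"]
        by_group = prev.groupby("group")["prevalence"].mean()
        assert by_group.idxmax() == "herbivore"


class TestIndval:
    def test_perfect_indicator(self):
        rows = ([[10, 1], [8, 1], [12, 1], [9, 1], [11, 1]]
                + [[0, 1]] * 5)
        ab = pd.DataFrame(rows, index=[f"s{i}" for i in range(10)],
                          columns=["ind", "flat"])
        groups = pd.Series(["g1"] * 5 + ["g2"] * 5, index=ab.index)
        res = ps.indval(ab, groups, n_perm=199, seed=0)
        row = res.table.loc["ind"]
        assert row["group"] == "g1"
        assert row["indval"] == pytest.approx(1.0)
        # attainable floor: 2 of C(10,5) label permutations reproduce the
        # perfect split
        assert row["p"] < 0.05

    def test_uniform_taxon_half(self):
        ab = pd.DataFrame({"t": [4, 4, 4, 4]},
                          index=[f"s{i}" for i in range(4)])
        groups = pd.Series(["g1", "g1", "g2", "g2"], index=ab.index)
        res = ps.indval(ab, groups, n_perm=49, seed=1)
        row = res.table.loc["t"]
        assert row["specificity"] == pytest.approx(0.5)
        assert row["fidelity"] == pytest.approx(1.0)
        assert row["indval"] == pytest.approx(0.5)

    def test_specificity_sums_to_one(self):
        rng = np.random.default_rng(2)
        ab = pd.DataFrame(rng.poisson(3, size=(12, 6)),
                          index=[f"s{i}" for i in range(12)],
                          columns=[f"t{j}" for j in range(6)])
        ab += 1                               # no absent taxa
        groups = pd.Series(rng.choice(["g1", "g2", "g3"], size=12),
                           index=ab.index)
        labels = pd.unique(groups)
        means = np.stack([ab[groups == g].mean(axis=0) for g in labels])
        a = means / means.sum(axis=0)
        assert np.allclose(a.sum(axis=0), 1.0)

    def test_shuffled_labels_rarely_significant(self):
        rng = np.random.default_rng(3)
        n_sig = 0
        for rep in range(20):
            ab = pd.DataFrame(rng.poisson(2, size=(16, 8)),
                              index=[f"s{i}" for i in range(16)],
                              columns=[f"t{j}" for j in range(8)]) + 1
            groups = pd.Series(rng.choice(["g1", "g2"], size=16),
                               index=ab.index)
            res = ps.indval(ab, groups, n_perm=99, seed=rep)
            n_sig += int((res.table["adjusted_p"] < 0.05).sum())
        assert n_sig <= 8
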