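"""Community assembly: ecophylogenetic null models, co-occurrence networks,
indicator species analysis, and sub-network prevalence comparisons.

MPD / MNTD standardized effect sizes compare each sample's phylogenetic
dispersion to a taxa-label-shuffle null (negative SES = clustering,
positive = evenness).  Pairwise co-occurrence uses the analytic
hypergeometric model: given two OTUs present in n1 and n2 of N samples,
the number of shared samples follows a hypergeometric distribution, giving
exact lower/upper tail probabilities without permutation.  Significant
pairs form a network whose positive-edge components are refined into
sub-networks by walktrap random-walk community detection.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import igraph
import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from skbio import DistanceMatrix

from .sensitivity import bh_adjust

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# MPD / MNTD and standardized effect sizes
# ---------------------------------------------------------------------------

def mpd_mntd(presence: pd.DataFrame, microbe_d: DistanceMatrix,
             metric: str = "mpd") -> pd.Series:
    """Observed MPD or MNTD per sample.

    MPD is the mean patristic distance over unordered pairs of present
    OTUs; MNTD the mean distance of each present OTU to its nearest other
    present OTU.  Samples with fewer than 2 present OTUs are skipped with
    a log message (NaN in the result).
    """
    if metric not in ("mpd", "mntd"):
        raise ValueError("metric must be 'mpd' or 'mntd'")
    d = microbe_d.filter(list(presence.columns))
    dmat = np.asarray(d.data, dtype=float)
    out = {}
    pres = presence.to_numpy(dtype=bool)
    for i, sid in enumerate(presence.index):
        idx = np.nonzero(pres[i])[0]
        if len(idx) < 2:
            logger.info("sample %s has <2 present OTUs; %s undefined", sid, metric)
            out[sid] = np.nan
            continue
        sub = dmat[np.ix_(idx, idx)]
        if metric == "mpd":
            out[sid] = float(sub[np.triu_indices(len(idx), k=1)].mean())
        else:
            np.fill_diagonal(sub, np.inf)
            out[sid] = float(sub.min(axis=1).mean())
    return pd.Series(out, name=metric)


@dataclass(frozen=True)
class SesResult:
    """Per-sample standardized effect sizes against a taxa-shuffle null."""

    observed: pd.Series
    null_mean: pd.Series
    null_sd: pd.Series
    ses: pd.Series
    p: pd.Series                 # two-sided null-rank p
    metric: str
    n_perm: int
    flagged: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "observed": self.observed, "null_mean": self.null_mean,
            "null_sd": self.null_sd, "ses": self.ses, "p": self.p,
        })


def ses(presence: pd.DataFrame, microbe_d: DistanceMatrix,
        metric: str = "mpd", n_perm: int = 999, seed: int = 0) -> SesResult:
    """SES of MPD or MNTD: (obs - null mean) / null sd per sample.

    The null shuffles OTU labels on the distance matrix (taxa-label null),
    holding each sample's richness fixed.  p is the two-sided null-rank
    quantile.  Samples with zero null sd (e.g. the entire OTU pool
    present) are flagged and get NaN SES.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    otus = list(presence.columns)
    d = microbe_d.filter(otus)
    dmat = np.asarray(d.data, dtype=float)
    n_otus = len(otus)
    obs = mpd_mntd(presence, d, metric)

    rng = np.random.default_rng(seed)
    pres = presence.to_numpy(dtype=bool)
    null = np.full((n_perm, len(presence.index)), np.nan)
    present_idx = [np.nonzero(pres[i])[0] for i in range(pres.shape[0])]
    for k in range(n_perm):
        perm = rng.permutation(n_otus)
        for i, idx in enumerate(present_idx):
            if len(idx) < 2:
                continue
            pidx = perm[idx]
            sub = dmat[np.ix_(pidx, pidx)]
            if metric == "mpd":
                null[k, i] = sub[np.triu_indices(len(pidx), k=1)].mean()
            else:
                np.fill_diagonal(sub, np.inf)
                null[k, i] = sub.min(axis=1).mean()

    with warnings.catch_warnings():
        # all-NaN null columns (skipped samples) are expected
        warnings.simplefilter("ignore", RuntimeWarning)
        null_mean = pd.Series(np.nanmean(null, axis=0), index=presence.index)
        null_sd = pd.Series(np.nanstd(null, axis=0, ddof=1), index=presence.index)
    flagged = []
    ses_vals, p_vals = {}, {}
    for i, sid in enumerate(presence.index):
        o = obs[sid]
        sd = null_sd[sid]
        if not np.isfinite(o):
            ses_vals[sid], p_vals[sid] = np.nan, np.nan
            continue
        if not np.isfinite(sd) or sd <= 1e-10 * max(abs(null_mean[sid]), 1.0):
            flagged.append(str(sid))
            logger.info("sample %s: zero null sd, SES undefined", sid)
            ses_vals[sid], p_vals[sid] = np.nan, np.nan
            continue
        ses_vals[sid] = (o - null_mean[sid]) / sd
        col = null[:, i]
        n_le = int(np.sum(col <= o)) + 1
        n_ge = int(np.sum(col >= o)) + 1
        p_vals[sid] = min(1.0, 2.0 * min(n_le, n_ge) / (n_perm + 1.0))
    return SesResult(
        observed=obs, null_mean=null_mean, null_sd=null_sd,
        ses=pd.Series(ses_vals, name="ses"), p=pd.Series(p_vals, name="p"),
        metric=metric, n_perm=n_perm, flagged=flagged,
    )


# ---------------------------------------------------------------------------
# probabilistic co-occurrence
# ---------------------------------------------------------------------------

def cooccur_pairs(presence: pd.DataFrame,
                  min_expected: float = 1.0) -> pd.DataFrame:
    """Exact pairwise co-occurrence probabilities.

    For OTUs present in n1 and n2 of N samples, the number of shared
    samples j is hypergeometric: P(j) = C(n1,j) C(N-n1,n2-j) / C(N,n2).
    ``p_lt`` is P(J <= observed), ``p_gt`` is P(J >= observed).  Pairs
    whose expected co-occurrence n1*n2/N is below ``min_expected`` are
    excluded.  Returns a frame with one row per retained pair.
    """
    n = presence.shape[0]
    if n == 0:
        raise ValueError("empty presence matrix")
    pres = presence.to_numpy(dtype=bool)
    otus = list(presence.columns)
    occ = pres.sum(axis=0)
    co = pres.T.astype(np.int64) @ pres.astype(np.int64)
    rows = []
    for i, j in combinations(range(len(otus)), 2):
        n1, n2 = int(occ[i]), int(occ[j])
        expected = n1 * n2 / n
        if expected < min_expected:
            continue
        obs = int(co[i, j])
        rv = stats.hypergeom(n, n1, n2)
        rows.append({
            "otu_a": otus[i], "otu_b": otus[j],
            "n_a": n1, "n_b": n2, "observed": obs, "expected": expected,
            "p_lt": float(rv.cdf(obs)),
            "p_gt": float(rv.sf(obs - 1)),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# network construction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CooccurNetwork:
    """Significant co-occurrence network with sub-network structure."""

    graph: nx.Graph                    # all significant edges, sign attribute
    subnetworks: pd.Series             # per node, sub-network label (int)
    betweenness: pd.Series             # per node, shortest-path betweenness
    density: pd.Series                 # per sub-network, edges / possible edges
    edges: pd.DataFrame                # tidy edge list

    def nodes_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "subnetwork": self.subnetworks,
            "betweenness": self.betweenness,
        })


def build_network(pairs: pd.DataFrame, alpha: float = 0.05,
                  walktrap_steps: int = 4) -> CooccurNetwork:
    """Build the significant co-occurrence network and its sub-networks.

    An edge is positive when p_gt < alpha, negative when p_lt < alpha.
    Sub-networks are connected components of the positive-edge graph
    refined by walktrap community detection (random walks of length
    ``walktrap_steps``).  Betweenness is shortest-path betweenness on the
    full significant-edge graph; density is edges / possible edges within
    each sub-network.
    """
    g = nx.Graph()
    edge_rows = []
    for row in pairs.itertuples(index=False):
        if row.p_gt < alpha:
            sign = "positive"
        elif row.p_lt < alpha:
            sign = "negative"
        else:
            continue
        g.add_edge(row.otu_a, row.otu_b, sign=sign,
                   observed=row.observed, expected=row.expected)
        edge_rows.append({
            "otu_a": row.otu_a, "otu_b": row.otu_b, "sign": sign,
            "observed": row.observed, "expected": row.expected,
            "p_lt": row.p_lt, "p_gt": row.p_gt,
        })
    if g.number_of_nodes() == 0:
        logger.info("no significant co-occurrences; empty network")
        empty = pd.Series(dtype=float)
        return CooccurNetwork(graph=g, subnetworks=pd.Series(dtype=int),
                              betweenness=empty, density=empty,
                              edges=pd.DataFrame(edge_rows))

    pos = nx.Graph((u, v) for u, v, d in g.edges(data=True)
                   if d["sign"] == "positive")
    labels: dict[str, int] = {}
    next_label = 0
    for comp in nx.connected_components(pos):
        comp = sorted(comp)
        sub = pos.subgraph(comp)
        if len(comp) <= 2:
            for node in comp:
                labels[node] = next_label
            next_label += 1
            continue
        ig = igraph.Graph()
        ig.add_vertices(comp)
        ig.add_edges([(u, v) for u, v in sub.edges()])
        communities = ig.community_walktrap(steps=walktrap_steps).as_clustering()
        for cluster in communities:
            for vidx in cluster:
                labels[ig.vs[vidx]["name"]] = next_label
            next_label += 1
    # nodes only touched by negative edges get their own singleton labels
    for node in g.nodes:
        if node not in labels:
            labels[node] = next_label
            next_label += 1

    subnet = pd.Series(labels, name="subnetwork")
    btw = pd.Series(nx.betweenness_centrality(g, normalized=False),
                    name="betweenness")
    density = {}
    for lab in sorted(set(labels.values())):
        members = [n for n, l in labels.items() if l == lab]
        k = len(members)
        possible = k * (k - 1) / 2
        within = g.subgraph(members).number_of_edges()
        density[lab] = within / possible if possible > 0 else 0.0
    return CooccurNetwork(
        graph=g, subnetworks=subnet, betweenness=btw,
        density=pd.Series(density, name="density"),
        edges=pd.DataFrame(edge_rows),
    )


def subnetwork_prevalence(network: CooccurNetwork, presence: pd.DataFrame,
                          metadata, grouping: str = "diet") -> dict:
    """Per-species sub-network prevalence and rank tests across groups.

    For each host species, prevalence of a sub-network is the fraction of
    that species' samples containing at least one of the sub-network's
    OTUs.  Per sub-network, a Kruskal-Wallis test compares species-level
    prevalences across groups (host order or general diet), followed by
    pairwise two-sample rank-sum tests with BH adjustment.
    """
    col = {"diet": "diet_general", "order": "order"}[grouping]
    meta = metadata.data
    species_of = meta["host_species"]
    group_of_species = meta.groupby("host_species")[col].first()

    prev_rows = []
    for lab in sorted(set(network.subnetworks)):
        members = [o for o in network.subnetworks.index
                   if network.subnetworks[o] == lab and o in presence.columns]
        if not members:
            continue
        any_member = presence[members].any(axis=1)
        for sp, sids in species_of.groupby(species_of).groups.items():
            sids = [s for s in sids if s in presence.index]
            if not sids:
                continue
            prev_rows.append({
                "subnetwork": lab, "species": sp,
                "group": group_of_species[sp],
                "prevalence": float(any_member.loc[sids].mean()),
            })
    prev = pd.DataFrame(prev_rows)

    kw_rows, pw_rows = [], []
    for lab, sub in prev.groupby("subnetwork"):
        groups = [v["prevalence"].to_numpy() for _, v in sub.groupby("group")]
        names = [g for g, _ in sub.groupby("group")]
        if len(groups) < 2:
            kw_rows.append({"subnetwork": lab, "statistic": np.nan, "p": np.nan})
            continue
        try:
            stat, p = stats.kruskal(*groups)
        except ValueError:          # all values identical: nothing to detect
            stat, p = np.nan, 1.0
        kw_rows.append({"subnetwork": lab, "statistic": stat, "p": p})
        for (ga, xa), (gb, xb) in combinations(zip(names, groups), 2):
            try:
                _, pw_p = stats.mannwhitneyu(xa, xb, alternative="two-sided")
            except ValueError:
                pw_p = np.nan
            pw_rows.append({"subnetwork": lab, "group_a": ga, "group_b": gb,
                            "p": pw_p})
    pairwise = pd.DataFrame(pw_rows)
    if len(pairwise):
        ok = pairwise["p"].notna()
        adj = np.full(len(pairwise), np.nan)
        adj[ok.to_numpy()] = bh_adjust(pairwise.loc[ok, "p"].to_numpy())
        pairwise["adjusted_p"] = adj
    return {
        "prevalence": prev,
        "kruskal_wallis": pd.DataFrame(kw_rows),
        "pairwise": pairwise,
    }


# ---------------------------------------------------------------------------
# IndVal
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IndvalResult:
    """Indicator value (specificity x fidelity) per taxon.

    ``table`` has per taxon: the argmax group, A (specificity), B
    (fidelity), indval, permutation p and BH-adjusted p.
    """

    table: pd.DataFrame
    n_perm: int
    seed: int


def indval(abundance: pd.DataFrame, groups, n_perm: int = 1000,
           seed: int = 0) -> IndvalResult:
    """Indicator species analysis with group-label permutation test.

    A(taxon, g) = mean abundance in g / sum over groups of mean
    abundances; B(taxon, g) = fraction of g's samples where the taxon is
    present; indval = A * B, reported for the argmax group.  p-values come
    from permuting group labels across samples and comparing the permuted
    max-group indval to the observed; BH adjustment is across taxa.
    """
    if isinstance(groups, pd.Series):
        groups = groups.reindex(abundance.index)
    else:
        groups = pd.Series(np.asarray(groups), index=abundance.index)
    labels = pd.unique(groups)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    x = abundance.to_numpy(dtype=float)
    if np.any(x.sum(axis=0) == 0):
        raise ValueError("taxon absent from every sample")
    pres = (x > 0).astype(float)
    group_idx = [np.nonzero((groups == g).to_numpy())[0] for g in labels]

    def indval_matrix(idx_list) -> np.ndarray:
        means = np.stack([x[idx].mean(axis=0) for idx in idx_list])
        fid = np.stack([pres[idx].mean(axis=0) for idx in idx_list])
        denom = means.sum(axis=0)
        a = np.where(denom > 0, means / denom, 0.0)
        return a * fid                          # groups x taxa

    iv_obs = indval_matrix(group_idx)
    best = iv_obs.argmax(axis=0)
    obs_stat = iv_obs.max(axis=0)

    rng = np.random.default_rng(seed)
    n = len(groups)
    sizes = [len(idx) for idx in group_idx]
    count = np.zeros(x.shape[1])
    for _ in range(n_perm):
        perm = rng.permutation(n)
        start = 0
        idx_list = []
        for size in sizes:
            idx_list.append(perm[start:start + size])
            start += size
        iv_perm = indval_matrix(idx_list).max(axis=0)
        count += iv_perm >= obs_stat
    p = (count + 1.0) / (n_perm + 1.0)
    adj = bh_adjust(p)

    means = np.stack([x[idx].mean(axis=0) for idx in group_idx])
    fid = np.stack([pres[idx].mean(axis=0) for idx in group_idx])
    denom = means.sum(axis=0)
    a_mat = np.where(denom > 0, means / denom, 0.0)
    taxa = list(abundance.columns)
    table = pd.DataFrame({
        "group": [labels[b] for b in best],
        "specificity": [a_mat[b, t] for t, b in enumerate(best)],
        "fidelity": [fid[b, t] for t, b in enumerate(best)],
        "indval": obs_stat,
        "p": p,
        "adjusted_p": adj,
    }, index=taxa)
    return IndvalResult(table=table, n_perm=n_perm, seed=seed)
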