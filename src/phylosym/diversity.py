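"""Alpha and beta diversity: Shannon, Faith's PD, UniFrac, PCoA, dispersion.

Beta diversity matrices are ``skbio.DistanceMatrix`` instances (symmetric,
hollow, labeled); principal coordinates analysis supports the Cailliez
additive correction so that non-Euclidean dissimilarities (e.g. many UniFrac
matrices) yield no negative eigenvalues, which downstream Procrustes-based
cophylogeny tests require.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode
from skbio.diversity import alpha_diversity, beta_diversity

from .core import OtuTable

logger = logging.getLogger(__name__)

#: alias documenting the role; all distances in this package use this type
LabeledDistanceMatrix = DistanceMatrix


def distance_to_tsv(dm: DistanceMatrix, path) -> None:
    pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids).to_csv(path, sep="\t")


def distance_from_tsv(path) -> DistanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return DistanceMatrix(df.to_numpy(), ids=[str(i) for i in df.index])


def shannon(table: OtuTable) -> pd.Series:
    """Shannon index H = -sum p_i ln p_i per sample (natural log)."""
    counts = table.counts.astype(float)
    totals = counts.sum(axis=1)
    if np.any(totals == 0):
        bad = [s for s, t in zip(table.sample_ids, totals) if t == 0]
        raise ValueError(f"all-zero samples: {bad}")
    p = counts / totals[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log(p), 0.0)
    h = -terms.sum(axis=1) + 0.0   # avoid negative zero for single-OTU samples
    return pd.Series(h, index=table.sample_ids, name="shannon")


def faiths_pd(table: OtuTable, tree: TreeNode) -> pd.Series:
    """Faith's phylogenetic diversity per sample (root-inclusive).

    Sum of branch lengths of the minimal rooted subtree spanning the tree
    root and all OTUs present in the sample.
    """
    _check_tips(table, tree)
    pd_series = alpha_diversity(
        "faith_pd", table.counts, ids=table.sample_ids, tree=tree,
        taxa=table.otu_ids,
    )
    pd_series.name = "faiths_pd"
    return pd_series


def unifrac(table: OtuTable, tree: TreeNode, weighted: bool = False,
            normalized: bool = True) -> DistanceMatrix:
    """UniFrac distances between samples.

    Unweighted UniFrac is the fraction of branch length unique to one of the
    two samples among the branch length covered by either.  Weighted UniFrac
    is the branch-length-weighted difference of relative abundances; the
    normalized variant (default) keeps values comparable across samples.
    """
    _check_tips(table, tree)
    if weighted:
        return beta_diversity(
            "weighted_unifrac", table.counts, ids=table.sample_ids,
            tree=tree, taxa=table.otu_ids, normalized=normalized,
        )
    return beta_diversity(
        "unweighted_unifrac", table.counts, ids=table.sample_ids,
        tree=tree, taxa=table.otu_ids,
    )


def _check_tips(table: OtuTable, tree: TreeNode) -> None:
    tips = {t.name for t in tree.tips()}
    missing = set(table.otu_ids) - tips
    if missing:
        raise ValueError(f"OTUs missing from tree: {sorted(missing)[:5]} ...")


@dataclass(frozen=True)
class Ordination:
    """Principal coordinates of a dissimilarity matrix.

    ``coordinates`` holds one row per item, axes ordered by decreasing
    eigenvalue; ``correction`` is the Cailliez constant added to
    off-diagonal dissimilarities (0 when no correction was applied or the
    input was already Euclidean).
    """

    coordinates: pd.DataFrame
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray
    correction: float


def _gower_center(a: np.ndarray) -> np.ndarray:
    n = a.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    return j @ a @ j


def cailliez_constant(d: np.ndarray, tol: float = 1e-10) -> float:
    """Smallest additive constant c making D + c (off-diagonal) Euclidean.

    Computed as the largest real eigenvalue of the standard 2n x 2n
    companion matrix built from the Gower-centered -D^2/2 and -D/2.
    """
    n = d.shape[0]
    delta1 = _gower_center(-0.5 * d * d)
    delta2 = _gower_center(-0.5 * d)
    upper = np.hstack([np.zeros((n, n)), 2.0 * delta1])
    lower = np.hstack([-np.eye(n), -4.0 * delta2])
    special = np.vstack([upper, lower])
    eigvals = np.linalg.eigvals(special)
    c = float(np.max(eigvals.real))
    return max(c, 0.0) if c > tol else 0.0


def pcoa(dm: DistanceMatrix, cailliez: bool = False,
         eig_tol: float = 1e-10) -> Ordination:
    """Principal coordinates analysis, optionally Cailliez-corrected.

    Eigendecomposition of the double-centered -D*D/2 matrix.  With
    ``cailliez=True`` the smallest constant c is first added to every
    off-diagonal dissimilarity such that the corrected matrix is Euclidean
    (all eigenvalues >= -1e-10).  Axes with eigenvalue <= ``eig_tol`` are
    dropped from the coordinates.
    """
    d = np.asarray(dm.data, dtype=float)
    correction = 0.0
    if cailliez:
        correction = cailliez_constant(d)
        if correction > 0.0:
            d = d + correction
            np.fill_diagonal(d, 0.0)
    b = _gower_center(-0.5 * d * d)
    eigvals, eigvecs = np.linalg.eigh(b)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]
    pos = eigvals > eig_tol
    coords = eigvecs[:, pos] * np.sqrt(eigvals[pos])
    positive_sum = eigvals[eigvals > 0].sum()
    prop = np.where(eigvals > 0, eigvals, 0.0) / positive_sum if positive_sum > 0 else eigvals * 0
    cols = [f"PC{i + 1}" for i in range(coords.shape[1])]
    return Ordination(
        coordinates=pd.DataFrame(coords, index=list(dm.ids), columns=cols),
        eigenvalues=eigvals,
        proportion_explained=prop,
        correction=correction,
    )


@dataclass(frozen=True)
class BetaDispersion:
    """Within-group dispersion: distances of members to the group centroid."""

    group_dispersion: pd.Series            # per group, mean distance to centroid
    sample_distances: pd.Series            # per sample, distance to its centroid
    groups: pd.Series                      # per sample group label


def beta_dispersion(dm: DistanceMatrix, groups) -> BetaDispersion:
    """Beta-dispersion: per-group mean distance to the group centroid.

    Works in the full PCoA space including negative-eigenvalue axes;
    squared distances on imaginary axes are subtracted from those on real
    axes (the standard multivariate-dispersion convention for
    non-Euclidean dissimilarities).  Singleton groups get dispersion 0
    with a warning.
    """
    if isinstance(groups, pd.Series):
        groups = groups.reindex(list(dm.ids))
        if groups.isna().any():
            raise ValueError("group labels missing for some samples")
    else:
        groups = pd.Series(np.asarray(groups), index=list(dm.ids))
    d = np.asarray(dm.data, dtype=float)
    b = _gower_center(-0.5 * d * d)
    eigvals, eigvecs = np.linalg.eigh(b)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    keep = np.abs(eigvals) > 1e-10
    eigvals, eigvecs = eigvals[keep], eigvecs[:, keep]
    coords = eigvecs * np.sqrt(np.abs(eigvals))
    is_real = eigvals > 0

    sample_d = pd.Series(0.0, index=list(dm.ids))
    group_d = {}
    for g in pd.unique(groups):
        members = groups.index[groups == g]
        idx = [list(dm.ids).index(m) for m in members]
        if len(idx) == 1:
            logger.warning("singleton group %s: dispersion set to 0", g)
            group_d[g] = 0.0
            sample_d.loc[members[0]] = 0.0
            continue
        centroid = coords[idx].mean(axis=0)
        sq = (coords[idx] - centroid) ** 2
        sq_real = sq[:, is_real].sum(axis=1)
        sq_imag = sq[:, ~is_real].sum(axis=1)
        dist = np.sqrt(np.maximum(sq_real - sq_imag, 0.0))
        sample_d.loc[members] = dist
        group_d[g] = float(dist.mean())
    return BetaDispersion(
        group_dispersion=pd.Series(group_d, name="dispersion"),
        sample_distances=sample_d,
        groups=groups,
    )
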