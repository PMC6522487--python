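"""Predictor distance matrices for regression on distance matrices.

Host phylogeny is represented by patristic distance, detailed diet /
habitat / technical covariates by Gower distance, geography by great-circle
distance, and alpha diversity by pairwise absolute difference.  All members
of a :class:`PredictorSet` share one label set and order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode

from .core import SampleMetadata

logger = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0


@dataclass(frozen=True)
class PredictorSet:
    """Named predictor distance matrices sharing one label order."""

    members: dict[str, DistanceMatrix]

    def __post_init__(self) -> None:
        ids = None
        for name, dm in self.members.items():
            if ids is None:
                ids = dm.ids
            elif dm.ids != ids:
                raise ValueError(f"predictor {name} has mismatched labels")

    @property
    def ids(self) -> tuple:
        return next(iter(self.members.values())).ids

    def __getitem__(self, name: str) -> DistanceMatrix:
        return self.members[name]

    def names(self) -> list[str]:
        return list(self.members)


def patristic_distance(tree: TreeNode) -> DistanceMatrix:
    """Pairwise sum of branch lengths along the tree path between tips."""
    for node in tree.traverse(include_self=False):
        if node.length is None:
            raise ValueError("tree has missing branch lengths")
    return tree.tip_tip_distances()


def gower_distance(variables: pd.DataFrame) -> DistanceMatrix:
    """Gower dissimilarity over mixed-type variables.

    Per-variable dissimilarity is a mismatch indicator for binary or
    categorical variables and |xi - xj| / range for numeric ones; the Gower
    distance is the mean over variables non-missing in both rows.
    Zero-range numeric variables are excluded with a warning.
    """
    if variables.shape[1] == 0:
        raise ValueError("need at least one variable")
    n = variables.shape[0]
    num = np.zeros((n, n))
    den = np.zeros((n, n))
    for col in variables.columns:
        x = variables[col]
        valid = x.notna().to_numpy()
        pair_valid = np.outer(valid, valid)
        is_float = pd.api.types.is_float_dtype(x)
        if is_float and x.dropna().nunique() <= 1:
            # zero-range continuous variable: |xi-xj|/range undefined
            logger.warning("zero-range numeric variable %s excluded", col)
            continue
        if pd.api.types.is_numeric_dtype(x) and x.dropna().nunique() > 2:
            vals = x.to_numpy(dtype=float)
            rng = np.nanmax(vals) - np.nanmin(vals)
            with np.errstate(invalid="ignore"):
                diff = np.abs(vals[:, None] - vals[None, :]) / rng
            diff = np.where(pair_valid, diff, 0.0)
        else:
            codes = pd.factorize(x, use_na_sentinel=True)[0]
            diff = (codes[:, None] != codes[None, :]).astype(float)
            diff = np.where(pair_valid, diff, 0.0)
        num += diff
        den += pair_valid
    if not den.any():
        logger.warning("all variables excluded; Gower distance is zero")
        return DistanceMatrix(np.zeros((n, n)),
                              ids=[str(i) for i in variables.index])
    if np.any(den == 0):
        raise ValueError("some sample pairs share no non-missing variables")
    d = num / den
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2
    return DistanceMatrix(d, ids=[str(i) for i in variables.index])


def great_circle_distance(latitudes, longitudes, ids=None) -> DistanceMatrix:
    """Haversine distances in km on a sphere of radius 6371 km."""
    lat = np.asarray(latitudes, dtype=float)
    lon = np.asarray(longitudes, dtype=float)
    if np.any((lat < -90) | (lat > 90)):
        raise ValueError("latitude out of range")
    if np.any((lon <= -180) | (lon > 180)):
        raise ValueError("longitude out of range")
    if ids is None:
        if isinstance(latitudes, pd.Series):
            ids = [str(i) for i in latitudes.index]
        else:
            ids = [str(i) for i in range(len(lat))]
    phi = np.radians(lat)
    lam = np.radians(lon)
    dphi = phi[:, None] - phi[None, :]
    dlam = lam[:, None] - lam[None, :]
    a = (np.sin(dphi / 2) ** 2
         + np.cos(phi)[:, None] * np.cos(phi)[None, :] * np.sin(dlam / 2) ** 2)
    a = np.clip(a, 0.0, 1.0)
    d = 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a))
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2
    return DistanceMatrix(d, ids=ids)


def euclidean_alpha(alpha: pd.Series) -> DistanceMatrix:
    """Pairwise |a_i - a_j| distance for a scalar alpha-diversity vector."""
    vals = alpha.to_numpy(dtype=float)
    if not np.all(np.isfinite(vals)):
        raise ValueError("non-finite alpha diversity values")
    d = np.abs(vals[:, None] - vals[None, :])
    return DistanceMatrix(d, ids=[str(i) for i in alpha.index])


def build_predictor_set(host_tree: TreeNode, metadata: SampleMetadata,
                        sample_ids=None) -> PredictorSet:
    """Assemble the standard predictor set on a shared label order.

    ``host_tree`` must carry one tip per sample (i.e. the grafted tree).
    Members: phylogeny (patristic), diet (Gower over detailed-diet binary
    components), habitat (Gower over habitat components), geography
    (great-circle), technical (Gower over sample type + captivity).
    """
    ids = list(sample_ids) if sample_ids is not None else metadata.sample_ids
    meta = metadata.select_samples(ids)
    phylo = patristic_distance(host_tree).filter(ids)
    diet = gower_distance(meta.diet_detailed())
    habitat = gower_distance(meta.habitat())
    geo = great_circle_distance(meta.data["latitude"], meta.data["longitude"])
    tech = gower_distance(meta.technical())
    return PredictorSet({
        "phylogeny": phylo,
        "diet": diet,
        "habitat": habitat,
        "geography": geo,
        "technical": tech,
    })
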