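"""Core data model and I/O for host-associated microbiome analyses.

The central objects are an OTU count table (samples x OTUs), two rooted
phylogenies (a dated host tree and a microbial 16S tree), and a per-sample
metadata table carrying host identity, taxonomy, diet, habitat, coordinates
and technical covariates.  All downstream modules consume these containers.

Conventions
-----------
* Tables are oriented samples x OTUs everywhere.
* Trees are ``skbio.TreeNode`` instances; host branch lengths are in time
  units (Myr), microbial branch lengths in substitutions/site.
* Rarefaction draws reads without replacement (multivariate hypergeometric);
  samples whose library is below the target depth are dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import TreeNode

logger = logging.getLogger(__name__)

#: metadata columns that must be present in every SampleMetadata table
REQUIRED_METADATA_COLUMNS = (
    "host_species",
    "class",
    "order",
    "family",
    "genus",
    "species",
    "diet_general",
    "latitude",
    "longitude",
    "sample_type",
    "captivity",
)

DIET_GENERAL_LEVELS = ("herbivore", "omnivore", "carnivore")
SAMPLE_TYPES = ("feces", "gut_contents")
CAPTIVITY_LEVELS = ("wild", "captive")

#: column prefixes for binary detailed-diet and habitat components
DIET_PREFIX = "diet__"
HABITAT_PREFIX = "hab__"


@dataclass(frozen=True)
class OtuTable:
    """Samples x OTUs table of non-negative integer counts."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.index.duplicated().any():
            raise ValueError("duplicate sample IDs in OTU table")
        if df.columns.duplicated().any():
            raise ValueError("duplicate OTU IDs in OTU table")
        values = df.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValueError("OTU table counts must be numeric")
        if np.any(values < 0):
            raise ValueError("OTU table counts must be non-negative")
        if not np.allclose(values, np.round(values)):
            raise ValueError("OTU table counts must be integral")
        object.__setattr__(self, "data", df.astype(np.int64))

    # -- accessors ---------------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def otu_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def counts(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_otus(self) -> int:
        return self.data.shape[1]

    def presence(self) -> pd.DataFrame:
        """Boolean presence/absence view (counts > 0)."""
        return self.data > 0

    def prevalence(self) -> pd.Series:
        """Per-OTU fraction of samples where present."""
        return (self.data > 0).mean(axis=0)

    # -- I/O ---------------------------------------------------------------
    @classmethod
    def from_tsv(cls, path) -> "OtuTable":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        return cls(df)

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index_label="sample")

    def select_samples(self, sample_ids) -> "OtuTable":
        return OtuTable(self.data.loc[list(sample_ids)])

    def select_otus(self, otu_ids) -> "OtuTable":
        return OtuTable(self.data[list(otu_ids)])


@dataclass(frozen=True)
class SampleMetadata:
    """Per-sample host and environmental metadata.

    Detailed-diet and habitat components are binary columns prefixed with
    ``diet__`` and ``hab__`` respectively.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.index.duplicated().any():
            raise ValueError("duplicate sample IDs in metadata")
        missing = [c for c in REQUIRED_METADATA_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"metadata missing required columns: {missing}")
        lat = df["latitude"].astype(float)
        lon = df["longitude"].astype(float)
        if ((lat < -90) | (lat > 90)).any():
            raise ValueError("latitude out of [-90, 90]")
        if ((lon <= -180) | (lon > 180)).any():
            raise ValueError("longitude out of (-180, 180]")
        bad_diet = set(df["diet_general"]) - set(DIET_GENERAL_LEVELS)
        if bad_diet:
            raise ValueError(f"unknown diet_general levels: {sorted(bad_diet)}")
        for col in self.diet_detailed_columns(df) + self.habitat_columns(df):
            vals = set(pd.unique(df[col]))
            if not vals <= {0, 1}:
                raise ValueError(f"column {col} must be binary 0/1")

    @staticmethod
    def diet_detailed_columns(df: pd.DataFrame) -> list[str]:
        return [c for c in df.columns if c.startswith(DIET_PREFIX)]

    @staticmethod
    def habitat_columns(df: pd.DataFrame) -> list[str]:
        return [c for c in df.columns if c.startswith(HABITAT_PREFIX)]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def host_species(self) -> pd.Series:
        return self.data["host_species"]

    def diet_detailed(self) -> pd.DataFrame:
        return self.data[self.diet_detailed_columns(self.data)]

    def habitat(self) -> pd.DataFrame:
        return self.data[self.habitat_columns(self.data)]

    def technical(self) -> pd.DataFrame:
        """Technical covariates: sample type and captivity status."""
        return self.data[["sample_type", "captivity"]]

    def samples_by_unit(self, unit: str = "species") -> dict[str, list[str]]:
        """Map each host unit (species or family) to its sample IDs."""
        col = {"species": "host_species", "family": "family"}[unit]
        out: dict[str, list[str]] = {}
        for sid, val in self.data[col].items():
            out.setdefault(val, []).append(sid)
        return out

    @classmethod
    def from_tsv(cls, path) -> "SampleMetadata":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index = df.index.astype(str)
        return cls(df)

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index_label="sample")

    def select_samples(self, sample_ids) -> "SampleMetadata":
        return SampleMetadata(self.data.loc[list(sample_ids)])


def read_tree(path) -> TreeNode:
    """Read a rooted newick tree with branch lengths."""
    tree = TreeNode.read(str(path), format="newick")
    for node in tree.traverse(include_self=False):
        if node.length is None:
            node.length = 0.0
        if node.length < 0:
            raise ValueError("negative branch length in tree")
    names = [t.name for t in tree.tips()]
    if len(names) != len(set(names)):
        raise ValueError("duplicate tip labels in tree")
    return tree


@dataclass
class Dataset:
    """A cross-validated bundle of the four core inputs."""

    table: OtuTable
    host_tree: TreeNode
    microbe_tree: TreeNode
    metadata: SampleMetadata
    dropped_otus: list[str] = field(default_factory=list)


def load_dataset(otu_table_path, host_tree_path, microbe_tree_path,
                 metadata_path) -> Dataset:
    """Load and cross-reference the four dataset files.

    Samples must be present in both the table and the metadata; every host
    species in the metadata must resolve to a host-tree tip.  OTUs absent
    from the microbe tree are dropped (logged).
    """
    table = OtuTable.from_tsv(otu_table_path)
    metadata = SampleMetadata.from_tsv(metadata_path)
    host_tree = read_tree(host_tree_path)
    microbe_tree = read_tree(microbe_tree_path)

    missing_meta = set(table.sample_ids) - set(metadata.sample_ids)
    if missing_meta:
        raise ValueError(
            f"samples in OTU table missing from metadata: {sorted(missing_meta)}"
        )
    extra_meta = set(metadata.sample_ids) - set(table.sample_ids)
    if extra_meta:
        logger.info("dropping %d metadata rows without counts", len(extra_meta))
        metadata = metadata.select_samples(
            [s for s in metadata.sample_ids if s not in extra_meta])

    host_tips = {t.name for t in host_tree.tips()}
    missing_species = set(metadata.host_species) - host_tips
    if missing_species:
        raise ValueError(
            f"host species missing from host tree: {sorted(missing_species)}"
        )

    microbe_tips = {t.name for t in microbe_tree.tips()}
    dropped = [o for o in table.otu_ids if o not in microbe_tips]
    if dropped:
        logger.info("dropping %d OTUs absent from microbe tree", len(dropped))
        table = table.select_otus([o for o in table.otu_ids if o in microbe_tips])

    metadata = metadata.select_samples(table.sample_ids)
    return Dataset(table, host_tree, microbe_tree, metadata, dropped)


def rarefy(table: OtuTable, depth: int, seed: int) -> OtuTable:
    """Rarefy every sample to exactly ``depth`` reads without replacement.

    Samples with fewer than ``depth`` total reads are dropped (logged).
    Sampling is multivariate hypergeometric and deterministic given ``seed``.
    """
    if depth <= 0:
        raise ValueError("rarefaction depth must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    kept = []
    for sid in table.sample_ids:
        row = table.data.loc[sid].to_numpy()
        total = int(row.sum())
        if total < depth:
            logger.info("dropping sample %s: %d reads < depth %d", sid, total, depth)
            continue
        if total == depth:
            rows.append(row.copy())
        else:
            rows.append(rng.multivariate_hypergeometric(row, depth))
        kept.append(sid)
    if not kept:
        raise ValueError("no sample reaches the rarefaction depth")
    df = pd.DataFrame(np.asarray(rows), index=kept, columns=table.otu_ids)
    return OtuTable(df)


def filter_by_prevalence(table: OtuTable, min_fraction: float) -> OtuTable:
    """Keep OTUs present in strictly more than ``min_fraction`` of samples."""
    if not 0 <= min_fraction < 1:
        raise ValueError("min_fraction must be in [0, 1)")
    keep = table.prevalence() > min_fraction
    return OtuTable(table.data.loc[:, keep])


def graft_sample_tips(species_tree: TreeNode, metadata: SampleMetadata,
                      epsilon: float | None = None) -> TreeNode:
    """Graft per-sample tips onto the species-level host tree.

    Each species tip with k >= 2 samples becomes a polytomy of k sample tips,
    each on a branch of length ``epsilon``; single-sample species tips are
    relabeled to the sample ID.  ``epsilon`` defaults to 1e-6 of the median
    root-to-tip depth (a negligible branch length on the tree's time scale).
    """
    tree = species_tree.copy()
    tips = {t.name: t for t in tree.tips()}
    by_species = metadata.samples_by_unit("species")
    unmatched = set(by_species) - set(tips)
    if unmatched:
        raise ValueError(f"species not in tree: {sorted(unmatched)}")
    if epsilon is None:
        depths = [tree.distance(t) for t in tree.tips()]
        epsilon = 1e-6 * float(np.median(depths))
    for species, samples in by_species.items():
        tip = tips[species]
        if len(samples) == 1:
            tip.name = samples[0]
        else:
            tip.name = None
            for sid in samples:
                tip.append(TreeNode(name=sid, length=epsilon))
    return tree


def species_level_profile(table: OtuTable, metadata: SampleMetadata,
                          depth: int, seed: int) -> OtuTable:
    """Pool reads per host species and subsample ``depth`` reads per species.

    Species whose pooled library is below ``depth`` are dropped with a
    warning.  Deterministic given ``seed``.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    rng = np.random.default_rng(seed)
    rows, kept = [], []
    for species, samples in metadata.samples_by_unit("species").items():
        samples = [s for s in samples if s in table.data.index]
        if not samples:
            continue
        pooled = table.data.loc[samples].sum(axis=0).to_numpy()
        total = int(pooled.sum())
        if total < depth:
            logger.warning("species %s pooled reads %d < depth %d; dropped",
                           species, total, depth)
            continue
        if total == depth:
            rows.append(pooled)
        else:
            rows.append(rng.multivariate_hypergeometric(pooled, depth))
        kept.append(species)
    data = (np.asarray(rows) if rows
            else np.empty((0, table.n_otus), dtype=np.int64))
    df = pd.DataFrame(data, index=kept, columns=table.otu_ids)
    return OtuTable(df)
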