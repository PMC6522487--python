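"""Synthetic vertebrate gut microbiome datasets with planted structure.

The generator emulates the statistical structure the analyses in this
package assume, with ground-truth labels for recovery tests:

* a dated, ultrametric host phylogeny with nested clade (class/order/
  family/genus) labels derived from the tree;
* host traits: a general diet evolved as a 3-state Markov process on the
  tree (phylogenetically conserved yet convergent, so diet and phylogeny
  can be decoupled), binary detailed-diet components noisily consistent
  with the general diet, habitat fields, and clade-clustered coordinates;
* five OTU classes: *heritable* OTUs whose presence follows a Brownian
  liability on the host tree, *diet-guild* OTUs keyed to one diet
  component, *cospeciating* clades confined to one host clade with the
  microbial subtree mirroring the host clade topology, *consortium* OTUs
  driven by a shared latent sample factor (positive co-occurrence blocks),
  and i.i.d. low-prevalence *noise* OTUs;
* counts drawn lognormal-multinomial at a fixed sequencing depth.

Defaults reproduce the study conditions: 128 host species, 1-11 samples
per species (mean ~1.7), and ~98% of OTUs detected in <=5% of samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import TreeNode

from .core import OtuTable, SampleMetadata

DIET_STATES = ("herbivore", "omnivore", "carnivore")

#: binary diet components and their probability given each general diet
DIET_COMPONENTS = {
    "diet__leaves":        {"herbivore": 0.8, "omnivore": 0.4, "carnivore": 0.02},
    "diet__grass":         {"herbivore": 0.7, "omnivore": 0.3, "carnivore": 0.02},
    "diet__fruit":         {"herbivore": 0.5, "omnivore": 0.6, "carnivore": 0.05},
    "diet__seeds":         {"herbivore": 0.4, "omnivore": 0.5, "carnivore": 0.05},
    "diet__invertebrates": {"herbivore": 0.05, "omnivore": 0.6, "carnivore": 0.7},
    "diet__vertebrates":   {"herbivore": 0.02, "omnivore": 0.4, "carnivore": 0.9},
    "diet__carrion":       {"herbivore": 0.02, "omnivore": 0.2, "carnivore": 0.4},
    "diet__fish":          {"herbivore": 0.02, "omnivore": 0.2, "carnivore": 0.4},
}

HABITAT_FIELDS = ("hab__forest", "hab__grassland", "hab__wetland", "hab__urban")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic generator.

    ``diet_switch_expected`` is the expected number of general-diet state
    changes along one root-to-tip path; ~1.5 keeps diet phylogenetically
    conserved while producing convergent states across clades.
    """

    n_species: int = 128
    extra_sample_mean: float = 0.7        # samples per species = 1 + truncated geometric
    max_samples_per_species: int = 11
    tree_depth: float = 400.0             # Myr
    n_heritable: int = 15
    n_diet_guild: int = 10
    n_cospeciating: int = 30
    n_consortium: int = 16
    n_noise: int = 2000
    heritable_slope: float = 2.0          # liability -> logit slope
    heritable_intercept: float = -2.0
    diet_log_odds: float = 3.0
    diet_intercept: float = -3.0
    cospec_within_p: float = 0.8
    cospec_clade_size: tuple = (4, 10)
    consortium_blocks: int = 2
    consortium_slope: float = 2.5
    consortium_intercept: float = -1.5
    noise_p_range: tuple = (0.001, 0.03)  # log-uniform baseline presence
    diet_switch_expected: float = 1.5
    diet_component_noise: float = 0.05
    depth: int = 5000
    seed: int = 0


@dataclass
class SyntheticDataset:
    """Generated dataset plus per-OTU ground truth."""

    table: OtuTable
    host_tree: TreeNode
    microbe_tree: TreeNode
    metadata: SampleMetadata
    truth: pd.DataFrame            # per OTU: class + planted parameters
    config: SimulationConfig


# ---------------------------------------------------------------------------
# host tree
# ---------------------------------------------------------------------------

def _yule_tree(n_tips: int, rng: np.random.Generator,
               depth: float, prefix: str = "sp") -> TreeNode:
    """Ultrametric pure-birth tree scaled to a fixed depth."""
    if n_tips < 3:
        raise ValueError("need at least 3 tips")
    root = TreeNode()
    root._birth = 0.0
    c1, c2 = TreeNode(), TreeNode()
    for c in (c1, c2):
        c._birth = 0.0
        root.append(c)
    active = [c1, c2]
    t = 0.0
    while len(active) < n_tips:
        t += rng.exponential(1.0 / len(active))
        node = active.pop(int(rng.integers(len(active))))
        a, b = TreeNode(), TreeNode()
        for c in (a, b):
            c._birth = t
            node.append(c)
        active.extend([a, b])
    total = t + rng.exponential(1.0 / len(active))
    scale = depth / total
    # branch lengths: internal nodes end where their first child begins
    for node in root.traverse(include_self=False):
        end = node.children[0]._birth if node.children else total
        node.length = (end - node._birth) * scale
    width = len(str(n_tips))
    for i, tip in enumerate(root.tips()):
        tip.name = f"{prefix}{i + 1:0{width}d}"
    for node in root.traverse():
        if hasattr(node, "_birth"):
            del node._birth
    return root


def _clade_labels(tree: TreeNode, depth: float) -> pd.DataFrame:
    """Nested class/order/family/genus labels cut at fixed tree depths."""
    cuts = {"class": 0.15 * depth, "order": 0.45 * depth,
            "family": 0.7 * depth, "genus": 0.85 * depth}
    rows = {t.name: {} for t in tree.tips()}
    for level, cut in cuts.items():
        counter = 0
        assigned: dict[int, str] = {}

        def walk(node, start):
            nonlocal counter
            for child in node.children:
                end = start + (child.length or 0.0)
                if end >= cut > start or (child.is_tip() and end < cut):
                    counter += 1
                    label = f"{level[0]}{counter:02d}"
                    for tip in ([child] if child.is_tip() else child.tips()):
                        rows[tip.name][level] = label
                else:
                    walk(child, end)

        walk(tree, 0.0)
    df = pd.DataFrame(rows).T
    df["species"] = df.index
    return df[["class", "order", "family", "genus", "species"]]


def simulate_host_tree(n_species: int, seed: int,
                       depth: float = 400.0) -> tuple[TreeNode, pd.DataFrame]:
    """Pure-birth dated host tree plus nested taxonomy labels."""
    rng = np.random.default_rng(seed)
    tree = _yule_tree(n_species, rng, depth)
    taxonomy = _clade_labels(tree, depth)
    return tree, taxonomy


# ---------------------------------------------------------------------------
# traits
# ---------------------------------------------------------------------------

def _markov_diet(tree: TreeNode, rate: float,
                 rng: np.random.Generator) -> dict[str, str]:
    """3-state symmetric Markov diet process down the tree.

    ``rate`` is the rate of redraw events (uniform over the 3 states,
    including the current one); P(unchanged over t) = e^{-rate t} +
    (1 - e^{-rate t}) / 3.
    """
    states = {}

    def walk(node, state):
        for child in node.children:
            t = child.length or 0.0
            if rng.random() < 1.0 - np.exp(-rate * t):
                new_state = DIET_STATES[rng.integers(3)]
            else:
                new_state = state
            if child.is_tip():
                states[child.name] = new_state
            else:
                walk(child, new_state)

    walk(tree, DIET_STATES[rng.integers(3)])
    return states


def _brownian_tips(tree: TreeNode, rng: np.random.Generator) -> pd.Series:
    """Brownian trait at the tips (unit rate), standardized to z-scores."""
    values = {}

    def walk(node, value):
        for child in node.children:
            v = value + rng.normal(0.0, np.sqrt(child.length or 0.0))
            if child.is_tip():
                values[child.name] = v
            else:
                walk(child, v)

    walk(tree, 0.0)
    s = pd.Series(values)
    sd = s.std(ddof=0)
    return (s - s.mean()) / (sd if sd > 0 else 1.0)


def simulate_traits(tree: TreeNode, config: SimulationConfig,
                    seed: int) -> pd.DataFrame:
    """Per-species diet, detailed diet components, habitat and coordinates."""
    rng = np.random.default_rng(seed)
    rate = config.diet_switch_expected / config.tree_depth
    diet = _markov_diet(tree, rate, rng)
    species = [t.name for t in tree.tips()]

    rows = {}
    # clade-clustered geography: one center per top-level clade
    top_clades = tree.children
    centers = {}
    for i, clade in enumerate(top_clades):
        centers[i] = (float(rng.uniform(-55, 65)), float(rng.uniform(-170, 170)))
    clade_of = {}
    for i, clade in enumerate(top_clades):
        for tip in ([clade] if clade.is_tip() else clade.tips()):
            clade_of[tip.name] = i

    for sp in species:
        d = diet[sp]
        row = {"diet_general": d}
        for comp, probs in DIET_COMPONENTS.items():
            row[comp] = int(rng.random() < probs[d])
        for i, hab in enumerate(HABITAT_FIELDS):
            # habitat loosely follows the top-level clade
            base = 0.7 if (clade_of[sp] + i) % len(HABITAT_FIELDS) == 0 else 0.15
            row[hab] = int(rng.random() < base)
        lat0, lon0 = centers[clade_of[sp]]
        row["latitude"] = float(np.clip(lat0 + rng.normal(0, 8), -90, 90))
        lon = lon0 + rng.normal(0, 8)
        row["longitude"] = float((lon + 180) % 360 - 180)
        if row["longitude"] == -180.0:
            row["longitude"] = 180.0
        rows[sp] = row
    return pd.DataFrame(rows).T.loc[species]


# ---------------------------------------------------------------------------
# presence
# ---------------------------------------------------------------------------

def _logistic(x):
    return 1.0 / (1.0 + np.exp(-x))


def _pick_clades(tree: TreeNode, size_range: tuple,
                 rng: np.random.Generator, n_needed: int) -> list[list[str]]:
    """Disjoint host clades with tip counts in ``size_range``."""
    lo, hi = size_range
    candidates = []
    for node in tree.non_tips():
        tips = [t.name for t in node.tips()]
        if lo <= len(tips) <= hi:
            candidates.append(tips)
    rng.shuffle(candidates)
    chosen: list[list[str]] = []
    used: set[str] = set()
    for tips in candidates:
        if used.isdisjoint(tips):
            chosen.append(tips)
            used.update(tips)
        if sum(len(c) for c in chosen) >= n_needed:
            break
    if not chosen:
        raise ValueError("no host clade matches the requested size range")
    return chosen


def simulate_presence(tree: TreeNode, traits: pd.DataFrame,
                      metadata: SampleMetadata, config: SimulationConfig,
                      seed: int) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sample x OTU presence matrix plus per-OTU truth labels."""
    rng = np.random.default_rng(seed)
    samples = metadata.sample_ids
    species_of = metadata.host_species
    n_samples = len(samples)

    presence: dict[str, np.ndarray] = {}
    truth_rows = []

    # heritable: Brownian liability on the host tree -> logistic presence
    for k in range(config.n_heritable):
        liab = _brownian_tips(tree, rng)
        p = _logistic(config.heritable_intercept
                      + config.heritable_slope * liab.loc[species_of].to_numpy())
        otu = f"herit{k + 1:03d}"
        presence[otu] = (rng.random(n_samples) < p).astype(np.int8)
        truth_rows.append({"otu": otu, "class": "heritable",
                           "parameter": config.heritable_slope, "detail": ""})

    # diet guild: logit shifted by one binary diet component
    components = list(DIET_COMPONENTS)
    for k in range(config.n_diet_guild):
        comp = components[k % len(components)]
        x = metadata.data[comp].to_numpy(dtype=float)
        p = _logistic(config.diet_intercept + config.diet_log_odds * x)
        otu = f"diet{k + 1:03d}"
        presence[otu] = (rng.random(n_samples) < p).astype(np.int8)
        truth_rows.append({"otu": otu, "class": "diet_guild",
                           "parameter": config.diet_log_odds, "detail": comp})

    # cospeciating: confined to one host clade; subtree mirrors the clade
    cospec_clades: list[tuple[str, list[str]]] = []
    if config.n_cospeciating > 0:
        clades = _pick_clades(tree, config.cospec_clade_size, rng,
                              config.n_cospeciating)
        counter = 0
        for g, clade_tips in enumerate(clades):
            if counter >= config.n_cospeciating:
                break
            group = f"cospec_g{g + 1}"
            for tip_name in clade_tips:
                if counter >= config.n_cospeciating:
                    break
                counter += 1
                otu = f"cospec{counter:03d}"
                in_clade = species_of.isin(clade_tips).to_numpy()
                anchored = (species_of == tip_name).to_numpy()
                p = np.where(anchored, 0.95,
                             np.where(in_clade, config.cospec_within_p, 0.0))
                presence[otu] = (rng.random(n_samples) < p).astype(np.int8)
                cospec_clades.append((otu, tip_name))
                truth_rows.append({"otu": otu, "class": "cospeciating",
                                   "parameter": config.cospec_within_p,
                                   "detail": f"{group}:{tip_name}",
                                   "clade": ",".join(clade_tips)})

    # consortium: shared latent sample factor per block
    per_block = max(config.n_consortium // max(config.consortium_blocks, 1), 1)
    counter = 0
    for b in range(config.consortium_blocks):
        u = rng.normal(0.0, 1.0, n_samples)
        for _ in range(per_block):
            if counter >= config.n_consortium:
                break
            counter += 1
            otu = f"consort{counter:03d}"
            p = _logistic(config.consortium_intercept + config.consortium_slope * u)
            presence[otu] = (rng.random(n_samples) < p).astype(np.int8)
            truth_rows.append({"otu": otu, "class": "consortium",
                               "parameter": config.consortium_slope,
                               "detail": f"block{b + 1}"})

    # noise: i.i.d. at a low, OTU-specific baseline
    lo, hi = config.noise_p_range
    base = np.exp(rng.uniform(np.log(lo), np.log(hi), config.n_noise))
    for k in range(config.n_noise):
        otu = f"noise{k + 1:05d}"
        presence[otu] = (rng.random(n_samples) < base[k]).astype(np.int8)
        truth_rows.append({"otu": otu, "class": "noise",
                           "parameter": base[k], "detail": ""})

    pres_df = pd.DataFrame(presence, index=samples)
    truth = pd.DataFrame(truth_rows).set_index("otu")
    return pres_df, truth


# ---------------------------------------------------------------------------
# counts and microbe tree
# ---------------------------------------------------------------------------

def simulate_counts(presence: pd.DataFrame, depth: int,
                    seed: int) -> OtuTable:
    """Lognormal-multinomial counts at fixed depth, respecting presence.

    Every present OTU receives at least one read; the remaining reads are
    split multinomially with lognormal relative weights.
    """
    rng = np.random.default_rng(seed)
    counts = np.zeros(presence.shape, dtype=np.int64)
    pres = presence.to_numpy(dtype=bool)
    for i in range(presence.shape[0]):
        idx = np.nonzero(pres[i])[0]
        if len(idx) == 0:
            continue
        k = len(idx)
        counts[i, idx] = 1
        remaining = depth - k
        if remaining > 0:
            w = rng.lognormal(0.0, 1.0, k)
            counts[i, idx] += rng.multinomial(remaining, w / w.sum())
    return OtuTable(pd.DataFrame(counts, index=presence.index,
                                 columns=presence.columns))


def simulate_microbe_tree(host_tree: TreeNode, truth: pd.DataFrame,
                          seed: int, depth: float = 1.0) -> TreeNode:
    """Random OTU tree in which each cospeciating group's subtree mirrors
    its host clade topology; all other OTUs attach randomly."""
    rng = np.random.default_rng(seed)
    cospec = truth[truth["class"] == "cospeciating"]
    groups: dict[str, dict[str, str]] = {}
    for otu, row in cospec.iterrows():
        group, host_tip = row["detail"].split(":")
        groups.setdefault(group, {})[host_tip] = otu

    other = [o for o in truth.index if truth.loc[o, "class"] != "cospeciating"]
    backbone_tips = other + [f"__{g}__" for g in groups]
    tree = _yule_tree(max(len(backbone_tips), 3), rng, depth, prefix="bb")
    tips = list(tree.tips())
    rng.shuffle(backbone_tips)
    for tip, name in zip(tips, backbone_tips):
        tip.name = name
    for tip in tips[len(backbone_tips):]:
        tip.name = f"pad{tip.name}"

    host_depth = max(host_tree.distance(t) for t in host_tree.tips())
    for g, mapping in groups.items():
        placeholder = next(t for t in tree.tips() if t.name == f"__{g}__")
        if len(mapping) == 1:
            placeholder.name = next(iter(mapping.values()))
            continue
        host_clade = host_tree.lowest_common_ancestor(list(mapping))
        sub = host_clade.copy()
        scale = 0.25 * depth / host_depth
        for node in sub.traverse(include_self=False):
            node.length = (node.length or 0.0) * scale
        kept = []
        for tip in list(sub.tips()):
            if tip.name in mapping:
                tip.name = mapping[tip.name]
                kept.append(tip)
            else:
                tip.name = f"__drop__{tip.name}"
        drop = [t.name for t in sub.tips() if t.name.startswith("__drop__")]
        if drop:
            sub = sub.shear([t.name for t in sub.tips()
                             if not t.name.startswith("__drop__")])
        if len(kept) == 1 or sub.count(tips=True) == 1:
            placeholder.name = list(mapping.values())[0]
            continue
        sub.length = placeholder.length
        parent = placeholder.parent
        parent.remove(placeholder)
        parent.append(sub)
    return tree


# ---------------------------------------------------------------------------
# full dataset
# ---------------------------------------------------------------------------

def _sample_counts_per_species(config: SimulationConfig,
                               rng: np.random.Generator) -> np.ndarray:
    """1 + truncated-geometric extra samples (mean ~1.7, max 11)."""
    q = config.extra_sample_mean / (1.0 + config.extra_sample_mean)
    extra = rng.geometric(1.0 - q, size=config.n_species) - 1
    extra = np.minimum(extra, config.max_samples_per_species - 1)
    return 1 + extra


def simulate_dataset(config: SimulationConfig | None = None) -> SyntheticDataset:
    """Generate a full synthetic dataset; a pure function of the config."""
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed)
    seeds = rng.integers(0, 2**31 - 1, size=6)

    host_tree, taxonomy = simulate_host_tree(config.n_species, int(seeds[0]),
                                             depth=config.tree_depth)
    traits = simulate_traits(host_tree, config, int(seeds[1]))

    # per-sample metadata
    counts_per_species = _sample_counts_per_species(config,
                                                    np.random.default_rng(int(seeds[2])))
    meta_rng = np.random.default_rng(int(seeds[3]))
    rows = []
    for sp, n_s in zip(taxonomy.index, counts_per_species):
        for i in range(n_s):
            sid = f"{sp}_s{i + 1}"
            row = {"sample": sid, "host_species": sp}
            row.update(taxonomy.loc[sp].to_dict())
            tr = traits.loc[sp]
            row["diet_general"] = tr["diet_general"]
            for comp in DIET_COMPONENTS:
                val = int(tr[comp])
                if meta_rng.random() < config.diet_component_noise:
                    val = 1 - val
                row[comp] = val
            for hab in HABITAT_FIELDS:
                row[hab] = int(tr[hab])
            row["latitude"] = float(tr["latitude"])
            row["longitude"] = float(tr["longitude"])
            row["sample_type"] = ("feces" if meta_rng.random() < 0.8
                                  else "gut_contents")
            row["captivity"] = "wild" if meta_rng.random() < 0.85 else "captive"
            rows.append(row)
    metadata = SampleMetadata(pd.DataFrame(rows).set_index("sample"))

    presence, truth = simulate_presence(host_tree, traits, metadata, config,
                                        int(seeds[4]))
    table = simulate_counts(presence, config.depth, int(seeds[5]))
    microbe_tree = simulate_microbe_tree(host_tree, truth, int(seeds[5]) + 1)
    return SyntheticDataset(table=table, host_tree=host_tree,
                            microbe_tree=microbe_tree, metadata=metadata,
                            truth=truth, config=config)


def sparsity_summary(table: OtuTable, threshold: float = 0.05) -> float:
    """Fraction of OTUs detected in <= ``threshold`` of samples."""
    prev = table.prevalence()
    return float((prev <= threshold).mean())
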