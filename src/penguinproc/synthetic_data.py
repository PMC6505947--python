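"""Generators for synthetic phylogenies, metacommunities and study designs.

Communities are drawn under controlled assembly regimes — neutral
(multinomial drift), trait-based environmental filtering (variable or
homogeneous selection) and patch-restricted sampling (dispersal
limitation) — so downstream null-model partitioning can be validated
against a known ground truth.  All generators are pure functions of their
parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .io_formats import (
    OtuTable,
    PhyloTree,
    RANKS,
    SampleMetadata,
    TaxonomyMap,
    tree_from_newick,
)

__all__ = [
    "Metacommunity",
    "GroupSpec",
    "ScenarioConfig",
    "REGIMES",
    "simulate_tree",
    "evolve_trait",
    "make_metacommunity",
    "simulate_neutral",
    "simulate_selection",
    "simulate_dispersal_limited",
    "simulate_study",
    "taxonomy_from_tree",
    "default_scenario",
]

REGIMES = ("neutral", "variable_selection", "homogeneous_selection", "dispersal_limited")


@dataclass
class Metacommunity:
    """Regional species pool: relative abundances on the simplex."""

    taxon_ids: list[str]
    abundances: np.ndarray
    occupancy_weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        a = np.asarray(self.abundances, dtype=float)
        if len(a) != len(self.taxon_ids):
            raise ValueError("abundances length != taxon_ids length")
        if len(a) == 0:
            raise ValueError("empty metacommunity")
        if a.min() < 0:
            raise ValueError("abundances must be >= 0")
        if abs(a.sum() - 1.0) > 1e-12:
            raise ValueError("abundances must sum to 1")
        self.abundances = a
        if self.occupancy_weights is None:
            self.occupancy_weights = np.ones(len(a))
        else:
            w = np.asarray(self.occupancy_weights, dtype=float)
            if len(w) != len(a) or w.min() < 0:
                raise ValueError("bad occupancy weights")
            self.occupancy_weights = w


# ---------------------------------------------------------------------------
# phylogeny
# ---------------------------------------------------------------------------


class _Node:
    __slots__ = ("children", "length", "label")

    def __init__(self) -> None:
        self.children: list["_Node"] = []
        self.length = 0.0
        self.label: str | None = None


def _to_newick(node: _Node) -> str:
    if not node.children:
        return f"{node.label}:{node.length:.12g}"
    inner = ",".join(_to_newick(c) for c in node.children)
    return f"({inner}):{node.length:.12g}"


def simulate_tree(
    n_tips: int,
    seed: int,
    birth_rate: float = 1.0,
    ultrametric: bool = True,
    label_width: int = 4,
) -> PhyloTree:
    """Pure-birth (Yule) tree with ``n_tips`` labelled tips.

    Ultrametric by default: all tips end at the same age.  With
    ``ultrametric=False`` each terminal branch is additionally stretched by
    an exponential jitter.  Deterministic given the seed.
    """
    if n_tips < 2:
        raise ValueError("n_tips must be >= 2")
    rng = np.random.default_rng([int(seed), 0x7EEE])
    root = _Node()
    active: list[tuple[_Node, float]] = []
    t = 0.0
    for _ in range(2):
        child = _Node()
        root.children.append(child)
        active.append((child, t))
    while len(active) < n_tips:
        t += rng.exponential(1.0 / (birth_rate * len(active)))
        i = int(rng.integers(len(active)))
        node, birth = active.pop(i)
        node.length = t - birth
        for _ in range(2):
            child = _Node()
            node.children.append(child)
            active.append((child, t))
    t_end = t + rng.exponential(1.0 / (birth_rate * n_tips))
    for node, birth in active:
        node.length = t_end - birth
        if not ultrametric:
            node.length += rng.exponential(0.1 * t_end)
    # label tips in left-to-right order
    counter = 0
    stack = [root]
    while stack:
        node = stack.pop()
        if node.children:
            stack.extend(reversed(node.children))
        else:
            counter += 1
            node.label = f"Otu{counter:0{label_width}d}"
    newick = f"({','.join(_to_newick(c) for c in root.children)});"
    return tree_from_newick(newick)


def evolve_trait(tree: PhyloTree, sigma: float, seed: int) -> dict[str, float]:
    """Brownian motion along branches: child = parent + N(0, sigma^2 * length).

    Root value is 0; returns tip label -> trait value.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    rng = np.random.default_rng([int(seed), 0x7471])
    values: dict[int, float] = {}
    traits: dict[str, float] = {}
    for node in tree.tree.preorder_node_iter():
        if node.parent_node is None:
            values[id(node)] = 0.0
        else:
            length = node.edge.length or 0.0
            step = rng.normal(0.0, sigma * np.sqrt(length)) if sigma > 0 and length > 0 else 0.0
            values[id(node)] = values[id(node.parent_node)] + step
        if node.is_leaf():
            traits[node.taxon.label] = values[id(node)]
    return traits


# ---------------------------------------------------------------------------
# metacommunity and community generators
# ---------------------------------------------------------------------------


def make_metacommunity(
    taxon_ids: Sequence[str],
    rank_exponent: float = 1.2,
    seed: int | None = None,
) -> Metacommunity:
    """Skewed rank-abundance pool: abundance of rank r proportional to r^-exponent.

    If a seed is given, ranks are shuffled over taxa (decoupling abundance
    from tip order); otherwise taxa keep rank order.
    """
    s = len(taxon_ids)
    if s == 0:
        raise ValueError("empty taxon list")
    ranks = np.arange(1, s + 1, dtype=float)
    weights = ranks ** (-rank_exponent)
    if seed is not None:
        rng = np.random.default_rng([int(seed), 0x3E7A])
        weights = weights[rng.permutation(s)]
    return Metacommunity(list(taxon_ids), weights / weights.sum())


def _sample_ids(n: int, prefix: str) -> list[str]:
    return [f"{prefix}{i + 1:02d}" for i in range(n)]


def simulate_neutral(
    meta: Metacommunity,
    n_samples: int,
    depth: int,
    seed: int,
    prefix: str = "S",
    concentration: float | None = None,
) -> OtuTable:
    """Drift-dominated communities.

    By default each sample is an independent multinomial(depth,
    metacommunity) draw.  With ``concentration`` set, each sample first
    perturbs the metacommunity by a Dirichlet draw with that total
    concentration (smaller = stronger demographic drift) before the
    multinomial, so between-sample variation exceeds pure sampling noise.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = np.random.default_rng([int(seed), 0x0EA7])
    if concentration is None:
        counts = rng.multinomial(depth, meta.abundances, size=n_samples)
    else:
        if concentration <= 0:
            raise ValueError("concentration must be > 0")
        counts = np.empty((n_samples, len(meta.taxon_ids)), dtype=np.int64)
        alpha = concentration * meta.abundances
        alpha = np.clip(alpha, 1e-9, None)
        for i in range(n_samples):
            p = rng.dirichlet(alpha)
            counts[i] = rng.multinomial(depth, p)
    return OtuTable(_sample_ids(n_samples, prefix), list(meta.taxon_ids), counts)


def simulate_selection(
    meta: Metacommunity,
    traits: Mapping[str, float],
    env: Sequence[float],
    sigma_f: float,
    depth: int,
    seed: int,
    prefix: str = "S",
) -> OtuTable:
    """Environmental filtering: sample i drawn multinomial with weights
    proportional to metacommunity abundance times a Gaussian filter
    exp(-(trait - env_i)^2 / (2 sigma_f^2)).
    """
    if sigma_f <= 0:
        raise ValueError("sigma_f must be > 0")
    missing = [t for t in meta.taxon_ids if t not in traits]
    if missing:
        raise ValueError(f"traits missing for taxa: {missing[:5]}...")
    rng = np.random.default_rng([int(seed), 0x5E1E])
    trait_vec = np.array([traits[t] for t in meta.taxon_ids])
    counts = np.empty((len(env), len(meta.taxon_ids)), dtype=np.int64)
    for i, e in enumerate(env):
        w = meta.abundances * np.exp(-((trait_vec - e) ** 2) / (2.0 * sigma_f**2))
        total = w.sum()
        if total <= 0:
            raise ValueError(
                f"degenerate filter: all weights underflowed to zero at env={e}"
            )
        counts[i] = rng.multinomial(depth, w / total)
    return OtuTable(_sample_ids(len(env), prefix), list(meta.taxon_ids), counts)


def simulate_dispersal_limited(
    meta: Metacommunity,
    n_patches: int,
    patch_mix: float,
    n_samples: int,
    depth: int,
    seed: int,
    prefix: str = "S",
) -> OtuTable:
    """Patch-restricted sampling.

    Taxa are partitioned into ``n_patches`` random subpools; each sample
    draws from its patch's restricted pool mixed with the full
    metacommunity by ``patch_mix`` (1 = fully neutral, 0 = fully
    restricted).
    """
    if n_patches < 1:
        raise ValueError("n_patches must be >= 1")
    if not 0.0 <= patch_mix <= 1.0:
        raise ValueError("patch_mix must be in [0, 1]")
    rng = np.random.default_rng([int(seed), 0xD15B])
    s = len(meta.taxon_ids)
    patch_of_taxon = rng.integers(n_patches, size=s)
    patch_of_sample = np.arange(n_samples) % n_patches
    rng.shuffle(patch_of_sample)
    counts = np.empty((n_samples, s), dtype=np.int64)
    for i in range(n_samples):
        mask = patch_of_taxon == patch_of_sample[i]
        restricted = meta.abundances * mask
        if restricted.sum() == 0:
            raise ValueError(f"patch {patch_of_sample[i]} contains no taxa")
        restricted = restricted / restricted.sum()
        p = patch_mix * meta.abundances + (1.0 - patch_mix) * restricted
        counts[i] = rng.multinomial(depth, p / p.sum())
    return OtuTable(_sample_ids(n_samples, prefix), list(meta.taxon_ids), counts)


# ---------------------------------------------------------------------------
# taxonomy from tree clades
# ---------------------------------------------------------------------------

_RANK_PREFIX = {"phylum": "Phy", "class": "Cls", "order": "Ord", "family": "Fam", "genus": "Gen"}


def taxonomy_from_tree(
    tree: PhyloTree,
    fracs: Sequence[float] = (0.15, 0.3, 0.45, 0.6, 0.75),
) -> TaxonomyMap:
    """Assign a 6-rank lineage to every tip by cutting the tree at increasing
    depth fractions; tips in the same clade at a cut share that rank's label.
    """
    if len(fracs) != len(RANKS) - 1:
        raise ValueError("need one depth fraction per rank below domain")
    tree.tree.calc_node_root_distances(return_leaf_distances_only=False)
    tip_depths = [leaf.root_distance for leaf in tree.tree.leaf_node_iter()]
    scale = min(tip_depths)
    if scale <= 0:
        raise ValueError("tree has a tip at zero depth")
    lineages: dict[str, list[str]] = {label: ["Bacteria"] for label in tree.tip_labels}
    for rank, frac in zip(RANKS[1:], fracs):
        threshold = frac * scale
        prefix = _RANK_PREFIX[rank]
        clade_idx = 0
        for node in tree.tree.preorder_node_iter():
            if node.parent_node is None:
                continue
            parent_d = node.parent_node.root_distance
            if node.root_distance >= threshold and parent_d < threshold:
                clade_idx += 1
                label = f"{prefix}{clade_idx:03d}"
                for leaf in node.leaf_iter():
                    lineages[leaf.taxon.label].append(label)
    return TaxonomyMap({t: tuple(l) for t, l in lineages.items()})


# ---------------------------------------------------------------------------
# full study scenario
# ---------------------------------------------------------------------------


@dataclass
class GroupSpec:
    """One species x stage cell of the design."""

    species: str
    stage: str
    n_samples: int
    regime: str
    env: list[float] | None = None  # per-sample environment (selection regimes)

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be positive")
        if self.regime not in REGIMES:
            raise ValueError(f"unknown regime {self.regime!r}; expected one of {REGIMES}")
        if self.env is not None and len(self.env) != self.n_samples:
            raise ValueError("env length must equal n_samples")


@dataclass
class ScenarioConfig:
    """Parameters of a synthetic 2-species x 2-stage study."""

    groups: list[GroupSpec]
    n_taxa: int = 500
    depth: int = 20000
    trait_sigma: float = 1.0
    filter_sigma: float = 0.35
    rank_exponent: float = 1.2
    n_patches: int = 4
    patch_mix: float = 0.0
    drift_concentration: float | None = 150.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValueError("at least one group required")
        if self.n_taxa < 2 or self.depth < 1:
            raise ValueError("n_taxa and depth must be positive")
        if self.filter_sigma <= 0:
            raise ValueError("filter_sigma must be > 0")
        if self.trait_sigma < 0:
            raise ValueError("trait_sigma must be >= 0")


def default_scenario(seed: int = 0, **overrides) -> ScenarioConfig:
    """The 7/6/7/5 two-species design: selection while feeding, drift while
    moulting."""
    groups = [
        GroupSpec("chinstrap", "feeding", 7, "variable_selection"),
        GroupSpec("chinstrap", "moulting", 6, "neutral"),
        GroupSpec("gentoo", "feeding", 7, "variable_selection"),
        GroupSpec("gentoo", "moulting", 5, "neutral"),
    ]
    return ScenarioConfig(groups=groups, seed=seed, **overrides)


#: Trait quantiles cycled over samples under variable selection: three
#: well-separated niches give strong, consistent between-niche turnover.
_NICHE_QUANTILES = (0.1, 0.5, 0.9)


def _default_env(traits: np.ndarray, regime: str, n: int) -> np.ndarray:
    if regime == "variable_selection":
        qs = [_NICHE_QUANTILES[i % len(_NICHE_QUANTILES)] for i in range(n)]
        return np.quantile(traits, qs)
    # homogeneous selection: every sample filtered toward the same optimum
    return np.full(n, float(np.quantile(traits, 0.5)))


def simulate_study(
    cfg: ScenarioConfig,
) -> tuple[OtuTable, PhyloTree, SampleMetadata, TaxonomyMap]:
    """Simulate one complete study: OTU table (all groups), phylogeny,
    metadata and clade-derived taxonomy, mutually consistent and
    byte-deterministic given the seed.
    """
    tree = simulate_tree(cfg.n_taxa, seed=cfg.seed)
    traits = evolve_trait(tree, cfg.trait_sigma, seed=cfg.seed)
    meta_pool = make_metacommunity(
        tree.tip_labels, rank_exponent=cfg.rank_exponent, seed=cfg.seed
    )
    trait_vec = np.array([traits[t] for t in meta_pool.taxon_ids])
    tables: list[OtuTable] = []
    factors: dict[str, tuple[str, str]] = {}
    for gi, group in enumerate(cfg.groups):
        prefix = f"{group.species[:2]}_{group.stage[:4]}_"
        gseed = cfg.seed * 1000 + gi
        if group.regime == "neutral":
            sub = simulate_neutral(
                meta_pool, group.n_samples, cfg.depth, gseed, prefix,
                concentration=cfg.drift_concentration,
            )
        elif group.regime in ("variable_selection", "homogeneous_selection"):
            env = (
                np.asarray(group.env, dtype=float)
                if group.env is not None
                else _default_env(trait_vec, group.regime, group.n_samples)
            )
            sub = simulate_selection(
                meta_pool, traits, env, cfg.filter_sigma, cfg.depth, gseed, prefix
            )
        else:  # dispersal_limited
            sub = simulate_dispersal_limited(
                meta_pool, cfg.n_patches, cfg.patch_mix,
                group.n_samples, cfg.depth, gseed, prefix,
            )
        tables.append(sub)
        for sample in sub.sample_ids:
            factors[sample] = (group.species, group.stage)
    sample_ids = [s for t in tables for s in t.sample_ids]
    counts = np.vstack([t.counts for t in tables])
    table = OtuTable(sample_ids, list(meta_pool.taxon_ids), counts)
    taxonomy = taxonomy_from_tree(tree)
    return table, tree, SampleMetadata(factors), taxonomy
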