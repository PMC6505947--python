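"""Phylogenetic null-model partitioning of community-assembly processes.

Abundance-weighted between-community mean nearest taxon distance (bMNTD),
its standardized effect size against a tip-label-shuffle null (bNTI), a
probabilistic reassembly null on Bray-Curtis (the Raup-Crick variant,
RC_bray), and the five-way classification of pairwise turnover into
variable selection, homogeneous selection, dispersal limitation,
homogenizing dispersal and drift.

Null reproducibility: each null stream is derived from the master seed plus
a structural key (iteration index or sample pair), so results do not depend
on evaluation order.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .community_matrix import bray_curtis_pair
from .io_formats import ConsistencyError, OtuTable, PhyloTree, SampleMetadata

__all__ = [
    "PROCESSES",
    "TaxonDistanceMatrix",
    "BetaNtiMatrix",
    "RcMatrix",
    "ProcessSummary",
    "cophenetic_distances",
    "beta_mntd",
    "beta_nti",
    "raup_crick_bray",
    "classify_pair",
    "summarize_processes",
]

logger = logging.getLogger(__name__)

PROCESSES = (
    "variable_selection",
    "homogeneous_selection",
    "dispersal_limitation",
    "homogenizing_dispersal",
    "drift",
)


@dataclass
class TaxonDistanceMatrix:
    """Patristic (cophenetic) distances between taxa."""

    taxon_ids: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        n = len(self.taxon_ids)
        if d.shape != (n, n):
            raise ValueError("distance matrix shape inconsistent with taxon ids")
        if not np.allclose(d, d.T, atol=1e-9):
            raise ValueError("taxon distances not symmetric")
        if not np.allclose(np.diag(d), 0.0, atol=1e-12):
            raise ValueError("taxon distance diagonal not zero")
        self.d = d


@dataclass
class BetaNtiMatrix:
    """Pairwise standardized effect sizes of bMNTD (NaN where not computed
    or where the null SD collapsed to zero)."""

    sample_ids: list[str]
    bnti: np.ndarray
    n_null: int
    weighted: bool


@dataclass
class RcMatrix:
    """Pairwise Raup-Crick scores on Bray-Curtis, in [-1, +1]."""

    sample_ids: list[str]
    rc: np.ndarray
    n_null: int


@dataclass
class ProcessSummary:
    """Per-group percentage of within-group pairs assigned to each process."""

    percentages: pd.DataFrame  # index: group label, columns: PROCESSES
    n_pairs: pd.Series  # valid (classified) pairs per group
    pair_table: pd.DataFrame  # long form: sample_i, sample_j, group, bnti, rc, process


# ---------------------------------------------------------------------------
# cophenetic distances
# ---------------------------------------------------------------------------


def cophenetic_distances(
    tree: PhyloTree, taxon_order: Sequence[str] | None = None
) -> TaxonDistanceMatrix:
    """Patristic distance between every pair of tips (sum of branch lengths
    along the connecting path)."""
    labels = tree.tip_labels
    index = {label: i for i, label in enumerate(labels)}
    if len(index) != len(labels):
        raise ValueError("duplicate tip labels")
    n = len(labels)
    d = np.zeros((n, n))
    # post-order merge: carry (tip index, distance-to-node) lists upward
    carry: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for node in tree.tree.postorder_node_iter():
        if node.is_leaf():
            carry[id(node)] = (
                np.array([index[node.taxon.label]]),
                np.zeros(1),
            )
            continue
        parts: list[tuple[np.ndarray, np.ndarray]] = []
        for child in node.child_nodes():
            idx, dist = carry.pop(id(child))
            parts.append((idx, dist + (child.edge.length or 0.0)))
        for (ia, da), (ib, db) in itertools.combinations(parts, 2):
            block = da[:, None] + db[None, :]
            d[np.ix_(ia, ib)] = block
            d[np.ix_(ib, ia)] = block.T
        carry[id(node)] = (
            np.concatenate([p[0] for p in parts]),
            np.concatenate([p[1] for p in parts]),
        )
    if taxon_order is not None:
        missing = [t for t in taxon_order if t not in index]
        if missing:
            raise ConsistencyError(f"taxa absent from tree: {missing}")
        order = [index[t] for t in taxon_order]
        return TaxonDistanceMatrix(list(taxon_order), d[np.ix_(order, order)])
    return TaxonDistanceMatrix(labels, d)


# ---------------------------------------------------------------------------
# bMNTD / bNTI
# ---------------------------------------------------------------------------


def _pair_mntd(
    pi: np.ndarray, fi: np.ndarray, pj: np.ndarray, fj: np.ndarray, d: np.ndarray
) -> float:
    sub = d[np.ix_(pi, pj)]
    return 0.5 * (fi @ sub.min(axis=1) + fj @ sub.min(axis=0))


def beta_mntd(
    x_i: np.ndarray,
    x_j: np.ndarray,
    td: TaxonDistanceMatrix | np.ndarray,
    weighted: bool = True,
) -> float:
    """Between-community mean nearest taxon distance.

    Average (abundance-weighted by default) distance from each taxon present
    in one community to its closest relative in the other, symmetrized.
    """
    d = td.d if isinstance(td, TaxonDistanceMatrix) else np.asarray(td, dtype=float)
    x_i = np.asarray(x_i, dtype=float)
    x_j = np.asarray(x_j, dtype=float)
    pi = np.flatnonzero(x_i > 0)
    pj = np.flatnonzero(x_j > 0)
    if pi.size == 0 or pj.size == 0:
        raise ValueError("beta_mntd: empty community")
    if weighted:
        fi = x_i[pi] / x_i[pi].sum()
        fj = x_j[pj] / x_j[pj].sum()
    else:
        fi = np.full(pi.size, 1.0 / pi.size)
        fj = np.full(pj.size, 1.0 / pj.size)
    return float(_pair_mntd(pi, fi, pj, fj, d))


def _resolve_pairs(
    n: int, pairs: Iterable[tuple[int, int]] | None
) -> list[tuple[int, int]]:
    if pairs is None:
        return [(i, j) for i in range(n) for j in range(i + 1, n)]
    out = []
    for i, j in pairs:
        if i == j or not (0 <= i < n and 0 <= j < n):
            raise ValueError(f"bad sample pair ({i}, {j})")
        out.append((min(i, j), max(i, j)))
    return sorted(set(out))


def within_group_pairs(table: OtuTable, meta: SampleMetadata) -> list[tuple[int, int]]:
    """Index pairs of samples belonging to the same species x stage group."""
    meta.require(table.sample_ids)
    idx = {s: i for i, s in enumerate(table.sample_ids)}
    pairs: list[tuple[int, int]] = []
    for members in meta.groups().values():
        members = [s for s in members if s in idx]
        for a, b in itertools.combinations(members, 2):
            pairs.append((idx[a], idx[b]))
    return pairs


def beta_nti(
    table: OtuTable,
    tree: PhyloTree,
    n_null: int = 999,
    weighted: bool = True,
    seed: int = 0,
    pairs: Iterable[tuple[int, int]] | None = None,
) -> BetaNtiMatrix:
    """Standardized effect size of bMNTD against a tip-label-shuffle null.

    For each null iteration one permutation of taxon labels across the tree
    tips (equivalently of the patristic matrix rows/columns) is drawn and
    applied to every sample pair.  bNTI = (observed - null mean) / null SD;
    pairs with zero null SD are flagged NaN.

    ``pairs`` restricts which sample pairs are evaluated (the null
    permutation sequence is unaffected); by default all pairs are computed.
    """
    if n_null < 2:
        raise ValueError("n_null must be >= 2")
    missing = set(table.taxon_ids) - set(tree.tip_labels)
    if missing:
        raise ConsistencyError(f"table taxa absent from tree: {sorted(missing)[:5]}")
    td = cophenetic_distances(tree, taxon_order=table.taxon_ids)
    d = td.d
    n = table.n_samples
    pair_list = _resolve_pairs(n, pairs)
    x = table.counts.astype(float)
    present = [np.flatnonzero(x[i] > 0) for i in range(n)]
    if weighted:
        freqs = [x[i][present[i]] / x[i][present[i]].sum() for i in range(n)]
    else:
        freqs = [np.full(present[i].size, 1.0 / present[i].size) for i in range(n)]
    for i in range(n):
        if present[i].size == 0:
            raise ValueError(f"empty community: sample {table.sample_ids[i]!r}")

    obs = np.array([_pair_mntd(present[i], freqs[i], present[j], freqs[j], d)
                    for i, j in pair_list])
    nulls = np.empty((n_null, len(pair_list)))
    n_taxa = table.n_taxa
    for it in range(n_null):
        rng = np.random.default_rng([int(seed), 0xB017, it])
        perm = rng.permutation(n_taxa)
        dp = d[np.ix_(perm, perm)]
        for k, (i, j) in enumerate(pair_list):
            nulls[it, k] = _pair_mntd(present[i], freqs[i], present[j], freqs[j], dp)
    mean = nulls.mean(axis=0)
    sd = nulls.std(axis=0, ddof=1)
    bnti = np.full((n, n), np.nan)
    n_degenerate = 0
    for k, (i, j) in enumerate(pair_list):
        if sd[k] == 0:
            n_degenerate += 1
            continue
        bnti[i, j] = bnti[j, i] = (obs[k] - mean[k]) / sd[k]
    if n_degenerate:
        logger.warning("beta_nti: %d pair(s) with zero null SD flagged NaN", n_degenerate)
    return BetaNtiMatrix(list(table.sample_ids), bnti, n_null, weighted)


# ---------------------------------------------------------------------------
# RC_bray
# ---------------------------------------------------------------------------


def _null_community(
    rng: np.random.Generator,
    richness: int,
    reads: int,
    occupancy: np.ndarray,
    meta_rel: np.ndarray,
) -> np.ndarray:
    """One probabilistic reassembly: draw ``richness`` taxa without
    replacement with probability proportional to occupancy, give each one
    read, then distribute the remaining reads multinomially with probability
    proportional to metacommunity relative abundance restricted to the drawn
    taxa."""
    # weighted sampling without replacement via exponential-race keys
    keys = rng.exponential(size=occupancy.size) / occupancy
    drawn = np.argpartition(keys, richness - 1)[:richness]
    counts = np.zeros(occupancy.size, dtype=np.int64)
    counts[drawn] = 1
    remaining = reads - richness
    if remaining > 0:
        p = meta_rel[drawn]
        total = p.sum()
        if total <= 0:
            p = np.full(richness, 1.0 / richness)
        else:
            p = p / total
        counts[drawn] += rng.multinomial(remaining, p)
    return counts


def raup_crick_bray(
    table: OtuTable,
    n_null: int = 999,
    seed: int = 0,
    pairs: Iterable[tuple[int, int]] | None = None,
) -> RcMatrix:
    """Bray-Curtis Raup-Crick: where the observed dissimilarity of a sample
    pair falls within a null distribution of reassembled community pairs,
    rescaled to [-1, +1].

    Each null community preserves its sample's observed richness and read
    total; membership is drawn by occupancy across the whole table and
    abundance by the table-wide metacommunity relative abundances.
    """
    if n_null < 1:
        raise ValueError("n_null must be >= 1")
    n = table.n_samples
    if n < 2:
        raise ValueError("need at least 2 samples")
    counts = table.counts
    sums = counts.sum(axis=1)
    if np.any(sums == 0):
        raise ValueError("raup_crick_bray: all-zero sample row")
    occupancy = (counts > 0).sum(axis=0).astype(float)
    pool = np.flatnonzero(occupancy > 0)
    occ_pool = occupancy[pool]
    meta_rel = counts.sum(axis=0)[pool].astype(float)
    meta_rel = meta_rel / meta_rel.sum()
    richness = (counts > 0).sum(axis=1)
    if richness.max() > pool.size:
        raise ValueError("sample richness exceeds taxon pool size")
    pair_list = _resolve_pairs(n, pairs)
    rel = counts / sums[:, None]
    rc = np.full((n, n), np.nan)
    for i, j in pair_list:
        obs = bray_curtis_pair(rel[i], rel[j])
        rng = np.random.default_rng([int(seed), 0x2CB2, i, j])
        below = 0.0
        for _ in range(n_null):
            ni = _null_community(rng, int(richness[i]), int(sums[i]), occ_pool, meta_rel)
            nj = _null_community(rng, int(richness[j]), int(sums[j]), occ_pool, meta_rel)
            null_bc = bray_curtis_pair(ni / ni.sum(), nj / nj.sum())
            if null_bc < obs - 1e-12:
                below += 1.0
            elif abs(null_bc - obs) <= 1e-12:
                below += 0.5
        rc_raw = below / n_null
        rc[i, j] = rc[j, i] = 2.0 * (rc_raw - 0.5)
    return RcMatrix(list(table.sample_ids), rc, n_null)


# ---------------------------------------------------------------------------
# classification and summary
# ---------------------------------------------------------------------------


def classify_pair(
    bnti: float, rc: float, th_bnti: float = 2.0, th_rc: float = 0.95
) -> str:
    """Five-way process assignment for one sample pair.

    bNTI beyond +/- the selection threshold indicates variable/homogeneous
    selection; otherwise RC beyond +/- its threshold indicates dispersal
    limitation/homogenizing dispersal; otherwise drift.  Boundary ties
    resolve toward the stochastic side (strict inequalities).  A NaN bNTI
    yields "undetermined".
    """
    if np.isnan(bnti):
        return "undetermined"
    if bnti > th_bnti:
        return "variable_selection"
    if bnti < -th_bnti:
        return "homogeneous_selection"
    if np.isnan(rc):
        return "undetermined"
    if rc > th_rc:
        return "dispersal_limitation"
    if rc < -th_rc:
        return "homogenizing_dispersal"
    return "drift"


def summarize_processes(
    bnti: BetaNtiMatrix,
    rc: RcMatrix,
    meta: SampleMetadata,
    th_bnti: float = 2.0,
    th_rc: float = 0.95,
) -> ProcessSummary:
    """Per species x stage group, the percentage of its within-group sample
    pairs assigned to each process (over valid, classified pairs)."""
    if bnti.sample_ids != rc.sample_ids:
        raise ConsistencyError("bNTI and RC matrices have different sample ids")
    samples = bnti.sample_ids
    meta.require(samples)
    idx = {s: i for i, s in enumerate(samples)}
    rows = []
    for label, members in meta.groups().items():
        members = [s for s in members if s in idx]
        if len(members) < 2:
            logger.warning("summarize_processes: group %s has < 2 samples; skipped", label)
            continue
        for a, b in itertools.combinations(members, 2):
            i, j = idx[a], idx[b]
            process = classify_pair(bnti.bnti[i, j], rc.rc[i, j], th_bnti, th_rc)
            rows.append(
                {
                    "sample_i": a,
                    "sample_j": b,
                    "group": label,
                    "bnti": bnti.bnti[i, j],
                    "rc": rc.rc[i, j],
                    "process": process,
                }
            )
    pair_table = pd.DataFrame(
        rows, columns=["sample_i", "sample_j", "group", "bnti", "rc", "process"]
    )
    percentages = {}
    n_pairs = {}
    for label, sub in pair_table.groupby("group", sort=False):
        n_und = int((sub["process"] == "undetermined").sum())
        if n_und:
            logger.warning(
                "summarize_processes: group %s: %d undetermined pair(s) excluded",
                label, n_und,
            )
        valid = sub[sub["process"] != "undetermined"]
        n_valid = len(valid)
        n_pairs[label] = n_valid
        if n_valid == 0:
            percentages[label] = {p: np.nan for p in PROCESSES}
            continue
        counts = valid["process"].value_counts()
        percentages[label] = {
            p: 100.0 * int(counts.get(p, 0)) / n_valid for p in PROCESSES
        }
    pct = pd.DataFrame(percentages).T.reindex(columns=list(PROCESSES))
    return ProcessSummary(pct, pd.Series(n_pairs, dtype=int), pair_table)
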