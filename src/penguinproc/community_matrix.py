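"""Count-matrix preprocessing and univariate diversity.

Singleton removal, rarefaction by uniform without-replacement subsampling,
Hellinger transform, Bray-Curtis dissimilarity, Shannon diversity/richness,
taxonomic aggregation and relative abundances.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import RANKS, OtuTable, TaxonomyMap

__all__ = [
    "AbundanceMatrix",
    "DistanceMatrix",
    "remove_singletons",
    "rarefy",
    "hellinger",
    "bray_curtis",
    "shannon",
    "aggregate_taxonomy",
    "relative_abundance",
]

logger = logging.getLogger(__name__)


@dataclass
class AbundanceMatrix:
    """Real-valued samples x taxa matrix (transformed or relative abundances)."""

    sample_ids: list[str]
    taxon_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.shape != (len(self.sample_ids), len(self.taxon_ids)):
            raise ValueError("values shape inconsistent with id lists")
        if values.size and not np.all(np.isfinite(values)):
            raise ValueError("values must be finite")
        if values.size and values.min() < 0:
            raise ValueError("values must be >= 0")
        self.values = values

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.taxon_ids)


@dataclass
class DistanceMatrix:
    """Symmetric pairwise dissimilarities with zero diagonal."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if d.shape != (n, n):
            raise ValueError("distance matrix shape inconsistent with ids")
        if not np.allclose(d, d.T, atol=1e-12):
            raise ValueError("distance matrix not symmetric")
        if not np.allclose(np.diag(d), 0.0, atol=1e-12):
            raise ValueError("distance matrix diagonal not zero")
        if np.any(d < -1e-12):
            raise ValueError("negative distances")
        self.values = d

    def submatrix(self, ids: Sequence[str]) -> "DistanceMatrix":
        idx = [self.ids.index(i) for i in ids]
        return DistanceMatrix(list(ids), self.values[np.ix_(idx, idx)])


def remove_singletons(table: OtuTable) -> OtuTable:
    """Drop taxa whose total count across all samples equals 1."""
    totals = table.column_sums()
    keep = totals != 1
    dropped = int((~keep).sum())
    if dropped:
        logger.info("remove_singletons: dropped %d singleton taxa", dropped)
    if not keep.any():
        logger.warning("remove_singletons: all taxa were singletons; table is empty")
    taxa = [t for t, k in zip(table.taxon_ids, keep) if k]
    return OtuTable(list(table.sample_ids), taxa, table.counts[:, keep])


def _read_keys(seed: int, sample_id: str, taxon_id: str, n: int) -> np.ndarray:
    """Uniform keys for the reads of one (sample, taxon) cell.

    The stream is keyed by (seed, sample, taxon) so the draw is invariant to
    column order: permuting taxa permutes the keys with them.
    """
    digest = hashlib.blake2b(
        f"{sample_id}\x00{taxon_id}".encode(), digest_size=16
    ).digest()
    entropy = [seed] + [int.from_bytes(digest[i : i + 8], "little") for i in (0, 8)]
    rng = np.random.default_rng(entropy)
    return rng.random(n)


def rarefy(table: OtuTable, depth: int, seed: int) -> OtuTable:
    """Subsample each sample to exactly ``depth`` reads without replacement.

    Each read in a sample gets an independent uniform key (keyed per
    sample/taxon, see :func:`_read_keys`); the ``depth`` smallest keys are
    retained, which is a uniform without-replacement subsample.  Samples with
    fewer than ``depth`` reads are dropped with a warning.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    sums = table.row_sums()
    keep_samples = sums >= depth
    dropped = int((~keep_samples).sum())
    if dropped:
        logger.warning(
            "rarefy: dropped %d sample(s) below depth %d: %s",
            dropped,
            depth,
            [s for s, k in zip(table.sample_ids, keep_samples) if not k],
        )
    samples = [s for s, k in zip(table.sample_ids, keep_samples) if k]
    out = np.zeros((len(samples), table.n_taxa), dtype=np.int64)
    for i, sample in enumerate(samples):
        row = table.counts[table.sample_ids.index(sample)]
        total = int(row.sum())
        if total == depth:
            out[i] = row
            continue
        nz = np.flatnonzero(row)
        keys = np.concatenate([_read_keys(seed, sample, table.taxon_ids[j], int(row[j])) for j in nz])
        owner = np.repeat(nz, row[nz])
        chosen = owner[np.argpartition(keys, depth - 1)[:depth]]
        out[i] = np.bincount(chosen, minlength=table.n_taxa)
    return OtuTable(samples, list(table.taxon_ids), out)


def _check_no_zero_rows(sample_ids: Sequence[str], matrix: np.ndarray, op: str) -> None:
    zero = np.flatnonzero(matrix.sum(axis=1) == 0)
    if zero.size:
        names = [sample_ids[i] for i in zero]
        raise ValueError(f"{op}: all-zero sample row(s): {names}")


def hellinger(table: OtuTable) -> AbundanceMatrix:
    """Hellinger transform: sqrt of within-sample relative abundances."""
    _check_no_zero_rows(table.sample_ids, table.counts, "hellinger")
    p = table.counts / table.row_sums()[:, None]
    return AbundanceMatrix(list(table.sample_ids), list(table.taxon_ids), np.sqrt(p))


def bray_curtis(m: AbundanceMatrix | OtuTable) -> DistanceMatrix:
    """Pairwise Bray-Curtis: sum|x-y| / sum(x+y) over taxa."""
    if isinstance(m, OtuTable):
        sample_ids, x = list(m.sample_ids), m.counts.astype(float)
    else:
        sample_ids, x = list(m.sample_ids), m.values
    if len(sample_ids) < 2:
        raise ValueError("bray_curtis: need at least 2 samples")
    sums = x.sum(axis=1)
    if int((sums == 0).sum()) >= 2:
        raise ValueError("bray_curtis: more than one all-zero sample row; distance undefined")
    diff = np.abs(x[:, None, :] - x[None, :, :]).sum(axis=2)
    tot = sums[:, None] + sums[None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(tot > 0, diff / np.where(tot > 0, tot, 1.0), 0.0)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(sample_ids, d)


def bray_curtis_pair(x: np.ndarray, y: np.ndarray) -> float:
    """Bray-Curtis between two abundance vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    tot = x.sum() + y.sum()
    if tot == 0:
        raise ValueError("bray_curtis: both vectors all-zero")
    return float(np.abs(x - y).sum() / tot)


def shannon(table: OtuTable, base: str | float = "e") -> pd.DataFrame:
    """Per-sample Shannon index and richness.

    Returns a DataFrame with columns sample, shannon, richness.  ``base``
    may be "e" (natural log, default) or 2.
    """
    _check_no_zero_rows(table.sample_ids, table.counts, "shannon")
    if base == "e":
        log = np.log
    elif base in (2, "2"):
        log = np.log2
    else:
        raise ValueError(f"unsupported log base {base!r}")
    p = table.counts / table.row_sums()[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * log(np.where(p > 0, p, 1.0)), 0.0)
    h = -terms.sum(axis=1)
    richness = (table.counts > 0).sum(axis=1)
    return pd.DataFrame(
        {"sample": table.sample_ids, "shannon": h, "richness": richness.astype(int)}
    )


def aggregate_taxonomy(table: OtuTable, tax: TaxonomyMap, rank: str) -> OtuTable:
    """Sum OTU columns into bins by taxonomy label at the given rank.

    Unclassified labels are kept as their own bins named after the nearest
    classified parent rank, e.g. ``Fusobacteria_unclassified``.
    """
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}")
    tax.require(table.taxon_ids)
    rank_idx = RANKS.index(rank)
    bins: dict[str, np.ndarray] = {}
    order: list[str] = []
    for j, taxon in enumerate(table.taxon_ids):
        lineage = tax.lineages[taxon]
        label = lineage[rank_idx]
        if label == "unclassified":
            parent = "unknown"
            for k in range(rank_idx - 1, -1, -1):
                if lineage[k] != "unclassified":
                    parent = lineage[k]
                    break
            label = f"{parent}_unclassified"
        if label not in bins:
            bins[label] = np.zeros(table.n_samples, dtype=np.int64)
            order.append(label)
        bins[label] += table.counts[:, j]
    counts = np.column_stack([bins[l] for l in order]) if order else np.zeros((table.n_samples, 0), dtype=np.int64)
    return OtuTable(list(table.sample_ids), order, counts)


def relative_abundance(table: OtuTable, percent: bool = False) -> AbundanceMatrix:
    """Within-sample proportions; rows sum to 1 (or 100 in percent mode)."""
    _check_no_zero_rows(table.sample_ids, table.counts, "relative_abundance")
    p = table.counts / table.row_sums()[:, None]
    if percent:
        p = p * 100.0
    return AbundanceMatrix(list(table.sample_ids), list(table.taxon_ids), p)


def group_mean_relative_abundance(
    rel: AbundanceMatrix, groups: dict[str, list[str]]
) -> pd.DataFrame:
    """Group label x taxon mean of per-sample proportions (not pooled counts)."""
    rows = {}
    df = rel.to_dataframe()
    for label, members in groups.items():
        rows[label] = df.loc[members].mean(axis=0)
    return pd.DataFrame(rows).T
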