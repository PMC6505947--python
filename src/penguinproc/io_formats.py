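"""Readers and writers for the tabular and tree formats used throughout the
pipeline: shared-style OTU count tables, consensus taxonomy, newick
phylogenies and sample metadata.

All readers validate strictly and raise :class:`FormatError` (malformed
file), ``ValueError`` (bad values) or :class:`ConsistencyError` (cross-file
mismatches) rather than silently coercing.  Every ``write_*``/``read_*``
pair round-trips its type exactly.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "ConsistencyError",
    "RANKS",
    "SPECIES_LEVELS",
    "STAGE_LEVELS",
    "OtuTable",
    "TaxonomyMap",
    "PhyloTree",
    "SampleMetadata",
    "read_shared",
    "write_shared",
    "read_taxonomy",
    "write_taxonomy",
    "read_newick",
    "write_newick",
    "read_metadata",
    "write_metadata",
]

#: Canonical taxonomic ranks, outermost first.
RANKS = ("domain", "phylum", "class", "order", "family", "genus")

SPECIES_LEVELS = frozenset({"chinstrap", "gentoo"})
STAGE_LEVELS = frozenset({"feeding", "moulting"})

#: Output float format: 6 significant digits.
FLOAT_FMT = "%.6g"


class FormatError(ValueError):
    """A file does not conform to its expected dialect."""


class ConsistencyError(ValueError):
    """Inputs are individually valid but mutually inconsistent."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen = set()
    dups = [i for i in ids if i in seen or seen.add(i)]
    if dups:
        raise ValueError(f"duplicate {what} id(s): {sorted(set(dups))}")


# ---------------------------------------------------------------------------
# OtuTable
# ---------------------------------------------------------------------------


@dataclass
class OtuTable:
    """Integer count matrix, samples (rows) x taxa (columns)."""

    sample_ids: list[str]
    taxon_ids: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.taxon_ids = [str(t) for t in self.taxon_ids]
        _check_unique(self.sample_ids, "sample")
        _check_unique(self.taxon_ids, "taxon")
        counts = np.asarray(self.counts)
        if counts.ndim != 2 or counts.shape != (len(self.sample_ids), len(self.taxon_ids)):
            raise ValueError(
                f"counts shape {counts.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.taxon_ids)} taxa"
            )
        if counts.size and not np.issubdtype(counts.dtype, np.integer):
            if not np.all(np.isfinite(counts)):
                raise ValueError("counts must be finite")
            if np.any(counts != np.floor(counts)):
                raise ValueError("counts must be integers")
            counts = counts.astype(np.int64)
        else:
            counts = counts.astype(np.int64)
        if counts.size and counts.min() < 0:
            raise ValueError("counts must be >= 0")
        self.counts = counts

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_ids)

    def row_sums(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def column_sums(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.sample_ids, columns=self.taxon_ids)

    def select_samples(self, sample_ids: Sequence[str]) -> "OtuTable":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return OtuTable(list(sample_ids), list(self.taxon_ids), self.counts[idx])

    def select_taxa(self, taxon_ids: Sequence[str]) -> "OtuTable":
        idx = [self.taxon_ids.index(t) for t in taxon_ids]
        return OtuTable(list(self.sample_ids), list(taxon_ids), self.counts[:, idx])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, OtuTable):
            return NotImplemented
        return (
            self.sample_ids == other.sample_ids
            and self.taxon_ids == other.taxon_ids
            and np.array_equal(self.counts, other.counts)
        )


# ---------------------------------------------------------------------------
# TaxonomyMap
# ---------------------------------------------------------------------------


@dataclass
class TaxonomyMap:
    """Mapping taxon id -> 6-rank lineage (domain..genus)."""

    lineages: dict[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        for taxon, lineage in self.lineages.items():
            lineage = tuple(str(x) for x in lineage)
            if len(lineage) != len(RANKS):
                raise ValueError(
                    f"lineage for {taxon!r} has {len(lineage)} ranks, expected {len(RANKS)}"
                )
            self.lineages[taxon] = lineage

    def __contains__(self, taxon: str) -> bool:
        return taxon in self.lineages

    def __len__(self) -> int:
        return len(self.lineages)

    def rank(self, taxon: str, rank: str) -> str:
        if rank not in RANKS:
            raise ValueError(f"unknown rank {rank!r}; expected one of {RANKS}")
        try:
            lineage = self.lineages[taxon]
        except KeyError:
            raise LookupError(f"taxon {taxon!r} absent from taxonomy") from None
        return lineage[RANKS.index(rank)]

    def require(self, taxon_ids: Iterable[str]) -> None:
        """Raise LookupError listing every id missing from the map."""
        missing = [t for t in taxon_ids if t not in self.lineages]
        if missing:
            raise LookupError(f"taxa absent from taxonomy: {missing}")


# ---------------------------------------------------------------------------
# PhyloTree
# ---------------------------------------------------------------------------


@dataclass
class PhyloTree:
    """Rooted tree with branch lengths; tip labels are taxon ids."""

    tree: dendropy.Tree

    def __post_init__(self) -> None:
        labels = self.tip_labels
        _check_unique(labels, "tip")
        for edge in self.tree.preorder_edge_iter():
            if edge.tail_node is None:
                continue
            if edge.length is not None and edge.length < 0:
                raise ValueError("negative branch length")

    @property
    def tip_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return sum(1 for _ in self.tree.leaf_node_iter())

    def as_newick(self) -> str:
        s = self.tree.as_string(schema="newick", suppress_rooting=True)
        return s.strip()

    def pruned_to(self, labels: Iterable[str]) -> "PhyloTree":
        """Return a copy retaining only the given tip labels."""
        keep = set(labels)
        missing = keep - set(self.tip_labels)
        if missing:
            raise ConsistencyError(f"labels absent from tree: {sorted(missing)}")
        clone = dendropy.Tree(self.tree)
        taxa = [t for t in clone.taxon_namespace if t.label in keep]
        clone.retain_taxa(taxa)
        return PhyloTree(clone)


def _parse_newick(newick: str, strict: bool) -> PhyloTree:
    try:
        tree = dendropy.Tree.get(
            data=newick,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises assorted error types
        raise FormatError(f"malformed newick: {exc}") from exc
    for edge in tree.preorder_edge_iter():
        if edge.tail_node is None:
            continue
        if edge.length is None:
            if strict:
                raise FormatError("branch without length (strict mode)")
            edge.length = 0.0
    return PhyloTree(tree)


# ---------------------------------------------------------------------------
# SampleMetadata
# ---------------------------------------------------------------------------


@dataclass
class SampleMetadata:
    """Per-sample design factors: species x stage."""

    factors: dict[str, tuple[str, str]]  # sample -> (species, stage)

    def __post_init__(self) -> None:
        if not self.factors:
            raise ValueError("metadata is empty")
        for sample, (species, stage) in self.factors.items():
            if species not in SPECIES_LEVELS:
                raise ValueError(
                    f"sample {sample!r}: unknown species {species!r}; "
                    f"expected one of {sorted(SPECIES_LEVELS)}"
                )
            if stage not in STAGE_LEVELS:
                raise ValueError(
                    f"sample {sample!r}: unknown stage {stage!r}; "
                    f"expected one of {sorted(STAGE_LEVELS)}"
                )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.factors)

    def species(self, sample: str) -> str:
        return self.factors[sample][0]

    def stage(self, sample: str) -> str:
        return self.factors[sample][1]

    def group_label(self, sample: str) -> str:
        species, stage = self.factors[sample]
        return f"{species}_{stage}"

    def groups(self) -> dict[str, list[str]]:
        """Group label -> ordered member sample ids (species x stage)."""
        out: dict[str, list[str]] = {}
        for sample in self.factors:
            out.setdefault(self.group_label(sample), []).append(sample)
        return out

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample": list(self.factors),
                "species": [v[0] for v in self.factors.values()],
                "stage": [v[1] for v in self.factors.values()],
            }
        )

    def require(self, sample_ids: Iterable[str]) -> None:
        missing = [s for s in sample_ids if s not in self.factors]
        if missing:
            raise ConsistencyError(f"samples absent from metadata: {missing}")


# ---------------------------------------------------------------------------
# shared-style OTU tables
# ---------------------------------------------------------------------------

_MOTHUR_PREFIX = ("label", "group", "numotus")


def read_shared(path: str | Path) -> OtuTable:
    """Read a shared-style OTU count table.

    Two dialects are auto-detected from the header: the mothur layout with
    ``label/Group/numOtus`` prefix columns, and a bare layout whose first
    column holds sample ids and remaining columns hold taxa.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, header=0)
    except Exception as exc:
        raise FormatError(f"{path}: cannot parse TSV: {exc}") from exc
    if df.shape[1] < 2:
        raise FormatError(f"{path}: need at least a sample column and one taxon column")
    header = [str(c) for c in df.columns]
    if tuple(h.lower() for h in header[:3]) == _MOTHUR_PREFIX:
        if df.shape[1] < 4:
            raise FormatError(f"{path}: mothur shared header but no taxon columns")
        sample_ids = df.iloc[:, 1].tolist()
        taxon_ids = header[3:]
        body = df.iloc[:, 3:]
    else:
        sample_ids = df.iloc[:, 0].tolist()
        taxon_ids = header[1:]
        body = df.iloc[:, 1:]
    counts = np.empty((len(sample_ids), len(taxon_ids)), dtype=np.int64)
    for j, taxon in enumerate(taxon_ids):
        col = pd.to_numeric(body.iloc[:, j], errors="coerce")
        bad = col.isna()
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"{path}: non-numeric count for sample {sample_ids[i]!r}, taxon {taxon!r}"
            )
        values = col.to_numpy()
        if np.any(values != np.floor(values)):
            i = int(np.flatnonzero(values != np.floor(values))[0])
            raise ValueError(
                f"{path}: non-integer count for sample {sample_ids[i]!r}, taxon {taxon!r}"
            )
        if values.min() < 0:
            i = int(np.flatnonzero(values < 0)[0])
            raise ValueError(
                f"{path}: negative count for sample {sample_ids[i]!r}, taxon {taxon!r}"
            )
        counts[:, j] = values.astype(np.int64)
    return OtuTable(sample_ids, taxon_ids, counts)


def write_shared(table: OtuTable, path: str | Path, dialect: str = "mothur") -> None:
    """Write an OtuTable as a shared-style TSV (``mothur`` or ``bare`` dialect)."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        if dialect == "mothur":
            fh.write("label\tGroup\tnumOtus\t" + "\t".join(table.taxon_ids) + "\n")
            for i, sample in enumerate(table.sample_ids):
                row = "\t".join(str(int(c)) for c in table.counts[i])
                fh.write(f"0.03\t{sample}\t{table.n_taxa}\t{row}\n")
        elif dialect == "bare":
            fh.write("sample\t" + "\t".join(table.taxon_ids) + "\n")
            for i, sample in enumerate(table.sample_ids):
                row = "\t".join(str(int(c)) for c in table.counts[i])
                fh.write(f"{sample}\t{row}\n")
        else:
            raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# taxonomy
# ---------------------------------------------------------------------------

_BOOTSTRAP_RE = re.compile(r"\(\d+(?:\.\d+)?\)")


def read_taxonomy(path: str | Path) -> TaxonomyMap:
    """Read a consensus-taxonomy TSV: OTU id, semicolon-delimited lineage.

    Bootstrap suffixes like ``(100)`` are stripped; lineages shorter than 6
    ranks are padded with ``unclassified``.  An optional mothur ``Size``
    column between id and lineage is tolerated.
    """
    path = Path(path)
    lineages: dict[str, tuple[str, ...]] = {}
    with path.open(encoding="utf-8") as fh:
        first = True
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if first:
                first = False
                # skip a header row (mothur writes "OTU\tSize\tTaxonomy")
                if parts[0].strip().lower() in {"otu", "otu_id", "taxon"}:
                    continue
            if len(parts) < 2:
                raise FormatError(f"{path}:{lineno}: expected >= 2 tab-separated columns")
            taxon = parts[0].strip()
            lineage_str = parts[-1].strip()
            lineage_str = _BOOTSTRAP_RE.sub("", lineage_str)
            ranks = [r.strip() for r in lineage_str.split(";") if r.strip()]
            if len(ranks) > len(RANKS):
                ranks = ranks[: len(RANKS)]
            ranks += ["unclassified"] * (len(RANKS) - len(ranks))
            if taxon in lineages:
                raise ValueError(f"{path}:{lineno}: duplicate taxon id {taxon!r}")
            lineages[taxon] = tuple(ranks)
    if not lineages:
        raise FormatError(f"{path}: empty taxonomy file")
    return TaxonomyMap(lineages)


def write_taxonomy(tax: TaxonomyMap, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("OTU\tTaxonomy\n")
        for taxon, lineage in tax.lineages.items():
            fh.write(f"{taxon}\t{';'.join(lineage)};\n")


# ---------------------------------------------------------------------------
# newick
# ---------------------------------------------------------------------------


def read_newick(path: str | Path, strict: bool = True) -> PhyloTree:
    """Read a rooted newick tree.

    In strict mode (default) every non-root branch must carry a length; in
    lenient mode missing lengths become 0.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if not text.strip():
        raise FormatError(f"{path}: empty newick file")
    return _parse_newick(text, strict=strict)


def tree_from_newick(newick: str, strict: bool = True) -> PhyloTree:
    """Parse a newick string (same semantics as :func:`read_newick`)."""
    return _parse_newick(newick, strict=strict)


def write_newick(tree: PhyloTree, path: str | Path) -> None:
    Path(path).write_text(tree.as_newick() + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# metadata
# ---------------------------------------------------------------------------


def read_metadata(path: str | Path) -> SampleMetadata:
    """Read a sample metadata TSV with columns sample, species, stage."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty metadata file") from None
    required = {"sample", "species", "stage"}
    if not required.issubset(df.columns):
        raise FormatError(
            f"{path}: metadata needs columns {sorted(required)}, got {list(df.columns)}"
        )
    if df.empty:
        raise FormatError(f"{path}: metadata has no rows")
    if df["sample"].duplicated().any():
        dups = df.loc[df["sample"].duplicated(), "sample"].tolist()
        raise ValueError(f"{path}: duplicate sample id(s): {dups}")
    if df[["sample", "species", "stage"]].isna().any().any():
        raise ValueError(f"{path}: missing values in sample/species/stage")
    factors = {
        row["sample"]: (row["species"], row["stage"]) for _, row in df.iterrows()
    }
    return SampleMetadata(factors)


def write_metadata(meta: SampleMetadata, path: str | Path) -> None:
    meta.to_dataframe().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# generic matrix / results output helpers (UTF-8, tab-delimited, 6 sig figs)
# ---------------------------------------------------------------------------


def write_square_matrix(ids: Sequence[str], values: np.ndarray, path: str | Path,
                        id_header: str = "id") -> None:
    df = pd.DataFrame(values, index=list(ids), columns=list(ids))
    df.to_csv(path, sep="\t", index_label=id_header, float_format=FLOAT_FMT)


def read_square_matrix(path: str | Path) -> tuple[list[str], np.ndarray]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    ids = [str(i) for i in df.index]
    if ids != [str(c) for c in df.columns]:
        raise FormatError(f"{path}: row and column ids differ")
    return ids, df.to_numpy(dtype=float)


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FMT)
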