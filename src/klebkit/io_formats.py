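"""Readers and writers for the external formats the pipeline touches.

Everything downstream (filtering, supermatrix construction, jackknife,
ancestral state reconstruction) consumes the in-memory containers defined
here: :class:`Alignment`, :class:`PartitionScheme`, :class:`TraitTable` and
:class:`HitTable`. Trees are plain :class:`dendropy.Tree` objects; the
helpers in this module only add strict validation and a canonical,
round-trip-safe Newick serialisation.

Conventions
-----------
* Residues are uppercased on read; ``*`` stop symbols are stripped with a
  warning (protein predictions from different tools disagree here).
* ``X`` is a residue of unknown identity; ``-`` and ``?`` are the gap/missing
  characters used by all gap-fraction computations.
* Partition coordinates are 1-based inclusive in files (the RAxML dialect)
  and 0-based half-open in memory.
* Newick internal-node labels (support strings such as ``95.3/100``) are
  stored verbatim and never parsed into numbers implicitly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "FormatError",
    "Alignment",
    "PartitionScheme",
    "TraitTable",
    "HitTable",
    "GAP_CHARS",
    "AMINO_ACIDS",
    "MISSING_STATE",
    "KEEP_CATEGORY",
    "CONTAMINANT_CATEGORIES",
    "parse_fasta",
    "write_fasta",
    "parse_newick",
    "tree_from_string",
    "newick_string",
    "write_newick",
    "parse_trait_table",
    "parse_hit_table",
    "write_supermatrix",
]

#: Characters counted as missing data in gap-fraction rules.
GAP_CHARS = frozenset("-?")

#: The 20 standard amino acids.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Marker for a missing character state in trait tables.
MISSING_STATE = "?"

#: Hit category whose best match marks a sequence as genuine.
KEEP_CATEGORY = "klebsormidiophyceae_nuclear"

#: Contaminant categories routed to separate output sets.
CONTAMINANT_CATEGORIES = ("bacteria", "fungi", "viruses", "archaea", "plastid")


class FormatError(ValueError):
    """An input file or in-memory object violates its format contract."""


# ---------------------------------------------------------------------------
# Alignment
# ---------------------------------------------------------------------------


@dataclass
class Alignment:
    """A named set of sequences, optionally aligned.

    Parameters
    ----------
    rows
        Ordered mapping from taxon label to residue string. Labels must be
        unique (enforced by the mapping) and non-empty.
    name
        Free-text identifier, e.g. a locus name.
    aligned
        When True, all rows must have equal length and column-wise
        operations are permitted.
    """

    rows: dict[str, str]
    name: str = ""
    aligned: bool = True

    def __post_init__(self) -> None:
        for label in self.rows:
            if not label:
                raise FormatError("empty taxon label in alignment %r" % self.name)
        if self.aligned and self.rows:
            lengths = {len(s) for s in self.rows.values()}
            if len(lengths) > 1:
                raise FormatError(
                    f"alignment {self.name!r} flagged as aligned but row lengths "
                    f"differ: {sorted(lengths)}"
                )

    @classmethod
    def from_pairs(
        cls, pairs: Iterable[tuple[str, str]], name: str = "", aligned: bool = True
    ) -> "Alignment":
        """Build an alignment from (label, sequence) pairs, rejecting duplicates."""
        rows: dict[str, str] = {}
        for label, seq in pairs:
            if label in rows:
                raise FormatError(f"duplicate sequence label: {label!r}")
            rows[label] = seq
        return cls(rows=rows, name=name, aligned=aligned)

    @property
    def length(self) -> int:
        """Number of columns (aligned alignments only; 0 when empty)."""
        if not self.rows:
            return 0
        if not self.aligned:
            raise FormatError("length is undefined for unaligned sequence sets")
        return len(next(iter(self.rows.values())))

    @property
    def taxa(self) -> tuple[str, ...]:
        return tuple(self.rows)

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    def to_char_array(self) -> np.ndarray:
        """Return the alignment as an (n_rows, length) array of single characters."""
        if not self.aligned:
            raise FormatError("char array requires an aligned input")
        if not self.rows:
            return np.empty((0, 0), dtype="<U1")
        return np.array([list(s) for s in self.rows.values()], dtype="<U1")

    def slice_columns(self, start: int, stop: int, name: str = "") -> "Alignment":
        """Extract a column window using 0-based half-open coordinates."""
        if not self.aligned:
            raise FormatError("column slicing requires an aligned input")
        return Alignment(
            rows={t: s[start:stop] for t, s in self.rows.items()},
            name=name or self.name,
            aligned=True,
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Alignment):
            return NotImplemented
        return self.rows == other.rows


def parse_fasta(path: str | Path, name: str = "", aligned: bool = False) -> Alignment:
    """Read a FASTA file into an :class:`Alignment`.

    Residues are uppercased; ``*`` symbols are stripped with a warning.
    Duplicate headers raise :class:`FormatError`; an empty file yields an
    empty sequence set.
    """
    path = Path(path)
    rows: dict[str, str] = {}
    stripped_stops = False
    for record in SeqIO.parse(str(path), "fasta"):
        label = record.id
        if label in rows:
            raise FormatError(f"duplicate sequence label in {path.name}: {label!r}")
        seq = str(record.seq).upper()
        if "*" in seq:
            seq = seq.replace("*", "")
            stripped_stops = True
        rows[label] = seq
    if stripped_stops:
        warnings.warn(f"stripped '*' stop symbols while reading {path.name}")
    return Alignment(rows=rows, name=name or path.stem, aligned=aligned)


def write_fasta(aln: Alignment, path: str | Path, wrap: int = 60) -> None:
    """Write sequences in FASTA, wrapping at ``wrap`` columns (0 = single line)."""
    path = Path(path)
    with path.open("w") as fh:
        for label, seq in aln.rows.items():
            fh.write(f">{label}\n")
            if wrap and wrap > 0:
                for i in range(0, len(seq), wrap):
                    fh.write(seq[i : i + wrap] + "\n")
            else:
                fh.write(seq + "\n")


# ---------------------------------------------------------------------------
# Trees (thin validation layer over dendropy)
# ---------------------------------------------------------------------------


def _validate_tree(tree: dendropy.Tree) -> dendropy.Tree:
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise FormatError(f"duplicate leaf labels: {dupes}")
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            raise FormatError(f"negative branch length: {edge.length}")
    return tree


def tree_from_string(newick: str) -> dendropy.Tree:
    """Parse a Newick string into a validated :class:`dendropy.Tree`."""
    try:
        tree = dendropy.Tree.get(
            data=newick,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several parser error types
        raise FormatError(f"malformed Newick: {exc}") from exc
    tree.is_rooted = True  # seed node is the root for all downstream work
    return _validate_tree(tree)


def parse_newick(path: str | Path) -> dendropy.Tree:
    """Read a single-tree Newick file with validation."""
    return tree_from_string(Path(path).read_text())


def newick_string(tree: dendropy.Tree) -> str:
    """Canonical Newick serialisation (10 significant digits on branch lengths)."""
    return tree.as_string(
        schema="newick",
        unquoted_underscores=True,
        suppress_rooting=True,
        real_value_format_specifier=".10g",
    )


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    Path(path).write_text(newick_string(tree))


# ---------------------------------------------------------------------------
# Partition scheme
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PartitionScheme:
    """Locus boundaries over a supermatrix, 1-based inclusive, contiguous."""

    parts: tuple[tuple[str, int, int], ...]

    def __post_init__(self) -> None:
        if not self.parts:
            raise FormatError("partition scheme must contain at least one locus")
        names = [p[0] for p in self.parts]
        if len(names) != len(set(names)):
            raise FormatError("duplicate locus names in partition scheme")
        expected_start = 1
        for name, start, end in self.parts:
            if start != expected_start:
                raise FormatError(
                    f"partition {name!r} starts at {start}, expected {expected_start}"
                )
            if end < start:
                raise FormatError(f"partition {name!r} has end {end} < start {start}")
            expected_start = end + 1

    @classmethod
    def from_lengths(cls, names_lengths: Iterable[tuple[str, int]]) -> "PartitionScheme":
        parts = []
        pos = 1
        for name, length in names_lengths:
            if length <= 0:
                raise FormatError(f"locus {name!r} has non-positive length {length}")
            parts.append((name, pos, pos + length - 1))
            pos += length
        return cls(tuple(parts))

    @property
    def total_length(self) -> int:
        return self.parts[-1][2]

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(p[0] for p in self.parts)

    def bounds(self, name: str) -> tuple[int, int]:
        """1-based inclusive (start, end) of a locus."""
        for n, s, e in self.parts:
            if n == name:
                return s, e
        raise KeyError(name)

    def slice0(self, name: str) -> tuple[int, int]:
        """0-based half-open (start, stop) of a locus."""
        s, e = self.bounds(name)
        return s - 1, e

    def to_raxml(self, model: str = "LG") -> str:
        return "".join(f"{model}, {n} = {s}-{e}\n" for n, s, e in self.parts)


# ---------------------------------------------------------------------------
# Trait tables
# ---------------------------------------------------------------------------


@dataclass
class TraitTable:
    """Mapping taxon label -> raw character state label (``?`` = missing)."""

    states: dict[str, str]

    def __getitem__(self, taxon: str) -> str:
        return self.states[taxon]

    def __contains__(self, taxon: str) -> bool:
        return taxon in self.states

    def __len__(self) -> int:
        return len(self.states)

    def is_missing(self, taxon: str) -> bool:
        return self.states.get(taxon, MISSING_STATE) == MISSING_STATE

    @property
    def taxa(self) -> tuple[str, ...]:
        return tuple(self.states)


def parse_trait_table(
    path: str | Path,
    delimiter: str = "\t",
    header: bool = False,
    columns: tuple[int, int] | None = None,
) -> TraitTable:
    """Read a two-column delimited taxon -> state table.

    Files with more than two columns are rejected unless an explicit column
    selection is supplied; duplicate taxa are always an error.
    """
    path = Path(path)
    states: dict[str, str] = {}
    with path.open() as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if header and lines:
        lines = lines[1:]
    for lineno, line in enumerate(lines, start=1 + int(header)):
        fields = line.split(delimiter)
        if len(fields) > 2 and columns is None:
            raise FormatError(
                f"{path.name} line {lineno}: {len(fields)} columns; pass an "
                "explicit column selection for multi-column tables"
            )
        use = columns if columns is not None else (0, 1)
        try:
            taxon = fields[use[0]].strip()
            state = fields[use[1]].strip()
        except IndexError as exc:
            raise FormatError(f"{path.name} line {lineno}: too few columns") from exc
        if taxon in states:
            raise FormatError(f"duplicate taxon in trait table: {taxon!r}")
        states[taxon] = state
    return TraitTable(states=states)


# ---------------------------------------------------------------------------
# Similarity hit tables (BLAST / MMseqs2 tabular "m8")
# ---------------------------------------------------------------------------

#: Default 12-column tabular field names (qseqid..bitscore).
M8_COLUMNS = (
    "query",
    "target",
    "pident",
    "length",
    "mismatch",
    "gapopen",
    "qstart",
    "qend",
    "sstart",
    "send",
    "evalue",
    "bitscore",
)


@dataclass
class HitTable:
    """Per-query similarity hits with a target -> category companion map.

    ``hits`` has columns ``query, target, bitscore, evalue, rank`` and is
    sorted per query by (bitscore desc, evalue asc, target asc) — a total
    order, so the ranking is deterministic across runs and platforms.
    """

    hits: pd.DataFrame
    categories: dict[str, str]
    default_category: str | None = None
    max_hits: int = 10

    def category_of(self, target: str) -> str:
        cat = self.categories.get(target, self.default_category)
        if cat is None:
            raise FormatError(f"target {target!r} has no category and no default is set")
        return cat

    @property
    def queries(self) -> set[str]:
        return set(self.hits["query"].unique())

    def hits_for(self, query: str) -> pd.DataFrame:
        return self.hits[self.hits["query"] == query]

    @classmethod
    def from_records(
        cls,
        records: Iterable[tuple[str, str, float, float]],
        categories: Mapping[str, str],
        max_hits: int = 10,
        default_category: str | None = None,
    ) -> "HitTable":
        """Build a hit table from (query, target, bitscore, evalue) tuples."""
        df = pd.DataFrame(records, columns=["query", "target", "bitscore", "evalue"])
        return cls._finalize(df, dict(categories), max_hits, default_category)

    @classmethod
    def _finalize(
        cls,
        df: pd.DataFrame,
        categories: dict[str, str],
        max_hits: int,
        default_category: str | None,
    ) -> "HitTable":
        if (df["bitscore"] < 0).any():
            raise FormatError("negative bitscore in hit table")
        if (df["evalue"] < 0).any():
            raise FormatError("negative e-value in hit table")
        if default_category is None:
            missing = sorted(set(df["target"]) - set(categories))
            if missing:
                shown = ", ".join(missing[:10])
                more = "" if len(missing) <= 10 else f" (+{len(missing) - 10} more)"
                raise FormatError(f"targets without a category: {shown}{more}")
        df = df.sort_values(
            ["query", "bitscore", "evalue", "target"],
            ascending=[True, False, True, True],
            kind="mergesort",
        ).reset_index(drop=True)
        df["rank"] = df.groupby("query").cumcount() + 1
        df = df[df["rank"] <= max_hits].reset_index(drop=True)
        return cls(
            hits=df[["query", "target", "bitscore", "evalue", "rank"]],
            categories=categories,
            default_category=default_category,
            max_hits=max_hits,
        )


def parse_hit_table(
    path: str | Path,
    category_map_path: str | Path,
    max_hits: int = 10,
    default_category: str | None = None,
) -> HitTable:
    """Read an m8-style tabular hit file plus its target -> category map.

    The 12 default tabular columns are assumed; extra trailing columns are
    ignored. Per query, hits are ranked by (bitscore desc, evalue asc,
    target asc) and truncated at ``max_hits``.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 12:
        raise FormatError(
            f"hit table has {df.shape[1]} columns; at least 12 (m8) are required"
        )
    df = df.iloc[:, :12]
    df.columns = list(M8_COLUMNS)
    cat_df = pd.read_csv(category_map_path, sep="\t", header=None, comment="#")
    if cat_df.shape[1] < 2:
        raise FormatError("category map must have two columns: target<TAB>category")
    categories = dict(zip(cat_df.iloc[:, 0].astype(str), cat_df.iloc[:, 1].astype(str)))
    return HitTable._finalize(
        df[["query", "target", "bitscore", "evalue"]].copy(),
        categories,
        max_hits,
        default_category,
    )


def write_hit_table_m8(hits: HitTable, path: str | Path) -> None:
    """Write hits back out in 12-column m8 format.

    Only query, target, e-value and bitscore are meaningful here; the
    remaining alignment-statistics columns are filled with zeros.
    """
    with Path(path).open("w") as fh:
        for row in hits.hits.itertuples(index=False):
            fh.write(
                f"{row.query}\t{row.target}\t0\t0\t0\t0\t0\t0\t0\t0\t"
                f"{row.evalue:g}\t{row.bitscore:g}\n"
            )


# ---------------------------------------------------------------------------
# Supermatrix output
# ---------------------------------------------------------------------------


def write_supermatrix(
    matrix: Alignment,
    partitions: PartitionScheme,
    fasta_path: str | Path,
    partition_path: str | Path | None = None,
    model: str = "LG",
    phylip: bool = False,
) -> None:
    """Write a concatenated matrix plus a RAxML-style partition file.

    The sequence file is FASTA by default, or relaxed PHYLIP when
    ``phylip=True``. Partition lines follow ``MODEL, name = start-end`` with
    1-based inclusive coordinates.
    """
    if partitions.total_length != matrix.length:
        raise FormatError(
            f"partition scheme covers {partitions.total_length} columns but the "
            f"matrix has {matrix.length}"
        )
    fasta_path = Path(fasta_path)
    if phylip:
        with fasta_path.open("w") as fh:
            fh.write(f"{matrix.n_rows} {matrix.length}\n")
            for label, seq in matrix.rows.items():
                fh.write(f"{label}  {seq}\n")
    else:
        write_fasta(matrix, fasta_path)
    if partition_path is not None:
        Path(partition_path).write_text(partitions.to_raxml(model=model))
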