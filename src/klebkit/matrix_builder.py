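"""Gap-threshold column trimming and supermatrix concatenation.

Two rules do all the work here:

* a column is removed iff its gap fraction is *strictly greater* than the
  threshold (``-`` and ``?`` are gaps, ``X`` is an unknown residue and
  therefore counts as data), and
* concatenation takes the union of taxa, fills absent taxon x locus cells
  with ``-``, orders rows lexicographically for byte-reproducible output,
  and records exact locus boundaries in a :class:`PartitionScheme`.

Both pipeline passes (per-locus trimming at 0.75, post-concatenation
trimming at 0.65) are configuration defaults, not constants.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import Alignment, FormatError, PartitionScheme

__all__ = [
    "TrimResult",
    "SuperMatrix",
    "OccupancyReport",
    "trim_gappy_columns",
    "concatenate_loci",
    "slice_locus",
    "occupancy_report",
    "PER_LOCUS_GAP_THRESHOLD",
    "SUPERMATRIX_GAP_THRESHOLD",
]

#: Default per-locus trimming threshold (columns with > 75% gaps removed).
PER_LOCUS_GAP_THRESHOLD = 0.75

#: Default post-concatenation threshold (columns with > 65% gaps removed).
SUPERMATRIX_GAP_THRESHOLD = 0.65

_GAPS = np.array(["-", "?"], dtype="<U1")


@dataclass
class TrimResult:
    """Outcome of gap-threshold trimming: what survived and why."""

    alignment: Alignment
    kept_columns: np.ndarray  # indices into the input alignment
    n_removed: int
    gap_fractions: np.ndarray  # per input column


def trim_gappy_columns(aln: Alignment, max_gap_fraction: float) -> TrimResult:
    """Remove columns whose gap fraction strictly exceeds the threshold.

    A column with gap fraction exactly equal to ``max_gap_fraction`` is
    retained ("over X% gaps" read literally). ``X`` counts as a residue.
    """
    if not aln.aligned:
        raise FormatError("trimming requires an aligned input")
    if not 0.0 <= max_gap_fraction <= 1.0:
        raise ValueError("max_gap_fraction must lie in [0, 1]")
    arr = aln.to_char_array()
    if arr.size == 0:
        return TrimResult(aln, np.empty(0, dtype=int), 0, np.empty(0))
    gap_fractions = np.isin(arr, _GAPS).mean(axis=0)
    keep = gap_fractions <= max_gap_fraction
    kept_columns = np.flatnonzero(keep)
    rows = {t: "".join(row[keep]) for t, row in zip(aln.taxa, arr)}
    trimmed = Alignment(rows=rows, name=aln.name, aligned=True)
    return TrimResult(
        alignment=trimmed,
        kept_columns=kept_columns,
        n_removed=int((~keep).sum()),
        gap_fractions=gap_fractions,
    )


@dataclass
class SuperMatrix:
    """Concatenated alignment over the union of taxa, with bookkeeping."""

    alignment: Alignment
    partitions: PartitionScheme
    presence: pd.DataFrame  # bool, taxa x loci: taxon present in locus

    @property
    def taxa(self) -> tuple[str, ...]:
        return self.alignment.taxa

    @property
    def length(self) -> int:
        return self.alignment.length


def _as_named_loci(
    loci: Mapping[str, Alignment] | Sequence[Alignment],
) -> list[tuple[str, Alignment]]:
    if isinstance(loci, Mapping):
        return list(loci.items())
    named = []
    for i, aln in enumerate(loci):
        named.append((aln.name or f"locus{i + 1}", aln))
    return named


def concatenate_loci(
    loci: Mapping[str, Alignment] | Sequence[Alignment],
    taxon_universe: Iterable[str] | None = None,
) -> SuperMatrix:
    """Concatenate aligned loci into a supermatrix.

    Rows are the union of taxa (or the given universe), sorted
    lexicographically; cells for taxa absent from a locus are filled with
    ``-``. Partitions are recorded in input order. A duplicate taxon within
    one locus, or a locus taxon outside the universe, is an error.
    """
    named = _as_named_loci(loci)
    if not named:
        raise FormatError("cannot concatenate an empty locus list")
    union: set[str] = set()
    for name, aln in named:
        if not aln.aligned:
            raise FormatError(f"locus {name!r} is not aligned")
        union |= set(aln.taxa)
    if taxon_universe is not None:
        taxa = sorted(set(taxon_universe))
        stray = union - set(taxa)
        if stray:
            raise FormatError(
                f"loci contain taxa outside the given universe: {sorted(stray)[:10]}"
            )
    else:
        taxa = sorted(union)

    pieces: dict[str, list[str]] = {t: [] for t in taxa}
    presence = np.zeros((len(taxa), len(named)), dtype=bool)
    for j, (name, aln) in enumerate(named):
        length = aln.length
        for i, taxon in enumerate(taxa):
            row = aln.rows.get(taxon)
            if row is None:
                pieces[taxon].append("-" * length)
            else:
                pieces[taxon].append(row)
                presence[i, j] = True
    rows = {t: "".join(pieces[t]) for t in taxa}
    partitions = PartitionScheme.from_lengths(
        (name, aln.length) for name, aln in named
    )
    presence_df = pd.DataFrame(
        presence, index=taxa, columns=[name for name, _ in named]
    )
    return SuperMatrix(
        alignment=Alignment(rows=rows, name="supermatrix", aligned=True),
        partitions=partitions,
        presence=presence_df,
    )


def slice_locus(sm: SuperMatrix, name: str, drop_absent: bool = True) -> Alignment:
    """Recover one locus's exact column slice from a supermatrix.

    With ``drop_absent=True`` (default) rows for taxa absent from the locus
    (all-gap fill) are omitted, so concatenate-then-slice is the identity on
    each input locus restricted to its taxa.
    """
    start, stop = sm.partitions.slice0(name)
    sliced = sm.alignment.slice_columns(start, stop, name=name)
    if drop_absent:
        present = set(sm.presence.index[sm.presence[name]])
        sliced = Alignment(
            rows={t: s for t, s in sliced.rows.items() if t in present},
            name=name,
            aligned=True,
        )
    return sliced


@dataclass
class OccupancyReport:
    per_taxon: pd.Series  # non-gap fraction per taxon over the whole matrix
    per_locus: pd.Series  # non-gap fraction per locus over all rows
    overall: float

    def to_frame(self) -> pd.DataFrame:
        taxon_df = self.per_taxon.rename("occupancy").rename_axis("taxon").reset_index()
        taxon_df.insert(0, "kind", "taxon")
        locus_df = self.per_locus.rename("occupancy").rename_axis("taxon").reset_index()
        locus_df.insert(0, "kind", "locus")
        total = pd.DataFrame(
            [{"kind": "matrix", "taxon": "overall", "occupancy": self.overall}]
        )
        return pd.concat([taxon_df, locus_df, total], ignore_index=True)


def occupancy_report(sm: SuperMatrix) -> OccupancyReport:
    """Per-taxon, per-locus and overall non-gap fractions of a supermatrix."""
    arr = sm.alignment.to_char_array()
    nongap = ~np.isin(arr, _GAPS)
    per_taxon = pd.Series(nongap.mean(axis=1), index=list(sm.taxa), name="occupancy")
    locus_vals = {}
    for name in sm.partitions.names:
        start, stop = sm.partitions.slice0(name)
        locus_vals[name] = float(nongap[:, start:stop].mean())
    per_locus = pd.Series(locus_vals, name="occupancy")
    return OccupancyReport(
        per_taxon=per_taxon,
        per_locus=per_locus,
        overall=float(nongap.mean()),
    )
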