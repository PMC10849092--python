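"""Decontamination and orthogroup occupancy filters.

The dataset-construction stages of a phylotranscriptomic study are a chain
of small, sharp filters. This module implements them as pure functions so
that every step is individually testable:

* :func:`best_hit_decontaminate` — keep a transcriptome sequence only when
  its best similarity hit is to the in-group nuclear reference, routing
  removed sequences into one set per contaminant category.
* :func:`filter_by_group_occupancy` — keep an orthogroup only when its
  members span at least ``min_groups`` taxonomic groups.
* :func:`filter_by_taxon_count` — keep an orthogroup/locus only when it
  contains at least ``min_taxa`` distinct taxa.
* :func:`filter_pruned_by_groups` — the same group-occupancy rule applied
  to one-sequence-per-taxon ortholog sets after paralog pruning.
* :func:`combine_locus_sets` — union two locus sets by id with an explicit
  collision policy.
* :func:`rename_for_pruner` — rewrite sequence labels to the
  ``taxon<delimiter>sequence-id`` convention expected by tree-based paralog
  pruners, with a reversal mapping.

Every filter partitions its input (kept + removed = input) and reports its
tallies in a :class:`FilterReport`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import dendropy
import pandas as pd

from .io_formats import (
    Alignment,
    CONTAMINANT_CATEGORIES,
    FormatError,
    HitTable,
    KEEP_CATEGORY,
)

__all__ = [
    "FilterError",
    "TaxonomyMap",
    "Orthogroup",
    "FilterReport",
    "DecontamResult",
    "best_hit_decontaminate",
    "filter_by_group_occupancy",
    "filter_by_taxon_count",
    "filter_pruned_by_groups",
    "combine_locus_sets",
    "rename_for_pruner",
    "load_bundled_taxonomy",
]

NO_HIT = "no_hit"


class FilterError(ValueError):
    """A filter precondition was violated (unmapped taxon, id collision, ...)."""


@dataclass
class TaxonomyMap:
    """Taxon label -> taxonomic group label."""

    groups: dict[str, str]

    def group_of(self, taxon: str) -> str:
        try:
            return self.groups[taxon]
        except KeyError:
            raise FilterError(f"taxon {taxon!r} is not in the taxonomy map") from None

    @property
    def n_groups(self) -> int:
        return len(set(self.groups.values()))

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TaxonomyMap":
        groups: dict[str, str] = {}
        for line in Path(path).read_text().splitlines():
            if not line.strip() or line.startswith("#"):
                continue
            taxon, group = line.split("\t")[:2]
            if taxon in groups:
                raise FormatError(f"duplicate taxon in taxonomy map: {taxon!r}")
            groups[taxon] = group
        return cls(groups=groups)


def load_bundled_taxonomy(name: str) -> TaxonomyMap:
    """Load one of the editable taxonomy fixtures shipped with the package.

    ``name`` is ``"groups14"`` (the broad green-lineage scheme) or
    ``"groups4"`` (chlorophytes / other streptophytes / Klebsormidium /
    other Klebsormidiophyceae). Both files are synthetic approximations of
    the deposited group assignments and are meant to be replaced by the
    user's own tables for real analyses.
    """
    path = Path(__file__).parent / "data" / f"taxonomic_{name}_synthetic.tsv"
    if not path.exists():
        raise FileNotFoundError(f"no bundled taxonomy named {name!r}")
    return TaxonomyMap.from_tsv(path)


@dataclass(frozen=True)
class Orthogroup:
    """A set of sequences across taxa putatively descending from one gene."""

    id: str
    members: tuple[tuple[str, str], ...]  # (taxon label, sequence id)

    @property
    def taxa(self) -> set[str]:
        return {taxon for taxon, _ in self.members}

    def groups(self, taxonomy: TaxonomyMap) -> set[str]:
        return {taxonomy.group_of(taxon) for taxon in self.taxa}


@dataclass
class FilterReport:
    """Bookkeeping for one filter application; counts must reconcile."""

    rule: str
    n_input: int
    n_kept: int
    n_removed: int
    tallies: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_kept + self.n_removed != self.n_input:
            raise FilterError(
                f"report for {self.rule!r} does not reconcile: "
                f"{self.n_kept} + {self.n_removed} != {self.n_input}"
            )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"key": "input", "count": self.n_input},
            {"key": "kept", "count": self.n_kept},
            {"key": "removed", "count": self.n_removed},
        ]
        rows += [{"key": k, "count": v} for k, v in sorted(self.tallies.items())]
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Best-hit decontamination
# ---------------------------------------------------------------------------


@dataclass
class DecontamResult:
    kept: dict[str, str]
    removed: dict[str, dict[str, str]]  # category -> {seq id: sequence}
    report: FilterReport


def best_hit_decontaminate(
    sequences: Mapping[str, str],
    hits: HitTable,
    keep_no_hit: bool = True,
    keep_category: str = KEEP_CATEGORY,
) -> DecontamResult:
    """Retain sequences whose best similarity hit is the in-group reference.

    A sequence is kept iff its rank-1 hit belongs to ``keep_category`` and
    no other category ties the top bitscore; a tie between the kept category
    and any contaminant removes the sequence (stringent decontamination —
    a lost genuine sequence is cheaper than a chimeric locus). Removed
    sequences are routed into one set per contaminant category, keyed by the
    best-scoring contaminant among the top hits. Queries with no hits at all
    follow ``keep_no_hit``: kept (and tallied separately) by default, or
    routed to a ``no_hit`` set in strict mode.
    """
    unknown = sorted(hits.queries - set(sequences))
    if unknown:
        raise FilterError(
            f"hit table references sequences absent from the input: {unknown[:10]}"
        )
    kept: dict[str, str] = {}
    removed: dict[str, dict[str, str]] = {}
    tallies: dict[str, int] = {}

    top_categories: dict[str, str | None] = {}
    for query, sub in hits.hits.groupby("query", sort=False):
        top_score = sub["bitscore"].iloc[0]
        top = sub[sub["bitscore"] == top_score]
        cats = [hits.category_of(t) for t in top["target"]]
        if all(c == keep_category for c in cats):
            top_categories[query] = keep_category
        else:
            # first (best-ranked) non-kept category among the tied top hits
            top_categories[query] = next(c for c in cats if c != keep_category)

    for seq_id, seq in sequences.items():
        cat = top_categories.get(seq_id)
        if cat is None:  # no hits at all
            tallies[NO_HIT] = tallies.get(NO_HIT, 0) + 1
            if keep_no_hit:
                kept[seq_id] = seq
            else:
                removed.setdefault(NO_HIT, {})[seq_id] = seq
            continue
        if cat == keep_category:
            kept[seq_id] = seq
        else:
            removed.setdefault(cat, {})[seq_id] = seq
            tallies[cat] = tallies.get(cat, 0) + 1

    n_removed = sum(len(v) for v in removed.values())
    report = FilterReport(
        rule="best_hit_decontaminate",
        n_input=len(sequences),
        n_kept=len(kept),
        n_removed=n_removed,
        tallies=tallies,
    )
    return DecontamResult(kept=kept, removed=removed, report=report)


# ---------------------------------------------------------------------------
# Occupancy filters
# ---------------------------------------------------------------------------


def filter_by_group_occupancy(
    orthogroups: Iterable[Orthogroup],
    taxonomy: TaxonomyMap,
    min_groups: int,
) -> tuple[list[Orthogroup], FilterReport]:
    """Keep orthogroups whose members span at least ``min_groups`` groups.

    Multiple sequences from one taxon count once toward that taxon's group;
    the rule counts groups, not sequences. An unmapped member taxon raises
    :class:`FilterError` naming the offender.
    """
    orthogroups = list(orthogroups)
    kept = [og for og in orthogroups if len(og.groups(taxonomy)) >= min_groups]
    report = FilterReport(
        rule=f"group_occupancy(min_groups={min_groups})",
        n_input=len(orthogroups),
        n_kept=len(kept),
        n_removed=len(orthogroups) - len(kept),
    )
    return kept, report


def filter_by_taxon_count(
    orthogroups: Iterable[Orthogroup],
    min_taxa: int,
) -> tuple[list[Orthogroup], FilterReport]:
    """Keep orthogroups/loci containing at least ``min_taxa`` distinct taxa."""
    orthogroups = list(orthogroups)
    kept = [og for og in orthogroups if len(og.taxa) >= min_taxa]
    report = FilterReport(
        rule=f"taxon_count(min_taxa={min_taxa})",
        n_input=len(orthogroups),
        n_kept=len(kept),
        n_removed=len(orthogroups) - len(kept),
    )
    return kept, report


def filter_pruned_by_groups(
    ortholog_sets: Iterable[Orthogroup],
    taxonomy: TaxonomyMap,
    min_groups: int,
) -> tuple[list[Orthogroup], FilterReport]:
    """Group-occupancy filtering of pruned, one-sequence-per-taxon sets.

    Semantics are identical to :func:`filter_by_group_occupancy`; the
    separate entry point mirrors the post-pruning stage of the pipeline
    (e.g. requiring 2 of the 4 coarse groups after paralog pruning).
    """
    kept, report = filter_by_group_occupancy(ortholog_sets, taxonomy, min_groups)
    report.rule = f"pruned_group_occupancy(min_groups={min_groups})"
    return kept, report


# ---------------------------------------------------------------------------
# Set combination
# ---------------------------------------------------------------------------


def combine_locus_sets(
    set_a: Mapping[str, object],
    set_b: Mapping[str, object],
    on_collision: str = "error",
) -> dict[str, object]:
    """Union two locus sets keyed by id.

    Identical-content duplicates merge silently; an id collision with
    differing content is an error under the default policy, or resolved by
    suffix-renaming the second set's copy under ``on_collision="rename"``.
    """
    if on_collision not in ("error", "rename"):
        raise ValueError(f"unknown collision policy {on_collision!r}")
    combined: dict[str, object] = dict(set_a)
    clashes: list[str] = []
    for locus_id, locus in set_b.items():
        if locus_id not in combined:
            combined[locus_id] = locus
        elif combined[locus_id] == locus:
            continue  # identical duplicate
        elif on_collision == "rename":
            new_id = f"{locus_id}__b"
            suffix = 2
            while new_id in combined:
                new_id = f"{locus_id}__b{suffix}"
                suffix += 1
            combined[new_id] = locus
        else:
            clashes.append(locus_id)
    if clashes:
        raise FilterError(
            f"locus id collisions with differing content: {sorted(clashes)[:10]}"
        )
    return combined


# ---------------------------------------------------------------------------
# Pruner-format renaming
# ---------------------------------------------------------------------------


def _default_splitter(label: str) -> tuple[str, str]:
    if "_" not in label:
        raise FilterError(
            f"cannot split {label!r} into taxon and sequence parts (no '_')"
        )
    taxon_part, seq_part = label.split("_", 1)
    return taxon_part, seq_part


def rename_for_pruner(
    alignments: Mapping[str, Alignment],
    taxon_map: Mapping[str, str],
    trees: Mapping[str, dendropy.Tree] | None = None,
    delimiter: str = "@",
    splitter: Callable[[str], tuple[str, str]] = _default_splitter,
) -> tuple[dict[str, Alignment], dict[str, dendropy.Tree] | None, dict[str, str]]:
    """Rewrite labels to ``taxon<delimiter>sequence-id`` for paralog pruners.

    ``taxon_map`` maps the taxon part of each label (as produced by
    ``splitter``) to the full taxon name. Returns renamed copies of the
    alignments and trees plus a new-label -> old-label mapping for exact
    reversal. A taxon name already containing the delimiter is an error.
    """
    mapping: dict[str, str] = {}

    def rename(label: str) -> str:
        taxon_part, seq_part = splitter(label)
        try:
            taxon = taxon_map[taxon_part]
        except KeyError:
            raise FilterError(f"no taxon mapping for prefix {taxon_part!r}") from None
        if delimiter in taxon:
            raise FilterError(
                f"taxon {taxon!r} contains the delimiter {delimiter!r}"
            )
        new_label = f"{taxon}{delimiter}{seq_part}"
        prior = mapping.get(new_label)
        if prior is not None and prior != label:
            raise FilterError(f"renaming collision: {new_label!r}")
        mapping[new_label] = label
        return new_label

    new_alignments = {
        aln_id: Alignment(
            rows={rename(lbl): seq for lbl, seq in aln.rows.items()},
            name=aln.name,
            aligned=aln.aligned,
        )
        for aln_id, aln in alignments.items()
    }
    new_trees: dict[str, dendropy.Tree] | None = None
    if trees is not None:
        new_trees = {}
        for tree_id, tree in trees.items():
            clone = tree.clone(depth=1)
            for leaf in clone.leaf_node_iter():
                leaf.taxon.label = rename(leaf.taxon.label)
            new_trees[tree_id] = clone
    return new_alignments, new_trees, mapping
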