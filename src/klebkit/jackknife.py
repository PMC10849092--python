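"""Gene-jackknife branch support.

Whole loci are resampled *without replacement* and concatenated until the
replicate first reaches a target length (10,000 / 30,000 / 60,000 / 85,000
aligned amino acids by default, 100 pseudo-replicates per length). Each
replicate matrix is handed to a pluggable tree engine, and every
non-trivial bipartition of the reference tree is scored by the proportion
of replicate trees that contain it. Compared with the non-parametric
bootstrap, replicates are more independent data subsets because no locus
appears twice.

The built-in engine is neighbor joining on uncorrected p-distances — fast
and deterministic, intended for desk-scale validation; real analyses plug
in an external maximum-likelihood command through :class:`CommandEngine`.
"""

from __future__ import annotations

import json
import shlex
import subprocess
import tempfile
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from .io_formats import Alignment, newick_string, tree_from_string, write_fasta
from .matrix_builder import concatenate_loci

__all__ = [
    "JackknifeConfig",
    "JackknifeResult",
    "bipartitions",
    "split_key",
    "draw_replicate",
    "recovery_proportions",
    "summarize_support",
    "run_jackknife",
    "annotate_support",
    "NeighborJoiningEngine",
    "CommandEngine",
    "star_tree",
    "p_distance_matrix",
]

DEFAULT_TARGET_LENGTHS = (10_000, 30_000, 60_000, 85_000)


# ---------------------------------------------------------------------------
# Bipartitions
# ---------------------------------------------------------------------------


def bipartitions(
    tree: dendropy.Tree, include_trivial: bool = False
) -> set[frozenset]:
    """The set of (unrooted) leaf bipartitions induced by a tree's edges.

    Each bipartition is a frozenset of the two frozensets of leaf labels.
    Root placement does not affect the result: the two edges incident to a
    degree-2 root induce the same split, and the set deduplicates them.
    Trivial splits (one side a single leaf) are excluded unless requested.
    """
    all_leaves = frozenset(l.taxon.label for l in tree.leaf_node_iter())
    splits: set[frozenset] = set()
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        below = frozenset(l.taxon.label for l in node.leaf_iter())
        above = all_leaves - below
        if not above:
            continue
        if not include_trivial and (len(below) < 2 or len(above) < 2):
            continue
        splits.add(frozenset((below, above)))
    return splits


def split_key(split: frozenset) -> str:
    """Canonical display string: the side holding the smallest label first."""
    side_a, side_b = sorted(split, key=lambda s: min(s))
    return " ".join(sorted(side_a)) + " | " + " ".join(sorted(side_b))


def star_tree(labels: Iterable[str], edge_length: float = 1.0) -> dendropy.Tree:
    """A star (single multifurcation) tree over the given leaf labels."""
    newick = "(" + ",".join(f"{l}:{edge_length}" for l in labels) + ");"
    return tree_from_string(newick)


# ---------------------------------------------------------------------------
# Replicate drawing
# ---------------------------------------------------------------------------


def draw_replicate(
    loci: Mapping[str, Alignment],
    target_length: int,
    rng: np.random.Generator,
    stop_below: bool = False,
) -> tuple[list[str], Alignment]:
    """Draw loci uniformly without replacement up to a target length.

    Loci are accumulated until the concatenated length first reaches or
    exceeds ``target_length``; the final, overshooting locus is included so
    the replicate carries at least the stated information content
    (``stop_below=True`` instead stops just under the target). If the loci
    cannot reach the target, all of them are returned with a warning.
    """
    if not loci:
        raise ValueError("cannot draw a replicate from an empty locus set")
    ids = sorted(loci)
    total = sum(loci[i].length for i in ids)
    if total < target_length:
        warnings.warn(
            f"total locus length {total} < target {target_length}; using all loci"
        )
        chosen = list(ids)
    else:
        order = rng.permutation(len(ids))
        chosen = []
        acc = 0
        for idx in order:
            locus_id = ids[idx]
            length = loci[locus_id].length
            if stop_below and acc + length > target_length:
                continue
            chosen.append(locus_id)
            acc += length
            if acc >= target_length:
                break
    sm = concatenate_loci({i: loci[i] for i in chosen})
    return chosen, sm.alignment


# ---------------------------------------------------------------------------
# Recovery proportions and summaries
# ---------------------------------------------------------------------------


def recovery_proportions(
    ref_tree: dendropy.Tree,
    replicate_trees: Sequence[dendropy.Tree],
) -> pd.Series:
    """Per reference branch, the fraction of replicates containing it.

    All trees must share an identical leaf set; a mismatch raises with the
    symmetric difference named. Returns a Series indexed by the canonical
    split string, one row per non-trivial reference bipartition.
    """
    ref_leaves = {l.taxon.label for l in ref_tree.leaf_node_iter()}
    for i, t in enumerate(replicate_trees):
        leaves = {l.taxon.label for l in t.leaf_node_iter()}
        if leaves != ref_leaves:
            diff = sorted(leaves ^ ref_leaves)
            raise ValueError(f"replicate {i} leaf set differs from reference: {diff}")
    ref_splits = bipartitions(ref_tree)
    counts = {s: 0 for s in ref_splits}
    for t in replicate_trees:
        rep_splits = bipartitions(t)
        for s in ref_splits:
            if s in rep_splits:
                counts[s] += 1
    n = max(len(replicate_trees), 1)
    data = {split_key(s): counts[s] / n for s in ref_splits}
    return pd.Series(data, name="proportion").sort_index()


def summarize_support(
    proportions: pd.Series | pd.DataFrame,
    thresholds: Sequence[float] = (0.95,),
) -> pd.DataFrame:
    """Fraction of reference branches above each support threshold.

    For each threshold t the summary reports the fraction of branches with
    recovery proportion strictly greater than t, plus a separate tally of
    branches recovered in every replicate (proportion exactly 1.0). An
    empty table gives an empty summary, not an error.
    """
    if isinstance(proportions, pd.Series):
        proportions = proportions.to_frame()
    rows = []
    for column in proportions.columns:
        vals = proportions[column].to_numpy(dtype=float)
        if vals.size == 0:
            continue
        for t in thresholds:
            rows.append(
                {
                    "tier": column,
                    "criterion": f">{t:g}",
                    "fraction": float((vals > t).mean()),
                }
            )
        rows.append(
            {"tier": column, "criterion": "=1.0", "fraction": float((vals == 1.0).mean())}
        )
    return pd.DataFrame(rows, columns=["tier", "criterion", "fraction"])


# ---------------------------------------------------------------------------
# Tree engines
# ---------------------------------------------------------------------------

_NON_RESIDUE = np.array(["-", "?", "X"], dtype="<U1")


def p_distance_matrix(aln: Alignment) -> tuple[np.ndarray, list[str]]:
    """Uncorrected p-distances over pairwise-complete residue columns.

    Columns where either sequence has a gap, ``?`` or ``X`` are skipped for
    that pair; a pair with no comparable columns is assigned the saturation
    value 0.75.
    """
    arr = aln.to_char_array()
    taxa = list(aln.taxa)
    n = len(taxa)
    valid = ~np.isin(arr, _NON_RESIDUE)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            m = int(both.sum())
            if m == 0:
                d = 0.75
            else:
                d = float((arr[i, both] != arr[j, both]).mean())
            D[i, j] = D[j, i] = d
    return D, taxa


class NeighborJoiningEngine:
    """Built-in test engine: neighbor joining on uncorrected p-distances.

    Negative NJ branch lengths are clamped to zero; only the topology is
    consumed by the support computation.
    """

    name = "builtin-nj"

    def __call__(self, aln: Alignment) -> dendropy.Tree:
        from skbio import DistanceMatrix
        from skbio.tree import nj

        D, taxa = p_distance_matrix(aln)
        sk_tree = nj(DistanceMatrix(D, ids=taxa))
        tree = tree_from_string(str(sk_tree))
        return tree


class CommandEngine:
    """Adapter for an external inference command.

    ``template`` must contain ``{aln}`` and ``{out}`` placeholders, e.g.
    ``"iqtree2 -s {aln} -m LG+G --prefix {out}"``; after the command exits,
    the first existing file among ``{out}``, ``{out}.treefile`` and
    ``{out}.nwk`` is parsed as Newick.
    """

    def __init__(self, template: str):
        if "{aln}" not in template or "{out}" not in template:
            raise ValueError("engine template must contain {aln} and {out}")
        self.template = template
        self.name = template

    def __call__(self, aln: Alignment) -> dendropy.Tree:
        with tempfile.TemporaryDirectory(prefix="klebkit_jk_") as tmp:
            aln_path = Path(tmp) / "replicate.fasta"
            out_path = Path(tmp) / "replicate.tree"
            write_fasta(aln, aln_path)
            cmd = self.template.format(aln=aln_path, out=out_path)
            subprocess.run(shlex.split(cmd), check=True, capture_output=True)
            for candidate in (
                out_path,
                out_path.with_suffix(out_path.suffix + ".treefile"),
                out_path.with_suffix(".nwk"),
            ):
                if candidate.exists():
                    return tree_from_string(candidate.read_text())
            raise RuntimeError(f"engine produced no tree file: {cmd}")


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------


@dataclass
class JackknifeConfig:
    """Resampling design for a gene-jackknife run."""

    seed: int
    target_lengths: Sequence[int] = DEFAULT_TARGET_LENGTHS
    n_replicates: int = 100
    engine: Callable[[Alignment], dendropy.Tree] = field(
        default_factory=NeighborJoiningEngine
    )
    stop_below: bool = False
    max_failure_fraction: float = 0.10

    def __post_init__(self) -> None:
        if any(l <= 0 for l in self.target_lengths):
            raise ValueError("target lengths must be strictly positive")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


@dataclass
class JackknifeResult:
    """Support table (branch x length tier), summaries, and a run manifest."""

    table: pd.DataFrame  # index: split key; one column per target length
    summary: pd.DataFrame
    manifest: dict

    def manifest_json(self) -> str:
        return json.dumps(self.manifest, indent=2, sort_keys=True)


def run_jackknife(
    loci: Mapping[str, Alignment],
    ref_tree: dendropy.Tree,
    config: JackknifeConfig,
) -> JackknifeResult:
    """Full gene-jackknife support analysis against a reference tree.

    Per target length, ``n_replicates`` replicates are drawn with
    per-replicate seeds derived deterministically from
    ``(config.seed, length, replicate index)``, so each tier is
    independently reproducible. The manifest records every derived seed,
    locus subset and engine, enabling exact re-runs. A replicate whose
    engine fails — or whose drawn loci do not cover the reference leaf set —
    is recorded as failed; more than ``max_failure_fraction`` failures in a
    tier aborts the run.
    """
    ref_leaves = {l.taxon.label for l in ref_tree.leaf_node_iter()}
    loci_taxa = set().union(*(set(a.taxa) for a in loci.values())) if loci else set()
    stray = loci_taxa - ref_leaves
    if stray:
        raise ValueError(
            f"loci contain taxa absent from the reference tree: {sorted(stray)[:10]}"
        )
    engine_name = getattr(config.engine, "name", repr(config.engine))
    columns: dict[int, pd.Series] = {}
    manifest: dict = {
        "seed": config.seed,
        "engine": engine_name,
        "n_replicates": config.n_replicates,
        "tiers": {},
    }
    for length in config.target_lengths:
        trees: list[dendropy.Tree] = []
        tier_manifest = []
        failures = 0
        for r in range(config.n_replicates):
            derived = [int(config.seed), int(length), int(r)]
            rng = np.random.default_rng(derived)
            chosen, replicate = draw_replicate(
                loci, length, rng, stop_below=config.stop_below
            )
            entry = {
                "replicate": r,
                "seed": derived,
                "loci": chosen,
                "length": replicate.length,
                "status": "ok",
            }
            try:
                if set(replicate.taxa) != ref_leaves:
                    raise ValueError("replicate does not cover the reference taxa")
                trees.append(config.engine(replicate))
            except Exception as exc:
                failures += 1
                entry["status"] = f"failed: {exc}"
            tier_manifest.append(entry)
        manifest["tiers"][str(length)] = tier_manifest
        if failures > config.max_failure_fraction * config.n_replicates:
            raise RuntimeError(
                f"{failures}/{config.n_replicates} replicates failed at length "
                f"{length}; aborting"
            )
        columns[length] = recovery_proportions(ref_tree, trees)
    table = pd.DataFrame(columns)
    summary = summarize_support(table)
    return JackknifeResult(table=table, summary=summary, manifest=manifest)


def annotate_support(ref_tree: dendropy.Tree, proportions: pd.Series) -> dendropy.Tree:
    """Copy the reference tree with recovery proportions as internal labels."""
    tree = ref_tree.clone(depth=1)
    all_leaves = frozenset(l.taxon.label for l in tree.leaf_node_iter())
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        below = frozenset(l.taxon.label for l in node.leaf_iter())
        split = frozenset((below, all_leaves - below))
        key = split_key(split)
        if key in proportions.index:
            node.label = f"{proportions[key]:.3f}"
    return tree
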