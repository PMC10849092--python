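"""Synthetic data generators with recorded ground truth.

Every input the pipeline consumes can be generated here at desk scale:

* :func:`sim_tree` — a pure-birth (Yule) tree of roughly chronogram size
  (tens of taxa), ultrametric by construction, optionally rescaled to a
  target root depth;
* :func:`sim_mk_characters` — discrete characters evolved under a known Mk
  model, with the true state at every internal node recorded;
* :func:`sim_loci` — amino-acid loci of heterogeneous length evolved under
  a uniform-exchangeability substitution model, with per-taxon occupancy
  and gappy-column structure;
* :func:`sim_contaminated_assembly` — an "assembly" in which a known
  fraction of sequences derives from contaminant sources, together with a
  similarity hit table whose top hit reflects the true source (optionally
  blurred by Gaussian bitscore noise).

All generators are pure functions of their arguments and seed (NumPy's
PCG64 via :func:`numpy.random.default_rng`), so outputs are byte-identical
across runs, and every generated dataset ships with a machine-readable
truth object enabling closed-loop tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import dendropy
import numpy as np

from .acsr import MkModel, _PCache, _TreeIndex
from .io_formats import (
    Alignment,
    AMINO_ACIDS,
    CONTAMINANT_CATEGORIES,
    HitTable,
    KEEP_CATEGORY,
)

__all__ = [
    "SimConfig",
    "CharacterTruth",
    "LocusTruth",
    "ContaminationTruth",
    "sim_tree",
    "sim_mk_characters",
    "sim_loci",
    "sim_contaminated_assembly",
]


@dataclass
class SimConfig:
    """Default study-scale conditions for the synthetic generators.

    The defaults emulate the structure of a densely sampled
    phylotranscriptomic dataset: a chronogram of 40 taxa, loci of 300-900
    aligned amino acids with high but incomplete taxon occupancy, and an
    assembly with a ~10% contaminant load spread over the five contaminant
    categories.
    """

    seed: int
    n_tips: int = 40
    birth_rate: float = 1.0
    tree_depth: float | None = 1.0
    n_chars: int = 1
    n_loci: int = 200
    locus_length_range: tuple[int, int] = (300, 900)
    occupancy: float = 0.9
    gap_rate: float = 0.1
    subst_rate: float = 1.0
    n_sequences: int = 1000
    contamination: Mapping[str, float] = field(
        default_factory=lambda: {
            "bacteria": 0.04,
            "fungi": 0.02,
            "viruses": 0.01,
            "archaea": 0.01,
            "plastid": 0.02,
        }
    )
    hit_noise_sd: float = 0.0


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------


def sim_tree(
    n_tips: int,
    seed: int,
    birth_rate: float = 1.0,
    depth: float | None = None,
) -> dendropy.Tree:
    """Simulate a pure-birth tree with leaves ``T0001..Tnnnn``.

    Speciation happens at rate ``birth_rate`` per lineage; all tips are
    extant, so the tree is ultrametric. When ``depth`` is given, all branch
    lengths are rescaled so the root-to-tip distance equals it exactly.
    """
    if n_tips < 2:
        raise ValueError("a tree needs at least 2 tips")
    rng = np.random.default_rng([int(seed), 7_001])
    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    # active lineages as (node, birth_time)
    root = tree.seed_node
    t = 0.0
    active: list[tuple[dendropy.Node, float]] = []
    for _ in range(2):
        child = dendropy.Node()
        root.add_child(child)
        active.append((child, 0.0))
    while len(active) < n_tips:
        t += rng.exponential(1.0 / (birth_rate * len(active)))
        i = int(rng.integers(len(active)))
        node, born = active.pop(i)
        node.edge.length = t - born
        for _ in range(2):
            child = dendropy.Node()
            node.add_child(child)
            active.append((child, t))
    t += rng.exponential(1.0 / (birth_rate * len(active)))
    for i, (node, born) in enumerate(active):
        node.edge.length = t - born
    # deterministic leaf labelling in ladderized postorder
    for i, leaf in enumerate(tree.leaf_node_iter(), start=1):
        leaf.taxon = taxa.new_taxon(label=f"T{i:04d}")
    root.edge.length = None
    tree.is_rooted = True
    if depth is not None:
        scale = depth / t
        for edge in tree.preorder_edge_iter():
            if edge.length is not None:
                edge.length *= scale
    return tree


# ---------------------------------------------------------------------------
# Discrete characters
# ---------------------------------------------------------------------------


@dataclass
class CharacterTruth:
    """True node states per character, keyed by descendant leaf set."""

    node_states: dict[frozenset, np.ndarray]  # (n_chars,) int arrays
    root_states: np.ndarray

    def state_of(self, leaves) -> np.ndarray:
        return self.node_states[frozenset(leaves)]


def sim_mk_characters(
    tree: dendropy.Tree,
    model: MkModel,
    n_chars: int,
    seed: int,
) -> tuple[dict[str, np.ndarray], CharacterTruth]:
    """Evolve ``n_chars`` independent characters under an Mk model.

    The root state is drawn from the model's root prior and states evolve
    down each branch with transition probabilities ``exp(Q t)``. Returns
    per-tip state arrays and the recorded truth at every node.
    """
    rng = np.random.default_rng([int(seed), 7_002])
    ix = _TreeIndex(tree)
    pcache = _PCache(model.Q)
    states = np.empty((ix.n_nodes, n_chars), dtype=int)
    states[ix.root] = rng.choice(model.k, size=n_chars, p=model.root_prior)
    for i in range(ix.n_nodes - 1, -1, -1):  # preorder
        for ci, t in ix.children[i]:
            P = pcache(t)
            cum = P.cumsum(axis=1)
            u = rng.random(n_chars)
            states[ci] = (u[:, None] > cum[states[i]]).sum(axis=1)
    tips = {
        label: states[i].copy()
        for i, label in enumerate(ix.leaf_label)
        if label is not None
    }
    truth = CharacterTruth(
        node_states={ix.leafsets[i]: states[i].copy() for i in range(ix.n_nodes)},
        root_states=states[ix.root].copy(),
    )
    return tips, truth


# ---------------------------------------------------------------------------
# Loci
# ---------------------------------------------------------------------------


@dataclass
class LocusTruth:
    """Generating tree and per-locus composition of a simulated locus set."""

    tree: dendropy.Tree
    locus_taxa: dict[str, tuple[str, ...]]
    locus_lengths: dict[str, int]


def _evolve_sequences(
    ix: _TreeIndex, length: int, rate: float, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Evolve integer-coded residues under the 20-state uniform-exchange model.

    Along a branch of length ``t`` each site retains the parental residue
    with probability ``exp(-(20/19) * rate * t)`` and otherwise redraws
    uniformly over the 20 amino acids — the exact transition kernel of the
    equal-rates chain.
    """
    seqs = np.empty((ix.n_nodes, length), dtype=np.int8)
    seqs[ix.root] = rng.integers(0, 20, size=length)
    for i in range(ix.n_nodes - 1, -1, -1):
        for ci, t in ix.children[i]:
            stay = math.exp(-(20.0 / 19.0) * rate * t)
            redraw = rng.random(length) >= stay
            child = seqs[i].copy()
            child[redraw] = rng.integers(0, 20, size=int(redraw.sum()))
            seqs[ci] = child
    return {
        label: seqs[i]
        for i, label in enumerate(ix.leaf_label)
        if label is not None
    }


def sim_loci(
    tree: dendropy.Tree,
    n_loci: int,
    seed: int,
    length_range: tuple[int, int] = (300, 900),
    occupancy: float = 1.0,
    gap_rate: float = 0.0,
    subst_rate: float = 1.0,
    prefix: str = "locus",
) -> tuple[dict[str, Alignment], LocusTruth]:
    """Simulate a concordant locus set on one generating tree.

    Per locus: the length is uniform over ``length_range``; sequences
    evolve under the uniform-exchange amino-acid model at ``subst_rate``
    expected substitutions per site per unit branch length; each taxon is
    retained independently with probability ``occupancy`` (at least two
    always survive); each column becomes "gappy" with probability
    ``gap_rate``, in which case a random 50-95% of its rows are replaced by
    gaps — producing the high-gap columns that trimming is meant to remove.
    """
    if not 0.0 <= occupancy <= 1.0 or not 0.0 <= gap_rate <= 1.0:
        raise ValueError("occupancy and gap_rate must lie in [0, 1]")
    rng = np.random.default_rng([int(seed), 7_003])
    ix = _TreeIndex(tree)
    aa = np.array(list(AMINO_ACIDS), dtype="<U1")
    loci: dict[str, Alignment] = {}
    locus_taxa: dict[str, tuple[str, ...]] = {}
    locus_lengths: dict[str, int] = {}
    width = max(4, len(str(n_loci)))
    for li in range(1, n_loci + 1):
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        seqs = _evolve_sequences(ix, length, subst_rate, rng)
        taxa = sorted(seqs)
        keep = rng.random(len(taxa)) < occupancy
        if keep.sum() < 2:  # a locus must stay usable
            keep[rng.choice(len(taxa), size=2, replace=False)] = True
        kept_taxa = [t for t, k in zip(taxa, keep) if k]
        chars = {t: aa[seqs[t]].copy() for t in kept_taxa}
        gappy = rng.random(length) < gap_rate
        for col in np.flatnonzero(gappy):
            frac = rng.uniform(0.5, 0.95)
            mask = rng.random(len(kept_taxa)) < frac
            for t, hit in zip(kept_taxa, mask):
                if hit:
                    chars[t][col] = "-"
        name = f"{prefix}{li:0{width}d}"
        loci[name] = Alignment(
            rows={t: "".join(chars[t]) for t in kept_taxa}, name=name, aligned=True
        )
        locus_taxa[name] = tuple(kept_taxa)
        locus_lengths[name] = length
    truth = LocusTruth(tree=tree, locus_taxa=locus_taxa, locus_lengths=locus_lengths)
    return loci, truth


# ---------------------------------------------------------------------------
# Contaminated assemblies
# ---------------------------------------------------------------------------


@dataclass
class ContaminationTruth:
    """True source category per simulated sequence."""

    categories: dict[str, str]

    def of(self, seq_id: str) -> str:
        return self.categories[seq_id]


def sim_contaminated_assembly(
    n_sequences: int,
    seed: int,
    fractions: Mapping[str, float] | None = None,
    noise_sd: float = 0.0,
    length_range: tuple[int, int] = (100, 300),
    max_hits: int = 10,
) -> tuple[dict[str, str], HitTable, ContaminationTruth]:
    """Simulate an assembly with known contaminant content plus its hit table.

    Each sequence is assigned a true source category (``fractions`` over the
    contaminant categories; the remainder is genuine nuclear). The hit
    table gives every sequence a top hit to a reference of its true
    category (base bitscore 150) and two decoy hits to other categories
    (base bitscore 100), each perturbed by N(0, ``noise_sd``) — so at zero
    noise best-hit decontamination must recover the truth exactly, while
    larger noise flips ranks at predictable rates.
    """
    fractions = dict(
        fractions
        if fractions is not None
        else {"bacteria": 0.04, "fungi": 0.02, "viruses": 0.01, "archaea": 0.01, "plastid": 0.02}
    )
    unknown = set(fractions) - set(CONTAMINANT_CATEGORIES)
    if unknown:
        raise ValueError(f"unknown contaminant categories: {sorted(unknown)}")
    total = sum(fractions.values())
    if total > 1.0 + 1e-12:
        raise ValueError("contaminant fractions must sum to at most 1")
    rng = np.random.default_rng([int(seed), 7_004])
    categories = list(fractions) + [KEEP_CATEGORY]
    probs = np.array(list(fractions.values()) + [1.0 - total])
    assigned = rng.choice(len(categories), size=n_sequences, p=probs)

    refs = {cat: [f"{cat}_ref{j}" for j in range(3)] for cat in categories}
    category_map = {ref: cat for cat, names in refs.items() for ref in names}
    aa = np.array(list(AMINO_ACIDS), dtype="<U1")
    sequences: dict[str, str] = {}
    truth: dict[str, str] = {}
    records: list[tuple[str, str, float, float]] = []
    for i in range(n_sequences):
        seq_id = f"contig{i + 1:05d}"
        cat = categories[assigned[i]]
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        sequences[seq_id] = "".join(aa[rng.integers(0, 20, size=length)])
        truth[seq_id] = cat
        true_ref = refs[cat][int(rng.integers(len(refs[cat])))]
        top_score = 150.0 + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
        records.append((seq_id, true_ref, max(top_score, 0.0), 10.0 ** (-top_score / 10)))
        others = [c for c in categories if c != cat]
        for c in rng.choice(len(others), size=min(2, len(others)), replace=False):
            decoy_cat = others[int(c)]
            ref = refs[decoy_cat][int(rng.integers(len(refs[decoy_cat])))]
            score = 100.0 + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
            records.append((seq_id, ref, max(score, 0.0), 10.0 ** (-score / 10)))
    hits = HitTable.from_records(records, category_map, max_hits=max_hits)
    return sequences, hits, ContaminationTruth(categories=truth)
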