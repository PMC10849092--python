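# Methods

This note documents the models, procedures and numerical choices behind
klebkit, and what the synthetic-data tests do and do not establish about
behaviour on real data.

## Decontamination by best hit

Input is a per-query table of similarity hits (12-column BLAST/MMseqs2
tabular) plus a target → category map. Hits are ordered per query by
(bitscore descending, e-value ascending, target id ascending) — a total
order, so ranking is deterministic across platforms — and truncated at a
configurable maximum (default 10 hits per query). A sequence is retained
iff its top hit belongs to the in-group nuclear category *and* no other
category ties the top bitscore; a tie with any contaminant removes the
sequence. The rationale is asymmetric costs: discarding a genuine
sequence shrinks the dataset slightly, while admitting a contaminant can
corrupt a locus. Removed sequences are routed into one set per
contaminant category (keyed by the best-ranked contaminant among the top
hits) for inspection. Queries with no hits are kept by default but
tallied separately; a strict mode drops them instead, since the original
wording of "retain only best matches" is ambiguous for hitless queries
and both readings are defensible.

## Occupancy filters

Group-occupancy filtering keeps an orthogroup iff its members span at
least `min_groups` distinct taxonomic groups; taxon-count filtering keeps
it iff it contains at least `min_taxa` distinct taxa. Groups and taxa are
counted once regardless of how many sequences a taxon contributes. Both
filters partition their input exactly and are idempotent and monotone in
their thresholds; the tests verify all three properties against
brute-force recounts. The 14-group and 4-group taxonomies used by the
published workflows are deposited data, not printed tables, so the
package ships *synthetic approximations* (marked as such in their file
names and docstrings) that users should replace with their own tables.

## Trimming and concatenation

A column is removed iff its gap fraction is strictly greater than the
threshold: a 4-row column with exactly 3 gaps (0.75) survives a 0.75
threshold. The gap alphabet is `{-, ?}`; `X` is an observed residue of
unknown identity, not missingness, and counts as data. The two default
thresholds (0.75 per locus before concatenation, 0.65 after) mirror the
two passes of the workflow the package supports but are plain arguments.
Concatenation sorts taxa lexicographically (byte-reproducible output),
fills absent taxon × locus cells with `-`, and records partitions as
1-based inclusive coordinates in the RAxML dialect (0-based half-open
internally). Slicing a partition back out of the supermatrix reproduces
the input locus exactly, which the tests exercise as a round-trip
identity.

## Gene jackknife

Replicates draw loci uniformly without replacement, accumulating until
the concatenated length *first reaches or exceeds* the target; the
overshooting locus is included so every replicate carries at least the
stated information content (a `stop_below` flag gives the conservative
alternative). Per-replicate seeds are derived from (master seed, target
length, replicate index), so each length tier is independently
reproducible, and the manifest records every seed, locus subset and
engine invocation. Support for a reference branch is the fraction of
replicate trees whose bipartition set contains it; bipartitions are
compared as unordered leaf-set pairs, so root placement is irrelevant.
Summaries report the fraction of branches strictly above each threshold
plus a separate exact-1.0 tally, matching the usual ">95%" and "100%"
reporting conventions. The built-in engine is neighbor joining on
uncorrected p-distances (pairwise-complete columns; saturation value 0.75
for incomparable pairs; negative NJ branch lengths clamped to zero) — it
exists so that desk-scale closed-loop tests need no external ML binary,
not as a recommendation for real analyses, which should use
`CommandEngine` with an ML program. A replicate whose engine fails or
whose drawn loci do not cover the reference leaf set is recorded as
failed; more than 10% failures in a tier aborts the run.

## Mk ancestral state reconstruction

Rate schemes: ER (1 free rate), SYM (k(k−1)/2), ARD (k(k−1)), and
FIXED_RATIO for two states with a fixed forward/backward ratio such as
2:1 (1 free rate). Because the direction of an a priori 2:1 asymmetry is
a modelling choice, `run_acsr` computes both directions by default and
reports them as separate models. All characters are unordered. The root
prior defaults to flat — the common convention of re-rooting
implementations — with a stationary-prior option that matters only for
asymmetric models, where flat ≠ stationary.

The likelihood uses Felsenstein pruning with per-node rescaling, so log
likelihoods are exact and underflow-free for trees with hundreds of
tips. `exp(Qt)` is computed once per unique branch length and cached;
correctness rather than speed is the contract, and the implementation is
vectorised across characters so that pooled fits over thousands of
simulated characters remain fast. Missing tips (explicit `?`, or tree
taxa absent from the trait table, which trigger a warning) contribute
all-ones partial likelihoods.

Marginal reconstruction uses a two-pass (downward conditional
likelihoods, then an upward "outside" pass seeded with the root prior);
the normalised product at each node is exactly the distribution obtained
by re-rooting the tree at that node and combining directional
conditionals — the re-rooting method — and the two formulations coincide
for the reversible schemes (ER/SYM, and any 2-state chain). Tests verify
both the likelihood and every node marginal against brute-force
enumeration over all internal-state assignments on random trees of ≤ 6
tips and k ∈ {2, 3, 4}, at 1e-8 tolerance (observed agreement is at
machine precision), and verify invariance of the likelihood to
re-rooting for reversible models.

Optimisation is multi-start L-BFGS-B on log rates with bounds
`[1e-8, 1e3]` per unit branch length: three deterministic starts sweep
around 1/tree-depth and the remainder are seeded log-uniform draws. All
starts' optima are reported so boundary fits (e.g. invariant characters
collapsing to the lower bound) are recognizable. An invariant character
legitimately yields a boundary fit with log-likelihood equal to the log
root prior.

Coding schemes: the 2-state scheme pools every non-unicellular growth
form (sarcinoid, coccoid, filamentous, parenchymatous, multicellular)
into "multicellular sensu lato"; a 3-state scheme separates sarcinoid
packets from filamentous-or-more-complex growth; a 4-state scheme
distinguishes unicellular / coccoid / filamentous / multicellular sensu
stricto; habitat schemes code terrestrial vs aquatic and humid vs arid.
Labels are matched case-insensitively and unmapped labels are hard
errors, never silently dropped.

## Synthetic data

The generators define the study conditions for all closed-loop tests.
Trees are pure-birth with all tips extant (hence ultrametric), by default
rescaled to unit depth so rates are interpretable per tree depth; the
default 40 tips match the scale of the chronograms the reconstruction
stage is aimed at. Characters evolve by drawing from `exp(Qt)` down each
branch with the true state recorded at every node. Loci (default 200 per
set, lengths uniform on 300–900 aligned amino acids, 90% taxon occupancy,
10% gappy-column rate) evolve under a 20-state uniform-exchangeability
amino-acid model — deliberately simpler than empirical matrices like LG,
because the pipeline under test never assumes the generating model; a
"gappy" column replaces a random 50–95% of its rows with gaps, producing
exactly the columns threshold trimming is meant to remove. Contaminated
assemblies default to a 10% total contaminant load spread over the five
categories, a realistic order of magnitude for transcriptome assemblies;
each sequence's true-category reference scores 150 and decoys 100, with
optional Gaussian bitscore noise to induce rank flips.

What passing these tests shows: the algorithms implement their stated
rules exactly and recover known truth when the signal is clean. What
they do not show: robustness to alignment error, rate heterogeneity
across sites or lineages, indels, paralogy, or model misspecification in
real transcriptome data — none of which the generators emulate.

## Validation experiment sizes and design choices

The acceptance script and test suite use desk-scale problem sizes chosen
to make each property measurable with comfortable statistical margins:
100 random oracle instances; rate recovery on a 64-tip tree with 1000 vs
100 characters, averaged over 5 replicate simulations (a single replicate
can invert the expected error ordering by chance); ancestral-state
recovery over 100 single-character reconstructions on a 40-tip tree with
a generating rate of 0.5 per unit depth (enough change to be non-trivial,
little enough that the root remains inferable); and a jackknife closed
loop of 200 concordant loci, 20 replicates at 5000 columns on a 16-taxon
tree. For the closed loop the reference tree is required to have every
internal branch ≥ 0.01 (≥ ~50 expected substitutions per replicate),
redrawing deterministically until that holds: the experiment asserts that
a concordant, *informative* locus set recovers every branch, and a
near-zero branch is unresolvable in principle at any replicate length,
which would turn the measurement into a statement about the random tree
rather than about the method.

## Known limitations

* The NJ engine is a test fixture; real branch support should come from
  an ML engine via `CommandEngine`.
* FIXED_RATIO is implemented for two states only.
* Mk fitting assumes a single character model per fit; correlated traits,
  hidden rate classes and stochastic character mapping are out of scope.
* Node ages are consumed as branch lengths, never estimated; time
  calibration must happen upstream.
* The bundled taxonomy tables are synthetic stand-ins meant to be
  replaced by study-specific group assignments.
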