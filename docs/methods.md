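# Methods

This note documents the models and procedures implemented in `cretrace`,
the parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic data does and does not emulate.

## Sequence handling and alignment

Sequences are uppercase DNA over {A,C,G,T}; records containing undetermined
bases (N) are rejected at load with `InvalidSequenceError` rather than
silently dropped (`read_fasta(..., drop_invalid=True)` and the CLI flag
`--drop-invalid` reproduce the discard behavior used when assembling
ortholog libraries). Coordinates are 0-based, half-open throughout,
including multiple-sequence-alignment (MSA) columns.

Global pairwise alignment is a three-state Gotoh dynamic program; the
linear-gap case is the special case `open_cost == gap_extend`. Two presets
are shipped:

- `RECONSTITUTION` — match 1, mismatch −1, gap −1 per column (linear);
  used for ancestor/extant mutation enumeration and identity/divergence.
- `ORIENTATION` — match 1, mismatch 0, affine gap opening −2 and extension
  −8 per column; used to pick the strand of a retrieved ortholog (the
  mismatch score follows the fuzzy-match default of the R alignment
  routine this parameterization originates from).

The DP is implemented in-package rather than delegated to a library
aligner because downstream trajectory design requires a *fixed,
deterministic tie-break*: traceback prefers the diagonal move, then a gap
in the target row (deletion), then a gap in the ancestor row (insertion).
Exhaustive-enumeration oracles in the test suite verify score optimality.
Note that under unit scoring a substitution adjacent to a repeat can tie
with a deletion+insertion placement; either alignment is score-optimal and
the tie-break picks one deterministically.

Mutation events are anchored in alignment-column space: substitutions are
single-column events, maximal runs of same-kind gap columns merge into one
indel event, and applying any subset of events edits columns in place, so
application order can never shift coordinates. Percent identity defaults
to matched columns over *all* alignment columns (gap columns included);
`denominator="ungapped"` is available.

## TFBS affinity model

A PSAM (position-specific affinity matrix) stores per-position, per-base
relative affinities; rows are max-normalized to 1 at load so the consensus
k-mer scores exactly 1 — a convention this package fixes because raw PSAM
scales are arbitrary. The raw affinity of a window is the product of
per-position weights; both strands are scanned (the reverse-strand score of
a window is the forward score of its reverse complement).

Raw affinities are normalized per TF by the q99.99 quantile of raw scores
over n = 10^6 uniformly random k-mers (seeded, cached, reproducible). The
wording "maximum affinity … (affinity > q99.99)" that motivates this
normalizer is internally ambiguous; the quantile reading is the default and
`method="max"` is available. The *exhaustive* reference implementation
enumerates all 4^k k-mers and takes the inverse-CDF quantile — the
definition the sampled estimator converges to; interpolating quantile
definitions disagree in the extreme tail because the affinity distribution
has large atoms (consensus and near-consensus k-mers). Random k-mers are
uniform over bases; composition-matched sampling is not implemented.

Hit calling: one candidate per start position, strand forward iff
fwd ≥ rev (ties forward), reported affinity = max(fwd, rev)/normalizer,
retained iff *strictly* greater than the threshold (default 0.05,
dimensionless). Paralogous TFs are merged per (sequence, start) by maximal
normalized affinity under a group label (e.g. "Gata4/6"). Overlap with
reference functional sites uses an any-overlap rule (≥ 1 shared position);
when several sites overlap a hit, the largest overlap wins, leftmost on
ties; unassigned hits are "novel".

## Phylogeny and lineage tracing

Trees are read from Newick via dendropy. Internal node labels are
*required* (error if absent): every downstream semantic — lineage paths,
step changes, derived mutations — references named ancestors. Polytomies
are allowed.

A step change on edge (parent, child) is `log2(μ_child / μ_parent)`.
Activities at or below a configurable floor (default 0; in practice the
negative-control mean) are treated as inactive and produce an undefined
(sentinel) step rather than a log2 against ~0. Defined steps telescope
exactly. `top_step_changes` sorts descending with a stable tie-break, so
an all-zero path returns its first k edges in path order.

Derived mutations on an edge are events where the child differs from its
immediate path predecessor AND the child state equals the extant state over
the event's MSA columns — i.e. changes that are retained to the present.
Spearman correlations in clade summaries use average ranks for ties and
are reported as NaN for clades with fewer than 3 points or constant input.

## Scoring oracle and marginal footprint

Any object with `score(Sequence) -> float` is an oracle. Real
sequence-to-accessibility models attach through a batch subprocess
contract (`ExternalOracle`: input FASTA → two-column TSV of scores), which
keeps heavyweight model runtimes out of the package's dependencies.

The shipped surrogate is a deterministic motif-gated activity function:

    score(s) = b0                                    if any required site absent
             = min(c_max, b0 + Σ_h w_tf(h) · a_h)    otherwise

over called, paralog-merged hits h with normalized affinity a_h. The
required-module AND gate (all of Foxa2, Sox17, Gata4/6 at minimum affinity
0.3 in the default configuration) encodes the empirical observation that a
heterotypic module is necessary but not sufficient; the ceiling c_max makes
boosters saturating. Defaults: b0 = 0.1, c_max = 8.0 (MPRA-activity-like
units), booster weights 1.0–2.0 per site. The surrogate is pure given its
configuration; its normalizers are computed once at construction from the
configured seed.

The marginal footprint embeds a candidate at the center of n background
sequences (replacing the central |candidate| bases, keeping the length the
oracle sees fixed), and reports mean embedded score divided by the pooled
mean background-only score (ratio of means; `mean_of_ratios` is available
— the source wording "averaged the predictions … normalized by the null
value" admits both). Backgrounds default to a seeded i.i.d. sampler;
user-supplied FASTA is accepted. Fixtures use tens of backgrounds; the
production-scale 1,000 is supported.

## Trajectories

Greedy reconstitution scores, at every step, each remaining mutation
applied singly to the current intermediate, and commits the argmax. Ties
break on lowest alignment column then lexicographic derived allele, making
trajectories reproducible without a seed. Candidates are scored by the raw
oracle by default and by the marginal footprint when background sequences
are supplied; one scorer is used throughout a run. (For the surrogate with
a pooled-null ratio-of-means footprint the two give identical greedy
choices — the ratio is monotone in the raw score — so the cheaper default
is the raw score.)

Random controls are independent uniform permutations of the same event set
(n = 10 by default), seeded. All reconstitution trajectories over a pair
share the endpoint and step count by construction. The phylogeny
trajectory passes through the ancestral orthologs in path order, with
percent divergence from the target (by global alignment) as its x-axis.

De novo tuning evaluates all 3L single-base substitutions per step
(substitutions only, never indels) for a fixed number of steps (default
50), committing argmax (enhance) or argmin (ablate). A candidate equal to
the immediately preceding sequence is excluded — a cycle guard added here
because a non-monotone oracle could otherwise oscillate; positions may be
mutated repeatedly. Step k is the sequence after k committed mutations;
step 0 is the unmutated start.

`reconstituted_tfbs_count` maps each reference functional site onto the
query through a global alignment and counts sites whose best normalized
affinity over the mapped window (own TF or any paralog-group member)
reaches the endogenous value; sites whose window is deleted count as not
reconstituted.

## MPRA quantification

Per replicate, each barcode's RNA and DNA UMI counts are divided by their
sample totals. The element activity estimator winsorizes the normalized
RNA and DNA vectors within the element at the [f, 1−f] quantiles
(f = 0.01 by default), sums each, and reports the ratio — the "winsorize
counts, then sum, then ratio" reading of the 1%-winsorized summed RNA/DNA
statistic; the alternative "winsorize per-barcode ratios, then mean" is
behind `method="ratio_mean"`. Both are tested. With f = 0 the estimator
reduces exactly to the plain summed ratio. Winsorization quantiles use
linear interpolation (numpy default), making results bit-reproducible.

Barcodes with zero DNA are excluded (a pseudocount flag exists, default
0). The barcode-map read-support filter defaults to min_reads = 2
(threshold not externally specified; configurable). Replicate summaries
are mean and standard error; fold changes divide by the mean
negative-control activity. The bootstrap CI helper is a convenience over
barcodes and is explicitly not a differential-activity test.

## Epistasis analytics

"Additive" is defined on the linear activity scale,
`ŷ = y0 + Σ(y_i − y0)` floored at 0; "multiplicative" is additive in
log2, `ŷ = y0 · Π(y_i/y0)`, where `y_i = y0·2^effect_i` are
single-mutation activities on a fixed measurement background. The two
coincide exactly for single mutations. The standing caveat — single
effects are measured on the extant background while trajectories start
from the ancestor — is surfaced in output metadata.

Order dependence: a mutation's per-step effect is log2(after/before) at
the step introducing it; the spread of that effect across trajectory
contexts (sd, ddof=1) is compared with replicate noise propagated to a
step difference, `sqrt(se_before² + se_after²)` in log2 units, summarized
as the root mean square across contexts. Mutations seen in fewer than two
trajectories are excluded with a warning.

TFBS attribution counts only positive per-step log2 gains (the "share of
functional recovery" reading); the expected share is mutation-count-based
(fraction of mutations overlapping a functional site), with a length-based
variant left to the caller. Step classification: *reconstituting* = first
raises an overlapped site's affinity from ≤ threshold to > threshold;
*optimizing* = changes an already-called site; *background* = overlaps no
reference site.

## Synthetic data

The simulator evolves a root sequence down a labeled tree: per branch,
substitution and indel counts are Poisson(L × rate × branch length),
positions uniform, derived bases uniform over alternatives
(Jukes–Cantor-like; no transition/transversion or CpG structure), indel
lengths geometric with mean 1.5. Every residue carries a stable token, so
the simulator emits an exact MSA, an event log that replays to each node,
and per-leaf retention flags — the ground truth for lineage-tracing tests.

Regulatory structure is *planted*: motif-creating or motif-destroying
edits on named branches. Three guards keep the ground truth well-defined:

1. the root background is scrubbed so that no window, in any realized
   window-state (site absent, planted, or broken by a planted loss),
   scores above 1% of consensus for any canonical motif — background
   starts at least two specific substitutions away from a callable site;
2. planted windows plus a one-motif-width margin are conserved (natural
   substitutions and indels rejected there), emulating the purifying
   selection that maintains functional sites in real enhancers;
3. a site guard rejects natural edits whose surrounding windows would
   exceed a small raw-affinity ceiling, emulating selection against
   ectopic gains, so clade-restricted gains and losses are exactly the
   planted ones.

Outside those windows, sequence evolves neutrally, including reversions.
Activity truth is always the surrogate oracle's score of the node sequence
— there is no separate activity bookkeeping to drift out of sync.

Two canonical scenarios (180 bp and 240 bp elements, 13 and 31 nodes):
(i) *conserved-but-repurposed* — Foxa2 and Sox17 sites present from the
root, the module-completing Gata4 site plus two AP-1 boosters planted on
one terminal-clade branch, substitution rate 0.5 events/site per unit
branch length (root-to-leaf divergence ≈ 13–16%); (ii) *module-dependent*
— the full heterotypic triplet planted at the base of a large clade, two
independent planted losses and two independent booster gains in disjoint
subclades, rate 1.0 (divergence ≈ 25%). Branch lengths are in
substitutions/site; rates were chosen so realized divergences span the
range typical of mammalian enhancer ortholog sets, and are not revisited.

MPRA counts: barcodes get lognormal(0, 0.8) DNA abundances fixed across
replicates; per replicate, DNA UMIs are Poisson(depth × abundance share)
and RNA UMIs Poisson(depth × share ∝ activity × abundance), depth 10^6,
3 replicates, 30 barcodes/element. An element of activity 0 yields zero
RNA counts (no baseline transcription unless a floor is configured).

What the generator does *not* emulate: realistic substitution models,
selection on background sequence, barcode sequencing errors or barcode
collisions, batch effects, plasmid-preparation biases, and position
effects of the reporter. Tests passing on this data therefore validate
the pipeline's bookkeeping, estimators, and decision logic under known
truth — not the biological fidelity of any specific inference on real
data.

## Numerical and degenerate-input choices

- DP scores are floats; traceback recomputes transitions with a 1e-9
  tolerance (scores are small integers in practice).
- `log2` ratios are never computed against zero or sub-floor activities;
  sentinels (None/NaN) propagate and are excluded from sums.
- A fold change for a site deleted in one sequence is the string sentinel
  `"lost"`, not a number; a 0 → positive affinity change reports `inf`.
- Spearman ρ is NaN for < 3 points or constant input.
- Winsorization with f = 0, single-barcode elements, single replicates
  (σ = None), and empty mutation subsets are all exact no-ops.
- Scan of a sequence shorter than the motif returns an empty profile with
  a warning rather than an error.

## Known limitations

- The affine aligner is O(nm) in time and memory with full traceback
  matrices; fine for enhancer-scale inputs (≤ a few kb), not for genomic
  alignment.
- Greedy reconstitution is O(n²) oracle calls in the mutation count;
  production-scale runs with an external model should batch through
  `ExternalOracle.score_batch`.
- The surrogate oracle's gate has no spatial constraint (module sites need
  not be clustered), which is weaker than real heterotypic-module grammar.
- `derived_mutations` requires all three rows in one shared MSA; it does
  not re-align on the fly.
- The order-dependence ratio assumes approximately lognormal replicate
  noise when propagating standard errors in log2 space.
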