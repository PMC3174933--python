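# Methods

## Objective function

`orfalign` maximises an additive, integer-valued score defined purely on
the amino-acid interpretation of a codon-site alignment.  Scores rather
than costs are used throughout so that the printed defaults (BLOSUM62,
gap open −7, gap extension −1, frameshift −30, internal stop −100) plug in
with their natural signs.

Per column and per row pair:

* both cells full non-stop codons → the substitution-matrix entry of
  their translations.  Codons containing `N` translate to `X` and use the
  matrix's `X` scores.
* a frameshifted cell (1-2 `!` padding a partial codon) → that row's
  frameshift score, once per site regardless of whether one or two
  nucleotides are missing: a single 1-2 nt deletion is one event.  No
  substitution term is added when either side is frameshifted or a stop,
  so a stop facing a frameshift costs `stop + fs`.
* a `---` cell → one gap-extension score, plus one gap-opening score per
  maximal internal gap run (affine gaps in codon-site units; the
  objective never looks below the codon-site level).
* nucleotide-level substitution scoring is deliberately out of scope: the
  objective is the amino-acid alignment score only.

### Terminal exemptions

Terminal gap runs are free (semi-global convention), and a stop codon in
a row's final codon position is free: ORFs normally end with one.

Frameshifts at sequence extremities need more care, and the rule adopted
here is deliberately narrow: **only the forced incomplete tail codon is
free** — the trailing partial codon of length `n mod 3` that a sequence of
length `n ≢ 0 (mod 3)` cannot avoid.  Every other frameshifted site,
including 1-2 nt chunks taken at either end of an in-frame sequence, pays
the full frameshift score.  Two cheaper-sounding alternatives fail:
making all terminal chunks free (or charging them a flat gap-extension)
lets *both* rows of a pair re-frame at their ends for (almost) nothing and
harvest spurious high-scoring codon pairs — even two identical clean ORFs
then prefer a re-framed alignment over the identity alignment, and the
reduction to classical amino-acid alignment at prohibitive frameshift cost
breaks.  With the forced-tail rule, an in-frame ORF can only leave frame 1
by paying `fs`, the identity alignment of a clean ORF with itself is
optimal, and pricing frameshifts out (`fs = −10⁶`) provably reduces the
15-move programme to a classical 3-move amino-acid aligner, which the
tests verify against Biopython's `PairwiseAligner` exactly.

## Pairwise dynamic programme

Tables are indexed by nucleotide prefix lengths `(i, j)`.  Each cell is
reachable from the 4×4 square of predecessors: 15 moves `(da, db)`,
`0 ≤ da, db ≤ 3`, `(0,0)` excluded.  A chunk of 1-2 nucleotides is padded
with leading `!` into a frameshifted site; `da = 0` (or `db = 0`)
produces a `---` site.  Affine gaps use three state tables (match /
deletion / insertion) in the Gotoh manner, with gap opening charged on
entering a gap state.  Only the `(0,0)` cell of the match table is
initialised; all other boundary accesses return a −2⁴⁰ sentinel that can
never win the maximisation, so first/last rows and columns need no special
initialisation.  Terminal gap freedom falls out of zero-cost gap moves
along the `j ∈ {0, m}` / `i ∈ {0, n}` borders.

Ties are broken deterministically: fewer total frameshifts first, then
the lexicographically larger `(da, db)`, then previous state in the order
match > deletion > insertion.  This biases reconstruction toward
frameshift-free explanations and makes output byte-reproducible.

The kernels are compiled with numba; the fill is
`(n+1)(m+1)` cells × 3 states × ≤ 15 candidate moves — the same
`O(nm)` complexity as Needleman-Wunsch at five times the per-cell work.

A frameshifted chunk facing a gap (`da ∈ {1,2}, db = 0`) charges both the
frameshift score and the gap costs of the gap row: a partial codon facing
nothing is both an event and an indel.

### Validation oracles

Three independent layers: (1) an exhaustive enumerator generates every
move sequence for inputs of ≤ ~12 nt and scores finished alignments with
the natural run-level scorer (`score_induced_pair`), the same function
that defines the sum-of-pairs objective; (2) a memoised top-down recursion
(`oracle_align`, refusing inputs > 24 nt combined) shares no code or
mechanism with the production kernel and is checked against (1); (3) the
production DP is checked against (2) on hundreds of random pairs under
random penalty draws, and its reported score is always recomputed from the
returned columns by the natural scorer before being returned.

## Multiple alignment

The MSA objective is the sum-of-pairs (SP) score: induced pairwise
alignments (dual-gap columns dropped) scored exactly as above.  The
pipeline is classical progressive alignment plus refinement:

* **Distances**: presence/absence sets of nucleotide 6-mers; similarity =
  shared types / smaller repertoire; distance = 1 − similarity.  The
  source method names neither `k` nor the formula; `k = 6` with
  min-normalisation mirrors common compositional practice and is a
  parameter.  Sequences shorter than `k` get distance 1 with a warning.
* **Guide tree**: UPGMA (arithmetic average linkage).  Ties merge the
  lexicographically smallest label pair (a cluster is labelled by its
  smallest member), making the tree deterministic.  The tree groups
  similar sequences for merge ordering; it is not a phylogeny.
* **Progressive merging**, post-order: two leaves use the full 15-move
  pairwise DP; a leaf against a block uses a hybrid 7-move DP whose moves
  consume one block column against 0-3 nucleotides of the sequence (or
  insert an all-gap column against a 1-3 nt chunk), so *new* frameshifts
  can still be placed in the incoming sequence; block-vs-block merges use
  a 3-move column DP.  Columns are atomic in block merges — no new
  frameshifts can arise there — which is what makes the frameshift
  representation (`!` padding inside a real codon site, never a "ghost"
  all-`!` codon) compatible with alignment-of-alignments in the first
  place.  Insertion-type frameshifts are therefore never modelled as
  such: an extra nucleotide in one sequence surfaces as `!` padding in the
  other rows facing it.
* **Gap costs when merging blocks**: extension costs come from per-column
  gap counts; opening costs use Altschul's quasi-natural ("pessimistic")
  count, computed from the gap configurations of the current and previous
  output column per cross pair of rows, with `!`-sites counted as
  residues.  The per-pair definition lives in `orfalign.gaps` next to an
  exact natural counter; the factorised per-column formulas inside the
  kernels are tested against those reference counters.  Terminal freedom
  in the merge DPs is block-level (gap columns beyond the other operand's
  first/last column are free); per-row terminal runs inside a block are
  approximated.  This only steers candidate generation — acceptance of
  any refinement step is always judged by the exact natural SP score.
* **2-cut refinement**: for each non-root guide-tree clade, split the
  current alignment into clade rows vs the rest (silently dropping
  all-gap columns on each side), re-merge (the hybrid DP when one side is
  a single row, so frameshifts can be re-placed; the column DP
  otherwise), and keep the candidate only if its natural SP score
  strictly increases.  After a full sweep the guide tree is re-estimated
  from normalised SP contributions — pair similarity is the induced pair
  score over the larger of the two self-scores, clamped into [0, 1] —
  and sweeping continues until a sweep yields no improvement or
  `max_iter` (default 10) sweeps have run.  The final score never falls
  below the initial one by construction.

Every merge preserves the induced sub-alignments of its operands exactly,
no output ever contains an all-gap column, and deleting `-` and `!` from
any row reproduces the input sequence byte-for-byte; these invariants are
tested after every pipeline stage.

## Two sequence sets and genetic codes

Each sequence belongs to the `reliable` or the `lowpen` set (the second
input file on the command line).  `lowpen` rows use `fs_lowpen` /
`stop_lowpen` for their own events.  Shipped guidelines: pseudogene sets
fs −20 / stop −10; raw-read sets fs −10 / stop −60.  The penalty scale
matters: with the default stop score (−100) an internal stop in a
"reliable" row is so expensive that the optimiser may prefer inventing two
frameshifts to reading through it — putting degraded sequences in the
soft set is what makes their events come out legibly.  NCBI translation
tables are taken from Biopython; a two-column `id<TAB>table` file assigns
codes per sequence, with a CLI default for unlisted ones.

## Synthetic data generator

`orfalign.simulate` builds test families with known truth: a random
stop-free ancestor ORF starting `ATG` evolves along a star topology with
per-codon substitutions (uniform over the 61 non-stop codons, so a 5%
setting is an upper bound on the realised change rate) and optional codon
indels, then explicit 1-2 nt deletions and premature stops are injected at
recorded positions.  The star topology keeps per-sequence truth exact; it
does not emulate realistic codon models (no dN/dS structure, no rate
heterogeneity, no transition/transversion bias) or real read-error
profiles (no homopolymer effects), so passing recovery tests demonstrate
that the optimiser localises isolated events under moderate divergence,
not performance on any particular instrument's error spectrum.

The recovery harness injects one 1-nt deletion at a uniformly drawn codon
in `[4, n−4]` of one sequence: closer to either end a deletion merges
into the free terminal-indel/forced-tail region and stops being an
internal event at all.  The injected row is placed in the `lowpen` set
with the pseudogene guideline penalties, mirroring how a user aligning
suspected pseudogenes would run the tool.

## Problem sizes and numerical choices

All scores are integers; no floating point enters any objective, so
determinism is exact (identical inputs produce byte-identical outputs;
the CLI `-seed` flag exists for workflow reproducibility but nothing in
the pipeline draws random numbers).  The validation suite uses the sizes
at which each property is fully informative: oracle equivalence on 500
pairs of 1-8 nt (the exponential oracle's comfort zone) with random
penalty draws, the amino-acid-aligner reduction on 100 ORF pairs of 2-15
codons, SP-monotonicity and structural invariants on 100 simulated
families of 5-10 sequences × 30 codons with indels and an injected
frameshift, and frameshift recovery on 100 families of 5 sequences × 100
codons at 5% codon substitution probability, one 1-nt deletion each.

## Known limitations

* Insertion-type frameshifts are represented indirectly (as `!` in the
  other rows), which over-penalises them in deep alignments.
* The quasi-natural opening count and block-level terminal freedom make
  merge candidate generation approximate; only accepted-step monotonicity
  of the exact SP score is guaranteed, not global optimality (exact SP
  optimisation is NP-hard and out of scope).
* Frameshift penalties are position-independent; error models in which
  frameshifts concentrate in homopolymers are not modelled.
* Local alignment (e.g. UTR-flanked ESTs) is not supported; alignment is
  semi-global.
* A deletion inside locally repetitive or near-palindromic codon context
  can be absorbed as cheap mismatches instead of an event when the
  penalties outweigh the substitution losses — the ±1-codon localisation
  tolerance of the recovery harness reflects the inherent ambiguity of
  placing an event inside identical neighbouring codons.
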