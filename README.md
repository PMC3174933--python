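# orfalign

Codon-aware multiple alignment of protein-coding nucleotide sequences that
explicitly models **frameshifts** and **stop codons**.

Most pipelines align coding DNA by translating every sequence in frame 1,
aligning the proteins, and back-threading the gaps at codon level.  That
breaks down on exactly the sequences molecular evolution studies often need
most: pseudogenes accumulating frame disruptions and premature stops,
high-throughput sequencing reads with indel errors, and mis-annotated CDSs
in public databases.  A single extra or missing nucleotide derails the
translation of everything downstream, and a single premature `*` aborts the
protein alignment.

`orfalign` scores alignments at the amino-acid level while letting each
sequence shift its reading frame at an explicit, penalised cost.  In the
output a 1-2 nt deletion that disrupts the frame is padded to a full codon
site with `!` (e.g. `!CG`), and internal stop codons appear as `*` in the
amino-acid view without interrupting anything.  Pseudogenes stay aligned
codon-by-codon against their functional orthologs, so downstream codon
models (dN/dS and friends) can run directly on the output, and the reported
`!`/`*` positions localise the underlying sequencing errors or
pseudogenization events.

## The model

An alignment is a sequence of *codon-site* columns; each row's cell is
either a full codon, a `!`-padded partial codon (frameshift), or `---`.
The additive, maximised objective scores a column as:

* `d(X, Y)` — BLOSUM62 entry of the two translations when both cells are
  full non-stop codons (`N`-containing codons translate to `X`);
* `cost_fs` (default −30) per frameshifted cell — no substitution term is
  added for that pair, so `*` facing `!` costs `cost_stop + cost_fs`;
* `cost_stop` (default −100) per *internal* stop-codon cell; a stop in a
  row's final codon position is free;
* affine gaps in codon-site units: `gap_open` −7 per maximal internal gap
  run plus `gap_ext` −1 per gap cell, with terminal gap runs free
  (semi-global).  The incomplete tail codon of a sequence whose length is
  not a multiple of 3 is an accident of sequence extent, not an event, and
  is free.

The optimal pairwise alignment comes from a Needleman-Wunsch/Gotoh-style
dynamic programme over nucleotide prefix lengths in which each cell looks
back at the 4×4 square of predecessors — **15 moves** instead of the
classical 3 (so five-fold work per cell, same asymptotic complexity).
Three moves are the classical codon substitution/insertion/deletion; the
other 12 consume 1-2 nucleotides on some side and induce frameshifts.
Affine gaps use three state tables; only cell (0,0) is initialised and all
other boundaries flow through a −∞ sentinel.

Multiple alignment is classical progressive + iterative refinement on top
of that pairwise engine: 6-mer distances → UPGMA guide tree → bottom-up
merging (sequence-vs-block merges use a hybrid 7-move DP that can still
re-frame the incoming sequence; block-vs-block merges align columns under
the sum-of-pairs objective with Altschul's quasi-natural "pessimistic"
gap-opening count) → 2-cut refinement that re-splits the alignment along
guide-tree clades and keeps strict sum-of-pairs improvements, re-estimating
the tree after every sweep.

Two *sequence sets* can carry different event penalties: guideline values
are fs −20 / stop −10 for pseudogene sets and fs −10 / stop −60 for raw
read sets, alongside the defaults (−30 / −100) for trusted sequences.
Alternative NCBI genetic codes are supported globally or per sequence.

## Worked example

A three-mammal ORF family plus one pseudogene copy that lost one
nucleotide in codon 4 and gained a premature TAG stop:

```bash
orfalign -i orfs.fasta -i2 pseudo.fasta -o family -fs2 -20 -stop2 -10
```

`family_NT.fasta`:

```text
>human
ATGGCTTTTCTCTCGGTGCTGAAGGCCAGGATCACCCCA
>mouse
ATGGCTTTTCTGTCGGTGTTGAAGGCGAGGATTACCCCA
>rat
ATGGCTTTTCTGTCTGTGTTGAAGGCAAGGATTACCCCA
>whale_psi
ATGGCTTTT!CGTCGGTGCTGTAGGCCAGGATCACTCCA
```

`family_AA.fasta`:

```text
>human
MAFLSVLKARITP
>mouse
MAFLSVLKARITP
>rat
MAFLSVLKARITP
>whale_psi
MAF!SVL*ARITP
```

`family_events.tsv`:

```text
sequence_id	event_type	nt_position	codon_column
whale_psi	frameshift	10	4
whale_psi	internal_stop	21	8
```

Reading: the pseudogene is frameshifted at alignment codon 4 (`!CG`, the
deletion sits at nucleotide 10 of the original sequence) and carries an
internal stop at codon 8 — both flagged without disturbing the codon
structure of the three functional rows, whose nucleotide rows are printed
unchanged.  `family_log.txt` records the parameters, the final guide tree
in Newick form, and the sum-of-pairs trajectory of the refinement.

The same functionality is available as a library
(`orfalign.align_sequences`, `orfalign.align_pair`, ...), and
`orfalign.simulate` generates coding families with known injected
frameshifts/stops for validation work.

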