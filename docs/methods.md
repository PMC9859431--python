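# Methods

## Coordinate model

All coordinates are 1-based inclusive on the plus-orientation reference
(the strand on which coordinates increase in the printed gene table);
PAF/BED 0-based half-open inputs are converted at the file boundary.
Circularity is carried as a `wraps` flag: a wrapped span occupies
`start..L` then `1..end`, and coordinates never exceed the genome length.
Orientation is internal `plus`/`minus` (plus = increasing-coordinate
transcription).  Published strand labels for this study system are
inconsistent between the gene table and the transcript descriptions, so the
mapping to J/N labels is applied only when writing fixture-style tables;
all inference uses the geometric convention.  Under it, the plus primary
transcript initiates at 15,377 in the control region (CR), crosses the
origin, and terminates at the trnS2/ND1 junction; the minus primary
initiates at 15,189, crosses the origin, and terminates at 15,406 in CR.
This assignment is forced by the transcript coordinates themselves: the
CR/trnI transcript (15,378→45) increases through the origin, the astrnI/CR
transcript (72→15,406) decreases through it, and the silent region lies at
coordinates just above trnS2 — exactly the loci antisense to ND1–srRNA,
which only the plus primary could have produced.

## Boundary refinement

*PCG 3′ ends.*  The dominant polyA-backed mature end (modal position after
collapsing within ±3 nt; ties prefer the current annotation) becomes the
new 3′ boundary, and the stop codon is recomputed from the genome: a full
UAA/UAG if the final codon is complete, otherwise the U or UA remnant that
polyadenylation completes.  Ends whose remnant cannot be A-completed are
flagged and the gene left unchanged, and the boundary never extends past
the DNA-based stop codon.  Where a stop codon's A residues could be either
templated or added post-transcriptionally, the boundary is placed at the
last genome-templated base, matching the printed table.

*PCG 5′ ends* move to the dominant transcript 5′ end only if a valid start
codon begins there ({AUU, AUC, AUA, AUG, GUG, UUG} — the standard
invertebrate mitochondrial set, a superset of the four codons appearing in
the packaged table); otherwise the nearest in-frame start within 12 nt
downstream is used, else the gene is left unchanged with a warning.

*rRNA ends* take the highest-support end cluster with support ≥ 3 (the
packaged fixture's srRNA 5′ revision is supported by 273 reads; no
published threshold exists, so a deliberately low floor is used and
exposed as a parameter).  Ties break toward the longer gene.

*Control region.*  After gene refinement the CR is the single largest
unannotated gap on the circle; two equally largest gaps are an error.
Overlap validation checks same-orientation gene pairs only and exempts the
two bicistron ORF pairs (ATP8/ATP6, ND4/ND4L), which overlap in the DNA
itself; this reproduces exactly the five overlaps that disappear upon
refinement.  Refinement is idempotent for fixed evidence.

*Evidence collection* assigns a read to a gene by reciprocal overlap ≥ 0.9
(so mature reads extending past a mis-drawn DNA boundary still count while
bicistronic reads match no single gene); a 3′ end is polyA-backed when the
unaligned tail (after any CCA) is ≥ 5 nt and ≥ 90% A.

## Classification and expression

Units are genes covered ≥ 50% by the read footprint, ordered along the
read path, antisense loci prefixed `as`.  Precedence: a read with an end
inside the CR is a CR lncRNA; a read whose covered genes are all
opposite-strand is antisense; one sense unit → mature monocistron (end
state records degradation); the whitelisted pairs ATP8/ATP6 and ND4/ND4L →
mature bicistron (ND6/CYTB and ATP8/ATP6/COX3 are deliberately excluded:
in this clade those precursors are cleaved to the forms above); otherwise
an unprocessed polycistronic precursor.  Classification is per-read and
deterministic, hence order-independent.  Expression counts: mature (and
truncated-mature) reads add one sense count per member gene; antisense
reads add antisense counts; precursors and CR lncRNAs are reported
separately, since published per-gene counts do not state whether precursor
reads were included.  End tolerance defaults to ±3 nt everywhere
("ends within gene boundaries" is published without a tolerance).

## Processing signals

*Tails.*  The longest tail prefix matching the genomic continuation of the
aligned 3′ end is templated.  For tRNAs a remaining exact CCA prefix is the
non-templated nucleotidyltransferase product; a single mismatch in CCA is
conservatively called absent, and the exhaustive 64-trimer test guarantees
zero false positives on templated continuations.  A polyA call requires
≥ 5 nt at ≥ 90% A (unquantified in the source; exposed as `min_polyA`).

*Cleavage direction.*  Only precursors whose read ends sit within
tolerance of their first unit's 5′ and last unit's 3′ ends are
informative.  For a focal mRNA/rRNA with its upstream-adjacent tRNA
retained, the first same-orientation downstream tRNA absent (walking past
retained genes to the precursor's 3′ unit) yields reverse support at the
junction (last unit, absent tRNA); the mirror yields forward support at
(absent tRNA, first unit).  Adjacency skips opposite-strand genes, which
belong to the other primary.  Per-gene bias estimates pool the two
junction types flanking each focal gene, because reverse and forward
evidence for one gene necessarily land on different junctions.

*Degradation.*  Per-gene directionality is a one-sided binomial test
(α = 0.05) on 5′- vs 3′-truncated read counts, undetermined below 10
truncated reads.  Read counts are used rather than coverage slopes; the
coverage "trapezoid" description in the literature is qualitative.

## TIS / TTS / isoforms

5′ ends are clustered greedily by descending frequency into clusters of
radius ≤ 3 nt.  A TIS is the transcriptionally most upstream cluster
inside the CR with ≥ 2 supporting reads (most upstream = smallest
coordinate for plus, largest for minus; the CR does not cross the origin).
A TTS is the 3′ end, inside the CR, of the transcript that entered the CR
from outside (5′ end outside CR) and penetrated transcriptionally
furthest; lncRNAs initiated inside the CR are not termination witnesses.
Near-TIS 5′-end scatter (e.g. 15,377/15,378/15,379) is reported as one
cluster with its spread; whether it reflects one TIS plus nibbling or
several TISs is left open, as in the source.  Junction termination scans
strand-specific mean coverage across consecutive features: downstream/
upstream ≤ 0.05 (`drop_ratio`; no published threshold) flags a junction,
a terminator if downstream mean coverage < 1 read, else an attenuator.
rRNA isoforms share a 3′ end (±3 nt) and differ at 5′-end clusters with
support ≥ max(5, 1% of the gene's reads) — the published isoform evidence
is "at least 4000" reads at full depth, so the default scales with depth.

## Repeat decomposition

Unit candidates come from self-match runs at lag p (10–50 bp, ≥ 80% match
density, mismatch stretches ≤ 3 bridged); each candidate region's copies
are phase-aligned by the frame maximising exact copy-consensus agreement
(ties prefer a consensus-exact first copy, then the run seed), consensus by
column majority, doubled periods folded to their fundamental unit, and
units requiring ≥ 2 tandem copies.  Because a block followed by a terminal
partial copy admits several equally-scoring frames, a joint re-phasing
pass aligns each unit's frame to the end of the preceding block's exact
tiling.  Decomposition is a DP over one contiguous chain of full-unit
copies (length within ±`max_edits` of the consensus, per-copy edit
distance ≤ `max_edits` = 3 by default, which absorbs length-variant
alleles like G/TTA), maximising covered length, then minimising edits,
blocks, and unit ids; one optional terminal partial (≥ 50% of unit length)
precedes the right flank.  Stored copies are literal input substrings, so
`reconstruct()` is always the identity.  Polymorphic sites are aggregated
per unit offset from edlib alignments of each copy to its consensus.
Copy-number heterogeneity across reads is summarised by per-unit
min/max/median and pairwise edit distance over block-order strings.  Edit
distances are computed with edlib throughout.

## Synthetic data generator

The generator is first-class, tested code defining the study conditions.
`simulate_genome` draws a random 16,214 bp circle that honours every
packaged codon constraint (DNA-based and refined start/stop codons,
incomplete stops written as their templated remnant only) and assembles
the CR from seeded random unit consensuses with the published block
architecture (19/18/37 bp units; 15/10/7 copies; 35 bp partial; four
polymorphic sites, applied within the per-copy edit budget).  The
published repeat-region arithmetic (759 bp of blocks from a stated start
at 15,464) overshoots the CR end by 8 bp, so the block is anchored to the
CR 3′ end; the printed start is kept as metadata only.

`simulate_reads` draws, per read: an orientation (default 65% plus); a
unit from the orientation's catalog by configured weights (defaults follow
the published expression ranking, with antisense units and CR lncRNAs
included and a rare full-primary class); a processing state — mature with
probability c², two-sided precursor with (1−c)², else a one-sided
intermediate that retains its upstream tRNA with probability
`reverse_bias` (reverse = downstream excised first) — with c =
`cleave_prob` = 0.85; exonucleolytic truncation (probability 0.25, 5′ side
per per-gene bias, geometric(0.05) length capped at 40% of the fragment so
the fragment's unit identity survives; applied to end-state products
only); tail chemistry (CCA with probability 0.95 on mature tRNAs, then
polyA ~ Geometric(0.2); suppressed on 3′-truncated reads); and uniform
substitution errors (0.2%).  Truncation-length and polyA laws and the
error rate are modelling choices, config-exposed, not published values.
Alignments are emitted as truth rather than re-aligned, isolating pipeline
logic from aligner behaviour; all outputs are deterministic under a fixed
seed.

What the generator does **not** emulate: indel-rich raw-instrument error
profiles, quality scores, chimeric reads, template-switching artefacts,
coverage biases along the molecule, or the real (unknown) read-length and
degradation-length distributions.  Passing tests therefore demonstrate the
correctness of the inference logic under the stated generative model, not
robustness to every artefact of real libraries.

`make_fixture_trnas` deterministically produces the 26-read tRNA set with
the published end-state composition (21 plus- / 5 minus-assigned across
nine tRNA genes; 15 complete, 10 5′-degraded, one 3′-degraded read lacking
its CCA); the nine contributing genes are not named in the source, so a
fixed deterministic choice is packaged.

## Scale of the packaged analyses

Shared test simulations use 2,000 reads (seeded); statistical recovery
checks (cleavage bias within 95% binomial intervals, unit frequencies
within 3σ) run at that depth, and the repeat analyses use the ~1.5 kb CR.
These sizes were chosen so each check carries adequate statistical power
while the whole suite remains quick to run.

## Known limitations

* The read-to-genome alignment itself is consumed, never computed; the
  mapping-parameter record (`AlignerConfig`) is provenance metadata.
* Tail extraction from PAF requires the read sequences (PAF carries none);
  without them, tail lengths are preserved but bases are `N`.
* TIS/TTS inference reports recurrent-end candidates; it cannot by itself
  distinguish one initiation site with 5′ nibbling from several sites.
* The repeat-unit finder assumes tandem (not dispersed) organisation for
  discovery; interspersed copies are handled at decomposition time.
* Single-sample design throughout; no cross-sample normalisation.
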