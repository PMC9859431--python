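# mitotx

Full-length transcriptome analysis for circular mitochondrial genomes.

Insect mitogenomes are compact circles (37 genes, a control region) that are
transcribed as two nearly genome-wide primary polycistrons, one per strand.
Mature RNAs are released by the **tRNA punctuation** mechanism — the tRNAs
flanking each mRNA/rRNA are excised from the precursor — after which tRNAs
receive a non-templated CCA triplet and transcripts are polyadenylated,
truncated stop codons (U or UA) being completed to UAA by the polyA tail.
Long-read (Iso-Seq) full-length transcripts make every one of these events
directly observable.  `mitotx` turns a circular mitogenome annotation plus
full-length transcript alignments into:

* a transcript-guided **re-annotation** of gene boundaries (mature
  polyadenylated 3′ ends, start-codon-consistent 5′ ends, rRNA end
  clusters, and the control region as the largest unannotated gap);
* a strand-aware **quantitative transcription map** (per-base coverage) and
  a total classification of every read (mature mono-/bicistron, unprocessed
  polycistronic precursor, antisense transcript, control-region lncRNA);
* **processing-signal inference**: non-templated CCA and polyA tail
  chemistry, per-read degradation end states, and the per-junction order of
  tRNA excision ("reverse" = downstream tRNA removed first, 3′→5′;
  "forward" = upstream first, 5′→3′);
* **transcription initiation/termination sites** from recurrent transcript
  5′/3′ ends inside the control region and from strand-specific coverage
  collapse at gene junctions, plus rRNA 5′-isoform calling and
  exonucleolytic degradation directionality (binomial test on 5′- vs
  3′-truncated read counts);
* edit-tolerant **tandem-repeat decomposition** of the control region and
  of the lncRNAs transcribed from it (unit discovery by self-match
  periodicity, dynamic-programming tiling with per-copy edit budgets,
  polymorphic-site aggregation, copy-number heterogeneity statistics);
* a seeded **synthetic-data generator** that emulates the whole
  transcription/processing model, so every stage is testable offline with
  known truth.

The packaged gene-table fixture and control-region transcript set reproduce
the *Coridius chinensis* mitogenome study system (16,214 bp; GenBank
OP921229), including both its DNA-based and transcript-refined annotation
columns.

## Worked example

Simulate a read set under the default study conditions and run the full
pipeline:

```sh
mitotx simulate --outdir sim --seed 3 --n-reads 500
mitotx run-all --genome sim/genome.fasta --annotation sim/annotation.gff3 \
               --alignments sim/alignments.tsv --outdir sim/run
```

which prints

```
wrote 500 simulated reads to sim
{"n_reads": 500, "cr_length": 1553, "tis_plus": 15377, "tis_minus": 15189}
```

`sim/run/summary.json` then contains, among other fields,

```
"cr_length": 1553, "tis_plus": 15377, "tis_minus": 15189,
"tts_minus": 15406,
"terminations": [{"orientation": "plus", "junction": ["trnS2", "ND1"],
                  "kind": "terminator"}],
"repeat_copy_counts": {"I": 15, "III": 10, "II": 7}
```

Reading it: the control region derived as the largest unannotated gap is
1553 bp; the two primary transcripts initiate at 15,377 (plus strand) and
15,189 (minus strand) inside the control region; the minus primary
terminates at 15,406 in the control region while the plus primary is
terminated at the trnS2/ND1 junction (coverage collapses to zero
downstream); and the control-region repeat region decomposes into three
unit types with 15, 10, and 7 copies.  All of these are recomputed from the
reads — the same numbers the generator planted.

The library surface mirrors the pipeline stages
(`mitotx.refine`, `mitotx.classify`, `mitotx.signals`, `mitotx.boundaries`,
`mitotx.repeats`, `mitotx.synthetic`); see `docs/methods.md` for the model
and parameter documentation.

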