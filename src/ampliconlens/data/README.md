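# Bundled data

## gene_fixtures.tsv

Annotation snapshots for the FGFR1 and NSD3 gene models used throughout the
package. Columns: `gene`, `element_type` (gene | exon | cds | tss | domain),
`name`, `start`, `end`, `frame_or_aa`.

* `exon` rows: 0-based half-open genomic coordinates on chr8, one row per
  exon, named by transcription-order exon number (for the minus-strand FGFR1
  model exon 1 has the highest coordinates).
* `cds` rows: genomic positions of the first and last coding base in
  transcript orientation.
* `domain` rows: 1-based inclusive amino-acid coordinates on the canonical
  protein (`frame_or_aa` = `aa`).
* `tss` rows: 0-based position of the first transcribed base.

Provenance: locus coordinates, exon counts, strand, and the domain layout
approximate the hg19 8p11-p12 annotation (FGFR1: 18 exons, minus strand,
822-aa receptor with IG-I / acid box / IG-II / IG-III / TM / kinase domains,
canonical ATG in exon 2; NSD3: 24 exons, plus strand, 1437-aa long isoform
with PWWP and SET domains). Exact intron sizes are representative, not
copied from any annotation release.

## fgfr1_cds.fasta, nsd3_cds.fasta

Spliced coding sequences for the two gene models. These are synthetic:
deterministically generated so that in-frame ATG codons occur exactly at
the documented alternative-start positions (FGFR1 aa 1, 142, 252 and 362,
falling in exons 2, 5, 7 and 9). Do not use them as biological sequence.

## pooled_cohort_junctions.tsv, pooled_cohort_labels.tsv

A 21-model cohort (9 FGFR-inhibitor responders, 12 nonresponders) of
rearrangement-junction records used by the cohort-level association
analysis. The `provenance` column marks, per record, whether the breakpoint
coordinate / support count / affected-exon range was reported for the named
model (`reported_*`) or is a representative coordinate consistent with the
model's description (`representative`).
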