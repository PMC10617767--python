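# ampliconlens

Analysis toolkit for the architecture of focal gene amplifications
(8p11-p12 / FGFR1-style loci): rearrangement-junction classification,
copy-number profiling, truncated-ORF prediction, breakage-fusion-bridge
(BFB) inference, and cohort-level association with inhibitor response —
plus a seeded synthetic-cohort generator so the whole pipeline can be
exercised without any external data.

## Modules

| module | what it does |
| --- | --- |
| `genome_model` | Gene/transcript/domain data model, GTF I/O, bundled FGFR1/NSD3 fixtures. Internal coordinates are 0-based half-open; exons are numbered in transcription order. |
| `rearrangements` | BEDPE / VCF-BND junction I/O, orientation classification (tail-to-tail `+/+`, head-to-head `-/-`, deletion-, duplication-type), fold-back detection, the 400 kb FGFR1 upstream-window rule, NSD3-disruption calling. |
| `robocop` | ROlling Binmeans Of COPy numbers: a 2 Mb view window around the locus split into 10,000 bins, per-bin overlap-weighted means, per-condition means across samples, centered rolling mean (window 10 for WGS, 500 for CAGE data), amplicon peak-centering and half-maximum focality. |
| `orf_predictor` | Retained exons after an intragenic rearrangement, first surviving in-frame ATG (canonical or downstream), lost/partial protein domains, kinase-retained flag. |
| `bfb` | BFB simulator (truncate at a boundary, append the inverted retained prefix), structural string checking, count-vector achievability by pruned search, Poisson matching of observed copy numbers to achievable vectors, confidence classes (high requires >= 8 segments plus fold-back support), amplicon reconstruction from observed breaks. |
| `cohort` | Per-sample integration into a dependency category (`deltaEC_FGFR1`, `FGFR1_inactivated`, `FGFR1_centered`, `non_centered`), two-sided Fisher's exact association, bundled 21-model pooled cohort. |
| `synthetic_data` | Deterministic generator of gene models and cohorts with planted rearrangements, BFB-stepped copy numbers and response labels. |

## CLI

```bash
ampliconlens junctions --bedpe junctions.bedpe --out annotated.tsv
ampliconlens robocop --seg segments.seg.tsv --labels labels.tsv --kind wgs --out profile.tsv
ampliconlens deltaec --junctions junctions.bedpe
ampliconlens bfb --seg segments.seg.tsv --junctions junctions.bedpe
ampliconlens bfb-sim --segments 5 --cycles 3 --seed 1
ampliconlens classify --seg segments.seg.tsv --junctions junctions.bedpe --labels labels.tsv --out calls.json
ampliconlens cohort --calls calls.json          # or: --pooled-fixture
ampliconlens simulate --out cohort_dir --seed 1
```

SEG input is a TSV with header `sample  chrom  start  end  total_cn`;
junction BEDPE strand columns encode retained flanks (`+` = left/low
coordinates, `-` = right/high coordinates). `simulate` writes a complete
synthetic dataset (SEG + BEDPE + labels + truth JSON) consumable by the
other commands.

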