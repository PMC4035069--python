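# ovamir

A tested, self-contained reimplementation of a classic two-library small-RNA
sequencing analysis: read cleaning with per-category accounting, priority
annotation of unique tags, known-miRNA quantification, exact-test
differential expression, hairpin-based novel miRNA prediction, seed-match
target prediction, hypergeometric GO/pathway enrichment, and qPCR
validation — all driven by a built-in synthetic study generator with a
machine-readable truth record, so every stage is testable offline.

## Layout

| Module | Role |
| --- | --- |
| `ovamir.synthetic_data` | toy genome/references, two FASTQ libraries with planted abundances, fold changes and novel hairpin loci, qPCR CT table |
| `ovamir.preprocess` | quality/adapter/length/polyA filtering with a conservation-checked filter report, length histogram, unique-tag collapsing |
| `ovamir.annotate` | genome mapping and single-category priority annotation (rRNA > tRNA > … > known miRNA > repeat > exon > intron > unann) |
| `ovamir.quantify` | tag-to-mature crediting with mismatch/offset tolerance, co-expressed vs library-specific sets, top-specific report |
| `ovamir.diffexpr` | TPM normalization, zero/low-expression revision, log2 fold change and ratio classes, exact two-library count test, significance labels, clustering |
| `ovamir.novel_mirna` | stack-energy folding DP, precursor window extraction, hairpin/Dicer-consistency calling |
| `ovamir.targets` | seed (positions 2–8) reverse-complement scanning of 3' UTRs |
| `ovamir.enrichment` | hypergeometric upper tail, per-ontology Bonferroni, BH FDR |
| `ovamir.qpcr` | 2^-dCT relative expression, two-group comparison, concordance with sequencing |
| `ovamir.pipeline` / `ovamir.cli` | end-to-end orchestration with a digest-stable run manifest |

## Command line

```bash
ovamir run --out demo/                    # full pipeline on default synthetic study
ovamir run --config cfg.yaml --seed 7 --out demo/
ovamir simulate --out sim/                # just generate a study
ovamir clean --lib1 sim/lib1.fastq --lib2 sim/lib2.fastq \
    --adapter3 TGGAATTCTCGGGTGCCAAGG --adapter5 GTTCAGAGTTCTACAGTCCGACGATC \
    --out cleaned/
ovamir enrich --targets genes.txt --term-map map.tsv --ontology kegg --out enrich.tsv
```

`ovamir run` writes every stage's TSV/FASTA/BED outputs plus
`manifest.json`; re-running with the same config produces byte-identical
outputs (identical digests).

A YAML config mirrors `SimulationConfig` (seed, n_mirnas, library_depths,
adapters, contamination_fractions, de_fraction, planted_log2fc,
length_profile, …); every analysis threshold (adapter overlap, quality
cutoff, mismatch tolerances, folding energy cutoff, Dicer fraction, …) is a
keyword argument on the corresponding function.

## Notes

- The exact two-library count test conditions on the first library's count
  (negative-binomial tails, evaluated in stable form); it is verified
  against an exact-rational brute-force oracle.
- The folding model is a deliberately simple nearest-neighbour stack-energy
  DP (exactly solvable and enumeration-verifiable); an external folding
  backend can be swapped in where higher fidelity is needed.
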