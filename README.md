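# gevescan

Genome-wide characterization of giant endogenous viral elements (GEVEs) in a
pair of related strain genomes: viral-candidate calling by taxonomic vote,
cross-strain conservation classification, divergent/viral region construction,
epigenetic-silencing profiling (CpG methylation, expression, Hi-C compaction)
and genomic-context statistics (sub-telomeric bias, mobile-element
composition, region similarity links). A synthetic two-strain genome
generator with planted ground truth exercises the full pipeline end to end.

## Modules

| module | purpose |
|---|---|
| `gevescan.simulate` | two-strain genome generator: backbone + substitutions, planted multi-gene viral insertions (end-biased), duplicate copies, mobile elements, telomeres, methylation/expression/Hi-C evidence files, exact truth tables |
| `gevescan.candidates` | intergenic ORF extraction (≥150 nt, six frames, no start codon required) and viral LGT calling: best-hit-viral or ≥ half of top-ten hits viral, after e-value (≤0.001) and self-genus filtering |
| `gevescan.regions` | conserved / non-conserved / unresolved classification against alignment blocks and gaps; divergent regions by concatenating contiguous GAP/DUP/JMP records (INV/BRK break); viral-region flagging; hallmark completeness (e < 1e-5) |
| `gevescan.silencing` | per-CpG levels, gene methylation (≥5% mean ⇒ methylated), 5 kb methylation / 2.5 kb log2-coverage tracks, TPM, Welch t-tests by category |
| `gevescan.context` | telomeric repeat arrays (TTAGGG ± 1 mismatch/unit), permutation test for chromosome-end bias, mobile-element chi-square, GC-shift track, k-mer-anchored region similarity links, Hi-C O/E detrending and region compaction scores |
| `gevescan.pipeline` / `gevescan.cli` | orchestration, input validation, run manifest, `gevescan` CLI |

Coordinates are 0-based half-open in memory; GFF3 I/O converts to 1-based
closed. All outputs are plain TSV/BED/bedGraph/FASTA.

## CLI

```sh
gevescan simulate --seed 1 --out data/              # synthetic pair + evidence
gevescan validate --data data/                      # dialect/coordinate checks
gevescan run-all --data data/ --out results/        # full pipeline
gevescan call-candidates --genome data/A.fasta --gff data/A.genes.gff3 \
    --hits data/A.hits.tsv --taxonomy data/taxonomy.tsv --out results/A
gevescan regions --diff data/diff.tsv --blocks data/blocks.tsv \
    --candidates results/A.candidates.tsv --strain A --out results/A
gevescan methylation --bedmethyl data/A.methylation.tsv \
    --gff data/A.genes.gff3 --out results/A.meth.tsv
gevescan context telomeres --genome data/A.fasta --out results/A.tel.tsv
gevescan context hic --matrix data/A.hic.chr01.tsv --out results/A.oe.tsv
```

`run-all` writes per-strain candidate/region/methylation/TPM tables, track
bedGraphs, a JSON report and a manifest with config echo and input checksums;
identical seeds give byte-identical outputs.

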