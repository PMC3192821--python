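# txrobust

Fragile-codon usage metrics and NMD-efficiency comparisons for coding
sequences.

A *fragile* codon is a sense codon that one nucleotide substitution can turn
into a stop codon (18 of the 61 sense codons under the standard genetic
code); the remaining 43 are *robust*. Wherever nonsense-mediated decay (NMD)
surveillance of premature stops is weak — single-exon genes, last exons of
multi-exon genes, the region downstream of the last exon–exon junction —
selection against transcriptional nonsense errors predicts a depletion of
fragile codons and, at the protein level, of amino acids encodable only by
fragile codons. This package implements the metrics and comparisons used to
detect that signature:

- **genetic_code** — derives the fragile/robust classification of codons and
  amino acids by enumeration, plus the GC-matched synonymous codon groups
  (NFCU) and amino-acid groups (NFAU) used for normalization. Note: the
  canonical five NFCU groups reproduce the published lists verbatim,
  including the group `{TTG, CTT, CTA}`, which encodes leucine (both lysine
  codons are fragile, so no GC-matched lysine group can exist); a `derived`
  mode provides the complete rule-based partition (adds AGT/AGC to the
  serine groups and AGG to the arginine group) for sensitivity analysis.
- **metrics** — FCU, NFCU, FAU, NFAU with explicit UNDEFINED semantics and
  per-group numerator/denominator bookkeeping.
- **gene_models** — FASTA + GFF3 loading into strand-resolved transcript
  models, representative-transcript selection (longest peptide),
  last-exon reliability filters, codon-to-exon assignment (junction-spanning
  codons belong to no exon), 50-codon boundary windows around the last
  exon–exon junction, ESE hexamer coverage, and Fop.
- **evolution** — built-in Nei–Gojobori (1986) Ka/Ks with Jukes–Cantor
  correction, pairwise Ks matrices and single-linkage redundancy clustering;
  externally computed Ka/Ks tables are accepted as a drop-in substitute.
- **comparative_stats** — rank-sum, signed-rank, sign/binomial tests,
  Spearman correlations with Fisher-z confidence intervals, quantile
  binning, and median/quartile group summaries with ratios.
- **synthetic_data** — a generator of synthetic genomes (FASTA + GFF3 +
  truth manifest) with independently controllable fragile-codon usage
  (per class and per region), fragile amino-acid usage, GC content and exon
  structure, so every pipeline stage is testable without external data.
- **pipeline / cli** — orchestration of the intergenic, intragenic,
  window-based, binned and constraint-correlation analyses.

## CLI

```sh
# make a synthetic genome with known generator truth
txrobust generate --out demo --seed 1 --n-multi 500 --n-single 150 \
    --single-ratio 0.92 --last-ratio 0.93

# analyses (each writes TSV/JSON tables to --out)
txrobust intergenic --fasta demo/genome.fa --gff3 demo/annotation.gff3 --out demo/results
txrobust intragenic --fasta demo/genome.fa --gff3 demo/annotation.gff3 --out demo/results
txrobust windows    --fasta demo/genome.fa --gff3 demo/annotation.gff3 --out demo/results
txrobust binned     --fasta demo/genome.fa --gff3 demo/annotation.gff3 --out demo/results
txrobust correlation --fasta demo/genome.fa --gff3 demo/annotation.gff3 \
    --kaks kaks.tsv --out demo/results
txrobust all        --fasta demo/genome.fa --gff3 demo/annotation.gff3 --out demo/results
```

Optional inputs: `--classes` (plain-text histone gene IDs, one per line),
`--ese` (one hexamer per line), `--optimal-codons` (one codon per line),
`--kaks` (TSV with `gene_id`, `ka`, `ks`[, `ratio`]), `--group-mode
canonical|derived`, `--window-size`, `--buffer-nt`, `--seed`.

## Conventions

- DNA alphabet (T, not U), uppercase codons, standard nuclear code only.
- GFF3 coordinates are 1-based inclusive on disk, 0-based half-open
  internally; all reported positions are transcript-oriented.
- Terminal stop codons are stripped before any metric; transcripts with
  internal stops or frame problems are flagged and excluded from analyses,
  with casualty counts reported.
- UNDEFINED metric values (no group represented) are first-class: they are
  dropped from comparisons and counted, never silently coerced.
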