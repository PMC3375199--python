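# g4prom

Promoter G-quadruplex analysis: scan DNA for putative quadruplex (PG4)
motifs, anchor them to transcription start sites, select differentially
expressed genes from an expression matrix, and quantify the association
between promoter quadruplexes and expression changes.

## The problem

Guanine-rich DNA matching

```
5'-(GGG N1-7)>=3 GGG-3'        N in {A, C, G, T}
```

can fold into a four-stranded G-quadruplex (G4). These motifs cluster
around transcription start sites (TSS) and, when stabilised by
quadruplex-selective small molecules, perturb transcription of the
downstream gene. A typical study therefore asks: among the genes whose
expression changes under compound treatment, is the fraction carrying at
least one PG4 motif within ±2 kb of the TSS higher than the genome-wide
fraction? And do position (before/after the TSS), strand (sense/antisense),
loop lengths or loop base composition of the motifs differ between affected
and unaffected genes?

`g4prom` implements that whole analysis for computational biologists:

* **g4scan** — a purpose-built backtracking scanner for the PG4 pattern on
  both strands, with PCRE-style greedy, leftmost, non-overlapping match
  semantics (checked span-by-span against a standard regex engine) and a
  stem/loop decomposition in which the 5'-most three guanines of a 4-G run
  form the stem and the surplus guanine joins the adjacent loop;
* **tss_map** — midpoint-anchored assignment of motifs to the nearest mRNA
  within a ±2 kb window, classified into the four subsets
  `af`/`ar`/`bf`/`br` (after/before TSS × forward/reverse strand relative
  to the gene's coding orientation);
* **expression_de** — quantile normalization, per-probe one-way ANOVA,
  Pearson correlation to a condition-of-interest indicator, and thresholded
  selection (p ≤ 0.05 and r ≥ 0.9 by default; "unchanged" means p > 0.75);
* **enrichment_stats** — exact hypergeometric tests: for a universe of `N`
  genes with `K` feature-positive and a sample of `n` with `k` positive,
  enrichment p = P(X ≥ k) and depletion p = P(X ≤ k); the same test drives
  G4-membership enrichment, positional-subset enrichment and the per-cell
  analysis of the 7×7×7 = 343 loop-length-combination grid;
* **loop_features** — pooled average loop length, per-motif loop
  composition frequencies f ∈ [0,1] for queries A/C/G/T/AT/CT/GT, Gaussian
  kernel density estimates (Silverman's rule bandwidth
  0.9·min(sd, IQR/1.34)·n^(−1/5)), and two-sample Kolmogorov–Smirnov
  comparisons;
* **synthetic_data** — a seeded generator of promoter contigs with planted
  motifs (controlled loop lengths, composition, side and strand) and of
  expression matrices whose G4↔DE association realises a configurable odds
  ratio, so the full pipeline runs and is testable with no downloads.

## Worked example

Run the whole pipeline on a simulated dataset of 2,000 genes (65%
G4-positive, 300 differentially expressed, planted G4↔DE odds ratio 3,
triplicate two-condition expression):

```sh
$ g4prom run --simulate --seed 7 --n-genes 2000 --odds-ratio 3 --out g4demo
DE genes with promoter G4: 140/174 (80.5%) vs universe 1300/2000 (65.0%), p_enrich=2.42e-06
tables -> g4demo
```

Of the 174 genes the expression stage calls differential, 140 (80.5%)
carry at least one promoter PG4 motif, against a 65.0% genome-wide rate —
an enrichment with hypergeometric p ≈ 2×10⁻⁶, i.e. the pipeline recovers
the planted association. `g4demo/` then contains the stage outputs as
plain TSV: `motifs.bed` (scanned motifs with loop tokens),
`assignments.tsv` (TSS distances and af/ar/bf/br labels),
`membership_enrichment.tsv`, `subset_enrichment.tsv`, `loop_combos.tsv`
(343 rows), `loop_composition_ks.tsv`, a per-set summary:

```
set        n_genes  n_genes_with_motif  n_motifs  avg_loop_length
up         87       65                  155       3.7
down       87       75                  167       3.7
unchanged  454      280                 610       3.7
```

and `manifest.json` recording version, config, seed and per-stage counts.
Each stage is also exposed separately (`g4prom scan|map|de|simulate`) on
ordinary FASTA/BED/TSV files; see `g4prom --help`.

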