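# Methods

## Motif model and match semantics

A putative G-quadruplex (PG4) motif is a match of

    5'-(GGG N1-7)>=3 GGG-3',   N in {A, C, G, T}

i.e. four or more tracts of three guanines separated by loops of 1–7
bases. The loop alphabet deliberately includes G, so loops may contain
guanines and a G-run longer than three can straddle a stem/loop boundary.

Because the pattern is ambiguous (a given string can admit several
stem/loop parses), the scanner fixes one reproducible contract:
**PCRE-style greedy backtracking, leftmost, non-overlapping matches** of
the canonical pattern `(?:G{3}[ACGT]{1,7}){3,}G{3}`. The implementation is
a purpose-built backtracking parser with failure memoisation (worst-case
linear in sequence length × loop range, no exponential blow-up on G-runs);
its spans are property-tested against a standard regex engine on seeded
random sequences, and its loop tokens against a capture-group oracle.
Consequences of the greedy order worth knowing:

* the 5'-most three guanines of a 4-G run form the stem and the surplus
  guanine falls into the following loop (`GGGGAGGGAGGGAGGG` → loops
  `GA, A, A`);
* an earlier loop-length choice dominates the tract count: a regex engine
  parses `GGGAGGGAGGGAGGGAGGG` (five GGG tracts with single-base spacers)
  as a **4-tract** motif with loops `AGGGA, A, A`, not as five tracts.
  Tract counts above four therefore arise only where loop absorption is
  blocked (e.g. long loops), and loops can contain `GGG`;
* non-greedy (minimal) matching would yield a different motif set and is
  intentionally not offered.

Reverse-strand motifs come from scanning the reverse complement and
mirroring spans back to forward coordinates; a motif's identity for
deduplication is (sequence, start, end, strand). Bases outside
{A,C,G,T} are normalised to N at I/O, and N never occurs inside a match.

## TSS anchoring and the af/ar/bf/br subsets

All coordinates are 0-based, half-open, on the forward reference strand.
A motif is anchored at its integer midpoint `floor((start+end)/2)` (the
midpoint is symmetric and avoids a strand-dependent bias for long motifs;
a 5'-end anchor would be the alternative). The signed distance to a TSS is
measured in the gene's 5'→3' orientation; a motif is assigned to anchors
within ±2,000 bp (`window`), by default only to the nearest one (ties keep
all tied anchors — deterministic and order-independent; the tie count is
logged). Distance 0 counts as *after* the TSS, since the TSS base itself
is transcribed. *Forward* means the G-rich run lies on the gene's
annotated sense strand; side × relative strand gives the four subsets
af, ar, bf, br. The unchanged/non-differential reference set for the
positional and loop analyses is the genes with ANOVA p > 0.75 that carry
at least one in-window motif.

## Expression selection

The expression matrix (probes × samples, ≥2 conditions with ≥2 replicates)
is quantile-normalised: every column is replaced by the mean of all
columns' order statistics at its ranks, ties receiving the mean of their
candidate values; afterwards all columns share one empirical distribution
exactly. Per probe, a one-way fixed-effects ANOVA F-test (p from
F(g−1, n−g); constant probes get p = 1 by convention) and a Pearson
correlation r against the 0/1 indicator of the condition of interest
(zero-variance probes are excluded and counted). Selection: up-regulated
means p ≤ 0.05 and r ≥ 0.9, down-regulated p ≤ 0.05 and −r ≥ 0.9,
unchanged p > 0.75. With a positive r threshold a probe can never be both
up and down. No multiple-testing correction enters the selection; a
Benjamini–Hochberg column is emitted alongside for users. With two
conditions, correlating against the per-condition mean profile instead of
the indicator gives the same |r| (the group-mean vector is affine in the
indicator), so the indicator is the canonical choice.

At the default synthetic effect size (three noise standard deviations,
triplicates) the population indicator correlation is
0.75·0.5/√(0.75²·0.25 + 0.25²) ≈ 0.83 — *below* the 0.9 threshold — so the
full selection recovers only ~44% of truly differential genes (ANOVA alone:
~73%). The selection is deliberately stringent, mirroring its origin;
downstream enrichment statistics are conditioned on the selected set and
remain valid at any recall.

## Hypergeometric layer

All enrichment questions reduce to one exact test. Universe N with K
feature-positive; sample n with k positive:

    p_enrich  = P(X >= k),   p_deplete = P(X <= k),   X ~ Hypergeom(N, K, n)

computed from scipy's hypergeometric distribution (log-space internally,
so N ~ 2.5×10⁴ does not underflow); both tails share P(X = k), so they sum
to ≥ 1. Fold = (k/n)/(K/N). The same test drives:

* **membership enrichment** — sample = a DE gene set, feature = genes with
  ≥1 in-window motif, universe = all probed genes (not all annotated
  genes; overridable);
* **subset enrichment** — per subset s ∈ {af, ar, bf, br}: universe =
  pooled set + reference assignments, feature = membership in s;
* **loop-combination enrichment** — 4-tract motifs binned by
  (loop1, loop2, loop3) length into the 7×7×7 = 343-cell grid; per cell
  N = |background|, K = background count, n = |set|, k = set count.
  Loops of length 8 (the absorbed surplus guanine on a 7-base loop) are
  routed to bin 7 and counted in the log. Cells empty in both set and
  background are flagged `no_data`; when the motif set is smaller than 343
  the per-cell p-values are suppressed (`skip_testing`) because a set
  smaller than the grid cannot speak to individual cells. Raw p-values
  are the primary statistic; a BH q column is emitted per family.

Motifs with more than four tracts are excluded from all loop analyses
(`four_tract_subset`) because which tracts form the folded stem is
ambiguous, and every motif is deduplicated so it contributes once even
when assigned to several genes.

## Loop composition, KDE and KS

For a 4-tract motif the composition frequency of a query base set
(A, C, G, T, AT, CT, GT) is the number of loop bases in the set divided by
the total loop length — 0 means complete exclusion, 1 means the loops
contain nothing else. Single-base frequencies sum to 1 per motif and
f(AT) = f(A) + f(T) exactly. Distributions over a motif set are summarised
by a Gaussian KDE with Silverman's rule-of-thumb bandwidth
h = 0.9·min(sd, IQR/1.34)·n^(−1/5) (the classic statistical-environment
default), evaluated on 512 points spanning [−3h, 1+3h] so the trapezoid
mass is 1 ± 0.01. Two motif sets are compared with the two-sample
Kolmogorov–Smirnov test: D is the supremum of the pooled-point ECDF gap;
p is asymptotic, Q_KS(√(nm/(n+m))·D), flagged approximate when ties are
present (composition frequencies are discrete, so ties are the norm); an
exact small-sample p is available for n·m ≤ 10⁴. The asymptotic p is
slightly conservative at these sizes (null rejection ≈ 3–5% at α = 0.05).

## Synthetic data generator

The generator emulates the inputs of a promoter-quadruplex compound study
at desk scale and is itself first-class, tested code. Defaults (the study
conditions):

| parameter | default | meaning |
|---|---|---|
| n_genes | 2,000 | one promoter contig per gene, TSS centred |
| promoter_len | 4,200 bp | covers the ±2 kb window plus placement margin |
| window | 2,000 bp | TSS assignment window |
| gc_background | 0.50 | i.i.d. background base composition |
| g4_gene_fraction | 0.65 | genes with ≥1 planted motif (genome-wide rate ~67%) |
| motifs per gene | geometric(p=0.45), max 16 | right-skewed promoter motif counts |
| loop_len_probs | (.18,.16,.15,.14,.13,.12,.12) | mean loop ≈ 3.7 nt, as in promoter PG4 tables |
| loop_base_probs | A .32, C .12, G .22, T .34 | C-poor loops, as observed in promoters |
| groups / replicates | control, treated × 3 | triplicate two-condition design |
| baseline | Normal(8, 1.5) log2 units | probe-level log-intensity |
| effect_size | 0.75 (= 3·noise_sd) | shift applied to DE genes in the treated group |
| noise_sd | 0.25 | replicate noise |
| de_fraction | 0.15 | 300 DE genes at n_genes = 2,000 |
| g4_de_odds_ratio | 1.0 | planted association; 1 = none |

Planted motifs are always 4-tract. Loop tokens are rejection-sampled with
two constraints beyond the length/composition distributions: no `GGG`
substring and no leading G. Both are needed to make the planted truth an
exact scanner oracle — a loop with a leading G would let the preceding
loop absorb stem guanines into an alternative same-span greedy parse.
Planted motifs keep >7 bp spacing (12 bp enforced), flanking bases are
forced to A/T, and G/C runs in a 10 bp guard zone on each side are broken
so the greedy match can neither extend a planted motif nor start early.
After assembly every contig is rescanned and any background region that
produces an accidental PG4 match (or perturbs a planted one) is resampled
until the scan reproduces the planted truth exactly (bounded retries;
~5–15% of contigs need at least one resample at these defaults).

The DE gene set is drawn so the 2×2 table (DE × G4) realises the requested
odds ratio exactly up to integer rounding, by solving the quadratic margin
equation for the overlap; the realized odds ratio spans [0, ∞] over the
feasible overlap range, so any positive request resolves. Up/down
directions are assigned 50/50. All randomness flows through substreams
derived from one seed; identical (seed, config) pairs give byte-identical
outputs.

What the generator does **not** emulate: real promoter sequence structure
(CpG islands, GC skew, repeat content), probe-level microarray noise
physics, probe↔mRNA multi-mapping, and inter-gene interference (one contig
per gene by default; a `dense` mode places all genes on one contig to
exercise nearest-TSS logic). Passing tests therefore demonstrate
correctness of the algorithms and calibration of the statistics under
i.i.d. backgrounds — not that any particular genome-wide count will be
reproduced on real data.

## Numerical and degenerate-input choices

* Hypergeometric bounds are validated and violations named; k = 0 with
  K = 0 gives p_enrich = 1, fold undefined (NaN).
* ANOVA with zero between- and within-group variance → p = 1, logged;
  zero within-group variance with signal → p = 0.
* KDE of identical values raises (suggesting a histogram); the Silverman
  spread falls back to the sd when the IQR is 0.
* KS with ties reports the exact pooled-point D and flags the asymptotic p.
* Quantile normalization ties: average ranks interpolate between adjacent
  order-statistic means, i.e. tied values receive the mean of their
  candidate values.
* Motif midpoint uses floor division; distance 0 classifies as "after".

## Problem sizes used by the test suite and acceptance script

Scanner oracle sweeps use 1,000 random sequences of 200–5,000 bp at GC
0.3–0.7; hypergeometric enumeration covers every valid (N ≤ 12, K, n, k);
KS calibration uses 500 replicates of two n = 200 samples; expression
calibration 2,000 pure-noise probes; end-to-end recovery 100 seeded
pipeline runs each at odds ratio 3 and 1 with the default study
conditions. These sizes keep a full run to a few minutes on one CPU while
leaving the binomial error on rate estimates at a percentage point or two.

## Known limitations

* Genome-scale results of the motivating analysis — total promoter motif
  counts (tens of thousands), per-set motif counts and average loop
  lengths on real gene sets, and the extreme printed p-values (down to
  10⁻⁹⁸) — require the actual reference genome build and expression
  repository accession plus the original (unknowable) matching convention
  of the custom scanner; they are supported as ordinary inputs but are not
  reproduced by the desk-scale synthetic runs, whose property-based checks
  stand in for them.
* Whether "forward" in the motivating analysis meant the sense or the
  template strand is ambiguous; this package defines forward = sense. The
  two readings are one configuration flip apart and the downstream
  statistics are label-symmetric.
* The scanner's greedy contract is one defensible reading of an
  under-specified pattern; motif sets under minimal matching differ.
* No thermodynamic scoring, bulged/two-tetrad quadruplexes, or RNA
  quadruplexes; no GO classification (external databases).
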