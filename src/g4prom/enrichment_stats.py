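"""Hypergeometric enrichment statistics.

Three layers share one exact test: membership enrichment of a gene sample
in a feature-positive subset of a finite universe, positional/strand
subset (af/ar/bf/br) enrichment of motif assignments, and the per-cell
enrichment of the 7x7x7 loop-length-combination grid of 4-tract motifs.

Tail convention: enrichment p = P(X >= k), depletion p = P(X <= k); the two
always overlap in P(X = k). Tails are computed from the exact
hypergeometric distribution in log space, so universes of tens of
thousands of genes do not underflow. Raw p-values are the primary
statistic; Benjamini-Hochberg q-values are emitted alongside wherever a
family of tests is run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from g4prom.g4scan import PG4Motif
from g4prom.sequence_io import GeneList
from g4prom.tss_map import SUBSETS, MotifAssignment

logger = logging.getLogger(__name__)

MAX_LOOP_BIN = 7
N_COMBO_CELLS = MAX_LOOP_BIN**3


@dataclass(frozen=True)
class EnrichmentResult:
    """2x2 hypergeometric summary.

    N: universe size; K: feature-positive in universe; n: sample size;
    k: feature-positive in sample.
    """

    N: int
    K: int
    n: int
    k: int
    p_enrich: float
    p_deplete: float

    @property
    def pct_sample(self) -> float:
        return 100.0 * self.k / self.n if self.n else float("nan")

    @property
    def pct_universe(self) -> float:
        return 100.0 * self.K / self.N if self.N else float("nan")

    @property
    def fold(self) -> float:
        if self.n == 0 or self.K == 0:
            return float("nan")
        return (self.k / self.n) / (self.K / self.N)


def hypergeom_test(N: int, K: int, n: int, k: int) -> EnrichmentResult:
    """Exact hypergeometric tail probabilities for drawing ``k``
    feature-positive items in a sample of ``n`` from a universe of ``N``
    containing ``K`` positives.
    """
    if not 0 <= K <= N:
        raise ValueError(f"bound violated: 0 <= K <= N (K={K}, N={N})")
    if not 0 <= n <= N:
        raise ValueError(f"bound violated: 0 <= n <= N (n={n}, N={N})")
    if k > min(n, K):
        raise ValueError(f"bound violated: k <= min(n, K) (k={k}, n={n}, K={K})")
    if k < max(0, n + K - N):
        raise ValueError(
            f"bound violated: k >= max(0, n + K - N) (k={k}, n={n}, K={K}, N={N})"
        )
    dist = stats.hypergeom(N, K, n)
    p_enrich = float(dist.sf(k - 1))
    p_deplete = float(dist.cdf(k))
    return EnrichmentResult(N, K, n, k, min(p_enrich, 1.0), min(p_deplete, 1.0))


def membership_enrichment(
    sample: GeneList, feature_genes: Iterable[str], universe: GeneList
) -> EnrichmentResult:
    """Enrichment of ``sample`` genes among feature-positive genes of the
    universe (e.g. genes with at least one promoter PG4 motif)."""
    feature = set(feature_genes)
    offending = sample.gene_ids - universe.gene_ids
    if offending:
        raise ValueError(
            f"sample genes outside universe: {sorted(offending)[:10]}"
        )
    N = len(universe.gene_ids)
    K = len(universe.gene_ids & feature)
    n = len(sample.gene_ids)
    k = len(sample.gene_ids & feature)
    return hypergeom_test(N, K, n, k)


def subset_enrichment(
    set_assignments: Sequence[MotifAssignment],
    reference_assignments: Sequence[MotifAssignment],
) -> dict[str, EnrichmentResult]:
    """Per positional/strand subset (af/ar/bf/br): is the gene set's motif
    complement over- or under-represented in that subset relative to the
    pooled set + reference assignments?
    """
    if not reference_assignments:
        raise ValueError("reference assignments must be non-empty")
    pool = list(set_assignments) + list(reference_assignments)
    N = len(pool)
    n = len(set_assignments)
    results = {}
    for s in SUBSETS:
        K = sum(1 for a in pool if a.subset == s)
        k = sum(1 for a in set_assignments if a.subset == s)
        results[s] = hypergeom_test(N, K, n, k)
    return results


@dataclass
class LoopComboTable:
    """7x7x7 loop-length-combination counts with per-cell enrichment.

    ``counts``/``background_counts`` are indexed [l1-1, l2-1, l3-1] for loop
    lengths 1..7 (motif loops longer than 7 nt — a surplus guanine absorbed
    from a 4-G run — are routed to bin 7, with the routed count logged).
    ``skip_testing`` is set when the motif set is smaller than the number of
    cells, in which case per-cell p-values are not meaningful and the table
    reports counts only.
    """

    counts: np.ndarray
    background_counts: np.ndarray
    table: pd.DataFrame
    set_size: int
    background_size: int
    skip_testing: bool


def _combo_counts(motifs: Iterable[PG4Motif]) -> tuple[np.ndarray, int, int]:
    counts = np.zeros((MAX_LOOP_BIN,) * 3, dtype=np.int64)
    total = 0
    routed = 0
    for m in motifs:
        if m.n_tracts != 4:
            raise ValueError(
                f"loop-combination analysis needs 4-tract motifs, got {m.n_tracts} tracts"
            )
        idx = []
        for loop in m.loops:
            ln = len(loop)
            if ln > MAX_LOOP_BIN:
                routed += 1
                ln = MAX_LOOP_BIN
            idx.append(ln - 1)
        counts[tuple(idx)] += 1
        total += 1
    return counts, total, routed


def loop_combo_enrichment(
    set_motifs: Sequence[PG4Motif], background_motifs: Sequence[PG4Motif]
) -> LoopComboTable:
    """Per-cell hypergeometric enrichment over the 343 loop-length
    combinations of 4-tract motifs.

    For each cell: N = |background|, K = background cell count,
    n = |set|, k = set cell count. Cells empty in both set and background
    are flagged ``no_data``; q is Benjamini-Hochberg over tested cells.
    """
    set_counts, n_set, routed_set = _combo_counts(set_motifs)
    bg_counts, n_bg, routed_bg = _combo_counts(background_motifs)
    if routed_set or routed_bg:
        logger.info(
            "loop_combo_enrichment: %d loops longer than 7 nt routed to bin 7",
            routed_set + routed_bg,
        )
    skip = n_set < N_COMBO_CELLS
    if skip:
        logger.info(
            "loop_combo_enrichment: set size %d < %d cells; per-cell testing skipped",
            n_set,
            N_COMBO_CELLS,
        )
    rows = []
    for l1 in range(1, MAX_LOOP_BIN + 1):
        for l2 in range(1, MAX_LOOP_BIN + 1):
            for l3 in range(1, MAX_LOOP_BIN + 1):
                k = int(set_counts[l1 - 1, l2 - 1, l3 - 1])
                K = int(bg_counts[l1 - 1, l2 - 1, l3 - 1])
                no_data = k == 0 and K == 0
                if skip or no_data or n_bg == 0:
                    p_e = p_d = np.nan
                else:
                    # the set must be drawn from the background population
                    res = hypergeom_test(n_bg, K, n_set, k)
                    p_e, p_d = res.p_enrich, res.p_deplete
                rows.append(
                    {
                        "l1": l1,
                        "l2": l2,
                        "l3": l3,
                        "count_set": k,
                        "count_bg": K,
                        "p_enrich": p_e,
                        "p_deplete": p_d,
                        "flag": "no_data" if no_data else ("not_tested" if skip else ""),
                    }
                )
    table = pd.DataFrame(rows)
    tested = table["p_enrich"].notna()
    table["q_enrich"] = np.nan
    if tested.any():
        table.loc[tested, "q_enrich"] = stats.false_discovery_control(
            table.loc[tested, "p_enrich"].to_numpy(), method="bh"
        )
    return LoopComboTable(set_counts, bg_counts, table, n_set, n_bg, skip)


def enrichment_table(results: Mapping[str, EnrichmentResult]) -> pd.DataFrame:
    """Flatten named EnrichmentResults into a TSV-ready table with a
    Benjamini-Hochberg q column over the family."""
    rows = []
    for name, r in results.items():
        rows.append(
            {
                "test": name,
                "N": r.N,
                "K": r.K,
                "n": r.n,
                "k": r.k,
                "pct_sample": r.pct_sample,
                "pct_universe": r.pct_universe,
                "fold": r.fold,
                "p_enrich": r.p_enrich,
                "p_deplete": r.p_deplete,
            }
        )
    df = pd.DataFrame(rows)
    if len(df):
        df["q_enrich"] = stats.false_discovery_control(df["p_enrich"].to_numpy(), method="bh")
    return df
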