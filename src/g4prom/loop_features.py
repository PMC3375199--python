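"""Loop-length and loop-composition statistics of 4-tract PG4 motifs.

Per motif, the three loop tokens of the greedy parse define (i) loop
lengths and (ii) a composition frequency for a query base set: the number
of loop bases in the query set divided by the total loop length, a value
in [0, 1] (0 = the query bases never occur in the loops, 1 = the loops
consist of nothing else). Queries are the single bases A, C, G, T and the
groupings AT, CT, GT; the complements (CG, AG, AC) follow as 1 - f.

Distributions of these frequencies are summarised by a Gaussian kernel
density estimate (Silverman's rule-of-thumb bandwidth) and compared
between motif sets with the two-sample Kolmogorov-Smirnov test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import special, stats

from g4prom.g4scan import PG4Motif

logger = logging.getLogger(__name__)

COMPOSITION_QUERIES = ("A", "C", "G", "T", "AT", "CT", "GT")


@dataclass
class CompositionSample:
    """Per-motif composition frequencies for one query in one motif set."""

    set_name: str
    query: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size and (self.values.min() < 0 or self.values.max() > 1):
            raise ValueError("composition frequencies must lie in [0, 1]")


@dataclass
class KDEResult:
    """Gaussian KDE evaluated on an even grid spanning [-3h, 1+3h]."""

    grid: np.ndarray
    density: np.ndarray
    bandwidth: float

    @property
    def integral(self) -> float:
        return float(np.trapezoid(self.density, self.grid))


def average_loop_length(motifs: Sequence[PG4Motif]) -> float:
    """Mean of all individual loop lengths pooled over motifs (not the mean
    of per-motif means; the two coincide for 4-tract-only sets)."""
    lengths = [len(loop) for m in motifs for loop in m.loops]
    if not lengths:
        raise ValueError("average_loop_length of an empty motif set")
    return float(np.mean(lengths))


def composition_frequency(motif: PG4Motif, query: str) -> float:
    """Fraction of loop bases belonging to the query base set."""
    if query not in COMPOSITION_QUERIES:
        raise ValueError(f"query must be one of {COMPOSITION_QUERIES}, got {query!r}")
    if motif.n_tracts != 4:
        raise ValueError("composition analysis is defined for 4-tract motifs")
    bases = set(query)
    total = sum(len(loop) for loop in motif.loops)
    assert total > 0, "loops are at least 1 nt by construction"
    hits = sum(1 for loop in motif.loops for c in loop if c in bases)
    return hits / total


def composition_sample(
    motifs: Iterable[PG4Motif], query: str, set_name: str = ""
) -> CompositionSample:
    """Composition frequencies across a (deduplicated, 4-tract) motif set."""
    values = np.array([composition_frequency(m, query) for m in motifs], dtype=float)
    return CompositionSample(set_name, query, values)


def silverman_bandwidth(values: np.ndarray) -> float:
    """Silverman's rule of thumb: 0.9 * min(sd, IQR/1.34) * n^(-1/5).

    Falls back to the standard deviation when the IQR is zero.
    """
    values = np.asarray(values, dtype=float)
    sd = float(values.std(ddof=1))
    iqr = float(np.subtract(*np.percentile(values, [75, 25])))
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    if spread == 0:
        raise ValueError("all values identical; a kernel density estimate is undefined"
                         " (use a histogram)")
    return 0.9 * spread * len(values) ** (-1 / 5)


def kde(values: Sequence[float], bandwidth: str | float = "silverman", n_grid: int = 512) -> KDEResult:
    """Gaussian kernel density estimate on [-3h, 1+3h] with 512 grid points.

    Frequencies live in [0, 1]; the grid extends three bandwidths past each
    end so the density mass is captured (trapezoid integral = 1 +/- 0.01).
    """
    values = np.asarray(values, dtype=float)
    if np.unique(values).size < 2:
        raise ValueError("kde needs >= 2 distinct values; for identical values use a histogram")
    if bandwidth == "silverman":
        h = silverman_bandwidth(values)
    else:
        h = float(bandwidth)
        if h <= 0:
            raise ValueError("bandwidth must be positive")
    grid = np.linspace(-3 * h, 1 + 3 * h, n_grid)
    z = (grid[:, None] - values[None, :]) / h
    density = np.exp(-0.5 * z**2).sum(axis=1) / (len(values) * h * np.sqrt(2 * np.pi))
    return KDEResult(grid, density, h)


def ks_two_sample(
    x: Sequence[float], y: Sequence[float], exact: bool = False
) -> tuple[float, float, bool]:
    """Two-sample Kolmogorov-Smirnov test.

    D is the supremum over the pooled sample points of |ECDF_x - ECDF_y|;
    p comes from the asymptotic Kolmogorov distribution at sqrt(nm/(n+m))*D
    (or, with ``exact=True`` and n*m <= 1e4, from the exact two-sample
    null distribution). Returns (D, p, ties_present); with ties the
    asymptotic p is approximate.
    """
    x = np.sort(np.asarray(x, dtype=float))
    y = np.sort(np.asarray(y, dtype=float))
    if x.size < 2 or y.size < 2:
        raise ValueError("ks_two_sample needs >= 2 observations per sample")
    pooled = np.concatenate([x, y])
    cdf_x = np.searchsorted(x, pooled, side="right") / x.size
    cdf_y = np.searchsorted(y, pooled, side="right") / y.size
    d = float(np.abs(cdf_x - cdf_y).max())
    ties = np.unique(pooled).size < pooled.size
    en = x.size * y.size / (x.size + y.size)
    if exact:
        if x.size * y.size > 10_000:
            raise ValueError("exact KS p-value offered only for n*m <= 10^4")
        p = float(stats.ks_2samp(x, y, method="exact").pvalue)
    else:
        p = float(np.clip(special.kolmogorov(np.sqrt(en) * d), 0.0, 1.0))
    if ties and not exact:
        logger.debug("ks_two_sample: ties present; asymptotic p is approximate")
    return d, p, ties


def zero_exclusion_fraction(sample: CompositionSample) -> float:
    """Fraction of motifs whose loops completely exclude the query bases
    (composition frequency exactly zero)."""
    if sample.values.size == 0:
        return 0.0
    return float(np.mean(sample.values == 0.0))
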