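"""Seeded synthetic genomes, annotations and expression matrices.

The generator emulates the inputs of a promoter-quadruplex study so the
whole pipeline runs with no downloads and with known ground truth:

* one promoter contig per gene with the TSS centred, i.i.d. background
  bases at a configured GC fraction;
* for G4-positive genes, PG4 motifs planted at controlled loop lengths
  (1-7 nt), loop base composition, side of the TSS and strand — placed so
  that the scanner recovers exactly the planted motifs (the background is
  rejection-sampled until it contains no accidental PG4 match and no
  extension of a planted one);
* an expression matrix (one probe per gene) with a log-intensity group
  effect on a chosen DE gene subset whose overlap with the G4-positive
  genes realises a configured odds ratio.

All randomness flows through substreams derived deterministically from a
single seed, so identical (seed, config) pairs give identical outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from g4prom.expression_de import ExpressionMatrix
from g4prom.g4scan import PG4Motif, scan_many
from g4prom.sequence_io import GeneList, GenomicSequence, TSSRecord, reverse_complement

logger = logging.getLogger(__name__)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_MAX_PLACE_TRIES = 200
_MAX_BG_TRIES = 50


@dataclass
class SimConfig:
    """Study conditions for the synthetic generator.

    Defaults reproduce the scale of a promoter microarray study: a ~2,000
    gene universe, ~65% of genes carrying at least one promoter PG4 motif,
    a +/- 2 kb TSS window, triplicate two-condition expression with a
    log-scale effect of three noise standard deviations on DE genes, and a
    configurable G4<->DE odds ratio (1 = no association).
    """

    seed: int = 0
    n_genes: int = 2000
    window: int = 2000
    promoter_len: int = 4200
    gc_background: float = 0.5
    g4_gene_fraction: float = 0.65
    motifs_per_gene_p: float = 0.45  # geometric success prob, truncated at max
    motifs_per_gene_max: int = 16
    # loop lengths 1..7; mean ~3.7 nt as typical of promoter PG4 loops
    loop_len_probs: tuple[float, ...] = (0.18, 0.16, 0.15, 0.14, 0.13, 0.12, 0.12)
    # A, C, G, T; C-poor, as promoter quadruplex loops tend to be
    loop_base_probs: tuple[float, ...] = (0.32, 0.12, 0.22, 0.34)
    side_probs: tuple[float, float] = (0.5, 0.5)  # before, after
    strand_probs: tuple[float, float] = (0.5, 0.5)  # forward, reverse (vs gene)
    n_samples_per_group: int = 3
    groups: tuple[str, str] = ("control", "treated")
    de_fraction: float = 0.15
    effect_size: float = 0.75  # log2-intensity shift on DE genes
    g4_de_odds_ratio: float = 1.0
    noise_sd: float = 0.25
    baseline_mean: float = 8.0
    baseline_sd: float = 1.5
    dense: bool = False  # place all genes on a single contig

    def __post_init__(self) -> None:
        for name in ("loop_len_probs", "loop_base_probs", "side_probs", "strand_probs"):
            v = np.asarray(getattr(self, name), dtype=float)
            if abs(v.sum() - 1.0) > 1e-9 or (v < 0).any():
                raise ValueError(f"{name} must be a probability vector summing to 1")
        if self.n_genes < 10:
            raise ValueError("n_genes must be >= 10")
        if self.promoter_len < 2 * self.window + 120:
            raise ValueError("promoter_len must exceed 2*window plus a placement margin")
        if not 0 <= self.g4_gene_fraction <= 1:
            raise ValueError("g4_gene_fraction must be in [0, 1]")
        if self.g4_de_odds_ratio <= 0:
            raise ValueError("g4_de_odds_ratio must be positive")


@dataclass(frozen=True)
class PlantedMotif:
    """Ground truth for one planted motif."""

    motif: PG4Motif
    gene_id: str
    distance: int  # signed, gene 5'->3' orientation, anchor = midpoint
    side: str  # before | after
    rel_strand: str  # forward | reverse


@dataclass
class GenomeTruth:
    """Ground truth of a simulated genome."""

    planted: list[PlantedMotif] = field(default_factory=list)
    g4_genes: frozenset[str] = frozenset()
    gene_ids: tuple[str, ...] = ()


def _rng(cfg: SimConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, stage])


def _sample_loop(rng: np.random.Generator, cum_len: np.ndarray, cum_base: np.ndarray) -> str:
    """One loop token: length from loop_len_probs, bases from
    loop_base_probs, rejected until it has no leading G and no GGG run
    (those constraints keep the greedy parse of the planted motif equal to
    the planted decomposition)."""
    length = int(np.searchsorted(cum_len, rng.random())) + 1
    for _ in range(_MAX_PLACE_TRIES):
        idx = np.searchsorted(cum_base, rng.random(length))
        tok = "".join("ACGT"[i] for i in idx)
        if tok[0] != "G" and "GGG" not in tok:
            return tok
    raise RuntimeError("could not sample an admissible loop token; loop_base_probs "
                       "may be degenerate (all mass on G)")


def _background(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    idx = np.searchsorted(np.cumsum(p[:-1]), rng.random(n), side="right")
    return _BASES[idx]


def simulate_genome(
    cfg: SimConfig,
) -> tuple[list[GenomicSequence], list[TSSRecord], GenomeTruth]:
    """Simulate promoter contigs with planted PG4 motifs.

    Returns (sequences, TSS annotation, ground truth). The scanner applied
    to the returned sequences recovers exactly the planted motifs: spans,
    strands and loop tokens (guaranteed by rejection-resampling the
    background wherever a scan disagrees with the truth).
    """
    rng_genes = _rng(cfg, 1)
    rng_bg = _rng(cfg, 2)
    rng_place = _rng(cfg, 3)

    n = cfg.n_genes
    gene_ids = tuple(f"g{i:05d}" for i in range(n))
    strands = np.where(rng_genes.random(n) < 0.5, "+", "-")
    n_g4 = int(round(cfg.g4_gene_fraction * n))
    g4_idx = set(rng_genes.choice(n, size=n_g4, replace=False).tolist())

    if cfg.dense:
        seq_ids = ["chr_dense"] * n
        gene_offsets = [i * cfg.promoter_len for i in range(n)]
        contig_lens = {"chr_dense": n * cfg.promoter_len}
    else:
        seq_ids = [f"chr_{g}" for g in gene_ids]
        gene_offsets = [0] * n
        contig_lens = {sid: cfg.promoter_len for sid in seq_ids}

    tss_local = cfg.promoter_len // 2
    anchors = [
        TSSRecord(gene_ids[i], f"{gene_ids[i]}.m1", seq_ids[i],
                  gene_offsets[i] + tss_local, strands[i])
        for i in range(n)
    ]

    # plan planted motifs per gene
    cum_len = np.cumsum(np.asarray(cfg.loop_len_probs)[:-1])
    cum_base = np.cumsum(np.asarray(cfg.loop_base_probs)[:-1])
    planted: list[PlantedMotif] = []
    occupied: dict[str, list[tuple[int, int]]] = {sid: [] for sid in contig_lens}
    margin = 12  # minimum gap between planted intervals (> 7 nt)
    for i in range(n):
        if i not in g4_idx:
            continue
        m_count = min(int(rng_place.geometric(cfg.motifs_per_gene_p)), cfg.motifs_per_gene_max)
        gene_strand = strands[i]
        sid = seq_ids[i]
        tss = gene_offsets[i] + tss_local
        for _ in range(m_count):
            loops = [_sample_loop(rng_place, cum_len, cum_base) for _ in range(3)]
            motif_fwd = "GGG" + "GGG".join(loops) + "GGG"
            mlen = len(motif_fwd)
            placed = False
            for _try in range(_MAX_PLACE_TRIES):
                side = "before" if rng_place.random() < cfg.side_probs[0] else "after"
                rel = "forward" if rng_place.random() < cfg.strand_probs[0] else "reverse"
                if side == "before":
                    dist = -int(rng_place.integers(1, cfg.window + 1))
                else:
                    dist = int(rng_place.integers(0, cfg.window + 1))
                gmid = tss + (dist if gene_strand == "+" else -dist)
                start = gmid - mlen // 2
                end = start + mlen
                lo = gene_offsets[i]
                hi = lo + cfg.promoter_len
                if start < lo + 2 or end > hi - 2:
                    continue
                if any(start < e + margin and s - margin < end for s, e in occupied[sid]):
                    continue
                motif_strand = gene_strand if rel == "forward" else ("-" if gene_strand == "+" else "+")
                # contig coordinates: per-gene contigs have offset 0, so the
                # global placement coordinate is the contig coordinate
                motif = PG4Motif(
                    sid, start, start + mlen, motif_strand, motif_fwd,
                    ("GGG",) * 4, tuple(loops),
                )
                occupied[sid].append((start, end))
                planted.append(PlantedMotif(motif, gene_ids[i], dist, side, rel))
                placed = True
                break
            if not placed:
                raise RuntimeError(
                    f"could not place a motif for gene {gene_ids[i]} after "
                    f"{_MAX_PLACE_TRIES} tries; window/promoter_len too crowded"
                )

    # assemble contigs: background + planted motifs written in place
    sids = list(contig_lens)
    big = _background(rng_bg, sum(contig_lens.values()), cfg.gc_background)
    arrays: dict[str, np.ndarray] = {}
    off = 0
    for sid in sids:
        arrays[sid] = big[off : off + contig_lens[sid]]
        off += contig_lens[sid]
    planted_by_sid: dict[str, list[PlantedMotif]] = {sid: [] for sid in contig_lens}
    for pm in planted:
        planted_by_sid[pm.motif.seq_id].append(pm)

    def write_motif(pm: PlantedMotif) -> None:
        # Flanking bases are forced to A/T so a background G (or C, seen as
        # a G on the reverse strand) cannot merge with a boundary stem, and
        # G/C runs of 3+ in a 10 bp guard zone on either side are broken so
        # the greedy match cannot absorb a continuation tract. Keeps the
        # planted truth an exact oracle for the scanner.
        m = pm.motif
        arr = arrays[m.seq_id]
        on_fwd = m.matched if m.motif_strand == "+" else reverse_complement(m.matched)
        arr[m.start : m.end] = np.frombuffer(on_fwd.encode(), dtype=np.uint8)
        arr[m.start - 1] = ord("A") if rng_bg.random() < 0.5 else ord("T")
        arr[m.end] = ord("A") if rng_bg.random() < 0.5 else ord("T")
        for ws, we in ((m.start - 11, m.start - 1), (m.end + 1, m.end + 11)):
            ws, we = max(0, ws), min(len(arr), we)
            zone = arr[ws:we]
            for bad in (ord("G"), ord("C")):
                run = 0
                for i in range(zone.size):
                    run = run + 1 if zone[i] == bad else 0
                    if run == 3:
                        zone[i] = ord("A") if rng_bg.random() < 0.5 else ord("T")
                        run = 0

    for pm in planted:
        write_motif(pm)

    seqs = {
        sid: GenomicSequence(sid, arrays[sid].tobytes().decode("ascii"))
        for sid in contig_lens
    }

    # rejection step: rescan and resample background of contigs where the
    # scan does not reproduce the planted truth exactly
    def truth_key(pm: PlantedMotif):
        m = pm.motif
        return (m.start, m.end, m.motif_strand, m.loops)

    def scan_key(m: PG4Motif):
        return (m.start, m.end, m.motif_strand, m.loops)

    want_by_sid = {
        sid: {truth_key(pm) for pm in planted_by_sid[sid]} for sid in contig_lens
    }

    def collect(motifs: list[PG4Motif]) -> dict[str, set]:
        got: dict[str, set] = {}
        for m in motifs:
            got.setdefault(m.seq_id, set()).add(scan_key(m))
        return got

    got_by_sid = collect(scan_many(list(seqs.values())))
    failing = [
        sid for sid in contig_lens if got_by_sid.get(sid, set()) != want_by_sid[sid]
    ]
    n_resampled = 0
    pad = 40
    for _round in range(_MAX_BG_TRIES):
        if not failing:
            break
        for sid in failing:
            # resample only the background around disagreeing spans
            arr = arrays[sid]
            got = got_by_sid.get(sid, set())
            bad = sorted((k[0], k[1]) for k in got.symmetric_difference(want_by_sid[sid]))
            windows: list[list[int]] = []
            for s, e in bad:
                s, e = max(0, s - pad), min(len(arr), e + pad)
                if windows and s <= windows[-1][1]:
                    windows[-1][1] = max(windows[-1][1], e)
                else:
                    windows.append([s, e])
            n_resampled += 1
            for ws, we in windows:
                arr[ws:we] = _background(rng_bg, we - ws, cfg.gc_background)
            for pm in planted_by_sid[sid]:  # restore planted bytes and flanks
                m = pm.motif
                if any(m.start - 1 < we and ws < m.end + 1 for ws, we in windows):
                    write_motif(pm)
            seqs[sid] = GenomicSequence(sid, arr.tobytes().decode("ascii"))
        rescanned = collect(scan_many([seqs[sid] for sid in failing]))
        failing = [
            sid for sid in failing if rescanned.get(sid, set()) != want_by_sid[sid]
        ]
        got_by_sid.update(rescanned)
    if failing:
        raise RuntimeError(
            f"background of {failing[:3]} could not be made free of accidental "
            f"PG4 matches after {_MAX_BG_TRIES} resample rounds"
        )
    if n_resampled:
        logger.debug("simulate_genome: %d background window resamples", n_resampled)

    planted_gene_ids = {pm.gene_id for pm in planted}
    truth = GenomeTruth(
        planted=planted,
        g4_genes=frozenset(planted_gene_ids),
        gene_ids=gene_ids,
    )
    return list(seqs.values()), anchors, truth


def _solve_overlap(N: int, K: int, d: int, odds_ratio: float) -> int:
    """Size x of DE ∩ G4 such that the 2x2 table (x, d-x, K-x, N-K-d+x)
    realises the requested odds ratio x(N-K-d+x) / ((d-x)(K-x))."""
    lo, hi = max(0, d - (N - K)), min(d, K)
    if odds_ratio == 1.0:
        x = d * K / N
    else:
        a = 1.0 - odds_ratio
        b = (N - K - d) + odds_ratio * (d + K)
        c = -odds_ratio * d * K
        disc = b * b - 4 * a * c
        roots = [(-b + np.sqrt(disc)) / (2 * a), (-b - np.sqrt(disc)) / (2 * a)]
        feasible = [r for r in roots if lo - 0.5 <= r <= hi + 0.5]
        if not feasible:
            raise ValueError(
                f"odds ratio {odds_ratio} unattainable with margins N={N}, K={K}, "
                f"d={d}; feasible overlap range is [{lo}, {hi}]"
            )
        x = feasible[0]
    xi = int(round(x))
    if not lo <= xi <= hi:
        raise ValueError(
            f"odds ratio {odds_ratio} unattainable with margins N={N}, K={K}, d={d}; "
            f"feasible overlap range is [{lo}, {hi}]"
        )
    return xi


def simulate_expression(
    cfg: SimConfig, g4_truth: GenomeTruth
) -> tuple[ExpressionMatrix, dict[str, GeneList], pd.DataFrame]:
    """Simulate a probe x sample expression matrix with planted DE genes.

    DE genes are drawn so that P(DE | G4) / P(DE | no G4) odds realise
    ``cfg.g4_de_odds_ratio`` exactly (up to integer rounding of the 2x2
    table). Each DE gene receives a +/- ``effect_size`` shift in the
    treatment group on top of a log-normal baseline plus Gaussian noise.

    Returns (matrix, truth gene lists keyed up/down/de, probe->gene table).
    """
    rng = _rng(cfg, 4)
    genes = list(g4_truth.gene_ids)
    N = len(genes)
    K_set = set(g4_truth.g4_genes)
    d = int(round(cfg.de_fraction * N))
    x = _solve_overlap(N, len(K_set), d, cfg.g4_de_odds_ratio)

    g4_list = sorted(K_set)
    non_g4 = sorted(set(genes) - K_set)
    de_genes = set(rng.choice(g4_list, size=x, replace=False).tolist()) | set(
        rng.choice(non_g4, size=d - x, replace=False).tolist()
    )
    de_sorted = sorted(de_genes)
    up_mask = rng.random(len(de_sorted)) < 0.5
    up = frozenset(g for g, u in zip(de_sorted, up_mask) if u)
    down = frozenset(de_genes) - up

    group_labels = [cfg.groups[0]] * cfg.n_samples_per_group + [cfg.groups[1]] * cfg.n_samples_per_group
    sample_ids = [f"{g}_{i+1}" for g in cfg.groups for i in range(cfg.n_samples_per_group)]
    treated = np.array([g == cfg.groups[1] for g in group_labels], dtype=float)

    baseline = rng.normal(cfg.baseline_mean, cfg.baseline_sd, size=N)
    effect = np.zeros(N)
    for i, g in enumerate(genes):
        if g in up:
            effect[i] = cfg.effect_size
        elif g in down:
            effect[i] = -cfg.effect_size
    values = (
        baseline[:, None]
        + effect[:, None] * treated[None, :]
        + rng.normal(0.0, cfg.noise_sd, size=(N, len(sample_ids)))
    )
    probes = [f"p_{g}" for g in genes]
    matrix = ExpressionMatrix(
        pd.DataFrame(values, index=probes, columns=sample_ids),
        dict(zip(sample_ids, group_labels)),
    )
    truth = {
        "up": GeneList("truth", "up", up),
        "down": GeneList("truth", "down", down),
        "de": GeneList("truth", "universe", frozenset(de_genes)),
    }
    probe_to_gene = pd.DataFrame({"probe_id": probes, "gene_id": genes})
    return matrix, truth, probe_to_gene
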