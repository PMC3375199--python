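"""TSS-anchored motif assignment and af/ar/bf/br subset classification.

Each motif is anchored at its integer midpoint and assigned to genes whose
transcription start site lies within a +/- window (2 kb by default). The
signed distance is measured in the gene's 5'->3' orientation, so
``before``/``after`` and ``forward``/``reverse`` are relative to the gene:

* side ``before``  — motif anchor upstream of the TSS (distance < 0);
* side ``after``   — motif anchor at or downstream of the TSS;
* rel_strand ``forward`` — the G-rich run lies on the gene's sense strand;
* rel_strand ``reverse`` — the G-rich run lies on the opposite strand.

The four combinations are labelled af, ar, bf, br.
"""

from __future__ import annotations

import logging
from bisect import bisect_left, bisect_right
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from g4prom.g4scan import PG4Motif
from g4prom.sequence_io import GeneList, TSSRecord

logger = logging.getLogger(__name__)

SUBSETS = ("af", "ar", "bf", "br")


@dataclass(frozen=True)
class MotifAssignment:
    """A motif <-> gene link with signed TSS distance and subset label."""

    motif: PG4Motif
    gene_id: str
    mrna_id: str
    distance: int
    side: str  # before | after
    rel_strand: str  # forward | reverse

    @property
    def subset(self) -> str:
        return self.side[0] + self.rel_strand[0]


def _classify(motif: PG4Motif, anchor: TSSRecord, window: int) -> MotifAssignment | None:
    offset = motif.midpoint - anchor.tss
    distance = offset if anchor.strand == "+" else -offset
    if abs(distance) > window:
        return None
    side = "before" if distance < 0 else "after"  # distance 0 counts as after
    rel_strand = "forward" if motif.motif_strand == anchor.strand else "reverse"
    return MotifAssignment(motif, anchor.gene_id, anchor.mrna_id, distance, side, rel_strand)


def assign_nearest(
    motifs: Sequence[PG4Motif],
    anchors: Sequence[TSSRecord],
    window: int = 2000,
    mode: str = "nearest",
) -> tuple[list[MotifAssignment], list[PG4Motif]]:
    """Assign motifs to TSS anchors within ``+/- window`` bp.

    ``mode="nearest"`` keeps, per motif, only the anchor(s) at minimal
    |distance| (all tied anchors are kept and the tie count is logged);
    ``mode="all"`` keeps every in-window anchor. Returns (assignments,
    unassigned motifs).
    """
    if not anchors:
        raise ValueError("anchors must be non-empty")
    if window <= 0:
        raise ValueError("window must be > 0")
    if mode not in ("nearest", "all"):
        raise ValueError(f"unknown mode {mode!r}")

    by_seq: dict[str, list[TSSRecord]] = defaultdict(list)
    for a in anchors:
        by_seq[a.seq_id].append(a)
    tss_sorted: dict[str, tuple[list[int], list[TSSRecord]]] = {}
    for seq_id, recs in by_seq.items():
        recs.sort(key=lambda r: (r.tss, r.gene_id, r.mrna_id))
        tss_sorted[seq_id] = ([r.tss for r in recs], recs)

    assignments: list[MotifAssignment] = []
    unassigned: list[PG4Motif] = []
    n_ties = 0
    for m in motifs:
        entry = tss_sorted.get(m.seq_id)
        if entry is None:
            unassigned.append(m)
            continue
        positions, recs = entry
        anchor_pt = m.midpoint
        lo = bisect_left(positions, anchor_pt - window)
        hi = bisect_right(positions, anchor_pt + window)
        in_window = [_classify(m, recs[i], window) for i in range(lo, hi)]
        in_window = [a for a in in_window if a is not None]
        if not in_window:
            unassigned.append(m)
            continue
        if mode == "nearest":
            best = min(abs(a.distance) for a in in_window)
            picked = [a for a in in_window if abs(a.distance) == best]
            if len(picked) > 1:
                n_ties += 1
        else:
            picked = in_window
        assignments.extend(picked)
    if n_ties:
        logger.info("assign_nearest: %d motifs with tied nearest anchors (all kept)", n_ties)
    return assignments, unassigned


def genes_with_motif(assignments: Iterable[MotifAssignment]) -> dict[str, int]:
    """Deduplicated motif count per gene; genes absent have zero motifs."""
    per_gene: dict[str, set] = defaultdict(set)
    for a in assignments:
        per_gene[a.gene_id].add(a.motif.key)
    return {g: len(keys) for g, keys in per_gene.items()}


def count_distribution(
    counts: Mapping[str, int],
    gene_sets: Sequence[GeneList],
    cap: int = 16,
) -> pd.DataFrame:
    """Per gene set, the fraction of motif-bearing genes with exactly m
    motifs (m = 1..cap) plus an overflow bucket for counts > cap.

    Fractions are taken over genes of the set with at least one motif and
    sum to 1 per set including the overflow column.
    """
    columns = [str(m) for m in range(1, cap + 1)] + [f">{cap}"]
    rows = {}
    for gs in gene_sets:
        set_counts = [counts[g] for g in gs.gene_ids if counts.get(g, 0) > 0]
        row = [0.0] * (cap + 1)
        if not set_counts:
            logger.warning("count_distribution: set %s has no G4-bearing genes", gs.set_name)
        else:
            total = len(set_counts)
            for c in set_counts:
                idx = c - 1 if c <= cap else cap
                row[idx] += 1.0 / total
        rows[gs.set_name] = row
    return pd.DataFrame.from_dict(rows, orient="index", columns=columns)
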