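"""Putative G-quadruplex (PG4) motif scanning and stem/loop decomposition.

A PG4 motif is a match of 5'-(GGG N1-7)>=3 GGG-3' where N is any of
A, T, G, C: four or more G-tracts of three guanines separated by 1-7 nt
loops. Matching is leftmost, non-overlapping, with PCRE-style greedy
backtracking: the tract count is maximised first, then each loop token is
taken longest-first. Under this order a G-run longer than three guanines
contributes its 5'-most three Gs to a stem and the surplus guanines fall
into an adjacent loop, which is exactly the stem/loop bookkeeping used for
the downstream loop statistics.

The matcher here is a purpose-built backtracking parser with failure
memoisation (it never calls a regex engine); the test suite checks its
spans against an independent regex engine run of the canonical pattern.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from g4prom.sequence_io import GenomicSequence, reverse_complement

logger = logging.getLogger(__name__)

_LOOP_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class PG4Motif:
    """One scanned quadruplex motif on the forward reference coordinate system.

    ``matched`` is the G-rich sequence as read 5'->3' on ``motif_strand``;
    ``stems`` are the "GGG" tract tokens and ``loops`` the spacer tokens of
    the greedy parse, interleaved as stems[0]+loops[0]+...+stems[-1].
    """

    seq_id: str
    start: int
    end: int
    motif_strand: str
    matched: str
    stems: tuple[str, ...]
    loops: tuple[str, ...]

    @property
    def n_tracts(self) -> int:
        return len(self.stems)

    @property
    def key(self) -> tuple[str, int, int, str]:
        """Identity for deduplication: (seq_id, start, end, motif_strand)."""
        return (self.seq_id, self.start, self.end, self.motif_strand)

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def __post_init__(self) -> None:
        interleaved = "".join(
            s + l for s, l in zip(self.stems, self.loops + ("",))
        )
        if interleaved != self.matched:
            raise ValueError("stems/loops do not reassemble to matched")
        if self.end - self.start != len(self.matched):
            raise ValueError("span length does not equal matched length")


def _greedy_parse(
    s: str,
    start: int,
    min_loop: int,
    max_loop: int,
    min_tracts: int,
    anchored_end: bool = False,
) -> tuple[int, list[str]] | None:
    """First-success greedy backtracking parse of the PG4 pattern at ``start``.

    Search order mirrors a greedy regex engine: at each junction another
    (loop, stem) unit is attempted before accepting, and loop lengths are
    tried longest-first. Returns (end, loops) of the first success, or None.
    Failure states are memoised on (position, capped tract count) so runs of
    guanines cannot cause exponential backtracking.
    """
    if not s.startswith("GGG", start):
        return None
    n = len(s)
    failed: set[tuple[int, int]] = set()
    # frame: [pos_after_stem, tracts_consumed, next_loop_len_to_try]
    stack: list[list[int]] = [[start + 3, 1, max_loop]]
    loops: list[str] = []
    while True:
        pos, tracts, L = stack[-1]
        descended = False
        while L >= min_loop:
            stack[-1][2] = L - 1
            stem_at = pos + L
            if stem_at + 3 <= n and s.startswith("GGG", stem_at):
                tok = s[pos:stem_at]
                if _LOOP_BASES.issuperset(tok):
                    nxt = stem_at + 3
                    key = (nxt, min(tracts + 1, min_tracts))
                    if key not in failed:
                        loops.append(tok)
                        stack.append([nxt, tracts + 1, max_loop])
                        descended = True
                        break
            L = stack[-1][2]
        if descended:
            continue
        # no further unit possible: the greedy quantifier stops here
        if tracts >= min_tracts and (not anchored_end or pos == n):
            return pos, loops
        failed.add((pos, min(tracts, min_tracts)))
        stack.pop()
        if not stack:
            return None
        loops.pop()


def _scan_strand(s: str, min_loop: int, max_loop: int, min_tracts: int) -> list[tuple[int, int, list[str]]]:
    """Leftmost non-overlapping greedy matches on one strand of ``s``."""
    matches: list[tuple[int, int, list[str]]] = []
    candidates = _iter_candidates(s, min_loop, max_loop, min_tracts)
    resume = 0
    for i in candidates:
        if i < resume:
            continue
        parsed = _greedy_parse(s, i, min_loop, max_loop, min_tracts)
        if parsed is not None:
            end, loops = parsed
            matches.append((i, end, loops))
            resume = end
    return matches


def _iter_candidates(s: str, min_loop: int, max_loop: int, min_tracts: int) -> np.ndarray:
    """GGG starts that head a chain of GGG starts at loop-compatible gaps.

    Necessary condition for a match start, used only to skip hopeless
    positions quickly; the parser itself decides matches.
    """
    min_len = 3 * min_tracts + min_loop * (min_tracts - 1)
    if len(s) < min_len:
        return np.empty(0, dtype=np.int64)
    b = np.frombuffer(s.encode("ascii"), dtype=np.uint8)
    is_g = b == ord("G")
    ggg_starts = np.flatnonzero(is_g[:-2] & is_g[1:-1] & is_g[2:])
    if ggg_starts.size == 0:
        return ggg_starts
    lo, hi = 3 + min_loop, 3 + max_loop
    # chain[i] = True if a chain of k further stems can start at ggg_starts[i]
    chain = np.ones(ggg_starts.size, dtype=bool)
    for _ in range(min_tracts - 1):
        tail = ggg_starts[chain]
        if tail.size == 0:
            return np.empty(0, dtype=np.int64)
        left = np.searchsorted(tail, ggg_starts + lo, side="left")
        right = np.searchsorted(tail, ggg_starts + hi, side="right")
        chain = right > left
    return ggg_starts[chain]


def scan_pg4(
    seq: GenomicSequence,
    min_loop: int = 1,
    max_loop: int = 7,
    min_tracts: int = 4,
) -> list[PG4Motif]:
    """Scan both strands of ``seq`` for PG4 motifs.

    Forward-strand motifs come from the sequence as given; reverse-strand
    motifs are found by scanning the reverse complement and mirroring the
    span back to forward coordinates. Per strand, matches are leftmost,
    non-overlapping, greedy. Returns motifs sorted by (start, strand).
    """
    if min_loop < 1 or max_loop < min_loop:
        raise ValueError("need 1 <= min_loop <= max_loop")
    if min_tracts < 2:
        raise ValueError("min_tracts must be >= 2")
    s = seq.bases
    L = len(s)
    motifs: list[PG4Motif] = []
    for start, end, loops in _scan_strand(s, min_loop, max_loop, min_tracts):
        matched = s[start:end]
        motifs.append(
            PG4Motif(
                seq.seq_id, start, end, "+", matched,
                tuple(["GGG"] * (len(loops) + 1)), tuple(loops),
            )
        )
    rc = reverse_complement(s)
    for rstart, rend, loops in _scan_strand(rc, min_loop, max_loop, min_tracts):
        matched = rc[rstart:rend]
        motifs.append(
            PG4Motif(
                seq.seq_id, L - rend, L - rstart, "-", matched,
                tuple(["GGG"] * (len(loops) + 1)), tuple(loops),
            )
        )
    motifs.sort(key=lambda m: (m.start, m.motif_strand))
    return motifs


def scan_many(
    seqs: Sequence[GenomicSequence],
    min_loop: int = 1,
    max_loop: int = 7,
    min_tracts: int = 4,
) -> list[PG4Motif]:
    """Scan many sequences in one pass.

    Equivalent to concatenating per-sequence ``scan_pg4`` results, but the
    sequences are joined with N spacers and scanned as one string, which
    amortises the candidate-prefilter cost over the whole input. No match
    can span a spacer because N never occurs inside a match.
    """
    if min_loop < 1 or max_loop < min_loop:
        raise ValueError("need 1 <= min_loop <= max_loop")
    if min_tracts < 2:
        raise ValueError("min_tracts must be >= 2")
    if not seqs:
        return []
    sep = "N" * 8
    offsets: list[int] = []
    pos = 0
    parts: list[str] = []
    for seq in seqs:
        offsets.append(pos)
        parts.append(seq.bases)
        pos += len(seq.bases) + len(sep)
    big = sep.join(parts)
    big_len = len(big)

    def locate(gstart: int) -> int:
        from bisect import bisect_right

        return bisect_right(offsets, gstart) - 1

    motifs: list[PG4Motif] = []
    for start, end, loops in _scan_strand(big, min_loop, max_loop, min_tracts):
        i = locate(start)
        seq = seqs[i]
        s0, e0 = start - offsets[i], end - offsets[i]
        motifs.append(
            PG4Motif(
                seq.seq_id, s0, e0, "+", big[start:end],
                tuple(["GGG"] * (len(loops) + 1)), tuple(loops),
            )
        )
    rc = reverse_complement(big)
    for rstart, rend, loops in _scan_strand(rc, min_loop, max_loop, min_tracts):
        gstart, gend = big_len - rend, big_len - rstart
        i = locate(gstart)
        seq = seqs[i]
        s0, e0 = gstart - offsets[i], gend - offsets[i]
        motifs.append(
            PG4Motif(
                seq.seq_id, s0, e0, "-", rc[rstart:rend],
                tuple(["GGG"] * (len(loops) + 1)), tuple(loops),
            )
        )
    order = {s.seq_id: i for i, s in enumerate(seqs)}
    motifs.sort(key=lambda m: (order[m.seq_id], m.start, m.motif_strand))
    return motifs


def decompose(
    matched: str, min_loop: int = 1, max_loop: int = 7, min_tracts: int = 4
) -> tuple[tuple[str, ...], tuple[str, ...]]:
    """Stem/loop token assignment of a full PG4 match.

    The assignment is the first successful parse in greedy-backtracking
    order with both ends anchored — the same order the scanner uses, so
    ``decompose(m.matched)`` reproduces the scanner's tokens. The 5'-most
    three guanines of a 4-G run form the stem and the surplus guanine
    joins the following loop token. Raises ValueError if ``matched`` is
    not a full pattern match.
    """
    parsed = _greedy_parse(matched, 0, min_loop, max_loop, min_tracts, anchored_end=True)
    if parsed is None or parsed[0] != len(matched):
        raise ValueError(f"not a PG4 motif: {matched!r}")
    _, loops = parsed
    return tuple(["GGG"] * (len(loops) + 1)), tuple(loops)


def four_tract_subset(motifs: Iterable[PG4Motif]) -> list[PG4Motif]:
    """Keep only motifs with exactly four G-tracts (three loops).

    Motifs with more tracts are ambiguous as to which tracts form the stem
    of the folded quadruplex and are excluded from loop analyses.
    """
    return [m for m in motifs if m.n_tracts == 4]


def deduplicate(motifs: Sequence[PG4Motif]) -> list[PG4Motif]:
    """Drop records identical on (seq_id, start, end, motif_strand).

    Each quadruplex is counted once in loop/composition statistics even if
    assigned to several genes downstream.
    """
    seen: set[tuple[str, int, int, str]] = set()
    out: list[PG4Motif] = []
    for m in motifs:
        if m.key not in seen:
            seen.add(m.key)
            out.append(m)
    return out


def write_motifs_bed(motifs: Iterable[PG4Motif], path, comment: str = "") -> None:
    """BED6+ output: chrom, start, end, name, score=n_tracts, strand,
    matched, comma-joined loops."""
    with open(path, "w") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        for m in motifs:
            fh.write(
                f"{m.seq_id}\t{m.start}\t{m.end}\tPG4\t{m.n_tracts}\t{m.motif_strand}"
                f"\t{m.matched}\t{','.join(m.loops)}\n"
            )
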