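"""Sequence/annotation I/O and the shared coordinate conventions.

All coordinates inside the package are 0-based, half-open intervals on the
forward reference strand; dialect conversions (BED6, GFF3) happen here at
the I/O boundary and nowhere else.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

ANNOTATION_DIALECTS = ("bed6", "gff3", "tsv")


@dataclass(frozen=True)
class GenomicSequence:
    """A named DNA sequence over the alphabet {A,C,G,T,N}, uppercase."""

    seq_id: str
    bases: str

    def __len__(self) -> int:
        return len(self.bases)


@dataclass(frozen=True)
class TSSRecord:
    """One mRNA/gene anchor: transcription start site on the forward strand.

    ``tss`` is 0-based; ``strand`` is the coding strand of the mRNA.
    """

    gene_id: str
    mrna_id: str
    seq_id: str
    tss: int
    strand: str

    def __post_init__(self) -> None:
        if self.tss < 0:
            raise ValueError(f"tss must be >= 0, got {self.tss} for {self.mrna_id}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")


@dataclass
class GeneList:
    """A named, direction-labelled set of gene identifiers."""

    set_name: str
    direction: str  # up | down | unchanged | universe
    gene_ids: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.direction not in ("up", "down", "unchanged", "universe"):
            raise ValueError(f"unknown direction {self.direction!r}")
        self.gene_ids = frozenset(self.gene_ids)

    def __len__(self) -> int:
        return len(self.gene_ids)


def normalize_bases(raw: str, seq_id: str = "?") -> str:
    """Uppercase, map U->T, and replace anything outside {A,C,G,T,N} by N."""
    bases = raw.upper().replace("U", "T")
    if not set(bases) <= VALID_BASES:
        n_bad = sum(c not in VALID_BASES for c in bases)
        logger.warning(
            "sequence %s: %d non-ACGTN characters replaced by N", seq_id, n_bad
        )
        bases = "".join(c if c in VALID_BASES else "N" for c in bases)
    return bases


def read_fasta(path: str | Path) -> list[GenomicSequence]:
    """Read a (multi-record) FASTA file into normalized GenomicSequence records.

    Raises on an empty file and on duplicate sequence ids.
    """
    records: list[GenomicSequence] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate seq_id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(GenomicSequence(rec.id, normalize_bases(str(rec.seq), rec.id)))
    if not records:
        raise ValueError(f"no records in FASTA file {path}")
    return records


def write_fasta(records: Iterable[GenomicSequence], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.seq_id}\n")
            for i in range(0, len(rec.bases), width):
                fh.write(rec.bases[i : i + width] + "\n")


def reverse_complement(bases: str) -> str:
    """Watson-Crick reverse complement over {A,C,G,T,N}."""
    if not set(bases) <= VALID_BASES:
        bad = sorted(set(bases) - VALID_BASES)
        raise ValueError(f"cannot reverse-complement characters {bad}")
    return bases.translate(_COMPLEMENT)[::-1]


def _check_unique(records: list[TSSRecord]) -> list[TSSRecord]:
    seen: set[tuple[str, str]] = set()
    for r in records:
        key = (r.mrna_id, r.seq_id)
        if key in seen:
            raise ValueError(f"duplicate (mrna_id, seq_id) = {key} in annotation")
        seen.add(key)
    return records


def _read_bed6(path: str | Path) -> list[TSSRecord]:
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        names=["chrom", "start", "end", "name", "score", "strand"],
        dtype={"chrom": str, "name": str, "strand": str},
    )
    records = []
    for row in df.itertuples(index=False):
        if row.strand not in ("+", "-"):
            raise ValueError(f"missing/invalid strand for {row.name}: {row.strand!r}")
        # BED is 0-based half-open; for '-' features the TSS is the last base.
        tss = int(row.start) if row.strand == "+" else int(row.end) - 1
        records.append(TSSRecord(row.name, row.name, row.chrom, tss, row.strand))
    return records


def _read_gff3(path: str | Path) -> list[TSSRecord]:
    records = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"malformed GFF3 line: {line!r}")
            seq_id, _src, _type, start, end, _score, strand, _phase, attrs = fields
            if strand not in ("+", "-"):
                raise ValueError(f"missing/invalid strand in GFF3 line: {line!r}")
            attr = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            mrna_id = attr.get("ID") or attr.get("transcript_id")
            gene_id = attr.get("gene_id") or attr.get("Parent") or mrna_id
            if mrna_id is None:
                raise ValueError(f"GFF3 record lacks ID/transcript_id: {line!r}")
            # GFF3 is 1-based closed: forward TSS = start-1; reverse TSS = end-1
            # in 0-based terms.
            tss = int(start) - 1 if strand == "+" else int(end) - 1
            records.append(TSSRecord(gene_id, mrna_id, seq_id, tss, strand))
    return records


def _read_tsv(path: str | Path) -> list[TSSRecord]:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    required = {"gene_id", "mrna_id", "seq_id", "tss", "strand"}
    if not required <= set(df.columns):
        raise ValueError(f"annotation TSV must have columns {sorted(required)}")
    records = []
    for row in df.itertuples(index=False):
        if row.strand not in ("+", "-"):
            raise ValueError(f"missing/invalid strand for {row.mrna_id}: {row.strand!r}")
        records.append(
            TSSRecord(row.gene_id, row.mrna_id, row.seq_id, int(row.tss), row.strand)
        )
    return records


def read_annotation(path: str | Path, dialect: str = "tsv") -> list[TSSRecord]:
    """Read TSS anchors from BED6, GFF3 or the native TSV dialect.

    The TSV dialect has header ``gene_id mrna_id seq_id tss strand`` with a
    0-based tss. BED6 intervals are taken as transcript spans (TSS = start
    for '+', end-1 for '-'); GFF3 1-based coordinates are shifted to 0-based.
    """
    if dialect not in ANNOTATION_DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {ANNOTATION_DIALECTS}")
    reader = {"bed6": _read_bed6, "gff3": _read_gff3, "tsv": _read_tsv}[dialect]
    return _check_unique(reader(path))


def write_annotation(records: Iterable[TSSRecord], path: str | Path, comment: str = "") -> None:
    """Write TSS records in the native TSV dialect (tss 0-based)."""
    with open(path, "w") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        fh.write("gene_id\tmrna_id\tseq_id\ttss\tstrand\n")
        for r in records:
            fh.write(f"{r.gene_id}\t{r.mrna_id}\t{r.seq_id}\t{r.tss}\t{r.strand}\n")


def read_gene_lists(path: str | Path) -> list[GeneList]:
    """Read gene lists from a TSV with header ``gene_id set direction``."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    required = {"gene_id", "set", "direction"}
    if not required <= set(df.columns):
        raise ValueError(f"gene-list TSV must have columns {sorted(required)}")
    lists = []
    for (set_name, direction), grp in df.groupby(["set", "direction"], sort=False):
        lists.append(GeneList(set_name, direction, frozenset(grp["gene_id"])))
    return lists


def write_gene_lists(lists: Iterable[GeneList], path: str | Path, comment: str = "") -> None:
    with open(path, "w") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        fh.write("gene_id\tset\tdirection\n")
        for gl in lists:
            for gid in sorted(gl.gene_ids):
                fh.write(f"{gid}\t{gl.set_name}\t{gl.direction}\n")
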