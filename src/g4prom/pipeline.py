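"""End-to-end orchestration: scan -> map -> de -> enrich -> loops.

``run_all`` executes the stages in order on either user-supplied inputs or
a simulated dataset, writes plain TSV tables for every figure-like and
table-like summary, and records a reproducibility manifest (tool version,
parameters, input digests, per-stage row counts, seed, timestamps). Stage
outputs are ordinary TSV contracts, so each stage can be re-run
individually from intermediate files.
"""

from __future__ import annotations

import datetime
import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

import g4prom
from g4prom import enrichment_stats, expression_de, loop_features, tss_map
from g4prom.g4scan import deduplicate, four_tract_subset, scan_many, write_motifs_bed
from g4prom.sequence_io import (
    GeneList,
    read_annotation,
    read_fasta,
    write_annotation,
    write_fasta,
    write_gene_lists,
)
from g4prom.synthetic_data import SimConfig, simulate_expression, simulate_genome

logger = logging.getLogger(__name__)


@dataclass
class RunResult:
    """In-memory handles to the main outputs of one pipeline run."""

    outdir: Path
    motifs: list = field(default_factory=list)
    assignments: list = field(default_factory=list)
    selection: object = None
    membership: dict = field(default_factory=dict)
    subset_results: dict = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, comment: str, index: bool = False) -> None:
    with open(path, "w") as fh:
        fh.write(f"# g4prom {g4prom.__version__} | {comment}\n")
        df.to_csv(fh, sep="\t", index=index)


def run_all(
    config: SimConfig | None = None,
    outdir: str | Path = "g4prom_out",
    fasta: str | Path | None = None,
    annotation: str | Path | None = None,
    annotation_dialect: str = "tsv",
    matrix: str | Path | None = None,
    samples: str | Path | None = None,
    condition: str | None = None,
    window: int = 2000,
    p_max: float = 0.05,
    r_min: float = 0.9,
    p_unchanged: float = 0.75,
    write_outputs: bool = True,
) -> RunResult:
    """Run the full promoter G4 analysis.

    With ``config`` set, all inputs are simulated from it; otherwise
    ``fasta``, ``annotation``, ``matrix``, ``samples`` and ``condition``
    name the external inputs. Writes summary tables to ``outdir`` unless
    ``write_outputs`` is False (used for fast repeated simulation runs).
    """
    outdir = Path(outdir)
    if write_outputs:
        outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool": "g4prom",
        "version": g4prom.__version__,
        "started": datetime.datetime.now().isoformat(),
        "stages": {},
        "inputs": {},
    }

    # ---- inputs -----------------------------------------------------------
    if config is not None:
        manifest["config"] = asdict(config)
        manifest["seed"] = config.seed
        seqs, anchors, g4_truth = simulate_genome(config)
        expr, de_truth, probe_to_gene = simulate_expression(config, g4_truth)
        condition = config.groups[1]
        window = config.window
        if write_outputs:
            write_fasta(seqs, outdir / "genome.fa")
            write_annotation(anchors, outdir / "annotation.tsv", "simulated TSS anchors")
            with open(outdir / "matrix.tsv", "w") as fh:
                expr.values.to_csv(fh, sep="\t")
            pd.DataFrame(
                {"sample_id": expr.sample_ids, "condition": [expr.groups[s] for s in expr.sample_ids]}
            ).to_csv(outdir / "samples.tsv", sep="\t", index=False)
            write_gene_lists(list(de_truth.values()), outdir / "truth_gene_sets.tsv", "simulation truth")
    else:
        for name, p in (("fasta", fasta), ("annotation", annotation), ("matrix", matrix), ("samples", samples)):
            if p is None:
                raise ValueError(f"missing input {name!r} (or pass a SimConfig to simulate)")
            manifest["inputs"][name] = _digest(Path(p))
        if condition is None:
            raise ValueError("condition of interest must be named for external inputs")
        seqs = read_fasta(fasta)
        anchors = read_annotation(annotation, annotation_dialect)
        expr = expression_de.read_expression_matrix(matrix, samples)
        probe_to_gene = None

    universe = GeneList("universe", "universe", frozenset(a.gene_id for a in anchors))
    manifest["stages"]["inputs"] = {"sequences": len(seqs), "anchors": len(anchors),
                                    "probes": len(expr.probe_ids)}

    # ---- scan -------------------------------------------------------------
    motifs = deduplicate(scan_many(seqs))
    manifest["stages"]["scan"] = {"motifs": len(motifs)}
    if write_outputs:
        write_motifs_bed(motifs, outdir / "motifs.bed", f"g4prom {g4prom.__version__} scan")

    # ---- map --------------------------------------------------------------
    assignments, unassigned = tss_map.assign_nearest(motifs, anchors, window=window, mode="nearest")
    counts = tss_map.genes_with_motif(assignments)
    manifest["stages"]["map"] = {"assignments": len(assignments), "unassigned": len(unassigned)}
    if write_outputs:
        amap = pd.DataFrame(
            [
                {
                    "seq_id": a.motif.seq_id, "start": a.motif.start, "end": a.motif.end,
                    "motif_strand": a.motif.motif_strand, "gene_id": a.gene_id,
                    "mrna_id": a.mrna_id, "distance": a.distance, "side": a.side,
                    "rel_strand": a.rel_strand, "subset": a.subset,
                }
                for a in assignments
            ]
        )
        _write_tsv(amap, outdir / "assignments.tsv", f"window={window} mode=nearest")

    # ---- differential expression -----------------------------------------
    norm = expression_de.quantile_normalize(expr)
    anova_p = expression_de.anova_per_probe(norm)
    r_up = expression_de.profile_correlation(norm, condition)
    r_down = -r_up
    selection = expression_de.select_sets(
        anova_p, r_up, r_down, probe_to_gene=probe_to_gene,
        p_max=p_max, r_min=r_min, p_unchanged=p_unchanged, set_name=condition,
    )
    manifest["stages"]["de"] = {
        "up": len(selection.up), "down": len(selection.down), "unchanged": len(selection.unchanged),
    }
    if write_outputs:
        stats_df = pd.DataFrame({"anova_p": anova_p, "r_up": r_up, "r_down": r_down})
        stats_df["q"] = expression_de.benjamini_hochberg(anova_p)
        _write_tsv(stats_df, outdir / "probe_stats.tsv",
                   f"condition={condition} p_max={p_max} r_min={r_min}", index=True)
        write_gene_lists([selection.up, selection.down, selection.unchanged],
                         outdir / "de_gene_sets.tsv", f"condition={condition}")

    # ---- enrichment -------------------------------------------------------
    feature_genes = set(counts)
    de_all = GeneList(condition, "universe", selection.up.gene_ids | selection.down.gene_ids)
    membership = {
        "up": enrichment_stats.membership_enrichment(selection.up, feature_genes, universe),
        "down": enrichment_stats.membership_enrichment(selection.down, feature_genes, universe),
        "de": enrichment_stats.membership_enrichment(de_all, feature_genes, universe),
    }
    manifest["stages"]["enrich"] = {
        name: {"N": r.N, "K": r.K, "n": r.n, "k": r.k, "p_enrich": r.p_enrich}
        for name, r in membership.items()
    }
    if write_outputs:
        _write_tsv(enrichment_stats.enrichment_table(membership),
                   outdir / "membership_enrichment.tsv", "G4 membership of DE gene sets")

    # gene sets for the positional/loop analyses
    gene_sets = {
        "up": selection.up, "down": selection.down, "unchanged": selection.unchanged,
    }
    assign_by_set = {
        name: [a for a in assignments if a.gene_id in gs.gene_ids]
        for name, gs in gene_sets.items()
    }
    ref = assign_by_set["unchanged"]
    subset_results = {}
    for name in ("up", "down"):
        if ref and assign_by_set[name]:
            subset_results[name] = enrichment_stats.subset_enrichment(assign_by_set[name], ref)
    if write_outputs and subset_results:
        rows = []
        for name, per_subset in subset_results.items():
            for s, r in per_subset.items():
                rows.append({"set": name, "subset": s, "N": r.N, "K": r.K, "n": r.n,
                             "k": r.k, "fold": r.fold, "p_enrich": r.p_enrich,
                             "p_deplete": r.p_deplete})
        _write_tsv(pd.DataFrame(rows), outdir / "subset_enrichment.tsv",
                   "af/ar/bf/br enrichment vs unchanged reference")

    # ---- summary tables ---------------------------------------------------
    summary_rows = []
    for name, gs in gene_sets.items():
        set_assign = assign_by_set[name]
        set_motifs = deduplicate([a.motif for a in set_assign])
        motif_genes = {g for g in gs.gene_ids if counts.get(g, 0) > 0}
        row = {
            "set": name,
            "n_genes": len(gs.gene_ids),
            "n_genes_with_motif": len(motif_genes),
            "n_motifs": len(set_motifs),
            "avg_loop_length": round(loop_features.average_loop_length(set_motifs), 1)
            if set_motifs else float("nan"),
        }
        summary_rows.append(row)
    summary = pd.DataFrame(summary_rows)
    if write_outputs:
        _write_tsv(summary, outdir / "summary.tsv", "per-set gene/motif summary")
        dist = tss_map.count_distribution(counts, list(gene_sets.values()))
        _write_tsv(dist, outdir / "motif_count_distribution.tsv",
                   "fraction of motif-bearing genes by motif count", index=True)

    # ---- loop length / composition ---------------------------------------
    if write_outputs:
        bg_motifs = four_tract_subset(deduplicate([a.motif for a in assignments]))
        ref_motifs = four_tract_subset(deduplicate([a.motif for a in ref]))
        combo_rows = []
        ks_rows = []
        for name in ("up", "down"):
            set_motifs = four_tract_subset(deduplicate([a.motif for a in assign_by_set[name]]))
            if not set_motifs:
                continue
            combo = enrichment_stats.loop_combo_enrichment(set_motifs, bg_motifs)
            combo.table.insert(0, "set", name)
            combo_rows.append(combo.table)
            for query in loop_features.COMPOSITION_QUERIES:
                xs = loop_features.composition_sample(set_motifs, query, name)
                ys = loop_features.composition_sample(ref_motifs, query, "unchanged")
                if xs.values.size >= 2 and ys.values.size >= 2:
                    d, p, ties = loop_features.ks_two_sample(xs.values, ys.values)
                    ks_rows.append({"set": name, "query": query, "D": d, "p": p,
                                    "ties": ties,
                                    "zero_fraction_set": loop_features.zero_exclusion_fraction(xs),
                                    "zero_fraction_ref": loop_features.zero_exclusion_fraction(ys)})
        if combo_rows:
            _write_tsv(pd.concat(combo_rows, ignore_index=True), outdir / "loop_combos.tsv",
                       "7x7x7 loop-length combinations vs all promoter motifs")
        if ks_rows:
            _write_tsv(pd.DataFrame(ks_rows), outdir / "loop_composition_ks.tsv",
                       "loop composition KS tests vs unchanged reference")

    manifest["finished"] = datetime.datetime.now().isoformat()
    if write_outputs:
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))

    return RunResult(
        outdir=outdir,
        motifs=motifs,
        assignments=assignments,
        selection=selection,
        membership=membership,
        subset_results=subset_results,
        manifest=manifest,
    )
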