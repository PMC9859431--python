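"""Pipeline orchestration and summary reporting.

``run_pipeline`` sequences the full analysis — annotation refinement,
coverage map, transcript classification, tail/cleavage signals, TIS/TTS and
termination inference, rRNA isoforms, and CR repeat decomposition — and
writes the machine-readable report bundle with a MANIFEST of checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import asdict, dataclass, field

import pandas as pd

from . import boundaries, classify, refine, repeats, signals
from .core_io import (
    MINUS,
    PLUS,
    AlignerConfig,
    read_fasta,
    write_annotation_gff3,
    write_tracks,
)

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    genome: str
    annotation: str
    alignments: str
    outdir: str
    end_tol: int = classify.DEFAULT_END_TOL
    cluster_tol: int = boundaries.DEFAULT_CLUSTER_TOL
    min_polyA: int = signals.DEFAULT_MIN_POLYA
    min_isoform_support: int | None = None
    drop_ratio: float = boundaries.DEFAULT_DROP_RATIO
    rrna_min_support: int = refine.DEFAULT_RRNA_MIN_SUPPORT
    repeat_min_unit: int = repeats.DEFAULT_MIN_UNIT
    repeat_max_unit: int = repeats.DEFAULT_MAX_UNIT
    repeat_max_edits: int = repeats.DEFAULT_MAX_EDITS
    seed: int = 0
    log_level: str = "INFO"
    aligner: AlignerConfig = field(default_factory=AlignerConfig)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig, alignments=None, annotation=None,
                 genome: str | None = None) -> dict:
    """Execute refine -> map/classify -> signals -> boundaries -> repeats.

    Inputs may be passed in-memory (tests) or read from the configured
    paths.  Returns the summary dict; all outputs land under ``outdir``.
    """
    from .core_io import load_alignments, load_annotation

    os.makedirs(config.outdir, exist_ok=True)
    manifest: dict[str, dict] = {}
    summary: dict = {"n_reads": 0}
    stage = "load"
    try:
        if genome is None:
            genome = next(iter(read_fasta(config.genome).values()))
        if annotation is None:
            annotation = load_annotation(config.annotation,
                                         genome_length=len(genome))
        if annotation.genome_length is None:
            annotation.genome_length = len(genome)
        if alignments is None:
            alignments = load_alignments(config.alignments)
        L = annotation.genome_length
        summary["n_reads"] = len(alignments)
        summary["genome_length"] = L
        _write_json(config, manifest, "run_config.json", {
            **{k: v for k, v in asdict(config).items() if k != "aligner"},
            "aligner_config": asdict(config.aligner),
        })

        stage = "refine"
        evidence = refine.collect_end_evidence(alignments, annotation,
                                               config.end_tol, config.min_polyA)
        refined, report = refine.refine_annotation(
            annotation, evidence, genome,
            rrna_min_support=config.rrna_min_support)
        gff = os.path.join(config.outdir, "annotation_refined.gff3")
        write_annotation_gff3(refined, gff)
        manifest["annotation_refined.gff3"] = {"sha256": _sha256(gff)}
        pd.DataFrame(report.to_records()).to_csv(
            os.path.join(config.outdir, "refinement.tsv"), sep="\t", index=False)
        summary["refined_genes"] = [c.gene for c in report.changes]
        summary["removed_overlaps"] = report.removed_overlaps
        cr = refined.get("CR")
        summary["cr_length"] = cr.span.length(L)

        stage = "map_classify"
        track = classify.build_coverage(alignments, L)
        write_tracks(track, refined, config.outdir)
        calls = classify.classify_all(alignments, refined, config.end_tol)
        classify.class_summary(calls).to_csv(
            os.path.join(config.outdir, "transcript_calls.tsv"),
            sep="\t", index=False)
        expr = classify.expression_table(calls)
        expr.to_csv(os.path.join(config.outdir, "expression.tsv"),
                    sep="\t", index=False)
        summary["mean_coverage"] = track.mean_coverage()
        summary["class_counts"] = (
            pd.Series([c.klass for c in calls]).value_counts().to_dict()
        )
        summary["top_genes"] = expr.head(5)["gene"].tolist()

        stage = "signals"
        aln_by_id = {a.read_id: a for a in alignments}
        tail_calls = []
        for call in calls:
            a = aln_by_id[call.read_id]
            if not a.tail3 or len(call.units) != 1:
                continue
            gene_name = call.units[0].removeprefix("as")
            if gene_name == "CR":
                continue
            gene = refined.get(gene_name)
            cont = _continuation(genome, a, len(a.tail3))
            tail_calls.append(
                signals.call_tail(a.tail3, cont, gene.category,
                                  read_id=call.read_id,
                                  min_polyA=config.min_polyA))
        signals.tail_table(tail_calls).to_csv(
            os.path.join(config.outdir, "tails.tsv"), sep="\t", index=False)
        junctions = signals.infer_cleavage(calls, refined, config.end_tol)
        _write_json(config, manifest, "junctions.json",
                    signals.junction_summary(junctions))
        summary["n_junctions_with_evidence"] = len(junctions)

        stage = "boundaries"
        site_calls = {}
        for orientation in (PLUS, MINUS):
            clusters = boundaries.cluster_ends(
                alignments, orientation, "five_prime", config.cluster_tol)
            tis = boundaries.infer_tis(clusters, cr.span, L)
            tts = boundaries.infer_tts(alignments, cr.span, orientation, L)
            site_calls[f"tis_{orientation}"] = tis.position if tis else None
            site_calls[f"tts_{orientation}"] = tts.position if tts else None
        terminations = boundaries.detect_termination(track, refined,
                                                     config.drop_ratio)
        site_calls["terminations"] = [
            {"orientation": t.orientation, "junction": list(t.junction),
             "kind": t.kind} for t in terminations
        ]
        summary.update(site_calls)
        iso_rows = []
        for rrna in ("lrRNA", "srRNA"):
            gene = refined.get(rrna)
            gene_alns = [
                a for a in alignments
                if a.orientation == gene.orientation
                and not a.span.wraps
                and a.span.start >= gene.span.start - config.end_tol
                and a.span.end <= gene.span.end + config.end_tol
            ]
            for iso in boundaries.call_isoforms(
                gene_alns, rrna, config.cluster_tol,
                config.min_isoform_support):
                iso_rows.append(asdict(iso))
            summary[f"degradation_{rrna}"] = boundaries.degradation_direction(
                gene_alns, gene, config.end_tol, L)
        pd.DataFrame(iso_rows).to_csv(
            os.path.join(config.outdir, "isoforms.tsv"), sep="\t", index=False)
        summary["n_isoforms"] = len(iso_rows)

        stage = "repeats"
        cr_seq = _cr_sequence(genome, cr)
        units = repeats.find_repeat_units(
            cr_seq, config.repeat_min_unit, config.repeat_max_unit)
        rep_rows = []
        if units:
            dec = repeats.decompose(cr_seq, units, config.repeat_max_edits)
            for b in dec.blocks:
                rep_rows.append({"unit": b.unit_id, "length": len(b.copy_seq),
                                 "edits": b.edits})
            summary["repeat_units"] = {u.id: u.length for u in units}
            summary["repeat_copy_counts"] = dec.copy_counts()
            summary["repeat_order"] = dec.order_string()
        else:
            summary["repeat_units"] = {}
        pd.DataFrame(rep_rows).to_csv(
            os.path.join(config.outdir, "repeats.tsv"), sep="\t", index=False)

        _write_json(config, manifest, "summary.json", summary)
    except Exception as exc:
        manifest["_incomplete"] = {"failed_stage": stage, "error": str(exc)}
        _write_manifest(config, manifest)
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    _write_manifest(config, manifest)
    return summary


def _continuation(genome: str, aln, n: int) -> str:
    """Genome sequence immediately 3' of the aligned end, read orientation."""
    from .core_io import revcomp

    L = len(genome)
    pos = aln.span.three_prime
    if aln.orientation == PLUS:
        idx = [(pos + i) % L for i in range(n)]
        return "".join(genome[i] for i in idx)
    idx = [(pos - 2 - i) % L for i in range(n)]
    return revcomp("".join(genome[i] for i in reversed(idx)))


def _cr_sequence(genome: str, cr) -> str:
    if cr.span.wraps:
        return genome[cr.span.start - 1:] + genome[: cr.span.end]
    return genome[cr.span.start - 1: cr.span.end]


def _write_json(config, manifest, name, obj) -> None:
    path = os.path.join(config.outdir, name)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=str)
    manifest[name] = {"sha256": _sha256(path)}


def _write_manifest(config, manifest) -> None:
    for name in os.listdir(config.outdir):
        if name == "MANIFEST.json" or name in manifest:
            continue
        p = os.path.join(config.outdir, name)
        if os.path.isfile(p):
            manifest[name] = {"sha256": _sha256(p)}
    with open(os.path.join(config.outdir, "MANIFEST.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)
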