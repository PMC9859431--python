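"""Circular-genome coordinate model and annotation / alignment I/O.

Coordinates are 1-based inclusive throughout, matching the printed gene
table convention of insect mitogenome annotations; the 0-based half-open
conventions of PAF and BED are converted at the file boundary.

Strand vocabulary is ``plus`` (transcription in increasing-coordinate
direction; the majority "J" coding strand when the genome is oriented that
way) and ``minus``.  Circularity is expressed with a ``wraps`` flag: a
wrapped span occupies ``start..L`` followed by ``1..end`` and never uses
coordinates outside ``[1, L]``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace

import numpy as np

log = logging.getLogger(__name__)

PLUS = "plus"
MINUS = "minus"

#: Mapping-parameter record kept as run metadata only; read-to-genome
#: alignment is consumed by this package, never executed.
ALIGNER_CONFIG_FIELDS = (
    "max_gap_per_read",
    "max_gap_size",
    "min_overlap_identity",
    "max_mismatches_per_read",
    "max_ambiguity",
)


class CoordinateError(ValueError):
    """A coordinate falls outside ``[1, genome_length]`` or a span is malformed."""


@dataclass(frozen=True)
class GenomeSpan:
    """An oriented, possibly origin-crossing span on a circular reference.

    ``start <= end`` always holds for non-wrapped spans regardless of
    orientation; the transcriptional 5'/3' ends are derived from
    ``orientation``.  A wrapped span runs ``start..L`` then ``1..end``.
    """

    start: int
    end: int
    orientation: str = PLUS
    wraps: bool = False

    def validate(self, genome_length: int) -> None:
        for pos in (self.start, self.end):
            if not 1 <= pos <= genome_length:
                raise CoordinateError(
                    f"position {pos} outside [1, {genome_length}]"
                )
        if not self.wraps and self.start > self.end:
            raise CoordinateError(
                f"non-wrapped span has start {self.start} > end {self.end}"
            )

    def length(self, genome_length: int) -> int:
        self.validate(genome_length)
        if self.wraps:
            return (genome_length - self.start + 1) + self.end
        return self.end - self.start + 1

    @property
    def five_prime(self) -> int:
        """Transcriptional 5' coordinate (start for plus, end for minus)."""
        return self.start if self.orientation == PLUS else self.end

    @property
    def three_prime(self) -> int:
        return self.end if self.orientation == PLUS else self.start

    def positions(self, genome_length: int) -> np.ndarray:
        """All occupied 1-based coordinates, in genomic (not read) order."""
        self.validate(genome_length)
        if self.wraps:
            return np.concatenate(
                [
                    np.arange(self.start, genome_length + 1),
                    np.arange(1, self.end + 1),
                ]
            )
        return np.arange(self.start, self.end + 1)

    def path(self, genome_length: int) -> np.ndarray:
        """Occupied coordinates ordered 5' -> 3' along the transcript."""
        pos = self.positions(genome_length)
        return pos if self.orientation == PLUS else pos[::-1]

    def contains(self, pos: int, genome_length: int) -> bool:
        if self.wraps:
            return pos >= self.start or pos <= self.end
        return self.start <= pos <= self.end


def span_length(span: GenomeSpan, genome_length: int) -> int:
    """Wrap-aware inclusive length of *span* on a circle of size *genome_length*."""
    return span.length(genome_length)


@dataclass
class GeneFeature:
    """One annotated gene (or the control region) on the mitogenome."""

    name: str
    category: str  # PCG | tRNA | rRNA | CR
    span: GenomeSpan
    start_codon: str = ""  # RNA alphabet, e.g. "AUG"; empty for RNA genes
    stop_codon: str = ""  # full ("UAA"), incomplete ("U"/"UA"), or empty

    @property
    def orientation(self) -> str:
        return self.span.orientation


@dataclass
class MitoAnnotation:
    """Ordered gene features on one circular mitochondrial reference."""

    genome_length: int | None
    features: list[GeneFeature] = field(default_factory=list)
    circular: bool = True
    sequence: str | None = None

    def __post_init__(self) -> None:
        self.sort()

    def sort(self) -> None:
        self.features.sort(key=lambda f: (f.span.start, f.span.end))

    def get(self, name: str) -> GeneFeature:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(name)

    def __contains__(self, name: str) -> bool:
        return any(f.name == name for f in self.features)

    def genes(self) -> list[GeneFeature]:
        """Features excluding the control region."""
        return [f for f in self.features if f.category != "CR"]

    def transcription_order(self, orientation: str) -> list[GeneFeature]:
        """Features in 5'->3' order for transcripts of *orientation*.

        Positional order along the strand: increasing coordinates for plus,
        decreasing for minus.  All features are included (a transcript of one
        orientation runs across the loci of both coding strands).
        """
        feats = sorted(self.features, key=lambda f: f.span.start)
        return feats if orientation == PLUS else feats[::-1]

    def replace_feature(self, feature: GeneFeature) -> None:
        self.features = [f for f in self.features if f.name != feature.name]
        self.features.append(feature)
        self.sort()

    def copy(self) -> "MitoAnnotation":
        return MitoAnnotation(
            genome_length=self.genome_length,
            features=[replace(f, span=f.span) for f in self.features],
            circular=self.circular,
            sequence=self.sequence,
        )


@dataclass
class TranscriptAlignment:
    """Wrap-aware aligned footprint of one full-length read, plus its
    unaligned 5'/3' tail sequences in read orientation."""

    read_id: str
    orientation: str
    span: GenomeSpan
    tail5: str = ""
    tail3: str = ""
    identity: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.identity <= 1.0:
            raise ValueError(f"identity {self.identity} outside [0, 1]")
        if self.span.orientation != self.orientation:
            self.span = replace(self.span, orientation=self.orientation)


@dataclass(frozen=True)
class AlignerConfig:
    """Geneious-style long-read mapping parameters, recorded for provenance.

    This package consumes alignments; it never maps reads.  The defaults are
    the mapping configuration under which the supported alignment inputs are
    expected to have been produced.
    """

    max_gap_per_read: float = 0.10
    max_gap_size: int = 20
    min_overlap_identity: float = 0.85
    max_mismatches_per_read: float = 0.10
    max_ambiguity: int = 16

    def to_json(self) -> str:
        return json.dumps({k: getattr(self, k) for k in ALIGNER_CONFIG_FIELDS})


# ---------------------------------------------------------------------------
# Annotation I/O
# ---------------------------------------------------------------------------

_CATEGORY_BY_PREFIX = (("trn", "tRNA"), ("lrRNA", "rRNA"), ("srRNA", "rRNA"), ("CR", "CR"))


def infer_category(name: str) -> str:
    for prefix, cat in _CATEGORY_BY_PREFIX:
        if name.startswith(prefix):
            return cat
    return "PCG"


def _normalize_row_span(start: int, end: int, strand_hint: str | None) -> GenomeSpan:
    """Tabular fixtures give minus genes with descending coordinates."""
    if start > end:
        return GenomeSpan(end, start, MINUS)
    orientation = MINUS if strand_hint in ("N", "-", MINUS) else PLUS
    return GenomeSpan(start, end, orientation)


def load_annotation(path, genome_length: int | None = None) -> MitoAnnotation:
    """Load a gene annotation from GFF3, BED, or the packaged tabular fixture.

    The tabular dialect is tab-separated with columns
    ``gene strand start end [start_codon stop_codon]`` where strand is J/N
    (or +/-) and minus-strand rows may give descending coordinates.
    Overlapping features are allowed (pre-refinement state).
    """
    path = str(path)
    lines = [ln.rstrip("\n") for ln in open(path)]
    if not any(ln.strip() and not ln.startswith("#") for ln in lines):
        log.warning("annotation file %s is empty", path)
        return MitoAnnotation(genome_length=genome_length, features=[])
    if path.endswith((".gff", ".gff3")):
        return _load_gff3(lines, genome_length)
    if path.endswith(".bed"):
        return _load_bed(lines, genome_length)
    return _load_tabular(lines, genome_length)


def _load_tabular(lines, genome_length) -> MitoAnnotation:
    feats = []
    for i, ln in enumerate(lines, 1):
        if not ln.strip() or ln.startswith("#"):
            continue
        parts = ln.split("\t")
        if len(parts) == 1:
            parts = ln.split()
        if len(parts) < 4:
            raise ValueError(f"malformed annotation row at line {i}: {ln!r}")
        name, strand, start, end = parts[:4]
        try:
            span = _normalize_row_span(int(start.replace(",", "")), int(end.replace(",", "")), strand)
        except ValueError as exc:
            raise ValueError(f"malformed annotation row at line {i}: {ln!r}") from exc
        start_codon = parts[4] if len(parts) > 4 else ""
        stop_codon = parts[5] if len(parts) > 5 else ""
        feats.append(
            GeneFeature(name, infer_category(name), span, start_codon, stop_codon)
        )
    ann = MitoAnnotation(genome_length=genome_length, features=feats)
    _check_bounds(ann)
    return ann


def _load_gff3(lines, genome_length) -> MitoAnnotation:
    # Minimal reader for the 9-column GFF3 this package itself writes.
    feats = []
    for i, ln in enumerate(lines, 1):
        if not ln.strip() or ln.startswith("#"):
            if ln.startswith("##sequence-region"):
                genome_length = int(ln.split()[-1])
            continue
        parts = ln.split("\t")
        if len(parts) != 9:
            raise ValueError(f"malformed GFF3 row at line {i}: {ln!r}")
        _, _, ftype, start, end, _, strand, _, attrs = parts
        info = dict(
            kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
        )
        name = info.get("Name", info.get("ID", f"feature{i}"))
        wraps = info.get("wraps", "false") == "true"
        span = GenomeSpan(
            int(start), int(end), MINUS if strand == "-" else PLUS, wraps=wraps
        )
        feats.append(
            GeneFeature(
                name,
                info.get("category", infer_category(name)),
                span,
                info.get("start_codon", ""),
                info.get("stop_codon", ""),
            )
        )
    ann = MitoAnnotation(genome_length=genome_length, features=feats)
    _check_bounds(ann)
    return ann


def _load_bed(lines, genome_length) -> MitoAnnotation:
    feats = []
    for i, ln in enumerate(lines, 1):
        if not ln.strip() or ln.startswith(("#", "track")):
            continue
        parts = ln.split("\t")
        if len(parts) < 4:
            raise ValueError(f"malformed BED row at line {i}: {ln!r}")
        start = int(parts[1]) + 1  # BED is 0-based half-open
        end = int(parts[2])
        name = parts[3]
        strand = parts[5] if len(parts) > 5 else "+"
        span = GenomeSpan(start, end, MINUS if strand == "-" else PLUS)
        feats.append(GeneFeature(name, infer_category(name), span))
    ann = MitoAnnotation(genome_length=genome_length, features=feats)
    _check_bounds(ann)
    return ann


def _check_bounds(ann: MitoAnnotation) -> None:
    if ann.genome_length is None:
        return
    for f in ann.features:
        f.span.validate(ann.genome_length)


def write_annotation_gff3(ann: MitoAnnotation, path, source: str = "mitotx",
                          descending_minus: bool = False) -> None:
    """Write annotation as GFF3 (1-based inclusive, strand +/-).

    ``descending_minus`` restores the printed-table convention of giving
    minus-strand features with descending coordinates (non-standard GFF3;
    only for fixture-style tabular export round-trips).
    """
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        if ann.genome_length:
            fh.write(f"##sequence-region ChrM 1 {ann.genome_length}\n")
        for f in ann.features:
            strand = "+" if f.orientation == PLUS else "-"
            attrs = [f"ID={f.name}", f"Name={f.name}", f"category={f.category}"]
            if f.start_codon:
                attrs.append(f"start_codon={f.start_codon}")
            if f.stop_codon:
                attrs.append(f"stop_codon={f.stop_codon}")
            if f.span.wraps:
                attrs.append("wraps=true")
            ftype = {"PCG": "gene", "tRNA": "tRNA", "rRNA": "rRNA", "CR": "region"}[
                f.category
            ]
            start, end = f.span.start, f.span.end
            if descending_minus and f.orientation == MINUS:
                start, end = end, start
            fh.write(
                "\t".join(
                    [
                        "ChrM",
                        source,
                        ftype,
                        str(start),
                        str(end),
                        ".",
                        strand,
                        ".",
                        ";".join(attrs),
                    ]
                )
                + "\n"
            )


def write_annotation_tabular(ann: MitoAnnotation, path) -> None:
    """Write the tabular dialect (minus rows in descending convention)."""
    with open(path, "w") as fh:
        fh.write("#gene\tstrand\tstart\tend\tstart_codon\tstop_codon\n")
        for f in ann.features:
            if f.orientation == MINUS:
                strand, start, end = "N", f.span.end, f.span.start
            else:
                strand, start, end = "J", f.span.start, f.span.end
            fh.write(
                f"{f.name}\t{strand}\t{start}\t{end}\t{f.start_codon}\t{f.stop_codon}\n"
            )


# ---------------------------------------------------------------------------
# Alignment I/O
# ---------------------------------------------------------------------------

TSV_COLUMNS = (
    "read_id",
    "orientation",
    "start",
    "end",
    "wraps",
    "tail5",
    "tail3",
    "identity",
)


def load_alignments(path, reference: str | None = None,
                    read_seqs: dict[str, str] | None = None) -> list[TranscriptAlignment]:
    """Load transcript alignments from PAF, SAM, or the 8-column TSV dialect.

    One :class:`TranscriptAlignment` is produced per primary record;
    secondary/supplementary records are skipped (count logged).  PAF blocks of
    the same read abutting positions L and 1 on the same strand are joined
    into a single wrapped span.  ``read_seqs`` (read name -> sequence, read
    orientation) enables tail extraction for PAF input, which does not carry
    sequence.
    """
    path = str(path)
    if path.endswith(".sam") or path.endswith(".bam"):
        return _load_sam(path, reference)
    if path.endswith(".paf"):
        return _load_paf(path, reference, read_seqs)
    return _load_tsv(path)


def _load_tsv(path) -> list[TranscriptAlignment]:
    out = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != list(TSV_COLUMNS):
            raise ValueError(
                f"unexpected alignment TSV header {header!r}; expected {list(TSV_COLUMNS)}"
            )
        for ln in fh:
            if not ln.strip():
                continue
            rid, orient, start, end, wraps, tail5, tail3, ident = ln.rstrip(
                "\n"
            ).split("\t")
            out.append(
                TranscriptAlignment(
                    read_id=rid,
                    orientation=orient,
                    span=GenomeSpan(
                        int(start), int(end), orient, wraps=wraps.lower() == "true"
                    ),
                    tail5=tail5,
                    tail3=tail3,
                    identity=float(ident),
                )
            )
    return out


def write_alignments_tsv(alignments, path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(TSV_COLUMNS) + "\n")
        for a in alignments:
            fh.write(
                "\t".join(
                    [
                        a.read_id,
                        a.orientation,
                        str(a.span.start),
                        str(a.span.end),
                        str(a.span.wraps).lower(),
                        a.tail5,
                        a.tail3,
                        f"{a.identity:.6g}",
                    ]
                )
                + "\n"
            )


def _load_paf(path, reference, read_seqs) -> list[TranscriptAlignment]:
    records = []  # (read_id, strand, tstart1, tend1, qlen, qstart, qend, tlen)
    with open(path) as fh:
        for i, ln in enumerate(fh, 1):
            if not ln.strip():
                continue
            parts = ln.rstrip("\n").split("\t")
            if len(parts) < 12:
                raise ValueError(f"malformed PAF row at line {i}")
            qname, qlen, qstart, qend, strand, tname = parts[:6]
            tlen, tstart, tend = int(parts[6]), int(parts[7]), int(parts[8])
            if reference is not None and tname != reference:
                raise ValueError(f"unknown reference name {tname!r} at line {i}")
            if any(p.startswith("tp:A:") and p[5] in "SI" for p in parts[12:]):
                continue  # secondary / inversion records
            records.append(
                (
                    qname,
                    PLUS if strand == "+" else MINUS,
                    tstart + 1,  # 0-based half-open -> 1-based inclusive
                    tend,
                    int(qlen),
                    int(qstart),
                    int(qend),
                    tlen,
                )
            )

    # Join the two blocks of origin-crossing reads.
    by_read: dict[tuple[str, str], list] = {}
    for rec in records:
        by_read.setdefault((rec[0], rec[1]), []).append(rec)

    out = []
    for (rid, orient), recs in by_read.items():
        recs.sort(key=lambda r: r[2])
        tlen = recs[0][7]
        if (
            len(recs) == 2
            and recs[0][2] == 1
            and recs[1][3] == tlen
        ):
            low, high = recs
            span = GenomeSpan(high[2], low[3], orient, wraps=True)
            qstart = min(low[5], high[5])
            qend = max(low[6], high[6])
            qlen = low[4]
        elif len(recs) == 1:
            (_, _, t1, t2, qlen, qstart, qend, _) = recs[0]
            span = GenomeSpan(t1, t2, orient)
        else:
            log.warning("read %s has %d blocks; keeping the longest", rid, len(recs))
            rec = max(recs, key=lambda r: r[3] - r[2])
            (_, _, t1, t2, qlen, qstart, qend, _) = rec
            span = GenomeSpan(t1, t2, orient)
        tail5 = tail3 = ""
        if read_seqs and rid in read_seqs:
            seq = read_seqs[rid]
            tail5, tail3 = seq[:qstart], seq[qend:]
        elif qstart or qlen - qend:
            tail5, tail3 = "N" * qstart, "N" * (qlen - qend)
        out.append(TranscriptAlignment(rid, orient, span, tail5, tail3))
    out.sort(key=lambda a: a.read_id)
    return out


_COMPLEMENT = str.maketrans("ACGTUNacgtun", "TGCAANtgcaan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _load_sam(path, reference) -> list[TranscriptAlignment]:
    import pysam

    out = []
    skipped = 0
    mode = "rb" if str(path).endswith(".bam") else "r"
    with pysam.AlignmentFile(path, mode, check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped:
                continue
            if rec.is_secondary or rec.is_supplementary:
                skipped += 1
                continue
            if reference is not None and rec.reference_name != reference:
                raise ValueError(f"unknown reference name {rec.reference_name!r}")
            orient = MINUS if rec.is_reverse else PLUS
            span = GenomeSpan(rec.reference_start + 1, rec.reference_end, orient)
            cig = rec.cigartuples or []
            left = cig[0][1] if cig and cig[0][0] in (4, 5) else 0
            right = cig[-1][1] if cig and cig[-1][0] in (4, 5) else 0
            seq = rec.query_sequence or ""
            # SEQ is reference-oriented; restore read orientation for tails.
            left_clip = seq[:left] if left and seq else "N" * left
            right_clip = seq[len(seq) - right:] if right and seq else "N" * right
            if rec.is_reverse:
                tail5, tail3 = revcomp(right_clip), revcomp(left_clip)
            else:
                tail5, tail3 = left_clip, right_clip
            nm = rec.get_tag("NM") if rec.has_tag("NM") else 0
            alen = rec.query_alignment_length or 1
            out.append(
                TranscriptAlignment(
                    rec.query_name, orient, span, tail5, tail3,
                    identity=max(0.0, 1.0 - nm / alen),
                )
            )
    if skipped:
        log.info("skipped %d secondary/supplementary SAM records", skipped)
    return out


# ---------------------------------------------------------------------------
# Track export
# ---------------------------------------------------------------------------

def write_bedgraph(counts: np.ndarray, path, name: str = "coverage") -> None:
    """Write a per-base integer array (index 0 == position 1) as bedGraph,
    merging contiguous runs of equal value and omitting zero runs."""
    counts = np.asarray(counts)
    with open(path, "w") as fh:
        fh.write(f'track type=bedGraph name="{name}"\n')
        if counts.size == 0:
            return
        boundaries = np.flatnonzero(np.diff(counts)) + 1
        starts = np.concatenate([[0], boundaries])
        ends = np.concatenate([boundaries, [counts.size]])
        for s, e in zip(starts, ends):
            v = counts[s]
            if v != 0:
                fh.write(f"ChrM\t{s}\t{e}\t{v}\n")


def write_tracks(track, annotation: MitoAnnotation, outdir) -> dict[str, str]:
    """Serialize a coverage track (plus/minus bedGraph) and the annotation
    (GFF3).  Returns the written paths keyed by role."""
    import os

    if annotation.genome_length is not None and len(track.plus_counts) != annotation.genome_length:
        raise ValueError(
            f"track length {len(track.plus_counts)} != genome length "
            f"{annotation.genome_length}"
        )
    os.makedirs(outdir, exist_ok=True)
    paths = {
        "plus_bedgraph": os.path.join(outdir, "coverage_plus.bedgraph"),
        "minus_bedgraph": os.path.join(outdir, "coverage_minus.bedgraph"),
        "annotation_gff3": os.path.join(outdir, "annotation.gff3"),
    }
    write_bedgraph(track.plus_counts, paths["plus_bedgraph"], "coverage_plus")
    write_bedgraph(track.minus_counts, paths["minus_bedgraph"], "coverage_minus")
    write_annotation_gff3(annotation, paths["annotation_gff3"])
    return paths


def read_fasta(path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i: i + width] + "\n")
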