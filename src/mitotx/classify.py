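"""Quantitative transcription map and per-read transcript classification.

Every mapped read increments a strand-specific per-base coverage track over
its wrap-aware footprint; each read is then assigned exactly one class
(mature monocistron, mature bicistron, unprocessed polycistronic precursor,
antisense transcript, control-region lncRNA, or ambiguous) together with
the ordered list of gene units it covers and a truncation end-state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import PLUS, MitoAnnotation, TranscriptAlignment
from .fixtures import BICISTRON_PAIRS

DEFAULT_END_TOL = 3
UNIT_COVER_FRACTION = 0.5


@dataclass
class CoverageTrack:
    plus_counts: np.ndarray
    minus_counts: np.ndarray

    @property
    def genome_length(self) -> int:
        return len(self.plus_counts)

    def total(self) -> int:
        return int(self.plus_counts.sum() + self.minus_counts.sum())

    def mean_coverage(self) -> float:
        return self.total() / self.genome_length


@dataclass
class TranscriptCall:
    read_id: str
    klass: str
    units: list[str] = field(default_factory=list)
    end_state: str = "complete"
    orientation: str = PLUS
    alignment: TranscriptAlignment | None = None


def build_coverage(alignments, genome_length: int) -> CoverageTrack:
    """Strand-specific per-base read coverage; each read counts each of its
    footprint bases exactly once, so the track total equals the summed
    wrap-aware aligned lengths."""
    plus = np.zeros(genome_length, dtype=np.int64)
    minus = np.zeros(genome_length, dtype=np.int64)
    for aln in alignments:
        arr = plus if aln.orientation == PLUS else minus
        s = aln.span
        if s.wraps:
            arr[s.start - 1:] += 1
            arr[: s.end] += 1
        else:
            arr[s.start - 1: s.end] += 1
    return CoverageTrack(plus, minus)


def _path_index(span, genome_length: int) -> dict[int, int]:
    """coordinate -> 0-based offset along the read 5'->3' path."""
    return {int(p): i for i, p in enumerate(span.path(genome_length))}


def _covered_units(aln: TranscriptAlignment, annotation: MitoAnnotation):
    """Genes covered >= UNIT_COVER_FRACTION, ordered along the read path.

    Returns (units, sense_genes): unit names carry an ``as`` prefix when the
    gene is coded on the strand opposite the read.
    """
    L = annotation.genome_length
    idx = _path_index(aln.span, L)
    entries = []
    sense_genes = []
    for gene in annotation.genes():
        glen = gene.span.length(L)
        hits = [idx[p] for p in gene.span.positions(L).tolist() if p in idx]
        if len(hits) / glen >= UNIT_COVER_FRACTION:
            first = min(hits)
            if gene.orientation == aln.orientation:
                entries.append((first, gene.name))
                sense_genes.append(gene.name)
            else:
                entries.append((first, "as" + gene.name))
    entries.sort()
    return [name for _, name in entries], sense_genes


def transcriptional_offset(from_pos: int, to_pos: int, orientation: str,
                           genome_length: int) -> int:
    """Circular distance from *from_pos* downstream (5'->3') to *to_pos*.

    Result in ``[0, L)``; values past ``L/2`` indicate *to_pos* actually lies
    upstream (the short way round in the other direction).
    """
    if orientation == PLUS:
        return (to_pos - from_pos) % genome_length
    return (from_pos - to_pos) % genome_length


def end_state_vs(aln, envelope_5p: int, envelope_3p: int, end_tol: int,
                 genome_length: int) -> str:
    """Truncation state of a read against a 5'/3' coordinate envelope.

    An end farther than *end_tol* inside the envelope is truncated; an end
    at or beyond the envelope boundary (overhang) is not.
    """
    half = genome_length // 2
    d5 = transcriptional_offset(envelope_5p, aln.span.five_prime,
                                aln.orientation, genome_length)
    d3 = transcriptional_offset(aln.span.three_prime, envelope_3p,
                                aln.orientation, genome_length)
    trunc5 = end_tol < d5 <= half
    trunc3 = end_tol < d3 <= half
    if trunc5 and trunc3:
        return "trunc_both"
    if trunc5:
        return "trunc5"
    if trunc3:
        return "trunc3"
    return "complete"


def classify_transcript(aln: TranscriptAlignment, annotation: MitoAnnotation,
                        end_tol: int = DEFAULT_END_TOL) -> TranscriptCall:
    """Assign one class to a read.

    Precedence: a read with an end inside the CR is a CR lncRNA; a read whose
    covered genes are all opposite-strand is antisense; single-unit reads are
    mature monocistrons (possibly truncated), whitelisted pairs mature
    bicistrons, any other multi-unit read an unprocessed precursor.
    """
    L = annotation.genome_length
    units, sense = _covered_units(aln, annotation)

    cr = annotation.get("CR") if "CR" in annotation else None
    end_in_cr = cr is not None and (
        cr.span.contains(aln.span.five_prime, L)
        or cr.span.contains(aln.span.three_prime, L)
    )

    def envelope_state(names: list[str]) -> str:
        feats = [annotation.get(n.removeprefix("as")) for n in names]
        # envelope ends in genome coordinates along the read's orientation
        if aln.orientation == PLUS:
            e5, e3 = feats[0].span.start, feats[-1].span.end
        else:
            e5, e3 = feats[0].span.end, feats[-1].span.start
        return end_state_vs(aln, e5, e3, end_tol, L)

    if end_in_cr:
        cr_units = units if "CR" in units else _insert_cr(units, aln, annotation)
        return TranscriptCall(aln.read_id, "lncRNA_CR", cr_units,
                              "complete", aln.orientation, aln)
    if not units:
        return TranscriptCall(aln.read_id, "ambiguous", [], "complete",
                              aln.orientation, aln)
    if not sense:
        return TranscriptCall(aln.read_id, "antisense", units,
                              envelope_state(units), aln.orientation, aln)
    if len(units) == 1:
        return TranscriptCall(aln.read_id, "mature_mono", units,
                              envelope_state(units), aln.orientation, aln)
    if len(units) == 2 and tuple(units) in _bicistron_unit_orders():
        return TranscriptCall(aln.read_id, "mature_bicistron", units,
                              envelope_state(units), aln.orientation, aln)
    return TranscriptCall(aln.read_id, "precursor_polycistron", units,
                          envelope_state(units), aln.orientation, aln)


def _bicistron_unit_orders():
    orders = set()
    for a, b in BICISTRON_PAIRS:
        orders.add((a, b))
        orders.add((b, a))
    return orders


def _insert_cr(units: list[str], aln, annotation) -> list[str]:
    """Place the CR unit at its path position among covered genes."""
    L = annotation.genome_length
    idx = _path_index(aln.span, L)
    cr = annotation.get("CR")
    hits = [idx[p] for p in cr.span.positions(L).tolist() if p in idx]
    cr_first = min(hits) if hits else 0
    entries = []
    for name in units:
        gene = annotation.get(name.removeprefix("as"))
        ghits = [idx[p] for p in gene.span.positions(L).tolist() if p in idx]
        entries.append((min(ghits), name))
    entries.append((cr_first, "CR"))
    entries.sort()
    return [n for _, n in entries]


def classify_all(alignments, annotation, end_tol: int = DEFAULT_END_TOL):
    """Classify every read; total and order-independent (pure per-read)."""
    return [classify_transcript(a, annotation, end_tol) for a in alignments]


def expression_table(calls) -> pd.DataFrame:
    """Per-gene sense/antisense read counts and sense-expression rank.

    Mature (and truncated-mature) reads contribute +1 sense count to every
    member gene of their unit(s); antisense reads contribute +1 antisense
    count per covered gene; unprocessed precursors and CR lncRNAs are
    reported separately and excluded here.
    """
    sense: dict[str, int] = {}
    anti: dict[str, int] = {}
    for call in calls:
        if call.klass in ("mature_mono", "mature_bicistron"):
            for unit in call.units:
                if not unit.startswith("as"):
                    sense[unit] = sense.get(unit, 0) + 1
        elif call.klass == "antisense":
            for unit in call.units:
                gene = unit.removeprefix("as")
                anti[gene] = anti.get(gene, 0) + 1
    genes = sorted(set(sense) | set(anti))
    df = pd.DataFrame(
        {
            "gene": genes,
            "sense_count": [sense.get(g, 0) for g in genes],
            "antisense_count": [anti.get(g, 0) for g in genes],
        }
    )
    df = df.sort_values(
        ["sense_count", "gene"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df


def class_summary(calls) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "read_id": [c.read_id for c in calls],
            "class": [c.klass for c in calls],
            "units": ["|".join(c.units) for c in calls],
            "end_state": [c.end_state for c in calls],
            "orientation": [c.orientation for c in calls],
        }
    )
    return df


def plot_transcription_map(track: CoverageTrack, annotation: MitoAnnotation,
                           path=None):
    """Render the strand-split coverage map (plus axis up, minus axis down)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    x = np.arange(1, track.genome_length + 1)
    fig, ax = plt.subplots(figsize=(12, 4))
    ax.fill_between(x, track.plus_counts, 0, color="#3465a4", lw=0,
                    label="plus strand")
    ax.fill_between(x, -track.minus_counts, 0, color="#f57900", lw=0,
                    label="minus strand")
    for f in annotation.features:
        ax.axvspan(f.span.start, f.span.end, color="0.8", alpha=0.2, lw=0)
    ax.axhline(0, color="k", lw=0.5)
    ax.set_xlabel("mitogenome position (bp)")
    ax.set_ylabel("read coverage")
    ax.legend(loc="upper left", frameon=False)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
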