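"""Transcript-guided re-annotation of mitochondrial gene boundaries.

Full-length transcript ends are used to (i) move PCG 3' boundaries to the
mature polyadenylated end, recomputing complete or incomplete (U / UA) stop
codons that polyadenylation completes to UAA; (ii) move PCG 5' boundaries
while keeping a valid start codon; (iii) re-locate rRNA boundaries from
high-support end clusters; and (iv) derive the control region as the single
largest unannotated stretch of the circle.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

from .core_io import (
    MINUS,
    PLUS,
    GeneFeature,
    GenomeSpan,
    MitoAnnotation,
    revcomp,
)
from .fixtures import BICISTRON_PAIRS

log = logging.getLogger(__name__)

#: Accepted invertebrate mitochondrial start codons (RNA alphabet).
START_CODONS = frozenset({"AUU", "AUC", "AUA", "AUG", "GUG", "UUG"})

FULL_STOPS = frozenset({"UAA", "UAG"})

#: Collapsing window for "dominant end" determination (nt).
END_COLLAPSE_TOL = 3

#: Minimum cluster support for moving an rRNA boundary.
DEFAULT_RRNA_MIN_SUPPORT = 3


@dataclass
class EndEvidence:
    """Read support for one transcript end position of one gene."""

    gene: str
    end_type: str  # five_prime | three_prime
    position: int
    support: int = 1
    polyA_backed: bool = False


@dataclass
class GeneChange:
    gene: str
    old_span: GenomeSpan
    new_span: GenomeSpan
    old_stop: str
    new_stop: str
    rule: str
    evidence: list[EndEvidence] = field(default_factory=list)


@dataclass
class RefinementReport:
    changes: list[GeneChange] = field(default_factory=list)
    removed_overlaps: list[tuple[str, str]] = field(default_factory=list)
    residual_overlaps: list[tuple[str, str]] = field(default_factory=list)

    def to_records(self):
        return [
            {
                "gene": c.gene,
                "old_start": c.old_span.start,
                "old_end": c.old_span.end,
                "new_start": c.new_span.start,
                "new_end": c.new_span.end,
                "old_stop": c.old_stop,
                "new_stop": c.new_stop,
                "rule": c.rule,
                "support": sum(e.support for e in c.evidence),
            }
            for c in self.changes
        ]


def rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def gene_sequence(genome: str, span: GenomeSpan) -> str:
    """Transcribed-orientation DNA sequence of a span (no wrap handling
    needed for gene features, which never cross the origin here)."""
    if span.wraps:
        seq = genome[span.start - 1:] + genome[: span.end]
    else:
        seq = genome[span.start - 1: span.end]
    return seq if span.orientation == PLUS else revcomp(seq)


def dominant_end(evidence: list[EndEvidence], prefer: int | None = None,
                 tol: int = END_COLLAPSE_TOL) -> tuple[int, int] | None:
    """Modal end position after collapsing within ``+-tol`` nt.

    Returns (position, support) or None for empty evidence.  Ties are broken
    toward *prefer* (the current annotation) when given, then toward the
    smaller coordinate for determinism.
    """
    if not evidence:
        return None
    counts: dict[int, int] = {}
    for e in evidence:
        counts[e.position] = counts.get(e.position, 0) + e.support
    # collapse: each position absorbs neighbours within tol, seeded from the
    # most-supported positions
    order = sorted(counts, key=lambda p: (-counts[p], p != prefer, p))
    taken: set[int] = set()
    clusters = []
    for seed in order:
        if seed in taken:
            continue
        members = [p for p in counts if abs(p - seed) <= tol and p not in taken]
        taken.update(members)
        clusters.append((seed, sum(counts[p] for p in members)))
    clusters.sort(key=lambda c: (-c[1], c[0] != prefer, c[0]))
    return clusters[0]


def refine_pcg_3prime(gene: GeneFeature, evidence: list[EndEvidence],
                      genome: str) -> GeneFeature:
    """Move a PCG 3' boundary to the dominant polyA-backed mature end and
    recompute the (possibly incomplete) stop codon from the genome.

    The boundary never extends transcriptionally past the DNA-based stop
    codon; a dominant end whose final base is not frame-consistent with a
    stop remnant leaves the gene unchanged (flagged).
    """
    if gene.category != "PCG":
        raise ValueError(f"{gene.name} is not a PCG")
    ev = [
        e for e in evidence
        if e.gene == gene.name and e.end_type == "three_prime" and e.polyA_backed
    ]
    dom = dominant_end(ev, prefer=gene.span.three_prime)
    if dom is None:
        return gene
    pos = dom[0]
    old3 = gene.span.three_prime
    # never extend past the DNA-based stop codon
    if (gene.orientation == PLUS and pos > old3) or (
        gene.orientation == MINUS and pos < old3
    ):
        pos = old3
    if gene.orientation == PLUS:
        new_span = replace(gene.span, end=pos)
    else:
        new_span = replace(gene.span, start=pos)
    length = new_span.end - new_span.start + 1
    seq = gene_sequence(genome, new_span)
    r = length % 3
    if r == 0:
        stop = rna(seq[-3:])
        ok = stop in FULL_STOPS
    elif r == 1:
        stop = rna(seq[-1:])
        ok = stop == "U"
    else:
        stop = rna(seq[-2:])
        ok = stop == "UA"
    if not ok:
        log.warning(
            "%s: dominant 3' end %d not frame-consistent with a stop remnant "
            "(%s); gene left unchanged", gene.name, pos, stop,
        )
        return gene
    return replace(gene, span=new_span, stop_codon=stop)


def refine_pcg_5prime(gene: GeneFeature, evidence: list[EndEvidence],
                      genome: str, start_codons=START_CODONS,
                      window: int = 12) -> GeneFeature:
    """Move a PCG 5' boundary to the dominant transcript 5' end, requiring
    the result to begin with an accepted start codon (searching up to
    *window* nt downstream in frame if the dominant end itself does not)."""
    if gene.category != "PCG":
        raise ValueError(f"{gene.name} is not a PCG")
    ev = [e for e in evidence if e.gene == gene.name and e.end_type == "five_prime"]
    dom = dominant_end(ev, prefer=gene.span.five_prime)
    if dom is None:
        return gene
    pos = dom[0]
    for offset in range(0, window + 1, 3):
        if gene.orientation == PLUS:
            cand = pos + offset
            span = replace(gene.span, start=cand)
            if cand > gene.span.end:
                break
        else:
            cand = pos - offset
            span = replace(gene.span, end=cand)
            if cand < gene.span.start:
                break
        codon = rna(gene_sequence(genome, span)[:3])
        if codon in start_codons:
            return replace(gene, span=span, start_codon=codon)
    warnings.warn(
        f"{gene.name}: no valid start codon within {window} nt of dominant "
        f"5' end {pos}; gene left unchanged"
    )
    return gene


def refine_rrna(gene: GeneFeature, evidence: list[EndEvidence],
                min_support: int = DEFAULT_RRNA_MIN_SUPPORT) -> GeneFeature:
    """Replace each rRNA boundary with its highest-support end cluster
    (support >= *min_support*); ties break toward the longer gene."""
    if gene.category != "rRNA":
        raise ValueError(f"{gene.name} is not an rRNA")
    span = gene.span
    for end_type in ("five_prime", "three_prime"):
        ev = [e for e in evidence if e.gene == gene.name and e.end_type == end_type]
        if not ev:
            warnings.warn(f"{gene.name}: no {end_type} evidence; boundary kept")
            continue
        counts: dict[int, int] = {}
        for e in ev:
            counts[e.position] = counts.get(e.position, 0) + e.support
        # tie-break toward the longer gene: for a minus-gene 5' end (== span.end)
        # larger coordinate lengthens the gene, etc.
        lengthens_with_larger = (end_type == "five_prime") == (
            gene.orientation == MINUS
        )
        best = max(
            counts,
            key=lambda p: (counts[p], p if lengthens_with_larger else -p),
        )
        if counts[best] < min_support:
            warnings.warn(
                f"{gene.name}: best {end_type} cluster support {counts[best]} "
                f"< {min_support}; boundary kept"
            )
            continue
        if (end_type == "five_prime") == (gene.orientation == PLUS):
            span = replace(span, start=best)
        else:
            span = replace(span, end=best)
    return replace(gene, span=span)


def derive_cr(annotation: MitoAnnotation) -> GeneFeature:
    """The control region: the single largest unannotated gap of the circle.

    Replaces any existing CR feature in *annotation* and returns it.
    Raises if two gaps tie for largest.
    """
    L = annotation.genome_length
    if L is None:
        raise ValueError("annotation has no genome length")
    genes = sorted(annotation.genes(), key=lambda f: f.span.start)
    if not genes:
        raise ValueError("no gene features to derive CR from")
    gaps = []  # (length, start, end)
    for a, b in zip(genes, genes[1:]):
        if b.span.start > a.span.end + 1:
            gaps.append((b.span.start - a.span.end - 1, a.span.end + 1, b.span.start - 1))
    # wrap gap between the last gene and the first
    last, first = genes[-1], genes[0]
    wrap_len = (L - last.span.end) + (first.span.start - 1)
    if wrap_len > 0:
        if last.span.end < L and first.span.start > 1:
            gaps.append((wrap_len, last.span.end + 1, first.span.start - 1))
        elif last.span.end < L:
            gaps.append((wrap_len, last.span.end + 1, L))
        else:
            gaps.append((wrap_len, 1, first.span.start - 1))
    if not gaps:
        raise ValueError("annotation leaves no unannotated gap for a CR")
    gaps.sort(reverse=True)
    if len(gaps) > 1 and gaps[0][0] == gaps[1][0]:
        cands = [g for g in gaps if g[0] == gaps[0][0]]
        raise ValueError(f"multiple equally largest gaps: {cands}")
    size, start, end = gaps[0]
    wraps = start > end
    cr = GeneFeature("CR", "CR", GenomeSpan(start, end, PLUS, wraps=wraps))
    annotation.replace_feature(cr)
    return cr


def _overlap(a: GenomeSpan, b: GenomeSpan, L: int) -> bool:
    if not a.wraps and not b.wraps:
        return a.start <= b.end and b.start <= a.end
    pa = set(a.positions(L).tolist())
    return any(p in pa for p in b.positions(L).tolist())


def validate_annotation(annotation: MitoAnnotation,
                        dna_annotation: MitoAnnotation | None = None,
                        allowed_pairs=BICISTRON_PAIRS) -> RefinementReport:
    """Check for residual same-orientation gene overlaps.

    Overlapping bicistron ORF partners (*allowed_pairs*) are exempt — they
    overlap in the DNA itself and survive refinement.  When the pre-refinement
    annotation is given, the report lists the overlaps that disappeared.
    """
    allowed = {frozenset(p) for p in allowed_pairs}

    def overlaps(ann: MitoAnnotation) -> list[tuple[str, str]]:
        out = []
        feats = ann.genes()
        L = ann.genome_length or max(f.span.end for f in feats)
        for i, a in enumerate(feats):
            for b in feats[i + 1:]:
                if a.orientation != b.orientation:
                    continue
                if frozenset((a.name, b.name)) in allowed:
                    continue
                if _overlap(a.span, b.span, L):
                    out.append((a.name, b.name))
        return out

    residual = overlaps(annotation)
    removed = []
    if dna_annotation is not None:
        before = overlaps(dna_annotation)
        removed = [p for p in before if p not in residual]
    report = RefinementReport(removed_overlaps=removed, residual_overlaps=residual)
    if residual:
        log.warning("residual same-orientation overlaps: %s", residual)
    return report


def collect_end_evidence(alignments, annotation: MitoAnnotation,
                         end_tol: int = END_COLLAPSE_TOL,
                         min_polyA: int = 5) -> list[EndEvidence]:
    """Build per-gene end evidence from mature-looking alignments.

    A read is assigned to the same-orientation gene whose span it matches
    with reciprocal overlap >= *min_overlap* (so mature reads extending a
    few bases past a mis-drawn DNA boundary still count, while bicistronic
    and polycistronic reads match no single gene).  A 3' end is polyA-backed
    when the read's unaligned 3' tail ends in a >=\ *min_polyA* run that is
    >=90% A (after any non-templated CCA).
    """
    min_overlap = 0.9
    evidence: list[EndEvidence] = []
    for aln in alignments:
        if aln.span.wraps:
            continue
        best = None
        for gene in annotation.genes():
            if gene.orientation != aln.orientation or gene.span.wraps:
                continue
            g, s = gene.span, aln.span
            inter = min(g.end, s.end) - max(g.start, s.start) + 1
            if inter <= 0:
                continue
            frac = inter / max(g.end - g.start + 1, s.end - s.start + 1)
            if frac >= min_overlap and (best is None or frac > best[0]):
                best = (frac, gene)
        if best is None:
            continue
        gene = best[1]
        s = aln.span
        tail = aln.tail3.upper().replace("U", "T")
        if tail.startswith("CCA"):
            tail = tail[3:]
        polyA = len(tail) >= min_polyA and tail.count("A") / len(tail) >= 0.9
        evidence.append(
            EndEvidence(gene.name, "five_prime", s.five_prime, 1, False)
        )
        evidence.append(
            EndEvidence(gene.name, "three_prime", s.three_prime, 1, polyA)
        )
    return evidence


def refine_annotation(annotation: MitoAnnotation,
                      evidence: list[EndEvidence],
                      genome: str,
                      rrna_min_support: int = DEFAULT_RRNA_MIN_SUPPORT,
                      ) -> tuple[MitoAnnotation, RefinementReport]:
    """Run the full refinement pass: PCG 3'/5' boundaries, rRNA boundaries,
    CR derivation, and overlap validation.  Idempotent for fixed evidence."""
    refined = annotation.copy()
    report = RefinementReport()
    for feat in list(refined.genes()):
        if feat.category == "PCG":
            new = refine_pcg_3prime(feat, evidence, genome)
            new = refine_pcg_5prime(new, evidence, genome)
        elif feat.category == "rRNA":
            new = refine_rrna(feat, evidence, min_support=rrna_min_support)
        else:
            continue
        if new.span != feat.span:
            report.changes.append(
                GeneChange(
                    feat.name, feat.span, new.span, feat.stop_codon,
                    new.stop_codon, rule=feat.category,
                    evidence=[e for e in evidence if e.gene == feat.name],
                )
            )
            refined.replace_feature(new)
    derive_cr(refined)
    val = validate_annotation(refined, dna_annotation=annotation)
    report.removed_overlaps = val.removed_overlaps
    report.residual_overlaps = val.residual_overlaps
    return refined, report
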