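"""Post-transcriptional processing signals.

Three inferences are made from read 3' tails and precursor structure:

* tail chemistry — the non-templated CCA triplet added to tRNA 3' ends by
  tRNA nucleotidyltransferase, and polyadenylation (for tRNAs, *after* the
  CCA) — distinguished from genome-templated continuation by stripping the
  longest tail prefix that matches the genomic sequence 3' of the cut site;
* per-read degradation end state (complete / 5'-truncated / 3'-truncated);
* per-junction tRNA-punctuation cleavage direction: an unprocessed precursor
  that still carries its upstream tRNA but ends exactly where an absent
  downstream tRNA would begin shows the downstream tRNA was excised first
  ("reverse", 3'->5'); the mirror pattern shows the upstream tRNA went first
  ("forward", 5'->3').
"""

from __future__ import annotations

from dataclasses import dataclass

from .classify import DEFAULT_END_TOL, end_state_vs, transcriptional_offset
from .core_io import GeneFeature, MitoAnnotation, TranscriptAlignment

DEFAULT_MIN_POLYA = 5
POLYA_PURITY = 0.9


@dataclass
class TailCall:
    read_id: str
    templated_len: int
    cca: str  # absent | templated | non_templated
    polyA_len: int
    order: str  # cca_then_polyA | polyA_only | none


@dataclass
class JunctionEvidence:
    junction: tuple[str, str]
    reverse_support: int = 0
    forward_support: int = 0

    @property
    def reverse_fraction(self) -> float | None:
        n = self.reverse_support + self.forward_support
        return self.reverse_support / n if n else None


def _norm(seq: str) -> str:
    return seq.upper().replace("U", "T")


def call_tail(tail3: str, genomic_continuation: str, gene_category: str,
              read_id: str = "", min_polyA: int = DEFAULT_MIN_POLYA) -> TailCall:
    """Classify a read's unaligned 3' tail.

    The longest tail prefix matching the genomic continuation of the aligned
    end is templated.  For tRNAs, a remaining exact CCA prefix is the
    non-templated nucleotidyltransferase product (a single mismatch in CCA
    is conservatively called absent).  The remainder is a polyA tail when it
    has >= *min_polyA* bases at >=90% A.
    """
    tail = _norm(tail3)
    cont = _norm(genomic_continuation)
    templated = 0
    while templated < len(tail) and templated < len(cont) and tail[templated] == cont[templated]:
        templated += 1
    rest = tail[templated:]
    cca = "absent"
    if gene_category == "tRNA":
        if templated >= 3 and tail[:3] == "CCA":
            cca = "templated"
        elif rest.startswith("CCA"):
            cca = "non_templated"
            rest = rest[3:]
    polyA_len = 0
    if len(rest) >= min_polyA and rest.count("A") / len(rest) >= POLYA_PURITY:
        polyA_len = len(rest)
    if cca == "non_templated" and polyA_len >= min_polyA:
        order = "cca_then_polyA"
    elif polyA_len >= min_polyA:
        order = "polyA_only"
    else:
        order = "none"
    return TailCall(read_id, templated, cca, polyA_len, order)


def classify_end_state(aln: TranscriptAlignment, gene: GeneFeature,
                       end_tol: int = DEFAULT_END_TOL,
                       genome_length: int | None = None) -> str:
    """Degradation end state of a read assigned to one gene."""
    if aln.orientation != gene.orientation:
        raise ValueError(
            f"read {aln.read_id} orientation differs from gene {gene.name}"
        )
    L = genome_length or max(gene.span.end, aln.span.end) + 1
    half = L // 2
    # the read must not extend beyond the gene by more than the tolerance
    over5 = transcriptional_offset(aln.span.five_prime, gene.span.five_prime,
                                   aln.orientation, L)
    over3 = transcriptional_offset(gene.span.three_prime, aln.span.three_prime,
                                   aln.orientation, L)
    if end_tol < over5 <= half or end_tol < over3 <= half:
        raise ValueError(
            f"read {aln.read_id} extends outside gene {gene.name}"
        )
    return end_state_vs(aln, gene.span.five_prime, gene.span.three_prime,
                        end_tol, L)


def _same_orientation_order(annotation: MitoAnnotation, orientation: str):
    return [
        f for f in annotation.transcription_order(orientation)
        if f.orientation == orientation and f.category != "CR"
    ]


def infer_cleavage(calls, annotation: MitoAnnotation,
                   end_tol: int = DEFAULT_END_TOL) -> dict[tuple[str, str], JunctionEvidence]:
    """Per-junction cleavage-direction support from exact-boundary precursors.

    Only precursor calls whose read ends sit within ``+-end_tol`` of the
    first unit's 5' end and the last unit's 3' end are informative.  For a
    focal mRNA/rRNA unit, a retained upstream-adjacent tRNA combined with an
    absent next downstream tRNA (walking past any retained same-orientation
    genes to the precursor's 3' unit) adds reverse support at the junction
    (last unit, absent tRNA); the mirror adds forward support at
    (absent tRNA, first unit).  Adjacency skips genes coded on the opposite
    strand, which belong to the other primary transcript.
    """
    L = annotation.genome_length
    evidence: dict[tuple[str, str], JunctionEvidence] = {}

    def bump(junction, direction):
        ev = evidence.setdefault(junction, JunctionEvidence(junction))
        if direction == "reverse":
            ev.reverse_support += 1
        else:
            ev.forward_support += 1

    for call in calls:
        if call.klass != "precursor_polycistron" or call.alignment is None:
            continue
        aln = call.alignment
        order = _same_orientation_order(annotation, call.orientation)
        names = [f.name for f in order]
        units = [u for u in call.units if not u.startswith("as")]
        if len(units) < 2 or any(u not in names for u in units):
            continue
        first, last = units[0], units[-1]
        ffeat, lfeat = annotation.get(first), annotation.get(last)
        # exact-boundary precursor?
        if end_state_vs(aln, ffeat.span.five_prime, lfeat.span.three_prime,
                        end_tol, L) != "complete":
            continue
        # units must be contiguous in same-orientation gene order
        i0, i1 = names.index(first), names.index(last)
        if names[i0: i1 + 1] != units:
            continue
        unit_feats = {u: annotation.get(u) for u in units}
        seen: set[tuple[tuple[str, str], str]] = set()
        for focal in units:
            if unit_feats[focal].category in ("PCG", "rRNA"):
                k = names.index(focal)
                up = names[k - 1] if k > 0 else None
                down = names[k + 1] if k + 1 < len(names) else None
                up_feat = annotation.get(up) if up else None
                down_feat = annotation.get(down) if down else None
                if (
                    up_feat is not None
                    and up_feat.category == "tRNA"
                    and up in units
                    and i1 + 1 < len(names)
                    and annotation.get(names[i1 + 1]).category == "tRNA"
                    and names[i1 + 1] not in units
                ):
                    key = ((last, names[i1 + 1]), "reverse")
                    if key not in seen:
                        bump(*key)
                        seen.add(key)
                if (
                    down_feat is not None
                    and down_feat.category == "tRNA"
                    and down in units
                    and i0 > 0
                    and annotation.get(names[i0 - 1]).category == "tRNA"
                    and names[i0 - 1] not in units
                ):
                    key = ((names[i0 - 1], first), "forward")
                    if key not in seen:
                        bump(*key)
                        seen.add(key)
    return evidence


def cleavage_bias_by_gene(evidence: dict[tuple[str, str], JunctionEvidence],
                          annotation: MitoAnnotation) -> dict[str, float]:
    """Reverse-cleavage fraction per focal mRNA/rRNA gene.

    Reverse support for a focal gene lands on the junction downstream of the
    precursor it was seen in; forward support on the junction upstream.  The
    two are pooled per focal gene by attributing each junction's support to
    the non-tRNA gene adjacent to it in same-orientation order.
    """
    rev: dict[str, int] = {}
    fwd: dict[str, int] = {}
    for (a, b), ev in evidence.items():
        for name, counter, n in ((a, rev, ev.reverse_support),
                                 (b, fwd, ev.forward_support)):
            feat = annotation.get(name) if name in annotation else None
            if n == 0:
                continue
            if feat is not None and feat.category in ("PCG", "rRNA"):
                counter[name] = counter.get(name, 0) + n
            else:
                # walk to the nearest non-tRNA unit inward of the junction
                order = _same_orientation_order(
                    annotation, feat.orientation if feat else "plus"
                )
                names = [f.name for f in order]
                if name not in names:
                    continue
                k = names.index(name)
                step = -1 if counter is rev else 1
                while 0 <= k < len(names):
                    if annotation.get(names[k]).category in ("PCG", "rRNA"):
                        counter[names[k]] = counter.get(names[k], 0) + n
                        break
                    k += step
    out = {}
    for gene in set(rev) | set(fwd):
        r, f = rev.get(gene, 0), fwd.get(gene, 0)
        out[gene] = r / (r + f) if (r + f) else float("nan")
    return out


def tail_table(tail_calls) -> "object":
    import pandas as pd

    return pd.DataFrame(
        {
            "read_id": [t.read_id for t in tail_calls],
            "templated_len": [t.templated_len for t in tail_calls],
            "cca": [t.cca for t in tail_calls],
            "polyA_len": [t.polyA_len for t in tail_calls],
            "order": [t.order for t in tail_calls],
        }
    )


def junction_summary(evidence) -> dict:
    return {
        f"{a}|{b}": {
            "reverse_support": ev.reverse_support,
            "forward_support": ev.forward_support,
            "reverse_fraction": ev.reverse_fraction,
        }
        for (a, b), ev in sorted(evidence.items())
    }
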