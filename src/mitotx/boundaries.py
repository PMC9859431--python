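"""Transcription start/termination inference and rRNA isoform calling.

TIS/TTS candidates come from recurrent transcript ends: a transcription
initiation site is the transcriptionally most upstream 5'-end cluster inside
the control region supported by at least two reads; a termination site is
the 3' end, inside the CR, of the transcript that entered the CR from
outside and penetrated transcriptionally furthest.  A strand-specific
coverage collapse across a gene junction marks a terminator (downstream
coverage essentially zero) or an attenuator.  rRNA isoforms share a 3' end
and differ at clustered 5' ends; degradation directionality per gene is a
binomial comparison of 5'- versus 3'-truncated read counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from scipy.stats import binomtest

from .classify import CoverageTrack, DEFAULT_END_TOL, transcriptional_offset
from .core_io import MINUS, PLUS, GenomeSpan, MitoAnnotation
from .signals import classify_end_state

DEFAULT_CLUSTER_TOL = 3
DEFAULT_TIS_MIN_SUPPORT = 2
DEFAULT_DROP_RATIO = 0.05


@dataclass
class EndCluster:
    orientation: str
    end_type: str  # five_prime | three_prime
    position: int  # modal coordinate
    support: int
    spread: int


@dataclass
class SiteCall:
    orientation: str
    position: int
    support: int
    basis: str  # end_cluster | coverage_drop


@dataclass
class TerminationCall:
    orientation: str
    junction: tuple[str, str]
    kind: str  # terminator | attenuator
    upstream_mean: float
    downstream_mean: float


@dataclass
class IsoformCall:
    gene: str
    five_prime: int
    three_prime: int
    support: int


def cluster_positions(positions, cluster_tol: int = DEFAULT_CLUSTER_TOL,
                      min_support: int = 1):
    """Greedy frequency-descending collapse of coordinates into clusters of
    radius <= *cluster_tol*; returns [(modal position, support, spread)]."""
    counts: dict[int, int] = {}
    for p in positions:
        counts[p] = counts.get(p, 0) + 1
    taken: set[int] = set()
    clusters = []
    for seed in sorted(counts, key=lambda p: (-counts[p], p)):
        if seed in taken:
            continue
        members = [p for p in counts if abs(p - seed) <= cluster_tol and p not in taken]
        taken.update(members)
        support = sum(counts[p] for p in members)
        spread = max(abs(p - seed) for p in members)
        clusters.append((seed, support, spread))
    clusters.sort(key=lambda c: (-c[1], c[0]))
    return [c for c in clusters if c[1] >= min_support]


def cluster_ends(alignments, orientation: str, end_type: str,
                 cluster_tol: int = DEFAULT_CLUSTER_TOL,
                 min_support: int = 1) -> list[EndCluster]:
    positions = [
        a.span.five_prime if end_type == "five_prime" else a.span.three_prime
        for a in alignments
        if a.orientation == orientation
    ]
    return [
        EndCluster(orientation, end_type, pos, support, spread)
        for pos, support, spread in cluster_positions(
            positions, cluster_tol, min_support
        )
    ]


def infer_tis(clusters: list[EndCluster], cr: GenomeSpan,
              genome_length: int,
              min_support: int = DEFAULT_TIS_MIN_SUPPORT) -> SiteCall | None:
    """Transcriptionally most upstream supported 5'-end cluster inside CR."""
    inside = [
        c for c in clusters
        if c.support >= min_support and cr.contains(c.position, genome_length)
    ]
    if not inside:
        return None
    orientation = inside[0].orientation
    # upstream = smallest coordinate for plus transcription, largest for minus
    # (the CR itself never crosses the origin here)
    best = min(inside, key=lambda c: c.position if orientation == PLUS
               else -c.position)
    return SiteCall(orientation, best.position, best.support, "end_cluster")


def infer_tts(alignments, cr: GenomeSpan, orientation: str,
              genome_length: int) -> SiteCall | None:
    """3' end, inside CR, of the transcript penetrating furthest into CR.

    Only transcripts that *entered* the CR (5' end outside it) witness
    termination; lncRNAs initiated inside the CR do not.
    """
    candidates = [
        a for a in alignments
        if a.orientation == orientation
        and cr.contains(a.span.three_prime, genome_length)
        and not cr.contains(a.span.five_prime, genome_length)
    ]
    if not candidates:
        return None
    # entry point of transcription into CR: the CR boundary nearest upstream
    entry = cr.start if orientation == PLUS else cr.end
    best = max(
        candidates,
        key=lambda a: transcriptional_offset(
            entry, a.span.three_prime, orientation, genome_length
        ),
    )
    pos = best.span.three_prime
    support = sum(1 for a in candidates if a.span.three_prime == pos)
    return SiteCall(orientation, pos, support, "end_cluster")


def detect_termination(track: CoverageTrack, annotation: MitoAnnotation,
                       drop_ratio: float = DEFAULT_DROP_RATIO,
                       min_upstream: float = 1.0) -> list[TerminationCall]:
    """Scan gene junctions for strand-specific coverage collapse.

    A junction where mean downstream-gene coverage / mean upstream-gene
    coverage <= *drop_ratio* is a terminator when downstream coverage falls
    below one read, otherwise an attenuator.
    """
    L = track.genome_length
    out = []
    for orientation, counts in ((PLUS, track.plus_counts),
                                (MINUS, track.minus_counts)):
        feats = [
            f for f in annotation.transcription_order(orientation)
            if f.category != "CR"
        ]
        means = {}
        for f in feats:
            pos = f.span.positions(L) - 1
            means[f.name] = float(counts[pos].mean())
        for up, down in zip(feats, feats[1:]):
            mu, md = means[up.name], means[down.name]
            if mu >= min_upstream and md / mu <= drop_ratio:
                kind = "terminator" if md < 1.0 else "attenuator"
                out.append(
                    TerminationCall(orientation, (up.name, down.name), kind, mu, md)
                )
    return out


def call_isoforms(gene_alignments, gene_name: str = "",
                  cluster_tol: int = DEFAULT_CLUSTER_TOL,
                  min_isoform_support: int | None = None) -> list[IsoformCall]:
    """Isoforms of one (rRNA) gene: shared 3' end, clustered 5' ends.

    ``min_isoform_support`` defaults to 1% of the gene's read count with a
    floor of 5.
    """
    alns = list(gene_alignments)
    if not alns:
        return []
    if min_isoform_support is None:
        min_isoform_support = max(5, round(0.01 * len(alns)))
    three = cluster_positions(
        [a.span.three_prime for a in alns], cluster_tol, min_support=1
    )
    if len(three) > 1 and three[1][1] >= min_isoform_support:
        warnings.warn(
            f"{gene_name or 'gene'}: 3' ends disagree beyond tolerance; "
            "calling isoforms per 3' cluster"
        )
        three_clusters = [t for t in three if t[1] >= min_isoform_support]
    else:
        three_clusters = three[:1]
    out = []
    for tpos, _, _ in three_clusters:
        members = [
            a for a in alns
            if abs(a.span.three_prime - tpos) <= cluster_tol
        ]
        for fpos, support, _ in cluster_positions(
            [a.span.five_prime for a in members], cluster_tol,
            min_support=min_isoform_support,
        ):
            out.append(IsoformCall(gene_name, fpos, tpos, support))
    out.sort(key=lambda c: (-c.support, c.five_prime))
    return out


def degradation_direction(gene_alignments, gene, end_tol: int = DEFAULT_END_TOL,
                          genome_length: int | None = None,
                          alpha: float = 0.05,
                          min_truncated: int = 10) -> str:
    """Dominant exonucleolytic degradation direction for one gene.

    5'-truncated reads witness 5'->3' degradation and vice versa; dominance
    is a one-sided binomial test at level *alpha* against p=0.5.
    """
    n5 = n3 = 0
    for aln in gene_alignments:
        try:
            state = classify_end_state(aln, gene, end_tol, genome_length)
        except ValueError:
            continue
        if state == "trunc5":
            n5 += 1
        elif state == "trunc3":
            n3 += 1
    n = n5 + n3
    if n < min_truncated:
        return "undetermined"
    p = binomtest(max(n5, n3), n, 0.5, alternative="greater").pvalue
    if p >= alpha:
        return "undetermined"
    return "five_to_three" if n5 > n3 else "three_to_five"
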