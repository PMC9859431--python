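"""Synthetic mitogenome, primary-transcript, and processed-read generator.

The generator emulates the study system's transcription/processing model so
every pipeline stage is testable offline:

* two nearly-genome-wide primary polycistrons launched from TIS positions in
  the control region — the plus (increasing-coordinate) primary initiates at
  15,377 and terminates at the trnS2/ND1 junction, the minus primary
  initiates at 15,189, crosses the origin and terminates at 15,406 in CR;
* tRNA-punctuation cleavage with a per-gene direction bias (an intermediate
  retains its upstream tRNA when the downstream tRNA was excised first);
* non-templated CCA on tRNA 3' ends followed by polyadenylation;
* 5'/3' exonucleolytic truncation with per-gene directional bias;
* antisense reads as opposite-strand primary-transcript fragments;
* a control region assembled from three tandem-repeat unit types with
  polymorphic sites and copy-number heterogeneity.

Truth alignments are emitted directly (no aligner is run), isolating
pipeline logic from mapping behaviour.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import fixtures
from .core_io import (
    MINUS,
    PLUS,
    GenomeSpan,
    MitoAnnotation,
    TranscriptAlignment,
    revcomp,
)

BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class PolymorphicSite:
    """A within-unit polymorphism: some copies carry *alt* instead of *ref*
    at *offset* (alleles may differ in length, e.g. G vs TTA)."""

    unit: str
    offset: int
    ref: str
    alt: str
    prob: float = 0.35


@dataclass
class RepeatArchitecture:
    """Block layout of a repeat region: unit lengths, ordered (unit, copies)
    blocks, one terminal partial unit, and polymorphic sites."""

    unit_lengths: dict[str, int] = field(
        default_factory=lambda: {"I": 19, "II": 18, "III": 37}
    )
    blocks: list[tuple[str, int]] = field(
        default_factory=lambda: [("I", 15), ("II", 10), ("III", 7)]
    )
    partial: tuple[str, int] | None = ("III", 35)
    polymorphic_sites: tuple[PolymorphicSite, ...] = (
        PolymorphicSite("I", 4, "C", "T"),      # CTA/TTA site
        PolymorphicSite("I", 11, "G", "TTA"),   # length-variant allele
        PolymorphicSite("III", 9, "T", "C"),
        PolymorphicSite("III", 22, "C", "T"),
    )

    def total_length(self) -> int:
        n = sum(self.unit_lengths[u] * c for u, c in self.blocks)
        if self.partial:
            n += self.partial[1]
        return n


#: Repeat block layout of CR lncRNA read no. 5243673.
LNCRNA_5243673_ARCHITECTURE = RepeatArchitecture(
    blocks=[("I", 17), ("II", 3), ("III", 2)], partial=("III", 33)
)

_DEFAULT_GENE_WEIGHTS = {
    # sense expression roughly follows the published ranking
    "lrRNA": 30.0, "COX2": 8.0, "srRNA": 6.0, "COX3": 5.0, "CYTB": 4.5,
    "ND1": 4.0, "COX1": 3.5, "ATP8/ATP6": 3.0, "ND5": 2.5, "ND2": 2.2,
    "ND6": 2.0, "ND4/ND4L": 1.8, "ND3": 1.5,
    # tRNAs individually low
    **{f"trn{x}": 0.4 for x in
       ["I", "Q", "M", "W", "C", "Y", "L2", "K", "D", "G", "A", "R", "N",
        "S1", "E", "F", "H", "T", "P", "S2", "L1", "V"]},
    # highly expressed antisense transcripts
    "asND6": 0.8, "asCYTB": 0.8, "asND5": 0.8, "asND2": 0.8, "asND4": 0.8,
    # CR lncRNAs, terminal antisense/CR fragments, rare full primaries
    "CR": 1.5, "cr_tail": 0.8, "primary": 0.2,
}


@dataclass
class SimConfig:
    """All tunable parameters of the generator (defaults = study conditions)."""

    seed: int = 0
    n_reads: int = 2000
    strand_weight: float = 0.65  # P(plus orientation)
    gene_weights: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_GENE_WEIGHTS)
    )
    cleave_prob: float = 0.85
    reverse_bias: dict[str, float] = field(
        default_factory=lambda: {"lrRNA": 0.15}
    )
    reverse_bias_default: float = 0.8
    cca_prob: float = 0.95
    polyA_geom_p: float = 0.2
    degrade_prob: float = 0.25
    degrade_dir_bias: dict[str, float] = field(
        default_factory=lambda: {"lrRNA": 0.9, "srRNA": 0.1}
    )
    degrade_dir_default: float = 0.5
    trunc_geom_p: float = 0.05
    subst_error_rate: float = 0.002
    tis_plus: int = fixtures.TIS_PLUS
    tis_minus: int = fixtures.TIS_MINUS
    tts_minus: int = fixtures.TTS_MINUS
    terminator_plus: tuple[str, str] = fixtures.TERMINATOR_PLUS
    repeat_architecture: RepeatArchitecture = field(
        default_factory=RepeatArchitecture
    )

    def validate(self) -> None:
        L = fixtures.GENOME_LENGTH
        for name in ("strand_weight", "cleave_prob", "cca_prob",
                     "polyA_geom_p", "degrade_prob", "trunc_geom_p",
                     "subst_error_rate", "reverse_bias_default",
                     "degrade_dir_default"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.polyA_geom_p == 0 or self.trunc_geom_p == 0:
            raise ValueError("geometric parameters must be positive")
        for name in ("tis_plus", "tis_minus", "tts_minus"):
            v = getattr(self, name)
            if not 1 <= v <= L:
                raise ValueError(f"{name}={v} outside genome")


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------

def _rna_to_dna(seq: str) -> str:
    return seq.upper().replace("U", "T")


def make_repeat_units(rng, unit_lengths: dict[str, int],
                      min_separation: int = 4) -> dict[str, str]:
    """Seeded random unit consensuses, pairwise edit distance > the default
    per-copy edit budget so types stay distinguishable."""
    import edlib

    units: dict[str, str] = {}
    for uid, length in unit_lengths.items():
        while True:
            cand = "".join(rng.choice(BASES, size=length))
            if all(
                edlib.align(cand, other, mode="NW")["editDistance"]
                > min_separation
                for other in units.values()
            ):
                units[uid] = cand
                break
    return units


def build_repeat_sequence(units: dict[str, str],
                          architecture: RepeatArchitecture,
                          rng=None,
                          apply_polymorphism: bool = False):
    """Concatenate unit copies per the architecture.

    Returns (sequence, truth) where truth records per-block copies and the
    polymorphic substitutions applied (reference alleles when
    ``apply_polymorphism`` is false).
    """
    pieces = []
    blocks = []
    sites_applied = []
    for uid, copies in architecture.blocks:
        cons = units[uid]
        for i in range(copies):
            copy = cons
            if apply_polymorphism and rng is not None:
                # per-copy edit budget: alternate alleles never push a copy
                # beyond the default per-copy decomposition tolerance
                budget = 3
                for site in architecture.polymorphic_sites:
                    cost = max(len(site.ref), len(site.alt))
                    if (site.unit == uid and cost <= budget
                            and rng.random() < site.prob):
                        copy = (
                            copy[: site.offset]
                            + site.alt
                            + copy[site.offset + len(site.ref):]
                        )
                        budget -= cost
                        sites_applied.append((uid, len(blocks), site.offset))
            pieces.append(copy)
            blocks.append((uid, copy))
    partial_seq = ""
    if architecture.partial:
        uid, plen = architecture.partial
        partial_seq = units[uid][:plen]
        pieces.append(partial_seq)
    truth = {
        "blocks": blocks,
        "partial": architecture.partial,
        "copy_counts": {
            uid: sum(c for u, c in architecture.blocks if u == uid)
            for uid in architecture.unit_lengths
        },
        "sites_applied": sites_applied,
    }
    return "".join(pieces), truth


def _write_transcribed(genome: list[str], span: GenomeSpan, seq_rna: str,
                       at_end: bool) -> None:
    """Write a transcript-orientation codon (RNA) into the plus-strand genome
    at the 5' (at_end=False) or 3' (True) edge of *span*."""
    dna = _rna_to_dna(seq_rna)
    k = len(dna)
    if span.orientation == PLUS:
        start = span.end - k + 1 if at_end else span.start
        genome[start - 1: start - 1 + k] = list(dna)
    else:
        # transcript reads revcomp(genome[start..end]); its 5' edge sits at
        # span.end, its 3' edge at span.start
        start = span.start if at_end else span.end - k + 1
        genome[start - 1: start - 1 + k] = list(revcomp(dna))


def simulate_genome(config: SimConfig | None = None, rng=None):
    """Seeded random mitogenome honouring the packaged annotation's codons
    and control-region repeat architecture.

    Returns (genome string, refined annotation with CR, repeat truth dict).
    """
    config = config or SimConfig()
    config.validate()
    rng = rng or np.random.default_rng(config.seed)
    L = fixtures.GENOME_LENGTH
    genome = list(rng.choice(BASES, size=L))

    dna_ann = fixtures.dna_annotation()
    ref_ann = fixtures.refined_annotation()
    for ann in (dna_ann, ref_ann):  # refined written last wins conflicts
        for f in ann.genes():
            if f.category != "PCG":
                continue
            if f.start_codon:
                _write_transcribed(genome, f.span, f.start_codon, at_end=False)
            if f.stop_codon:
                # incomplete stops (U / UA) are written as-is: the missing
                # A's are added by polyadenylation, not encoded
                _write_transcribed(genome, f.span, f.stop_codon, at_end=True)

    arch = config.repeat_architecture
    units = make_repeat_units(rng, arch.unit_lengths)
    repeat_seq, truth = build_repeat_sequence(units, arch)
    cr = ref_ann.get("CR").span
    repeat_start = cr.end - len(repeat_seq) + 1
    genome[repeat_start - 1: cr.end] = list(repeat_seq)
    truth.update(units=units, repeat_start=repeat_start,
                 architecture=arch)
    seq = "".join(genome)
    ref_ann.sequence = seq
    return seq, ref_ann, truth


# ---------------------------------------------------------------------------
# primary transcripts and read units
# ---------------------------------------------------------------------------

@dataclass
class SimUnit:
    name: str  # weight key; "asX" for antisense, "ATP8/ATP6" for bicistrons
    kind: str  # mRNA | rRNA | tRNA | antisense | CR | primary
    genes: tuple[str, ...]
    a: int  # 5' offset on the primary path
    b: int  # 3' offset (inclusive)
    up_trna: str | None = None
    down_trna: str | None = None


def _span_from_path(path: np.ndarray, a: int, b: int,
                    orientation: str) -> GenomeSpan:
    c5, c3 = int(path[a]), int(path[b])
    if orientation == PLUS:
        return GenomeSpan(c5, c3, PLUS, wraps=c5 > c3)
    return GenomeSpan(c3, c5, MINUS, wraps=c3 > c5)


def primary_path(annotation: MitoAnnotation, config: SimConfig,
                 orientation: str) -> np.ndarray:
    """Genome coordinates of the primary transcript, 5'->3'."""
    L = annotation.genome_length
    if orientation == PLUS:
        start = config.tis_plus
        end = annotation.get(config.terminator_plus[0]).span.three_prime
        span = GenomeSpan(start, end, PLUS, wraps=start > end)
    else:
        start = config.tis_minus
        end = config.tts_minus
        span = GenomeSpan(end, start, MINUS, wraps=end > start)
    return span.path(L)


def unit_catalog(annotation: MitoAnnotation, config: SimConfig,
                 orientation: str, path: np.ndarray) -> list[SimUnit]:
    offset = {int(p): i for i, p in enumerate(path)}
    sense_order = [
        f for f in annotation.transcription_order(orientation)
        if f.orientation == orientation and f.category != "CR"
    ]
    on_path = [
        f for f in sense_order
        if f.span.five_prime in offset and f.span.three_prime in offset
    ]
    names_on = [f.name for f in on_path]

    def flank(idx: int, step: int) -> str | None:
        j = idx + step
        if 0 <= j < len(on_path) and on_path[j].category == "tRNA":
            return on_path[j].name
        return None

    pair_of = {a: b for a, b in fixtures.BICISTRON_PAIRS}
    pair_of.update({b: a for a, b in fixtures.BICISTRON_PAIRS})
    done: set[str] = set()
    units: list[SimUnit] = []
    for i, f in enumerate(on_path):
        if f.name in done:
            continue
        if f.name in pair_of and pair_of[f.name] in names_on:
            # bicistron: f is the transcriptionally first member here
            other = annotation.get(pair_of[f.name])
            done.add(other.name)
            name = "/".join(sorted((f.name, other.name),
                                   key=lambda n: n != f.name))
            a = offset[f.span.five_prime]
            b = offset[other.span.three_prime]
            j = names_on.index(other.name)
            units.append(
                SimUnit(name, "mRNA", (f.name, other.name), a, b,
                        up_trna=flank(i, -1), down_trna=flank(j, +1))
            )
            continue
        kind = {"PCG": "mRNA", "rRNA": "rRNA", "tRNA": "tRNA"}[f.category]
        units.append(
            SimUnit(f.name, kind, (f.name,),
                    offset[f.span.five_prime], offset[f.span.three_prime],
                    up_trna=flank(i, -1), down_trna=flank(i, +1))
        )
    # antisense units: opposite-strand genes inside the path
    for f in annotation.genes():
        if f.orientation == orientation:
            continue
        if f.span.five_prime in offset and f.span.three_prime in offset:
            a = offset[f.span.three_prime]  # gene 3' is the fragment 5' here
            b = offset[f.span.five_prime]
            units.append(SimUnit("as" + f.name, "antisense", (f.name,),
                                 min(a, b), max(a, b)))
    # terminal fragment: from the last same-orientation gene junction to the
    # path end; when the primary terminates inside the CR this is the
    # antisense/CR read that witnesses the termination site (its 5' end lies
    # outside the CR, its 3' end at the TTS)
    cr = annotation.get("CR").span if "CR" in annotation else None
    if cr is not None and cr.contains(int(path[-1]), annotation.genome_length):
        last3 = max(
            (offset[f.span.three_prime] for f in on_path
             if f.span.three_prime in offset),
            default=None,
        )
        if last3 is not None and last3 + 40 < len(path) - 1:
            units.append(
                SimUnit("cr_tail", "CR_tail", (), last3 + 1, len(path) - 1)
            )
    units.append(SimUnit("primary", "primary", (), 0, len(path) - 1))
    return units


# ---------------------------------------------------------------------------
# reads
# ---------------------------------------------------------------------------

@dataclass
class SimRead:
    alignment: TranscriptAlignment
    truth: dict


def _strand_seq(genome: str, span: GenomeSpan) -> str:
    if span.wraps:
        s = genome[span.start - 1:] + genome[: span.end]
    else:
        s = genome[span.start - 1: span.end]
    return s if span.orientation == PLUS else revcomp(s)


def simulate_reads(genome: str, annotation: MitoAnnotation,
                   config: SimConfig | None = None, rng=None
                   ) -> tuple[list[TranscriptAlignment], pd.DataFrame, dict]:
    """Draw processed reads from the two primary transcripts.

    Returns (alignments, truth table, read sequences dict).  Alignments are
    emitted as truth; read sequences include tails and substitution errors.
    """
    config = config or SimConfig()
    config.validate()
    rng = rng or np.random.default_rng(config.seed + 1)
    L = annotation.genome_length
    cr = annotation.get("CR").span

    catalogs = {}
    for orientation in (PLUS, MINUS):
        path = primary_path(annotation, config, orientation)
        units = unit_catalog(annotation, config, orientation, path)
        # the CR lncRNA unit: from the TIS into the CR
        weights = np.array(
            [config.gene_weights.get(u.name, 0.1) for u in units]
            + [config.gene_weights.get("CR", 1.0)]
        )
        catalogs[orientation] = (path, units, weights / weights.sum())

    alignments: list[TranscriptAlignment] = []
    rows = []
    seqs: dict[str, str] = {}
    trna_names = {f.name for f in annotation.genes() if f.category == "tRNA"}

    for i in range(config.n_reads):
        orientation = PLUS if rng.random() < config.strand_weight else MINUS
        path, units, probs = catalogs[orientation]
        k = rng.choice(len(units) + 1, p=probs)
        read_id = f"sim{i:06d}"

        if k == len(units):  # CR lncRNA
            unit_name, kind, genes = "CR", "CR", ("CR",)
            state = "lncRNA"
            a = 0
            cr_len_on_path = int(
                np.sum([cr.contains(int(p), L) for p in path[:2000]])
            )
            b = int(rng.integers(40, max(41, cr_len_on_path)))
            up = down = None
        else:
            u = units[k]
            unit_name, kind, genes = u.name, u.kind, u.genes
            a, b, up, down = u.a, u.b, u.up_trna, u.down_trna
            state = "mature"
            if kind in ("mRNA", "rRNA") and (up or down):
                c = config.cleave_prob
                r = rng.random()
                bias = config.reverse_bias.get(
                    unit_name, config.reverse_bias_default
                )
                if r < c * c or (up is None and down is None):
                    state = "mature"
                elif r < c * c + (1 - c) * (1 - c) and up and down:
                    state = "precursor"
                else:
                    retain_up = rng.random() < bias
                    if retain_up and up:
                        state = "intermediate_rev"
                    elif down:
                        state = "intermediate_fwd"
                    elif up:
                        state = "intermediate_rev"
                if state in ("precursor", "intermediate_rev") and up:
                    a = _unit_bound(units, up, "a")
                if state in ("precursor", "intermediate_fwd") and down:
                    b = _unit_bound(units, down, "b")
            elif kind == "primary":
                state = "primary"

        # exonucleolytic truncation: acts on end-state products (mature
        # RNAs, antisense fragments, lncRNAs), capped below the unit-coverage
        # threshold so the covered-unit identity of the read is preserved
        trunc_end, trunc_len = "none", 0
        frag_len = b - a + 1
        if state in ("mature", "lncRNA") and kind != "primary" \
                and rng.random() < config.degrade_prob:
            bias = config.degrade_dir_bias.get(
                genes[0] if genes else unit_name, config.degrade_dir_default
            )
            trunc_end = "5" if rng.random() < bias else "3"
            trunc_len = int(min(rng.geometric(config.trunc_geom_p),
                                max(0, int(0.4 * frag_len))))
            if trunc_len <= 0:
                trunc_end = "none"
            elif trunc_end == "5":
                a += trunc_len
            else:
                b -= trunc_len

        span = _span_from_path(path, a, b, orientation)

        # 3' tail chemistry (suppressed on 3'-truncated reads)
        cca = False
        polyA_len = 0
        if trunc_end != "3":
            if kind == "tRNA" and state == "mature":
                cca = bool(rng.random() < config.cca_prob)
            if kind in ("mRNA", "rRNA", "tRNA", "CR") and state in (
                "mature", "intermediate_rev", "lncRNA"
            ):
                polyA_len = int(rng.geometric(config.polyA_geom_p))
        tail3 = ("CCA" if cca else "") + "A" * polyA_len

        body = _strand_seq(genome, span)
        n_err = rng.binomial(len(body), config.subst_error_rate)
        if n_err:
            body_arr = np.array(list(body))
            pos = rng.choice(len(body), size=n_err, replace=False)
            for p in pos:
                choices = [c for c in "ACGT" if c != body_arr[p]]
                body_arr[p] = choices[rng.integers(3)]
            body = "".join(body_arr)
        identity = 1.0 - n_err / max(1, len(body))

        aln = TranscriptAlignment(read_id, orientation, span,
                                  tail5="", tail3=tail3, identity=identity)
        alignments.append(aln)
        seqs[read_id] = body + tail3
        rows.append(
            {
                "read_id": read_id,
                "orientation": orientation,
                "unit": unit_name,
                "kind": kind,
                "state": state,
                "start": span.start,
                "end": span.end,
                "wraps": span.wraps,
                "trunc_end": trunc_end,
                "trunc_len": trunc_len,
                "cca": cca,
                "polyA_len": polyA_len,
                "class_label": _class_label(kind, state, trunc_end, unit_name),
            }
        )
    truth = pd.DataFrame(rows)
    return alignments, truth, seqs


def _unit_bound(units: list[SimUnit], name: str, side: str) -> int:
    for u in units:
        if u.name == name:
            return u.a if side == "a" else u.b
    raise KeyError(name)


def _class_label(kind, state, trunc_end, unit_name) -> str:
    if kind in ("CR", "CR_tail"):
        return "lncRNA_CR"
    if kind == "primary":
        # the full primary initiates inside the CR, so its 5' end marks it
        # as a CR transcript under the classification precedence
        return "lncRNA_CR"
    if kind == "antisense":
        return "antisense"
    if state in ("precursor", "intermediate_rev", "intermediate_fwd"):
        return "precursor_polycistron"
    if "/" in unit_name:
        return "mature_bicistron"
    return "mature_mono"


# ---------------------------------------------------------------------------
# deterministic tRNA fixture
# ---------------------------------------------------------------------------

#: Nine tRNA genes contributing reads: seven plus-coded, two minus-coded.
FIXTURE_TRNA_GENES = ("trnM", "trnW", "trnL2", "trnK", "trnD", "trnG",
                      "trnS2", "trnQ", "trnC")


def make_fixture_trnas(seed: int = 0, annotation: MitoAnnotation | None = None
                       ) -> tuple[list[TranscriptAlignment], pd.DataFrame]:
    """Deterministic 26-read tRNA set mirroring the published end-state
    composition: 21 reads on plus-coded and 5 on minus-coded tRNA genes;
    15 complete, 11 incomplete of which 10 lack 5' sequence and exactly one
    is 3'-degraded with loss of its CCA."""
    ann = annotation or fixtures.refined_annotation()
    rng = np.random.default_rng(seed)
    plus_genes = [g for g in FIXTURE_TRNA_GENES
                  if ann.get(g).orientation == PLUS]
    minus_genes = [g for g in FIXTURE_TRNA_GENES
                   if ann.get(g).orientation == MINUS]
    assignments = [plus_genes[i % len(plus_genes)] for i in range(21)]
    assignments += [minus_genes[i % len(minus_genes)] for i in range(5)]
    # end states: 15 complete, 10 trunc5, 1 trunc3 (spread across both strands)
    states = ["complete"] * 15 + ["trunc5"] * 10 + ["trunc3"]
    order = rng.permutation(26)
    alignments = []
    rows = []
    for i, (gene_name, state) in enumerate(
        zip(assignments, [states[j] for j in order])
    ):
        gene = ann.get(gene_name)
        span = gene.span
        glen = span.end - span.start + 1
        cca, polyA = True, int(rng.integers(5, 15))
        if state == "trunc5":
            cut = int(rng.integers(5, min(30, glen - 10)))
            span = (replace(span, start=span.start + cut)
                    if gene.orientation == PLUS
                    else replace(span, end=span.end - cut))
        elif state == "trunc3":
            cut = int(rng.integers(4, 12))
            span = (replace(span, end=span.end - cut)
                    if gene.orientation == PLUS
                    else replace(span, start=span.start + cut))
            cca, polyA = False, 0  # 3' degradation removed the CCA
        tail3 = ("CCA" if cca else "") + "A" * polyA
        aln = TranscriptAlignment(f"trna{i:03d}", gene.orientation, span,
                                  tail5="", tail3=tail3)
        alignments.append(aln)
        rows.append(
            {"read_id": aln.read_id, "gene": gene_name,
             "orientation": gene.orientation, "state": state,
             "cca": cca, "polyA_len": polyA}
        )
    return alignments, pd.DataFrame(rows)
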