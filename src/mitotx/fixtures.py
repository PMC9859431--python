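"""Packaged reference data for the *Coridius chinensis* mitogenome study system.

The gene tables mirror the published annotation of the 16,214 bp
*C. chinensis* mitogenome (GenBank OP921229): one column set from DNA
sequence features alone, one refined against full-length transcripts.
``CR_TRANSCRIPTS`` is the published set of control-region-proximal
transcripts used for transcription initiation/termination inference;
coordinates printed in the study are used verbatim, the remaining members
(described only as a group) carry representative coordinates consistent
with that description and are marked ``representative=True``.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

from .core_io import (
    MINUS,
    PLUS,
    GenomeSpan,
    MitoAnnotation,
    TranscriptAlignment,
    load_annotation,
)

GENOME_LENGTH = 16_214

#: Read support for the refined srRNA 5' boundary at 14,661.
SRRNA_5P_SUPPORT = 273
SRRNA_5P_POSITION = 14_661

#: Planted/inferred transcription landmarks (see boundaries module).
TIS_PLUS = 15_377
TIS_MINUS = 15_189
TTS_MINUS = 15_406
TERMINATOR_PLUS = ("trnS2", "ND1")

#: Start of the CR tandem-repeat region as published (fixture metadata only;
#: the repeat finder never assumes it).
REPEAT_REGION_START = 15_464

#: Mature bicistronic mRNAs; all other mature mRNAs are monocistronic.
BICISTRON_PAIRS = (("ATP8", "ATP6"), ("ND4", "ND4L"))

#: lrRNA isoform spans (shared 3' end, heterogeneous 5' ends).
LRRNA_ISOFORMS = ((13_687, 12_501), (13_498, 12_501), (13_484, 12_501))


def _load(name: str) -> MitoAnnotation:
    with resources.as_file(resources.files("mitotx.data") / name) as p:
        return load_annotation(p, genome_length=GENOME_LENGTH)


def dna_annotation() -> MitoAnnotation:
    """Annotation from DNA sequence features alone (pre-refinement)."""
    return _load("table1_dna.tsv")


def refined_annotation() -> MitoAnnotation:
    """Annotation refined against full-length transcripts."""
    return _load("table1_refined.tsv")


@dataclass(frozen=True)
class CRTranscript:
    """One CR-proximal transcript: published read number (or a label),
    5'/3' end coordinates, orientation, and origin-crossing flag."""

    label: str
    five_prime: int
    three_prime: int
    orientation: str
    wraps: bool = False
    representative: bool = False

    def to_alignment(self) -> TranscriptAlignment:
        if self.orientation == PLUS:
            start, end = self.five_prime, self.three_prime
        else:
            start, end = self.three_prime, self.five_prime
        return TranscriptAlignment(
            read_id=self.label,
            orientation=self.orientation,
            span=GenomeSpan(start, end, self.orientation, wraps=self.wraps),
        )


#: The 14 CR-concentrated transcripts: four launched in the plus
#: (increasing-coordinate) direction, ten in the minus direction.
CR_TRANSCRIPTS = (
    # plus-direction: two lncRNAs sharing the 15,377 start, and the
    # incomplete polycistrons CR/trnI (15,378-45) and
    # CR/trnI/astrnQ/trnM/ND2 (15,379-408), both crossing the origin.
    CRTranscript("5243673", 15_377, 16_100, PLUS, representative=True),
    CRTranscript("95946640", 15_377, 15_900, PLUS, representative=True),
    CRTranscript("119408095", 15_378, 45, PLUS, wraps=True),
    CRTranscript("127142199", 15_379, 408, PLUS, wraps=True),
    # minus-direction: astrnI/CR crossing the origin with its 3' end at
    # 15,406 in CR; two transcripts initiated at 15,189; five concentrated
    # in CR and four reaching srRNA, all other 5' ends downstream of 15,189.
    CRTranscript("90702191", 72, 15_406, MINUS, wraps=True),
    CRTranscript("97583892", 15_189, 14_901, MINUS),
    CRTranscript("138412294", 15_189, 12_846, MINUS),
    CRTranscript("cr_only_1", 15_150, 14_800, MINUS, representative=True),
    CRTranscript("cr_only_2", 15_050, 14_750, MINUS, representative=True),
    CRTranscript("cr_only_3", 14_980, 14_700, MINUS, representative=True),
    CRTranscript("cr_only_4", 14_900, 14_680, MINUS, representative=True),
    CRTranscript("srrna_cr_1", 15_120, 13_900, MINUS, representative=True),
    CRTranscript("srrna_cr_2", 15_000, 13_850, MINUS, representative=True),
    CRTranscript("srrna_cr_3", 14_950, 13_870, MINUS, representative=True),
)


def cr_alignments(orientation: str | None = None) -> list[TranscriptAlignment]:
    """CR-proximal transcript set as alignments, optionally one orientation."""
    return [
        t.to_alignment()
        for t in CR_TRANSCRIPTS
        if orientation is None or t.orientation == orientation
    ]
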