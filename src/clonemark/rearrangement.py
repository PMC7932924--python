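"""Rearrangement records, junction translation, productivity and identity.

A :class:`Rearrangement` describes one annotated junction: the class, the
two germline genes, the junctional segmentation statistics (bases trimmed
from the 5' gene, inserted N-(D)-N length, bases trimmed from the 3' gene),
the junction nucleotide and amino-acid sequence, a functional status, and a
de-duplicated abundance.  The 7-component :class:`IdentityKey` — class,
5' gene, the three segmentation statistics, 3' gene and junction amino
acids — is what defines "the same rearrangement" for de-duplication,
cross-case uniqueness filtering and cross-platform marker matching.

Functional status follows the usual clonality-analysis conventions:

* ``productive`` — complete V-J joint, reading frame preserved between the
  V and J frame anchors, no stop codon in the junction;
* ``unproductive`` — complete joint that is out of frame or contains a
  stop, or an incomplete D-J joint with a stop in the J frame;
* ``potentially_productive`` — incomplete D-J joint whose junction is
  stop-free in the J reading frame (it could become productive upon
  completion to a V-D-J joint);
* ``unknown`` — V-D and "other" classes (including the non-coding Kde and
  intronRSS joints) and any *damaged* record, i.e. one whose junction was
  only partially covered by read sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

from Bio.Seq import Seq

from .classes import (
    COMPLETE_VJ,
    INCOMPLETE_DJ,
    INCOMPLETE_VD,
    OTHER,
    JunctionClass,
)

PRODUCTIVE = "productive"
POTENTIALLY_PRODUCTIVE = "potentially_productive"
UNPRODUCTIVE = "unproductive"
UNKNOWN = "unknown"
PRODUCTIVITY_STATES = (PRODUCTIVE, POTENTIALLY_PRODUCTIVE, UNPRODUCTIVE, UNKNOWN)

#: sanity ceiling on per-field segmentation statistics
MAX_SEGMENTATION = 1000

_ACGT = frozenset("ACGT")


class FrameError(ValueError):
    """Frame information required but unavailable."""


def translate_junction(junction_nt: str, frame_offset: int) -> str:
    """Translate `junction_nt` from `frame_offset` with the standard code.

    Stop codons render as ``*``; a trailing partial codon is dropped.
    """
    if not 0 <= frame_offset <= 2:
        raise ValueError(f"frame_offset {frame_offset} outside [0, 2]")
    if not set(junction_nt) <= _ACGT:
        raise ValueError("junction contains non-ACGT characters")
    sub = junction_nt[frame_offset:]
    sub = sub[: len(sub) - len(sub) % 3]
    if not sub:
        return ""
    return str(Seq(sub).translate())


class IdentityKey(NamedTuple):
    """The tuple that defines rearrangement identity.

    Components of a damaged record that its read coverage did not determine
    are ``None``; such keys are *partial* and only match under the
    permissive concordance mode.
    """

    junction_class: str
    five_gene: str
    five_del: int | None
    ndn_length: int | None
    three_del: int | None
    three_gene: str
    junction_aa: str

    @property
    def is_partial(self) -> bool:
        return None in (self.five_del, self.ndn_length, self.three_del)


@dataclass
class Rearrangement:
    """One annotated IG/TR junction."""

    junction_class: JunctionClass
    five_gene: str
    three_gene: str
    five_del: int | None
    ndn_length: int | None
    three_del: int | None
    junction_nt: str = ""
    junction_aa: str = ""
    in_frame: bool | None = None
    productivity: str = UNKNOWN
    damaged: bool = False
    count: int = 1

    def __post_init__(self):
        for label, value in (("five_del", self.five_del),
                             ("ndn_length", self.ndn_length),
                             ("three_del", self.three_del)):
            if value is not None and not 0 <= value <= MAX_SEGMENTATION:
                raise ValueError(f"{label}={value} outside [0, {MAX_SEGMENTATION}]")
        if self.count < 1:
            raise ValueError("count must be >= 1")
        if self.damaged and (self.junction_aa or self.productivity != UNKNOWN):
            raise ValueError("damaged records carry no junction_aa and "
                             "unknown productivity")


def determine_productivity(r: Rearrangement) -> str:
    """Functional status of a rearrangement (see module docstring).

    For complete V-J classes the frame verdict must already be recorded on
    the record (``in_frame``); it is derived from the V and J frame anchors
    at annotation time.
    """
    if r.damaged:
        return UNKNOWN
    category = r.junction_class.category
    if category in (OTHER, INCOMPLETE_VD):
        return UNKNOWN
    if category == COMPLETE_VJ:
        if r.in_frame is None:
            raise FrameError(
                f"{r.junction_class.label}: complete V-J record lacks a frame verdict"
            )
        if r.in_frame and "*" not in r.junction_aa:
            return PRODUCTIVE
        return UNPRODUCTIVE
    if category == INCOMPLETE_DJ:
        if "*" not in r.junction_aa:
            return POTENTIALLY_PRODUCTIVE
        return UNPRODUCTIVE
    raise ValueError(f"unknown category {category!r}")  # pragma: no cover


def identity_key(r: Rearrangement) -> IdentityKey:
    """The 7-component identity key of a rearrangement."""
    return IdentityKey(
        r.junction_class.label,
        r.five_gene,
        r.five_del,
        r.ndn_length,
        r.three_del,
        r.three_gene,
        r.junction_aa,
    )


def junction_window(v_end: int, j_start: int, v_frame_phase: int | None,
                    flank_codons: int = 3) -> tuple[int, int]:
    """Junction window boundaries around a resolved joint.

    The window runs from `flank_codons` codons upstream of the last 5'-gene
    base through `flank_codons` codons downstream of the first 3'-gene
    base.  For joints whose 5' element is a V gene the start is shifted
    down to a codon boundary of the V reading frame (``v_frame_phase`` is
    the phase, mod 3, of the V frame anchor in the same coordinate system)
    and the end is padded up to a codon boundary, so that translating the
    window at offset 0 reads the V frame.  Coordinates may fall outside the
    available sequence; the caller treats that as partial junction
    coverage.
    """
    ws = v_end - 3 * flank_codons
    we = j_start + 3 * flank_codons
    if v_frame_phase is not None:
        ws -= (ws - v_frame_phase) % 3
        we = ws + -(-(we - ws) // 3) * 3
    return ws, we
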