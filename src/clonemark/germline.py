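"""Germline segment reference for the seven IG/TR loci.

The reference holds every germline element rearrangements are built from:
V, D and J gene segments plus the two non-coding IGK elements involved in
kappa-locus inactivation (the kappa-deleting element Kde and the intronic
recombination signal sequence).  V and J segments carry an explicit
``frame_anchor`` — the 0-based offset of the first base of the reference
reading frame — used for frame and stop-codon analysis of junctions.

References are exchanged as FASTA with structured headers::

    >name|locus|segment_type[|frame_anchor]

``frame_anchor`` is present for V and J records only.
"""

from __future__ import annotations

import io as _io
import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO

from .classes import D, INTRON_RSS, J, KDE, LOCI, SEGMENT_TYPES, V

_ACGT = frozenset("ACGT")

#: codons of the standard genetic code that do not encode a stop
_NON_STOP_CODONS = tuple(
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
)


class GermlineFormatError(ValueError):
    """Malformed or inconsistent germline reference input."""


@dataclass(frozen=True)
class GeneSegment:
    """One germline element (V/D/J gene or IGK Kde/intronRSS)."""

    name: str
    locus: str
    segment_type: str
    sequence: str
    frame_anchor: int | None = None

    def __post_init__(self):
        if self.locus not in LOCI:
            raise GermlineFormatError(f"{self.name}: unknown locus {self.locus!r}")
        if self.segment_type not in SEGMENT_TYPES:
            raise GermlineFormatError(
                f"{self.name}: unknown segment type {self.segment_type!r}"
            )
        if not self.sequence:
            raise GermlineFormatError(f"{self.name}: empty sequence")
        if self.sequence != self.sequence.upper():
            raise GermlineFormatError(f"{self.name}: sequence must be uppercase")
        if self.segment_type in (V, J):
            if self.frame_anchor is None:
                raise GermlineFormatError(
                    f"{self.name}: {self.segment_type} segment needs a frame_anchor"
                )
            if not 0 <= self.frame_anchor <= 2:
                raise GermlineFormatError(
                    f"{self.name}: frame_anchor {self.frame_anchor} outside [0, 2]"
                )
        elif self.frame_anchor is not None:
            raise GermlineFormatError(
                f"{self.name}: frame_anchor not allowed for {self.segment_type}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)

    def header(self) -> str:
        parts = [self.name, self.locus, self.segment_type]
        if self.frame_anchor is not None:
            parts.append(str(self.frame_anchor))
        return "|".join(parts)


@dataclass
class GermlineReference:
    """Validated collection of germline segments, addressable by name."""

    segments: dict[str, GeneSegment] = field(default_factory=dict)

    def add(self, seg: GeneSegment) -> None:
        if seg.name in self.segments:
            raise GermlineFormatError(f"duplicate segment name {seg.name!r}")
        self.segments[seg.name] = seg

    def __getitem__(self, name: str) -> GeneSegment:
        return self.segments[name]

    def __contains__(self, name: str) -> bool:
        return name in self.segments

    def __len__(self) -> int:
        return len(self.segments)

    def __eq__(self, other) -> bool:
        return isinstance(other, GermlineReference) and self.segments == other.segments

    @property
    def loci_present(self) -> frozenset[str]:
        return frozenset(s.locus for s in self.segments.values())

    def select(self, locus: str | None = None, segment_type: str | None = None,
               name_prefix: str | None = None) -> list[GeneSegment]:
        """Segments filtered by locus / type / name prefix, in insertion order."""
        out = []
        for seg in self.segments.values():
            if locus is not None and seg.locus != locus:
                continue
            if segment_type is not None and seg.segment_type != segment_type:
                continue
            if name_prefix is not None and not seg.name.startswith(name_prefix):
                continue
            out.append(seg)
        return out

    def validate(self) -> None:
        if not self.segments:
            raise GermlineFormatError("reference contains no segments")
        for locus in self.loci_present:
            if not self.select(locus=locus):  # pragma: no cover - unreachable
                raise GermlineFormatError(f"locus {locus} declared but empty")

    def to_fasta(self) -> str:
        lines = []
        for seg in self.segments.values():
            lines.append(">" + seg.header())
            seq = seg.sequence
            for i in range(0, len(seq), 60):
                lines.append(seq[i:i + 60])
        return "\n".join(lines) + "\n"

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_fasta())


def _parse_header(header: str) -> tuple[str, str, str, int | None]:
    parts = header.split("|")
    if len(parts) not in (3, 4):
        raise GermlineFormatError(
            f"malformed header {header!r}: expected name|locus|type[|frame_anchor]"
        )
    name, locus, segment_type = parts[:3]
    anchor: int | None = None
    if len(parts) == 4:
        try:
            anchor = int(parts[3])
        except ValueError:
            raise GermlineFormatError(
                f"malformed header {header!r}: frame_anchor must be an integer"
            ) from None
    return name, locus, segment_type, anchor


def load_germline_reference(fasta_path, strict: bool = True) -> GermlineReference:
    """Load and validate a germline reference FASTA.

    In strict mode any record with non-ACGT characters raises; in lenient
    mode such records are skipped with a warning.  Duplicate names and
    malformed headers always raise.
    """
    ref = GermlineReference()
    with open(fasta_path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            header = rec.description or rec.id
            name, locus, segment_type, anchor = _parse_header(header)
            seq = str(rec.seq).upper()
            if not set(seq) <= _ACGT:
                if strict:
                    raise GermlineFormatError(
                        f"{name}: sequence contains non-ACGT characters"
                    )
                warnings.warn(f"skipping {name}: non-ACGT characters", stacklevel=2)
                continue
            ref.add(GeneSegment(name, locus, segment_type, seq, anchor))
    ref.validate()
    return ref


def load_germline_reference_string(text: str, strict: bool = True) -> GermlineReference:
    """As :func:`load_germline_reference`, from an in-memory FASTA string."""
    ref = GermlineReference()
    for rec in SeqIO.parse(_io.StringIO(text), "fasta"):
        name, locus, segment_type, anchor = _parse_header(rec.description or rec.id)
        seq = str(rec.seq).upper()
        if not set(seq) <= _ACGT:
            if strict:
                raise GermlineFormatError(f"{name}: sequence contains non-ACGT characters")
            warnings.warn(f"skipping {name}: non-ACGT characters", stacklevel=2)
            continue
        ref.add(GeneSegment(name, locus, segment_type, seq, anchor))
    ref.validate()
    return ref


def _random_coding(rng: np.random.Generator, length: int, anchor: int) -> str:
    """Random sequence of `length` nt that is stop-free in the frame starting
    at `anchor`; bases outside complete in-frame codons are unconstrained."""
    head = "".join(rng.choice(list("ACGT"), size=anchor)) if anchor else ""
    n_codons = (length - anchor) // 3
    body = "".join(rng.choice(_NON_STOP_CODONS, size=n_codons))
    tail_len = length - anchor - 3 * n_codons
    tail = "".join(rng.choice(list("ACGT"), size=tail_len)) if tail_len else ""
    return head + body + tail


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


def build_toy_reference(rng_seed: int, segments_per_type: int = 3) -> GermlineReference:
    """Deterministic synthetic germline reference covering all seven loci.

    V segments are 250-300 nt, D segments 16-30 nt, J segments 40-60 nt;
    IGK additionally carries a Kde element and one intronRSS element.  V and
    J bodies are generated stop-free in their anchored reading frame, so any
    stop codon in a simulated rearrangement necessarily involves junctional
    sequence.  TRD D segments are fixed to the named pair TRDD2/TRDD3 (the
    two that participate in D-gene-specific classes) and TRB always gets at
    least two D genes so that D-D joints are constructible.  Same seed,
    same reference, byte-identical FASTA.
    """
    if segments_per_type < 1:
        raise ValueError("segments_per_type must be >= 1")
    rng = np.random.default_rng(rng_seed)
    ref = GermlineReference()
    d_loci = {"IGH", "TRB", "TRD"}
    for locus in LOCI:
        for i in range(segments_per_type):
            anchor = int(rng.integers(0, 3))
            length = int(rng.integers(250, 301))
            ref.add(GeneSegment(f"{locus}V{i + 1}-1", locus, V,
                                _random_coding(rng, length, anchor), anchor))
        if locus in d_loci:
            if locus == "TRD":
                d_names = ["TRDD2", "TRDD3"]
            else:
                d_names = [f"{locus}D{i + 1}"
                           for i in range(max(2, segments_per_type))]
            for name in d_names:
                length = int(rng.integers(16, 31))
                ref.add(GeneSegment(name, locus, D, _random_seq(rng, length)))
        for i in range(segments_per_type):
            anchor = int(rng.integers(0, 3))
            length = int(rng.integers(40, 61))
            # TRD J genes are all J1-family so Dd2-Jd1 joints stay in-taxonomy
            name = f"TRDJ1-{i + 1}" if locus == "TRD" else f"{locus}J{i + 1}"
            ref.add(GeneSegment(name, locus, J,
                                _random_coding(rng, length, anchor), anchor))
    ref.add(GeneSegment("Kde", "IGK", KDE, _random_seq(rng, 60)))
    ref.add(GeneSegment("intronRSS", "IGK", INTRON_RSS, _random_seq(rng, 40)))
    ref.validate()
    return ref
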