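"""Protospacer coordinate system and edit calls.

All positions in this package are 1-based protospacer coordinates on the
protospacer strand: position 1 is the 5' end of the 20-nt protospacer, the
PAM occupies positions 21-23, and bases 5' of the protospacer carry negative
coordinates with -1 immediately adjacent to +1 (there is no position 0).
Every caller that touches an amplicon goes through :class:`ProtospacerSpec`
so the strand convention lives in exactly one place.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
VALID_BASES = frozenset("ACGTN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class CoordinateError(ValueError):
    """A protospacer coordinate or segment is out of range."""


@dataclass(frozen=True)
class ProtospacerSpec:
    """An amplicon reference with a located protospacer and PAM.

    Parameters
    ----------
    reference:
        The amplicon sequence as sequenced (A/C/G/T/N).
    protospacer_offset:
        0-based index of protospacer position 1 *on the protospacer strand*
        (i.e. on ``reference`` itself for forward-strand specs, and on the
        reverse complement of ``reference`` for reverse-strand specs).
    strand:
        ``"forward"`` or ``"reverse"`` -- orientation of the protospacer
        relative to the reference.
    pam:
        The 3-nt PAM, occupying protospacer positions 21-23.
    """

    reference: str
    protospacer_offset: int
    strand: str = "forward"
    protospacer_length: int = 20
    pam: str = ""

    def __post_init__(self) -> None:
        ref = self.reference.upper()
        object.__setattr__(self, "reference", ref)
        object.__setattr__(self, "pam", self.pam.upper())
        if self.strand not in ("forward", "reverse"):
            raise ValueError(f"strand must be forward/reverse, got {self.strand!r}")
        if set(ref) - VALID_BASES:
            bad = sorted(set(ref) - VALID_BASES)
            raise ValueError(f"reference contains non-ACGTN characters: {bad}")
        if self.protospacer_offset < 0:
            raise CoordinateError("protospacer_offset must be >= 0")
        if self.protospacer_offset + self.protospacer_length + 3 > len(ref):
            raise CoordinateError(
                "protospacer plus PAM extends past the end of the reference"
            )
        if self.pam:
            found = self.oriented_reference[
                self.protospacer_offset + self.protospacer_length :
                self.protospacer_offset + self.protospacer_length + 3
            ]
            if found != self.pam:
                raise ValueError(
                    f"declared PAM {self.pam} does not match reference ({found})"
                )

    @property
    def oriented_reference(self) -> str:
        """The reference read 5'->3' on the protospacer strand."""
        if self.strand == "forward":
            return self.reference
        return reverse_complement(self.reference)

    @property
    def protospacer(self) -> str:
        o = self.protospacer_offset
        return self.oriented_reference[o : o + self.protospacer_length]

    def index_of(self, position: int) -> int:
        """0-based index in the oriented reference of a protospacer position."""
        if position == 0:
            raise CoordinateError("protospacer coordinates have no position 0")
        idx = self.protospacer_offset + (position - 1 if position > 0 else position)
        if not 0 <= idx < len(self.reference):
            raise CoordinateError(f"position {position} falls outside the amplicon")
        return idx

    def position_of(self, index: int) -> int:
        """Protospacer coordinate of a 0-based oriented-reference index."""
        if not 0 <= index < len(self.reference):
            raise CoordinateError(f"index {index} outside reference")
        d = index - self.protospacer_offset
        return d + 1 if d >= 0 else d

    def base_at(self, position: int) -> str:
        return self.oriented_reference[self.index_of(position)]

    def positions(self, start: int, stop: int) -> list[int]:
        """All protospacer coordinates from start to stop inclusive, skipping 0."""
        if start > stop:
            raise CoordinateError("start must be <= stop")
        return [p for p in range(start, stop + 1) if p != 0]

    def complemented(self) -> "ProtospacerSpec":
        """The same physical protospacer declared against the opposite
        reference strand (reference reverse-complemented, strand flipped).

        The protospacer strand itself is unchanged, so ``complemented()`` is
        an involution and all protospacer coordinates keep their meaning.
        """
        new_strand = "reverse" if self.strand == "forward" else "forward"
        return ProtospacerSpec(
            reference=reverse_complement(self.reference),
            protospacer_offset=self.protospacer_offset,
            strand=new_strand,
            protospacer_length=self.protospacer_length,
            pam=self.pam,
        )


@dataclass(frozen=True, order=True)
class EditCall:
    """A single-base substitution in protospacer coordinates.

    ``ref_base`` and ``alt_base`` are reported on the protospacer strand
    regardless of the orientation of the sequenced amplicon.
    """

    position: int
    ref_base: str
    alt_base: str

    def __post_init__(self) -> None:
        if self.position == 0:
            raise CoordinateError("EditCall position cannot be 0")
        if self.ref_base == self.alt_base:
            raise ValueError("ref_base and alt_base must differ")
        for b in (self.ref_base, self.alt_base):
            if b not in VALID_BASES:
                raise ValueError(f"invalid base {b!r}")

    def __str__(self) -> str:
        return f"{self.position}{self.ref_base}>{self.alt_base}"


Combo = frozenset[EditCall]

WILDTYPE_LABEL = "WT"


def combo_key(edits: Iterable[EditCall]) -> Combo:
    """Canonical (hashable) form of a set of edit calls."""
    combo = frozenset(edits)
    seen: dict[int, EditCall] = {}
    for e in combo:
        if e.position in seen:
            raise ValueError(f"two edit calls share position {e.position}")
        seen[e.position] = e
    return combo


def format_combo(combo: Iterable[EditCall]) -> str:
    """Render a combo as e.g. ``"5A>G;8A>G"`` (``"WT"`` for the empty combo)."""
    calls = sorted(combo, key=lambda e: e.position)
    if not calls:
        return WILDTYPE_LABEL
    return ";".join(str(c) for c in calls)


def parse_combo(text: str) -> Combo:
    """Inverse of :func:`format_combo`."""
    text = text.strip()
    if text in ("", WILDTYPE_LABEL, "."):
        return frozenset()
    calls = []
    for token in text.split(";"):
        token = token.strip()
        body, _, alt = token.partition(">")
        if not alt:
            raise ValueError(f"malformed edit token {token!r}")
        pos_part, ref = body[:-1], body[-1]
        calls.append(EditCall(int(pos_part), ref, alt))
    return combo_key(calls)


def protospacer_view(
    spec: ProtospacerSpec, segment: str, segment_offset: int = 0
) -> Mapping[int, str]:
    """Bases of an aligned read segment keyed by protospacer coordinate.

    ``segment`` must be given in reference orientation, starting at 0-based
    reference index ``segment_offset``, and must cover the protospacer.
    Reverse-strand specs are reverse-complemented exactly once here; callers
    never handle strand themselves.
    """
    segment = segment.upper()
    if spec.strand == "forward":
        oriented = segment
        start = segment_offset
    else:
        oriented = reverse_complement(segment)
        start = len(spec.reference) - segment_offset - len(segment)
    proto_start = spec.protospacer_offset
    proto_end = proto_start + spec.protospacer_length
    if start > proto_start or start + len(oriented) < proto_end:
        raise CoordinateError("segment does not cover the protospacer")
    view = {}
    for i, base in enumerate(oriented):
        idx = start + i
        if 0 <= idx < len(spec.reference):
            view[spec.position_of(idx)] = base
    return view
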