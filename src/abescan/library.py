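"""Deaminase variant-library enumeration and oligo design.

Implements the three sub-library rules used to diversify the TadA deaminase
active-site region (single-substitution scanning over a residue range, site
saturation over chosen positions, same-charge swaps at selected residues),
the ancestral back-mutation rule that reverts residues toward TadA-7.10
around screen hits, and emission of clonable oligos that avoid an internal
Type IIS (BsmBI/Esp3I) recognition site on either strand.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from Bio.Seq import Seq

from .coords import reverse_complement

logger = logging.getLogger(__name__)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Default charge/polarity partition of the 20 canonical amino acids.
#: "Same charge" is unambiguous only for charged residues; polar-uncharged
#: and nonpolar classes are a documented, configurable choice.
CHARGE_CLASSES: dict[str, frozenset[str]] = {
    "positive": frozenset("KRH"),
    "negative": frozenset("DE"),
    "polar_uncharged": frozenset("STNQCY"),
    "nonpolar": frozenset("AVLIPFMWG"),
}

#: Human codon-usage ranking per amino acid (most frequent first), used as
#: the default codon policy for oligos synthesised for expression in human
#: cells. Next-ranked codons are fallbacks when the top choice would create
#: a forbidden restriction motif in context.
HUMAN_CODON_RANKS: dict[str, tuple[str, ...]] = {
    "A": ("GCC", "GCT", "GCA", "GCG"),
    "C": ("TGC", "TGT"),
    "D": ("GAC", "GAT"),
    "E": ("GAG", "GAA"),
    "F": ("TTC", "TTT"),
    "G": ("GGC", "GGA", "GGG", "GGT"),
    "H": ("CAC", "CAT"),
    "I": ("ATC", "ATT", "ATA"),
    "K": ("AAG", "AAA"),
    "L": ("CTG", "CTC", "TTG", "CTT", "CTA", "TTA"),
    "M": ("ATG",),
    "N": ("AAC", "AAT"),
    "P": ("CCC", "CCT", "CCA", "CCG"),
    "Q": ("CAG", "CAA"),
    "R": ("CGG", "AGA", "AGG", "CGC", "CGA", "CGT"),
    "S": ("AGC", "TCC", "TCT", "AGT", "TCA", "TCG"),
    "T": ("ACC", "ACA", "ACT", "ACG"),
    "V": ("GTG", "GTC", "GTT", "GTA"),
    "W": ("TGG",),
    "Y": ("TAC", "TAT"),
}

#: BsmBI/Esp3I recognition sequence (the cloning enzyme); oligos must not
#: contain it internally on either strand.
BSMBI_SITE = "CGTCTC"

Substitution = tuple[int, str, str]  # (1-based residue index, from_aa, to_aa)


class LibraryError(ValueError):
    pass


@dataclass(frozen=True)
class AminoAcidVariant:
    """A protein variant as a set of residue substitutions vs a parent.

    The identity (parent) variant is the empty substitution set. Substitution
    tuples are stored sorted by position so equality and hashing are
    canonical.
    """

    variant_id: str
    substitutions: tuple[Substitution, ...]
    sub_library: str

    @staticmethod
    def build(
        parent: str,
        substitutions: Iterable[Substitution],
        sub_library: str,
        variant_id: str | None = None,
    ) -> "AminoAcidVariant":
        subs = tuple(sorted(substitutions))
        seen_positions = set()
        for pos, from_aa, to_aa in subs:
            if not 1 <= pos <= len(parent):
                raise LibraryError(f"substitution position {pos} outside parent")
            if parent[pos - 1] != from_aa:
                raise LibraryError(
                    f"parent has {parent[pos - 1]} at {pos}, not {from_aa}"
                )
            if from_aa == to_aa:
                raise LibraryError(
                    f"identity substitution {from_aa}{pos}{to_aa}; represent the "
                    "wild type as an empty substitution set"
                )
            if pos in seen_positions:
                raise LibraryError(f"two substitutions share position {pos}")
            seen_positions.add(pos)
        if variant_id is None:
            variant_id = (
                "+".join(f"{f}{p}{t}" for p, f, t in subs) if subs else "WT"
            )
        return AminoAcidVariant(variant_id, subs, sub_library)

    @property
    def is_identity(self) -> bool:
        return not self.substitutions

    def apply(self, parent: str) -> str:
        residues = list(parent)
        for pos, _, to_aa in self.substitutions:
            residues[pos - 1] = to_aa
        return "".join(residues)


def _identity(parent: str, sub_library: str) -> AminoAcidVariant:
    return AminoAcidVariant.build(parent, (), sub_library)


def enumerate_range_scan(
    parent: str,
    first: int,
    last: int,
    alphabet: Sequence[str] = AMINO_ACIDS,
) -> list[AminoAcidVariant]:
    """One single-substitution variant per (position, amino acid) pair over
    ``first..last`` inclusive; pairs equal to the parent residue collapse to
    a single identity entry."""
    if not 1 <= first <= last <= len(parent):
        raise LibraryError(
            f"range {first}-{last} outside parent of length {len(parent)}"
        )
    variants: list[AminoAcidVariant] = []
    if not alphabet:
        return variants
    saw_identity = False
    for pos in range(first, last + 1):
        for aa in alphabet:
            if aa == parent[pos - 1]:
                saw_identity = True
                continue
            variants.append(
                AminoAcidVariant.build(
                    parent, [(pos, parent[pos - 1], aa)], "range_scan"
                )
            )
    if saw_identity:
        variants.append(_identity(parent, "range_scan"))
    return variants


def enumerate_site_saturation(
    parent: str,
    positions: Sequence[int],
    alphabet: Sequence[str] = AMINO_ACIDS,
) -> list[AminoAcidVariant]:
    """Full Cartesian product of the alphabet over the given positions.

    A position assigned its parent residue contributes no substitution, so
    the all-parent tuple is the single identity variant and partially-parent
    tuples collapse onto lower-order combinations. The returned list has one
    entry per *distinct* variant.
    """
    if not positions:
        raise LibraryError("site saturation needs at least one position")
    if len(set(positions)) != len(positions):
        raise LibraryError("duplicate positions in site-saturation input")
    for pos in positions:
        if not 1 <= pos <= len(parent):
            raise LibraryError(f"position {pos} outside parent")
    seen: dict[tuple[Substitution, ...], AminoAcidVariant] = {}
    for assignment in itertools.product(alphabet, repeat=len(positions)):
        subs = [
            (pos, parent[pos - 1], aa)
            for pos, aa in zip(positions, assignment)
            if aa != parent[pos - 1]
        ]
        variant = AminoAcidVariant.build(parent, subs, "site_saturation")
        seen.setdefault(variant.substitutions, variant)
    return list(seen.values())


def enumerate_charge_swap(
    parent: str,
    residues: Sequence[tuple[int, str]],
    charge_classes: Mapping[str, frozenset[str]] | None = None,
) -> list[AminoAcidVariant]:
    """For each (position, expected residue), one variant per other member
    of the residue's charge/polarity class."""
    classes = charge_classes or CHARGE_CLASSES
    covered = sorted(aa for members in classes.values() for aa in members)
    if len(covered) != len(set(covered)):
        raise LibraryError("charge classes overlap; must be a partition")
    by_aa = {aa: members for members in classes.values() for aa in members}
    variants: list[AminoAcidVariant] = []
    for pos, expected in residues:
        if not 1 <= pos <= len(parent) or parent[pos - 1] != expected:
            actual = parent[pos - 1] if 1 <= pos <= len(parent) else "<out of range>"
            raise LibraryError(
                f"expected {expected} at position {pos}, parent has {actual}"
            )
        members = by_aa.get(expected)
        if members is None:
            raise LibraryError(f"residue {expected} not covered by charge classes")
        for aa in sorted(members - {expected}):
            variants.append(
                AminoAcidVariant.build(parent, [(pos, expected, aa)], "charge_swap")
            )
    return variants


def enumerate_back_mutations(
    seed_variants: Sequence[AminoAcidVariant],
    modern: str,
    ancestral: str,
    flank: int = 10,
) -> list[AminoAcidVariant]:
    """Ancestral-reversion variants around single-substitution screen hits.

    For each seed hit, the two nearest residues (scanning outward within
    ``flank``, ties broken toward the lower index) where the modern
    deaminase differs from its ancestor are selected; the seed substitution
    is combined with each single reversion and with both reversions,
    yielding up to three variants per seed. Duplicated substitution sets
    across seeds are emitted once.
    """
    if len(modern) != len(ancestral):
        raise LibraryError("modern and ancestral sequences differ in length")
    out: dict[tuple[Substitution, ...], AminoAcidVariant] = {}
    for seed in seed_variants:
        if len(seed.substitutions) != 1:
            raise LibraryError(
                f"back-mutation seeds must carry exactly one substitution "
                f"({seed.variant_id} has {len(seed.substitutions)})"
            )
        (seed_pos, _, _) = seed.substitutions[0]
        neighbors: list[int] = []
        for distance in range(1, flank + 1):
            for pos in (seed_pos - distance, seed_pos + distance):
                if len(neighbors) == 2:
                    break
                if not 1 <= pos <= len(modern):
                    continue
                if modern[pos - 1] != ancestral[pos - 1]:
                    neighbors.append(pos)
            if len(neighbors) == 2:
                break
        if len(neighbors) < 2:
            logger.warning(
                "seed %s: only %d ancestral-differing residues within +/-%d",
                seed.variant_id, len(neighbors), flank,
            )
        reversions = [
            (pos, modern[pos - 1], ancestral[pos - 1]) for pos in neighbors
        ]
        combos: list[list[Substitution]] = [[r] for r in reversions]
        if len(reversions) == 2:
            combos.append(list(reversions))
        for extra in combos:
            subs = list(seed.substitutions) + extra
            variant = AminoAcidVariant.build(modern, subs, "back_mutation")
            out.setdefault(variant.substitutions, variant)
    return list(out.values())


@dataclass(frozen=True)
class OligoRecord:
    variant_id: str
    dna: str
    flank_5: str = ""
    flank_3: str = ""

    @property
    def full_sequence(self) -> str:
        return self.flank_5 + self.dna + self.flank_3


@dataclass(frozen=True)
class OligoRejection:
    variant_id: str
    reason: str


def _contains_motif(dna: str, motif: str) -> bool:
    return motif in dna or reverse_complement(motif) in dna


def back_translate(protein: str, codon_policy: Mapping[str, tuple[str, ...]] | None = None) -> str:
    policy = codon_policy or HUMAN_CODON_RANKS
    try:
        return "".join(policy[aa][0] for aa in protein)
    except KeyError as exc:
        raise LibraryError(f"codon policy missing amino acid {exc}") from exc


def emit_oligos(
    variants: Sequence[AminoAcidVariant],
    parent_cds: str,
    codon_policy: Mapping[str, tuple[str, ...]] | None = None,
    forbidden_site: str = BSMBI_SITE,
    flank_5: str = "",
    flank_3: str = "",
) -> tuple[list[OligoRecord], list[OligoRejection]]:
    """Build one oligo per variant by swapping codons in the parent CDS.

    Substituted codons follow ``codon_policy`` rank order; if the chosen
    codon creates ``forbidden_site`` (either strand) in context, the next
    ranked codon for that amino acid is tried. Variants whose every codon
    choice creates the motif are returned as explicit rejection records,
    never silently dropped.
    """
    policy = codon_policy or HUMAN_CODON_RANKS
    parent_cds = parent_cds.upper()
    if len(parent_cds) % 3:
        raise LibraryError("parent CDS length is not a multiple of 3")
    parent_protein = str(Seq(parent_cds).translate())
    oligos: list[OligoRecord] = []
    rejections: list[OligoRejection] = []
    for variant in variants:
        codons = [parent_cds[i : i + 3] for i in range(0, len(parent_cds), 3)]
        ok = True
        for pos, from_aa, to_aa in variant.substitutions:
            if pos > len(codons) or parent_protein[pos - 1] != from_aa:
                raise LibraryError(
                    f"CDS does not encode {from_aa} at residue {pos}"
                )
            if to_aa not in policy:
                raise LibraryError(f"codon policy missing amino acid {to_aa}")
            placed = False
            for codon in policy[to_aa]:
                codons[pos - 1] = codon
                window_start = max(0, (pos - 1) * 3 - len(forbidden_site) + 1)
                window_end = pos * 3 + len(forbidden_site) - 1
                context = "".join(codons)[window_start:window_end]
                if not _contains_motif(context, forbidden_site):
                    placed = True
                    break
            if not placed:
                rejections.append(
                    OligoRejection(
                        variant.variant_id,
                        f"every codon for {to_aa} at residue {pos} creates "
                        f"the forbidden site {forbidden_site}",
                    )
                )
                ok = False
                break
        if not ok:
            continue
        dna = "".join(codons)
        oligos.append(OligoRecord(variant.variant_id, dna, flank_5, flank_3))
    return oligos, rejections
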