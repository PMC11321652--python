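"""Product-purity combinatorics and therapeutic outcome classification.

Given an allele table and a locus description (which protospacer positions
carry editable adenines, which one is the therapeutic target, and the codon
context of each), this module computes the statistics used to compare
editors at disease loci: the distribution of edit combinations (none /
single / dual / triple ...), purity ratios such as single-at-target versus
dual-with-bystander, and the precise / bystander-missense / wild-type
trichotomy, with an explicit fourth category for combinations whose only
bystanders are benign (e.g. synonymous).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml
from Bio.Seq import Seq

from .coords import Combo, EditCall, format_combo
from .quant import AlleleTable, FreqVector, QuantError, per_position_frequencies

CARDINALITY_LABELS = {0: "none", 1: "single", 2: "dual", 3: "triple"}

CONSEQUENCES = (
    "corrective",
    "missense",
    "synonymous",
    "nonsense",
    "stop_loss",
    "noncoding",
)

#: consequences that make a bystander-containing allele deleterious
HARMFUL_CONSEQUENCES = frozenset({"missense", "nonsense"})


class TargetSpecError(ValueError):
    pass


def codon_consequence(
    ref_codon: str, alt_codon: str, target: bool = False
) -> str:
    """Classify a codon change under the standard genetic code.

    ``corrective`` is assigned only when the caller designates the position
    as the therapeutic target; otherwise the raw consequence is returned.
    """
    ref_codon, alt_codon = ref_codon.upper(), alt_codon.upper()
    for codon in (ref_codon, alt_codon):
        if len(codon) != 3 or set(codon) - set("ACGT"):
            raise TargetSpecError(f"not a DNA codon: {codon!r}")
    if ref_codon == alt_codon:
        raise TargetSpecError("codons are identical")
    if target:
        return "corrective"
    ref_aa = str(Seq(ref_codon).translate())
    alt_aa = str(Seq(alt_codon).translate())
    if ref_aa == alt_aa:
        return "synonymous"
    if alt_aa == "*":
        return "nonsense"
    if ref_aa == "*":
        return "stop_loss"
    return "missense"


@dataclass(frozen=True)
class PositionConsequence:
    """Codon context and consequence of editing one protospacer position."""

    position: int
    consequence: str
    ref_codon: str = ""
    edited_codon: str = ""

    def __post_init__(self) -> None:
        if self.consequence not in CONSEQUENCES:
            raise TargetSpecError(f"unknown consequence {self.consequence!r}")
        if bool(self.ref_codon) != bool(self.edited_codon):
            raise TargetSpecError("supply both codons or neither")
        if self.ref_codon:
            diffs = [
                i for i, (a, b) in enumerate(zip(self.ref_codon, self.edited_codon))
                if a != b
            ]
            if len(diffs) != 1:
                raise TargetSpecError(
                    f"position {self.position}: ref and edited codon must differ "
                    "at exactly one base"
                )


@dataclass(frozen=True)
class TargetSpec:
    """Editable adenines at a locus, the therapeutic target among them, and
    per-position codon consequences."""

    name: str
    editable_positions: tuple[int, ...]
    target_position: int
    consequences: Mapping[int, PositionConsequence]

    def __post_init__(self) -> None:
        if self.target_position not in self.editable_positions:
            raise TargetSpecError("target_position must be an editable position")
        missing = set(self.editable_positions) - set(self.consequences)
        if missing:
            raise TargetSpecError(f"no consequence for positions {sorted(missing)}")

    def consequence_at(self, position: int) -> str:
        try:
            return self.consequences[position].consequence
        except KeyError:
            raise TargetSpecError(
                f"{self.name}: combo position {position} not covered by the "
                "target specification"
            ) from None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "TargetSpec":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        consequences = {}
        for entry in raw["positions"]:
            pos = int(entry["position"])
            consequences[pos] = PositionConsequence(
                position=pos,
                consequence=entry["consequence"],
                ref_codon=entry.get("ref_codon", ""),
                edited_codon=entry.get("edited_codon", ""),
            )
        return cls(
            name=raw["name"],
            editable_positions=tuple(sorted(consequences)),
            target_position=int(raw["target_position"]),
            consequences=consequences,
        )


@dataclass
class OutcomeSummary:
    """Fractions of passing reads per therapeutic outcome category.

    precise: edited at the target position and nowhere else.
    bystander_missense: any combination containing a missense or nonsense
        bystander.
    other_edited: edited combinations whose bystanders are all benign
        (synonymous / noncoding), or edits outside the locus positions.
    wild_type: unedited reads.
    """

    name: str
    precise: float
    bystander_missense: float
    other_edited: float
    wild_type: float
    combo_distribution: dict[Combo, float]

    def three_way(self) -> dict[str, float]:
        """Fold ``other_edited`` into ``bystander_missense`` to recover a
        three-category precise / missense / wild-type split."""
        return {
            "precise": self.precise,
            "missense": self.bystander_missense + self.other_edited,
            "wild_type": self.wild_type,
        }

    def as_dict(self) -> dict:
        return {
            "name": self.name,
            "precise": self.precise,
            "bystander_missense": self.bystander_missense,
            "other_edited": self.other_edited,
            "wild_type": self.wild_type,
            "combo_distribution": {
                format_combo(c): f for c, f in sorted(
                    self.combo_distribution.items(),
                    key=lambda kv: format_combo(kv[0]),
                )
            },
        }


def combo_distribution(
    table: AlleleTable, positions: Iterable[int]
) -> dict[frozenset[int], float]:
    """Fractions of reads per edit combination projected onto ``positions``.

    Edits outside the projection set are ignored, so e.g. a read edited at
    {+6, +9} projected onto {6, 7} counts as single-{6}. Keys are frozensets
    of positions; fractions are over all passing reads.
    """
    positions = frozenset(positions)
    if table.n_total == 0:
        raise QuantError("allele table holds no passing reads")
    out: dict[frozenset[int], float] = {frozenset(): 0.0}
    for combo, frac in table.fractions().items():
        projected = frozenset(c.position for c in combo if c.position in positions)
        out[projected] = out.get(projected, 0.0) + frac
    return out


def project_allele_table(
    table: AlleleTable,
    positions: Iterable[int],
    from_base: str = "A",
    to_base: str = "G",
) -> AlleleTable:
    """Restrict an allele table to the given substitution at the given
    positions, merging combos that become indistinguishable.

    The outcome trichotomy is defined over a locus's editable adenines, so
    sequencing noise and off-window calls are projected away before
    classification; read counts and discard counters are preserved.
    """
    positions = frozenset(positions)
    combos: dict[Combo, int] = {}
    for combo, count in table.combos.items():
        projected = frozenset(
            c for c in combo
            if c.position in positions
            and c.ref_base == from_base
            and c.alt_base == to_base
        )
        combos[projected] = combos.get(projected, 0) + count
    return AlleleTable(
        spec=table.spec,
        combos=combos,
        window=table.window,
        n_discarded_indel=table.n_discarded_indel,
        n_discarded_mismatch=table.n_discarded_mismatch,
        n_discarded_short=table.n_discarded_short,
    )


def cardinality_label(combo: frozenset[int]) -> str:
    return CARDINALITY_LABELS.get(len(combo), f"{len(combo)}-fold")


def purity_ratio(
    dist: Mapping[frozenset[int], float],
    focal_combo: Iterable[int],
    competing_combo: Iterable[int],
) -> float | None:
    """focal / (focal + competing) between two combination fractions.

    Returns None when both fractions are zero (the ratio is undefined).
    """
    focal = dist.get(frozenset(focal_combo), 0.0)
    competing = dist.get(frozenset(competing_combo), 0.0)
    if focal == 0 and competing == 0:
        return None
    return focal / (focal + competing)


def classify_outcomes(table: AlleleTable, spec: TargetSpec) -> OutcomeSummary:
    """Partition all reads into precise / bystander-missense / other-edited /
    wild-type fractions (summing to 1 exactly)."""
    fractions = table.fractions()
    precise = missense = other = wild = 0.0
    for combo, frac in fractions.items():
        if not combo:
            wild += frac
            continue
        positions = {c.position for c in combo}
        if positions == {spec.target_position}:
            precise += frac
            continue
        if any(
            spec.consequence_at(p) in HARMFUL_CONSEQUENCES
            for p in positions
        ):
            missense += frac
        else:
            other += frac
    return OutcomeSummary(
        name=spec.name,
        precise=precise,
        bystander_missense=missense,
        other_edited=other,
        wild_type=wild,
        combo_distribution=dict(fractions),
    )


def bystander_report(
    table: AlleleTable, spec: TargetSpec, to_base: str = "G"
) -> list[dict]:
    """Per non-target editable position: editing frequency (over all passing
    reads) with its consequence label."""
    freq = per_position_frequencies(table, from_base="A", to_base=to_base)
    rows = []
    for pos in spec.editable_positions:
        if pos == spec.target_position:
            continue
        rows.append(
            {
                "position": pos,
                "frequency": freq.freqs.get(pos, 0.0),
                "consequence": spec.consequence_at(pos),
            }
        )
    return rows
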