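"""Independent oracles shared between unit and acceptance tests.

Each oracle re-derives an expected result by brute force (exhaustive
enumeration, codon-by-codon translation, direct marginal counting) without
touching the implementation path it checks.
"""

from __future__ import annotations

import itertools

from Bio.Seq import Seq

from abescan.coords import Combo, EditCall
from abescan.quant import AlleleTable


def marginal_oracle(
    table: AlleleTable, from_base: str = "A", to_base: str = "G"
) -> dict[int, float]:
    """Per-position frequencies by exhaustively expanding every combo."""
    n = table.n_total
    freqs: dict[int, float] = {}
    for pos in table.window_positions():
        if table.spec.base_at(pos) != from_base:
            continue
        hits = 0
        for combo, count in table.combos.items():
            for call in combo:
                if (
                    call.position == pos
                    and call.ref_base == from_base
                    and call.alt_base == to_base
                ):
                    hits += count
        freqs[pos] = hits / n
    return freqs


def projection_oracle(
    table: AlleleTable, positions: set[int]
) -> dict[frozenset[int], float]:
    """Combo distribution by iterating reads one combo at a time."""
    n = table.n_total
    out: dict[frozenset[int], float] = {frozenset(): 0.0}
    for combo, count in table.combos.items():
        projected = frozenset(c.position for c in combo if c.position in positions)
        out[projected] = out.get(projected, 0.0) + count / n
    return out


def classification_oracle(
    combo_positions: frozenset[int],
    target: int,
    consequence_of: dict[int, str],
) -> str:
    """Direct evaluation of the precise / missense / other / wild-type rule
    for one combination of edited positions."""
    if not combo_positions:
        return "wild_type"
    if combo_positions == {target}:
        return "precise"
    if any(consequence_of[p] in ("missense", "nonsense") for p in combo_positions):
        return "bystander_missense"
    return "other_edited"


def translate_and_scan(insert: str, frame_offset: int = 0) -> bool:
    """True iff the insert read in frame contains no stop codon and keeps
    the downstream ORF in frame (codon-by-codon translation oracle)."""
    phased = insert[frame_offset:]
    if len(phased) % 3 != 0:
        return False
    for i in range(0, len(phased), 3):
        if str(Seq(phased[i : i + 3]).translate()) == "*":
            return False
    return True


def range_scan_oracle(parent: str, first: int, last: int, alphabet: str) -> set:
    """Distinct single-substitution variants over the (position, aa) grid."""
    variants = set()
    for pos in range(first, last + 1):
        for aa in alphabet:
            if aa == parent[pos - 1]:
                variants.add(frozenset())
            else:
                variants.add(frozenset({(pos, parent[pos - 1], aa)}))
    return variants


def site_saturation_oracle(parent: str, positions: list[int], alphabet: str) -> set:
    """Distinct variants from the full Cartesian product, by nested loops."""
    variants = set()
    for assignment in itertools.product(alphabet, repeat=len(positions)):
        subs = frozenset(
            (pos, parent[pos - 1], aa)
            for pos, aa in zip(positions, assignment)
            if aa != parent[pos - 1]
        )
        variants.add(subs)
    return variants


def random_allele_table(rng, spec, positions, window=(-3, 12), max_count=50) -> AlleleTable:
    """A random allele table over all subsets of up to 6 A-positions."""
    combos: dict[Combo, int] = {}
    for r in range(len(positions) + 1):
        for subset in itertools.combinations(positions, r):
            count = int(rng.integers(0, max_count + 1))
            if count or not subset:
                combos[
                    frozenset(EditCall(p, spec.base_at(p), "G") for p in subset)
                ] = count
    if sum(combos.values()) == 0:
        combos[frozenset()] = 1
    return AlleleTable(spec=spec, combos=combos, window=window)
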