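"""Allele-level quantification of base-editing outcomes from amplicon reads.

The quantifier is deliberately ungapped: amplicon sequencing places every
read at a fixed (or nearly fixed) offset on its reference, so each read is
anchored at the offset minimising Hamming distance within a small slack,
substitutions inside the quantification window become edit calls on the
protospacer strand, and length anomalies are discarded as putative indels.
Base editors produce almost exclusively substitutions, which keeps this
exact, auditable and fast.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

from .coords import Combo, EditCall, ProtospacerSpec, combo_key, format_combo, parse_combo
from .io import RunConfig, read_tsv_rows, write_tsv


class QuantError(ValueError):
    pass


@dataclass
class AlleleTable:
    """Read counts per edit combination inside the quantification window."""

    spec: ProtospacerSpec
    combos: dict[Combo, int]
    window: tuple[int, int]
    n_discarded_indel: int = 0
    n_discarded_mismatch: int = 0
    n_discarded_short: int = 0

    def __post_init__(self) -> None:
        self.combos.setdefault(frozenset(), 0)
        lo, hi = self.window
        for combo in self.combos:
            for call in combo:
                if not lo <= call.position <= hi:
                    raise QuantError(
                        f"edit at {call.position} outside window {self.window}"
                    )

    @property
    def n_total(self) -> int:
        return sum(self.combos.values())

    def fractions(self) -> dict[Combo, float]:
        n = self.n_total
        if n == 0:
            raise QuantError("allele table holds no passing reads")
        return {combo: count / n for combo, count in self.combos.items()}

    def window_positions(self) -> list[int]:
        return self.spec.positions(*self.window)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"combo": format_combo(c), "count": n, "n_edits": len(c)}
            for c, n in sorted(
                self.combos.items(), key=lambda kv: (-kv[1], format_combo(kv[0]))
            )
        ]
        return pd.DataFrame(rows, columns=["combo", "count", "n_edits"])

    def write_tsv(self, path, config: RunConfig | None = None) -> None:
        write_tsv(
            path,
            ["combo", "count", "n_edits"],
            self.to_frame().itertuples(index=False),
            config=config,
            reference=self.spec.reference,
            protospacer_offset=self.spec.protospacer_offset,
            strand=self.spec.strand,
            pam=self.spec.pam,
            window=f"{self.window[0]}..{self.window[1]}",
            n_total=self.n_total,
            n_discarded_indel=self.n_discarded_indel,
            n_discarded_mismatch=self.n_discarded_mismatch,
            n_discarded_short=self.n_discarded_short,
        )

    @classmethod
    def read_tsv(cls, path) -> "AlleleTable":
        meta, header, rows = read_tsv_rows(path)
        spec = ProtospacerSpec(
            reference=meta["reference"],
            protospacer_offset=int(meta["protospacer_offset"]),
            strand=meta.get("strand", "forward"),
            pam=meta.get("pam", ""),
        )
        lo, hi = meta["window"].split("..")
        icombo = header.index("combo")
        icount = header.index("count")
        combos = {parse_combo(r[icombo]): int(r[icount]) for r in rows}
        return cls(
            spec=spec,
            combos=combos,
            window=(int(lo), int(hi)),
            n_discarded_indel=int(meta.get("n_discarded_indel", 0)),
            n_discarded_mismatch=int(meta.get("n_discarded_mismatch", 0)),
            n_discarded_short=int(meta.get("n_discarded_short", 0)),
        )


@dataclass
class FreqVector:
    """Per-protospacer-position frequency of one substitution type.

    Positions whose reference base is not the from-base are *not applicable*
    and are excluded from ``freqs`` rather than reported as zero.
    """

    from_base: str
    to_base: str
    freqs: dict[int, float]
    ref_bases: dict[int, str]
    n_total: int

    def applicable_positions(self) -> list[int]:
        return sorted(self.freqs)

    def max_frequency(self) -> float:
        return max(self.freqs.values(), default=0.0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "position": self.applicable_positions(),
                "ref_base": [self.ref_bases[p] for p in self.applicable_positions()],
                "frequency": [self.freqs[p] for p in self.applicable_positions()],
            }
        )


def _best_anchor(
    read: str, reference: str, nominal: int, slack: int
) -> tuple[int, list[int]]:
    """Offset within ``nominal +/- slack`` minimising Hamming distance.

    Returns (offset, mismatch reference indices). Ties break toward the
    lower offset.
    """
    best: tuple[int, list[int]] | None = None
    lo = max(0, nominal - slack)
    hi = min(len(reference) - len(read), nominal + slack)
    if hi < lo:
        raise QuantError("read longer than reference")
    for offset in range(lo, hi + 1):
        segment = reference[offset : offset + len(read)]
        if segment == read:
            return offset, []
        mism = [offset + i for i, (a, b) in enumerate(zip(segment, read)) if a != b]
        if best is None or len(mism) < len(best[1]):
            best = (offset, mism)
    assert best is not None
    return best


def align_and_call(
    reads: Iterable[tuple[str, str, str]] | Iterable[str],
    spec: ProtospacerSpec,
    quant_window: tuple[int, int] = (-3, 12),
    mismatch_budget: int = 5,
    expected_length: int | None = None,
    anchor_offset: int = 0,
    anchor_slack: int = 5,
) -> AlleleTable:
    """Anchor amplicon reads to the reference and tabulate edit combinations.

    Reads whose length differs from ``expected_length`` (default: the full
    reference) are discarded as indel-bearing. Substitutions inside
    ``quant_window`` (protospacer coordinates, protospacer strand) become
    edit calls; substitutions outside it count against ``mismatch_budget``
    and reads exceeding the budget are discarded as off-amplicon. Ns in a
    read are treated as mismatches but never called as edits.
    """
    lo, hi = quant_window
    if lo > hi:
        raise QuantError(f"empty quantification window {quant_window}")
    for bound in (lo, hi):
        try:
            spec.index_of(bound if bound != 0 else 1)
        except Exception as exc:
            raise QuantError(f"window {quant_window} outside amplicon") from exc
    if expected_length is None:
        expected_length = len(spec.reference)
    reference = spec.reference
    oriented = spec.oriented_reference
    reverse = spec.strand == "reverse"
    n_ref = len(reference)

    combos: dict[Combo, int] = {frozenset(): 0}
    n_indel = n_mismatch = n_short = 0
    n_reads = 0
    for record in reads:
        seq = record if isinstance(record, str) else record[1]
        seq = seq.upper()
        n_reads += 1
        if len(seq) != expected_length:
            if len(seq) < expected_length:
                n_short += 1
            n_indel += 1
            continue
        offset, mismatch_idx = _best_anchor(seq, reference, anchor_offset, anchor_slack)
        in_window: list[EditCall] = []
        n_outside = 0
        for ref_i in mismatch_idx:
            read_base = seq[ref_i - offset]
            if reverse:
                oriented_i = n_ref - 1 - ref_i
            else:
                oriented_i = ref_i
            pos = spec.position_of(oriented_i)
            ref_base = oriented[oriented_i]
            alt = read_base
            if reverse:
                alt = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}[alt]
            if lo <= pos <= hi and alt != "N" and ref_base != "N":
                in_window.append(EditCall(pos, ref_base, alt))
            else:
                n_outside += 1
        if n_outside > mismatch_budget:
            n_mismatch += 1
            continue
        key = combo_key(in_window)
        combos[key] = combos.get(key, 0) + 1
    if n_reads == 0:
        raise QuantError("empty read stream")
    return AlleleTable(
        spec=spec,
        combos=combos,
        window=quant_window,
        n_discarded_indel=n_indel,
        n_discarded_mismatch=n_mismatch,
        n_discarded_short=n_short,
    )


def per_position_frequencies(
    table: AlleleTable, from_base: str = "A", to_base: str = "G"
) -> FreqVector:
    """Fraction of passing reads edited ``from_base -> to_base`` at each
    applicable window position (denominator: all passing reads)."""
    n = table.n_total
    if n == 0:
        raise QuantError("allele table holds no passing reads")
    hits: dict[int, int] = {}
    ref_bases: dict[int, str] = {}
    for pos in table.window_positions():
        base = table.spec.base_at(pos)
        ref_bases[pos] = base
        if base == from_base:
            hits[pos] = 0
    for combo, count in table.combos.items():
        for call in combo:
            if call.ref_base == from_base and call.alt_base == to_base:
                if call.position in hits:
                    hits[call.position] += count
    freqs = {pos: count / n for pos, count in hits.items()}
    return FreqVector(from_base, to_base, freqs, ref_bases, n)


def byproduct_profile(table: AlleleTable) -> dict[str, FreqVector]:
    """One frequency vector per substitution type observed in the table
    (always including A>G and C>T), all over the same denominator."""
    types = {("A", "G"), ("C", "T")}
    for combo in table.combos:
        for call in combo:
            types.add((call.ref_base, call.alt_base))
    return {
        f"{f}>{t}": per_position_frequencies(table, f, t)
        for f, t in sorted(types)
    }


def editing_window(
    freq: FreqVector, threshold_fraction: float
) -> tuple[int, int] | None:
    """Maximal contiguous run of applicable positions at >= threshold_fraction
    of the peak frequency, containing the peak. Ties on the peak break
    toward the 5' end. Returns None for an all-zero vector."""
    if not 0 < threshold_fraction <= 1:
        raise ValueError("threshold_fraction must be in (0, 1]")
    positions = freq.applicable_positions()
    if not positions:
        return None
    peak = freq.max_frequency()
    if peak == 0:
        return None
    argmax = min(p for p in positions if freq.freqs[p] == peak)
    cutoff = threshold_fraction * peak
    above = {p for p in positions if freq.freqs[p] >= cutoff}
    idx = positions.index(argmax)
    left = idx
    while left > 0 and positions[left - 1] in above:
        left -= 1
    right = idx
    while right < len(positions) - 1 and positions[right + 1] in above:
        right += 1
    return positions[left], positions[right]
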