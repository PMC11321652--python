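"""Stop-codon EGFP reporter logic and sort-seq enrichment scoring.

The screen couples deaminase activity to fluorescence through a defective
EGFP: a short insert between the start codon and the EGFP ORF carries an
in-frame premature stop (TGA) inside the protospacer, and an A-to-G edit of
the stop's adenine (protospacer position +7 in the shipped fixture)
converts it to TGG, restoring translation. Variants are scored by log2
enrichment of sorted-pool versus input-pool relative frequencies, and hits
are aggregated across replicates as the union of per-replicate top-k ranks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .coords import CoordinateError, EditCall, ProtospacerSpec

STOP_SYMBOL = "*"


class ScreenError(ValueError):
    pass


@dataclass(frozen=True)
class ReporterConstruct:
    """A defective fluorescent reporter with an editable premature stop.

    ``insert`` sits between the start codon ATG and the EGFP coding
    sequence; ``spec`` locates the protospacer within an amplicon whose
    sequence contains the insert starting at ``insert_start`` (0-based index
    into ``spec.reference`` on the protospacer strand). ``frame_offset`` is
    the phase of the insert relative to the ATG (0 = insert codons are read
    directly).
    """

    insert: str
    spec: ProtospacerSpec
    insert_start: int
    frame_offset: int = 0

    def __post_init__(self) -> None:
        insert = self.insert.upper()
        object.__setattr__(self, "insert", insert)
        if self.frame_offset == 0 and len(insert) % 3 != 0:
            raise ScreenError(
                "in-frame insert length must be a multiple of 3 "
                f"(got {len(insert)})"
            )
        oriented = self.spec.oriented_reference
        if oriented[self.insert_start : self.insert_start + len(insert)] != insert:
            raise ScreenError("insert does not match the reference at insert_start")
        if STOP_SYMBOL not in self._translate(insert):
            raise ScreenError("unedited insert must contain an in-frame stop codon")

    def _translate(self, insert_seq: str) -> str:
        phased = insert_seq[self.frame_offset :]
        usable = len(phased) - len(phased) % 3
        return str(Seq(phased[:usable]).translate())

    def insert_index(self, position: int) -> int:
        """0-based index into the insert of a protospacer coordinate."""
        idx = self.spec.index_of(position) - self.insert_start
        if not 0 <= idx < len(self.insert):
            raise CoordinateError(
                f"protospacer position {position} lies outside the reporter insert"
            )
        return idx

    def edited_insert(self, edits: Iterable[EditCall]) -> str:
        bases = list(self.insert)
        for edit in edits:
            idx = self.insert_index(edit.position)
            if bases[idx] != edit.ref_base:
                raise ScreenError(
                    f"edit {edit} does not match insert base {bases[idx]}"
                )
            bases[idx] = edit.alt_base
        return "".join(bases)


def egfp_state(construct: ReporterConstruct, edits: Iterable[EditCall]) -> str:
    """``"on"`` iff the edited insert, read in frame from the ATG, contains
    no premature stop before the EGFP ORF and keeps EGFP in frame."""
    edited = construct.edited_insert(edits)
    if (len(edited) - construct.frame_offset) % 3 != 0:
        return "off"
    return "off" if STOP_SYMBOL in construct._translate(edited) else "on"


@dataclass
class VariantCounts:
    """Read counts per variant for one pool of one replicate."""

    pool_id: str
    replicate: int
    counts: dict[str, int]

    def __post_init__(self) -> None:
        if self.pool_id not in ("input", "sorted"):
            raise ScreenError(f"pool_id must be input/sorted, got {self.pool_id!r}")
        for vid, c in self.counts.items():
            if c < 0 or c != int(c):
                raise ScreenError(f"count for {vid} must be a non-negative integer")
        if sum(self.counts.values()) <= 0:
            raise ScreenError(f"pool {self.pool_id}/{self.replicate} is empty")

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def enrichment_scores(
    input_counts: VariantCounts,
    sorted_counts: VariantCounts,
    pseudocount: float = 0.5,
    rank_by: str = "enrichment",
) -> pd.DataFrame:
    """Log2 relative-frequency enrichment of sorted vs input pool.

    score(v) = log2[(sorted_v + pc) / (sum(sorted) + pc * n)]
             - log2[(input_v + pc) / (sum(input) + pc * n)]

    over the union of variants in either pool (absent = 0). Ranks descend by
    score (or sorted-pool frequency when ``rank_by="frequency"``); ties
    break by higher sorted count, then lexicographic variant id.
    """
    if pseudocount <= 0:
        raise ScreenError("pseudocount must be positive")
    if rank_by not in ("enrichment", "frequency"):
        raise ScreenError("rank_by must be 'enrichment' or 'frequency'")
    universe = sorted(set(input_counts.counts) | set(sorted_counts.counts))
    n = len(universe)
    if n == 0:
        raise ScreenError("no variants in either pool")
    inp = np.array([input_counts.counts.get(v, 0) for v in universe], dtype=float)
    srt = np.array([sorted_counts.counts.get(v, 0) for v in universe], dtype=float)
    score = np.log2((srt + pseudocount) / (srt.sum() + pseudocount * n)) - np.log2(
        (inp + pseudocount) / (inp.sum() + pseudocount * n)
    )
    df = pd.DataFrame(
        {
            "variant_id": universe,
            "input_count": inp.astype(int),
            "sorted_count": srt.astype(int),
            "score": score,
        }
    )
    key = df["score"] if rank_by == "enrichment" else df["sorted_count"]
    order = sorted(
        range(n),
        key=lambda i: (-key.iloc[i], -df["sorted_count"].iloc[i], df["variant_id"].iloc[i]),
    )
    ranks = np.empty(n, dtype=int)
    for r, i in enumerate(order, start=1):
        ranks[i] = r
    df["rank"] = ranks
    df["replicate"] = input_counts.replicate
    return df.sort_values("rank").reset_index(drop=True)


def rank_aggregate(
    tables: Sequence[pd.DataFrame], top_k: int
) -> dict[str, int]:
    """Union of variants ranked <= top_k in at least one replicate, mapped to
    the number of supporting replicates."""
    if top_k < 1:
        raise ScreenError("top_k must be >= 1")
    if not tables:
        raise ScreenError("need at least one replicate table")
    support: dict[str, int] = {}
    for table in tables:
        hits = table.loc[table["rank"] <= top_k, "variant_id"]
        for vid in hits:
            support[vid] = support.get(vid, 0) + 1
    return support
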