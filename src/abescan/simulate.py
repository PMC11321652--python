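"""Synthetic amplicon reads, FACS-gated screen pools and locus fixtures.

Amplicon reads are drawn from an explicit joint distribution over edit
combinations (base-editing outcomes co-occur on the same molecule, so the
generator is parameterised by whole-allele probabilities, not independent
per-position rates) with i.i.d. uniform substitution sequencing error.
Screen pools emulate the sort-seq readout: cells receive variants
multinomially, fluoresce in proportion to their variant's activity plus
Gaussian reporter noise, and the brightest fixed fraction of cells is
sorted. Locus fixtures are synthetic amplicons that honour the published
protospacer layouts (editable-adenine positions and codon contexts) of the
HFE-C282Y, sickle HBB, PCSK9 intron-1 and stop-codon reporter loci without
reproducing genomic sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .coords import (
    Combo,
    EditCall,
    ProtospacerSpec,
    combo_key,
    format_combo,
    reverse_complement,
)
from .outcomes import PositionConsequence, TargetSpec
from .reporter import ReporterConstruct, VariantCounts

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_DEFAULT_QUALITY_CHAR = "I"  # constant Q40; qualities are parsed but unused


class SimulationError(ValueError):
    pass


@dataclass
class SimProfile:
    """Generative parameters for one synthetic amplicon sequencing run."""

    spec: ProtospacerSpec
    combo_dist: dict[Combo, float]
    error_rate: float = 0.001
    n_reads: int = 20_000
    read_length: int | None = None
    indel_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.combo_dist.values())
        if abs(total - 1.0) > 1e-9:
            raise SimulationError(f"combo probabilities sum to {total}, not 1")
        if not 0 <= self.error_rate <= 0.1:
            raise SimulationError("error_rate must lie in [0, 0.1]")
        if not 0 <= self.indel_rate < 1:
            raise SimulationError("indel_rate must lie in [0, 1)")
        if self.n_reads < 1:
            raise SimulationError("n_reads must be >= 1")
        if self.read_length is None:
            self.read_length = len(self.spec.reference)
        if self.read_length > len(self.spec.reference):
            raise SimulationError("read_length exceeds the amplicon")


def _apply_combo(spec: ProtospacerSpec, combo: Combo) -> str:
    """The amplicon (reference orientation) carrying a combo's edits."""
    oriented = list(spec.oriented_reference)
    for call in combo:
        idx = spec.index_of(call.position)
        if oriented[idx] != call.ref_base:
            raise SimulationError(
                f"combo edit {call} does not match the reference base "
                f"{oriented[idx]}"
            )
        oriented[idx] = call.alt_base
    seq = "".join(oriented)
    return seq if spec.strand == "forward" else reverse_complement(seq)


def simulate_amplicon_reads(
    profile: SimProfile,
) -> list[tuple[str, str, str]]:
    """Draw reads as ``(id, sequence, quality)`` tuples, deterministic in
    the profile seed.

    Each read samples a combo, applies its substitutions to the reference,
    then applies i.i.d. uniform substitution errors at ``error_rate``; with
    probability ``indel_rate`` the read is finally truncated or extended by
    one base to exercise the quantifier's indel discard path.
    """
    rng = np.random.default_rng(profile.seed)
    combos = sorted(profile.combo_dist, key=format_combo)
    probs = np.array([profile.combo_dist[c] for c in combos])
    counts = rng.multinomial(profile.n_reads, probs / probs.sum())

    length = profile.read_length
    rows = np.empty((profile.n_reads, length), dtype=np.uint8)
    start = 0
    for combo, count in zip(combos, counts):
        if count == 0:
            continue
        template = np.frombuffer(
            _apply_combo(profile.spec, combo)[:length].encode(), dtype=np.uint8
        )
        rows[start : start + count] = template
        start += count

    if profile.error_rate > 0:
        err_mask = rng.random(rows.shape) < profile.error_rate
        n_err = int(err_mask.sum())
        if n_err:
            # substitute uniformly among the three non-reference bases
            shift = rng.integers(1, 4, size=n_err)
            current = rows[err_mask]
            base_idx = np.searchsorted(_BASES, current)
            rows[err_mask] = _BASES[(base_idx + shift) % 4]

    order = rng.permutation(profile.n_reads)
    indel_draws = rng.random(profile.n_reads)
    qual_full = _DEFAULT_QUALITY_CHAR * (length + 1)
    reads = []
    for out_i, row_i in enumerate(order):
        seq = rows[row_i].tobytes().decode()
        if indel_draws[out_i] < profile.indel_rate:
            # half truncations, half single-base extensions
            if indel_draws[out_i] < profile.indel_rate / 2:
                seq = seq[:-1]
            else:
                seq = seq + seq[-1]
        reads.append((f"read_{out_i + 1:06d}", seq, qual_full[: len(seq)]))
    return reads


@dataclass
class ScreenSimSpec:
    """Generative parameters for one sort-seq screen replicate."""

    variants: dict[str, tuple[float, float]]  # id -> (true_activity, input_freq)
    n_cells: int = 1_000_000
    gate_fraction: float = 0.05
    reporter_noise_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        freqs = np.array([f for _, f in self.variants.values()])
        acts = np.array([a for a, _ in self.variants.values()])
        if abs(freqs.sum() - 1.0) > 1e-9:
            raise SimulationError("input frequencies must sum to 1")
        if np.any((acts < 0) | (acts > 1)):
            raise SimulationError("activities must lie in [0, 1]")
        if not 0 < self.gate_fraction < 1:
            raise SimulationError("gate_fraction must lie in (0, 1)")
        if self.reporter_noise_sd < 0:
            raise SimulationError("reporter_noise_sd must be >= 0")
        if self.n_cells < 1 or round(self.gate_fraction * self.n_cells) < 1:
            raise SimulationError("gate would contain zero cells")


def simulate_screen_pools(
    sim: ScreenSimSpec, replicate: int = 1
) -> tuple[VariantCounts, VariantCounts]:
    """Simulate one replicate: multinomial variant assignment over cells,
    fluorescence = activity + Gaussian noise, top ``gate_fraction`` of cells
    sorted. Returns (input pool, sorted pool) integer counts."""
    rng = np.random.default_rng(sim.seed + replicate)
    ids = sorted(sim.variants)
    freqs = np.array([sim.variants[v][1] for v in ids])
    acts = np.array([sim.variants[v][0] for v in ids])

    cell_counts = rng.multinomial(sim.n_cells, freqs / freqs.sum())
    cell_variant = np.repeat(np.arange(len(ids)), cell_counts)
    fluorescence = acts[cell_variant] + rng.normal(
        0.0, sim.reporter_noise_sd, size=sim.n_cells
    )
    n_gate = int(round(sim.gate_fraction * sim.n_cells))
    gated = np.argpartition(fluorescence, -n_gate)[-n_gate:]
    sorted_counts = np.bincount(cell_variant[gated], minlength=len(ids))

    input_pool = VariantCounts(
        "input", replicate, {v: int(c) for v, c in zip(ids, cell_counts)}
    )
    sorted_pool = VariantCounts(
        "sorted", replicate, {v: int(c) for v, c in zip(ids, sorted_counts)}
    )
    return input_pool, sorted_pool


@dataclass(frozen=True)
class LocusFixture:
    name: str
    spec: ProtospacerSpec
    target: TargetSpec | None = None
    reporter: ReporterConstruct | None = None


def _hfe_c282y() -> LocusFixture:
    # Editable adenines at +1/+5/+8; the therapeutic adenine at +5 restores
    # the cysteine codon, while +1 (ACG->GCG, Thr->Ala) and +8 (CAG->CGG,
    # Gln->Arg) bystanders are missense. Codons are in frame with the
    # protospacer start.
    protospacer = "ACGTACCAGCTGCTGCTGCT"
    flank5 = "GTCCTCCTGGTCCTCCTGGTCCTCCTGGTC"
    flank3 = "CTCCTGGTCCTCCTGGTCCTCCTGGTC"
    pam = "TGG"
    reference = flank5 + protospacer + pam + flank3
    spec = ProtospacerSpec(reference, len(flank5), "forward", pam=pam)
    target = TargetSpec(
        name="hfe_c282y",
        editable_positions=(1, 5, 8),
        target_position=5,
        consequences={
            1: PositionConsequence(1, "missense", "ACG", "GCG"),
            5: PositionConsequence(5, "corrective", "TAC", "TGC"),
            8: PositionConsequence(8, "missense", "CAG", "CGG"),
        },
    )
    return LocusFixture("hfe_c282y", spec, target=target)


def _hbb_s() -> LocusFixture:
    # Sickle-locus layout: target adenine +7; bystanders +9 and +12 sit at
    # codon third positions so their A->G edits are synonymous.
    protospacer = "CTGCTGACACCATTGCTGCT"
    flank5 = "GTCCTCCTGGTCCTCCTGGTCCTCCTGGTC"
    flank3 = "CTCCTGGTCCTCCTGGTCCTCCTGGTC"
    pam = "TGG"
    reference = flank5 + protospacer + pam + flank3
    spec = ProtospacerSpec(reference, len(flank5), "forward", pam=pam)
    target = TargetSpec(
        name="hbb_s",
        editable_positions=(7, 9, 12),
        target_position=7,
        consequences={
            7: PositionConsequence(7, "corrective", "ACA", "GCA"),
            9: PositionConsequence(9, "synonymous", "ACA", "ACG"),
            12: PositionConsequence(12, "synonymous", "CCA", "CCG"),
        },
    )
    return LocusFixture("hbb_s", spec, target=target)


def _pcsk9_intron1() -> LocusFixture:
    # Splice-donor disruption layout: therapeutic adenine at +6 with a
    # noncoding bystander adenine immediately 5' of the protospacer (-1).
    protospacer = "CTGCTACGTCGTCGTCGTCG"
    flank5 = "GTCCTCCTGGTCCTCCTGGTCCTCCTGGA"  # ends with the -1 adenine
    flank3 = "CTCCTGGTCCTCCTGGTCCTCCTGGTCC"
    pam = "TGG"
    reference = flank5 + protospacer + pam + flank3
    spec = ProtospacerSpec(reference, len(flank5), "forward", pam=pam)
    target = TargetSpec(
        name="pcsk9_intron1",
        editable_positions=(-1, 6),
        target_position=6,
        consequences={
            -1: PositionConsequence(-1, "noncoding"),
            6: PositionConsequence(6, "corrective"),
        },
    )
    return LocusFixture("pcsk9_intron1", spec, target=target)


def _stop_egfp_reporter() -> LocusFixture:
    # 27-nt insert between ATG and the EGFP ORF; the in-frame TGA stop sits
    # at protospacer positions +5..+7 so the +7 A->G edit (TGA->TGG)
    # restores translation; an adjacent adenine sits at +8.
    insert = "CTGCACTGAACTGGCACTCTGGGGGCC"
    egfp_start = "GTGAGCAAGGGCGAGGAG"
    reference = "ATG" + insert + egfp_start
    spec = ProtospacerSpec(reference, 5, "forward", pam="GGG")
    reporter = ReporterConstruct(insert=insert, spec=spec, insert_start=3)
    return LocusFixture("stop_egfp_reporter", spec, reporter=reporter)


def _aavs1_like() -> LocusFixture:
    # Generic safe-harbour-style site with editable adenines at +4, +6 and
    # +7, used for product-purity simulations (single vs dual vs triple
    # editing combinations).
    protospacer = "CTGATAACGTCGTCGTCGTC"
    flank5 = "GTCCTCCTGGTCCTCCTGGTCCTCCTGGTC"
    flank3 = "CTCCTGGTCCTCCTGGTCCTCCTGGTC"
    pam = "TGG"
    reference = flank5 + protospacer + pam + flank3
    spec = ProtospacerSpec(reference, len(flank5), "forward", pam=pam)
    return LocusFixture("aavs1_like", spec)


_FIXTURES = {
    "aavs1_like": _aavs1_like,
    "hfe_c282y": _hfe_c282y,
    "hbb_s": _hbb_s,
    "pcsk9_intron1": _pcsk9_intron1,
    "stop_egfp_reporter": _stop_egfp_reporter,
}


def make_locus_fixture(name: str) -> LocusFixture:
    """Build one of the named synthetic locus fixtures.

    Available: ``hfe_c282y``, ``hbb_s``, ``pcsk9_intron1``,
    ``stop_egfp_reporter``. Amplicons are synthetic stand-ins that honour
    the published protospacer layouts, not genomic sequence.
    """
    try:
        return _FIXTURES[name]()
    except KeyError:
        raise SimulationError(
            f"unknown fixture {name!r}; choose from {sorted(_FIXTURES)}"
        ) from None


def edit(position: int, ref: str = "A", alt: str = "G") -> EditCall:
    """Convenience constructor for the ubiquitous A>G edit call."""
    return EditCall(position, ref, alt)


def combo(*positions: int, ref: str = "A", alt: str = "G") -> Combo:
    """A combo of A>G edits at the given protospacer positions."""
    return combo_key(EditCall(p, ref, alt) for p in positions)
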