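"""Packaged fixture data: deaminase sequences and locus target specs."""

from __future__ import annotations

from importlib import resources
from pathlib import Path

from .io import read_fasta
from .outcomes import TargetSpec


def data_path(filename: str) -> Path:
    return Path(resources.files("abescan").joinpath("data", filename))  # type: ignore[arg-type]


def tada8e() -> str:
    """Synthetic stand-in for the TadA-8e deaminase (167 aa).

    A constructed scaffold, not the published sequence: it honours the
    residue identities the library rules depend on (F84, V106, 109S, 111R,
    119N, 122N, 147D, 149Y, P152) and differs from the ancestral stand-in
    at exactly the six active-site-region positions.
    """
    return read_fasta(data_path("tada8e_synthetic.fasta"))[0][1]


def tada710() -> str:
    """Synthetic stand-in for the ancestral TadA-7.10 comparison sequence."""
    return read_fasta(data_path("tada710_synthetic.fasta"))[0][1]


def target_spec(name: str) -> TargetSpec:
    """Load a packaged locus TargetSpec (hfe_c282y, hbb_s, pcsk9_intron1)."""
    return TargetSpec.from_yaml(data_path(f"{name}.yaml"))
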