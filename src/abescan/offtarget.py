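"""On- vs off-target specificity comparison with background subtraction.

Each site (the intended protospacer or a partially homologous off-target
locus) is summarised by the maximum per-position A-to-G frequency across its
protospacer, optionally net of the same quantity measured in untreated
control cells; an editor's specificity is the share of its net editing that
lands on target.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .quant import AlleleTable, QuantError, per_position_frequencies

ROLES = ("on_target", "off_target", "control_locus")


class OffTargetError(ValueError):
    pass


@dataclass(frozen=True)
class SiteResult:
    site_id: str
    role: str
    editor_id: str
    freq: float
    control_freq: float = 0.0

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise OffTargetError(f"unknown site role {self.role!r}")
        for value in (self.freq, self.control_freq):
            if not 0 <= value <= 1:
                raise OffTargetError("frequencies must lie in [0, 1]")

    @property
    def net_freq(self) -> float:
        return max(self.freq - self.control_freq, 0.0)


def site_frequency(
    table: AlleleTable, position: int | None = None
) -> float:
    """Site-level editing frequency: the maximum per-position A>G frequency
    over the site's quantification window, or the frequency at one chosen
    ``position``."""
    freq = per_position_frequencies(table, "A", "G")
    if position is not None:
        if position not in freq.freqs:
            raise OffTargetError(
                f"position {position} is not an applicable adenine at this site"
            )
        return freq.freqs[position]
    if not freq.freqs:
        raise OffTargetError("site has no applicable adenine positions")
    return freq.max_frequency()


def make_site_result(
    site_id: str,
    role: str,
    editor_id: str,
    table: AlleleTable,
    control_table: AlleleTable | None = None,
    position: int | None = None,
) -> SiteResult:
    freq = site_frequency(table, position)
    control = site_frequency(control_table, position) if control_table else 0.0
    return SiteResult(site_id, role, editor_id, freq, control)


def specificity_summary(on: SiteResult, ots: Sequence[SiteResult]) -> dict:
    """Net on-target frequency, net off-target frequencies and the on:OT
    specificity ratio net_on / (net_on + sum(net_OT)).

    The ratio is 1.0 when no off-target editing is detected but on-target
    editing is, and None (undefined) when nothing is edited anywhere.
    """
    for site in ots:
        if site.editor_id != on.editor_id:
            raise OffTargetError(
                f"off-target site {site.site_id} belongs to editor "
                f"{site.editor_id}, not {on.editor_id}"
            )
    net_on = on.net_freq
    net_ots = {s.site_id: s.net_freq for s in ots}
    total_ot = sum(net_ots.values())
    if net_on == 0 and total_ot == 0:
        ratio = None
    else:
        ratio = net_on / (net_on + total_ot)
    return {
        "editor_id": on.editor_id,
        "on_site": on.site_id,
        "net_on_target": net_on,
        "net_off_target": net_ots,
        "specificity_ratio": ratio,
    }
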