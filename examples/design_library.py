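"""Enumerate a deaminase variant library from the three sub-library rules
plus ancestral back-mutations, and emit clonable oligos.

Run: python examples/design_library.py
"""

from Bio.Seq import Seq

import abescan as ab
from abescan import resources
from abescan.library import AminoAcidVariant, back_translate, emit_oligos

parent = resources.tada8e()        # modern deaminase (synthetic stand-in)
ancestral = resources.tada710()    # ancestral comparison sequence

scan = ab.enumerate_range_scan(parent, 106, 157)
saturation = ab.enumerate_site_saturation(parent, [111, 119, 149])
swaps = ab.enumerate_charge_swap(
    parent, [(109, "S"), (111, "R"), (119, "N"), (122, "N"), (147, "D"), (149, "Y")]
)
print(f"range scan 106-157:      {len(scan):5d} variants (19 per position + identity)")
print(f"site saturation x3:      {len(saturation):5d} variants (full 20^3 product)")
print(f"same-charge swaps:       {len(swaps):5d} variants at six residues")

# ancestral back-mutation around three hypothetical screen hits: each seed
# plus its two nearest ancestor-differing residues, singly and combined
seeds = [
    AminoAcidVariant.build(parent, [(p, parent[p - 1], "W")], "screen_hit")
    for p in (112, 121, 148)
]
back = ab.enumerate_back_mutations(seeds, parent, ancestral)
print(f"back-mutation variants:  {len(back):5d} (3 per single-substitution seed)")

# oligos: parent CDS with swapped codons, avoiding an internal BsmBI site
cds = back_translate(parent)
oligos, rejected = emit_oligos(back, cds)
ok = all(
    str(Seq(o.dna).translate())
    == next(v for v in back if v.variant_id == o.variant_id).apply(parent)
    for o in oligos
)
print(f"oligos emitted:          {len(oligos):5d} (translation round-trip ok: {ok}, "
      f"rejected: {len(rejected)})")
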