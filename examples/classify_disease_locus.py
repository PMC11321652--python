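"""Classify editing outcomes at a disease-correction locus.

The hereditary-hemochromatosis fixture places the therapeutic adenine at
protospacer +5 with missense-risk bystander adenines at +1 and +8. Reads
are partitioned into precise correction (target only), bystander-missense,
benign-bystander ("other") and unedited, and purity ratios compare the
precise product with its dual-edited competitors.

Run: python examples/classify_disease_locus.py
"""

import abescan as ab
from abescan.outcomes import combo_distribution, purity_ratio
from abescan.simulate import SimProfile, combo

fx = ab.make_locus_fixture("hfe_c282y")

# a high-purity engineered editor: 90% precise correction, small
# missense-bystander leakage at +8 and +1
profile = SimProfile(
    spec=fx.spec,
    combo_dist={
        frozenset(): 0.05,
        combo(5): 0.90,
        combo(5, 8): 0.03,
        combo(1, 5): 0.02,
    },
    error_rate=0.001,
    n_reads=20_000,
    seed=5,
)
table = ab.align_and_call(ab.simulate_amplicon_reads(profile), fx.spec)
table = ab.project_allele_table(table, fx.target.editable_positions)
summary = ab.classify_outcomes(table, fx.target)

print(f"locus: {fx.target.name} (editable adenines "
      f"{fx.target.editable_positions}, target +{fx.target.target_position})")
print(f"  precise correction:  {summary.precise:6.2%}  (edited at +5 only)")
print(f"  bystander missense:  {summary.bystander_missense:6.2%}  (any combo touching +1 or +8)")
print(f"  wild type:           {summary.wild_type:6.2%}  (unedited)")

dist = combo_distribution(table, {5, 8})
ratio = purity_ratio(dist, {5}, {5, 8})
print(f"\npurity, single +5 vs dual +5&+8: {ratio:6.2%}")
print("values near 100% mean the editor rarely co-edits the +8 bystander")

rows = ab.bystander_report(table, fx.target)
print("\nbystander frequencies:")
for row in rows:
    print(f"  position {row['position']:+d}: {row['frequency']:6.2%} ({row['consequence']})")
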