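"""Compare on- and off-target editing for one editor with background
subtraction from untreated controls.

Run: python examples/offtarget_specificity.py
"""

import abescan as ab
from abescan.offtarget import make_site_result, specificity_summary
from abescan.simulate import SimProfile, combo

on_spec = ab.make_locus_fixture("aavs1_like").spec
ot_spec = ab.make_locus_fixture("hbb_s").spec


def quantify(spec, dist, seed):
    profile = SimProfile(
        spec=spec, combo_dist=dist, error_rate=0.001, n_reads=10_000, seed=seed
    )
    return ab.align_and_call(ab.simulate_amplicon_reads(profile), spec)


# treated and untreated (control) tables per site
on = quantify(on_spec, {frozenset(): 0.35, combo(6): 0.65}, seed=1)
on_ctrl = quantify(on_spec, {frozenset(): 0.995, combo(6): 0.005}, seed=2)
on_site = make_site_result("AAVS1-like", "on_target", "narrow_abe", on, on_ctrl)

ot_sites = []
for i, leak in enumerate((0.05, 0.02, 0.01)):
    treated = quantify(ot_spec, {frozenset(): 1 - leak, combo(7): leak}, seed=10 + i)
    control = quantify(ot_spec, {frozenset(): 0.997, combo(7): 0.003}, seed=20 + i)
    ot_sites.append(
        make_site_result(f"OT{i + 1}", "off_target", "narrow_abe", treated, control)
    )

summary = specificity_summary(on_site, ot_sites)
print(f"editor: {summary['editor_id']}")
print(f"net on-target frequency:  {summary['net_on_target']:6.2%}")
for site, net in summary["net_off_target"].items():
    print(f"net off-target {site}:       {net:6.2%}")
print(f"specificity ratio:        {summary['specificity_ratio']:.3f}")
print("(1.0 = all detected editing is on target; ratios fall as OT editing rises)")
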