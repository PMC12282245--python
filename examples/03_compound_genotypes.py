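"""Two compound genotypes that defeat single-purpose assays.

Case A: a point variant (aCD74a, Hb Q-Thailand) in trans with the 4.2 kb
deletion, plus a heterozygous beta CD17 mutation.  The 2:1/2:1 dosage ratios
plus the mutation peaks pin a unique genotype.

Case B: a point variant (aWSa) in trans with the SEA whole-cluster deletion,
plus a beta CD37 mutation.  The deletion halves every dosage amplicon, so the
ratios look wild-type (1:1/1:1) and only the breakpoint peak reveals it; and
because the panel carries no CD37 wild-type control, the beta side cannot be
resolved: the call is honestly AMBIGUOUS between CD37 het and hom.
"""

import cefacall as cc
from cefacall.genotyper import get_catalog

panel = cc.default_panel()
catalog = get_catalog(panel)
zero = cc.zero_noise_params()

for title, label in (
    ("Case A", "aCD74a/-a4.2;bCD17/bN"),
    ("Case B", "aWSa/--SEA;bCD37/bN"),
):
    sample = cc.simulate_peak_table(label, panel, zero, seed=1)
    call = cc.call_sample(sample.peak_table, panel, catalog)
    m = call.measurement
    print(f"{title}: truth {label}")
    print(f"  a1/a2 = {m.a_ratio:g}, Y1/Y2 = {m.y_ratio:g}, "
          f"class = {call.evidence.cnv.class_name}")
    print(f"  markers: {sorted(call.evidence.markers_present) or '-'}  "
          f"mutations: {sorted(call.evidence.mutations_present)}")
    print(f"  zygosity evidence: "
          f"{ {k: v for k, v in call.evidence.zygosity.items() if v != 'ABSENT'} }")
    print(f"  -> {call.status}: {call.labels(panel)}")
    if call.qc_flags:
        print(f"  flags: {call.qc_flags}")
    print()
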