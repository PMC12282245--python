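"""The dosage copy model: per-allele amplicon copies and theoretical ratios.

Each alpha-cluster allele carries an integer number of amplifiable copies of
the four dosage amplicons (alpha1, alpha2, Y1, Y2).  A diploid genotype sums
the two alleles' copies, and the alpha1/alpha2 and Y1/Y2 peak-height ratios
follow directly.  Printed below: the six validated heterozygote-with-normal
configurations; e.g. 2:1 with 1:2 pins the 3.7 kb single-gene deletion, while
1:1 with 1:3 is the HKaa rearrangement's signature.
"""

import cefacall as cc

panel = cc.default_panel()

print(f"{'genotype':24s} {'a1,a2,Y1,Y2 copies':>20s} {'a1/a2':>8s} {'Y1/Y2':>8s}")
for variant in ("aa", "-a3.7", "-a4.2", "aaa_anti3.7", "aaa_anti4.2", "HKaa"):
    pair = (variant, "aa")
    copies = cc.expected_copy_numbers(pair, panel)
    ratios = cc.expected_ratio(pair, panel)
    copy_str = ",".join(str(copies[t]) for t in ("a1", "a2", "Y1", "Y2"))
    print(f"{variant + '/aa':24s} {copy_str:>20s} "
          f"{str(ratios.a_ratio):>8s} {str(ratios.y_ratio):>8s}")

print()
print("Whole-cluster deletion in trans with a point variant keeps 1:1 ratios")
print("(half the signal everywhere, which cancels in the ratios):")
r = cc.expected_ratio(("aWSa", "--SEA"), panel)
print(f"  aWSa/--SEA -> a1/a2 = {r.a_ratio}, Y1/Y2 = {r.y_ratio}")
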