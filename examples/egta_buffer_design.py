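"""Designing free-Ca2+/Mg2+ levels with EGTA (MaxChelator-style).

Solves the H/Ca/Mg-EGTA equilibrium for the printed bath recipes and,
inversely, finds the CaCl2 total needed to clamp free Ca2+ at a target
level in a 2 mM EGTA bath.
"""

from vactrace import design_total_for_target_free, solve_equilibrium
from vactrace.solutions import egta_buffered_bath

print("forward solve: free ion levels of EGTA-buffered baths (pH 7)")
for cacl2, mgcl2, what in [(2.08, 2.0, "free Ca2+"), (1.84, 2.0, "free Ca2+"),
                           (1.04, 2.0, "free Ca2+")]:
    st = solve_equilibrium(egta_buffered_bath(cacl2_mM=cacl2, mgcl2_mM=mgcl2))
    print(f"  2 mM EGTA + {cacl2:.2f} mM CaCl2 + {mgcl2:g} mM MgCl2 "
          f"-> {what} = {st.free_ca_uM:7.2f} uM")
for mgcl2 in (10.44, 2.11):
    st = solve_equilibrium(egta_buffered_bath(cacl2_mM=0.0, mgcl2_mM=mgcl2))
    print(f"  2 mM EGTA + {mgcl2:.2f} mM MgCl2            "
          f"-> free Mg2+ = {st.free_mg_mM:6.3f} mM")
print("  -> EGTA binds Ca2+ ~10^5-fold more tightly than Mg2+ at pH 7, so")
print("     a mM-scale CaCl2 total sets a uM-scale free level, while MgCl2")
print("     stays almost unbuffered.")

print("\ninverse design: CaCl2 total for a target free Ca2+")
for target_uM in (100.0, 10.0, 1.0):
    total = design_total_for_target_free(target_uM * 1e-6, "Ca")
    print(f"  target {target_uM:6.1f} uM -> add {total:.3f} mM CaCl2")
print("  -> these are the totals a chelator calculator would prescribe for")
print("     a 2 mM EGTA / 2 mM MgCl2 bath at pH 7.")
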