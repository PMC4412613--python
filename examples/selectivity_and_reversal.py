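"""Reversal potentials and anion selectivity of a vacuolar channel.

Builds the BTP-buffered nitrate/chloride media used in tonoplast
patch-clamp work, computes the activity-corrected NO3- Nernst potential
across a tenfold gradient, and inverts the Goldman-Hodgkin-Katz equation
at a measured reversal potential to obtain the NO3-/Cl- permeability
ratio.
"""

from vactrace import fit_permeability_ratio, ghk_reversal_potential, nernst_potential
from vactrace.solutions import btp_acid_solution

# tenfold NO3- gradient: 200 mM HNO3 on the vacuolar side (pipette),
# 20 mM on the cytoplasmic side (bath), both BTP-buffered
vac = btp_acid_solution("NO3", acid_mM=200, btp_mM=101, pH=5.0)
cyt = btp_acid_solution("NO3", acid_mM=20, btp_mM=16, pH=7.0)

e_no3 = nernst_potential("NO3", cyt, vac)
e_ideal = nernst_potential("NO3", cyt, vac, model="ideal")
print(f"E_NO3 (activity-corrected) = {e_no3:6.1f} mV")
print(f"E_NO3 (concentrations)     = {e_ideal:6.1f} mV")
print("  -> the voltage at which NO3- flux reverses; activity corrections")
print("     pull it several mV off the ideal-solution Nernst value.")

# selectivity: vacuolar Cl- vs cytoplasmic NO3-, reversal measured at +26.6 mV
vac_cl = btp_acid_solution("Cl", acid_mM=200, btp_mM=82, pH=5.0)
cyt_no3 = btp_acid_solution("NO3", acid_mM=200, btp_mM=160, pH=7.0)
res = fit_permeability_ratio(26.6, "NO3", "Cl", cyt_no3, vac_cl)
print(f"\nP_NO3/P_Cl = {res.permeability_ratio:.2f} at E_rev = +26.6 mV")
e_check = ghk_reversal_potential(
    [("NO3", res.permeability_ratio), ("Cl", 1.0)], cyt_no3, vac_cl)
print(f"GHK check: ratio reproduces E_rev = {e_check:.2f} mV")
print("  -> the channel passes nitrate about three times better than chloride.")
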