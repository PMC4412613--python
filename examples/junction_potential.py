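"""Liquid-junction potential estimates for patch-clamp solution pairs.

Henderson-equation estimates of the offset at the pipette/bath junction;
these are the corrections folded into the command voltages (e.g. a
protocol nominally spanning -100..+80 mV is recorded at -94..+86 mV
after a +6 mV correction).
"""

from vactrace import henderson_junction_potential
from vactrace.solutions import btp_acid_solution, simple_salt_solution

kcl_100 = simple_salt_solution("100 mM KCl", "K", "Cl", 100.0)
kcl_10 = simple_salt_solution("10 mM KCl", "K", "Cl", 10.0)
e = henderson_junction_potential(kcl_100, kcl_10)
print(f"KCl 100 mM pipette | 10 mM bath: LJP = {e:+.2f} mV")
print("  -> small, because K+ and Cl- mobilities nearly match.")

pipette = btp_acid_solution("NO3", acid_mM=200, btp_mM=101, pH=5.0)
bath = btp_acid_solution("NO3", acid_mM=20, btp_mM=16, pH=7.0)
e = henderson_junction_potential(pipette, bath)
print(f"\n200 mM HNO3/BTP pipette | 20 mM HNO3/BTP bath: LJP = {e:+.2f} mV")
print("  -> a tenfold salt gradient with a slow buffer cation (BTP ~ TRIS")
print("     mobility) produces a sizeable offset; swapping the solutions")
print(f"     flips the sign: {henderson_junction_potential(bath, pipette):+.2f} mV.")
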