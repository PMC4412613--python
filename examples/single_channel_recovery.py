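"""Simulate a multi-channel patch and recover its gating parameters.

Generates a 30 s cytoplasm-out recording of four identical 72.75 pS
channels with open probability 0.21 at +40 mV (10 kHz sampling, 2 kHz
Bessel filter, 0.5 pA baseline noise), then runs the amplitude-histogram /
Gaussian-mixture pipeline to recover the channel count N, the per-channel
open probability Po, and the unitary current and chord conductance.
"""

from vactrace import GatingModel, analyze_trace, simulate_constant_voltage

model = GatingModel.from_open_probability(
    0.21, n_channels=4, unitary_conductance_pS=72.75, reversal_mV=0.0)
trace = simulate_constant_voltage(model, voltage_mV=40.0, duration_s=30.0,
                                  noise_sd_pA=0.5, seed=1)
print(f"simulated {trace.duration_s:.0f} s at {trace.voltage_mV:+.0f} mV, "
      f"{trace.n_samples} samples, truth: N=4, Po=0.21, g=72.75 pS")

res = analyze_trace(trace, bin_width_pA=0.1, max_channels=6)
print(f"recovered N  = {res.n_channels} channels "
      "(peak count of the amplitude histogram minus baseline)")
print(f"recovered Po = {res.open_probability:.3f} "
      "(area-weighted NPo / N from the Gaussian peaks)")
print(f"recovered i  = {res.unitary_current_pA:+.2f} pA "
      "(mean spacing of adjacent peak centres)")
print(f"recovered g  = {res.conductance_pS:.1f} pS "
      "(chord conductance i/V at the applied voltage)")
print("-> all four quantities should sit within a few percent of the truth;")
print("   the small Po scatter is Monte-Carlo error of a single 30 s patch.")
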