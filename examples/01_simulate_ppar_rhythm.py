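"""Simulate the clock-forced PPARalpha mRNA equation over several days.

Builds the cosinor BMAL1 drive (mesor 1, amplitude 0.5, peak 10 AM), runs the
8-parameter kinetic model for the lean-control ground truth, and prints the
entrained one-period trajectory at the six experimental clock times.
"""

import numpy as np

import pparclock as pc

forcing = pc.default_bmal1_forcing()
params = pc.stepwise_degradation_params()[("lean", "control")]

traj = pc.periodic_solution(params, forcing)
print("entrained PPARalpha mRNA (relative expression) per clock hour:")
for t in (6.0, 10.0, 14.0, 18.0, 22.0, 26.0):
    x = float(np.interp(t, traj.times, traj.values))
    print(f"  {t % 24:4.0f}h  X = {x:6.3f}   B = {forcing(t):5.3f}")

peak = traj.times[np.argmax(traj.values)] % 24
print(f"\npeak expression at ~{peak:.1f} h; the mRNA rhythm lags the BMAL1")
print("drive (peak 10 AM) because clearance filters the synthesis waveform.")
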