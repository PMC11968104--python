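"""Behavioral and physiology score formulas on worked inputs.

Computes the SING climbing score from tube counts, the olfactory preference
index from a two-odor choice, the daily nicotine dose from food dosing, and
activity metrics from synthetic fluorescence traces with planted spikes.
"""

import numpy as np

from vulnscan import phenoscores, synthgen

# SING: 2 flies in each of tubes 1..5 -> (2+4+6+8+10)/(10*5) = 0.6
score = phenoscores.sing_score(phenoscores.TubeCounts((2, 2, 2, 2, 2)))
print(f"SING score: {score:.2f}  (1 = all flies climb to the top tube, 0.2 = none leave tube 1)")

# olfactory preference: 30 vs 20 of 50 flies -> 0.2 toward odor A
pref = phenoscores.preference_index(30, 20, 50)
print(f"preference index: {pref:+.2f}  (+1 = all choose odor A, 0 = indecisive)")

# nicotine feeding: 0.2 per ml food, ~1 ul food/day, ~0.1 mg fly
dose = phenoscores.nicotine_dose(0.2, 1.0, 0.1)
print(f"nicotine dose: {dose:.3f} ug per mg body weight per day (~10 cigarettes/day for a smoker)")

# calcium traces: 30 planted spike frames out of 300 at 5 Hz
traces, truth = synthgen.generate_traces(
    n_rois=3, frame_rate=5.0, n_frames=300, baseline=10.0,
    spike_times=list(range(100, 130)), spike_amp=5.0, noise_sd=0.02, seed=9,
    stimulus_frame=50,
)
dff = phenoscores.dff_trace(traces, baseline_mode="prestim_mean5")
fraction, amplitude = phenoscores.activity_metrics(dff, baseline_frames=np.arange(0, 50))
print(
    f"activity fraction: {fraction.mean():.3f} (planted {truth['active_fraction']:.3f}), "
    f"max dF/F amplitude: {amplitude.mean():.2f} (planted spike = 0.5 of baseline)"
)
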