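"""Simulate the rat's trajectory and the frozen spatial inputs.

Builds a 5-lap session on the 200 cm track (triangular 15/80 cm/s target
speed profile, smooth multiplicative speed noise) and the bank of 128
weakly spatially tuned features, then prints summary numbers.
"""

import dataclasses

import numpy as np

import thetasweeps as ts

track = dataclasses.replace(ts.TrackSpec(), n_laps=5)
traj = ts.simulate_trajectory(track, ts.SpeedProfile(), ts.SpeedNoiseSpec(), seed=1)
bank = ts.generate_features(track, ts.FeatureParams(), seed=2)

lap_times = [
    (traj.lap_id == lap).sum() * traj.dt for lap in range(track.n_laps)
]
print(f"session: {traj.t[-1]:.1f} s, {traj.n_steps} steps of {traj.dt*1e3:.0f} ms")
print("lap durations (s):", np.round(lap_times, 2))
print(
    f"speed range {traj.v.min():.1f}-{traj.v.max():.1f} cm/s "
    "(profile 15-80 cm/s times noise 0.5-1.5)"
)
mid = ts.target_speed(100.0, ts.SpeedProfile(), track)
print(f"target speed mid-track: {mid:.0f} cm/s; at the ends: "
      f"{ts.target_speed(0.0, ts.SpeedProfile(), track):.0f} cm/s")
print(
    f"feature bank: {bank.n_features} features x {bank.n_bins} one-cm bins, "
    f"each scaled to [{bank.values.min():.0f}, {bank.values.max():.0f}], "
    f"smoothing stds {bank.smoothing_stds.min():.1f}-{bank.smoothing_stds.max():.1f} cm"
)
# The lap-to-lap variability is what the Hebbian anchoring must average
# over; the features are the fixed sensory scaffold it anchors to.
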