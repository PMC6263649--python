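"""Simulate a labeled accelerometer session with gait-cycle ground truth.

Builds a 100 s session (walk / stand / walk / run) for a front-pocket
sensor in a free orientation, then prints what a real data collection
would have to annotate by hand: activity segments and one interval per
gait cycle. The cycle count is the true step count of the instrumented
side.
"""

import numpy as np

from stridekit import GaitModelParams, compose_session, magnitude, random_rotation

rng = np.random.default_rng(0)
params = GaitModelParams(
    stride_frequency_hz=1.1,     # cadence of the instrumented leg (Hz)
    noise_sd=0.05,               # sensor + soft-tissue noise (g)
    placement="FrontPocket",     # Group I: one signal period per cycle
    orientation=random_rotation(rng),
)

plan = [("walk", 40.0), ("stand", 15.0), ("walk", 30.0), ("run", 15.0)]
rec, truth = compose_session(plan, rate_hz=200.0, seed=1, walk_params=params)

print(f"session: {rec.duration_s:.0f} s at {rec.rate_hz:.0f} Hz, {rec.n} samples")
print("label segments:")
for start, end, activity in rec.labels:
    print(f"  {start:6.1f}-{end:6.1f} s  {activity}")
print(f"annotated gait cycles (true steps): {truth.cgt}")
mag = magnitude(rec).samples
print(f"magnitude mean {mag.mean():.3f} g (gravity), std {mag.std():.3f} g")
# 40 s + 30 s of walking at 1.1 Hz -> floor(40*1.1) + floor(30*1.1) = 77 cycles
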