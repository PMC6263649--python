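"""Frame-level walk detection with the five detectors.

Simulates a mixed session, cuts the low-passed magnitude into 3 s frames
with 0.5 s overlap, and compares the variance threshold (THR), walk-band
spectral energy (STFT), wavelet detail energy (DWT) and the two
machine-learning classifiers (k-NN, SVM-RBF with 10-fold CV). Accuracy
is the fraction of frames whose walk/non-walk state is correct.
"""

import numpy as np

from stridekit import GaitModelParams, compose_session, frame, magnitude
from stridekit import walk_detection as wd
from stridekit.features import extract_features
from stridekit.preprocess import WD_LOWPASS_HZ, lowpass

plan = [("walk", 60.0), ("stairs_up", 30.0), ("run", 30.0),
        ("ride", 30.0), ("stand", 30.0), ("walk", 30.0)]
rec, _ = compose_session(plan, rate_hz=200.0, seed=2,
                         walk_params=GaitModelParams(noise_sd=0.05))

mag = magnitude(rec)
filt = lowpass(mag.samples, WD_LOWPASS_HZ, rec.rate_hz)
fset = frame(mag, 3.0, 0.5)
frames = [filt[s:e] for s, e, _ in fset.frames]
y = np.array([1 if lbl == "walk" else 0 for lbl in fset.labels()])
print(f"{len(fset)} frames, {y.sum()} walking")

model = wd.thr_fit(frames, y)
pred = wd.thr_predict(frames, model)
print(f"THR : accuracy {np.mean(pred.states == y):.3f} "
      f"(variance threshold {model.threshold:.4f})")

pred, _ = wd.stft_wd(frames, rec.rate_hz, labels=y)
print(f"STFT: accuracy {np.mean(pred.states == y):.3f} (band [0.66, 1.66] Hz)")

pred, _ = wd.dwt_wd(filt, fset, labels=y)
print(f"DWT : accuracy {np.mean(pred.states == y):.3f} (db10 detail levels 7-8)")

X = np.vstack([extract_features(f, rec.rate_hz) for f in frames])
for algo in ("knn", "svm"):
    _, acc = wd.ml_wd_fit_predict(X, y, algo=algo, folds=10, seed=0)
    print(f"{algo.upper():4s}: accuracy {acc:.3f} (10-fold CV)")
# The ML detectors should dominate: they see the whole feature vector,
# the signal detectors one statistic each.
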