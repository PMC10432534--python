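"""Derive the statistical feature tables for the SVM/FFN models.

Computes mean and population SD of each of the six normalised signals (12
base features) and of their central-difference time derivatives (24 in
total) and writes both tables as CSV.  Prints the features that separate
the classes most, previewing why derivative features help the kernel
models.

Run from the repository root:  python analysis/03_features.py
"""

import numpy as np
import pandas as pd

from matmotion import feature_names, io
from matmotion.pipeline import featurize

signals = io.read_signals("results/data/signals.h5")
manifest = pd.read_csv("results/data/manifest.csv")
f12, f24 = featurize(signals)
io.write_features("results/features12.csv", manifest, f12, feature_names(False))
io.write_features("results/features24.csv", manifest, f24, feature_names(True))
print(f"wrote results/features12.csv ({f12.shape[1]} features) and "
      f"results/features24.csv ({f24.shape[1]} features)")

pos = (manifest["label"] == "FMplus").to_numpy()
names = feature_names(True)
sep = []
for k, name in enumerate(names):
    a, b = f24[pos, k], f24[~pos, k]
    pooled = np.sqrt((a.var() + b.var()) / 2)
    sep.append((abs(a.mean() - b.mean()) / max(pooled, 1e-12), name))
print("most class-separating features (|Cohen's d|):")
for d, name in sorted(sep, reverse=True)[:5]:
    print(f"  {name}: d = {d:.2f}")
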