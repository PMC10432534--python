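"""Encode the cohort's pressure frames into the six motion signals.

Each (500, 32, 32) snippet is cropped to the active 29x26 area, split into
shoulder/head (12x26) and hip (17x26) regions, reduced to per-frame centre
of pressure and mean pressure, smoothed (5-frame moving average) and
jointly min-max normalised — 500 x 6 per snippet.  Writes
results/data/signals.h5 and a per-class summary of signal variability.

Run from the repository root:  python analysis/02_encode.py
"""

import time

import numpy as np

from matmotion import io
from matmotion.pipeline import encode_cohort

t0 = time.time()
snippets, manifest = io.read_snippets("results/data")
signals = encode_cohort(snippets)
io.write_signals("results/data", signals)

print(f"encoded {signals.shape[0]} snippets -> {signals.shape[1]} x "
      f"{signals.shape[2]} signals in {time.time() - t0:.0f}s")
for label in ("FMminus", "FMplus"):
    mask = (manifest["label"] == label).to_numpy()
    sd = signals[mask].std(axis=1).mean()
    print(f"  {label}: mean within-snippet signal SD {sd:.3f}")
print("wrote results/data/signals.h5")
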