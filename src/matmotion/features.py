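"""Statistical summary features for the kernel and feed-forward models.

Each encoded snippet is summarised by the mean and (population) standard
deviation of its six motion signals, optionally extended by the same two
statistics of the signals' first time derivatives — 12 or 24 features.
Derivatives are central finite differences scaled by the 0.01 s sampling
interval, one-sided at the ends.
"""

from __future__ import annotations

import numpy as np

from .encode import SAMPLING_HZ, SIGNAL_NAMES, MotionSignals

DT = 1.0 / SAMPLING_HZ


def derivative(series: np.ndarray, dt: float = DT) -> np.ndarray:
    """First time derivative, length-preserving.

    Central differences at interior points, one-sided at the edges.
    """
    series = np.asarray(series, float)
    if series.size < 2:
        raise ValueError("need at least 2 samples to differentiate")
    return np.gradient(series, dt)


def feature_names(include_derivatives: bool = False) -> list[str]:
    names = [f"{stat}_{sig}" for sig in SIGNAL_NAMES for stat in ("mean", "sd")]
    if include_derivatives:
        names += [f"{stat}_d{sig}" for sig in SIGNAL_NAMES for stat in ("mean", "sd")]
    return names


def extract_features(signals: MotionSignals,
                     include_derivatives: bool = False) -> np.ndarray:
    """Mean/SD feature vector of one snippet: 12 values, or 24 with derivatives.

    Ordering: (mean, SD) per signal in the order x_t, y_t, p_t, x_b, y_b,
    p_b, then the same over the derivatives.  SD is the population standard
    deviation.  Raises on non-finite input.
    """
    arr = signals.as_array()
    if not np.all(np.isfinite(arr)):
        raise ValueError("signals contain non-finite values")
    feats = np.empty(24 if include_derivatives else 12)
    feats[0:12:2] = arr.mean(axis=0)
    feats[1:12:2] = arr.std(axis=0)
    if include_derivatives:
        d = np.stack([derivative(arr[:, k]) for k in range(6)], axis=1)
        feats[12:24:2] = d.mean(axis=0)
        feats[13:24:2] = d.std(axis=0)
    return feats
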