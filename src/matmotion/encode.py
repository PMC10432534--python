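"""Motion encoding: 500x32x32 pressure snippets -> six 500-step signals.

The encoder reduces each pressure-image sequence to centre-of-pressure
(CoP) and mean-pressure time series.  Per frame the 32x32 grid is cropped
to its active 29x26 area (rows 1-29, columns 4-29, 1-based inclusive) and
split head-to-feet into a 12x26 top area (shoulders/head) and a 17x26
bottom area (hips).  For each area the CoP coordinates ``x`` (row), ``y``
(column) and the mean pressure ``p`` are first spatial moments:

    x = sum_i i * p(i, j) / sum_ij p(i, j)
    y = sum_j j * p(i, j) / sum_ij p(i, j)
    p = sum_ij p(i, j) / (m * n)

with 1-based area indices.  The six signals are smoothed with a centred
5-frame moving average and min-max normalised to [0, 1], the four position
signals sharing one denominator (the largest of their ranges) and the two
pressure signals sharing another, so that relative amplitudes between body
parts are preserved while infant size and weight are divided out.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

# Active area of the 32x32 mat, 0-based half-open: rows 1..29 and columns
# 4..29 in the 1-based inclusive convention.
CROP_ROWS = (0, 29)
CROP_COLS = (3, 29)
TOP_SHAPE = (12, 26)
BOTTOM_SHAPE = (17, 26)
SIGNAL_NAMES = ("x_t", "y_t", "p_t", "x_b", "y_b", "p_b")
SAMPLING_HZ = 100.0


@dataclass
class MotionSignals:
    """The six encoded signals plus the processing stage they are at."""

    x_t: np.ndarray
    y_t: np.ndarray
    p_t: np.ndarray
    x_b: np.ndarray
    y_b: np.ndarray
    p_b: np.ndarray
    stage: str = "raw"  # raw | filtered | normalised

    def as_array(self) -> np.ndarray:
        """Stack to (T, 6) in the order x_t, y_t, p_t, x_b, y_b, p_b."""
        return np.stack([self.x_t, self.y_t, self.p_t,
                         self.x_b, self.y_b, self.p_b], axis=1)

    @classmethod
    def from_array(cls, arr: np.ndarray, stage: str) -> "MotionSignals":
        arr = np.asarray(arr, float)
        if arr.ndim != 2 or arr.shape[1] != 6:
            raise ValueError("expected a (T, 6) signal array")
        return cls(*(arr[:, k] for k in range(6)), stage=stage)

    def __len__(self) -> int:
        return len(self.x_t)


def crop_and_split(frame: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Crop a 32x32 frame to 29x26 and split into top 12x26 / bottom 17x26."""
    frame = np.asarray(frame)
    if frame.shape != (32, 32):
        raise ValueError(f"expected a 32x32 frame, got {frame.shape}")
    crop = frame[CROP_ROWS[0]:CROP_ROWS[1], CROP_COLS[0]:CROP_COLS[1]]
    return crop[:TOP_SHAPE[0]].astype(float), crop[TOP_SHAPE[0]:].astype(float)


def compute_cop(area: np.ndarray) -> tuple[float, float, float]:
    """First spatial moments of one area: (x row, y column, mean pressure).

    Coordinates are 1-based along the area's own axes, so x lies in
    [1, m] and y in [1, n] whenever total pressure is positive.  An
    all-zero area is degenerate: the CoP is placed at the geometric centre
    and p = 0, with a warning logged.
    """
    area = np.asarray(area, float)
    m, n = area.shape
    total = area.sum()
    p = total / (m * n)
    if total <= 0:
        logger.warning("zero-pressure area: CoP set to geometric centre")
        return (m + 1) / 2.0, (n + 1) / 2.0, 0.0
    i = np.arange(1, m + 1, dtype=float)
    j = np.arange(1, n + 1, dtype=float)
    x = float(i @ area.sum(axis=1) / total)
    y = float(j @ area.sum(axis=0) / total)
    return x, y, float(p)


def _cop_tracks(frames: np.ndarray) -> MotionSignals:
    """Vectorised crop/split + CoP over all frames of a snippet."""
    frames = np.asarray(frames, float)
    if frames.ndim != 3 or frames.shape[1:] != (32, 32):
        raise ValueError(f"expected (T, 32, 32) frames, got {frames.shape}")
    crop = frames[:, CROP_ROWS[0]:CROP_ROWS[1], CROP_COLS[0]:CROP_COLS[1]]
    out = []
    for area in (crop[:, :TOP_SHAPE[0]], crop[:, TOP_SHAPE[0]:]):
        m, n = area.shape[1:]
        total = area.sum(axis=(1, 2))
        degenerate = total <= 0
        if degenerate.any():
            logger.warning("%d zero-pressure frames: CoP set to geometric centre",
                           int(degenerate.sum()))
        safe = np.where(degenerate, 1.0, total)
        i = np.arange(1, m + 1, dtype=float)
        j = np.arange(1, n + 1, dtype=float)
        x = np.where(degenerate, (m + 1) / 2.0, area.sum(axis=2) @ i / safe)
        y = np.where(degenerate, (n + 1) / 2.0, area.sum(axis=1) @ j / safe)
        out += [x, y, total / (m * n)]
    return MotionSignals(out[0], out[1], out[2], out[3], out[4], out[5], stage="raw")


def moving_average(series: np.ndarray, window: int = 5) -> np.ndarray:
    """Centred moving average, window truncated at the boundaries.

    Length-preserving; the edge windows shrink instead of padding, which
    avoids phase shift and artificial boundary values.
    """
    series = np.asarray(series, float)
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    if series.size < window:
        raise ValueError("series shorter than the smoothing window")
    kernel = np.ones(window)
    sums = np.convolve(series, kernel, mode="same")
    counts = np.convolve(np.ones_like(series), kernel, mode="same")
    return sums / counts


def filter_signals(signals: MotionSignals, window: int = 5) -> MotionSignals:
    """Apply the moving average to each of the six signals."""
    arr = signals.as_array()
    smoothed = np.stack([moving_average(arr[:, k], window) for k in range(6)], axis=1)
    out = MotionSignals.from_array(smoothed, stage="filtered")
    return out


def normalize(signals: MotionSignals) -> MotionSignals:
    """Joint min-max normalisation of the six signals to [0, 1].

    Each signal is shifted by its own minimum; the four position signals
    are divided by the single largest position range and the two pressure
    signals by the larger pressure range.  A zero group denominator (all
    signals in the group constant) maps that group to all-zero.
    """
    if signals.stage not in ("filtered", "raw"):
        raise ValueError("normalize expects raw- or filtered-stage signals")

    def ranges(*series: np.ndarray) -> float:
        return max(float(s.max() - s.min()) for s in series)

    pos_denom = ranges(signals.x_t, signals.x_b, signals.y_t, signals.y_b)
    prs_denom = ranges(signals.p_t, signals.p_b)

    def norm(s: np.ndarray, denom: float) -> np.ndarray:
        if denom <= 0:
            return np.zeros_like(s)
        return (s - s.min()) / denom

    return MotionSignals(
        x_t=norm(signals.x_t, pos_denom), y_t=norm(signals.y_t, pos_denom),
        p_t=norm(signals.p_t, prs_denom),
        x_b=norm(signals.x_b, pos_denom), y_b=norm(signals.y_b, pos_denom),
        p_b=norm(signals.p_b, prs_denom),
        stage="normalised",
    )


def encode_snippet(frames: np.ndarray, stage: str = "normalised",
                   window: int = 5) -> MotionSignals:
    """Full encoding pipeline for one snippet of (T, 32, 32) frames.

    Order: crop/split -> CoP per frame -> moving average -> normalisation.
    ``stage`` allows stopping early ("raw" or "filtered") for diagnostics.
    """
    signals = _cop_tracks(frames)
    if stage == "raw":
        return signals
    signals = filter_signals(signals, window)
    if stage == "filtered":
        return signals
    if stage != "normalised":
        raise ValueError(f"unknown stage {stage!r}")
    return normalize(signals)


def area_to_grid(x: float | np.ndarray, y: float | np.ndarray,
                 area: str) -> tuple[np.ndarray, np.ndarray]:
    """Convert 1-based area CoP coordinates to 0-based full-grid ones."""
    row_offset = {"top": 0, "bottom": TOP_SHAPE[0]}[area]
    return (np.asarray(x) - 1 + CROP_ROWS[0] + row_offset,
            np.asarray(y) - 1 + CROP_COLS[0])
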