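"""Synthetic pressure-mat cohort generator.

Emulates 5-second pressure-image snippets (500 frames at 100 Hz, each a
32x32 grid of 8-bit values) of a supine infant on a pressure-sensing mat.
Two contact regions produce the pressure signal: shoulders/head at the top
of the mat and hips at the bottom.  Each region is modelled as an isotropic
Gaussian pressure blob whose centre and peak pressure oscillate over time.

The two label classes differ in their motion law: snippets without fidgety
movements (``FMminus``) move at low frequency with large displacement
amplitude, snippets with fidgety movements (``FMplus``) at higher frequency
with small amplitude.  The class-conditional frequency/amplitude bands are
configurable; the defaults make the two classes spectrally disjoint so the
downstream classification task is provably solvable from the ground-truth
trajectories alone.

Every snippet carries its exact ground-truth blob trajectories, so the
centre-of-pressure encoder can be validated against the motion that was
actually rendered.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

# Grid geometry shared with the encoder: the mat is 32x32; only the area
# rows 1..29, columns 4..29 (1-based, inclusive) carries signal.
GRID_SIZE = 32
CROP_ROWS = (0, 29)   # 0-based half-open
CROP_COLS = (3, 29)
N_FRAMES = 500
SAMPLING_HZ = 100.0

LABEL_POS = "FMplus"
LABEL_NEG = "FMminus"


@dataclass(frozen=True)
class BodyModel:
    """Static geometry of one infant's contact with the mat.

    Coordinates are 0-based (row, col) grid positions; rows run head to
    feet, so the shoulder/head blob must lie above the hip blob.
    """

    top_center: tuple[float, float] = (8.0, 15.5)
    bottom_center: tuple[float, float] = (21.0, 15.5)
    blob_sd_top: float = 2.5
    blob_sd_bottom: float = 3.0
    weight_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.top_center[0] >= self.bottom_center[0]:
            raise ValueError("top blob must lie above bottom blob (smaller row)")
        if self.blob_sd_top <= 0 or self.blob_sd_bottom <= 0:
            raise ValueError("blob spreads must be positive")
        if self.weight_scale <= 0:
            raise ValueError("weight_scale must be positive")


@dataclass(frozen=True)
class MotionLaw:
    """Oscillatory motion of the two blobs for one snippet.

    Each blob centre moves as a sum of ``n_components`` sinusoids with
    frequencies inside ``freq_band`` (Hz), total displacement amplitude
    ``disp_amp`` (grid cells), plus a slow baseline drift.  Peak pressure is
    modulated by the same frequencies with relative amplitude
    ``pressure_amp``.  ``noise_sd`` is additive Gaussian sensor noise on the
    8-bit count scale.
    """

    freq_band: tuple[float, float] = (0.3, 1.0)
    disp_amp: float = 3.0
    pressure_amp: float = 0.15
    n_components: tuple[int, int] = (2, 4)
    drift_amp: float = 0.5
    drift_hz: float = 0.08
    noise_sd: float = 2.0

    def __post_init__(self) -> None:
        lo, hi = self.freq_band
        if not (0.0 < lo <= hi <= SAMPLING_HZ / 2):
            raise ValueError("frequency band must lie in (0, Nyquist]")
        if min(self.disp_amp, self.pressure_amp, self.noise_sd) < 0:
            raise ValueError("amplitudes must be non-negative")


#: Default class-conditional motion laws: low-frequency/large-amplitude for
#: the FM-absent class, high-frequency/small-amplitude for the FM-present
#: class, with disjoint frequency bands.
FM_MINUS_LAW = MotionLaw(freq_band=(0.3, 1.0), disp_amp=3.0, pressure_amp=0.20)
FM_PLUS_LAW = MotionLaw(freq_band=(1.5, 4.0), disp_amp=1.0, pressure_amp=0.08)


@dataclass(frozen=True)
class CohortConfig:
    """Shape and randomness of a synthetic cohort.

    Defaults emulate the study cohort: 45 infants, ~40 snippets each, with
    a positive-class fraction near 948/1776.
    """

    n_infants: int = 45
    snippets_per_infant: int = 40
    class_ratio: float = 948.0 / 1776.0
    law_pos: MotionLaw = FM_PLUS_LAW
    law_neg: MotionLaw = FM_MINUS_LAW
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_infants < 5:
            raise ValueError("cohort needs at least 5 infants (one per CV fold)")
        if not 0.0 < self.class_ratio < 1.0:
            raise ValueError("class_ratio must be in (0, 1)")


@dataclass
class PressureSnippet:
    """One 5-s recording: (500, 32, 32) uint8 frames + provenance."""

    frames: np.ndarray
    infant_id: str
    label: str
    seed: int = 0
    trajectories: dict | None = field(default=None, repr=False)


def render_frame(
    body: BodyModel,
    top_center: tuple[float, float],
    bottom_center: tuple[float, float],
    top_scale: float = 1.0,
    bottom_scale: float = 1.0,
    quantize: bool = True,
) -> np.ndarray:
    """Render one 32x32 pressure frame from displaced blob states.

    ``top_center``/``bottom_center`` are the displaced blob centres;
    ``*_scale`` multiply the peak pressure of each blob.  Values outside the
    active mat area are forced to zero, matching the hardware behaviour.
    Raises ``ValueError`` for centres off the grid.
    """
    frames = render_frames(
        body,
        np.asarray(top_center, float)[None, :],
        np.asarray(bottom_center, float)[None, :],
        np.array([top_scale]),
        np.array([bottom_scale]),
        quantize=quantize,
    )
    return frames[0]


def render_frames(
    body: BodyModel,
    top_centers: np.ndarray,
    bottom_centers: np.ndarray,
    top_scales: np.ndarray,
    bottom_scales: np.ndarray,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
    quantize: bool = True,
) -> np.ndarray:
    """Vectorised renderer: (T, 2) centre tracks -> (T, 32, 32) frames."""
    top_centers = np.asarray(top_centers, float)
    bottom_centers = np.asarray(bottom_centers, float)
    for name, c in (("top", top_centers), ("bottom", bottom_centers)):
        if c.min() < 0 or c.max() > GRID_SIZE - 1:
            raise ValueError(f"{name} blob centre off the 32x32 grid")

    rows = np.arange(GRID_SIZE, dtype=float)
    cols = np.arange(GRID_SIZE, dtype=float)
    peak = 160.0 * body.weight_scale  # peak counts on the 8-bit scale

    def blob(centers: np.ndarray, sd: float, scales: np.ndarray) -> np.ndarray:
        dr = rows[None, :] - centers[:, 0:1]          # (T, 32)
        dc = cols[None, :] - centers[:, 1:2]
        gr = np.exp(-0.5 * (dr / sd) ** 2)
        gc = np.exp(-0.5 * (dc / sd) ** 2)
        return peak * scales[:, None, None] * gr[:, :, None] * gc[:, None, :]

    frames = blob(top_centers, body.blob_sd_top, np.asarray(top_scales, float))
    frames += blob(bottom_centers, body.blob_sd_bottom, np.asarray(bottom_scales, float))

    if noise_sd > 0:
        if rng is None:
            raise ValueError("noise requires an rng")
        frames += rng.normal(0.0, noise_sd, frames.shape)

    # The sensor reports zero outside the active area.
    mask = np.zeros((GRID_SIZE, GRID_SIZE), bool)
    mask[CROP_ROWS[0]:CROP_ROWS[1], CROP_COLS[0]:CROP_COLS[1]] = True
    frames *= mask

    frames = np.clip(frames, 0.0, 255.0)
    if quantize:
        return np.round(frames).astype(np.uint8)
    return frames


def _sample_track(law: MotionLaw, rng: np.random.Generator, t: np.ndarray) -> np.ndarray:
    """One scalar displacement track: sum of sinusoids plus slow drift.

    The component amplitudes are normalised so the sinusoid mix has total
    amplitude ``disp_amp``; random phases give local, non-repeating
    patterns rather than a pure tone.
    """
    k = rng.integers(law.n_components[0], law.n_components[1] + 1)
    freqs = rng.uniform(*law.freq_band, size=k)
    weights = rng.uniform(0.5, 1.0, size=k)
    weights *= law.disp_amp / weights.sum()
    phases = rng.uniform(0.0, 2 * np.pi, size=k)
    track = np.sum(
        weights[:, None] * np.sin(2 * np.pi * freqs[:, None] * t[None, :] + phases[:, None]),
        axis=0,
    )
    drift_phase = rng.uniform(0.0, 2 * np.pi)
    track += law.drift_amp * np.sin(2 * np.pi * law.drift_hz * t + drift_phase)
    return track


def generate_snippet(
    body: BodyModel,
    law: MotionLaw,
    label: str,
    seed: int,
    n_frames: int = N_FRAMES,
) -> tuple[PressureSnippet, dict]:
    """Generate one snippet and its exact ground-truth trajectories.

    Deterministic for a given seed: the same seed yields bit-identical
    frames.  The returned trajectory dict holds the (T, 2) centre track and
    (T,) pressure-scale track per blob, exactly as rendered.
    """
    rng = np.random.default_rng(seed)
    t = np.arange(n_frames) / SAMPLING_HZ
    body_center = {"top": np.asarray(body.top_center), "bottom": np.asarray(body.bottom_center)}

    tracks, scales = {}, {}
    for blob_name in ("top", "bottom"):
        dr = _sample_track(law, rng, t)
        dc = _sample_track(law, rng, t)
        tracks[blob_name] = body_center[blob_name][None, :] + np.stack([dr, dc], axis=1)
        pk = rng.integers(1, 3)
        pf = rng.uniform(*law.freq_band, size=pk)
        pp = rng.uniform(0.0, 2 * np.pi, size=pk)
        mod = np.sum(np.sin(2 * np.pi * pf[:, None] * t[None, :] + pp[:, None]), axis=0) / pk
        scales[blob_name] = 1.0 + law.pressure_amp * mod

    frames = render_frames(
        body,
        tracks["top"], tracks["bottom"],
        scales["top"], scales["bottom"],
        noise_sd=law.noise_sd, rng=rng,
    )
    traj = {
        "top": tracks["top"], "bottom": tracks["bottom"],
        "top_scale": scales["top"], "bottom_scale": scales["bottom"],
    }
    snippet = PressureSnippet(frames=frames, infant_id="", label=label, seed=seed,
                              trajectories=traj)
    return snippet, traj


def _sample_body(rng: np.random.Generator) -> BodyModel:
    """Per-infant geometry: position and size vary between infants."""
    top_row = rng.uniform(6.0, 10.0)
    bottom_row = rng.uniform(18.0, 23.0)
    col = rng.uniform(13.0, 18.0)
    return BodyModel(
        top_center=(top_row, col + rng.uniform(-1, 1)),
        bottom_center=(bottom_row, col + rng.uniform(-1, 1)),
        blob_sd_top=rng.uniform(2.0, 3.0),
        blob_sd_bottom=rng.uniform(2.5, 3.5),
        weight_scale=rng.uniform(0.7, 1.3),
    )


def _vary_law(law: MotionLaw, rng: np.random.Generator) -> MotionLaw:
    """Per-snippet jitter of amplitude within +-30% of the class default."""
    return replace(
        law,
        disp_amp=law.disp_amp * rng.uniform(0.7, 1.3),
        pressure_amp=law.pressure_amp * rng.uniform(0.7, 1.3),
    )


def generate_cohort(config: CohortConfig, render: bool = True
                    ) -> tuple[list[PressureSnippet], pd.DataFrame]:
    """Generate a labelled cohort plus its manifest.

    Body geometry is sampled once per infant and reused for all of that
    infant's snippets; the motion law is sampled per snippet from the
    class-conditional defaults.  Labels are drawn i.i.d. with probability
    ``class_ratio`` for the positive class.  Fully deterministic given
    ``rng_seed``.  With ``render=False`` only the manifest is produced
    (snippet frames are None); the manifest is identical either way
    because frame rendering never consumes the cohort-level rng.
    """
    master = np.random.default_rng(config.rng_seed)
    snippets: list[PressureSnippet] = []
    rows = []
    for i in range(config.n_infants):
        infant_id = f"inf{i:03d}"
        body = _sample_body(master)
        for s in range(config.snippets_per_infant):
            positive = master.random() < config.class_ratio
            label = LABEL_POS if positive else LABEL_NEG
            law = _vary_law(config.law_pos if positive else config.law_neg, master)
            seed = int(master.integers(0, 2**31 - 1))
            if render:
                snippet, _ = generate_snippet(body, law, label, seed)
            else:
                snippet = PressureSnippet(frames=None, label=label, seed=seed,
                                          infant_id=infant_id)
            snippet.infant_id = infant_id
            snippets.append(snippet)
            rows.append({
                "snippet_id": f"{infant_id}_s{s:03d}",
                "infant_id": infant_id,
                "label": label,
                "seed": seed,
            })
    manifest = pd.DataFrame(rows)
    return snippets, manifest


def spectral_peak_frequency(track: np.ndarray, min_hz: float = 0.25) -> float:
    """Dominant frequency of a scalar track, ignoring the drift band.

    A Hann window confines the slow baseline drift to the lowest bins,
    which are excluded via ``min_hz`` so the oscillatory components
    dominate the peak.
    """
    track = np.asarray(track, float)
    windowed = (track - track.mean()) * np.hanning(track.size)
    spectrum = np.abs(np.fft.rfft(windowed))
    freqs = np.fft.rfftfreq(track.size, d=1.0 / SAMPLING_HZ)
    valid = freqs >= min_hz
    return float(freqs[valid][np.argmax(spectrum[valid])])
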