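"""Readers and writers for the pipeline's on-disk artefacts.

Native container layout: a directory holding ``frames.h5`` (dataset
``frames``, uint8, shape (n, 500, 32, 32)), optional ``signals.h5``
(dataset ``signals``, float, (n, 500, 6)), a ``manifest.csv`` with columns
snippet_id, infant_id, label, seed, and JSON fold files.  Labels use the
ASCII vocabulary ``FMplus`` / ``FMminus``.

A best-effort adapter for externally deposited recordings is included: it
accepts any HDF5 file containing a (n, 500, 32, 32) uint8 array, validates
the shape and label vocabulary, and maps common label spellings onto the
native ones.  It is never required by the rest of the package.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .evaluate import FoldAssignment
from .synth import LABEL_NEG, LABEL_POS, PressureSnippet

MANIFEST_COLUMNS = ["snippet_id", "infant_id", "label", "seed"]

_LABEL_ALIASES = {
    "FMplus": LABEL_POS, "FM+": LABEL_POS, "FM−": LABEL_NEG,
    "FMminus": LABEL_NEG, "FM-": LABEL_NEG,
}


def write_cohort(outdir: str | Path, snippets: list[PressureSnippet],
                 manifest: pd.DataFrame) -> Path:
    """Write frames + manifest to a native-layout directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    frames = np.stack([s.frames for s in snippets])
    with h5py.File(outdir / "frames.h5", "w") as f:
        f.create_dataset("frames", data=frames, dtype="uint8",
                         chunks=(1,) + frames.shape[1:], compression="gzip")
    manifest[MANIFEST_COLUMNS].to_csv(outdir / "manifest.csv", index=False)
    return outdir


def read_snippets(path: str | Path, layout: str = "native"
                  ) -> tuple[list[PressureSnippet], pd.DataFrame]:
    """Load snippets + manifest from a native or adapter layout.

    Raises a descriptive error for missing files, shape mismatches or
    unknown labels.
    """
    path = Path(path)
    if layout == "native":
        frames_path, manifest_path = path / "frames.h5", path / "manifest.csv"
        if not frames_path.exists():
            raise FileNotFoundError(f"missing dataset file {frames_path}")
        if not manifest_path.exists():
            raise FileNotFoundError(f"missing manifest {manifest_path}")
        with h5py.File(frames_path, "r") as f:
            if "frames" not in f:
                raise ValueError(f"{frames_path}: no 'frames' dataset")
            frames = f["frames"][...]
        manifest = pd.read_csv(manifest_path)
    elif layout == "zenodo":
        frames, manifest = _read_adapter(path)
    else:
        raise ValueError(f"unknown layout {layout!r}")

    if frames.ndim != 4 or frames.shape[1:] != (500, 32, 32):
        raise ValueError(
            f"dataset 'frames': expected (n, 500, 32, 32), got {frames.shape}")
    missing = set(MANIFEST_COLUMNS[:3]) - set(manifest.columns)
    if missing:
        raise ValueError(f"manifest lacks columns {sorted(missing)}")
    bad = set(manifest["label"]) - {LABEL_POS, LABEL_NEG}
    if bad:
        raise ValueError(f"unknown labels {sorted(bad)}")
    if len(manifest) != len(frames):
        raise ValueError(
            f"manifest rows ({len(manifest)}) != frames ({len(frames)})")

    snippets = [
        PressureSnippet(frames=frames[k], infant_id=row.infant_id,
                        label=row.label, seed=int(getattr(row, "seed", 0)))
        for k, row in enumerate(manifest.itertuples())
    ]
    return snippets, manifest


def _read_adapter(path: Path) -> tuple[np.ndarray, pd.DataFrame]:
    """Best-effort loader for an external deposit directory."""
    h5s = sorted(path.glob("*.h5")) + sorted(path.glob("*.hdf5"))
    if not h5s:
        raise FileNotFoundError(f"no HDF5 file under {path}")
    with h5py.File(h5s[0], "r") as f:
        arrays = [k for k in f if getattr(f[k], "ndim", 0) == 4]
        if not arrays:
            raise ValueError(f"{h5s[0]}: no 4-D dataset found")
        frames = f[arrays[0]][...]
    csvs = sorted(path.glob("*.csv"))
    if not csvs:
        raise FileNotFoundError(f"no manifest CSV under {path}")
    manifest = pd.read_csv(csvs[0])
    manifest["label"] = manifest["label"].map(
        lambda s: _LABEL_ALIASES.get(str(s).strip(), s))
    return frames, manifest


def write_signals(outdir: str | Path, signals: np.ndarray) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with h5py.File(outdir / "signals.h5", "w") as f:
        f.create_dataset("signals", data=np.asarray(signals, np.float64))
    return outdir / "signals.h5"


def read_signals(path: str | Path) -> np.ndarray:
    with h5py.File(Path(path), "r") as f:
        return f["signals"][...]


def write_features(path: str | Path, manifest: pd.DataFrame,
                   features: np.ndarray, names: list[str]) -> Path:
    table = manifest[["snippet_id", "infant_id", "label"]].copy()
    for k, name in enumerate(names):
        table[name] = features[:, k]
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False)
    return path


def read_features(path: str | Path) -> tuple[pd.DataFrame, np.ndarray]:
    table = pd.read_csv(path)
    meta = table[["snippet_id", "infant_id", "label"]]
    return meta, table.drop(columns=["snippet_id", "infant_id", "label"]).to_numpy()


def write_folds(path: str | Path, folds: list[FoldAssignment]) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = [{
        "fold_id": f.fold_id, "test_infants": f.test_infants,
        "fit_infants": f.fit_infants, "val_infants": f.val_infants,
    } for f in folds]
    path.write_text(json.dumps(payload, indent=2))
    return path


def read_folds(path: str | Path) -> list[FoldAssignment]:
    payload = json.loads(Path(path).read_text())
    return [FoldAssignment(**d) for d in payload]
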