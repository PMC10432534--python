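"""The four classifier families and their training protocol.

Declarative ``ModelSpec``s reproduce the study's variant naming scheme:

* ``S1.*`` / ``S2.*`` — SVMs (RBF or polynomial kernel of degree 1-3) on
  the 12 / 24 statistical features, tuned over the 5x5 grid
  C in {0.1, 1, 10, 100, 1000} x gamma in {0.01, 0.1, 1, 10, 100} by
  validation accuracy.
* ``F1.x`` / ``F2`` — feed-forward networks on the features.
* ``C*F*`` — 1-D convolutional networks on the raw (500, 6) signals, with
  average pooling after the convolutional stack and one or two FC layers.
* ``L*F*`` — LSTM networks on the raw signals.

Networks train with Adam (lr 0.001, beta1 0.9, beta2 0.999, eps 1e-7),
binary cross-entropy, batch size 4, and a validation stop with patience
10; per fold the network is trained from ``n_restarts`` random
initialisations and the restart with the lowest validation loss is kept.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from . import nn

SVM_C_GRID = (0.1, 1.0, 10.0, 100.0, 1000.0)
SVM_GAMMA_GRID = (0.01, 0.1, 1.0, 10.0, 100.0)


@dataclass(frozen=True)
class ModelSpec:
    """Declarative description of one classifier variant."""

    name: str
    family: str              # svm | ffn | cnn | lstm
    input_kind: str          # features12 | features24 | signals500x6
    kernel: str | None = None          # svm: rbf | poly
    degree: int = 3                    # svm poly degree
    fc_layers: tuple[int, ...] = ()    # widths of hidden FC layers
    conv_layers: tuple[tuple[int, int], ...] = ()  # (filters, kernel_size)
    pool: int = 4                      # average-pool window after convs
    lstm_layers: tuple[int, ...] = ()  # LSTM unit counts

    def __post_init__(self) -> None:
        if self.family in ("svm", "ffn") and not self.input_kind.startswith("features"):
            raise ValueError(f"{self.name}: {self.family} requires feature input")
        if self.family in ("cnn", "lstm") and self.input_kind != "signals500x6":
            raise ValueError(f"{self.name}: {self.family} requires signal input")

    @property
    def n_features(self) -> int:
        return {"features12": 12, "features24": 24}[self.input_kind]


def _svm(name, kernel, degree=3, derivatives=False):
    return ModelSpec(name=name, family="svm",
                     input_kind="features24" if derivatives else "features12",
                     kernel=kernel, degree=degree)


def _ffn(name, fc, derivatives=True):
    return ModelSpec(name=name, family="ffn",
                     input_kind="features24" if derivatives else "features12",
                     fc_layers=fc)


def _cnn(name, conv, fc, pool=4):
    return ModelSpec(name=name, family="cnn", input_kind="signals500x6",
                     conv_layers=conv, fc_layers=fc, pool=pool)


def _lstm(name, units, fc):
    return ModelSpec(name=name, family="lstm", input_kind="signals500x6",
                     lstm_layers=units, fc_layers=fc)


#: Registry of every named variant.  Conv stacks beyond one layer repeat the
#: smallest filter shape with doubling filter counts (4 -> 8 -> 16); exact
#: per-variant layer tables can be dropped in by replacing entries.
MODEL_SPECS: dict[str, ModelSpec] = {spec.name: spec for spec in [
    _svm("S1.RBF", "rbf"),
    _svm("S1.P1", "poly", 1), _svm("S1.P2", "poly", 2), _svm("S1.P3", "poly", 3),
    _svm("S2.RBF", "rbf", derivatives=True),
    _svm("S2.P1", "poly", 1, True), _svm("S2.P2", "poly", 2, True),
    _svm("S2.P3", "poly", 3, True),
    _ffn("F1.1", (100,), derivatives=False),
    _ffn("F1.2", (100,)),
    _ffn("F1.3", (200,)),
    _ffn("F2", (100, 100)),
    _cnn("C1F1.1", ((4, 7),), (100,)),
    _cnn("C1F1.2", ((16, 13),), (100,)),
    _cnn("C1F1.3", ((64, 21),), (100,)),
    _cnn("C1F1.4", ((4, 7),), (200,)),
    _cnn("C1F2", ((4, 7),), (100, 100)),
    _cnn("C2F1", ((4, 7), (8, 7)), (100,)),
    _cnn("C3F1.1", ((4, 7), (8, 7), (16, 7)), (100,)),
    _cnn("C3F1.2", ((4, 7), (8, 7), (16, 7)), (200,)),
    _cnn("C3F2", ((4, 7), (8, 7), (16, 7)), (100, 100)),
    _lstm("L1F1.1", (32,), (100,)),
    _lstm("L1F1.2", (32,), (200,)),
    _lstm("L1F2", (32,), (100, 100)),
    _lstm("L2F2", (32, 32), (100, 100)),
]}


def spec_to_dict(spec: ModelSpec) -> dict:
    """Plain-dict form of a spec, suitable for YAML/JSON files."""
    d = dataclasses.asdict(spec)
    d["fc_layers"] = list(spec.fc_layers)
    d["conv_layers"] = [list(c) for c in spec.conv_layers]
    d["lstm_layers"] = list(spec.lstm_layers)
    return d


def spec_from_dict(d: dict) -> ModelSpec:
    d = dict(d)
    d["fc_layers"] = tuple(d.get("fc_layers", ()))
    d["conv_layers"] = tuple(tuple(c) for c in d.get("conv_layers", ()))
    d["lstm_layers"] = tuple(d.get("lstm_layers", ()))
    return ModelSpec(**d)


@dataclass(frozen=True)
class TrainingConfig:
    """Network training recipe (Adam defaults, validation stop, restarts)."""

    learning_rate: float = 0.001
    beta1: float = 0.9
    beta2: float = 0.999
    epsilon: float = 1e-7
    batch_size: int = 4
    validation_split: float = 1.0 / 6.0
    patience: int = 10
    min_delta: float = 1e-4   # smallest val-loss drop that counts as improvement
    max_epochs: int = 500
    n_restarts: int = 20

    def __post_init__(self) -> None:
        if min(self.learning_rate, self.batch_size, self.patience,
               self.max_epochs, self.n_restarts) <= 0:
            raise ValueError("training parameters must be positive")


def build_model(spec: ModelSpec, seed: int = 0, n_steps: int = 500,
                dtype=np.float32) -> nn.Sequential:
    """Construct an untrained network for a ffn/cnn/lstm spec.

    The head is always a single logit unit (sigmoid applied at predict
    time).  SVM specs are rejected: they are fitted by
    :func:`train_svm_grid`, not built as networks.
    """
    if spec.family == "svm":
        raise ValueError("svm specs are trained via train_svm_grid, not built")
    rng = np.random.default_rng(seed)
    layers: list[nn.Layer] = []
    if spec.family == "ffn":
        width = spec.n_features
        for w in spec.fc_layers:
            layers.append(nn.Dense(width, w, "relu", rng, dtype))
            width = w
        layers.append(nn.Dense(width, 1, None, rng, dtype))
        return nn.Sequential(layers)

    channels, steps = 6, n_steps
    if spec.family == "cnn":
        for filters, ksize in spec.conv_layers:
            layers.append(nn.Conv1D(channels, filters, ksize, "relu", rng, dtype))
            channels, steps = filters, steps - ksize + 1
        layers.append(nn.AvgPool1D(spec.pool))
        steps //= spec.pool
        layers.append(nn.Flatten())
        width = channels * steps
    else:  # lstm
        for units in spec.lstm_layers[:-1]:
            layers.append(nn.LSTM(channels, units, rng, dtype, return_sequences=True))
            channels = units
        width = spec.lstm_layers[-1]
        layers.append(nn.LSTM(channels, width, rng, dtype))
    for w in spec.fc_layers:
        layers.append(nn.Dense(width, w, "relu", rng, dtype))
        width = w
    layers.append(nn.Dense(width, 1, None, rng, dtype))
    return nn.Sequential(layers)


@dataclass
class GridFit:
    C: float
    gamma: float
    val_accuracy: float


def train_svm_grid(
    x_train: np.ndarray, y_train: np.ndarray,
    x_val: np.ndarray, y_val: np.ndarray,
    kernel: str = "rbf", degree: int = 3,
) -> tuple[Pipeline, pd.DataFrame]:
    """Fit the full 25-point (C, gamma) grid and select by validation accuracy.

    Features are z-scored with training-set statistics inside the returned
    pipeline.  Ties are broken deterministically: smallest C, then smallest
    gamma.  Returns the refitted best pipeline and the 25-row grid report.
    """
    if len(np.unique(y_train)) < 2:
        raise ValueError("training set contains a single class")
    fits: list[GridFit] = []
    best = None
    for C in SVM_C_GRID:
        for gamma in SVM_GAMMA_GRID:
            clf = Pipeline([
                ("scale", StandardScaler()),
                ("svc", SVC(C=C, gamma=gamma, kernel=kernel, degree=degree)),
            ])
            clf.fit(x_train, y_train)
            acc = float(np.mean(clf.predict(x_val) == y_val))
            fits.append(GridFit(C, gamma, acc))
            # strict > keeps the earliest (smallest C, then gamma) on ties
            if best is None or acc > best[0]:
                best = (acc, clf)
    report = pd.DataFrame([f.__dict__ for f in fits])
    return best[1], report


def train_network(
    spec: ModelSpec, config: TrainingConfig,
    x_train: np.ndarray, y_train: np.ndarray,
    x_val: np.ndarray, y_val: np.ndarray,
    seed: int = 0,
) -> tuple[nn.Sequential, nn.History]:
    """Train one network from one initialisation; returns model + history.

    The validation stop halts training after ``patience`` epochs without
    validation-loss improvement and restores the best state.  Reproducible
    given ``seed`` (initialisation and batch shuffling both derive from it).
    """
    if len(x_train) == 0 or len(x_val) == 0:
        raise ValueError("empty training or validation set")
    dtype = np.float32
    x_train = np.asarray(x_train, dtype)
    x_val = np.asarray(x_val, dtype)
    model = build_model(spec, seed=seed, n_steps=x_train.shape[1] if x_train.ndim == 3 else 500,
                        dtype=dtype)
    hist = nn.fit(
        model, x_train, np.asarray(y_train, dtype), x_val, np.asarray(y_val, dtype),
        batch_size=config.batch_size, lr=config.learning_rate,
        beta1=config.beta1, beta2=config.beta2, eps=config.epsilon,
        patience=config.patience, min_delta=config.min_delta,
        max_epochs=config.max_epochs, seed=seed,
    )
    return model, hist


def train_with_restarts(
    spec: ModelSpec, config: TrainingConfig,
    x_train: np.ndarray, y_train: np.ndarray,
    x_val: np.ndarray, y_val: np.ndarray,
    master_seed: int = 0,
) -> tuple[nn.Sequential, list[float]]:
    """Train ``config.n_restarts`` times; keep the lowest-validation-loss run.

    Restart seeds derive deterministically from ``master_seed``; all final
    validation losses are returned alongside the selected model.
    """
    seeds = np.random.default_rng(master_seed).integers(0, 2**31 - 1,
                                                        size=config.n_restarts)
    losses: list[float] = []
    best_model, best_loss = None, np.inf
    for s in seeds:
        model, hist = train_network(spec, config, x_train, y_train,
                                    x_val, y_val, seed=int(s))
        losses.append(hist.best_val_loss)
        if hist.best_val_loss < best_loss:
            best_loss, best_model = hist.best_val_loss, model
    return best_model, losses
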