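"""Two-view NSA fusion with a small fully connected network.

The AP NSA measured by the vision pipeline carries view-dependent
error; the lateral view measures the same implant under a different
projection.  A small multilayer perceptron (two hidden layers of 128
ReLU units) takes the two CV-derived NSAs as features and is trained
against clinician (trapezoid-technique) AP NSAs to produce a corrected
AP value.

The network output unit is a sigmoid and both features and target are
min-max scaled to [0, 1] over a fixed angle range, so the default loss
is binary cross-entropy on the scaled target — a proper scoring rule
whose optimum is the target itself — with plain squared error
available as an alternative.  Optimisation is full-batch Adam; given a
seed, training is exactly reproducible.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic_scene import patient_of

__all__ = [
    "NsaRecord",
    "FusionConfig",
    "FusionModel",
    "SplitReport",
    "scale_nsa",
    "unscale_nsa",
    "train_fusion",
    "predict_fused",
    "records_from_csv",
    "records_to_csv",
    "save_model",
    "load_model",
]


@dataclass
class NsaRecord:
    """Per-hip measurements entering fusion."""

    hip_id: str
    patient_id: str
    nsa_ap_cv: float
    nsa_lateral_cv: float
    nsa_ap_clinician: float
    nsa_ap_fused: float | None = None

    def __post_init__(self):
        for name in ("nsa_ap_cv", "nsa_lateral_cv", "nsa_ap_clinician"):
            v = getattr(self, name)
            if not (0.0 < v < 180.0):
                raise ValueError(f"{name}={v} outside (0, 180) degrees")


@dataclass(frozen=True)
class FusionConfig:
    """Architecture, loss and training-protocol settings."""

    hidden_layers: int = 2
    hidden_width: int = 128
    optimizer: str = "adam"
    loss: str = "bce_on_scaled"
    nsa_scale_min: float = 90.0
    nsa_scale_max: float = 180.0
    learning_rate: float = 3e-3
    epochs: int = 400
    train_fraction: float = 0.8
    seed: int = 0
    split_by: str = "patient"  # or "hip"

    def __post_init__(self):
        if self.hidden_layers < 1 or self.hidden_width < 1:
            raise ValueError("network must have at least one hidden unit/layer")
        if self.optimizer != "adam":
            raise ValueError(f"unsupported optimizer {self.optimizer!r}")
        if self.loss not in ("bce_on_scaled", "mse"):
            raise ValueError(f"unsupported loss {self.loss!r}")
        if not self.nsa_scale_min < self.nsa_scale_max:
            raise ValueError("nsa_scale_min must be < nsa_scale_max")
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.split_by not in ("patient", "hip"):
            raise ValueError("split_by must be 'patient' or 'hip'")


def scale_nsa(nsa: float, config: FusionConfig) -> float:
    """Affine map of an angle onto [0, 1] over the configured range."""
    lo, hi = config.nsa_scale_min, config.nsa_scale_max
    nsa = float(nsa)
    if not lo <= nsa <= hi:
        raise ValueError(f"NSA {nsa} outside the scale range [{lo}, {hi}]")
    return (nsa - lo) / (hi - lo)


def unscale_nsa(value: float, config: FusionConfig) -> float:
    """Inverse of :func:`scale_nsa`."""
    lo, hi = config.nsa_scale_min, config.nsa_scale_max
    return lo + float(value) * (hi - lo)


def _sigmoid(z):
    return 0.5 * (1.0 + np.tanh(0.5 * z))


class FusionModel:
    """Fully connected 2 -> (width x layers) -> 1 network, sigmoid output."""

    def __init__(self, config: FusionConfig):
        self.config = config
        self.weights = None  # list of (W, b)

    @property
    def trained(self) -> bool:
        return self.weights is not None

    def _init_weights(self, rng: np.random.Generator):
        sizes = [2] + [self.config.hidden_width] * self.config.hidden_layers + [1]
        self.weights = []
        for n_in, n_out in zip(sizes[:-1], sizes[1:]):
            w = rng.normal(0.0, math.sqrt(2.0 / n_in), size=(n_in, n_out))
            self.weights.append([w, np.zeros(n_out)])

    def _forward(self, x01: np.ndarray):
        """Return activations per layer; final entry is the sigmoid output."""
        acts = [x01]
        a = x01
        for i, (w, b) in enumerate(self.weights):
            z = a @ w + b
            a = _sigmoid(z) if i == len(self.weights) - 1 else np.maximum(z, 0.0)
            acts.append(a)
        return acts

    def predict_scaled(self, x01: np.ndarray) -> np.ndarray:
        if not self.trained:
            raise RuntimeError("model has not been trained")
        return self._forward(np.atleast_2d(x01))[-1][:, 0]

    def fit(self, x01: np.ndarray, y01: np.ndarray) -> "FusionModel":
        """Full-batch Adam on the configured loss; deterministic per seed."""
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        self._init_weights(rng)
        x01 = np.asarray(x01, float)
        y = np.asarray(y01, float).reshape(-1, 1)
        n = len(y)
        m = [[np.zeros_like(w), np.zeros_like(b)] for w, b in self.weights]
        v = [[np.zeros_like(w), np.zeros_like(b)] for w, b in self.weights]
        b1, b2, eps = 0.9, 0.999, 1e-8
        for t in range(1, cfg.epochs + 1):
            acts = self._forward(x01)
            p = acts[-1]
            if cfg.loss == "bce_on_scaled":
                # d(BCE)/dz with sigmoid output
                delta = (p - y) / n
            else:  # mse on the scaled target
                delta = 2.0 * (p - y) * p * (1.0 - p) / n
            grads = []
            for i in range(len(self.weights) - 1, -1, -1):
                a_prev = acts[i]
                gw = a_prev.T @ delta
                gb = delta.sum(axis=0)
                grads.append((gw, gb))
                if i > 0:
                    delta = (delta @ self.weights[i][0].T) * (acts[i] > 0)
            grads.reverse()
            corr1 = 1.0 - b1**t
            corr2 = 1.0 - b2**t
            for i, (gw, gb) in enumerate(grads):
                for j, g in enumerate((gw, gb)):
                    m[i][j] = b1 * m[i][j] + (1 - b1) * g
                    v[i][j] = b2 * v[i][j] + (1 - b2) * g**2
                    step = cfg.learning_rate * (m[i][j] / corr1) / (
                        np.sqrt(v[i][j] / corr2) + eps
                    )
                    self.weights[i][j] = self.weights[i][j] - step
        return self


@dataclass
class SplitReport:
    """Which hips landed in the train and test folds."""

    train_ids: list
    test_ids: list
    excluded_ids: list = field(default_factory=list)


def _features(records, config):
    x = np.array(
        [
            [scale_nsa(r.nsa_ap_cv, config), scale_nsa(r.nsa_lateral_cv, config)]
            for r in records
        ]
    )
    y = np.array([scale_nsa(r.nsa_ap_clinician, config) for r in records])
    return x, y


def _split(records, config: FusionConfig):
    """Seeded shuffle then split; train side takes floor(n * fraction)."""
    rng = np.random.default_rng(config.seed)
    n_train = int(math.floor(len(records) * config.train_fraction))
    if config.split_by == "hip":
        order = rng.permutation(len(records))
        train_idx = sorted(order[:n_train].tolist())
        test_idx = sorted(order[n_train:].tolist())
    else:
        patients = list(dict.fromkeys(r.patient_id for r in records))
        order = rng.permutation(len(patients))
        train_patients = set()
        count = 0
        for k in order:
            if count >= n_train:
                break
            train_patients.add(patients[k])
            count += sum(r.patient_id == patients[k] for r in records)
        train_idx = [i for i, r in enumerate(records) if r.patient_id in train_patients]
        test_idx = [i for i, r in enumerate(records) if r.patient_id not in train_patients]
    return train_idx, test_idx


def train_fusion(records, config: FusionConfig | None = None):
    """Split, train, and return ``(model, SplitReport)``.

    Records whose angles fall outside the scale range are flagged with
    a warning and excluded.  Splitting is per patient by default (both
    hips of a bilateral patient land in the same fold); training is
    reproducible given the config seed.
    """
    config = config or FusionConfig()
    usable, excluded = [], []
    for r in records:
        angles = (r.nsa_ap_cv, r.nsa_lateral_cv, r.nsa_ap_clinician)
        if all(config.nsa_scale_min <= a <= config.nsa_scale_max for a in angles):
            usable.append(r)
        else:
            excluded.append(r.hip_id)
    if excluded:
        warnings.warn(
            f"excluded {len(excluded)} record(s) outside the NSA scale range: {excluded}"
        )
    if len(usable) < 5:
        raise ValueError("need at least 5 usable records to train")
    train_idx, test_idx = _split(usable, config)
    if len(train_idx) < 2:
        raise ValueError("fewer than 2 training records after the split")
    x, y = _features([usable[i] for i in train_idx], config)
    model = FusionModel(config).fit(x, y)
    report = SplitReport(
        train_ids=[usable[i].hip_id for i in train_idx],
        test_ids=[usable[i].hip_id for i in test_idx],
        excluded_ids=excluded,
    )
    return model, report


def predict_fused(model: FusionModel, nsa_ap_cv: float, nsa_lateral_cv: float) -> float:
    """Corrected AP NSA in degrees for one hip."""
    if not model.trained:
        raise RuntimeError("model has not been trained")
    cfg = model.config
    x = np.array([[scale_nsa(nsa_ap_cv, cfg), scale_nsa(nsa_lateral_cv, cfg)]])
    return unscale_nsa(model.predict_scaled(x)[0], cfg)


# ---------------------------------------------------------------------------
# CSV + model (de)serialisation
# ---------------------------------------------------------------------------

_RECORD_COLUMNS = ["hip_id", "patient_id", "nsa_ap_cv", "nsa_lateral_cv", "nsa_ap_clinician"]


def records_from_csv(path) -> list:
    df = pd.read_csv(Path(path))
    missing = set(_RECORD_COLUMNS) - {"patient_id"} - set(df.columns)
    if missing:
        raise ValueError(f"records CSV missing columns: {sorted(missing)}")
    records = []
    for row in df.itertuples():
        pid = str(row.patient_id) if "patient_id" in df.columns else patient_of(str(row.hip_id))
        records.append(
            NsaRecord(
                hip_id=str(row.hip_id),
                patient_id=pid,
                nsa_ap_cv=float(row.nsa_ap_cv),
                nsa_lateral_cv=float(row.nsa_lateral_cv),
                nsa_ap_clinician=float(row.nsa_ap_clinician),
                nsa_ap_fused=float(row.nsa_ap_fused)
                if "nsa_ap_fused" in df.columns and not pd.isna(row.nsa_ap_fused)
                else None,
            )
        )
    return records


def records_to_csv(records, path) -> None:
    rows = [
        [r.hip_id, r.patient_id, r.nsa_ap_cv, r.nsa_lateral_cv, r.nsa_ap_clinician, r.nsa_ap_fused]
        for r in records
    ]
    pd.DataFrame(rows, columns=_RECORD_COLUMNS + ["nsa_ap_fused"]).to_csv(
        path, index=False, float_format="%.6f"
    )


def save_model(model: FusionModel, path) -> None:
    """Portable JSON weights + config."""
    if not model.trained:
        raise RuntimeError("cannot save an untrained model")
    payload = {
        "config": model.config.__dict__,
        "weights": [[w.tolist(), b.tolist()] for w, b in model.weights],
    }
    Path(path).write_text(json.dumps(payload))


def load_model(path) -> FusionModel:
    payload = json.loads(Path(path).read_text())
    model = FusionModel(FusionConfig(**payload["config"]))
    model.weights = [
        [np.asarray(w, float), np.asarray(b, float)] for w, b in payload["weights"]
    ]
    return model
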