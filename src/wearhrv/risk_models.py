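"""Cardiovascular-risk labelling, HR-feature construction and classifiers.

Risk labels follow the NYHA heart-failure grading: classes 0-1 are low
cardiovascular risk, classes 2-4 high risk. The HR feature set available to
a wearable — SDANNHR24, cosinor MESOR and amplitude — feeds logistic
regression, a random forest and a small feed-forward network, compared
against two baselines (B1: labels drawn from the training class
distribution; B2: constant majority class). Models are fitted on a
stratified 70% split and scored on the held-out 30% with per-class
precision/recall/F1.

Two fixed-coefficient predictors are also provided:

* ``predict_sdnn24_linear`` — a frozen linear model mapping SDANNHR24
  (entered in seconds; the coefficient magnitudes are only dimensionally
  coherent that way) and MESOR (bpm) to SDNN24 in ms.
* ``risk_probability_linear`` — a frozen logistic model on z-scored
  (SDANNHR24, MESOR, amplitude) returning the probability of high risk.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import precision_recall_fscore_support
from sklearn.model_selection import train_test_split
from sklearn.preprocessing import StandardScaler

from .io_formats import SubjectRecord, ValidationError
from .cosinor import fit_cosinor
from .time_domain import inject_hr_noise, ppg_noise_sigma, sdannhr24, sdnn24, segment

__all__ = [
    "FeatureRow",
    "ClassReport",
    "label_risk",
    "predict_sdnn24_linear",
    "risk_probability_linear",
    "build_features",
    "train_classifier",
    "baseline",
    "MODEL_FEATURES",
]

CLASSES = ("low", "high")

# Frozen linear-model coefficients: SDNN24[ms] from SDANNHR24[s] and MESOR[bpm].
SDNN24_LINEAR_INTERCEPT = 47.248
SDNN24_LINEAR_COEF_SDANNHR24_S = 951.590
SDNN24_LINEAR_COEF_MESOR = -0.347

# Frozen logistic coefficients on z-scored (SDANNHR24, MESOR, amplitude);
# the linear index enters the sigmoid denominator exponent directly.
RISK_LOGIT_INTERCEPT = 0.121
RISK_LOGIT_COEF_SDANNHR24 = 0.283
RISK_LOGIT_COEF_MESOR = -0.293
RISK_LOGIT_COEF_AMPLITUDE = 0.225

MODEL_FEATURES: dict[str, tuple[str, ...]] = {
    "lr_sdnn24": ("sdnn24_ms",),
    "lr_sdnnhr24": ("sdannhr24_ms",),
    "lr_hr": ("sdannhr24_ms", "mesor_bpm", "amplitude_bpm"),
    "rf_hr": ("sdannhr24_ms", "mesor_bpm", "amplitude_bpm"),
    "nn_hr": ("sdannhr24_ms", "mesor_bpm", "amplitude_bpm"),
}


@dataclass(frozen=True)
class FeatureRow:
    """Per-subject features for risk classification."""

    subject_id: str
    sdannhr24_ms: float
    mesor_bpm: float
    amplitude_bpm: float
    label: str
    sdnn24_ms: Optional[float] = None


@dataclass(frozen=True)
class ClassReport:
    """Per-class precision/recall/F1 on the held-out test split."""

    model: str
    per_class: dict  # label -> {"precision": .., "recall": .., "f1": ..}
    split_seed: int
    train_fraction: float = 0.7
    accuracy: float = float("nan")


def label_risk(nyha_class: int) -> str:
    """Map NYHA class to a risk label: 0-1 -> low, 2-4 -> high."""
    if nyha_class not in (0, 1, 2, 3, 4):
        raise ValidationError("NYHA class must be an integer in 0..4")
    return "low" if nyha_class <= 1 else "high"


def predict_sdnn24_linear(sdannhr24_s: float, mesor_bpm: float) -> float:
    """Frozen linear prediction of SDNN24 (ms); SDANNHR24 enters in seconds."""
    return (
        SDNN24_LINEAR_INTERCEPT
        + SDNN24_LINEAR_COEF_SDANNHR24_S * sdannhr24_s
        + SDNN24_LINEAR_COEF_MESOR * mesor_bpm
    )


def risk_probability_linear(
    sdannhr24_z: float, mesor_z: float, amplitude_z: float
) -> float:
    """Frozen logistic probability of high risk from z-scored HR features."""
    z = (
        RISK_LOGIT_INTERCEPT
        + RISK_LOGIT_COEF_SDANNHR24 * sdannhr24_z
        + RISK_LOGIT_COEF_MESOR * mesor_z
        + RISK_LOGIT_COEF_AMPLITUDE * amplitude_z
    )
    return float(1.0 / (1.0 + np.exp(z)))


def build_features(
    records: Sequence[SubjectRecord],
    window_min: float = 5.0,
    noise: Literal["none", "table"] | float = "table",
    seed: int = 0,
) -> pd.DataFrame:
    """Compute the HR feature table (one row per subject) from beat series.

    SDANNHR24 uses the given window with the calibrated PPG noise by
    default; MESOR and amplitude come from a cosinor fit on the segment HR
    values. SDNN24 of the full beat series is included for the
    beat-interval-based reference models.
    """
    rows = []
    rng = np.random.default_rng(seed)
    for rec in records:
        series = rec.beat_series
        seg = segment(series, window_min)
        if noise == "table":
            sigma = ppg_noise_sigma(window_min)
        elif noise == "none":
            sigma = 0.0
        else:
            sigma = float(noise)
        noisy = inject_hr_noise(seg, sigma, int(rng.integers(2**31)))
        fit = fit_cosinor(noisy.start_s + 30.0 * window_min, noisy.hr_bpm)
        label = rec.risk_label
        if label is None and rec.nyha_class is not None:
            label = label_risk(rec.nyha_class)
        rows.append(
            {
                "subject_id": series.subject_id,
                "sdannhr24_ms": sdannhr24(noisy),
                "mesor_bpm": fit.mesor_bpm,
                "amplitude_bpm": fit.amplitude_bpm,
                "sdnn24_ms": sdnn24(series),
                "label": label,
            }
        )
    return pd.DataFrame(rows)


def _split(
    frame: pd.DataFrame, split_seed: int, train_fraction: float
) -> tuple[pd.DataFrame, pd.DataFrame]:
    train, test = train_test_split(
        frame,
        train_size=train_fraction,
        stratify=frame["label"],
        random_state=split_seed,
    )
    return train, test


def _report(
    model: str, y_true, y_pred, split_seed: int, train_fraction: float
) -> ClassReport:
    prec, rec, f1, _ = precision_recall_fscore_support(
        y_true, y_pred, labels=list(CLASSES), zero_division=0
    )
    per_class = {
        c: {"precision": float(p), "recall": float(r), "f1": float(f)}
        for c, p, r, f in zip(CLASSES, prec, rec, f1)
    }
    acc = float(np.mean(np.asarray(y_true) == np.asarray(y_pred)))
    return ClassReport(
        model=model,
        per_class=per_class,
        split_seed=split_seed,
        train_fraction=train_fraction,
        accuracy=acc,
    )


class _LeakyReluNet:
    """Single-hidden-layer network trained by minibatch gradient descent.

    Architecture: dense hidden layer with leaky-rectifier activation and
    (inverted) dropout, single sigmoid output. Small enough that plain numpy
    is adequate.
    """

    def __init__(
        self,
        n_hidden: int,
        leak: float,
        dropout: float,
        batch_size: int,
        lr: float = 0.05,
        epochs: int = 150,
        seed: int = 0,
    ) -> None:
        self.n_hidden = n_hidden
        self.leak = leak
        self.dropout = dropout
        self.batch_size = batch_size
        self.lr = lr
        self.epochs = epochs
        self.seed = seed

    def fit(self, X: np.ndarray, y: np.ndarray) -> "_LeakyReluNet":
        rng = np.random.default_rng(self.seed)
        n, d = X.shape
        self.W1 = rng.normal(0, 1.0 / np.sqrt(d), size=(d, self.n_hidden))
        self.b1 = np.zeros(self.n_hidden)
        self.W2 = rng.normal(0, 1.0 / np.sqrt(self.n_hidden), size=(self.n_hidden, 1))
        self.b2 = np.zeros(1)
        keep = 1.0 - self.dropout
        for _ in range(self.epochs):
            order = rng.permutation(n)
            for start in range(0, n, self.batch_size):
                idx = order[start : start + self.batch_size]
                xb, yb = X[idx], y[idx, None]
                h_pre = xb @ self.W1 + self.b1
                h = np.where(h_pre > 0, h_pre, self.leak * h_pre)
                if keep < 1.0:
                    drop_mask = rng.random(h.shape) < keep
                    h = h * drop_mask / keep
                z = h @ self.W2 + self.b2
                p = 1.0 / (1.0 + np.exp(-z))
                # cross-entropy gradients
                dz = (p - yb) / len(idx)
                dW2 = h.T @ dz
                db2 = dz.sum(axis=0)
                dh = dz @ self.W2.T
                if keep < 1.0:
                    dh = dh * drop_mask / keep
                dpre = dh * np.where(h_pre > 0, 1.0, self.leak)
                dW1 = xb.T @ dpre
                db1 = dpre.sum(axis=0)
                self.W2 -= self.lr * dW2
                self.b2 -= self.lr * db2
                self.W1 -= self.lr * dW1
                self.b1 -= self.lr * db1
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        h_pre = X @ self.W1 + self.b1
        h = np.where(h_pre > 0, h_pre, self.leak * h_pre)
        z = h @ self.W2 + self.b2
        return (1.0 / (1.0 + np.exp(-z))).ravel()

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.predict_proba(X) >= 0.5).astype(int)


def _tune_nn(
    X_train: np.ndarray,
    y_train: np.ndarray,
    split_seed: int,
    n_configs: int,
) -> _LeakyReluNet:
    """Random search over the network hyper-parameter ranges.

    Candidate ranges: 1-8 hidden units, leak slope in [0, 1], dropout in
    [0, 0.99], batch size 1-32. Each candidate is scored on a stratified
    80/20 train/validation split of the training data; the best
    configuration is refitted on the full training split.
    """
    rng = np.random.default_rng(split_seed)
    idx_tr, idx_val = train_test_split(
        np.arange(len(y_train)),
        train_size=0.8,
        stratify=y_train,
        random_state=split_seed,
    )
    best, best_score = None, -np.inf
    for _ in range(n_configs):
        cfg = dict(
            n_hidden=int(rng.integers(1, 9)),
            leak=float(rng.uniform(0.0, 1.0)),
            dropout=float(rng.uniform(0.0, 0.99)),
            batch_size=int(rng.integers(1, 33)),
            seed=int(rng.integers(2**31)),
        )
        net = _LeakyReluNet(**cfg).fit(X_train[idx_tr], y_train[idx_tr])
        score = np.mean(net.predict(X_train[idx_val]) == y_train[idx_val])
        if score > best_score:
            best, best_score = cfg, score
    return _LeakyReluNet(**best).fit(X_train, y_train)


def train_classifier(
    features: pd.DataFrame,
    model: Literal["lr_sdnn24", "lr_sdnnhr24", "lr_hr", "rf_hr", "nn_hr"],
    split_seed: int = 0,
    train_fraction: float = 0.7,
    nn_configs: int = 60,
) -> ClassReport:
    """Fit one classifier on a stratified 70/30 split and score the test part.

    Features are z-scored on the training split before logistic/network
    fitting (the forest consumes raw features). Deterministic given
    ``split_seed``.
    """
    if model not in MODEL_FEATURES:
        raise ValidationError(f"unknown model {model!r}")
    cols = list(MODEL_FEATURES[model])
    if features["label"].nunique() < 2:
        raise ValidationError("training data must contain both classes")
    train, test = _split(features, split_seed, train_fraction)
    X_train = train[cols].to_numpy(dtype=float)
    X_test = test[cols].to_numpy(dtype=float)
    y_train = (train["label"] == "high").to_numpy(int)
    y_test = test["label"].to_numpy()

    if model == "rf_hr":
        clf = RandomForestClassifier(n_estimators=200, random_state=split_seed)
        clf.fit(X_train, y_train)
        pred = clf.predict(X_test)
    else:
        scaler = StandardScaler().fit(X_train)
        Xs_train = scaler.transform(X_train)
        Xs_test = scaler.transform(X_test)
        if model == "nn_hr":
            net = _tune_nn(Xs_train, y_train, split_seed, nn_configs)
            pred = net.predict(Xs_test)
        else:
            clf = LogisticRegression(max_iter=1000)
            clf.fit(Xs_train, y_train)
            pred = clf.predict(Xs_test)
    pred_labels = np.where(np.asarray(pred) == 1, "high", "low")
    return _report(model, y_test, pred_labels, split_seed, train_fraction)


def baseline(
    features: pd.DataFrame,
    kind: Literal["b1", "b2"],
    seed: int = 0,
    train_fraction: float = 0.7,
) -> ClassReport:
    """Reference baselines on the same stratified split as the classifiers.

    B1 samples predictions from the empirical class distribution of the
    training split; B2 always predicts the training-split majority class.
    """
    if kind not in ("b1", "b2"):
        raise ValidationError("baseline kind must be 'b1' or 'b2'")
    if len(features) < 2:
        raise ValidationError("need at least 2 rows")
    train, test = _split(features, seed, train_fraction)
    counts = train["label"].value_counts()
    y_test = test["label"].to_numpy()
    if kind == "b2":
        pred = np.full(len(test), counts.idxmax())
    else:
        rng = np.random.default_rng(seed)
        probs = (counts / counts.sum()).reindex(list(CLASSES)).fillna(0.0)
        pred = rng.choice(list(CLASSES), size=len(test), p=probs.to_numpy())
    return _report(kind, y_test, pred, seed, train_fraction)
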