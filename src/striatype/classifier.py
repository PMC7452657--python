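"""Three-class neuron-type classifier.

A feedforward network with a single hidden layer of 13 logistic units and a
softmax output over the classes (MSN, THIN, FAN), trained on the 12
intrinsic properties.  Performance is estimated by stratified 10-fold
cross-validation with the standardizer fit on each training split only (no
leakage); the deployed model is refit on all rows.  The trained model is a
self-contained, JSON-serializable weight container so predictions do not
depend on the training backend.

Training uses scikit-learn's multilayer perceptron with full-batch L-BFGS,
L2 penalty 1e-3 and at most 500 iterations; these are package defaults, all
recorded in the model metadata.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPClassifier

from .ephys import FEATURE_NAMES
from .exceptions import ValidationError
from .feature_tables import CLASS_LABELS

__all__ = [
    "MLPModel",
    "CVResult",
    "train_classifier",
    "predict",
    "classify_table",
    "save_model",
    "load_model",
]

DEFAULT_HIDDEN = 13
DEFAULT_FOLDS = 10
DEFAULT_ALPHA = 1e-3
DEFAULT_MAX_ITER = 500

#: Accepted case-insensitive synonyms for the canonical feature columns.
COLUMN_SYNONYMS = {
    "capacitance": ("capacitance", "cm", "c_m", "membrane_capacitance"),
    "input_resistance": ("input_resistance", "rin", "r_in", "ir"),
    "rmp": ("rmp", "resting_membrane_potential", "vrest", "v_rest"),
    "sag": ("sag", "voltage_sag", "sag_amplitude"),
    "rheobase": ("rheobase", "threshold_current"),
    "ap_amplitude": ("ap_amplitude", "spike_amplitude", "ap_amp"),
    "ahp_amplitude": ("ahp_amplitude", "ahp", "ahp_amp"),
    "ap_half_width": ("ap_half_width", "half_width", "hw"),
    "max_rise_rate": ("max_rise_rate", "max_rise", "dvdt_max_rise"),
    "max_fall_rate": ("max_fall_rate", "max_fall", "dvdt_max_fall"),
    "freq_adaptation": ("freq_adaptation", "frequency_adaptation", "isi_ratio"),
    "amp_adaptation": ("amp_adaptation", "amplitude_adaptation", "amp_ratio"),
}


@dataclass
class MLPModel:
    """Standardizer + single-hidden-layer network, fully self-contained."""

    means: np.ndarray  # per-feature standardizer
    sds: np.ndarray
    W1: np.ndarray  # 12 x hidden
    b1: np.ndarray
    W2: np.ndarray  # hidden x 3
    b2: np.ndarray
    classes: tuple[str, ...] = CLASS_LABELS
    hidden_activation: str = "logistic"
    feature_names: tuple[str, ...] = FEATURE_NAMES
    seed: int = 0
    training_meta: dict = field(default_factory=dict)

    @property
    def n_hidden(self) -> int:
        return self.W1.shape[1]

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Class probabilities, rows on the simplex."""
        x = np.atleast_2d(np.asarray(x, dtype=float))
        if x.shape[1] != self.W1.shape[0]:
            raise ValidationError(
                f"expected {self.W1.shape[0]} features, got {x.shape[1]}"
            )
        z = (x - self.means) / self.sds
        pre = z @ self.W1 + self.b1
        if self.hidden_activation == "logistic":
            from scipy.special import expit

            h = expit(pre)
        elif self.hidden_activation == "tanh":
            h = np.tanh(pre)
        elif self.hidden_activation == "relu":
            h = np.maximum(pre, 0.0)
        else:
            raise ValidationError(f"unknown activation '{self.hidden_activation}'")
        logits = h @ self.W2 + self.b2
        logits -= logits.max(axis=1, keepdims=True)
        p = np.exp(logits)
        return p / p.sum(axis=1, keepdims=True)


@dataclass
class CVResult:
    fold_accuracies: list[float]
    mean_accuracy: float  # mean of per-fold accuracies
    pooled_accuracy: float  # total correct / total rows across folds
    confusion: np.ndarray  # true x predicted counts, class order fixed
    fold_assignment: np.ndarray  # per-row fold index
    classes: tuple[str, ...] = CLASS_LABELS
    fold_standardizers: list[tuple[np.ndarray, np.ndarray]] = field(default_factory=list)


def _fit_mlp(
    x: np.ndarray, y: np.ndarray, hidden: int, seed: int, alpha: float, max_iter: int
) -> MLPClassifier:
    clf = MLPClassifier(
        hidden_layer_sizes=(hidden,),
        activation="logistic",
        solver="lbfgs",
        alpha=alpha,
        max_iter=max_iter,
        random_state=seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        clf.fit(x, y)
    return clf


def _standardize_fit(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    means = x.mean(axis=0)
    sds = x.std(axis=0, ddof=0)
    sds = np.where(sds == 0, 1.0, sds)
    return means, sds


def train_classifier(
    table: pd.DataFrame,
    hidden: int = DEFAULT_HIDDEN,
    folds: int = DEFAULT_FOLDS,
    seed: int = 0,
    alpha: float = DEFAULT_ALPHA,
    max_iter: int = DEFAULT_MAX_ITER,
) -> tuple[MLPModel, CVResult]:
    """Train the network and estimate accuracy by stratified k-fold CV.

    ``table`` needs the 12 feature columns and a ``label`` column.  Each
    fold's standardizer and network are fit on the training split only; the
    returned model is refit on all rows.  Deterministic for fixed seed.
    """
    if "label" not in table.columns:
        raise ValidationError("training table needs a 'label' column")
    missing = [f for f in FEATURE_NAMES if f not in table.columns]
    if missing:
        raise ValidationError(f"training table missing feature columns: {missing}")
    x = table[list(FEATURE_NAMES)].to_numpy(dtype=float)
    y = table["label"].to_numpy()
    if np.isnan(x).any():
        bad = list(np.nonzero(np.isnan(x).any(axis=1))[0])
        raise ValidationError(f"NaN features in rows {bad}; complete rows only")
    classes = tuple(c for c in CLASS_LABELS if c in set(y)) or tuple(
        sorted(set(map(str, y)))
    )
    counts = pd.Series(y).value_counts()
    if (counts < folds).any():
        raise ValidationError(
            f"every class needs >= {folds} rows for stratified {folds}-fold CV; "
            f"counts: {counts.to_dict()}"
        )

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    class_index = {c: i for i, c in enumerate(classes)}
    fold_acc: list[float] = []
    confusion = np.zeros((len(classes), len(classes)), dtype=int)
    fold_assignment = np.empty(len(y), dtype=int)
    fold_standardizers: list[tuple[np.ndarray, np.ndarray]] = []
    n_correct = 0
    for fi, (tr, te) in enumerate(skf.split(x, y)):
        fold_assignment[te] = fi
        means, sds = _standardize_fit(x[tr])
        fold_standardizers.append((means, sds))
        clf = _fit_mlp((x[tr] - means) / sds, y[tr], hidden, seed, alpha, max_iter)
        pred = clf.predict((x[te] - means) / sds)
        fold_acc.append(float(np.mean(pred == y[te])))
        n_correct += int(np.sum(pred == y[te]))
        for yt, yp in zip(y[te], pred):
            confusion[class_index[yt], class_index[yp]] += 1

    means, sds = _standardize_fit(x)
    clf = _fit_mlp((x - means) / sds, y, hidden, seed, alpha, max_iter)
    order = [int(np.nonzero(clf.classes_ == c)[0][0]) for c in classes]
    model = MLPModel(
        means=means,
        sds=sds,
        W1=np.asarray(clf.coefs_[0]),
        b1=np.asarray(clf.intercepts_[0]),
        W2=np.asarray(clf.coefs_[1])[:, order],
        b2=np.asarray(clf.intercepts_[1])[order],
        classes=classes,
        seed=seed,
        training_meta={
            "hidden": hidden,
            "folds": folds,
            "alpha": alpha,
            "max_iter": max_iter,
            "solver": "lbfgs",
            "activation": "logistic",
            "n_rows": int(len(y)),
        },
    )
    cv = CVResult(
        fold_accuracies=fold_acc,
        mean_accuracy=float(np.mean(fold_acc)),
        pooled_accuracy=n_correct / len(y),
        confusion=confusion,
        fold_assignment=fold_assignment,
        classes=classes,
        fold_standardizers=fold_standardizers,
    )
    return model, cv


def predict(model: MLPModel, features: np.ndarray) -> tuple[np.ndarray, str]:
    """Probabilities and argmax label for one 12-vector.

    Ties break toward the first class in the model's class order.
    """
    features = np.asarray(features, dtype=float).ravel()
    if features.size != len(model.feature_names):
        raise ValidationError(
            f"expected {len(model.feature_names)} features, got {features.size}"
        )
    p = model.predict_proba(features[None, :])[0]
    return p, model.classes[int(np.argmax(p))]


def _map_columns(table: pd.DataFrame) -> tuple[dict[str, str], list[str]]:
    lookup = {}
    for canonical, synonyms in COLUMN_SYNONYMS.items():
        for s in synonyms:
            lookup[s.lower()] = canonical
    mapping: dict[str, str] = {}
    extras: list[str] = []
    for col in table.columns:
        canonical = lookup.get(str(col).strip().lower())
        if canonical and canonical not in mapping.values():
            mapping[col] = canonical
        elif str(col).strip().lower() not in ("label", "cell_id"):
            extras.append(str(col))
    return mapping, extras


def classify_table(
    model: MLPModel, table: pd.DataFrame, explain: bool = False, seed: int = 0
) -> pd.DataFrame:
    """Classify every row of a pasted/loaded feature table.

    Column names are matched case-insensitively against documented synonyms;
    extra columns are ignored with a warning; rows with missing values are
    flagged (label empty, probabilities NaN), never dropped.
    """
    mapping, extras = _map_columns(table)
    found = set(mapping.values())
    missing = [f for f in FEATURE_NAMES if f not in found]
    if missing:
        raise ValidationError(
            f"could not map columns for features {missing}; expected names "
            f"(or synonyms) of {list(FEATURE_NAMES)}"
        )
    if extras:
        warnings.warn(f"ignoring unmapped columns: {extras}", stacklevel=2)
    if len(table) == 0:
        cols = ["label"] + [f"p_{c}" for c in model.classes] + ["complete"]
        return pd.DataFrame(columns=cols)

    renamed = table.rename(columns=mapping)
    x = renamed[list(FEATURE_NAMES)].to_numpy(dtype=float)
    complete = ~np.isnan(x).any(axis=1)
    probs = np.full((len(x), len(model.classes)), np.nan)
    labels = np.full(len(x), "", dtype=object)
    if complete.any():
        p = model.predict_proba(x[complete])
        probs[complete] = p
        labels[complete] = [model.classes[i] for i in np.argmax(p, axis=1)]
    out = pd.DataFrame(index=table.index)
    out["label"] = labels
    for j, c in enumerate(model.classes):
        out[f"p_{c}"] = probs[:, j]
    out["complete"] = complete
    if explain:
        from .explain import explain_lime

        out["top_feature"] = [
            explain_lime(model, x[i], seed=seed).top_features(1)[0][0]
            if complete[i]
            else ""
            for i in range(len(x))
        ]
    return out


def save_model(model: MLPModel, path: str) -> None:
    """Serialize the model to a portable JSON container."""
    doc = {
        "format": "striatype-mlp",
        "version": 1,
        "classes": list(model.classes),
        "feature_names": list(model.feature_names),
        "hidden_activation": model.hidden_activation,
        "seed": model.seed,
        "training_meta": model.training_meta,
        "means": model.means.tolist(),
        "sds": model.sds.tolist(),
        "W1": model.W1.tolist(),
        "b1": model.b1.tolist(),
        "W2": model.W2.tolist(),
        "b2": model.b2.tolist(),
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def load_model(path: str) -> MLPModel:
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("format") != "striatype-mlp":
        raise ValidationError(f"{path}: not a striatype model container")
    return MLPModel(
        means=np.array(doc["means"]),
        sds=np.array(doc["sds"]),
        W1=np.array(doc["W1"]),
        b1=np.array(doc["b1"]),
        W2=np.array(doc["W2"]),
        b2=np.array(doc["b2"]),
        classes=tuple(doc["classes"]),
        hidden_activation=doc["hidden_activation"],
        feature_names=tuple(doc["feature_names"]),
        seed=int(doc.get("seed", 0)),
        training_meta=doc.get("training_meta", {}),
    )
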