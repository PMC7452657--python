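"""Local surrogate explanations for individual classifications.

For one instance, the classifier's probability surface for its predicted
class is probed with Gaussian perturbations in standardized feature space,
each perturbation weighted by an exponential distance kernel, and a weighted
ridge-regression line is fit through the probed probabilities.  The signed
coefficients of that local linear surrogate are the per-feature weights:
positive means the feature pushes the instance toward the predicted class
near this point in feature space.  This is the tabular local-surrogate
recipe popularized by LIME.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.linear_model import Ridge

from .classifier import MLPModel
from .exceptions import ValidationError

__all__ = ["Explanation", "explain_lime"]

DEFAULT_N_PERTURBATIONS = 5000
#: Default kernel width in standardized space: 0.75 * sqrt(n_features).
DEFAULT_KERNEL_SCALE = 0.75
RIDGE_PENALTY = 1e-3


@dataclass
class Explanation:
    """Signed per-feature weights of the local linear surrogate."""

    instance_id: str
    predicted_class: str
    feature_names: tuple[str, ...]
    weights: np.ndarray  # signed, standardized space
    intercept: float
    local_fit_quality: float  # weighted R^2 of the surrogate
    kernel_width: float
    n_perturbations: int
    seed: int

    def top_features(self, n: int = 5) -> list[tuple[str, float]]:
        """Features sorted by |weight|, largest first."""
        order = np.argsort(-np.abs(self.weights))[:n]
        return [(self.feature_names[i], float(self.weights[i])) for i in order]


def explain_lime(
    model: MLPModel,
    instance: np.ndarray,
    n_perturbations: int = DEFAULT_N_PERTURBATIONS,
    kernel_width: float | None = None,
    seed: int = 0,
    instance_id: str = "",
) -> Explanation:
    """Explain one classification with a weighted linear surrogate.

    Perturbations are unit-variance Gaussian draws around the standardized
    instance; the surrogate regresses the model's probability for the
    predicted class on the perturbations with kernel weights
    ``exp(-d^2 / width^2)``.  Deterministic under ``seed``.
    """
    x = np.asarray(instance, dtype=float).ravel()
    d = len(model.feature_names)
    if x.size != d:
        raise ValidationError(f"expected {d} features, got {x.size}")
    if not np.all(np.isfinite(x)):
        raise ValidationError("instance must be complete (finite features)")
    if n_perturbations < d + 2:
        raise ValidationError("n_perturbations too small for a stable surrogate")
    if kernel_width is None:
        kernel_width = DEFAULT_KERNEL_SCALE * np.sqrt(d)

    z0 = (x - model.means) / model.sds
    p0 = model.predict_proba(x[None, :])[0]
    predicted = int(np.argmax(p0))

    rng = np.random.default_rng(seed)
    Z = z0 + rng.normal(0.0, 1.0, size=(n_perturbations, d))
    X = Z * model.sds + model.means
    y = model.predict_proba(X)[:, predicted]

    dist = np.linalg.norm(Z - z0, axis=1)
    w = np.exp(-(dist**2) / kernel_width**2)

    reg = Ridge(alpha=RIDGE_PENALTY)
    reg.fit(Z - z0, y, sample_weight=w)
    pred = reg.predict(Z - z0)
    ybar = np.average(y, weights=w)
    ss_res = float(np.average((y - pred) ** 2, weights=w))
    ss_tot = float(np.average((y - ybar) ** 2, weights=w))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0

    return Explanation(
        instance_id=instance_id,
        predicted_class=model.classes[predicted],
        feature_names=model.feature_names,
        weights=np.asarray(reg.coef_, dtype=float),
        intercept=float(reg.intercept_),
        local_fit_quality=float(r2),
        kernel_width=float(kernel_width),
        n_perturbations=n_perturbations,
        seed=seed,
    )
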