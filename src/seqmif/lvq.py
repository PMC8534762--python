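"""Generalized (matrix) learning vector quantization with relevance learning.

GLVQ places labeled prototype vectors in feature space and classifies by the
nearest-prototype rule.  Training minimizes, by per-sample stochastic
gradient descent, the margin-like cost sum_x f(mu(x)) with the classifier
function

    mu(x) = (d+ - d-) / (d+ + d-)  in  (-1, 1),

where d+ (d-) is the distance to the closest prototype of the correct
(a wrong) class; mu < 0 means a correct nearest-prototype decision, and the
cost effectively maximizes the hypothesis margin d- - d+, which confers
robustness.  GMLVQ replaces the squared Euclidean distance by the mapped
distance

    d_Omega(x, w) = || Omega (x - w) ||^2,

with Omega an m x n matrix learned alongside the prototypes; m < n gives the
limited-rank variant.  The Gram matrix Lambda = Omega^T Omega (classification
correlation matrix, CCM) is the model's interpretation device: its diagonal
is the classification relevance profile (CRP) and its row sums the
classification influence profile (CIP).
"""

from __future__ import annotations

import json
import os
import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence as TypingSequence

import numpy as np

__all__ = [
    "LVQModel",
    "Interpretation",
    "init_model",
    "distance",
    "classify",
    "predict",
    "accuracy",
    "train",
    "interpretation",
    "glvq_local_cost",
    "glvq_local_gradients",
    "save_model",
    "load_model",
]

Squashing = Literal["identity", "logistic"]


@dataclass
class LVQModel:
    """Labeled prototypes plus the rectangular mapping matrix Omega."""

    prototypes: np.ndarray = field(repr=False)  # (N, n)
    prototype_labels: list = field(repr=False)  # length N
    omega: np.ndarray = field(repr=False)  # (m, n), m <= n
    seed: int = 0
    hyperparams: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.prototypes = np.asarray(self.prototypes, dtype=float)
        self.omega = np.asarray(self.omega, dtype=float)
        if self.prototypes.ndim != 2:
            raise ValueError("prototypes must be an N x n array")
        if len(self.prototype_labels) != self.prototypes.shape[0]:
            raise ValueError("one label per prototype required")
        m, n = self.omega.shape
        if n != self.prototypes.shape[1] or m > n:
            raise ValueError(
                f"omega must be m x n with m <= n = {self.prototypes.shape[1]}, "
                f"got {self.omega.shape}"
            )

    @property
    def n_features(self) -> int:
        return self.prototypes.shape[1]

    @property
    def classes(self) -> list:
        seen: dict = {}
        for lab in self.prototype_labels:
            seen.setdefault(lab, None)
        return sorted(seen)


@dataclass
class Interpretation:
    """CCM, relevance profile and influence profile of a trained model.

    ``ccm`` is Lambda = Omega^T Omega (symmetric PSD); ``crp`` its diagonal
    (per-feature relevance, non-negative); ``cip`` its signed row sums (a
    feature's influence in combination with all others — signed entries can
    cancel, so the absolute-value variant ``cip_abs`` is also provided).
    """

    ccm: np.ndarray = field(repr=False)
    crp: np.ndarray = field(repr=False)
    cip: np.ndarray = field(repr=False)
    cip_abs: np.ndarray = field(repr=False)
    feature_names: list[str] | None = None


def init_model(
    X: np.ndarray,
    y: TypingSequence,
    prototypes_per_class: int = 1,
    m: int | None = None,
    seed: int = 0,
) -> LVQModel:
    """Initialize prototypes as random class-conditional data points.

    Omega starts from seeded standard-normal entries scaled to
    trace(Omega^T Omega) = 1; ``m`` defaults to n (full-rank GMLVQ).
    """
    X = np.asarray(X, dtype=float)
    y = list(y)
    if X.ndim != 2 or X.shape[0] != len(y):
        raise ValueError("X must be K x n with one label per row")
    n = X.shape[1]
    if m is None:
        m = n
    if not 1 <= m <= n:
        raise ValueError(f"mapping dimension m must satisfy 1 <= m <= {n}, got {m}")

    rng = np.random.default_rng(seed)
    classes = sorted(set(y))
    protos, labels = [], []
    for cls in classes:
        idx = [i for i, lab in enumerate(y) if lab == cls]
        if len(idx) < prototypes_per_class:
            raise ValueError(
                f"class {cls!r} has {len(idx)} samples, fewer than "
                f"{prototypes_per_class} prototypes requested"
            )
        chosen = rng.choice(idx, size=prototypes_per_class, replace=False)
        for i in chosen:
            protos.append(X[i].copy())
            labels.append(cls)
    omega = rng.standard_normal((m, n))
    omega /= np.linalg.norm(omega)  # Frobenius norm => trace(Omega^T Omega) = 1
    return LVQModel(
        prototypes=np.array(protos),
        prototype_labels=labels,
        omega=omega,
        seed=seed,
        hyperparams={"prototypes_per_class": prototypes_per_class, "m": m},
    )


def distance(model: LVQModel, x: np.ndarray) -> np.ndarray:
    """Mapped squared distances d_Omega(x, w_j) to every prototype."""
    x = np.asarray(x, dtype=float)
    if x.shape != (model.n_features,):
        raise ValueError(
            f"x must have {model.n_features} components, got shape {x.shape}"
        )
    if not np.any(model.omega):
        warnings.warn("omega is the zero matrix: all mapped distances are 0")
    diff = x - model.prototypes  # (N, n)
    mapped = diff @ model.omega.T  # (N, m)
    return np.einsum("ij,ij->i", mapped, mapped)


def _winners(d: np.ndarray, proto_labels: list, true_label) -> tuple[int, int]:
    """Indices of the closest correct and closest incorrect prototype.

    Ties break toward the lowest prototype index (np.argmin convention).
    """
    same = np.array([lab == true_label for lab in proto_labels])
    if not same.any():
        raise ValueError(f"label {true_label!r} not represented by any prototype")
    if same.all():
        raise ValueError("need at least one prototype of a different class")
    d_plus = np.where(same, d, np.inf)
    d_minus = np.where(same, np.inf, d)
    return int(np.argmin(d_plus)), int(np.argmin(d_minus))


def classify(
    model: LVQModel, x: np.ndarray, true_label=None
) -> tuple[object, int] | tuple[object, int, float]:
    """Nearest-prototype label for ``x`` (plus mu if the true label is given).

    Returns ``(label, winner_index)`` or ``(label, winner_index, mu)``.
    mu = (d+ - d-)/(d+ + d-) is in [-1, 1] and negative exactly when the
    nearest prototype has the correct label (strictly, when d+ != d-);
    if both distances are 0 the boundary value mu = 0 is returned.
    """
    d = distance(model, x)
    winner = int(np.argmin(d))
    label = model.prototype_labels[winner]
    if true_label is None:
        return label, winner
    jp, jm = _winners(d, model.prototype_labels, true_label)
    dp, dm = d[jp], d[jm]
    mu = 0.0 if dp + dm == 0 else (dp - dm) / (dp + dm)
    return label, winner, float(mu)


def predict(model: LVQModel, X: np.ndarray) -> list:
    """Nearest-prototype labels for a batch of inputs (vectorized)."""
    X = np.asarray(X, dtype=float)
    mapped_x = X @ model.omega.T  # (K, m)
    mapped_w = model.prototypes @ model.omega.T  # (N, m)
    d = ((mapped_x[:, None, :] - mapped_w[None, :, :]) ** 2).sum(axis=2)
    winners = np.argmin(d, axis=1)
    return [model.prototype_labels[j] for j in winners]


def accuracy(model: LVQModel, X: np.ndarray, y: TypingSequence) -> float:
    pred = predict(model, X)
    return float(np.mean([p == t for p, t in zip(pred, y)]))


def _squash(mu: float, squashing: Squashing, beta: float) -> tuple[float, float]:
    """f(mu) and f'(mu) for the configured squashing."""
    if squashing == "identity":
        return mu, 1.0
    if squashing == "logistic":
        f = 1.0 / (1.0 + np.exp(-beta * mu))
        return f, beta * f * (1.0 - f)
    raise ValueError(f"unknown squashing {squashing!r}")


def glvq_local_cost(
    x: np.ndarray,
    true_label,
    prototypes: np.ndarray,
    proto_labels: list,
    omega: np.ndarray,
    squashing: Squashing = "identity",
    beta: float = 1.0,
) -> float:
    """Per-sample GLVQ cost f(mu(x)) under the mapped distance."""
    diff = np.asarray(x, dtype=float) - prototypes
    mapped = diff @ omega.T
    d = np.einsum("ij,ij->i", mapped, mapped)
    jp, jm = _winners(d, proto_labels, true_label)
    dp, dm = d[jp], d[jm]
    mu = 0.0 if dp + dm == 0 else (dp - dm) / (dp + dm)
    return _squash(mu, squashing, beta)[0]


def glvq_local_gradients(
    x: np.ndarray,
    true_label,
    prototypes: np.ndarray,
    proto_labels: list,
    omega: np.ndarray,
    squashing: Squashing = "identity",
    beta: float = 1.0,
) -> tuple[float, int, int, np.ndarray, np.ndarray, np.ndarray]:
    """Analytic gradients of the per-sample cost.

    Returns ``(cost, jp, jm, grad_wp, grad_wm, grad_omega)``.  With
    S = d+ + d-, the chain rule gives dmu/dd+ = 2 d-/S^2 and
    dmu/dd- = -2 d+/S^2; for the mapped squared distance,
    dd/dw = -2 Lambda (x - w) and dd/dOmega = 2 Omega (x - w)(x - w)^T.
    A sample with S = 0 (both winners coincide with x) contributes no update.
    """
    x = np.asarray(x, dtype=float)
    diff = x - prototypes
    mapped = diff @ omega.T
    d = np.einsum("ij,ij->i", mapped, mapped)
    jp, jm = _winners(d, proto_labels, true_label)
    dp, dm = d[jp], d[jm]
    S = dp + dm
    n = prototypes.shape[1]
    if S == 0:
        cost = _squash(0.0, squashing, beta)[0]
        return cost, jp, jm, np.zeros(n), np.zeros(n), np.zeros_like(omega)
    mu = (dp - dm) / S
    cost, fprime = _squash(mu, squashing, beta)
    dmu_dp = 2.0 * dm / S**2
    dmu_dm = -2.0 * dp / S**2
    lam = omega.T @ omega
    delta_p = diff[jp]
    delta_m = diff[jm]
    grad_wp = fprime * dmu_dp * (-2.0) * (lam @ delta_p)
    grad_wm = fprime * dmu_dm * (-2.0) * (lam @ delta_m)
    grad_omega = fprime * 2.0 * omega @ (
        dmu_dp * np.outer(delta_p, delta_p) + dmu_dm * np.outer(delta_m, delta_m)
    )
    return cost, jp, jm, grad_wp, grad_wm, grad_omega


def train(
    model: LVQModel,
    X: np.ndarray,
    y: TypingSequence,
    epochs: int = 100,
    lr_w: float = 0.01,
    lr_omega: float = 0.01,
    squashing: Squashing = "identity",
    beta: float = 1.0,
    normalize_omega: bool = True,
    early_stop_tol: float = 1e-6,
    early_stop_patience: int = 10,
) -> tuple[LVQModel, list[float]]:
    """Stochastic gradient descent on the GLVQ cost (in place).

    One epoch visits every sample once in a per-epoch shuffled order drawn
    from the model seed; w+ is attracted toward the sample, w- repelled, and
    Omega follows the analytic gradient of the local cost.  With
    ``normalize_omega`` Omega is rescaled to trace(Omega^T Omega) = 1 after
    each epoch, which fixes the overall metric scale and makes CCMs
    comparable across runs and folds.  Training stops early once the epoch
    cost has improved by less than ``early_stop_tol`` for
    ``early_stop_patience`` consecutive epochs.

    Returns the model and the per-epoch cost trace (sum of f(mu)).
    """
    X = np.asarray(X, dtype=float)
    y = list(y)
    if epochs < 1:
        raise ValueError("epochs must be >= 1")
    rng = np.random.default_rng(model.seed)
    trace: list[float] = []
    best = np.inf
    stall = 0
    for _epoch in range(epochs):
        order = rng.permutation(len(y))
        cost_sum = 0.0
        for i in order:
            cost, jp, jm, g_wp, g_wm, g_om = glvq_local_gradients(
                X[i], y[i], model.prototypes, model.prototype_labels,
                model.omega, squashing=squashing, beta=beta,
            )
            if not (
                np.isfinite(cost)
                and np.all(np.isfinite(g_wp))
                and np.all(np.isfinite(g_wm))
                and np.all(np.isfinite(g_om))
            ):
                raise FloatingPointError(
                    f"non-finite gradient at sample index {i} (epoch {_epoch})"
                )
            cost_sum += cost
            model.prototypes[jp] -= lr_w * g_wp
            model.prototypes[jm] -= lr_w * g_wm
            model.omega -= lr_omega * g_om
        if normalize_omega:
            norm = np.linalg.norm(model.omega)
            if norm > 0:
                model.omega /= norm
        trace.append(cost_sum)
        if best - cost_sum < early_stop_tol:
            stall += 1
            if stall >= early_stop_patience:
                break
        else:
            stall = 0
        best = min(best, cost_sum)
    model.hyperparams.update(
        {
            "epochs": epochs,
            "lr_w": lr_w,
            "lr_omega": lr_omega,
            "squashing": squashing,
            "beta": beta,
            "normalize_omega": normalize_omega,
        }
    )
    return model, trace


def interpretation(
    model: LVQModel, feature_names: TypingSequence[str] | None = None
) -> Interpretation:
    """CCM Lambda = Omega^T Omega with its relevance and influence profiles."""
    lam = model.omega.T @ model.omega
    lam = 0.5 * (lam + lam.T)  # exact symmetry against rounding
    if feature_names is not None and len(feature_names) != lam.shape[0]:
        raise ValueError("feature_names length must equal the feature dimension")
    return Interpretation(
        ccm=lam,
        crp=np.diag(lam).copy(),
        cip=lam.sum(axis=1),
        cip_abs=np.abs(lam).sum(axis=1),
        feature_names=list(feature_names) if feature_names is not None else None,
    )


def save_model(model: LVQModel, path: str | os.PathLike) -> None:
    """Serialize a model to JSON (exact float round trip via repr)."""
    payload = {
        "prototypes": model.prototypes.tolist(),
        "prototype_labels": list(model.prototype_labels),
        "omega": model.omega.tolist(),
        "seed": model.seed,
        "hyperparams": model.hyperparams,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_model(path: str | os.PathLike) -> LVQModel:
    with open(path) as fh:
        payload = json.load(fh)
    return LVQModel(
        prototypes=np.array(payload["prototypes"], dtype=float),
        prototype_labels=payload["prototype_labels"],
        omega=np.array(payload["omega"], dtype=float),
        seed=payload["seed"],
        hyperparams=payload.get("hyperparams", {}),
    )
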