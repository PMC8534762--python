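"""Experiment driver: featurization, standardization, cross-validation,
grid search, and influence-based feature selection.

The canonical workflow mirrors a standard alignment-free classification
study: generate fingerprint features (MIF/rMIF profiles or natural vectors)
per sequence, Z-score them with statistics from the training fold only, run
stratified k-fold cross-validation of the limited-rank matrix LVQ, average
the per-fold classification correlation matrices, and optionally refit on
the top-k features ranked by the classification influence profile.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Iterable, Literal, Sequence as TypingSequence

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.preprocessing import StandardScaler

from . import lvq
from .lvq import Interpretation, LVQModel
from .mif import ShiftTooLargeError, feature_table
from .natural_vectors import nv_feature_table
from .sequence_io import Sequence

__all__ = [
    "LVQConfig",
    "FeatureConfig",
    "CVResult",
    "GridSearchResult",
    "RefitResult",
    "zscore_fit",
    "zscore_apply",
    "featurize",
    "cross_validate",
    "grid_search",
    "select_top_features",
    "refit_on_selected",
]


@dataclass
class LVQConfig:
    """Classifier hyperparameters for one cross-validation run.

    ``m`` is the mapping dimension of Omega (capped at the feature
    dimension at fit time); learning rates default to 0.01 for both the
    prototypes and Omega.
    """

    prototypes_per_class: int = 1
    m: int = 10
    epochs: int = 100
    lr_w: float = 0.01
    lr_omega: float = 0.01
    squashing: str = "identity"
    beta: float = 1.0
    normalize_omega: bool = True


@dataclass
class FeatureConfig:
    """One feature-generator setting (a grid point in the hyper search)."""

    method: Literal["mif", "rmif", "nv"] = "rmif"
    family: str = "shannon"
    alpha: float = 2.0
    tau_max: int = 7
    jmax: int = 4

    @property
    def n_features(self) -> int:
        if self.method == "rmif":
            return 4 * self.tau_max
        if self.method == "mif":
            return self.tau_max
        return 4 * (self.jmax + 1)

    @property
    def size_param(self) -> int:
        """The complexity knob of this generator (tau_max or jmax)."""
        return self.jmax if self.method == "nv" else self.tau_max


@dataclass
class CVResult:
    """Cross-validation outcome with per-fold interpretation matrices."""

    fold_accuracies: list[float]
    mean_accuracy: float
    std_accuracy: float
    interpretations: list[Interpretation] = field(repr=False)
    averaged_ccm: np.ndarray = field(repr=False)
    feature_names: list[str] | None
    config: dict

    @property
    def averaged_interpretation(self) -> Interpretation:
        lam = self.averaged_ccm
        return Interpretation(
            ccm=lam,
            crp=np.diag(lam).copy(),
            cip=lam.sum(axis=1),
            cip_abs=np.abs(lam).sum(axis=1),
            feature_names=self.feature_names,
        )

    def to_dict(self) -> dict:
        return {
            "fold_accuracies": self.fold_accuracies,
            "mean_accuracy": self.mean_accuracy,
            "std_accuracy": self.std_accuracy,
            "feature_names": self.feature_names,
            "config": self.config,
            "averaged_ccm": self.averaged_ccm.tolist(),
        }


def zscore_fit(X_train: np.ndarray) -> StandardScaler:
    """Fit a Z-score scaler (population standard deviation) on training data.

    Zero-variance columns are mapped to 0 when the scaler is applied.
    """
    X_train = np.asarray(X_train, dtype=float)
    if X_train.size == 0:
        raise ValueError("X_train must be non-empty")
    return StandardScaler().fit(X_train)


def zscore_apply(scaler: StandardScaler, X: np.ndarray) -> np.ndarray:
    """Apply a fitted scaler (training statistics) to any data matrix."""
    return scaler.transform(np.asarray(X, dtype=float))


def featurize(seqs: Iterable[Sequence], config: FeatureConfig,
              on_short: str = "error") -> pd.DataFrame:
    """Feature table (id, label, features) for a corpus per ``config``."""
    seqs = list(seqs)
    if config.method == "nv":
        return nv_feature_table(seqs, config.jmax)
    return feature_table(
        seqs,
        method=config.method,
        tau_max=config.tau_max,
        family=config.family,
        alpha=config.alpha,
        on_short=on_short,
    )


def split_feature_frame(df: pd.DataFrame) -> tuple[np.ndarray, list, list[str]]:
    """Split a feature table into (X, labels, feature_names)."""
    feature_cols = [c for c in df.columns if c not in ("id", "label")]
    X = df[feature_cols].to_numpy(dtype=float)
    return X, df["label"].tolist(), feature_cols


def cross_validate(
    features: np.ndarray | pd.DataFrame,
    labels: TypingSequence | None = None,
    k: int = 3,
    config: LVQConfig | None = None,
    seed: int = 0,
    feature_names: TypingSequence[str] | None = None,
    stratified: bool = True,
) -> CVResult:
    """Stratified k-fold cross-validation of the matrix-LVQ classifier.

    Per fold: the Z-score scaler is fit on the training split only, the
    model is initialized and trained on the standardized training data, and
    accuracy is measured on the standardized held-out split.  Per-fold CCMs
    (trace-normalized when omega normalization is on) are averaged
    element-wise into ``averaged_ccm``.

    ``features`` may be a plain matrix plus ``labels``, or a feature table
    frame with ``id``/``label`` columns.
    """
    if config is None:
        config = LVQConfig()
    if isinstance(features, pd.DataFrame):
        X, y, names = split_feature_frame(features)
        feature_names = feature_names or names
    else:
        X = np.asarray(features, dtype=float)
        if labels is None:
            raise ValueError("labels are required when features is a plain matrix")
        y = list(labels)
    if np.isnan(X).any():
        raise ValueError("feature matrix contains NaN; filter short sequences first")
    y_arr = np.asarray(y)
    counts = pd.Series(y).value_counts()
    if stratified and (counts < k).any():
        small = counts[counts < k].index.tolist()
        raise ValueError(
            f"classes {small} have fewer than k={k} samples; cannot stratify"
        )

    rng = np.random.default_rng(seed)
    fold_seed = int(rng.integers(0, 2**31 - 1))
    model_seeds = rng.integers(0, 2**31 - 1, size=k)
    splitter = (
        StratifiedKFold(n_splits=k, shuffle=True, random_state=fold_seed)
        if stratified
        else KFold(n_splits=k, shuffle=True, random_state=fold_seed)
    )

    accs: list[float] = []
    interps: list[Interpretation] = []
    for fold, (tr, te) in enumerate(splitter.split(X, y_arr)):
        scaler = zscore_fit(X[tr])
        X_tr = zscore_apply(scaler, X[tr])
        X_te = zscore_apply(scaler, X[te])
        y_tr = y_arr[tr].tolist()  # native python scalars (JSON-safe labels)
        m_eff = min(config.m, X.shape[1])
        model = lvq.init_model(
            X_tr, y_tr,
            prototypes_per_class=config.prototypes_per_class,
            m=m_eff, seed=int(model_seeds[fold]),
        )
        lvq.train(
            model, X_tr, y_tr,
            epochs=config.epochs, lr_w=config.lr_w, lr_omega=config.lr_omega,
            squashing=config.squashing, beta=config.beta,
            normalize_omega=config.normalize_omega,
        )
        accs.append(lvq.accuracy(model, X_te, y_arr[te].tolist()))
        interps.append(lvq.interpretation(model, feature_names))

    averaged = np.mean([it.ccm for it in interps], axis=0)
    averaged = 0.5 * (averaged + averaged.T)
    return CVResult(
        fold_accuracies=accs,
        mean_accuracy=float(np.mean(accs)),
        std_accuracy=float(np.std(accs)),
        interpretations=interps,
        averaged_ccm=averaged,
        feature_names=list(feature_names) if feature_names is not None else None,
        config={"k": k, "seed": seed, "stratified": stratified, **asdict(config)},
    )


@dataclass
class GridSearchResult:
    best_config: FeatureConfig
    best_result: CVResult
    table: pd.DataFrame
    results: dict[int, CVResult] = field(repr=False)


def grid_search(
    seqs: TypingSequence[Sequence],
    grid: TypingSequence[FeatureConfig],
    k: int = 3,
    lvq_config: LVQConfig | None = None,
    seed: int = 0,
) -> GridSearchResult:
    """Exhaustive evaluation of feature-generator settings by CV accuracy.

    A grid point whose tau_max/jmax is infeasible for the corpus (some
    sequence too short) is recorded as failed, not fatal.  Ties in mean
    accuracy break toward the smaller feature dimension, then the smaller
    complexity parameter.
    """
    if not grid:
        raise ValueError("grid must be non-empty")
    rows = []
    results: dict[int, CVResult] = {}
    for i, fc in enumerate(grid):
        row = {
            "method": fc.method, "family": fc.family, "alpha": fc.alpha,
            "tau_max": fc.tau_max, "jmax": fc.jmax, "n_features": fc.n_features,
        }
        try:
            df = featurize(seqs, fc)
            res = cross_validate(df, k=k, config=lvq_config, seed=seed)
        except (ShiftTooLargeError, ValueError) as exc:
            row.update(status=f"failed: {exc}", mean_accuracy=np.nan,
                       std_accuracy=np.nan)
        else:
            results[i] = res
            row.update(status="ok", mean_accuracy=res.mean_accuracy,
                       std_accuracy=res.std_accuracy)
        rows.append(row)
    table = pd.DataFrame(rows)
    if not results:
        raise ValueError("every grid point failed; no feasible configuration")
    best_i = min(
        results,
        key=lambda i: (
            -results[i].mean_accuracy,
            grid[i].n_features,
            grid[i].size_param,
            i,
        ),
    )
    return GridSearchResult(
        best_config=grid[best_i],
        best_result=results[best_i],
        table=table,
        results=results,
    )


def select_top_features(
    interp: Interpretation, k: int, use_abs: bool = False
) -> list[int]:
    """Indices of the k features with the largest influence (CIP).

    Ranking is on the signed CIP by default (the printed definition) or on
    absolute row sums with ``use_abs``; ties break toward the lower index.
    """
    scores = interp.cip_abs if use_abs else interp.cip
    n = len(scores)
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    order = sorted(range(n), key=lambda i: (-scores[i], i))
    return order[:k]


@dataclass
class RefitResult:
    cv: CVResult
    selected: list[int]
    accuracy_delta: float  # subset mean accuracy minus full-model mean accuracy


def refit_on_selected(
    features: np.ndarray | pd.DataFrame,
    labels: TypingSequence | None,
    selected: TypingSequence[int],
    k: int = 3,
    config: LVQConfig | None = None,
    seed: int = 0,
    full_result: CVResult | None = None,
) -> RefitResult:
    """Re-run the full CV pipeline on a feature subset.

    Reports the accuracy delta against ``full_result`` (computed here with
    the same seed when not supplied).
    """
    if isinstance(features, pd.DataFrame):
        X, y, names = split_feature_frame(features)
    else:
        X = np.asarray(features, dtype=float)
        if labels is None:
            raise ValueError("labels required with a plain feature matrix")
        y, names = list(labels), None
    selected = list(selected)
    if not selected or min(selected) < 0 or max(selected) >= X.shape[1]:
        raise ValueError(f"selected indices must lie in [0, {X.shape[1] - 1}]")
    if full_result is None:
        full_result = cross_validate(
            X, y, k=k, config=config, seed=seed, feature_names=names
        )
    sub_names = [names[i] for i in selected] if names else None
    sub = cross_validate(
        X[:, selected], y, k=k, config=config, seed=seed, feature_names=sub_names
    )
    return RefitResult(
        cv=sub,
        selected=selected,
        accuracy_delta=sub.mean_accuracy - full_result.mean_accuracy,
    )
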