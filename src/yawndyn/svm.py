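"""Soft-margin C-SVM with RBF kernel for yawn classification.

Two feature sets are defined:

* **Model A** — all five temporal variables: total duration, plateau
  duration, opening duration, opening/closing asymmetry, opening/closing
  ratio.
* **Model B** — total duration, plateau duration and asymmetry only.

"Interactions" between temporal variables are captured implicitly by the
RBF kernel in the default ``raw_features`` mode; an ``add_product_term``
mode appends the literal three-way product total·plateau·asymmetry for
the reading of Model B as a single interaction term.

Features are z-standardized with parameters fitted on training data only
(LibSVM-style preprocessing); constant columns are dropped with a warning.
Training solves the standard dual

    max Σαᵢ − ½ ΣᵢΣⱼ αᵢαⱼyᵢyⱼK(xᵢ,xⱼ)   s.t. 0 ≤ αᵢ ≤ C, Σαᵢyᵢ = 0

with K(x,z) = exp(−γ‖x−z‖²), via the libsvm solver (scikit-learn ``SVC``).
The fitted model stores support vectors, dual coefficients αᵢyᵢ, bias and
scaling so that predictions and the dual objective can be recomputed from
the stored parameters alone.

Hyperparameters (C, γ) are tuned by grid search over powers of ten in
[1e−3, 1e3] on stratified k-fold cross-validation error (default 10
folds), with deterministic seeded folds and a smallest-C-then-smallest-γ
tie-break.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .annotations import NON_YAWN, YAWN


class SVMError(ValueError):
    pass


@dataclass(frozen=True)
class ModelSpec:
    """A named feature-set specification."""

    name: str
    features: tuple[str, ...]
    interaction_mode: str = "raw_features"  # or "add_product_term"

    def __post_init__(self) -> None:
        if not self.features:
            raise SVMError("feature list must be non-empty")
        if self.interaction_mode not in ("raw_features", "add_product_term"):
            raise SVMError(f"unknown interaction mode {self.interaction_mode!r}")

    @property
    def column_names(self) -> tuple[str, ...]:
        if self.interaction_mode == "add_product_term":
            return self.features + ("product:" + "*".join(self.features),)
        return self.features


MODEL_A = ModelSpec(
    name="A",
    features=(
        "total_duration",
        "plateau_duration",
        "opening_duration",
        "asymmetry",
        "oc_ratio",
    ),
)
MODEL_B = ModelSpec(
    name="B",
    features=("total_duration", "plateau_duration", "asymmetry"),
)


def feature_matrix(
    features: pd.DataFrame, spec: ModelSpec
) -> tuple[np.ndarray, list[str]]:
    """Numeric design matrix for a model spec, with row episode ids.

    Columns follow ``spec.features`` order; in ``add_product_term`` mode a
    final column holds the product of all listed features. Rows with
    non-finite entries (e.g. undefined opening/closing ratio) are rejected
    by name.
    """
    missing = [f for f in spec.features if f not in features.columns]
    if missing:
        raise SVMError(f"feature table lacks columns {missing}")
    X = features[list(spec.features)].to_numpy(dtype=float)
    bad = ~np.isfinite(X).all(axis=1)
    if bad.any():
        raise SVMError(
            f"non-finite feature values for episodes {list(features.index[bad])}"
        )
    if spec.interaction_mode == "add_product_term":
        X = np.column_stack([X, np.prod(X, axis=1)])
    return X, list(features.index)


@dataclass(frozen=True)
class ScalingParams:
    center: np.ndarray
    scale: np.ndarray
    kept: np.ndarray  # boolean mask over original columns
    fitted_on: str = ""

    @property
    def n_features_in(self) -> int:
        return len(self.kept)


def fit_scaling(X: np.ndarray, fitted_on: str = "") -> ScalingParams:
    """Column means and sample SDs (n−1) for z-standardization.

    Constant columns (zero SD) are dropped with a warning and recorded in
    the ``kept`` mask.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise SVMError("scaling requires a 2-D matrix with at least 2 rows")
    center = X.mean(axis=0)
    scale = X.std(axis=0, ddof=1)
    kept = scale > 0
    if not kept.all():
        warnings.warn(
            f"dropping constant feature columns {list(np.nonzero(~kept)[0])}",
            stacklevel=2,
        )
    return ScalingParams(center=center, scale=scale, kept=kept, fitted_on=fitted_on)


def apply_scaling(X: np.ndarray, params: ScalingParams) -> np.ndarray:
    """Standardize with previously fitted parameters (never refit)."""
    X = np.asarray(X, dtype=float)
    if X.shape[1] != params.n_features_in:
        raise SVMError(
            f"dimension mismatch: expected {params.n_features_in} feature "
            f"columns, got {X.shape[1]}"
        )
    Z = (X - params.center)[:, params.kept] / params.scale[params.kept]
    return Z


@dataclass
class SVMModel:
    """A fitted RBF C-SVM: everything needed to reproduce its decisions.

    ``dual_coef`` holds αᵢyᵢ for the support vectors (0 < αᵢ ≤ C); the
    decision function is f(x) = Σ αᵢyᵢ K(xᵢ, x) + b with
    K(x,z) = exp(−γ‖x−z‖²), and the label is yawn iff f(x) > 0.
    """

    support_vectors: np.ndarray
    dual_coef: np.ndarray  # shape (n_sv,), αᵢyᵢ
    bias: float
    gamma: float
    C: float
    scaling: ScalingParams | None = None
    spec: ModelSpec | None = None

    def kernel(self, X: np.ndarray) -> np.ndarray:
        d2 = cdist(X, self.support_vectors, "sqeuclidean")
        return np.exp(-self.gamma * d2)

    def decision_function(self, X: np.ndarray, scale: bool = True) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.size == 0:
            return np.zeros(0)
        if scale and self.scaling is not None:
            X = apply_scaling(X, self.scaling)
        if X.shape[1] != self.support_vectors.shape[1]:
            raise SVMError(
                f"dimension mismatch: model has {self.support_vectors.shape[1]} "
                f"features, input has {X.shape[1]}"
            )
        return self.kernel(X) @ self.dual_coef + self.bias

    def dual_objective(self, y_sign: np.ndarray | None = None) -> float:
        """Value of the dual objective at the stored solution.

        α is recovered as |dual_coef|; the kernel term uses the stored
        support vectors. Non-support points have α = 0 and do not
        contribute.
        """
        alpha = np.abs(self.dual_coef)
        K = self.kernel(self.support_vectors)
        quad = self.dual_coef @ K @ self.dual_coef
        return float(alpha.sum() - 0.5 * quad)

    def to_json(self, path: str | Path | None = None) -> str:
        doc = {
            "support_vectors": self.support_vectors.tolist(),
            "dual_coef": self.dual_coef.tolist(),
            "bias": self.bias,
            "gamma": self.gamma,
            "C": self.C,
            "scaling": None
            if self.scaling is None
            else {
                "center": self.scaling.center.tolist(),
                "scale": self.scaling.scale.tolist(),
                "kept": self.scaling.kept.tolist(),
                "fitted_on": self.scaling.fitted_on,
            },
            "spec": None
            if self.spec is None
            else {
                "name": self.spec.name,
                "features": list(self.spec.features),
                "interaction_mode": self.spec.interaction_mode,
            },
        }
        text = json.dumps(doc, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, text_or_path: str | Path) -> "SVMModel":
        s = str(text_or_path)
        if isinstance(text_or_path, Path) or not s.lstrip().startswith("{"):
            text = Path(s).read_text()
        else:
            text = s
        doc = json.loads(text)
        scaling = None
        if doc["scaling"] is not None:
            scaling = ScalingParams(
                center=np.array(doc["scaling"]["center"]),
                scale=np.array(doc["scaling"]["scale"]),
                kept=np.array(doc["scaling"]["kept"], dtype=bool),
                fitted_on=doc["scaling"]["fitted_on"],
            )
        spec = None
        if doc["spec"] is not None:
            spec = ModelSpec(
                name=doc["spec"]["name"],
                features=tuple(doc["spec"]["features"]),
                interaction_mode=doc["spec"]["interaction_mode"],
            )
        return cls(
            support_vectors=np.array(doc["support_vectors"]),
            dual_coef=np.array(doc["dual_coef"]),
            bias=doc["bias"],
            gamma=doc["gamma"],
            C=doc["C"],
            scaling=scaling,
            spec=spec,
        )


def _encode_labels(y: Sequence[str]) -> np.ndarray:
    arr = np.asarray(y, dtype=object)
    out = np.where(arr == YAWN, 1.0, np.where(arr == NON_YAWN, -1.0, np.nan))
    if np.isnan(out.astype(float)).any():
        bad = sorted(set(arr) - {YAWN, NON_YAWN})
        raise SVMError(f"unknown labels {bad}")
    return out.astype(float)


def train_svm(
    X: np.ndarray,
    y: Sequence[str],
    C: float,
    gamma: float,
    scale: bool = True,
    spec: ModelSpec | None = None,
    fitted_on: str = "train",
) -> SVMModel:
    """Fit a soft-margin RBF C-SVM (libsvm solver) on labelled features.

    When ``scale`` is True (default), z-scaling parameters are fitted on
    ``X`` and stored in the model; prediction re-applies them. ``y`` uses
    the {yawn, non_yawn} labels; yawn is the positive class.
    """
    X = np.asarray(X, dtype=float)
    if not np.isfinite(X).all():
        raise SVMError("non-finite values in feature matrix")
    if C <= 0 or gamma <= 0:
        raise SVMError("C and gamma must be positive")
    y_sign = _encode_labels(y)
    if len(set(y_sign)) < 2:
        raise SVMError("both classes must be present in training labels")
    scaling = None
    Z = X
    if scale:
        scaling = fit_scaling(X, fitted_on=fitted_on)
        Z = apply_scaling(X, scaling)
    clf = SVC(C=C, gamma=gamma, kernel="rbf", tol=1e-7)
    clf.fit(Z, y_sign)
    # libsvm's dual_coef_ is ordered by class (-1 first); its sign already
    # encodes αᵢyᵢ with the convention of the positive class being classes_[1]
    dual = clf.dual_coef_.ravel().copy()
    return SVMModel(
        support_vectors=clf.support_vectors_.copy(),
        dual_coef=dual,
        bias=float(clf.intercept_[0]),
        gamma=gamma,
        C=C,
        scaling=scaling,
        spec=spec,
    )


def predict(model: SVMModel, X: np.ndarray) -> tuple[list[str], np.ndarray]:
    """Labels and decision values for new episodes.

    The label is yawn when the decision value is strictly positive; an
    exact zero ties to non-yawn.
    """
    f = model.decision_function(X)
    labels = [YAWN if v > 0 else NON_YAWN for v in f]
    return labels, f


@dataclass(frozen=True)
class GridSpec:
    """Hyperparameter grid: powers of 10 spanning [1e−3, 1e3] by default."""

    C_values: tuple[float, ...] = tuple(10.0 ** k for k in range(-3, 4))
    gamma_values: tuple[float, ...] = tuple(10.0 ** k for k in range(-3, 4))
    folds: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise SVMError("at least 2 folds required")
        for v in self.C_values + self.gamma_values:
            if not (1e-3 <= v <= 1e3):
                raise SVMError(f"grid value {v} outside [1e-3, 1e3]")


@dataclass
class GridSearchResult:
    best_C: float
    best_gamma: float
    cv_error: pd.DataFrame  # index: C, columns: gamma
    folds_used: int


def grid_search_cv(
    X: np.ndarray,
    y: Sequence[str],
    grid: GridSpec | None = None,
    scale: bool = True,
) -> GridSearchResult:
    """Stratified k-fold CV error over the (C, γ) grid; returns the argmin.

    Scaling is fitted inside each training fold. If the minority class has
    fewer members than the requested fold count, the folds are reduced to
    that count with a warning. Ties on CV error break toward the smallest
    C, then the smallest γ. Deterministic for a fixed seed.
    """
    grid = grid or GridSpec()
    y_arr = np.asarray(y, dtype=object)
    _encode_labels(y_arr)  # label validation
    class_counts = pd.Series(y_arr).value_counts()
    if class_counts.size < 2:
        raise SVMError("both classes required for cross-validation")
    k = int(min(grid.folds, class_counts.min()))
    if k < grid.folds:
        warnings.warn(
            f"reducing folds from {grid.folds} to {k}: minority class has "
            f"only {class_counts.min()} members",
            stacklevel=2,
        )
    if k < 2:
        raise SVMError("minority class too small for cross-validation")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=grid.seed)
    splits = list(skf.split(X, y_arr))
    err = pd.DataFrame(
        index=pd.Index(grid.C_values, name="C"),
        columns=pd.Index(grid.gamma_values, name="gamma"),
        dtype=float,
    )
    for C in grid.C_values:
        for gamma in grid.gamma_values:
            wrong = 0
            for tr, te in splits:
                model = train_svm(X[tr], y_arr[tr], C=C, gamma=gamma, scale=scale)
                labels, _ = predict(model, X[te])
                wrong += int(np.sum(np.asarray(labels, object) != y_arr[te]))
            err.loc[C, gamma] = wrong / len(y_arr)
    best = min(
        ((err.loc[C, g], C, g) for C in grid.C_values for g in grid.gamma_values),
        key=lambda t: (t[0], t[1], t[2]),
    )
    return GridSearchResult(best_C=best[1], best_gamma=best[2], cv_error=err, folds_used=k)
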