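"""Repeated hold-out validation and end-to-end study reports.

The evaluation protocol: on each iteration, two thirds of the episodes
(87 of 130 at the study's sample size) are drawn at random for training
and the rest held out for testing; feature scaling and the SVM are fitted
on the training split only, and test-set agreement, Cohen's kappa,
sensitivity and specificity are recorded. Summaries are the mean and SD
over iterations. Splits are simple random (not stratified); an iteration
whose test split contains no yawns keeps its other metrics and records
sensitivity as undefined rather than being resampled.

Hyperparameter tuning modes:

* ``fixed`` — use the (C, γ) supplied in the config;
* ``tune_once_full_data`` — one grid search on the full sample before the
  hold-out loop (mirrors reporting a single optimum per model; note the
  tuning then sees future test episodes);
* ``tune_per_split`` — a grid search inside every training split
  (leakage-free, slower).

``run_study1`` chains features → timing rule → contingency analysis;
``run_study2`` chains features → descriptives and group comparison →
tuning → hold-out model comparison.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .agreement import AgreementStats, ContingencyTable, agreement_stats, contingency
from .annotations import AnnotationSet
from .features import (
    GroupComparisonResult,
    descriptive_table,
    features_frame,
    group_compare,
)
from .rulebased import classify_all
from .svm import (
    MODEL_A,
    MODEL_B,
    GridSpec,
    ModelSpec,
    feature_matrix,
    grid_search_cv,
    predict,
    train_svm,
)

METRICS = ("percent_agreement", "kappa", "sensitivity", "specificity")


class ValidationError(ValueError):
    pass


@dataclass(frozen=True)
class HoldoutConfig:
    n_iterations: int = 200
    train_fraction: float = 2.0 / 3.0
    tuning_mode: str = "fixed"  # fixed | tune_once_full_data | tune_per_split
    C: float | None = None
    gamma: float | None = None
    seed: int = 0
    spec: ModelSpec = MODEL_A
    scale: bool = True
    grid: GridSpec | None = None

    def __post_init__(self) -> None:
        if not (0 < self.train_fraction < 1):
            raise ValidationError("train_fraction must be in (0, 1)")
        if self.n_iterations < 1:
            raise ValidationError("need at least one iteration")
        if self.tuning_mode not in ("fixed", "tune_once_full_data", "tune_per_split"):
            raise ValidationError(f"unknown tuning mode {self.tuning_mode!r}")
        if self.tuning_mode == "fixed" and (self.C is None or self.gamma is None):
            raise ValidationError("fixed tuning mode requires C and gamma")


@dataclass
class HoldoutResult:
    per_iteration: pd.DataFrame  # one row per iteration, METRICS columns
    config: HoldoutConfig
    C: float  # hyperparameters actually used (fixed or tuned-once);
    gamma: float  # NaN in tune_per_split mode (varies per split)
    n_undefined_sensitivity: int = 0

    @property
    def summary(self) -> pd.DataFrame:
        """Mean and SD of each metric over iterations (NaN-excluding)."""
        rows = {}
        for m in METRICS:
            vals = self.per_iteration[m]
            rows[m] = {"mean": float(vals.mean()), "sd": float(vals.std(ddof=1))}
        return pd.DataFrame(rows).T


def holdout_splits(
    n: int, train_fraction: float, n_iterations: int, seed: int
) -> list[tuple[np.ndarray, np.ndarray]]:
    """The deterministic sequence of train/test index splits.

    A pure function of (seed, n, train_fraction, n_iterations): iteration
    i permutes 0..n−1 with a seeded generator and takes the first
    round(train_fraction·n) indices for training.
    """
    rng = np.random.default_rng(seed)
    n_train = int(round(train_fraction * n))
    if n_train < 1 or n_train >= n:
        raise ValidationError(f"degenerate split sizes at n={n}")
    out = []
    for _ in range(n_iterations):
        perm = rng.permutation(n)
        out.append((np.sort(perm[:n_train]), np.sort(perm[n_train:])))
    return out


def evaluate_split(
    X: np.ndarray,
    y: np.ndarray,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    C: float,
    gamma: float,
    spec: ModelSpec,
    scale: bool,
) -> tuple[AgreementStats, ContingencyTable]:
    classes = set(y[train_idx])
    if len(classes) < 2:
        # a random split can strand every yawn in the test set; the only
        # classifier consistent with such training data is the constant one
        pred = [next(iter(classes))] * len(test_idx)
    else:
        model = train_svm(
            X[train_idx], y[train_idx], C=C, gamma=gamma, scale=scale, spec=spec
        )
        pred, _ = predict(model, X[test_idx])
    table = contingency(pred, list(y[test_idx]))
    return agreement_stats(table), table


def holdout_evaluate(
    features: pd.DataFrame,
    labels=None,
    config: HoldoutConfig = HoldoutConfig(C=1.0, gamma=0.1),
) -> HoldoutResult:
    """Repeated random-split hold-out evaluation of one SVM model spec."""
    df = features
    if labels is None:
        labels = df["label_ref"]
    y = np.asarray(labels, dtype=object)
    if len(set(y)) < 2:
        raise ValidationError("both classes must be present")
    X, _ = feature_matrix(df, config.spec)
    n = len(y)
    if n < 3:
        raise ValidationError("need at least 3 episodes")

    C, gamma = config.C, config.gamma
    if config.tuning_mode == "tune_once_full_data":
        grid = config.grid or GridSpec(seed=config.seed)
        res = grid_search_cv(X, y, grid, scale=config.scale)
        C, gamma = res.best_C, res.best_gamma

    splits = holdout_splits(n, config.train_fraction, config.n_iterations, config.seed)
    records = []
    n_undef = 0
    for i, (tr, te) in enumerate(splits):
        if config.tuning_mode == "tune_per_split":
            grid = config.grid or GridSpec(seed=config.seed)
            res = grid_search_cv(X[tr], y[tr], grid, scale=config.scale)
            C_i, gamma_i = res.best_C, res.best_gamma
        else:
            C_i, gamma_i = C, gamma
        stats, table = evaluate_split(
            X, y, tr, te, C_i, gamma_i, config.spec, config.scale
        )
        if math.isnan(stats.sensitivity):
            n_undef += 1
        records.append(
            {
                "iteration": i,
                "percent_agreement": stats.percent_agreement,
                "kappa": stats.kappa,
                "sensitivity": stats.sensitivity,
                "specificity": stats.specificity,
                "tp": table.tp,
                "fp": table.fp,
                "fn": table.fn,
                "tn": table.tn,
            }
        )
    per_iter = pd.DataFrame(records).set_index("iteration")
    return HoldoutResult(
        per_iteration=per_iter,
        config=config,
        C=C if config.tuning_mode != "tune_per_split" else math.nan,
        gamma=gamma if config.tuning_mode != "tune_per_split" else math.nan,
        n_undefined_sensitivity=n_undef,
    )


def compare_models(
    features: pd.DataFrame,
    labels=None,
    specs: tuple[ModelSpec, ...] = (MODEL_A, MODEL_B),
    config: HoldoutConfig = HoldoutConfig(C=1.0, gamma=0.1),
) -> tuple[pd.DataFrame, dict[str, HoldoutResult]]:
    """Hold-out results for several model specs on identical split sequences.

    Every spec sees the same seeded sequence of train/test splits. Models
    are ranked by mean kappa, ties broken by mean sensitivity. Returns the
    ranked summary table and the per-spec results.
    """
    if len(specs) < 2:
        raise ValidationError("need at least two model specs to compare")
    results: dict[str, HoldoutResult] = {}
    rows = []
    for spec in specs:
        res = holdout_evaluate(features, labels, replace(config, spec=spec))
        results[spec.name] = res
        s = res.summary
        rows.append(
            {
                "model": spec.name,
                "mean_kappa": s.loc["kappa", "mean"],
                "sd_kappa": s.loc["kappa", "sd"],
                "mean_agreement": s.loc["percent_agreement", "mean"],
                "mean_sensitivity": s.loc["sensitivity", "mean"],
                "mean_specificity": s.loc["specificity", "mean"],
                "C": res.C,
                "gamma": res.gamma,
                "n_undefined_sensitivity": res.n_undefined_sensitivity,
            }
        )
    table = (
        pd.DataFrame(rows)
        .sort_values(["mean_kappa", "mean_sensitivity"], ascending=False)
        .set_index("model")
    )
    return table, results


# ---------------------------------------------------------------------------
# End-to-end study reports


@dataclass
class Study1Report:
    features: pd.DataFrame
    rule_labels: pd.DataFrame
    table: ContingencyTable
    stats: AgreementStats
    prop_rule_yawn: float  # % of episodes the timing rule calls yawns
    prop_ref_yawn: float  # % of episodes the reference coding calls yawns

    def to_markdown(self) -> str:
        t, s = self.table, self.stats
        lines = [
            "# Timing-rule validity report",
            "",
            f"Episodes: {t.n}",
            f"Timing-rule yawns: {t.tp + t.fp} ({self.prop_rule_yawn:.1f}%)",
            f"Reference yawns: {t.tp + t.fn} ({self.prop_ref_yawn:.1f}%)",
            "",
            "| | ref yawn | ref non-yawn |",
            "|---|---|---|",
            f"| rule yawn | {t.tp} | {t.fp} |",
            f"| rule non-yawn | {t.fn} | {t.tn} |",
            "",
            f"Sensitivity: {s.sensitivity:.2f}",
            f"Specificity: {s.specificity:.2f}",
            f"Percent agreement: {s.percent_agreement:.0f}%",
            f"Cohen's kappa: {s.kappa:.2f}",
        ]
        return "\n".join(lines)


def run_study1(annset: AnnotationSet) -> Study1Report:
    """Timing-rule construct-validity analysis against reference labels."""
    labels = annset.labels
    if any(l is None for l in labels):
        raise ValidationError("every episode needs a reference label")
    feats = features_frame(annset)
    rule = classify_all(feats)
    table = contingency(list(rule["label"]), labels)
    stats = agreement_stats(table)
    n = table.n
    return Study1Report(
        features=feats,
        rule_labels=rule,
        table=table,
        stats=stats,
        prop_rule_yawn=100.0 * (table.tp + table.fp) / n,
        prop_ref_yawn=100.0 * (table.tp + table.fn) / n,
    )


@dataclass
class Study2Report:
    features: pd.DataFrame
    descriptives: pd.DataFrame
    comparison: GroupComparisonResult
    ranking: pd.DataFrame
    holdout: dict[str, HoldoutResult]
    config: HoldoutConfig
    tuned: dict[str, tuple[float, float]]  # spec name -> (C, gamma) used

    def to_markdown(self) -> str:
        lines = [
            "# SVM model-comparison report",
            "",
            f"Config: iterations={self.config.n_iterations}, "
            f"train_fraction={self.config.train_fraction:.4f}, "
            f"tuning_mode={self.config.tuning_mode}, seed={self.config.seed}",
            "",
            "## Per-class descriptives (seconds)",
            "",
            self.descriptives.round(2).to_markdown(),
            "",
            "## Group comparison (variable ~ class indicator)",
            "",
            self.comparison.table.round(3).to_markdown(),
            "",
            "## Hold-out ranking",
            "",
            self.ranking.round(2).to_markdown(),
        ]
        return "\n".join(lines)


def run_study2(
    annset: AnnotationSet,
    config: HoldoutConfig = HoldoutConfig(tuning_mode="tune_once_full_data"),
    specs: tuple[ModelSpec, ...] = (MODEL_A, MODEL_B),
) -> Study2Report:
    """Descriptives, group comparison, tuning and hold-out model comparison."""
    labels = annset.labels
    if any(l is None for l in labels):
        raise ValidationError("every episode needs a reference label")
    feats = features_frame(annset)
    desc = descriptive_table(feats)
    comp = group_compare(feats)
    ranking, results = compare_models(feats, labels, specs=specs, config=config)
    tuned = {name: (res.C, res.gamma) for name, res in results.items()}
    return Study2Report(
        features=feats,
        descriptives=desc,
        comparison=comp,
        ranking=ranking,
        holdout=results,
        config=config,
        tuned=tuned,
    )
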