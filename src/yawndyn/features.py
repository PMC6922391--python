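"""Temporal features of mouth-opening episodes and Study-style descriptives.

Six variables summarise the temporal dynamics of an episode (all in
seconds except the dimensionless ratio):

* ``total_duration``  — onset to offset
* ``opening_duration`` — onset to plateau onset
* ``plateau_duration`` — plateau onset to plateau offset
* ``closing_duration`` — plateau offset to offset
* ``asymmetry``        — opening minus closing duration
* ``oc_ratio``         — opening divided by closing duration (undefined when
  the closing phase has zero length; the episode is flagged, the other five
  features are still returned)

The module also provides per-class descriptive tables (mean, SD, median,
min, max) and a simple group comparison: each variable regressed on the
class indicator, reporting the mean difference, t statistic, degrees of
freedom, two-sided p and the standardized slope. An optional covariate hook
is exposed for adjusted comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .annotations import NON_YAWN, YAWN, AnnotationSet, EpisodeAnnotation

FEATURE_NAMES = (
    "total_duration",
    "opening_duration",
    "plateau_duration",
    "closing_duration",
    "asymmetry",
    "oc_ratio",
)


class FeatureError(ValueError):
    pass


@dataclass(frozen=True)
class EpisodeFeatures:
    """The six temporal variables of one episode.

    ``oc_ratio`` is ``None`` when the closing phase is degenerate
    (``ratio_undefined`` is then True).
    """

    episode_id: str
    total_duration: float
    opening_duration: float
    plateau_duration: float
    closing_duration: float
    asymmetry: float
    oc_ratio: float | None
    label_ref: str | None = None

    @property
    def ratio_undefined(self) -> bool:
        return self.oc_ratio is None

    def as_dict(self) -> dict[str, float | None]:
        return {name: getattr(self, name) for name in FEATURE_NAMES}


def compute_features(episode: EpisodeAnnotation) -> EpisodeFeatures:
    """Derive the six temporal variables from one episode's boundaries."""
    opening = episode.plateau_onset - episode.onset
    plateau = episode.plateau_offset - episode.plateau_onset
    closing = episode.offset - episode.plateau_offset
    total = episode.offset - episode.onset
    return EpisodeFeatures(
        episode_id=episode.episode_id,
        total_duration=total,
        opening_duration=opening,
        plateau_duration=plateau,
        closing_duration=closing,
        asymmetry=opening - closing,
        oc_ratio=(opening / closing) if closing > 0 else None,
        label_ref=episode.label_ref,
    )


def features_frame(annset: AnnotationSet) -> pd.DataFrame:
    """Feature table for a whole annotation set, indexed by episode id.

    Columns are the six variables plus ``label_ref``; undefined ratios
    appear as NaN.
    """
    rows = [compute_features(e) for e in annset]
    df = pd.DataFrame(
        {
            "episode_id": [f.episode_id for f in rows],
            **{
                name: [
                    np.nan if getattr(f, name) is None else getattr(f, name)
                    for f in rows
                ]
                for name in FEATURE_NAMES
            },
            "label_ref": [f.label_ref for f in rows],
        }
    ).set_index("episode_id")
    return df


def descriptive_table(features: pd.DataFrame, labels=None) -> pd.DataFrame:
    """Per-class descriptive statistics of the six variables.

    Returns a table indexed by (class, variable) with columns ``mean``,
    ``sd``, ``median``, ``min``, ``max`` and ``n``. SD uses the sample
    (n−1) denominator and is reported as 0.0 for singleton classes.
    """
    df = features.copy()
    if labels is not None:
        df = df.assign(label_ref=np.asarray(labels, dtype=object))
    if "label_ref" not in df.columns or df["label_ref"].isna().all():
        raise FeatureError("reference labels required for descriptive table")
    out = []
    for cls in (YAWN, NON_YAWN):
        sub = df[df["label_ref"] == cls]
        if len(sub) == 0:
            raise FeatureError(f"empty class: {cls}")
        for name in FEATURE_NAMES:
            vals = sub[name].dropna().to_numpy(dtype=float)
            sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
            out.append(
                {
                    "class": cls,
                    "variable": name,
                    "mean": float(np.mean(vals)),
                    "sd": sd,
                    "median": float(np.median(vals)),
                    "min": float(np.min(vals)),
                    "max": float(np.max(vals)),
                    "n": int(len(vals)),
                }
            )
    return pd.DataFrame(out).set_index(["class", "variable"])


@dataclass(frozen=True)
class GroupComparisonResult:
    """Per-variable linear-model comparison of yawns vs non-yawns."""

    table: pd.DataFrame  # index: variable; columns: mean_diff, t, df, p, beta

    def __getitem__(self, variable: str) -> pd.Series:
        return self.table.loc[variable]


def group_compare(
    features: pd.DataFrame,
    labels=None,
    covariates: pd.DataFrame | None = None,
) -> GroupComparisonResult:
    """Regress each temporal variable on the class indicator.

    The model is ``variable ~ 1 + is_yawn`` (plus optional covariates); the
    reported ``beta`` is the standardized slope of the indicator, which for
    the unadjusted model equals the point-biserial correlation. ``df`` is
    the residual degrees of freedom (n − parameters). Variables with zero
    variance get NaN statistics and ``flagged=True``.
    """
    df = features.copy()
    if labels is not None:
        df = df.assign(label_ref=np.asarray(labels, dtype=object))
    y_ind = (df["label_ref"] == YAWN).astype(float).to_numpy()
    if y_ind.sum() == 0 or y_ind.sum() == len(y_ind):
        raise FeatureError("both classes must be present for group comparison")
    rows = []
    for name in FEATURE_NAMES:
        mask = df[name].notna().to_numpy()
        v = df.loc[mask, name].to_numpy(dtype=float)
        x = y_ind[mask]
        X = x[:, None]
        if covariates is not None:
            # covariates must be row-aligned with the feature table
            X = np.column_stack([X, covariates.to_numpy(dtype=float)[mask]])
        exog = sm.add_constant(X)
        if np.std(v) == 0 or np.std(x) == 0:
            rows.append(
                {
                    "variable": name,
                    "mean_diff": float(np.mean(v[x == 1]) - np.mean(v[x == 0]))
                    if 0 < x.sum() < len(x)
                    else np.nan,
                    "t": 0.0 if np.std(v) == 0 else np.nan,
                    "df": len(v) - exog.shape[1],
                    "p": np.nan,
                    "beta": 0.0 if np.std(v) == 0 else np.nan,
                    "flagged": True,
                }
            )
            continue
        fit = sm.OLS(v, exog).fit()
        slope = fit.params[1]
        beta = slope * np.std(x, ddof=1) / np.std(v, ddof=1)
        rows.append(
            {
                "variable": name,
                "mean_diff": float(np.mean(v[x == 1]) - np.mean(v[x == 0])),
                "t": float(fit.tvalues[1]),
                "df": int(fit.df_resid),
                "p": float(fit.pvalues[1]),
                "beta": float(beta),
                "flagged": False,
            }
        )
    return GroupComparisonResult(pd.DataFrame(rows).set_index("variable"))
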