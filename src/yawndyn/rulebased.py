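"""The timing rule for calling a mouth opening a yawn.

The rule classifies an episode as a yawn when the time to maximum mouth
opening is strictly longer than the time from maximum opening to closure.
The plateau — the stretch at maximum opening — counts as part of the
opening phase, so the comparison is

    opening_duration + plateau_duration  >  closing_duration

Ties are classified as non-yawns: "longer" is a strict inequality, and the
inputs are frame-quantized so exact ties are meaningful, not numerical
noise. The signed ``margin`` (left side minus right side) is returned for
diagnostics; the label is yawn iff the margin is positive.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import pandas as pd

from .annotations import NON_YAWN, YAWN
from .features import EpisodeFeatures


@dataclass(frozen=True)
class RuleLabel:
    episode_id: str
    label: str
    margin: float  # seconds; time-to-max-opening minus closing duration


def classify_criterion_a(features: EpisodeFeatures) -> RuleLabel:
    """Apply the timing rule to one episode's features."""
    margin = features.opening_duration + features.plateau_duration - features.closing_duration
    return RuleLabel(
        episode_id=features.episode_id,
        label=YAWN if margin > 0 else NON_YAWN,
        margin=margin,
    )


def classify_all(features: Iterable[EpisodeFeatures] | pd.DataFrame) -> pd.DataFrame:
    """Rule labels for a collection of episodes.

    Accepts either EpisodeFeatures objects or a feature table with
    ``opening_duration``, ``plateau_duration`` and ``closing_duration``
    columns. Returns a DataFrame indexed by episode id with ``label`` and
    ``margin`` columns.
    """
    if isinstance(features, pd.DataFrame):
        margin = (
            features["opening_duration"]
            + features["plateau_duration"]
            - features["closing_duration"]
        )
        return pd.DataFrame(
            {
                "label": [YAWN if m > 0 else NON_YAWN for m in margin],
                "margin": margin,
            },
            index=features.index,
        )
    rows = [classify_criterion_a(f) for f in features]
    return pd.DataFrame(
        {"label": [r.label for r in rows], "margin": [r.margin for r in rows]},
        index=pd.Index([r.episode_id for r in rows], name="episode_id"),
    )
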