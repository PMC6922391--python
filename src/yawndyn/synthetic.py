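"""Synthetic mouth-opening episodes with class-conditional phase durations.

The generator emulates the temporal structure of a coded sample of 130
neonatal mouth openings: 15 yawns and 115 non-yawn episodes, with the
three phase durations (opening, plateau, closing) drawn per class from
independent truncated normal distributions. Defaults reproduce the
published per-class summary statistics (mean, SD, min, max in seconds):

======== ========= ============== ==============
class    phase     mean (SD)      [min, max]
======== ========= ============== ==============
yawn     opening   2.01 (0.65)    [1.12, 3.67]
yawn     plateau   2.10 (0.83)    [1.04, 3.20]
yawn     closing   1.01 (0.36)    [0.53, 2.01]
non-yawn opening   0.77 (0.56)    [0.13, 3.84]
non-yawn plateau   0.44 (0.36)    [0.04, 1.88]
non-yawn closing   0.92 (0.58)    [0.11, 3.39]
======== ========= ============== ==============

A structural consequence of the yawn bounds: opening + plateau ≥ 2.16 s
while closing ≤ 2.01 s, so every generated yawn satisfies the timing rule
(time to maximum opening strictly longer than closing) — synthetic yawns
reproduce the rule's perfect sensitivity by construction.

Durations are quantized to the video frame grid (24 fps) by default, with
at least one frame per nonzero phase, mirroring frame-by-frame coding;
``fps=0`` keeps continuous durations for analytic tests. Phases are
independent within an episode (no within-episode correlations are
published); a correlation hook exists but defaults to zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .annotations import (
    NON_YAWN,
    YAWN,
    AnnotationSet,
    EpisodeAnnotation,
)

PHASES = ("opening", "plateau", "closing")


class SyntheticError(ValueError):
    pass


@dataclass(frozen=True)
class PhaseDist:
    """Truncated normal parameters for one phase duration, in seconds."""

    mean: float
    sd: float
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not (self.lower <= self.mean <= self.upper):
            raise SyntheticError(
                f"mean {self.mean} outside truncation bounds [{self.lower}, {self.upper}]"
            )
        if not self.sd > 0:
            raise SyntheticError("sd must be positive")
        if self.lower < 0:
            raise SyntheticError("durations cannot be negative")

    @property
    def _ab(self) -> tuple[float, float]:
        return (self.lower - self.mean) / self.sd, (self.upper - self.mean) / self.sd

    @property
    def acceptance_mass(self) -> float:
        a, b = self._ab
        return float(stats.norm.cdf(b) - stats.norm.cdf(a))

    def truncated_mean(self) -> float:
        """Closed-form mean of the truncated distribution."""
        a, b = self._ab
        return float(stats.truncnorm.mean(a, b, loc=self.mean, scale=self.sd))

    def truncated_sd(self) -> float:
        a, b = self._ab
        return float(stats.truncnorm.std(a, b, loc=self.mean, scale=self.sd))


#: Defaults matching the published per-class phase summaries (seconds).
YAWN_PHASES: dict[str, PhaseDist] = {
    "opening": PhaseDist(mean=2.01, sd=0.65, lower=1.12, upper=3.67),
    "plateau": PhaseDist(mean=2.10, sd=0.83, lower=1.04, upper=3.20),
    "closing": PhaseDist(mean=1.01, sd=0.36, lower=0.53, upper=2.01),
}
NON_YAWN_PHASES: dict[str, PhaseDist] = {
    "opening": PhaseDist(mean=0.77, sd=0.56, lower=0.13, upper=3.84),
    "plateau": PhaseDist(mean=0.44, sd=0.36, lower=0.04, upper=1.88),
    "closing": PhaseDist(mean=0.92, sd=0.58, lower=0.11, upper=3.39),
}

DEFAULT_N_YAWN = 15
DEFAULT_N_NON_YAWN = 115
DEFAULT_N_SUBJECTS = 17


@dataclass(frozen=True)
class SyntheticParams:
    """Per-class, per-phase distributions plus prevalence and frame grid."""

    yawn: dict[str, PhaseDist] = field(default_factory=lambda: dict(YAWN_PHASES))
    non_yawn: dict[str, PhaseDist] = field(
        default_factory=lambda: dict(NON_YAWN_PHASES)
    )
    prevalence: float = DEFAULT_N_YAWN / (DEFAULT_N_YAWN + DEFAULT_N_NON_YAWN)
    fps: float = 24.0  # 0 = continuous (no quantization)

    def __post_init__(self) -> None:
        for dists in (self.yawn, self.non_yawn):
            missing = [p for p in PHASES if p not in dists]
            if missing:
                raise SyntheticError(f"missing phase distributions: {missing}")
        if not (0 < self.prevalence < 1):
            raise SyntheticError("prevalence must be in (0, 1)")
        if self.fps < 0:
            raise SyntheticError("fps must be >= 0")

    def for_class(self, label: str) -> dict[str, PhaseDist]:
        return self.yawn if label == YAWN else self.non_yawn


DEFAULT_PARAMS = SyntheticParams()


def sample_phase(dist: PhaseDist, rng: np.random.Generator, size: int | None = None):
    """Draw duration(s) from the truncated normal; always within bounds."""
    if dist.acceptance_mass < 1e-6:
        raise SyntheticError(
            f"truncation bounds [{dist.lower}, {dist.upper}] leave negligible "
            f"mass ({dist.acceptance_mass:.2e}) under N({dist.mean}, {dist.sd}²)"
        )
    a, b = dist._ab
    draw = stats.truncnorm.rvs(
        a, b, loc=dist.mean, scale=dist.sd, size=size, random_state=rng
    )
    return float(draw) if size is None else np.asarray(draw)


def _quantize(duration: float, fps: float) -> float:
    """Snap a positive duration to the frame grid, at least one frame."""
    if fps <= 0 or duration == 0:
        return duration
    frames = max(1, round(duration * fps))
    return frames / fps


def generate_dataset(
    n_yawn: int = DEFAULT_N_YAWN,
    n_non_yawn: int = DEFAULT_N_NON_YAWN,
    params: SyntheticParams = DEFAULT_PARAMS,
    seed: int | np.random.Generator = 0,
    gap: float | None = None,
    n_subjects: int = DEFAULT_N_SUBJECTS,
) -> AnnotationSet:
    """Generate a labelled annotation set with the study's class structure.

    Per episode the three phase durations are drawn independently from the
    class's distributions, quantized to the frame grid when ``params.fps``
    > 0, and assembled into boundaries by cumulative sum from onset 0 (or
    from sequential onsets separated by ``gap`` seconds when ``gap`` is
    given, placing all episodes on one shared timeline). Class order is
    shuffled so yawns are interleaved; subjects are assigned round-robin.
    Fully reproducible from the seed.
    """
    if n_yawn < 0 or n_non_yawn < 0 or n_yawn + n_non_yawn == 0:
        raise SyntheticError("need a non-negative, non-empty episode count")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    labels = [YAWN] * n_yawn + [NON_YAWN] * n_non_yawn
    order = rng.permutation(len(labels))
    labels = [labels[i] for i in order]
    episodes = []
    t0 = 0.0
    for k, label in enumerate(labels):
        dists = params.for_class(label)
        durs = {p: sample_phase(dists[p], rng) for p in PHASES}
        if params.fps > 0:
            durs = {p: _quantize(d, params.fps) for p, d in durs.items()}
        onset = t0 if gap is not None else 0.0
        plateau_on = onset + durs["opening"]
        plateau_off = plateau_on + durs["plateau"]
        offset = plateau_off + durs["closing"]
        episodes.append(
            EpisodeAnnotation(
                episode_id=f"syn{k:04d}",
                subject_id=f"subj{(k % n_subjects) + 1:02d}",
                onset=onset,
                plateau_onset=plateau_on,
                plateau_offset=plateau_off,
                offset=offset,
                label_ref=label,
            )
        )
        if gap is not None:
            t0 = offset + gap
    return AnnotationSet(
        episodes,
        fps=params.fps if params.fps > 0 else None,
        source=f"synthetic(n_yawn={n_yawn}, n_non_yawn={n_non_yawn})",
    )


def generate_coder_pair(
    annset: AnnotationSet,
    jitter_sd: float,
    seed: int | np.random.Generator = 0,
    max_resample: int = 1000,
) -> AnnotationSet:
    """A second coder's version of an annotation set: boundaries perturbed
    by independent normal jitter, with episode ids preserved.

    Draws violating the boundary ordering (or non-positive total duration)
    are resampled. With ``jitter_sd = 0`` the copy is identical.
    """
    if jitter_sd < 0:
        raise SyntheticError("jitter_sd must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    episodes = []
    for e in annset:
        for _ in range(max_resample):
            j = rng.normal(0.0, jitter_sd, size=4) if jitter_sd > 0 else np.zeros(4)
            on, p_on, p_off, off = (
                e.onset + j[0],
                e.plateau_onset + j[1],
                e.plateau_offset + j[2],
                e.offset + j[3],
            )
            if on >= 0 and on <= p_on <= p_off <= off and off > on:
                episodes.append(
                    replace(
                        e,
                        onset=on,
                        plateau_onset=p_on,
                        plateau_offset=p_off,
                        offset=off,
                    )
                )
                break
        else:
            raise SyntheticError(
                f"could not produce an ordered jittered copy of {e.episode_id}"
            )
    return AnnotationSet(episodes, fps=annset.fps, source=annset.source + "+jitter")
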