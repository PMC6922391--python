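"""Episode annotations: validation, frame/second conversion, and file I/O.

A mouth-opening *episode* is described by four time boundaries on a common
timeline: onset of mouth opening, onset of the maximum-opening plateau,
offset of the plateau, and offset of the episode (mouth fully closed again).
The three phases — opening, plateau, closing — partition the episode.

Boundaries are stored in seconds. Frame-based codings (video coded frame by
frame at a known frame rate) are converted under a half-open convention:
an episode coded from its first visible frame ``f0`` to its last visible
frame ``f1`` occupies the interval ``[f0/fps, (f1+1)/fps)``, so a
single-frame event has duration ``1/fps`` and the phases tile the episode
exactly.
"""

from __future__ import annotations

import numbers
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd
from lxml import etree

YAWN = "yawn"
NON_YAWN = "non_yawn"
LABELS = (YAWN, NON_YAWN)

#: Canonical CSV column layouts for the two dialects.
SECONDS_COLUMNS = (
    "episode_id",
    "subject_id",
    "onset_s",
    "plateau_onset_s",
    "plateau_offset_s",
    "offset_s",
    "label_ref",
)
FRAMES_COLUMNS = (
    "episode_id",
    "subject_id",
    "onset_frame",
    "plateau_onset_frame",
    "plateau_offset_frame",
    "offset_frame",
    "label_ref",
)

DEFAULT_FPS = 24.0


class AnnotationError(ValueError):
    """Raised when an episode annotation violates the schema or ordering."""


@dataclass(frozen=True)
class EpisodeAnnotation:
    """One mouth-opening episode with four boundary times in seconds.

    Invariants (enforced at construction):

    * ``onset <= plateau_onset <= plateau_offset <= offset``
    * ``offset > onset`` (strictly positive total duration)
    * a zero-length plateau (``plateau_onset == plateau_offset``) is legal.
    """

    episode_id: str
    subject_id: str
    onset: float
    plateau_onset: float
    plateau_offset: float
    offset: float
    label_ref: str | None = None
    coder_id: str | None = None

    def __post_init__(self) -> None:
        for name in ("onset", "plateau_onset", "plateau_offset", "offset"):
            value = getattr(self, name)
            if not isinstance(value, numbers.Real) or value != value:
                raise AnnotationError(f"{name} must be a finite number, got {value!r}")
            object.__setattr__(self, name, float(value))
        if self.onset < 0:
            raise AnnotationError(f"negative onset time: {self.onset}")
        pairs = [
            ("onset", "plateau_onset"),
            ("plateau_onset", "plateau_offset"),
            ("plateau_offset", "offset"),
        ]
        for lo, hi in pairs:
            if getattr(self, lo) > getattr(self, hi):
                raise AnnotationError(
                    f"{hi} < {lo} ({getattr(self, hi)} < {getattr(self, lo)})"
                )
        if not self.offset > self.onset:
            raise AnnotationError("offset must be strictly greater than onset")
        if self.label_ref is not None and self.label_ref not in LABELS:
            raise AnnotationError(
                f"unknown label {self.label_ref!r}; expected one of {LABELS}"
            )

    def shifted(self, dt: float) -> "EpisodeAnnotation":
        """Return a copy with every boundary translated by ``dt`` seconds."""
        return replace(
            self,
            onset=self.onset + dt,
            plateau_onset=self.plateau_onset + dt,
            plateau_offset=self.plateau_offset + dt,
            offset=self.offset + dt,
        )


@dataclass
class AnnotationSet:
    """An ordered collection of episodes from one source/recording."""

    episodes: list[EpisodeAnnotation] = field(default_factory=list)
    fps: float | None = DEFAULT_FPS
    source: str = ""

    def __post_init__(self) -> None:
        if self.fps is not None and not self.fps > 0:
            raise AnnotationError(f"fps must be positive, got {self.fps}")
        ids = [e.episode_id for e in self.episodes]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise AnnotationError(f"duplicate episode ids: {dupes}")

    def __len__(self) -> int:
        return len(self.episodes)

    def __iter__(self) -> Iterator[EpisodeAnnotation]:
        return iter(self.episodes)

    def __getitem__(self, i: int) -> EpisodeAnnotation:
        return self.episodes[i]

    @property
    def labels(self) -> list[str | None]:
        return [e.label_ref for e in self.episodes]

    def to_frame(self) -> pd.DataFrame:
        """Episode boundaries and metadata as a seconds-dialect DataFrame."""
        return pd.DataFrame(
            {
                "episode_id": [e.episode_id for e in self.episodes],
                "subject_id": [e.subject_id for e in self.episodes],
                "onset_s": [e.onset for e in self.episodes],
                "plateau_onset_s": [e.plateau_onset for e in self.episodes],
                "plateau_offset_s": [e.plateau_offset for e in self.episodes],
                "offset_s": [e.offset for e in self.episodes],
                "label_ref": [e.label_ref for e in self.episodes],
                "coder_id": [e.coder_id for e in self.episodes],
            }
        )


def validate_episode(record: Mapping[str, object]) -> EpisodeAnnotation:
    """Validate a raw field mapping into an :class:`EpisodeAnnotation`.

    Required keys: ``episode_id``, ``subject_id``, ``onset``,
    ``plateau_onset``, ``plateau_offset``, ``offset``. Optional:
    ``label_ref``, ``coder_id``.
    """
    required = (
        "episode_id",
        "subject_id",
        "onset",
        "plateau_onset",
        "plateau_offset",
        "offset",
    )
    missing = [k for k in required if k not in record or record[k] is None]
    if missing:
        raise AnnotationError(f"missing required fields: {missing}")
    for k in ("onset", "plateau_onset", "plateau_offset", "offset"):
        if not isinstance(record[k], numbers.Real):
            raise AnnotationError(f"field {k} must be numeric, got {record[k]!r}")
    label = record.get("label_ref")
    if isinstance(label, float) and label != label:  # NaN from pandas
        label = None
    return EpisodeAnnotation(
        episode_id=str(record["episode_id"]),
        subject_id=str(record["subject_id"]),
        onset=float(record["onset"]),  # type: ignore[arg-type]
        plateau_onset=float(record["plateau_onset"]),  # type: ignore[arg-type]
        plateau_offset=float(record["plateau_offset"]),  # type: ignore[arg-type]
        offset=float(record["offset"]),  # type: ignore[arg-type]
        label_ref=None if label is None else str(label),
        coder_id=None if record.get("coder_id") is None else str(record["coder_id"]),
    )


def frames_to_boundaries(
    onset_f: int,
    plateau_on_f: int,
    plateau_off_f: int,
    offset_f: int,
    fps: float = DEFAULT_FPS,
) -> tuple[float, float, float, float]:
    """Convert inclusive first/last frame indices to second boundaries.

    ``onset_f``/``offset_f`` are the first and last frame where the episode
    is visible; ``plateau_on_f``/``plateau_off_f`` the first and last frame
    of the plateau. Under the half-open convention the returned boundaries
    are ``onset_f/fps``, ``plateau_on_f/fps``, ``(plateau_off_f+1)/fps`` and
    ``(offset_f+1)/fps``, so opening + plateau + closing tile the episode.
    """
    frames = (onset_f, plateau_on_f, plateau_off_f, offset_f)
    for f in frames:
        if not isinstance(f, numbers.Integral):
            raise AnnotationError(f"frame indices must be integers, got {f!r}")
    if not fps > 0:
        raise AnnotationError(f"fps must be positive, got {fps}")
    if not (onset_f <= plateau_on_f <= plateau_off_f <= offset_f):
        raise AnnotationError(f"frame indices out of order: {frames}")
    return (
        onset_f / fps,
        plateau_on_f / fps,
        (plateau_off_f + 1) / fps,
        (offset_f + 1) / fps,
    )


def _require_columns(df: pd.DataFrame, columns: Sequence[str], path: object) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise AnnotationError(f"{path}: missing required columns {missing}")


def read_episodes(
    path: str | Path,
    dialect: str = "seconds_csv",
    fps: float | None = None,
) -> AnnotationSet:
    """Read an annotation file; ``dialect`` is one of ``seconds_csv``,
    ``frames_csv`` or ``eaf``.

    The frames dialect needs a frame rate, either as an ``fps`` column in the
    file or via the ``fps`` argument. Row order is preserved; every row goes
    through :func:`validate_episode`.
    """
    path = Path(path)
    if dialect == "eaf":
        return read_eaf(path)
    if dialect not in ("seconds_csv", "frames_csv"):
        raise AnnotationError(f"unknown dialect {dialect!r}")
    df = pd.read_csv(path)
    episodes: list[EpisodeAnnotation] = []
    if dialect == "seconds_csv":
        _require_columns(df, SECONDS_COLUMNS[:6], path)
        for i, row in df.iterrows():
            try:
                episodes.append(
                    validate_episode(
                        {
                            "episode_id": row["episode_id"],
                            "subject_id": row["subject_id"],
                            "onset": row["onset_s"],
                            "plateau_onset": row["plateau_onset_s"],
                            "plateau_offset": row["plateau_offset_s"],
                            "offset": row["offset_s"],
                            "label_ref": row.get("label_ref"),
                            "coder_id": row.get("coder_id"),
                        }
                    )
                )
            except AnnotationError as err:
                raise AnnotationError(f"{path}, row {i}: {err}") from err
        return AnnotationSet(episodes, fps=fps, source=str(path))
    # frames dialect
    _require_columns(df, FRAMES_COLUMNS[:6], path)
    if fps is None:
        if "fps" not in df.columns:
            raise AnnotationError(
                f"{path}: frames dialect requires an fps column or fps argument"
            )
        fps_values = df["fps"].unique()
        if len(fps_values) != 1:
            raise AnnotationError(f"{path}: mixed fps values {fps_values}")
        fps = float(fps_values[0])
    for i, row in df.iterrows():
        try:
            on, p_on, p_off, off = frames_to_boundaries(
                int(row["onset_frame"]),
                int(row["plateau_onset_frame"]),
                int(row["plateau_offset_frame"]),
                int(row["offset_frame"]),
                fps,
            )
            episodes.append(
                validate_episode(
                    {
                        "episode_id": row["episode_id"],
                        "subject_id": row["subject_id"],
                        "onset": on,
                        "plateau_onset": p_on,
                        "plateau_offset": p_off,
                        "offset": off,
                        "label_ref": row.get("label_ref"),
                        "coder_id": row.get("coder_id"),
                    }
                )
            )
        except AnnotationError as err:
            raise AnnotationError(f"{path}, row {i}: {err}") from err
    return AnnotationSet(episodes, fps=fps, source=str(path))


def write_episodes(annset: AnnotationSet, path: str | Path) -> None:
    """Write a seconds-dialect CSV. Floats use Python ``repr`` so that a
    read-back reproduces every boundary bit-exactly."""
    path = Path(path)
    df = annset.to_frame()
    for col in ("onset_s", "plateau_onset_s", "plateau_offset_s", "offset_s"):
        df[col] = df[col].map(repr)
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# ELAN EAF (XML) reading — two independent interval tiers, paired by
# containment: each plateau interval must fall inside exactly one episode
# interval. EAF stores times in milliseconds via TIME_SLOT references.


def _eaf_tier_intervals(
    root: etree._Element, tier_id: str, times: Mapping[str, float]
) -> list[tuple[float, float, str]]:
    tier = root.find(f"TIER[@TIER_ID='{tier_id}']")
    if tier is None:
        raise AnnotationError(f"EAF tier {tier_id!r} not found")
    out = []
    for ann in tier.iter("ALIGNABLE_ANNOTATION"):
        t0 = times[ann.get("TIME_SLOT_REF1")]
        t1 = times[ann.get("TIME_SLOT_REF2")]
        out.append((t0, t1, ann.get("ANNOTATION_ID", "")))
    out.sort(key=lambda iv: iv[0])
    return out


def read_eaf(
    path: str | Path,
    episode_tier: str = "mouth_opening",
    plateau_tier: str = "plateau",
    subject_id: str | None = None,
) -> AnnotationSet:
    """Read episodes from an ELAN EAF file.

    ``episode_tier`` holds the full mouth-opening extents, ``plateau_tier``
    the plateau extents; a plateau is assigned to the episode interval that
    contains it. Episodes without a plateau annotation are rejected.
    """
    path = Path(path)
    tree = etree.parse(str(path))
    root = tree.getroot()
    times = {
        slot.get("TIME_SLOT_ID"): float(slot.get("TIME_VALUE")) / 1000.0
        for slot in root.iter("TIME_SLOT")
        if slot.get("TIME_VALUE") is not None
    }
    episodes_iv = _eaf_tier_intervals(root, episode_tier, times)
    plateaus_iv = _eaf_tier_intervals(root, plateau_tier, times)
    subject = subject_id if subject_id is not None else path.stem
    episodes = []
    for k, (on, off, ann_id) in enumerate(episodes_iv):
        inside = [p for p in plateaus_iv if p[0] >= on and p[1] <= off]
        if len(inside) != 1:
            raise AnnotationError(
                f"{path}: episode [{on}, {off}] contains {len(inside)} plateau "
                "intervals; expected exactly 1"
            )
        p_on, p_off, _ = inside[0]
        episodes.append(
            EpisodeAnnotation(
                episode_id=ann_id or f"ep{k:03d}",
                subject_id=subject,
                onset=on,
                plateau_onset=p_on,
                plateau_offset=p_off,
                offset=off,
            )
        )
    return AnnotationSet(episodes, fps=None, source=str(path))


def from_records(
    records: Iterable[Mapping[str, object]],
    fps: float | None = DEFAULT_FPS,
    source: str = "records",
) -> AnnotationSet:
    """Build an :class:`AnnotationSet` from an iterable of raw field maps."""
    return AnnotationSet([validate_episode(r) for r in records], fps=fps, source=source)
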