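"""Validate episode annotations and convert frame-based coding to seconds.

Builds two mouth-opening episodes from raw fields, converts a frame-coded
episode (video at 24 fps) to second boundaries, and round-trips the set
through the canonical CSV schema.
"""

from pathlib import Path
import tempfile

import yawndyn as yd

# A yawn-shaped episode: 2 s opening, 2.1 s plateau, 1 s closing.
episode = yd.validate_episode(
    dict(
        episode_id="ep001",
        subject_id="neonate01",
        onset=0.0,
        plateau_onset=2.0,
        plateau_offset=4.1,
        offset=5.1,
        label_ref="yawn",
    )
)
print("validated:", episode)

# Frame-coded episode: first/last visible frames, inclusive, at 24 fps.
on, p_on, p_off, off = yd.frames_to_boundaries(0, 48, 98, 122, fps=24)
print(f"frames (0, 48, 98, 122) @24fps -> boundaries "
      f"({on:.3f}, {p_on:.3f}, {p_off:.3f}, {off:.3f}) s")
print(f"  opening {p_on - on:.3f} s, plateau {p_off - p_on:.3f} s, "
      f"closing {off - p_off:.3f} s  (phases tile the episode)")

annset = yd.AnnotationSet([episode])
with tempfile.TemporaryDirectory() as d:
    path = Path(d) / "episodes.csv"
    yd.write_episodes(annset, path)
    back = yd.read_episodes(path, "seconds_csv")
    print("round-trip boundaries identical:",
          back[0].onset == episode.onset and back[0].offset == episode.offset)
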