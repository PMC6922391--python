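import numpy as np
import pytest

import yawndyn as yd


@pytest.fixture
def tiny_annset() -> yd.AnnotationSet:
    """Three hand-built episodes: one yawn-shaped, two non-yawn-shaped."""
    return yd.from_records(
        [
            dict(
                episode_id="e1",
                subject_id="s1",
                onset=0.0,
                plateau_onset=2.0,
                plateau_offset=4.1,
                offset=5.1,
                label_ref="yawn",
            ),
            dict(
                episode_id="e2",
                subject_id="s1",
                onset=10.0,
                plateau_onset=10.3,
                plateau_offset=10.4,
                offset=11.4,
                label_ref="non_yawn",
            ),
            dict(
                episode_id="e3",
                subject_id="s2",
                onset=20.0,
                plateau_onset=20.5,
                plateau_offset=21.0,
                offset=22.0,
                label_ref="non_yawn",
            ),
        ]
    )


@pytest.fixture(scope="session")
def study_sized_dataset() -> yd.AnnotationSet:
    """A generated 15-yawn / 115-non-yawn sample at the study's size."""
    return yd.generate_dataset(15, 115, seed=12345)


@pytest.fixture(scope="session")
def study_features(study_sized_dataset):
    return yd.features_frame(study_sized_dataset)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(987654321)
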