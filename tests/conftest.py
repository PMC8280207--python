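import numpy as np
import pytest

from deeppbs.imputation import make_imputer
from deeppbs.preprocessing import SegmentedSample, preprocess_cohort
from deeppbs.synthetic_cohort import SyntheticSpec, generate_cohort


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small balanced cohort with 8-h recordings (96 steps after padding)."""
    spec = SyntheticSpec(n_infants=12, death_fraction=0.5,
                         recording_hours=8.0, seed=42)
    recordings, clinical = generate_cohort(spec)
    return spec, recordings, clinical


@pytest.fixture(scope="session")
def tiny_samples(tiny_cohort):
    spec, recordings, clinical = tiny_cohort
    return preprocess_cohort(recordings, clinical,
                             imputer=make_imputer("mean"),
                             target_hours=spec.recording_hours)


def make_fake_samples(n_infants: int, S: int, n_v: int, n_dying: int,
                      seed: int = 0, signal: float = 3.0):
    """Hand-built segmented samples with a separable alert suffix, for fast
    training-loop tests without the preprocessing pipeline."""
    rng = np.random.default_rng(seed)
    samples = []
    onset = S // 4
    for i in range(n_infants):
        dying = i < n_dying
        X = rng.normal(0.0, 1.0, size=(S, n_v))
        labels = np.zeros(S, dtype=np.int8)
        if dying:
            X[onset:S - 1, 0] += signal
            labels[onset:S - 1] = 1
        X[S - 1] = 0.0
        pad_mask = np.zeros(S, dtype=bool)
        pad_mask[S - 1] = True
        end_times = np.append(300.0 * (np.arange(S - 1) + 2), np.nan)
        samples.append(SegmentedSample(
            infant_id=f"fake{i:03d}", X=X, pad_mask=pad_mask, labels=labels,
            turning_point=onset if dying else S - 1,
            segment_end_times=end_times,
            global_features=rng.normal(size=9)))
    return samples
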