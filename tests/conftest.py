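"""Shared fixtures.

The heavy end-to-end experiment (2,000-record cohort, reduced-width network,
5 epochs) is session-scoped so the acceptance tests for classification
performance and Grad-CAM interpretability share one training run.
"""

import numpy as np
import pytest

from fastegm import (ResNet1DClassifier, SynthConfig, minmax_scale,
                     resample_fft, synth_cohort)

E2E_SEED = 11


def to_classifier_input(records):
    """Downsample unipolar traces of (record, truth) pairs to 200 Hz."""
    return np.stack([resample_fft(rec.unipolar, rec.sampling_rate, 200.0)
                     for rec, _ in records])


@pytest.fixture(scope="session")
def e2e_experiment():
    """Train the reduced network on a 2,000-record synthetic cohort.

    Prevalence 0.10, default class mix, patient-level 75/25 train/test
    split, quarter-width stages, 5 epochs.  Returns the fitted classifier,
    the held-out scores and everything needed to evaluate baselines on the
    identical split.
    """
    config = SynthConfig(prevalence=0.10, seed=E2E_SEED)
    manifest, records = synth_cohort(2000, config)
    X = to_classifier_input(records)
    y = manifest["label"].to_numpy()
    groups = manifest["patient_id"].to_numpy()

    patients = np.unique(groups)
    rng = np.random.default_rng(1)
    rng.shuffle(patients)
    test_patients = set(patients[: len(patients) // 4])
    test_mask = np.array([p in test_patients for p in groups])

    clf = ResNet1DClassifier(stage_channels=(16, 32, 64, 128), epochs=5,
                             random_state=0)
    clf.fit(X[~test_mask], y[~test_mask], groups=groups[~test_mask])
    scores = clf.decision_function(X[test_mask])
    X_scaled = np.stack([minmax_scale(row) for row in X])
    return {
        "clf": clf,
        "X": X,
        "X_scaled": X_scaled,
        "y": y,
        "groups": groups,
        "test_mask": test_mask,
        "scores": scores,
    }
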