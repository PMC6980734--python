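"""Shared fixtures.

The trained phase model is expensive (generate 22k curves, train the CNN),
so it is built once per session and reused by the recovery, agreement and
end-to-end pipeline tests.
"""

import numpy as np
import pytest

import circascreen as cs
from circascreen.network import TrainingConfig, save_model, train_model


@pytest.fixture(scope="session")
def activity_template():
    return cs.canonical_template("activity")


@pytest.fixture(scope="session")
def trained_setup(activity_template, tmp_path_factory):
    """Model trained on 20k synthetic curves + a 2k held-out labelled set.

    Returns (model, model_path, X_test, y_test).
    """
    curves = cs.generate_training_set(activity_template, 22000, seed=7)
    X, y = cs.curves_to_arrays(curves)
    X_train, y_train = X[:20000], y[:20000]
    X_test, y_test = X[20000:], y[20000:]
    model, _ = train_model(X_train, y_train, TrainingConfig(max_epochs=15, seed=0))
    path = tmp_path_factory.mktemp("model") / "phase_model.npz"
    save_model(model, path)
    return model, path, X_test, y_test


def make_profile(values, zt=None, modality="activity", subject="m1",
                 genotype="WT", centre="SIM"):
    """Convenience constructor for hand-built profiles in tests."""
    if zt is None:
        zt = cs.CANONICAL_ZT.copy()
    return cs.TimeSeriesProfile(
        subject_id=subject, genotype=genotype, centre=centre,
        modality=modality, zt=np.asarray(zt, dtype=float),
        values=np.asarray(values, dtype=float),
    )
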