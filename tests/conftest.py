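import numpy as np
import pytest

from gmmwake import analog as an
from gmmwake import pipeline as pl
from gmmwake import simulate as sim
from gmmwake.features import FEATURE_COLUMNS
from gmmwake.gmm import ClassGMM, GaussianComponent, GMMClassifier


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def _symmetric_two_class(sep: float = 6.0) -> GMMClassifier:
    """Two mirror-image single-cluster classes on the x-axis."""
    a = ClassGMM(components=[GaussianComponent(mean=[-sep / 2, 0.0], var=[1.0, 1.0], weight=1.0)])
    b = ClassGMM(components=[GaussianComponent(mean=[+sep / 2, 0.0], var=[1.0, 1.0], weight=1.0)])
    return GMMClassifier(classes=[a, b])


@pytest.fixture
def mirror_classifier():
    return _symmetric_two_class()


@pytest.fixture(scope="session")
def device():
    return an.DeviceModel()


@pytest.fixture(scope="session")
def calibration(device):
    return an.calibrate_width(device)


@pytest.fixture(scope="session")
def day_scenario():
    """Day-scale synthetic study: 24 h timeline with 4 seizures, per-window
    features from the well-separated ground-truth mixtures, split 50/50,
    and a trained K=2 classifier."""
    tl = sim.generate_timeline(seed=7)
    feats = sim.generate_window_features(tl, seed=7)
    train, test = pl.train_test_split_windows(feats, train_frac=0.5, seed=7)
    clf = pl.train_classifier(train, n_clusters=2, seed=7)
    return {"timeline": tl, "features": feats, "train": train, "test": test, "clf": clf}


@pytest.fixture(scope="session")
def mapped_analog(day_scenario, device, calibration):
    scaler = an.FeatureScaler.from_data(day_scenario["train"][FEATURE_COLUMNS].to_numpy())
    cfg = an.map_gmm_to_analog(day_scenario["clf"], device=device, scaler=scaler,
                               calibration=calibration)
    return cfg
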