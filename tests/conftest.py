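import numpy as np
import pytest

from ramansom import preprocess as pre
from ramansom import synthesis as syn


@pytest.fixture(scope="session")
def default_profiles():
    return syn.make_default_profiles()


@pytest.fixture(scope="session")
def noiseless_profiles():
    """Core three states with all stochastic structure switched off."""
    profs = syn.make_default_profiles()[:3]
    out = []
    for p, w in zip(profs, (1.0, 18 / 91, 73 / 91)):
        q = syn.PopulationProfile(
            name=p.name, class_label=p.class_label,
            bands=[syn.BandSpec(b.centre, b.width, b.amplitude, 0.0)
                   for b in p.bands],
            baseline_coeffs=p.baseline_coeffs, mixing_weight=w)
        out.append(q)
    return out


@pytest.fixture(scope="session")
def small_dataset():
    """Reduced two-class set at the default effect sizes (30 + 30 cells)."""
    cfg = syn.SynthConfig(n_per_class={"normal": 30, "cancer": 30}, seed=11)
    return syn.generate_dataset(cfg)


@pytest.fixture(scope="session")
def small_preprocessed(small_dataset):
    sset, truth = small_dataset
    return pre.preprocess_set(sset), truth


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
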