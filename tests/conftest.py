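import numpy as np
import pandas as pd
import pytest

from aviantrends import specimen_data as sd
from aviantrends import synthetic_data as syn
from aviantrends import visual_model as vm


@pytest.fixture(scope="session")
def violet_eye() -> vm.VisualSystem:
    return vm.VisualSystem.violet_default()


@pytest.fixture(scope="session")
def noise(violet_eye) -> vm.ReceptorNoise:
    return vm.receptor_noise(violet_eye)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


def random_catches(rng: np.random.Generator) -> vm.QuantumCatches:
    q = np.exp(rng.normal(0.0, 1.0, 4))
    return vm.QuantumCatches(q=q, f=np.log(q))


@pytest.fixture(scope="session")
def specimen_frame() -> pd.DataFrame:
    """One synthetic species' curated specimen table (wing trait)."""
    cfg = syn.StudyConfig(master_seed=9)
    truth = syn.SpeciesTruth(name="spA", wing_slope=-0.02, depth_slope=0.0)
    recs, _ = syn.simulate_specimens(truth, cfg, seed=77, n_specimens=150)
    return sd.records_to_frame(recs)


def flat_spectrum(level: float = 1.0) -> sd.ReflectanceSpectrum:
    return sd.ReflectanceSpectrum(sd.STANDARD_GRID, np.full(401, level))
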