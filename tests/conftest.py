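import numpy as np
import pytest

from isoniche.core_data import FFG, WaterBodyType
from isoniche.synthetic_data import (
    ChemSpec,
    GroupSpec,
    ScenarioConfig,
    SubstanceSpec,
    balanced_scenario,  # noqa: F401  (re-exported for test modules)
    paper_like_scenario,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def survey_scenario():
    return paper_like_scenario(seed=11)


def simple_chem_scenario(seed: int = 0, detection_prob: float = 0.5, n_sites: int = 6):
    sites = [
        (f"S{i}", WaterBodyType.pond if i % 2 == 0 else WaterBodyType.ditch)
        for i in range(n_sites)
    ]
    substances = tuple(
        SubstanceSpec(
            name=f"sub{i}",
            detection_prob=detection_prob,
            median_conc=0.1,
            sigma_log=0.5,
            loq=0.02,
            ec50_invertebrate=10.0,
            ec50_algae=5.0,
        )
        for i in range(4)
    )
    groups = {
        (s, FFG.omnivore): GroupSpec(mu=(-28.0, 7.0), sigma=((1.0, 0.0), (0.0, 1.0)), n=5)
        for s, _ in sites
    }
    return ScenarioConfig(
        sites=sites,
        groups=groups,
        chem_spec=ChemSpec(nutrients={}, substances=substances),
        seed=seed,
    )
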