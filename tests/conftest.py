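import numpy as np
import pytest

from pkbioval.config import SimulationConfig
from pkbioval.nca import ConcentrationTimeProfile


@pytest.fixture
def default_config() -> SimulationConfig:
    return SimulationConfig(seed=7)


@pytest.fixture
def noise_free_config() -> SimulationConfig:
    return SimulationConfig(seed=7, residual_cv=0.0, body_weight_sd_kg=0.0)


def make_profile(times, concs, blq=None, dose=40.0, weight=58.3,
                 subject="s1", group="g1") -> ConcentrationTimeProfile:
    return ConcentrationTimeProfile(
        subject_id=subject,
        group=group,
        dose_mg_per_kg=dose,
        body_weight_kg=weight,
        times=np.asarray(times, dtype=float),
        concentrations=np.asarray(concs, dtype=float),
        blq_flags=None if blq is None else np.asarray(blq, dtype=bool),
    )
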