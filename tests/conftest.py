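import numpy as np
import pytest

from pdptools import (
    GrowthTruthSpec,
    LogisticParams,
    PlateTruthSpec,
    PlaqueClass,
)
from pdptools.host_range import make_standard_layout


@pytest.fixture
def small_plate_spec():
    """A small, fast plate: three well-separated plaque classes, no noise."""
    return PlateTruthSpec(
        image_size_px=(512, 512),
        concentrations={
            PlaqueClass.RED_HOST_PHAGE: 100.0,
            PlaqueClass.GREEN_HOST_PHAGE: 50.0,
            PlaqueClass.PLASMID_DEPENDENT: 30.0,
        },
        plated_volume_ml=0.1,
        lawn_noise_sd=0.0,
        plaque_radius_log_mean=1.9,
        plaque_radius_log_sd=0.2,
        min_separation_px=6.0,
        rng_seed=42,
    )


@pytest.fixture
def two_host_layout():
    return make_standard_layout(["hostA", "hostB"], ["phi1", "phi2"], replicates=3)


@pytest.fixture
def growth_spec():
    return GrowthTruthSpec(
        hosts={
            "hostA": LogisticParams(),
            "hostB": LogisticParams(rate_per_min=0.012),
        },
        inhibition={
            ("hostA", "phi1"): 1.0,
            ("hostA", "phi2"): 0.3,
            ("hostB", "phi1"): 0.0,
            ("hostB", "phi2"): 0.8,
        },
        noise_sd=0.0,
        rng_seed=1,
    )
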