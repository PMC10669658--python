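import numpy as np
import pytest

from expr2img.ingest import intersect_probes, merge_and_normalize
from expr2img.simdata import SimConfig, simulate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def small_cohort():
    """A fast two-dataset cohort with clear signal, merged and normalized."""
    cfg = SimConfig(
        n_datasets=2,
        samples_per_class_per_dataset=30,
        n_genes=120,
        n_informative=12,
        effect_size=1.5,
        noise_sd=1.0,
        classes=("AD", "NC"),
        seed=11,
    )
    mats = simulate_cohort(cfg)
    return cfg, merge_and_normalize(intersect_probes(mats))
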