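import numpy as np
import pytest

from capdyn.synthetic import SimConfig, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """Reduced 4-state cohort for structural tests (no extra-state subgroup)."""
    cfg = SimConfig(n_subjects=8, n_parcels=16, frames_per_run=80,
                    frac_subgroup_C=0.0, seed=42)
    cohort, gt, behavior, meta, subjects = generate_cohort(cfg)
    return {"config": cfg, "cohort": cohort, "gt": gt,
            "behavior": behavior, "meta": meta, "subjects": subjects}
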