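from dataclasses import replace

import pytest

import arthrasight as a
from arthrasight.cohort import add_binary_markers


def make_labelled(seed: int = 0, missing_rate: float = 0.0, scale: int = 1):
    """Generate, label and dichotomise a default-calibrated cohort."""
    cfg = replace(a.default_config(seed=seed), missing_rate=missing_rate)
    if scale != 1:
        cfg = cfg.scaled(scale)
    cohort = a.label_pre_ra(a.generate_cohort(cfg))
    cohort.df = add_binary_markers(cohort.df)
    return cohort


@pytest.fixture(scope="session")
def labelled_cohort():
    """Default study-sized cohort (180 arthralgia / 73 UA / 63 RA), complete."""
    return make_labelled(seed=0, missing_rate=0.0)


@pytest.fixture(scope="session")
def labelled_cohort_missing():
    """Default cohort with the 1.98% item missingness switched on."""
    return make_labelled(seed=0, missing_rate=0.0198)
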