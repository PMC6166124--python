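import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

import rnaedit as re_


@pytest.fixture(scope="session")
def small_cohort():
    """Error-free cohort with 7 planted sites; clean truth recovery."""
    cfg = re_.SimConfig(
        seed=11, n_edit_sites=7, n_samples=10, error_rate=0.0,
        reference_length=6000, n_genes=4, rate_range=(0.3, 0.7),
    )
    design = re_.make_design(5, 5)
    matrix, truth, design = re_.simulate_cohort(cfg, design)
    return cfg, matrix, truth, design


@pytest.fixture(scope="session")
def recovery_fixture():
    """100 planted sites, rates U[0.1, 0.9], 80 samples, depth 50.

    The fixture behind the recovery and monotonicity checks; single
    cohort, default beta dispersion.
    """
    cfg = re_.SimConfig(
        seed=101, n_edit_sites=100, n_samples=80, error_rate=0.001,
        reference_length=20_000, n_genes=10, mean_depth=50,
        rate_range=(0.1, 0.9), minus_strand_fraction=0.5,
    )
    design = re_.make_design(80, 0)
    matrix, truth, design = re_.simulate_cohort(
        cfg, design, group_rates={"healthy": (0.1, 0.9)}
    )
    profile = re_.get_profile("aorta").replace(min_supporting_samples=60)
    report = re_.run_cascade(matrix, profile)
    return cfg, matrix, truth, profile, report
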