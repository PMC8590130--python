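import math

import numpy as np
import pytest

from cosinormixed import CosinorParams, SimulationDesign, simulate_dataset
from cosinormixed.core import TWO_PI, acrophase_to_peak_time


def make_params(mesor, amplitude, acrophase, period=24.0):
    """CosinorParams with the peak time derived from the acrophase."""
    return CosinorParams(
        mesor=mesor,
        amplitude=amplitude,
        acrophase=acrophase,
        peak_time=acrophase_to_peak_time(acrophase, period),
    )


def two_group_design(
    n_subjects=40,
    obs_per_subject=8,
    amp=(10.0, 6.0),
    phase_shift=0.5,
    mesor=(60.0, 60.0),
    re_sd=(6.0, 0.0, 0.0),
    residual_sd=5.0,
    seed=0,
    **kwargs,
):
    """Binary-group design: group b differs in amplitude and acrophase."""
    phi_a = -TWO_PI * 14.0 / 24.0
    truth = {
        ("a",): make_params(mesor[0], amp[0], phi_a),
        ("b",): make_params(mesor[1], amp[1], phi_a + phase_shift),
    }
    return SimulationDesign(
        n_subjects=n_subjects,
        obs_per_subject=obs_per_subject,
        group_factors=[("grp", ["a", "b"], [0.5, 0.5])],
        truth=truth,
        random_effects_sd=re_sd,
        residual_sd=residual_sd,
        seed=seed,
        **kwargs,
    )


@pytest.fixture(scope="session")
def two_group_data():
    """One moderately sized two-group dataset shared across tests."""
    design = two_group_design(seed=20)
    ds, truth = simulate_dataset(design)
    return design, ds, truth
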