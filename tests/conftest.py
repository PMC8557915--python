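import numpy as np
import pytest

from flyfitness.vial_data import IntervalMeasurement, VialRecord
from flyfitness.synthetic import default_design, simulate_study


def make_vial(
    vial_id="v1",
    treatment="t1",
    experiment_day=1,
    replicate=1,
    pupae=(0, 12, 30, 25, 10, 4, 1, 0),
    deaths=(1, 0, 2, 1, 0, 1, 0, 1),
    censored=(0, 0, 0, 1, 0, 0, 0, 0),
    n_start=20,
):
    """Hand-buildable vial with the standard 8-interval twice-weekly grid."""
    starts = (10, 13, 17, 20, 24, 27, 31, 34)
    lengths = (3, 4, 3, 4, 3, 4, 3, 4)
    alive = n_start
    ivs = []
    for st, ln, p, d, c in zip(starts, lengths, pupae, deaths, censored):
        ivs.append(
            IntervalMeasurement(
                start_day=st,
                class_length_days=ln,
                laying_window_hours=18,
                pupae_count=p,
                females_at_start=alive,
                female_deaths=d,
                females_censored=c,
            )
        )
        alive -= d + c
    return VialRecord(
        vial_id=vial_id,
        treatment=treatment,
        experiment_day=experiment_day,
        replicate=replicate,
        intervals=ivs,
    )


@pytest.fixture
def vial():
    return make_vial()


@pytest.fixture(scope="session")
def study():
    """One default synthetic study, shared across tests (seed fixed)."""
    design = default_design(seed=1234)
    vials, logs, truth = simulate_study(design)
    return design, vials, logs, truth


@pytest.fixture
def rng():
    return np.random.default_rng(987654321)
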