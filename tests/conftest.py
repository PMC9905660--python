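import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from climtrack import PlotSurvey, Scenario

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


def make_plot(plot_id, era, counts, region="FoxeBasin", habitat="lowland", area_ha=16.0):
    return PlotSurvey(
        plot_id=plot_id, region=region, era=era, habitat=habitat, counts=counts, area_ha=area_ha
    )


@pytest.fixture
def toy_surveys():
    """4 plots x 2 eras spanning both regions and habitats, 3 species."""
    spec = [
        ("P1", "FoxeBasin", "lowland"),
        ("P2", "FoxeBasin", "upland"),
        ("P3", "Rasmussen", "lowland"),
        ("P4", "Rasmussen", "upland"),
    ]
    counts = {
        ("P1", "early"): {"AAAA": 3, "BBBB": 0, "CCCC": 1},
        ("P2", "early"): {"AAAA": 0, "BBBB": 0, "CCCC": 0},
        ("P3", "early"): {"AAAA": 2, "BBBB": 2, "CCCC": 0},
        ("P4", "early"): {"AAAA": 0, "BBBB": 1, "CCCC": 0},
        ("P1", "late"): {"AAAA": 0, "BBBB": 4, "CCCC": 2},
        ("P2", "late"): {"AAAA": 1, "BBBB": 0, "CCCC": 0},
        ("P3", "late"): {"AAAA": 0, "BBBB": 0, "CCCC": 0},
        ("P4", "late"): {"AAAA": 5, "BBBB": 0, "CCCC": 1},
    }
    return [
        make_plot(pid, era, counts[(pid, era)], region=reg, habitat=hab)
        for pid, reg, hab in spec
        for era in ("early", "late")
    ]


@pytest.fixture
def small_scenario():
    return Scenario(
        n_species=6,
        sti_targets=(-1.0, 0.0, 1.0, 2.0, 3.0, 4.0),
        n_plots=16,
        seed=3,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20230207)
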