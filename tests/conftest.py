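import numpy as np
import pytest

from brcapath.config import AGE_MAX, Cohort, ModelConfiguration
from brcapath.incidence import constrain_total_hazards, split_endpoints
from brcapath.markers import builtin_marker_tables
from brcapath.model import RiskModel


def make_config(
    freq1: float = 0.002,
    freq2: float = 0.003,
    n_loci: int = 1,
    sigma: float = 0.5,
    pop_scale: float = 1.0,
    carrier_scale: float = 1.0,
    ovarian: bool = True,
) -> ModelConfiguration:
    """A small single-cohort configuration for fast exact tests."""
    ages = np.arange(AGE_MAX)
    pop = np.where(ages >= 20, 2e-4 + 3e-5 * (ages - 20), 0.0) * pop_scale
    b1 = np.where(ages >= 20, 2e-3 + 1e-4 * np.minimum(ages - 20, 30), 0.0)
    b2 = np.where(ages >= 20, 1e-3 + 1e-4 * (ages - 20), 0.0)
    ov_pop = np.where(ages >= 30, 1e-4, 0.0) if ovarian else np.zeros(AGE_MAX)
    ov1 = np.where(ages >= 40, 5e-3, 0.0) if ovarian else np.zeros(AGE_MAX)
    ov2 = np.where(ages >= 40, 2e-3, 0.0) if ovarian else np.zeros(AGE_MAX)
    er = np.clip(0.55 - 0.004 * ages, 0.2, 1.0)
    return ModelConfiguration(
        carrier_frequency_brca1=freq1,
        carrier_frequency_brca2=freq2,
        n_polygenic_loci=n_loci,
        polygenic_sd=np.full(AGE_MAX, float(sigma)),
        test_sensitivity_brca1=0.70,
        test_sensitivity_brca2=0.80,
        cohorts=(Cohort("all", 1900, 1999),),
        population_breast_incidence={"all": pop},
        population_ovarian_incidence={"all": ov_pop},
        carrier_breast_incidence={"brca1": b1 * carrier_scale,
                                  "brca2": b2 * carrier_scale},
        carrier_ovarian_incidence={"brca1": ov1, "brca2": ov2},
        population_er_negative_proportion=er,
    )


def make_endpoints(**kwargs):
    config = make_config(**kwargs)
    hazards = constrain_total_hazards(config, "all")
    return split_endpoints(hazards, builtin_marker_tables(), config), config


@pytest.fixture(scope="session")
def toy_config():
    return make_config()


@pytest.fixture(scope="session")
def toy_endpoints(toy_config):
    hazards = constrain_total_hazards(toy_config, "all")
    return split_endpoints(hazards, builtin_marker_tables(), toy_config)


@pytest.fixture(scope="session")
def default_model():
    """The bundled illustrative parameter set, built once per session."""
    return RiskModel()
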