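"""High-level engine: cached hazard sets, risk curves and scenario grids."""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd

from .config import AGE_MAX, GENOTYPES, ModelConfiguration, default_config
from .incidence import (EndpointHazardSet, constrain_total_hazards,
                        cumulative_risk, split_endpoints)
from .likelihood import CarrierPosterior, carrier_probabilities, pedigree_loglikelihood
from .markers import MarkerProportionTable, builtin_marker_tables
from .pedigree import MarkerPanel, Pedigree, mother_daughter, single_case
from .simulate import simulate_pedigree_with_truth

#: End points exported by default in risk curves.
DEFAULT_ENDPOINTS = ("total", "er_negative", "er_positive")


class _LazyCohortMap(dict):
    """Cohort label -> EndpointHazardSet, built on first use."""

    def __init__(self, model: "RiskModel"):
        super().__init__()
        self._model = model

    def __missing__(self, label: str) -> EndpointHazardSet:
        ep = self._model._build(label)
        self[label] = ep
        return ep


class RiskModel:
    """A configured model instance: hazards, likelihoods and posteriors."""

    def __init__(
        self,
        config: ModelConfiguration | None = None,
        tables: MarkerProportionTable | None = None,
    ):
        self.config = config or default_config()
        self.tables = tables or builtin_marker_tables()
        self._cohorts = _LazyCohortMap(self)
        # ensure the mapping is never empty for downstream consumers
        self._cohorts[self.config.cohorts[-1].label]

    def _build(self, cohort: str) -> EndpointHazardSet:
        hazards = constrain_total_hazards(self.config, cohort)
        return split_endpoints(hazards, self.tables, self.config)

    def endpoints(self, cohort: str | None = None) -> EndpointHazardSet:
        """The subtype hazard set for a cohort (latest by default)."""
        return self._cohorts[cohort or self.config.cohorts[-1].label]

    @property
    def cohort_endpoints(self) -> dict:
        """Lazy mapping of cohort label to hazard set (for the likelihood)."""
        return self._cohorts

    # -- inference ----------------------------------------------------------

    def loglikelihood(self, ped: Pedigree, use_pathology: bool = True) -> float:
        return pedigree_loglikelihood(
            ped, self._cohorts, self.config, use_pathology)

    def carrier_probabilities(
        self, ped: Pedigree, target: str, use_pathology: bool = True
    ) -> CarrierPosterior:
        return carrier_probabilities(
            ped, target, self._cohorts, self.config, use_pathology)

    # -- risks --------------------------------------------------------------

    def cumulative_risk(
        self,
        genotype: str,
        endpoint: str = "total",
        to_age: int = 70,
        cohort: str | None = None,
    ) -> float:
        return cumulative_risk(self.endpoints(cohort), genotype, endpoint, to_age)

    def risk_curves(
        self,
        genotypes=GENOTYPES,
        endpoints=DEFAULT_ENDPOINTS,
        cohort: str | None = None,
    ) -> pd.DataFrame:
        """Per-age genotype-average hazards and cumulative risks.

        Hazard columns are survivor-weighted genotype averages per 100,000;
        cumulative risks are polygene-averaged cause-specific risks by the
        end of each age.
        """
        ep = self.endpoints(cohort)
        rows = []
        for g, e in itertools.product(genotypes, endpoints):
            avg = ep.average_hazard_curve(g, e) * 1e5
            for age in range(AGE_MAX):
                rows.append((ep.cohort, g, e, age, avg[age],
                             cumulative_risk(ep, g, e, age + 1)))
        return pd.DataFrame(rows, columns=[
            "cohort", "genotype", "endpoint", "age",
            "hazard_per_100000", "cumulative_risk"])

    def simulate(self, skeleton, seed: int, forced_classes=None):
        return simulate_pedigree_with_truth(
            skeleton, self.config, self._cohorts, seed, forced_classes)


# ---------------------------------------------------------------------------
# scenario grids


def _panel_from_shorthand(er="untested", tn="untested",
                          ck56="untested", ck14="untested") -> MarkerPanel:
    """Build a panel from ER/TN/CK shorthand ('tn' implies PR-, HER2-)."""
    if er == "untested":
        return MarkerPanel()
    if er == "positive":
        return MarkerPanel(er="positive")
    if tn == "untested":
        return MarkerPanel(er="negative")
    if tn == "non_tn":
        return MarkerPanel(er="negative", pr="positive")
    return MarkerPanel(er="negative", pr="negative", her2="negative",
                       ck5_6=ck56, ck14=ck14)


def _single_case_cell(age=30, er="untested", tn="untested",
                      ck56="untested", ck14="untested",
                      genetic_test="untested") -> Pedigree:
    return single_case(diagnosis_age=int(age),
                       panel=_panel_from_shorthand(er, tn, ck56, ck14),
                       genetic_test=genetic_test)


def _mother_daughter_cell(proband_age=40, mother_age=50,
                          mother_er="untested", proband_er="untested",
                          proband_test="untested") -> Pedigree:
    return mother_daughter(
        proband_age=int(proband_age), mother_age=int(mother_age),
        mother_panel=_panel_from_shorthand(er=mother_er),
        proband_panel=_panel_from_shorthand(er=proband_er),
        proband_genetic_test=proband_test)


def _tested_negative_cell(**kwargs) -> Pedigree:
    kwargs.setdefault("proband_test", "negative")
    return _mother_daughter_cell(**kwargs)


SCENARIOS = {
    "single_case": _single_case_cell,
    "mother_daughter": _mother_daughter_cell,
    "tested_negative": _tested_negative_cell,
}


def generate_probability_grid(
    model: RiskModel,
    scenario: str,
    param_ranges: dict[str, list],
    target: str = "proband",
) -> pd.DataFrame:
    """Carrier posteriors over the Cartesian grid of scenario parameters.

    One row per cell with the parameter values and the three posterior
    components (plus the combined carrier probability).
    """
    if scenario not in SCENARIOS:
        raise KeyError(f"unknown scenario {scenario!r}; "
                       f"choose from {sorted(SCENARIOS)}")
    if not param_ranges or any(len(v) == 0 for v in param_ranges.values()):
        raise ValueError("every parameter range must be non-empty")
    builder = SCENARIOS[scenario]
    names = list(param_ranges)
    rows = []
    for combo in itertools.product(*(param_ranges[n] for n in names)):
        ped = builder(**dict(zip(names, combo)))
        post = model.carrier_probabilities(ped, target)
        rows.append((*combo, post.p_noncarrier, post.p_brca1, post.p_brca2,
                     post.p_carrier))
    return pd.DataFrame(rows, columns=names + [
        "p_noncarrier", "p_brca1", "p_brca2", "p_carrier"])


def export_risk_curves(
    model: RiskModel,
    genotypes=GENOTYPES,
    endpoints=DEFAULT_ENDPOINTS,
    cohort: str | None = None,
) -> pd.DataFrame:
    """Alias of :meth:`RiskModel.risk_curves` (CSV-ready frame)."""
    return model.risk_curves(genotypes, endpoints, cohort)
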