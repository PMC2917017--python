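"""Genotype- and subtype-specific hazard construction.

Breast-cancer incidence for a woman with major genotype g and polygene level
r at age t is lambda_{g,r}(t) = c_g(t) * exp(sigma(t) * z_r).  The scale
c_g(t) is not free: for each carrier genotype the polygene-average incidence
among women still unaffected at age t must equal the configured
genotype-average incidence curve, and the average over all genotypes and
polygene levels among unaffected women must equal the configured population
incidence.  Both constraints are imposed yearly in a single forward pass that
tracks the joint (genotype, level) distribution among survivors, solving the
carrier scales directly and the noncarrier average by subtraction.

Subtype end points are split off multiplicatively: a genotype- and
age-specific fraction of the total hazard is ER-negative (carrier fractions
from the marker tables, the noncarrier fraction closed by the population
ER-negative constraint), a fraction of ER-negative disease is triple-negative,
and TN disease is partitioned into cytokeratin classes per assay scenario.
All levels of a genotype share its fractions, so every polygene level
inherits the genotype's subtype decomposition and the end points add back to
the total hazard exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import AGE_MAX, GENOTYPES, ModelConfiguration
from .errors import ConfigurationError
from .markers import CK_SCENARIOS, MarkerProportionTable, builtin_marker_tables
from .pedigree import MarkerPanel
from .polygene import PolygenicModel

_G = len(GENOTYPES)  # noncarrier, brca1, brca2


@dataclass(frozen=True)
class GenotypeHazardSet:
    """Per-(genotype, polygene level) total breast and ovarian hazards for
    one birth cohort, with the survivor distribution used to build them."""

    cohort: str
    breast: np.ndarray          # (3, L, 80) per-level breast hazards
    ovarian: np.ndarray         # (3, 80) ovarian hazards (no polygene)
    breast_average: np.ndarray  # (3, 80) survivor-weighted genotype averages
    survivor_joint: np.ndarray  # (80, 3, L) P(g, level | unaffected at age t)
    founder_joint: np.ndarray   # (3, L) founder prior
    polygene: PolygenicModel

    @property
    def n_levels(self) -> int:
        return self.breast.shape[1]


def _conditional_levels(w_g: np.ndarray, founder_levels: np.ndarray) -> np.ndarray:
    s = w_g.sum()
    return w_g / s if s > 0 else founder_levels


def constrain_total_hazards(
    config: ModelConfiguration,
    cohort: str | None = None,
    polygene: PolygenicModel | None = None,
) -> GenotypeHazardSet:
    """Build the constrained per-(genotype, level) hazard set for a cohort."""
    if cohort is None:
        cohort = config.cohorts[-1].label
    if cohort not in config.population_breast_incidence:
        raise ConfigurationError(f"unknown cohort {cohort!r}", "cohort")
    pm = polygene or PolygenicModel.from_config(config)
    L = pm.n_levels
    founder_levels = pm.founder_probabilities
    prior_g = config.genotype_prior()
    founder_joint = prior_g[:, None] * founder_levels[None, :]

    lam_pop = config.population_breast_incidence[cohort]
    lam_ov_pop = config.population_ovarian_incidence[cohort]
    lam_carrier = config.carrier_breast_incidence
    lam_ov_carrier = config.carrier_ovarian_incidence

    breast = np.zeros((_G, L, AGE_MAX))
    ovarian = np.zeros((_G, AGE_MAX))
    breast_avg = np.zeros((_G, AGE_MAX))
    survivor = np.zeros((AGE_MAX, _G, L))

    w = founder_joint.copy()  # unnormalized mass of alive-unaffected women
    for t in range(AGE_MAX):
        total = w.sum()
        if total <= 0:
            raise ConfigurationError(
                f"survivor pool exhausted at age {t} (degenerate hazards)")
        cond = w / total
        survivor[t] = cond
        pi = cond.sum(axis=1)  # genotype marginal among survivors
        u = pm.multipliers(t)

        # carrier genotypes: scale so the survivor-weighted polygene average
        # matches the configured genotype-average incidence
        for gi, g in ((1, "brca1"), (2, "brca2")):
            target = lam_carrier[g][t]
            levels = _conditional_levels(cond[gi], founder_levels)
            breast[gi, :, t] = target / float(levels @ u) * u
            breast_avg[gi, t] = target
            ovarian[gi, t] = lam_ov_carrier[g][t]

        # noncarrier averages solved from the population constraints
        lam_non = (lam_pop[t] - pi[1] * breast_avg[1, t]
                   - pi[2] * breast_avg[2, t]) / pi[0]
        if lam_non < 0:
            raise ConfigurationError(
                f"age {t}: carrier burden exceeds the population breast "
                f"incidence (implied noncarrier hazard {lam_non:.3e})")
        levels = _conditional_levels(cond[0], founder_levels)
        breast[0, :, t] = lam_non / float(levels @ u) * u
        breast_avg[0, t] = lam_non

        ov_non = (lam_ov_pop[t] - pi[1] * ovarian[1, t]
                  - pi[2] * ovarian[2, t]) / pi[0]
        if ov_non < 0:
            raise ConfigurationError(
                f"age {t}: carrier burden exceeds the population ovarian "
                f"incidence (implied noncarrier hazard {ov_non:.3e})")
        ovarian[0, t] = ov_non

        attrition = breast[:, :, t].copy()
        if config.survivor_pool == "breast_ovarian":
            attrition = attrition + ovarian[:, t][:, None]
        w = w * np.exp(-attrition)

    return GenotypeHazardSet(
        cohort=cohort, breast=breast, ovarian=ovarian,
        breast_average=breast_avg, survivor_joint=survivor,
        founder_joint=founder_joint, polygene=pm)


def genotype_distribution_among_unaffected(
    config: ModelConfiguration,
    hazards: GenotypeHazardSet,
    cohort: str | None = None,
) -> np.ndarray:
    """Joint (genotype, level) distribution among women alive and cancer-free
    at the start of each age, by forward recursion from the founder prior.

    Works for any hazard set (not only constrained ones); shape (80, 3, L).
    """
    del cohort  # the hazard set carries its cohort
    w = hazards.founder_joint.copy()
    out = np.zeros_like(hazards.survivor_joint)
    for t in range(AGE_MAX):
        total = w.sum()
        if total <= 0:
            raise ConfigurationError(
                f"survivor pool exhausted at age {t} (degenerate hazards)")
        out[t] = w / total
        attrition = hazards.breast[:, :, t].copy()
        if config.survivor_pool == "breast_ovarian":
            attrition = attrition + hazards.ovarian[:, t][:, None]
        w = w * np.exp(-attrition)
    return out


# ---------------------------------------------------------------------------
# subtype decomposition


@dataclass(frozen=True)
class EndpointHazardSet:
    """Total hazards plus the multiplicative subtype fraction layers.

    ``er_neg_frac[g, t]`` is the ER-negative share of genotype g's total
    hazard at age t; ``tn_frac`` the TN share of ER-negative disease;
    ``ck_frac[scenario][g, c, t]`` the class shares of TN disease.
    """

    base: GenotypeHazardSet
    er_neg_frac: np.ndarray                 # (3, 80)
    tn_frac: np.ndarray                     # (3, 80)
    ck_frac: dict[str, np.ndarray]          # scenario -> (3, n_classes, 80)

    @property
    def cohort(self) -> str:
        return self.base.cohort

    @property
    def n_levels(self) -> int:
        return self.base.n_levels

    def endpoint_fraction(self, genotype: str, endpoint: str) -> np.ndarray:
        """Share of the total breast hazard in the end point, per age."""
        gi = GENOTYPES.index(genotype)
        q = self.er_neg_frac[gi]
        r = self.tn_frac[gi]
        if endpoint == "total":
            return np.ones(AGE_MAX)
        if endpoint == "er_positive":
            return 1.0 - q
        if endpoint == "er_negative":
            return q
        if endpoint == "er_negative_non_tn":
            return q * (1.0 - r)
        if endpoint == "tn":
            return q * r
        for scenario, classes in CK_SCENARIOS.items():
            prefix = {"both_tested": ("tn_both_ck_positive", "tn_one_ck_positive",
                                      "tn_no_ck_positive"),
                      "ck56_only": ("tn_ck56_positive", "tn_ck56_negative"),
                      "ck14_only": ("tn_ck14_positive", "tn_ck14_negative")}[scenario]
            if endpoint in prefix:
                ci = prefix.index(endpoint)
                return q * r * self.ck_frac[scenario][gi, ci]
        raise KeyError(f"unknown end point {endpoint!r}")

    def hazard_curve(self, genotype: str, level: int, endpoint: str) -> np.ndarray:
        gi = GENOTYPES.index(genotype)
        return self.base.breast[gi, level] * self.endpoint_fraction(genotype, endpoint)

    def hazard(self, genotype: str, level: int, age: int, endpoint: str) -> float:
        return float(self.hazard_curve(genotype, level, endpoint)[age])

    def average_hazard_curve(self, genotype: str, endpoint: str) -> np.ndarray:
        """Survivor-weighted genotype-average hazard for an end point."""
        gi = GENOTYPES.index(genotype)
        return (self.base.breast_average[gi]
                * self.endpoint_fraction(genotype, endpoint))


def _closed_fraction(
    pop_frac: np.ndarray,      # (80,) population-level share of the parent layer
    parent_avg: np.ndarray,    # (3, 80) genotype-average parent-layer hazards
    carrier_frac: np.ndarray,  # (3, 80) with rows 1,2 filled
    pi: np.ndarray,            # (80, 3) genotype distribution among survivors
    layer: str,
) -> np.ndarray:
    """Solve the noncarrier share so the survivor mixture reproduces the
    population share of the parent layer at every age."""
    pop_avg = np.einsum("tg,gt->t", pi, parent_avg)
    num = pop_frac * pop_avg
    for gi in (1, 2):
        num = num - pi[:, gi] * carrier_frac[gi] * parent_avg[gi]
    denom = pi[:, 0] * parent_avg[0]
    frac = np.where(denom > 0, num / np.where(denom > 0, denom, 1.0), pop_frac)
    bad = np.nonzero((frac < -1e-12) | (frac > 1 + 1e-12))[0]
    if bad.size:
        t = int(bad[0])
        raise ConfigurationError(
            f"age {t}, end point {layer}: implied noncarrier share "
            f"{frac[t]:.4f} outside [0, 1]; carrier subtype burden is "
            "inconsistent with the population proportions")
    return np.clip(frac, 0.0, 1.0)


def split_endpoints(
    hazards: GenotypeHazardSet,
    tables: MarkerProportionTable | None = None,
    config: ModelConfiguration | None = None,
) -> EndpointHazardSet:
    """Split the constrained total hazards into tumour-subtype end points."""
    if config is None:
        raise ValueError("config is required")
    tables = tables or builtin_marker_tables()
    pi = hazards.survivor_joint.sum(axis=2)  # (80, 3)
    lam_avg = hazards.breast_average         # (3, 80)
    pop_curve = config.population_er_negative_proportion

    # ER layer
    q = np.zeros((_G, AGE_MAX))
    for t in range(AGE_MAX):
        q[1, t] = tables.er_negative_proportion("brca1", t)
        q[2, t] = tables.er_negative_proportion(
            "brca2", t, pop_curve, config.use_brca2_er_table)
    q[0] = _closed_fraction(pop_curve, lam_avg, q, pi, "er_negative")

    # TN layer (within ER-negative disease); population share = control value
    nu_avg = q * lam_avg
    r = np.zeros((_G, AGE_MAX))
    r[1] = tables.tn_given_er_neg["brca1"]
    r[2] = tables.tn_given_er_neg["brca2"]
    r_pop = np.full(AGE_MAX, tables.tn_given_er_neg["noncarrier"])
    r[0] = _closed_fraction(r_pop, nu_avg, r, pi, "tn")

    # CK layers (within TN disease), one partition per assay scenario
    tau_avg = r * nu_avg
    ck = {}
    for scenario, classes in CK_SCENARIOS.items():
        arr = np.zeros((_G, len(classes), AGE_MAX))
        for ci, cls in enumerate(classes):
            frac = np.zeros((_G, AGE_MAX))
            frac[1] = tables.ck_class_proportion("brca1", scenario, cls)
            frac[2] = tables.ck_class_proportion("brca2", scenario, cls)
            s_pop = np.full(
                AGE_MAX, tables.ck_class_proportion("noncarrier", scenario, cls))
            frac[0] = _closed_fraction(
                s_pop, tau_avg, frac, pi, f"{scenario}:{cls}")
            arr[:, ci, :] = frac
        # classes partition TN exactly; remove rounding drift in the closure
        arr[0] /= arr[0].sum(axis=0, keepdims=True)
        ck[scenario] = arr

    return EndpointHazardSet(base=hazards, er_neg_frac=q, tn_frac=r, ck_frac=ck)


def endpoint_hazard_for_panel(
    endpoints: EndpointHazardSet,
    genotype: str,
    level: int,
    age: int,
    panel: MarkerPanel,
) -> float:
    """Hazard of the finest end point observed by a marker panel, with all
    untested deeper layers marginalized."""
    return endpoints.hazard(genotype, level, age, panel.classify())


def cumulative_risk(
    endpoints: EndpointHazardSet,
    genotype: str,
    endpoint: str,
    to_age: int,
    cohort: str | None = None,
) -> float:
    """Polygene-averaged cause-specific cumulative risk by ``to_age``.

    Probability that the first breast cancer occurs before ``to_age`` and is
    of the given end point, ignoring non-breast-cancer mortality:
    E_r[ sum_t frac_e(t) * (S_r(t) - S_r(t+1)) ] with S_r the survival
    function of the level-r total breast hazard.  End-point risks therefore
    add to the total breast risk 1 - E_r[S_r(to_age)] exactly.
    """
    if cohort is not None and cohort != endpoints.cohort:
        raise ValueError(
            f"hazard set is for cohort {endpoints.cohort!r}, not {cohort!r}")
    if not 0 <= to_age <= AGE_MAX:
        raise ValueError(f"to_age must be in 0..{AGE_MAX}")
    gi = GENOTYPES.index(genotype)
    frac = endpoints.endpoint_fraction(genotype, endpoint)[:to_age]
    lam = endpoints.base.breast[gi, :, :to_age]          # (L, to_age)
    surv = np.exp(-np.cumsum(lam, axis=1))               # S(t+1)
    s_prev = np.concatenate([np.ones((lam.shape[0], 1)), surv[:, :-1]], axis=1)
    event_mass = s_prev - surv                           # per-year first-event mass
    p = endpoints.base.polygene.founder_probabilities
    return float(p @ (event_mass @ frac))
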