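"""Exact pedigree likelihood and Bayesian carrier posteriors.

The joint genetic state of an individual is (major-locus genotype, polygene
level).  The major locus has three alleles (wild, b1, b2) in Hardy-Weinberg
equilibrium among founders and Mendelian transmission; its six unordered
genotypes collapse by dominance onto the three carrier classes (noncarrier,
BRCA1 carrier, BRCA2 carrier), with b1 taking precedence in the rare double
heterozygote.  The polygene level follows the hypergeometric transmission
law.  Phenotypes (cancer diagnoses with marker panels, censoring, mutation
tests) enter as per-individual penetrance factors, and the likelihood is the
exact sum over all joint assignments, computed by peeling (sum-product
variable elimination over the family graph, exact for the loop-free
pedigrees this package accepts).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .config import AGE_MAX, GENOTYPES, ModelConfiguration
from .errors import PedigreeError
from .incidence import EndpointHazardSet
from .pedigree import Individual, Pedigree, validate_pedigree
from .polygene import transmission_tensor

#: Unordered genotypes of the three-allele major locus (0=wild, 1=b1, 2=b2).
GENO6 = ((0, 0), (0, 1), (0, 2), (1, 1), (1, 2), (2, 2))
#: Carrier class of each genotype (index into GENOTYPES).
GENO6_CLASS = (0, 1, 2, 1, 1, 2)


@lru_cache(maxsize=1)
def mendelian_tensor() -> np.ndarray:
    """M[child, father, mother] over the six unordered genotypes."""
    M = np.zeros((6, 6, 6))
    index = {g: i for i, g in enumerate(GENO6)}
    for fi, fg in enumerate(GENO6):
        for mi, mg in enumerate(GENO6):
            for fa in fg:
                for ma in mg:
                    child = tuple(sorted((fa, ma)))
                    M[index[child], fi, mi] += 0.25
    M.setflags(write=False)
    return M


def founder_genotype_prior(config: ModelConfiguration) -> np.ndarray:
    """Hardy-Weinberg masses over the six unordered genotypes."""
    f1, f2 = config.allele_frequency_brca1, config.allele_frequency_brca2
    p = np.array([1.0 - f1 - f2, f1, f2])
    out = np.empty(6)
    for i, (a, b) in enumerate(GENO6):
        out[i] = p[a] * p[b] if a == b else 2.0 * p[a] * p[b]
    return out


def class_collapse(values_by_class: np.ndarray) -> np.ndarray:
    """Expand an array indexed by carrier class (3, ...) to genotype (6, ...)."""
    return values_by_class[list(GENO6_CLASS)]


# ---------------------------------------------------------------------------
# penetrance


def _genetic_test_factor(ind: Individual, config: ModelConfiguration) -> np.ndarray:
    """Per-class likelihood of the mutation-test result (specificity 1)."""
    s1, s2 = config.test_sensitivity_brca1, config.test_sensitivity_brca2
    if ind.genetic_test == "untested":
        return np.ones(3)
    if ind.genetic_test == "negative":
        return np.array([1.0, 1.0 - s1, 1.0 - s2])
    if ind.genetic_test == "brca1_positive":
        return np.array([0.0, s1, 0.0])
    return np.array([0.0, 0.0, s2])


def penetrance_table(
    ind: Individual,
    endpoints: EndpointHazardSet,
    config: ModelConfiguration,
    use_pathology: bool = True,
) -> np.ndarray:
    """Likelihood of the individual's phenotype for every (class, level).

    Product of a survival term to the first event (or censoring), the breast
    end-point hazard at diagnosis (the finest observed panel level, or the
    total hazard when ``use_pathology`` is off), the ovarian hazard at
    diagnosis, and the mutation-test term.  Returns shape (3, n_levels).
    """
    L = endpoints.n_levels
    out = np.ones((3, L))
    if ind.sex == "F":
        for name, age in (("breast_cancer_age", ind.breast_cancer_age),
                          ("ovarian_cancer_age", ind.ovarian_cancer_age)):
            if age is not None and not 0 <= age < AGE_MAX:
                raise PedigreeError(f"{ind.id}: {name} {age} outside model grid")
        T = min(ind.censor_age, AGE_MAX)
        if T > 0:
            cum = (endpoints.base.breast[:, :, :T].sum(axis=2)
                   + endpoints.base.ovarian[:, :T].sum(axis=1)[:, None])
            out *= np.exp(-cum)
        first = ind.censor_age
        if ind.breast_cancer_age is not None and ind.breast_cancer_age == first:
            key = ind.panel.classify() if use_pathology else "total"
            gi_haz = np.stack([
                [endpoints.hazard(g, lev, first, key) for lev in range(L)]
                for g in GENOTYPES])
            out *= gi_haz
        if ind.ovarian_cancer_age is not None and ind.ovarian_cancer_age == first:
            out *= endpoints.base.ovarian[:, first][:, None]
    out *= _genetic_test_factor(ind, config)[:, None]
    return out


def individual_penetrance(
    ind: Individual,
    genotype: str,
    level: int,
    endpoints: EndpointHazardSet,
    config: ModelConfiguration,
    use_pathology: bool = True,
) -> float:
    """Penetrance factor for one (major genotype, polygene level) state."""
    table = penetrance_table(ind, endpoints, config, use_pathology)
    return float(table[GENOTYPES.index(genotype), level])


# ---------------------------------------------------------------------------
# variable elimination


def _multiply_factors(factors, K: int):
    """Multiply factors (vars-tuple, ndarray) over the union of their scopes."""
    union: list[str] = []
    for fvars, _ in factors:
        for v in fvars:
            if v not in union:
                union.append(v)
    out = np.ones((1,) * len(union))
    for fvars, arr in factors:
        # transpose/expand the factor's axes into the union's axis order
        perm = sorted(range(len(fvars)), key=lambda i: union.index(fvars[i]))
        a = np.transpose(arr, perm)
        shape = [K if v in fvars else 1 for v in union]
        out = out * a.reshape(shape)
    return union, out


class _Peeler:
    """Sum-product elimination over per-individual joint states."""

    def __init__(self, factors, K: int):
        self.factors = list(factors)
        self.K = K
        self.log_scale = 0.0
        self.zero = False

    def eliminate(self, keep: set[str]) -> np.ndarray | float:
        variables = {v for fvars, _ in self.factors for v in fvars}
        while variables - keep:
            # greedy min-fill-ish: smallest union scope when eliminated
            def cost(v: str) -> int:
                scope = {u for fvars, _ in self.factors if v in fvars
                         for u in fvars}
                return len(scope)

            v = min(sorted(variables - keep), key=cost)
            related = [f for f in self.factors if v in f[0]]
            rest = [f for f in self.factors if v not in f[0]]
            union, prod = _multiply_factors(related, self.K)
            summed = prod.sum(axis=union.index(v))
            scale = summed.sum()
            if scale <= 0.0 or not np.isfinite(scale):
                self.zero = True
                return 0.0
            self.log_scale += math.log(scale)
            new_vars = tuple(u for u in union if u != v)
            self.factors = rest + [(new_vars, summed / scale)]
            variables = {u for fvars, _ in self.factors for u in fvars}
        union, prod = _multiply_factors(self.factors, self.K)
        return prod


def _build_factors(
    ped: Pedigree,
    endpoints_by_cohort,
    config: ModelConfiguration,
    use_pathology: bool,
):
    """Founder priors, transmissions and penetrances as joint-state factors."""
    any_ep = next(iter(endpoints_by_cohort.values()))
    L = any_ep.n_levels
    K = 6 * L
    prior6 = founder_genotype_prior(config)
    founder_levels = any_ep.base.polygene.founder_probabilities
    prior = (prior6[:, None] * founder_levels[None, :]).reshape(K)
    M = mendelian_tensor()
    H = transmission_tensor(any_ep.base.polygene.n_loci)
    trans = np.einsum("cfm,CFM->cCfFmM", M, H).reshape(K, K, K)

    factors = []
    for ind in ped:
        if ind.is_founder:
            factors.append(((ind.id,), prior))
        else:
            factors.append(((ind.id, ind.father_id, ind.mother_id), trans))
        ep = _resolve_endpoints(ind, endpoints_by_cohort, config)
        pen = penetrance_table(ind, ep, config, use_pathology)
        factors.append(((ind.id,), class_collapse(pen).reshape(K)))
    return factors, K, L


def _resolve_endpoints(ind, endpoints_by_cohort, config) -> EndpointHazardSet:
    label = config.cohort_for_birth_year(ind.birth_year).label
    try:
        return endpoints_by_cohort[label]
    except KeyError:
        raise KeyError(f"no hazard set built for cohort {label!r}") from None


def _as_cohort_mapping(endpoints) -> dict:
    if isinstance(endpoints, EndpointHazardSet):
        import collections

        return collections.defaultdict(lambda: endpoints, {None: endpoints})
    return endpoints


def _check_valid(ped: Pedigree) -> None:
    issues = validate_pedigree(ped)
    if issues:
        raise PedigreeError(
            "pedigree failed validation: " + "; ".join(str(i) for i in issues))


def pedigree_loglikelihood(
    ped: Pedigree,
    endpoints,
    config: ModelConfiguration,
    use_pathology: bool = True,
) -> float:
    """Exact log-likelihood of all observed data in the pedigree.

    ``endpoints`` is an :class:`EndpointHazardSet` (applied to every member)
    or a mapping of cohort label to hazard set.
    """
    _check_valid(ped)
    factors, K, _ = _build_factors(
        ped, _as_cohort_mapping(endpoints), config, use_pathology)
    peeler = _Peeler(factors, K)
    remainder = peeler.eliminate(keep=set())
    if peeler.zero:
        return -math.inf
    return peeler.log_scale + math.log(float(np.asarray(remainder).reshape(())))


@dataclass(frozen=True)
class CarrierPosterior:
    """Posterior over the proband's major-genotype class."""

    p_noncarrier: float
    p_brca1: float
    p_brca2: float

    def __post_init__(self):
        total = self.p_noncarrier + self.p_brca1 + self.p_brca2
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"posterior does not normalize: sum={total!r}")
        if min(self.p_noncarrier, self.p_brca1, self.p_brca2) < 0:
            raise ValueError("negative posterior component")

    @property
    def p_carrier(self) -> float:
        """Combined BRCA1 + BRCA2 carrier probability."""
        return self.p_brca1 + self.p_brca2

    def as_dict(self) -> dict[str, float]:
        return {"noncarrier": self.p_noncarrier, "brca1": self.p_brca1,
                "brca2": self.p_brca2}


def carrier_probabilities(
    ped: Pedigree,
    target: str,
    endpoints,
    config: ModelConfiguration,
    use_pathology: bool = True,
) -> CarrierPosterior:
    """P(target's class | all family data), polygene marginalized.

    Ratio of the pedigree likelihoods with the target's major genotype
    clamped to each class, obtained in one peeling pass that keeps the
    target's joint state.
    """
    if target not in ped:
        raise KeyError(f"no individual {target!r} in pedigree")
    _check_valid(ped)
    factors, K, L = _build_factors(
        ped, _as_cohort_mapping(endpoints), config, use_pathology)
    peeler = _Peeler(factors, K)
    marginal = peeler.eliminate(keep={target})
    if peeler.zero:
        raise ZeroDivisionError("pedigree data have zero likelihood")
    marginal = np.asarray(marginal).reshape(6, L).sum(axis=1)
    by_class = np.zeros(3)
    for gi, cls in enumerate(GENO6_CLASS):
        by_class[cls] += marginal[gi]
    total = by_class.sum()
    if total <= 0:
        raise ZeroDivisionError("pedigree data have zero likelihood")
    by_class = by_class / total
    # exact renormalization guard against accumulated roundoff
    by_class = by_class / by_class.sum()
    return CarrierPosterior(*by_class)
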