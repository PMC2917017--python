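"""Forward pedigree simulation: the generative mirror of the model.

Founder genotypes are drawn from the Hardy-Weinberg prior and the binomial
polygene distribution; children receive one allele from each parent and a
hypergeometric polygene draw.  Ages at first cancer are sampled year by year
from the per-(genotype, level) total hazards, and tumour subtype labels from
the same marker-proportion conditionals the likelihood uses.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .config import AGE_MAX, GENOTYPES, ModelConfiguration
from .incidence import EndpointHazardSet
from .likelihood import GENO6, GENO6_CLASS, founder_genotype_prior
from .pedigree import Individual, MarkerPanel, Pedigree

#: Forced-founder genotype per carrier class (heterozygote for carriers).
_FORCED_GENO = {"noncarrier": (0, 0), "brca1": (0, 1), "brca2": (0, 2)}


def _resolve(endpoints, config, ind) -> EndpointHazardSet:
    if isinstance(endpoints, EndpointHazardSet):
        return endpoints
    return endpoints[config.cohort_for_birth_year(ind.birth_year).label]


def _sample_panel(
    rng: np.random.Generator, ep: EndpointHazardSet, gi: int, age: int
) -> MarkerPanel:
    """Draw a fully assayed marker panel from the subtype conditionals."""
    if rng.random() >= ep.er_neg_frac[gi, age]:
        return MarkerPanel(er="positive")
    if rng.random() >= ep.tn_frac[gi, age]:
        # ER-negative, non-TN: a positive PR establishes non-TN status
        return MarkerPanel(er="negative", pr="positive")
    base = dict(er="negative", pr="negative", her2="negative")
    probs = ep.ck_frac["both_tested"][gi, :, age]
    cls = rng.choice(3, p=probs / probs.sum())
    if cls == 0:
        return MarkerPanel(**base, ck5_6="positive", ck14="positive")
    if cls == 2:
        return MarkerPanel(**base, ck5_6="negative", ck14="negative")
    # exactly one CK positive: split by the single-assay marginal excesses
    e56 = max(ep.ck_frac["ck56_only"][gi, 0, age]
              - ep.ck_frac["both_tested"][gi, 0, age], 0.0)
    e14 = max(ep.ck_frac["ck14_only"][gi, 0, age]
              - ep.ck_frac["both_tested"][gi, 0, age], 0.0)
    p56 = 0.5 if e56 + e14 == 0 else e56 / (e56 + e14)
    if rng.random() < p56:
        return MarkerPanel(**base, ck5_6="positive", ck14="negative")
    return MarkerPanel(**base, ck5_6="negative", ck14="positive")


def _sample_onset(
    rng: np.random.Generator,
    ep: EndpointHazardSet,
    gi: int,
    level: int,
    max_age: int,
) -> tuple[int, str] | None:
    """First cancer (age, type) before ``max_age``, or None."""
    lam_b = ep.base.breast[gi, level]
    lam_o = ep.base.ovarian[gi]
    tot = lam_b + lam_o
    stop = min(max_age + 1, AGE_MAX)
    u = rng.random(stop)
    p_event = 1.0 - np.exp(-tot[:stop])
    hits = np.nonzero(u < p_event)[0]
    if hits.size == 0:
        return None
    t = int(hits[0])
    kind = "breast" if rng.random() < lam_b[t] / tot[t] else "ovarian"
    return t, kind


def simulate_pedigree_with_truth(
    skeleton: Pedigree,
    config: ModelConfiguration,
    endpoints,
    seed: int,
    forced_classes: dict[str, str] | None = None,
) -> tuple[Pedigree, dict[str, dict]]:
    """Simulate phenotypes onto a skeleton; also return the latent states.

    The skeleton provides structure, sexes, birth years and observation ages;
    phenotype fields are overwritten.  ``forced_classes`` clamps named
    founders' major genotypes ({"noncarrier", "brca1", "brca2"}, carriers as
    heterozygotes).  Reproducible given the seed.
    """
    rng = np.random.default_rng(seed)
    forced = forced_classes or {}
    prior6 = founder_genotype_prior(config)
    truth: dict[str, dict] = {}
    geno: dict[str, tuple[int, int]] = {}
    level: dict[str, int] = {}
    out: list[Individual] = []

    for ind in skeleton.topological_order():
        ep = _resolve(endpoints, config, ind)
        n = ep.base.polygene.n_loci
        if ind.id in forced:
            geno[ind.id] = _FORCED_GENO[forced[ind.id]]
        elif ind.is_founder:
            geno[ind.id] = GENO6[rng.choice(6, p=prior6 / prior6.sum())]
        else:
            fa, fb = geno[ind.father_id]
            ma, mb = geno[ind.mother_id]
            geno[ind.id] = tuple(sorted((
                fa if rng.random() < 0.5 else fb,
                ma if rng.random() < 0.5 else mb)))
        if ind.is_founder or ind.id in forced:
            level[ind.id] = int(rng.binomial(2 * n, 0.5))
        else:
            level[ind.id] = int(
                rng.hypergeometric(level[ind.father_id],
                                   2 * n - level[ind.father_id], n)
                + rng.hypergeometric(level[ind.mother_id],
                                     2 * n - level[ind.mother_id], n))
        g6 = GENO6.index(geno[ind.id])
        gi = GENO6_CLASS[g6]
        truth[ind.id] = {"genotype": geno[ind.id],
                         "class": GENOTYPES[gi], "level": level[ind.id]}

        obs = ind.observation_age if ind.observation_age is not None else AGE_MAX - 1
        breast_age = ovarian_age = None
        panel = MarkerPanel()
        if ind.sex == "F" and obs > 0:
            onset = _sample_onset(rng, ep, gi, level[ind.id], min(obs, AGE_MAX - 1))
            if onset is not None:
                t, kind = onset
                if kind == "breast":
                    breast_age = t
                    panel = _sample_panel(rng, ep, gi, t)
                else:
                    ovarian_age = t
        out.append(replace(ind, breast_cancer_age=breast_age,
                           ovarian_cancer_age=ovarian_age, panel=panel,
                           genetic_test="untested"))
    return Pedigree(out, auto_complete=False), truth


def simulate_pedigree(
    skeleton: Pedigree,
    config: ModelConfiguration,
    endpoints,
    seed: int,
    forced_classes: dict[str, str] | None = None,
) -> Pedigree:
    """Simulate phenotypes onto a skeleton pedigree (see the detailed variant)."""
    ped, _ = simulate_pedigree_with_truth(
        skeleton, config, endpoints, seed, forced_classes)
    return ped


def simulate_cases(
    endpoints: EndpointHazardSet,
    genotype: str,
    n_cases: int,
    seed: int,
    max_age: int = AGE_MAX - 1,
) -> pd.DataFrame:
    """Breast-cancer cases in women of a clamped major genotype.

    Draws independent women (founder polygene levels), follows each to
    ``max_age``, and keeps the first ``n_cases`` breast cancers.  Returns a
    frame with onset age and subtype labels (ER, TN, CK class under the
    both-CKs-tested scenario).
    """
    if genotype not in GENOTYPES:
        raise KeyError(f"unknown genotype {genotype!r}")
    gi = GENOTYPES.index(genotype)
    rng = np.random.default_rng(seed)
    n_loci = endpoints.base.polygene.n_loci
    lam_o = endpoints.base.ovarian[gi]
    stop = min(max_age + 1, AGE_MAX)

    rows: list[tuple] = []
    batch = max(1024, n_cases)
    while len(rows) < n_cases:
        levels = rng.binomial(2 * n_loci, 0.5, size=batch)
        lam_b = endpoints.base.breast[gi][levels, :stop]     # (batch, stop)
        tot = lam_b + lam_o[:stop]
        u = rng.random((batch, stop))
        hit = u < 1.0 - np.exp(-tot)
        has = hit.any(axis=1)
        first = np.where(has, hit.argmax(axis=1), -1)
        for i in np.nonzero(has)[0]:
            t = int(first[i])
            if rng.random() >= lam_b[i, t] / tot[i, t]:
                continue  # first event was ovarian
            gi_ep = endpoints
            er_neg = rng.random() < gi_ep.er_neg_frac[gi, t]
            tn = bool(er_neg and rng.random() < gi_ep.tn_frac[gi, t])
            ck = ""
            if tn:
                probs = gi_ep.ck_frac["both_tested"][gi, :, t]
                ck = ("both_pos", "one_pos", "neither_pos")[
                    rng.choice(3, p=probs / probs.sum())]
            rows.append((t, er_neg, tn, ck))
            if len(rows) >= n_cases:
                break
    return pd.DataFrame(rows, columns=["age", "er_negative", "tn", "ck_class"])
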