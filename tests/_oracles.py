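"""Independent oracles for cross-checking the peeling likelihood.

``enumerate_loglikelihood`` sums the full joint over every assignment of
(major genotype, polygene level) to every pedigree member by materializing
the K^n joint table — no elimination, no factor ordering — so it shares no
summation machinery with the production path it checks.
"""

from __future__ import annotations

import math

import numpy as np

from brcapath.likelihood import (class_collapse, founder_genotype_prior,
                                 mendelian_tensor, penetrance_table)
from brcapath.pedigree import Individual, MarkerPanel, Pedigree
from brcapath.polygene import transmission_tensor


def enumerate_loglikelihood(ped, endpoints, config, use_pathology=True) -> float:
    """Exhaustive sum over all joint genotype assignments."""
    pm = endpoints.base.polygene
    L = pm.n_levels
    K = 6 * L
    ids = list(ped.ids)
    pos = {i: k for k, i in enumerate(ids)}
    n = len(ids)

    prior6 = founder_genotype_prior(config)
    prior = (prior6[:, None] * pm.founder_probabilities[None, :]).reshape(K)
    trans = np.einsum("cfm,CFM->cCfFmM", mendelian_tensor(),
                      transmission_tensor(pm.n_loci)).reshape(K, K, K)

    def place(arr: np.ndarray, axes: list[int]) -> np.ndarray:
        """Broadcast ``arr`` (one axis per entry of ``axes``) into the joint."""
        order = np.argsort(axes)
        arr = np.transpose(arr, order)
        shape = [1] * n
        for a in sorted(axes):
            shape[a] = K
        return arr.reshape(shape)

    joint = np.ones((K,) * n)
    for ind in ped:
        i = pos[ind.id]
        if ind.is_founder:
            joint *= place(prior, [i])
        else:
            joint *= place(trans, [i, pos[ind.father_id], pos[ind.mother_id]])
        pen = class_collapse(
            penetrance_table(ind, endpoints, config, use_pathology)).reshape(K)
        joint *= place(pen, [i])
    total = float(joint.sum())
    return math.log(total) if total > 0 else -math.inf


def random_pedigree(rng: np.random.Generator, n_members: int,
                    p_affected: float = 0.5) -> Pedigree:
    """A random loop-free pedigree with random phenotypes and marker panels.

    Structure grows by attaching either a child of an existing couple or a
    new-founder spouse plus child, so the marriage graph stays a tree.
    """
    members = [
        _random_individual(rng, "f0", "M", p_affected),
        _random_individual(rng, "m0", "F", p_affected),
    ]
    couples = [("f0", "m0")]
    matable: list[Individual] = []
    k = 0
    while len(members) < n_members:
        k += 1
        sex = "M" if rng.random() < 0.5 else "F"
        if matable and rng.random() < 0.4 and len(members) + 1 < n_members:
            # marry in a new founder and give the couple a child
            old = matable.pop(rng.integers(len(matable)))
            spouse = _random_individual(
                rng, f"s{k}", "F" if old.sex == "M" else "M", p_affected)
            members.append(spouse)
            father, mother = ((old.id, spouse.id) if old.sex == "M"
                              else (spouse.id, old.id))
            couples.append((father, mother))
            child = _random_individual(rng, f"c{k}", sex, p_affected,
                                       father=father, mother=mother)
        else:
            father, mother = couples[rng.integers(len(couples))]
            child = _random_individual(rng, f"c{k}", sex, p_affected,
                                       father=father, mother=mother)
        members.append(child)
        matable.append(child)
    return Pedigree(members[:n_members], auto_complete=False)


def _random_panel(rng: np.random.Generator) -> MarkerPanel:
    u = rng.random()
    if u < 0.3:
        return MarkerPanel()
    if u < 0.5:
        return MarkerPanel(er="positive")
    if u < 0.65:
        return MarkerPanel(er="negative")
    if u < 0.75:
        return MarkerPanel(er="negative", pr="positive")
    base = dict(er="negative", pr="negative", her2="negative")
    if u < 0.85:
        return MarkerPanel(**base)
    flip = lambda: "positive" if rng.random() < 0.5 else "negative"  # noqa: E731
    if u < 0.93:
        return MarkerPanel(**base, ck5_6=flip(), ck14=flip())
    return MarkerPanel(**base, ck5_6=flip())


def _random_individual(rng, ind_id, sex, p_affected,
                       father=None, mother=None) -> Individual:
    obs = int(rng.integers(20, 80))
    breast = ovarian = None
    panel = MarkerPanel()
    if sex == "F" and rng.random() < p_affected:
        if rng.random() < 0.85:
            breast = int(rng.integers(25, obs + 1)) if obs >= 25 else None
            if breast is not None:
                panel = _random_panel(rng)
        else:
            ovarian = int(rng.integers(30, obs + 1)) if obs >= 30 else None
    test = "negative" if rng.random() < 0.1 else "untested"
    return Individual(
        id=ind_id, sex=sex, father_id=father, mother_id=mother,
        birth_year=int(rng.integers(1925, 1975)), observation_age=obs,
        breast_cancer_age=breast, ovarian_cancer_age=ovarian,
        panel=panel, genetic_test=test)
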