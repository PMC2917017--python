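"""Hypergeometric polygenic model.

A standard-normal polygenic log-hazard component is approximated by a
discrete allele count over N diallelic loci: an individual's level r is the
number of "high" alleles among 2N, Binomial(2N, 1/2) in founders.  A child
receives N alleles sampled without replacement from each parent's 2N
(hypergeometric draws), which preserves the founder distribution under random
mating.  The standardized value z = (r - N) / sqrt(N/2) has mean 0 and
variance 1, and multiplies the hazard by exp(sigma(t) * z).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import stats

from .config import AGE_MAX, ModelConfiguration


def founder_distribution(n_loci: int) -> np.ndarray:
    """Binomial(2N, 1/2) masses over levels 0..2N."""
    if n_loci < 1:
        raise ValueError("n_loci must be >= 1")
    return stats.binom.pmf(np.arange(2 * n_loci + 1), 2 * n_loci, 0.5)


def standardized_levels(n_loci: int) -> np.ndarray:
    """z_r = (r - N) / sqrt(N/2) for r = 0..2N."""
    r = np.arange(2 * n_loci + 1, dtype=float)
    return (r - n_loci) / np.sqrt(n_loci / 2.0)


def transmission_distribution(
    father_level: int, mother_level: int, n_loci: int
) -> np.ndarray:
    """Distribution of the child's level given parental levels.

    The child level is K_f + K_m where K_p ~ Hypergeometric(2N, r_p, N):
    N alleles drawn without replacement from parent p's 2N alleles, r_p of
    which are high.
    """
    n = n_loci
    for lev in (father_level, mother_level):
        if not 0 <= lev <= 2 * n:
            raise ValueError(f"level {lev} invalid for N={n}")
    k = np.arange(n + 1)
    pf = stats.hypergeom.pmf(k, 2 * n, father_level, n)
    pm = stats.hypergeom.pmf(k, 2 * n, mother_level, n)
    return np.convolve(pf, pm)  # length 2N+1


@lru_cache(maxsize=None)
def transmission_tensor(n_loci: int) -> np.ndarray:
    """T[child, father, mother] over levels 0..2N (cached per N)."""
    L = 2 * n_loci + 1
    T = np.empty((L, L, L))
    for f in range(L):
        for m in range(L):
            T[:, f, m] = transmission_distribution(f, m, n_loci)
    T.setflags(write=False)
    return T


@dataclass(frozen=True)
class PolygenicModel:
    """Discrete polygene: level space, founder masses and age scale."""

    n_loci: int
    sd_schedule: np.ndarray  # sigma(t), shape (80,)

    def __post_init__(self):
        if self.n_loci < 1:
            raise ValueError("n_loci must be >= 1")
        if self.sd_schedule.shape != (AGE_MAX,):
            raise ValueError("sd schedule must cover ages 0..79")

    @classmethod
    def from_config(cls, config: ModelConfiguration) -> "PolygenicModel":
        return cls(n_loci=int(config.n_polygenic_loci),
                   sd_schedule=np.asarray(config.polygenic_sd, dtype=float))

    @property
    def n_levels(self) -> int:
        return 2 * self.n_loci + 1

    @property
    def levels(self) -> np.ndarray:
        return np.arange(self.n_levels)

    @property
    def founder_probabilities(self) -> np.ndarray:
        return founder_distribution(self.n_loci)

    @property
    def z(self) -> np.ndarray:
        return standardized_levels(self.n_loci)

    def sigma(self, age: int) -> float:
        if not 0 <= age < AGE_MAX:
            raise ValueError(f"sigma undefined at age {age}")
        return float(self.sd_schedule[age])

    def multipliers(self, age: int) -> np.ndarray:
        """Hazard multipliers exp(sigma(age) * z) for every level."""
        return np.exp(self.sigma(age) * self.z)


def polygene_multiplier(level: int, age: int, model: PolygenicModel) -> float:
    """Hazard multiplier exp(sigma(age) * (level - N)/sqrt(N/2))."""
    if not 0 <= level < model.n_levels:
        raise ValueError(f"level {level} invalid for N={model.n_loci}")
    return float(np.exp(model.sigma(age) * model.z[level]))
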