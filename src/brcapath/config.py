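"""Model-parameter configuration: incidence tables, mutation frequencies,
polygenic scale and genetic-test sensitivities.

All rates are stored internally as events per person-year on a yearly age grid
0..79; configuration files give them per 100,000 person-years in age-banded
step tables (a value applies from its age key up to the next key).  Incidence
tables may also be supplied as CSV side-files with columns
``cohort, age, rate_per_100000``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError

#: Upper age of the model grid; hazards are defined on integer ages 0..79.
AGE_MAX = 80

#: Major genotype labels, in canonical order.
GENOTYPES = ("noncarrier", "brca1", "brca2")
CARRIER_GENOTYPES = ("brca1", "brca2")

_RATE_SCALE = 1e-5  # configuration rates are per 100,000 person-years


@dataclass(frozen=True)
class Cohort:
    """A birth-cohort interval [start, end] in calendar years (inclusive)."""

    label: str
    start: int
    end: int

    def contains(self, year: int) -> bool:
        return self.start <= year <= self.end


def expand_age_bands(bands: Mapping[int, float], field_path: str = "") -> np.ndarray:
    """Expand an age-banded step table to the yearly 0..79 grid.

    Each value applies from its age key (inclusive) up to the next key; the
    last value extends to age 79.  The table must start at age 0.
    """
    if not bands:
        raise ConfigurationError("empty age table", field_path)
    try:
        items = sorted((int(a), float(v)) for a, v in bands.items())
    except (TypeError, ValueError) as exc:
        raise ConfigurationError(f"non-numeric age or value ({exc})", field_path)
    ages = [a for a, _ in items]
    if ages[0] != 0:
        raise ConfigurationError(
            f"age coverage gap: table starts at age {ages[0]}, must start at 0",
            field_path,
        )
    if ages[-1] >= AGE_MAX:
        raise ConfigurationError(
            f"age {ages[-1]} outside model grid 0..{AGE_MAX - 1}", field_path
        )
    out = np.empty(AGE_MAX, dtype=float)
    for (a, v), nxt in zip(items, ages[1:] + [AGE_MAX]):
        out[a:nxt] = v
    return out


def _check_rates(arr: np.ndarray, field_path: str) -> np.ndarray:
    if np.any(~np.isfinite(arr)):
        raise ConfigurationError("non-finite rate", field_path)
    bad = np.nonzero(arr < 0)[0]
    if bad.size:
        raise ConfigurationError(f"negative rate at age {bad[0]}", field_path)
    return arr


def _check_prob(x: float, field_path: str) -> float:
    x = float(x)
    if not (0.0 <= x <= 1.0):
        raise ConfigurationError(f"probability {x} outside [0, 1]", field_path)
    return x


@dataclass(eq=False)
class ModelConfiguration:
    """All numeric parameters for one model instance.

    ``carrier_frequency_*`` are population carrier probabilities, i.e. the
    probability that a woman drawn from the population carries at least one
    mutated allele of the gene.  Incidence arrays are per person-year on the
    yearly grid.
    """

    carrier_frequency_brca1: float
    carrier_frequency_brca2: float
    n_polygenic_loci: int
    polygenic_sd: np.ndarray  # sigma(t), shape (80,)
    test_sensitivity_brca1: float
    test_sensitivity_brca2: float
    cohorts: tuple[Cohort, ...]
    population_breast_incidence: dict[str, np.ndarray]  # cohort label -> (80,)
    population_ovarian_incidence: dict[str, np.ndarray]
    carrier_breast_incidence: dict[str, np.ndarray]  # genotype -> (80,)
    carrier_ovarian_incidence: dict[str, np.ndarray]
    population_er_negative_proportion: np.ndarray  # (80,)
    survivor_pool: str = "breast_ovarian"  # or "breast_only"
    use_brca2_er_table: bool = False

    def __post_init__(self) -> None:
        self.validate()

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        _check_prob(self.carrier_frequency_brca1, "mutation_frequencies.brca1")
        _check_prob(self.carrier_frequency_brca2, "mutation_frequencies.brca2")
        if self.carrier_frequency_brca1 + self.carrier_frequency_brca2 >= 1:
            raise ConfigurationError(
                "carrier frequencies must sum to less than 1", "mutation_frequencies"
            )
        if int(self.n_polygenic_loci) < 1:
            raise ConfigurationError("need at least 1 locus", "polygene.n_loci")
        _check_prob(self.test_sensitivity_brca1, "test_sensitivity.brca1")
        _check_prob(self.test_sensitivity_brca2, "test_sensitivity.brca2")
        if self.polygenic_sd.shape != (AGE_MAX,):
            raise ConfigurationError("sd schedule must cover ages 0..79",
                                     "polygene.sd_schedule")
        if np.any(self.polygenic_sd < 0):
            raise ConfigurationError("negative sigma", "polygene.sd_schedule")
        if not self.cohorts:
            raise ConfigurationError("at least one cohort required", "cohorts")
        for prev, nxt in zip(self.cohorts, self.cohorts[1:]):
            if nxt.start != prev.end + 1:
                raise ConfigurationError(
                    f"cohorts must partition the calendar range; gap between "
                    f"{prev.label} and {nxt.label}", "cohorts")
        labels = {c.label for c in self.cohorts}
        for name, table in (("population_incidence.breast",
                             self.population_breast_incidence),
                            ("population_incidence.ovarian",
                             self.population_ovarian_incidence)):
            missing = labels - set(table)
            if missing:
                raise ConfigurationError(f"missing cohort(s) {sorted(missing)}", name)
            for lab, arr in table.items():
                _check_rates(np.asarray(arr), f"{name}.{lab}")
        for name, table in (("carrier_incidence.breast", self.carrier_breast_incidence),
                            ("carrier_incidence.ovarian", self.carrier_ovarian_incidence)):
            for g in CARRIER_GENOTYPES:
                if g not in table:
                    raise ConfigurationError(f"missing genotype {g}", name)
                _check_rates(np.asarray(table[g]), f"{name}.{g}")
        curve = np.asarray(self.population_er_negative_proportion)
        if curve.shape != (AGE_MAX,):
            raise ConfigurationError("curve must cover ages 0..79",
                                     "population_er_negative_proportion")
        if np.any((curve < 0) | (curve > 1)):
            raise ConfigurationError("proportions must lie in [0, 1]",
                                     "population_er_negative_proportion")
        if self.survivor_pool not in ("breast_ovarian", "breast_only"):
            raise ConfigurationError("must be breast_ovarian or breast_only",
                                     "options.survivor_pool")

    # -- derived quantities -------------------------------------------------

    @property
    def allele_frequency_brca1(self) -> float:
        """Allele frequency implied by the carrier probability under
        Hardy-Weinberg: P(carrier) = 1 - (1 - f)^2."""
        return 1.0 - math.sqrt(1.0 - self.carrier_frequency_brca1)

    @property
    def allele_frequency_brca2(self) -> float:
        return 1.0 - math.sqrt(1.0 - self.carrier_frequency_brca2)

    def genotype_prior(self) -> np.ndarray:
        """Prior probabilities of the three collapsed major-genotype classes.

        Modelled as one three-allele locus (wild, b1, b2) in Hardy-Weinberg
        equilibrium; any genotype containing a b1 allele counts as a BRCA1
        carrier (b1 takes precedence in the rare double heterozygote).
        """
        f1, f2 = self.allele_frequency_brca1, self.allele_frequency_brca2
        p_non = (1.0 - f1 - f2) ** 2
        p_b1 = 1.0 - (1.0 - f1) ** 2
        p_b2 = 1.0 - p_non - p_b1
        return np.array([p_non, p_b1, p_b2])

    def cohort_for_birth_year(self, year: int | None) -> Cohort:
        """Map a birth year to its cohort; years outside the configured range
        take the nearest cohort with a warning, missing years the latest."""
        if year is None:
            return self.cohorts[-1]
        for c in self.cohorts:
            if c.contains(year):
                return c
        import warnings

        nearest = self.cohorts[0] if year < self.cohorts[0].start else self.cohorts[-1]
        warnings.warn(
            f"birth year {year} outside configured cohorts; using {nearest.label}",
            stacklevel=2,
        )
        return nearest

    # -- (de)serialization --------------------------------------------------

    def to_dict(self) -> dict:
        """Plain-python representation (rates back on the per-100,000 scale,
        fully expanded to yearly ages) suitable for YAML round-tripping."""
        def yearly(arr: np.ndarray, scale: float = 1.0 / _RATE_SCALE) -> dict[int, float]:
            return {int(a): float(v * scale) for a, v in enumerate(arr)}

        return {
            "mutation_frequencies": {
                "brca1": self.carrier_frequency_brca1,
                "brca2": self.carrier_frequency_brca2,
            },
            "test_sensitivity": {
                "brca1": self.test_sensitivity_brca1,
                "brca2": self.test_sensitivity_brca2,
            },
            "polygene": {
                "n_loci": int(self.n_polygenic_loci),
                "sd_schedule": yearly(self.polygenic_sd, scale=1.0),
            },
            "cohorts": [
                {"label": c.label, "start": c.start, "end": c.end} for c in self.cohorts
            ],
            "population_incidence": {
                "breast": {lab: yearly(arr)
                           for lab, arr in self.population_breast_incidence.items()},
                "ovarian": {lab: yearly(arr)
                            for lab, arr in self.population_ovarian_incidence.items()},
            },
            "carrier_incidence": {
                "breast": {g: yearly(arr)
                           for g, arr in self.carrier_breast_incidence.items()},
                "ovarian": {g: yearly(arr)
                            for g, arr in self.carrier_ovarian_incidence.items()},
            },
            "population_er_negative_proportion": yearly(
                self.population_er_negative_proportion, scale=1.0),
            "options": {
                "survivor_pool": self.survivor_pool,
                "use_brca2_er_table": bool(self.use_brca2_er_table),
            },
        }

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ModelConfiguration):
            return NotImplemented
        a, b = self.to_dict(), other.to_dict()
        return _dicts_close(a, b)

    def copy_with(self, **kwargs) -> "ModelConfiguration":
        return replace(self, **kwargs)


def _dicts_close(a, b, rtol: float = 0.0) -> bool:
    if isinstance(a, dict) and isinstance(b, dict):
        return a.keys() == b.keys() and all(_dicts_close(a[k], b[k], rtol) for k in a)
    if isinstance(a, list) and isinstance(b, list):
        return len(a) == len(b) and all(_dicts_close(x, y, rtol) for x, y in zip(a, b))
    if isinstance(a, float) or isinstance(b, float):
        return math.isclose(float(a), float(b), rel_tol=max(rtol, 1e-12), abs_tol=1e-12)
    return a == b


# ---------------------------------------------------------------------------
# loading


def _require(mapping: Mapping, key: str, path: str):
    if key not in mapping:
        raise ConfigurationError("missing field", f"{path}.{key}" if path else key)
    return mapping[key]


def _load_rate_table(spec, field_path: str, base_dir: Path,
                     keys: list[str]) -> dict[str, np.ndarray]:
    """Load a keyed rate table: either ``{key: {age: rate}}`` (with the special
    key ``all`` applying to every cohort), or ``{csv: side-file.csv}``."""
    if isinstance(spec, Mapping) and "csv" in spec:
        df = pd.read_csv(base_dir / spec["csv"])
        need = {"cohort", "age", "rate_per_100000"}
        if not need <= set(df.columns):
            raise ConfigurationError(
                f"CSV side-file must have columns {sorted(need)}", field_path)
        out = {}
        for lab, sub in df.groupby("cohort"):
            bands = dict(zip(sub["age"].astype(int), sub["rate_per_100000"]))
            out[str(lab)] = _check_rates(
                expand_age_bands(bands, f"{field_path}.{lab}") * _RATE_SCALE,
                f"{field_path}.{lab}")
        return out
    if not isinstance(spec, Mapping):
        raise ConfigurationError("expected a mapping", field_path)
    if "all" in spec:
        arr = _check_rates(
            expand_age_bands(spec["all"], f"{field_path}.all") * _RATE_SCALE,
            f"{field_path}.all")
        return {k: arr.copy() for k in keys}
    out = {}
    for lab, bands in spec.items():
        out[str(lab)] = _check_rates(
            expand_age_bands(bands, f"{field_path}.{lab}") * _RATE_SCALE,
            f"{field_path}.{lab}")
    return out


def load_model_config(path: str | Path) -> ModelConfiguration:
    """Load and validate a model-parameter file (YAML dialect, see README)."""
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, Mapping):
        raise ConfigurationError("configuration file is not a mapping", str(path))
    return model_config_from_dict(raw, base_dir=path.parent)


def model_config_from_dict(raw: Mapping, base_dir: str | Path = ".") -> ModelConfiguration:
    base_dir = Path(base_dir)
    freqs = _require(raw, "mutation_frequencies", "")
    sens = raw.get("test_sensitivity", {}) or {}
    poly = _require(raw, "polygene", "")
    cohorts = tuple(
        Cohort(str(c["label"]), int(c["start"]), int(c["end"]))
        for c in _require(raw, "cohorts", "")
    )
    labels = [c.label for c in cohorts]
    pop = _require(raw, "population_incidence", "")
    car = _require(raw, "carrier_incidence", "")
    opts = raw.get("options", {}) or {}

    def carrier_table(spec, field_path):
        out = {}
        for g in CARRIER_GENOTYPES:
            bands = _require(spec, g, field_path)
            out[g] = expand_age_bands(bands, f"{field_path}.{g}") * _RATE_SCALE
        return out

    return ModelConfiguration(
        carrier_frequency_brca1=float(_require(freqs, "brca1", "mutation_frequencies")),
        carrier_frequency_brca2=float(_require(freqs, "brca2", "mutation_frequencies")),
        n_polygenic_loci=int(_require(poly, "n_loci", "polygene")),
        polygenic_sd=expand_age_bands(
            _require(poly, "sd_schedule", "polygene"), "polygene.sd_schedule"),
        # default assay sensitivities: 70% for BRCA1, 80% for BRCA2
        test_sensitivity_brca1=float(sens.get("brca1", 0.70)),
        test_sensitivity_brca2=float(sens.get("brca2", 0.80)),
        cohorts=cohorts,
        population_breast_incidence=_load_rate_table(
            _require(pop, "breast", "population_incidence"),
            "population_incidence.breast", base_dir, labels),
        population_ovarian_incidence=_load_rate_table(
            _require(pop, "ovarian", "population_incidence"),
            "population_incidence.ovarian", base_dir, labels),
        carrier_breast_incidence=carrier_table(
            _require(car, "breast", "carrier_incidence"), "carrier_incidence.breast"),
        carrier_ovarian_incidence=carrier_table(
            _require(car, "ovarian", "carrier_incidence"), "carrier_incidence.ovarian"),
        population_er_negative_proportion=expand_age_bands(
            _require(raw, "population_er_negative_proportion", ""),
            "population_er_negative_proportion"),
        survivor_pool=str(opts.get("survivor_pool", "breast_ovarian")),
        use_brca2_er_table=bool(opts.get("use_brca2_er_table", False)),
    )


def save_model_config(config: ModelConfiguration, path: str | Path) -> None:
    """Serialize a configuration to YAML (yearly-expanded tables)."""
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)


def default_config() -> ModelConfiguration:
    """The bundled illustrative parameter set (see ``data/default_config.yaml``)."""
    from importlib import resources

    ref = resources.files("brcapath").joinpath("data/default_config.yaml")
    with resources.as_file(ref) as p:
        return load_model_config(p)
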