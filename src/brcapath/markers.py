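"""Tumour-marker proportion tables.

The model layers breast-cancer end points as

    case -> {ER+, ER-} -> within ER-: {TN, non-TN}
         -> within TN: cytokeratin classes, per assay scenario.

ER-negative proportions are age-banded (10-year bands); the TN and CK
proportions are age-constant.  For BRCA1 carriers the ER proportions come from
a consortium case series; for BRCA2 carriers and noncarriers the model uses
the general-population ER curve (the published BRCA2 series is too sparse,
and its ER distribution does not differ from population controls).  CK
proportions among TN tumours for BRCA2 carriers likewise use the control
values.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, field

import numpy as np

from .config import AGE_MAX, GENOTYPES
from .errors import ConfigurationError

#: Age-band lower edges for the ER tables: <30, 30-39, 40-49, 50-59, 60-69, >=70.
ER_BAND_EDGES = (0, 30, 40, 50, 60, 70)

#: Cytokeratin assay scenarios and the classes each partitions TN disease into.
CK_SCENARIOS = {
    "both_tested": ("both_pos", "one_pos", "neither_pos"),
    "ck56_only": ("pos", "neg"),
    "ck14_only": ("pos", "neg"),
}


def _band_index(age: int) -> int:
    if not (0 <= age < AGE_MAX):
        raise ValueError(f"age {age} outside model grid 0..{AGE_MAX - 1}")
    return bisect_right(ER_BAND_EDGES, age) - 1


@dataclass(frozen=True)
class MarkerProportionTable:
    """Genotype-specific marker proportions with their age-band semantics.

    ``er_neg_brca1`` maps band lower edge -> P(ER- | case) for BRCA1 carriers;
    BRCA2 and noncarrier ER proportions delegate to the population curve
    supplied at query time.  ``tn_given_er_neg`` and the CK tables are
    age-constant, keyed by genotype.
    """

    er_neg_brca1: dict[int, float]
    er_neg_brca2_raw: dict[int, float]  # printed series; unused unless enabled
    tn_given_er_neg: dict[str, float]
    ck_both_tested: dict[str, tuple[float, float, float]]  # (both, one, neither)
    ck56_only_pos: dict[str, float]
    ck14_only_pos: dict[str, float]
    raw_brca2_ck: dict[str, float] = field(default_factory=dict)
    extrapolated_bands: dict[str, tuple[int, ...]] = field(default_factory=dict)

    def __post_init__(self):
        for g, (a, b, c) in self.ck_both_tested.items():
            if abs(a + b + c - 1.0) > 1e-9:
                raise ConfigurationError(
                    f"CK classes for {g} do not sum to 1", "ck_both_tested")
        for table in (self.er_neg_brca1, self.er_neg_brca2_raw):
            for band, p in table.items():
                if not 0 <= p <= 1:
                    raise ConfigurationError(
                        f"band {band}: proportion {p} outside [0, 1]", "er_neg")

    # -- lookups ------------------------------------------------------------

    def er_negative_proportion(
        self,
        genotype: str,
        age: int,
        population_curve: np.ndarray | None = None,
        use_brca2_er_table: bool = False,
    ) -> float:
        """P(ER- | breast cancer at ``age``, genotype)."""
        if genotype == "brca1":
            return self.er_neg_brca1[ER_BAND_EDGES[_band_index(age)]]
        if genotype == "brca2" and use_brca2_er_table:
            return self.er_neg_brca2_raw[ER_BAND_EDGES[_band_index(age)]]
        if genotype not in GENOTYPES:
            raise KeyError(f"unknown genotype {genotype!r}")
        if population_curve is None:
            raise ValueError(
                f"ER proportions for {genotype} delegate to the population "
                "curve; pass population_curve")
        return float(population_curve[age])

    def ck_class_proportion(self, genotype: str, scenario: str, cls: str) -> float:
        """P(CK class | TN, genotype) under the given assay scenario."""
        if scenario not in CK_SCENARIOS:
            raise KeyError(f"unknown CK scenario {scenario!r}")
        if cls not in CK_SCENARIOS[scenario]:
            raise KeyError(f"unknown class {cls!r} for scenario {scenario!r}")
        if genotype not in GENOTYPES:
            raise KeyError(f"unknown genotype {genotype!r}")
        if scenario == "both_tested":
            both, one, neither = self.ck_both_tested[genotype]
            return {"both_pos": both, "one_pos": one, "neither_pos": neither}[cls]
        pos = (self.ck56_only_pos if scenario == "ck56_only"
               else self.ck14_only_pos)[genotype]
        return pos if cls == "pos" else 1.0 - pos


def builtin_marker_tables() -> MarkerProportionTable:
    """The embedded default marker-proportion tables.

    ER-negative proportions among BRCA1 tumours by age band; the >=70 band is
    extrapolated from 60-69 (sparse data).  TN and CK proportions are
    age-constant; BRCA2 CK classes use the control values (its published CK
    series is sparse and indistinguishable from controls), with the printed
    BRCA2 values retained in ``raw_brca2_ck``.
    """
    controls_ck_both = (0.14, 0.24, 1.0 - 0.14 - 0.24)
    return MarkerProportionTable(
        er_neg_brca1={0: 0.93, 30: 0.91, 40: 0.86, 50: 0.89, 60: 0.83, 70: 0.83},
        er_neg_brca2_raw={0: 0.44, 30: 0.26, 40: 0.47, 50: 0.14, 60: 0.20, 70: 0.15},
        tn_given_er_neg={"noncarrier": 0.53, "brca1": 0.90, "brca2": 0.86},
        ck_both_tested={
            "noncarrier": controls_ck_both,
            "brca1": (0.49, 0.30, 1.0 - 0.49 - 0.30),
            "brca2": controls_ck_both,
        },
        ck56_only_pos={"noncarrier": 0.26, "brca1": 0.64, "brca2": 0.26},
        ck14_only_pos={"noncarrier": 0.27, "brca1": 0.63, "brca2": 0.27},
        raw_brca2_ck={"ck_both_pos": 0.38, "ck_either_pos": 0.13,
                      "ck56_only_pos": 0.38, "ck14_only_pos": 0.50},
        extrapolated_bands={"brca1": (70,)},
    )


def marker_proportion(
    tables: MarkerProportionTable,
    genotype: str,
    age: int,
    query: str,
    population_curve: np.ndarray | None = None,
    use_brca2_er_table: bool = False,
) -> float:
    """Evaluate one marker-level proportion.

    ``query`` is one of ``er_neg``, ``er_pos`` (proportion of cases),
    ``tn``, ``non_tn`` (proportion of ER-negative cases), or
    ``ck:<scenario>:<class>`` (proportion of TN cases), e.g.
    ``ck:ck56_only:pos``.
    """
    if genotype not in GENOTYPES:
        raise KeyError(f"unknown genotype {genotype!r}")
    if query in ("er_neg", "er_pos"):
        p = tables.er_negative_proportion(
            genotype, age, population_curve, use_brca2_er_table)
        return p if query == "er_neg" else 1.0 - p
    if query in ("tn", "non_tn"):
        p = tables.tn_given_er_neg[genotype]
        return p if query == "tn" else 1.0 - p
    if query.startswith("ck:"):
        _, scenario, cls = query.split(":")
        return tables.ck_class_proportion(genotype, scenario, cls)
    raise KeyError(f"unknown marker query {query!r}")
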