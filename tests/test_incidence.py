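import numpy as np
import pytest

from brcapath.config import AGE_MAX, GENOTYPES
from brcapath.errors import ConfigurationError
from brcapath.incidence import (constrain_total_hazards, cumulative_risk,
                                endpoint_hazard_for_panel,
                                genotype_distribution_among_unaffected,
                                split_endpoints)
from brcapath.markers import MarkerProportionTable, builtin_marker_tables
from brcapath.pedigree import MarkerPanel

from .conftest import make_config, make_endpoints

LEAF_ENDPOINTS = ("er_positive", "er_negative_non_tn")
CK_LEAVES = {
    "both_tested": ("tn_both_ck_positive", "tn_one_ck_positive",
                    "tn_no_ck_positive"),
    "ck56_only": ("tn_ck56_positive", "tn_ck56_negative"),
    "ck14_only": ("tn_ck14_positive", "tn_ck14_negative"),
}


class TestConstraints:
    def test_degenerate_mixture_reduces_to_population(self):
        """No carriers and no polygenic variance: the noncarrier hazard is
        the population incidence itself."""
        cfg = make_config(freq1=0.0, freq2=0.0, sigma=0.0)
        h = constrain_total_hazards(cfg, "all")
        for level in range(h.n_levels):
            np.testing.assert_allclose(
                h.breast[0, level], cfg.population_breast_incidence["all"],
                rtol=1e-12)

    @pytest.mark.parametrize("kwargs", [
        {}, {"n_loci": 3, "sigma": 1.2}, {"freq1": 0.01, "freq2": 0.02},
    ])
    def test_mixture_reproduces_population_incidence(self, kwargs):
        cfg = make_config(**kwargs)
        h = constrain_total_hazards(cfg, "all")
        mix = np.einsum("tgl,glt->t", h.survivor_joint, h.breast)
        pop = cfg.population_breast_incidence["all"]
        mask = pop > 0
        np.testing.assert_allclose(mix[mask], pop[mask], rtol=1e-8)

    def test_carrier_averages_match_configured_curves(self):
        cfg = make_config(n_loci=2, sigma=1.0)
        h = constrain_total_hazards(cfg, "all")
        for gi, g in ((1, "brca1"), (2, "brca2")):
            cond = h.survivor_joint[:, gi, :]
            cond = cond / cond.sum(axis=1, keepdims=True)
            avg = np.einsum("tl,lt->t", cond, h.breast[gi])
            np.testing.assert_allclose(
                avg, cfg.carrier_breast_incidence[g], rtol=1e-8)

    def test_excess_carrier_burden_rejected(self):
        cfg = make_config(freq1=0.5, carrier_scale=10.0)
        with pytest.raises(ConfigurationError, match="exceeds the population"):
            constrain_total_hazards(cfg, "all")


class TestSurvivorDistribution:
    def test_age_zero_is_founder_prior(self, toy_config, toy_endpoints):
        dist = genotype_distribution_among_unaffected(
            toy_config, toy_endpoints.base)
        np.testing.assert_allclose(dist[0], toy_endpoints.base.founder_joint,
                                   rtol=1e-12)

    def test_zero_hazards_leave_distribution_constant(self):
        cfg = make_config(pop_scale=0.0, carrier_scale=0.0, ovarian=False)
        h = constrain_total_hazards(cfg, "all")
        dist = genotype_distribution_among_unaffected(cfg, h)
        for t in range(AGE_MAX):
            np.testing.assert_allclose(dist[t], dist[0], rtol=1e-12)

    def test_carrier_mass_decreases_under_excess_hazard(self, toy_config,
                                                        toy_endpoints):
        """Carriers face strictly higher hazards from age 20, so their share
        of the unaffected pool declines monotonically thereafter."""
        pi = toy_endpoints.base.survivor_joint.sum(axis=2)
        carrier_share = pi[:, 1] + pi[:, 2]
        diffs = np.diff(carrier_share[20:])
        assert np.all(diffs < 0)


class TestEndpointSplit:
    def test_er_layers_sum_to_total_at_machine_precision(self, toy_endpoints):
        ep = toy_endpoints
        for g in GENOTYPES:
            for level in range(ep.n_levels):
                total = ep.base.breast[GENOTYPES.index(g), level]
                er = (ep.hazard_curve(g, level, "er_negative")
                      + ep.hazard_curve(g, level, "er_positive"))
                np.testing.assert_allclose(er, total, rtol=1e-14, atol=1e-300)
                tn = (ep.hazard_curve(g, level, "tn")
                      + ep.hazard_curve(g, level, "er_negative_non_tn"))
                np.testing.assert_allclose(
                    tn, ep.hazard_curve(g, level, "er_negative"),
                    rtol=1e-14, atol=1e-300)
                for scenario, leaves in CK_LEAVES.items():
                    ck = sum(ep.hazard_curve(g, level, e) for e in leaves)
                    np.testing.assert_allclose(
                        ck, ep.hazard_curve(g, level, "tn"),
                        rtol=1e-12, atol=1e-300)

    def test_population_er_negative_incidence_reproduced(self, toy_config,
                                                         toy_endpoints):
        ep = toy_endpoints
        pi = ep.base.survivor_joint.sum(axis=2)
        mix = np.einsum("tg,gt->t", pi, ep.er_neg_frac * ep.base.breast_average)
        pop = toy_config.population_breast_incidence["all"]
        target = toy_config.population_er_negative_proportion * pop
        mask = pop > 0
        np.testing.assert_allclose(mix[mask], target[mask], rtol=1e-8)

    def test_brca1_subtype_shares_match_tables(self, toy_endpoints):
        gi = GENOTYPES.index("brca1")
        assert toy_endpoints.er_neg_frac[gi, 45] == pytest.approx(0.86)
        assert toy_endpoints.tn_frac[gi, 45] == pytest.approx(0.90)

    def test_zero_er_proportion_gives_zero_er_negative_hazard(self):
        cfg = make_config()
        cfg = cfg.copy_with(population_er_negative_proportion=np.zeros(AGE_MAX))
        tables = builtin_marker_tables()
        tables = MarkerProportionTable(
            er_neg_brca1={b: 0.0 for b in (0, 30, 40, 50, 60, 70)},
            er_neg_brca2_raw=tables.er_neg_brca2_raw,
            tn_given_er_neg=tables.tn_given_er_neg,
            ck_both_tested=tables.ck_both_tested,
            ck56_only_pos=tables.ck56_only_pos,
            ck14_only_pos=tables.ck14_only_pos)
        h = constrain_total_hazards(cfg, "all")
        ep = split_endpoints(h, tables, cfg)
        for g in GENOTYPES:
            assert np.all(ep.hazard_curve(g, 0, "er_negative") == 0.0)

    def test_unknown_endpoint_rejected(self, toy_endpoints):
        with pytest.raises(KeyError):
            toy_endpoints.endpoint_fraction("brca1", "her2_positive")


class TestPanelHazards:
    def test_untested_panel_gives_total_hazard(self, toy_endpoints):
        ep = toy_endpoints
        for g in GENOTYPES:
            h = endpoint_hazard_for_panel(ep, g, 1, 45, MarkerPanel())
            assert h == ep.hazard(g, 1, 45, "total")

    def test_er_negative_panel_marginalizes_deeper_layers(self, toy_endpoints):
        ep = toy_endpoints
        panel = MarkerPanel(er="negative")
        got = endpoint_hazard_for_panel(ep, "brca1", 0, 45, panel)
        leaves = (["er_negative_non_tn"] + list(CK_LEAVES["both_tested"]))
        total = sum(ep.hazard("brca1", 0, 45, e) for e in leaves)
        assert got == pytest.approx(total, rel=1e-12)

    def test_tn_ck56_positive_layer_product(self, toy_endpoints):
        ep = toy_endpoints
        panel = MarkerPanel(er="negative", pr="negative", her2="negative",
                            ck5_6="positive")
        got = endpoint_hazard_for_panel(ep, "brca1", 2, 45, panel)
        gi = GENOTYPES.index("brca1")
        lam = ep.base.breast[gi, 2, 45]
        expected = lam * 0.86 * 0.90 * 0.64
        assert got == pytest.approx(expected, rel=1e-12)


class TestCumulativeRisk:
    def test_zero_horizon_is_zero(self, toy_endpoints):
        assert cumulative_risk(toy_endpoints, "brca1", "total", 0) == 0.0

    def test_subtype_risks_partition_total(self, toy_endpoints):
        for g in GENOTYPES:
            for to_age in (30, 50, 70, 79):
                total = cumulative_risk(toy_endpoints, g, "total", to_age)
                split = (cumulative_risk(toy_endpoints, g, "er_negative", to_age)
                         + cumulative_risk(toy_endpoints, g, "er_positive", to_age))
                assert split == pytest.approx(total, rel=1e-12)

    def test_curves_monotone_and_bounded(self, toy_endpoints):
        for g in GENOTYPES:
            risks = [cumulative_risk(toy_endpoints, g, "er_negative", t)
                     for t in range(0, AGE_MAX, 5)]
            assert all(b >= a for a, b in zip(risks, risks[1:]))
            assert 0.0 <= risks[-1] <= 1.0

    def test_unknown_endpoint_rejected(self, toy_endpoints):
        with pytest.raises(KeyError):
            cumulative_risk(toy_endpoints, "brca1", "lobular", 70)
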