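import math

import numpy as np
import pytest

from brcapath.config import AGE_MAX, GENOTYPES
from brcapath.incidence import constrain_total_hazards, split_endpoints
from brcapath.likelihood import (carrier_probabilities, individual_penetrance,
                                 pedigree_loglikelihood, penetrance_table)
from brcapath.markers import MarkerProportionTable, builtin_marker_tables
from brcapath.pedigree import (Individual, MarkerPanel, Pedigree,
                               mother_daughter, single_case)

from ._oracles import enumerate_loglikelihood, random_pedigree
from .conftest import make_config, make_endpoints


class TestPenetranceFactors:
    def test_newborn_contributes_unit_factor(self, toy_endpoints, toy_config):
        baby = Individual(id="b", sex="F", observation_age=0)
        table = penetrance_table(baby, toy_endpoints, toy_config)
        np.testing.assert_array_equal(table, np.ones_like(table))

    def test_unknown_observation_age_contributes_nothing(self, toy_endpoints,
                                                         toy_config):
        woman = Individual(id="w", sex="F")
        table = penetrance_table(woman, toy_endpoints, toy_config)
        np.testing.assert_array_equal(table, np.ones_like(table))

    def test_negative_mutation_test_leaves_residual_sensitivity(
            self, toy_endpoints, toy_config):
        """A negative assay multiplies the carrier states by 1 - sensitivity:
        0.30 for BRCA1 and 0.20 for BRCA2."""
        ind = Individual(id="t", sex="F", observation_age=0,
                         genetic_test="negative")
        assert individual_penetrance(
            ind, "brca1", 0, toy_endpoints, toy_config) == pytest.approx(0.30)
        assert individual_penetrance(
            ind, "brca2", 0, toy_endpoints, toy_config) == pytest.approx(0.20)
        assert individual_penetrance(
            ind, "noncarrier", 0, toy_endpoints, toy_config) == 1.0

    def test_affected_er_negative_closed_form(self, toy_endpoints, toy_config):
        """Survival to diagnosis under the total breast + ovarian hazards,
        times the ER-negative hazard at diagnosis."""
        age = 45
        ind = Individual(id="a", sex="F", observation_age=age,
                         breast_cancer_age=age, panel=MarkerPanel(er="negative"))
        for g in GENOTYPES:
            gi = GENOTYPES.index(g)
            for level in (0, toy_endpoints.n_levels - 1):
                cum = sum(toy_endpoints.base.breast[gi, level, t]
                          + toy_endpoints.base.ovarian[gi, t]
                          for t in range(age))
                nu = (toy_endpoints.base.breast[gi, level, age]
                      * toy_endpoints.er_neg_frac[gi, age])
                expected = math.exp(-cum) * nu
                got = individual_penetrance(ind, g, level, toy_endpoints,
                                            toy_config)
                assert got == pytest.approx(expected, rel=1e-12)

    def test_male_contributes_only_test_factor(self, toy_endpoints, toy_config):
        man = Individual(id="m", sex="M", observation_age=70,
                         genetic_test="negative")
        table = penetrance_table(man, toy_endpoints, toy_config)
        np.testing.assert_allclose(table[0], 1.0)
        np.testing.assert_allclose(table[1], 0.30)


class TestPeeling:
    def test_single_unobserved_founder_has_unit_likelihood(
            self, toy_endpoints, toy_config):
        ped = Pedigree([Individual(id="f", sex="F", observation_age=0)])
        ll = pedigree_loglikelihood(ped, toy_endpoints, toy_config)
        assert ll == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("n_members,n_loci,seed", [
        (2, 1, 1), (3, 1, 2), (4, 1, 3), (5, 1, 4),
        (2, 2, 5), (3, 2, 6), (4, 2, 7),
    ])
    def test_peeling_matches_exhaustive_enumeration(self, n_members, n_loci,
                                                    seed):
        ep, cfg = make_endpoints(n_loci=n_loci, sigma=0.8)
        rng = np.random.default_rng(seed)
        for _ in range(3):
            ped = random_pedigree(rng, n_members)
            got = pedigree_loglikelihood(ped, ep, cfg)
            want = enumerate_loglikelihood(ped, ep, cfg)
            assert got == pytest.approx(want, abs=1e-10)

    def test_likelihood_invariant_under_member_reordering(self, toy_endpoints,
                                                          toy_config):
        rng = np.random.default_rng(11)
        ped = random_pedigree(rng, 5)
        reordered = Pedigree(list(ped)[::-1], auto_complete=False)
        a = pedigree_loglikelihood(ped, toy_endpoints, toy_config)
        b = pedigree_loglikelihood(reordered, toy_endpoints, toy_config)
        assert a == pytest.approx(b, abs=1e-10)


class TestCarrierPosteriors:
    def test_posterior_normalizes(self, toy_endpoints, toy_config):
        post = carrier_probabilities(single_case(40), "proband",
                                     toy_endpoints, toy_config)
        total = post.p_noncarrier + post.p_brca1 + post.p_brca2
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_concordant_positive_test_is_certain(self, toy_endpoints,
                                                 toy_config):
        ped = single_case(40, genetic_test="brca1_positive")
        post = carrier_probabilities(ped, "proband", toy_endpoints, toy_config)
        assert post.p_brca1 == pytest.approx(1.0, abs=1e-12)

    def test_unknown_target_rejected(self, toy_endpoints, toy_config):
        with pytest.raises(KeyError):
            carrier_probabilities(single_case(40), "nobody", toy_endpoints,
                                  toy_config)

    @pytest.mark.parametrize("age", [30, 50, 70])
    def test_er_status_moves_brca1_posterior(self, age, toy_endpoints,
                                             toy_config):
        """ER-negative tumours are enriched in BRCA1 carriers, so observing
        ER- raises the BRCA1 posterior and ER+ lowers it."""
        def post(panel):
            return carrier_probabilities(single_case(age, panel), "proband",
                                         toy_endpoints, toy_config).p_brca1

        untested = post(MarkerPanel())
        assert post(MarkerPanel(er="negative")) > untested
        assert post(MarkerPanel(er="positive")) < untested

    def test_untested_panel_equals_base_model_posterior(self, toy_endpoints,
                                                        toy_config):
        ped = mother_daughter(40, 50)
        with_path = carrier_probabilities(ped, "proband", toy_endpoints,
                                          toy_config, use_pathology=True)
        base = carrier_probabilities(ped, "proband", toy_endpoints,
                                     toy_config, use_pathology=False)
        assert with_path.as_dict() == base.as_dict()

    def test_er_marginalization_recovers_untested_posterior(self, toy_endpoints,
                                                            toy_config):
        """Averaging the ER-observed posteriors over the model-implied ER
        distribution for the family reproduces the untested posterior."""
        def fam(er):
            panel = MarkerPanel(er=er) if er else MarkerPanel()
            return mother_daughter(40, 50, proband_panel=panel)

        ll = {er: pedigree_loglikelihood(fam(er), toy_endpoints, toy_config)
              for er in (None, "negative", "positive")}
        w_neg, w_pos = math.exp(ll["negative"]), math.exp(ll["positive"])
        assert w_neg + w_pos == pytest.approx(math.exp(ll[None]), rel=1e-10)
        p = {er: carrier_probabilities(fam(er), "proband", toy_endpoints,
                                       toy_config) for er in
             (None, "negative", "positive")}
        for attr in ("p_noncarrier", "p_brca1", "p_brca2"):
            mixed = (w_neg * getattr(p["negative"], attr)
                     + w_pos * getattr(p["positive"], attr)) / (w_neg + w_pos)
            assert mixed == pytest.approx(getattr(p[None], attr), abs=1e-10)

    def test_uninformative_markers_leave_posterior_unchanged(self):
        """When carrier marker proportions equal the population proportions,
        marker observations carry no carrier information."""
        cfg = make_config().copy_with(
            population_er_negative_proportion=np.full(AGE_MAX, 0.5))
        flat = MarkerProportionTable(
            er_neg_brca1={b: 0.5 for b in (0, 30, 40, 50, 60, 70)},
            er_neg_brca2_raw={b: 0.5 for b in (0, 30, 40, 50, 60, 70)},
            tn_given_er_neg={g: 0.6 for g in GENOTYPES},
            ck_both_tested={g: (0.2, 0.3, 0.5) for g in GENOTYPES},
            ck56_only_pos={g: 0.4 for g in GENOTYPES},
            ck14_only_pos={g: 0.45 for g in GENOTYPES})
        ep = split_endpoints(constrain_total_hazards(cfg, "all"), flat, cfg)
        panels = [MarkerPanel(), MarkerPanel(er="negative"),
                  MarkerPanel(er="negative", pr="negative", her2="negative",
                              ck5_6="positive", ck14="positive")]
        posts = [carrier_probabilities(single_case(45, p), "proband", ep, cfg)
                 for p in panels]
        for post in posts[1:]:
            for attr in ("p_noncarrier", "p_brca1", "p_brca2"):
                assert getattr(post, attr) == pytest.approx(
                    getattr(posts[0], attr), abs=1e-12)
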