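"""Generator correctness: planted effects, batch shifts, reproducibility."""

import dataclasses

import numpy as np
import pytest
from scipy import stats

import ibcsig as ib
from ibcsig.io_core import CohortError


def planted_effect(cohort, truth, signed=True):
    """Per-gene IBC-minus-nonIBC mean difference over the planted genes,
    re-signed by the true effect direction."""
    idx = cohort.gene_indices(truth.planted_genes)
    pos = [j for j, s in enumerate(cohort.sample_ids) if cohort.class_of(s) == "IBC"]
    neg = [j for j, s in enumerate(cohort.sample_ids) if cohort.class_of(s) == "nonIBC"]
    diff = cohort.values[np.ix_(idx, pos)].mean(1) - cohort.values[np.ix_(idx, neg)].mean(1)
    if signed:
        diff = diff * np.array([truth.effect_signs[g] for g in truth.planted_genes])
    return diff


def gene_tstats(cohort):
    pos = [j for j, s in enumerate(cohort.sample_ids) if cohort.class_of(s) == "IBC"]
    neg = [j for j, s in enumerate(cohort.sample_ids) if cohort.class_of(s) == "nonIBC"]
    return stats.ttest_ind(
        cohort.values[:, pos], cohort.values[:, neg], axis=1
    ).statistic


class TestDiscoveryCohort:
    def test_default_structure(self, default_cohort):
        _, cohort, truth = default_cohort
        assert cohort.n_samples == 45
        assert cohort.class_counts() == {"IBC": 20, "nonIBC": 20, "normal": 5}
        assert len(truth.planted_genes) == 59
        assert set(truth.planted_genes) <= set(cohort.gene_ids)

    def test_planted_effect_magnitude(self, default_cohort):
        # sample-mean oracle: planted shift is 1.5 noise-SD units
        _, cohort, truth = default_cohort
        assert np.mean(planted_effect(cohort, truth)) == pytest.approx(1.5, abs=0.15)

    def test_normals_carry_no_shift(self, default_cohort):
        _, cohort, truth = default_cohort
        idx = cohort.gene_indices(truth.planted_genes)
        nrm = [j for j, s in enumerate(cohort.sample_ids)
               if cohort.class_of(s) == "normal"]
        neg = [j for j, s in enumerate(cohort.sample_ids)
               if cohort.class_of(s) == "nonIBC"]
        diff = (cohort.values[np.ix_(idx, nrm)].mean(1)
                - cohort.values[np.ix_(idx, neg)].mean(1))
        assert abs(diff.mean()) < 0.3

    def test_zero_effect_exchangeability(self):
        # with effect_size=0 planted-gene t statistics are distributed as
        # background t statistics
        cfg = ib.SimulationConfig(seed=11, effect_size=0.0)
        cohort, truth = ib.simulate_cohort(cfg)
        t = gene_tstats(cohort)
        planted = set(cohort.gene_indices(truth.planted_genes))
        mask = np.array([i in planted for i in range(cohort.n_genes)])
        ks = stats.ks_2samp(t[mask], t[~mask])
        assert ks.pvalue > 0.01

    def test_effect_size_linearity(self):
        effs = {}
        for e in (0.75, 1.5):
            cfg = ib.SimulationConfig(seed=5, effect_size=e)
            cohort, truth = ib.simulate_cohort(cfg)
            effs[e] = np.mean(planted_effect(cohort, truth))
        assert effs[1.5] / effs[0.75] == pytest.approx(2.0, abs=0.2)

    def test_seed_reproducibility(self):
        cfg = ib.SimulationConfig(seed=3)
        a, ta = ib.simulate_cohort(cfg)
        b, tb = ib.simulate_cohort(ib.SimulationConfig(seed=3))
        assert np.array_equal(a.values, b.values)
        assert ta.planted_genes == tb.planted_genes
        assert [a.annotation(s).er_score for s in a.sample_ids] == \
               [b.annotation(s).er_score for s in b.sample_ids]

    def test_receptor_matchability_level(self, default_cohort):
        # ~90% of the smaller class should find an exact partner
        _, cohort, _ = default_cohort
        design = ib.match_training_set(cohort)
        assert len(design.training_pairs) >= 15

    def test_invalid_configs_rejected(self):
        with pytest.raises(CohortError):
            ib.SimulationConfig(n_signal=10, n_genes=5).validate()
        with pytest.raises(CohortError):
            ib.SimulationConfig(attenuation=1.5).validate()
        with pytest.raises(CohortError):
            ib.SimulationConfig(n_per_class={"IBC": 0, "nonIBC": 5}).validate()


class TestValidationCohort:
    def test_pre_mode_preserves_effect_despite_batch(self, default_cohort):
        cfg, _, truth = default_cohort
        v = ib.simulate_validation_cohort(cfg, truth, "pre")
        assert v.class_counts() == {"IBC": 33, "nonIBC": 28}
        eff = np.mean(planted_effect(v, truth))
        assert eff == pytest.approx(1.5, rel=0.10)

    def test_no_batch_mirrors_discovery(self, default_cohort):
        cfg, cohort, truth = default_cohort
        cfg0 = dataclasses.replace(cfg, batch_shift=0.0, batch_jitter_sd=0.0)
        v = ib.simulate_validation_cohort(
            cfg0, truth, "pre", n_per_class={"IBC": 20, "nonIBC": 20, "normal": 5}
        )
        # same generative law as a fresh discovery cohort: global mean and
        # per-gene means agree within sampling error
        assert v.values.mean() == pytest.approx(cohort.values.mean(), abs=0.05)
        gene_mean_delta = v.values.mean(1) - cohort.values.mean(1)
        assert np.abs(gene_mean_delta).mean() < 0.5

    def test_post_mode_attenuates(self, default_cohort):
        cfg, _, truth = default_cohort
        v = ib.simulate_validation_cohort(cfg, truth, "post")
        eff = np.mean(planted_effect(v, truth))
        assert eff == pytest.approx(0.2 * 1.5, abs=0.12)

    def test_zero_attenuation_removes_effect(self, default_cohort):
        cfg, _, truth = default_cohort
        cfg0 = dataclasses.replace(cfg, attenuation=0.0)
        v = ib.simulate_validation_cohort(cfg0, truth, "post")
        eff = np.mean(planted_effect(v, truth))
        # mean of 59 per-gene differences has SE ~0.034; 3.5 SE bound
        assert abs(eff) < 0.12

    def test_bad_mode_rejected(self, default_cohort):
        cfg, _, truth = default_cohort
        with pytest.raises(CohortError, match="mode"):
            ib.simulate_validation_cohort(cfg, truth, "mid")


class TestSurvivalSimulation:
    def test_reproducible(self):
        cfg = ib.SimulationConfig(seed=2)
        labels = {f"s{i}": i < 10 for i in range(30)}
        a = ib.simulate_survival(labels, cfg)
        b = ib.simulate_survival(labels, cfg)
        assert a.time == b.time and a.event == b.event

    def test_full_censoring_breaks_logrank(self):
        cfg = ib.SimulationConfig(
            seed=2, survival=ib.SurvivalConfig(censoring_rate=1.0)
        )
        labels = {f"s{i}": i < 10 for i in range(30)}
        table = ib.simulate_survival(labels, cfg)
        assert sum(table.event) == 0
        with pytest.raises(CohortError, match="no events"):
            ib.logrank_hr(table)

    def test_invalid_hazard_ratio(self):
        with pytest.raises(CohortError, match="hazard_ratio"):
            ib.SimulationConfig(
                survival=ib.SurvivalConfig(hazard_ratio=-1.0)
            ).validate()

    def test_censoring_rate_respected(self):
        cfg = ib.SimulationConfig(
            seed=4, survival=ib.SurvivalConfig(censoring_rate=0.3)
        )
        labels = {f"s{i}": i < 500 for i in range(1000)}
        table = ib.simulate_survival(labels, cfg)
        frac_censored = 1 - np.mean(table.event)
        assert frac_censored == pytest.approx(0.3, abs=0.05)
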