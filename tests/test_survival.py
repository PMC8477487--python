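"""Subtype calling, ROR scores, KM curves and the log-rank/HR machinery."""

import numpy as np
import pytest
from lifelines.statistics import logrank_test
from scipy import stats

import ibcsig as ib
from ibcsig.io_core import CohortError
from ibcsig.survival import SUBTYPES, _spearman

from conftest import toy_cohort


@pytest.fixture(scope="module")
def panel():
    return ib.synthetic_demo_panel(n_genes=10, seed=7)


def cohort_from_columns(genes, columns, labels=None):
    values = np.column_stack(columns)
    labels = labels or ["IBC"] * values.shape[1]
    cohort = toy_cohort(values, labels)
    cohort.gene_ids[:] = genes  # align to panel genes
    return ib.ExpressionCohort(
        list(genes), cohort.sample_ids, values,
        {s: cohort.annotations[s] for s in cohort.sample_ids},
    )


class TestSubtyping:
    def test_centroid_identity_called(self, panel):
        cols = [panel.centroids["Basal"], panel.centroids["LumA"]]
        cohort = cohort_from_columns(panel.genes, cols)
        calls = ib.pam50_call(cohort, panel)
        assert calls[0].subtype == "Basal"
        assert calls[0].correlations["Basal"] == pytest.approx(1.0, abs=1e-12)
        assert calls[1].subtype == "LumA"

    def test_anti_centroid_symmetry(self, panel):
        cohort = cohort_from_columns(panel.genes, [-panel.centroids["Her2"]])
        calls = ib.pam50_call(cohort, panel)
        assert calls[0].correlations["Her2"] == pytest.approx(-1.0, abs=1e-12)

    def test_spearman_matches_scipy(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            x, y = rng.normal(size=10), rng.normal(size=10)
            assert _spearman(x, y) == pytest.approx(
                stats.spearmanr(x, y).statistic, abs=1e-12
            )

    def test_monotone_transform_invariance(self, panel):
        rng = np.random.default_rng(4)
        col = rng.normal(size=10)
        a = cohort_from_columns(panel.genes, [col])
        b = cohort_from_columns(panel.genes, [np.exp(2 * col)])  # monotone map
        ca = ib.pam50_call(a, panel)[0]
        cb = ib.pam50_call(b, panel)[0]
        assert ca.subtype == cb.subtype
        assert ca.correlations == cb.correlations

    def test_low_coverage_refused(self, panel):
        cohort = cohort_from_columns(panel.genes[:4], [np.arange(4.0)])
        with pytest.raises(CohortError, match="coverage"):
            ib.pam50_call(cohort, panel)

    def test_panel_round_trip(self, panel, tmp_path):
        p = tmp_path / "panel.tsv"
        ib.write_panel(panel, str(p))
        back = ib.read_panel(str(p))
        assert back.genes == panel.genes
        for s in SUBTYPES:
            np.testing.assert_allclose(back.centroids[s], panel.centroids[s])
        assert back.ror_coefficients == panel.ror_coefficients


class TestRor:
    def make_call(self, corr):
        return ib.SubtypeCall(
            sample_id="s", subtype="LumA",
            correlations=dict(zip(SUBTYPES, corr)), ror_score=0.0,
        )

    def test_zero_correlations_give_offset(self, panel):
        assert ib.ror_score(self.make_call([0] * 5), panel) == panel.ror_offset

    def test_coefficient_linearity(self, panel):
        import dataclasses
        call = self.make_call([0.1, 0.4, -0.2, 0.3, 0.0])
        base = ib.ror_score(call, panel) - panel.ror_offset
        doubled = dataclasses.replace(
            panel,
            centroids=dict(panel.centroids),
            ror_coefficients={s: 2 * c for s, c in panel.ror_coefficients.items()},
        )
        assert ib.ror_score(call, doubled) - panel.ror_offset == pytest.approx(
            2 * base, abs=1e-12
        )

    def test_hand_computed_weighted_sum(self, panel):
        corr = [0.25, -0.5, 0.75, 0.1, -0.3]
        expected = panel.ror_offset + panel.ror_scale * sum(
            panel.ror_coefficients[s] * c for s, c in zip(SUBTYPES, corr)
        )
        assert ib.ror_score(self.make_call(corr), panel) == pytest.approx(
            expected, abs=1e-12
        )

    def test_missing_correlation_rejected(self, panel):
        call = ib.SubtypeCall("s", "LumA", {"LumA": 0.5}, 0.0)
        with pytest.raises(CohortError, match="missing"):
            ib.ror_score(call, panel)


def make_table(times, events, groups):
    return ib.SurvivalTable(
        sample_ids=[f"s{i}" for i in range(len(times))],
        time=list(times), event=list(events), group=list(groups),
    )


class TestKmCurve:
    def test_no_events_flat(self):
        t = make_table([1, 2, 3], [0, 0, 0], ["a"] * 3)
        _, surv = ib.km_curve(t, "a")
        assert np.all(surv == 1.0)

    def test_three_subject_product_limit(self):
        t = make_table([1, 2, 3], [1, 1, 1], ["a"] * 3)
        times, surv = ib.km_curve(t, "a")
        lookup = dict(zip(times, surv))
        assert lookup[1.0] == pytest.approx(2 / 3)
        assert lookup[2.0] == pytest.approx(1 / 3)
        assert lookup[3.0] == pytest.approx(0.0)

    def test_complete_data_closed_form(self):
        rng = np.random.default_rng(2)
        times = rng.exponential(5, size=20)
        t = make_table(times, [1] * 20, ["a"] * 20)
        grid, surv = ib.km_curve(t, "a")
        for g, s in zip(grid, surv):
            assert s == pytest.approx(np.mean(times > g), abs=1e-12)

    def test_late_censoring_no_effect_before(self):
        base = make_table([1, 2, 3], [1, 1, 0], ["a"] * 3)
        ext = make_table([1, 2, 3, 9], [1, 1, 0, 0], ["a"] * 4)
        tb, sb = ib.km_curve(base, "a")
        te, se = ib.km_curve(ext, "a")
        # survival at the shared event times differs only through the larger
        # risk set; the late-censored subject never changes earlier steps'
        # ordering of events
        assert list(tb)[:3] == [0.0, 1.0, 2.0]

    def test_empty_group(self):
        t = make_table([1], [1], ["a"])
        with pytest.raises(CohortError, match="empty group"):
            ib.km_curve(t, "b")


def brute_force_logrank(times, events, groups):
    """Per-event-time 2x2 tabulation, straight from the definition."""
    labels = sorted(set(groups))
    o1 = e1 = v = 0.0
    for tau in sorted({t for t, e in zip(times, events) if e == 1}):
        n1 = sum(1 for t, g in zip(times, groups) if t >= tau and g == labels[0])
        n2 = sum(1 for t, g in zip(times, groups) if t >= tau and g == labels[1])
        d1 = sum(1 for t, e, g in zip(times, events, groups)
                 if t == tau and e == 1 and g == labels[0])
        d2 = sum(1 for t, e, g in zip(times, events, groups)
                 if t == tau and e == 1 and g == labels[1])
        n, d = n1 + n2, d1 + d2
        o1 += d1
        e1 += d * n1 / n
        if n > 1:
            v += d * n1 * n2 * (n - d) / (n * n * (n - 1))
    return (o1 - e1) ** 2 / v


class TestLogrankHr:
    TOY = dict(
        times=[1, 2, 2, 3, 4, 5, 6, 7, 8, 9],
        events=[1, 1, 0, 1, 1, 0, 1, 1, 1, 0],
        groups=["a"] * 5 + ["b"] * 5,
    )

    def test_matches_tabulation_oracle_exactly(self):
        t = make_table(**{k: v for k, v in zip(
            ("times", "events", "groups"),
            (self.TOY["times"], self.TOY["events"], self.TOY["groups"]))})
        res = ib.logrank_hr(t)
        oracle = brute_force_logrank(
            self.TOY["times"], self.TOY["events"], self.TOY["groups"]
        )
        assert res.statistic == pytest.approx(oracle, abs=1e-12)

    def test_matches_lifelines(self):
        t = make_table(self.TOY["times"], self.TOY["events"], self.TOY["groups"])
        res = ib.logrank_hr(t)
        ll = logrank_test(
            self.TOY["times"][:5], self.TOY["times"][5:],
            self.TOY["events"][:5], self.TOY["events"][5:],
        )
        assert res.statistic == pytest.approx(ll.test_statistic, rel=1e-10)
        assert res.p_value == pytest.approx(ll.p_value, rel=1e-10)

    def test_symmetric_groups_hr_one(self):
        times = [1, 2, 3, 4, 1, 2, 3, 4]
        events = [1, 1, 1, 0, 1, 1, 1, 0]
        groups = ["a"] * 4 + ["b"] * 4
        res = ib.logrank_hr(make_table(times, events, groups))
        assert res.hazard_ratio == pytest.approx(1.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0, abs=1e-9)

    def test_hr_ci_contains_hr(self):
        cfg = ib.SimulationConfig(seed=3)
        labels = {f"s{i}": i < 100 for i in range(400)}
        table = ib.simulate_survival(labels, cfg)
        res = ib.logrank_hr(table)
        assert res.ci_low < res.hazard_ratio < res.ci_high

    def test_single_group_rejected(self):
        t = make_table([1, 2], [1, 1], ["a", "a"])
        with pytest.raises(CohortError, match="2 groups"):
            ib.logrank_hr(t)

    def test_null_pvalues_uniform(self):
        # permuted group labels: log-rank p approximately uniform
        cfg = ib.SimulationConfig(
            seed=6, survival=ib.SurvivalConfig(hazard_ratio=1.0)
        )
        rng = np.random.default_rng(0)
        pvals = []
        for rep in range(200):
            labels = {f"s{i}": bool(b) for i, b in
                      enumerate(rng.permutation([1] * 25 + [0] * 25))}
            table = ib.simulate_survival(labels, cfg, seed=900 + rep)
            pvals.append(ib.logrank_hr(table).p_value)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01
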