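"""Lifetime validation harness and the statistical comparison pipeline."""

import math

import numpy as np
import pytest

from bnct_fluence import (
    METHOD_COMPENSATED,
    METHOD_CONSTANT_FLUX,
    FluxModel,
    compare_methods,
    default_fixture,
    fit_flux_model,
    prescribe_fluence,
    run_full_validation,
    run_lifetime_validation,
    summarize,
)
from bnct_fluence.validation import _shapiro_p

from conftest import make_series


def split_by_method(records):
    comp = [r.discrepancy_percent for r in records if r.method == METHOD_COMPENSATED]
    const = [
        r.discrepancy_percent for r in records if r.method == METHOD_CONSTANT_FLUX
    ]
    return np.array(comp), np.array(const)


class TestHarness:
    def test_noise_free_compensation_is_exact(self, clinical_plan):
        """With exact measurements the tentative fit equals the reference,
        so compensated deliveries land on NF at every treatment point."""
        truth = FluxModel(a=3e-16, b=4e-7, c=1.05e-15)
        charges = np.linspace(4e4, 2.4e6, 60)
        series = make_series(truth, charges)
        reference = fit_flux_model(series)
        records, skipped = run_lifetime_validation(
            series, reference, clinical_plan
        )
        comp, const = split_by_method(records)
        assert len(skipped) == 4  # first n_min-1 points lack history
        assert len(comp) == len(const) == 56
        assert np.max(np.abs(comp)) < 1e-6
        # the naive method still under-delivers from intra-treatment decay
        assert np.all(const < 0)

    def test_constant_target_no_decay_no_noise(self, clinical_plan):
        """A non-degrading target makes both methods exact."""
        truth = FluxModel(a=0.0, b=0.0, c=1.2e-15)
        series = make_series(truth, np.linspace(4e4, 2.4e6, 60))
        reference = fit_flux_model(series)
        records, _ = run_lifetime_validation(series, reference, clinical_plan)
        comp, const = split_by_method(records)
        assert np.max(np.abs(comp)) < 1e-6
        assert np.max(np.abs(const)) < 1e-6

    def test_default_fixture_compensation_beats_naive(self, clinical_plan):
        """On the 5-lot fixture the compensated method has the smaller
        worst-case |discrepancy| in at least 4 of 5 targets."""
        wins = 0
        for series, _ in default_fixture(seed=1):
            reference = fit_flux_model(series)
            records, _ = run_lifetime_validation(
                series, reference, clinical_plan
            )
            comp, const = split_by_method(records)
            wins += np.abs(comp).max() < np.abs(const).max()
        assert wins >= 4


class TestSummarize:
    def test_symmetric_triple(self):
        s = summarize([-1.0, 0.0, 1.0])
        assert s.median == 0.0
        assert (s.minimum, s.maximum) == (-1.0, 1.0)
        assert s.fraction_within == 1.0

    def test_single_value_sd_flagged(self):
        s = summarize([0.42])
        assert s.median == 0.42
        assert math.isnan(s.sd)  # sample convention: undefined for n=1

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize([])

    def test_matches_independent_recomputation(self, clinical_plan):
        """Summary statistics agree with direct numpy recomputation."""
        series, _ = default_fixture(seed=2)[0]
        reference = fit_flux_model(series)
        records, _ = run_lifetime_validation(series, reference, clinical_plan)
        comp, _ = split_by_method(records)
        s = summarize(comp)
        assert s.median == pytest.approx(float(np.median(comp)))
        assert s.sd == pytest.approx(float(np.std(comp, ddof=1)))
        assert s.fraction_within == pytest.approx(
            float(np.mean(np.abs(comp) <= 1.0))
        )


class TestCompareMethods:
    def test_identical_lists_degenerate(self):
        vals = [0.1, -0.2, 0.3, 0.0, 0.5]
        paired, _ = compare_methods({"t1": (vals, vals)})
        assert paired[0].test_name == "degenerate"
        assert math.isnan(paired[0].p_value)
        assert paired[0].significant is None

    def test_outlier_breaks_normality(self):
        """A right outlier drives Shapiro-Wilk below 0.05."""
        vec = np.array([1, 2, 3, 4, 5, 6, 7, 8, 20], float)
        assert _shapiro_p(vec) < 0.05
        assert _shapiro_p(vec) == pytest.approx(0.011857, rel=1e-3)

    def test_selection_rule(self):
        """Normal paired differences -> paired t-test; heavy-tailed
        differences -> Wilcoxon signed-rank."""
        rng = np.random.default_rng(3)
        base = rng.normal(0, 1, 40)
        normal_pair = {"t": (base + rng.normal(0.1, 0.3, 40), base)}
        paired, _ = compare_methods(normal_pair)
        assert paired[0].test_name == "paired t-test"

        skewed_diff = np.concatenate(
            [rng.normal(0, 0.05, 36), np.array([4.0, 5.0, 6.0, 7.0])]
        )
        skew_pair = {"t": (base + skewed_diff, base)}
        paired, _ = compare_methods(skew_pair)
        assert paired[0].test_name == "Wilcoxon signed-rank"

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError, match="unpaired"):
            compare_methods({"t": ([1.0, 2.0], [1.0, 2.0, 3.0])})

    def test_group_gate(self):
        """Homogeneous variances route to ANOVA, heterogeneous to
        Kruskal-Wallis."""
        rng = np.random.default_rng(10)
        same = {f"t{i}": (rng.normal(0, 1, 30), rng.normal(0, 1, 30))
                for i in range(3)}
        _, group = compare_methods(same)
        assert all(g.test_name == "one-way ANOVA" for g in group)

        hetero = {
            "t0": (rng.normal(0, 0.1, 30), rng.normal(0, 0.1, 30)),
            "t1": (rng.normal(0, 3.0, 30), rng.normal(0, 3.0, 30)),
        }
        _, group = compare_methods(hetero)
        assert all(g.test_name == "Kruskal-Wallis" for g in group)

    def test_single_target_group_not_applicable(self):
        _, group = compare_methods({"t": ([0.1, 0.2, 0.3], [0.2, 0.1, 0.4])})
        assert all(g.test_name == "not applicable" for g in group)
        assert all(g.significant is None for g in group)

    def test_type_one_error_rate_under_null(self):
        """With mean-zero paired differences the pipeline rejects at
        roughly the nominal 5% level (wide 0-15% band)."""
        rejections = 0
        n_seeds = 40
        for seed in range(n_seeds):
            rng = np.random.default_rng(1000 + seed)
            base = rng.normal(0, 1.0, 50)
            diff = rng.normal(0, 0.5, 50)
            paired, _ = compare_methods({"t": (base + diff, base)})
            if paired[0].significant:
                rejections += 1
        assert 0 <= rejections / n_seeds <= 0.15


class TestFullValidation:
    def test_records_reproducible_from_rows(self, clinical_plan):
        """Each summary list element traces back to a stored record."""
        fixture = default_fixture(seed=4, n_targets=2)
        summary = run_full_validation([s for s, _ in fixture], clinical_plan)
        for tid, methods in summary.per_target.items():
            for method, stats in methods.items():
                from_records = [
                    r.discrepancy_percent
                    for r in summary.records
                    if r.target_id == tid and r.method == method
                ]
                assert stats.n == len(from_records)
                assert stats.median == pytest.approx(
                    float(np.median(from_records))
                )

    def test_paired_lists_aligned(self, clinical_plan):
        """Skipped points are excluded from both methods symmetrically."""
        fixture = default_fixture(seed=6, n_targets=2)
        summary = run_full_validation([s for s, _ in fixture], clinical_plan)
        for t in summary.paired_tests:
            comp_n = summary.per_target[t.target_id][METHOD_COMPENSATED].n
            const_n = summary.per_target[t.target_id][METHOD_CONSTANT_FLUX].n
            assert t.n_pairs == comp_n == const_n
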