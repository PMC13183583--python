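"""Transport-model algebra, curve fitting, QC and group statistics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nucleoflux.kinetics import (
    CellCohort,
    QCReason,
    TransportParams,
    compare_groups,
    export_ratio_recovery,
    fit_recovery,
    qc_filter,
    rates_from_fit,
    ratio_recovery,
    split_percent,
)
from nucleoflux.quant import TimeCourse
from nucleoflux.simulate import CellSimSpec, gen_cell_timecourse


class TestRatioRecovery:
    def test_zero_at_time_zero(self):
        assert ratio_recovery(0.0, 1.87, 4.94e-3, 1.0) == 0.0

    def test_asymptote_is_accumulation_ratio(self):
        assert ratio_recovery(1e9, 1.87, 4.94e-3, 1.0) == pytest.approx(1.87, abs=1e-12)

    def test_mcherry_value_at_200s(self):
        # independent closed-form evaluation: 1.87(1-e^-0.988)/(1+1.87 e^-0.988)
        e = np.exp(-4.94e-3 * 200.0)
        expected = 1.87 * (1 - e) / (1 + 1.87 * e)
        assert ratio_recovery(200.0, 1.87, 4.94e-3, 1.0) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(0.692, abs=5e-4)

    def test_export_form_mirrors_import(self):
        t = np.linspace(0, 5000, 50)
        np.testing.assert_allclose(
            export_ratio_recovery(t, 0.95, 3.5e-3, 1.2),
            ratio_recovery(t, 0.95, 3.5e-3, 1.2),
        )

    @pytest.mark.parametrize("bad", [(-1, 1, 1), (1, 0, 1), (1, 1, -2)])
    def test_domain_violations(self, bad):
        with pytest.raises(ValueError):
            ratio_recovery(10.0, *bad)

    @settings(max_examples=50, derandomize=True)
    @given(
        K_e=st.floats(0.05, 40), k=st.floats(1e-4, 0.5), v=st.floats(0.1, 10)
    )
    def test_monotone_increasing_and_bounded(self, K_e, k, v):
        t = np.linspace(0, 10 / k, 200)
        r = ratio_recovery(t, K_e, k, v)
        assert np.all(np.diff(r) > 0)
        assert np.all(r <= K_e + 1e-12)


class TestRates:
    def test_symmetric_split(self):
        assert rates_from_fit(1.0, 2.0) == (1.0, 1.0)

    def test_mcherry_import_rate(self):
        k_I, k_E = rates_from_fit(1.87, 4.94)  # ks^-1
        assert k_I == pytest.approx(3.22, abs=5e-3)
        assert k_I + k_E == pytest.approx(4.94, abs=0)

    def test_large_accumulation_limit(self):
        k_I, _ = rates_from_fit(1e9, 2.0)
        assert k_I == pytest.approx(2.0, rel=1e-6)

    def test_export_mode_swaps_roles(self):
        k_I, k_E = rates_from_fit(1.87, 4.94, mode="export")
        assert k_E > k_I

    @settings(max_examples=50, derandomize=True)
    @given(K_e=st.floats(0.01, 50), k=st.floats(1e-4, 1.0))
    def test_ratio_of_rates_equals_accumulation(self, K_e, k):
        k_I, k_E = rates_from_fit(K_e, k)
        assert k_I + k_E == pytest.approx(k, rel=1e-12)
        assert k_I / k_E == pytest.approx(K_e, rel=1e-9)


class TestFitRecovery:
    def test_noiseless_roundtrip_recovers_truth(self):
        p = TransportParams.from_accumulation(1.87, 4.94e-3, 0.8)
        tc, _ = gen_cell_timecourse(
            CellSimSpec(params=p, activation_duration=0.0, noise_cv=0.0, seed=0)
        )
        res = fit_recovery(tc, v_policy="free")
        assert res.converged
        assert res.params.K_e == pytest.approx(p.K_e, rel=1e-6)
        assert res.params.k == pytest.approx(p.k, rel=1e-6)
        assert res.params.v == pytest.approx(p.v, rel=1e-6)

    def test_noisy_cohort_median_error(self, mcherry_params):
        errs = []
        for i in range(60):
            tc, _ = gen_cell_timecourse(
                CellSimSpec(
                    params=mcherry_params,
                    activation_duration=0.0,
                    noise_cv=0.1,
                    seed=300 + i,
                )
            )
            r = fit_recovery(tc, v_policy=("fixed", 1.0))
            errs.append(abs(r.params.K_e - mcherry_params.K_e) / mcherry_params.K_e)
        assert np.median(errs) <= 0.05

    def test_degenerate_zero_series_raises(self):
        n = 10
        tc = TimeCourse(
            t_s=np.arange(n, dtype=float) * 60,
            phase=np.array(["recovery"] * n, dtype=object),
            N=np.zeros(n),
            C=np.ones(n),
            ratio=np.zeros(n),
        )
        with pytest.raises(ValueError):
            fit_recovery(tc)

    def test_too_few_points_raises(self):
        tc = TimeCourse(
            t_s=np.arange(3, dtype=float),
            phase=np.array(["recovery"] * 3, dtype=object),
            N=np.ones(3),
            C=np.ones(3),
            ratio=np.ones(3),
        )
        with pytest.raises(ValueError):
            fit_recovery(tc)


def _fit_for(params, seed, noise=0.1):
    tc, _ = gen_cell_timecourse(
        CellSimSpec(params=params, activation_duration=0.0, noise_cv=noise, seed=seed)
    )
    f = fit_recovery(tc, v_policy=("fixed", 1.0))
    f.cell_id = f"cell{seed}"
    return f


class TestQCFilter:
    def test_poor_activation_discarded(self, mcherry_params):
        fits = [_fit_for(mcherry_params, s) for s in range(6)]
        # one cell whose activation trace never drops below its plateau
        traces = {f.cell_id: np.array([1.8, 1.8, 1.8]) for f in fits[:1]}
        cohort = qc_filter(CellCohort(fits=fits), activation_traces=traces)
        assert cohort.qc_status[0] is QCReason.POOR_ACTIVATION
        assert all(s is QCReason.PASS for s in cohort.qc_status[1:])

    def test_planted_outliers_removed(self, mcherry_params):
        fits = [_fit_for(mcherry_params, s) for s in range(40)]
        outlier_params = TransportParams.from_accumulation(18.7, 4.94e-3, 1.0)
        planted = [_fit_for(outlier_params, 100 + s, noise=0.05) for s in range(2)]
        cohort = qc_filter(CellCohort(fits=fits + planted))
        statuses = cohort.qc_status
        assert all(s is not QCReason.PASS for s in statuses[-2:])
        false_removals = sum(s is not QCReason.PASS for s in statuses[:-2])
        assert false_removals <= 1

    def test_unconverged_fit_tagged_unphysical(self, mcherry_params):
        good = _fit_for(mcherry_params, 0)
        bad = _fit_for(mcherry_params, 1)
        bad.converged = False
        cohort = qc_filter(CellCohort(fits=[good, bad, _fit_for(mcherry_params, 2)]))
        assert cohort.qc_status[1] is QCReason.UNPHYSICAL


class TestSplit:
    def test_printed_import_rates_give_56_percent(self):
        assert round(split_percent([3.22], [2.06])) == 56

    def test_identical_groups_zero(self):
        assert split_percent([1.0, 2.0], [1.0, 2.0]) == 0.0

    def test_reversed_rates(self):
        assert round(split_percent([2.06], [3.22])) == -36

    @settings(max_examples=50, derandomize=True)
    @given(
        a=st.floats(0.1, 100), b=st.floats(0.1, 100)
    )
    def test_inverse_relation_under_group_exchange(self, a, b):
        s_ab = split_percent([a], [b])
        s_ba = split_percent([b], [a])
        assert s_ab == pytest.approx(100.0 * (1.0 / (1.0 + s_ba / 100.0) - 1.0), rel=1e-9)

    def test_zero_mean_denominator_raises(self):
        with pytest.raises(ValueError):
            split_percent([1.0], [0.0])


class TestCompareGroups:
    def test_identical_samples_maximal_p(self):
        _, p, _, _ = compare_groups([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == 1.0

    def test_fully_separated_exact_p(self):
        # all 20 arrangements of ranks: the observed split is one of 2 extremes
        U, p, _, _ = compare_groups([1.0, 2.0, 3.0], [10.0, 11.0, 12.0])
        assert U in (0.0, 9.0)
        assert p == pytest.approx(0.1, abs=1e-12)

    def test_null_rejection_rate_nominal(self):
        rng = np.random.default_rng(42)
        rej = 0
        n_rep = 10_000
        for _ in range(n_rep):
            a = rng.normal(size=10)
            b = rng.normal(size=10)
            _, p, _, _ = compare_groups(a, b)
            rej += p < 0.05
        assert 0.04 <= rej / n_rep <= 0.06

    def test_small_group_raises(self):
        with pytest.raises(ValueError):
            compare_groups([1.0], [2.0, 3.0])


class TestTransportParams:
    def test_mass_conservation_enforced(self):
        with pytest.raises(ValueError):
            TransportParams(K_e=1.0, k=2.0, k_I=1.0, k_E=1.0, v=1.0, N0=0, Ne=1, C0=5, Ce=1)

    def test_rate_sum_enforced(self):
        with pytest.raises(ValueError):
            TransportParams(K_e=1.0, k=2.0, k_I=1.5, k_E=1.0, v=1.0)

    def test_from_accumulation_consistent(self):
        p = TransportParams.from_accumulation(1.87, 4.94e-3, 1.3)
        assert p.k_I / p.k_E == pytest.approx(1.87, rel=1e-12)
        assert p.v * (p.Ne - p.N0) == pytest.approx(p.C0 - p.Ce, rel=1e-12)
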