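import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from herbqc import (
    ConsistencyError,
    ContentResult,
    DomainError,
    InsufficientDataError,
    compare_methods,
    compute_rcf,
    esm_content,
    qams_content,
    rcf_summary,
    recovery,
    summarize,
)
from .conftest import (
    PRECISION_D,
    RCF_D_A,
    RCF_D_B9,
    RCF_D_F,
    REPEATABILITY_D,
    STABILITY_D,
)

positive = st.floats(1e-3, 1e6, allow_nan=False, allow_infinity=False)


class TestComputeRCF:
    def test_identity_when_masses_and_areas_match(self):
        assert compute_rcf(5.0, 123.0, 5.0, 123.0) == 1.0

    def test_published_mass_area_arithmetic(self):
        # D vs F: (12.28 * 3332.7) / (9.92 * 3571.0) -> printed 1.15 at 20 µl
        assert compute_rcf(12.28, 3571.0, 9.92, 3332.7) == pytest.approx(1.155, abs=0.005)
        # D vs B9 -> printed 0.85 at 20 µl
        assert compute_rcf(12.28, 3571.0, 7.70, 1892.7) == pytest.approx(0.845, abs=0.005)

    def test_nonpositive_input_is_domain_error(self):
        with pytest.raises(DomainError):
            compute_rcf(1.0, 0.0, 1.0, 1.0)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(w_k=positive, a_k=positive, w_s=positive, a_s=positive)
    def test_reciprocal_identity(self, w_k, a_k, w_s, a_s):
        f_ks = compute_rcf(w_k, a_k, w_s, a_s)
        f_sk = compute_rcf(w_s, a_s, w_k, a_k)
        assert f_ks * f_sk == pytest.approx(1.0, rel=1e-12)


class TestRCFSummary:
    def test_published_per_volume_factors(self):
        reps = [
            (str(v), {"A": a, "F": f, "B9": b})
            for v, a, f, b in zip([3, 5, 10, 15, 20, 25, 30], RCF_D_A, RCF_D_F, RCF_D_B9)
        ]
        rs = rcf_summary(reps, irs="D")
        assert rs.mean["A"] == pytest.approx(1.63, abs=0.005)
        assert rs.rsd_pct["A"] == pytest.approx(1.56, abs=0.01)
        assert rs.mean["F"] == pytest.approx(1.15, abs=0.005)
        assert rs.mean["B9"] == pytest.approx(0.84, abs=0.005)

    def test_identical_replicates_zero_rsd(self):
        rs = rcf_summary([("a", {"A": 1.5}), ("b", {"A": 1.5})], irs="D")
        assert rs.mean["A"] == 1.5 and rs.rsd_pct["A"] == 0.0

    def test_rsd_invariant_under_rescaling(self):
        reps = [(str(i), {"A": v}) for i, v in enumerate(RCF_D_A)]
        scaled = [(label, {"A": 7.3 * f["A"]}) for label, f in reps]
        assert rcf_summary(reps, "D").rsd_pct["A"] == pytest.approx(
            rcf_summary(scaled, "D").rsd_pct["A"], rel=1e-12
        )

    def test_mismatched_components_error(self):
        with pytest.raises(ConsistencyError):
            rcf_summary([("a", {"A": 1.0}), ("b", {"F": 1.0})])

    def test_single_replicate_insufficient(self):
        with pytest.raises(InsufficientDataError):
            rcf_summary([("a", {"A": 1.0})])


class TestSummarize:
    @pytest.mark.parametrize(
        "values, mean, rsd",
        [
            (PRECISION_D, 3571.0, 0.50),
            (REPEATABILITY_D, 3451.0, 1.41),
            (STABILITY_D, 3474.5, 0.56),
        ],
        ids=["precision", "repeatability", "stability"],
    )
    def test_published_replicate_series(self, values, mean, rsd):
        s = summarize(values)
        assert s.mean == pytest.approx(mean, abs=0.05)
        assert s.rsd_pct == pytest.approx(rsd, abs=0.005)

    def test_constant_list_zero_rsd(self):
        s = summarize([7.0, 7.0, 7.0])
        assert s.sd == 0.0 and s.rsd_pct == 0.0

    def test_single_value_insufficient(self):
        with pytest.raises(InsufficientDataError):
            summarize([1.0])


class TestContents:
    def test_esm_identity(self):
        assert esm_content(100.0, 100.0, 40.0, 40.0) == pytest.approx(100.0)

    def test_esm_published_arithmetic(self):
        # repeatability-mean IRS area vs reference-mean area; 40 µg sample load
        assert esm_content(3451.0, 3571.0, 12.28, 40.0) == pytest.approx(29.7, abs=0.05)

    def test_esm_linear_in_sample_area(self):
        full = esm_content(3451.0, 3571.0, 12.28, 40.0)
        assert esm_content(3451.0 / 2, 3571.0, 12.28, 40.0) == pytest.approx(full / 2)

    def test_qams_self_consistency_with_unit_factor(self):
        # component = IRS: f = 1, same areas -> IRS content itself
        irs = esm_content(3451.0, 3571.0, 12.28, 40.0)
        w_k = (3451.0 / 3571.0) * 12.28
        assert qams_content(3451.0, 3451.0, w_k, 1.0, 40.0) == pytest.approx(irs)

    def test_qams_published_arithmetic(self):
        assert qams_content(1797.3, 3451.0, 11.87, 1.15, 40.0) == pytest.approx(13.4, abs=0.05)

    def test_qams_equals_esm_on_noise_free_response(self):
        # same power-law response model generates areas and the factor
        slope_k, int_k = 0.9781, 5.7314
        slope_s, int_s = 1.0209, 5.7846
        area = lambda sl, ic, m: np.exp(ic + sl * np.log(m))
        w_k_ref, w_s_ref = 12.28, 9.92
        a_k_ref, a_s_ref = area(slope_k, int_k, w_k_ref), area(slope_s, int_s, w_s_ref)
        f_ks = compute_rcf(w_k_ref, a_k_ref, w_s_ref, a_s_ref)
        w_k_smp, w_s_smp = 11.9, 9.92   # same s mass as reference: f is exact there
        a_k_smp, a_s_smp = area(slope_k, int_k, w_k_smp), area(slope_s, int_s, w_s_smp)
        esm = esm_content(a_s_smp, a_s_ref, w_s_ref, 40.0)
        w_k_meas = (a_k_smp / a_k_ref) * w_k_ref
        qams = qams_content(a_s_smp, a_k_smp, w_k_meas, f_ks, 40.0)
        assert qams == pytest.approx(esm, rel=1e-9)


class TestRecovery:
    @pytest.mark.parametrize(
        "content, added, measured, rate",
        [
            (5.715, 5.700, 11.425, 100.18),
            (5.717, 5.700, 11.488, 101.25),
            # printed rate for this row (101.83) mis-rounds its own inputs;
            # direct arithmetic gives 101.84
            (5.720, 5.700, 11.525, 101.84),
            (0.630, 0.630, 1.262, 100.31),
        ],
    )
    def test_published_spike_rows(self, content, added, measured, rate):
        assert recovery(content, added, measured).rate_pct == pytest.approx(rate, abs=0.01)

    def test_exact_spike_return_is_100(self):
        assert recovery(3.0, 2.0, 5.0).rate_pct == pytest.approx(100.0)

    def test_zero_addition_is_domain_error(self):
        with pytest.raises(DomainError):
            recovery(1.0, 0.0, 2.0)


class TestCompareMethods:
    @staticmethod
    def _results(values_by_batch, method):
        return [
            ContentResult(batch=b, method=method, contents_pct={"D": v})
            for b, v in values_by_batch.items()
        ]

    def test_identical_inputs_degenerate_p_one(self):
        esm = self._results({"1": 2.0, "2": 3.0, "3": 4.0}, "ESM")
        qams = self._results({"1": 2.0, "2": 3.0, "3": 4.0}, "QAMS")
        (c,) = compare_methods(esm, qams)
        assert c.degenerate and c.p == 1.0 and c.t == 0.0
        assert c.no_significant_difference

    def test_constant_shift_reported_as_exact_shift(self):
        esm = self._results({"1": 2.0, "2": 3.0, "3": 4.0}, "ESM")
        qams = self._results({"1": 1.0, "2": 2.0, "3": 3.0}, "QAMS")
        (c,) = compare_methods(esm, qams)
        assert c.degenerate and c.shift == pytest.approx(1.0)
        assert not c.no_significant_difference

    def test_null_noise_rejection_rate_matches_alpha(self):
        # QAMS = ESM + N(0, 0.01^2): differences are pure noise, so the
        # paired-t p-value is uniform and p > 0.05 should hold ~95% of runs
        rng = np.random.default_rng(2024)
        base = {"1": 2.07, "2": 1.63, "3": 3.83, "4": 3.14, "5": 10.57}
        ok = 0
        n_runs = 1000
        for _ in range(n_runs):
            esm = self._results(base, "ESM")
            qams = self._results(
                {b: v + rng.normal(0, 0.01) for b, v in base.items()}, "QAMS"
            )
            (c,) = compare_methods(esm, qams)
            ok += c.no_significant_difference
        assert 0.93 <= ok / n_runs <= 0.97

    def test_mismatched_batches_error(self):
        esm = self._results({"1": 2.0, "2": 3.0}, "ESM")
        qams = self._results({"1": 2.0, "3": 3.0}, "QAMS")
        with pytest.raises(ConsistencyError):
            compare_methods(esm, qams)

    def test_fewer_than_two_batches_error(self):
        with pytest.raises(InsufficientDataError):
            compare_methods(self._results({"1": 2.0}, "ESM"),
                            self._results({"1": 2.0}, "QAMS"))

    def test_matches_scipy_on_noisy_pairs(self):
        rng = np.random.default_rng(5)
        x = rng.uniform(1, 10, 6)
        y = x + rng.normal(0, 0.3, 6)
        esm = self._results({str(i): v for i, v in enumerate(x)}, "ESM")
        qams = self._results({str(i): v for i, v in enumerate(y)}, "QAMS")
        (c,) = compare_methods(esm, qams)
        ref = stats.ttest_rel(x, y)
        assert c.t == pytest.approx(float(ref.statistic))
        assert c.p == pytest.approx(float(ref.pvalue))
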