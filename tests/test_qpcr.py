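import math

import numpy as np
import pytest

from cdrlight import (
    Assay,
    Call,
    CtMeasurement,
    InputError,
    InsufficientReplicatesError,
    MixtureSeries,
    TitrationSeries,
    aggregate_replicates,
    call_scnv,
    detection_limit,
    is_informative,
    mixture_linearity,
    quantify_pair,
    relative_copy_number,
    titration_efficiency,
)
from cdrlight.errors import AnalysisError
from cdrlight.qpcr import _monotone_lowest
from cdrlight.synth import gen_mixture_series


def wells(sample_id, target_cts, reference_cts):
    out = []
    for i, ct in enumerate(target_cts, 1):
        out.append(CtMeasurement(sample_id, Assay.TARGET, i, ct))
    for i, ct in enumerate(reference_cts, 1):
        out.append(CtMeasurement(sample_id, Assay.REFERENCE, i, ct))
    return out


class TestAggregateReplicates:
    def test_identical_triplicate(self):
        mean, sd, n = aggregate_replicates(wells("s", [30.0, 30.0, 30.0], [])[:3])
        assert (mean, sd, n) == (30.0, 0.0, 3)

    def test_two_replicates_sample_sd(self):
        ms = [CtMeasurement("s", Assay.TARGET, i, ct) for i, ct in enumerate([30.0, 31.0], 1)]
        mean, sd, n = aggregate_replicates(ms)
        assert mean == 30.5
        assert sd == pytest.approx(math.sqrt(0.5))  # hand-computed sample SD

    def test_dropout_leaves_too_few(self):
        ms = [
            CtMeasurement("s", Assay.TARGET, 1, 30.0),
            CtMeasurement("s", Assay.TARGET, 2, None),
        ]
        with pytest.raises(InsufficientReplicatesError):
            aggregate_replicates(ms)


class TestInformativeness:
    @pytest.mark.parametrize(
        "mean_ct,expected", [(34.0, True), (34.01, False), (20.0, True), (None, False)]
    )
    def test_cutoff_boundary_inclusive(self, mean_ct, expected):
        assert is_informative(mean_ct) is expected


class TestRelativeCopyNumber:
    def test_calibrator_identity(self):
        assert relative_copy_number(5.0, 5.0) == 1.0

    def test_one_cycle_halves(self):
        assert relative_copy_number(6.0, 5.0) == pytest.approx(0.5)

    def test_twenty_percent_spike_algebra(self):
        dd = math.log2(1 / 0.8)
        rcn = relative_copy_number(dd, 0.0)
        assert rcn == pytest.approx(0.8)
        assert 1 - rcn == pytest.approx(0.2)

    def test_log_linearity_slope_minus_one(self):
        ddcts = np.linspace(-2, 3, 7)
        log_rcn = [math.log2(relative_copy_number(d, 0.0)) for d in ddcts]
        np.testing.assert_allclose(log_rcn, -ddcts)

    def test_efficiency_bounds(self):
        with pytest.raises(InputError):
            relative_copy_number(1.0, 0.0, efficiency=1.0)
        with pytest.raises(InputError):
            relative_copy_number(1.0, 0.0, efficiency=2.3)


class TestCallScnv:
    def test_zero_difference_is_neutral(self):
        with pytest.warns(UserWarning, match="zero-variance"):
            call, p = call_scnv([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])
        assert (call, p) == (Call.NEUTRAL, 1.0)

    def test_clear_deletion(self):
        # two-sample t: means 0.60 vs 1.00, sd 0.02 each -> |t| = 24.49, p << 0.001
        call, p = call_scnv([0.60, 0.62, 0.58], [1.00, 0.98, 1.02])
        assert call is Call.DELETION
        assert p < 0.001

    def test_clear_amplification(self):
        call, p = call_scnv([1.50, 1.48, 1.52], [1.00, 0.98, 1.02])
        assert call is Call.AMPLIFICATION
        assert p < 0.001

    def test_insufficient_replicates(self):
        with pytest.raises(InsufficientReplicatesError):
            call_scnv([1.0], [1.0, 1.0])


class TestQuantifyPair:
    def test_one_cycle_shift_called_deletion(self):
        tumor = wells("T1", [29.0, 29.0, 29.0], [28.0, 28.0, 28.0])
        normal = wells("N1", [28.0, 28.0, 28.0], [28.0, 28.0, 28.0])
        with pytest.warns(UserWarning):
            q = quantify_pair(tumor, normal)
        assert q.call is Call.DELETION
        assert q.rel_copy_number == pytest.approx(0.5)
        assert q.deletion_proportion == pytest.approx(0.5)

    def test_reference_gate_blocks_calling(self):
        tumor = wells("T1", [29.0, 29.0, 29.0], [35.0, 35.0, 35.0])
        normal = wells("N1", [28.0, 28.0, 28.0], [28.0, 28.0, 28.0])
        q = quantify_pair(tumor, normal)
        assert q.call is Call.NON_INFORMATIVE
        assert not q.informative
        assert q.rel_copy_number is None and q.p_value is None

    def test_complete_target_dropout_is_deletion(self):
        tumor = wells("T1", [None, None, None], [28.0, 28.0, 28.0])
        normal = wells("N1", [28.0, 28.0, 28.0], [28.0, 28.0, 28.0])
        q = quantify_pair(tumor, normal)
        assert q.call is Call.DELETION
        assert q.complete_dropout
        assert q.rel_copy_number == 0.0
        assert q.p_value == 0.0


class TestTitrationEfficiency:
    def test_perfect_doubling(self):
        amounts = (10.0, 5.0, 2.5)
        cts = {10.0: (30.0,), 5.0: (31.0,), 2.5: (32.0,)}
        series = TitrationSeries(amounts, cts, cts)
        slope, eff, dcts = titration_efficiency(series)
        assert slope == pytest.approx(-1.0)
        assert eff == pytest.approx(2.0)
        assert all(abs(d) < 1e-12 for d in dcts.values())

    def test_flat_response_rejected(self):
        amounts = (10.0, 5.0, 2.5)
        cts = {a: (30.0,) for a in amounts}
        with pytest.raises(AnalysisError, match="no amplification response"):
            titration_efficiency(TitrationSeries(amounts, cts, cts))

    def test_least_squares_slope_matches_normal_equations(self):
        amounts = (10.0, 5.0, 2.5)
        target = {10.0: (30.0,), 5.0: (31.1,), 2.5: (32.0,)}
        series = TitrationSeries(amounts, target, target)
        x = np.log2(sorted(amounts))
        y = np.array([np.mean(target[a]) for a in sorted(amounts)])
        expected = np.sum((x - x.mean()) * (y - y.mean())) / np.sum((x - x.mean()) ** 2)
        slope, eff, _ = titration_efficiency(series)
        assert slope == pytest.approx(expected)  # == -1.0 exactly for these values
        assert slope == pytest.approx(-1.0)

    def test_too_few_amounts(self):
        with pytest.raises(InputError):
            TitrationSeries((10.0, 5.0), {}, {})

    def test_span_under_two_doublings(self):
        amounts = (10.0, 8.0, 6.0)
        cts = {a: (30.0,) for a in amounts}
        with pytest.raises(InputError, match="doublings"):
            titration_efficiency(TitrationSeries(amounts, cts, cts))


class TestMixtureLinearity:
    def test_noise_free_is_exact(self):
        series = gen_mixture_series(seed=1, ct_noise_sd=0.0)
        slope, intercept, r = mixture_linearity(series)
        assert slope == pytest.approx(1.0)
        assert intercept == pytest.approx(0.0, abs=1e-12)
        assert r == pytest.approx(1.0)

    def test_noisy_slope_near_unity(self):
        series = gen_mixture_series(
            seed=42,
            null_fractions=(0.0, 0.05, 0.10, 0.15, 0.20, 0.30),
            replicates=3,
        )
        slope, intercept, r = mixture_linearity(series)
        assert 0.9 <= slope <= 1.1

    def test_too_few_fractions(self):
        series = MixtureSeries(
            (0.0, 0.2),
            {0.0: (28.0,), 0.2: (28.3,)},
            {0.0: (28.0,), 0.2: (28.0,)},
        )
        with pytest.raises(InputError):
            mixture_linearity(series)

    def test_parameter_recovery_many_replicates(self):
        # mean deletion proportion converges to the spiked fraction
        for f in (0.1, 0.2, 0.3):
            series = gen_mixture_series(
                seed=int(f * 1000), null_fractions=(0.0, f), replicates=100
            )
            cal = float(series.dcts(0.0).mean())
            rcns = 2.0 ** -(series.dcts(f) - cal)
            assert abs((1 - rcns.mean()) - f) < 0.02


class TestDetectionLimit:
    def test_monotone_rule_forced(self):
        assert _monotone_lowest({0.10: 0.30, 0.20: 0.03, 0.30: 0.001}, 0.05) == 0.20

    def test_all_insignificant_not_detected(self):
        assert _monotone_lowest({0.1: 0.5, 0.2: 0.9}, 0.05) is None

    def test_isolated_false_positive_ignored(self):
        assert _monotone_lowest({0.1: 0.01, 0.2: 0.50, 0.3: 0.001}, 0.05) == 0.3

    def test_noise_free_limit_is_smallest_fraction(self):
        series = gen_mixture_series(seed=5, ct_noise_sd=0.0)
        with pytest.warns(UserWarning, match="zero-variance"):
            res = detection_limit(series)
        assert res.detected
        assert res.detection_limit == 0.10

    def test_series_must_include_control(self):
        with pytest.raises(InputError, match="0% control"):
            MixtureSeries((0.1, 0.2), {}, {})

    def test_fractions_must_increase(self):
        with pytest.raises(InputError):
            MixtureSeries((0.0, 0.2, 0.1), {}, {})
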