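import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import K, make_record
from ctlensdose import dose_analysis as da


class TestGroupSummary:
    def test_basic_three_values(self):
        s = da.group_summary([1, 2, 3])
        assert (s.mean, s.median, s.min, s.max) == (2.0, 2.0, 1.0, 3.0)
        assert s.sd == pytest.approx(1.0)

    def test_quantiles_linear_interpolation_convention(self):
        s = da.group_summary([1, 2, 3, 4])
        assert s.median == 2.5
        assert s.q25 == pytest.approx(1.75)
        assert s.q75 == pytest.approx(3.25)

    def test_constant_list_degenerate(self):
        s = da.group_summary([5.0, 5.0, 5.0])
        assert s.sd == 0.0
        assert s.ci95 == (5.0, 5.0)

    def test_ci_uses_t_distribution(self):
        s = da.group_summary([1, 2, 3])
        half = 4.302652729911275 * 1.0 / np.sqrt(3)  # t(0.975, 2) sd/sqrt(n)
        assert s.ci95[0] == pytest.approx(2 - half)
        assert s.ci95[1] == pytest.approx(2 + half)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            da.group_summary([])


class TestPairedRatioSummary:
    def test_identical_pairs_give_unit_median(self):
        s, excluded = da.paired_ratio_summary([(2.0, 2.0)] * 5)
        assert s.median == 1.0 and excluded == 0

    def test_hand_arithmetic(self):
        s, _ = da.paired_ratio_summary([(2, 1), (1, 2), (1, 1)])
        assert s.median == 1.0
        assert (s.min, s.max) == (0.5, 2.0)

    def test_zero_denominators_excluded_and_counted(self):
        s, excluded = da.paired_ratio_summary([(1, 1), (1, 0), (2, 0)])
        assert excluded == 2 and s.n == 1

    def test_symmetric_noise_gives_unit_median(self):
        """n=91 lognormal symmetric V/H pairs should summarise to ~1.00."""
        rng = np.random.default_rng(42)
        base = rng.lognormal(mean=-1.5, sigma=0.6, size=91)
        noise = rng.lognormal(mean=0.0, sigma=0.14, size=(2, 91))
        s, _ = da.paired_ratio_summary(list(zip(base * noise[0], base * noise[1])))
        assert 0.95 <= s.median <= 1.05


class TestReductions:
    @pytest.mark.parametrize("ratio,expected", [(2.04, 51), (1.00, 0), (2.00, 50)])
    def test_reduction_from_ratio(self, ratio, expected):
        assert da.reduction_from_ratio(ratio) == expected

    def test_reduction_from_ratio_below_one_is_negative(self):
        assert da.reduction_from_ratio(0.8) == -25

    @pytest.mark.parametrize(
        "without,with_,expected",
        [(5.16, 2.92, 43), (2.18, 1.51, 31), (0.31, 0.12, 61), (7.0, 7.0, 0)],
    )
    def test_reduction_from_pair(self, without, with_, expected):
        assert da.reduction_from_pair(without, with_) == expected

    def test_reduction_from_pair_zero_without_rejected(self):
        with pytest.raises(ValueError):
            da.reduction_from_pair(0.0, 1.0)

    @given(st.floats(min_value=0.05, max_value=50, allow_nan=False))
    @settings(max_examples=200, deadline=None)
    def test_ratio_and_pair_formulas_agree(self, ratio):
        assert da.reduction_from_ratio(ratio) == da.reduction_from_pair(ratio, 1.0)


class TestGlassesEfficiency:
    def test_engineered_constant_ratio(self):
        """Records built with outside/inside kerma ratio exactly 2.04 must
        recover the 51% reduction."""
        records = [
            make_record(
                pid=f"G{i}",
                kermas=tuple(v * s for v in (0.204, 0.15, 0.1, 0.08, 0.05, 0.06)),
            )
            for i, s in enumerate([1.0, 2.0, 0.5, 1.3])
        ]
        ratio, pct = da.glasses_efficiency(records, K)
        assert ratio == pytest.approx(2.04, rel=1e-12)
        assert pct == 51

    def test_equal_outside_inside_gives_zero(self):
        records = [make_record(kermas=(0.2, 0.1, 0.2, 0.1, 0.05, 0.06))]
        ratio, pct = da.glasses_efficiency(records, K)
        assert ratio == 1.0 and pct == 0

    def test_zero_inside_records_excluded(self):
        good = make_record(pid="A", kermas=(0.2, 0.1, 0.1, 0.08, 0.05, 0.06))
        bad = make_record(pid="B", kermas=(0.2, 0.1, 0.0, 0.0, 0.0, 0.0))
        ratio, _ = da.glasses_efficiency([good, bad], K)
        assert ratio == pytest.approx(2.0)

    def test_all_zero_inside_rejected(self):
        with pytest.raises(ValueError):
            da.glasses_efficiency([make_record(kermas=(0.2, 0.1, 0, 0, 0, 0))], K)


class TestDlpNormalize:
    def test_reporting_scale(self):
        assert da.dlp_normalize(0.50, 1000.0) == pytest.approx(5.0)

    def test_scale_invariance(self):
        assert da.dlp_normalize(1.0, 500.0) == da.dlp_normalize(2.0, 1000.0)

    def test_zero_dlp_rejected(self):
        with pytest.raises(ValueError):
            da.dlp_normalize(1.0, 0.0)


class TestTubeEfficiency:
    @staticmethod
    def _stratum_record(pid, tube, out_norm, in_norm, dlp=10000.0):
        # choose kermas so hp3/dlp*1e4 hits the requested normalized values
        out_kerma = out_norm * dlp / 1e4 / K
        in_kerma = in_norm * dlp / 1e4 / K
        return make_record(
            pid=pid,
            extension_tube=tube,
            dlp=dlp,
            kermas=(out_kerma, out_kerma * 0.9, in_kerma, in_kerma * 0.9, in_kerma * 0.8, in_kerma * 0.7),
        )

    def test_engineered_strata_medians(self):
        """Normalized medians (5.16, 2.92) outside and (2.18, 1.51) inside
        must yield 43% and 31%."""
        records = [self._stratum_record(f"W{i}", False, 5.16, 2.18) for i in range(3)]
        records += [self._stratum_record(f"T{i}", True, 2.92, 1.51) for i in range(5)]
        assert da.tube_efficiency(records, K) == (43, 31)

    def test_identical_strata_give_zero(self):
        records = [self._stratum_record("A", False, 3.0, 1.5), self._stratum_record("B", True, 3.0, 1.5)]
        assert da.tube_efficiency(records, K) == (0, 0)

    def test_empty_stratum_raises_named_error(self):
        records = [self._stratum_record("A", True, 3.0, 1.5)]
        with pytest.raises(ValueError, match="without extension tube"):
            da.tube_efficiency(records, K)

    def test_non_ventilation_records_ignored(self):
        records = [
            self._stratum_record("A", False, 3.0, 1.5),
            self._stratum_record("B", True, 3.0, 1.5),
            make_record(pid="C", practice="observation", kermas=(9, 9, 9, 9, 9, 9)),
        ]
        assert da.tube_efficiency(records, K) == (0, 0)


class TestCombineMeasures:
    @pytest.mark.parametrize(
        "fractions,expected",
        [([0.31, 0.51], 66), ([0.31, 0.51, 0.61], 87), ([], 0), ([0.4], 40)],
    )
    def test_multiplicative_combination(self, fractions, expected):
        assert da.combine_measures(fractions) == expected

    def test_accepts_protection_measure_objects(self):
        measures = [
            da.ProtectionMeasure("glasses", 0.51),
            da.ProtectionMeasure("tube", 0.31),
        ]
        assert da.combine_measures(measures) == 66

    @given(
        st.lists(st.floats(min_value=0, max_value=0.95, allow_nan=False), min_size=0, max_size=5)
    )
    @settings(max_examples=200, deadline=None)
    def test_commutative_and_bounded(self, fractions):
        perm = list(reversed(fractions))
        combined = da.combine_measures(fractions)
        assert combined == da.combine_measures(perm)
        # the raw combined reduction is strictly below 100%; the printed
        # integer may round up to 100
        raw = 1.0 - np.prod([1 - f for f in fractions]) if fractions else 0.0
        assert 0 <= raw < 1
        assert 0 <= combined <= 100

    def test_adding_a_positive_measure_increases_reduction(self):
        base = da.combine_measures([0.3, 0.2])
        assert da.combine_measures([0.3, 0.2, 0.25]) > base

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            da.combine_measures([1.0])
        with pytest.raises(ValueError):
            da.combine_measures([-0.1])


class TestMaxProcedures:
    @pytest.mark.parametrize(
        "median,expected",
        [(0.51, 39), (0.49, 40), (0.25, 80), (0.36, 55), (0.19, 105), (0.16, 125),
         (0.12, 166), (0.30, 66), (0.28, 71), (20.0, 1), (25.0, 0)],
    )
    def test_floor_of_limit_over_median(self, median, expected):
        assert da.max_procedures(20.0, median) == expected

    def test_monotone_and_linear_in_limit(self):
        assert da.max_procedures(20, 0.5) >= da.max_procedures(20, 0.6)
        assert da.max_procedures(40, 0.51) == int(np.floor(40 / 0.51))

    def test_zero_median_rejected(self):
        with pytest.raises(ValueError):
            da.max_procedures(20.0, 0.0)


class TestDrlCompare:
    @pytest.mark.parametrize(
        "median,drl,expected",
        [(52.8, 85.0, False), (2196.6, 1800.0, True), (7.0, 7.0, False)],
    )
    def test_strict_comparison(self, median, drl, expected):
        assert da.drl_compare(median, drl) is expected

    def test_entry_flag_consistency(self):
        e = da.DrlEntry("liver multi-phase", "DLP", 2196.6, 1800.0)
        assert e.exceeds is True
        e2 = da.DrlEntry("routine brain", "CTDIvol", 52.8, 85.0)
        assert e2.exceeds is False


def test_round_half_up_convention():
    assert da.round_half_up(50.5) == 51
    assert da.round_half_up(50.4999) == 50
    assert da.round_half_up(-0.5) == -1
    assert da.round_half_up(2.5) == 3  # not banker's rounding
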