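import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from muvi.indices import INDEX_NAMES, IndexSet
from muvi.score import (
    PEReport,
    Thresholds,
    aggregate_replicates,
    classify,
    pe_profile,
    percent_error,
    sssad,
)
from muvi.spectra_io import Spectrum
from muvi.standards import bundled_standard


def make_indexset(values):
    return IndexSet.from_dict(dict(zip(INDEX_NAMES, values)))


def uniform_report(sample_id, pe_value, raw_a254=0.2, standards=("SRFA",)):
    per_index = {std: {k: pe_value for k in INDEX_NAMES} for std in standards}
    return PEReport.from_per_index(sample_id, per_index, raw_a254)


class TestPercentError:
    @pytest.mark.parametrize(
        "va,vs,expected",
        [
            (0.36, 0.40, 10.0),
            (0.22, 0.22, 0.0),
            (0.16, 0.22, 27.272727272727273),
        ],
    )
    def test_reference_values(self, va, vs, expected):
        assert percent_error(va, vs) == pytest.approx(expected)

    def test_zero_standard_rejected(self):
        with pytest.raises(ZeroDivisionError):
            percent_error(1.0, 0.0)

    @given(
        st.floats(0.01, 10), st.floats(0.01, 10), st.floats(0.01, 100)
    )
    def test_scale_invariance(self, a, b, c):
        assert percent_error(c * a, c * b) == pytest.approx(
            percent_error(a, b), rel=1e-9
        )

    @given(st.floats(0.01, 10))
    def test_self_comparison_is_zero(self, a):
        assert percent_error(a, a) == 0.0

    def test_asymmetry(self):
        assert percent_error(2.0, 1.0) != percent_error(1.0, 2.0)


class TestPEProfile:
    def test_self_comparison_all_zero(self):
        srfa = bundled_standard("SRFA")
        report = pe_profile(srfa.indices, [srfa], raw_a254=0.2, sample_id="self")
        assert all(v == 0 for v in report.per_index_pe["SRFA"].values())
        assert report.pe_avg["SRFA"] == 0.0
        assert report.pe_avg_min == 0.0

    def test_doubled_indices_give_uniform_100(self):
        srfa = bundled_standard("SRFA")
        doubled = make_indexset(2 * srfa.indices.as_array())
        report = pe_profile(doubled, [srfa], raw_a254=0.2)
        assert report.pe_avg["SRFA"] == pytest.approx(100.0)

    def test_min_across_standards(self):
        srfa = bundled_standard("SRFA")
        ppfa = bundled_standard("PPFA")
        report = pe_profile(ppfa.indices, [srfa, ppfa], raw_a254=0.2)
        assert report.pe_avg["PPFA"] == 0.0
        assert report.pe_avg["SRFA"] > 0
        assert report.pe_avg_min == 0.0

    def test_requires_a_standard(self):
        with pytest.raises(ValueError):
            pe_profile(bundled_standard("SRFA").indices, [], raw_a254=0.2)

    def test_inconsistent_pe_avg_rejected(self):
        per_index = {"SRFA": {k: 10.0 for k in INDEX_NAMES}}
        with pytest.raises(ValueError, match="inconsistent"):
            PEReport(
                sample_id="x",
                per_index_pe=per_index,
                pe_avg={"SRFA": 55.0},
                pe_avg_min=55.0,
                raw_a254=0.2,
            )

    @given(st.lists(st.floats(0, 500), min_size=10, max_size=10))
    def test_pe_avg_matches_mean_of_per_index(self, pes):
        per_index = {"STD": dict(zip(INDEX_NAMES, pes))}
        report = PEReport.from_per_index("x", per_index, raw_a254=0.1)
        assert report.pe_avg["STD"] == pytest.approx(np.mean(pes), abs=1e-9)


class TestAggregateReplicates:
    def test_identical_reports_unchanged(self):
        reports = [uniform_report("s", 15.0) for _ in range(3)]
        agg = aggregate_replicates(reports)
        assert agg.pe_avg["SRFA"] == pytest.approx(15.0)
        assert agg.concordance_ok
        assert agg.replicate_count == 3

    def test_spread_over_20_points_flags_discordance(self):
        reports = [uniform_report("s", v) for v in (10.0, 10.0, 40.0)]
        agg = aggregate_replicates(reports)
        assert not agg.concordance_ok
        assert agg.pe_avg["SRFA"] == pytest.approx(20.0)

    def test_spread_at_exactly_20_points_is_concordant(self):
        reports = [uniform_report("s", v) for v in (10.0, 30.0)]
        assert aggregate_replicates(reports).concordance_ok

    def test_two_replicate_mean(self):
        reports = [uniform_report("s", 20.0), uniform_report("s", 30.0)]
        agg = aggregate_replicates(reports)
        assert agg.pe_avg["SRFA"] == pytest.approx(25.0)

    def test_mixed_sample_ids_rejected(self):
        with pytest.raises(ValueError, match="mixed sample_ids"):
            aggregate_replicates(
                [uniform_report("a", 10.0), uniform_report("b", 10.0)]
            )

    def test_averaging_order_does_not_change_pe_avg(self):
        rng = np.random.default_rng(2)
        reports = [
            PEReport.from_per_index(
                "s",
                {"SRFA": dict(zip(INDEX_NAMES, rng.uniform(0, 50, 10)))},
                raw_a254=0.2,
            )
            for _ in range(3)
        ]
        agg = aggregate_replicates(reports)
        assert agg.pe_avg["SRFA"] == pytest.approx(
            np.mean([r.pe_avg["SRFA"] for r in reports]), abs=1e-9
        )


class TestClassify:
    @pytest.mark.parametrize(
        "a254,pe,verdict",
        [
            (0.005, 38.8, "non_fulvic"),   # molasses: fails the a254 gate
            (0.212, 32.1, "fulvic"),
            (0.080, 76.9, "non_fulvic"),   # boundary a254 fails the strict gate
            (0.168, 76.1, "non_fulvic"),   # PE above cutoff despite strong a254
        ],
    )
    def test_published_cases(self, a254, pe, verdict):
        assert classify(a254, pe).verdict == verdict

    def test_gray_zone_flagged(self):
        d = classify(0.168, 76.1)
        assert d.gray_zone
        assert classify(0.2, 30.0).gray_zone is False

    def test_gray_zone_mode_downgrades_to_indeterminate(self):
        d = classify(0.168, 76.1, gray_zone_mode=True)
        assert d.verdict == "indeterminate"
        # gate failure beats the gray zone: still non-fulvic
        assert classify(0.01, 76.1, gray_zone_mode=True).verdict == "non_fulvic"

    def test_boundary_pe_fails_strict_cutoff(self):
        assert classify(0.2, 70.0).verdict == "non_fulvic"
        assert classify(0.2, 69.999).verdict == "fulvic"

    @given(
        st.floats(0.0, 1.0),
        st.floats(0, 200),
        st.floats(0, 200),
    )
    def test_monotone_in_pe(self, a254, p1, p2):
        lo, hi = sorted((p1, p2))
        if classify(a254, hi).verdict == "fulvic":
            assert classify(a254, lo).verdict == "fulvic"

    @given(
        st.floats(0, 1), st.floats(0, 1), st.floats(0, 200)
    )
    def test_monotone_in_a254(self, a1, a2, pe):
        lo, hi = sorted((a1, a2))
        if classify(lo, pe).verdict == "fulvic":
            assert classify(hi, pe).verdict == "fulvic"

    def test_invalid_thresholds_rejected(self):
        with pytest.raises(ValueError):
            Thresholds(gray_low=80, pe_cutoff=70, gray_high=90)


class TestSssad:
    @staticmethod
    def ramp_spectrum(bump_at=None, bump=0.0):
        """1 AU at 290 nm declining linearly to 0 at 330 nm."""
        wl = np.arange(280.0, 341.0)
        vals = np.clip((330.0 - wl) / 40.0, 0.0, 1.5)
        s = Spectrum(wl, vals)
        if bump_at is not None:
            vals = vals.copy()
            vals[wl == bump_at] += bump
            s = Spectrum(wl, vals)
        return s

    def test_identity_is_zero(self):
        s = self.ramp_spectrum()
        assert sssad(s, s) == 0.0

    def test_single_point_difference(self):
        std = self.ramp_spectrum()
        sample = self.ramp_spectrum(bump_at=310.0, bump=0.1)
        assert sssad(sample, std) == pytest.approx(0.01)

    def test_scale_invariance(self):
        std = self.ramp_spectrum()
        tripled = Spectrum(std.wavelengths, 3.0 * std.absorbance)
        assert sssad(tripled, std) == pytest.approx(0.0, abs=1e-15)

    def test_flat_series_rejected(self):
        wl = np.arange(280.0, 341.0)
        flat = Spectrum(wl, np.ones(wl.size))
        with pytest.raises(ZeroDivisionError, match="290"):
            sssad(flat, flat)

    def test_absolute_mode(self):
        std = self.ramp_spectrum()
        sample = self.ramp_spectrum(bump_at=310.0, bump=0.1)
        assert sssad(sample, std, mode="absolute") == pytest.approx(0.1)
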