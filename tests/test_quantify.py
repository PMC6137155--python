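"""STD quantification: formula, normalisation, classes, bins, binder calls."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from stdgem.quantify import (
    AbsBin, EpitopeClass, PeakRecord, bin_absolute, classify_epitope,
    count_by_bin, detect_binding, fractional_std, quantify_peaks,
    read_peak_table, relative_std, write_peak_table,
)
from oracles import bin_oracle


def make_records(abs_pcts, compound="c1", I0=200.0):
    """Peak records whose absolute STD percentages are exactly abs_pcts."""
    return [
        PeakRecord(compound, f"H{i+1}", 7.5 - 0.1 * i, I0,
                   I0 * (1 - pct / 100.0), 2.94)
        for i, pct in enumerate(abs_pcts)
    ]


class TestFractionalSTD:
    @pytest.mark.parametrize(
        "I0,Isat,expected",
        [(100.0, 100.0, 0.0), (200.0, 198.0, 0.01), (100.0, 0.0, 1.0)],
    )
    def test_reference_values(self, I0, Isat, expected):
        assert fractional_std(I0, Isat) == pytest.approx(expected, abs=1e-15)

    @pytest.mark.parametrize("I0", [0.0, -5.0])
    def test_nonpositive_reference_integral_rejected(self, I0):
        with pytest.raises(ValueError, match="I0"):
            fractional_std(I0, 1.0)

    def test_negative_effect_kept_and_warned(self):
        with pytest.warns(UserWarning, match="artefact"):
            f = fractional_std(100.0, 110.0)
        assert f == pytest.approx(-0.1)

    @given(
        I0=st.floats(1e-6, 1e9, allow_nan=False),
        Isat=st.floats(0.0, 1e9, allow_nan=False),
    )
    @settings(max_examples=500, derandomize=True)
    def test_matches_printed_formula_to_machine_precision(self, I0, Isat):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            assert fractional_std(I0, Isat) == (I0 - Isat) / I0


class TestRelativeSTD:
    def test_direct_normalisation(self):
        prof = quantify_peaks(make_records([0.5, 1.0, 0.25]))
        rel = {p.proton_label: p.relative_std_pct for p in prof}
        assert rel["H1"] == pytest.approx(50.0)
        assert rel["H2"] == 100.0
        assert rel["H3"] == pytest.approx(25.0)

    def test_lone_proton_is_the_maximum(self):
        prof = quantify_peaks(make_records([0.3]))
        assert prof.protons[0].relative_std_pct == 100.0
        assert prof.protons[0].epitope_class is EpitopeClass.MAX

    def test_exactly_one_maximum_even_with_ties(self):
        prof = quantify_peaks(make_records([0.8, 0.8, 0.4]))
        assert [p.relative_std_pct for p in prof].count(100.0) >= 1
        assert sum(
            p.epitope_class is EpitopeClass.MAX for p in prof
        ) == 1

    def test_no_signal_leaves_relative_unset(self):
        prof = quantify_peaks(make_records([0.0, 0.0]))
        assert not prof.binder
        assert all(p.relative_std_pct is None for p in prof)
        assert all(p.epitope_class is None for p in prof)

    @given(
        pcts=st.lists(st.floats(0.01, 5.0), min_size=1, max_size=12),
        scale=st.floats(0.1, 100.0),
    )
    @settings(max_examples=200, derandomize=True)
    def test_scale_invariance_and_range(self, pcts, scale):
        """Rescaling all integrals by c > 0 leaves relative values and
        classes unchanged; defined relative values lie in [0, 100]."""
        base = quantify_peaks(make_records(pcts, I0=200.0))
        scaled = quantify_peaks(make_records(pcts, I0=200.0 * scale))
        for p, q in zip(base.protons, scaled.protons):
            if p.relative_std_pct is None:
                assert q.relative_std_pct is None
                continue
            assert q.relative_std_pct == pytest.approx(
                p.relative_std_pct, abs=1e-9
            )
            assert 0.0 <= p.relative_std_pct <= 100.0
            assert p.epitope_class == q.epitope_class
        if base.binder:
            assert max(p.relative_std_pct for p in base) == 100.0


class TestEpitopeClasses:
    @pytest.mark.parametrize(
        "value,is_max,expected",
        [
            (85.0, False, EpitopeClass.DARK_RED),
            (50.0, False, EpitopeClass.ORANGE),
            (30.0, False, EpitopeClass.LIME),
            (100.0, True, EpitopeClass.MAX),
            (80.0, False, EpitopeClass.ORANGE),   # strict "over 80"
            (40.0, False, EpitopeClass.LIME),     # strict "over 40"
            (0.0, False, EpitopeClass.LIME),
        ],
    )
    def test_colour_thresholds(self, value, is_max, expected):
        assert classify_epitope(value, is_max) is expected

    @pytest.mark.parametrize("value", [-0.1, 100.1])
    def test_out_of_range_rejected(self, value):
        with pytest.raises(ValueError):
            classify_epitope(value, False)


class TestAbsoluteBins:
    @pytest.mark.parametrize(
        "value,expected",
        [
            (1.2, AbsBin.GT_1),
            (0.95, AbsBin.R10_09),  # rounds to 1.0
            (0.15, AbsBin.LT_02),
            (0.25, AbsBin.R04_02),  # rounds half away from zero to 0.3
            (-0.3, AbsBin.LT_02),   # artefact values fall below the floor
        ],
    )
    def test_reference_values(self, value, expected):
        assert bin_absolute(value) is expected

    def test_grid_sweep_matches_piecewise_oracle(self):
        """0.01-step sweep against an independent piecewise assignment."""
        for v in np.arange(-0.5, 1.55, 0.01):
            v = round(float(v), 2)
            assert bin_absolute(v).value == bin_oracle(v), v

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            bin_absolute(float("nan"))


class TestBinderCall:
    def test_all_zero_is_nonbinder(self):
        prof = quantify_peaks(make_records([0.0, 0.0, 0.0]))
        assert prof.binder is False

    def test_one_signal_above_floor_is_binder(self):
        prof = quantify_peaks(make_records([1.0, 0.0]))
        assert prof.binder is True

    def test_exactly_at_floor_is_nonbinder(self):
        prof = quantify_peaks(make_records([0.05, 0.05]),
                              noise_floor_pct=0.05)
        assert detect_binding(prof) is False

    def test_negative_floor_rejected(self):
        prof = quantify_peaks(make_records([1.0]))
        with pytest.raises(ValueError):
            detect_binding(prof, noise_floor_pct=-1.0)

    def test_below_floor_protons_of_a_binder_are_classed_below_floor(self):
        prof = quantify_peaks(make_records([1.0, 0.01]))
        assert prof.proton("H2").epitope_class is EpitopeClass.BELOW_FLOOR


class TestBinCounts:
    def test_single_compound_counts(self):
        prof = quantify_peaks(make_records([1.2, 0.3, 0.3, 0.1]))
        table = count_by_bin([prof])
        row = table.loc["c1"]
        assert row[">1"] == 1 and row["0.4-0.2"] == 2 and row["<0.2"] == 1
        assert row.sum() == 4

    def test_empty_profile_set(self):
        assert count_by_bin([]).empty

    def test_row_sums_conserve_above_floor_protons(self, panel13):
        profiles = [quantify_peaks(c.records) for c in panel13]
        table = count_by_bin(profiles)
        for prof in profiles:
            expected = sum(
                p.absolute_std_pct > prof.noise_floor_pct for p in prof
            )
            assert table.loc[prof.compound_id].sum() == expected

    def test_panel_has_exactly_one_empty_row(self, panel13):
        profiles = [quantify_peaks(c.records) for c in panel13]
        table = count_by_bin(profiles)
        assert (table.sum(axis=1) == 0).sum() == 1


class TestPeakTableIO:
    def test_round_trip(self, tmp_path):
        records = make_records([0.5, 1.0])
        path = tmp_path / "peaks.csv"
        write_peak_table(records, path)
        back = read_peak_table(path)
        assert back == records

    def test_comment_lines_skipped(self, tmp_path):
        path = tmp_path / "peaks.csv"
        path.write_text(
            "# comment\ncompound_id,proton_label,shift_ppm,I0,Isat,"
            "saturation_time_s\nc1,H1,7.2,100,99,2.94\n"
        )
        assert len(read_peak_table(path)) == 1

    def test_bad_row_names_the_location(self, tmp_path):
        path = tmp_path / "peaks.csv"
        path.write_text(
            "compound_id,proton_label,shift_ppm,I0,Isat,saturation_time_s\n"
            "c1,H1,7.2,100,bad,2.94\n"
        )
        with pytest.raises(ValueError, match="row 0"):
            read_peak_table(path)

    def test_missing_column_rejected(self, tmp_path):
        path = tmp_path / "peaks.csv"
        path.write_text("compound_id,proton_label\nc1,H1\n")
        with pytest.raises(ValueError, match="missing columns"):
            read_peak_table(path)


class TestQuantifyValidation:
    def test_duplicate_proton_labels_rejected(self):
        records = make_records([0.5]) + make_records([0.6])
        with pytest.raises(ValueError, match="duplicate"):
            quantify_peaks(records)

    def test_mixed_compounds_rejected(self):
        records = make_records([0.5], compound="a") + make_records(
            [0.6], compound="b"
        )
        records[1] = PeakRecord("b", "H2", 7.0, 100, 99, 2.94)
        with pytest.raises(ValueError, match="mixes compounds"):
            quantify_peaks(records)

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            quantify_peaks([])
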