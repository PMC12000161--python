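"""Slope angles and the 12-contrast battery for apparent asperities."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from chelamorph import (
    DigitProfile,
    apply_battery,
    battery_table,
    build_battery,
    replicate_consistency,
    slope_angles,
    smoothed_surface,
    species_summary,
)
from chelamorph.contrasts import CONTRAST_CENTRES, CONTRAST_LABELS, SlopeVector
from chelamorph.profile_model import N_STATIONS


def profile_from_heights(y, l2m=170.0, taxon="t", ind="i"):
    return DigitProfile(taxon, ind, np.linspace(0, l2m, N_STATIONS), np.asarray(y, float))


def slope_vector(phi9):
    phi = np.zeros(17)
    phi[: len(phi9)] = phi9
    return SlopeVector("t", "i", g=np.tan(np.radians(phi)), phi=phi, c=np.zeros(16))


class TestSlopeAngles:
    def test_flat_profile_gives_zero_angles(self):
        s = slope_angles(profile_from_heights(np.zeros(N_STATIONS)))
        assert s.phi.shape == (17,)
        assert np.allclose(s.phi, 0.0)

    def test_unit_slope_gives_45_degrees(self):
        x = np.linspace(0, 170, N_STATIONS)
        s = slope_angles(profile_from_heights(x.copy()))
        assert np.allclose(s.phi, 45.0)

    def test_dimensions_17_angles_16_accelerations(self, rng):
        y = rng.normal(0, 5, N_STATIONS)
        y[0] = 0
        s = slope_angles(profile_from_heights(y))
        assert s.phi.shape == (17,) and s.g.shape == (17,) and s.c.shape == (16,)
        assert np.all(np.abs(s.phi) < 90)

    def test_sign_convention(self):
        y = np.zeros(N_STATIONS)
        y[1] = 5.0  # rises then falls posteriorly
        s = slope_angles(profile_from_heights(y))
        assert s.phi[0] > 0 and s.phi[1] < 0


class TestBatteryStructure:
    def test_twelve_labelled_rows_with_printed_centres(self):
        b = build_battery()
        assert b.labels == CONTRAST_LABELS
        assert b.coefficients.shape == (12, 9)
        assert tuple(b.centres) == CONTRAST_CENTRES

    def test_row_sums_of_squares(self):
        b = build_battery()
        ssq = (b.raw_coefficients**2).sum(axis=1)
        assert np.allclose(ssq, [18] + [12] * 4 + [6] * 7)
        # scaled rows all have unit-free comparable norm sqrt(ssq)*scale = sqrt(ssq/ssq)=1
        assert np.allclose((b.coefficients**2).sum(axis=1), 1.0)

    def test_rows_annihilate_constants(self):
        b = build_battery()
        assert np.allclose(b.raw_coefficients.sum(axis=1), 0.0)

    def test_b_rows_lie_in_span_of_c_rows(self):
        # structural regression: each 6-point module row is a combination of
        # adjacent atomic rows — the binomial identity b_k = c_k + 3c_{k+1}
        # + 3c_{k+2} + c_{k+3} on the unscaled coefficients
        raw = build_battery().raw_coefficients
        c_rows = raw[5:]
        for k in range(4):
            expected = c_rows[k] + 3 * c_rows[k + 1] + 3 * c_rows[k + 2] + c_rows[k + 3]
            assert np.allclose(raw[1 + k], expected)
            coef, res, *_ = np.linalg.lstsq(c_rows.T, raw[1 + k], rcond=None)
            assert np.allclose(c_rows.T @ coef, raw[1 + k], atol=1e-10)


class TestApplyBattery:
    def test_zero_and_constant_phi_give_zero_scalars(self):
        for phi in (np.zeros(9), np.full(9, 17.3)):
            scalars, valid = apply_battery(slope_vector(phi))
            assert np.allclose(scalars, 0.0, atol=1e-12)
            assert valid

    def test_breasting_pattern_matches_hand_dot_product(self):
        scalars, _ = apply_battery(slope_vector([0, 0, 0, 10, 10, 10, 0, 0, 0]))
        assert scalars[0] == pytest.approx(-60 / np.sqrt(18))
        assert scalars[0] < 0  # a raised middle = "peak" sign

    def test_short_tooth_row_flagged(self):
        _, valid = apply_battery(slope_vector(np.zeros(9)), e_index=9)
        assert not valid
        _, valid = apply_battery(slope_vector(np.zeros(9)), e_index=10)
        assert valid

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(shift=st.floats(-30, 30), phi=st.lists(st.floats(-60, 60), min_size=9, max_size=9))
    def test_constant_shift_invariance(self, shift, phi):
        s0, _ = apply_battery(slope_vector(np.array(phi)))
        s1, _ = apply_battery(slope_vector(np.array(phi) + shift))
        assert np.allclose(s0, s1, atol=1e-9)

    def test_scale_invariance_under_joint_um_rescale(self, rng):
        y = rng.normal(0, 8, N_STATIONS)
        y[0] = 0
        p1 = profile_from_heights(y, l2m=170.0)
        p2 = profile_from_heights(y * 3.7, l2m=170.0 * 3.7)
        s1, _ = apply_battery(slope_angles(p1))
        s2, _ = apply_battery(slope_angles(p2))
        assert np.allclose(s1, s2, atol=1e-10)


def individual_frame(values_by_taxon, contrast="a", centre=6.0):
    rows = []
    for taxon, vals in values_by_taxon.items():
        for i, v in enumerate(vals):
            rows.append(
                dict(taxon=taxon, individual=f"{taxon}{i}", contrast=contrast,
                     centre=centre, value=float(v), valid=True)
            )
    return pd.DataFrame(rows)


class TestSpeciesSummary:
    def test_identical_zero_scalars_all_level(self):
        tab = species_summary(individual_frame({"X": [0, 0, 0], "Y": [0, 0, 0]}))
        assert set(tab.species["call"]) == {"level"}

    def test_strong_negative_mean_called_peak(self):
        tab = species_summary(individual_frame({"X": [-50, -51, -49], "Y": [0.1, -0.1, 0.0]}))
        call = tab.species.set_index("taxon")["call"]
        assert call["X"] == "peak" and call["Y"] == "level"

    def test_band_matches_pooled_variance_oracle(self):
        vals = {"X": [1.0, 2.0, 3.0], "Y": [2.0, 4.0, 6.0]}
        tab = species_summary(individual_frame(vals))
        # textbook pooled residual: SS = 2 + 8 over df = 4
        s_pooled = np.sqrt((2.0 + 8.0) / 4.0)
        expected = stats.t.ppf(0.975, 4) * s_pooled / np.sqrt(3)
        assert np.allclose(tab.species["band"], expected)

    def test_single_individual_taxon_flagged_level(self):
        tab = species_summary(individual_frame({"X": [5.0]}))
        row = tab.species.iloc[0]
        assert row["call"] == "level"
        assert "band_undefined" in row["flags"]
        assert np.isnan(row["band"])

    def test_bonferroni_widens_bands(self):
        frame = individual_frame({"X": [1.0, 2.0, 3.0], "Y": [2.0, 4.0, 6.0]})
        plain = species_summary(frame).species["band"].iloc[0]
        wide = species_summary(frame, bonferroni=True).species["band"].iloc[0]
        assert wide > plain


class TestReplicateConsistency:
    def make_table(self, x2_vals):
        frames = [
            individual_frame({"X1": [-50, -51, -49], "X2": x2_vals, "Y": [0.1, -0.1, 0.0]}, contrast=c, centre=cc)
            for c, cc in zip(CONTRAST_LABELS, CONTRAST_CENTRES)
        ]
        return species_summary(pd.concat(frames, ignore_index=True))

    def test_identical_replicates_no_flags(self):
        tab = self.make_table([-50, -51, -49])
        assert replicate_consistency(tab, [("X1", "X2")]) == {}

    def test_straddling_replicates_flagged_everywhere(self):
        tab = self.make_table([50, 51, 49])  # opposite side of the band
        flags = replicate_consistency(tab, [("X1", "X2")])
        assert set(flags) == set(CONTRAST_LABELS)
        assert flags["a"] == [("X1", "X2")]

    def test_empty_pair_list_and_unknown_label(self):
        tab = self.make_table([-50, -51, -49])
        assert replicate_consistency(tab, []) == {}
        with pytest.raises(KeyError):
            replicate_consistency(tab, [("X1", "nope")])


class TestSmoothedSurface:
    def table_from_means(self, means):
        frames = [
            individual_frame({"X": [m - 0.5, m + 0.5]}, contrast=c, centre=cc)
            for (c, cc), m in zip(zip(CONTRAST_LABELS, CONTRAST_CENTRES), means)
        ]
        return species_summary(pd.concat(frames, ignore_index=True))

    def test_constant_sequence_stays_constant(self):
        sm = smoothed_surface(self.table_from_means([3.0] * 12))
        assert np.allclose(sm["value"], 3.0)

    def test_pair_average(self):
        means = np.zeros(12)
        tab = self.table_from_means(means)
        sm = smoothed_surface(tab)
        assert np.allclose(sm["value"], 0.0)
        # ordering is by centre: first smoothed point averages the two
        # lowest-centred contrasts (c1 at x3, c2 at x4)
        x_tab = tab.species.sort_values(["centre", "contrast"])
        assert x_tab["contrast"].iloc[0] == "c1"

    def test_alternating_sequence_cancels(self):
        sm = smoothed_surface(self.table_from_means([7, -7] * 6))
        ordered = sm[sm.taxon == "X"].sort_values("centre")
        # wherever consecutive centre-ordered means alternate exactly,
        # the two-point average vanishes
        vals = self.table_from_means([7, -7] * 6).species.sort_values(["centre", "contrast"])["mean"].to_numpy()
        expected = (vals[:-1] + vals[1:]) / 2
        assert np.allclose(ordered["value"].to_numpy(), expected)


class TestBatteryTable:
    def test_tidy_frame_shape_and_peak_detection(self, rng):
        y_flat = np.zeros(N_STATIONS)
        profs = []
        for i in range(5):
            noise = rng.normal(0, 0.05, N_STATIONS)
            noise[0] = 0
            profs.append(profile_from_heights(y_flat + noise, taxon="F", ind=f"f{i}"))
            y_peak = y_flat.copy()
            y_peak[4] = 6.0  # tooth at station 5
            profs.append(profile_from_heights(y_peak + noise, taxon="P", ind=f"p{i}"))
        frame = battery_table(profs)
        assert len(frame) == 10 * 12
        tab = species_summary(frame)
        call = tab.species.set_index(["taxon", "contrast"])["call"]
        assert call[("P", "c3")] == "peak"  # c3 is centred at station 5
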