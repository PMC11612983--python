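"""Single-cell metrics: SI, PFs, OI, classification, COM, DI."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from placecode1d import (
    AnalysisConfig,
    MetricUndefinedError,
    center_of_mass,
    classify_cell,
    com_distance,
    di_timecourse,
    directionality_index,
    make_grid,
    normalized_firing_rate,
    overlap_index,
    pair_trials,
    place_field_size,
    select_pyramidal,
    spatial_information,
)
from placecode1d.preprocess import LapSegment

GRID = make_grid(170.0, 3.0)
CFG = AnalysisConfig()

positive_profiles = arrays(float, 57, elements=st.floats(min_value=0.01, max_value=30.0))


def brute_force_oi(pr: np.ndarray, pl: np.ndarray) -> float:
    """Literal elementwise evaluation of 2*sum(min)/sum(sum) on area-normalised profiles."""
    n = len(pr)
    pr = n * pr / sum(pr)
    pl = n * pl / sum(pl)
    num = 2 * sum(min(a, b) for a, b in zip(pr, pl))
    den = sum(a + b for a, b in zip(pr, pl))
    return num / den


def direct_si(rate: np.ndarray, occ: np.ndarray) -> float:
    """Literal per-bin evaluation of sum Pi (Ri/R) log2(Ri/R)."""
    keep = occ > 0
    p = occ[keep] / occ[keep].sum()
    r = rate[keep]
    mean = sum(p * r)
    total = 0.0
    for pi, ri in zip(p, r):
        if ri > 0:
            total += pi * (ri / mean) * np.log2(ri / mean)
    return total


class TestSpatialInformation:
    def test_uniform_rate_uniform_occupancy_is_zero(self):
        assert spatial_information(np.full(57, 2.0), np.full(57, 1.0)) == pytest.approx(0.0)

    @pytest.mark.parametrize("n_bins", [2, 8, 57])
    def test_single_bin_firing_equals_log2_n(self, n_bins):
        rate = np.zeros(n_bins)
        rate[n_bins // 2] = 3.0
        si = spatial_information(rate, np.ones(n_bins))
        assert si == pytest.approx(np.log2(n_bins), abs=1e-12)

    def test_two_bin_hand_evaluation(self):
        # rates (2, 0), P = (1/2, 1/2): R = 1, SI = 0.5*2*log2(2) = 1 bit/spike
        assert spatial_information(np.array([2.0, 0.0]), np.array([1.0, 1.0])) == pytest.approx(1.0)

    def test_silent_cell_undefined(self):
        with pytest.raises(MetricUndefinedError):
            spatial_information(np.zeros(57), np.ones(57))

    @given(positive_profiles, positive_profiles)
    def test_matches_direct_formula_and_is_nonnegative(self, rate, occ):
        si = spatial_information(rate, occ)
        assert si >= -1e-12
        assert si == pytest.approx(direct_si(rate, occ), abs=1e-12)

    def test_zero_occupancy_bins_excluded(self):
        rate = np.array([5.0, 1.0, 1.0])
        occ = np.array([0.0, 1.0, 1.0])  # the 5 Hz bin is never visited
        assert spatial_information(rate, occ) == pytest.approx(0.0)

    def test_bias_correction_subtracts_first_order_term(self):
        rate = np.zeros(8)
        rate[3] = 2.0
        raw = spatial_information(rate, np.ones(8))
        corrected = spatial_information(rate, np.ones(8), n_spikes=100, bias_correction=True)
        assert raw - corrected == pytest.approx(7 / (2 * 100 * np.log(2)))


class TestPlaceFieldSize:
    def test_single_bin_delta_is_one_bin_wide(self):
        prof = np.zeros(57)
        prof[20] = 4.0
        assert place_field_size(prof, 3.0) == pytest.approx(3.0)

    def test_flat_profile_covers_whole_track(self):
        assert place_field_size(np.full(57, 1.0), 3.0) == pytest.approx(171.0)

    def test_discretized_gaussian_matches_analytic_width(self):
        """sigma = 9 cm: width at 20% of peak is 2*9*sqrt(2 ln 5) = 32.3 cm."""
        centers = GRID.centers
        prof = 5.0 * np.exp(-((centers - 85.5) ** 2) / (2 * 81.0))
        assert 30.0 <= place_field_size(prof, 3.0) <= 36.0
        assert place_field_size(prof, 3.0, interpolate=True) == pytest.approx(32.3, abs=1.0)

    def test_contiguity_stops_at_first_gap(self):
        prof = np.zeros(57)
        prof[10:13] = [2.0, 4.0, 2.0]
        prof[20] = 3.0  # disconnected secondary bump is not part of the field
        assert place_field_size(prof, 3.0) == pytest.approx(9.0)

    def test_monotone_under_field_widening(self):
        centers = GRID.centers
        widths = []
        for sigma in [4.0, 6.0, 9.0, 12.0, 15.0]:
            prof = np.exp(-((centers - 85.5) ** 2) / (2 * sigma**2))
            widths.append(place_field_size(prof, 3.0))
        assert all(a <= b for a, b in zip(widths, widths[1:]))

    def test_silent_profile_undefined(self):
        with pytest.raises(MetricUndefinedError):
            place_field_size(np.zeros(57), 3.0)


class TestOverlapIndex:
    def test_identical_profiles_give_one(self, rng):
        prof = rng.uniform(0.1, 5.0, 57)
        assert overlap_index(prof, prof) == pytest.approx(1.0)

    def test_disjoint_supports_give_zero(self):
        a = np.zeros(57)
        b = np.zeros(57)
        a[:20] = 1.0
        b[30:50] = 1.0
        assert overlap_index(a, b) == 0.0

    def test_uniform_57_versus_uniform_19(self):
        """Brute-force value: sub-uniform over 19 of 57 bins overlaps 1/3."""
        a = np.full(57, 1.0)
        b = np.zeros(57)
        b[10:29] = 1.0
        assert overlap_index(a, b) == pytest.approx(1 / 3, abs=1e-12)
        assert overlap_index(a, b) == pytest.approx(brute_force_oi(a, b), abs=1e-12)

    @given(positive_profiles, positive_profiles, st.floats(min_value=0.1, max_value=50))
    def test_symmetric_scale_invariant_and_matches_brute_force(self, a, b, scale):
        oi = overlap_index(a, b)
        assert 0.0 <= oi <= 1.0 + 1e-12
        assert oi == pytest.approx(overlap_index(b, a), abs=1e-12)
        assert oi == pytest.approx(overlap_index(scale * a, b), abs=1e-12)
        assert oi == pytest.approx(brute_force_oi(a, b), abs=1e-12)


class TestClassification:
    def _gauss(self, center_cm, peak):
        return peak * np.exp(-((GRID.centers - center_cm) ** 2) / (2 * 36.0))

    def test_bidirectional_overlapping(self):
        right = self._gauss(80, 2.0)
        left = self._gauss(84, 1.5)
        cls = classify_cell(right, left, CFG, GRID)
        assert cls.label == "OBC"
        assert cls.oi > 0.4

    def test_bidirectional_non_overlapping(self):
        cls = classify_cell(self._gauss(40, 2.0), self._gauss(130, 1.5), CFG, GRID)
        assert cls.label == "NOBC"
        assert cls.oi <= 0.4
        assert cls.merged_label == "UC"

    def test_single_peak_is_unidirectional(self):
        cls = classify_cell(self._gauss(80, 2.0), self._gauss(80, 0.8), CFG, GRID)
        assert cls.label == "UC"

    def test_sub_threshold_peaks_are_non_classified(self):
        cls = classify_cell(self._gauss(80, 1.0), self._gauss(90, 0.9), CFG, GRID)
        assert cls.label == "NCC"

    def test_reward_zone_peak_is_non_classified(self):
        narrow = 3.0 * np.exp(-((GRID.centers - 3.0) ** 2) / (2 * 9.0))
        cls = classify_cell(narrow, 0.9 * narrow, CFG, GRID)
        assert cls.label == "NCC"
        assert "reward" in cls.reason


class TestCentreOfMass:
    def test_symmetric_profile_centres_mid_track(self):
        centers = GRID.centers
        prof = np.exp(-((centers - 85.5) ** 2) / (2 * 100.0))
        assert center_of_mass(prof, 3.0) == pytest.approx(85.5)

    def test_delta_at_bin_10(self):
        prof = np.zeros(57)
        prof[10] = 1.0
        assert center_of_mass(prof, 3.0) == pytest.approx(31.5)

    def test_com_distance_of_deltas(self):
        a = np.zeros(57)
        b = np.zeros(57)
        a[10] = 2.0
        b[40] = 5.0
        assert com_distance(a, b, 3.0) == pytest.approx(90.0)
        assert com_distance(b, a, 3.0) == pytest.approx(90.0)
        assert com_distance(a, a, 3.0) == 0.0


class TestDirectionalityIndex:
    @pytest.mark.parametrize(
        "a,b,expected", [(2.0, 2.0, 0.0), (3.0, 0.0, 1.0), (3.0, 1.0, 0.5)]
    )
    def test_examples(self, a, b, expected):
        assert directionality_index(a, b) == pytest.approx(expected)

    def test_both_zero_undefined(self):
        with pytest.raises(MetricUndefinedError):
            directionality_index(0.0, 0.0)

    @given(
        st.floats(min_value=0, max_value=50),
        st.floats(min_value=0.01, max_value=50),
        st.floats(min_value=0.1, max_value=10),
    )
    def test_symmetric_and_scale_invariant(self, a, b, c):
        di = directionality_index(a, b)
        assert 0.0 <= di <= 1.0
        assert di == pytest.approx(directionality_index(b, a))
        assert di == pytest.approx(directionality_index(c * a, c * b))


def _alternating_laps(n):
    return [
        LapSegment(i, float(i), float(i) + 0.9, 1 if i % 2 == 0 else -1)
        for i in range(n)
    ]


class TestDITimecourse:
    def test_trial_pairing_drops_odd_trailing_lap(self):
        laps = _alternating_laps(7)
        assert pair_trials(laps) == [(0, 1), (2, 3), (4, 5)]

    def test_pairing_skips_same_direction_neighbours(self):
        laps = [
            LapSegment(0, 0.0, 0.9, 1),
            LapSegment(1, 1.0, 1.9, 1),  # direction repeats after a dropped excursion
            LapSegment(2, 2.0, 2.9, -1),
            LapSegment(3, 3.0, 3.9, 1),
        ]
        assert pair_trials(laps) == [(1, 2)]

    def test_perfectly_directional_cells_give_constant_one(self):
        laps = _alternating_laps(8)
        rates = np.tile([4.0, 0.0], (3, 4))
        tc = di_timecourse(rates, laps)
        np.testing.assert_allclose(tc.mean, 1.0)
        np.testing.assert_allclose(tc.first3, 1.0)

    def test_population_mean_of_two_cells(self):
        laps = _alternating_laps(2)
        rates = np.array([[3.0, 2.0], [4.0, 1.0]])  # DIs 0.2 and 0.6
        tc = di_timecourse(rates, laps)
        assert tc.mean[0] == pytest.approx(0.4)
        assert tc.n[0] == 2

    def test_silent_trials_excluded_from_population_mean(self):
        laps = _alternating_laps(2)
        rates = np.array([[0.0, 0.0], [4.0, 1.0]])
        tc = di_timecourse(rates, laps)
        assert tc.mean[0] == pytest.approx(0.6)
        assert tc.n[0] == 1

    def test_growing_asymmetry_recovers_positive_slope(self):
        """Cells whose rate asymmetry grows across 10 trials yield a rising
        population DI in nearly every seeded replicate."""
        laps = _alternating_laps(20)
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            cells = []
            for _ in range(25):
                base = rng.uniform(2, 6)
                lap_rates = []
                for trial in range(10):
                    asym = 0.05 * trial  # linear growth of directional contrast
                    ra = rng.poisson(base * (1 + asym) * 10) / 10.0
                    rb = rng.poisson(base * (1 - asym) * 10) / 10.0
                    lap_rates += [ra, rb]
                cells.append(lap_rates)
            tc = di_timecourse(np.array(cells), laps)
            slope = np.polyfit(np.arange(10), tc.mean, 1)[0]
            hits += slope > 0
        assert hits >= 95


class TestNormalizedRate:
    def test_scaling_across_sessions(self):
        out = normalized_firing_rate(
            {"familiar": np.array([1.0, 2.0, 4.0]), "novel": np.array([2.0, 3.0])}
        )
        np.testing.assert_allclose(out["familiar"], [0.25, 0.5, 1.0])
        np.testing.assert_allclose(out["novel"], [0.5, 0.75])

    def test_constant_rate_maps_to_ones(self):
        out = normalized_firing_rate({"familiar": np.full(4, 2.2), "novel": np.full(3, 2.2)})
        for v in out.values():
            np.testing.assert_allclose(v, 1.0)

    def test_silent_cell_undefined(self):
        with pytest.raises(MetricUndefinedError):
            normalized_firing_rate({"familiar": np.zeros(3), "novel": np.zeros(3)})


class TestPyramidalSelection:
    def test_band_is_closed_interval(self):
        rates = np.array([0.05, 0.1, 1.0, 6.0, 6.01])
        np.testing.assert_array_equal(
            select_pyramidal(rates), [False, True, True, True, False]
        )
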