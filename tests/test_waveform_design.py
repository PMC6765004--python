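"""Transmit-scheme designers: delay laws, pseudo-inverse two-foci, interlacing."""

import numpy as np
import pytest

from uslr import (
    Medium,
    TransmitScheme,
    USLRParams,
    even_elements,
    focus_delays,
    hamming_scheme,
    interlace,
    lateral_profile_of_scheme,
    make_array,
    odd_elements,
    two_foci_scheme,
    uslr_scheme,
)
from uslr.waveform_design import load_scheme, odd_element_mask, restrict


class TestFocusDelays:
    def test_simultaneous_arrival(self, array, medium):
        """delay_i + R_i/c is the same instant for every element."""
        scheme = focus_delays(array, (0.0, 60.0), medium)
        r = np.hypot(array.element_x, 60.0)
        arrival = scheme.delays + r / medium.c
        np.testing.assert_allclose(arrival, arrival[0], rtol=1e-12)
        assert scheme.delays.min() == 0.0
        assert np.all(scheme.apodization == 1.0)

    def test_on_axis_symmetry_and_center_max(self, array, medium):
        scheme = focus_delays(array, (0.0, 60.0), medium)
        d = scheme.delays
        np.testing.assert_allclose(d, d[::-1], rtol=1e-12)
        # central elements are closest to the focus -> largest delay
        assert d.argmax() in (array.n_elements // 2 - 1, array.n_elements // 2)

    def test_edge_delay_matches_hand_geometry(self, array, medium):
        """Edge element at x = 13.97 mm: its extra path over the nearest
        element to the axis fixes the center-edge delay difference."""
        scheme = focus_delays(array, (0.0, 60.0), medium)
        r_edge = np.hypot(13.97, 60.0)
        r_center = np.hypot(0.11, 60.0)
        expected = (r_edge - r_center) / 1.54
        measured = scheme.delays.max() - scheme.delays.min()
        assert measured == pytest.approx(expected, rel=1e-9)

    def test_two_element_equidistant_focus(self, medium):
        arr2 = make_array(2, 0.5, 3.0)
        scheme = focus_delays(arr2, (0.0, 40.0), medium)
        np.testing.assert_allclose(scheme.delays, 0.0, atol=1e-15)

    def test_nonpositive_depth_rejected(self, array, medium):
        with pytest.raises(ValueError):
            focus_delays(array, (0.0, 0.0), medium)


class TestTwoFoci:
    def test_degenerate_zero_separation_is_single_focus(self, array, medium):
        """Coincident foci reduce to the single-focus law modulo one
        carrier period, with near-uniform apodization."""
        single = focus_delays(array, (0.0, 60.0), medium)
        two = two_foci_scheme(array, 60.0, 0.0, medium)
        period = 1.0 / array.center_frequency
        diff = single.delays - two.delays
        np.testing.assert_allclose(diff - np.round(diff / period) * period,
                                   0.0, atol=1e-9)
        assert two.apodization.min() > 0.95

    def test_apodization_symmetric(self, array, medium):
        two = two_foci_scheme(array, 60.0, 2.85, medium)
        np.testing.assert_allclose(two.apodization, two.apodization[::-1],
                                   rtol=1e-9)
        assert two.apodization.max() == pytest.approx(1.0)
        assert np.all(two.delays >= 0)

    def test_swapping_foci_is_invariant(self, array, medium):
        from uslr import multi_foci_scheme
        f = np.array([[-1.4, 60.0], [1.4, 60.0]])
        a = multi_foci_scheme(array, f, medium)
        b = multi_foci_scheme(array, f[::-1], medium)
        np.testing.assert_allclose(a.delays, b.delays, atol=1e-12)
        np.testing.assert_allclose(a.apodization, b.apodization, rtol=1e-12)

    def test_field_peaks_near_both_foci(self, array, medium, pulse):
        """The simulated field of the dx = 2.85 mm design shows its two
        strongest lateral peaks close to +/- 1.425 mm."""
        from scipy.signal import find_peaks
        two = two_foci_scheme(array, 60.0, 2.85, medium)
        prof = lateral_profile_of_scheme(array, two, pulse, 60.0, medium,
                                         half_span=3.0)
        pk, _ = find_peaks(prof.level, prominence=1.0)
        top = pk[np.argsort(prof.level[pk])[-2:]]
        pos = np.sort(prof.x[top])
        # interference of the overlapping beams pulls the envelope peaks
        # slightly inward of the geometric foci
        np.testing.assert_allclose(pos, [-1.425, 1.425], atol=0.08)


class TestHamming:
    def test_window_endpoints_and_peak(self, medium):
        arr = make_array(129, 0.22, 3.0)   # odd count: exact center sample
        scheme = hamming_scheme(arr, (0.0, 60.0), medium)
        a = scheme.apodization
        assert a[0] == pytest.approx(0.08)
        assert a[-1] == pytest.approx(0.08)
        assert a[64] == pytest.approx(1.0)

    def test_window_symmetric_delays_unchanged(self, array, medium):
        scheme = hamming_scheme(array, (0.0, 60.0), medium)
        single = focus_delays(array, (0.0, 60.0), medium)
        np.testing.assert_allclose(scheme.apodization,
                                   scheme.apodization[::-1], rtol=1e-12)
        np.testing.assert_array_equal(scheme.delays, single.delays)


class TestInterlace:
    def test_odd_elements_carry_single_focus(self, array, medium):
        single = focus_delays(array, (0.0, 60.0), medium)
        two = two_foci_scheme(array, 60.0, 3.0, medium)
        out = interlace(single, two, 0.35)
        odd = odd_element_mask(array.n_elements)
        np.testing.assert_array_equal(out.delays[odd], single.delays[odd])
        np.testing.assert_array_equal(out.apodization[odd],
                                      single.apodization[odd])
        np.testing.assert_array_equal(out.delays[~odd], two.delays[~odd])
        np.testing.assert_allclose(out.apodization[~odd],
                                   0.35 * two.apodization[~odd], rtol=1e-12)

    def test_active_element_counts(self, array, medium):
        single = focus_delays(array, (0.0, 60.0), medium)
        two = two_foci_scheme(array, 60.0, 3.0, medium)
        n = array.n_elements
        assert interlace(single, two, 0.35).n_active == n
        assert interlace(single, two, 0.0).n_active == int(np.ceil(n / 2))

    def test_mismatched_lengths_rejected(self, array, medium):
        single = focus_delays(array, (0.0, 60.0), medium)
        small = focus_delays(make_array(64, 0.22, 3.0), (0.0, 60.0), medium)
        with pytest.raises(ValueError):
            interlace(single, small, 0.3)

    def test_uslr_params_validation(self):
        with pytest.raises(ValueError):
            USLRParams(-0.1, 3.0)
        with pytest.raises(ValueError):
            USLRParams(0.3, 0.0)


class TestSchemeContainer:
    def test_masks_and_subsets(self, array, medium):
        scheme = focus_delays(array, (0.0, 60.0), medium)
        odd = odd_elements(scheme)
        even = even_elements(scheme)
        assert odd.n_active + even.n_active == array.n_elements
        assert np.all(odd.apodization * even.apodization == 0)
        with pytest.raises(ValueError):
            restrict(scheme, np.ones(3, bool))

    def test_validation(self):
        with pytest.raises(ValueError):
            TransmitScheme(delays=np.array([0.0, -1.0]),
                           apodization=np.ones(2))
        with pytest.raises(ValueError):
            TransmitScheme(delays=np.zeros(3), apodization=np.ones(2))

    def test_csv_round_trip(self, array, medium, tmp_path):
        scheme = uslr_scheme(array, 60.0, USLRParams(0.37, 3.0), medium)
        path = tmp_path / "scheme.csv"
        scheme.to_csv(path)
        back = load_scheme(path)
        np.testing.assert_allclose(back.delays, scheme.delays, atol=1e-12)
        np.testing.assert_allclose(back.apodization, scheme.apodization,
                                   atol=1e-12)
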