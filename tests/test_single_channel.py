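"""Amplitude histograms, Gaussian mixtures, Po, conductance, I/V analysis."""

import math

import numpy as np
import pytest

from vactrace.errors import InvalidInputError, NoReversalError
from vactrace.gating import GatingModel, simulate_constant_voltage
from vactrace.single_channel import (
    AmplitudeHistogram,
    IVCurve,
    IVPoint,
    Peak,
    PeakMixture,
    analyze_trace,
    build_amplitude_histogram,
    build_iv_curve,
    chord_conductance_extreme_voltage,
    estimate_reversal,
    fit_peak_mixture,
    open_probability,
    unitary_current,
)


def _analytic_histogram(weights, centres, sd, n_samples=200_000, bin_width=0.1):
    """Noise-free histogram drawn exactly from a Gaussian mixture density."""
    lo = min(centres) - 5 * sd
    hi = max(centres) + 5 * sd
    edges = np.arange(math.floor(lo / bin_width) * bin_width,
                      hi + bin_width, bin_width)
    x = 0.5 * (edges[:-1] + edges[1:])
    dens = sum(wk * np.exp(-0.5 * ((x - ck) / sd) ** 2) / (sd * math.sqrt(2 * math.pi))
               for wk, ck in zip(weights, centres))
    counts = np.round(dens * n_samples * bin_width).astype(int)
    return AmplitudeHistogram(edges, counts)


class TestHistogram:
    def test_constant_trace_single_bin(self):
        h = build_amplitude_histogram(np.full(1000, 5.03), 0.1)
        assert h.total_samples == 1000
        assert (h.counts > 0).sum() == 1

    def test_counts_conserved_exactly(self, rng):
        samples = rng.normal(0, 1, 34567)
        h = build_amplitude_histogram(samples, 0.1)
        assert h.total_samples == samples.size

    def test_concatenation_adds_histograms(self, rng):
        a = rng.normal(0, 0.4, 5000)
        b = rng.normal(-6.0, 0.4, 3000)
        ha = build_amplitude_histogram(a, 0.1)
        hb = build_amplitude_histogram(b, 0.1)
        hab = build_amplitude_histogram(np.concatenate([a, b]), 0.1)
        # bins are anchored to an absolute grid, so edges can be aligned
        summed = {}
        for h in (ha, hb):
            for c, n in zip(np.round(h.bin_centres_pA, 6), h.counts):
                summed[c] = summed.get(c, 0) + int(n)
        for c, n in zip(np.round(hab.bin_centres_pA, 6), hab.counts):
            assert summed.get(c, 0) == int(n)

    def test_two_level_trace_is_bimodal(self):
        m = GatingModel.from_open_probability(
            0.35, unitary_conductance_pS=75.0)  # i = -6 pA at -80 mV
        tr = simulate_constant_voltage(m, -80.0, 10.0, seed=4)
        h = build_amplitude_histogram(tr, 0.1)
        x, c = h.bin_centres_pA, h.counts
        near0 = c[np.abs(x) < 0.5].max()
        near6 = c[np.abs(x + 6.0) < 0.5].max()
        between = c[(x > -4.0) & (x < -2.0)].max()
        assert near0 > 10 * between and near6 > 10 * between

    def test_empty_trace_rejected(self):
        with pytest.raises(InvalidInputError):
            build_amplitude_histogram(np.array([]), 0.1)

    def test_bad_bin_width_rejected(self, rng):
        with pytest.raises(InvalidInputError):
            build_amplitude_histogram(rng.normal(size=10), 0.0)


class TestPeakMixtureFit:
    def test_single_gaussian_gives_baseline_only(self):
        h = _analytic_histogram([1.0], [0.2], 0.4)
        mix = fit_peak_mixture(h, max_channels=4)
        assert mix.n_channels == 0
        assert mix.peaks[0].centre_pA == pytest.approx(0.2, abs=0.05)

    def test_two_component_areas_recovered(self):
        # closed/open occupancies 0.75/0.25 at 0 and -6.4 pA, sd 0.4
        h = _analytic_histogram([0.75, 0.25], [0.0, -6.4], 0.4)
        mix = fit_peak_mixture(h, max_channels=4, current_direction=-1)
        assert len(mix.peaks) == 2
        total = sum(p.area for p in mix.peaks)
        assert mix.peaks[0].area / total == pytest.approx(0.75, rel=0.02)
        assert mix.peaks[1].area / total == pytest.approx(0.25, rel=0.02)
        assert mix.peaks[1].centre_pA == pytest.approx(-6.4, abs=0.05)

    def test_four_channel_patch_five_equally_spaced_levels(self):
        # binomial occupancies of 4 independent channels at Po = 0.21
        po, n, i = 0.21, 4, 2.91
        weights = [math.comb(n, k) * po**k * (1 - po)**(n - k) for k in range(n + 1)]
        h = _analytic_histogram(weights, [k * i for k in range(n + 1)], 0.3,
                                n_samples=400_000)
        mix = fit_peak_mixture(h, max_channels=6, current_direction=+1)
        assert mix.n_channels == 4
        spacings = np.diff(mix.centres_pA)
        assert np.allclose(spacings, i, atol=0.1)

    def test_degenerate_histogram_rejected(self):
        h = AmplitudeHistogram(np.array([0.0, 0.1]), np.array([5]))
        with pytest.raises(InvalidInputError):
            fit_peak_mixture(h)


class TestOpenProbability:
    def _mix(self, areas, spacing=-6.0):
        peaks = tuple(Peak(k * spacing, 0.3, a) for k, a in enumerate(areas))
        return PeakMixture(peaks=peaks)

    def test_all_area_in_baseline_gives_zero(self):
        mix = self._mix([1000.0, 1e-9])
        assert open_probability(mix, 1) == pytest.approx(0.0, abs=1e-9)

    def test_single_channel_quarter_open(self):
        mix = self._mix([0.75, 0.25])
        assert open_probability(mix, 1) == pytest.approx(0.25)

    def test_npo_per_channel_weighting(self):
        # 2 channels: occupancies 0.25/0.5/0.25 -> NPo = 1, Po = 0.5
        mix = self._mix([0.25, 0.5, 0.25])
        assert open_probability(mix, 2) == pytest.approx(0.5)

    def test_invariant_under_area_rescaling(self):
        a = self._mix([0.6, 0.3, 0.1])
        b = self._mix([6000.0, 3000.0, 1000.0])
        assert open_probability(a) == pytest.approx(open_probability(b), rel=1e-12)

    def test_inconsistent_channel_count_rejected(self):
        mix = self._mix([0.5, 0.3, 0.2])
        with pytest.raises(InvalidInputError):
            open_probability(mix, 1)


class TestUnitaryCurrentAndConductance:
    def test_two_peak_spacing(self):
        mix = PeakMixture(peaks=(Peak(0.0, 0.3, 1.0), Peak(-6.42, 0.3, 0.5)))
        assert unitary_current(mix) == pytest.approx(-6.42)

    def test_equal_spacing_mean(self):
        mix = PeakMixture(peaks=(Peak(0.0, 0.3, 1.0), Peak(-6.0, 0.3, 0.5),
                                 Peak(-12.0, 0.3, 0.2)))
        assert unitary_current(mix) == pytest.approx(-6.0)

    def test_single_peak_undefined(self):
        mix = PeakMixture(peaks=(Peak(0.0, 0.3, 1.0),))
        with pytest.raises(InvalidInputError):
            unitary_current(mix)

    def test_chord_conductance_printed_value(self):
        # -6.42 pA at -74 mV -> 86.75 pS
        assert chord_conductance_extreme_voltage(-74.0, -6.42) == pytest.approx(
            86.75, abs=0.05)

    def test_chord_conductance_from_amplitude(self):
        # 8.07 pA single-channel amplitude at 80 mV magnitude -> ~100.9 pS
        assert chord_conductance_extreme_voltage(80.0, 8.07) == pytest.approx(
            100.9, abs=0.1)

    def test_ratio_invariance(self):
        g1 = chord_conductance_extreme_voltage(-74.0, -6.42)
        g2 = chord_conductance_extreme_voltage(-148.0, -12.84)
        assert g1 == pytest.approx(g2, rel=1e-12)

    def test_extreme_voltage_point_selected(self):
        iv = IVCurve((IVPoint(-80.0, -7.64), IVPoint(-40.0, -3.0),
                      IVPoint(20.0, 0.5)))
        assert chord_conductance_extreme_voltage(iv) == pytest.approx(
            1000.0 * -7.64 / -80.0)

    def test_zero_voltage_rejected(self):
        with pytest.raises(InvalidInputError):
            chord_conductance_extreme_voltage(0.0, 1.0)


class TestIVCurve:
    def test_build_records_dispersion(self):
        iv = build_iv_curve([(-80.0, [-7.5, -7.7, -7.6]), (-40.0, [-3.6, -3.4])])
        assert iv.points[0].n == 3
        assert iv.points[0].current_pA == pytest.approx(-7.6)
        assert iv.points[0].sd_pA == pytest.approx(0.1, rel=1e-6)

    def test_duplicate_voltage_rejected(self):
        with pytest.raises(InvalidInputError):
            IVCurve((IVPoint(-80.0, -7.6), IVPoint(-80.0, -7.5)))

    def test_empty_rejected(self):
        with pytest.raises(InvalidInputError):
            IVCurve(())

    def test_symmetric_interpolation_gives_zero(self):
        iv = IVCurve((IVPoint(-20.0, -2.0), IVPoint(20.0, 2.0)))
        assert estimate_reversal(iv) == pytest.approx(0.0, abs=1e-12)

    def test_no_sign_change_errors(self):
        iv = IVCurve((IVPoint(-20.0, 1.0), IVPoint(20.0, 2.0)))
        with pytest.raises(NoReversalError):
            estimate_reversal(iv)

    def test_crossing_nearest_zero_preferred(self):
        iv = IVCurve((IVPoint(-60.0, -1.0), IVPoint(-40.0, 1.0),
                      IVPoint(-20.0, -1.0), IVPoint(0.0, 1.0)))
        assert estimate_reversal(iv) == pytest.approx(-10.0)

    def test_reversal_recovered_from_simulated_channel(self):
        # ohmic channel with E_rev = -34.9 mV; mean current NPo*g*(V-E)
        # crosses zero at E_rev
        m = GatingModel.from_open_probability(
            0.3, unitary_conductance_pS=95.5, reversal_mV=-34.9)
        points = []
        for v in (-75.0, -55.0, -35.0, -15.0, 5.0):
            tr = simulate_constant_voltage(m, v, 8.0, seed=int(100 + v))
            points.append((v, float(tr.samples_pA.mean())))
        e = estimate_reversal(build_iv_curve(points))
        assert e == pytest.approx(-34.9, abs=1.0)


class TestEndToEnd:
    def test_po_stable_under_bin_width_halving(self):
        m = GatingModel.from_open_probability(0.39, unitary_conductance_pS=95.5)
        tr = simulate_constant_voltage(m, -80.0, 20.0, seed=1)
        po_coarse = analyze_trace(tr, bin_width_pA=0.1).open_probability
        po_fine = analyze_trace(tr, bin_width_pA=0.05).open_probability
        assert abs(po_coarse - po_fine) < 0.02

    def test_chord_conductance_consistent_across_voltages(self):
        # an ohmic simulated channel shows its true g at every voltage,
        # not just the most extreme one
        m = GatingModel.from_open_probability(0.35, unitary_conductance_pS=95.5)
        for v in (-80.0, -60.0, -40.0):
            tr = simulate_constant_voltage(m, v, 15.0, seed=int(-v))
            res = analyze_trace(tr)
            assert res.conductance_pS == pytest.approx(95.5, rel=0.05)
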