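"""Bond-order derivatives, event detection, crossings and spans."""

import numpy as np
import pytest

import ircmech as m
from ircmech.errors import InsufficientDataError, IrcmechError


def _series(curves, pairs=None):
    curves = np.atleast_2d(np.asarray(curves, float))
    pairs = pairs or [(1, k + 2) for k in range(curves.shape[0])]
    return m.BondOrderSeries(pairs=pairs, values=curves)


def _logistic(xi, mu, s):
    return 1.0 / (1.0 + np.exp(-(xi - mu) / s))


class TestDerivative:
    def test_constant_series_has_zero_derivative(self):
        xi = np.linspace(0, 1, 11)
        d = m.bond_order_derivative(_series(np.full((1, 11), 0.7)), xi)
        np.testing.assert_allclose(d, 0.0, atol=1e-12)

    def test_linear_series_exact_on_nonuniform_grid(self):
        xi = np.array([0.0, 0.1, 0.35, 0.5, 0.9, 1.3])
        d = m.bond_order_derivative(_series(0.3 * xi), xi)
        np.testing.assert_allclose(d[0, 1:-1], 0.3, atol=1e-12)

    def test_logistic_peak_at_midpoint(self):
        xi = np.arange(0, 10.0001, 0.1)
        b = _logistic(xi, 5.0, 0.5)
        d = m.bond_order_derivative(_series(b), xi)
        peak_xi = xi[np.argmax(d[0])]
        assert abs(peak_xi - 5.0) <= 0.1  # within one grid step

    def test_non_monotone_xi_rejected(self):
        xi = np.array([0.0, 0.2, 0.1])
        with pytest.raises(IrcmechError):
            m.bond_order_derivative(_series([[0.1, 0.2, 0.3]]), xi)

    def test_integral_closure_linear_exact(self):
        xi = np.linspace(0, 2, 21)
        b = 0.4 * xi
        d = m.bond_order_derivative(_series(b), xi)
        integral = np.trapezoid(d[0], xi)
        assert integral == pytest.approx(b[-1] - b[0], abs=1e-10)

    def test_integral_closure_logistic_within_two_percent(self):
        xi = np.linspace(0, 10, 101)
        b = 0.9 * _logistic(xi, 5.0, 0.4)
        d = m.bond_order_derivative(_series(b), xi)
        integral = np.trapezoid(d[0], xi)
        net = b[-1] - b[0]
        assert abs(integral - net) <= 0.02 * abs(net)


class TestEvents:
    def test_single_logistic_rise_is_one_forming_event(self):
        xi = np.linspace(0, 10, 101)
        s = _series(0.8 * _logistic(xi, 4.0, 0.3))
        events = m.detect_bond_events(s, xi)
        assert len(events) == 1
        e = events[0]
        assert e.direction == "forming"
        assert e.net_change > 0 and e.peak_height > 0
        assert abs(e.xi_peak - 4.0) <= 0.1

    def test_flat_series_has_no_events(self):
        xi = np.linspace(0, 1, 21)
        assert m.detect_bond_events(_series(np.full((1, 21), 0.5)), xi) == []

    def test_break_then_reform_ordered_events(self):
        xi = np.linspace(0, 10, 201)
        b = 0.9 - 0.85 * _logistic(xi, 3.0, 0.2) \
            + 0.85 * _logistic(xi, 7.0, 0.2)
        events = m.detect_bond_events(_series(b), xi)
        assert [e.direction for e in events] == ["breaking", "forming"]
        assert abs(events[0].xi_peak - 3.0) <= 0.05
        assert abs(events[1].xi_peak - 7.0) <= 0.05

    def test_planted_event_recovery_under_noise(self):
        # four events, midpoints well separated, sigma = 0.01
        xi = np.linspace(0, 1, 201)
        step = xi[1] - xi[0]
        mus = [0.15, 0.40, 0.65, 0.85]
        spec = m.SyntheticPathSpec(
            n_atoms=14, n_frames=201, xi_range=(0.0, 1.0),
            events=tuple(
                m.LogisticEventSpec((1, 3 + k), 0.9 if k % 2 else 0.0,
                                    0.0 if k % 2 else 0.9, mu=mu, s=0.02)
                for k, mu in enumerate(mus)),
            profile=m.ProfileSpec((
                m.StationaryTarget(0.0, 0.0, "reactant"),
                m.StationaryTarget(1.0, 1.0, "product"))),
            noise=m.NoiseSpec(bond_order=0.01),
            seed=11,
        )
        _, bonds, _, truth = m.generate_path(spec)
        events = m.detect_bond_events(bonds, xi,
                                      smooth=("moving_poly", 5, 2))
        # planted events are full transitions; noise wobbles may appear as
        # strengthening/weakening but never clear the net-change bar
        events = [e for e in events
                  if e.direction in ("forming", "breaking")]
        assert len(events) == len(mus)
        recovered = sorted(e.xi_peak for e in events)
        for got, mu in zip(recovered, sorted(mus)):
            assert abs(got - mu) <= step + 1e-12

    def test_smoothing_does_not_shift_symmetric_peak(self):
        xi = np.linspace(0, 10, 101)
        s = _series(0.9 * _logistic(xi, 5.0, 0.4))
        raw = m.detect_bond_events(s, xi)
        smoothed = m.detect_bond_events(s, xi, smooth=("moving_poly", 5, 2))
        assert abs(raw[0].xi_peak - smoothed[0].xi_peak) <= 0.1

    def test_small_net_change_is_strengthening(self):
        xi = np.linspace(0, 10, 101)
        s = _series(0.30 + 0.05 * _logistic(xi, 5.0, 0.3))
        events = m.detect_bond_events(s, xi)
        assert [e.direction for e in events] == ["strengthening"]


class TestCrossings:
    def test_symmetric_logistics_cross_at_half(self):
        xi = np.linspace(0, 10, 101)
        up = _logistic(xi, 5.0, 0.5)
        down = 1.0 - up
        s = _series(np.vstack([up, down]), pairs=[(1, 2), (1, 3)])
        crossings = m.find_crossings(s, xi, (1, 2), (1, 3))
        assert len(crossings) == 1
        xc, bc = crossings[0]
        assert xc == pytest.approx(5.0, abs=1e-6)
        assert bc == pytest.approx(0.5, abs=1e-6)

    def test_parallel_curves_never_cross(self):
        xi = np.linspace(0, 1, 11)
        s = _series(np.vstack([np.full(11, 0.2), np.full(11, 0.8)]),
                    pairs=[(1, 2), (1, 3)])
        assert m.find_crossings(s, xi, (1, 2), (1, 3)) == []

    def test_interpolated_crossing_matches_dense_grid(self):
        # refinement oracle: evaluate the same analytic curves on a grid
        # 100x denser and compare the located crossing
        def curves(x):
            return 0.9 * _logistic(x, 4.3, 0.7), 0.8 - 0.6 * _logistic(x, 5.1, 0.9)

        xi = np.linspace(0, 10, 101)
        a, b = curves(xi)
        s = _series(np.vstack([a, b]), pairs=[(1, 2), (1, 3)])
        (xc, bc), = m.find_crossings(s, xi, (1, 2), (1, 3))
        xi_dense = np.linspace(0, 10, 10001)
        ad, bd = curves(xi_dense)
        sd = _series(np.vstack([ad, bd]), pairs=[(1, 2), (1, 3)])
        (xc_d, bc_d), = m.find_crossings(sd, xi_dense, (1, 2), (1, 3))
        assert abs(xc - xc_d) < 1e-2
        assert abs(bc - bc_d) < 1e-3


class TestSpan:
    def _event(self, xi_peak):
        return m.BondEvent(pair=(1, 2), direction="forming",
                           xi_peak=xi_peak, peak_height=1.0, width=0.1,
                           net_change=0.5)

    def test_identical_peaks_are_synchronous(self):
        span, _ = m.synchronicity_span(
            [self._event(3.0), self._event(3.0)], np.linspace(0, 10, 11))
        assert span == 0.0

    def test_span_arithmetic(self):
        span, offsets = m.synchronicity_span(
            [self._event(2.0), self._event(8.0)], np.linspace(0, 10, 11))
        assert span == pytest.approx(0.6)
        assert offsets[(0, 1)] == pytest.approx(6.0)

    def test_needs_two_events(self):
        with pytest.raises(InsufficientDataError):
            m.synchronicity_span([self._event(1.0)], np.linspace(0, 1, 5))

    def test_asynchronous_proton_transfer_span_recovered(self, base_bundle):
        # the stepwise preset plants its two proton transfers 0.05 apart
        path, bonds, _, truth = base_bundle
        events = m.detect_bond_events(bonds, path.xi,
                                      smooth=("moving_poly", 5, 2))
        proton = [e for e in events
                  if e.pair in {(8, 9), (5, 9), (3, 10), (10, 11)}]
        span, _ = m.synchronicity_span(proton, path.xi)
        step = path.xi[1] - path.xi[0]
        assert abs(span - truth.proton_transfer_span) <= step + 1e-12
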