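"""Full-system simulation, burst features, Hopf detection."""

import numpy as np
import pytest

from lactoburst import ModelParams, extract_features, full_hopf_slice, \
    rhs_full, simulate
from lactoburst.desing import find_ordinary_singularities
from lactoburst.simulate import (
    FeatureConfig, InsufficientDataError, simulate_features,
)


class TestSimulate:
    def test_converges_to_depolarized_equilibrium(self, p):
        q = p.replace(gK=0.1, Cm=10.0)
        tr = simulate(q, t_end=30000, transient=20000)
        bf = extract_features(tr)
        assert bf.regime == "steady"
        eq = find_ordinary_singularities(q)[0]
        assert tr.V[-1] == pytest.approx(eq.V, abs=1e-4)
        end = (tr.V[-1], tr.n[-1], tr.c[-1])
        assert np.max(np.abs(rhs_full(end, q))) < 1e-8

    def test_calcium_stays_nonnegative(self, p):
        for gK in (0.1, 4.0, 5.1):
            tr = simulate(p.replace(gK=gK, Cm=10.0), t_end=25000,
                          transient=0.0)
            assert np.all(tr.c >= 0.0)

    def test_time_grid_strictly_increasing(self, p):
        tr = simulate(p, t_end=22000, transient=20000)
        assert np.all(np.diff(tr.t) > 0)
        assert np.all(np.isfinite(tr.V))

    def test_invalid_capacitance_rejected(self, p):
        with pytest.raises(ValueError):
            simulate(p.replace(Cm=0.0))


class TestRegimes:
    def test_spiking_at_gK_51(self, p):
        bf = simulate_features(p.replace(gK=5.1, Cm=10.0))
        assert bf.regime == "spiking"
        assert bf.spikes_per_burst == 1

    def test_bursting_at_gK_4(self, p):
        bf = simulate_features(p.replace(gK=4.0, Cm=10.0))
        assert bf.regime == "bursting"
        assert bf.spikes_per_burst >= 2

    def test_delta_sign_predicts_regime_near_singular_limit(self, p,
                                                            orbit_gk4,
                                                            orbit_gk51):
        # delta > 0 at gK = 4 and < 0 at gK = 5.1 must map onto bursting
        # and spiking of the full system at Cm = 0.5 pF
        assert orbit_gk4.delta > 0 and orbit_gk51.delta < 0
        bf4 = simulate_features(p.replace(gK=4.0, Cm=0.5), dt=0.25)
        bf51 = simulate_features(p.replace(gK=5.1, Cm=0.5), dt=0.25)
        assert bf4.regime == "bursting"
        assert bf51.regime == "spiking"

    def test_three_spikes_per_burst(self, p):
        bf = simulate_features(p.replace(gK=6.0, gBK=1.0, Cm=5.0))
        assert bf.regime == "bursting"
        assert bf.spikes_per_burst == 3

    def test_small_oscillation_amplitude_grows_with_Cm(self, p):
        # the canard-induced small oscillations vanish in the singular
        # limit and grow with Cm (checked as monotonicity only); measured
        # on the interior of the active phase, away from the jump-up
        # transient at its start and the exit oscillation at its end
        from scipy.signal import find_peaks

        amps = []
        for Cm in (0.001, 0.1, 2.0):
            tr = simulate(p.replace(gK=4.0, Cm=Cm), t_end=40000,
                          transient=20000, dt=0.25)
            active = tr.V > -40.0
            edges = np.flatnonzero(np.diff(active.astype(int)))
            bounds = np.r_[0, edges + 1, active.size]
            runs = [(a, b) for a, b in zip(bounds[:-1], bounds[1:])
                    if active[a]]
            a, b = max(runs, key=lambda r: r[1] - r[0])
            peaks, props = find_peaks(tr.V[a:b], prominence=1e-8)
            pos = peaks / (b - a)
            proms = props["prominences"]
            keep = (proms < 15.0) & (pos > 0.15) & (pos < 0.85)
            amps.append(float(np.max(proms[keep])) if keep.any() else 0.0)
        assert amps[0] < amps[1] < amps[2]

    def test_insufficient_periods_raise(self, p):
        tr = simulate(p.replace(gK=4.0, Cm=10.0), t_end=21000, transient=20000)
        with pytest.raises(InsufficientDataError):
            extract_features(tr)


class TestFeatureConfigThresholds:
    def test_visible_spike_floor_is_configurable(self, p):
        tr = simulate(p.replace(gK=6.0, gBK=1.0, Cm=5.0))
        strict = extract_features(tr, FeatureConfig(spike_prominence=0.5))
        loose = extract_features(tr, FeatureConfig(spike_prominence=1e-3))
        assert strict.spikes_per_burst == loose.spikes_per_burst == 3


class TestHopf:
    def test_overlaps_transcritical_at_small_Cm(self, p):
        from lactoburst import find_TR

        hb = full_hopf_slice(p, "gK", (0.1, 1.5), Cm=0.01)
        tr1 = find_TR(p, "gK", (0.1, 1.0)).gK
        assert abs(hb - tr1) / tr1 < 0.01

    def test_moves_smoothly_with_Cm(self, p):
        hbs = [full_hopf_slice(p, "gK", (0.1, 1.5), Cm=Cm)
               for Cm in (0.01, 1.0, 5.0)]
        assert hbs[0] < hbs[1] < hbs[2] < 1.0
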