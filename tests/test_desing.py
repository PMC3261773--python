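"""Desingularized flow: singularities, classification, mu and s_max."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lactoburst import ModelParams, F_of, desing_rhs, desing_jacobian, \
    find_folded_singularities, find_ordinary_singularities, mu_of, s_max_of
from lactoburst.desing import Singularity, classify_2x2
from lactoburst.manifold import f_and_partials, fold_voltages, n_of


def _by_curve(sings, curve):
    return [s for s in sings if s.on_curve == curve]


class TestVectorField:
    def test_dc_dtau_vanishes_on_folds(self, p):
        for Vf in fold_voltages(p):
            for c in (0.1, 0.4, 1.0):
                assert desing_rhs(Vf, c, p)[1] == pytest.approx(0.0, abs=1e-10)

    def test_dc_dtau_vanishes_on_CN1(self, p):
        for s in find_ordinary_singularities(p):
            assert desing_rhs(s.V, s.c, p)[1] == pytest.approx(0.0, abs=1e-12)

    def test_F_vanishes_at_singularities(self, p):
        for s in find_ordinary_singularities(p) + find_folded_singularities(p):
            assert abs(F_of(s.V, s.c, p)) < 1e-9

    def test_matches_reduced_system_scaling(self, p, rng):
        # the desingularized field is the reduced field (independent
        # term-by-term evaluation here) times -df/dV
        from lactoburst.model import boltzmann, currents, hill2_d1

        Vm, Vp = fold_voltages(p)
        for _ in range(10):
            V = rng.uniform(Vp + 1.0, 20.0)
            c = rng.uniform(0.05, 1.2)
            n = n_of(c, V, p)
            _, fV, fc_, fn = f_and_partials(V, c, n, p)
            ICa = currents(V, n, c, p)[0]
            H = p.fc * (p.alpha * ICa + p.kc * c)
            ninf = boltzmann(V, p.vn, p.sn)
            reduced_V = (-H * fc_ + (ninf - n) / p.taun * fn) / (-fV)
            reduced_c = -H
            dV, dc = desing_rhs(V, c, p)
            assert dV == pytest.approx(reduced_V * (-fV), rel=1e-10)
            assert dc == pytest.approx(reduced_c * (-fV), rel=1e-10)

    def test_jacobian_matches_finite_differences(self, p, rng):
        h = 1e-6
        for _ in range(10):
            V = rng.uniform(-70.0, 20.0)
            c = rng.uniform(0.05, 1.2)
            J = desing_jacobian(V, c, p)
            num = np.empty((2, 2))
            num[:, 0] = (np.array(desing_rhs(V + h, c, p))
                         - np.array(desing_rhs(V - h, c, p))) / (2 * h)
            num[:, 1] = (np.array(desing_rhs(V, c + h, p))
                         - np.array(desing_rhs(V, c - h, p))) / (2 * h)
            assert np.allclose(J, num, rtol=1e-5, atol=1e-10)


class TestOrdinarySingularities:
    def test_depolarized_stable_state_at_low_gK(self, p):
        sings = find_ordinary_singularities(p.replace(gK=0.1))
        assert len(sings) == 1
        s = sings[0]
        assert s.classification == "stable_node"
        assert s.V > fold_voltages(p)[1]   # upper sheet (depolarized)

    def test_saddle_at_default_gK(self, p):
        sings = find_ordinary_singularities(p)   # gK = 4
        assert [s.classification for s in sings] == ["saddle"]

    def test_hyperpolarized_stable_node_at_high_gK(self, p):
        sings = find_ordinary_singularities(p.replace(gK=150.0))
        assert len(sings) == 1
        s = sings[0]
        assert s.classification == "stable_node"
        assert s.V < fold_voltages(p)[0]   # bottom sheet

    def test_equilibrium_conditions_equal_full_rhs_zero(self, p):
        from lactoburst import rhs_full

        for s in find_ordinary_singularities(p):
            assert np.max(np.abs(rhs_full((s.V, s.n, s.c), p))) < 1e-9


class TestFoldedSingularities:
    def test_residuals_below_1e9(self, p):
        for s in find_folded_singularities(p):
            f, fV, _, _ = f_and_partials(s.V, s.c, s.n, p)
            assert abs(f) < 1e-9
            assert abs(fV) < 1e-9
            assert abs(F_of(s.V, s.c, p)) < 1e-9

    def test_node_and_saddle_on_upper_fold_at_default(self, p):
        up = _by_curve(find_folded_singularities(p), "L_plus")
        kinds = sorted(s.classification for s in up)
        assert kinds == ["folded_node", "folded_saddle"]
        lo = _by_curve(find_folded_singularities(p), "L_minus")
        assert {s.classification for s in lo} == {"folded_focus"}

    def test_two_saddles_on_upper_fold_below_first_transcritical(self, p):
        up = _by_curve(find_folded_singularities(p.replace(gK=0.3)), "L_plus")
        assert [s.classification for s in up] == ["folded_saddle"] * 2
        lo = _by_curve(find_folded_singularities(p.replace(gK=0.3)), "L_minus")
        assert [s.classification for s in lo] == ["folded_focus"] * 2

    def test_none_on_upper_fold_past_saddle_node(self, p):
        up = _by_curve(find_folded_singularities(p.replace(gK=8.0)), "L_plus")
        assert up == []

    def test_roots_agree_with_dense_scan_oracle(self, p):
        Vf = fold_voltages(p)[1]
        c_grid = np.linspace(-1.0, 1.4, 100001)
        F = F_of(Vf, c_grid, p)
        sign_changes = np.nonzero(np.sign(F[:-1]) * np.sign(F[1:]) < 0)[0]
        found = sorted(s.c for s in _by_curve(find_folded_singularities(p),
                                              "L_plus"))
        assert len(found) == len(sign_changes)
        for c, i in zip(found, sign_changes):
            assert c_grid[i] <= c <= c_grid[i + 1]


class TestMuAndSmax:
    def test_folded_node_mu_in_unit_interval(self, p):
        fn = [s for s in find_folded_singularities(p)
              if s.classification == "folded_node"][0]
        assert 0.0 < mu_of(fn) <= 1.0

    def test_folded_saddle_mu_negative(self, p):
        fs = [s for s in find_folded_singularities(p)
              if s.classification == "folded_saddle"][0]
        assert mu_of(fs) < 0.0

    def test_mu_undefined_for_focus(self, p):
        ff = [s for s in find_folded_singularities(p)
              if s.classification == "folded_focus"][0]
        with pytest.raises(ValueError):
            mu_of(ff)

    def test_s_max_values(self):
        assert s_max_of(1.0) == 1
        assert s_max_of(0.07) == 7   # floor(1.07 / 0.14) = floor(7.64)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.floats(1e-4, 1.0), st.floats(1e-4, 1.0))
    def test_s_max_non_increasing(self, mu1, mu2):
        lo, hi = sorted((mu1, mu2))
        assert s_max_of(lo) >= s_max_of(hi)

    def test_s_max_domain(self):
        with pytest.raises(ValueError):
            s_max_of(0.0)
        with pytest.raises(ValueError):
            s_max_of(-0.2)


def test_classification_labels_cover_fig5_sequence(p):
    """Qualitative singularity inventory along the gK axis at gBK = 0.4."""
    seq = {}
    for gK in (0.1, 4.0, 43.1, 129.2, 150.0):
        q = p.replace(gK=gK)
        ords = find_ordinary_singularities(q)
        folded = find_folded_singularities(q)
        seq[gK] = (sorted(s.classification for s in ords),
                   sorted(s.classification for s in folded))
    assert seq[0.1][0] == ["stable_node"]
    assert "folded_node" in seq[4.0][1] and "folded_saddle" in seq[4.0][1]
    assert seq[129.2][0] == ["saddle"]
    assert seq[150.0] == (["stable_node"], [])
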