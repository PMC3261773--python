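"""Critical manifold: fold voltages, n-parameterization, projections."""

import numpy as np
import pytest

from lactoburst import ModelParams, f_and_partials, fold_voltages, n_of, \
    project_to_sheet
from lactoburst.manifold import (
    ProjectionError, fold_curves, n_on_fold, phi, phi_d1,
)

from conftest import random_states


class TestPartials:
    def test_fn_vanishes_at_potassium_reversal(self, p):
        assert f_and_partials(p.VK, 0.3, 0.2, p)[3] == 0.0

    def test_f_zero_on_manifold(self, p, rng):
        for c in rng.uniform(0.02, 1.2, 10):
            for V in rng.uniform(-70, 40, 5):
                n = n_of(c, V, p)
                assert abs(f_and_partials(V, c, n, p)[0]) < 1e-10

    def test_partials_match_finite_differences(self, p, rng):
        h = 1e-6
        for V, n, c in random_states(rng, 10):
            f0, fV, fc, fn = f_and_partials(V, c, n, p)
            num_V = (f_and_partials(V + h, c, n, p)[0]
                     - f_and_partials(V - h, c, n, p)[0]) / (2 * h)
            num_c = (f_and_partials(V, c + h, n, p)[0]
                     - f_and_partials(V, c - h, n, p)[0]) / (2 * h)
            num_n = (f_and_partials(V, c, n + h, p)[0]
                     - f_and_partials(V, c, n - h, p)[0]) / (2 * h)
            assert fV == pytest.approx(num_V, rel=1e-6, abs=1e-7)
            assert fc == pytest.approx(num_c, rel=1e-6, abs=1e-7)
            assert fn == pytest.approx(num_n, rel=1e-6, abs=1e-7)

    def test_phi_derivative_matches_fd(self, p):
        h = 1e-6
        for V in (-60.0, -40.0, -25.0, -10.0):
            num = (phi(V + h, p) - phi(V - h, p)) / (2 * h)
            assert phi_d1(V, p) == pytest.approx(num, rel=1e-6)


class TestNOf:
    def test_monotone_decreasing_in_c_above_VK(self, p):
        c = np.linspace(0.01, 1.4, 100)
        for V in (-60.0, -30.0, 0.0):
            n = n_of(c, V, p)
            assert np.all(np.diff(n) < 0)

    def test_independent_of_c_without_SK_current(self, p):
        q = p.replace(gKCa=0.0)
        assert n_of(0.1, -30.0, q) == n_of(1.0, -30.0, q)

    def test_singular_at_potassium_reversal(self, p):
        with pytest.raises(ValueError):
            n_of(0.3, p.VK, p)


class TestFoldVoltages:
    def test_independent_of_gK(self, p):
        ref = fold_voltages(p)
        for gK in (0.1, 1.0, 50.0, 120.0):
            assert fold_voltages(p.replace(gK=gK)) == pytest.approx(ref)

    def test_absent_beyond_merge(self, p):
        assert fold_voltages(p.replace(gBK=32.2, gK=7.588)) is None

    def test_defining_property(self, p):
        for V in fold_voltages(p):
            for c in (0.1, 0.5, 1.0):
                n = n_on_fold(c, V, p)
                f, fV, _, _ = f_and_partials(V, c, n, p)
                assert abs(f) < 1e-9 and abs(fV) < 1e-9

    def test_single_transition_in_gBK(self, p):
        # exactly two folds below the merge value, zero above, one switch
        gbk = np.linspace(0.2, 35.0, 60)
        has = [fold_voltages(p.replace(gBK=g)) is not None for g in gbk]
        flips = sum(a != b for a, b in zip(has[:-1], has[1:]))
        assert flips == 1 and has[0] and not has[-1]

    def test_sheet_stability_signs(self, p):
        Vm, Vp = fold_voltages(p)
        for c in (0.1, 0.4, 0.9):
            for V, sign in ((Vm - 5, -1), (0.5 * (Vm + Vp), +1), (Vp + 5, -1)):
                fV = f_and_partials(V, c, n_of(c, V, p), p)[1]
                assert np.sign(fV) == sign


class TestProjection:
    def test_fold_point_projects_onto_PLminus(self, p):
        Vm, Vp = fold_voltages(p)
        c = 0.3
        n = n_on_fold(c, Vm, p)
        V = project_to_sheet(c, n, "upper", p)
        assert V > Vp
        f, fV, _, _ = f_and_partials(V, c, n, p)
        assert abs(f) < 1e-8 and fV < 0

    def test_idempotent_on_own_sheet(self, p):
        Vm, Vp = fold_voltages(p)
        c = 0.3
        V0 = Vp + 8.0
        n = n_of(c, V0, p)
        assert project_to_sheet(c, n, "upper", p) == pytest.approx(V0, abs=1e-8)

    def test_agrees_with_dense_grid_oracle(self, p, rng):
        Vm, Vp = fold_voltages(p)
        hits = 0
        for _ in range(20):
            c = rng.uniform(0.05, 1.0)
            n = rng.uniform(0.0, 0.3)
            grid = np.linspace(Vp, 45.0, 20001)
            f = f_and_partials(grid, c, n, p)[0]
            s = np.sign(f)
            idx = np.nonzero(s[:-1] * s[1:] < 0)[0]
            try:
                V = project_to_sheet(c, n, "upper", p)
            except ProjectionError:
                assert idx.size == 0
                continue
            hits += 1
            assert any(grid[i] <= V <= grid[i + 1] for i in idx)
        assert hits > 5   # the oracle comparison actually exercised roots

    def test_failure_off_sheet(self, p):
        with pytest.raises(ProjectionError):
            project_to_sheet(0.3, 0.9, "upper", p)   # n too high: no root


def test_fold_curves_csv_export(p):
    fc = fold_curves(p)
    df = fc.sample(np.linspace(0.0, 1.4, 21))
    assert set(df.columns) == {"c", "V", "n", "sheet_label"}
    assert set(df.sheet_label) == {"L-", "L+"}
    assert len(df) == 42
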