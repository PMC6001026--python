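import numpy as np
import pytest

import boundsharp as bs
from boundsharp.landscape import FPConfig


def quadratic_bowl(cx=1.5, cy=1.5, lam=1.0):
    def f(X, Y):
        return -lam * (X - cx), -lam * (Y - cy)

    return f


class TestSolver:
    def test_zero_drift_gives_uniform_density(self):
        cfg = FPConfig(D=0.01, domain=(2.0, 2.0), resolution=(60, 60))
        land = bs.solve_fokker_planck(
            None, None, cfg,
            drift_fn=lambda X, Y: (np.zeros_like(X), np.zeros_like(Y)),
        )
        assert np.max(np.abs(land.Pss - 0.25)) < 1e-8  # 1/area

    def test_ou_matches_gaussian_stationary_density(self):
        lam, D = 1.0, 0.005
        cfg = FPConfig(D=D, domain=(3.0, 3.0), resolution=(200, 200))
        land = bs.solve_fokker_planck(None, None, cfg, drift_fn=quadratic_bowl(lam=lam))
        xx, yy = np.meshgrid(land.x, land.y, indexing="ij")
        s2 = D / lam
        ana = np.exp(-((xx - 1.5) ** 2 + (yy - 1.5) ** 2) / (2 * s2)) / (2 * np.pi * s2)
        mask = ana >= 1e-4 * ana.max()
        rel = np.abs(land.Pss[mask] - ana[mask]) / ana[mask]
        assert rel.max() < 0.02

    def test_normalization(self, mrsa):
        cfg = FPConfig(D=0.005, resolution=(100, 100))
        land = bs.solve_fokker_planck(mrsa, 0.8, cfg)
        assert abs(land.Pss.sum() * land.dx * land.dy - 1.0) < 1e-8

    def test_deterministic_given_config(self, mrsa):
        cfg = FPConfig(D=0.005, resolution=(80, 80))
        a = bs.solve_fokker_planck(mrsa, 0.5, cfg)
        b = bs.solve_fokker_planck(mrsa, 0.5, cfg)
        assert np.array_equal(a.Pss, b.Pss)

    def test_symmetric_circuit_symmetric_landscape(self):
        from boundsharp.params import CircuitParams, ModelID

        p = CircuitParams(
            model_id=ModelID.MRSA, a=1.0, a1=0.1, b=0.7, A=1.0, R=0.6,
            k_deg=0.7, S=0.8, n=4,
        )
        cfg = FPConfig(D=0.005, domain=(3.0, 3.0), resolution=(120, 120))
        land = bs.solve_fokker_planck(p, 0.3, cfg)
        assert np.max(np.abs(land.U - land.U.T)) < 1e-4


class TestPotential:
    def test_uniform_density_constant_potential(self):
        cfg = FPConfig(D=0.01, domain=(2.0, 2.0), resolution=(60, 60))
        land = bs.solve_fokker_planck(
            None, None, cfg,
            drift_fn=lambda X, Y: (np.zeros_like(X), np.zeros_like(Y)),
        )
        assert np.ptp(land.U) < 1e-7

    def test_density_rescaling_shifts_potential_leaves_barriers(self):
        """U = -ln P: scaling P shifts U by a constant, so barrier
        heights (potential differences) are unchanged."""
        U = np.add.outer((np.linspace(-1, 1, 80) ** 2 - 1) ** 2,
                         np.linspace(0, 1, 60) ** 2)
        a, b = bs.find_attractors(U, min_depth=0.2)[:2]
        a2, b2 = bs.find_attractors(U + 3.7, min_depth=0.2)[:2]
        h1 = bs.barrier(U, a, b).height
        h2 = bs.barrier(U + 3.7, a2, b2).height  # P scaled by e^-3.7
        assert h1 == pytest.approx(h2, rel=1e-12)

    def test_ou_potential_curvature(self):
        """For the OU stationary density U(x)-U(0) = lam x^2 / (2D)."""
        lam, D = 1.0, 0.005
        cfg = FPConfig(D=D, domain=(3.0, 3.0), resolution=(200, 200))
        land = bs.solve_fokker_planck(None, None, cfg, drift_fn=quadratic_bowl(lam=lam))
        ic = np.argmin(np.abs(land.x - 1.5))
        dx_off = 12
        du = land.U[ic + dx_off, ic] - land.U[ic, ic]
        expected = lam * (
            (land.x[ic + dx_off] - 1.5) ** 2 - (land.x[ic] - 1.5) ** 2
        ) / (2 * D)
        assert du == pytest.approx(expected, rel=0.03)


class TestAttractors:
    def test_single_bowl_single_attractor(self):
        x = np.linspace(-1, 1, 101)
        U = np.add.outer(x**2, x**2)
        attrs = bs.find_attractors(U, min_depth=0.2)
        assert len(attrs) == 1
        assert attrs[0].ix == 50 and attrs[0].iy == 50

    def test_double_well_two_attractors(self):
        x = np.linspace(-1.6, 1.6, 161)
        y = np.linspace(-1.0, 1.0, 101)
        U = np.add.outer((x**2 - 1) ** 2, y**2)
        attrs = bs.find_attractors(U, min_depth=0.2, x=x, y=y)
        assert len(attrs) == 2
        xs = sorted(a.x for a in attrs)
        assert xs[0] == pytest.approx(-1.0, abs=0.03)
        assert xs[1] == pytest.approx(1.0, abs=0.03)

    def test_depth_filter_suppresses_shallow_minima(self):
        x = np.linspace(-1.6, 1.6, 161)
        y = np.linspace(-0.3, 0.3, 11)
        U = np.add.outer((x**2 - 1) ** 2, y**2)  # barrier height 1
        assert len(bs.find_attractors(U, min_depth=0.5)) == 2
        assert len(bs.find_attractors(U, min_depth=1.5)) == 1

    def test_mrsa_bimodal_density_matches_fixed_points(self, mrsa):
        """At M=0.5 the stationary density has two modes whose locations
        agree with the stable fixed points within 2 grid cells."""
        cfg = FPConfig(D=0.005, domain=(3.0, 3.0), resolution=(150, 150))
        land = bs.solve_fokker_planck(mrsa, 0.5, cfg)
        attrs = bs.find_attractors(land, min_depth=0.01)
        assert len(attrs) == 2
        stable = [f.state for f in bs.find_fixed_points(mrsa, 0.5) if f.is_stable]
        cell = land.dx
        for a in attrs:
            assert any(
                abs(a.x - s.X) <= 2 * cell and abs(a.y - s.Y) <= 2 * cell
                for s in stable
            )


class TestBarrier:
    def _double_well(self, tilt=0.0):
        x = np.linspace(-1.6, 1.6, 321)
        y = np.linspace(-0.5, 0.5, 41)
        U = np.add.outer((x**2 - 1) ** 2 + tilt * x, y**2)
        return U, x, y

    def test_symmetric_well_unit_barrier_both_ways(self):
        U, x, y = self._double_well()
        a, b = bs.find_attractors(U, min_depth=0.2, x=x, y=y)
        bar_ab = bs.barrier(U, a, b, x=x, y=y)
        bar_ba = bs.barrier(U, b, a, x=x, y=y)
        assert bar_ab.saddle_x == pytest.approx(0.0, abs=0.02)
        assert bar_ab.height == pytest.approx(1.0, rel=0.01)
        assert bar_ba.height == pytest.approx(1.0, rel=0.01)
        assert bar_ab.saddle_U == bar_ba.saddle_U

    def test_tilted_well_asymmetric_barriers(self):
        U, x, y = self._double_well(tilt=0.3)
        attrs = bs.find_attractors(U, min_depth=0.2, x=x, y=y)
        left = min(attrs, key=lambda a: a.x)
        right = max(attrs, key=lambda a: a.x)
        from_deep = bs.barrier(U, left, right, x=x, y=y).height
        from_shallow = bs.barrier(U, right, left, x=x, y=y).height
        # +0.3x tilt deepens the left well, so escaping it is harder
        assert from_shallow < from_deep

    def test_identical_attractors_rejected(self):
        U = np.add.outer(np.linspace(-1, 1, 31) ** 2, np.linspace(-1, 1, 31) ** 2)
        a = bs.find_attractors(U, min_depth=0.1)[0]
        with pytest.raises(ValueError):
            bs.barrier(U, a, a)

    def test_mrsa_barrier_decreases_with_morphogen(self, mrsa):
        cfg = FPConfig(D=0.005, resolution=(120, 120))
        heights = []
        for m in (0.6, 0.7, 0.8):
            land = bs.solve_fokker_planck(mrsa, m, cfg)
            attrs = bs.find_attractors(land, min_depth=0.01)
            xa = [a for a in attrs if a.x > a.y][0]
            ya = [a for a in attrs if a.y > a.x][0]
            heights.append(bs.barrier(land, xa, ya).height)
        assert heights[0] > heights[1] > heights[2]
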