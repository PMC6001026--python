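import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import boundsharp as bs
from boundsharp.params import CircuitParams, GeneState, ModelID


class TestDrift:
    def test_zero_state_zero_morphogen_gives_basal_rates(self, mrsa):
        """All Hill terms vanish at the origin, leaving the basal synthesis."""
        dx, dy = bs.drift(mrsa, (0.0, 0.0), 0.0)
        assert dx == pytest.approx(mrsa.a * mrsa.b / mrsa.A)
        assert dy == pytest.approx(mrsa.a * mrsa.b)

    def test_half_saturation_at_threshold(self, mrsa):
        """At X = S the self-activation Hill term equals exactly 1/2."""
        S = mrsa.S
        dx, _ = bs.drift(mrsa, (S, 0.0), 0.0)
        rep = 1.0  # Y = 0 -> no repression
        expected = mrsa.a * (mrsa.b / mrsa.A + 0.5) * rep - mrsa.k_deg * S
        assert dx == pytest.approx(expected, rel=1e-12)

    def test_repression_limit_scales_with_one_minus_R(self, mrsa):
        """For Y >> S the repression factor tends to (1 - R)."""
        y_big = 1e6
        base = mrsa.with_(R=0.0)
        full = mrsa.with_(R=1.0)
        dx0, _ = bs.drift(base, (1.0, y_big), 0.0)
        dx1, _ = bs.drift(full, (1.0, y_big), 0.0)
        # remove shared morphogen/degradation parts: both are zero here
        synth0 = dx0 + mrsa.k_deg * 1.0
        synth1 = dx1 + mrsa.k_deg * 1.0
        assert synth1 == pytest.approx(0.0, abs=1e-10)
        assert synth0 > 0

    def test_residual_vanishes_at_detected_fixed_point(self, mrsa):
        fps = bs.find_fixed_points(mrsa, 0.8)
        assert fps, "calibrated MRSA must have fixed points at M=0.8"
        for f in fps:
            dx, dy = bs.drift(mrsa, (f.state.X, f.state.Y), 0.8)
            assert max(abs(dx), abs(dy)) < 1e-9

    def test_negative_state_rejected(self, mrsa):
        with pytest.raises(ValueError):
            bs.drift(mrsa, (-0.1, 0.0), 0.5)

    def test_morphogen_arity_enforced(self, mrsa, cross):
        with pytest.raises(ValueError):
            bs.drift(mrsa, (0.5, 0.5), (0.5, 0.5))
        with pytest.raises(ValueError):
            bs.drift(cross, (0.5, 0.5), 0.5)

    def test_vectorized_drift_matches_scalar_kernel(self, mrsa, sa, mr, cross):
        rng = np.random.default_rng(1)
        pts = rng.uniform(0, 2.5, size=(40, 2))
        for params in (mrsa, sa, mr, cross):
            m = (0.7, 0.5) if params.needs_two_morphogens else 0.7
            f = bs.vector_drift(params, m)
            FX, FY = f(pts[:, 0], pts[:, 1])
            for (x, y), fx, fy in zip(pts, FX, FY):
                sx, sy = bs.drift(params, (x, y), m)
                assert fx == pytest.approx(sx, rel=1e-12, abs=1e-12)
                assert fy == pytest.approx(sy, rel=1e-12, abs=1e-12)

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(
        x=st.floats(0, 10),
        y=st.floats(0, 10),
        m=st.floats(0, 5),
    )
    def test_drift_finite_and_inward_beyond_trapping_box(self, x, y, m):
        """Drift stays finite, and points inward outside the trapping box."""
        params = bs.default_params("MRSA")
        dx, dy = bs.drift(params, (x, y), m)
        assert np.isfinite(dx) and np.isfinite(dy)
        box = params.trapping_box()
        if x > box:
            assert dx < 0
        if y > box:
            assert dy < 0


class TestFixedPoints:
    def test_pure_decay_single_origin_fixed_point(self):
        p = CircuitParams(
            model_id=ModelID.MRSA, a=0.0, a1=0.0, b=0.7, A=1.4, R=0.6,
            k_deg=0.7, S=0.8, n=4,
        )
        fps = bs.find_fixed_points(p, 0.0, search_box=2.0)
        assert len(fps) == 1
        assert fps[0].is_stable
        assert fps[0].state.X == pytest.approx(0.0, abs=1e-8)
        assert fps[0].state.Y == pytest.approx(0.0, abs=1e-8)

    @pytest.mark.parametrize("m,n_stable", [(0.5, 2), (0.8, 2), (1.2, 1)])
    def test_mrsa_attractor_count_matches_relaxation_oracle(
        self, mrsa, grid_scan_stable_count, m, n_stable
    ):
        """Newton-based count agrees with dense grid relaxation."""
        stable = [f for f in bs.find_fixed_points(mrsa, m) if f.is_stable]
        assert len(stable) == n_stable
        n_oracle, reps = grid_scan_stable_count(mrsa, m)
        assert n_oracle == n_stable
        # locations agree pairwise
        for f in stable:
            assert any(
                np.max(np.abs(f.state.as_array() - r)) < 2e-2 for r in reps
            )

    def test_stability_consistent_with_eigenvalues(self, mrsa):
        for f in bs.find_fixed_points(mrsa, 0.5):
            re = [ev.real for ev in f.eigenvalues]
            if f.stability == bs.Stability.STABLE:
                assert all(r < 0 for r in re)
            elif f.stability == bs.Stability.SADDLE:
                assert min(re) < 0 < max(re)

    def test_symmetric_circuit_has_mirror_fixed_points(self):
        """With A=1 and equal inputs the drift commutes with (X,Y) swap."""
        p = CircuitParams(
            model_id=ModelID.MRSA, a=1.0, a1=0.1, b=0.7, A=1.0, R=0.6,
            k_deg=0.7, S=0.8, n=4,
        )
        fps = bs.find_fixed_points(p, 0.3)
        pts = [(f.state.X, f.state.Y) for f in fps]
        for x, y in pts:
            assert any(
                abs(x - y2) < 1e-6 and abs(y - x2) < 1e-6 for x2, y2 in pts
            ), f"mirror of ({x:.4f}, {y:.4f}) missing"


class TestBifurcationScan:
    def test_calibrated_mrsa_regime_sequence(self, mrsa):
        df = bs.bifurcation_scan(mrsa, [0.0, 0.3, 0.5, 0.8, 1.0, 1.2, 1.5])
        regimes = df["regime"].tolist()
        assert regimes[0] == "bistable"
        assert regimes[-1] == "mono_Y"
        # exactly one bistable -> mono_Y transition, no re-entry
        flips = sum(
            1 for a, b in zip(regimes, regimes[1:]) if a == "bistable" and b == "mono_Y"
        )
        assert flips == 1
        assert "bistable" not in regimes[regimes.index("mono_Y"):]

    def test_disconnected_morphogen_gives_constant_regime(self, mrsa):
        p = mrsa.with_(a1=0.0)
        df = bs.bifurcation_scan(p, [0.0, 0.5, 1.0, 1.5])
        assert df["regime"].nunique() == 1
        assert df["n_stable"].nunique() == 1

    def test_scan_invariant_under_row_reordering(self, mrsa):
        grid = [0.2, 0.9, 1.3]
        a = bs.bifurcation_scan(mrsa, grid)
        b = bs.bifurcation_scan(mrsa, grid[::-1])
        merged = a.merge(b, on="m", suffixes=("_f", "_r"))
        assert (merged["regime_f"] == merged["regime_r"]).all()
        assert (merged["n_stable_f"] == merged["n_stable_r"]).all()


class TestParams:
    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            CircuitParams(model_id=ModelID.MRSA, a=1.0, a1=0.1, R=1.5, S=0.8)
        with pytest.raises(ValueError):
            CircuitParams(model_id=ModelID.MRSA, a=-1.0, a1=0.1, S=0.8)
        with pytest.raises(ValueError):
            CircuitParams(model_id=ModelID.MRSA, a=1.0, a1=0.1, S=0.8, n=0)
        with pytest.raises(ValueError):
            GeneState(-0.1, 0.2)

    def test_vector_layout_roundtrip(self, mrsa):
        v = mrsa.as_vector()
        assert v.shape == (11,)
        assert v[0] == mrsa.a and v[8] == mrsa.S and v[9] == mrsa.n

    def test_shipped_config_loads_as_defaults(self, tmp_path):
        from importlib import resources

        src = resources.files("boundsharp.data").joinpath("circuits.toml")
        params = bs.load_params(str(src))
        for mid, p in params.items():
            assert p == bs.default_params(mid)
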