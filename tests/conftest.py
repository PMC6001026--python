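import numpy as np
import pytest

import boundsharp as bs


@pytest.fixture(scope="session")
def mrsa():
    return bs.default_params("MRSA")


@pytest.fixture(scope="session")
def sa():
    return bs.default_params("SA")


@pytest.fixture(scope="session")
def mr():
    return bs.default_params("MR")


@pytest.fixture(scope="session")
def cross():
    return bs.default_params("MRSA_CROSS")


@pytest.fixture(scope="session")
def field30():
    """Deterministic 30-column linear gradient (0 -> 1.5)."""
    return bs.parametric_gradient(bs.linear_profile(), 0.0, 30, 1, seed=0)


@pytest.fixture(scope="session")
def grid_scan_stable_count():
    """Brute-force oracle: count stable attractors by relaxing a dense
    grid of initial conditions with damped Euler and clustering the
    endpoints. Independent of the Newton-based find_fixed_points."""

    def count(params, m, box=3.2, n=14, t_end=400.0, dt=0.05):
        f = bs.vector_drift(params, m)
        g = np.linspace(0.01, box, n)
        X, Y = np.meshgrid(g, g, indexing="ij")
        X = X.ravel().copy()
        Y = Y.ravel().copy()
        for _ in range(int(t_end / dt)):
            fx, fy = f(X, Y)
            X = np.maximum(X + dt * fx, 0.0)
            Y = np.maximum(Y + dt * fy, 0.0)
        pts = np.column_stack([X, Y])
        reps: list[np.ndarray] = []
        for p in pts:
            if not any(np.max(np.abs(p - r)) < 1e-2 for r in reps):
                reps.append(p)
        return len(reps), reps

    return count
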