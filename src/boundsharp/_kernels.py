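"""Numba-compiled inner loops: drift fields and Euler-Maruyama integrators.

Parameter vectors follow the layout of ``CircuitParams.as_vector()``:
``[a, a1, b, b1, b2, A, R, k_deg, S, n, k_selfact]``.

All stochastic kernels seed numpy's legacy RNG *inside* the jitted
function, so a given (seed, config) pair is bit-reproducible.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# indices into the parameter vector
_A, _A1, _B, _B1, _B2, _ASYM, _R, _K, _S, _N, _KSA = range(11)

MRSA, SA, MR, MRSA_CROSS = 0, 1, 2, 3


@njit(cache=False)
def _hill(x, Sn, n):
    if x <= 0.0:
        return 0.0
    xn = x**n
    return xn / (Sn + xn)


@njit(cache=False)
def drift(code, p, X, Y, M1, M2):
    """Deterministic drift (dX/dt, dY/dt) of one cell.

    ``M1`` is the single morphogen level for MRSA/SA/MR; the cross
    variant uses ``M1`` on gene X and ``M2`` on gene Y.
    """
    a = p[_A]
    a1 = p[_A1]
    R = p[_R]
    k = p[_K]
    S = p[_S]
    n = p[_N]
    ksa = p[_KSA]
    Sn = S**n

    hx = _hill(X, Sn, n)
    hy = _hill(Y, Sn, n)
    rep_by_y = 1.0 - R + R * Sn / (Sn + Y**n)
    rep_by_x = 1.0 - R + R * Sn / (Sn + X**n)

    if code == MRSA or code == MRSA_CROSS:
        hm_x = _hill(M1, Sn, n)
        hm_y = _hill(M2, Sn, n) if code == MRSA_CROSS else hm_x
        b = p[_B]
        asym = p[_ASYM]
        fx = a * (b / asym + ksa * hx) * rep_by_y + a1 * hm_x - k * X
        fy = a * (b + ksa * hy) * rep_by_x + a1 * hm_y - k * Y
    elif code == SA:
        hm = _hill(M1, Sn, n)
        fx = a * p[_B1] * rep_by_y + a1 * hm - k * X
        fy = a * (p[_B2] + ksa * hy) + a1 * hm - k * Y
    else:  # MR
        hm = _hill(M1, Sn, n)
        b = p[_B]
        asym = p[_ASYM]
        fx = a * (b / asym) * rep_by_y + a1 * hm - k * X
        fy = a * b * rep_by_x + a1 * hm - k * Y
    return fx, fy


@njit(cache=False)
def simulate_grid(
    code,
    p,
    m1_field,  # (n_mtimes, n_cols) morphogen values for gene X input
    m2_field,  # same shape; ignored unless code == MRSA_CROSS
    m_dt,  # time spacing of the morphogen field rows
    n_rows,
    dt,
    save_times,  # sorted array of output times
    x0,
    y0,  # (n_rows, n_cols) initial conditions
    d,  # gene-expression noise amplitude
    eps_m,  # per-cell morphogen readout noise amplitude
    seed,
):
    """Euler-Maruyama integration of every cell on the grid.

    Gene noise is multiplicative (``d * x * dW``) and independent per
    cell and gene. Each cell reads its column's field value at the
    current time (piecewise-constant in time), dressed with its own
    multiplicative readout fluctuation ``max(0, 1 + eps_m * xi)``
    redrawn once per morphogen time step. Negative excursions are
    clamped to zero.

    Returns X, Y arrays of shape (n_save, n_rows, n_cols).
    """
    np.random.seed(seed)
    n_mtimes, n_cols = m1_field.shape
    n_save = save_times.shape[0]
    X = x0.copy()
    Y = y0.copy()
    outX = np.empty((n_save, n_rows, n_cols))
    outY = np.empty((n_save, n_rows, n_cols))
    M1 = np.empty((n_rows, n_cols))
    M2 = np.empty((n_rows, n_cols))

    t = 0.0
    isave = 0
    last_midx = -1
    sqdt = np.sqrt(dt)
    t_end = save_times[n_save - 1]
    n_steps = int(np.round(t_end / dt))
    for step in range(n_steps + 1):
        # save before stepping so save_times are inclusive
        while isave < n_save and t >= save_times[isave] - 1e-9:
            for i in range(n_rows):
                for j in range(n_cols):
                    outX[isave, i, j] = X[i, j]
                    outY[isave, i, j] = Y[i, j]
            isave += 1
        if isave >= n_save:
            break
        midx = int(t / m_dt)
        if midx != last_midx:
            row = midx if midx < n_mtimes else n_mtimes - 1
            for i in range(n_rows):
                for j in range(n_cols):
                    if eps_m > 0.0:
                        f1 = 1.0 + eps_m * np.random.normal()
                        f2 = 1.0 + eps_m * np.random.normal()
                        if f1 < 0.0:
                            f1 = 0.0
                        if f2 < 0.0:
                            f2 = 0.0
                    else:
                        f1 = 1.0
                        f2 = 1.0
                    M1[i, j] = m1_field[row, j] * f1
                    M2[i, j] = m2_field[row, j] * f2
            last_midx = midx
        for i in range(n_rows):
            for j in range(n_cols):
                fx, fy = drift(code, p, X[i, j], Y[i, j], M1[i, j], M2[i, j])
                x = X[i, j] + fx * dt + d * X[i, j] * sqdt * np.random.normal()
                y = Y[i, j] + fy * dt + d * Y[i, j] * sqdt * np.random.normal()
                X[i, j] = x if x > 0.0 else 0.0
                Y[i, j] = y if y > 0.0 else 0.0
        t += dt
    return outX, outY


@njit(cache=False)
def first_passage_times(
    code,
    p,
    m1,
    m2,
    x0,
    y0,
    xt,
    yt,  # target point
    radius,  # max-norm capture radius
    d,
    dt,
    t_max,
    n_runs,
    seed,
):
    """First passage times of the single-cell SDE into the target ball.

    Runs that do not reach the target before ``t_max`` are reported as
    ``np.inf`` (censored).
    """
    np.random.seed(seed)
    out = np.empty(n_runs)
    sqdt = np.sqrt(dt)
    n_steps = int(t_max / dt)
    for r in range(n_runs):
        X = x0
        Y = y0
        fpt = np.inf
        for step in range(n_steps):
            if abs(X - xt) <= radius and abs(Y - yt) <= radius:
                fpt = step * dt
                break
            fx, fy = drift(code, p, X, Y, m1, m2)
            x = X + fx * dt + d * X * sqdt * np.random.normal()
            y = Y + fy * dt + d * Y * sqdt * np.random.normal()
            X = x if x > 0.0 else 0.0
            Y = y if y > 0.0 else 0.0
        out[r] = fpt
    return out


@njit(cache=False)
def sample_additive_ensemble(
    code,
    p,
    m1,
    m2,
    starts,  # (n_walkers, 2) initial points
    D,  # additive diffusion coefficient; noise is sqrt(2 D) dW
    dt,
    t_burn,
    t_sample,
    sample_every,
    seed,
):
    """Long-run ensemble of the drift with additive noise sqrt(2D)dW.

    Used to cross-check the Fokker-Planck landscape: after a burn-in,
    walker positions are recorded every ``sample_every`` time units.
    Returns an (n_samples, 2) array.
    """
    np.random.seed(seed)
    n_walkers = starts.shape[0]
    sig = np.sqrt(2.0 * D)
    sqdt = np.sqrt(dt)
    n_burn = int(t_burn / dt)
    n_rec = int(t_sample / sample_every)
    every = int(sample_every / dt)
    out = np.empty((n_walkers * n_rec, 2))
    idx = 0
    for w in range(n_walkers):
        X = starts[w, 0]
        Y = starts[w, 1]
        for step in range(n_burn + n_rec * every):
            fx, fy = drift(code, p, X, Y, m1, m2)
            x = X + fx * dt + sig * sqdt * np.random.normal()
            y = Y + fy * dt + sig * sqdt * np.random.normal()
            X = x if x > 0.0 else 0.0
            Y = y if y > 0.0 else 0.0
            if step >= n_burn and (step - n_burn) % every == 0:
                out[idx, 0] = X
                out[idx, 1] = Y
                idx += 1
    return out[:idx]


@njit(cache=False)
def quartic_well_fpt(D, x0, x_target, radius, dt, t_max, n_runs, seed):
    """First passage times for the 1-D quartic double well U=(x^2-1)^2.

    dx = -U'(x) dt + sqrt(2 D) dW; the analytic Kramers benchmark.
    """
    np.random.seed(seed)
    out = np.empty(n_runs)
    sig = np.sqrt(2.0 * D)
    sqdt = np.sqrt(dt)
    n_steps = int(t_max / dt)
    for r in range(n_runs):
        x = x0
        fpt = np.inf
        for step in range(n_steps):
            if abs(x - x_target) <= radius:
                fpt = step * dt
                break
            x += -4.0 * x * (x * x - 1.0) * dt + sig * sqdt * np.random.normal()
        out[r] = fpt
    return out
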