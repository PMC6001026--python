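"""Deterministic drift fields of the circuit variants and their fixed points.

The drift of each variant is a two-component vector field F(X, Y; M)
built from Hill-type synthesis terms, mutual repression factors and
first-order degradation. Bistability — two stable fixed points
separated by a saddle — is the object of interest: the morphogen level
M moves the system from a balanced bistable regime through an
asymmetric one to a monostable (Y-only) regime.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import fsolve

from . import _kernels
from .params import CircuitParams, GeneState, ModelID

__all__ = [
    "Stability",
    "FixedPoint",
    "drift",
    "jacobian",
    "find_fixed_points",
    "bifurcation_scan",
]

#: roots closer than this (max-norm) are considered duplicates
DEDUP_TOL = 1e-4


class Stability(str, Enum):
    STABLE = "stable"
    SADDLE = "saddle"
    UNSTABLE = "unstable"


@dataclass(frozen=True)
class FixedPoint:
    """A root of the drift field with its linear stability."""

    state: GeneState
    stability: Stability
    eigenvalues: tuple[complex, complex]

    @property
    def is_stable(self) -> bool:
        return self.stability == Stability.STABLE


def _morphogen_pair(params: CircuitParams, m) -> tuple[float, float]:
    """Validate morphogen arity and return (M1, M2) for the kernels."""
    if params.needs_two_morphogens:
        try:
            m1, m2 = m
        except TypeError:
            raise ValueError(
                f"{params.model_id.name} needs a morphogen pair (M1, M2), got {m!r}"
            ) from None
    else:
        if np.ndim(m) != 0:
            raise ValueError(
                f"{params.model_id.name} takes a scalar morphogen level, got {m!r}"
            )
        m1 = m2 = float(m)
    if m1 < 0 or m2 < 0:
        raise ValueError(f"morphogen levels must be non-negative, got {m!r}")
    return float(m1), float(m2)


def drift(params: CircuitParams, state: GeneState | tuple[float, float], m):
    """Evaluate the deterministic drift (dX/dt, dY/dt).

    Parameters
    ----------
    params
        Circuit constants.
    state
        Gene expression levels (X, Y), both >= 0.
    m
        Morphogen level; a scalar for MRSA/SA/MR, a pair (M1, M2) for
        the cross-gradient variant.
    """
    if isinstance(state, GeneState):
        X, Y = state.X, state.Y
    else:
        X, Y = float(state[0]), float(state[1])
    if X < 0 or Y < 0:
        raise ValueError(f"expression levels must be non-negative, got ({X}, {Y})")
    m1, m2 = _morphogen_pair(params, m)
    return _kernels.drift(int(params.model_id), params.as_vector(), X, Y, m1, m2)


def vector_drift(params: CircuitParams, m):
    """Return a numpy-vectorized drift function ``f(X, Y) -> (F1, F2)``.

    Mirrors the scalar kernel exactly (asserted by a unit test); used by
    the Fokker-Planck solver to evaluate the drift on whole grids.
    """
    m1, m2 = _morphogen_pair(params, m)
    a, a1 = params.a, params.a1
    R, k, S, n = params.R, params.k_deg, params.S, float(params.n)
    ksa = params.k_selfact
    Sn = S**n

    def hill(v):
        vn = np.maximum(v, 0.0) ** n
        return vn / (Sn + vn)

    hm1 = hill(np.asarray(m1))
    hm2 = hill(np.asarray(m2))
    mid = params.model_id

    def f(X, Y):
        X = np.asarray(X, dtype=float)
        Y = np.asarray(Y, dtype=float)
        rep_by_y = 1.0 - R + R * Sn / (Sn + Y**n)
        rep_by_x = 1.0 - R + R * Sn / (Sn + X**n)
        if mid in (ModelID.MRSA, ModelID.MRSA_CROSS):
            hmx = hm1
            hmy = hm2 if mid == ModelID.MRSA_CROSS else hm1
            fx = a * (params.b / params.A + ksa * hill(X)) * rep_by_y + a1 * hmx - k * X
            fy = a * (params.b + ksa * hill(Y)) * rep_by_x + a1 * hmy - k * Y
        elif mid == ModelID.SA:
            fx = a * params.b1 * rep_by_y + a1 * hm1 - k * X
            fy = a * (params.b2 + ksa * hill(Y)) + a1 * hm1 - k * Y
        else:
            fx = a * (params.b / params.A) * rep_by_y + a1 * hm1 - k * X
            fy = a * params.b * rep_by_x + a1 * hm1 - k * Y
        return fx, fy

    return f


def jacobian(
    params: CircuitParams, state: tuple[float, float], m, eps: float = 1e-7
) -> np.ndarray:
    """Central-difference Jacobian of the drift at ``state``."""
    m1, m2 = _morphogen_pair(params, m)
    p = params.as_vector()
    code = int(params.model_id)
    J = np.empty((2, 2))
    x, y = float(state[0]), float(state[1])
    for j, (dx, dy) in enumerate(((eps, 0.0), (0.0, eps))):
        fp = _kernels.drift(code, p, x + dx, y + dy, m1, m2)
        fm = _kernels.drift(code, p, max(x - dx, 0.0), max(y - dy, 0.0), m1, m2)
        h = (x + dx - max(x - dx, 0.0)) if j == 0 else (y + dy - max(y - dy, 0.0))
        J[0, j] = (fp[0] - fm[0]) / h
        J[1, j] = (fp[1] - fm[1]) / h
    return J


def _classify(eigvals: np.ndarray) -> Stability:
    re = eigvals.real
    if np.all(re < 0):
        return Stability.STABLE
    if np.all(re > 0):
        return Stability.UNSTABLE
    return Stability.SADDLE


def find_fixed_points(
    params: CircuitParams,
    m,
    search_box: float | None = None,
    n_starts: int = 12,
    seed: int = 0,
    residual_tol: float = 1e-9,
) -> list[FixedPoint]:
    """Locate and classify the fixed points of the drift field.

    A deterministic grid of ``n_starts x n_starts`` initial guesses over
    ``[0, search_box]**2`` (plus jittered extras from ``seed``) is
    refined by a damped Newton solve; converged roots are deduplicated
    at ``DEDUP_TOL`` in max-norm and classified by the eigenvalues of
    the Jacobian. Non-converged starts are silently discarded.
    """
    m1, m2 = _morphogen_pair(params, m)
    if search_box is None:
        search_box = params.trapping_box() * 1.05
    p = params.as_vector()
    code = int(params.model_id)

    def fun(v):
        return _kernels.drift(code, p, max(v[0], 0.0), max(v[1], 0.0), m1, m2)

    grid = np.linspace(0.0, search_box, n_starts)
    starts = [(x, y) for x in grid for y in grid]
    rng = np.random.default_rng(seed)
    starts += [tuple(rng.uniform(0, search_box, 2)) for _ in range(n_starts)]

    roots: list[np.ndarray] = []
    for s in starts:
        sol, info, ier, _ = fsolve(fun, s, full_output=True)
        if ier != 1:
            continue
        sol = np.clip(sol, 0.0, None)
        if np.max(np.abs(fun(sol))) > residual_tol:
            continue
        if any(np.max(np.abs(sol - r)) < DEDUP_TOL for r in roots):
            continue
        roots.append(sol)

    out = []
    for r in roots:
        ev = np.linalg.eigvals(jacobian(params, r, m))
        out.append(
            FixedPoint(
                state=GeneState(float(r[0]), float(r[1])),
                stability=_classify(ev),
                eigenvalues=(complex(ev[0]), complex(ev[1])),
            )
        )
    out.sort(key=lambda f: (f.state.X, f.state.Y))
    return out


def _regime(stable: list[FixedPoint]) -> str:
    if len(stable) >= 2:
        return "bistable"
    if len(stable) == 1:
        s = stable[0].state
        return "mono_X" if s.X > s.Y else "mono_Y"
    return "none"


def bifurcation_scan(
    params: CircuitParams,
    m_grid: Sequence,
    search_box: float | None = None,
    n_starts: int = 12,
    seed: int = 0,
) -> pd.DataFrame:
    """Count fixed points of each type along a morphogen grid.

    Returns a DataFrame with columns ``m``, ``n_stable``, ``n_saddle``,
    ``regime`` (one of ``bistable``, ``mono_X``, ``mono_Y``); rows are
    independent, so the scan is invariant under reordering of ``m_grid``.
    """
    rows = []
    for m in m_grid:
        fps = find_fixed_points(params, m, search_box, n_starts, seed)
        stable = [f for f in fps if f.stability == Stability.STABLE]
        saddles = [f for f in fps if f.stability == Stability.SADDLE]
        rows.append(
            {
                "m": m if np.ndim(m) == 0 else tuple(m),
                "n_stable": len(stable),
                "n_saddle": len(saddles),
                "regime": _regime(stable),
            }
        )
    return pd.DataFrame(rows)


def stable_states(params: CircuitParams, m) -> dict[str, GeneState]:
    """Convenience: the stable fixed points keyed by dominant gene.

    Returns a dict with keys among {"X", "Y"}; in a bistable regime both
    are present, in a monostable regime only the surviving state.
    """
    fps = find_fixed_points(params, m)
    out: dict[str, GeneState] = {}
    for f in fps:
        if f.is_stable:
            key = "X" if f.state.X > f.state.Y else "Y"
            # keep the most extreme representative of each type
            if key not in out or abs(f.state.X - f.state.Y) > abs(
                out[key].X - out[key].Y
            ):
                out[key] = f.state
    return out
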