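"""Steady-state Fokker-Planck landscapes U = -ln(Pss).

The probability density P(x1, x2, t) of the noisy circuit obeys

    dP/dt = -d/dx1 [F1 P] - d/dx2 [F2 P] + D (d2P/dx1^2 + d2P/dx2^2)

with constant diffusion coefficient D and zero-flux (reflecting)
boundaries. The stationary solution Pss defines the potential
landscape U = -ln(Pss): attractors are local minima of U, and the
barrier from attractor A towards B is U(saddle) - U(A), where the
saddle is the minimax level over all grid paths between the two
basins.

The solver uses a Scharfetter-Gummel (exponentially fitted) finite
volume discretization, which conserves probability exactly, keeps the
stationary solution non-negative, and is exact for linear potentials
across each cell face. The stationary density is obtained directly as
the null vector of the discrete generator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import spsolve

from .params import CircuitParams

__all__ = [
    "FPConfig",
    "Landscape",
    "Attractor",
    "Barrier",
    "solve_fokker_planck",
    "potential",
    "find_attractors",
    "barrier",
]

#: default relative probability floor applied before taking logs
U_FLOOR_REL = 1e-12


@dataclass(frozen=True)
class FPConfig:
    """Discretization settings for the stationary Fokker-Planck solve."""

    D: float = 0.005
    domain: tuple[float, float] = (3.0, 3.0)
    resolution: tuple[int, int] = (200, 200)
    solver_tol: float = 1e-8

    def __post_init__(self) -> None:
        if self.D <= 0:
            raise ValueError("diffusion coefficient D must be > 0")
        if min(self.resolution) < 50:
            raise ValueError("resolution must be at least 50 cells per axis")
        if min(self.domain) <= 0:
            raise ValueError("domain extents must be positive")


@dataclass(frozen=True)
class Attractor:
    ix: int
    iy: int
    x: float
    y: float
    U: float


@dataclass(frozen=True)
class Barrier:
    """Potential barrier from ``a`` towards ``b`` over the connecting saddle."""

    a: Attractor
    b: Attractor
    saddle_x: float
    saddle_y: float
    saddle_U: float

    @property
    def height(self) -> float:
        return self.saddle_U - self.a.U


@dataclass(frozen=True)
class Landscape:
    """Stationary density and potential on a uniform cell-centred grid.

    ``Pss[i, j]`` is the probability *density* at cell centre
    ``(x[i], y[j])`` and integrates to one over the domain;
    ``U = -ln(max(Pss, floor))``.
    """

    x: np.ndarray
    y: np.ndarray
    Pss: np.ndarray
    U: np.ndarray
    floor: float
    D: float
    residual: float

    @property
    def dx(self) -> float:
        return float(self.x[1] - self.x[0])

    @property
    def dy(self) -> float:
        return float(self.y[1] - self.y[0])

    def to_hdf5(self, path) -> None:
        """Gridded container with Pss, U and solver provenance."""
        import h5py

        with h5py.File(path, "w") as fh:
            fh.create_dataset("x", data=self.x)
            fh.create_dataset("y", data=self.y)
            fh.create_dataset("Pss", data=self.Pss, compression="gzip")
            fh.create_dataset("U", data=self.U, compression="gzip")
            fh.attrs["D"] = self.D
            fh.attrs["floor"] = self.floor
            fh.attrs["residual"] = self.residual

    def cell_of(self, x: float, y: float) -> tuple[int, int]:
        ix = int(np.argmin(np.abs(self.x - x)))
        iy = int(np.argmin(np.abs(self.y - y)))
        return ix, iy


def _bernoulli(z: np.ndarray) -> np.ndarray:
    """B(z) = z / (exp(z) - 1), computed stably for large |z|."""
    z = np.asarray(z, dtype=float)
    out = np.empty_like(z)
    small = np.abs(z) < 1e-10
    out[small] = 1.0 - 0.5 * z[small]
    zb = np.clip(z[~small], -700.0, 700.0)
    out[~small] = zb / np.expm1(zb)
    return out


def solve_fokker_planck(
    params: CircuitParams | None,
    m,
    cfg: FPConfig,
    drift_fn=None,
) -> Landscape:
    """Stationary Fokker-Planck solution for a circuit at morphogen level m.

    ``drift_fn(X, Y) -> (F1, F2)`` may be supplied instead of a
    parameter set (used for analytic benchmarks); vectorized over
    numpy arrays.
    """
    nx, ny = cfg.resolution
    Lx, Ly = cfg.domain
    dx = Lx / nx
    dy = Ly / ny
    xc = (np.arange(nx) + 0.5) * dx
    yc = (np.arange(ny) + 0.5) * dy

    if drift_fn is None:
        if params is None:
            raise ValueError("either params or drift_fn must be given")
        from .models import vector_drift

        drift_fn = vector_drift(params, m)
        box = params.trapping_box()
        if Lx < box or Ly < box:
            warnings.warn(
                f"domain {cfg.domain} does not contain the trapping box [0, {box:.2f}]^2"
            )

    # drift at vertical faces (between (i,j) and (i+1,j)) and horizontal faces
    Xv, Yv = np.meshgrid(xc[:-1] + 0.5 * dx, yc, indexing="ij")
    Fxv, _ = drift_fn(Xv, Yv)
    Xh, Yh = np.meshgrid(xc, yc[:-1] + 0.5 * dy, indexing="ij")
    _, Fyh = drift_fn(Xh, Yh)

    D = cfg.D
    wx = Fxv * dx / D
    wy = Fyh * dy / D
    # Scharfetter-Gummel transition rates across each face
    rate_right = (D / dx**2) * _bernoulli(-wx)  # (i,j) -> (i+1,j)
    rate_left = (D / dx**2) * _bernoulli(wx)  # (i+1,j) -> (i,j)
    rate_up = (D / dy**2) * _bernoulli(-wy)  # (i,j) -> (i,j+1)
    rate_down = (D / dy**2) * _bernoulli(wy)  # (i,j+1) -> (i,j)

    def lin(i, j):
        return i * ny + j

    Iv, Jv = np.meshgrid(np.arange(nx - 1), np.arange(ny), indexing="ij")
    Ih, Jh = np.meshgrid(np.arange(nx), np.arange(ny - 1), indexing="ij")

    rows = np.concatenate(
        [
            lin(Iv + 1, Jv).ravel(),  # gain at right cell from left
            lin(Iv, Jv).ravel(),  # gain at left cell from right
            lin(Ih, Jh + 1).ravel(),
            lin(Ih, Jh).ravel(),
        ]
    )
    cols = np.concatenate(
        [
            lin(Iv, Jv).ravel(),
            lin(Iv + 1, Jv).ravel(),
            lin(Ih, Jh).ravel(),
            lin(Ih, Jh + 1).ravel(),
        ]
    )
    vals = np.concatenate(
        [
            rate_right.ravel(),
            rate_left.ravel(),
            rate_up.ravel(),
            rate_down.ravel(),
        ]
    )
    N = nx * ny
    Q = sp.coo_matrix((vals, (rows, cols)), shape=(N, N)).tocsr()
    # diagonal: total outflow of each cell
    outflow = np.asarray(Q.sum(axis=0)).ravel()
    Q = Q - sp.diags(outflow)

    # null vector with normalization sum(p) = 1 in place of one balance row
    A = Q.tolil()
    A[0, :] = 1.0
    b = np.zeros(N)
    b[0] = 1.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", sp.SparseEfficiencyWarning)
        pvec = spsolve(A.tocsr(), b)

    residual = float(np.max(np.abs(Q @ pvec)))
    neg = pvec < 0
    if np.any(neg):
        worst = float(pvec[neg].min())
        if abs(worst) > 1e-10 * pvec.max():
            warnings.warn(f"stationary solution has negative entries down to {worst:g}")
        pvec = np.clip(pvec, 0.0, None)
    pvec = pvec / pvec.sum()
    if residual > cfg.solver_tol * max(1.0, float(np.max(outflow))):
        raise RuntimeError(
            f"Fokker-Planck solve did not converge: residual {residual:g}"
        )

    P = pvec.reshape(nx, ny) / (dx * dy)  # density
    edge = np.zeros_like(P, dtype=bool)
    edge[:2, :] = edge[-2:, :] = edge[:, :2] = edge[:, -2:] = True
    edge_mass = float(P[edge].sum() * dx * dy)
    if edge_mass > 0.01:
        warnings.warn(
            f"{edge_mass:.1%} of probability mass lies within 2 cells of the "
            "boundary; the domain is probably too small"
        )

    floor = U_FLOOR_REL * float(P.max())
    U = -np.log(np.maximum(P, floor))
    return Landscape(
        x=xc, y=yc, Pss=P, U=U, floor=floor, D=D, residual=residual
    )


def potential(landscape: Landscape) -> np.ndarray:
    """The potential U = -ln(max(Pss, floor)) of a solved landscape."""
    return -np.log(np.maximum(landscape.Pss, landscape.floor))


# ---------------------------------------------------------------------------
# attractors, saddles, barriers on the discrete landscape
# ---------------------------------------------------------------------------

_NEIGHBORS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def _local_minima(U: np.ndarray) -> list[tuple[int, int]]:
    nx, ny = U.shape
    pad = np.pad(U, 1, mode="constant", constant_values=np.inf)
    core = pad[1:-1, 1:-1]
    is_min = np.ones_like(U, dtype=bool)
    for di, dj in _NEIGHBORS:
        is_min &= core < pad[1 + di : 1 + di + nx, 1 + dj : 1 + dj + ny]
    return [tuple(idx) for idx in np.argwhere(is_min)]


class _UnionFind:
    def __init__(self, n: int):
        self.parent = np.arange(n)

    def find(self, i: int) -> int:
        p = self.parent
        while p[i] != i:
            p[i] = p[p[i]]
            i = p[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[ri] = rj


def _prominences(U: np.ndarray, minima: list[tuple[int, int]]) -> dict:
    """Merge level of each local minimum's basin (watershed prominence).

    Cells are activated in ascending U order; when the component of a
    minimum first touches a component holding a deeper minimum, the
    activating cell's level is its merge level. The global minimum has
    infinite prominence.
    """
    nx, ny = U.shape
    order = np.argsort(U, axis=None, kind="stable")
    uf = _UnionFind(nx * ny)
    active = np.zeros(nx * ny, dtype=bool)
    min_ids = {m[0] * ny + m[1]: m for m in minima}
    # lowest minimum in each component (by U); -1 = none
    comp_min = np.full(nx * ny, -1, dtype=np.int64)
    merge_level: dict[tuple[int, int], float] = {}

    for flat in order:
        i, j = divmod(int(flat), ny)
        active[flat] = True
        if flat in min_ids:
            comp_min[flat] = flat
        for di, dj in _NEIGHBORS:
            ni, nj = i + di, j + dj
            if ni < 0 or nj < 0 or ni >= nx or nj >= ny:
                continue
            nflat = ni * ny + nj
            if not active[nflat]:
                continue
            ra, rb = uf.find(flat), uf.find(nflat)
            if ra == rb:
                continue
            ma, mb = comp_min[ra], comp_min[rb]
            if ma >= 0 and mb >= 0:
                # the shallower minimum merges here
                shallower = ma if U.flat[ma] > U.flat[mb] else mb
                keep = mb if shallower == ma else ma
                key = min_ids.get(int(shallower))
                if key is not None and key not in merge_level:
                    merge_level[key] = float(U[i, j])
                winner = keep
            else:
                winner = ma if ma >= 0 else mb
            uf.union(ra, rb)
            comp_min[uf.find(ra)] = winner
    return merge_level


def find_attractors(
    landscape: Landscape | np.ndarray,
    min_depth: float = 0.5,
    x: np.ndarray | None = None,
    y: np.ndarray | None = None,
) -> list[Attractor]:
    """Local minima of U, filtered by basin depth (prominence).

    A minimum is kept if the minimax level at which its basin merges
    into a deeper basin lies at least ``min_depth`` potential units
    above it; the global minimum is always kept. Results are sorted by
    U (deepest first).
    """
    if isinstance(landscape, Landscape):
        U = landscape.U
        x = landscape.x
        y = landscape.y
    else:
        U = np.asarray(landscape)
        if x is None or y is None:
            x = np.arange(U.shape[0], dtype=float)
            y = np.arange(U.shape[1], dtype=float)
    if not np.all(np.isfinite(U)):
        raise ValueError("U must be finite on the grid")

    minima = _local_minima(U)
    if not minima:
        return []
    merge = _prominences(U, minima)
    global_min = min(minima, key=lambda ij: U[ij])
    out = []
    for ij in minima:
        prom = np.inf if ij == global_min else merge.get(ij, np.inf) - U[ij]
        if prom >= min_depth:
            out.append(
                Attractor(
                    ix=int(ij[0]),
                    iy=int(ij[1]),
                    x=float(x[ij[0]]),
                    y=float(y[ij[1]]),
                    U=float(U[ij]),
                )
            )
    out.sort(key=lambda a: a.U)
    return out


def barrier(
    landscape: Landscape | np.ndarray,
    attractor_a: Attractor,
    attractor_b: Attractor,
    x: np.ndarray | None = None,
    y: np.ndarray | None = None,
) -> Barrier:
    """Exact minimax saddle between two attractors on the grid.

    Cells are activated in ascending U order with union-find; the cell
    whose activation first connects the two attractors is the saddle.
    The barrier height for the A -> B transition is
    ``U(saddle) - U(A)``; swapping the arguments changes the height but
    not the saddle.
    """
    if isinstance(landscape, Landscape):
        U = landscape.U
        x = landscape.x
        y = landscape.y
    else:
        U = np.asarray(landscape)
        if x is None or y is None:
            x = np.arange(U.shape[0], dtype=float)
            y = np.arange(U.shape[1], dtype=float)
    nx, ny = U.shape
    fa = attractor_a.ix * ny + attractor_a.iy
    fb = attractor_b.ix * ny + attractor_b.iy
    if fa == fb:
        raise ValueError("attractors are identical")

    order = np.argsort(U, axis=None, kind="stable")
    uf = _UnionFind(nx * ny)
    active = np.zeros(nx * ny, dtype=bool)
    for flat in order:
        i, j = divmod(int(flat), ny)
        active[flat] = True
        for di, dj in _NEIGHBORS:
            ni, nj = i + di, j + dj
            if ni < 0 or nj < 0 or ni >= nx or nj >= ny:
                continue
            nflat = ni * ny + nj
            if active[nflat]:
                uf.union(flat, nflat)
        if active[fa] and active[fb] and uf.find(fa) == uf.find(fb):
            return Barrier(
                a=attractor_a,
                b=attractor_b,
                saddle_x=float(x[i]),
                saddle_y=float(y[j]),
                saddle_U=float(U[i, j]),
            )
    raise RuntimeError("attractors are not connected on the grid")
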