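"""Noisy morphogen profiles along the tissue axis.

Two generators are provided:

* :func:`simulate_ra_gradient` integrates a 1-D reaction-diffusion
  system for extracellular / intracellular retinoic acid (RA) with
  multiplicative space-time white noise, no-flux at the anterior end
  and a leaky (Robin) condition at the posterior end. The intracellular
  concentration plays the role of the morphogen M.
* :func:`parametric_gradient` dresses an arbitrary deterministic
  profile with multiplicative Gaussian noise. This is the default
  driver for the tissue simulations: the circuit response depends on a
  noisy monotone gradient, not on the specific RA kinetics.

Columns are indexed 0..n_columns-1 left to right and the default
profiles increase to the right, so the Y-dominated domain forms on the
right-hand side of the tissue.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd

__all__ = [
    "FieldKind",
    "MorphogenField",
    "RAParams",
    "simulate_ra_gradient",
    "parametric_gradient",
    "cross_gradients",
    "linear_profile",
    "opposed_exponential_profiles",
]


class FieldKind(str, Enum):
    RA_PDE = "RA_PDE"
    PARAMETRIC = "PARAMETRIC"


@dataclass(frozen=True)
class MorphogenField:
    """Morphogen level per column over saved times.

    ``values`` has shape (n_times, n_columns) and is non-negative;
    ``times`` gives the time stamp of each row.
    """

    x_coords: np.ndarray
    times: np.ndarray
    values: np.ndarray
    noise_amp: float
    kind: FieldKind

    def __post_init__(self) -> None:
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (n_times, n_columns)")
        if self.values.shape != (len(self.times), len(self.x_coords)):
            raise ValueError(
                f"shape mismatch: values {self.values.shape} vs "
                f"{len(self.times)} times x {len(self.x_coords)} columns"
            )
        if np.any(self.values < 0):
            raise ValueError("morphogen values must be non-negative")

    @property
    def n_columns(self) -> int:
        return self.values.shape[1]

    @property
    def time_step(self) -> float:
        if len(self.times) < 2:
            return 1.0
        return float(self.times[1] - self.times[0])

    def to_frame(self) -> pd.DataFrame:
        """Long-format (time, x_index, value) table."""
        t_idx, x_idx = np.meshgrid(
            np.arange(len(self.times)), np.arange(self.n_columns), indexing="ij"
        )
        return pd.DataFrame(
            {
                "time": self.times[t_idx.ravel()],
                "x_index": x_idx.ravel(),
                "value": self.values.ravel(),
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_hdf5(self, path: str | Path) -> None:
        """Gridded container for large runs."""
        import h5py

        with h5py.File(path, "w") as fh:
            fh.create_dataset("x_coords", data=self.x_coords)
            fh.create_dataset("times", data=self.times)
            fh.create_dataset("values", data=self.values, compression="gzip")
            fh.attrs["noise_amp"] = self.noise_amp
            fh.attrs["kind"] = self.kind.value

    @classmethod
    def from_hdf5(cls, path: str | Path) -> "MorphogenField":
        import h5py

        with h5py.File(path, "r") as fh:
            return cls(
                x_coords=fh["x_coords"][:],
                times=fh["times"][:],
                values=fh["values"][:],
                noise_amp=float(fh.attrs["noise_amp"]),
                kind=FieldKind(fh.attrs["kind"]),
            )


# ---------------------------------------------------------------------------
# parametric generator
# ---------------------------------------------------------------------------


def linear_profile(m_left: float = 0.0, m_right: float = 1.5) -> Callable:
    """Linear profile on normalized position u in [0, 1]."""

    def profile(u):
        return m_left + (m_right - m_left) * u

    return profile


def parametric_gradient(
    profile: Callable,
    eps: float,
    n_columns: int,
    n_times: int,
    seed: int,
    dt: float = 1.0,
) -> MorphogenField:
    """Deterministic profile with multiplicative Gaussian noise.

    ``values[t, j] = profile(u_j) * max(0, 1 + eps * xi_tj)`` with
    i.i.d. standard normal ``xi`` redrawn per column and per time step
    (spacing ``dt``); ``eps = 0`` reproduces the profile exactly at
    every time.
    """
    if eps < 0:
        raise ValueError(f"noise amplitude eps must be >= 0, got {eps}")
    if n_columns < 1 or n_times < 1:
        raise ValueError("n_columns and n_times must be >= 1")
    u = np.linspace(0.0, 1.0, n_columns)
    base = np.asarray([profile(ui) for ui in u], dtype=float)
    if np.any(base < 0):
        raise ValueError("profile must be non-negative")
    rng = np.random.default_rng(seed)
    if eps == 0.0:
        vals = np.tile(base, (n_times, 1))
    else:
        xi = rng.standard_normal((n_times, n_columns))
        vals = base[None, :] * np.maximum(0.0, 1.0 + eps * xi)
    return MorphogenField(
        x_coords=u,
        times=np.arange(n_times) * dt,
        values=vals,
        noise_amp=eps,
        kind=FieldKind.PARAMETRIC,
    )


def opposed_exponential_profiles(
    m_max: float = 1.0, m_min: float = 0.38
) -> tuple[Callable, Callable]:
    """Opposed exponential gradients anchored at the reference levels.

    M1 decays from ``m_max`` on the left to ``m_min`` on the right,
    M2 is its mirror image; at the centre both equal
    ``sqrt(m_max * m_min)`` (0.616 for the defaults 1.0 / 0.38).
    """
    ratio = m_min / m_max

    def p1(u):
        return m_max * ratio**u

    def p2(u):
        return m_max * ratio ** (1.0 - u)

    return p1, p2


def cross_gradients(
    profile1: Callable | None = None,
    profile2: Callable | None = None,
    eps: float = 0.0,
    n_columns: int = 30,
    n_times: int = 1,
    seed: int = 0,
    dt: float = 1.0,
) -> tuple[MorphogenField, MorphogenField]:
    """A pair of opposed noisy gradients with independent noise streams.

    Defaults to the anchored opposed exponential profiles; the two
    fields use seeds derived from ``seed`` via numpy's seed-spawning,
    so they are independent but jointly reproducible.
    """
    if profile1 is None or profile2 is None:
        d1, d2 = opposed_exponential_profiles()
        profile1 = profile1 or d1
        profile2 = profile2 or d2
    ss = np.random.SeedSequence(seed)
    s1, s2 = ss.spawn(2)
    f1 = parametric_gradient(profile1, eps, n_columns, n_times, _seed_int(s1), dt)
    f2 = parametric_gradient(profile2, eps, n_columns, n_times, _seed_int(s2), dt)
    return f1, f2


def _seed_int(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0])


# ---------------------------------------------------------------------------
# RA reaction-diffusion generator
# ---------------------------------------------------------------------------


def _default_source(n_columns: int) -> np.ndarray:
    """Production localized to the anterior fifth of the domain."""
    v = np.zeros(n_columns)
    v[: max(1, n_columns // 5)] = 1.0
    return v


@dataclass(frozen=True)
class RAParams:
    """Rate constants of the extracellular/intracellular RA system.

    The coupled equations integrated by :func:`simulate_ra_gradient`:

    d[RA]_out/dt = D_RA d2[RA]_out/dx2 + V_RA(x)
                   - (1 + beta) k_A [RA]_out + k_A [RA]_in
                   + eps_out [RA]_out dW_out
    d[RA]_in/dt  = k_A [RA]_out - (k_A + Cyp([RA]_in)) [RA]_in
                   + eps [RA]_in dW_in

    ``Cyp`` is the intracellular degradation response, modelled as a
    basal rate plus an optional Hill-type self-enhanced term:
    ``cyp_basal + cyp_gain * R^h / (cyp_K^h + R^h)``.
    """

    D_RA: float = 1.0
    V_RA: np.ndarray | None = None  # per-column production; None -> anterior source
    k_A: float = 1.0
    beta: float = 1.0
    cyp_basal: float = 1.0
    cyp_gain: float = 0.0
    cyp_K: float = 1.0
    cyp_h: int = 2
    leak: float | None = None  # posterior Robin leak rate; None -> 0.1 * k_A
    eps_out: float = 0.0
    eps: float = 0.0

    def __post_init__(self) -> None:
        if self.D_RA <= 0 or self.k_A <= 0:
            raise ValueError("D_RA and k_A must be > 0")
        if self.beta < 0 or self.eps < 0 or self.eps_out < 0:
            raise ValueError("beta, eps, eps_out must be >= 0")
        if self.cyp_basal < 0 or self.cyp_gain < 0:
            raise ValueError("Cyp rates must be >= 0")

    def cyp(self, ra_in: np.ndarray) -> np.ndarray:
        ra = np.maximum(ra_in, 0.0)
        out = np.full_like(ra, self.cyp_basal)
        if self.cyp_gain > 0:
            rh = ra**self.cyp_h
            out = out + self.cyp_gain * rh / (self.cyp_K**self.cyp_h + rh)
        return out


def simulate_ra_gradient(
    params: RAParams,
    n_columns: int = 100,
    dx: float = 0.1,
    dt: float = 1e-3,
    t_end: float = 20.0,
    seed: int = 0,
    save_every: float = 1.0,
    return_extracellular: bool = False,
    init_out: np.ndarray | None = None,
    init_in: np.ndarray | None = None,
) -> MorphogenField:
    """Integrate the RA system by explicit Euler-Maruyama.

    No-flux at the anterior boundary (x = 0); at the posterior boundary
    the extracellular pool loses mass at rate ``leak`` (Robin
    condition). The multiplicative noise terms use independent Wiener
    increments per column scaled by 1/sqrt(dt dx); negative excursions
    are clamped at zero. The returned field is the intracellular
    concentration (the morphogen M).
    """
    if n_columns < 3:
        raise ValueError("n_columns must be >= 3")
    stab = dx * dx / (2.0 * params.D_RA)
    if dt > stab:
        raise ValueError(
            f"dt={dt} violates the explicit stability bound dx^2/(2 D_RA)={stab:.3g}"
        )
    V = params.V_RA if params.V_RA is not None else _default_source(n_columns)
    V = np.asarray(V, dtype=float)
    if V.shape != (n_columns,):
        raise ValueError(f"V_RA must have shape ({n_columns},), got {V.shape}")
    leak = params.leak if params.leak is not None else 0.1 * params.k_A

    rng = np.random.default_rng(seed)
    out = np.zeros(n_columns) if init_out is None else np.asarray(init_out, float).copy()
    inn = np.zeros(n_columns) if init_in is None else np.asarray(init_in, float).copy()
    n_steps = int(round(t_end / dt))
    every = max(1, int(round(save_every / dt)))
    times = [0.0]
    snaps_in = [inn.copy()]
    snaps_out = [out.copy()]
    noise_scale = 1.0 / np.sqrt(dt * dx)

    for step in range(1, n_steps + 1):
        lap = np.empty(n_columns)
        lap[1:-1] = out[2:] - 2.0 * out[1:-1] + out[:-2]
        lap[0] = out[1] - out[0]  # no-flux ghost at the anterior end
        lap[-1] = out[-2] - out[-1] - (leak * dx / params.D_RA) * out[-1]
        lap *= params.D_RA / (dx * dx)

        d_out = lap + V - (1.0 + params.beta) * params.k_A * out + params.k_A * inn
        d_in = params.k_A * out - (params.k_A + params.cyp(inn)) * inn
        if params.eps_out > 0.0:
            d_out = d_out + params.eps_out * out * noise_scale * rng.standard_normal(
                n_columns
            )
        if params.eps > 0.0:
            d_in = d_in + params.eps * inn * noise_scale * rng.standard_normal(
                n_columns
            )
        out = np.maximum(out + dt * d_out, 0.0)
        inn = np.maximum(inn + dt * d_in, 0.0)
        if step % every == 0:
            times.append(step * dt)
            snaps_in.append(inn.copy())
            snaps_out.append(out.copy())

    values = np.asarray(snaps_out if return_extracellular else snaps_in)
    return MorphogenField(
        x_coords=np.arange(n_columns) * dx,
        times=np.asarray(times),
        values=values,
        noise_amp=params.eps,
        kind=FieldKind.RA_PDE,
    )
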