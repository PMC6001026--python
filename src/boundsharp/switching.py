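"""Mean first passage times (MFPT) of noise-induced state switching.

The switching time from the X attractor to the Y attractor is
estimated directly from trajectories of the multiplicative-noise SDE
(the same integrator as the tissue simulations, for a single cell):
each run starts at the X attractor and stops when it first enters a
capture ball around the Y attractor; the MFPT is the mean over
uncensored runs. A 1-D quartic double well with additive noise serves
as the analytic (Kramers) benchmark for the estimator.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from . import _kernels
from .landscape import FPConfig, barrier, find_attractors, solve_fokker_planck
from .models import stable_states
from .params import CircuitParams, GeneState

__all__ = [
    "MFPTConfig",
    "MFPTResult",
    "mfpt",
    "mfpt_sweep",
    "barrier_vs_mfpt",
    "kramers_mfpt_quartic",
    "quartic_well_mfpt",
]


@dataclass(frozen=True)
class MFPTConfig:
    """Settings of a switching-time estimate.

    ``start``/``target`` default to the X and Y stable fixed points at
    the given morphogen level; ``radius`` is the max-norm capture
    radius around the target.
    """

    d: float = 0.05
    start: GeneState | None = None
    target: GeneState | None = None
    radius: float = 0.1
    n_runs: int = 200
    t_max: float = 1e5
    dt: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("capture radius must be > 0")
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        if self.t_max <= 0 or self.dt <= 0:
            raise ValueError("t_max and dt must be > 0")


@dataclass(frozen=True)
class MFPTResult:
    """Mean first passage time over uncensored runs."""

    mean: float
    sem: float
    n_runs: int
    n_censored: int
    bistable: bool
    config: MFPTConfig

    @property
    def all_censored(self) -> bool:
        return self.n_censored == self.n_runs


def _endpoints(params: CircuitParams, m, cfg: MFPTConfig):
    start, target = cfg.start, cfg.target
    bistable = True
    if start is None or target is None:
        states = stable_states(params, m)
        bistable = "X" in states and "Y" in states
        if start is None:
            if "X" not in states:
                raise ValueError(
                    "no X-dominant stable state at this morphogen level; "
                    "pass an explicit start state"
                )
            start = states["X"]
        if target is None:
            if "Y" not in states:
                raise ValueError(
                    "no Y-dominant stable state at this morphogen level; "
                    "pass an explicit target state"
                )
            target = states["Y"]
        if not bistable:
            warnings.warn(
                "system is not bistable at this morphogen level; the reported "
                "time is a relaxation time, not a barrier-crossing time"
            )
    return start, target, bistable


def mfpt(params: CircuitParams, m, cfg: MFPTConfig) -> MFPTResult:
    """Estimate the X -> Y mean first passage time from SDE trajectories.

    Censored runs (no capture before ``t_max``) are excluded from the
    mean and reported in ``n_censored``; if every run is censored the
    mean is ``inf``.
    """
    start, target, bistable = _endpoints(params, m, cfg)
    if params.needs_two_morphogens:
        m1, m2 = float(m[0]), float(m[1])
    else:
        m1 = m2 = float(m)
    fpts = _kernels.first_passage_times(
        int(params.model_id),
        params.as_vector(),
        m1,
        m2,
        start.X,
        start.Y,
        target.X,
        target.Y,
        cfg.radius,
        cfg.d,
        cfg.dt,
        cfg.t_max,
        cfg.n_runs,
        cfg.seed % (2**31),
    )
    ok = np.isfinite(fpts)
    n_cens = int(np.sum(~ok))
    if n_cens == cfg.n_runs:
        warnings.warn("all runs censored at t_max; MFPT reported as inf")
        return MFPTResult(math.inf, math.nan, cfg.n_runs, n_cens, bistable, cfg)
    vals = fpts[ok]
    sem = float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else math.nan
    return MFPTResult(float(vals.mean()), sem, cfg.n_runs, n_cens, bistable, cfg)


_SWEEPABLE = {"d", "M", "A", "R", "k_selfact"}


def mfpt_sweep(
    params: CircuitParams,
    sweep_var: str,
    values: Sequence[float],
    cfg: MFPTConfig,
    m=None,
) -> pd.DataFrame:
    """MFPT along a sweep of noise level, morphogen, or a circuit constant.

    ``sweep_var`` is one of ``d``, ``M``, ``A``, ``R``, ``k_selfact``.
    ``m`` gives the (fixed) morphogen level for the non-M sweeps. Each
    condition uses an independent substream of ``cfg.seed``.
    """
    if sweep_var not in _SWEEPABLE:
        raise ValueError(f"sweep_var must be one of {sorted(_SWEEPABLE)}")
    if sweep_var != "M" and m is None:
        raise ValueError("fixed morphogen level m required for non-M sweeps")
    ss = np.random.SeedSequence(cfg.seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(len(values))]
    rows = []
    for v, seed in zip(values, seeds):
        p_i = params
        m_i = m
        cfg_i = replace(cfg, seed=seed)
        if sweep_var == "d":
            cfg_i = replace(cfg_i, d=float(v))
        elif sweep_var == "M":
            m_i = float(v)
        elif sweep_var == "A":
            p_i = params.with_(A=float(v))
        elif sweep_var == "R":
            p_i = params.with_(R=float(v))
        else:
            p_i = params.with_(k_selfact=float(v))
        try:
            res = mfpt(p_i, m_i, cfg_i)
            row = {
                "mean": res.mean,
                "sem": res.sem,
                "n_censored": res.n_censored,
                "bistable": res.bistable,
            }
        except ValueError:
            # condition lost bistability (no X or no Y state): flagged row
            row = {"mean": math.nan, "sem": math.nan, "n_censored": 0, "bistable": False}
        rows.append({"sweep_var": sweep_var, "value": v, "d": cfg_i.d, **row})
    return pd.DataFrame(rows)


def barrier_vs_mfpt(
    params: CircuitParams,
    m_values: Sequence[float],
    fp_cfg: FPConfig,
    mfpt_cfg: MFPTConfig,
    min_depth: float = 0.01,
) -> pd.DataFrame:
    """Pair the X -> Y barrier height with the MFPT at each morphogen level.

    Returns a table (m, barrier, mfpt_mean, mfpt_sem, n_censored) plus
    the Spearman rank correlation between barrier and MFPT in
    ``df.attrs["spearman"]`` (nan when fewer than 3 rows).
    """
    from scipy.stats import spearmanr

    rows = []
    ss = np.random.SeedSequence(mfpt_cfg.seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(len(m_values))]
    for m, seed in zip(m_values, seeds):
        land = solve_fokker_planck(params, m, fp_cfg)
        attrs = find_attractors(land, min_depth=min_depth)
        x_att = [a for a in attrs if a.x > a.y]
        y_att = [a for a in attrs if a.y > a.x]
        if not x_att or not y_att:
            raise ValueError(f"landscape at M={m} is not bistable")
        bar = barrier(land, x_att[0], y_att[0])
        res = mfpt(params, m, replace(mfpt_cfg, seed=seed))
        rows.append(
            {
                "m": m,
                "barrier": bar.height,
                "mfpt_mean": res.mean,
                "mfpt_sem": res.sem,
                "n_censored": res.n_censored,
            }
        )
    df = pd.DataFrame(rows)
    finite = df[np.isfinite(df["mfpt_mean"])]
    if len(finite) >= 3:
        rho = float(spearmanr(finite["barrier"], finite["mfpt_mean"]).statistic)
    else:
        rho = math.nan
    df.attrs["spearman"] = rho
    return df


# ---------------------------------------------------------------------------
# 1-D Kramers benchmark
# ---------------------------------------------------------------------------


def kramers_mfpt_quartic(D: float) -> float:
    """Kramers escape time for U = (x^2 - 1)^2 with dx = -U' dt + sqrt(2D) dW.

    MFPT ~ 2 pi / sqrt(U''(min) |U''(saddle)|) * exp(dU / D) with
    U''(+-1) = 8, U''(0) = -4, dU = 1.
    """
    return 2.0 * math.pi / math.sqrt(8.0 * 4.0) * math.exp(1.0 / D)


def quartic_well_mfpt(
    D: float,
    n_runs: int = 400,
    dt: float = 1e-3,
    t_max: float = 1e5,
    radius: float = 0.1,
    seed: int = 0,
) -> MFPTResult:
    """Simulated escape time from x = -1 to x = +1 in the quartic well."""
    fpts = _kernels.quartic_well_fpt(
        D, -1.0, 1.0, radius, dt, t_max, n_runs, seed % (2**31)
    )
    ok = np.isfinite(fpts)
    n_cens = int(np.sum(~ok))
    cfg = MFPTConfig(d=D, n_runs=n_runs, t_max=t_max, dt=dt, seed=seed)
    if n_cens == n_runs:
        return MFPTResult(math.inf, math.nan, n_runs, n_cens, True, cfg)
    vals = fpts[ok]
    sem = float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else math.nan
    return MFPTResult(float(vals.mean()), sem, n_runs, n_cens, True, cfg)
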