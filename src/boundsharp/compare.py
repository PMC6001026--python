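"""Robustness comparison of the circuit topologies.

The three single-gradient motifs are compared by their boundary
sharpening performance under random perturbation of their kinetic
constants: each replicate perturbs every constant multiplicatively
(relative amplitude sigma), simulates the tissue and records the
sharpening-index trace. Replicates are paired across models — same
morphogen noise realization, same gene-noise seeds — so differences
reflect the circuit topology, not the noise draw.

``noise_grid`` maps the terminal sharpening index over gene-expression
noise d and morphogen/gene noise-amplitude ratio L = eps / d.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .morphogen import linear_profile, parametric_gradient
from .params import CircuitParams, ModelID, default_params
from .tissue import InitMode, SDEConfig, si_trace, simulate_tissue

__all__ = [
    "PerturbationConfig",
    "ComparisonReport",
    "perturb_params",
    "compare_models",
    "noise_grid",
]

#: parameters never perturbed (structural / integer constants)
_EXCLUDED = frozenset({"n", "model_id"})
_KINETIC = ("a", "a1", "b", "b1", "b2", "A", "R", "k_deg", "S", "k_selfact")


@dataclass(frozen=True)
class PerturbationConfig:
    """Multiplicative Gaussian perturbation of the kinetic constants.

    Each selected parameter p is replaced by ``p * max(0.01, 1 + sigma * xi)``
    with independent standard normals xi; R is additionally clipped to
    [0, 1]. The Hill coefficient n is structural and never perturbed.
    """

    sigma: float = 0.1
    n_replicates: int = 20
    which: tuple[str, ...] = _KINETIC
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        bad = set(self.which) & _EXCLUDED
        if bad:
            raise ValueError(f"cannot perturb structural parameters {sorted(bad)}")


def perturb_params(
    params: CircuitParams, cfg: PerturbationConfig, rng: np.random.Generator | None = None
) -> CircuitParams:
    """One random multiplicative perturbation of a parameter set."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    changes = {}
    for name in cfg.which:
        base = getattr(params, name)
        if base == 0.0:
            continue  # zero stays zero under multiplicative noise
        factor = max(0.01, 1.0 + cfg.sigma * rng.standard_normal())
        val = base * factor
        if name == "R":
            val = float(np.clip(val, 0.0, 1.0))
        changes[name] = val
    return params.with_(**changes)


@dataclass(frozen=True)
class ComparisonReport:
    """Per-model sharpening-index summaries of a paired comparison."""

    times: np.ndarray
    traces: dict[str, np.ndarray]  # model -> (n_replicates, n_times) SI
    n_lost_bistability: dict[str, int]
    seed: int

    def mean_trace(self, model: str) -> np.ndarray:
        return self.traces[model].mean(axis=0)

    def sem_trace(self, model: str) -> np.ndarray:
        t = self.traces[model]
        return t.std(axis=0, ddof=1) / np.sqrt(t.shape[0])

    def median_trace(self, model: str) -> np.ndarray:
        return np.median(self.traces[model], axis=0)

    def terminal_mean(self, model: str) -> float:
        return float(self.mean_trace(model)[-1])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for model, tr in self.traces.items():
            for r in range(tr.shape[0]):
                for t_idx, t in enumerate(self.times):
                    rows.append(
                        {
                            "model": model,
                            "replicate": r,
                            "time": t,
                            "si": tr[r, t_idx],
                        }
                    )
        return pd.DataFrame(rows)


def _mid_m_bistable(params: CircuitParams) -> bool:
    from .models import stable_states
    from .params import REFERENCE_MORPHOGEN_LEVELS

    m_mid = REFERENCE_MORPHOGEN_LEVELS[params.model_id][1]
    try:
        states = stable_states(params, m_mid)
    except Exception:
        return False
    return "X" in states and "Y" in states


def compare_models(
    models: Sequence[ModelID | str] = (ModelID.MRSA, ModelID.SA, ModelID.MR),
    grid: tuple[int, int] = (10, 30),
    sde_cfg: SDEConfig | None = None,
    pert_cfg: PerturbationConfig | None = None,
    profile: Callable | None = None,
    check_bistability: bool = False,
) -> ComparisonReport:
    """Paired sharpening-index comparison of the circuit topologies.

    For every replicate, each model's calibrated constants are
    independently perturbed, but the tissue seed (hence the morphogen
    readout and gene noise streams) is shared across models.
    Replicates whose perturbed set lost mid-gradient bistability are
    kept and counted (only when ``check_bistability`` is set; the
    fixed-point solve is not free).
    """
    sde_cfg = sde_cfg or SDEConfig()
    pert_cfg = pert_cfg or PerturbationConfig()
    profile = profile or linear_profile()
    model_ids = [ModelID[m.upper()] if isinstance(m, str) else m for m in models]

    ss = np.random.SeedSequence(pert_cfg.seed)
    rep_seeds = ss.spawn(pert_cfg.n_replicates)
    n_times = len(sde_cfg.save_times)
    traces = {m.name: np.empty((pert_cfg.n_replicates, n_times)) for m in model_ids}
    lost = {m.name: 0 for m in model_ids}
    field = parametric_gradient(profile, 0.0, n_columns=grid[1], n_times=1, seed=0)

    for r, rep_ss in enumerate(rep_seeds):
        tissue_seed, pert_seed = (
            int(s.generate_state(1)[0] % (2**31)) for s in rep_ss.spawn(2)
        )
        prng = np.random.default_rng(pert_seed)
        for mid in model_ids:
            pert = perturb_params(default_params(mid), pert_cfg, prng)
            if check_bistability and not _mid_m_bistable(pert):
                lost[mid.name] += 1
            state = simulate_tissue(
                pert, field, grid, replace(sde_cfg, seed=tissue_seed)
            )
            traces[mid.name][r] = si_trace(state).si

    return ComparisonReport(
        times=np.asarray(sde_cfg.save_times, dtype=float),
        traces=traces,
        n_lost_bistability=lost,
        seed=pert_cfg.seed,
    )


def noise_grid(
    model: ModelID | str,
    d_values: Sequence[float],
    L_values: Sequence[float],
    grid: tuple[int, int] = (10, 30),
    sde_cfg: SDEConfig | None = None,
    n_replicates: int = 10,
    seed: int = 0,
    profile: Callable | None = None,
) -> pd.DataFrame:
    """Terminal mean SI over the (d, L) noise plane (eps_m = L * d).

    Replicate seeds are shared across grid cells, so the matrix is a
    paired design. Returns a tidy DataFrame (d, L, eps, si_mean, si_sem).
    """
    params = default_params(model)
    sde_cfg = sde_cfg or SDEConfig()
    profile = profile or linear_profile()
    ss = np.random.SeedSequence(seed)
    rep_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_replicates)]
    field = parametric_gradient(profile, 0.0, n_columns=grid[1], n_times=1, seed=0)
    rows = []
    for d in d_values:
        for L in L_values:
            eps = float(L) * float(d)
            terminal = []
            for tissue_seed in rep_seeds:
                state = simulate_tissue(
                    params,
                    field,
                    grid,
                    replace(sde_cfg, d=float(d), eps_m=eps, seed=tissue_seed),
                )
                terminal.append(si_trace(state).terminal())
            terminal = np.asarray(terminal, dtype=float)
            rows.append(
                {
                    "d": d,
                    "L": L,
                    "eps": eps,
                    "si_mean": terminal.mean(),
                    "si_sem": (
                        terminal.std(ddof=1) / np.sqrt(len(terminal))
                        if len(terminal) > 1
                        else np.nan
                    ),
                }
            )
    return pd.DataFrame(rows)
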