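"""Circuit parameter sets for the two-gene boundary-sharpening motifs.

Four circuit variants are supported:

``MRSA``
    Mutual repression with self-activation. Both genes self-activate,
    mutually repress, and are activated by a single morphogen M.
``SA``
    Self-activation only on gene Y; gene X keeps the repressive input
    from Y but has no self-activation term.
``MR``
    Pure mutual repression (a toggle switch) driven by the morphogen.
``MRSA_CROSS``
    The MRSA circuit driven by two opposed morphogen gradients, M1
    acting on gene X and M2 on gene Y.

The canonical default parameter sets live in ``data/circuits.toml``.
They were produced by the seeded calibration script shipped with the
repository (``scripts/calibrate.py``), which pins the published kinetic
constants and tunes the remaining ones so that every variant traverses
the regime sequence balanced bistable -> asymmetric bistable ->
monostable (Y) as its morphogen input sweeps the reference levels.
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, field, replace
from enum import IntEnum
from importlib import resources
from pathlib import Path

import numpy as np

__all__ = [
    "ModelID",
    "CircuitParams",
    "GeneState",
    "default_params",
    "load_params",
    "REFERENCE_MORPHOGEN_LEVELS",
]


class ModelID(IntEnum):
    """Integer codes for the circuit variants (used by the numba kernels)."""

    MRSA = 0
    SA = 1
    MR = 2
    MRSA_CROSS = 3


#: Morphogen levels at which each variant's landscape is inspected:
#: low (balanced bistable), mid (asymmetric bistable), high (monostable Y).
REFERENCE_MORPHOGEN_LEVELS = {
    ModelID.MRSA: (0.5, 0.8, 1.2),
    ModelID.SA: (0.4, 0.6, 1.2),
    ModelID.MR: (0.2, 0.4, 0.8),
    ModelID.MRSA_CROSS: ((1.0, 0.38), (0.61, 0.61), (0.38, 1.0)),
}


@dataclass(frozen=True)
class GeneState:
    """Expression levels of the two genes (concentrations, >= 0)."""

    X: float
    Y: float

    def __post_init__(self) -> None:
        if self.X < 0 or self.Y < 0:
            raise ValueError(f"expression levels must be non-negative, got {self}")

    def as_array(self) -> np.ndarray:
        return np.array([self.X, self.Y], dtype=float)


@dataclass(frozen=True)
class CircuitParams:
    """Kinetic constants of one circuit variant.

    Parameters
    ----------
    model_id
        Which circuit variant the constants belong to.
    a
        Basal synthesis scale (concentration / time).
    a1
        Morphogen-activation strength (concentration / time).
    b
        Basal-synthesis coefficient (dimensionless). Gene X receives
        ``b / A``, gene Y receives ``b`` (MRSA / MR variants).
    b1, b2
        Basal coefficients of the SA variant (X and Y respectively);
        unused by the other variants.
    A
        Synthesis-rate asymmetry ratio; ``A > 1`` favours gene Y.
    R
        Mutual-inhibition strength in ``[0, 1]``; ``R = 0`` removes the
        cross-repression, ``R = 1`` allows complete shut-off.
    k_deg
        First-order degradation rate (1 / time).
    S
        Hill threshold of every sigmoidal regulation term.
    n
        Hill coefficient (integer >= 1).
    k_selfact
        Multiplicative gain on the self-activation Hill term. This is
        the "self-activation strength" swept for the SA variant;
        defaults to 1 (the equations as written).
    """

    model_id: ModelID
    a: float
    a1: float
    b: float = 0.0
    b1: float = 0.0
    b2: float = 0.0
    A: float = 1.0
    R: float = 0.0
    k_deg: float = 1.0
    S: float = 0.5
    n: int = 4
    k_selfact: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.R <= 1.0):
            raise ValueError(f"R must lie in [0, 1], got {self.R}")
        for name in ("a", "a1", "b", "b1", "b2"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        for name in ("A", "k_deg", "S", "k_selfact"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.n < 1 or int(self.n) != self.n:
            raise ValueError(f"Hill coefficient n must be an integer >= 1, got {self.n}")

    # -- numba interface ------------------------------------------------
    def as_vector(self) -> np.ndarray:
        """Pack the constants into the flat float64 layout of the kernels."""
        return np.array(
            [
                self.a,
                self.a1,
                self.b,
                self.b1,
                self.b2,
                self.A,
                self.R,
                self.k_deg,
                self.S,
                float(self.n),
                self.k_selfact,
            ],
            dtype=np.float64,
        )

    def with_(self, **changes) -> "CircuitParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **changes)

    @property
    def needs_two_morphogens(self) -> bool:
        return self.model_id == ModelID.MRSA_CROSS

    def synthesis_bound(self) -> float:
        """Upper bound on the total synthesis rate of either gene.

        Outside the box ``[0, synthesis_bound()/k_deg]**2`` both drift
        components point inward (trapping region).
        """
        if self.model_id == ModelID.SA:
            basal = self.a * max(self.b1, self.b2 + self.k_selfact)
        else:
            basal = self.a * (max(self.b, self.b / self.A) + self.k_selfact)
        return basal + self.a1

    def trapping_box(self) -> float:
        """Side length of the invariant (trapping) box ``[0, L]**2``."""
        return self.synthesis_bound() / self.k_deg


_FIELDS = ("a", "a1", "b", "b1", "b2", "A", "R", "k_deg", "S", "n", "k_selfact")


def load_params(path: str | Path) -> dict[ModelID, CircuitParams]:
    """Read parameter sets from a TOML config (one table per variant)."""
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    return _from_mapping(raw)


def _from_mapping(raw: dict) -> dict[ModelID, CircuitParams]:
    out: dict[ModelID, CircuitParams] = {}
    for name, table in raw.items():
        mid = ModelID[name.upper()]
        kwargs = {k: table[k] for k in _FIELDS if k in table}
        out[mid] = CircuitParams(model_id=mid, **kwargs)
    return out


def _load_defaults() -> dict[ModelID, CircuitParams]:
    src = resources.files("boundsharp.data").joinpath("circuits.toml")
    with src.open("rb") as fh:
        raw = tomllib.load(fh)
    return _from_mapping(raw)


_DEFAULTS: dict[ModelID, CircuitParams] | None = None


def default_params(model: ModelID | str) -> CircuitParams:
    """Return the shipped calibrated parameter set for a circuit variant."""
    global _DEFAULTS
    if _DEFAULTS is None:
        _DEFAULTS = _load_defaults()
    if isinstance(model, str):
        model = ModelID[model.upper()]
    return _DEFAULTS[model]
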