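"""Model parameters and fixed simulation constants.

The agent-based model has six free parameters, fitted by maximum
likelihood; everything else (gap-junction threshold, simulation tails,
time step) is a fixed constant recorded alongside every result.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from typing import Iterator

import numpy as np

#: Order of the free parameters everywhere a flat vector is used.
PARAM_NAMES: tuple[str, ...] = (
    "strain_threshold",   # T^eps_x, microstrain
    "er_capacity",        # ER^0, % (maximal ER Ca2+ store capacity)
    "er_recovery",        # R^0, %/s (maximal store refill rate)
    "nfat_memory",        # alpha, dimensionless in [0, 1]
    "nfat_capacity",      # NFAT^n_x, %*s (nuclear NFAT DNA-binding capacity)
    "mar_max",            # r.MAR_x, um/d (maximal relative apposition rate)
)

#: Admissible box used for estimation (lower, upper) per parameter.
PARAM_BOUNDS: dict[str, tuple[float, float]] = {
    "strain_threshold": (0.0, 5500.0),
    "er_capacity": (0.0, 50000.0),
    "er_recovery": (0.0, 200.0),
    "nfat_memory": (0.0, 1.0),
    "nfat_capacity": (0.0, 1.0e7),
    "mar_max": (0.0, 50.0),
}


@dataclass(frozen=True)
class ParameterVector:
    """The six free parameters of the Ca2+/NFAT pathway model.

    Units: ``strain_threshold`` microstrain; ``er_capacity`` percent;
    ``er_recovery`` percent/s; ``nfat_memory`` dimensionless;
    ``nfat_capacity`` percent-seconds; ``mar_max`` um/day.
    """

    strain_threshold: float
    er_capacity: float
    er_recovery: float
    nfat_memory: float
    nfat_capacity: float
    mar_max: float

    def __post_init__(self) -> None:
        for name in PARAM_NAMES:
            lo, hi = PARAM_BOUNDS[name]
            v = getattr(self, name)
            if not np.isfinite(v) or v < lo or v > hi:
                raise ValueError(
                    f"parameter {name}={v!r} outside admissible range [{lo}, {hi}]"
                )

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PARAM_NAMES], dtype=float)

    @classmethod
    def from_array(cls, arr) -> "ParameterVector":
        arr = np.asarray(arr, dtype=float)
        if arr.shape != (len(PARAM_NAMES),):
            raise ValueError(f"expected {len(PARAM_NAMES)} parameters, got {arr.shape}")
        return cls(**dict(zip(PARAM_NAMES, arr.tolist())))

    def replace(self, **kwargs) -> "ParameterVector":
        return replace(self, **kwargs)

    def to_dict(self) -> dict[str, float]:
        return asdict(self)

    def __iter__(self) -> Iterator[float]:
        return iter(self.to_array())


@dataclass(frozen=True)
class SimConstants:
    """Fixed constants of the simulation, identical across calibration.

    ``gj_threshold`` is the minimal averaged incoming Ca2+ level (percent)
    required to initiate oscillations in a recipient cell.  ``ca_tail_s``
    extends the Ca2+ simulation past the end of a loading bout so cell-cell
    cross-talk can unfold; ``nfat_tail_s`` extends NFAT dephosphorylation
    past the cessation of Ca2+ oscillations.  ``nfat_gain`` is the
    translocation scale k_t (fraction of the instantaneous Ca2+ level fed
    into the dephosphorylated pool per second).
    """

    gj_threshold: float = 2.5     # %
    ca_tail_s: int = 200          # s
    nfat_tail_s: int = 100        # s
    dt: float = 1.0               # s; the model's smallest time unit
    nfat_gain: float = 0.05       # per s
    nfatd_max: float = 100.0      # % saturation of the dephosphorylated pool
    strain_on_precursors: bool = False  # strain influx applies to osteocytes only
    sigmoidal_mar: bool = False   # optional smooth variant of the r.MAR law

    def to_dict(self) -> dict:
        return asdict(self)


#: Fitted optima for the young-adult network (shipped fixture).
YOUNG_MLE = ParameterVector(
    strain_threshold=2524.0,
    er_capacity=9430.0,
    er_recovery=1.79,
    nfat_memory=0.873,
    nfat_capacity=239610.0,
    mar_max=2.58,
)

#: Fitted optima for the senescent (aged) network (shipped fixture).
AGED_MLE = ParameterVector(
    strain_threshold=2619.0,
    er_capacity=9215.0,
    er_recovery=1.03,
    nfat_memory=0.684,
    nfat_capacity=130550.0,
    mar_max=2.03,
)

FIXTURES: dict[str, ParameterVector] = {"young_mle": YOUNG_MLE, "aged_mle": AGED_MLE}

def bounds_array() -> np.ndarray:
    """Bounds as a (6, 2) array in :data:`PARAM_NAMES` order."""
    return np.array([PARAM_BOUNDS[n] for n in PARAM_NAMES], dtype=float)
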