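"""Tissue-level relative bone-formation indices from per-cell outcomes.

Mirrors dynamic histomorphometry: the relative mineralizing surface
(r.MS/BS) is the fraction of a surface's osteoblasts with non-zero
apposition, tissue r.MAR is the mean over the non-zero subset, and the
surface-referent formation rate is their product, r.BFR/BS = r.MS/BS x
r.MAR.  Only periosteal outcomes are validated against data; endocortical
outcomes are computed but the model is not expected to predict them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: Absolute tolerance below which an apposition rate counts as zero.
ZERO_TOL = 1e-12

SURFACES = ("periosteal", "endocortical")


@dataclass(frozen=True)
class TissueOutcome:
    surface: str
    rms_bs: float      # fraction of surface osteoblasts mineralizing
    rmar: float        # um/d, mean over the mineralizing subset
    rbfr_bs: float     # um/d, surface-referent product

    def __post_init__(self):
        if self.surface not in SURFACES:
            raise ValueError(f"unknown surface {self.surface!r}")


def protocol_rmar(per_bout_rmar, n_bouts: int | None = None) -> np.ndarray:
    """Per-precursor r.MAR over a protocol: the mean across its bouts.

    ``per_bout_rmar`` is (n_bouts, n_precursors) or (n_precursors,) for the
    stationary case where every bout is identical (repeated loading is
    assumed not to alter the cells, so the mean equals the single-bout
    value; ``n_bouts`` is then irrelevant and only validated).
    """
    arr = np.atleast_2d(np.asarray(per_bout_rmar, dtype=float))
    if n_bouts is not None and n_bouts < 1:
        raise ValueError("n_bouts must be >= 1")
    return arr.mean(axis=0)


def tissue_outcomes(rmar, surfaces) -> dict[str, TissueOutcome]:
    """Aggregate per-precursor r.MAR into per-surface tissue indices."""
    rmar = np.asarray(rmar, dtype=float)
    surfaces = np.asarray(surfaces)
    unknown = set(np.unique(surfaces)) - set(SURFACES)
    if unknown:
        raise ValueError(f"unknown surface label(s): {sorted(unknown)}")
    out: dict[str, TissueOutcome] = {}
    for surface in SURFACES:
        vals = rmar[surfaces == surface]
        if vals.size == 0:
            continue
        active = vals > ZERO_TOL
        rms_bs = float(active.mean())
        mean_active = float(vals[active].mean()) if active.any() else 0.0
        out[surface] = TissueOutcome(surface, rms_bs, mean_active,
                                     rms_bs * mean_active)
    if not out:
        raise ValueError("no precursors on any known surface")
    return out


def outcomes_frame(outcomes_by_protocol: dict[str, dict[str, TissueOutcome]]
                   ) -> pd.DataFrame:
    """Flatten {protocol_id: {surface: TissueOutcome}} to the outcome CSV
    dialect (protocol_id, surface, rMS_BS, rMAR_um_d, rBFR_BS_um_d)."""
    rows = [
        (pid, o.surface, o.rms_bs, o.rmar, o.rbfr_bs)
        for pid, per_surface in outcomes_by_protocol.items()
        for o in per_surface.values()
    ]
    return pd.DataFrame(
        rows, columns=["protocol_id", "surface", "rMS_BS", "rMAR_um_d",
                       "rBFR_BS_um_d"])
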