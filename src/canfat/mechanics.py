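"""Loading protocols and their expansion into per-cell strain timelines.

Loading is applied at 1 Hz, so each load cycle occupies exactly one 1-s
time step at the full peak magnitude; rest-inserted protocols interleave
``rest_interval`` unloaded seconds between consecutive cycles.  Tissue
strain across the cross-section follows an idealized beam-bending field:
linear in the distance from a neutral axis through the centroid, scaled so
the extreme periosteal fiber sees the protocol's peak strain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .network import CellNetwork


@dataclass(frozen=True)
class LoadingProtocol:
    """One loading protocol: peak strain (microstrain), cycle count per
    daily bout, rest interval (s) between cycles, bouts/week and weeks."""

    id: str
    peak_strain: float          # microstrain at the periosteal surface
    cycles_per_day: int
    rest_interval: float = 0.0  # s
    bouts_per_week: int = 3
    n_weeks: int = 3
    frequency: float = 1.0      # Hz, fixed

    def __post_init__(self):
        if self.peak_strain < 0:
            raise ValueError("peak_strain must be >= 0")
        if self.cycles_per_day < 1:
            raise ValueError("cycles_per_day must be >= 1")
        if self.rest_interval < 0:
            raise ValueError("rest_interval must be >= 0")
        if self.rest_interval != int(self.rest_interval):
            raise ValueError("rest_interval must be a whole number of seconds")
        if self.frequency != 1.0:
            raise ValueError("only 1 Hz loading is supported (1 s resolution)")

    @property
    def n_bouts(self) -> int:
        return self.bouts_per_week * self.n_weeks

    @property
    def t_bout(self) -> int:
        """Bout duration in seconds: cycles + (cycles-1) * rest."""
        c = self.cycles_per_day
        return int(c + (c - 1) * self.rest_interval)


def protocol_timeline(protocol: LoadingProtocol) -> np.ndarray:
    """Per-second load indicator w(t), t = 1..t_bout.

    ``w[t-1] = 1`` on loaded seconds; exactly ``cycles_per_day`` entries are
    1, separated by ``rest_interval`` zeros.  (t = 0 is the zero-strain
    initialization step and is not part of this array.)
    """
    c, r = protocol.cycles_per_day, int(protocol.rest_interval)
    w = np.zeros(protocol.t_bout, dtype=np.int8)
    w[:: r + 1] = 1
    assert int(w.sum()) == c
    return w


def strain_field(
    network: CellNetwork, peak_strain: float, axis: str = "x"
) -> tuple[np.ndarray, np.ndarray]:
    """Per-cell strain scale s_i in [0, 1] and strain magnitude (microstrain).

    Bending about a neutral axis through the centroid: with medio-lateral
    loading (default) the neutral axis is the y-axis and strain grows
    linearly with |x|, normalized by the extreme periosteal fiber.  Strain
    magnitude is used (tension and compression are not distinguished).
    Precursors receive a scale for reporting, but the Ca2+ drive applies
    to osteocytes only (see :mod:`canfat.abm`).
    """
    if not network.cells:
        raise ValueError("network has no cells")
    if peak_strain < 0:
        raise ValueError("peak_strain must be >= 0")
    pos = network.positions()
    cx, cy = network.geometry.centroid
    if axis == "x":
        dist = np.abs(pos[:, 0] - cx)
        dist_max = network.geometry.outer_a
    elif axis == "y":
        dist = np.abs(pos[:, 1] - cy)
        dist_max = network.geometry.outer_b
    else:
        raise ValueError(f"axis must be 'x' or 'y', got {axis!r}")
    if dist_max <= 0:
        raise ValueError("degenerate geometry: zero extreme-fiber distance")
    scale = np.clip(dist / dist_max, 0.0, 1.0)
    return scale, peak_strain * scale


# ---------------------------------------------------------------------------
# protocol table I/O

_COLUMNS = ["id", "peak_strain_ue", "cycles_per_day", "rest_interval_s",
            "bouts_per_week", "n_weeks"]


def protocols_to_frame(protocols: list[LoadingProtocol]) -> pd.DataFrame:
    return pd.DataFrame(
        [(p.id, p.peak_strain, p.cycles_per_day, p.rest_interval,
          p.bouts_per_week, p.n_weeks) for p in protocols],
        columns=_COLUMNS,
    )


def frame_to_protocols(df: pd.DataFrame) -> list[LoadingProtocol]:
    missing = set(_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"protocol table missing columns: {sorted(missing)}")
    return [
        LoadingProtocol(
            id=str(r.id), peak_strain=float(r.peak_strain_ue),
            cycles_per_day=int(r.cycles_per_day),
            rest_interval=float(r.rest_interval_s),
            bouts_per_week=int(r.bouts_per_week), n_weeks=int(r.n_weeks),
        )
        for r in df.itertuples(index=False)
    ]


def read_protocols(path) -> list[LoadingProtocol]:
    return frame_to_protocols(pd.read_csv(path))


def write_protocols(protocols: list[LoadingProtocol], path) -> None:
    protocols_to_frame(protocols).to_csv(path, index=False)
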