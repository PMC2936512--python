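"""Agent-based Ca2+/ER-store/NFAT dynamics over a loading bout.

Every cell carries an instantaneous intracellular Ca2+ level (percent of
maximal), an ER Ca2+ store, and — for surface precursors — a
dephosphorylated cytoplasmic NFAT pool plus the nuclear NFAT accumulated
over the bout.  The update is synchronous at 1-s steps:

* osteocytes receive a sigmoidal strain drive (0–100 %) that saturates at
  the threshold strain ``strain_threshold``;
* every cell receives a gap-junction drive equal to the mean of its
  coupled neighbors' previous-step Ca2+, gated below ``gj_threshold``;
* Ca2+ release is the total drive scaled by the current store filling
  ``ER/ER0``; the store loses what is released and, when the cell is
  quiescent (zero drive), refills SERCA-like at rate ``R0 * (1 - ER/ER0)``;
* precursor NFATd integrates Ca2+ with geometric memory ``alpha`` and
  gain ``k_t``; nuclear NFAT accumulates NFATd second by second.

Ca2+ is simulated for 200 s past the end of the bout, and NFAT
dephosphorylation for a further 100 s, before nuclear NFAT is mapped to a
relative mineral apposition rate saturating at ``mar_max``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit

from .mechanics import LoadingProtocol, protocol_timeline, strain_field
from .network import CellNetwork
from .params import ParameterVector, SimConstants


def smoothstep(u):
    """Cubic sigmoid 3u^2 - 2u^3 clamped to [0, 1]."""
    u = np.clip(u, 0.0, 1.0)
    return u * u * (3.0 - 2.0 * u)


def ca_drive_from_strain(strain, strain_threshold: float):
    """Sigmoidal strain dose-response, percent of maximal Ca2+ amplitude.

    0 at zero strain, exactly 100 % at or above the threshold strain.  A
    zero threshold is the knock-out limit: any positive strain saturates.
    """
    strain = np.asarray(strain, dtype=float)
    if strain_threshold <= 0.0:
        out = np.where(strain > 0, 100.0, 0.0)
    else:
        out = 100.0 * smoothstep(strain / strain_threshold)
    return out if out.ndim else float(out)


def gap_junction_drive(neighbor_ca, gj_threshold: float = 2.5) -> float:
    """Averaged incoming Ca2+ from coupled neighbors, gated at the
    initiation threshold; 0 for an isolated cell."""
    arr = np.asarray(neighbor_ca, dtype=float)
    if arr.size == 0:
        return 0.0
    m = float(arr.mean())
    return m if m >= gj_threshold else 0.0


def step_cell(ca, er, strain_drive, gj_drive, theta: ParameterVector,
              constants: SimConstants = SimConstants()) -> tuple[float, float]:
    """One 1-s update of a single cell's (Ca, ER) given its total drive."""
    er0, r0, dt = theta.er_capacity, theta.er_recovery, constants.dt
    drive = min(max(strain_drive + gj_drive, 0.0), 100.0)
    if drive > 0.0:
        ca_next = drive * (er / er0) if er0 > 0 else 0.0
        er_next = max(0.0, er - ca_next * dt)
    else:
        ca_next = 0.0
        er_next = min(er0, er + r0 * (1.0 - er / er0) * dt) if er0 > 0 else 0.0
    return ca_next, er_next


def step_nfat(nfatd, ca, alpha: float,
              constants: SimConstants = SimConstants()) -> float:
    """Leaky-integrator NFAT dephosphorylation: geometric memory ``alpha``
    plus translocation gain ``k_t`` times the current Ca2+ level."""
    return min(constants.nfatd_max, alpha * nfatd + constants.nfat_gain * ca)


def accumulate_nuclear_nfat(nfatn, nfatd, dt: float = 1.0) -> float:
    return nfatn + nfatd * dt


def rmar_from_nfat(nfatn, nfat_capacity: float, mar_max: float,
                   sigmoidal: bool = False):
    """Map accumulated nuclear NFAT to a relative mineral apposition rate.

    Saturating-linear by default; zero capacity is the binary on/off
    knock-out limit (full rate for any positive nuclear NFAT).
    """
    nfatn = np.asarray(nfatn, dtype=float)
    if nfat_capacity <= 0.0:
        out = np.where(nfatn > 0, mar_max, 0.0)
    elif sigmoidal:
        out = mar_max * smoothstep(nfatn / nfat_capacity)
    else:
        out = mar_max * np.minimum(1.0, nfatn / nfat_capacity)
    return out if out.ndim else float(out)


def _bout_impl(w, strain_drive, indptr, indices, is_prec,
               er0, r0, alpha, gj_thr, k_t, nfatd_max, dt,
               ca_tail, nfat_tail, do_trace, tr_ca, tr_er, tr_nd, tr_nn):
    n = strain_drive.shape[0]
    ca = np.zeros(n)
    ca_prev = np.zeros(n)
    er = np.full(n, er0)
    nfatd = np.zeros(n)
    nfatn = np.zeros(n)
    t_load = w.shape[0]
    t_ca = t_load + ca_tail
    if do_trace:
        for i in range(n):
            tr_er[0, i] = er0
    allzero_prev = True
    for t in range(1, t_ca + nfat_tail + 1):
        if t <= t_ca:
            wt = w[t - 1] if t - 1 < t_load else 0.0
            if allzero_prev and wt == 0.0:
                # fully quiescent step: no release anywhere, stores refill
                if not do_trace and t > t_load:
                    # Ca2+ stays zero for the rest of the simulation; the
                    # remaining NFAT dynamics is pure geometric decay
                    # (identical arithmetic to the stepped path)
                    for i in range(n):
                        if is_prec[i]:
                            nd = nfatd[i]
                            nn = nfatn[i]
                            for _ in range(t, t_ca + nfat_tail + 1):
                                nd = alpha * nd
                                nn += nd * dt
                            nfatd[i] = nd
                            nfatn[i] = nn
                    return nfatn
                if er0 > 0.0 and r0 > 0.0:
                    for i in range(n):
                        er[i] += r0 * (1.0 - er[i] / er0) * dt
                        if er[i] > er0:
                            er[i] = er0
            else:
                allzero = True
                for i in range(n):
                    lo, hi = indptr[i], indptr[i + 1]
                    gj = 0.0
                    if hi > lo:
                        s = 0.0
                        for k in range(lo, hi):
                            s += ca_prev[indices[k]]
                        m = s / (hi - lo)
                        if m >= gj_thr:
                            gj = m
                    drive = strain_drive[i] * wt + gj
                    if drive > 100.0:
                        drive = 100.0
                    if drive > 0.0:
                        newca = drive * (er[i] / er0) if er0 > 0.0 else 0.0
                        er[i] -= newca * dt
                        if er[i] < 0.0:
                            er[i] = 0.0
                        ca[i] = newca
                        if newca != 0.0:
                            allzero = False
                    else:
                        ca[i] = 0.0
                        if er0 > 0.0 and r0 > 0.0:
                            er[i] += r0 * (1.0 - er[i] / er0) * dt
                            if er[i] > er0:
                                er[i] = er0
                for i in range(n):
                    ca_prev[i] = ca[i]
                allzero_prev = allzero
        else:
            # Ca2+ oscillations have ceased; only NFAT keeps evolving.
            for i in range(n):
                ca[i] = 0.0
        for i in range(n):
            if is_prec[i]:
                nd = alpha * nfatd[i] + k_t * ca[i]
                nfatd[i] = nd if nd < nfatd_max else nfatd_max
                nfatn[i] += nfatd[i] * dt
        if do_trace:
            for i in range(n):
                tr_ca[t, i] = ca[i]
                tr_er[t, i] = er[i]
                tr_nd[t, i] = nfatd[i]
                tr_nn[t, i] = nfatn[i]
    return nfatn


_run_bout = njit(cache=False)(_bout_impl)


@dataclass
class BoutResult:
    """Per-precursor outcome of one loading bout."""

    precursor_ids: np.ndarray       # cell ids of precursors
    surfaces: np.ndarray            # "periosteal" / "endocortical"
    nfat_nuclear: np.ndarray        # %*s accumulated over the bout
    rmar: np.ndarray                # um/d
    trace_arrays: dict | None = None    # cell_ids + (T+1, n) Ca/ER/NFATd/NFATn

    @property
    def trace(self) -> pd.DataFrame | None:
        """Per-cell time series as a long table (t, cell_id, Ca, ER,
        NFATd, NFATn); built on demand from the trace arrays."""
        if self.trace_arrays is None:
            return None
        ta = self.trace_arrays
        t_total, n = ta["Ca"].shape
        return pd.DataFrame({
            "t": np.repeat(np.arange(t_total), n),
            "cell_id": np.tile(ta["cell_ids"], t_total),
            "Ca": ta["Ca"].ravel(), "ER": ta["ER"].ravel(),
            "NFATd": ta["NFATd"].ravel(), "NFATn": ta["NFATn"].ravel(),
        })

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "precursor_id": self.precursor_ids,
            "surface": self.surfaces,
            "NFATn": self.nfat_nuclear,
            "rMAR": self.rmar,
        })


def _csr_adjacency(network: CellNetwork) -> tuple[np.ndarray, np.ndarray]:
    idx = {c.id: i for i, c in enumerate(network.cells)}
    n = len(network.cells)
    neigh: list[list[int]] = [[] for _ in range(n)]
    for a, b in network.adjacency:
        ia, ib = idx[a], idx[b]
        neigh[ia].append(ib)
        neigh[ib].append(ia)
    indptr = np.zeros(n + 1, dtype=np.int64)
    for i, lst in enumerate(neigh):
        lst.sort()
        indptr[i + 1] = indptr[i] + len(lst)
    indices = np.zeros(indptr[-1], dtype=np.int64)
    for i, lst in enumerate(neigh):
        indices[indptr[i]:indptr[i + 1]] = lst
    return indptr, indices


def simulate_bout(
    network: CellNetwork,
    protocol: LoadingProtocol,
    theta: ParameterVector,
    constants: SimConstants = SimConstants(),
    trace: bool = False,
    _cache: dict | None = None,
) -> BoutResult:
    """Run one loading bout and return per-precursor nuclear NFAT and r.MAR.

    ``_cache`` may hold precomputed network structure (CSR adjacency and
    strain scales) to amortize repeated simulation of the same network.
    """
    cache = _cache if _cache is not None else {}
    if "csr" not in cache:
        cache["csr"] = _csr_adjacency(network)
        cache["scale"], _ = strain_field(network, 1.0)
        cache["is_prec"] = np.array(
            [c.kind == "precursor" for c in network.cells], dtype=np.bool_)
    indptr, indices = cache["csr"]
    is_prec = cache["is_prec"]
    strain = protocol.peak_strain * cache["scale"]
    drive = np.asarray(ca_drive_from_strain(strain, theta.strain_threshold),
                       dtype=float)
    if not constants.strain_on_precursors:
        drive = np.where(is_prec, 0.0, drive)
    w = protocol_timeline(protocol).astype(np.float64)
    n = len(network.cells)
    t_total = len(w) + constants.ca_tail_s + constants.nfat_tail_s
    if trace:
        shape = (t_total + 1, n)
        tr = tuple(np.zeros(shape) for _ in range(4))
    else:
        tr = tuple(np.zeros((1, 1)) for _ in range(4))
    nfatn = _run_bout(
        w, drive, indptr, indices, is_prec,
        float(theta.er_capacity), float(theta.er_recovery),
        float(theta.nfat_memory), float(constants.gj_threshold),
        float(constants.nfat_gain), float(constants.nfatd_max),
        float(constants.dt), int(constants.ca_tail_s),
        int(constants.nfat_tail_s), trace, *tr,
    )
    prec_mask = is_prec
    prec_ids = np.array([c.id for c in network.cells])[prec_mask]
    surfaces = np.array([c.surface for c in network.cells])[prec_mask]
    nn = nfatn[prec_mask]
    rmar = np.asarray(
        rmar_from_nfat(nn, theta.nfat_capacity, theta.mar_max,
                       constants.sigmoidal_mar), dtype=float)
    trace_arrays = None
    if trace:
        trace_arrays = {
            "cell_ids": np.array([c.id for c in network.cells]),
            "Ca": tr[0], "ER": tr[1], "NFATd": tr[2], "NFATn": tr[3],
        }
    return BoutResult(prec_ids, surfaces, nn, rmar, trace_arrays)


def cycle_peaks(
    network: CellNetwork,
    protocol: LoadingProtocol,
    theta: ParameterVector,
    constants: SimConstants = SimConstants(),
) -> np.ndarray:
    """Per-cycle, per-cell Ca2+ amplitude over a bout.

    Entry (k, i) is cell i's peak Ca2+ in the window from load cycle k to
    the next cycle (the last window extends through the simulation tail).
    Comparing successive rows of this matrix is how secondary transients —
    post-rest amplitudes exceeding the pre-rest amplitude, enabled by
    store recovery during rest intervals — are detected.
    """
    res = simulate_bout(network, protocol, theta, constants, trace=True)
    ca = res.trace_arrays["Ca"]
    loaded = np.flatnonzero(protocol_timeline(protocol)) + 1
    bounds = np.append(loaded, ca.shape[0])
    return np.array([
        ca[bounds[k]:bounds[k + 1]].max(axis=0) for k in range(len(loaded))
    ])
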