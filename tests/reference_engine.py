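"""Naive, independently coded reference simulator for tiny networks.

Implements the documented cell-update rules with plain Python dictionaries
and per-cell loops — no numpy vectorization, no compiled kernel — so the
production engine can be checked against it step by step on networks of a
few cells.
"""

from __future__ import annotations

import math


def strain_dose(strain: float, threshold: float) -> float:
    """Sigmoidal (smoothstep) strain dose-response on 0..100 %."""
    if threshold <= 0:
        return 100.0 if strain > 0 else 0.0
    u = strain / threshold
    if u <= 0:
        return 0.0
    if u >= 1:
        return 100.0
    return 100.0 * (u * u * (3.0 - 2.0 * u))


def simulate_reference(
    cells: list[dict],
    neighbors: dict[int, list[int]],
    load_pattern: list[int],
    peak_strain: float,
    scales: dict[int, float],
    theta: dict,
    gj_threshold: float = 2.5,
    ca_tail: int = 200,
    nfat_tail: int = 100,
    k_t: float = 0.05,
    nfatd_max: float = 100.0,
    strain_on_precursors: bool = False,
) -> dict[int, dict[str, list[float]]]:
    """Step a tiny network second by second.

    ``cells`` is a list of {"id": int, "kind": "osteocyte"|"precursor"};
    ``neighbors`` maps cell id to the sorted ids of its coupled partners;
    ``load_pattern`` is the 0/1 per-second load indicator for the bout.
    Returns per-cell time series including the initial state (t = 0).
    """
    er0 = theta["er_capacity"]
    r0 = theta["er_recovery"]
    alpha = theta["nfat_memory"]
    tex = theta["strain_threshold"]

    state = {}
    series = {}
    for c in cells:
        state[c["id"]] = {"ca": 0.0, "er": er0, "nfatd": 0.0, "nfatn": 0.0}
        series[c["id"]] = {"Ca": [0.0], "ER": [er0], "NFATd": [0.0],
                           "NFATn": [0.0]}
    kind = {c["id"]: c["kind"] for c in cells}

    t_ca = len(load_pattern) + ca_tail
    for t in range(1, t_ca + nfat_tail + 1):
        if t <= t_ca:
            loaded = load_pattern[t - 1] if t - 1 < len(load_pattern) else 0
            prev_ca = {i: s["ca"] for i, s in state.items()}
            for c in cells:
                i = c["id"]
                drive = 0.0
                if loaded and (kind[i] == "osteocyte" or strain_on_precursors):
                    drive += strain_dose(peak_strain * scales[i], tex)
                nbrs = neighbors.get(i, [])
                if nbrs:
                    mean_in = sum(prev_ca[j] for j in nbrs) / len(nbrs)
                    if mean_in >= gj_threshold:
                        drive += mean_in
                if drive > 100.0:
                    drive = 100.0
                s = state[i]
                if drive > 0.0:
                    new_ca = drive * (s["er"] / er0) if er0 > 0 else 0.0
                    s["er"] = max(0.0, s["er"] - new_ca)
                    s["ca"] = new_ca
                else:
                    s["ca"] = 0.0
                    if er0 > 0 and r0 > 0:
                        s["er"] = min(er0, s["er"] + r0 * (1.0 - s["er"] / er0))
        else:
            for s in state.values():
                s["ca"] = 0.0
        for c in cells:
            i = c["id"]
            s = state[i]
            if kind[i] == "precursor":
                s["nfatd"] = min(nfatd_max, alpha * s["nfatd"] + k_t * s["ca"])
                s["nfatn"] = s["nfatn"] + s["nfatd"]
            series[i]["Ca"].append(s["ca"])
            series[i]["ER"].append(s["er"])
            series[i]["NFATd"].append(s["nfatd"])
            series[i]["NFATn"].append(s["nfatn"])
    return series


def reference_rmar(nfatn: float, capacity: float, mar_max: float) -> float:
    if capacity <= 0:
        return mar_max if nfatn > 0 else 0.0
    return mar_max * min(1.0, nfatn / capacity)


def reference_load_pattern(cycles: int, rest: int) -> list[int]:
    out = []
    for k in range(cycles):
        out.append(1)
        if k < cycles - 1:
            out.extend([0] * rest)
    return out


def reference_tissue(rmars: list[float]) -> tuple[float, float, float]:
    """(r.MS/BS, r.MAR, r.BFR/BS) computed straight from the definitions."""
    active = [v for v in rmars if v > 1e-12]
    ms = len(active) / len(rmars)
    mar = sum(active) / len(active) if active else 0.0
    return ms, mar, ms * mar


def reference_loglik(groups: list[list[float]], means: list[float],
                     floor: float = 1e-8) -> float:
    """Profiled normal log-likelihood by direct summation."""
    ll = 0.0
    for y, m in zip(groups, means):
        n = len(y)
        v = max(sum((yi - m) ** 2 for yi in y) / n, floor)
        ll += -0.5 * n * math.log(2 * math.pi * v) \
              - sum((yi - m) ** 2 for yi in y) / (2 * v)
    return ll
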