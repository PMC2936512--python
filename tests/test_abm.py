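import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from canfat.abm import (accumulate_nuclear_nfat, ca_drive_from_strain,
                        cycle_peaks, gap_junction_drive, rmar_from_nfat,
                        simulate_bout, step_cell, step_nfat)
from canfat.mechanics import LoadingProtocol
from canfat.network import Cell
from canfat.params import ParameterVector, SimConstants, YOUNG_MLE

from conftest import make_toy_network
from reference_engine import (reference_load_pattern, reference_rmar,
                              simulate_reference, strain_dose)


class TestStrainDose:
    def test_anchors(self):
        assert ca_drive_from_strain(0.0, 2524.0) == 0.0
        assert ca_drive_from_strain(2524.0, 2524.0) == 100.0
        assert ca_drive_from_strain(5000.0, 2524.0) == 100.0
        assert ca_drive_from_strain(2524.0 / 2, 2524.0) == pytest.approx(50.0)

    def test_zero_threshold_knockout_semantics(self):
        assert ca_drive_from_strain(0.0, 0.0) == 0.0
        assert ca_drive_from_strain(0.001, 0.0) == 100.0

    @given(st.floats(0, 6000), st.floats(1, 5500))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_monotone_and_bounded(self, eps, tex):
        v = ca_drive_from_strain(eps, tex)
        assert 0.0 <= v <= 100.0
        assert v <= ca_drive_from_strain(eps * 1.1 + 1, tex) + 1e-9


class TestGapJunction:
    def test_empty_neighborhood(self):
        assert gap_junction_drive([]) == 0.0

    def test_averaging(self):
        assert gap_junction_drive([10.0, 20.0]) == 15.0

    def test_threshold_gating(self):
        assert gap_junction_drive([2.0, 2.0]) == 0.0      # mean 2 % < 2.5 %
        assert gap_junction_drive([2.5, 2.5]) == 2.5


class TestStepCell:
    def test_er_knockout_kills_calcium(self, young_theta):
        theta = young_theta.replace(er_capacity=0.0)
        ca, er = step_cell(0.0, 0.0, 100.0, 50.0, theta)
        assert ca == 0.0 and er == 0.0

    def test_full_store_full_drive(self, young_theta):
        ca, er = step_cell(0.0, young_theta.er_capacity, 100.0, 0.0, young_theta)
        assert ca == 100.0
        assert er == young_theta.er_capacity - 100.0

    def test_recovery_from_empty_store(self, young_theta):
        ca, er = step_cell(0.0, 0.0, 0.0, 0.0, young_theta)
        assert ca == 0.0
        assert er == pytest.approx(1.79)

    def test_no_recovery_when_r0_zero(self, young_theta):
        theta = young_theta.replace(er_recovery=0.0)
        _, er = step_cell(0.0, 100.0, 0.0, 0.0, theta)
        assert er == 100.0


class TestNFAT:
    def test_rest_state(self):
        assert step_nfat(0.0, 0.0, 0.873) == 0.0

    def test_memoryless_alpha_zero(self):
        # alpha = 0 tracks current Ca only (non-lethal knock-out)
        assert step_nfat(123.0, 40.0, 0.0) == pytest.approx(2.0)

    def test_geometric_decay(self):
        assert step_nfat(10.0, 0.0, 0.873) == pytest.approx(8.73)

    def test_accumulation(self):
        n = 0.0
        for _ in range(10):
            n = accumulate_nuclear_nfat(n, 50.0)
        assert n == 500.0


class TestRmar:
    def test_anchors(self, young_theta):
        cap, mx = young_theta.nfat_capacity, young_theta.mar_max
        assert rmar_from_nfat(0.0, cap, mx) == 0.0
        assert rmar_from_nfat(cap, cap, mx) == mx
        assert rmar_from_nfat(cap / 2, cap, mx) == pytest.approx(mx / 2)
        assert rmar_from_nfat(10 * cap, cap, mx) == mx

    def test_binary_limit(self):
        assert rmar_from_nfat(5.0, 0.0, 2.58) == 2.58
        assert rmar_from_nfat(0.0, 0.0, 2.58) == 0.0


def _engine_series(network, protocol, theta, constants=SimConstants()):
    res = simulate_bout(network, protocol, theta, constants, trace=True)
    ta = res.trace_arrays
    return {int(cid): {k: ta[k][:, i] for k in ("Ca", "ER", "NFATd", "NFATn")}
            for i, cid in enumerate(ta["cell_ids"])}


def _reference_series(network, protocol, theta, constants=SimConstants()):
    from canfat.mechanics import strain_field
    scale, _ = strain_field(network, 1.0)
    scales = {c.id: float(scale[i]) for i, c in enumerate(network.cells)}
    neighbors = {c.id: [] for c in network.cells}
    for a, b in network.adjacency:
        neighbors[a].append(b)
        neighbors[b].append(a)
    for v in neighbors.values():
        v.sort()
    return simulate_reference(
        [{"id": c.id, "kind": c.kind} for c in network.cells],
        neighbors,
        reference_load_pattern(protocol.cycles_per_day,
                               int(protocol.rest_interval)),
        protocol.peak_strain, scales, theta.to_dict(),
        gj_threshold=constants.gj_threshold, ca_tail=constants.ca_tail_s,
        nfat_tail=constants.nfat_tail_s, k_t=constants.nfat_gain,
        nfatd_max=constants.nfatd_max,
        strain_on_precursors=constants.strain_on_precursors,
    )


class TestOracleEquivalence:
    """The production engine must match the naive reference exactly on
    networks of up to three cells, second by second."""

    @pytest.mark.parametrize("protocol", [
        LoadingProtocol("c1", 2524, 20, 0),
        LoadingProtocol("r1", 1250, 10, 10),
        LoadingProtocol("r2", 3000, 5, 30),
    ])
    @pytest.mark.parametrize("theta_name", ["young", "aged", "lowcap"])
    def test_trajectories_match(self, protocol, theta_name, young_theta,
                                aged_theta):
        theta = {"young": young_theta, "aged": aged_theta,
                 "lowcap": ParameterVector(1000, 150, 5.0, 0.5, 1000, 10.0),
                 }[theta_name]
        net = make_toy_network(
            [(0, "osteocyte", 600, 0, "none"),
             (1, "osteocyte", 560, 10, "none"),
             (2, "precursor", 590, 40, "periosteal")],
            [(0, 1), (0, 2)])
        eng = _engine_series(net, protocol, theta)
        ref = _reference_series(net, protocol, theta)
        for cid in (0, 1, 2):
            for key in ("Ca", "ER", "NFATd", "NFATn"):
                np.testing.assert_array_equal(
                    eng[cid][key], np.asarray(ref[cid][key]),
                    err_msg=f"cell {cid} series {key}")

    def test_pair_network_rmar_matches_reference(self, pair_network,
                                                 young_theta):
        protocol = LoadingProtocol("p", 2600, 15, 5)
        res = simulate_bout(pair_network, protocol, young_theta)
        ref = _reference_series(pair_network, protocol, young_theta)
        nfatn_ref = ref[1]["NFATn"][-1]
        assert res.nfat_nuclear[0] == pytest.approx(nfatn_ref, rel=1e-12)
        assert res.rmar[0] == pytest.approx(
            reference_rmar(nfatn_ref, young_theta.nfat_capacity,
                           young_theta.mar_max), rel=1e-12)


class TestBoutInvariants:
    def test_zero_strain_gives_zero_rmar(self, small_network, young_theta):
        res = simulate_bout(small_network,
                            LoadingProtocol("z", 0, 50, 0), young_theta)
        assert np.all(res.rmar == 0.0)

    def test_er_knockout_is_lethal(self, small_network, young_theta):
        theta = young_theta.replace(er_capacity=0.0)
        res = simulate_bout(small_network,
                            LoadingProtocol("p", 2400, 50, 10), theta)
        assert np.all(res.rmar == 0.0)
        assert np.all(res.nfat_nuclear == 0.0)

    def test_state_bounds(self, small_network, young_theta):
        res = simulate_bout(small_network,
                            LoadingProtocol("p", 2400, 30, 5), young_theta,
                            trace=True)
        ta = res.trace_arrays
        assert ta["Ca"].min() >= 0 and ta["Ca"].max() <= 100 + 1e-9
        assert ta["ER"].min() >= 0
        assert ta["ER"].max() <= young_theta.er_capacity + 1e-9
        assert np.all(res.rmar >= 0)
        assert np.all(res.rmar <= young_theta.mar_max + 1e-12)

    def test_iteration_order_invariance(self, small_network, young_theta):
        """Synchronous updates: a relabeled/reordered cell list gives the
        same per-cell outcomes."""
        protocol = LoadingProtocol("p", 2000, 20, 5)
        base = simulate_bout(small_network, protocol, young_theta)
        order = np.random.default_rng(0).permutation(len(small_network.cells))
        relabel = {small_network.cells[int(k)].id: r
                   for r, k in enumerate(order)}
        cells = [Cell(relabel[c.id], c.kind, c.x, c.y, c.surface, c.sector)
                 for c in small_network.cells]
        cells.sort(key=lambda c: c.id)
        adj = {(min(relabel[a], relabel[b]), max(relabel[a], relabel[b]))
               for a, b in small_network.adjacency}
        shuffled = make_toy_network([], [])
        shuffled.geometry = small_network.geometry
        shuffled.cells = cells
        shuffled.adjacency = adj
        perm = simulate_bout(shuffled, protocol, young_theta)
        base_by_id = dict(zip(base.precursor_ids, base.rmar))
        perm_by_id = dict(zip(perm.precursor_ids, perm.rmar))
        for old_id, new_id in relabel.items():
            if old_id in base_by_id:
                # neighbor sums run in a different order, so agreement is
                # to float accumulation error, not bit-exact
                assert perm_by_id[new_id] == pytest.approx(
                    base_by_id[old_id], rel=1e-9, abs=1e-12)

    def test_monotone_in_peak_strain_and_alpha(self, small_network,
                                               young_theta):
        protos = [LoadingProtocol(f"s{e}", e, 20, 5) for e in (800, 1600, 2400)]
        means = []
        for p in protos:
            res = simulate_bout(small_network, p, young_theta)
            means.append(res.rmar.mean())
        assert means[0] <= means[1] + 1e-12 <= means[2] + 2e-12
        alphas = [0.2, 0.6, 0.95]
        vals = []
        for a in alphas:
            res = simulate_bout(small_network, protos[1],
                                young_theta.replace(nfat_memory=a))
            vals.append(res.rmar.mean())
        assert vals[0] <= vals[1] + 1e-12 <= vals[2] + 2e-12


class TestSecondaryTransients:
    """Store recovery during rest intervals lets Ca2+ amplitudes rebound;
    knocking out the recovery rate eliminates these secondary transients."""

    SETTLE = 10   # cycles of network-propagation transient to skip

    PROTO = LoadingProtocol("r", 1250, 150, 45)  # extended rest-inserted

    def test_r0_knockout_monotone_amplitudes(self, default_network,
                                             young_theta):
        theta = young_theta.replace(er_recovery=0.0)
        pk = cycle_peaks(default_network, self.PROTO, theta)
        diffs = np.diff(pk, axis=0)[self.SETTLE:]
        assert diffs.max() <= 1e-9

    def test_recovery_creates_post_rest_rebound(self, default_network,
                                                young_theta):
        pk = cycle_peaks(default_network, self.PROTO, young_theta)
        diffs = np.diff(pk, axis=0)[self.SETTLE:]
        assert diffs.max() > 1e-9
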