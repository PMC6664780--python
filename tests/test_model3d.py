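"""Annealer correctness, distance laws, ensembles, distance statistics."""

import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from loopforge import fixtures as fx
from loopforge.model3d import (
    AnnealSchedule,
    ChainEnergy,
    EnergyParams,
    Ensemble,
    PairEnergy,
    SingletonHeatmap,
    Structure,
    anneal,
    ensemble_distance_test,
    ensemble_for_network,
    generate_ensemble,
    model_anchors,
    model_lowres,
    model_subloops,
    split_blocks,
)

FAST = AnnealSchedule(n_sweeps=150)


class TestSplitBlocks:
    def test_chain_is_one_block(self):
        net = fx.network_from_plan("c", [(0, 100, "+"), (1000, 1100, "-"),
                                         (2000, 2100, "+")],
                                   [(0, 1, 1), (1, 2, 1)])
        assert split_blocks(net) == [[0, 1, 2]]

    def test_disjoint_loops_two_blocks(self):
        net = fx.network_from_plan("c", [(0, 100, "+"), (1000, 1100, "-"),
                                         (2000, 2100, "+"), (3000, 3100, "-")],
                                   [(0, 1, 1), (2, 3, 1)])
        assert split_blocks(net) == [[0, 1], [2, 3]]

    def test_random_matches_unionfind_oracle(self, rng):
        import networkx as nx

        n = 20
        anchors = [(i * 1000, i * 1000 + 100, "+") for i in range(n)]
        edges = set()
        while len(edges) < 20:
            i, j = sorted(rng.choice(n, 2, replace=False))
            if i != j:
                edges.add((int(i), int(j)))
        net = fx.network_from_plan("c", anchors, [(i, j, 1) for i, j in edges],
                                   with_ccds=False)
        got = {frozenset(b) for b in split_blocks(net)}
        g = nx.Graph(list(edges))
        want = {frozenset(c) for c in nx.connected_components(g)}
        assert got == want


class TestAnnealer:
    def test_two_beads_exact_target(self, rng):
        energy = PairEnergy(2, [(0, 1, 1.0)])
        coords, info = anneal(energy, rng.normal(size=(2, 3)), rng, FAST)
        assert abs(np.linalg.norm(coords[0] - coords[1]) - 1.0) < 1e-6
        assert info["E_final"] <= info["E_initial"]

    def test_triangle_targets_satisfiable(self, rng):
        # targets = side lengths of a 3-4-5 triangle: exactly embeddable
        energy = PairEnergy(3, [(0, 1, 3.0), (1, 2, 4.0), (0, 2, 5.0)])
        coords, _ = anneal(energy, rng.normal(size=(3, 3)), rng, FAST)
        assert energy.residuals(coords).max() < 1e-3

    def test_regular_simplex_for_equal_targets(self, rng):
        pairs = [(i, j, 2.0) for i in range(4) for j in range(i + 1, 4)]
        energy = PairEnergy(4, pairs)
        coords, _ = anneal(energy, rng.normal(size=(4, 3)), rng, FAST)
        assert energy.residuals(coords).max() < 1e-3

    def test_zero_temperature_trace_monotone(self, rng):
        energy = PairEnergy(4, [(0, 1, 1.0), (1, 2, 2.0), (2, 3, 1.0),
                                (0, 3, 2.5)])
        sched = AnnealSchedule(initial_temperature=0.0, n_sweeps=50,
                               polish=False)
        _, info = anneal(energy, rng.normal(size=(4, 3)), rng, sched,
                         record_trace=True)
        trace = info["trace"]
        assert all(b <= a + 1e-12 for a, b in zip(trace, trace[1:]))

    def test_rigid_motion_invariance(self, rng):
        pairs = [(0, 1, 1.0), (1, 2, 2.0), (0, 2, 2.5)]
        chain = ChainEnergy(3, np.array([1.0, 2.0]),
                            pair_terms=PairEnergy(3, pairs))
        coords = rng.normal(size=(3, 3))
        rot = Rotation.random(random_state=7).as_matrix()
        shifted = coords @ rot.T + np.array([3.0, -1.0, 2.0])
        assert math.isclose(chain.total(coords), chain.total(shifted),
                            abs_tol=1e-9)
        pe = PairEnergy(3, pairs)
        assert math.isclose(pe.total(coords), pe.total(shifted), abs_tol=1e-9)

    def test_final_never_exceeds_initial(self, rng):
        for _ in range(5):
            n = int(rng.integers(3, 7))
            pairs = [(i, j, float(rng.uniform(0.5, 3)))
                     for i in range(n) for j in range(i + 1, n)
                     if rng.random() < 0.6]
            if not pairs:
                continue
            energy = PairEnergy(n, pairs)
            _, info = anneal(energy, rng.normal(size=(n, 3)), rng, FAST)
            assert info["E_final"] <= info["E_initial"] + 1e-12


class TestDistanceLaws:
    def test_anchor_law_plug_ins(self):
        p = EnergyParams(delta=1.0, a=1.0, upsilon=0.5, gamma=1.0)
        # f = gamma -> delta + a
        assert p.anchor_target(1.0) == pytest.approx(2.0)
        # f = 3 -> 1 + e^-1
        assert p.anchor_target(3.0) == pytest.approx(1.0 + math.exp(-1.0))
        # f -> inf -> delta
        assert p.anchor_target(1e9) == pytest.approx(1.0)

    def test_anchor_law_strictly_decreasing(self):
        p = EnergyParams()
        f = np.linspace(1, 50, 200)
        d = np.array([p.anchor_target(x) for x in f])
        assert np.all(np.diff(d) < 0)

    def test_upsilon_must_be_positive(self):
        with pytest.raises(ValueError):
            EnergyParams(upsilon=0.0)


class TestLowres:
    def test_two_bins_unit_target(self, rng):
        hm = SingletonHeatmap("c", [0, 1_000_000, 2_000_000],
                              np.array([[0.0, 1.0], [1.0, 0.0]]))
        p = EnergyParams(scale_c=1.0, alpha_low=1.0,
                         anneal=FAST)
        st = model_lowres(hm, p, rng)
        assert abs(st.distance(0, 1) - 1.0) < 1e-3

    def test_consistent_triangle_embeds(self, rng):
        # frequencies 1/3, 1/4, 1/5 with c=1, alpha=1 -> targets 3,4,5
        f = np.array([[0, 1 / 3, 1 / 5], [1 / 3, 0, 1 / 4], [1 / 5, 1 / 4, 0]])
        hm = SingletonHeatmap("c", [0, 10, 20, 30], f)
        st = model_lowres(hm, EnergyParams(anneal=FAST), rng)
        assert st.distance(0, 1) == pytest.approx(3.0, abs=1e-3)
        assert st.distance(1, 2) == pytest.approx(4.0, abs=1e-3)
        assert st.distance(0, 2) == pytest.approx(5.0, abs=1e-3)

    def test_single_bin_at_origin(self, rng):
        hm = SingletonHeatmap("c", [0, 10], np.zeros((1, 1)))
        st = model_lowres(hm, EnergyParams(), rng)
        assert np.array_equal(st.coords, np.zeros((1, 3)))

    def test_heatmap_validation(self):
        with pytest.raises(ValueError, match="symmetric"):
            SingletonHeatmap("c", [0, 1, 2], np.array([[0, 1], [2, 0.0]]))
        with pytest.raises(ValueError, match="increasing"):
            SingletonHeatmap("c", [0, 0], np.zeros((1, 1)))


class TestAnchorStage:
    def test_single_loop_hand_value(self, rng):
        net = fx.network_from_plan("c", [(0, 600, "+"), (30_000, 30_600, "-")],
                                   [(0, 1, 3)])
        p = EnergyParams(delta=1.0, a=1.0, upsilon=0.5, gamma=1.0, anneal=FAST)
        st = model_anchors(net, [0, 1], p, rng)
        assert st.distance(0, 1) == pytest.approx(1.0 + math.exp(-1.0), abs=1e-3)

    def test_unconnected_pair_has_no_term(self, rng):
        net = fx.network_from_plan("c", [(0, 600, "+"), (30_000, 30_600, "-"),
                                         (60_000, 60_600, "+")],
                                   [(0, 1, 3), (1, 2, 3)])
        st = model_anchors(net, [0, 1, 2], EnergyParams(anneal=FAST), rng)
        # only 2 restraints for 3 beads: satisfiable exactly
        assert st.energies["E_final"] < 1e-6


class TestSubloops:
    def _chain(self, rng, k=3):
        net = fx.network_from_plan("c", [(0, 600, "+"), (30_000, 30_600, "-")],
                                   [(0, 1, 5)])
        p = EnergyParams(k_subanchors=k, anneal=FAST)
        anchor_st = model_anchors(net, [0, 1], p, rng)
        return net, p, anchor_st

    def test_collinear_exact_targets_zero_energy(self):
        # beads on a line with spacing == target: E_s = 0 and E_b = 0
        t = np.array([1.0, 2.0, 1.5])
        chain = ChainEnergy(4, t)
        xs = np.concatenate([[0.0], np.cumsum(t)])
        coords = np.column_stack([xs, np.zeros(4), np.zeros(4)])
        assert chain.stretch(coords) == pytest.approx(0.0, abs=1e-12)
        assert chain.bend(coords) == pytest.approx(0.0, abs=1e-12)

    def test_right_angle_bend_contribution(self):
        chain = ChainEnergy(3, np.array([1.0, 1.0]))
        coords = np.array([[0.0, 0, 0], [1.0, 0, 0], [1.0, 1.0, 0]])
        # unit vectors orthogonal: E_b = 0.5 * (1 - 0)^2 = 0.5
        assert chain.bend(coords) == pytest.approx(0.5)

    def test_subloop_stage_reduces_energy(self, rng):
        net, p, anchor_st = self._chain(rng)
        st = model_subloops(net, [0, 1], anchor_st, p, rng)
        assert st.n_beads == 2 + 3
        assert st.energies["E_final"] <= st.energies["E_initial"]
        assert st.energies["E"] == pytest.approx(
            st.energies["E_s"] + st.energies["E_b"] + st.energies["E_h"])
        # anchors stayed fixed
        np.testing.assert_array_equal(st.coords[0], anchor_st.coords[0])
        np.testing.assert_array_equal(st.coords[-1], anchor_st.coords[1])

    def test_heatmap_term_reported(self, rng):
        net, p, anchor_st = self._chain(rng)
        f = np.array([[0, 3.0], [3.0, 0]])
        hm = SingletonHeatmap("c", [0, 15_000, 31_000], f)
        st = model_subloops(net, [0, 1], anchor_st, p, rng, heatmap=hm)
        assert "E_h" in st.energies


class TestEnsembles:
    def test_same_seed_identical(self):
        net = fx.insulated_neighborhood_fixture().network
        p = EnergyParams(anneal=FAST)
        e1 = ensemble_for_network(net, p, n=1, seed=5)
        e2 = ensemble_for_network(net, p, n=1, seed=5)
        np.testing.assert_array_equal(e1.structures[0].coords,
                                      e2.structures[0].coords)

    def test_different_seeds_distinct_conformations(self):
        net = fx.insulated_neighborhood_fixture().network
        p = EnergyParams(anneal=FAST)
        ens = ensemble_for_network(net, p, n=5, seed=9)
        coords = [s.coords for s in ens.structures]
        distinct = sum(1 for a, b in zip(coords, coords[1:])
                       if not np.allclose(a, b))
        assert distinct >= 2  # degenerate solution set, many minima

    def test_all_runs_lower_energy(self):
        net = fx.insulated_neighborhood_fixture().network
        p = EnergyParams(anneal=FAST)
        ens = ensemble_for_network(net, p, n=5, seed=2)
        for st in ens.structures:
            assert st.energies["E_final"] <= st.energies["E_initial"]

    def test_n_must_be_positive(self):
        with pytest.raises(ValueError):
            generate_ensemble(lambda rng: None, 0, 1)


class TestDistanceTest:
    @staticmethod
    def _point_ensemble(rng, sep, n=100):
        structures = []
        for _ in range(n):
            c = np.zeros((2, 3))
            c[1, 0] = sep + rng.normal(0, 0.01)
            structures.append(Structure(
                beads=[("c", 0, 100), ("c", 1000, 1100)], coords=c))
        return Ensemble(structures)

    def test_identical_ensembles_p_one(self, rng):
        ens = self._point_ensemble(rng, 1.0, n=20)
        res = ensemble_distance_test(ens, ens, [("d", ("c", 50), ("c", 1050))])
        assert res[0].p_value > 0.9
        assert res[0].ref_median == res[0].alt_median

    def test_separated_ensembles_significant(self, rng):
        a = self._point_ensemble(rng, 1.0)
        b = self._point_ensemble(rng, 10.0)
        res = ensemble_distance_test(a, b, [("d", ("c", 50), ("c", 1050))])[0]
        assert res.p_value < 1e-3
        assert res.alt_median > res.ref_median

    def test_locus_outside_region_errors(self, rng):
        ens = self._point_ensemble(rng, 1.0, n=3)
        with pytest.raises(ValueError, match="outside modeled region"):
            ensemble_distance_test(ens, ens, [("d", ("c", 50), ("c", 99_999))])

    def test_locate_between_spans_uses_nearest(self):
        st = Structure(beads=[("c", 0, 100), ("c", 1000, 1100)],
                       coords=np.zeros((2, 3)))
        assert st.locate("c", 120) == 0
        assert st.locate("c", 990) == 1
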