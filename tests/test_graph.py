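import math

import numpy as np
import pytest

from contextcut4d import (
    EnergyParams,
    brute_force_min_cut,
    build_global_graph,
    energy_of,
    fit_intensity_model,
    max_flow_min_cut,
    segment_4dct,
)
from contextcut4d.graph import GraphSpec, segment_single_phase, write_dimacs
from contextcut4d.errors import ResourceError, ValidationError

from conftest import random_graphspec

EMPTY_I = np.empty(0, dtype=np.intp)
EMPTY_F = np.empty(0)


def _bare_graph(ts, tk, edges=(), hard=math.inf):
    ts, tk = np.asarray(ts, float), np.asarray(tk, float)
    n = len(ts)
    if edges:
        src, dst, w = (np.asarray(a) for a in zip(*edges))
    else:
        src, dst, w = EMPTY_I, EMPTY_I, EMPTY_F
    return GraphSpec((1, 1, 1, n), ts, tk, src.astype(np.intp), dst.astype(np.intp),
                     w.astype(float), EMPTY_I, EMPTY_I, EMPTY_F, hard_weight=hard)


class TestBuildGlobalGraph:
    @pytest.fixture()
    def tiny(self, small_phantom, small_seeds):
        return small_phantom.volume, small_seeds

    def test_node_and_context_arc_counts_linear(self):
        from contextcut4d import Volume4D, SeedSet
        rng = np.random.default_rng(0)
        vol = Volume4D(rng.random((3, 2, 2, 2)), (1, 1, 1))
        seeds = SeedSet(0, [[0, 0, 0]], [[1, 1, 1]])
        model = fit_intensity_model(vol, seeds)
        g = build_global_graph(vol, model, seeds, EnergyParams(chain="linear"))
        assert g.n_nodes == 24
        assert len(g.ctx_weight) == 16          # 2 adjacent pairs x 8 voxels
        g_cyc = build_global_graph(vol, model, seeds, EnergyParams(chain="cyclic"))
        assert len(g_cyc.ctx_weight) == 24      # 3 adjacent pairs x 8 voxels

    def test_single_phase_has_no_context_arcs(self):
        from contextcut4d import Volume4D, SeedSet
        vol = Volume4D(np.random.default_rng(1).random((1, 3, 3, 3)), (1, 1, 1))
        seeds = SeedSet(0, [[1, 1, 1]], [[0, 0, 0]])
        model = fit_intensity_model(vol, seeds)
        g = build_global_graph(vol, model, seeds, EnergyParams())
        assert len(g.ctx_weight) == 0
        assert len(g.n_weight) == 3 * (2 * 3 * 3)   # 6-neighborhood within the phase

    def test_nlink_weights_respect_anisotropic_spacing(self):
        from contextcut4d import Volume4D, SeedSet
        vol = Volume4D(np.full((1, 2, 2, 2), 0.5), (2.5, 1.0, 1.0))
        seeds = SeedSet(0, [[0, 0, 0]], [[1, 1, 1]])
        model = fit_intensity_model(vol, seeds)
        g = build_global_graph(vol, model, seeds, EnergyParams())
        # z-edges first (4 of them), then y (4), then x (4); flat image
        assert g.n_weight[:4] == pytest.approx(1.0 / 2.5)
        assert g.n_weight[4:] == pytest.approx(1.0)

    def test_hard_weight_exceeds_total_finite_weight(self, tiny):
        vol, seeds = tiny
        model = fit_intensity_model(vol, seeds)
        g = build_global_graph(vol, model, seeds, EnergyParams())
        finite_total = (g.t_source[g.t_source < g.hard_weight].sum()
                        + g.t_sink[g.t_sink < g.hard_weight].sum()
                        + g.n_weight.sum() + g.ctx_weight.sum())
        assert g.hard_weight > finite_total


class TestMaxFlowMinCut:
    def test_single_node_picks_cheaper_tlink(self):
        g = _bare_graph([3.0], [1.0])
        res = max_flow_min_cut(g)
        assert res.labeling.labels.ravel().tolist() == [1]
        assert res.cut_value == 1.0
        assert res.energy == res.cut_value

    def test_strong_nlink_forces_agreement(self):
        # two nodes pulled to opposite terminals (weight 1) joined by weight 10
        g = _bare_graph([1.0, 0.0], [0.0, 1.0], edges=[(0, 1, 10.0)])
        res = max_flow_min_cut(g)
        labels = res.labeling.labels.ravel()
        assert labels[0] == labels[1]
        assert res.cut_value == pytest.approx(1.0)

    @pytest.mark.parametrize("integer", [False, True])
    def test_matches_brute_force_oracle(self, integer):
        rng = np.random.default_rng(42 + integer)
        for _ in range(40):
            g = random_graphspec(rng, integer=integer)
            mf = max_flow_min_cut(g)
            bf = brute_force_min_cut(g)
            if integer:
                assert mf.energy == bf.energy
            else:
                assert mf.energy == pytest.approx(bf.energy, abs=1e-9)

    def test_solver_backends_agree(self):
        # same instance through the float (BK) and scaled-integer (Dinic) paths
        import contextcut4d.graph as G
        rng = np.random.default_rng(9)
        for _ in range(10):
            g = random_graphspec(rng)
            e_bk = max_flow_min_cut(g).energy
            old = G._BK_MAX_NODES
            G._BK_MAX_NODES = 0
            try:
                e_dinic = max_flow_min_cut(g).energy
            finally:
                G._BK_MAX_NODES = old
            assert e_bk == pytest.approx(e_dinic, abs=1e-6)

    def test_negative_weight_rejected(self):
        g = _bare_graph([1.0, -0.5], [0.0, 1.0])
        with pytest.raises(ValidationError):
            max_flow_min_cut(g)


class TestBruteForce:
    def test_single_node_enumerates_both(self):
        res = brute_force_min_cut(_bare_graph([0.5], [2.0]))
        assert res.labeling.labels.ravel().tolist() == [0]
        assert res.energy == 0.5

    def test_all_zero_weights_lexicographic_tiebreak(self):
        res = brute_force_min_cut(_bare_graph([0.0] * 3, [0.0] * 3, edges=[(0, 1, 0.0)]))
        assert res.energy == 0.0
        assert res.labeling.labels.ravel().tolist() == [0, 0, 0]

    def test_too_many_nodes_rejected(self):
        with pytest.raises(ResourceError):
            brute_force_min_cut(_bare_graph([1.0] * 21, [1.0] * 21))


class TestEnergyConsistency:
    def test_cut_value_equals_direct_energy(self, small_phantom, small_seeds):
        vol = small_phantom.volume
        params = EnergyParams()
        model = fit_intensity_model(vol, small_seeds)
        g = build_global_graph(vol, model, small_seeds, params)
        res = max_flow_min_cut(g)
        direct = energy_of(res.labeling, vol, model, small_seeds, params)
        assert direct == pytest.approx(res.cut_value, rel=1e-12)

    def test_solution_not_beaten_by_perturbations(self, small_phantom, small_seeds):
        vol = small_phantom.volume
        params = EnergyParams()
        labeling, res, model = segment_4dct(vol, small_seeds, params, return_details=True)
        rng = np.random.default_rng(0)
        base = energy_of(labeling, vol, model, small_seeds, params)
        for _ in range(20):
            flipped = labeling.labels.copy()
            k = rng.integers(vol.phase_count)
            z, y, x = (rng.integers(s) for s in vol.grid_shape)
            flipped[k, z, y, x] ^= 1
            from contextcut4d import Labeling4D
            e = energy_of(Labeling4D(flipped), vol, model, small_seeds, params)
            assert e >= base - 1e-9

    def test_uniform_labeling_has_zero_context_term(self, small_phantom, small_seeds):
        from contextcut4d import Labeling4D
        vol = small_phantom.volume
        model = fit_intensity_model(vol, small_seeds)
        ones = Labeling4D(np.ones_like(vol.phases, dtype=np.uint8))
        # fixed hard weight so the two parameterizations share seed penalties
        e_ctx = energy_of(ones, vol, model, small_seeds,
                          EnergyParams(lambda2=5.0, hard_weight=1e6))
        e_no = energy_of(ones, vol, model, small_seeds,
                         EnergyParams(lambda2=0.0, hard_weight=1e6))
        # no label disagreement anywhere: context term contributes nothing
        assert e_ctx == pytest.approx(e_no)


class TestSegment4dct:
    def test_recovers_phantom_in_every_phase(self, small_phantom, small_seeds):
        from contextcut4d import evaluate_labeling
        labeling = segment_4dct(small_phantom.volume, small_seeds)
        rep = evaluate_labeling(labeling, small_phantom.masks, small_phantom.volume.spacing)
        assert all(d > 0.9 for d in rep.dsc_per_phase)

    def test_seed_constraints_always_respected(self, small_phantom, small_seeds):
        labeling = segment_4dct(small_phantom.volume, small_seeds)
        phase = labeling.labels[small_seeds.phase_index]
        assert all(phase[z, y, x] == 1 for z, y, x in small_seeds.object_voxels)
        assert all(phase[z, y, x] == 0 for z, y, x in small_seeds.background_voxels)

    def test_lambda2_zero_decomposes_into_per_phase_cuts(self, small_phantom, small_seeds):
        vol = small_phantom.volume
        params = EnergyParams(lambda2=0.0)
        labeling, res, model = segment_4dct(vol, small_seeds, params, return_details=True)
        total = 0.0
        for i in range(vol.phase_count):
            total += segment_single_phase(vol, i, model, small_seeds, params).energy
        assert res.energy == pytest.approx(total, rel=1e-6)

    def test_raising_lambda2_never_increases_interphase_disagreements(
            self, small_phantom, small_seeds):
        vol = small_phantom.volume
        counts = []
        for lam2 in (0.0, 0.5, 1.0, 2.0, 4.0):
            labels = segment_4dct(vol, small_seeds, EnergyParams(lambda2=lam2)).labels
            counts.append(int((labels[:-1] != labels[1:]).sum()))
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestDimacsDump:
    def test_roundtrippable_header_and_arc_count(self, tmp_path):
        g = _bare_graph([1.0, 2.0], [3.0, 0.0], edges=[(0, 1, 5.0)])
        path = tmp_path / "graph.dimacs"
        write_dimacs(g, path)
        lines = path.read_text().strip().splitlines()
        n_declared, m_declared = (int(v) for v in lines[0].split()[2:])
        arcs = [ln for ln in lines if ln.startswith("a ")]
        assert n_declared == 4
        assert len(arcs) == m_declared == 3 + 2  # 3 nonzero t-links + both arc directions
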