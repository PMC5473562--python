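"""Global s-t graph construction and exact max-flow/min-cut optimization.

One node per (phase, voxel).  T-links carry the regional costs with the
standard zero-offset encoding

    to_source(v) = R_v(0),   to_sink(v) = R_v(1),

so that the edge (s, v) is cut exactly when v is labelled background and
the edge (v, t) exactly when v is labelled object: the cut value equals
the labeling energy with zero constant offset.  N-links join 6-neighbors
within a phase (boundary term); context arcs join identical (z, y, x)
positions of chain-adjacent phases (Potts context term).  All pairwise
weights are non-negative, hence the energy is submodular and a single
max-flow/min-cut computation yields the global optimum over all phases
simultaneously.

Two exact solver backends sit behind one contract: small graphs go
through the Boykov-Kolmogorov algorithm on float capacities, large ones
through scipy's Dinic max-flow on integer capacities scaled to fit the
solver's 32-bit per-edge limit, with seed hard constraints contracted
into the terminals so the scale stays fine.  The reported energy is
always re-evaluated from the unscaled float weights.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import breadth_first_order, maximum_flow

from .datamodel import Labeling4D, SeedSet, Volume4D
from .energy import (
    EnergyParams,
    IntensityModel,
    boundary_cost,
    context_cost,
    fit_intensity_model,
    regional_cost,
)
from .errors import ResourceError, ValidationError

_BRUTE_FORCE_MAX_NODES = 20


@dataclass
class GraphSpec:
    """The global graph in flat arrays.

    Node ids enumerate (phase, z, y, x) in C order: node = ((phase*Z + z)*Y
    + y)*X + x.  The two terminals are implicit (ids n_nodes and
    n_nodes + 1 when materialized).
    """

    shape: tuple[int, int, int, int]           # (k, Z, Y, X)
    t_source: np.ndarray                       # (N,) weight of edge (s, v) = R_v(0)
    t_sink: np.ndarray                         # (N,) weight of edge (v, t) = R_v(1)
    n_src: np.ndarray                          # intra-phase 6-neighbor edges
    n_dst: np.ndarray
    n_weight: np.ndarray
    ctx_src: np.ndarray                        # inter-phase context arcs
    ctx_dst: np.ndarray
    ctx_weight: np.ndarray
    hard_weight: float = math.inf

    @property
    def n_nodes(self) -> int:
        return int(np.prod(self.shape))

    def pair_edges(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """All pairwise (undirected) edges: n-links then context arcs."""
        return (np.concatenate([self.n_src, self.ctx_src]),
                np.concatenate([self.n_dst, self.ctx_dst]),
                np.concatenate([self.n_weight, self.ctx_weight]))

    def validate(self) -> None:
        n = self.n_nodes
        if len(self.t_source) != n or len(self.t_sink) != n:
            raise ValidationError("t-link arrays must have one entry per node")
        for name, arr in (("t_source", self.t_source), ("t_sink", self.t_sink),
                          ("n_weight", self.n_weight), ("ctx_weight", self.ctx_weight)):
            a = np.asarray(arr, dtype=np.float64)
            if a.size and (not np.all(np.isfinite(a)) or a.min() < 0):
                raise ValidationError(f"{name} must be non-negative and finite")
        for src, dst in ((self.n_src, self.n_dst), (self.ctx_src, self.ctx_dst)):
            if len(src) != len(dst):
                raise ValidationError("edge endpoint arrays must have equal length")
            if len(src) and (min(src.min(), dst.min()) < 0 or max(src.max(), dst.max()) >= n):
                raise ValidationError("edge endpoint outside node range")

    def labeling_energy(self, labels_flat: np.ndarray) -> float:
        """Cut value of a labeling: t-links plus disagreeing pairwise edges."""
        f = np.asarray(labels_flat).astype(bool).ravel()
        src, dst, w = self.pair_edges()
        e = self.t_source[~f].sum() + self.t_sink[f].sum()
        if len(w):
            e += w[f[src] != f[dst]].sum()
        return float(e)


@dataclass
class CutResult:
    """A minimum cut: the induced labeling, the cut value, and the energy.

    With the zero-offset t-link encoding used here the cut value *is* the
    global energy of the labeling, so the two fields coincide.
    """

    labeling: Labeling4D
    cut_value: float
    energy: float


def _context_pairs(k: int, chain: str) -> list[tuple[int, int]]:
    pairs = [(i, i + 1) for i in range(k - 1)]
    if chain == "cyclic" and k > 2:
        pairs.append((k - 1, 0))
    return pairs


def build_global_graph(volume: Volume4D, model: IntensityModel, seeds: SeedSet,
                       params: EnergyParams) -> GraphSpec:
    """Assemble t-links, n-links and context arcs for all phases at once.

    The one intensity model fitted from the single-phase seeds supplies
    the regional costs of every phase.  Seed voxels get the hard override
    (a per-instance finite bound exceeding the sum of all other weights)
    on their forbidden label, only in the seed phase.
    """
    seeds.validate_for(volume)
    k, Z, Y, X = volume.phases.shape
    shape = (k, Z, Y, X)
    vol = volume.phases

    t_sink = regional_cost(model, vol, 1).ravel()    # R_v(1), cut when labelled object
    t_source = regional_cost(model, vol, 0).ravel()  # R_v(0), cut when labelled background

    idx = np.arange(k * Z * Y * X).reshape(shape)
    n_src, n_dst, n_w = [], [], []
    for ax, sp in zip((1, 2, 3), volume.spacing):
        sl_a = [slice(None)] * 4
        sl_b = [slice(None)] * 4
        sl_a[ax] = slice(None, -1)
        sl_b[ax] = slice(1, None)
        a, b = tuple(sl_a), tuple(sl_b)
        n_src.append(idx[a].ravel())
        n_dst.append(idx[b].ravel())
        n_w.append(boundary_cost(vol[a], vol[b], sp, params).ravel())
    n_src = np.concatenate(n_src)
    n_dst = np.concatenate(n_dst)
    n_w = np.concatenate(n_w)

    ctx_src, ctx_dst, ctx_w = [], [], []
    for i, j in _context_pairs(k, params.chain):
        ctx_src.append(idx[i].ravel())
        ctx_dst.append(idx[j].ravel())
        ctx_w.append(context_cost(vol[i], vol[j], params).ravel())
    empty = np.empty(0, dtype=np.intp)
    ctx_src = np.concatenate(ctx_src) if ctx_src else empty
    ctx_dst = np.concatenate(ctx_dst) if ctx_dst else empty
    ctx_w = np.concatenate(ctx_w) if ctx_w else empty.astype(np.float64)

    hard = params.hard_weight
    if hard is None:
        hard = 1.0 + float(t_source.sum() + t_sink.sum() + n_w.sum() + ctx_w.sum())

    phase_offset = seeds.phase_index * Z * Y * X
    obj_nodes = phase_offset + np.ravel_multi_index(seeds.object_voxels.T, (Z, Y, X))
    bkg_nodes = phase_offset + np.ravel_multi_index(seeds.background_voxels.T, (Z, Y, X))
    t_source = t_source.copy()
    t_sink = t_sink.copy()
    t_source[obj_nodes] = hard   # R_v(0) = inf: object seed cannot become background
    t_sink[bkg_nodes] = hard     # R_v(1) = inf: background seed cannot become object

    return GraphSpec(shape, t_source, t_sink, n_src, n_dst, n_w,
                     ctx_src, ctx_dst, ctx_w, hard_weight=float(hard))


def instance_hard_weight(volume: Volume4D, model: IntensityModel,
                         params: EnergyParams) -> float:
    """The per-instance realization of the infinite seed penalty.

    1 + the sum of every finite t-link, n-link and context weight of the
    instance, so no finite cut can prefer violating a hard constraint.
    Mirrors the bound computed inside :func:`build_global_graph`.
    """
    k = volume.phase_count
    vol = volume.phases
    total = float(regional_cost(model, vol, 0).sum() + regional_cost(model, vol, 1).sum())
    for ax, sp in zip((1, 2, 3), volume.spacing):
        sl_a = [slice(None)] * 4
        sl_b = [slice(None)] * 4
        sl_a[ax] = slice(None, -1)
        sl_b[ax] = slice(1, None)
        total += float(boundary_cost(vol[tuple(sl_a)], vol[tuple(sl_b)], sp, params).sum())
    for i, j in _context_pairs(k, params.chain):
        total += float(context_cost(vol[i], vol[j], params).sum())
    return 1.0 + total


#: graphs with at most this many nodes are solved with the
#: Boykov-Kolmogorov algorithm on exact float capacities (networkx);
#: larger ones use scipy's Dinic on scaled integer capacities.
_BK_MAX_NODES = 512


def _min_cut_bk(graph: GraphSpec, src, dst, w) -> np.ndarray:
    """Boykov-Kolmogorov min cut on float capacities (small graphs)."""
    import networkx as nx
    from networkx.algorithms.flow import boykov_kolmogorov

    n = graph.n_nodes
    s, t = n, n + 1
    G = nx.Graph()
    G.add_nodes_from(range(n + 2))
    for v in range(n):
        if graph.t_source[v] > 0:
            G.add_edge(s, v, capacity=float(graph.t_source[v]))
        if graph.t_sink[v] > 0:
            G.add_edge(v, t, capacity=float(graph.t_sink[v]))
    for u, v, wt in zip(src, dst, w):
        u, v = int(u), int(v)
        if G.has_edge(u, v):
            G[u][v]["capacity"] += float(wt)
        elif wt > 0:
            G.add_edge(u, v, capacity=float(wt))
    if not G.has_edge(s, t):  # keep degenerate all-zero graphs well-defined
        G.add_edge(s, t, capacity=0.0)
    # the BK residual exposes the source search tree, which defines the
    # source side of a minimum cut
    R = boykov_kolmogorov(G, s, t)
    source_side = set(R.graph["trees"][0])
    source_side.add(s)
    labels = np.zeros(n + 2, dtype=np.uint8)
    labels[list(source_side)] = 1
    return labels[:n]


def _min_cut_scaled(graph: GraphSpec, src, dst, w) -> np.ndarray:
    """Dinic min cut on integer-scaled capacities (large graphs).

    Hard-pinned seed nodes (t-link weight >= the instance hard weight) are
    contracted into the terminals, so the integer scale is set by the
    largest *finite regular* weight: per-edge capacities must stay below
    2**31 for scipy's solver.
    """
    n = graph.n_nodes
    t_source = graph.t_source.astype(np.float64).copy()
    t_sink = graph.t_sink.astype(np.float64).copy()
    hard = graph.hard_weight
    pin_s = t_source >= hard  # object seeds: edge (s, v) uncuttable
    pin_t = t_sink >= hard    # background seeds: edge (v, t) uncuttable
    if np.any(pin_s & pin_t):
        raise ValidationError("a node cannot be hard-pinned to both terminals")

    free = ~(pin_s | pin_t)
    m = int(free.sum())
    new_id = np.full(n, -1, dtype=np.int64)
    new_id[free] = np.arange(m)
    s, t = m, m + 1

    # reroute pair edges with a pinned endpoint; edges pinned on both
    # sides are constants (or never cut) and drop out of the optimization
    ts = t_source[free]
    tk = t_sink[free]
    a = np.asarray(src, dtype=np.int64)
    b = np.asarray(dst, dtype=np.int64)
    wt = np.asarray(w, dtype=np.float64)
    for p, q in ((a, b), (b, a)):
        sel = pin_s[p] & free[q]
        np.add.at(ts, new_id[q[sel]], wt[sel])   # edge (s, q): cut when q background
        sel = pin_t[p] & free[q]
        np.add.at(tk, new_id[q[sel]], wt[sel])   # edge (q, t): cut when q object
    keep = free[a] & free[b]
    a, b, wt = new_id[a[keep]], new_id[b[keep]], wt[keep]

    max_w = max(float(ts.max(initial=0.0)), float(tk.max(initial=0.0)),
                float(wt.max(initial=0.0)), 1e-300)
    scale = max(1, int((2 ** 31 - 1) / (max_w * (1.0 + 1e-12))))

    nodes = np.arange(m)
    rows = np.concatenate([a, b, np.full(m, s), nodes])
    cols = np.concatenate([b, a, nodes, np.full(m, t)])
    caps_i = np.rint(np.concatenate([wt, wt, ts, tk]) * scale).astype(np.int64)
    A = coo_matrix((caps_i, (rows, cols)), shape=(m + 2, m + 2)).tocsr()

    res = maximum_flow(A, s, t)
    residual = A - res.flow
    residual.data[residual.data <= 0] = 0
    residual.eliminate_zeros()
    reachable = breadth_first_order(residual, s, directed=True, return_predecessors=False)
    free_labels = np.zeros(m + 2, dtype=np.uint8)
    free_labels[reachable] = 1          # source side = object

    labels = np.zeros(n, dtype=np.uint8)
    labels[free] = free_labels[:m]
    labels[pin_s] = 1
    return labels


def max_flow_min_cut(graph: GraphSpec) -> CutResult:
    """Exact minimum s-t cut of the global graph.

    Small graphs are solved by the Boykov-Kolmogorov algorithm on float
    capacities; large ones by an integer-capacity Dinic solve with seed
    nodes contracted into the terminals (see the module docstring).  The
    returned cut value / energy is evaluated from the original float
    weights of the chosen labeling, so it equals the global energy with
    zero offset.
    """
    graph.validate()
    src, dst, w = graph.pair_edges()
    if graph.n_nodes <= _BK_MAX_NODES:
        labels_flat = _min_cut_bk(graph, src, dst, w)
    else:
        labels_flat = _min_cut_scaled(graph, src, dst, w)
    value = graph.labeling_energy(labels_flat)
    labeling = Labeling4D(labels_flat.reshape(graph.shape))
    return CutResult(labeling, value, value)


def brute_force_min_cut(graph: GraphSpec) -> CutResult:
    """Exhaustive minimum-energy labeling; the test oracle.

    Enumerates all 2**n labelings (n <= 20) and returns the minimum, with
    ties broken by the lexicographically smallest labeling (node 0 most
    significant).
    """
    graph.validate()
    n = graph.n_nodes
    if n > _BRUTE_FORCE_MAX_NODES:
        raise ResourceError(f"brute force limited to {_BRUTE_FORCE_MAX_NODES} nodes, got {n}")
    # row i of L = labeling whose bit string (node 0 first) is i in binary,
    # so np.argmin's first-hit rule returns the lexicographically smallest.
    codes = np.arange(2 ** n, dtype=np.uint32)
    L = (codes[:, None] >> (n - 1 - np.arange(n))) & 1
    src, dst, wgt = graph.pair_edges()
    energies = L @ graph.t_sink + (1 - L) @ graph.t_source
    if len(wgt):
        energies += (L[:, src] != L[:, dst]) @ wgt
    best = int(np.argmin(energies))
    labels_flat = L[best].astype(np.uint8)
    value = float(energies[best])
    return CutResult(Labeling4D(labels_flat.reshape(graph.shape)), value, value)


def energy_of(labeling: Labeling4D, volume: Volume4D, model: IntensityModel,
              seeds: SeedSet, params: EnergyParams) -> float:
    """Direct evaluation of the global energy of a given labeling.

    Sums, over phases: regional costs (with hard seed overrides), boundary
    costs of 6-neighbor pairs with disagreeing labels, and context costs
    of chain-adjacent corresponding voxels with disagreeing labels.
    Violated hard constraints contribute the instance hard weight.
    """
    if labeling.labels.shape != volume.phases.shape:
        raise ValidationError(
            f"labeling shape {labeling.labels.shape} != volume shape {volume.phases.shape}")
    seeds.validate_for(volume)
    f = labeling.labels.astype(bool)
    vol = volume.phases

    r1 = regional_cost(model, vol, 1)
    r0 = regional_cost(model, vol, 0)
    hard = params.hard_weight
    if hard is None:
        hard = instance_hard_weight(volume, model, params)
    p = seeds.phase_index
    oz, oy, ox = seeds.object_voxels.T
    bz, by, bx = seeds.background_voxels.T
    r0 = r0.copy()
    r1 = r1.copy()
    r0[p, oz, oy, ox] = hard
    r1[p, bz, by, bx] = hard
    energy = float(np.where(f, r1, r0).sum())

    for ax, sp in zip((1, 2, 3), volume.spacing):
        sl_a = [slice(None)] * 4
        sl_b = [slice(None)] * 4
        sl_a[ax] = slice(None, -1)
        sl_b[ax] = slice(1, None)
        a, b = tuple(sl_a), tuple(sl_b)
        disagree = f[a] != f[b]
        if disagree.any():
            energy += float(boundary_cost(vol[a][disagree], vol[b][disagree], sp, params).sum())

    for i, j in _context_pairs(volume.phase_count, params.chain):
        disagree = f[i] != f[j]
        if disagree.any():
            energy += float(context_cost(vol[i][disagree], vol[j][disagree], params).sum())
    return energy


def segment_4dct(volume: Volume4D, seeds: SeedSet,
                 params: EnergyParams | None = None,
                 return_details: bool = False):
    """Segment the tumor in every phase from seeds drawn in one phase.

    Fits the intensity model from the seeds, builds the global graph over
    all phases, and solves one max-flow/min-cut.  Returns the
    :class:`Labeling4D` (and, with ``return_details``, the
    :class:`CutResult` and fitted :class:`IntensityModel`).
    """
    params = params or EnergyParams()
    model = fit_intensity_model(volume, seeds, n_bins=params.n_bins, floor=params.prob_floor)
    graph = build_global_graph(volume, model, seeds, params)
    result = max_flow_min_cut(graph)
    if return_details:
        return result.labeling, result, model
    return result.labeling


def segment_single_phase(volume: Volume4D, phase_index: int, model: IntensityModel,
                         seeds: SeedSet, params: EnergyParams) -> CutResult:
    """Independent single-phase cut (no context arcs) of one phase.

    Seeds are applied only when ``phase_index`` is the seed phase; other
    phases are segmented from the shared intensity model alone.  Used for
    the no-context baseline and for decomposition checks.
    """
    sub = Volume4D(volume.phases[phase_index:phase_index + 1], volume.spacing)
    if phase_index == seeds.phase_index:
        sub_seeds = SeedSet(0, seeds.object_voxels, seeds.background_voxels)
        graph = build_global_graph(sub, model, sub_seeds, params)
    else:
        t_sink = regional_cost(model, sub.phases, 1).ravel()
        t_source = regional_cost(model, sub.phases, 0).ravel()
        Z, Y, X = sub.phases.shape[1:]
        idx = np.arange(Z * Y * X).reshape(1, Z, Y, X)
        n_src, n_dst, n_w = [], [], []
        for ax, sp in zip((1, 2, 3), volume.spacing):
            sl_a = [slice(None)] * 4
            sl_b = [slice(None)] * 4
            sl_a[ax] = slice(None, -1)
            sl_b[ax] = slice(1, None)
            n_src.append(idx[tuple(sl_a)].ravel())
            n_dst.append(idx[tuple(sl_b)].ravel())
            n_w.append(boundary_cost(sub.phases[tuple(sl_a)], sub.phases[tuple(sl_b)],
                                     sp, params).ravel())
        empty = np.empty(0, dtype=np.intp)
        graph = GraphSpec((1, Z, Y, X), t_source, t_sink,
                          np.concatenate(n_src), np.concatenate(n_dst), np.concatenate(n_w),
                          empty, empty, np.empty(0),
                          hard_weight=math.inf)
    return max_flow_min_cut(graph)


def write_dimacs(graph: GraphSpec, path: str | Path) -> None:
    """Dump the graph in DIMACS max-flow format (1-based node ids) for debugging."""
    graph.validate()
    n = graph.n_nodes
    src, dst, w = graph.pair_edges()
    lines = []
    s_id, t_id = n + 1, n + 2
    arcs = []
    for v in range(n):
        if graph.t_source[v] > 0:
            arcs.append(f"a {s_id} {v + 1} {graph.t_source[v]:.17g}")
        if graph.t_sink[v] > 0:
            arcs.append(f"a {v + 1} {t_id} {graph.t_sink[v]:.17g}")
    for u, v, wt in zip(src, dst, w):
        arcs.append(f"a {u + 1} {v + 1} {wt:.17g}")
        arcs.append(f"a {v + 1} {u + 1} {wt:.17g}")
    lines.append(f"p max {n + 2} {len(arcs)}")
    lines.append(f"n {s_id} s")
    lines.append(f"n {t_id} t")
    Path(path).write_text("\n".join(lines + arcs) + "\n")
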