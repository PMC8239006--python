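"""Dendrite geometry, synapse placement, and structural plasticity.

A dendrite is either a linear branch (optionally with periodic boundary
conditions, used for the two-synapse and branch-clustering protocols) or a
rooted tree of ~10-um segments obtained from an SWC reconstruction or the
synthetic tree generator.  Synapse positions live on the dendrite; pairwise
path distances feed the Gaussian proximity matrix s_kl = exp(-d^2/(2 sigma^2))
through which postsynaptic calcium spreads.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "Dendrite", "SynapseSet", "TurnoverRecord",
    "place_synapses", "pairwise_distance", "proximity_matrix",
    "load_swc", "parse_swc", "write_swc", "resample", "synthetic_tree",
    "apply_turnover", "density_ramp_schedule",
]


# ---------------------------------------------------------------------------
# dendrite representation

@dataclass
class Dendrite:
    """Linear branch or segmented rooted tree.

    Tree mode stores one row per segment: ``parent`` (index into segments,
    -1 for segments attached to the soma), ``length`` (um) and the
    path distance from the soma to the segment's proximal end
    (``proximal_path``).  Synapse positions on a tree are (segment, offset)
    pairs with offset measured from the proximal end.
    """

    mode: str                       # "linear" | "tree"
    length: float = 0.0             # linear: branch length, um
    periodic: bool = False
    seg_parent: np.ndarray | None = None     # (S,) int
    seg_length: np.ndarray | None = None     # (S,) float
    swc_meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.mode not in ("linear", "tree"):
            raise ValueError(f"unknown dendrite mode {self.mode!r}")
        if self.mode == "linear" and self.length <= 0:
            raise ValueError("linear dendrite needs positive length")
        if self.mode == "tree":
            self.seg_parent = np.asarray(self.seg_parent, dtype=int)
            self.seg_length = np.asarray(self.seg_length, dtype=float)
            self._validate_tree()

    # -- tree helpers ------------------------------------------------------
    def _validate_tree(self):
        par = self.seg_parent
        n = len(par)
        if n == 0:
            raise ValueError("tree has no segments")
        if not np.any(par < 0):
            raise ValueError("tree has no root-attached segment")
        # acyclicity / single connected rooted structure
        for i in range(n):
            seen = set()
            j = i
            while j >= 0:
                if j in seen:
                    raise ValueError("cycle detected in segment parents")
                seen.add(j)
                j = par[j]

    @property
    def n_segments(self) -> int:
        return 0 if self.mode == "linear" else len(self.seg_length)

    @property
    def total_length(self) -> float:
        if self.mode == "linear":
            return self.length
        return float(np.sum(self.seg_length))

    def proximal_path(self) -> np.ndarray:
        """Path distance from soma to each segment's proximal end."""
        par, ln = self.seg_parent, self.seg_length
        out = np.zeros(len(ln))
        # parents precede children is not guaranteed; walk iteratively
        for i in range(len(ln)):
            d, j = 0.0, par[i]
            while j >= 0:
                d += ln[j]
                j = par[j]
            out[i] = d
        return out

    def soma_distance(self, positions: np.ndarray) -> np.ndarray:
        """Path distance from the soma (root / coordinate 0) per position."""
        positions = np.asarray(positions, dtype=float)
        if self.mode == "linear":
            if self.periodic:
                return np.minimum(positions, self.length - positions)
            return positions
        seg = positions[:, 0].astype(int)
        off = positions[:, 1]
        return self.proximal_path()[seg] + off

    def segment_graph(self) -> nx.Graph:
        """Node graph: node -1 is the soma; node i is segment i's distal end."""
        g = nx.Graph()
        g.add_node(-1)
        for i in range(self.n_segments):
            g.add_edge(int(self.seg_parent[i]), i, weight=float(self.seg_length[i]))
        return g


# ---------------------------------------------------------------------------
# synapse sets

@dataclass
class TurnoverRecord:
    time_ms: float
    old_id: int
    new_id: int
    new_position: float      # linear coordinate, or path distance for trees
    new_theta: float


@dataclass
class SynapseSet:
    """Synapses on a dendrite with identities stable across turnover.

    ``positions`` is (N,) for linear dendrites or (N, 2) [segment, offset]
    for trees.  ``ids`` are persistent labels: a replaced synapse gets a
    fresh id so survival statistics can distinguish original from
    replacement synapses.
    """

    dendrite: Dendrite
    positions: np.ndarray
    efficacy: np.ndarray
    ids: np.ndarray
    kind: np.ndarray                # "exc" | "gaba"
    birth_time: np.ndarray
    rfs: list = field(default_factory=list)   # GaborRF per synapse (optional)
    log: list = field(default_factory=list)   # TurnoverRecord list
    _next_id: int = 0

    @property
    def n(self) -> int:
        return len(self.ids)

    def distances(self) -> np.ndarray:
        return pairwise_distance(self.dendrite, self.positions)

    def linear_coordinate(self) -> np.ndarray:
        """Scalar coordinate usable for logs (path distance on trees)."""
        if self.dendrite.mode == "linear":
            return np.asarray(self.positions, dtype=float)
        return self.dendrite.soma_distance(self.positions)

    def log_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r.time_ms, r.old_id, r.new_position, r.new_theta) for r in self.log],
            columns=["time_ms", "old_id", "new_position_um", "new_theta_deg"],
        )


def _random_positions(dendrite: Dendrite, n: int, rng: np.random.Generator) -> np.ndarray:
    if dendrite.mode == "linear":
        return rng.uniform(0.0, dendrite.length, size=n)
    # uniform over total cable: pick segment proportional to length
    p = dendrite.seg_length / dendrite.total_length
    seg = rng.choice(len(p), size=n, p=p)
    off = rng.uniform(0.0, 1.0, size=n) * dendrite.seg_length[seg]
    return np.column_stack([seg.astype(float), off])


def place_synapses(dendrite: Dendrite, nu: float, seed=None, *,
                   initial_efficacy: float = 0.5, kind: str = "exc",
                   rng: np.random.Generator | None = None) -> SynapseSet:
    """Distribute ``N = floor(L * nu)`` synapses uniformly on the dendrite.

    Efficacies start at 0.5 (the reference efficacy used by every protocol).
    """
    if nu <= 0:
        raise ValueError("density nu must be positive")
    n = int(math.floor(dendrite.total_length * nu))
    if n == 0:
        raise ValueError("density too low: would place zero synapses")
    if rng is None:
        rng = np.random.default_rng(seed)
    pos = _random_positions(dendrite, n, rng)
    return SynapseSet(
        dendrite=dendrite,
        positions=pos,
        efficacy=np.full(n, initial_efficacy, dtype=float),
        ids=np.arange(n),
        kind=np.array([kind] * n, dtype=object),
        birth_time=np.zeros(n),
        _next_id=n,
    )


# ---------------------------------------------------------------------------
# distances and proximity

def _node_distances(dendrite: Dendrite):
    """Distance matrix between segment distal ends (cached; node -1 = soma)."""
    cached = getattr(dendrite, "_node_dist_cache", None)
    if cached is not None:
        return cached
    g = dendrite.segment_graph()
    nodes = sorted(g.nodes)
    idx = {u: i for i, u in enumerate(nodes)}
    nd = np.zeros((len(nodes), len(nodes)))
    for u, dists in nx.all_pairs_dijkstra_path_length(g, weight="weight"):
        for v, d in dists.items():
            nd[idx[u], idx[v]] = d
    dendrite._node_dist_cache = (nd, idx)
    return nd, idx


def _tree_pairwise(dendrite: Dendrite, positions: np.ndarray) -> np.ndarray:
    seg = positions[:, 0].astype(int)
    off = positions[:, 1]
    if np.any(seg < 0) or np.any(seg >= dendrite.n_segments):
        raise ValueError("segment index off the dendrite")
    if np.any(off < -1e-9) or np.any(off > dendrite.seg_length[seg] + 1e-9):
        raise ValueError("offset outside its segment")
    nd, idx = _node_distances(dendrite)
    seg_len = dendrite.seg_length
    par = dendrite.seg_parent
    imap = np.vectorize(idx.__getitem__)
    # each synapse can exit its segment through the proximal or distal end
    ends = np.stack([imap(par[seg]), imap(seg)])            # (2, n)
    costs = np.stack([off, seg_len[seg] - off])             # (2, n)
    best = np.full((len(seg), len(seg)), np.inf)
    for a in range(2):
        for b in range(2):
            cand = (costs[a][:, None] + nd[np.ix_(ends[a], ends[b])]
                    + costs[b][None, :])
            np.minimum(best, cand, out=best)
    same = seg[:, None] == seg[None, :]
    direct = np.abs(off[:, None] - off[None, :])
    out = np.where(same, direct, best)
    np.fill_diagonal(out, 0.0)
    return out


def pairwise_distance(dendrite: Dendrite, positions: np.ndarray) -> np.ndarray:
    """Pairwise path distance (um) between synapse positions."""
    positions = np.asarray(positions, dtype=float)
    if dendrite.mode == "linear":
        if np.any(positions < 0) or np.any(positions > dendrite.length):
            raise ValueError("position off the dendrite")
        delta = np.abs(positions[:, None] - positions[None, :])
        if dendrite.periodic:
            delta = np.minimum(delta, dendrite.length - delta)
        return delta
    return _tree_pairwise(dendrite, positions)


def cross_distance(dendrite: Dendrite, pos_a: np.ndarray, pos_b: np.ndarray) -> np.ndarray:
    """Distances between two position sets (rows of joint pairwise matrix)."""
    pos_a = np.atleast_1d(np.asarray(pos_a, dtype=float))
    pos_b = np.atleast_1d(np.asarray(pos_b, dtype=float))
    if dendrite.mode == "linear":
        delta = np.abs(pos_a[:, None] - pos_b[None, :])
        if dendrite.periodic:
            delta = np.minimum(delta, dendrite.length - delta)
        return delta
    both = np.vstack([np.atleast_2d(pos_a), np.atleast_2d(pos_b)])
    full = _tree_pairwise(dendrite, both)
    na = np.atleast_2d(pos_a).shape[0]
    return full[:na, na:]


def proximity_matrix(distances: np.ndarray, sigma: float, *,
                     cutoff_sigmas: float = 5.0) -> np.ndarray:
    """Gaussian proximity s = exp(-d^2 / (2 sigma^2)), zero beyond the cutoff.

    The cutoff (default 5 sigma, where s < 4e-6) keeps the coupling sparse
    without measurable effect on the dynamics.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    d = np.asarray(distances, dtype=float)
    s = np.exp(-d * d / (2.0 * sigma * sigma))
    s[d > cutoff_sigmas * sigma] = 0.0
    return s


# ---------------------------------------------------------------------------
# SWC input / output and resampling

def parse_swc(text: str) -> pd.DataFrame:
    rows = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 7:
            raise ValueError(f"malformed SWC line: {line!r}")
        rows.append((int(parts[0]), int(parts[1]), float(parts[2]),
                     float(parts[3]), float(parts[4]), float(parts[5]),
                     int(parts[6])))
    if not rows:
        raise ValueError("empty SWC")
    df = pd.DataFrame(rows, columns=["id", "type", "x", "y", "z", "radius", "parent"])
    roots = df[df.parent == -1]
    if len(roots) != 1:
        raise ValueError(f"SWC must have exactly one root, found {len(roots)}")
    known = set(df.id)
    if not set(df.parent) - {-1} <= known:
        raise ValueError("SWC references unknown parent ids")
    return df


def load_swc(path_or_text, *, step: float = 10.0) -> Dendrite:
    """Read an SWC morphology and resample it into ~`step`-um segments.

    The soma (the single root sample) becomes the tree root; cumulative path
    lengths are preserved to within one resampling step.
    """
    if hasattr(path_or_text, "read"):
        text = path_or_text.read()
    elif isinstance(path_or_text, str) and "\n" in path_or_text:
        text = path_or_text
    else:
        with open(path_or_text) as fh:
            text = fh.read()
    df = parse_swc(text)
    # build point tree
    parent = dict(zip(df.id, df.parent))
    coords = {r.id: np.array([r.x, r.y, r.z]) for r in df.itertuples()}
    children: dict[int, list[int]] = {i: [] for i in df.id}
    for i, p in parent.items():
        if p != -1:
            # cycle guard
            seen, j = set(), i
            while j != -1:
                if j in seen:
                    raise ValueError("cyclic SWC")
                seen.add(j)
                j = parent[j]
            children[p].append(i)
    root = int(df[df.parent == -1].id.iloc[0])
    # walk unbranched paths from every branch point (or root)
    seg_parent: list[int] = []
    seg_length: list[float] = []

    def walk(start_node: int, attach_seg: int):
        for child in children[start_node]:
            # accumulate the unbranched run starting at (start_node -> child)
            run = [start_node, child]
            node = child
            while len(children[node]) == 1:
                node = children[node][0]
                run.append(node)
            length = sum(np.linalg.norm(coords[run[i + 1]] - coords[run[i]])
                         for i in range(len(run) - 1))
            if length <= 0:
                # zero-length connector (duplicate sample): recurse through
                walk(node, attach_seg)
                continue
            nseg = max(1, int(round(length / step)))
            piece = length / nseg
            par = attach_seg
            for _ in range(nseg):
                seg_parent.append(par)
                seg_length.append(piece)
                par = len(seg_parent) - 1
            walk(node, par)

    walk(root, -1)
    return Dendrite(mode="tree", seg_parent=np.array(seg_parent, dtype=int),
                    seg_length=np.array(seg_length, dtype=float),
                    swc_meta={"source_points": len(df), "step": step})


def resample(dendrite: Dendrite, step: float = 10.0) -> Dendrite:
    """Re-segment a tree into ~`step`-um pieces (idempotent on segment count
    when the current piece lengths already divide evenly)."""
    if dendrite.mode != "tree":
        raise ValueError("resample applies to tree dendrites")
    return load_swc(write_swc(dendrite), step=step)


def write_swc(dendrite: Dendrite, path=None) -> str:
    """Serialize a tree dendrite to SWC (synthetic planar layout).

    Segment chain geometry is laid out so that Euclidean distances along each
    branch equal path lengths; coordinates are otherwise arbitrary.
    """
    if dendrite.mode != "tree":
        raise ValueError("write_swc applies to tree dendrites")
    par = dendrite.seg_parent
    ln = dendrite.seg_length
    n = len(ln)
    children: dict[int, list[int]] = {i: [] for i in range(-1, n)}
    for i in range(n):
        children[int(par[i])].append(i)
    # assign a direction per segment: branch children fan out
    pos = {-1: np.array([0.0, 0.0, 0.0])}
    direc = {-1: np.array([0.0, 1.0, 0.0])}
    order = []
    stack = [-1]
    while stack:
        u = stack.pop()
        kids = children[u]
        for j, k in enumerate(kids):
            if len(kids) == 1:
                d = direc[u]
            else:
                ang = (j - (len(kids) - 1) / 2.0) * (math.pi / 4.0)
                base = math.atan2(direc[u][1], direc[u][0]) + ang
                d = np.array([math.cos(base), math.sin(base), 0.0])
            direc[k] = d
            pos[k] = pos[u] + d * ln[k]
            order.append(k)
            stack.append(k)
    lines = ["# synthetic SWC written by dendroclust", "1 1 0.0 0.0 0.0 1.0 -1"]
    swc_id = {-1: 1}
    next_id = 2
    for k in sorted(order):
        swc_id[k] = next_id
        next_id += 1
    for k in sorted(order):
        p = pos[k]
        lines.append(f"{swc_id[k]} 3 {p[0]:.4f} {p[1]:.4f} {p[2]:.4f} 0.5 "
                     f"{swc_id[int(par[k])]}")
    text = "\n".join(lines) + "\n"
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def synthetic_tree(n_branches: int = 12, depth: int = 3, *,
                   trunk_length: float = 50.0, mean_branch_length: float = 120.0,
                   total_length: float | None = 1500.0,
                   step: float = 10.0, seed=None) -> Dendrite:
    """Random binary-branching tree, written/read as valid SWC.

    Stands in for a reconstructed pyramidal-cell morphology when no download
    is available: what matters downstream is the path-distance structure, not
    the precise arborization.  Total cable length defaults to ~1500 um so
    both proximal and distal regimes exist for every bAP attenuation factor.
    """
    if n_branches < 1:
        raise ValueError("n_branches must be >= 1")
    rng = np.random.default_rng(seed)
    seg_parent: list[int] = []
    seg_length: list[float] = []

    def add_cable(parent: int, length: float) -> int:
        nseg = max(1, int(round(length / step)))
        piece = length / nseg
        for _ in range(nseg):
            seg_parent.append(parent)
            seg_length.append(piece)
            parent = len(seg_parent) - 1
        return parent

    tips = [add_cable(-1, trunk_length)]
    made = 1
    level = 0
    while made < n_branches and level < depth + 4:
        new_tips = []
        for t in tips:
            for _ in range(2):
                if made >= n_branches:
                    break
                ln = max(step, rng.normal(mean_branch_length, mean_branch_length / 4))
                new_tips.append(add_cable(t, ln))
                made += 1
        tips = new_tips or tips
        level += 1
    dend = Dendrite(mode="tree", seg_parent=np.array(seg_parent, dtype=int),
                    seg_length=np.array(seg_length, dtype=float))
    if total_length is not None:
        scale = total_length / dend.total_length
        dend = Dendrite(mode="tree", seg_parent=dend.seg_parent,
                        seg_length=dend.seg_length * scale)
    return dend


# ---------------------------------------------------------------------------
# structural plasticity

def apply_turnover(synapses: SynapseSet, rf_sampler, rng: np.random.Generator,
                   *, W_thr: float = 0.02, time_ms: float = 0.0) -> list[int]:
    """Replace every synapse whose efficacy fell below ``W_thr``.

    Each replacement gets a fresh uniform position, a freshly sampled
    receptive field (uniform orientation, Gaussian centre), efficacy 0.5 and
    a new id; the total count is preserved and each event is logged.
    Returns the indices that were replaced.
    """
    low = np.where(synapses.efficacy < W_thr)[0]
    for k in low:
        new_pos = _random_positions(synapses.dendrite, 1, rng)[0]
        new_rf = rf_sampler(rng) if rf_sampler is not None else None
        old_id = int(synapses.ids[k])
        new_id = synapses._next_id
        synapses._next_id += 1
        synapses.positions[k] = new_pos
        synapses.efficacy[k] = 0.5
        synapses.ids[k] = new_id
        synapses.birth_time[k] = time_ms
        if synapses.rfs:
            synapses.rfs[k] = new_rf
        coord = (float(new_pos) if synapses.dendrite.mode == "linear"
                 else float(synapses.dendrite.soma_distance(new_pos[None, :])[0]))
        theta = float(new_rf.theta) if new_rf is not None else float("nan")
        synapses.log.append(TurnoverRecord(time_ms, old_id, new_id, coord, theta))
    return list(low)


def density_ramp_schedule(length: float, nu_start: float, nu_end: float,
                          duration_ms: float, *, add_interval_ms: float = 64 * 60e3):
    """Insertion times and concurrent calcium-conservation scaling.

    Returns ``(times_ms, scale_fn)`` where ``times_ms`` are the regular
    insertion times needed to go from ``floor(L*nu_start)`` to
    ``floor(L*nu_end)`` synapses, and ``scale_fn(t)`` gives the factor by
    which both the calcium spread sigma_c and the per-event calcium
    increment are multiplied so that sigma_c * increment * nu stays constant
    (total neighbourhood calcium conserved): scale(t) = sqrt(nu_start/nu(t)).
    """
    if nu_end <= nu_start:
        raise ValueError("end density must exceed start density")
    n0 = math.floor(length * nu_start)
    n1 = math.floor(length * nu_end)
    n_add = n1 - n0
    times = add_interval_ms * np.arange(1, n_add + 1)
    if len(times) and times[-1] > duration_ms:
        times = times[times <= duration_ms]

    def scale_fn(t: float) -> float:
        frac = min(max(t / duration_ms, 0.0), 1.0)
        nu_t = nu_start + (nu_end - nu_start) * frac
        return math.sqrt(nu_start / nu_t)

    return times, scale_fn
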