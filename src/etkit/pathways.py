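"""Tunneling-pathway search and the distance-decay electron-transfer rate.

The route model is the classic empirical tunneling-pathway picture: each
step between heavy atoms carries a multiplicative coupling decay that
depends on whether the step is covalent, hydrogen-bond mediated, or a
through-space jump.  The best donor→acceptor route maximizes the product
of decays, found as a shortest path under additive weights -ln(decay).
The ET rate follows the exponential distance-decay law
k_ET = A0 * exp(-beta * R) with R the summed step length of the route.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field

import numpy as np

from .structures import BondTopology, Structure, detect_hbonds

__all__ = [
    "TunnelingParams",
    "ETRateParams",
    "TunnelingGraph",
    "TunnelingPath",
    "build_tunneling_graph",
    "best_pathway",
    "path_length",
    "compute_ket",
]


@dataclass(frozen=True)
class TunnelingParams:
    """Per-step decay parameters of the empirical pathway model.

    Defaults follow the standard parameterization: covalent steps decay by
    0.6; through-space by 0.6*exp(-1.7*(d-1.4)); hydrogen bonds by
    0.36*exp(-1.7*(d-2.8)).  All overridable.
    """

    eps_covalent: float = 0.6
    space_prefactor: float = 0.6
    space_decay: float = 1.7  # 1/Å
    space_offset: float = 1.4  # Å
    hbond_prefactor: float = 0.36
    hbond_decay: float = 1.7  # 1/Å
    hbond_offset: float = 2.8  # Å
    space_cutoff: float = 6.0  # Å

    def __post_init__(self):
        if self.space_decay <= 0 or self.hbond_decay <= 0:
            raise ValueError("decay constants must be positive")
        for p in (self.eps_covalent, self.space_prefactor, self.hbond_prefactor):
            if not (0 < p <= 1):
                raise ValueError("prefactors must lie in (0, 1]")
        if self.space_cutoff <= self.space_offset:
            raise ValueError("space_cutoff must exceed space_offset")

    def space_decay_at(self, d: float) -> float:
        val = self.space_prefactor * math.exp(-self.space_decay * (d - self.space_offset))
        return min(val, self.eps_covalent)

    def hbond_decay_at(self, d: float) -> float:
        val = self.hbond_prefactor * math.exp(-self.hbond_decay * (d - self.hbond_offset))
        return min(val, self.eps_covalent)


@dataclass(frozen=True)
class ETRateParams:
    """Constants of the distance-decay rate law k_ET = A0 exp(-beta R)."""

    A0: float = 2.0e12  # s^-1
    beta_tunnel: float = 1.06  # 1/Å

    def __post_init__(self):
        if self.A0 <= 0 or self.beta_tunnel <= 0:
            raise ValueError("A0 and beta_tunnel must be positive")


@dataclass(frozen=True)
class TunnelingEdge:
    i: int
    j: int
    step_type: str  # covalent | hbond | space
    step_distance: float  # Å
    decay: float

    def __post_init__(self):
        if self.step_distance < 0:
            raise ValueError("step distance must be non-negative")
        if not (0 < self.decay <= 1):
            raise ValueError("decay must lie in (0, 1]")


@dataclass
class TunnelingGraph:
    """Atom-level tunneling graph: nodes are heavy-atom indices."""

    nodes: list[int]
    edges: list[TunnelingEdge]
    structure: Structure | None = None

    def adjacency(self) -> dict[int, list[TunnelingEdge]]:
        adj: dict[int, list[TunnelingEdge]] = {n: [] for n in self.nodes}
        for e in self.edges:
            adj[e.i].append(e)
            adj[e.j].append(e)
        return adj


@dataclass
class TunnelingPath:
    """A simple donor→acceptor route through the tunneling graph."""

    node_sequence: list[int]
    step_types: list[str]
    step_distances: list[float]
    total_R: float = field(init=False)
    total_coupling: float = field(init=False)
    residue_trace: list[str] = field(default_factory=list)
    step_decays: list[float] = field(default_factory=list)

    def __post_init__(self):
        if len(set(self.node_sequence)) != len(self.node_sequence):
            raise ValueError("path must be simple (no repeated node)")
        self.total_R = float(sum(self.step_distances))
        self.total_coupling = float(np.prod(self.step_decays)) if self.step_decays else 1.0


def build_tunneling_graph(
    structure: Structure,
    bonds: BondTopology,
    params: TunnelingParams = TunnelingParams(),
) -> TunnelingGraph:
    """Classify every heavy-atom pair as covalent, H-bond, or space edge.

    Precedence covalent > hbond > space; space edges only within
    ``params.space_cutoff``; H-bond edges connect donor and acceptor heavy
    atoms of hydrogen bonds detected on the single frame.
    """
    heavy = structure.heavy_atom_indices()
    if len(heavy) < 2:
        raise ValueError("need at least two heavy atoms")
    coords = structure.coords
    heavy_set = set(heavy)

    edges: dict[frozenset, TunnelingEdge] = {}
    for b in bonds.bonds:
        i, j = sorted(b)
        if i in heavy_set and j in heavy_set:
            d = float(np.linalg.norm(coords[i] - coords[j]))
            edges[frozenset((i, j))] = TunnelingEdge(
                i, j, "covalent", d, params.eps_covalent
            )

    for hb in detect_hbonds(structure, bonds):
        key = frozenset((hb.donor, hb.acceptor))
        if key in edges:
            continue
        i, j = sorted(key)
        edges[key] = TunnelingEdge(
            i, j, "hbond", hb.distance, params.hbond_decay_at(hb.distance)
        )

    arr = np.array(heavy)
    c = coords[arr]
    dmat = np.linalg.norm(c[:, None, :] - c[None, :, :], axis=-1)
    for a in range(len(arr)):
        for b2 in range(a + 1, len(arr)):
            d = float(dmat[a, b2])
            if d > params.space_cutoff:
                continue
            key = frozenset((int(arr[a]), int(arr[b2])))
            if key in edges:
                continue
            i, j = sorted(key)
            edges[key] = TunnelingEdge(i, j, "space", d, params.space_decay_at(d))

    return TunnelingGraph(nodes=list(heavy), edges=list(edges.values()), structure=structure)


def _residue_trace(structure: Structure | None, node_sequence: list[int]) -> list[str]:
    if structure is None:
        return []
    trace: list[str] = []
    for idx in node_sequence:
        a = structure.atoms[idx]
        label = f"{a.residue_name}{a.residue_id}:{a.chain}"
        if not trace or trace[-1] != label:
            trace.append(label)
    return trace


def best_pathway(
    graph: TunnelingGraph,
    donor: set[int],
    acceptor: set[int],
) -> TunnelingPath | None:
    """Maximum-coupling simple path from any donor to any acceptor atom.

    Equivalent to a shortest path under weights -ln(decay); ties broken by
    smaller total R, then lexicographically on the node sequence.  Returns
    None when donor and acceptor are disconnected.
    """
    donor = set(donor)
    acceptor = set(acceptor)
    node_set = set(graph.nodes)
    if not donor or not acceptor:
        raise ValueError("donor and acceptor sets must be non-empty")
    if donor & acceptor:
        raise ValueError("donor and acceptor sets must be disjoint")
    if not donor <= node_set or not acceptor <= node_set:
        raise ValueError("donor/acceptor atoms must be graph nodes")

    adj = graph.adjacency()
    edge_info = {frozenset((e.i, e.j)): e for e in graph.edges}
    # label = (cost, total_R, path); all edge weights -ln(decay) >= 0
    heap: list[tuple[float, float, tuple[int, ...]]] = []
    for d in sorted(donor):
        heapq.heappush(heap, (0.0, 0.0, (d,)))
    settled: set[int] = set()
    while heap:
        cost, R, path = heapq.heappop(heap)
        node = path[-1]
        if node in settled:
            continue
        settled.add(node)
        if node in acceptor:
            seq = list(path)
            types, dists, decays = [], [], []
            for u, v in zip(seq[:-1], seq[1:]):
                e = edge_info[frozenset((u, v))]
                types.append(e.step_type)
                dists.append(e.step_distance)
                decays.append(e.decay)
            return TunnelingPath(
                node_sequence=seq,
                step_types=types,
                step_distances=dists,
                step_decays=decays,
                residue_trace=_residue_trace(graph.structure, seq),
            )
        for e in adj[node]:
            nb = e.j if e.i == node else e.i
            if nb in settled or nb in path:
                continue
            heapq.heappush(
                heap, (cost - math.log(e.decay), R + e.step_distance, path + (nb,))
            )
    return None


def path_length(
    path: TunnelingPath,
    residue_step_distances: list[float] | None = None,
) -> float:
    """Total pathway length R in Å.

    By default the sum of atom-level step distances; when per-residue step
    distances are supplied (the residue-level convention of summing shortest
    distances between neighbouring residues on the route), those are summed
    instead.
    """
    if residue_step_distances is not None:
        return float(sum(residue_step_distances))
    return float(sum(path.step_distances))


def compute_ket(R: float, params: ETRateParams = ETRateParams()) -> float:
    """Distance-decay ET rate k_ET = A0 * exp(-beta * R), in s^-1."""
    if R < 0:
        raise ValueError("pathway length R must be non-negative")
    return params.A0 * math.exp(-params.beta_tunnel * R)
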