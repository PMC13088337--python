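"""Synthetic inputs with known ground truth for every pipeline stage.

Four generators: Metropolis samples of analytic 1-D potentials under
harmonic umbrella biases (for the MBAR/PMF machinery), toy tunneling
graphs small enough for exhaustive route enumeration, trajectories whose
distance/angle/H-bond series follow exactly planted draws, and a small
two-domain structure fixture whose best tunneling route is known by
construction.  All generators are pure functions of their spec (seed
included) and emit a machine-readable truth record.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np

from .constants import KB_KCAL
from .pathways import TunnelingEdge, TunnelingGraph, TunnelingParams, TunnelingPath
from .pmf import UmbrellaWindow
from .structures import Atom, Structure, Trajectory

__all__ = [
    "AnalyticPotential",
    "SamplerSpec",
    "PlantedTrajectorySpec",
    "sample_umbrella_windows",
    "make_toy_graph",
    "make_planted_trajectory",
    "make_two_domain_structure",
    "write_xyz",
]


@dataclass(frozen=True)
class AnalyticPotential:
    """1-D potential with closed-form landmarks, kcal/mol.

    ``harmonic``: U = 1/2 κ (x-x0)^2.  ``double_well``: U = a (x^2-b^2)^2
    with minima at ±b and an exact central barrier of a·b^4.
    """

    kind: str
    kappa: float = 1.0
    x0: float = 0.0
    a: float = 1.5
    b: float = 1.0

    def __post_init__(self):
        if self.kind not in ("harmonic", "double_well"):
            raise ValueError(f"unknown potential kind {self.kind!r}")
        if self.kind == "harmonic" and self.kappa <= 0:
            raise ValueError("kappa must be positive")
        if self.kind == "double_well" and (self.a <= 0 or self.b <= 0):
            raise ValueError("a and b must be positive")

    def energy(self, x):
        x = np.asarray(x, dtype=float)
        if self.kind == "harmonic":
            return 0.5 * self.kappa * (x - self.x0) ** 2
        return self.a * (x**2 - self.b**2) ** 2

    @property
    def analytic_barrier(self) -> float:
        if self.kind != "double_well":
            raise ValueError("barrier defined only for the double well")
        return self.a * self.b**4

    @property
    def analytic_minima(self):
        if self.kind == "harmonic":
            return (self.x0,)
        return (-self.b, self.b)


@dataclass(frozen=True)
class SamplerSpec:
    """Umbrella-sampling spec: potential, windows, chain-length bookkeeping."""

    potential: AnalyticPotential
    centers: tuple
    force_constant: float = 100.0  # kcal/mol/Å^2 under the stated convention
    convention: str = "k_full"
    temperature: float = 300.0
    n_samples: int = 5000
    step_size: float | None = None
    burn_in_steps: int = 500
    thin: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.convention not in ("k_full", "k_half"):
            raise ValueError(f"unknown convention {self.convention!r}")


def sample_umbrella_windows(spec: SamplerSpec) -> tuple[list[UmbrellaWindow], dict]:
    """Metropolis-sample exp(-β(U + U_bias)) in every window simultaneously.

    The proposal step is tuned toward ~40 % acceptance during burn-in and
    then frozen, so the production samples follow the exact target
    distribution.  Returns the windows plus a truth/metadata record
    (potential, acceptance rates, warn flags, seed).
    """
    rng = np.random.default_rng(spec.seed)
    centers = np.asarray(spec.centers, dtype=float)
    K = centers.size
    beta = 1.0 / (KB_KCAL * spec.temperature)
    pref = spec.force_constant if spec.convention == "k_full" else 0.5 * spec.force_constant

    def total_energy(x):
        return spec.potential.energy(x) + pref * (x - centers) ** 2

    if spec.step_size is not None:
        step = np.full(K, float(spec.step_size))
    elif spec.force_constant > 0:
        sigma = np.sqrt(1.0 / (2.0 * beta * pref))
        step = np.full(K, 2.0 * sigma)
    else:
        step = np.full(K, 0.5)

    x = centers.copy()
    e = total_energy(x)

    def sweep(n_steps, adapt: bool):
        nonlocal x, e, step
        accepted = np.zeros(K)
        block = np.zeros(K)
        for t in range(n_steps):
            prop = x + step * rng.uniform(-1.0, 1.0, size=K)
            e_prop = total_energy(prop)
            accept = rng.uniform(size=K) < np.exp(-beta * np.clip(e_prop - e, -700 / beta, 700 / beta))
            x = np.where(accept, prop, x)
            e = np.where(accept, e_prop, e)
            accepted += accept
            block += accept
            if adapt and (t + 1) % 50 == 0:
                rate = block / 50.0
                step = np.where(rate > 0.5, step * 1.2, step)
                step = np.where(rate < 0.3, step / 1.2, step)
                block[:] = 0.0
        return accepted / max(n_steps, 1)

    sweep(spec.burn_in_steps, adapt=True)
    samples = np.empty((K, spec.n_samples))
    accepted = np.zeros(K)
    for i in range(spec.n_samples):
        accepted += sweep(spec.thin, adapt=False) * spec.thin
        samples[:, i] = x
    acc_rate = accepted / (spec.n_samples * spec.thin)

    windows = [
        UmbrellaWindow(
            window_id=k,
            bias_center=float(centers[k]),
            force_constant=spec.force_constant,
            rc_samples=samples[k],
        )
        for k in range(K)
    ]
    meta = {
        "potential": spec.potential,
        "seed": spec.seed,
        "acceptance_rates": acc_rate,
        "step_sizes": step,
        "acceptance_warning": bool(np.any((acc_rate < 0.1) | (acc_rate > 0.9))),
    }
    return windows, meta


# ---------------------------------------------------------------------------
# Toy tunneling graphs with exhaustive oracle
# ---------------------------------------------------------------------------

def _enumerate_best_path(graph: TunnelingGraph, donor: int, acceptor: int) -> TunnelingPath | None:
    """Exhaustive simple-path oracle with the production tie-breaking:
    max coupling, then min total R, then lexicographic node sequence."""
    G = nx.Graph()
    G.add_nodes_from(graph.nodes)
    info = {}
    for e in graph.edges:
        G.add_edge(e.i, e.j)
        info[frozenset((e.i, e.j))] = e
    best_key = None
    best_path = None
    for path in nx.all_simple_paths(G, donor, acceptor):
        cost = 0.0
        R = 0.0
        for u, v in zip(path[:-1], path[1:]):
            e = info[frozenset((u, v))]
            cost += -math.log(e.decay)
            R += e.step_distance
        key = (cost, R, tuple(path))
        if best_key is None or key < best_key:
            best_key = key
            best_path = path
    if best_path is None:
        return None
    types, dists, decays = [], [], []
    for u, v in zip(best_path[:-1], best_path[1:]):
        e = info[frozenset((u, v))]
        types.append(e.step_type)
        dists.append(e.step_distance)
        decays.append(e.decay)
    return TunnelingPath(
        node_sequence=list(best_path),
        step_types=types,
        step_distances=dists,
        step_decays=decays,
    )


def make_toy_graph(
    n_nodes: int,
    edge_density: float = 0.5,
    seed: int = 0,
    params: TunnelingParams = TunnelingParams(),
) -> tuple[TunnelingGraph, TunnelingPath]:
    """Random geometric tunneling graph plus its exhaustively enumerated
    optimum (donor = node 0, acceptor = last node)."""
    if not (3 <= n_nodes <= 12):
        raise ValueError("n_nodes must lie in [3, 12] (oracle is exhaustive)")
    if not (0 < edge_density <= 1):
        raise ValueError("edge_density must lie in (0, 1]")
    for attempt in range(100):
        rng = np.random.default_rng(seed + 7919 * attempt)
        pos = rng.uniform(0.0, 8.0, size=(n_nodes, 3))
        edges: list[TunnelingEdge] = []
        for i in range(n_nodes):
            for j in range(i + 1, n_nodes):
                if rng.uniform() > edge_density:
                    continue
                d = float(np.linalg.norm(pos[i] - pos[j]))
                kind = rng.choice(["covalent", "hbond", "space"], p=[0.5, 0.25, 0.25])
                if kind == "covalent":
                    decay = params.eps_covalent
                elif kind == "hbond":
                    decay = params.hbond_decay_at(d)
                else:
                    decay = params.space_decay_at(d)
                edges.append(TunnelingEdge(i, j, str(kind), d, decay))
        graph = TunnelingGraph(nodes=list(range(n_nodes)), edges=edges)
        oracle = _enumerate_best_path(graph, 0, n_nodes - 1)
        if oracle is not None:
            return graph, oracle
    raise RuntimeError(
        f"could not generate a connected toy graph in 100 attempts (seed {seed})"
    )


# ---------------------------------------------------------------------------
# Planted trajectories
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedTrajectorySpec:
    """Distribution spec for a trajectory with exactly planted observables.

    ``distance_law`` / ``angle_law``: ("constant", v), ("gaussian", mu,
    sigma), or ("mixture", ((w, mu, sigma), ...)).  Distances are the oxo-
    oxygen-to-substrate-hydrogen attack distance in Å; angles the
    Fe–O⋯target angle in degrees.  ``hbond_frame_fraction`` of the frames
    carry a geometrically satisfied donor–H⋯acceptor triplet (exact count).
    """

    n_frames: int = 2000
    distance_law: tuple = ("gaussian", 4.63, 1.01)
    angle_law: tuple = ("gaussian", 142.0, 7.7)
    hbond_frame_fraction: float = 0.3728
    seed: int = 0

    def __post_init__(self):
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if not (0 <= self.hbond_frame_fraction <= 1):
            raise ValueError("hbond_frame_fraction must lie in [0, 1]")
        for law in (self.distance_law, self.angle_law):
            if law[0] not in ("constant", "gaussian", "mixture"):
                raise ValueError(f"unknown law {law[0]!r}")


@dataclass
class PlantedTruth:
    distances: np.ndarray
    angles: np.ndarray
    hbond_labels: np.ndarray
    indices: dict = field(default_factory=dict)
    spec: PlantedTrajectorySpec | None = None


def _draw_law(law: tuple, n: int, rng: np.random.Generator) -> np.ndarray:
    kind = law[0]
    if kind == "constant":
        return np.full(n, float(law[1]))
    if kind == "gaussian":
        return rng.normal(law[1], law[2], size=n)
    comps = law[1]
    w = np.array([c[0] for c in comps], dtype=float)
    w = w / w.sum()
    which = rng.choice(len(comps), size=n, p=w)
    out = np.empty(n)
    for ci, (_, mu, sigma) in enumerate(comps):
        mask = which == ci
        out[mask] = rng.normal(mu, sigma, size=mask.sum())
    return out


def make_planted_trajectory(
    spec: PlantedTrajectorySpec,
) -> tuple[Trajectory, PlantedTruth]:
    """Build a minimal 7-atom trajectory whose measured series equal the
    planted draws exactly (coordinates constructed from the draws)."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_frames
    d = _draw_law(spec.distance_law, n, rng)
    # keep the attack hydrogen's nearest heavy atom its own carbon
    d = np.clip(d, 1.6, None)
    theta = np.clip(_draw_law(spec.angle_law, n, rng), 1.0, 179.0)
    if np.any(~np.isfinite(d)) or np.any(~np.isfinite(theta)):
        raise ValueError("infeasible planted geometry (non-finite draws)")

    m = int(round(spec.hbond_frame_fraction * n))
    labels = np.zeros(n, dtype=bool)
    labels[rng.permutation(n)[:m]] = True

    fe = np.array([0.0, 0.0, 0.0])
    oxo = np.array([0.0, 0.0, 1.62])
    hb_base = np.array([30.0, 0.0, 0.0])

    th = np.radians(theta)
    direction = np.stack(
        [np.sin(th), np.zeros(n), -np.cos(th)], axis=1
    )  # unit vectors from the oxo oxygen; angle to Fe-ward -z axis is theta
    h25 = oxo + d[:, None] * direction
    c25 = oxo + (d + 1.09)[:, None] * direction
    nd = np.tile(hb_base, (n, 1))
    hd = np.tile(hb_base + [1.0, 0.0, 0.0], (n, 1))
    oa = np.where(
        labels[:, None], hb_base + np.array([2.9, 0.0, 0.0]), hb_base + np.array([5.0, 0.0, 0.0])
    )

    frames = [
        np.vstack([fe, oxo, c25[k], h25[k], nd[k], hd[k], oa[k]]) for k in range(n)
    ]
    atoms = [
        Atom(1, "FE", "Fe", "HEM", 1, "A", frames[0][0], True),
        Atom(2, "O1", "O", "HEM", 1, "A", frames[0][1], True),
        Atom(3, "C25", "C", "VD3", 2, "A", frames[0][2], True),
        Atom(4, "H25", "H", "VD3", 2, "A", frames[0][3], True),
        Atom(5, "NZ", "N", "LYS", 3, "A", frames[0][4], False),
        Atom(6, "HZ", "H", "LYS", 3, "A", frames[0][5], False),
        Atom(7, "O", "O", "THR", 4, "A", frames[0][6], False),
    ]
    topo = Structure(atoms=atoms, cofactor_groups={"HEME": {0, 1}})
    truth = PlantedTruth(
        distances=d,
        angles=theta,
        hbond_labels=labels,
        indices={
            "fe": 0,
            "oxo": 1,
            "c25": 2,
            "h25": 3,
            "donor": 4,
            "hydrogen": 5,
            "acceptor": 6,
        },
        spec=spec,
    )
    return Trajectory(topology=topo, frames=frames), truth


def write_xyz(traj: Trajectory) -> str:
    """Serialize a trajectory as multi-frame XYZ text."""
    elements = [a.element for a in traj.topology.atoms]
    lines = []
    for k, frame in enumerate(traj.frames):
        lines.append(str(len(elements)))
        lines.append(f"frame {k}")
        for el, xyz in zip(elements, frame):
            lines.append(f"{el} {xyz[0]:.6f} {xyz[1]:.6f} {xyz[2]:.6f}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Two-domain structure fixture
# ---------------------------------------------------------------------------

def make_two_domain_structure(seed: int = 0) -> tuple[Structure, dict]:
    """Small two-domain fixture: an iron–sulfur cluster, a covalent backbone,
    a planted side-chain hydrogen bond bridging a through-space gap, and a
    heme iron — laid out so the optimal tunneling route is forced by
    construction.

    The seed jitters coordinates by < 0.01 Å (determinism check hook) without
    changing any classification.  Returns the structure and a truth record
    with the intended route, its step distances, and the conformer label.
    """
    rng = np.random.default_rng(seed)

    atoms_spec: list[tuple] = []  # (name, element, resname, resid, het, xyz)

    def put(name, element, resname, resid, het, x, y, z):
        atoms_spec.append((name, element, resname, resid, het, np.array([x, y, z], float)))

    # [2Fe-2S]-like cluster
    put("FE1", "Fe", "FES", 101, True, 0.0, 0.0, 0.0)
    put("FE2", "Fe", "FES", 101, True, -2.7, 0.0, 0.0)
    put("S1", "S", "FES", 101, True, 2.2, 0.0, 0.0)
    put("S2", "S", "FES", 101, True, 0.0, 2.2, 0.0)

    # chain 1: residues 1-4, N/CA/C backbone marching along +x at 1.5 Å
    x = 3.7
    for resid in range(1, 5):
        resname = "LYS" if resid == 4 else "GLY"
        for name in ("N", "CA", "C"):
            put(name, name[0], resname, resid, False, x, 0.0, 0.0)
            if name == "CA":
                put("HA", "H", resname, resid, False, x, 1.1, 0.0)
            if name == "C":
                put("O", "O", resname, resid, False, x + 0.1, -1.25, 0.0)
            x += 1.5
    chain1_end_x = x - 1.5  # C of residue 4 at 20.2

    # lysine-like donor branch with its hydrogen
    put("NZ", "N", "LYS", 4, False, chain1_end_x + 0.2, 1.5, 0.0)
    put("HZ", "H", "LYS", 4, False, chain1_end_x + 1.2, 1.5, 0.0)
    # acceptor: main-chain oxygen of residue 5, across the interdomain gap
    put("O", "O", "THR", 5, False, chain1_end_x + 3.2, 1.5, 0.0)

    # chain 2: residues 5-8
    x = chain1_end_x + 3.4
    for resid in range(5, 9):
        resname = "THR" if resid == 5 else "GLY"
        for name in ("N", "CA", "C"):
            put(name, name[0], resname, resid, False, x, 0.0, 0.0)
            if name == "CA":
                put("HA", "H", resname, resid, False, x, 1.1, 0.0)
            if name == "C" and resid != 5:
                put("O", "O", resname, resid, False, x + 0.1, -1.25, 0.0)
            x += 1.5
    chain2_end_x = x - 1.5

    # heme: one pyrrole-like nitrogen and the iron
    put("NA", "N", "HEM", 201, True, chain2_end_x + 1.5, 0.0, 0.0)
    put("FE", "Fe", "HEM", 201, True, chain2_end_x + 3.5, 0.0, 0.0)

    atoms = []
    for serial, (name, element, resname, resid, het, xyz) in enumerate(atoms_spec, 1):
        jitter = rng.uniform(-0.005, 0.005, size=3)
        atoms.append(
            Atom(serial, name, element, resname, resid, "A", xyz + jitter, het)
        )
    groups: dict[str, set[int]] = {}
    for i, a in enumerate(atoms):
        if a.residue_name == "FES":
            groups.setdefault("FES", set()).add(i)
        elif a.residue_name == "HEM":
            groups.setdefault("HEME", set()).add(i)
    structure = Structure(atoms=atoms, cofactor_groups=groups, title="synthetic two-domain fixture")

    def idx(resname, resid, name):
        for i, a in enumerate(atoms):
            if (a.residue_name, a.residue_id, a.name) == (resname, resid, name):
                return i
        raise KeyError((resname, resid, name))

    route = [idx("FES", 101, "FE1"), idx("FES", 101, "S1")]
    for resid in range(1, 5):
        resname = "LYS" if resid == 4 else "GLY"
        route += [idx(resname, resid, n) for n in ("N", "CA", "C")]
    route += [idx("LYS", 4, "NZ"), idx("THR", 5, "O")]
    for resid in range(5, 9):
        resname = "THR" if resid == 5 else "GLY"
        route += [idx(resname, resid, n) for n in ("N", "CA", "C")]
    route += [idx("HEM", 201, "NA"), idx("HEM", 201, "FE")]

    coords = structure.coords
    step_distances = [
        float(np.linalg.norm(coords[u] - coords[v]))
        for u, v in zip(route[:-1], route[1:])
    ]
    from .structures import min_distance
    from .pmf import classify_conformation

    d_fe_fe = min_distance(structure, groups["FES"], groups["HEME"], mode="fe-fe")
    # donor/acceptor anchored at the metal atoms (field convention)
    donor = sorted(
        i for i in groups["FES"] if structure.atoms[i].element.upper() == "FE"
    )
    acceptor = sorted(
        i for i in groups["HEME"] if structure.atoms[i].element.upper() == "FE"
    )
    truth = {
        "route": route,
        "step_distances": step_distances,
        "total_R": float(sum(step_distances)),
        "hbond_step_index": route.index(idx("LYS", 4, "NZ")),
        "d_fes_heme": d_fe_fe,
        "conformation": classify_conformation(d_fe_fe),
        "donor": donor,
        "acceptor": acceptor,
        "seed": seed,
    }
    return structure, truth
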