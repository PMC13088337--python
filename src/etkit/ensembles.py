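"""Per-frame trajectory observables: cofactor distances, attack angles,
near-attack-conformation statistics, hydrogen-bond occupancy, RMSD, and
pairwise nonbonded interaction-energy distributions.

Statistics over frames report the population standard deviation, matching
the mean ± sd convention of ensemble summaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .constants import COULOMB_KCAL
from .structures import Trajectory, angle_deg, infer_covalent_bonds

__all__ = [
    "GeometrySeries",
    "NACSummary",
    "HBondCriterion",
    "NonbondedParams",
    "EnergyDistribution",
    "distance_series",
    "attack_angle_series",
    "nac_summary",
    "hbond_occupancy",
    "rmsd_series",
    "interaction_energy_series",
    "read_nonbonded_table",
]


@dataclass
class GeometrySeries:
    name: str
    frame_values: np.ndarray

    def __post_init__(self):
        self.frame_values = np.asarray(self.frame_values, dtype=float)

    @property
    def mean(self) -> float:
        return float(self.frame_values.mean())

    @property
    def sd(self) -> float:
        return float(self.frame_values.std())  # population sd


@dataclass
class NACSummary:
    """Near-attack-conformation statistics of a distance/angle ensemble."""

    threshold: float
    fraction_within: float
    mean_distance: float
    sd_distance: float
    mean_angle: float
    sd_angle: float

    def __post_init__(self):
        if not (0 <= self.fraction_within <= 1):
            raise ValueError("fraction_within must lie in [0, 1]")


@dataclass(frozen=True)
class HBondCriterion:
    donor_acceptor_max: float = 3.5  # Å
    dha_angle_min: float = 135.0  # degrees

    def __post_init__(self):
        if self.donor_acceptor_max <= 0:
            raise ValueError("distance criterion must be positive")
        if not (0 < self.dha_angle_min <= 180):
            raise ValueError("angle criterion must lie in (0, 180]")


@dataclass
class NonbondedParams:
    """Per-atom charges and Lennard-Jones parameters, aligned with topology.

    Missing entries are NaN and rejected for atoms participating in an
    energy evaluation.
    """

    charges: np.ndarray  # e
    sigma: np.ndarray  # Å
    epsilon: np.ndarray  # kcal/mol
    combining_rule: str = "lorentz_berthelot"
    coulomb_constant: float = COULOMB_KCAL
    dielectric: float = 1.0
    cutoff: float = 99.0  # Å

    def __post_init__(self):
        self.charges = np.asarray(self.charges, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        self.epsilon = np.asarray(self.epsilon, dtype=float)
        if self.combining_rule not in ("lorentz_berthelot", "geometric"):
            raise ValueError(f"unknown combining rule {self.combining_rule!r}")
        ok = np.isnan(self.sigma) | (self.sigma > 0)
        if not ok.all():
            raise ValueError("sigma must be positive")
        ok = np.isnan(self.epsilon) | (self.epsilon >= 0)
        if not ok.all():
            raise ValueError("epsilon must be non-negative")


def read_nonbonded_table(csv_text_or_path, topology) -> NonbondedParams:
    """Load a `serial,charge_e,sigma_A,epsilon_kcal` table aligned by serial."""
    import io

    src = csv_text_or_path
    if isinstance(src, str) and "\n" in src:
        src = io.StringIO(src)
    df = pd.read_csv(src)
    by_serial = df.set_index("serial")
    n = topology.n_atoms
    q = np.full(n, np.nan)
    s = np.full(n, np.nan)
    e = np.full(n, np.nan)
    for i, atom in enumerate(topology.atoms):
        if atom.serial in by_serial.index:
            row = by_serial.loc[atom.serial]
            q[i], s[i], e[i] = row["charge_e"], row["sigma_A"], row["epsilon_kcal"]
    return NonbondedParams(charges=q, sigma=s, epsilon=e)


@dataclass
class EnergyDistribution:
    electrostatic: np.ndarray  # per frame, kcal/mol
    vdw: np.ndarray

    def __post_init__(self):
        self.electrostatic = np.asarray(self.electrostatic, dtype=float)
        self.vdw = np.asarray(self.vdw, dtype=float)
        if not (np.isfinite(self.electrostatic).all() and np.isfinite(self.vdw).all()):
            raise ValueError("non-finite interaction energies")

    @property
    def mean_elec(self) -> float:
        return float(self.electrostatic.mean())

    @property
    def sd_elec(self) -> float:
        return float(self.electrostatic.std())

    @property
    def mean_vdw(self) -> float:
        return float(self.vdw.mean())

    @property
    def sd_vdw(self) -> float:
        return float(self.vdw.std())


def distance_series(
    traj: Trajectory,
    selA,
    selB,
    mode: str = "min",
    name: str = "distance",
) -> GeometrySeries:
    """Per-frame distance between two selections under a chosen convention."""
    from .structures import min_distance

    A, B = set(selA), set(selB)
    if not A or not B:
        raise ValueError("selections must be non-empty")
    vals = [
        min_distance(frame, A, B, mode=mode, structure=traj.topology)
        for frame in traj.frames
    ]
    return GeometrySeries(name=name, frame_values=np.array(vals))


def attack_angle_series(
    traj: Trajectory, fe_atom: int, oxo_atom: int, target_atom: int
) -> GeometrySeries:
    """Per-frame attack angle ∠(Fe, O, target) with vertex at the oxo oxygen."""
    if len({fe_atom, oxo_atom, target_atom}) != 3:
        raise ValueError("fe, oxo, and target atoms must be distinct")
    vals = []
    for k, frame in enumerate(traj.frames):
        try:
            vals.append(angle_deg(frame[fe_atom], frame[oxo_atom], frame[target_atom]))
        except ValueError:
            raise ValueError(f"frame {k}: coincident atoms, angle undefined") from None
    return GeometrySeries(name="attack_angle", frame_values=np.array(vals))


def nac_summary(
    dist: GeometrySeries, angle: GeometrySeries, threshold: float = 4.0
) -> NACSummary:
    """Fraction of frames with the attack distance within ``threshold`` Å,
    plus mean ± sd of distance and angle over all frames."""
    d = dist.frame_values
    a = angle.frame_values
    if d.size != a.size:
        raise ValueError("distance and angle series lengths differ")
    return NACSummary(
        threshold=threshold,
        fraction_within=float(np.mean(d <= threshold)),
        mean_distance=dist.mean,
        sd_distance=dist.sd,
        mean_angle=angle.mean,
        sd_angle=angle.sd,
    )


def hbond_occupancy(
    traj: Trajectory,
    donor: int,
    hydrogen: int,
    acceptor: int,
    criterion: HBondCriterion = HBondCriterion(),
) -> float:
    """Percentage of frames in which the D–H⋯A triplet satisfies the
    distance/angle criterion."""
    if len({donor, hydrogen, acceptor}) != 3:
        raise ValueError("donor, hydrogen, and acceptor must be distinct atoms")
    bonds = infer_covalent_bonds(traj.topology)
    if not bonds.bonded(donor, hydrogen):
        raise ValueError("hydrogen is not covalently bonded to the donor in topology")
    hits = 0
    for frame in traj.frames:
        dda = float(np.linalg.norm(frame[donor] - frame[acceptor]))
        if dda > criterion.donor_acceptor_max:
            continue
        if angle_deg(frame[donor], frame[hydrogen], frame[acceptor]) >= criterion.dha_angle_min:
            hits += 1
    return 100.0 * hits / traj.n_frames


def rmsd_series(
    traj: Trajectory, reference_frame: int = 0, selection=None
) -> GeometrySeries:
    """Least-squares-superposed RMSD of each frame to a reference frame.

    Optimal translation plus proper rotation (Kabsch) over the selection.
    """
    sel = (
        sorted(set(selection))
        if selection is not None
        else list(range(traj.topology.n_atoms))
    )
    if len(sel) < 3:
        raise ValueError("selection must contain at least 3 atoms")
    ref = traj.frames[reference_frame][sel]
    ref_c = ref - ref.mean(axis=0)
    if np.linalg.matrix_rank(ref_c, tol=1e-8) < 2:
        raise ValueError("reference selection is collinear; superposition degenerate")
    vals = []
    for frame in traj.frames:
        mob = frame[sel]
        mob_c = mob - mob.mean(axis=0)
        rot, _ = Rotation.align_vectors(ref_c, mob_c)
        diff = ref_c - rot.apply(mob_c)
        vals.append(float(np.sqrt((diff**2).sum() / len(sel))))
    return GeometrySeries(name="rmsd", frame_values=np.array(vals))


def interaction_energy_series(
    traj: Trajectory,
    groupA,
    groupB,
    params: NonbondedParams,
) -> EnergyDistribution:
    """Cross-group Coulomb and Lennard-Jones energies per frame.

    elec = sum_ij C q_i q_j / (eps_d r_ij), vdW = sum_ij 4 ε̄ [(σ̄/r)^12 −
    (σ̄/r)^6], over pairs within the cutoff (hard truncation, no switching).
    """
    A = np.array(sorted(set(groupA)), dtype=int)
    B = np.array(sorted(set(groupB)), dtype=int)
    if A.size == 0 or B.size == 0:
        raise ValueError("groups must be non-empty")
    if set(A) & set(B):
        raise ValueError("groups must be disjoint")
    needed = np.concatenate([A, B])
    missing = [
        traj.topology.atoms[i].serial
        for i in needed
        if np.isnan(params.charges[i])
        or np.isnan(params.sigma[i])
        or np.isnan(params.epsilon[i])
    ]
    if missing:
        raise ValueError(f"missing nonbonded parameters for atom serials {missing}")

    qA, qB = params.charges[A], params.charges[B]
    sA, sB = params.sigma[A], params.sigma[B]
    eA, eB = params.epsilon[A], params.epsilon[B]
    if params.combining_rule == "lorentz_berthelot":
        sig = 0.5 * (sA[:, None] + sB[None, :])
    else:
        sig = np.sqrt(sA[:, None] * sB[None, :])
    eps = np.sqrt(eA[:, None] * eB[None, :])
    qq = qA[:, None] * qB[None, :]

    elec_frames, vdw_frames = [], []
    for frame in traj.frames:
        r = np.linalg.norm(frame[A][:, None, :] - frame[B][None, :, :], axis=-1)
        within = r <= params.cutoff
        with np.errstate(divide="ignore", invalid="ignore"):
            elec = params.coulomb_constant * qq / (params.dielectric * r)
            sr6 = (sig / r) ** 6
            vdw = 4.0 * eps * (sr6**2 - sr6)
        elec_frames.append(float(elec[within].sum()))
        vdw_frames.append(float(vdw[within].sum()))
    return EnergyDistribution(
        electrostatic=np.array(elec_frames), vdw=np.array(vdw_frames)
    )
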