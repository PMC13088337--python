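"""Ensemble geometry statistics on planted trajectories.

Emulates the reference and pocket-engineered active-site ensembles with
planted attack-distance/angle laws (4.63 ± 1.01 Å, 157.3 ± 9.2° vs
4.19 ± 0.75 Å, 142.0 ± 7.7°), measures near-attack-conformation fractions
at the 4 Å cutoff, the planted interface hydrogen-bond occupancy
(37.28 % of 10000 frames), and the interdomain nonbonded interaction
energies of the two-domain fixture.
"""

import argparse
import json
import pathlib
import sys

import numpy as np

sys.path.insert(0, str(pathlib.Path(__file__).resolve().parents[1] / "src"))

from etkit.ensembles import (
    NonbondedParams,
    attack_angle_series,
    distance_series,
    hbond_occupancy,
    interaction_energy_series,
    nac_summary,
)
from etkit.structures import Trajectory, select
from etkit.synthetic import (
    PlantedTrajectorySpec,
    make_planted_trajectory,
    make_two_domain_structure,
)

ENSEMBLES = {
    "reference": PlantedTrajectorySpec(
        n_frames=2000, distance_law=("gaussian", 4.63, 1.01),
        angle_law=("gaussian", 157.3, 9.2),
    ),
    "engineered": PlantedTrajectorySpec(
        n_frames=2000, distance_law=("gaussian", 4.19, 0.75),
        angle_law=("gaussian", 142.0, 7.7),
    ),
}


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--outdir", type=pathlib.Path, default=pathlib.Path("results"))
    args = parser.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    summary = {}
    for offset, (label, base) in enumerate(ENSEMBLES.items()):
        spec = PlantedTrajectorySpec(
            n_frames=base.n_frames,
            distance_law=base.distance_law,
            angle_law=base.angle_law,
            seed=args.seed + 101 * (offset + 1),
        )
        traj, truth = make_planted_trajectory(spec)
        i = truth.indices
        d = distance_series(traj, {i["oxo"]}, {i["h25"]}, name="d_FeO_H")
        a = attack_angle_series(traj, i["fe"], i["oxo"], i["c25"])
        nac = nac_summary(d, a, threshold=4.0)
        summary[label] = {
            "nac_fraction_pct": 100.0 * nac.fraction_within,
            "d_FeO_H_A": f"{nac.mean_distance:.2f} ± {nac.sd_distance:.2f}",
            "theta_deg": f"{nac.mean_angle:.1f} ± {nac.sd_angle:.1f}",
        }
        print(
            f"{label}: d[Fe=O-H] = {nac.mean_distance:.2f} ± {nac.sd_distance:.2f} Å, "
            f"θ = {nac.mean_angle:.1f} ± {nac.sd_angle:.1f}°, "
            f"NAC fraction (≤4 Å) = {100 * nac.fraction_within:.1f} %"
        )

    hb_traj, hb_truth = make_planted_trajectory(
        PlantedTrajectorySpec(n_frames=10_000, hbond_frame_fraction=0.3728, seed=args.seed + 7)
    )
    i = hb_truth.indices
    occ = hbond_occupancy(hb_traj, i["donor"], i["hydrogen"], i["acceptor"])
    summary["interface_hbond_occupancy_pct"] = occ
    print(f"planted interface H-bond occupancy: {occ:.2f} % of 10000 frames")

    # interdomain nonbonded energies on the static two-domain fixture with
    # nominal parameters (unit-scale charges, generic LJ)
    structure, truth = make_two_domain_structure(seed=args.seed)
    rng = np.random.default_rng(args.seed + 3)
    n = structure.n_atoms
    params = NonbondedParams(
        charges=rng.uniform(-0.5, 0.5, n),
        sigma=rng.uniform(2.8, 3.8, n),
        epsilon=rng.uniform(0.05, 0.2, n),
        cutoff=99.0,
    )
    traj = Trajectory(topology=structure, frames=[structure.coords])
    ferredoxin = select(structure, "group FES or resid 1-4")
    rest = set(range(n)) - ferredoxin
    energies = interaction_energy_series(traj, ferredoxin, rest, params)
    summary["interdomain_energy_kcal_mol"] = {
        "electrostatic": f"{energies.mean_elec:.1f} ± {energies.sd_elec:.1f}",
        "vdw": f"{energies.mean_vdw:.1f} ± {energies.sd_vdw:.1f}",
    }
    print(
        f"fixture interdomain energies: elec {energies.mean_elec:.1f} kcal/mol, "
        f"vdW {energies.mean_vdw:.1f} kcal/mol"
    )

    (args.outdir / "ensemble_summary.json").write_text(json.dumps(summary, indent=2))


if __name__ == "__main__":
    main()
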