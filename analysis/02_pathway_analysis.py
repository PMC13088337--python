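"""Tunneling-pathway search on the two-domain fixture and ET-rate evaluation.

Finds the maximum-coupling donor→acceptor route through the fixture (it
traverses the planted side-chain hydrogen bond), reports its step table,
and evaluates the distance-decay rate law at the route length and at the
two reference pathway lengths (32.36 and 28.31 Å), whose rate ratio
quantifies the gain from a 4.05 Å pathway shortening.
"""

import argparse
import json
import pathlib
import sys

import pandas as pd

sys.path.insert(0, str(pathlib.Path(__file__).resolve().parents[1] / "src"))

from etkit.pathways import best_pathway, build_tunneling_graph, compute_ket
from etkit.structures import infer_covalent_bonds
from etkit.synthetic import make_two_domain_structure


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--outdir", type=pathlib.Path, default=pathlib.Path("results"))
    args = parser.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    structure, truth = make_two_domain_structure(seed=args.seed)
    bonds = infer_covalent_bonds(structure)
    graph = build_tunneling_graph(structure, bonds)
    path = best_pathway(graph, set(truth["donor"]), set(truth["acceptor"]))
    assert path is not None

    steps = pd.DataFrame(
        {
            "from_atom": path.node_sequence[:-1],
            "to_atom": path.node_sequence[1:],
            "step_type": path.step_types,
            "distance_A": path.step_distances,
            "decay": path.step_decays,
        }
    )
    steps.to_csv(args.outdir / "pathway_steps.csv", index=False)
    report = {
        "n_steps": len(path.step_types),
        "total_R_A": path.total_R,
        "total_coupling": path.total_coupling,
        "residue_trace": path.residue_trace,
        "matches_planted_route": path.node_sequence == truth["route"],
        "k_ET_per_s_at_route_R": compute_ket(path.total_R),
    }
    (args.outdir / "pathway_report.json").write_text(json.dumps(report, indent=2))

    print(
        f"best route: {len(path.step_types)} steps, R = {path.total_R:.2f} Å, "
        f"coupling = {path.total_coupling:.3e} "
        f"(planted route recovered: {report['matches_planted_route']})"
    )
    print("residue trace:", " -> ".join(path.residue_trace))

    k_long = compute_ket(32.36)
    k_short = compute_ket(28.31)
    rates = pd.DataFrame(
        {
            "pathway": ["reference_long", "reference_short", "fixture_route"],
            "R_A": [32.36, 28.31, path.total_R],
            "k_ET_per_s": [k_long, k_short, report["k_ET_per_s_at_route_R"]],
        }
    )
    rates.to_csv(args.outdir / "et_rates.csv", index=False)
    print(
        f"k_ET(32.36 Å) = {k_long:.3g} /s, k_ET(28.31 Å) = {k_short:.3g} /s; "
        f"a 4.05 Å shortening accelerates ET {k_short / k_long:.1f}-fold"
    )


if __name__ == "__main__":
    main()
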