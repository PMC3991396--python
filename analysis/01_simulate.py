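"""Generate the bundled synthetic study: 6 stimulation conditions x 10
replicates, 6 planted coexpression modules, one exclusive marker per
stimulus, 200 genes total — plus the hub-structured dependency fixture used
for reverse network engineering.

Writes expression/design TSVs and the ground truth JSON under results/data.
"""

from pathlib import Path

from macspectrum.io import write_expression_tsv, write_json
from macspectrum.synthetic import demo_dataset, simulate_hub_network_data

OUT = Path(__file__).resolve().parents[1] / "results" / "data"


def main(seed: int = 11) -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    matrix, structure = demo_dataset(seed=seed)
    write_expression_tsv(matrix, OUT / "expression.tsv", OUT / "design.tsv")
    write_json(
        {
            "modules": {f"M{i + 1}": m.genes for i, m in enumerate(structure.modules)},
            "markers": [list(t) for t in structure.exclusive_markers],
            "noise_sd": structure.noise_sd,
        },
        OUT / "simulated_truth.json",
    )
    print(f"expression: {matrix.n_genes} genes x {matrix.n_samples} samples, "
          f"{len(matrix.conditions)} conditions (baseline {matrix.baseline})")

    hub_matrix, truth = simulate_hub_network_data(50, 1000, hub_fraction=0.1, seed=seed)
    write_expression_tsv(hub_matrix, OUT / "hub_expression.tsv", OUT / "hub_design.tsv")
    write_json(
        {"edges": sorted(truth.edges), "hubs": truth.hubs, "degrees": truth.degrees},
        OUT / "hub_truth.json",
    )
    print(f"hub fixture: {hub_matrix.n_genes} genes x {hub_matrix.n_samples} samples, "
          f"{len(truth.edges)} true edges, hubs {truth.hubs}")


if __name__ == "__main__":
    main()
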