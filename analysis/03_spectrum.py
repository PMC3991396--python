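"""Coregulation analysis and the activation spectrum: sample correlation
graph, Markov clusters, 3-D layout, condition correlation matrix, and the
cluster mean vectors anchored at the baseline centroid.

Also runs the dedicated bipolar-axis experiment: two antagonistic programs
(one gene set induced by one condition, repressed by another) plus an
orthogonal third program, to measure the angles the spectrum claims.
"""

from pathlib import Path

import pandas as pd

from macspectrum.condition_space import condition_ccm, spectrum_angles, spectrum_vectors
from macspectrum.io import read_expression_tsv, write_edge_list, write_json
from macspectrum.preprocess import quantile_normalize
from macspectrum.sample_network import correlation_graph, layout_3d, mcl_cluster
from macspectrum.synthetic import spectrum_fixture

ROOT = Path(__file__).resolve().parents[1] / "results"


def main(seed: int = 11) -> None:
    out = ROOT / "spectrum"
    out.mkdir(parents=True, exist_ok=True)
    norm = quantile_normalize(
        read_expression_tsv(ROOT / "data" / "expression.tsv", ROOT / "data" / "design.tsv")
    )
    graph = correlation_graph(norm, r_threshold=0.85)
    clusters = mcl_cluster(graph)
    layout = layout_3d(graph, seed=seed)
    write_edge_list(graph, out / "sample_graph_edges.tsv")
    pd.Series(clusters, name="mcl_cluster").rename_axis("sample").to_csv(out / "mcl_clusters.tsv", sep="\t")
    ccm = condition_ccm(norm, top_n=min(1000, norm.n_genes), k=len(norm.conditions))
    vecs = spectrum_vectors(layout, norm.design, ccm)
    write_json(
        [{"cluster": v.cluster_id, "baseline": v.is_baseline, "vector": list(map(float, v.vector)),
          "magnitude": v.magnitude} for v in vecs],
        out / "spectrum_vectors.json",
    )
    print(f"sample graph: {graph.number_of_nodes()} nodes, {graph.number_of_edges()} edges, "
          f"{len(set(clusters.values()))} MCL clusters; {len(vecs)} spectrum vectors")

    # bipolar axis + orthogonal program
    m, design = spectrum_fixture(seed=seed)
    g = correlation_graph(m, r_threshold=0.6)
    lay = layout_3d(g, iterations=300, seed=seed)
    ccm2 = condition_ccm(m, top_n=200, k=4)
    vecs2 = spectrum_vectors(lay, design, ccm2)
    ang = spectrum_angles(vecs2)
    ang.to_csv(out / "axis_angles.tsv", sep="\t", index=False, float_format="%.4g")
    conds = list(dict.fromkeys(design["condition"]))
    cl = ccm2.cluster_of
    lookup = {(min(a.cluster_a, a.cluster_b), max(a.cluster_a, a.cluster_b)): a.angle_deg
              for a in ang.itertuples()}
    def angle(c1, c2):
        k1, k2 = cl[c1], cl[c2]
        return lookup[(min(k1, k2), max(k1, k2))]
    print(f"antagonistic programs ({conds[1]} vs {conds[2]}): {angle(conds[1], conds[2]):.1f} deg; "
          f"orthogonal program vs each: {angle(conds[3], conds[1]):.1f}, {angle(conds[3], conds[2]):.1f} deg")


if __name__ == "__main__":
    main()
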