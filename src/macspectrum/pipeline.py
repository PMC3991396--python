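"""End-to-end orchestration: configuration, stage execution, provenance.

Stages run in dependency order
``preprocess -> sample_network / condition_space / som -> modules -> gsea ->
minet``; each writes plain-text artifacts (TSV/JSON/GMT/GraphML) plus PNG
side-effect plots into the output directory, and a run manifest records the
config snapshot, package version, per-artifact SHA-256 checksums (text
artifacts only), and accumulated warnings. Every stage parameter the
upstream literature leaves open has an explicit default here, and the
manifest snapshot is the provenance record of what was actually used.
"""

from __future__ import annotations

import hashlib
import warnings as _warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.cluster import hierarchy

from . import __version__
from . import plots
from .condition_space import condition_ccm, spectrum_angles, spectrum_vectors
from .coexpression import (
    adjacency_matrix,
    detect_modules,
    module_assignments,
    module_trait_correlation,
    pick_soft_threshold,
    topological_overlap,
)
from .containers import ExpressionMatrix
from .enrichment import gsea_permutation, volcano_table
from .io import (
    read_expression_tsv,
    read_gmt,
    write_edge_list,
    write_expression_tsv,
    write_gmt,
    write_graphml,
    write_json,
)
from .mi_network import (
    all_vs_all,
    degree_table,
    dpi_prune,
    extract_hubs,
    mi_significance_threshold,
    tf_neighborhoods,
)
from .preprocess import anova_screen, detection_filter, quantile_normalize, top_variable_genes
from .sample_network import correlation_graph, layout_3d, mcl_cluster
from .som import exclusive_markers, som_fit, som_metaclusters
from .synthetic import demo_dataset

ALL_STAGES = ("preprocess", "sample_network", "condition_space", "som", "modules", "gsea", "minet")

TEXT_SUFFIXES = {".tsv", ".json", ".gmt", ".graphml", ".txt", ".nwk", ".yaml"}


@dataclass
class PipelineConfig:
    """All stage parameters with their defaults; the run manifest snapshots it."""

    expression_tsv: str | None = None
    design_tsv: str | None = None
    tf_list: list[str] = field(default_factory=list)
    gene_sets_gmt: str | None = None
    stages: list[str] = field(default_factory=lambda: list(ALL_STAGES))
    seed: int = 0
    outdir: str = "macspectrum_out"
    # preprocess
    background_quantile: float = 0.25
    detection_margin: float = 0.5
    anova_q_max: float = 0.05
    # sample network
    r_threshold: float = 0.85
    mcl_inflation: float = 2.0
    layout_iterations: int = 500
    # condition space
    ccm_top_n: int = 1000
    ccm_k: int = 10
    # som
    som_grid: tuple[int, int] = (10, 10)
    som_epochs: int = 50
    som_metaclusters: int = 8
    marker_margin: float = 1.0
    # coexpression; power 0 means select by scale-free fit
    wgcna_power: float = 6.0
    wgcna_target_r2: float = 0.8
    wgcna_min_module: int = 20
    wgcna_cut_height: float = 0.95
    wgcna_merge_r: float = 0.8
    # gsea
    gsea_n_perm: int = 1000
    gsea_mode: str = "phenotype"
    gsea_metric: str = "signal2noise"
    gsea_weight: float = 1.0
    nes_min: float = 1.0
    gsea_p_max: float = 0.05
    # mi network; the corrected level the full-scale analysis uses is 1e-7,
    # which needs hundreds of arrays to be reachable — desk-scale runs with
    # tens of samples use a Bonferroni-corrected 0.05 instead
    mi_alpha: float = 0.05
    mi_n_null: int = 20000
    mi_max_genes: int = 2000
    dpi_tolerance: float = 0.1
    hub_fraction: float = 0.1
    tf_top_k: int = 5

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        cfg = cls(**raw)
        if isinstance(cfg.som_grid, list):
            cfg.som_grid = tuple(cfg.som_grid)
        return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _linkage_newick(link: np.ndarray, labels: list[str]) -> str:
    tree = hierarchy.to_tree(link)

    def rec(node) -> str:
        if node.is_leaf():
            return labels[node.id]
        return f"({rec(node.left)},{rec(node.right)}):{node.dist:.6g}"

    return rec(tree) + ";"


def run_pipeline(config: PipelineConfig, matrix: ExpressionMatrix | None = None) -> dict:
    """Execute the enabled stages and return the run manifest (also written
    to ``<outdir>/manifest.json``).

    ``matrix`` may be passed directly; otherwise it is read from the config's
    expression/design TSV paths, and if those are unset the bundled demo
    dataset (200 genes x 60 samples, 6 conditions) is generated from the
    config seed.
    """
    unknown = [s for s in config.stages if s not in ALL_STAGES]
    if unknown:
        raise ValueError(f"unknown stage(s): {unknown}; choose from {ALL_STAGES}")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    captured: list[str] = []
    manifest: dict = {"version": __version__, "config": asdict(config), "stages": {}, "warnings": captured}

    with _warnings.catch_warnings(record=True) as wlist:
        _warnings.simplefilter("always")
        try:
            _run_stages(config, matrix, outdir, manifest)
        finally:
            captured.extend(f"{w.category.__name__}: {w.message}" for w in wlist)

    checksums = {}
    for path in sorted(outdir.rglob("*")):
        if path.is_file() and path.suffix in TEXT_SUFFIXES and path.name != "manifest.json":
            checksums[str(path.relative_to(outdir))] = _sha256(path)
    manifest["checksums"] = checksums
    manifest["plots"] = sorted(str(p.relative_to(outdir)) for p in outdir.rglob("*.png"))
    write_json(manifest, outdir / "manifest.json")
    return manifest


def _run_stages(config: PipelineConfig, matrix, outdir: Path, manifest: dict) -> None:
    if matrix is None:
        if config.expression_tsv and config.design_tsv:
            matrix = read_expression_tsv(config.expression_tsv, config.design_tsv)
        else:
            matrix, structure = demo_dataset(seed=config.seed)
            truth = {
                "modules": {f"M{i + 1}": m.genes for i, m in enumerate(structure.modules)},
                "markers": [list(t) for t in structure.exclusive_markers],
            }
            write_expression_tsv(matrix, outdir / "expression.tsv", outdir / "design.tsv")
            write_json(truth, outdir / "simulated_truth.json")
            manifest["stages"]["simulate"] = {"n_genes": matrix.n_genes, "n_samples": matrix.n_samples}

    stage = dict.fromkeys(config.stages)
    expressed = matrix.genes
    norm = matrix

    def fail(name: str, exc: Exception) -> None:
        raise RuntimeError(f"stage {name!r} failed: {exc}") from exc

    if "preprocess" in stage:
        try:
            norm = quantile_normalize(matrix)
            det = detection_filter(norm, config.background_quantile, config.detection_margin)
            expressed = det.expressed_genes
            screen = anova_screen(norm, q_max=config.anova_q_max)
            write_expression_tsv(norm, outdir / "normalized.tsv", outdir / "design.tsv")
            pd.Series(expressed, name="gene").to_csv(outdir / "expressed_genes.tsv", sep="\t", index=False)
            screen.to_csv(outdir / "anova_screen.tsv", sep="\t", index_label="gene", float_format="%.6g")
            manifest["stages"]["preprocess"] = {
                "background": det.background,
                "n_expressed": len(expressed),
                "n_anova_pass": int(screen["pass"].sum()),
            }
        except Exception as exc:
            fail("preprocess", exc)

    graph = layout = None
    if "sample_network" in stage:
        try:
            graph = correlation_graph(norm, genes=expressed, r_threshold=config.r_threshold)
            clusters = mcl_cluster(graph, inflation=config.mcl_inflation)
            layout = layout_3d(graph, iterations=config.layout_iterations, seed=config.seed)
            write_edge_list(graph, outdir / "sample_graph_edges.tsv")
            write_graphml(graph, outdir / "sample_graph.graphml")
            pd.DataFrame(
                [(s, *map(float, xyz)) for s, xyz in sorted(layout.items())],
                columns=["sample", "x", "y", "z"],
            ).to_csv(outdir / "sample_layout.tsv", sep="\t", index=False, float_format="%.10g")
            pd.Series(clusters, name="mcl_cluster").rename_axis("sample").to_csv(
                outdir / "sample_clusters.tsv", sep="\t"
            )
            manifest["stages"]["sample_network"] = {
                "n_nodes": graph.number_of_nodes(),
                "n_edges": graph.number_of_edges(),
                "n_mcl_clusters": len(set(clusters.values())),
            }
        except Exception as exc:
            fail("sample_network", exc)

    ccm = None
    if "condition_space" in stage:
        try:
            k = min(config.ccm_k, len(norm.conditions))
            ccm = condition_ccm(norm, top_n=min(config.ccm_top_n, norm.n_genes), k=k)
            ccm.r_matrix.to_csv(outdir / "ccm.tsv", sep="\t", float_format="%.10g")
            (outdir / "ccm_dendrogram.nwk").write_text(_linkage_newick(ccm.linkage, ccm.conditions) + "\n")
            pd.Series(ccm.cluster_of, name="ccm_cluster").rename_axis("condition").to_csv(
                outdir / "ccm_clusters.tsv", sep="\t"
            )
            plots.plot_ccm(ccm, outdir / "ccm.png")
            info = {"k": k}
            if layout is not None:
                vectors = spectrum_vectors(layout, norm.design, ccm)
                write_json(
                    [
                        {
                            "cluster": v.cluster_id,
                            "is_baseline": v.is_baseline,
                            "vector": [float(x) for x in v.vector],
                            "magnitude": v.magnitude,
                            "n_samples": len(v.members),
                        }
                        for v in vectors
                    ],
                    outdir / "spectrum_vectors.json",
                )
                nonzero = [v for v in vectors if v.magnitude > 1e-12]
                if len(nonzero) >= 2:
                    spectrum_angles(vectors).to_csv(
                        outdir / "spectrum_angles.tsv", sep="\t", index=False, float_format="%.6g"
                    )
                plots.plot_spectrum(vectors, outdir / "spectrum.png")
                info["n_vectors"] = len(vectors)
            manifest["stages"]["condition_space"] = info
        except Exception as exc:
            fail("condition_space", exc)

    if "som" in stage:
        try:
            profiles = norm.subset_genes(expressed).condition_means()
            w, h = config.som_grid
            som = som_fit(profiles, grid_w=w, grid_h=h, epochs=config.som_epochs, seed=config.seed)
            som = som_metaclusters(som, k=min(config.som_metaclusters, som.n_units))
            tables = []
            for cond in norm.conditions:
                t = exclusive_markers(norm.subset_genes(expressed), cond, margin_min=config.marker_margin)
                tables.append(t)
            markers = pd.concat(tables)
            markers.to_csv(outdir / "exclusive_markers.tsv", sep="\t", index_label="gene", float_format="%.6g")
            som.bmu_of.rename_axis("gene").to_csv(outdir / "som_bmu.tsv", sep="\t")
            plots.plot_som_portraits(som, outdir / "som_portraits.png")
            manifest["stages"]["som"] = {"grid": [w, h], "n_markers": int(len(markers))}
        except Exception as exc:
            fail("som", exc)

    modules = []
    if "modules" in stage:
        try:
            sub = norm.subset_genes(expressed)
            if config.wgcna_power:
                power = float(config.wgcna_power)
                diag = pd.DataFrame({"power": [power], "fit_r2": [np.nan], "mean_k": [np.nan]})
            else:
                power, diag = pick_soft_threshold(sub, target_r2=config.wgcna_target_r2)
            adj = adjacency_matrix(sub, power=power)
            tom = topological_overlap(adj)
            modules = detect_modules(
                sub,
                tom,
                min_size=config.wgcna_min_module,
                cut_height=config.wgcna_cut_height,
                merge_r=config.wgcna_merge_r,
            )
            write_gmt({f"module_{m.module_id}": m.genes for m in modules}, outdir / "modules.gmt")
            diag.to_csv(outdir / "soft_threshold.tsv", sep="\t", index=False, float_format="%.6g")
            module_assignments(modules, sub.genes).rename_axis("gene").to_csv(
                outdir / "module_assignments.tsv", sep="\t"
            )
            if modules:
                me = pd.DataFrame({f"module_{m.module_id}": m.eigengene for m in modules})
                me.rename_axis("sample").to_csv(outdir / "module_eigengenes.tsv", sep="\t", float_format="%.10g")
                r, p, q = module_trait_correlation(modules, norm.design)
                r.rename_axis("module").to_csv(outdir / "module_trait_r.tsv", sep="\t", float_format="%.6g")
                q.rename_axis("module").to_csv(outdir / "module_trait_q.tsv", sep="\t", float_format="%.6g")
                plots.plot_module_trait_heatmap(r, outdir / "module_trait.png")
            manifest["stages"]["modules"] = {"power": power, "n_modules": len(modules)}
        except Exception as exc:
            fail("modules", exc)

    if "gsea" in stage:
        try:
            if config.gene_sets_gmt:
                gene_sets = read_gmt(config.gene_sets_gmt)
            elif modules:
                gene_sets = {f"module_{m.module_id}": m.genes for m in modules}
            else:
                raise ValueError("gsea stage needs gene_sets_gmt or a preceding modules stage")
            base = norm.baseline
            frames = []
            for cond in norm.conditions:
                if cond == base:
                    continue
                res = gsea_permutation(
                    norm,
                    cond,
                    base,
                    gene_sets,
                    n_perm=config.gsea_n_perm,
                    mode=config.gsea_mode,
                    seed=config.seed,
                    metric=config.gsea_metric,
                    weight=config.gsea_weight,
                )
                res = volcano_table(res, nes_min=config.nes_min, p_max=config.gsea_p_max)
                res.insert(0, "contrast", f"{cond}_vs_{base}")
                frames.append(res)
                plots.plot_volcano(res, outdir / f"volcano_{cond.replace('/', '_')}.png",
                                   nes_min=config.nes_min, p_max=config.gsea_p_max)
            gsea_all = pd.concat(frames, ignore_index=True)
            gsea_all.to_csv(outdir / "gsea_results.tsv", sep="\t", index=False, float_format="%.6g")
            manifest["stages"]["gsea"] = {
                "n_contrasts": len(frames),
                "n_enriched": int(gsea_all["enriched"].sum()),
                "n_depleted": int(gsea_all["depleted"].sum()),
            }
        except Exception as exc:
            fail("gsea", exc)

    if "minet" in stage:
        try:
            genes = expressed
            if len(genes) > config.mi_max_genes:
                genes = top_variable_genes(norm.subset_genes(genes), config.mi_max_genes)
            sub = norm.subset_genes(genes)
            cutoff, null_info = mi_significance_threshold(
                sub, alpha=config.mi_alpha, n_null=config.mi_n_null, seed=config.seed
            )
            net = all_vs_all(sub, cutoff=cutoff)
            net = dpi_prune(net, tolerance=config.dpi_tolerance)
            hubs, hub_stats = extract_hubs(net, fraction=config.hub_fraction)
            write_edge_list(net, outdir / "mi_edges.tsv", weight="mi")
            write_graphml(net, outdir / "mi_network.graphml")
            deg = degree_table(net)
            deg["is_hub"] = deg["gene"].isin(hubs)
            deg.to_csv(outdir / "mi_hubs.tsv", sep="\t", index=False)
            write_json({"cutoff": cutoff, "null_fit": null_info, **hub_stats}, outdir / "mi_stats.json")
            if config.tf_list:
                subnets = tf_neighborhoods(
                    net, config.tf_list, sub, top_k=config.tf_top_k, hub_fraction=config.hub_fraction,
                    cluster_of=ccm.cluster_of if ccm is not None else None,
                )
                for tf, g in subnets.items():
                    write_graphml(g, outdir / f"tf_subnetwork_{tf.replace('/', '_')}.graphml")
            manifest["stages"]["minet"] = {"cutoff": cutoff, **hub_stats}
        except Exception as exc:
            fail("minet", exc)
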