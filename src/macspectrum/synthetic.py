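"""Synthetic expression data with known planted structure.

Every downstream stage of the pipeline (correlation networks, SOM marker
calling, coexpression modules, module-set GSEA, mutual-information network
inference) is exercised against data generated here, where the ground truth
— module memberships, condition markers, true dependency edges, hub genes —
is known by construction.

The generative model mirrors log2 microarray intensities:

    x[g, s] = baseline_mean + offset[g] + sum_m effect_m * 1[cond(s) in drivers_m, g in m]
              + sum_k effect_k * 1[cond(s) = c_k, g = g_k]            (exclusive markers)
              + N(0, noise_sd^2)

``offset[g] ~ N(0, gene_sd^2)`` is a per-gene baseline level shared by all
samples. Real transcriptomes have large between-gene variation relative to
between-sample variation, which is what makes any two arrays correlate at
r ~ 0.9; without it sample-sample Pearson graphs would be empty, so the
offset scale is a first-class parameter of the generator.

Module genes share a single condition-driven latent factor with per-gene
loading 1, giving a closed-form within-module correlation
``effect^2 var(ind) / (effect^2 var(ind) + noise_sd^2)`` that the tests use
as an oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix

# Stimulus labels used when auto-naming conditions; drawn from the standard
# macrophage-activation vocabulary (cytokines, TLR ligands, metabolic cues).
STIMULUS_NAMES = [
    "IFN-g", "IL-4", "TPP", "sLPS", "uLPS", "TNF", "IL-13", "IL-10",
    "IFN-b", "PGE2", "P3C", "PA", "OA", "LA", "HDL", "GC", "IFN-g+TNF",
    "IL4+uLPS", "upLPS+IC", "sLPS+IFN-g", "TPP+IFN-b", "PGE2+P3C",
    "TNF+PGE2", "TNF+P3C", "IL-6", "sLPS+IC", "P3C+PGE2+TNF-early", "HDL+sLPS",
]


@dataclass
class PlantedModule:
    """A coexpressed gene set elevated together under its driver conditions."""

    genes: list[str]
    driver_conditions: list[str]
    effect: float  # log2 units added when the sample's condition is a driver


@dataclass
class PlantedStructure:
    """Everything the generator plants into a simulated expression matrix."""

    modules: list[PlantedModule] = field(default_factory=list)
    exclusive_markers: list[tuple[str, str, float]] = field(default_factory=list)
    hub_spec: dict | None = None  # reserved for dependency-graph simulations
    noise_sd: float = 0.5
    baseline_mean: float = 8.0
    gene_sd: float = 1.0

    def validate(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.gene_sd < 0:
            raise ValueError("gene_sd must be >= 0")
        seen: set[str] = set()
        for i, mod in enumerate(self.modules):
            if not math.isfinite(mod.effect):
                raise ValueError(f"module {i}: non-finite effect")
            overlap = seen & set(mod.genes)
            if overlap:
                raise ValueError(f"module {i}: gene(s) {sorted(overlap)[:5]} already in another module")
            seen |= set(mod.genes)
        for g, c, e in self.exclusive_markers:
            if not math.isfinite(e):
                raise ValueError(f"marker {g}: non-finite effect")


def make_design(
    n_conditions: int,
    replicates: int,
    baseline_name: str = "Mb",
    seed: int = 0,
    n_donors: int = 5,
    time_h: float = 72.0,
) -> pd.DataFrame:
    """Build a sample annotation table: ``n_conditions`` x ``replicates`` rows.

    The first condition is the baseline (unstimulated) group; the rest take
    stimulus names from the standard vocabulary. Donors are assigned from a
    rotating pool with a seeded shuffle per condition.
    """
    if n_conditions < 2:
        raise ValueError("n_conditions must be >= 2 (baseline plus at least one stimulus)")
    if replicates < 2:
        raise ValueError("replicates must be >= 2")
    rng = np.random.default_rng(seed)
    names = [baseline_name]
    for i in range(n_conditions - 1):
        names.append(STIMULUS_NAMES[i] if i < len(STIMULUS_NAMES) else f"stim{i + 1}")
    rows = []
    donors = [f"D{i + 1}" for i in range(n_donors)]
    for cond in names:
        pool = list(donors)
        rng.shuffle(pool)
        for r in range(replicates):
            rows.append(
                {
                    "sample_id": f"{cond}.r{r + 1}",
                    "condition": cond,
                    "time_h": time_h,
                    "donor": pool[r % len(pool)],
                    "is_baseline": cond == baseline_name,
                }
            )
    design = pd.DataFrame(rows).set_index("sample_id")
    return design


def simulate_expression(
    design: pd.DataFrame,
    structure: PlantedStructure,
    n_background_genes: int = 100,
    seed: int = 0,
) -> ExpressionMatrix:
    """Draw an expression matrix with the given planted structure.

    Gene order: module genes (in module order), marker genes not already
    present, then background genes named ``BG####``.
    """
    structure.validate()
    conditions = set(design["condition"].astype(str))
    for i, mod in enumerate(structure.modules):
        unknown = [c for c in mod.driver_conditions if c not in conditions]
        if unknown:
            raise ValueError(f"module {i}: unknown driver condition(s) {unknown}")
    for g, c, _ in structure.exclusive_markers:
        if c not in conditions:
            raise ValueError(f"marker {g!r}: unknown condition {c!r}")

    genes: list[str] = []
    for mod in structure.modules:
        genes.extend(mod.genes)
    for g, _, _ in structure.exclusive_markers:
        if g not in genes:
            genes.append(g)
    width = max(4, len(str(n_background_genes)))
    genes.extend(f"BG{i + 1:0{width}d}" for i in range(n_background_genes))
    if len(set(genes)) != len(genes):
        raise ValueError("gene ids collide across modules/markers/background")

    rng = np.random.default_rng(seed)
    n_g, n_s = len(genes), len(design)
    gene_index = {g: i for i, g in enumerate(genes)}
    cond_of = design["condition"].astype(str).to_numpy()

    values = np.full((n_g, n_s), structure.baseline_mean, dtype=float)
    values += rng.normal(0.0, structure.gene_sd, size=n_g)[:, None]
    for mod in structure.modules:
        ind = np.isin(cond_of, mod.driver_conditions).astype(float)
        rows = [gene_index[g] for g in mod.genes]
        values[rows, :] += mod.effect * ind[None, :]
    for g, c, e in structure.exclusive_markers:
        values[gene_index[g], :] += e * (cond_of == c).astype(float)
    values += rng.normal(0.0, structure.noise_sd, size=(n_g, n_s))

    frame = pd.DataFrame(values, index=genes, columns=design.index)
    return ExpressionMatrix(frame, design.copy())


def within_module_correlation(effect: float, noise_sd: float, indicator: np.ndarray) -> float:
    """Closed-form expected gene-gene Pearson r inside a planted module.

    The shared signal is ``effect * indicator`` (per-gene loading 1) plus
    independent ``N(0, noise_sd^2)`` noise, so
    ``r = e^2 v / (e^2 v + sigma^2)`` with ``v = var(indicator)``.
    """
    v = float(np.var(indicator))
    s = effect**2 * v
    denom = s + noise_sd**2
    return 1.0 if denom == 0 else s / denom


# ---------------------------------------------------------------------------
# Hub-structured dependency networks (ground truth for reverse engineering)
# ---------------------------------------------------------------------------


@dataclass
class HubNetworkTruth:
    """Ground truth of a simulated sparse Gaussian dependency network."""

    edges: set[tuple[str, str]]  # sorted gene-id pairs
    hubs: list[str]
    implied_corr: dict[tuple[str, str], float]  # marginal Pearson r per true edge
    degrees: dict[str, int]


def simulate_hub_network_data(
    n_genes: int,
    n_samples: int,
    hub_fraction: float = 0.1,
    seed: int = 0,
    baseline_mean: float = 8.0,
    edge_weight_range: tuple[float, float] = (0.90, 1.00),
    edges: list[tuple[str, str]] | None = None,
) -> tuple[ExpressionMatrix, HubNetworkTruth]:
    """Sample expression from a sparse Gaussian graphical model with hubs.

    A fraction ``hub_fraction`` of genes are designated hubs; every other
    gene attaches to one hub (dealt round-robin after a seeded shuffle, so
    hub degrees are balanced and strictly exceed non-hub degrees) and the
    hubs themselves are chained. Edge weights populate a symmetric precision
    matrix whose diagonal is inflated to strict dominance, guaranteeing a
    valid covariance; data are drawn from the implied correlation matrix.

    Passing ``edges`` explicitly overrides the hub wiring (an empty list
    yields mutually independent genes); hubs are then labelled by degree.
    """
    if n_genes < 10:
        raise ValueError("n_genes must be >= 10")
    if not (0.0 < hub_fraction < 1.0):
        raise ValueError("hub_fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    width = max(3, len(str(n_genes)))
    genes = [f"G{i + 1:0{width}d}" for i in range(n_genes)]
    gene_index = {g: i for i, g in enumerate(genes)}

    n_hubs = max(1, round(hub_fraction * n_genes))
    if edges is None:
        hubs = genes[:n_hubs]
        leaves = genes[n_hubs:]
        order = list(leaves)
        rng.shuffle(order)
        edge_pairs = [tuple(sorted((order[i], hubs[i % n_hubs]))) for i in range(len(order))]
        edge_pairs += [tuple(sorted((hubs[i], hubs[i + 1]))) for i in range(n_hubs - 1)]
    else:
        edge_pairs = [tuple(sorted((str(a), str(b)))) for a, b in edges]
        hubs = None  # assigned from degrees below

    omega = np.eye(n_genes)
    lo, hi = edge_weight_range
    for a, b in edge_pairs:
        w = rng.uniform(lo, hi)
        i, j = gene_index[a], gene_index[b]
        omega[i, j] = omega[j, i] = -w
    row_offdiag = np.abs(omega).sum(axis=1) - np.diag(omega)
    np.fill_diagonal(omega, np.maximum(1.0, 1.05 * row_offdiag))

    sigma = np.linalg.inv(omega)
    d = np.sqrt(np.diag(sigma))
    corr = sigma / np.outer(d, d)

    chol = np.linalg.cholesky(corr)
    data = baseline_mean + (chol @ rng.standard_normal((n_genes, n_samples)))

    degrees = {g: 0 for g in genes}
    implied = {}
    for a, b in edge_pairs:
        degrees[a] += 1
        degrees[b] += 1
        implied[(a, b)] = float(corr[gene_index[a], gene_index[b]])
    if hubs is None:
        ranked = sorted(genes, key=lambda g: (-degrees[g], g))
        hubs = ranked[:n_hubs]

    design = pd.DataFrame(
        {
            "condition": "expr",
            "time_h": 0.0,
            "donor": "sim",
            "is_baseline": True,
        },
        index=pd.Index([f"S{j + 1:04d}" for j in range(n_samples)], name="sample_id"),
    )
    matrix = ExpressionMatrix(pd.DataFrame(data, index=genes, columns=design.index), design)
    truth = HubNetworkTruth(set(edge_pairs), list(hubs), implied, degrees)
    return matrix, truth


# ---------------------------------------------------------------------------
# Standard study-condition fixtures
# ---------------------------------------------------------------------------


def module_recovery_structure(
    design: pd.DataFrame,
    n_modules: int = 6,
    module_size: int = 50,
    effect: float = 2.0,
    noise_sd: float = 0.5,
    markers: bool = False,
) -> PlantedStructure:
    """Planted structure with one module per condition (module i driven by
    condition i, the first being the baseline program)."""
    conditions = list(dict.fromkeys(design["condition"].astype(str)))
    if n_modules > len(conditions):
        raise ValueError("need at least one condition per module")
    modules = []
    for m in range(n_modules):
        genes = [f"M{m + 1:02d}.{k + 1:03d}" for k in range(module_size)]
        modules.append(PlantedModule(genes, [conditions[m]], effect))
    marker_list = []
    if markers:
        for c in conditions[1:]:
            marker_list.append((f"MK.{c}", c, 3.0))
    return PlantedStructure(modules=modules, exclusive_markers=marker_list, noise_sd=noise_sd)


def spectrum_fixture(
    seed: int = 0,
    with_orthogonal: bool = True,
    replicates: int = 8,
    program_size: int = 40,
    effect: float = 2.0,
    noise_sd: float = 0.3,
    n_genes: int = 200,
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Planted activation geometry for the spectrum model.

    Two antagonistic programs share one gene set: condition ``M1like``
    induces it (+effect) and ``M2like`` represses it (-effect) — the classic
    bipolar axis. With ``with_orthogonal`` a third condition ``Mx`` drives a
    disjoint gene set, a program orthogonal to that axis. Returns the matrix
    and its design.
    """
    n_conditions = 4 if with_orthogonal else 3
    design = make_design(n_conditions, replicates, baseline_name="Mb", seed=seed)
    conds = list(dict.fromkeys(design["condition"]))
    m1, m2 = conds[1], conds[2]
    axis_genes = [f"AX.{i + 1:03d}" for i in range(program_size)]
    modules = [PlantedModule(axis_genes, [m1], effect)]
    markers = [(g, m2, -effect) for g in axis_genes]
    if with_orthogonal:
        ortho_genes = [f"OR.{i + 1:03d}" for i in range(program_size)]
        modules.append(PlantedModule(ortho_genes, [conds[3]], effect))
    structure = PlantedStructure(modules=modules, exclusive_markers=markers, noise_sd=noise_sd)
    named = sum(len(m.genes) for m in modules)
    matrix = simulate_expression(design, structure, n_background_genes=n_genes - named, seed=seed)
    return matrix, design


def demo_dataset(seed: int = 0) -> tuple[ExpressionMatrix, PlantedStructure]:
    """Bundled demo: 6 conditions x 10 replicates, 6 planted modules of 25
    genes (effect 2, noise 0.5), one exclusive marker per stimulus, background
    genes bringing the matrix to 200 genes x 60 samples."""
    design = make_design(6, 10, baseline_name="Mb", seed=seed)
    structure = module_recovery_structure(design, n_modules=6, module_size=25, markers=True)
    n_named = sum(len(m.genes) for m in structure.modules) + len(structure.exclusive_markers)
    matrix = simulate_expression(design, structure, n_background_genes=200 - n_named, seed=seed)
    return matrix, structure
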