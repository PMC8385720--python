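"""Synthetic multi-omics cohort generator with planted ground truth.

Every pipeline stage (stratification, immune scoring, differential calling,
DMEG integration, enrichment, drug proximity, survival modelling) can be
exercised on cohorts produced here without any external download.  The
generator emulates a paired normal/tumor design with:

* per-gene baseline log2 expression plus group shifts plus Gaussian noise;
* a checkpoint gene elevated in a configurable fraction of tumors, so that
  checkpoint-negative stratification selects the complement;
* region-annotated methylation probes whose beta values scatter around a
  gene-region mean, with planted tumor delta-beta shifts;
* stromal/immune signature structure driven by a per-sample infiltration
  factor (lower in tumors by default);
* survival times drawn from a proportional-hazards model with an
  exponential baseline hazard and independent uniform censoring;
* a preferential-attachment PPI graph and drug target sets at controlled
  graph distance from a disease gene set.

All randomness flows through one :class:`numpy.random.Generator` seeded by
``CohortSpec.seed``; the seed fully determines the cohort.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .io import (
    NORMAL,
    TUMOR,
    ClinicalTable,
    DrugTargetTable,
    ExpressionMatrix,
    GeneSet,
    GeneSetCollection,
    MethylationDataset,
    PPIGraph,
)

__all__ = [
    "CohortSpec",
    "CohortTruth",
    "SyntheticCohort",
    "gene_names",
    "generate_cohort",
    "generate_ppi",
    "generate_drug_targets",
]


def gene_names(n: int, prefix: str = "G") -> list[str]:
    """Deterministic gene identifiers G0001, G0002, ..."""
    width = max(4, len(str(n)))
    return [f"{prefix}{i:0{width}d}" for i in range(1, n + 1)]


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic cohort.

    Defaults mirror the cohort this generator emulates: 50 normal and 177
    tumor samples, log2-scale expression with unit noise, beta noise 0.05,
    an exponential baseline hazard of 1e-3 per day and uniform censoring on
    (0, 3000] days (about 30% censored).
    """

    n_normal: int = 50
    n_tumor: int = 177
    n_genes: int = 500
    #: (gene, log2 shift in tumors)
    planted_deg: tuple[tuple[str, float], ...] = ()
    #: (gene, region, delta beta in tumors)
    planted_dmg: tuple[tuple[str, str, float], ...] = ()
    #: (gene, region, delta beta, log2 shift) — methylation/expression coupled
    planted_dmeg: tuple[tuple[str, str, float, float], ...] = ()
    checkpoint_gene: str = "PDCD1"
    checkpoint_shift: float = 2.0
    #: fraction of tumors in which the checkpoint gene is elevated
    checkpoint_high_fraction: float = 0.5
    n_stromal: int = 40
    n_immune: int = 40
    infiltration_normal_mean: float = 1.0
    infiltration_tumor_mean: float = -1.0
    infiltration_sd: float = 0.5
    #: (gene, Cox log-hazard coefficient per log2-expression unit)
    prognostic_genes: tuple[tuple[str, float], ...] = ()
    baseline_hazard: float = 1e-3
    censor_window: float = 3000.0
    expr_noise_sd: float = 1.0
    beta_noise_sd: float = 0.05
    probes_per_region_mean: float = 2.0
    regions: tuple[str, ...] = ("TSS200", "TSS1500", "Body")
    n_ppi_nodes: int = 150
    ppi_edges_per_node: int = 3
    n_drugs: int = 12
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_normal", "n_tumor", "n_genes", "n_stromal", "n_immune"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.checkpoint_high_fraction <= 1.0:
            raise ValueError("checkpoint_high_fraction must be in [0, 1]")
        for gene, region, dbeta, *_ in (*self.planted_dmg, *self.planted_dmeg):
            if abs(dbeta) > 0.9:
                raise ValueError(
                    f"planted delta beta {dbeta} for {gene}/{region} infeasible: "
                    "group means cannot both stay inside [0, 1]"
                )


@dataclass
class CohortTruth:
    """Planted ground truth of a synthetic cohort."""

    deg: dict[str, float]  # gene -> log2 shift (DEG + expression arm of DMEGs)
    dmg: dict[tuple[str, str], float]  # (gene, region) -> delta beta
    dmeg: dict[str, tuple[str, float, float]]  # gene -> (region, dbeta, lfc)
    prognostic: dict[str, float]  # gene -> Cox coefficient
    checkpoint_high_tumors: list[str]
    infiltration: pd.Series  # per-sample planted infiltration factor
    stromal_genes: list[str]
    immune_genes: list[str]
    disease_genes: list[str]  # DMEG genes embedded in the PPI graph


@dataclass
class SyntheticCohort:
    expression: ExpressionMatrix
    methylation: MethylationDataset
    clinical: ClinicalTable
    ppi: PPIGraph
    drug_targets: DrugTargetTable
    gene_sets: GeneSetCollection
    truth: CohortTruth


# ---------------------------------------------------------------------------
# graph generation
# ---------------------------------------------------------------------------


def generate_ppi(
    n_nodes: int,
    edges_per_node: int,
    seed: int | np.random.Generator = 0,
    node_names: Sequence[str] | None = None,
) -> PPIGraph:
    """Connected preferential-attachment (Barabási–Albert) graph.

    Each of the ``n_nodes - edges_per_node`` arriving nodes attaches
    ``edges_per_node`` edges, so the edge count is
    ``edges_per_node * (n_nodes - edges_per_node)``.
    """
    if edges_per_node < 1 or n_nodes <= edges_per_node:
        raise ValueError("need n_nodes > edges_per_node >= 1")
    rng = np.random.default_rng(seed) if isinstance(seed, int) else seed
    g = nx.barabasi_albert_graph(n_nodes, edges_per_node, seed=int(rng.integers(2**31)))
    if node_names is not None:
        if len(node_names) < n_nodes:
            raise ValueError("not enough node names supplied")
        g = nx.relabel_nodes(g, {i: node_names[i] for i in range(n_nodes)})
    else:
        g = nx.relabel_nodes(g, {i: f"P{i:04d}" for i in range(n_nodes)})
    return PPIGraph(g)


def generate_drug_targets(
    ppi: PPIGraph,
    disease_set: Sequence[str],
    n_drugs: int,
    distance_profile: str = "mixed",
    seed: int | np.random.Generator = 0,
    targets_per_drug: int = 3,
) -> DrugTargetTable:
    """Drug target sets at controlled graph distance from ``disease_set``.

    Profiles: ``on_target`` draws targets from the disease set itself
    (proximity <= 0); ``near`` draws from nodes at hop distance 1–2;
    ``remote`` draws from the farthest distance band (proximity >= 1);
    ``mixed`` cycles through the three.
    """
    rng = np.random.default_rng(seed) if isinstance(seed, int) else seed
    disease = [g for g in disease_set if g in ppi]
    if not disease:
        raise ValueError("no disease genes present in the PPI graph")
    dist = nx.multi_source_dijkstra_path_length(ppi.graph, set(disease), weight=None)
    bands = {
        "on_target": list(disease),
        "near": sorted(n for n, d in dist.items() if 1 <= d <= 2),
        "remote": sorted(n for n, d in dist.items() if d >= max(2, max(dist.values()))),
    }
    profiles = ["on_target", "near", "remote"] if distance_profile == "mixed" else [distance_profile]
    if any(p not in bands for p in profiles):
        raise ValueError(f"unknown distance profile {distance_profile!r}")
    targets: dict[str, frozenset[str]] = {}
    for i in range(n_drugs):
        profile = profiles[i % len(profiles)]
        pool = bands[profile]
        if not pool:
            raise ValueError(f"distance profile {profile!r} unachievable in this graph")
        k = min(targets_per_drug, len(pool))
        picked = rng.choice(np.array(pool, dtype=object), size=k, replace=False)
        targets[f"DRUG{i + 1:03d}_{profile}"] = frozenset(str(t) for t in picked)
    return DrugTargetTable(targets)


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------


def _sample_ids(spec: CohortSpec) -> tuple[list[str], list[str]]:
    normals = [f"N{i:03d}" for i in range(1, spec.n_normal + 1)]
    tumors = [f"T{i:03d}" for i in range(1, spec.n_tumor + 1)]
    return normals, tumors


def generate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Generate a full in-memory cohort from ``spec`` (deterministic under its seed)."""
    rng = np.random.default_rng(spec.seed)
    normals, tumors = _sample_ids(spec)
    samples = normals + tumors
    labels = pd.Series([NORMAL] * len(normals) + [TUMOR] * len(tumors), index=samples, name="group")

    genes = gene_names(spec.n_genes)
    extra = [g for g, *_ in (*spec.planted_deg, *spec.planted_dmg, *spec.planted_dmeg)]
    extra += [g for g, _ in spec.prognostic_genes]
    unknown = sorted(set(extra) - set(genes))
    genes = genes + [g for g in unknown if g != spec.checkpoint_gene]
    if spec.checkpoint_gene not in genes:
        genes.append(spec.checkpoint_gene)

    # signature genes: last blocks of the baseline universe (disjoint from G0001..)
    stromal = [f"STRO{i:03d}" for i in range(1, spec.n_stromal + 1)]
    immune = [f"IMMU{i:03d}" for i in range(1, spec.n_immune + 1)]
    genes = genes + stromal + immune

    n_g, n_s = len(genes), len(samples)
    gidx = {g: i for i, g in enumerate(genes)}
    sidx = {s: j for j, s in enumerate(samples)}

    baseline = rng.normal(6.0, 2.0, size=n_g)
    expr = baseline[:, None] + rng.normal(0.0, spec.expr_noise_sd, size=(n_g, n_s))

    # planted expression shifts in tumors (DEGs + expression arm of DMEGs)
    tumor_cols = np.array([sidx[s] for s in tumors])
    deg_truth: dict[str, float] = {}
    for gene, lfc in spec.planted_deg:
        expr[gidx[gene], tumor_cols] += lfc
        deg_truth[gene] = lfc
    for gene, _region, _dbeta, lfc in spec.planted_dmeg:
        expr[gidx[gene], tumor_cols] += lfc
        deg_truth[gene] = lfc

    # checkpoint gene elevated in a subset of tumors
    n_high = int(round(spec.checkpoint_high_fraction * len(tumors)))
    high = sorted(rng.choice(len(tumors), size=n_high, replace=False).tolist())
    high_samples = [tumors[i] for i in high]
    expr[gidx[spec.checkpoint_gene], tumor_cols[high]] += spec.checkpoint_shift

    # infiltration factor added to signature genes
    infil = np.where(
        labels.values == NORMAL,
        rng.normal(spec.infiltration_normal_mean, spec.infiltration_sd, size=n_s),
        rng.normal(spec.infiltration_tumor_mean, spec.infiltration_sd, size=n_s),
    )
    for g in stromal + immune:
        expr[gidx[g], :] += infil

    expression = ExpressionMatrix(
        pd.DataFrame(expr, index=genes, columns=samples), log_scale=True, group_labels=labels
    )

    # ----- methylation -------------------------------------------------
    planted_beta: dict[tuple[str, str], float] = {}
    for gene, region, dbeta in spec.planted_dmg:
        planted_beta[(gene, region)] = dbeta
    for gene, region, dbeta, _lfc in spec.planted_dmeg:
        planted_beta[(gene, region)] = dbeta

    probe_rows, beta_rows = [], []
    region_base = {"TSS200": 0.2, "TSS1500": 0.25, "Body": 0.6, "5'UTR": 0.3, "1stExon": 0.25, "3'UTR": 0.5}
    probe_no = 0
    meth_genes = [g for g in genes if not g.startswith(("STRO", "IMMU"))]
    tumor_mask = labels.values == TUMOR
    for g in meth_genes:
        for region in spec.regions:
            dbeta = planted_beta.get((g, region), 0.0)
            if dbeta:
                # centre the planted pair so both group means are interior
                mu = float(np.clip(0.5 - dbeta / 2.0, 0.05, 0.95))
            else:
                mu = float(np.clip(rng.normal(region_base.get(region, 0.4), 0.1), 0.05, 0.95))
            if not (0.0 <= mu + dbeta <= 1.0):
                raise ValueError(f"infeasible beta shift {dbeta} for {g}/{region}")
            n_probes = 1 + rng.poisson(spec.probes_per_region_mean)
            for _ in range(n_probes):
                probe_no += 1
                pid = f"cg{probe_no:07d}"
                vals = mu + dbeta * tumor_mask + rng.normal(0.0, spec.beta_noise_sd, size=n_s)
                beta_rows.append(np.clip(vals, 0.0, 1.0))
                probe_rows.append((pid, g, region))

    beta = pd.DataFrame(
        np.vstack(beta_rows), index=[p for p, _, _ in probe_rows], columns=samples
    )
    chrom_names = [f"chr{i}" for i in range(1, 23)] + ["chrX", "chrY"]
    gene_chrom = {g: chrom_names[i % len(chrom_names)] for i, g in enumerate(genes)}
    manifest = pd.DataFrame(
        {
            "gene": [g for _, g, _ in probe_rows],
            "region": [r for _, _, r in probe_rows],
            "chromosome": [gene_chrom[g] for _, g, _ in probe_rows],
        },
        index=pd.Index([p for p, _, _ in probe_rows], name="probe"),
    )
    methylation = MethylationDataset(beta=beta, manifest=manifest)

    # ----- survival (tumor samples) ------------------------------------
    prog = dict(spec.prognostic_genes)
    tumor_expr = expr[:, tumor_cols]
    risk = np.zeros(len(tumors))
    for g, coef in prog.items():
        row = tumor_expr[gidx[g], :]
        risk += coef * (row - row.mean())
    rate = spec.baseline_hazard * np.exp(risk)
    event_t = rng.exponential(1.0 / rate)
    censor_t = rng.uniform(0.0, spec.censor_window, size=len(tumors))
    time = np.maximum(np.minimum(event_t, censor_t), 1e-6)
    event = (event_t <= censor_t).astype(int)
    clinical = ClinicalTable(pd.DataFrame({"time": time, "event": event}, index=pd.Index(tumors, name="sample")))

    # ----- graph, drugs, signatures ------------------------------------
    dmeg_genes = [g for g, *_ in spec.planted_dmeg]
    ppi_pool = dmeg_genes + [g for g in meth_genes if g not in dmeg_genes]
    n_nodes = min(spec.n_ppi_nodes, len(ppi_pool))
    ppi = generate_ppi(n_nodes, spec.ppi_edges_per_node, seed=rng, node_names=ppi_pool)
    disease = [g for g in dmeg_genes if g in ppi] or ppi.nodes[: max(3, len(dmeg_genes))]
    drug_targets = generate_drug_targets(ppi, disease, spec.n_drugs, "mixed", seed=rng)

    gene_sets = GeneSetCollection(
        [
            GeneSet("STROMAL", "synthetic stromal signature", tuple(stromal)),
            GeneSet("IMMUNE", "synthetic immune signature", tuple(immune)),
        ]
    )

    truth = CohortTruth(
        deg=deg_truth,
        dmg=planted_beta,
        dmeg={g: (r, db, lfc) for g, r, db, lfc in spec.planted_dmeg},
        prognostic=prog,
        checkpoint_high_tumors=high_samples,
        infiltration=pd.Series(infil, index=samples, name="infiltration"),
        stromal_genes=stromal,
        immune_genes=immune,
        disease_genes=list(disease),
    )
    return SyntheticCohort(expression, methylation, clinical, ppi, drug_targets, gene_sets, truth)


def with_seed(spec: CohortSpec, seed: int) -> CohortSpec:
    """Copy of ``spec`` with a different seed."""
    return replace(spec, seed=seed)
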