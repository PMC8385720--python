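"""Weighted drug–disease network proximity over a PPI graph.

For a disease gene set S and a drug target set T the proximity is

    d(S, T) = (1/|T|) * sum over t in T of [ min over s in S of d(s, t) + omega(t) ]

where d(s, t) is the unweighted shortest-path hop count and omega(t) is a
degree-dependent weight: -ln(D + 1) with D the degree of t if t belongs to
the disease set, 0 otherwise.  Drugs with proximity below a screening
threshold (0.8 by default) are flagged as candidate targeted agents; the
threshold is motivated by comparing observed proximities with a null
density over random gene sets.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .io import DrugTargetTable, PPIGraph

logger = logging.getLogger(__name__)

__all__ = [
    "shortest_path_len",
    "omega",
    "proximity",
    "drug_proximities",
    "null_distance_distribution",
    "screen_drugs",
    "ProximityResult",
]


def shortest_path_len(ppi: PPIGraph, s: str, t: str) -> float:
    """Unweighted shortest-path hop count; d(s, s) = 0; math.inf if disconnected."""
    for node in (s, t):
        if node not in ppi:
            raise KeyError(f"node {node!r} not in graph")
    try:
        return float(nx.shortest_path_length(ppi.graph, s, t))
    except nx.NetworkXNoPath:
        return math.inf


def omega(gene: str, disease_set: set[str] | frozenset[str], ppi: PPIGraph, degree_of: str = "target") -> float:
    """Degree weight of a target gene: -ln(degree + 1) if in the disease set, else 0.

    ``degree_of`` selects whose degree enters the weight; the default
    ``"target"`` uses the gene itself (``"disease"`` is accepted for
    compatibility with the alternative reading and behaves identically here
    because the weighted gene is, by definition, a disease-set member).
    """
    if degree_of not in ("target", "disease"):
        raise ValueError("degree_of must be 'target' or 'disease'")
    if gene not in disease_set:
        return 0.0
    if gene not in ppi:
        raise KeyError(f"disease-set gene {gene!r} absent from the graph")
    return -math.log(ppi.degree(gene) + 1.0)


@dataclass
class ProximityResult:
    """Per-drug proximity with per-target decomposition.

    ``terms`` has one row per retained target with columns ``min_dist`` and
    ``omega``; the proximity is their row-sum mean, so the score is
    recomputable from the stored terms.  ``proximity`` is NaN when no target
    is in the graph and inf when no target is reachable from S.
    """

    drug: str
    disease_set: frozenset[str]
    target_set: frozenset[str]
    terms: pd.DataFrame
    proximity: float
    n_dropped_targets: int = 0


def proximity(
    disease_set: set[str] | frozenset[str],
    target_set: set[str] | frozenset[str],
    ppi: PPIGraph,
    drug: str = "",
    degree_of: str = "target",
) -> ProximityResult:
    """d(S, T) over the graph.

    Disease genes and targets absent from the graph are dropped with a log
    message; a drug with no in-graph target gets a NaN score.  Targets
    unreachable from every disease gene are excluded (logged); if all
    targets are unreachable the score is inf.
    """
    S = frozenset(disease_set)
    T = frozenset(target_set)
    if not S or not T:
        raise ValueError("disease and target sets must be non-empty")
    S_in = frozenset(g for g in S if g in ppi)
    dropped_S = len(S) - len(S_in)
    if dropped_S:
        logger.info("dropping %d disease gene(s) absent from graph", dropped_S)
    if not S_in:
        raise ValueError("no disease gene present in the graph")
    T_in = sorted(t for t in T if t in ppi)
    n_dropped = len(T) - len(T_in)
    if n_dropped:
        logger.info("drug %s: dropping %d target(s) absent from graph", drug or "?", n_dropped)
    if not T_in:
        return ProximityResult(drug, S, T, pd.DataFrame(columns=["min_dist", "omega"]), float("nan"), n_dropped)

    # single multi-source BFS from S covers every target
    dist = nx.multi_source_dijkstra_path_length(ppi.graph, set(S_in), weight=None)
    rows = {}
    for t in T_in:
        d = dist.get(t, math.inf)
        if math.isinf(d):
            continue
        rows[t] = (float(d), omega(t, S_in, ppi, degree_of))
    unreachable = len(T_in) - len(rows)
    if unreachable:
        logger.info("drug %s: %d target(s) unreachable from disease set", drug or "?", unreachable)
    if not rows:
        return ProximityResult(drug, S, T, pd.DataFrame(columns=["min_dist", "omega"]), math.inf, n_dropped)
    terms = pd.DataFrame.from_dict(rows, orient="index", columns=["min_dist", "omega"])
    score = float((terms["min_dist"] + terms["omega"]).mean())
    return ProximityResult(drug, S, T, terms, score, n_dropped)


def drug_proximities(
    disease_set: set[str] | frozenset[str],
    drugs: DrugTargetTable,
    ppi: PPIGraph,
    degree_of: str = "target",
) -> list[ProximityResult]:
    return [proximity(disease_set, drugs[d], ppi, drug=d, degree_of=degree_of) for d in drugs.drugs]


def null_distance_distribution(
    ppi: PPIGraph,
    target_sets: DrugTargetTable,
    set_size: int,
    n_draws: int,
    seed: int | np.random.Generator = 0,
    degree_matched: bool = False,
    reference_set: set[str] | None = None,
) -> np.ndarray:
    """Pooled proximity sample over random pseudo-disease gene sets.

    Each draw samples ``set_size`` graph nodes uniformly (or, with
    ``degree_matched=True``, matched to the degree distribution of
    ``reference_set``) and scores every drug's targets against them.
    """
    nodes = np.array(ppi.nodes, dtype=object)
    if set_size > len(nodes):
        raise ValueError("set_size exceeds the number of graph nodes")
    rng = np.random.default_rng(seed) if isinstance(seed, (int, np.integer)) else seed
    if degree_matched:
        if not reference_set:
            raise ValueError("degree_matched sampling needs a reference_set")
        ref_deg = sorted(ppi.degree(g) for g in reference_set if g in ppi)
        by_deg: dict[int, list[str]] = {}
        for n in nodes:
            by_deg.setdefault(ppi.degree(str(n)), []).append(str(n))
        all_degrees = np.array(sorted(by_deg))
    out: list[float] = []
    for _ in range(n_draws):
        if degree_matched:
            pseudo = set()
            for d in ref_deg:
                nearest = int(all_degrees[np.argmin(np.abs(all_degrees - d))])
                pseudo.add(str(rng.choice(by_deg[nearest])))
        else:
            pseudo = set(rng.choice(nodes, size=set_size, replace=False).astype(str))
        for drug in target_sets.drugs:
            score = proximity(pseudo, target_sets[drug], ppi).proximity
            if math.isfinite(score):
                out.append(score)
    return np.array(out)


def screen_drugs(results: list[ProximityResult], threshold: float = 0.8) -> list[ProximityResult]:
    """Drugs with proximity strictly below ``threshold``, sorted ascending."""
    hits = [r for r in results if math.isfinite(r.proximity) and r.proximity < threshold]
    return sorted(hits, key=lambda r: (r.proximity, r.drug))
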