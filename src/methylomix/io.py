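"""Containers and tab-separated readers/writers for every format the pipeline touches.

All identifiers (genes, probes, samples, drugs) are opaque strings; no
symbol/Ensembl translation is attempted.  Files are UTF-8 TSV with ``#``
comment lines; writers emit a deterministic column order so that a
write/read round trip reproduces identifiers and values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Closed vocabulary of probe region annotations (450K-style).
REGION_TAGS: tuple[str, ...] = ("TSS200", "TSS1500", "Body", "5'UTR", "1stExon", "3'UTR")

#: Group labels for samples.
NORMAL, TUMOR = "normal", "tumor"

_NA_TOKENS = {"", "NA", "NaN", "nan", "N/A", "null", "None"}


class FormatError(ValueError):
    """A file violated its declared format (named row/column/line in the message)."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Gene x sample abundance matrix with optional normal/tumor labels.

    Parameters
    ----------
    values : DataFrame
        Rows are genes, columns are samples.  Missing entries are NaN.
    log_scale : bool
        Whether values are on the log2 scale.  Linear-scale matrices must be
        non-negative.
    group_labels : Series, optional
        Per-sample label, either ``"normal"`` or ``"tumor"``.
    """

    values: pd.DataFrame
    log_scale: bool = True
    group_labels: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()][0]
            raise FormatError(f"duplicate gene identifier {dup!r}")
        if self.values.columns.duplicated().any():
            dup = self.values.columns[self.values.columns.duplicated()][0]
            raise FormatError(f"duplicate sample identifier {dup!r}")
        if not self.log_scale:
            vals = self.values.to_numpy(dtype=float)
            if np.nanmin(vals, initial=0.0) < 0:
                raise ValueError("negative values in a linear-scale expression matrix")
        if self.group_labels is not None:
            self.group_labels = self.group_labels.reindex(self.values.columns)
            bad = set(self.group_labels.dropna()) - {NORMAL, TUMOR}
            if bad:
                raise ValueError(f"unknown group labels: {sorted(bad)}")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def samples_in_group(self, group: str) -> list[str]:
        if self.group_labels is None:
            raise ValueError("expression matrix has no group labels")
        return [s for s in self.samples if self.group_labels[s] == group]

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        labels = None if self.group_labels is None else self.group_labels[list(samples)]
        return ExpressionMatrix(self.values[list(samples)], self.log_scale, labels)


@dataclass
class MethylationDataset:
    """Probe x sample beta-value matrix plus a probe -> (gene, region, chromosome) manifest."""

    beta: pd.DataFrame
    manifest: pd.DataFrame  # index: probe; columns: gene, region, chromosome

    def __post_init__(self) -> None:
        vals = self.beta.to_numpy(dtype=float)
        finite = vals[np.isfinite(vals)]
        if finite.size and (finite.min() < 0.0 or finite.max() > 1.0):
            raise ValueError("beta values must lie in [0, 1] (or be missing)")
        bad = set(self.manifest["region"]) - set(REGION_TAGS)
        if bad:
            raise FormatError(f"unknown region tag(s): {sorted(bad)}")
        missing = self.beta.index.difference(self.manifest.index)
        if len(missing):
            raise ValueError(
                f"{len(missing)} probes in beta matrix absent from manifest "
                f"(first: {missing[0]!r})"
            )

    @property
    def probes(self) -> list[str]:
        return list(self.beta.index)

    @property
    def samples(self) -> list[str]:
        return list(self.beta.columns)

    def probes_in_region(self, region: str, gene: str | None = None) -> list[str]:
        if region not in REGION_TAGS:
            raise ValueError(f"unknown region tag {region!r}; expected one of {REGION_TAGS}")
        man = self.manifest.loc[self.beta.index]
        mask = man["region"] == region
        if gene is not None:
            mask &= man["gene"] == gene
        return list(man.index[mask])


@dataclass
class ClinicalTable:
    """Per-sample survival time (days, > 0) and event indicator (1 death, 0 censored)."""

    data: pd.DataFrame  # index: sample; columns: time, event

    def __post_init__(self) -> None:
        if self.data.index.duplicated().any():
            raise FormatError("duplicate sample identifier in clinical table")
        if (self.data["time"] <= 0).any():
            raise ValueError("survival times must be strictly positive")
        if not self.data["event"].isin([0, 1]).all():
            raise ValueError("event indicator must be 0 or 1")

    @property
    def samples(self) -> list[str]:
        return list(self.data.index)

    @property
    def time(self) -> pd.Series:
        return self.data["time"]

    @property
    def event(self) -> pd.Series:
        return self.data["event"]

    def subset(self, samples: Sequence[str]) -> "ClinicalTable":
        return ClinicalTable(self.data.loc[list(samples)].copy())


@dataclass(frozen=True)
class GeneSet:
    name: str
    description: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")

    @property
    def members(self) -> frozenset[str]:
        return frozenset(self.genes)

    def __len__(self) -> int:
        return len(set(self.genes))

    def __contains__(self, gene: object) -> bool:
        return gene in self.members


@dataclass
class GeneSetCollection:
    """Ordered collection of named gene sets (GMT semantics)."""

    sets: list[GeneSet] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [s.name for s in self.sets]
        if len(names) != len(set(names)):
            raise FormatError("duplicate gene-set name in collection")
        self._by_name = {s.name: s for s in self.sets}

    def __getitem__(self, name: str) -> GeneSet:
        return self._by_name[name]

    def __iter__(self) -> Iterator[GeneSet]:
        return iter(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.sets]


@dataclass
class PPIGraph:
    """Undirected simple protein–protein interaction graph over gene identifiers."""

    graph: nx.Graph

    def __post_init__(self) -> None:
        loops = list(nx.selfloop_edges(self.graph))
        if loops:
            self.graph = self.graph.copy()
            self.graph.remove_edges_from(loops)
            logger.info("removed %d self-loop(s) from PPI graph", len(loops))

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    def __contains__(self, gene: object) -> bool:
        return gene in self.graph

    def degree(self, gene: str) -> int:
        if gene not in self.graph:
            raise KeyError(f"gene {gene!r} not in PPI graph")
        return int(self.graph.degree[gene])

    def number_of_edges(self) -> int:
        return self.graph.number_of_edges()


@dataclass
class DrugTargetTable:
    """Mapping drug identifier -> non-empty set of target gene identifiers."""

    targets: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        for drug, tset in self.targets.items():
            if not tset:
                raise ValueError(f"drug {drug!r} has an empty target set")

    @property
    def drugs(self) -> list[str]:
        return list(self.targets)

    def __getitem__(self, drug: str) -> frozenset[str]:
        return self.targets[drug]

    def __len__(self) -> int:
        return len(self.targets)


# ---------------------------------------------------------------------------
# numeric TSV parsing
# ---------------------------------------------------------------------------


def _read_numeric_tsv(path: str | Path, what: str) -> pd.DataFrame:
    """Read a feature x sample TSV; non-numeric cells outside the NA vocabulary error."""
    with open(path, encoding="utf-8") as fh:  # pandas mangles duplicate header ids
        for line in fh:
            if line.strip() and not line.startswith("#"):
                header = line.rstrip("\n").split("\t")[1:]
                break
        else:
            raise FormatError(f"{what}: {path} has no header line")
    seen: set[str] = set()
    for col in header:
        if col in seen:
            raise FormatError(f"{what}: duplicate sample id {col!r} in {path}")
        seen.add(col)
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0, dtype=str)
    out = {}
    for col in df.columns:
        raw = df[col]
        num = pd.to_numeric(raw.where(~raw.isin(_NA_TOKENS)), errors="coerce")
        bad = num.isna() & raw.notna() & ~raw.isin(_NA_TOKENS)
        if bad.any():
            row = df.index[bad][0]
            raise FormatError(
                f"{what}: non-numeric value {raw[bad].iloc[0]!r} at row {row!r}, "
                f"column {col!r} in {path}"
            )
        out[col] = num
    result = pd.DataFrame(out, index=df.index)
    result.index.name = None
    return result


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def read_expression(
    path: str | Path,
    log_scale: bool = True,
    groups_path: str | Path | None = None,
) -> ExpressionMatrix:
    """Read a gene x sample expression TSV.

    The first column holds gene identifiers; the header row holds sample
    identifiers.  Duplicate gene rows are collapsed by their arithmetic mean
    (count logged).  ``groups_path`` optionally names a two-column TSV
    (sample, group) with group in {normal, tumor}.
    """
    df = _read_numeric_tsv(path, "expression")
    if df.index.duplicated().any():
        n_dup = int(df.index.duplicated().sum())
        logger.info("collapsing %d duplicate gene row(s) by mean in %s", n_dup, path)
        order = df.index.drop_duplicates()
        df = df.groupby(level=0, sort=False).mean().loc[order]
    labels = None
    if groups_path is not None:
        labels = read_group_labels(groups_path)
    return ExpressionMatrix(df, log_scale=log_scale, group_labels=labels)


def read_group_labels(path: str | Path) -> pd.Series:
    g = pd.read_csv(path, sep="\t", comment="#", header=None, names=["sample", "group"], dtype=str)
    if g["sample"].duplicated().any():
        raise FormatError(f"duplicate sample id in group file {path}")
    return pd.Series(g["group"].values, index=g["sample"].values, name="group")


def read_methylation(beta_path: str | Path, manifest_path: str | Path) -> MethylationDataset:
    """Read a probe x sample beta TSV and a probe manifest TSV.

    Manifest columns: probe, gene, region, chromosome.  Probes absent from
    the manifest are dropped (count logged); beta values outside [0, 1] error.
    """
    beta = _read_numeric_tsv(beta_path, "methylation")
    man = pd.read_csv(manifest_path, sep="\t", comment="#", dtype=str)
    required = {"probe", "gene", "region", "chromosome"}
    if not required.issubset(man.columns):
        raise FormatError(
            f"manifest {manifest_path} must have columns {sorted(required)}; "
            f"got {list(man.columns)}"
        )
    if man["probe"].duplicated().any():
        raise FormatError(f"duplicate probe in manifest {manifest_path}")
    man = man.set_index("probe")[["gene", "region", "chromosome"]]
    unknown = beta.index.difference(man.index)
    if len(unknown):
        logger.info("dropping %d probe(s) absent from manifest", len(unknown))
        beta = beta.drop(index=unknown)
    return MethylationDataset(beta=beta, manifest=man)


def read_clinical(path: str | Path) -> ClinicalTable:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={0: str})
    cols = {c.lower(): c for c in df.columns}
    try:
        df = df.rename(
            columns={cols["sample"]: "sample", cols["time"]: "time", cols["event"]: "event"}
        )
    except KeyError as exc:
        raise FormatError(f"clinical table {path} needs columns sample/time/event") from exc
    df = df.set_index("sample")[["time", "event"]].astype({"time": float, "event": int})
    return ClinicalTable(df)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: name <tab> description <tab> member genes..."""
    sets: list[GeneSet] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line needs name, description, >=1 gene")
            sets.append(GeneSet(parts[0], parts[1], tuple(g for g in parts[2:] if g)))
    return GeneSetCollection(sets)


def read_ppi(path: str | Path, min_score: float = 600.0) -> PPIGraph:
    """Read an edge-list TSV (geneA, geneB, score), keeping edges with score >= min_score.

    A two-column file (no score) keeps every edge.  Orientation is ignored and
    duplicate edges collapse to one undirected edge; self-loops are dropped.
    """
    g = nx.Graph()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise FormatError(f"{path}:{lineno}: edge line needs at least two columns")
            a, b = parts[0], parts[1]
            score = None
            if len(parts) >= 3 and parts[2] not in _NA_TOKENS:
                try:
                    score = float(parts[2])
                except ValueError as exc:
                    raise FormatError(f"{path}:{lineno}: non-numeric score {parts[2]!r}") from exc
                if score < min_score:
                    continue
            if a == b:
                continue
            if score is None:
                g.add_edge(a, b)
            else:
                g.add_edge(a, b, score=score)
    return PPIGraph(g)


def read_drug_targets(path: str | Path) -> DrugTargetTable:
    """Read a long-format drug-target TSV with columns (drug, target)."""
    targets: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2 or not parts[0] or not parts[1]:
                raise FormatError(f"{path}:{lineno}: drug-target line needs (drug, target)")
            if parts[0] == "drug" and lineno == 1:  # optional header
                continue
            targets.setdefault(parts[0], set()).add(parts[1])
    return DrugTargetTable({d: frozenset(t) for d, t in targets.items()})


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    df = expr.values.copy()
    df.index.name = "gene"
    df.to_csv(path, sep="\t", na_rep="NA")


def write_group_labels(labels: pd.Series, path: str | Path) -> None:
    labels.to_csv(path, sep="\t", header=False)


def write_methylation(meth: MethylationDataset, beta_path: str | Path, manifest_path: str | Path) -> None:
    beta = meth.beta.copy()
    beta.index.name = "probe"
    beta.to_csv(beta_path, sep="\t", na_rep="NA")
    man = meth.manifest.copy()
    man.index.name = "probe"
    man.to_csv(manifest_path, sep="\t")


def write_clinical(clin: ClinicalTable, path: str | Path) -> None:
    df = clin.data.copy()
    df.index.name = "sample"
    df.to_csv(path, sep="\t")


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for s in collection:
            fh.write("\t".join([s.name, s.description, *s.genes]) + "\n")


def write_ppi(ppi: PPIGraph, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for a, b, data in sorted(ppi.graph.edges(data=True)):
            score = data.get("score")
            if score is None:
                fh.write(f"{a}\t{b}\n")
            else:
                fh.write(f"{a}\t{b}\t{score}\n")


def write_drug_targets(table: DrugTargetTable, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("drug\ttarget\n")
        for drug in sorted(table.targets):
            for target in sorted(table.targets[drug]):
                fh.write(f"{drug}\t{target}\n")
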