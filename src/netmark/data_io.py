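"""Readers and writers for expression matrices, labels, annotations,
interaction networks and subnetwork sets.

All formats are plain UTF-8, tab-delimited text.  The expression dialect is a
TSV with one header row of sample ids and gene/probe ids in the first column;
GEO series-matrix banner lines (prefixed with ``!``) are skipped so exported
series matrices can be fed in directly.  Networks are accepted either as
two-column edge lists or as SIF (``id<TAB>relation<TAB>id [id ...]``).
Subnetwork sets are written both as GMT (one gene set per line) and as a JSON
document that round-trips every record field losslessly.
"""

from __future__ import annotations

import functools
import json
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

from .errors import (
    EmptyResultError,
    FormatError,
    LabeledDataError,
    ParseError,
)

logger = logging.getLogger(__name__)

CASE = "case"
CONTROL = "control"


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ExpressionDataset:
    """A genes x samples real matrix with a two-class sample labelling.

    Values are assumed to be on an already-normalized continuous scale
    (e.g. quantile-normalized microarray intensities); nothing in the
    pipeline re-normalizes between samples unless explicitly requested.
    """

    gene_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    values: np.ndarray  # shape (n_genes, n_samples), float64
    labels: Mapping[str, str]  # sample_id -> CASE | CONTROL

    def __post_init__(self) -> None:
        object.__setattr__(self, "gene_ids", tuple(self.gene_ids))
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "labels", dict(self.labels))
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise FormatError("duplicate gene ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise FormatError("duplicate sample ids")
        if values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise FormatError(
                f"matrix shape {values.shape} does not match "
                f"({len(self.gene_ids)}, {len(self.sample_ids)})"
            )
        if values.size and not np.all(np.isfinite(values)):
            raise FormatError("expression matrix contains NaN or infinite values")
        missing = [s for s in self.sample_ids if s not in self.labels]
        if missing:
            raise LabeledDataError(f"samples without a label: {missing[:5]}")
        bad = {c for c in self.labels.values()} - {CASE, CONTROL}
        if bad:
            raise LabeledDataError(
                f"labels must be '{CASE}' or '{CONTROL}', got {sorted(bad)}"
            )
        classes = {self.labels[s] for s in self.sample_ids}
        if classes != {CASE, CONTROL}:
            raise LabeledDataError("both classes must be non-empty")

    # -- convenience accessors -------------------------------------------

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def case_ids(self) -> tuple[str, ...]:
        return tuple(s for s in self.sample_ids if self.labels[s] == CASE)

    @property
    def control_ids(self) -> tuple[str, ...]:
        return tuple(s for s in self.sample_ids if self.labels[s] == CONTROL)

    def class_indicator(self) -> np.ndarray:
        """0/1 vector over samples, 1 for the case class."""
        return np.array(
            [1 if self.labels[s] == CASE else 0 for s in self.sample_ids],
            dtype=np.intp,
        )

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_ids)}

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionDataset":
        idx = {s: j for j, s in enumerate(self.sample_ids)}
        cols = [idx[s] for s in sample_ids]
        return ExpressionDataset(
            gene_ids=self.gene_ids,
            sample_ids=tuple(sample_ids),
            values=self.values[:, cols],
            labels={s: self.labels[s] for s in sample_ids},
        )

    def subset_genes(self, gene_ids: Sequence[str]) -> "ExpressionDataset":
        idx = self.gene_index()
        rows = [idx[g] for g in gene_ids]
        return ExpressionDataset(
            gene_ids=tuple(gene_ids),
            sample_ids=self.sample_ids,
            values=self.values[rows, :],
            labels=self.labels,
        )


@dataclass(frozen=True)
class AnnotationTable:
    """Probe -> gene mapping; many probes may map to one gene."""

    probe_to_gene: Mapping[str, str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "probe_to_gene", dict(self.probe_to_gene))
        for probe, gene in self.probe_to_gene.items():
            if not gene:
                raise FormatError(f"empty gene id for probe {probe!r}")


@dataclass(frozen=True)
class InteractionNetwork:
    """Undirected simple graph over gene identifiers (the search space)."""

    graph: nx.Graph

    def __post_init__(self) -> None:
        if any(u == v for u, v in self.graph.edges()):
            raise FormatError("network contains self-loops")

    @functools.cached_property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes())

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_set(self) -> set[frozenset[str]]:
        return {frozenset((u, v)) for u, v in self.graph.edges()}

    def neighbors(self, node: str) -> list[str]:
        return sorted(self.graph.neighbors(node))

    def is_connected_subset(self, members: Iterable[str]) -> bool:
        members = set(members)
        if not members:
            return False
        if not members <= self.nodes:
            return False
        sub = self.graph.subgraph(members)
        return nx.is_connected(sub)


@dataclass(frozen=True)
class Subnetwork:
    """A connected gene set scored as one candidate marker.

    ``score`` is the mutual information (bits) between the subnetwork's
    activity and the class labels.  The three p-values are filled in by the
    permutation filter; before filtering they are ``None``.
    """

    seed: str
    members: frozenset[str]
    score: float
    p_gene_null: float | None = None
    p_label_null: float | None = None
    p_random_null: float | None = None
    frequency: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "members", frozenset(self.members))
        if self.seed not in self.members:
            raise FormatError(f"seed {self.seed!r} not among members")
        if not math.isfinite(self.score):
            raise FormatError("subnetwork score must be finite")

    @property
    def size(self) -> int:
        return len(self.members)

    def sorted_members(self) -> tuple[str, ...]:
        return tuple(sorted(self.members))


@dataclass
class SubnetworkSet:
    """A list of subnetwork records plus provenance metadata."""

    subnetworks: list[Subnetwork]
    metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.subnetworks)

    def member_sets(self) -> list[frozenset[str]]:
        return [s.members for s in self.subnetworks]


# ---------------------------------------------------------------------------
# Expression / label IO
# ---------------------------------------------------------------------------


def _data_lines(path: str | Path) -> list[tuple[int, str]]:
    """Non-empty, non-banner lines with 1-based line numbers."""
    out = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            if line.startswith("!"):  # GEO series-matrix banner
                continue
            out.append((lineno, line))
    return out


def read_labels(path: str | Path) -> dict[str, str]:
    """Read a two-column (sample_id, class) TSV; classes must be case/control."""
    lines = _data_lines(path)
    if not lines:
        raise FormatError(f"empty label file: {path}")
    labels: dict[str, str] = {}
    for lineno, line in lines:
        fields = line.split("\t")
        if len(fields) != 2:
            raise ParseError(f"{path}: line {lineno}: expected 2 columns, got {len(fields)}")
        sample, cls = fields[0].strip(), fields[1].strip()
        if (sample, cls) in (("sample_id", "class"), ("sample", "label")):
            continue  # optional header
        if sample in labels:
            raise FormatError(f"{path}: duplicate sample id {sample!r}")
        if cls not in (CASE, CONTROL):
            raise LabeledDataError(
                f"{path}: line {lineno}: class must be '{CASE}' or '{CONTROL}', got {cls!r}"
            )
        labels[sample] = cls
    return labels


def read_expression(path: str | Path, label_path: str | Path) -> ExpressionDataset:
    """Read an expression TSV (header row of sample ids, first column row ids)
    together with its sample-label table."""
    lines = _data_lines(path)
    if not lines:
        raise FormatError(f"empty expression file: {path}")
    _, header = lines[0]
    cols = header.split("\t")
    sample_ids = [c.strip() for c in cols[1:]]
    if len(set(sample_ids)) != len(sample_ids):
        dupes = sorted({s for s in sample_ids if sample_ids.count(s) > 1})
        raise FormatError(f"{path}: duplicate sample ids {dupes}")
    gene_ids: list[str] = []
    rows: list[list[float]] = []
    for lineno, line in lines[1:]:
        fields = line.split("\t")
        if len(fields) != len(sample_ids) + 1:
            raise ParseError(
                f"{path}: line {lineno}: expected {len(sample_ids) + 1} columns, "
                f"got {len(fields)}"
            )
        gene = fields[0].strip()
        row = []
        for j, cell in enumerate(fields[1:]):
            try:
                val = float(cell)
            except ValueError:
                raise ParseError(
                    f"{path}: non-numeric value {cell!r} at row {gene!r}, "
                    f"column {sample_ids[j]!r} (line {lineno})"
                ) from None
            if not math.isfinite(val):
                raise FormatError(
                    f"{path}: non-finite value at row {gene!r}, column {sample_ids[j]!r}"
                )
            row.append(val)
        gene_ids.append(gene)
        rows.append(row)
    if len(set(gene_ids)) != len(gene_ids):
        dupes = sorted({g for g in gene_ids if gene_ids.count(g) > 1})
        raise FormatError(f"{path}: duplicate row ids {dupes}")
    labels = read_labels(label_path)
    missing = [s for s in sample_ids if s not in labels]
    if missing:
        raise LabeledDataError(f"no label for samples {missing[:5]} (and possibly more)")
    return ExpressionDataset(
        gene_ids=tuple(gene_ids),
        sample_ids=tuple(sample_ids),
        values=np.array(rows, dtype=float) if rows else np.empty((0, len(sample_ids))),
        labels={s: labels[s] for s in sample_ids},
    )


def write_expression(ds: ExpressionDataset, path: str | Path, label_path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("id\t" + "\t".join(ds.sample_ids) + "\n")
        for g, row in zip(ds.gene_ids, ds.values):
            fh.write(g + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")
    with open(label_path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("sample_id\tclass\n")
        for s in ds.sample_ids:
            fh.write(f"{s}\t{ds.labels[s]}\n")


def read_annotation(path: str | Path) -> AnnotationTable:
    """Read a (probe_id, gene_id) TSV; a ``probe_id<TAB>gene_id`` header is optional.

    Rows with an empty gene id are dropped (unannotated probes).
    """
    lines = _data_lines(path)
    if not lines:
        raise FormatError(f"empty annotation file: {path}")
    mapping: dict[str, str] = {}
    n_dropped = 0
    for lineno, line in lines:
        fields = line.split("\t")
        if len(fields) < 2:
            raise ParseError(f"{path}: line {lineno}: expected 2 columns")
        probe, gene = fields[0].strip(), fields[1].strip()
        if (probe, gene) == ("probe_id", "gene_id"):
            continue
        if not gene:
            n_dropped += 1
            continue
        if probe in mapping:
            raise FormatError(f"{path}: duplicate probe id {probe!r}")
        mapping[probe] = gene
    if n_dropped:
        logger.info("annotation: dropped %d unannotated probes", n_dropped)
    return AnnotationTable(probe_to_gene=mapping)


def collapse_probes(
    ds: ExpressionDataset,
    ann: AnnotationTable,
    *,
    return_report: bool = False,
):
    """Collapse probe-level rows to gene-level rows.

    Rows for probes mapping to the same gene id are replaced by their
    arithmetic column-wise mean, on the provided (already normalized) scale.
    Probes without an annotation entry are dropped.  Output gene order is the
    order of first appearance of each gene among the input probes.
    """
    mapped: dict[str, list[int]] = {}
    order: list[str] = []
    n_dropped = 0
    for i, probe in enumerate(ds.gene_ids):
        gene = ann.probe_to_gene.get(probe)
        if gene is None:
            n_dropped += 1
            continue
        if gene not in mapped:
            mapped[gene] = []
            order.append(gene)
        mapped[gene].append(i)
    if not mapped:
        raise EmptyResultError("no probe in the dataset has an annotation entry")
    values = np.vstack([ds.values[mapped[g], :].mean(axis=0) for g in order])
    if n_dropped:
        logger.info("collapse_probes: dropped %d unmapped probes", n_dropped)
    out = ExpressionDataset(
        gene_ids=tuple(order),
        sample_ids=ds.sample_ids,
        values=values,
        labels=ds.labels,
    )
    if return_report:
        report = {
            "n_probes": ds.n_genes,
            "n_genes": len(order),
            "n_dropped_unmapped": n_dropped,
        }
        return out, report
    return out


def quantile_normalize(ds: ExpressionDataset) -> ExpressionDataset:
    """Optional classical quantile normalization across samples.

    Each sample (column) is replaced by the mean expression at each rank
    across all samples; ties within a column receive the mean of their tied
    quantiles.  Inputs to the pipeline are assumed pre-normalized, so this is
    OFF by default everywhere and provided only as a utility.
    """
    from scipy.stats import rankdata

    X = ds.values
    sorted_cols = np.sort(X, axis=0)
    ref = sorted_cols.mean(axis=1)  # mean value at each rank
    out = np.empty_like(X)
    for j in range(X.shape[1]):
        ranks = rankdata(X[:, j], method="average")  # 1-based, ties averaged
        out[:, j] = np.interp(ranks, np.arange(1, X.shape[0] + 1), ref)
    return replace(ds, values=out)


# ---------------------------------------------------------------------------
# Network IO
# ---------------------------------------------------------------------------


def read_network(path: str | Path) -> InteractionNetwork:
    """Read an undirected simple graph from an edge-list TSV or a SIF file.

    Lines with two whitespace/tab-separated tokens are treated as edges; lines
    with three or more as SIF records (``source relation target [target ...]``).
    Duplicate and reversed-duplicate edges are collapsed; self-loops are
    dropped with a logged count.
    """
    lines = _data_lines(path)
    if not lines:
        raise FormatError(f"empty network file: {path}")
    g = nx.Graph()
    n_self = 0
    for lineno, line in lines:
        fields = line.split("\t") if "\t" in line else line.split()
        fields = [f.strip() for f in fields if f.strip()]
        if len(fields) == 1:
            raise ParseError(f"{path}: line {lineno}: expected at least 2 columns")
        if len(fields) == 2:
            pairs = [(fields[0], fields[1])]
        else:  # SIF: source relation target [target...]
            src = fields[0]
            pairs = [(src, tgt) for tgt in fields[2:]]
        for u, v in pairs:
            if u == v:
                n_self += 1
                g.add_node(u)
                continue
            g.add_edge(u, v)
    if n_self:
        logger.info("read_network: dropped %d self-loops", n_self)
    return InteractionNetwork(graph=g)


def write_network(net: InteractionNetwork, path: str | Path) -> None:
    """Write a two-column edge-list TSV.

    Isolated nodes are emitted as ``n<TAB>n`` self-loop lines, which the
    reader strips back to a bare node, so re-serialization is lossless.
    """
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for u, v in sorted(tuple(sorted(e)) for e in net.graph.edges()):
            fh.write(f"{u}\t{v}\n")
        for n in sorted(n for n in net.graph.nodes() if net.graph.degree(n) == 0):
            fh.write(f"{n}\t{n}\n")


# ---------------------------------------------------------------------------
# Subnetwork set IO
# ---------------------------------------------------------------------------


def write_subnetworks(
    sset: SubnetworkSet, path_gmt: str | Path, path_json: str | Path
) -> None:
    """Write GMT (one line per subnetwork) and a lossless JSON document."""
    if not sset.subnetworks:
        logger.warning("write_subnetworks: empty subnetwork set")
    with open(path_gmt, "w", encoding="utf-8", newline="\n") as fh:
        for i, sub in enumerate(sset.subnetworks, start=1):
            name = f"sub{i:03d}_{sub.seed}"
            fields = [name, f"score={sub.score:.6g}"] + list(sub.sorted_members())
            fh.write("\t".join(fields) + "\n")
    doc = {
        "format": "netmark-subnetworks",
        "version": 1,
        "metadata": sset.metadata,
        "subnetworks": [
            {
                "seed": sub.seed,
                "members": list(sub.sorted_members()),
                "score": sub.score,
                "p_gene_null": sub.p_gene_null,
                "p_label_null": sub.p_label_null,
                "p_random_null": sub.p_random_null,
                "frequency": sub.frequency,
            }
            for sub in sset.subnetworks
        ],
    }
    with open(path_json, "w", encoding="utf-8", newline="\n") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_subnetworks(path_json: str | Path) -> SubnetworkSet:
    with open(path_json, "r", encoding="utf-8") as fh:
        doc = json.load(fh)
    if doc.get("format") != "netmark-subnetworks":
        raise FormatError(f"{path_json}: not a netmark subnetwork JSON document")
    subs = [
        Subnetwork(
            seed=rec["seed"],
            members=frozenset(rec["members"]),
            score=rec["score"],
            p_gene_null=rec.get("p_gene_null"),
            p_label_null=rec.get("p_label_null"),
            p_random_null=rec.get("p_random_null"),
            frequency=rec.get("frequency", 0),
        )
        for rec in doc["subnetworks"]
    ]
    return SubnetworkSet(subnetworks=subs, metadata=doc.get("metadata", {}))
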