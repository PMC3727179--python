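"""Expression-based comparator: per-gene t-tests, top-k differential genes,
two-way complete-linkage hierarchical clustering on 1 - Pearson correlation,
misclassification counting from a two-cluster cut, and subnetwork / DE-gene
overlap.

The t-test is Welch's (unequal variances) by default; a pooled-variance
variant is available by flag.  No multiple-testing correction is applied —
the DE flag is the raw two-tailed P < 0.05, matching how single-gene marker
lists are conventionally drawn in this comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .data_io import CASE, CONTROL, ExpressionDataset
from .errors import ContractError

logger = logging.getLogger(__name__)

DE_ALPHA = 0.05


# ---------------------------------------------------------------------------
# Differential expression
# ---------------------------------------------------------------------------


def t_test_rank(ds: ExpressionDataset, equal_var: bool = False) -> pd.DataFrame:
    """Per-gene two-sample two-tailed t-test (Welch by default).

    Returns a DataFrame indexed by gene id with columns ``t``, ``p``,
    ``mean_diff`` (case mean minus control mean), ``de_flag`` (p < 0.05) and
    ``rank`` (1..n by ascending p, ties by descending |t| then gene id).
    """
    y = ds.class_indicator().astype(bool)
    if y.sum() < 2 or (~y).sum() < 2:
        raise ContractError("each class needs at least 2 samples for a t-test")
    case = ds.values[:, y]
    ctrl = ds.values[:, ~y]
    t, p = stats.ttest_ind(case, ctrl, axis=1, equal_var=equal_var)
    t = np.nan_to_num(t, nan=0.0)
    p = np.nan_to_num(p, nan=1.0)  # zero-variance-in-both-groups genes
    df = pd.DataFrame(
        {
            "t": t,
            "p": p,
            "mean_diff": case.mean(axis=1) - ctrl.mean(axis=1),
            "de_flag": p < DE_ALPHA,
        },
        index=pd.Index(ds.gene_ids, name="gene_id"),
    )
    order = sorted(
        range(len(df)), key=lambda i: (p[i], -abs(t[i]), ds.gene_ids[i])
    )
    ranks = np.empty(len(df), dtype=int)
    ranks[order] = np.arange(1, len(df) + 1)
    df["rank"] = ranks
    return df


def top_k(de: pd.DataFrame, k: int) -> list[str]:
    """The k most differential genes (smallest p, rank order)."""
    if k > len(de):
        raise ContractError(f"k={k} exceeds the {len(de)} tested genes")
    if k < 0:
        raise ContractError("k must be >= 0")
    return list(de.sort_values("rank").index[:k])


# ---------------------------------------------------------------------------
# Hierarchical clustering
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Dendrogram:
    """Complete-linkage merge history over named leaves."""

    ids: tuple[str, ...]  # leaf ids in input order (linkage indexing)
    linkage: np.ndarray  # scipy (n-1) x 4 linkage matrix

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    @property
    def leaf_order(self) -> tuple[str, ...]:
        return tuple(self.ids[i] for i in hierarchy.leaves_list(self.linkage))

    def cut(self, n_clusters: int) -> dict[str, int]:
        flat = hierarchy.fcluster(self.linkage, t=n_clusters, criterion="maxclust")
        return {leaf: int(c) for leaf, c in zip(self.ids, flat)}

    def to_newick(self) -> str:
        """Serialize as a rooted Newick string with merge heights as branch lengths."""
        n = len(self.ids)
        heights = {i: 0.0 for i in range(n)}

        def render(node: int) -> str:
            if node < n:
                return self.ids[node]
            row = self.linkage[node - n]
            left, right, h = int(row[0]), int(row[1]), float(row[2])
            parts = []
            for child in (left, right):
                child_h = heights[child]
                parts.append(f"{render(child)}:{max(h - child_h, 0.0):.6g}")
            heights[node] = h
            return "(" + ",".join(parts) + ")"

        for i in range(n, 2 * n - 1):  # fill internal heights bottom-up
            row = self.linkage[i - n]
            heights[i] = float(row[2])
        return render(2 * n - 2) + ";"


def _pearson_distance_matrix(rows: np.ndarray, what: str) -> np.ndarray:
    sds = rows.std(axis=1)
    if np.any(sds == 0):
        bad = int(np.argmax(sds == 0))
        raise ContractError(
            f"zero-variance {what} at position {bad}: Pearson distance undefined"
        )
    corr = np.corrcoef(rows)
    d = 1.0 - corr
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, 2.0)  # symmetrize away float jitter
    return d


def hcluster(
    ds: ExpressionDataset, genes: Sequence[str]
) -> tuple[Dendrogram, Dendrogram]:
    """Two-way complete-linkage clustering on 1 - Pearson correlation.

    Genes are clustered by their profiles across all samples; samples by
    their profiles across the selected genes.  Returns (gene dendrogram,
    sample dendrogram).
    """
    genes = list(genes)
    if len(genes) < 2:
        raise ContractError("need at least 2 genes to cluster")
    if ds.n_samples < 2:
        raise ContractError("need at least 2 samples to cluster")
    index = ds.gene_index()
    missing = [g for g in genes if g not in index]
    if missing:
        raise ContractError(f"genes not in dataset: {missing[:5]}")
    sub = ds.values[[index[g] for g in genes], :]

    sds = sub.std(axis=1)
    if np.any(sds == 0):
        bad = genes[int(np.argmax(sds == 0))]
        raise ContractError(f"zero-variance gene {bad!r}: Pearson distance undefined")
    gene_d = _pearson_distance_matrix(sub, "gene")
    gene_link = hierarchy.linkage(squareform(gene_d, checks=False), method="complete")

    col_sds = sub.std(axis=0)
    if np.any(col_sds == 0):
        bad = ds.sample_ids[int(np.argmax(col_sds == 0))]
        raise ContractError(f"zero-variance sample {bad!r} over selected genes")
    sample_d = _pearson_distance_matrix(sub.T, "sample")
    sample_link = hierarchy.linkage(squareform(sample_d, checks=False), method="complete")

    return (
        Dendrogram(ids=tuple(genes), linkage=gene_link),
        Dendrogram(ids=tuple(ds.sample_ids), linkage=sample_link),
    )


class MisclassifiedCounts(NamedTuple):
    case_errors: int
    control_errors: int


def count_misclassified(
    sample_dend: Dendrogram, labels
) -> MisclassifiedCounts:
    """Cut the sample dendrogram into two clusters at the highest merge,
    assign each cluster its majority label (ties go to 'case' for the cluster
    with more cases), and count the per-class minority members.

    This formalizes reading misclassified samples off a clustered heat map.
    """
    labels = dict(labels)
    classes = set(labels.values())
    if classes != {CASE, CONTROL}:
        raise ContractError("labels must contain both classes")
    assign = sample_dend.cut(2)
    clusters: dict[int, list[str]] = {}
    for leaf, c in assign.items():
        clusters.setdefault(c, []).append(leaf)
    case_errors = 0
    control_errors = 0
    for members in clusters.values():
        n_case = sum(1 for s in members if labels[s] == CASE)
        n_ctrl = len(members) - n_case
        cluster_label = CASE if n_case >= n_ctrl else CONTROL
        if cluster_label == CASE:
            control_errors += n_ctrl
        else:
            case_errors += n_case
    return MisclassifiedCounts(case_errors, control_errors)


class OverlapReport(NamedTuple):
    common: frozenset
    n_left: int
    n_right: int


def overlap(subnet_genes, top_genes) -> OverlapReport:
    """Intersection of a subnetwork gene set with a top-DE gene list."""
    left = set(subnet_genes)
    right = set(top_genes)
    return OverlapReport(frozenset(left & right), len(left), len(right))


def plot_heatmap(ds: ExpressionDataset, genes: Sequence[str], path) -> None:
    """Basic clustered expression heat map (rows = genes, columns = samples)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    gene_dend, sample_dend = hcluster(ds, genes)
    index = ds.gene_index()
    row_order = [index[g] for g in gene_dend.leaf_order]
    col_index = {s: j for j, s in enumerate(ds.sample_ids)}
    col_order = [col_index[s] for s in sample_dend.leaf_order]
    mat = ds.values[np.ix_(row_order, col_order)]
    fig, ax = plt.subplots(figsize=(8, 6))
    im = ax.imshow(mat, aspect="auto", cmap="RdYlGn_r")
    ax.set_xlabel("samples (clustered)")
    ax.set_ylabel("genes (clustered)")
    fig.colorbar(im, ax=ax, label="expression")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
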