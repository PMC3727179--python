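"""Greedy subnetwork search with mutual-information scoring and
permutation-test significance filtering.

The integration algorithm superimposes z-scored expression on the
interactome.  The activity of a gene set is the per-sample mean of its
members' z-scores (by default oriented so every member's class association
points the same way; see SearchConfig).  Its discriminative score is the
plug-in mutual information (bits) between the discretized activity and the two-class
phenotype, with equal-width bins over the observed activity range and a
Sturges bin count by default.  One greedy search is started from every gene
present in both the network and the dataset; candidates adjacent to the
current member set and within a bounded distance of the seed are added while
the relative score gain stays above a threshold.  Candidates are then
filtered by three one-sided permutation tests (gene-assignment null, class
label null, random connected-subnetwork null); a candidate is significant
only if all three p-values fall at or below alpha.

All tie-breaking is lexicographic on gene ids and every random draw is
seeded, so results are bit-identical across platforms and run orders.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
import zlib
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np

from .data_io import ExpressionDataset, InteractionNetwork, Subnetwork, SubnetworkSet
from .errors import ConfigError, ContractError, IntegrationError

logger = logging.getLogger(__name__)

_GENE_NULL_STREAM = 11
_LABEL_NULL_STREAM = 12
_RANDOM_NULL_STREAM = 13


@dataclass(frozen=True)
class SearchConfig:
    """Knobs of the search and the permutation filter.

    ``n_bins="auto"`` resolves to the Sturges count floor(log2(n_samples)) + 1.

    ``activity_mode`` selects the member aggregation used for *scoring*:

    - ``"oriented_mean"`` (default): each member's z-profile is flipped, if
      necessary, so that its class-mean difference is non-negative, then the
      profiles are averaged.  Real disease modules mix up- and down-regulated
      members, whose raw z-scores cancel in a plain mean; orienting by the
      observed association direction makes such modules scoreable while
      leaving single-gene scores unchanged (MI is invariant to a sign flip).
      The orientation is recomputed from whatever labelling is being scored,
      so permutation nulls stay process-matched.
    - ``"mean"``: plain arithmetic mean of member z-scores.
    - ``"sqrt_sum"``: sum of z-scores divided by sqrt(set size).

    ``label_null_mode`` controls how the class-label permutation null is
    built.  ``"search"`` (default) re-runs the greedy search from each seed
    under every label permutation, so the null scores undergo the same
    greedy maximization as the observed score — this is what keeps the
    filter's type-I error at the nominal level.  ``"score"`` merely
    re-scores the fixed member set under permuted labels; it is much
    cheaper but strongly anti-conservative, since a greedily maximized
    score is compared against un-maximized nulls.
    """

    max_distance_from_seed: int = 2
    min_improvement_rate: float = 0.05
    max_subnetwork_size: int = 10
    n_bins: int | str = "auto"
    n_permutations: int = 100
    alpha: float = 0.05
    rng_seed: int = 0
    activity_mode: str = "oriented_mean"
    label_null_mode: str = "search"

    def __post_init__(self) -> None:
        if self.max_distance_from_seed < 1:
            raise ConfigError("max_distance_from_seed must be >= 1")
        if self.min_improvement_rate < 0:
            raise ConfigError("min_improvement_rate must be >= 0")
        if self.max_subnetwork_size < 1:
            raise ConfigError("max_subnetwork_size must be >= 1")
        if isinstance(self.n_bins, str):
            if self.n_bins != "auto":
                raise ConfigError("n_bins must be an integer or 'auto'")
        elif self.n_bins < 2:
            raise ConfigError("n_bins must be >= 2")
        if self.n_permutations < 1:
            raise ConfigError("n_permutations must be >= 1")
        if not 0.0 < self.alpha < 1.0:
            raise ConfigError("alpha must be in (0, 1)")
        if self.activity_mode not in ("oriented_mean", "mean", "sqrt_sum"):
            raise ConfigError(f"unknown activity_mode {self.activity_mode!r}")
        if self.label_null_mode not in ("search", "score"):
            raise ConfigError(f"unknown label_null_mode {self.label_null_mode!r}")

    def resolve_n_bins(self, n_samples: int) -> int:
        if self.n_bins == "auto":
            return int(math.floor(math.log2(n_samples))) + 1
        return int(self.n_bins)

    def digest(self) -> str:
        doc = json.dumps(self.__dict__, sort_keys=True, default=str)
        return hashlib.sha256(doc.encode()).hexdigest()[:16]


def sturges_bins(n_samples: int) -> int:
    return int(math.floor(math.log2(n_samples))) + 1


# ---------------------------------------------------------------------------
# z-scoring and activity
# ---------------------------------------------------------------------------


def zscore_stats(values: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-row mean, sample standard deviation (ddof=1), and constant mask."""
    mu = values.mean(axis=1)
    sd = values.std(axis=1, ddof=1) if values.shape[1] > 1 else np.zeros(len(values))
    constant = sd == 0
    return mu, sd, constant


def zscore_normalize(ds: ExpressionDataset) -> ExpressionDataset:
    """Standardize each gene to mean 0 and (sample) standard deviation 1
    across all samples.  Constant genes are set to all-zero and logged."""
    mu, sd, constant = zscore_stats(ds.values)
    safe_sd = np.where(constant, 1.0, sd)
    z = (ds.values - mu[:, None]) / safe_sd[:, None]
    z[constant, :] = 0.0
    if constant.any():
        flagged = [g for g, c in zip(ds.gene_ids, constant) if c]
        logger.warning("zscore_normalize: %d constant genes set to zero: %s",
                       len(flagged), flagged[:5])
    return replace(ds, values=z)


def _orientation_signs(values: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Per-row +-1 sign of the (case mean - control mean) difference; 0 -> +1."""
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        return np.ones(len(values))
    w = y / n1 - (1 - y) / n0
    diff = values @ w
    return np.where(diff < 0, -1.0, 1.0)


def activity(
    ds_z: ExpressionDataset, members: Iterable[str], mode: str = "mean"
) -> np.ndarray:
    """Per-sample activity of a gene set.

    ``"mean"`` (default): arithmetic mean of member z-scores.
    ``"oriented_mean"``: mean of member z-scores after flipping each member
    so its class-mean difference (from ``ds_z.labels``) is non-negative.
    ``"sqrt_sum"``: sum of member z-scores over sqrt(set size).
    """
    members = sorted(set(members))
    if not members:
        raise ContractError("activity of an empty gene set is undefined")
    index = ds_z.gene_index()
    missing = [g for g in members if g not in index]
    if missing:
        raise ContractError(f"genes not in dataset: {missing[:5]}")
    rows = ds_z.values[[index[g] for g in members], :]
    if mode == "mean":
        return rows.mean(axis=0)
    if mode == "oriented_mean":
        signs = _orientation_signs(rows, ds_z.class_indicator().astype(float))
        return (rows * signs[:, None]).mean(axis=0)
    if mode == "sqrt_sum":
        return rows.sum(axis=0) / math.sqrt(len(members))
    raise ConfigError(f"unknown activity mode {mode!r}")


# ---------------------------------------------------------------------------
# Mutual information
# ---------------------------------------------------------------------------


def _as_binary_labels(labels: Sequence) -> np.ndarray:
    y = np.asarray(labels)
    uniq = sorted(set(y.tolist()))
    if len(uniq) != 2:
        raise ContractError(f"exactly two classes required, got {uniq}")
    return (y == uniq[1]).astype(np.intp)


def mutual_information(act: np.ndarray, labels: Sequence, n_bins: int) -> float:
    """Plug-in mutual information (bits) between binned activity and labels.

    The activity is discretized into ``n_bins`` equal-width bins spanning
    [min(act), max(act)]; constant activity yields 0 bits.
    """
    act = np.asarray(act, dtype=float)
    y = _as_binary_labels(labels)
    if len(act) != len(y):
        raise ContractError("activity and labels must have the same length")
    if len(act) < 2:
        raise ContractError("need at least two samples")
    if n_bins < 2:
        raise ConfigError("n_bins must be >= 2")
    return float(_mi_rows(act[None, :], y, n_bins)[0])


def _bin_indices(acts: np.ndarray, n_bins: int) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise equal-width bin indices; second return flags constant rows."""
    lo = acts.min(axis=1, keepdims=True)
    hi = acts.max(axis=1, keepdims=True)
    span = hi - lo
    constant = span[:, 0] <= 0
    safe = np.where(span <= 0, 1.0, span)
    idx = ((acts - lo) * (n_bins / safe)).astype(np.intp)
    np.clip(idx, 0, n_bins - 1, out=idx)
    return idx, constant


def _mi_from_joint(joint: np.ndarray) -> np.ndarray:
    """MI in bits from joint count arrays of shape (m, n_bins, 2)."""
    n = joint.sum(axis=(1, 2), keepdims=True).astype(float)
    p = joint / n
    pb = p.sum(axis=2, keepdims=True)  # bin marginal
    pc = p.sum(axis=1, keepdims=True)  # class marginal
    with np.errstate(divide="ignore", invalid="ignore"):
        term = p * (np.log2(p) - np.log2(pb) - np.log2(pc))
    term = np.where(p > 0, term, 0.0)
    mi = term.sum(axis=(1, 2))
    return np.maximum(mi, 0.0)


def _mi_rows_numpy(acts: np.ndarray, y: np.ndarray, n_bins: int) -> np.ndarray:
    """Vectorized plug-in MI (bits) of each activity row against labels y."""
    m, n = acts.shape
    idx, constant = _bin_indices(acts, n_bins)
    comb = idx * 2 + y[None, :]
    comb += (np.arange(m, dtype=np.intp) * (2 * n_bins))[:, None]
    counts = np.bincount(comb.ravel(), minlength=m * 2 * n_bins)
    joint = counts.reshape(m, n_bins, 2)
    mi = _mi_from_joint(joint)
    mi[constant] = 0.0
    return mi


try:  # compiled kernel: the search evaluates MI millions of times
    from numba import njit as _njit

    @_njit(cache=False, fastmath=False)
    def _mi_rows_kernel(acts, y, n_bins):  # pragma: no cover - compiled
        m, n = acts.shape
        out = np.empty(m)
        joint = np.empty((n_bins, 2))
        n1 = 0
        for j in range(n):
            n1 += y[j]
        pc1 = n1 / n
        pc0 = 1.0 - pc1
        inv_log2 = 1.0 / np.log(2.0)
        for i in range(m):
            lo = acts[i, 0]
            hi = acts[i, 0]
            for j in range(1, n):
                v = acts[i, j]
                if v < lo:
                    lo = v
                if v > hi:
                    hi = v
            span = hi - lo
            if span <= 0.0:
                out[i] = 0.0
                continue
            for b in range(n_bins):
                joint[b, 0] = 0.0
                joint[b, 1] = 0.0
            scale = n_bins / span
            for j in range(n):
                b = int((acts[i, j] - lo) * scale)
                if b >= n_bins:
                    b = n_bins - 1
                joint[b, y[j]] += 1.0
            mi = 0.0
            for b in range(n_bins):
                pb = (joint[b, 0] + joint[b, 1]) / n
                if pb <= 0.0:
                    continue
                p0 = joint[b, 0] / n
                p1 = joint[b, 1] / n
                if p0 > 0.0:
                    mi += p0 * np.log(p0 / (pb * pc0)) * inv_log2
                if p1 > 0.0:
                    mi += p1 * np.log(p1 / (pb * pc1)) * inv_log2
            out[i] = mi if mi > 0.0 else 0.0
        return out

    def _mi_rows(acts: np.ndarray, y: np.ndarray, n_bins: int) -> np.ndarray:
        acts = np.ascontiguousarray(acts, dtype=np.float64)
        return _mi_rows_kernel(acts, y.astype(np.int64), n_bins)

except ImportError:  # pragma: no cover - numba always present in practice
    _mi_rows = _mi_rows_numpy


def _mi_label_perms(act: np.ndarray, ymat: np.ndarray, n_bins: int) -> np.ndarray:
    """MI of one fixed activity against many permuted label rows."""
    idx, constant = _bin_indices(act[None, :], n_bins)
    if constant[0]:
        return np.zeros(ymat.shape[0])
    m = ymat.shape[0]
    comb = idx[0][None, :] * 2 + ymat
    comb = comb + (np.arange(m, dtype=np.intp) * (2 * n_bins))[:, None]
    counts = np.bincount(comb.ravel(), minlength=m * 2 * n_bins)
    joint = counts.reshape(m, n_bins, 2)
    return _mi_from_joint(joint)


class _Scorer:
    """Cached (oriented) z-score matrix + labels for fast repeated MI
    evaluation.  ``set_labels`` re-derives the orientation from the supplied
    labelling so permutation nulls score with signs matched to their own
    permuted labels, exactly as the observed score does with the real ones."""

    def __init__(self, ds_z: ExpressionDataset, n_bins: int, mode: str = "oriented_mean"):
        self.Z = np.ascontiguousarray(ds_z.values)
        self.n_bins = n_bins
        self.mode = mode
        self.index = ds_z.gene_index()
        self.genes = ds_z.gene_ids
        self.set_labels(ds_z.class_indicator())

    def set_labels(self, y: np.ndarray) -> None:
        self.y = y
        if self.mode == "oriented_mean":
            signs = _orientation_signs(self.Z, y.astype(float))
            self.S = np.ascontiguousarray(self.Z * signs[:, None])
        else:
            self.S = self.Z

    def _aggregate(self, sums: np.ndarray, k: int) -> np.ndarray:
        if self.mode == "sqrt_sum":
            return sums / math.sqrt(k)
        return sums / k

    def mi_of_members(self, members: Iterable[str]) -> float:
        rows = [self.index[g] for g in members]
        act = self._aggregate(self.S[rows, :].sum(axis=0), len(rows))
        return float(_mi_rows(act[None, :], self.y, self.n_bins)[0])

    def mi_of_row_sets(self, row_sets: np.ndarray, k: int) -> np.ndarray:
        """MI of many same-size row-index sets, shape (m, k)."""
        acts = self._aggregate(self.S[row_sets, :].sum(axis=1), k)
        return _mi_rows(acts, self.y, self.n_bins)


# ---------------------------------------------------------------------------
# Greedy search
# ---------------------------------------------------------------------------


def greedy_search(
    seed: str,
    ds_z: ExpressionDataset,
    net: InteractionNetwork,
    cfg: SearchConfig,
    _scorer: _Scorer | None = None,
    _ball_cache: dict[str, set[str]] | None = None,
    _seed_mi: float | None = None,
    _step1_cache: dict[str, tuple[list[str], np.ndarray]] | None = None,
    _adj_cache: dict[str, set[str]] | None = None,
) -> Subnetwork:
    """Grow one subnetwork from ``seed`` by greedy mutual-information ascent.

    At each step every measured gene adjacent to the current member set and
    within ``max_distance_from_seed`` of the seed is evaluated; the candidate
    with the largest MI is added (ties to the lexicographically smallest gene
    id).  Growth stops when the best relative gain drops below
    ``min_improvement_rate``, the set reaches ``max_subnetwork_size``, or no
    candidates remain.
    """
    if seed not in net.nodes:
        raise ContractError(f"seed {seed!r} not in network")
    scorer = _scorer or _Scorer(ds_z, cfg.resolve_n_bins(ds_z.n_samples), cfg.activity_mode)
    if seed not in scorer.index:
        raise ContractError(f"seed {seed!r} not measured in dataset")

    # genes reachable within the distance bound, restricted to measured genes
    if _ball_cache is not None and seed in _ball_cache:
        allowed = _ball_cache[seed]
    else:
        allowed = _bounded_ball(net, seed, cfg.max_distance_from_seed)
        allowed &= set(scorer.index)
        if _ball_cache is not None:
            _ball_cache[seed] = allowed

    members = [seed]
    member_set = {seed}
    cur_sum = scorer.S[scorer.index[seed], :].copy()
    if _seed_mi is not None:
        cur_mi = _seed_mi
    else:
        cur_mi = float(_mi_rows(
            scorer._aggregate(cur_sum, 1)[None, :], scorer.y, scorer.n_bins)[0])
    # the first step's candidate list and row indices do not depend on the
    # labels, so repeated null searches can reuse them
    first = _step1_cache.get(seed) if _step1_cache is not None else None
    if first is None:
        cand0 = sorted({g for g in net.graph.neighbors(seed)} & allowed - member_set)
        rows0 = np.array([scorer.index[g] for g in cand0], dtype=np.intp)
        if _step1_cache is not None:
            _step1_cache[seed] = (cand0, rows0)
    else:
        cand0, rows0 = first
    candidates = set(cand0)

    first_step = True
    while len(members) < cfg.max_subnetwork_size and candidates:
        if first_step:
            cand, rows = cand0, rows0
            first_step = False
        else:
            cand = sorted(candidates)
            rows = np.array([scorer.index[g] for g in cand], dtype=np.intp)
        acts = scorer._aggregate(cur_sum[None, :] + scorer.S[rows, :], len(members) + 1)
        mis = _mi_rows(acts, scorer.y, scorer.n_bins)
        best = int(np.argmax(mis))  # first max -> lexicographically smallest
        best_mi = float(mis[best])
        if cur_mi > 0:
            rel_gain = (best_mi - cur_mi) / cur_mi
        else:
            rel_gain = math.inf if best_mi > 0 else 0.0
        if rel_gain < cfg.min_improvement_rate:
            break
        g = cand[best]
        members.append(g)
        member_set.add(g)
        cur_sum += scorer.S[scorer.index[g], :]
        cur_mi = best_mi
        if _adj_cache is not None:
            nbrs = _adj_cache.get(g)
            if nbrs is None:
                nbrs = set(net.graph.neighbors(g))
                _adj_cache[g] = nbrs
        else:
            nbrs = set(net.graph.neighbors(g))
        candidates |= nbrs & allowed
        candidates -= member_set

    return Subnetwork(seed=seed, members=frozenset(members), score=cur_mi)


def _bounded_ball(net: InteractionNetwork, seed: str, radius: int) -> set[str]:
    """Nodes within graph distance ``radius`` of ``seed`` (including it)."""
    dist = {seed: 0}
    frontier = [seed]
    for d in range(1, radius + 1):
        nxt = []
        for u in frontier:
            for v in net.graph.neighbors(u):
                if v not in dist:
                    dist[v] = d
                    nxt.append(v)
        frontier = nxt
        if not frontier:
            break
    return set(dist)


def search_all_seeds(
    ds: ExpressionDataset, net: InteractionNetwork, cfg: SearchConfig
) -> SubnetworkSet:
    """Run one greedy search from every gene present in both the dataset and
    the network; returns one candidate per eligible seed."""
    shared = sorted(set(ds.gene_ids) & net.nodes)
    if not shared:
        raise IntegrationError("dataset and network share no genes")
    ds_z = zscore_normalize(ds)
    scorer = _Scorer(ds_z, cfg.resolve_n_bins(ds.n_samples), cfg.activity_mode)
    balls: dict[str, set[str]] = {}
    subs = [
        greedy_search(seed, ds_z, net, cfg, _scorer=scorer, _ball_cache=balls)
        for seed in shared
    ]
    meta = {
        "n_seeds": len(shared),
        "n_samples": ds.n_samples,
        "config_digest": cfg.digest(),
    }
    return SubnetworkSet(subnetworks=subs, metadata=meta)


# ---------------------------------------------------------------------------
# Permutation filtering
# ---------------------------------------------------------------------------


def _candidate_rng(master: int, stream: int, seed_gene: str) -> np.random.Generator:
    # keyed by the seed gene so results are independent of candidate order
    return np.random.default_rng([master, stream, zlib.crc32(seed_gene.encode())])


def _sample_connected_subgraph(
    adj: dict[str, list[str]],
    start_pool: list[str],
    size: int,
    rng: np.random.Generator,
) -> list[str]:
    """One random connected node set of ``size`` grown from a random start."""
    for _ in range(200):
        start = start_pool[int(rng.integers(len(start_pool)))]
        members = {start}
        frontier = list(adj[start])
        while len(members) < size and frontier:
            pick = frontier.pop(int(rng.integers(len(frontier))))
            if pick in members:
                continue
            members.add(pick)
            frontier.extend(v for v in adj[pick] if v not in members)
        if len(members) == size:
            return sorted(members)
    raise ContractError(f"cannot sample a connected subgraph of size {size}")


def permutation_filter(
    sset: SubnetworkSet,
    ds: ExpressionDataset,
    net: InteractionNetwork,
    cfg: SearchConfig,
) -> SubnetworkSet:
    """Attach three one-sided permutation p-values to each candidate and keep
    those significant under all three.

    Nulls (``n_permutations`` draws each, add-one p-value estimator
    p = (1 + #{null >= observed}) / (1 + n_permutations)):

    1. gene null — the member set's z-score rows are replaced by the same
       number of rows drawn at random from the whole matrix;
    2. label null — class labels are permuted; by default the greedy search
       is re-run from the candidate's seed under each permutation, so the
       null scores are maximized exactly as the observed one (the cheap
       ``label_null_mode="score"`` variant merely re-scores the fixed set);
    3. random-subnetwork null — random connected subgraphs of the same size
       are scored on the unpermuted data.

    In ``"search"`` mode one permutation is shared by all candidates of a
    run: each permuted labelling triggers one search from every candidate
    seed, which keeps the cost at ``n_permutations`` full search passes.
    """
    if 1.0 / (1 + cfg.n_permutations) > cfg.alpha:
        raise ConfigError(
            f"n_permutations={cfg.n_permutations} cannot reach alpha={cfg.alpha}; "
            f"need at least {math.ceil(1 / cfg.alpha) - 1}"
        )
    ds_z = zscore_normalize(ds)
    n_bins = cfg.resolve_n_bins(ds.n_samples)
    scorer = _Scorer(ds_z, n_bins, cfg.activity_mode)
    measured = set(scorer.index)
    adj = {
        u: sorted(set(net.graph.neighbors(u)) & measured)
        for u in sorted(net.nodes & measured)
    }
    n_genes = len(ds.gene_ids)
    n_perm = cfg.n_permutations

    # start pool per size: nodes whose measured component can hold the set
    comp_size: dict[str, int] = {}
    seen: set[str] = set()
    for u in adj:
        if u in seen:
            continue
        comp = _component(adj, u)
        for v in comp:
            comp_size[v] = len(comp)
        seen |= comp

    label_null_scores: dict[str, np.ndarray] | None = None
    if cfg.label_null_mode == "search":
        label_null_scores = _label_null_searched(sset, ds_z, net, cfg)

    retained: list[Subnetwork] = []
    annotated: list[Subnetwork] = []
    for sub in sset.subnetworks:
        k = sub.size
        obs = sub.score

        rng_g = _candidate_rng(cfg.rng_seed, _GENE_NULL_STREAM, sub.seed)
        row_sets = np.argpartition(
            rng_g.random((n_perm, n_genes)), k - 1, axis=1
        )[:, :k]
        null_g = scorer.mi_of_row_sets(row_sets, k)
        p_gene = (1 + int(np.sum(null_g >= obs - 1e-12))) / (1 + n_perm)

        if label_null_scores is not None:
            null_l = label_null_scores[sub.seed]
        else:
            rng_l = _candidate_rng(cfg.rng_seed, _LABEL_NULL_STREAM, sub.seed)
            act = activity(ds_z, sub.members, cfg.activity_mode)
            ymat = np.stack([rng_l.permutation(scorer.y) for _ in range(n_perm)])
            null_l = _mi_label_perms(act, ymat, n_bins)
        p_label = (1 + int(np.sum(null_l >= obs - 1e-12))) / (1 + n_perm)

        rng_r = _candidate_rng(cfg.rng_seed, _RANDOM_NULL_STREAM, sub.seed)
        pool = [u for u in adj if comp_size[u] >= k]
        if pool:
            null_r = np.empty(n_perm)
            for i in range(n_perm):
                members = _sample_connected_subgraph(adj, pool, k, rng_r)
                null_r[i] = scorer.mi_of_members(members)
        else:
            null_r = np.zeros(n_perm)
        p_random = (1 + int(np.sum(null_r >= obs - 1e-12))) / (1 + n_perm)

        out = replace(
            sub, p_gene_null=p_gene, p_label_null=p_label, p_random_null=p_random
        )
        annotated.append(out)
        if max(p_gene, p_label, p_random) <= cfg.alpha:
            retained.append(out)

    meta = dict(sset.metadata)
    meta.update(
        n_candidates=len(sset.subnetworks),
        n_retained=len(retained),
        n_permutations=n_perm,
        alpha=cfg.alpha,
    )
    result = SubnetworkSet(subnetworks=retained, metadata=meta)
    result.metadata["all_p_values"] = [
        {
            "seed": s.seed,
            "p_gene_null": s.p_gene_null,
            "p_label_null": s.p_label_null,
            "p_random_null": s.p_random_null,
        }
        for s in annotated
    ]
    return result


def _component(adj: dict[str, list[str]], start: str) -> set[str]:
    comp = {start}
    stack = [start]
    while stack:
        u = stack.pop()
        for v in adj[u]:
            if v not in comp:
                comp.add(v)
                stack.append(v)
    return comp


def _label_null_searched(
    sset: SubnetworkSet,
    ds_z: ExpressionDataset,
    net: InteractionNetwork,
    cfg: SearchConfig,
) -> dict[str, np.ndarray]:
    """Selection-matched label null: per permutation, re-run the greedy
    search from every candidate seed on the permuted labelling.

    Returns the per-seed null score vectors.  One labelling is shared by all
    seeds of a permutation, so the total cost is ``n_permutations`` search
    passes over the candidate seeds.
    """
    n_bins = cfg.resolve_n_bins(ds_z.n_samples)
    seeds = sorted({sub.seed for sub in sset.subnetworks})
    rng = np.random.default_rng([cfg.rng_seed, _LABEL_NULL_STREAM])
    nulls = {s: np.empty(cfg.n_permutations) for s in seeds}
    scorer = _Scorer(ds_z, n_bins, cfg.activity_mode)
    base_y = scorer.y.copy()
    balls: dict[str, set[str]] = {}
    step1: dict[str, tuple[list[str], np.ndarray]] = {}
    seed_rows = np.array([scorer.index[s] for s in seeds], dtype=np.intp)

    # warm the per-seed caches and flatten every seed's first-step candidate
    # pairs so each permutation needs only two batched MI evaluations; seeds
    # whose best first-step gain clears the threshold fall back to the full
    # greedy search (identical arithmetic, so results match exactly)
    adj: dict[str, set[str]] = {}
    for s in seeds:
        greedy_search(s, ds_z, net, cfg, _scorer=scorer,
                      _ball_cache=balls, _step1_cache=step1, _adj_cache=adj)
    pair_seed: list[int] = []
    pair_cand: list[int] = []
    starts: list[int] = []
    has_cands = np.zeros(len(seeds), dtype=bool)
    for j, s in enumerate(seeds):
        cand, rows = step1[s]
        if len(rows):
            has_cands[j] = True
            starts.append(len(pair_seed))
            pair_seed.extend([scorer.index[s]] * len(rows))
            pair_cand.extend(rows.tolist())
    pair_seed_arr = np.array(pair_seed, dtype=np.intp)
    pair_cand_arr = np.array(pair_cand, dtype=np.intp)
    starts_arr = np.array(starts, dtype=np.intp)

    try:
        for i in range(cfg.n_permutations):
            scorer.set_labels(rng.permutation(base_y))
            seed_acts = scorer._aggregate(scorer.S[seed_rows, :], 1)
            seed_mis = _mi_rows(seed_acts, scorer.y, n_bins)
            if len(pair_seed_arr):
                acts = scorer._aggregate(
                    scorer.S[pair_seed_arr, :] + scorer.S[pair_cand_arr, :], 2
                )
                pair_mis = _mi_rows(acts, scorer.y, n_bins)
                best1 = np.full(len(seeds), -1.0)
                best1[has_cands] = np.maximum.reduceat(pair_mis, starts_arr)
            else:  # pragma: no cover - every seed isolated
                best1 = np.full(len(seeds), -1.0)
            for j, s in enumerate(seeds):
                smi = float(seed_mis[j])
                if not has_cands[j]:
                    nulls[s][i] = smi
                    continue
                b = float(best1[j])
                if smi > 0:
                    grow = (b - smi) / smi >= cfg.min_improvement_rate
                else:
                    grow = b > 0 or cfg.min_improvement_rate <= 0
                if grow:
                    res = greedy_search(
                        s, ds_z, net, cfg, _scorer=scorer,
                        _ball_cache=balls, _seed_mi=smi, _step1_cache=step1,
                        _adj_cache=adj,
                    )
                    nulls[s][i] = res.score
                else:
                    nulls[s][i] = smi
    finally:
        scorer.set_labels(base_y)
    return nulls
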