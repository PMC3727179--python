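"""Patient-half resampling design and frequency-based consensus selection.

Case samples are repeatedly split into two random halves; each half is merged
with the full control set (so class sizes stay comparable) and the search plus
permutation filter is run K times on each merged dataset with independent
filter seeds.  With R resamples this yields 2*R*K runs (the study design used
R=5, K=4, i.e. 40 runs).  Candidate subnetworks are then grouped across runs
by exact member-set equality and ranked by how many runs recovered them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .data_io import ExpressionDataset, InteractionNetwork, Subnetwork, SubnetworkSet
from .errors import ConfigError, ContractError
from .search import SearchConfig, permutation_filter, search_all_seeds

logger = logging.getLogger(__name__)

# a gene belongs to a pooled cluster's reported membership when the variants
# containing it cover at least this fraction of the cluster's run weight;
# 2/3 keeps consistently recovered members and prunes one-off tag-alongs
_MAJORITY_WEIGHT = 2.0 / 3.0


@dataclass(frozen=True)
class SplitPlan:
    """One run of the resampling design: a case half merged with all controls."""

    resample_index: int  # 1..R
    half_index: int  # 1 or 2
    run_index: int  # 1..K
    case_ids: tuple[str, ...]
    control_ids: tuple[str, ...]
    run_seed: int

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return self.case_ids + self.control_ids


@dataclass(frozen=True)
class ConsensusGroup:
    members: frozenset[str]
    frequency: int  # number of runs whose filtered set contains this member set
    mean_score: float
    representative: Subnetwork
    run_indices: frozenset[int] = frozenset()  # which runs contained it


@dataclass
class ConsensusResult:
    groups: list[ConsensusGroup]  # all distinct member sets, ranked
    selected: list[ConsensusGroup]
    total_candidates: int  # number of distinct member sets across runs
    n_runs: int
    selection: dict = field(default_factory=dict)

    def selected_member_sets(self) -> list[frozenset[str]]:
        return [g.members for g in self.selected]


def _derive_run_seed(master_seed: int, r: int, h: int, k: int) -> int:
    ss = np.random.SeedSequence([int(master_seed), 201, r, h, k])
    return int(ss.generate_state(1)[0] % (2**31))


def make_split_plans(
    ds: ExpressionDataset, R: int = 5, K: int = 4, master_seed: int = 0
) -> list[SplitPlan]:
    """Build the 2*R*K run plans.

    Each of the R resamples is an independent random bipartition of the case
    samples into halves of ceil(n/2) and floor(n/2); controls are reused in
    full by every plan.  Everything is deterministic under ``master_seed``.
    """
    if R < 1 or K < 1:
        raise ConfigError("R and K must be >= 1")
    cases = sorted(ds.case_ids)
    controls = tuple(sorted(ds.control_ids))
    if len(cases) < 2:
        raise ContractError("need at least 2 case samples to split")
    plans: list[SplitPlan] = []
    for r in range(1, R + 1):
        rng = np.random.default_rng([int(master_seed), 200, r])
        perm = rng.permutation(len(cases))
        cut = (len(cases) + 1) // 2  # ceil(n/2)
        halves = (
            tuple(sorted(cases[i] for i in perm[:cut])),
            tuple(sorted(cases[i] for i in perm[cut:])),
        )
        for h, half in enumerate(halves, start=1):
            for k in range(1, K + 1):
                plans.append(
                    SplitPlan(
                        resample_index=r,
                        half_index=h,
                        run_index=k,
                        case_ids=half,
                        control_ids=controls,
                        run_seed=_derive_run_seed(master_seed, r, h, k),
                    )
                )
    return plans


def run_all(
    plans: Sequence[SplitPlan],
    ds: ExpressionDataset,
    net: InteractionNetwork,
    cfg: SearchConfig,
) -> list[SubnetworkSet]:
    """Execute search + permutation filter for every plan.

    The greedy search itself is deterministic given the merged dataset, so
    candidate sets are computed once per distinct case half and only the
    (seeded) permutation filter is re-run per plan.
    """
    search_cache: dict[tuple[str, ...], tuple[ExpressionDataset, SubnetworkSet]] = {}
    results: list[SubnetworkSet] = []
    for plan in plans:
        key = plan.case_ids
        if key not in search_cache:
            sub_ds = ds.subset_samples(plan.sample_ids)
            candidates = search_all_seeds(sub_ds, net, cfg)
            search_cache[key] = (sub_ds, candidates)
        sub_ds, candidates = search_cache[key]
        run_cfg = replace(cfg, rng_seed=plan.run_seed)
        filtered = permutation_filter(candidates, sub_ds, net, run_cfg)
        filtered.metadata.update(
            resample_index=plan.resample_index,
            half_index=plan.half_index,
            run_index=plan.run_index,
            run_seed=plan.run_seed,
            n_case=len(plan.case_ids),
            n_control=len(plan.control_ids),
        )
        results.append(filtered)
    return results


def group_and_rank(
    results: Sequence[SubnetworkSet],
    top_k: int | None = None,
    min_frequency: int | None = None,
    jaccard_merge: float | None = 0.6,
) -> ConsensusResult:
    """Group filtered candidates across runs and rank by
    (frequency desc, mean score desc, lexicographic member list).

    Grouping starts from exact member-set equality.  By default,
    near-duplicate groups (Jaccard >= ``jaccard_merge``) are then pooled in
    rank order: the same underlying module recovered with one member swapped
    or tagged on across different patient halves would otherwise split its
    run count and lose to trivially stable small sets.  A pooled cluster is
    reported with the weighted member-wise majority of its variants, the
    union of their runs as frequency, and their weighted mean score.  Pass
    ``jaccard_merge=None`` for strict exact-identity consensus.

    Exactly one of ``top_k`` / ``min_frequency`` selects the reported groups.
    """
    if (top_k is None) == (min_frequency is None):
        raise ConfigError("give exactly one of top_k or min_frequency")
    if not results:
        raise ContractError("need at least one run result")
    if jaccard_merge is not None and not 0.0 < jaccard_merge <= 1.0:
        raise ConfigError("jaccard_merge must be in (0, 1] or None")

    run_ids: dict[frozenset[str], set[int]] = {}
    scores: dict[frozenset[str], list[float]] = {}
    rep: dict[frozenset[str], Subnetwork] = {}
    for i, run in enumerate(results):
        for sub in run.subnetworks:
            key = sub.members
            run_ids.setdefault(key, set()).add(i)
            scores.setdefault(key, []).append(sub.score)
            cur = rep.get(key)
            if (
                cur is None
                or sub.score > cur.score
                or (sub.score == cur.score and sub.seed < cur.seed)
            ):
                rep[key] = sub

    groups = [
        ConsensusGroup(
            members=key,
            frequency=len(run_ids[key]),
            mean_score=float(np.mean(scores[key])),
            representative=replace(rep[key], frequency=len(run_ids[key])),
            run_indices=frozenset(run_ids[key]),
        )
        for key in run_ids
    ]
    groups.sort(key=lambda g: (-g.frequency, -g.mean_score, tuple(sorted(g.members))))

    if jaccard_merge is not None:
        groups = _merge_groups(groups, jaccard_merge)

    if top_k is not None:
        if top_k < 0:
            raise ConfigError("top_k must be >= 0")
        selected = groups[:top_k]
        selection = {"mode": "top_k", "top_k": top_k}
    else:
        selected = [g for g in groups if g.frequency >= min_frequency]
        selection = {"mode": "min_frequency", "min_frequency": min_frequency}

    return ConsensusResult(
        groups=groups,
        selected=selected,
        total_candidates=len(groups),
        n_runs=len(results),
        selection=selection,
    )


def _merge_groups(
    groups: list[ConsensusGroup], jaccard_threshold: float
) -> list[ConsensusGroup]:
    """Pool near-duplicate recoveries of the same module.

    Groups are scanned in rank order; each is absorbed into the first kept
    cluster whose founding member set it matches at Jaccard >= threshold.
    A cluster's frequency is the union of the runs containing any variant
    (so it never exceeds the run count), its membership is the weighted
    member-wise majority over its variants (genes present in variants
    covering at least ``_MAJORITY_WEIGHT`` of the variant weight; weight =
    each variant's run count), and its mean score is the weighted mean of
    variant scores.
    """
    clusters: list[dict] = []  # anchor, variants [(members, weight, scores)], runs
    for g in groups:
        placed = False
        for cl in clusters:
            anchor = cl["anchor"]
            inter = len(g.members & anchor)
            union = len(g.members | anchor)
            if union and inter / union >= jaccard_threshold:
                cl["variants"].append((g.members, g.frequency, g.mean_score))
                cl["runs"] |= g.run_indices
                placed = True
                break
        if not placed:
            clusters.append(
                {
                    "anchor": g.members,
                    "variants": [(g.members, g.frequency, g.mean_score)],
                    "runs": set(g.run_indices),
                    "rep": g.representative,
                }
            )

    kept: list[ConsensusGroup] = []
    for cl in clusters:
        total_w = sum(w for _, w, _ in cl["variants"])
        gene_w: dict[str, int] = {}
        for members, w, _ in cl["variants"]:
            for gene in members:
                gene_w[gene] = gene_w.get(gene, 0) + w
        majority = frozenset(
            g for g, w in gene_w.items() if w >= _MAJORITY_WEIGHT * total_w
        ) or cl["anchor"]
        mean_score = float(
            sum(w * s for _, w, s in cl["variants"]) / total_w
        )
        runs = frozenset(cl["runs"])
        kept.append(
            ConsensusGroup(
                members=majority,
                frequency=len(runs),
                mean_score=mean_score,
                representative=replace(cl["rep"], frequency=len(runs)),
                run_indices=runs,
            )
        )

    # two clusters may collapse onto the same majority set: combine them
    by_members: dict[frozenset[str], ConsensusGroup] = {}
    for g in kept:
        cur = by_members.get(g.members)
        if cur is None:
            by_members[g.members] = g
        else:
            runs = cur.run_indices | g.run_indices
            by_members[g.members] = ConsensusGroup(
                members=g.members,
                frequency=len(runs),
                mean_score=max(cur.mean_score, g.mean_score),
                representative=cur.representative,
                run_indices=runs,
            )
    out = list(by_members.values())
    out.sort(key=lambda g: (-g.frequency, -g.mean_score, tuple(sorted(g.members))))
    return out


def merge_similar_groups(
    result: ConsensusResult, jaccard_threshold: float = 0.8
) -> ConsensusResult:
    """Post-hoc merge of near-duplicate groups (Jaccard >= threshold) for
    results produced with ``jaccard_merge=None``."""
    kept = _merge_groups(result.groups, jaccard_threshold)
    sel_mode = result.selection.get("mode")
    if sel_mode == "top_k":
        selected = kept[: result.selection["top_k"]]
    elif sel_mode == "min_frequency":
        selected = [g for g in kept if g.frequency >= result.selection["min_frequency"]]
    else:  # pragma: no cover
        selected = kept
    return ConsensusResult(
        groups=kept,
        selected=selected,
        total_candidates=len(kept),
        n_runs=result.n_runs,
        selection=dict(result.selection, jaccard_threshold=jaccard_threshold),
    )
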