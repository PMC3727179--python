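"""End-to-end orchestration: simulate/load -> search -> filter -> consensus
-> classification evaluation -> DE baseline -> machine-readable report.

A single master seed is fanned out to per-stage seeds by counter-based
derivation (``SeedSequence([master, stage, index])``), so adding runs or
stages never perturbs the randomness of earlier ones, and re-running the
same configuration reproduces the report byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import baseline as bl
from . import classify as cl
from .consensus import group_and_rank, make_split_plans, run_all
from .data_io import (
    collapse_probes,
    read_annotation,
    read_expression,
    read_network,
)
from .errors import ConfigError, NetmarkError
from .search import SearchConfig
from .synthetic_data import SyntheticConfig, simulate

logger = logging.getLogger(__name__)

REPORT_VERSION = 1


@dataclass
class RunConfig:
    """Full pipeline configuration.

    Exactly one of ``synthetic`` or the real-input paths
    (``expression_path``/``labels_path``/``network_path``) must be given.
    """

    master_seed: int
    synthetic: SyntheticConfig | None = None
    expression_path: str | None = None
    labels_path: str | None = None
    network_path: str | None = None
    annotation_path: str | None = None
    search: SearchConfig = field(default_factory=SearchConfig)
    R: int = 2
    K: int = 2
    top_k: int = 19
    de_top_k: int = 100
    classifiers: tuple[str, ...] = ("tree", "rbf")
    cv_folds: int = 10
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        has_real = self.expression_path is not None
        if has_real == (self.synthetic is not None):
            raise ConfigError("give either a synthetic block or real input paths")
        if has_real and (self.labels_path is None or self.network_path is None):
            raise ConfigError("real inputs need expression, labels and network paths")
        for c in self.classifiers:
            if c not in cl.CLASSIFIER_NAMES:
                raise ConfigError(f"unknown classifier {c!r}")
        if self.R < 1 or self.K < 1 or self.cv_folds < 2:
            raise ConfigError("R, K must be >= 1 and cv_folds >= 2")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
        return cls.from_dict(doc)

    @classmethod
    def from_dict(cls, doc: dict) -> "RunConfig":
        doc = dict(doc)
        if "synthetic" in doc and doc["synthetic"] is not None:
            doc["synthetic"] = SyntheticConfig(**doc["synthetic"])
        if "search" in doc and doc["search"] is not None:
            doc["search"] = SearchConfig(**doc["search"])
        if "classifiers" in doc:
            doc["classifiers"] = tuple(doc["classifiers"])
        if "master_seed" not in doc:
            raise ConfigError("master_seed is mandatory")
        return cls(**doc)

    def to_dict(self) -> dict:
        doc = dataclasses.asdict(self)
        return doc

    def digest(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _stage_seed(master: int, stage: int, index: int = 0) -> int:
    return int(np.random.SeedSequence([int(master), stage, index]).generate_state(1)[0] % (2**31))


def _load_inputs(cfg: RunConfig):
    if cfg.synthetic is not None:
        syn = dataclasses.replace(cfg.synthetic, seed=_stage_seed(cfg.master_seed, 1))
        net, truth, ds = simulate(syn)
        return ds, net, truth
    ds = read_expression(cfg.expression_path, cfg.labels_path)
    if cfg.annotation_path:
        ds = collapse_probes(ds, read_annotation(cfg.annotation_path))
    net = read_network(cfg.network_path)
    return ds, net, None


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute every stage and return the (JSON-serializable) run report."""
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    try:
        ds, net, truth = _load_inputs(cfg)
    except NetmarkError as exc:
        raise NetmarkError(f"stage 'inputs' failed: {exc}") from exc

    search_cfg = dataclasses.replace(
        cfg.search, rng_seed=_stage_seed(cfg.master_seed, 2)
    )
    plans = make_split_plans(ds, R=cfg.R, K=cfg.K, master_seed=_stage_seed(cfg.master_seed, 3))
    results = run_all(plans, ds, net, search_cfg)
    consensus = group_and_rank(results, top_k=cfg.top_k)

    report: dict = {
        "report_version": REPORT_VERSION,
        "config_digest": cfg.digest(),
        "master_seed": cfg.master_seed,
        "n_genes": ds.n_genes,
        "n_samples": ds.n_samples,
        "n_case": len(ds.case_ids),
        "n_control": len(ds.control_ids),
        "network": {"n_nodes": net.n_nodes, "n_edges": net.n_edges},
        "runs": [
            {
                "resample_index": r.metadata["resample_index"],
                "half_index": r.metadata["half_index"],
                "run_index": r.metadata["run_index"],
                "n_candidates": r.metadata["n_candidates"],
                "n_significant": r.metadata["n_retained"],
            }
            for r in results
        ],
        "consensus": {
            "total_distinct_groups": consensus.total_candidates,
            "n_runs": consensus.n_runs,
            "selected": [
                {
                    "members": sorted(g.members),
                    "frequency": g.frequency,
                    "mean_score": round(g.mean_score, 6),
                }
                for g in consensus.selected
            ],
        },
    }

    # classification of consensus subnetwork activities
    cv_seed = _stage_seed(cfg.master_seed, 4)
    classification: dict = {}
    if consensus.selected:
        fm = cl.build_features(ds, consensus)
        for name in cfg.classifiers:
            res = cl.kfold_cv(fm, classifier=name, k=cfg.cv_folds, seed=cv_seed)
            classification[name] = {
                "cv_accuracy_pct": round(res.mean_accuracy_pct, 2),
                "fold_accuracies": [round(a, 2) for a in res.fold_accuracies],
            }
        # half-to-half cross-testing on the first resample
        half1 = next(p for p in plans if p.resample_index == 1 and p.half_index == 1)
        half2 = next(p for p in plans if p.resample_index == 1 and p.half_index == 2)
        train = ds.subset_samples(half1.sample_ids)
        test = ds.subset_samples(half2.sample_ids)
        for name in cfg.classifiers:
            acc = cl.cross_test(train, test, consensus, classifier=name, seed=cv_seed)
            classification[name]["cross_test_accuracy_pct"] = round(acc, 2)
    report["classification"] = classification

    # DE baseline
    de = bl.t_test_rank(ds)
    k = min(cfg.de_top_k, ds.n_genes)
    top = bl.top_k(de, k)
    baseline: dict = {"de_top_k": k, "n_de_flagged": int(de["de_flag"].sum())}
    try:
        _, sample_dend = bl.hcluster(ds, top)
        errs = bl.count_misclassified(sample_dend, ds.labels)
        baseline["misclassified_case"] = errs.case_errors
        baseline["misclassified_control"] = errs.control_errors
    except NetmarkError as exc:
        baseline["clustering_error"] = str(exc)
    fm_de = cl.build_features(ds, top)
    for name in cfg.classifiers:
        res = cl.kfold_cv(fm_de, classifier=name, k=cfg.cv_folds, seed=cv_seed)
        baseline[f"cv_accuracy_{name}_pct"] = round(res.mean_accuracy_pct, 2)
    if consensus.selected:
        subnet_genes = set().union(*consensus.selected_member_sets())
        ov = bl.overlap(subnet_genes, top)
        baseline["overlap_with_subnetworks"] = {
            "common": sorted(ov.common),
            "n_subnetwork_genes": ov.n_left,
            "n_top_de_genes": ov.n_right,
        }
    report["baseline"] = baseline

    if truth is not None:
        report["synthetic_truth"] = {
            "planted_modules": [sorted(m) for m in truth.planted_modules],
            "n_de_genes": sum(1 for g, e in truth.effect.items() if e != 0),
        }

    validate_report(report)
    return report


def write_report(report: dict, path: str | Path) -> None:
    validate_report(report)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
        fh.write("\n")


def validate_report(report: dict) -> None:
    """Minimal schema check applied on write and read."""
    required = {
        "report_version",
        "config_digest",
        "master_seed",
        "runs",
        "consensus",
        "classification",
        "baseline",
    }
    missing = required - set(report)
    if missing:
        raise ConfigError(f"report is missing keys: {sorted(missing)}")
    if report["report_version"] != REPORT_VERSION:
        raise ConfigError(
            f"unsupported report version {report['report_version']!r}"
        )
    for run in report["runs"]:
        if run["n_significant"] > run["n_candidates"]:
            raise ConfigError("report invariant violated: significant > candidates")


def read_report(path: str | Path) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        report = json.load(fh)
    validate_report(report)
    return report
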