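"""Synthetic interactomes and two-class expression data with planted modules.

The generator emulates the statistical structure the search stage assumes: a
sparse, mostly connected interactome; two sample classes; gene-wise Gaussian
expression on a continuous (microarray-like) scale; a handful of planted
connected modules whose members are mean-shifted between classes, except for
"connector" members that carry no shift of their own; and additive noise.
Ground truth (module memberships, per-gene signed effects, DE flags) is
recorded so recovery can be scored exactly.

Everything is deterministic given ``SyntheticConfig.seed``; the three stages
draw from independent seeded streams so regenerating one stage never perturbs
another.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import numpy as np

from .data_io import CASE, CONTROL, ExpressionDataset, InteractionNetwork
from .errors import ConfigError, PlacementError

_NETWORK_STREAM = 1
_MODULE_STREAM = 2
_EXPRESSION_STREAM = 3


@dataclass(frozen=True)
class SyntheticConfig:
    """Generation parameters.

    ``effect_size`` is the raw between-class mean shift on the expression
    scale and ``noise_sd`` the within-class standard deviation, so the
    standardized effect is ``effect_size / noise_sd`` (the two coincide at
    the default ``noise_sd = 1``).  ``connector_fraction`` is the fraction
    of each module's members that receive a zero effect.
    """

    n_genes: int = 300
    n_case: int = 50
    n_control: int = 50
    network_model: str = "scale_free"  # or "erdos_renyi"
    mean_degree: float = 4.0
    n_modules: int = 1
    module_size: int = 5
    effect_size: float = 2.0
    connector_fraction: float = 0.2
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 2:
            raise ConfigError("n_genes must be >= 2")
        if self.n_case < 1 or self.n_control < 1:
            raise ConfigError("both classes must have at least one sample")
        if self.network_model not in ("scale_free", "erdos_renyi"):
            raise ConfigError(f"unknown network_model {self.network_model!r}")
        if self.mean_degree <= 0 or self.mean_degree >= self.n_genes:
            raise ConfigError("mean_degree must be in (0, n_genes)")
        if self.module_size < 1:
            raise ConfigError("module_size must be >= 1")
        if self.n_modules * self.module_size > self.n_genes:
            raise ConfigError("n_modules * module_size exceeds n_genes")
        if not 0.0 <= self.connector_fraction <= 1.0:
            raise ConfigError("connector_fraction must be in [0, 1]")
        if self.effect_size < 0:
            raise ConfigError("effect_size must be >= 0")
        if self.noise_sd <= 0:
            raise ConfigError("noise_sd must be > 0")


@dataclass(frozen=True)
class SyntheticTruth:
    """Planted ground truth for parameter-recovery scoring."""

    planted_modules: tuple[frozenset[str], ...]
    effect: Mapping[str, float]  # gene -> signed mean shift (0 off-module/connector)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "planted_modules", tuple(frozenset(m) for m in self.planted_modules)
        )
        object.__setattr__(self, "effect", dict(self.effect))

    def de_flag(self, gene: str) -> bool:
        return self.effect.get(gene, 0.0) != 0.0

    @property
    def module_genes(self) -> frozenset[str]:
        out: set[str] = set()
        for m in self.planted_modules:
            out |= m
        return frozenset(out)

    @property
    def connector_genes(self) -> frozenset[str]:
        return frozenset(g for g in self.module_genes if self.effect.get(g, 0.0) == 0.0)


def _gene_name(i: int) -> str:
    return f"G{i:04d}"


def generate_network(cfg: SyntheticConfig) -> InteractionNetwork:
    """Generate a simple undirected interactome.

    ``scale_free`` uses preferential attachment (Barabasi-Albert with
    ``m = round(mean_degree / 2)``), giving the heavy-tailed degree
    distribution typical of curated interactomes; ``erdos_renyi`` draws a
    G(n, p) graph with ``p = mean_degree / (n - 1)``.  Smaller components are
    then bridged to the largest one with single random edges so the graph is
    connected — a negligible perturbation of the degree sequence that keeps
    every planted module placeable.
    """
    rng = np.random.default_rng([cfg.seed, _NETWORK_STREAM])
    n = cfg.n_genes
    nx_seed = int(rng.integers(0, 2**31 - 1))
    if cfg.network_model == "scale_free":
        m = max(1, round(cfg.mean_degree / 2.0))
        if m >= n:
            raise ConfigError("mean_degree infeasible for node count")
        g = nx.barabasi_albert_graph(n, m, seed=nx_seed)
    else:
        p = cfg.mean_degree / (n - 1)
        g = nx.gnp_random_graph(n, p, seed=nx_seed)
    g = nx.relabel_nodes(g, {i: _gene_name(i) for i in range(n)})
    comps = sorted(nx.connected_components(g), key=len, reverse=True)
    if len(comps) > 1:
        giant = sorted(comps[0])
        for comp in comps[1:]:
            u = rng.choice(sorted(comp))
            v = rng.choice(giant)
            g.add_edge(str(u), str(v))
    return InteractionNetwork(graph=g)


def plant_modules(net: InteractionNetwork, cfg: SyntheticConfig) -> SyntheticTruth:
    """Place ``n_modules`` vertex-disjoint connected modules of exactly
    ``module_size`` nodes and assign per-gene effects.

    Per module, ``ceil(connector_fraction * module_size)`` members are
    connectors (effect exactly 0); the rest get a signed effect of magnitude
    ``effect_size``, the sign drawn per gene so a module can mix up- and
    down-shifted members.
    """
    rng = np.random.default_rng([cfg.seed, _MODULE_STREAM])
    nodes = sorted(net.nodes)
    adj = {u: set(net.graph.neighbors(u)) for u in nodes}
    n_retry = 200
    for _ in range(n_retry):
        used: set[str] = set()
        modules: list[frozenset[str]] = []
        ok = True
        for _mod in range(cfg.n_modules):
            placed = _grow_module(nodes, adj, used, cfg.module_size, rng)
            if placed is None:
                ok = False
                break
            modules.append(frozenset(placed))
            used |= placed
        if ok:
            break
    else:
        raise PlacementError(
            f"could not place {cfg.n_modules} disjoint modules of size "
            f"{cfg.module_size} after {n_retry} attempts"
        )
    effect: dict[str, float] = {g: 0.0 for g in nodes}
    n_conn = math.ceil(cfg.connector_fraction * cfg.module_size)
    for module in modules:
        members = sorted(module)
        conn_idx = rng.choice(len(members), size=n_conn, replace=False) if n_conn else []
        connectors = {members[i] for i in np.atleast_1d(conn_idx)}
        for g in members:
            if g in connectors:
                effect[g] = 0.0
            else:
                sign = 1.0 if rng.random() < 0.5 else -1.0
                effect[g] = sign * cfg.effect_size
    return SyntheticTruth(planted_modules=tuple(modules), effect=effect)


def _grow_module(
    nodes: Sequence[str],
    adj: Mapping[str, set[str]],
    used: set[str],
    size: int,
    rng: np.random.Generator,
) -> set[str] | None:
    """Grow one connected module avoiding ``used`` nodes; None on failure."""
    free = [n for n in nodes if n not in used]
    if len(free) < size:
        return None
    for _ in range(50):
        start = free[int(rng.integers(len(free)))]
        members = {start}
        frontier = sorted((adj[start] - used) - members)
        while len(members) < size and frontier:
            nxt = frontier[int(rng.integers(len(frontier)))]
            members.add(nxt)
            frontier = sorted(
                set(frontier) | (adj[nxt] - used) - members - {nxt}
            )
            frontier = [f for f in frontier if f not in members]
        if len(members) == size:
            return members
    return None


def generate_expression(
    net: InteractionNetwork, truth: SyntheticTruth, cfg: SyntheticConfig
) -> ExpressionDataset:
    """Draw the expression matrix.

    value(g, s) = mu_g + effect(g) * 1[s is case] + eps, with per-gene
    baseline mu_g ~ N(0, 1) and noise eps ~ N(0, noise_sd).  Case samples come
    first, then controls.
    """
    if not truth.module_genes <= net.nodes:
        raise ConfigError("truth references genes not in the network")
    rng = np.random.default_rng([cfg.seed, _EXPRESSION_STREAM])
    genes = sorted(net.nodes)
    n_samples = cfg.n_case + cfg.n_control
    mu = rng.normal(0.0, 1.0, size=len(genes))
    noise = rng.normal(0.0, cfg.noise_sd, size=(len(genes), n_samples))
    eff = np.array([truth.effect.get(g, 0.0) for g in genes])
    values = mu[:, None] + noise
    values[:, : cfg.n_case] += eff[:, None]
    sample_ids = [f"case{i + 1:03d}" for i in range(cfg.n_case)] + [
        f"ctrl{i + 1:03d}" for i in range(cfg.n_control)
    ]
    labels = {s: (CASE if s.startswith("case") else CONTROL) for s in sample_ids}
    return ExpressionDataset(
        gene_ids=tuple(genes),
        sample_ids=tuple(sample_ids),
        values=values,
        labels=labels,
    )


def simulate(cfg: SyntheticConfig):
    """Convenience wrapper: network, planted truth and expression in one call."""
    net = generate_network(cfg)
    truth = plant_modules(net, cfg)
    ds = generate_expression(net, truth, cfg)
    return net, truth, ds
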