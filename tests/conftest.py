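import numpy as np
import pytest

import netmark as nm


@pytest.fixture
def tiny_ds() -> nm.ExpressionDataset:
    """3 genes x 4 samples, 2 case / 2 control."""
    return nm.ExpressionDataset(
        gene_ids=("gA", "gB", "gC"),
        sample_ids=("s1", "s2", "s3", "s4"),
        values=np.array(
            [[1.0, 2.0, 3.0, 4.0], [4.0, 3.0, 2.0, 1.0], [0.5, 0.5, 1.5, 1.5]]
        ),
        labels={"s1": "case", "s2": "case", "s3": "control", "s4": "control"},
    )


@pytest.fixture
def small_sim():
    """Default-scale synthetic scenario: one planted 5-gene module, effect 2."""
    cfg = nm.SyntheticConfig(seed=42)
    net, truth, ds = nm.simulate(cfg)
    return cfg, net, truth, ds


def make_two_class_ds(
    n_genes: int,
    n_case: int,
    n_control: int,
    effects: dict[int, float] | None = None,
    seed: int = 0,
    noise_sd: float = 1.0,
) -> nm.ExpressionDataset:
    """Direct expression matrix with optional per-row mean shifts in cases."""
    rng = np.random.default_rng(seed)
    n = n_case + n_control
    values = rng.normal(0.0, noise_sd, size=(n_genes, n))
    for row, eff in (effects or {}).items():
        values[row, :n_case] += eff
    samples = [f"c{i}" for i in range(n_case)] + [f"h{i}" for i in range(n_control)]
    labels = {s: ("case" if s.startswith("c") else "control") for s in samples}
    return nm.ExpressionDataset(
        gene_ids=tuple(f"g{i:03d}" for i in range(n_genes)),
        sample_ids=tuple(samples),
        values=values,
        labels=labels,
    )
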