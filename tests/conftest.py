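import numpy as np
import pandas as pd
import pytest

from fibromod.simulate import (ModulePlan, SimulationConfig, simulate_invivo)


@pytest.fixture(scope="session")
def small_invivo():
    """A reduced but fully structured in vivo dataset: 600 genes, three
    planted modules (one per phase), 4 animals per group."""
    config = SimulationConfig(
        n_genes=600,
        module_plans=[
            ModulePlan("M1", 40, "inflammatory"),
            ModulePlan("M2", 50, "acute"),
            ModulePlan("M3", 60, "late"),
        ],
        n_per_group=4,
        seed=11,
    )
    expr, design, truth = simulate_invivo(config)
    return config, expr, design, truth


def planted_block_matrix(rng, n_block=50, n_blocks=2, n_noise=100, n_samples=40,
                         cor=0.9):
    """Expression matrix with tightly correlated gene blocks plus noise genes
    (factor-model construction giving within-block correlation ~``cor``)."""
    lam = np.sqrt(cor)
    rows = []
    labels = []
    for b in range(n_blocks):
        z = rng.normal(size=n_samples)
        block = lam * z[None, :] + np.sqrt(1 - lam**2) * rng.normal(
            size=(n_block, n_samples))
        rows.append(block)
        labels += [b + 1] * n_block
    rows.append(rng.normal(size=(n_noise, n_samples)))
    labels += [0] * n_noise
    x = np.vstack(rows)
    genes = [f"g{i:04d}" for i in range(len(x))]
    return pd.DataFrame(x, index=genes), np.array(labels)
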