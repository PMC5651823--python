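import numpy as np
import pandas as pd
import pytest

from triadexpr import ExpressionMatrix, SimulationConfig, simulate_triad


def make_matrix(values, conditions=None, tissues=None, sources=None,
                genes=None, scale="counts"):
    """Build a small ExpressionMatrix from an array and minimal metadata."""
    values = np.asarray(values)
    n_genes, n_samples = values.shape
    genes = list(genes) if genes is not None else [f"g{i}" for i in range(n_genes)]
    samples = [f"s{j}" for j in range(n_samples)]
    meta = pd.DataFrame({
        "sample": samples,
        "tissue": list(tissues) if tissues is not None else ["t1"] * n_samples,
        "condition": list(conditions) if conditions is not None else ["H"] * n_samples,
        "source": list(sources) if sources is not None else ["c1"] * n_samples,
        "subject": samples,
    })
    return ExpressionMatrix(values=pd.DataFrame(values, index=genes, columns=samples),
                            samples=meta, scale=scale)


@pytest.fixture(scope="session")
def small_triad():
    """One modest triad dataset with planted shared TASA genes, reused across tests."""
    cfg = SimulationConfig(n_genes=800, n_tissues=4,
                           samples_per_condition={"H": 20, "A": 20, "T": 20},
                           n_shared_tasa=12, effect_log2fc=2.0, seed=123)
    em, truth = simulate_triad(cfg)
    return cfg, em, truth
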