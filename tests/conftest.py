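import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from temposeq.counting import CountMatrix

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def toy_matrix(counts: np.ndarray, n_reps: int = 3) -> CountMatrix:
    """Genes x (3 states x n_reps) matrix with D/Grh/Ey labels."""
    states = ["D", "Grh", "Ey"]
    columns = [f"{s}_r{r + 1}" for s in states for r in range(n_reps)]
    genes = [f"g{i:03d}" for i in range(counts.shape[0])]
    samples = pd.DataFrame(
        {
            "state": [s for s in states for _ in range(n_reps)],
            "replicate": list(range(1, n_reps + 1)) * 3,
        },
        index=pd.Index(columns, name="sample_id"),
    )
    return CountMatrix(
        counts=pd.DataFrame(counts, index=pd.Index(genes, name="gene_id"), columns=columns),
        samples=samples,
    )


@pytest.fixture
def two_state_matrix():
    """6 genes x (3+3) samples with hand-set counts for D and Grh only."""
    rng = np.random.default_rng(0)
    counts = rng.poisson(50, size=(6, 9))
    return toy_matrix(counts)
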