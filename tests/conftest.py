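import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def tiny_de_table():
    """The four-gene DE contrast used in the threshold-filtering examples."""
    from repositioning.io_formats import DETable

    return DETable(
        contrast_label="1dpi_vs_4hpi",
        table=pd.DataFrame(
            {
                "gene_id": ["gA", "gB", "gC", "gD"],
                "log2fc": [2.0, -1.5, 0.2, 1.2],
                "p_adj": [0.01, 0.04, 0.01, 0.20],
            }
        ),
    )


@pytest.fixture
def small_profile():
    """A deterministic 10-gene ranked profile."""
    from repositioning.connectivity import RankedProfile

    genes = [f"g{i}" for i in range(1, 11)]
    return RankedProfile(
        instance_id="inst1",
        compound_id="cmpdA",
        cell_line="MCF7",
        n=10,
        rank_of={g: i + 1 for i, g in enumerate(genes)},
    )


def random_ranked_profile(rng: np.random.Generator, n: int, instance="i", compound="c"):
    from repositioning.connectivity import RankedProfile

    perm = rng.permutation(n) + 1
    return RankedProfile(
        instance_id=instance,
        compound_id=compound,
        cell_line="MCF7",
        n=n,
        rank_of={f"g{i}": int(perm[i]) for i in range(n)},
    )
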