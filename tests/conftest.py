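import numpy as np
import pandas as pd
import pytest

from gutosi.simulate import StudySpec, simulate_abundance_table, simulate_two_group_study


@pytest.fixture(scope="session")
def worked_abundance() -> pd.DataFrame:
    """3-sample / 2-taxon table whose relationship matrix is known by hand."""
    return pd.DataFrame(
        {"a": [0.2, 0.4, 0.6], "b": [0.6, 0.4, 0.2]},
        index=pd.Index(["s1", "s2", "s3"], name="sample_id"),
    )


@pytest.fixture(scope="session")
def medium_abundance() -> pd.DataFrame:
    table, _ = simulate_abundance_table(40, 25, seed=7)
    return table


@pytest.fixture(scope="session")
def small_bundle():
    """A compact two-group study reused across pipeline-facing tests."""
    spec = StudySpec(
        n_cohort=30, k=5, n_taxa=60,
        correlation_blocks=[(["g001", "g002", "g003", "g004"], 0.97)],
        taxon_effects=[("g030", 4.0), ("g031", 0.25)],
        n_metabolite_features=120,
        metabolite_log2fc=[("m0001", 1.2), ("m0002", -1.2)],
    )
    return simulate_two_group_study(spec, seed=3)


def brute_force_bh(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up from the definition, for cross-checks."""
    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, p[i] * m / rank_from_top)
        adj[i] = running
    return adj
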