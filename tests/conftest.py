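import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from resistm import SyntheticCohortConfig, builtin_registry, simulate_cohort

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

# 9-gene x 5-sample fixture for the reflected-median oracle: rows are the
# combined signature genes (risk-up arm first), values drawn once and
# committed.  Synthetic — log2-scale magnitudes only, not real cohort data.
SCORING_FIXTURE_GENES = [
    "SERPINE1", "SMARCD3",  # up arm
    "SC5D", "FDPS", "MVD", "HMGCS1", "HMGCR", "CYP51A1", "ACAT2",  # down arm
]
SCORING_FIXTURE_SAMPLES = ["A", "B", "C", "D", "E"]
SCORING_FIXTURE_VALUES = [
    [6.768, 8.652, 7.321, 5.854, 6.226],
    [4.699, 6.934, 6.961, 5.731, 7.326],
    [10.230, 7.266, 7.389, 4.758, 7.215],
    [7.388, 6.469, 6.633, 8.239, 5.351],
    [6.821, 5.818, 3.731, 5.940, 4.547],
    [5.927, 6.677, 4.699, 3.373, 4.885],
    [4.574, 6.481, 8.330, 3.756, 5.592],
    [3.746, 6.741, 4.144, 4.711, 6.856],
    [7.917, 5.755, 5.651, 7.917, 5.626],
]

# 5-gene x 3-sample fixture for the mean-score oracle (Yin signature).
MEAN_FIXTURE_GENES = ["P4HA1", "ATF6", "PHLDB3", "IBTK", "COPE"]
MEAN_FIXTURE_SAMPLES = ["A", "B", "C"]
MEAN_FIXTURE_VALUES = [
    [3.458, 6.889, 5.460],
    [5.403, 5.062, 5.241],
    [3.662, 5.772, 5.615],
    [3.071, 7.242, 5.323],
    [5.069, 5.292, 4.294],
]


@pytest.fixture(scope="session")
def registry():
    return builtin_registry()


@pytest.fixture
def scoring_fixture():
    return pd.DataFrame(
        SCORING_FIXTURE_VALUES,
        index=pd.Index(SCORING_FIXTURE_GENES, name="gene"),
        columns=SCORING_FIXTURE_SAMPLES,
    )


@pytest.fixture
def mean_fixture():
    return pd.DataFrame(
        MEAN_FIXTURE_VALUES,
        index=pd.Index(MEAN_FIXTURE_GENES, name="gene"),
        columns=MEAN_FIXTURE_SAMPLES,
    )


@pytest.fixture(scope="session")
def demo_cohort():
    """One moderately sized planted cohort shared across tests."""
    return simulate_cohort(SyntheticCohortConfig(n_samples=400, seed=1))


def reflected_median_oracle(matrix: pd.DataFrame, up_genes, down_genes):
    """Brute-force combined score: apply the printed reflection formula
    gene-by-gene, then take per-sample medians.  Independent of the
    package implementation."""
    transformed = []
    for gene in list(up_genes) + list(down_genes):
        row = matrix.loc[gene].to_numpy(dtype=float)
        if gene in up_genes:
            lo, hi = row.min(), row.max()
            row = lo + (hi - lo) * (hi - row) / (hi - lo)
        transformed.append(row)
    arr = np.array(transformed)
    return np.array([float(np.median(arr[:, j])) for j in range(arr.shape[1])])
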