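import numpy as np
import pandas as pd
import pytest

from atf6scope import simulate
from atf6scope.datatypes import ExpressionCohort


@pytest.fixture
def small_spec() -> simulate.SimulationSpec:
    return simulate.SimulationSpec(
        n_genes=300,
        n_samples_per_group=20,
        n_up_genes=30,
        n_dn_genes=15,
        seed=11,
    )


@pytest.fixture
def toy_cohort() -> ExpressionCohort:
    rng = np.random.default_rng(5)
    genes = [f"g{i:03d}" for i in range(50)]
    samples = [f"s{i}" for i in range(10)]
    expr = pd.DataFrame(rng.normal(size=(50, 10)), index=genes, columns=samples)
    return ExpressionCohort(expr=expr)


def ssgsea_oracle(values: pd.Series, gene_set, alpha: float) -> float:
    """Straight-loop running-sum ssGSEA reference, independent of the
    vectorized implementation: sort genes by descending value (ties by id),
    walk the list accumulating normalized rank-statistic weights for set
    genes and uniform mass for the rest."""
    items = sorted(values.items(), key=lambda kv: (-kv[1], kv[0]))
    n = len(items)
    members = [g in set(gene_set) for g, _ in items]
    m = sum(members)
    weights = [(n - i) ** alpha if members[i] else 0.0 for i in range(n)]
    total_w = sum(weights)
    score = 0.0
    p_in = 0.0
    p_out = 0.0
    for i in range(n):
        if members[i]:
            p_in += weights[i] / total_w
        elif m < n:
            p_out += 1.0 / (n - m)
        score += p_in - p_out
    return score
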