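import numpy as np
import pandas as pd
import pytest

from valveproteome import (
    IntensityMatrix,
    SampleMeta,
    SynthConfig,
    generate_cohort,
    inject_missingness,
)


@pytest.fixture(scope="session")
def small_config() -> SynthConfig:
    return SynthConfig(n_proteins=400, seed=11)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    """Complete (no-missing) synthetic cohort with default group sizes."""
    return generate_cohort(small_config)


@pytest.fixture(scope="session")
def censored_cohort(small_config, small_cohort):
    matrix, meta, truth = small_cohort
    censored, dropout = inject_missingness(matrix, small_config)
    return censored, meta, truth, dropout


@pytest.fixture()
def two_group_matrix():
    """Tiny 3 vs 3 two-group fixture with hand-checkable OLS solution."""
    values = pd.DataFrame(
        [[1.0, 2.0, 3.0, 4.0, 5.0, 6.0]],
        index=pd.Index(["P1"], name="Protein ID"),
        columns=[f"s{i}" for i in range(6)],
    )
    meta = SampleMeta(
        pd.DataFrame(
            {
                "condition": ["AS"] * 3 + ["CON"] * 3,
                "sex": ["female"] * 6,
            },
            index=values.columns,
        )
    )
    return IntensityMatrix(values), meta


def make_meta(n_per_condition: dict[str, dict[str, int]]) -> SampleMeta:
    rows = []
    for cond, sexes in n_per_condition.items():
        for sex, n in sexes.items():
            for k in range(n):
                rows.append((f"{cond}_{sex[0]}{k}", cond, sex))
    return SampleMeta(
        pd.DataFrame(
            {"condition": [r[1] for r in rows], "sex": [r[2] for r in rows]},
            index=[r[0] for r in rows],
        )
    )
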