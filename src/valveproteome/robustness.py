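"""Down-sampling robustness analysis of differential-abundance counts.

Quantifies how much the larger group's sample size drives its number of
differentially abundant proteins: repeatedly draw ``n_subset`` samples from
one condition, rerun the moderated two-group analysis against all control
samples, count adjusted p < alpha, and compare the counts against a
reference count with a one-sample t-test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import IntensityMatrix, SampleMeta
from .linear_model import (
    estimate_variance_prior,
    fit_linear_model,
    moderated_statistics,
    two_group_design,
)


@dataclass
class DownsampleResult:
    counts: np.ndarray
    reference_count: float | None
    t_statistic: float | None
    p_value: float | None

    @property
    def mean_count(self) -> float:
        return float(np.mean(self.counts))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"repetition": np.arange(1, len(self.counts) + 1), "de_count": self.counts}
        )

    def summary(self) -> dict:
        return {
            "reps": int(len(self.counts)),
            "mean_count": self.mean_count,
            "reference_count": self.reference_count,
            "t_statistic": self.t_statistic,
            "p_value": self.p_value,
        }


def count_de(
    matrix: IntensityMatrix,
    meta: SampleMeta,
    group_a: str,
    group_b: str = "CON",
    alpha: float = 0.05,
    trend: bool = True,
) -> int:
    """Number of proteins with adjusted p < alpha in a two-group comparison."""
    samples = meta.samples_in_condition(group_a) + meta.samples_in_condition(
        group_b
    )
    sub_meta = meta.subset(samples)
    sub = matrix.subset_samples(samples)
    design = two_group_design(sub_meta, group_a, group_b)
    fit = fit_linear_model(sub, design)
    prior = estimate_variance_prior(fit, trend=trend)
    res = moderated_statistics(fit, prior, f"{group_a}_vs_{group_b}")
    return int((res.table["adj_p"] < alpha).sum())


def downsample_analysis(
    matrix: IntensityMatrix,
    meta: SampleMeta,
    from_group: str = "AS",
    to_group: str = "CON",
    n_subset: int = 17,
    reps: int = 100,
    reference_count: float | None = None,
    alpha: float = 0.05,
    trend: bool = True,
    seed: int = 0,
) -> DownsampleResult:
    """Down-sample ``from_group`` to ``n_subset`` and recount DE proteins.

    Each repetition draws without replacement, refits the moderated model
    (variance prior re-estimated within the repetition) against all
    ``to_group`` samples and counts adjusted p < ``alpha``.  The matrix is
    expected already imputed (imputation is performed once, upstream).
    """
    pool = meta.samples_in_condition(from_group)
    if n_subset > len(pool):
        raise ValueError(
            f"n_subset={n_subset} exceeds {from_group} group size {len(pool)}"
        )
    controls = meta.samples_in_condition(to_group)
    rng = np.random.default_rng([int(seed), 7])
    counts = np.empty(reps, dtype=int)
    for r in range(reps):
        chosen = list(rng.choice(pool, size=n_subset, replace=False))
        samples = chosen + controls
        sub_meta = meta.subset(samples)
        sub = matrix.subset_samples(samples)
        design = two_group_design(sub_meta, from_group, to_group)
        fit = fit_linear_model(sub, design)
        prior = estimate_variance_prior(fit, trend=trend)
        res = moderated_statistics(fit, prior, f"{from_group}_vs_{to_group}")
        counts[r] = int((res.table["adj_p"] < alpha).sum())

    t_stat = p_val = None
    if reference_count is not None:
        if np.all(counts == counts[0]):
            # zero-variance counts: the t-test is undefined, report p = 1
            diff = counts[0] - reference_count
            t_stat = 0.0 if diff == 0 else float(np.inf * np.sign(diff))
            p_val = 1.0
            warnings.warn("degenerate zero-variance count vector")
        else:
            t_stat, p_val = stats.ttest_1samp(counts, reference_count)
            t_stat, p_val = float(t_stat), float(p_val)
    return DownsampleResult(
        counts=counts,
        reference_count=reference_count,
        t_statistic=t_stat,
        p_value=p_val,
    )
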