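"""Clinical statistics: rank tests, 2x2 chi-squared, ECV arithmetic, ratios.

Covers the cohort-characteristics comparisons (two-sided two-sample
Wilcoxon rank test for numeric variables, continuity-corrected chi-squared
for 2x2 categorical tables), the cardiac-MRI extracellular-volume
computations

    ECV  = (1 - hematocrit) * dR1_myo / dR1_blood,   dR1 = 1/T1_post - 1/T1_pre
    aECV = (LV mass / 1.05 g/ml) * ECV,

and proteome-derived summaries: per-sample median log2 intensity over an
annotation set (e.g. ECM, mitochondrion, actin binding) compared between
condition groups, and the MYH6/MYH7 sarcomeric myosin heavy-chain ratio, a
fetal-gene-program marker in pressure overload.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import IntensityMatrix, SampleMeta

MYOCARDIAL_DENSITY_G_PER_ML = 1.05


@dataclass
class CmrRecord:
    """One subject's cardiac-MRI T1 mapping record (times in ms, mass in g)."""

    hematocrit: float
    t1_myo_pre: float
    t1_myo_post: float
    t1_blood_pre: float
    t1_blood_post: float
    lv_mass: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.hematocrit < 1.0:
            raise ValueError("hematocrit must be in (0, 1)")
        for name in ("t1_myo_pre", "t1_myo_post", "t1_blood_pre", "t1_blood_post"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.t1_blood_post >= self.t1_blood_pre:
            raise ValueError("post-contrast blood T1 must be below pre-contrast")
        if self.lv_mass is not None and self.lv_mass <= 0:
            raise ValueError("LV mass must be positive")


def wilcoxon_two_sample(x, y) -> tuple[float, float]:
    """Two-sided two-sample Wilcoxon (Mann-Whitney) rank test.

    Exact p for combined n <= 50 without ties; otherwise the normal
    approximation with tie and continuity correction.  Returns the
    Mann-Whitney U statistic of the first sample and the p-value.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("empty input sample")
    combined = np.concatenate([x, y])
    has_ties = len(np.unique(combined)) < combined.size
    method = "exact" if (combined.size <= 50 and not has_ties) else "asymptotic"
    if method == "asymptotic" and np.all(combined == combined[0]):
        # all values identical: no evidence either way
        return float(x.size * y.size / 2.0), 1.0
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True
    )
    return float(res.statistic), float(min(1.0, res.pvalue))


def wilcoxon_one_sample(x, mu_ref: float) -> tuple[float, float]:
    """Two-sided one-sample Wilcoxon signed-rank test against a reference mean.

    Zero differences are dropped; exact p for n <= 25 without tied absolute
    differences, otherwise the normal approximation with continuity
    correction.
    """
    x = np.asarray(x, dtype=float)
    d = x - mu_ref
    d = d[d != 0]
    if d.size == 0:
        raise ValueError("all differences are zero")
    abs_ties = len(np.unique(np.abs(d))) < d.size
    method = "exact" if (d.size <= 25 and not abs_ties) else "approx"
    res = stats.wilcoxon(
        d,
        zero_method="wilcox",
        alternative="two-sided",
        method=method,
        correction=True,
    )
    return float(res.statistic), float(min(1.0, res.pvalue))


def chi_squared_2x2(
    table, yates: bool = True
) -> tuple[float, float]:
    """Chi-squared test of a 2x2 table, Yates-corrected by default.

    Statistic = sum over cells of (|O - E| - c)^2 / E with the continuity
    correction c = min(0.5, |O - E|) per cell, so the statistic is never
    negative; p from chi-square with 1 df.  Both margins must be positive.
    """
    obs = np.asarray(table, dtype=float)
    if obs.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if (obs < 0).any():
        raise ValueError("counts must be non-negative")
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    if (row <= 0).any() or (col <= 0).any():
        raise ValueError("zero margin in contingency table")
    expected = np.outer(row, col) / obs.sum()
    dev = np.abs(obs - expected)
    if yates:
        dev = dev - np.minimum(0.5, dev)
    statistic = float((dev**2 / expected).sum())
    p = float(stats.chi2.sf(statistic, df=1))
    return statistic, p


def drop_zero_columns(table) -> np.ndarray:
    """Remove all-zero columns from a 2xk count table (for degenerate grades)."""
    obs = np.asarray(table, dtype=float)
    keep = obs.sum(axis=0) > 0
    return obs[:, keep]


def compute_ecv(record: CmrRecord) -> float:
    """Extracellular volume fraction from T1 times and hematocrit.

    ECV = (1 - hct) * [(1/T1_myo_post - 1/T1_myo_pre) /
    (1/T1_blood_post - 1/T1_blood_pre)]; invariant to rescaling all four T1
    values by a common factor.
    """
    dr1_blood = 1.0 / record.t1_blood_post - 1.0 / record.t1_blood_pre
    if dr1_blood == 0:
        raise ZeroDivisionError("blood dR1 is zero; ECV undefined")
    dr1_myo = 1.0 / record.t1_myo_post - 1.0 / record.t1_myo_pre
    return (1.0 - record.hematocrit) * dr1_myo / dr1_blood


def compute_aecv(
    ecv: float, lv_mass: float, density: float = MYOCARDIAL_DENSITY_G_PER_ML
) -> float:
    """Absolute ECV (ml): LV myocardial volume (mass/density) times ECV."""
    if lv_mass <= 0:
        raise ValueError("LV mass must be positive")
    if not 0.0 <= ecv <= 1.0:
        raise ValueError("ECV must be a fraction in [0, 1]")
    return (lv_mass / density) * ecv


def ecv_table(clinical: pd.DataFrame) -> pd.DataFrame:
    """Per-subject ECV and aECV from a clinical records table."""
    rows = {}
    for subject, rec in clinical.iterrows():
        record = CmrRecord(
            hematocrit=float(rec["hematocrit"]),
            t1_myo_pre=float(rec["T1_myo_pre"]),
            t1_myo_post=float(rec["T1_myo_post"]),
            t1_blood_pre=float(rec["T1_blood_pre"]),
            t1_blood_post=float(rec["T1_blood_post"]),
            lv_mass=float(rec["LV_mass"]),
        )
        ecv = compute_ecv(record)
        rows[subject] = {
            "ECV": ecv,
            "aECV": compute_aecv(min(max(ecv, 0.0), 1.0), record.lv_mass),
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def annotation_median_test(
    matrix: IntensityMatrix,
    members,
    meta: SampleMeta,
    pairs=(("AS", "CON"), ("MR", "CON"), ("AS", "MR")),
) -> tuple[pd.Series, dict[str, float]]:
    """Per-sample median log2 intensity over an annotation set, plus tests.

    Returns the per-sample medians and a two-sample Wilcoxon p-value for
    each requested condition pair.
    """
    present = [m for m in members if m in matrix.proteins]
    if not present:
        raise ValueError("no annotation members present in the matrix")
    medians = matrix.values.loc[present].median(axis=0)
    medians.name = "median_log2"
    pvals = {}
    for a, b in pairs:
        xa = medians[meta.samples_in_condition(a)].to_numpy()
        xb = medians[meta.samples_in_condition(b)].to_numpy()
        _, p = wilcoxon_two_sample(xa, xb)
        pvals[f"{a}_vs_{b}"] = p
    return medians, pvals


def myh_ratio(
    matrix: IntensityMatrix,
    meta: SampleMeta,
    gene_a: str = "MYH6",
    gene_b: str = "MYH7",
    pairs=(("AS", "CON"), ("MR", "CON"), ("AS", "MR")),
) -> tuple[pd.Series, dict[str, float]]:
    """Per-sample linear-scale abundance ratio gene_a/gene_b plus group tests."""
    for gene in (gene_a, gene_b):
        if gene not in matrix.proteins:
            raise KeyError(f"gene row not found: {gene!r}")
    ratio = np.power(
        2.0, matrix.values.loc[gene_a] - matrix.values.loc[gene_b]
    )
    ratio.name = f"{gene_a}/{gene_b}"
    pvals = {}
    for a, b in pairs:
        xa = ratio[meta.samples_in_condition(a)].dropna().to_numpy()
        xb = ratio[meta.samples_in_condition(b)].dropna().to_numpy()
        _, p = wilcoxon_two_sample(xa, xb)
        pvals[f"{a}_vs_{b}"] = p
    return ratio, pvals
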