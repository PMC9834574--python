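"""Classification of per-protein effects across contrasts.

Condition level: a protein is *condition-specific* (AS or MR) when it is
significant versus control and versus the other condition with a conserved
direction while the other condition shows no significant change versus
control; *shared* when both versus-control contrasts are significant with
the same sign; *divergent* when both are significant with opposing signs.
Proteins significant in neither versus-control contrast are *ns*; remaining
significance patterns (e.g. significant versus control but not versus the
other condition) fall into *other*.

Sex level, within a condition: *female-only* / *male-only* when significant
versus the sex-matched control in exactly one sex, *both* when in both.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .linear_model import ContrastResult

CONDITION_CLASSES = (
    "AS-specific",
    "MR-specific",
    "shared",
    "divergent",
    "ns",
    "other",
)
SEX_CLASSES = ("female-only", "male-only", "both", "ns")


def _check_aligned(*results: ContrastResult) -> pd.Index:
    index = results[0].proteins
    for res in results[1:]:
        if not res.proteins.equals(index):
            raise ValueError("contrast results cover different protein sets")
    return index


def classify_condition_effects(
    res_as: ContrastResult,
    res_mr: ContrastResult,
    res_as_vs_mr: ContrastResult,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Assign each protein exactly one condition-level class.

    Significance is strict (``adj_p < alpha``); a zero log fold change
    counts as no direction, so it can never support a specific call.
    """
    index = _check_aligned(res_as, res_mr, res_as_vs_mr)
    sig_as = (res_as.table["adj_p"] < alpha).to_numpy()
    sig_mr = (res_mr.table["adj_p"] < alpha).to_numpy()
    sig_avm = (res_as_vs_mr.table["adj_p"] < alpha).to_numpy()
    sgn_as = np.sign(res_as.table["logFC"].to_numpy())
    sgn_mr = np.sign(res_mr.table["logFC"].to_numpy())
    sgn_avm = np.sign(res_as_vs_mr.table["logFC"].to_numpy())

    labels = np.full(len(index), "other", dtype=object)
    both = sig_as & sig_mr
    same_dir = (sgn_as == sgn_mr) & (sgn_as != 0)
    opposite = (sgn_as == -sgn_mr) & (sgn_as != 0)
    labels[both & same_dir] = "shared"
    labels[both & opposite] = "divergent"

    as_specific = (
        sig_as
        & ~sig_mr
        & sig_avm
        & (sgn_as == sgn_avm)
        & (sgn_as != 0)
    )
    mr_specific = (
        sig_mr
        & ~sig_as
        & sig_avm
        & (sgn_mr == -sgn_avm)
        & (sgn_mr != 0)
    )
    labels[as_specific] = "AS-specific"
    labels[mr_specific] = "MR-specific"
    labels[~sig_as & ~sig_mr] = "ns"

    return pd.DataFrame(
        {
            "condition_class": labels,
            "sign_AS_vs_CON": sgn_as,
            "sign_MR_vs_CON": sgn_mr,
            "sign_AS_vs_MR": sgn_avm,
        },
        index=index,
    )


def classify_sex_effects(
    res_female: ContrastResult,
    res_male: ContrastResult,
    alpha: float = 0.05,
) -> pd.Series:
    """Sex-stratified class per protein for one condition."""
    index = _check_aligned(res_female, res_male)
    sig_f = (res_female.table["adj_p"] < alpha).to_numpy()
    sig_m = (res_male.table["adj_p"] < alpha).to_numpy()
    labels = np.full(len(index), "ns", dtype=object)
    labels[sig_f & ~sig_m] = "female-only"
    labels[~sig_f & sig_m] = "male-only"
    labels[sig_f & sig_m] = "both"
    return pd.Series(labels, index=index, name="sex_class")


def count_effect_classes(calls: pd.DataFrame | pd.Series) -> pd.Series:
    """Counts per class; classes partition the protein set."""
    if isinstance(calls, pd.DataFrame):
        col = calls["condition_class"]
        vocab = CONDITION_CLASSES
    else:
        col = calls
        vocab = SEX_CLASSES if set(col) <= set(SEX_CLASSES) else CONDITION_CLASSES
    counts = col.value_counts()
    return pd.Series({c: int(counts.get(c, 0)) for c in vocab}, name="count")


def effect_calls_table(
    condition_calls: pd.DataFrame,
    sex_calls: dict[str, pd.Series] | None = None,
) -> pd.DataFrame:
    """Merge condition- and per-condition sex-level calls into one table."""
    out = condition_calls.copy()
    for cond, series in (sex_calls or {}).items():
        out[f"sex_class_{cond}"] = series
    return out
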