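"""Core in-memory containers shared across the pipeline.

The pipeline's central object is an :class:`IntensityMatrix`: a proteins x
samples table of log2 label-free quantification (LFQ) intensities in which
missing cells (protein not quantified in a sample) are carried as NaN, with
the missingness mask recoverable at any stage.  Sample annotations live in a
:class:`SampleMeta` table assigning each sample a condition (AS = aortic
stenosis, MR = mitral regurgitation, CON = control) and a sex, from which the
condition x sex group label used by the cell-means linear model is derived.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CONDITIONS = ("AS", "MR", "CON")
SEXES = ("female", "male")

#: The six condition x sex cells in fixed design order.
GROUPS = tuple(f"{c}.{s}" for c in CONDITIONS for s in SEXES)


def group_label(condition: str, sex: str) -> str:
    return f"{condition}.{sex}"


@dataclass
class SampleMeta:
    """Per-sample condition and sex annotations.

    Parameters
    ----------
    table
        DataFrame indexed by sample id with columns ``condition`` and
        ``sex``.  A ``group`` column (``"<condition>.<sex>"``) is derived on
        construction.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"condition", "sex"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"metadata missing columns: {sorted(missing)}")
        bad_cond = set(self.table["condition"]) - set(CONDITIONS)
        if bad_cond:
            raise ValueError(f"unknown conditions: {sorted(bad_cond)}")
        bad_sex = set(self.table["sex"]) - set(SEXES)
        if bad_sex:
            raise ValueError(f"unknown sexes: {sorted(bad_sex)}")
        if self.table.index.duplicated().any():
            raise ValueError("duplicate sample ids in metadata")
        self.table = self.table.copy()
        self.table["group"] = [
            group_label(c, s)
            for c, s in zip(self.table["condition"], self.table["sex"])
        ]

    @property
    def samples(self) -> pd.Index:
        return self.table.index

    def condition_of(self, sample: str) -> str:
        return str(self.table.loc[sample, "condition"])

    def samples_in_condition(self, condition: str) -> list[str]:
        return list(self.table.index[self.table["condition"] == condition])

    def samples_in_group(self, group: str) -> list[str]:
        return list(self.table.index[self.table["group"] == group])

    def group_sizes(self) -> pd.Series:
        return self.table["group"].value_counts()

    def subset(self, samples) -> "SampleMeta":
        return SampleMeta(self.table.loc[list(samples), ["condition", "sex"]])


@dataclass
class IntensityMatrix:
    """Proteins x samples log2 intensity matrix with missingness as NaN."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            raise ValueError("duplicate protein ids")
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate sample ids")
        self.values = self.values.astype(float)

    @property
    def proteins(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    @property
    def mask(self) -> pd.DataFrame:
        """Boolean missingness mask (True = missing)."""
        return self.values.isna()

    @property
    def n_proteins(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def is_complete(self) -> bool:
        return not bool(self.values.isna().any().any())

    def subset_samples(self, samples) -> "IntensityMatrix":
        return IntensityMatrix(self.values.loc[:, list(samples)].copy())

    def subset_proteins(self, proteins) -> "IntensityMatrix":
        return IntensityMatrix(self.values.loc[list(proteins), :].copy())

    def to_tsv(self, path, id_column: str = "Protein ID") -> None:
        out = self.values.copy()
        out.index.name = id_column
        out.to_csv(path, sep="\t", na_rep="NA")

    @classmethod
    def from_tsv(cls, path, id_column: str = "Protein ID") -> "IntensityMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
        return cls(df)


@dataclass
class FilterReport:
    """Tally of rows removed per filtering rule, in application order.

    Each removed row is attributed to exactly one rule (the first that
    triggered), so ``sum(removed.values()) + retained == n_input``.
    """

    n_input: int
    removed: dict[str, int] = field(default_factory=dict)

    @property
    def retained(self) -> int:
        return self.n_input - sum(self.removed.values())

    def record(self, rule: str, count: int) -> None:
        if count < 0:
            raise ValueError("negative removal count")
        self.removed[rule] = self.removed.get(rule, 0) + count

    def merged_with(self, other: "FilterReport") -> "FilterReport":
        """Chain a report from a downstream filtering stage."""
        if other.n_input != self.retained:
            raise ValueError("reports do not chain: row totals mismatch")
        out = FilterReport(self.n_input, dict(self.removed))
        for rule, count in other.removed.items():
            out.record(rule, count)
        return out

    def as_series(self) -> pd.Series:
        data = dict(self.removed)
        data["retained"] = self.retained
        data["input"] = self.n_input
        return pd.Series(data, dtype=int)
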