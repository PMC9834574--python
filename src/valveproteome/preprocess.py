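"""Log2 transform, valid-value filtering, and downshifted-Gaussian imputation.

Missing LFQ values in label-free proteomics are predominantly left-censored
(low-abundance proteins drop below the detection limit), so they are imputed
from a Gaussian narrowed to ``width``·SD and shifted down by ``shift``·SD of
the observed values of each sample — by default 0.3·SD and 1.8·SD, the
convention of the Perseus ecosystem.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import CONDITIONS, FilterReport, IntensityMatrix, SampleMeta
from .maxquant import RawProteinTable, row_ids

# sub-stream tag offset for per-sample imputation generators
_STREAM_IMPUTE = 1000


@dataclass
class ImputationParams:
    """Downshifted-Gaussian imputation parameters (fractions of per-sample SD)."""

    width: float = 0.3
    shift: float = 1.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("width must be positive")
        if self.shift < 0:
            raise ValueError("shift must be non-negative")


def log2_transform(raw: RawProteinTable) -> IntensityMatrix:
    """Log2-transform linear LFQ intensities; zeros become missing cells."""
    if len(raw) == 0:
        raise ValueError("empty protein table")
    lfq = raw.lfq.to_numpy(dtype=float)
    if (lfq < 0).any():
        raise ValueError("negative intensity")
    values = np.full_like(lfq, np.nan)
    observed = lfq > 0
    values[observed] = np.log2(lfq[observed])
    return IntensityMatrix(
        pd.DataFrame(values, index=row_ids(raw), columns=raw.samples)
    )


def filter_valid_values(
    matrix: IntensityMatrix,
    meta: SampleMeta,
    min_frac: float = 0.5,
    by: str = "condition",
) -> tuple[IntensityMatrix, FilterReport]:
    """Keep proteins with >= ``min_frac`` valid values in at least one group.

    ``by="condition"`` compares across the three condition groups (the
    default reading of the valid-value rule); ``by="group"`` switches to the
    six condition x sex cells.
    """
    if by not in ("condition", "group"):
        raise ValueError("by must be 'condition' or 'group'")
    unknown = set(matrix.samples) - set(meta.samples)
    if unknown:
        raise ValueError(f"samples missing from metadata: {sorted(unknown)}")
    col = "condition" if by == "condition" else "group"
    observed = ~matrix.mask
    keep = pd.Series(False, index=matrix.proteins)
    groups = CONDITIONS if by == "condition" else sorted(
        meta.table[col].unique()
    )
    for grp in groups:
        samples = meta.table.index[meta.table[col] == grp]
        samples = [s for s in samples if s in matrix.samples]
        if not samples:
            continue
        frac = observed[samples].sum(axis=1) / len(samples)
        keep |= frac >= min_frac
    report = FilterReport(matrix.n_proteins)
    report.record("valid_values", int((~keep).sum()))
    filtered = IntensityMatrix(matrix.values.loc[keep].copy())
    if filtered.n_proteins == 0:
        raise ValueError("no proteins retained by the valid-value filter")
    return filtered, report


def impute_downshift(
    matrix: IntensityMatrix, params: ImputationParams | None = None
) -> tuple[IntensityMatrix, pd.DataFrame]:
    """Impute missing cells per sample from Normal(mu - shift*sd, (width*sd)^2).

    mu and sd are the mean and sample standard deviation (n-1 denominator)
    of the *observed* values of the sample column; observed cells are left
    bit-identical.  Each column draws from its own generator seeded from
    (seed, column index), so subsetting columns reproduces draws.  Returns
    the completed matrix and the imputed-cell mask.
    """
    params = params or ImputationParams()
    values = matrix.values.to_numpy(copy=True)
    mask = matrix.mask.to_numpy()
    for j in range(values.shape[1]):
        col = values[:, j]
        obs = col[~mask[:, j]]
        if obs.size < 2:
            raise ValueError(
                f"sample {matrix.samples[j]!r} has <2 observed values"
            )
        n_missing = int(mask[:, j].sum())
        if n_missing == 0:
            continue
        mu, sd = obs.mean(), obs.std(ddof=1)
        rng = np.random.default_rng([int(params.seed), _STREAM_IMPUTE + j])
        col[mask[:, j]] = rng.normal(
            mu - params.shift * sd, params.width * sd, size=n_missing
        )
    imputed = IntensityMatrix(
        pd.DataFrame(values, index=matrix.proteins, columns=matrix.samples)
    )
    imputed_mask = pd.DataFrame(
        mask, index=matrix.proteins, columns=matrix.samples
    )
    return imputed, imputed_mask


def write_before_after_tsv(
    before: IntensityMatrix, after: IntensityMatrix, path_before, path_after
) -> None:
    """Emit paired TSVs of log2 intensities before and after imputation."""
    before.to_tsv(path_before)
    after.to_tsv(path_after)
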