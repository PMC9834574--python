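"""Reading MaxQuant-style protein-groups tables and identification filters.

Consumes the ``proteinGroups.txt`` dialect: tab-separated, one row per
protein group, "+"-flag columns (``Reverse``, ``Potential contaminant``,
``Only identified by site``), semicolon-separated accession lists in
``Majority protein IDs``, FASTA headers in ``Fasta headers``, and one
``LFQ intensity <sample>`` column per sample with 0 meaning not quantified.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import FilterReport, IntensityMatrix

logger = logging.getLogger(__name__)

LFQ_PREFIX = "LFQ intensity "

FLAG_COLUMNS = {
    "reverse": "Reverse",
    "contaminant": "Potential contaminant",
    "only_by_site": "Only identified by site",
}

#: Identification filters in fixed application/reporting order.
FILTER_ORDER = ("reverse", "contaminant", "only_by_site", "fragment")


@dataclass
class RawProteinTable:
    """Parsed protein-groups table.

    ``annotations`` holds identifiers, gene symbols, FASTA headers and the
    boolean flag columns; ``lfq`` the linear-scale intensities (0 = not
    quantified), one column per sample, row-aligned with ``annotations``.
    """

    annotations: pd.DataFrame
    lfq: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.annotations.index.equals(self.lfq.index):
            raise ValueError("annotation and LFQ rows misaligned")
        if self.lfq.columns.duplicated().any():
            raise ValueError("duplicate sample columns")
        if (self.lfq.to_numpy() < 0).any():
            raise ValueError("negative LFQ intensity")

    @property
    def samples(self) -> pd.Index:
        return self.lfq.columns

    def __len__(self) -> int:
        return len(self.annotations)

    def subset(self, keep: pd.Series) -> "RawProteinTable":
        return RawProteinTable(
            self.annotations.loc[keep].copy(), self.lfq.loc[keep].copy()
        )


def _parse_flag(col: pd.Series) -> pd.Series:
    return col.fillna("").astype(str).str.strip() == "+"


def read_protein_groups(path, lfq_prefix: str = LFQ_PREFIX) -> RawProteinTable:
    """Read a proteinGroups-style TSV.

    Flags are parsed from "+"-columns (absent column = no row flagged);
    intensities stay linear with 0 recorded as not-quantified.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.columns.duplicated().any():
        dupes = df.columns[df.columns.duplicated()].tolist()
        raise ValueError(f"duplicate columns in header: {dupes}")
    lfq_cols = [c for c in df.columns if c.startswith(lfq_prefix)]
    if not lfq_cols:
        raise ValueError(f"no columns with LFQ prefix {lfq_prefix!r}")

    lfq = df[lfq_cols].apply(pd.to_numeric, errors="coerce")
    if lfq.isna().any().any():
        bad = lfq.columns[lfq.isna().any()].tolist()
        raise ValueError(f"non-numeric intensity in columns: {bad}")
    lfq.columns = [c[len(lfq_prefix):] for c in lfq_cols]

    ann = df[[c for c in df.columns if c not in lfq_cols]].copy()
    for key, col in FLAG_COLUMNS.items():
        ann[key] = _parse_flag(ann[col]) if col in ann.columns else False
    for col in ("Majority protein IDs", "Gene names", "Fasta headers"):
        if col not in ann.columns:
            ann[col] = ""
        ann[col] = ann[col].fillna("")
    return RawProteinTable(ann, lfq)


def _lead_fasta_entry(headers: str) -> str:
    return str(headers).split(";")[0]


def apply_identification_filters(
    raw: RawProteinTable, fragment_token: str = "Fragment"
) -> tuple[RawProteinTable, FilterReport]:
    """Drop reverse hits, contaminants, only-by-site ids and Fragment leads.

    A row matching several rules is counted once, under the first rule in
    :data:`FILTER_ORDER`; ``fragment`` means a case-sensitive substring match
    of ``fragment_token`` in the lead (first) FASTA-header entry.
    """
    ann = raw.annotations
    triggers = {
        "reverse": ann["reverse"].to_numpy(dtype=bool),
        "contaminant": ann["contaminant"].to_numpy(dtype=bool),
        "only_by_site": ann["only_by_site"].to_numpy(dtype=bool),
        "fragment": np.array(
            [
                fragment_token in _lead_fasta_entry(h)
                for h in ann["Fasta headers"]
            ]
        ),
    }
    report = FilterReport(len(raw))
    removed_so_far = np.zeros(len(raw), dtype=bool)
    for rule in FILTER_ORDER:
        newly = triggers[rule] & ~removed_so_far
        report.record(rule, int(newly.sum()))
        removed_so_far |= newly
    keep = pd.Series(~removed_so_far, index=ann.index)
    return raw.subset(keep), report


def resolve_gene_symbols(
    raw: RawProteinTable, id_map: dict[str, str]
) -> RawProteinTable:
    """Substitute gene symbols with the mapped symbol of the first majority id.

    Rows whose first accession is not in the map keep their original symbol
    and are logged; an empty map is the identity.
    """
    out = raw.subset(pd.Series(True, index=raw.annotations.index))
    symbols = []
    n_unmapped = 0
    for ids, sym in zip(
        out.annotations["Majority protein IDs"], out.annotations["Gene names"]
    ):
        entries = [e.strip() for e in str(ids).split(";") if e.strip()]
        if not entries and str(ids).strip():
            raise ValueError(f"malformed accession list: {ids!r}")
        first = entries[0] if entries else ""
        if first in id_map:
            symbols.append(id_map[first])
        else:
            if id_map and first:
                n_unmapped += 1
            symbols.append(sym)
    if n_unmapped:
        logger.info("resolve_gene_symbols: %d rows left unmapped", n_unmapped)
    out.annotations["Gene names"] = symbols
    return out


def row_ids(raw: RawProteinTable, prefer_gene_symbol: bool = True) -> pd.Index:
    """Unique per-row identifiers: gene symbol, disambiguated by accession.

    Ambiguous symbols shared by several protein groups are suffixed with the
    majority protein id in brackets, mirroring how figure legends in the
    field disambiguate them; empty symbols fall back to the accession.
    """
    symbols = raw.annotations["Gene names"].astype(str).to_numpy()
    accs = [
        str(ids).split(";")[0].strip()
        for ids in raw.annotations["Majority protein IDs"]
    ]
    if not prefer_gene_symbol:
        return pd.Index(accs)
    base = [s if s else a for s, a in zip(symbols, accs)]
    counts = pd.Series(base).value_counts()
    out = [
        f"{b} ({a})" if counts[b] > 1 else b for b, a in zip(base, accs)
    ]
    return pd.Index(out)


def write_protein_groups_tsv(
    matrix: IntensityMatrix, path, lfq_prefix: str = LFQ_PREFIX
) -> None:
    """Write a log2 matrix as a proteinGroups-style TSV (linear scale).

    Missing cells become 0, flags are left unset; reading the file back with
    :func:`read_protein_groups` and log2-transforming round-trips the matrix.
    """
    linear = np.power(2.0, matrix.values.to_numpy())
    linear[matrix.mask.to_numpy()] = 0.0
    df = pd.DataFrame(
        {
            "Majority protein IDs": matrix.proteins,
            "Gene names": matrix.proteins,
            "Fasta headers": [f">sp|{p}|{p}_HUMAN" for p in matrix.proteins],
            "Reverse": "",
            "Potential contaminant": "",
            "Only identified by site": "",
        }
    )
    for j, sample in enumerate(matrix.samples):
        df[f"{lfq_prefix}{sample}"] = linear[:, j]
    df.to_csv(path, sep="\t", index=False)
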