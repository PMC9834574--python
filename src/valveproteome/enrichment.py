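"""Over-representation analysis against gene-set collections.

Hypergeometric upper-tail tests of up- and down-regulated query lists
against gene sets, with a background of all detected proteins, BH control
at 5% FDR, a minimum in-background set size of three, post-hoc filters on
trivially small intersections, reduction of redundant terms (identical
matched gene lists within a GO branch keep the lowest p), and proportion
summaries over user-supplied functional categories.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .linear_model import ContrastResult, adjust_bh

logger = logging.getLogger(__name__)

TABLE_COLUMNS = (
    "set",
    "direction",
    "branch",
    "set_size_bg",
    "query_size",
    "background_size",
    "overlap",
    "p",
    "adj_p",
    "significant",
    "members",
)

OTHER_CATEGORY = "other terms"


@dataclass
class GeneSetCollection:
    """Named gene sets with a namespace/branch tag per set (e.g. BP/CC/MF)."""

    sets: dict[str, frozenset]
    branch: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sets = {name: frozenset(m) for name, m in self.sets.items()}
        for name in self.sets:
            self.branch.setdefault(name, "NA")

    def __len__(self) -> int:
        return len(self.sets)

    def write_gmt(self, path) -> None:
        with open(path, "w") as fh:
            for name, members in self.sets.items():
                fields = [name, self.branch[name], *sorted(members)]
                fh.write("\t".join(fields) + "\n")

    @classmethod
    def read_gmt(cls, path) -> "GeneSetCollection":
        sets: dict[str, frozenset] = {}
        branch: dict[str, str] = {}
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line:
                    continue
                fields = line.split("\t")
                if len(fields) < 3:
                    raise ValueError(f"malformed GMT line: {line[:60]!r}")
                name, desc, members = fields[0], fields[1], fields[2:]
                if name in sets:
                    raise ValueError(f"duplicate set name: {name!r}")
                sets[name] = frozenset(m for m in members if m)
                branch[name] = desc or "NA"
        return cls(sets=sets, branch=branch)


def ora_test(query, gene_set, background) -> float:
    """Hypergeometric upper-tail p-value P(X >= overlap).

    Population = |background|, successes = |set ∩ background|, draws =
    |query|; the query must be contained in the background.
    """
    query = frozenset(query)
    background = frozenset(background)
    if not background:
        raise ValueError("empty background")
    if not query <= background:
        raise ValueError("query is not a subset of the background")
    in_bg = frozenset(gene_set) & background
    overlap = len(query & in_bg)
    p = stats.hypergeom.sf(overlap - 1, len(background), len(in_bg), len(query))
    return float(np.clip(p, 0.0, 1.0))


def queries_from_result(
    res: ContrastResult, alpha: float = 0.05
) -> dict[str, list[str]]:
    """Up/down query lists, ordered largest to smallest |log2 fold change|."""
    sig = res.table[res.table["adj_p"] < alpha]
    sig = sig.reindex(sig["logFC"].abs().sort_values(ascending=False).index)
    return {
        "up": list(sig.index[sig["logFC"] > 0]),
        "down": list(sig.index[sig["logFC"] < 0]),
    }


def run_enrichment(
    queries: dict[str, list],
    background,
    collection: GeneSetCollection,
    fdr: float = 0.05,
    min_size: int = 3,
    max_intersection_frac: float = 0.05,
    min_overlap: int = 2,
    ordered: bool = False,
) -> pd.DataFrame:
    """ORA of each query direction against every eligible set.

    Sets with in-background size < ``min_size`` are dropped before testing;
    BH adjustment runs within each direction; significant terms
    (adj_p < ``fdr``) whose overlap is below ``max_intersection_frac`` of
    the set's in-background size or below ``min_overlap`` genes are
    demoted to non-significant.  ``ordered=True`` additionally scans
    prefixes of the ranked query list and keeps each set's best
    prefix-length p Bonferroni-corrected by the number of prefixes scanned
    (a simple rank-threshold variant; default off).
    """
    background = frozenset(background)
    if not background:
        raise ValueError("empty background")
    rows = []
    for direction, query in queries.items():
        query_list = [q for q in query if q in background]
        if set(query) - background:
            raise ValueError("query is not a subset of the background")
        qset = frozenset(query_list)
        for name, members in collection.sets.items():
            in_bg = members & background
            if len(in_bg) < min_size:
                continue
            if not query_list:
                continue
            hit = sorted(qset & in_bg)
            if ordered and query_list:
                cuts = range(1, len(query_list) + 1)
                best = min(
                    ora_test(query_list[:k], in_bg, background) for k in cuts
                )
                p = float(min(1.0, best * len(query_list)))
            else:
                p = ora_test(qset, in_bg, background)
            rows.append(
                {
                    "set": name,
                    "direction": direction,
                    "branch": collection.branch[name],
                    "set_size_bg": len(in_bg),
                    "query_size": len(qset),
                    "background_size": len(background),
                    "overlap": len(hit),
                    "p": p,
                    "members": ";".join(hit),
                }
            )
    table = pd.DataFrame(rows, columns=[c for c in TABLE_COLUMNS if c not in ("adj_p", "significant")])
    if table.empty:
        table["adj_p"] = pd.Series(dtype=float)
        table["significant"] = pd.Series(dtype=bool)
        return table[list(TABLE_COLUMNS)]
    adj = np.empty(len(table))
    for direction in table["direction"].unique():
        sel = table["direction"] == direction
        adj[sel.to_numpy()] = adjust_bh(table.loc[sel, "p"].to_numpy())
    table["adj_p"] = adj
    frac_ok = table["overlap"] >= max_intersection_frac * table["set_size_bg"]
    table["significant"] = (
        (table["adj_p"] < fdr)
        & frac_ok
        & (table["overlap"] >= min_overlap)
    )
    return table[list(TABLE_COLUMNS)].reset_index(drop=True)


def reduce_redundant_terms(table: pd.DataFrame) -> pd.DataFrame:
    """Collapse terms with identical matched gene lists within a branch.

    Within each (branch, direction, member-list) group only the
    lowest-raw-p term survives; ties break lexicographically by set name.
    Idempotent.
    """
    if table.empty:
        return table.copy()
    ordered = table.sort_values(["p", "set"], kind="mergesort")
    key_cols = ["branch", "direction", "members"]
    kept = ordered.drop_duplicates(subset=key_cols, keep="first")
    return kept.sort_index().reset_index(drop=True)


def summarize_categories(
    table: pd.DataFrame,
    category_map: dict[str, str],
    weights: dict[str, float] | None = None,
) -> pd.Series:
    """Category proportions over the merged up+down significant terms.

    Each distinct significant set counts once (union over directions);
    unmapped sets fall into the "other terms" category and are logged.
    ``weights`` (e.g. annotation frequencies of representative terms)
    default to uniform.
    """
    sig = table[table["significant"]] if "significant" in table else table
    names = sorted(set(sig["set"])) if not sig.empty else []
    if not names:
        return pd.Series(dtype=float, name="proportion")
    cats, mass = {}, 0.0
    n_unmapped = 0
    for name in names:
        cat = category_map.get(name)
        if cat is None:
            cat = OTHER_CATEGORY
            n_unmapped += 1
        w = (weights or {}).get(name, 1.0)
        cats[cat] = cats.get(cat, 0.0) + w
        mass += w
    if n_unmapped:
        logger.info("summarize_categories: %d sets unmapped", n_unmapped)
    return pd.Series(
        {k: v / mass for k, v in sorted(cats.items())}, name="proportion"
    )


def read_category_map(path) -> dict[str, str]:
    """Two-column TSV (set name, category) without header."""
    df = pd.read_csv(path, sep="\t", header=None, names=["set", "category"])
    return dict(zip(df["set"], df["category"]))


def write_category_map(category_map: dict[str, str], path) -> None:
    pd.DataFrame(
        {"set": list(category_map), "category": list(category_map.values())}
    ).to_csv(path, sep="\t", header=False, index=False)
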