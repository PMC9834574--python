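"""Synthetic cohort generator with planted ground truth.

Emulates the statistical structure of a left-ventricular proteomics cohort
with three conditions (AS pressure overload, MR volume overload, CON healthy
controls) and both sexes: log-normal LFQ intensities (uniform log2 baselines),
additive condition and condition x sex effects, i.i.d. Gaussian residuals and
intensity-dependent left-censored (MNAR) dropout.  Every planted effect is
recorded so downstream calls can be scored against ground truth.

Planted effect classes mirror the effect taxonomy used downstream:

``AS-specific``
    equal shift in both AS cells, none in MR.
``MR-specific``
    equal shift in both MR cells, none in AS.
``shared``
    same-sign equal shift in all four disease cells.
``divergent``
    opposite-sign shifts in AS and MR.
``sex-only-female`` / ``sex-only-male``
    shift confined to the AS female (resp. male) cell, the condition with
    the largest sex cells.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .containers import CONDITIONS, GROUPS, SEXES, IntensityMatrix, SampleMeta

PLANTED_CLASSES = (
    "AS-specific",
    "MR-specific",
    "shared",
    "divergent",
    "sex-only-female",
    "sex-only-male",
)

#: Fixed condition-level contrast vocabulary for truth log2 fold changes.
TRUTH_CONTRASTS = (
    "AS_vs_CON",
    "MR_vs_CON",
    "AS_vs_MR",
    "ASf_vs_CONf",
    "ASm_vs_CONm",
    "MRf_vs_CONf",
    "MRm_vs_CONm",
)

# Sub-stream tags so each generation sub-step has its own named generator.
_STREAM_BASELINE = 1
_STREAM_EFFECTS = 2
_STREAM_NOISE = 3
_STREAM_DROPOUT = 4
_STREAM_GENESETS = 5
_STREAM_CLINICAL = 6


def _rng(seed: int, *tags: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), *[int(t) for t in tags]])


def _default_group_sizes() -> dict[str, int]:
    # 41 AS (21 female / 20 male), 17 MR (5/12), 17 CON (8/9)
    return {
        "AS.female": 21,
        "AS.male": 20,
        "MR.female": 5,
        "MR.male": 12,
        "CON.female": 8,
        "CON.male": 9,
    }


def _default_effect_mix() -> dict[str, float]:
    # Loosely mirrors the observed preponderance of AS-specific over
    # MR-specific regulation in valve-disease myocardium.
    return {
        "AS-specific": 0.35,
        "MR-specific": 0.10,
        "shared": 0.30,
        "divergent": 0.05,
        "sex-only-female": 0.10,
        "sex-only-male": 0.10,
    }


@dataclass
class SynthConfig:
    """Parameters of the synthetic cohort.

    Defaults emulate the study design the pipeline targets: the 41/17/17
    cohort with its sex split, ~3,000 quantifiable proteins with log2 LFQ
    baselines in the low-20s to mid-30s, and left-censored dropout
    concentrated on low-abundance proteins.
    """

    n_proteins: int = 3000
    group_sizes: dict[str, int] = field(default_factory=_default_group_sizes)
    frac_effect: float = 0.15
    effect_mix: dict[str, float] = field(default_factory=_default_effect_mix)
    effect_size_lfc: float = 1.0
    base_mean_range: tuple[float, float] = (22.0, 34.0)
    noise_sd: float = 0.5
    dropout_midpoint: float = 23.0
    dropout_steepness: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins <= 0:
            raise ValueError("n_proteins must be positive")
        unknown = set(self.group_sizes) - set(GROUPS)
        if unknown:
            raise ValueError(f"unknown groups: {sorted(unknown)}")
        if any(n <= 0 for n in self.group_sizes.values()):
            raise ValueError("group sizes must be positive")
        if not 0.0 <= self.frac_effect <= 1.0:
            raise ValueError("frac_effect must be in [0, 1]")
        unknown = set(self.effect_mix) - set(PLANTED_CLASSES)
        if unknown:
            raise ValueError(f"unknown effect classes: {sorted(unknown)}")
        if any(v < 0 for v in self.effect_mix.values()):
            raise ValueError("effect_mix proportions must be non-negative")
        if abs(sum(self.effect_mix.values()) - 1.0) > 1e-9:
            raise ValueError("effect_mix must sum to 1")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.dropout_steepness < 0:
            raise ValueError("dropout_steepness must be non-negative")
        lo, hi = self.base_mean_range
        if not lo < hi:
            raise ValueError("base_mean_range must be an increasing interval")

    def replace(self, **kwargs) -> "SynthConfig":
        return dataclasses.replace(self, **kwargs)


@dataclass
class SynthTruth:
    """Ground truth of a generated cohort.

    ``classes`` holds one planted class label per protein ("null" when no
    effect was planted); ``lfc`` the true log2 fold change of every protein
    under each contrast in :data:`TRUTH_CONTRASTS`; ``cell_effects`` the
    planted per-group shifts; ``dropout`` the per-cell dropout indicator
    (filled by :func:`inject_missingness`).
    """

    classes: pd.Series
    lfc: pd.DataFrame
    cell_effects: pd.DataFrame
    dropout: pd.DataFrame | None = None

    def proteins_in_class(self, label: str) -> list[str]:
        return list(self.classes.index[self.classes == label])

    def to_tsv(self, path) -> None:
        out = self.lfc.copy()
        out.insert(0, "true_class", self.classes)
        out.index.name = "Protein ID"
        out.to_csv(path, sep="\t")


# Contrast vectors over GROUPS order (ASf, ASm, MRf, MRm, CONf, CONm) used to
# translate planted cell effects into true log2 fold changes.  Condition
# contrasts average the two sexes with equal weight.
_TRUTH_VECTORS = {
    "AS_vs_CON": np.array([0.5, 0.5, 0.0, 0.0, -0.5, -0.5]),
    "MR_vs_CON": np.array([0.0, 0.0, 0.5, 0.5, -0.5, -0.5]),
    "AS_vs_MR": np.array([0.5, 0.5, -0.5, -0.5, 0.0, 0.0]),
    "ASf_vs_CONf": np.array([1.0, 0.0, 0.0, 0.0, -1.0, 0.0]),
    "ASm_vs_CONm": np.array([0.0, 1.0, 0.0, 0.0, 0.0, -1.0]),
    "MRf_vs_CONf": np.array([0.0, 0.0, 1.0, 0.0, -1.0, 0.0]),
    "MRm_vs_CONm": np.array([0.0, 0.0, 0.0, 1.0, 0.0, -1.0]),
}


def _cell_effect_pattern(label: str, delta: float) -> np.ndarray:
    """Planted shift per group (GROUPS order) for one protein."""
    asf, asm, mrf, mrm = 0.0, 0.0, 0.0, 0.0
    if label == "AS-specific":
        asf = asm = delta
    elif label == "MR-specific":
        mrf = mrm = delta
    elif label == "shared":
        asf = asm = mrf = mrm = delta
    elif label == "divergent":
        asf = asm = delta
        mrf = mrm = -delta
    elif label == "sex-only-female":
        asf = delta
    elif label == "sex-only-male":
        asm = delta
    else:
        raise ValueError(f"unknown planted class: {label}")
    return np.array([asf, asm, mrf, mrm, 0.0, 0.0])


def _make_meta(group_sizes: dict[str, int]) -> SampleMeta:
    rows = []
    for cond in CONDITIONS:
        for sex in SEXES:
            group = f"{cond}.{sex}"
            n = group_sizes.get(group, 0)
            for k in range(n):
                rows.append((f"{cond}_{sex[0]}{k + 1:02d}", cond, sex))
    table = pd.DataFrame(
        {"condition": [r[1] for r in rows], "sex": [r[2] for r in rows]},
        index=pd.Index([r[0] for r in rows], name="sample"),
    )
    return SampleMeta(table)


def generate_cohort(
    config: SynthConfig,
) -> tuple[IntensityMatrix, SampleMeta, SynthTruth]:
    """Generate a complete (no-missing) synthetic log2 LFQ matrix.

    The matrix is baseline + planted group effect + i.i.d. Gaussian noise.
    Apply :func:`inject_missingness` afterwards to create MNAR dropout.
    """
    meta = _make_meta(config.group_sizes)
    n_prot, n_samp = config.n_proteins, len(meta.samples)
    proteins = pd.Index(
        [f"PROT{i + 1:05d}" for i in range(n_prot)], name="Protein ID"
    )

    rng_base = _rng(config.seed, _STREAM_BASELINE)
    lo, hi = config.base_mean_range
    baselines = rng_base.uniform(lo, hi, size=n_prot)

    # Assign planted classes: first round(frac_effect * n) proteins carry
    # effects, partitioned by effect_mix proportions; remainder are null.
    rng_eff = _rng(config.seed, _STREAM_EFFECTS)
    n_effect = int(round(config.frac_effect * n_prot))
    classes = np.array(["null"] * n_prot, dtype=object)
    if n_effect > 0:
        labels = list(config.effect_mix)
        probs = np.array([config.effect_mix[k] for k in labels])
        counts = np.floor(probs * n_effect).astype(int)
        # distribute the rounding remainder to the largest fractional parts
        remainder = n_effect - counts.sum()
        order = np.argsort(-(probs * n_effect - counts))
        for j in order[:remainder]:
            counts[j] += 1
        assigned = np.concatenate(
            [np.repeat(lab, c) for lab, c in zip(labels, counts)]
        )
        idx = rng_eff.choice(n_prot, size=n_effect, replace=False)
        classes[idx] = assigned

    signs = rng_eff.choice([-1.0, 1.0], size=n_prot)
    cell_effects = np.zeros((n_prot, len(GROUPS)))
    for i in range(n_prot):
        if classes[i] != "null":
            cell_effects[i] = _cell_effect_pattern(
                str(classes[i]), signs[i] * config.effect_size_lfc
            )

    group_idx = np.array(
        [GROUPS.index(g) for g in meta.table["group"]], dtype=int
    )
    rng_noise = _rng(config.seed, _STREAM_NOISE)
    noise = rng_noise.normal(0.0, config.noise_sd, size=(n_prot, n_samp))
    values = baselines[:, None] + cell_effects[:, group_idx] + noise

    matrix = IntensityMatrix(
        pd.DataFrame(values, index=proteins, columns=meta.samples)
    )
    lfc = pd.DataFrame(
        {
            name: cell_effects @ vec
            for name, vec in _TRUTH_VECTORS.items()
        },
        index=proteins,
    )[list(TRUTH_CONTRASTS)]
    truth = SynthTruth(
        classes=pd.Series(classes, index=proteins, name="true_class"),
        lfc=lfc,
        cell_effects=pd.DataFrame(
            cell_effects, index=proteins, columns=list(GROUPS)
        ),
    )
    return matrix, meta, truth


def inject_missingness(
    matrix: IntensityMatrix, config: SynthConfig
) -> tuple[IntensityMatrix, pd.DataFrame]:
    """Left-censor the matrix with logistic intensity-dependent dropout.

    Each cell goes missing independently with probability
    ``logistic(-steepness * (x - midpoint))``, so low-intensity cells are
    lost more often; observed cells keep their exact values.  Returns the
    censored matrix and the dropout indicator (True = dropped).
    """
    if config.dropout_steepness < 0:
        raise ValueError("dropout_steepness must be non-negative")
    values = matrix.values.to_numpy(copy=True)
    p_missing = expit(
        -config.dropout_steepness * (values - config.dropout_midpoint)
    )
    rng = _rng(config.seed, _STREAM_DROPOUT)
    dropped = rng.random(values.shape) < p_missing
    values[dropped] = np.nan
    censored = IntensityMatrix(
        pd.DataFrame(values, index=matrix.proteins, columns=matrix.samples)
    )
    dropout = pd.DataFrame(
        dropped, index=matrix.proteins, columns=matrix.samples
    )
    return censored, dropout


def generate_gene_sets(
    truth: SynthTruth,
    n_sets: int = 50,
    size_range: tuple[int, int] = (5, 60),
    n_enriched: int = 5,
    enriched_class: str = "AS-specific",
    enriched_purity: float = 0.8,
    seed: int = 0,
):
    """Random gene sets plus ``n_enriched`` sets over-sampling a planted class.

    Enriched sets draw ``enriched_purity`` of their members from proteins of
    ``enriched_class`` (all of them if the class is smaller) and the rest at
    random; the remaining sets are uniform draws from all proteins.
    """
    from .enrichment import GeneSetCollection

    proteins = list(truth.classes.index)
    lo, hi = size_range
    if not 1 <= lo <= hi:
        raise ValueError("size_range must satisfy 1 <= lo <= hi")
    if hi > len(proteins):
        raise ValueError("size_range exceeds number of proteins")
    if n_enriched > n_sets:
        raise ValueError("n_enriched exceeds n_sets")

    rng = _rng(seed, _STREAM_GENESETS)
    class_members = truth.proteins_in_class(enriched_class)
    branches = ("BP", "CC", "MF")
    sets: dict[str, frozenset] = {}
    branch_of: dict[str, str] = {}
    for k in range(n_sets):
        size = int(rng.integers(lo, hi + 1))
        name = f"SET{k + 1:04d}"
        if k < n_enriched and class_members:
            n_from_class = min(
                int(round(enriched_purity * size)), len(class_members)
            )
            members = list(
                rng.choice(class_members, size=n_from_class, replace=False)
            )
            pool = [p for p in proteins if p not in set(members)]
            fill = size - n_from_class
            if fill > 0:
                members += list(rng.choice(pool, size=fill, replace=False))
        else:
            members = list(rng.choice(proteins, size=size, replace=False))
        sets[name] = frozenset(members)
        branch_of[name] = branches[k % len(branches)]
    return GeneSetCollection(sets=sets, branch=branch_of)


def generate_clinical(meta: SampleMeta, seed: int = 0) -> pd.DataFrame:
    """Synthetic per-subject clinical records matching the cohort metadata.

    Emits hematocrit (fraction), four T1 relaxation times (myocardium and
    blood pool, pre- and post-contrast, ms), left-ventricular mass (g) and
    binary comorbidity/medication flags with condition-dependent prevalence,
    from which 2x2 contingency tables can be formed.
    """
    rng = _rng(seed, _STREAM_CLINICAL)
    n = len(meta.samples)
    cond = meta.table["condition"].to_numpy()

    hct = np.clip(rng.normal(0.42, 0.03, n), 0.25, 0.55)
    t1_myo_pre = rng.normal(1000.0, 40.0, n)
    t1_blood_pre = rng.normal(1600.0, 60.0, n)
    # contrast shortens T1; disease raises ECV (myocardial post T1 lower)
    ecv_shift = np.where(cond == "CON", 0.0, -40.0)
    t1_myo_post = np.clip(rng.normal(460.0, 30.0, n) + ecv_shift, 200.0, None)
    t1_blood_post = np.clip(rng.normal(350.0, 25.0, n), 150.0, None)
    mass_mu = np.where(cond == "AS", 160.0, np.where(cond == "MR", 150.0, 120.0))
    lv_mass = np.clip(rng.normal(mass_mu, 25.0), 50.0, None)

    prevalence = {
        "hypertension": {"AS": 0.66, "MR": 0.65, "CON": 0.15},
        "diabetes": {"AS": 0.17, "MR": 0.12, "CON": 0.05},
        "af_paroxysmal": {"AS": 0.05, "MR": 0.12, "CON": 0.02},
        "diuretics": {"AS": 0.29, "MR": 0.29, "CON": 0.0},
    }
    flags = {
        name: (rng.random(n) < np.vectorize(p.get)(cond)).astype(int)
        for name, p in prevalence.items()
    }

    table = pd.DataFrame(
        {
            "condition": cond,
            "sex": meta.table["sex"].to_numpy(),
            "hematocrit": hct,
            "T1_myo_pre": t1_myo_pre,
            "T1_myo_post": t1_myo_post,
            "T1_blood_pre": t1_blood_pre,
            "T1_blood_post": t1_blood_post,
            "LV_mass": lv_mass,
            **flags,
        },
        index=meta.samples,
    )
    return table


def contingency_from_flags(
    clinical: pd.DataFrame, flag: str, cond_a: str = "AS", cond_b: str = "MR"
) -> np.ndarray:
    """2x2 table [[a_yes, a_no], [b_yes, b_no]] for a binary flag column."""
    rows = []
    for cond in (cond_a, cond_b):
        sub = clinical.loc[clinical["condition"] == cond, flag]
        rows.append([int(sub.sum()), int((1 - sub).sum())])
    return np.array(rows, dtype=int)


def write_metadata_tsv(meta: SampleMeta, path) -> None:
    meta.table[["condition", "sex"]].to_csv(path, sep="\t")


def read_metadata_tsv(path) -> SampleMeta:
    table = pd.read_csv(path, sep="\t", index_col=0)
    return SampleMeta(table[["condition", "sex"]])
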