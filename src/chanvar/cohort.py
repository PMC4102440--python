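"""Case-control association statistics for rare channel variants.

Subjects carry 0/1/2 alleles of each variant in a panel; every panel
variant belongs to a functional class -- "CF" (classic loss of chloride
conductance), "BD" (bicarbonate-defective: chloride conductance retained,
regulated bicarbonate permeation lost) or "other" (benign/uncertain).
Carrier (dominant) coding is used throughout: a subject is exposed if they
carry at least one allele of a variant (or of any variant in a class).

Supported analyses mirror the standard design of rare-variant pancreatitis
studies: per-variant and per-class carrier odds ratios, trans-heterozygote
enrichment (a channel variant co-occurring with a single SPINK1 N34S
allele), and phenotype-subgroup odds ratios (carrier cases of a genotype
class against all controls).  Odds ratios from tables with empty cells are
reported as 0, infinity or undefined (NaN) rather than corrected.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

__all__ = [
    "TwoByTwo",
    "AssociationResult",
    "PanelVariant",
    "VariantPanel",
    "odds_ratio",
    "odds_ratio_from_prevalence",
    "fisher_exact_two_tailed",
    "chi_square_p",
    "woolf_ci",
    "classify_subject",
    "classify_cohort",
    "build_two_by_two",
    "associate",
    "trans_het_association",
    "phenotype_association",
]

logger = logging.getLogger(__name__)

#: Cohort-table columns that are not variant genotype columns.
META_COLUMNS = frozenset({
    "id", "status", "spink1_n34s", "r117h_t5_cis", "ivs8_t5_cis_pathogenic",
    "rhinosinusitis", "male_infertility", "sex", "age",
})

GENOTYPE_CLASSES = (
    "none",
    "CF_carrier",
    "BD_carrier",
    "CFBD_or_BDBD_recessive",
    "transhet_N34S",
)


@dataclass(frozen=True)
class TwoByTwo:
    """2x2 contingency counts: rows exposed/unexposed, columns outcome yes/no.

    Layout: a = exposed & outcome, b = exposed & no outcome,
    c = unexposed & outcome, d = unexposed & no outcome.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])


@dataclass
class AssociationResult:
    table: TwoByTwo
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    test: str
    ci_level: float = 0.95
    note: str = ""


def odds_ratio(table: TwoByTwo) -> float:
    """(a*d)/(b*c) with degenerate tables mapped to 0, inf or NaN.

    b*c = 0 with a*d > 0 -> inf; a*d = 0 with b*c > 0 -> 0; both zero ->
    NaN (undefined).  Degenerate states are values, not exceptions, matching
    how sparse rare-variant tables are reported.
    """
    ad = table.a * table.d
    bc = table.b * table.c
    if bc == 0:
        return math.inf if ad > 0 else math.nan
    return ad / bc


def odds_ratio_from_prevalence(p_exposed: float, p_unexposed: float) -> float:
    """Carrier odds ratio from two printed prevalences (fractions in [0, 1))."""
    for p in (p_exposed, p_unexposed):
        if not 0 <= p < 1:
            raise ValueError("prevalences must be in [0, 1)")
    if p_unexposed == 0:
        return math.inf if p_exposed > 0 else math.nan
    return (p_exposed / (1 - p_exposed)) / (p_unexposed / (1 - p_unexposed))


def fisher_exact_two_tailed(table: TwoByTwo) -> float:
    """Two-tailed Fisher exact p-value.

    Conditioning on the margins, the first cell follows a hypergeometric
    law; the two-tailed p sums the probabilities of all tables whose
    probability does not exceed the observed one (with a tiny relative
    slack so exact ties computed in floating point are included).
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    n = table.total
    if n == 0:
        return 1.0
    r = a + b  # first row margin
    m = a + c  # first column margin
    lo = max(0, r + m - n)
    hi = min(r, m)
    ks = np.arange(lo, hi + 1)
    logw = (
        gammaln(r + 1) - gammaln(ks + 1) - gammaln(r - ks + 1)
        + gammaln(n - r + 1) - gammaln(m - ks + 1)
        - gammaln(n - r - m + ks + 1)
    )
    w = np.exp(logw - logw.max())
    observed = w[a - lo]
    p = float(w[w <= observed * (1.0 + 1e-9)].sum() / w.sum())
    return min(p, 1.0)


def chi_square_p(table: TwoByTwo, correction: bool = False) -> float:
    """Pearson chi-square two-tailed p (1 df); Yates correction optional."""
    arr = table.as_array()
    if arr.sum() == 0 or np.any(arr.sum(axis=0) == 0) or np.any(
        arr.sum(axis=1) == 0
    ):
        raise ValueError(
            "zero expected count: use fisher_exact_two_tailed instead"
        )
    result = stats.chi2_contingency(arr, correction=correction)
    return float(result.pvalue)


def woolf_ci(
    table: TwoByTwo, level: float = 0.95
) -> tuple[float, float]:
    """Woolf (log-OR normal) confidence interval; undefined with a zero cell."""
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    if min(table.a, table.b, table.c, table.d) == 0:
        return (math.nan, math.nan)
    log_or = math.log(odds_ratio(table))
    se = math.sqrt(1 / table.a + 1 / table.b + 1 / table.c + 1 / table.d)
    z = stats.norm.ppf(0.5 + level / 2)
    return (math.exp(log_or - z * se), math.exp(log_or + z * se))


# ---------------------------------------------------------------------------
# Variant panels and genotype classification


@dataclass
class PanelVariant:
    """One panel variant: its class and an optional cis-phase rule.

    A cis rule re-classifies the variant when a phase flag column is true
    for the subject (e.g. R117H counts as CF only in cis with the intron-8
    T5 allele; unphased carriers keep the base class).
    """

    name: str
    vclass: str  # "CF" | "BD" | "other"
    phase_column: str | None = None
    class_if_cis: str | None = None

    def __post_init__(self) -> None:
        if self.vclass not in ("CF", "BD", "other"):
            raise ValueError(f"unknown variant class {self.vclass!r}")


@dataclass
class VariantPanel:
    variants: dict[str, PanelVariant] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, var in self.variants.items():
            if name != var.name:
                raise ValueError("panel key must equal variant name")

    @classmethod
    def from_dict(cls, spec: dict) -> "VariantPanel":
        variants = {}
        for name, entry in spec["variants"].items():
            if isinstance(entry, str):
                entry = {"class": entry}
            variants[name] = PanelVariant(
                name=name,
                vclass=entry["class"],
                phase_column=entry.get("phase_column"),
                class_if_cis=entry.get("class_if_cis"),
            )
        return cls(variants)

    def effective_class(self, variant: str, record: pd.Series) -> str:
        var = self.variants[variant]
        if var.phase_column is not None:
            phased = record.get(var.phase_column)
            if phased is None or pd.isna(phased):
                if var.class_if_cis != var.vclass:
                    logger.warning(
                        "unphased %s carrier: defaulting to class %s",
                        variant, var.vclass,
                    )
            elif bool(phased):
                return var.class_if_cis or var.vclass
        return var.vclass


def default_panel() -> VariantPanel:
    """The 43-variant pancreatitis screening panel with its class labels."""
    bd = ["R74Q", "R75Q", "R170H", "L967S", "L997F", "D1152H", "S1235R",
          "D1270N"]
    cf = ["F508del", "2789+5G>A", "3849+10kbC>T", "N1303K", "621+1G>T",
          "2184delA", "3120+1G>A", "G551D", "W1282X", "G542X", "R1162X",
          "2183AA>G"]
    other = ["M470V", "T854T", "Q1463Q", "1001+11C>T", "125G>C", "P1290P",
             "1716G>A", "R668C", "G576A", "F508C", "R1162L", "I1027T",
             "R31C", "I148T", "R297Q", "R74W", "F1052V", "I807M", "R258G",
             "G1069R", "V201M"]
    variants = {name: PanelVariant(name, "BD") for name in bd}
    variants |= {name: PanelVariant(name, "CF") for name in cf}
    variants |= {name: PanelVariant(name, "other") for name in other}
    # R117H is BD on its own and CF only in cis with the intron-8 T5 allele.
    variants["R117H"] = PanelVariant(
        "R117H", "BD", phase_column="r117h_t5_cis", class_if_cis="CF"
    )
    # IVS8-T5 is pathogenic (CF) only under its own cis rule (with R117H or
    # a TG12/13 tract); otherwise it does not count toward any risk class.
    variants["IVS8T5"] = PanelVariant(
        "IVS8T5", "other", phase_column="ivs8_t5_cis_pathogenic",
        class_if_cis="CF",
    )
    return VariantPanel(variants)


def _allele_counts_by_class(
    record: pd.Series, panel: VariantPanel
) -> tuple[int, int]:
    n_cf = 0
    n_bd = 0
    for name in record.index:
        if name in META_COLUMNS:
            continue
        if name not in panel.variants:
            raise KeyError(f"variant {name!r} not in panel")
        count = record[name]
        if pd.isna(count) or count == 0:
            continue
        count = int(count)
        if count not in (1, 2):
            raise ValueError(f"allele count for {name} must be 0/1/2")
        eff = panel.effective_class(name, record)
        if eff == "CF":
            n_cf += count
        elif eff == "BD":
            n_bd += count
    return n_cf, n_bd


def classify_subject(record: pd.Series, panel: VariantPanel) -> str:
    """Assign one genotype class with precedence
    recessive > trans-het > single-class carrier > none."""
    n_cf, n_bd = _allele_counts_by_class(record, panel)
    n34s = record.get("spink1_n34s", 0)
    n34s = 0 if pd.isna(n34s) else int(n34s)
    if n_cf + n_bd >= 2 and n_bd >= 1:
        return "CFBD_or_BDBD_recessive"
    if n34s == 1 and n_cf + n_bd >= 1:
        return "transhet_N34S"
    if n_cf >= 1:
        return "CF_carrier"
    if n_bd >= 1:
        return "BD_carrier"
    return "none"


def classify_cohort(
    cohort: pd.DataFrame, panel: VariantPanel
) -> pd.DataFrame:
    """Annotate a cohort table with per-subject class and allele tallies.

    Adds columns ``genotype_class``, ``n_cf_alleles``, ``n_bd_alleles``.
    """
    out = cohort.copy()
    tallies = [
        _allele_counts_by_class(row, panel) for _, row in cohort.iterrows()
    ]
    out["n_cf_alleles"] = [t[0] for t in tallies]
    out["n_bd_alleles"] = [t[1] for t in tallies]
    out["genotype_class"] = [
        classify_subject(row, panel) for _, row in cohort.iterrows()
    ]
    return out


def build_two_by_two(
    cohort: pd.DataFrame,
    exposure: pd.Series,
    outcome: pd.Series,
) -> TwoByTwo:
    """Count a 2x2 table from boolean exposure/outcome series.

    Subjects with a missing value in either predicate are excluded listwise
    (the exclusion count is logged).  Zero cells are allowed; an empty
    margin is a warning condition handled downstream by the statistics.
    """
    valid = exposure.notna() & outcome.notna()
    n_excluded = int((~valid).sum())
    if n_excluded:
        logger.info("build_two_by_two: excluded %d subject(s) with missing "
                    "values", n_excluded)
    e = exposure[valid].astype(bool)
    o = outcome[valid].astype(bool)
    return TwoByTwo(
        a=int((e & o).sum()),
        b=int((e & ~o).sum()),
        c=int((~e & o).sum()),
        d=int((~e & ~o).sum()),
    )


def associate(table: TwoByTwo, ci_level: float = 0.95) -> AssociationResult:
    """Odds ratio, Woolf CI and a p-value for a 2x2 table.

    Test choice follows the usual rule of thumb: Fisher's exact test when
    any expected count is below 5, Pearson chi-square otherwise.
    """
    arr = table.as_array().astype(float)
    note = ""
    if arr.sum() == 0:
        return AssociationResult(table, math.nan, math.nan, math.nan,
                                 math.nan, "none", ci_level, "empty table")
    expected = np.outer(arr.sum(axis=1), arr.sum(axis=0)) / arr.sum()
    if np.any(expected < 5):
        p = fisher_exact_two_tailed(table)
        test = "fisher"
    else:
        p = chi_square_p(table)
        test = "chi2"
    or_ = odds_ratio(table)
    low, high = woolf_ci(table, ci_level)
    if math.isnan(low):
        note = "CI undefined (zero cell)"
    return AssociationResult(table, or_, low, high, p, test, ci_level, note)


def trans_het_association(
    cohort: pd.DataFrame,
    variant: str,
    panel: VariantPanel,
    phenotype: str | None = None,
) -> AssociationResult:
    """Variant enrichment among SPINK1 N34S-heterozygous cases.

    Exposure contrasts carriers of ``variant`` among N34S-heterozygous
    cases against carriers among all controls (only heterozygotes are
    informative: a homozygous N34S genotype is a sufficient risk genotype
    by itself).
    """
    if "spink1_n34s" not in cohort.columns:
        raise ValueError("cohort lacks SPINK1 N34S genotypes")
    if variant not in panel.variants:
        raise KeyError(f"variant {variant!r} not in panel")
    cases = cohort[(cohort["status"] == "case")
                   & (cohort["spink1_n34s"] == 1)]
    controls = cohort[cohort["status"] == "control"]
    if cases.empty:
        return AssociationResult(
            TwoByTwo(0, 0, 0, 0), math.nan, math.nan, math.nan, math.nan,
            "none", note="no N34S-heterozygous cases",
        )
    a = int((cases[variant] >= 1).sum())
    b = int(len(cases) - a)
    c = int((controls[variant] >= 1).sum())
    d = int(len(controls) - c)
    return associate(TwoByTwo(a, b, c, d))


_CLASS_SELECTORS = {
    "all": lambda df: pd.Series(True, index=df.index),
    "none": lambda df: (df["n_cf_alleles"] + df["n_bd_alleles"]) == 0,
    "one_cf": lambda df: (df["n_cf_alleles"] == 1) & (df["n_bd_alleles"] == 0),
    "one_bd": lambda df: (df["n_bd_alleles"] == 1) & (df["n_cf_alleles"] == 0),
    "one_cf_or_bd": lambda df: (df["n_cf_alleles"] + df["n_bd_alleles"]) == 1,
    "recessive": lambda df: (
        (df["n_cf_alleles"] + df["n_bd_alleles"] >= 2)
        & (df["n_bd_alleles"] >= 1)
    ),
}


def phenotype_association(
    cohort: pd.DataFrame,
    genotype_class: str,
    phenotype: str,
    panel: VariantPanel | None = None,
) -> AssociationResult:
    """Phenotype odds ratio for cases of a genotype class vs all controls.

    ``genotype_class`` selects the case subgroup: "all", "none" (no panel
    variant), "one_cf", "one_bd", "one_cf_or_bd" or "recessive".  The 2x2
    table contrasts phenotype prevalence in that case subgroup against all
    controls; subjects with a missing phenotype flag are excluded listwise.
    """
    if genotype_class not in _CLASS_SELECTORS:
        raise ValueError(
            f"genotype_class must be one of {sorted(_CLASS_SELECTORS)}"
        )
    if "n_cf_alleles" not in cohort.columns:
        if panel is None:
            panel = default_panel()
        cohort = classify_cohort(cohort, panel)
    cases = cohort[cohort["status"] == "case"]
    controls = cohort[cohort["status"] == "control"]
    sub = cases[_CLASS_SELECTORS[genotype_class](cases)]
    if sub.empty:
        return AssociationResult(
            TwoByTwo(0, 0, 0, 0), math.nan, math.nan, math.nan, math.nan,
            "none", note=f"no cases in class {genotype_class!r}",
        )
    pheno_cases = sub[phenotype]
    pheno_controls = controls[phenotype]
    n_missing = int(pheno_cases.isna().sum() + pheno_controls.isna().sum())
    if n_missing:
        logger.info("phenotype_association: %d subject(s) missing %s flag "
                    "excluded", n_missing, phenotype)
    a = int(pheno_cases.fillna(False).astype(bool).sum())
    b = int(pheno_cases.notna().sum()) - a
    c = int(pheno_controls.fillna(False).astype(bool).sum())
    d = int(pheno_controls.notna().sum()) - c
    return associate(TwoByTwo(a, b, c, d))
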