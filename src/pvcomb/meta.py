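"""Two-stage meta-analysis of odds ratios via p-value combination.

Each study reports an odds ratio (OR) with a 95% confidence interval
(L, U).  On the log scale the standard error is recovered from the CI
width, ln(U/L)/3.92, giving the per-study z-score

    z = ln(OR) / (ln(U/L) / 3.92),

asymptotically N(0,1) under the study's null (OR = 1).  Each study then
yields three p-values -- left-sided Phi(z) (protective effect), right-sided
1 - Phi(z) (harmful/beneficial, OR > 1), two-sided 2 Phi(-|z|).

Stage 1 combines the independent studies' left-sided p-values, right-sided
p-values, and two-sided p-values separately with MinP (Sidak), Fisher, and
Stouffer's z-test.  Stage 2 combines the two *dependent* p-values from the
left and right sets (they come from the same data) with the
dependence-robust combiners: CCT, MinP (Bonferroni), MCM, and CMC.  All
stage-2 inputs are taken at full precision; rounding happens only when
formatting reports.

An alternative z formula, ``midpoint`` (z = 1.96 ln(U*L)/ln(U/L), using
the CI midpoint on the log scale instead of ln OR), is provided for
comparison; with rounded published ORs the two differ slightly and
``log_or`` is the default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from importlib import resources
from math import log

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .combine import (
    PValueVector,
    cct_pvalue,
    cmc_pvalue,
    fisher_pvalue,
    mcm_pvalue,
    minp_pvalue,
    stouffer_pvalue,
)

__all__ = [
    "StudyRecord",
    "MetaTable",
    "or_ci_to_z",
    "study_pvalues",
    "load_studies",
    "geriatric_rehab_studies",
    "run_meta_pipeline",
]

_FORMULAS = ("log_or", "midpoint")

#: packaged 12-trial geriatric-rehabilitation meta-analysis (OR + 95% CI)
FIXTURE_NAME = "geriatric_rehab_12.csv"


@dataclass(frozen=True)
class StudyRecord:
    """One meta-analysis row: the published OR and CI, and derived p-values."""

    label: str
    odds_ratio: float
    ci_lower: float
    ci_upper: float
    z: float | None = None
    p_left: float | None = None
    p_right: float | None = None
    p_two: float | None = None

    def __post_init__(self):
        if min(self.odds_ratio, self.ci_lower, self.ci_upper) <= 0:
            raise ValueError(
                f"study {self.label!r}: OR and CI bounds must be positive "
                f"(got OR={self.odds_ratio}, CI=({self.ci_lower}, {self.ci_upper}))"
            )
        if self.ci_lower >= self.ci_upper:
            raise ValueError(f"study {self.label!r}: CI lower bound must be below upper bound")
        if not self.ci_lower <= self.odds_ratio <= self.ci_upper:
            # published values are rounded, so warn rather than reject
            warnings.warn(
                f"study {self.label!r}: OR {self.odds_ratio} outside its CI "
                f"({self.ci_lower}, {self.ci_upper})",
                stacklevel=2,
            )


def or_ci_to_z(
    odds_ratio: float, ci_lower: float, ci_upper: float, formula: str = "log_or"
) -> float:
    """z-score of one study from its OR and 95% CI.

    ``log_or``: z = ln(OR) / (ln(U/L)/3.92); ``midpoint`` replaces ln(OR)
    with the CI midpoint on the log scale, ln(U*L)/2.
    """
    if formula not in _FORMULAS:
        raise ValueError(f"unknown formula {formula!r}; expected one of {_FORMULAS}")
    if min(odds_ratio, ci_lower, ci_upper) <= 0:
        raise ValueError("OR and CI bounds must be positive")
    if ci_lower >= ci_upper:
        raise ValueError("CI lower bound must be below upper bound")
    se = log(ci_upper / ci_lower) / 3.92
    num = log(odds_ratio) if formula == "log_or" else 0.5 * log(ci_upper * ci_lower)
    return num / se


def study_pvalues(record: StudyRecord, formula: str = "log_or") -> StudyRecord:
    """Fill in z and the three p-values of one study.

    The smaller of the two one-sided p-values is computed directly and the
    other as its exact floating-point complement, so p_left + p_right == 1.
    """
    z = or_ci_to_z(record.odds_ratio, record.ci_lower, record.ci_upper, formula=formula)
    small = float(ndtr(-abs(z)))
    large = 1.0 - small
    p_left, p_right = (small, large) if z <= 0 else (large, small)
    return replace(record, z=z, p_left=p_left, p_right=p_right,
                   p_two=min(1.0, 2.0 * small))


@dataclass
class MetaTable:
    """Output of the two-stage pipeline.

    ``studies``: one row per study with z and the three p-values.
    ``combined``: one row per stage-1 combiner (MinP, Fisher, StoufferZ)
    with its left/right/two-sided combined p-values and the four stage-2
    combinations of the dependent (left, right) pair.
    """

    studies: pd.DataFrame
    combined: pd.DataFrame

    def cell(self, stage1: str, column: str) -> float:
        return float(self.combined.loc[self.combined.method == stage1, column].iloc[0])


def load_studies(path) -> list[StudyRecord]:
    """Read a CSV with header ``study,or,ci_lower,ci_upper``."""
    df = pd.read_csv(path)
    df.columns = [c.strip().lower() for c in df.columns]
    required = {"study", "or", "ci_lower", "ci_upper"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing required columns {sorted(missing)} in {path}")
    records = []
    for i, row in enumerate(df.to_dict("records")):  # keeps per-column dtypes
        try:
            records.append(StudyRecord(
                label=str(row["study"]),
                odds_ratio=float(row["or"]),
                ci_lower=float(row["ci_lower"]),
                ci_upper=float(row["ci_upper"]),
            ))
        except (TypeError, ValueError) as exc:
            raise ValueError(f"row {i + 2} of {path}: {exc}") from exc
    return records


def geriatric_rehab_studies() -> list[StudyRecord]:
    """The packaged 12-trial geriatric-rehabilitation fixture."""
    with resources.files("pvcomb.data").joinpath(FIXTURE_NAME).open("rb") as fh:
        return load_studies(fh)


def run_meta_pipeline(
    records: list[StudyRecord],
    formula: str = "log_or",
    stage1_minp_mode: str = "sidak",
    stage2_minp_mode: str = "bonferroni",
) -> MetaTable:
    """Run the full two-stage combination over a list of studies."""
    if not records:
        raise ValueError("the meta pipeline needs at least one study")
    filled = [study_pvalues(r, formula=formula) for r in records]
    studies = pd.DataFrame({
        "study": [r.label for r in filled],
        "or": [r.odds_ratio for r in filled],
        "ci_lower": [r.ci_lower for r in filled],
        "ci_upper": [r.ci_upper for r in filled],
        "z": [r.z for r in filled],
        "p_left": [r.p_left for r in filled],
        "p_right": [r.p_right for r in filled],
        "p_two": [r.p_two for r in filled],
    })

    sets = {side: np.array(studies["p_" + side]) for side in ("left", "right", "two")}
    stage1 = {
        "MinP": lambda p: minp_pvalue(p, mode=stage1_minp_mode).pvalue,
        "Fisher": lambda p: fisher_pvalue(p).pvalue,
        "StoufferZ": lambda p: stouffer_pvalue(p).pvalue,
    }
    rows = []
    for name, combine in stage1.items():
        left, right, two = (combine(sets[s]) for s in ("left", "right", "two"))
        pair = PValueVector([left, right])
        rows.append({
            "method": name,
            "left": left, "right": right, "two": two,
            "cct": cct_pvalue(pair).pvalue,
            "minp": minp_pvalue(pair, mode=stage2_minp_mode).pvalue,
            "mcm": mcm_pvalue(pair, minp_mode=stage2_minp_mode).pvalue,
            "cmc": cmc_pvalue(pair, minp_mode=stage2_minp_mode).pvalue,
        })
    return MetaTable(studies=studies, combined=pd.DataFrame(rows))
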