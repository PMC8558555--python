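"""Cohort-level statistics: prevalence tables, correlations, two-group
tests, and disease-free-survival stratification.

Survival analysis is the downstream clinical readout: Kaplan–Meier
curves with per-group median DFS (explicitly "unreached" when the curve
never crosses 0.5), the log-rank test, univariate Cox proportional
hazards with a Wald confidence interval, and a multivariate Cox model
built by forward likelihood-ratio selection (entry p = 0.05) over the
standard clinicopathologic covariates.  Cox ties use the Efron
approximation.  No multiple-testing correction is applied anywhere;
p-values are reported as computed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats as sps

from .calls import SpecimenProfile

#: covariates eligible for the multivariate Cox model, in entry-scan order
COX_COVARIATES = [
    "stage_ii_iv",
    "tumor_size_gt4cm",
    "poor_differentiation",
    "lymph_node",
    "nerve_invasion",
    "vascular_invasion",
    "adjuvant_chemo",
]


@dataclass
class ClinicalRecord:
    """Per-patient covariates and disease-free-survival outcome."""

    patient_id: str
    age: float
    sex: str  # "M" / "F"
    stage_ii_iv: bool
    tumor_size_gt4cm: bool
    poor_differentiation: bool
    lymph_node: bool
    nerve_invasion: bool
    vascular_invasion: bool
    adjuvant_chemo: bool
    tcf: float
    dfs_months: float
    event: bool

    def __post_init__(self) -> None:
        if self.dfs_months < 0:
            raise ValueError("dfs_months must be nonnegative")


@dataclass
class SurvivalResult:
    """Result of a two-group DFS comparison."""

    grouping: str
    group_labels: tuple[str, str]
    group_sizes: tuple[int, int]
    median_dfs: tuple[Optional[float], Optional[float]]  # None = unreached
    hazard_ratio: float
    hr_ci: tuple[float, float]
    logrank_p: float
    cox_p: float
    multivariate: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        lo, hi = self.hr_ci
        if not lo <= self.hazard_ratio <= hi:
            raise ValueError("CI must bracket the hazard ratio estimate")


def clinical_to_frame(records: Sequence[ClinicalRecord]) -> pd.DataFrame:
    rows = [vars(r).copy() for r in records]
    df = pd.DataFrame(rows)
    df["event"] = df["event"].astype(int)
    for col in COX_COVARIATES:
        df[col] = df[col].astype(int)
    return df


def prevalence_table(
    profiles: Sequence[SpecimenProfile], denominator: Optional[int] = None
) -> pd.DataFrame:
    """Per-gene patient counts and percentages for one component.

    A patient counts once per gene regardless of how many distinct
    mutations they carry in it.  ``denominator`` defaults to the number
    of profiles passed (use all sequenced patients for the neoplasm and
    the mutant-stroma patients for the stroma, mirroring how prevalence
    is usually quoted for each component).
    """
    if not profiles:
        raise ValueError("prevalence_table needs >=1 profile")
    if denominator is None:
        denominator = len(profiles)
    counts: dict[str, set[str]] = {}
    for p in profiles:
        for m in p.mutations:
            counts.setdefault(m.gene.upper(), set()).add(p.patient_id)
    rows = [
        {
            "gene": gene,
            "n_patients": len(patients),
            "percent": 100.0 * len(patients) / denominator,
        }
        for gene, patients in counts.items()
    ]
    df = pd.DataFrame(rows, columns=["gene", "n_patients", "percent"])
    return df.sort_values(
        ["n_patients", "gene"], ascending=[False, True]
    ).reset_index(drop=True)


def vaf_correlation(pairs: Sequence[tuple[float, float]]) -> tuple[float, float, float]:
    """Spearman rank correlation of paired VAFs (e.g. KRAS vs TP53).

    Returns ``(rho, rho_squared, p)`` with a two-sided p-value; requires
    at least three pairs.
    """
    if len(pairs) < 3:
        raise ValueError("need >=3 co-mutant specimens for a rank correlation")
    x, y = zip(*pairs)
    res = sps.spearmanr(x, y)
    rho = float(res.statistic)
    return rho, rho * rho, float(res.pvalue)


def group_compare(
    groups: Sequence[Sequence[float]] | np.ndarray,
    test: str = "mann_whitney",
) -> tuple[float, float]:
    """Two-group comparison: Mann–Whitney U or Pearson chi-square.

    ``mann_whitney`` takes two sequences of continuous values (TCF,
    mutation burden) and uses the tie-corrected two-sided test.
    ``chi_square`` takes a 2x2 count table and uses the Pearson
    statistic without continuity correction.
    """
    if test == "mann_whitney":
        if len(groups) != 2 or not all(len(g) for g in groups):
            raise ValueError("mann_whitney needs two nonempty groups")
        res = sps.mannwhitneyu(groups[0], groups[1], alternative="two-sided")
        return float(res.statistic), float(res.pvalue)
    if test == "chi_square":
        table = np.asarray(groups, dtype=float)
        if table.shape != (2, 2):
            raise ValueError("chi_square expects a 2x2 count table")
        chi2, p, _, _ = sps.chi2_contingency(table, correction=False)
        return float(chi2), float(p)
    raise ValueError(f"unknown test {test!r}")


def _km_median(durations: np.ndarray, events: np.ndarray) -> Optional[float]:
    kmf = KaplanMeierFitter()
    kmf.fit(durations, events)
    median = kmf.median_survival_time_
    return None if np.isinf(median) else float(median)


def km_curve(durations: Sequence[float], events: Sequence[bool]) -> pd.DataFrame:
    """Product-limit survival curve as a (time, survival) table."""
    kmf = KaplanMeierFitter()
    kmf.fit(np.asarray(durations, dtype=float), np.asarray(events, dtype=int))
    df = kmf.survival_function_.reset_index()
    df.columns = ["time", "survival"]
    return df


def _forward_lr_cox(
    df: pd.DataFrame,
    candidates: Sequence[str],
    forced: Sequence[str],
    entry_p: float = 0.05,
) -> Optional[pd.DataFrame]:
    """Forward likelihood-ratio covariate selection for a Cox model.

    Starts from the forced covariates (the grouping under study) and at
    each step admits the candidate with the largest significant LR-test
    improvement (chi-square with 1 df, entry p < ``entry_p``).
    """

    def fit(cols: Sequence[str]) -> Optional[CoxPHFitter]:
        if not cols:
            return None
        cph = CoxPHFitter()
        cph.fit(
            df[list(cols) + ["dfs_months", "event"]],
            duration_col="dfs_months",
            event_col="event",
        )
        return cph

    selected = list(forced)
    current = fit(selected)
    if current is None:
        return None
    remaining = [c for c in candidates if c not in selected]
    while remaining:
        best_gain, best_col, best_fit = 0.0, None, None
        for col in remaining:
            if df[col].nunique() < 2:
                continue
            try:
                trial = fit(selected + [col])
            except Exception:
                continue
            gain = 2.0 * (trial.log_likelihood_ - current.log_likelihood_)
            if gain > best_gain:
                best_gain, best_col, best_fit = gain, col, trial
        if best_col is None or sps.chi2.sf(best_gain, df=1) >= entry_p:
            break
        selected.append(best_col)
        remaining.remove(best_col)
        current = best_fit
    return current.summary.copy()


def survival_analysis(
    records: Sequence[ClinicalRecord],
    group_flags: dict[str, bool],
    grouping: str = "neoplasm_like",
    multivariate: bool = False,
    entry_p: float = 0.05,
    min_followup_months: Optional[float] = None,
) -> SurvivalResult:
    """Stratify DFS by a binary genomic status.

    ``group_flags`` maps patient_id to the flag under study
    (neoplasm-like stroma, stromal KRAS, stromal TP53, ...).  With
    ``min_followup_months`` set, censored patients followed for less
    than that horizon are excluded (events always stay).  Requires two
    nonempty groups and at least one relapse event overall.
    """
    recs = [r for r in records if r.patient_id in group_flags]
    if min_followup_months is not None:
        recs = [r for r in recs if r.event or r.dfs_months >= min_followup_months]
    df = clinical_to_frame(recs)
    if df.empty or df["event"].sum() == 0:
        raise ValueError("survival analysis needs >=1 observed event")
    df["group"] = df["patient_id"].map(group_flags).astype(int)
    if df["group"].nunique() < 2:
        raise ValueError("survival analysis needs two nonempty groups")

    pos = df[df["group"] == 1]
    neg = df[df["group"] == 0]
    medians = (
        _km_median(pos["dfs_months"].to_numpy(), pos["event"].to_numpy()),
        _km_median(neg["dfs_months"].to_numpy(), neg["event"].to_numpy()),
    )
    lr = logrank_test(
        pos["dfs_months"], neg["dfs_months"], pos["event"], neg["event"]
    )

    cph = CoxPHFitter()
    cph.fit(
        df[["group", "dfs_months", "event"]],
        duration_col="dfs_months",
        event_col="event",
    )
    def safe_exp(x: float) -> float:
        # complete separation can push the Cox coefficient past exp() range
        try:
            return float(math.exp(x))
        except OverflowError:
            return float("inf")

    row = cph.summary.loc["group"]
    hr = safe_exp(row["coef"])
    ci = (safe_exp(row["coef lower 95%"]), safe_exp(row["coef upper 95%"]))

    multi = None
    if multivariate:
        multi = _forward_lr_cox(df, COX_COVARIATES, forced=["group"], entry_p=entry_p)

    return SurvivalResult(
        grouping=grouping,
        group_labels=(f"{grouping}+", f"{grouping}-"),
        group_sizes=(len(pos), len(neg)),
        median_dfs=medians,
        hazard_ratio=hr,
        hr_ci=ci,
        logrank_p=float(lr.p_value),
        cox_p=float(row["p"]),
        multivariate=multi,
    )
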