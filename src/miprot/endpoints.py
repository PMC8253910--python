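"""Urine analyte and serum creatinine endpoint statistics.

Urinary analyte concentrations are normalized to urinary creatinine,
expressed per animal as POD3 fold change over baseline, and compared
between arms with an exact Mann-Whitney test (the group sizes of 4-5
make full enumeration the default).  Longitudinal serum creatinine is
modelled as a quadratic in time with a treatment term; the treatment
effect is assessed by an extra-sum-of-squares F-test of the full model
against the model lacking every treatment term.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import f as f_dist
from scipy.stats import mannwhitneyu

from .errors import UserInputError

EXACT_MAX_N = 12  # combined size up to which the exact null is enumerated


def normalize_and_fold_change(records: pd.DataFrame) -> pd.DataFrame:
    """Per-animal POD3 fold change over baseline of conc/creatinine.

    ``records`` holds one analyte with columns animal_id, group,
    timepoint, concentration, urinary_creatinine.  Animals missing the
    baseline or POD3 record are excluded with a warning; a zero baseline
    ratio is an error.
    """
    required = {"animal_id", "group", "timepoint", "concentration", "urinary_creatinine"}
    missing = required - set(records.columns)
    if missing:
        raise UserInputError(f"analyte table missing columns: {sorted(missing)}")
    if (records["urinary_creatinine"] <= 0).any():
        raise UserInputError("urinary creatinine must be positive")
    ratio = records["concentration"] / records["urinary_creatinine"]
    records = records.assign(ratio=ratio)
    rows = []
    for animal, sub in records.groupby("animal_id"):
        by_tp = sub.set_index("timepoint")["ratio"]
        if "BL" not in by_tp.index or "POD3" not in by_tp.index:
            warnings.warn(f"animal {animal!r} lacks BL or POD3; excluded", stacklevel=2)
            continue
        baseline = float(by_tp["BL"])
        if baseline == 0:
            raise UserInputError(f"zero baseline ratio for animal {animal!r}")
        rows.append(
            {
                "animal_id": animal,
                "group": sub["group"].iloc[0],
                "fold_change": float(by_tp["POD3"]) / baseline,
            }
        )
    return pd.DataFrame(rows, columns=["animal_id", "group", "fold_change"])


@dataclass(frozen=True)
class MannWhitneyResult:
    u_statistic: float
    p_value: float
    method: str  # "exact" or "asymptotic"


def mann_whitney(group_a, group_b) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U.

    Exact enumeration when the combined sample is small (<= 12) and
    tie-free, tie-corrected normal approximation otherwise; the result
    records which path was taken.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise UserInputError("both groups must be nonempty")
    combined = np.concatenate([a, b])
    has_ties = np.unique(combined).size < combined.size
    exact = (a.size + b.size) <= EXACT_MAX_N and not has_ties
    method = "exact" if exact else "asymptotic"
    res = mannwhitneyu(a, b, alternative="two-sided", method=method)
    return MannWhitneyResult(float(res.statistic), float(res.pvalue), method)


@dataclass(frozen=True)
class PolynomialTestResult:
    """Treatment-term F-test of the quadratic creatinine model."""

    f_treatment: float
    p_treatment: float
    df_treatment: tuple[int, int]
    f_model: float
    p_model: float
    n_observations: int


def creatinine_polynomial_test(
    series: pd.DataFrame, include_interactions: bool = False
) -> PolynomialTestResult:
    """F-test for treatment in creatinine ~ treatment + day + day^2.

    ``series`` has columns animal_id, group, day, serum_creatinine with
    one value per (animal, day).  ``include_interactions`` adds
    treatment x day and treatment x day^2 terms; the test then compares
    against the model lacking all three treatment terms.  Also reports
    the whole-model F against the intercept-only model.
    """
    required = {"animal_id", "group", "day", "serum_creatinine"}
    missing = required - set(series.columns)
    if missing:
        raise UserInputError(f"series table missing columns: {sorted(missing)}")
    if series.duplicated(subset=["animal_id", "day"]).any():
        raise UserInputError("more than one value per (animal, day)")
    groups = sorted(series["group"].unique())
    if len(groups) != 2:
        raise UserInputError(f"need exactly two treatment groups, got {groups}")
    for g in groups:
        if series.loc[series["group"] == g, "animal_id"].nunique() < 2:
            raise UserInputError(f"fewer than 2 animals in group {g!r}")
    if series["day"].nunique() < 3:
        raise UserInputError("need at least 3 distinct days to fit day + day^2")

    y = series["serum_creatinine"].to_numpy(dtype=float)
    day = series["day"].to_numpy(dtype=float)
    treat = (series["group"] == groups[1]).to_numpy(dtype=float)
    base_cols = {"day": day, "day2": day**2}
    treat_cols = {"treatment": treat}
    if include_interactions:
        treat_cols["treatment:day"] = treat * day
        treat_cols["treatment:day2"] = treat * day**2

    def fit(cols: dict) -> sm.regression.linear_model.RegressionResultsWrapper:
        x = sm.add_constant(pd.DataFrame(cols), has_constant="add")
        rank = np.linalg.matrix_rank(x.to_numpy())
        if rank < x.shape[1]:
            raise UserInputError(
                f"rank-deficient design: collinear term among {list(x.columns)}"
            )
        return sm.OLS(y, x).fit()

    full = fit({**base_cols, **treat_cols})
    reduced = fit(base_cols)
    q = len(treat_cols)
    df_resid = int(full.df_resid)
    f_stat = ((reduced.ssr - full.ssr) / q) / (full.ssr / df_resid)
    p = float(f_dist.sf(f_stat, q, df_resid))
    return PolynomialTestResult(
        f_treatment=float(f_stat),
        p_treatment=p,
        df_treatment=(q, df_resid),
        f_model=float(full.fvalue),
        p_model=float(full.f_pvalue),
        n_observations=int(len(series)),
    )
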