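"""Covariate-adjusted cohort statistics on the outcome tables.

The statistical pipeline applied to every inflammation outcome:

1. assumption checks — Shapiro-Wilk normality per group and Levene
   homogeneity at alpha = 0.05; on failure a natural-log transform is
   applied (shifted when non-positive values are present);
2. a two-factor covariate-adjusted linear model
   ``value ~ group + roi + age + sex + fixation_interval`` with F tests for
   the group and ROI effects (equivalently, ANCOVA);
3. Bonferroni correction within outcome families (microglia, astroglia,
   perivascular), ``p_bonf = min(1, m * p_raw)``;
4. chi-square tests (no continuity correction) for categorical contrasts;
5. WMH-burden stratification by Fazekas score — mild (0-1) versus moderate
   to severe (2-3) — re-running the same adjusted model with the burden
   factor in place of group.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

logger = logging.getLogger(__name__)

ALPHA_ASSUMPTIONS = 0.05
LOG_SHIFT_EPS = 1e-6

#: Bonferroni families: outcomes corrected together, per report block
DEFAULT_FAMILIES = {
    "microglia": ["frequency_per_mm2", "area_pct", "intensity_pct",
                  "avg_length_um", "avg_circularity"],
    "astroglia": ["area_pct", "intensity_pct"],
    "perivascular": ["pct_with_inflammation", "pct_mild", "pct_moderate",
                     "pct_severe", "pct_close_range"],
}

COVARIATES = ["age", "sex", "fixation_interval_months"]


@dataclass(frozen=True)
class TestResult:
    outcome_name: str
    effect: str  # "group" | "roi" | "burden" | covariate names
    statistic: float
    df: tuple
    p_raw: float
    p_bonferroni: float
    transform_applied: bool
    n_used: int
    family_size: int = 1

    def as_dict(self) -> dict:
        return {
            "outcome_name": self.outcome_name, "effect": self.effect,
            "statistic": self.statistic, "df_num": self.df[0],
            "df_den": self.df[1], "p_raw": self.p_raw,
            "p_bonferroni": self.p_bonferroni,
            "transform_applied": self.transform_applied,
            "n_used": self.n_used, "family_size": self.family_size,
        }


def bonferroni(p_raw: float, m: int) -> float:
    return min(1.0, m * p_raw)


# ---------------------------------------------------------------------------
# assumption checks
# ---------------------------------------------------------------------------

def check_and_transform(values: np.ndarray, groups: np.ndarray):
    """Normality/homogeneity check with natural-log fallback.

    Shapiro-Wilk per group and Levene across groups at alpha = 0.05; when
    either fails, a natural log is applied — directly when all values are
    positive, otherwise as ``ln(x - min + eps)``.  Degenerate (constant)
    samples are returned untouched and flagged.

    Returns ``(values_out, transform_applied)``.
    """
    values = np.asarray(values, float)
    groups = np.asarray(groups)
    by_group = [values[groups == g] for g in np.unique(groups)]
    if any(len(v) < 3 for v in by_group):
        raise ValueError("need at least 3 values per group")
    if np.ptp(values) < 1e-12:
        logger.warning("constant outcome; assumption checks skipped (degenerate)")
        return values, False
    ok = True
    for v in by_group:
        if np.ptp(v) < 1e-12:
            continue
        if stats.shapiro(v).pvalue < ALPHA_ASSUMPTIONS:
            ok = False
            break
    if ok and stats.levene(*by_group).pvalue < ALPHA_ASSUMPTIONS:
        ok = False
    if ok:
        return values, False
    if values.min() > 0:
        return np.log(values), True
    shifted = values - values.min() + LOG_SHIFT_EPS
    logger.info("non-positive values; using shifted log transform")
    return np.log(shifted), True


# ---------------------------------------------------------------------------
# ANCOVA
# ---------------------------------------------------------------------------

def _drop_degenerate_covariates(df: pd.DataFrame, covariates) -> list:
    kept = []
    for cov in covariates:
        if df[cov].nunique() < 2:
            logger.warning("covariate %s has no variation; dropped", cov)
            continue
        kept.append(cov)
    return kept


def _fit_anova(df: pd.DataFrame, factor_term: str, covariates) -> tuple:
    rhs = [factor_term, "C(roi_name)"] if factor_term != "C(roi_name)" else [factor_term]
    for cov in covariates:
        rhs.append("C(sex)" if cov == "sex" else cov)
    model = smf.ols("value ~ " + " + ".join(rhs), data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)  # no interactions: type II == III
    return model, table


def ancova_group_roi(outcome_table: pd.DataFrame, outcome_name: str,
                     family_size: int = 1,
                     covariates=COVARIATES) -> list:
    """Adjusted two-factor ANOVA of one outcome: group and ROI effects.

    ``outcome_table`` is long format with columns ``group``, ``roi_name``,
    the covariates, and either a ``value`` column with
    ``outcome_name`` rows, or a column named ``outcome_name``.  Missing
    values are dropped; covariates without variation (e.g. a single-sex
    cohort) are dropped with a warning.  Returns group and ROI TestResults.
    """
    df = _extract(outcome_table, outcome_name)
    if df["group"].nunique() < 2 or df["roi_name"].nunique() < 2:
        raise ValueError("both groups and both ROIs must be represented")
    vals, transformed = check_and_transform(df["value"].to_numpy(),
                                            df["group"].to_numpy())
    df = df.assign(value=vals)
    covs = _drop_degenerate_covariates(df, list(covariates))
    _, table = _fit_anova(df, "C(group)", covs)
    out = []
    for effect, term in (("group", "C(group)"), ("roi", "C(roi_name)")):
        row = table.loc[term]
        p = float(row["PR(>F)"])
        out.append(TestResult(
            outcome_name=outcome_name, effect=effect,
            statistic=float(row["F"]),
            df=(int(row["df"]), int(table.loc["Residual", "df"])),
            p_raw=p, p_bonferroni=bonferroni(p, family_size),
            transform_applied=transformed, n_used=len(df),
            family_size=family_size))
    return out


def _extract(outcome_table: pd.DataFrame, outcome_name: str) -> pd.DataFrame:
    if "outcome_name" in outcome_table.columns and "value" in outcome_table.columns:
        df = outcome_table[outcome_table["outcome_name"] == outcome_name].copy()
    elif outcome_name in outcome_table.columns:
        df = outcome_table.rename(columns={outcome_name: "value"}).copy()
    else:
        raise KeyError(f"outcome {outcome_name!r} not found in table")
    df = df.dropna(subset=["value"])
    if len(df) == 0:
        raise ValueError(f"no finite values for outcome {outcome_name!r}")
    return df


# ---------------------------------------------------------------------------
# categorical contrasts
# ---------------------------------------------------------------------------

def chi_square_test(table, outcome_name: str = "categorical") -> TestResult:
    """Pearson chi-square on an r x c contingency table, no Yates correction."""
    arr = np.asarray(table, float)
    if arr.ndim != 2 or min(arr.shape) < 2:
        raise ValueError("contingency table must be at least 2x2")
    if np.any(arr < 0) or not np.allclose(arr, np.round(arr)):
        raise ValueError("counts must be nonnegative integers")
    if np.any(arr.sum(axis=0) == 0) or np.any(arr.sum(axis=1) == 0):
        raise ValueError("zero-margin contingency table")
    res = stats.chi2_contingency(arr, correction=False)
    return TestResult(outcome_name=outcome_name, effect="group",
                      statistic=float(res.statistic), df=(int(res.dof), 0),
                      p_raw=float(res.pvalue),
                      p_bonferroni=float(res.pvalue),
                      transform_applied=False, n_used=int(arr.sum()))


# ---------------------------------------------------------------------------
# WMH-burden stratification
# ---------------------------------------------------------------------------

def stratify_burden(subjects) -> dict:
    """Map subjects to WMH burden strata: Fazekas 0-1 mild, 2-3 moderate_severe."""
    out = {}
    for rec in subjects:
        fazekas = rec.fazekas if hasattr(rec, "fazekas") else int(rec["fazekas"])
        sid = rec.subject_id if hasattr(rec, "subject_id") else str(rec["subject_id"])
        out[sid] = "mild" if fazekas <= 1 else "moderate_severe"
    return out


def burden_analysis(outcome_table: pd.DataFrame, outcome_name: str,
                    family_size: int = 1, covariates=COVARIATES) -> list:
    """Same adjusted model with the burden stratum replacing group."""
    df = _extract(outcome_table, outcome_name)
    if "burden" not in df.columns:
        if "fazekas" not in df.columns:
            raise ValueError("table needs a 'burden' or 'fazekas' column")
        df["burden"] = np.where(df["fazekas"] <= 1, "mild", "moderate_severe")
    if df["burden"].nunique() < 2:
        raise ValueError("both burden strata must be nonempty")
    vals, transformed = check_and_transform(df["value"].to_numpy(),
                                            df["burden"].to_numpy())
    df = df.assign(value=vals)
    covs = _drop_degenerate_covariates(df, list(covariates))
    _, table = _fit_anova(df, "C(burden)", covs)
    row = table.loc["C(burden)"]
    p = float(row["PR(>F)"])
    return [TestResult(outcome_name=outcome_name, effect="burden",
                       statistic=float(row["F"]),
                       df=(int(row["df"]), int(table.loc["Residual", "df"])),
                       p_raw=p, p_bonferroni=bonferroni(p, family_size),
                       transform_applied=transformed, n_used=len(df),
                       family_size=family_size)]


# ---------------------------------------------------------------------------
# demographics
# ---------------------------------------------------------------------------

def demographics_table(subjects, wmh_volumes: dict | None = None,
                       continuous=("age", "fixation_interval_months"),
                       categorical=("sex",)) -> pd.DataFrame:
    """Cohort characteristics by group: mean +/- SD or n (%) with p values.

    Continuous rows are compared by one-way ANOVA, categorical rows by
    chi-square; rows with missing values are computed on the available n
    (reported per row).  Optional covariates in ``SubjectRecord.extra`` can
    be included by name; ``wmh_volumes`` (subject_id -> mL, from the
    semi-automatic MRI volumetry consumed as input) adds a WMH-volume row.
    """
    if len(subjects) < 2:
        raise ValueError("need at least 2 subjects")
    rows = []
    df = _subjects_frame(subjects)
    if wmh_volumes is not None:
        df["wmh_volume_ml"] = df["subject_id"].map(wmh_volumes)
        continuous = tuple(continuous) + ("wmh_volume_ml",)
    groups = sorted(df["group"].unique())
    for var in continuous:
        sub = df.dropna(subset=[var])
        samples = [sub.loc[sub["group"] == g, var].astype(float) for g in groups]
        if len(groups) == 2 and all(len(s) >= 2 for s in samples):
            if all(s.var() < 1e-24 for s in samples) and samples[0].mean() == samples[1].mean():
                p = 1.0
            else:
                p = float(stats.f_oneway(*samples).pvalue)
        else:
            p = float("nan")
        row = {"variable": var, "type": "continuous", "n": len(sub), "p": p}
        for g in groups:
            vals = sub.loc[sub["group"] == g, var].astype(float)
            row[f"{g}_mean"] = vals.mean()
            row[f"{g}_sd"] = vals.std(ddof=1)
        rows.append(row)
    for var in categorical:
        sub = df.dropna(subset=[var])
        tab = pd.crosstab(sub["group"], sub[var])
        try:
            p = float(stats.chi2_contingency(tab.to_numpy(), correction=False).pvalue)
        except ValueError:
            p = float("nan")
        row = {"variable": var, "type": "categorical", "n": len(sub), "p": p}
        for g in groups:
            counts = tab.loc[g] if g in tab.index else None
            if counts is not None and counts.sum() > 0:
                top = counts.index[np.argmax(counts.to_numpy())]
                row[f"{g}_n_pct"] = f"{top}: {counts.max()} ({100 * counts.max() / counts.sum():.1f}%)"
        rows.append(row)
    return pd.DataFrame(rows)


def _subjects_frame(subjects) -> pd.DataFrame:
    if isinstance(subjects, pd.DataFrame):
        return subjects
    rows = []
    for r in subjects:
        row = {"subject_id": r.subject_id, "group": r.group, "age": r.age,
               "sex": r.sex,
               "fixation_interval_months": r.fixation_interval_months,
               "fazekas": r.fazekas}
        row.update(getattr(r, "extra", {}))
        rows.append(row)
    return pd.DataFrame(rows)


def run_family(outcome_table: pd.DataFrame, family_name: str, outcomes,
               mode: str = "group_roi") -> list:
    """Run the adjusted model for every outcome in one Bonferroni family."""
    m = len(outcomes)
    results = []
    for name in outcomes:
        try:
            if mode == "group_roi":
                results.extend(ancova_group_roi(outcome_table, name, family_size=m))
            else:
                results.extend(burden_analysis(outcome_table, name, family_size=m))
        except (ValueError, KeyError) as exc:
            logger.warning("family %s outcome %s skipped: %s", family_name, name, exc)
    return results


def results_frame(results) -> pd.DataFrame:
    return pd.DataFrame([r.as_dict() for r in results])
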