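"""Psychometric evaluation of the movement sense test.

Implements the validity / reliability battery applied to pooled subject
outcomes: Shapiro-Wilk normality gating with Ln transform, one-way ANOVA
with Bonferroni post-hoc over the three groups (healthy controls CON,
idiopathic neck pain INP, traumatic neck pain TNP), ROC discriminative
analysis, Pearson correlation against the Neck Disability Index, and
test-retest reliability: paired t for systematic bias, ICC(2,k) (two-way
random effects, absolute agreement, average measures) with an F-based 95%
CI, SEM from the test-retest difference SD, and MDC.

The ICC and AUC computations are written out from their defining mean-square
and rank-sum forms; scipy provides the distributions.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import (
    DegenerateSampleError,
    IncompleteMatrixError,
    InsufficientDataError,
    InvalidInputError,
    InvalidLabelsError,
    TransformInfeasibleError,
)

MDC_FACTOR = 1.96 * np.sqrt(2.0)  # = 2.7719 to 4 d.p.


# ---------------------------------------------------------------- normality


@dataclass
class NormalityReport:
    variable: str
    w_statistic: float
    p_value: float
    decision: str  # "normal" | "ln_transformed"
    transformed: np.ndarray | None = None


def shapiro_gate(values, alpha: float = 0.05, variable: str = "") -> NormalityReport:
    """Shapiro-Wilk gate: Ln-transform a variable that fails normality.

    Statistics downstream run on the transformed values when gated;
    descriptive tables stay untransformed.

    Raises
    ------
    DegenerateSampleError
        On constant input (W undefined).
    TransformInfeasibleError
        If the transform is needed but values are not strictly positive.
    """
    x = np.asarray(values, dtype=float)
    if len(x) < 3 or not np.isfinite(x).all():
        raise InvalidInputError("need >= 3 finite values")
    if np.ptp(x) == 0:
        raise DegenerateSampleError("constant sample: Shapiro-Wilk undefined")
    w, p = sps.shapiro(x)
    if p >= alpha:
        return NormalityReport(variable, float(w), float(p), "normal")
    if (x <= 0).any():
        raise TransformInfeasibleError(
            "Ln transform required but sample contains non-positive values"
        )
    return NormalityReport(variable, float(w), float(p), "ln_transformed", np.log(x))


# ------------------------------------------------------------------- ANOVA


@dataclass
class AnovaResult:
    f_statistic: float
    p_value: float
    eta_squared: float
    group_n: dict[str, int]
    posthoc_p: dict[tuple[str, str], float]  # Bonferroni-adjusted
    posthoc_p_raw: dict[tuple[str, str], float]


def group_anova(samples: dict[str, np.ndarray]) -> AnovaResult:
    """One-way fixed-effects ANOVA with Bonferroni-corrected pairwise t tests.

    ``samples`` maps group label to that group's values.  The post-hoc tests
    are independent two-sample t tests (pooled variance per pair) with the
    raw p multiplied by the number of pairwise comparisons and capped at 1.
    Effect size is eta-squared (between-group SS / total SS).
    """
    groups = {g: np.asarray(v, dtype=float) for g, v in samples.items()}
    if len(groups) < 2:
        raise InsufficientDataError("need >= 2 groups")
    for g, v in groups.items():
        if len(v) < 2:
            raise InsufficientDataError(f"group {g!r} has n < 2")
    values = list(groups.values())
    f, p = sps.f_oneway(*values)
    allv = np.concatenate(values)
    if np.ptp(allv) == 0:
        f, p = 0.0, 1.0  # identical groups: no effect, scipy returns nan
    grand = allv.mean()
    ss_between = sum(len(v) * (v.mean() - grand) ** 2 for v in values)
    ss_total = float(((allv - grand) ** 2).sum())
    eta2 = ss_between / ss_total if ss_total > 0 else 0.0

    pairs = list(itertools.combinations(sorted(groups), 2))
    m = len(pairs)
    raw, adj = {}, {}
    for g1, g2 in pairs:
        if np.ptp(np.concatenate([groups[g1], groups[g2]])) == 0:
            tp = 1.0
        else:
            tp = float(sps.ttest_ind(groups[g1], groups[g2], equal_var=True).pvalue)
        raw[(g1, g2)] = tp
        adj[(g1, g2)] = min(1.0, m * tp)
    return AnovaResult(
        f_statistic=float(f),
        p_value=float(p),
        eta_squared=float(eta2),
        group_n={g: len(v) for g, v in groups.items()},
        posthoc_p=adj,
        posthoc_p_raw=raw,
    )


# --------------------------------------------------------------------- ROC


@dataclass
class RocResult:
    auc: float
    auc_p: float
    cutoff: float | None
    sensitivity: float | None
    one_minus_specificity: float | None
    n_cases: int
    n_controls: int


def roc_analysis(
    scores,
    labels,
    low_scores_are_cases: bool = True,
    cutoff: float | None = None,
) -> RocResult:
    """ROC AUC via the rank-sum (Mann-Whitney) formulation with tie handling.

    ``labels`` are truthy for cases.  When ``low_scores_are_cases`` (the
    movement-sense situation: patients have lower NormAcuity) the score axis
    is negated so the AUC still reads "probability a random case ranks on the
    case side of a random control".  ``auc_p`` comes from the normal
    approximation to the U statistic with tie-corrected variance.  At an
    optional ``cutoff``, sensitivity is the fraction of cases on the case
    side and 1-specificity the fraction of controls there (case side =
    strictly below the cutoff when low scores are cases, strictly above
    otherwise).
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    if len(s) != len(y):
        raise InvalidInputError("scores and labels length mismatch")
    n1, n0 = int(y.sum()), int((~y).sum())
    if n1 == 0 or n0 == 0:
        raise InvalidLabelsError("both classes must be present")

    direction = -s if low_scores_are_cases else s  # higher = more case-like
    ranks = sps.rankdata(direction)  # midranks
    u = float(ranks[y].sum() - n1 * (n1 + 1) / 2.0)
    auc = u / (n1 * n0)

    # tie-corrected normal approximation for the U statistic
    n = n1 + n0
    _, counts = np.unique(direction, return_counts=True)
    tie_term = ((counts**3 - counts).sum()) / (n * (n - 1)) if n > 1 else 0.0
    var_u = n1 * n0 / 12.0 * ((n + 1) - tie_term)
    if var_u <= 0:
        auc_p = 1.0
    else:
        z = (u - n1 * n0 / 2.0) / np.sqrt(var_u)
        auc_p = float(2 * sps.norm.sf(abs(z)))

    sens = oms = None
    if cutoff is not None:
        case_side = s < cutoff if low_scores_are_cases else s > cutoff
        sens = float(case_side[y].mean())
        oms = float(case_side[~y].mean())
    return RocResult(float(auc), auc_p, cutoff, sens, oms, n1, n0)


# ------------------------------------------------------- correlation / bias


def pearson_with_ndi(x, y) -> tuple[float, float]:
    """Pearson product-moment r and two-sided t-based p for paired data."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise InsufficientDataError("need paired samples with n >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise InvalidInputError("non-finite values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateSampleError("zero variance in one of the variables")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def paired_bias_test(test1, test2) -> tuple[float, float]:
    """Paired t test for systematic bias (learning/adaptation) between occasions."""
    a = np.asarray(test1, dtype=float)
    b = np.asarray(test2, dtype=float)
    if len(a) != len(b) or len(a) < 2:
        raise InsufficientDataError("need paired samples with n >= 2")
    d = b - a
    if np.ptp(d) == 0:
        if d[0] == 0:
            return 0.0, 1.0  # identical occasions: no bias
        raise DegenerateSampleError(
            "constant nonzero difference: paired t degenerates to infinity"
        )
    t, p = sps.ttest_rel(b, a)
    return float(t), float(p)


# -------------------------------------------------------------- reliability


ICC_BANDS = (
    (0.5, "poor"),
    (0.75, "moderate"),
    (0.90, "good"),
    (1.0, "excellent"),
)


def interpret_icc(icc: float) -> str:
    """Reliability band label: <0.5 poor, 0.5-0.75 moderate, 0.75-0.9 good,
    >0.9 excellent, 1 perfect agreement."""
    if icc == 1.0:
        return "perfect"
    for upper, name in ICC_BANDS:
        if icc < upper:
            return name
    return "excellent"


@dataclass
class IccResult:
    icc: float
    ci95: tuple[float, float]
    label: str
    n_subjects: int
    n_occasions: int


def icc_2k(measurements, alpha: float = 0.05) -> IccResult:
    """ICC(2,k): two-way random effects, absolute agreement, average measures.

    ``measurements`` is a complete subjects x occasions matrix.  The estimate
    comes from the two-way ANOVA mean squares (rows = subjects, columns =
    occasions); the 95% CI uses the F-distribution interval for the
    single-measure form (Satterthwaite df) stepped up to k measures by
    Spearman-Brown, with bounds clipped to [-1, 1].
    """
    x = np.asarray(measurements, dtype=float)
    if x.ndim != 2:
        raise InvalidInputError("measurements must be 2-D (subjects x occasions)")
    n, k = x.shape
    if k < 2 or n < 3:
        raise InsufficientDataError("need >= 3 subjects and >= 2 occasions")
    if np.isnan(x).any():
        raise IncompleteMatrixError("missing cells in the reliability matrix")
    if np.ptp(x) == 0:
        raise DegenerateSampleError("zero total variance")

    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    msr = k * ((row_means - grand) ** 2).sum() / (n - 1)
    msc = n * ((col_means - grand) ** 2).sum() / (k - 1)
    resid = x - row_means[:, None] - col_means[None, :] + grand
    mse = (resid**2).sum() / ((n - 1) * (k - 1))

    icc_k = (msr - mse) / (msr + (msc - mse) / n)
    icc_1 = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)

    # F-based CI on the single-measure form (McGraw & Wong), then step up
    r = icc_1
    if mse == 0 and msc == 0:
        lo_k, hi_k = 1.0, 1.0  # perfect agreement: interval collapses
    else:
        a = k * r / (n * (1 - r)) if r < 1 else np.inf
        b = 1 + k * r * (n - 1) / (n * (1 - r)) if r < 1 else np.inf
        if np.isinf(a) or np.isinf(b):
            lo_k, hi_k = 1.0, 1.0
        else:
            v_num = (a * msc + b * mse) ** 2
            v_den = (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
            v = v_num / v_den if v_den > 0 else 1.0
            f_lo = sps.f.ppf(1 - alpha / 2, n - 1, v)
            f_hi = sps.f.ppf(1 - alpha / 2, v, n - 1)
            lo1 = n * (msr - f_lo * mse) / (
                f_lo * (k * msc + (k * n - k - n) * mse) + n * msr
            )
            hi1 = n * (f_hi * msr - mse) / (
                k * msc + (k * n - k - n) * mse + n * f_hi * msr
            )
            lo_k = lo1 * k / (1 + lo1 * (k - 1))
            hi_k = hi1 * k / (1 + hi1 * (k - 1))
    lo_k, hi_k = float(np.clip(lo_k, -1, 1)), float(np.clip(hi_k, -1, 1))
    icc_k = float(np.clip(icc_k, -1, 1))
    lo_k = min(lo_k, icc_k)
    hi_k = max(hi_k, icc_k)
    return IccResult(icc_k, (lo_k, hi_k), interpret_icc(icc_k), n, k)


def sem_from_diff(test1, test2) -> float:
    """Standard error of measurement: SD of test-retest differences / sqrt(2).

    Always computed on untransformed data so the SEM keeps the variable's
    units.  Uses the n-1 sample SD; a purely systematic shift (constant
    difference) yields SEM 0 because it carries no random error.
    """
    a = np.asarray(test1, dtype=float)
    b = np.asarray(test2, dtype=float)
    if len(a) != len(b) or len(a) < 2:
        raise InsufficientDataError("need paired samples with n >= 2")
    return float(np.std(b - a, ddof=1) / np.sqrt(2.0))


def mdc_from_sem(sem: float) -> float:
    """Minimal detectable change at 95% confidence: SEM x 1.96 x sqrt(2)."""
    if sem < 0:
        raise InvalidInputError("sem must be >= 0")
    return float(sem * MDC_FACTOR)


# ----------------------------------------------------------- report tables


OUTCOME_VARS = ("acuity_pct", "speed_mm_s", "time_s", "norm_acuity_au")
PATIENT_GROUPS = ("INP", "TNP")


def _gated_values(df: pd.DataFrame, var: str, alpha: float) -> tuple[pd.Series, str]:
    """Normality-gate a variable on pooled group-mean residuals; return the
    (possibly Ln) analysis values and the gate decision."""
    resid = (df[var] - df.groupby("group")[var].transform("mean")).to_numpy()
    if np.ptp(resid) == 0:
        return df[var], "normal"
    _, p = sps.shapiro(resid)
    if p < alpha and (df[var] > 0).all():
        return np.log(df[var]), "ln_transformed"
    return df[var], "normal"


def validity_report(
    outcomes: pd.DataFrame,
    alpha: float = 0.05,
    roc_variable: str = "norm_acuity_au",
    roc_cutoff: float = 2.5,
) -> dict[str, pd.DataFrame]:
    """Group-discrimination battery on a pooled outcomes table.

    ``outcomes`` needs columns ``subject_id, group`` plus the four outcome
    variables and ``ndi_pct`` for patients.  Returns three tables:

    * ``groups`` — per-variable group means +/- SD (untransformed), ANOVA F
      and p on gated data, eta-squared, Bonferroni post-hoc p per pair;
    * ``roc`` — AUC / p / sensitivity / 1-specificity for patients-vs-CON
      (pooled and per patient group) on ``roc_variable`` at ``roc_cutoff``;
    * ``ndi_correlations`` — Pearson r and p of NDI against each variable
      within each patient group.
    """
    required = {"group", *OUTCOME_VARS}
    if not required.issubset(outcomes.columns):
        raise InvalidInputError(f"outcomes table needs columns {sorted(required)}")
    rows = []
    for var in OUTCOME_VARS:
        vals, decision = _gated_values(outcomes, var, alpha)
        samples = {g: vals[outcomes["group"] == g].to_numpy() for g in
                   outcomes["group"].unique()}
        res = group_anova(samples)
        row = {"variable": var, "normality": decision,
               "F": res.f_statistic, "p": res.p_value,
               "eta_squared": res.eta_squared}
        for g, sub in outcomes.groupby("group"):
            row[f"mean_{g}"] = sub[var].mean()
            row[f"sd_{g}"] = sub[var].std(ddof=1)
        for (g1, g2), pv in res.posthoc_p.items():
            row[f"p_{g1}_vs_{g2}"] = pv
        rows.append(row)
    groups_tbl = pd.DataFrame(rows)

    roc_rows = []
    is_patient = outcomes["group"].isin(PATIENT_GROUPS)
    contrasts = [("NP_vs_CON", is_patient)] + [
        (f"{g}_vs_CON", outcomes["group"] == g) for g in PATIENT_GROUPS
    ]
    for name, case_mask in contrasts:
        sel = case_mask | (outcomes["group"] == "CON")
        sub = outcomes[sel]
        roc = roc_analysis(
            sub[roc_variable], case_mask[sel], low_scores_are_cases=True,
            cutoff=roc_cutoff,
        )
        roc_rows.append(
            {"contrast": name, "variable": roc_variable, "auc": roc.auc,
             "auc_p": roc.auc_p, "cutoff": roc_cutoff,
             "sensitivity": roc.sensitivity,
             "one_minus_specificity": roc.one_minus_specificity,
             "n_cases": roc.n_cases, "n_controls": roc.n_controls}
        )
    roc_tbl = pd.DataFrame(roc_rows)

    corr_rows = []
    if "ndi_pct" in outcomes.columns:
        for g in PATIENT_GROUPS:
            sub = outcomes[(outcomes["group"] == g) & outcomes["ndi_pct"].notna()]
            for var in OUTCOME_VARS:
                if len(sub) >= 3:
                    r, p = pearson_with_ndi(sub["ndi_pct"], sub[var])
                    corr_rows.append({"group": g, "variable": var, "r": r, "p": p,
                                      "n": len(sub)})
    corr_tbl = pd.DataFrame(corr_rows)
    return {"groups": groups_tbl, "roc": roc_tbl, "ndi_correlations": corr_tbl}


def reliability_report(
    occasion1: pd.DataFrame,
    occasion2: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Test-retest battery: per variable, descriptives at each occasion,
    paired-t bias p, ICC(2,k) with 95% CI and band label, SEM and MDC.

    Occasion tables are matched on ``subject_id``.  Paired t and ICC run on
    Ln data when the pooled values fail the normality gate; SEM (hence MDC)
    is always computed on untransformed data.
    """
    merged = occasion1.merge(
        occasion2, on="subject_id", suffixes=("_1", "_2"), validate="one_to_one"
    )
    if merged.empty:
        raise InsufficientDataError("no subjects present at both occasions")
    rows = []
    for var in OUTCOME_VARS:
        a = merged[f"{var}_1"].to_numpy(dtype=float)
        b = merged[f"{var}_2"].to_numpy(dtype=float)
        pooled = np.concatenate([a, b])
        try:
            gate = shapiro_gate(pooled, alpha=alpha, variable=var)
            use_ln = gate.decision == "ln_transformed"
            decision = gate.decision
        except (DegenerateSampleError, TransformInfeasibleError):
            use_ln, decision = False, "normal"
        aa, bb = (np.log(a), np.log(b)) if use_ln else (a, b)
        t, p = paired_bias_test(aa, bb)
        icc = icc_2k(np.column_stack([aa, bb]))
        sem = sem_from_diff(a, b)
        rows.append(
            {"variable": var, "normality": decision,
             "mean_1": a.mean(), "sd_1": a.std(ddof=1),
             "mean_2": b.mean(), "sd_2": b.std(ddof=1),
             "paired_t": t, "paired_p": p,
             "icc": icc.icc, "icc_ci_low": icc.ci95[0],
             "icc_ci_high": icc.ci95[1], "icc_label": icc.label,
             "sem": sem, "mdc": mdc_from_sem(sem), "n": len(merged)}
        )
    return pd.DataFrame(rows)
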