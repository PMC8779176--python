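"""Sex-difference and treatment-effect statistics for behavioural metrics.

The analysis follows the convention for large behavioural cohorts whose
metrics violate normality and variance-homogeneity assumptions:

* sex differences are tested per metric on the *raw* values with a
  two-group Kruskal–Wallis H test (df = 1), reported with Cohen's d
  (pooled-SD, F − M sign convention);
* before treatment comparisons each metric is Box–Cox transformed with a
  single maximum-likelihood lambda shared by every generation, lineage,
  sex and treatment cell of that metric ("separately but equally");
* treatment effects are one-way fixed-effects ANOVAs within sex (and
  generation × lineage cell), with partial eta squared
  SS_treatment / (SS_treatment + SS_error) as effect size and Tukey HSD
  all-pairs post hocs whenever the omnibus test is significant at 0.05.

Shapiro–Wilk and Bartlett checks are computed and reported but advisory:
the pipeline proceeds regardless, since the transform + rank tests are the
designed response to their failure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .pose_io import ALL_METRICS, NOVELTY_METRICS, SOCIABILITY_METRICS

ALPHA = 0.05

#: partial-eta-squared magnitude labels (small / medium / large cutpoints)
ETA_SQ_CUTPOINTS = ((0.25, "large"), (0.09, "medium"), (0.01, "small"))


def effect_size_label(partial_eta_sq: float) -> str:
    for cut, label in ETA_SQ_CUTPOINTS:
        if partial_eta_sq >= cut:
            return label
    return "negligible"


# ---------------------------------------------------------------------------
# Assumption checks
# ---------------------------------------------------------------------------


def assumption_checks(
    values_by_group: Mapping[str, Sequence[float]],
) -> tuple[dict[str, float], float]:
    """Per-group Shapiro–Wilk p-values and one overall Bartlett p-value.

    Constant groups have undefined normality and are reported as NaN.
    """
    normality: dict[str, float] = {}
    for g, vals in values_by_group.items():
        v = np.asarray(vals, float)
        v = v[np.isfinite(v)]
        if len(v) < 3 or np.ptp(v) == 0:
            normality[g] = float("nan")
        else:
            normality[g] = float(sps.shapiro(v).pvalue)
    groups = [np.asarray(v, float) for v in values_by_group.values()]
    groups = [g[np.isfinite(g)] for g in groups if len(g) >= 2]
    if len(groups) < 2:
        bartlett_p = float("nan")
    elif all(np.ptp(g) == 0 for g in groups):
        bartlett_p = 1.0  # zero statistic: variances identical(ly zero)
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            bartlett_p = float(sps.bartlett(*groups).pvalue)
    return normality, bartlett_p


# ---------------------------------------------------------------------------
# Sex differences
# ---------------------------------------------------------------------------


def cohens_d(a: np.ndarray, b: np.ndarray) -> float:
    """Classical pooled-SD Cohen's d, mean(a) − mean(b)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    na, nb = len(a), len(b)
    if na < 2 or nb < 2:
        return float("nan")
    pooled = np.sqrt(
        ((na - 1) * np.var(a, ddof=1) + (nb - 1) * np.var(b, ddof=1)) / (na + nb - 2)
    )
    if pooled == 0:
        return 0.0 if np.mean(a) == np.mean(b) else float("inf")
    return float((np.mean(a) - np.mean(b)) / pooled)


def sex_difference_tests(
    cohort: pd.DataFrame, metrics: Sequence[str] | None = None
) -> pd.DataFrame:
    """Kruskal–Wallis F-vs-M tests on raw values, one row per metric.

    All treatments/generations/lineages present in ``cohort`` are collapsed
    into sex.  Cohen's d is signed F − M.  Metrics entirely missing for one
    sex are skipped.
    """
    if metrics is None:
        metrics = [m for m in ALL_METRICS if m in cohort.columns]
    rows = []
    for metric in metrics:
        f = cohort.loc[cohort["sex"] == "F", metric].to_numpy(float)
        m = cohort.loc[cohort["sex"] == "M", metric].to_numpy(float)
        f, m = f[np.isfinite(f)], m[np.isfinite(m)]
        if len(f) == 0 or len(m) == 0:
            continue
        mean_f, mean_m = float(np.mean(f)), float(np.mean(m))
        sem_f = float(sps.sem(f)) if len(f) > 1 else float("nan")
        sem_m = float(sps.sem(m)) if len(m) > 1 else float("nan")
        if np.ptp(np.concatenate([f, m])) == 0:
            H, p = 0.0, 1.0
        else:
            H, p = sps.kruskal(f, m)
        rows.append(
            {
                "metric": metric,
                "mean_F": mean_f,
                "sem_F": sem_f,
                "mean_M": mean_m,
                "sem_M": sem_m,
                "H": float(H),
                "p": float(p),
                "cohens_d": cohens_d(f, m),
                "n_F": len(f),
                "n_M": len(m),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Box–Cox transformation
# ---------------------------------------------------------------------------


def boxcox_metric(values: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Box–Cox transform one metric's pooled values with a single MLE lambda.

    Returns (transformed, lambda, offset).  NaNs pass through untouched.
    Non-positive values are shifted by half the smallest positive value
    (recorded in ``offset``) since the power family needs positivity.
    Degenerate (constant) metrics return the identity with lambda NaN.
    """
    values = np.asarray(values, float)
    out = values.copy()
    finite = np.isfinite(values)
    v = values[finite]
    if len(v) < 3 or np.ptp(v) == 0:
        return out, float("nan"), 0.0
    offset = 0.0
    if v.min() <= 0:
        positive = v[v > 0]
        if len(positive) == 0:
            return out, float("nan"), 0.0
        offset = float(positive.min() / 2.0 - v.min())
    transformed, lam = sps.boxcox(v + offset)
    out[finite] = transformed
    return out, float(lam), offset


# ---------------------------------------------------------------------------
# One-way ANOVA with partial eta squared and Tukey HSD
# ---------------------------------------------------------------------------


@dataclass
class TreatmentResult:
    """Within-sex one-way treatment ANOVA for one metric in one design cell."""

    metric: str
    generation: str
    lineage: str
    sex: str
    boxcox_lambda: float
    F: float
    df1: int
    df2: int
    p: float
    partial_eta_sq: float
    effect_label: str
    group_ns: dict[str, int]
    posthoc: list[tuple[str, str, float]] = field(default_factory=list)


def oneway_anova(groups: Mapping[str, Sequence[float]]) -> tuple[float, int, int, float, float]:
    """Fixed-effects one-way ANOVA from group sums of squares.

    Returns (F, df1, df2, p, partial_eta_sq) where partial eta squared is
    SS_between / (SS_between + SS_within).
    """
    arrays = [np.asarray(v, float) for v in groups.values()]
    arrays = [a[np.isfinite(a)] for a in arrays]
    if len(arrays) < 2:
        raise ValueError("ANOVA needs at least two groups")
    ns = [len(a) for a in arrays]
    if any(n < 2 for n in ns):
        raise ValueError("every group needs at least two observations")
    grand = np.concatenate(arrays)
    grand_mean = grand.mean()
    ss_between = sum(n * (a.mean() - grand_mean) ** 2 for n, a in zip(ns, arrays))
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    df1 = len(arrays) - 1
    df2 = sum(ns) - len(arrays)
    eta = ss_between / (ss_between + ss_within) if (ss_between + ss_within) > 0 else 0.0
    if ss_within == 0:
        F = float("inf") if ss_between > 0 else 0.0
        p = 0.0 if ss_between > 0 else 1.0
    else:
        F = (ss_between / df1) / (ss_within / df2)
        p = float(sps.f.sf(F, df1, df2))
    return float(F), df1, df2, float(p), float(eta)


def tukey_posthoc(groups: Mapping[str, Sequence[float]]) -> list[tuple[str, str, float]]:
    """All-pairs Tukey HSD adjusted p-values (studentized-range based)."""
    labels = list(groups)
    arrays = [np.asarray(groups[g], float) for g in labels]
    arrays = [a[np.isfinite(a)] for a in arrays]
    if np.ptp(np.concatenate(arrays)) == 0:
        # all values identical across every group: no pair differs
        return [
            (labels[i], labels[j], 1.0)
            for i in range(len(labels))
            for j in range(i + 1, len(labels))
        ]
    res = sps.tukey_hsd(*arrays)
    out = []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            out.append((labels[i], labels[j], float(res.pvalue[i, j])))
    return out


def treatment_anova(
    cell: pd.DataFrame,
    metric: str,
    value_col: str | None = None,
    boxcox_lambda: float = float("nan"),
    alpha: float = ALPHA,
) -> TreatmentResult | None:
    """One-way treatment ANOVA for one (metric, generation, lineage, sex) cell.

    ``cell`` holds Box–Cox-transformed values in ``value_col`` (defaults to
    the metric column) and a ``treatment`` factor.  Groups with fewer than
    two observations are dropped with a warning; with fewer than two groups
    left the result is missing (None).  Post hocs are attached only when
    the omnibus p is below ``alpha``.
    """
    value_col = value_col or metric
    groups: dict[str, np.ndarray] = {}
    for label, sub in cell.groupby("treatment", sort=True):
        v = sub[value_col].to_numpy(float)
        v = v[np.isfinite(v)]
        if len(v) < 2:
            import warnings

            warnings.warn(
                f"dropping treatment group {label!r} with <2 observations for {metric}",
                stacklevel=2,
            )
            continue
        groups[str(label)] = v
    if len(groups) < 2:
        return None
    F, df1, df2, p, eta = oneway_anova(groups)
    result = TreatmentResult(
        metric=metric,
        generation=str(cell["generation"].iloc[0]) if "generation" in cell else "",
        lineage=str(cell["lineage"].iloc[0]) if "lineage" in cell else "",
        sex=str(cell["sex"].iloc[0]) if "sex" in cell else "",
        boxcox_lambda=boxcox_lambda,
        F=F,
        df1=df1,
        df2=df2,
        p=p,
        partial_eta_sq=eta,
        effect_label=effect_size_label(eta),
        group_ns={g: len(v) for g, v in groups.items()},
    )
    if p < alpha:
        result.posthoc = tukey_posthoc(groups)
    return result


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------


@dataclass
class AnalysisBundle:
    sex_differences: pd.DataFrame
    treatment_effects: pd.DataFrame
    posthoc: pd.DataFrame
    boxcox_lambdas: pd.DataFrame
    assumptions: pd.DataFrame
    skipped: list[str] = field(default_factory=list)


def run_full_analysis(
    cohort: pd.DataFrame,
    qc_report=None,
    metrics: Sequence[str] | None = None,
    alpha: float = ALPHA,
) -> AnalysisBundle:
    """QC-filter, then run the sex-difference and treatment analyses.

    ``cohort`` is the tidy per-(animal, phase) metric table carrying the
    design factors sex / generation / lineage and a ``treatment`` label
    column (built from the record's first/second hit).  Returns tidy result
    tables; empty post-QC cells are skipped and listed in ``skipped``.
    """
    from .trial_qc import apply_exclusions

    if qc_report is not None:
        cohort, _ = apply_exclusions(cohort, qc_report)
    if metrics is None:
        metrics = [m for m in ALL_METRICS if m in cohort.columns]

    phase_metrics = {
        "sociability": [m for m in metrics if m in SOCIABILITY_METRICS],
        "social_novelty": [m for m in metrics if m in NOVELTY_METRICS],
    }

    sex_rows, lam_rows, anova_rows, post_rows, assum_rows, skipped = [], [], [], [], [], []
    for phase, phase_cols in phase_metrics.items():
        sub = cohort[cohort["phase"] == phase].copy()
        if sub.empty or not phase_cols:
            continue
        # sex differences on raw values (skipped for single-sex cohorts)
        if set(sub["sex"]) >= {"F", "M"}:
            sd = sex_difference_tests(sub, phase_cols)
            sd.insert(0, "phase", phase)
            sex_rows.append(sd)
        # one shared Box-Cox lambda per metric across every design cell
        for metric in phase_cols:
            transformed, lam, offset = boxcox_metric(sub[metric].to_numpy(float))
            tcol = f"__bc_{metric}"
            sub[tcol] = transformed
            lam_rows.append(
                {"phase": phase, "metric": metric, "boxcox_lambda": lam, "offset": offset}
            )
            for (gen, lin, sex), cell in sub.groupby(
                ["generation", "lineage", "sex"], sort=True
            ):
                groups = {
                    str(t): g[tcol].to_numpy(float)
                    for t, g in cell.groupby("treatment", sort=True)
                }
                try:
                    norm_p, bart_p = assumption_checks(
                        {t: cell.loc[cell["treatment"] == t, metric] for t in groups}
                    )
                    finite_norm = [v for v in norm_p.values() if np.isfinite(v)]
                    assum_rows.append(
                        {
                            "phase": phase,
                            "metric": metric,
                            "generation": gen,
                            "lineage": lin,
                            "sex": sex,
                            "min_shapiro_p": min(finite_norm)
                            if finite_norm
                            else float("nan"),
                            "bartlett_p": bart_p,
                        }
                    )
                except ValueError:
                    pass
                res = treatment_anova(cell, metric, value_col=tcol, boxcox_lambda=lam, alpha=alpha)
                if res is None:
                    skipped.append(f"{phase}/{metric}/{gen}/{lin}/{sex}")
                    continue
                anova_rows.append(
                    {
                        "phase": phase,
                        "metric": metric,
                        "generation": gen,
                        "lineage": lin,
                        "sex": sex,
                        "boxcox_lambda": lam,
                        "F": res.F,
                        "df1": res.df1,
                        "df2": res.df2,
                        "p": res.p,
                        "partial_eta_sq": res.partial_eta_sq,
                        "effect_label": res.effect_label,
                    }
                )
                for a, b, padj in res.posthoc:
                    post_rows.append(
                        {
                            "phase": phase,
                            "metric": metric,
                            "generation": gen,
                            "lineage": lin,
                            "sex": sex,
                            "group_a": a,
                            "group_b": b,
                            "p_adjusted": padj,
                        }
                    )

    empty = pd.DataFrame()
    return AnalysisBundle(
        sex_differences=pd.concat(sex_rows, ignore_index=True) if sex_rows else empty,
        treatment_effects=pd.DataFrame(anova_rows),
        posthoc=pd.DataFrame(post_rows),
        boxcox_lambdas=pd.DataFrame(lam_rows),
        assumptions=pd.DataFrame(assum_rows),
        skipped=skipped,
    )
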