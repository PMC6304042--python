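"""The sustained/transient frequency-ratio index and group statistics.

The frequency-ratio index is the normalized contrast between the first
(1F, sustained) and second (2F, transient) harmonic amplitudes,

    ratio = (1F - 2F) / (1F + 2F),

computed per subject and contrast condition and averaged over the
supra-baseline conditions, giving a single index per subject.  Because the
ratio is scale-invariant, a change in a subject's overall responsiveness
(both harmonics scaled by a common factor) leaves the index untouched; a
selective change in the transient component shifts it.

The statistical battery mirrors a standard cross-species design:

* mixed-design ANOVA (harmonic as a 2-level within-subject factor, group
  between) on amplitudes at the highest contrast;
* one-way ANOVA with simple planned contrasts (each mutant genotype vs the
  control) for three-group comparisons;
* pooled-variance independent t-tests on the ratio index for two-group
  comparisons;
* ordinary least-squares regression of the ratio index on a per-subject
  trait score (e.g. an autism-spectrum-quotient questionnaire total).

All tests are two-tailed unless noted; the mixed ANOVA is implemented as
the classical split-plot sums-of-squares decomposition, which for a
2-level within factor needs no sphericity correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .crf import SupraBaselineSet

__all__ = [
    "RatioIndex",
    "GroupStatsResult",
    "frequency_ratio",
    "ratio_index",
    "baseline_ratios",
    "mixed_anova",
    "oneway_anova_contrasts",
    "ttest_ind",
    "regress_ratio_on_trait",
    "median_split",
]


@dataclass(frozen=True)
class RatioIndex:
    """Per-subject frequency-ratio index in [-1, 1]."""

    subject_id: str
    group: str
    value: float
    n_conditions_averaged: int


@dataclass(frozen=True)
class GroupStatsResult:
    """One test statistic with degrees of freedom and p-value.

    ``effect_direction`` is the sign of the underlying effect (+1/-1, or 0
    when undefined); ``extra`` carries test-specific quantities such as
    the multiple R of a regression or group means.
    """

    test: str
    effect: str
    statistic: float
    dof: tuple[float, ...]
    p_value: float
    effect_direction: int = 0
    extra: Mapping[str, float] = field(default_factory=dict)


def frequency_ratio(amp_1f, amp_2f):
    """(1F - 2F) / (1F + 2F) for non-negative amplitudes.

    Vectorized; returns NaN (with a warning) where both amplitudes are
    zero, since the ratio is then undefined.
    """
    a1 = np.asarray(amp_1f, dtype=float)
    a2 = np.asarray(amp_2f, dtype=float)
    if np.any(a1 < 0) or np.any(a2 < 0):
        raise ValueError("harmonic amplitudes must be non-negative")
    total = a1 + a2
    both_zero = total == 0
    if np.any(both_zero):
        warnings.warn("frequency ratio undefined where 1F + 2F == 0; returning NaN",
                      stacklevel=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(both_zero, np.nan, (a1 - a2) / np.where(both_zero, 1.0, total))
    return float(out) if np.isscalar(amp_1f) and np.isscalar(amp_2f) else out


def ratio_index(
    responses: pd.DataFrame,
    conditions: SupraBaselineSet | Sequence[float],
) -> pd.DataFrame:
    """One frequency-ratio index per subject.

    ``responses`` holds per-subject coherent amplitudes (columns
    subject_id, group, contrast, harmonic, amplitude).  The ratio is
    computed at each selected contrast and averaged arithmetically across
    conditions.  Subjects missing a selected condition are flagged with a
    warning and averaged over the conditions they do have.

    Returns a frame with columns subject_id, group, value,
    n_conditions_averaged.
    """
    selected = (conditions.selected_contrasts
                if isinstance(conditions, SupraBaselineSet) else tuple(conditions))
    if len(selected) == 0:
        raise ValueError("no supra-baseline conditions selected")
    wide = responses.pivot_table(index=["subject_id", "group", "contrast"],
                                 columns="harmonic", values="amplitude",
                                 aggfunc="mean").reset_index()
    if 1 not in wide.columns or 2 not in wide.columns:
        raise ValueError("responses must contain harmonics 1 and 2")
    rows = []
    for (subject, group), tbl in wide.groupby(["subject_id", "group"], sort=True):
        tbl = tbl.set_index("contrast")
        present = [c for c in selected if c in tbl.index]
        if len(present) < len(selected):
            missing = sorted(set(selected) - set(present))
            warnings.warn(
                f"subject {subject!r} missing selected conditions {missing}; "
                "index computed over available conditions", stacklevel=2)
        if not present:
            continue
        ratios = frequency_ratio(tbl.loc[present, 1].to_numpy(),
                                 tbl.loc[present, 2].to_numpy())
        rows.append((subject, group, float(np.nanmean(ratios)), len(present)))
    return pd.DataFrame(rows, columns=["subject_id", "group", "value",
                                       "n_conditions_averaged"])


def baseline_ratios(indices: pd.DataFrame) -> pd.DataFrame:
    """Shift ratio values by the grand mean of group means (display only).

    Group differences are unchanged; the shifted group means sum to zero
    across groups.  Expects columns group, value.
    """
    group_means = indices.groupby("group")["value"].mean()
    if len(group_means) < 2:
        raise ValueError("need at least two groups to baseline")
    shifted = indices.copy()
    shifted["value"] = shifted["value"] - group_means.mean()
    return shifted


# ---------------------------------------------------------------------------
# statistical battery


def _as_groups(data, value_col="value", group_col="group") -> dict[str, np.ndarray]:
    if isinstance(data, pd.DataFrame):
        return {str(g): sub[value_col].to_numpy(dtype=float)
                for g, sub in data.groupby(group_col, sort=False)}
    return {str(g): np.asarray(v, dtype=float) for g, v in dict(data).items()}


def mixed_anova(
    data: pd.DataFrame,
    dv: str = "amplitude",
    within: str = "harmonic",
    subject: str = "subject_id",
    between: str = "group",
) -> dict[str, GroupStatsResult]:
    """Split-plot ANOVA: within-subject factor x between-subject group.

    Classical univariate decomposition: the between-subject effect is
    tested against subject-within-group variation; the within factor and
    the interaction against the subject x within residual.  With two
    within levels and two groups the interaction has (1, N-2) degrees of
    freedom.  Subjects missing any within level are dropped with a
    warning.

    Returns results keyed ``"group"``, ``"harmonic"`` (the within factor)
    and ``"interaction"``.
    """
    pivot = data.pivot_table(index=subject, columns=within, values=dv,
                             aggfunc="mean")
    groups = data.groupby(subject)[between].agg(lambda s: s.iloc[0])
    if data.groupby(subject)[between].nunique().max() > 1:
        raise ValueError("a subject appears in more than one group")
    incomplete = pivot.index[pivot.isna().any(axis=1)]
    if len(incomplete):
        warnings.warn(
            f"excluding {len(incomplete)} subject(s) missing a within-level: "
            f"{list(incomplete)}", stacklevel=2)
        pivot = pivot.drop(index=incomplete)
    y = pivot.to_numpy(dtype=float)
    glabels = groups.loc[pivot.index].to_numpy()
    n_subj, k = y.shape
    unique_groups = pd.unique(glabels)
    g = len(unique_groups)
    if n_subj <= g or g < 2 or k < 2:
        raise ValueError("need >= 2 groups, >= 2 within levels and enough subjects")

    grand = y.mean()
    subj_means = y.mean(axis=1)
    within_means = y.mean(axis=0)

    ss_group = 0.0
    ss_cells = 0.0
    for lab in unique_groups:
        sel = glabels == lab
        n_j = sel.sum()
        ss_group += k * n_j * (subj_means[sel].mean() - grand) ** 2
        ss_cells += n_j * ((y[sel].mean(axis=0) - grand) ** 2).sum()
    ss_subj = k * ((subj_means - grand) ** 2).sum()
    ss_err_between = ss_subj - ss_group
    ss_within_total = ((y - subj_means[:, None]) ** 2).sum()
    ss_within = n_subj * ((within_means - grand) ** 2).sum()
    ss_inter = ss_cells - ss_group - ss_within
    ss_err_within = ss_within_total - ss_within - ss_inter

    df_group = (g - 1, n_subj - g)
    df_w = ((k - 1), (n_subj - g) * (k - 1))
    df_i = ((g - 1) * (k - 1), (n_subj - g) * (k - 1))

    def f_result(effect, ss, df, ms_err):
        ms = ss / df[0]
        f = ms / ms_err if ms_err > 0 else np.inf
        p = float(sstats.f.sf(f, *df))
        return effect, f, p

    ms_err_b = ss_err_between / df_group[1]
    ms_err_w = ss_err_within / df_w[1]

    results: dict[str, GroupStatsResult] = {}
    _, f, p = f_result("group", ss_group, df_group, ms_err_b)
    results["group"] = GroupStatsResult(
        test="mixed_anova", effect=between, statistic=f,
        dof=tuple(float(d) for d in df_group), p_value=p)
    _, f, p = f_result(within, ss_within, df_w, ms_err_w)
    results["harmonic"] = GroupStatsResult(
        test="mixed_anova", effect=within, statistic=f,
        dof=tuple(float(d) for d in df_w), p_value=p)
    _, f, p = f_result("interaction", ss_inter, df_i, ms_err_w)
    direction = 0
    if g == 2 and k == 2:
        d0 = y[glabels == unique_groups[0]][:, 1] - y[glabels == unique_groups[0]][:, 0]
        d1 = y[glabels == unique_groups[1]][:, 1] - y[glabels == unique_groups[1]][:, 0]
        direction = int(np.sign(d1.mean() - d0.mean()))
    results["interaction"] = GroupStatsResult(
        test="mixed_anova", effect=f"{within} x {between}", statistic=f,
        dof=tuple(float(d) for d in df_i), p_value=p,
        effect_direction=direction)
    return results


def oneway_anova_contrasts(
    data,
    control_label: str,
    value_col: str = "value",
    group_col: str = "group",
) -> dict[str, GroupStatsResult]:
    """One-way ANOVA with simple planned contrasts against a control group.

    The omnibus F has (g-1, N-g) degrees of freedom.  Each non-control
    group is compared to the control with a t-test using the pooled
    mean-square error from the omnibus ANOVA (so the contrast t shares the
    omnibus error degrees of freedom); two-tailed, uncorrected.
    """
    groups = _as_groups(data, value_col, group_col)
    if control_label not in groups:
        raise ValueError(f"control group {control_label!r} not in data")
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(len(v) < 2 for v in groups.values()):
        raise ValueError("need at least two subjects per group")
    labels = list(groups)
    values = [groups[lab] for lab in labels]
    n_total = sum(len(v) for v in values)
    g = len(values)
    f_stat, p = sstats.f_oneway(*values)
    ss_within = sum(((v - v.mean()) ** 2).sum() for v in values)
    df_err = n_total - g
    mse = ss_within / df_err
    results = {
        "omnibus": GroupStatsResult(
            test="oneway_anova", effect=group_col, statistic=float(f_stat),
            dof=(float(g - 1), float(df_err)), p_value=float(p))
    }
    control = groups[control_label]
    for lab in labels:
        if lab == control_label:
            continue
        other = groups[lab]
        se = np.sqrt(mse * (1.0 / len(other) + 1.0 / len(control)))
        t = (other.mean() - control.mean()) / se if se > 0 else 0.0
        p_c = float(2.0 * sstats.t.sf(abs(t), df_err))
        results[f"contrast_{lab}"] = GroupStatsResult(
            test="planned_contrast", effect=f"{lab} vs {control_label}",
            statistic=float(t), dof=(float(df_err),), p_value=p_c,
            effect_direction=int(np.sign(t)))
    return results


def ttest_ind(group_a, group_b) -> GroupStatsResult:
    """Two-tailed pooled-variance (Student) independent-samples t-test."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least two observations per group")
    t, p = sstats.ttest_ind(a, b, equal_var=True)
    if np.isnan(t):
        # both groups constant: t = 0 when means agree, infinite otherwise
        t, p = (0.0, 1.0) if a.mean() == b.mean() else (np.inf, 0.0)
    dof = float(len(a) + len(b) - 2)
    return GroupStatsResult(
        test="ttest_ind", effect="group", statistic=float(t), dof=(dof,),
        p_value=float(p), effect_direction=int(np.sign(t)),
        extra={"mean_a": float(a.mean()), "mean_b": float(b.mean())})


def regress_ratio_on_trait(trait_scores, indices) -> GroupStatsResult:
    """Simple OLS regression of the ratio index on a per-subject trait score.

    Reports the multiple R (positive root of R^2) and the regression F
    with (1, N-2) degrees of freedom; ``effect_direction`` is the sign of
    the slope.
    """
    x = np.asarray(trait_scores, dtype=float)
    y = np.asarray(indices, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("scores and indices must be 1-D and equal length")
    if len(x) < 3:
        raise ValueError("need at least three subjects")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite inputs")
    if np.var(x) == 0:
        raise ValueError("zero-variance predictor")
    fit = sstats.linregress(x, y)
    r2 = fit.rvalue**2
    dof = (1.0, float(len(x) - 2))
    f = np.inf if r2 >= 1.0 else r2 * dof[1] / (1.0 - r2)
    return GroupStatsResult(
        test="ols_regression", effect="trait", statistic=float(f), dof=dof,
        p_value=float(fit.pvalue), effect_direction=int(np.sign(fit.slope)),
        extra={"R": float(abs(fit.rvalue)), "slope": float(fit.slope),
               "intercept": float(fit.intercept)})


def median_split(scores, labels: tuple[str, str] = ("low", "high")):
    """Split subjects at the median score; returns (labels array, median).

    Scores at or below the median are labelled ``labels[0]``.  Utility for
    trait-based grouping; the regression analysis operates on the raw
    scores instead.
    """
    x = np.asarray(scores, dtype=float)
    med = float(np.median(x))
    return np.where(x <= med, labels[0], labels[1]), med
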