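"""Fold-change normalisation, group comparison, and pipeline validation.

The quantitative layer behind the figures: per-well means are normalised as
fold change over the control (vehicle) condition's mean, compared with
two-tailed Student's t (parametric) or Mann-Whitney / Wilcoxon
(non-parametric) tests, and the pipeline is validated against manual
reference counts by ordinary least-squares regression.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .errors import InsufficientDataError, ZeroControlError


def fold_change_normalize(values, control_values) -> np.ndarray:
    """Divide each value by the arithmetic mean of the control values.

    By construction the control condition's own fold changes average to 1.
    Scale-invariant: multiplying all inputs and controls by a constant
    leaves the output unchanged.
    """
    control = np.asarray(control_values, dtype=float)
    if control.size == 0:
        raise ZeroControlError("control_values is empty")
    mean = control.mean()
    if mean == 0:
        raise ZeroControlError("control mean is zero; fold change undefined")
    return np.asarray(values, dtype=float) / mean


@dataclass
class GroupComparison:
    test_name: str
    statistic: float
    degrees_of_freedom: float | None
    p_value: float


def compare_groups(a, b, paired: bool = False, parametric: bool = True) -> GroupComparison:
    """Two-tailed comparison of two groups.

    parametric & unpaired → Student's t (pooled variance); parametric &
    paired → paired t; non-parametric & unpaired → Mann-Whitney U;
    non-parametric & paired → Wilcoxon signed-rank.  The caller selects
    parametric vs non-parametric after checking normality.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InsufficientDataError("each group needs at least 2 observations")
    if paired and a.size != b.size:
        raise InsufficientDataError("paired comparison needs equal group sizes")
    if parametric:
        if paired:
            if np.all(a == b):  # zero-variance differences: no effect at all
                return GroupComparison("paired t", 0.0, float(a.size - 1), 1.0)
            res = sps.ttest_rel(a, b)
            return GroupComparison("paired t", float(res.statistic),
                                   float(res.df), float(res.pvalue))
        res = sps.ttest_ind(a, b, equal_var=True)
        return GroupComparison("Student t", float(res.statistic),
                               float(res.df), float(res.pvalue))
    if paired:
        res = sps.wilcoxon(a, b)
        return GroupComparison("Wilcoxon", float(res.statistic), None, float(res.pvalue))
    res = sps.mannwhitneyu(a, b, alternative="two-sided")
    return GroupComparison("Mann-Whitney U", float(res.statistic), None, float(res.pvalue))


@dataclass
class ValidationResult:
    """OLS fit of pipeline counts against reference (manual) counts."""

    slope: float
    intercept: float
    r_squared: float
    n_points: int


def validate_counts(pipeline_counts, reference_counts) -> ValidationResult:
    """Least-squares regression of pipeline vs reference counts.

    A faithful pipeline gives slope ≈ 1, intercept ≈ 0, r² ≈ 1.
    """
    y = np.asarray(pipeline_counts, dtype=float)
    x = np.asarray(reference_counts, dtype=float)
    if y.size != x.size:
        raise InsufficientDataError("count vectors must have equal length")
    if y.size < 3:
        raise InsufficientDataError("validation regression needs >= 3 points")
    if np.ptp(x) == 0:
        raise InsufficientDataError("reference counts have zero variance")
    res = sps.linregress(x, y)
    return ValidationResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        n_points=int(y.size),
    )


def match_centroids(detected, reference, max_dist: float = 5.0) -> int:
    """Number of detected points matched one-to-one to reference points.

    Greedy nearest-pair matching under a distance ceiling; the count of
    matches is the true-positive count when *reference* is ground truth.
    """
    detected = np.atleast_2d(np.asarray(detected, dtype=float))
    reference = np.atleast_2d(np.asarray(reference, dtype=float))
    if detected.size == 0 or reference.size == 0:
        return 0
    d = np.linalg.norm(detected[:, None, :] - reference[None, :, :], axis=2)
    order = np.dstack(np.unravel_index(np.argsort(d, axis=None), d.shape))[0]
    used_d, used_r = set(), set()
    n = 0
    for i, j in order:
        if d[i, j] > max_dist:
            break
        if i in used_d or j in used_r:
            continue
        used_d.add(int(i))
        used_r.add(int(j))
        n += 1
    return n


@dataclass
class ConditionResult:
    """Well-level fold changes of one condition vs the control condition."""

    experiment_id: str
    condition: str
    well_means: list[float]
    fold_changes: list[float]
    test_name: str | None = None
    statistic: float | None = None
    degrees_of_freedom: float | None = None
    p_value: float | None = None


def summarize_conditions(
    well_means_by_condition: dict[str, list[float]],
    control: str,
    experiment_id: str = "",
    parametric: bool = True,
) -> list[ConditionResult]:
    """Fold-change-normalise every condition against the control's mean and
    test each non-control condition against the control."""
    if control not in well_means_by_condition:
        raise InsufficientDataError(f"control condition {control!r} missing")
    control_vals = list(well_means_by_condition[control])
    out = []
    for cond, vals in well_means_by_condition.items():
        fc = fold_change_normalize(vals, control_vals)
        res = ConditionResult(experiment_id, cond, list(map(float, vals)),
                              [float(v) for v in fc])
        if cond != control and len(vals) >= 2 and len(control_vals) >= 2:
            cmp = compare_groups(vals, control_vals, paired=False, parametric=parametric)
            res.test_name = cmp.test_name
            res.statistic = cmp.statistic
            res.degrees_of_freedom = cmp.degrees_of_freedom
            res.p_value = cmp.p_value
        out.append(res)
    return out
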