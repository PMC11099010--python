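"""Lifetime validation of the compensatory approach on measurement series.

Every measurement point of a target's lifetime series is treated as the
start of a hypothetical treatment.  At each eligible point two prescriptions
are computed for the same required fluence NF:

* compensated — a tentative degradation model is fitted to the measurements
  available up to that point and the fluence integral is inverted for the
  beam-on charge;
* constant-flux — the flux measured immediately before the treatment is
  taken as constant and the charge is simply NF / flux.

Both charges are pushed through a reference model fitted on the *full*
lifetime series, and the delivered fluence is compared with NF as a percent
discrepancy.  The statistics stage summarizes the per-target discrepancy
distributions and reproduces the test-selection pipeline: Shapiro-Wilk
normality on the paired differences chooses between a paired t-test and the
Wilcoxon signed-rank test within each target; across targets, Bartlett's
variance-homogeneity test gates one-way ANOVA versus Kruskal-Wallis.
Significance level is 0.05 throughout, all tests two-sided.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .compensator import (
    METHOD_COMPENSATED,
    METHOD_CONSTANT_FLUX,
    TreatmentPlan,
    constant_flux_charge,
    score_delivery,
    solve_required_charge,
)
from .flux_model import (
    FitFailureError,
    FluxModel,
    InsufficientDataError,
    N_MIN_DEFAULT,
    fit_flux_model,
)
from .measurement_io import MeasurementSeries

__all__ = [
    "ALPHA",
    "NEAR_THRESHOLD_PERCENT",
    "ValidationRecord",
    "MethodSummary",
    "PairedComparison",
    "GroupComparison",
    "ValidationSummary",
    "run_lifetime_validation",
    "summarize",
    "compare_methods",
    "run_full_validation",
    "format_report",
]

#: Two-sided significance level of every test in the pipeline.
ALPHA = 0.05

#: "Near 1%" discrepancy threshold used for the within-threshold rate.
NEAR_THRESHOLD_PERCENT = 1.0


@dataclass(frozen=True)
class ValidationRecord:
    """One simulated treatment at one measurement point, one method."""

    target_id: str
    treatment_index: int  # index of the measurement point used as d
    d: float  # mC on target before the treatment
    required_charge: float  # mC
    method: str
    delivered_fluence: float  # atom^-1 under the reference model
    discrepancy_percent: float


@dataclass(frozen=True)
class MethodSummary:
    """Location/spread summary of one method's discrepancies on one target."""

    n: int
    median: float
    minimum: float
    maximum: float
    sd: float  # sample sd (ddof=1); NaN when n < 2
    fraction_within: float  # fraction with |discrepancy| <= threshold
    threshold: float = NEAR_THRESHOLD_PERCENT


@dataclass(frozen=True)
class PairedComparison:
    """Within-target comparison of the two methods' discrepancies."""

    target_id: str
    n_pairs: int
    normality_p_compensated: float
    normality_p_constant: float
    normality_p_differences: float
    test_name: str  # "paired t-test" | "Wilcoxon signed-rank" | "degenerate"
    statistic: float
    p_value: float
    significant: Optional[bool]  # None when degenerate


@dataclass(frozen=True)
class GroupComparison:
    """Across-target comparison of one method's discrepancies."""

    method: str
    bartlett_p: float
    test_name: str  # "one-way ANOVA" | "Kruskal-Wallis" | "not applicable"
    statistic: float
    p_value: float
    significant: Optional[bool]


@dataclass(frozen=True)
class ValidationSummary:
    """Everything the validation harness produces."""

    records: tuple = field(default_factory=tuple)
    per_target: dict = field(default_factory=dict)  # id -> {method: MethodSummary}
    paired_tests: tuple = field(default_factory=tuple)
    group_tests: tuple = field(default_factory=tuple)
    skipped: dict = field(default_factory=dict)  # id -> list of skipped indices


def run_lifetime_validation(
    series: MeasurementSeries,
    reference: FluxModel,
    plan: TreatmentPlan,
    n_min: int = N_MIN_DEFAULT,
) -> tuple[list[ValidationRecord], list[int]]:
    """Score both methods at every eligible point of one target's series.

    A point ``i`` (0-based) is eligible when at least ``n_min`` measurements
    up to and including it are available for the tentative fit.  For each
    eligible point the tentative model is fitted on measurements ``0..i``,
    the compensated charge is solved starting from ``d = charge_i``, and the
    constant-flux charge uses the flux measured at point ``i``.  Both are
    scored against ``reference``.  Points skipped (insufficient history or
    a failed tentative fit) are excluded from *both* methods so the paired
    comparison stays aligned; their indices are returned alongside.
    """
    nf = plan.required_fluence
    records: list[ValidationRecord] = []
    skipped: list[int] = []
    for i, point in enumerate(series.measurements):
        if i + 1 < n_min:
            skipped.append(i)
            continue
        try:
            tentative = fit_flux_model(series.prefix(i + 1), n_min=n_min)
        except (InsufficientDataError, FitFailureError):
            skipped.append(i)
            continue
        d = point.cumulative_charge
        comp_charge = solve_required_charge(tentative, d, nf)
        const_charge = constant_flux_charge(point.flux, nf)
        for method, charge in (
            (METHOD_COMPENSATED, comp_charge),
            (METHOD_CONSTANT_FLUX, const_charge),
        ):
            scored = score_delivery(reference, d, charge, nf, method)
            records.append(
                ValidationRecord(
                    target_id=series.target_id,
                    treatment_index=i,
                    d=scored.d,
                    required_charge=scored.required_charge,
                    method=method,
                    delivered_fluence=scored.delivered_fluence,
                    discrepancy_percent=scored.discrepancy_percent,
                )
            )
    return records, skipped


def summarize(
    discrepancies: Sequence[float],
    threshold_near: float = NEAR_THRESHOLD_PERCENT,
) -> MethodSummary:
    """Median, range, sample sd, and the |d| <= threshold rate.

    The sd uses the sample convention (ddof=1) and is NaN for a single
    value, flagging the degenerate case rather than reporting 0.
    """
    arr = np.asarray(discrepancies, dtype=float)
    if arr.size == 0:
        raise ValueError("no discrepancies to summarize")
    return MethodSummary(
        n=int(arr.size),
        median=float(np.median(arr)),
        minimum=float(arr.min()),
        maximum=float(arr.max()),
        sd=float(arr.std(ddof=1)) if arr.size > 1 else math.nan,
        fraction_within=float(np.mean(np.abs(arr) <= threshold_near)),
        threshold=threshold_near,
    )


def _shapiro_p(values: np.ndarray) -> float:
    """Shapiro-Wilk p-value; NaN for degenerate (constant or tiny) samples."""
    if values.size < 3 or np.ptp(values) == 0.0:
        return math.nan
    return float(stats.shapiro(values).pvalue)


def _paired_comparison(
    target_id: str, comp: np.ndarray, const: np.ndarray
) -> PairedComparison:
    if comp.size != const.size:
        raise ValueError(
            f"target {target_id!r}: unpaired lists "
            f"({comp.size} vs {const.size} discrepancies)"
        )
    diff = comp - const
    p_comp = _shapiro_p(comp)
    p_const = _shapiro_p(const)
    p_diff = _shapiro_p(diff)
    if np.all(diff == 0.0) or diff.size < 3:
        return PairedComparison(
            target_id=target_id,
            n_pairs=int(comp.size),
            normality_p_compensated=p_comp,
            normality_p_constant=p_const,
            normality_p_differences=p_diff,
            test_name="degenerate",
            statistic=math.nan,
            p_value=math.nan,
            significant=None,
        )
    if not math.isnan(p_diff) and p_diff >= ALPHA:
        res = stats.ttest_rel(comp, const)
        name = "paired t-test"
    else:
        res = stats.wilcoxon(comp, const)
        name = "Wilcoxon signed-rank"
    return PairedComparison(
        target_id=target_id,
        n_pairs=int(comp.size),
        normality_p_compensated=p_comp,
        normality_p_constant=p_const,
        normality_p_differences=p_diff,
        test_name=name,
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        significant=bool(res.pvalue < ALPHA),
    )


def _group_comparison(method: str, groups: list[np.ndarray]) -> GroupComparison:
    if len(groups) < 2:
        return GroupComparison(
            method=method,
            bartlett_p=math.nan,
            test_name="not applicable",
            statistic=math.nan,
            p_value=math.nan,
            significant=None,
        )
    bartlett_p = float(stats.bartlett(*groups).pvalue)
    if bartlett_p >= ALPHA:
        res = stats.f_oneway(*groups)
        name = "one-way ANOVA"
    else:
        res = stats.kruskal(*groups)
        name = "Kruskal-Wallis"
    return GroupComparison(
        method=method,
        bartlett_p=bartlett_p,
        test_name=name,
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        significant=bool(res.pvalue < ALPHA),
    )


def compare_methods(
    per_target: dict[str, tuple[Sequence[float], Sequence[float]]],
) -> tuple[tuple[PairedComparison, ...], tuple[GroupComparison, ...]]:
    """Statistical comparison of the two methods.

    ``per_target`` maps target id to ``(compensated, constant_flux)``
    discrepancy lists, paired point-by-point.  Within each target the
    paired test is a t-test when the paired differences pass Shapiro-Wilk
    normality at alpha=0.05 and Wilcoxon signed-rank otherwise; identical
    lists are flagged degenerate.  Across targets each method's
    discrepancy groups get Bartlett's test, then one-way ANOVA if variances
    are homogeneous (p >= 0.05) and Kruskal-Wallis otherwise.
    """
    paired = tuple(
        _paired_comparison(
            tid, np.asarray(comp, float), np.asarray(const, float)
        )
        for tid, (comp, const) in per_target.items()
    )
    comp_groups = [np.asarray(v[0], float) for v in per_target.values()]
    const_groups = [np.asarray(v[1], float) for v in per_target.values()]
    group = (
        _group_comparison(METHOD_COMPENSATED, comp_groups),
        _group_comparison(METHOD_CONSTANT_FLUX, const_groups),
    )
    return paired, group


def run_full_validation(
    series_list: Sequence[MeasurementSeries],
    plan: TreatmentPlan,
    n_min: int = N_MIN_DEFAULT,
    threshold_near: float = NEAR_THRESHOLD_PERCENT,
) -> ValidationSummary:
    """End-to-end harness over several targets.

    Fits the lifetime reference model per target, validates both methods at
    every eligible point, summarizes each method per target, and runs the
    statistical comparison pipeline.
    """
    records: list[ValidationRecord] = []
    per_target_lists: dict[str, tuple[list[float], list[float]]] = {}
    skipped: dict[str, list[int]] = {}
    for series in series_list:
        reference = fit_flux_model(series, n_min=n_min)
        recs, skip = run_lifetime_validation(series, reference, plan, n_min=n_min)
        records.extend(recs)
        skipped[series.target_id] = skip
        comp = [r.discrepancy_percent for r in recs if r.method == METHOD_COMPENSATED]
        const = [
            r.discrepancy_percent for r in recs if r.method == METHOD_CONSTANT_FLUX
        ]
        per_target_lists[series.target_id] = (comp, const)

    per_target = {
        tid: {
            METHOD_COMPENSATED: summarize(comp, threshold_near),
            METHOD_CONSTANT_FLUX: summarize(const, threshold_near),
        }
        for tid, (comp, const) in per_target_lists.items()
    }
    paired, group = compare_methods(per_target_lists)
    return ValidationSummary(
        records=tuple(records),
        per_target=per_target,
        paired_tests=paired,
        group_tests=group,
        skipped=skipped,
    )


def _fmt_p(p: float) -> str:
    return "NA" if math.isnan(p) else f"{p:.3g}"


def format_report(summary: ValidationSummary, plan: TreatmentPlan) -> str:
    """Human-readable validation report."""
    lines = []
    lines.append("Fluence delivery validation")
    lines.append(
        f"  prescribed fluence NF = {plan.required_fluence:.6g} atom^-1 "
        f"(planning flux {plan.planning_flux:.6g} Bq/mA/atom x "
        f"{plan.tentative_charge:.6g} mC)"
    )
    lines.append("")
    header = (
        f"  {'target':<8} {'method':<14} {'n':>4} {'median%':>8} "
        f"{'min%':>7} {'max%':>7} {'sd%':>6} {'|d|<=1%':>8}"
    )
    lines.append(header)
    for tid, methods in summary.per_target.items():
        for method, s in methods.items():
            sd = "NA" if math.isnan(s.sd) else f"{s.sd:.2f}"
            lines.append(
                f"  {tid:<8} {method:<14} {s.n:>4} {s.median:>8.2f} "
                f"{s.minimum:>7.2f} {s.maximum:>7.2f} {sd:>6} "
                f"{s.fraction_within:>8.1%}"
            )
    lines.append("")
    lines.append("  Paired method comparison per target:")
    for t in summary.paired_tests:
        flag = (
            "NA" if t.significant is None
            else ("significant" if t.significant else "not significant")
        )
        lines.append(
            f"    {t.target_id}: {t.test_name}, p = {_fmt_p(t.p_value)} "
            f"({flag}; diff-normality p = {_fmt_p(t.normality_p_differences)})"
        )
    lines.append("  Across-target comparison per method:")
    for g in summary.group_tests:
        lines.append(
            f"    {g.method}: Bartlett p = {_fmt_p(g.bartlett_p)} -> "
            f"{g.test_name}, p = {_fmt_p(g.p_value)}"
        )
    skipped_total = sum(len(v) for v in summary.skipped.values())
    lines.append(
        f"  Skipped treatment points (insufficient history/fit): {skipped_total}"
    )
    return "\n".join(lines) + "\n"
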