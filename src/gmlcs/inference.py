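"""Nested-model likelihood-ratio machinery and the invariance ladder.

The likelihood-ratio test compares a parent model, in which the parameter(s)
of interest are free, against a child model in which they are fixed (to zero
or to equality across groups).  For single-df tests with a directional
hypothesis the one-sided p-value is half the two-sided one when the free
estimate's sign matches the hypothesis, and 1 minus that half otherwise —
the convention here is positive change hypothesized in the exercise group
and negative change in the control group.

The factorial-invariance ladder runs, in order: group invariance at
occasion 1 (configural -> metric, df 2; metric -> strict, df 3), then time
invariance with groups collapsed into a single pooled fit (configural ->
metric, df 4; metric -> strict, df 6), stopping at the first step that is
significant two-sided at alpha.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from . import model_builders as mb
from .sem_engine import POOLED, FitResult, ModelSpec, fit, start_from
from .studytable import StudyTable

#: tolerance for a negative chi-square difference attributable to numerical
#: noise in two separate optimizations; anything worse is an error
NEGATIVE_DELTA_TOL = 1e-4


@dataclass
class LRTResult:
    delta_chi_square: float
    delta_df: int
    p_two_sided: float
    p_one_sided: float | None
    direction_hypothesis: str  # "positive" | "negative" | "none"
    estimate_sign_matches: bool | None
    parent_model: str
    child_model: str

    def __post_init__(self) -> None:
        if self.delta_df < 0:
            raise ValueError("delta_df must be >= 0")
        if (self.p_one_sided is None) != (self.direction_hypothesis == "none"):
            raise ValueError("one-sided p present iff a direction is hypothesized")

    @property
    def p(self) -> float:
        """The operative p-value: one-sided when a direction was hypothesized."""
        return self.p_one_sided if self.p_one_sided is not None else self.p_two_sided


@dataclass
class InvarianceReport:
    roi: str
    steps: list[tuple[str, LRTResult]] = field(default_factory=list)
    invariant: bool = True
    failing_step: str | None = None

    def step(self, label: str) -> LRTResult | None:
        for lbl, res in self.steps:
            if lbl == label:
                return res
        return None


# ----------------------------------------------------------------------
def lrt(
    parent: FitResult,
    child: FitResult,
    direction: str = "none",
    estimate: float | None = None,
) -> LRTResult:
    """Likelihood-ratio test of ``child`` (constrained) against ``parent``.

    ``estimate`` is the freely estimated value of the tested parameter in
    the parent model; its sign against ``direction`` decides which tail the
    one-sided p-value lives in.  Nesting is verified structurally.
    """
    if direction not in ("positive", "negative", "none"):
        raise ValueError("direction must be 'positive', 'negative' or 'none'")
    if not child.spec.nested_within(parent.spec):
        raise ValueError(
            f"model {child.spec.name!r} is not nested within {parent.spec.name!r}"
        )
    if not (parent.converged and child.converged):
        raise ValueError("both models must have converged for a valid LRT")
    delta_df = child.spec.df() - parent.spec.df()
    if delta_df < 0:
        raise ValueError("child must not have more free parameters than parent")
    delta = child.neg2ll - parent.neg2ll
    if delta < -NEGATIVE_DELTA_TOL:
        raise RuntimeError(
            f"negative chi-square difference ({delta:.4g}) between "
            f"{child.spec.name!r} and {parent.spec.name!r}: the parent fit did "
            "not reach its optimum — refit with more restarts"
        )
    delta = max(delta, 0.0)
    # df = 0: comparing a model against itself (or a reparameterization)
    p_two = 1.0 if delta_df == 0 else float(stats.chi2.sf(delta, delta_df))
    p_one = None
    matches = None
    if direction != "none":
        if delta_df != 1:
            raise ValueError("directional tests are defined for delta_df = 1 only")
        if estimate is None:
            raise ValueError("a directional test needs the parent's free estimate")
        matches = (estimate > 0) == (direction == "positive")
        p_one = p_two / 2 if matches else 1.0 - p_two / 2
    return LRTResult(
        delta_chi_square=float(delta),
        delta_df=delta_df,
        p_two_sided=p_two,
        p_one_sided=p_one,
        direction_hypothesis=direction,
        estimate_sign_matches=matches,
        parent_model=parent.spec.name,
        child_model=child.spec.name,
    )


# ----------------------------------------------------------------------
def fit_nested(
    parent: FitResult,
    child_spec: ModelSpec,
    data,
    restarts: int = 2,
    seed: int = 0,
    **fit_kwargs,
) -> tuple[FitResult, FitResult]:
    """Fit a constrained child warm-started from its parent's solution.

    If the child nevertheless lands below the parent's -2lnL (the parent
    stuck in a local optimum), the parent is refitted warm-started from the
    child — its solution is feasible for the parent, so the refit can only
    improve.  Returns (possibly-updated parent, child).
    """
    fit_kwargs.setdefault("indices", False)
    fit_kwargs.setdefault("standard_errors", False)
    child = fit(
        child_spec, data, start=start_from(parent, child_spec),
        restarts=restarts, seed=seed, **fit_kwargs,
    )
    if child.neg2ll < parent.neg2ll - NEGATIVE_DELTA_TOL:
        refit = fit(
            parent.spec, data, start=start_from(child, parent.spec),
            restarts=max(restarts, 3), seed=seed + 1,
            indices=parent.chi_square is not None,
            standard_errors=any(v is not None for v in parent.se.values()),
        )
        if refit.neg2ll < parent.neg2ll:
            parent = refit
    return parent, child


def invariance_ladder(
    config: "mb.ROIModelConfig",
    data: StudyTable,
    alpha: float = 0.05,
    restarts: int = 2,
    seed: int = 0,
) -> InvarianceReport:
    """Run the four-step factorial-invariance ladder for one ROI.

    Steps (in order, each a two-sided LRT at ``alpha``): group-metric
    (df 2) and group-strict (df 3) on the occasion-1 factor across groups;
    time-metric (df 4) and time-strict (df 6) on the pooled three-occasion
    model.  Stops at the first significant step; the ROI is invariant iff
    no step rejects.
    """
    roi = config.roi
    report = InvarianceReport(roi=roi)

    def _fit(spec: ModelSpec) -> FitResult:
        return fit(
            spec, data, restarts=restarts, indices=False, standard_errors=False, seed=seed
        )

    # --- group invariance at occasion 1 -------------------------------
    group_specs = [
        (lvl, mb.build_occasion_factor(roi, 1, config.groups, lvl, config.modalities))
        for lvl in mb.INVARIANCE_LEVELS
    ]
    time_specs = [
        (
            lvl,
            mb.build_integrity_lcsm(
                mb.ROIModelConfig(
                    roi=roi, modalities=config.modalities, groups=(POOLED,), invariance=lvl
                )
            ),
        )
        for lvl in mb.INVARIANCE_LEVELS
    ]
    for prefix, chain in (("group", group_specs), ("time", time_specs)):
        parent = _fit(chain[0][1])
        for lvl, spec in chain[1:]:
            label = f"{prefix}-{lvl}"
            try:
                parent, child = fit_nested(parent, spec, data, restarts=restarts, seed=seed)
                res = lrt(parent, child)
            except (RuntimeError, ValueError) as exc:
                raise RuntimeError(f"invariance step {label!r} for {roi}: {exc}") from exc
            report.steps.append((label, res))
            if res.p_two_sided < alpha:
                report.invariant = False
                report.failing_step = label
                return report
            parent = child
    return report


# ----------------------------------------------------------------------
def wald_loading_test(result: FitResult, label: str, direction: str) -> float:
    """One-sided Wald test of a single estimate against zero.

    z = estimate / SE; p is the standard-normal tail probability in the
    hypothesized direction.
    """
    if direction not in ("positive", "negative"):
        raise ValueError("direction must be 'positive' or 'negative'")
    if label not in result.estimates:
        raise ValueError(f"no estimate for label {label!r}")
    se = result.se.get(label)
    if se is None or not np.isfinite(se) or se <= 0:
        raise ValueError(f"no standard error available for label {label!r}")
    z = result.estimates[label] / se
    return float(stats.norm.sf(z) if direction == "positive" else stats.norm.cdf(z))


def welch_t(group_a, group_b) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test with Satterthwaite df (two-sided p)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        raise ValueError("both groups have zero variance; t undefined")
    sa, sb = va / a.size, vb / b.size
    t = (a.mean() - b.mean()) / np.sqrt(sa + sb)
    df = (sa + sb) ** 2 / (sa**2 / (a.size - 1) + sb**2 / (b.size - 1))
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return float(t), float(df), p
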