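"""Critical-age detection by iterative decade pooling, and biphasic regression.

Cross-sectional visual metrics in choroideremia follow a biphasic course: a
quiescent phase followed by linear decline. The breakpoint ("critical age")
is found nonparametrically: subjects are grouped by decade of age, a
Kruskal–Wallis ANOVA is run over the groups with Dunn's pairwise z-tests
(Bonferroni-corrected), and, starting from the youngest decade, each group
is pooled with the next-oldest while the two are not significantly
different. The first significant pooled-vs-next comparison fixes the
critical age at the upper bound of the pooled group. One ordinary
least-squares regression of the metric on age is then fitted per phase.

The procedure is exposed both as plain functions and as a
``CriticalAgeModel`` whose ``fit()`` returns a ``CriticalAgeResults`` with a
``summary()`` table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats

from .cohort import SubjectRecord
from .vision import ALL_DECADES, DecadeBin, better_eye_series, decade_bin

__all__ = [
    "KWResult",
    "DunnComparison",
    "PhaseRegression",
    "CriticalAgeResults",
    "CriticalAgeModel",
    "kruskal_wallis",
    "dunn_pairwise",
    "fit_phase_regression",
    "find_critical_age",
    "biphasic_report",
]


@dataclass(frozen=True)
class KWResult:
    """Tie-corrected Kruskal–Wallis H with chi-square p (df = k-1)."""

    H: float
    df: int
    p: float


@dataclass(frozen=True)
class DunnComparison:
    """One Dunn pairwise rank z-test with Bonferroni-adjusted p."""

    group_a: str
    group_b: str
    z: float
    p_raw: float
    p_adjusted: float
    significant: bool


@dataclass(frozen=True)
class PhaseRegression:
    """OLS fit of a visual metric on age within one phase."""

    slope: float
    intercept: float
    slope_ci_low: float
    slope_ci_high: float
    p_slope: float
    n: int


@dataclass
class PoolingStep:
    """Audit record of one pooled-vs-next comparison."""

    pooled_bins: tuple
    next_bin: DecadeBin
    comparison: DunnComparison
    omnibus: KWResult


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> KWResult:
    """Kruskal–Wallis rank ANOVA over k >= 2 non-empty groups."""
    if len(groups) < 2:
        raise ValueError("at least two groups are required")
    if any(len(g) == 0 for g in groups):
        raise ValueError("empty group passed to kruskal_wallis")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if all(np.all(a == arrays[0][0]) for a in arrays):
        # All observations identical: H = 0 by definition, but scipy raises.
        return KWResult(H=0.0, df=len(groups) - 1, p=1.0)
    H, p = stats.kruskal(*arrays)
    return KWResult(H=float(H), df=len(groups) - 1, p=float(p))


def _midranks(groups):
    pooled = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    ranks = stats.rankdata(pooled)
    out, start = [], 0
    for g in groups:
        out.append(ranks[start:start + len(g)])
        start += len(g)
    return out, pooled


def dunn_pairwise(
    groups: Sequence[Sequence[float]],
    alpha: float = 0.05,
    labels: Optional[Sequence[str]] = None,
) -> list[DunnComparison]:
    """Dunn's z-tests on mean ranks for every pair of groups.

    The pooled-rank variance uses the tie correction sum(t^3 - t)/(12(N-1));
    two-sided p-values are Bonferroni-adjusted over all k(k-1)/2 pairs.
    """
    if len(groups) < 2:
        raise ValueError("at least two groups are required")
    if any(len(g) == 0 for g in groups):
        raise ValueError("empty group passed to dunn_pairwise")
    k = len(groups)
    labels = list(labels) if labels is not None else [str(i) for i in range(k)]
    rank_groups, pooled = _midranks(groups)
    N = pooled.size
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (N - 1)) if N > 1 else 0.0
    base_var = N * (N + 1) / 12.0 - tie_term
    mean_ranks = [float(np.mean(r)) for r in rank_groups]
    m = k * (k - 1) // 2
    out = []
    for i in range(k):
        for j in range(i + 1, k):
            var = base_var * (1.0 / len(groups[i]) + 1.0 / len(groups[j]))
            if var <= 0:  # total ties: all values identical
                z = 0.0
            else:
                z = (mean_ranks[i] - mean_ranks[j]) / math.sqrt(var)
            p_raw = 2.0 * stats.norm.sf(abs(z))
            p_adj = min(1.0, m * p_raw)
            out.append(
                DunnComparison(
                    group_a=labels[i],
                    group_b=labels[j],
                    z=float(z),
                    p_raw=float(p_raw),
                    p_adjusted=float(p_adj),
                    significant=bool(p_adj < alpha),
                )
            )
    return out


def fit_phase_regression(ages: Sequence[float], values: Sequence[float]) -> PhaseRegression:
    """OLS of metric on age with a t-based 95% CI on the slope."""
    ages = np.asarray(ages, dtype=float)
    values = np.asarray(values, dtype=float)
    n = ages.size
    if n < 3:
        raise ValueError("phase regression requires n >= 3")
    if np.ptp(ages) == 0:
        raise ValueError("zero variance in age: slope undefined")
    if np.ptp(values) == 0:
        # constant response: zero slope, no evidence against it
        return PhaseRegression(0.0, float(values[0]), 0.0, 0.0, 1.0, int(n))
    import statsmodels.api as sm

    X = sm.add_constant(ages)
    fit = sm.OLS(values, X).fit()
    ci_low, ci_high = fit.conf_int(alpha=0.05)[1]
    p = float(fit.pvalues[1])
    if math.isnan(p):  # perfectly constant response: slope 0 with no evidence
        p = 1.0
    return PhaseRegression(
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        slope_ci_low=float(ci_low),
        slope_ci_high=float(ci_high),
        p_slope=p,
        n=int(n),
    )


@dataclass
class CriticalAgeResults:
    """Detected critical age, the pooling audit trail and both phase fits.

    ``critical_age`` is the closed upper bound of the final pooled young
    group (40 means "the <=40 group differs from the 41-50 group"); it is
    ``None`` when no comparison ever reaches significance, in which case
    ``phase1`` holds a single whole-range regression and ``phase2`` is None.
    """

    metric: str
    critical_age: Optional[int]
    pooling_trace: list = field(default_factory=list)
    phase1: Optional[PhaseRegression] = None
    phase2: Optional[PhaseRegression] = None
    alpha: float = 0.05

    @property
    def decline_rate(self) -> Optional[float]:
        """Post-break progression rate in the metric's reporting convention:
        logMAR lost per year for VA, degrees of field lost per year for VF
        (both positive when worsening)."""
        if self.phase2 is None:
            return None
        return self.phase2.slope if self.metric == "va" else -self.phase2.slope

    def summary(self) -> str:
        lines = []
        name = {"va": "visual acuity (logMAR)", "vf": "visual-field width (degrees)"}.get(self.metric, self.metric)
        lines.append(f"Critical-age analysis: {name}")
        lines.append("=" * 58)
        if self.critical_age is None:
            lines.append("critical age: not detected (no significant pooled comparison)")
        else:
            lines.append(f"critical age: {self.critical_age} years")
        for step in self.pooling_trace:
            pooled = f"{step.pooled_bins[0].lower}–{step.pooled_bins[-1].upper}"
            c = step.comparison
            lines.append(
                f"  pooled {pooled:>7} vs {step.next_bin.label:>5}: "
                f"z = {c.z:6.2f}, adj. p = {c.p_adjusted:.4f}"
                + ("  *" if c.significant else "")
            )
        for label, ph in (("phase 1", self.phase1), ("phase 2", self.phase2)):
            if ph is None:
                continue
            lines.append(
                f"{label}: slope {ph.slope:+.4f}/yr "
                f"(95% CI {ph.slope_ci_low:.4f} to {ph.slope_ci_high:.4f}; "
                f"P = {ph.p_slope:.3g}; n = {ph.n})"
            )
        return "\n".join(lines)


class CriticalAgeModel:
    """Biphasic natural-history model of a visual metric against age.

    Parameters
    ----------
    records
        Subject records (or anything ``better_eye_series`` accepts).
    metric
        ``"va"`` (better-eye logMAR) or ``"vf"`` (better-eye field width).
    comparison
        How the pooled-vs-next p-value is obtained at each step:

        * ``"selected"`` (default) — Dunn's z on the ranks of *all* current
          groups, corrected for the single comparison examined (m = 1). This
          matches re-running the omnibus test after every pooling and
          reading off only the youngest-vs-second-youngest comparison.
        * ``"all_pairs"`` — the same z, Bonferroni-corrected over all
          k(k−1)/2 current pairs.
        * ``"two_group"`` — a fresh two-group Dunn test (pooled vs next
          only), uncorrected.
    """

    def __init__(self, records: Iterable[SubjectRecord], metric: str = "va",
                 comparison: str = "selected"):
        if comparison not in ("selected", "all_pairs", "two_group"):
            raise ValueError(f"unknown comparison scheme {comparison!r}")
        self.metric = metric
        self.comparison = comparison
        self.ages, self.values = better_eye_series(records, metric)

    @classmethod
    def from_arrays(cls, ages, values, metric: str = "va", **kwargs) -> "CriticalAgeModel":
        model = cls.__new__(cls)
        model.metric = metric
        model.comparison = kwargs.get("comparison", "selected")
        model.ages = np.asarray(ages, dtype=float)
        model.values = np.asarray(values, dtype=float)
        return model

    def _decade_groups(self):
        bins, groups = [], []
        for b in ALL_DECADES:
            mask = np.array([a in b for a in self.ages])
            if mask.any():
                bins.append(b)
                groups.append(self.values[mask])
        return bins, groups

    def fit(self, alpha: float = 0.05) -> CriticalAgeResults:
        bins, groups = self._decade_groups()
        if len(bins) < 2:
            raise ValueError("need at least two non-empty decade bins")
        trace: list[PoolingStep] = []
        critical: Optional[int] = None
        n_pooled = 1  # bins currently merged into the young pooled group
        while n_pooled < len(bins):
            pooled_values = np.concatenate(groups[:n_pooled])
            current = [pooled_values] + groups[n_pooled:]
            labels = [f"≤{bins[n_pooled - 1].upper}"] + [b.label for b in bins[n_pooled:]]
            omnibus = kruskal_wallis(current)
            if self.comparison == "two_group":
                comp = dunn_pairwise(current[:2], alpha=alpha, labels=labels[:2])[0]
            else:
                comparisons = dunn_pairwise(current, alpha=alpha, labels=labels)
                comp = next(
                    c for c in comparisons
                    if {c.group_a, c.group_b} == {labels[0], labels[1]}
                )
                if self.comparison == "selected":
                    comp = DunnComparison(
                        group_a=comp.group_a, group_b=comp.group_b, z=comp.z,
                        p_raw=comp.p_raw, p_adjusted=comp.p_raw,
                        significant=bool(comp.p_raw < alpha),
                    )
            trace.append(
                PoolingStep(
                    pooled_bins=tuple(bins[:n_pooled]),
                    next_bin=bins[n_pooled],
                    comparison=comp,
                    omnibus=omnibus,
                )
            )
            if comp.significant:
                critical = bins[n_pooled - 1].upper
                break
            n_pooled += 1

        results = CriticalAgeResults(
            metric=self.metric, critical_age=critical, pooling_trace=trace, alpha=alpha
        )
        if critical is None:
            results.phase1 = fit_phase_regression(self.ages, self.values)
        else:
            young = self.ages <= critical
            if young.sum() >= 3 and np.ptp(self.ages[young]) > 0:
                results.phase1 = fit_phase_regression(self.ages[young], self.values[young])
            if (~young).sum() >= 3 and np.ptp(self.ages[~young]) > 0:
                results.phase2 = fit_phase_regression(self.ages[~young], self.values[~young])
        return results


def find_critical_age(records: Iterable[SubjectRecord], metric: str, alpha: float = 0.05,
                      comparison: str = "selected") -> CriticalAgeResults:
    """Run the iterative decade-pooling procedure on a cohort."""
    return CriticalAgeModel(records, metric=metric, comparison=comparison).fit(alpha=alpha)


def biphasic_report(records: Iterable[SubjectRecord], metric: str, alpha: float = 0.05) -> CriticalAgeResults:
    """Alias of :func:`find_critical_age`; the results object carries both
    phase regressions and the reporting-convention ``decline_rate``."""
    return find_critical_age(records, metric, alpha=alpha)
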