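"""Onset-of-symptom survival analysis and intereye correlation.

Self-reported onset ages (nyctalopia, other visual symptoms) are analyzed
with Kaplan–Meier product-limit curves per genotype group; a subject who has
not reported the symptom by his last assessment is right-censored at that
age. Group curves are compared with the log-rank (Mantel–Cox) test, with a
Wilcoxon–Breslow alternative. Between-eye agreement of VA and VF is
quantified with Spearman's rank correlation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .cohort import GenotypeGroup, SubjectRecord, assign_genotype_group

__all__ = [
    "SurvivalCurve",
    "GroupComparison",
    "CorrelationResult",
    "km_curve",
    "compare_onset",
    "onset_summary",
    "intereye_spearman",
    "OnsetSurvivalModel",
    "OnsetSurvivalResults",
    "onset_groups",
    "intereye_pairs",
]


@dataclass(frozen=True)
class SurvivalCurve:
    """Kaplan–Meier step function.

    ``times`` are the distinct event/censoring ages; ``survival[i]`` is
    S(times[i]) just after that age; ``at_risk[i]`` the number at risk just
    before it. ``median`` is the first time with S <= 0.5 (None if S never
    reaches 0.5); ``median_interpolated`` is the midpoint between the last
    time with S > 0.5 and that time — the convention some packages print.
    """

    times: tuple
    survival: tuple
    at_risk: tuple
    median: Optional[float]
    median_interpolated: Optional[float]

    def s(self, t: float) -> float:
        """S(t): probability of remaining symptom-free beyond age t."""
        s = 1.0
        for time, surv in zip(self.times, self.survival):
            if time <= t:
                s = surv
            else:
                break
        return s


@dataclass(frozen=True)
class GroupComparison:
    statistic: float
    df: int
    p: float
    groups: tuple  # (label, n) pairs


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    n: int


def km_curve(event_ages: Sequence[float], observed: Optional[Sequence[bool]] = None) -> SurvivalCurve:
    """Product-limit estimate of the onset-free curve.

    ``observed[i]`` False means censoring at ``event_ages[i]`` (no symptom by
    that age).
    """
    ages = np.asarray(event_ages, dtype=float)
    if ages.size == 0:
        raise ValueError("km_curve requires at least one subject")
    if observed is None:
        observed = np.ones(ages.size, dtype=bool)
    observed = np.asarray(observed, dtype=bool)

    from lifelines import KaplanMeierFitter

    kmf = KaplanMeierFitter()
    kmf.fit(ages, event_observed=observed)
    table = kmf.event_table
    sf = kmf.survival_function_["KM_estimate"]
    # lifelines prepends t=0 with S=1; keep observed/censoring times only.
    times = [float(t) for t in sf.index if t in set(ages)]
    survival = [float(sf.loc[t]) for t in times]
    at_risk = [int(table.loc[t, "at_risk"]) for t in times]

    # median: first time with S <= 0.5. When S lands exactly on 0.5 the
    # interpolated convention averages with the next event time (the classic
    # even-n sample median, e.g. 10.5 for onsets {...,10,11,...}); a strict
    # crossing needs no interpolation.
    median = None
    median_interp = None
    for i, (t, s) in enumerate(zip(times, survival)):
        if s <= 0.5 + 1e-9:
            median = float(t)
            if abs(s - 0.5) < 1e-9 and i + 1 < len(times):
                median_interp = (t + times[i + 1]) / 2.0
            else:
                median_interp = float(t)
            break
    return SurvivalCurve(
        times=tuple(times),
        survival=tuple(survival),
        at_risk=tuple(at_risk),
        median=median,
        median_interpolated=median_interp,
    )


def compare_onset(groups: Mapping, test: str = "logrank") -> GroupComparison:
    """k-group comparison of onset curves.

    ``groups`` maps a label to ``(ages, observed)``. ``test`` is
    ``"logrank"`` (Mantel–Cox, default) or ``"wilcoxon"`` (Breslow weights).
    """
    items = [(str(k), np.asarray(a, float), np.asarray(o, bool)) for k, (a, o) in groups.items()]
    items = [(k, a, o) for k, a, o in items if a.size > 0]
    if len(items) < 2:
        raise ValueError("compare_onset requires at least two non-empty groups")
    durations = np.concatenate([a for _, a, _ in items])
    events = np.concatenate([o for _, _, o in items])
    labels = np.concatenate([np.repeat(k, a.size) for k, a, _ in items])

    from lifelines.statistics import multivariate_logrank_test

    weightings = None if test == "logrank" else "wilcoxon"
    if test not in ("logrank", "wilcoxon"):
        raise ValueError(f"unknown test {test!r}")
    res = multivariate_logrank_test(durations, labels, events, weightings=weightings)
    return GroupComparison(
        statistic=float(res.test_statistic),
        df=len(items) - 1,
        p=float(res.p_value),
        groups=tuple((k, int(a.size)) for k, a, _ in items),
    )


def onset_summary(ages: Sequence[float]) -> Tuple[float, Optional[float], int]:
    """(mean, SEM, n) of reported onset ages; SEM is None for n = 1."""
    ages = np.asarray(ages, dtype=float)
    if ages.size == 0:
        raise ValueError("onset_summary requires at least one onset age")
    mean = float(np.mean(ages))
    sem = float(np.std(ages, ddof=1) / math.sqrt(ages.size)) if ages.size > 1 else None
    return mean, sem, int(ages.size)


def intereye_spearman(pairs: Iterable[Tuple[Optional[float], Optional[float]]]) -> CorrelationResult:
    """Spearman rank correlation between fellow eyes; incomplete pairs dropped."""
    complete = [(od, os) for od, os in pairs if od is not None and os is not None]
    if len(complete) < 3:
        raise ValueError("intereye correlation requires at least 3 complete pairs")
    od, os = zip(*complete)
    rho, _ = stats.spearmanr(od, os)
    return CorrelationResult(rho=float(rho), n=len(complete))


# ---------------------------------------------------------------------------
# cohort-level helpers and the Model/Results wrapper
# ---------------------------------------------------------------------------


def onset_groups(records: Iterable[SubjectRecord], symptom: str = "nyctalopia") -> dict:
    """Per-genotype-group (ages, observed) arrays for one symptom.

    Subjects without a recorded onset are censored at their age at
    assessment; subjects without variants are skipped.
    """
    attr = {"nyctalopia": "onset_nyctalopia_years", "other": "onset_other_years"}[symptom]
    out: dict = {}
    for r in records:
        if not r.variants:
            continue
        group = assign_genotype_group(r.variants).value
        onset = getattr(r, attr)
        ages, observed = out.setdefault(group, ([], []))
        if onset is None:
            ages.append(float(r.age_years))
            observed.append(False)
        else:
            ages.append(float(onset))
            observed.append(True)
    return out


def intereye_pairs(records: Iterable[SubjectRecord], metric: str = "va"):
    """(OD, OS) value pairs for subjects with both eyes measured."""
    pairs = []
    for r in records:
        if metric == "va":
            od = r.va_od.logmar if r.va_od is not None else None
            os = r.va_os.logmar if r.va_os is not None else None
        else:
            od = r.vf_od.width_degrees if r.vf_od is not None else None
            os = r.vf_os.width_degrees if r.vf_os is not None else None
        pairs.append((od, os))
    return pairs


@dataclass
class OnsetSurvivalResults:
    symptom: str
    curves: dict  # group label -> SurvivalCurve
    comparison: Optional[GroupComparison]
    summaries: dict  # group label -> (mean, sem, n) of observed onsets

    def summary(self) -> str:
        lines = [f"Onset analysis: {self.symptom}", "=" * 50]
        for label, curve in self.curves.items():
            med = "n/a" if curve.median is None else f"{curve.median:g}"
            mean, sem, n = self.summaries.get(label, (None, None, 0))
            stat = "" if mean is None else f", mean onset {mean:.1f} ± {0 if sem is None else sem:.1f} (SEM), n = {n}"
            lines.append(f"  {label}: median onset {med}{stat}")
        if self.comparison is not None:
            c = self.comparison
            lines.append(f"log-rank chi2 = {c.statistic:.2f}, df = {c.df}, P = {c.p:.3g}")
        return "\n".join(lines)


class OnsetSurvivalModel:
    """Kaplan–Meier onset model stratified by genotype group."""

    def __init__(self, records: Iterable[SubjectRecord], symptom: str = "nyctalopia"):
        self.symptom = symptom
        self.groups = onset_groups(list(records), symptom)

    def fit(self, test: str = "logrank") -> OnsetSurvivalResults:
        curves, summaries = {}, {}
        for label, (ages, observed) in self.groups.items():
            curves[label] = km_curve(ages, observed)
            reported = [a for a, o in zip(ages, observed) if o]
            if reported:
                summaries[label] = onset_summary(reported)
        comparison = compare_onset(self.groups, test=test) if len(self.groups) >= 2 else None
        return OnsetSurvivalResults(self.symptom, curves, comparison, summaries)
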