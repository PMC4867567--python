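"""Acuity and visual-field normalization, better-eye selection, decade binning.

Acuity is expressed throughout in logMAR (log10 of the minimum angle of
resolution, 0.0 = Snellen 20/20, larger = worse). Semiquantitative grades
use the fixed conversion CF 1.9, HM 2.3, LP 2.7, NLP 3.0. For each subject
the better eye is analyzed: the *smaller* logMAR, the *larger* field width.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from .cohort import SubjectRecord

__all__ = [
    "SEMIQUANT_LOGMAR",
    "semiquant_to_logmar",
    "snellen_to_logmar",
    "better_eye",
    "decade_bin",
    "DecadeBin",
    "StratumSummary",
    "stratified_summary",
    "pooled_mean",
    "severity_bands",
    "SEVERITY_BAND_EDGES",
    "better_eye_series",
]

SEMIQUANT_LOGMAR = {"CF": 1.9, "HM": 2.3, "LP": 2.7, "NLP": 3.0}


def semiquant_to_logmar(code: str) -> float:
    """logMAR equivalent of a semiquantitative acuity grade (CF/HM/LP/NLP)."""
    try:
        return SEMIQUANT_LOGMAR[code.upper()]
    except (KeyError, AttributeError):
        raise ValueError(f"unknown semiquantitative acuity code {code!r}") from None


def snellen_to_logmar(numerator: float, denominator: float) -> float:
    """logMAR of a Snellen fraction: log10(denominator / numerator)."""
    if numerator <= 0 or denominator <= 0:
        raise ValueError("Snellen numerator and denominator must be positive")
    return math.log10(denominator / numerator)


def better_eye(od: Optional[float], os: Optional[float], metric: str = "logmar") -> Optional[float]:
    """Value of the better-seeing eye; passes a single eye through.

    ``metric="logmar"`` takes the minimum (lower logMAR is better);
    ``metric="field_width"`` takes the maximum (wider field is better).
    """
    if metric not in ("logmar", "field_width"):
        raise ValueError(f"unknown metric {metric!r}")
    values = [v for v in (od, os) if v is not None]
    if not values:
        return None
    return min(values) if metric == "logmar" else max(values)


@dataclass(frozen=True, order=True)
class DecadeBin:
    """Closed decade age interval, e.g. 1–10 or 41–50."""

    lower: int

    def __post_init__(self):
        if self.lower % 10 != 1 or not 1 <= self.lower <= 71:
            raise ValueError(f"invalid decade lower bound {self.lower}")

    @property
    def upper(self) -> int:
        return self.lower + 9

    @property
    def label(self) -> str:
        return f"{self.lower}–{self.upper}"

    def __contains__(self, age) -> bool:
        return self.lower <= age <= self.upper


ALL_DECADES = tuple(DecadeBin(lo) for lo in range(1, 80, 10))


def decade_bin(age) -> DecadeBin:
    """Decade bin of an integer age in [1, 80]; fractional ages are floored."""
    age = math.floor(age)
    if not 1 <= age <= 80:
        raise ValueError(f"age {age} outside the supported range 1-80")
    return DecadeBin(10 * ((age - 1) // 10) + 1)


@dataclass(frozen=True)
class StratumSummary:
    bin: DecadeBin
    n: int
    mean: Optional[float] = None
    sd: Optional[float] = None
    median: Optional[float] = None


def _metric_value(record: SubjectRecord, metric: str) -> Optional[float]:
    if metric == "age":
        return float(record.age_years)
    if metric == "va":
        od = record.va_od.logmar if record.va_od is not None else None
        os = record.va_os.logmar if record.va_os is not None else None
        return better_eye(od, os, "logmar")
    if metric == "vf":
        od = record.vf_od.width_degrees if record.vf_od is not None and not record.vf_od.excluded else None
        os = record.vf_os.width_degrees if record.vf_os is not None and not record.vf_os.excluded else None
        return better_eye(od, os, "field_width")
    raise ValueError(f"unknown metric {metric!r}")


def better_eye_series(records: Iterable[SubjectRecord], metric: str):
    """(ages, better-eye values) for subjects with the metric recorded."""
    ages, values = [], []
    for r in records:
        v = _metric_value(r, metric)
        if v is not None:
            ages.append(r.age_years)
            values.append(v)
    return np.asarray(ages, dtype=float), np.asarray(values, dtype=float)


def stratified_summary(records: Iterable[SubjectRecord], metric: str) -> list[StratumSummary]:
    """Per-decade n, mean, sample SD and median of a metric.

    Subjects missing the metric do not count toward ``n``. All eight decade
    bins are emitted; empty bins carry ``n=0`` and absent statistics.
    """
    by_bin: dict[DecadeBin, list[float]] = {b: [] for b in ALL_DECADES}
    for r in records:
        v = _metric_value(r, metric)
        if v is not None:
            by_bin[decade_bin(r.age_years)].append(v)
    out = []
    for b in ALL_DECADES:
        vals = np.asarray(by_bin[b], dtype=float)
        if vals.size == 0:
            out.append(StratumSummary(bin=b, n=0))
        else:
            sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
            out.append(
                StratumSummary(
                    bin=b,
                    n=int(vals.size),
                    mean=float(np.mean(vals)),
                    sd=sd,
                    median=float(np.median(vals)),
                )
            )
    return out


def pooled_mean(strata: Sequence) -> float:
    """n-weighted grand mean across strata: sum(n_i * mean_i) / sum(n_i).

    Accepts StratumSummary objects or plain ``(n, mean)`` pairs.
    """
    pairs = []
    for s in strata:
        if isinstance(s, StratumSummary):
            pairs.append((s.n, s.mean))
        else:
            pairs.append(tuple(s))
    total_n = sum(n for n, _ in pairs)
    if total_n == 0:
        raise ValueError("pooled mean undefined: all strata empty")
    return sum(n * m for n, m in pairs if n > 0) / total_n


#: VA severity band upper edges (logMAR): 20/40, 20/70, 20/200.
SEVERITY_BAND_EDGES = (0.3, 0.54, 1.0)
_BAND_LABELS = ("<=0.3", "0.3-0.54", "0.54-1.0", ">1.0")


def severity_bands(records: Iterable[SubjectRecord]):
    """Better-eye VA counts in severity bands, per decade and total.

    Bands are (-inf, 0.3], (0.3, 0.54], (0.54, 1.0], (1.0, inf) in logMAR,
    closed on the better-vision side. Returns a dict with per-decade counts
    (keyed by decade label), per-decade ``n`` and the cohort totals.
    """
    counts = {b.label: dict.fromkeys(_BAND_LABELS, 0) for b in ALL_DECADES}
    for r in records:
        v = _metric_value(r, "va")
        if v is None:
            continue
        idx = sum(v > edge for edge in SEVERITY_BAND_EDGES)
        counts[decade_bin(r.age_years).label][_BAND_LABELS[idx]] += 1
    totals = dict.fromkeys(_BAND_LABELS, 0)
    for decade in counts.values():
        for band, c in decade.items():
            totals[band] += c
    return {"bands": _BAND_LABELS, "per_decade": counts, "total": totals}
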