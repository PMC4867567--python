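"""Mutation-spectrum comparison, REP-1 unfolding propensity, trial design.

The unfolding propensity maps a mutation's stabilization free-energy change
ΔΔG (kcal/mol, positive = destabilizing) onto the probability that the
mutant protein occupies the unfolded state under a two-state (folded ↔
unfolded) Boltzmann model:

    U = exp(ΔΔG/RT) / (1 + exp(ΔΔG/RT)),   F = 1 − U

with an effective RT of 0.6 kcal/mol. The constant is inferred: it is the
single value that reproduces the published propensities of all six REP-1
missense variants to three decimals, and it is close to (but not exactly)
RT at body temperature.

The trial-design calculator answers "how long until a progressing
visual-field width is distinguishable from its baseline?", taking the
within/inter-visit variability of Goldmann perimetry (17–22% of the field
diameter in retinitis pigmentosa, adopted here) as the detectability
threshold: years = variability_fraction × baseline / rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

__all__ = [
    "RT_EFFECTIVE",
    "SpectrumComparison",
    "StabilityRecord",
    "TrialDesignEstimate",
    "spectrum_chisq",
    "unfolding_propensity",
    "double_mutant_check",
    "time_to_detectable_change",
    "predicted_baseline",
    "HGMD_CATEGORIES",
]

#: Effective RT (kcal/mol) of the two-state propensity model (inferred, see module docstring).
RT_EFFECTIVE = 0.6

#: Mutation-class taxonomy used for genome-wide (HGMD-style) spectrum
#: comparisons; ten categories, so a goodness-of-fit test has df = 9.
HGMD_CATEGORIES = (
    "missense",
    "nonsense",
    "splicing",
    "small_deletion",
    "small_insertion",
    "small_indel",
    "gross_deletion",
    "gross_insertion_duplication",
    "complex_rearrangement",
    "regulatory",
)


@dataclass(frozen=True)
class SpectrumComparison:
    categories: tuple
    observed: tuple
    reference: tuple
    chi2: float
    df: int
    p: float


@dataclass(frozen=True)
class StabilityRecord:
    mutant: str
    ddG: float
    U: float
    F: float


@dataclass(frozen=True)
class TrialDesignEstimate:
    age: Optional[float]
    baseline_width: float
    rate: float
    variability_fraction: float
    years_to_detectable: float


def spectrum_chisq(observed: Sequence[float], reference: Sequence[float],
                   categories: Optional[Sequence[str]] = None) -> SpectrumComparison:
    """Pearson goodness-of-fit of observed class counts against reference
    proportions (expected = N × reference), p from chi-square with df = k−1."""
    observed = np.asarray(observed, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if observed.shape != reference.shape:
        raise ValueError("observed and reference must have the same length")
    if abs(reference.sum() - 1.0) > 1e-9:
        raise ValueError("reference proportions must sum to 1")
    if np.any(reference <= 0):
        raise ValueError("every reference proportion must be positive")
    if observed.sum() < 1:
        raise ValueError("at least one observation is required")
    expected = observed.sum() * reference
    chi2, p = stats.chisquare(observed, f_exp=expected)
    k = observed.size
    if categories is None:
        categories = tuple(str(i) for i in range(k))
    return SpectrumComparison(
        categories=tuple(categories),
        observed=tuple(float(o) for o in observed),
        reference=tuple(float(r) for r in reference),
        chi2=float(chi2),
        df=k - 1,
        p=float(p),
    )


def unfolding_propensity(ddG: float, rt: float = RT_EFFECTIVE) -> Tuple[float, float]:
    """(U, F) of a mutant under the two-state Boltzmann model."""
    if rt <= 0:
        raise ValueError("rt must be positive")
    # logistic form is overflow-safe for large |ddG|
    u = 1.0 / (1.0 + math.exp(-ddG / rt))
    return u, 1.0 - u


def double_mutant_check(ddG_single_a: float, ddG_single_b: float, ddG_double: float,
                        rt: float = RT_EFFECTIVE, atol: float = 1e-9) -> dict:
    """Compare a double mutant's ΔΔG with the sum of its single mutants.

    Reports each variant's unfolding propensity and whether the combined
    destabilization is additive, sub-additive (double < sum) or
    super-additive (double > sum).
    """
    expected_sum = ddG_single_a + ddG_single_b
    diff = ddG_double - expected_sum
    if abs(diff) <= atol:
        additivity = "additive"
    elif diff < 0:
        additivity = "sub-additive"
    else:
        additivity = "super-additive"
    return {
        "ddG_sum_singles": expected_sum,
        "ddG_double": ddG_double,
        "difference": diff,
        "additivity": additivity,
        "U_single_a": unfolding_propensity(ddG_single_a, rt)[0],
        "U_single_b": unfolding_propensity(ddG_single_b, rt)[0],
        "U_double": unfolding_propensity(ddG_double, rt)[0],
    }


def time_to_detectable_change(baseline_width: float, rate: float,
                              variability_fraction: float = 0.22) -> float:
    """Years until a declining field width exits the measurement-variability
    band around baseline: variability_fraction × baseline / rate.

    ``rate`` is the loss in degrees/year (positive); the default variability
    fraction is the upper (22%) bound of Goldmann test–retest variability,
    the 17% bound being available via the argument.
    """
    if rate <= 0:
        raise ValueError("rate must be positive: no detectable change otherwise")
    if baseline_width <= 0:
        raise ValueError("baseline_width must be positive")
    if not 0 < variability_fraction < 1:
        raise ValueError("variability_fraction must be in (0, 1)")
    return variability_fraction * baseline_width / rate


def predicted_baseline(age: float, anchor_age: float = 20.0, anchor_width: float = 38.0,
                       rate: float = 0.868) -> float:
    """Expected field width at a given age on the post-break linear decline
    anchored at 38° at age 20, floored at zero."""
    if age < anchor_age:
        raise ValueError(f"age must be >= the anchor age {anchor_age}")
    return max(0.0, anchor_width - rate * (age - anchor_age))


def trial_design_estimate(age: float, variability_fraction: float = 0.22,
                          anchor_age: float = 20.0, anchor_width: float = 38.0,
                          rate: float = 0.868) -> TrialDesignEstimate:
    """Convenience: baseline at age via the fitted decline, then the
    detectability horizon, reported to the printed precision (1 dp)."""
    baseline = predicted_baseline(age, anchor_age, anchor_width, rate)
    years = time_to_detectable_change(baseline, rate, variability_fraction)
    return TrialDesignEstimate(
        age=age,
        baseline_width=baseline,
        rate=rate,
        variability_fraction=variability_fraction,
        years_to_detectable=round(years, 1),
    )
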