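"""Kaplan-Meier onset curves, log-rank comparison, intereye correlation."""

import itertools
import math

import numpy as np
import pytest

from chmnat.cohort import AcuityMeasure, FieldMeasure, SubjectRecord, parse_variant
from chmnat.survival import (
    OnsetSurvivalModel,
    compare_onset,
    intereye_pairs,
    intereye_spearman,
    km_curve,
    onset_groups,
    onset_summary,
)


def test_km_hand_computed_product_limit():
    """{10,10,11,12,15,20,30} all observed: S(12) = 3/7, median 12."""
    curve = km_curve([10, 10, 11, 12, 15, 20, 30])
    assert curve.s(12) == pytest.approx(3 / 7)
    assert curve.median == 12
    # no censoring: KM equals the empirical survivor function everywhere
    ages = np.array([10, 10, 11, 12, 15, 20, 30])
    for t in (9, 10, 11, 14.5, 30):
        assert curve.s(t) == pytest.approx(np.mean(ages > t))


def test_km_single_event_and_all_censored():
    single = km_curve([15.0])
    assert single.survival == (0.0,)
    assert single.median == 15.0
    censored = km_curve([10, 20, 30], observed=[False, False, False])
    assert all(s == 1.0 for s in censored.survival)
    assert censored.median is None


def test_km_median_interpolation_convention():
    """Six events with S exactly 0.5 at t=10: the step-function median is
    10, the interpolated (classic even-n) convention gives 10.5."""
    curve = km_curve([8, 9, 10, 11, 12, 13])
    assert curve.median == 10
    assert curve.median_interpolated == 10.5


def test_km_requires_subjects():
    with pytest.raises(ValueError):
        km_curve([])


def test_compare_onset_identical_groups():
    g = ([10.0, 12.0, 15.0], [True, True, True])
    res = compare_onset({"a": g, "b": g})
    assert res.statistic == pytest.approx(0.0, abs=1e-12)
    assert res.p == pytest.approx(1.0)
    assert res.df == 1


def test_compare_onset_requires_two_groups():
    with pytest.raises(ValueError):
        compare_onset({"a": ([1.0, 2.0], [True, True])})


def logrank_chi2(groups):
    """Independent textbook log-rank statistic for k groups, no ties across
    the observed/expected bookkeeping beyond shared event times."""
    all_times = sorted({t for ages, obs in groups for t, o in zip(ages, obs) if o})
    k = len(groups)
    O = np.zeros(k)
    E = np.zeros(k)
    for t in all_times:
        at_risk = np.array([sum(a >= t for a in ages) for ages, _ in groups], float)
        deaths = np.array(
            [sum(1 for a, o in zip(ages, obs) if o and a == t) for ages, obs in groups], float
        )
        N, D = at_risk.sum(), deaths.sum()
        O += deaths
        E += D * at_risk / N
    return float(np.sum((O - E) ** 2 / np.where(E > 0, E, 1.0)))


def test_separated_groups_significant_and_permutation_extreme():
    """{5,6,7} vs {30,31,32}: log-rank flags the difference, and the label
    permutation oracle confirms the observed statistic is the extreme of its
    permutation distribution."""
    groups = {"young": ([5.0, 6.0, 7.0], [True] * 3), "old": ([30.0, 31.0, 32.0], [True] * 3)}
    res = compare_onset(groups)
    assert res.p < 0.05

    ages = [5.0, 6.0, 7.0, 30.0, 31.0, 32.0]
    observed_stat = logrank_chi2([(ages[:3], [True] * 3), (ages[3:], [True] * 3)])
    perms = list(itertools.combinations(range(6), 3))
    stats_all = []
    for idx in perms:
        g1 = [ages[i] for i in idx]
        g2 = [ages[i] for i in range(6) if i not in idx]
        stats_all.append(logrank_chi2([(g1, [True] * 3), (g2, [True] * 3)]))
    n_extreme = sum(s >= observed_stat - 1e-9 for s in stats_all)
    assert n_extreme == 2  # the split and its mirror image
    assert observed_stat == pytest.approx(max(stats_all))


def test_compare_onset_matches_oracle_statistic():
    """Implementation and the independent summation oracle agree on a mixed
    censored dataset (n = 10)."""
    a = ([4.0, 7.0, 9.0, 12.0, 15.0], [True, True, False, True, True])
    b = ([6.0, 8.0, 10.0, 11.0, 20.0], [True, False, True, True, False])
    res = compare_onset({"a": a, "b": b})
    # the oracle must extend at-risk counting to censored subjects
    def oracle(groups):
        all_times = sorted({t for ages, obs in groups for t, o in zip(ages, obs) if o})
        O = np.zeros(2)
        E = np.zeros(2)
        V = 0.0
        for t in all_times:
            n_i = np.array([sum(a >= t for a in ages) for ages, _ in groups], float)
            d_i = np.array(
                [sum(1 for a, o in zip(ages, obs) if o and a == t) for ages, obs in groups],
                float,
            )
            N, D = n_i.sum(), d_i.sum()
            O += d_i
            E += D * n_i / N
            if N > 1:
                V += D * (n_i[0] / N) * (1 - n_i[0] / N) * (N - D) / (N - 1)
        return (O[0] - E[0]) ** 2 / V

    assert res.statistic == pytest.approx(oracle([a, b]), abs=1e-8)


def test_onset_summary_hand_values():
    mean, sem, n = onset_summary([10, 10, 20])
    assert mean == pytest.approx(13.333, abs=1e-3)
    assert sem == pytest.approx(10 / math.sqrt(3) / math.sqrt(3), abs=1e-3)  # sd 5.7735
    assert n == 3


def test_onset_summary_single_value():
    mean, sem, n = onset_summary([12])
    assert (mean, sem, n) == (12.0, None, 1)


def test_spearman_examples():
    assert intereye_spearman([(1, 1), (2, 2), (3, 3)]).rho == pytest.approx(1.0)
    assert intereye_spearman([(1, 3), (2, 2), (3, 1)]).rho == pytest.approx(-1.0)
    res = intereye_spearman([(1, 1), (2, 3), (3, 2), (4, 4)])
    assert res.rho == pytest.approx(0.8)
    assert res.n == 4


def test_spearman_monotone_transform_invariance():
    rng = np.random.default_rng(4)
    od = rng.normal(size=30)
    os = od + rng.normal(scale=0.5, size=30)
    base = intereye_spearman(list(zip(od, os))).rho
    transformed = intereye_spearman(list(zip(np.exp(od), os**3))).rho
    assert transformed == pytest.approx(base, abs=1e-12)


def test_spearman_drops_incomplete_pairs():
    res = intereye_spearman([(1, 1), (2, 2), (None, 5), (3, 3), (4, None)])
    assert res.n == 3
    with pytest.raises(ValueError):
        intereye_spearman([(1, 1), (2, 2), (None, 3)])


def _subject(sid, age, onset, hgvs, protein):
    return SubjectRecord(
        subject_id=sid, family_id=sid, age_years=age,
        onset_nyctalopia_years=onset,
        variants=[parse_variant(hgvs, protein)],
    )


def test_onset_groups_censor_at_assessment_age():
    records = [
        _subject("a", 40, 12, "c.757C>T", "p.Arg253*"),
        _subject("b", 35, None, "c.757C>T", "p.Arg253*"),
        _subject("c", 20, 9, "c.238C>T", "p.Leu80Phe"),
    ]
    groups = onset_groups(records, "nyctalopia")
    ages, observed = groups["other"]
    assert ages == [12.0, 35.0]
    assert observed == [True, False]
    assert groups["missense"] == ([9.0], [True])


def test_onset_model_summary_runs(va_cohort):
    res = OnsetSurvivalModel(va_cohort, symptom="nyctalopia").fit()
    assert res.comparison is None or 0.0 <= res.comparison.p <= 1.0
    text = res.summary()
    assert "Onset analysis" in text and "median onset" in text
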