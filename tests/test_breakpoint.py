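"""Kruskal-Wallis/Dunn machinery and the iterative critical-age procedure.

Oracles: a textbook summation formula for H, exhaustive rank-label
permutation nulls at small n, and closed-form normal equations for OLS.
"""

import itertools
import math

import numpy as np
import pytest
from scipy import stats

from chmnat.breakpoint import (
    CriticalAgeModel,
    dunn_pairwise,
    find_critical_age,
    fit_phase_regression,
    kruskal_wallis,
)
from chmnat.simulate import CohortConfig, simulate_cohort


def kw_h_oracle(groups):
    """Independent textbook H: 12/(N(N+1)) * sum n_i rbar_i^2 - 3(N+1),
    divided by the tie-correction factor 1 - sum(t^3-t)/(N^3-N)."""
    pooled = np.concatenate([np.asarray(g, float) for g in groups])
    ranks = stats.rankdata(pooled)
    N = pooled.size
    h = 0.0
    start = 0
    for g in groups:
        r = ranks[start:start + len(g)]
        h += len(g) * np.mean(r) ** 2
        start += len(g)
    h = 12.0 / (N * (N + 1)) * h - 3 * (N + 1)
    _, t = np.unique(pooled, return_counts=True)
    correction = 1.0 - np.sum(t**3 - t) / (N**3 - N)
    return h / correction


def test_kruskal_wallis_hand_example():
    """Three fully separated triples: mean ranks 2/5/8 give H = 7.2."""
    res = kruskal_wallis([[1, 2, 3], [4, 5, 6], [7, 8, 9]])
    assert res.H == pytest.approx(7.2, abs=1e-12)
    assert res.df == 2
    assert res.p == pytest.approx(1 - stats.chi2.cdf(7.2, 2))


def test_kruskal_wallis_identical_groups():
    res = kruskal_wallis([[5, 5, 5], [5, 5, 5]])
    assert res.H == 0.0
    assert res.p == 1.0


def test_kruskal_wallis_requires_two_nonempty_groups():
    with pytest.raises(ValueError):
        kruskal_wallis([[1, 2, 3]])
    with pytest.raises(ValueError):
        kruskal_wallis([[1, 2], []])


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_h_matches_summation_oracle_with_ties(seed):
    rng = np.random.default_rng(seed)
    groups = [list(rng.integers(0, 5, size=n)) for n in (4, 6, 5)]
    assert kruskal_wallis(groups).H == pytest.approx(kw_h_oracle(groups), abs=1e-10)


def test_kw_two_groups_against_exhaustive_permutation():
    """k=2, n=8 total: the chi-square p approximates the exact permutation
    null of H; they agree to within 0.1 and in the rejection decision."""
    a, b = [1.0, 2.0, 5.0, 7.0], [3.0, 4.0, 6.0, 8.0]
    obs = kruskal_wallis([a, b])
    pooled = a + b
    count = 0
    perms = list(itertools.combinations(range(8), 4))
    for idx in perms:
        g1 = [pooled[i] for i in idx]
        g2 = [pooled[i] for i in range(8) if i not in idx]
        if kw_h_oracle([g1, g2]) >= kw_h_oracle([a, b]) - 1e-12:
            count += 1
    p_perm = count / len(perms)
    assert abs(obs.p - p_perm) < 0.1
    assert (obs.p < 0.05) == (p_perm < 0.05)


def test_dunn_identical_groups_not_significant():
    comps = dunn_pairwise([[1, 2, 3]] * 3)
    assert all(c.p_adjusted == 1.0 and not c.significant for c in comps)


def test_dunn_two_groups_unadjusted():
    comps = dunn_pairwise([[1, 2, 3], [7, 8, 9]])
    assert len(comps) == 1
    assert comps[0].p_adjusted == comps[0].p_raw


def test_dunn_bonferroni_multiplicity():
    comps = dunn_pairwise([[1, 2], [3, 4], [5, 6], [7, 8]])
    assert len(comps) == 6
    for c in comps:
        assert c.p_adjusted == pytest.approx(min(1.0, 6 * c.p_raw))


def test_dunn_separated_groups_against_permutation_oracle():
    """Group gap >> spread (4 per group): Dunn flags a-vs-c, and the exact
    label-permutation null of the a/c mean-rank gap agrees."""
    a = [1.0, 2.0, 3.0, 4.0]
    b = [1.5, 2.5, 3.5, 4.5]
    c = [50.0, 60.0, 70.0, 80.0]
    comps = dunn_pairwise([a, b, c], alpha=0.05, labels=["a", "b", "c"])
    ac = next(x for x in comps if {x.group_a, x.group_b} == {"a", "c"})
    assert ac.significant

    def rank_gap(g1, g3):
        ranks = stats.rankdata(np.concatenate([g1, b, g3]))
        return abs(np.mean(ranks[:4]) - np.mean(ranks[8:]))

    observed = rank_gap(a, c)
    pool = a + c
    gaps = []
    for idx in itertools.combinations(range(8), 4):
        g1 = [pool[i] for i in idx]
        g3 = [pool[i] for i in range(8) if i not in idx]
        gaps.append(rank_gap(g1, g3))
    p_perm = sum(g >= observed - 1e-12 for g in gaps) / len(gaps)
    assert p_perm < 0.05
    assert abs(p_perm - ac.p_raw) < 0.05


def test_ols_matches_normal_equations():
    ages = np.array([20.0, 30.0, 41.0, 55.0, 62.0, 70.0])
    values = np.array([0.1, 0.15, 0.3, 0.9, 1.2, 1.4])
    fit = fit_phase_regression(ages, values)
    sxx = np.sum((ages - ages.mean()) ** 2)
    sxy = np.sum((ages - ages.mean()) * (values - values.mean()))
    slope = sxy / sxx
    assert fit.slope == pytest.approx(slope, abs=1e-10)
    assert fit.intercept == pytest.approx(values.mean() - slope * ages.mean(), abs=1e-10)
    assert fit.slope_ci_low <= fit.slope <= fit.slope_ci_high


def test_ols_exact_line_and_constant():
    ages = np.arange(41, 60, dtype=float)
    fit = fit_phase_regression(ages, 0.048 * ages)
    assert fit.slope == pytest.approx(0.048, abs=1e-12)
    flat = fit_phase_regression(ages, np.full_like(ages, 0.7))
    assert flat.slope == pytest.approx(0.0, abs=1e-12)
    assert flat.p_slope == 1.0


def test_ols_input_validation():
    with pytest.raises(ValueError):
        fit_phase_regression([1, 2], [1, 2])
    with pytest.raises(ValueError):
        fit_phase_regression([5, 5, 5], [1, 2, 3])


def test_noiseless_biphasic_recovered_exactly():
    """Two noiseless segments with a break at 40: the procedure finds the
    break and returns both generating slopes exactly."""
    ages = np.arange(1, 81, dtype=float)
    values = np.where(ages <= 40, 0.05, 0.05 + 0.048 * (ages - 40))
    model = CriticalAgeModel.from_arrays(ages, values, metric="va")
    res = model.fit()
    assert res.critical_age == 40
    assert res.phase1.slope == pytest.approx(0.0, abs=1e-12)
    assert res.phase2.slope == pytest.approx(0.048, abs=1e-10)


def test_flat_cohort_has_no_critical_age():
    ages = np.arange(1, 81, dtype=float)
    model = CriticalAgeModel.from_arrays(ages, np.full(80, 0.1), metric="va")
    res = model.fit()
    assert res.critical_age is None
    assert res.phase2 is None
    assert res.phase1.n == 80


def test_pooling_trace_monotone_and_bounded(va_cohort):
    res = find_critical_age(va_cohort, "va")
    sizes = [len(step.pooled_bins) for step in res.pooling_trace]
    assert sizes == list(range(1, len(sizes) + 1))
    assert len(sizes) <= 7
    if res.critical_age is not None:
        assert res.pooling_trace[-1].comparison.significant
        assert res.critical_age in {10, 20, 30, 40, 50, 60, 70}


def test_comparison_scheme_ordering(va_cohort):
    """The all-pairs Bonferroni scheme can never flag earlier than the
    selected-comparison scheme on the same data."""
    selected = find_critical_age(va_cohort, "va", comparison="selected")
    all_pairs = find_critical_age(va_cohort, "va", comparison="all_pairs")
    if all_pairs.critical_age is not None:
        assert selected.critical_age is not None
        assert selected.critical_age <= all_pairs.critical_age


def test_no_age_effect_rarely_finds_breakpoint():
    """Flat generating process (both slopes 0, age-independent symmetric
    noise, so the value distribution truly does not depend on age): the
    Bonferroni-protected procedure declares no critical age in >= 90% of
    seeds."""
    absent = 0
    n_seeds = 60
    for seed in range(n_seeds):
        cfg = CohortConfig(
            seed=seed, va_slope_pre=0.0, va_slope_post=0.0,
            noise="gaussian", va_noise_sd_by_decade=(0.15,) * 8,
        )
        res = find_critical_age(simulate_cohort(cfg), "va", comparison="all_pairs")
        absent += res.critical_age is None
    assert absent / n_seeds >= 0.9
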