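"""Synthetic CHM cohort generator.

Emulates the statistical structure of the cross-sectional study cohort so
that every analysis stage can be exercised without patient data:

* decade age structure of the 128-male VA cohort (and the 64-male VF
  subcohort) with heteroskedastic per-decade noise taken from the published
  decade SDs;
* biphasic better-eye trajectories — VA flat near 0.05 logMAR to a break at
  40 years then worsening 0.048 logMAR/yr; VF a high-variance plateau in
  childhood then a linear constriction of 0.868°/yr from 38° at the age-20
  break;
* fellow-eye values through a Gaussian copula targeting the observed
  intereye Spearman correlations (VA ≈ 0.76, VF ≈ 0.95);
* self-reported onset ages (nyctalopia ≈ N(12.6, 8.4), other symptoms ≈
  N(19.7, 11.0), truncated at 1 year), right-censored when later than the
  age at assessment or simply unreported;
* family structure and mutation classes drawn from the bundled 106-family
  spectrum, with a representative HGVS string per class.

The generator is deterministic given ``CohortConfig.seed``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .cohort import (
    AcuityMeasure,
    FieldMeasure,
    MutationClass,
    SubjectRecord,
    VariantCall,
)
from .vision import SEMIQUANT_LOGMAR

__all__ = ["CohortConfig", "simulate_cohort", "table_fixtures"]

# Table-derived defaults: per-decade n for the VA cohort (sum 128) and the
# VF subcohort (sum 64), and the per-decade sample SDs of each metric.
_VA_DECADE_N = (10, 28, 17, 19, 24, 15, 12, 3)
_VF_DECADE_N = (5, 16, 7, 7, 15, 10, 4, 0)
_VA_DECADE_SD = (0.118, 0.126, 0.059, 0.172, 0.497, 0.765, 0.845, 0.231)
_VF_DECADE_SD = (51.0, 56.0, 45.0, 11.0, 9.0, 6.0, 2.0, 2.0)


@dataclass(frozen=True)
class CohortConfig:
    """Generator parameters; defaults are the study conditions."""

    n_subjects: int = 128
    seed: int = 0
    age_decade_counts: Sequence[int] = _VA_DECADE_N

    # visual acuity (better-eye logMAR vs age)
    va_break_age: float = 40.0
    va_baseline: float = 0.05
    va_slope_pre: float = 0.001
    va_slope_post: float = 0.048
    va_noise_sd_by_decade: Sequence[float] = _VA_DECADE_SD

    # visual field (better-eye width, degrees, vs age)
    vf_break_age: float = 20.0
    vf_anchor_width: float = 38.0
    vf_slope_post: float = 0.868
    #: mean width of the pre-break high-variance plateau (n-weighted mean of
    #: the published 1-10 and 11-20 decade means).
    vf_plateau_mean: float = 73.5
    vf_noise_sd_by_decade: Sequence[float] = _VF_DECADE_SD
    #: how many subjects per decade have fields measured (sum 64 of 128).
    vf_decade_counts: Sequence[int] = _VF_DECADE_N

    # intereye agreement (Spearman)
    intereye_rho_va: float = 0.76
    intereye_rho_vf: float = 0.95

    # symptom onset (years)
    onset_nyct_mean: float = 12.6
    onset_nyct_sd: float = 8.4
    onset_other_mean: float = 19.7
    onset_other_sd: float = 11.0
    #: probability that an experienced onset is actually on record
    #: (71 and 72 of 128 subjects reported onsets).
    onset_report_prob: float = 0.58

    #: noise family: "lognormal" (right-skewed above a floor, matching the
    #: published decade medians, which sit well below the means) or
    #: "gaussian" (symmetric, clipped).
    noise: str = "lognormal"
    #: best recordable acuity (logMAR); the VA distribution is a lognormal
    #: shifted to start here.
    va_floor: float = -0.1
    #: residual central-island width (degrees): expected VF never falls
    #: below this, matching the small positive widths of the oldest decade.
    vf_floor: float = 2.0

    #: per-class family weights; None = family counts of the bundled spectrum.
    mutation_class_weights: Optional[dict] = None
    #: re-code generated logMAR >= 1.9 to the nearest CF/HM/LP/NLP grade, as
    #: severely affected eyes are recorded in practice.
    semiquant_recode: bool = False

    def __post_init__(self):
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if len(self.age_decade_counts) != 8 or any(c < 0 for c in self.age_decade_counts):
            raise ValueError("age_decade_counts must be 8 nonnegative counts")
        if len(self.vf_decade_counts) != 8:
            raise ValueError("vf_decade_counts must have 8 entries")
        for name in ("va_noise_sd_by_decade", "vf_noise_sd_by_decade"):
            sds = getattr(self, name)
            if len(sds) != 8 or any(s <= 0 for s in sds):
                raise ValueError(f"{name} must be 8 positive SDs")
        for rho in (self.intereye_rho_va, self.intereye_rho_vf):
            if not -1.0 <= rho <= 1.0:
                raise ValueError("intereye correlations must lie in [-1, 1]")
        if not 0.0 <= self.onset_report_prob <= 1.0:
            raise ValueError("onset_report_prob must lie in [0, 1]")
        if self.noise not in ("lognormal", "gaussian"):
            raise ValueError("noise must be 'lognormal' or 'gaussian'")
        if self.vf_floor <= 0:
            raise ValueError("vf_floor must be positive")
        if self.mutation_class_weights is not None and any(
            w < 0 for w in self.mutation_class_weights.values()
        ):
            raise ValueError("mutation class weights must be nonnegative")

    @classmethod
    def vf_study(cls, n_subjects: int = 64, seed: int = 0, **overrides) -> "CohortConfig":
        """Configuration for the field-assessed subcohort: the decade
        structure of the 64 males with measured fields, every subject's
        fields recorded."""
        counts = _scale_counts(_VF_DECADE_N, n_subjects)
        return cls(
            n_subjects=n_subjects,
            seed=seed,
            age_decade_counts=counts,
            vf_decade_counts=counts,
            **overrides,
        )


def _scale_counts(counts: Sequence[int], n: int) -> tuple:
    """Scale integer counts to sum n by largest remainder."""
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if total == 0:
        raise ValueError("cannot scale an all-zero count vector")
    exact = counts * n / total
    floors = np.floor(exact).astype(int)
    short = n - floors.sum()
    order = np.argsort(-(exact - floors))
    floors[order[:short]] += 1
    return tuple(int(c) for c in floors)


def _spearman_to_pearson(rho_s: float) -> float:
    """Pearson correlation of the Gaussian copula achieving a target
    Spearman correlation: r = 2 sin(pi * rho_s / 6)."""
    return 2.0 * math.sin(math.pi * rho_s / 6.0)


def _correlated_pair(rng: np.random.Generator, r: float):
    z1 = rng.standard_normal()
    z2 = r * z1 + math.sqrt(max(0.0, 1.0 - r * r)) * rng.standard_normal()
    return z1, z2


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float, lower: float) -> float:
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if x >= lower:
            return x
    return lower  # pathological config; keep the draw valid


def _lognormal_from_z(z: float, mean: float, sd: float) -> float:
    """Value of a lognormal with the given mean and SD at normal score z.

    A monotone transform of z, so Gaussian-copula rank correlations pass
    through unchanged.
    """
    sigma2 = math.log1p((sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return math.exp(mu + math.sqrt(sigma2) * z)


def _noise_value(z: float, mean: float, sd: float, floor: float, cfg: CohortConfig) -> float:
    if cfg.noise == "gaussian":
        return mean + sd * z
    return floor + _lognormal_from_z(z, max(mean - floor, 1e-6), sd)


def _acuity(value: float, recode: bool) -> AcuityMeasure:
    value = float(np.clip(value, -0.1, 3.0))
    if recode and value >= 1.9:
        code = min(SEMIQUANT_LOGMAR, key=lambda c: abs(SEMIQUANT_LOGMAR[c] - value))
        return AcuityMeasure(raw=code, logmar=SEMIQUANT_LOGMAR[code])
    return AcuityMeasure(raw=round(value, 3), logmar=round(value, 3))


def _class_representatives() -> dict:
    """One fixture family's variant strings per mutation class."""
    from .datasets import mutation_family_variants

    reps: dict = {}
    weights: dict = {}
    for fam, variants in mutation_family_variants():
        classes = {v.mutation_class for v in variants}
        for cls in classes:
            weights[cls] = weights.get(cls, 0) + 1
            reps.setdefault(cls, []).append(variants)
    return reps, weights


def _mean_va(age: float, cfg: CohortConfig) -> float:
    if age <= cfg.va_break_age:
        return cfg.va_baseline + cfg.va_slope_pre * age
    return (cfg.va_baseline + cfg.va_slope_pre * cfg.va_break_age
            + cfg.va_slope_post * (age - cfg.va_break_age))


def _mean_vf(age: float, cfg: CohortConfig) -> float:
    if age <= cfg.vf_break_age:
        return cfg.vf_plateau_mean
    return max(cfg.vf_floor, cfg.vf_anchor_width - cfg.vf_slope_post * (age - cfg.vf_break_age))


def simulate_cohort(config: CohortConfig = CohortConfig()) -> list:
    """Draw a synthetic cohort of SubjectRecords; deterministic given the seed."""
    cfg = config  # validation happened in __post_init__
    rng = np.random.default_rng(cfg.seed)

    decade_counts = _scale_counts(cfg.age_decade_counts, cfg.n_subjects)
    if cfg.n_subjects == sum(cfg.age_decade_counts):
        decade_counts = tuple(int(c) for c in cfg.age_decade_counts)
    vf_quota = list(cfg.vf_decade_counts)
    if cfg.n_subjects != sum(cfg.age_decade_counts):
        scale = cfg.n_subjects / sum(cfg.age_decade_counts)
        vf_quota = [min(dc, int(round(q * scale))) for q, dc in zip(vf_quota, decade_counts)]
    vf_quota = [min(q, dc) for q, dc in zip(vf_quota, decade_counts)]

    # family structure: ~106 families per 128 subjects; extra subjects join
    # existing families.
    n_families = max(1, int(round(cfg.n_subjects * 106.0 / 128.0)))
    reps, fixture_weights = _class_representatives()
    if cfg.mutation_class_weights is not None:
        weights = {MutationClass(k): v for k, v in cfg.mutation_class_weights.items()}
    else:
        weights = fixture_weights
    classes = [c for c in weights if weights[c] > 0 and c in reps]
    probs = np.array([weights[c] for c in classes], dtype=float)
    probs /= probs.sum()
    family_variants = []
    for _ in range(n_families):
        cls = classes[rng.choice(len(classes), p=probs)]
        candidates = reps[cls]
        family_variants.append(candidates[rng.integers(len(candidates))])
    membership = list(range(n_families))
    membership += list(rng.integers(0, n_families, size=cfg.n_subjects - n_families))
    rng.shuffle(membership)

    r_va = _spearman_to_pearson(cfg.intereye_rho_va)
    r_vf = _spearman_to_pearson(cfg.intereye_rho_vf)

    records = []
    idx = 0
    for d, (count, quota) in enumerate(zip(decade_counts, vf_quota)):
        lower = 10 * d + 1
        measure_vf = [True] * quota + [False] * (count - quota)
        rng.shuffle(measure_vf)
        for j in range(count):
            age = int(rng.integers(lower, lower + 10))
            mu_va = _mean_va(age, cfg)
            z1, z2 = _correlated_pair(rng, r_va)
            sd_va = cfg.va_noise_sd_by_decade[d]
            va_od = _acuity(_noise_value(z1, mu_va, sd_va, cfg.va_floor, cfg), cfg.semiquant_recode)
            va_os = _acuity(_noise_value(z2, mu_va, sd_va, cfg.va_floor, cfg), cfg.semiquant_recode)

            vf_od = vf_os = None
            if measure_vf[j]:
                mu_vf = _mean_vf(age, cfg)
                w1, w2 = _correlated_pair(rng, r_vf)
                sd_vf = cfg.vf_noise_sd_by_decade[d]
                v1 = _noise_value(w1, mu_vf, sd_vf, 0.0, cfg)
                v2 = _noise_value(w2, mu_vf, sd_vf, 0.0, cfg)
                vf_od = FieldMeasure(float(np.clip(v1, 0.0, 180.0)))
                vf_os = FieldMeasure(float(np.clip(v2, 0.0, 180.0)))

            onset_nyct = onset_other = None
            if rng.random() < cfg.onset_report_prob:
                x = _truncated_normal(rng, cfg.onset_nyct_mean, cfg.onset_nyct_sd, 1.0)
                if x <= age:
                    onset_nyct = int(round(x))
            if rng.random() < cfg.onset_report_prob:
                x = _truncated_normal(rng, cfg.onset_other_mean, cfg.onset_other_sd, 1.0)
                if x <= age:
                    onset_other = int(round(x))

            fam = membership[idx]
            records.append(
                SubjectRecord(
                    subject_id=f"SYN{idx + 1:04d}",
                    family_id=f"FAM{fam + 1:03d}",
                    variants=list(family_variants[fam]),
                    age_years=age,
                    onset_nyctalopia_years=onset_nyct,
                    onset_other_years=onset_other,
                    va_od=va_od,
                    va_os=va_os,
                    vf_od=vf_od,
                    vf_os=vf_os,
                )
            )
            idx += 1
    return records


def table_fixtures():
    """The bundled reference tables as typed objects: (decade summaries
    DataFrame, mutation-family variant lists, stability records, missense
    subjects)."""
    from .datasets import (
        load_decade_summaries,
        load_missense_subjects,
        load_stability_records,
        mutation_family_variants,
    )

    return (
        load_decade_summaries(),
        mutation_family_variants(),
        load_stability_records(),
        load_missense_subjects(),
    )
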