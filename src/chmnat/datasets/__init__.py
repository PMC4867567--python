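"""Bundled reference tables for the CHM natural-history analyses.

Three small plain-text tables ship with the package:

``chm_mutation_families.tsv``
    The mutation spectrum of 106 CHM families (coding-DNA change, exon,
    protein consequence; two families carry two changes), transcribed with
    the original typographic dashes so the parser's normalization is
    exercised.
``decade_summaries.csv``
    Decade-stratified demographics of the 128-male cross-sectional cohort:
    n, age mean/SD/median and better-eye VA (logMAR) or VF width (degrees)
    mean/SD/median per decade of age.
``rep1_stability.csv``
    ΔΔG (kcal/mol) and published unfolding/folding propensities for the six
    REP-1 missense variants.
``missense_subjects.csv``
    The eight missense-genotype subjects in the cohort-table schema.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = [
    "load_mutation_families",
    "mutation_family_variants",
    "load_decade_summaries",
    "load_stability_records",
    "load_missense_subjects",
]


def _path(name: str):
    return resources.files(__package__).joinpath(name)


def load_mutation_families() -> pd.DataFrame:
    """Raw mutation-spectrum table, one row per family."""
    with resources.as_file(_path("chm_mutation_families.tsv")) as p:
        return pd.read_csv(p, sep="\t", dtype=str, keep_default_na=False)


def mutation_family_variants() -> list:
    """Parsed spectrum: list of (family_id, [VariantCall, ...])."""
    from ..cohort import parse_variant

    out = []
    for row in load_mutation_families().itertuples(index=False):
        variants = [parse_variant(row.hgvs_c, row.protein_change or None)]
        if row.hgvs_c_2:
            variants.append(parse_variant(row.hgvs_c_2, row.protein_change_2 or None))
        out.append((row.family, variants))
    return out


def load_decade_summaries() -> pd.DataFrame:
    """Decade-stratified cohort summaries (metrics ``va`` and ``vf``)."""
    with resources.as_file(_path("decade_summaries.csv")) as p:
        return pd.read_csv(p)


def load_stability_records() -> list:
    """REP-1 missense ΔΔG table as StabilityRecord objects (published U/F)."""
    from ..stability import StabilityRecord

    with resources.as_file(_path("rep1_stability.csv")) as p:
        df = pd.read_csv(p)
    return [
        StabilityRecord(mutant=r.mutant, ddG=float(r.ddg_kcal_mol),
                        U=float(r.u_printed), F=float(r.f_printed))
        for r in df.itertuples(index=False)
    ]


def load_missense_subjects() -> list:
    """The eight missense-genotype subjects as SubjectRecord objects."""
    from ..cohort import read_cohort

    with resources.as_file(_path("missense_subjects.csv")) as p:
        return read_cohort(p)
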