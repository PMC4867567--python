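"""Cohort domain types, table I/O and CHM variant classification.

The cohort table is one row per affected male: identifiers, the family's
*CHM* coding-DNA change(s) in HGVS ``c.`` notation, age at the most recent
assessment, self-reported symptom-onset ages, per-eye best-corrected visual
acuity (Snellen fraction, logMAR decimal, or a semiquantitative code
CF/HM/LP/NLP) and per-eye horizontal visual-field width in degrees.
Missing values are written as ``NC`` ("not collected").

Variant classification is annotation-driven: the study dialect of HGVS
(gene/exon-level rearrangements with ``?`` breakpoints, intronic offsets,
small indels, substitutions) is mapped onto a fixed mutation-class taxonomy
by a deterministic rule cascade; no general HGVS grammar is attempted.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import pandas as pd

__all__ = [
    "MutationClass",
    "GenotypeGroup",
    "VariantCall",
    "AcuityMeasure",
    "FieldMeasure",
    "Instrument",
    "SubjectRecord",
    "parse_variant",
    "assign_genotype_group",
    "read_cohort",
    "write_cohort",
    "spectrum_counts",
    "cohort_to_frame",
    "COHORT_COLUMNS",
    "MISSING_TOKEN",
]

MISSING_TOKEN = "NC"

#: Column order of the on-disk cohort table.
COHORT_COLUMNS = [
    "subject_id",
    "family_id",
    "hgvs_c",
    "hgvs_c_2",
    "protein_change",
    "protein_change_2",
    "age",
    "onset_nyctalopia",
    "onset_other",
    "va_od",
    "va_os",
    "vf_od",
    "vf_os",
    "vf_isopter",
    "vf_instrument",
]

# Typographic dash/minus variants that appear in published mutation tables.
_DASH_TRANSLATION = str.maketrans({
    "‐": "-",  # hyphen
    "‑": "-",  # non-breaking hyphen
    "‒": "-",  # figure dash
    "–": "-",  # en dash
    "—": "-",  # em dash
    "−": "-",  # minus sign
})


class MutationClass(str, Enum):
    WHOLE_GENE_DELETION = "whole_gene_deletion"
    EXON_DELETION = "exon_deletion"
    EXON_DUPLICATION = "exon_duplication"
    START_CODON = "start_codon"
    NONSENSE = "nonsense"
    FRAMESHIFT = "frameshift"
    SPLICE_SITE = "splice_site"
    MISSENSE = "missense"
    OTHER = "other"


class GenotypeGroup(str, Enum):
    """Qualitative genotype strata used for phenotype comparisons.

    ``missense`` — any missense change present; ``rep1_absent`` — all changes
    ablate REP-1 expression outright (whole-gene deletion, or loss of the ATG
    start codon); ``other`` — everything else (nonsense, frameshift, splice,
    partial deletions downstream of the start).
    """

    MISSENSE = "missense"
    REP1_ABSENT = "rep1_absent"
    OTHER = "other"


class Instrument(str, Enum):
    GOLDMANN = "Goldmann"
    HUMPHREY = "Humphrey"
    MAIA = "MAIA"


@dataclass(frozen=True)
class VariantCall:
    """A single *CHM* coding change with its derived functional class."""

    hgvs_c: str
    protein_annotation: Optional[str] = None
    mutation_class: MutationClass = MutationClass.OTHER
    rep1_absent_predicted: bool = False
    #: True when the rearrangement removes the translation start (exon 1).
    removes_start: bool = False


# Semiquantitative acuity grades and their logMAR equivalents.
_SEMIQUANT_CODES = ("CF", "HM", "LP", "NLP")


@dataclass(frozen=True)
class AcuityMeasure:
    """One eye's best-corrected visual acuity.

    ``raw`` is the value as recorded: a Snellen fraction ``(num, den)``, a
    semiquantitative code, or a plain logMAR decimal. ``logmar`` is the
    normalized value used in every analysis.
    """

    raw: Union[tuple, str, float]
    logmar: float

    def __post_init__(self):
        if not (-0.3 <= self.logmar <= 3.0):
            raise ValueError(f"logMAR {self.logmar} outside [-0.3, 3.0]")


@dataclass(frozen=True)
class FieldMeasure:
    """One eye's visual-field width across the horizontal meridian, degrees."""

    width_degrees: float
    isopter: str = "III4e"
    instrument: Instrument = Instrument.GOLDMANN

    def __post_init__(self):
        if not (0.0 <= self.width_degrees <= 180.0):
            raise ValueError(f"field width {self.width_degrees} outside [0, 180]")

    @property
    def excluded(self) -> bool:
        """Goldmann fields measured with a non-III4e isopter are not analyzable."""
        return self.instrument is Instrument.GOLDMANN and self.isopter != "III4e"


@dataclass
class SubjectRecord:
    """One affected male at his most recent assessment."""

    subject_id: str
    family_id: str
    variants: list = field(default_factory=list)
    age_years: int = 0
    onset_nyctalopia_years: Optional[int] = None
    onset_other_years: Optional[int] = None
    va_od: Optional[AcuityMeasure] = None
    va_os: Optional[AcuityMeasure] = None
    vf_od: Optional[FieldMeasure] = None
    vf_os: Optional[FieldMeasure] = None

    def __post_init__(self):
        if self.age_years < 1:
            raise ValueError("age_years must be >= 1")
        for onset in (self.onset_nyctalopia_years, self.onset_other_years):
            if onset is not None and onset > self.age_years:
                raise ValueError("onset age exceeds age at assessment")

    @property
    def analyzable(self) -> bool:
        return any(x is not None for x in (self.va_od, self.va_os, self.vf_od, self.vf_os))


# ---------------------------------------------------------------------------
# variant parsing
# ---------------------------------------------------------------------------

_RE_NONSENSE = re.compile(r"p\.\(?[A-Za-z]{1,3}\d+(\*|Ter)\)?$")
_RE_MISSENSE = re.compile(r"p\.\(?(?:[A-Z][a-z]{2}\d+[A-Z][a-z]{2}|[A-Z]\d+[A-Z])\)?$")
_RE_INTRONIC = re.compile(r"c\.[-*]?\d+[+-]\d+")
_RE_START_SUB = re.compile(r"c\.[123][ACGT]>[ACGT]$")
_RE_RANGE_REARR = re.compile(r"_.*(del|dup)")


def _normalize_hgvs(s: str) -> str:
    s = s.strip().translate(_DASH_TRANSLATION)
    s = re.sub(r"\s+", "", s)
    if s[:2].upper() == "C.":
        s = "c." + s[2:]
    return s


def parse_variant(hgvs_c: str, protein_annotation: Optional[str] = None) -> VariantCall:
    """Classify a *CHM* coding change.

    The cascade is deterministic given the pair of strings; an unparseable
    input is classified ``other`` with a warning rather than raising.

    Parameters
    ----------
    hgvs_c
        Coding-DNA change, e.g. ``"c.757C>T"``. Typographic dashes and an
        upper-case ``C.`` prefix are normalized first.
    protein_annotation
        Free-text protein-level consequence, e.g. ``"p.Arg253*"`` or
        ``"Complete gene deletion – REP-1 absent"``.
    """
    if not hgvs_c or not hgvs_c.strip():
        raise ValueError("hgvs_c must be a non-empty string")
    hgvs = _normalize_hgvs(hgvs_c)
    if not hgvs.startswith("c."):
        warnings.warn(f"unrecognized HGVS prefix in {hgvs_c!r}; classified as 'other'")
        return VariantCall(hgvs, protein_annotation, MutationClass.OTHER)

    ann = (protein_annotation or "").translate(_DASH_TRANSLATION).strip()
    ann_lower = ann.lower()
    rep1_absent = "rep-1 absent" in ann_lower or "absent rep-1" in ann_lower

    # Gene/exon-level rearrangements first: their protein consequence (when
    # predictable) may read as a frameshift, but the lesion is structural.
    if "complete gene deletion" in ann_lower:
        return VariantCall(hgvs, ann, MutationClass.WHOLE_GENE_DELETION, True, True)
    structural = bool(_RE_RANGE_REARR.search(hgvs)) and "?" in hgvs
    if structural or re.search(r"(deletion|duplication) of exon", ann_lower):
        removes_start = hgvs.startswith("c.-") or "exon 1 " in ann_lower + " "
        if "dup" in hgvs or "duplication" in ann_lower:
            return VariantCall(hgvs, ann, MutationClass.EXON_DUPLICATION, False, False)
        # A deletion taking out the 5' UTR and exon 1 removes the start codon.
        if removes_start:
            # Spanning into the 3' UTR (a '*'-offset endpoint) means the whole gene.
            if "*" in hgvs.split("_", 1)[-1]:
                return VariantCall(hgvs, ann, MutationClass.WHOLE_GENE_DELETION, True, True)
            return VariantCall(hgvs, ann, MutationClass.EXON_DELETION, True, True)
        return VariantCall(hgvs, ann, MutationClass.EXON_DELETION, rep1_absent, False)

    # Protein-level consequences.
    if "fs" in ann:
        return VariantCall(hgvs, ann, MutationClass.FRAMESHIFT, rep1_absent, False)
    if _RE_NONSENSE.search(ann):
        return VariantCall(hgvs, ann, MutationClass.NONSENSE, rep1_absent, False)

    if "start codon" in ann_lower or _RE_START_SUB.match(hgvs):
        return VariantCall(hgvs, ann, MutationClass.START_CODON, True, True)

    if _RE_INTRONIC.match(hgvs) or "splic" in ann_lower:
        return VariantCall(hgvs, ann, MutationClass.SPLICE_SITE, rep1_absent, False)

    if _RE_MISSENSE.search(ann):
        return VariantCall(hgvs, ann, MutationClass.MISSENSE, False, False)

    if not ann and re.match(r"c\.\d+[ACGT]>[ACGT]$", hgvs):
        # Substitution with no stated consequence — cannot be classified.
        return VariantCall(hgvs, None, MutationClass.OTHER)

    warnings.warn(f"could not classify variant {hgvs_c!r} / {protein_annotation!r}")
    return VariantCall(hgvs, ann or None, MutationClass.OTHER)


def assign_genotype_group(variants: Sequence[VariantCall]) -> GenotypeGroup:
    """Stratify a genotype: missense > REP-1-absent > other.

    A subject carrying any missense change is ``missense``; a subject whose
    every change removes REP-1 expression at the source (whole-gene deletion,
    or loss of the ATG start codon) is ``rep1_absent``; all remaining
    genotypes — prematurely truncating or splice-altering changes that still
    allow some transcript — are ``other``.
    """
    if not variants:
        raise ValueError("at least one variant is required")
    if any(v.mutation_class is MutationClass.MISSENSE for v in variants):
        return GenotypeGroup.MISSENSE
    if all(
        v.mutation_class in (MutationClass.WHOLE_GENE_DELETION, MutationClass.START_CODON)
        or (v.mutation_class is MutationClass.EXON_DELETION and v.removes_start)
        for v in variants
    ):
        return GenotypeGroup.REP1_ABSENT
    return GenotypeGroup.OTHER


# ---------------------------------------------------------------------------
# table I/O
# ---------------------------------------------------------------------------


def _is_missing(token) -> bool:
    if token is None:
        return True
    if isinstance(token, float) and math.isnan(token):
        return True
    s = str(token).strip()
    return s == "" or s.upper() == MISSING_TOKEN


def _parse_acuity(token) -> Optional[AcuityMeasure]:
    from .vision import semiquant_to_logmar, snellen_to_logmar

    if _is_missing(token):
        return None
    s = str(token).strip()
    if s.upper() in _SEMIQUANT_CODES:
        code = s.upper()
        return AcuityMeasure(raw=code, logmar=semiquant_to_logmar(code))
    if "/" in s:
        num, den = (float(x) for x in s.split("/", 1))
        return AcuityMeasure(raw=(num, den), logmar=round(snellen_to_logmar(num, den), 3))
    value = float(s)
    return AcuityMeasure(raw=value, logmar=value)


def _parse_field(token, isopter, instrument) -> Optional[FieldMeasure]:
    if _is_missing(token):
        return None
    iso = "III4e" if _is_missing(isopter) else str(isopter).strip()
    ins = Instrument.GOLDMANN if _is_missing(instrument) else Instrument(str(instrument).strip())
    width = float(str(token).strip().rstrip("°"))
    return FieldMeasure(width_degrees=width, isopter=iso, instrument=ins)


def _parse_int(token) -> Optional[int]:
    return None if _is_missing(token) else int(float(str(token)))


def read_cohort(path: Union[str, Path], dialect: str = ",") -> list[SubjectRecord]:
    """Read a cohort table into typed subject records.

    ``dialect`` is the field delimiter (``","`` or ``"\\t"``). Missing values
    are encoded ``NC`` (case-insensitive) or left empty. Raises a schema
    error naming the first absent mandatory column.
    """
    df = pd.read_csv(path, sep=dialect, dtype=str, keep_default_na=False)
    mandatory = ["subject_id", "family_id", "hgvs_c", "age"]
    for col in mandatory:
        if col not in df.columns:
            raise ValueError(f"cohort table is missing mandatory column {col!r}")
    records = []
    for row in df.itertuples(index=False):
        get = lambda col: getattr(row, col, None) if col in df.columns else None
        variants = []
        if not _is_missing(get("hgvs_c")):
            variants.append(parse_variant(get("hgvs_c"), _none_if_missing(get("protein_change"))))
        if not _is_missing(get("hgvs_c_2")):
            variants.append(parse_variant(get("hgvs_c_2"), _none_if_missing(get("protein_change_2"))))
        records.append(
            SubjectRecord(
                subject_id=str(get("subject_id")),
                family_id=str(get("family_id")),
                variants=variants,
                age_years=_parse_int(get("age")),
                onset_nyctalopia_years=_parse_int(get("onset_nyctalopia")),
                onset_other_years=_parse_int(get("onset_other")),
                va_od=_parse_acuity(get("va_od")),
                va_os=_parse_acuity(get("va_os")),
                vf_od=_parse_field(get("vf_od"), get("vf_isopter"), get("vf_instrument")),
                vf_os=_parse_field(get("vf_os"), get("vf_isopter"), get("vf_instrument")),
            )
        )
    return records


def _none_if_missing(token):
    return None if _is_missing(token) else str(token).strip()


def _format_acuity(m: Optional[AcuityMeasure]) -> str:
    if m is None:
        return MISSING_TOKEN
    if isinstance(m.raw, tuple):
        num, den = m.raw
        return f"{num:g}/{den:g}"
    if isinstance(m.raw, str):
        return m.raw
    return repr(float(m.raw))


def cohort_to_frame(records: Iterable[SubjectRecord]) -> pd.DataFrame:
    """Serialize records to a string DataFrame in the cohort-table schema."""
    rows = []
    for r in records:
        vf = r.vf_od or r.vf_os
        rows.append({
            "subject_id": r.subject_id,
            "family_id": r.family_id,
            "hgvs_c": r.variants[0].hgvs_c if r.variants else MISSING_TOKEN,
            "hgvs_c_2": r.variants[1].hgvs_c if len(r.variants) > 1 else MISSING_TOKEN,
            "protein_change": (r.variants[0].protein_annotation or MISSING_TOKEN) if r.variants else MISSING_TOKEN,
            "protein_change_2": (r.variants[1].protein_annotation or MISSING_TOKEN) if len(r.variants) > 1 else MISSING_TOKEN,
            "age": str(r.age_years),
            "onset_nyctalopia": MISSING_TOKEN if r.onset_nyctalopia_years is None else str(r.onset_nyctalopia_years),
            "onset_other": MISSING_TOKEN if r.onset_other_years is None else str(r.onset_other_years),
            "va_od": _format_acuity(r.va_od),
            "va_os": _format_acuity(r.va_os),
            "vf_od": MISSING_TOKEN if r.vf_od is None else repr(r.vf_od.width_degrees),
            "vf_os": MISSING_TOKEN if r.vf_os is None else repr(r.vf_os.width_degrees),
            "vf_isopter": vf.isopter if vf is not None else MISSING_TOKEN,
            "vf_instrument": vf.instrument.value if vf is not None else MISSING_TOKEN,
        })
    return pd.DataFrame(rows, columns=COHORT_COLUMNS, dtype=str)


def write_cohort(records: Iterable[SubjectRecord], path: Union[str, Path], dialect: str = ",") -> None:
    """Write records as delimited text; ``read_cohort`` round-trips exactly."""
    cohort_to_frame(records).to_csv(path, sep=dialect, index=False)


# ---------------------------------------------------------------------------
# mutation spectrum
# ---------------------------------------------------------------------------


def spectrum_counts(records_or_variants) -> dict:
    """Family-level mutation-class counts.

    Accepts either subject records (deduplicated on ``family_id``) or an
    iterable of ``(family_id, [VariantCall, ...])`` pairs. A family carrying
    two variants of different classes contributes one count to each class but
    one family to the total, so class counts can sum to more than the number
    of families.
    """
    per_family: dict[str, set] = {}
    for item in records_or_variants:
        if isinstance(item, SubjectRecord):
            fam, variants = item.family_id, item.variants
        else:
            fam, variants = item
        classes = per_family.setdefault(str(fam), set())
        classes.update(v.mutation_class for v in variants)
    counts = {cls: 0 for cls in MutationClass}
    for classes in per_family.values():
        for cls in classes:
            counts[cls] += 1
    counts["n_families"] = len(per_family)
    return counts
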