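"""Data model and I/O for monozygotic-twin cohort count tables.

A twin-cohort record summarises one disease in one MZ-twin registry as three
pair counts: ``n_pairs_total`` (N_T, all pairs followed), ``n_concordant``
(N_C, both twins affected) and ``n_discordant`` (N_D, exactly one affected).
These three numbers are sufficient for probandwise concordance, the implied
co-twin relative risk, and the case-based population attributable fraction.

The package bundles a reference table of 28 chronic-disease phenotypes
compiled from published Western European MZ-twin cohorts (Swedish, Danish,
Finnish and Norwegian registries, reported around the year 2000), available
via :func:`bundled_table2`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .errors import TableFormatError, ValidationError

__all__ = [
    "CATEGORIES",
    "SEX_SUBSETS",
    "DISEASE_CATEGORY",
    "TwinCohortRecord",
    "read_twin_table",
    "write_twin_table",
    "bundled_table2",
    "combine_records",
]

CATEGORIES = (
    "cancer",
    "cardiovascular",
    "neurological",
    "lung",
    "obesity-associated",
    "autoimmune",
    "genitourinary",
    "other",
)

SEX_SUBSETS = ("both", "female", "male")

#: Fixed disease -> category grouping for the 28 bundled phenotypes:
#: nine cancers; heart disease and stroke (cardiovascular); Parkinson's,
#: Alzheimer's, dementia and migraine (neurological); COPD and asthma (lung);
#: type-2 diabetes and gallstones (obesity-associated); rheumatoid arthritis,
#: type-1 diabetes and thyroid autoimmunity (autoimmune); dystocia, stress
#: urinary incontinence and pelvic organ prolapse (genitourinary); chronic
#: fatigue, irritable bowel syndrome and gastroesophageal reflux (other).
DISEASE_CATEGORY: dict[str, str] = {
    "Bladder cancer": "cancer",
    "Breast cancer (female)": "cancer",
    "Colorectal cancer": "cancer",
    "Leukemia": "cancer",
    "Lung cancer": "cancer",
    "Ovarian cancer (female)": "cancer",
    "Pancreatic cancer": "cancer",
    "Prostate cancer (male)": "cancer",
    "Stomach cancer": "cancer",
    "Coronary heart disease death": "cardiovascular",
    "Stroke-related death": "cardiovascular",
    "Parkinson disease": "neurological",
    "Alzheimer's disease": "neurological",
    "Dementia": "neurological",
    "Migraine": "neurological",
    "Chronic obstructive pulmonary disease": "lung",
    "Asthma": "lung",
    "Type 2 diabetes": "obesity-associated",
    "Gallstone disease": "obesity-associated",
    "Rheumatoid arthritis": "autoimmune",
    "Type 1 diabetes": "autoimmune",
    "Thyroid autoimmunity": "autoimmune",
    "General dystocia (female)": "genitourinary",
    "Stress urinary incontinence (female)": "genitourinary",
    "Pelvic organ prolapse (female)": "genitourinary",
    "Chronic fatigue": "other",
    "Irritable bowel syndrome": "other",
    "Gastroesophageal reflux disorder": "other",
}

FIELDS = (
    "disease_name",
    "category",
    "country",
    "sex_subset",
    "n_pairs_total",
    "n_concordant",
    "n_discordant",
)

_COUNT_RE = re.compile(r"^\d+$")


@dataclass(frozen=True)
class TwinCohortRecord:
    """Pair counts for one disease in one MZ-twin cohort.

    Invariants (checked on construction): ``n_pairs_total >= 1``, counts
    non-negative, ``n_concordant + n_discordant <= n_pairs_total``, and for
    the bundled phenotypes the category must match :data:`DISEASE_CATEGORY`.
    """

    disease_name: str
    category: str
    country: str
    sex_subset: str
    n_pairs_total: int
    n_concordant: int
    n_discordant: int

    def __post_init__(self) -> None:
        if not self.disease_name:
            raise ValidationError("disease_name must be non-empty")
        if self.category not in CATEGORIES:
            raise ValidationError(
                f"unknown category {self.category!r} for {self.disease_name!r}; "
                f"expected one of {CATEGORIES}"
            )
        if self.sex_subset not in SEX_SUBSETS:
            raise ValidationError(
                f"unknown sex_subset {self.sex_subset!r} for {self.disease_name!r}; "
                f"expected one of {SEX_SUBSETS}"
            )
        for field in ("n_pairs_total", "n_concordant", "n_discordant"):
            value = getattr(self, field)
            if not isinstance(value, (int,)) or isinstance(value, bool):
                raise ValidationError(f"{field} must be an integer, got {value!r}")
            if value < 0:
                raise ValidationError(f"{field} must be non-negative, got {value}")
        if self.n_pairs_total < 1:
            raise ValidationError("n_pairs_total must be at least 1")
        if self.n_concordant + self.n_discordant > self.n_pairs_total:
            raise ValidationError(
                f"{self.disease_name!r}: n_concordant + n_discordant "
                f"({self.n_concordant} + {self.n_discordant}) exceeds "
                f"n_pairs_total ({self.n_pairs_total})"
            )
        expected = DISEASE_CATEGORY.get(self.disease_name)
        if expected is not None and self.category != expected:
            raise ValidationError(
                f"{self.disease_name!r} is categorised as {expected!r} "
                f"in the bundled grouping, got {self.category!r}"
            )

    @property
    def n_unaffected_pairs(self) -> int:
        return self.n_pairs_total - self.n_concordant - self.n_discordant

    @property
    def n_affected_individuals(self) -> int:
        """Number of affected twins: two per concordant pair, one per discordant."""
        return 2 * self.n_concordant + self.n_discordant


def _parse_count(raw: str, column: str, row: int) -> int:
    if not _COUNT_RE.match(raw.strip()):
        raise ValidationError(
            f"row {row}: column {column!r} must be a plain non-negative integer "
            f"(no thousands separators), got {raw!r}"
        )
    return int(raw)


def read_twin_table(path: str | Path) -> list[TwinCohortRecord]:
    """Read a UTF-8 comma-separated twin-cohort table.

    The file must have a header row naming exactly the seven fields of
    :class:`TwinCohortRecord`; counts must be plain non-negative integers
    (``15,668``-style thousands separators are rejected). Row order is
    preserved. Raises :class:`TableFormatError` for schema problems and
    :class:`ValidationError` for invariant violations or an empty table.
    """
    frame = pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8")
    missing = [c for c in FIELDS if c not in frame.columns]
    if missing:
        raise TableFormatError(f"missing column(s): {', '.join(missing)}")
    if frame.empty:
        raise ValidationError(f"empty table: {path}")
    records = []
    for i, row in enumerate(frame.itertuples(index=False), start=1):
        try:
            records.append(
                TwinCohortRecord(
                    disease_name=row.disease_name,
                    category=row.category,
                    country=row.country,
                    sex_subset=row.sex_subset,
                    n_pairs_total=_parse_count(row.n_pairs_total, "n_pairs_total", i),
                    n_concordant=_parse_count(row.n_concordant, "n_concordant", i),
                    n_discordant=_parse_count(row.n_discordant, "n_discordant", i),
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"row {i}: {exc}") from exc
    return records


def write_twin_table(records: Iterable[TwinCohortRecord], path: str | Path) -> None:
    """Write records to CSV in the schema accepted by :func:`read_twin_table`."""
    rows = [{f: getattr(r, f) for f in FIELDS} for r in records]
    pd.DataFrame(rows, columns=list(FIELDS)).to_csv(path, index=False, encoding="utf-8")


def bundled_table2() -> list[TwinCohortRecord]:
    """The bundled 28-phenotype reference table of MZ-twin pair counts."""
    source = resources.files("twinpaf.data").joinpath("table2.csv")
    with resources.as_file(source) as path:
        return read_twin_table(path)


def combine_records(records: Sequence[TwinCohortRecord]) -> TwinCohortRecord:
    """Pool sex-specific cohorts of one disease by summing pair counts.

    All inputs must share ``disease_name`` and have pairwise-distinct
    ``sex_subset`` values. The pooled record is labelled ``both`` when the
    inputs jointly cover both sexes (either a ``both`` record or both a
    ``female`` and a ``male`` one); a single input is returned unchanged.
    """
    records = list(records)
    if not records:
        raise ValidationError("combine_records requires at least one record")
    names = {r.disease_name for r in records}
    if len(names) > 1:
        raise ValidationError(f"conflicting disease names: {sorted(names)}")
    subsets = [r.sex_subset for r in records]
    if len(set(subsets)) != len(subsets):
        raise ValidationError(f"duplicate sex_subset values: {sorted(subsets)}")
    if len(records) == 1:
        return records[0]
    covers_both = "both" in subsets or {"female", "male"} <= set(subsets)
    countries = list(dict.fromkeys(r.country for r in records))
    return replace(
        records[0],
        country="; ".join(countries),
        sex_subset="both" if covers_both else subsets[0],
        n_pairs_total=sum(r.n_pairs_total for r in records),
        n_concordant=sum(r.n_concordant for r in records),
        n_discordant=sum(r.n_discordant for r in records),
    )
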