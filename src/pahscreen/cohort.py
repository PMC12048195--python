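"""Cohort table I/O: one row per (patient, variant call), TSV.

The packaged fixture ``data/pku_cohort.tsv`` transcribes the 40-patient ONT
PKU cohort this package analyzes: pre-treatment phenylalanine, clinical type,
demographics, and per-variant ONT calls (depth, allele fraction, ACMG codes,
APV) together with the genotype-level phenotype value (GPV) and the majority
BioPKU category.  Decimal separators are normalized to ``.``; qualitative Phe
entries (historical Guthrie screen, not determined) are kept as enum markers
and never converted to µmol/L.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path
from typing import Iterable

import pandas as pd

from .hgvs import HgvsVariant, parse_hgvs_c

__all__ = [
    "VariantCall",
    "PatientRecord",
    "CohortLoadError",
    "PHE_QUALITATIVE",
    "CONSANGUINEOUS",
    "load_cohort",
    "write_cohort",
    "load_packaged_cohort",
    "packaged_cohort_path",
]

#: qualitative pre-treatment Phe markers (no µmol/L conversion exists)
PHE_QUALITATIVE = frozenset({"guthrie_gt_8mgdl", "not_determined"})

#: consanguinity codes that count as consanguineous; "unknown" is excluded
#: from any denominator, "none" counts as evaluable non-consanguineous.
CONSANGUINEOUS = frozenset(
    {
        "first_degree_cousin",
        "second_degree_cousin",
        "third_degree_cousin",
        "yes_unknown_degree",
    }
)

_COLUMNS = [
    "patient_id", "phe_pretreatment", "clinical_type", "sex", "birth_year",
    "consanguinity", "variant", "depth", "allele_fraction", "acmg_codes",
    "acmg_class", "apv", "gpv", "biopku_type", "biopku_support",
]


class CohortLoadError(ValueError):
    pass


@dataclass(frozen=True)
class VariantCall:
    """One sequenced variant observation on one patient."""

    variant: HgvsVariant
    depth: int
    allele_fraction: float
    acmg_codes: frozenset[str] = frozenset()
    acmg_class: str | None = None  # pathogenic | likely_pathogenic
    apv: float | None = None  # allelic phenotype value, 0 (severe) .. 10

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ValueError(f"depth must be >= 1, got {self.depth}")
        if not 0.0 <= self.allele_fraction <= 1.0:
            raise ValueError(f"allele fraction outside [0,1]: {self.allele_fraction}")
        if self.apv is not None and not 0.0 <= self.apv <= 10.0:
            raise ValueError(f"APV outside [0,10]: {self.apv}")

    @property
    def key(self) -> str:
        """Canonical ``c.`` string identifying the variant."""
        return self.variant.c_notation


@dataclass(frozen=True)
class PatientRecord:
    """One patient: demographics plus 1-2 variant calls."""

    patient_id: int
    phe_pretreatment: float | str  # µmol/L, or a PHE_QUALITATIVE marker
    clinical_type: str  # cPKU | mPKU
    sex: str  # F | M
    birth_year: int | None
    consanguinity: str
    calls: tuple[VariantCall, ...]
    gpv: float | None = None
    biopku_type: str | None = None  # classic | mild | mild_HPA
    biopku_support: str | None = None  # e.g. "673/681" majority count
    truth_zygosity: tuple[str, ...] | None = None  # simulator-only labels

    def __post_init__(self) -> None:
        if not 1 <= len(self.calls) <= 2:
            raise ValueError(
                f"patient {self.patient_id}: expected 1-2 calls, got {len(self.calls)}"
            )
        if self.clinical_type not in ("cPKU", "mPKU"):
            raise ValueError(f"patient {self.patient_id}: bad clinical type")
        if isinstance(self.phe_pretreatment, str) and (
            self.phe_pretreatment not in PHE_QUALITATIVE
        ):
            raise ValueError(
                f"patient {self.patient_id}: bad Phe marker {self.phe_pretreatment!r}"
            )


def _opt_float(value: object) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    s = str(value).strip()
    if s in ("", "NA"):
        return None
    return float(s.replace(",", "."))


def load_cohort(path: str | Path) -> list[PatientRecord]:
    """Read a cohort TSV into grouped, validated patient records."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise CohortLoadError(f"{path}: empty cohort file") from None
    if df.empty:
        raise CohortLoadError(f"{path}: cohort file has no data rows")
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise CohortLoadError(f"{path}: missing mandatory column(s) {missing}")

    dup = df.duplicated(subset=["patient_id", "variant"], keep=False)
    if dup.any():
        rows = [i + 2 for i in df.index[dup]]  # 1-based incl. header
        raise CohortLoadError(f"{path}: duplicate (patient, variant) rows {rows}")

    records: list[PatientRecord] = []
    for pid_str, group in df.groupby("patient_id", sort=False):
        if len(group) > 2:
            rows = [i + 2 for i in group.index]
            raise CohortLoadError(
                f"{path}: patient {pid_str} has {len(group)} variants (rows {rows})"
            )
        first = group.iloc[0]
        calls = []
        truth = []
        for _, row in group.iterrows():
            calls.append(
                VariantCall(
                    variant=parse_hgvs_c(row["variant"]),
                    depth=int(row["depth"]),
                    allele_fraction=float(row["allele_fraction"]),
                    acmg_codes=frozenset(
                        c for c in row["acmg_codes"].split(",") if c
                    ),
                    acmg_class=row["acmg_class"] or None,
                    apv=_opt_float(row["apv"]),
                )
            )
            truth.append(row.get("truth_zygosity", ""))
        phe_raw = first["phe_pretreatment"]
        phe: float | str = (
            phe_raw if phe_raw in PHE_QUALITATIVE else float(phe_raw)
        )
        year = first["birth_year"]
        records.append(
            PatientRecord(
                patient_id=int(pid_str),
                phe_pretreatment=phe,
                clinical_type=first["clinical_type"],
                sex=first["sex"],
                birth_year=None if year in ("", "unknown", "NA") else int(year),
                consanguinity=first["consanguinity"],
                calls=tuple(calls),
                gpv=_opt_float(first["gpv"]),
                biopku_type=(first["biopku_type"] or "NA").replace("NA", "") or None,
                biopku_support=(first["biopku_support"] or "NA").replace("NA", "")
                or None,
                truth_zygosity=tuple(truth) if any(truth) else None,
            )
        )
    return records


def _fmt_num(x: float | None) -> str:
    if x is None:
        return "NA"
    return f"{x:g}"


def write_cohort(records: Iterable[PatientRecord], path: str | Path) -> None:
    """Serialize records to the same one-row-per-call TSV schema."""
    rows = []
    for rec in records:
        for i, call in enumerate(rec.calls):
            row = {
                "patient_id": rec.patient_id,
                "phe_pretreatment": (
                    rec.phe_pretreatment
                    if isinstance(rec.phe_pretreatment, str)
                    else f"{rec.phe_pretreatment:g}"
                ),
                "clinical_type": rec.clinical_type,
                "sex": rec.sex,
                "birth_year": rec.birth_year if rec.birth_year else "unknown",
                "consanguinity": rec.consanguinity,
                "variant": call.variant.raw or call.variant.format(),
                "depth": call.depth,
                "allele_fraction": f"{call.allele_fraction:g}",
                "acmg_codes": ",".join(sorted(call.acmg_codes)),
                "acmg_class": call.acmg_class or "NA",
                "apv": _fmt_num(call.apv),
                "gpv": _fmt_num(rec.gpv),
                "biopku_type": rec.biopku_type or "NA",
                "biopku_support": rec.biopku_support or "NA",
            }
            if rec.truth_zygosity is not None:
                row["truth_zygosity"] = rec.truth_zygosity[i]
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def packaged_cohort_path() -> Path:
    return Path(resources.files("pahscreen").joinpath("data/pku_cohort.tsv"))  # type: ignore[arg-type]


def load_packaged_cohort() -> list[PatientRecord]:
    """The 40-patient cohort table shipped with the package."""
    return load_cohort(packaged_cohort_path())


def strip_truth(record: PatientRecord) -> PatientRecord:
    """Drop simulator truth labels (for blinded re-analysis)."""
    return replace(record, truth_zygosity=None)
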