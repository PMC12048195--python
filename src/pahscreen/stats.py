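"""Cohort-level statistics: variant frequencies, zygosity tallies,
demographics, allele frequencies, depth range, and the assembled summary.

Percentages are rounded to one decimal, half away from zero, against the
stated denominator (consanguinity excludes unknowns from its denominator;
everything else is over the full cohort).
"""

from __future__ import annotations

from dataclasses import dataclass

from .cohort import CONSANGUINEOUS, PatientRecord
from .genotyping import HOMOZYGOSITY_THRESHOLD, GenotypeProfile, profile_cohort

__all__ = [
    "round_percent",
    "variant_patient_frequency",
    "zygosity_breakdown",
    "demographics",
    "allele_frequency",
    "depth_summary",
    "CohortSummary",
    "summarize",
    "render_report",
]


def round_percent(numerator: float, denominator: float, digits: int = 1) -> float:
    """Percentage rounded half away from zero (matches printed style,
    e.g. 17/36 -> 47.2)."""
    if denominator == 0:
        return 0.0
    x = numerator / denominator * 100.0
    scale = 10**digits
    return int(x * scale + (0.5 if x >= 0 else -0.5)) / scale


def _carriers(cohort: list[PatientRecord], variant_key: str) -> list[PatientRecord]:
    return [
        rec for rec in cohort if any(c.key == variant_key for c in rec.calls)
    ]


def variant_patient_frequency(
    cohort: list[PatientRecord], variant_key: str
) -> tuple[int, float]:
    """(carrier count, percent of patients), any zygosity counts once."""
    n = len(_carriers(cohort, variant_key))
    return n, round_percent(n, len(cohort))


def zygosity_breakdown(
    cohort: list[PatientRecord],
    variant_key: str,
    threshold: float = HOMOZYGOSITY_THRESHOLD,
) -> tuple[int, int, int]:
    """(n hom, n compound-het carriers, n single-het) for one variant,
    partitioned by the carrier's genotype category."""
    n_hom = n_comp = n_single = 0
    for rec in _carriers(cohort, variant_key):
        profile = profile_cohort([rec], threshold)[0]
        if profile.category == "homozygous":
            n_hom += 1
        elif profile.category == "compound_heterozygous":
            n_comp += 1
        else:
            n_single += 1
    return n_hom, n_comp, n_single


def demographics(cohort: list[PatientRecord]) -> dict:
    """Sex, clinical type (percent over all patients) and consanguinity
    (percent over evaluable records: unknowns excluded, 'yes, degree
    unknown' counts as consanguineous)."""
    n = len(cohort)
    n_f = sum(1 for r in cohort if r.sex == "F")
    n_c = sum(1 for r in cohort if r.clinical_type == "cPKU")
    n_consang = sum(1 for r in cohort if r.consanguinity in CONSANGUINEOUS)
    n_eval = sum(1 for r in cohort if r.consanguinity != "unknown")
    return {
        "n_patients": n,
        "n_female": n_f,
        "n_male": n - n_f,
        "pct_female": round_percent(n_f, n),
        "pct_male": round_percent(n - n_f, n),
        "n_cPKU": n_c,
        "n_mPKU": n - n_c,
        "pct_cPKU": round_percent(n_c, n),
        "pct_mPKU": round_percent(n - n_c, n),
        "n_consanguineous": n_consang,
        "n_consanguinity_evaluable": n_eval,
        "pct_consanguineous": round_percent(n_consang, n_eval),
    }


def allele_frequency(
    cohort: list[PatientRecord],
    variant_key: str,
    threshold: float = HOMOZYGOSITY_THRESHOLD,
) -> float:
    """Fraction of the cohort's 2n alleles carrying the variant: a
    homozygous carrier contributes two, a heterozygous carrier one."""
    if not cohort:
        return 0.0
    alleles = 0
    for rec in _carriers(cohort, variant_key):
        profile = profile_cohort([rec], threshold)[0]
        for call, zyg in zip(profile.calls, profile.zygosities):
            if call.key == variant_key:
                alleles += 2 if zyg == "hom" else 1
    return alleles / (2 * len(cohort))


def depth_summary(cohort: list[PatientRecord]) -> tuple[int, int]:
    depths = [c.depth for r in cohort for c in r.calls]
    return min(depths), max(depths)


@dataclass(frozen=True)
class CohortSummary:
    n_patients: int
    threshold: float
    demographics: dict
    genotype_categories: dict[str, int]
    genotype_percentages: dict[str, float]
    per_variant: list[dict]  # count, percent, zygosity breakdown, allele freq
    depth_min: int
    depth_max: int


def summarize(
    cohort: list[PatientRecord], threshold: float = HOMOZYGOSITY_THRESHOLD
) -> CohortSummary:
    """Assemble every cohort-level statistic into one deterministic summary."""
    if not cohort:
        return CohortSummary(0, threshold, demographics([]), {}, {}, [], 0, 0)
    profiles = profile_cohort(cohort, threshold)
    categories = {"homozygous": 0, "compound_heterozygous": 0, "single_heterozygous": 0}
    for p in profiles:
        categories[p.category] += 1
    n = len(cohort)
    percentages = {k: round_percent(v, n) for k, v in categories.items()}

    keys: list[str] = []
    for rec in cohort:
        for call in rec.calls:
            if call.key not in keys:
                keys.append(call.key)
    per_variant = []
    for key in keys:
        count, pct = variant_patient_frequency(cohort, key)
        hom, comp, single = zygosity_breakdown(cohort, key, threshold)
        per_variant.append(
            {
                "variant": key,
                "n_patients": count,
                "pct_patients": pct,
                "n_hom": hom,
                "n_compound_het": comp,
                "n_single_het": single,
                "allele_frequency": allele_frequency(cohort, key, threshold),
            }
        )
    per_variant.sort(key=lambda r: (-r["n_patients"], r["variant"]))
    dmin, dmax = depth_summary(cohort)
    return CohortSummary(
        n_patients=n,
        threshold=threshold,
        demographics=demographics(cohort),
        genotype_categories=categories,
        genotype_percentages=percentages,
        per_variant=per_variant,
        depth_min=dmin,
        depth_max=dmax,
    )


def render_report(summary: CohortSummary) -> str:
    """Human-readable text report, deterministic line order."""
    d = summary.demographics
    lines = [
        f"Cohort summary ({summary.n_patients} patients, "
        f"homozygosity threshold >= {summary.threshold:g})",
        "",
    ]
    if summary.n_patients == 0:
        lines.append("empty cohort")
        return "\n".join(lines) + "\n"
    lines += [
        f"Sex: {d['n_female']} F ({d['pct_female']:g}%), "
        f"{d['n_male']} M ({d['pct_male']:g}%)",
        f"Clinical type: {d['n_cPKU']} cPKU ({d['pct_cPKU']:g}%), "
        f"{d['n_mPKU']} mPKU ({d['pct_mPKU']:g}%)",
        f"Consanguinity: {d['n_consanguineous']}/{d['n_consanguinity_evaluable']} "
        f"evaluable ({d['pct_consanguineous']:g}%)",
        f"Depth range: {summary.depth_min}-{summary.depth_max}x",
        "",
        "Genotype categories:",
    ]
    for cat, count in summary.genotype_categories.items():
        lines.append(
            f"  {cat}: {count} ({summary.genotype_percentages[cat]:g}%)"
        )
    lines += ["", "Per-variant (carriers | hom/compound/single | allele freq):"]
    for row in summary.per_variant:
        lines.append(
            f"  {row['variant']}: {row['n_patients']} ({row['pct_patients']:g}%) | "
            f"{row['n_hom']}/{row['n_compound_het']}/{row['n_single_het']} | "
            f"{row['allele_frequency']:.4f}"
        )
    return "\n".join(lines) + "\n"
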