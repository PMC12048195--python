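"""Zygosity from allele fraction, patient genotype assembly, data-driven
threshold derivation, and pileup-based calling for simulations.

Long-read amplicon sequencing of this assay shows systematically depressed
variant allele fractions (mapping bias), so the homozygous/heterozygous
boundary is far below the naive 0.75-1.0: a call is homozygous iff its
allele fraction is **>= threshold**, default 0.58, the value the cohort data
themselves yield (see :func:`derive_threshold`).
"""

from __future__ import annotations

from dataclasses import dataclass

from .cohort import PatientRecord, VariantCall
from .simulate import PileupObservation

__all__ = [
    "HOMOZYGOSITY_THRESHOLD",
    "MIN_DEPTH",
    "MIN_AF",
    "GenotypeProfile",
    "ThresholdResult",
    "ThresholdError",
    "PileupCallResult",
    "call_zygosity",
    "assemble_genotype",
    "profile_cohort",
    "derive_threshold",
    "derive_threshold_detail",
    "pileup_call",
]

#: allele fraction at/above which a single call is homozygous (inclusive)
HOMOZYGOSITY_THRESHOLD = 0.58
#: minimum adequate per-site read depth
MIN_DEPTH = 50
#: minimum allele fraction retained by the pileup caller; just below the
#: smallest fraction the assay's pipeline itself retained (0.18)
MIN_AF = 0.15


def call_zygosity(allele_fraction: float, threshold: float = HOMOZYGOSITY_THRESHOLD) -> str:
    """``"hom"`` iff ``allele_fraction >= threshold``, else ``"het"``."""
    if not 0.0 <= allele_fraction <= 1.0:
        raise ValueError(f"allele fraction outside [0,1]: {allele_fraction}")
    return "hom" if allele_fraction >= threshold else "het"


@dataclass(frozen=True)
class GenotypeProfile:
    """Patient-level genotype category under the allele-fraction rule.

    ``explained`` is True iff two pathogenic alleles are accounted for
    (homozygous, or two heterozygous calls in trans).  ``inconsistent``
    flags a two-variant patient with a homozygous-classified fraction —
    impossible under a bi-allelic model (3+ pathogenic alleles) — without
    aborting batch processing.  Two-variant patients are assumed bi-allelic
    (trans); no phasing is performed (``trans_assumed``).
    """

    patient_id: int
    category: str  # homozygous | compound_heterozygous | single_heterozygous
    calls: tuple[VariantCall, ...]
    zygosities: tuple[str, ...]
    explained: bool
    inconsistent: bool = False
    trans_assumed: bool = False


def assemble_genotype(
    calls: tuple[VariantCall, ...] | list[VariantCall],
    threshold: float = HOMOZYGOSITY_THRESHOLD,
    patient_id: int = 0,
) -> GenotypeProfile:
    """Classify each call and derive the patient-level category.

    One hom call -> homozygous; two het calls -> compound heterozygous
    (assumed trans); one het call -> single heterozygous, unexplained.  Two
    calls with any hom-classified fraction keep the compound category but are
    flagged inconsistent.
    """
    calls = tuple(calls)
    if not 1 <= len(calls) <= 2:
        raise ValueError(f"expected 1-2 calls, got {len(calls)}")
    zyg = tuple(call_zygosity(c.allele_fraction, threshold) for c in calls)
    if len(calls) == 1:
        hom = zyg[0] == "hom"
        return GenotypeProfile(
            patient_id=patient_id,
            category="homozygous" if hom else "single_heterozygous",
            calls=calls,
            zygosities=zyg,
            explained=hom,
        )
    inconsistent = "hom" in zyg
    return GenotypeProfile(
        patient_id=patient_id,
        category="compound_heterozygous",
        calls=calls,
        zygosities=zyg,
        explained=not inconsistent,
        inconsistent=inconsistent,
        trans_assumed=True,
    )


def profile_cohort(
    cohort: list[PatientRecord], threshold: float = HOMOZYGOSITY_THRESHOLD
) -> list[GenotypeProfile]:
    return [
        assemble_genotype(rec.calls, threshold, patient_id=rec.patient_id)
        for rec in cohort
    ]


class ThresholdError(ValueError):
    pass


@dataclass(frozen=True)
class ThresholdResult:
    threshold: float
    n_violations: int
    violations: tuple[str, ...]  # human-readable descriptions of conflicts
    candidates: tuple[float, ...]  # sorted single-variant fractions


def derive_threshold_detail(cohort: list[PatientRecord]) -> ThresholdResult:
    """Derive the homozygosity cutoff from the cohort itself.

    Candidate thresholds are the observed allele fractions of single-variant
    patients (the only fractions that can anchor a homozygous call).  Two
    constraint sets are built from record structure alone, without using any
    pre-existing threshold:

    * must stay heterozygous — every call of a two-variant patient (a
      bi-allelic model allows at most two pathogenic alleles), and
      single-variant records whose genotype-level phenotype value is missing
      (the record itself says the genotype is unexplained);
    * must be homozygous — single-variant records carrying a recorded
      genotype-level value (the genotype was treated as two identical
      alleles).

    The returned threshold is the smallest candidate minimizing the number of
    violated constraints.  On cleanly separated data this is the smallest
    fraction classified homozygous, with zero violations; conflicting records
    (they exist in the real cohort) are reported, not silently dropped.
    """
    singles = [rec for rec in cohort if len(rec.calls) == 1]
    if not singles:
        raise ThresholdError("no single-variant records: nothing can anchor homozygosity")

    must_het: list[tuple[float, str]] = []
    must_hom: list[tuple[float, str]] = []
    for rec in cohort:
        if len(rec.calls) == 2:
            for call in rec.calls:
                must_het.append(
                    (call.allele_fraction, f"patient {rec.patient_id} {call.key}")
                )
        elif rec.gpv is None:
            must_het.append(
                (rec.calls[0].allele_fraction, f"patient {rec.patient_id} unexplained")
            )
        else:
            must_hom.append(
                (rec.calls[0].allele_fraction, f"patient {rec.patient_id} explained")
            )

    candidates = sorted(rec.calls[0].allele_fraction for rec in singles)
    best: tuple[int, float] | None = None
    best_viol: list[str] = []
    for t in candidates:
        viol = [f"{d} (af {af:g} above threshold {t:g})" for af, d in must_het if af >= t]
        viol += [f"{d} (af {af:g} below threshold {t:g})" for af, d in must_hom if af < t]
        if best is None or (len(viol), t) < best:
            best = (len(viol), t)
            best_viol = viol
    assert best is not None
    return ThresholdResult(
        threshold=best[1],
        n_violations=best[0],
        violations=tuple(best_viol),
        candidates=tuple(candidates),
    )


def derive_threshold(cohort: list[PatientRecord]) -> float:
    return derive_threshold_detail(cohort).threshold


@dataclass(frozen=True)
class PileupCallResult:
    calls: tuple[VariantCall, ...]
    zygosities: tuple[str, ...]
    dropped: tuple[str, ...]  # drop log, one line per filtered observation


def pileup_call(
    observations: list[PileupObservation],
    min_depth: int = MIN_DEPTH,
    min_af: float = MIN_AF,
    threshold: float = HOMOZYGOSITY_THRESHOLD,
) -> PileupCallResult:
    """Naive pileup caller for simulated data.

    Emits a call for every observation with ``depth >= min_depth`` (50x is
    adequate, inclusive) and ``observed_af >= min_af``; zygosity is then
    assigned by :func:`call_zygosity`.  Filtered observations go to the drop
    log, never silently away.
    """
    if min_depth < 1:
        raise ValueError("min_depth must be >= 1")
    calls: list[VariantCall] = []
    zyg: list[str] = []
    dropped: list[str] = []
    for obs in observations:
        if obs.depth < min_depth:
            dropped.append(
                f"{obs.variant.c_notation}: depth {obs.depth} < {min_depth}"
            )
            continue
        if obs.observed_af < min_af:
            dropped.append(
                f"{obs.variant.c_notation}: af {obs.observed_af:.3f} < {min_af}"
            )
            continue
        calls.append(
            VariantCall(
                variant=obs.variant,
                depth=obs.depth,
                allele_fraction=obs.observed_af,
            )
        )
        zyg.append(call_zygosity(obs.observed_af, threshold))
    return PileupCallResult(tuple(calls), tuple(zyg), tuple(dropped))
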