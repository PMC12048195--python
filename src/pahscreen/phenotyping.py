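"""Genotype -> predicted phenotype via allelic/genotypic phenotype values.

APV (allelic phenotype value) scores each PAH allele's residual function on
a 0 (most severe) .. 10 scale; the genotype-level value (GPV) is the maximum
of the two allelic values — PKU is recessive, so the milder allele dominates
the biochemical phenotype.  GPV bins: 0-2.7 classic PKU, 2.8-6.6 mild PKU,
6.7-10.0 mild hyperphenylalaninemia.  APVs are inputs transcribed from the
cohort table, never fetched from the live database.
"""

from __future__ import annotations

from dataclasses import dataclass

from .cohort import PHE_QUALITATIVE, PatientRecord

__all__ = [
    "UNPREDICTABLE",
    "GPV_BINS",
    "build_apv_table",
    "gpv",
    "classify_gpv",
    "phe_to_clinical",
    "predict_phenotype",
    "predict_cohort",
    "ConcordanceResult",
    "DEFAULT_CONCORDANCE_MAP",
    "concordance",
]

#: marker for genotypes whose phenotype cannot be predicted (missing APV or
#: an unexplained single-heterozygous genotype)
UNPREDICTABLE = "unpredictable"

#: (upper bound inclusive, label); values rounded to one decimal before
#: binning, so the printed bin gaps (2.7, 2.8) cannot swallow a value
GPV_BINS = ((2.7, "classic_PKU"), (6.6, "mild_PKU"), (10.0, "mild_HPA"))


def build_apv_table(cohort: list[PatientRecord] | None = None) -> dict[str, float]:
    """Canonical variant key -> APV, from the cohort's per-call APV column.

    Raises if two rows disagree on a variant's APV (they never do in the
    packaged table).
    """
    if cohort is None:
        from .cohort import load_packaged_cohort

        cohort = load_packaged_cohort()
    table: dict[str, float] = {}
    for rec in cohort:
        for call in rec.calls:
            if call.apv is None:
                continue
            if call.key in table and table[call.key] != call.apv:
                raise ValueError(
                    f"conflicting APV for {call.key}: "
                    f"{table[call.key]} vs {call.apv} (patient {rec.patient_id})"
                )
            table[call.key] = call.apv
    return table


def gpv(apv_a: float | None, apv_b: float | None) -> float | str:
    """Genotypic phenotype value = max of the two allelic values.

    A missing APV makes the genotype unpredictable, not a number.
    """
    if apv_a is None or apv_b is None:
        return UNPREDICTABLE
    for v in (apv_a, apv_b):
        if not 0.0 <= v <= 10.0:
            raise ValueError(f"APV outside [0,10]: {v}")
    return max(apv_a, apv_b)


def classify_gpv(value: float) -> str:
    """Bin a GPV into the predicted clinical category."""
    if not 0.0 <= value <= 10.0:
        raise ValueError(f"GPV outside [0,10]: {value}")
    v = round(value, 1)
    for upper, label in GPV_BINS:
        if v <= upper:
            return label
    return GPV_BINS[-1][1]  # pragma: no cover - unreachable after rounding


def phe_to_clinical(phe_umol: float | str) -> str:
    """Clinical type from pre-treatment phenylalanine (µmol/L).

    > 1200 is classic PKU; 600-1200 (inclusive) is mild PKU.  Below 600 is
    outside the two-class scheme and an error; qualitative markers return
    ``"unclassifiable"`` (the recorded label is used instead).
    """
    if isinstance(phe_umol, str):
        if phe_umol in PHE_QUALITATIVE:
            return "unclassifiable"
        raise ValueError(f"bad Phe value {phe_umol!r}")
    if phe_umol < 600:
        raise ValueError(f"Phe {phe_umol} below the 600 µmol/L classification floor")
    return "cPKU" if phe_umol > 1200 else "mPKU"


@dataclass(frozen=True)
class PhenotypePrediction:
    patient_id: int
    apv_pair: tuple[float, float] | None
    gpv: float | None
    predicted_type: str  # classic_PKU | mild_PKU | mild_HPA | unpredictable


def predict_phenotype(
    record: PatientRecord,
    apv_table: dict[str, float],
    category: str,
) -> PhenotypePrediction:
    """Prediction for one patient given its genotype category.

    Homozygous -> the allele's APV twice; compound heterozygous -> both
    APVs; single heterozygous -> unpredictable (one allele unexplained).
    """
    if category == "single_heterozygous":
        return PhenotypePrediction(record.patient_id, None, None, UNPREDICTABLE)
    apvs = [apv_table.get(c.key, c.apv) for c in record.calls]
    if len(apvs) == 1:
        apvs = apvs * 2
    value = gpv(apvs[0], apvs[1])
    if value == UNPREDICTABLE:
        return PhenotypePrediction(record.patient_id, None, None, UNPREDICTABLE)
    assert isinstance(value, float | int)
    return PhenotypePrediction(
        record.patient_id,
        (float(apvs[0]), float(apvs[1])),  # type: ignore[arg-type]
        float(value),
        classify_gpv(float(value)),
    )


def predict_cohort(
    cohort: list[PatientRecord], threshold: float | None = None
) -> list[PhenotypePrediction]:
    from .genotyping import HOMOZYGOSITY_THRESHOLD, profile_cohort

    apv_table = build_apv_table(cohort)
    profiles = profile_cohort(
        cohort, HOMOZYGOSITY_THRESHOLD if threshold is None else threshold
    )
    return [
        predict_phenotype(rec, apv_table, prof.category)
        for rec, prof in zip(cohort, profiles)
    ]


#: which recorded labels count as concordant with each predicted/clinical
#: label; made explicit because no single obvious mapping reproduces the
#: originally reported concordance count
DEFAULT_CONCORDANCE_MAP: dict[str, frozenset[str]] = {
    "cPKU": frozenset({"classic"}),
    "mPKU": frozenset({"mild", "mild_HPA"}),
    "classic_PKU": frozenset({"classic"}),
    "mild_PKU": frozenset({"mild"}),
    "mild_HPA": frozenset({"mild_HPA"}),
}


@dataclass(frozen=True)
class ConcordanceResult:
    n_concordant: int
    n_evaluable: int
    rate: float | None  # None when nothing is evaluable
    mapping: dict[str, frozenset[str]]  # echoed, never implicit
    warning: str | None = None


def concordance(
    predicted: list[str | None],
    recorded: list[str | None],
    mapping: dict[str, frozenset[str]] | None = None,
    exclude_missing: bool = True,
) -> ConcordanceResult:
    """Count concordant (predicted, recorded) label pairs under a mapping.

    Missing entries (None) are excluded from the denominator when
    ``exclude_missing``; an unmapped predicted label raises, listing the
    offending pair.
    """
    if len(predicted) != len(recorded):
        raise ValueError("label lists differ in length")
    mapping = DEFAULT_CONCORDANCE_MAP if mapping is None else mapping
    n_conc = n_eval = 0
    for pred, rec in zip(predicted, recorded):
        if pred is None or rec is None or pred == UNPREDICTABLE:
            if exclude_missing:
                continue
            n_eval += 1
            continue
        if pred not in mapping:
            raise ValueError(f"unmapped label pair ({pred!r}, {rec!r})")
        n_eval += 1
        if rec in mapping[pred] or rec == pred:
            n_conc += 1
    if n_eval == 0:
        return ConcordanceResult(0, 0, None, mapping, warning="empty evaluable set")
    return ConcordanceResult(n_conc, n_eval, n_conc / n_eval, mapping)
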