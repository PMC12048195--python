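"""Synthetic ONT pileup and cohort generation with known truth.

The unit of observation is the per-site (depth, alt count) pileup, matching
what the assay reports per call; read-level FASTQ simulation is deliberately
out of scope.  Depth is log-uniform on [50, 2000] — the spread the assay
shows across amplicons, without modeling per-amplicon bias.  The variant
allele fraction is beta-binomial: a latent per-assay fraction drawn around a
zygosity-specific center (defaults 0.72 homozygous / 0.38 heterozygous, the
empirical cohort means, encoding the long-read mapping bias that pushes
fractions well below 1.0/0.5), then binomial sampling at the drawn depth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .cohort import PatientRecord, VariantCall
from .hgvs import HgvsVariant

__all__ = [
    "SimulationConfig",
    "PileupObservation",
    "GenotypeSpec",
    "simulate_pileup",
    "simulate_cohort",
    "default_genotype_table",
]

#: one genotype category: ((variant_key, "hom"),) or two het entries
GenotypeSpec = tuple[tuple[str, str], ...]


@dataclass(frozen=True)
class SimulationConfig:
    depth_min: int = 50
    depth_max: int = 2000
    af_center_hom: float = 0.72
    af_center_het: float = 0.38
    #: beta-binomial concentration; fitted to the within-variant replicate
    #: spread of the cohort (the six shared-variant homozygotes give ~36)
    af_concentration: float = 35.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth_min < 1 or self.depth_max < self.depth_min:
            raise ValueError("need 1 <= depth_min <= depth_max")
        if not 0.0 < self.af_center_het < self.af_center_hom <= 1.0:
            raise ValueError("need 0 < af_center_het < af_center_hom <= 1")
        if self.af_concentration <= 0:
            raise ValueError("af_concentration must be positive")


_PLACEHOLDER = HgvsVariant(
    kind="substitution", start_pos=1, ref_allele="A", alt_allele="G"
)


@dataclass(frozen=True)
class PileupObservation:
    """Simulated per-site pileup with its generating truth."""

    variant: HgvsVariant
    true_zygosity: str  # hom | het
    depth: int
    alt_count: int

    def __post_init__(self) -> None:
        if not 0 <= self.alt_count <= self.depth:
            raise ValueError("need 0 <= alt_count <= depth")

    @property
    def observed_af(self) -> float:
        return self.alt_count / self.depth


def _draw_depth(config: SimulationConfig, rng: np.random.Generator) -> int:
    u = rng.uniform(math.log(config.depth_min), math.log(config.depth_max + 1))
    return min(int(math.exp(u)), config.depth_max)


def simulate_pileup(
    true_zygosity: str,
    config: SimulationConfig,
    rng: np.random.Generator,
    variant: HgvsVariant = _PLACEHOLDER,
) -> PileupObservation:
    """One beta-binomial pileup draw for a site of known zygosity."""
    if true_zygosity not in ("hom", "het"):
        raise ValueError(f"bad zygosity {true_zygosity!r}")
    center = (
        config.af_center_hom if true_zygosity == "hom" else config.af_center_het
    )
    depth = _draw_depth(config, rng)
    if math.isinf(config.af_concentration):
        p = center
    else:
        c = config.af_concentration
        p = rng.beta(center * c, (1.0 - center) * c) if 0.0 < center < 1.0 else center
    alt = int(rng.binomial(depth, p))
    return PileupObservation(
        variant=variant, true_zygosity=true_zygosity, depth=depth, alt_count=alt
    )


def default_genotype_table(
    cohort: list[PatientRecord] | None = None,
    threshold: float | None = None,
) -> list[tuple[GenotypeSpec, float]]:
    """Empirical genotype-frequency table of the packaged cohort.

    Each observed patient genotype (variant identities plus zygosity under
    the allele-fraction rule) contributes 1/n probability mass, so marginal
    carrier frequencies reproduce the cohort's (e.g. 15/40 for the most
    common intronic variant).
    """
    from .cohort import load_packaged_cohort
    from .genotyping import HOMOZYGOSITY_THRESHOLD, call_zygosity

    if cohort is None:
        cohort = load_packaged_cohort()
    if threshold is None:
        threshold = HOMOZYGOSITY_THRESHOLD
    counts: dict[GenotypeSpec, int] = {}
    for rec in cohort:
        spec: GenotypeSpec = tuple(
            (c.key, call_zygosity(c.allele_fraction, threshold)) for c in rec.calls
        )
        counts[spec] = counts.get(spec, 0) + 1
    n = len(cohort)
    return [(spec, k / n) for spec, k in counts.items()]


def _variant_catalog() -> dict[str, HgvsVariant]:
    from .assay import cohort_variants

    return {v.c_notation: v for v in cohort_variants()}


def _apv_lookup() -> dict[str, float]:
    from .phenotyping import build_apv_table

    return build_apv_table()


def simulate_cohort(
    n_patients: int,
    genotype_frequency_table: list[tuple[GenotypeSpec, float]] | None = None,
    config: SimulationConfig | None = None,
    seed: int | None = None,
) -> list[PatientRecord]:
    """Synthetic cohort with truth labels stored on each record.

    Genotypes are drawn from the frequency table (default: the packaged
    cohort's empirical table); each call gets a beta-binomial pileup.  The
    genotype-level phenotype value is filled in from the cohort's APV map
    when the genotype is explained, so that downstream threshold derivation
    sees the same explained/unexplained structure as the real table.
    """
    config = config or SimulationConfig()
    table = (
        genotype_frequency_table
        if genotype_frequency_table is not None
        else default_genotype_table()
    )
    if not table:
        raise ValueError("empty genotype frequency table")
    probs = np.array([p for _, p in table], dtype=float)
    if abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError(f"genotype frequencies sum to {probs.sum()}, not 1")

    rng = np.random.default_rng(config.seed if seed is None else seed)
    catalog = _variant_catalog()
    apv = _apv_lookup()

    records: list[PatientRecord] = []
    for pid in range(1, n_patients + 1):
        spec, _ = table[int(rng.choice(len(table), p=probs))]
        calls = []
        truth = []
        apvs: list[float | None] = []
        for vkey, zyg in spec:
            variant = catalog.get(vkey) or _parse_key(vkey)
            obs = simulate_pileup(zyg, config, rng, variant=variant)
            calls.append(
                VariantCall(
                    variant=variant,
                    depth=obs.depth,
                    allele_fraction=round(obs.observed_af, 4),
                    apv=apv.get(vkey),
                )
            )
            truth.append(zyg)
            apvs.append(apv.get(vkey))
        explained = (len(spec) == 1 and truth[0] == "hom") or len(spec) == 2
        gpv: float | None = None
        if explained and all(a is not None for a in apvs):
            pair = (apvs[0], apvs[0]) if len(apvs) == 1 else (apvs[0], apvs[1])
            gpv = max(pair)  # type: ignore[type-var]
        clinical = "cPKU" if gpv is None or gpv <= 2.7 else "mPKU"
        phe = (
            float(rng.uniform(1201, 2500))
            if clinical == "cPKU"
            else float(rng.uniform(600, 1200))
        )
        records.append(
            PatientRecord(
                patient_id=pid,
                phe_pretreatment=round(phe, 0),
                clinical_type=clinical,
                sex=str(rng.choice(["F", "M"])),
                birth_year=int(rng.integers(1985, 2024)),
                consanguinity="none",
                calls=tuple(calls),
                gpv=gpv,
                truth_zygosity=tuple(truth),
            )
        )
    return records


def _parse_key(key: str) -> HgvsVariant:
    from .hgvs import parse_hgvs_c

    return parse_hgvs_c(key)
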