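"""Zygosity calling, genotype assembly, threshold derivation, pileup calls."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from pahscreen.cohort import PatientRecord, VariantCall
from pahscreen.genotyping import (
    ThresholdError,
    assemble_genotype,
    call_zygosity,
    derive_threshold,
    derive_threshold_detail,
    pileup_call,
    profile_cohort,
)
from pahscreen.hgvs import parse_hgvs_c
from pahscreen.simulate import SimulationConfig, simulate_cohort, simulate_pileup


@pytest.mark.parametrize(
    "af, expected",
    [(0.58, "hom"), (0.56, "het"), (1.0, "hom"), (0.0, "het"), (0.579999, "het")],
)
def test_call_zygosity_inclusive_threshold(af, expected):
    assert call_zygosity(af) == expected


def test_call_zygosity_rejects_out_of_range():
    with pytest.raises(ValueError):
        call_zygosity(1.2)
    with pytest.raises(ValueError):
        call_zygosity(-0.1)


@given(
    st.floats(min_value=0, max_value=1),
    st.floats(min_value=0, max_value=1),
)
def test_call_zygosity_monotone(a, b):
    lo, hi = min(a, b), max(a, b)
    # hom at the lower fraction implies hom at the higher one
    assert not (call_zygosity(lo) == "hom" and call_zygosity(hi) == "het")


def _call(af, key="c.782G>A", depth=100):
    return VariantCall(variant=parse_hgvs_c(key), depth=depth, allele_fraction=af)


def test_assemble_single_hom():
    p = assemble_genotype([_call(0.62)])
    assert p.category == "homozygous" and p.explained and not p.inconsistent


def test_assemble_compound_het_assumes_trans():
    p = assemble_genotype([_call(0.40), _call(0.45, "c.473G>A")])
    assert p.category == "compound_heterozygous"
    assert p.explained and p.trans_assumed and not p.inconsistent


def test_assemble_single_het_unexplained():
    p = assemble_genotype([_call(0.31)])
    assert p.category == "single_heterozygous" and not p.explained


def test_assemble_two_calls_with_hom_fraction_flagged_not_fatal():
    p = assemble_genotype([_call(0.50), _call(0.67, "c.898G>T")])
    assert p.category == "compound_heterozygous"
    assert p.inconsistent and not p.explained


def test_assemble_rejects_zero_or_three_calls():
    with pytest.raises(ValueError):
        assemble_genotype([])
    with pytest.raises(ValueError):
        assemble_genotype([_call(0.3), _call(0.3, "c.473G>A"), _call(0.3, "c.781C>T")])


def test_cohort_partition_matches_study(cohort):
    """The 40-patient table partitions into 20 homozygous, 17 compound
    heterozygous and 3 single heterozygous under the >= 0.58 rule."""
    profiles = profile_cohort(cohort)
    counts = {}
    for p in profiles:
        counts[p.category] = counts.get(p.category, 0) + 1
    assert counts == {
        "homozygous": 20,
        "compound_heterozygous": 17,
        "single_heterozygous": 3,
    }
    # the single inconsistent profile is patient 7 (two variants, af 0.67)
    flagged = [p.patient_id for p in profiles if p.inconsistent]
    assert flagged == [7]


def test_specific_patients(cohort):
    by_id = {r.patient_id: r for r in cohort}
    assert profile_cohort([by_id[4]])[0].category == "homozygous"
    assert profile_cohort([by_id[2]])[0].category == "compound_heterozygous"
    assert profile_cohort([by_id[33]])[0].category == "single_heterozygous"


def test_derive_threshold_on_study_cohort(cohort):
    """The data themselves yield the 0.58 cutoff — the 4th-smallest
    single-variant fraction — with exactly the three known conflicts."""
    detail = derive_threshold_detail(cohort)
    assert detail.threshold == 0.58
    assert detail.candidates[3] == 0.58  # 4th smallest single-variant fraction
    assert detail.n_violations == 3
    assert len(detail.candidates) == 23


def test_derive_threshold_order_invariant(cohort):
    assert derive_threshold(list(reversed(cohort))) == 0.58


def test_derive_threshold_perfect_separation():
    def rec(pid, calls, gpv):
        return PatientRecord(
            patient_id=pid, phe_pretreatment=1500.0, clinical_type="cPKU",
            sex="F", birth_year=2000, consanguinity="none",
            calls=tuple(calls), gpv=gpv,
        )

    cohort = [
        rec(1, [_call(1.0)], gpv=0.0),
        rec(2, [_call(1.0)], gpv=0.0),
        rec(3, [_call(0.5), _call(0.5, "c.473G>A")], gpv=0.0),
    ]
    detail = derive_threshold_detail(cohort)
    assert detail.threshold == 1.0 and detail.n_violations == 0


def test_derive_threshold_needs_single_variant_records():
    rec = PatientRecord(
        patient_id=1, phe_pretreatment=1500.0, clinical_type="cPKU",
        sex="F", birth_year=2000, consanguinity="none",
        calls=(_call(0.4), _call(0.5, "c.473G>A")),
    )
    with pytest.raises(ThresholdError):
        derive_threshold([rec])


def test_derive_threshold_recovers_truth_on_separated_synthetic_cohort():
    """With well-separated allele-fraction centers the derived threshold
    classifies every simulated call to its true zygosity."""
    cfg = SimulationConfig(
        af_center_hom=0.90, af_center_het=0.30, af_concentration=200, seed=11
    )
    cohort = simulate_cohort(200, config=cfg, seed=11)
    t = derive_threshold(cohort)
    errors = sum(
        1
        for rec in cohort
        for call, truth in zip(rec.calls, rec.truth_zygosity)
        if ("hom" if call.allele_fraction >= t else "het") != truth
    )
    assert errors == 0


def test_pileup_call_depth_boundary():
    cfg = SimulationConfig(seed=0)
    rng = np.random.default_rng(0)
    shallow = simulate_pileup("hom", cfg, rng)
    shallow = type(shallow)(shallow.variant, "hom", 49, 30)
    adequate = type(shallow)(shallow.variant, "hom", 50, 35)
    res = pileup_call([shallow, adequate])
    assert len(res.calls) == 1 and res.calls[0].depth == 50
    assert len(res.dropped) == 1 and "depth 49" in res.dropped[0]


def test_pileup_call_min_af_filter():
    obs = simulate_pileup("het", SimulationConfig(), np.random.default_rng(1))
    low = type(obs)(obs.variant, "het", 1000, 100)  # af 0.10 < 0.15
    res = pileup_call([low])
    assert res.calls == () and len(res.dropped) == 1


def test_hom_recovery_rate_at_high_depth():
    """1000 simulated homozygous pileups at depth >= 500 under default noise:
    at least 95% classify homozygous at the 0.58 cutoff."""
    cfg = SimulationConfig(depth_min=500, seed=0)
    rng = np.random.default_rng(123)
    obs = [simulate_pileup("hom", cfg, rng) for _ in range(1000)]
    res = pileup_call(obs, min_af=0.0)
    assert len(res.calls) == 1000
    rate = sum(z == "hom" for z in res.zygosities) / 1000
    assert rate >= 0.95
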