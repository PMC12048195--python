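"""In-silico PCR: primer-site search vs brute force, amplicons, coverage,
pooling, and the shipped toy panel's design constraints."""

import numpy as np
import pytest

from pahscreen.panel import (
    Amplicon,
    PoolingError,
    PrimerPair,
    TargetRegion,
    assign_pools,
    coverage_report,
    enumerate_amplicons,
    find_primer_sites,
    reverse_complement,
)

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T", "R": "AG", "Y": "CT", "S": "GC",
    "W": "AT", "K": "GT", "M": "AC", "B": "CGT", "D": "AGT", "H": "ACT",
    "V": "ACG", "N": "ACGT",
}


def brute_force_sites(primer, reference, max_mismatch, anchor_len):
    """Independent exhaustive window scan (position, strand, mismatches)."""
    hits = []
    k = len(primer)
    for strand, oriented in (("+", primer), ("-", reverse_complement(primer))):
        anchor = (
            set(range(k - anchor_len, k)) if strand == "+" else set(range(anchor_len))
        )
        for p in range(len(reference) - k + 1):
            window = reference[p : p + k]
            bad = [
                i
                for i, (code, base) in enumerate(zip(oriented, window))
                if base not in _IUPAC[code]
            ]
            if any(i in anchor for i in bad):
                continue
            if len(bad) <= max_mismatch:
                hits.append((p, strand, len(bad)))
    return sorted(hits)


def test_exact_plus_strand_site():
    sites = find_primer_sites("ACGT", "TTACGTTT", max_mismatch=0, anchor_len=0)
    # ACGT is palindromic, so the same window is also a minus-strand site
    assert (2, "+", 0) in [(s.position, s.strand, s.mismatches) for s in sites]
    assert all(s.position == 2 for s in sites)

    sites = find_primer_sites("AACGTT"[:4], "TTAACGTT", 0, 0)  # non-palindromic AACG
    plus = [(s.position, s.strand) for s in sites if s.strand == "+"]
    assert plus == [(2, "+")]


def test_minus_strand_site_by_symmetry():
    rng = np.random.default_rng(5)
    ref = "".join(rng.choice(list("ACGT"), 400))
    primer = reverse_complement(ref[100:130])
    sites = find_primer_sites(primer, ref, max_mismatch=0, anchor_len=3)
    assert [(s.position, s.strand) for s in sites] == [(100, "-")]


def test_iupac_codes_match_their_base_sets():
    # window "AAGTACGAGACAAAA" satisfies every code of the primer in turn
    sites = find_primer_sites("ANGTRYSWKMBDHVN", "AAGTACGAGACAAAA" + "TTT", 0, 0)
    assert any(s.position == 0 and s.strand == "+" for s in sites)


def test_primer_longer_than_reference_is_empty_not_error():
    assert find_primer_sites("ACGTACGTACGTACGTACGT", "ACGT", 0, 0) == []


def test_non_dna_primer_rejected():
    with pytest.raises(ValueError, match="non-DNA"):
        find_primer_sites("ACGTX", "ACGTACGT", 0, 0)


def test_matches_brute_force_on_random_instances():
    """100 random (primer, reference) pairs, mismatches allowed: identical
    site sets to the exhaustive position-by-position scan."""
    rng = np.random.default_rng(42)
    for i in range(100):
        n = int(rng.integers(200, 2000))
        ref = "".join(rng.choice(list("ACGT"), n))
        k = int(rng.integers(15, 31))
        start = int(rng.integers(0, n - k))
        primer = list(ref[start : start + k])
        for _ in range(int(rng.integers(0, 4))):  # inject mismatches
            primer[int(rng.integers(0, k))] = str(rng.choice(list("ACGT")))
        primer = "".join(primer)
        mm = int(rng.integers(0, 3))
        anchor = int(rng.integers(0, 4))
        got = [
            (s.position, s.strand, s.mismatches)
            for s in find_primer_sites(primer, ref, mm, anchor)
        ]
        assert got == brute_force_sites(primer, ref, mm, anchor), f"instance {i}"


def test_brute_force_on_long_reference():
    rng = np.random.default_rng(7)
    ref = "".join(rng.choice(list("ACGT"), 20_000))
    primer = ref[4000:4030]
    got = [
        (s.position, s.strand, s.mismatches)
        for s in find_primer_sites(primer, ref, 2, 3)
    ]
    assert got == brute_force_sites(primer, ref, 2, 3)


def test_enumerate_amplicons_planted_pair():
    rng = np.random.default_rng(3)
    ref = "".join(rng.choice(list("ACGT"), 2000))
    pair = PrimerPair("p1", ref[0:20], reverse_complement(ref[1980:2000]))
    amps, warnings = enumerate_amplicons([pair], ref, min_len=1500, max_len=5000)
    assert warnings == []
    assert len(amps) == 1
    assert (amps[0].start, amps[0].end, amps[0].length) == (0, 2000, 2000)


def test_enumerate_amplicons_out_of_range_is_design_failure():
    rng = np.random.default_rng(3)
    ref = "".join(rng.choice(list("ACGT"), 2000))
    pair = PrimerPair("p1", ref[0:20], reverse_complement(ref[500:520]))
    amps, warnings = enumerate_amplicons([pair], ref, min_len=1500, max_len=5000)
    assert amps == []
    assert any("design failure" in w for w in warnings)


def test_empty_size_range_warns():
    amps, warnings = enumerate_amplicons([], "ACGT" * 100, min_len=10, max_len=5)
    assert amps == [] and any("empty size range" in w for w in warnings)


def test_coverage_full_and_partial():
    amp = Amplicon("a", "c", 0, 5000)
    targets = [TargetRegion("c", 100, 200), TargetRegion("c", 4000, 4100)]
    rows, complete = coverage_report([amp], targets)
    assert [r["covered_fraction"] for r in rows] == [1.0, 1.0] and complete

    rows, complete = coverage_report(
        [Amplicon("a", "c", 0, 150)], [TargetRegion("c", 100, 200)]
    )
    assert rows[0]["covered_fraction"] == 0.5 and not complete


def test_coverage_empty_amplicons_all_zero():
    rows, complete = coverage_report([], [TargetRegion("c", 0, 10)])
    assert rows[0]["covered_fraction"] == 0.0 and not complete


def test_coverage_monotone_in_amplicons():
    """Adding amplicons never decreases any covered fraction."""
    rng = np.random.default_rng(9)
    targets = [TargetRegion("c", 100, 700), TargetRegion("c", 900, 1400)]
    amps = [
        Amplicon("a", "c", int(s), int(s) + int(w))
        for s, w in zip(rng.integers(0, 1400, 12), rng.integers(50, 400, 12))
    ]
    prev = [0.0, 0.0]
    for i in range(len(amps) + 1):
        rows, _ = coverage_report(amps[:i], targets)
        fracs = [r["covered_fraction"] for r in rows]
        assert all(0.0 <= f <= 1.0 for f in fracs)
        assert all(f >= p for f, p in zip(fracs, prev))
        prev = fracs


def test_two_overlapping_amplicons_take_two_pools():
    a = Amplicon("a", "c", 0, 100)
    b = Amplicon("b", "c", 50, 150)
    pools = {x.pool for x in assign_pools([a, b], n_pools=2)}
    assert pools == {1, 2}


def test_three_mutually_overlapping_amplicons_infeasible_in_two_pools():
    amps = [Amplicon(n, "c", 0, 100) for n in "abc"]
    with pytest.raises(PoolingError, match="overlap"):
        assign_pools(amps, n_pools=2)


def test_pool_assignment_deterministic_under_input_order():
    rng = np.random.default_rng(2)
    amps = [
        Amplicon(f"a{i}", "c", int(s), int(s) + 300)
        for i, s in enumerate(rng.integers(0, 3000, 10))
    ]
    ref = assign_pools(amps, n_pools=4)
    shuffled = list(reversed(amps))
    assert assign_pools(shuffled, n_pools=4) == ref


# -- the shipped toy panel --------------------------------------------------

def test_shipped_panel_has_nine_in_range_amplicons(design):
    assert len(design.amplicons) == 9
    assert all(1500 <= a.length <= 5000 for a in design.amplicons)
    assert design.warnings == ()


def test_shipped_panel_covers_every_target(design):
    rows, complete = coverage_report(list(design.amplicons), list(design.targets))
    assert complete
    assert all(r["covered_fraction"] == 1.0 for r in rows)
    kinds = {r["kind"] for r in rows}
    assert {"exon", "utr5", "utr3", "junction_flank", "deep_intronic_site"} <= kinds


def test_shipped_panel_pools_internally_non_overlapping(design):
    """Brute-force pairwise interval check inside each pool."""
    assert {a.pool for a in design.amplicons} == {1, 2}
    for pool in (1, 2):
        members = [a for a in design.amplicons if a.pool == pool]
        for i, a in enumerate(members):
            for b in members[i + 1 :]:
                assert not a.overlaps(b), (a, b)


def test_shipped_panel_is_on_target(design):
    assert not any(a.off_target for a in design.amplicons)
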