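"""In-silico PCR over a reference: primer-site search, amplicon enumeration,
target coverage, and pooling of primer pairs into non-interacting tubes.

Specificity is sequence-level only: a primer binds where the window has at
most ``max_mismatch`` mismatches outside an exact 3'-terminal anchor.  Primer
thermodynamics (Tm, dimers) are deliberately out of scope — the assay this
models was validated with sequence-level virtual PCR.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "PrimerPair",
    "TargetRegion",
    "Amplicon",
    "PrimerSite",
    "PoolingError",
    "IUPAC",
    "reverse_complement",
    "find_primer_sites",
    "enumerate_amplicons",
    "coverage_report",
    "assign_pools",
    "read_bed",
    "write_bed",
    "read_fasta",
]

IUPAC: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("GC"),
    "W": frozenset("AT"), "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"),
    "V": frozenset("ACG"), "N": frozenset("ACGT"),
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class PrimerPair:
    """Forward/reverse primers, both written 5'->3' as synthesized."""

    name: str
    fwd_seq: str
    rev_seq: str

    def __post_init__(self) -> None:
        for label, seq in (("fwd", self.fwd_seq), ("rev", self.rev_seq)):
            if not 15 <= len(seq) <= 35:
                raise ValueError(
                    f"{self.name} {label}: primer length {len(seq)} outside 15-35"
                )
            bad = set(seq) - set(IUPAC)
            if bad:
                raise ValueError(f"{self.name} {label}: non-IUPAC characters {bad}")


@dataclass(frozen=True)
class TargetRegion:
    """0-based half-open genomic interval that the panel must cover."""

    contig: str
    start: int
    end: int
    kind: str = "exon"  # exon | utr5 | utr3 | junction_flank | deep_intronic_site
    name: str = ""

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"empty target interval [{self.start},{self.end})")


@dataclass(frozen=True)
class PrimerSite:
    position: int  # 0-based window start on the plus strand
    strand: str  # "+" | "-"
    mismatches: int


@dataclass(frozen=True)
class Amplicon:
    """A predicted PCR product, coordinates including both primers."""

    primer_pair: str
    contig: str
    start: int
    end: int
    pool: int | None = None
    off_target: bool = False

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Amplicon") -> bool:
        return self.contig == other.contig and (
            self.start < other.end and other.start < self.end
        )


class PoolingError(ValueError):
    pass


def _match_matrix(primer: str, reference: str) -> np.ndarray:
    """Boolean (len(ref), len(primer)) array: ref base matches primer base."""
    ref = np.frombuffer(reference.encode(), dtype=np.uint8)
    out = np.zeros((len(reference), len(primer)), dtype=bool)
    for j, code in enumerate(primer):
        allowed = np.frombuffer("".join(sorted(IUPAC[code])).encode(), np.uint8)
        out[:, j] = np.isin(ref, allowed)
    return out


def find_primer_sites(
    primer: str,
    reference: str,
    max_mismatch: int = 2,
    anchor_len: int = 3,
) -> list[PrimerSite]:
    """All windows where the primer binds either strand.

    A window is a site when the 3'-terminal ``anchor_len`` bases match
    exactly and at most ``max_mismatch`` of the remaining bases mismatch.
    Positions are window starts on the plus strand for both strands; on the
    minus strand the primer binds the reverse complement, i.e. the window
    ``reference[p : p+len]`` equals the primer's reverse complement (up to
    mismatches).
    """
    primer = primer.upper()
    if max_mismatch < 0 or anchor_len < 0:
        raise ValueError("max_mismatch and anchor_len must be >= 0")
    bad = set(primer) - set(IUPAC)
    if bad:
        raise ValueError(f"non-DNA characters in primer: {sorted(bad)}")
    k = len(primer)
    if k > len(reference):
        return []

    sites: list[PrimerSite] = []
    for strand, oriented in (("+", primer), ("-", reverse_complement(primer))):
        # the primer's 3' end maps to the window's last base on "+",
        # to the window's first base on "-"
        anchor_idx = (
            range(k - anchor_len, k) if strand == "+" else range(anchor_len)
        )
        match = _match_matrix(oriented, reference)
        n_win = len(reference) - k + 1
        # windowed view: row i gives matches of window starting at i
        win = np.lib.stride_tricks.sliding_window_view(
            np.arange(len(reference)), k
        )[:n_win]
        per_window = match[win, np.arange(k)]
        anchor_cols = np.fromiter(anchor_idx, dtype=int)
        anchor_ok = (
            per_window[:, anchor_cols].all(axis=1)
            if anchor_len
            else np.ones(n_win, dtype=bool)
        )
        rest = np.setdiff1d(np.arange(k), anchor_cols)
        mismatches = (~per_window[:, rest]).sum(axis=1)
        hits = np.flatnonzero(anchor_ok & (mismatches <= max_mismatch))
        sites.extend(
            PrimerSite(int(p), strand, int(mismatches[p])) for p in hits
        )
    sites.sort(key=lambda s: (s.position, s.strand))
    return sites


def enumerate_amplicons(
    pairs: Sequence[PrimerPair],
    reference: str,
    contig: str = "ref",
    min_len: int = 1500,
    max_len: int = 5000,
    max_mismatch: int = 2,
    anchor_len: int = 3,
    targets: Sequence[TargetRegion] | None = None,
) -> tuple[list[Amplicon], list[str]]:
    """Predicted products for every pair, plus a design-failure report.

    Every combination of a plus-strand forward site and a downstream
    minus-strand reverse site whose product length falls inside
    ``[min_len, max_len]`` is emitted.  Products that do not touch any target
    are flagged ``off_target``, never dropped.  A pair with zero in-range
    products is recorded in the returned report, not raised.
    """
    warnings: list[str] = []
    if min_len > max_len:
        warnings.append(f"empty size range [{min_len}, {max_len}]")
        return [], warnings
    amplicons: list[Amplicon] = []
    for pair in pairs:
        fwd_sites = [
            s for s in find_primer_sites(pair.fwd_seq, reference, max_mismatch, anchor_len)
            if s.strand == "+"
        ]
        rev_sites = [
            s for s in find_primer_sites(pair.rev_seq, reference, max_mismatch, anchor_len)
            if s.strand == "-"
        ]
        n_before = len(amplicons)
        for f in fwd_sites:
            for r in rev_sites:
                end = r.position + len(pair.rev_seq)
                length = end - f.position
                if f.position < end and min_len <= length <= max_len:
                    amp = Amplicon(pair.name, contig, f.position, end)
                    if targets is not None:
                        on = any(
                            t.contig == contig
                            and t.start < amp.end
                            and amp.start < t.end
                            for t in targets
                        )
                        amp = replace(amp, off_target=not on)
                    amplicons.append(amp)
        if len(amplicons) == n_before:
            warnings.append(f"design failure: pair {pair.name} yields no in-range product")
    amplicons.sort(key=lambda a: (a.start, a.end, a.primer_pair))
    return amplicons, warnings


def _merged(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    out: list[tuple[int, int]] = []
    for s, e in sorted(intervals):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def coverage_report(
    amplicons: Sequence[Amplicon], targets: Sequence[TargetRegion]
) -> tuple[list[dict], bool]:
    """Per-target coverage rows and an overall completeness flag.

    Covered fraction is interval arithmetic on half-open intervals; the panel
    is complete iff every target's fraction is exactly 1.0.
    """
    rows = []
    complete = True
    for t in targets:
        covering = [
            a for a in amplicons
            if a.contig == t.contig and a.start < t.end and t.start < a.end
        ]
        merged = _merged((max(a.start, t.start), min(a.end, t.end)) for a in covering)
        covered = sum(e - s for s, e in merged)
        fraction = covered / (t.end - t.start)
        complete &= fraction == 1.0
        rows.append(
            {
                "target": t.name or f"{t.contig}:{t.start}-{t.end}",
                "kind": t.kind,
                "contig": t.contig,
                "start": t.start,
                "end": t.end,
                "n_amplicons": len(covering),
                "covered_fraction": fraction,
            }
        )
    return rows, complete


def assign_pools(amplicons: Sequence[Amplicon], n_pools: int = 2) -> list[Amplicon]:
    """Greedy interval coloring: no two overlapping amplicons share a pool.

    Deterministic: amplicons are processed sorted by (start, length); each
    takes the lowest pool unused by any overlapping, already-assigned
    amplicon.  Raises :class:`PoolingError` naming the mutually overlapping
    set when ``n_pools`` colors do not suffice.
    """
    if n_pools < 1:
        raise ValueError("n_pools must be >= 1")
    ordered = sorted(amplicons, key=lambda a: (a.start, a.length, a.primer_pair))
    assigned: list[Amplicon] = []
    for amp in ordered:
        used = {a.pool for a in assigned if a.overlaps(amp)}
        pool = next((p for p in range(1, n_pools + 1) if p not in used), None)
        if pool is None:
            clique = [a.primer_pair for a in assigned if a.overlaps(amp)] + [
                amp.primer_pair
            ]
            raise PoolingError(
                f"{n_pools} pools infeasible: mutually overlapping amplicons {clique}"
            )
        assigned.append(replace(amp, pool=pool))
    return assigned


# -- plain-text interchange -------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def read_bed(path: str | Path, kind: str = "exon") -> list[TargetRegion]:
    """Minimal BED reader (0-based half-open, name in column 4)."""
    regions = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        name = fields[3] if len(fields) > 3 else ""
        regions.append(
            TargetRegion(fields[0], int(fields[1]), int(fields[2]), kind, name)
        )
    return regions


def write_bed(regions: Iterable[TargetRegion | Amplicon], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in regions:
            name = getattr(r, "name", "") or getattr(r, "primer_pair", "")
            fh.write(f"{r.contig}\t{r.start}\t{r.end}\t{name}\n")
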