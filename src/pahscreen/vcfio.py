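"""Minimal VCF 4.2 writer for cohort calls lifted onto the toy reference.

Output is 1-based and left-anchored: a deletion's REF spans the anchor base
plus the deleted bases, ALT is the anchor base.  Records are ordered by
position, then by alternate allele, so output is deterministic.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

from .cohort import VariantCall
from .hgvs import HgvsVariant
from .reference import AnnotatedReference, LiftError

__all__ = ["to_vcf_record", "write_vcf"]


def to_vcf_record(
    variant: HgvsVariant, reference: AnnotatedReference
) -> tuple[int, str, str]:
    """(POS 1-based, REF, ALT) for one variant on the toy reference."""
    seq = reference.sequence
    g_start = reference.lift(variant)
    if variant.kind == "substitution":
        ref = seq[g_start]
        if variant.ref_allele and variant.ref_allele != ref:
            raise LiftError(
                f"{variant.c_notation}: stated ref {variant.ref_allele} != "
                f"reference base {ref} at {g_start}"
            )
        return g_start + 1, ref, variant.alt_allele
    end_pos = variant.end_pos if variant.end_pos is not None else variant.start_pos
    g_end = reference.transcript_map.to_genomic(end_pos, variant.end_offset)
    if variant.kind == "deletion":
        anchor = seq[g_start - 1]
        deleted = seq[g_start : g_end + 1]
        if variant.ref_allele and variant.ref_allele != deleted:
            raise LiftError(
                f"{variant.c_notation}: stated deleted sequence does not match "
                "reference"
            )
        return g_start, anchor + deleted, anchor
    # delins: replace [g_start, g_end] with alt, no anchor required
    return g_start + 1, seq[g_start : g_end + 1], variant.alt_allele


def write_vcf(
    calls: Iterable[VariantCall],
    reference: AnnotatedReference,
    path: str | Path,
    source: str = "pahscreen",
) -> None:
    """Write calls as a minimal, position-sorted VCF 4.2 file."""
    lines = [
        "##fileformat=VCFv4.2",
        f"##source={source}",
        f"##contig=<ID={reference.contig},length={reference.length}>",
        '##INFO=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        '##INFO=<ID=AF,Number=A,Type=Float,Description="Allele fraction">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
    ]
    records = []
    for call in calls:
        pos, ref, alt = to_vcf_record(call.variant, reference)
        records.append((pos, alt, ref, call))
    for pos, alt, ref, call in sorted(records, key=lambda r: (r[0], r[1])):
        lines.append(
            f"{reference.contig}\t{pos}\t{call.variant.c_notation}\t{ref}\t{alt}"
            f"\t.\tPASS\tDP={call.depth};AF={call.allele_fraction:g}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
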