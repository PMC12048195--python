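"""Synthetic PAH-like annotated reference and transcript coordinate map.

The toy gene reproduces the *structure* of PAH (13 exons whose CDS spans
match the real transcript annotation, 5'/3' UTRs, introns) on a random
~31 kb contig, with the reference base at every cohort variant position
patched to the variant's reference allele so that every cohort variant lifts
cleanly to genomic coordinates.  The sequence itself is synthetic: no real
genome data ships with the package.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .hgvs import HgvsVariant
from .panel import TargetRegion

__all__ = [
    "TranscriptMap",
    "AnnotatedReference",
    "LiftError",
    "build_toy_reference",
    "CDS_EXONS",
]

#: CDS spans (1-based, inclusive) of the 13 exons of the PAH transcript
#: (NM_000277.3 annotation); the toy gene reuses them so that intron-offset
#: positions printed in the cohort (c.168+5, c.169-13, c.353-1, c.1066-11)
#: fall at real junction offsets.
CDS_EXONS: tuple[tuple[int, int], ...] = (
    (1, 60), (61, 168), (169, 352), (353, 441), (442, 509), (510, 706),
    (707, 842), (843, 912), (913, 969), (970, 1065), (1066, 1199),
    (1200, 1315), (1316, 1359),
)

_INTRON_LENGTHS = (1500, 3000, 2400, 1200, 2800, 3200, 3000, 1400, 2600,
                   1800, 2600, 3400)
_UTR5_LEN = 100
_UTR3_LEN = 200
_PAD = 500  # flanking sequence outside the gene


class LiftError(ValueError):
    """Coding coordinate outside the region covered by the transcript map."""


@dataclass(frozen=True)
class TranscriptMap:
    """Bijection between CDS coordinates (pos, intron offset) and genomic
    positions, for a plus-strand single-transcript gene.

    Covered domain: every exonic CDS position, plus intron positions up to
    half the intron length from the nearest exon boundary (ties go to the
    donor side).  ``to_genomic`` and ``to_coding`` invert each other on that
    domain.
    """

    exon_starts: tuple[int, ...]  # genomic 0-based starts, CDS part only
    cds_spans: tuple[tuple[int, int], ...] = CDS_EXONS

    def to_genomic(self, pos: int, offset: int = 0) -> int:
        """Genomic 0-based position of CDS coordinate ``pos±offset``."""
        for (c_start, c_end), g_start in zip(self.cds_spans, self.exon_starts):
            if c_start <= pos <= c_end:
                g = g_start + (pos - c_start)
                if offset == 0:
                    return g
                if offset > 0:
                    if pos != c_end:
                        raise LiftError(
                            f"+{offset} offset requires a donor-side exon end, "
                            f"got c.{pos}"
                        )
                    limit = self._intron_after(pos)
                    if offset > limit - limit // 2:
                        raise LiftError(f"offset +{offset} beyond intron midpoint")
                    return g + offset
                if pos != c_start:
                    raise LiftError(
                        f"{offset} offset requires an acceptor-side exon start, "
                        f"got c.{pos}"
                    )
                limit = self._intron_before(pos)
                if -offset > limit // 2:
                    raise LiftError(f"offset {offset} beyond intron midpoint")
                return g + offset
        raise LiftError(f"c.{pos} outside CDS (1..{self.cds_spans[-1][1]})")

    def to_coding(self, genomic: int) -> tuple[int, int]:
        """Inverse of :meth:`to_genomic` on the covered domain."""
        for i, ((c_start, c_end), g_start) in enumerate(
            zip(self.cds_spans, self.exon_starts)
        ):
            g_end = g_start + (c_end - c_start)
            if g_start <= genomic <= g_end:
                return c_start + (genomic - g_start), 0
            if genomic < g_start:
                if i == 0:
                    break
                prev_span, prev_start = self.cds_spans[i - 1], self.exon_starts[i - 1]
                prev_g_end = prev_start + (prev_span[1] - prev_span[0])
                d_donor = genomic - prev_g_end
                d_acceptor = g_start - genomic
                if d_donor <= d_acceptor:
                    return prev_span[1], d_donor
                return c_start, -d_acceptor
        raise LiftError(f"genomic position {genomic} outside mapped gene body")

    def _intron_after(self, cds_end: int) -> int:
        idx = [e for _, e in self.cds_spans].index(cds_end)
        nxt = self.exon_starts[idx + 1]
        cur_end = self.exon_starts[idx] + (
            self.cds_spans[idx][1] - self.cds_spans[idx][0]
        )
        return nxt - cur_end - 1

    def _intron_before(self, cds_start: int) -> int:
        idx = [s for s, _ in self.cds_spans].index(cds_start)
        return self._intron_after(self.cds_spans[idx - 1][1])


@dataclass(frozen=True)
class AnnotatedReference:
    contig: str
    sequence: str
    exons: tuple[TargetRegion, ...]  # CDS-bearing exon bodies, genomic
    utr5: TargetRegion
    utr3: TargetRegion
    transcript_map: TranscriptMap

    @property
    def length(self) -> int:
        return len(self.sequence)

    def lift(self, variant: HgvsVariant) -> int:
        """Genomic 0-based position of the variant's start coordinate."""
        return self.transcript_map.to_genomic(
            variant.start_pos, variant.start_offset
        )

    def write_fasta(self, path: str | Path, width: int = 80) -> None:
        with open(path, "w") as fh:
            fh.write(f">{self.contig}\n")
            for i in range(0, len(self.sequence), width):
                fh.write(self.sequence[i : i + width] + "\n")

    def target_regions(
        self,
        junction_flank: int = 25,
        extra_sites: tuple[tuple[int, int], ...] = (),
    ) -> list[TargetRegion]:
        """Panel targets: exons, UTRs, junction flanks, explicit intron sites.

        ``extra_sites`` are (cds_pos, offset) point targets for deep-intronic
        positions with reported pathogenic variants.
        """
        targets: list[TargetRegion] = [self.utr5, self.utr3]
        for i, ex in enumerate(self.exons):
            targets.append(ex)
            targets.append(
                TargetRegion(
                    self.contig,
                    max(0, ex.start - junction_flank),
                    ex.start,
                    "junction_flank",
                    f"{ex.name}_acceptor",
                )
            )
            targets.append(
                TargetRegion(
                    self.contig, ex.end, ex.end + junction_flank,
                    "junction_flank", f"{ex.name}_donor",
                )
            )
        for pos, off in extra_sites:
            g = self.transcript_map.to_genomic(pos, off)
            targets.append(
                TargetRegion(
                    self.contig, g, g + 1, "deep_intronic_site",
                    f"c.{pos}{off:+d}",
                )
            )
        return targets


def build_toy_reference(
    seed: int,
    planted_variants: tuple[HgvsVariant, ...] = (),
    contig: str = "toyPAH",
) -> AnnotatedReference:
    """Deterministically generate the annotated toy reference.

    ``planted_variants``: the reference base at each variant's lifted
    position is set to its stated reference allele (substitutions only;
    deletions without spelled-out sequence need no planting).
    """
    rng = np.random.default_rng(seed)

    exon_starts = []
    cursor = _PAD + _UTR5_LEN
    for (c_start, c_end), intron in zip(
        CDS_EXONS, _INTRON_LENGTHS + (0,)
    ):
        exon_starts.append(cursor)
        cursor += (c_end - c_start + 1) + intron
    total = cursor - _INTRON_LENGTHS[-1] * 0 + _UTR3_LEN + _PAD

    seq = rng.choice(np.frombuffer(b"ACGT", dtype="S1"), size=total)
    tmap = TranscriptMap(exon_starts=tuple(exon_starts))

    for v in planted_variants:
        if v.kind != "substitution" or not v.ref_allele:
            continue
        g = tmap.to_genomic(v.start_pos, v.start_offset)
        seq[g] = v.ref_allele.encode()

    exons = tuple(
        TargetRegion(
            contig,
            g_start,
            g_start + (c_end - c_start + 1),
            "exon",
            f"exon{i + 1}",
        )
        for i, ((c_start, c_end), g_start) in enumerate(zip(CDS_EXONS, exon_starts))
    )
    utr5 = TargetRegion(contig, _PAD, _PAD + _UTR5_LEN, "utr5", "utr5")
    last_end = exons[-1].end
    utr3 = TargetRegion(contig, last_end, last_end + _UTR3_LEN, "utr3", "utr3")

    return AnnotatedReference(
        contig=contig,
        sequence=b"".join(seq).decode(),
        exons=exons,
        utr5=utr5,
        utr3=utr3,
        transcript_map=tmap,
    )
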