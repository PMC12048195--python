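"""Parser for the coding (c.) HGVS subset used in PAH diagnostics.

Supported events: single-base substitutions, deletions (with or without the
deleted sequence spelled out) and deletion-insertions, at exonic positions or
at intron positions expressed as signed offsets from the nearest exon
boundary (``c.1066-11``, ``c.168+5``).  Anything else (dup, ins, inv, protein
or genomic notation) raises :class:`UnsupportedHgvsError` — deliberately an
error rather than a silent skip, so that a cohort table containing an event
outside the model cannot pass unnoticed.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

__all__ = [
    "HgvsVariant",
    "HgvsParseError",
    "UnsupportedHgvsError",
    "parse_hgvs_c",
]


class HgvsParseError(ValueError):
    """Malformed HGVS string; the message names the offending token."""


class UnsupportedHgvsError(HgvsParseError):
    """Well-formed HGVS, but an event kind outside the supported subset."""


_PREFIX_RE = re.compile(
    r"^(?:(?P<genome>[A-Z]{2}_[\d.]+)\s*\(\s*(?P<tx1>[A-Z]{2}_[\d.]+)\s*\)"
    r"|(?P<tx2>[A-Z]{2}_[\d.]+))\s*:\s*"
)
_POS_RE = re.compile(r"(?P<pos>\d+)(?P<off>[+-]\d+)?")


@dataclass(frozen=True)
class HgvsVariant:
    """One coding-coordinate variant (1-based CDS numbering).

    ``start_offset``/``end_offset`` are signed intron offsets; 0 means the
    position is exonic.  ``ref_allele`` may be empty for deletions written
    without sequence (``c.592_613del``); ``alt_allele`` is empty for
    deletions.
    """

    kind: str  # substitution | deletion | delins
    start_pos: int
    start_offset: int = 0
    end_pos: int | None = None
    end_offset: int = 0
    ref_allele: str = ""
    alt_allele: str = ""
    transcript_id: str = ""
    genome_accession: str = ""
    raw: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        if self.start_pos < 1:
            raise HgvsParseError(f"start_pos must be >= 1, got {self.start_pos}")
        if self.end_pos is None:
            end, end_off = self.start_pos, self.start_offset
        else:
            end, end_off = self.end_pos, self.end_offset
        if (end, end_off) < (self.start_pos, self.start_offset):
            raise HgvsParseError(
                f"end position {end}{end_off:+d} precedes start "
                f"{self.start_pos}{self.start_offset:+d}"
            )
        if self.kind == "substitution" and not (
            len(self.ref_allele) == 1 and len(self.alt_allele) == 1
        ):
            raise HgvsParseError("substitution requires single-base ref and alt")

    # -- coordinate helpers -------------------------------------------------

    @property
    def span(self) -> tuple[tuple[int, int], tuple[int, int]]:
        """((start_pos, start_offset), (end_pos, end_offset))."""
        if self.end_pos is None:
            return (self.start_pos, self.start_offset), (self.start_pos, self.start_offset)
        return (self.start_pos, self.start_offset), (self.end_pos, self.end_offset)

    # -- formatting ---------------------------------------------------------

    def _coord(self, pos: int, off: int) -> str:
        return f"{pos}{off:+d}" if off else f"{pos}"

    @property
    def c_notation(self) -> str:
        """Canonical ``c.`` string without transcript prefix (dict key)."""
        start = self._coord(self.start_pos, self.start_offset)
        if self.kind == "substitution":
            return f"c.{start}{self.ref_allele}>{self.alt_allele}"
        if self.end_pos is not None and self.span[1] != self.span[0]:
            coord = f"{start}_{self._coord(self.end_pos, self.end_offset)}"
        else:
            coord = start
        if self.kind == "deletion":
            return f"c.{coord}del{self.ref_allele}"
        return f"c.{coord}delins{self.alt_allele}"

    def format(self) -> str:
        """Canonical full string, with accession prefix when known."""
        if self.genome_accession and self.transcript_id:
            return f"{self.genome_accession}({self.transcript_id}):{self.c_notation}"
        if self.transcript_id:
            return f"{self.transcript_id}:{self.c_notation}"
        return self.c_notation

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.format()


def _parse_coord(token: str, s: str) -> tuple[int, int]:
    m = _POS_RE.fullmatch(token)
    if not m:
        raise HgvsParseError(f"bad position token {token!r} in {s!r}")
    return int(m.group("pos")), int(m.group("off") or 0)


def parse_hgvs_c(s: str) -> HgvsVariant:
    """Parse an HGVS ``c.`` string of the supported subset.

    Whitespace inside the event (as printed in clinical tables, e.g.
    ``c.143 T > C``) is tolerated.
    """
    if not isinstance(s, str) or not s.strip():
        raise HgvsParseError("empty HGVS string")
    work = s.strip()
    genome = transcript = ""
    m = _PREFIX_RE.match(work)
    if m:
        genome = m.group("genome") or ""
        transcript = m.group("tx1") or m.group("tx2") or ""
        work = work[m.end():]
    work = work.replace(" ", "")
    if not work.startswith("c."):
        raise HgvsParseError(f"expected 'c.' notation in {s!r}")
    body = work[2:]

    for bad in ("dup", "ins", "inv", "con"):
        # delins contains "ins"; only reject a bare insertion
        if bad in body and not (bad == "ins" and "delins" in body):
            raise UnsupportedHgvsError(f"unsupported HGVS kind {bad!r} in {s!r}")

    m = re.match(r"^(?P<c1>\d+(?:[+-]\d+)?)(?:_(?P<c2>\d+(?:[+-]\d+)?))?", body)
    if not m or m.end() == 0:
        raise HgvsParseError(f"no position found in {s!r}")
    start_pos, start_off = _parse_coord(m.group("c1"), s)
    end_pos = end_off = None
    if m.group("c2"):
        end_pos, end_off = _parse_coord(m.group("c2"), s)
    event = body[m.end():]

    if re.fullmatch(r"[ACGT]>[ACGT]", event):
        if end_pos is not None:
            raise HgvsParseError(f"substitution cannot span a range: {s!r}")
        ref, alt = event[0], event[2]
        if ref == alt:
            raise HgvsParseError(f"ref equals alt in {s!r}")
        return HgvsVariant(
            kind="substitution", start_pos=start_pos, start_offset=start_off,
            ref_allele=ref, alt_allele=alt,
            transcript_id=transcript, genome_accession=genome, raw=s,
        )

    m2 = re.fullmatch(r"del(?P<seq>[ACGT]*)(?:ins(?P<ins>[ACGT]+))?", event)
    if m2:
        kind = "delins" if m2.group("ins") else "deletion"
        return HgvsVariant(
            kind=kind, start_pos=start_pos, start_offset=start_off,
            end_pos=end_pos if end_pos is not None else start_pos,
            end_offset=end_off if end_pos is not None else start_off,
            ref_allele=m2.group("seq") or "",
            alt_allele=m2.group("ins") or "",
            transcript_id=transcript, genome_accession=genome, raw=s,
        )

    raise HgvsParseError(f"unrecognized event token {event!r} in {s!r}")
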