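"""The shipped toy assay: a 9-pair tiling panel over the synthetic PAH-like
reference, mirroring the printed design constraints of the real assay —
nine primer pairs, products of 1500-5000 bp, every exon/UTR/junction target
fully covered, primers pooled into two mutually non-overlapping tubes.

The real assay's primer sequences are not published; this panel is generated
(24-mers lifted from the toy reference at tiling positions) and satisfies the
same constraints, which is what the in-silico validation exercises.
"""

from __future__ import annotations

from dataclasses import dataclass

from .cohort import load_packaged_cohort
from .hgvs import HgvsVariant
from .panel import (
    Amplicon,
    PrimerPair,
    TargetRegion,
    assign_pools,
    coverage_report,
    enumerate_amplicons,
    reverse_complement,
)
from .reference import AnnotatedReference, build_toy_reference

__all__ = ["PanelDesign", "cohort_variants", "build_toy_panel", "DEFAULT_PANEL_SEED"]

DEFAULT_PANEL_SEED = 17

_N_AMPLICONS = 9
_AMPLICON_LEN = 3800
_TILE_START = 400
_PRIMER_LEN = 24
#: deep-intronic / junction positions with reported pathogenic variants,
#: added as explicit point targets (cds_pos, offset)
DEEP_INTRONIC_SITES = ((1066, -11), (169, -13), (168, 5), (353, -1))


@dataclass(frozen=True)
class PanelDesign:
    reference: AnnotatedReference
    primer_pairs: tuple[PrimerPair, ...]
    targets: tuple[TargetRegion, ...]
    amplicons: tuple[Amplicon, ...]  # pooled
    coverage: tuple[dict, ...]
    complete: bool
    warnings: tuple[str, ...]


def cohort_variants() -> tuple[HgvsVariant, ...]:
    """The distinct variants of the packaged cohort, in first-seen order."""
    seen: dict[str, HgvsVariant] = {}
    for rec in load_packaged_cohort():
        for call in rec.calls:
            seen.setdefault(call.key, call.variant)
    return tuple(seen.values())


def build_toy_panel(
    seed: int = DEFAULT_PANEL_SEED,
    min_len: int = 1500,
    max_len: int = 5000,
    max_mismatch: int = 2,
    anchor_len: int = 3,
    n_pools: int = 2,
) -> PanelDesign:
    """Construct the reference, primers, predicted amplicons and pools.

    Deterministic for a given seed.  Nine 3.8 kb products tile the gene body
    with ~400 bp overlap between neighbours, so consecutive products land in
    alternate pools.
    """
    reference = build_toy_reference(seed, planted_variants=cohort_variants())
    seq = reference.sequence

    step = (reference.length - 2 * _TILE_START - _AMPLICON_LEN) // (_N_AMPLICONS - 1)
    pairs = []
    for i in range(_N_AMPLICONS):
        start = _TILE_START + i * step
        end = start + _AMPLICON_LEN
        pairs.append(
            PrimerPair(
                name=f"PAH_amp{i + 1}",
                fwd_seq=seq[start : start + _PRIMER_LEN],
                rev_seq=reverse_complement(seq[end - _PRIMER_LEN : end]),
            )
        )

    targets = tuple(reference.target_regions(extra_sites=DEEP_INTRONIC_SITES))
    amplicons, warnings = enumerate_amplicons(
        pairs,
        seq,
        contig=reference.contig,
        min_len=min_len,
        max_len=max_len,
        max_mismatch=max_mismatch,
        anchor_len=anchor_len,
        targets=targets,
    )
    pooled = assign_pools(amplicons, n_pools=n_pools)
    coverage, complete = coverage_report(pooled, targets)
    return PanelDesign(
        reference=reference,
        primer_pairs=tuple(pairs),
        targets=targets,
        amplicons=tuple(pooled),
        coverage=tuple(coverage),
        complete=complete,
        warnings=tuple(warnings),
    )
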