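"""Linkage-based marker extraction.

Legacy microsatellite assays map to amplicon intervals on the reference
genome; SNPs inside low-recombination haplotype blocks hit by those amplicons
inherit the microsatellites' discriminating power. All interval math is
0-based half-open: touching endpoints do not overlap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datatypes import Interval, IntervalSet, PanelDefinition


@dataclass
class SnpPositions:
    """SNP identifiers with genomic coordinates (0-based)."""

    snp_ids: list[str]
    chrom: list[str]
    pos: np.ndarray

    def __post_init__(self) -> None:
        self.pos = np.asarray(self.pos, dtype=np.int64)
        n = len(self.snp_ids)
        if len(self.chrom) != n or self.pos.shape != (n,):
            raise ValueError("chrom and pos must align with snp_ids")
        if (self.pos < 0).any():
            raise ValueError("positions must be non-negative")
        coords = list(zip(self.chrom, self.pos.tolist()))
        if len(set(coords)) != len(coords):
            raise ValueError("duplicate (chrom, pos) coordinates")


def _overlaps(a: Interval, b: Interval) -> bool:
    return a.chrom == b.chrom and a.start < b.end and b.start < a.end


def overlap_intervals(amplicons: IntervalSet, blocks: IntervalSet) -> IntervalSet:
    """Blocks sharing at least one base with at least one amplicon.

    An amplicon crossing block boundaries hits every block it touches; each
    hit block is reported once, in its original order.
    """
    hits: list[Interval] = []
    seen: set[Interval] = set()
    for block in blocks:
        if block in seen:
            continue
        if any(_overlaps(amp, block) for amp in amplicons):
            hits.append(block)
            seen.add(block)
    return IntervalSet(hits)


def snps_in_blocks(blocks: IntervalSet, snps: SnpPositions) -> PanelDefinition:
    """SNPs with block.start <= pos < block.end on the block's chromosome,
    deduplicated, ordered by (chrom, pos), tagged ``linkage_block``."""
    chosen: dict[str, tuple[str, int]] = {}
    for i, sid in enumerate(snps.snp_ids):
        c, p = snps.chrom[i], int(snps.pos[i])
        for block in blocks:
            if block.chrom == c and block.start <= p < block.end:
                chosen[sid] = (c, p)
                break
    order = sorted(chosen, key=lambda s: chosen[s])
    return PanelDefinition(
        marker_ids=order,
        provenance=["linkage_block"] * len(order),
        score=[0.0] * len(order),
    )


def merge_panels(a: PanelDefinition, b: PanelDefinition) -> PanelDefinition:
    """Union of two panels; markers present in both get provenance ``both``
    and keep the larger score. Order: a's markers first, then b's new ones."""
    prov: dict[str, str] = {}
    score: dict[str, float] = {}
    order: list[str] = []
    in_a = set(a.marker_ids)
    for panel in (a, b):
        for m, pv, sc in zip(panel.marker_ids, panel.provenance, panel.score):
            if m not in prov:
                prov[m] = pv
                score[m] = float(sc)
                order.append(m)
            else:
                score[m] = max(score[m], float(sc))
                if panel is b and m in in_a:
                    prov[m] = "both"
    return PanelDefinition(
        marker_ids=order,
        provenance=[prov[m] for m in order],
        score=[score[m] for m in order],
    )
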