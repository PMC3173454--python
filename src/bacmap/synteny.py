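"""Synteny-block chaining of sequence anchors against a reference genome.

BAC-end (or marker) anchors tie positions on a map source unit (contig or
pseudomolecule) to reference coordinates.  Collinear runs of anchors —
monotone in both genomes, consecutive anchors no farther apart than a gap
limit on either side — are chained into forward or inverted synteny
blocks.  Block-size bins and reference coverage statistics summarize the
comparison, and unanchored contigs can inherit a linkage-group prediction
from the blocks of anchored contigs they align beside.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "BesAnchor",
    "SyntenyBlock",
    "filter_repeats",
    "chain_anchors",
    "block_stats",
    "predict_linkage_groups",
]


@dataclass(frozen=True)
class BesAnchor:
    """A sequence-tagged anchor point: a position on a map source unit
    matched to a reference interval."""

    anchor_id: str
    source: str
    source_pos: float  # bp (or CB converted to bp) on the source unit
    ref_chrom: str
    ref_start: int
    ref_end: int
    strand: str = "+"
    percent_identity: float = 100.0

    def __post_init__(self) -> None:
        if self.ref_start >= self.ref_end:
            raise ValueError(f"{self.anchor_id}: ref_start must be < ref_end")
        if not 0.0 <= self.percent_identity <= 100.0:
            raise ValueError(f"{self.anchor_id}: identity outside [0, 100]")


@dataclass(frozen=True)
class SyntenyBlock:
    source: str
    source_start: float
    source_end: float
    ref_chrom: str
    ref_start: int
    ref_end: int
    n_anchors: int
    orientation: str  # forward | inverted

    @property
    def length_bp(self) -> int:
        return self.ref_end - self.ref_start


def filter_repeats(
    anchors: Sequence[BesAnchor], max_hits: int = 8
) -> list[BesAnchor]:
    """Drop anchors whose sequence id maps to more than ``max_hits``
    reference locations (repeat-derived multi-mappers)."""
    counts = Counter(a.anchor_id for a in anchors)
    return [a for a in anchors if counts[a.anchor_id] <= max_hits]


def _best_chain(
    anchors: list[BesAnchor], max_gap_bp: float, inverted: bool
) -> list[int]:
    """Longest chain (by anchor count) monotone increasing on source and
    increasing (forward) or decreasing (inverted) on reference, with
    consecutive anchors <= max_gap_bp apart on both sides.  Anchors must be
    pre-sorted by source position."""
    k = len(anchors)
    best_len = [1] * k
    prev = [-1] * k
    for j in range(k):
        aj = anchors[j]
        for i in range(j):
            ai = anchors[i]
            if aj.source_pos < ai.source_pos:
                continue
            if aj.source_pos - ai.source_pos > max_gap_bp:
                continue
            if inverted:
                if aj.ref_end > ai.ref_start:
                    continue
                if ai.ref_start - aj.ref_end > max_gap_bp:
                    continue
            else:
                if aj.ref_start < ai.ref_end:
                    continue
                if aj.ref_start - ai.ref_end > max_gap_bp:
                    continue
            if best_len[i] + 1 > best_len[j]:
                best_len[j] = best_len[i] + 1
                prev[j] = i
    end = int(np.argmax(best_len))
    chain = []
    while end != -1:
        chain.append(end)
        end = prev[end]
    return chain[::-1]


def chain_anchors(
    anchors: Sequence[BesAnchor],
    max_gap_bp: float = 500_000,
    min_anchors: int = 3,
) -> list[SyntenyBlock]:
    """Chain anchors into synteny blocks per (source unit, reference
    chromosome) group.

    Within each group the longest monotone chain (forward or inverted) is
    extracted repeatedly; accepted blocks claim their reference span, so
    remaining anchors inside it are dropped and blocks never overlap on the
    reference within a group.  Chains shorter than ``min_anchors`` are
    discarded.
    """
    groups: dict[tuple[str, str], list[BesAnchor]] = {}
    for a in anchors:
        groups.setdefault((a.source, a.ref_chrom), []).append(a)
    blocks: list[SyntenyBlock] = []
    for (source, chrom) in sorted(groups):
        pool = sorted(
            groups[(source, chrom)],
            key=lambda a: (a.source_pos, a.ref_start, a.anchor_id),
        )
        while len(pool) >= min_anchors:
            fwd = _best_chain(pool, max_gap_bp, inverted=False)
            inv = _best_chain(pool, max_gap_bp, inverted=True)
            chain, orient = (
                (fwd, "forward") if len(fwd) >= len(inv) else (inv, "inverted")
            )
            if len(chain) < min_anchors:
                break
            picked = [pool[i] for i in chain]
            ref_lo = min(a.ref_start for a in picked)
            ref_hi = max(a.ref_end for a in picked)
            blocks.append(
                SyntenyBlock(
                    source=source,
                    source_start=min(a.source_pos for a in picked),
                    source_end=max(a.source_pos for a in picked),
                    ref_chrom=chrom,
                    ref_start=ref_lo,
                    ref_end=ref_hi,
                    n_anchors=len(picked),
                    orientation=orient,
                )
            )
            pool = [
                a
                for i, a in enumerate(pool)
                if i not in set(chain)
                and not (a.ref_start >= ref_lo and a.ref_end <= ref_hi)
            ]
    blocks.sort(key=lambda b: (b.source, b.ref_chrom, b.ref_start))
    return blocks


def block_stats(
    blocks: Sequence[SyntenyBlock],
    reference_sizes: Mapping[str, int],
) -> dict:
    """Block-size bins (<1, 1-3, >3 Mbp; lower edge inclusive), reference
    coverage (fraction covered by >=1 block), double coverage (>=2
    blocks), and the longest block."""
    total = sum(reference_sizes.values())
    if total <= 0:
        raise ValueError("reference has zero length")
    bins = {"<1Mbp": 0, "1-3Mbp": 0, ">3Mbp": 0}
    for b in blocks:
        if b.length_bp < 1_000_000:
            bins["<1Mbp"] += 1
        elif b.length_bp < 3_000_000:
            bins["1-3Mbp"] += 1
        else:
            bins[">3Mbp"] += 1
    covered = 0
    doubled = 0
    for chrom in reference_sizes:
        events: list[tuple[int, int]] = []
        for b in blocks:
            if b.ref_chrom == chrom:
                events.append((b.ref_start, +1))
                events.append((b.ref_end, -1))
        events.sort()
        depth = 0
        last = None
        for pos, delta in events:
            if last is not None and pos > last:
                if depth >= 1:
                    covered += pos - last
                if depth >= 2:
                    doubled += pos - last
            depth += delta
            last = pos
    longest = max((b.length_bp for b in blocks), default=0)
    return {
        "bins": bins,
        "n_blocks": len(blocks),
        "coverage": covered / total,
        "double_coverage": doubled / total,
        "longest_block_bp": longest,
    }


def predict_linkage_groups(
    contig_anchors: Mapping[str, Sequence[BesAnchor]],
    blocks_by_lg: Mapping[str, Sequence[SyntenyBlock]],
) -> dict[str, tuple[str | None, str, int]]:
    """Predict a linkage group for each unanchored contig from where its
    anchors land on the reference.

    An anchor votes for a linkage group when its reference midpoint lies
    inside a block aligned by that group's anchored contigs.  A contig
    inherits the group collecting votes from more than half of its anchors
    and strictly more than any rival; otherwise the call is "ambiguous",
    or "none" when no anchor lands in any annotated block.

    Returns contig -> (linkage group or None, status, supporting votes).
    """
    intervals: list[tuple[str, int, int, str]] = []
    for lg, blocks in blocks_by_lg.items():
        for b in blocks:
            intervals.append((b.ref_chrom, b.ref_start, b.ref_end, lg))
    out: dict[str, tuple[str | None, str, int]] = {}
    for contig in sorted(contig_anchors):
        anchors = list(contig_anchors[contig])
        votes: Counter = Counter()
        for a in anchors:
            mid = (a.ref_start + a.ref_end) / 2.0
            hit_lgs = {
                lg
                for chrom, lo, hi, lg in intervals
                if chrom == a.ref_chrom and lo <= mid < hi
            }
            for lg in hit_lgs:
                votes[lg] += 1
        if not votes:
            out[contig] = (None, "none", 0)
            continue
        ranked = votes.most_common()
        top_lg, top_n = ranked[0]
        rival = ranked[1][1] if len(ranked) > 1 else 0
        if top_n > 0.5 * len(anchors) and top_n > rival:
            out[contig] = (top_lg, "assigned", top_n)
        else:
            out[contig] = (None, "ambiguous", top_n)
    return out
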