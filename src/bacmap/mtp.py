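"""Dense minimum-tile-path selection for BAC-end sequencing.

A map built at ~30x coverage does not need both ends of every clone
sequenced; an end roughly every k bp suffices.  The CB spacing between
selected clone left-ends is n = m*k/i, where m is the median CB span per
clone, i the average insert size (bp), and k the desired inter-anchor
distance (bp).  Selection walks each contig left to right, picking at each
n-CB target the clone whose left end lies nearest, while skipping regions
already covered by pre-existing BAC ends or by the right end of an earlier
selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .assembly import PhysicalMap

__all__ = ["MtpParams", "MtpSelection", "cb_spacing", "select_mtp"]


@dataclass(frozen=True)
class MtpParams:
    median_cb_per_bac: float  # m
    avg_insert_bp: float      # i
    anchor_distance_bp: float # k

    def __post_init__(self) -> None:
        if min(self.median_cb_per_bac, self.avg_insert_bp, self.anchor_distance_bp) <= 0:
            raise ValueError("m, i, k must all be positive")

    @property
    def spacing_cb(self) -> int:
        return cb_spacing(
            self.median_cb_per_bac, self.avg_insert_bp, self.anchor_distance_bp
        )


def cb_spacing(m: float, i: float, k: float) -> int:
    """CB units between selected clone ends: n = max(1, round(m*k/i))."""
    if min(m, i, k) <= 0:
        raise ValueError("m, i, k must all be positive")
    return max(1, round(m * k / i))


@dataclass
class MtpSelection:
    """Selected clones per contig with the CB targets they satisfied."""

    per_contig: dict[str, list[tuple[str, int, int]]]  # (clone, left_cb, target)
    skipped_targets: dict[str, int] = field(default_factory=dict)

    @property
    def clones(self) -> list[str]:
        return sorted(
            c for rows in self.per_contig.values() for c, _, _ in rows
        )

    @property
    def n_clones(self) -> int:
        return sum(len(rows) for rows in self.per_contig.values())

    @property
    def n_reactions(self) -> int:
        # both ends of every selected clone are sequenced
        return 2 * self.n_clones


def select_mtp(
    pmap: PhysicalMap,
    n: int,
    existing_bes: Iterable[str] = (),
) -> MtpSelection:
    """Greedy dense-MTP walk over each contig's CB span.

    Targets T = 0, n, 2n, ... ; at each target the unselected clone with
    the left end nearest T is taken (ties to the smaller clone id), unless
    an existing-BES clone end or a previously selected clone's right end
    lies within n/2 CB of T (region already covered), or the nearest
    candidate's left end falls within n/2 CB of an already selected left
    end (keeps selected ends at least n/2 apart).
    """
    if n < 1:
        raise ValueError("spacing n must be >= 1")
    existing = set(existing_bes)
    half = n / 2.0
    per_contig: dict[str, list[tuple[str, int, int]]] = {}
    skipped: dict[str, int] = {}
    for cid in sorted(pmap.contigs):
        contig = pmap.contigs[cid]
        if not contig.members:
            raise ValueError(f"{cid}: contig has no layout")
        members = sorted(contig.members, key=lambda m: (m.left_cb, m.clone_id))
        lefts = np.array([m.left_cb for m in members])
        span_hi = max(m.right_cb for m in members)
        existing_ends = sorted(
            e
            for m in members
            if m.clone_id in existing
            for e in (m.left_cb, m.right_cb)
        )
        existing_ends = np.array(existing_ends, dtype=float)
        chosen: list[tuple[str, int, int]] = []
        chosen_idx: set[int] = set()
        chosen_rights: list[int] = []
        chosen_lefts: list[int] = []
        n_skipped = 0
        for target in range(0, span_hi + 1, n):
            if existing_ends.size and np.min(np.abs(existing_ends - target)) <= half:
                n_skipped += 1
                continue
            if chosen_rights and min(abs(r - target) for r in chosen_rights) <= half:
                n_skipped += 1
                continue
            best = None
            for idx in np.argsort(np.abs(lefts - target), kind="stable"):
                if idx in chosen_idx:
                    continue
                cand = members[idx]
                if cand.clone_id in existing:
                    continue  # both ends already sequenced
                if chosen_lefts and min(
                    abs(cand.left_cb - l) for l in chosen_lefts
                ) < half:
                    continue
                # stable argsort keeps equal-distance candidates in left-end
                # order; among equal left ends, members order is by clone id
                best = (idx, cand)
                break
            if best is None:
                n_skipped += 1
                continue
            idx, cand = best
            chosen.append((cand.clone_id, cand.left_cb, target))
            chosen_idx.add(int(idx))
            chosen_rights.append(cand.right_cb)
            chosen_lefts.append(cand.left_cb)
        per_contig[cid] = chosen
        skipped[cid] = n_skipped
    return MtpSelection(per_contig=per_contig, skipped_targets=skipped)
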