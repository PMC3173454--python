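"""Pooled-overgo marker anchoring: 3-D pool design, hit-matrix
deconvolution, repetitive-probe screening, and framework anchoring of
contigs to linkage groups.

Probes are arranged on a dx x dy x dz grid and hybridized as axis pools
(dx + dy + dz pools for the cube), so each probe lies in exactly three
pools.  A clone carrying one probe lights up one pool per axis and its
probe coordinate is recovered directly; clones carrying several probes
produce ambiguous candidate sets that are reported, never auto-resolved.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Iterable, Mapping, Sequence

import numpy as np

from .assembly import PhysicalMap

__all__ = [
    "MarkerRecord",
    "PoolDesign",
    "HitMatrix",
    "CloneCall",
    "DeconvolutionResult",
    "AnchoredContig",
    "design_3d_pools",
    "simulate_hit_matrix",
    "deconvolve",
    "screen_probes",
    "anchor_contigs",
]


@dataclass(frozen=True)
class MarkerRecord:
    """A genetic marker: SSR markers carry a linkage group and cM position;
    COSII markers may lack both and inherit a linkage group from the contig
    they land in.  ``truth_position`` is the simulated genome coordinate."""

    marker_id: str
    marker_class: str = "SSR"  # SSR | COSII
    linkage_group: str | None = None
    cm_position: float | None = None
    truth_position: int | None = None

    def __post_init__(self) -> None:
        if self.linkage_group is not None and (
            self.cm_position is None or self.cm_position < 0
        ):
            raise ValueError(
                f"{self.marker_id}: linkage group requires cm_position >= 0"
            )


@dataclass
class PoolDesign:
    """3-D pooling layout: probe -> (x, y, z) grid coordinate, pools are
    the axis slices Xi, Yj, Zk."""

    dims: tuple[int, int, int]
    coords: dict[str, tuple[int, int, int]]

    @property
    def pool_ids(self) -> list[str]:
        dx, dy, dz = self.dims
        return (
            [f"X{i}" for i in range(dx)]
            + [f"Y{j}" for j in range(dy)]
            + [f"Z{k}" for k in range(dz)]
        )

    def pool_members(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {pid: set() for pid in self.pool_ids}
        for probe, (x, y, z) in self.coords.items():
            out[f"X{x}"].add(probe)
            out[f"Y{y}"].add(probe)
            out[f"Z{z}"].add(probe)
        return out


def design_3d_pools(
    probe_ids: Sequence[str], dims: tuple[int, int, int] = (5, 5, 5)
) -> PoolDesign:
    """Assign probes to cube coordinates row-major; a full 5x5x5 cube holds
    125 probes hybridized as 15 axis pools."""
    dx, dy, dz = dims
    capacity = dx * dy * dz
    if len(probe_ids) > capacity:
        raise ValueError(
            f"{len(probe_ids)} probes exceed the {dx}x{dy}x{dz} capacity of "
            f"{capacity}"
        )
    if len(set(probe_ids)) != len(probe_ids):
        raise ValueError("probe ids must be unique")
    coords = {}
    for idx, probe in enumerate(probe_ids):
        x, rem = divmod(idx, dy * dz)
        y, z = divmod(rem, dz)
        coords[probe] = (x, y, z)
    return PoolDesign(dims=dims, coords=coords)


@dataclass
class HitMatrix:
    """Boolean pool x clone hybridization readout."""

    pool_ids: list[str]
    clone_ids: list[str]
    hits: np.ndarray  # bool, shape (n_pools, n_clones)

    def __post_init__(self) -> None:
        self.hits = np.asarray(self.hits, dtype=bool)
        if self.hits.shape != (len(self.pool_ids), len(self.clone_ids)):
            raise ValueError("hit matrix shape does not match pool/clone lists")


def simulate_hit_matrix(
    design: PoolDesign,
    truth: Mapping[str, set[str]],
    clone_ids: Sequence[str],
    fp_rate: float = 0.0,
    fn_rate: float = 0.0,
    seed: int = 0,
) -> HitMatrix:
    """Build the pool x clone readout implied by probe->clone truth, with
    optional per-cell false-positive/negative noise."""
    rng = np.random.default_rng(seed)
    pools = design.pool_ids
    members = design.pool_members()
    idx = {c: j for j, c in enumerate(clone_ids)}
    hits = np.zeros((len(pools), len(clone_ids)), dtype=bool)
    for i, pid in enumerate(pools):
        for probe in members[pid]:
            for clone in truth.get(probe, ()):
                if clone in idx:
                    hits[i, idx[clone]] = True
    if fn_rate > 0:
        hits &= rng.random(hits.shape) >= fn_rate
    if fp_rate > 0:
        hits |= rng.random(hits.shape) < fp_rate
    return HitMatrix(list(pools), list(clone_ids), hits)


@dataclass(frozen=True)
class CloneCall:
    clone_id: str
    status: str  # negative | unique | ambiguous | inconsistent
    candidates: tuple[str, ...] = ()

    @property
    def probe(self) -> str | None:
        return self.candidates[0] if self.status == "unique" else None


@dataclass
class DeconvolutionResult:
    calls: dict[str, CloneCall]
    probe_hits: dict[str, list[str]]  # probe -> clones called for it

    def status_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for call in self.calls.values():
            out[call.status] = out.get(call.status, 0) + 1
        return out


def deconvolve(design: PoolDesign, hits: HitMatrix) -> DeconvolutionResult:
    """HybDecon-style deconvolution of a 3-D pooled readout.

    Per clone, with A/B/C the positive pools on the three axes: all three
    empty -> negative; exactly one positive per axis naming a designed
    probe -> unique; one axis empty while another is positive (or the
    unique coordinate names no designed probe) -> inconsistent; otherwise
    ambiguous, with candidates the designed probes in A x B x C.
    """
    valid = set(design.pool_ids)
    for pid in hits.pool_ids:
        if pid not in valid:
            raise ValueError(f"unknown pool id {pid!r} for this design")
    by_probe_coord = {v: k for k, v in design.coords.items()}
    calls: dict[str, CloneCall] = {}
    probe_hits: dict[str, list[str]] = {p: [] for p in design.coords}
    for j, clone in enumerate(hits.clone_ids):
        pos = [hits.pool_ids[i] for i in np.flatnonzero(hits.hits[:, j])]
        ax = {
            "X": sorted(int(p[1:]) for p in pos if p[0] == "X"),
            "Y": sorted(int(p[1:]) for p in pos if p[0] == "Y"),
            "Z": sorted(int(p[1:]) for p in pos if p[0] == "Z"),
        }
        sizes = [len(ax["X"]), len(ax["Y"]), len(ax["Z"])]
        if all(s == 0 for s in sizes):
            calls[clone] = CloneCall(clone, "negative")
            continue
        if any(s == 0 for s in sizes):
            calls[clone] = CloneCall(clone, "inconsistent")
            continue
        cands = tuple(
            sorted(
                by_probe_coord[(x, y, z)]
                for x, y, z in product(ax["X"], ax["Y"], ax["Z"])
                if (x, y, z) in by_probe_coord
            )
        )
        if not cands:
            calls[clone] = CloneCall(clone, "inconsistent")
        elif all(s == 1 for s in sizes):
            calls[clone] = CloneCall(clone, "unique", cands)
            probe_hits[cands[0]].append(clone)
        else:
            calls[clone] = CloneCall(clone, "ambiguous", cands)
    return DeconvolutionResult(calls, probe_hits)


def screen_probes(
    hit_counts: Mapping[str, int], max_hits: int = 8
) -> tuple[dict[str, int], dict[str, str]]:
    """Mask probes hitting more than ``max_hits`` locations as repetitive.

    Returns (kept probe->count, masked probe->reason)."""
    kept: dict[str, int] = {}
    masked: dict[str, str] = {}
    for probe, count in hit_counts.items():
        if count < 0:
            raise ValueError(f"negative hit count for {probe}")
        if count > max_hits:
            masked[probe] = "repetitive"
        else:
            kept[probe] = count
    return kept, masked


@dataclass
class AnchoredContig:
    """A contig tied to a linkage group through its marker placements."""

    contig_id: str
    linkage_group: str
    placements: list[tuple[str, float, float | None]]  # (marker, cb, cM)
    length_cb: int
    conflict: bool = False
    orientation: str = "unknown"  # + | - | unknown

    @property
    def mean_cm(self) -> float:
        cms = [cm for _, _, cm in self.placements if cm is not None]
        return float(np.mean(cms)) if cms else float("nan")


def anchor_contigs(
    pmap: PhysicalMap,
    probe_clones: Mapping[str, Iterable[str]],
    markers: Sequence[MarkerRecord],
) -> tuple[list[AnchoredContig], list[str], dict]:
    """Framework-anchor contigs to linkage groups from marker->clone hits.

    A marker's CB position in a contig is the median midpoint of the spans
    of its hit clones there.  A contig is anchored when it carries at least
    one linkage-group-bearing marker; contigs collecting markers from more
    than one linkage group are flagged as conflicts (anchored to the
    majority group, ties by name).  COSII markers without a linkage group
    are placed and inherit their contig's group; markers hitting no mapped
    clone are reported unplaced.
    """
    by_id = {m.marker_id: m for m in markers}
    contig_of = pmap.contig_of()
    spans = {
        mb.clone_id: (mb.left_cb, mb.right_cb)
        for c in pmap.contigs.values()
        for mb in c.members
    }
    # marker -> contig -> CB placement
    placements: dict[str, dict[str, float]] = {}
    unplaced: list[str] = []
    for marker_id in sorted(probe_clones):
        per_contig: dict[str, list[float]] = {}
        for clone in probe_clones[marker_id]:
            cid = contig_of.get(clone)
            if cid is None:
                continue
            lo, hi = spans[clone]
            per_contig.setdefault(cid, []).append((lo + hi) / 2.0)
        if not per_contig:
            unplaced.append(marker_id)
            continue
        placements[marker_id] = {
            cid: float(np.median(mids)) for cid, mids in per_contig.items()
        }

    per_contig_markers: dict[str, list[tuple[str, float]]] = {}
    for marker_id, by_contig in placements.items():
        for cid, cb in by_contig.items():
            per_contig_markers.setdefault(cid, []).append((marker_id, cb))

    anchored: list[AnchoredContig] = []
    inherited: dict[str, str] = {}  # COSII marker -> inferred LG
    for cid in sorted(pmap.contigs):
        mks = per_contig_markers.get(cid, [])
        lg_votes: dict[str, int] = {}
        for marker_id, _ in mks:
            mk = by_id.get(marker_id)
            if mk is not None and mk.linkage_group is not None:
                lg_votes[mk.linkage_group] = lg_votes.get(mk.linkage_group, 0) + 1
        if not lg_votes:
            continue
        lg = sorted(lg_votes.items(), key=lambda kv: (-kv[1], kv[0]))[0][0]
        conflict = len(lg_votes) > 1
        placed = []
        for marker_id, cb in sorted(mks, key=lambda kv: (kv[1], kv[0])):
            mk = by_id.get(marker_id)
            cm = mk.cm_position if mk is not None else None
            placed.append((marker_id, cb, cm))
            if mk is not None and mk.linkage_group is None:
                inherited[marker_id] = lg
        anchored.append(
            AnchoredContig(
                contig_id=cid,
                linkage_group=lg,
                placements=placed,
                length_cb=pmap.contigs[cid].length_cb,
                conflict=conflict,
            )
        )
    anchored_ids = {a.contig_id for a in anchored}
    unanchored = sorted(set(pmap.contigs) - anchored_ids)
    multi = sorted(m for m, by in placements.items() if len(by) > 1)
    n_placed = len(placements)
    report = {
        "markers_placed": n_placed,
        "markers_unplaced": unplaced,
        "markers_multi_contig": multi,
        "single_location_rate": (
            round(100.0 * (n_placed - len(multi)) / n_placed, 1) if n_placed else None
        ),
        "cosii_inherited_lg": inherited,
        "contigs_conflict": sorted(a.contig_id for a in anchored if a.conflict),
    }
    return anchored, unanchored, report
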