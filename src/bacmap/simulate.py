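"""Seeded synthetic data: genomes, BAC libraries, HICF fingerprints,
marker truth, rearranged reference genomes, and BAC-end anchors.

Every generator is deterministic under a fixed seed, and every downstream
stage of the toolkit can be exercised against planted truth produced here:
clone intervals, marker coordinates, and rearrangement event logs are all
retained so tests can compare assembled maps, anchorings, and synteny
blocks against what was simulated.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .fingerprint import Fingerprint

__all__ = [
    "ENZYMES",
    "GenomeSim",
    "LibrarySpec",
    "CloneRecord",
    "HicfSpec",
    "RearrangementEvent",
    "RearrangedReference",
    "InfeasibleLibraryError",
    "simulate_genome",
    "simulate_bac_library",
    "hicf_fingerprint",
    "fingerprint_library",
    "simulate_marker_truth",
    "simulate_rearranged_reference",
    "simulate_bes_anchors",
    "default_hicf_spec",
    "default_library_specs",
]

# recognition sequence and cut offset within it (position of the cut
# relative to the first base of the site, on the top strand)
ENZYMES: dict[str, tuple[str, int]] = {
    "HindIII": ("AAGCTT", 1),  # A^AGCTT
    "EcoRI": ("GAATTC", 1),    # G^AATTC
    "MboI": ("GATC", 0),       # ^GATC
    "BamHI": ("GGATCC", 1),    # G^GATCC
    "XbaI": ("TCTAGA", 1),     # T^CTAGA
    "XhoI": ("CTCGAG", 1),     # C^TCGAG
    "HaeIII": ("GGCC", 2),     # GG^CC
}

HICF_ENZYMES = ("HindIII", "BamHI", "XbaI", "XhoI", "HaeIII")
# SNaPshot labelling marks the 5' overhangs left by the four six-cutters;
# blunt HaeIII ends are unlabelled, so only fragments with a six-cutter
# terminus are detected on the capillary.
HICF_LABELED = ("HindIII", "BamHI", "XbaI", "XhoI")

_COMP = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def _find_cut_sites(sequence: str, recognition: str, offset: int) -> np.ndarray:
    pattern = re.compile(f"(?={re.escape(recognition)})")
    return np.array(
        [m.start() + offset for m in pattern.finditer(sequence)], dtype=np.int64
    )


@dataclass
class GenomeSim:
    """A simulated genome with a per-enzyme index of cut positions."""

    sequence: str
    seed: int
    site_index: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def length(self) -> int:
        return len(self.sequence)

    def sites(self, enzyme: str) -> np.ndarray:
        if enzyme not in self.site_index:
            rec, off = ENZYMES[enzyme]
            self.site_index[enzyme] = _find_cut_sites(self.sequence, rec, off)
        return self.site_index[enzyme]


def simulate_genome(
    length: int,
    gc: float = 0.5,
    seed: int = 0,
    enzymes: Sequence[str] | None = None,
) -> GenomeSim:
    """Generate an i.i.d. random genome with the requested GC content.

    ``enzymes`` selects which cut-site indexes to precompute (default: the
    full registry).  Reproducible: a fixed seed gives an identical sequence.
    """
    if length < 10_000:
        raise ValueError("genome length must be >= 10 kb")
    if not 0.0 < gc < 1.0:
        raise ValueError("gc must be strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    at = (1.0 - gc) / 2.0
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    seq = rng.choice(bases, size=length, p=[at, gc / 2, gc / 2, at])
    genome = GenomeSim(sequence=seq.tobytes().decode("ascii"), seed=seed)
    for name in enzymes if enzymes is not None else ENZYMES:
        genome.sites(name)
    return genome


@dataclass(frozen=True)
class LibrarySpec:
    """One BAC library: cloning enzyme, clone count, insert-size window."""

    name: str
    enzyme: str
    clone_count: int
    insert_min: int
    insert_max: int
    insert_mean: float | None = None  # size-selection target; default midpoint
    target_coverage: float | None = None

    def __post_init__(self) -> None:
        if self.insert_min >= self.insert_max:
            raise ValueError("insert_min must be < insert_max")
        if self.clone_count < 1:
            raise ValueError("clone_count must be >= 1")
        if self.enzyme not in ENZYMES:
            raise ValueError(f"unknown enzyme {self.enzyme!r}")

    @property
    def mean_insert(self) -> float:
        if self.insert_mean is not None:
            return float(self.insert_mean)
        return (self.insert_min + self.insert_max) / 2.0

    def nominal_coverage(self, genome_length: int) -> float:
        return self.clone_count * self.mean_insert / genome_length


@dataclass(frozen=True)
class CloneRecord:
    """A BAC clone: an interval of the simulated genome between two cut
    sites of its library's cloning enzyme."""

    clone_id: str
    library: str
    true_start: int
    true_end: int
    well: str | None = None

    @property
    def insert_size(self) -> int:
        return self.true_end - self.true_start


class InfeasibleLibraryError(ValueError):
    pass


def simulate_bac_library(
    genome: GenomeSim, spec: LibrarySpec, seed: int = 0
) -> list[CloneRecord]:
    """Draw clones by partial digestion: uniform random left cut site, right
    cut site nearest a size-selection target drawn around the library mean.

    Both clone ends always coincide with cut sites of the library enzyme,
    and every insert lies within [insert_min, insert_max].
    """
    sites = genome.sites(spec.enzyme)
    if sites.size < 2:
        raise InfeasibleLibraryError(
            f"library {spec.name}: fewer than 2 {spec.enzyme} sites in genome"
        )
    lo = np.searchsorted(sites, sites + spec.insert_min, side="left")
    hi = np.searchsorted(sites, sites + spec.insert_max, side="right")
    feasible = np.flatnonzero(hi > lo)
    if feasible.size == 0:
        raise InfeasibleLibraryError(
            f"library {spec.name}: no {spec.enzyme} site pair with insert in "
            f"[{spec.insert_min}, {spec.insert_max}]"
        )
    rng = np.random.default_rng(seed)
    sd = (spec.insert_max - spec.insert_min) / 6.0
    clones: list[CloneRecord] = []
    for k in range(spec.clone_count):
        i = int(feasible[rng.integers(feasible.size)])
        target = float(
            np.clip(
                rng.normal(spec.mean_insert, sd), spec.insert_min, spec.insert_max
            )
        )
        window = sites[lo[i] : hi[i]]
        j = int(np.argmin(np.abs(window - (sites[i] + target))))
        start, end = int(sites[i]), int(window[j])
        clones.append(
            CloneRecord(
                clone_id=f"{spec.name}_{k:05d}",
                library=spec.name,
                true_start=start,
                true_end=end,
            )
        )
    return clones


@dataclass(frozen=True)
class HicfSpec:
    """In-silico HICF protocol: enzyme set, sizing window, resolution,
    sizing noise, and the QC band-count filter.

    ``labeled_enzymes`` restricts detection to fragments whose left cut was
    made by a labelled enzyme (fluorescent end-labelling); ``None`` means
    every fragment of the union digest is detected.
    """

    enzymes: tuple[str, ...] = HICF_ENZYMES
    size_min_bp: float = 35.0
    size_max_bp: float = 600.0
    resolution_bp: float = 0.1
    noise_sd_units: float = 0.5
    band_min: int = 20
    band_max: int = 220
    labeled_enzymes: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.size_min_bp >= self.size_max_bp:
            raise ValueError("size window must satisfy min < max")
        if self.resolution_bp <= 0:
            raise ValueError("resolution must be positive")


def default_hicf_spec() -> HicfSpec:
    """Five-enzyme HICF with six-cutter end-labelling; yields fingerprints
    averaging ~110 bands on 138-kb inserts, matching capillary practice."""
    return HicfSpec(labeled_enzymes=HICF_LABELED)


def default_library_specs(
    genome_length: int, coverage: float = 10.0
) -> list[LibrarySpec]:
    """Three complementary libraries (HindIII / EcoRI / MboI) at the given
    per-library coverage, with production-scale insert windows."""
    table = [
        ("TCB_A", "HindIII", 90_000, 185_000, 145_000.0),
        ("TCB_B", "EcoRI", 40_000, 160_000, 120_000.0),
        ("TCB_C", "MboI", 80_000, 180_000, 140_000.0),
    ]
    return [
        LibrarySpec(
            name=name,
            enzyme=enz,
            clone_count=max(1, round(coverage * genome_length / mean)),
            insert_min=mn,
            insert_max=mx,
            insert_mean=mean,
            target_coverage=coverage,
        )
        for name, enz, mn, mx, mean in table
    ]


def hicf_fingerprint(
    clone: CloneRecord,
    genome: GenomeSim,
    spec: HicfSpec,
    rng: np.random.Generator | int = 0,
) -> Fingerprint:
    """Digest a clone insert in silico and digitize the detected fragments.

    Fragments run between consecutive cut sites of the union of the
    protocol's enzymes inside the insert (insert boundaries included).
    Detected fragments within the sizing window are converted to integer
    size-units (``round(bp / resolution)``) with Gaussian sizing noise and
    returned sorted ascending.  A clone with no in-window fragment yields an
    empty band list (removed later by QC).
    """
    if not (0 <= clone.true_start < clone.true_end <= genome.length):
        raise ValueError(f"clone {clone.clone_id} outside genome bounds")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    start, end = clone.true_start, clone.true_end
    cuts = [np.array([start, end], dtype=np.int64)]
    for enz in spec.enzymes:
        s = genome.sites(enz)
        inner = s[(s > start) & (s < end)]
        cuts.append(inner)
    allcuts = np.unique(np.concatenate(cuts))
    lefts = allcuts[:-1]
    sizes = np.diff(allcuts).astype(float)
    if spec.labeled_enzymes is not None:
        labeled = np.unique(
            np.concatenate(
                [genome.sites(e) for e in spec.labeled_enzymes]
                + [np.array([], dtype=np.int64)]
            )
        )
        detected = np.isin(lefts, labeled)
    else:
        detected = np.ones(lefts.size, dtype=bool)
    in_window = (sizes >= spec.size_min_bp) & (sizes <= spec.size_max_bp)
    frag = sizes[detected & in_window]
    units = np.round(
        frag / spec.resolution_bp + rng.normal(0.0, spec.noise_sd_units, frag.size)
    ).astype(np.int64)
    units = np.maximum(units, 1)
    return Fingerprint(
        clone_id=clone.clone_id, library=clone.library, bands=tuple(sorted(units))
    )


def fingerprint_library(
    clones: Sequence[CloneRecord],
    genome: GenomeSim,
    spec: HicfSpec,
    seed: int = 0,
) -> list[Fingerprint]:
    rng = np.random.default_rng(seed)
    return [hicf_fingerprint(c, genome, spec, rng) for c in clones]


def simulate_marker_truth(
    genome: GenomeSim,
    markers: Iterable,
    clones: Sequence[CloneRecord],
) -> dict[str, set[str]]:
    """Which clones each marker probe truly hybridizes to: exactly the
    clones whose insert interval contains the marker's genome coordinate."""
    starts = np.array([c.true_start for c in clones])
    ends = np.array([c.true_end for c in clones])
    ids = [c.clone_id for c in clones]
    truth: dict[str, set[str]] = {}
    for mk in markers:
        pos = getattr(mk, "truth_position", None)
        mid = getattr(mk, "marker_id", str(mk))
        if pos is None:
            raise ValueError(f"marker {mid} has no simulated genome coordinate")
        if not 0 <= pos < genome.length:
            raise ValueError(f"marker {mid} coordinate {pos} outside genome")
        hit = (starts <= pos) & (pos < ends)
        truth[mid] = {ids[i] for i in np.flatnonzero(hit)}
    return truth


@dataclass(frozen=True)
class RearrangementEvent:
    """One structural event applied to the simulated genome when building a
    diverged reference: inversion in place, or translocation/duplication of
    a source interval to a destination coordinate."""

    kind: str  # inversion | translocation | duplication
    start: int
    end: int
    dest: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("inversion", "translocation", "duplication"):
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.start >= self.end:
            raise ValueError("event interval must satisfy start < end")
        if self.kind != "inversion" and self.dest is None:
            raise ValueError(f"{self.kind} requires a destination coordinate")


@dataclass(frozen=True)
class Segment:
    """A reference segment: a genome interval, its strand in the reference,
    and its reference start coordinate."""

    src_start: int
    src_end: int
    strand: int  # +1 forward, -1 inverted
    ref_start: int

    @property
    def length(self) -> int:
        return self.src_end - self.src_start

    @property
    def ref_end(self) -> int:
        return self.ref_start + self.length


@dataclass
class RearrangedReference:
    """A rearranged copy of the simulated genome plus the replayable event
    log and segment map needed to derive planted synteny-block truth."""

    sequence: str
    segments: list[Segment]
    events: list[RearrangementEvent]
    name: str = "ref1"

    @property
    def length(self) -> int:
        return len(self.sequence)

    def map_interval(self, start: int, end: int) -> list[tuple[int, int, int]]:
        """Reference placements of a genome interval wholly inside one
        segment: list of (ref_start, ref_end, strand).  Duplicated intervals
        return one placement per copy; intervals spanning a breakpoint
        return none."""
        out = []
        for seg in self.segments:
            if seg.src_start <= start and end <= seg.src_end:
                if seg.strand > 0:
                    rs = seg.ref_start + (start - seg.src_start)
                else:
                    rs = seg.ref_start + (seg.src_end - end)
                out.append((rs, rs + (end - start), seg.strand))
        return out

    def true_blocks(self) -> list[Segment]:
        """Maximal runs collinear in both genomes: consecutive segments
        adjacent on source and reference with equal strand are merged."""
        blocks: list[Segment] = []
        for seg in self.segments:
            if blocks:
                prev = blocks[-1]
                if (
                    prev.strand == seg.strand == 1
                    and prev.src_end == seg.src_start
                    and prev.ref_end == seg.ref_start
                ) or (
                    prev.strand == seg.strand == -1
                    and seg.src_end == prev.src_start
                    and prev.ref_end == seg.ref_start
                ):
                    src0 = min(prev.src_start, seg.src_start)
                    src1 = max(prev.src_end, seg.src_end)
                    blocks[-1] = Segment(src0, src1, seg.strand, prev.ref_start)
                    continue
            blocks.append(seg)
        return blocks


def simulate_rearranged_reference(
    genome: GenomeSim,
    events: Sequence[RearrangementEvent],
    seed: int = 0,
) -> RearrangedReference:
    """Apply inversions, translocations, and duplications (all specified in
    original-genome coordinates, non-overlapping on source) to produce a
    diverged reference whose segment map is the planted synteny truth."""
    L = genome.length
    for ev in events:
        if not (0 <= ev.start < ev.end <= L):
            raise ValueError(f"event interval [{ev.start},{ev.end}) out of bounds")
        if ev.dest is not None and not 0 <= ev.dest <= L:
            raise ValueError(f"event destination {ev.dest} out of bounds")
    ivs = sorted((ev.start, ev.end) for ev in events)
    for (a0, b0), (a1, b1) in zip(ivs, ivs[1:]):
        if a1 < b0:
            raise ValueError("events overlap on the source genome")
    for ev in events:
        if ev.dest is not None and any(
            e.start < ev.dest < e.end for e in events
        ):
            raise ValueError("event destination falls inside another event")

    cutpoints = {0, L}
    for ev in events:
        cutpoints.update((ev.start, ev.end))
        if ev.dest is not None:
            cutpoints.add(ev.dest)
    cuts = sorted(cutpoints)
    atoms = list(zip(cuts[:-1], cuts[1:]))  # (start, end) atomic intervals

    moved = {
        (ev.start, ev.end) for ev in events if ev.kind == "translocation"
    }
    inverted = {(ev.start, ev.end) for ev in events if ev.kind == "inversion"}
    inserts: dict[int, list[tuple[int, int, int]]] = {}
    for ev in events:
        if ev.kind in ("translocation", "duplication"):
            inserts.setdefault(ev.dest, []).append((ev.start, ev.end, +1))

    order: list[tuple[int, int, int]] = []
    for a, b in atoms:
        if a in inserts:
            order.extend(inserts[a])
        covered_moved = any(s <= a and b <= e for s, e in moved)
        if covered_moved:
            continue
        strand = -1 if any(s <= a and b <= e for s, e in inverted) else +1
        order.append((a, b, strand))
    if L in inserts:
        order.extend(inserts[L])

    # inverted intervals may have been cut into atoms by other breakpoints:
    # reverse the atom order within each inversion footprint
    final: list[tuple[int, int, int]] = []
    i = 0
    while i < len(order):
        a, b, strand = order[i]
        owner = next(
            ((s, e) for s, e in inverted if s <= a and b <= e), None
        )
        if owner is None:
            final.append((a, b, strand))
            i += 1
            continue
        j = i
        run = []
        while j < len(order):
            aa, bb, _ = order[j]
            if owner[0] <= aa and bb <= owner[1]:
                run.append(order[j])
                j += 1
            else:
                break
        final.extend(reversed(run))
        i = j

    segments: list[Segment] = []
    pieces: list[str] = []
    ref_pos = 0
    for a, b, strand in final:
        seq = genome.sequence[a:b]
        if strand < 0:
            seq = revcomp(seq)
        segments.append(Segment(a, b, strand, ref_pos))
        pieces.append(seq)
        ref_pos += b - a
    return RearrangedReference(
        sequence="".join(pieces), segments=segments, events=list(events)
    )


def simulate_bes_anchors(
    clones: Sequence[CloneRecord],
    reference: RearrangedReference,
    read_len: int = 600,
    seed: int = 0,
    identity_range: tuple[float, float] = (74.0, 100.0),
):
    """Paired BAC-end reads mapped onto the rearranged reference.

    Each clone contributes a left-end and a right-end read; an anchor is
    emitted for every reference placement of the read interval (duplicated
    regions yield multi-placement anchors, later removable by the repeat
    screen).  Reads spanning a rearrangement breakpoint are unmappable and
    yield no anchor.
    """
    from .synteny import BesAnchor

    rng = np.random.default_rng(seed)
    anchors: list[BesAnchor] = []
    for clone in clones:
        if read_len > clone.insert_size:
            raise ValueError(
                f"read_len {read_len} exceeds insert of {clone.clone_id}"
            )
        for tag, s in (
            ("L", clone.true_start),
            ("R", clone.true_end - read_len),
        ):
            for rs, re_, strand in reference.map_interval(s, s + read_len):
                anchors.append(
                    BesAnchor(
                        anchor_id=f"{clone.clone_id}_{tag}",
                        source=clone.clone_id,
                        source_pos=s,
                        ref_chrom=reference.name,
                        ref_start=rs,
                        ref_end=re_,
                        strand="+" if strand > 0 else "-",
                        percent_identity=float(
                            rng.uniform(*identity_range)
                        ),
                    )
                )
    return anchors
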