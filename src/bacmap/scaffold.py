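"""Pseudomolecule construction: CB->bp conversion, ordering and orienting
anchored contigs along their linkage groups, fixed inter-contig gaps, map
statistics, and CMAP/AGP export.

Contigs are sorted by the mean genetic (cM) position of their markers;
orientation is the sign of the rank correlation between marker CB position
and cM.  Consecutive contigs are separated by a fixed gap (default
0.25 Mbp) that is annotated but never counted in physical-map length
statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import spearmanr

from .anchoring import AnchoredContig
from .assembly import PhysicalMap

__all__ = [
    "CbBpModel",
    "Feature",
    "Pseudomolecule",
    "cb_to_bp_factor",
    "order_and_orient",
    "build_pseudomolecules",
    "genome_size_stats",
    "export_cmap",
    "export_agp",
]

GAP_BP_DEFAULT = 250_000


@dataclass(frozen=True)
class CbBpModel:
    """Conversion between consensus-band (CB) units and base pairs:
    bp per CB = average insert size / average bands per clone."""

    avg_insert_bp: float
    avg_bands_per_clone: float

    def __post_init__(self) -> None:
        if self.avg_insert_bp <= 0 or self.avg_bands_per_clone <= 0:
            raise ValueError("insert size and band count must be positive")

    @property
    def bp_per_cb(self) -> float:
        return self.avg_insert_bp / self.avg_bands_per_clone

    @property
    def bp_per_cb_rounded(self) -> int:
        """Reporting helper: bp/CB rounded to the nearest 10 bp."""
        return int(round(self.bp_per_cb / 10.0) * 10)

    def cb_to_bp(self, cb: float) -> int:
        return int(round(cb * self.bp_per_cb))


def cb_to_bp_factor(avg_insert_bp: float, avg_bands: float) -> CbBpModel:
    return CbBpModel(avg_insert_bp, avg_bands)


@dataclass(frozen=True)
class Feature:
    """One pseudomolecule feature; coordinates 0-based half-open
    internally, exported 1-based inclusive."""

    kind: str  # contig | gap | marker | STS
    name: str
    start_bp: int
    end_bp: int


@dataclass
class Pseudomolecule:
    name: str
    features: list[Feature]

    @property
    def length_bp(self) -> int:
        if not self.features:
            return 0
        return max(f.end_bp for f in self.features)

    def backbone(self) -> list[Feature]:
        return [f for f in self.features if f.kind in ("contig", "gap")]


def order_and_orient(
    anchored: Sequence[AnchoredContig],
) -> tuple[dict[str, list[AnchoredContig]], list[str]]:
    """Sort anchored contigs by mean marker cM within each linkage group
    and orient each by the sign of the Spearman correlation between marker
    CB position and cM (>=2 distinct markers required, else "unknown").

    Returns (ordered contigs per linkage group, excluded contig ids —
    those without any cM-bearing marker)."""
    per_lg: dict[str, list[AnchoredContig]] = {}
    excluded: list[str] = []
    for ctg in anchored:
        cms = [(cb, cm) for _, cb, cm in ctg.placements if cm is not None]
        if not cms:
            excluded.append(ctg.contig_id)
            continue
        orientation = "unknown"
        if len(cms) >= 2:
            cb = [c for c, _ in cms]
            cm = [m for _, m in cms]
            if len(set(cb)) > 1 and len(set(cm)) > 1:
                rho = spearmanr(cb, cm).statistic
                if rho > 0:
                    orientation = "+"
                elif rho < 0:
                    orientation = "-"
        oriented = AnchoredContig(
            contig_id=ctg.contig_id,
            linkage_group=ctg.linkage_group,
            placements=list(ctg.placements),
            length_cb=ctg.length_cb,
            conflict=ctg.conflict,
            orientation=orientation,
        )
        per_lg.setdefault(ctg.linkage_group, []).append(oriented)
    for lg in per_lg:
        per_lg[lg].sort(key=lambda c: (c.mean_cm, c.contig_id))
    return dict(sorted(per_lg.items())), sorted(excluded)


def build_pseudomolecules(
    ordered: Mapping[str, Sequence[AnchoredContig]],
    model: CbBpModel,
    gap_bp: int = GAP_BP_DEFAULT,
    sts: Mapping[str, Sequence[tuple[str, float]]] | None = None,
) -> list[Pseudomolecule]:
    """Concatenate each linkage group's ordered contigs with fixed gaps.

    Contig spans are ``length_cb * bp_per_cb``; markers (and optional STS
    per contig, given as (name, cb)) are placed at converted CB positions,
    mirrored within the contig when its orientation is "-".  Empty linkage
    groups are omitted.
    """
    out: list[Pseudomolecule] = []
    for lg, contigs in ordered.items():
        if not contigs:
            continue
        features: list[Feature] = []
        cursor = 0
        for i, ctg in enumerate(contigs):
            if i > 0:
                features.append(
                    Feature("gap", f"gap_{lg}_{i}", cursor, cursor + gap_bp)
                )
                cursor += gap_bp
            span = max(1, model.cb_to_bp(ctg.length_cb))
            features.append(
                Feature("contig", ctg.contig_id, cursor, cursor + span)
            )

            def place(cb: float) -> int:
                if ctg.orientation == "-":
                    cb = ctg.length_cb - cb
                pos = cursor + model.cb_to_bp(cb)
                return min(max(pos, cursor), cursor + span)

            for marker_id, cb, _cm in ctg.placements:
                pos = place(cb)
                features.append(Feature("marker", marker_id, pos, pos))
            for name, cb in (sts or {}).get(ctg.contig_id, ()):
                pos = place(cb)
                features.append(Feature("STS", name, pos, pos))
            cursor += span
        features.sort(key=lambda f: (f.start_bp, f.kind, f.name))
        out.append(Pseudomolecule(name=lg, features=features))
    return out


def genome_size_stats(
    pmap: PhysicalMap,
    anchored_ids: Iterable[str],
    model: CbBpModel,
    include_gaps: bool = False,
    gap_bp: int = GAP_BP_DEFAULT,
    lg_of: Mapping[str, str] | None = None,
) -> dict:
    """Physical-map genome-size accounting in Mbp.

    Genome size = anchored + unanchored contig lengths (each component
    rounded to one decimal, then summed); gap padding is excluded unless
    ``include_gaps`` is set, in which case 0.25 Mbp per internal adjacency
    (requires ``lg_of`` to count adjacencies per linkage group) is added to
    the anchored span.
    """
    anchored_ids = set(anchored_ids)
    anch_bp = sum(
        model.cb_to_bp(c.length_cb)
        for cid, c in pmap.contigs.items()
        if cid in anchored_ids
    )
    unanch_bp = sum(
        model.cb_to_bp(c.length_cb)
        for cid, c in pmap.contigs.items()
        if cid not in anchored_ids
    )
    if include_gaps:
        if lg_of is None:
            raise ValueError("include_gaps requires lg_of to count adjacencies")
        per_lg: dict[str, int] = {}
        for cid in anchored_ids:
            if cid in lg_of:
                per_lg[lg_of[cid]] = per_lg.get(lg_of[cid], 0) + 1
        anch_bp += gap_bp * sum(max(0, n - 1) for n in per_lg.values())
    anchored_mbp = round(anch_bp / 1e6, 1)
    unanchored_mbp = round(unanch_bp / 1e6, 1)
    genome_mbp = round(anchored_mbp + unanchored_mbp, 1)
    pct = round(100.0 * anchored_mbp / genome_mbp, 1) if genome_mbp else 0.0
    return {
        "anchored_mbp": anchored_mbp,
        "unanchored_mbp": unanchored_mbp,
        "genome_mbp": genome_mbp,
        "pct_anchored": pct,
        "n_anchored_contigs": len(anchored_ids & set(pmap.contigs)),
        "n_unanchored_contigs": len(set(pmap.contigs) - anchored_ids),
    }


def _check_backbone(ps: Pseudomolecule) -> None:
    backbone = sorted(ps.backbone(), key=lambda f: f.start_bp)
    for a, b in zip(backbone, backbone[1:]):
        if a.end_bp > b.start_bp:
            raise ValueError(
                f"{ps.name}: overlapping backbone features {a.name}/{b.name}"
            )


def export_cmap(pseudomolecules: Sequence[Pseudomolecule]) -> str:
    """CMAP-style tab file: map_name, feature_name, feature_type, start,
    stop — 1-based inclusive on export (point features: start == stop)."""
    lines = ["map_name\tfeature_name\tfeature_type\tstart_bp\tstop_bp"]
    for ps in pseudomolecules:
        _check_backbone(ps)
        for f in ps.features:
            if f.kind in ("marker", "STS"):
                start, stop = f.start_bp + 1, f.start_bp + 1
            else:
                start, stop = f.start_bp + 1, f.end_bp
            lines.append(f"{ps.name}\t{f.name}\t{f.kind}\t{start}\t{stop}")
    return "\n".join(lines) + "\n"


def export_agp(pseudomolecules: Sequence[Pseudomolecule]) -> str:
    """AGP v2: W lines for contigs, N lines for the fixed 250-kb gaps
    (gap_type "contig", linkage "no")."""
    lines = ["##agp-version\t2.0"]
    for ps in pseudomolecules:
        _check_backbone(ps)
        part = 0
        for f in sorted(ps.backbone(), key=lambda x: x.start_bp):
            part += 1
            beg, end = f.start_bp + 1, f.end_bp
            if f.kind == "contig":
                lines.append(
                    f"{ps.name}\t{beg}\t{end}\t{part}\tW\t{f.name}\t1\t"
                    f"{f.end_bp - f.start_bp}\t+"
                )
            else:
                lines.append(
                    f"{ps.name}\t{beg}\t{end}\t{part}\tN\t"
                    f"{f.end_bp - f.start_bp}\tcontig\tno\tna"
                )
    return "\n".join(lines) + "\n"
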