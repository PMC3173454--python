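"""Readers and writers for the toolkit's text formats.

Band files follow the FPC ".sizes" dialect (header ``clone_id band_count``
then one size per line); the project file is a documented subset of the
FPC dialect sufficient for round-tripping by this toolkit, not full FPC.
CMAP and AGP v2 exports are 1-based inclusive; all internal coordinates
are 0-based half-open.  Parsers are whitespace-tolerant and report the
offending line number on malformed input.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .anchoring import MarkerRecord
from .assembly import Contig, ContigMember, PhysicalMap
from .fingerprint import Fingerprint, ScoreParams
from .scaffold import Feature, Pseudomolecule
from .synteny import BesAnchor

__all__ = [
    "write_bands",
    "read_bands",
    "write_clone_table",
    "write_marker_table",
    "read_marker_table",
    "write_anchor_table",
    "read_anchor_table",
    "read_cmap",
    "read_agp",
    "write_fasta",
    "write_fpc",
]


class FormatError(ValueError):
    def __init__(self, path, lineno: int, message: str):
        super().__init__(f"{path}:{lineno}: {message}")
        self.lineno = lineno


def write_bands(fingerprints: Iterable[Fingerprint], path) -> None:
    """Write a band file: per clone a ``clone_id band_count`` header line
    followed by one band size (size-units) per line."""
    with open(path, "w") as fh:
        for fp in fingerprints:
            fh.write(f"{fp.clone_id} {fp.n_bands}\n")
            for b in fp.bands:
                fh.write(f"{b}\n")


def read_bands(path, library: str = "unknown") -> list[Fingerprint]:
    out: list[Fingerprint] = []
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        i += 1
        if not line:
            continue
        parts = line.split()
        if len(parts) != 2:
            raise FormatError(path, i, "expected 'clone_id band_count' header")
        clone_id, count_s = parts
        try:
            count = int(count_s)
        except ValueError:
            raise FormatError(path, i, f"bad band count {count_s!r}") from None
        bands = []
        while len(bands) < count:
            if i >= len(lines):
                raise FormatError(path, i, f"{clone_id}: truncated band list")
            v = lines[i].strip()
            i += 1
            if not v:
                continue
            try:
                bands.append(int(v))
            except ValueError:
                raise FormatError(path, i, f"bad band size {v!r}") from None
        out.append(Fingerprint(clone_id, library, tuple(sorted(bands))))
    return out


def write_clone_table(clones, path) -> None:
    pd.DataFrame(
        [
            {
                "clone_id": c.clone_id,
                "library": c.library,
                "true_start_bp": c.true_start,
                "true_end_bp": c.true_end,
                "insert_size_bp": c.insert_size,
            }
            for c in clones
        ]
    ).to_csv(path, sep="\t", index=False)


def write_marker_table(markers: Iterable[MarkerRecord], path) -> None:
    pd.DataFrame(
        [
            {
                "marker_id": m.marker_id,
                "class": m.marker_class,
                "linkage_group": m.linkage_group if m.linkage_group else "",
                "cm_position": "" if m.cm_position is None else m.cm_position,
                "truth_position_bp": (
                    "" if m.truth_position is None else m.truth_position
                ),
            }
            for m in markers
        ]
    ).to_csv(path, sep="\t", index=False)


def read_marker_table(path) -> list[MarkerRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    out = []
    for _, row in df.iterrows():
        out.append(
            MarkerRecord(
                marker_id=row["marker_id"],
                marker_class=row.get("class", "SSR") or "SSR",
                linkage_group=row["linkage_group"] or None,
                cm_position=(
                    float(row["cm_position"]) if row["cm_position"] else None
                ),
                truth_position=(
                    int(float(row["truth_position_bp"]))
                    if row.get("truth_position_bp", "")
                    else None
                ),
            )
        )
    return out


ANCHOR_COLUMNS = [
    "anchor_id",
    "source",
    "source_pos_bp",
    "ref_chrom",
    "ref_start_bp",
    "ref_end_bp",
    "strand",
    "percent_identity",
]


def write_anchor_table(anchors: Iterable[BesAnchor], path) -> None:
    pd.DataFrame(
        [
            {
                "anchor_id": a.anchor_id,
                "source": a.source,
                "source_pos_bp": a.source_pos,
                "ref_chrom": a.ref_chrom,
                "ref_start_bp": a.ref_start,
                "ref_end_bp": a.ref_end,
                "strand": a.strand,
                "percent_identity": round(a.percent_identity, 2),
            }
            for a in anchors
        ],
        columns=ANCHOR_COLUMNS,
    ).to_csv(path, sep="\t", index=False)


def read_anchor_table(path) -> list[BesAnchor]:
    df = pd.read_csv(path, sep="\t")
    missing = set(ANCHOR_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(path, 1, f"missing columns: {sorted(missing)}")
    return [
        BesAnchor(
            anchor_id=str(r.anchor_id),
            source=str(r.source),
            source_pos=float(r.source_pos_bp),
            ref_chrom=str(r.ref_chrom),
            ref_start=int(r.ref_start_bp),
            ref_end=int(r.ref_end_bp),
            strand=str(r.strand),
            percent_identity=float(r.percent_identity),
        )
        for r in df.itertuples()
    ]


def read_cmap(path) -> list[Pseudomolecule]:
    """Parse a CMAP tab file back into pseudomolecules (0-based
    half-open internally)."""
    maps: dict[str, list[Feature]] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("map_name"):
            raise FormatError(path, 1, "missing CMAP header line")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 5:
                raise FormatError(path, lineno, "expected 5 tab-separated fields")
            name, feat, kind, start_s, stop_s = (p.strip() for p in parts)
            try:
                start, stop = int(start_s), int(stop_s)
            except ValueError:
                raise FormatError(path, lineno, "bad coordinates") from None
            if kind in ("marker", "STS"):
                f = Feature(kind, feat, start - 1, start - 1)
            else:
                f = Feature(kind, feat, start - 1, stop)
            maps.setdefault(name, []).append(f)
    return [Pseudomolecule(name, feats) for name, feats in maps.items()]


def read_agp(path) -> list[Pseudomolecule]:
    """Parse AGP v2 back into backbone-only pseudomolecules."""
    maps: dict[str, list[Feature]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 8:
                raise FormatError(path, lineno, "expected >=8 AGP fields")
            obj, beg, end, _part, ctype = parts[:5]
            try:
                start, stop = int(beg) - 1, int(end)
            except ValueError:
                raise FormatError(path, lineno, "bad coordinates") from None
            if ctype == "W":
                f = Feature("contig", parts[5], start, stop)
            elif ctype in ("N", "U"):
                f = Feature("gap", f"gap_{obj}_{lineno}", start, stop)
            else:
                raise FormatError(path, lineno, f"unsupported component {ctype!r}")
            maps.setdefault(obj, []).append(f)
    return [Pseudomolecule(name, feats) for name, feats in maps.items()]


def write_fasta(records: Mapping[str, str], path) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    SeqIO.write(
        [SeqRecord(Seq(seq), id=name, description="") for name, seq in records.items()],
        path,
        "fasta",
    )


def write_fpc(
    pmap: PhysicalMap,
    path,
    markers_by_contig: Mapping[str, Sequence[tuple[str, float]]] | None = None,
) -> None:
    """Write a minimal FPC-dialect project file: contig records with clone
    placements in CB units plus optional marker lines.  A documented
    subset of the FPC format, sufficient for round-trip by this toolkit."""
    with open(path, "w") as fh:
        fh.write("// bacmap minimal FPC-dialect project (CB units)\n")
        fh.write(f"// cutoff 1e{pmap.params.log10_cutoff:.0f} "
                 f"tolerance {pmap.params.tolerance} gellen {pmap.params.gellen}\n")
        for cid in sorted(pmap.contigs):
            contig = pmap.contigs[cid]
            fh.write(f"Ctg {cid} {len(contig.members)} {contig.length_cb}\n")
            for m in contig.members:
                q = " Q" if m.q_flag else ""
                fh.write(f"BAC {m.clone_id} Map {cid} Ends {m.left_cb} "
                         f"{m.right_cb}{q}\n")
            for marker_id, cb in (markers_by_contig or {}).get(cid, ()):
                fh.write(f"Marker {marker_id} Map {cid} {cb:.1f}\n")
        for s in pmap.singletons:
            fh.write(f"Single {s}\n")


def read_fpc(path) -> tuple[dict[str, list[tuple[str, int, int, bool]]], list[str]]:
    """Read the minimal FPC dialect back: contig -> clone placements
    (clone, left_cb, right_cb, q_flag), plus singletons."""
    contigs: dict[str, list[tuple[str, int, int, bool]]] = {}
    singles: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("//"):
                continue
            parts = line.split()
            if parts[0] == "Ctg":
                contigs.setdefault(parts[1], [])
            elif parts[0] == "BAC":
                if len(parts) < 7:
                    raise FormatError(path, lineno, "short BAC line")
                contigs.setdefault(parts[3], []).append(
                    (parts[1], int(parts[5]), int(parts[6]), "Q" in parts[7:])
                )
            elif parts[0] == "Marker":
                continue
            elif parts[0] == "Single":
                singles.append(parts[1])
            else:
                raise FormatError(path, lineno, f"unknown record {parts[0]!r}")
    return contigs, singles
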