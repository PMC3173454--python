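"""End-to-end orchestration: simulate -> QC -> assemble -> anchor ->
scaffold -> MTP -> synteny, writing every artifact into a run directory.

The pipeline is fully seeded: an identical configuration and seed produce
byte-identical outputs.  Each stage writes its own files and never mutates
a previous stage's artifacts.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as bio
from .anchoring import (
    MarkerRecord,
    anchor_contigs,
    deconvolve,
    design_3d_pools,
    screen_probes,
    simulate_hit_matrix,
)
from .assembly import (
    PhysicalMap,
    ScoreCache,
    build_contigs,
    contig_summary,
    dqer,
    relaxed_merge,
)
from .fingerprint import ScoreParams, qc_filter
from .mtp import cb_spacing, select_mtp
from .scaffold import (
    build_pseudomolecules,
    cb_to_bp_factor,
    export_agp,
    export_cmap,
    genome_size_stats,
    order_and_orient,
)
from .simulate import (
    RearrangementEvent,
    default_hicf_spec,
    default_library_specs,
    fingerprint_library,
    simulate_bac_library,
    simulate_bes_anchors,
    simulate_genome,
    simulate_marker_truth,
    simulate_rearranged_reference,
)
from .synteny import block_stats, chain_anchors, filter_repeats, predict_linkage_groups

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass
class PipelineConfig:
    """All pipeline knobs with study-scale defaults: a 2-Mbp genome, three
    10x libraries, stringent 1e-80 build refined to 1e-50/1e-25, 0.25-Mbp
    pseudomolecule gaps, and 8-kb MTP anchor spacing."""

    seed: int = 1
    genome_length: int = 2_000_000
    gc: float = 0.5
    coverage: float = 10.0
    n_ssr_markers: int = 10
    n_cosii_markers: int = 2
    n_linkage_groups: int = 1
    bp_per_cm: float = 50_000.0
    tolerance: int = 3
    gellen: int = 5650
    build_cutoff: float = 1e-80
    merge_cutoff: float = 1e-50
    evidence_floor: float = 1e-25
    band_min: int = 20
    band_max: int = 220
    q_threshold: float = 0.10
    pool_dims: tuple[int, int, int] = (5, 5, 5)
    gap_bp: int = 250_000
    mtp_k_bp: float = 8_000.0
    bes_read_len: int = 600
    # chain gap must sit between the anchor spacing (~8 kb) and the scale
    # of the rearrangements to be resolved (~100 kb at a 2-Mbp genome)
    synteny_max_gap_bp: float = 50_000.0
    synteny_min_anchors: int = 3
    marker_table: str | None = None  # external table overrides simulation
    anchoring_enabled: bool = True

    def validate(self) -> None:
        if self.genome_length < 10_000:
            raise ValueError("genome_length must be >= 10 kb")
        if self.anchoring_enabled and self.marker_table is None and (
            self.n_ssr_markers <= 0
        ):
            raise ValueError(
                "anchoring enabled but no marker table and no simulated markers"
            )
        if self.marker_table is not None and not Path(self.marker_table).exists():
            raise ValueError(f"marker table {self.marker_table} not found")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "pool_dims" in data:
            data["pool_dims"] = tuple(data["pool_dims"])
        return cls(**data)

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["pool_dims"] = list(self.pool_dims)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


@dataclass
class PipelineResult:
    config: PipelineConfig
    genome: object
    clones: list
    fingerprints: list
    kept_fingerprints: list
    cache: ScoreCache
    pmap: PhysicalMap
    markers: list[MarkerRecord]
    marker_truth: dict
    probe_clones: dict
    anchored: list
    unanchored: list
    anchor_report: dict
    ordered: dict
    pseudomolecules: list
    model: object
    stats: dict
    mtp_selection: object
    mtp_n: int
    reference: object
    anchors: list
    blocks: list
    synteny_stats: dict
    lg_predictions: dict
    run_dir: Path | None


def _make_markers(cfg: PipelineConfig, rng: np.random.Generator) -> list[MarkerRecord]:
    """Simulated marker panel: SSRs with linkage group and cM from their
    genome position (linkage groups are equal windows of the genome), plus
    COSII markers carrying no genetic position."""
    L = cfg.genome_length
    window = L / cfg.n_linkage_groups
    n = cfg.n_ssr_markers + cfg.n_cosii_markers
    # evenly spaced with jitter: keeps probe spacing above the insert size
    # so few clones carry two probes (the pooled design assumes this)
    grid = (np.arange(n) + 0.5) * (L / n)
    jitter = rng.uniform(-0.1, 0.1, size=n) * (L / n)
    positions = np.sort(np.clip(grid + jitter, 1000, L - 1001).astype(int))
    which_cos = set(
        rng.choice(
            len(positions), size=cfg.n_cosii_markers, replace=False
        ).tolist()
    )
    markers = []
    for i, pos in enumerate(positions):
        pos = int(pos)
        if i in which_cos:
            markers.append(
                MarkerRecord(
                    marker_id=f"COS{i:03d}",
                    marker_class="COSII",
                    truth_position=pos,
                )
            )
        else:
            lg_i = min(int(pos // window), cfg.n_linkage_groups - 1)
            cm = (pos - lg_i * window) / cfg.bp_per_cm
            markers.append(
                MarkerRecord(
                    marker_id=f"SSR{i:03d}",
                    marker_class="SSR",
                    linkage_group=f"LG{lg_i + 1}",
                    cm_position=round(float(cm), 3),
                    truth_position=pos,
                )
            )
    return markers


def _default_events(L: int) -> list[RearrangementEvent]:
    return [
        RearrangementEvent("inversion", int(0.30 * L), int(0.36 * L)),
        RearrangementEvent(
            "translocation", int(0.60 * L), int(0.64 * L), dest=int(0.10 * L)
        ),
        RearrangementEvent(
            "duplication", int(0.80 * L), int(0.82 * L), dest=int(0.50 * L)
        ),
    ]


def run_pipeline(
    cfg: PipelineConfig, run_dir: str | Path | None = None
) -> PipelineResult:
    """Execute every stage on a simulated genome and (optionally) write
    all artifacts plus a provenance log into ``run_dir``."""
    cfg.validate()
    out = Path(run_dir) if run_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    log: list[str] = [f"seed {cfg.seed}", f"genome {cfg.genome_length} bp"]

    # --- simulate ---------------------------------------------------------
    genome = simulate_genome(cfg.genome_length, cfg.gc, seed=cfg.seed)
    lib_specs = default_library_specs(cfg.genome_length, cfg.coverage)
    clones = []
    for k, spec in enumerate(lib_specs):
        clones.extend(simulate_bac_library(genome, spec, seed=cfg.seed * 1000 + k))
    hicf = default_hicf_spec()
    fingerprints = fingerprint_library(clones, genome, hicf, seed=cfg.seed + 7)
    log.append(f"{len(clones)} clones from {len(lib_specs)} libraries")

    # --- QC ---------------------------------------------------------------
    kept, removed = qc_filter(fingerprints, cfg.band_min, cfg.band_max)
    log.append(f"QC kept {len(kept)} / removed {len(removed)}")

    # --- assemble ---------------------------------------------------------
    params = ScoreParams(cfg.tolerance, cfg.gellen, cfg.build_cutoff)
    cache = ScoreCache(kept, params)
    pmap = build_contigs(kept, params, cache)
    pmap = dqer(pmap, cache, q_threshold=cfg.q_threshold)
    pmap = relaxed_merge(pmap, cache, cfg.merge_cutoff, "singles_to_ends")
    pmap = relaxed_merge(pmap, cache, cfg.merge_cutoff, "ends_to_ends")
    log.extend(pmap.log)

    # --- anchor -----------------------------------------------------------
    rng = np.random.default_rng(cfg.seed + 11)
    if cfg.marker_table is not None:
        markers = bio.read_marker_table(cfg.marker_table)
    else:
        markers = _make_markers(cfg, rng)
    marker_truth = simulate_marker_truth(genome, markers, clones)
    probe_ids = [m.marker_id for m in markers]
    capacity = int(np.prod(cfg.pool_dims))
    probe_clones: dict[str, list[str]] = {}
    n_amb = 0
    for start in range(0, len(probe_ids), capacity):
        cube = probe_ids[start : start + capacity]
        design = design_3d_pools(cube, cfg.pool_dims)
        hits = simulate_hit_matrix(
            design, marker_truth, [c.clone_id for c in clones], seed=cfg.seed + 13
        )
        result = deconvolve(design, hits)
        for probe, hit_clones in result.probe_hits.items():
            probe_clones.setdefault(probe, []).extend(hit_clones)
        n_amb += result.status_counts().get("ambiguous", 0)
    # repetitive-probe screen counts distinct map locations (contigs, or a
    # singleton clone as its own location), not raw clone hits
    contig_of = pmap.contig_of()
    hit_counts = {
        p: len({contig_of.get(c, c) for c in set(probe_clones.get(p, ()))})
        for p in probe_ids
    }
    kept_probes, masked = screen_probes(hit_counts, max_hits=8)
    probe_clones = {p: sorted(set(probe_clones[p])) for p in kept_probes
                    if p in probe_clones}
    anchored, unanchored, report = anchor_contigs(pmap, probe_clones, markers)
    report["ambiguous_clones"] = n_amb
    report["masked_probes"] = sorted(masked)
    log.append(
        f"anchoring: {len(anchored)} anchored, {len(unanchored)} unanchored, "
        f"{len(masked)} probes masked"
    )

    # --- evidence merge and re-anchor ------------------------------------
    evidence = {
        a.contig_id: [
            (a.linkage_group, cm)
            for _, _, cm in a.placements
            if cm is not None
        ]
        for a in anchored
    }
    pmap = relaxed_merge(
        pmap, cache, cfg.merge_cutoff, "evidence",
        evidence=evidence, floor=cfg.evidence_floor,
    )
    anchored, unanchored, report2 = anchor_contigs(pmap, probe_clones, markers)
    report["post_evidence"] = {
        k: v for k, v in report2.items() if k != "cosii_inherited_lg"
    }
    if pmap.log and "evidence" in pmap.log[-1]:
        log.append(pmap.log[-1])

    # --- scaffold ---------------------------------------------------------
    spans = [m.span_cb for c in pmap.contigs.values() for m in c.members]
    avg_bands = float(np.mean(spans)) if spans else 1.0
    avg_insert = float(np.mean([c.insert_size for c in clones]))
    model = cb_to_bp_factor(avg_insert, avg_bands)
    ordered, excluded = order_and_orient(anchored)
    pseudomolecules = build_pseudomolecules(ordered, model, cfg.gap_bp)
    lg_of = {a.contig_id: a.linkage_group for a in anchored}
    stats = genome_size_stats(pmap, [a.contig_id for a in anchored], model)
    stats["bp_per_cb"] = round(model.bp_per_cb, 1)
    stats["bp_per_cb_rounded"] = model.bp_per_cb_rounded

    # --- MTP --------------------------------------------------------------
    median_cb = float(np.median(spans)) if spans else 1.0
    n_cb = cb_spacing(median_cb, avg_insert, cfg.mtp_k_bp)
    selection = select_mtp(pmap, n_cb)
    log.append(
        f"MTP: n={n_cb} CB, {selection.n_clones} clones, "
        f"{selection.n_reactions} reactions"
    )

    # --- synteny ----------------------------------------------------------
    reference = simulate_rearranged_reference(
        genome, _default_events(cfg.genome_length), seed=cfg.seed
    )
    clone_by_id = {c.clone_id: c for c in clones}
    selected = [clone_by_id[c] for c in selection.clones]
    raw_anchors = simulate_bes_anchors(
        selected, reference, read_len=cfg.bes_read_len, seed=cfg.seed + 17
    )
    raw_anchors = filter_repeats(raw_anchors, max_hits=8)
    # re-express anchors on contig coordinates (CB converted to bp)
    contig_of = pmap.contig_of()
    member_of = {
        mb.clone_id: mb for c in pmap.contigs.values() for mb in c.members
    }
    anchors = []
    for a in raw_anchors:
        cid = contig_of.get(a.source)
        mb = member_of.get(a.source)
        if cid is None or mb is None:
            continue
        cb = mb.left_cb if a.anchor_id.endswith("_L") else mb.right_cb
        anchors.append(
            type(a)(
                anchor_id=a.anchor_id,
                source=cid,
                source_pos=float(model.cb_to_bp(cb)),
                ref_chrom=a.ref_chrom,
                ref_start=a.ref_start,
                ref_end=a.ref_end,
                strand=a.strand,
                percent_identity=a.percent_identity,
            )
        )
    anchored_ids = {a.contig_id for a in anchored}
    blocks = chain_anchors(
        [a for a in anchors if a.source in anchored_ids],
        cfg.synteny_max_gap_bp,
        cfg.synteny_min_anchors,
    )
    syn_stats = block_stats(blocks, {reference.name: reference.length})
    blocks_by_lg: dict[str, list] = {}
    for b in blocks:
        blocks_by_lg.setdefault(lg_of.get(b.source, "?"), []).append(b)
    un_anchor_map = {}
    for a in anchors:
        if a.source not in anchored_ids:
            un_anchor_map.setdefault(a.source, []).append(a)
    predictions = predict_linkage_groups(un_anchor_map, blocks_by_lg)
    log.append(
        f"synteny: {len(blocks)} blocks, coverage "
        f"{syn_stats['coverage']:.2f}"
    )

    result = PipelineResult(
        config=cfg, genome=genome, clones=clones, fingerprints=fingerprints,
        kept_fingerprints=kept, cache=cache, pmap=pmap, markers=markers,
        marker_truth=marker_truth, probe_clones=probe_clones,
        anchored=anchored, unanchored=unanchored, anchor_report=report,
        ordered=ordered, pseudomolecules=pseudomolecules, model=model,
        stats=stats, mtp_selection=selection, mtp_n=n_cb,
        reference=reference, anchors=anchors, blocks=blocks,
        synteny_stats=syn_stats, lg_predictions=predictions, run_dir=out,
    )
    if out is not None:
        _write_artifacts(result, log)
    return result


def _write_artifacts(res: PipelineResult, log: list[str]) -> None:
    out = res.run_dir
    cfg = res.config
    bio.write_fasta({"genome": res.genome.sequence}, out / "genome.fasta")
    bio.write_fasta({res.reference.name: res.reference.sequence},
                    out / "reference.fasta")
    bio.write_clone_table(res.clones, out / "clones.tsv")
    for lib in sorted({fp.library for fp in res.fingerprints}):
        bio.write_bands(
            [fp for fp in res.fingerprints if fp.library == lib],
            out / f"bands_{lib}.sizes",
        )
    bio.write_marker_table(res.markers, out / "markers.tsv")
    markers_by_contig = {
        a.contig_id: [(m, cb) for m, cb, _ in a.placements] for a in res.anchored
    }
    bio.write_fpc(res.pmap, out / "map.fpc", markers_by_contig)
    summary = contig_summary(res.pmap)
    summary["table"].to_csv(out / "contigs.tsv", sep="\t", index=False)
    with open(out / "anchoring_report.json", "w") as fh:
        json.dump(res.anchor_report, fh, indent=1, default=str)
    (out / "pseudomolecules.cmap").write_text(export_cmap(res.pseudomolecules))
    (out / "pseudomolecules.agp").write_text(export_agp(res.pseudomolecules))
    pd.DataFrame([res.stats]).to_csv(out / "stats.tsv", sep="\t", index=False)
    rows = [
        {"contig": cid, "clone_id": c, "left_cb": l, "target_cb": t}
        for cid, sel in sorted(res.mtp_selection.per_contig.items())
        for c, l, t in sel
    ]
    pd.DataFrame(rows, columns=["contig", "clone_id", "left_cb", "target_cb"]).to_csv(
        out / "mtp_selection.tsv", sep="\t", index=False
    )
    with open(out / "mtp_summary.json", "w") as fh:
        json.dump(
            {
                "n_cb": res.mtp_n,
                "clones": res.mtp_selection.n_clones,
                "reactions": res.mtp_selection.n_reactions,
            },
            fh,
            indent=1,
        )
    bio.write_anchor_table(res.anchors, out / "bes_anchors.tsv")
    pd.DataFrame(
        [
            {
                "source": b.source,
                "source_start_bp": b.source_start,
                "source_end_bp": b.source_end,
                "ref_chrom": b.ref_chrom,
                "ref_start_bp": b.ref_start,
                "ref_end_bp": b.ref_end,
                "n_anchors": b.n_anchors,
                "orientation": b.orientation,
            }
            for b in res.blocks
        ]
    ).to_csv(out / "synteny_blocks.tsv", sep="\t", index=False)
    with open(out / "synteny_report.json", "w") as fh:
        json.dump(res.synteny_stats, fh, indent=1)
    pd.DataFrame(
        [
            {"contig": c, "linkage_group": lg or "", "status": status,
             "support": n}
            for c, (lg, status, n) in sorted(res.lg_predictions.items())
        ],
        columns=["contig", "linkage_group", "status", "support"],
    ).to_csv(out / "lg_predictions.tsv", sep="\t", index=False)
    cfg.to_yaml(out / "config.yaml")
    (out / "run_log.txt").write_text("\n".join(log) + "\n")
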