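"""CB->bp conversion, contig ordering/orientation, pseudomolecule
construction, size statistics, and CMAP/AGP export."""

import pytest

from bacmap.anchoring import AnchoredContig
from bacmap.assembly import Contig, ContigMember, PhysicalMap
from bacmap.fingerprint import ScoreParams
from bacmap.scaffold import (
    CbBpModel,
    Pseudomolecule,
    build_pseudomolecules,
    cb_to_bp_factor,
    export_agp,
    export_cmap,
    genome_size_stats,
    order_and_orient,
)


class TestCbBpModel:
    def test_reporting_example(self):
        model = cb_to_bp_factor(138_000, 114.2)
        assert model.bp_per_cb == pytest.approx(1208.4, abs=0.05)
        assert model.bp_per_cb_rounded == 1210

    def test_rounding_to_nearest_ten(self):
        assert CbBpModel(1204, 1.0).bp_per_cb_rounded == 1200
        assert CbBpModel(1206, 1.0).bp_per_cb_rounded == 1210
        assert CbBpModel(1216, 1.0).bp_per_cb_rounded == 1220

    def test_conversion(self):
        model = CbBpModel(1000.0, 1.0)
        assert model.cb_to_bp(3.5) == 3500

    def test_validation(self):
        with pytest.raises(ValueError):
            CbBpModel(0, 5)
        with pytest.raises(ValueError):
            CbBpModel(5, 0)


def anchored(cid, lg, placements, length_cb=100):
    return AnchoredContig(
        contig_id=cid,
        linkage_group=lg,
        placements=placements,
        length_cb=length_cb,
    )


class TestOrderAndOrient:
    def test_sorted_by_mean_cm(self):
        contigs = [
            anchored("c40", "LG1", [("m1", 10.0, 40.0)]),
            anchored("c10", "LG1", [("m2", 10.0, 10.0)]),
            anchored("c25", "LG1", [("m3", 10.0, 25.0)]),
        ]
        ordered, excluded = order_and_orient(contigs)
        assert [c.contig_id for c in ordered["LG1"]] == ["c10", "c25", "c40"]
        assert excluded == []

    def test_orientation_signs(self):
        fwd = anchored("f", "LG1", [("a", 10.0, 5.0), ("b", 90.0, 15.0)])
        rev = anchored("r", "LG1", [("a", 10.0, 15.0), ("b", 90.0, 5.0)])
        one = anchored("s", "LG1", [("a", 10.0, 5.0)])
        ordered, _ = order_and_orient([fwd, rev, one])
        orient = {c.contig_id: c.orientation for c in ordered["LG1"]}
        assert orient == {"f": "+", "r": "-", "s": "unknown"}

    def test_no_cm_excluded(self):
        cos_only = anchored("x", "LG1", [("cos", 10.0, None)])
        ordered, excluded = order_and_orient([cos_only])
        assert ordered == {} and excluded == ["x"]


class TestPseudomolecules:
    def test_length_identity_and_gaps(self):
        model = CbBpModel(1000.0, 1.0)  # 1 kb per CB
        contigs = [
            anchored("c1", "LG1", [("m1", 10.0, 1.0)], length_cb=300),
            anchored("c2", "LG1", [("m2", 10.0, 2.0)], length_cb=500),
            anchored("c3", "LG1", [("m3", 10.0, 3.0)], length_cb=200),
        ]
        ordered, _ = order_and_orient(contigs)
        [ps] = build_pseudomolecules(ordered, model, gap_bp=250_000)
        spans = [300_000, 500_000, 200_000]
        assert ps.length_bp == sum(spans) + 250_000 * (len(spans) - 1)
        gaps = [f for f in ps.features if f.kind == "gap"]
        assert len(gaps) == 2
        assert all(f.end_bp - f.start_bp == 250_000 for f in gaps)

    def test_marker_mirrored_on_minus_contig(self):
        model = CbBpModel(1000.0, 1.0)
        rev = anchored(
            "r", "LG1", [("a", 10.0, 15.0), ("b", 90.0, 5.0)], length_cb=100
        )
        ordered, _ = order_and_orient([rev])
        [ps] = build_pseudomolecules(ordered, model)
        pos = {f.name: f.start_bp for f in ps.features if f.kind == "marker"}
        assert pos == {"a": 90_000, "b": 10_000}

    def test_empty_group_omitted(self):
        assert build_pseudomolecules({"LG9": []}, CbBpModel(1000.0, 1.0)) == []


def stats_map(anchored_cb, unanchored_cb):
    params = ScoreParams()
    contigs = {}
    k = 0
    for cb in anchored_cb + unanchored_cb:
        k += 1
        contigs[f"ctg{k}"] = Contig(
            f"ctg{k}", [ContigMember(f"c{k}", 0, cb)], -80.0
        )
    anchored_ids = [f"ctg{i + 1}" for i in range(len(anchored_cb))]
    return PhysicalMap(contigs, [], params), anchored_ids


class TestGenomeSizeStats:
    def test_component_rounding_example(self):
        # 307.2 Mbp anchored + 67.4 Mbp unanchored -> 374.6 Mbp, 82.0%
        model = CbBpModel(1000.0, 1.0)
        pmap, anchored_ids = stats_map([307_200], [67_400])
        s = genome_size_stats(pmap, anchored_ids, model)
        assert s["anchored_mbp"] == 307.2
        assert s["unanchored_mbp"] == 67.4
        assert s["genome_mbp"] == 374.6
        assert s["pct_anchored"] == 82.0

    def test_gaps_excluded_by_default(self):
        model = CbBpModel(1000.0, 1.0)
        pmap, anchored_ids = stats_map([100_000, 100_000], [])
        s = genome_size_stats(pmap, anchored_ids, model)
        assert s["genome_mbp"] == 200.0

    def test_gap_inclusion_arithmetic(self):
        # 70 contigs on one group: 69 gaps x 0.25 Mbp = 17.25 Mbp extra
        model = CbBpModel(1000.0, 1.0)
        pmap, anchored_ids = stats_map([1_000] * 70, [])
        lg_of = {cid: "LG1" for cid in anchored_ids}
        base = genome_size_stats(pmap, anchored_ids, model)
        with_gaps = genome_size_stats(
            pmap, anchored_ids, model, include_gaps=True, lg_of=lg_of
        )
        assert with_gaps["anchored_mbp"] - base["anchored_mbp"] == pytest.approx(
            17.25, abs=0.1
        )
        with pytest.raises(ValueError):
            genome_size_stats(pmap, anchored_ids, model, include_gaps=True)


class TestExports:
    def build(self):
        model = CbBpModel(1000.0, 1.0)
        contigs = [
            anchored("c1", "LG1", [("m1", 10.0, 1.0)], length_cb=300),
            anchored("c2", "LG1", [("m2", 20.0, 2.0)], length_cb=500),
        ]
        ordered, _ = order_and_orient(contigs)
        return build_pseudomolecules(ordered, model, gap_bp=250_000)

    def test_cmap_roundtrip_identity(self, tmp_path):
        from bacmap.io import read_cmap

        ps = self.build()
        text = export_cmap(ps)
        path = tmp_path / "x.cmap"
        path.write_text(text)
        assert export_cmap(read_cmap(path)) == text

    def test_agp_roundtrip_preserves_gap(self, tmp_path):
        from bacmap.io import read_agp

        ps = self.build()
        text = export_agp(ps)
        assert "\t250000\tcontig\tno\tna" in text
        path = tmp_path / "x.agp"
        path.write_text(text)
        back = read_agp(path)
        assert [f.end_bp - f.start_bp for f in back[0].backbone()] == [
            f.end_bp - f.start_bp for f in ps[0].backbone()
        ]

    def test_one_based_export(self):
        ps = self.build()
        first = export_agp(ps).splitlines()[1].split("\t")
        assert first[1] == "1"  # internal 0 exports as 1

    def test_overlapping_backbone_rejected(self):
        bad = Pseudomolecule(
            "LG1",
            [
                type(self.build()[0].features[0])("contig", "a", 0, 100),
                type(self.build()[0].features[0])("contig", "b", 50, 150),
            ],
        )
        with pytest.raises(ValueError):
            export_agp([bad])
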