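"""Synthetic genome / library / fingerprint / rearrangement generators,
checked against independent brute-force oracles on toy inputs."""

import numpy as np
import pytest

from bacmap.simulate import (
    ENZYMES,
    GenomeSim,
    HicfSpec,
    InfeasibleLibraryError,
    LibrarySpec,
    RearrangementEvent,
    default_hicf_spec,
    default_library_specs,
    fingerprint_library,
    hicf_fingerprint,
    revcomp,
    simulate_bac_library,
    simulate_bes_anchors,
    simulate_genome,
    simulate_marker_truth,
    simulate_rearranged_reference,
)


def naive_cut_sites(sequence, recognition, offset):
    """Brute-force oracle for cut-site discovery (overlap-aware)."""
    out = []
    for i in range(len(sequence) - len(recognition) + 1):
        if sequence[i : i + len(recognition)] == recognition:
            out.append(i + offset)
    return out


class TestGenome:
    def test_deterministic(self):
        g1 = simulate_genome(10_000, seed=42, enzymes=())
        g2 = simulate_genome(10_000, seed=42, enzymes=())
        g3 = simulate_genome(10_000, seed=43, enzymes=())
        assert g1.sequence == g2.sequence
        assert g1.sequence != g3.sequence

    def test_validation(self):
        with pytest.raises(ValueError):
            simulate_genome(5_000)
        with pytest.raises(ValueError):
            simulate_genome(10_000, gc=0.0)
        with pytest.raises(ValueError):
            simulate_genome(10_000, gc=1.0)

    def test_gc_content_binomial(self):
        # observed GC fraction within 4 SD of the binomial expectation
        n, gc = 100_000, 0.37
        g = simulate_genome(n, gc=gc, seed=7, enzymes=())
        obs = sum(g.sequence.count(b) for b in "GC") / n
        sd = np.sqrt(gc * (1 - gc) / n)
        assert abs(obs - gc) < 4 * sd

    def test_cut_sites_match_bruteforce(self):
        g = simulate_genome(20_000, seed=9, enzymes=())
        for enz, (rec, off) in ENZYMES.items():
            expected = naive_cut_sites(g.sequence, rec, off)
            assert g.sites(enz).tolist() == expected

    def test_overlapping_sites_found(self):
        # GGCCGGCC: HaeIII GGCC at 0 and 4, cuts at 2 and 6
        g = GenomeSim(sequence="TTTGGCCGGCCTTT", seed=0)
        assert g.sites("HaeIII").tolist() == [5, 9]


class TestLibrary:
    def test_clone_ends_on_cut_sites(self):
        g = simulate_genome(500_000, seed=1)
        spec = LibrarySpec("L", "HindIII", 30, 90_000, 185_000, 145_000.0)
        clones = simulate_bac_library(g, spec, seed=2)
        sites = set(g.sites("HindIII").tolist())
        assert len(clones) == 30
        for c in clones:
            assert c.true_start in sites and c.true_end in sites
            assert spec.insert_min <= c.insert_size <= spec.insert_max

    def test_deterministic(self):
        g = simulate_genome(300_000, seed=1)
        spec = LibrarySpec("L", "MboI", 10, 80_000, 180_000)
        a = simulate_bac_library(g, spec, seed=5)
        b = simulate_bac_library(g, spec, seed=5)
        assert a == b

    def test_infeasible_library(self):
        g = GenomeSim(sequence="A" * 20_000, seed=0)
        spec = LibrarySpec("L", "HindIII", 5, 1_000, 5_000)
        with pytest.raises(InfeasibleLibraryError):
            simulate_bac_library(g, spec, seed=0)

    def test_coverage_oracle(self):
        g = simulate_genome(1_000_000, seed=3)
        specs = default_library_specs(1_000_000, coverage=5.0)
        for spec in specs:
            assert spec.nominal_coverage(1_000_000) == pytest.approx(
                spec.clone_count * spec.mean_insert / 1_000_000
            )
            clones = simulate_bac_library(g, spec, seed=4)
            realized = sum(c.insert_size for c in clones) / 1_000_000
            assert realized == pytest.approx(5.0, rel=0.15)

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            LibrarySpec("L", "HindIII", 5, 100, 100)
        with pytest.raises(ValueError):
            LibrarySpec("L", "NotAnEnzyme", 5, 100, 200)


class TestHicf:
    def test_single_site_toy(self):
        # one HaeIII site (GG^CC): insert [2, 12) cut at 7 -> fragments 5, 5
        g = GenomeSim(sequence="TT" + "TTTGG" + "CCTTT" + "AA" * 5_000, seed=0)
        clone = type("C", (), {})
        from bacmap.simulate import CloneRecord

        rec = CloneRecord("toy", "lib", 2, 12)
        spec = HicfSpec(
            enzymes=("HaeIII",),
            size_min_bp=1,
            size_max_bp=600,
            resolution_bp=1.0,
            noise_sd_units=0.0,
        )
        fp = hicf_fingerprint(rec, g, spec)
        assert fp.bands == (5, 5)

    def test_digestion_bruteforce_oracle(self):
        """Noise-free five-enzyme digest vs an independent fragment
        computation on a 10-kb toy clone."""
        g = simulate_genome(12_000, seed=21)
        from bacmap.simulate import CloneRecord, HICF_ENZYMES

        rec = CloneRecord("toy", "lib", 500, 10_500)
        spec = HicfSpec(resolution_bp=1.0, noise_sd_units=0.0)
        fp = hicf_fingerprint(rec, g, spec)
        cuts = {500, 10_500}
        for enz in HICF_ENZYMES:
            rcv, off = ENZYMES[enz]
            for pos in naive_cut_sites(g.sequence, rcv, off):
                if 500 < pos < 10_500:
                    cuts.add(pos)
        cuts = sorted(cuts)
        frags = [b - a for a, b in zip(cuts, cuts[1:])]
        expected = tuple(sorted(s for s in frags if 35 <= s <= 600))
        assert fp.bands == expected

    def test_labeling_restricts_detection(self):
        g = simulate_genome(200_000, seed=8)
        from bacmap.simulate import CloneRecord

        rec = CloneRecord("c", "lib", 10_000, 150_000)
        plain = hicf_fingerprint(rec, g, HicfSpec(noise_sd_units=0.0))
        labeled = hicf_fingerprint(rec, g, default_hicf_spec())
        assert 0 < labeled.n_bands < plain.n_bands

    def test_default_band_count_in_qc_window(self, pipe):
        counts = [fp.n_bands for fp in pipe.fingerprints]
        assert 80 < np.mean(counts) < 150
        kept = [n for n in counts if 20 <= n <= 220]
        assert len(kept) / len(counts) > 0.95

    def test_fingerprints_deterministic(self):
        g = simulate_genome(200_000, seed=8)
        spec = LibrarySpec("L", "HindIII", 5, 90_000, 185_000)
        clones = simulate_bac_library(g, spec, seed=2)
        a = fingerprint_library(clones, g, default_hicf_spec(), seed=3)
        b = fingerprint_library(clones, g, default_hicf_spec(), seed=3)
        assert a == b

    def test_bounds_validation(self):
        g = simulate_genome(20_000, seed=1)
        from bacmap.simulate import CloneRecord

        with pytest.raises(ValueError):
            hicf_fingerprint(CloneRecord("c", "l", 10, 30_000), g, HicfSpec())


class TestMarkerTruth:
    def test_containment(self):
        from bacmap.simulate import CloneRecord

        g = simulate_genome(50_000, seed=2, enzymes=())
        clones = [
            CloneRecord("c1", "l", 0, 10_000),
            CloneRecord("c2", "l", 5_000, 20_000),
        ]
        mk = type("M", (), {"marker_id": "m1", "truth_position": 7_000})()
        truth = simulate_marker_truth(g, [mk], clones)
        assert truth == {"m1": {"c1", "c2"}}
        mk2 = type("M", (), {"marker_id": "m2", "truth_position": 15_000})()
        assert simulate_marker_truth(g, [mk2], clones) == {"m2": {"c2"}}

    def test_out_of_range(self):
        g = simulate_genome(50_000, seed=2, enzymes=())
        mk = type("M", (), {"marker_id": "m", "truth_position": 90_000})()
        with pytest.raises(ValueError):
            simulate_marker_truth(g, [mk], [])


class TestRearrangement:
    def test_no_events_identity(self):
        g = simulate_genome(20_000, seed=4, enzymes=())
        ref = simulate_rearranged_reference(g, [])
        assert ref.sequence == g.sequence
        assert len(ref.segments) == 1
        assert ref.true_blocks()[0].src_end == 20_000

    def test_inversion_sequence(self):
        g = simulate_genome(20_000, seed=4, enzymes=())
        ev = RearrangementEvent("inversion", 5_000, 8_000)
        ref = simulate_rearranged_reference(g, [ev])
        assert ref.sequence[:5_000] == g.sequence[:5_000]
        assert ref.sequence[5_000:8_000] == revcomp(g.sequence[5_000:8_000])
        assert ref.sequence[8_000:] == g.sequence[8_000:]

    def test_map_interval(self):
        g = simulate_genome(20_000, seed=4, enzymes=())
        ev = RearrangementEvent("inversion", 5_000, 8_000)
        ref = simulate_rearranged_reference(g, [ev])
        # forward segment maps identically
        assert ref.map_interval(1_000, 1_100) == [(1_000, 1_100, 1)]
        # inside the inversion the interval is mirrored
        [(rs, re, strand)] = ref.map_interval(5_000, 5_100)
        assert strand == -1 and (rs, re) == (7_900, 8_000)
        # spanning the breakpoint: unmappable
        assert ref.map_interval(4_900, 5_100) == []

    def test_duplication_two_placements(self):
        g = simulate_genome(20_000, seed=4, enzymes=())
        ev = RearrangementEvent("duplication", 10_000, 11_000, dest=2_000)
        ref = simulate_rearranged_reference(g, [ev])
        assert ref.length == 21_000
        assert len(ref.map_interval(10_200, 10_300)) == 2

    def test_validation(self):
        g = simulate_genome(20_000, seed=4, enzymes=())
        with pytest.raises(ValueError):
            RearrangementEvent("inversion", 10, 10)
        with pytest.raises(ValueError):
            RearrangementEvent("translocation", 10, 20)
        with pytest.raises(ValueError):
            simulate_rearranged_reference(
                g,
                [
                    RearrangementEvent("inversion", 1_000, 5_000),
                    RearrangementEvent("inversion", 4_000, 9_000),
                ],
            )


class TestBesAnchors:
    def test_identity_reference(self):
        from bacmap.simulate import CloneRecord

        g = simulate_genome(50_000, seed=6, enzymes=())
        ref = simulate_rearranged_reference(g, [])
        clone = CloneRecord("c1", "l", 10_000, 40_000)
        anchors = simulate_bes_anchors([clone], ref, read_len=600, seed=0)
        assert len(anchors) == 2
        by_id = {a.anchor_id: a for a in anchors}
        assert by_id["c1_L"].ref_start == 10_000
        assert by_id["c1_R"].ref_start == 40_000 - 600
        assert all(a.strand == "+" for a in anchors)
        assert all(74.0 <= a.percent_identity <= 100.0 for a in anchors)

    def test_read_longer_than_insert(self):
        from bacmap.simulate import CloneRecord

        g = simulate_genome(50_000, seed=6, enzymes=())
        ref = simulate_rearranged_reference(g, [])
        with pytest.raises(ValueError):
            simulate_bes_anchors(
                [CloneRecord("c1", "l", 100, 500)], ref, read_len=600
            )
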