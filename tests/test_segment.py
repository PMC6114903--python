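"""Multi-SIT dissection, boundary selection, distances and pairwise identity."""

import pytest

from multisit.motifs import MotifHit
from multisit.segment import (
    DistanceRecord,
    NotSitLikeError,
    SegmentationConfig,
    boundary_positive,
    choose_boundary,
    cmld_dxdid_distances,
    distance_histogram,
    identity_similarity,
    map_reference_positions,
    segment_multi_sit,
)
from multisit.simulate import MultiSitSpec, ancestral_unit, make_multi_sit


def _hit(start, length=5):
    return MotifHit("DXDID", "x", start, start + length - 1, "D" * length)


class TestChooseBoundary:
    def test_closest_to_target_length_wins(self):
        cfg = SegmentationConfig(target_unit_length=441)
        chosen = choose_boundary([_hit(431), _hit(521)], cfg, upstream_unit_start=1)
        assert chosen.start == 431  # |430-441| < |520-441|

    def test_equidistant_candidates_break_leftmost(self):
        cfg = SegmentationConfig(target_unit_length=441)
        chosen = choose_boundary([_hit(437), _hit(447)], cfg, upstream_unit_start=1)
        assert chosen.start == 437

    def test_empty_candidates_rejected(self):
        with pytest.raises(ValueError):
            choose_boundary([], SegmentationConfig())


class TestSegmentation:
    def test_triplicate_recovers_planted_envelopes(self, triplicate, reference_unit):
        _, protein, truth = triplicate
        units = segment_multi_sit(protein, SegmentationConfig(), reference=reference_unit)
        assert [(u.start, u.end) for u in units] == truth.unit_envelopes
        assert [u.ordinal for u in units] == ["A", "B", "C"]
        assert all(u.cmld_count == 1 for u in units)
        assert all(u.length_ok for u in units)
        assert all(u.gxq_count >= 4 for u in units)

    def test_single_unit_spans_whole_sequence(self):
        seq, _ = make_multi_sit(MultiSitSpec(n_units=1, seed=5))
        units = segment_multi_sit(seq, SegmentationConfig())
        assert len(units) == 1
        assert (units[0].raw_start, units[0].raw_end) == (1, len(seq))

    def test_no_anchor_raises_not_sit_like(self):
        with pytest.raises(NotSitLikeError, match="not a SIT-like"):
            segment_multi_sit("A" * 100, SegmentationConfig())

    def test_missing_boundary_falls_back_to_target_length(self):
        spec = MultiSitSpec(n_units=2, linker_motif="ESEIE", boundary_pattern="EXEIE", seed=6)
        seq, _ = make_multi_sit(spec)  # linkers carry no DXDID
        units = segment_multi_sit(seq, SegmentationConfig())
        assert len(units) == 2
        assert not units[0].boundary_motif_found
        assert units[0].raw_end - units[0].raw_start + 1 == 441

    def test_raw_segments_reconstitute_parent(self, triplicate):
        _, protein, _ = triplicate
        units = segment_multi_sit(protein, SegmentationConfig())
        rebuilt = "".join(protein[u.raw_start - 1 : u.raw_end] for u in units)
        assert rebuilt == protein

    def test_units_never_overlap(self, triplicate, reference_unit):
        _, protein, _ = triplicate
        units = segment_multi_sit(protein, SegmentationConfig(), reference=reference_unit)
        for a, b in zip(units, units[1:]):
            assert a.end < b.start

    def test_envelope_recovery_under_noise(self):
        """Planted envelopes recovered exactly at 5% substitution noise."""
        hits = 0
        for seed in range(20):
            spec = MultiSitSpec(seed=seed, mutation_rate=0.05)
            protein, truth = make_multi_sit(spec)
            units = segment_multi_sit(
                protein, SegmentationConfig(), reference=ancestral_unit(spec)
            )
            hits += [(u.start, u.end) for u in units] == truth.unit_envelopes
        assert hits >= 19


class TestDistances:
    def test_arithmetic(self):
        rec = DistanceRecord("x", "A", cmld_cys_pos=100, dxdid_first_pos=350)
        assert rec.distance == 250

    def test_planted_triplicate_distances(self, triplicate):
        _, protein, truth = triplicate
        records = cmld_dxdid_distances(protein, SegmentationConfig())
        # the last CMLD has no downstream boundary: n_units - 1 records
        assert len(records) == 2
        cmlds = truth.motif_positions["CMLD"]
        expected = [b - c for c, b in zip(cmlds, truth.boundary_positions)]
        assert [r.distance for r in records] == expected

    def test_anchor_after_last_boundary_dropped(self):
        seq = "AA" + "CMLD" + "A" * 10 + "DSDID" + "A" * 10 + "CMLD" + "AA"
        records = cmld_dxdid_distances(seq, SegmentationConfig())
        assert len(records) == 1 and records[0].unit_ordinal == "A"

    def test_histogram_bins(self):
        records = [DistanceRecord("x", "A", 0, d) for d in (370, 372, 376, 381)]
        table = distance_histogram(records, bin_width=5)
        assert table["count"].sum() == 4
        assert (table["bin_end"] - table["bin_start"] == 4).all()

    def test_synedra_distances_fall_in_narrow_band(self, triplicate):
        _, protein, _ = triplicate
        d = [r.distance for r in cmld_dxdid_distances(protein, SegmentationConfig())]
        assert max(d) - min(d) <= 15


class TestReferenceMapping:
    def test_identity_maps_to_self(self):
        m = map_reference_positions("QNHYSSAW", "QNHYSSAW", [1, 4, 8])
        assert m == {1: ("Q", 1, "Q"), 4: ("Y", 4, "Y"), 8: ("W", 8, "W")}

    def test_substituted_position_still_maps(self):
        m = map_reference_positions("QAHY", "QNHY", [1, 3])
        assert m[1] == ("Q", 1, "Q") and m[3] == ("H", 3, "H")

    def test_planted_conserved_set_recovered(self, triplicate, reference_unit):
        from multisit.simulate import UnitSpec

        _, protein, truth = triplicate
        units = segment_multi_sit(protein, SegmentationConfig(), reference=reference_unit)
        spec = UnitSpec()
        m = map_reference_positions(
            units[1].sequence, reference_unit, sorted(spec.conserved_positions)
        )
        for pos, res in spec.conserved_positions.items():
            assert m[pos][2] == res

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            map_reference_positions("", "QNHY", [1])


class TestIdentitySimilarity:
    def test_identical_sequences(self):
        assert identity_similarity("CMLDFIN", "CMLDFIN") == (100.0, 100.0)

    def test_single_substitution_no_gaps(self):
        ident, sim = identity_similarity("AAAA", "AAAT")
        assert ident == pytest.approx(75.0)

    def test_similarity_bounds_identity(self):
        pairs = [("CMLDFINAA", "CMLDYINAA"), ("WWWW", "FFFF"), ("AC", "GT")]
        for a, b in pairs:
            ident, sim = identity_similarity(a, b)
            assert sim >= ident

    def test_symmetry(self, default_unit, reference_unit):
        a = default_unit[0][:120]
        b = reference_unit[:110]
        assert identity_similarity(a, b) == pytest.approx(identity_similarity(b, a))


class TestBoundaryPositive:
    def test_triplicate_positive(self, triplicate):
        _, protein, _ = triplicate
        assert boundary_positive(protein)

    def test_single_unit_negative(self):
        seq, _ = make_multi_sit(MultiSitSpec(n_units=1, seed=4))
        assert not boundary_positive(seq)
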