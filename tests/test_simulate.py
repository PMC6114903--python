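"""Generator/scanner closure, noise-model properties and truth round-trips."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from multisit.motifs import degap, scan
from multisit.simulate import (
    AMINO_ACIDS,
    HYDROPHOBIC,
    ClusterSpec,
    MultiSitSpec,
    SpecError,
    UnitSpec,
    make_gene_cluster,
    make_mature_unit,
    make_multi_sit,
    make_multisit_panel,
    make_unit_alignment,
    mutate,
    read_truth,
    write_truth,
)


class TestMatureUnit:
    def test_default_unit_has_exactly_one_cmld(self, default_unit):
        seq, truth = default_unit
        assert len(seq) == 441
        hits = scan(seq, "CMLD")
        assert [h.start for h in hits] == truth.motif_positions["CMLD"]

    def test_short_unit_length_within_window(self):
        # a 436-residue unit: trim the C-terminal stretch by five residues
        tm = list(UnitSpec().tm_segments)
        tm[-1] = (tm[-1][0], tm[-1][1] - 5)
        seq, _ = make_mature_unit(UnitSpec(length=436, tm_segments=tuple(tm)), seed=1)
        assert 436 <= len(seq) <= 446

    def test_gxq_found_at_all_planted_offsets(self, default_unit):
        seq, truth = default_unit
        found = {h.start for h in scan(seq, "GXQ")}
        assert set(truth.motif_positions["GXQ"]) <= found

    def test_planted_yq_and_conserved_residues(self, default_unit):
        seq, truth = default_unit
        spec = UnitSpec()
        assert [h.start for h in scan(seq, "YQXDXVYL")] == [spec.yq_offset]
        for pos, res in spec.conserved_positions.items():
            assert seq[pos - 1] == res

    def test_tm_residues_come_from_hydrophobic_alphabet(self, default_unit):
        seq, truth = default_unit
        for s, e in truth.tm_segments[0]:
            assert set(seq[s - 1 : e]) <= set(HYDROPHOBIC)

    def test_overlapping_features_rejected_naming_both(self):
        spec = UnitSpec(cmld_offset=47)  # inside the second planted TM stretch
        with pytest.raises(SpecError, match="CMLD") as err:
            make_mature_unit(spec, seed=0)
        assert "TM2" in str(err.value)


class TestMultiSit:
    def test_triplicate_has_three_cmld(self, triplicate):
        _, protein, truth = triplicate
        assert len(scan(protein, "CMLD")) == 3
        assert len(truth.unit_envelopes) == 3

    def test_single_unit_degenerate_case(self):
        seq, truth = make_multi_sit(MultiSitSpec(n_units=1, seed=0))
        assert len(scan(seq, "CMLD")) == 1
        assert scan(seq, "DXDID") == []
        assert truth.boundary_positions == []

    def test_boundary_motifs_only_in_linkers(self, triplicate):
        _, protein, truth = triplicate
        assert [h.start for h in scan(protein, "DXDID")] == truth.boundary_positions

    def test_default_triplicate_length_matches_real_protein(self, triplicate):
        _, protein, _ = triplicate
        assert len(protein) == 1416

    def test_linker_too_short_rejected(self):
        with pytest.raises(SpecError, match="linker"):
            MultiSitSpec(linker_length=3).validate()

    def test_envelopes_disjoint_and_ordered(self, triplicate):
        _, _, truth = triplicate
        env = truth.unit_envelopes
        assert all(e1 < s2 for (_, e1), (s2, _) in zip(env, env[1:]))


class TestMutate:
    def test_rate_zero_is_identity(self):
        seq = "ACDEFGHIKLMNPQRSTVWY" * 5
        assert mutate(seq, 0.0, seed=1) == seq

    def test_fully_protected_sequence_untouched(self):
        seq = "ACDEFGHIKL" * 10
        assert mutate(seq, 0.5, seed=1, protected=[(1, len(seq))]) == seq

    def test_observed_rate_matches_binomial_expectation(self):
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list(AMINO_ACIDS), size=10000))
        out = mutate(seq, 0.1, seed=3)
        frac = sum(a != b for a, b in zip(seq, out)) / len(seq)
        assert abs(frac - 0.1) < 0.01

    def test_deterministic_per_seed(self):
        seq = "ACDEFGHIKL" * 20
        assert mutate(seq, 0.2, seed=9) == mutate(seq, 0.2, seed=9)
        assert mutate(seq, 0.2, seed=9) != mutate(seq, 0.2, seed=10)

    def test_rate_one_rejected(self):
        with pytest.raises(ValueError):
            mutate("ACDE", 1.0, seed=0)

    @settings(max_examples=10, deadline=None, derandomize=True)
    @given(rate=st.sampled_from([0.02, 0.05, 0.1]), seed=st.integers(0, 50))
    def test_pairwise_identity_of_two_mutated_copies(self, rate, seed):
        """Identity of two independently mutated copies ~ (1-r)^2 plus the
        chance both sites mutate to the same residue, within 3 s.d."""
        rng = np.random.default_rng(123)
        seq = "".join(rng.choice(list(AMINO_ACIDS), size=1000))
        a = mutate(seq, rate, seed=2 * seed + 1)
        b = mutate(seq, rate, seed=2 * seed + 2)
        ident = sum(x == y for x, y in zip(a, b)) / len(seq)
        p = (1 - rate) ** 2 + rate**2 / 19
        sd = (p * (1 - p) / len(seq)) ** 0.5
        assert abs(ident - p) <= 3 * sd


class TestGeneCluster:
    def test_spacer_length_round_trips_through_truth(self, gene_cluster):
        _, _, truth = gene_cluster
        assert truth.spacer_length == 5239
        g1, g2 = truth.gene_loci[0], truth.gene_loci[1]
        assert g2[1] - g1[2] - 1 == 5239

    def test_duplicate_genes_byte_identical(self, gene_cluster):
        _, contigs, truth = gene_cluster
        (_, s1, e1, _, _), (_, s2, e2, _, _) = truth.gene_loci[:2]
        assert contigs["cluster"][s1 - 1 : e1] == contigs["cluster"][s2 - 1 : e2]

    def test_zero_spacer_abuts_genes(self):
        contigs, truth = make_gene_cluster(
            ClusterSpec(spacer_length=0), MultiSitSpec(n_units=1, seed=3)
        )
        g1, g2 = truth.gene_loci[:2]
        assert g2[1] == g1[2] + 1

    def test_third_gene_diverged(self, gene_cluster):
        mspec, contigs, truth = gene_cluster
        from multisit.genes import paralog_identity

        (_, s1, e1, _, _) = truth.gene_loci[0]
        (_, s3, e3, _, _) = truth.gene_loci[2]
        ident, same = paralog_identity(
            contigs["cluster"][s1 - 1 : e1], contigs["paralog"][s3 - 1 : e3]
        )
        assert not same
        assert ident == pytest.approx(0.9, abs=0.03)


class TestTruthSerialization:
    def test_round_trip_lossless(self, tmp_path, triplicate):
        _, _, truth = triplicate
        path = tmp_path / "truth.tsv"
        write_truth(truth, path, record_id="tri")
        back = read_truth(path)
        assert back.unit_envelopes == truth.unit_envelopes
        assert back.boundary_positions == truth.boundary_positions
        assert back.tm_segments == truth.tm_segments
        assert {k: sorted(v) for k, v in back.motif_positions.items()} == {
            k: sorted(v) for k, v in truth.motif_positions.items()
        }

    def test_gene_truth_round_trip(self, tmp_path, gene_cluster):
        _, _, truth = gene_cluster
        path = tmp_path / "gtruth.tsv"
        write_truth(truth, path)
        back = read_truth(path)
        assert back.gene_loci == truth.gene_loci
        assert back.spacer_length == truth.spacer_length


class TestSyntheticAlignmentStandIns:
    def test_alignment_plants_cmld_free_rows_and_w_column(self):
        aln, info = make_unit_alignment(seed=11)
        assert len(aln) == 87
        from multisit.motifs import column_conservation, motif_presence

        _, absent = motif_presence(aln, "CMLD")
        assert sorted(absent) == info["cmld_absent"]
        col = column_conservation(aln).column(info["w_column"])
        assert col["consensus"] == "W" and col["absolutely_conserved"]

    def test_degapped_lengths_in_window(self):
        aln, info = make_unit_alignment(seed=11)
        lo, hi = info["length_window"]
        assert all(lo <= len(degap(s)) <= hi for s in aln.values())

    def test_panel_boundary_positive_count(self):
        panel, info = make_multisit_panel(seed=11)
        from multisit.segment import boundary_positive

        measured = {i for i, s in panel.items() if boundary_positive(s)}
        assert len(panel) == 48
        assert measured == set(info["boundary_positive"])
        assert len(measured) == 43
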