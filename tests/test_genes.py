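"""ORF finding, translation, cluster arithmetic and in-silico PCR."""

import itertools

import pytest

from multisit.genes import (
    Amplicon,
    GeneLocus,
    InternalStopError,
    find_orfs,
    in_silico_pcr,
    intergenic_distance,
    paralog_identity,
    reverse_complement,
    translate,
)
from multisit.primers import IUPAC_SETS, reverse_complement_iupac


class TestFindOrfs:
    def test_minimal_orf(self):
        loci = find_orfs("ATGAAATAA", min_length=3, both_strands=False)
        assert [(g.start, g.end, g.strand) for g in loci] == [(1, 9, "+")]

    def test_no_start_codon_no_orf(self):
        assert find_orfs("AAATTTCCCGGGTAA", min_length=3) == []

    def test_synthetic_cluster_yields_exactly_the_planted_genes(self, gene_cluster):
        _, contigs, truth = gene_cluster
        loci = find_orfs(
            contigs["cluster"], min_length=3000, both_strands=True, longest_per_stop=True
        )
        assert [(g.start, g.end, g.strand) for g in loci] == [
            (t[1], t[2], t[3]) for t in truth.gene_loci[:2]
        ]

    def test_reverse_complement_mirrors_plus_strand(self):
        dna = "CCATGAAACCCTAAGG"
        plus = find_orfs(dna, min_length=3, both_strands=False)
        mirrored = find_orfs(reverse_complement(dna), min_length=3, both_strands=True)
        minus = [g for g in mirrored if g.strand == "-"]
        n = len(dna)
        assert {(n - g.end + 1, n - g.start + 1) for g in minus} == {
            (g.start, g.end) for g in plus
        }

    def test_non_iupac_characters_rejected(self):
        with pytest.raises(ValueError):
            find_orfs("ATGXXXTAA", min_length=3)


class TestTranslate:
    def test_basic(self):
        assert translate("ATGGAA") == "ME"

    def test_terminal_stop_excluded(self):
        assert translate("ATGTAA") == "M"

    def test_internal_stop_strict_names_position(self):
        with pytest.raises(InternalStopError, match="residue 2"):
            translate("ATGTAAGAA")

    def test_minus_strand_orf_translates_consistently(self):
        dna = "ATGAAACCCGGGTAA"
        rc = reverse_complement(dna)
        # the ORF on rc's minus strand is dna itself
        assert translate(reverse_complement(rc)) == translate(dna)

    def test_triplicate_gene_protein_length(self, gene_cluster):
        _, contigs, truth = gene_cluster
        (_, s, e, _, _) = truth.gene_loci[0]
        assert len(translate(contigs["cluster"][s - 1 : e])) == 1416


class TestIntergenic:
    def test_separated_loci(self):
        a = GeneLocus("c", 1, 100, "+")
        b = GeneLocus("c", 201, 300, "+")
        assert intergenic_distance(a, b) == 100
        assert intergenic_distance(b, a) == 100

    def test_abutting_loci(self):
        assert intergenic_distance(GeneLocus("c", 1, 100, "+"), GeneLocus("c", 101, 200, "+")) == 0

    def test_overlap_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            intergenic_distance(GeneLocus("c", 1, 100, "+"), GeneLocus("c", 50, 200, "+"))

    def test_different_contigs_rejected(self):
        with pytest.raises(ValueError):
            intergenic_distance(GeneLocus("c1", 1, 10, "+"), GeneLocus("c2", 20, 30, "+"))

    def test_planted_spacer(self, gene_cluster):
        _, _, truth = gene_cluster
        (c1, s1, e1, st1, _), (c2, s2, e2, st2, _) = truth.gene_loci[:2]
        d = intergenic_distance(GeneLocus(c1, s1, e1, st1), GeneLocus(c2, s2, e2, st2))
        assert d == truth.spacer_length == 5239


class TestParalogIdentity:
    def test_equal_sequences(self):
        assert paralog_identity("ACGT" * 100, "ACGT" * 100) == (1.0, True)

    def test_single_substitution_in_thousand(self):
        a = "ACGT" * 250
        b = a[:500] + ("C" if a[500] != "C" else "G") + a[501:]
        ident, same = paralog_identity(a, b)
        assert not same
        assert ident == pytest.approx(0.999)

    def test_diverged_copy(self):
        from multisit.simulate import mutate

        a = "ACGT" * 500
        b = mutate(a, 0.1, seed=4)
        ident, same = paralog_identity(a, b)
        assert not same
        assert ident == pytest.approx(0.9, abs=0.02)


def _brute_force_pcr(template, fwd, rev, max_product):
    """Oracle: enumerate all (fwd site, rev site) pairs by direct set matching."""
    site_r = reverse_complement_iupac(rev)

    def sites(primer):
        out = []
        for i in range(len(template) - len(primer) + 1):
            if all(b in IUPAC_SETS[c] for c, b in zip(primer, template[i : i + len(primer)])):
                out.append(i)
        return out

    pairs = []
    for f, r in itertools.product(sites(fwd), sites(site_r)):
        if r >= f + len(fwd) and (r + len(site_r) - f) <= max_product:
            pairs.append((f + 1, r + len(site_r)))
    return sorted(pairs)


class TestInSilicoPcr:
    def test_exact_sites_give_one_amplicon(self):
        template = "G" * 100 + "ATGCATGCAT" + "T" * 980 + "AACCGGTTAA" + "G" * 100
        fwd, rev = "ATGCATGCAT", reverse_complement_iupac("AACCGGTTAA")
        amps = in_silico_pcr(template, fwd, rev, max_product=2000)
        assert len(amps) == 1
        a = amps[0]
        assert a.product_length == a.rev_site.end - a.fwd_site.start + 1 == 1000

    def test_missing_reverse_site_is_empty(self):
        template = "G" * 50 + "ATGCATGCAT" + "G" * 50
        assert in_silico_pcr(template, "ATGCATGCAT", "AAAAAAAAAA") == []

    def test_degenerate_code_matches_both_bases(self):
        for mid in "CT":
            template = "G" * 30 + f"TG{mid}ATGAAA" + "A" * 50 + "TTTTTCCCC" + "G" * 30
            amps = in_silico_pcr(template, "TGYATGAAA", reverse_complement_iupac("TTTTTCCCC"))
            assert len(amps) == 1

    def test_matches_brute_force_oracle_on_random_templates(self):
        import numpy as np

        rng = np.random.default_rng(7)
        fwd, rev = "TGYATG", "CATRTG"
        for _ in range(20):
            template = "".join(rng.choice(list("ACGT"), size=400))
            got = sorted(
                (a.fwd_site.start, a.rev_site.end)
                for a in in_silico_pcr(template, fwd, rev, max_product=400)
            )
            assert got == _brute_force_pcr(template, fwd, rev, 400)

    def test_three_prime_mismatch_blocks_amplification(self):
        core = "ATGCATGCAT"
        bad = core[:-1] + ("A" if core[-1] != "A" else "C")
        template = "G" * 20 + core + "A" * 100 + "AACCGGTTAA" + "G" * 20
        rev = reverse_complement_iupac("AACCGGTTAA")
        assert in_silico_pcr(template, core, rev, max_mismatch=1)
        assert in_silico_pcr(template, bad, rev, max_mismatch=1) == []
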