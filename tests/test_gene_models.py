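"""Structure handling: loading, exon assignment, windows, ESE, Fop."""

import pytest

from txrobust import gene_models as gm
from txrobust.metrics import CodonSequence

from conftest import ToyGene, make_cds


def load_single(factory, gene):
    fasta, gff3 = factory([gene])
    models = gm.load_annotation(fasta, gff3)
    assert len(models) == 1
    return models[0]


class TestLoadAnnotation:
    def test_three_exon_plus_strand(self, toy_genome_factory):
        cds = make_cds(30)  # 90 nt + TAA
        gene = ToyGene("gA", cds, [30, 31, 32])
        t = load_single(toy_genome_factory, gene)
        assert t.exon_count == 3
        assert t.strand == "+"
        # hand-spliced CDS equals loaded CDS
        assert "".join(t.codons.codons) + "TAA" == cds
        assert t.is_clean

    def test_minus_strand_identical_codons(self, toy_genome_factory):
        cds = make_cds(30)
        plus = load_single(toy_genome_factory, ToyGene("gA", cds, [30, 31, 32]))
        minus = load_single(
            toy_genome_factory, ToyGene("gA", cds, [30, 31, 32], strand="-")
        )
        assert plus.codons.codons == minus.codons.codons
        assert plus.codon_exon == minus.codon_exon
        assert plus.utr3_length == minus.utr3_length

    def test_internal_stop_flagged(self, toy_genome_factory):
        cds = "GCTTAAGAA" + "TAA"  # TAA at codon 1
        t = load_single(toy_genome_factory, ToyGene("gA", cds, [len(cds)]))
        assert gm.FLAG_INTERNAL_STOP in t.flags

    def test_missing_terminal_stop_flagged(self, toy_genome_factory):
        cds = "GCTGAAGGT"
        t = load_single(toy_genome_factory, ToyGene("gA", cds, [len(cds)]))
        assert gm.FLAG_NO_TERMINAL_STOP in t.flags

    def test_bad_length_flagged(self, toy_genome_factory):
        cds = "GCTGAAGG"
        t = load_single(toy_genome_factory, ToyGene("gA", cds, [len(cds)]))
        assert gm.FLAG_BAD_LENGTH in t.flags

    def test_utr3_length(self, toy_genome_factory):
        gene = ToyGene("gA", make_cds(30), [93], utr3="A" * 123)
        t = load_single(toy_genome_factory, gene)
        assert t.utr3_length == 123

    def test_validation_report(self, toy_genome_factory):
        fasta, gff3 = toy_genome_factory(
            [ToyGene("gA", make_cds(30), [93])]
        )
        report = gm.validation_report(gm.load_annotation(fasta, gff3))
        assert list(report["gene_id"]) == ["gA"]
        assert report["flags"].iloc[0] == ""


class TestRepresentativeSelection:
    def _two_transcript_models(self, len_a, len_b):
        a = _fake_model("g1", "t_b", len_a)
        b = _fake_model("g1", "t_a", len_b)
        return [a, b]

    def test_longest_peptide_wins(self):
        models = self._two_transcript_models(100, 250)
        assert gm.select_representative_transcript(models).peptide_length == 250

    def test_tie_breaks_by_id(self):
        models = self._two_transcript_models(100, 100)
        assert gm.select_representative_transcript(models).transcript_id == "t_a"

    def test_single_is_identity(self):
        m = _fake_model("g1", "t1", 50)
        assert gm.select_representative_transcript([m]) is m

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            gm.select_representative_transcript([])


def _fake_model(gene_id, transcript_id, n_codons):
    codons = tuple(["GCT"] * n_codons)
    return gm.TranscriptModel(
        gene_id=gene_id,
        transcript_id=transcript_id,
        chrom="chrT",
        strand="+",
        exons=((0, 3 * n_codons + 3),),
        cds_segments=((0, 3 * n_codons + 3, 0),),
        codons=CodonSequence(codons),
        codon_exon=tuple([0] * n_codons),
        nt_exon=tuple([0] * (3 * n_codons)),
        cds_nt="GCT" * n_codons + "TAA",
        utr3_length=0,
        flags=(),
    )


class TestExonCount:
    def test_counts_noncoding_exons(self, toy_genome_factory):
        gene = ToyGene(
            "gA", make_cds(60), [90, 93], extra_noncoding_exon=True,
            utr3="A" * 150,
        )
        t = load_single(toy_genome_factory, gene)
        assert gm.exon_count(t) == 3  # 2 coding + 1 non-coding

    def test_intronless(self, toy_genome_factory):
        t = load_single(toy_genome_factory, ToyGene("gA", make_cds(30), [93]))
        assert gm.exon_count(t) == 1


class TestReliability:
    def test_reliable(self, toy_genome_factory):
        t = load_single(
            toy_genome_factory,
            ToyGene("gA", make_cds(60), [90, 93], utr3="A" * 150),
        )
        assert gm.is_reliable_last_exon(t)

    def test_short_utr3(self, toy_genome_factory):
        t = load_single(
            toy_genome_factory,
            ToyGene("gA", make_cds(60), [90, 93], utr3="A" * 40),
        )
        assert not gm.is_reliable_last_exon(t)

    def test_downstream_noncoding_exon(self, toy_genome_factory):
        t = load_single(
            toy_genome_factory,
            ToyGene(
                "gA", make_cds(60), [90, 93], extra_noncoding_exon=True,
                utr3="A" * 150,
            ),
        )
        assert not gm.is_reliable_last_exon(t)

    def test_no_terminal_stop(self, toy_genome_factory):
        cds = make_cds(60)[:-3]  # drop the stop
        t = load_single(
            toy_genome_factory, ToyGene("gA", cds, [90, 90], utr3="A" * 150)
        )
        assert not gm.is_reliable_last_exon(t)


class TestCodonExonAssignment:
    @pytest.mark.parametrize("j1,expected_spanning", [(30, 0), (31, 1), (32, 1)])
    def test_junction_phases(self, toy_genome_factory, j1, expected_spanning):
        cds = make_cds(30)
        gene = ToyGene("gA", cds, [j1, 93 - j1])
        t = load_single(toy_genome_factory, gene)
        spanning = sum(1 for xi in t.codon_exon if xi is None)
        assert spanning == expected_spanning

    def test_assignment_partition(self, toy_genome_factory):
        cds = make_cds(30)
        gene = ToyGene("gA", cds, [30, 31, 32])
        t = load_single(toy_genome_factory, gene)
        per_exon = gm.assign_codons_to_exons(t)
        total = sum(len(ec.codons) for ec in per_exon)
        spanning = sum(1 for xi in t.codon_exon if xi is None)
        assert total + spanning == t.peptide_length
        # junction at 61 (phase 1): codon 20 spans exons 1 and 2
        assert t.codon_exon[20] is None
        labels = [ec.exon_index for ec in per_exon]
        assert labels == sorted(labels)
        assert per_exon[-1].is_last

    def test_single_exon_all_in_one(self, toy_genome_factory):
        t = load_single(toy_genome_factory, ToyGene("gA", make_cds(30), [93]))
        per_exon = gm.assign_codons_to_exons(t)
        assert len(per_exon) == 1
        assert len(per_exon[0].codons) == 30

    def test_spliced_reconstruction(self, toy_genome_factory):
        cds = make_cds(40)
        gene = ToyGene("gA", cds, [37, 41, 45])
        t = load_single(toy_genome_factory, gene)
        rebuilt = [None] * t.peptide_length
        for ec in gm.assign_codons_to_exons(t):
            for off, codon in zip(ec.codons.positions, ec.codons.codons):
                rebuilt[off // 3] = codon
        for i, xi in enumerate(t.codon_exon):
            if xi is None:
                rebuilt[i] = t.codons.codons[i]
        assert tuple(rebuilt) == t.codons.codons


class TestBoundaryWindows:
    def _window_gene(self, j, n_codons=220, utr3="A" * 150):
        cds = make_cds(n_codons)
        return ToyGene("gA", cds, [j, len(cds) - j], utr3=utr3)

    @pytest.mark.parametrize(
        "j,five_start,three_start",
        [
            (300, 33, 100),  # phase 0: codon 100 starts the last exon
            (301, 33, 101),  # phase 1: codon 100 spans the junction
            (302, 34, 101),  # phase 2: spanning codon excluded, 5' shifted
        ],
    )
    def test_phases(self, toy_genome_factory, j, five_start, three_start):
        t = load_single(toy_genome_factory, self._window_gene(j))
        windows, reason = gm.extract_boundary_windows(t)
        assert reason is None
        five, three = windows.five_prime_window, windows.three_prime_window
        assert len(five) == 50 and len(three) == 50
        assert five.positions[0] // 3 == five_start
        assert three.positions[0] // 3 == three_start
        # buffer bound: last 5'-window nucleotide >= 50 nt before junction
        assert j - (five.positions[-1] + 3) >= 50
        # no codon in both windows
        assert not set(five.positions) & set(three.positions)
        # 3' window codons lie fully in the last exon
        for off in three.positions:
            assert t.codon_exon[off // 3] == t.exon_count - 1
        # spanning codon (if any) is in neither window
        for i, xi in enumerate(t.codon_exon):
            if xi is None:
                assert 3 * i not in five.positions
                assert 3 * i not in three.positions

    def test_last_exon_too_short(self, toy_genome_factory):
        t = load_single(toy_genome_factory, self._window_gene(393))
        windows, reason = gm.extract_boundary_windows(t)
        assert windows is None and reason == gm.REASON_SHORT_LAST_EXON

    def test_insufficient_upstream(self, toy_genome_factory):
        t = load_single(toy_genome_factory, self._window_gene(120))
        windows, reason = gm.extract_boundary_windows(t)
        assert windows is None and reason == gm.REASON_INSUFFICIENT_UPSTREAM

    def test_unreliable(self, toy_genome_factory):
        t = load_single(
            toy_genome_factory, self._window_gene(300, utr3="A" * 40)
        )
        windows, reason = gm.extract_boundary_windows(t)
        assert windows is None and reason == gm.REASON_UNRELIABLE

    def test_single_exon(self, toy_genome_factory):
        t = load_single(toy_genome_factory, ToyGene("gA", make_cds(220), [663]))
        windows, reason = gm.extract_boundary_windows(t)
        assert windows is None and reason == gm.REASON_SINGLE_EXON

    def test_minus_strand_same_windows(self, toy_genome_factory):
        plus = load_single(toy_genome_factory, self._window_gene(301))
        minus_gene = self._window_gene(301)
        minus_gene.strand = "-"
        minus = load_single(toy_genome_factory, minus_gene)
        wp, _ = gm.extract_boundary_windows(plus)
        wm, _ = gm.extract_boundary_windows(minus)
        assert wp.five_prime_window.codons == wm.five_prime_window.codons
        assert wp.three_prime_window.codons == wm.three_prime_window.codons


class TestCdsInLastExon:
    def test_true_case(self, toy_genome_factory):
        # pure-UTR first exon, entire CDS in the last exon
        t = load_single(
            toy_genome_factory,
            ToyGene("gA", make_cds(60), [183], utr5_own_exon=True),
        )
        assert t.exon_count == 2
        assert gm.cds_in_last_exon(t)

    def test_false_when_cds_spans_exons(self, toy_genome_factory):
        t = load_single(
            toy_genome_factory, ToyGene("gA", make_cds(60), [90, 93])
        )
        assert not gm.cds_in_last_exon(t)

    def test_noncoding_first_exon_counts_as_multi(self, toy_genome_factory):
        t = load_single(
            toy_genome_factory,
            ToyGene("gA", make_cds(60), [183], utr5_own_exon=True),
        )
        assert gm.exon_count(t) == 2  # classified multi-exon

    def test_single_exon_rejected(self, toy_genome_factory):
        t = load_single(toy_genome_factory, ToyGene("gA", make_cds(30), [93]))
        with pytest.raises(ValueError):
            gm.cds_in_last_exon(t)


class TestEse:
    def test_exact_hexamer(self):
        assert gm.ese_density("GAAGAA", {"GAAGAA"}) == 1.0

    def test_absent_hexamer(self):
        assert gm.ese_density("T" * 30, {"GAAGAA"}) == 0.0

    def test_overlap_union(self):
        # ACACAC at 0 and 2 covers positions 0..7 of a 12-nt sequence
        assert gm.ese_density("ACACACACGGGG", {"ACACAC"}) == pytest.approx(8 / 12)

    def test_short_sequence(self):
        assert gm.ese_density("ACG", {"ACACAC"}) == 0.0

    def test_empty_hexamer_set_rejected(self):
        with pytest.raises(ValueError):
            gm.hexamer_coverage("ACGTACGT", set())

    def test_partition_rules(self):
        seq = "ACACACAC" + "T" * 30
        codons = CodonSequence(
            codons=("ACA", "CAC", "TTT"), offsets=(0, 3, 30)
        )
        over, ext = gm.partition_codons_by_ese(codons, {"ACACAC"}, seq)
        assert over.codons == ("ACA", "CAC")
        assert ext.codons == ("TTT",)

    def test_partition_single_nt_overlap(self):
        seq = "T" * 2 + "ACACAC" + "T" * 10
        # codon at offset 0 shares exactly one nt (position 2) with the hexamer
        codons = CodonSequence(codons=("TTA", "TTT"), offsets=(0, 12))
        over, ext = gm.partition_codons_by_ese(codons, {"ACACAC"}, seq)
        assert over.codons == ("TTA",)
        assert ext.codons == ("TTT",)

    def test_read_hexamers(self, tmp_path):
        path = tmp_path / "ese.txt"
        path.write_text("GAAGAA\n# comment\nacgtac\n\n")
        assert gm.read_hexamers(path) == {"GAAGAA", "ACGTAC"}
        bad = tmp_path / "bad.txt"
        bad.write_text("ACGT\n")
        with pytest.raises(ValueError):
            gm.read_hexamers(bad)


class TestFop:
    def test_all_optimal(self):
        seq = CodonSequence(("GCC", "GCC", "AAG"))
        assert gm.fop(seq, {"GCC", "AAG"}).value == 1.0

    def test_no_multi_codon_families(self):
        seq = CodonSequence(("ATG", "TGG"))  # Met and Trp only
        assert gm.fop(seq, {"GCC"}).value is None

    def test_mixed_hand_computed(self):
        # 10 codons: 4 GCC (opt), 2 GCT, 2 AAG (opt), 1 AAA, 1 ATG (excluded)
        codons = ("GCC",) * 4 + ("GCT",) * 2 + ("AAG",) * 2 + ("AAA", "ATG")
        mv = gm.fop(CodonSequence(codons), {"GCC", "AAG"})
        assert mv.value == pytest.approx(6 / 9)

    def test_empty_optimal_set(self):
        with pytest.raises(ValueError):
            gm.fop(CodonSequence(("GCC",)), set())

    def test_gc_controlled_mode(self):
        # Ala family by GC: GCT(1), GCA(1), GCC(2), GCG(2); optimal = {GCC}
        # only the GC=2 subgroup mixes optimal/non-optimal
        codons = ("GCC", "GCC", "GCG", "GCT")
        mv = gm.fop(CodonSequence(codons), {"GCC"}, mode="gc_controlled")
        assert mv.value == pytest.approx(2 / 3)


def test_structural_table(toy_genome_factory):
    fasta, gff3 = toy_genome_factory(
        [ToyGene("gA", make_cds(60), [90, 93], utr3="A" * 150)]
    )
    models = gm.load_annotation(fasta, gff3)
    df = gm.structural_table(
        models, hexamers={"GAAGAA"}, optimal_codons={"GCC"}
    )
    assert df.loc[0, "reliable_last_exon"]
    assert df.loc[0, "exon_count"] == 2
    assert "ese_density" in df.columns and "fop" in df.columns
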