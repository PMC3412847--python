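"""Gene-model parsing, intron extraction and structural statistics."""

import pytest
from hypothesis import given, settings, strategies as st

from introntrace.gene_models import (
    GeneModel,
    extract_introns,
    gc_fraction,
    introns_to_bed,
    load_gene_models,
    revcomp,
    summarize_intron_stats,
)
from introntrace.simulate import SimConfig, simulate

from conftest import families_of


def make_gene(sequence, exons, cds_start, cds_end, gene_id="g1"):
    return GeneModel(gene_id=gene_id, species_id="sp", sequence=sequence,
                     exons=exons, cds_start=cds_start, cds_end=cds_end)


class TestExtractIntrons:
    def test_single_exon_gene_has_no_introns(self):
        g = make_gene("ATGAAATAA", [(0, 9)], 0, 9)
        assert extract_introns(g) == []

    def test_phase_from_coding_offset(self):
        # exons [0,10)+[50,80); cds_start=2 -> intron after 8 coding nt -> phase 2
        exon1 = "TTATGAAACC"
        intron = "GT" + "A" * 36 + "AG"
        exon2 = "C" * 30
        g = make_gene(exon1 + intron + exon2, [(0, 10), (50, 80)], 2, 38)
        recs = extract_introns(g)
        assert len(recs) == 1
        r = recs[0]
        assert (r.phase, r.length, r.start, r.end) == ("2", 40, 10, 50)
        assert r.splice_class == "GT-AG"

    def test_gc_ag_minor_splice_class(self):
        intron = "GC" + "T" * 30 + "AG"
        g = make_gene("ATGAAA" + intron + "CCCTAA", [(0, 6), (40, 46)], 0, 12)
        (r,) = extract_introns(g)
        assert r.splice_class == "GC-AG"

    def test_intron_at_cds_start_is_utr5(self):
        # insertion point exactly at cds_start: UTR5 by convention
        g = make_gene("TT" + "GTAAAG" + "ATGTAA", [(0, 2), (8, 14)], 2, 8)
        (r,) = extract_introns(g)
        assert r.phase == "UTR5"

    def test_intron_at_cds_end_is_utr3(self):
        g = make_gene("ATGTAA" + "GTAAAG" + "TT", [(0, 6), (12, 14)], 0, 6)
        (r,) = extract_introns(g)
        assert r.phase == "UTR3"

    def test_splice_tiling_invariant(self, small_bundle):
        """Exons plus extracted introns exactly tile the gene span."""
        for sp, models in small_bundle.gene_models.items():
            for g in models:
                recs = extract_introns(g)
                pieces = sorted(
                    list(g.exons) + [(r.start, r.end) for r in recs]
                )
                assert pieces[0][0] == 0
                assert pieces[-1][1] == len(g.sequence)
                for (s1, e1), (s2, e2) in zip(pieces, pieces[1:]):
                    assert e1 == s2  # no gap, no overlap

    def test_phase_partition(self, small_bundle):
        """Phase counts plus UTR counts equal total introns."""
        for models in small_bundle.gene_models.values():
            recs = [r for g in models for r in extract_introns(g)]
            n_phase = sum(1 for r in recs if r.phase in "012")
            n_utr = sum(1 for r in recs if r.phase.startswith("UTR"))
            assert n_phase + n_utr == len(recs)


class TestGCFraction:
    @pytest.mark.parametrize("seq,expected", [
        ("ATAT", 0.0), ("GCGC", 1.0), ("ATGC", 0.5), ("ANNGT", 1 / 3),
    ])
    def test_values(self, seq, expected):
        assert gc_fraction(seq) == pytest.approx(expected)

    def test_all_n_is_undefined(self):
        with pytest.raises(ValueError):
            gc_fraction("NNNN")
        with pytest.raises(ValueError):
            gc_fraction("")

    @given(st.text(alphabet="ACGT", min_size=1, max_size=60))
    @settings(max_examples=50, deadline=None)
    def test_complement_preserves_gc(self, seq):
        assert gc_fraction(revcomp(seq)) == pytest.approx(gc_fraction(seq))


class TestStats:
    def test_mean_and_lower_median(self):
        lengths = [37, 68, 2263]  # echoes the observed extremes
        genes, introns = [], []
        for i, L in enumerate(lengths):
            intron = "GT" + "A" * (L - 4) + "AG"
            g = make_gene("ATGAAA" + intron + "TAA", [(0, 6), (6 + L, 9 + L)],
                          0, 9, gene_id=f"g{i}")
            genes.append(g)
            introns.extend(extract_introns(g))
        stats = summarize_intron_stats(introns, genes, [0, 100, 5000])
        assert stats.mean_length == pytest.approx(789.33, abs=0.01)
        assert stats.median_length == 68
        # even n -> lower central value
        stats2 = summarize_intron_stats(introns[:2], genes[:2], [0, 5000])
        assert stats2.median_length == 37

    def test_pure_phase0(self):
        genes, introns = [], []
        for i in range(10):
            intron = "GT" + "A" * 40 + "AG"
            g = make_gene("ATGAAA" + intron + "TAA", [(0, 6), (50, 53)],
                          0, 9, gene_id=f"g{i}")
            genes.append(g)
            introns.extend(extract_introns(g))
        stats = summarize_intron_stats(introns, genes)
        assert stats.phase_fractions == (1.0, 0.0, 0.0)
        assert sum(stats.length_histogram) == stats.n_introns == 10

    def test_phase_fraction_recovery_from_simulation(self):
        """Configured 0.5/0.3/0.2 phases recovered within binomial noise."""
        bundle = simulate(SimConfig(n_families=150, seed=33,
                                    tree_newick="(SPA:0.05,SPB:0.05);",
                                    minus_strand_prob=0.0))
        models = bundle.gene_models["SPA"]
        introns = [r for g in models for r in extract_introns(g)]
        stats = summarize_intron_stats(introns, models)
        for got, want in zip(stats.phase_fractions, (0.5, 0.3, 0.2)):
            assert abs(got - want) < 0.03
        assert abs(stats.introns_per_gene_mean - 4.0) < 0.4
        assert abs(stats.mean_gc_introns - 0.312) < 0.02
        assert abs(stats.mean_gc_cds - 0.442) < 0.02


class TestLoadRoundTrip:
    def test_fixture_round_trip(self, small_bundle, bundle_dir):
        """Written GFF3+FASTA reload to the identical sense-strand models."""
        for sp in small_bundle.species:
            models, problems = load_gene_models(
                str(bundle_dir / f"{sp}.gff3"), str(bundle_dir / f"{sp}.fasta"),
                species_id=sp)
            assert problems == []
            orig = {g.gene_id: g for g in small_bundle.gene_models[sp]}
            assert set(orig) == {m.gene_id for m in models}
            for m in models:
                o = orig[m.gene_id]
                assert m.sequence == o.sequence
                assert m.exons == o.exons
                assert (m.cds_start, m.cds_end) == (o.cds_start, o.cds_end)

    def test_strand_invariance(self, tmp_path):
        """A minus-strand fixture yields the same statistics as its plus
        mirror."""
        plus = simulate(SimConfig(n_families=5, seed=77, minus_strand_prob=0.0))
        minus = simulate(SimConfig(n_families=5, seed=77, minus_strand_prob=1.0))
        dp, dm = tmp_path / "plus", tmp_path / "minus"
        plus.write(dp)
        minus.write(dm)
        for sp in plus.species:
            mp, _ = load_gene_models(str(dp / f"{sp}.gff3"), str(dp / f"{sp}.fasta"))
            mm, _ = load_gene_models(str(dm / f"{sp}.gff3"), str(dm / f"{sp}.fasta"))
            assert {g.strand_original for g in mm} == {"-"}
            sp_stats = summarize_intron_stats(
                [r for g in mp for r in extract_introns(g)], mp)
            sm_stats = summarize_intron_stats(
                [r for g in mm for r in extract_introns(g)], mm)
            assert sp_stats.mean_length == sm_stats.mean_length
            assert sp_stats.phase_fractions == sm_stats.phase_fractions
            assert sp_stats.mean_gc_introns == pytest.approx(sm_stats.mean_gc_introns)

    def test_missing_contig_is_hard_error(self, tmp_path):
        gff = tmp_path / "x.gff3"
        fa = tmp_path / "x.fasta"
        gff.write_text(
            "##gff-version 3\n"
            "ctgX\t.\tgene\t1\t30\t.\t+\t.\tID=g1\n"
            "ctgX\t.\tmRNA\t1\t30\t.\t+\t.\tID=g1.t1;Parent=g1\n"
            "ctgX\t.\texon\t1\t30\t.\t+\t.\tID=e1;Parent=g1.t1\n"
            "ctgX\t.\tCDS\t1\t30\t.\t+\t0\tID=c1;Parent=g1.t1\n"
        )
        fa.write_text(">other\nATGAAATAA\n")
        with pytest.raises(Exception, match="ctgX"):
            load_gene_models(str(gff), str(fa))

    def test_cds_not_multiple_of_three_flags_incomplete(self, tmp_path):
        gff = tmp_path / "x.gff3"
        fa = tmp_path / "x.fasta"
        seq = "ATGAAAACCTAA"
        gff.write_text(
            "##gff-version 3\n"
            "c\t.\tgene\t1\t12\t.\t+\t.\tID=g1\n"
            "c\t.\tmRNA\t1\t12\t.\t+\t.\tID=g1.t1;Parent=g1\n"
            "c\t.\texon\t1\t12\t.\t+\t.\tID=e1;Parent=g1.t1\n"
            "c\t.\tCDS\t1\t11\t.\t+\t0\tID=c1;Parent=g1.t1\n"
        )
        fa.write_text(f">c\n{seq}\n")
        models, problems = load_gene_models(str(gff), str(fa))
        assert len(models) == 1 and models[0].incomplete
        assert any("not divisible by 3" in p for p in problems)


def test_bed_output_scores_phase():
    intron = "GT" + "A" * 40 + "AG"
    g = make_gene("ATGAAA" + intron + "TAA", [(0, 6), (50, 53)], 0, 9)
    bed = introns_to_bed(extract_introns(g))
    fields = bed.strip().split("\t")
    assert fields[3] == "g1.I1" and fields[4] == "0"
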