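import numpy as np
import pytest

from medseq.reference import (
    GeneModel,
    MotifSpec,
    ReferenceGenome,
    build_region_catalog,
    build_site_index,
    load_gene_table,
    load_genome,
    load_gtf_genes,
)
from .conftest import naive_anchor_scan, random_genome


class TestLoadGenome:
    def test_single_record(self, tmp_path):
        path = tmp_path / "g.fa"
        path.write_text(">chr1\n" + "ACGT" * 25 + "\n")
        genome = load_genome(path)
        assert genome.lengths == {"chr1": 100}

    def test_two_records_order_preserved(self, tmp_path):
        path = tmp_path / "g.fa"
        path.write_text(">b\nACGT\n>a\nGGCC\n")
        genome = load_genome(path)
        assert genome.chroms == ["b", "a"]

    def test_lowercase_uppercased_and_n_allowed(self, tmp_path):
        path = tmp_path / "g.fa"
        path.write_text(">chr1\nacgtn\n")
        assert load_genome(path).sequences["chr1"] == "ACGTN"

    def test_invalid_character_names_record_and_position(self, tmp_path):
        path = tmp_path / "g.fa"
        path.write_text(">chrZ\nACXGT\n")
        with pytest.raises(ValueError, match="chrZ.*position 3"):
            load_genome(path)

    def test_duplicate_names_fatal(self, tmp_path):
        path = tmp_path / "g.fa"
        path.write_text(">chr1\nACGT\n>chr1\nACGT\n")
        with pytest.raises(ValueError, match="duplicate"):
            load_genome(path)

    def test_empty_file_fatal(self, tmp_path):
        path = tmp_path / "g.fa"
        path.write_text("")
        with pytest.raises(ValueError, match="no FASTA records"):
            load_genome(path)


class TestMotifSpec:
    def test_anchor_must_be_inside_motif(self):
        with pytest.raises(ValueError):
            MotifSpec("CCGG", anchor_offset=4)

    def test_cpg_validation(self):
        MotifSpec("CCGG", 1, validate_cpg=True)  # contains CG
        MotifSpec("CCDG", 1, validate_cpg=True)  # D can be G -> CG possible
        with pytest.raises(ValueError, match="CpG"):
            MotifSpec("AATT", 1, validate_cpg=True)


class TestSiteIndex:
    def test_hand_enumeration_single_strand(self):
        genome = ReferenceGenome({"chr1": "AACCGGTT"})
        motif = MotifSpec("CCGG", anchor_offset=1, search_both_strands=False)
        sites = list(build_site_index(genome, motif).sites())
        assert sites == [("chr1", 3, "+")]

    def test_palindromic_occurrence_is_one_site(self):
        genome = ReferenceGenome({"chr1": "AACCGGTT"})
        motif = MotifSpec("CCGG", anchor_offset=1, search_both_strands=True)
        sites = list(build_site_index(genome, motif).sites())
        assert sites == [("chr1", 3, ".")]

    def test_absent_motif_gives_empty_index(self):
        genome = ReferenceGenome({"chr1": "AAAATTTT"})
        motif = MotifSpec("CCGG", 1)
        assert build_site_index(genome, motif).n_sites == 0

    def test_overlapping_occurrences_all_recorded(self):
        # CCCGGG: CCGG matches nowhere overlapping, use CCWGG-style overlap
        genome = ReferenceGenome({"chr1": "ACACACA"})
        motif = MotifSpec("ACA", anchor_offset=0, search_both_strands=False)
        positions = [p for _, p, _ in build_site_index(genome, motif).sites()]
        assert positions == [0, 2, 4]

    @pytest.mark.parametrize("motif_str,both", [("CCWGG", True), ("CCGG", True), ("CCGG", False)])
    def test_matches_naive_scan_on_random_genome(self, motif_str, both):
        rng = np.random.default_rng(11)
        genome = random_genome(50_000, rng)
        motif = MotifSpec(motif_str, 1, search_both_strands=both)
        index = build_site_index(genome, motif)
        expected = naive_anchor_scan(genome.sequences["chr1"], motif)
        got = [(p, s) for _, p, s in index.sites()]
        assert got == sorted(set(expected))

    def test_rerun_bit_identical(self):
        rng = np.random.default_rng(5)
        genome = random_genome(20_000, rng)
        motif = MotifSpec("CCGG", 1)
        a = build_site_index(genome, motif)
        b = build_site_index(genome, motif)
        assert np.array_equal(a.positions["chr1"], b.positions["chr1"])
        assert np.array_equal(a.strands["chr1"], b.strands["chr1"])


class TestRegionCatalog:
    LENGTHS = {"chr1": 20_000}

    def test_plus_strand_windows(self):
        gene = GeneModel("g1", "chr1", "+", 5000, 9000)
        catalog = build_region_catalog([gene], [], self.LENGTHS)
        tss = catalog.tss_windows[0]
        body = catalog.gene_bodies[0]
        assert (tss.start, tss.end) == (4000, 6000)
        assert (body.start, body.end) == (6000, 9000)

    def test_minus_strand_windows(self):
        gene = GeneModel("g1", "chr1", "-", 9000, 5000)
        catalog = build_region_catalog([gene], [], self.LENGTHS)
        tss = catalog.tss_windows[0]
        body = catalog.gene_bodies[0]
        assert (tss.start, tss.end) == (8000, 10000)
        assert (body.start, body.end) == (5000, 8000)

    def test_short_gene_yields_no_body(self, caplog):
        gene = GeneModel("tiny", "chr1", "+", 1000, 1800)
        catalog = build_region_catalog([gene], [], self.LENGTHS)
        assert len(catalog.tss_windows) == 1
        assert catalog.gene_bodies == []

    def test_tss_outside_chromosome_fatal(self):
        gene = GeneModel("g1", "chr1", "+", 30_000, 31_000)
        with pytest.raises(ValueError, match="outside chromosome"):
            build_region_catalog([gene], [], self.LENGTHS)

    def test_windows_clipped_to_chromosome(self):
        gene = GeneModel("edge", "chr1", "+", 400, 5000)
        catalog = build_region_catalog([gene], [], self.LENGTHS)
        tss = catalog.tss_windows[0]
        assert tss.start == 0 and tss.end == 1400

    def test_unclipped_tss_windows_are_2kb(self, small_reference):
        _, genome, _, catalog = small_reference
        for window in catalog.tss_windows:
            length = window.end - window.start
            clipped = window.start == 0 or window.end == genome.lengths[window.chrom]
            assert length == 2000 or clipped

    def test_lookup_unknown_region_lists_near_matches(self, small_reference):
        *_, catalog = small_reference
        with pytest.raises(KeyError, match="close matches"):
            catalog.lookup("tss", "g9999")


class TestAnnotationReaders:
    def test_gene_table_roundtrip_and_dedup(self, tmp_path):
        path = tmp_path / "genes.tsv"
        path.write_text(
            "# comment\ngene_id\tchrom\tstrand\ttss\ttes\n"
            "gA\tchr1\t+\t100\t900\n"
            "gA\tchr1\t-\t900\t100\n"
        )
        genes = load_gene_table(path)
        assert [g.gene_id for g in genes] == ["gA", "gA.1"]

    def test_gtf_coordinates_converted(self, tmp_path):
        path = tmp_path / "genes.gtf"
        path.write_text(
            "# header\n"
            'chr1\tsrc\tgene\t101\t900\t.\t+\t.\tgene_id "gp";\n'
            'chr1\tsrc\tgene\t101\t900\t.\t-\t.\tgene_id "gm";\n'
        )
        gp, gm = load_gtf_genes(path)
        assert (gp.tss, gp.tes) == (100, 900)
        assert (gm.tss, gm.tes) == (899, 100)
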