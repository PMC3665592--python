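"""PTT parsing and strand-aware promoter-to-gene assignment."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import sigma54scan as sc
from sigma54scan.errors import InputError, PTTError
from sigma54scan.genome_scan import reverse_complement

PTT_FIXTURE = """Escherichia coli K-12 MG1655, complete genome - 1..4641652
3 proteins
Location\tStrand\tLength\tPID\tGene\tSynonym\tCode\tCOG\tProduct
190..255\t+\t21\t1\tthrL\tb0001\t-\t-\tleader peptide
2000..2500\t-\t166\t2\t-\tb0002\t-\tCOG3321\tpolyketide synthase
3000..3900\t+\t299\t3\tglnA\tb0003\t-\tCOG0174\tglutamine synthetase
"""


def make_hit(start, end, strand, score=80.0, genome_id="g"):
    return sc.PromoterHit(genome_id, start, end, strand, score, "A" * (end - start + 1))


def plus_gene(start=1000, end=1900, genome_id="g", **kw):
    return sc.GeneRecord(genome_id, start, end, "+", **kw)


class TestReadPTT:
    def test_fixture_rows_parsed(self, tmp_path):
        path = tmp_path / "g.ptt"
        path.write_text(PTT_FIXTURE)
        genes = sc.read_ptt(path, genome_id="g")
        assert len(genes) == 3
        first = genes[0]
        assert (first.start, first.end, first.strand) == (190, 255, "+")
        assert (first.gene_name, first.synonym) == ("thrL", "b0001")
        assert first.cog_id == ""  # "-" maps to empty
        assert genes[1].cog_id == "COG3321"
        assert genes[1].start_codon == 2500  # minus-strand start codon

    def test_unknown_strand_symbol_rejected(self, tmp_path):
        path = tmp_path / "g.ptt"
        path.write_text(PTT_FIXTURE.replace("190..255\t+", "190..255\t?"))
        with pytest.raises(PTTError):
            sc.read_ptt(path)

    def test_malformed_location_rejected(self, tmp_path):
        path = tmp_path / "g.ptt"
        path.write_text(PTT_FIXTURE.replace("190..255", "190-255"))
        with pytest.raises(PTTError):
            sc.read_ptt(path)

    def test_write_read_round_trip(self, tmp_path):
        path = tmp_path / "g.ptt"
        path.write_text(PTT_FIXTURE)
        genes = sc.read_ptt(path, genome_id="g")
        out = tmp_path / "rt.ptt"
        sc.write_ptt(genes, out)
        assert sc.read_ptt(out, genome_id="g") == genes


class TestLinking:
    def test_adjacent_upstream_hit_links_at_distance_1(self, config):
        gene = plus_gene(start=1000)
        hit = make_hit(984, 999, "+")
        links = sc.link_hits_to_genes([hit], [gene], config)
        assert len(links) == 1 and links[0].distance == 1

    def test_distance_501_excluded_500_included(self, config):
        gene = plus_gene(start=1000)
        too_far = make_hit(484, 499, "+")  # distance 501
        boundary = make_hit(485, 500, "+")  # distance 500
        links = sc.link_hits_to_genes([too_far, boundary], [gene], config)
        assert [l.distance for l in links] == [500]

    def test_minus_strand_gene_links_downstream_in_forward_coords(self, config):
        gene = sc.GeneRecord("g", 2000, 2500, "-")
        hit = make_hit(2501, 2516, "-")
        links = sc.link_hits_to_genes([hit], [gene], config)
        assert len(links) == 1 and links[0].distance == 1

    def test_minus_strand_rule_agrees_with_mirrored_plus_case(self, pwm, config):
        # score a real motif upstream of a - gene, then mirror the whole
        # locus and re-run the + strand case as the oracle
        locus_len = 3000
        motif = pwm.modal_string
        site_start, site_end = 2600, 2615  # motif 3' edge 100 bp past the gene end
        gene = sc.GeneRecord("locus", 1600, 2500, "-")
        seq = ["A"] * locus_len
        seq[site_start - 1 : site_end] = list(reverse_complement(motif))
        genome = sc.GenomeSequence("locus", "".join(seq))
        links = sc.link_hits_to_genes(
            sc.scan_genome(genome, pwm, config), [gene], config
        )
        mirrored = sc.GenomeSequence("locus", reverse_complement(genome.seq))
        m_gene = sc.GeneRecord(
            "locus", locus_len - 2500 + 1, locus_len - 1600 + 1, "+"
        )
        m_links = sc.link_hits_to_genes(
            sc.scan_genome(mirrored, pwm, config), [m_gene], config
        )
        assert len(links) == len(m_links) == 1
        assert links[0].distance == m_links[0].distance == 100
        assert links[0].hit.score == m_links[0].hit.score

    def test_wrong_strand_hit_not_linked(self, config):
        gene = plus_gene(start=1000)
        assert sc.link_hits_to_genes([make_hit(984, 999, "-")], [gene], config) == []

    def test_low_score_hit_not_linked(self, config):
        gene = plus_gene(start=1000)
        hit = make_hit(984, 999, "+", score=70.0)  # above floor, below link cutoff
        assert sc.link_hits_to_genes([hit], [gene], config) == []

    def test_hit_overlapping_start_codon_not_linked(self, config):
        gene = plus_gene(start=1000)
        assert sc.link_hits_to_genes([make_hit(990, 1005, "+")], [gene], config) == []

    def test_one_hit_may_serve_multiple_genes(self, config):
        genes = [plus_gene(start=1000), plus_gene(start=1200, end=1900)]
        hit = make_hit(984, 999, "+")
        links = sc.link_hits_to_genes([hit], genes, config)
        assert len(links) == 2 and {l.distance for l in links} == {1, 201}

    def test_translation_invariance(self, config):
        offset = 10_000
        genes = [plus_gene(start=1000), sc.GeneRecord("g", 3000, 3600, "-")]
        hits = [make_hit(700, 715, "+"), make_hit(3700, 3715, "-")]
        base = sc.link_hits_to_genes(hits, genes, config)
        moved_genes = [
            sc.GeneRecord("g", g.start + offset, g.end + offset, g.strand)
            for g in genes
        ]
        moved_hits = [
            make_hit(h.start + offset, h.end + offset, h.strand) for h in hits
        ]
        moved = sc.link_hits_to_genes(moved_hits, moved_genes, config)
        assert [l.distance for l in base] == [l.distance for l in moved]
        assert len(base) == 2

    @given(
        st.floats(min_value=75, max_value=100),
        st.integers(min_value=1, max_value=500),
    )
    @settings(max_examples=40, deadline=None)
    def test_tightening_cutoffs_never_adds_links(self, cutoff, window):
        genes = [plus_gene(start=1000), sc.GeneRecord("g", 3000, 3600, "-")]
        hits = [
            make_hit(984, 999, "+", score=80),
            make_hit(600, 615, "+", score=92),
            make_hit(3610, 3625, "-", score=77),
            make_hit(4050, 4065, "-", score=99),
        ]
        base_cfg = sc.ScanConfig()
        tight_cfg = sc.ScanConfig(
            report_score=65, link_score=max(cutoff, 75), max_upstream=window
        )
        base = sc.link_hits_to_genes(hits, genes, base_cfg)
        tight = sc.link_hits_to_genes(hits, genes, tight_cfg)
        key = lambda l: (l.hit.start, l.gene.start, l.distance)
        assert set(map(key, tight)) <= set(map(key, base))

    def test_emitted_links_satisfy_their_invariants(self, survey, pwm, config):
        genome, genes, _ = survey
        hits = sc.scan_genome(genome, pwm, config)
        for l in sc.link_hits_to_genes(hits, genes, config):
            assert l.hit.strand == l.gene.strand
            assert 1 <= l.distance <= config.max_upstream
            assert l.hit.score >= config.link_score


class TestGeneFraction:
    def test_no_links_gives_zero(self, config):
        assert sc.fraction_genes_with_promoter([plus_gene()], []) == 0.0

    def test_every_gene_linked_gives_one(self, config):
        gene = plus_gene(start=1000)
        links = sc.link_hits_to_genes([make_hit(984, 999, "+")], [gene], config)
        assert sc.fraction_genes_with_promoter([gene], links) == 1.0

    def test_repeated_links_count_distinct_genes(self, config):
        genes = [plus_gene(start=1000)] + [
            plus_gene(start=s, end=s + 600) for s in (5000, 8000, 11000)
        ]
        hits = [make_hit(984 - k, 999 - k, "+") for k in (0, 20, 40)]
        links = sc.link_hits_to_genes(hits, genes, config)
        assert len(links) == 3
        assert sc.fraction_genes_with_promoter(genes, links) == 0.25

    def test_empty_gene_table_is_an_error(self):
        with pytest.raises(InputError):
            sc.fraction_genes_with_promoter([], [])


class TestLinksIO:
    def test_links_tsv_round_trip_recovers_genes(self, survey, pwm, config, tmp_path):
        genome, genes, _ = survey
        hits = sc.scan_genome(genome, pwm, config)
        links = sc.link_hits_to_genes(hits, genes, config)
        path = tmp_path / "links.tsv"
        sc.annotation_link.write_links_tsv(links, path)
        again = sc.annotation_link.read_links_tsv(path, genes)
        assert [(l.gene, l.distance, l.hit.start) for l in again] == [
            (l.gene, l.distance, l.hit.start) for l in links
        ]
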