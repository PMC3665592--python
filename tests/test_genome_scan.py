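"""FASTA input and both-strand scanning against a naive oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import sigma54scan as sc
from sigma54scan.errors import FastaError, UnscorableWindowError
from sigma54scan.genome_scan import reverse_complement

dna = st.text(alphabet="ACGT", min_size=0, max_size=400)


def naive_scan(genome, pwm, config):
    """Per-window rescoring oracle: score every forward and reverse
    window with score_window directly."""
    hits = []
    w = pwm.width
    for pos in range(len(genome.seq) - w + 1):
        window = genome.seq[pos : pos + w]
        for strand, site in (("+", window), ("-", reverse_complement(window))):
            try:
                score = sc.score_window(pwm, site)
            except UnscorableWindowError:
                continue
            if score >= config.report_score:
                hits.append(
                    sc.PromoterHit(
                        genome_id=genome.id,
                        start=pos + 1,
                        end=pos + w,
                        strand=strand,
                        score=score,
                        site_seq=site,
                    )
                )
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


class TestReadFasta:
    def test_multi_record_lengths_and_ids(self, tmp_path):
        path = tmp_path / "g.fna"
        path.write_text(">chr1 some description\nACGTACGT\nACGT\n>plasmid1\nTTTT\n")
        genomes = sc.read_fasta(path)
        assert [(g.id, g.length) for g in genomes] == [("chr1", 12), ("plasmid1", 4)]

    def test_lowercase_uppercased(self, tmp_path):
        path = tmp_path / "g.fna"
        path.write_text(">x\nacgtn\n")
        assert sc.read_fasta(path)[0].seq == "ACGTN"

    def test_illegal_character_rejected(self, tmp_path):
        path = tmp_path / "g.fna"
        path.write_text(">x\nACGJ\n")
        with pytest.raises(FastaError):
            sc.read_fasta(path)

    def test_duplicate_ids_rejected(self, tmp_path):
        path = tmp_path / "g.fna"
        path.write_text(">x\nACGT\n>x\nTTTT\n")
        with pytest.raises(FastaError):
            sc.read_fasta(path)

    def test_empty_file_rejected(self, tmp_path):
        path = tmp_path / "g.fna"
        path.write_text("")
        with pytest.raises(FastaError):
            sc.read_fasta(path)

    def test_fasta_round_trip(self, tmp_path):
        genomes = [sc.GenomeSequence("a", "ACGTACGT"), sc.GenomeSequence("b", "TTG")]
        path = tmp_path / "out.fna"
        sc.write_fasta(genomes, path)
        assert sc.read_fasta(path) == genomes


class TestScanGenome:
    def test_implanted_consensus_found_at_known_position(self, pwm, config):
        rng = np.random.default_rng(5)
        background = "".join("ACGT"[i] for i in rng.integers(0, 4, 10_000))
        motif = pwm.modal_string
        assert background.find(motif) == -1  # implant is the unique match
        assert background.find(reverse_complement(motif)) == -1
        seq = background[:100] + motif + background[116:]
        hits = sc.scan_genome(sc.GenomeSequence("g", seq), pwm, config)
        perfect = [h for h in hits if h.score == pytest.approx(100.0)]
        assert len(perfect) == 1
        hit = perfect[0]
        assert (hit.start, hit.end, hit.strand, hit.site_seq) == (101, 116, "+", motif)

    def test_reverse_complemented_genome_mirrors_hits(self, pwm, config):
        rng = np.random.default_rng(6)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 3000))
        seq = seq[:500] + pwm.modal_string + seq[516:]
        genome = sc.GenomeSequence("g", seq)
        mirrored = sc.GenomeSequence("g", reverse_complement(seq))
        length = len(seq)
        fwd = sc.scan_genome(genome, pwm, config)
        rev = sc.scan_genome(mirrored, pwm, config)
        mapped = {
            (length - h.end + 1, length - h.start + 1,
             "+" if h.strand == "-" else "-", round(h.score, 6))
            for h in rev
        }
        assert {(h.start, h.end, h.strand, round(h.score, 6)) for h in fwd} == mapped

    def test_sequence_shorter_than_width_yields_no_hits(self, pwm, config):
        assert sc.scan_genome(sc.GenomeSequence("g", "ACGTACGTACG"), pwm, config) == []

    def test_ambiguous_windows_skipped_and_accounted(self, pwm, config):
        rng = np.random.default_rng(7)
        seq = list("ACGT"[i] for i in rng.integers(0, 4, 500))
        seq[250] = "N"
        genome = sc.GenomeSequence("g", "".join(seq))
        hits, stats = sc.scan_genome_with_stats(genome, pwm, config)
        # one N knocks out `width` windows on each strand
        assert stats.windows_total == 2 * (500 - pwm.width + 1)
        assert stats.windows_skipped == 2 * pwm.width
        assert stats.windows_scored == stats.windows_total - stats.windows_skipped
        assert all(h.score >= config.report_score for h in hits)

    @given(dna)
    @settings(max_examples=30, deadline=None)
    def test_matches_naive_oracle_exactly(self, soft_pwm, seq):
        genome = sc.GenomeSequence("g", seq)
        cfg = sc.ScanConfig(report_score=30.0)  # low floor: compare many hits
        fast = sc.scan_genome(genome, soft_pwm, cfg)
        slow = naive_scan(genome, soft_pwm, cfg)
        assert [(h.start, h.end, h.strand, h.site_seq) for h in fast] == [
            (h.start, h.end, h.strand, h.site_seq) for h in slow
        ]
        np.testing.assert_allclose(
            [h.score for h in fast], [h.score for h in slow], atol=1e-9
        )

    def test_oracle_equivalence_on_2kb_with_implants(self, pwm, config):
        rng = np.random.default_rng(8)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 2000))
        motif = pwm.modal_string
        seq = seq[:300] + motif + seq[316:1200] + reverse_complement(motif) + seq[1216:]
        genome = sc.GenomeSequence("g", seq)
        assert sc.scan_genome(genome, pwm, config) == naive_scan(genome, pwm, config)

    def test_circular_scan_finds_origin_spanning_site(self, pwm):
        rng = np.random.default_rng(9)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 1000))
        motif = pwm.modal_string
        # split the motif across the origin: last 8 bp at the start,
        # first 8 bp at the end
        seq = motif[8:] + seq[8:992] + motif[:8]
        genome = sc.GenomeSequence("g", seq)
        linear = sc.scan_genome(genome, pwm, sc.ScanConfig())
        circular = sc.scan_genome(genome, pwm, sc.ScanConfig(circular=True))
        assert not any(h.score == pytest.approx(100.0) for h in linear)
        wrapped = [h for h in circular if h.score == pytest.approx(100.0)]
        assert len(wrapped) == 1
        assert wrapped[0].start == 993 and wrapped[0].site_seq == motif


class TestHitsIO:
    def test_tsv_round_trip(self, survey, pwm, config, tmp_path):
        genome, _, _ = survey
        hits = sc.scan_genome(genome, pwm, config)
        path = tmp_path / "hits.tsv"
        sc.genome_scan.write_hits_tsv(hits, path)
        assert sc.genome_scan.read_hits_tsv(path) == hits

    def test_bed_is_zero_based_half_open(self, tmp_path):
        hit = sc.PromoterHit("g", 101, 116, "+", 88.5, "TGGCACGAAAATTGCA")
        path = tmp_path / "hits.bed"
        sc.genome_scan.write_hits_bed([hit], path)
        chrom, start, end, name, score, strand = path.read_text().split()
        assert (chrom, start, end, strand) == ("g", "100", "116", "+")
        assert name == hit.site_seq and float(score) == pytest.approx(88.5)
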