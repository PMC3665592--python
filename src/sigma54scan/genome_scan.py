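"""Genome FASTA input and both-strand sliding-window promoter scanning.

Every window of matrix width on the forward strand and on the reverse
complement is scored; all hits at or above the scan floor are reported,
intragenic positions included — downstream steps, not the scanner,
decide which hits are biologically placed to act as promoters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import FastaError
from .pwm_core import _BASE_INDEX, PWM, ScanConfig

logger = logging.getLogger(__name__)

#: IUPAC nucleotide codes accepted in genome sequences.
IUPAC_DNA = set("ACGTRYSWKMBDHVN")

_ENCODE = np.full(256, 4, dtype=np.int8)
for _b, _i in _BASE_INDEX.items():
    _ENCODE[ord(_b)] = _i


@dataclass(frozen=True)
class GenomeSequence:
    """One replicon: id plus uppercased DNA string."""

    id: str
    seq: str

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class PromoterHit:
    """One scored motif occurrence.

    ``start``/``end`` are 1-based inclusive forward-strand coordinates;
    ``site_seq`` is the motif read 5'->3' on its own strand, i.e. the
    reverse complement of the forward-strand slice for a ``-`` hit.
    """

    genome_id: str
    start: int
    end: int
    strand: str
    score: float
    site_seq: str


@dataclass(frozen=True)
class ScanStats:
    """Window accounting for one scan: total enumerated vs skipped."""

    windows_total: int
    windows_skipped: int

    @property
    def windows_scored(self) -> int:
        return self.windows_total - self.windows_skipped


def read_fasta(path: str | Path) -> list[GenomeSequence]:
    """Read a (multi-record) FASTA/FNA file.

    Record ids are the first whitespace-delimited header token;
    sequences are uppercased and checked against the IUPAC alphabet.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FastaError(f"{path}: no FASTA records found")
    genomes: list[GenomeSequence] = []
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise FastaError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        bad = set(seq) - IUPAC_DNA
        if bad:
            raise FastaError(
                f"{path}: record {rec.id!r} contains non-IUPAC characters {sorted(bad)}"
            )
        genomes.append(GenomeSequence(id=rec.id, seq=seq))
    return genomes


def write_fasta(genomes: Sequence[GenomeSequence], path: str | Path) -> None:
    SeqIO.write(
        (SeqRecord(Seq(g.seq), id=g.id, description="") for g in genomes),
        str(path),
        "fasta",
    )


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def _window_scores(codes: np.ndarray, pwm: PWM) -> tuple[np.ndarray, np.ndarray]:
    """Raw-score and validity arrays for all windows of a coded sequence."""
    width = pwm.width
    n_win = codes.size - width + 1
    logf = pwm.log_frequencies
    safe = np.where(codes == 4, 0, codes)
    scores = np.zeros(n_win, dtype=float)
    for offset in range(width):
        scores += logf[offset, safe[offset : offset + n_win]]
    invalid = np.cumsum(np.concatenate(([0], (codes == 4).astype(np.int64))))
    valid = (invalid[width:] - invalid[:-width]) == 0
    return scores, valid


def _normalize(raw: np.ndarray, pwm: PWM) -> np.ndarray:
    denom = pwm.s_max - pwm.s_min
    if denom == 0:
        return np.full_like(raw, 100.0)
    return np.clip(100.0 * (raw - pwm.s_min) / denom, 0.0, 100.0)


def scan_genome_with_stats(
    genome: GenomeSequence, pwm: PWM, config: ScanConfig | None = None
) -> tuple[list[PromoterHit], ScanStats]:
    """Scan both strands; return hits >= ``config.report_score`` plus stats.

    The scan is linear unless ``config.circular`` is set, in which case
    the ``width - 1`` origin-wrapping windows per strand are scored too
    (a wrapped hit keeps the 1-based start of its first base; its end
    coordinate exceeds the sequence length by the wrapped amount).
    Windows containing ambiguous bases are skipped and counted.
    """
    config = config or ScanConfig()
    width = pwm.width
    seq = genome.seq
    length = len(seq)
    if length < width:
        return [], ScanStats(0, 0)

    work = seq + seq[: width - 1] if config.circular else seq
    codes = _ENCODE[np.frombuffer(work.encode("ascii"), dtype=np.uint8)]
    rc_codes = np.where(codes == 4, 4, 3 - codes)[::-1]

    fwd_raw, fwd_ok = _window_scores(codes, pwm)
    rev_raw, rev_ok = _window_scores(rc_codes, pwm)
    fwd_score = _normalize(fwd_raw, pwm)
    rev_score = _normalize(rev_raw, pwm)

    n_win = fwd_raw.size
    skipped = int((~fwd_ok).sum() + (~rev_ok).sum())
    hits: list[PromoterHit] = []
    for pos in np.nonzero(fwd_ok & (fwd_score >= config.report_score))[0]:
        hits.append(
            PromoterHit(
                genome_id=genome.id,
                start=int(pos) + 1,
                end=int(pos) + width,
                strand="+",
                score=float(fwd_score[pos]),
                site_seq=work[pos : pos + width],
            )
        )
    work_len = len(work)
    for pos in np.nonzero(rev_ok & (rev_score >= config.report_score))[0]:
        # window on the reversed sequence -> forward coordinates
        fstart = work_len - int(pos) - width + 1
        hits.append(
            PromoterHit(
                genome_id=genome.id,
                start=fstart,
                end=fstart + width - 1,
                strand="-",
                score=float(rev_score[pos]),
                site_seq=reverse_complement(work[fstart - 1 : fstart - 1 + width]),
            )
        )
    hits.sort(key=lambda h: (h.start, h.strand))  # "+" < "-" in ASCII
    stats = ScanStats(windows_total=2 * n_win, windows_skipped=skipped)
    logger.info(
        "%s: %d windows enumerated, %d skipped (ambiguous), %d hits >= %.4g",
        genome.id,
        stats.windows_total,
        stats.windows_skipped,
        len(hits),
        config.report_score,
    )
    return hits, stats


def scan_genome(
    genome: GenomeSequence, pwm: PWM, config: ScanConfig | None = None
) -> list[PromoterHit]:
    """Scan both strands and return all hits at or above the scan floor."""
    hits, _ = scan_genome_with_stats(genome, pwm, config)
    return hits


# ---------------------------------------------------------------------------
# tabular output


def hits_to_frame(hits: Sequence[PromoterHit]):
    """Hits as a DataFrame with 1-based inclusive coordinates."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "genome_id": h.genome_id,
                "start": h.start,
                "end": h.end,
                "strand": h.strand,
                "score": h.score,
                "site_seq": h.site_seq,
            }
            for h in hits
        ],
        columns=["genome_id", "start", "end", "strand", "score", "site_seq"],
    )


def write_hits_tsv(hits: Sequence[PromoterHit], path: str | Path) -> None:
    hits_to_frame(hits).to_csv(path, sep="\t", index=False)


def read_hits_tsv(path: str | Path) -> list[PromoterHit]:
    import pandas as pd

    frame = pd.read_csv(path, sep="\t", dtype={"genome_id": str})
    return [
        PromoterHit(
            genome_id=row.genome_id,
            start=int(row.start),
            end=int(row.end),
            strand=row.strand,
            score=float(row.score),
            site_seq=row.site_seq,
        )
        for row in frame.itertuples()
    ]


def write_hits_bed(hits: Sequence[PromoterHit], path: str | Path) -> None:
    """BED6: 0-based half-open; name carries the site sequence, score the
    0-100 fit score."""
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                f"{h.genome_id}\t{h.start - 1}\t{h.end}\t{h.site_seq}"
                f"\t{h.score:.4f}\t{h.strand}\n"
            )

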