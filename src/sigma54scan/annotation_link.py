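"""PTT annotation tables and promoter-to-gene assignment.

A hit is assigned to a gene when it lies on the gene's coding strand,
scores at or above the linking cutoff, and its 3' end (in gene
orientation, i.e. the -12-proximal edge) sits 1..max_upstream bp before
the first base of the start codon.  One hit may serve several genes and
one gene may carry several hits; a hit's intragenic position relative to
*other* genes never disqualifies it.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import InputError, PTTError
from .genome_scan import PromoterHit
from .pwm_core import ScanConfig

PTT_COLUMNS = [
    "Location",
    "Strand",
    "Length",
    "PID",
    "Gene",
    "Synonym",
    "Code",
    "COG",
    "Product",
]


@dataclass(frozen=True)
class GeneRecord:
    """One row of a PTT protein table.

    ``start``/``end`` are 1-based inclusive forward-strand coordinates
    with ``start <= end`` regardless of strand; the start codon begins
    at ``start`` for a ``+`` gene and at ``end`` for a ``-`` gene.
    """

    genome_id: str
    start: int
    end: int
    strand: str
    length_aa: int = 0
    pid: str = ""
    gene_name: str = ""
    synonym: str = ""
    cog_id: str = ""
    product: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise InputError(f"gene {self.synonym or self.gene_name}: start > end")
        if self.strand not in "+-":
            raise InputError(f"bad strand {self.strand!r}")

    @property
    def start_codon(self) -> int:
        """Forward coordinate of the first base of the start codon."""
        return self.start if self.strand == "+" else self.end


@dataclass(frozen=True)
class PromoterGeneLink:
    """A hit assigned to a gene it may regulate.

    ``distance`` is the gene-strand gap in bp from the motif's 3' end to
    the start codon's first base (adjacent = 1).
    """

    hit: PromoterHit
    gene: GeneRecord
    distance: int


def _clean(field: str) -> str:
    field = field.strip()
    return "" if field == "-" else field


def read_ptt(path: str | Path, genome_id: str | None = None) -> list[GeneRecord]:
    """Parse a legacy NCBI PTT protein table.

    Expects two preamble lines (replicon description, "N proteins"),
    then a tab-delimited header and one row per protein with Location
    formatted ``start..end``.  ``-`` placeholder fields map to empty
    strings.  ``genome_id`` defaults to the file stem.
    """
    path = Path(path)
    if genome_id is None:
        genome_id = path.stem
    lines = path.read_text().splitlines()
    # skip preamble up to (and including) the header row
    header_idx = None
    for i, line in enumerate(lines):
        if line.startswith("Location"):
            header_idx = i
            break
    if header_idx is None:
        raise PTTError(f"{path}: no 'Location...' header row found")
    genes: list[GeneRecord] = []
    for lineno, line in enumerate(lines[header_idx + 1 :], start=header_idx + 2):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < 9:
            raise PTTError(f"{path}:{lineno}: expected 9 tab-delimited fields")
        loc, strand = fields[0].strip(), fields[1].strip()
        if ".." not in loc:
            raise PTTError(f"{path}:{lineno}: malformed Location {loc!r}")
        s_txt, _, e_txt = loc.partition("..")
        try:
            start, end = int(s_txt), int(e_txt)
        except ValueError as exc:
            raise PTTError(f"{path}:{lineno}: malformed Location {loc!r}") from exc
        if strand not in "+-":
            raise PTTError(f"{path}:{lineno}: unknown strand symbol {strand!r}")
        try:
            length_aa = int(_clean(fields[2]) or 0)
        except ValueError as exc:
            raise PTTError(f"{path}:{lineno}: bad Length field") from exc
        try:
            genes.append(
                GeneRecord(
                    genome_id=genome_id,
                    start=start,
                    end=end,
                    strand=strand,
                    length_aa=length_aa,
                    pid=_clean(fields[3]),
                    gene_name=_clean(fields[4]),
                    synonym=_clean(fields[5]),
                    cog_id=_clean(fields[7]),
                    product=_clean(fields[8]),
                )
            )
        except InputError as exc:
            raise PTTError(f"{path}:{lineno}: {exc}") from exc
    return genes


def write_ptt(genes: Sequence[GeneRecord], path: str | Path, title: str = "") -> None:
    """Write records as a PTT table readable by :func:`read_ptt`."""
    with open(path, "w") as fh:
        fh.write(f"{title or (genes[0].genome_id if genes else 'empty')}\n")
        fh.write(f"{len(genes)} proteins\n")
        fh.write("\t".join(PTT_COLUMNS) + "\n")
        for g in genes:
            fh.write(
                "\t".join(
                    [
                        f"{g.start}..{g.end}",
                        g.strand,
                        str(g.length_aa),
                        g.pid or "-",
                        g.gene_name or "-",
                        g.synonym or "-",
                        "-",
                        g.cog_id or "-",
                        g.product or "-",
                    ]
                )
                + "\n"
            )


def link_hits_to_genes(
    hits: Sequence[PromoterHit],
    genes: Sequence[GeneRecord],
    config: ScanConfig | None = None,
) -> list[PromoterGeneLink]:
    """All (hit, gene) assignments satisfying the linking rule.

    Same strand, ``hit.score >= config.link_score``, and
    ``1 <= distance <= config.max_upstream`` where distance runs from
    the motif 3' end to the start codon in gene orientation.
    """
    config = config or ScanConfig()
    links: list[PromoterGeneLink] = []
    by_strand: dict[str, tuple[np.ndarray, list[PromoterHit]]] = {}
    for strand in "+-":
        kept = [
            h
            for h in hits
            if h.strand == strand and h.score >= config.link_score
        ]
        # motif 3' end in gene orientation: forward end for "+", forward
        # start for "-"
        edges = np.array(
            [h.end if strand == "+" else h.start for h in kept], dtype=np.int64
        )
        order = np.argsort(edges, kind="stable")
        by_strand[strand] = (edges[order], [kept[i] for i in order])

    for gene in genes:
        edges, kept = by_strand[gene.strand]
        if gene.strand == "+":
            lo = gene.start - config.max_upstream  # edge in [start-max, start-1]
            hi = gene.start - 1
        else:
            lo = gene.end + 1  # edge in [end+1, end+max]
            hi = gene.end + config.max_upstream
        left = int(np.searchsorted(edges, lo, side="left"))
        right = int(np.searchsorted(edges, hi, side="right"))
        for idx in range(left, right):
            hit = kept[idx]
            if hit.genome_id != gene.genome_id:
                continue
            distance = (
                gene.start - hit.end if gene.strand == "+" else hit.start - gene.end
            )
            links.append(PromoterGeneLink(hit=hit, gene=gene, distance=distance))
    return links


def fraction_genes_with_promoter(
    genes: Sequence[GeneRecord], links: Sequence[PromoterGeneLink]
) -> float:
    """Distinct genes carrying >= 1 link, over all genes."""
    if not genes:
        raise InputError("fraction undefined for an empty gene table")
    linked = {(l.gene.genome_id, l.gene.start, l.gene.end, l.gene.strand) for l in links}
    return len(linked) / len(genes)


def links_to_frame(links: Sequence[PromoterGeneLink]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "genome_id": l.gene.genome_id,
                "synonym": l.gene.synonym,
                "gene_name": l.gene.gene_name,
                "cog_id": l.gene.cog_id,
                "hit_start": l.hit.start,
                "hit_end": l.hit.end,
                "strand": l.hit.strand,
                "score": l.hit.score,
                "distance": l.distance,
            }
            for l in links
        ],
        columns=[
            "genome_id",
            "synonym",
            "gene_name",
            "cog_id",
            "hit_start",
            "hit_end",
            "strand",
            "score",
            "distance",
        ],
    )


def write_links_tsv(links: Sequence[PromoterGeneLink], path: str | Path) -> None:
    links_to_frame(links).to_csv(path, sep="\t", index=False)


def read_links_tsv(
    path: str | Path, genes: Sequence[GeneRecord]
) -> list[PromoterGeneLink]:
    """Rehydrate links written by :func:`write_links_tsv`.

    The linked gene is recovered from the hit coordinates: distance runs
    from the motif 3' end to the start codon, so the start codon sits at
    ``hit_end + distance`` (+ strand) or ``hit_start - distance``
    (- strand); that coordinate is matched against the gene table.
    """
    frame = pd.read_csv(path, sep="\t", dtype={"genome_id": str})
    by_codon = {(g.genome_id, g.strand, g.start_codon): g for g in genes}
    links = []
    for row in frame.itertuples():
        codon = (
            row.hit_end + row.distance
            if row.strand == "+"
            else row.hit_start - row.distance
        )
        gene = by_codon.get((row.genome_id, row.strand, int(codon)))
        if gene is None:
            raise InputError(
                f"{path}: no gene with a {row.strand} start codon at {codon} "
                f"in {row.genome_id}"
            )
        hit = PromoterHit(
            genome_id=row.genome_id,
            start=int(row.hit_start),
            end=int(row.hit_end),
            strand=row.strand,
            score=float(row.score),
            site_seq="",
        )
        links.append(PromoterGeneLink(hit=hit, gene=gene, distance=int(row.distance)))
    return links
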