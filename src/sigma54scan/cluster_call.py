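"""PKS/NRPS biosynthetic gene cluster calling from COG annotations.

Clusters are anchored on the three COG families that mark secondary
metabolite assembly lines: COG3321 (modular polyketide synthase),
COG0304 (3-oxoacyl-ACP synthase; the KSa/KSb class used by type II
systems) and COG1020 (non-ribosomal peptide synthetase).  COG0304 genes
named ``fab*`` are excluded — they are primary fatty-acid biosynthesis
enzymes, not cluster anchors.  Anchors close together in the gene order
are merged, with the intervening genes, into one cluster; transposase /
housekeeping products terminate extension so mobile elements stay
outside cluster boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .annotation_link import GeneRecord, PromoterGeneLink

ANCHOR_COGS = frozenset({"COG3321", "COG0304", "COG1020"})
PKS_COGS = frozenset({"COG3321", "COG0304"})
NRPS_COGS = frozenset({"COG1020"})

#: product keywords that mark a gene as a cluster boundary
DEFAULT_BOUNDARY_STOPLIST = (
    "transposase",
    "integrase",
    "ribosomal protein",
    "tRNA ligase",
)

DEFAULT_MAX_GAP_GENES = 5


@dataclass(frozen=True)
class GeneCluster:
    """A contiguous run of genes anchored by PKS/NRPS COGs."""

    cluster_id: str
    genome_id: str
    genes: tuple[GeneRecord, ...]
    anchors: tuple[GeneRecord, ...]

    def __post_init__(self) -> None:
        assert self.anchors, "a cluster needs at least one anchor"

    @property
    def span(self) -> tuple[int, int]:
        return (min(g.start for g in self.genes), max(g.end for g in self.genes))

    @property
    def cls(self) -> str:
        """PKS if anchored only by synthase COGs, NRPS if only by
        COG1020, hybrid otherwise."""
        cogs = {a.cog_id for a in self.anchors}
        if cogs <= PKS_COGS:
            return "PKS"
        if cogs <= NRPS_COGS:
            return "NRPS"
        return "hybrid"


@dataclass(frozen=True)
class ClusterPromoterSummary:
    cluster_id: str
    genome_id: str
    n_promoters: int
    has_promoter: bool
    anchor_direct: bool


def find_anchor_genes(genes: Sequence[GeneRecord]) -> list[GeneRecord]:
    """Genes with anchor COGs, minus fatty-acid (``fab``) COG0304 genes."""
    anchors = []
    for g in genes:
        if g.cog_id not in ANCHOR_COGS:
            continue
        if g.cog_id == "COG0304" and "fab" in g.gene_name.lower():
            continue
        anchors.append(g)
    return anchors


def _is_boundary(gene: GeneRecord, stoplist: Sequence[str]) -> bool:
    product = gene.product.lower()
    return any(word.lower() in product for word in stoplist)


def assemble_clusters(
    genes: Sequence[GeneRecord],
    anchors: Sequence[GeneRecord] | None = None,
    max_gap_genes: int = DEFAULT_MAX_GAP_GENES,
    boundary_stoplist: Sequence[str] = DEFAULT_BOUNDARY_STOPLIST,
) -> list[GeneCluster]:
    """Merge nearby anchors (and intervening genes) into clusters.

    Two consecutive anchors in the gene order join one cluster when at
    most ``max_gap_genes`` genes separate them and none of those genes
    matches the boundary stoplist.  Isolated anchors become singleton
    clusters.  Genes are grouped per genome and sorted by start, so the
    input order does not matter.
    """
    if anchors is None:
        anchors = find_anchor_genes(genes)
    anchor_set = set(anchors)
    clusters: list[GeneCluster] = []
    by_genome: dict[str, list[GeneRecord]] = {}
    for g in sorted(genes, key=lambda g: (g.genome_id, g.start, g.end)):
        by_genome.setdefault(g.genome_id, []).append(g)

    for genome_id in sorted(by_genome):
        ordered = by_genome[genome_id]
        anchor_idx = [i for i, g in enumerate(ordered) if g in anchor_set]
        if not anchor_idx:
            continue
        runs: list[list[int]] = [[anchor_idx[0]]]
        for prev, cur in zip(anchor_idx, anchor_idx[1:]):
            between = ordered[prev + 1 : cur]
            blocked = any(_is_boundary(g, boundary_stoplist) for g in between)
            if not blocked and len(between) <= max_gap_genes:
                runs[-1].append(cur)
            else:
                runs.append([cur])
        for run in runs:
            members = tuple(ordered[run[0] : run[-1] + 1])
            clusters.append(
                GeneCluster(
                    cluster_id=f"{genome_id}:c{len(clusters) + 1:03d}",
                    genome_id=genome_id,
                    genes=members,
                    anchors=tuple(g for g in members if g in anchor_set),
                )
            )
    return clusters


def summarize_cluster_promoters(
    cluster: GeneCluster, links: Sequence[PromoterGeneLink]
) -> ClusterPromoterSummary:
    """Count links landing on the cluster's genes.

    ``anchor_direct`` flags a promoter placed to drive a PKS/NRPS
    anchor itself, the stronger form of evidence for sigma-54 control
    of the pathway.
    """
    member_keys = {(g.genome_id, g.start, g.end, g.strand) for g in cluster.genes}
    anchor_keys = {(g.genome_id, g.start, g.end, g.strand) for g in cluster.anchors}
    n = 0
    direct = False
    for link in links:
        key = (link.gene.genome_id, link.gene.start, link.gene.end, link.gene.strand)
        if key in member_keys:
            n += 1
            if key in anchor_keys:
                direct = True
    return ClusterPromoterSummary(
        cluster_id=cluster.cluster_id,
        genome_id=cluster.genome_id,
        n_promoters=n,
        has_promoter=n >= 1,
        anchor_direct=direct,
    )


def clusters_to_frame(clusters: Sequence[GeneCluster]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "cluster_id": c.cluster_id,
                "genome_id": c.genome_id,
                "span_start": c.span[0],
                "span_end": c.span[1],
                "n_genes": len(c.genes),
                "class": c.cls,
                "anchor_synonyms": ",".join(a.synonym or a.gene_name for a in c.anchors),
            }
            for c in clusters
        ],
        columns=[
            "cluster_id",
            "genome_id",
            "span_start",
            "span_end",
            "n_genes",
            "class",
            "anchor_synonyms",
        ],
    )


def summaries_to_frame(summaries: Sequence[ClusterPromoterSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "cluster_id": s.cluster_id,
                "genome_id": s.genome_id,
                "n_promoters": s.n_promoters,
                "has_promoter": s.has_promoter,
                "anchor_direct": s.anchor_direct,
            }
            for s in summaries
        ],
        columns=["cluster_id", "genome_id", "n_promoters", "has_promoter", "anchor_direct"],
    )
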