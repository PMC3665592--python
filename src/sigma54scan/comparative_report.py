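"""Cross-genome comparative summaries.

Individual PWM predictions carry many false positives, but false
positives are not conserved: tabulating, across a panel of genomes, how
often a given ortholog family (COG) carries a predicted promoter
separates real regulon members (e.g. glnA/COG0174, the archetypal
sigma-54 target) from negative controls (ribosomal proteins,
elongation factors, ATP synthase).  This module also provides the
cutoff-stringency sweep over cluster promoter counts and per-taxon
aggregation of cluster summaries.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .annotation_link import GeneRecord, PromoterGeneLink, link_hits_to_genes
from .cluster_call import GeneCluster, summarize_cluster_promoters
from .errors import InputError
from .genome_scan import PromoterHit
from .pwm_core import ScanConfig

#: negative-control ortholog families: ribosomal proteins, translation
#: elongation factors, ATP synthase gamma subunit.
DEFAULT_CONTROL_COGS = ("COG0093", "COG0049", "COG0264", "COG0231", "COG0224")

#: glutamine synthetase, the archetypal sigma-54-controlled gene.
GLNA_COG = "COG0174"


@dataclass(frozen=True)
class OrthologPromoterSummary:
    """Of the genomes carrying an ortholog, how many have a predicted
    promoter upstream of it.  ``fraction`` is None when no genome
    carries the COG (absence is not evidence about promoters)."""

    cog_id: str
    n_genomes_with_cog: int
    n_genomes_with_promoter: int

    @property
    def fraction(self) -> float | None:
        if self.n_genomes_with_cog == 0:
            return None
        return self.n_genomes_with_promoter / self.n_genomes_with_cog


@dataclass(frozen=True)
class SweepRow:
    cutoff: float
    n_clusters_with_promoter: int


GenomeTable = Mapping[str, tuple[Sequence[GeneRecord], Sequence[PromoterGeneLink]]]


def ortholog_promoter_fraction(
    per_genome_tables: GenomeTable, cog_id: str
) -> OrthologPromoterSummary:
    """A genome counts in the numerator iff >= 1 of its ``cog_id`` genes
    carries >= 1 link."""
    n_with_cog = 0
    n_with_promoter = 0
    for genes, links in per_genome_tables.values():
        carriers = [g for g in genes if g.cog_id == cog_id]
        if not carriers:
            continue
        n_with_cog += 1
        carrier_keys = {(g.start, g.end, g.strand) for g in carriers}
        if any(
            (l.gene.start, l.gene.end, l.gene.strand) in carrier_keys
            and l.gene.cog_id == cog_id
            for l in links
        ):
            n_with_promoter += 1
    return OrthologPromoterSummary(
        cog_id=cog_id,
        n_genomes_with_cog=n_with_cog,
        n_genomes_with_promoter=n_with_promoter,
    )


def sweep_thresholds(
    clusters: Sequence[GeneCluster],
    hits: Sequence[PromoterHit],
    genes: Sequence[GeneRecord],
    cutoffs: Sequence[float],
    config: ScanConfig | None = None,
) -> list[SweepRow]:
    """Clusters with >= 1 linked promoter at each linking cutoff.

    Hits must have been retained down to ``config.report_score``;
    sweeping below that floor would recount hits that were never kept,
    so it is an error.  Counts are non-increasing in the cutoff.
    """
    config = config or ScanConfig()
    rows = []
    for cutoff in sorted(cutoffs):
        if cutoff < config.report_score:
            raise InputError(
                f"cutoff {cutoff} below the scan floor {config.report_score}"
            )
        cfg = ScanConfig(
            report_score=config.report_score,
            link_score=min(cutoff, 100.0),
            max_upstream=config.max_upstream,
            circular=config.circular,
        )
        links = link_hits_to_genes(hits, genes, cfg) if cutoff <= 100 else []
        n = sum(
            1
            for c in clusters
            if summarize_cluster_promoters(c, links).has_promoter
        )
        rows.append(SweepRow(cutoff=float(cutoff), n_clusters_with_promoter=n))
    return rows


def aggregate_by_group(
    cluster_summaries: Sequence,
    genome_to_group: Mapping[str, str],
) -> pd.DataFrame:
    """Per-group cluster counts: columns group, n_clusters,
    n_with_promoter; rows partition the input."""
    records = []
    for s in cluster_summaries:
        if s.genome_id not in genome_to_group:
            raise InputError(f"genome {s.genome_id!r} has no group label")
        records.append(
            {"group": genome_to_group[s.genome_id], "has_promoter": bool(s.has_promoter)}
        )
    if not records:
        return pd.DataFrame(columns=["group", "n_clusters", "n_with_promoter"])
    frame = pd.DataFrame(records)
    out = (
        frame.groupby("group", sort=True)
        .agg(n_clusters=("has_promoter", "size"), n_with_promoter=("has_promoter", "sum"))
        .reset_index()
    )
    out["n_with_promoter"] = out["n_with_promoter"].astype(int)
    return out


def ortholog_summaries_to_frame(
    summaries: Sequence[OrthologPromoterSummary],
) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "cog_id": s.cog_id,
                "n_genomes_with_cog": s.n_genomes_with_cog,
                "n_genomes_with_promoter": s.n_genomes_with_promoter,
                "fraction": s.fraction,
            }
            for s in summaries
        ],
        columns=["cog_id", "n_genomes_with_cog", "n_genomes_with_promoter", "fraction"],
    )
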