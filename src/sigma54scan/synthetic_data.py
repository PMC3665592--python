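"""Synthetic genomes with known, implanted sigma-54 promoter sites.

The generator emulates the inputs of a genome-wide promoter survey:
an i.i.d. background sequence of configurable length and GC content, a
PTT-style gene layout with strands and COG labels, and motif implants
written upstream of chosen genes at known distances.  Implant kinds:

``modal_consensus``
    the matrix's column-wise modal string (scores exactly 100), so
    recovery through scan + link is guaranteed at any cutoff;
``pwm_sample``
    a site drawn column-wise from the matrix frequencies, recovered
    exactly when its realized score clears the linking cutoff;
``decoy_far``
    a modal site placed beyond the upstream window (never linkable to
    its target gene);
``decoy_wrong_strand``
    a modal site written on the non-coding strand at an otherwise valid
    distance (a real hit, but never linked to its target gene).

Every implant is recorded in a truth table so recovery can be checked
row by row against the pipeline's output.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation_link import GeneRecord, write_ptt
from .errors import InputError
from .genome_scan import GenomeSequence, reverse_complement, write_fasta
from .pwm_core import BASES, PWM

IMPLANT_KINDS = ("pwm_sample", "modal_consensus", "decoy_far", "decoy_wrong_strand")

_SEED_MOD = 2**31


@dataclass(frozen=True)
class ImplantSpec:
    """One site to write upstream of ``target_gene`` (by gene name)."""

    target_gene: str
    distance: int
    kind: str

    def __post_init__(self) -> None:
        if self.kind not in IMPLANT_KINDS:
            raise InputError(f"unknown implant kind {self.kind!r}")
        if self.distance < 1:
            raise InputError("implant distance must be >= 1")


@dataclass(frozen=True)
class SyntheticGenomeSpec:
    """Recipe for one synthetic replicon.

    ``genes`` may be GeneRecords or raw ``(start, end, strand,
    gene_name, cog_id, product)`` tuples; they must lie within the
    sequence and not overlap one another.
    """

    length: int
    genes: tuple = ()
    implants: tuple[ImplantSpec, ...] = ()
    gc_content: float = 0.5
    seed: int = 0
    genome_id: str = "synthetic"

    def __post_init__(self) -> None:
        if self.length < 1:
            raise InputError("length must be positive")
        if not 0 < self.gc_content < 1:
            raise InputError("gc_content must lie in (0, 1)")


@dataclass(frozen=True)
class TruthRow:
    """Ground truth for one implant, in forward-strand coordinates."""

    implant_id: str
    start: int
    end: int
    strand: str
    kind: str
    site_seq: str
    target_gene: str
    distance: int


def _as_gene_records(spec: SyntheticGenomeSpec) -> list[GeneRecord]:
    genes = []
    for i, g in enumerate(spec.genes):
        if isinstance(g, GeneRecord):
            genes.append(
                g if g.genome_id == spec.genome_id else GeneRecord(
                    genome_id=spec.genome_id, start=g.start, end=g.end,
                    strand=g.strand, length_aa=g.length_aa, pid=g.pid,
                    gene_name=g.gene_name, synonym=g.synonym,
                    cog_id=g.cog_id, product=g.product,
                )
            )
        else:
            start, end, strand, name, cog, product = g
            genes.append(
                GeneRecord(
                    genome_id=spec.genome_id, start=start, end=end, strand=strand,
                    length_aa=max((end - start + 1) // 3 - 1, 0),
                    pid=str(i + 1), gene_name=name, synonym=name,
                    cog_id=cog, product=product,
                )
            )
    return genes


def _validate_layout(genes: Sequence[GeneRecord], length: int) -> None:
    ordered = sorted(genes, key=lambda g: g.start)
    for g in ordered:
        if g.start < 1 or g.end > length:
            raise InputError(f"gene {g.gene_name!r} outside [1, {length}]")
    for a, b in zip(ordered, ordered[1:]):
        if b.start <= a.end:
            raise InputError(f"genes {a.gene_name!r} and {b.gene_name!r} overlap")


def _implant_window(
    gene: GeneRecord, implant: ImplantSpec, width: int
) -> tuple[int, int, str]:
    """Forward-strand window and site strand for an implant."""
    site_strand = gene.strand
    if implant.kind == "decoy_wrong_strand":
        site_strand = "-" if gene.strand == "+" else "+"
    if gene.strand == "+":
        end = gene.start - implant.distance
        start = end - width + 1
    else:
        start = gene.end + implant.distance
        end = start + width - 1
    return start, end, site_strand


def _sample_site(pwm: PWM, kind: str, rng: np.random.Generator) -> str:
    if kind == "pwm_sample":
        freqs = pwm.frequencies
        return "".join(
            BASES[rng.choice(4, p=freqs[i] / freqs[i].sum())]
            for i in range(pwm.width)
        )
    return pwm.modal_string


def generate_genome(
    spec: SyntheticGenomeSpec, pwm: PWM, max_upstream: int = 500
) -> tuple[GenomeSequence, list[GeneRecord], list[TruthRow]]:
    """Draw the background, write the implants, return the truth table.

    Deterministic given ``spec.seed``.  Raises on infeasible placement:
    out-of-bounds windows, implants overlapping each other, a decoy_far
    distance within ``max_upstream``, or a linkable-kind distance beyond
    it.
    """
    genes = _as_gene_records(spec)
    _validate_layout(genes, spec.length)
    by_name = {g.gene_name: g for g in genes}
    if len(by_name) != len(genes):
        raise InputError("gene names must be unique to address implants")

    rng = np.random.default_rng(spec.seed)
    gc = spec.gc_content
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G T
    seq = np.array(list(BASES), dtype="U1")[
        rng.choice(4, size=spec.length, p=probs)
    ]

    truth: list[TruthRow] = []
    occupied: list[tuple[int, int]] = []
    for i, implant in enumerate(spec.implants):
        gene = by_name.get(implant.target_gene)
        if gene is None:
            raise InputError(f"implant target {implant.target_gene!r} not in layout")
        if implant.kind == "decoy_far":
            if implant.distance <= max_upstream:
                raise InputError(
                    f"decoy_far distance {implant.distance} must exceed {max_upstream}"
                )
        elif implant.distance > max_upstream:
            raise InputError(
                f"{implant.kind} distance {implant.distance} exceeds {max_upstream}"
            )
        start, end, site_strand = _implant_window(gene, implant, pwm.width)
        if start < 1 or end > spec.length:
            raise InputError(
                f"implant {i + 1} window {start}..{end} outside the sequence"
            )
        if any(not (end < s or start > e) for s, e in occupied):
            raise InputError(f"implant {i + 1} overlaps an earlier implant")
        occupied.append((start, end))
        site = _sample_site(pwm, implant.kind, rng)
        forward = site if site_strand == "+" else reverse_complement(site)
        seq[start - 1 : end] = list(forward)
        truth.append(
            TruthRow(
                implant_id=f"imp{i + 1:03d}",
                start=start,
                end=end,
                strand=site_strand,
                kind=implant.kind,
                site_seq=site,
                target_gene=implant.target_gene,
                distance=implant.distance,
            )
        )
    genome = GenomeSequence(id=spec.genome_id, seq="".join(seq))
    return genome, genes, truth


# ---------------------------------------------------------------------------
# layout builders


def periodic_gene_layout(
    n_genes: int,
    genome_length: int,
    gene_length: int = 900,
    seed: int = 0,
    genome_id: str = "synthetic",
    first_start: int | None = None,
    cogs: Mapping[int, str] | None = None,
    products: Mapping[int, str] | None = None,
) -> list[tuple]:
    """Evenly spaced genes with random strands, as spec gene tuples.

    ``cogs``/``products`` override the COG label / product of the
    gene at a given 0-based index.
    """
    if n_genes < 1:
        raise InputError("need at least one gene")
    rng = np.random.default_rng(seed)
    period = genome_length // (n_genes + 1)
    if period <= gene_length:
        raise InputError("genome too short for the requested layout")
    offset = first_start if first_start is not None else period
    genes = []
    for i in range(n_genes):
        start = offset + i * period
        if start + gene_length - 1 > genome_length:
            raise InputError("layout overruns the genome")
        strand = "+" if rng.integers(2) else "-"
        genes.append(
            (
                start,
                start + gene_length - 1,
                strand,
                f"g{i + 1:03d}",
                (cogs or {}).get(i, ""),
                (products or {}).get(i, "hypothetical protein"),
            )
        )
    return genes


def survey_spec(
    length: int = 100_000,
    n_genes: int = 20,
    n_pwm_sample: int = 10,
    n_modal: int = 5,
    n_decoy_far: int = 5,
    n_decoy_wrong_strand: int = 5,
    gc_content: float = 0.5,
    seed: int = 0,
    max_upstream: int = 500,
    genome_id: str = "synthetic",
    pwm_width: int = 16,
) -> SyntheticGenomeSpec:
    """Standard single-genome recovery benchmark.

    Implants are dealt round-robin over the genes; distances are drawn
    uniformly (linkable kinds within the upstream window, decoy_far
    beyond it) and redrawn if two windows would collide.
    """
    rng = np.random.default_rng(seed)
    genes = periodic_gene_layout(
        n_genes, length, seed=int(rng.integers(_SEED_MOD)), genome_id=genome_id
    )
    kinds = (
        ["pwm_sample"] * n_pwm_sample
        + ["modal_consensus"] * n_modal
        + ["decoy_far"] * n_decoy_far
        + ["decoy_wrong_strand"] * n_decoy_wrong_strand
    )
    taken: list[tuple[int, int]] = []
    implants = []
    for j, kind in enumerate(kinds):
        gene = genes[j % n_genes]
        start, end, strand = gene[0], gene[1], gene[2]
        for _ in range(1000):
            if kind == "decoy_far":
                distance = int(rng.integers(max_upstream + 50, max_upstream + 400))
            else:
                distance = int(rng.integers(30, max_upstream + 1))
            g = GeneRecord(
                genome_id=genome_id, start=start, end=end, strand=strand
            )
            w_start, w_end, _ = _implant_window(
                g, ImplantSpec(gene[3], distance, kind), pwm_width
            )
            if w_start < 1 or w_end > length:
                continue
            if all(w_end < s or w_start > e for s, e in taken):
                taken.append((w_start, w_end))
                implants.append(ImplantSpec(gene[3], distance, kind))
                break
        else:  # pragma: no cover - layout leaves ample room
            raise InputError("could not place all implants without overlap")
    return SyntheticGenomeSpec(
        length=length,
        genes=tuple(genes),
        implants=tuple(implants),
        gc_content=gc_content,
        seed=int(rng.integers(_SEED_MOD)),
        genome_id=genome_id,
    )


def generate_cluster_layout(
    n_clusters: int,
    genes_per_cluster: int,
    spacer_genes: int = 2,
    stoplist_insertions: int = 1,
    seed: int = 0,
    genome_id: str = "synthetic",
    first_start: int = 1000,
    gene_length: int = 900,
    intergenic: int = 200,
    strand: str = "+",
) -> list[GeneRecord]:
    """Gene-table fragment of anchor-bearing clusters for boundary tests.

    Each cluster carries anchors (COGs cycled through COG3321, COG0304,
    COG1020) at its first and last positions with tailoring genes in
    between.  Between consecutive clusters lie ``spacer_genes`` neutral
    genes plus ``stoplist_insertions`` transposase genes.
    """
    if n_clusters < 1 or genes_per_cluster < 1:
        raise InputError("cluster layout sizes must be positive")
    rng = np.random.default_rng(seed)
    anchor_cogs = ["COG3321", "COG0304", "COG1020"]
    tailoring = [
        "cytochrome P450 monooxygenase",
        "glycosyltransferase",
        "O-methyltransferase",
        "ketoreductase",
    ]
    genes: list[GeneRecord] = []
    pos = first_start
    counter = 0

    def add(name: str, cog: str, product: str) -> None:
        nonlocal pos, counter
        counter += 1
        genes.append(
            GeneRecord(
                genome_id=genome_id,
                start=pos,
                end=pos + gene_length - 1,
                strand=strand,
                length_aa=(gene_length // 3) - 1,
                pid=str(counter),
                gene_name=name,
                synonym=f"syn{counter:04d}",
                cog_id=cog,
                product=product,
            )
        )
        pos += gene_length + intergenic

    for c in range(n_clusters):
        anchor_positions = {0, genes_per_cluster - 1}
        for k in range(genes_per_cluster):
            if k in anchor_positions:
                cog = anchor_cogs[(c + k) % len(anchor_cogs)]
                add(f"bgc{c + 1}_{k + 1}", cog, "polyketide/NRPS core enzyme")
            else:
                add(
                    f"bgc{c + 1}_{k + 1}",
                    "",
                    tailoring[int(rng.integers(len(tailoring)))],
                )
        if c < n_clusters - 1:
            for s in range(spacer_genes):
                add(f"spc{c + 1}_{s + 1}", "", "hypothetical protein")
            for t in range(stoplist_insertions):
                add(f"tnp{c + 1}_{t + 1}", "", "IS5 family transposase")
    return genes


# ---------------------------------------------------------------------------
# fixture writers


def truth_to_frame(truth: Sequence[TruthRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "implant_id": t.implant_id,
                "start": t.start,
                "end": t.end,
                "strand": t.strand,
                "kind": t.kind,
                "site_seq": t.site_seq,
                "target_gene": t.target_gene,
                "distance": t.distance,
            }
            for t in truth
        ],
        columns=[
            "implant_id",
            "start",
            "end",
            "strand",
            "kind",
            "site_seq",
            "target_gene",
            "distance",
        ],
    )


def write_fixture(
    outdir: str | Path,
    genome: GenomeSequence,
    genes: Sequence[GeneRecord],
    truth: Sequence[TruthRow],
) -> dict[str, Path]:
    """Write FASTA + PTT + truth TSV under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": outdir / f"{genome.id}.fna",
        "ptt": outdir / f"{genome.id}.ptt",
        "truth": outdir / f"{genome.id}.truth.tsv",
    }
    write_fasta([genome], paths["fasta"])
    write_ptt(list(genes), paths["ptt"], title=genome.id)
    truth_to_frame(list(truth)).to_csv(paths["truth"], sep="\t", index=False)
    return paths
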