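# Methods

## Scoring model

The σ⁵⁴ −24/−12 element is modeled as a positional weight matrix over
A/C/G/T with a fixed width of 16 bp, matching the consensus
`TGGCACG-N4-TTGC(T/A)` (7 consensus bases, a 4-bp spacer, 5 more
consensus bases with the final position degenerate T/A). Counts are
smoothed with an additive pseudocount κ (default 0.5 per base per
column) so log frequencies stay finite when a base is unobserved. A
window's raw score is the sum of per-column log frequencies; it is
reported on a 0–100 scale obtained by linear rescaling between the raw
scores of the column-wise worst and best strings. This scale is strictly
monotone in the window's likelihood under the matrix, puts the consensus
at exactly 100, and makes the familiar working thresholds meaningful:
hits are retained from a fit score of 65, and promoter-gene assignment
requires 75. Experimentally validated σ⁵⁴ promoters typically score in
the 80s–90s on this kind of scale, with some GC-rich-genome promoters in
the low-to-mid 70s, which is why the linking cutoff sits at 75 rather
than higher.

The shipped default matrix is consensus-derived: each consensus column
places all of its count mass (scale 186, mirroring the size of curated
σ⁵⁴ promoter collections) on the consensus base, the spacer columns are
uniform, and the final column splits evenly between T and A. It is a
deliberately sharp matrix — adequate for demonstrating and testing the
pipeline, and exactly reproducible from the consensus — but it is not a
substitute for a matrix estimated from aligned experimental sites, which
users can supply as a tab-delimited count file (`read_pwm`).

## Scanning

Every window of matrix width on the forward strand and on the reverse
complement is scored; coordinates are reported 1-based inclusive on the
forward strand, with a `-` hit's site sequence read 5′→3′ on its own
strand. All hits at or above the scan floor are kept, including
intragenic ones: whether a hit is positioned to act as a promoter is
decided by the linking step, not the scanner. Windows containing
ambiguous IUPAC codes are skipped and counted in the scan statistics.
Replicons are scanned linearly by default; a `circular` flag adds the
width−1 origin-wrapping windows per strand (at most ~30 windows per
replicon, so the default omission is negligible). Scoring is vectorized
over the genome, and the standalone `score_window` accumulates the same
per-column terms left to right so that rescoring a reported site
reproduces its scan score bit for bit — several recovery checks rely on
that exact agreement.

## Promoter-gene linking

A hit is assigned to a gene when (i) it lies on the gene's coding
strand, (ii) its score is at or above the linking cutoff (default 75),
and (iii) the gap from the motif's 3′ end (the −12-proximal edge, in
gene orientation) to the first base of the start codon is between 1 and
500 bp inclusive. The inclusive upper bound follows the "within 500 bp"
reading; both the bound and the anchor edge are configuration fields,
since the opposite conventions are defensible. Hits overlapping the
start codon (gap ≤ 0) are not linked — they are not upstream. A hit may
serve several genes (operon-internal genes are linkable; no operon model
is imposed) and a gene may carry several hits. The per-gene summary
statistic is the fraction of genes with at least one linked hit.

## Cluster calling

Anchor genes are those annotated COG3321 (modular PKS), COG0304
(3-oxoacyl-ACP synthase) or COG1020 (NRPS), except COG0304 genes whose
name contains "fab" (case-insensitive), which belong to primary
fatty-acid metabolism. Published cluster catalogues of this kind were
assembled by manual curation; as a deterministic proxy, consecutive
anchors are merged — together with all intervening genes — when at most
`max_gap_genes` (default 5) genes separate them and none of the
intervening products matches a boundary stoplist (default: transposase,
integrase, ribosomal protein, tRNA ligase). Isolated anchors form
singleton clusters; cluster membership therefore runs from the first to
the last anchor of a merged run. A cluster is classed PKS if its anchors
are all synthase COGs (COG3321/COG0304 — COG0304-only clusters are PKS,
the type II KSα/KSβ case), NRPS if all COG1020, hybrid otherwise. The
gene-count gap criterion is robust to intergenic-length variation but
cannot reproduce judgment calls of manual curation; counts from this
module are comparable across parameter settings, not a re-derivation of
any hand-curated catalogue. A cluster "has a promoter" when any of its
genes carries a link; "anchor-direct" when a linked gene is itself an
anchor.

## Null model

The false-positive baseline shuffles the genome and re-runs scan + link
with the original gene coordinates, reporting the fraction of genes that
still gain a predicted promoter. The default shuffle is a uniform
permutation of nucleotides (exact mononucleotide conservation), the
minimal model consistent with "sequence-randomized"; a dinucleotide-
preserving alternative (random Eulerian walk on the base-transition
multigraph, Altschul–Erickson style) is available via `mode="dinuc"`
since dinucleotide structure inflates motif hit rates in skewed genomes.
Where a single randomized genome would give one number, the default is 5
replicates with per-replicate reporting, quantifying the Monte-Carlo
spread. Replicate seeds derive from one user seed, so runs are
reproducible and cutoff comparisons can be made on paired shuffles.

## Comparative reports

Ortholog-level validation counts, for a COG family across a genome
panel, the fraction of COG-carrying genomes whose family member has a
linked promoter. Genomes lacking the family are excluded from the
denominator and an empty denominator yields an undefined (None)
fraction, not zero — absence of the ortholog says nothing about its
promoter. The positive control is *glnA* (COG0174); default negative
controls are ribosomal proteins (COG0093, COG0049), elongation factors
(COG0264, COG0231) and ATP synthase γ (COG0224). The control list is
configuration, not hard-coded, because published control sets are not
fully unambiguous. Threshold sweeps re-link retained hits at increasing
cutoffs (an error below the scan floor, where hits were never kept) and
count promoter-bearing clusters; counts are non-increasing by the subset
property. Per-taxon aggregation is a strict partition of the cluster
summaries.

## Synthetic data

The generator emulates the survey's inputs: an order-0 i.i.d. background
at a chosen GC content (0.50 default; 0.65 approximates actinobacterial
genomes), non-overlapping genes (default 900 bp, a typical bacterial
gene length) with strands and COG labels, and implants written upstream
of target genes at stated distances. `modal_consensus` implants score
exactly 100; `pwm_sample` implants are drawn column-wise from the matrix
frequencies; `decoy_far` sits beyond the upstream window on the correct
strand; `decoy_wrong_strand` sits at a valid distance on the wrong
strand. Implants may overlap gene bodies (as real promoters overlap
neighboring genes) but never each other; every implant is recorded in a
truth table keyed by exact coordinates. The standard benchmark
(`survey_spec`) is a 100-kb genome with 20 evenly spaced genes, 10
pwm_sample + 5 modal implants and 5 + 5 decoys, with distances drawn
uniformly and redrawn on window collision.

What the generator does not emulate: higher-order sequence composition,
operon structure, gene-length/intergenic-length distributions, mobile
elements, or any transcriptional readout. Passing recovery tests
therefore demonstrates correctness of the scanning/linking machinery
under the model's own assumptions — not calibration of the thresholds on
real genomes, where composition and annotation quality shift both the
hit rate and the baseline.

## Numerical choices and degenerate inputs

- log(0) (possible only at pseudocount 0) is floored at the log of the
  smallest positive double, far below any attainable log frequency, so
  scores stay finite and ordered.
- A fully uniform matrix has S_min = S_max; every window then scores 100
  by convention (all windows are modal).
- Modal/anti-modal strings break frequency ties in base order A<C<G<T;
  the default matrix's spacer columns and T/A column are tied, so any
  base there still attains the column maximum and scores 100.
- Hits sort by (start, strand) with `+` before `-`; gene tables sort by
  (genome, start) — outputs are diff-stable.
- Sequences shorter than the matrix width scan to an empty hit list; an
  empty gene table makes the gene fraction an error rather than 0/0.
- All stochastic components consume `numpy.random.default_rng` seeds
  derived from a single user seed (kept below 2³¹).

## Problem sizes

The test suite and the acceptance script run on the 100-kb benchmark
genome (≈200,000 scored windows per scan), 5 shuffle replicates, a
three-genome ortholog panel, and a six-cluster synthetic genome —
seconds on one CPU. Larger genomes scan at roughly 10⁷ windows/s/core;
a 4.6-Mb chromosome takes a few seconds.

## Known limitations

- The shipped consensus matrix overstates conservation relative to a
  site-derived matrix; absolute background hit rates with it are not
  calibrated to published per-genome percentages.
- Cluster boundaries are a deterministic heuristic for what was
  historically a manual call; gap and stoplist defaults are exposed.
- Linking is gene-based, not operon-based: a promoter upstream of an
  operon's lead gene is not credited to downstream genes.
- σ⁵⁴ transcription additionally requires enhancer-binding-protein
  co-activation; sequence scanning alone cannot establish that a
  predicted promoter is active.
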