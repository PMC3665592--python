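# sigma54scan

Genome-wide prediction of σ⁵⁴ (RpoN) promoters in bacterial genomes, with
promoter-to-gene assignment, PKS/NRPS biosynthetic gene cluster calling,
a shuffled-genome false-positive baseline, and cross-genome ortholog
reports. It is written for microbial genomicists and natural-product
researchers who want to ask, for a genome or a panel of genomes: which
genes — and in particular which polyketide synthase (PKS) and
non-ribosomal peptide synthetase (NRPS) gene clusters — sit downstream of
candidate σ⁵⁴ promoters?

## The model

σ⁵⁴ recognizes a 16-bp −24/−12 element with consensus
`TGGCACG-N4-TTGC(T/A)`; the GG (−24) and GC (−12) dinucleotides are the
most conserved positions. The element is modeled as a positional weight
matrix (PWM): per-position base counts c_i(b) smoothed with a pseudocount
into frequencies

    f_i(b) = (c_i(b) + κ) / (N_i + 4κ),      κ = 0.5 by default.

A window w of matrix width gets the raw log-likelihood score
S(w) = Σ_i log f_i(w_i), reported on a normalized 0–100 "fit" scale

    score(w) = 100 · (S(w) − S_min) / (S_max − S_min),

where S_min and S_max are the raw scores of the column-wise worst and
modal strings. The scale is strictly monotone in likelihood: the
consensus scores 100, the worst string 0.

The pipeline scans every window on both strands (intragenic positions
included), keeps hits scoring ≥ 65, and calls a hit a putative promoter
for a gene when it scores ≥ 75, lies on the gene's coding strand, and its
3′ edge falls 1–500 bp upstream of the start codon. Clusters are anchored
on COG3321 (modular PKS), COG0304 (3-oxoacyl-ACP synthase, excluding
`fab*` fatty-acid genes) and COG1020 (NRPS). Because a 16-bp PWM fires
often by chance, the package also measures the false-positive baseline on
composition-preserving shuffles of the genome and supports ortholog-level
comparisons (e.g. *glnA*/COG0174 versus ribosomal-protein controls)
across genome panels, where false positives fail to replicate.

## Worked example

```python
import sigma54scan as sc

pwm = sc.load_default_pwm()
config = sc.ScanConfig()          # report 65, link 75, window 500 bp

spec = sc.survey_spec(seed=11)    # 100 kb, 20 genes, 25 implants
genome, genes, truth = sc.generate_genome(spec, pwm)

hits = sc.scan_genome(genome, pwm, config)
links = sc.link_hits_to_genes(hits, genes, config)
native = sc.fraction_genes_with_promoter(genes, links)
null = sc.estimate_false_positive_rate(genome, genes, pwm, config,
                                       n_reps=5, seed=17)
```

prints, via the obvious `print` statements:

```
hits >= 65: 882
links at >= 75 within 500 bp: 16
native gene fraction: 0.75
shuffled gene fraction (mean of 5): 0.080
consensus score: 100.0
-24 GG->TT mutant score: 83.2
```

The synthetic genome carries 15 linkable implants (10 sampled from the
PWM, 5 exact consensus) plus 10 decoys; the 16 links recover all 15 (one
gene also picks up a background hit), so 75 % of genes have a predicted
promoter, against a ~8 % baseline once the sequence is shuffled — the gap
is the signal attributable to the implanted sites. Mutating the conserved
−24 GG to TT knocks the consensus window from 100 to 83, the scoring
contrast used to confirm that the −24 element drives recognition.

The same steps are available from the shell:

```
sigma54scan simulate --seed 5 --outdir fx
sigma54scan scan  --fasta fx/synthetic.fna --out hits.tsv --bed hits.bed
sigma54scan link  --hits hits.tsv --ptt fx/synthetic.ptt \
                  --genome-id synthetic --out links.tsv
sigma54scan clusters --ptt fx/synthetic.ptt --genome-id synthetic \
                  --links links.tsv --out clusters.tsv
sigma54scan null  --fasta fx/synthetic.fna --ptt fx/synthetic.ptt \
                  --reps 5 --seed 17 --out null.tsv
sigma54scan compare --manifest genomes.tsv --out orthologs.tsv
```

Inputs are plain FASTA/FNA genomes and legacy NCBI PTT protein tables;
outputs are TSV (and BED6 for hits). The shipped PWM is consensus-derived
(see `docs/methods.md`); a site-derived matrix in the same tab-delimited
format can be supplied with `--pwm`.

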