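# Methods

## Problem setting

In flowering plants the endosperm is triploid: two maternal genome
copies and one paternal copy. Under purely dosage-driven expression,
RNA-seq reads from a cross of two polymorphic accessions should
therefore split 2:1 between the maternal and paternal allele at every
gene. Genomic imprinting — parent-of-origin-dependent silencing —
shows up as a reproducible deviation from that ratio in *both*
reciprocal crosses (A×B and B×A), which separates imprinting from
accession-specific (strain) expression bias: a strain effect favours
the same accession in both crosses and therefore favours the *maternal*
allele in one cross but the *paternal* allele in the other.

`imprintkit` implements the counting rules, the statistical test and
the benchmarking machinery for this design. Genes with significant
maternal excess over the expected ratio are called MEGs (maternally
expressed imprinted genes); paternal excess gives PEGs.

## Allelic counting

Reads are assigned to parental alleles at known biallelic SNPs:

* The reference genome is masked with `N` at every SNP position before
  alignment so the aligner cannot systematically favour reference
  alleles.
* Only uniquely mapped reads count (NH tag equal to 1 when the aligner
  reports it, otherwise MAPQ ≥ 20).
* A base at a SNP must have phred quality ≥ 20.
* **One SNP per read**: a read overlapping several SNPs contributes a
  single allele observation, at the leftmost SNP with a usable
  (high-quality, ref- or alt-matching) base. Counting every covered SNP
  would replicate the same molecule several times and overstate the
  evidence. Mates of a pair covering the same SNP are counted once for
  the same reason; mates covering different SNPs are treated as
  independent observations.
* Bases matching neither allele, and low-quality bases, are tallied
  separately but never counted.
* SNP counts are summed per gene using exon models; SNPs inside no gene
  or inside two genes are dropped with a logged tally.
* Genes with fewer than `min_total` (default 10) allelic reads summed
  over both parents and both crosses are unassessable and removed.

Coordinates are 1-based in VCF/GFF3 files and 0-based half-open in all
internal structures. No duplicate-read removal is performed by default
(`--dedup` exists); allele-specific counts at a single SNP are already
capped at one observation per fragment.

## The paired negative-binomial GLM test

For each gene the four (or `2 × n_crosses`) allelic counts are modelled
as negative binomial with a log link:

    log mu_gj = offset_j + cross(j) + beta_g * maternal(j)

The *cross* blocking factor treats the two allelic counts of one cross
as paired samples. This is the key design decision: total expression
noise (biological replication, sequencing depth) is absorbed by the
cross term, and the parent effect `beta_g` is estimated from the
allelic ratio *within* crosses, whose sampling noise is essentially
binomial. `beta_g` is tested against zero with a likelihood-ratio test
(deviance difference against the cross-only model, 1 df, two-sided).

Offsets are log *effective library sizes*: raw column totals times TMM
normalization factors (trimmed mean of M-values; 30% two-sided trim on
log-ratios, 5% on log-abundance, delta-method precision weights,
reference column the one whose upper count quartile is closest to the
column mean). Because the bulk of genes follows the 2:1 ratio, TMM
yields maternal:paternal effective library sizes of ≈ 2 within each
cross, so the null ratio is absorbed by normalization and `beta_g = 0`
corresponds to 2:1. This holds only when most genes are unimprinted
genome-wide; for datasets where that assumption fails,
`normalization="offset"` instead encodes the null proportion `p0` as a
fixed offset (`log(N_c * p0)` / `log(N_c * (1-p0))` per cross) and
leaves depth correction to the raw totals.

### Dispersion estimation

NB dispersions are estimated by maximizing the Cox-Reid adjusted
profile likelihood (APL): the NB log-likelihood at the fitted GLM minus
half the log-determinant of the Fisher information `X'WX`, which
corrects the profile for the estimated coefficients. Three modes:

* **common** — one value maximizing the mean APL over all genes;
* **trended** — genes are binned by average log2 CPM (20 equal-size
  bins, ≥ 100 genes each), a common dispersion is estimated per bin and
  log-dispersion is linearly interpolated across bin medians;
* **tagwise** (default) — per-gene APL evaluated on a 13-point log2
  grid spanning ±6 doublings around the trend; a moving average of the
  APL across abundance-ordered genes (window `(10/G)^0.23 · G` genes)
  provides a shared likelihood, and `APL_g + prior_n · APL_shared` is
  maximized with `prior_n = prior_df / residual_df`. `prior_df`
  defaults to 10 and is exposed; infinite `prior_df` returns the trend
  (complete shrinkage).

With two crosses the residual df is 1, so per-gene estimates are very
noisy and the empirical-Bayes shrinkage is what makes tagwise estimates
usable. On endosperm allelic tables the estimated dispersions are tiny
(~1e-4): the paired design cancels the count overdispersion, as
intended.

### Numerical choices

* IRLS with batched per-gene weighted least squares (all genes share
  the design matrix), deviance-based step halving, at most 50
  iterations, relative deviance tolerance 1e-8. Non-converged genes are
  reported with `p = NaN` and a logged warning.
* The linear predictor is clipped to ±30, which bounds fitted means
  away from 0/overflow when a parent has no reads at all.
* The Cox-Reid log-determinant uses a *pseudo*-determinant: eigenvalues
  below 1e-8 of the largest are excluded. When a gene has zero counts
  for one parent the MLE sits on the parameter-space boundary and
  `X'WX` is singular in one direction; regularizing that direction with
  a ridge instead would leak a spurious dispersion dependence into the
  APL and inflate tagwise estimates for exactly the strongly imprinted
  genes.
* The NB deviance uses a `log1p` formulation so that the zero-dispersion
  limit reproduces the Poisson deviance to machine precision.
* Genes with one parent entirely at zero get a 0.5-count working
  adjustment *only* for the displayed `log2_fold_effect`; the test
  statistic uses the untouched likelihood.
* BH adjustment is the standard step-up (via statsmodels), NaN p-values
  excluded from the number of tests; ties are resolved by stable gene
  order, so output is deterministic.

Calls: `fdr < fdr_level` (default 0.05) with positive effect ⇒ MEG,
negative ⇒ PEG.

## Fisher baselines

Two classical count-test baselines share the same FDR/classification
path:

* **Fisher-summed** — one two-sided Fisher's exact test per gene on
  counts summed over the crosses.
* **Fisher-combined** — one Fisher test per cross; the two p-values are
  combined by Stouffer's method, `Z = (z1+z2)/√2` with
  `z_i = Φ⁻¹(1−p_i)`. Boundary p-values are clipped to the nearest
  representable number. Combining two-sided p-values naively can let
  opposite-direction imbalance in the two crosses reinforce rather than
  cancel; a direction-aware variant (signed z by maternal excess) is
  available behind `directional=True`.

The 2×2 table construction is configurable. The default, `margin`,
tests the gene's maternal/paternal counts against the rest of the
library (`[[m, p], [M−m, P−p]]`): since nearly all genes follow the
expected ratio, the library margin embodies the null, and its large
counts make the test close to a one-sample test of the gene's
proportion — this is the construction used by the earlier plant
imprinting studies these baselines emulate. The alternative,
`expected`, compares against a pseudo-count column at the gene's own
depth apportioned at the null ratio (`[[m, p], [round(T·p0), T−·]]`);
the expected column then carries as much sampling variance as the
observation, which roughly halves the effective information and makes
the baseline noticeably more conservative. Benchmarks here default to
`margin` as the historically faithful variant.

## The synthetic-data generator

`simulate_dataset` emulates an endosperm allelic counting experiment:

* per-gene log2 baseline `beta0 ~ Normal(2, 3)` (mean/SD of log2
  expression typical of published endosperm allelic count tables), NB
  mean `mu = 2^beta0`;
* NB dispersion trend `phi(mu) = 4/mu + 0.1`, the documented default of
  the generator family this simulation follows;
* two crosses with identical per-gene means (no differential
  expression, no outliers), totals drawn independently per cross;
* every total split binomially: maternal successes at the gene's true
  maternal proportion (2/3 at the null);
* 15,000 genes; 200 spike-ins — 50 each of strong MEGs (99% maternal),
  weak MEGs (85%), strong PEGs (34%) and weak PEGs (48%);
* spike-ins are drawn among genes whose totals pass the ≥ 10 count
  filter. Spiking only changes the allelic split, never the totals, so
  eligibility is well defined before spiking; restricting to eligible
  genes makes every spike-in assessable, which is what makes
  sensitivities on the panel interpretable (`spike_eligible_only=False`
  disables this);
* optionally, `n_strain_bias` extra genes with an accession-specific
  fold change, whose maternal proportion is high in one cross and low
  in the reciprocal — the confounder the reciprocal design exists to
  reject;
* a single integer seed drives all randomness; identical configs are
  bit-reproducible.

What the generator does **not** emulate: seed-coat/maternal-tissue
contamination, mapping bias toward either parental genome, uneven SNP
coverage along transcripts, library-preparation batch effects, or
replicate-level biological variation beyond NB noise. Passing
benchmarks on these simulations therefore demonstrates correctness of
the statistical machinery under its own assumptions, not robustness to
those real-data artefacts.

## Benchmarking

Spike-ins are the positive class, all other genes negatives; genes
removed by the count filter count as "not called" (score 1 in ROC
sweeps), so TPRs are always out of the full panel of 200. Reported per
method: true/false positives at the FDR cut-off, per-category TPR, ROC
(threshold sweep over p-values), TPR/FPR per count quartile (rank-based
equal-size bins, ties to the lower bin), top-N candidate lists
(deterministic p → |effect| → gene-id ranking with optional
maternal-fraction post-filters), pairwise Jaccard/Venn concordance, and
saturation curves (binomial thinning of every count cell at proportion
q, full re-analysis per replicate, 10 replicates by default; q = 1 is
the identity and reproduces the full run exactly).

The test suite runs the full benchmark at its standard size (15,000
genes, five seeds, ~20 s per seed); unit and property tests use 2,000–
6,000 gene simulations. Cross-checks against independent
implementations (TMM factors and fixed-dispersion GLM fits against the
Bioconductor edgeR package via Rscript; Poisson-limit LRTs against
statsmodels; Fisher p-values against exhaustive hypergeometric
enumeration; BH against a hand-coded step-up) pin the numerics.

## Known limitations

* With two crosses and no replicates the residual df is 1; tagwise
  dispersions are then dominated by the shrinkage prior. This mirrors
  the intended workflow, but `prior_df` deserves care on richer
  designs.
* NB-GLM-based detection counts on simulated benchmarks are sensitive
  to the exact dispersion-estimation recipe; different generations of
  moderated-dispersion estimators legitimately differ by ~10–20% in
  spike-in sensitivity at matched false-positive counts. The Fisher
  baselines carry no such estimation freedom and reproduce tightly.
* The margin Fisher construction degenerates (p = 1) when the table
  holds a single gene, since there is no "rest of the library".
* `classify_imprinted` uses direction only; it applies no minimum
  allelic-bias cut-off. Historical bias filters (e.g. ≥ 85% maternal
  for MEGs) are available as post-filters in `top_n`.
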