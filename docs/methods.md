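# Methods

## The inference chain

The package targets a specific population-genetic situation: an admixed,
predominantly indicine cattle population in which one X-chromosome segment of
taurine origin has been driven to high frequency by selection on male
fertility. Three estimators are chained:

**Window painting.** Haplotypes of `window_size` (default 10) consecutive
SNPs are counted in a taurine and an indicine reference panel. For a window
haplotype with relative panel frequencies `p_Bt` and `p_Bi`, the
taurine-origin score is `b = p_Bt / (p_Bt + p_Bi)`; calls are taurine for
`b > 0.6`, indicine for `b < 0.4`, undetermined on the closed interval
between (the thresholds are strict inequalities, so the boundary values fall
to undetermined). Windows are disjoint and consecutive; trailing markers that
do not fill a window are dropped with a warning. A haplotype unseen in both
panels, or a window containing a missing genotype, yields no call and is
excluded from denominators rather than imputed or smoothed — pseudocounts
would silently bias `b` toward 0.5. Only haploid (male X) genotypes are
painted; diploid data would need phasing, which is out of scope. Painting is
fully deterministic.

**Supervised admixture.** With reference allele frequencies fixed, each
animal's taurine proportion `alpha` is the single parameter of a binomial
mixture (`q_m = alpha p_t,m + (1-alpha) p_i,m`), estimated by EM over allele
draws (one per marker on X, two for diploids). The likelihood is unimodal in
one dimension; EM is monotone in the log-likelihood and is verified in tests
against a 1e-4 grid search. Reference frequencies are clipped to
[0.001, 0.999] so the log-likelihood stays finite; markers with equal
(clipped) frequencies in both panels carry no information and are skipped.
With no informative markers the animal is flagged unidentifiable and
reported at alpha = 0.5 with `converged = False`.

**Mixed-model association.** Per trait, `y = X beta + s a_j + u + e` with
`u ~ N(0, sigma_g2 K)` and `e ~ N(0, sigma_e2 I)`. Fixed effects are an
intercept plus full-rank dummies (first level dropped) for contemporary
group and the year-month-of-birth interaction. `K` is a VanRaden-style
genomic relationship matrix: counts centered by per-marker means, the
cross-product scaled by the summed ploidy-appropriate binomial variance
`sum_m k p_m (1-p_m)`; monomorphic markers are excluded and missing
genotypes mean-imputed (their centered contribution is zero). The original
analysis used a pedigree-based polygenic effect; no pedigree exists in the
synthetic design, so the GRM is this package's substitute, and the
substitution is validated only on synthetic data.

REML uses one spectral decomposition of `K`: in the eigenbasis the
covariance is diagonal, and the restricted likelihood is a 1-D function of
`lambda = sigma_g2 / sigma_e2`, scanned on a 121-point log10 grid over
[-6, 6] and refined by bounded Brent search. A flat profile (e.g. `K = I`,
where only `sigma_g2 + sigma_e2` is identifiable) is detected and returns
the boundary solution `sigma_g2 = 0` with `converged = False`. Variance
components are estimated once per trait under the null (no-SNP) model and
reused for every SNP — the EMMAX approximation; exact per-SNP REML is
available via `exact=True` / `--exact-reml`. SNP effects and SEs come from
GLS with `V = sigma_g2 K + sigma_e2 I`; p-values are 1-df Wald chi-square,
reported raw without multiple-testing correction.

Hemizygous males are coded 0/1 allele copies, so effects are per single
copy — half the scale a 0/2 coding would give. The per-SNP share of genetic
variance is `%Va = 100 * 2 p q a^2 / sigma_g2` with the diploid `2pq` form
regardless of ploidy, because that is the published formula for this
quantity; it can exceed 100 and is then reported as-is with a warning.

## The synthetic study

No per-sample genotypes or phenotypes from the original populations are
publicly retrievable, so the generator emulates the study design and the
analysis is validated by parameter recovery.

- **Allele frequencies.** Balding-Nichols: ancestral `p ~ U(0.05, 0.95)` per
  marker; each population draws from `Beta(p(1-F)/F, (1-p)(1-F)/F)` with
  `F = fst = 0.3` (strong taurine/indicine divergence), clipped to
  [0.01, 0.99] to avoid monomorphic markers. The implied divergence is
  checked against an independent Hudson-estimator computation.
- **Within-breed LD.** The painting method's discrimination comes from
  breed-level haplotype structure: real 10-SNP windows segregate a limited
  number of haplotypes per breed. Marker-independent draws destroy that
  structure and leave the frequency-ratio classifier with an irreducible
  ~7% false-taurine window rate at fst 0.3 even with perfect panel
  frequencies. The default generator therefore draws X haplotypes
  window-wise from founder pools: 30 founder haplotypes per population per
  window (Dirichlet(1) frequencies), sampled by panels and targets alike.
  Genome-background markers are drawn marker-independently — at ~100 kb
  chip spacing inter-marker LD is weak. Setting
  `n_founder_haplotypes = None` gives the fully independent-marker model.
- **Ancestry mosaic.** Per animal, a two-state switch process along genetic
  distance: breakpoints Poisson at `switch_rate_per_morgan = 20` per Morgan
  over `morgans = 1.0` (roughly twenty generations since admixture), each
  segment taurine with probability `baseline_taurine = 0.025`. Inside the
  tract (`tract_interval`, default 5 windows) the haplotype is taurine with
  probability `tract_taurine_freq = 0.67`, and all taurine tract copies are
  one swept founder lineage — a hard selective sweep, which is what makes a
  single tag SNP informative.
- **Candidate SNP.** The swept lineage carries the favourable allele, whose
  frequencies are set near-fixed between ancestries (0.98 taurine / 0.02
  indicine), emulating the perfect-LD tag SNPs of the original study. With
  `tag_candidate = False` the candidate is instead forced to be
  ancestry-uninformative (0.5 / 0.5) — the clean null for end-to-end
  calibration runs.
- **Panels.** 3,666 taurine and 1,105 indicine haplotypes, the reference
  sizes of the original design.
- **Phenotypes.** `y = group effects + s a + u + e` per trait, with
  `u = sigma_g K^{1/2} z`. Total baseline variance is fixed at 1.0 (trait
  units are arbitrary) and split by `h2 = 0.4`; contemporary-group effects
  are N(0, 0.5²) over 5 groups, year-month effects N(0, 0.3²) over 6 levels,
  and the default candidate effect is 1.0 per allele copy — a major QTL, in
  line with the large published variance shares. Each trait draws its own
  polygenic and residual vectors from trait-indexed seeds.
- **Background markers.** `n_background_snps = 1000` tract-free markers on a
  separate chromosome stand in for the genome-wide chip SNPs used for global
  ancestry; the same animals receive an independent baseline mosaic there.
  Estimating alpha on these markers (rather than the tract-bearing X) is
  what reproduces the tract-versus-genome-wide dissociation: on a 100-window
  X, a 5-window tract mechanically adds ~5% to carriers' chromosome-wide
  alpha.

What the generator does **not** emulate: pedigree structure and
generation-by-generation breeding, female/diploid X dosage, chip
ascertainment bias, genotyping error, mutation or gene conversion within the
swept lineage, and recombination decay at the tract edges. Passing recovery
tests therefore show that the estimators are correct under the stated model,
not that real-data values would be reproduced.

## Numerical and design choices

- Stage seeds derive deterministically from one master seed
  (`seed * 1000003 + crc32(stage)` mod 2^31), so stages re-run independently
  yet reproducibly, and a fixed config + seed reproduces every output file
  byte for byte.
- VCF is the single genotype interchange format; internal coordinates are
  1-based (VCF convention) and BED output 0-based half-open — the only
  coordinate translation in the codebase. Haploid GT fields are written as
  single alleles; multi-allelic records and mixed ploidy are rejected, not
  coerced.
- Reported taurine proportions default to the classified-only denominator
  (#taurine / (#taurine + #indicine)); the all-windows denominator (calls
  including undetermined) is available everywhere. Because it is unclear how
  a group summary over a window range should average (per window then group,
  or per animal then group), both summaries are emitted.
- Calibration studies (`calibration.py`) use n = 500 animals with a
  400-marker GRM and replicate counts of 200 (recovery means) or 1,000
  (type-I error); genotypes are redrawn every replicate except in the
  type-I study, where ten genotype draws each share one eigendecomposition
  across 100 phenotype replicates. The tested SNP there is fixed at
  frequency 0.5 in both ancestries so it is never monomorphic and not
  confounded with ancestry.

## Known limitations

- The EMMAX approximation slightly misstates SEs for SNPs explaining a large
  variance share; `--exact-reml` removes this at per-SNP cost.
- Per-animal admixture estimates have sampling SD ≈ 0.025 at 5,000 markers
  and fst 0.3; individual estimates outside ±0.05 are expected for a few
  animals in twenty.
- The painting classifier's error rates depend on the assumed founder
  diversity; with marker-independent draws the background false-taurine
  rate rises to ~7% and group contrasts blur accordingly.
- `%Va` uses the diploid 2pq form on haploid X data by design; for a
  hemizygous locus the within-population variance is `pq a^2`, so the
  reported share is twice the strictly hemizygous value.
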