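# Methods

## The model

`tenderqtl` implements a GBLUP association pipeline for Warner–Bratzler
shear force (WBSF, kg) in multi-breed beef-cattle half-sib cohorts. The
single-trait animal model is

    y = Xβ + Zu + e,    Var(u) = G σ²_A,   Var(e) = I σ²_E,

with `y` the WBSF records, `β` fixed contemporary-group effects
(breed × herd of origin × sex × slaughter date, fitted as cell means),
`u` additive genetic merits and `Z = I` (one record per genotyped
animal). `G` is the first VanRaden realized-relationship form
`G = MM′/c` with `c = 2Σᵢpᵢqᵢ`, where column *i* of `M` codes genotypes
as deviations from allele-frequency expectation: `2qᵢ`, `qᵢ−pᵢ`, `−2pᵢ`
for diploid AA/AB/BB, and `qᵢ`, `−pᵢ` for hemizygous AY/BY male-X
genotypes (pseudoautosomal cells are coded diploid). Allele
substitution effects (ASEs) are back-solved from the GBLUP as

    α̂ = c⁻¹ M′ G⁻¹ û,     σ²_M = σ²_A / c,     tᵢ = |α̂ᵢ| / σ_M,

and ranked with 1 = largest `tᵢ`, ties broken by genome order so that
region tables are reproducible.

### REML

Variance components are estimated by REML after rotating the model
through the eigendecomposition `G = U D U′`, which diagonalizes both
covariance structures; every restricted-likelihood evaluation then
costs `O(n p²)`. A profiled scalar search over the heritability locates
the optimum, after which EM-REML iterations — whose restricted
log-likelihood is non-decreasing by construction and asserted at every
step — run until two successive heritability iterates print identically
at 4 significant figures (configurable). `σ²_A` is floored at 1e-12 and
flagged when it pins there. Contemporary-group cells with fewer than
two records are dropped with their records and logged; a cell-means
design keeps `X` full rank.

The optional identity blend `(1−ε)G + εI` (default ε = 0.01 in the
pipeline) guarantees an invertible `G` for the back-solve; ε is always
recorded. With ε = 0 and `G` full rank the identities `Mα̂ = û` and the
equivalence of `α̂` with ridge-regression SNP-BLUP
(`Var(a) = I σ²_M`) hold to machine precision and are asserted in the
test suite at 1e-8 relative. Note that `G` built from in-sample allele
frequencies is always singular (centered columns of `M` sum to zero),
so those exact identities are exercised with generative frequencies.

### QC, phasing, imputation

SNPs are retained when they map uniquely to an autosome or the X, have
call rate strictly above 0.89 and minor allele frequency strictly above
0.01 within every breed (computed from allele counts, so boundary cases
are exact); animals with call rate below 0.85 are then dropped. The SNP
filter runs first over all genotyped animals, one pass, no iteration.

Phasing and imputation use an overlapping-window EM over haplotype
frequencies (window 9 SNPs — matching the analysis window — stride 4,
random restarts, deterministic under the seed). Each animal receives
its maximum-posterior haplotype pair; windows are stitched by choosing
the orientation that agrees with the already-assigned overlap at the
most sites. Observed genotypes are preserved exactly; imputed cells
carry their posterior. This is a deliberately local phaser: downstream
analyses only require phase consistency within 9-SNP windows.

### Region concordance

`tᵢ` ranks from the across-breed analysis seed regions (rank ≤ 500 of
~40k, the published "top 500"); seeds within 1 Mb merge; regions grow
outward to within-breed top-500 SNPs up to a 5.7 Mb cap (the largest
published region). A region is a shared QTL when ≥ 3 breeds have a SNP
in it ranked ≤ the threshold (500, or 999 for the "< 1000" variant).
The published region table ships as a packaged fixture and is the
reference input for the concordance summaries; spans are `end − start`
bp, matching the published arithmetic (e.g. 8187 = 44 070 881 −
44 062 694).

### Fine-mapping

Single-SNP and 9-SNP haplotype-window tests are generalized least
squares under the *frozen* covariance `V = Gσ²_A + Iσ²_E` from a prior
REML fit — components are not re-estimated per test. All sums of
squares are computed on the whitened scale (inverse Cholesky factor of
`V`), which reduces exactly to OLS when `V ∝ I`;
`F = (ΔSS/Δdf) / (full-model residual mean square)` with Δdf the rank
gain over the contemporary-group-only model. Window statistics attach
to the centre (5th) SNP. Because the haplotype count varies between
windows, the max-F and max-%VarP windows can differ; both are reported.
The percentage of phenotypic variation explained is

    %VarP = 100 · (SS_full − SS_cg) / (SS_total − SS_cg),

the denominator being the total SS corrected for the mean and
contemporary groups. Haplotypes with fewer than `min_count` carriers
(default 5) pool into one level; pooling never increases the numerator
degrees of freedom.

## The synthetic cohort generator

No genotype or phenotype data are deposited with the study, so every
statistical claim is exercised on synthetic cohorts with known truth.
The generator emulates the study design: five breeds (Angus and
Hereford purebred; Charolais, Limousin and Simmental sired onto Angus
dams), 18–29 sires per breed with ~29 male progeny each, ~40k autosomal
+ X SNPs with two locally densified assay regions mimicking the *CAST*
(BTA7) and *CAPN1* (BTA29) intervals, per-breed heritabilities spanning
0.08–0.52 with the published additive variances as defaults, and one
major QTL per dense region explaining ~1–2 % of phenotypic variance.

Breed allele frequencies follow a Balding–Nichols draw around shared
ancestral frequencies (default F = 0.10). Each breed's haplotypes come
from a finite founder pool (default 100) that is first evolved through
`pool_generations` rounds (default 30) of random mating with
recombination at `pool_recomb_scale` × 1 cM/Mb (default 4): drift sets
the long-range LD floor while accumulated recombination makes LD decay
with distance, the two properties the haplotype analyses depend on. At
the settings used in the fine-mapping tests the simulated r² falls from
~0.8 below 80 kb to ~0.05 beyond 1.2 Mb, similar in shape to real
within-breed cattle LD under strong family structure. Because deep
drift occasionally sweeps a whole local region to one lineage, pools
are conditioned on the assay regions staying variable — the analogue of
a targeted assay designed against sites known to segregate. Dense-region
SNPs draw ancestral frequencies from the intermediate range
(0.25–0.75), emulating validated-assay ascertainment; the backbone uses
0.05–0.95.

Sires are pool haplotype pairs; each progeny receives one recombinant
sire gamete (Haldane model, 1 cM/Mb) and one recombinant gamete from
the dam breed's pool; male X comes from the dam only. Phenotypes are
`mean + CG + QTL + polygenic + residual`: the polygenic term is a sum
of per-SNP effects scaled so each breed's realized background variance
equals `σ²_A − Var(QTL)` exactly (finite pools would otherwise deflate
it); the residual variance follows from the configured heritability.
Default QTL placement picks an interior assay-region SNP that
segregates in every breed with polymorphic flanking SNPs — a causal
variant that local haplotypes can tag, which is the premise of the
fine-mapping experiments. Missingness is MCAR at the published overall
rate (0.89 %).

What the generator does **not** model: genotyping error, carcass
misidentification, dam pedigree, mutation, selection, or
coalescent-exact LD (the pool model is forward drift, not an ancestral
recombination graph). Passing tests therefore demonstrate correctness
of the estimators under the stated generative model, not robustness to
those artefacts.

## Validation experiments and problem sizes

The statistical acceptance checks run at sizes chosen to keep the full
suite desk-scale while preserving the operating regime of the study:

- **Heritability recovery** — 20 cohorts, n = 2000 (25 sires × 80),
  5000 SNPs, true h² = 0.4; ĥ² must fall within ±0.1 in ≥ 90 % of
  replicates.
- **Null calibration** — 1000 genotype columns permuted against a
  fitted cohort (n = 400); GLS single-SNP P-values must pass a KS test
  for uniformity at α = 0.01.
- **Equivalence identities** — `Mα̂ = û` and SNP-BLUP agreement at
  1e-8 relative on a 400-animal cohort.
- **Window localization** — 20 cohorts, n = 1000, 12k genome SNPs
  (keeping n/c near the study's ratio, which controls how much of a
  causal signal the fixed covariance absorbs), a 56-SNP assay region
  over 2.86 Mb, and a causal variant of 5 % phenotypic variance removed
  from the array. The true variance is set above the printed window
  percentages deliberately: the %VarP statistic measures the signal
  *after* `V` has absorbed part of it, and at these settings the
  measured best-window %VarP lands in the published 1.8–5.4 % range.
  Two properties are asserted: the best-%VarP window's span contains
  the causal position (strict), and the best window lies within half a
  window (4 SNPs, ~300 kb) of one that does. The strict form is an
  intrinsically sharp event — neighbouring windows share 8 of 9 SNPs
  and their %VarP values differ by less than the replicate noise — and
  sits near 70 % here, while the half-window form holds in ~90 % of
  replicates, consistent with the published resolution (best *CAST*
  window displaced 83.7 kb from the top SNP; causal location argued for
  a 678-kb interval).

## Numerical choices

- Rank ties in `tᵢ` break by (chromosome, position); dense ordinal
  ranks, so "top 500" and "< 1000" contain exactly 500 and 999 SNPs.
- "Converged to 4 significant figures" is operationalized as two
  successive h² iterates formatting identically at 4 significant
  digits.
- MAF uses allele *counts*, so a frequency of exactly 0.01 is excluded
  without floating-point ambiguity; `1 − p` rounding was observed to
  mis-classify boundary cases and is avoided.
- The EM phaser caps per-pattern enumeration at 2¹² configurations;
  surplus missing cells in a window are demoted to single-bit
  (heterozygous-like) choices. Windows never cross chromosome or
  region boundaries.
- `c` sums `2pᵢqᵢ` over all analysis SNPs including X-linked ones; the
  alternative X weight (`pᵢqᵢ`) is available behind a flag
  (`x_half_weight`) since the original description fixes only the
  coding, not the scaling.
- P-values are reported as −log₁₀ from the F distribution; no
  multiple-testing correction enters any decision rule, matching the
  rank-based reporting.

## Known limitations

- The EM phaser is a local stand-in for a full HMM phaser; switch
  accuracy across window stitches is adequate for 9-SNP analyses but
  not for long-range haplotyping.
- GLS absorption means window %VarP underestimates the causal variance
  when the causal variant's LD partners sit in `G`; this mirrors the
  published procedure rather than correcting it.
- `Z = I` is assumed (one record per genotyped animal); repeated
  records per animal are not supported.
- The X pseudoautosomal region is supported in coding and QC but the
  generator does not simulate it by default.
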