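# Methods

## System being modelled

Males of *Drosophila albomicans* carry a Robertsonian fusion of the X and the
ancestral third chromosome (X-3). In hybrids with *D. nasuta*, X-3-linked
distorter elements (D1–D4) drive against Y-bearing sperm, giving female-biased
progeny; autosomal suppressors (S3 on the second chromosome, S4 likewise)
silence the drive. The same six regions carry hybrid-male-sterility effects:
distorters reduce the count of functional sperm (measured as lifetime
offspring T), suppressors restore it. The package simulates this architecture
end to end — crosses, phenotypes, the mating assay, QTL mapping, interval
colocalization and genotype contrasts — so that every statistical step of the
inference chain can be exercised and validated against known synthetic truth.

## Genome model

Chromosomes are the fused X-3 (200 cM: X arm 0–100, chromosome-3 arm
100–200, sex-linked and hemizygous in males), chromosome 2 (120 cM) and the
dot chromosome 4 (20 cM). Marker positions default to an even grid per arm,
with per-design counts 62/67/39 (Exp1/Exp2/Exp3); exact positions are
configurable. Meiosis uses the Haldane map function (no interference) —
chosen because it keeps gamete sampling a Markov chain along each chromosome
and gives closed forms for tests. Crosses between the two species are
heterozygous for fixed inversions across the chromosome-3 arm, modelled as a
hard recombination block (`InversionRegion` active for Exp2/Exp3) with an
optional leak parameter, default 0: intervals inside an active, heterozygous
region contribute no map length to crossover sampling, so recombinants across
the arm are exactly absent. Coordinates are cM, 0-based, half-open intervals.

## Phenotype model

Sex ratio (proportion of females k) uses a saturating latent-scale link:

    k = 0.5 + Δmax · σ(z),   z = Σⱼ dⱼ xⱼ − Σₗ sₗ doseₗ,
    σ(z) = max(z,0) / (1 + max(z,0)),  Δmax = 0.48

with xⱼ ∈ {0,1} hemizygous distorter presence and doseₗ ∈ {0, wₗ, 1} for
0/1/2 suppressor copies (dominance weight w = 0.64 by default, reflecting the
larger first-copy effect of the semidominant suppressors). The link
guarantees k ∈ [0.5, 1), monotone in each effect, and k = 0.5 exactly when no
drive is active; drive also requires a sensitive Y-linked responder (a flag,
default sensitive). Suppression strengths live on the same latent scale as
drive (a bounded fractional suppression could never silence strong drive
down to the observed Mendelian ratios of fully suppressed genotypes).

Fertility is a hurdle model: sterility probability is logistic in summed
per-locus sterility log-odds (distorters positive, suppressors negative);
conditional on fertile, T is negative binomial (dispersion θ = 5.5) with a
mean multiplicative in per-locus log-fecundity effects, clipped at a
physiological ceiling of 220 offspring. Offspring sexes are binomial in k.

The shipped calibration targets the published genotype summaries
*qualitatively* — control mean T ≈ 115, the three-distorter stack k ≈ 0.86
and nearly sterile, the F1 genotype k ≈ 0.92, D1 alone sterilizing, S3/S4
rescuing, and the strict one-copy/two-copy suppression ordering. Those
summaries are data, not parameters, and an additive latent model cannot match
every genotype mean simultaneously (e.g. full suppression of D1 by S3 alone
is not reproduced, and the simulated S3 dominance index lands near 0.8 rather
than the published 0.36); only orderings and the anchor levels above are
contractual. Calibration values ship in the `EffectModel` config
(YAML round-trippable).

## Exhaustive-mating estimator

Males get fresh females on a 4+1-day schedule; only 1-day vials (days 1, 2,
3, 8, 13, …) are sexed and counted. Each uncounted 4-day block is estimated
as 2 × (preceding + following 1-day counts). For daily output linear in day,
block days b…b+3 sum to 4c₀ − 22s while the flanks give 2[(c₀−3s) + (c₀−8s)]
— identical, so the estimator is exact under linear decline; under geometric
decline with daily rate 0.85–0.95 the relative error stays below 3%. A
trailing uncounted block with no following counted vial (male died) is
estimated as 4 × the preceding 1-day vial and flagged; a leading uncounted
block is an error. Sex ratio uses counted offspring only (interpolated
offspring have unknown sex) and males need ≥ 30 counted offspring to
contribute a sex ratio. Group sex ratios of sub-fertile genotypes are
bootstrap summaries over males with counts pooled within each replicate, so
males whose individual k is undefined still contribute; sterile males are
excluded. Whether the original assay resampled males or offspring is not
determinable from the published description; male-level resampling with
pooled counts is the default.

## QTL machinery

Scans are Haley-Knott-style: at each 1-cM grid position the expected
focal-line dose given flanking marker doses (Haldane probabilities) is the
regressor. Continuous traits use LOD = (n/2)·log₁₀(RSS₀/RSS₁) (computed via
the correlation identity, capped at LOD 50 for degenerate fits); the binary
fertile/sterile trait uses a two-parameter Newton logistic likelihood-ratio
LOD. Composite-interval-mapping-style cofactors are available (forward
selection, default 3, 10 cM exclusion window) but off by default; fidelity to
any particular mapping package is not a goal — validation is parameter
recovery on synthetic truth. Markers inside an active inversion are perfectly
collinear, so each blocked region collapses to a single representative scan
position. Genome-wide thresholds are permutation-based (default 500
permutations, α = 0.05, type-7 quantile of the max-LOD sample); trait values
are permuted against genotype rows within the eligible subset. Support
intervals are 1.5-LOD-drop intervals, labelled approximate 95% intervals; U
is the interval width as a fraction of the chromosome's map length. The
multi-locus fit reports H² (R² of the joint linear model, plus pairwise
interaction terms when requested) and h² (additive-only R²), with per-locus
shares by incremental R² in map order; ties in peak LOD resolve to the
smallest cM.

Validation (in `drivemap.validation`, run by `analysis/06_scan_validation.py`
and the acceptance suite): 200 null backcross scans (n = 200 males, 40
markers, 200 permutations) give a genome-wide rejection rate of ~0.075,
inside the 99% binomial band around 0.05; 50 replicates with a true additive
variance fraction of 0.64 over four loci recover mean ĥ² = 0.642 (sd 0.02)
with 100% per-locus detection. These problem sizes were chosen to make the
sampling error of the validation itself small while keeping the default run
desk-scale.

## Colocalization

For m disjoint intervals with fractional widths Uᵢ on one chromosome, the
probability that m independently, uniformly placed genes land exactly one per
interval is m!·∏Uᵢ (each of the m! assignments contributes ∏Uᵢ).
Chromosome-level probabilities multiply across chromosomes; the combined
six-interval probability is therefore (4!·∏U_X-3)·(2!·∏U_chr2) ≈ 4×10⁻⁶ —
the alternative reading 6!·∏(all six U) would conflate placements across
chromosomes and does not reproduce the published combined value, so it is
rejected. Widths are map-length fractions taken at face value; the published
interval widths are inputs (`drivemap.studydata`), never recomputed, because
the original per-male data needed to re-estimate them are not available. The
Monte-Carlo oracle lays the intervals contiguously from the origin (the
success probability depends only on the widths given disjointness) and
counts exact one-per-interval occupancy.

## Contrasts

Fertility contrasts use the two-sample Wilcoxon rank-sum test (exact
enumeration when both groups have n ≤ 10 and no ties, normal approximation
with tie correction otherwise; the original variant is unstated). Sex-ratio
contrasts model per-male (female, male) counts with a binomial logistic
regression on a group indicator; with a single binary covariate the MLEs are
the per-group pooled proportions, so the likelihood-ratio statistic is
computed in closed form and referred to χ²₁ (statsmodels GLM serves as an
independent cross-check in the tests). Groups pooled to a single sex get a
0.5-count continuity adjustment and a flag. Overdispersion correction is off
by default. The dominance index d = (k₁−k₂)/(k₀−k₂) is affine-invariant and
classifies a suppressor as semidominant when 0 < d < 1.

## Pipeline and reproducibility

`RunConfig` fully serializes a run; the master seed is hashed (SHA-256) with
each stage name to derive per-stage streams, so adding a stage never
perturbs earlier ones and identical configs give byte-identical tables.
Tables use the cross CSV dialect (three header rows: marker, chromosome, cM;
codes A/H/B/−, hemizygous X-3 coded A/B) and tidy CSV/JSON for scans,
thresholds, intervals and contrasts. The package is a library plus numbered
analysis drivers; there is no separate console command because the scripts
and functions are the interface.

## What the synthetic data do and do not show

The generator reproduces the designs' sample sizes, marker counts, the
blocked chromosome-3 arm, hemizygous X-3 transmission, hurdle-shaped
fertility with a large sterile class, and drive/suppression orderings. It
does not model viability selection during introgression, genotyping error
(parameter exposed, default 0), temperature or tester-female covariates,
sperm storage/competition differences between assay protocols, or
distorter×distorter epistasis (consistent with the mostly additive variance
decomposition). Passing tests therefore demonstrate that the statistical
machinery is correct and well-calibrated on data satisfying these
assumptions — not that the biological effect sizes themselves are
re-estimated from nature.
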