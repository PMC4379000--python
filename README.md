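# drivemap

Simulation and analysis of **sex-ratio meiotic drive (SRD)** and **hybrid male
sterility (HMS)** in *Drosophila albomicans* × *D. nasuta* crosses.

In this species pair the X and the ancestral third chromosome are fused into a
sex-linked X-3 element. X-3-linked *distorter* loci (D1–D4) bias transmission
against Y-bearing sperm, so carrier males sire female-biased progeny
(sex ratio k > 0.5); autosomal *suppressor* loci (S3, S4) silence the drive
semidominantly. The same loci carry sterility effects: distorters reduce a
male's functional sperm count T, suppressors rescue it. `drivemap` implements
the full inference chain that ties these two phenotypes together on synthetic
data:

1. **Genome model** — genetic maps with an inversion-heterozygous,
   recombination-suppressed chromosome-3 arm; Haldane-model gamete sampling
   (`drivemap.genome`).
2. **Cross simulation** — the three backcross mapping designs
   (Exp1: n = 459 / 62 markers, Exp2: n = 442 / 67, Exp3: n = 470 / 39) and
   marker-assisted introgression genotypes (`drivemap.crosses`).
3. **Phenotype model** — k = 0.5 + Δmax·σ(Σⱼ dⱼxⱼ − Σₗ sₗ·doseₗ) for sex
   ratio and a hurdle negative-binomial for fertility (`drivemap.phenotypes`).
4. **Exhaustive-mating estimator** — the 4+1-day vial schedule in which
   uncounted 4-day blocks are interpolated as 2×(sum of the flanking 1-day
   vials); exact under linear daily decline (`drivemap.protocol`).
5. **QTL scans** — Haley-Knott expected-genotype regression LOD scans for the
   four trait treatments (T, log₁₀(T+1), fertile/sterile, sex ratio with the
   T ≥ 30 rule), 500-permutation genome-wide thresholds, LOD-drop support
   intervals, and H²/h² variance components from joint multi-locus fits
   (`drivemap.qtl`).
6. **Colocalization** — the probability m!·∏ᵢUᵢ that m independently placed
   genes fall one-per-interval into m disjoint QTL intervals of fractional
   widths Uᵢ, with a Monte-Carlo oracle (`drivemap.coloc`).
7. **Contrasts** — Wilcoxon rank-sum fertility tests, binomial-logistic
   likelihood-ratio sex-ratio tests, and the suppressor dominance index
   d = (k₁−k₂)/(k₀−k₂) (`drivemap.contrasts`).

## Worked example

The analysis chain lives in the numbered scripts under `analysis/` (each takes
an optional seed argument). The central calculation — do the sterility and
drive phenotypes share genes? — takes the six published QTL support-interval
widths as fractions of their chromosomes (X-3: 3.7%, 3.8%, 11.1%, 5.4%;
chromosome 2: 4.0%, 25.5%) and asks how often independent gene placements
would match them one-per-interval:

```bash
$ python analysis/04_colocalization.py 1
X-3: 4 intervals, analytic 2.023e-04, MC 1.880e-04 +/- 1.4e-05
2: 2 intervals, analytic 2.040e-02, MC 2.065e-02 +/- 1.4e-04
combined probability that distinct genes explain all six intervals: 4.1e-06
```

Reading: the chance that four distinct sterility genes happen to colocalize
with the four X-3 distorters is 4!·∏U ≈ 0.0002, the chromosome-2 analogue is
≈ 0.02, and the joint probability ≈ 4×10⁻⁶ — strong evidence that the dual
SRD/HMS functions are pleiotropic effects of the same loci. The simulated
Exp2 population behind the mapping steps looks like this:

```bash
$ python analysis/01_simulate_population.py 1
simulated 442 Exp2 males at 67 markers
  sterile (T=0): 30.8%   mean T: 112.5
  sex-ratio eligible (T>=30): 270
  pooled sex ratio k = 0.674 +/- 0.013 (bootstrap)
```

and the scan validation (`analysis/06_scan_validation.py`) confirms the
permutation threshold holds its 5% genome-wide error (observed 0.075 over 200
null scans) and that a true additive variance fraction of 0.64 is recovered
(mean ĥ² = 0.642 over 50 replicates, all four loci detected).

## Layout

- `src/drivemap/` — the library (all computation).
- `analysis/01…06` — numbered narrative drivers writing tables under `results/`.
- `tests/` — unit, property and acceptance suites.
- `docs/methods.md` — model assumptions, calibration and limitations.
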