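# Methods

This note documents the models, defaults and numerical choices behind
`ridqtl`, and what the synthetic generator does and does not emulate.

## Synthetic RI panel

**Genotypes.** Each strain is an independent Markov mosaic of founder
alleles (B = −1, D = +1) along each chromosome. The switch probability
between adjacent markers is the recombinant-inbred map expansion for
sib-mating, `R = 4r/(1+6r)`, applied to a Haldane recombination fraction
`r = (1 − e^{−2d})/2` with `d` in Morgans obtained from the Mb distance at
a fixed rate (default 0.5 cM/Mb; the rate is a config knob because map
units vary between genotype releases and the analysis only needs a
plausible decay of marker-marker correlation). The default map places
7,320 markers over the 19 mouse autosomes proportionally to physical
length. The simulator never emits heterozygous or missing calls; the
GeneNetwork-format parser maps `H`/`U` to missing because real RI panels
retain residual heterozygosity.

**Intake records.** For animal *a* of strain *s* in week *w*:

    intake(w, d) = m_d · (base_s + slope_s·(w−1) + animal_a + ε),  truncated at 0

with `base_s` = baseline (2.0 g/kg) + planted level-QTL effects × genotype
+ N(0, 0.45²) strain effect; `slope_s` = 0.14 g/kg/week + slope-QTL
effects + N(0, 0.08²); `animal_a ~ N(0, 0.40²)`; `ε ~ N(0, 0.50²)` per
session; and `m_d` = 1 for 2 h days, 2 for the day-4 4 h session.
Replicates per strain are drawn uniformly from 1–16. These defaults are
the study conditions the package targets: a ~0.14 g/kg/week population
escalation of 2 h intake, weekly 2 h heritabilities in the 0.3–0.5 range,
and first-exposure intake near 2 g/kg. Truncation at zero exists because
g/kg is non-negative; at the default variance components it affects well
under 1% of sessions. Planted QTLs target either the intake level
("level", shifting every session) or the escalation rate ("slope"); a
per-week target is not offered because the generative model is
strain-level and would not propagate coherently to the slope traits.

What the generator does **not** emulate: sex chromosomes, dominance and
epistasis (RI strains are homozygous), litter/cage effects, body-weight
trajectories, front-loading within sessions, and any non-Gaussian
heavy-tailed intake behaviour. Passing tests therefore demonstrate
correctness of the statistical machinery under a well-specified additive
model, not robustness to every pathology of real drinking data.

**Omics tables.** Genes are placed uniformly; a configurable fraction is
cis-regulated (expression = baseline N(8, 1.5) + 0.8 × nearest-marker
genotype + N(0, 0.3)). Every gene carries founder variants by default
(BXD founders segregate ~5M variants), and a configurable fraction of
genes receives one consequence from the high-impact list, the rest benign
consequences.

## Phenotype statistics

- g/kg conversion uses ethanol density 0.7893 g/ml (20 °C).
- `Wkavg` pools all 2 h animal-sessions of a strain in week k (animals ×
  3 days) rather than averaging day means — "averaged by strain" taken
  literally.
- Heritability is `h² = SS_strain/SS_total` from fixed-effects one-way
  ANOVA. This statistic is *not* an unbiased ICC estimator: with k strains
  and r replicates its expectation is
  `(k−1)(σ²w + r σ²b) / [(k−1)(σ²w + r σ²b) + (N−k)σ²w]`, which exceeds
  the ICC by ≈0.05 at ICC ≈ 0.45 and by ≈0.02 at ICC ≈ 0.7 for 40 strains
  × 10 replicates. The recovery test uses a generative ICC of ~0.7 and
  averages 20 panels so the estimator's own bias stays inside the ±0.05
  recovery band; the bias is a property of the reported statistic, kept
  deliberately because it is the field's conventional panel-heritability
  summary.
- Escalation fits regress the 5 weekly strain means on week 1..5; the
  intercept is reported at week 0 (extrapolated baseline — reference
  slope tables are systematically below week-1 means by about one slope
  unit, which matches this convention). Slope significance is the 3-df t
  test; the slope standard error comes from the same regression.
- Winsorization clamps to the 2.5%/97.5% quantiles by default.

## Haley–Knott scan

Marker-only regression of strain means on the ±1 code (no pseudomarkers:
RI maps are dense enough that interval positions add nothing).
`LOD = (n/2)·log10(RSS₀/RSS₁)`; p from the equivalent F(1, n−2) test.
Strains missing a call are dropped marker-wise; markers without both
alleles in ≥2 strains are excluded as (near-)monomorphic. Perfect fits
(RSS₁ = 0) are capped at LOD 50 and flagged. Peak ties break to lowest
chromosome, then lowest Mb.

**Permutation thresholds** shuffle the phenotype across strains with
genotypes fixed and take nearest-rank quantiles (no interpolation) of the
per-permutation genome-wide max LOD: 0.37/0.95 for the HK convention
(suggestive = genome-wide adjusted p < 0.63, significant = p < 0.05),
0.67/0.95 for the LMM convention. The two conventions are deliberately
kept distinct, not reconciled.

**1.5-LOD support intervals** walk outward from the peak to the first
marker whose LOD falls below peak − 1.5 on each side; that marker's
position is the reported bound, clamped to the chromosome ends if the
profile never crosses.

## Mixed-model scan

Kinship is the centered product `K = GcGcᵀ/p` over all markers with both
alleles present (mean-imputing missing calls), optionally
leave-one-chromosome-out so the polygenic term cannot absorb the tested
locus. λ = σ²g/σ²e maximises the restricted likelihood on the eigenbasis
of K: a 100-point log₁₀ grid over [1e−5, 1e5] followed by bounded Brent
refinement (tolerance 1e−6 in log λ), with the λ→0 boundary checked
explicitly. A flat restricted likelihood (K = I up to scale, where only
total variance is identified) returns λ = 0 by convention, which makes
the scan collapse exactly to per-marker OLS. Per-marker effects are GLS
estimates given λ̂ (refit per chromosome under LOCO); the Wald statistic
β̂²/Var(β̂) is referred to F(1, n−2). LOD is −log10(Wald p) by default
(the GeneNetwork display convention); a likelihood-ratio-style
`(n/2)·log10(RSS₀/RSS₁)` scale — equivalent to LRS/4.61 — is available
via `lod_scale="lrs"` because the mapping from Wald p to a published
"LOD" is not standardised. LMM permutations shuffle the phenotype while
keeping genotypes and K fixed (the kinship is computed and eigendecomposed
once per threshold run); λ is refit per permuted phenotype. No
minor-allele-frequency filter is applied beyond excluding monomorphic
markers — the panel is biallelic and inbred.

## Consensus calling

One locus per chromosome per trait: the chromosome-wise HK peak at or
above the suggestive threshold, confirmed when the LMM exceeds LOD > 3 at
any marker inside the HK 1.5-LOD interval on that chromosome.
"Detected by both methods" needs a concrete co-localization rule because
published peak markers sometimes coincide and sometimes merely overlap in
interval; the in-interval-exceedance rule accommodates both. The reported
LMM peak is the in-interval argmax — this guarantees the two support
intervals intersect, and the intersection is reported alongside both.
The trait-increasing allele is D when the HK additive effect is positive,
B when negative. Reported positions round to 3 decimals (Mb).

## Candidate prioritization

Filter order mirrors the published cascade: interval membership
(half-open [left, right), overlap rule) → biotype filter (drop
pseudo-genes, predicted genes, non-coding, gene models) → high-impact
variant filter (the 21 shipped VEP-style consequence strings, lower-cased)
→ expression evidence. The cis window is ±10 Mb of the gene ("local" is
otherwise undefined) and cis calls require the *genome-wide* peak of the
probe scan to be both above threshold and local — a stronger distal peak
means trans regulation and yields "none". Tier 1 = high-impact ∧ cis ∧
trait correlation p < 0.05; tier 2 = high-impact ∧ (cis ∨ correlated);
tier 3 = high-impact only; within tier, rank by |r|. Genes without a
high-impact variant never enter the table, whatever their correlation.
The legacy-trait screen uses Pearson correlation (Spearman behind a flag)
over ≥4 shared strains at p < 0.005.

## Problem sizes

The test suite and acceptance script run on reduced panels chosen to keep
the statistical checks well-powered while staying quick: 19 × 25–30
marker chromosomes (≈500–600 markers) for calibration and recovery
checks, 200 permutations where the published convention uses 1,000
(nearest-rank quantiles are stable at both sizes for the 0.37 quantile),
500 null scans for threshold calibration, and 100–200 simulation
replicates for coverage/consensus aggregates. The pipeline default
remains 1,000 permutations.

## Known limitations

- The LMM is a single-marker Wald approximation, not an exact-likelihood
  ratio test; with ~40 strains the F(1, n−2) reference is conservative at
  extreme tails.
- Permutation thresholds assume exchangeability of strain means; the LMM
  permutation deliberately keeps K fixed while shuffling phenotypes,
  which breaks the phenotype–kinship correspondence by design (implemented
  as specified by the convention it follows, not re-derived).
- `h²` is the conventional SS-ratio, upward-biased for the ICC (see
  above).
- Candidate evidence is correlational; tiers rank plausibility, not
  causality.
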