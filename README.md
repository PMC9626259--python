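# minkedemog

Non-lethal demography inference for Antarctic minke whales (*Balaenoptera
bonaerensis*): a tested Python pipeline that turns biopsy genotypes, blubber
hormone assays, drone photogrammetry and historical catch records into
population-level sex ratios, maturity structure and pregnancy rates.

## Who this is for

Cetacean ecologists and quantitative wildlife biologists who collect remote
biopsy samples and unoccupied-aircraft-system (UAS) imagery and want the full
inference chain — individual identification, pregnancy assignment with
uncertainty, length estimation with calibrated measurement error, and a
maturity-at-length correction — reproducible from the shell or from Python,
with a synthetic-data generator so every stage can be validated without
field data.

## The analysis chain

1. **Genetic identity** (`minkedemog.identity`). Biopsy samples carrying a
   sex-marker call and a 10-locus microsatellite genotype are resolved to
   individuals: samples typed at fewer than 7 loci are excluded, and samples
   matching exactly at ≥ 7 mutually typed loci are treated as recaptures.
   Locus summaries follow standard population genetics: number of alleles
   *K*, observed heterozygosity *H*ₒ, unbiased expected heterozygosity
   *H*ₑ = (2n/(2n−1))(1 − Σpᵢ²), and the probability of identity
   P_ID = Σpᵢ⁴ + ΣΣ_{i<j}(2pᵢpⱼ)². Sex ratios are tested against parity with
   central two-tailed exact binomial tests and Clopper–Pearson limits.

2. **Pregnancy assay** (`minkedemog.pregnancy`). Blubber progesterone
   (ng g⁻¹, adjusted for extraction efficiency; < 60% efficiency is
   rejected) is classified by a logistic regression of pregnancy state on
   log₁₀ concentration. The reference labels come either from an external
   labeled set or from the cohort itself using the concentration gap
   observed in common minke whales of known status (not-pregnant ≤ 3.43,
   pregnant ≥ 22.84 ng g⁻¹). A 10 000-replicate nonparametric bootstrap
   yields a pointwise 95% confidence envelope; females with point
   probability > 99.9% are called pregnant, < 0.1% not-pregnant, anything
   in between undetermined. The cohort pregnancy rate is the per-replicate
   probability sum divided by the sample size, summarized over replicates.

3. **Photogrammetry** (`minkedemog.photogrammetry`). Pixel lengths scale to
   metres through the pinhole relation L = px · altitude · sensor /
   (focal · image width), but the altimeter is noisy. A hierarchical error
   model — multiplicative altitude bias, additive altitude noise, and a
   multiplicative measurement residual — is calibrated by MCMC against
   images of known-size training objects, then propagated to give each
   whale a posterior predictive length distribution with 95% and 65%
   highest-posterior-density (HPD) intervals. Images are gated on seven
   quality scores before measurement.

4. **Maturity correction** (`minkedemog.demography`). Catch records supply
   two logistic curves on length: p_F(L) (probability female) and p_M(L)
   (probability a female is mature, with L50 = −α/β). Applied to the UAS
   length sample these give the expected proportion of mature females
   P_mat = Σ p_F p_M / Σ p_F and the adjusted sex ratio (1−f)/f. Dividing
   the pregnant count by P_mat × (females assayed) converts the raw
   pregnancy rate into a mature-female rate; MCMC draws of the curves
   propagate catch uncertainty, and rates above 100% are reported
   unclamped.

A synthetic-cohort generator (`minkedemog.synth`) emulates all five input
streams with the statistical structure above, and `minkedemog.pipeline`
plus the `minkedemog` CLI orchestrate the stages end to end from one master
seed.

## Worked example

```bash
minkedemog run --config cfg.yaml
```

with `cfg.yaml`:

```yaml
outdir: demo_out
seed: 11
simulate: {n_individuals: 50, catch_n: 500, n_training: 60}
bootstrap_B: 300
mcmc_draws: 800
error_model_draws: 800
```

prints (abridged):

```
minkedemog pipeline report
============================

Individuals: 50 (20 M, 30 F) from 57 samples (0 excluded)
Sex ratio 0.67 M:F, parity p = 0.203, males 40.00% (95% CL 26.41-54.82)

Pregnancy: 14 pregnant / 12 not pregnant / 4 undetermined of 30 females
Probability-sum rate 47.29% (95% CI 46.80-48.84, B = 300)

Lengths: n = 44, mean 8.30 m (sd 0.96, range 6.49-10.45)
95% HPD width mean 0.78 m (range 0.39-2.01)

L50: 8.28 m (95% CrI 8.16-8.39)
Proportion mature females: 66.1% (95% CrI 61.7-70.8)
Adjusted sex ratio: 0.74 M:F
Corrected pregnancy rate: 70.6% (95% CrI 65.9-75.7)
```

Reading it: 57 simulated biopsies resolve to 50 individuals; the female
bias is not significant (exact binomial p = 0.203). Fourteen of 30 females
assay as pregnant with certainty; four sit in the hormonal gap and stay
undetermined. The UAS stage keeps 44 individuals after quality gating and
recovers the cohort length structure, the catch fit places the female
length at 50% maturity near 8.2 m, and the maturity correction lifts the
raw 47% all-female rate to a 71% mature-female rate with catch-data
uncertainty attached. (Numbers are for this toy seed; stage outputs land
in `demo_out/`.)

Per-stage subcommands (`minkedemog simulate | identity | pregnancy |
lengths | demography`) expose the same steps on individual CSV files, and
everything is importable from Python.

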