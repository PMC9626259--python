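# Methods

This note documents the statistical models behind `minkedemog`, the choices
made where the design was genuinely open, and what the synthetic-data tests
do and do not demonstrate about real data.

## Genetic identity

Samples are matched by exact multilocus comparison: two samples belong to
the same individual when they show zero mismatches at mutually typed loci
and at least `min_match_loci` (default 7) loci were compared; samples typed
at fewer than `min_typed_loci` (default 7) loci are excluded. Clusters are
the transitive closure of pairwise matches (union–find), which makes the
result independent of sample order. Mismatch tolerance is deliberately
zero — allowing one-allele mismatches would require an explicit genotyping
error model — but pairs with exactly one mismatch are surfaced in a QC
side-report, since such pairs are the usual signature of allelic dropout.
Sex conflicts inside a cluster are flagged, never silently resolved.

Locus statistics use sample allele frequencies: K (distinct alleles),
observed heterozygosity H_O (fraction of typed individuals heterozygous),
expected heterozygosity with the small-sample correction
H_E = (2n/(2n−1))(1 − Σp²) (the convention of the standard genotyping
software; the uncorrected value is reported alongside), and the probability
of identity P_ID = Σpᵢ⁴ + Σ_{i<j}(2pᵢpⱼ)², verified in the tests against
brute-force enumeration of Hardy–Weinberg genotype collision probabilities.
Multi-locus P_ID values multiply across loci under independence;
`combined_pid` enumerates every locus subset of a given size and reports
the min/max/mean product.

Sex-ratio inference uses the *central* two-tailed exact binomial test,
p = min(1, 2·min(P(X≤k), P(X≥k))) — at p₀ = ½ this coincides with the
minimum-likelihood definition, and it reproduces every published p-value at
printed precision. Confidence limits are Clopper–Pearson (Beta quantiles),
which likewise reproduce the published bounds; the exact interval is
conservative, so simulated coverage sits at or above the nominal level.

## Pregnancy assay

Concentrations are divided by the extraction efficiency before analysis;
efficiencies below 60% are flagged invalid. QC helpers compute intra- and
inter-assay CVs (100·sd/mean within and across plates) and a parallelism
check that regresses response on log₂ dilution for the pooled extract and
the kit standards, reporting the slope ratio and the r² of the joint
common-slope fit.

The assignment model is a logistic regression of pregnancy state on log₁₀
concentration. Two reference modes exist: `external_reference` (a labeled
training set from another population) and `self_bounded`, which labels the
cohort's own samples by the concentration gap seen in conspecifics of
known status — not-pregnant at ≤ 3.43 ng/g, pregnant at ≥ 22.84 ng/g —
leaving in-gap samples unlabeled. Uncertainty comes from a nonparametric
bootstrap (default B = 10 000) of the reference records; the "95%
confidence envelope" is the pointwise 2.5–97.5 percentile band of the
replicate predicted probabilities (the band construction is our choice —
only the envelope's existence and mass are specified upstream).

Because the two classes are separated by a wide gap, most fits (and nearly
all bootstrap refits) encounter complete separation, where the
unpenalized MLE diverges. Every fit therefore carries a tiny ridge penalty
(1e−4 on both coefficients) solved by damped Newton iteration: coefficients
stay finite, predicted probabilities still reach ≈0/≈1 outside the gap,
and the envelope remains defined. Bootstrap resamples containing a single
class are assigned the degenerate flat curve at that class. One
consequence worth knowing: the penalized slope is large but bounded, so
point probabilities within a few percent of the gap edges can fall
marginally inside (0.001, 0.999) and draw an `undetermined` call; this
mirrors the biological reality that concentrations at the boundary are
genuinely ambiguous.

Calls key on the point estimate (> 99.9% pregnant, < 0.1% not pregnant,
otherwise undetermined) with the envelope reported alongside; a CI-based
call rule is available behind a flag. The cohort pregnancy rate is the
probability-sum estimator: within each bootstrap replicate b, rate_b =
Σᵢ p_b(xᵢ)/n, summarized by mean and percentile interval — this uses the
information in undetermined samples instead of discarding them.

## Photogrammetry

Deterministic scaling is the pinhole relation
L = px · altitude · sensor_width / (focal_length · image_width)
(altitudes m, focal/sensor mm, lengths m; conversions live in one place).
Image quality gating: any attribute scored 3 rejects an image, as does a
score of 2 on two of {roll, arch, pitch}; at most five passing images are
kept per individual (best total score first, ties by table order).

The measurement-error model is this package's own hierarchical form, built
to the external contract "training objects in, posterior predictive lengths
with HPD out": the observed altitude is true·bias + Normal(0, sd), and
pixel measurement carries a multiplicative Normal(0, cv) residual. For a
training object of known length L at observed altitude a this yields the
Gaussian likelihood  naive_length ~ N(L·bias, (L·bias)²(sd²/a² + cv²)),
with a 1 mm floor on the per-image sd so exact data stay well-posed.
Priors: bias ~ N(1, 0.25²), sd ~ HalfNormal(5 m), cv ~ HalfNormal(0.15).
The posterior is sampled with an affine-invariant ensemble sampler
(24 walkers, 500 warm-up + 2000 steps by default); chains are thinned by
half the integrated autocorrelation time, and convergence requires both
chain length > 50·τ and split-R̂ < 1.1 on the thinned chains. Calibration
is per aircraft (barometer-only and laser-equipped airframes differ).

For a whale with images j, each posterior draw of (bias, sd, cv) defines a
conditional Gaussian posterior for true length (plug-in variance per image,
precision-weighted combination), truncated to a Uniform(3, 12) m length
prior; one length is sampled per draw, giving ≥ 2000 posterior predictive
samples per individual. HPD intervals are exact shortest windows over the
sorted samples (⌈mass·n⌉ points), checked against exhaustive search.
Simulation-based calibration shows ~95% coverage when the error parameters
are known and ~93–95% with estimated parameters; note that all whales
measured under one calibration share its estimation error, so per-survey
coverage fluctuates more than binomially.

## Maturity correction

Catch records give two individual-level Bernoulli logistic fits on length:
P(female | L) over all records and P(mature | L) over females of known
maturity (a binned display is available, but fitting uses the raw records).
ML fits use IRLS (GLM); perfect separation falls back to the penalized
Newton fit with a warning. The joint posterior of the four parameters is
sampled under weak Normal(0, 10²) priors (the prior is a declared choice;
with catch samples of a few hundred the likelihood dominates and the only
visible prior effect is a negligible flattening along the weakly identified
intercept–slope ridge). Per draw, L50 = −α_M/β_M.

Applied to the UAS length sample (collapsed to posterior mean lengths by
default; full propagation by sampling one length per individual per draw
is available behind a flag):

- proportion mature females P_mat = Σ p_F p_M / Σ p_F,
- adjusted sex ratio (1 − f)/f with f = mean p_F,
- corrected pregnancy rate = pregnant count / (P_mat · females assayed),
  computed per draw and left unclamped above 100% — the upper tail is the
  honest image of P_mat uncertainty, not an error. The pregnant count
  defaults to the fixed classified count; per-bootstrap probability sums
  can be paired with maturity draws by independent uniform resampling (the
  two analyses are independent).

The correction is valid only under the assumption that the probability of
being female, and of a female being mature, at a given length is the same
in the catch data and in the sampled population, and that the UAS length
distribution matches that of the biopsied animals.

## Synthetic data: what it emulates and what it does not

The generator draws ground-truth individuals (sex, length, maturity,
pregnancy, progesterone, genotype) and then the observation processes.
Calibrated defaults: progesterone classes are lognormals moment-matched to
the published class summaries (not-pregnant 1.98 ± 1.58, pregnant
144.86 ± 96.53 ng/g); maturity logistic (−41.0, 5.0) gives L50 = 8.20 m;
the sex-at-length logistic (−11.55, 1.43) was solved once so that, under
pooled lengths Normal(8.04, 1.06), the overall female fraction is 0.49
(adjusted ratio 1.04) and the proportion mature among females is 0.665.
Two length–sex structures are available: the default draws sex first and
lengths from per-sex normals (F 8.3 m, M 7.8 m, sd 0.9 — plausible
dimorphism consistent with the pooled summary); the `sex_at_length` mode
draws pooled lengths and assigns sex by the logistic, which is the
structure the maturity correction assumes and is therefore what the
end-to-end recovery tests use. Genotypes default to uniform allele
frequencies with the published per-locus allele counts; quality scores are
independent per attribute; within-year replicates are duplicates by
default (triplicates behind a flag).

Passing tests on these data demonstrate internal consistency — each stage
recovers the parameters of the process that generated its input — not
robustness to features real data have and the generator lacks: genotyping
error and null alleles (two loci in the real panel show H_O far below H_E;
no correction is attempted), assay matrix effects, non-lognormal hormone
tails, spatially or temporally structured sampling, seasonal composition
shifts, and any dependence between image-quality attributes.

## Problem sizes and numerical choices in the checks

The committed test suite scales simulations to what the checks need rather
than to field scale: end-to-end recovery uses 50 seeded chains of
(cohort 5000, catch 250, B = 50, 1500 MCMC draws) — sized by an error
budget in which the catch-posterior width must dominate the assay-side
binomial noise that the posterior does not model, since otherwise no
honest interval can reach nominal coverage of the generating values;
photogrammetry coverage uses four independent calibrations (110 training
images each, the study's training size) of 50 whales to keep the coverage
outcomes nearly independent; bootstrap tests use B = 200–1000 with fixed
seeds (the pipeline default stays B = 10 000). The acceptance script
emulates the study's uncertainty rather than its raw data volumes: catch
n = 800 reproduces the reported L50 credible-interval width, and UAS noise
(bias 1.02, altitude sd 0.8 m, pixel cv 1%) reproduces the reported HPD
width scale.

Degenerate inputs: monomorphic loci return H_E = 0, P_ID = 1; zero-female
strata report an undefined ratio rather than raising; single-class
references and single-class maturity data are rejected with explicit
errors; zero-mature-proportion posterior draws are excluded from the
corrected rate with their count reported; HPD of a constant sample returns
a zero-width interval.

## Known limitations

- The pregnancy envelope is pointwise, not simultaneous, across
  concentrations.
- The photogrammetry likelihood is a first-order Gaussian approximation of
  a multiplicative error process; at very low altitudes with large
  altimeter noise its intervals are mildly narrow (a few coverage points).
- The maturity MCMC treats sex-at-length and maturity-at-length as
  independent likelihoods; any real correlation between them (e.g. shared
  length mismeasurement in catch records) is not modelled.
- Within-stratum de-duplication keeps the most recent sample; no attempt
  is made to reconcile conflicting hormone values across replicates beyond
  the consistency report.
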