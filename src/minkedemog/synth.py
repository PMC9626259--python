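"""Synthetic cohort, survey and catch generators.

Every downstream stage of the pipeline (genotype identity, pregnancy assay,
photogrammetry, maturity correction) is exercised against data produced here.
The generator draws a ground-truth population of whales — sex, total length,
maturity, pregnancy, blubber progesterone, multilocus genotype — and then
emulates the observation processes: biopsy genotyping with within-year
replicates and locus dropout, hormone extraction with per-sample efficiency,
UAS photogrammetry with altimeter error, and historical catch records.

Default parameters encode the study conditions: a bimodal blubber-progesterone
distribution (lognormals moment-matched to not-pregnant 1.98 +/- 1.58 and
pregnant 144.86 +/- 96.53 ng/g), pooled lengths near 8.04 +/- 1.06 m, female
length at 50% maturity of 8.20 m, and a 10-locus microsatellite panel with the
published allele counts per locus.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

#: mean, sd (ng/g) of the two progesterone classes used to calibrate defaults
NOT_PREGNANT_MEAN_SD = (1.98, 1.58)
PREGNANT_MEAN_SD = (144.86, 96.53)

LOCUS_NAMES = (
    "Ev1", "Ev37", "Ev104", "GATA98", "GT23",
    "GT211", "GT509", "GT575", "rw4_10", "rw48",
)
#: published allele counts (K) per locus, same order as LOCUS_NAMES
LOCUS_ALLELE_COUNTS = (13, 16, 16, 8, 16, 14, 31, 15, 28, 10)


def lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of a lognormal with the given arithmetic mean and sd."""
    if mean <= 0 or sd <= 0:
        raise ValueError("mean and sd must be positive")
    sigma2 = np.log1p((sd / mean) ** 2)
    return float(np.log(mean) - sigma2 / 2.0), float(np.sqrt(sigma2))


@dataclass
class CohortConfig:
    """Parameters of the true population and its observation processes.

    The logistic parameters are (intercept, slope-per-metre) pairs;
    ``maturity_logistic`` defaults give L50 = 8.20 m, and together with
    ``sex_at_length_logistic`` they imply an overall female fraction of 0.49
    and a proportion mature among females of 0.665 under the pooled length
    distribution.
    """

    n_individuals: int = 69
    prop_female: float = 40 / 69
    #: "by_sex": sex ~ Bernoulli(prop_female), lengths Normal per sex.
    #: "sex_at_length": pooled lengths, sex from the sex-at-length logistic —
    #: the self-consistent structure the maturity correction assumes.
    length_sex_mode: str = "by_sex"
    length_mean_by_sex: dict = field(default_factory=lambda: {"F": 8.3, "M": 7.8})
    length_sd_by_sex: dict = field(default_factory=lambda: {"F": 0.9, "M": 0.9})
    pooled_length_distribution: tuple = (8.04, 1.06)
    maturity_logistic: tuple = (-41.0, 5.0)
    sex_at_length_logistic: tuple = (-11.55, 1.43)
    preg_prob_mature: float = 0.92
    progesterone_lognormal_np: tuple = lognormal_params(*NOT_PREGNANT_MEAN_SD)
    progesterone_lognormal_p: tuple = lognormal_params(*PREGNANT_MEAN_SD)
    n_loci: int = 10
    alleles_per_locus: tuple = LOCUS_ALLELE_COUNTS
    allele_freqs: list | None = None  # per-locus simplex; None -> uniform
    resample_rate: float = 9 / 69
    allow_triplicates: bool = False
    missing_locus_rate: float = 0.0
    years: tuple = (2013, 2014, 2016, 2017, 2018, 2019, 2020)
    seed: int = 0

    def validate(self) -> None:
        if self.n_individuals <= 0:
            raise ValueError("n_individuals must be positive")
        for name in ("prop_female", "preg_prob_mature", "resample_rate",
                     "missing_locus_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.maturity_logistic[1] <= 0:
            raise ValueError("maturity slope must be positive")
        if self.length_sex_mode not in ("by_sex", "sex_at_length"):
            raise ValueError("length_sex_mode must be 'by_sex' or 'sex_at_length'")
        if len(self.alleles_per_locus) != self.n_loci:
            raise ValueError("alleles_per_locus length must equal n_loci")
        mu_np = self.progesterone_lognormal_np[0]
        mu_p = self.progesterone_lognormal_p[0]
        if not mu_p > mu_np:
            raise ValueError("pregnant progesterone median must exceed not-pregnant")
        freqs = self.locus_allele_freqs()
        for i, f in enumerate(freqs):
            f = np.asarray(f, dtype=float)
            if len(f) != self.alleles_per_locus[i]:
                raise ValueError(f"locus {i}: frequency vector has wrong length")
            if np.any(f < 0) or abs(f.sum() - 1.0) > 1e-9:
                raise ValueError(f"locus {i}: allele frequencies must form a simplex")

    def locus_allele_freqs(self) -> list[np.ndarray]:
        if self.allele_freqs is not None:
            return [np.asarray(f, dtype=float) for f in self.allele_freqs]
        return [np.full(k, 1.0 / k) for k in self.alleles_per_locus]

    def locus_names(self) -> tuple[str, ...]:
        if self.n_loci == len(LOCUS_NAMES):
            return LOCUS_NAMES
        return tuple(f"locus{i + 1}" for i in range(self.n_loci))

    def replace(self, **kw) -> "CohortConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class TrueIndividual:
    """Ground truth for one whale; the recovery target of every test."""

    id: str
    sex: str                      # "M" or "F"
    total_length: float           # m
    mature: bool
    pregnant: bool
    progesterone: float           # ng/g; nan for males
    genotype: list                # per-locus (allele, allele) tuples


def gen_population(config: CohortConfig, rng: np.random.Generator | None = None) -> list[TrueIndividual]:
    """Draw the true population. Deterministic given ``config.seed``.

    Sexes are Bernoulli(prop_female); lengths Normal by sex; maturity
    Bernoulli on the maturity logistic; pregnancy Bernoulli(preg_prob_mature)
    for mature females only; progesterone from the class-conditional
    lognormal (males carry NaN).
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_individuals
    if config.length_sex_mode == "sex_at_length":
        mu, sd = config.pooled_length_distribution
        lengths = rng.normal(mu, sd, n)
        a_f, b_f = config.sex_at_length_logistic
        female = rng.random(n) < expit(a_f + b_f * lengths)
    else:
        female = rng.random(n) < config.prop_female
        lengths = np.empty(n)
        for is_f, sx in ((True, "F"), (False, "M")):
            m = female == is_f
            lengths[m] = rng.normal(config.length_mean_by_sex[sx],
                                    config.length_sd_by_sex[sx], m.sum())
    a_m, b_m = config.maturity_logistic
    mature = rng.random(n) < expit(a_m + b_m * lengths)
    pregnant = female & mature & (rng.random(n) < config.preg_prob_mature)
    mu_np, sd_np = config.progesterone_lognormal_np
    mu_p, sd_p = config.progesterone_lognormal_p
    prog = np.where(pregnant,
                    rng.lognormal(mu_p, sd_p, n),
                    rng.lognormal(mu_np, sd_np, n))
    prog = np.where(female, prog, np.nan)
    freqs = config.locus_allele_freqs()
    # allele "sizes" in bp-like integers, even spacing; drawn per locus for all
    # individuals at once
    locus_alleles = []
    for f in freqs:
        idx = rng.choice(len(f), size=(n, 2), p=f)
        locus_alleles.append(np.sort(100 + 2 * idx, axis=1))
    pop: list[TrueIndividual] = []
    for i in range(n):
        genotype = [tuple(int(a) for a in la[i]) for la in locus_alleles]
        pop.append(TrueIndividual(
            id=f"ind{i:04d}",
            sex="F" if female[i] else "M",
            total_length=float(lengths[i]),
            mature=bool(mature[i]),
            pregnant=bool(pregnant[i]),
            progesterone=float(prog[i]),
            genotype=genotype,
        ))
    return pop


def _sample_date(rng: np.random.Generator, year: int) -> str:
    month = int(rng.integers(1, 5))  # Jan-Apr field season
    day = int(rng.integers(1, 29))
    return f"{year:04d}-{month:02d}-{day:02d}"


def gen_genotype_table(pop: list[TrueIndividual], config: CohortConfig,
                       rng: np.random.Generator | None = None) -> pd.DataFrame:
    """One row per biopsy sample; a ``resample_rate`` fraction of individuals
    is biopsied twice within the same year with identical genotypes.

    Loci are dropped (both alleles empty) at ``missing_locus_rate`` to
    exercise the minimum-typed-loci exclusion rule downstream.
    """
    if not pop:
        raise ValueError("population is empty")
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    n = len(pop)
    years = np.asarray(config.years)[rng.integers(0, len(config.years), n)]
    n_dup = int(round(config.resample_rate * n))
    dup_idx = set(rng.choice(n, size=n_dup, replace=False)) if n_dup else set()
    trip_idx = set()
    if config.allow_triplicates and dup_idx:
        trip_idx = {sorted(dup_idx)[0]}
    names = config.locus_names()
    rows = []
    counter = 0
    for i, ind in enumerate(pop):
        n_samples = 1 + (i in dup_idx) + (i in trip_idx)
        for _ in range(n_samples):
            row = {
                "sample_id": f"s{counter:04d}",
                "individual_id_truth": ind.id,
                "date": _sample_date(rng, int(years[i])),
                "sex_marker": ind.sex,
            }
            for name, pair in zip(names, ind.genotype):
                if rng.random() < config.missing_locus_rate:
                    row[f"{name}_a"], row[f"{name}_b"] = np.nan, np.nan
                else:
                    row[f"{name}_a"], row[f"{name}_b"] = pair
            rows.append(row)
            counter += 1
    return pd.DataFrame(rows)


def gen_hormone_table(pop: list[TrueIndividual], config: CohortConfig,
                      rng: np.random.Generator | None = None,
                      efficiency_mean: float = 0.83,
                      efficiency_sd: float = 0.09,
                      plate_size: int = 20) -> pd.DataFrame:
    """Hormone table for the female fraction of the population.

    The stored raw concentration times 1/efficiency recovers the individual's
    true progesterone, mirroring the extraction-efficiency adjustment done in
    the assay QC stage. Efficiencies are truncated to the acceptable range.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    females = [ind for ind in pop if ind.sex == "F"]
    rows = []
    for j, ind in enumerate(females):
        eff = float(np.clip(rng.normal(efficiency_mean, efficiency_sd), 0.62, 1.05))
        rows.append({
            "sample_id": f"h{j:04d}",
            "individual_id": ind.id,
            "raw_progesterone": ind.progesterone * eff,
            "extraction_efficiency": eff,
            "plate_id": f"plate{j // plate_size:02d}",
            "replicate_id": 1,
        })
    return pd.DataFrame(rows)


@dataclass
class AircraftConfig:
    """Camera and altimeter description of one UAS airframe."""

    aircraft_id: str = "LemHex-44"
    focal_length_mm: float = 35.0
    sensor_width_mm: float = 23.5
    image_width_px: float = 6000.0

    def validate(self) -> None:
        for name in ("focal_length_mm", "sensor_width_mm", "image_width_px"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class UASNoise:
    """Observation error of the altimeter and of pixel measurement."""

    altitude_bias: float = 1.0   # multiplicative
    altitude_sd: float = 0.0     # m, additive
    pixel_cv: float = 0.0        # multiplicative on pixel length

    def validate(self) -> None:
        if self.altitude_bias <= 0:
            raise ValueError("altitude_bias must be positive")
        if self.altitude_sd < 0 or self.pixel_cv < 0:
            raise ValueError("noise magnitudes must be non-negative")


def project_to_pixels(true_length_m, true_altitude_m, aircraft: AircraftConfig):
    """Pinhole projection: metres on the sea surface to image pixels."""
    return (np.asarray(true_length_m, dtype=float) * aircraft.focal_length_mm
            * aircraft.image_width_px
            / (aircraft.sensor_width_mm * np.asarray(true_altitude_m, dtype=float)))


QUALITY_ATTRIBUTES = ("focus", "straightness", "roll", "arch", "pitch",
                     "length_meas", "width_meas")


def gen_uas_survey(pop: list[TrueIndividual],
                   aircraft: AircraftConfig | None = None,
                   altitude_range: tuple = (15.0, 83.0),
                   noise: UASNoise | None = None,
                   quality_score_rates: tuple = (0.0, 0.0),
                   n_training: int = 110,
                   training_lengths: tuple = (1.33, 1.40, 1.27, 1.48),
                   training_altitude_range: tuple | None = None,
                   max_images: int = 5,
                   rng: np.random.Generator | None = None,
                   seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Image-measurement and training-object tables for one airframe.

    ``quality_score_rates`` is (P(score 2), P(score 3)) applied independently
    to each of the seven quality attributes. The observed altitude is
    ``true * altitude_bias + Normal(0, altitude_sd)``; training objects pass
    through the identical error process.
    """
    aircraft = aircraft or AircraftConfig()
    noise = noise or UASNoise()
    aircraft.validate()
    noise.validate()
    lo, hi = altitude_range
    if lo <= 0 or hi < lo:
        raise ValueError("altitude_range must be positive and ordered")
    if rng is None:
        rng = np.random.default_rng(seed)
    p2, p3 = quality_score_rates

    def observe(true_len, true_alt):
        px = project_to_pixels(true_len, true_alt, aircraft)
        px = px * (1.0 + rng.normal(0.0, noise.pixel_cv, np.shape(px)) if noise.pixel_cv else 1.0)
        alt_obs = true_alt * noise.altitude_bias + rng.normal(0.0, noise.altitude_sd, np.shape(true_alt))
        return px, alt_obs

    img_rows = []
    for ind in pop:
        n_img = int(rng.integers(1, max_images + 1))
        true_alt = rng.uniform(lo, hi, n_img)
        px, alt_obs = observe(np.full(n_img, ind.total_length), true_alt)
        for j in range(n_img):
            row = {
                "individual_id": ind.id,
                "image_id": f"{ind.id}_img{j}",
                "aircraft_id": aircraft.aircraft_id,
                "pixel_length": float(px[j]),
                "observed_altitude": float(alt_obs[j]),
                "true_altitude": float(true_alt[j]),
                "focal_length_mm": aircraft.focal_length_mm,
                "sensor_width_mm": aircraft.sensor_width_mm,
                "image_width_px": aircraft.image_width_px,
            }
            for attr in QUALITY_ATTRIBUTES:
                u = rng.random()
                row[f"q_{attr}"] = 3 if u < p3 else (2 if u < p3 + p2 else 1)
            img_rows.append(row)
    images = pd.DataFrame(img_rows)

    t_lo, t_hi = training_altitude_range or altitude_range
    tr_len = np.asarray(training_lengths, dtype=float)[
        np.arange(n_training) % len(training_lengths)]
    tr_alt = rng.uniform(t_lo, t_hi, n_training)
    tr_px, tr_obs = observe(tr_len, tr_alt)
    training = pd.DataFrame({
        "known_length": tr_len,
        "pixel_length": tr_px,
        "observed_altitude": tr_obs,
        "true_altitude": tr_alt,
        "aircraft_id": aircraft.aircraft_id,
        "focal_length_mm": aircraft.focal_length_mm,
        "sensor_width_mm": aircraft.sensor_width_mm,
        "image_width_px": aircraft.image_width_px,
    })
    return images, training


def gen_catch_table(n: int,
                    sex_at_length_logistic: tuple = CohortConfig.sex_at_length_logistic,
                    maturity_logistic: tuple = CohortConfig.maturity_logistic,
                    length_distribution: tuple = (8.04, 1.06),
                    rng: np.random.Generator | None = None,
                    seed: int = 0) -> pd.DataFrame:
    """Historical-catch-style records: length, sex and (females) maturity.

    Sex is Bernoulli on the sex-at-length logistic and maturity Bernoulli on
    the maturity logistic, so refitting the two curves on a large table
    recovers the generating parameters.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if rng is None:
        rng = np.random.default_rng(seed)
    a_f, b_f = sex_at_length_logistic
    a_m, b_m = maturity_logistic
    lengths = rng.normal(length_distribution[0], length_distribution[1], n)
    female = rng.random(n) < expit(a_f + b_f * lengths)
    mature = rng.random(n) < expit(a_m + b_m * lengths)
    df = pd.DataFrame({
        "length": lengths,
        "sex": np.where(female, "F", "M"),
        "mature": pd.array(np.where(female, mature, None), dtype="boolean"),
    })
    return df


def ground_truth_frame(pop: list[TrueIndividual]) -> pd.DataFrame:
    return pd.DataFrame([
        {"individual_id": ind.id, "sex": ind.sex, "total_length": ind.total_length,
         "mature": ind.mature, "pregnant": ind.pregnant,
         "progesterone": ind.progesterone}
        for ind in pop
    ])
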