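"""Length-structured maturity correction of the pregnancy rate.

Historical catch records supply two logistic curves on total length: the
probability that a whale of length L is female, p_F(L), and the probability
that a female of length L is sexually mature, p_M(L). Applied to the UAS
length sample, their product yields the expected proportion of mature females

    P_mat = sum_i p_F(L_i) p_M(L_i) / sum_i p_F(L_i),

and the female fraction f = mean_i p_F(L_i) gives the adjusted sex ratio
(1 - f) / f. Dividing the number of pregnant females by P_mat times the
number assayed converts the all-female pregnancy rate into a mature-female
rate; MCMC draws of the curve parameters propagate catch-data uncertainty
into all three quantities. Corrected rates above 1 are reported unclamped —
the upper tail reflects uncertainty in the proportion mature, not an error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import emcee
import statsmodels.api as sm
from scipy.special import expit

from ._logistic import fit_logistic
from .photogrammetry import _harvest


@dataclass
class LogisticCurve:
    alpha: float            # intercept
    beta: float             # per-metre slope
    role: str               # "sex_at_length" or "maturity_at_length"

    def __call__(self, length) -> np.ndarray:
        return expit(self.alpha + self.beta * np.asarray(length, dtype=float))

    @property
    def l50(self) -> float:
        return -self.alpha / self.beta


def _catch_arrays(catch: pd.DataFrame):
    lengths = catch["length"].to_numpy(dtype=float)
    female = (catch["sex"].astype(str).str.upper() == "F").to_numpy()
    mat = catch["mature"]
    known = female & mat.notna().to_numpy()
    mature = mat[known].astype(bool).to_numpy()
    if np.any((lengths < 3) | (lengths > 12)):
        warnings.warn("catch lengths outside the 3-12 m plausibility band",
                      stacklevel=3)
    return lengths, female, lengths[known], mature


def _ml_logistic(x: np.ndarray, y: np.ndarray, role: str) -> LogisticCurve:
    X = sm.add_constant(x)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.GLM(y.astype(float), X, family=sm.families.Binomial()).fit()
        coef = np.asarray(res.params, dtype=float)
        if not np.all(np.isfinite(coef)) or np.max(np.abs(coef)) > 1e3:
            raise ValueError("separation")
    except Exception:
        warnings.warn(f"{role}: perfect separation; using penalized fit",
                      stacklevel=3)
        coef = fit_logistic(x, y.astype(float), ridge=1e-6)
    return LogisticCurve(alpha=float(coef[0]), beta=float(coef[1]), role=role)


def fit_curves_ml(catch: pd.DataFrame) -> tuple[LogisticCurve, LogisticCurve]:
    """Maximum-likelihood logistic fits: P(female | length) over all records,
    P(mature | length) over females of known maturity."""
    lengths, female, f_len, mature = _catch_arrays(catch)
    if female.all() or not female.any():
        raise ValueError("catch must contain both sexes")
    if len(mature) == 0 or mature.all() or not mature.any():
        raise ValueError("catch must contain mature and immature females")
    sex_curve = _ml_logistic(lengths, female, "sex_at_length")
    mat_curve = _ml_logistic(f_len, mature, "maturity_at_length")
    return sex_curve, mat_curve


@dataclass
class MaturityPosterior:
    """MCMC draws of (alpha_F, beta_F, alpha_M, beta_M) with derived L50."""

    alpha_F: np.ndarray
    beta_F: np.ndarray
    alpha_M: np.ndarray
    beta_M: np.ndarray
    diagnostics: dict

    @property
    def n_draws(self) -> int:
        return len(self.alpha_F)

    @property
    def l50(self) -> np.ndarray:
        return -self.alpha_M / self.beta_M

    def p_female(self, lengths) -> np.ndarray:
        """(n_draws, n_lengths) matrix of p_F."""
        L = np.asarray(lengths, dtype=float)
        return expit(self.alpha_F[:, None] + self.beta_F[:, None] * L[None, :])

    def p_mature(self, lengths) -> np.ndarray:
        L = np.asarray(lengths, dtype=float)
        return expit(self.alpha_M[:, None] + self.beta_M[:, None] * L[None, :])


def fit_curves_mcmc(catch: pd.DataFrame, draws: int = 2000,
                    seed: int | None = None, nwalkers: int = 16,
                    warmup: int = 500, steps: int = 3000,
                    prior_sd: float = 10.0,
                    likelihood: bool = True) -> MaturityPosterior:
    """Joint posterior of the two logistic curves under Normal(0, prior_sd^2)
    priors on all four parameters.

    The two Bernoulli likelihoods (sex over all records, maturity over
    females) are independent, so this is two 2-parameter fits sampled
    together. ``likelihood=False`` is a priors-only debug mode.
    """
    lengths, female, f_len, mature = _catch_arrays(catch)
    yF = female.astype(float)
    yM = mature.astype(float)

    def log_prob(theta):
        aF, bF, aM, bM = theta
        if bM <= 0:
            return -np.inf
        lp = -0.5 * np.sum(np.asarray(theta) ** 2) / prior_sd ** 2
        if not likelihood:
            return lp
        etaF = aF + bF * lengths
        etaM = aM + bM * f_len
        llF = np.sum(yF * etaF - np.logaddexp(0.0, etaF))
        llM = np.sum(yM * etaM - np.logaddexp(0.0, etaM))
        return lp + llF + llM

    rng = np.random.default_rng(seed)
    if likelihood:
        sex_c, mat_c = fit_curves_ml(catch)
        center = np.array([sex_c.alpha, sex_c.beta, mat_c.alpha, mat_c.beta])
    else:
        center = np.array([0.0, 0.0, 0.0, 1.0])
    p0 = center[None, :] + rng.normal(0.0, 0.05, (nwalkers, 4)) * np.maximum(np.abs(center), 1.0)
    p0[:, 3] = np.abs(p0[:, 3]) + 1e-3
    sampler = emcee.EnsembleSampler(nwalkers, 4, log_prob)
    if seed is not None:
        sampler.random_state = np.random.RandomState(seed % 2 ** 31).get_state()
    sampler.run_mcmc(p0, warmup + steps, progress=False)
    names = ("alpha_F", "beta_F", "alpha_M", "beta_M")
    flat, diagnostics = _harvest(sampler, warmup, draws, names, rng)
    if not diagnostics["converged"]:
        warnings.warn(f"maturity MCMC convergence not established: "
                      f"{diagnostics['rhat']}", stacklevel=2)
    return MaturityPosterior(alpha_F=flat[:, 0], beta_F=flat[:, 1],
                             alpha_M=flat[:, 2], beta_M=flat[:, 3],
                             diagnostics=diagnostics)


def proportion_mature_females(lengths, posterior: MaturityPosterior) -> np.ndarray:
    """Per-draw expected proportion of mature females in the length sample."""
    L = np.asarray(lengths, dtype=float)
    if L.size == 0:
        raise ValueError("lengths must be non-empty")
    pF = posterior.p_female(L)
    pM = posterior.p_mature(L)
    denom = pF.sum(axis=1)
    if np.any(denom == 0):
        raise ValueError("degenerate draw: sum of female probabilities is zero")
    return (pF * pM).sum(axis=1) / denom


def adjusted_sex_ratio(lengths, posterior: MaturityPosterior) -> np.ndarray:
    """Per-draw M:F ratio implied by the sex-at-length curve on the sample."""
    L = np.asarray(lengths, dtype=float)
    if L.size == 0:
        raise ValueError("lengths must be non-empty")
    f = posterior.p_female(L).mean(axis=1)
    if np.any(f == 0):
        raise ValueError("degenerate draw: female fraction is zero")
    return (1.0 - f) / f


@dataclass
class PosteriorSummary:
    draws: np.ndarray
    median: float
    ci_low: float
    ci_high: float
    n_excluded: int = 0

    @classmethod
    def from_draws(cls, draws: np.ndarray, ci_mass: float = 0.95,
                   n_excluded: int = 0) -> "PosteriorSummary":
        a = 100 * (1 - ci_mass) / 2
        return cls(draws=draws, median=float(np.median(draws)),
                   ci_low=float(np.percentile(draws, a)),
                   ci_high=float(np.percentile(draws, 100 - a)),
                   n_excluded=n_excluded)


def corrected_pregnancy_rate(n_females_assayed: int, pregnant,
                             prop_mature: np.ndarray,
                             rng: np.random.Generator | None = None,
                             ci_mass: float = 0.95) -> PosteriorSummary:
    """Maturity-corrected pregnancy rate: pregnant / (P_mat * n assayed), per draw.

    ``pregnant`` is a fixed classified count, or an array of per-bootstrap
    pregnant-probability sums (counts), or a pregnancy ``RateEstimate`` whose
    replicate rates are converted to counts; replicate values are paired with
    maturity draws by independent uniform resampling. Draws with zero mature
    proportion are excluded and counted.
    """
    if n_females_assayed <= 0:
        raise ValueError("n_females_assayed must be positive")
    pm = np.asarray(prop_mature, dtype=float)
    ok = pm > 0
    n_excluded = int((~ok).sum())
    pm = pm[ok]
    if pm.size == 0:
        raise ValueError("all draws have zero mature proportion")
    if np.isscalar(pregnant) or isinstance(pregnant, (int, float)):
        counts = np.full(pm.size, float(pregnant))
    else:
        per_rep = (np.asarray(pregnant.per_replicate_rates) * pregnant.n
                   if hasattr(pregnant, "per_replicate_rates")
                   else np.asarray(pregnant, dtype=float))
        if rng is None:
            rng = np.random.default_rng()
        counts = per_rep[rng.integers(0, len(per_rep), pm.size)]
    rates = counts / (pm * n_females_assayed)
    return PosteriorSummary.from_draws(rates, ci_mass, n_excluded=n_excluded)


@dataclass
class DemographyEstimate:
    prop_mature_females: PosteriorSummary
    adjusted_sex_ratio_MF: PosteriorSummary
    corrected_pregnancy_rate: PosteriorSummary
    l50: PosteriorSummary


def demography_estimate(lengths, posterior: MaturityPosterior,
                        n_females_assayed: int, pregnant,
                        rng: np.random.Generator | None = None) -> DemographyEstimate:
    """Bundle the three corrected demographic quantities plus L50."""
    pm = proportion_mature_females(lengths, posterior)
    ratio = adjusted_sex_ratio(lengths, posterior)
    rate = corrected_pregnancy_rate(n_females_assayed, pregnant, pm, rng=rng)
    return DemographyEstimate(
        prop_mature_females=PosteriorSummary.from_draws(pm),
        adjusted_sex_ratio_MF=PosteriorSummary.from_draws(ratio),
        corrected_pregnancy_rate=rate,
        l50=PosteriorSummary.from_draws(posterior.l50),
    )


def curves_frame(posterior: MaturityPosterior, grid=None) -> pd.DataFrame:
    """Median curves and 95% bands on a length grid, for reporting."""
    if grid is None:
        grid = np.linspace(4.0, 11.0, 141)
    grid = np.asarray(grid, dtype=float)
    pF = posterior.p_female(grid)
    pM = posterior.p_mature(grid)
    prod = pF * pM
    def med_band(m):
        return (np.median(m, axis=0), np.percentile(m, 2.5, axis=0),
                np.percentile(m, 97.5, axis=0))
    f_med, f_lo, f_hi = med_band(pF)
    m_med, m_lo, m_hi = med_band(pM)
    q_med, q_lo, q_hi = med_band(prod)
    return pd.DataFrame({
        "length_m": grid,
        "p_female": f_med, "p_female_lo": f_lo, "p_female_hi": f_hi,
        "p_mature": m_med, "p_mature_lo": m_lo, "p_mature_hi": m_hi,
        "p_mature_female": q_med, "p_mature_female_lo": q_lo,
        "p_mature_female_hi": q_hi,
    })
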