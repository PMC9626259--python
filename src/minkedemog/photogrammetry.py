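"""UAS photogrammetric length estimation with calibrated measurement error.

Pixel measurements scale to metres through the pinhole relation
``length = pixels * altitude * sensor_width / (focal_length * image_width)``,
but the reported altitude is itself a noisy measurement. A hierarchical error
model — multiplicative altitude bias, additive altitude noise, and a
multiplicative measurement residual — is calibrated by MCMC against training
images of objects of known size, then propagated to each whale: every
posterior draw of the error parameters yields a conditional Gaussian posterior
for true length given that individual's images, producing posterior
predictive length samples summarized by mean and highest-posterior-density
(HPD) intervals.

Image quality gating follows the standard seven-attribute scoring: any
attribute scored 3 rejects the image, as does a score of 2 on two of
{roll, arch, pitch}; at most five passing images are kept per individual.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import emcee

QUALITY_COLUMNS = ("q_focus", "q_straightness", "q_roll", "q_arch", "q_pitch",
                   "q_length_meas", "q_width_meas")
PAIRED_ATTRIBUTES = ("q_roll", "q_arch", "q_pitch")

#: floor on the per-image length sd (m); keeps noise-free data well-posed
SIGMA_FLOOR = 1e-3


def quality_filter(images: pd.DataFrame, max_per_individual: int = 5
                   ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the quality-score gate and the per-individual image cap.

    Returns (kept, rejection_log). The log has one row per dropped image with
    the reason. When more than ``max_per_individual`` images pass, the ones
    with the best (lowest) total quality score are retained, ties broken by
    table order.
    """
    qcols = [c for c in QUALITY_COLUMNS if c in images.columns]
    if not qcols:
        raise ValueError("no quality score columns found")
    q = images[qcols].to_numpy()
    if not np.isin(q, (1, 2, 3)).all():
        raise ValueError("quality scores must be 1, 2 or 3")
    any3 = (q == 3).any(axis=1)
    paired = [c for c in PAIRED_ATTRIBUTES if c in images.columns]
    two2 = (images[paired].to_numpy() == 2).sum(axis=1) >= 2 if paired else np.zeros(len(images), bool)
    reasons = np.where(any3, "score 3 attribute",
                       np.where(two2, "paired score 2 in roll/arch/pitch", ""))
    kept = images.loc[~any3 & ~two2].copy()
    log_rows = [{"image_id": r.get("image_id", i), "individual_id": r.get("individual_id"),
                 "reason": reasons[i]}
                for i, r in images.reset_index(drop=True).iterrows() if reasons[i]]
    # cap per individual, best total score first (stable sort keeps table order)
    kept["_total_q"] = kept[qcols].sum(axis=1)
    capped = []
    for ind, g in kept.groupby("individual_id", sort=False):
        g2 = g.sort_values("_total_q", kind="stable")
        capped.append(g2.iloc[:max_per_individual])
        for _, r in g2.iloc[max_per_individual:].iterrows():
            log_rows.append({"image_id": r.get("image_id"), "individual_id": ind,
                             "reason": f"more than {max_per_individual} passing images"})
    out = pd.concat(capped).drop(columns="_total_q") if capped else kept.drop(columns="_total_q")
    return out, pd.DataFrame(log_rows, columns=["image_id", "individual_id", "reason"])


def naive_length(pixel_length, observed_altitude, sensor_width_mm,
                 focal_length_mm, image_width_px):
    """Deterministic pinhole length (m), treating the observed altitude as true."""
    f = np.asarray(focal_length_mm, dtype=float)
    w = np.asarray(image_width_px, dtype=float)
    if np.any(f <= 0) or np.any(w <= 0) or np.any(np.asarray(sensor_width_mm, float) <= 0):
        raise ValueError("camera parameters must be positive")
    return (np.asarray(pixel_length, dtype=float)
            * np.asarray(observed_altitude, dtype=float)
            * np.asarray(sensor_width_mm, dtype=float) / (f * w))


def naive_length_frame(df: pd.DataFrame) -> np.ndarray:
    return naive_length(df["pixel_length"], df["observed_altitude"],
                        df["sensor_width_mm"], df["focal_length_mm"],
                        df["image_width_px"])


@dataclass
class ErrorModel:
    """Posterior draws of the per-aircraft measurement-error parameters."""

    aircraft_id: str
    bias: np.ndarray            # multiplicative altitude bias
    altitude_sd: np.ndarray     # m
    residual_cv: np.ndarray     # fraction
    diagnostics: dict

    @property
    def n_draws(self) -> int:
        return len(self.bias)


def _split_rhat(chains: np.ndarray) -> float:
    """Split-chain potential scale reduction for one parameter.

    ``chains`` is (n_walkers, n_steps); each walker chain is split in half.
    Applied to autocorrelation-thinned ensemble chains.
    """
    n = chains.shape[1] // 2
    halves = np.concatenate([chains[:, :n], chains[:, n:2 * n]], axis=0)
    w = halves.var(axis=1, ddof=1).mean()
    b = n * halves.mean(axis=1).var(ddof=1)
    if w == 0:
        return 1.0
    return float(np.sqrt((n - 1) / n + b / (n * w)))


def _harvest(sampler: emcee.EnsembleSampler, warmup: int, draws: int,
             names: tuple, rng: np.random.Generator) -> tuple[np.ndarray, dict]:
    """Thin by autocorrelation time, flatten, and report convergence.

    Convergence follows the ensemble-sampler convention: the post-warmup
    chain must exceed 50 integrated autocorrelation times, and split-Rhat on
    the thinned chains must stay below 1.1.
    """
    from emcee.autocorr import integrated_time
    full = sampler.get_chain(discard=warmup)
    try:
        tau = np.asarray(integrated_time(full, tol=0), dtype=float)
    except Exception:
        tau = np.full(len(names), np.nan)
    nsteps = full.shape[0]
    tau_max = float(np.nanmax(tau)) if np.isfinite(tau).any() else float("nan")
    thin = max(1, int(tau_max / 2)) if np.isfinite(tau_max) else 1
    chain = sampler.get_chain(discard=warmup, thin=thin)   # (steps, walkers, d)
    flat = chain.reshape(-1, chain.shape[-1])
    if len(flat) >= draws:
        flat = flat[-draws:]
    else:
        flat = flat[rng.integers(0, len(flat), draws)]
    rhat = {nm: _split_rhat(chain[:, :, k].T) for k, nm in enumerate(names)}
    diagnostics = {
        "rhat": rhat,
        "autocorr_time": {nm: float(t) for nm, t in zip(names, tau)},
        "acceptance_fraction": float(sampler.acceptance_fraction.mean()),
        "converged": bool(np.isfinite(tau_max) and nsteps > 50 * tau_max
                          and all(v < 1.1 for v in rhat.values())),
    }
    return flat, diagnostics


def fit_error_model(training: pd.DataFrame, draws: int = 2000,
                    seed: int | None = None, nwalkers: int = 24,
                    warmup: int = 500, steps: int = 2000) -> ErrorModel:
    """Calibrate (bias, altitude sd, residual CV) from known-size objects.

    The observed naive length of a training object of known size ``L`` imaged
    at observed altitude ``a`` is modelled as Normal with mean ``L * bias``
    and variance ``(L*bias)^2 * (sd^2/a^2 + cv^2)``: the first term propagates
    altimeter noise through the altitude-proportional scaling, the second is
    the multiplicative measurement residual. Priors: bias ~ N(1, 0.25^2),
    sd ~ HalfNormal(5 m), cv ~ HalfNormal(0.15).
    """
    if len(training) < 10:
        raise ValueError("need at least 10 training images")
    known = training["known_length"].to_numpy(dtype=float)
    alt = training["observed_altitude"].to_numpy(dtype=float)
    obs = naive_length_frame(training)
    if alt.std() < 2.0:
        warnings.warn("training altitudes span < 2 m; bias and altitude noise "
                      "are weakly identified", stacklevel=2)
    aircraft_id = str(training["aircraft_id"].iloc[0]) if "aircraft_id" in training else "uas"

    def log_prob(theta):
        bias, sd, cv = theta
        if bias <= 0 or sd < 0 or cv < 0:
            return -np.inf
        lp = (-0.5 * ((bias - 1.0) / 0.25) ** 2
              - 0.5 * (sd / 5.0) ** 2
              - 0.5 * (cv / 0.15) ** 2)
        mu = known * bias
        var = mu ** 2 * (sd ** 2 / alt ** 2 + cv ** 2) + SIGMA_FLOOR ** 2
        return lp - 0.5 * float(np.sum((obs - mu) ** 2 / var + np.log(2 * np.pi * var)))

    rng = np.random.default_rng(seed)
    p0 = np.column_stack([
        rng.normal(1.0, 0.02, nwalkers),
        np.abs(rng.normal(1.0, 0.3, nwalkers)),
        np.abs(rng.normal(0.03, 0.01, nwalkers)),
    ])
    sampler = emcee.EnsembleSampler(nwalkers, 3, log_prob)
    if seed is not None:
        sampler.random_state = np.random.RandomState(seed % 2 ** 31).get_state()
    sampler.run_mcmc(p0, warmup + steps, progress=False)
    flat, diagnostics = _harvest(sampler, warmup, draws,
                                 ("bias", "altitude_sd", "residual_cv"), rng)
    return ErrorModel(aircraft_id=aircraft_id, bias=flat[:, 0],
                      altitude_sd=flat[:, 1], residual_cv=flat[:, 2],
                      diagnostics=diagnostics)


@dataclass
class LengthPosterior:
    individual_id: str
    samples: np.ndarray         # posterior predictive total lengths (m)
    mean: float
    hpd95: tuple
    hpd65: tuple
    n_images: int


def hpd_interval(samples, mass: float = 0.95) -> tuple[float, float]:
    """Shortest contiguous interval containing ``ceil(mass * n)`` samples."""
    s = np.sort(np.asarray(samples, dtype=float))
    n = len(s)
    if n < 2:
        raise ValueError("need at least 2 samples")
    if not 0 < mass < 1:
        raise ValueError("mass must lie in (0, 1)")
    k = int(np.ceil(mass * n))
    k = min(max(k, 2), n)
    widths = s[k - 1:] - s[:n - k + 1]
    i = int(np.argmin(widths))
    return float(s[i]), float(s[i + k - 1])


def estimate_length(measurements: pd.DataFrame, model: ErrorModel,
                    prior: tuple = (3.0, 12.0), draws: int = 2000,
                    seed: int | None = None) -> LengthPosterior:
    """Posterior predictive total length for one individual.

    For each resampled error-model draw, the images' naive lengths define a
    conditional Gaussian posterior for true length (independent Gaussian
    likelihood per image with the plug-in variance of the calibration model),
    truncated to the length prior; one length is drawn per error draw.
    """
    if len(measurements) == 0:
        raise ValueError("no quality-passing measurements for this individual")
    rng = np.random.default_rng(seed)
    obs = naive_length_frame(measurements)                 # (J,)
    alt = measurements["observed_altitude"].to_numpy(dtype=float)
    idx = rng.integers(0, model.n_draws, draws)
    bias = model.bias[idx][:, None]
    sd = model.altitude_sd[idx][:, None]
    cv = model.residual_cv[idx][:, None]
    var = obs[None, :] ** 2 * (sd ** 2 / alt[None, :] ** 2 + cv ** 2) + SIGMA_FLOOR ** 2
    prec = (bias ** 2 / var).sum(axis=1)
    mu = (bias * obs[None, :] / var).sum(axis=1) / prec
    sigma = 1.0 / np.sqrt(prec)
    lo, hi = prior
    # inverse-CDF sampling of the truncated normal
    from scipy.stats import norm
    a = norm.cdf((lo - mu) / sigma)
    b = norm.cdf((hi - mu) / sigma)
    u = rng.uniform(a, np.maximum(b, a + 1e-12))
    samples = mu + sigma * norm.ppf(np.clip(u, 1e-12, 1 - 1e-12))
    samples = np.clip(samples, lo, hi)
    ind = str(measurements["individual_id"].iloc[0]) if "individual_id" in measurements else ""
    return LengthPosterior(
        individual_id=ind, samples=samples, mean=float(samples.mean()),
        hpd95=hpd_interval(samples, 0.95), hpd65=hpd_interval(samples, 0.65),
        n_images=len(measurements),
    )


def estimate_lengths(images: pd.DataFrame, model: ErrorModel,
                     prior: tuple = (3.0, 12.0), draws: int = 2000,
                     seed: int | None = None) -> list[LengthPosterior]:
    """Per-individual posteriors for a quality-filtered image table."""
    rng = np.random.default_rng(seed)
    out = []
    for ind, g in images.groupby("individual_id", sort=True):
        out.append(estimate_length(g, model, prior=prior, draws=draws,
                                   seed=int(rng.integers(0, 2 ** 31 - 1))))
    return out


def lengths_frame(posteriors: list[LengthPosterior]) -> pd.DataFrame:
    return pd.DataFrame([{
        "individual_id": p.individual_id, "mean_m": p.mean,
        "hpd95_lo": p.hpd95[0], "hpd95_hi": p.hpd95[1],
        "hpd65_lo": p.hpd65[0], "hpd65_hi": p.hpd65[1],
        "n_images": p.n_images,
    } for p in posteriors])


def length_summary(posteriors: list[LengthPosterior]) -> dict:
    """Cohort summary of posterior mean lengths and 95% HPD widths."""
    if not posteriors:
        raise ValueError("no posteriors supplied")
    means = np.array([p.mean for p in posteriors])
    widths = np.array([p.hpd95[1] - p.hpd95[0] for p in posteriors])
    def stats(x):
        return {"mean": float(x.mean()),
                "sd": float(x.std(ddof=1)) if len(x) > 1 else 0.0,
                "min": float(x.min()), "max": float(x.max())}
    return {"n_individuals": len(posteriors),
            "length_m": stats(means), "hpd95_width_m": stats(widths)}
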