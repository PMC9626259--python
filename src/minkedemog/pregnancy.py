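"""Blubber-progesterone pregnancy assignment.

The assay stage adjusts concentrations for extraction efficiency, checks
assay QC (replicate coefficients of variation, parallelism of serial
dilutions against the standard curve), fits a logistic pregnancy-probability
model on log10 concentration from a labeled reference set, wraps it in a
nonparametric-bootstrap confidence envelope, classifies each female as
pregnant / not-pregnant / undetermined, and estimates the cohort pregnancy
rate by summing per-sample probabilities within each bootstrap replicate.

Two reference modes mirror the two assignment models used in the field:
``external_reference`` takes a labeled training set from another population,
while ``self_bounded`` labels the cohort's own samples using the concentration
gap observed in common minke whales of known status (not-pregnant at most
3.43 ng/g, pregnant at least 22.84 ng/g), leaving in-gap samples unlabeled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._logistic import fit_logistic, predict_logistic

#: minimum acceptable extraction efficiency
MIN_EFFICIENCY = 0.60
#: concentration bounds (ng/g) defining the self-bounded reference classes
NOT_PREGNANT_MAX = 3.43
PREGNANT_MIN = 22.84


def adjust_for_efficiency(raw: float, efficiency: float) -> float:
    """Efficiency-adjusted concentration, raw / efficiency (ng/g)."""
    if efficiency <= 0 or efficiency > 1.5:
        raise ValueError("efficiency must lie in (0, 1.5]")
    return raw / efficiency


def efficiency_acceptable(efficiency: float) -> bool:
    return efficiency >= MIN_EFFICIENCY


def prepare_hormones(df: pd.DataFrame) -> pd.DataFrame:
    """Add adjusted concentration and validity columns to a hormone table."""
    out = df.copy()
    eff = out["extraction_efficiency"].to_numpy(dtype=float)
    if np.any(eff <= 0) or np.any(eff > 1.5):
        raise ValueError("extraction efficiencies must lie in (0, 1.5]")
    out["adjusted_progesterone"] = out["raw_progesterone"] / eff
    out["efficiency_ok"] = eff >= MIN_EFFICIENCY
    return out


@dataclass
class AssayCV:
    intra_cv: float    # percent
    inter_cv: float    # percent; nan when no group spans plates


def _cv(values: np.ndarray) -> float:
    m = float(np.mean(values))
    if m == 0:
        raise ValueError("group mean is zero; CV undefined")
    return 100.0 * float(np.std(values, ddof=1)) / m


def assay_cv(df: pd.DataFrame, value: str = "concentration",
             plate: str = "plate_id", group: str = "replicate_group") -> AssayCV:
    """Intra- and inter-assay coefficients of variation (percent).

    Intra: CV of replicate wells within each (plate, group) cell, averaged.
    Inter: CV of per-plate means for groups run on more than one plate,
    averaged. Every within-plate cell must hold at least two replicates.
    """
    intra = []
    for _, cell in df.groupby([plate, group]):
        vals = cell[value].to_numpy(dtype=float)
        if len(vals) < 2:
            raise ValueError("each within-plate replicate group needs >= 2 replicates")
        intra.append(_cv(vals))
    inter = []
    for _, g in df.groupby(group):
        plate_means = g.groupby(plate)[value].mean().to_numpy(dtype=float)
        if len(plate_means) >= 2:
            inter.append(_cv(plate_means))
    return AssayCV(intra_cv=float(np.mean(intra)),
                   inter_cv=float(np.mean(inter)) if inter else float("nan"))


@dataclass
class ParallelismResult:
    slope_sample: float
    slope_standard: float
    slope_ratio: float
    r_squared: float          # of the joint common-slope fit
    parallel: bool


def parallelism_check(dilution_series, standard_curve,
                      slope_tolerance: float = 0.1) -> ParallelismResult:
    """Compare the serially diluted pooled extract against the standard curve.

    Both inputs are sequences of (dilution factor, response) pairs. Responses
    are regressed on log2 dilution separately (for the slope ratio) and
    jointly with a common slope and separate intercepts (for the r-squared of
    the parallel fit). Parallelism is accepted when the sample/standard slope
    ratio lies within ``slope_tolerance`` of 1.
    """
    def parts(series):
        arr = np.asarray(series, dtype=float)
        if arr.ndim != 2 or arr.shape[0] < 3:
            raise ValueError("each series needs at least 3 (dilution, response) points")
        return np.log2(arr[:, 0]), arr[:, 1]

    xs, ys = parts(dilution_series)
    xt, yt = parts(standard_curve)
    slope_s = float(np.polyfit(xs, ys, 1)[0])
    slope_t = float(np.polyfit(xt, yt, 1)[0])
    # joint fit: response = a_s*[sample] + a_t*[standard] + b*logdose
    X = np.zeros((len(xs) + len(xt), 3))
    X[:len(xs), 0] = 1.0
    X[len(xs):, 1] = 1.0
    X[:, 2] = np.concatenate([xs, xt])
    y = np.concatenate([ys, yt])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid ** 2)) / sst if sst > 0 else 1.0
    ratio = slope_s / slope_t if slope_t != 0 else float("inf")
    return ParallelismResult(slope_sample=slope_s, slope_standard=slope_t,
                             slope_ratio=ratio, r_squared=r2,
                             parallel=abs(ratio - 1.0) <= slope_tolerance)


@dataclass
class ReferenceSet:
    """Labeled (log10 concentration, pregnancy) records for model fitting."""

    log10_conc: np.ndarray
    labels: np.ndarray                  # 1 pregnant, 0 not pregnant
    provenance: str                     # "external_reference" or "self_bounded"
    bounds: tuple = (NOT_PREGNANT_MAX, PREGNANT_MIN)
    unlabeled_log10: np.ndarray = field(default_factory=lambda: np.array([]))


def build_reference(concentrations, mode: str,
                    external: pd.DataFrame | None = None,
                    bounds: tuple = (NOT_PREGNANT_MAX, PREGNANT_MIN)) -> ReferenceSet:
    """Assemble the labeled reference for the pregnancy model.

    ``external_reference`` returns the supplied labeled table unchanged
    (columns ``conc`` or ``log10_conc`` plus ``label``). ``self_bounded``
    labels the cohort's own concentrations by the gap bounds; samples inside
    the gap stay unlabeled and are scored by the fitted model only.
    """
    np_max, p_min = bounds
    if mode == "external_reference":
        if external is None or len(external) == 0:
            raise ValueError("external_reference mode requires a labeled set")
        if "log10_conc" in external:
            lc = external["log10_conc"].to_numpy(dtype=float)
        else:
            lc = np.log10(external["conc"].to_numpy(dtype=float))
        labels = external["label"].to_numpy(dtype=int)
        if labels.min() == labels.max():
            raise ValueError("external reference must contain both classes")
        return ReferenceSet(log10_conc=lc, labels=labels, provenance=mode, bounds=bounds)
    if mode != "self_bounded":
        raise ValueError(f"unknown reference mode: {mode!r}")
    conc = np.asarray(concentrations, dtype=float)
    if np.any(conc <= 0):
        raise ValueError("concentrations must be positive")
    is_np = conc <= np_max
    is_p = conc >= p_min
    if is_np.sum() < 2 or is_p.sum() < 2:
        raise ValueError("self_bounded mode needs >= 2 samples in each bound region")
    labeled = is_np | is_p
    return ReferenceSet(
        log10_conc=np.log10(conc[labeled]),
        labels=is_p[labeled].astype(int),
        provenance=mode,
        bounds=bounds,
        unlabeled_log10=np.log10(conc[~labeled]),
    )


@dataclass
class PregnancyModel:
    """Point logistic fit plus B bootstrap replicate coefficient sets."""

    coef: np.ndarray                    # (intercept, slope) on log10 conc
    boot_coefs: np.ndarray              # (B, 2)
    envelope_mass: float = 0.95
    reference: ReferenceSet | None = None

    @property
    def B(self) -> int:
        return len(self.boot_coefs)

    def predict_point(self, conc) -> np.ndarray:
        return predict_logistic(self.coef, np.log10(np.asarray(conc, dtype=float)))

    def predict_replicates(self, conc) -> np.ndarray:
        """(B, n) matrix of replicate predicted probabilities."""
        return predict_logistic(self.boot_coefs, np.log10(np.asarray(conc, dtype=float)))

    def envelope(self, conc) -> tuple[np.ndarray, np.ndarray]:
        """Pointwise bootstrap percentile band at the given concentrations."""
        reps = self.predict_replicates(conc)
        a = 100 * (1.0 - self.envelope_mass) / 2.0
        return (np.percentile(reps, a, axis=0),
                np.percentile(reps, 100 - a, axis=0))


def fit_pregnancy_model(reference: ReferenceSet, B: int = 10_000,
                        seed: int | None = None,
                        ridge: float = 1e-4) -> PregnancyModel:
    """Logistic fit of pregnancy on log10 concentration with B bootstrap refits.

    Each replicate resamples the reference records with replacement and
    refits; the concentration gap makes complete separation routine, so all
    fits are ridge-stabilized (tiny penalty) to keep coefficients finite.
    """
    x, y = reference.log10_conc, reference.labels.astype(float)
    if y.min() == y.max():
        raise ValueError("reference must contain both classes")
    if B < 1:
        raise ValueError("B must be >= 1")
    coef = fit_logistic(x, y, ridge=ridge)
    rng = np.random.default_rng(seed)
    n = len(x)
    boot = np.empty((B, 2))
    for b in range(B):
        idx = rng.integers(0, n, n)
        yb = y[idx]
        if yb.min() == yb.max():
            # single-class resample: probability curve is flat at the class
            boot[b] = (50.0 if yb[0] == 1 else -50.0, 0.0)
        else:
            boot[b] = fit_logistic(x[idx], yb, ridge=ridge)
    return PregnancyModel(coef=coef, boot_coefs=boot, reference=reference)


@dataclass
class PregnancyCall:
    individual_id: str
    concentration: float
    point_probability: float
    ci_low: float
    ci_high: float
    call: str                           # pregnant / not_pregnant / undetermined


def classify(model: PregnancyModel, conc: float, individual_id: str = "",
             upper: float = 0.999, lower: float = 0.001,
             use_ci: bool = False) -> PregnancyCall:
    """Assign pregnancy status from the point probability at ``conc``.

    The default rule keys on the point estimate (> upper -> pregnant,
    < lower -> not pregnant, else undetermined) with the bootstrap percentile
    interval reported alongside; ``use_ci=True`` instead requires the whole
    interval to clear the threshold.
    """
    if conc <= 0:
        raise ValueError("concentration must be positive")
    p = float(model.predict_point([conc])[0])
    reps = model.predict_replicates([conc])[:, 0]
    a = 100 * (1.0 - model.envelope_mass) / 2.0
    lo, hi = float(np.percentile(reps, a)), float(np.percentile(reps, 100 - a))
    if use_ci:
        call = ("pregnant" if lo > upper
                else "not_pregnant" if hi < lower else "undetermined")
    else:
        call = ("pregnant" if p > upper
                else "not_pregnant" if p < lower else "undetermined")
    return PregnancyCall(individual_id=individual_id, concentration=float(conc),
                         point_probability=p, ci_low=lo, ci_high=hi, call=call)


def classify_table(model: PregnancyModel, hormones: pd.DataFrame,
                   conc_col: str = "adjusted_progesterone",
                   id_col: str = "individual_id", **kw) -> pd.DataFrame:
    calls = [classify(model, row[conc_col], str(row[id_col]), **kw)
             for _, row in hormones.iterrows()]
    return pd.DataFrame([vars(c) for c in calls])


@dataclass
class RateEstimate:
    mean_rate: float
    ci_low: float
    ci_high: float
    per_replicate_rates: np.ndarray
    n: int


def rate_from_probabilities(probs, n: int | None = None,
                            ci_mass: float = 0.95) -> RateEstimate:
    """Pregnancy rate from per-replicate probabilities.

    ``probs`` is (B, n) — replicate b's predicted probabilities for the n
    samples — or 1-D for a single replicate. Each replicate's rate is the
    probability sum over samples divided by n.
    """
    p = np.atleast_2d(np.asarray(probs, dtype=float))
    if p.size == 0:
        raise ValueError("no probabilities supplied")
    n = p.shape[1] if n is None else n
    rates = p.sum(axis=1) / n
    a = 100 * (1.0 - ci_mass) / 2.0
    return RateEstimate(mean_rate=float(rates.mean()),
                        ci_low=float(np.percentile(rates, a)),
                        ci_high=float(np.percentile(rates, 100 - a)),
                        per_replicate_rates=rates, n=n)


def pregnancy_rate(model: PregnancyModel, concentrations,
                   ci_mass: float = 0.95) -> RateEstimate:
    """Probability-sum pregnancy rate over the cohort with bootstrap CI."""
    conc = np.asarray(concentrations, dtype=float)
    if conc.size == 0:
        raise ValueError("no concentrations supplied")
    return rate_from_probabilities(model.predict_replicates(conc), ci_mass=ci_mass)


def replicate_consistency(calls: pd.DataFrame,
                          id_col: str = "individual_id",
                          call_col: str = "call") -> pd.DataFrame:
    """Per-individual agreement of pregnancy calls across repeat samples."""
    rows = []
    for ind, g in calls.groupby(id_col):
        rows.append({
            id_col: ind,
            "n_samples": len(g),
            "calls": sorted(g[call_col].unique()),
            "consistent": g[call_col].nunique() == 1,
        })
    return pd.DataFrame(rows)
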