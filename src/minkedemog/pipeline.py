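"""End-to-end orchestration: simulate or load the five input tables, run
identity -> pregnancy -> lengths -> demography, and emit a consolidated
report.

All randomness derives from one master seed fanned out to per-stage seeds
through ``numpy.random.SeedSequence`` spawn keys, so any stage can be rerun
independently yet reproducibly, and an identical config + seed yields a
byte-identical report.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import demography, identity, photogrammetry, pregnancy, synth

STAGES = ("simulate", "identity", "pregnancy", "lengths", "demography")


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    ss = np.random.SeedSequence(master_seed, spawn_key=(STAGES.index(stage),))
    return int(ss.generate_state(1)[0] % (2 ** 31))


@dataclass
class RunConfig:
    """Everything a pipeline run needs: inputs (or a simulate block), stage
    parameters, master seed and output directory."""

    outdir: str = "minkedemog_out"
    seed: int = 0
    simulate: dict | None = None        # CohortConfig overrides + survey/catch sizes
    inputs: dict = field(default_factory=dict)   # genotypes/hormones/images/training/catch paths
    min_match_loci: int = 7
    min_typed_loci: int = 7
    bootstrap_B: int = 10_000
    reference_mode: str = "self_bounded"
    mcmc_draws: int = 2000
    error_model_draws: int = 2000
    length_prior: tuple = (3.0, 12.0)
    hpd_masses: tuple = (0.95, 0.65)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["length_prior"] = list(self.length_prior)
        d["hpd_masses"] = list(self.hpd_masses)
        return d


def _simulate_bundle(config: RunConfig, outdir: Path) -> dict:
    """Generate the five input tables plus ground truth; returns paths."""
    sim = dict(config.simulate or {})
    survey_keys = {"n_training", "quality_score_rates", "altitude_range",
                   "altitude_bias", "altitude_sd", "pixel_cv", "catch_n"}
    cohort_kw = {k: v for k, v in sim.items() if k not in survey_keys}
    cohort_kw.setdefault("seed", stage_seed(config.seed, "simulate"))
    for tuple_key in ("maturity_logistic", "sex_at_length_logistic",
                      "progesterone_lognormal_np", "progesterone_lognormal_p",
                      "alleles_per_locus", "years"):
        if tuple_key in cohort_kw:
            cohort_kw[tuple_key] = tuple(cohort_kw[tuple_key])
    cc = synth.CohortConfig(**cohort_kw)
    pop = synth.gen_population(cc)
    genotypes = synth.gen_genotype_table(pop, cc)
    hormones = synth.gen_hormone_table(pop, cc)
    noise = synth.UASNoise(altitude_bias=sim.get("altitude_bias", 1.02),
                           altitude_sd=sim.get("altitude_sd", 1.0),
                           pixel_cv=sim.get("pixel_cv", 0.02))
    images, training = synth.gen_uas_survey(
        pop, altitude_range=tuple(sim.get("altitude_range", (15.0, 83.0))),
        noise=noise,
        quality_score_rates=tuple(sim.get("quality_score_rates", (0.08, 0.04))),
        n_training=sim.get("n_training", 110),
        seed=cc.seed + 10)
    catch = synth.gen_catch_table(
        sim.get("catch_n", 2000),
        sex_at_length_logistic=cc.sex_at_length_logistic,
        maturity_logistic=cc.maturity_logistic,
        seed=cc.seed + 11)
    paths = {}
    for name, df in (("genotypes", genotypes), ("hormones", hormones),
                     ("images", images), ("training", training),
                     ("catch", catch),
                     ("ground_truth", synth.ground_truth_frame(pop))):
        p = outdir / f"{name}.csv"
        df.to_csv(p, index=False)
        paths[name] = str(p)
    return paths


def validate_inputs(config: RunConfig) -> list[dict]:
    """Schema and plausibility checks; returns machine-readable issues."""
    issues = []
    required_cols = {
        "genotypes": {"sample_id", "date", "sex_marker"},
        "hormones": {"sample_id", "raw_progesterone", "extraction_efficiency"},
        "images": {"individual_id", "pixel_length", "observed_altitude",
                   "focal_length_mm", "sensor_width_mm", "image_width_px"},
        "training": {"known_length", "pixel_length", "observed_altitude"},
        "catch": {"length", "sex", "mature"},
    }
    for name, cols in required_cols.items():
        path = config.inputs.get(name)
        if path is None:
            continue
        if not Path(path).exists():
            issues.append({"severity": "error", "file": name,
                           "message": f"file not found: {path}"})
            continue
        df = pd.read_csv(path)
        missing = cols - set(df.columns)
        if missing:
            issues.append({"severity": "error", "file": name,
                           "message": f"missing columns: {sorted(missing)}"})
            continue
        if name == "hormones":
            bad = df["extraction_efficiency"] < pregnancy.MIN_EFFICIENCY
            if bad.any():
                issues.append({
                    "severity": "warning", "file": name,
                    "message": f"{int(bad.sum())} sample(s) below the "
                               f"{pregnancy.MIN_EFFICIENCY:.0%} extraction-"
                               "efficiency acceptance rule"})
        if name in ("images", "training"):
            if (df["observed_altitude"] <= 0).any():
                issues.append({"severity": "error", "file": name,
                               "message": "non-positive altitude"})
        if name == "catch":
            out = (df["length"] < 3) | (df["length"] > 12)
            if out.any():
                issues.append({"severity": "warning", "file": name,
                               "message": f"{int(out.sum())} catch length(s) "
                                          "outside 3-12 m"})
    return issues


def _file_hash(path: str) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Execute all available stages and write per-stage outputs + report.

    Missing inputs degrade gracefully: without a catch table the demography
    section is marked unavailable, without images the length section, etc.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    inputs = dict(config.inputs)
    if config.simulate is not None:
        inputs.update(_simulate_bundle(config, outdir))
    report: dict = {"provenance": {
        "config": config.to_dict(),
        "master_seed": config.seed,
        "stage_seeds": {s: stage_seed(config.seed, s) for s in STAGES},
        "input_hashes": {k: _file_hash(v) for k, v in inputs.items()
                         if Path(v).exists()},
    }}

    # ---- identity ---------------------------------------------------------
    clusters = None
    if "genotypes" in inputs:
        gdf = pd.read_csv(inputs["genotypes"])
        profiles = identity.profiles_from_frame(gdf)
        stats = identity.locus_statistics(
            profiles, locus_names=[c[:-2] for c in gdf.columns if c.endswith("_a")])
        match = identity.match_genotypes(profiles, config.min_match_loci,
                                         config.min_typed_loci)
        clusters = match.clusters
        tallies = identity.sex_ratio_report(clusters)
        identity.locus_stats_frame(stats).to_csv(outdir / "locus_stats.csv", index=False)
        identity.sex_tally_frame(tallies).to_csv(outdir / "sex_tally.csv", index=False)
        pd.DataFrame([{
            "individual_id": c.individual_id, "n_samples": len(c.sample_ids),
            "sex": c.consensus_sex, "sample_ids": ";".join(c.sample_ids),
        } for c in clusters]).to_csv(outdir / "individuals.csv", index=False)
        pid7 = identity.combined_pid(stats, min(config.min_match_loci, len(stats)))
        total = [t for t in tallies if t.stratum == "total"][0]
        report["identity"] = {
            "available": True,
            "n_samples": len(profiles),
            "n_excluded": len(match.excluded),
            "n_individuals": len(clusters),
            "n_males": total.n_males, "n_females": total.n_females,
            "ratio_MF": total.ratio_MF, "parity_p": total.binomial_p,
            "male_pct": 100 * total.male_fraction,
            "male_cl_pct": [100 * v for v in total.male_cl],
            "combined_pid_7loci": {"min": pid7.min, "max": pid7.max,
                                   "mean": pid7.mean},
        }
    else:
        report["identity"] = {"available": False}

    # ---- pregnancy --------------------------------------------------------
    rate = None
    n_females_assayed = 0
    if "hormones" in inputs:
        hdf = pregnancy.prepare_hormones(pd.read_csv(inputs["hormones"]))
        hdf = hdf[hdf["efficiency_ok"]]
        ref = pregnancy.build_reference(
            hdf["adjusted_progesterone"].to_numpy(), config.reference_mode)
        model = pregnancy.fit_pregnancy_model(
            ref, B=config.bootstrap_B, seed=stage_seed(config.seed, "pregnancy"))
        calls = pregnancy.classify_table(model, hdf)
        rate = pregnancy.pregnancy_rate(model, hdf["adjusted_progesterone"].to_numpy())
        calls.to_csv(outdir / "calls.csv", index=False)
        n_females_assayed = len(hdf)
        counts = calls["call"].value_counts().to_dict()
        rate_info = {
            "mean_rate_pct": 100 * rate.mean_rate,
            "ci_pct": [100 * rate.ci_low, 100 * rate.ci_high],
            "B": model.B, "mode": config.reference_mode,
            "n_assayed": n_females_assayed,
            "n_pregnant": int(counts.get("pregnant", 0)),
            "n_not_pregnant": int(counts.get("not_pregnant", 0)),
            "n_undetermined": int(counts.get("undetermined", 0)),
        }
        (outdir / "rate.json").write_text(json.dumps(rate_info, indent=2))
        report["pregnancy"] = {"available": True, **rate_info}
    else:
        report["pregnancy"] = {"available": False}

    # ---- lengths ----------------------------------------------------------
    lengths_m = None
    if "images" in inputs and "training" in inputs:
        images = pd.read_csv(inputs["images"])
        training = pd.read_csv(inputs["training"])
        kept, _ = photogrammetry.quality_filter(images)
        err = photogrammetry.fit_error_model(
            training, draws=config.error_model_draws,
            seed=stage_seed(config.seed, "lengths"))
        posts = photogrammetry.estimate_lengths(
            kept, err, prior=tuple(config.length_prior),
            seed=stage_seed(config.seed, "lengths") + 1)
        photogrammetry.lengths_frame(posts).to_csv(outdir / "lengths.csv", index=False)
        summary = photogrammetry.length_summary(posts)
        (outdir / "length_summary.json").write_text(json.dumps(summary, indent=2))
        lengths_m = np.array([p.mean for p in posts])
        report["lengths"] = {"available": True,
                             "error_model": err.diagnostics, **summary}
    else:
        report["lengths"] = {"available": False}

    # ---- demography -------------------------------------------------------
    if "catch" in inputs and lengths_m is not None and rate is not None:
        catch = pd.read_csv(inputs["catch"])
        seed_d = stage_seed(config.seed, "demography")
        post = demography.fit_curves_mcmc(catch, draws=config.mcmc_draws,
                                          seed=seed_d)
        n_pregnant = report["pregnancy"]["n_pregnant"]
        est = demography.demography_estimate(
            lengths_m, post, n_females_assayed, n_pregnant,
            rng=np.random.default_rng(seed_d + 1))
        demography.curves_frame(post).to_csv(outdir / "curves.csv", index=False)

        def summ(s: demography.PosteriorSummary, scale=1.0):
            return {"median": scale * s.median,
                    "ci": [scale * s.ci_low, scale * s.ci_high]}

        demo = {
            "available": True,
            "l50_m": summ(est.l50),
            "prop_mature_females_pct": summ(est.prop_mature_females, 100),
            "adjusted_sex_ratio_MF": summ(est.adjusted_sex_ratio_MF),
            "corrected_pregnancy_rate_pct": summ(est.corrected_pregnancy_rate, 100),
            "n_pregnant": n_pregnant, "n_females_assayed": n_females_assayed,
            "mcmc": post.diagnostics,
        }
        (outdir / "demography.json").write_text(json.dumps(demo, indent=2))
        report["demography"] = demo
    else:
        report["demography"] = {"available": False}

    report_json = json.dumps(report, indent=2, sort_keys=True)
    (outdir / "report.json").write_text(report_json)
    (outdir / "report.txt").write_text(_render_text(report))
    report["provenance"]["report_hash"] = hashlib.sha256(
        report_json.encode()).hexdigest()[:16]
    return report


def _render_text(report: dict) -> str:
    lines = ["minkedemog pipeline report", "=" * 28]
    ident = report.get("identity", {})
    if ident.get("available"):
        lines += [
            "",
            f"Individuals: {ident['n_individuals']} "
            f"({ident['n_males']} M, {ident['n_females']} F) "
            f"from {ident['n_samples']} samples "
            f"({ident['n_excluded']} excluded)",
            f"Sex ratio {ident['ratio_MF']:.2f} M:F, parity p = {ident['parity_p']:.3f}, "
            f"males {ident['male_pct']:.2f}% "
            f"(95% CL {ident['male_cl_pct'][0]:.2f}-{ident['male_cl_pct'][1]:.2f})",
        ]
    preg = report.get("pregnancy", {})
    if preg.get("available"):
        lines += [
            "",
            f"Pregnancy: {preg['n_pregnant']} pregnant / "
            f"{preg['n_not_pregnant']} not pregnant / "
            f"{preg['n_undetermined']} undetermined of {preg['n_assayed']} females",
            f"Probability-sum rate {preg['mean_rate_pct']:.2f}% "
            f"(95% CI {preg['ci_pct'][0]:.2f}-{preg['ci_pct'][1]:.2f}, B = {preg['B']})",
        ]
    lng = report.get("lengths", {})
    if lng.get("available"):
        s = lng["length_m"]
        w = lng["hpd95_width_m"]
        lines += [
            "",
            f"Lengths: n = {lng['n_individuals']}, mean {s['mean']:.2f} m "
            f"(sd {s['sd']:.2f}, range {s['min']:.2f}-{s['max']:.2f})",
            f"95% HPD width mean {w['mean']:.2f} m (range {w['min']:.2f}-{w['max']:.2f})",
        ]
    demo = report.get("demography", {})
    if demo.get("available"):
        lines += [
            "",
            f"L50: {demo['l50_m']['median']:.2f} m "
            f"(95% CrI {demo['l50_m']['ci'][0]:.2f}-{demo['l50_m']['ci'][1]:.2f})",
            f"Proportion mature females: {demo['prop_mature_females_pct']['median']:.1f}% "
            f"(95% CrI {demo['prop_mature_females_pct']['ci'][0]:.1f}-"
            f"{demo['prop_mature_females_pct']['ci'][1]:.1f})",
            f"Adjusted sex ratio: {demo['adjusted_sex_ratio_MF']['median']:.2f} M:F",
            f"Corrected pregnancy rate: "
            f"{demo['corrected_pregnancy_rate_pct']['median']:.1f}% "
            f"(95% CrI {demo['corrected_pregnancy_rate_pct']['ci'][0]:.1f}-"
            f"{demo['corrected_pregnancy_rate_pct']['ci'][1]:.1f})",
        ]
    return "\n".join(lines) + "\n"
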