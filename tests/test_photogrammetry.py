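"""Quality gating, pinhole scaling, HPD computation and error-model tests."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from minkedemog import photogrammetry, synth


def _image_row(ind="w1", **scores):
    row = {"individual_id": ind, "image_id": f"{ind}_{len(scores)}",
           "pixel_length": 1000.0, "observed_altitude": 40.0,
           "focal_length_mm": 35.0, "sensor_width_mm": 23.5,
           "image_width_px": 6000.0}
    for attr in photogrammetry.QUALITY_COLUMNS:
        row[attr] = scores.get(attr, 1)
    return row


class TestQualityFilter:
    def test_all_ones_kept(self):
        df = pd.DataFrame([_image_row()])
        kept, log = photogrammetry.quality_filter(df)
        assert len(kept) == 1 and len(log) == 0

    def test_any_score_three_dropped(self):
        df = pd.DataFrame([_image_row(q_focus=3)])
        kept, log = photogrammetry.quality_filter(df)
        assert len(kept) == 0
        assert log.iloc[0]["reason"] == "score 3 attribute"

    def test_paired_two_rule_limited_to_roll_arch_pitch(self):
        dropped = pd.DataFrame([_image_row(q_roll=2, q_arch=2)])
        kept, _ = photogrammetry.quality_filter(dropped)
        assert len(kept) == 0
        ok = pd.DataFrame([_image_row(q_roll=2, q_focus=2)])
        kept, _ = photogrammetry.quality_filter(ok)
        assert len(kept) == 1

    @pytest.mark.parametrize("pair", list(itertools.combinations(
        ("q_roll", "q_arch", "q_pitch"), 2)))
    def test_all_three_pairings_drop(self, pair):
        df = pd.DataFrame([_image_row(**{pair[0]: 2, pair[1]: 2})])
        kept, _ = photogrammetry.quality_filter(df)
        assert len(kept) == 0

    def test_cap_at_five_best_scores(self):
        rows = [_image_row() for _ in range(4)]
        rows += [_image_row(q_focus=2, q_straightness=2) for _ in range(3)]
        df = pd.DataFrame(rows)
        df["image_id"] = [f"img{i}" for i in range(7)]
        kept, log = photogrammetry.quality_filter(df)
        assert len(kept) == 5
        # the four pristine images survive; only one of the score-2 images
        assert (kept[photogrammetry.QUALITY_COLUMNS[0]] == 1).sum() == 4
        assert len(log) == 2

    def test_order_independent(self):
        rng = np.random.default_rng(3)
        rows = []
        for i in range(30):
            scores = {a: int(rng.integers(1, 4))
                      for a in photogrammetry.QUALITY_COLUMNS}
            rows.append(_image_row(ind=f"w{i % 5}", **scores))
        df = pd.DataFrame(rows)
        df["image_id"] = [f"img{i}" for i in range(30)]
        kept_a, _ = photogrammetry.quality_filter(df)
        kept_b, _ = photogrammetry.quality_filter(
            df.sample(frac=1, random_state=1))
        assert sorted(kept_a["image_id"]) == sorted(kept_b["image_id"])

    def test_invalid_scores_rejected(self):
        df = pd.DataFrame([_image_row(q_focus=4)])
        with pytest.raises(ValueError):
            photogrammetry.quality_filter(df)


class TestNaiveLength:
    def test_known_projection_inverts(self):
        px = 8.00 * 35 * 6000 / (23.5 * 40)
        m = photogrammetry.naive_length(px, 40.0, 23.5, 35.0, 6000.0)
        assert m == pytest.approx(8.00)

    def test_linear_in_pixels_and_altitude(self):
        base = photogrammetry.naive_length(1000.0, 40.0, 23.5, 35.0, 6000.0)
        assert photogrammetry.naive_length(2000.0, 40.0, 23.5, 35.0, 6000.0) \
            == pytest.approx(2 * base)
        assert photogrammetry.naive_length(1000.0, 80.0, 23.5, 35.0, 6000.0) \
            == pytest.approx(2 * base)

    def test_zero_pixels_zero_length(self):
        assert photogrammetry.naive_length(0.0, 40.0, 23.5, 35.0, 6000.0) == 0.0

    def test_bad_camera(self):
        with pytest.raises(ValueError):
            photogrammetry.naive_length(100.0, 40.0, 23.5, 0.0, 6000.0)


def brute_force_hpd(samples, mass):
    s = np.sort(samples)
    n = len(s)
    k = min(max(int(np.ceil(mass * n)), 2), n)
    best = min(((s[i + k - 1] - s[i], i) for i in range(n - k + 1)))
    return float(s[best[1]]), float(s[best[1] + k - 1])


class TestHPD:
    def test_uniform_grid(self):
        lo, hi = photogrammetry.hpd_interval(np.arange(1, 101), 0.95)
        assert hi - lo == 94

    def test_near_total_mass_returns_range(self):
        x = np.array([3.0, 1.0, 9.0, 4.0])
        assert photogrammetry.hpd_interval(x, 0.999) == (1.0, 9.0)

    def test_symmetric_samples_match_equal_tails(self):
        rng = np.random.default_rng(5)
        x = rng.normal(0, 1, 40_000)
        lo, hi = photogrammetry.hpd_interval(x, 0.95)
        qlo, qhi = np.quantile(x, [0.025, 0.975])
        assert lo == pytest.approx(qlo, abs=0.06)
        assert hi == pytest.approx(qhi, abs=0.06)

    @given(st.lists(st.floats(-1e6, 1e6), min_size=2, max_size=120),
           st.floats(0.05, 0.99))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_matches_exhaustive_window_search(self, xs, mass):
        assert photogrammetry.hpd_interval(xs, mass) == brute_force_hpd(xs, mass)

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            photogrammetry.hpd_interval([1.0], 0.95)


def _training(noise, n=60, seed=0, alt=(15.0, 83.0)):
    pop = []  # training only
    _, tr = synth.gen_uas_survey(
        synth.gen_population(synth.CohortConfig(n_individuals=1, seed=seed)),
        altitude_range=alt, noise=noise, n_training=n, seed=seed)
    return tr


class TestErrorModel:
    def test_noise_free_posterior_collapses(self):
        tr = _training(synth.UASNoise(), seed=21)
        model = photogrammetry.fit_error_model(tr, draws=1500, seed=22)
        assert model.bias.mean() == pytest.approx(1.0, abs=0.005)
        assert model.residual_cv.mean() < 0.01

    def test_parameter_recovery_within_posterior(self):
        truth = synth.UASNoise(altitude_bias=1.03, altitude_sd=1.0, pixel_cv=0.02)
        tr = _training(truth, n=110, seed=23)
        model = photogrammetry.fit_error_model(tr, draws=2000, seed=24)
        for draws, value in ((model.bias, 1.03), (model.altitude_sd, 1.0),
                             (model.residual_cv, 0.02)):
            lo, hi = np.percentile(draws, [2.5, 97.5])
            assert lo <= value <= hi

    def test_single_altitude_warns(self):
        tr = _training(synth.UASNoise(1.02, 1.0, 0.02), n=30, seed=25,
                       alt=(40.0, 40.5))
        with pytest.warns(UserWarning, match="weakly identified"):
            photogrammetry.fit_error_model(tr, draws=1000, seed=26)

    def test_too_few_training_images(self):
        tr = _training(synth.UASNoise(), n=5, seed=27)
        with pytest.raises(ValueError):
            photogrammetry.fit_error_model(tr)


class TestLengthEstimation:
    @staticmethod
    def _exact_image(length=8.0, alt=40.0, ind="w1"):
        px = synth.project_to_pixels(length, alt, synth.AircraftConfig())
        return pd.DataFrame([{
            "individual_id": ind, "pixel_length": px, "observed_altitude": alt,
            "focal_length_mm": 35.0, "sensor_width_mm": 23.5,
            "image_width_px": 6000.0}])

    def test_noise_free_collapses_to_truth(self):
        tr = _training(synth.UASNoise(), seed=31)
        model = photogrammetry.fit_error_model(tr, draws=1500, seed=32)
        post = photogrammetry.estimate_length(self._exact_image(), model,
                                              seed=33)
        assert post.mean == pytest.approx(8.00, abs=0.02)
        assert post.hpd95[1] - post.hpd95[0] < 0.1
        assert post.samples.size >= 2000

    def test_hpd_nesting_and_mean_containment(self):
        truth = synth.UASNoise(1.02, 1.0, 0.02)
        pop = synth.gen_population(synth.CohortConfig(n_individuals=8, seed=34))
        imgs, tr = synth.gen_uas_survey(pop, noise=truth, seed=35)
        model = photogrammetry.fit_error_model(tr, draws=1500, seed=36)
        posts = photogrammetry.estimate_lengths(imgs, model, seed=37)
        for p in posts:
            assert p.hpd95[0] <= p.hpd65[0] <= p.hpd65[1] <= p.hpd95[1]
            assert p.hpd95[0] <= p.mean <= p.hpd95[1]

    def test_more_images_narrower_posterior(self):
        truth = synth.UASNoise(1.02, 1.5, 0.03)
        tr = _training(truth, n=110, seed=38)
        model = photogrammetry.fit_error_model(tr, draws=1500, seed=39)
        widths = {1: [], 5: []}
        ac = synth.AircraftConfig()
        for rep in range(12):
            rng = np.random.default_rng(500 + rep)
            for n_img in (1, 5):
                alt_true = rng.uniform(20, 70, n_img)
                px = synth.project_to_pixels(8.0, alt_true, ac) \
                    * (1 + rng.normal(0, truth.pixel_cv, n_img))
                alt_obs = alt_true * truth.altitude_bias \
                    + rng.normal(0, truth.altitude_sd, n_img)
                df = pd.DataFrame({
                    "individual_id": "w", "pixel_length": px,
                    "observed_altitude": alt_obs, "focal_length_mm": 35.0,
                    "sensor_width_mm": 23.5, "image_width_px": 6000.0})
                p = photogrammetry.estimate_length(df, model, seed=600 + rep)
                widths[n_img].append(p.hpd95[1] - p.hpd95[0])
        assert np.mean(widths[5]) < np.mean(widths[1])

    def test_no_images_raises(self):
        tr = _training(synth.UASNoise(), seed=40)
        model = photogrammetry.fit_error_model(tr, draws=1000, seed=41)
        with pytest.raises(ValueError):
            photogrammetry.estimate_length(self._exact_image().iloc[:0], model)


class TestSummary:
    def test_single_individual(self):
        post = photogrammetry.LengthPosterior(
            individual_id="w1", samples=np.array([8.0, 8.1]), mean=8.05,
            hpd95=(8.0, 8.1), hpd65=(8.0, 8.1), n_images=1)
        s = photogrammetry.length_summary([post])
        assert s["length_m"]["mean"] == pytest.approx(8.05)
        assert s["length_m"]["sd"] == 0.0

    def test_cohort_mean_recovers_generator(self):
        truth = synth.UASNoise(1.0, 0.5, 0.01)
        cfg = synth.CohortConfig(n_individuals=68, seed=42)
        pop = synth.gen_population(cfg)
        imgs, tr = synth.gen_uas_survey(pop, noise=truth, seed=43)
        model = photogrammetry.fit_error_model(tr, draws=1500, seed=44)
        posts = photogrammetry.estimate_lengths(imgs, model, seed=45)
        s = photogrammetry.length_summary(posts)
        true_mean = np.mean([p.total_length for p in pop])
        # within 2 standard errors of the realized cohort mean
        assert s["length_m"]["mean"] == pytest.approx(
            true_mean, abs=2 * 1.06 / np.sqrt(68))
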