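"""Assay QC arithmetic, reference construction, classification and rate tests."""

import numpy as np
import pandas as pd
import pytest

from minkedemog import pregnancy, synth
from minkedemog._logistic import fit_logistic, predict_logistic


class TestEfficiencyAdjustment:
    def test_identity_and_division(self):
        assert pregnancy.adjust_for_efficiency(1.0, 1.0) == 1.0
        assert pregnancy.adjust_for_efficiency(0.80, 0.80) == pytest.approx(1.00)

    def test_low_efficiency_flagged_invalid(self):
        assert not pregnancy.efficiency_acceptable(0.55)
        assert pregnancy.efficiency_acceptable(0.60)

    @pytest.mark.parametrize("eff", [0.0, -0.1, 1.6])
    def test_bad_efficiency_raises(self, eff):
        with pytest.raises(ValueError):
            pregnancy.adjust_for_efficiency(1.0, eff)


class TestAssayCV:
    @staticmethod
    def _frame(rows):
        return pd.DataFrame(rows, columns=["plate_id", "replicate_group",
                                           "concentration"])

    def test_identical_replicates_zero_cv(self):
        df = self._frame([("p1", "a", 5.0), ("p1", "a", 5.0)])
        assert pregnancy.assay_cv(df).intra_cv == 0.0

    def test_hand_computed_cv(self):
        df = self._frame([("p1", "a", 9.0), ("p1", "a", 11.0)])
        cv = pregnancy.assay_cv(df)
        assert cv.intra_cv == pytest.approx(100 * np.sqrt(2) / 10, rel=1e-9)

    def test_inter_plate_cv(self):
        df = self._frame([("p1", "a", 9.0), ("p1", "a", 9.0),
                          ("p2", "a", 11.0), ("p2", "a", 11.0)])
        cv = pregnancy.assay_cv(df)
        assert cv.inter_cv == pytest.approx(100 * np.sqrt(2) / 10, rel=1e-9)

    def test_singleton_group_raises(self):
        with pytest.raises(ValueError):
            pregnancy.assay_cv(self._frame([("p1", "a", 5.0)]))


class TestParallelism:
    @staticmethod
    def _series(slope, intercept, dilutions=(1, 1 / 2, 1 / 4, 1 / 8, 1 / 16, 1 / 32)):
        return [(d, intercept + slope * np.log2(d)) for d in dilutions]

    def test_exact_copy_is_parallel(self):
        std = self._series(0.9, 1.5)
        res = pregnancy.parallelism_check(std, std)
        assert res.slope_ratio == pytest.approx(1.0)
        assert res.r_squared == pytest.approx(1.0)
        assert res.parallel

    def test_slope_ratio_recovered(self):
        res = pregnancy.parallelism_check(self._series(0.997 * 0.9, 1.2),
                                          self._series(0.9, 1.5))
        assert res.slope_ratio == pytest.approx(0.997, rel=1e-6)
        assert res.parallel

    def test_flat_sample_rejected(self):
        res = pregnancy.parallelism_check(self._series(0.0, 1.0),
                                          self._series(0.9, 1.5))
        assert res.slope_ratio == pytest.approx(0.0, abs=1e-9)
        assert not res.parallel

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            pregnancy.parallelism_check(self._series(0.9, 1.0)[:2],
                                        self._series(0.9, 1.0))


class TestReference:
    def test_self_bounded_labels_by_gap(self):
        conc = [0.36, 1.2, 30.0, 307.01, 10.20, 5.92]
        ref = pregnancy.build_reference(conc, "self_bounded")
        assert ref.provenance == "self_bounded"
        # 0.36, 1.2 not pregnant; 30, 307.01 pregnant; 10.20 and 5.92 in gap
        assert len(ref.labels) == 4 and ref.labels.sum() == 2
        assert sorted(10 ** ref.unlabeled_log10) == pytest.approx([5.92, 10.20])

    def test_self_bounded_needs_both_classes(self):
        with pytest.raises(ValueError):
            pregnancy.build_reference([0.3, 0.5, 1.0], "self_bounded")

    def test_external_mode_passthrough(self):
        ext = pd.DataFrame({"conc": [1.0, 2.0, 100.0, 200.0],
                            "label": [0, 0, 1, 1]})
        ref = pregnancy.build_reference(None, "external_reference", external=ext)
        assert ref.labels.tolist() == [0, 0, 1, 1]
        assert np.allclose(10 ** ref.log10_conc, ext["conc"])

    def test_unknown_mode(self):
        with pytest.raises(ValueError):
            pregnancy.build_reference([1.0], "magic")


class TestModelFit:
    def test_single_class_rejected(self):
        ref = pregnancy.ReferenceSet(log10_conc=np.array([0.1, 0.2]),
                                     labels=np.array([1, 1]), provenance="x")
        with pytest.raises(ValueError):
            pregnancy.fit_pregnancy_model(ref, B=10)

    def test_replicate_count_and_determinism(self, calibrated_model):
        assert calibrated_model.B == 500
        again = pregnancy.fit_pregnancy_model(calibrated_model.reference,
                                              B=500, seed=303)
        assert np.array_equal(again.boot_coefs, calibrated_model.boot_coefs)

    def test_b_one(self, calibrated_model):
        m = pregnancy.fit_pregnancy_model(calibrated_model.reference, B=1, seed=1)
        assert m.boot_coefs.shape == (1, 2)

    def test_point_and_envelope_monotone_in_concentration(self, calibrated_model):
        grid = np.logspace(-1, 2.6, 60)
        p = calibrated_model.predict_point(grid)
        lo, hi = calibrated_model.envelope(grid)
        for arr in (p, lo, hi):
            assert np.all(np.diff(arr) >= -1e-12)

    def test_separated_classes_sharp_transition(self):
        ref = pregnancy.ReferenceSet(
            log10_conc=np.array([0.0, 0.1, 0.2, 2.0, 2.1, 2.2]),
            labels=np.array([0, 0, 0, 1, 1, 1]), provenance="x")
        m = pregnancy.fit_pregnancy_model(ref, B=50, seed=2)
        assert m.predict_point([0.5])[0] < 1e-3
        assert m.predict_point([500.0])[0] > 1 - 1e-3


class TestClassification:
    def test_reference_class_concentrations(self, calibrated_model):
        assert pregnancy.classify(calibrated_model, 0.36).call == "not_pregnant"
        assert pregnancy.classify(calibrated_model, 307.01).call == "pregnant"

    def test_gap_concentration_undetermined(self, calibrated_model):
        call = pregnancy.classify(calibrated_model, 10.20)
        assert call.call == "undetermined"
        assert call.ci_high - call.ci_low > 0.1

    def test_recovery_outside_gap(self, default_population, calibrated_model):
        lo, hi = calibrated_model.reference.bounds
        females = [p for p in default_population if p.sex == "F"]
        outside = [p for p in females
                   if not lo < p.progesterone < hi]
        calls = [pregnancy.classify(calibrated_model, p.progesterone)
                 for p in outside]
        truth = ["pregnant" if p.progesterone >= hi else "not_pregnant"
                 for p in outside]
        correct = np.mean([c.call == t for c, t in zip(calls, truth)])
        assert correct >= 0.95
        # never a confident call in the wrong direction
        assert not any((c.call == "pregnant") != (t == "pregnant")
                       for c, t in zip(calls, truth) if c.call != "undetermined")

    def test_in_gap_only_undetermined(self, default_population, calibrated_model):
        lo, hi = calibrated_model.reference.bounds
        females = [p for p in default_population if p.sex == "F"]
        in_gap = [p for p in females if lo < p.progesterone < hi]
        for p in in_gap:
            assert pregnancy.classify(calibrated_model, p.progesterone).call \
                == "undetermined"

    def test_nonpositive_concentration(self, calibrated_model):
        with pytest.raises(ValueError):
            pregnancy.classify(calibrated_model, 0.0)


class TestRate:
    def test_hand_example_two_samples(self):
        rate = pregnancy.rate_from_probabilities([[0.2, 0.4], [0.8, 0.6]])
        assert rate.per_replicate_rates.tolist() == pytest.approx([0.3, 0.7])
        assert rate.mean_rate == pytest.approx(0.5)

    def test_all_high_concentrations(self, calibrated_model):
        rate = pregnancy.pregnancy_rate(calibrated_model, [250.0, 300.0, 280.0])
        assert rate.mean_rate > 0.99

    def test_rate_within_call_bounds(self, default_population, calibrated_model):
        conc = np.array([p.progesterone for p in default_population
                         if p.sex == "F"])
        calls = [pregnancy.classify(calibrated_model, c).call for c in conc]
        rate = pregnancy.pregnancy_rate(calibrated_model, conc)
        frac_p = np.mean([c == "pregnant" for c in calls])
        frac_np = np.mean([c == "not_pregnant" for c in calls])
        assert frac_p <= rate.mean_rate <= 1 - frac_np

    def test_empty_input(self, calibrated_model):
        with pytest.raises(ValueError):
            pregnancy.pregnancy_rate(calibrated_model, [])


class TestParameterRecovery:
    def test_bootstrap_intervals_cover_generator(self):
        """Refit on data simulated from a known logistic: the bootstrap 95%
        intervals should cover the generating slope and intercept in >= 90%
        of seeded trials."""
        true = np.array([-4.0, 3.5])
        cover = np.zeros(2)
        n_trials = 100
        n = 150
        for trial in range(n_trials):
            rng = np.random.default_rng(1000 + trial)
            x = rng.normal(1.1, 0.8, n)
            y = (rng.random(n) < predict_logistic(true, x)).astype(float)
            if y.min() == y.max():
                cover += 1  # degenerate draw carries no evidence against truth
                continue
            ref = pregnancy.ReferenceSet(log10_conc=x, labels=y.astype(int),
                                         provenance="external_reference")
            m = pregnancy.fit_pregnancy_model(ref, B=200, seed=trial)
            lo = np.percentile(m.boot_coefs, 2.5, axis=0)
            hi = np.percentile(m.boot_coefs, 97.5, axis=0)
            cover += (lo <= true) & (true <= hi)
        assert np.all(cover >= 0.90 * n_trials)


class TestReplicateConsistency:
    def test_agreement_and_disagreement(self):
        calls = pd.DataFrame({
            "individual_id": ["a", "a", "b", "b", "c"],
            "call": ["not_pregnant", "not_pregnant", "pregnant",
                     "not_pregnant", "pregnant"],
        })
        rep = pregnancy.replicate_consistency(calls).set_index("individual_id")
        assert bool(rep.loc["a", "consistent"])
        assert not bool(rep.loc["b", "consistent"])
        assert bool(rep.loc["c", "consistent"])  # single sample: vacuous
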