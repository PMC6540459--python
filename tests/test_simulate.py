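"""Synthetic-study generator: calibration, determinism, self-consistency."""

import math

import numpy as np
import pytest

import h2axdose as hx
import h2axdose.biokinetics as bk
from h2axdose.cells import filter_high_fluorescence, group_summary
from h2axdose.model import H2AXKineticsModel
from h2axdose.presets import BLOOD_BACKGROUND_AU, BLOOD_BESTFIT


class TestGroupMeans:
    def test_zero_noise_equals_predictions(self, design, noiseless_data):
        for m in noiseless_data:
            assert m.mean_fluorescence == pytest.approx(
                hx.predict_fluorescence(BLOOD_BESTFIT, activity=m.activity, time=m.time),
                rel=1e-12,
            )

    def test_design_grid_and_counts(self, design, noisy_data):
        assert len(noisy_data) == len(design.activities) * len(design.necropsy_days)
        assert all(m.n_animals == design.animals_per_point for m in noisy_data)
        assert all(m.sem > 0 for m in noisy_data)

    def test_seed_determinism(self, design, bestfit):
        noise = hx.NoiseConfig()
        a = hx.generate_group_means(design, bestfit, noise, seed=3)
        b = hx.generate_group_means(design, bestfit, noise, seed=3)
        c = hx.generate_group_means(design, bestfit, noise, seed=4)
        assert all(x.mean_fluorescence == y.mean_fluorescence for x, y in zip(a, b))
        assert any(x.mean_fluorescence != y.mean_fluorescence for x, y in zip(a, c))

    def test_replicate_spread_matches_sem_target(self, design, bestfit):
        # Monte-Carlo calibration: SD of the group mean across replicates
        # approximates the configured SEM scale
        noise = hx.NoiseConfig()
        rng = np.random.default_rng(1234)
        means = [
            hx.generate_group_means(design, bestfit, noise, seed=rng)[0].mean_fluorescence
            for _ in range(500)
        ]
        assert np.std(means) == pytest.approx(noise.group_sem_scale, rel=0.10)


class TestRetentionCurves:
    def test_zero_cv_reproduces_group_curve(self, design):
        curves = hx.generate_retention_curves(design, cv=0.0, seed=0)
        params = bk.RetentionParams()
        for _, series in curves[:5]:
            assert series.fractions == pytest.approx(
                bk.retention_fraction(params, series.times), rel=1e-12
            )

    def test_group_mean_day5_near_half(self, design):
        curves = hx.generate_retention_curves(design, cv=0.15, seed=8)
        day5 = [s.fractions[s.times == 5.0][0] for _, s in curves]
        assert np.mean(day5) == pytest.approx(0.514, abs=0.05)

    def test_fit_recovers_each_animal_at_zero_cv(self, design):
        curves = hx.generate_retention_curves(design, cv=0.0, seed=0)
        res = bk.fit_retention(curves[0][1], n_terms=2)
        assert res.params.halftime_slow == pytest.approx(7.8, rel=1e-4)
        assert res.params.fraction_fast == pytest.approx(0.2, rel=1e-3)


class TestCellGenerator:
    def test_zero_tail_weight_survives_filter(self):
        noise = hx.NoiseConfig(apoptotic_weight=0.0)
        s = hx.generate_cells(900.0, 400, noise, seed=0)
        _, n_removed = filter_high_fluorescence(s)
        assert n_removed == 0

    def test_post_filter_mean_calibrated_at_large_n(self):
        s = hx.generate_cells(1006.0, 100_000, hx.NoiseConfig(), seed=1)
        kept, _ = filter_high_fluorescence(s)
        assert kept.cell_fluorescence.mean() == pytest.approx(1006.0, rel=0.02)

    def test_control_preset_group_mean_within_band(self):
        # eight control animals, aggregated as in the study; the group mean
        # sits within a 3-SEM band of the 1006 +- 36 control level
        noise = hx.NoiseConfig()
        rng = np.random.default_rng(5)
        animals = [
            hx.generate_cells(
                1006.0 + math.sqrt(8) * 36.0 * rng.standard_normal(),
                400, noise, seed=rng,
            )
            for _ in range(8)
        ]
        summary = group_summary(animals)
        assert abs(summary.mean_fluorescence - 1006.0) < 3 * 36.0

    def test_unattainable_target_rejected(self):
        with pytest.raises(ValueError):
            hx.generate_cells(3500.0, 100, hx.NoiseConfig(), seed=0)


class TestFullStudy:
    def test_zero_noise_bundle_fit_roundtrip(self, design):
        noise = hx.NoiseConfig(group_sem_scale=0.0)
        bundle = hx.generate_full_study(
            design, BLOOD_BESTFIT, noise=noise, seed=0, with_cells=False,
            include_control=False,
        )
        res = H2AXKineticsModel(bundle.group_means, BLOOD_BACKGROUND_AU).fit(
            n_starts=10, seed=0
        )
        for name in ("k", "alpha", "r", "p"):
            assert abs(
                getattr(res.params, name) - getattr(BLOOD_BESTFIT, name)
            ) / getattr(BLOOD_BESTFIT, name) < 0.01

    def test_cell_layer_aggregates_to_group_table(self, design):
        small = hx.StudyDesign(
            activities=(5.74, 9.28), necropsy_days=(2, 5), animals_per_point=4,
            cells_per_sample=(300, 400),
        )
        bundle = hx.generate_full_study(small, seed=2, include_control=False)
        for m in bundle.group_means:
            animals = [
                s for s in bundle.cell_samples
                if s.activity == m.activity and s.day == m.time
            ]
            assert len(animals) == small.animals_per_point
            summary = group_summary(animals)
            # cell-level Monte-Carlo error: a few percent of the group mean
            assert summary.mean_fluorescence == pytest.approx(
                m.mean_fluorescence, rel=0.05
            )

    def test_bundle_csvs_byte_identical_under_seed(self, tmp_path, design):
        small = hx.StudyDesign(
            activities=(5.74,), necropsy_days=(2, 5), animals_per_point=2,
            cells_per_sample=(60, 80),
        )
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            b1 = hx.generate_full_study(small, seed=9)
            b2 = hx.generate_full_study(small, seed=9)
        p1 = b1.to_csvs(tmp_path / "a")
        p2 = b2.to_csvs(tmp_path / "b")
        for name in ("group_means", "retention", "cells", "manifest"):
            assert p1[name].read_bytes() == p2[name].read_bytes()

    def test_design_spans_dose_and_dose_rate_contrasts(self, design):
        # the activity/day grid contains both "similar dose, different dose
        # rate" and "similar dose rate, different dose" group pairs
        params = bk.RetentionParams()
        model = bk.DoseModel.calibrated(params, 9.28e6, 14.0, 12.31)
        conditions = []
        for a in design.activities:
            doses = [0.0] + [
                bk.committed_dose(a * 1e6, bk.dose_coefficient(params, model, d))
                for d in range(1, 15)
            ]
            rates = np.diff(doses)
            for d in design.necropsy_days:
                conditions.append((a, d, doses[int(d)], rates[int(d) - 1]))
        similar_dose_diff_rate = similar_rate_diff_dose = False
        for i, (a1, d1, dose1, rate1) in enumerate(conditions):
            for a2, d2, dose2, rate2 in conditions[i + 1:]:
                if a1 == a2:
                    continue
                if abs(dose1 - dose2) / max(dose1, dose2) < 0.15:
                    if max(rate1, rate2) / min(rate1, rate2) > 1.3:
                        similar_dose_diff_rate = True
                if abs(rate1 - rate2) / max(rate1, rate2) < 0.15:
                    if max(dose1, dose2) / min(dose1, dose2) > 1.3:
                        similar_rate_diff_dose = True
        assert similar_dose_diff_rate and similar_rate_diff_dose
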