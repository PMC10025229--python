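"""Synthetic cohort generator: determinism, effect directions, phantoms."""

import dataclasses

import numpy as np
import pytest

from glymphflow.dce import AIF, ToftsParams, tofts_forward
from glymphflow.features import extract_features
from glymphflow.stats import Subject
from glymphflow.synthetic import (
    SimulationConfig,
    generate_cohort,
    generate_slice_masks,
    null_config,
    simulate_ctc,
)


def _small_config(**overrides):
    cfg = SimulationConfig()
    base = dict(
        n_subjects={"NC": 4, "OSA_pre": 3, "OSA_post": 2},
        curves_per_subject_mean={"NC": 3.0, "OSA_pre": 3.0, "OSA_post": 3.0},
        image_size=64,
    )
    base.update(overrides)
    return dataclasses.replace(cfg, **base)


class TestSimulateCtc:
    def test_no_exchange_no_plasma_gives_pure_noise(self, bolus_aif):
        ctc = simulate_ctc(ToftsParams(0.0, 0.0, 0.0), bolus_aif,
                           noise_sd=0.01, seed=0)
        assert abs(ctc.C.mean()) < 0.01
        rng = np.random.default_rng(0)
        np.testing.assert_array_equal(
            ctc.C, rng.normal(0, 0.01, ctc.C.shape))

    def test_noiseless_equals_forward_model(self, bolus_aif):
        p = ToftsParams(0.1, 0.4, 0.01)
        ctc = simulate_ctc(p, bolus_aif, noise_sd=0.0, seed=5)
        np.testing.assert_array_equal(ctc.C, tofts_forward(p, bolus_aif))

    def test_same_seed_bit_identical(self, bolus_aif):
        p = ToftsParams(0.1, 0.4, 0.01)
        a = simulate_ctc(p, bolus_aif, noise_sd=0.003, seed=42)
        b = simulate_ctc(p, bolus_aif, noise_sd=0.003, seed=42)
        np.testing.assert_array_equal(a.C, b.C)

    def test_negative_noise_rejected(self, bolus_aif):
        with pytest.raises(ValueError):
            simulate_ctc(ToftsParams(0.1, 0.4, 0.0), bolus_aif, noise_sd=-1.0)

    def test_rectangular_aif_closed_form(self):
        """Noiseless curve under a rectangular AIF matches the analytic
        convolution (Ktrans c0 / kep)(1 - exp(-kep t))."""
        t = np.arange(0.0, 300.1, 2.0)
        aif = AIF(t=t, Cp=np.full_like(t, 2.0))
        ktrans, kep = 0.15, 0.6
        ctc = simulate_ctc(ToftsParams(ktrans, kep, 0.0), aif, 0.0, seed=0)
        expected = ktrans * 2.0 / kep * (1.0 - np.exp(-kep * t / 60.0))
        mask = expected > 1e-12
        assert np.max(np.abs(ctc.C[mask] - expected[mask]) / expected[mask]) < 1e-6


class TestGenerateCohort:
    def test_group_sizes_match_config(self):
        cfg = _small_config(n_subjects={"NC": 25, "OSA_pre": 11, "OSA_post": 13},
                            include_slices=False)
        cohort = generate_cohort(cfg, seed=0)
        groups = cohort.subjects_frame()["group"].value_counts().to_dict()
        assert groups == {"NC": 25, "OSA_pre": 11, "OSA_post": 13}

    def test_bit_identical_for_same_seed(self):
        cfg = _small_config()
        a = generate_cohort(cfg, seed=9)
        b = generate_cohort(cfg, seed=9)
        assert a.subjects_frame().equals(b.subjects_frame())
        assert a.ctc_frame().equals(b.ctc_frame())
        assert a.truth == b.truth
        for sid in a.slices:
            for lvl in a.slices[sid]:
                np.testing.assert_array_equal(
                    a.slices[sid][lvl].image.pixels,
                    b.slices[sid][lvl].image.pixels)
                assert (a.slices[sid][lvl].true_areas_mm2
                        == b.slices[sid][lvl].true_areas_mm2)

    def test_every_curve_references_a_subject_and_truth_covers_all(self):
        cohort = generate_cohort(_small_config(), seed=1)
        sids = set(s.subject_id for s in cohort.subjects)
        for c in cohort.ctcs:
            assert c.subject_id in sids
            assert c.roi_id in cohort.truth
        assert len(cohort.truth) == len(cohort.ctcs)

    def test_covariates_monotone_in_latent_severity(self):
        cfg = _small_config(n_subjects={"NC": 1, "OSA_pre": 60, "OSA_post": 1},
                            include_slices=False)
        cohort = generate_cohort(cfg, seed=2)
        df = cohort.subjects_frame()
        osa = df[df.group == "OSA_pre"]
        sev = np.array([cohort.severity[s] for s in osa.subject_id])
        for col, sign in [("AHI", 1), ("ODI", 1), ("LSaO2", -1),
                          ("MMSE", -1), ("MoCA", -1), ("PSQI", 1), ("ESS", 1)]:
            r = np.corrcoef(sev, osa[col])[0, 1]
            assert sign * r > 0.5, f"{col}: r={r}"

    def test_peak_multiplier_monotone_in_cohort_mean_type1_peak(self):
        """Raising the type-I peak multiplier strictly raises the cohort-mean
        type-I peak feature (same seed, same draws)."""
        means = []
        for mult in (1.0, 1.5):
            cfg = _small_config(include_slices=False)
            cfg.group_effects = dataclasses.replace(
                cfg.group_effects, typeI_peak_mult=mult)
            cohort = generate_cohort(cfg, seed=3)
            peaks = [
                extract_features(c).peak_concentration
                for c in cohort.ctcs
                if cohort.truth[c.roi_id]["type"] == "I"
            ]
            means.append(np.mean(peaks))
        assert means[1] > means[0]

    def test_invalid_config_rejected(self):
        cfg = _small_config()
        cfg.noise_sd = -1.0
        with pytest.raises(ValueError):
            generate_cohort(cfg, seed=0)
        cfg = _small_config(n_subjects={"NC": 0, "OSA_pre": 1, "OSA_post": 1})
        with pytest.raises(ValueError):
            generate_cohort(cfg, seed=0)

    def test_osa_type1_fraction_exceeds_nc_in_most_replicates(self):
        """With default effects the OSA_pre type-I (ground-truth) fraction
        exceeds the NC fraction in at least 95% of 200 replicate cohorts."""
        cfg = dataclasses.replace(SimulationConfig(), include_slices=False)
        wins = 0
        n_rep = 200
        for seed in range(n_rep):
            cohort = generate_cohort(cfg, seed=seed)
            frac = {"NC": [], "OSA_pre": []}
            for roi_id, info in cohort.truth.items():
                g = info["subject_id"].rsplit("_", 1)[0]
                if g in frac:
                    frac[g].append(info["type"] == "I")
            wins += np.mean(frac["OSA_pre"]) > np.mean(frac["NC"])
        assert wins >= 0.95 * n_rep

    def test_null_config_equalises_groups(self):
        cfg = null_config()
        assert cfg.group_effects.typeI_peak_mult == 1.0
        assert cfg.group_effects.typeI_washout_mult == 1.0
        assert len(set(cfg.type1_fraction.values())) == 1
        assert len(set(cfg.severity_mean.values())) == 1


class TestSliceMasks:
    def _subject(self, ahi=28.9):
        return Subject("s1", "OSA_pre", AHI=ahi, LSaO2=80.0)

    def test_zero_area_request_gives_empty_mask(self):
        cfg = _small_config()
        cfg.base_area_fraction = dict(cfg.base_area_fraction,
                                      frontal_PVS=0.0)
        levels = generate_slice_masks(cfg, self._subject(), seed=0, severity=0.0)
        ss = levels["frontal"]
        assert ss.true_areas_mm2["frontal_PVS"] == 0.0
        assert not ss.masks["frontal_PVS"].pixels.any()

    def test_true_area_equals_pixel_count_times_pixel_area(self):
        cfg = _small_config(pixel_spacing=(0.5, 0.5))
        levels = generate_slice_masks(cfg, self._subject(), seed=1, severity=0.0)
        for ss in levels.values():
            for label, mask in ss.masks.items():
                expected = float(mask.pixels.sum()) * 0.25
                assert ss.true_areas_mm2[label] == pytest.approx(expected)

    def test_ellipse_rasterisation_matches_analytic_area(self):
        """The lateral-ventricle ellipses at 0.5 mm pixels match their
        analytic area to within 2%."""
        cfg = dataclasses.replace(SimulationConfig(), image_size=384,
                                  pixel_spacing=(0.5, 0.5),
                                  morphometry_noise_cv=0.0, image_noise_sd=0.0)
        levels = generate_slice_masks(cfg, self._subject(), seed=2, severity=-2.0)
        # at severity == NC mean the multiplier is exactly 1
        scale = 384 / 192.0
        a_mm = 10 * scale * 0.5
        b_mm = 25 * scale * 0.5
        analytic = 2 * np.pi * a_mm * b_mm
        measured = levels["ventricle"].true_areas_mm2["lateral_ventricles"]
        assert abs(measured - analytic) / analytic < 0.02

    def test_higher_severity_strictly_enlarges_pvs(self):
        cfg = _small_config(morphometry_noise_cv=0.0)
        low = generate_slice_masks(cfg, self._subject(), seed=3, severity=0.0)
        high = generate_slice_masks(cfg, self._subject(), seed=3, severity=2.0)
        assert (high["frontal"].true_areas_mm2["frontal_PVS"]
                > low["frontal"].true_areas_mm2["frontal_PVS"])

    def test_structure_masks_nested_in_reference_regions(self):
        cfg = _small_config()
        levels = generate_slice_masks(cfg, self._subject(), seed=4, severity=1.0)
        pairs = [("frontal", "frontal_PVS", "brain_at_frontal_level"),
                 ("basal_ganglia", "basal_ganglia_PVS", "basal_ganglia_total"),
                 ("ventricle", "lateral_ventricles", "brain_at_ventricle_level"),
                 ("fourth", "fourth_ventricle", "cerebellum_at_fourth_level")]
        for level, inner, outer in pairs:
            ss = levels[level]
            assert not (ss.masks[inner].pixels & ~ss.masks[outer].pixels).any()

    def test_excessive_area_request_rejected(self):
        cfg = _small_config()
        cfg.base_area_fraction = dict(cfg.base_area_fraction, frontal_PVS=1.5)
        with pytest.raises(ValueError, match="exceeds"):
            generate_slice_masks(cfg, self._subject(), seed=5, severity=0.0)


class TestConfigRoundTrip:
    def test_yaml_round_trip(self, tmp_path):
        import yaml

        cfg = _small_config()
        path = tmp_path / "config.yaml"
        with open(path, "w") as fh:
            yaml.safe_dump(cfg.to_dict(), fh)
        loaded = SimulationConfig.from_yaml(path)
        assert loaded.to_dict() == cfg.to_dict()
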