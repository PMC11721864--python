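"""Synthetic cohort generator: design arithmetic, determinism, statistical
faithfulness of the direct metric-table simulator, and the geometry/statistics
consistency sweep."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from autosegeval import (CohortConfig, generate_cohort, generate_metric_table,
                         metrics_for_cohort, n_scan_units, read_cohort,
                         records_to_frame, write_cohort)
from autosegeval.mixed_model import fit_crossed_model

PARAMS = dict(beta0=0.86, beta1=-0.35, sigma2_patient=0.005,
              sigma2_observer=0.002, sigma2_residual=0.004,
              n_patients=20, n_observers=3)


class TestConfig:
    def test_validation_errors(self):
        with pytest.raises(ValueError):
            CohortConfig(n_patients=1).validate()
        with pytest.raises(ValueError):
            CohortConfig(sigma2_observer=-1).validate()
        with pytest.raises(ValueError):
            CohortConfig(organs=("prostate", "liver")).validate()
        with pytest.raises(ValueError):
            CohortConfig(outlier_patient=25).validate()
        cfg = CohortConfig()
        cfg.confidence_model["bladder"]["conventional"] = [0.5, 0.5, 0.5, 0, 0]
        with pytest.raises(ValueError):
            cfg.validate()

    def test_yaml_roundtrip(self, tmp_path):
        cfg = CohortConfig(n_patients=4, seed=9)
        cfg.to_yaml(tmp_path / "c.yaml")
        back = CohortConfig.from_yaml(tmp_path / "c.yaml")
        assert back == cfg

    def test_unknown_keys_rejected(self):
        with pytest.raises(ValueError, match="unknown config keys"):
            CohortConfig.from_dict({"n_patientz": 4})

    def test_grid_too_small_names_organ(self):
        with pytest.raises(ValueError, match="bladder"):
            generate_cohort(CohortConfig(grid_shape=(40, 40, 40), n_patients=2))


class TestGeneration:
    def test_record_counts_small_design(self):
        cfg = CohortConfig(n_patients=3, n_observers=2,
                           organs=("prostate", "rectum"), seed=1)
        recs = generate_cohort(cfg)
        assert len(recs) == 3 * 2 * 2 * 2
        assert n_scan_units(recs) == 6

    def test_zero_noise_cohort_is_exact(self):
        cfg = CohortConfig(n_patients=2, deformation_scale=0.0, sigma2_patient=0,
                           sigma2_observer=0, sigma2_residual=0, seed=1)
        mt = metrics_for_cohort(generate_cohort(cfg))
        assert (mt["dsc"] == 1.0).all()
        assert (mt["hd95_mm"] == 0.0).all()

    def test_same_seed_bit_identical(self):
        r1 = generate_cohort(CohortConfig(n_patients=2, organs=("prostate",), seed=7))
        r2 = generate_cohort(CohortConfig(n_patients=2, organs=("prostate",), seed=7))
        for a, b in zip(r1, r2):
            assert np.array_equal(a.ai_mask.voxels, b.ai_mask.voxels)
            assert np.array_equal(a.corrected_mask.voxels, b.corrected_mask.voxels)
        pd.testing.assert_frame_equal(records_to_frame(r1), records_to_frame(r2))

    def test_cohort_directory_roundtrip(self, tmp_path):
        cfg = CohortConfig(n_patients=2, organs=("prostate", "rectum"), seed=2)
        recs = generate_cohort(cfg)
        write_cohort(recs, tmp_path)
        back = read_cohort(tmp_path)
        assert len(back) == len(recs)
        for a, b in zip(recs, back):
            assert a.patient_id == b.patient_id and a.observer_id == b.observer_id
            assert np.array_equal(a.corrected_mask.voxels, b.corrected_mask.voxels)
            assert a.confidence == b.confidence

    def test_correction_times_and_confidence_ranges(self):
        recs = generate_cohort(CohortConfig(n_patients=3, organs=("prostate",), seed=4))
        meta = records_to_frame(recs)
        assert (meta["correction_time_s"] > 0).all()
        assert meta["confidence"].between(1, 5).all()


class TestMetricTableSimulator:
    def test_zero_variance_is_deterministic_linear_model(self):
        tab = generate_metric_table(dict(PARAMS, sigma2_patient=0,
                                         sigma2_observer=0, sigma2_residual=0),
                                    seed=0, response="y")
        hp = tab[tab.imaging_system == "high_performance"]["y"]
        conv = tab[tab.imaging_system == "conventional"]["y"]
        assert (hp == PARAMS["beta0"]).all()
        assert (conv == PARAMS["beta0"] + PARAMS["beta1"]).all()

    def test_arm_difference_recovers_beta1_at_large_n(self):
        p = dict(PARAMS, n_patients=2000)
        tab = generate_metric_table(p, seed=11, response="y")
        hp = tab[tab.imaging_system == "high_performance"]["y"]
        conv = tab[tab.imaging_system == "conventional"]["y"]
        diff = conv.mean() - hp.mean()
        # difference of arm means: residual-only noise, 2*sigma2_res/n
        mc_se = np.sqrt(2 * p["sigma2_residual"] / len(hp))
        assert abs(diff - p["beta1"]) < 3 * mc_se

    def test_variance_decomposition_recovers_components(self):
        # method-of-moments (expected mean squares) on 10,000 patients
        a, b = 10000, 3
        p = dict(PARAMS, n_patients=a)
        tab = generate_metric_table(p, seed=5, response="y")
        y = tab["y"].to_numpy().reshape(a, 2, b)
        gm = y.mean()
        ybp, ybo, ybk = y.mean((1, 2)), y.mean((0, 1)), y.mean((0, 2))
        ms_p = 2 * b * ((ybp - gm) ** 2).sum() / (a - 1)
        ms_o = 2 * a * ((ybo - gm) ** 2).sum() / (b - 1)
        ss_e = ((y - ybp[:, None, None] - ybo[None, None, :]
                 - ybk[None, :, None] + 2 * gm) ** 2).sum()
        ms_e = ss_e / (2 * a * b - a - b)
        assert (ms_p - ms_e) / (2 * b) == pytest.approx(p["sigma2_patient"], rel=0.05)
        assert ms_e == pytest.approx(p["sigma2_residual"], rel=0.05)
        # the observer mean square estimates sigma2_obs with only b-1 = 2 df,
        # so only an order-of-magnitude statement is meaningful at any n
        assert (ms_o - ms_e) / (2 * a) < 10 * p["sigma2_observer"]

    def test_missing_params_rejected(self):
        with pytest.raises(ValueError, match="missing params"):
            generate_metric_table({"beta0": 1}, seed=0)


def test_variance_ordering_matches_configuration():
    """Metrics computed from generated masks must rank configured patient,
    observer and residual components correctly across a parameter sweep."""
    levels = [(0.0005, 0.0002, 0.0005), (0.002, 0.001, 0.002), (0.008, 0.004, 0.008)]
    est = []
    for lv, (sp, so, se) in enumerate(levels):
        comps = np.zeros(3)
        for rep in range(3):
            cfg = CohortConfig(n_patients=5, n_observers=5, organs=("prostate",),
                               sigma2_patient=sp, sigma2_observer=so,
                               sigma2_residual=se, seed=500 + 10 * lv + rep)
            mt = metrics_for_cohort(generate_cohort(cfg))
            f = fit_crossed_model(mt, "dsc", organ="prostate")
            comps += np.array([f.sigma2_patient, f.sigma2_observer,
                               f.sigma2_residual]) / 3
        est.append(comps)
    est = np.array(est)
    for i, name in enumerate(["patient", "observer", "residual"]):
        rho = spearmanr([l[i] for l in levels], est[:, i]).statistic
        assert rho > 0.9, f"{name} component ordering not recovered (rho={rho})"
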