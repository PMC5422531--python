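"""The synthetic cohort generator: determinism, calibration, recovery."""

import json

import numpy as np
import pandas as pd
import pytest

import hemiasym as ha
from hemiasym.config import CohortConfig, SessionDesign
from hemiasym.errors import ConfigurationError
from hemiasym.simulate import (
    generate_cohort,
    generate_profiles,
    generate_roi_contrast_table,
    generate_session,
    generate_subject_volumes,
    grid_from_config,
    read_cohort,
    subject_amplitudes,
    write_cohort,
)
from hemiasym.volume import sphere_mask


class TestConfigValidation:
    @pytest.mark.parametrize(
        "field,value",
        [
            ("n_young", 1),
            ("rt_sd_old", 0.0),
            ("voxel_size", -1.0),
            ("accuracy_rate", 0.0),
            ("accuracy_rate", 1.5),
            ("noise_sd", -0.1),
        ],
    )
    def test_invalid_field_named_in_error(self, field, value):
        cfg = CohortConfig(**{field: value})
        with pytest.raises(ConfigurationError, match=field):
            cfg.validate()

    def test_design_requires_tr_consistency(self):
        with pytest.raises(ConfigurationError):
            SessionDesign(stimulus_duration=2.0, isi=0.6, tr=2.5).validate()

    def test_config_dict_round_trip(self):
        cfg = CohortConfig(seed=5, n_young=4)
        assert CohortConfig.from_dict(cfg.to_dict()) == cfg


class TestCohortStructure:
    def test_determinism_under_identical_seed(self, coarse_cfg):
        c1 = generate_cohort(coarse_cfg)
        c2 = generate_cohort(coarse_cfg)
        assert c1.participants.equals(c2.participants)
        assert c1.trials.equals(c2.trials)
        for sid in c1.task_volumes:
            assert np.array_equal(c1.task_volumes[sid].data, c2.task_volumes[sid].data)
            assert np.array_equal(c1.control_volumes[sid].data, c2.control_volumes[sid].data)

    def test_group_counts(self):
        cfg = CohortConfig(n_young=13, n_old=14)
        profiles = generate_profiles(cfg, ha.default_catalog())
        assert len(profiles) == 27
        assert sum(1 for p in profiles if p.true_group == "young") == 13

    def test_ages_within_group_ranges(self, coarse_cohort):
        for p in coarse_cohort.profiles:
            lo, hi = (
                coarse_cohort.config.age_range_young
                if p.true_group == "young"
                else coarse_cohort.config.age_range_old
            )
            assert lo <= p.age <= hi

    def test_rt_group_gap_matches_configuration(self):
        # old-minus-young expected gap 917.56 - 818.59 = 98.97 ms
        cfg = CohortConfig(n_young=500, n_old=500, seed=21)
        profiles = generate_profiles(cfg, ha.default_catalog())
        young = np.mean([p.mean_rt for p in profiles if p.true_group == "young"])
        old = np.mean([p.mean_rt for p in profiles if p.true_group == "old"])
        assert old - young == pytest.approx(98.97, abs=30.0)


class TestSubjectVolumes:
    def test_zero_amplitudes_give_zero_task_volume(self, catalog):
        cfg = CohortConfig(
            n_young=2, n_old=2, grid_shape=(31, 37, 31), voxel_size=6.0,
            noise_sd=0.0, jitter_sd=0.0, lapa_delta=0.0, harold_gain=0.0,
            base_amplitude={k: 0.0 for k in ha.config.AMPLITUDE_CELLS}, seed=1,
        )
        profiles = generate_profiles(cfg, catalog)
        task, control = generate_subject_volumes(profiles[0], catalog, cfg)
        assert np.array_equal(task.data, np.zeros(task.shape))
        assert np.array_equal(control.data, np.zeros(task.shape))

    def test_single_focus_peaks_at_canonical_center(self, catalog):
        cfg = CohortConfig(
            n_young=2, n_old=2, grid_shape=(31, 37, 31), voxel_size=6.0,
            noise_sd=0.0, jitter_sd=0.0, seed=1,
        )
        profiles = generate_profiles(cfg, catalog)
        roi = catalog.get("Hippocampus", "L")  # well separated from neighbours
        profile = profiles[0]
        amps = {key: 0.0 for key in profile.amplitudes}
        amps[roi.key] = 1.0
        single = type(profile)(
            subject_id=profile.subject_id, index=profile.index, age=profile.age,
            true_group=profile.true_group, mean_rt=profile.mean_rt, amplitudes=amps,
        )
        task, _ = generate_subject_volumes(single, catalog, cfg)
        grid = grid_from_config(cfg)
        peak_vox = np.unravel_index(np.argmax(task.data), task.shape)
        assert peak_vox == grid.mm_to_voxel(roi.canonical_center)

    def test_extraction_at_expected_peaks_recovers_amplitudes_exactly(self, catalog):
        # the calibration guarantee: on the noiseless expected field,
        # sphere extraction at the locations the calibration targets
        # returns the planted amplitude for every ROI
        from hemiasym.simulate import coupling_matrix

        cfg = CohortConfig(noise_sd=0.0, jitter_sd=0.0, seed=2)
        profiles = generate_profiles(cfg, catalog)
        p = profiles[0]
        M = coupling_matrix(cfg, catalog)
        a = np.array([p.amplitudes[r.key] for r in catalog])
        b = np.linalg.pinv(M, rcond=1e-8) @ a
        assert np.allclose(M @ b, a, atol=1e-9)

    def test_closed_loop_recovery_through_loso_pipeline(self, catalog):
        # full define->extract on a homogeneous low-noise cohort: the
        # typical ROI is recovered well; peak selection on a noisy t-map
        # carries an irreducible downward selection loss that stays bounded
        cfg = CohortConfig(
            noise_sd=0.3, jitter_sd=0.0, lapa_delta=0.0, harold_gain=0.0, seed=2
        )
        cohort = generate_cohort(cfg)
        betas, _ = ha.build_beta_table(
            cohort.task_volumes, cohort.control_volumes, cohort.catalog
        )
        truth = {p.subject_id: p.amplitudes for p in cohort.profiles}
        rel = np.array(
            [
                (row["contrast"] - truth[row["subject_id"]][(row["roi"], row["hemisphere"])])
                / abs(truth[row["subject_id"]][(row["roi"], row["hemisphere"])])
                for _, row in betas.iterrows()
            ]
        )
        assert np.median(np.abs(rel)) < 0.15
        assert np.abs(rel).max() < 0.40  # bounded selection loss
        assert rel.mean() < 0.0  # the loss is a downward bias, never inflation

    def test_amplitude_model(self, catalog):
        cfg = CohortConfig()
        amps_young = subject_amplitudes(cfg, "young", 0.0, catalog)
        amps_old = subject_amplitudes(cfg, "old", 1.0, catalog)
        assert amps_young[("FG", "L")] == cfg.base_amplitude["L_posterior"]
        assert amps_old[("FG", "L")] == pytest.approx(
            cfg.base_amplitude["L_posterior"] + cfg.lapa_delta
        )
        assert amps_old[("IFG", "R")] == pytest.approx(
            cfg.base_amplitude["R_anterior"] + cfg.harold_gain
        )
        assert amps_old[("IFG", "L")] == cfg.base_amplitude["L_anterior"]

    def test_harold_gain_lowers_a_lr_of_fast_old_subjects(self, catalog):
        base = CohortConfig(seed=4, harold_gain=0.0)
        boosted = CohortConfig(seed=4, harold_gain=0.2)
        means = {}
        for cfg in (base, boosted):
            profiles = generate_profiles(cfg, catalog)
            old = [p for p in profiles if p.true_group == "old"]
            fast = sorted(old, key=lambda p: p.mean_rt)[: len(old) // 2]
            a_lr = [
                np.mean([p.amplitudes[(n, "L")] for n in ha.catalog.ANTERIOR_ROIS])
                - np.mean([p.amplitudes[(n, "R")] for n in ha.catalog.ANTERIOR_ROIS])
                for p in fast
            ]
            means[cfg.harold_gain] = np.mean(a_lr)
        assert means[0.2] < means[0.0]


class TestSession:
    def test_default_session_block_structure(self, coarse_cohort):
        trials = coarse_cohort.trials
        sub = trials[trials["subject_id"] == coarse_cohort.profiles[0].subject_id]
        assert len(sub) == 160
        assert (sub["block_type"] == "task").sum() == 80
        assert sub["trial_index"].is_unique
        assert np.allclose(sub["scan_onset"], np.arange(160) * 2.5)

    def test_full_accuracy(self, catalog):
        cfg = CohortConfig(accuracy_rate=1.0, seed=5)
        profiles = generate_profiles(cfg, catalog)
        trials = generate_session(profiles[0], SessionDesign(), accuracy_rate=1.0)
        assert trials["correct"].all()

    def test_latency_calibration_monte_carlo(self, catalog):
        # 10^4 simulated latencies at a subject mean of 830.52 ms
        cfg = CohortConfig(seed=6)
        profiles = generate_profiles(cfg, catalog)
        p = profiles[0]
        target = 830.52
        fixed = type(p)(
            subject_id=p.subject_id, index=p.index, age=p.age,
            true_group=p.true_group, mean_rt=target, amplitudes=p.amplitudes,
        )
        design = SessionDesign(n_task_blocks=250, n_control_blocks=250)  # 10^4 trials
        rng = np.random.default_rng(123)
        trials = generate_session(fixed, design, rng=rng)
        latencies = (trials["response_onset"] - trials["scan_onset"]) * 1000.0
        assert len(latencies) == 10_000
        assert latencies.mean() == pytest.approx(target, abs=15.0)
        assert latencies.min() >= 150.0
        assert latencies.max() <= 2500.0

    def test_responses_stay_inside_scan_windows(self, coarse_cohort):
        trials = coarse_cohort.trials
        lat = (trials["response_onset"] - trials["scan_onset"]) * 1000.0
        assert (lat >= 0).all()
        assert (lat < 2500.0 + 1e-9).all()

    def test_accuracy_converges_to_configured_rate(self, catalog):
        cfg = CohortConfig(seed=7)
        profiles = generate_profiles(cfg, catalog)
        design = SessionDesign(n_task_blocks=250, n_control_blocks=250)
        trials = generate_session(
            profiles[0], design, rng=np.random.default_rng(9), accuracy_rate=0.985
        )
        task = trials[trials["block_type"] == "task"]
        pct = 100.0 * task["correct"].mean()
        assert pct == pytest.approx(98.5, abs=1.0)


class TestCohortIO:
    def test_file_inventory(self, tmp_path, catalog):
        cfg = CohortConfig(
            n_young=2, n_old=2, grid_shape=(31, 37, 31), voxel_size=6.0, seed=8
        )
        cohort = generate_cohort(cfg)
        cohort.profiles = cohort.profiles[:2]
        for extra in list(cohort.task_volumes)[2:]:
            del cohort.task_volumes[extra], cohort.control_volumes[extra]
        manifest = write_cohort(cohort, tmp_path)
        niftis = list(tmp_path.glob("*.nii.gz"))
        tsvs = list(tmp_path.glob("*.tsv"))
        jsons = list(tmp_path.glob("*.json"))
        assert len(niftis) == 4 and len(tsvs) == 2 and len(jsons) == 1
        assert manifest["seed"] == 8

    def test_round_trip(self, tmp_path, coarse_cohort):
        write_cohort(coarse_cohort, tmp_path)
        back = read_cohort(tmp_path)
        assert back.participants.equals(coarse_cohort.participants)
        pd.testing.assert_frame_equal(back.trials, coarse_cohort.trials)
        assert back.config == coarse_cohort.config
        for sid, vol in coarse_cohort.task_volumes.items():
            assert np.max(np.abs(back.task_volumes[sid].data - vol.data)) < 1e-5

    def test_manifest_echoes_config(self, tmp_path, coarse_cohort):
        write_cohort(coarse_cohort, tmp_path)
        manifest = json.loads((tmp_path / "manifest.json").read_text())
        assert manifest["config"]["seed"] == coarse_cohort.config.seed
        assert manifest["n_subjects"] == len(coarse_cohort.profiles)


class TestTableFastPath:
    def test_structure_and_determinism(self):
        cfg = CohortConfig(seed=9)
        p1, t1 = generate_roi_contrast_table(cfg)
        p2, t2 = generate_roi_contrast_table(cfg)
        assert len(t1) == 27 * 22
        pd.testing.assert_frame_equal(t1, t2)

    def test_expected_index_means_near_calibration(self):
        # averaging over many subjects, L_AP should sit near the planted
        # young/old expectations
        cfg = CohortConfig(n_young=200, n_old=200, seed=10)
        profiles, table = generate_roi_contrast_table(cfg)
        idx = ha.index_table(table)
        groups = {p.subject_id: p.true_group for p in profiles}
        young = idx[idx["subject_id"].map(groups) == "young"]["L_AP"].mean()
        old = idx[idx["subject_id"].map(groups) == "old"]["L_AP"].mean()
        assert young == pytest.approx(-0.21, abs=0.05)
        assert old == pytest.approx(-0.48, abs=0.05)
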