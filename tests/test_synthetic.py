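"""Synthetic-data generator tests: determinism, planted structure, validity."""

import json

import numpy as np
import pandas as pd
import pytest

from stressnet.connectivity import correlation_matrix
from stressnet.synthetic import (
    CohortSpec,
    DotProbeSpec,
    latent_stress_scores,
    simulate_behavior,
    simulate_dotprobe,
    simulate_timeseries,
    write_cohort,
)


class TestCohortSpecValidation:
    def test_duplicate_network_names_rejected(self):
        with pytest.raises(ValueError, match="unique"):
            CohortSpec(partition_sizes=(("A", 3), ("A", 3)))

    def test_within_target_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="within target"):
            CohortSpec(partition_sizes=(("A", 3),), within_targets=1.0)

    def test_non_positive_definite_base_rejected_naming_blocks(self):
        # between correlation far above both within values breaks PD
        with pytest.raises(ValueError, match="positive definite"):
            CohortSpec(
                partition_sizes=(("A", 3), ("B", 3)),
                within_targets=0.1,
                between_targets=0.9,
            )

    def test_excessive_planted_r2_rejected(self):
        with pytest.raises(ValueError, match="R\\^2"):
            CohortSpec(mediation_coeffs=(0.5, 0.9, 0.9))

    def test_bad_subject_index_rejected(self, tiny_spec):
        with pytest.raises(ValueError, match="out of range"):
            simulate_timeseries(tiny_spec, tiny_spec.n_subjects)


class TestTimeSeries:
    def test_deterministic_given_seed_and_subject(self, tiny_spec):
        a = simulate_timeseries(tiny_spec, 3)
        b = simulate_timeseries(tiny_spec, 3)
        assert np.array_equal(a.values, b.values)

    def test_different_subjects_differ(self, tiny_spec):
        a = simulate_timeseries(tiny_spec, 0)
        b = simulate_timeseries(tiny_spec, 1)
        assert not np.allclose(a.values, b.values)

    def test_independent_nodes_give_near_zero_correlation(self):
        spec = CohortSpec(
            n_subjects=1,
            t_points=900,
            partition_sizes=(("A", 6), ("B", 6)),
            within_targets=0.0,
            between_targets=0.0,
            mediation_coeffs=(0.0, 0.0, 0.0),
            target_sd=0.0,
            seed=1,
        )
        A = correlation_matrix(simulate_timeseries(spec, 0)).A
        off = A[~np.eye(12, dtype=bool)]
        assert abs(off.mean()) < 3 / np.sqrt(spec.t_points)

    def test_within_block_correlation_matches_target(self):
        # Fisher-z sampling error at T = 2000 is ~1/sqrt(T-3) = 0.022
        spec = CohortSpec(
            n_subjects=1,
            t_points=2000,
            partition_sizes=(("A", 10),),
            within_targets=0.5,
            between_targets={},
            mediation_coeffs=(0.0, 0.0, 0.0),
            mediator_measure="within:A",
            target_sd=0.0,
            seed=2,
        )
        A = correlation_matrix(simulate_timeseries(spec, 0)).A
        off = A[~np.eye(10, dtype=bool)]
        assert off.mean() == pytest.approx(0.5, abs=0.05)

    def test_block_structure_converges_with_t(self):
        # realized block means approach targets at the Fisher-z rate
        spec = CohortSpec(
            n_subjects=1,
            t_points=3000,
            partition_sizes=(("A", 8), ("B", 8)),
            within_targets={"A": 0.4, "B": 0.2},
            between_targets=0.1,
            mediation_coeffs=(0.0, 0.0, 0.0),
            mediator_measure="within:A",
            target_sd=0.0,
            seed=4,
        )
        A = correlation_matrix(simulate_timeseries(spec, 0)).A
        tol = 3 / np.sqrt(spec.t_points - 3)
        blockA, blockB = A[:8, :8], A[8:, 8:]
        assert blockA[~np.eye(8, dtype=bool)].mean() == pytest.approx(0.4, abs=tol)
        assert blockB[~np.eye(8, dtype=bool)].mean() == pytest.approx(0.2, abs=tol)
        assert A[:8, 8:].mean() == pytest.approx(0.1, abs=tol)


class TestBehavior:
    def test_null_model_has_no_correlations(self):
        spec = CohortSpec(
            n_subjects=900,
            partition_sizes=(("A", 3),),
            mediation_coeffs=(0.0, 0.0, 0.0),
            mediator_measure="within:A",
            stress_loading=0.0,
            seed=5,
        )
        beh = simulate_behavior(spec)
        tol = 3 / np.sqrt(spec.n_subjects)
        x = latent_stress_scores(spec)
        assert abs(np.corrcoef(x, beh["depression"])[0, 1]) < tol
        assert abs(beh.attrs["realized_a"]) < tol

    def test_large_sample_path_recovery(self):
        # closed-form OLS on the generating model: regressing z(Y) on
        # [z(X), z(M)] recovers (c_prime, b); z(M) on z(X) recovers a
        spec = CohortSpec(
            n_subjects=5000,
            partition_sizes=(("A", 3),),
            mediation_coeffs=(0.5, 0.4, 0.2),
            mediator_measure="within:A",
            noise_sd=np.sqrt(1 - (0.2**2 + 0.4**2 + 2 * 0.5 * 0.4 * 0.2)),
            seed=6,
        )
        beh = simulate_behavior(spec)
        x = latent_stress_scores(spec)
        m = beh["mediator_z"].to_numpy()
        y = beh["depression"].to_numpy()
        y = (y - y.mean()) / y.std()
        # closed-form OLS oracle on the generating model
        a_hat = np.linalg.lstsq(np.column_stack([np.ones_like(x), x]), m, rcond=None)[0][1]
        design = np.column_stack([np.ones_like(x), x, m])
        _, c_prime_hat, b_hat = np.linalg.lstsq(design, y, rcond=None)[0]
        assert a_hat == pytest.approx(0.5, abs=0.05)
        assert b_hat == pytest.approx(0.4, abs=0.05)
        assert c_prime_hat == pytest.approx(0.2, abs=0.05)

    def test_behavior_deterministic(self, tiny_spec):
        a = simulate_behavior(tiny_spec)
        b = simulate_behavior(tiny_spec)
        pd.testing.assert_frame_equal(a, b)

    def test_realized_mediator_branch_couples_y(self):
        spec = CohortSpec(
            n_subjects=3000,
            partition_sizes=(("A", 3),),
            mediation_coeffs=(0.0, 0.5, 0.0),
            mediator_measure="within:A",
            noise_sd=np.sqrt(1 - 0.25),
            seed=7,
        )
        rng = np.random.default_rng(0)
        m = rng.standard_normal(spec.n_subjects)
        beh = simulate_behavior(spec, m_values=m)
        m_z = (m - m.mean()) / m.std()
        y = beh["depression"].to_numpy()
        assert np.corrcoef(m_z, y)[0, 1] == pytest.approx(0.5, abs=0.05)

    def test_wrong_mediator_length_rejected(self, tiny_spec):
        with pytest.raises(ValueError, match="length"):
            simulate_behavior(tiny_spec, m_values=np.zeros(tiny_spec.n_subjects + 1))

    def test_demographics_realism(self):
        spec = CohortSpec(n_subjects=2000, partition_sizes=(("A", 3),),
                          mediator_measure="within:A", seed=8)
        beh = simulate_behavior(spec)
        assert beh["age"].between(16, 26).all()
        assert set(beh["sex"]) <= {0, 1}
        assert beh["sex"].mean() == pytest.approx(157 / 528, abs=0.05)
        assert beh["els"].mean() == pytest.approx(37.35, abs=1.0)


class TestDotProbe:
    def test_default_trial_count_per_subject(self, probe_spec):
        # 2 blocks x (40 + 37 + 37 + 37) = 302 trials
        trials = simulate_dotprobe(probe_spec)
        counts = trials.groupby("subject_id").size()
        assert (counts == 302).all()

    def test_per_condition_counts(self, probe_spec):
        trials = simulate_dotprobe(probe_spec)
        per = trials.groupby(["subject_id", "condition"]).size().unstack()
        assert (per["NH"] == 80).all()
        assert (per[["NS", "NA", "NF"]] == 74).all().all()

    def test_deterministic(self, probe_spec):
        pd.testing.assert_frame_equal(simulate_dotprobe(probe_spec), simulate_dotprobe(probe_spec))

    def test_noiseless_shift_exact(self):
        spec = DotProbeSpec(
            n_subjects=2, bias_shift_ms={"NS": 20.0}, rt_noise_sd_ms=0.0,
            error_rate=0.0, seed=1,
        )
        trials = simulate_dotprobe(spec)
        ns = trials[trials["condition"] == "NS"]
        incong = ns["face_side"] != ns["probe_side"]
        assert set(ns.loc[incong, "rt_ms"]) == {520.0}
        assert set(ns.loc[~incong, "rt_ms"]) == {500.0}

    def test_all_rts_positive_and_error_rate(self):
        spec = DotProbeSpec(n_subjects=20, error_rate=0.05, seed=2)
        trials = simulate_dotprobe(spec)
        assert (trials["rt_ms"] > 0).all()
        assert (~trials["correct"]).mean() == pytest.approx(0.05, abs=0.01)

    def test_unknown_shift_condition_rejected(self):
        with pytest.raises(ValueError, match="unknown conditions"):
            DotProbeSpec(bias_shift_ms={"XX": 5.0})


class TestWriteCohort:
    def test_writes_all_artifacts_and_manifest(self, tmp_path):
        spec = CohortSpec(n_subjects=3, t_points=50,
                          partition_sizes=(("VAN", 4), ("VN", 3)), seed=9)
        probe = DotProbeSpec(n_subjects=3, seed=10)
        manifest = write_cohort(spec, tmp_path, dotprobe_spec=probe)
        assert (tmp_path / "partition.csv").exists()
        assert (tmp_path / "behavior.csv").exists()
        assert (tmp_path / "dotprobe_trials.csv").exists()
        assert len(list((tmp_path / "timeseries").glob("*.tsv"))) == 3
        saved = json.loads((tmp_path / "manifest.json").read_text())
        assert saved["cohort_spec"]["seed"] == 9
        assert manifest["files"]["behavior"] == "behavior.csv"
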