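import dataclasses
import filecmp

import numpy as np
import pytest

from axokin.synthetic_data import (
    BetaPulse,
    HeadTemplate,
    Individual,
    ScalingLaw,
    SimConfig,
    export_cohort,
    generate_bout,
    sample_cohort,
    sample_records,
    simulate_cohort,
)
from axokin.trajectory_io import CalibrationSpec, read_pose_table


class TestBetaPulse:
    def test_value_peaks_at_rise_end(self):
        p = BetaPulse(0.1, 0.5, 0.04, 0.05)
        assert p.value(np.array([p.peak_time]))[0] == pytest.approx(0.5)
        assert p.value(np.array([0.05, 0.25]))[0] == 0.0
        assert p.value(np.array([0.25]))[0] == 0.0

    def test_max_rate_matches_dense_numeric_derivative(self):
        p = BetaPulse(0.0, 0.3, 0.05, 0.06)
        t = np.linspace(1e-6, p.duration - 1e-6, 400_001)
        num = np.max(np.abs(np.gradient(p.value(t), t)))
        assert p.max_rate(0.0, p.duration) == pytest.approx(num, rel=1e-5)

    def test_max_accel_matches_dense_numeric_derivative(self):
        p = BetaPulse(0.0, 0.3, 0.05, 0.06)
        t = np.linspace(1e-6, p.duration - 1e-6, 400_001)
        d2 = np.gradient(np.gradient(p.value(t), t), t)
        assert p.max_accel(0.0, p.duration) == pytest.approx(
            np.max(np.abs(d2[5:-5])), rel=1e-4)

    def test_crossing_inverts_value(self):
        p = BetaPulse(0.2, 1.0, 0.03, 0.04)
        for frac in (0.05, 0.10, 0.5):
            for side in ("rise", "fall"):
                t = p.crossing(frac, side)
                assert p.value(np.array([t]))[0] == pytest.approx(frac,
                                                                  abs=1e-9)

    def test_too_asymmetric_raises(self):
        with pytest.raises(ValueError, match="asymmetry"):
            BetaPulse(0.0, 1.0, 0.01, 0.10)


class TestSampleCohort:
    def test_same_seed_bitwise_identical(self):
        cfg = SimConfig()
        b1, i1 = simulate_cohort(cfg, seed=5)
        b2, i2 = simulate_cohort(cfg, seed=5)
        assert len(b1) == len(b2)
        for (t1, g1), (t2, g2) in zip(b1, b2):
            assert t1.bout_id == t2.bout_id
            for name in t1.landmarks:
                assert np.array_equal(t1.landmarks[name], t2.landmarks[name])
            assert g1.params == g2.params

    def test_zero_cv_collapses_stage_svl(self):
        cfg = dataclasses.replace(SimConfig(), svl_distributions={
            "larva": (2.8, 0.0), "juvenile": (3.5, 0.0), "adult": (8.4, 0.0)})
        cohort = sample_cohort(cfg, np.random.default_rng(0))
        svls = {}
        for ind in cohort:
            svls.setdefault(ind.stage, set()).add(ind.svl)
        assert all(len(v) == 1 for v in svls.values())

    def test_adult_to_larva_mean_ratio(self):
        cfg = dataclasses.replace(SimConfig(), n_larvae=4000, n_juveniles=0,
                                  n_adults=4000)
        cohort = sample_cohort(cfg, np.random.default_rng(123))
        larva = np.mean([i.svl for i in cohort if i.stage == "larva"])
        adult = np.mean([i.svl for i in cohort if i.stage == "adult"])
        assert adult / larva == pytest.approx(3.0, abs=0.1)

    def test_empty_cohort_raises(self):
        cfg = dataclasses.replace(SimConfig(), n_larvae=0, n_juveniles=0,
                                  n_adults=0)
        with pytest.raises(ValueError, match="empty"):
            sample_cohort(cfg, np.random.default_rng(0))


class TestGenerateBout:
    def test_geometric_similarity_self_test(self):
        """With slope-1 laws and no noise, doubling SVL doubles lengths and
        durations and leaves peak speeds unchanged."""
        laws = {k: dataclasses.replace(law, slope=1.0, sd_individual=0.0,
                                       sd_bout=0.0, loading=0.0)
                for k, law in SimConfig().laws.items()}
        cfg = dataclasses.replace(SimConfig().noiseless(), laws=laws,
                                  effort_sd=0.0, quality_sd=0.0)
        out = {}
        for svl in (3.0, 6.0):
            ind = Individual("i", "larva", svl, 0.0,
                             {k: 0.0 for k in laws})
            _, gt = generate_bout(ind, cfg, np.random.default_rng(0))
            out[svl] = gt.true
        assert out[6.0]["MG"] == pytest.approx(2 * out[3.0]["MG"], rel=1e-9)
        assert out[6.0]["DG"] == pytest.approx(2 * out[3.0]["DG"], rel=1e-9)
        assert out[6.0]["MSGO"] == pytest.approx(out[3.0]["MSGO"], rel=1e-9)

    def test_ground_truth_peak_rate_closed_form(self, noiseless_bout):
        """True peak hyoid speeds equal the pulse derivative maxima."""
        from axokin.synthetic_data import _bout_pulses

        _, gt, _ = noiseless_bout
        pulses = _bout_pulses(gt.params, 0.0)
        hd1 = pulses["hd1"]
        assert gt.true["MShd1down"] == pytest.approx(
            hd1.max_rate(hd1.onset, hd1.peak_time), rel=1e-9)

    def test_too_short_gape_cycle_raises(self):
        laws = dict(SimConfig().laws)
        laws["DGO"] = ScalingLaw(-3.5, 0.0)
        laws["DGC"] = ScalingLaw(-3.5, 0.0)
        cfg = dataclasses.replace(SimConfig().noiseless(), laws=laws)
        ind = Individual("i", "larva", 3.0, 0.0, {k: 0.0 for k in laws})
        with pytest.raises(ValueError, match="4 frames"):
            generate_bout(ind, cfg, np.random.default_rng(0))

    def test_head_template_gape_geometry(self):
        tpl = HeadTemplate(svl=4.0)
        assert tpl.gape_angle_deg(2 * tpl.r_jaw * np.sin(np.radians(30)))  \
            == pytest.approx(60.0)
        with pytest.raises(ValueError, match="chord"):
            tpl.gape_angle_deg(2.1 * tpl.r_jaw)


class TestExportCohort:
    def test_round_trip_and_reproducibility(self, tmp_path):
        cfg = dataclasses.replace(SimConfig(), n_larvae=2, n_juveniles=0,
                                  n_adults=1, bouts_min=1, bouts_max=2)
        bouts, _ = simulate_cohort(cfg, seed=3)
        export_cohort(bouts, tmp_path / "a", config=cfg, seed=3)
        export_cohort(bouts, tmp_path / "b", config=cfg, seed=3)
        import pandas as pd

        meta = pd.read_csv(tmp_path / "a" / "individuals.csv").set_index(
            "individual_id")
        traj, gt = bouts[0]
        calib = CalibrationSpec(
            pixels_per_square=meta.loc[traj.individual_id,
                                       "pixels_per_square"])
        back = read_pose_table(
            tmp_path / "a" / "pose" / f"{traj.bout_id}.csv",
            fps=traj.fps, calibration=calib)
        for name in traj.landmarks:
            assert np.allclose(back.landmarks[name][:, :2],
                               traj.landmarks[name][:, :2],
                               rtol=1e-8, atol=1e-10)
        for f in (tmp_path / "a" / "pose").iterdir():
            assert filecmp.cmp(f, tmp_path / "b" / "pose" / f.name,
                               shallow=False)

    def test_default_cohort_exports_25_individuals(self, tmp_path):
        bouts, individuals = simulate_cohort(SimConfig(), seed=8)
        export_cohort(bouts, tmp_path / "c", seed=8)
        import pandas as pd

        meta = pd.read_csv(tmp_path / "c" / "individuals.csv")
        assert len(meta) == 25


class TestRecordTier:
    def test_deterministic(self):
        a = sample_records(SimConfig(), seed=2)
        b = sample_records(SimConfig(), seed=2)
        assert a.equals(b)

    def test_all_25_variables_positive(self, record_table):
        from axokin.event_extraction import KINEMATIC_VARIABLES

        assert set(KINEMATIC_VARIABLES) <= set(record_table.columns)
        assert (record_table[list(KINEMATIC_VARIABLES)] > 0).all().all()
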