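"""Relative-deviation statistic, boundary calibration, and motion classification."""

import numpy as np
import pytest

import sptkit as sk
from sptkit.motion import RDCalibration


class TestComputeRD:
    def test_brownian_ensemble_centers_on_one(self, brownian_300):
        rds = np.array([sk.compute_rd(tr).rd for tr in brownian_300])
        assert np.nanmean(rds) == pytest.approx(1.0, abs=0.05)

    def test_confined_rd_below_half(self):
        cfg = sk.SimConfig(n_tracks=150, n_steps=300, dt=0.1, D=0.01,
                           mode="confined_square", L=0.2, seed=60)
        rds = [sk.compute_rd(tr).rd for tr in sk.simulate_confined(cfg)]
        assert np.nanmean(rds) < 0.5

    def test_directed_rd_above_one(self):
        cfg = sk.SimConfig(n_tracks=100, n_steps=300, dt=0.1, D=0.05,
                           mode="directed", v=(0.2, 0.0), seed=61)
        rds = [sk.compute_rd(tr).rd for tr in sk.simulate_directed(cfg)]
        assert np.mean(rds) > 1.0

    def test_short_track_rejected(self):
        cfg = sk.SimConfig(n_tracks=1, n_steps=40, dt=0.1, D=0.1, seed=62)
        with pytest.raises(ValueError):
            sk.compute_rd(sk.simulate_brownian(cfg)[0], n=25)

    def test_scale_invariance_with_D(self):
        # RD is dimensionless: scaling a track spatially (i.e. changing D)
        # leaves it unchanged
        cfg = sk.SimConfig(n_tracks=5, n_steps=200, dt=0.1, D=0.1, seed=63)
        for tr in sk.simulate_brownian(cfg):
            scaled = sk.Trajectory(tr.track_id, tr.frames, tr.x * 0.3,
                                   tr.y * 0.3, dt=tr.dt)
            assert sk.compute_rd(scaled).rd == pytest.approx(
                sk.compute_rd(tr).rd, rel=1e-9)

    def test_dt_invariance(self):
        cfg = sk.SimConfig(n_tracks=5, n_steps=200, dt=0.1, D=0.1, seed=64)
        for tr in sk.simulate_brownian(cfg):
            re_timed = sk.Trajectory(tr.track_id, tr.frames, tr.x, tr.y, dt=0.03)
            assert sk.compute_rd(re_timed).rd == pytest.approx(
                sk.compute_rd(tr).rd, rel=1e-9)


class TestCalibration:
    def test_band_brackets_one(self, calibration):
        for lo, hi in zip(calibration.p2_5, calibration.p97_5):
            assert lo < 1.0 < hi

    def test_band_narrows_with_length(self, calibration):
        width_first = calibration.p97_5[0] - calibration.p2_5[0]
        width_last = calibration.p97_5[-1] - calibration.p2_5[-1]
        assert width_last < width_first

    def test_lower_boundary_positive_on_range(self, calibration):
        N = np.asarray(calibration.lengths)
        assert np.all(calibration.lower_boundary(N) > 0)

    def test_replicate_lower_tail(self, calibration):
        # below the raw 2.5th percentile: ~2.5% by construction; below the
        # fitted line: less, because the percentile-vs-N curve is concave
        # and the line undershoots it at mid-range N
        cfg = sk.SimConfig(n_tracks=1000, n_steps=300, dt=0.1, D=0.1, seed=65)
        rds = np.array([sk.compute_rd(tr).rd for tr in sk.simulate_brownian(cfg)])
        i = calibration.lengths.index(300)
        frac_pct = np.mean(rds < calibration.p2_5[i])
        assert frac_pct == pytest.approx(0.025, abs=0.01)
        frac_line = np.mean(rds < calibration.lower_boundary(300))
        assert 0 < frac_line <= frac_pct + 0.01

    def test_reproducible_and_stable_across_seeds(self):
        a = sk.calibrate_cutoffs(lengths=(100, 300), n_per_length=400,
                                 upper_order=1, seed=1)
        b = sk.calibrate_cutoffs(lengths=(100, 300), n_per_length=400,
                                 upper_order=1, seed=1)
        assert a.p2_5 == b.p2_5 and a.p97_5 == b.p97_5
        c = sk.calibrate_cutoffs(lengths=(100, 300), n_per_length=400,
                                 upper_order=1, seed=2)
        assert np.allclose(a.p2_5, c.p2_5, rtol=0.10)

    def test_boundary_D_independence(self):
        a = sk.calibrate_cutoffs(lengths=(100, 300), n_per_length=500,
                                 D=0.1, upper_order=1, seed=3)
        b = sk.calibrate_cutoffs(lengths=(100, 300), n_per_length=500,
                                 D=0.01, upper_order=1, seed=3)
        assert np.allclose(a.p2_5, b.p2_5, rtol=0.05)

    def test_underdetermined_upper_fit_rejected(self):
        with pytest.raises(ValueError):
            sk.calibrate_cutoffs(lengths=(100, 200, 300), n_per_length=100,
                                 upper_order=4)

    def test_json_roundtrip(self, calibration, tmp_path):
        p = tmp_path / "calib.json"
        calibration.to_json(p)
        back = RDCalibration.from_json(p)
        assert back.lengths == calibration.lengths
        assert np.allclose(back.lower_fit, calibration.lower_fit)


class TestClassification:
    def test_rd_one_is_free(self, calibration):
        from sptkit.motion import RDValue

        for N in calibration.lengths:
            assert sk.classify_track(RDValue(1.0, 25, N, 0.1), calibration) == "free"

    def test_tiny_rd_is_restricted(self, calibration):
        from sptkit.motion import RDValue

        assert sk.classify_track(RDValue(0.01, 25, 300, 0.1),
                                 calibration) == "restricted"

    def test_out_of_range_warns(self, calibration):
        from sptkit.motion import RDValue

        with pytest.warns(UserWarning, match="extrapolat"):
            sk.classify_track(RDValue(1.0, 25, 2000, 0.1), calibration)

    def test_confined_power_and_brownian_specificity(self, calibration, brownian_300):
        cfg = sk.SimConfig(n_tracks=150, n_steps=300, dt=0.1, D=0.01,
                           mode="confined_square", L=0.2, seed=66)
        conf = [sk.classify_track(r, calibration)
                for r in map(sk.compute_rd, sk.simulate_confined(cfg)) if r.valid]
        assert np.mean([lab == "restricted" for lab in conf]) > 0.8
        free = [sk.classify_track(r, calibration)
                for r in map(sk.compute_rd, brownian_300) if r.valid]
        assert np.mean([lab == "free" for lab in free]) > 0.9


class TestClassifyTrackset:
    def test_all_immobile(self, calibration):
        cfg = sk.SimConfig(n_tracks=10, n_steps=60, dt=0.1, D=0.0, seed=67)
        ts = sk.add_localization_noise(sk.simulate_brownian(cfg), 0.02, seed=68)
        d_mle = {tr.track_id: 1e-5 for tr in ts}
        out = sk.classify_trackset(ts, calibration, d_mle=d_mle)
        assert out.fractions == {"immobile": 1.0}

    def test_mixture_fractions(self, calibration):
        half = sk.SimConfig(n_tracks=100, n_steps=300, dt=0.1, D=0.1, seed=69)
        conf = sk.SimConfig(n_tracks=100, n_steps=300, dt=0.1, D=0.01,
                            mode="confined_square", L=0.2, seed=70)
        tracks = list(sk.simulate_brownian(half)) + [
            sk.Trajectory(f"c{tr.track_id}", tr.frames, tr.x, tr.y, dt=tr.dt)
            for tr in sk.simulate_confined(conf)
        ]
        out = sk.classify_trackset(sk.TrackSet(tracks), calibration)
        restricted = out.counts.get("restricted", 0) / len(tracks)
        assert 0.4 <= restricted <= 0.6
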