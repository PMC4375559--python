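"""Detection, fitting, linking, rendering and precision-summary checks."""

import numpy as np
import pandas as pd
import pytest

from basintrap import localize, palm
from basintrap.localize import LocalizationTable, SpotROI


def synthetic_roi(photons=500.0, bg=10.0, x=5.3, y=4.7, gain=50.0,
                  offset=100.0, read=1.0, rng=None, size=11,
                  psf_sigma_px=1.3):
    mu = photons * palm.integrated_gaussian((size, size), x, y, psf_sigma_px) + bg
    if rng is None:
        data = mu * gain + offset
    else:
        data = (rng.poisson(mu) * gain
                + rng.normal(0, read * gain, (size, size)) + offset)
    return SpotROI(data, 0, 0, 0)


def table_from_ci(ci_values, photons=100.0):
    n = len(ci_values)
    df = pd.DataFrame({
        "frame": np.arange(n), "x_nm": np.zeros(n), "y_nm": np.zeros(n),
        "photons": np.full(n, photons), "background": np.zeros(n),
        "sigma_nm": np.full(n, 130.0), "ci95_nm": np.asarray(ci_values),
        "fit_ok": np.ones(n, bool), "reason": ["ok"] * n})
    return LocalizationTable(df)


class TestDetect:
    def test_single_bright_emitter_gives_one_roi(self):
        rng = np.random.default_rng(0)
        frame = rng.normal(100, 2, (64, 64))
        frame += 5000 * palm.integrated_gaussian((64, 64), 30.2, 40.7, 1.3)
        rois = localize.detect_spots(frame)
        assert len(rois) == 1
        r = rois[0]
        assert r.y0 <= 40.7 <= r.y0 + 11 and r.x0 <= 30.2 <= r.x0 + 11

    def test_blank_frames_rarely_false_positive(self):
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            frame = rng.normal(100, 5, (64, 64))
            hits += bool(localize.detect_spots(frame, threshold=5.0))
        assert hits <= 1  # >= 99% clean frames

    def test_two_separated_emitters_give_two_rois(self):
        frame = np.random.default_rng(1).normal(100, 2, (64, 64))
        for x, y in [(20.0, 32.0), (40.0, 32.0)]:
            frame += 3000 * palm.integrated_gaussian((64, 64), x, y, 1.3)
        rois = localize.detect_spots(frame)
        assert len(rois) == 2
        assert abs(rois[0].x0 - rois[1].x0) >= 11

    def test_activation_frame_warns_and_returns_nothing(self):
        with pytest.warns(UserWarning):
            assert localize.detect_spots(np.zeros((32, 32)),
                                         is_imaging_frame=False) == []


class TestFitSpot:
    def test_noiseless_fit_recovers_subpixel_centre(self):
        rec = localize.fit_spot(synthetic_roi(photons=1000, bg=0, gain=1.0,
                                              offset=0.0),
                                gain=1.0, camera_offset=0.0)
        assert rec["fit_ok"]
        assert abs(rec["x_nm"] / 100 - 5.3) < 1e-4
        assert abs(rec["y_nm"] / 100 - 4.7) < 1e-4

    def test_photon_estimate_is_unbiased(self):
        rng = np.random.default_rng(3)
        ph = [localize.fit_spot(synthetic_roi(rng=rng), gain=50.0,
                                camera_offset=100.0)["photons"]
              for _ in range(100)]
        assert np.nanmean(ph) == pytest.approx(500, rel=0.05)

    def test_pure_background_roi_fails(self):
        roi = SpotROI(np.random.default_rng(0).normal(100, 3, (11, 11)), 0, 0, 0)
        rec = localize.fit_spot(roi, gain=50.0, camera_offset=100.0)
        assert not rec["fit_ok"]

    def test_rmse_agrees_with_reported_precision(self):
        # Monte-Carlo calibration: empirical error vs covariance-based ci95
        rng = np.random.default_rng(11)
        errs, cis = [], []
        for _ in range(300):
            x = 5 + rng.uniform(-0.5, 0.5)
            y = 5 + rng.uniform(-0.5, 0.5)
            rec = localize.fit_spot(synthetic_roi(x=x, y=y, rng=rng),
                                    gain=50.0, camera_offset=100.0)
            if rec["fit_ok"]:
                errs += [rec["x_nm"] / 100 - x, rec["y_nm"] / 100 - y]
                cis.append(rec["ci95_nm"] / 100)
        rmse = np.sqrt(np.mean(np.square(errs)))
        assert rmse == pytest.approx(np.mean(cis) / 1.96, rel=0.25)

    def test_thompson_cross_check_same_order(self):
        rng = np.random.default_rng(5)
        rec = localize.fit_spot(synthetic_roi(rng=rng), gain=50.0,
                                camera_offset=100.0)
        th = localize.thompson_precision_nm(rec["photons"], rec["sigma_nm"],
                                            100.0, rec["background"])
        assert 0.3 < (rec["ci95_nm"] / 1.96) / th < 3.0


class TestLinking:
    def test_one_molecule_in_five_consecutive_frames(self):
        tab = table_from_ci([20.0] * 5)
        assert localize.link_and_count_molecules(tab) == 1

    def test_two_distant_molecules(self):
        df = table_from_ci([20.0] * 4).df
        df.loc[2:, "x_nm"] = 5000.0
        df.loc[2:, "frame"] = [10, 11]
        assert localize.link_and_count_molecules(LocalizationTable(df)) == 2

    def test_recovers_known_emitter_count(self):
        cfg = palm.AcquisitionConfig(activation_pulses=80, max_frames=800,
                                     detector_shape=(48, 48), seed=5)
        em = palm.EmitterSet.two_clusters([(1400, 2400), (3400, 2400)],
                                          n_per_cluster=15, scatter_nm=120,
                                          seed=5, activation_prob=0.02)
        stack = palm.simulate_movie(em, cfg)
        tab = localize.localize_stack(stack)
        truth = stack.ground_truth.emitter.nunique()
        got = localize.link_and_count_molecules(tab)
        assert got == pytest.approx(truth, rel=0.1)


class TestRender:
    def test_total_intensity_conserves_photons(self):
        tab = table_from_ci([20.0], photons=345.0)
        img = localize.render(tab)
        assert img.total == pytest.approx(345.0, rel=1e-6)

    def test_duplicate_records_double_the_image(self):
        one = localize.render(table_from_ci([20.0], photons=100.0))
        two = localize.render(table_from_ci([20.0, 20.0], photons=100.0))
        assert two.total == pytest.approx(2 * one.total, rel=1e-9)

    def test_two_clusters_render_as_two_maxima(self):
        df = table_from_ci([15.0] * 40, photons=200.0).df
        df.loc[:19, "x_nm"] = 1000.0
        df.loc[20:, "x_nm"] = 2500.0
        sr = localize.render(LocalizationTable(df), render_px_nm=10.0)
        profile = sr.data.sum(axis=0)
        peaks = np.flatnonzero((profile > np.roll(profile, 1))
                               & (profile > np.roll(profile, -1))
                               & (profile > profile.max() * 0.25))
        assert peaks.size == 2
        assert (peaks[1] - peaks[0]) * 10.0 == pytest.approx(1500.0, abs=30)

    def test_empty_table_warns(self):
        empty = LocalizationTable(table_from_ci([]).df)
        with pytest.warns(UserWarning):
            img = localize.render(empty)
        assert img.total == 0.0


class TestModalPrecision:
    def test_constant_distribution(self):
        assert localize.modal_precision(table_from_ci([20.0] * 10)) == 20.0

    def test_bimodal_takes_the_heavier_mode(self):
        ci = [15.0] * 30 + [30.0] * 20
        assert localize.modal_precision(table_from_ci(ci)) == pytest.approx(15.0, abs=1.0)

    def test_tie_breaks_toward_smaller_precision(self):
        ci = [15.0] * 10 + [31.0] * 10
        assert localize.modal_precision(table_from_ci(ci)) < 20.0

    def test_empty_table_raises(self):
        with pytest.raises(ValueError):
            localize.modal_precision(table_from_ci([]))


class TestCsvRoundTrip:
    def test_column_contract_and_round_trip(self, tmp_path):
        tab = table_from_ci([20.0, 22.0])
        p = tmp_path / "locs.csv"
        tab.to_csv(p)
        back = LocalizationTable.from_csv(p)
        assert list(back.df.columns) == localize.COLUMNS
        pd.testing.assert_frame_equal(back.df, tab.df)
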