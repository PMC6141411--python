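"""Phantom ground truth, kinetics and rendering contracts."""

import numpy as np
import pytest
from scipy.integrate import quad

from gatedpet import phantom
from gatedpet.phantom import BolusConfig, PhantomConfig


class TestChamberVolumeCurve:
    @pytest.mark.parametrize(
        "edv,ef,expected_min",
        [(100.0, 0.40, 60.0), (96.0, 0.65, 33.6), (100.0, 0.60, 40.0)],
    )
    def test_extremes_forced_by_construction(self, edv, ef, expected_min):
        vols, times = phantom.chamber_volume_curve(edv, ef, 8, 870.0)
        assert vols[0] == pytest.approx(edv)
        assert vols.max() == pytest.approx(edv)
        assert vols.min() == pytest.approx(expected_min)
        assert times.shape == (8,) and times[0] == 0.0

    def test_vanishing_ef_gives_constant_curve(self):
        vols, _ = phantom.chamber_volume_curve(100.0, 1e-9, 8, 870.0)
        assert np.allclose(vols, 100.0)

    def test_biphasic_filling_shape(self):
        vols, _ = phantom.chamber_volume_curve(100.0, 0.6, 16, 870.0)
        es = int(np.argmin(vols))
        assert 0 < es < 15
        # monotone ejection then filling with a slow diastasis in between
        assert np.all(np.diff(vols[: es + 1]) < 0)
        assert np.all(np.diff(vols[es:]) > 0)

    @pytest.mark.parametrize("ef", [0.0, 1.0, -0.2, 1.5])
    def test_rejects_ef_outside_unit_interval(self, ef):
        with pytest.raises(ValueError):
            phantom.chamber_volume_curve(100.0, ef, 8, 870.0)


class TestBolusKinetics:
    def test_zero_before_injection(self):
        cfg = PhantomConfig()
        rv, lv, myo = phantom.bolus_kinetics(cfg, np.array([0.0]))
        assert rv[0] == lv[0] == myo[0] == 0.0

    def test_lv_peaks_after_rv(self):
        b = BolusConfig(lv_delay_s=4.0, dispersion_s=2.5)
        t = np.arange(0, 120, 0.05)
        rv, lv, _ = phantom.bolus_kinetics(b, t)
        assert t[np.argmax(lv)] > t[np.argmax(rv)]
        assert np.all(rv >= 0) and np.all(lv >= 0)

    def test_myocardium_rises_monotonically_to_plateau(self):
        b = BolusConfig()
        t = np.arange(0, 400, 0.5)
        _, lv, myo = phantom.bolus_kinetics(b, t)
        assert np.all(np.diff(myo) >= 0)
        assert myo[-1] == pytest.approx(b.myo_plateau_frac * lv.max(), rel=0.02)

    def test_closed_form_integrals_match_quadrature(self):
        b = BolusConfig()
        for t0, t1 in [(0.0, 10.0), (8.0, 25.0), (30.0, 90.0)]:
            closed = phantom.kinetics_integrals(b, t0, t1)
            for idx in range(3):
                num = quad(
                    lambda t: phantom.bolus_kinetics(b, np.array([t]))[idx][0],
                    t0, t1, limit=300,
                )[0]
                assert closed[idx] == pytest.approx(num, rel=1e-6, abs=1e-12)

    def test_first_pass_end_after_lv_peak(self):
        cfg = PhantomConfig()
        t_end = phantom.first_pass_end_true(cfg)
        t = np.arange(0, 120, 0.05)
        _, lv, _ = phantom.bolus_kinetics(cfg, t)
        assert t_end > t[np.argmax(lv)]
        # first-pass LV washout down to the configured fraction of peak
        lv_at_end = phantom.bolus_kinetics(cfg, np.array([t_end]))[1][0]
        assert lv_at_end == pytest.approx(cfg.bolus.first_pass_frac * lv.max(), rel=1e-4)

    def test_dispersion_must_exceed_bolus_scale(self):
        with pytest.raises(ValueError):
            BolusConfig(gamma_scale_s=3.0, dispersion_s=2.0)


class TestRender:
    def test_deterministic_given_seed(self, small_config):
        cfg = small_config.model_copy(update={"poisson_noise": True, "rng_seed": 7})
        d1, g1, _ = phantom.render(cfg)
        d2, g2, _ = phantom.render(cfg)
        assert np.array_equal(g1.intensities, g2.intensities)
        assert np.array_equal(d1.data, d2.data)

    def test_ground_truth_function_identities(self, small_run):
        for fn, vols in [
            (small_run.truth.lv, small_run.truth.lv_volumes_ml),
            (small_run.truth.rv, small_run.truth.rv_volumes_ml),
        ]:
            assert fn.edv_ml == vols.max()
            assert fn.esv_ml == vols.min()
            assert fn.sv_ml == fn.edv_ml - fn.esv_ml
            assert fn.ef == (fn.edv_ml - fn.esv_ml) / fn.edv_ml

    def test_rendered_masks_realize_ground_truth_volumes(self, small_run):
        vv = small_run.config.voxel_volume_ml
        assert np.array_equal(
            small_run.truth.lv_masks.sum(axis=(1, 2, 3)) * vv,
            small_run.truth.lv_volumes_ml,
        )
        # and the discretized volumes track the analytic gate curve closely
        analytic, _ = phantom.chamber_volume_curve(
            small_run.config.lv_edv_ml,
            small_run.config.lv_ef_frac,
            small_run.config.n_gates,
            small_run.config.cycle_ms,
        )
        assert np.allclose(small_run.truth.lv_volumes_ml, analytic, rtol=0.05)

    def test_frame_counts_conserve_kinetics(self):
        """Noiseless, PSF-free frame totals equal the kinetic time integrals
        (checked against adaptive quadrature of the pointwise curves)."""
        cfg = PhantomConfig(
            grid_shape=(32, 32, 24), voxel_size_mm=6.54,
            psf_fwhm_mm=0.0, poisson_noise=False,
        )
        dyn, _, truth = phantom.render(cfg)
        n = {k: int(m.sum()) for k, m in truth.dyn_masks.items()}
        for f in (0, 3, 6, 17, 23):
            a, d = dyn.start_s[f], dyn.duration_s[f]
            expected = truth.dynamic_count_scale * sum(
                n[k]
                * quad(
                    lambda t: phantom.bolus_kinetics(cfg, np.array([t]))[i][0],
                    a, a + d, limit=300,
                )[0]
                for i, k in enumerate(("rv", "lv", "myo"))
            )
            got = dyn.data[f].sum()
            if expected == 0:
                assert got == 0
            else:
                assert got == pytest.approx(expected, rel=1e-6)

    def test_poisson_sampling_is_unbiased(self):
        """Across seeds the per-voxel sample mean stays within 3 standard
        errors of the noiseless expectation (downsampled grid)."""
        base = PhantomConfig(
            grid_shape=(24, 24, 16), voxel_size_mm=8.72,
            poisson_noise=False, total_prompts=5e5,
        )
        _, clean, _ = phantom.render(base)
        n_rep = 20
        acc = np.zeros_like(clean.intensities)
        for s in range(n_rep):
            _, noisy, _ = phantom.render(
                base.model_copy(update={"poisson_noise": True, "rng_seed": 500 + s})
            )
            acc += noisy.intensities
        mean = acc / n_rep
        sel = clean.intensities > 0
        se = np.sqrt(clean.intensities[sel] / n_rep)
        within = np.abs(mean[sel] - clean.intensities[sel]) <= 3 * se
        assert within.mean() > 0.985  # ~99.7% expected for Gaussian-ish counts

    def test_geometry_overflow_names_chamber(self):
        with pytest.raises(ValueError, match="RV"):
            phantom.render(PhantomConfig(rv_edv_ml=2000.0, grid_shape=(32, 32, 24),
                                         voxel_size_mm=6.54))

    def test_total_gated_counts_match_prompts(self, small_config):
        _, gated, _ = phantom.render(small_config)
        assert gated.intensities.sum() == pytest.approx(
            small_config.total_prompts, rel=1e-9
        )
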