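"""Profile construction, smoothing-spline limits, extrema and borders."""

import numpy as np
import pandas as pd
import pytest

from stripeflow import quantify, synth
from stripeflow.quantify import EmbryoAxis, ExpressionProfile


class TestRegisterTime:
    def test_shift_by_event_time(self):
        reg = quantify.register_time([10, 13, 16], 10)
        assert np.allclose(reg.times, [0, 3, 6])

    def test_uncertainty_flag_carried(self):
        reg = quantify.register_time([10, 13], 10)
        assert reg.uncertainty_min == 0.5

    def test_non_monotone_rejected(self):
        with pytest.raises(ValueError):
            quantify.register_time([10, 9, 16], 10)

    def test_missing_t0_rejected(self):
        with pytest.raises(ValueError):
            quantify.register_time([10, 13], None)


class TestEdgeProfile:
    AXIS = EmbryoAxis(anterior=(26.0, 256.0), posterior=(486.0, 256.0))

    def _nuclei(self, pts, fluo=None):
        fluo = fluo if fluo is not None else np.ones(len(pts))
        return pd.DataFrame({"x_px": [p[0] for p in pts],
                             "y_px": [p[1] for p in pts],
                             "mean_fluo": fluo})

    def test_pole_calibration(self):
        nuc = self._nuclei([(26.0, 300.0), (486.0, 300.0), (256.0, 300.0)])
        with pytest.warns(UserWarning):
            prof = quantify.extract_edge_profile(nuc, "ventral", self.AXIS)
        assert prof.x[0] == pytest.approx(0.0)
        assert prof.x[-1] == pytest.approx(100.0)

    def test_ventral_dorsal_split(self):
        # dorsal is up: smaller row index
        nuc = self._nuclei([(100.0, 100.0), (100.0, 400.0)])
        with pytest.warns(UserWarning):
            dors = quantify.extract_edge_profile(nuc, "dorsal", self.AXIS)
        with pytest.warns(UserWarning):
            vent = quantify.extract_edge_profile(nuc, "ventral", self.AXIS)
        assert len(dors.x) == 1 and len(vent.x) == 1

    def test_matches_generator_truth(self):
        params = synth.stripe_model_params("WT", sigma_n=0.0)
        scene = synth.SceneSpec(seed=1)
        series, truth = synth.generate_embryo_series(params, scene,
                                                     times=np.array([36.0]))
        nuc = truth.nuclei.rename(columns={"true_value": "mean_fluo"})
        axis = EmbryoAxis(series.anterior_px, series.posterior_px)
        prof = quantify.extract_edge_profile(nuc, "ventral", axis)
        # ventral nuclei AP positions agree with the generator's projection
        vent = nuc[nuc["y_px"] >= series.anterior_px[1]]
        assert len(prof.x) == len(vent)
        assert np.allclose(np.sort(prof.x), np.sort(vent["ap_percent_el"]),
                           atol=1e-6)


class TestSplineLimits:
    def _noisy(self, seed=0):
        rng = np.random.default_rng(seed)
        x = np.linspace(0, 100, 101)
        y = np.sin(x / 7.0) + rng.normal(0, 0.2, size=x.size)
        return x, y

    def test_p1_interpolates(self):
        x, y = self._noisy()
        fit = quantify.fit_smoothing_spline((x, y), p=1.0)
        assert np.max(np.abs(fit.residuals)) < 1e-8

    def test_p0_is_least_squares_line(self):
        x, y = self._noisy()
        fit = quantify.fit_smoothing_spline((x, y), p=0.0)
        coef = np.polyfit(x, y, 1)
        xx = np.linspace(0, 100, 57)
        assert np.allclose(fit(xx), np.polyval(coef, xx), atol=1e-8)
        assert quantify.detect_extrema(fit) == []

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            quantify.fit_smoothing_spline(self._noisy(), p=1.5)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            quantify.fit_smoothing_spline(([1, 2, 3], [1, 2, 3]), p=0.5)

    def test_duplicate_x_averaged(self):
        x = np.array([0.0, 0.0, 1.0, 2.0, 3.0, 4.0])
        y = np.array([0.0, 2.0, 1.0, 1.0, 1.0, 1.0])
        fit = quantify.fit_smoothing_spline((x, y), p=1.0)
        assert fit(0.0) == pytest.approx(1.0, abs=1e-8)


class TestExtremaAndBorders:
    def test_monotone_data_no_extrema(self):
        x = np.linspace(0, 10, 30)
        fit = quantify.fit_smoothing_spline((x, x ** 2), p=0.5)
        assert quantify.detect_extrema(fit) == []

    def test_single_bump_one_maximum(self):
        x = np.linspace(0, 10, 60)
        y = np.exp(-0.5 * ((x - 5) / 1.2) ** 2)
        fit = quantify.fit_smoothing_spline((x, y), p=0.5)
        ext = quantify.detect_extrema(fit)
        assert [e.kind for e in ext] == ["max"]
        assert ext[0].position == pytest.approx(5.0, abs=0.05)

    def test_extrema_alternate(self, wt_params):
        prof = synth.generate_profile(wt_params, 42.0, seed=5)
        fit = quantify.fit_smoothing_spline(prof, p=0.5)
        ext = quantify.detect_extrema(fit)
        kinds = [e.kind for e in ext]
        assert all(a != b for a, b in zip(kinds, kinds[1:]))

    def test_extrema_match_dense_grid_oracle(self, wt_params):
        """Exact-root extrema agree with brute-force sign changes of f' on a
        10^4-point grid."""
        prof = synth.generate_profile(wt_params, 36.0, seed=9)
        fit = quantify.fit_smoothing_spline(prof, p=0.5)
        ext = quantify.detect_extrema(fit)
        lo, hi = fit.domain
        gx = np.linspace(lo, hi, 10_001)
        d = fit.derivative(gx)
        flips = np.where(np.sign(d[:-1]) * np.sign(d[1:]) < 0)[0]
        grid_pos = gx[flips]
        assert len(ext) == len(grid_pos)
        for e, g in zip(ext, grid_pos):
            assert abs(e.position - g) <= (hi - lo) / 10_000 + 1e-9

    def test_border_is_midlevel_crossing(self, wt_params):
        prof = synth.generate_profile(wt_params, 42.0, seed=3)
        fit = quantify.fit_smoothing_spline(prof, p=0.5)
        feats = quantify.stripe_features(quantify.detect_extrema(fit), fit,
                                         min_prominence=0.05)
        checked = 0
        for s in (2, 3):
            for side in ("A", "P"):
                b = feats.border(s, side)
                if b is None:
                    continue
                assert fit(b.position) == pytest.approx(
                    0.5 * (b.min_value + b.max_value), abs=1e-6)
                assert b.height == pytest.approx(b.max_value - b.min_value)
                assert b.height >= 0
                checked += 1
        assert checked >= 3

    def test_border_unique_crossing(self, wt_params):
        """f is strictly monotone between consecutive extrema, so the
        mid-level crossing is unique (checked on a dense grid)."""
        prof = synth.generate_profile(wt_params, 42.0, seed=4)
        fit = quantify.fit_smoothing_spline(prof, p=0.5)
        ext = quantify.detect_extrema(fit)
        for a, b in zip(ext, ext[1:]):
            level = 0.5 * (a.value + b.value)
            gx = np.linspace(a.position, b.position, 2000)[1:-1]
            crossings = np.sum(np.diff(np.sign(fit(gx) - level)) != 0)
            assert crossings == 1

    def test_non_alternating_extrema_rejected(self, wt_params):
        prof = synth.generate_profile(wt_params, 42.0, seed=3)
        fit = quantify.fit_smoothing_spline(prof, p=0.5)
        bad = [quantify.Extremum(10.0, 0.1, "min"),
               quantify.Extremum(12.0, 0.2, "min")]
        with pytest.raises(ValueError):
            quantify.stripe_features(bad, fit)

    def test_noiseless_profile_recovers_stripe_centers(self):
        """p=0.5 on a noiseless seven-stripe profile: peak positions within
        0.5% EL of the dense-grid extrema of the generative model."""
        params = synth.stripe_model_params("WT", sigma_n=0.0)
        prof = synth.generate_profile(params, 48.0, seed=0)
        fit = quantify.fit_smoothing_spline(prof, p=0.5)
        feats = quantify.stripe_features(quantify.detect_extrema(fit), fit,
                                         min_prominence=0.05)
        gx = np.linspace(0, 100, 10_001)
        gy = synth.model_intensity(params, gx, 48.0)
        for s in range(1, 8):
            peak = feats.peak(s)
            assert peak is not None
            m = np.abs(gx - params.mu[s - 1]) < 3
            true_pos = gx[m][np.argmax(gy[m])]
            assert abs(peak[0] - true_pos) <= 0.5


class TestNormalization:
    def test_divides_by_reference_peak(self, wt_params):
        params = synth.stripe_model_params("WT", sigma_n=0.0)
        prof = synth.generate_profile(params, 48.0, seed=0)
        normed = quantify.normalize_profile(prof, reference=1)
        fit = quantify.fit_smoothing_spline(normed, p=0.5)
        feats = quantify.stripe_features(quantify.detect_extrema(fit), fit,
                                         min_prominence=0.05)
        assert feats.peak(1)[1] == pytest.approx(1.0, abs=0.01)

    def test_idempotent(self):
        params = synth.stripe_model_params("WT", sigma_n=0.0)
        prof = synth.generate_profile(params, 48.0, seed=0)
        once = quantify.normalize_profile(prof, reference=1)
        twice = quantify.normalize_profile(once, reference=1)
        assert np.allclose(once.y, twice.y, rtol=1e-6)

    def test_reference_quotient_identity(self):
        """Normalizing by stripe 3 vs stripe 1 differs exactly by the ratio
        of the two reference peaks."""
        params = synth.stripe_model_params("WT", sigma_n=0.0)
        prof = synth.generate_profile(params, 48.0, seed=0)
        fit = quantify.fit_smoothing_spline(prof, p=0.5)
        feats = quantify.stripe_features(quantify.detect_extrema(fit), fit,
                                         min_prominence=0.05)
        n1 = quantify.normalize_profile(prof, reference=1, features=feats)
        n3 = quantify.normalize_profile(prof, reference=3, features=feats)
        ratio = feats.peak(1)[1] / feats.peak(3)[1]
        assert np.allclose(n3.y / np.where(n1.y == 0, 1, n1.y),
                           np.where(n1.y == 0, 1, ratio), rtol=1e-9)

    def test_missing_reference_peak_is_error(self):
        x = np.linspace(0, 100, 50)
        prof = ExpressionProfile(x=x, y=np.full_like(x, 0.5) + 0.001 * x)
        with pytest.raises(ValueError):
            quantify.normalize_profile(prof, reference=2)


class TestStripeTracking:
    def test_identities_stable_across_time(self, wt_params):
        times = np.arange(21.0, 49.0, 3.0)
        profs = [synth.generate_profile(wt_params, t, seed=100 + i)
                 for i, t in enumerate(times)]
        feats = []
        for prof in profs:
            scaled = ExpressionProfile(x=prof.x, y=prof.y / prof.y.max(),
                                       t_min=prof.t_min)
            fit = quantify.fit_smoothing_spline(scaled, p=0.5)
            feats.append(quantify.stripe_features(
                quantify.detect_extrema(fit), fit, min_prominence=0.06,
                t_min=prof.t_min))
        quantify.track_stripes(feats)
        # at mature timepoints all seven stripes are identified near their centers
        for f in feats[-3:]:
            for s in range(1, 8):
                peak = f.peak(s)
                assert peak is not None
                assert abs(peak[0] - wt_params.mu[s - 1]) < 3.5
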