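"""Stripe-2 phenotypes, initiation timing, cohort statistics."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from stripeflow import phenotype, quantify, synth
from stripeflow.quantify import Border, Extremum, StripeFeatures


def make_features(peak1=None, peak2=None, b2a=None, b2p=None):
    """Hand-built StripeFeatures with stripe-1/2 peaks and stripe-2 borders."""
    maxima, ids, ant, post = [], [], [], []
    if peak1 is not None:
        maxima.append(Extremum(31.0, peak1, "max"))
        ids.append(1)
        ant.append(None)
        post.append(None)
    if peak2 is not None:
        maxima.append(Extremum(40.0, peak2, "max"))
        ids.append(2)
        ant.append(Border(38.0, b2a, peak2 - b2a, peak2) if b2a is not None else None)
        post.append(Border(42.0, b2p, peak2 - b2p, peak2) if b2p is not None else None)
    return StripeFeatures(extrema=[], maxima=maxima, stripe_ids=ids,
                          anterior_borders=ant, posterior_borders=post)


def presence_frame(times, anterior, posterior):
    return pd.DataFrame({"t_min": times, "anterior": anterior,
                         "posterior": posterior})


class TestRatios:
    def test_relative_activation_half(self):
        f = make_features(peak1=1.0, peak2=0.5)
        assert phenotype.relative_activation(f) == pytest.approx(0.5)

    def test_equal_peaks_unity(self):
        f = make_features(peak1=0.8, peak2=0.8)
        assert phenotype.relative_activation(f) == pytest.approx(1.0)

    def test_missing_peak_undefined(self):
        assert phenotype.relative_activation(make_features(peak1=1.0)) is None

    def test_symmetric_borders_unity(self):
        f = make_features(peak1=1.0, peak2=0.9, b2a=0.4, b2p=0.4)
        ratio, excluded = phenotype.relative_repression(f)
        assert ratio == pytest.approx(1.0)
        assert not excluded

    def test_half_repression(self):
        f = make_features(peak1=1.0, peak2=0.9, b2a=0.2, b2p=0.4)
        assert phenotype.relative_repression(f)[0] == pytest.approx(0.5)

    def test_large_ratio_flagged_but_returned(self):
        f = make_features(peak1=1.0, peak2=6.5, b2a=6.0, b2p=0.1)
        ratio, excluded = phenotype.relative_repression(f)
        assert ratio == pytest.approx(60.0)
        assert excluded

    def test_zero_posterior_height_infinite_flagged(self):
        f = make_features(peak1=1.0, peak2=0.9, b2a=0.3, b2p=0.0)
        ratio, excluded = phenotype.relative_repression(f)
        assert np.isinf(ratio) and excluded


class TestIncipientStripe:
    T = np.arange(30.0, 49.0, 3.0)

    def test_both_minima_from_start(self):
        p = presence_frame(self.T, [True] * 7, [True] * 7)
        assert phenotype.detect_incipient_stripe(p) == 30.0

    def test_one_missing_timepoint_tolerated(self):
        ant = [False, True, False, True, True, True, True]
        post = [False, True, True, True, True, True, True]
        p = presence_frame(self.T, ant, post)
        assert phenotype.detect_incipient_stripe(p) == 33.0

    def test_two_missing_timepoints_not_tolerated(self):
        ant = [True, False, False, True, True, True, True]
        p = presence_frame(self.T, ant, [True] * 7)
        assert phenotype.detect_incipient_stripe(p) == 39.0

    def test_never_detected_is_undefined(self):
        p = presence_frame(self.T, [False] * 7, [True] * 7)
        assert phenotype.detect_incipient_stripe(p) is None

    def test_too_few_timepoints_rejected(self):
        p = presence_frame([30.0, 33.0], [True, True], [True, True])
        with pytest.raises(ValueError):
            phenotype.detect_incipient_stripe(p)


class TestBorderOrder:
    T = np.arange(24.0, 49.0, 3.0)

    def _presence(self, t_ant, t_post):
        ant = [t >= t_ant for t in self.T]
        post = [t >= t_post for t in self.T]
        return presence_frame(self.T, ant, post)

    def test_posterior_first(self):
        assert phenotype.classify_border_order(self._presence(27.0, 24.0)) == \
            "posterior_first"

    def test_anterior_first(self):
        assert phenotype.classify_border_order(self._presence(27.0, 30.0)) == \
            "anterior_first"

    def test_same_frame_unresolved(self):
        assert phenotype.classify_border_order(self._presence(30.0, 30.0)) == \
            "unresolved"

    def test_transient_blip_does_not_count(self):
        # anterior flickers on at 24 only; stable from 33
        ant = [True, False, False, True, True, True, True, True, True]
        post = [True] * 9
        p = presence_frame(self.T, ant, post)
        assert phenotype.classify_border_order(p) == "posterior_first"

    def test_pipeline_accuracy_on_separated_onsets(self, wt_params):
        """Classification matches generator order for onsets two frames
        apart; exactly simultaneous onsets stay unresolved."""
        times = np.arange(21.0, 49.0, 3.0)
        correct = 0
        n = 20
        rng = np.random.default_rng(5)
        for i in range(n):
            z = float(rng.normal())
            t12, t23 = (24.5, 31.0) if i % 2 == 0 else (31.0, 24.5)
            want = "anterior_first" if t12 < t23 else "posterior_first"
            profs = [synth.generate_profile(wt_params, t, seed=900 * i + j,
                                            z=z, t_on12=t12, t_on23=t23)
                     for j, t in enumerate(times)]
            ps = phenotype.phenotype_series(profs)
            correct += ps.border_order == want
        assert correct / n >= 0.95


class TestPositionalVariation:
    def test_identical_positions_zero_sd(self):
        df = pd.DataFrame({"t_min": [30.0] * 5, "peak2_pos": [40.0] * 5})
        out = phenotype.positional_variation(df, "peak2_pos")
        assert out["sd"].iloc[0] == pytest.approx(0.0)

    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(40, 2, size=50)
        df = pd.DataFrame({"t_min": 30.0, "peak2_pos": vals})
        out = phenotype.positional_variation(df, "peak2_pos")
        direct = np.sqrt(((vals - vals.mean()) ** 2).sum() / (len(vals) - 1))
        assert out["sd"].iloc[0] == pytest.approx(direct, rel=1e-12)

    def test_single_embryo_cell_undefined(self):
        df = pd.DataFrame({"t_min": [30.0, 33.0, 33.0],
                           "peak2_pos": [40.0, 40.5, 41.0]})
        out = phenotype.positional_variation(df, "peak2_pos")
        assert np.isnan(out.loc[out["t_min"] == 30.0, "sd"].iloc[0])
        assert out.loc[out["t_min"] == 33.0, "n"].iloc[0] == 2

    def test_unknown_trait_rejected(self):
        with pytest.raises(ValueError):
            phenotype.positional_variation(pd.DataFrame({"t_min": []}), "nope")


class TestRankSum:
    def test_identical_samples_p_one(self):
        assert phenotype.compare_groups([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_most_extreme_small_samples(self):
        # only 2 of the C(6,3)=20 rank assignments are this extreme
        assert phenotype.compare_groups([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            phenotype.compare_groups([], [1.0])

    def test_exact_matches_enumeration_with_ties(self):
        """All sample-size pairs with n_total <= 10, tied data included."""
        rng = np.random.default_rng(0)
        for n1 in range(1, 6):
            for n2 in range(n1, 11 - n1):
                vals = np.round(rng.normal(size=n1 + n2), 1)
                a, b = vals[:n1], vals[n1:]
                ranks = stats.rankdata(vals)
                n = n1 + n2
                wobs = ranks[:n1].sum()
                mean = n1 * (n + 1) / 2
                cnt = tot = 0
                for idx in combinations(range(n), n1):
                    w = ranks[list(idx)].sum()
                    tot += 1
                    cnt += abs(w - mean) >= abs(wobs - mean) - 1e-9
                assert phenotype.compare_groups(a, b) == pytest.approx(
                    cnt / tot, abs=1e-12)

    def test_matches_scipy_exact_without_ties(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            a = rng.normal(size=rng.integers(2, 8))
            b = rng.normal(size=rng.integers(2, 8))
            ref = stats.mannwhitneyu(a, b, alternative="two-sided",
                                     method="exact").pvalue
            assert phenotype.compare_groups(a, b) == pytest.approx(ref, abs=1e-12)

    def test_large_sample_normal_approximation(self):
        rng = np.random.default_rng(2)
        a = rng.normal(0, 1, 40)
        b = rng.normal(0.8, 1, 40)
        ref = stats.mannwhitneyu(a, b, alternative="two-sided",
                                 method="asymptotic", use_continuity=False).pvalue
        assert phenotype.compare_groups(a, b) == pytest.approx(ref, rel=1e-9)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.integers(0, 5), min_size=2, max_size=6),
           st.lists(st.integers(0, 5), min_size=2, max_size=6))
    def test_symmetry(self, a, b):
        assert phenotype.compare_groups(a, b) == pytest.approx(
            phenotype.compare_groups(b, a), abs=1e-12)


class TestTimeScaling:
    def test_equal_landmarks_identity(self):
        assert phenotype.scale_developmental_time(30.0, 38.2, 38.2) == 30.0

    def test_default_landmarks(self):
        assert phenotype.scale_developmental_time(30.0) == pytest.approx(
            30.0 * 38.2 / 30.6)

    def test_linearity(self):
        assert phenotype.scale_developmental_time(20.0) * 2 == pytest.approx(
            phenotype.scale_developmental_time(40.0))

    def test_nonpositive_landmark_rejected(self):
        with pytest.raises(ValueError):
            phenotype.scale_developmental_time(30.0, 38.2, 0.0)


class TestChannelConcordance:
    def _table(self, x, y):
        return pd.DataFrame({"embryo_id": "e1", "channel_a": x, "channel_b": y})

    def test_identity_and_proportionality(self):
        x = np.linspace(0.1, 1, 200)
        assert phenotype.channel_concordance(self._table(x, x))["r_squared"][0] \
            == pytest.approx(1.0)
        assert phenotype.channel_concordance(self._table(x, 2 * x))["r_squared"][0] \
            == pytest.approx(1.0)

    def test_analytic_r2_under_additive_noise(self):
        rng = np.random.default_rng(0)
        n = 10_000
        x = rng.uniform(0, 1, n)
        sigma = 0.2
        y = x + rng.normal(0, sigma, n)
        vx = 1 / 12  # variance of U(0,1)
        expected = vx / (vx + sigma ** 2)
        r2 = phenotype.channel_concordance(self._table(x, y))["r_squared"][0]
        assert r2 == pytest.approx(expected, abs=0.02)

    def test_constant_channel_undefined(self):
        x = np.linspace(0, 1, 50)
        out = phenotype.channel_concordance(self._table(x, np.ones(50)))
        assert np.isnan(out["r_squared"][0])


class TestCohortSummary:
    def test_counts_and_comparisons(self, wt_params):
        coh_w = synth.generate_cohort(wt_params, 4, seed=1,
                                      times=np.arange(30.0, 49.0, 3.0))
        pm = synth.stripe_model_params("MSE")
        coh_m = synth.generate_cohort(pm, 4, seed=2,
                                      times=np.arange(30.0, 49.0, 3.0))
        series = [phenotype.phenotype_series(e.profiles,
                                             embryo_id=e.realization.embryo_id,
                                             genotype=g)
                  for g, coh in (("WT", coh_w), ("MSE", coh_m))
                  for e in coh.embryos]
        summary = phenotype.cohort_summary(series)
        assert set(summary["genotype"]) == {"WT", "MSE"}
        assert (summary["n"] <= 4).all()
        comps = summary.attrs["comparisons"]
        assert ((comps["group_a"] == "MSE") & (comps["group_b"] == "WT")).any()
        assert comps["p_value"].between(0, 1).all()
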