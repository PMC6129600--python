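"""Arch-height linear model, cut-off schemes, quartile derivation, OLS fit."""

import numpy as np
import pytest
import statsmodels.api as sm
from hypothesis import given, settings, strategies as st

from archmorph import (
    AhiCoefficients,
    CutoffScheme,
    FootprintError,
    FootprintParams,
    ahi_score,
    classify_ahi,
    derive_quartile_cutoffs,
    fit_ahi_model,
    generate_footprint,
)
from archmorph.estimators import FootprintFeaturizer, QuartileCutoffClassifier


class TestScore:
    def test_intercept_at_zero_predictors(self):
        assert ahi_score(0.0, 0.0) == pytest.approx(0.4597)

    def test_direct_evaluation(self):
        # 0.4597 - 7.351e-5*1000 - 1050.964*1.2e-4
        assert ahi_score(1000.0, 1.2e-4) == pytest.approx(0.26007, abs=5e-6)

    def test_strictly_decreasing_in_both_predictors(self):
        base = ahi_score(700.0, 2e-4)
        assert ahi_score(701.0, 2e-4) < base
        assert ahi_score(700.0, 2.1e-4) < base

    def test_negative_inputs_rejected(self):
        with pytest.raises(FootprintError):
            ahi_score(-1.0, 0.0)


class TestClassify:
    @pytest.mark.parametrize(
        "score,label",
        [(0.23, "high"), (0.28, "low"), (0.27, "low"), (0.25, "normal")],
    )
    def test_mbe_p_cutoffs_boundary_inclusive(self, score, label):
        assert classify_ahi(score).label == label

    def test_dense_grid_partition(self):
        """Scores below/within/above (0.23, 0.27) map to high/normal/low."""
        for s in np.linspace(0.0, 0.5, 501):
            label = classify_ahi(float(s)).label
            if s <= 0.23:
                assert label == "high"
            elif s >= 0.27:
                assert label == "low"
            else:
                assert label == "normal"

    def test_invalid_scheme_ordering_rejected(self):
        with pytest.raises(FootprintError):
            CutoffScheme(high_max=0.3, low_min=0.2)


class TestQuartileCutoffs:
    def test_linear_interpolation_rule_on_1_to_8(self):
        cuts = derive_quartile_cutoffs(np.arange(1.0, 9.0))
        assert cuts.high_max == pytest.approx(2.75)
        assert cuts.low_min == pytest.approx(6.25)

    def test_normal_sample_reproduces_published_regime(self):
        """Q1/Q3 of Normal(0.25, 0.025) sit at mu -/+ 0.6745 sigma, i.e.
        0.2331 / 0.2669, reported as 0.23 / 0.27."""
        rng = np.random.default_rng(12345)
        cuts = derive_quartile_cutoffs(rng.normal(0.25, 0.025, 10000))
        assert cuts.high_max == pytest.approx(0.2331, abs=0.005)
        assert cuts.low_min == pytest.approx(0.2669, abs=0.005)
        assert (round(cuts.high_max, 2), round(cuts.low_min, 2)) == (0.23, 0.27)

    def test_degenerate_constant_scores_rejected(self):
        with pytest.raises(FootprintError):
            derive_quartile_cutoffs(np.full(10, 0.25))
        with pytest.raises(FootprintError):
            derive_quartile_cutoffs([0.2, 0.3])

    @settings(deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(-1e3, 1e3), min_size=4, max_size=40, unique=True),
        st.floats(0.1, 5.0),
        st.floats(-10.0, 10.0),
    )
    def test_monotone_equivariance_under_affine_maps(self, scores, a, b):
        base = derive_quartile_cutoffs(scores)
        mapped = derive_quartile_cutoffs([a * s + b for s in scores])
        assert mapped.high_max == pytest.approx(a * base.high_max + b, abs=1e-6 + 1e-6 * abs(b))
        assert mapped.low_min == pytest.approx(a * base.low_min + b, abs=1e-6 + 1e-6 * abs(b))


class TestOlsCalibration:
    def test_exact_targets_recover_coefficients(self):
        rng = np.random.default_rng(3)
        X = np.column_stack([rng.uniform(500, 900, 50), rng.uniform(1e-4, 5e-4, 50)])
        true = AhiCoefficients()
        y = true.beta_p * X[:, 0] + true.beta_mbe * X[:, 1] + true.intercept
        fit = fit_ahi_model(X, y)
        assert fit.beta_p == pytest.approx(true.beta_p, abs=1e-8)
        assert fit.beta_mbe == pytest.approx(true.beta_mbe, abs=1e-8)
        assert fit.intercept == pytest.approx(true.intercept, abs=1e-8)

    def test_noisy_targets_recover_within_three_standard_errors(self):
        rng = np.random.default_rng(7)
        n = 200
        X = np.column_stack([rng.uniform(500, 900, n), rng.uniform(1e-4, 5e-4, n)])
        true = AhiCoefficients()
        y = true.beta_p * X[:, 0] + true.beta_mbe * X[:, 1] + true.intercept
        y = y + rng.normal(0, 0.01, n)
        fit = fit_ahi_model(X, y)
        se = sm.OLS(y, sm.add_constant(X)).fit().bse  # (const, P, MBE)
        assert abs(fit.intercept - true.intercept) < 3 * se[0]
        assert abs(fit.beta_p - true.beta_p) < 3 * se[1]
        assert abs(fit.beta_mbe - true.beta_mbe) < 3 * se[2]

    def test_collinear_design_rejected(self):
        X = np.column_stack([np.arange(10.0), 2.0 * np.arange(10.0)])
        with pytest.raises(FootprintError, match="collinear|rank"):
            fit_ahi_model(X, np.arange(10.0))


class TestEndToEndLabelRecovery:
    def test_quartile_labels_separate_arch_depth_strata(self):
        """Quartile cut-offs derived from a 60-print batch put more deep-arch
        prints in 'high' and more flat prints in 'low' than vice versa."""
        rng = np.random.default_rng(42)
        feats = FootprintFeaturizer(compute_gabor=False, compute_arch_index=False)
        scores, depths = [], []
        for depth in (0.1, 0.5, 0.9):
            for _ in range(20):
                p = FootprintParams(
                    length_mm=float(rng.uniform(165, 195)),
                    width_mm=float(rng.uniform(80, 100)),
                    arch_depth=depth,
                    boundary_noise_px=0.5,
                    seed=int(rng.integers(2**31 - 1)),
                )
                fp = generate_footprint(p)
                t = feats.fit([fp]).transform([fp]).iloc[0]
                scores.append(ahi_score(t.perimeter_px, t.mbe))
                depths.append(depth)
        scores, depths = np.asarray(scores), np.asarray(depths)
        labels = QuartileCutoffClassifier().fit(scores).predict(scores)
        n_high = {d: int(((labels == "high") & (depths == d)).sum()) for d in (0.1, 0.9)}
        n_low = {d: int(((labels == "low") & (depths == d)).sum()) for d in (0.1, 0.9)}
        assert n_high[0.9] > n_high[0.1]
        assert n_low[0.1] > n_low[0.9]
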