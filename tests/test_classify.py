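"""Prediction-band fitting, bootstrap classification, polygons and consensus."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mitovar import (
    PredictionBand,
    PolygonAnnotation,
    fit_control_regression,
    classify_frequentist,
    classify_by_polygons,
    consensus_certainty,
    small_section_flags,
)


def _control_frame(x, y, protein="NDUFB8"):
    return pd.DataFrame({"vdac1": x, protein: y})


class TestPredictionBand:
    def test_noiseless_fit_recovers_line(self):
        x = np.linspace(1, 10, 20)
        band = fit_control_regression(_control_frame(x, 2 * x + 1), "NDUFB8")
        assert band.slope == pytest.approx(2.0)
        assert band.intercept == pytest.approx(1.0)
        assert band.residual_sd == pytest.approx(0.0, abs=1e-9)

    def test_ols_recovery_within_own_ci(self, rng):
        x = rng.uniform(0, 100, 200)
        y = 1.5 * x + 10 + rng.normal(0, 5, 200)
        band = fit_control_regression(_control_frame(x, y), "NDUFB8")
        # 99% CI on the slope from the fit's own standard error
        se = band.residual_sd / np.sqrt(band.x_ss)
        from scipy import stats
        t99 = stats.t.ppf(0.995, band.n_control - 2)
        assert abs(band.slope - 1.5) < t99 * se

    def test_band_coverage_matches_level(self, rng):
        """Fresh draws from the generating model fall inside the 95% band at
        the nominal rate."""
        x = rng.uniform(100, 1000, 200)
        y = 0.8 * x + 150 + rng.normal(0, 40, 200)
        band = fit_control_regression(_control_frame(x, y), "NDUFB8")
        m = 10_000
        xf = rng.uniform(100, 1000, m)
        yf = 0.8 * xf + 150 + rng.normal(0, 40, m)
        inside = ((yf >= band.lower(xf)) & (yf <= band.upper(xf))).mean()
        assert abs(inside - 0.95) < 3 * np.sqrt(0.95 * 0.05 / m)

    def test_band_ordering(self):
        x = np.linspace(0, 10, 50)
        band = PredictionBand.fit(x, 2 * x + np.sin(x))
        grid = np.linspace(-5, 15, 30)
        assert (band.lower(grid) < band.upper(grid)).all()

    def test_degenerate_predictor_raises(self):
        with pytest.raises(ValueError, match="degenerate|equal"):
            PredictionBand.fit(np.full(10, 5.0), np.arange(10.0))
        with pytest.raises(ValueError, match="at least 3"):
            PredictionBand.fit(np.array([1.0, 2.0]), np.array([1.0, 2.0]))


class TestClassifyFrequentist:
    @staticmethod
    def _controls(rng, n=200, resid_sd=5.0):
        x = rng.uniform(10, 100, n)
        y = 2.0 * x + 20 + rng.normal(0, resid_sd, n)
        return _control_frame(x, y)

    def test_far_outlier_is_certainly_deficient(self, rng):
        controls = self._controls(rng)
        band = fit_control_regression(controls, "NDUFB8")
        xbar = controls["vdac1"].mean()
        fibre = pd.DataFrame({
            "fibre_id": ["f0"], "vdac1": [xbar],
            "NDUFB8": [band.predict(xbar) - 10 * band.residual_sd],
        })
        out = classify_frequentist(fibre, controls, "NDUFB8", n_models=200, seed=1)
        assert out["mean_label"].iloc[0] == -1.0
        assert out["final_call"].iloc[0] == "deficient"

    def test_null_fibres_rarely_called_deficient(self, rng):
        """Fibres drawn from the control model itself: the one-sided band
        miss rate bounds the deficient-call rate below 2.5%."""
        controls = self._controls(rng, n=400)
        x = rng.uniform(10, 100, 2000)
        y = 2.0 * x + 20 + rng.normal(0, 5.0, 2000)
        fibres = pd.DataFrame({"fibre_id": [f"f{i}" for i in range(2000)],
                               "vdac1": x, "NDUFB8": y})
        out = classify_frequentist(fibres, controls, "NDUFB8", n_models=300, seed=2)
        assert (out["final_call"] == "deficient").mean() < 0.025

    def test_exact_recovery_of_shifted_proportion(self, rng):
        """100 fibres, 30 shifted down 10 residual SDs: the estimated
        deficient proportion is exactly 0.30 with certainty -1."""
        controls = self._controls(rng, n=200)
        x = rng.uniform(30, 80, 100)
        y = 2.0 * x + 20 + rng.normal(0, 5.0, 100)
        y[:30] -= 10 * 5.0
        fibres = pd.DataFrame({"fibre_id": [f"f{i}" for i in range(100)],
                               "vdac1": x, "NDUFB8": y})
        out = classify_frequentist(fibres, controls, "NDUFB8", n_models=1000, seed=3)
        deficient = out["final_call"] == "deficient"
        assert deficient.mean() == pytest.approx(0.30)
        assert np.all(out.loc[deficient, "mean_label"] == -1.0)

    def test_single_model_equals_plain_band_classification(self, rng):
        """A single bootstrap model with a fixed resample behaves like one
        deterministic band: labels agree with a direct band fit on that
        resample."""
        controls = self._controls(rng, n=50)
        x = rng.uniform(10, 100, 200)
        y = 2.0 * x + 20 + rng.normal(0, 25.0, 200)
        fibres = pd.DataFrame({"fibre_id": [f"f{i}" for i in range(200)],
                               "vdac1": x, "NDUFB8": y})
        seed = 42
        out = classify_frequentist(fibres, controls, "NDUFB8", n_models=1, seed=seed)
        # replay the single resample
        resample_rng = np.random.default_rng(seed)
        idx = resample_rng.integers(0, len(controls), size=(1, len(controls)))[0]
        band = PredictionBand.fit(controls["vdac1"].to_numpy()[idx],
                                  controls["NDUFB8"].to_numpy()[idx])
        expected = band.classify(x, y)
        assert np.array_equal(out["mean_label"].to_numpy(), expected.astype(float))

    def test_monotone_in_oxphos_signal(self, rng):
        """Lowering a fibre's OXPHOS value never raises its mean label."""
        controls = self._controls(rng)
        x = np.full(20, 50.0)
        y = np.linspace(160, 60, 20)  # decreasing OXPHOS at fixed VDAC1
        fibres = pd.DataFrame({"fibre_id": [f"f{i}" for i in range(20)],
                               "vdac1": x, "NDUFB8": y})
        out = classify_frequentist(fibres, controls, "NDUFB8", n_models=300, seed=5)
        ml = out["mean_label"].to_numpy()
        assert (np.diff(ml) <= 1e-12).all()

    def test_batch_specific_fits(self, rng):
        """Controls are fitted per staining batch: a fibre normal in its own
        batch is not judged against another batch's line."""
        xa = rng.uniform(10, 100, 200)
        xb = rng.uniform(10, 100, 200)
        controls = pd.DataFrame({
            "batch": ["A"] * 200 + ["B"] * 200,
            "vdac1": np.concatenate([xa, xb]),
            "NDUFB8": np.concatenate([2 * xa + 20 + rng.normal(0, 5, 200),
                                      0.5 * xb + 5 + rng.normal(0, 2, 200)]),
        })
        fibres = pd.DataFrame({
            "fibre_id": ["fa", "fb"], "batch": ["A", "B"], "vdac1": [50.0, 50.0],
            "NDUFB8": [120.0, 30.0],  # each on its own batch line
        })
        out = classify_frequentist(fibres, controls, "NDUFB8", n_models=200, seed=6)
        assert (out["final_call"] == "normal").all()

    def test_small_section_warning(self, rng):
        controls = self._controls(rng)
        fibres = pd.DataFrame({
            "fibre_id": ["f0", "f1"], "section": ["s1", "s1"],
            "vdac1": [50.0, 60.0], "NDUFB8": [120.0, 140.0],
        })
        with pytest.warns(UserWarning, match="fewer than 100"):
            classify_frequentist(fibres, controls, "NDUFB8", n_models=10, seed=0)
        assert small_section_flags(fibres) == ["s1"]


SQUARE = [(0.0, 0.0), (10.0, 0.0), (10.0, 10.0), (0.0, 10.0)]


class TestClassifyByPolygons:
    @staticmethod
    def _fibres(points):
        return pd.DataFrame({
            "fibre_id": [f"f{i}" for i in range(len(points))],
            "section": "s1",
            "vdac1": [p[0] for p in points],
            "NDUFB8": [p[1] for p in points],
        })

    @pytest.mark.parametrize("point,expected", [
        ((5.0, 5.0), -1),     # interior
        ((10.0, 5.0), -1),    # on the edge: boundary-inclusive
        ((0.0, 0.0), -1),     # vertex
        ((20.0, 20.0), 0),    # outside
    ])
    def test_low_polygon_membership(self, point, expected):
        ann = [PolygonAnnotation("I1", "NDUFB8", "s1", "low", SQUARE)]
        out = classify_by_polygons(self._fibres([point]), ann, "NDUFB8")
        assert out["label"].iloc[0] == expected

    def test_high_polygon_gives_plus_one(self):
        ann = [PolygonAnnotation("I1", "NDUFB8", "s1", "high", SQUARE)]
        out = classify_by_polygons(self._fibres([(5.0, 5.0)]), ann, "NDUFB8")
        assert out["label"].iloc[0] == 1

    def test_contradictory_annotation_raises(self):
        ann = [PolygonAnnotation("I1", "NDUFB8", "s1", "low", SQUARE),
               PolygonAnnotation("I1", "NDUFB8", "s1", "high", SQUARE)]
        with pytest.raises(ValueError, match="contradictory"):
            classify_by_polygons(self._fibres([(5.0, 5.0)]), ann, "NDUFB8")

    def test_malformed_polygon_raises(self):
        bowtie = [(0.0, 0.0), (10.0, 10.0), (10.0, 0.0), (0.0, 10.0)]
        ann = [PolygonAnnotation("I1", "NDUFB8", "s1", "low", bowtie)]
        with pytest.raises(ValueError, match="self-intersecting"):
            classify_by_polygons(self._fibres([(5.0, 5.0)]), ann, "NDUFB8")
        with pytest.raises(ValueError, match="3 vertices"):
            PolygonAnnotation("I1", "NDUFB8", "s1", "low", SQUARE[:2]).validate()

    def test_scope_restricts_to_section(self):
        fibres = pd.DataFrame({
            "fibre_id": ["f0", "f1"], "section": ["s1", "s2"],
            "vdac1": [5.0, 5.0], "NDUFB8": [5.0, 5.0],
        })
        ann = [PolygonAnnotation("I1", "NDUFB8", "s1", "low", SQUARE)]
        out = classify_by_polygons(fibres, ann, "NDUFB8")
        assert out["label"].tolist() == [-1, 0]


def _tables(label_sets):
    """Build one label table per investigator from per-investigator labels."""
    m = len(label_sets[0])
    return [
        pd.DataFrame({"fibre_id": [f"f{i}" for i in range(m)],
                      "protein": "NDUFB8", "label": labels})
        for labels in label_sets
    ]


class TestConsensusCertainty:
    def test_unanimous_deficient(self):
        out = consensus_certainty(_tables([[-1], [-1], [-1]]), n_resamples=500, seed=0)
        assert out["mean_label"].iloc[0] == -1.0
        assert out["final_call"].iloc[0] == "deficient"

    def test_two_of_three_expected_mean(self):
        """{-1,-1,0}: bootstrap mean converges to the plain mean -2/3 and the
        call stays normal."""
        out = consensus_certainty(_tables([[-1], [-1], [0]]), n_resamples=10_000, seed=1)
        assert out["mean_label"].iloc[0] == pytest.approx(-2 / 3, abs=0.02)
        assert out["final_call"].iloc[0] == "normal"

    def test_symmetric_labels_centre_on_zero(self):
        out = consensus_certainty(_tables([[-1], [0], [1]]), n_resamples=10_000, seed=2)
        assert out["mean_label"].iloc[0] == pytest.approx(0.0, abs=0.03)
        assert out["final_call"].iloc[0] == "normal"

    def test_label_resampling_mode_agrees_in_expectation(self):
        out = consensus_certainty(_tables([[-1], [-1], [0]]), n_resamples=10_000,
                                  seed=3, resample="labels")
        assert out["mean_label"].iloc[0] == pytest.approx(-2 / 3, abs=0.02)

    def test_mismatched_fibre_sets_raise(self):
        a, b = _tables([[-1, 0], [0, -1]])
        b = b.iloc[::-1].reset_index(drop=True)
        with pytest.raises(ValueError, match="different fibre sets"):
            consensus_certainty([a, b])

    @given(labels=st.lists(st.sampled_from([-1, 0, 1]), min_size=1, max_size=5))
    @settings(max_examples=30, deadline=None)
    def test_consensus_mean_matches_arithmetic_mean(self, labels):
        """The bootstrap mean converges to the plain mean of investigator
        labels, for any label multiset."""
        out = consensus_certainty(_tables([[l] for l in labels]),
                                  n_resamples=20_000, seed=4)
        assert out["mean_label"].iloc[0] == pytest.approx(np.mean(labels), abs=0.03)
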