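"""Growth metrics, Tukey separation, and the consecutive-detection criterion."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import canopymass as cm
from canopymass._studentized_range import studentized_range_sf
from canopymass.monitoring import (
    SeparationResult,
    detect_response,
    growth_metrics,
    growth_rate,
    moving_average,
    relative_growth_rate,
    response_time,
    separation_over_time,
    timepoints_to_days,
    tukey_pairwise,
)


class TestMovingAverage:
    def test_hand_substitution(self):
        assert np.allclose(moving_average([1, 2, 3, 4], 3), [2.0, 3.0])

    def test_constant_series(self):
        assert np.allclose(moving_average(np.full(6, 4.2), 3), np.full(4, 4.2))

    def test_window_one_is_identity(self):
        x = np.array([3.0, 1.0, 4.0])
        assert np.array_equal(moving_average(x, 1), x)

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            moving_average([1.0, 2.0], 3)


class TestGrowthRates:
    def test_gr_hand_substitution(self):
        assert np.allclose(growth_rate([2.0, 4.0]), [2.0])

    def test_constant_mass_zero_gr(self):
        assert np.allclose(growth_rate(np.full(5, 7.0)), 0.0)

    def test_linear_mass_constant_gr(self):
        t = np.arange(6)
        assert np.allclose(growth_rate(1.0 + 0.3 * t), 0.3)

    def test_nonpositive_dt_rejected(self):
        with pytest.raises(ValueError):
            growth_rate([1.0, 2.0], dt=0.0)

    def test_rgr_hand_substitution(self):
        # m goes 2 -> 4: GR = 2, RGR = GR / m_t = 0.5
        gr = growth_rate([2.0, 4.0])
        assert np.allclose(relative_growth_rate(gr, [2.0, 4.0]), [0.5])

    def test_rgr_of_exponential_matches_closed_form(self):
        """For m_t = m0 e^{rt} (no smoothing) the discrete estimator gives
        RGR = (1 - e^{-r dt}) / dt at every step; r=0.1, dt=1 -> 0.095163."""
        t = np.arange(20)
        m = 0.5 * np.exp(0.1 * t)
        rgr = relative_growth_rate(growth_rate(m), m)
        assert np.allclose(rgr, 1.0 - np.exp(-0.1))
        assert rgr[0] == pytest.approx(0.095163, abs=1e-6)

    def test_nonpositive_mass_rejected(self):
        with pytest.raises(ValueError):
            relative_growth_rate([1.0], [1.0, 0.0])

    def test_time_unit_equivariance(self):
        """Doubling dt halves both GR and RGR."""
        m = np.array([1.0, 1.5, 2.2, 3.1])
        gr1 = growth_rate(m, dt=1.0)
        gr2 = growth_rate(m, dt=2.0)
        assert np.allclose(gr2, gr1 / 2.0)
        assert np.allclose(
            relative_growth_rate(gr2, m), relative_growth_rate(gr1, m) / 2.0
        )

    def test_mass_rescaling(self):
        """RGR is scale-free; GR scales with mass units."""
        m = np.array([1.0, 1.4, 2.0, 2.9])
        c = 7.3
        assert np.allclose(growth_rate(c * m), c * growth_rate(m))
        assert np.allclose(
            relative_growth_rate(growth_rate(c * m), c * m),
            relative_growth_rate(growth_rate(m), m),
        )


class TestTukeyPairwise:
    def test_identical_groups_not_separated(self):
        g = {"a": np.array([1.0, 2.0, 3.0]), "b": np.array([1.0, 2.0, 3.0])}
        assert tukey_pairwise(g).loc["a", "b"] > 0.999

    def test_near_zero_variance_separation(self):
        g = {"a": np.zeros(5), "b": np.array([10.0, 10.0, 10.0, 10.0, 10.001])}
        assert tukey_pairwise(g).loc["a", "b"] < 0.001

    def test_degenerate_variance_equal_means(self):
        g = {"a": np.full(4, 2.0), "b": np.full(4, 2.0)}
        assert tukey_pairwise(g).loc["a", "b"] == 1.0

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            tukey_pairwise({"a": np.array([1.0]), "b": np.array([1.0, 2.0])})

    def test_matches_scipy_reference(self):
        """Dual route: the fast studentized-range evaluation must agree
        with scipy's adaptive-quadrature implementation."""
        rng = np.random.default_rng(3)
        x = [rng.normal(0, 1, 9), rng.normal(0.8, 1, 11), rng.normal(0.2, 1, 8)]
        mine = tukey_pairwise({"a": x[0], "b": x[1], "c": x[2]}).to_numpy()
        ref = stats.tukey_hsd(*x).pvalue
        assert np.abs(mine - ref).max() < 1e-9
        for k in (2, 4):
            for nu in (5, 30, 120):
                for q in (0.7, 2.2, 4.1):
                    assert studentized_range_sf(q, k, nu) == pytest.approx(
                        float(stats.studentized_range.sf(q, k, nu)), abs=1e-8
                    )

    def test_matches_permutation_reference(self):
        """Two-group Tukey reduces to an equal-variance two-sample test;
        a permutation test on |mean difference| must agree within 0.02."""
        rng = np.random.default_rng(11)

        def t_stat(x, n1):
            a, b = x[..., :n1], x[..., n1:]
            va = a.var(axis=-1, ddof=1)
            vb = b.var(axis=-1, ddof=1)
            n2 = x.shape[-1] - n1
            s2 = ((n1 - 1) * va + (n2 - 1) * vb) / (n1 + n2 - 2)
            return np.abs(a.mean(axis=-1) - b.mean(axis=-1)) / np.sqrt(
                s2 * (1.0 / n1 + 1.0 / n2)
            )

        n_perm = 6000
        for _ in range(20):
            n1, n2 = rng.integers(6, 14, 2)
            shift = rng.uniform(0.0, 1.5)
            a = rng.normal(0, 1, n1)
            b = rng.normal(shift, 1, n2)
            p_tukey = tukey_pairwise({"a": a, "b": b}).loc["a", "b"]
            pooled = np.concatenate([a, b])
            obs = t_stat(pooled, n1)
            perms = pooled[rng.random((n_perm, n1 + n2)).argsort(axis=1)]
            p_perm = (np.sum(t_stat(perms, n1) >= obs) + 1) / (n_perm + 1)
            assert abs(p_tukey - p_perm) < 0.02


def _metric_frame(values: dict[str, np.ndarray]) -> pd.DataFrame:
    """values: treatment -> (n_plants, n_timepoints) array."""
    rows = []
    for tr, arr in values.items():
        for i, series in enumerate(arr):
            for t, v in enumerate(series):
                rows.append((f"{tr}{i}", tr, t, v))
    return pd.DataFrame(rows, columns=["plant_id", "treatment", "timepoint", "value"])


class TestSeparationOverTime:
    def test_separated_constants_always_significant(self):
        offsets = 0.01 * np.arange(4)[:, None] * np.ones((1, 5))
        df = _metric_frame({"a": 1.0 + offsets, "b": 5.0 + offsets})
        sep = separation_over_time(df)[("a", "b")]
        assert sep.significant.all()

    def test_invariant_to_label_order(self, rng):
        arr = {t: rng.normal(i, 1, (5, 6)) for i, t in enumerate("abc")}
        res1 = separation_over_time(_metric_frame(arr))
        res2 = separation_over_time(_metric_frame(dict(reversed(arr.items()))))
        for pair in res1:
            assert np.allclose(res1[pair].p_values, res2[pair].p_values)

    def test_mismatched_timepoints_rejected(self, rng):
        df = _metric_frame({"a": rng.normal(0, 1, (3, 5)), "b": rng.normal(0, 1, (3, 5))})
        df = df[~((df.treatment == "b") & (df.timepoint == 4))]
        with pytest.raises(ValueError):
            separation_over_time(df)


class TestDetection:
    def test_pattern_walk(self):
        sig = np.array([False, False, True, False, True, True, True])
        sep = SeparationResult(("a", "b"), np.arange(7), np.where(sig, 0.01, 0.5))
        assert detect_response(sep, "single") == 2
        assert detect_response(sep, "double") == 5

    def test_never_significant(self):
        sep = SeparationResult(("a", "b"), np.arange(4), np.full(4, 0.9))
        assert detect_response(sep, "single") is None
        assert detect_response(sep, "double") is None

    def test_always_significant(self):
        sep = SeparationResult(("a", "b"), np.arange(4), np.full(4, 0.001))
        assert detect_response(sep, "single") == 0
        assert detect_response(sep, "double") == 1

    def test_unknown_criterion_rejected(self):
        sep = SeparationResult(("a", "b"), np.arange(2), np.ones(2))
        with pytest.raises(ValueError):
            detect_response(sep, "triple")

    def test_response_time_arithmetic(self):
        assert response_time(9.3, 6.0) == pytest.approx(3.3)
        assert response_time(6.0, 6.0) == 0.0
        assert timepoints_to_days(5) == pytest.approx(5 * 8 / 24)
        with pytest.raises(ValueError):
            response_time(5.0, 6.0)


class TestGrowthMetricsFrame:
    def test_boundaries_dropped_and_aligned(self):
        df = pd.DataFrame(
            {
                "plant_id": ["p"] * 5,
                "treatment": ["c"] * 5,
                "timepoint": range(5),
                "mass_g": [1.0, 2.0, 3.0, 4.0, 5.0],
            }
        )
        met = growth_metrics(df)
        bio = met[met.metric == "biomass"]
        assert list(bio.timepoint) == [2, 3, 4]
        assert np.allclose(bio.value, [2.0, 3.0, 4.0])
        gr = met[met.metric == "GR"]
        assert list(gr.timepoint) == [3, 4]
        assert np.allclose(gr.value, [1.0, 1.0])
        rgr = met[met.metric == "RGR"]
        assert np.allclose(rgr.value, [1.0 / 3.0, 1.0 / 4.0])
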