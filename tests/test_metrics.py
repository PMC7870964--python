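import numpy as np
import pytest

from emberfire.grid import GridSpec, KM2_PER_MHA
from emberfire.metrics import (MetricError, MetricReport, MetricWeights,
                               aggregate_score, aggregate_series,
                               compute_metrics, corr, history_null_model,
                               niche_histogram)


def brute_force_metrics(pred, obs, mask, area_weighting=True):
    """Loop-based reimplementation of every skill metric (test oracle)."""
    areas = pred.grid.cell_areas() / KM2_PER_MHA if area_weighting else None
    nt = pred.n_time
    valid = mask[None] & np.isfinite(pred.values) & np.isfinite(obs.values)

    def agg(fld):
        out = np.zeros(nt)
        for t in range(nt):
            acc, wsum = 0.0, 0.0
            for i in range(pred.grid.n_lat):
                for j in range(pred.grid.n_lon):
                    if valid[t, i, j]:
                        w = areas[i, j] if area_weighting else 1.0
                        acc += fld.values[t, i, j] * (w if area_weighting else 1.0)
                        wsum += 1.0
            out[t] = acc if area_weighting else (acc / wsum if wsum else np.nan)
        return out

    mon_p, mon_o = agg(pred), agg(obs)
    years = sorted(set(pred.years.tolist()))
    year_p = np.array([mon_p[pred.years == y].sum() for y in years])
    year_o = np.array([mon_o[pred.years == y].sum() for y in years])

    def pearson(a, b):
        a, b = np.asarray(a, float), np.asarray(b, float)
        am, bm = a - a.mean(), b - b.mean()
        return float((am * bm).sum() / np.sqrt((am ** 2).sum() * (bm ** 2).sum()))

    # per-cell means and anomalies by explicit loops
    mean_p, mean_o, pool_p, pool_o = [], [], [], []
    an_p, an_o = [], []
    for i in range(pred.grid.n_lat):
        for j in range(pred.grid.n_lon):
            if not mask[i, j]:
                continue
            vp = [pred.values[t, i, j] for t in range(nt) if valid[t, i, j]]
            vo = [obs.values[t, i, j] for t in range(nt) if valid[t, i, j]]
            if not vp:
                continue
            mean_p.append(np.mean(vp))
            mean_o.append(np.mean(vo))
            pool_p.extend(vp)
            pool_o.extend(vo)
            cy_p = [sum(pred.values[t, i, j] for t in range(nt)
                        if pred.years[t] == y and valid[t, i, j]) for y in years]
            cy_o = [sum(obs.values[t, i, j] for t in range(nt)
                        if obs.years[t] == y and valid[t, i, j]) for y in years]
            an_p.extend(np.array(cy_p) - np.mean(cy_p))
            an_o.extend(np.array(cy_o) - np.mean(cy_o))

    ba_p, ba_o = year_p.mean(), year_o.mean()
    slope = lambda y: np.polyfit(years, y, 1)[0]
    return {
        "r_T": pearson(mon_p, mon_o), "r_IA": pearson(year_p, year_o),
        "r_S": pearson(mean_p, mean_o), "r_I": pearson(pool_p, pool_o),
        "r_An": pearson(an_p, an_o),
        "r_BA": 1 - abs(1 - ba_p / ba_o),
        "LT_pred": slope(year_p), "LT_obs": slope(year_o),
    }


def random_fields(field_factory, rng, n_lat=5, n_lon=4, years=3):
    grid = GridSpec.regular(n_lat, n_lon, resolution=10.0)
    shape = (years * 12, n_lat, n_lon)
    obs = field_factory(rng.random(shape) * 0.1, grid=grid)
    pred = field_factory(
        np.clip(obs.values * (1 + 0.3 * rng.standard_normal(shape)), 0, 1),
        grid=grid)
    return pred, obs


class TestCorr:
    def test_affine_invariance(self):
        x = np.array([1.0, 2.0, 4.0, 8.0])
        assert corr(x, 2 * x + 3) == pytest.approx(1.0)
        assert corr(x, -x) == pytest.approx(-1.0)

    def test_hand_computed_value(self):
        assert corr([1, 2, 3], [1, 3, 2]) == pytest.approx(0.5)

    def test_constant_series_nan_with_warning(self):
        with pytest.warns(UserWarning, match="constant"):
            assert np.isnan(corr([1, 1, 1], [1, 2, 3]))

    def test_length_mismatch(self):
        with pytest.raises(MetricError):
            corr([1, 2, 3], [1, 2])


class TestAggregateSeries:
    def test_flat_mean(self, field_factory):
        vals = np.full((12, 2, 5), 0.1)
        monthly, yrs, yearly = aggregate_series(
            field_factory(vals), np.ones((2, 5), dtype=bool),
            area_weighting=False)
        np.testing.assert_allclose(monthly, 0.1)
        np.testing.assert_allclose(yearly, [1.2])

    def test_zero_field(self, field_factory):
        monthly, _, yearly = aggregate_series(
            field_factory(np.zeros((24, 2, 2))), np.ones((2, 2), dtype=bool),
            area_weighting=False)
        assert np.all(monthly == 0) and np.all(yearly == 0)

    def test_incomplete_year_excluded(self, field_factory):
        vals = np.full((15, 1, 1), 0.1)  # one year + 3 months
        with pytest.warns(UserWarning, match="incomplete"):
            _, yrs, yearly = aggregate_series(
                field_factory(vals), np.ones((1, 1), dtype=bool),
                area_weighting=False)
        assert list(yrs) == [2002]


class TestComputeMetrics:
    def test_identity_prediction(self, field_factory, rng):
        pred, obs = random_fields(field_factory, rng)
        report = compute_metrics(obs, obs, np.ones((5, 4), dtype=bool))
        for r in (report.r_T, report.r_IA, report.r_An, report.r_S,
                  report.r_I, report.r_BA):
            assert r == pytest.approx(1.0)

    def test_doubled_prediction(self, field_factory, rng):
        _, obs = random_fields(field_factory, rng)
        pred = obs.like(2 * obs.values, "pred")
        report = compute_metrics(pred, obs, np.ones((5, 4), dtype=bool))
        assert report.r_T == pytest.approx(1.0)
        assert report.r_IA == pytest.approx(1.0)
        assert report.r_S == pytest.approx(1.0)
        assert report.r_BA == pytest.approx(0.0)

    def test_zero_prediction(self, field_factory, rng):
        _, obs = random_fields(field_factory, rng)
        pred = obs.like(np.zeros_like(obs.values), "pred")
        report = compute_metrics(pred, obs, np.ones((5, 4), dtype=bool))
        assert report.r_BA == pytest.approx(0.0)

    @pytest.mark.parametrize("area_weighting", [True, False])
    def test_matches_brute_force(self, field_factory, rng, area_weighting):
        """Vectorized metrics agree with an explicit loop implementation."""
        for _ in range(5):
            pred, obs = random_fields(field_factory, rng)
            mask = rng.random((5, 4)) > 0.2
            report = compute_metrics(pred, obs, mask,
                                     area_weighting=area_weighting)
            expected = brute_force_metrics(pred, obs, mask, area_weighting)
            for key, val in expected.items():
                assert getattr(report, key) == pytest.approx(val, abs=1e-12), key


def make_report(r_T=1.0, r_IA=1.0, r_An=1.0, r_S=1.0, r_BA=1.0):
    return MetricReport(r_T=r_T, r_IA=r_IA, r_An=r_An, r_S=r_S, r_BA=r_BA,
                        r_I=0.5, BA_pred_total=1.0, BA_obs_total=1.0,
                        LT_pred=0.0, LT_obs=0.0, n_samples=100)


class TestAggregateScore:
    def test_perfect_report_scores_100(self):
        assert aggregate_score(make_report()) == pytest.approx(100.0)

    def test_zero_report_scores_0(self):
        assert aggregate_score(make_report(0, 0, 0, 0, 0)) == 0.0

    def test_interannual_only(self):
        report = make_report(0, 1, 0, 0, 0)
        assert aggregate_score(report) == pytest.approx(100 * np.sqrt(4 / 8))

    def test_printed_normalization_caps_at_50(self):
        assert aggregate_score(make_report(),
                               printed_normalization=True) == pytest.approx(50.0)

    def test_monotone_in_each_metric_magnitude(self, rng):
        names = ["r_T", "r_IA", "r_An", "r_S", "r_BA"]
        for _ in range(200):
            vals = dict(zip(names, rng.uniform(-1, 1, 5)))
            base = aggregate_score(make_report(**vals))
            k = rng.choice(names)
            bumped = dict(vals)
            bumped[k] = np.sign(bumped[k] or 1.0) * min(1.0, abs(bumped[k]) + 0.1)
            assert aggregate_score(make_report(**bumped)) >= base - 1e-12

    def test_negative_correlations_enter_squared(self):
        assert aggregate_score(make_report(r_T=-1.0)) == pytest.approx(
            aggregate_score(make_report(r_T=1.0)))

    def test_missing_metric_named(self):
        with pytest.raises(MetricError, match="r_IA"):
            aggregate_score(make_report(r_IA=float("nan")))

    def test_weights_validation(self):
        with pytest.raises(MetricError):
            MetricWeights(w_T=-1.0)
        with pytest.raises(MetricError):
            MetricWeights(0, 0, 0, 0, 0)


class TestHistoryNullModel:
    def test_identical_years_predict_exactly(self, field_factory, rng):
        one_year = rng.random((12, 3, 3)) * 0.2
        vals = np.tile(one_year, (4, 1, 1))
        pred, r = history_null_model(field_factory(vals))
        np.testing.assert_allclose(pred.values, vals, atol=1e-12)
        assert r == pytest.approx(1.0)

    def test_iid_years_no_skill(self, field_factory, rng):
        vals = rng.random((12 * 6, 15, 15))
        _, r = history_null_model(field_factory(vals))
        assert abs(r) < 0.05

    def test_persistent_world_positive_skill(self, field_factory, rng):
        cell_rate = rng.random((1, 10, 10)) * 0.2
        noise = 0.02 * rng.standard_normal((48, 10, 10))
        vals = np.clip(cell_rate + noise, 0, 1)
        _, r = history_null_model(field_factory(vals))
        assert r > 0.5

    def test_single_year_rejected(self, field_factory):
        with pytest.raises(MetricError):
            history_null_model(field_factory(np.zeros((12, 2, 2))))


class TestNicheHistogram:
    def test_single_bin_degenerate_case(self, rng):
        a = np.full(50, 0.5)
        b = np.full(50, 1.5)
        ba = rng.random(50)
        counts, mean, _, _ = niche_histogram(a, b, ba, bins=1)
        assert counts[0, 0] == 50
        assert mean[0, 0] == pytest.approx(ba.mean())

    def test_counts_conserved(self, rng):
        a, b, ba = rng.random(500), rng.random(500), rng.random(500)
        counts, mean, _, _ = niche_histogram(a, b, ba, bins=7)
        assert counts.sum() == 500

    def test_per_bin_conditional_means(self):
        a = np.array([0.1, 0.1, 0.9, 0.9])
        b = np.array([0.1, 0.1, 0.9, 0.9])
        ba = np.array([0.1, 0.1, 0.3, 0.3])
        counts, mean, _, _ = niche_histogram(a, b, ba, bins=2)
        assert mean[0, 0] == pytest.approx(0.1)
        assert mean[1, 1] == pytest.approx(0.3)
        assert np.isnan(mean[0, 1])
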