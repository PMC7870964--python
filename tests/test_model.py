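import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from emberfire.model import (BurnedAreaModel, DiscretizedMLP, TrainConfig,
                             TrainingError, build_partition, class_of, elu,
                             expected_ba, fit_burned_area_model, predict_field,
                             split_samples, train)
from emberfire.features import Standardizer
from emberfire.grid import GridSpec, month_range


@pytest.fixture(scope="module")
def partition():
    return build_partition()


class TestPartition:
    def test_default_structure(self, partition):
        p = partition
        assert p.n_classes == 25
        assert len(p.edges) == 26
        assert p.edges[0] == 0.0 and p.edges[1] == 1e-6 and p.edges[-1] == 1.0
        np.testing.assert_allclose(p.edges[1:],
                                   10.0 ** (-6 + 0.25 * np.arange(25)))

    def test_edge_between_top_classes(self, partition):
        assert partition.edges[24] == pytest.approx(10 ** -0.25)

    def test_top_representative(self, partition):
        assert partition.representatives[-1] == pytest.approx(10 ** -0.125)

    def test_zero_class_representative_is_zero(self, partition):
        assert partition.representatives[0] == 0.0

    def test_representatives_round_trip(self, partition):
        """Each nonzero representative falls back into its own class."""
        for i in range(2, 26):
            assert class_of(partition.representatives[i - 1], partition) == i

    @pytest.mark.parametrize("ba,expected", [(0.0, 1), (1e-6, 2), (0.5, 24),
                                             (1.0, 25)])
    def test_class_of(self, partition, ba, expected):
        assert class_of(ba, partition) == expected

    def test_out_of_range_rejected(self, partition):
        with pytest.raises(ValueError):
            class_of(1.5, partition)

    @given(st.floats(min_value=0.0, max_value=1.0))
    @settings(max_examples=200, deadline=None)
    def test_every_value_gets_one_class(self, ba):
        p = build_partition()
        c = class_of(ba, p)
        assert 1 <= c <= 25
        if c < 25:
            assert p.edges[c - 1] <= ba < p.edges[c]


class TestActivations:
    @pytest.mark.parametrize("x,expected", [(0.0, 0.0), (2.0, 2.0),
                                            (-1.0, np.expm1(-1.0))])
    def test_elu(self, x, expected):
        assert elu(x) == pytest.approx(expected)

    def test_forward_uniform_for_zero_weights(self):
        m = DiscretizedMLP(np.zeros((3, 12)), np.zeros(12),
                           np.zeros((12, 25)), np.zeros(25))
        p = m.forward(np.ones(3))
        np.testing.assert_allclose(p, 0.04)

    def test_forward_shift_invariance(self, rng):
        m = DiscretizedMLP(rng.normal(size=(3, 12)), rng.normal(size=12),
                           rng.normal(size=(12, 25)), rng.normal(size=25))
        x = rng.normal(size=(5, 3))
        p1 = m.forward(x)
        m.b2 = m.b2 + 7.5
        np.testing.assert_allclose(m.forward(x), p1, atol=1e-12)

    def test_forward_saturates_on_dominant_logit(self):
        b2 = np.zeros(25)
        b2[7] = 1000.0
        m = DiscretizedMLP(np.zeros((2, 12)), np.zeros(12),
                           np.zeros((12, 25)), b2)
        p = m.forward(np.zeros(2))
        assert p[0, 7] == pytest.approx(1.0)

    def test_forward_is_probability_vector(self, rng):
        m = DiscretizedMLP(rng.normal(size=(4, 12)), rng.normal(size=12),
                           rng.normal(size=(12, 25)), rng.normal(size=25))
        p = m.forward(rng.normal(size=(10, 4)))
        assert np.all(p >= 0)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-9)


class TestExpectedBa:
    def test_one_hot_extremes(self, partition):
        low = np.zeros(25)
        low[0] = 1.0
        assert expected_ba(low, partition) == 0.0
        high = np.zeros(25)
        high[24] = 1.0
        assert expected_ba(high, partition) == pytest.approx(10 ** -0.125)

    def test_linear_mixture(self, partition):
        p = np.zeros(25)
        p[0] = p[24] = 0.5
        assert expected_ba(p, partition) == pytest.approx(0.5 * 10 ** -0.125)

    def test_unnormalized_rejected(self, partition):
        with pytest.raises(ValueError):
            expected_ba(np.full(25, 0.05), partition)


def toy_frame(n, seed=0, years=6):
    rng = np.random.default_rng(seed)
    year = 2002 + rng.integers(0, years, n)
    return pd.DataFrame({"year": year, "x": rng.normal(size=n)})


class TestSplit:
    def test_test_window_is_years_4_to_6(self):
        df = toy_frame(5000, years=10)
        split = split_samples(df, TrainConfig(seed=0))
        test_years = set(df["year"].iloc[split["test"]])
        assert test_years == {2005, 2006, 2007}
        n = len(df)
        assert (len(split["train"]) + len(split["validation"])
                + len(split["test"])) == n
        all_idx = np.concatenate([split[k] for k in split])
        assert len(np.unique(all_idx)) == n

    def test_seventy_thirty_split(self):
        df = toy_frame(2000, years=10)
        n_rest = int((~df["year"].isin([2005, 2006, 2007])).sum())
        split = split_samples(df, TrainConfig(seed=1))
        assert len(split["train"]) == round(0.7 * n_rest)

    def test_same_seed_same_split(self):
        df = toy_frame(1000)
        a = split_samples(df, TrainConfig(seed=3))
        b = split_samples(df, TrainConfig(seed=3))
        for k in a:
            np.testing.assert_array_equal(a[k], b[k])

    def test_empty_stratum_rejected(self):
        df = toy_frame(100, years=2)  # no rows in the test window
        with pytest.raises(ValueError, match="empty split"):
            split_samples(df, TrainConfig(seed=0))


def learnable_problem(n, seed=0, shuffle=False):
    """Burned area a smooth monotone function of one feature, discretized."""
    rng = np.random.default_rng(seed)
    x = rng.uniform(-2, 2, size=(n, 2))
    ba = 0.3 / (1 + np.exp(-2 * x[:, 0]))
    p = build_partition()
    y = np.asarray(class_of(ba, p)) - 1
    if shuffle:
        y = rng.permutation(y)
    return x, y, ba, p


class TestTraining:
    CFG = TrainConfig(max_epochs=40, patience=10, batch_size=256,
                      min_train_rows_per_hidden=0, seed=0)

    def test_learns_smooth_signal(self):
        x, y, ba, p = learnable_problem(6000)
        model, hist = train(x[:5000], y[:5000], self.CFG,
                            val=(x[5000:], y[5000:]))
        pred = expected_ba(model.forward(x[5000:]), p)
        assert np.corrcoef(pred, ba[5000:])[0, 1] > 0.8

    def test_shuffled_labels_no_skill(self):
        """With targets shuffled, held-out predictions carry no information
        about the held-out targets."""
        x, y, ba, p = learnable_problem(12000, shuffle=True)
        model, _ = train(x[:10000], y[:10000], self.CFG,
                         val=(x[10000:], y[10000:]))
        pred = expected_ba(model.forward(x[10000:]), p)
        target = p.representatives[y[10000:]]
        assert abs(np.corrcoef(pred, target)[0, 1]) < 0.1

    def test_same_seed_identical_fit(self):
        x, y, _, _ = learnable_problem(3000)
        m1, h1 = train(x, y, self.CFG)
        m2, h2 = train(x, y, self.CFG)
        np.testing.assert_array_equal(m1.W1, m2.W1)
        assert h1["train_ce"] == h2["train_ce"]

    def test_best_loss_sequence_non_increasing(self):
        x, y, _, _ = learnable_problem(3000)
        _, hist = train(x, y, self.CFG)
        ce = hist["train_ce"]
        best_so_far = np.minimum.accumulate(ce)
        assert np.all(np.diff(best_so_far) <= 0)

    def test_too_few_rows_guard(self):
        x, y, _, _ = learnable_problem(100)
        with pytest.raises(TrainingError, match="training rows"):
            train(x, y, TrainConfig(seed=0))

    def test_wider_hidden_layer_keeps_contracts(self):
        x, y, _, p = learnable_problem(2000)
        cfg = TrainConfig(hidden=24, max_epochs=5, batch_size=256,
                          min_train_rows_per_hidden=0, seed=0)
        model, _ = train(x, y, cfg)
        probs = model.forward(x[:10])
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-9)


class TestModelBundle:
    def _bundle(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"ts": rng.normal(20, 5, 500),
                           "veg_savannas": rng.random(500)})
        std = Standardizer().fit(df, ["ts", "veg_savannas"])
        mlp = DiscretizedMLP.init(2, 12, 25, rng)
        return BurnedAreaModel(mlp, build_partition(), std,
                               ["ts", "veg_savannas"], region="AUS"), df

    def test_save_load_round_trip(self, tmp_path):
        bundle, df = self._bundle()
        path = tmp_path / "model.json"
        bundle.save(path)
        loaded = BurnedAreaModel.load(path)
        np.testing.assert_allclose(loaded.predict_ba(df), bundle.predict_ba(df),
                                   atol=1e-12)
        assert loaded.region == "AUS"

    def test_predict_field_scatter(self):
        bundle, df = self._bundle()
        grid = GridSpec.regular(2, 2)
        years, months = month_range(2002, 1, 2)
        rows = pd.DataFrame({
            "ts": [20.0, 25.0], "veg_savannas": [0.5, 0.2],
            "time_idx": [0, 1], "ilat": [0, 1], "ilon": [1, 0]})
        fld = predict_field(bundle, rows, grid, years, months)
        pred = bundle.predict_ba(rows)
        assert fld.values[0, 0, 1] == pytest.approx(pred[0])
        assert fld.values[1, 1, 0] == pytest.approx(pred[1])
        assert np.isnan(fld.values[0, 0, 0])  # unmodelled stays missing
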