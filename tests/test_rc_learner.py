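import numpy as np
import pytest

from unbindkit.io import TimeSeriesTable
from unbindkit.rc_learner import (
    RCModel,
    decoder_forward,
    encode,
    make_pairs,
    reweighted_loss,
    train_rc,
)

MORPHINE_RC = np.array([0.5, -0.1, 0.3, 0.2, -0.1, 0.3, -0.3, -0.1, 0.7])


def tiny_model(k=2, K=1, fill=0.0):
    return RCModel(
        w=np.ones(k),
        W1=np.full((K, 1), fill), b1=np.zeros(K),
        W2=np.full((K, K), fill), b2=np.zeros(K),
        W3=np.full((k, K), fill), b3=np.zeros(k),
    )


@pytest.fixture(scope="module")
def planted_table():
    """AR(1) latent mode spread over 10 features, plus a pure-noise channel."""
    r = np.random.default_rng(5)
    nf, n = 10, 4000
    wstar = r.standard_normal(nf)
    wstar /= np.linalg.norm(wstar)
    s = np.empty(n)
    s[0] = 0.0
    for t in range(1, n):
        s[t] = 0.97 * s[t - 1] + 0.2 * r.standard_normal()
    x = np.outer(s, wstar) + 0.3 * r.standard_normal((n, nf))
    cols = {f"f{i}": x[:, i] for i in range(nf)}
    cols["noise"] = r.standard_normal(n)
    return TimeSeriesTable.from_arrays(np.arange(n, dtype=float), cols), wstar


class TestEncode:
    def test_basis_projection(self):
        x = np.array([3.0, 5.0, 7.0])
        assert encode(x, np.array([1.0, 0.0, 0.0])) == 3.0

    def test_linearity(self, rng):
        x = rng.standard_normal(6)
        w = rng.standard_normal(6)
        assert encode(2.5 * x, w) == pytest.approx(2.5 * encode(x, w))
        assert encode(x, 2.5 * w) == pytest.approx(2.5 * encode(x, w))

    def test_published_morphine_coefficients_on_unit_input(self):
        # 0.5-0.1+0.3+0.2-0.1+0.3-0.3-0.1+0.7 on a 9-vector of ones
        assert encode(np.ones(9), MORPHINE_RC) == pytest.approx(1.4)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            encode(np.ones(3), np.ones(4))


class TestDecoderForward:
    def test_all_zero_parameters_give_zero(self):
        m = tiny_model(k=3, K=4, fill=0.0)
        assert np.all(decoder_forward(2.7, m) == 0.0)

    def test_identity_branch_of_elu(self):
        # K=1, all weights 1, biases 0: ELU is identity for z >= 0
        m = tiny_model(k=3, K=1, fill=1.0)
        for z in (0.0, 0.5, 2.0):
            assert np.allclose(decoder_forward(z, m), z)

    def test_finite_for_large_bottleneck_values(self, rng):
        m = RCModel(
            w=rng.standard_normal(4),
            W1=rng.standard_normal((8, 1)), b1=rng.standard_normal(8),
            W2=rng.standard_normal((8, 8)), b2=rng.standard_normal(8),
            W3=rng.standard_normal((4, 8)), b3=rng.standard_normal(4),
        )
        assert np.all(np.isfinite(decoder_forward(1e3, m)))
        assert np.all(np.isfinite(decoder_forward(-1e3, m)))


class TestReweightedLoss:
    def test_zero_bias_equals_plain_mse(self, rng):
        m = tiny_model(k=2, K=1, fill=0.3)
        x = rng.standard_normal((6, 2))
        y = rng.standard_normal((6, 2))
        pred = decoder_forward(encode(x, m.w), m)
        mse = ((pred - y) ** 2).sum(axis=1).mean()
        assert reweighted_loss((x, y), m, np.zeros(6)) == pytest.approx(mse)
        assert reweighted_loss((x, y), m, None) == pytest.approx(mse)

    def test_two_pair_hand_computed_weighted_mean(self):
        # beta*V = {0, ln 2} -> weights {1/3, 2/3}: loss = (e1 + 2 e2)/3
        m = tiny_model(k=1, K=1, fill=0.0)  # predicts 0
        x = np.array([[0.0], [0.0]])
        y = np.array([[1.0], [3.0]])        # errors e1=1, e2=9
        loss = reweighted_loss((x, y), m, np.array([0.0, np.log(2.0)]), beta=1.0)
        assert loss == pytest.approx((1.0 + 2.0 * 9.0) / 3.0)

    def test_perfect_model_zero_loss(self):
        m = tiny_model(k=2, K=1, fill=1.0)
        x = np.array([[0.5, 0.5]])         # z=1 -> prediction (1,1)
        y = np.array([[1.0, 1.0]])
        assert reweighted_loss((x, y), m) == pytest.approx(0.0)


class TestTraining:
    def test_recovers_planted_slow_mode(self, planted_table):
        table, wstar = planted_table
        model, rec = train_rc(
            table, lag=2.0, epochs=400, lr=2e-3, K=16, seed=0, bias_column=None
        )
        w = model.w[:10]  # planted channels
        cosine = abs(w @ wstar) / np.linalg.norm(w)
        assert cosine > 0.95
        # pure-noise channel rounds to 0.0 in the reported RC
        assert model.reported_coefficients()[-1] == 0.0

    def test_fractional_loss_bounded_and_decreasing_in_windows(self, planted_table):
        table, _ = planted_table
        _, rec = train_rc(
            table, lag=2.0, epochs=300, lr=2e-3, K=16, seed=1, bias_column=None
        )
        frac = rec.fractional_loss
        assert np.all(frac[1:] <= 1.0)
        window = frac.reshape(3, 100).mean(axis=1)
        assert np.all(np.diff(window) < 0)

    def test_deterministic_and_zero_bias_equals_unweighted(self, planted_table):
        table, _ = planted_table
        cols = {c: table.column(c) for c in table.columns}
        cols["bias"] = np.zeros(table.n_frames)
        tb = TimeSeriesTable.from_arrays(table.times, cols)
        kw = dict(lag=2.0, epochs=40, lr=2e-3, K=8, seed=3)
        m1, _ = train_rc(tb, **kw)                    # reweighting with V=0
        m2, _ = train_rc(tb, reweight=False, **kw)    # reweighting disabled
        m3, _ = train_rc(tb, **kw)
        assert np.array_equal(m1.w, m2.w)
        assert np.array_equal(m1.w, m3.w)

    def test_nonfinite_loss_aborts_with_diagnostic(self):
        # overflow in the squared error must abort, not train on garbage
        r = np.random.default_rng(0)
        cols = {f"f{i}": 1e200 * r.standard_normal(100) for i in range(3)}
        table = TimeSeriesTable.from_arrays(np.arange(100.0), cols)
        with pytest.raises(FloatingPointError, match="epoch"):
            train_rc(table, lag=2.0, epochs=10, lr=1e-3, K=4, seed=0,
                     bias_column=None, standardize=False)

    def test_make_pairs_validates_lag(self, planted_table):
        table, _ = planted_table
        with pytest.raises(ValueError):
            make_pairs(table, 0.1, table.columns, None)  # lag < frame spacing

    def test_model_round_trips_through_hdf5(self, planted_table, tmp_path):
        table, _ = planted_table
        m, _ = train_rc(table, lag=2.0, epochs=10, lr=1e-3, K=4, seed=0,
                        bias_column=None)
        m.save(tmp_path / "rc.h5")
        back = RCModel.load(tmp_path / "rc.h5")
        assert np.array_equal(back.w, m.w)
        assert back.feature_names == m.feature_names
        assert np.array_equal(back.feature_mean, m.feature_mean)
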