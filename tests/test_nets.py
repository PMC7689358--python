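"""Network layers, parameter accounting and the training protocol."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gpbench.nets import (Conv1D, LocalConv1D, NetworkModel, NetworkSpec,
                          TrainConfig, build_network, cnn_baseline,
                          conv_layer_parameters, count_parameters,
                          layer_breakdown, lcnn_baseline, mlp_baseline,
                          n_windows)


def _lcl_reference(X, W, b, k, s):
    """Triple-nested-loop oracle for the local convolution forward pass."""
    B, p = X.shape
    nw = (p - k) // s + 1
    out = np.zeros((B, nw))
    for bi in range(B):
        for w in range(nw):
            acc = b[w]
            for i in range(k):
                acc += W[w, i] * X[bi, s * w + i]
            out[bi, w] = acc
    return out


class TestLocalConvLayer:
    @pytest.mark.parametrize("p,k,s,batch", [(30, 3, 3, 4), (31, 4, 2, 5),
                                             (25, 7, 7, 2)])
    def test_forward_matches_triple_loop(self, rng, p, k, s, batch):
        lay = LocalConv1D(p, k, s, rng)
        X = rng.standard_normal((batch, p))
        np.testing.assert_allclose(lay.forward(X),
                                   _lcl_reference(X, lay.W, lay.b, k, s),
                                   atol=1e-10)

    def test_zero_weights_give_zero_output(self, rng):
        lay = LocalConv1D(20, 5, 5, rng)
        lay.W[:] = 0.0
        lay.b[:] = 0.0
        assert np.all(lay.forward(rng.standard_normal((3, 20))) == 0)

    def test_window_count_at_maize_scale(self):
        assert n_windows(34_595, 10, 10) == 3459

    @settings(derandomize=True, max_examples=80)
    @given(st.integers(1, 500), st.integers(1, 50), st.integers(1, 50))
    def test_windows_always_fit_inside_the_input(self, p, k, s):
        """Every window reads positions s*w .. s*w+k-1; the last one must end
        at or before p, and adding one more window would overflow."""
        if p < k:
            with pytest.raises(ValueError):
                n_windows(p, k, s)
            return
        nw = n_windows(p, k, s)
        assert nw >= 1
        assert s * (nw - 1) + k <= p
        assert s * nw + k > p

    def test_input_shorter_than_kernel_rejected(self, rng):
        with pytest.raises(ValueError):
            LocalConv1D(5, 10, 10, rng)

    def test_weight_tied_lcl_reproduces_conv(self, rng):
        """A conv layer is the weight-tied special case of the local layer."""
        conv = Conv1D(40, 4, 4, 1, rng)
        lcl = LocalConv1D(40, 4, 4, rng)
        lcl.W[:] = conv.F[0]
        lcl.b[:] = conv.b[0]
        X = rng.standard_normal((6, 40))
        np.testing.assert_allclose(lcl.forward(X), conv.forward(X), atol=1e-12)

    def test_gradients_match_finite_differences(self, rng):
        lay = LocalConv1D(12, 3, 2, rng)
        X = rng.standard_normal((3, 12))
        dY = rng.standard_normal((3, lay.n_windows))
        lay.forward(X, cache=True)
        dX, (dW, db) = lay.backward(dY)
        eps = 1e-6
        for (a, b_) in [(0, 1), (2, 5)]:
            Xp = X.copy(); Xp[a, b_] += eps
            Xm = X.copy(); Xm[a, b_] -= eps
            num = ((lay.forward(Xp) - lay.forward(Xm)) * dY).sum() / (2 * eps)
            assert num == pytest.approx(dX[a, b_], abs=1e-5)
        Wp = lay.W.copy()
        lay.W[1, 2] += eps
        up = (lay.forward(X) * dY).sum()
        lay.W[1, 2] -= 2 * eps
        dn = (lay.forward(X) * dY).sum()
        lay.W = Wp
        assert (up - dn) / (2 * eps) == pytest.approx(dW[1, 2], abs=1e-5)


class TestParameterAccounting:
    def test_baseline_mlp_count_rounds_to_2p2_million(self):
        count = count_parameters(mlp_baseline(), 34_595)
        assert count == 34_595 * 64 + 64 + 64 * 64 + 64 + 64 + 1
        assert round(count / 1e6, 1) == 2.2

    def test_single_shared_filter_counts_eleven(self):
        assert conv_layer_parameters(kernel_size=10, n_filters=1) == 11
        assert layer_breakdown(cnn_baseline(), 34_595)[0] == ("conv", 10, 1)

    @pytest.mark.parametrize("p", [3000, 34_590])
    def test_fcl_to_lcl_weight_ratio_is_64(self, p):
        """Weights-only: a 64-node FCL on p inputs vs an LCL with k = s that
        tiles p exactly."""
        fcl_weights = p * 64
        lcl_weights = count_parameters(
            NetworkSpec("LCNN", fcl_nodes=()), p, weights_only=True)
        lcl_weights -= n_windows(p, 10, 10) * 1  # drop the output layer weights
        assert fcl_weights / lcl_weights == 64

    def test_baseline_ordering_at_maize_scale(self):
        mlp = count_parameters(mlp_baseline(), 34_595)
        cnn = count_parameters(cnn_baseline(), 34_595)
        lcnn = count_parameters(lcnn_baseline(), 34_595)
        assert mlp > lcnn > cnn > 0


class TestBuildNetwork:
    def test_same_seed_identical_weights(self):
        a = build_network(lcnn_baseline(), 120, seed=5)
        b = build_network(lcnn_baseline(), 120, seed=5)
        for pa, pb in zip(a.params, b.params):
            np.testing.assert_array_equal(pa, pb)

    def test_baseline_lcnn_structure(self):
        net = build_network(lcnn_baseline(), 200, seed=1)
        lcl = net.layers[0]
        assert isinstance(lcl, LocalConv1D)
        assert lcl.kernel_size == lcl.stride == 10
        assert [l.n_out for l in net.layers[1:]] == [64, 64]
        assert net.out.n_out == 1

    def test_multi_trait_head(self):
        net = build_network(lcnn_baseline(n_outputs=5), 100, seed=2)
        X = np.random.default_rng(0).integers(0, 3, (7, 100)).astype(float)
        assert net.forward(X).shape == (7, 5)


@pytest.fixture(scope="module")
def linear_data():
    rng = np.random.default_rng(33)
    X = rng.integers(0, 3, (600, 120)).astype(float)
    y = X[:, 11].copy()  # noiseless single-marker trait
    return X, y


class TestTraining:
    def test_fits_noiseless_linear_signal(self, linear_data):
        X, y = linear_data
        mdl = NetworkModel(y[:500], X[:500], mlp_baseline(),
                           y_val=y[500:], X_val=X[500:])
        res = mdl.fit(TrainConfig(seed=2))
        r = np.corrcoef(res.predict(X[:500]), y[:500])[0, 1]
        assert r > 0.95
        assert res.loss_history[-1] < res.loss_history[0]
        assert 1 <= res.selected_epoch <= 50

    def test_selected_epoch_is_validation_argmax(self, linear_data):
        X, y = linear_data
        res = NetworkModel(y[:500], X[:500], mlp_baseline(), y_val=y[500:],
                           X_val=X[500:]).fit(TrainConfig(seed=3, max_epochs=10))
        hist = np.array(res.val_history)
        assert res.selected_epoch == int(np.argmax(hist)) + 1

    def test_fixed_mode_ignores_validation_data(self, linear_data):
        X, y = linear_data
        cfg = TrainConfig(mode="fixed", max_epochs=5, seed=4)
        with_val = NetworkModel(y[:500], X[:500], cnn_baseline(),
                                y_val=y[500:], X_val=X[500:]).fit(cfg)
        without = NetworkModel(y[:500], X[:500], cnn_baseline()).fit(cfg)
        np.testing.assert_array_equal(with_val.predict(X[500:]),
                                      without.predict(X[500:]))
        assert with_val.selected_epoch == 5
        assert with_val.val_history == []

    def test_fixed_mode_default_is_25_epochs(self):
        assert TrainConfig(mode="fixed").max_epochs == 25
        assert TrainConfig().max_epochs == 50

    def test_early_stop_without_validation_rejected(self, linear_data):
        X, y = linear_data
        with pytest.raises(ValueError):
            NetworkModel(y, X, mlp_baseline()).fit(TrainConfig(seed=1))

    def test_prediction_is_deterministic_and_shaped(self, linear_data):
        X, y = linear_data
        res = NetworkModel(y[:500], X[:500], lcnn_baseline(), y_val=y[500:],
                           X_val=X[500:]).fit(TrainConfig(seed=5, max_epochs=3))
        p1, p2 = res.predict(X[:50]), res.predict(X[:50])
        np.testing.assert_array_equal(p1, p2)
        assert p1.shape == (50,)
        const = res.predict(np.ones((4, 120)))
        assert np.ptp(const) == 0  # constant rows give constant outputs
        with pytest.raises(ValueError):
            res.predict(X[:, :100])

    def test_multi_trait_training_returns_column_per_trait(self):
        rng = np.random.default_rng(44)
        X = rng.integers(0, 3, (300, 80)).astype(float)
        Y = np.stack([X[:, 3], X[:, 9] * 0.5], axis=1)
        res = NetworkModel(Y[:250], X[:250], NetworkSpec("MLP", n_outputs=2),
                           y_val=Y[250:], X_val=X[250:]
                           ).fit(TrainConfig(seed=6, max_epochs=5))
        assert res.predict(X[:10]).shape == (10, 2)
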