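"""Forward-pass contracts for the GRU cell and the three architectures,
checked against independent scalar/compositional oracles."""

import numpy as np
import pytest

from hftraj.networks import (
    ContractError,
    GruParams,
    ModelSpec,
    TrainedModel,
    build_network,
    dhtm_forward,
    dhtmc_forward,
    gru_step,
    load_checkpoint,
    lstm_forward,
    save_checkpoint,
)


def sigma(x):
    return 1.0 / (1.0 + np.exp(-x))


def random_gru_params(rng, hidden, inputs, scale=0.4) -> GruParams:
    shape = (hidden, hidden + inputs)
    return GruParams(
        W_z=rng.normal(size=shape) * scale,
        W_r=rng.normal(size=shape) * scale,
        W_h=rng.normal(size=shape) * scale,
        b_z=rng.normal(size=hidden) * 0.1,
        b_r=rng.normal(size=hidden) * 0.1,
        b_h=rng.normal(size=hidden) * 0.1,
    )


def scalar_gru_oracle(params: GruParams, h, x):
    """Component-by-component evaluation of the four gate formulas."""
    H = params.W_z.shape[0]
    hx = np.concatenate([h, x])
    z = np.array([sigma(params.W_z[j] @ hx + params.b_z[j]) for j in range(H)])
    r = np.array([sigma(params.W_r[j] @ hx + params.b_r[j]) for j in range(H)])
    rhx = np.concatenate([r * h, x])
    h_tilde = np.array([np.tanh(params.W_h[j] @ rhx + params.b_h[j]) for j in range(H)])
    return (1 - z) * h + z * h_tilde


class TestGruStep:
    def test_zero_weights_halve_previous_state(self):
        H, I = 4, 3
        params = GruParams(*(np.zeros((H, H + I)) for _ in range(3)))
        v = np.array([0.2, -0.4, 0.6, 0.1])
        # z = 0.5 and h_tilde = 0, so h' = 0.5 v
        assert gru_step(params, v, np.zeros(I)) == pytest.approx(0.5 * v)

    def test_zero_state_and_weights_stay_zero(self):
        params = GruParams(*(np.zeros((2, 5)) for _ in range(3)))
        assert gru_step(params, np.zeros(2), np.ones(3)) == pytest.approx(np.zeros(2))

    def test_matches_scalar_oracle(self):
        rng = np.random.default_rng(42)
        params = random_gru_params(rng, hidden=3, inputs=2)
        h = np.tanh(rng.normal(size=3))
        x = rng.normal(size=2)
        expected = scalar_gru_oracle(params, h, x)
        assert gru_step(params, h, x) == pytest.approx(expected, abs=1e-12)

    def test_output_bounded_when_state_bounded(self):
        # convex combination of the bounded state and a tanh term; weight
        # scale kept moderate so float rounding cannot saturate tanh to ±1
        rng = np.random.default_rng(7)
        for _ in range(50):
            params = random_gru_params(rng, 5, 4, scale=1.0)
            h = rng.uniform(-1, 1, size=5)
            out = gru_step(params, h, rng.normal(size=4))
            assert np.abs(out).max() < 1.0

    def test_dimension_mismatch_rejected(self):
        params = GruParams(*(np.zeros((2, 5)) for _ in range(3)))
        with pytest.raises(ContractError):
            gru_step(params, np.zeros(3), np.zeros(3))


def fresh_model(variant, **spec_kw) -> TrainedModel:
    spec = ModelSpec(variant=variant, **spec_kw)
    return TrainedModel(spec=spec, network=build_network(spec, seed=1))


def zero_head(model):
    model.network.head.W.data[:] = 0.0
    model.network.head.b.data[:] = 0.0


@pytest.mark.parametrize("variant", ["dhtm", "dhtm_c", "lstm"])
class TestForwardContracts:
    def test_zero_final_affine_gives_half(self, variant):
        model = fresh_model(variant, hidden_width=8)
        zero_head(model)
        X = np.random.default_rng(0).normal(size=(5, 20))
        if variant == "dhtm_c":
            _, probs = dhtmc_forward(model, X)
        elif variant == "lstm":
            probs = lstm_forward(model, X)
        else:
            probs = dhtm_forward(model, X)
        assert probs == pytest.approx(np.full(5, 0.5))

    def test_causality_under_late_perturbation(self, variant):
        model = fresh_model(variant, hidden_width=8)
        rng = np.random.default_rng(1)
        X = rng.normal(size=(7, 20))
        X2 = X.copy()
        X2[4] += 10.0
        fwd = dhtmc_forward if variant == "dhtm_c" else dhtm_forward
        if variant == "lstm":
            fwd = lstm_forward
        a = fwd(model, X)
        b = fwd(model, X2)
        a_hf = a[1] if variant == "dhtm_c" else a
        b_hf = b[1] if variant == "dhtm_c" else b
        assert a_hf[:4] == pytest.approx(b_hf[:4], abs=1e-12)
        assert not np.allclose(a_hf[4:], b_hf[4:])

    def test_batch_permutation_equivariance(self, variant):
        model = fresh_model(variant, hidden_width=6)
        rng = np.random.default_rng(2)
        X = rng.normal(size=(4, 5, 20))
        fwd = dhtmc_forward if variant == "dhtm_c" else dhtm_forward
        if variant == "lstm":
            fwd = lstm_forward
        full = fwd(model, X)
        full_hf = full[1] if variant == "dhtm_c" else full
        perm = [2, 0, 3, 1]
        permuted = fwd(model, X[perm])
        permuted_hf = permuted[1] if variant == "dhtm_c" else permuted
        assert permuted_hf == pytest.approx(full_hf[perm], abs=1e-12)


class TestDhtm:
    def test_single_layer_matches_compositional_oracle(self):
        model = fresh_model(
            "dhtm", hidden_width=3, n_recurrent_layers=1,
            use_residual=False, use_layer_norm=False, input_width=4,
        )
        net = model.network
        rng = np.random.default_rng(3)
        X = rng.normal(size=(6, 4))
        probs = dhtm_forward(model, X)

        params = GruParams(
            net.grus[0].W_z.data, net.grus[0].W_r.data, net.grus[0].W_h.data,
            net.grus[0].b_z.data, net.grus[0].b_r.data, net.grus[0].b_h.data,
        )
        h = np.zeros(3)
        expected = []
        for t in range(6):
            u = X[t] @ net.dense_in.W.data + net.dense_in.b.data
            h = gru_step(params, h, u)
            expected.append(sigma(h @ net.head.W.data + net.head.b.data)[0])
        assert probs == pytest.approx(np.array(expected), abs=1e-6)

    def test_residual_blocks_act_as_identity_with_zero_gru_weights(self):
        model = fresh_model("dhtm", hidden_width=5, n_recurrent_layers=2)
        net = model.network
        for gru in net.grus:
            for W in (gru.W_z, gru.W_r, gru.W_h):
                W.data[:] = 0.0
        rng = np.random.default_rng(4)
        X = rng.normal(size=(4, 20))
        probs = dhtm_forward(model, X)
        # hidden state stays 0, so each block passes its input through and the
        # output is a memoryless function of the current input
        expected = [
            sigma(
                (x @ net.dense_in.W.data + net.dense_in.b.data) @ net.head.W.data
                + net.head.b.data
            )[0]
            for x in X
        ]
        assert probs == pytest.approx(np.array(expected), abs=1e-12)

    def test_wrong_input_width_rejected(self):
        model = fresh_model("dhtm", hidden_width=4)
        with pytest.raises(ContractError):
            dhtm_forward(model, np.zeros((3, 7)))


class TestDhtmc:
    def test_output_arity(self):
        model = fresh_model("dhtm_c", hidden_width=6)
        cm, hf = dhtmc_forward(model, np.zeros((9, 20)))
        assert cm.shape == (9, 3)
        assert hf.shape == (9,)
        assert ((cm > 0) & (cm < 1)).all()

    def test_matches_compositional_oracle(self):
        model = fresh_model("dhtm_c", hidden_width=3, input_width=4)
        net = model.network
        rng = np.random.default_rng(5)
        X = rng.normal(size=(5, 4))
        cm, hf = dhtmc_forward(model, X)

        p1 = GruParams(net.gru1.W_z.data, net.gru1.W_r.data, net.gru1.W_h.data,
                       net.gru1.b_z.data, net.gru1.b_r.data, net.gru1.b_h.data)
        p2 = GruParams(net.gru2.W_z.data, net.gru2.W_r.data, net.gru2.W_h.data,
                       net.gru2.b_z.data, net.gru2.b_r.data, net.gru2.b_h.data)
        h1 = np.zeros(3)
        h2 = np.zeros(3)
        for t in range(5):
            u = X[t] @ net.dense_in.W.data + net.dense_in.b.data
            h1 = gru_step(p1, h1, u)
            cm_logits = h1 @ net.cm_head.W.data + net.cm_head.b.data
            c_hat = sigma(cm_logits)
            u2 = cm_logits @ net.dense2.W.data + net.dense2.b.data
            h2 = gru_step(p2, h2, u2)
            feats = np.concatenate([h1, h2, c_hat])
            y_hat = sigma(feats @ net.head.W.data + net.head.b.data)[0]
            assert cm[t] == pytest.approx(c_hat, abs=1e-6)
            assert hf[t] == pytest.approx(y_hat, abs=1e-6)

    def test_spec_disables_residual_and_layer_norm(self):
        spec = ModelSpec(variant="dhtm_c", use_residual=True, use_layer_norm=True)
        assert spec.use_residual is False
        assert spec.use_layer_norm is False


class TestLstm:
    def test_matches_scalar_oracle(self):
        model = fresh_model("lstm", hidden_width=3, n_recurrent_layers=1,
                            input_width=4)
        net = model.network
        rng = np.random.default_rng(6)
        X = rng.normal(size=(5, 4))
        probs = lstm_forward(model, X)

        cell = net.cells[0]
        h = np.zeros(3)
        c = np.zeros(3)
        expected = []
        for t in range(5):
            u = X[t] @ net.dense_in.W.data + net.dense_in.b.data
            hx = np.concatenate([h, u])
            i = sigma(cell.W_i.data @ hx + cell.b_i.data)
            f = sigma(cell.W_f.data @ hx + cell.b_f.data)
            o = sigma(cell.W_o.data @ hx + cell.b_o.data)
            c = f * c + i * np.tanh(cell.W_c.data @ hx + cell.b_c.data)
            h = o * np.tanh(c)
            expected.append(sigma(h @ net.head.W.data + net.head.b.data)[0])
        assert probs == pytest.approx(np.array(expected), abs=1e-6)


class TestCheckpoint:
    def test_round_trip_preserves_outputs_and_contract(self, tmp_path):
        model = fresh_model("dhtm_c", hidden_width=5)
        model.feature_names = [f"f{i}" for i in range(20)]
        model.input_mean = np.linspace(0, 1, 20)
        model.input_std = np.full(20, 2.0)
        path = tmp_path / "model.npz"
        save_checkpoint(model, path)
        loaded = load_checkpoint(path)
        X = np.random.default_rng(8).normal(size=(6, 20))
        a_cm, a_hf = dhtmc_forward(model, X)
        b_cm, b_hf = dhtmc_forward(loaded, X)
        assert a_hf == pytest.approx(b_hf, abs=1e-15)
        assert a_cm == pytest.approx(b_cm, abs=1e-15)
        assert loaded.feature_names == model.feature_names
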