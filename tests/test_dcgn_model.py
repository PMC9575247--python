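"""Layer-level oracles and the assembled network's contracts."""

import numpy as np
import pytest

from dcgn import DCGNConfig, build_dcgn, dcgn_forward
from dcgn.activations import gelu_approx
from dcgn.dcgn_model import (
    GRUCellParams,
    ReshapeToMap,
    TrainedDCGN,
    bigru_forward,
    conv2d_forward,
    gru_cell_step,
    maxpool_forward,
)
from dcgn.preprocessing import StandardizationParams

# --- dense ------------------------------------------------------------------


def test_dense_identity_passthrough(rng):
    from dcgn.dcgn_model import Dense

    layer = Dense(4, 4, "relu", np.random.default_rng(0))
    layer.params["W"] = np.eye(4)
    layer.params["b"] = np.zeros(4)
    x = np.abs(rng.normal(size=(5, 4)))
    np.testing.assert_allclose(layer.forward(x), x)


def test_dense_matches_scalar_hand_computation():
    from dcgn.dcgn_model import Dense

    layer = Dense(2, 1, "gelu_approx", np.random.default_rng(0))
    layer.params["W"] = np.array([[0.5], [-1.5]])
    layer.params["b"] = np.array([0.25])
    x = np.array([[2.0, 1.0]])
    pre = 2.0 * 0.5 + 1.0 * (-1.5) + 0.25  # = -0.25
    assert layer.forward(x)[0, 0] == pytest.approx(float(gelu_approx(pre)), abs=1e-12)


def test_dense_preserves_batch_and_checks_width(rng):
    from dcgn.dcgn_model import Dense

    layer = Dense(6, 3, "tanh", np.random.default_rng(1))
    assert layer.forward(rng.normal(size=(17, 6))).shape == (17, 3)
    with pytest.raises(ValueError, match="width"):
        layer.forward(rng.normal(size=(17, 5)))


# --- reshape ----------------------------------------------------------------


def test_reshape_1024_to_32x32():
    x = np.arange(2 * 1024, dtype=float).reshape(2, 1024)
    y = ReshapeToMap(1024).forward(x)
    assert y.shape == (2, 32, 32, 1)
    assert y[0, 0, 1, 0] == 1.0  # row-major

    assert ReshapeToMap(64).forward(np.zeros((3, 64))).shape == (3, 8, 8, 1)
    with pytest.raises(ValueError, match="1000 is not a perfect square"):
        ReshapeToMap(1000)


# --- convolution ------------------------------------------------------------


def _naive_conv(x, kernels, stride):
    """Quadruple-loop cross-correlation with 'same' zero padding."""
    n, h, w, c = x.shape
    kh, kw, _, f = kernels.shape
    oh, ow = -(-h // stride), -(-w // stride)
    ph = max((oh - 1) * stride + kh - h, 0)
    pw = max((ow - 1) * stride + kw - w, 0)
    xp = np.pad(x, ((0, 0), (ph // 2, ph - ph // 2), (pw // 2, pw - pw // 2), (0, 0)))
    out = np.zeros((n, oh, ow, f))
    for b in range(n):
        for i in range(oh):
            for j in range(ow):
                for k in range(f):
                    patch = xp[b, i * stride : i * stride + kh,
                               j * stride : j * stride + kw, :]
                    out[b, i, j, k] = np.sum(patch * kernels[:, :, :, k])
    return out


def test_conv_shape_follows_ceil_rule(rng):
    x = rng.normal(size=(2, 32, 32, 1))
    k = rng.normal(size=(3, 3, 1, 128))
    assert conv2d_forward(x, k, stride=2).shape == (2, 16, 16, 128)


def test_conv_1x1_unit_kernel_is_identity(rng):
    x = rng.normal(size=(3, 5, 5, 1))
    k = np.ones((1, 1, 1, 1))
    np.testing.assert_allclose(conv2d_forward(x, k, stride=1), x)


def test_conv_all_ones_hand_case():
    x = np.ones((1, 3, 3, 1))
    k = np.ones((3, 3, 1, 1))
    y = conv2d_forward(x, k, stride=1)[0, :, :, 0]
    assert y[1, 1] == 9.0
    for corner in (y[0, 0], y[0, 2], y[2, 0], y[2, 2]):
        assert corner == 4.0


@pytest.mark.parametrize("stride", [1, 2])
@pytest.mark.parametrize("shape", [(5, 5, 1), (8, 8, 2), (7, 6, 2)])
def test_conv_matches_naive_loop_oracle(rng, stride, shape):
    x = rng.normal(size=(2, *shape))
    k = rng.normal(size=(3, 3, shape[2], 4))
    np.testing.assert_allclose(
        conv2d_forward(x, k, stride=stride), _naive_conv(x, k, stride), atol=1e-6
    )


def test_conv_channel_mismatch_errors(rng):
    with pytest.raises(ValueError, match="channels"):
        conv2d_forward(rng.normal(size=(1, 4, 4, 2)), rng.normal(size=(3, 3, 1, 4)))


# --- max pooling ------------------------------------------------------------


def test_maxpool_examples(rng):
    x = np.array([[1.0, 2.0], [3.0, 4.0]]).reshape(1, 2, 2, 1)
    assert maxpool_forward(x, (2, 2))[0, 0, 0, 0] == 4.0

    const = np.full((2, 4, 4, 3), 7.0)
    np.testing.assert_array_equal(maxpool_forward(const, (2, 2)), np.full((2, 2, 2, 3), 7.0))

    x = rng.normal(size=(2, 16, 16, 128))
    assert maxpool_forward(x, (2, 2), 2).shape == (2, 8, 8, 128)

    with pytest.raises(ValueError, match="larger"):
        maxpool_forward(np.zeros((1, 2, 2, 1)), (3, 3))


# --- GRU cell ---------------------------------------------------------------


def _scalar_gru_oracle(x, h, p):
    """Elementwise re-derivation of the gate equations with python loops."""
    hsz = p.hidden_size
    gin = np.concatenate([h, x])
    z = np.array([1.0 / (1.0 + np.exp(-(gin @ p.W_z[:, i] + p.b_z[i]))) for i in range(hsz)])
    r = np.array([1.0 / (1.0 + np.exp(-(gin @ p.W_r[:, i] + p.b_r[i]))) for i in range(hsz)])
    cin = np.concatenate([h * r, x])
    hc = np.array([np.tanh(cin @ p.W[:, i] + p.b[i]) for i in range(hsz)])
    return (1.0 - z) * hc + z * h


def _random_cell(rng, hsz, isz):
    tot = hsz + isz
    return GRUCellParams(
        W_z=rng.normal(size=(tot, hsz)),
        W_r=rng.normal(size=(tot, hsz)),
        W=rng.normal(size=(tot, hsz)),
        hidden_size=hsz,
        b_z=rng.normal(size=hsz),
        b_r=rng.normal(size=hsz),
        b=rng.normal(size=hsz),
    )


def test_gru_cell_matches_scalar_oracle_on_random_instances(rng):
    for _ in range(100):
        hsz = int(rng.integers(1, 5))
        isz = int(rng.integers(1, 5))
        p = _random_cell(rng, hsz, isz)
        x = rng.normal(size=isz)
        h = rng.normal(size=hsz)
        np.testing.assert_allclose(
            gru_cell_step(x, h, p), _scalar_gru_oracle(x, h, p), atol=1e-6
        )


def test_gru_update_gate_saturated_keeps_old_state(rng):
    p = _random_cell(rng, 3, 2)
    p.b_z = np.full(3, 1e3)  # drive z -> 1
    h = rng.normal(size=3)
    np.testing.assert_allclose(gru_cell_step(rng.normal(size=2), h, p), h, atol=1e-9)


def test_gru_zero_weights_halve_previous_state(rng):
    p = GRUCellParams(
        W_z=np.zeros((5, 3)), W_r=np.zeros((5, 3)), W=np.zeros((5, 3)), hidden_size=3
    )
    h = rng.normal(size=3)
    # z = r = 0.5, candidate = tanh(0) = 0, so h_new = 0.5 * h
    np.testing.assert_allclose(gru_cell_step(rng.normal(size=2), h, p), 0.5 * h)


def test_gru_shape_mismatch_errors(rng):
    p = _random_cell(rng, 3, 2)
    with pytest.raises(ValueError, match="expected input"):
        gru_cell_step(rng.normal(size=4), rng.normal(size=3), p)


# --- BiGRU ------------------------------------------------------------------


def test_bigru_single_step_reduces_to_cells(rng):
    fwd = _random_cell(rng, 3, 4)
    bwd = _random_cell(rng, 3, 4)
    x = rng.normal(size=(1, 4))
    out = bigru_forward(x, fwd, bwd)
    h0 = np.zeros(3)
    np.testing.assert_allclose(out[0, :3], gru_cell_step(x[0], h0, fwd))
    np.testing.assert_allclose(out[0, 3:], gru_cell_step(x[0], h0, bwd))


def test_bigru_reversal_symmetry(rng):
    fwd = _random_cell(rng, 3, 4)
    bwd = _random_cell(rng, 3, 4)
    x = rng.normal(size=(6, 4))
    out = bigru_forward(x, fwd, bwd)
    flipped = bigru_forward(x[::-1], bwd, fwd)
    np.testing.assert_allclose(
        flipped[::-1], np.concatenate([out[:, 3:], out[:, :3]], axis=1), atol=1e-12
    )


def test_bigru_zero_everything_stays_zero():
    z = GRUCellParams(
        W_z=np.zeros((7, 3)), W_r=np.zeros((7, 3)), W=np.zeros((7, 3)), hidden_size=3
    )
    out = bigru_forward(np.zeros((5, 4)), z, z)
    np.testing.assert_array_equal(out, 0.0)


def test_bigru_rejects_empty_sequence(rng):
    p = _random_cell(rng, 2, 3)
    with pytest.raises(ValueError, match="T >= 1"):
        bigru_forward(np.zeros((0, 3)), p, p)


def test_batched_bigru_layer_matches_reference(rng):
    """The trainable BiGRU layer agrees with the per-sample reference pass."""
    from dcgn.dcgn_model import BiGRU

    layer = BiGRU(4, 3, np.random.default_rng(5))
    x = rng.normal(size=(3, 6, 4))
    out = layer.forward(x)
    fwd = GRUCellParams(
        W_z=layer.fwd.params["Wz"], W_r=layer.fwd.params["Wr"],
        W=layer.fwd.params["Wh"], hidden_size=3,
    )
    bwd = GRUCellParams(
        W_z=layer.bwd.params["Wz"], W_r=layer.bwd.params["Wr"],
        W=layer.bwd.params["Wh"], hidden_size=3,
    )
    for b in range(3):
        np.testing.assert_allclose(out[b], bigru_forward(x[b], fwd, bwd), atol=1e-10)


# --- assembled network ------------------------------------------------------


def test_default_shape_chain_asserted_at_build():
    cfg = DCGNConfig(n_classes=10, seed=0)
    model = build_dcgn(cfg, 500)
    chain = model.shape_chain
    assert (32, 32, 1) in chain
    assert (16, 16, 128) in chain
    assert (8, 8, 128) in chain
    assert (8, 128) in chain
    assert chain[-1] == (10,)


def test_final_layer_width_matches_n_classes(small_config):
    small_config.n_classes = 10
    model = build_dcgn(small_config, 50)
    assert model.shape_chain[-1] == (10,)


def test_build_is_deterministic_under_seed(small_config):
    a = build_dcgn(small_config, 30).parameters()
    b = build_dcgn(small_config, 30).parameters()
    assert a.keys() == b.keys()
    for k in a:
        np.testing.assert_array_equal(a[k], b[k])


def test_parameter_count_matches_closed_form(small_config):
    model = build_dcgn(small_config, 30)
    c = small_config
    side = 4  # sqrt(16)
    conv1_out = ((side + 1) // 2, (side + 1) // 2, c.conv1_kernels)  # ceil(4/2)=2
    pool_out = (1, 1, c.conv1_kernels)
    t_steps, feat = 1, 1 * c.conv1_kernels
    expected = (
        (30 * c.fc_nodes + c.fc_nodes)                                  # FC
        + (3 * 3 * 1 * c.conv1_kernels + c.conv1_kernels)               # conv1
        + 2 * (3 * (c.gru_units + feat) * c.gru_units + 3 * c.gru_units)  # BiGRU
        + (3 * 3 * 1 * c.conv2_kernels + c.conv2_kernels)               # conv2
    )
    flat = 1 * ((2 * c.gru_units + 1) // 2) * c.conv2_kernels  # ceil(6/2)=3 -> 1x3x3
    widths = [flat, *c.classifier_nodes, c.n_classes]
    expected += sum(w_in * w_out + w_out for w_in, w_out in zip(widths, widths[1:]))
    assert model.n_parameters() == expected


def test_forward_contract_and_inference_determinism(small_config, rng):
    model = build_dcgn(small_config, 30)
    x = rng.normal(size=(7, 30))
    a = dcgn_forward(model, x, training=False)
    assert a.shape == (7, small_config.n_classes)
    assert np.isfinite(a).all()
    b = dcgn_forward(model, x, training=False)
    np.testing.assert_array_equal(a, b)
    with pytest.raises(ValueError, match="input must be"):
        dcgn_forward(model, rng.normal(size=(7, 31)))


def test_forward_is_row_equivariant(small_config, rng):
    model = build_dcgn(small_config, 30)
    x = rng.normal(size=(6, 30))
    perm = rng.permutation(6)
    np.testing.assert_allclose(
        dcgn_forward(model, x[perm]), dcgn_forward(model, x)[perm], atol=1e-12
    )


def test_zero_dropout_training_forward_equals_inference(small_config, rng):
    model = build_dcgn(small_config, 30)
    x = rng.normal(size=(4, 30))
    np.testing.assert_array_equal(
        model.forward(x, training=True), model.forward(x, training=False)
    )


def test_trained_model_save_load_roundtrip(tmp_path, small_config, rng):
    model = build_dcgn(small_config, 30)
    std = StandardizationParams(mean=np.zeros(30), std=np.ones(30))
    trained = TrainedDCGN(model, small_config, std, ["a", "b", "c"])
    x = rng.normal(size=(5, 30))
    before = trained.predict_logits(x)
    trained.save(tmp_path / "model")
    back = TrainedDCGN.load(tmp_path / "model")
    np.testing.assert_allclose(back.predict_logits(x), before, atol=1e-12)
    assert back.label_names == ["a", "b", "c"]
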