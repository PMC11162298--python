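import numpy as np
import pytest

from dasv import nn
from dasv.candidate_regions import Window
from dasv.dual_attention_model import (DualAttentionNet, ModelConfig,
                                       batch_to_arrays, channel_attention,
                                       load_checkpoint, save_checkpoint,
                                       spatial_attention)
from dasv.feature_encoding import WindowSample

SMALL = ModelConfig(image_channels_per_scale=[4, 8, 16], seq_embed_dim=8,
                    head_dim=16, dropout=0.0, seed=0)


def _numerical_grad(f, x, eps=1e-3):
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        orig = x[i]
        x[i] = orig + eps
        hi = f()
        x[i] = orig - eps
        lo = f()
        x[i] = orig
        g[i] = (hi - lo) / (2 * eps)
    return g


@pytest.mark.parametrize("op_name", ["conv2d", "conv1d", "softmax",
                                     "channelnorm", "maxpool2d", "amax"])
def test_gradients_match_numerical_differences(op_name, rng):
    """Analytic gradients of the core differentiable ops check out against
    central differences on small random inputs."""
    if op_name == "conv2d":
        x = rng.standard_normal((2, 3, 6, 6)).astype(np.float64)
        layer = nn.Conv2d(rng, 3, 4)
        param = layer.w
        fwd = lambda: nn.conv2d(nn.Tensor(x), layer.w, layer.b)
    elif op_name == "conv1d":
        x = rng.standard_normal((2, 3, 8)).astype(np.float64)
        layer = nn.Conv1d(rng, 3, 4)
        param = layer.w
        fwd = lambda: nn.conv1d(nn.Tensor(x), layer.w, layer.b)
    elif op_name == "softmax":
        param = nn.Parameter(rng.standard_normal((2, 3, 10)))
        fwd = lambda: nn.softmax(param, axis=2)
    elif op_name == "channelnorm":
        layer = nn.ChannelNorm(3)
        xt = nn.Parameter(rng.standard_normal((2, 3, 5, 5)))
        param = xt
        fwd = lambda: layer(xt)
    elif op_name == "maxpool2d":
        param = nn.Parameter(rng.standard_normal((2, 3, 4, 4)))
        fwd = lambda: nn.maxpool2d(param)
    else:
        param = nn.Parameter(rng.standard_normal((2, 3, 7)))
        fwd = lambda: nn.amax(param, axis=(2,))

    # scalarise with a fixed random projection so every output matters
    out0 = fwd()
    proj = rng.standard_normal(out0.shape).astype(np.float32)

    def scalar():
        return float((fwd().data * proj).sum())

    loss = nn.mean(nn.mul(fwd(), nn.Tensor(proj)),
                   axis=tuple(range(out0.data.ndim)))
    loss = nn.reshape(loss, (1,))
    loss.backward()
    analytic = param.grad * float(np.prod(out0.shape))  # undo the mean
    numeric = _numerical_grad(scalar, param.data)
    np.testing.assert_allclose(analytic, numeric, rtol=2e-2, atol=2e-2)


def test_spatial_attention_normalisation_and_uniform_case(rng):
    f1 = nn.Tensor(np.ones((2, 3, 4, 5), np.float32))
    f2 = nn.Tensor(np.ones((2, 3, 4, 5), np.float32))
    out, a = spatial_attention(f1, f2)
    np.testing.assert_allclose(a.data, 1.0 / 20, atol=1e-7)
    g1 = nn.Tensor(rng.standard_normal((2, 3, 4, 5)).astype(np.float32))
    g2 = nn.Tensor(rng.standard_normal((2, 3, 4, 5)).astype(np.float32))
    _out, a2 = spatial_attention(g1, g2)
    np.testing.assert_allclose(a2.data.sum(axis=(2, 3)), 1.0, atol=1e-5)


def test_spatial_attention_shape_mismatch_raises():
    with pytest.raises(ValueError):
        spatial_attention(nn.Tensor(np.zeros((1, 2, 3, 3))),
                          nn.Tensor(np.zeros((1, 2, 4, 4))))


def test_spatial_attention_against_out_of_graph_recompute(rng):
    """The module's attention map equals a direct numpy recomputation."""
    model = DualAttentionNet(SMALL)
    i1 = rng.random((2, 3, 100, 100)).astype(np.float32)
    black = np.zeros((2, 3, 100, 100), np.float32)
    f1 = nn.relu(model.stem_bn(model.stem(nn.Tensor(i1))))
    out, a = model.spatial(f1, nn.Tensor(black))
    # independent path: conv as explicit correlation + plain softmax
    w, b = model.spatial.conv_mask.w.data, model.spatial.conv_mask.b.data
    xp = np.pad(black, ((0, 0), (0, 0), (1, 1), (1, 1)))
    f2 = np.zeros_like(f1.data)
    for f in range(w.shape[0]):
        for c in range(3):
            for i in range(3):
                for j in range(3):
                    f2[:, f] += w[f, c, i, j] * xp[:, c, i:i + 100, j:j + 100]
        f2[:, f] += b[f]
    prod = (f1.data * f2).reshape(2, w.shape[0], -1)
    e = np.exp(prod - prod.max(axis=2, keepdims=True))
    expected = (e / e.sum(axis=2, keepdims=True)).reshape(f1.shape)
    np.testing.assert_allclose(a.data, expected, atol=1e-5)


def test_channel_attention_contract(rng):
    c = 8
    lin_a, lin_m = nn.Linear(rng, c, c), nn.Linear(rng, c, c)
    img = nn.Tensor(rng.random((3, c, 10, 10)).astype(np.float32))
    seq = nn.Tensor(rng.random((3, c, 25)).astype(np.float32))
    out, w = channel_attention(img, seq, lin_a, lin_m)
    assert ((w.data > 0) & (w.data < 1)).all()
    # independent recomputation of the gate weights
    gap = img.data.mean(axis=(2, 3))
    gmp = img.data.max(axis=(2, 3))
    z = gap @ lin_a.w.data + lin_a.b.data + gmp @ lin_m.w.data + lin_m.b.data
    np.testing.assert_allclose(w.data, 1 / (1 + np.exp(-z)), atol=1e-6)
    np.testing.assert_allclose(out.data, seq.data * w.data[:, :, None],
                               atol=1e-6)


def test_channel_attention_half_weight_halves_channel():
    c = 4
    rng = np.random.default_rng(0)
    lin_a, lin_m = nn.Linear(rng, c, c), nn.Linear(rng, c, c)
    for lin in (lin_a, lin_m):
        lin.w.data[:] = 0
        lin.b.data[:] = 0
    seq = nn.Tensor(np.arange(8, dtype=np.float32).reshape(1, c, 2))
    img = nn.Tensor(np.ones((1, c, 3, 3), np.float32))
    out, w = channel_attention(img, seq, lin_a, lin_m)
    np.testing.assert_allclose(w.data, 0.5)
    np.testing.assert_allclose(out.data, seq.data * 0.5)


def _random_samples(rng, n):
    out = []
    for i in range(n):
        i1 = rng.integers(0, 2, (100, 100, 3)).astype(np.uint8) * 255
        i2 = rng.integers(0, 2, (100, 100, 3)).astype(np.uint8) * 255
        s = rng.choice([0, 2, 3, 4, 5, 9], size=100).astype(np.int16)
        out.append(WindowSample(Window("chr1", i * 50), s, i1, i2,
                                label=int(i % 2)))
    return out


def test_forward_outputs_probability_and_determinism(rng):
    model = DualAttentionNet(SMALL)
    samples = _random_samples(rng, 6)
    p1 = model.predict_proba(samples)
    p2 = model.predict_proba(samples)
    assert ((p1 >= 0) & (p1 <= 1)).all()
    assert np.array_equal(p1, p2)


def test_ablation_differs_only_by_attention_parameters():
    full = DualAttentionNet(SMALL)
    abl = DualAttentionNet(SMALL, ablation=True)
    ch = SMALL.image_channels_per_scale
    k = SMALL.kernel_size
    spatial = ch[0] * 3 * k * k + ch[0]            # conv over I2
    gates = sum(2 * (c * c + c) for c in ch)       # per-scale channel gates
    assert full.count_parameters() - abl.count_parameters() == spatial + gates


def test_single_step_decreases_loss(rng):
    model = DualAttentionNet(SMALL)
    model.set_training(True)
    samples = _random_samples(rng, 8)
    i1, i2, s = batch_to_arrays(samples)
    y = np.array([smp.label for smp in samples], np.float32).reshape(-1, 1)
    opt = nn.Adam(model.parameters(), lr=1e-3)
    loss0 = nn.bce_with_logits(model.forward(i1, i2, s), y)
    opt.zero_grad()
    loss0.backward()
    opt.step()
    loss1 = nn.bce_with_logits(model.forward(i1, i2, s), y)
    loss1.free_graph()
    assert float(loss1.data) < float(loss0.data)


def test_checkpoint_round_trip(tmp_path, rng):
    model = DualAttentionNet(SMALL)
    samples = _random_samples(rng, 4)
    before = model.predict_proba(samples)
    path = tmp_path / "model.ckpt"
    save_checkpoint(model, path)
    loaded = load_checkpoint(path)
    after = loaded.predict_proba(samples)
    np.testing.assert_array_equal(before, after)
    assert loaded.config == model.config


def test_checkpoint_rejects_unknown_format(tmp_path):
    import json
    model = DualAttentionNet(SMALL)
    path = tmp_path / "model.ckpt"
    save_checkpoint(model, path)
    with np.load(path) as z:
        arrays = {k: z[k] for k in z.files}
    meta = json.loads(bytes(arrays["meta_json"]).decode())
    meta["format_version"] = 999
    arrays["meta_json"] = np.frombuffer(json.dumps(meta).encode(),
                                        dtype=np.uint8)
    with open(path, "wb") as fh:
        np.savez(fh, **arrays)
    with pytest.raises(ValueError, match="format"):
        load_checkpoint(path)


def test_config_validation():
    with pytest.raises(ValueError):
        ModelConfig(image_channels_per_scale=[8, 16])
    with pytest.raises(ValueError):
        ModelConfig(image_channels_per_scale=[8, 16, 32],
                    seq_channels_per_scale=[8, 16, 64])
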