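"""The dual-attention window classifier.

Two branches read each window.  The image branch runs a convolutional stem
over I1, lets the binary deletion mask I2 steer a spatial-attention map over
it, then descends three residual scales (2x2 max-pooling between scales; the
first scale keeps full resolution).  The sequence branch embeds the integer
codes of S and mirrors the same scales in 1-D; at every scale the image
branch's feature tap gates the sequence channels through channel attention
(global average + max pooling -> per-channel recalculation -> sigmoid -> a
multiplicative per-channel weight).  Globally pooled features from both
branches are concatenated into a dense head with a multiplicative residual
recalculation and a sigmoid output: the probability that the window overlaps
a deletion.

The "simple fusion" ablation keeps the identical backbone but drops both
attention mechanisms: I2 is ignored and the branch features are fused by
plain concatenation at the head.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import List, Optional, Sequence, Tuple

import numpy as np

from . import nn
from .candidate_regions import Window
from .feature_encoding import WindowSample

CHECKPOINT_FORMAT_VERSION = 1
VOCAB_SIZE = 10  # sequence codes live in {0, 2, 3, 4, 5, 9}


@dataclass
class ModelConfig:
    image_channels_per_scale: List[int] = field(default_factory=lambda: [16, 32, 64])
    seq_embed_dim: int = 16
    seq_channels_per_scale: Optional[List[int]] = None
    kernel_size: int = 3
    n_scales: int = 3
    dropout: float = 0.1
    head_dim: int = 64
    seed: int = 0

    def __post_init__(self):
        if self.seq_channels_per_scale is None:
            self.seq_channels_per_scale = list(self.image_channels_per_scale)
        if len(self.image_channels_per_scale) != self.n_scales:
            raise ValueError("image_channels_per_scale length must equal n_scales")
        if self.seq_channels_per_scale != self.image_channels_per_scale:
            # channel attention multiplies image-derived weights onto sequence
            # channels, so the per-scale channel counts must agree
            raise ValueError("sequence and image channel counts must match per scale")


@dataclass(frozen=True)
class WindowPrediction:
    window: Window
    p_del: float


# ------------------------------------------------------------- attention ops

def spatial_attention(f1: nn.Tensor, f2: nn.Tensor) -> Tuple[nn.Tensor, nn.Tensor]:
    """Deletion-mask-guided spatial attention.

    The two feature maps are multiplied elementwise, softmax-normalised over
    the spatial positions within each channel (so each channel's weights sum
    to 1), and the resulting map reweights ``f1``.  Returns (output, map).
    """
    if f1.shape != f2.shape:
        raise ValueError(f"feature map shapes differ: {f1.shape} vs {f2.shape}")
    n, c, h, w = f1.shape
    prod = nn.mul(f1, f2)
    a = nn.reshape(nn.softmax(nn.reshape(prod, (n, c, h * w)), axis=2),
                   (n, c, h, w))
    return nn.mul(a, f1), a


def channel_attention(image_features: nn.Tensor, seq_features: nn.Tensor,
                      lin_avg: nn.Linear, lin_max: nn.Linear
                      ) -> Tuple[nn.Tensor, nn.Tensor]:
    """Gate sequence channels by globally pooled image features.

    w = sigmoid(lin_avg(GAP(img)) + lin_max(GMP(img))) in (0,1)^C, applied
    multiplicatively to each sequence channel.  Returns (output, weights).
    """
    if image_features.shape[1] != seq_features.shape[1]:
        raise ValueError("channel counts differ between image and sequence")
    gap = nn.mean(image_features, axis=(2, 3))
    gmp = nn.amax(image_features, axis=(2, 3))
    w = nn.sigmoid(nn.add(lin_avg(gap), lin_max(gmp)))
    n, c = w.shape
    return nn.mul(seq_features, nn.reshape(w, (n, c, 1))), w


# ------------------------------------------------------------------- blocks

class _ResBlock2d(nn.Module):
    """conv-bn-relu-conv-bn with an additive identity shortcut."""

    def __init__(self, rng, channels, k):
        self.c1 = nn.Conv2d(rng, channels, channels, k)
        self.n1 = nn.ChannelNorm(channels)
        self.c2 = nn.Conv2d(rng, channels, channels, k)
        self.n2 = nn.ChannelNorm(channels)

    def __call__(self, x):
        y = self.n2(self.c2(nn.relu(self.n1(self.c1(x)))))
        return nn.relu(nn.add(y, x))


class _ResBlock1d(nn.Module):
    def __init__(self, rng, channels, k):
        self.c1 = nn.Conv1d(rng, channels, channels, k)
        self.n1 = nn.ChannelNorm(channels)
        self.c2 = nn.Conv1d(rng, channels, channels, k)
        self.n2 = nn.ChannelNorm(channels)

    def __call__(self, x):
        y = self.n2(self.c2(nn.relu(self.n1(self.c1(x)))))
        return nn.relu(nn.add(y, x))


class _SpatialAttention(nn.Module):
    """Owns the learnable convolution over I2 and applies spatial attention."""

    def __init__(self, rng, channels, k):
        self.conv_mask = nn.Conv2d(rng, 3, channels, k)

    def __call__(self, f1, i2):
        out, a = spatial_attention(f1, self.conv_mask(i2))
        return out, a


class _ChannelAttention(nn.Module):
    def __init__(self, rng, channels):
        self.lin_avg = nn.Linear(rng, channels, channels)
        self.lin_max = nn.Linear(rng, channels, channels)

    def __call__(self, image_features, seq_features):
        return channel_attention(image_features, seq_features,
                                 self.lin_avg, self.lin_max)


class DualAttentionNet(nn.Module):
    """The full classifier; ``ablation=True`` builds the simple-fusion variant.

    The ablation differs from the full model only by the absence of the
    attention sub-modules (the I2 stem convolution and the per-scale channel
    gates); the backbone and head are identical, so the two are comparable
    parameter-for-parameter up to exactly those sub-modules.
    """

    def __init__(self, config: ModelConfig, ablation: bool = False):
        self.config = config
        self.ablation = ablation
        rng = np.random.default_rng(config.seed)
        self._dropout_rng = np.random.default_rng(config.seed + 1)
        ch = config.image_channels_per_scale
        k = config.kernel_size

        self.stem = nn.Conv2d(rng, 3, ch[0], k)
        self.stem_bn = nn.ChannelNorm(ch[0])
        self.spatial = None if ablation else _SpatialAttention(rng, ch[0], k)

        self.img_transitions = []
        self.img_blocks = []
        for s in range(config.n_scales):
            if s > 0:
                self.img_transitions.append(
                    (nn.Conv2d(rng, ch[s - 1], ch[s], k), nn.ChannelNorm(ch[s])))
            self.img_blocks.append(_ResBlock2d(rng, ch[s], k))

        self.embed = nn.Embedding(rng, VOCAB_SIZE, config.seq_embed_dim)
        self.seq_in = nn.Conv1d(rng, config.seq_embed_dim, ch[0], k)
        self.seq_in_bn = nn.ChannelNorm(ch[0])
        self.seq_transitions = []
        self.seq_blocks = []
        self.channel_gates = []
        for s in range(config.n_scales):
            if s > 0:
                self.seq_transitions.append(
                    (nn.Conv1d(rng, ch[s - 1], ch[s], k), nn.ChannelNorm(ch[s])))
            self.seq_blocks.append(_ResBlock1d(rng, ch[s], k))
            if not ablation:
                self.channel_gates.append(_ChannelAttention(rng, ch[s]))

        head_in = 2 * ch[-1]
        self.fc1 = nn.Linear(rng, head_in, config.head_dim)
        self.gate = nn.Linear(rng, config.head_dim, config.head_dim)
        self.fc2 = nn.Linear(rng, config.head_dim, 1)

    # -- parameters must include modules stored inside (conv, bn) tuples,
    #    which the base-class scan does not descend into
    def parameters(self):
        params = super().parameters()
        for conv, bn2 in self.img_transitions + self.seq_transitions:
            params.extend(conv.parameters())
            params.extend(bn2.parameters())
        # _transition_modules would double-count; dedupe by identity
        seen, out = set(), []
        for p in params:
            if id(p) not in seen:
                seen.add(id(p))
                out.append(p)
        return out

    def modules(self):
        mods = super().modules()
        for conv, bn2 in self.img_transitions + self.seq_transitions:
            mods.extend(conv.modules())
            mods.extend(bn2.modules())
        seen, out = set(), []
        for m in mods:
            if id(m) not in seen:
                seen.add(id(m))
                out.append(m)
        return out

    # ------------------------------------------------------------- forward

    def forward(self, i1: np.ndarray, i2: np.ndarray, s_codes: np.ndarray,
                return_attention: bool = False):
        """Batched forward pass.

        ``i1``/``i2``: (N, 3, 100, 100) float32 in [0, 1]; ``s_codes``:
        (N, 100) integer codes.  Returns the logits tensor (N, 1), plus the
        per-scale attention artefacts when ``return_attention`` is set.
        """
        cfg = self.config
        x1 = nn.Tensor(i1)
        x = nn.relu(self.stem_bn(self.stem(x1)))
        spat_map = None
        if self.spatial is not None:
            x, spat_map = self.spatial(x, nn.Tensor(i2))

        taps = []
        ti = 0
        for s in range(cfg.n_scales):
            if s > 0:
                x = nn.maxpool2d(x)
                conv, bn2 = self.img_transitions[ti]
                ti += 1
                x = nn.relu(bn2(conv(x)))
            x = self.img_blocks[s](x)
            taps.append(x)

        e = self.embed(np.asarray(s_codes, dtype=np.int64))  # (N, L, D)
        q = _move_ld_to_dl(e)                                # (N, D, L)
        q = nn.relu(self.seq_in_bn(self.seq_in(q)))
        ti = 0
        gate_weights = []
        for s in range(cfg.n_scales):
            if s > 0:
                q = nn.maxpool1d(q)
                conv, bn2 = self.seq_transitions[ti]
                ti += 1
                q = nn.relu(bn2(conv(q)))
            q = self.seq_blocks[s](q)
            if not self.ablation:
                q, w = self.channel_gates[s](taps[s], q)
                gate_weights.append(w)

        img_pool = nn.mean(taps[-1], axis=(2, 3))
        seq_pool = nn.mean(q, axis=(2,))
        h = nn.relu(self.fc1(nn.concat([img_pool, seq_pool], axis=1)))
        h = nn.add(nn.mul(h, nn.sigmoid(self.gate(h))), h)
        if self.training and cfg.dropout > 0:
            h = nn.dropout(h, cfg.dropout, self._dropout_rng)
        logits = self.fc2(h)
        if return_attention:
            return logits, spat_map, gate_weights
        return logits

    def predict_proba(self, samples: Sequence[WindowSample],
                      batch_size: int = 64) -> np.ndarray:
        """Deterministic per-window deletion probabilities (eval mode)."""
        self.set_training(False)
        out = np.empty(len(samples), dtype=np.float64)
        for lo in range(0, len(samples), batch_size):
            batch = samples[lo:lo + batch_size]
            i1, i2, s = batch_to_arrays(batch)
            logits = self.forward(i1, i2, s)
            z = logits.data[:, 0]
            logits.free_graph()
            out[lo:lo + len(batch)] = np.where(
                z >= 0, 1.0 / (1.0 + np.exp(-np.abs(z))),
                np.exp(-np.abs(z)) / (1.0 + np.exp(-np.abs(z))))
        return out

    def count_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))


def _move_ld_to_dl(x: nn.Tensor) -> nn.Tensor:
    """(N, L, D) -> (N, D, L) with gradient support."""
    out = nn.Tensor(np.ascontiguousarray(x.data.transpose(0, 2, 1)),
                    x.requires_grad, (x,))

    def bwd():
        if x.requires_grad:
            if x.grad is None:
                x.grad = np.zeros_like(x.data)
            x.grad += out.grad.transpose(0, 2, 1)

    out._backward = bwd
    return out


# ----------------------------------------------------------- array plumbing

def sample_to_arrays(sample: WindowSample):
    i1 = (sample.I1.astype(np.float32) / 255.0).transpose(2, 0, 1)
    i2 = (sample.I2.astype(np.float32) / 255.0).transpose(2, 0, 1)
    return i1, i2, sample.S.astype(np.int64)


def batch_to_arrays(samples: Sequence[WindowSample]):
    i1 = np.stack([(s.I1.astype(np.float32) / 255.0).transpose(2, 0, 1)
                   for s in samples])
    i2 = np.stack([(s.I2.astype(np.float32) / 255.0).transpose(2, 0, 1)
                   for s in samples])
    codes = np.stack([s.S.astype(np.int64) for s in samples])
    return i1, i2, codes


def predict_windows(model: DualAttentionNet,
                    samples: Sequence[WindowSample]) -> List[WindowPrediction]:
    probs = model.predict_proba(samples)
    return [WindowPrediction(s.window, float(p))
            for s, p in zip(samples, probs)]


# ------------------------------------------------------------- checkpointing

def save_checkpoint(model: DualAttentionNet, path) -> None:
    """Single-file checkpoint: parameters, embedded config JSON, version."""
    arrays = {f"param_{i}": p.data for i, p in enumerate(model.parameters())}
    meta = {"format_version": CHECKPOINT_FORMAT_VERSION,
            "ablation": model.ablation,
            "config": asdict(model.config)}
    arrays["meta_json"] = np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8)
    with open(path, "wb") as fh:
        np.savez(fh, **arrays)


def load_checkpoint(path) -> DualAttentionNet:
    with np.load(path) as z:
        meta = json.loads(bytes(z["meta_json"]).decode())
        if meta.get("format_version") != CHECKPOINT_FORMAT_VERSION:
            raise ValueError(
                f"unsupported checkpoint format: {meta.get('format_version')}")
        config = ModelConfig(**meta["config"])
        model = DualAttentionNet(config, ablation=meta["ablation"])
        params = model.parameters()
        for i, p in enumerate(params):
            data = z[f"param_{i}"]
            if data.shape != p.data.shape:
                raise ValueError("checkpoint does not match model config "
                                 f"(param {i}: {data.shape} vs {p.data.shape})")
            p.data = data.astype(np.float32)
    model.set_training(False)
    return model
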