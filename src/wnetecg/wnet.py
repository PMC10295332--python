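"""The W-Net: two cascaded 1-D U-blocks mapping a PPG segment to an ECG segment.

Each U-block is a fully convolutional encoder-decoder in the wave U-Net
lineage: ``depth`` encoder stages of (conv k15 -> batchnorm -> leaky ReLU
-> maxpool /2), a bottleneck, and ``depth`` decoder stages of (upsample x2
-> concat skip -> conv -> batchnorm -> leaky ReLU), with channel
concatenation (not addition) of the matching-resolution encoder output.
Channel widths double per level from ``base_filters``.

The W-Net feeds the raw PPG through U-block 1, concatenates U-block 1's
output with the raw PPG on the channel axis, passes that through U-block 2,
and finishes with a kernel-1 convolution to one channel activated directly
by leaky ReLU with **no** batch normalization — the output is therefore
unbounded, so reconstructed R waves can exceed 1 mV without any output
rescaling.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import List, Optional, Sequence

import numpy as np

from . import nn
from .types import SegmentPair

__all__ = ["WNetConfig", "UBlock", "WNet", "build_ublock", "build_wnet",
           "reconstruct_segments", "save_model", "load_model"]


@dataclass
class WNetConfig:
    """Architecture hyperparameters.

    kernel_size 15, final_kernel_size 1 and leaky_slope 0.1 are the fixed
    published values; depth and base_filters are schematic in the source
    architecture diagram and are exposed as knobs (defaults 4 and 16).
    """

    depth: int = 4
    base_filters: int = 16
    kernel_size: int = 15
    final_kernel_size: int = 1
    leaky_slope: float = 0.1
    pool_factor: int = 2
    upsample_factor: int = 2
    input_length: int = 1024
    upsample_mode: str = "nearest"

    def __post_init__(self) -> None:
        if self.depth < 1 or self.base_filters < 1:
            raise ValueError("depth and base_filters must be >= 1")
        if self.kernel_size % 2 != 1:
            raise ValueError("kernel_size must be odd")
        if self.input_length % (self.pool_factor ** self.depth) != 0:
            raise ValueError(
                f"input_length {self.input_length} not divisible by "
                f"pool_factor^depth = {self.pool_factor ** self.depth}"
            )


class UBlock:
    """One encoder-decoder block; output length == input length,
    output channels == base_filters."""

    def __init__(self, cfg: WNetConfig, in_channels: int, rng: np.random.Generator,
                 name: str = "u"):
        d, f, k = cfg.depth, cfg.base_filters, cfg.kernel_size
        self.cfg = cfg
        self.enc_convs, self.enc_bns, self.enc_acts, self.pools = [], [], [], []
        c_in = in_channels
        for i in range(d):
            c_out = f * 2 ** i
            self.enc_convs.append(nn.Conv1d(c_in, c_out, k, rng, name=f"{name}.enc{i}"))
            self.enc_bns.append(nn.BatchNorm1d(c_out, name=f"{name}.enc{i}"))
            self.enc_acts.append(nn.LeakyReLU(cfg.leaky_slope))
            self.pools.append(nn.MaxPool1d(cfg.pool_factor))
            c_in = c_out
        c_bott = f * 2 ** d
        self.bott_conv = nn.Conv1d(c_in, c_bott, k, rng, name=f"{name}.bott")
        self.bott_bn = nn.BatchNorm1d(c_bott, name=f"{name}.bott")
        self.bott_act = nn.LeakyReLU(cfg.leaky_slope)
        self.ups, self.dec_convs, self.dec_bns, self.dec_acts = [], [], [], []
        c_prev = c_bott
        for i in reversed(range(d)):
            c_skip = f * 2 ** i
            self.ups.append(nn.Upsample1d(cfg.upsample_factor, cfg.upsample_mode))
            self.dec_convs.append(nn.Conv1d(c_prev + c_skip, c_skip, k, rng,
                                            name=f"{name}.dec{i}"))
            self.dec_bns.append(nn.BatchNorm1d(c_skip, name=f"{name}.dec{i}"))
            self.dec_acts.append(nn.LeakyReLU(cfg.leaky_slope))
            c_prev = c_skip
        self.out_channels = c_prev

    def _layers(self):
        yield from self.enc_convs
        yield from self.enc_bns
        yield self.bott_conv
        yield self.bott_bn
        yield from self.dec_convs
        yield from self.dec_bns

    def parameters(self) -> List[nn.Parameter]:
        out: List[nn.Parameter] = []
        for layer in self._layers():
            out.extend(layer.parameters())
        return out

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        d = self.cfg.depth
        skips = []
        for i in range(d):
            x = self.enc_acts[i].forward(
                self.enc_bns[i].forward(
                    self.enc_convs[i].forward(x, training), training), training)
            skips.append(x)
            x = self.pools[i].forward(x, training)
        x = self.bott_act.forward(
            self.bott_bn.forward(self.bott_conv.forward(x, training), training),
            training)
        self._skip_channels = [s.shape[2] for s in skips]
        for j, i in enumerate(reversed(range(d))):
            x = self.ups[j].forward(x, training)
            x = nn.concat_channels([x, skips[i]])
            x = self.dec_acts[j].forward(
                self.dec_bns[j].forward(self.dec_convs[j].forward(x, training),
                                        training), training)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        d = self.cfg.depth
        dskips = [None] * d
        x = dy
        # decoder in reverse execution order: j = d-1 .. 0, encoder level i = d-1-j
        for j in reversed(range(d)):
            i = d - 1 - j
            x = self.dec_convs[j].backward(
                self.dec_bns[j].backward(self.dec_acts[j].backward(x)))
            c_skip = self._skip_channels[i]
            x, dskip = nn.split_channels(x, [x.shape[2] - c_skip, c_skip])
            dskips[i] = dskip
            x = self.ups[j].backward(x)
        x = self.bott_conv.backward(self.bott_bn.backward(self.bott_act.backward(x)))
        for i in reversed(range(d)):
            x = self.pools[i].backward(x) + dskips[i]
            x = self.enc_convs[i].backward(
                self.enc_bns[i].backward(self.enc_acts[i].backward(x)))
        return x


class WNet:
    """Two U-blocks plus a kernel-1 output convolution.

    Carries the PPG z-score normalization statistics learned from the
    training split (``ppg_mean``/``ppg_std``) so that inference applies the
    same transform as training.
    """

    def __init__(self, cfg: WNetConfig, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.cfg = cfg
        self.u1 = UBlock(cfg, in_channels=1, rng=rng, name="u1")
        self.u2 = UBlock(cfg, in_channels=cfg.base_filters + 1, rng=rng, name="u2")
        self.final_conv = nn.Conv1d(cfg.base_filters, 1, cfg.final_kernel_size,
                                    rng, name="final")
        self.final_act = nn.LeakyReLU(cfg.leaky_slope)
        self.ppg_mean: float = 0.0
        self.ppg_std: float = 1.0

    def parameters(self) -> List[nn.Parameter]:
        return self.u1.parameters() + self.u2.parameters() + self.final_conv.parameters()

    def num_parameters(self) -> int:
        return sum(p.value.size for p in self.parameters())

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        """Forward pass on (already normalized) input, (B, L, 1) -> (B, L, 1)."""
        if x.ndim != 3 or x.shape[2] != 1:
            raise ValueError(f"expected input of shape (B, L, 1), got {x.shape}")
        if x.shape[1] != self.cfg.input_length:
            raise ValueError(
                f"segment length {x.shape[1]} != configured input_length "
                f"{self.cfg.input_length}"
            )
        h1 = self.u1.forward(x, training)
        h = nn.concat_channels([h1, x])
        h2 = self.u2.forward(h, training)
        y = self.final_conv.forward(h2, training)
        return self.final_act.forward(y, training)

    def backward(self, dy: np.ndarray) -> None:
        d = self.final_conv.backward(self.final_act.backward(dy))
        d = self.u2.backward(d)
        d_h1, _d_input = nn.split_channels(d, [self.cfg.base_filters, 1])
        self.u1.backward(d_h1)

    # ---- inference -------------------------------------------------------

    def normalize(self, ppg: np.ndarray) -> np.ndarray:
        return (ppg - self.ppg_mean) / self.ppg_std

    def reconstruct(self, ppg_segments: Sequence[np.ndarray],
                    batch_size: int = 32) -> List[np.ndarray]:
        """Reconstruct ECG (mV) from PPG windows in inference mode."""
        segs = [np.asarray(s, dtype=np.float64) for s in ppg_segments]
        for i, s in enumerate(segs):
            if s.ndim != 1 or s.size != self.cfg.input_length:
                raise ValueError(
                    f"segment {i} has length {s.size}, expected "
                    f"{self.cfg.input_length}"
                )
        out: List[np.ndarray] = []
        for i in range(0, len(segs), batch_size):
            batch = np.stack(segs[i:i + batch_size]).astype(nn.DTYPE)[:, :, None]
            y = self.forward(self.normalize(batch), training=False)
            out.extend(np.asarray(yi, dtype=np.float64) for yi in y[:, :, 0])
        return out


def build_ublock(cfg: WNetConfig, in_channels: int = 1, seed: int = 0) -> UBlock:
    """Build a standalone U-block (mainly for inspection and tests)."""
    return UBlock(cfg, in_channels, np.random.default_rng(seed))


def build_wnet(cfg: WNetConfig = WNetConfig(), seed: int = 0) -> WNet:
    """Build a freshly initialized W-Net with reproducible weights."""
    return WNet(cfg, seed=seed)


def reconstruct_segments(model, ppg_segments: Sequence[np.ndarray]) -> List[np.ndarray]:
    """Run a model on a list of PPG windows; order preserved, one output
    array (mV) per input of identical length."""
    if not ppg_segments:
        return []
    return model.reconstruct(ppg_segments)


# ---- checkpointing -------------------------------------------------------

def save_model(model: WNet, path) -> Path:
    """Save weights (+BN running stats) as .npz with a JSON sidecar holding
    the architecture config and PPG normalization parameters."""
    path = Path(path)
    arrays = {}
    for i, p in enumerate(model.parameters()):
        arrays[f"param_{i}"] = p.value
    for j, ub in enumerate((model.u1, model.u2)):
        for k, layer in enumerate(ub._layers()):
            if isinstance(layer, nn.BatchNorm1d):
                arrays[f"bn_{j}_{k}_mean"] = layer.running_mean
                arrays[f"bn_{j}_{k}_var"] = layer.running_var
    np.savez(path.with_suffix(".npz"), **arrays)
    sidecar = {"wnet_config": asdict(model.cfg),
               "ppg_mean": model.ppg_mean, "ppg_std": model.ppg_std}
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
    return path.with_suffix(".npz")


def load_model(path) -> WNet:
    """Load a checkpoint written by :func:`save_model`."""
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    cfg = WNetConfig(**sidecar["wnet_config"])
    model = WNet(cfg, seed=0)
    model.ppg_mean = float(sidecar["ppg_mean"])
    model.ppg_std = float(sidecar["ppg_std"])
    data = np.load(path.with_suffix(".npz"))
    for i, p in enumerate(model.parameters()):
        p.value[...] = data[f"param_{i}"]
    for j, ub in enumerate((model.u1, model.u2)):
        for k, layer in enumerate(ub._layers()):
            if isinstance(layer, nn.BatchNorm1d):
                layer.running_mean = data[f"bn_{j}_{k}_mean"]
                layer.running_var = data[f"bn_{j}_{k}_var"]
    return model
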