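"""Dual-encoder fusion network and the single-stream concatenation baseline.

Both models map a fine-resolution optical patch (side ``2s``) and a coarse
SAR patch (side ``s``) to per-pixel class logits at the fine resolution.

Dual-encoder layout (``YNet``): each input passes through its own first
convolution block; the optical features are max-pooled once to the coarse
grid and concatenated channel-wise with the SAR features (early fusion).  A
shared encoder-decoder then runs at the coarse scale and below, with skip
connections from every encoder level plus the SAR stem, and a final 2x
upsampling stage that concatenates the pre-pool optical stem features to
restore fine detail.

Baseline (``UNetConcat``): the optical patch is max-pooled to the coarse grid
and concatenated with the SAR patch into a single multi-channel input to a
standard U-Net whose decoder upsamples back to the fine grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from dryshift.ynet_model.layers import (
    BatchNorm2d,
    Conv2d,
    ConvBlock,
    MaxPool2,
    UpsampleNearest2,
)
from dryshift.ynet_model.loss import softmax


@dataclass
class YNetConfig:
    """Architecture hyper-parameters shared by both builders.

    ``base_width`` 16 is the desk-scale default (64 for full scale);
    ``depth`` counts shared-encoder levels, so valid patch sides are
    multiples of ``2**depth`` on the optical grid.
    """

    optical_channels: int = 6  # R, G, B, NIR, NDVI, GNDVI
    sar_channels: int = 4
    n_classes: int = 6
    base_width: int = 16
    depth: int = 4
    fusion_point: str = "after_first_conv_block"

    def __post_init__(self):
        if self.depth < 2:
            raise ValueError("depth must be >= 2")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if self.base_width < 1 or self.optical_channels < 1 or self.sar_channels < 1:
            raise ValueError("channel/width fields must be positive")


class _ModelBase:
    def params(self):
        raise NotImplementedError

    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.params()))

    def zero_grad(self):
        for p in self.params():
            p.grad[...] = 0.0

    def bn_params(self):
        """Batch-norm scale/shift params (typically exempt from weight decay)."""
        out = []
        for bn in self._bns:
            out.extend(bn.params())
        return out

    def state_dict(self) -> dict:
        state = {f"param_{i}": p.value.copy() for i, p in enumerate(self.params())}
        for i, bn in enumerate(self._bns):
            state[f"bn_{i}_mean"] = bn.running_mean.copy()
            state[f"bn_{i}_var"] = bn.running_var.copy()
        return state

    def load_state_dict(self, state: dict):
        for i, p in enumerate(self.params()):
            p.value[...] = state[f"param_{i}"]
        for i, bn in enumerate(self._bns):
            bn.running_mean[...] = state[f"bn_{i}_mean"]
            bn.running_var[...] = state[f"bn_{i}_var"]

    def _collect_bns(self, blocks) -> list:
        bns = []
        for blk in blocks:
            if isinstance(blk, ConvBlock):
                bns.extend([blk.bn1, blk.bn2])
            elif isinstance(blk, BatchNorm2d):
                bns.append(blk)
        return bns

    def predict_proba(self, optical: np.ndarray, sar: np.ndarray) -> np.ndarray:
        """Per-pixel class probabilities (inference mode)."""
        logits = self.forward(optical, sar, training=False)
        return softmax(logits, axis=1)


def _check_inputs(cfg: YNetConfig, optical: np.ndarray, sar: np.ndarray):
    if optical.ndim != 4 or sar.ndim != 4:
        raise ValueError("inputs must be (batch, channels, rows, cols)")
    if optical.shape[1] != cfg.optical_channels:
        raise ValueError(
            f"optical channels: expected {cfg.optical_channels}, got {optical.shape[1]}"
        )
    if sar.shape[1] != cfg.sar_channels:
        raise ValueError(f"sar channels: expected {cfg.sar_channels}, got {sar.shape[1]}")
    if optical.shape[0] != sar.shape[0]:
        raise ValueError("batch size mismatch between optical and SAR inputs")
    oh, ow = optical.shape[2:]
    sh, sw = sar.shape[2:]
    if (oh, ow) != (2 * sh, 2 * sw):
        raise ValueError(
            f"fusion stage: pooled optical grid {oh // 2}x{ow // 2} does not match "
            f"SAR grid {sh}x{sw}"
        )
    div = 2**cfg.depth
    if oh % div or ow % div:
        raise ValueError(
            f"optical patch side must be divisible by 2**depth={div}, got {oh}x{ow}"
        )


class YNet(_ModelBase):
    """Dual-stem fusion segmentation network."""

    def __init__(self, config: YNetConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        w, d = config.base_width, config.depth

        self.opt_stem = ConvBlock(config.optical_channels, w, rng)
        self.opt_pool = MaxPool2()
        self.sar_stem = ConvBlock(config.sar_channels, w, rng)

        def width(level):  # shared-encoder width at coarse-scale level
            return 2 * w * 2**level

        self.enc_blocks = [ConvBlock(2 * w, width(0), rng)]
        self.enc_pools = []
        for lvl in range(1, d):
            self.enc_pools.append(MaxPool2())
            self.enc_blocks.append(ConvBlock(width(lvl - 1), width(lvl), rng))

        self.dec_ups = []
        self.dec_blocks = []
        for lvl in range(d - 2, -1, -1):
            self.dec_ups.append(UpsampleNearest2())
            c_in = width(lvl + 1) + width(lvl) + (w if lvl == 0 else 0)  # + SAR stem skip
            self.dec_blocks.append(ConvBlock(c_in, width(lvl), rng))

        self.final_up = UpsampleNearest2()
        self.head = ConvBlock(width(0) + w, w, rng)
        self.classifier = Conv2d(w, config.n_classes, 1, rng)

        self._blocks = (
            [self.opt_stem, self.sar_stem]
            + self.enc_blocks
            + self.dec_blocks
            + [self.head, self.classifier]
        )
        self._bns = self._collect_bns(self._blocks)
        self._fwd = None

    def params(self):
        out = []
        for blk in self._blocks:
            out.extend(blk.params())
        return out

    def forward(self, optical: np.ndarray, sar: np.ndarray, training: bool = False):
        cfg = self.config
        _check_inputs(cfg, optical, sar)
        d = cfg.depth

        f_opt = self.opt_stem.forward(optical, training)  # w @ fine
        p_opt = self.opt_pool.forward(f_opt, training)  # w @ coarse
        f_sar = self.sar_stem.forward(sar, training)  # w @ coarse

        x = np.concatenate([p_opt, f_sar], axis=1)
        skips = []
        x = self.enc_blocks[0].forward(x, training)
        skips.append(x)
        for lvl in range(1, d):
            x = self.enc_pools[lvl - 1].forward(x, training)
            x = self.enc_blocks[lvl].forward(x, training)
            if lvl < d - 1:
                skips.append(x)

        cat_channels = []
        for i, lvl in enumerate(range(d - 2, -1, -1)):
            x = self.dec_ups[i].forward(x, training)
            pieces = [x, skips[lvl]] + ([f_sar] if lvl == 0 else [])
            cat_channels.append([p.shape[1] for p in pieces])
            x = self.dec_blocks[i].forward(np.concatenate(pieces, axis=1), training)

        x = self.final_up.forward(x, training)
        head_cat = [x.shape[1], f_opt.shape[1]]
        x = self.head.forward(np.concatenate([x, f_opt], axis=1), training)
        logits = self.classifier.forward(x, training)
        self._fwd = {"cat_channels": cat_channels, "head_cat": head_cat, "depth": d}
        return logits

    def backward(self, dlogits: np.ndarray):
        fwd = self._fwd
        d = fwd["depth"]
        g = self.classifier.backward(dlogits)
        g = self.head.backward(g)
        c_up, c_fopt = fwd["head_cat"]
        g_fopt = g[:, c_up:]
        g = self.final_up.backward(g[:, :c_up])

        g_skips = [None] * (d - 1)
        g_fsar = None
        # dec_blocks[j] handled level d-2-j; reverse from the last applied (level 0).
        g_cur = g
        for j in range(d - 2, -1, -1):
            lvl = d - 2 - j  # level handled by dec_blocks[j]
            gcat = self.dec_blocks[j].backward(g_cur)
            sizes = fwd["cat_channels"][j]
            c0 = sizes[0]
            g_up = gcat[:, :c0]
            g_skip = gcat[:, c0 : c0 + sizes[1]]
            if lvl == 0:
                g_fsar = gcat[:, c0 + sizes[1] :]
            g_skips[lvl] = g_skip
            g_cur = self.dec_ups[j].backward(g_up)

        # encoder reverse: g_cur is gradient at bottleneck output
        for lvl in range(d - 1, 0, -1):
            gb = self.enc_blocks[lvl].backward(g_cur)
            g_cur = self.enc_pools[lvl - 1].backward(gb)
            if lvl - 1 >= 0 and g_skips[lvl - 1] is not None:
                g_cur = g_cur + g_skips[lvl - 1]
                g_skips[lvl - 1] = None
        g_cat = self.enc_blocks[0].backward(g_cur)

        w = self.config.base_width
        g_popt = g_cat[:, :w]
        g_sar_feat = g_cat[:, w:]
        if g_fsar is not None:
            g_sar_feat = g_sar_feat + g_fsar
        g_sar_in = self.sar_stem.backward(g_sar_feat)
        g_fopt_total = self.opt_pool.backward(g_popt) + g_fopt
        g_opt_in = self.opt_stem.backward(g_fopt_total)
        return g_opt_in, g_sar_in


class UNetConcat(_ModelBase):
    """Single-stream baseline: pooled optical + SAR concatenated at the coarse grid."""

    def __init__(self, config: YNetConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        w, d = config.base_width, config.depth
        c_in = config.optical_channels + config.sar_channels

        self.input_pool = MaxPool2()

        def width(level):
            return w * 2**level

        self.enc_blocks = [ConvBlock(c_in, width(0), rng)]
        self.enc_pools = []
        for lvl in range(1, d):
            self.enc_pools.append(MaxPool2())
            self.enc_blocks.append(ConvBlock(width(lvl - 1), width(lvl), rng))

        self.dec_ups = []
        self.dec_blocks = []
        for lvl in range(d - 2, -1, -1):
            self.dec_ups.append(UpsampleNearest2())
            self.dec_blocks.append(ConvBlock(width(lvl + 1) + width(lvl), width(lvl), rng))

        self.final_up = UpsampleNearest2()
        self.head = ConvBlock(width(0), w, rng)
        self.classifier = Conv2d(w, config.n_classes, 1, rng)

        self._blocks = self.enc_blocks + self.dec_blocks + [self.head, self.classifier]
        self._bns = self._collect_bns(self._blocks)

    def params(self):
        out = []
        for blk in self._blocks:
            out.extend(blk.params())
        return out

    def forward(self, optical: np.ndarray, sar: np.ndarray, training: bool = False):
        cfg = self.config
        _check_inputs(cfg, optical, sar)
        d = cfg.depth
        x = np.concatenate([self.input_pool.forward(optical, training), sar], axis=1)
        skips = []
        x = self.enc_blocks[0].forward(x, training)
        skips.append(x)
        for lvl in range(1, d):
            x = self.enc_pools[lvl - 1].forward(x, training)
            x = self.enc_blocks[lvl].forward(x, training)
            if lvl < d - 1:
                skips.append(x)
        self._skip_channels = [s.shape[1] for s in skips]
        for j, lvl in enumerate(range(d - 2, -1, -1)):
            x = self.dec_ups[j].forward(x, training)
            x = self.dec_blocks[j].forward(np.concatenate([x, skips[lvl]], axis=1), training)
        x = self.final_up.forward(x, training)
        x = self.head.forward(x, training)
        return self.classifier.forward(x, training)

    def backward(self, dlogits: np.ndarray):
        d = self.config.depth
        g = self.classifier.backward(dlogits)
        g = self.head.backward(g)
        g = self.final_up.backward(g)
        g_skips = [None] * (d - 1)
        for j in range(d - 2, -1, -1):
            lvl = d - 2 - j
            gcat = self.dec_blocks[j].backward(g)
            c_skip = self._skip_channels[lvl]
            c_up = gcat.shape[1] - c_skip
            g_skips[lvl] = gcat[:, c_up:]
            g = self.dec_ups[j].backward(gcat[:, :c_up])
        for lvl in range(d - 1, 0, -1):
            gb = self.enc_blocks[lvl].backward(g)
            g = self.enc_pools[lvl - 1].backward(gb)
            if g_skips[lvl - 1] is not None:
                g = g + g_skips[lvl - 1]
        g_in = self.enc_blocks[0].backward(g)
        c_opt = self.config.optical_channels
        g_opt = self.input_pool.backward(g_in[:, :c_opt])
        return g_opt, g_in[:, c_opt:]


def build_ynet(config: YNetConfig, seed: int = 0) -> YNet:
    """Construct the dual-encoder model; raises on incompatible configs."""
    return YNet(config, seed=seed)


def build_unet_concat(config: YNetConfig, seed: int = 0) -> UNetConcat:
    """Construct the single-stream concatenation baseline."""
    return UNetConcat(config, seed=seed)


def forward(model: _ModelBase, optical_patch: np.ndarray, sar_patch: np.ndarray) -> np.ndarray:
    """Inference-mode per-pixel class probabilities at the fine resolution."""
    return model.predict_proba(optical_patch, sar_patch)
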