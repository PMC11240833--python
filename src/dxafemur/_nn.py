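"""Minimal NumPy convolutional encoder-decoder for pixel classification.

Architecture (channels-first, 'same' zero padding):

    input (1,H,W)
      -> conv 3x3 (C) + ReLU          encoder
      -> maxpool 2x2
      -> conv 3x3 (2C) + ReLU         bottleneck
      -> nearest upsample x2          decoder
      -> conv 3x3 (C) + ReLU
      -> conv 1x1 (3) + softmax       per-class score maps

Trained with weighted cross-entropy under Adadelta.  Everything is plain
NumPy with manual backpropagation, so a fixed seed gives bit-identical
training runs on a fixed backend.
"""
from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["TinyEncoderDecoder", "Adadelta"]


def _conv_fwd(x: np.ndarray, w: np.ndarray, b: np.ndarray):
    """'same' 3x3 convolution. x: (B,Cin,H,W), w: (Cout,Cin,3,3)."""
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    win = sliding_window_view(xp, (3, 3), axis=(2, 3))  # (B,Cin,H,W,3,3)
    out = np.einsum("bchwij,ocij->bohw", win, w, optimize=True)
    return out + b[None, :, None, None], win


def _conv_bwd(win: np.ndarray, w: np.ndarray, dout: np.ndarray, x_shape):
    dw = np.einsum("bchwij,bohw->ocij", win, dout, optimize=True)
    db = dout.sum(axis=(0, 2, 3))
    dp = np.pad(dout, ((0, 0), (0, 0), (1, 1), (1, 1)))
    dwin = sliding_window_view(dp, (3, 3), axis=(2, 3))
    # full correlation with the flipped kernel gives the input gradient
    dx = np.einsum("bohwij,ocij->bchw", dwin, w[:, :, ::-1, ::-1], optimize=True)
    return dx, dw, db


class Adadelta:
    """Adadelta accumulator; ``lr`` scales the computed update."""

    def __init__(self, params: dict, lr: float = 0.2, rho: float = 0.95, eps: float = 1e-6):
        self.lr = lr
        self.rho = rho
        self.eps = eps
        self.eg2 = {k: np.zeros_like(v) for k, v in params.items()}
        self.edx2 = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict, grads: dict) -> None:
        for k, g in grads.items():
            self.eg2[k] = self.rho * self.eg2[k] + (1 - self.rho) * g * g
            dx = -np.sqrt(self.edx2[k] + self.eps) / np.sqrt(self.eg2[k] + self.eps) * g
            self.edx2[k] = self.rho * self.edx2[k] + (1 - self.rho) * dx * dx
            params[k] += self.lr * dx


class TinyEncoderDecoder:
    """Small 3-class encoder-decoder pixel classifier."""

    N_CLASSES = 3

    def __init__(self, channels: int = 8, seed: int = 0):
        rng = np.random.default_rng(seed)
        c = channels
        he = lambda *shape: rng.standard_normal(shape) * np.sqrt(
            2.0 / np.prod(shape[1:])
        )
        self.params = {
            "w1": he(c, 1, 3, 3), "b1": np.zeros(c),
            "w2": he(2 * c, c, 3, 3), "b2": np.zeros(2 * c),
            "w3": he(c, 2 * c, 3, 3), "b3": np.zeros(c),
            "w4": he(self.N_CLASSES, c), "b4": np.zeros(self.N_CLASSES),
        }
        self.channels = c
        # input normalization constants, set by the trainer
        self.in_shift = 0.0
        self.in_scale = 1.0

    # ---- forward -----------------------------------------------------
    def forward(self, x: np.ndarray):
        """x: (B,1,H,W) with H, W even. Returns (probs, cache)."""
        p = self.params
        z1, win1 = _conv_fwd(x, p["w1"], p["b1"])
        a1 = np.maximum(z1, 0.0)
        B, C, H, W = a1.shape
        blocks = a1.reshape(B, C, H // 2, 2, W // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        flat = blocks.reshape(B, C, H // 2, W // 2, 4)
        amax = flat.argmax(axis=-1)
        pooled = np.take_along_axis(flat, amax[..., None], axis=-1)[..., 0]
        z2, win2 = _conv_fwd(pooled, p["w2"], p["b2"])
        a2 = np.maximum(z2, 0.0)
        up = a2.repeat(2, axis=2).repeat(2, axis=3)
        z3, win3 = _conv_fwd(up, p["w3"], p["b3"])
        a3 = np.maximum(z3, 0.0)
        logits = np.einsum("bchw,oc->bohw", a3, p["w4"]) + p["b4"][None, :, None, None]
        logits -= logits.max(axis=1, keepdims=True)
        e = np.exp(logits)
        probs = e / e.sum(axis=1, keepdims=True)
        cache = (x, win1, z1, amax, pooled, win2, z2, up, win3, z3, a3)
        return probs, cache

    # ---- loss + gradients -------------------------------------------
    def loss_and_grads(self, x: np.ndarray, onehot: np.ndarray, class_w: np.ndarray):
        """Weighted cross-entropy over all pixels of the batch.

        onehot: (B,3,H,W); class_w: (3,).  Returns (loss, grads).
        """
        probs, cache = self.forward(x)
        (x0, win1, z1, amax, pooled, win2, z2, up, win3, z3, a3) = cache
        B, _, H, W = probs.shape
        npix = B * H * W
        wpix = np.einsum("bchw,c->bhw", onehot, class_w)  # weight of each pixel
        logp = np.log(np.clip(probs, 1e-7, 1.0))
        loss = -np.einsum("bchw,c,bchw->", onehot, class_w, logp) / npix

        p = self.params
        dlogits = (probs - onehot) * wpix[:, None, :, :] / npix
        dw4 = np.einsum("bohw,bchw->oc", dlogits, a3)
        db4 = dlogits.sum(axis=(0, 2, 3))
        da3 = np.einsum("bohw,oc->bchw", dlogits, p["w4"])
        dz3 = da3 * (z3 > 0)
        dup, dw3, db3 = _conv_bwd(win3, p["w3"], dz3, up.shape)
        # nearest-upsample backward: sum each 2x2 block
        Bh, Ch = dup.shape[0], dup.shape[1]
        da2 = dup.reshape(Bh, Ch, dup.shape[2] // 2, 2, dup.shape[3] // 2, 2).sum(
            axis=(3, 5)
        )
        dz2 = da2 * (z2 > 0)
        dpooled, dw2, db2 = _conv_bwd(win2, p["w2"], dz2, pooled.shape)
        # maxpool backward: scatter to argmax positions
        da1_flat = np.zeros((B, self.channels, H // 2, W // 2, 4))
        np.put_along_axis(da1_flat, amax[..., None], dpooled[..., None], axis=-1)
        da1 = (
            da1_flat.reshape(B, self.channels, H // 2, W // 2, 2, 2)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(B, self.channels, H, W)
        )
        dz1 = da1 * (z1 > 0)
        _, dw1, db1 = _conv_bwd(win1, p["w1"], dz1, x0.shape)
        grads = {
            "w1": dw1, "b1": db1, "w2": dw2, "b2": db2,
            "w3": dw3, "b3": db3, "w4": dw4, "b4": db4,
        }
        return float(loss), grads

    def predict_proba(self, img: np.ndarray) -> np.ndarray:
        """Class probability maps (3,H,W) for one normalized image."""
        x = np.asarray(img, dtype=float)[None, None, :, :]
        probs, _ = self.forward(x)
        return probs[0]
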