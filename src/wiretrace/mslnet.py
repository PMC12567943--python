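"""Coarse-to-fine segmentation network for thin structures.

An encoder maps an H x W image to an h x w x C feature grid with stride z
(h = H/z, w = W/z).  Two 1x1 convolution heads read the features: a *coarse*
head w0 (C -> 1) that classifies whole z x z patches, and a *fine* head w1
(C -> z^2) whose z^2-vector at each cell is reshaped to a z x z patch and
tiled into a full-resolution logit map s.  The final segmentation keeps fine
logits only inside coarse-positive cells:

    y_hat = s * M(1[s0 > 0]),     M(U)_{i,j} = U_{floor(i/z), floor(j/z)}

i.e. the coarse grid is a low-dimensional marginal space searched first, and
only its promising cells are refined — there is no decoder and there are no
skip connections.  This suits objects occupying ~0.3% of the pixels, where a
patch-level classifier overfits far less than a dense per-pixel one.

The built-in encoder is a windowed-patch MLP: each z x z cell is described by
the surrounding (context*z)^2 intensity window, passed through a two-layer
MLP to C features.  It is a pure-numpy model (~1.4M parameters at C = 256)
with hand-written backprop, sized for CPU training on synthetic scenes; any
object with the same ``(z, C, forward)`` contract can replace it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Protocol, runtime_checkable

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from wiretrace.losses import LossConfig, total_loss

# ---------------------------------------------------------------------------
# grid primitives


def pad_to_multiple(image: np.ndarray, z: int) -> tuple[np.ndarray, tuple[int, int]]:
    """Zero-pad bottom/right to the smallest multiple of z; returns (padded, (H, W))."""
    if z < 1:
        raise ValueError("z must be >= 1")
    h, w = image.shape[:2]
    ph = (-h) % z
    pw = (-w) % z
    if ph == 0 and pw == 0:
        return image, (h, w)
    pad = [(0, ph), (0, pw)] + [(0, 0)] * (image.ndim - 2)
    return np.pad(image, pad, mode="constant"), (h, w)


def crop_to_original(arr: np.ndarray, original: tuple[int, int]) -> np.ndarray:
    """Exact inverse of :func:`pad_to_multiple`."""
    h, w = original
    return arr[:h, :w]


def upscale_indicator(u: np.ndarray, z: int) -> np.ndarray:
    """Nearest-neighbor upscale by z: out[i, j] = u[i//z, j//z] (no interpolation)."""
    u = np.asarray(u)
    return np.repeat(np.repeat(u, z, axis=0), z, axis=1)


def tile_patch_logits(s1: np.ndarray) -> np.ndarray:
    """Tile per-cell z^2 logit vectors into an (h*z, w*z) map.

    Each z^2-vector is reshaped row-major to a z x z patch placed at
    (i*z, j*z).  The map is a bijection; :func:`untile_patch_logits` is its
    exact inverse.
    """
    h, w, zz = s1.shape
    z = int(round(np.sqrt(zz)))
    if z * z != zz:
        raise ValueError(f"channel count {zz} is not a perfect square")
    return s1.reshape(h, w, z, z).transpose(0, 2, 1, 3).reshape(h * z, w * z)


def untile_patch_logits(s: np.ndarray, z: int) -> np.ndarray:
    """Inverse of :func:`tile_patch_logits`: (h*z, w*z) -> (h, w, z^2)."""
    hz, wz = s.shape
    if hz % z or wz % z:
        raise ValueError("map dimensions must be multiples of z")
    h, w = hz // z, wz // z
    return s.reshape(h, z, w, z).transpose(0, 2, 1, 3).reshape(h, w, z * z)


def coarse_target(y: np.ndarray, z: int) -> np.ndarray:
    """Coarse binary target: y0[u, v] = 1 iff the z x z patch of y has a positive."""
    h, w = y.shape
    if h % z or w % z:
        raise ValueError("mask must be padded to a multiple of z")
    return (
        np.asarray(y).reshape(h // z, z, w // z, z).max(axis=(1, 3)).astype(np.uint8)
    )


# ---------------------------------------------------------------------------
# encoder contract and the built-in patch-MLP encoder


@runtime_checkable
class EncoderContract(Protocol):
    """Stride-z feature extractor: image (H x W) -> features (H/z x W/z x C)."""

    z: int
    C: int

    def forward(self, image: np.ndarray) -> np.ndarray: ...


def _relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def _cell_patches(channel: np.ndarray, z: int) -> np.ndarray:
    """Split a (H, W) map into per-cell z^2 vectors -> (h*w, z^2), row-major."""
    h, w = channel.shape[0] // z, channel.shape[1] // z
    return channel.reshape(h, z, w, z).transpose(0, 2, 1, 3).reshape(h * w, z * z)


class PatchMLPEncoder:
    """Small desk-scale encoder: windowed-patch MLP plus local-contrast channels.

    For each z x z cell, a two-layer ReLU MLP (window (context*z)^2 ->
    ``hidden`` -> ``mlp_channels``) summarizes the surrounding intensity
    window (reflect padding at the border; the image is standardized first).
    With ``local_contrast`` on (the default), the feature vector additionally
    carries two fixed per-pixel channels of the cell itself: its Gaussian
    smoothed intensities (sigma 1) and a difference-of-Gaussians map
    (sigma 3 minus sigma 1, positive on dark ridges), z^2 values each.  The
    learned part supplies context (is there a wire here, which way does it
    run); the fixed part gives the fine head pixel-accurate ridge evidence,
    which keeps the predicted band free of speckle holes.  Total channels
    C = mlp_channels + 2 z^2.  ~1.4M parameters at the defaults.
    """

    DOG_GAIN = 4.0  # scale of the difference-of-Gaussians channel

    def __init__(
        self,
        z: int = 16,
        mlp_channels: int = 256,
        hidden: int = 512,
        context: int = 3,
        local_contrast: bool = True,
        seed: int = 0,
    ) -> None:
        self.z = z
        self.mlp_channels = mlp_channels
        self.hidden = hidden
        self.context = context
        self.local_contrast = local_contrast
        self.C = mlp_channels + (2 * z * z if local_contrast else 0)
        win = context * z
        rng = np.random.default_rng(seed)
        # He initialization, float32 throughout for CPU speed
        self.W1 = (rng.standard_normal((win * win, hidden)) * np.sqrt(2.0 / (win * win))).astype(np.float32)
        self.b1 = np.zeros(hidden, dtype=np.float32)
        self.W2 = (rng.standard_normal((hidden, mlp_channels)) * np.sqrt(2.0 / hidden)).astype(np.float32)
        self.b2 = np.zeros(mlp_channels, dtype=np.float32)

    @property
    def params(self) -> dict[str, np.ndarray]:
        return {"W1": self.W1, "b1": self.b1, "W2": self.W2, "b2": self.b2}

    def n_params(self) -> int:
        return sum(p.size for p in self.params.values())

    @staticmethod
    def _standardize(image: np.ndarray) -> np.ndarray:
        img = image.astype(np.float32)
        return (img - img.mean()) / (img.std() + 1e-6)

    def _windows(self, image: np.ndarray) -> np.ndarray:
        """Extract per-cell context windows -> (h*w, win^2) float32."""
        z, win = self.z, self.context * self.z
        h, w = image.shape[0] // z, image.shape[1] // z
        pad = (win - z) // 2
        img = np.pad(self._standardize(image), pad, mode="reflect")
        v = sliding_window_view(img, (win, win))[::z, ::z]
        assert v.shape[:2] == (h, w)
        return np.ascontiguousarray(v).reshape(h * w, win * win)

    def forward(self, image: np.ndarray) -> np.ndarray:
        """image (H x W, multiple of z) -> features (H/z x W/z x C)."""
        feats, _ = self.forward_cached(image)
        return feats

    def forward_cached(self, image: np.ndarray):
        from scipy.ndimage import gaussian_filter

        z = self.z
        h, w = image.shape[0] // z, image.shape[1] // z
        x = self._windows(image)
        a1 = _relu(x @ self.W1 + self.b1)
        a2 = _relu(a1 @ self.W2 + self.b2)
        cache = (x, a1, a2)
        if not self.local_contrast:
            return a2.reshape(h, w, self.C), cache
        img = self._standardize(image)
        g1 = gaussian_filter(img, 1.0)
        dog = gaussian_filter(img, 3.0) - g1
        feats = np.concatenate(
            [a2, _cell_patches(g1, z), self.DOG_GAIN * _cell_patches(dog, z)], axis=1
        )
        return feats.reshape(h, w, self.C), cache

    def backward(self, cache, d_feat: np.ndarray) -> dict[str, np.ndarray]:
        """d_feat: (h, w, C) gradient -> parameter gradients (accumulated batch).

        The fixed local-contrast channels carry no parameters; only the MLP
        columns of the gradient propagate.
        """
        x, a1, a2 = cache
        g2 = d_feat.reshape(-1, self.C)[:, : self.mlp_channels].astype(np.float32) * (a2 > 0)
        grads = {
            "W2": a1.T @ g2,
            "b2": g2.sum(axis=0),
        }
        g1 = (g2 @ self.W2.T) * (a1 > 0)
        grads["W1"] = x.T @ g1
        grads["b1"] = g1.sum(axis=0)
        return grads


# ---------------------------------------------------------------------------
# heads and the full model


class SegmentationHeads:
    """The two 1x1 convolution filters: w0 (C -> 1) and w1 (C -> z^2)."""

    def __init__(self, C: int, z: int, seed: int = 0) -> None:
        self.C = C
        self.z = z
        rng = np.random.default_rng(seed)
        self.w0 = (rng.standard_normal(C) * np.sqrt(1.0 / C)).astype(np.float32)
        self.b0 = np.zeros(1, dtype=np.float32)
        self.w1 = (rng.standard_normal((C, z * z)) * np.sqrt(1.0 / C)).astype(np.float32)
        self.b1 = np.zeros(z * z, dtype=np.float32)

    @property
    def params(self) -> dict[str, np.ndarray]:
        return {"w0": self.w0, "b0": self.b0, "w1": self.w1, "b1": self.b1}


@dataclass
class SegmentationOutput:
    """All maps produced by one forward pass (original image size restored)."""

    s: np.ndarray  # fine logit map H x W
    s0: np.ndarray  # coarse logit map h x w
    s1: np.ndarray  # patch logits h x w x z^2
    y_hat: np.ndarray  # masked fine logits H x W
    mask: np.ndarray  # final binary segmentation H x W (uint8)


class MSLNet:
    """Encoder + two heads; the coarse grid gates the fine segmentation."""

    def __init__(self, encoder: EncoderContract, heads: SegmentationHeads | None = None) -> None:
        if heads is None:
            heads = SegmentationHeads(encoder.C, encoder.z)
        if heads.C != encoder.C or heads.z != encoder.z:
            raise ValueError("head dimensions do not match the encoder contract")
        self.encoder = encoder
        self.heads = heads

    @property
    def z(self) -> int:
        return self.encoder.z

    def forward(self, image: np.ndarray) -> SegmentationOutput:
        """Forward pass on an already padded image (dims multiples of z)."""
        z = self.z
        if image.shape[0] % z or image.shape[1] % z:
            raise ValueError("image dims must be multiples of z; use pad_to_multiple")
        feats = self.encoder.forward(image)
        h, w = image.shape[0] // z, image.shape[1] // z
        if feats.shape != (h, w, self.encoder.C):
            raise ValueError(
                f"encoder contract violation: got {feats.shape}, "
                f"expected {(h, w, self.encoder.C)}"
            )
        return self._heads_forward(feats)

    def _heads_forward(self, feats: np.ndarray) -> SegmentationOutput:
        z = self.z
        h, w, C = feats.shape
        flat = feats.reshape(-1, C)
        s0 = (flat @ self.heads.w0 + self.heads.b0[0]).reshape(h, w).astype(float)
        s1 = (flat @ self.heads.w1 + self.heads.b1).reshape(h, w, z * z).astype(float)
        s = tile_patch_logits(s1)
        gate = upscale_indicator((s0 > 0).astype(np.uint8), z)
        y_hat = s * gate
        mask = ((s > 0) & (gate > 0)).astype(np.uint8)
        return SegmentationOutput(s=s, s0=s0, s1=s1, y_hat=y_hat, mask=mask)

    def predict(self, image: np.ndarray) -> SegmentationOutput:
        """Pad, run forward, crop every map back to the original size."""
        padded, orig = pad_to_multiple(image, self.z)
        out = self.forward(padded)
        h0, w0 = orig[0] // self.z + (orig[0] % self.z > 0), orig[1] // self.z + (orig[1] % self.z > 0)
        return SegmentationOutput(
            s=crop_to_original(out.s, orig),
            s0=out.s0[:h0, :w0],
            s1=out.s1[:h0, :w0],
            y_hat=crop_to_original(out.y_hat, orig),
            mask=crop_to_original(out.mask, orig),
        )

    # -- persistence ---------------------------------------------------------

    def save(self, path: Path) -> None:
        enc = self.encoder
        np.savez(
            path,
            kind="patch_mlp",
            z=enc.z,
            mlp_channels=enc.mlp_channels,
            hidden=enc.hidden,
            context=enc.context,
            local_contrast=enc.local_contrast,
            enc_W1=enc.W1,
            enc_b1=enc.b1,
            enc_W2=enc.W2,
            enc_b2=enc.b2,
            head_w0=self.heads.w0,
            head_b0=self.heads.b0,
            head_w1=self.heads.w1,
            head_b1=self.heads.b1,
        )

    @classmethod
    def load(cls, path: Path) -> "MSLNet":
        d = np.load(path, allow_pickle=False)
        enc = PatchMLPEncoder(
            z=int(d["z"]),
            mlp_channels=int(d["mlp_channels"]),
            hidden=int(d["hidden"]),
            context=int(d["context"]),
            local_contrast=bool(d["local_contrast"]),
        )
        enc.W1, enc.b1 = d["enc_W1"], d["enc_b1"]
        enc.W2, enc.b2 = d["enc_W2"], d["enc_b2"]
        heads = SegmentationHeads(enc.C, enc.z)
        heads.w0, heads.b0 = d["head_w0"], d["head_b0"]
        heads.w1, heads.b1 = d["head_w1"], d["head_b1"]
        return cls(enc, heads)


# ---------------------------------------------------------------------------
# training


@dataclass
class TrainConfig:
    """Desk-scale training recipe.

    SGD with momentum, learning rate decaying linearly from ``lr`` to 0 over
    the epochs, weight decay 3e-5; augmentation is horizontal/vertical flips,
    rotations up to 15 degrees and translations up to 4 px.
    """

    epochs: int = 20
    batch_size: int = 8
    lr: float = 0.03
    momentum: float = 0.9
    weight_decay: float = 3e-5
    augment: bool = True
    max_rotate_deg: float = 15.0
    max_translate_px: int = 4
    fine_variant: str = "bce"  # 'bce' | 'lorenz'
    alpha: float = 50.0
    seed: int = 0
    verbose: bool = False

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


def _augment_pair(image, mask, rng, cfg: TrainConfig):
    from scipy.ndimage import rotate, shift

    img, msk = image, mask
    if rng.random() < 0.5:
        img, msk = img[:, ::-1], msk[:, ::-1]
    if rng.random() < 0.5:
        img, msk = img[::-1, :], msk[::-1, :]
    if cfg.max_rotate_deg > 0:
        ang = rng.uniform(-cfg.max_rotate_deg, cfg.max_rotate_deg)
        img = rotate(img, ang, reshape=False, order=1, mode="reflect")
        msk = rotate(msk.astype(float), ang, reshape=False, order=0, mode="constant") > 0.5
    if cfg.max_translate_px > 0:
        dr = rng.integers(-cfg.max_translate_px, cfg.max_translate_px + 1)
        dc = rng.integers(-cfg.max_translate_px, cfg.max_translate_px + 1)
        img = shift(img, (dr, dc), order=1, mode="reflect")
        msk = shift(msk.astype(float), (dr, dc), order=0, mode="constant") > 0.5
    return np.ascontiguousarray(img), np.ascontiguousarray(msk.astype(np.uint8))


def train(
    model: MSLNet,
    dataset: list[tuple[np.ndarray, np.ndarray]],
    config: TrainConfig = TrainConfig(),
) -> list[float]:
    """Minimize the two-part loss by SGD; returns the per-epoch mean train loss.

    ``dataset`` is a list of (image, mask) pairs; images are padded to a
    multiple of z internally.  Deterministic given ``config.seed``.
    """
    if not dataset:
        raise ValueError("empty dataset")
    enc, heads = model.encoder, model.heads
    z = model.z
    rng = np.random.default_rng(config.seed)
    loss_cfg = LossConfig(alpha=config.alpha, fine_variant=config.fine_variant)

    velocity = {k: np.zeros_like(v) for k, v in {**_prefixed(enc.params, "e."), **_prefixed(heads.params, "h.")}.items()}
    history: list[float] = []
    n = len(dataset)
    total_steps = config.epochs * max(1, int(np.ceil(n / config.batch_size)))
    step = 0
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        epoch_losses: list[float] = []
        for start in range(0, n, config.batch_size):
            batch = order[start : start + config.batch_size]
            lr = config.lr * (1.0 - step / total_steps)
            grads = {k: np.zeros_like(v) for k, v in velocity.items()}
            batch_loss = 0.0
            for idx in batch:
                image, mask = dataset[idx]
                if config.augment:
                    image, mask = _augment_pair(image, mask, rng, config)
                image, _ = pad_to_multiple(image, z)
                mask, _ = pad_to_multiple(mask, z)
                feats, cache = enc.forward_cached(image)
                out = model._heads_forward(feats)
                y0 = coarse_target(mask, z)
                region = upscale_indicator(y0, z).astype(bool)
                value, ds0, ds = total_loss(
                    out.s0, out.s, mask, y0, loss_cfg, region=region
                )
                batch_loss += value
                # heads backward: s0 = F w0 + b0 ; s1 = F w1 + b1 ; s = tile(s1)
                h, w, C = feats.shape
                flat = feats.reshape(-1, C).astype(np.float32)
                ds0f = ds0.reshape(-1).astype(np.float32)
                ds1f = untile_patch_logits(ds, z).reshape(-1, z * z).astype(np.float32)
                grads["h.w0"] += flat.T @ ds0f
                grads["h.b0"] += np.array([ds0f.sum()], dtype=np.float32)
                grads["h.w1"] += flat.T @ ds1f
                grads["h.b1"] += ds1f.sum(axis=0)
                d_feat = np.outer(ds0f, heads.w0) + ds1f @ heads.w1.T
                for k, v in enc.backward(cache, d_feat.reshape(h, w, C)).items():
                    grads["e." + k] += v
            m = len(batch)
            epoch_losses.append(batch_loss / m)
            params = {**_prefixed(enc.params, "e."), **_prefixed(heads.params, "h.")}
            for k, p in params.items():
                g = grads[k] / m + config.weight_decay * p
                velocity[k] = config.momentum * velocity[k] - lr * g
                p += velocity[k].astype(p.dtype)
            step += 1
        history.append(float(np.mean(epoch_losses)))
        if config.verbose:
            print(f"epoch {epoch + 1}/{config.epochs}  loss {history[-1]:.4f}")
    return history


def _prefixed(d: dict[str, np.ndarray], prefix: str) -> dict[str, np.ndarray]:
    return {prefix + k: v for k, v in d.items()}
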