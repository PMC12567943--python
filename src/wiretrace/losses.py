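"""Training losses for imbalanced thin-structure segmentation.

The total loss has a coarse and a fine part.  Each part combines a soft-Dice
loss (sigmoid-relaxed Dice coefficient, sharpness ``alpha``) with a
class-balanced pixel loss: weighted binary cross-entropy, or the Lorenz loss
log(1 + relu(margin)^2), a robust margin loss that saturates on large errors
and therefore tolerates annotation noise on 1-px-wide targets.

The fine part is evaluated only inside the upscaled coarse-positive region
M(y0): that raises the foreground fraction from ~0.3% of the image to a few
percent of the considered pixels, which is the class-balancing idea of the
coarse-to-fine design.

Every loss returns ``(value, d value / d logits)`` so the numpy trainer can
backpropagate without an autograd framework.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

EPS = 1e-6  # Dice denominator guard for empty-foreground batches


@dataclass(frozen=True)
class LossConfig:
    """alpha: soft-Dice sigmoid sharpness; fine_variant: 'bce' or 'lorenz'."""

    alpha: float = 50.0
    fine_variant: str = "bce"

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if self.fine_variant not in ("bce", "lorenz"):
            raise ValueError("fine_variant must be 'bce' or 'lorenz'")


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _log_sigmoid(x: np.ndarray) -> np.ndarray:
    # stable log(sigmoid(x)) = -log(1+exp(-x)) = min(x,0) - log1p(exp(-|x|))
    return np.minimum(x, 0.0) - np.log1p(np.exp(-np.abs(x)))


def soft_dice_loss(
    s: np.ndarray,
    y: np.ndarray,
    alpha: float = 50.0,
    region: np.ndarray | None = None,
) -> tuple[float, np.ndarray]:
    """1 - soft Dice coefficient of sigmoid(alpha*s) against binary y.

    The coefficient 2*sum(y*p)/sum(y+p) with p = sigmoid(alpha*s) is maximal
    for a correct saturated prediction, so the *loss* is one minus it.  With
    ``region`` given, sums run over region pixels only (fine-loss
    restriction); the gradient is zero outside.  Value is in [0, 1].
    """
    s = np.asarray(s, dtype=float)
    y = np.asarray(y, dtype=float)
    grad = np.zeros_like(s)
    if region is not None:
        reg = np.asarray(region, dtype=bool)
        sv, yv = s[reg], y[reg]
    else:
        sv, yv = s.ravel(), y.ravel()
    p = _sigmoid(alpha * sv)
    num = 2.0 * float(np.sum(yv * p))
    den = float(np.sum(yv + p)) + EPS
    loss = 1.0 - num / den
    # d(1 - num/den)/dp_j = -(2*y_j*den - num)/den^2 ; dp/ds = alpha*p*(1-p)
    gflat = -(2.0 * yv * den - num) / den**2 * alpha * p * (1.0 - p)
    if region is not None:
        grad[reg] = gflat
    else:
        grad = gflat.reshape(s.shape)
    return loss, grad


def weighted_bce(
    s: np.ndarray,
    y: np.ndarray,
    region: np.ndarray | None = None,
) -> tuple[float, np.ndarray]:
    """Class-balanced BCE on logits: mean over positives + mean over negatives.

    value = (1/|y+|) sum_{y+} -log sigmoid(s) + (1/|y-|) sum_{y-} (s - log sigmoid(s)),
    where s - log sigmoid(s) = -log(1 - sigmoid(s)).  An empty class
    contributes 0.  ``region`` restricts both classes to a pixel subset.
    """
    s = np.asarray(s, dtype=float)
    y = np.asarray(y)
    reg = np.ones(s.shape, dtype=bool) if region is None else np.asarray(region, dtype=bool)
    pos = (y > 0) & reg
    neg = (y == 0) & reg
    npos, nneg = int(pos.sum()), int(neg.sum())
    loss = 0.0
    grad = np.zeros_like(s)
    if npos:
        loss += float(np.sum(-_log_sigmoid(s[pos]))) / npos
        grad[pos] = -(1.0 - _sigmoid(s[pos])) / npos
    if nneg:
        loss += float(np.sum(s[neg] - _log_sigmoid(s[neg]))) / nneg
        grad[neg] = _sigmoid(s[neg]) / nneg
    return loss, grad


def lorenz_loss(
    s: np.ndarray,
    y: np.ndarray,
    region: np.ndarray | None = None,
) -> tuple[float, np.ndarray]:
    """Robust margin loss log(1 + relu(1 -/+ s)^2), class-balanced like the BCE.

    Positives are penalized when their logit is below +1, negatives when above
    -1; beyond that margin the loss is exactly 0, and for large violations it
    grows only logarithmically, which is what makes it robust to label noise.
    """
    s = np.asarray(s, dtype=float)
    y = np.asarray(y)
    reg = np.ones(s.shape, dtype=bool) if region is None else np.asarray(region, dtype=bool)
    pos = (y > 0) & reg
    neg = (y == 0) & reg
    npos, nneg = int(pos.sum()), int(neg.sum())
    loss = 0.0
    grad = np.zeros_like(s)
    if npos:
        r = np.maximum(1.0 - s[pos], 0.0)
        loss += float(np.sum(np.log1p(r**2))) / npos
        grad[pos] = -2.0 * r / (1.0 + r**2) / npos
    if nneg:
        r = np.maximum(1.0 + s[neg], 0.0)
        loss += float(np.sum(np.log1p(r**2))) / nneg
        grad[neg] = 2.0 * r / (1.0 + r**2) / nneg
    return loss, grad


def total_loss(
    s0: np.ndarray,
    s: np.ndarray,
    y: np.ndarray,
    y0: np.ndarray,
    config: LossConfig = LossConfig(),
    region: np.ndarray | None = None,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Coarse + fine two-part loss.

    ``s0`` are coarse logits (h x w) scored against the coarse target ``y0``;
    ``s`` are fine logits (H x W) scored against ``y`` inside the region
    M(y0) (upscaled coarse-positive cells).  Each part is
    soft-Dice + (BCE | Lorenz).  Returns ``(value, d/ds0, d/ds)``.

    ``region`` may be passed precomputed (it is ``upscale_indicator(y0, z)``);
    otherwise it is derived from the shape ratio of ``s`` and ``s0``.
    """
    import warnings

    from wiretrace.mslnet import coarse_target, upscale_indicator

    s0 = np.asarray(s0, dtype=float)
    s = np.asarray(s, dtype=float)
    y = np.asarray(y)
    y0 = np.asarray(y0)
    z = s.shape[0] // s0.shape[0]
    if not np.array_equal(y0, coarse_target(y, z).astype(y0.dtype)):
        warnings.warn("y0 is not the per-patch max of y; proceeding anyway")
    if region is None:
        region = upscale_indicator(y0, z).astype(bool)

    dice_c, g_dice_c = soft_dice_loss(s0, y0, config.alpha)
    bce_c, g_bce_c = weighted_bce(s0, y0)
    dice_f, g_dice_f = soft_dice_loss(s, y, config.alpha, region=region)
    fine_fn = weighted_bce if config.fine_variant == "bce" else lorenz_loss
    pix_f, g_pix_f = fine_fn(s, y, region=region)

    value = dice_c + bce_c + dice_f + pix_f
    return value, g_dice_c + g_bce_c, g_dice_f + g_pix_f
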