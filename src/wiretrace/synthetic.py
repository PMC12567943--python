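"""Seeded generator of fluoroscopy-like scenes with thin dark curves.

Real fluoroscopy frames show a guidewire as a 1–5 px wide, smooth, dark curve
occupying roughly 0.3% of the pixels, over a smooth soft-tissue background
with strong sensor noise; parts of the wire are locally invisible.  This
module emulates exactly those statistics — smooth random curves, low contrast,
additive Gaussian noise, gap segments and optional blob clutter — so that
segmentation, curve extraction, grouping and evaluation are all testable with
no external data.

Curves are sampled as cubic splines through jittered control points and
rasterized to ordered 8-connected pixel chains with bounded curvature (no
direction change above 45 degrees over any 10-pixel window), which is the
smoothness regime the perceptual-grouping gates assume.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.ndimage import gaussian_filter, distance_transform_edt

Curve = np.ndarray  # (n, 2) int array of (row, col), consecutive rows 8-adjacent


@dataclass(frozen=True)
class SceneConfig:
    """Parameters of one synthetic scene.

    Defaults emulate the imaging regime the pipeline targets: 512x512 frames,
    one wire of width ~3 px (foreground fraction a few tenths of a percent),
    contrast drop 0.3 on a [0, 1] intensity scale, noise sigma 0.08, and on
    average one invisible (gap) segment of 5-20 px per curve.
    """

    height: int = 512
    width: int = 512
    n_curves: int = 1
    curve_width: int = 3
    contrast: float = 0.3
    noise_sigma: float = 0.08
    gap_rate: float = 1.0
    gap_len_range: tuple[int, int] = (5, 20)
    clutter_level: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height < 64 or self.width < 64:
            raise ValueError("height and width must be >= 64")
        if not 1 <= self.n_curves <= 3:
            raise ValueError("n_curves must be in 1..3")
        if not 1 <= self.curve_width <= 5:
            raise ValueError("curve_width must be in 1..5")
        if self.noise_sigma < 0 or self.gap_rate < 0 or self.clutter_level < 0:
            raise ValueError("rates must be >= 0")


@dataclass
class SyntheticSample:
    """One generated scene: image, ground-truth mask and curves.

    ``mask`` is the rasterization of the *full* ground-truth curves dilated to
    ``curve_width``; ``fragmented_curves`` are the visible sub-chains after gap
    insertion (the image darkens only the visible parts, mirroring locally
    invisible wire segments).
    """

    image: np.ndarray
    mask: np.ndarray
    curves: list[Curve]
    fragmented_curves: list[Curve]
    config: SceneConfig = field(repr=False, default=None)


# ---------------------------------------------------------------------------
# curve geometry helpers


def curve_is_chain(curve: Curve) -> bool:
    """True iff consecutive points are distinct king-move steps and no pixel repeats."""
    c = np.asarray(curve)
    if len(c) < 2:
        return True
    d = np.abs(np.diff(c, axis=0)).max(axis=1)
    if not np.all(d == 1):
        return False
    return len(np.unique(c, axis=0)) == len(c)


def window_directions(curve: Curve, window: int = 10) -> np.ndarray:
    """Unit principal direction of each length-`window` sliding window (PCA)."""
    c = np.asarray(curve, dtype=float)
    n = len(c)
    if n < window:
        window = n
    # batched PCA over all sliding windows at once
    from numpy.lib.stride_tricks import sliding_window_view

    wins = sliding_window_view(c, (window, 2)).reshape(-1, window, 2)
    wins = wins - wins.mean(axis=1, keepdims=True)
    # first right singular vector = direction of maximal variance
    _, _, vt = np.linalg.svd(wins, full_matrices=False)
    dirs = vt[:, 0, :]
    # orient along the chain for comparability between windows
    idx = np.arange(len(dirs))
    steps = c[np.minimum(idx + window, n - 1)] - c[idx]
    flip = np.sum(dirs * steps, axis=1) < 0
    dirs[flip] *= -1
    return dirs


def max_direction_change(curve: Curve, window: int = 10) -> float:
    """Largest angle (radians) between principal directions of adjacent windows."""
    dirs = window_directions(curve, window)
    if len(dirs) < 2:
        return 0.0
    dots = np.clip(np.sum(dirs[:-1] * dirs[1:], axis=1), -1.0, 1.0)
    return float(np.arccos(dots.min()))


def _rasterize_dense(points: np.ndarray) -> np.ndarray:
    """Round densely sampled float points to an ordered 8-connected pixel chain."""
    px = np.rint(points).astype(int)
    # drop consecutive duplicates
    keep = np.ones(len(px), dtype=bool)
    keep[1:] = np.any(px[1:] != px[:-1], axis=1)
    px = px[keep]
    # dense sampling guarantees consecutive Chebyshev distance <= 1 already;
    # remove immediate backtracks a->b->a that rounding can create
    out = [px[0]]
    for p in px[1:]:
        if len(out) >= 2 and np.array_equal(p, out[-2]):
            out.pop()
            continue
        out.append(p)
    return _simplify_chain(np.asarray(out))


def _simplify_chain(chain: np.ndarray) -> np.ndarray:
    """Drop pixels whose two chain neighbors are themselves adjacent.

    Rasterized corners produce diagonal shortcuts (p[i-1] adjacent to
    p[i+1]), which would give the pixel *set* degree-3 nodes in the
    8-neighbor graph.  Removing the middle pixel until a fixpoint yields a
    minimal 8-connected chain that is a simple path as a pixel set.
    """
    changed = True
    while changed and len(chain) > 2:
        changed = False
        keep = [chain[0]]
        i = 1
        while i < len(chain):
            if (
                i + 1 < len(chain)
                and np.abs(chain[i + 1] - keep[-1]).max() <= 1
            ):
                i += 1  # shortcut exists; drop chain[i]
                changed = True
            keep.append(chain[i])
            i += 1
        chain = np.asarray(keep)
    return chain


def _is_simple_path(chain: np.ndarray) -> bool:
    """True iff no two non-consecutive chain pixels are 8-adjacent."""
    index = {tuple(p): i for i, p in enumerate(chain)}
    if len(index) != len(chain):
        return False
    for i, (r, c) in enumerate(chain):
        for dr, dc in ((-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)):
            j = index.get((r + dr, c + dc))
            if j is not None and abs(j - i) != 1:
                return False
    return True


def generate_curve(config: SceneConfig, rng: np.random.Generator) -> Curve:
    """Sample one smooth curve as an ordered 8-connected pixel chain.

    The curve is a cubic spline through 4-8 control points placed along a
    random chord of the image with lateral jitter, rasterized at sub-pixel
    step.  Retries until the chain is >= 100 px long, in bounds, self-avoiding
    and has bounded curvature; raises ``ValueError`` if the image cannot host
    such a curve after bounded retries.
    """
    h, w = config.height, config.width
    margin = max(4, config.curve_width)
    for _ in range(60):
        # random chord across the image interior
        center = np.array([h / 2, w / 2])
        theta = rng.uniform(0, 2 * np.pi)
        u = np.array([np.sin(theta), np.cos(theta)])
        half = 0.5 * rng.uniform(0.6, 0.95) * min(h, w)
        p0, p1 = center - half * u, center + half * u
        n_ctrl = int(rng.integers(4, 9))
        t = np.linspace(0, 1, n_ctrl)
        base = p0[None, :] + t[:, None] * (p1 - p0)[None, :]
        perp = np.array([-u[1], u[0]])
        amp = 2 * half / (n_ctrl * 2.5)
        jitter = rng.normal(0.0, amp, size=n_ctrl)
        jitter[0] = jitter[-1] = 0.0
        ctrl = base + jitter[:, None] * perp[None, :]
        ctrl = np.clip(ctrl, margin, [h - 1 - margin, w - 1 - margin])
        spline = CubicSpline(t, ctrl, axis=0)
        # arc length ~ 2*half; sample at ~0.25 px steps
        n_samp = max(400, int(8 * half))
        pts = spline(np.linspace(0, 1, n_samp))
        inb = (
            (pts[:, 0] >= 0)
            & (pts[:, 0] <= h - 1)
            & (pts[:, 1] >= 0)
            & (pts[:, 1] <= w - 1)
        )
        if not np.all(inb):
            continue
        chain = _rasterize_dense(pts)
        if len(chain) < 100:
            continue
        if not curve_is_chain(chain):
            continue
        if not _is_simple_path(chain):
            continue  # curve passes within 1 px of itself
        if max_direction_change(chain, 10) > np.pi / 4:
            continue
        return chain
    raise ValueError(
        f"could not generate a valid >=100 px curve in a "
        f"{h}x{w} image after bounded retries"
    )


# ---------------------------------------------------------------------------
# rendering


def _curve_indicator(curves: list[Curve], shape: tuple[int, int]) -> np.ndarray:
    ind = np.zeros(shape, dtype=bool)
    for c in curves:
        c = np.asarray(c)
        if len(c):
            ind[c[:, 0], c[:, 1]] = True
    return ind


def _dilate_to_width(ind: np.ndarray, width: int) -> np.ndarray:
    """Thicken a 1-px indicator to ~`width` px via the Euclidean distance map."""
    if width <= 2 or not ind.any():
        return ind.copy()
    dt = distance_transform_edt(~ind)
    return dt <= (width - 1) / 2.0


def render_scene(
    curves: list[Curve],
    config: SceneConfig,
    rng: np.random.Generator,
    visible_curves: list[Curve] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Render (image, mask) for a set of curves.

    image = smooth background - contrast * (dilated visible-curve indicator)
    + Gaussian noise, clipped to [0, 1].  The mask is the dilated indicator of
    ``curves`` (ground truth); ``visible_curves`` (default: ``curves``)
    controls which parts actually darken the image, which is how gap segments
    are made invisible.
    """
    h, w = config.height, config.width
    shape = (h, w)
    # low-frequency background around mid-gray (not a physical X-ray model)
    bg = gaussian_filter(rng.normal(size=shape), sigma=min(h, w) / 8.0)
    if bg.std() > 0:
        bg = 0.6 + 0.08 * (bg - bg.mean()) / bg.std()
    else:  # pragma: no cover - degenerate rng
        bg = np.full(shape, 0.6)
    mask = _dilate_to_width(_curve_indicator(curves, shape), config.curve_width)
    vis = curves if visible_curves is None else visible_curves
    vis_ind = _dilate_to_width(_curve_indicator(vis, shape), config.curve_width)
    image = bg - config.contrast * vis_ind.astype(float)
    for _ in range(config.clutter_level):
        r = rng.uniform(0, h - 1)
        c = rng.uniform(0, w - 1)
        sig = rng.uniform(2, 8)
        rr, cc = np.mgrid[0:h, 0:w]
        image -= 0.5 * config.contrast * np.exp(
            -((rr - r) ** 2 + (cc - c) ** 2) / (2 * sig**2)
        )
    if config.noise_sigma > 0:
        image = image + rng.normal(0.0, config.noise_sigma, size=shape)
    return np.clip(image, 0.0, 1.0), mask.astype(np.uint8)


def fragment_curves(
    curves: list[Curve],
    gap_rate: float,
    gap_len_range: tuple[int, int],
    rng: np.random.Generator,
) -> list[Curve]:
    """Split curves by removing randomly placed gap intervals.

    The number of gaps per curve is Poisson(``gap_rate``); gap lengths are
    uniform in ``gap_len_range`` and measured in arc length (px, diagonal
    steps count sqrt(2)), so the Euclidean distance between the endpoints
    straddling a gap never exceeds the upper bound by more than 2 px.
    Fragments preserve the original point order; fragments shorter than
    3 points are discarded.  ``gap_rate = 0`` returns the input unchanged.
    """
    if gap_rate == 0:
        return [np.asarray(c).copy() for c in curves]
    lo, hi = gap_len_range
    out: list[Curve] = []
    for c in curves:
        c = np.asarray(c)
        n = len(c)
        steps = np.linalg.norm(np.diff(c, axis=0).astype(float), axis=1)
        arc = np.concatenate([[0.0], np.cumsum(steps)])  # arc[i] = length to point i
        removed = np.zeros(n, dtype=bool)
        for _ in range(rng.poisson(gap_rate)):
            glen = float(rng.integers(lo, hi + 1))
            # keep gaps >= 3 points apart so gaps never chain into longer ones
            for _attempt in range(10):
                start = int(rng.integers(1, max(n - 4, 2)))
                # smallest end with arc(start -> end) >= glen - sqrt(2)
                end = int(np.searchsorted(arc, arc[start] + glen - np.sqrt(2)))
                end = min(max(end, start + 1), n - 1)
                pad_lo, pad_hi = max(start - 3, 0), min(end + 3, n)
                if not removed[pad_lo:pad_hi].any():
                    removed[start:end] = True
                    break
        # contiguous runs of kept points become fragments
        idx = 0
        while idx < n:
            if removed[idx]:
                idx += 1
                continue
            j = idx
            while j < n and not removed[j]:
                j += 1
            if j - idx >= 3:
                out.append(c[idx:j].copy())
            idx = j
    return out


def make_sample(config: SceneConfig, rng: np.random.Generator | None = None) -> SyntheticSample:
    """Generate a complete scene: curves, gaps, rendered image and GT mask."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    curves = [generate_curve(config, rng) for _ in range(config.n_curves)]
    frags = fragment_curves(curves, config.gap_rate, config.gap_len_range, rng)
    image, mask = render_scene(curves, config, rng, visible_curves=frags)
    return SyntheticSample(
        image=image, mask=mask, curves=curves, fragmented_curves=frags, config=config
    )


def make_dataset(
    config: SceneConfig, n: int, seed: int | None = None
) -> list[SyntheticSample]:
    """Generate ``n`` independent scenes from one stream seeded by ``seed``."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    return [make_sample(config, rng) for _ in range(n)]


def write_sample(sample: SyntheticSample, stem: Path) -> None:
    """Write image/mask PNGs plus a curves JSON next to ``stem``."""
    from wiretrace import io as wio

    stem = Path(stem)
    stem.parent.mkdir(parents=True, exist_ok=True)
    wio.write_image(stem.with_suffix(".png"), sample.image)
    wio.write_mask(stem.with_name(stem.name + "_mask.png"), sample.mask)
    wio.write_curves(
        stem.with_name(stem.name + "_curves.json"),
        sample.curves,
        image_size=sample.mask.shape,
        stage="ground_truth",
        params=asdict(sample.config) if sample.config else {},
    )


def write_dataset(samples: list[SyntheticSample], outdir: Path, split: str = "train") -> Path:
    """Write all samples plus a JSON manifest for one split; returns manifest path."""
    outdir = Path(outdir)
    entries = []
    for i, s in enumerate(samples):
        stem = outdir / f"{split}_{i:04d}"
        write_sample(s, stem)
        entries.append(
            {
                "image": stem.with_suffix(".png").name,
                "mask": stem.with_name(stem.name + "_mask.png").name,
                "curves": stem.with_name(stem.name + "_curves.json").name,
            }
        )
    manifest = outdir / f"{split}_manifest.json"
    manifest.write_text(json.dumps({"split": split, "samples": entries}, indent=1))
    return manifest
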