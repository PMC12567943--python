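"""Perceptual grouping of curve fragments by good continuation.

Thin structures come out of segmentation broken into fragments wherever they
are locally invisible.  This module merges fragments into whole curves:

1. Each curve end is summarized by a PCA model over its first/last ``npts``
   points: mean ``v``, unit principal direction ``d`` aligned to point
   outward, and the singular values.
2. Every endpoint pair (i, j) is scored by a *continuation cost*: a cubic
   f(x) = ax + bx^2 + cx^3 is fitted analytically in the local frame
   (origin v_i, x-axis toward v_j) to pass through both endpoints tangent to
   both directions, and the cost is its bending energy
   integral_0^l f''(x)^2 dx = 4 b^2 l + 12 b c l^2 + 12 c^2 l^3.
   Pairs failing the gates (gap length within [1, dmax], both directions
   aligned with the join axis beyond ``rho``) get a sentinel cost of 1e5.
   A Bhattacharyya-distance cost over PPCA endpoint Gaussians is available
   as an alternative measure.
3. Endpoints are matched by the Hungarian algorithm (global minimum-cost
   permutation), matches costlier than ``tau`` are voided, and only *mutual*
   matches are kept — a symmetric partial matching.
4. Matched curves are concatenated end-to-end, reversing point order where
   needed for a consistent chain; the whole cycle repeats ``nit`` times
   (or until no merge happens).

Endpoints are indexed 0-based: 2i is the start of curve i (built from its
first points), 2i+1 its end; -1 marks an unmatched endpoint.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

Curve = np.ndarray

SENTINEL = 1e5


@dataclass(frozen=True)
class GroupingParams:
    """Tuning parameters of the grouping loop (defaults: the reference setting).

    nit: grouping iterations; npts: endpoint PCA window (points); dmax:
    maximum endpoint gap (px); rho: minimum |cos| alignment of each end
    direction with the join axis (0.7 ~ 45 degrees); tau: maximum accepted
    continuation cost; lmin: cleanup length (px, 0 disables); measure:
    'polynomial' bending energy or 'bhattacharyya'; sigma2: isotropic PPCA
    noise variance for the Bhattacharyya measure.
    """

    nit: int = 3
    npts: int = 10
    dmax: float = 40.0
    rho: float = 0.7
    tau: float = 10.0
    lmin: int = 0
    measure: str = "polynomial"
    sigma2: float = 10.0
    sentinel: float = SENTINEL

    def __post_init__(self) -> None:
        if self.nit < 1 or self.npts < 2 or self.dmax < 1:
            raise ValueError("require nit >= 1, npts >= 2, dmax >= 1")
        if not 0 < self.rho < 1:
            raise ValueError("rho must be in (0, 1)")
        if self.tau <= 0:
            raise ValueError("tau must be > 0")
        if self.measure not in ("polynomial", "bhattacharyya"):
            raise ValueError("measure must be 'polynomial' or 'bhattacharyya'")


@dataclass
class EndpointModel:
    """PCA summary of one curve end.

    v: mean of the window points; d: unit principal direction aligned outward
    (toward the curve's terminal point); lam: singular values of the centered
    window; valid: False when the direction is undefined (degenerate window).
    """

    v: np.ndarray
    d: np.ndarray
    lam: np.ndarray
    curve_id: int
    end_id: int
    valid: bool = True


def endpoint_models(curves: list[Curve], npts: int = 10) -> list[EndpointModel]:
    """Two PCA endpoint models per curve: index 2i = start, 2i+1 = end.

    The start model uses the first min(npts, len) points and is aligned
    toward the first point; the end model mirrors this.  Curves shorter than
    ``npts`` use all their points for both models.
    """
    models: list[EndpointModel] = []
    for i, curve in enumerate(curves):
        pts = np.asarray(curve, dtype=float)
        k = min(npts, len(pts))
        for end_id, (window, outward) in enumerate(
            [(pts[:k], pts[0]), (pts[-k:], pts[-1])]
        ):
            v = window.mean(axis=0)
            centered = window - v
            _, svals, vt = np.linalg.svd(centered, full_matrices=False)
            valid = bool(svals[0] > 1e-12)
            d = vt[0] if valid else np.array([1.0, 0.0])
            if valid and np.dot(d, outward - v) < 0:
                d = -d
            lam = np.zeros(2)
            lam[: len(svals)] = svals
            models.append(
                EndpointModel(v=v, d=d, lam=lam, curve_id=i, end_id=2 * i + end_id, valid=valid)
            )
    return models


def fit_poly(s1: float, s2: float, l: float) -> tuple[float, float, float]:
    """Closed-form cubic f(x) = ax + bx^2 + cx^3 with f(0)=0, f(l)=0, f'(0)=s1, f'(l)=s2.

    (a, b, c) = (s1, -(2 s1 + s2)/l, (s1 + s2)/l^2).
    """
    if l <= 0:
        raise ValueError("gap length must be > 0")
    return s1, -(2.0 * s1 + s2) / l, (s1 + s2) / l**2


def _bending_energy(b: float, c: float, l: float) -> float:
    """integral_0^l (2b + 6cx)^2 dx = 4 b^2 l + 12 b c l^2 + 12 c^2 l^3."""
    return 4.0 * b * b * l + 12.0 * b * c * l * l + 12.0 * c * c * l**3


def _gates(ei: EndpointModel, ej: EndpointModel, params: GroupingParams):
    """Apply the pairing gates; returns (l, ux) or None if any gate fails."""
    if not (ei.valid and ej.valid):
        return None
    diff = ej.v - ei.v
    l = float(np.linalg.norm(diff))
    if not (1.0 <= l <= params.dmax):
        return None
    ux = diff / l
    if not (np.dot(ei.d, ux) > params.rho and np.dot(ej.d, ux) < -params.rho):
        return None
    return l, ux


def continuation_cost(
    ei: EndpointModel, ej: EndpointModel, params: GroupingParams = GroupingParams()
) -> float:
    """Cubic bending-energy continuation cost, or the sentinel if gated out.

    The local frame is centered at v_i with x-axis ux toward v_j and y-axis
    uy = rot90(ux); slopes passed to the cubic fit are d_i . uy and
    -d_j . uy (the gates keep both x-components above rho, so the slope
    approximation is controlled).  Symmetric: cost(i, j) = cost(j, i).
    """
    g = _gates(ei, ej, params)
    if g is None:
        return params.sentinel
    l, ux = g
    uy = np.array([-ux[1], ux[0]])
    s1 = float(np.dot(ei.d, uy))
    s2 = float(-np.dot(ej.d, uy))
    _, b, c = fit_poly(s1, s2, l)
    return _bending_energy(b, c, l)


def bhattacharyya_cost(
    ei: EndpointModel, ej: EndpointModel, params: GroupingParams = GroupingParams()
) -> float:
    """Bhattacharyya distance between the PPCA endpoint Gaussians.

    Sigma_i = lam_i d_i d_i^T + sigma2 I_2 (rank-1 principal part plus
    isotropic noise); the distance is
    (1/8)(v_i - v_j)^T Sigma^-1 (v_i - v_j) + (1/2) ln(|Sigma| / sqrt(|Sigma_i||Sigma_j|))
    with Sigma the average covariance.  The same gates as the polynomial
    measure apply; gated-out pairs get the sentinel.
    """
    if _gates(ei, ej, params) is None:
        return params.sentinel
    eye = np.eye(2)
    cov_i = ei.lam[0] * np.outer(ei.d, ei.d) + params.sigma2 * eye
    cov_j = ej.lam[0] * np.outer(ej.d, ej.d) + params.sigma2 * eye
    cov = 0.5 * (cov_i + cov_j)
    diff = ei.v - ej.v
    maha = 0.125 * float(diff @ np.linalg.solve(cov, diff))
    logdet = 0.5 * float(
        np.log(np.linalg.det(cov) / np.sqrt(np.linalg.det(cov_i) * np.linalg.det(cov_j)))
    )
    return maha + logdet


def build_cost_matrix(
    models: list[EndpointModel], params: GroupingParams = GroupingParams()
) -> np.ndarray:
    """2n x 2n continuation matrix; diagonal and same-curve pairs are sentinel."""
    cost_fn = continuation_cost if params.measure == "polynomial" else bhattacharyya_cost
    m = len(models)
    M = np.full((m, m), params.sentinel)
    for i in range(m):
        for j in range(m):
            if i == j or models[i].curve_id == models[j].curve_id:
                continue
            M[i, j] = cost_fn(models[i], models[j], params)
    return M


def assign(M: np.ndarray) -> np.ndarray:
    """Minimum-cost permutation sigma (Hungarian): minimizes sum_i M[i, sigma_i]."""
    _, col = linear_sum_assignment(M)
    return col


def threshold_and_validate(
    sigma: np.ndarray, M: np.ndarray, tau: float
) -> np.ndarray:
    """Void matches costlier than tau, then keep only mutual pairs.

    Returns v with v[i] = j iff i and j are matched to each other with cost
    <= tau, else v[i] = -1.  The result is an involution on matched indices.
    """
    sigma = np.asarray(sigma)
    n = len(sigma)
    kept = np.array(
        [sigma[i] if M[i, sigma[i]] <= tau else -1 for i in range(n)]
    )
    v = np.full(n, -1, dtype=int)
    for i in range(n):
        j = kept[i]
        if j >= 0 and j != i and kept[j] == i:
            v[i] = j
    return v


def merge_curves(
    curves: list[Curve], v: np.ndarray, M: np.ndarray | None = None
) -> list[Curve]:
    """Concatenate curves along the validated endpoint matching.

    Each output curve is assembled by walking from a free (unmatched) end:
    a curve entered at its start (even endpoint index) is appended in forward
    order, one entered at its end (odd index) is appended reversed, and the
    walk follows the matching across endpoints.  Every input curve appears in
    exactly one output curve, exactly once.

    A closed ring of matched curves has no free end; the costliest matched
    pair in the ring is broken (``M`` supplies costs; without it an arbitrary
    link is broken) and a warning is emitted.
    """
    v = np.asarray(v).copy()
    n = len(curves)
    if len(v) != 2 * n:
        raise ValueError("match vector length must be 2 * number of curves")
    done = np.zeros(n, dtype=bool)
    out: list[Curve] = []

    def walk(entry: int) -> np.ndarray:
        parts = []
        j = entry
        while True:
            i = j // 2
            done[i] = True
            pts = np.asarray(curves[i])
            parts.append(pts if j % 2 == 0 else pts[::-1])
            exit_end = j ^ 1
            j = v[exit_end]
            if j < 0:
                break
        return np.concatenate(parts, axis=0)

    for e in range(2 * n):
        if v[e] == -1 and not done[e // 2]:
            out.append(walk(e))
    # remaining curves sit on closed rings: break the weakest (costliest) link
    while not done.all():
        i = int(np.flatnonzero(~done)[0])
        e0 = 2 * i
        ring = []
        e = e0
        while True:  # hop match -> other end of the next curve until back home
            ring.append(e)
            e = v[e] ^ 1
            if e == e0:
                break
        matched_pairs = [(e, v[e]) for e in ring]
        if M is not None:
            e, f = max(matched_pairs, key=lambda p: M[p[0], p[1]])
        else:
            e, f = matched_pairs[0]
        warnings.warn("closed ring of matched curves; breaking the costliest link")
        v[e], v[f] = -1, -1
        out.append(walk(e))
    return out


def group(
    curves: list[Curve], params: GroupingParams = GroupingParams()
) -> list[Curve]:
    """Full grouping loop: models -> costs -> Hungarian -> validate -> merge, nit times.

    Endpoint models are recomputed on the merged curves each iteration; stops
    early when an iteration makes no merge.  The union of output points
    always equals the union of input points.
    """
    curves = [np.asarray(c) for c in curves]
    for _ in range(params.nit):
        if len(curves) <= 1:
            break
        models = endpoint_models(curves, params.npts)
        M = build_cost_matrix(models, params)
        sigma = assign(M)
        v = threshold_and_validate(sigma, M, params.tau)
        if np.all(v == -1):
            break
        merged = merge_curves(curves, v, M)
        if len(merged) == len(curves):
            break
        curves = merged
    return curves


def cleanup(curves: list[Curve], lmin: int = 0) -> list[Curve]:
    """Remove curves shorter than ``lmin`` points (lmin = 0 keeps everything)."""
    if lmin < 0:
        raise ValueError("lmin must be >= 0")
    return [c for c in curves if len(c) >= lmin]
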