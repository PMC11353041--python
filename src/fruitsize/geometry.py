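"""Robust circle estimation from 2D contour points.

The measurement core of the package: a fruit silhouette extracted from an
edge map is modelled as a circle ``(x - a)^2 + (y - b)^2 = r^2``.  Fitting
proceeds in three stages:

1. **Minimal solver** — three non-collinear points determine a circle
   exactly through a 3x3 linear system in the algebraic parameters.
2. **RANSAC consensus** — random 3-point samples are scored by how many
   contour points fall within a radial tolerance ``epsilon`` of the
   candidate circle; the best-supported model wins.
3. **Activation filtering and refit** — every point receives a logistic
   weight ``Y = 1 / (1 + exp(alpha * (d_i - r)))`` computed from its
   distance ``d_i`` to the consensus centre.  Points whose activation
   reaches the retention threshold (default 0.5 of the mode's peak
   activation) are retained and the circle is re-estimated on them by an
   algebraic (Kasa) least-squares fit.

As printed, the logistic weight is one-sided: any point strictly inside
the circle gets ``Y > 0.5`` no matter how far inside it lies.  The default
``residual_mode="absolute"`` therefore substitutes ``|d_i - r|`` for
``d_i - r``, which filters by closeness to the circle on both sides;
``"signed"`` keeps the literal one-sided form.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy.special import expit

from .errors import (
    DegenerateConfigurationError,
    DegenerateSampleError,
    FitFailureError,
    InsufficientPointsError,
)

__all__ = [
    "Circle",
    "RansacConfig",
    "FitResult",
    "solve_circle_3pt",
    "point_circle_distance",
    "activation_weight",
    "refit_circle",
    "ransac_circle",
]

# Relative determinant tolerance below which a 3-point sample is treated
# as collinear.  Scaled by the cube of the sample's coordinate span so the
# test is invariant to the units of the pixel grid.
_DEGENERACY_RTOL = 1e-12


@dataclass(frozen=True)
class Circle:
    """A circle in pixel coordinates: centre ``(a, b)``, radius ``r``."""

    a: float
    b: float
    r: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.a) and np.isfinite(self.b) and np.isfinite(self.r)):
            raise ValueError("circle parameters must be finite")
        if self.r <= 0:
            raise ValueError(f"circle radius must be positive, got {self.r}")


@dataclass(frozen=True)
class RansacConfig:
    """Parameters of the consensus loop and the activation filter.

    Attributes
    ----------
    n_iterations:
        Number of valid (non-degenerate) random samples to evaluate.
        Degenerate samples are redrawn and do not consume an iteration.
    epsilon:
        Radial inlier tolerance in pixels: a point is an inlier of a
        candidate circle when ``|d_i - r| < epsilon``.
    alpha:
        Steepness of the logistic activation; larger values sharpen the
        transition between retained and rejected points.
    activation_threshold:
        Points with activation strictly greater than this are retained
        for the refit.
    residual_mode:
        ``"absolute"`` (default) uses ``|d_i - r|`` in the activation so
        the filter is symmetric about the circle; ``"signed"`` uses the
        literal ``d_i - r`` (one-sided: all interior points retained).
    refit_mode:
        ``"algebraic"`` refits with unit weights; ``"activation_weighted"``
        weights each retained point by its activation value.
    sampling:
        ``"random"`` draws ``n_iterations`` triples from the seeded
        generator; ``"exhaustive"`` enumerates every distinct triple
        (useful only for small point sets).
    seed:
        Seed of the private sampling stream; identical seed and config
        give a bit-identical result.
    """

    n_iterations: int = 1000
    epsilon: float = 2.0
    alpha: float = 1.0
    activation_threshold: float = 0.5
    residual_mode: Literal["signed", "absolute"] = "absolute"
    refit_mode: Literal["algebraic", "activation_weighted"] = "algebraic"
    sampling: Literal["random", "exhaustive"] = "random"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if not 0.0 < self.activation_threshold < 1.0:
            raise ValueError("activation_threshold must lie in (0, 1)")
        if self.residual_mode not in ("signed", "absolute"):
            raise ValueError(f"unknown residual_mode {self.residual_mode!r}")
        if self.refit_mode not in ("algebraic", "activation_weighted"):
            raise ValueError(f"unknown refit_mode {self.refit_mode!r}")
        if self.sampling not in ("random", "exhaustive"):
            raise ValueError(f"unknown sampling {self.sampling!r}")


@dataclass(frozen=True)
class FitResult:
    """Outcome of a consensus fit.

    ``best_model`` is the winning consensus circle before activation
    filtering; ``circle`` is the final refit on the retained points.
    ``mean_abs_residual`` is the mean of ``|d_i - r|`` of the retained
    points with respect to the final circle.
    """

    circle: Circle
    best_model: Circle
    inlier_mask: np.ndarray
    retained_mask: np.ndarray
    n_inliers: int
    mean_abs_residual: float


def _as_points(points: Iterable, min_count: int = 0) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError(f"points must have shape (n, 2), got {pts.shape}")
    if not np.all(np.isfinite(pts)):
        raise ValueError("points must be finite")
    if pts.shape[0] < min_count:
        raise InsufficientPointsError(
            f"need at least {min_count} points, got {pts.shape[0]}"
        )
    return pts


def solve_circle_3pt(p1: Sequence[float], p2: Sequence[float], p3: Sequence[float]) -> Circle:
    """Exact circle through three distinct, non-collinear points.

    Solves the linear system in the algebraic parameters ``(D_x, D_y, C)``
    of ``x^2 + y^2 = D_x x + D_y y + C``; the centre is
    ``(D_x / 2, D_y / 2)`` and the radius ``sqrt(C + a^2 + b^2)``.

    Raises
    ------
    DegenerateSampleError
        If the points are collinear or not distinct.
    """
    pts = _as_points([p1, p2, p3])
    x, y = pts[:, 0], pts[:, 1]
    A = np.column_stack([x, y, np.ones(3)])
    B = x * x + y * y
    det = np.linalg.det(A)
    span = max(np.ptp(x), np.ptp(y), 1.0)
    if abs(det) <= _DEGENERACY_RTOL * span**3:
        raise DegenerateSampleError("sample points are collinear or coincident")
    dx, dy, c = np.linalg.solve(A, B)
    a, b = dx / 2.0, dy / 2.0
    r2 = c + a * a + b * b
    if r2 <= 0:
        raise DegenerateSampleError("sample yields a non-positive radius")
    return Circle(a, b, float(np.sqrt(r2)))


def point_circle_distance(p: Sequence[float], c: Circle) -> float:
    """Euclidean distance ``d_i`` from a point to the circle *centre*."""
    x, y = float(p[0]), float(p[1])
    return float(np.hypot(x - c.a, y - c.b))


def activation_weight(
    d: float | np.ndarray,
    r: float,
    alpha: float = 1.0,
    residual_mode: Literal["signed", "absolute"] = "absolute",
) -> float | np.ndarray:
    """Logistic retention weight of a point at centre distance ``d``.

    ``Y = 1 / (1 + exp(alpha * residual))`` with ``residual = d - r``
    (signed mode) or ``|d - r|`` (absolute mode).  ``Y = 0.5`` exactly at
    ``d = r`` in both modes.  Overflow saturates to 0 or 1; the output is
    always finite.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    d = np.asarray(d, dtype=float)
    residual = d - r
    if residual_mode == "absolute":
        residual = np.abs(residual)
    elif residual_mode != "signed":
        raise ValueError(f"unknown residual_mode {residual_mode!r}")
    out = expit(-alpha * residual)
    return float(out) if out.ndim == 0 else out


def refit_circle(points: Iterable, weights: np.ndarray | None = None) -> Circle:
    """Weighted algebraic (Kasa) least-squares circle.

    Minimises ``sum_i w_i * (x_i^2 + y_i^2 - D_x x_i - D_y y_i - C)^2``,
    the linearisation of the squared-radius residual.  With exactly three
    points and unit weights this coincides with :func:`solve_circle_3pt`.

    Raises
    ------
    InsufficientPointsError
        Fewer than 3 points.
    DegenerateConfigurationError
        Collinear points or a fit with non-positive squared radius.
    """
    pts = _as_points(points, min_count=3)
    x, y = pts[:, 0], pts[:, 1]
    A = np.column_stack([x, y, np.ones(len(x))])
    B = x * x + y * y
    if weights is not None:
        w = np.asarray(weights, dtype=float)
        if w.shape != (len(x),):
            raise ValueError("weights must be one value per point")
        if np.any(w <= 0) or not np.all(np.isfinite(w)):
            raise ValueError("weights must be finite and positive")
        sw = np.sqrt(w)
        A = A * sw[:, None]
        B = B * sw
    sol, _, rank, _ = np.linalg.lstsq(A, B, rcond=None)
    if rank < 3:
        raise DegenerateConfigurationError("points do not determine a unique circle")
    dx, dy, c = sol
    a, b = dx / 2.0, dy / 2.0
    r2 = c + a * a + b * b
    if r2 <= 0:
        raise DegenerateConfigurationError("least-squares circle has non-positive radius")
    return Circle(float(a), float(b), float(np.sqrt(r2)))


# --------------------------------------------------------------------------
# vectorised candidate evaluation


def _solve_triples(pts: np.ndarray, idx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Solve the 3-point circle for each row of index triples.

    Returns ``(params, valid)`` where ``params[k] = (a, b, r)`` and
    ``valid[k]`` flags non-degenerate triples.  Uses the closed-form
    Cramer solution of the same linear system as :func:`solve_circle_3pt`.
    """
    p = pts[idx]  # (m, 3, 2)
    x, y = p[..., 0], p[..., 1]
    z = x * x + y * y
    # determinant of [[x1,y1,1],[x2,y2,1],[x3,y3,1]]
    det = (
        x[:, 0] * (y[:, 1] - y[:, 2])
        - y[:, 0] * (x[:, 1] - x[:, 2])
        + (x[:, 1] * y[:, 2] - x[:, 2] * y[:, 1])
    )
    span = np.maximum(np.ptp(x, axis=1), np.ptp(y, axis=1))
    span = np.maximum(span, 1.0)
    valid = np.abs(det) > _DEGENERACY_RTOL * span**3
    safe_det = np.where(valid, det, 1.0)
    dx = (
        z[:, 0] * (y[:, 1] - y[:, 2])
        + z[:, 1] * (y[:, 2] - y[:, 0])
        + z[:, 2] * (y[:, 0] - y[:, 1])
    ) / safe_det
    dy = (
        x[:, 0] * (z[:, 1] - z[:, 2])
        + x[:, 1] * (z[:, 2] - z[:, 0])
        + x[:, 2] * (z[:, 0] - z[:, 1])
    ) / safe_det
    cc = (
        x[:, 0] * (y[:, 1] * z[:, 2] - y[:, 2] * z[:, 1])
        - y[:, 0] * (x[:, 1] * z[:, 2] - x[:, 2] * z[:, 1])
        + (x[:, 1] * y[:, 2] - x[:, 2] * y[:, 1]) * z[:, 0]
    ) / safe_det
    a, b = dx / 2.0, dy / 2.0
    r2 = cc + a * a + b * b
    valid &= r2 > 0
    r = np.sqrt(np.where(valid, r2, 1.0))
    return np.column_stack([a, b, r]), valid


def _draw_triples(rng: np.random.Generator, n_points: int, n_iterations: int,
                  pts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Draw non-degenerate index triples, redrawing degenerate ones.

    A degenerate draw does not consume an iteration; after a bounded
    number of redraw rounds the remaining degenerate slots are flagged.
    """
    idx = np.empty((n_iterations, 3), dtype=np.intp)
    for k in range(n_iterations):
        idx[k] = rng.choice(n_points, size=3, replace=False)
    params, valid = _solve_triples(pts, idx)
    for _ in range(100):  # redraw cap; all-degenerate data exits below
        bad = np.flatnonzero(~valid)
        if bad.size == 0:
            break
        for k in bad:
            idx[k] = rng.choice(n_points, size=3, replace=False)
        new_params, new_valid = _solve_triples(pts, idx[bad])
        params[bad] = new_params
        valid[bad] = new_valid
    return params, valid


def ransac_circle(points: Iterable, config: RansacConfig | None = None) -> FitResult:
    """Consensus circle fit with activation filtering and refit.

    Each iteration draws three distinct point indices, solves the exact
    circle, and counts inliers by ``|d_i - r| < epsilon``.  The model with
    the most inliers wins; ties go to the smaller mean absolute inlier
    residual, then to the earlier iteration.  The winning model then
    drives the activation filter: points with logistic weight above the
    threshold are retained and the circle is refit on them.

    Raises
    ------
    InsufficientPointsError
        Fewer than 3 points.
    FitFailureError
        Every sampled triple was degenerate, or the retained set cannot
        be refit.
    """
    if config is None:
        config = RansacConfig()
    pts = _as_points(points, min_count=3)
    n = pts.shape[0]

    if config.sampling == "exhaustive":
        idx = np.array(list(itertools.combinations(range(n), 3)), dtype=np.intp)
        params, valid = _solve_triples(pts, idx)
    else:
        rng = np.random.default_rng(config.seed)
        params, valid = _draw_triples(rng, n, config.n_iterations, pts)

    if not np.any(valid):
        raise FitFailureError("all sampled 3-point sets were degenerate")

    # residuals of every point against every candidate: (m, n)
    d = np.hypot(pts[:, 0] - params[:, 0, None], pts[:, 1] - params[:, 1, None])
    abs_res = np.abs(d - params[:, 2, None])
    inliers = abs_res < config.epsilon
    counts = np.where(valid, inliers.sum(axis=1), -1)

    best_count = counts.max()
    if best_count < 0:
        raise FitFailureError("no valid candidate model")
    tied = np.flatnonzero(counts == best_count)
    if tied.size > 1 and best_count > 0:
        mean_res = np.array(
            [abs_res[k][inliers[k]].mean() for k in tied]
        )
        tied = tied[mean_res == mean_res.min()]
    best = int(tied[0])  # earliest iteration among remaining ties

    best_model = Circle(*map(float, params[best]))
    inlier_mask = inliers[best].copy()

    weights = activation_weight(
        d[best], best_model.r, config.alpha, config.residual_mode
    )
    # Retention compares against the mode's peak activation: the signed
    # logistic tops out at 1 (threshold 0.5 retains interior points, the
    # literal one-sided rule) while the absolute one tops out at 0.5 (a
    # point exactly on the circle), so the same threshold selects the
    # symmetric band |d - r| <= ln(2/t - 1) / alpha around the circle.
    sup = 1.0 if config.residual_mode == "signed" else 0.5
    retained_mask = weights >= config.activation_threshold * sup
    if retained_mask.sum() < 3:
        raise FitFailureError(
            f"activation filter retained only {int(retained_mask.sum())} points"
        )
    try:
        if config.refit_mode == "activation_weighted":
            circle = refit_circle(pts[retained_mask], weights[retained_mask])
        else:
            circle = refit_circle(pts[retained_mask])
    except DegenerateConfigurationError as exc:
        raise FitFailureError(f"refit failed: {exc}") from exc

    d_final = np.hypot(pts[retained_mask, 0] - circle.a, pts[retained_mask, 1] - circle.b)
    mean_abs_residual = float(np.abs(d_final - circle.r).mean())

    return FitResult(
        circle=circle,
        best_model=best_model,
        inlier_mask=inlier_mask,
        retained_mask=retained_mask,
        n_inliers=int(inlier_mask.sum()),
        mean_abs_residual=mean_abs_residual,
    )
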