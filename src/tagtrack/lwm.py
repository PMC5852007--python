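"""Local Weighted Mean (LWM) scattered-landmark transformation.

Given N control-point pairs (source -> target), a degree-2 bivariate
polynomial is fitted through each control point and its n-1 nearest
neighbours, separately for the x- and y-target components.  At an arbitrary
query point the transform is the weighted mean of all local polynomials
whose support reaches the query, with the compactly supported cubic weight

    W(D) = 1 - 3 D^2 + 2 D^3   for 0 <= D <= 1,   W(D) = 0 for D > 1,

where D is the distance to the polynomial's center divided by D_n, the
distance from that center to its (n-1)-th nearest control point.  W has
zero slope at both ends, so the blended field is continuous and smooth, and
no global system of equations is ever solved: each fit involves only n
points.

Fewer than 6 local points cannot determine the 6 quadratic monomials and
yields an ill-conditioned polynomial, so n >= 6 is enforced; n = 12 is the
recommended default.  Near-collinear neighbourhoods are detected through a
condition estimate and fall back to an affine (degree-1) local fit.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .image_parts import PointSet

logger = logging.getLogger(__name__)

#: condition threshold on the normal equations of a local fit
CONDITION_LIMIT = 1e8

_MIN_N = 6  # monomials of a degree-2 bivariate polynomial


def weight(D):
    """Cubic blending weight W(D); compact support on [0, 1].

    Accepts scalars or arrays; negative distances are an error.
    """
    d = np.asarray(D, dtype=float)
    if np.any(d < 0):
        raise ValueError("distance ratio D must be non-negative")
    w = np.where(d <= 1.0, 1.0 - 3.0 * d * d + 2.0 * d * d * d, 0.0)
    if np.isscalar(D) or np.ndim(D) == 0:
        return float(w)
    return w


@dataclass(frozen=True)
class ControlPoints:
    """Paired source/target landmark sets defining the mapping to fit."""

    source: np.ndarray
    target: np.ndarray

    def __post_init__(self) -> None:
        src = np.atleast_2d(np.asarray(self.source, float))
        tgt = np.atleast_2d(np.asarray(self.target, float))
        if src.shape != tgt.shape or src.shape[1] != 2:
            raise ValueError("source and target must be matching (N, 2) arrays")
        if len(np.unique(src, axis=0)) != len(src):
            raise ValueError("duplicate source control points")
        object.__setattr__(self, "source", src)
        object.__setattr__(self, "target", tgt)

    def __len__(self) -> int:
        return self.source.shape[0]


@dataclass(frozen=True)
class LocalPolynomial:
    """One control point's local fit.

    Coefficients are in the basis centered on ``center``:
    ``[1, dx, dy, dx^2, dx*dy, dy^2]`` (first three only when the fit fell
    back to degree 1), where ``(dx, dy) = (x, y) - center``.
    """

    center: tuple[float, float]
    coefficients_x: np.ndarray
    coefficients_y: np.ndarray
    D_n: float
    condition_estimate: float
    degree_used: int = 2

    def __call__(self, pts: np.ndarray) -> np.ndarray:
        """Evaluate (f_x, f_y) at (M, 2) points."""
        A = _design_matrix(np.atleast_2d(pts) - np.asarray(self.center), self.degree_used)
        return np.column_stack((A @ self.coefficients_x, A @ self.coefficients_y))


def _design_matrix(d: np.ndarray, degree: int) -> np.ndarray:
    dx, dy = d[:, 0], d[:, 1]
    cols = [np.ones_like(dx), dx, dy]
    if degree == 2:
        cols += [dx * dx, dx * dy, dy * dy]
    return np.column_stack(cols)


@dataclass
class LWMTransform:
    """Fitted LWM transformation: N local polynomials blended by W."""

    polys: list[LocalPolynomial]
    n: int
    degree: int = 2
    _tree: cKDTree = field(default=None, repr=False)
    _Dn: np.ndarray = field(default=None, repr=False)
    _cx: np.ndarray = field(default=None, repr=False)
    _cy: np.ndarray = field(default=None, repr=False)

    def __post_init__(self) -> None:
        centers = np.array([p.center for p in self.polys], float)
        object.__setattr__(self, "_tree", cKDTree(centers))
        object.__setattr__(self, "_Dn", np.array([p.D_n for p in self.polys], float))
        # stacked coefficient matrices (degree-1 fits zero-padded: identical values)
        cx = np.zeros((len(self.polys), 6))
        cy = np.zeros((len(self.polys), 6))
        for i, p in enumerate(self.polys):
            cx[i, : p.coefficients_x.size] = p.coefficients_x
            cy[i, : p.coefficients_y.size] = p.coefficients_y
        object.__setattr__(self, "_cx", cx)
        object.__setattr__(self, "_cy", cy)

    @property
    def centers(self) -> np.ndarray:
        return np.array([p.center for p in self.polys], float)

    @property
    def n_ill_conditioned(self) -> int:
        return sum(p.degree_used < self.degree for p in self.polys)

    def __call__(self, pts, extrapolate: bool = False) -> np.ndarray:
        return transform_points(self, pts, extrapolate=extrapolate).points

    def to_json(self, path) -> None:
        payload = {
            "n": self.n,
            "degree": self.degree,
            "polys": [
                {
                    "center": list(p.center),
                    "coefficients_x": p.coefficients_x.tolist(),
                    "coefficients_y": p.coefficients_y.tolist(),
                    "D_n": p.D_n,
                    "condition_estimate": p.condition_estimate,
                    "degree_used": p.degree_used,
                }
                for p in self.polys
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "LWMTransform":
        with open(path) as fh:
            payload = json.load(fh)
        polys = [
            LocalPolynomial(
                center=tuple(d["center"]),
                coefficients_x=np.array(d["coefficients_x"], float),
                coefficients_y=np.array(d["coefficients_y"], float),
                D_n=d["D_n"],
                condition_estimate=d["condition_estimate"],
                degree_used=d["degree_used"],
            )
            for d in payload["polys"]
        ]
        return cls(polys=polys, n=payload["n"], degree=payload["degree"])


def fit_lwm(cp: ControlPoints, n: int = 12, degree: int = 2) -> LWMTransform:
    """Fit one local polynomial per control point over its n nearest points.

    With n = 6 the quadratic fit interpolates exactly; with n > 6 it is an
    overdetermined least-squares fit, which stabilises conditioning.
    """
    if degree != 2:
        raise ValueError("only degree-2 local polynomials are supported")
    if n < _MIN_N:
        raise ValueError(
            f"n = {n} < {_MIN_N}: fewer than 6 local points yields an "
            "ill-conditioned polynomial (6 quadratic coefficients); use n >= 6"
        )
    N = len(cp)
    if N < n:
        raise ValueError(f"need at least n = {n} control points, got {N}")

    tree = cKDTree(cp.source)
    # row i: the point itself (distance 0) and its n-1 nearest neighbours
    dists, idx = tree.query(cp.source, k=n)
    polys: list[LocalPolynomial] = []
    n_fallback = 0
    for i in range(N):
        D_n = float(dists[i, -1])
        nbr = idx[i]
        d = cp.source[nbr] - cp.source[i]
        A = _design_matrix(d, 2)
        cond = float(np.linalg.cond(A)) ** 2  # normal-equations estimate
        deg = 2
        if cond > CONDITION_LIMIT:
            deg = 1
            n_fallback += 1
            A = _design_matrix(d, 1)
        sol, *_ = np.linalg.lstsq(A, cp.target[nbr], rcond=None)
        polys.append(
            LocalPolynomial(
                center=(float(cp.source[i, 0]), float(cp.source[i, 1])),
                coefficients_x=sol[:, 0],
                coefficients_y=sol[:, 1],
                D_n=D_n,
                condition_estimate=cond,
                degree_used=deg,
            )
        )
    if n_fallback:
        logger.warning(
            "fit_lwm: %d/%d local fits ill-conditioned (cond > %.0e); "
            "fell back to affine fits",
            n_fallback, N, CONDITION_LIMIT,
        )
    return LWMTransform(polys=polys, n=n, degree=degree)


def transform_points(
    t: LWMTransform, pts, extrapolate: bool = False
) -> PointSet:
    """Apply the LWM transform to points.

    Each output is the W-weighted mean of all local polynomials whose
    support reaches the query.  A query with zero total weight lies outside
    the transform's support: by default this is an error naming the point;
    with ``extrapolate=True`` the nearest polynomial is used instead and a
    warning is logged (pipeline mode).
    """
    if isinstance(pts, PointSet):
        arr = pts.points
        spacing = pts.spacing
    else:
        arr = np.atleast_2d(np.asarray(pts, float))
        spacing = 0.0
    out = np.empty_like(arr)
    rmax = float(t._Dn.max())
    candidates = t._tree.query_ball_point(arr, r=rmax)
    centers = t._tree.data
    n_extrapolated = 0

    def _eval(ids: np.ndarray, p: np.ndarray) -> np.ndarray:
        d = p[None, :] - centers[ids]
        A = np.column_stack(
            (np.ones(len(ids)), d[:, 0], d[:, 1],
             d[:, 0] ** 2, d[:, 0] * d[:, 1], d[:, 1] ** 2)
        )
        return np.column_stack(((A * t._cx[ids]).sum(1), (A * t._cy[ids]).sum(1)))

    for q, (p, cand) in enumerate(zip(arr, candidates)):
        cand = np.asarray(cand, dtype=int)
        if cand.size:
            d = np.linalg.norm(centers[cand] - p, axis=1)
            ratio = d / t._Dn[cand]
            inside = ratio < 1.0
        else:
            inside = np.zeros(0, bool)
        if not inside.any():
            if not extrapolate:
                raise ValueError(
                    f"point ({p[0]:.3f}, {p[1]:.3f}) is outside the transform's "
                    "support (zero total weight)"
                )
            n_extrapolated += 1
            _, j = t._tree.query(p)
            out[q] = _eval(np.array([int(j)]), p)[0]
            continue
        ids = cand[inside]
        w = weight(ratio[inside])
        vals = _eval(ids, p)
        out[q] = (w[:, None] * vals).sum(axis=0) / w.sum()
    if n_extrapolated:
        logger.warning(
            "transform_points: %d/%d points outside support; used "
            "nearest-polynomial extrapolation", n_extrapolated, len(arr),
        )
    return PointSet(points=out, spacing=spacing)
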