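"""Sequential cardiac-cycle tracking and Eulerian strain.

Material points seeded on the first frame are carried through the cycle by
chaining one registration per consecutive image pair: dense window
correspondences -> LWM transform -> apply to the current point positions.

Strain follows the Eulerian (Almansi) convention.  With U = L - L_1 the
displacement of a tracked point relative to the first frame, the
displacement gradient dU is taken with respect to the *current* (deformed)
coordinates, estimated by a moving least-squares plane fit of U over
neighbouring tracked points.  Then

    F = (I - dU)^{-1},        E = 1/2 [I - (F F^T)^{-1}],

so E vanishes for any rigid motion.  E is projected onto radial and
circumferential unit vectors about the LV centroid to give E_rr and E_cc,
and averaged within the six standard AHA sectors of the short-axis wall.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .hierarchy import Correspondences, SearchConfig, tracking_correspondences
from .image_parts import ImageFrame, PointSet, decompose
from .lwm import ControlPoints, fit_lwm, transform_points

logger = logging.getLogger(__name__)

#: AHA sector names in counter-clockwise order starting at the reference angle
AHA_REGIONS = (
    "Anterior",
    "Anteroseptal",
    "Inferoseptal",
    "Inferior",
    "Inferolateral",
    "Anterolateral",
)

_SINGULAR_TOL = 1e-8


@dataclass(frozen=True)
class Trajectories:
    """Positions of P material points over T frames, ``(T, P, 2)``."""

    positions: np.ndarray
    pixel_size_mm: float = 1.0

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, float)
        if pos.ndim != 3 or pos.shape[2] != 2:
            raise ValueError("positions must be a (T, P, 2) array")
        if not np.all(np.isfinite(pos)):
            raise ValueError("trajectory positions must be finite")
        object.__setattr__(self, "positions", pos)

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def n_points(self) -> int:
        return self.positions.shape[1]

    def to_csv(self, path) -> None:
        T, P, _ = self.positions.shape
        frames = np.repeat(np.arange(T), P)
        ids = np.tile(np.arange(P), T)
        flat = self.positions.reshape(-1, 2)
        pd.DataFrame(
            {"frame": frames, "point_id": ids, "row": flat[:, 0], "col": flat[:, 1]}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, pixel_size_mm: float = 1.0) -> "Trajectories":
        df = pd.read_csv(path).sort_values(["frame", "point_id"])
        T = df["frame"].nunique()
        P = df["point_id"].nunique()
        pos = df[["row", "col"]].to_numpy(float).reshape(T, P, 2)
        return cls(positions=pos, pixel_size_mm=pixel_size_mm)


def track_cycle(
    frames: list[ImageFrame],
    seeds: PointSet,
    cfg: SearchConfig | None = None,
    lwm_n: int = 12,
    keep_correspondences: bool = False,
) -> Trajectories | tuple[Trajectories, list[Correspondences]]:
    """Track seed points through consecutive registrations I_1 -> ... -> I_n.

    Each pair (I_k, I_k+1) contributes one correspondence set and one LWM
    transform; the transform (in extrapolating pipeline mode) advances the
    current point positions.  Control points come from the segment-scale
    cascade matches (sub-pixel, centre-attributed); degenerate matches are
    excluded before fitting.

    The default search radius is 3 px rather than the standalone-
    registration default of 8: consecutive cardiac phases move by at most
    a pixel or two, and keeping the search below half a tag period makes
    period-aliased matches ("tag jumping") geometrically impossible.
    """
    if len(frames) < 2:
        raise ValueError("need at least 2 frames to track")
    if cfg is None:
        cfg = SearchConfig(template_search_radius=3)
    H, W = frames[0].shape
    pts = np.asarray(seeds.points, float)
    if np.any(pts < 0) or np.any(pts[:, 0] > H - 1) or np.any(pts[:, 1] > W - 1):
        raise ValueError("seed points must lie inside frame 0")

    grid = decompose(frames[0].shape)
    positions = [pts.copy()]
    all_corr: list[Correspondences] = []
    for k in range(len(frames) - 1):
        try:
            corr = tracking_correspondences(frames[k], frames[k + 1], cfg, grid=grid)
            keep = corr.ok_mask()
            cp = ControlPoints(
                source=corr.moving.points[keep],
                target=corr.reference.points[keep],
            )
            transform = fit_lwm(cp, n=lwm_n)
            moved = transform_points(transform, positions[-1], extrapolate=True)
        except Exception as exc:
            raise RuntimeError(
                f"tracking failed at frame pair ({k}, {k + 1}): {exc}"
            ) from exc
        positions.append(moved.points)
        if keep_correspondences:
            all_corr.append(corr)
    traj = Trajectories(
        positions=np.stack(positions), pixel_size_mm=frames[0].pixel_size_mm
    )
    if keep_correspondences:
        return traj, all_corr
    return traj


def displacement_gradient(
    traj: Trajectories, frame: int, neighbourhood_radius: float = 8.0
) -> tuple[np.ndarray, np.ndarray]:
    """Per-point 2x2 Eulerian displacement gradient at one frame.

    U = L - L_1 is fitted as a local plane of the *current* coordinates over
    each point's neighbours within ``neighbourhood_radius`` px; the plane's
    slope is dU.  Returns ``(dU (P, 2, 2), valid (P,))``; points with fewer
    than 3 non-collinear neighbours are flagged invalid.
    """
    if frame < 1 or frame >= traj.n_frames:
        raise ValueError(f"frame must be in [1, {traj.n_frames - 1}]")
    cur = traj.positions[frame]
    U = cur - traj.positions[0]
    P = cur.shape[0]
    dU = np.zeros((P, 2, 2))
    valid = np.zeros(P, bool)
    tree = cKDTree(cur)
    neighbours = tree.query_ball_point(cur, r=neighbourhood_radius)
    for i in range(P):
        nbr = np.asarray(neighbours[i], int)
        if nbr.size < 3:
            continue
        d = cur[nbr] - cur[i]
        A = np.column_stack((np.ones(len(nbr)), d))
        s = np.linalg.svd(A, compute_uv=False)
        if s[-1] <= 1e-8 * s[0]:  # collinear neighbourhood
            continue
        sol, *_ = np.linalg.lstsq(A, U[nbr], rcond=None)
        # sol rows: [intercept; dU/drow; dU/dcol], columns: (U_row, U_col)
        dU[i] = sol[1:].T
        valid[i] = True
    n_bad = int((~valid).sum())
    if n_bad:
        logger.info(
            "displacement_gradient: %d/%d points lack a valid neighbourhood "
            "and are excluded from strain", n_bad, P,
        )
    return dU, valid


def deformation_gradient(dU: np.ndarray) -> np.ndarray:
    """F = (I - dU)^{-1}; raises on a singular (I - dU)."""
    dU = np.asarray(dU, float)
    single = dU.ndim == 2
    M = np.eye(2) - dU.reshape(-1, 2, 2)
    det = M[:, 0, 0] * M[:, 1, 1] - M[:, 0, 1] * M[:, 1, 0]
    bad = np.abs(det) < _SINGULAR_TOL
    if bad.any():
        i = int(np.argmax(bad))
        raise np.linalg.LinAlgError(
            f"(I - dU) is singular at point {i} (|det| = {abs(det[i]):.2e})"
        )
    F = np.linalg.inv(M)
    return F[0] if single else F.reshape(dU.shape)


def eulerian_strain(F: np.ndarray) -> np.ndarray:
    """Almansi strain E = 1/2 [I - (F F^T)^{-1}], explicitly symmetrised."""
    F = np.asarray(F, float)
    single = F.ndim == 2
    Fb = F.reshape(-1, 2, 2)
    B = Fb @ np.transpose(Fb, (0, 2, 1))
    E = 0.5 * (np.eye(2) - np.linalg.inv(B))
    E = 0.5 * (E + np.transpose(E, (0, 2, 1)))
    return E[0] if single else E.reshape(F.shape)


def polar_strain(E: np.ndarray, point, centroid) -> tuple[float, float]:
    """Project a strain tensor onto circumferential/radial directions.

    ``e_r`` points from the centroid to the point (row/col components),
    ``e_c`` is ``e_r`` rotated 90 degrees.  Returns ``(E_cc, E_rr)``.
    """
    p = np.asarray(point, float)
    c = np.asarray(centroid, float)
    d = p - c
    norm = np.hypot(d[0], d[1])
    if norm == 0:
        raise ValueError("point coincides with the centroid")
    e_r = d / norm
    e_c = np.array([-e_r[1], e_r[0]])
    E = np.asarray(E, float)
    return float(e_c @ E @ e_c), float(e_r @ E @ e_r)


def _polar_strain_many(E: np.ndarray, points: np.ndarray, centroid) -> np.ndarray:
    """Vectorised (E_cc, E_rr) for (P,2,2) tensors at (P,2) points."""
    d = points - np.asarray(centroid, float)
    norm = np.linalg.norm(d, axis=1, keepdims=True)
    if np.any(norm == 0):
        raise ValueError("a point coincides with the centroid")
    e_r = d / norm
    e_c = np.column_stack((-e_r[:, 1], e_r[:, 0]))
    err = np.einsum("pi,pij,pj->p", e_r, E, e_r)
    ecc = np.einsum("pi,pij,pj->p", e_c, E, e_c)
    return np.column_stack((ecc, err))


def point_angles(points: np.ndarray, centroid) -> np.ndarray:
    """Angle (degrees, [0, 360)) of each point about the centroid.

    Measured counter-clockwise in the anatomical sense: 0 deg towards
    +col ("east"), 90 deg towards -row ("up" in the image).
    """
    pts = np.atleast_2d(np.asarray(points, float))
    c = np.asarray(centroid, float)
    dx = pts[:, 1] - c[1]
    dy = -(pts[:, 0] - c[0])
    return np.degrees(np.arctan2(dy, dx)) % 360.0


def assign_aha_regions(
    points, centroid, reference_angle: float = 90.0
) -> np.ndarray:
    """Label points by 60-degree AHA sector.

    Sector 1 (Anterior) begins at ``reference_angle`` (degrees, same
    convention as :func:`point_angles`) and sectors proceed
    counter-clockwise; boundaries are half-open (a point on a boundary
    belongs to the sector it begins).
    """
    pts = points.points if isinstance(points, PointSet) else np.atleast_2d(points)
    ang = point_angles(pts, centroid)
    sector = np.floor(((ang - reference_angle) % 360.0) / 60.0).astype(int)
    sector = np.clip(sector, 0, 5)
    return np.array([AHA_REGIONS[s] for s in sector], dtype=object)


@dataclass(frozen=True)
class RegionalStrain:
    """Mean E_cc / E_rr per frame in the six AHA regions."""

    ecc: pd.DataFrame  # frames x regions
    err: pd.DataFrame
    centroid: tuple[float, float]
    reference_angle: float
    region_counts: dict[str, int] = field(default_factory=dict)

    def to_csv(self, path) -> None:
        rows = []
        for frame in self.ecc.index:
            for region in AHA_REGIONS:
                rows.append(
                    {
                        "frame": frame,
                        "region": region,
                        "Ecc": self.ecc.loc[frame, region],
                        "Err": self.err.loc[frame, region],
                    }
                )
        pd.DataFrame(rows).to_csv(path, index=False)

    def to_dict(self) -> dict:
        return {
            "centroid": list(self.centroid),
            "reference_angle": self.reference_angle,
            "regions": list(AHA_REGIONS),
            "Ecc": self.ecc.to_dict(orient="list"),
            "Err": self.err.to_dict(orient="list"),
        }


def strain_tensors(
    traj: Trajectories, frame: int, neighbourhood_radius: float = 8.0
) -> tuple[np.ndarray, np.ndarray]:
    """Per-point Eulerian strain tensors at one frame, with validity mask."""
    dU, valid = displacement_gradient(traj, frame, neighbourhood_radius)
    E = np.zeros_like(dU)
    if valid.any():
        F = deformation_gradient(dU[valid])
        E[valid] = eulerian_strain(F)
    return E, valid


def regional_strain_curves(
    traj: Trajectories,
    centroid,
    reference_angle: float = 90.0,
    neighbourhood_radius: float = 8.0,
) -> RegionalStrain:
    """Mean circumferential/radial strain per frame and AHA region.

    Points are assigned to their region once, from their frame-0 positions
    (a material point stays in its anatomical sector); strain at frame 0 is
    identically zero.  Empty regions are reported as NaN and logged.
    """
    labels = assign_aha_regions(traj.positions[0], centroid, reference_angle)
    counts = {r: int((labels == r).sum()) for r in AHA_REGIONS}
    for r, nc in counts.items():
        if nc == 0:
            logger.warning("regional_strain_curves: region %s has no points", r)
    T = traj.n_frames
    ecc = np.full((T, 6), np.nan)
    err = np.full((T, 6), np.nan)
    ecc[0] = err[0] = 0.0
    for t in range(1, T):
        E, valid = strain_tensors(traj, t, neighbourhood_radius)
        polar = np.full((traj.n_points, 2), np.nan)
        if valid.any():
            polar[valid] = _polar_strain_many(
                E[valid], traj.positions[t][valid], centroid
            )
        for ri, region in enumerate(AHA_REGIONS):
            sel = (labels == region) & valid
            if sel.any():
                ecc[t, ri] = polar[sel, 0].mean()
                err[t, ri] = polar[sel, 1].mean()
    idx = pd.RangeIndex(T, name="frame")
    return RegionalStrain(
        ecc=pd.DataFrame(ecc, index=idx, columns=list(AHA_REGIONS)),
        err=pd.DataFrame(err, index=idx, columns=list(AHA_REGIONS)),
        centroid=(float(centroid[0]), float(centroid[1])),
        reference_angle=float(reference_angle),
        region_counts=counts,
    )
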