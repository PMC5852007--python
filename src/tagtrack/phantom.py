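"""Synthetic tagged short-axis phantom with analytic ground truth.

The phantom emulates an ECG-gated tagged (SPAMM-like) short-axis
acquisition: an annular myocardium carrying a multiplicative
cos^2(pi x / s) * cos^2(pi y / s) tag grid, deformed by a known smooth
motion over a cardiac cycle, with optional per-frame tag fading and
additive Gaussian noise.  Because every motion model has a closed-form
inverse, frames are rendered by evaluating the undeformed pattern (an
analytic expression, including the annulus mask) exactly at the
inverse-mapped pixel coordinates — tags genuinely move with the tissue.

Motion models (all about the annulus centre, ``(row, col)`` coordinates):

``translation``
    phi_t(p) = p + ramp(t) * c with a linear ramp t/(T-1).
``rotation``
    rigid rotation by s(t) * theta_max.
``scale``
    uniform radial scaling r -> alpha(t) * r, alpha = 1 - s(t)(1 - alpha_min).
``contract_twist``
    radial contraction as ``scale`` plus a transmural twist: material at
    initial radius r is additionally rotated by
    s(t) * tau_max * (r - r_in) / (r_out - r_in).

s(t) = sin^2(pi t / (T-1)) is a smooth systole-diastole profile peaking
mid-cycle and closing the cycle (phi_0 = phi_{T-1} = identity).

Ground truth: the forward map, its Jacobian F = d(phi)/dp, and the Almansi
strain E = 1/2 [I - (F F^T)^{-1}] are available in closed form, along with
18 labelled landmarks (3 rings x 6 sector centres) and their trajectories.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace

import numpy as np

from .image_parts import ImageFrame, PointSet

_J = np.array([[0.0, -1.0], [1.0, 0.0]])  # d/dpsi of a rotation matrix, at psi=0

MOTION_TYPES = ("translation", "rotation", "scale", "contract_twist")


@dataclass(frozen=True)
class PhantomConfig:
    """Study conditions of the synthetic phantom.

    Defaults describe a 19-frame, 128 x 128 short-axis cycle at the
    clinical 1.48 mm pixel scale: annulus radii 20-36 px (~3-5.3 cm
    diameter), 6 px tag spacing (~0.9 cm), peak radial contraction to
    alpha_min = 0.85 and peak transmural twist of 8 degrees, noise-free
    with no tag fading unless requested.
    """

    image_size: tuple[int, int] = (128, 128)
    center: tuple[float, float] | None = None
    inner_radius: float = 20.0
    outer_radius: float = 36.0
    tag_spacing: float = 6.0
    tag_contrast: float = 0.9
    background: float = 0.05
    motion: str = "contract_twist"
    translation: tuple[float, float] = (3.0, -2.0)
    rotation_max_deg: float = 8.0
    alpha_min: float = 0.85
    twist_max_deg: float = 8.0
    frames: int = 19
    tag_fading: float = 1.0
    noise_sigma: float = 0.0
    seed: int = 0
    pixel_size_mm: float = 1.48
    reference_angle: float = 90.0

    def __post_init__(self) -> None:
        h, w = self.image_size
        if not 0 < self.inner_radius < self.outer_radius < min(h, w) / 2:
            raise ValueError("need 0 < inner < outer < min(H, W)/2")
        if self.frames < 2:
            raise ValueError("need at least 2 frames")
        if not 0 < self.alpha_min <= 1:
            raise ValueError("alpha_min must be in (0, 1]")
        if self.motion not in MOTION_TYPES:
            raise ValueError(f"motion must be one of {MOTION_TYPES}")
        if not 0 <= self.tag_contrast <= 1:
            raise ValueError("tag_contrast must be in [0, 1]")

    @property
    def centre(self) -> np.ndarray:
        if self.center is not None:
            return np.asarray(self.center, float)
        h, w = self.image_size
        return np.array([(h - 1) / 2.0, (w - 1) / 2.0])

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "PhantomConfig":
        with open(path) as fh:
            d = json.load(fh)
        for key in ("image_size", "translation"):
            if d.get(key) is not None:
                d[key] = tuple(d[key])
        if d.get("center") is not None:
            d["center"] = tuple(d["center"])
        return cls(**d)


def motion_profile(cfg: PhantomConfig, t: int) -> float:
    """Temporal amplitude in [0, 1] at frame t."""
    x = t / (cfg.frames - 1)
    if cfg.motion == "translation":
        return x  # linear ramp; not cyclic
    return float(np.sin(np.pi * x) ** 2)


def _rot(psi):
    """Rotation matrices for scalar or (P,) psi, acting on (row, col)."""
    c, s = np.cos(psi), np.sin(psi)
    return np.stack(
        [np.stack([c, -s], axis=-1), np.stack([s, c], axis=-1)], axis=-2
    )


@dataclass(frozen=True)
class MotionState:
    """Closed-form motion of one frame: forward/inverse maps, Jacobian, strain."""

    cfg: PhantomConfig
    t: int
    amplitude: float = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "amplitude", motion_profile(self.cfg, self.t))

    # -- helpers -----------------------------------------------------------
    @property
    def _alpha(self) -> float:
        return 1.0 - self.amplitude * (1.0 - self.cfg.alpha_min)

    @property
    def _theta(self) -> float:
        return self.amplitude * np.deg2rad(self.cfg.rotation_max_deg)

    def _twist(self, r: np.ndarray) -> np.ndarray:
        cfg = self.cfg
        frac = np.clip(
            (r - cfg.inner_radius) / (cfg.outer_radius - cfg.inner_radius), 0.0, 1.0
        )
        return self.amplitude * np.deg2rad(cfg.twist_max_deg) * frac

    def _twist_slope(self, r: np.ndarray) -> np.ndarray:
        cfg = self.cfg
        inside = (r > cfg.inner_radius) & (r < cfg.outer_radius)
        slope = self.amplitude * np.deg2rad(cfg.twist_max_deg) / (
            cfg.outer_radius - cfg.inner_radius
        )
        return np.where(inside, slope, 0.0)

    # -- public surface ----------------------------------------------------
    def forward(self, pts: np.ndarray) -> np.ndarray:
        """phi_t of (P, 2) initial-frame points."""
        cfg = self.cfg
        p = np.atleast_2d(np.asarray(pts, float))
        if cfg.motion == "translation":
            return p + self.amplitude * np.asarray(cfg.translation)
        q = p - cfg.centre
        if cfg.motion == "rotation":
            return cfg.centre + q @ _rot(self._theta).T
        if cfg.motion == "scale":
            return cfg.centre + self._alpha * q
        r = np.linalg.norm(q, axis=1)
        R = _rot(self._twist(r))
        return cfg.centre + self._alpha * np.einsum("pij,pj->pi", R, q)

    def inverse(self, pts: np.ndarray) -> np.ndarray:
        """phi_t^{-1} of (P, 2) deformed-frame points (exact)."""
        cfg = self.cfg
        X = np.atleast_2d(np.asarray(pts, float))
        if cfg.motion == "translation":
            return X - self.amplitude * np.asarray(cfg.translation)
        qd = X - cfg.centre
        if cfg.motion == "rotation":
            return cfg.centre + qd @ _rot(-self._theta).T
        if cfg.motion == "scale":
            return cfg.centre + qd / self._alpha
        r = np.linalg.norm(qd, axis=1) / self._alpha
        R = _rot(-self._twist(r))
        return cfg.centre + np.einsum("pij,pj->pi", R, qd) / self._alpha

    def jacobian(self, pts: np.ndarray) -> np.ndarray:
        """Deformation gradient F = d(phi)/dp at (P, 2) initial points."""
        cfg = self.cfg
        p = np.atleast_2d(np.asarray(pts, float))
        P = p.shape[0]
        if cfg.motion == "translation":
            return np.broadcast_to(np.eye(2), (P, 2, 2)).copy()
        if cfg.motion == "rotation":
            return np.broadcast_to(_rot(self._theta), (P, 2, 2)).copy()
        if cfg.motion == "scale":
            return np.broadcast_to(self._alpha * np.eye(2), (P, 2, 2)).copy()
        q = p - cfg.centre
        r = np.linalg.norm(q, axis=1)
        if np.any(r == 0):
            raise ValueError("contract_twist Jacobian undefined at the centre")
        psi = self._twist(r)
        R = _rot(psi)
        u = q / r[:, None]
        JRq = np.einsum("ij,pjk,pk->pi", _J, R, q)
        F = self._alpha * (
            R + self._twist_slope(r)[:, None, None] * JRq[:, :, None] * u[:, None, :]
        )
        return F

    def almansi(self, pts: np.ndarray) -> np.ndarray:
        """Analytic Eulerian strain E = 1/2 [I - (F F^T)^{-1}] at initial points.

        The tensor lives at the deformed location phi_t(p) of each point.
        """
        F = self.jacobian(pts)
        B = F @ np.transpose(F, (0, 2, 1))
        E = 0.5 * (np.eye(2) - np.linalg.inv(B))
        return 0.5 * (E + np.transpose(E, (0, 2, 1)))


def analytic_motion(cfg: PhantomConfig, t: int) -> MotionState:
    """Motion of frame ``t`` (0-based) with closed-form map/Jacobian/strain."""
    if not 0 <= t < cfg.frames:
        raise ValueError(f"t must be in [0, {cfg.frames - 1}]")
    return MotionState(cfg=cfg, t=t)


def render_tag_image(cfg: PhantomConfig, t: int) -> ImageFrame:
    """Render frame ``t``: advected tag pattern, fading, seeded noise."""
    motion = analytic_motion(cfg, t)
    h, w = cfg.image_size
    rows, cols = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    pix = np.column_stack((rows.ravel(), cols.ravel())).astype(float)
    p0 = motion.inverse(pix)
    r0 = np.linalg.norm(p0 - cfg.centre, axis=1)
    inside = (r0 >= cfg.inner_radius) & (r0 <= cfg.outer_radius)
    s = cfg.tag_spacing
    pattern = (np.cos(np.pi * p0[:, 0] / s) ** 2) * (np.cos(np.pi * p0[:, 1] / s) ** 2)
    amp = cfg.tag_contrast * cfg.tag_fading**t
    img = np.where(inside, amp * pattern, cfg.background).reshape(h, w)
    if cfg.noise_sigma > 0:
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=cfg.seed, spawn_key=(t,))
        )
        img = img + rng.normal(0.0, cfg.noise_sigma, size=img.shape)
    return ImageFrame(pixels=img, frame_index=t, pixel_size_mm=cfg.pixel_size_mm)


def landmark_points(cfg: PhantomConfig, rings=(0.25, 0.5, 0.75)) -> PointSet:
    """18 labelled landmarks: 3 transmural rings x 6 AHA sector centres."""
    wall = cfg.outer_radius - cfg.inner_radius
    radii = [cfg.inner_radius + f * wall for f in rings]
    angles = np.deg2rad(cfg.reference_angle + 30.0 + 60.0 * np.arange(6))
    pts = []
    for r in radii:
        for a in angles:
            pts.append(
                (cfg.centre[0] - r * np.sin(a), cfg.centre[1] + r * np.cos(a))
            )
    return PointSet(points=np.array(pts), spacing=0.0)


def midwall_seeds(
    cfg: PhantomConfig, n_per_ring: int = 72, rings=(0.25, 0.5, 0.75)
) -> PointSet:
    """Dense rings of myocardial sample points for strain estimation."""
    wall = cfg.outer_radius - cfg.inner_radius
    pts = []
    for f in rings:
        r = cfg.inner_radius + f * wall
        a = 2 * np.pi * np.arange(n_per_ring) / n_per_ring
        rows = cfg.centre[0] - r * np.sin(a)
        cols = cfg.centre[1] + r * np.cos(a)
        pts.append(np.column_stack((rows, cols)))
    return PointSet(points=np.vstack(pts), spacing=0.0)


@dataclass(frozen=True)
class PhantomStudy:
    """Rendered frames plus all analytic ground truth for one phantom run."""

    config: PhantomConfig
    frames: list[ImageFrame]
    landmarks: PointSet
    truth_trajectories: np.ndarray  # (T, 18, 2)
    truth_strain: np.ndarray  # (T, 18, 2, 2) Almansi tensors
    truth_polar: np.ndarray  # (T, 18, 2) = (E_cc, E_rr)

    def motion(self, t: int) -> MotionState:
        return analytic_motion(self.config, t)


def generate_study(cfg: PhantomConfig) -> PhantomStudy:
    """Render the full cycle and tabulate landmark/strain ground truth."""
    from .motion import _polar_strain_many  # local import avoids cycle at import time

    frames = [render_tag_image(cfg, t) for t in range(cfg.frames)]
    lm = landmark_points(cfg)
    T = cfg.frames
    traj = np.zeros((T, len(lm), 2))
    strain = np.zeros((T, len(lm), 2, 2))
    polar = np.zeros((T, len(lm), 2))
    for t in range(T):
        m = analytic_motion(cfg, t)
        traj[t] = m.forward(lm.points)
        strain[t] = m.almansi(lm.points)
        polar[t] = _polar_strain_many(strain[t], traj[t], cfg.centre)
    return PhantomStudy(
        config=cfg,
        frames=frames,
        landmarks=lm,
        truth_trajectories=traj,
        truth_strain=strain,
        truth_polar=polar,
    )


def write_study(study: PhantomStudy, outdir, image_format: str = "png") -> None:
    """Write frames (16-bit PNG/TIFF or one NIfTI volume) and truth tables."""
    import os

    import pandas as pd

    os.makedirs(outdir, exist_ok=True)
    cfg = study.config
    cfg.to_json(os.path.join(outdir, "config.json"))
    stack = np.stack([f.pixels for f in study.frames])
    if image_format in ("png", "tiff", "tif"):
        import imageio.v3 as iio

        lo, hi = stack.min(), stack.max()
        scale = 65535.0 / (hi - lo) if hi > lo else 1.0
        for t, f in enumerate(study.frames):
            img16 = ((f.pixels - lo) * scale).round().astype(np.uint16)
            iio.imwrite(os.path.join(outdir, f"frame_{t:03d}.{image_format}"), img16)
    elif image_format == "nifti":
        import nibabel as nib

        affine = np.diag([cfg.pixel_size_mm, cfg.pixel_size_mm, 1.0, 1.0])
        vol = np.transpose(stack, (1, 2, 0))[:, :, None, :]
        nib.save(
            nib.Nifti1Image(vol.astype(np.float32), affine),
            os.path.join(outdir, "frames.nii"),
        )
    else:
        raise ValueError(f"unknown image format {image_format!r}")

    T, L, _ = study.truth_trajectories.shape
    rows = {
        "frame": np.repeat(np.arange(T), L),
        "point_id": np.tile(np.arange(L), T),
        "row": study.truth_trajectories[:, :, 0].ravel(),
        "col": study.truth_trajectories[:, :, 1].ravel(),
        "Ecc_truth": study.truth_polar[:, :, 0].ravel(),
        "Err_truth": study.truth_polar[:, :, 1].ravel(),
    }
    pd.DataFrame(rows).to_csv(os.path.join(outdir, "landmarks.csv"), index=False)
    study.landmarks.to_csv(os.path.join(outdir, "landmarks_frame0.csv"))


def with_seed(cfg: PhantomConfig, seed: int) -> PhantomConfig:
    """Copy of a config with a different RNG seed."""
    return replace(cfg, seed=seed)
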