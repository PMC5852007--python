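"""Fixed four-level decomposition of a short-axis image into matching parts.

A moving image is tiled by 16x16 *templates*; each template splits into four
8x8 *segments*, each segment into four 4x4 *chunks*, each chunk into four
2x2 *windows*.  The top-left pixel of every window forms the dense, uniform
moving point set that drives the correspondence search.  Between the main
levels sit *overlap* sections (14/12/10 px under a template, 6 px under a
segment) used to shrink the reference search area step by step.

All coordinates are 0-based ``(row, col)``; part ordering is row-major at
every level so downstream correspondences are reproducible.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: side lengths of the four main part levels, largest first
LEVEL_SIZES = {"template": 16, "segment": 8, "chunk": 4, "window": 2}
#: overlap-section sizes between template and segment, and segment and chunk
TEMPLATE_OVERLAP_SIZES = (14, 12, 10)
SEGMENT_OVERLAP_SIZE = 6

_VALID_SIZES = frozenset({16, 14, 12, 10, 8, 6, 4, 2})


@dataclass(frozen=True)
class ImageFrame:
    """A single 2D grayscale frame of a cardiac sequence.

    Parameters
    ----------
    pixels
        2D array of finite intensities (arbitrary units).
    frame_index
        Position of the frame in its cycle, 0-based.
    pixel_size_mm
        Isotropic pixel spacing in millimetres.
    """

    pixels: np.ndarray
    frame_index: int = 0
    pixel_size_mm: float = 1.0

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2:
            raise ValueError(f"pixels must be 2D, got shape {px.shape}")
        if px.shape[0] < 16 or px.shape[1] < 16:
            raise ValueError(f"image must be at least 16x16, got {px.shape}")
        if not np.all(np.isfinite(px)):
            raise ValueError("image intensities must be finite")
        if self.frame_index < 0:
            raise ValueError("frame_index must be >= 0")
        if self.pixel_size_mm <= 0:
            raise ValueError("pixel_size_mm must be positive")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class Part:
    """One square part of the hierarchy.

    ``indices`` is the hierarchical address ``(i,)`` for a template,
    ``(i, j)`` for a segment, ``(i, j, k)`` for a chunk and ``(i, j, k, l)``
    for a window, each index 0-based and row-major within its parent.
    """

    level: str
    origin: tuple[int, int]
    size: int
    indices: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.size not in _VALID_SIZES:
            raise ValueError(f"invalid part size {self.size}")

    @property
    def rect(self) -> tuple[int, int, int, int]:
        """``(row, col, height, width)`` of the part."""
        return (self.origin[0], self.origin[1], self.size, self.size)

    def to_dict(self) -> dict:
        return {
            "level": self.level,
            "origin": list(self.origin),
            "size": self.size,
            "indices": list(self.indices),
        }


@dataclass(frozen=True)
class PointSet:
    """An ordered set of ``(row, col)`` points with a nominal grid spacing."""

    points: np.ndarray
    spacing: float = 2.0

    def __post_init__(self) -> None:
        pts = np.atleast_2d(np.asarray(self.points, dtype=float))
        if pts.size == 0:
            pts = pts.reshape(0, 2)
        if pts.shape[1] != 2:
            raise ValueError("points must be an (N, 2) array of (row, col)")
        object.__setattr__(self, "points", pts)

    def __len__(self) -> int:
        return self.points.shape[0]

    def to_csv(self, path) -> None:
        df = pd.DataFrame(
            {
                "id": np.arange(len(self)),
                "row": self.points[:, 0],
                "col": self.points[:, 1],
            }
        )
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, spacing: float = 2.0) -> "PointSet":
        df = pd.read_csv(path)
        return cls(points=df[["row", "col"]].to_numpy(float), spacing=spacing)


@dataclass(frozen=True)
class PartGrid:
    """The complete part hierarchy for one image.

    Templates tile the largest ``t``-divisible sub-rectangle anchored at
    (0, 0); any remaining border strip is excluded (and recorded in
    ``excluded_rows`` / ``excluded_cols``).
    """

    t: int
    image_dims: tuple[int, int]
    grid_shape: tuple[int, int]  # number of templates (rows, cols)
    excluded_rows: int = 0
    excluded_cols: int = 0
    _templates: tuple[Part, ...] = field(default=(), repr=False)

    @property
    def templates(self) -> tuple[Part, ...]:
        return self._templates

    def children(self, part: Part) -> list[Part]:
        """The four equal quadrant sub-parts of ``part``, row-major."""
        child_level = {"template": "segment", "segment": "chunk", "chunk": "window"}
        if part.level not in child_level:
            raise ValueError(f"part of level {part.level!r} has no children")
        half = part.size // 2
        out = []
        for q, (dr, dc) in enumerate(((0, 0), (0, half), (half, 0), (half, half))):
            out.append(
                Part(
                    level=child_level[part.level],
                    origin=(part.origin[0] + dr, part.origin[1] + dc),
                    size=half,
                    indices=part.indices + (q,),
                )
            )
        return out

    def iter_level(self, level: str):
        """Yield all parts of one main level in hierarchical row-major order."""
        if level == "template":
            yield from self._templates
            return
        for tpl in self._templates:
            if level == "segment":
                yield from self.children(tpl)
            else:
                for seg in self.children(tpl):
                    if level == "chunk":
                        yield from self.children(seg)
                    else:
                        for ch in self.children(seg):
                            yield from self.children(ch)

    @property
    def parts(self) -> list[Part]:
        """Every part at all four main levels."""
        out: list[Part] = []
        for level in ("template", "segment", "chunk", "window"):
            out.extend(self.iter_level(level))
        return out

    def counts(self) -> dict[str, int]:
        n_t = self.grid_shape[0] * self.grid_shape[1]
        return {
            "template": n_t,
            "segment": 4 * n_t,
            "chunk": 16 * n_t,
            "window": 64 * n_t,
        }

    def to_json(self, path) -> None:
        payload = {
            "t": self.t,
            "image_dims": list(self.image_dims),
            "grid_shape": list(self.grid_shape),
            "excluded_rows": self.excluded_rows,
            "excluded_cols": self.excluded_cols,
            "parts": [p.to_dict() for p in self.parts],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)


def decompose(image_dims: tuple[int, int], t: int = 16) -> PartGrid:
    """Tile an image of ``image_dims`` into the fixed part hierarchy.

    Raises a dimension error when the image is smaller than one template.
    Border strips narrower than ``t`` are excluded from the tiling.
    """
    h, w = image_dims
    if t < 2 or t % 2:
        raise ValueError(f"template size must be a positive even number, got {t}")
    if h < t or w < t:
        raise ValueError(
            f"image dims {image_dims} smaller than template size {t}"
        )
    n_rows, n_cols = h // t, w // t
    excl_r, excl_c = h - n_rows * t, w - n_cols * t
    if excl_r or excl_c:
        logger.info(
            "decompose: excluding border strip of %d rows / %d cols "
            "(image %dx%d, template %d)",
            excl_r, excl_c, h, w, t,
        )
    templates = tuple(
        Part(level="template", origin=(r * t, c * t), size=t, indices=(r * n_cols + c,))
        for r in range(n_rows)
        for c in range(n_cols)
    )
    return PartGrid(
        t=t,
        image_dims=(h, w),
        grid_shape=(n_rows, n_cols),
        excluded_rows=excl_r,
        excluded_cols=excl_c,
        _templates=templates,
    )


def window_points(grid: PartGrid) -> PointSet:
    """Top-left pixel of every window, in hierarchical enumeration order.

    This is the dense moving point set: one point per 2x2 window, spacing 2,
    ordered template-major then segment/chunk/window row-major.
    """
    pts = np.array([p.origin for p in grid.iter_level("window")], dtype=float)
    return PointSet(points=pts.reshape(-1, 2), spacing=grid.t / 8)


def coarse_points(grid: PartGrid) -> PointSet:
    """First points of *all* parts (diagnostic coarse set, duplicates removed
    only by ordering — a template and its first segment share an origin)."""
    pts = np.array([p.origin for p in grid.parts], dtype=float)
    return PointSet(points=pts.reshape(-1, 2), spacing=float(grid.t))
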