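"""The hierarchical template-matching cascade.

Each 16x16 moving template is first located in the reference image by NCC
over a search area around its own position.  The matched reference region is
then shrunk through the overlap layers (14, 12, 10 px) towards each segment,
the segment is matched inside the refined region, the 6 px overlap layer
bridges segment to chunk, and finally each 2x2 window is matched inside its
chunk's reference region.  The top-left pixels of the moving windows and of
their matched reference regions form the dense point correspondence.

Every sub-template search looks at the child's *expected* position (its
offset relative to the matched parent) dilated by ``overlap_margin`` pixels.
Overlap sections are aligned so that they always contain the child they are
refining towards; this keeps each search window smaller than one tag period,
so a periodic tag pattern cannot alias the match, while guaranteeing the
child's true position is inside the searched area.  Flat (zero-variance)
parts and searches clipped below the part size fall back to the moving
part's own relative position and are flagged degenerate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .image_parts import (
    SEGMENT_OVERLAP_SIZE,
    TEMPLATE_OVERLAP_SIZES,
    ImageFrame,
    Part,
    PartGrid,
    PointSet,
    decompose,
)
from .ncc import best_match, ncc_map

FLAG_OK = "ok"
FLAG_DEGENERATE = "degenerate"
FLAG_LOW_CONFIDENCE = "low_confidence"


@dataclass(frozen=True)
class SearchConfig:
    """Search-extent knobs of the cascade (plumbing, not model parameters).

    template_search_radius
        Padding (px) around a template's own location when searching the
        reference image; ``None`` searches the whole reference image.
        Default 8: inter-frame cardiac motion is small.
    overlap_margin
        Padding (px) around a child's expected position inside its matched
        parent region.  Default 2.
    min_peak_cc
        Window-level correlations below this are flagged low-confidence.
    tie_tolerance
        Correlation peaks within this of the maximum count as tied and
        resolve towards the expected position.  Smooth tag patterns leave
        small patches under-constrained along a tag line (the aperture
        problem): their correlation ridge is flat to ~1e-3, so such offsets
        carry no localisation information and the parent's prediction is
        the best estimate.
    """

    template_search_radius: int | None = 8
    overlap_margin: int = 2
    min_peak_cc: float = 0.0
    tie_tolerance: float = 1e-3

    def __post_init__(self) -> None:
        if self.template_search_radius is not None and self.template_search_radius < 0:
            raise ValueError("template_search_radius must be >= 0")
        if self.overlap_margin < 0:
            raise ValueError("overlap_margin must be >= 0")
        if not -1.0 <= self.min_peak_cc <= 1.0:
            raise ValueError("min_peak_cc must be in [-1, 1]")


@dataclass(frozen=True)
class MatchedRegion:
    """A square reference-image region matched to some moving part.

    ``subpixel`` is a sub-pixel correction of the match position from a
    parabolic fit of the correlation peak; it refines the emitted point but
    never the integer region geometry used to search children.
    """

    origin: tuple[int, int]
    size: int
    peak_cc: float
    degenerate: bool
    subpixel: tuple[float, float] = (0.0, 0.0)

    @property
    def rect(self) -> tuple[int, int, int, int]:
        return (self.origin[0], self.origin[1], self.size, self.size)

    @property
    def point(self) -> tuple[float, float]:
        """Matched location (top-left) including the sub-pixel correction."""
        return (self.origin[0] + self.subpixel[0], self.origin[1] + self.subpixel[1])


@dataclass(frozen=True)
class Correspondences:
    """Paired moving/reference window points with per-pair peak correlation."""

    moving: PointSet
    reference: PointSet
    peak_cc: np.ndarray
    flags: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.moving)
        if not (len(self.reference) == n == len(self.peak_cc) == len(self.flags)):
            raise ValueError("moving/reference/peak_cc/flags lengths differ")

    def __len__(self) -> int:
        return len(self.moving)

    @property
    def displacements(self) -> np.ndarray:
        return self.reference.points - self.moving.points

    def ok_mask(self) -> np.ndarray:
        """Pairs usable as transform control points (not degenerate)."""
        return self.flags != FLAG_DEGENERATE

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {
                "id": np.arange(len(self)),
                "mov_row": self.moving.points[:, 0],
                "mov_col": self.moving.points[:, 1],
                "ref_row": self.reference.points[:, 0],
                "ref_col": self.reference.points[:, 1],
                "peak_cc": self.peak_cc,
                "flag": self.flags,
            }
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "Correspondences":
        df = pd.read_csv(path)
        return cls(
            moving=PointSet(df[["mov_row", "mov_col"]].to_numpy(float)),
            reference=PointSet(df[["ref_row", "ref_col"]].to_numpy(float)),
            peak_cc=df["peak_cc"].to_numpy(float),
            flags=df["flag"].to_numpy(str),
        )


def _clip_origin(origin: tuple[int, int], size: int, shape: tuple[int, int]):
    r = int(min(max(origin[0], 0), shape[0] - size))
    c = int(min(max(origin[1], 0), shape[1] - size))
    return (r, c)


def _parabolic_delta(g: np.ndarray, off: tuple[int, int]) -> tuple[float, float]:
    """Sub-pixel peak position from a 1D parabola through gamma along each
    axis; 0 where the peak sits on the map border or the fit degenerates."""
    delta = [0.0, 0.0]
    for ax in range(2):
        idx = off[ax]
        if idx <= 0 or idx >= g.shape[ax] - 1:
            continue
        if ax == 0:
            gm, g0, gp = g[idx - 1, off[1]], g[idx, off[1]], g[idx + 1, off[1]]
        else:
            gm, g0, gp = g[off[0], idx - 1], g[off[0], idx], g[off[0], idx + 1]
        denom = gm - 2.0 * g0 + gp
        if denom >= 0:  # not a concave peak
            continue
        d = 0.5 * (gm - gp) / denom
        delta[ax] = float(np.clip(d, -0.5, 0.5))
    return (delta[0], delta[1])


def _search(
    part_px: np.ndarray,
    ref_px: np.ndarray,
    expected_origin: tuple[int, int],
    pad: int | None,
    subpixel: bool = False,
    tie_tol: float = 1e-9,
) -> MatchedRegion:
    """Match ``part_px`` near ``expected_origin`` in the reference image.

    The search area is the expected rect dilated by ``pad`` px (whole image
    if ``pad`` is None), clipped to the image.  Degenerate searches fall
    back to the (clipped) expected position.  With ``subpixel`` the peak
    position is refined by a parabolic fit of gamma, except when the match
    is exact (peak at 1 within rounding).
    """
    ph, pw = part_px.shape
    H, W = ref_px.shape
    fallback = _clip_origin(expected_origin, ph, ref_px.shape)
    if pad is None:
        r0, c0, r1, c1 = 0, 0, H, W
    else:
        r0 = max(expected_origin[0] - pad, 0)
        c0 = max(expected_origin[1] - pad, 0)
        r1 = min(expected_origin[0] + ph + pad, H)
        c1 = min(expected_origin[1] + pw + pad, W)
    if r1 - r0 < ph or c1 - c0 < pw:
        return MatchedRegion(origin=fallback, size=ph, peak_cc=0.0, degenerate=True)
    cmap = ncc_map(part_px, ref_px[r0:r1, c0:c1])
    # near-ties resolve towards the expected (parent-relative) position
    m = best_match(
        cmap, prefer=(expected_origin[0] - r0, expected_origin[1] - c0), tol=tie_tol
    )
    if m.is_degenerate:
        return MatchedRegion(origin=fallback, size=ph, peak_cc=m.peak_cc, degenerate=True)
    delta = (0.0, 0.0)
    if subpixel and m.peak_cc < 1.0 - 1e-9:
        delta = _parabolic_delta(cmap.gamma, m.offset)
    return MatchedRegion(
        origin=(r0 + m.offset[0], c0 + m.offset[1]),
        size=ph,
        peak_cc=m.peak_cc,
        degenerate=False,
        subpixel=delta,
    )


def match_template(
    moving: ImageFrame, reference: ImageFrame, mt: Part, cfg: SearchConfig
) -> MatchedRegion:
    """Locate one 16x16 moving template in the reference image."""
    r, c, h, w = mt.rect
    part = moving.pixels[r : r + h, c : c + w]
    return _search(
        part, reference.pixels, mt.origin, cfg.template_search_radius,
        tie_tol=cfg.tie_tolerance,
    )


def _aligned_section_origin(
    parent_origin: tuple[int, int],
    parent_size: int,
    section_size: int,
    target: Part | None,
) -> tuple[int, int]:
    """Origin of a section inside its parent: centered, or clamped-centered
    on ``target`` so the section contains the part being refined towards."""
    if target is None:
        off = (parent_size - section_size) // 2
        return (parent_origin[0] + off, parent_origin[1] + off)
    out = []
    for ax in range(2):
        want = target.origin[ax] + target.size / 2.0 - section_size / 2.0
        rel = int(round(want)) - parent_origin[ax]
        rel = min(max(rel, 0), parent_size - section_size)
        out.append(parent_origin[ax] + rel)
    return (out[0], out[1])


def refine_by_overlap(
    moving: ImageFrame,
    reference: ImageFrame,
    parent: Part,
    matched: MatchedRegion,
    section_sizes,
    cfg: SearchConfig,
    target: Part | None = None,
) -> tuple[tuple[int, int], MatchedRegion]:
    """Shrink a matched reference region through the overlap layers.

    At each size the moving section (centered in its parent, or aligned to
    contain ``target``) is matched near its expected position in the current
    reference region.  Returns the final moving-section origin together with
    the final, smallest matched reference region.
    """
    sizes = list(section_sizes)
    if any(b >= a for a, b in zip([parent.size] + sizes, sizes)):
        raise ValueError(f"section sizes must strictly decrease below {parent.size}")
    cur_mov = parent.origin
    cur_size = parent.size
    cur_ref = matched
    for z in sizes:
        sec_origin = _aligned_section_origin(cur_mov, cur_size, z, target)
        rel = (sec_origin[0] - cur_mov[0], sec_origin[1] - cur_mov[1])
        expected = (cur_ref.origin[0] + rel[0], cur_ref.origin[1] + rel[1])
        sec_px = moving.pixels[sec_origin[0] : sec_origin[0] + z, sec_origin[1] : sec_origin[1] + z]
        cur_ref = _search(
            sec_px, reference.pixels, expected, cfg.overlap_margin,
            tie_tol=cfg.tie_tolerance,
        )
        cur_mov, cur_size = sec_origin, z
    return cur_mov, cur_ref


def match_children(
    moving: ImageFrame,
    reference: ImageFrame,
    children,
    parent_moving_origin: tuple[int, int],
    ref_parent: MatchedRegion,
    cfg: SearchConfig,
    subpixel: bool = False,
) -> list[MatchedRegion]:
    """Match each child part near its expected position in the matched
    parent region (expected rect dilated by ``overlap_margin``)."""
    out = []
    for child in children:
        r, c, h, w = child.rect
        rel = (r - parent_moving_origin[0], c - parent_moving_origin[1])
        expected = (ref_parent.origin[0] + rel[0], ref_parent.origin[1] + rel[1])
        part = moving.pixels[r : r + h, c : c + w]
        out.append(
            _search(part, reference.pixels, expected, cfg.overlap_margin, subpixel,
                    tie_tol=cfg.tie_tolerance)
        )
    return out


def htm_correspondences(
    moving: ImageFrame,
    reference: ImageFrame,
    cfg: SearchConfig | None = None,
    grid: PartGrid | None = None,
) -> Correspondences:
    """Run the full cascade and emit one point pair per 2x2 window.

    The moving point is the window's top-left pixel, the reference point the
    top-left of its matched reference region, ordered by the hierarchical
    template/segment/chunk/window enumeration.
    """
    if cfg is None:
        cfg = SearchConfig()
    if moving.shape != reference.shape:
        raise ValueError(
            f"moving {moving.shape} and reference {reference.shape} dims differ"
        )
    if grid is None:
        grid = decompose(moving.shape)

    mov_pts: list[tuple[int, int]] = []
    ref_pts: list[tuple[int, int]] = []
    peaks: list[float] = []
    flags: list[str] = []

    def emit(win: Part, region: MatchedRegion) -> None:
        mov_pts.append(win.origin)
        ref_pts.append(region.point)
        peaks.append(region.peak_cc)
        if region.degenerate:
            flags.append(FLAG_DEGENERATE)
        elif region.peak_cc < cfg.min_peak_cc:
            flags.append(FLAG_LOW_CONFIDENCE)
        else:
            flags.append(FLAG_OK)

    for tpl in grid.templates:
        r, c, h, w = tpl.rect
        tpl_px = moving.pixels[r : r + h, c : c + w]
        if np.ptp(tpl_px) == 0.0:
            # exactly flat template: every descendant is flat too
            for seg in grid.children(tpl):
                for ch in grid.children(seg):
                    for win in grid.children(ch):
                        emit(win, MatchedRegion(win.origin, win.size, 0.0, True))
            continue
        rt = match_template(moving, reference, tpl, cfg)
        for seg in grid.children(tpl):
            mov_sec, rx = refine_by_overlap(
                moving, reference, tpl, rt, TEMPLATE_OVERLAP_SIZES, cfg, target=seg
            )
            rs = match_children(moving, reference, [seg], mov_sec, rx, cfg)[0]
            for ch in grid.children(seg):
                mov_y, ry = refine_by_overlap(
                    moving, reference, seg, rs, [SEGMENT_OVERLAP_SIZE], cfg, target=ch
                )
                rc = match_children(moving, reference, [ch], mov_y, ry, cfg)[0]
                for win, rw in zip(
                    grid.children(ch),
                    match_children(
                        moving, reference, grid.children(ch), ch.origin, rc, cfg
                    ),
                ):
                    emit(win, rw)

    return Correspondences(
        moving=PointSet(np.array(mov_pts, float), spacing=2.0),
        reference=PointSet(np.array(ref_pts, float), spacing=2.0),
        peak_cc=np.array(peaks, float),
        flags=np.array(flags, dtype=object),
    )


def tracking_correspondences(
    moving: ImageFrame,
    reference: ImageFrame,
    cfg: SearchConfig | None = None,
    grid: PartGrid | None = None,
) -> Correspondences:
    """Segment-scale control-point correspondences for transform fitting.

    Runs the cascade down to the segment level only and emits one pair per
    non-flat segment: moving point = segment centre, reference point =
    matched segment centre refined to sub-pixel by a parabolic fit of the
    correlation peak.  A tag pattern makes parts smaller than one tag
    period impossible to localise on their own (their correlation surface
    is flat or deceptive along tag lines), so the 8x8 segment — the
    smallest part spanning a full tag period in both axes — is the finest
    scale at which a displacement estimate is statistically reliable; the
    estimate is attributed to the segment centre, where block-matching
    actually measures it.  Sequential tracking fits the LWM transform on
    these points.
    """
    if cfg is None:
        cfg = SearchConfig()
    if moving.shape != reference.shape:
        raise ValueError(
            f"moving {moving.shape} and reference {reference.shape} dims differ"
        )
    if grid is None:
        grid = decompose(moving.shape)

    mov_pts: list[np.ndarray] = []
    ref_pts: list[np.ndarray] = []
    peaks: list[float] = []
    flags: list[str] = []
    centre_off = 3.5  # centre of an 8x8 part relative to its origin
    for tpl in grid.templates:
        r, c, h, w = tpl.rect
        if np.ptp(moving.pixels[r : r + h, c : c + w]) == 0.0:
            continue  # flat template: no usable control points inside
        rt = match_template(moving, reference, tpl, cfg)
        for seg in grid.children(tpl):
            mov_sec, rx = refine_by_overlap(
                moving, reference, tpl, rt, TEMPLATE_OVERLAP_SIZES, cfg, target=seg
            )
            rs = match_children(
                moving, reference, [seg], mov_sec, rx, cfg, subpixel=True
            )[0]
            if rs.degenerate:
                continue
            mov_pts.append(np.asarray(seg.origin, float) + centre_off)
            ref_pts.append(np.asarray(rs.point, float) + centre_off)
            peaks.append(rs.peak_cc)
            flags.append(
                FLAG_LOW_CONFIDENCE if rs.peak_cc < cfg.min_peak_cc else FLAG_OK
            )

    return Correspondences(
        moving=PointSet(np.array(mov_pts, float).reshape(-1, 2), spacing=8.0),
        reference=PointSet(np.array(ref_pts, float).reshape(-1, 2), spacing=8.0),
        peak_cc=np.array(peaks, float),
        flags=np.array(flags, dtype=object),
    )
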