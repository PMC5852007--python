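"""Normalized cross-correlation of a small part against a search region.

The correlation coefficient at offset (u, v),

    gamma(u, v) = sum[(f - fbar_{u,v}) (p - pbar)]
                  / sqrt(sum (f - fbar_{u,v})^2 * sum (p - pbar)^2),

is computed in three steps: raw cross-correlation of the mean-removed part
against the region, local sums/energies of the region from pre-computed
running (integral) sums, and normalisation of the cross-correlation by the
local statistics.  Offsets where either the part or the region window has
zero variance are undefined under this normalisation; they are reported as
gamma = 0 and flagged degenerate so that flat 2x2 blood-pool windows never
produce NaN.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

#: tolerance absorbing floating-point rounding on |gamma| <= 1
GAMMA_EPS = 1e-9

# Relative variance floor: a window whose variance is below this fraction of
# its mean-square intensity is treated as flat.  Well below any real tag
# modulation, well above accumulated rounding of the running sums.
_REL_VAR_FLOOR = 1e-12
_ABS_VAR_FLOOR = 1e-30


@dataclass(frozen=True)
class Patch:
    """A rectangular pixel patch and where it came from in its source image."""

    pixels: np.ndarray
    origin_in_source: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2 or px.size == 0:
            raise ValueError("patch must be a non-empty 2D array")
        if not np.all(np.isfinite(px)):
            raise ValueError("patch values must be finite")
        object.__setattr__(self, "pixels", px)


@dataclass(frozen=True)
class CorrelationMap:
    """gamma(u, v) over all valid offsets of a part within a region."""

    gamma: np.ndarray
    degenerate_mask: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        return self.gamma.shape


@dataclass(frozen=True)
class MatchResult:
    """Best-match offset (top-left, region coordinates) and its correlation."""

    offset: tuple[int, int]
    peak_cc: float
    is_degenerate: bool


def _local_sums(a: np.ndarray, h: int, w: int) -> np.ndarray:
    """Sum of every h x w window of ``a`` via a running-sum table."""
    ii = np.zeros((a.shape[0] + 1, a.shape[1] + 1), dtype=float)
    np.cumsum(a, axis=0, out=ii[1:, 1:])
    np.cumsum(ii[1:, 1:], axis=1, out=ii[1:, 1:])
    return ii[h:, w:] - ii[:-h, w:] - ii[h:, :-w] + ii[:-h, :-w]


def ncc_map(template, region) -> CorrelationMap:
    """Correlate ``template`` against every window of ``region``.

    Accepts :class:`Patch` or plain 2D arrays.  Raises a dimension error if
    the region is smaller than the template in either axis.
    """
    tpl = template.pixels if isinstance(template, Patch) else np.asarray(template, float)
    reg = region.pixels if isinstance(region, Patch) else np.asarray(region, float)
    th, tw = tpl.shape
    rh, rw = reg.shape
    if th * tw < 2:
        raise ValueError("template must have at least 2 pixels")
    if rh < th or rw < tw:
        raise ValueError(
            f"search region {reg.shape} smaller than template {tpl.shape}"
        )

    p = tpl - tpl.mean()
    p_energy = float((p * p).sum())
    tpl_scale = float((tpl * tpl).mean())
    tpl_flat = p_energy <= max(_ABS_VAR_FLOOR, _REL_VAR_FLOOR * th * tw * tpl_scale)

    # step i: raw cross-correlation (sum f * (p - pbar), the fbar term cancels)
    windows = sliding_window_view(reg, (th, tw))
    cross = np.einsum("uvxy,xy->uv", windows, p, optimize=False)

    # step ii: local sums of the region via running sums
    s1 = _local_sums(reg, th, tw)
    s2 = _local_sums(reg * reg, th, tw)
    n = th * tw
    f_var = s2 - s1 * s1 / n  # sum (f - fbar)^2 per window
    reg_flat = f_var <= np.maximum(_ABS_VAR_FLOOR, _REL_VAR_FLOOR * s2)

    # step iii: normalise
    degenerate = reg_flat | tpl_flat
    denom = np.sqrt(np.clip(f_var * p_energy, _ABS_VAR_FLOOR, None))
    gamma = np.where(degenerate, 0.0, cross / denom)
    gamma = np.clip(gamma, -1.0 - GAMMA_EPS, 1.0 + GAMMA_EPS)
    return CorrelationMap(gamma=gamma, degenerate_mask=degenerate)


def best_match(
    cmap: CorrelationMap,
    prefer: tuple[int, int] | None = None,
    tol: float = GAMMA_EPS,
) -> MatchResult:
    """Offset of the maximum non-degenerate gamma.

    Offsets within ``tol`` of the maximum are treated as tied (by default
    only float-rounding ties; a caller tracking smooth, locally 1-D texture
    may widen this to treat statistically indistinguishable peaks as tied,
    e.g. correlation flat along a tag line).  Ties
    are broken towards ``prefer`` (the a-priori expected offset, smallest
    Euclidean distance) when given, then by smallest row, then smallest
    column.  If every offset is degenerate the centre offset is returned
    with ``is_degenerate=True``.
    """
    g = cmap.gamma
    if g.size == 0:
        raise ValueError("empty correlation map")
    if cmap.degenerate_mask.all():
        h, w = g.shape
        return MatchResult(offset=(h // 2, w // 2), peak_cc=0.0, is_degenerate=True)
    masked = np.where(cmap.degenerate_mask, -np.inf, g)
    peak = masked.max()
    tied = np.argwhere(masked >= peak - max(tol, GAMMA_EPS))  # row-major order
    if prefer is not None and len(tied) > 1:
        d2 = ((tied - np.asarray(prefer)) ** 2).sum(axis=1)
        off = tied[int(np.argmin(d2))]  # argmin keeps row-major among equals
    else:
        off = tied[0]
    off = (int(off[0]), int(off[1]))
    return MatchResult(offset=off, peak_cc=float(g[off]), is_degenerate=False)
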