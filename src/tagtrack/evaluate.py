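"""Target registration error and model-comparison harness.

TRE is the RMSE between tracked and true positions of landmarks that were
withheld from transform estimation; it is reported per frame (px and mm)
and aggregated as mean +/- sd over the tracked frames.  The comparison
harness pairs per-image errors of two models, runs a paired t-test, and
expresses model B's error as a percentage of model A's (A = 100%).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class TREReport:
    """Per-frame and aggregate landmark registration error."""

    per_frame_px: np.ndarray
    per_frame_mm: np.ndarray
    mean_px: float
    sd_px: float
    mean_mm: float
    sd_mm: float
    landmark_count: int
    pixel_size_mm: float
    pooling: str = "frames"  # what mean +/- sd pools over

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frame": np.arange(len(self.per_frame_px)),
                "rmse_px": self.per_frame_px,
                "rmse_mm": self.per_frame_mm,
            }
        )

    def to_dict(self) -> dict:
        return {
            "per_frame_px": self.per_frame_px.tolist(),
            "per_frame_mm": self.per_frame_mm.tolist(),
            "mean_px": self.mean_px,
            "sd_px": self.sd_px,
            "mean_mm": self.mean_mm,
            "sd_mm": self.sd_mm,
            "landmark_count": self.landmark_count,
            "pixel_size_mm": self.pixel_size_mm,
            "pooling": self.pooling,
        }


def tre(tracked, truth, pixel_size_mm: float = 1.0) -> TREReport:
    """RMSE between tracked and true landmark trajectories.

    Both inputs are ``(T, P, 2)`` arrays (or objects with a ``positions``
    attribute of that shape) over the same points and frames.  Frame 0 is
    the seeding frame (error 0 by construction); the aggregate mean +/- sd
    pools the per-frame RMSE of frames 1..T-1.
    """
    a = np.asarray(getattr(tracked, "positions", tracked), float)
    b = np.asarray(getattr(truth, "positions", truth), float)
    if a.shape != b.shape or a.ndim != 3 or a.shape[2] != 2:
        raise ValueError(f"shape mismatch: tracked {a.shape} vs truth {b.shape}")
    sq = ((a - b) ** 2).sum(axis=2)  # (T, P) squared distances
    per_frame = np.sqrt(sq.mean(axis=1))
    tracked_frames = per_frame[1:] if len(per_frame) > 1 else per_frame
    return TREReport(
        per_frame_px=per_frame,
        per_frame_mm=per_frame * pixel_size_mm,
        mean_px=float(tracked_frames.mean()),
        sd_px=float(tracked_frames.std(ddof=1)) if len(tracked_frames) > 1 else 0.0,
        mean_mm=float(tracked_frames.mean() * pixel_size_mm),
        sd_mm=float(tracked_frames.std(ddof=1) * pixel_size_mm)
        if len(tracked_frames) > 1
        else 0.0,
        landmark_count=a.shape[1],
        pixel_size_mm=pixel_size_mm,
    )


@dataclass(frozen=True)
class ComparisonReport:
    """Paired comparison of two models' per-image errors (A is the base)."""

    mean_a: float
    mean_b: float
    t_statistic: float
    p_value: float
    percent_error_b: float  # B as % of A (A = 100%)
    percent_reduction: float  # 100 * (mean_a - mean_b) / mean_a
    degenerate: bool  # zero-variance paired differences: t-test undefined
    n_pairs: int

    def to_dict(self) -> dict:
        return {
            "mean_a": self.mean_a,
            "mean_b": self.mean_b,
            "t_statistic": self.t_statistic,
            "p_value": self.p_value,
            "percent_error_b": self.percent_error_b,
            "percent_reduction": self.percent_reduction,
            "degenerate": self.degenerate,
            "n_pairs": self.n_pairs,
        }


def compare(errors_a, errors_b) -> ComparisonReport:
    """Paired t-test and percentage error reduction of model B vs model A.

    Identical error vectors (or any zero-variance paired difference) make
    the t statistic undefined; the reduction is still exact and the report
    is flagged degenerate instead of emitting infinities.
    """
    a = np.asarray(errors_a, float)
    b = np.asarray(errors_b, float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError(f"paired error vectors must match: {a.shape} vs {b.shape}")
    if len(a) < 2:
        raise ValueError("need at least 2 paired errors")
    mean_a, mean_b = float(a.mean()), float(b.mean())
    diff = a - b
    degenerate = bool(np.allclose(diff, diff[0]))
    if degenerate:
        t_stat, p_val = float("nan"), float("nan")
    else:
        res = stats.ttest_rel(a, b)
        t_stat, p_val = float(res.statistic), float(res.pvalue)
    if mean_a == 0:
        pct_b = float("nan")
        reduction = float("nan")
    else:
        pct_b = 100.0 * mean_b / mean_a
        reduction = 100.0 * (mean_a - mean_b) / mean_a
    return ComparisonReport(
        mean_a=mean_a,
        mean_b=mean_b,
        t_statistic=t_stat,
        p_value=p_val,
        percent_error_b=pct_b,
        percent_reduction=reduction,
        degenerate=degenerate,
        n_pairs=len(a),
    )
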