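"""Reference-region Patlak quantification of irreversible tracer uptake.

For a tracer that is irreversibly trapped in the target tissue (here
[18F]-FDOPA converted to dopamine in the striatum), the Gjedde–Patlak
graphical analysis linearises the late part of the scan: plotting

    y(t) = C_T(t) / C_ref(t)   against   x(t) = \\int_0^t C_ref(s) ds / C_ref(t)

yields, after the reversible compartments equilibrate (t >= t*), a straight
line whose slope is the influx rate constant k_i^cer (min^-1) relative to the
reference region (cerebellar grey matter, essentially devoid of specific
trapping).  The slope is the package's index of dopamine synthesis capacity.

The module provides the frame-schedule and time-activity-curve containers,
the Patlak transform, and a small statsmodels-flavoured model/results pair
(:class:`PatlakModel` / :class:`PatlakResults`).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FrameSchedule",
    "TimeActivityCurve",
    "PatlakModel",
    "PatlakResults",
    "build_frame_schedule",
    "study_frame_schedule",
    "cumulative_integral",
    "patlak_transform",
    "patlak_fit",
    "roi_mean_ki",
    "load_ki_map_nifti",
]

logger = logging.getLogger(__name__)

#: 24-frame dynamic schedule used for the 89-min [18F]-FDOPA acquisition:
#: 4 x 1 min, 3 x 2 min, 3 x 3 min, 14 x 5 min.
STUDY_FRAME_BLOCKS: tuple[tuple[int, float], ...] = ((4, 1.0), (3, 2.0), (3, 3.0), (14, 5.0))


@dataclass(frozen=True)
class FrameSchedule:
    """Start/end times (minutes) of the frames of a dynamic PET acquisition."""

    frame_start: np.ndarray
    frame_end: np.ndarray

    def __post_init__(self) -> None:
        start = np.asarray(self.frame_start, dtype=float)
        end = np.asarray(self.frame_end, dtype=float)
        object.__setattr__(self, "frame_start", start)
        object.__setattr__(self, "frame_end", end)
        if start.ndim != 1 or start.shape != end.shape:
            raise ValueError("frame_start and frame_end must be 1-D arrays of equal length")
        if len(start) == 0:
            raise ValueError("schedule must contain at least one frame")
        if start[0] < 0:
            raise ValueError("first frame must start at a non-negative time")
        if np.any(end <= start):
            raise ValueError("every frame must end after it starts")
        if np.any(np.diff(start) <= 0):
            raise ValueError("frame starts must be strictly increasing")
        if np.any(start[1:] < end[:-1] - 1e-12):
            raise ValueError("frames must not overlap")

    @property
    def n_frames(self) -> int:
        return len(self.frame_start)

    @property
    def mid_times(self) -> np.ndarray:
        return 0.5 * (self.frame_start + self.frame_end)

    @property
    def durations(self) -> np.ndarray:
        return self.frame_end - self.frame_start

    @property
    def total_duration(self) -> float:
        return float(self.frame_end[-1] - self.frame_start[0])


@dataclass(frozen=True)
class TimeActivityCurve:
    """Frame-wise activity (kBq/mL) for one region."""

    schedule: FrameSchedule
    activity: np.ndarray
    region_label: str = ""

    def __post_init__(self) -> None:
        act = np.asarray(self.activity, dtype=float)
        object.__setattr__(self, "activity", act)
        if act.shape != (self.schedule.n_frames,):
            raise ValueError(
                f"activity length {act.shape} does not match schedule "
                f"({self.schedule.n_frames} frames)"
            )
        if not np.all(np.isfinite(act)):
            raise ValueError("activity values must be finite")


def build_frame_schedule(blocks: list[tuple[int, float]]) -> FrameSchedule:
    """Build a contiguous schedule from ``(count, duration_min)`` blocks.

    ``[(4, 1), (3, 2), (3, 3), (14, 5)]`` gives the study's 24-frame,
    89-minute acquisition.
    """
    if not blocks:
        raise ValueError("block list must not be empty")
    durations: list[float] = []
    for count, dur in blocks:
        if count < 1:
            raise ValueError(f"block count must be >= 1, got {count}")
        if dur <= 0:
            raise ValueError(f"frame duration must be positive, got {dur}")
        durations.extend([float(dur)] * int(count))
    edges = np.concatenate([[0.0], np.cumsum(durations)])
    return FrameSchedule(frame_start=edges[:-1], frame_end=edges[1:])


def study_frame_schedule() -> FrameSchedule:
    """The study's 24-frame / 89-min dynamic schedule."""
    return build_frame_schedule(list(STUDY_FRAME_BLOCKS))


def cumulative_integral(tac: TimeActivityCurve) -> np.ndarray:
    """Running integral of the TAC evaluated at frame mid-times (kBq*min/mL).

    The frame value is treated as constant over its interval (matching how
    frame-averaged data are generated); activity before the first frame start
    is taken as zero, and gaps between frames contribute nothing.  At the
    mid-time of frame ``i`` the integral is the sum of all completed earlier
    frames plus ``activity[i] * (mid - start)`` of the current frame.
    """
    sched = tac.schedule
    frame_area = tac.activity * sched.durations
    completed = np.concatenate([[0.0], np.cumsum(frame_area)[:-1]])
    return completed + tac.activity * (sched.mid_times - sched.frame_start)


def patlak_transform(
    target: TimeActivityCurve,
    reference: TimeActivityCurve,
    eps: float = 1e-12,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Patlak coordinates ``x = int C_ref / C_ref`` (min), ``y = C_T / C_ref``.

    Returns ``(x, y, used)`` where ``used`` is the boolean frame mask after
    dropping frames with reference activity <= ``eps``.
    """
    if target.schedule.n_frames != reference.schedule.n_frames or not (
        np.allclose(target.schedule.frame_start, reference.schedule.frame_start)
        and np.allclose(target.schedule.frame_end, reference.schedule.frame_end)
    ):
        raise ValueError("target and reference schedules must be identical")
    ref = reference.activity
    used = ref > eps
    n_dropped = int(np.sum(~used))
    if n_dropped:
        logger.info("patlak_transform: dropped %d frame(s) with reference activity <= %g",
                    n_dropped, eps)
    if np.sum(used) < 3:
        raise ValueError("fewer than 3 frames with usable reference activity")
    x = cumulative_integral(reference)[used] / ref[used]
    y = target.activity[used] / ref[used]
    return x, y, used


@dataclass(frozen=True)
class PatlakResults:
    """Results of the late-time linear fit of the Patlak plot."""

    ki_cer: float
    intercept: float
    t_star: float
    n_frames_used: int
    r_squared_fit: float
    x: np.ndarray = field(repr=False, default=None)
    y: np.ndarray = field(repr=False, default=None)

    def summary(self) -> str:
        lines = [
            "Reference-region Patlak fit",
            "---------------------------",
            f"influx rate k_i^cer : {self.ki_cer: .6f} min^-1",
            f"intercept           : {self.intercept: .4f}",
            f"t*                  : {self.t_star: .1f} min",
            f"frames used         : {self.n_frames_used:d}",
            f"R^2 (linear segment): {self.r_squared_fit: .5f}",
        ]
        return "\n".join(lines)


class PatlakModel:
    """Reference-region Patlak model for one target/reference TAC pair.

    Parameters
    ----------
    target, reference
        Frame-averaged activity curves on the same schedule.
    t_star
        Equilibration time (minutes); only frames whose mid-time is
        >= ``t_star`` enter the linear fit.  The study used 24 min.
    """

    def __init__(
        self,
        target: TimeActivityCurve,
        reference: TimeActivityCurve,
        t_star: float = 24.0,
    ) -> None:
        span = (reference.schedule.frame_start[0], reference.schedule.frame_end[-1])
        if not (span[0] <= t_star <= span[1]):
            raise ValueError(f"t_star={t_star} outside scan span {span}")
        self.target = target
        self.reference = reference
        self.t_star = float(t_star)

    def fit(self) -> PatlakResults:
        x_all, y_all, used = patlak_transform(self.target, self.reference)
        mids = self.target.schedule.mid_times[used]
        late = mids >= self.t_star
        if np.sum(late) < 3:
            raise ValueError(
                f"need >= 3 frames with mid-time >= t*={self.t_star}; have {int(np.sum(late))}"
            )
        x, y = x_all[late], y_all[late]
        xc = x - x.mean()
        sxx = float(xc @ xc)
        if sxx <= 0:
            raise ValueError("degenerate Patlak abscissa (zero variance)")
        slope = float(xc @ (y - y.mean())) / sxx
        intercept = float(y.mean() - slope * x.mean())
        resid = y - (intercept + slope * x)
        ss_tot = float(((y - y.mean()) ** 2).sum())
        r2 = 1.0 - float(resid @ resid) / ss_tot if ss_tot > 0 else 1.0
        return PatlakResults(
            ki_cer=slope,
            intercept=intercept,
            t_star=self.t_star,
            n_frames_used=int(np.sum(late)),
            r_squared_fit=r2,
            x=x,
            y=y,
        )


def patlak_fit(
    target: TimeActivityCurve,
    reference: TimeActivityCurve,
    t_star: float = 24.0,
) -> PatlakResults:
    """Convenience wrapper: ``PatlakModel(target, reference, t_star).fit()``."""
    return PatlakModel(target, reference, t_star=t_star).fit()


def roi_mean_ki(ki_map: np.ndarray, mask: np.ndarray) -> float:
    """Arithmetic mean of a voxel-wise k_i^cer map over a binary ROI mask.

    Non-finite voxels inside the mask are ignored with a warning.
    """
    ki_map = np.asarray(ki_map, dtype=float)
    mask = np.asarray(mask)
    if ki_map.shape != mask.shape:
        raise ValueError(f"map shape {ki_map.shape} != mask shape {mask.shape}")
    inside = mask > 0.5
    if not inside.any():
        raise ValueError("empty ROI mask")
    vals = ki_map[inside]
    bad = ~np.isfinite(vals)
    if bad.any():
        warnings.warn(f"roi_mean_ki: ignoring {int(bad.sum())} non-finite voxel(s)",
                      RuntimeWarning, stacklevel=2)
        vals = vals[~bad]
        if vals.size == 0:
            raise ValueError("no finite voxels inside the ROI mask")
    return float(vals.mean())


def load_ki_map_nifti(map_path: str, mask_path: str) -> tuple[np.ndarray, np.ndarray]:
    """Read a voxel-wise ki map and an ROI mask from NIfTI-1 files.

    The two images must be voxel-wise aligned (no resampling is performed);
    the mask is binarised at 0.5.
    """
    import nibabel as nib  # optional dependency

    img = nib.load(map_path)
    msk = nib.load(mask_path)
    if img.shape != msk.shape:
        raise ValueError(f"map shape {img.shape} != mask shape {msk.shape}")
    return np.asarray(img.get_fdata()), (np.asarray(msk.get_fdata()) > 0.5).astype(np.uint8)
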