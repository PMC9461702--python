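"""Microwell detection and per-doublet well tracking.

Circular agarose microwells appear as dark-rimmed circles in bright-field
frames.  They are detected with a circular Hough transform on the edge map of
the frame; each selected doublet's well is then re-localized frame by frame
inside a crop around its previous position.  A sample is dropped as soon as
no acceptable circle is found or the well moves partly out of the field of
view — wells are anchored in the agarose insert, so only slow stage drift is
expected and the search can stay local.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd
from skimage.feature import canny
from skimage.transform import hough_circle, hough_circle_peaks

__all__ = ["WellCircle", "DropReason", "DoubletTrack",
           "detect_microwells", "track_microwell", "track_sequence"]


@dataclass(frozen=True)
class WellCircle:
    """A detected microwell: centre (x, y) in 0-based px, radius, score."""

    x: float
    y: float
    radius: float
    score: float = 0.0

    @property
    def center(self) -> tuple[float, float]:
        return (self.x, self.y)

    def inside_frame(self, shape: tuple[int, int]) -> bool:
        """Whole well disk inside the frame bounds?"""
        h, w = shape
        return (self.x - self.radius >= 0 and self.y - self.radius >= 0
                and self.x + self.radius <= w - 1
                and self.y + self.radius <= h - 1)


class DropReason(str, Enum):
    NO_CIRCLE = "no_circle"
    OUT_OF_FOV = "out_of_fov"
    JUMP_EXCEEDED = "jump_exceeded"
    REGISTRATION_FAILED = "registration_failed"
    SEGMENTATION_FAILED = "segmentation_failed"


@dataclass
class DoubletTrack:
    """Per-frame well localization of one doublet sample."""

    circles: list[WellCircle] = field(default_factory=list)
    status: str = "active"              # 'active' | 'dropped'
    drop_frame: int | None = None
    drop_reason: DropReason | None = None

    def drop(self, frame: int, reason: DropReason) -> None:
        if self.status == "dropped":
            return
        self.status = "dropped"
        self.drop_frame = frame
        self.drop_reason = reason

    @property
    def n_frames(self) -> int:
        return len(self.circles)

    def to_frame(self) -> pd.DataFrame:
        rows = [{"frame": i, "x": c.x, "y": c.y, "radius": c.radius,
                 "status": "active"} for i, c in enumerate(self.circles)]
        if self.status == "dropped":
            rows.append({"frame": self.drop_frame, "x": np.nan, "y": np.nan,
                         "radius": np.nan,
                         "status": f"dropped:{self.drop_reason.value}"})
        return pd.DataFrame(rows)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def _normalize(frame: np.ndarray) -> np.ndarray:
    frame = np.asarray(frame, dtype=float)
    lo, hi = frame.min(), frame.max()
    if hi - lo <= 0:
        return np.zeros_like(frame)
    return (frame - lo) / (hi - lo)


def _hough_radii(radius_range: tuple[float, float]) -> np.ndarray:
    rmin, rmax = radius_range
    step = max(1, int(round((rmax - rmin) / 12)))
    return np.arange(int(np.floor(rmin)), int(np.ceil(rmax)) + 1, step)


def detect_microwells(frame: np.ndarray, radius_range: tuple[float, float],
                      min_separation: float | None = None,
                      max_wells: int | None = None,
                      canny_sigma: float = 3.0,
                      accumulator_threshold: float = 0.35,
                      ) -> list[WellCircle]:
    """Detect circular microwells in a grayscale frame.

    A circular Hough transform is run on the Canny edge map over the
    configured radius range; peaks are greedily accepted in score order with
    a minimum centre separation (default: the smallest search radius).
    Returns circles sorted by descending detector score.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 2 or frame.size == 0:
        raise ValueError("frame must be a non-empty 2-D grayscale image")
    rmin, rmax = radius_range
    if not (0 < rmin < rmax) or rmax >= max(frame.shape):
        raise ValueError("degenerate radius range")
    if min_separation is None:
        min_separation = rmin
    img = _normalize(frame)
    edges = canny(img, sigma=canny_sigma)
    if not edges.any():
        return []
    radii = _hough_radii(radius_range)
    accum = hough_circle(edges, radii)
    n_peaks = max_wells if max_wells is not None else int(
        frame.size / (np.pi * rmin * rmin)) + 1
    scores, cxs, cys, rads = hough_circle_peaks(
        accum, radii, min_xdistance=int(min_separation),
        min_ydistance=int(min_separation), num_peaks=n_peaks,
        threshold=accumulator_threshold * accum.max())
    out: list[WellCircle] = []
    h, w = frame.shape
    for s, cx, cy, r in sorted(zip(scores, cxs, cys, rads), reverse=True):
        if not (0 <= cx < w and 0 <= cy < h):
            continue
        if any(np.hypot(cx - c.x, cy - c.y) < min_separation for c in out):
            continue
        r_ref = _refine_radius(img, float(cx), float(cy), rmin, rmax)
        out.append(WellCircle(float(cx), float(cy), r_ref, float(s)))
    return out


def _refine_radius(img: np.ndarray, cx: float, cy: float,
                   rmin: float, rmax: float, n_angles: int = 64) -> float:
    """Inner rim-edge radius from the angular-mean radial intensity profile.

    The Hough accumulator cannot distinguish the inner and outer edge of the
    dark rim annulus; the inner edge is where the angular-averaged intensity
    drops fastest going outward (bright interior -> dark rim), which is
    stable under noise because of the angular averaging.
    """
    radii = np.arange(max(rmin - 3, 2.0), rmax + 4, 0.5)
    ang = np.linspace(0, 2 * np.pi, n_angles, endpoint=False)
    xs = cx + np.outer(radii, np.cos(ang))
    ys = cy + np.outer(radii, np.sin(ang))
    h, w = img.shape
    xs = np.clip(xs, 0, w - 1)
    ys = np.clip(ys, 0, h - 1)
    from scipy.ndimage import uniform_filter1d
    prof = img[ys.round().astype(int), xs.round().astype(int)].mean(axis=1)
    prof = uniform_filter1d(prof, 3, mode="nearest")
    grad = np.gradient(prof)
    inner = 1 + int(np.argmin(grad[1:-1]))  # endpoints carry boundary bias
    return float(radii[inner])


def _crop(frame: np.ndarray, cx: float, cy: float, half: int
          ) -> tuple[np.ndarray, tuple[int, int]]:
    """Clamped crop around (cx, cy); returns (crop, (x0, y0))."""
    h, w = frame.shape
    x0 = max(0, int(round(cx)) - half)
    y0 = max(0, int(round(cy)) - half)
    x1 = min(w, int(round(cx)) + half)
    y1 = min(h, int(round(cy)) + half)
    return frame[y0:y1, x0:x1], (x0, y0)


def track_microwell(frame: np.ndarray, prev: WellCircle,
                    search_margin: float = 20.0,
                    max_step: float | None = None,
                    radius_tol: float = 0.15,
                    ) -> WellCircle | DropReason:
    """Re-localize a microwell in the next frame near its previous position.

    Circles are detected in a crop of half-side ``prev.radius +
    search_margin`` around the previous centre.  The best candidate is the
    highest-scoring circle within ``max_step`` (default half the well radius)
    of the previous centre and within ``radius_tol`` of the previous radius;
    score ties break toward the smallest displacement.  Returns a
    :class:`DropReason` when no circle qualifies or the selected well disk
    extends beyond the frame.
    """
    if max_step is None:
        max_step = 0.5 * prev.radius
    half = int(round(prev.radius + search_margin))
    crop, (x0, y0) = _crop(frame, prev.x, prev.y, half)
    if crop.size == 0 or min(crop.shape) < 2 * prev.radius * (1 - radius_tol):
        return DropReason.OUT_OF_FOV
    rr = (prev.radius * (1 - radius_tol) - 1, prev.radius * (1 + radius_tol) + 1)
    try:
        found = detect_microwells(crop, rr, min_separation=prev.radius,
                                  max_wells=4)
    except ValueError:
        return DropReason.NO_CIRCLE
    candidates = []
    for c in found:
        disp = np.hypot(c.x + x0 - prev.x, c.y + y0 - prev.y)
        if disp <= max_step and abs(c.radius - prev.radius) <= radius_tol * prev.radius:
            candidates.append((c, disp))
    if not candidates:
        return DropReason.NO_CIRCLE
    best, _ = min(candidates, key=lambda cd: (-cd[0].score, cd[1]))
    best = WellCircle(best.x + x0, best.y + y0, best.radius, best.score)
    if not best.inside_frame(frame.shape):
        return DropReason.OUT_OF_FOV
    return best


def track_sequence(frames: np.ndarray, initial: WellCircle,
                   search_margin: float = 20.0,
                   max_step: float | None = None,
                   radius_tol: float = 0.15) -> DoubletTrack:
    """Track one microwell through a (T, H, W) stack starting from frame 0."""
    track = DoubletTrack(circles=[initial])
    prev = initial
    for t in range(1, len(frames)):
        res = track_microwell(frames[t], prev, search_margin=search_margin,
                              max_step=max_step, radius_tol=radius_tol)
        if isinstance(res, DropReason):
            track.drop(t, res)
            break
        track.circles.append(res)
        prev = res
    return track
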