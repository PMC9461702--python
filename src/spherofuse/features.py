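"""Morphometric feature extraction from doublet masks.

From each binary doublet mask the pipeline extracts the fusion readouts:
area, perimeter, roundness (4*pi*A/P^2), doublet length and width, the
contact length across the neck between the two spheroids, both spheroid
widths, the upper and lower intersphere angles, and the frame-to-frame
rotation.  The neck is located by combining two cues: local minima of the
upper/lower boundary-distance profiles of the horizontally aligned mask, and
the interface position predicted by two maximally inscribed circles of the
mask's distance transform.  A cost function selects the best minima pair,
optionally windowed around the previous frame's neck.

Extraction runs in three stages: full extraction on frame 0 (stage 1), full
extraction with temporal neck windowing until the doublet roundness reaches
0.8 (stage 2), and a reduced feature set afterwards (stage 3), where neck,
contact length, spheroid widths and intersphere angles are no longer
meaningful and are not monitored.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.signal import find_peaks
from skimage import measure

__all__ = [
    "FeatureRecord", "FeatureError", "align_mask", "basic_shape",
    "boundary_profiles", "inscribed_circles", "select_neck",
    "contact_and_widths", "intersphere_angles", "extract_timeseries",
    "records_to_frame",
]

#: roundness above which the doublet is treated as effectively fused
ROUNDNESS_CUTOFF = 0.8

#: Gaussian smoothing (px) applied before contour tracing; removes the
#: pixel-staircase bias of marching squares on binary masks
CONTOUR_SIGMA = 0.9


class FeatureError(RuntimeError):
    """A per-frame feature could not be computed."""


class AlignmentError(FeatureError):
    pass


class ProfileError(FeatureError):
    pass


class SingleBlobError(FeatureError):
    """The mask has no second inscribed circle — effectively one spheroid."""


class NeckNotFoundError(FeatureError):
    pass


class SeparationError(FeatureError):
    pass


@dataclass
class FeatureRecord:
    """All per-frame morphometrics of one doublet (units: um, degrees, h)."""

    frame: int
    time: float                      # hours since first acquired frame
    stage: int                       # 1 | 2 | 3
    area: float = np.nan             # um^2
    perimeter: float = np.nan        # um
    doublet_length: float = np.nan   # um
    doublet_width: float = np.nan    # um
    roundness: float = np.nan
    contact_length: float = np.nan   # um   (stages 1-2)
    width_left: float = np.nan       # um   (stages 1-2)
    width_right: float = np.nan      # um   (stages 1-2)
    angle_up: float = np.nan         # deg  (stages 1-2)
    angle_down: float = np.nan       # deg  (stages 1-2)
    rotation: float = np.nan         # deg/frame
    neck_points: tuple | None = None # ((x,y) upper, (x,y) lower), aligned px
    error: str | None = None

    @property
    def angle_mean(self) -> float:
        return (self.angle_up + self.angle_down) / 2.0


def records_to_frame(records: list[FeatureRecord]) -> pd.DataFrame:
    """Feature matrix: one row per frame, documented column per feature."""
    cols = ["frame", "time", "stage", "area", "perimeter", "doublet_length",
            "doublet_width", "roundness", "contact_length", "width_left",
            "width_right", "angle_up", "angle_down", "rotation", "error"]
    df = pd.DataFrame([{c: getattr(r, c) for c in cols} for r in records])
    df["angle_mean"] = (df["angle_up"] + df["angle_down"]) / 2.0
    return df


# ---------------------------------------------------------------------------
# Geometry helpers
# ---------------------------------------------------------------------------

def _moments_orientation(mask: np.ndarray) -> tuple[float, tuple[float, float]]:
    """Major-axis angle (deg, image convention x-right/y-down) and centroid."""
    ys, xs = np.nonzero(mask)
    if xs.size == 0:
        raise FeatureError("empty mask")
    cx, cy = xs.mean(), ys.mean()
    mu20 = np.mean((xs - cx) ** 2)
    mu02 = np.mean((ys - cy) ** 2)
    mu11 = np.mean((xs - cx) * (ys - cy))
    theta = 0.5 * math.atan2(2 * mu11, mu20 - mu02)
    return math.degrees(theta), (cx, cy)


def align_mask(mask: np.ndarray) -> tuple[np.ndarray, float]:
    """Rotate a mask so its principal (major) axis is horizontal.

    Returns ``(aligned_mask, orientation_deg)``; the rotation applied is
    ``-orientation`` about the centroid.  Raises :class:`AlignmentError` for
    degenerate (near-collinear) masks.
    """
    mask = np.asarray(mask, dtype=bool)
    ys, xs = np.nonzero(mask)
    if xs.size == 0:
        raise AlignmentError("empty mask")
    if np.ptp(xs) < 3 and np.ptp(ys) < 3:
        raise AlignmentError("mask too small to orient")
    orientation, _ = _moments_orientation(mask)
    # scipy rotates CCW in (row, col) display; image-convention angle is CW,
    # so rotating by -orientation brings the major axis onto the x axis
    aligned = ndimage.rotate(mask.astype(np.uint8), orientation,
                             reshape=True, order=0) > 0
    return aligned, orientation


def _smooth_contour(mask: np.ndarray) -> np.ndarray:
    """Sub-pixel closed boundary contour (N, 2) as (row, col) vertices."""
    f = ndimage.gaussian_filter(np.pad(mask, 4).astype(float), CONTOUR_SIGMA)
    contours = measure.find_contours(f, 0.5)
    if not contours:
        raise FeatureError("no boundary contour")
    c = max(contours, key=len) - 4.0
    return c


def basic_shape(mask: np.ndarray, pixel_size: float
                ) -> tuple[float, float, float, float, float]:
    """(area, perimeter, doublet_length, doublet_width, roundness).

    Area is the pixel count scaled by ``pixel_size**2``; the perimeter is the
    arc length of a sub-pixel marching-squares contour of the lightly
    smoothed mask (raw pixel-edge perimeters overestimate P and depress the
    roundness of even a perfect disk).  Length and width are the boundary
    extents along and across the principal axis; roundness is 4*pi*A/P^2.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise FeatureError("empty mask")
    area_px = float(mask.sum())
    contour = _smooth_contour(mask)
    seg = np.diff(contour, axis=0)
    perim_px = float(np.hypot(seg[:, 0], seg[:, 1]).sum())
    theta_deg, (cx, cy) = _moments_orientation(mask)
    th = math.radians(theta_deg)
    u = np.array([math.cos(th), math.sin(th)])     # major axis (x, y)
    v = np.array([-math.sin(th), math.cos(th)])
    pts = np.stack([contour[:, 1] - cx, contour[:, 0] - cy], axis=1)
    proj_u = pts @ u
    proj_v = pts @ v
    length = float(np.ptp(proj_u)) * pixel_size
    width = float(np.ptp(proj_v)) * pixel_size
    area = area_px * pixel_size ** 2
    perimeter = perim_px * pixel_size
    roundness = 4 * math.pi * area / perimeter ** 2
    return area, perimeter, length, width, roundness


# ---------------------------------------------------------------------------
# Neck detection
# ---------------------------------------------------------------------------

@dataclass
class BoundaryProfiles:
    """Distance-from-axis profiles of an aligned mask, with local minima."""

    x: np.ndarray            # column indices spanned by the mask
    upper: np.ndarray        # distance from axis to the topmost pixel
    lower: np.ndarray        # distance from axis to the bottommost pixel
    axis_row: float
    upper_minima: np.ndarray # indices into x
    lower_minima: np.ndarray


def boundary_profiles(aligned_mask: np.ndarray,
                      min_prominence: float = 0.5) -> BoundaryProfiles:
    """Upper/lower boundary-distance profiles of a horizontally aligned mask.

    For every column the distances from the major axis (the centroid row) to
    the topmost and bottommost mask pixels are recorded; interior local
    minima of each profile (prominence-filtered) are neck candidates.  A
    column gap inside the span signals a split mask and raises
    :class:`ProfileError`.
    """
    aligned_mask = np.asarray(aligned_mask, dtype=bool)
    cols = np.nonzero(aligned_mask.any(axis=0))[0]
    if cols.size == 0:
        raise ProfileError("empty mask")
    if np.any(np.diff(cols) > 1):
        raise ProfileError("mask has a column gap (split segmentation)")
    ys, xs = np.nonzero(aligned_mask)
    axis_row = ys.mean()
    upper = np.empty(cols.size)
    lower = np.empty(cols.size)
    for i, c in enumerate(cols):
        rows = ys[xs == c]
        upper[i] = axis_row - rows.min()
        lower[i] = rows.max() - axis_row
    up_min, _ = find_peaks(-upper, prominence=min_prominence)
    lo_min, _ = find_peaks(-lower, prominence=min_prominence)
    return BoundaryProfiles(x=cols, upper=upper, lower=lower,
                            axis_row=axis_row, upper_minima=up_min,
                            lower_minima=lo_min)


@dataclass
class InscribedCircles:
    """The two maximally inscribed circles of a doublet mask."""

    c1: tuple[float, float]  # (x, y), larger circle first
    r1: float
    c2: tuple[float, float]
    r2: float

    @property
    def interface_point(self) -> tuple[float, float]:
        """Where the two circle boundaries approach on the centre line."""
        p1 = np.asarray(self.c1, dtype=float)
        p2 = np.asarray(self.c2, dtype=float)
        d = np.linalg.norm(p2 - p1)
        if d == 0:
            return tuple(p1)
        u = (p2 - p1) / d
        a = p1 + u * self.r1
        b = p2 - u * self.r2
        return tuple((a + b) / 2.0)


def inscribed_circles(mask: np.ndarray,
                      min_radius_frac: float = 0.35) -> InscribedCircles:
    """Two maximally inscribed circles from the interior distance transform.

    The first circle is the global maximum of the Euclidean distance
    transform; the second is the maximum restricted to points farther than
    ``r1`` from the first centre.  When that restricted maximum is below
    ``min_radius_frac * r1`` the mask is effectively a single blob and
    :class:`SingleBlobError` is raised.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise FeatureError("empty mask")
    edt = ndimage.distance_transform_edt(mask)
    iy, ix = np.unravel_index(np.argmax(edt), edt.shape)
    r1 = float(edt[iy, ix])
    yy, xx = np.mgrid[: mask.shape[0], : mask.shape[1]]
    far = np.hypot(xx - ix, yy - iy) > r1
    edt2 = np.where(far, edt, 0.0)
    jy, jx = np.unravel_index(np.argmax(edt2), edt2.shape)
    r2 = float(edt2[jy, jx])
    if r2 < min_radius_frac * r1 or r2 <= 1.0:
        raise SingleBlobError("no second inscribed circle above the floor")
    return InscribedCircles(c1=(float(ix), float(iy)), r1=r1,
                            c2=(float(jx), float(jy)), r2=r2)


def select_neck(profiles: BoundaryProfiles,
                circles: InscribedCircles | None,
                prev_neck: tuple[float, float] | None = None,
                weights: tuple[float, float, float] = (1.0, 1.0, 1.0),
                window: float = 12.0,
                ) -> tuple[tuple[float, float], tuple[float, float]]:
    """Select the neck (interface) points from profile minima.

    Every (upper-minimum, lower-minimum) pair is scored with
    ``w1*|x_mid - x_interface| + w2*(profile height at the minima) +
    w3*|x_up - x_down|`` after min-max normalizing each term over the
    candidate set; the pair with the lowest cost wins.  When ``prev_neck``
    (the previous frame's mean neck x and its mask x-offset already applied)
    is given, candidates are restricted to a window around it, and if no
    minima survive the previous x-position is reused directly.

    Returns ``((x_up, y_up), (x_lo, y_lo))`` in aligned-mask pixel
    coordinates (y up = axis_row - upper, y down = axis_row + lower).
    """
    w1, w2, w3 = weights
    ups = list(profiles.upper_minima)
    los = list(profiles.lower_minima)
    if prev_neck is not None:
        px = prev_neck[0]
        ups = [i for i in ups if abs(profiles.x[i] - px) <= window]
        los = [i for i in los if abs(profiles.x[i] - px) <= window]
        if not ups or not los:
            # flat/ambiguous profiles late in fusion: hold the previous x
            xi = int(np.clip(np.searchsorted(profiles.x, round(px)), 0,
                             profiles.x.size - 1))
            ups = ups or [xi]
            los = los or [xi]
    if not ups or not los:
        raise NeckNotFoundError("no neck candidates and no previous neck")
    pairs = [(i, j) for i in ups for j in los]
    t_int = np.zeros(len(pairs))
    t_depth = np.empty(len(pairs))
    t_mismatch = np.empty(len(pairs))
    for k, (i, j) in enumerate(pairs):
        xm = (profiles.x[i] + profiles.x[j]) / 2.0
        if circles is not None:
            t_int[k] = abs(xm - circles.interface_point[0])
        t_depth[k] = profiles.upper[i] + profiles.lower[j]
        t_mismatch[k] = abs(profiles.x[i] - profiles.x[j])

    def _norm(a: np.ndarray) -> np.ndarray:
        rng = a.max() - a.min()
        return (a - a.min()) / rng if rng > 0 else np.zeros_like(a)

    cost = w1 * _norm(t_int) + w2 * _norm(t_depth) + w3 * _norm(t_mismatch)
    i, j = pairs[int(np.argmin(cost))]
    up_pt = (float(profiles.x[i]), profiles.axis_row - profiles.upper[i])
    lo_pt = (float(profiles.x[j]), profiles.axis_row + profiles.lower[j])
    return up_pt, lo_pt


def refine_neck_points(mask: np.ndarray,
                       neck_up: tuple[float, float],
                       neck_down: tuple[float, float],
                       ) -> tuple[tuple[float, float], tuple[float, float]]:
    """Snap integer-pixel neck points onto the sub-pixel boundary contour.

    Profile heights are quantized to whole pixels, which shortens the
    measured contact chord by up to a pixel per side; snapping each neck
    point to the nearest vertex of the raw marching-squares contour restores
    half-pixel placement.  (The smoothed contour is unsuitable here: it
    rounds the concave notch outward and would lengthen the chord.)
    """
    contours = measure.find_contours(np.asarray(mask, dtype=float), 0.5)
    if not contours:
        raise FeatureError("no boundary contour")
    contour = max(contours, key=len)
    pts = np.stack([contour[:, 1], contour[:, 0]], axis=1)
    out = []
    for anchor in (neck_up, neck_down):
        a = np.asarray(anchor, dtype=float)
        idx = int(np.argmin(np.linalg.norm(pts - a, axis=1)))
        out.append((float(pts[idx, 0]), float(pts[idx, 1])))
    return out[0], out[1]


def contact_and_widths(aligned_mask: np.ndarray,
                       neck_up: tuple[float, float],
                       neck_down: tuple[float, float],
                       pixel_size: float) -> tuple[float, float, float]:
    """Contact length across the neck and both spheroid widths (um).

    The mask is split by the line through the neck points; each side's width
    is its extent perpendicular to the (horizontal) major axis.  Raises
    :class:`SeparationError` when the neck line fails to produce two parts.
    """
    p1 = np.asarray(neck_up, dtype=float)
    p2 = np.asarray(neck_down, dtype=float)
    contact = float(np.linalg.norm(p1 - p2)) * pixel_size
    ys, xs = np.nonzero(aligned_mask)
    v = p2 - p1
    if np.allclose(v, 0):
        v = np.array([0.0, 1.0])
    side = np.sign(v[0] * (ys - p1[1]) - v[1] * (xs - p1[0]))
    pos, neg = side > 0, side < 0
    if not pos.any() or not neg.any():
        raise SeparationError("neck line does not split the mask")
    if xs[pos].mean() < xs[neg].mean():
        left, right = pos, neg
    else:
        left, right = neg, pos
    width_left = float(np.ptp(ys[left]) + 1) * pixel_size
    width_right = float(np.ptp(ys[right]) + 1) * pixel_size
    return contact, width_left, width_right


#: contour samples skipped next to the anchor before each tangent fit;
#: the immediate corner neighbourhood is distorted by rasterization
TANGENT_OFFSET = 4


def _resample_contour(contour: np.ndarray, spacing: float = 1.0) -> np.ndarray:
    """Resample a (row, col) contour at uniform arc length; returns (x, y)."""
    seg = np.diff(contour, axis=0)
    s = np.concatenate([[0.0], np.cumsum(np.hypot(seg[:, 0], seg[:, 1]))])
    si = np.arange(0.0, s[-1], spacing)
    return np.stack([np.interp(si, s, contour[:, 1]),
                     np.interp(si, s, contour[:, 0])], axis=1)


def _kasa_center(pts: np.ndarray) -> np.ndarray:
    """Least-squares (Kasa) circle-fit centre of a point set."""
    x, y = pts[:, 0], pts[:, 1]
    A = np.column_stack([x, y, np.ones(len(pts))])
    sol, *_ = np.linalg.lstsq(A, x * x + y * y, rcond=None)
    return np.array([sol[0] / 2.0, sol[1] / 2.0])


def _anchor_on_circle(anchor, circles: "InscribedCircles",
                      tol: float = 0.15) -> bool:
    """Does the anchor lie on both inscribed-circle boundaries (within tol)?"""
    a = np.asarray(anchor, dtype=float)
    for c, r in ((circles.c1, circles.r1), (circles.c2, circles.r2)):
        if abs(np.linalg.norm(a - np.asarray(c)) - r) > tol * r:
            return False
    return True


def _circle_tangent_angle(anchor, circles: "InscribedCircles") -> float:
    """Angle between the tangents of the two inscribed circles at the anchor."""
    a = np.asarray(anchor, dtype=float)
    mid = (np.asarray(circles.c1) + np.asarray(circles.c2)) / 2.0
    dirs = []
    for c in (circles.c1, circles.c2):
        rad = a - np.asarray(c)
        t = np.array([-rad[1], rad[0]]) / max(np.linalg.norm(rad), 1e-9)
        away = np.asarray(c) - mid  # orient outward along the doublet axis
        if np.dot(t, away) < 0:
            t = -t
        dirs.append(t)
    cosang = float(np.clip(np.dot(dirs[0], dirs[1]), -1.0, 1.0))
    return math.degrees(math.acos(cosang))


def intersphere_angles(mask: np.ndarray,
                       neck_up: tuple[float, float],
                       neck_down: tuple[float, float],
                       k: int = 7) -> tuple[float, float]:
    """Upper and lower intersphere angles at the neck anchor points.

    From each anchor, a tangent ray is drawn to each side of the spheroid
    pair and the reported angle between the two rays lies in [0, 180]
    degrees: a smooth merged boundary yields 180 deg, a first-contact cusp
    0 deg.  When the two maximally inscribed circles are consistent with the
    anchors (each anchor lies on both circle boundaries), each ray is the
    tangent of the respective circle at the anchor — robust down to the
    near-cusp regime.  Otherwise (shallow necks, where the second inscribed
    circle is unreliable, and near-fused masks) each ray comes from a local
    circle fit to ``k`` boundary samples spread over roughly one spheroid
    radius of arc on that side; chord-secant line fits are biased by ~(k/r)
    radians on curved boundaries, which both circle-based estimators avoid.
    """
    mask = np.asarray(mask, dtype=bool)
    contour = _smooth_contour(mask)
    pts = _resample_contour(contour)
    if len(pts) < 4 * k:
        raise FeatureError("contour too short for tangent fits")
    try:
        circles = inscribed_circles(mask)
        scale = circles.r1
    except FeatureError:
        circles = None
        scale = math.sqrt(mask.sum() / math.pi)
    if circles is not None and all(
            _anchor_on_circle(a, circles) for a in (neck_up, neck_down)):
        return (_circle_tangent_angle(neck_up, circles),
                _circle_tangent_angle(neck_down, circles))
    step = max(1, int(round(max(8.0, scale) / k)))

    def angle_at(anchor: tuple[float, float]) -> float:
        a = np.asarray(anchor, dtype=float)
        idx = int(np.argmin(np.linalg.norm(pts - a, axis=1)))
        n = len(pts)
        dirs = []
        for sgn in (1, -1):
            ii = (idx + sgn * (TANGENT_OFFSET + step * np.arange(1, k + 1))) % n
            side = pts[ii]
            c = _kasa_center(side)
            # evaluate the tangent at the caller's anchor: the smoothed
            # contour rounds deep notches, but the anchor itself is exact
            rad = a - c
            nrm = np.linalg.norm(rad)
            t = np.array([-rad[1], rad[0]]) / max(nrm, 1e-9)
            if np.dot(t, side.mean(axis=0) - pts[idx]) < 0:
                t = -t
            dirs.append(t)
        cosang = float(np.clip(np.dot(dirs[0], dirs[1]), -1.0, 1.0))
        return math.degrees(math.acos(cosang))

    return angle_at(neck_up), angle_at(neck_down)


# ---------------------------------------------------------------------------
# Time-series driver
# ---------------------------------------------------------------------------

def _extract_full(mask: np.ndarray, pixel_size: float,
                  prev_neck_offset: float | None, k: int,
                  ) -> tuple[dict, float]:
    """Stage-1/2 extraction on one mask.

    ``prev_neck_offset`` is the previous neck x relative to the aligned-mask
    centroid (aligned frames differ in shape, so absolute columns are not
    comparable across time).  Returns the feature dict and the new offset.
    """
    out: dict = {}
    aligned, orientation = align_mask(mask)
    _, (cx, _cy) = _moments_orientation(aligned)
    profiles = boundary_profiles(aligned)
    try:
        circles = inscribed_circles(aligned)
    except SingleBlobError:
        circles = None
    prev_abs = (cx + prev_neck_offset, 0.0) if prev_neck_offset is not None else None
    up, lo = select_neck(profiles, circles, prev_neck=prev_abs)
    up, lo = refine_neck_points(aligned, up, lo)
    contact, wl, wr = contact_and_widths(aligned, up, lo, pixel_size)
    au, ad = intersphere_angles(aligned, up, lo, k=k)
    out.update(contact_length=contact, width_left=wl, width_right=wr,
               angle_up=au, angle_down=ad,
               neck_points=(up, lo))
    return out, (up[0] + lo[0]) / 2.0 - cx


def extract_timeseries(masks, rotations=None, pixel_size: float = 1.0,
                       frame_interval: float = 5.0,
                       acquisition_delay_h: float = 0.0,
                       roundness_cutoff: float = ROUNDNESS_CUTOFF,
                       k: int = 7) -> list[FeatureRecord]:
    """Extract the per-frame feature matrix from a mask sequence.

    ``masks`` may be a list of binary arrays or of objects with a
    ``binary_mask`` attribute.  Stage 3 (reduced features) is entered at the
    first frame whose roundness reaches ``roundness_cutoff`` and is sticky
    from then on.  Per-frame feature failures are recorded on the
    :class:`FeatureRecord` rather than raised, so one bad frame never loses
    the series.
    """
    seq = [getattr(m, "binary_mask", m) for m in masks]
    if not seq:
        raise FeatureError("empty mask sequence")
    if rotations is None:
        rotations = np.zeros(len(seq))
    records: list[FeatureRecord] = []
    stage3 = False
    prev_offset: float | None = None
    for t, mask in enumerate(seq):
        rec = FeatureRecord(frame=t,
                            time=t * frame_interval / 60.0 + acquisition_delay_h,
                            stage=3 if stage3 else (1 if t == 0 else 2),
                            rotation=float(rotations[t]))
        try:
            area, perim, length, width, roundness = basic_shape(mask, pixel_size)
            rec.area, rec.perimeter = area, perim
            rec.doublet_length, rec.doublet_width = length, width
            rec.roundness = roundness
            if not stage3 and roundness >= roundness_cutoff:
                stage3 = True
                rec.stage = 3
            if not stage3:
                full, prev_offset = _extract_full(
                    mask, pixel_size, prev_offset if t > 0 else None, k)
                for key, val in full.items():
                    setattr(rec, key, val)
        except FeatureError as exc:
            rec.error = str(exc)
        records.append(rec)
    return records
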