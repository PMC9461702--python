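"""Doublet segmentation and rigid mask propagation through time.

Frame 0 is segmented inside the well interior (background flattening,
intensity thresholding, morphological cleanup, retention of the one or two
central components).  Both a binary mask and a grayscale reference mask (the
raw intensities under the binary mask) are stored.  For every later frame the
well is re-localized, the grayscale reference is rigidly registered
(translation + small rotation, normalized cross-correlation) to the new crop,
the frame is segmented afresh, and the fresh mask is refined against the
transformed reference: components that do not overlap it are discarded, and
implausible area jumps fall back to the transformed reference.  Both
references are then replaced with the new masks and the cycle repeats.  Any
failure (lost well, registration below the similarity floor, empty
segmentation) drops the sample at that frame instead of raising.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.feature import match_template

from .microwell import DoubletTrack, DropReason, WellCircle, track_microwell

__all__ = ["MaskPair", "RigidTransform", "SegmentationResult",
           "EmptyWellError", "initialize_mask", "register_reference",
           "refine_mask", "segment_sequence"]


class EmptyWellError(RuntimeError):
    """No object of at least ``min_area`` pixels inside the well."""


@dataclass
class MaskPair:
    """Binary mask (fine-tuning) + grayscale reference mask (registration)."""

    binary_mask: np.ndarray     # bool, crop coordinates
    gray_ref: np.ndarray        # raw intensities where binary_mask, 0 outside
    frame_index: int
    crop_origin: tuple[int, int]  # (x0, y0) of the crop in full-frame px


@dataclass(frozen=True)
class RigidTransform:
    """Rigid motion (dx, dy in px, dtheta in degrees) with its NCC score."""

    dx: float
    dy: float
    dtheta: float
    score: float = 1.0

    def inverse(self) -> "RigidTransform":
        th = math.radians(-self.dtheta)
        dx = -(self.dx * math.cos(th) - self.dy * math.sin(th))
        dy = -(self.dx * math.sin(th) + self.dy * math.cos(th))
        return RigidTransform(dx, dy, -self.dtheta, self.score)


@dataclass
class SegmentationResult:
    """Mask sequence, per-frame rotations and drop bookkeeping."""

    masks: list[MaskPair]
    rotations: list[float]          # dtheta per frame (frame 0 -> 0)
    track: DoubletTrack
    drop_frame: int | None = None
    drop_reason: DropReason | None = None
    fallback_frames: list[int] = field(default_factory=list)

    @property
    def n_frames(self) -> int:
        return len(self.masks)


# ---------------------------------------------------------------------------
# Frame-0 segmentation
# ---------------------------------------------------------------------------

def _crop_with_origin(frame: np.ndarray, cx: float, cy: float, half: int
                      ) -> tuple[np.ndarray, tuple[int, int]]:
    """Edge-padded square crop of side 2*half centred on (cx, cy)."""
    h, w = frame.shape
    x0 = int(round(cx)) - half
    y0 = int(round(cy)) - half
    pad_l = max(0, -x0)
    pad_t = max(0, -y0)
    pad_r = max(0, x0 + 2 * half - w)
    pad_b = max(0, y0 + 2 * half - h)
    sub = frame[max(0, y0): y0 + 2 * half, max(0, x0): x0 + 2 * half]
    if pad_l or pad_t or pad_r or pad_b:
        sub = np.pad(sub, ((pad_t, pad_b), (pad_l, pad_r)), mode="edge")
    return sub, (x0, y0)


def _otsu(values: np.ndarray) -> float:
    from skimage.filters import threshold_otsu
    return float(threshold_otsu(values))


def _segment_crop(crop: np.ndarray, center: tuple[float, float],
                  interior_radius: float, min_area: int,
                  max_components: int = 2,
                  second_component_frac: float = 0.25) -> np.ndarray:
    """Segment dark objects inside the well-interior disk of a crop."""
    crop = np.asarray(crop, dtype=float)
    yy, xx = np.mgrid[: crop.shape[0], : crop.shape[1]]
    interior = np.hypot(xx - center[0], yy - center[1]) < interior_radius
    if not interior.any():
        raise EmptyWellError("well interior outside the crop")
    # background flattening: divide by a coarse illumination estimate
    illum = ndimage.gaussian_filter(crop, sigma=max(interior_radius, 8.0))
    flat = crop / np.maximum(illum, 1e-6)
    vals = flat[interior]
    if vals.max() - vals.min() < 1e-6:
        raise EmptyWellError("flat well interior, nothing to segment")
    thr = _otsu(vals)
    dark = interior & (flat < thr)
    # guard against Otsu splitting pure background noise: require real contrast
    if dark.any() and (vals.mean() - flat[dark].mean()) < 0.05 * vals.mean():
        raise EmptyWellError("no object darker than background")
    dark = ndimage.binary_closing(dark, structure=_disk(2))
    dark = ndimage.binary_fill_holes(dark)
    labels, n = ndimage.label(dark)
    if n == 0:
        raise EmptyWellError("no object found in well interior")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, range(1, n + 1))
    order = np.argsort(sizes)[::-1]
    keep = np.zeros_like(dark)
    kept = 0
    for rank, idx in enumerate(order):
        if sizes[idx] < min_area:
            break
        if kept >= max_components:
            break
        if kept == 1 and sizes[idx] < second_component_frac * sizes[order[0]]:
            break
        keep |= labels == idx + 1
        kept += 1
    if kept == 0:
        raise EmptyWellError("no object of at least min_area pixels")
    return keep


def _disk(radius: int) -> np.ndarray:
    yy, xx = np.mgrid[-radius: radius + 1, -radius: radius + 1]
    return (xx * xx + yy * yy) <= radius * radius


def initialize_mask(frame: np.ndarray, well: WellCircle,
                    min_area: int = 150, rim_margin: float | None = None,
                    crop_margin: float = 12.0) -> MaskPair:
    """Segment the doublet in a well of the first frame (stage of Fig.-style
    initialization): returns the binary mask and the grayscale reference.

    Segmentation is restricted to the well interior (the well disk eroded by
    the rim width), keeps the one or two largest central components of at
    least ``min_area`` px, and stores the raw crop intensities under the mask
    as the registration reference.
    """
    half = int(round(well.radius + crop_margin))
    crop, origin = _crop_with_origin(frame, well.x, well.y, half)
    center = (well.x - origin[0], well.y - origin[1])
    if rim_margin is None:
        rim_margin = 1.0  # the rim annulus lies outside the detected radius
    mask = _segment_crop(crop, center, well.radius - rim_margin, min_area)
    gray = np.where(mask, crop, 0.0)
    return MaskPair(binary_mask=mask, gray_ref=gray, frame_index=0,
                    crop_origin=origin)


# ---------------------------------------------------------------------------
# Rigid registration
# ---------------------------------------------------------------------------

def _signal_image(img: np.ndarray) -> np.ndarray:
    """Invert so that dark objects become positive signal on ~zero background."""
    img = np.asarray(img, dtype=float)
    return img.max() - img


def _masked_template(gray_ref: np.ndarray) -> tuple[np.ndarray, tuple[int, int], tuple[float, float]]:
    """Tight positive-signal template of the reference + its bbox offset."""
    support = gray_ref > 0
    if not support.any():
        raise ValueError("empty grayscale reference")
    ys, xs = np.nonzero(support)
    y0, y1 = ys.min(), ys.max() + 1
    x0, x1 = xs.min(), xs.max() + 1
    sub = gray_ref[y0:y1, x0:x1]
    subm = support[y0:y1, x0:x1]
    tpl = np.where(subm, sub.max() - sub + 1.0, 0.0)
    cyx = ((ys.mean() - y0), (xs.mean() - x0))
    return tpl, (x0, y0), (xs.mean(), ys.mean())


def _best_shift(image_sig: np.ndarray, tpl: np.ndarray) -> tuple[float, float, float]:
    """NCC peak position (sub-pixel, parabolic) and score."""
    if (image_sig.shape[0] < tpl.shape[0]) or (image_sig.shape[1] < tpl.shape[1]):
        return 0.0, 0.0, -1.0
    cc = match_template(image_sig, tpl)
    iy, ix = np.unravel_index(np.argmax(cc), cc.shape)
    score = float(cc[iy, ix])

    def _para(cm: float, c0: float, cp: float) -> float:
        denom = cm - 2 * c0 + cp
        return 0.5 * (cm - cp) / denom if denom < 0 else 0.0

    dy = _para(cc[iy - 1, ix], cc[iy, ix], cc[iy + 1, ix]) if 0 < iy < cc.shape[0] - 1 else 0.0
    dx = _para(cc[iy, ix - 1], cc[iy, ix], cc[iy, ix + 1]) if 0 < ix < cc.shape[1] - 1 else 0.0
    return ix + dx, iy + dy, score


def register_reference(gray_ref: np.ndarray, frame_crop: np.ndarray,
                       max_rotation: float = 6.0,
                       coarse_step: float = 1.0,
                       fine_step: float = 0.25,
                       min_score: float = 0.35,
                       theta_hint: float | None = None,
                       hint_margin: float = 0.025) -> RigidTransform:
    """Rigid transform (translation + rotation) of the grayscale reference
    onto a new crop, by normalized cross-correlation.

    The rotation is searched on a coarse grid over ``+-max_rotation`` degrees
    and refined locally; translation comes from the NCC peak with parabolic
    sub-pixel interpolation.  The returned ``score`` is the best NCC value; a
    value below ``min_score`` flags a registration failure (the caller drops
    the sample).

    ``theta_hint`` (degrees) injects an externally estimated rotation — e.g.
    the change of the mask's second-moment orientation — which is preferred
    unless a grid angle beats its NCC score by more than ``hint_margin``:
    sub-degree rotations move boundary pixels by fractions of a pixel, below
    what integer-grid correlation can resolve, so the hint carries the
    sub-degree information while the grid still catches large rotations.
    """
    tpl_raw, (bx0, by0), (cx_ref, cy_ref) = _masked_template(gray_ref)
    img_sig = _signal_image(frame_crop)

    support = gray_ref > 0
    ys, xs = np.nonzero(support)

    def try_angle(theta: float) -> tuple[float, RigidTransform]:
        if abs(theta) < 1e-9:
            tpl = tpl_raw
            cx_t, cy_t = cx_ref - bx0, cy_ref - by0
        else:
            rot = ndimage.rotate(tpl_raw, -theta, reshape=True, order=1)
            rot[rot < 1e-3] = 0.0
            tpl = rot
            # centroid position moves with the rotation about the array centre
            h0, w0 = tpl_raw.shape
            h1, w1 = rot.shape
            th = math.radians(theta)
            cx0, cy0 = cx_ref - bx0 - (w0 - 1) / 2, cy_ref - by0 - (h0 - 1) / 2
            cx_t = cx0 * math.cos(th) - cy0 * math.sin(th) + (w1 - 1) / 2
            cy_t = cx0 * math.sin(th) + cy0 * math.cos(th) + (h1 - 1) / 2
        px, py, score = _best_shift(img_sig, tpl)
        new_cx = px + cx_t
        new_cy = py + cy_t
        t = RigidTransform(dx=new_cx - cx_ref, dy=new_cy - cy_ref,
                           dtheta=theta, score=score)
        return score, t

    hint_score = None
    hint_t = None
    if theta_hint is not None and abs(theta_hint) <= max_rotation:
        hint_score, hint_t = try_angle(float(theta_hint))
    best_score, best_t = try_angle(0.0)
    for th in np.arange(-max_rotation, max_rotation + 1e-9, coarse_step):
        if abs(th) < 1e-9:
            continue
        s, t = try_angle(float(th))
        if s > best_score:
            best_score, best_t = s, t
    for th in np.arange(best_t.dtheta - coarse_step,
                        best_t.dtheta + coarse_step + 1e-9, fine_step):
        s, t = try_angle(float(th))
        if s > best_score:
            best_score, best_t = s, t
    if hint_t is not None and best_score <= hint_score + hint_margin:
        return hint_t
    return best_t


def apply_transform(mask: np.ndarray, transform: RigidTransform,
                    center: tuple[float, float]) -> np.ndarray:
    """Apply (rotation about ``center``, then translation) to a binary mask.

    Angles follow the image convention (x rightward, y downward, positive
    rotation turns x toward y); forward map ``p' = R (p - c) + c + t``.
    """
    th = math.radians(transform.dtheta)
    cos, sin = math.cos(th), math.sin(th)
    cx, cy = center
    tx, ty = transform.dx, transform.dy
    # affine_transform maps output (row, col) -> input coords: p = M p' + o
    # with p = R^-1 (p' - c - t) + c;  R in (row, col) = [[cos, sin], [-sin, cos]]
    Minv = np.array([[cos, -sin], [sin, cos]])
    c_rc = np.array([cy, cx])
    t_rc = np.array([ty, tx])
    offset = c_rc - Minv @ (c_rc + t_rc)
    out = ndimage.affine_transform(mask.astype(float), Minv, offset=offset,
                                   order=1, output_shape=mask.shape)
    return out > 0.5


def refine_mask(fine_mask: np.ndarray, transformed_ref: np.ndarray,
                prev_area: float | None = None,
                overlap_frac: float = 0.3, dilation: int = 3,
                max_area_jump: float = 0.2) -> tuple[np.ndarray, bool]:
    """Refine a fresh segmentation against the transformed reference mask.

    Keeps connected components of ``fine_mask`` whose fractional overlap with
    the dilated reference exceeds ``overlap_frac`` and fills holes.  When the
    result is empty, or its area jumps more than ``max_area_jump`` relative
    to ``prev_area``, the transformed reference itself is returned (fusion
    changes area slowly at 5-min sampling, so a large jump means a failed
    fine segmentation).  Returns ``(mask, fallback_used)``.
    """
    fine_mask = np.asarray(fine_mask, dtype=bool)
    transformed_ref = np.asarray(transformed_ref, dtype=bool)
    if not fine_mask.any() and not transformed_ref.any():
        raise EmptyWellError("both fine mask and reference are empty")
    if not fine_mask.any():
        return transformed_ref.copy(), True
    ref_dil = ndimage.binary_dilation(transformed_ref, structure=_disk(dilation))
    labels, n = ndimage.label(fine_mask)
    keep = np.zeros_like(fine_mask)
    for i in range(1, n + 1):
        comp = labels == i
        if np.count_nonzero(comp & ref_dil) / np.count_nonzero(comp) > overlap_frac:
            keep |= comp
    keep = ndimage.binary_fill_holes(keep)
    if not keep.any():
        return transformed_ref.copy(), True
    if prev_area is not None and prev_area > 0:
        area = float(keep.sum())
        if abs(area - prev_area) / prev_area > max_area_jump:
            return transformed_ref.copy(), True
    return keep, False


# ---------------------------------------------------------------------------
# Sequence driver
# ---------------------------------------------------------------------------

def _orientation_delta(prev_mask: np.ndarray, new_mask: np.ndarray) -> float:
    """Change of principal-axis orientation between two masks, in (-90, 90]."""
    def _ori(mask: np.ndarray) -> float:
        ys, xs = np.nonzero(mask)
        cx, cy = xs.mean(), ys.mean()
        mu20 = np.mean((xs - cx) ** 2)
        mu02 = np.mean((ys - cy) ** 2)
        mu11 = np.mean((xs - cx) * (ys - cy))
        return 0.5 * math.degrees(math.atan2(2 * mu11, mu20 - mu02))
    d = _ori(new_mask) - _ori(prev_mask)
    return (d + 90.0) % 180.0 - 90.0

def segment_sequence(stack, initial_well: WellCircle,
                     min_area: int = 150,
                     search_margin: float = 20.0,
                     max_rotation: float = 6.0,
                     min_score: float = 0.35,
                     crop_margin: float = 12.0) -> SegmentationResult:
    """Segment a doublet through a whole stack with rolling references.

    Per frame: re-localize the well, register the grayscale reference to the
    new crop, segment the crop afresh, refine against the transformed
    reference, then replace both references with the new masks.  The sample
    is dropped (never raising) when the well is lost, the registration score
    falls below ``min_score``, or segmentation fails.
    """
    frames = stack.frames if hasattr(stack, "frames") else np.asarray(stack)
    track = DoubletTrack(circles=[initial_well])
    first = initialize_mask(frames[0], initial_well, min_area=min_area,
                            crop_margin=crop_margin)
    result = SegmentationResult(masks=[first], rotations=[0.0], track=track)
    half = int(round(initial_well.radius + crop_margin))
    prev_pair = first
    prev_well = initial_well
    rim_margin = 1.0
    for t in range(1, len(frames)):
        res = track_microwell(frames[t], prev_well, search_margin=search_margin)
        if isinstance(res, DropReason):
            track.drop(t, res)
            result.drop_frame, result.drop_reason = t, res
            break
        well = res
        track.circles.append(well)
        crop, origin = _crop_with_origin(frames[t], well.x, well.y, half)
        center = (well.x - origin[0], well.y - origin[1])
        try:
            fine = _segment_crop(crop, center, well.radius - rim_margin,
                                 min_area)
        except EmptyWellError:
            fine = np.zeros(crop.shape, dtype=bool)
        # sub-degree rotations are invisible to grid NCC; hint them from the
        # change in second-moment orientation of the mask
        hint = None
        if fine.any():
            hint = _orientation_delta(prev_pair.binary_mask, fine)
        transform = register_reference(prev_pair.gray_ref, crop,
                                       max_rotation=max_rotation,
                                       min_score=min_score, theta_hint=hint)
        if transform.score < min_score:
            track.drop(t, DropReason.REGISTRATION_FAILED)
            result.drop_frame = t
            result.drop_reason = DropReason.REGISTRATION_FAILED
            break
        sup = prev_pair.gray_ref > 0
        ys, xs = np.nonzero(sup)
        ref_center = (xs.mean(), ys.mean())
        transformed = apply_transform(prev_pair.binary_mask, transform,
                                      ref_center)
        try:
            refined, fallback = refine_mask(fine, transformed,
                                            prev_area=float(prev_pair.binary_mask.sum()))
        except EmptyWellError:
            track.drop(t, DropReason.SEGMENTATION_FAILED)
            result.drop_frame = t
            result.drop_reason = DropReason.SEGMENTATION_FAILED
            break
        if fallback:
            result.fallback_frames.append(t)
        pair = MaskPair(binary_mask=refined,
                        gray_ref=np.where(refined, crop, 0.0),
                        frame_index=t, crop_origin=origin)
        result.masks.append(pair)
        result.rotations.append(transform.dtheta)
        prev_pair = pair
        prev_well = well
    return result
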