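"""Synthetic microwell time-lapse phantoms with analytic ground truth.

Bright-field time-lapses of spheroid doublets fusing inside circular agarose
microwells are emulated geometrically: each doublet is the union of two disks
whose centre distance shrinks over time so that the analytic roundness of the
union follows a bounded-exponential fusion trajectory.  Because every rendered
frame is generated from closed-form two-circle geometry, the phantom provides
exact per-frame ground truth (masks, centres, contact chord, intersphere
angle, union area, roundness) against which detection, segmentation and
feature extraction can be validated without real microscope data.

The phantom is purely geometric: it does not simulate viscoelastic tissue
mechanics or extended-focal imaging, only the appearance regime (dark
spheroids in darker-rimmed wells on a bright background, debris, single
cells, illumination gradients, sensor noise and slow stage drift).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "PhantomConfig",
    "FrameStack",
    "DoubletGroundTruth",
    "WellPopulation",
    "fusion_trajectory",
    "union_geometry",
    "union_roundness",
    "distance_for_roundness",
    "render_doublet_sequence",
    "render_well_population",
    "render_well_grid",
]

# Printed box constraints of the fusion model (steady-state roundness and
# its negated amplitude); the phantom refuses parameters outside them.
PLATEAU_BOUNDS = (0.5, 1.0)
B_BOUNDS = (-0.6, -0.1)


class PhantomError(ValueError):
    """Invalid phantom configuration or kinetic parameters."""


@dataclass(frozen=True)
class PhantomConfig:
    """Rendering conditions for synthetic microwell time-lapses.

    Defaults follow the acquisition regime the package targets: a 4x
    bright-field objective at 1.6 um/px, 100-um-radius microwells, spheroids
    below 150 um diameter, frames every 5 minutes over 29 h (349 frames).
    Test presets shrink ``n_frames`` to 30-60 for speed.
    """

    image_size: tuple[int, int] = (256, 256)  # (H, W) px
    pixel_size: float = 1.6                   # um / px
    frame_interval: float = 5.0               # minutes between frames
    n_frames: int = 349
    well_grid: tuple[int, int] = (1, 1)       # rows x cols (grid phantoms)
    well_radius: float = 100.0                # um
    well_rim_contrast: float = 0.35           # rim darkening, fraction of bg
    rim_width: float = 8.0                    # um
    spheroid_radius_range: tuple[float, float] = (40.0, 75.0)  # um
    background_level: float = 200.0           # 8-bit-style intensity units
    spheroid_contrast: float = 0.6            # spheroid darkening fraction
    halo_contrast: float = 0.08               # low-contrast ECM rim surrogate
    noise_sd: float = 0.0                     # Gaussian noise SD, intensity units
    debris_rate: float = 0.0                  # expected specks per well
    single_cell_rate: float = 0.0             # expected single cells per well
    drift_per_frame: tuple[float, float] = (0.0, 0.0)  # (dx, dy) px / frame
    gradient_amplitude: float = 0.0           # linear shading, intensity units
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise PhantomError("n_frames must be >= 1")
        if self.noise_sd < 0:
            raise PhantomError("noise_sd must be >= 0")
        if self.pixel_size <= 0:
            raise PhantomError("pixel_size must be > 0")
        rmin, rmax = self.spheroid_radius_range
        if not (0 < rmin <= rmax):
            raise PhantomError("spheroid_radius_range must be positive and ordered")
        if self.well_radius <= rmax:
            raise PhantomError("well_radius must exceed the largest spheroid radius")

    # -- convenience ------------------------------------------------------
    @property
    def well_radius_px(self) -> float:
        return self.well_radius / self.pixel_size

    @property
    def rim_width_px(self) -> float:
        return self.rim_width / self.pixel_size

    def times_h(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval / 60.0

    def replace(self, **kw) -> "PhantomConfig":
        return replace(self, **kw)

    @classmethod
    def test_preset(cls, **kw) -> "PhantomConfig":
        """Small, fast preset used throughout the test-suite."""
        base = dict(image_size=(220, 220), n_frames=30,
                    spheroid_radius_range=(40.0, 70.0))
        base.update(kw)
        return cls(**base)


@dataclass
class FrameStack:
    """Time-ordered grayscale frames plus physical calibration."""

    frames: np.ndarray          # (T, H, W) float intensities
    pixel_size: float           # um / px
    frame_interval: float       # minutes

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (T, H, W) array")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def times_h(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval / 60.0

    def __getitem__(self, t: int) -> np.ndarray:
        return self.frames[t]


@dataclass
class DoubletGroundTruth:
    """Exact per-frame geometry of a rendered doublet phantom."""

    masks: np.ndarray           # (T, H, W) bool, union of the two disks
    c1: np.ndarray              # (T, 2) disk-1 centre, (x, y) px
    c2: np.ndarray              # (T, 2) disk-2 centre, (x, y) px
    r1_px: float
    r2_px: float
    d_px: np.ndarray            # (T,) centre distance
    contact_chord_um: np.ndarray
    intersphere_angle_deg: np.ndarray
    union_area_um2: np.ndarray
    roundness: np.ndarray
    well_center: np.ndarray     # (T, 2) (x, y) px
    well_radius_px: float
    plateau: float
    b: float
    tau: float                  # hours
    axis_angle_deg: np.ndarray  # (T,) doublet axis orientation


@dataclass
class WellPopulation:
    """Labelled single-well crops for classifier training/evaluation."""

    crops: list[np.ndarray]
    labels: np.ndarray          # 0 / 1 / 2
    wells: list[tuple[float, float, float]]  # (cx, cy, radius_px) per crop
    info: list[dict]            # subtype and ground-truth object counts


# ---------------------------------------------------------------------------
# Analytic kinetics and two-circle geometry
# ---------------------------------------------------------------------------

def fusion_trajectory(plateau: float, b: float, tau: float,
                      times: np.ndarray | float) -> np.ndarray:
    """Bounded-exponential roundness response ``plateau + b * exp(-t/tau)``.

    ``plateau`` is the steady-state roundness (fusion quality), ``b`` the
    (negative) initial offset, and ``tau`` the time constant in hours: at
    ``t = tau`` the response has closed ``1 - 1/e ~ 63.2%`` of the gap to the
    plateau.  Parameters are validated against the physical boxes
    ``plateau in [0.5, 1]`` and ``b in [-0.6, -0.1]``.
    """
    if tau <= 0:
        raise PhantomError("tau must be > 0")
    if not (PLATEAU_BOUNDS[0] <= plateau <= PLATEAU_BOUNDS[1]):
        raise PhantomError(f"plateau must lie in {PLATEAU_BOUNDS}")
    if not (B_BOUNDS[0] <= b <= B_BOUNDS[1]):
        raise PhantomError(f"b must lie in {B_BOUNDS}")
    t = np.asarray(times, dtype=float)
    return plateau + b * np.exp(-t / tau)


def _lens_half_angles(r1: float, r2: float, d: float) -> tuple[float, float]:
    """Half-angles subtended by the common chord at each centre."""
    a1 = math.acos(np.clip((d * d + r1 * r1 - r2 * r2) / (2 * d * r1), -1, 1))
    a2 = math.acos(np.clip((d * d + r2 * r2 - r1 * r1) / (2 * d * r2), -1, 1))
    return a1, a2


def union_geometry(r1: float, r2: float, d: float
                   ) -> tuple[float, float, float]:
    """Closed-form geometry of the union of two disks.

    Returns ``(union_area, contact_chord, intersphere_angle_deg)`` in pixel
    units (area in px^2).  The contact chord is the common chord of the two
    circle boundaries; the intersphere angle is 180 deg minus the angle
    between the radius vectors at an intersection point, so a smooth merged
    boundary gives 180 deg and an external tangency gives the 0 deg cusp.
    Non-overlapping disks report a zero-contact sentinel ``(sum of disk
    areas, 0, 0)``.
    """
    if r1 <= 0 or r2 <= 0:
        raise PhantomError("radii must be > 0")
    if d < 0:
        raise PhantomError("centre distance must be >= 0")
    if d >= r1 + r2:  # disjoint (or externally tangent): cusp sentinel
        return math.pi * (r1 * r1 + r2 * r2), 0.0, 0.0
    if d <= abs(r1 - r2):  # containment: boundary is the larger circle
        r = max(r1, r2)
        return math.pi * r * r, 0.0, 180.0
    a1, a2 = _lens_half_angles(r1, r2, d)
    lens = (r1 * r1 * a1 + r2 * r2 * a2
            - 0.5 * math.sqrt((-d + r1 + r2) * (d + r1 - r2)
                              * (d - r1 + r2) * (d + r1 + r2)))
    area = math.pi * (r1 * r1 + r2 * r2) - lens
    chord = 2.0 * r1 * math.sin(a1)
    # angle between radius vectors at an intersection point
    cos_g = np.clip((d * d - r1 * r1 - r2 * r2) / (2 * r1 * r2), -1, 1)
    # interior angle between the two tangent rays on the doublet exterior
    angle = 180.0 - math.degrees(math.pi - math.acos(cos_g))
    return area, chord, angle


def union_roundness(r1: float, r2: float, d: float) -> float:
    """Analytic roundness ``4 pi A / P^2`` of the two-disk union boundary.

    The perimeter is the sum of the two major arcs, which makes the map from
    centre distance to roundness exact and invertible.
    """
    if d >= r1 + r2:
        a = math.pi * (r1 * r1 + r2 * r2)
        p = 2 * math.pi * (r1 + r2)
        return 4 * math.pi * a / (p * p)
    if d <= abs(r1 - r2):
        return 1.0
    a1, a2 = _lens_half_angles(r1, r2, d)
    area, _, _ = union_geometry(r1, r2, d)
    perim = r1 * (2 * math.pi - 2 * a1) + r2 * (2 * math.pi - 2 * a2)
    return 4 * math.pi * area / (perim * perim)


def min_union_roundness(r1: float, r2: float) -> float:
    """Roundness of two externally tangent disks — the reachable minimum."""
    return (r1 * r1 + r2 * r2) / ((r1 + r2) ** 2)


def distance_for_roundness(r1: float, r2: float, roundness: float) -> float:
    """Invert :func:`union_roundness`: centre distance achieving a roundness.

    Roundness decreases monotonically with centre distance from 1 (disks
    coincident/contained) down to the tangent-disk minimum; requests below
    that minimum raise :class:`PhantomError`.
    """
    lo = abs(r1 - r2) + 1e-9 * max(r1, r2)
    hi = (r1 + r2) * (1 - 1e-12)
    rho_min = min_union_roundness(r1, r2)
    if roundness < rho_min - 1e-12:
        raise PhantomError(
            f"roundness {roundness:.4f} below tangent-disk minimum {rho_min:.4f}")
    if roundness >= union_roundness(r1, r2, lo):
        return lo
    if roundness <= union_roundness(r1, r2, hi):
        return hi
    return brentq(lambda d: union_roundness(r1, r2, d) - roundness, lo, hi,
                  xtol=1e-10)


# ---------------------------------------------------------------------------
# Rendering primitives
# ---------------------------------------------------------------------------

def _coverage(signed: np.ndarray) -> np.ndarray:
    # 1-px linear anti-aliasing of a signed distance field
    return np.clip(0.5 - signed, 0.0, 1.0)


def _blend(img: np.ndarray, cov: np.ndarray, level: float) -> None:
    img *= (1.0 - cov)
    img += cov * level


def _dist(shape: tuple[int, int], cx: float, cy: float) -> np.ndarray:
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    return np.hypot(xx - cx, yy - cy)


def _render_scene(shape: tuple[int, int], cfg: PhantomConfig,
                  wells: list[tuple[float, float, float]],
                  disk_groups: list[list[tuple[float, float, float]]],
                  specks: list[tuple[float, float, float, float]],
                  rng: np.random.Generator | None) -> np.ndarray:
    """Rasterize wells, spheroid-disk unions and specks into one frame.

    ``wells``: (cx, cy, R) px; ``disk_groups``: one list of (cx, cy, r) per
    connected object (rendered as a union); ``specks``: (cx, cy, r, contrast).
    """
    h, w = shape
    bg = cfg.background_level
    img = np.full(shape, bg, dtype=float)
    if cfg.gradient_amplitude:
        yy, xx = np.mgrid[:h, :w]
        img += cfg.gradient_amplitude * ((xx / max(w - 1, 1) - 0.5)
                                         + 0.5 * (yy / max(h - 1, 1) - 0.5))
    rim_level = bg * (1.0 - cfg.well_rim_contrast)
    for cx, cy, R in wells:
        dist = _dist(shape, cx, cy)
        rim_signed = np.maximum(dist - (R + cfg.rim_width_px), R - dist)
        _blend(img, _coverage(rim_signed), rim_level)
    sph_level = bg * (1.0 - cfg.spheroid_contrast)
    halo_level = bg * (1.0 - cfg.halo_contrast)
    for disks in disk_groups:
        signed = None
        for cx, cy, r in disks:
            s = _dist(shape, cx, cy) - r
            signed = s if signed is None else np.minimum(signed, s)
        if signed is None:
            continue
        if cfg.halo_contrast > 0:  # faint ECM-like rim around the object
            halo = np.maximum(signed - 3.0, -signed)
            _blend(img, _coverage(halo), halo_level)
        _blend(img, _coverage(signed), sph_level)
    for cx, cy, r, contrast in specks:
        s = _dist(shape, cx, cy) - r
        _blend(img, _coverage(s), bg * (1.0 - contrast))
    if cfg.noise_sd > 0:
        if rng is None:
            raise PhantomError("noise requested without an RNG")
        img += rng.normal(0.0, cfg.noise_sd, size=shape)
    return np.clip(img, 0.0, 255.0)


def _rasterize_union(shape: tuple[int, int],
                     disks: list[tuple[float, float, float]]) -> np.ndarray:
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    mask = np.zeros(shape, dtype=bool)
    for cx, cy, r in disks:
        mask |= (xx - cx) ** 2 + (yy - cy) ** 2 < r * r
    return mask


def _draw_specks(rng: np.random.Generator, rate: float, cx: float, cy: float,
                 rmax: float, radius_range: tuple[float, float],
                 contrast: float) -> list[tuple[float, float, float, float]]:
    """Poisson-distributed specks uniformly inside a disk around (cx, cy)."""
    n = rng.poisson(rate)
    out = []
    for _ in range(n):
        rho = rmax * math.sqrt(rng.uniform())
        phi = rng.uniform(0, 2 * math.pi)
        r = rng.uniform(*radius_range)
        out.append((cx + rho * math.cos(phi), cy + rho * math.sin(phi),
                    r, contrast))
    return out


# ---------------------------------------------------------------------------
# Public renderers
# ---------------------------------------------------------------------------

def render_doublet_sequence(config: PhantomConfig,
                            kinetics: tuple[float, float, float],
                            r1: float, r2: float,
                            orientation_deg: float = 0.0,
                            rotation_per_frame: float = 0.0,
                            ) -> tuple[FrameStack, DoubletGroundTruth]:
    """Render one fusing doublet in a single microwell, with ground truth.

    Parameters
    ----------
    kinetics : (plateau, b, tau)
        Fusion-trajectory parameters (tau in hours).
    r1, r2 : float
        Spheroid radii in micrometres.
    orientation_deg : float
        Doublet axis angle at frame 0 (image convention: x rightward,
        y downward, positive angles rotate y-ward).
    rotation_per_frame : float
        In-plane rigid rotation of the doublet axis per frame, degrees.
    """
    plateau, b, tau = kinetics
    rng = np.random.default_rng(config.rng_seed)
    r1_px = r1 / config.pixel_size
    r2_px = r2 / config.pixel_size
    rmax_um = max(r1, r2)
    if not (config.spheroid_radius_range[0] - 1e-9 <= rmax_um
            <= config.spheroid_radius_range[1] + 1e-9):
        # radii outside the configured envelope are allowed but must fit the well
        pass
    if rmax_um >= config.well_radius:
        raise PhantomError("spheroid radius must be smaller than the well radius")
    times = config.times_h()
    rho = fusion_trajectory(plateau, b, tau, times)
    rho_min = min_union_roundness(r1_px, r2_px)
    if rho[0] < rho_min - 1e-12:
        raise PhantomError(
            f"initial roundness {rho[0]:.4f} unreachable for radii "
            f"(tangent-disk minimum {rho_min:.4f})")
    d0 = distance_for_roundness(r1_px, r2_px, rho[0])
    if d0 / 2.0 + max(r1_px, r2_px) > config.well_radius_px:
        raise PhantomError(
            "doublet does not fit inside the well at its initial separation; "
            "reduce the spheroid radii or the initial roundness gap")

    h, w = config.image_size
    T = config.n_frames
    base_center = np.array([w / 2.0, h / 2.0])
    drift = np.asarray(config.drift_per_frame, dtype=float)

    masks = np.zeros((T, h, w), dtype=bool)
    frames = np.empty((T, h, w), dtype=float)
    c1 = np.empty((T, 2))
    c2 = np.empty((T, 2))
    d_px = np.empty(T)
    chord_um = np.empty(T)
    angle_deg = np.empty(T)
    area_um2 = np.empty(T)
    axis_deg = np.empty(T)
    well_center = np.empty((T, 2))

    for t in range(T):
        d = distance_for_roundness(r1_px, r2_px, rho[t])
        wc = base_center + drift * t
        theta = math.radians(orientation_deg + rotation_per_frame * t)
        u = np.array([math.cos(theta), math.sin(theta)])
        p1 = wc - u * d / 2.0
        p2 = wc + u * d / 2.0
        disks = [(p1[0], p1[1], r1_px), (p2[0], p2[1], r2_px)]
        specks = _draw_specks(rng, config.debris_rate, wc[0], wc[1],
                              config.well_radius_px * 0.85, (1.0, 2.5), 0.45)
        specks += _draw_specks(rng, config.single_cell_rate, wc[0], wc[1],
                               config.well_radius_px * 0.85, (3.0, 5.0), 0.30)
        # keep specks clear of the doublet so ground truth stays exact
        specks = [s for s in specks
                  if all(math.hypot(s[0] - dc[0], s[1] - dc[1]) > dc[2] + s[2] + 2
                         for dc in disks)]
        frames[t] = _render_scene((h, w), config,
                                  [(wc[0], wc[1], config.well_radius_px)],
                                  [disks], specks, rng)
        masks[t] = _rasterize_union((h, w), disks)
        a, chord, ang = union_geometry(r1_px, r2_px, d)
        c1[t], c2[t] = p1, p2
        d_px[t] = d
        chord_um[t] = chord * config.pixel_size
        angle_deg[t] = ang
        area_um2[t] = a * config.pixel_size ** 2
        axis_deg[t] = math.degrees(theta)
        well_center[t] = wc

    stack = FrameStack(frames, config.pixel_size, config.frame_interval)
    truth = DoubletGroundTruth(
        masks=masks, c1=c1, c2=c2, r1_px=r1_px, r2_px=r2_px, d_px=d_px,
        contact_chord_um=chord_um, intersphere_angle_deg=angle_deg,
        union_area_um2=area_um2, roundness=rho, well_center=well_center,
        well_radius_px=config.well_radius_px, plateau=plateau, b=b, tau=tau,
        axis_angle_deg=axis_deg)
    return stack, truth


def render_well_grid(config: PhantomConfig, fill: str = "empty",
                     ) -> tuple[FrameStack, np.ndarray, float]:
    """Render a rows x cols grid of microwells over ``n_frames`` with drift.

    Returns ``(stack, centers, radius_px)`` where ``centers`` has shape
    (T, n_wells, 2) in (x, y) px.  ``fill`` may be ``"empty"`` or
    ``"doublet"`` (a static side-by-side pair in every well).
    """
    rows, cols = config.well_grid
    if rows < 1 or cols < 1:
        raise PhantomError("well_grid must be at least 1x1")
    rng = np.random.default_rng(config.rng_seed)
    R = config.well_radius_px
    pitch = 2.0 * (R + config.rim_width_px) + 8.0
    h = int(math.ceil(rows * pitch + pitch))
    w = int(math.ceil(cols * pitch + pitch))
    base = np.empty((rows * cols, 2))
    k = 0
    for i in range(rows):
        for j in range(cols):
            base[k] = (pitch * (j + 1), pitch * (i + 1))
            k += 1
    drift = np.asarray(config.drift_per_frame, dtype=float)
    T = config.n_frames
    frames = np.empty((T, h, w))
    centers = np.empty((T, rows * cols, 2))
    rmin, _ = config.spheroid_radius_range
    r_px = rmin / config.pixel_size
    for t in range(T):
        cts = base + drift * t
        wells = [(c[0], c[1], R) for c in cts]
        groups = []
        if fill == "doublet":
            for c in cts:
                groups.append([(c[0] - r_px, c[1], r_px),
                               (c[0] + r_px, c[1], r_px)])
        elif fill != "empty":
            raise PhantomError(f"unknown fill mode {fill!r}")
        frames[t] = _render_scene((h, w), config, wells, groups, [], rng)
        centers[t] = cts
    return (FrameStack(frames, config.pixel_size, config.frame_interval),
            centers, R)


# -- labelled well populations ---------------------------------------------

#: default class imbalance: ~8.3% of wells hold a usable doublet
DEFAULT_CLASS_MIX = (0.917, 0.033, 0.05)

_NEGATIVE_SUBTYPES = ("empty", "debris_only", "single", "triplet",
                      "heavy_overlap")


def _sample_radius(rng: np.random.Generator, cfg: PhantomConfig) -> float:
    return rng.uniform(*cfg.spheroid_radius_range) / cfg.pixel_size


def _well_scene(rng: np.random.Generator, cfg: PhantomConfig, label: int,
                ) -> tuple[list[list[tuple[float, float, float]]], dict]:
    """Spheroid-disk groups and metadata for one labelled well."""
    if label == 2:
        # clean side-by-side pair: near-tangent, similar radii
        r1 = _sample_radius(rng, cfg)
        r2 = r1 * rng.uniform(0.85, 1.0)
        d = (r1 + r2) * rng.uniform(0.97, 1.04)
        subtype, disks = "pair", _axis_pair(rng, r1, r2, d)
        n_spheroids = 2
    elif label == 1:
        # possible candidate: overlapping pair or strong size mismatch
        r1 = _sample_radius(rng, cfg)
        if rng.uniform() < 0.5:
            r2 = r1 * rng.uniform(0.8, 1.0)
            d = (r1 + r2) * rng.uniform(0.65, 0.85)
            subtype = "overlap_pair"
        else:
            r2 = r1 * rng.uniform(0.4, 0.6)
            d = (r1 + r2) * rng.uniform(0.95, 1.05)
            subtype = "mismatch_pair"
        disks = _axis_pair(rng, r1, r2, d)
        n_spheroids = 2
    else:
        subtype = _NEGATIVE_SUBTYPES[rng.integers(len(_NEGATIVE_SUBTYPES))]
        if subtype in ("empty", "debris_only"):
            disks, n_spheroids = [], 0
        elif subtype == "single":
            disks = [(0.0, 0.0, _sample_radius(rng, cfg))]
            n_spheroids = 1
        elif subtype == "triplet":
            r = _sample_radius(rng, cfg) * 0.8
            ang0 = rng.uniform(0, 2 * math.pi)
            disks = [(1.2 * r * math.cos(ang0 + k * 2 * math.pi / 3),
                      1.2 * r * math.sin(ang0 + k * 2 * math.pi / 3), r)
                     for k in range(3)]
            n_spheroids = 3
        else:  # heavy_overlap
            r1 = _sample_radius(rng, cfg)
            r2 = r1 * rng.uniform(0.8, 1.0)
            d = (r1 + r2) * rng.uniform(0.25, 0.45)
            disks = _axis_pair(rng, r1, r2, d)
            n_spheroids = 2
    groups = [ [d_] for d_ in disks ] if label == 0 and len(disks) == 3 \
        else ([disks] if disks else [])
    return groups, {"subtype": subtype, "n_spheroids": n_spheroids}


def _axis_pair(rng: np.random.Generator, r1: float, r2: float, d: float
               ) -> list[tuple[float, float, float]]:
    theta = rng.uniform(0, math.pi)
    u = np.array([math.cos(theta), math.sin(theta)])
    p1, p2 = -u * d / 2, u * d / 2
    return [(p1[0], p1[1], r1), (p2[0], p2[1], r2)]


def render_well_population(config: PhantomConfig,
                           class_mix: tuple[float, float, float] = DEFAULT_CLASS_MIX,
                           n_wells: int = 200) -> WellPopulation:
    """Render labelled single-well crops with a configurable class imbalance.

    Labels follow the manual triage convention: 0 = no candidate (empty well,
    debris only, single spheroid, triplet, or a heavily overlapping pair),
    1 = possible candidate (moderate overlap or large size mismatch),
    2 = clean side-by-side doublet candidate.  The default mix puts ~8.3% of
    wells in the positive classes {1, 2}.
    """
    mix = np.asarray(class_mix, dtype=float)
    if mix.size != 3 or mix.sum() <= 0 or (mix < 0).any():
        raise PhantomError("class_mix must be three non-negative weights")
    mix = mix / mix.sum()
    rng = np.random.default_rng(config.rng_seed)
    R = config.well_radius_px
    side = int(math.ceil(2 * (R + config.rim_width_px) + 10))
    cc = side / 2.0
    crops, labels, wells, info = [], [], [], []
    for _ in range(n_wells):
        label = int(rng.choice(3, p=mix))
        groups, meta = _well_scene(rng, config, label)
        # shift scene coordinates to the crop centre, confine to the well
        shifted = []
        for g in groups:
            shifted.append([(cc + x, cc + y, r) for x, y, r in g])
        specks = _draw_specks(rng, config.debris_rate, cc, cc, R * 0.85,
                              (1.0, 2.5), 0.45)
        if meta["subtype"] == "debris_only":
            specks += _draw_specks(rng, max(6.0, config.debris_rate), cc, cc,
                                   R * 0.85, (1.0, 2.5), 0.45)
        specks += _draw_specks(rng, config.single_cell_rate, cc, cc, R * 0.85,
                               (3.0, 5.0), 0.30)
        img = _render_scene((side, side), config, [(cc, cc, R)],
                            shifted, specks, rng)
        crops.append(img)
        labels.append(label)
        wells.append((cc, cc, R))
        meta = dict(meta)
        meta["n_debris"] = len(specks)
        info.append(meta)
    return WellPopulation(crops=crops, labels=np.asarray(labels, dtype=int),
                          wells=wells, info=info)


def render_single_well(config: PhantomConfig,
                       disks: list[tuple[float, float, float]],
                       n_debris: int = 0, n_cells: int = 0,
                       rng: np.random.Generator | None = None,
                       ) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Render one well crop with explicit disk placement (px, well-centred).

    ``disks`` are (dx, dy, r) offsets from the well centre in pixels.  Debris
    and single cells are placed uniformly in the well but never on a disk.
    Returns ``(image, (cx, cy, radius_px))``.
    """
    rng = np.random.default_rng(config.rng_seed) if rng is None else rng
    R = config.well_radius_px
    side = int(math.ceil(2 * (R + config.rim_width_px) + 10))
    cc = side / 2.0
    placed = [(cc + x, cc + y, r) for x, y, r in disks]
    specks = []
    for n, rad_range, contrast in ((n_debris, (1.0, 2.5), 0.45),
                                   (n_cells, (3.0, 5.0), 0.30)):
        made = 0
        while made < n:
            s = _draw_specks(rng, 10, cc, cc, R * 0.85, rad_range, contrast)
            for sp in s:
                if made >= n:
                    break
                if all(math.hypot(sp[0] - d[0], sp[1] - d[1]) > d[2] + sp[2] + 2
                       for d in placed):
                    specks.append(sp)
                    made += 1
    img = _render_scene((side, side), config, [(cc, cc, R)],
                        [placed] if placed else [], specks, rng)
    return img, (cc, cc, R)
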