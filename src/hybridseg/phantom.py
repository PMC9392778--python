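"""Synthetic 3D phantoms with exact ground-truth masks.

Three scene families, chosen so every ground-truth volume has a closed form
usable as a test oracle:

* ``aneurysm`` — a bright tubular stent+lumen (swept sphere along a
  sinusoidally perturbed vertical centerline) inside a larger coaxial
  low-contrast thrombus ring, in a textured abdomen-like background.  This
  mimics a contrast-enhanced CT after endovascular aneurysm repair, where
  the stented lumen is hyperdense and the surrounding thrombus is hypodense
  with a weak boundary against soft tissue.
* ``tumour`` — an irregular bright blob (union of overlapping random
  spheres) in a smooth background.
* ``organ`` — a superellipsoid of intermediate intensity.

Contrast, additive Gaussian noise and simulated boundary-contrast dropouts
(angular sectors of the outer thrombus boundary where the intensity step is
erased, standing in for artifacts and regions with no contrast at the
boundary) are all controllable, and every sample of randomness flows through
``rng_seed``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .grids import LabelMask, Volume

__all__ = [
    "Intensities",
    "PhantomSpec",
    "Phantom",
    "generate_phantom",
    "generate_cohort",
    "analytic_volume_mm3",
]

TASKS = ("aneurysm", "tumour", "organ")

# aneurysm truth labels
THROMBUS, STENT_LUMEN = 1, 2


@dataclass(frozen=True)
class Intensities:
    """Noise-free scalar levels per region, arbitrary units on [0, 1].

    Default ordering lumen > background > thrombus mimics contrast-enhanced
    CT with a hypodense thrombus.  When ``PhantomSpec.boundary_contrast`` is
    set, the effective thrombus level is ``background - boundary_contrast``
    and the ``thrombus`` entry here is ignored.
    """

    background: float = 0.40
    thrombus: float = 0.25
    lumen: float = 0.90


@dataclass(frozen=True)
class PhantomSpec:
    """Full parameterization of one synthetic scene."""

    grid_shape: tuple[int, int, int] = (48, 48, 48)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    task: str = "aneurysm"
    lumen_radius_mm: float = 5.0
    thrombus_outer_radius_mm: float = 12.0
    centerline_amplitude_mm: float = 3.0
    center_offset_y_mm: float = 0.0
    center_offset_x_mm: float = 0.0
    sac_length_mm: float | None = None  # None: uniform ring; else fusiform sac
    sac_center_offset_mm: float = 0.0
    ellipse_ratio: float = 1.0  # thrombus cross-section axis ratio (area-preserving)
    ellipse_angle_rad: float = 0.0
    wobble_cycles: float = 1.0  # centerline periods over the volume extent
    wobble_phase_rad: float = 0.0
    intensities: Intensities = field(default_factory=Intensities)
    boundary_contrast: float | None = 0.15
    noise_sigma: float = 0.02
    dropout_fraction: float = 0.0
    n_distractors: int = 3
    spine: bool = True  # shared bony landmark behind the aorta (aneurysm task)
    texture_amplitude: float = 0.02
    texture_scale_voxels: float = 4.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.task not in TASKS:
            raise ValueError(f"task must be one of {TASKS}, got {self.task!r}")
        if any(n < 16 for n in self.grid_shape):
            raise ValueError(f"grid_shape must be >= (16,16,16), got {self.grid_shape}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        if not (self.lumen_radius_mm < self.thrombus_outer_radius_mm):
            raise ValueError(
                "lumen_radius_mm must be smaller than thrombus_outer_radius_mm "
                f"({self.lumen_radius_mm} >= {self.thrombus_outer_radius_mm})"
            )
        if self.noise_sigma < 0:
            raise ValueError(f"noise_sigma must be >= 0, got {self.noise_sigma}")
        if not (0.0 <= self.dropout_fraction <= 1.0):
            raise ValueError(f"dropout_fraction must lie in [0,1], got {self.dropout_fraction}")
        if self.boundary_contrast is not None and not (0.0 <= self.boundary_contrast <= 1.0):
            raise ValueError(f"boundary_contrast must lie in [0,1], got {self.boundary_contrast}")
        if self.n_distractors < 0:
            raise ValueError(f"n_distractors must be >= 0, got {self.n_distractors}")

    @property
    def thrombus_level(self) -> float:
        if self.boundary_contrast is not None:
            return self.intensities.background - self.boundary_contrast
        return self.intensities.thrombus

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["grid_shape"] = list(self.grid_shape)
        d["spacing"] = list(self.spacing)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        d = dict(d)
        if "intensities" in d and isinstance(d["intensities"], dict):
            d["intensities"] = Intensities(**d["intensities"])
        for key in ("grid_shape", "spacing"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class Phantom:
    """A rendered scene: scalar volume + exact truth mask + its spec."""

    volume: Volume
    truth: LabelMask
    spec: PhantomSpec

    def __post_init__(self) -> None:
        if self.volume.shape != self.truth.shape:
            raise ValueError("volume and truth must share a grid")


def _coords_mm(spec: PhantomSpec):
    nz, ny, nx = spec.grid_shape
    sz, sy, sx = spec.spacing
    z = np.arange(nz)[:, None, None] * sz
    y = np.arange(ny)[None, :, None] * sy
    x = np.arange(nx)[None, None, :] * sx
    return z, y, x


def _aneurysm_geometry(spec: PhantomSpec):
    """In-plane distances (mm) to the wobbling centerline, plus angle.

    Returns (radial, radial_ell, angle): the circular distance (used for the
    stented lumen, which stays circular) and the elliptical-metric distance
    (used for the thrombus outer boundary; the sac cross-section is an
    area-preserving ellipse with axis ratio ``ellipse_ratio`` rotated by
    ``ellipse_angle_rad``).
    """
    z, y, x = _coords_mm(spec)
    nz, ny, nx = spec.grid_shape
    length_mm = nz * spec.spacing[0]
    cy0 = (ny - 1) * spec.spacing[1] / 2.0 + spec.center_offset_y_mm
    cx0 = (nx - 1) * spec.spacing[2] / 2.0 + spec.center_offset_x_mm
    a = spec.centerline_amplitude_mm
    # y and x wobbles in quadrature
    phase = 2.0 * np.pi * spec.wobble_cycles * z / max(length_mm, 1e-9) + spec.wobble_phase_rad
    cy = cy0 + a * np.sin(phase)
    cx = cx0 + a * np.cos(phase)
    dy = y - cy
    dx = x - cx
    radial = np.sqrt(dy**2 + dx**2)
    s = np.sqrt(max(spec.ellipse_ratio, 1e-6))
    cos_t, sin_t = np.cos(spec.ellipse_angle_rad), np.sin(spec.ellipse_angle_rad)
    u = cos_t * dy + sin_t * dx
    v = -sin_t * dy + cos_t * dx
    radial_ell = np.sqrt((u / s) ** 2 + (v * s) ** 2)
    angle = np.arctan2(dx, dy)  # in (-pi, pi]
    return radial, radial_ell, angle


def _outer_radius_profile(spec: PhantomSpec) -> np.ndarray:
    """Thrombus outer radius per slice, (nz, 1, 1), in mm.

    A uniform tube when ``sac_length_mm`` is None; otherwise a fusiform sac:
    the ring bulges to ``thrombus_outer_radius_mm`` over the sac and tapers
    smoothly to the bare lumen at both necks, the way an aneurysm sac tapers
    between the renal arteries and the bifurcation.
    """
    nz = spec.grid_shape[0]
    z = np.arange(nz)[:, None, None] * spec.spacing[0]
    if spec.sac_length_mm is None:
        return np.full_like(z, spec.thrombus_outer_radius_mm)
    center = (nz - 1) * spec.spacing[0] / 2.0 + spec.sac_center_offset_mm
    half = max(spec.sac_length_mm / 2.0, 1e-6)
    bump = np.exp(-(((z - center) / (0.72 * half)) ** 4))
    return spec.lumen_radius_mm + (spec.thrombus_outer_radius_mm - spec.lumen_radius_mm) * bump


def _render_aneurysm(spec: PhantomSpec, rng: np.random.Generator):
    radial, radial_ell, angle = _aneurysm_geometry(spec)
    outer_r = _outer_radius_profile(spec)
    truth = np.zeros(spec.grid_shape, dtype=np.int16)
    truth[radial_ell <= outer_r] = THROMBUS
    truth[radial <= spec.lumen_radius_mm] = STENT_LUMEN

    img = np.full(spec.grid_shape, spec.intensities.background, dtype=np.float64)
    img[truth == THROMBUS] = spec.thrombus_level
    img[truth == STENT_LUMEN] = spec.intensities.lumen

    if spec.dropout_fraction > 0:
        # angular sector(s) of the outer boundary where the thrombus/background
        # step is erased within a 2-voxel shell (simulated artifact)
        start = rng.uniform(-np.pi, np.pi)
        width = spec.dropout_fraction * 2.0 * np.pi
        rel = np.mod(angle - start, 2.0 * np.pi)
        in_sector = rel <= width + 1e-12
        # boundary shell: nominally 2 voxels, but never more than half the
        # local ring thickness — dropout degrades the boundary, not the region
        shell_mm = np.minimum(
            2.0 * min(spec.spacing[1], spec.spacing[2]),
            (outer_r - spec.lumen_radius_mm) / 2.0,
        )
        shell = (truth == THROMBUS) & (radial_ell >= outer_r - shell_mm)
        img[shell & in_sector] = spec.intensities.background
    else:
        rng.uniform(-np.pi, np.pi)  # keep the rng stream aligned across dropout settings

    if spec.n_distractors > 0:
        img = _add_distractors(spec, img, truth, rng)
    if spec.spine:
        # vertebral column: the one landmark every volume of a cohort shares,
        # posterior to the aorta at a nearly fixed position; registration
        # anchors on it the way it anchors on bone in real scans
        nz, ny, nx = spec.grid_shape
        _, y, x = _coords_mm(spec)
        sy_mm = (ny - 1) * spec.spacing[1]
        py = 0.86 * sy_mm + float(rng.uniform(-0.5, 0.5))
        px = (nx - 1) * spec.spacing[2] / 2.0 + float(rng.uniform(-0.5, 0.5))
        r_spine = 0.10 * sy_mm
        col = ((y - py) ** 2 + (x - px) ** 2 <= r_spine**2) & (truth == 0)
        img[col] = 0.75
    return img, truth


def _add_distractors(spec: PhantomSpec, img, truth, rng: np.random.Generator):
    """Abdomen-like background structures that are NOT the target.

    An abdominal scan contains other vessels and organs with intensities
    matching the lumen or the thrombus: contrast-filled veins (bright
    tubes) and hypodense soft-tissue blobs.  They clutter the scene the way
    bowel and vessels clutter a real abdomen.  Distractors never touch the
    target tube and leave the truth mask untouched.
    """
    nz, ny, nx = spec.grid_shape
    sy, sx = spec.spacing[1], spec.spacing[2]
    z, y, x = _coords_mm(spec)
    cy0 = (ny - 1) * sy / 2.0 + spec.center_offset_y_mm
    cx0 = (nx - 1) * sx / 2.0 + spec.center_offset_x_mm
    tube_extent = spec.thrombus_outer_radius_mm + spec.centerline_amplitude_mm

    kinds = ["dark_blob", "bright_tube"]
    for _ in range(spec.n_distractors):
        kind = kinds[int(rng.integers(0, len(kinds)))]
        r_core = float(rng.uniform(1.2, 2.2))
        r_out = float(rng.uniform(2.0, 3.5)) if kind == "dark_blob" else r_core
        placed = False
        for _ in range(50):  # rejection sampling; deterministic from rng
            py = float(rng.uniform(r_out + 1.0, (ny - 1) * sy - r_out - 1.0))
            px = float(rng.uniform(r_out + 1.0, (nx - 1) * sx - r_out - 1.0))
            if np.hypot(py - cy0, px - cx0) >= tube_extent + r_out + 1.5:
                placed = True
                break
        if not placed:
            continue
        dist = np.sqrt((y - py) ** 2 + (x - px) ** 2)
        if kind == "dark_blob":
            pz = float(rng.uniform(r_out, nz * spec.spacing[0] - r_out))
            blob = dist**2 + (z - pz) ** 2 <= r_out**2
            img[blob & (truth == 0)] = spec.thrombus_level
        else:  # bright_tube
            tube = dist <= r_core
            img[tube & (truth == 0)] = spec.intensities.lumen
    return img


def _render_tumour(spec: PhantomSpec, rng: np.random.Generator):
    z, y, x = _coords_mm(spec)
    nz, ny, nx = spec.grid_shape
    extent = np.array([nz * spec.spacing[0], ny * spec.spacing[1], nx * spec.spacing[2]])
    center = (np.array(spec.grid_shape) - 1) * np.array(spec.spacing) / 2.0
    n_spheres = int(rng.integers(3, 8))
    mask = np.zeros(spec.grid_shape, dtype=bool)
    base_r = spec.thrombus_outer_radius_mm * 0.6
    for _ in range(n_spheres):
        c = center + rng.uniform(-0.12, 0.12, size=3) * extent
        r = base_r * rng.uniform(0.6, 1.0)
        mask |= (z - c[0]) ** 2 + (y - c[1]) ** 2 + (x - c[2]) ** 2 <= r**2
    truth = mask.astype(np.int16)
    img = np.full(spec.grid_shape, spec.intensities.background, dtype=np.float64)
    img[mask] = spec.intensities.lumen
    return img, truth


def _render_organ(spec: PhantomSpec, rng: np.random.Generator):
    z, y, x = _coords_mm(spec)
    center = (np.array(spec.grid_shape) - 1) * np.array(spec.spacing) / 2.0
    semi = np.array(
        [
            spec.grid_shape[0] * spec.spacing[0] * 0.30,
            spec.grid_shape[1] * spec.spacing[1] * 0.25,
            spec.grid_shape[2] * spec.spacing[2] * 0.20,
        ]
    )
    p = 2.5  # superellipsoid exponent: boxier than an ellipsoid
    f = (
        np.abs((z - center[0]) / semi[0]) ** p
        + np.abs((y - center[1]) / semi[1]) ** p
        + np.abs((x - center[2]) / semi[2]) ** p
    )
    truth = (f <= 1.0).astype(np.int16)
    img = np.full(spec.grid_shape, spec.intensities.background, dtype=np.float64)
    img[truth == 1] = spec.intensities.lumen
    return img, truth


_RENDERERS = {"aneurysm": _render_aneurysm, "tumour": _render_tumour, "organ": _render_organ}


def generate_phantom(spec: PhantomSpec) -> Phantom:
    """Render one phantom; deterministic given ``spec.rng_seed``."""
    rng = np.random.default_rng(spec.rng_seed)
    img, truth = _RENDERERS[spec.task](spec, rng)

    if spec.texture_amplitude > 0:
        tex = ndimage.gaussian_filter(
            rng.standard_normal(spec.grid_shape), spec.texture_scale_voxels
        )
        std = tex.std()
        if std > 0:
            img = img + (truth == 0) * spec.texture_amplitude * tex / std
    if spec.noise_sigma > 0:
        img = img + rng.normal(0.0, spec.noise_sigma, spec.grid_shape)
    img = np.clip(img, 0.0, 1.0)

    return Phantom(
        volume=Volume(img, spec.spacing, "normalized"),
        truth=LabelMask(truth, spec.spacing),
        spec=spec,
    )


def analytic_volume_mm3(spec: PhantomSpec, label: int) -> float:
    """Closed-form region volume for a straight-tube aneurysm phantom.

    Valid when ``centerline_amplitude_mm`` is small relative to the grid (the
    swept tube keeps a constant cross-section, so the formula holds for any
    amplitude as long as the tube stays inside the grid).
    """
    if spec.task != "aneurysm":
        raise ValueError("closed-form volumes are defined for the aneurysm task")
    if spec.sac_length_mm is not None:
        raise ValueError("closed-form volumes require a uniform (non-fusiform) tube")
    length = spec.grid_shape[0] * spec.spacing[0]
    if label == STENT_LUMEN:
        return float(np.pi * spec.lumen_radius_mm**2 * length)
    if label == THROMBUS:
        return float(
            np.pi * (spec.thrombus_outer_radius_mm**2 - spec.lumen_radius_mm**2) * length
        )
    raise ValueError(f"unknown aneurysm label {label}")


_JITTERABLE = (
    "lumen_radius_mm",
    "thrombus_outer_radius_mm",
    "centerline_amplitude_mm",
    "center_offset_y_mm",
    "center_offset_x_mm",
    "sac_length_mm",
    "sac_center_offset_mm",
    "ellipse_ratio",
    "ellipse_angle_rad",
    "wobble_cycles",
    "wobble_phase_rad",
    "boundary_contrast",
    "noise_sigma",
    "dropout_fraction",
)


def generate_cohort(
    n: int,
    base_spec: PhantomSpec,
    jitter: dict[str, tuple[float, float]] | None = None,
    seed: int = 0,
) -> list[Phantom]:
    """n independently jittered phantoms, reproducible from ``seed``.

    ``jitter`` maps spec field names to inclusive (low, high) ranges sampled
    uniformly per phantom.  A zero-width range pins the field; phantoms then
    differ only through their per-phantom noise/geometry realization, since
    each receives its own derived ``rng_seed``.
    """
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    jitter = jitter or {}
    for name, rng_pair in jitter.items():
        if name not in _JITTERABLE:
            raise ValueError(f"cannot jitter field {name!r}; allowed: {_JITTERABLE}")
        lo, hi = rng_pair
        if hi < lo:
            raise ValueError(f"empty jitter range for {name!r}: ({lo}, {hi})")
    master = np.random.default_rng(seed)
    phantoms = []
    for _ in range(n):
        overrides: dict[str, float] = {}
        for name in _JITTERABLE:  # fixed order: reproducible draws
            if name in jitter:
                lo, hi = jitter[name]
                overrides[name] = float(master.uniform(lo, hi))
        overrides["rng_seed"] = int(master.integers(0, 2**31 - 1))
        phantoms.append(generate_phantom(dataclasses.replace(base_spec, **overrides)))
    return phantoms
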