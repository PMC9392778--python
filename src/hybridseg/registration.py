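"""Registration-based propagation of a saved segmentation onto new volumes.

One volume is segmented once (variationally, from markers); every subsequent
volume receives an *estimate* by registering the segmented reference onto it
and resampling the saved label mask through the recovered transform.  The
estimate does not need to be exact — it feeds the refinement network as a
second input channel and serves as a pseudo-label source — but it removes all
per-volume user interaction.

Implementation: classical multiresolution affine registration (3 levels,
normalized cross-correlation metric, regular-step gradient descent, dense
sampling so runs are deterministic), optionally followed by a
symmetric-forces demons deformable refinement.  Transforms live in physical
(mm) coordinates and map fixed-grid points to moving-grid points
(fixed ← moving convention, the direction resampling needs).  Images are
interpolated linearly, label masks nearest-neighbour; voxels mapped outside
the field of view become background (0).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import SimpleITK as sitk

from .grids import LabelMask, Volume

__all__ = ["RegistrationResult", "register", "propagate_mask", "make_estimates", "ncc"]


def _to_sitk(vol: Volume | LabelMask, dtype=None) -> sitk.Image:
    data = vol.data if dtype is None else vol.data.astype(dtype)
    img = sitk.GetImageFromArray(data)  # (z,y,x) array -> (x,y,z) image
    img.SetSpacing(tuple(reversed(vol.spacing)))
    return img


def _from_sitk(img: sitk.Image) -> tuple[np.ndarray, tuple[float, float, float]]:
    arr = sitk.GetArrayFromImage(img)
    sp = img.GetSpacing()
    return arr, (float(sp[2]), float(sp[1]), float(sp[0]))


def ncc(a: np.ndarray, b: np.ndarray) -> float:
    """Normalized cross-correlation of two equally shaped arrays."""
    a = np.asarray(a, dtype=np.float64).ravel()
    b = np.asarray(b, dtype=np.float64).ravel()
    a = a - a.mean()
    b = b - b.mean()
    den = np.linalg.norm(a) * np.linalg.norm(b)
    if den == 0:
        raise ValueError("constant image: NCC undefined")
    return float(np.dot(a, b) / den)


@dataclass
class RegistrationResult:
    """Transform mapping fixed-grid physical points to moving-grid points."""

    transform: sitk.Transform
    fixed_shape: tuple[int, int, int]
    fixed_spacing: tuple[float, float, float]
    moving_shape: tuple[int, int, int]
    moving_spacing: tuple[float, float, float]
    similarity_trace: list[float] = field(default_factory=list)
    mode: str = "affine"

    @property
    def affine_matrix(self) -> np.ndarray:
        """4x4 homogeneous matrix (sitk x,y,z order) of the affine part."""
        t = self.transform
        if isinstance(t, sitk.CompositeTransform):
            for i in range(t.GetNumberOfTransforms()):
                inner = t.GetNthTransform(i)
                if isinstance(inner, sitk.AffineTransform):
                    t = inner
                    break
        if not isinstance(t, sitk.AffineTransform):
            raise TypeError("no affine component in transform")
        m = np.eye(4)
        m[:3, :3] = np.asarray(t.GetMatrix()).reshape(3, 3)
        center = np.asarray(t.GetCenter())
        trans = np.asarray(t.GetTranslation())
        # fold the rotation center into the homogeneous translation column
        m[:3, 3] = trans + center - m[:3, :3] @ center
        return m

    def save(self, path: str | Path) -> None:
        """Affine part as JSON; a composite's displacement field goes alongside."""
        path = Path(path)
        payload = {
            "mode": self.mode,
            "affine_fixed_to_moving_mm_xyz": self.affine_matrix.tolist(),
            "fixed_shape": list(self.fixed_shape),
            "fixed_spacing": list(self.fixed_spacing),
            "similarity_trace": self.similarity_trace,
        }
        path.write_text(json.dumps(payload, indent=1))


def _center_of_mass(img: sitk.Image) -> np.ndarray:
    """Structural centre of mass in physical coordinates (x, y, z).

    Weights are |I - median(I)| so both hyper- and hypo-dense structures pull
    the centre, while the flat background contributes almost nothing.
    """
    arr = sitk.GetArrayFromImage(img).astype(np.float64)
    arr = np.abs(arr - np.median(arr))
    total = arr.sum()
    if total == 0:
        return np.array(img.TransformContinuousIndexToPhysicalPoint(
            [(s - 1) / 2.0 for s in img.GetSize()]
        ))
    idx = [
        (arr.sum(axis=tuple(a for a in range(3) if a != ax)) * np.arange(arr.shape[ax])).sum()
        / total
        for ax in range(3)
    ]  # (z, y, x) index order
    return np.array(img.TransformContinuousIndexToPhysicalPoint([idx[2], idx[1], idx[0]]))


def _unwrap(t: sitk.Transform) -> sitk.Transform:
    """Downcast a registration result to its concrete transform type."""
    t = t.Downcast()
    if isinstance(t, sitk.CompositeTransform):
        t = t.GetNthTransform(0).Downcast()
    return t


def _registration_method(trace: list[float]) -> sitk.ImageRegistrationMethod:
    reg = sitk.ImageRegistrationMethod()
    reg.SetMetricAsCorrelation()
    reg.SetMetricSamplingStrategy(reg.NONE)  # dense: deterministic
    reg.SetInterpolator(sitk.sitkLinear)
    reg.SetOptimizerAsRegularStepGradientDescent(
        learningRate=1.0,
        minStep=1e-4,
        numberOfIterations=100,
        relaxationFactor=0.6,
    )
    reg.SetOptimizerScalesFromPhysicalShift()
    reg.SetShrinkFactorsPerLevel([4, 2, 1])
    reg.SetSmoothingSigmasPerLevel([2.0, 1.0, 0.0])
    reg.SmoothingSigmasAreSpecifiedInPhysicalUnitsOff()
    reg.AddCommand(sitk.sitkIterationEvent, lambda: trace.append(reg.GetMetricValue()))
    return reg


def register(moving: Volume, fixed: Volume, mode: str = "affine") -> RegistrationResult:
    """Recover the fixed←moving transform; see module docstring.

    mode ``"affine"`` or ``"affine+deformable"`` (demons refinement on the
    affine-resampled pair).
    """
    if mode not in ("affine", "affine+deformable"):
        raise ValueError(f"unknown registration mode {mode!r}")
    for name, v in (("moving", moving), ("fixed", fixed)):
        if np.ptp(v.data) == 0:
            raise ValueError(f"{name} image is constant; registration is degenerate")

    f_img = _to_sitk(fixed, np.float32)
    m_img = _to_sitk(moving, np.float32)

    # moments-based initialization: aligning the structural centres of mass
    # puts an off-centre structure roughly on target before optimisation
    t_init = _center_of_mass(m_img) - _center_of_mass(f_img)
    affine0 = sitk.AffineTransform(3)
    affine0.SetCenter(tuple(_center_of_mass(f_img)))  # rotate/scale about content
    affine0.SetTranslation(tuple(t_init))

    trace: list[float] = []
    reg = _registration_method(trace)
    reg.SetInitialTransform(affine0, inPlace=False)
    affine = _unwrap(reg.Execute(f_img, m_img))

    # divergence guard: score candidates by NCC on smoothed volumes
    # (uncorrelated texture/noise cannot reward a diverged optimum) and keep
    # the most expressive candidate within a small margin of the best —
    # resampling blur biases the raw score slightly toward candidates that
    # move less, so an outright argmax would discard good registrations.
    f_smooth = sitk.SmoothingRecursiveGaussian(f_img, 2.0)
    m_smooth = sitk.SmoothingRecursiveGaussian(m_img, 2.0)
    f_arr = sitk.GetArrayFromImage(f_smooth)

    def _score(t: sitk.Transform) -> float:
        moved = sitk.Resample(m_smooth, f_smooth, t, sitk.sitkLinear, float(np.mean(moving.data)))
        return ncc(f_arr, sitk.GetArrayFromImage(moved))

    candidates = [sitk.AffineTransform(3), affine0, affine]
    scores = [_score(t) for t in candidates]
    within = [t for t, s in zip(candidates, scores) if s >= max(scores) - 0.02]
    affine = within[-1]

    transform: sitk.Transform = affine
    if mode == "affine+deformable":
        moved = sitk.Resample(m_img, f_img, affine, sitk.sitkLinear, 0.0)
        demons = sitk.FastSymmetricForcesDemonsRegistrationFilter()
        demons.SetNumberOfIterations(30)
        demons.SetStandardDeviations(1.5)
        disp = demons.Execute(f_img, moved)
        composite = sitk.CompositeTransform(3)
        composite.AddTransform(affine)
        composite.AddTransform(sitk.DisplacementFieldTransform(disp))  # applied first
        transform = composite

    return RegistrationResult(
        transform=transform,
        fixed_shape=fixed.shape,
        fixed_spacing=fixed.spacing,
        moving_shape=moving.shape,
        moving_spacing=moving.spacing,
        similarity_trace=trace,
        mode=mode,
    )


def propagate_mask(saved_mask: LabelMask, result: RegistrationResult) -> LabelMask:
    """Resample a label mask from the moving grid onto the fixed grid.

    Nearest-neighbour interpolation preserves the label set (it can only
    shrink when a label falls entirely outside the field of view).
    """
    if saved_mask.shape != result.moving_shape:
        raise ValueError(
            f"mask grid {saved_mask.shape} does not match the registration's "
            f"moving grid {result.moving_shape}"
        )
    m_img = _to_sitk(saved_mask, np.int16)
    ref = sitk.Image([int(n) for n in reversed(result.fixed_shape)], sitk.sitkInt16)
    ref.SetSpacing(tuple(reversed(result.fixed_spacing)))
    out = sitk.Resample(m_img, ref, result.transform, sitk.sitkNearestNeighbor, 0)
    arr, spacing = _from_sitk(out)
    return LabelMask(arr.astype(np.int16), spacing)


def make_estimates(
    cohort: list[Volume],
    reference: tuple[Volume, LabelMask],
    mode: str = "affine",
) -> list[LabelMask]:
    """Registration-propagated segmentation estimate for every cohort volume.

    The reference pair is the one volume that was segmented interactively;
    it stays in the cohort (its estimate is its own saved mask) rather than
    being excluded downstream.
    """
    if not cohort:
        raise ValueError("cohort is empty")
    ref_vol, ref_mask = reference
    estimates = []
    for vol in cohort:
        if vol is ref_vol or (
            vol.shape == ref_vol.shape and np.array_equal(vol.data, ref_vol.data)
        ):
            estimates.append(LabelMask(ref_mask.data.copy(), ref_mask.spacing))
            continue
        result = register(moving=ref_vol, fixed=vol, mode=mode)
        estimates.append(propagate_mask(ref_mask, result))
    return estimates
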