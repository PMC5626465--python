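"""Reading, writing, realignment and brain masking of 4D DSC perfusion series.

A dynamic susceptibility contrast (DSC) perfusion acquisition is a 4D volume
(x, y, z, t) of T2*-weighted signal sampled every ``TR`` seconds while a
gadolinium bolus passes through the brain.  This module provides:

* :class:`DynamicSeries` — the in-memory 4D container with acquisition
  metadata, round-tripped through NIfTI-1 via nibabel;
* :func:`realign` — rigid-body (6 degrees of freedom) motion correction of
  every dynamic to a reference volume;
* :func:`make_brain_mask` — the whole-brain analysis mask, excluding
  out-of-brain background, areas of susceptibility signal loss, and
  (optionally) ventricles supplied as an external mask.

Conventions: voxel indices are 0-based in (x, y, z, t) order; all masks share
the series grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
from scipy import ndimage, optimize
from skimage.filters import threshold_otsu
from skimage.registration import phase_cross_correlation

from .errors import FormatError, MaskingError, MetadataError, RegistrationError, ShapeError

__all__ = [
    "DynamicSeries",
    "BrainMask",
    "RigidTransform",
    "read_series",
    "write_series",
    "read_mask",
    "write_mask",
    "realign",
    "make_brain_mask",
    "write_transforms",
    "read_transforms",
]


@dataclass
class DynamicSeries:
    """A 4D perfusion signal series with acquisition metadata.

    Parameters
    ----------
    data
        Signal array, shape (nx, ny, nz, nt), arbitrary units.
    tr
        Repetition time in seconds (sampling interval of the dynamics).
    te
        Echo time in milliseconds.
    voxel_dims
        Physical voxel size (dx, dy, dz) in millimetres.
    affine
        4x4 voxel-to-world affine.  Defaults to a diagonal scaling by
        ``voxel_dims``.
    """

    data: np.ndarray
    tr: float
    te: float
    voxel_dims: tuple[float, float, float] = (0.9375, 0.9375, 7.0)
    affine: np.ndarray | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 4:
            raise FormatError(f"DynamicSeries requires 4D data, got {self.data.ndim}D")
        if self.data.shape[3] < 2:
            raise FormatError("time dimension must have length >= 2")
        if not self.tr > 0:
            raise MetadataError(f"TR must be positive, got {self.tr}")
        if any(d <= 0 for d in self.voxel_dims):
            raise MetadataError(f"voxel dimensions must be positive, got {self.voxel_dims}")
        if self.affine is None:
            self.affine = np.diag(list(self.voxel_dims) + [1.0])

    @property
    def shape(self) -> tuple[int, int, int]:
        """Spatial grid shape (nx, ny, nz)."""
        return self.data.shape[:3]

    @property
    def n_dynamics(self) -> int:
        return self.data.shape[3]

    @property
    def times(self) -> np.ndarray:
        """Acquisition time of each dynamic in seconds (0, TR, 2*TR, ...)."""
        return np.arange(self.n_dynamics) * self.tr

    def voxel_volume_mm3(self) -> float:
        dx, dy, dz = self.voxel_dims
        return dx * dy * dz


@dataclass
class BrainMask:
    """Binary analysis mask on the series grid with per-exclusion provenance.

    ``exclusions`` maps a label (``out-of-brain``, ``signal-loss``,
    ``ventricle``) to the boolean volume of voxels removed for that reason.
    """

    mask: np.ndarray
    exclusions: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise ShapeError("BrainMask must be 3D")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.mask.shape

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


@dataclass
class RigidTransform:
    """A 6-DOF rigid-body transform: Euler rotations (degrees, x-y-z order)
    and a translation in voxel units on the series grid."""

    rotations_deg: tuple[float, float, float] = (0.0, 0.0, 0.0)
    translation_vox: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def translation_mm(self, voxel_dims) -> tuple[float, float, float]:
        return tuple(t * d for t, d in zip(self.translation_vox, voxel_dims))

    def is_identity(self, tol: float = 1e-12) -> bool:
        return (max(abs(r) for r in self.rotations_deg) <= tol
                and max(abs(t) for t in self.translation_vox) <= tol)

    def magnitude_vox(self) -> float:
        return float(np.linalg.norm(self.translation_vox))


def _rotation_matrix(rot_deg) -> np.ndarray:
    rx, ry, rz = np.deg2rad(rot_deg)
    cx, sx = np.cos(rx), np.sin(rx)
    cy, sy = np.cos(ry), np.sin(ry)
    cz, sz = np.cos(rz), np.sin(rz)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return Rz @ Ry @ Rx


def apply_rigid(volume: np.ndarray, transform: RigidTransform, order: int = 1) -> np.ndarray:
    """Resample ``volume`` under a rigid transform about the grid centre.

    The output at voxel x is ``volume(R @ (x - c) + c + t)`` — i.e. the
    transform maps output (reference-frame) coordinates into the input
    volume, which is the convention used when undoing estimated motion.
    Trilinear interpolation by default.
    """
    if transform.is_identity():
        return volume.copy()
    R = _rotation_matrix(transform.rotations_deg)
    centre = (np.asarray(volume.shape) - 1) / 2.0
    offset = centre - R @ centre + np.asarray(transform.translation_vox)
    return ndimage.affine_transform(volume, R, offset=offset, order=order, mode="nearest")


# --------------------------------------------------------------------------
# NIfTI I/O


def write_series(series: DynamicSeries, path) -> None:
    """Write a 4D series as NIfTI-1, storing TR in the header timing field
    and TE in the description (NIfTI-1 has no dedicated TE slot)."""
    img = nib.Nifti1Image(series.data.astype(np.float64), series.affine)
    zooms = list(series.voxel_dims) + [series.tr]
    img.header.set_zooms(zooms)
    img.header.set_xyzt_units(xyz="mm", t="sec")
    img.header["descrip"] = f"TE={series.te:g}ms".encode()
    nib.save(img, str(path))


def read_series(path, tr: float | None = None, te: float | None = None) -> DynamicSeries:
    """Read a 4D NIfTI perfusion series.

    TR is taken from the header timing field (4th zoom) and TE from the
    description written by :func:`write_series`; ``tr``/``te`` arguments
    override the header.  A 3D file raises :class:`FormatError`; a missing
    TR with no override raises :class:`MetadataError`.
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 4:
        raise FormatError(
            f"{path}: expected a 4D series (x,y,z,t), got {data.ndim}D shape {data.shape}")
    zooms = img.header.get_zooms()
    header_tr = float(zooms[3]) if len(zooms) > 3 else 0.0
    if tr is None:
        if header_tr <= 0:
            raise MetadataError(f"{path}: no TR in header timing field and no override given")
        tr = header_tr
    if te is None:
        descrip = bytes(img.header["descrip"].tobytes()).decode(errors="ignore")
        te = _parse_te(descrip)
        if te is None:
            raise MetadataError(f"{path}: no TE found in header description and no override given")
    voxel_dims = tuple(float(z) for z in zooms[:3])
    return DynamicSeries(data=data, tr=float(tr), te=float(te),
                         voxel_dims=voxel_dims, affine=np.asarray(img.affine))


def _parse_te(descrip: str) -> float | None:
    descrip = descrip.strip("\x00 ")
    for token in descrip.replace(";", " ").split():
        if token.upper().startswith("TE="):
            try:
                return float(token[3:].lower().removesuffix("ms"))
            except ValueError:
                return None
    return None


def write_mask(mask: np.ndarray, path, voxel_dims=(0.9375, 0.9375, 7.0),
               affine: np.ndarray | None = None) -> None:
    """Write a binary 3D mask as NIfTI-1 (uint8)."""
    if affine is None:
        affine = np.diag(list(voxel_dims) + [1.0])
    img = nib.Nifti1Image(np.asarray(mask, dtype=np.uint8), affine)
    img.header.set_zooms(voxel_dims)
    nib.save(img, str(path))


def read_mask(path) -> np.ndarray:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a 3D mask, got {data.ndim}D")
    return data > 0


# --------------------------------------------------------------------------
# Realignment


def _block_mean_downsample(vol: np.ndarray, factor: int) -> np.ndarray:
    if factor <= 1:
        return vol
    slices = tuple(slice(0, (s // factor) * factor) for s in vol.shape)
    v = vol[slices]
    nx, ny, nz = (s // factor for s in vol.shape)
    return v.reshape(nx, factor, ny, factor, nz, factor).mean(axis=(1, 3, 5))


def _registration_cost(params, moving, reference):
    t = RigidTransform(tuple(params[:3]), tuple(params[3:]))
    resampled = apply_rigid(moving, t)
    return float(np.mean((resampled - reference) ** 2))


def _register_volume(moving: np.ndarray, reference: np.ndarray) -> RigidTransform:
    """Estimate the rigid transform resampling ``moving`` onto ``reference``.

    Multi-resolution least-squares: a subvoxel phase-correlation translation
    initialises a Powell search at a 2x block-averaged level, refined at full
    resolution.
    """
    # phase_cross_correlation returns the shift to apply to moving; our
    # resampling convention samples moving at x + t, so negate.
    shift, _, _ = phase_cross_correlation(reference, moving, upsample_factor=10,
                                          normalization=None)
    x0 = np.array([0.0, 0.0, 0.0, -shift[0], -shift[1], -shift[2]])

    can_coarsen = min(moving.shape) >= 8
    if can_coarsen:
        mov_c = _block_mean_downsample(moving, 2)
        ref_c = _block_mean_downsample(reference, 2)
        x_c = x0.copy()
        x_c[3:] /= 2.0
        res = optimize.minimize(_registration_cost, x_c, args=(mov_c, ref_c),
                                method="Powell", options={"xtol": 0.02, "ftol": 1e-4,
                                                          "maxiter": 30})
        x0 = res.x.copy()
        x0[3:] *= 2.0

    # full-resolution refinement only pays off when real motion was found;
    # near-identity coarse estimates are accepted as-is
    near_identity = (np.max(np.abs(x0[:3])) < 0.02 and np.max(np.abs(x0[3:])) < 0.02)
    if near_identity:
        p = x0
    else:
        res = optimize.minimize(_registration_cost, x0, args=(moving, reference),
                                method="Powell", options={"xtol": 0.005, "ftol": 1e-6,
                                                          "maxiter": 20})
        p = res.x
    return RigidTransform(tuple(float(v) for v in p[:3]), tuple(float(v) for v in p[3:]))


def realign(series: DynamicSeries, reference_index: int = 0,
            skip_threshold_vox: float = 0.05
            ) -> tuple[DynamicSeries, list[RigidTransform]]:
    """Rigid-body motion correction of every dynamic to a reference volume.

    Each volume is registered to ``series.data[..., reference_index]`` with a
    6-DOF intensity least-squares fit and resampled by trilinear
    interpolation.  Volumes whose estimated motion is below
    ``skip_threshold_vox`` (translation, voxels) and 0.05 degrees are copied
    through untouched, so motion-free data round-trips bit-identically.

    Returns the realigned series and the per-volume transforms (the
    resampling map applied to each volume; identity for the reference).
    """
    data = series.data
    nt = series.n_dynamics
    if not 0 <= reference_index < nt:
        raise RegistrationError(f"reference index {reference_index} out of range", reference_index)
    reference = data[..., reference_index]
    if not np.any(reference):
        raise RegistrationError(f"reference volume {reference_index} is all zero",
                                reference_index)

    out = np.empty_like(data)
    transforms: list[RigidTransform] = []
    for i in range(nt):
        vol = data[..., i]
        if i == reference_index:
            out[..., i] = vol
            transforms.append(RigidTransform())
            continue
        if not np.any(vol):
            raise RegistrationError(f"volume {i} is all zero; cannot register", i)
        t = _register_volume(vol, reference)
        negligible = (t.magnitude_vox() < skip_threshold_vox
                      and max(abs(r) for r in t.rotations_deg) < 0.05)
        if negligible:
            t = RigidTransform()
            out[..., i] = vol
        else:
            out[..., i] = apply_rigid(vol, t)
        transforms.append(t)

    realigned = DynamicSeries(data=out, tr=series.tr, te=series.te,
                              voxel_dims=series.voxel_dims, affine=series.affine.copy())
    return realigned, transforms


def write_transforms(transforms: list[RigidTransform], path, voxel_dims) -> None:
    """Write per-volume transforms as a plain-text table:
    volume index, 3 rotations (degrees), 3 translations (mm)."""
    with open(path, "w") as fh:
        fh.write("volume\trot_x_deg\trot_y_deg\trot_z_deg\ttrans_x_mm\ttrans_y_mm\ttrans_z_mm\n")
        for i, t in enumerate(transforms):
            mm = t.translation_mm(voxel_dims)
            fh.write(f"{i}\t" + "\t".join(f"{v:.6f}" for v in (*t.rotations_deg, *mm)) + "\n")


def read_transforms(path, voxel_dims) -> list[RigidTransform]:
    transforms = []
    with open(path) as fh:
        next(fh)
        for line in fh:
            parts = line.split()
            rot = tuple(float(v) for v in parts[1:4])
            mm = [float(v) for v in parts[4:7]]
            vox = tuple(m / d for m, d in zip(mm, voxel_dims))
            transforms.append(RigidTransform(rot, vox))
    return transforms


# --------------------------------------------------------------------------
# Brain masking


def make_brain_mask(series: DynamicSeries, ventricle_mask: np.ndarray | None = None,
                    signal_loss_fraction: float = 0.2) -> BrainMask:
    """Build the whole-brain analysis mask from the first pre-contrast volume.

    Steps: (1) foreground by Otsu threshold on dynamic 0, reduced to the
    largest connected component with holes filled; (2) exclude signal-loss
    voxels below ``signal_loss_fraction`` x the median foreground signal;
    (3) exclude an externally supplied ventricle mask, if any.

    The first dynamic is assumed pre-contrast; a warning is emitted if its
    global mean differs by more than 5% from the mean of the first three
    dynamics (suggesting the bolus had already arrived).
    """
    vol0 = series.data[..., 0]
    n_early = min(3, series.n_dynamics)
    early_mean = float(series.data[..., :n_early].mean())
    if early_mean > 0 and abs(float(vol0.mean()) - early_mean) > 0.05 * early_mean:
        warnings.warn("first dynamic differs from the first-3-volume mean by >5%; "
                      "it may not be pre-contrast", stacklevel=2)

    finite = vol0[np.isfinite(vol0)]
    if finite.size == 0 or finite.max() <= finite.min():
        raise MaskingError("first volume is constant; cannot threshold foreground")
    thresh = threshold_otsu(vol0)
    foreground = vol0 > thresh

    labels, n_labels = ndimage.label(foreground)
    if n_labels == 0:
        raise MaskingError("no foreground voxels above threshold")
    largest = int(np.argmax(ndimage.sum_labels(foreground, labels, range(1, n_labels + 1)))) + 1
    foreground = ndimage.binary_fill_holes(labels == largest)

    out_of_brain = ~foreground
    robust_level = float(np.median(vol0[foreground]))
    signal_loss = foreground & (vol0 < signal_loss_fraction * robust_level)

    mask = foreground & ~signal_loss
    exclusions = {"out-of-brain": out_of_brain, "signal-loss": signal_loss}
    if ventricle_mask is not None:
        ventricle_mask = np.asarray(ventricle_mask, dtype=bool)
        if ventricle_mask.shape != vol0.shape:
            raise ShapeError(f"ventricle mask shape {ventricle_mask.shape} != grid {vol0.shape}")
        exclusions["ventricle"] = mask & ventricle_mask
        mask = mask & ~ventricle_mask

    if not mask.any():
        raise MaskingError("brain mask is empty after exclusions")
    return BrainMask(mask=mask, exclusions=exclusions)
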