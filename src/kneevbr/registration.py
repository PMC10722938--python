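"""Rigid echo alignment and subject-to-atlas registration.

The phantom cohorts are generated directly in atlas space, so the default
atlas mode is ``identity`` (a checked passthrough).  A simple rigid and
affine optimizer (mean-squared-error metric, Powell search on Gaussian-
smoothed volumes, translation initialized by phase correlation) covers the
within-modality alignment the pipeline needs; full deformable registration
is delegated to an external executable through the ``plugin`` contract.

Transforms act on world coordinates (mm).  ``resample`` maps each output
voxel center through the transform and interpolates the moving image there,
so applying the transform that *created* a shifted image brings it back.
"""

from __future__ import annotations

import dataclasses
import subprocess
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage, optimize
from scipy.spatial.transform import Rotation
from skimage.registration import phase_cross_correlation

from .core import EchoSeries, RelaxationMap
from .errors import GridMismatchError, KneeVBRError, RegistrationError


@dataclass(frozen=True)
class RigidTransform:
    """Rigid world-space transform: rotation (xyz Euler, radians) about
    ``center_mm`` followed by translation (mm)."""

    rotation: tuple[float, float, float] = (0.0, 0.0, 0.0)
    translation_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    center_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def matrix(self) -> np.ndarray:
        """4x4 homogeneous matrix mapping world points: y = R(x - c) + c + t."""
        R = Rotation.from_euler("xyz", self.rotation).as_matrix()
        c = np.asarray(self.center_mm)
        t = np.asarray(self.translation_mm)
        M = np.eye(4)
        M[:3, :3] = R
        M[:3, 3] = c + t - R @ c
        return M

    def inverse(self) -> "RigidTransform":
        R = Rotation.from_euler("xyz", self.rotation)
        Rinv = R.inv()
        c = np.asarray(self.center_mm)
        t = np.asarray(self.translation_mm)
        # inverse of y = R(x-c)+c+t is x = R^-1(y-c-t)+c
        t_inv = tuple(-(Rinv.as_matrix() @ t))
        return RigidTransform(
            rotation=tuple(Rinv.as_euler("xyz")),
            translation_mm=t_inv,
            center_mm=tuple(c),
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class DeformationField:
    """Per-voxel displacement (mm) on the atlas grid, shape (x, y, z, 3)."""

    displacement: np.ndarray
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.displacement = np.asarray(self.displacement, dtype=float)
        if self.displacement.ndim != 4 or self.displacement.shape[-1] != 3:
            raise KneeVBRError("displacement field must have shape (x, y, z, 3)")
        if not np.all(np.isfinite(self.displacement)):
            raise KneeVBRError("displacement field contains non-finite values")

    def jacobian_determinant(self) -> np.ndarray:
        """det(I + grad u) per voxel; > 0 means locally fold-free."""
        sp = self.spacing_mm
        grads = np.empty(self.displacement.shape[:3] + (3, 3))
        for comp in range(3):
            for ax in range(3):
                grads[..., comp, ax] = np.gradient(
                    self.displacement[..., comp], sp[ax], axis=ax
                )
        return np.linalg.det(np.eye(3) + grads)


def _world_matrix_to_voxel(matrix: np.ndarray, spacing) -> tuple[np.ndarray, np.ndarray]:
    """Convert a world-space affine to the voxel-space (matrix, offset) pair
    consumed by ``scipy.ndimage.affine_transform`` (output -> input mapping)."""
    S = np.diag(spacing)
    Sinv = np.diag([1.0 / s for s in spacing])
    A = matrix[:3, :3]
    b = matrix[:3, 3]
    # output voxel v_out -> world y; input point x = A^-1 (y - b); voxel coords
    Ainv = np.linalg.inv(A)
    M = Sinv @ Ainv @ S
    off = Sinv @ Ainv @ (-b)
    return M, off


def resample(
    volume: np.ndarray,
    matrix: np.ndarray,
    spacing,
    order: int = 1,
    cval: float = 0.0,
) -> np.ndarray:
    """Resample ``volume`` so the output equals the transform applied to it.

    ``matrix`` is the 4x4 world transform that maps moving-image points to
    output points; interpolation order 0 for labels/masks, 1 for values.
    """
    M, off = _world_matrix_to_voxel(matrix, spacing)
    return ndimage.affine_transform(
        np.asarray(volume, dtype=float), M, offset=off, order=order,
        mode="constant", cval=cval,
    )


def _smooth(vol: np.ndarray, sigma: float) -> np.ndarray:
    return ndimage.gaussian_filter(np.asarray(vol, float), sigma) if sigma > 0 else vol


def _mse(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.mean((a - b) ** 2))


def register_echoes_rigid(
    series: EchoSeries,
    smooth_sigma: float = 1.0,
    refine: bool = True,
    maxfev: int = 300,
) -> tuple[EchoSeries, list[RigidTransform]]:
    """Rigidly align every echo to echo 0 by minimizing squared error.

    Translation is initialized with subpixel phase correlation and (optionally)
    refined jointly with rotation by Powell search on smoothed volumes.
    Echo 0 is returned untouched.  Raises :class:`RegistrationError` naming
    the echo if optimization diverges.
    """
    if series.n_echoes < 2:
        raise KneeVBRError("echo registration needs at least 2 echoes")
    spacing = np.asarray(series.spacing_mm)
    fixed = series.data[..., 0]
    fixed_s = _smooth(fixed, smooth_sigma)
    center = tuple((np.asarray(fixed.shape) - 1) / 2.0 * spacing)

    out = series.data.copy()
    transforms: list[RigidTransform] = [RigidTransform(center_mm=center)]
    for e in range(1, series.n_echoes):
        moving = series.data[..., e]
        moving_s = _smooth(moving, smooth_sigma)
        shift_vox, _, _ = phase_cross_correlation(
            fixed_s, moving_s, upsample_factor=20, normalization=None
        )
        # the moving image must be shifted by `shift_vox` voxels to match fixed
        t0 = np.asarray(shift_vox) * spacing

        def cost(params, moving_s=moving_s):
            tr = RigidTransform(
                rotation=tuple(params[:3]),
                translation_mm=tuple(params[3:]),
                center_mm=center,
            )
            return _mse(resample(moving_s, tr.matrix(), spacing), fixed_s)

        params = np.concatenate([np.zeros(3), t0])
        if refine:
            res = optimize.minimize(
                cost, params, method="Powell",
                options={"maxfev": maxfev, "xtol": 1e-4, "ftol": 1e-8},
            )
            if not np.isfinite(res.fun) or res.fun > cost(params) + 1e-9:
                raise RegistrationError(f"rigid optimization diverged on echo {e}")
            params = res.x
        tr = RigidTransform(
            rotation=tuple(params[:3]), translation_mm=tuple(params[3:]),
            center_mm=center,
        )
        out[..., e] = resample(moving, tr.matrix(), spacing)
        transforms.append(tr)

    aligned = EchoSeries(
        data=out, echo_times_ms=series.echo_times_ms, modality=series.modality,
        spacing_mm=series.spacing_mm,
        meta={**series.meta, "echo_registration": "rigid"},
    )
    return aligned, transforms


def _resample_map(rmap: RelaxationMap, matrix: np.ndarray) -> RelaxationMap:
    sp = rmap.spacing_mm
    mask = resample(rmap.mask.astype(float), matrix, sp, order=0) > 0.5
    conv = resample(rmap.converged.astype(float), matrix, sp, order=0) > 0.5
    return RelaxationMap(
        time_ms=resample(np.nan_to_num(rmap.time_ms), matrix, sp, order=1),
        s0=resample(np.nan_to_num(rmap.s0), matrix, sp, order=1),
        r_squared=resample(np.nan_to_num(rmap.r_squared), matrix, sp, order=1),
        converged=conv, mask=mask, spacing_mm=sp, meta=dict(rmap.meta),
    )


def _affine_displacement(matrix: np.ndarray, shape, spacing) -> DeformationField:
    coords = np.meshgrid(
        *[np.arange(n) * s for n, s in zip(shape, spacing)], indexing="ij"
    )
    pts = np.stack(coords, axis=-1)
    disp = pts @ matrix[:3, :3].T + matrix[:3, 3] - pts
    return DeformationField(displacement=disp, spacing_mm=tuple(spacing))


def register_to_atlas(
    subject_map: RelaxationMap,
    atlas_reference: np.ndarray,
    mode: str = "identity",
    smooth_sigma: float = 1.0,
    maxfev: int = 4000,
    plugin_cmd: list[str] | None = None,
) -> tuple[RelaxationMap, DeformationField]:
    """Bring a subject relaxation map onto the atlas grid.

    ``identity`` requires matching grids and performs no resampling;
    ``affine`` optimizes 12 parameters on an MSE metric between the subject's
    time map and the atlas reference volume; ``plugin`` delegates to an
    external executable (see README for the file contract).
    """
    atlas_reference = np.asarray(atlas_reference, dtype=float)
    shape = subject_map.grid_shape
    spacing = subject_map.spacing_mm

    if mode == "identity":
        if atlas_reference.shape != shape:
            raise GridMismatchError(
                f"identity registration requires matching grids: "
                f"subject {shape} vs atlas {atlas_reference.shape}"
            )
        zero = DeformationField(
            displacement=np.zeros(shape + (3,)), spacing_mm=spacing
        )
        return subject_map, zero

    if mode == "affine":
        if atlas_reference.shape != shape:
            raise GridMismatchError("affine mode requires a shared grid shape")
        moving = np.nan_to_num(subject_map.time_ms)

        def unpack(p):
            M = np.eye(4)
            M[:3, :3] = np.eye(3) + p[:9].reshape(3, 3)
            M[:3, 3] = p[9:]
            return M

        shift_vox, _, _ = phase_cross_correlation(
            _smooth(atlas_reference, smooth_sigma), _smooth(moving, smooth_sigma),
            upsample_factor=10, normalization=None,
        )
        p = np.zeros(12)
        p[9:] = np.asarray(shift_vox) * np.asarray(spacing)
        # Gauss-Newton on the smoothed image residual: 12 parameters with a
        # translation init is well-conditioned here, unlike direct search
        fixed_s = _smooth(atlas_reference, smooth_sigma)
        moving_s = _smooth(moving, smooth_sigma)

        def residual(q):
            return (resample(moving_s, unpack(q), spacing) - fixed_s).ravel()

        res = optimize.least_squares(
            residual, p, method="lm", diff_step=1e-4,
            max_nfev=maxfev, xtol=1e-12, ftol=1e-12,
        )
        if not np.isfinite(res.cost):
            raise RegistrationError("affine optimization diverged")
        matrix = unpack(res.x)
        warped = _resample_map(subject_map, matrix)
        return warped, _affine_displacement(matrix, shape, spacing)

    if mode == "plugin":
        if not plugin_cmd:
            raise KneeVBRError("plugin mode requires plugin_cmd")
        return _run_plugin(subject_map, atlas_reference, plugin_cmd)

    raise KneeVBRError(f"unknown registration mode {mode!r}")


def _run_plugin(
    subject_map: RelaxationMap,
    atlas_reference: np.ndarray,
    plugin_cmd: list[str],
) -> tuple[RelaxationMap, DeformationField]:
    """External-backend exchange contract.

    ``plugin_cmd`` entries may contain the placeholders ``{moving}``,
    ``{fixed}`` and ``{out}``.  The moving time map and the fixed reference
    are written as NIfTI; the executable must exit 0 and produce
    ``{out}_warped.nii`` (the map on the atlas grid) and ``{out}_disp.nii``
    (a 4D displacement field in mm, vector on the 4th axis).
    """
    import tempfile

    from . import io as kio

    with tempfile.TemporaryDirectory() as tmp:
        tmp = Path(tmp)
        moving_p = tmp / "moving.nii"
        fixed_p = tmp / "fixed.nii"
        out_prefix = tmp / "reg"
        kio.save_volume(np.nan_to_num(subject_map.time_ms),
                        subject_map.spacing_mm, moving_p)
        kio.save_volume(atlas_reference, subject_map.spacing_mm, fixed_p)
        cmd = [
            arg.format(moving=moving_p, fixed=fixed_p, out=out_prefix)
            for arg in plugin_cmd
        ]
        proc = subprocess.run(cmd, capture_output=True, text=True)
        if proc.returncode != 0:
            raise RegistrationError(
                f"registration plugin failed (exit {proc.returncode}): "
                f"stderr={proc.stderr.strip()[:500]!r}"
            )
        warped_p = Path(f"{out_prefix}_warped.nii")
        disp_p = Path(f"{out_prefix}_disp.nii")
        if not warped_p.exists() or not disp_p.exists():
            raise RegistrationError(
                f"plugin exited 0 but outputs missing: {warped_p.name}, "
                f"{disp_p.name}; stdout={proc.stdout.strip()[:200]!r}"
            )
        warped, _ = kio.load_volume(warped_p)
        disp, _ = kio.load_volume(disp_p)
    mask = warped > 0
    rmap = RelaxationMap(
        time_ms=np.where(mask, warped, np.nan), s0=np.zeros_like(warped),
        r_squared=np.where(mask, 1.0, np.nan), converged=mask, mask=mask,
        spacing_mm=subject_map.spacing_mm,
        meta={**subject_map.meta, "registration": "plugin"},
    )
    return rmap, DeformationField(displacement=disp,
                                  spacing_mm=subject_map.spacing_mm)
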