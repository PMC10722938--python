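"""NIfTI and tabular I/O.

All phantom volumes use a diagonal affine (voxel spacing on the diagonal,
zero origin).  Echo series are 4D NIfTI images with the echo index on the
4th dimension and the echo times stored in a JSON sidecar.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .core import CompartmentAtlas, EchoSeries, RelaxationMap
from .errors import KneeVBRError
from . import synthetic


def _affine(spacing) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


def save_volume(data: np.ndarray, spacing, path: str | Path) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float64), _affine(spacing))
    img.header.set_zooms(tuple(spacing) + ((1.0,) if data.ndim == 4 else ()))
    nib.save(img, str(path))
    return path


def load_volume(path: str | Path) -> tuple[np.ndarray, tuple[float, ...]]:
    try:
        img = nib.load(str(path))
    except Exception as exc:  # corrupt / missing file
        raise KneeVBRError(f"cannot read NIfTI {path}: {exc}") from exc
    data = np.asarray(img.dataobj, dtype=np.float64)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return data, spacing


def save_series(series: EchoSeries, path: str | Path) -> Path:
    path = Path(path)
    save_volume(series.data, series.spacing_mm, path)
    sidecar = path.with_suffix("").with_suffix(".json")
    sidecar.write_text(json.dumps({
        "echo_times_ms": list(series.echo_times_ms),
        "modality": series.modality,
        "meta": {k: v for k, v in series.meta.items()
                 if isinstance(v, (str, int, float, bool, list))},
    }, indent=1))
    return path


def load_series(path: str | Path) -> EchoSeries:
    path = Path(path)
    data, spacing = load_volume(path)
    if data.ndim != 4:
        raise KneeVBRError(f"{path} is not a 4D echo series")
    sidecar = path.with_suffix("").with_suffix(".json")
    if not sidecar.exists():
        raise KneeVBRError(f"missing echo-time sidecar {sidecar}")
    info = json.loads(sidecar.read_text())
    return EchoSeries(
        data=data, echo_times_ms=tuple(info["echo_times_ms"]),
        modality=info.get("modality", "t1rho"), spacing_mm=spacing,
        meta=info.get("meta", {}),
    )


def save_atlas(atlas: CompartmentAtlas, path: str | Path) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(atlas.labels.astype(np.int16), _affine(atlas.spacing_mm))
    nib.save(img, str(path))
    return path


def load_atlas(path: str | Path) -> CompartmentAtlas:
    data, spacing = load_volume(path)
    return CompartmentAtlas(labels=np.rint(data).astype(np.int16), spacing_mm=spacing)


def save_map(rmap: RelaxationMap, prefix: str | Path) -> list[Path]:
    """Write a relaxation map as <prefix>_{time,s0,rsq,mask}.nii + JSON report."""
    prefix = Path(prefix)
    paths = [
        save_volume(np.nan_to_num(rmap.time_ms), rmap.spacing_mm,
                    prefix.parent / f"{prefix.name}_time.nii"),
        save_volume(np.nan_to_num(rmap.s0), rmap.spacing_mm,
                    prefix.parent / f"{prefix.name}_s0.nii"),
        save_volume(np.nan_to_num(rmap.r_squared), rmap.spacing_mm,
                    prefix.parent / f"{prefix.name}_rsq.nii"),
        save_volume((rmap.mask & rmap.converged).astype(float), rmap.spacing_mm,
                    prefix.parent / f"{prefix.name}_mask.nii"),
    ]
    report = prefix.parent / f"{prefix.name}_fit.json"
    report.write_text(json.dumps({
        "n_mask": int(rmap.mask.sum()),
        "n_converged": int(rmap.converged.sum()),
        "meta": {k: v for k, v in rmap.meta.items()
                 if isinstance(v, (str, int, float, bool, list, tuple))},
    }, indent=1, default=list))
    paths.append(report)
    return paths


def load_map(prefix: str | Path) -> RelaxationMap:
    prefix = Path(prefix)
    time, spacing = load_volume(prefix.parent / f"{prefix.name}_time.nii")
    s0, _ = load_volume(prefix.parent / f"{prefix.name}_s0.nii")
    rsq, _ = load_volume(prefix.parent / f"{prefix.name}_rsq.nii")
    maskconv, _ = load_volume(prefix.parent / f"{prefix.name}_mask.nii")
    mask = maskconv > 0.5
    time = np.where(mask, time, np.nan)
    meta = {}
    report = prefix.parent / f"{prefix.name}_fit.json"
    if report.exists():
        meta = json.loads(report.read_text()).get("meta", {})
    return RelaxationMap(time_ms=time, s0=s0, r_squared=rsq,
                         converged=mask, mask=mask, spacing_mm=spacing, meta=meta)


def write_cohort(cohort: "synthetic.Cohort", out_dir: str | Path,
                 write_truth: bool = False) -> dict[str, Path]:
    """Write a cohort bundle to disk: atlas, per-knee echo series, records CSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    files: dict[str, Path] = {}
    files["atlas"] = save_atlas(cohort.atlas, out_dir / "atlas.nii")
    frame = synthetic.records_to_frame(cohort.records)
    csv = out_dir / "records.csv"
    frame.to_csv(csv, index=False)
    files["records"] = csv
    for (sid, modality), series in sorted(cohort.echoes.items()):
        p = out_dir / f"{sid}_{modality}.nii"
        save_series(series, p)
        files[f"{sid}_{modality}"] = p
    if write_truth:
        for rec, truth in zip(cohort.records, cohort.truths):
            for modality in ("t1rho", "t2"):
                p = out_dir / f"{rec.subject_id}_truth_{modality}.nii"
                save_volume(truth.modality_map(modality), truth.spacing_mm, p)
                files[f"{rec.subject_id}_truth_{modality}"] = p
    return files
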