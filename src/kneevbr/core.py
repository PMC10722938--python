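"""Shared data containers for the knee VBR pipeline.

Conventions used throughout the package:

* volumes are numpy arrays indexed (sagittal, coronal, axial); the sagittal
  slice index is axis 0;
* world coordinates are millimetres, voxel index * spacing (NIfTI affine is
  diagonal for all phantom volumes);
* 4D echo series put the echo index on the 4th axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Mapping

import numpy as np

from .errors import KneeVBRError

#: Atlas label table: integer label -> compartment short name.
LABEL_NAMES: dict[int, str] = {1: "LFC", 2: "LT", 3: "MFC", 4: "MT", 5: "TRO", 6: "PAT"}
NAME_TO_LABEL: dict[str, int] = {name: lab for lab, name in LABEL_NAMES.items()}

#: Broad anatomical groupings (femoral/tibial/patellar) used for thickness.
COMPARTMENT_GROUPS: dict[str, tuple[str, ...]] = {
    "femoral": ("MFC", "LFC", "TRO"),
    "tibial": ("MT", "LT"),
    "patellar": ("PAT",),
}

#: Default preparation-time schedules (ms) for the two modalities.
T1RHO_ECHO_TIMES_MS: tuple[float, ...] = (0.0, 10.0, 40.0, 80.0)
T2_ECHO_TIMES_MS: tuple[float, ...] = (0.0, 12.87, 25.69, 51.39)
DEFAULT_ECHO_TIMES: dict[str, tuple[float, ...]] = {
    "t1rho": T1RHO_ECHO_TIMES_MS,
    "t2": T2_ECHO_TIMES_MS,
}

MODALITIES = ("t1rho", "t2")


def _as_tuple(x, n: int | None = None) -> tuple:
    t = tuple(float(v) for v in np.atleast_1d(x))
    if n is not None and len(t) == 1:
        t = t * n
    return t


@dataclass
class EchoSeries:
    """A 4D multi-echo magnitude volume plus its ordered preparation times.

    ``data`` has shape (x, y, z, n_echoes); ``echo_times_ms`` is strictly
    increasing and non-negative.  Magnitude data are expected to be
    non-negative, but Gaussian-noise simulations may dip below zero; the
    fitting code handles that explicitly, so no hard check is made here.
    """

    data: np.ndarray
    echo_times_ms: tuple[float, ...]
    modality: str = "t1rho"
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.echo_times_ms = _as_tuple(self.echo_times_ms)
        self.spacing_mm = _as_tuple(self.spacing_mm, 3)
        if self.data.ndim != 4:
            raise KneeVBRError(f"echo series must be 4D, got {self.data.ndim}D")
        if self.data.shape[3] != len(self.echo_times_ms):
            raise KneeVBRError(
                f"{self.data.shape[3]} echoes in data but "
                f"{len(self.echo_times_ms)} echo times"
            )
        te = np.asarray(self.echo_times_ms)
        if len(te) == 0 or te[0] < 0 or np.any(np.diff(te) <= 0):
            raise KneeVBRError("echo times must be non-negative and strictly increasing")

    @property
    def n_echoes(self) -> int:
        return len(self.echo_times_ms)

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]


@dataclass
class RelaxationMap:
    """Per-voxel relaxation time (ms), amplitude and fit quality."""

    time_ms: np.ndarray
    s0: np.ndarray
    r_squared: np.ndarray
    converged: np.ndarray
    mask: np.ndarray
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        self.converged = np.asarray(self.converged, dtype=bool)
        self.spacing_mm = _as_tuple(self.spacing_mm, 3)
        shapes = {a.shape for a in (self.time_ms, self.s0, self.r_squared,
                                    self.converged, self.mask)}
        if len(shapes) != 1:
            raise KneeVBRError(f"inconsistent map shapes: {shapes}")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.mask.shape

    def fitted_mask(self) -> np.ndarray:
        """Voxels that were fitted, converged and carry a finite time."""
        return self.mask & self.converged & np.isfinite(self.time_ms)


@dataclass
class CompartmentAtlas:
    """Labeled reference-space volume housing the 6 cartilage compartments."""

    labels: np.ndarray
    label_names: Mapping[int, str] = field(default_factory=lambda: dict(LABEL_NAMES))
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise KneeVBRError("atlas labels must be integer-valued")
        self.spacing_mm = _as_tuple(self.spacing_mm, 3)
        present = set(int(v) for v in np.unique(self.labels)) - {0}
        expected = set(self.label_names)
        if present != expected:
            raise KneeVBRError(
                f"atlas must contain exactly labels {sorted(expected)}, "
                f"found {sorted(present)}"
            )

    @property
    def foreground(self) -> np.ndarray:
        return self.labels > 0

    def name_of(self, label: int) -> str:
        return self.label_names[label]

    def label_of(self, name: str) -> int:
        for lab, n in self.label_names.items():
            if n == name:
                return lab
        raise KeyError(name)


@dataclass
class SubjectRecord:
    """Covariates, MRI abnormality grades and KOOS outcomes for one knee."""

    subject_id: str
    knee_side: str  # "left" | "right"
    age: float
    sex: str  # "F" | "M"
    bmi: float
    site: str
    grade_bone_marrow_edema: int = 0
    grade_patellar_tendinosis: int = 0
    grade_quadriceps_tendinosis: int = 0
    koos_items: dict[str, list[int]] = field(default_factory=dict)
    koos_subscales: dict[str, float] = field(default_factory=dict)
    player_id: str = ""

    GRADE_RANGES = {
        "grade_bone_marrow_edema": (0, 2),
        "grade_patellar_tendinosis": (0, 3),
        "grade_quadriceps_tendinosis": (0, 1),
    }

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.GRADE_RANGES.items():
            g = getattr(self, name)
            if not lo <= int(g) <= hi:
                raise KneeVBRError(f"{name}={g} outside [{lo}, {hi}]")
        for sub, val in self.koos_subscales.items():
            if np.isfinite(val) and not 0.0 <= val <= 100.0:
                raise KneeVBRError(f"KOOS {sub}={val} outside [0, 100]")
        if not self.player_id:
            self.player_id = self.subject_id
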