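"""Synthetic knee-phantom cohorts in atlas space.

Generates everything a desk-scale VBR run needs: a 6-compartment atlas,
ground-truth relaxation fields with injected group effects, noisy multi-echo
signals, and per-knee records (covariates, abnormality grades, KOOS items and
subscales) with known effect sizes.

All randomness flows from a single integer seed through
:class:`numpy.random.SeedSequence`, so identical inputs reproduce every
artifact bit-exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core import (
    DEFAULT_ECHO_TIMES,
    LABEL_NAMES,
    NAME_TO_LABEL,
    CompartmentAtlas,
    EchoSeries,
    SubjectRecord,
)
from .errors import GeometryError, KneeVBRError

# --------------------------------------------------------------------------- #
# phantom geometry
# --------------------------------------------------------------------------- #


@dataclass(frozen=True)
class Shell:
    """Parametric cartilage-shell description in world millimetres.

    ``kind="slab"``: an axis-aligned box centred at ``center_mm`` with
    half-extents ``radii_mm`` except along ``axis`` where the half-extent is
    ``thickness_mm / 2``.

    ``kind="annulus"``: a cylindrical shell whose axis runs along ``axis``
    through ``center_mm``; in-plane radial distance lies in
    ``[inner_radius_mm, inner_radius_mm + thickness_mm]`` and the extent along
    the cylinder axis is ``radii_mm[axis]`` on each side.
    """

    center_mm: tuple[float, float, float]
    radii_mm: tuple[float, float, float]
    thickness_mm: float
    kind: str = "slab"
    axis: int = 2
    inner_radius_mm: float = 0.0

    def rasterize(self, grid_shape: Sequence[int],
                  spacing_mm: Sequence[float]) -> np.ndarray:
        coords = np.meshgrid(
            *[np.arange(n) * s for n, s in zip(grid_shape, spacing_mm)],
            indexing="ij",
        )
        d = [c - cc for c, cc in zip(coords, self.center_mm)]
        if self.kind == "slab":
            half = list(self.radii_mm)
            half[self.axis] = self.thickness_mm / 2.0
            m = np.ones(tuple(grid_shape), dtype=bool)
            for di, hi in zip(d, half):
                m &= np.abs(di) <= hi
            return m
        if self.kind == "annulus":
            inplane = [d[i] for i in range(3) if i != self.axis]
            rho = np.hypot(inplane[0], inplane[1])
            m = (rho >= self.inner_radius_mm) & (
                rho <= self.inner_radius_mm + self.thickness_mm
            )
            m &= np.abs(d[self.axis]) <= self.radii_mm[self.axis]
            return m
        raise GeometryError(f"unknown shell kind {self.kind!r}")


@dataclass(frozen=True)
class PhantomSpec:
    """Grid, spacing and per-compartment shell geometry of a phantom."""

    grid_shape: tuple[int, int, int] = (32, 32, 32)
    voxel_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    compartment_geometry: Mapping[str, Shell] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        geom = dict(self.compartment_geometry) or _default_geometry(
            self.grid_shape, self.voxel_spacing
        )
        object.__setattr__(self, "compartment_geometry", geom)
        missing = set(NAME_TO_LABEL) - set(geom)
        if missing:
            raise GeometryError(f"missing compartments: {sorted(missing)}")
        for name, shell in geom.items():
            normal_sp = (
                self.voxel_spacing[shell.axis]
                if shell.kind == "slab"
                else max(sp for i, sp in enumerate(self.voxel_spacing) if i != shell.axis)
            )
            if shell.thickness_mm < 2.0 * normal_sp:
                raise GeometryError(
                    f"{name}: thickness {shell.thickness_mm} mm < 2 voxels "
                    f"({2 * normal_sp} mm) along its normal"
                )


def _default_geometry(grid_shape, spacing) -> dict[str, Shell]:
    """Six disjoint slabs stacked along the axial axis."""
    nx, ny, nz = grid_shape
    sx, sy, sz = spacing
    cx, cy = (nx - 1) * sx / 2.0, (ny - 1) * sy / 2.0
    rx, ry = nx * sx * 0.38, ny * sy * 0.38
    thick = max(2, min(4, nz // 8)) * sz  # 6 slabs + gaps must fit along z
    step = (nz * sz - thick) / 6.0
    geom = {}
    for i, label in enumerate(sorted(LABEL_NAMES)):
        cz = step * i + step / 2.0 + thick / 2.0
        geom[LABEL_NAMES[label]] = Shell(
            center_mm=(cx, cy, cz), radii_mm=(rx, ry, 0.0),
            thickness_mm=thick, kind="slab", axis=2,
        )
    return geom


def generate_atlas(spec: PhantomSpec) -> CompartmentAtlas:
    """Rasterize the spec's shells into a labeled compartment volume.

    Raises :class:`GeometryError` naming the offending pair if two shells
    share voxels.  Purely deterministic: the same spec always yields the
    same volume.
    """
    labels = np.zeros(spec.grid_shape, dtype=np.int16)
    masks: dict[str, np.ndarray] = {}
    for name in sorted(spec.compartment_geometry, key=lambda n: NAME_TO_LABEL[n]):
        shell = spec.compartment_geometry[name]
        m = shell.rasterize(spec.grid_shape, spec.voxel_spacing)
        if not m.any():
            raise GeometryError(f"compartment {name} rasterizes to zero voxels")
        for other, om in masks.items():
            if np.any(m & om):
                raise GeometryError(f"shells overlap: {other} and {name}")
        masks[name] = m
        labels[m] = NAME_TO_LABEL[name]
    return CompartmentAtlas(labels=labels, spacing_mm=spec.voxel_spacing)


# --------------------------------------------------------------------------- #
# ground-truth fields and effects
# --------------------------------------------------------------------------- #

#: Baseline per-compartment (T1rho, T2) means in ms.
DEFAULT_COMPARTMENT_MEANS: dict[str, tuple[float, float]] = {
    "LFC": (45.0, 35.0),
    "LT": (42.0, 33.0),
    "MFC": (46.0, 36.0),
    "MT": (40.0, 32.0),
    "TRO": (48.0, 38.0),
    "PAT": (50.0, 40.0),
}


@dataclass(frozen=True)
class EffectSpec:
    """A known, recoverable group effect injected into the phantom.

    ``true_percentage_difference`` follows the APD sign convention used by
    the statistics module: reference-group mean minus affected-group mean,
    relative to the reference mean, in percent.  A negative value therefore
    means *higher* relaxation times in knees with the abnormality.
    """

    target_compartments: tuple[str, ...] = ("MT",)
    affected_fraction_of_compartment: float = 1.0
    group_variable: str = "grade_patellar_tendinosis"
    true_percentage_difference: float = 0.0
    between_subject_sd_pct: float = 0.0
    outcome_slope: float = 0.0  # KOOS units per ms of regional mean deviation
    outcome_noise_sd: float = 0.0  # KOOS units
    outcome_subscale: str = "Symptoms"
    modalities: tuple[str, ...] = ("t1rho", "t2")

    def __post_init__(self) -> None:
        if not 0.0 <= self.affected_fraction_of_compartment <= 1.0:
            raise KneeVBRError("affected_fraction_of_compartment must be in [0, 1]")
        if not np.isfinite(self.true_percentage_difference):
            raise KneeVBRError("true_percentage_difference must be finite")


@dataclass
class TruthField:
    """Per-voxel ground-truth T1rho/T2 (ms) and equilibrium amplitude."""

    t1rho_ms: np.ndarray
    t2_ms: np.ndarray
    s0: np.ndarray
    mask: np.ndarray
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def modality_map(self, modality: str) -> np.ndarray:
        if modality == "t1rho":
            return self.t1rho_ms
        if modality == "t2":
            return self.t2_ms
        raise KneeVBRError(f"unknown modality {modality!r}")


def affected_mask(atlas: CompartmentAtlas, effect: EffectSpec) -> np.ndarray:
    """Deterministic sub-region of the target compartments carrying the effect.

    The first ``affected_fraction`` of each target compartment's voxels in
    lexicographic index order — spatially coherent and identical across
    subjects, as a real focal lesion pattern would be.
    """
    out = np.zeros(atlas.labels.shape, dtype=bool)
    for name in effect.target_compartments:
        if name not in NAME_TO_LABEL:
            raise KneeVBRError(f"unknown compartment label {name!r} in effect")
        idx = np.argwhere(atlas.labels == NAME_TO_LABEL[name])
        n_aff = int(round(effect.affected_fraction_of_compartment * len(idx)))
        for i, j, k in idx[:n_aff]:
            out[i, j, k] = True
    return out


def subject_is_affected(subject: SubjectRecord, effect: EffectSpec,
                        threshold: int = 1) -> bool:
    return int(getattr(subject, effect.group_variable)) >= threshold


def generate_truth(
    atlas: CompartmentAtlas,
    compartment_means: Mapping[str, tuple[float, float]] | None = None,
    effect: EffectSpec | None = None,
    subject: SubjectRecord | None = None,
    rng: np.random.Generator | int | None = None,
    s0: float = 100.0,
) -> TruthField:
    """Build a subject's ground-truth relaxation fields.

    Each compartment's value is its configured mean times a per-subject,
    per-compartment multiplicative offset ``N(1, sd_pct/100)``.  If the
    subject carries the effect's grade (>= 1), voxels inside the affected
    sub-region additionally have their mean scaled by
    ``1 - true_percentage_difference / 100``.
    """
    means = dict(compartment_means or DEFAULT_COMPARTMENT_MEANS)
    for name, (a, b) in means.items():
        if a <= 0 or b <= 0:
            raise KneeVBRError(f"compartment means must be positive ({name})")
    rng = np.random.default_rng(rng)
    sd = (effect.between_subject_sd_pct if effect is not None else 0.0) / 100.0

    t1rho = np.zeros(atlas.labels.shape)
    t2 = np.zeros(atlas.labels.shape)
    for lab in sorted(LABEL_NAMES):
        name = LABEL_NAMES[lab]
        m = atlas.labels == lab
        factor = 1.0 + rng.normal(0.0, sd)
        t1rho[m] = means[name][0] * factor
        t2[m] = means[name][1] * factor

    if effect is not None and subject is not None and subject_is_affected(subject, effect):
        scale = 1.0 - effect.true_percentage_difference / 100.0
        aff = affected_mask(atlas, effect)
        if "t1rho" in effect.modalities:
            t1rho[aff] *= scale
        if "t2" in effect.modalities:
            t2[aff] *= scale

    mask = atlas.foreground
    s0_map = np.where(mask, float(s0), 0.0)
    return TruthField(t1rho_ms=t1rho, t2_ms=t2, s0=s0_map, mask=mask,
                      spacing_mm=atlas.spacing_mm)


# --------------------------------------------------------------------------- #
# echo-signal simulation
# --------------------------------------------------------------------------- #


def simulate_echo_series(
    truth: TruthField,
    modality: str = "t1rho",
    echo_times_ms: Sequence[float] | None = None,
    noise_model: str = "gaussian",
    noise_sd: float = 0.0,
    rng: np.random.Generator | int | None = None,
) -> EchoSeries:
    """Mono-exponential signals ``S0 * exp(-t / T)`` plus magnitude noise.

    Background voxels (outside the cartilage mask) contain noise only.
    ``rician`` takes the magnitude of a complex Gaussian perturbation,
    ``gaussian`` adds real noise directly (and may produce small negative
    magnitudes, handled downstream by the fitters).
    """
    if echo_times_ms is None:
        echo_times_ms = DEFAULT_ECHO_TIMES[modality]
    te = np.asarray(echo_times_ms, dtype=float)
    if len(te) < 3:
        raise KneeVBRError("need at least 3 echoes for a 2-parameter fit")
    if te[0] < 0 or np.any(np.diff(te) <= 0):
        raise KneeVBRError("echo times must be non-negative and strictly increasing")

    T = truth.modality_map(modality)
    with np.errstate(divide="ignore", invalid="ignore"):
        decay = np.exp(-te[None, None, None, :] / T[..., None])
    signal = truth.s0[..., None] * np.where(truth.mask[..., None], decay, 0.0)
    signal = np.nan_to_num(signal, nan=0.0, posinf=0.0, neginf=0.0)

    if noise_sd > 0:
        rng = np.random.default_rng(rng)
        if noise_model == "gaussian":
            signal = signal + rng.normal(0.0, noise_sd, signal.shape)
        elif noise_model == "rician":
            n1 = rng.normal(0.0, noise_sd, signal.shape)
            n2 = rng.normal(0.0, noise_sd, signal.shape)
            signal = np.hypot(signal + n1, n2)
        else:
            raise KneeVBRError(f"unknown noise model {noise_model!r}")

    return EchoSeries(
        data=signal, echo_times_ms=tuple(te), modality=modality,
        spacing_mm=truth.spacing_mm,
        meta={"noise_model": noise_model, "noise_sd": float(noise_sd)},
    )


# --------------------------------------------------------------------------- #
# records: grades, covariates, KOOS
# --------------------------------------------------------------------------- #

#: Default per-grade category probabilities (cohort marginal frequencies).
DEFAULT_GRADE_PREVALENCE: dict[str, tuple[float, ...]] = {
    "grade_bone_marrow_edema": (62 / 75, 11 / 75, 2 / 75),
    "grade_patellar_tendinosis": (0.373, 0.427, 0.187, 0.013),
    "grade_quadriceps_tendinosis": (46 / 75, 29 / 75),
}

#: Standard KOOS instrument: items per subscale.
KOOS_ITEM_COUNTS: dict[str, int] = {
    "Symptoms": 7, "Pain": 9, "ADL": 17, "Sport/Rec": 5, "QOL": 4,
}

#: Default generator calibration: (mean, sd) per subscale on the 0-100 scale.
DEFAULT_KOOS_TARGETS: dict[str, tuple[float, float]] = {
    "Symptoms": (87.72, 11.61),
    "Pain": (90.73, 9.55),
    "ADL": (96.11, 5.26),
    "Sport/Rec": (84.32, 18.67),
    "QOL": (83.26, 19.78),
}

KOOS_SUBSCALES = tuple(KOOS_ITEM_COUNTS)


@dataclass(frozen=True)
class CovariateModel:
    """Simple parametric sampling model for per-knee covariates."""

    age_mean: float = 18.69
    age_sd: float = 0.84
    bmi_mean: float = 23.78
    bmi_sd: float = 2.56
    p_female: float = 40 / 75
    site_probs: tuple[float, ...] = (1 / 3, 1 / 3, 1 / 3)
    site_names: tuple[str, ...] = ("site_A", "site_B", "site_C")


def score_koos(items: Mapping[str, Sequence[int | None]]) -> dict[str, float]:
    """Score KOOS subscales from ordinal item responses.

    ``subscale = 100 - mean(items) * 25`` so 0 items (no problems) -> 100 and
    all-4 items -> 0.  If more than half of a subscale's items are missing
    (``None``/NaN), the subscale is undefined and returned as NaN.
    """
    scores: dict[str, float] = {}
    for sub, responses in items.items():
        vals = [r for r in responses if r is not None and np.isfinite(r)]
        for r in vals:
            if not 0 <= r <= 4:
                raise KneeVBRError(f"KOOS item response {r} outside 0..4")
        if len(responses) == 0 or len(vals) < len(responses) / 2.0:
            scores[sub] = float("nan")
        else:
            scores[sub] = 100.0 - float(np.mean(vals)) * 25.0
    return scores


def _beta_params(mean: float, sd: float) -> tuple[float, float]:
    m, v = mean / 100.0, (sd / 100.0) ** 2
    nu = m * (1 - m) / v - 1.0
    if nu <= 0:
        raise KneeVBRError(f"KOOS target mean={mean}, sd={sd} not representable")
    return m * nu, (1 - m) * nu


def _subscale_to_items(value: float, n_items: int,
                       rng: np.random.Generator) -> list[int]:
    """Decompose a 0-100 subscale value into n ordinal items scoring back to
    (approximately, via rounding to the item grid) the same value."""
    total = int(round((100.0 - value) / 25.0 * n_items))
    total = min(max(total, 0), 4 * n_items)
    q, r = divmod(total, n_items)
    items = np.array([q + 1] * r + [q] * (n_items - r))
    rng.shuffle(items)
    return [int(v) for v in items]


def _draw_koos(rng: np.random.Generator,
               targets: Mapping[str, tuple[float, float]]) -> dict[str, float]:
    out = {}
    for sub in KOOS_SUBSCALES:
        a, b = _beta_params(*targets[sub])
        out[sub] = 100.0 * rng.beta(a, b)
    return out


def simulate_records(
    n_knees: int,
    grade_prevalence: Mapping[str, Sequence[float]] | None = None,
    covariate_model: CovariateModel | None = None,
    koos_targets: Mapping[str, tuple[float, float]] | None = None,
    rng: np.random.Generator | int | None = None,
) -> list[SubjectRecord]:
    """Draw per-knee records: grades, covariates and KOOS outcomes.

    Grade variables are sampled independently at their marginal prevalences;
    KOOS subscales are drawn from Beta distributions moment-matched to the
    configured (mean, sd) targets and then decomposed into ordinal items.
    """
    prevalence = dict(DEFAULT_GRADE_PREVALENCE)
    if grade_prevalence:
        prevalence.update(grade_prevalence)
    for var, probs in prevalence.items():
        if abs(sum(probs) - 1.0) > 1e-8:
            raise KneeVBRError(f"prevalence for {var} sums to {sum(probs)}, not 1")
    cov = covariate_model or CovariateModel()
    targets = dict(DEFAULT_KOOS_TARGETS)
    if koos_targets:
        targets.update(koos_targets)
    rng = np.random.default_rng(rng)

    records = []
    for i in range(n_knees):
        grades = {
            var: int(rng.choice(len(probs), p=np.asarray(probs)))
            for var, probs in prevalence.items()
        }
        subscales = _draw_koos(rng, targets)
        items = {
            sub: _subscale_to_items(subscales[sub], KOOS_ITEM_COUNTS[sub], rng)
            for sub in KOOS_SUBSCALES
        }
        rec = SubjectRecord(
            subject_id=f"K{i:04d}",
            player_id=f"P{i // 2:04d}",
            knee_side="left" if i % 2 == 0 else "right",
            age=float(rng.normal(cov.age_mean, cov.age_sd)),
            sex="F" if rng.random() < cov.p_female else "M",
            bmi=float(rng.normal(cov.bmi_mean, cov.bmi_sd)),
            site=str(rng.choice(cov.site_names, p=np.asarray(cov.site_probs))),
            koos_items=items,
            koos_subscales=score_koos(items),
            **grades,
        )
        records.append(rec)
    return records


def records_to_frame(records: Sequence[SubjectRecord]) -> pd.DataFrame:
    """Flatten records into a one-row-per-knee table (CSV schema).

    Columns: identifiers, covariates, the three grade variables,
    ``koos_<sub>`` subscale scores and ``koos_<sub>_q<i>`` item responses.
    """
    rows = []
    for r in records:
        row: dict[str, object] = {
            "subject_id": r.subject_id, "player_id": r.player_id,
            "knee_side": r.knee_side, "age": r.age, "sex": r.sex,
            "bmi": r.bmi, "site": r.site,
            "grade_bone_marrow_edema": r.grade_bone_marrow_edema,
            "grade_patellar_tendinosis": r.grade_patellar_tendinosis,
            "grade_quadriceps_tendinosis": r.grade_quadriceps_tendinosis,
        }
        for sub in KOOS_SUBSCALES:
            key = sub.replace("/", "")
            row[f"koos_{key}"] = r.koos_subscales.get(sub, float("nan"))
        for sub in KOOS_SUBSCALES:
            key = sub.replace("/", "")
            for qi, v in enumerate(r.koos_items.get(sub, []), start=1):
                row[f"koos_{key}_q{qi}"] = v
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_records(frame: pd.DataFrame) -> list[SubjectRecord]:
    records = []
    for _, row in frame.iterrows():
        items: dict[str, list[int]] = {}
        subscales: dict[str, float] = {}
        for sub in KOOS_SUBSCALES:
            key = sub.replace("/", "")
            if f"koos_{key}" in row:
                subscales[sub] = float(row[f"koos_{key}"])
            qcols = sorted(
                (c for c in frame.columns if c.startswith(f"koos_{key}_q")),
                key=lambda c: int(c.rsplit("q", 1)[1]),
            )
            if qcols:
                items[sub] = [int(row[c]) for c in qcols]
        records.append(SubjectRecord(
            subject_id=str(row["subject_id"]),
            player_id=str(row.get("player_id", row["subject_id"])),
            knee_side=str(row["knee_side"]),
            age=float(row["age"]), sex=str(row["sex"]),
            bmi=float(row["bmi"]), site=str(row["site"]),
            grade_bone_marrow_edema=int(row["grade_bone_marrow_edema"]),
            grade_patellar_tendinosis=int(row["grade_patellar_tendinosis"]),
            grade_quadriceps_tendinosis=int(row["grade_quadriceps_tendinosis"]),
            koos_items=items, koos_subscales=subscales,
        ))
    return records


# --------------------------------------------------------------------------- #
# full cohort bundles
# --------------------------------------------------------------------------- #


@dataclass
class Cohort:
    """In-memory phantom cohort: atlas, records, truths and echo series."""

    atlas: CompartmentAtlas
    records: list[SubjectRecord]
    truths: list[TruthField]
    echoes: dict[tuple[str, str], EchoSeries]  # (subject_id, modality) -> series
    seed: int = 0

    @property
    def n_knees(self) -> int:
        return len(self.records)

    def series(self, subject_id: str, modality: str) -> EchoSeries:
        return self.echoes[(subject_id, modality)]


def _apply_outcome_coupling(
    record: SubjectRecord,
    truth: TruthField,
    atlas: CompartmentAtlas,
    effects: Sequence[EffectSpec],
    means: Mapping[str, tuple[float, float]],
    rng: np.random.Generator,
) -> SubjectRecord:
    """Couple KOOS subscales to regional mean relaxation deviations."""
    subscales = dict(record.koos_subscales)
    items = dict(record.koos_items)
    changed = False
    for eff in effects:
        if eff.outcome_slope == 0.0 and eff.outcome_noise_sd == 0.0:
            continue
        modality = eff.modalities[0]
        col = 0 if modality == "t1rho" else 1
        region = np.isin(
            atlas.labels, [NAME_TO_LABEL[n] for n in eff.target_compartments]
        )
        regional_mean = float(truth.modality_map(modality)[region].mean())
        base = float(np.mean([means[n][col] for n in eff.target_compartments]))
        dev = regional_mean - base
        sub = eff.outcome_subscale
        v = subscales[sub] - eff.outcome_slope * dev
        if eff.outcome_noise_sd > 0:
            v += rng.normal(0.0, eff.outcome_noise_sd)
        subscales[sub] = float(np.clip(v, 0.0, 100.0))
        items[sub] = _subscale_to_items(subscales[sub], KOOS_ITEM_COUNTS[sub], rng)
        changed = True
    if not changed:
        return record
    rec = replace(record, koos_items=items, koos_subscales={})
    rec.koos_subscales = score_koos(items)
    return rec


def generate_cohort(
    n_knees: int,
    atlas: CompartmentAtlas | None = None,
    compartment_means: Mapping[str, tuple[float, float]] | None = None,
    effects: Sequence[EffectSpec] = (),
    grade_prevalence: Mapping[str, Sequence[float]] | None = None,
    covariate_model: CovariateModel | None = None,
    koos_targets: Mapping[str, tuple[float, float]] | None = None,
    noise_model: str = "gaussian",
    noise_sd: float = 1.0,
    modalities: Sequence[str] = ("t1rho", "t2"),
    echo_times: Mapping[str, Sequence[float]] | None = None,
    seed: int = 0,
    s0: float = 100.0,
    records: list[SubjectRecord] | None = None,
) -> Cohort:
    """Generate a complete, seeded phantom cohort.

    Grades/covariates/KOOS are drawn per knee; ground-truth fields receive
    the configured effects for affected knees plus between-subject offsets;
    multi-echo signals are simulated with the requested noise model; and any
    outcome coupling (``outcome_slope``) shifts the targeted KOOS subscale by
    the knee's regional mean relaxation deviation.
    """
    if atlas is None:
        atlas = generate_atlas(PhantomSpec(seed=seed))
    means = dict(compartment_means or DEFAULT_COMPARTMENT_MEANS)
    ss = np.random.SeedSequence(seed)
    rec_seed, *knee_seeds = ss.spawn(1 + n_knees)
    if records is None:
        records = simulate_records(
            n_knees, grade_prevalence, covariate_model, koos_targets,
            rng=np.random.default_rng(rec_seed),
        )
    else:
        records = list(records)
        if len(records) != n_knees:
            raise KneeVBRError(f"{len(records)} records supplied for {n_knees} knees")

    # Between-subject variation: use the max sd over effects so a cohort with
    # a single effect spec behaves as documented.
    sd_pct = max((e.between_subject_sd_pct for e in effects), default=0.0)
    base_effect = EffectSpec(between_subject_sd_pct=sd_pct,
                             true_percentage_difference=0.0)

    truths: list[TruthField] = []
    echoes: dict[tuple[str, str], EchoSeries] = {}
    for i, rec in enumerate(records):
        krng = np.random.default_rng(knee_seeds[i])
        truth = generate_truth(atlas, means, base_effect, rec, rng=krng, s0=s0)
        for eff in effects:
            if eff.true_percentage_difference != 0.0 and subject_is_affected(rec, eff):
                scale = 1.0 - eff.true_percentage_difference / 100.0
                aff = affected_mask(atlas, eff)
                if "t1rho" in eff.modalities:
                    truth.t1rho_ms[aff] *= scale
                if "t2" in eff.modalities:
                    truth.t2_ms[aff] *= scale
        records[i] = _apply_outcome_coupling(rec, truth, atlas, effects, means, krng)
        truths.append(truth)
        for modality in modalities:
            te = (echo_times or {}).get(modality) if echo_times else None
            echoes[(rec.subject_id, modality)] = simulate_echo_series(
                truth, modality, te, noise_model, noise_sd, rng=krng,
            )
    return Cohort(atlas=atlas, records=records, truths=truths,
                  echoes=echoes, seed=seed)
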