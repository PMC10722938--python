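"""Voxel-wise statistical parametric mapping in atlas space.

Group contrasts are per-voxel OLS fits of relaxation time on a binary
abnormality indicator plus covariates (age, sex, BMI, acquisition site, and
optionally cartilage thickness), with a two-sided t-test on the group
coefficient.  Correlation contrasts are Pearson partial correlations of the
voxel value with a continuous outcome after residualizing both on the
covariates.

Sign convention (locked throughout): the reported percentage difference is
``100 * (mean_without - mean_with) / mean_without`` using covariate-adjusted
group means, so a NEGATIVE value means HIGHER relaxation times in knees WITH
the abnormality.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy import stats as sps

from .core import LABEL_NAMES, CompartmentAtlas, RelaxationMap, SubjectRecord
from .errors import DesignError, GridMismatchError, KneeVBRError

log = logging.getLogger(__name__)

DEFAULT_COVARIATES = ("age", "sex", "bmi", "site")
_DEGENERATE_RTOL = 1e-18  # catches exact-zero residuals, not tiny real noise


# --------------------------------------------------------------------------- #
# cohort stack
# --------------------------------------------------------------------------- #


@dataclass
class CohortStack:
    """Subject x voxel matrix of atlas-space relaxation values (ms)."""

    values: np.ndarray  # (n_subjects, n_voxels); NaN where a subject lacks a voxel
    common_mask: np.ndarray  # 3D bool
    subjects: list[SubjectRecord]
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.common_mask.shape

    def to_volume(self, flat: np.ndarray, fill: float = np.nan) -> np.ndarray:
        vol = np.full(self.common_mask.shape, fill, dtype=float)
        vol[self.common_mask] = flat
        return vol


def _record_has_covariates(rec: SubjectRecord) -> bool:
    return (
        np.isfinite(rec.age) and np.isfinite(rec.bmi)
        and rec.sex in ("F", "M") and bool(rec.site)
    )


def build_cohort_stack(
    maps: Sequence[RelaxationMap],
    records: Sequence[SubjectRecord],
    min_coverage_fraction: float = 1.0,
    quality_masks: Sequence[np.ndarray] | None = None,
    n_covariates_hint: int = 0,
) -> CohortStack:
    """Stack per-subject atlas-space maps into a (subject x voxel) matrix.

    ``common_mask`` keeps voxels fitted in at least ``min_coverage_fraction``
    of the retained subjects.  Subjects with missing covariates are excluded
    with a logged reason.
    """
    if len(maps) != len(records):
        raise KneeVBRError(f"{len(maps)} maps but {len(records)} records")
    if not maps:
        raise KneeVBRError("empty cohort")
    shape = maps[0].grid_shape
    for i, m in enumerate(maps):
        if m.grid_shape != shape:
            raise GridMismatchError(
                f"map {i} grid {m.grid_shape} != atlas grid {shape}")

    keep_maps, keep_recs, keep_q = [], [], []
    for i, (m, r) in enumerate(zip(maps, records)):
        if not _record_has_covariates(r):
            log.warning("excluding %s: missing covariates", r.subject_id)
            continue
        keep_maps.append(m)
        keep_recs.append(r)
        keep_q.append(None if quality_masks is None else quality_masks[i])
    n = len(keep_recs)
    if n < 4 + n_covariates_hint:
        raise DesignError(
            f"only {n} usable subjects; need >= {4 + n_covariates_hint} "
            f"for an identifiable model")

    fitted = []
    for m, q in zip(keep_maps, keep_q):
        fm = m.fitted_mask()
        if q is not None:
            fm = fm & np.asarray(q, bool)
        fitted.append(fm)
    coverage = np.mean(np.stack(fitted), axis=0)
    common = coverage >= min_coverage_fraction - 1e-12
    common &= np.stack(fitted).any(axis=0)

    values = np.full((n, int(common.sum())), np.nan)
    for i, (m, fm) in enumerate(zip(keep_maps, fitted)):
        vox_ok = fm[common]
        v = m.time_ms[common]
        values[i] = np.where(vox_ok, v, np.nan)
    return CohortStack(values=values, common_mask=common, subjects=keep_recs,
                       spacing_mm=maps[0].spacing_mm)


# --------------------------------------------------------------------------- #
# designs
# --------------------------------------------------------------------------- #


def resolve_field(records: Sequence[SubjectRecord], name: str) -> np.ndarray:
    """Resolve a per-subject numeric vector by field name.

    Accepts record attributes (``age``, ``grade_*``...), ``koos_<Subscale>``
    subscale scores, and ``koos_<Subscale>_q<i>`` single items.
    """
    def available() -> list[str]:
        fields = ["age", "bmi", "grade_bone_marrow_edema",
                  "grade_patellar_tendinosis", "grade_quadriceps_tendinosis"]
        r0 = records[0]
        fields += [f"koos_{s.replace('/', '')}" for s in r0.koos_subscales]
        return fields

    if hasattr(records[0], name):
        return np.asarray([float(getattr(r, name)) for r in records])
    if name.startswith("koos_"):
        rest = name[5:]
        if "_q" in rest:
            sub_key, qn = rest.rsplit("_q", 1)
            for sub in records[0].koos_items:
                if sub.replace("/", "") == sub_key:
                    return np.asarray(
                        [float(r.koos_items[sub][int(qn) - 1]) for r in records])
        for sub in records[0].koos_subscales:
            if sub.replace("/", "") == rest:
                return np.asarray([float(r.koos_subscales[sub]) for r in records])
    raise KneeVBRError(
        f"unknown field {name!r}; available fields include {available()}")


def design_matrix(
    records: Sequence[SubjectRecord],
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    extra: Mapping[str, np.ndarray] | None = None,
) -> tuple[np.ndarray, list[str]]:
    """Intercept + covariate columns (site one-hot with first level as
    reference; sex binary, female = 1).  Single-site cohorts drop the site
    column with a log message."""
    n = len(records)
    cols: list[np.ndarray] = [np.ones(n)]
    names = ["intercept"]
    for cov in covariates:
        if cov == "sex":
            cols.append(np.asarray([1.0 if r.sex == "F" else 0.0 for r in records]))
            names.append("sex_F")
        elif cov == "site":
            sites = sorted({r.site for r in records})
            if len(sites) < 2:
                log.info("single-site cohort: dropping site covariate")
                continue
            for s in sites[1:]:
                cols.append(np.asarray([1.0 if r.site == s else 0.0
                                        for r in records]))
                names.append(f"site_{s}")
        else:
            cols.append(resolve_field(records, cov))
            names.append(cov)
    for name, vec in (extra or {}).items():
        cols.append(np.asarray(vec, dtype=float))
        names.append(name)
    return np.column_stack(cols), names


def _check_full_rank(X: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        collinear = []
        for j in range(1, X.shape[1]):
            others = np.delete(X, j, axis=1)
            beta, res, *_ = np.linalg.lstsq(others, X[:, j], rcond=None)
            resid = X[:, j] - others @ beta
            if np.sum(resid**2) < 1e-10 * (np.sum(X[:, j] ** 2) + 1.0):
                collinear.append(names[j])
        raise DesignError(
            f"design matrix rank {rank} < {X.shape[1]} columns; "
            f"collinear columns: {collinear or names}")


# --------------------------------------------------------------------------- #
# SPM results
# --------------------------------------------------------------------------- #


@dataclass
class Cluster:
    cluster_id: int
    size: int
    indices: np.ndarray  # (size, 3)
    mean_p: float


@dataclass
class SPMResult:
    """Voxel-wise effect and p maps plus significance bookkeeping."""

    effect: np.ndarray  # 3D; signed %-difference or partial r, NaN outside mask
    p: np.ndarray  # 3D in (0, 1]; NaN outside mask
    common_mask: np.ndarray
    analysis_kind: str  # "difference" | "correlation"
    covariates_used: list[str] = field(default_factory=list)
    sig_mask: np.ndarray | None = None
    clusters: list[Cluster] = field(default_factory=list)
    alpha: float | None = None
    meta: dict = field(default_factory=dict)


def _solve_ols(X: np.ndarray, Y: np.ndarray, j: int):
    """OLS of each Y column on X; t-test on coefficient j.

    Returns (beta (k, V), t, p, degenerate).  Zero-residual voxels are
    flagged degenerate with p = 1."""
    n, k = X.shape
    dfree = n - k
    if dfree < 1:
        raise DesignError(f"{n} subjects with {k} design columns: no residual df")
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ (X.T @ Y)
    resid = Y - X @ beta
    ss_res = np.sum(resid**2, axis=0)
    scale = np.sum(Y**2, axis=0) + 1.0
    degenerate = ss_res <= _DEGENERATE_RTOL * scale
    sigma2 = ss_res / dfree
    se = np.sqrt(np.maximum(sigma2 * xtx_inv[j, j], 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta[j] / se
    p = 2.0 * sps.t.sf(np.abs(t), dfree)
    p = np.where(degenerate, 1.0, np.clip(p, np.finfo(float).tiny, 1.0))
    return beta, t, p, degenerate


def _iter_patterns(Y: np.ndarray):
    """Yield (row_index_array, voxel_index_array) grouped by missingness."""
    nan = np.isnan(Y)
    if not nan.any():
        yield np.arange(Y.shape[0]), np.arange(Y.shape[1])
        return
    patterns, inverse = np.unique(nan.T, axis=0, return_inverse=True)
    for pi in range(patterns.shape[0]):
        vox = np.flatnonzero(inverse == pi)
        rows = np.flatnonzero(~patterns[pi])
        yield rows, vox


def voxelwise_group_difference(
    stack: CohortStack,
    group: str | np.ndarray,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    group_threshold: int = 1,
    extra_covariates: Mapping[str, np.ndarray] | None = None,
) -> SPMResult:
    """Covariate-adjusted voxel-wise group difference map.

    ``group`` is a grade-variable name (dichotomized at ``grade >=
    group_threshold``) or an explicit binary vector.  The effect map is the
    signed percentage difference of adjusted group means (see module
    docstring for the sign convention); p is the two-sided t-test on the
    group coefficient.
    """
    recs = stack.subjects
    if isinstance(group, str):
        gvec = (resolve_field(recs, group) >= group_threshold).astype(float)
    else:
        gvec = np.asarray(group, dtype=float)
    if gvec.shape != (stack.n_subjects,):
        raise DesignError("group vector length != number of subjects")
    if gvec.sum() == 0 or gvec.sum() == len(gvec):
        raise DesignError("both groups must be nonempty")

    Xcov, names = design_matrix(recs, covariates, extra_covariates)
    X = np.insert(Xcov, 1, gvec, axis=1)
    names = [names[0], "group"] + names[1:]
    _check_full_rank(X, names)

    V = stack.values.shape[1]
    eff = np.full(V, np.nan)
    pvals = np.full(V, np.nan)
    degen = np.zeros(V, dtype=bool)
    for rows, vox in _iter_patterns(stack.values):
        if len(rows) < X.shape[1] + 1:
            continue
        Xp = X[rows]
        gp = Xp[:, 1]
        if gp.sum() == 0 or gp.sum() == len(gp):
            continue
        beta, t, p, dg = _solve_ols(Xp, stack.values[np.ix_(rows, vox)], j=1)
        xbar = Xp.mean(axis=0)
        xbar[1] = 0.0  # reference (without-abnormality) group
        y0 = xbar @ beta
        with np.errstate(divide="ignore", invalid="ignore"):
            e = -100.0 * beta[1] / y0
        e = np.where(np.abs(y0) < 1e-12, np.nan, e)
        eff[vox], pvals[vox], degen[vox] = e, p, dg

    return SPMResult(
        effect=stack.to_volume(eff), p=stack.to_volume(pvals),
        common_mask=stack.common_mask, analysis_kind="difference",
        covariates_used=names[2:],
        meta={"degenerate": stack.to_volume(degen.astype(float)),
              "group_threshold": group_threshold,
              "group": group if isinstance(group, str) else "custom"},
    )


def voxelwise_partial_correlation(
    stack: CohortStack,
    outcome: str | np.ndarray,
    covariates: Sequence[str] = (),
    extra_covariates: Mapping[str, np.ndarray] | None = None,
) -> SPMResult:
    """Pearson partial correlation of voxel values with a per-subject outcome.

    Both the outcome and each voxel's values are residualized on the
    covariates (plus intercept); r is the correlation of the residuals and
    p comes from ``t = r * sqrt((n - k - 2) / (1 - r^2))`` with k covariate
    columns, two-sided.
    """
    recs = stack.subjects
    y = resolve_field(recs, outcome) if isinstance(outcome, str) \
        else np.asarray(outcome, dtype=float)
    if y.shape != (stack.n_subjects,):
        raise DesignError("outcome length != number of subjects")
    if np.var(y) <= 0:
        raise DesignError("outcome has zero variance")

    Z, names = design_matrix(recs, covariates, extra_covariates)
    k = Z.shape[1] - 1

    V = stack.values.shape[1]
    rr = np.full(V, np.nan)
    pvals = np.full(V, np.nan)
    for rows, vox in _iter_patterns(stack.values):
        n = len(rows)
        dfree = n - k - 2
        if dfree < 1:
            if np.isnan(stack.values).any():
                continue
            raise DesignError(
                f"n - k - 2 = {dfree} < 1 (n={n}, {k} covariates)")
        Zp = Z[rows]
        H = Zp @ np.linalg.pinv(Zp)
        ry = y[rows] - H @ y[rows]
        RY = stack.values[np.ix_(rows, vox)]
        RY = RY - H @ RY
        num = ry @ RY
        den = np.sqrt(np.sum(ry**2) * np.sum(RY**2, axis=0))
        with np.errstate(divide="ignore", invalid="ignore"):
            r = np.clip(num / den, -1.0, 1.0)
        r = np.where(den <= 0, np.nan, r)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = r * np.sqrt(dfree / (1.0 - r**2))
        p = 2.0 * sps.t.sf(np.abs(t), dfree)
        p = np.where(np.isclose(np.abs(r), 1.0), np.finfo(float).tiny, p)
        rr[vox] = r
        pvals[vox] = np.clip(p, np.finfo(float).tiny, 1.0)

    return SPMResult(
        effect=stack.to_volume(rr), p=stack.to_volume(pvals),
        common_mask=stack.common_mask, analysis_kind="correlation",
        covariates_used=names[1:],
        meta={"outcome": outcome if isinstance(outcome, str) else "custom"},
    )


# --------------------------------------------------------------------------- #
# thresholding, clustering, summaries
# --------------------------------------------------------------------------- #

_CONNECTIVITY_RANK = {6: 1, 18: 2, 26: 3}


def threshold_and_cluster(
    spm: SPMResult,
    alpha: float = 0.05,
    connectivity: int = 26,
    min_cluster_voxels: int = 1,
) -> SPMResult:
    """Apply the p <= alpha threshold and extract connected components."""
    if connectivity not in _CONNECTIVITY_RANK:
        raise KneeVBRError(f"connectivity must be one of {list(_CONNECTIVITY_RANK)}")
    with np.errstate(invalid="ignore"):
        sig = spm.common_mask & (spm.p <= alpha)
    structure = ndimage.generate_binary_structure(3, _CONNECTIVITY_RANK[connectivity])
    labeled, n = ndimage.label(sig, structure=structure)
    clusters: list[Cluster] = []
    keep = sig.copy()
    cid = 0
    for lab in range(1, n + 1):
        idx = np.argwhere(labeled == lab)
        if len(idx) < min_cluster_voxels:
            keep[tuple(idx.T)] = False
            continue
        cid += 1
        clusters.append(Cluster(
            cluster_id=cid, size=len(idx), indices=idx,
            mean_p=float(np.mean(spm.p[tuple(idx.T)])),
        ))
    return replace(spm, sig_mask=keep, clusters=clusters, alpha=alpha)


@dataclass
class CompartmentSummary:
    """Per-compartment PSV / APD (or avg r) / average p over significant voxels."""

    analysis_kind: str
    table: pd.DataFrame  # compartment, n_voxels, n_sig, psv_pct, effect col, avg_p

    @property
    def effect_column(self) -> str:
        return "apd_pct" if self.analysis_kind == "difference" else "avg_r"

    def row(self, compartment: str) -> pd.Series:
        return self.table.set_index("compartment").loc[compartment]


def summarize_by_compartment(
    spm: SPMResult, atlas: CompartmentAtlas
) -> CompartmentSummary:
    """PSV, mean effect and mean p over each compartment's significant voxels.

    Empty intersections leave the effect/p summaries as NaN (flagged
    undefined), never raise.
    """
    if spm.sig_mask is None:
        raise KneeVBRError("run threshold_and_cluster before summarizing")
    if atlas.labels.shape != spm.common_mask.shape:
        raise GridMismatchError("SPM and atlas grids differ")
    effect_col = "apd_pct" if spm.analysis_kind == "difference" else "avg_r"
    rows = []
    for lab in sorted(LABEL_NAMES):
        name = LABEL_NAMES[lab]
        comp = atlas.labels == lab
        n_comp = int(comp.sum())
        sig = comp & spm.sig_mask
        n_sig = int(sig.sum())
        psv = 100.0 * n_sig / n_comp if n_comp else float("nan")
        rows.append({
            "compartment": name,
            "n_voxels": n_comp,
            "n_sig_voxels": n_sig,
            "psv_pct": psv,
            effect_col: float(np.mean(spm.effect[sig])) if n_sig else float("nan"),
            "avg_p": float(np.mean(spm.p[sig])) if n_sig else float("nan"),
        })
    return CompartmentSummary(analysis_kind=spm.analysis_kind,
                              table=pd.DataFrame(rows))


def neglog_p_map(spm: SPMResult) -> np.ndarray:
    """Display transform ``10 * log10(1 / p)``; NaN outside the common mask."""
    tiny = np.finfo(float).tiny
    p = spm.p
    if np.any(p[spm.common_mask] <= 0):
        log.warning("p = 0 encountered; clipping to smallest positive float")
    with np.errstate(divide="ignore", invalid="ignore"):
        out = 10.0 * np.log10(1.0 / np.clip(p, tiny, 1.0))
    return np.where(spm.common_mask, out, np.nan)


# --------------------------------------------------------------------------- #
# permutation cross-check
# --------------------------------------------------------------------------- #


def permutation_group_p(
    stack: CohortStack,
    group: str | np.ndarray,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    group_threshold: int = 1,
    n_permutations: int = 999,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Permutation p-map for the group contrast (labels permuted, covariates
    fixed); ``p = (1 + #{|t_perm| >= |t_obs|}) / (n_perm + 1)``."""
    if np.isnan(stack.values).any():
        raise KneeVBRError("permutation test requires a complete stack")
    recs = stack.subjects
    if isinstance(group, str):
        gvec = (resolve_field(recs, group) >= group_threshold).astype(float)
    else:
        gvec = np.asarray(group, dtype=float)
    Xcov, names = design_matrix(recs, covariates)
    rng = np.random.default_rng(rng)

    def tstats(g):
        X = np.insert(Xcov, 1, g, axis=1)
        _, t, _, dg = _solve_ols(X, stack.values, j=1)
        return np.where(dg, 0.0, t)

    t_obs = np.abs(tstats(gvec))
    count = np.ones_like(t_obs)
    for _ in range(n_permutations):
        count += np.abs(tstats(rng.permutation(gvec))) >= t_obs
    return stack.to_volume(count / (n_permutations + 1.0))


# --------------------------------------------------------------------------- #
# contrast battery
# --------------------------------------------------------------------------- #


@dataclass(frozen=True)
class Contrast:
    kind: str  # "difference" | "correlation"
    variable: str  # grade variable or outcome field name
    group_threshold: int = 1

    @property
    def name(self) -> str:
        return f"{self.kind}:{self.variable}"


@dataclass
class BatteryResult:
    results: dict[tuple[str, str], tuple[SPMResult, CompartmentSummary]]
    alpha: float

    def difference_table(self) -> pd.DataFrame:
        """Rows = compartments, one PSV/APD/avg-P column triple per contrast
        and modality (the layout of the group-comparison tables)."""
        rows: dict[str, dict] = {n: {"compartment": n} for n in LABEL_NAMES.values()}
        for (modality, cname), (spm, summ) in sorted(self.results.items()):
            if spm.analysis_kind != "difference":
                continue
            var = cname.split(":", 1)[1]
            for _, r in summ.table.iterrows():
                base = f"{modality}_{var}"
                rows[r["compartment"]][f"{base}_psv_pct"] = r["psv_pct"]
                rows[r["compartment"]][f"{base}_apd_pct"] = r["apd_pct"]
                rows[r["compartment"]][f"{base}_avg_p"] = r["avg_p"]
        df = pd.DataFrame(list(rows.values()))
        return df if len(df.columns) > 1 else pd.DataFrame(
            columns=["compartment", "psv_pct", "apd_pct", "avg_p"])

    def correlation_table(self) -> pd.DataFrame:
        """Rows = (compartment, outcome): PSV correlated %, average r, average P."""
        rows = []
        for (modality, cname), (spm, summ) in sorted(self.results.items()):
            if spm.analysis_kind != "correlation":
                continue
            var = cname.split(":", 1)[1]
            for _, r in summ.table.iterrows():
                rows.append({
                    "modality": modality,
                    "outcome": var,
                    "compartment": r["compartment"],
                    "psv_correlated_pct": r["psv_pct"],
                    "average_r": r["avg_r"],
                    "average_p": r["avg_p"],
                })
        return pd.DataFrame(rows, columns=[
            "modality", "outcome", "compartment", "psv_correlated_pct",
            "average_r", "average_p"])


def run_contrast_battery(
    stacks: Mapping[str, CohortStack],
    contrasts: Sequence[Contrast],
    atlas: CompartmentAtlas,
    alpha: float = 0.05,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    connectivity: int = 26,
    min_cluster_voxels: int = 1,
    extra_covariates: Mapping[str, np.ndarray] | None = None,
) -> BatteryResult:
    """Run every contrast on every modality stack and summarize per
    compartment.  No cross-contrast multiplicity adjustment is applied."""
    results: dict[tuple[str, str], tuple[SPMResult, CompartmentSummary]] = {}
    for modality, stack in stacks.items():
        for c in contrasts:
            resolve_field(stack.subjects, c.variable)  # fail fast with field list
            if c.kind == "difference":
                spm = voxelwise_group_difference(
                    stack, c.variable, covariates=covariates,
                    group_threshold=c.group_threshold,
                    extra_covariates=extra_covariates)
            elif c.kind == "correlation":
                spm = voxelwise_partial_correlation(
                    stack, c.variable, covariates=covariates,
                    extra_covariates=extra_covariates)
            else:
                raise KneeVBRError(f"unknown contrast kind {c.kind!r}")
            spm = threshold_and_cluster(spm, alpha=alpha,
                                        connectivity=connectivity,
                                        min_cluster_voxels=min_cluster_voxels)
            results[(modality, c.name)] = (spm, summarize_by_compartment(spm, atlas))
    return BatteryResult(results=results, alpha=alpha)
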