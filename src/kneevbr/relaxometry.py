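"""Per-voxel mono-exponential T1rho/T2 mapping.

Two estimators of ``S(t) = S0 * exp(-t / T)``:

* :func:`loglinear_fit` — closed-form ordinary least squares of ``ln S`` on
  the echo time.  Exact on noiseless data; used as the initializer for the
  nonlinear fit and as an independent oracle in tests.
* :func:`fit_monoexponential` — damped Gauss-Newton (Levenberg-Marquardt)
  minimization of the sum of squared signal residuals, vectorized over all
  masked voxels at once (the per-voxel problem is only 2-parameter, so the
  normal equations are solved in closed form).
"""

from __future__ import annotations

import numpy as np

from .core import EchoSeries, RelaxationMap
from .errors import KneeVBRError

DEFAULT_BOUNDS_MS = (1.0, 200.0)
_LOG_EPS = 1e-12


def _default_mask(series: EchoSeries) -> np.ndarray:
    return np.all(series.data > 0, axis=-1)


def _r_squared(signals: np.ndarray, model: np.ndarray) -> np.ndarray:
    """Coefficient of determination against the mean-signal null, per voxel."""
    ss_res = np.sum((signals - model) ** 2, axis=1)
    ss_tot = np.sum((signals - signals.mean(axis=1, keepdims=True)) ** 2, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = 1.0 - ss_res / ss_tot
    r2 = np.where(ss_tot <= 0, 0.0, r2)
    return np.minimum(r2, 1.0)


def _empty_map(series: EchoSeries, mask: np.ndarray, **meta) -> RelaxationMap:
    shape = series.grid_shape
    return RelaxationMap(
        time_ms=np.full(shape, np.nan),
        s0=np.full(shape, np.nan),
        r_squared=np.full(shape, np.nan),
        converged=np.zeros(shape, dtype=bool),
        mask=mask.copy(),
        spacing_mm=series.spacing_mm,
        meta={"modality": series.modality, **meta},
    )


def loglinear_fit(series: EchoSeries, mask: np.ndarray | None = None) -> RelaxationMap:
    """Closed-form log-linear estimator.

    OLS of ``ln S`` on echo time: slope ``-1/T``, intercept ``ln S0``.
    Voxels with any non-positive signal, or a non-decaying slope, are flagged
    unconverged rather than raising.
    """
    if series.n_echoes < 2:
        raise KneeVBRError("log-linear fit needs at least 2 echoes")
    mask = _default_mask(series) if mask is None else np.asarray(mask, dtype=bool)
    out = _empty_map(series, mask, method="loglinear")
    if not mask.any():
        return out

    te = np.asarray(series.echo_times_ms)
    signals = series.data[mask]  # (V, E)
    positive = np.all(signals > 0, axis=1)
    logs = np.log(np.maximum(signals, _LOG_EPS))

    t_mean = te.mean()
    y_mean = logs.mean(axis=1)
    sxx = float(np.sum((te - t_mean) ** 2))
    sxy = logs @ (te - t_mean)
    slope = sxy / sxx
    intercept = y_mean - slope * t_mean

    with np.errstate(divide="ignore", over="ignore", invalid="ignore"):
        time = -1.0 / slope
        s0 = np.exp(intercept)
        model = s0[:, None] * np.exp(-te[None, :] / time[:, None])
    r2 = _r_squared(signals, np.nan_to_num(model, nan=np.inf))

    ok = positive & (slope < 0) & np.isfinite(time)
    out.time_ms[mask] = np.where(ok, time, np.nan)
    out.s0[mask] = np.where(ok, s0, np.nan)
    out.r_squared[mask] = np.where(ok, r2, np.nan)
    conv = np.zeros(series.grid_shape, dtype=bool)
    conv[mask] = ok
    out.converged = conv
    return out


def _lm_exponential(
    signals: np.ndarray,
    te: np.ndarray,
    s0_init: np.ndarray,
    t_init: np.ndarray,
    max_iter: int = 60,
    tol: float = 1e-12,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized Levenberg-Marquardt over voxels for (S0, T).

    Returns (s0, t, converged).  The 2x2 damped normal equations are solved
    in closed form per voxel; each voxel carries its own damping factor.
    """
    s0 = s0_init.astype(float).copy()
    t = np.clip(t_init.astype(float), 1e-3, 1e6)
    lam = np.full(s0.shape, 1e-3)
    last_step = np.full(s0.shape, np.inf)

    def residuals(s0v, tv):
        model = s0v[:, None] * np.exp(-te[None, :] / tv[:, None])
        r = signals - model
        return r, 0.5 * np.sum(r * r, axis=1)

    r, cost = residuals(s0, t)
    for _ in range(max_iter):
        E = np.exp(-te[None, :] / t[:, None])
        j0 = E
        j1 = s0[:, None] * te[None, :] / (t**2)[:, None] * E
        a00 = np.sum(j0 * j0, axis=1)
        a01 = np.sum(j0 * j1, axis=1)
        a11 = np.sum(j1 * j1, axis=1)
        g0 = np.sum(j0 * r, axis=1)
        g1 = np.sum(j1 * r, axis=1)

        m00 = a00 * (1.0 + lam)
        m11 = a11 * (1.0 + lam)
        det = m00 * m11 - a01 * a01
        with np.errstate(divide="ignore", invalid="ignore"):
            d0 = (m11 * g0 - a01 * g1) / det
            d1 = (m00 * g1 - a01 * g0) / det
        bad = ~np.isfinite(d0) | ~np.isfinite(d1)
        d0 = np.where(bad, 0.0, d0)
        d1 = np.where(bad, 0.0, d1)

        s0_new = s0 + d0
        t_new = np.clip(t + d1, 1e-3, 1e6)
        r_new, cost_new = residuals(s0_new, t_new)
        accept = np.isfinite(cost_new) & (cost_new <= cost)

        step = np.hypot(d0, d1) / (1.0 + np.hypot(s0, t))
        last_step = np.where(accept, step, last_step)
        s0 = np.where(accept, s0_new, s0)
        t = np.where(accept, t_new, t)
        r = np.where(accept[:, None], r_new, r)
        cost = np.where(accept, cost_new, cost)
        lam = np.clip(np.where(accept, lam * 0.3, lam * 4.0), 1e-12, 1e12)
        if np.all(last_step < tol):
            break

    # Converged where the last accepted relative step is tiny or the gradient
    # has vanished relative to the curvature scale.
    E = np.exp(-te[None, :] / t[:, None])
    g0 = np.sum(E * r, axis=1)
    g1 = np.sum(s0[:, None] * te[None, :] / (t**2)[:, None] * E * r, axis=1)
    curv = np.sum(E * E, axis=1) + np.sum(
        (s0[:, None] * te[None, :] / (t**2)[:, None] * E) ** 2, axis=1
    )
    grad_rel = np.hypot(g0, g1) / (np.sqrt(curv * np.maximum(2.0 * cost, 1e-300)) + 1e-300)
    converged = np.isfinite(t) & np.isfinite(s0) & (
        (last_step < 1e-8) | (grad_rel < 1e-4) | (cost < 1e-20)
    )
    return s0, t, converged


def fit_monoexponential(
    series: EchoSeries,
    mask: np.ndarray | None = None,
    bounds: tuple[float, float] = DEFAULT_BOUNDS_MS,
    init: str = "loglinear",
    max_iter: int = 60,
) -> RelaxationMap:
    """Levenberg-Marquardt mono-exponential fit per masked voxel.

    ``bounds`` are the physiologic window in ms; estimates are reported raw
    but voxels landing at/outside the bounds are meant to be excluded with
    :func:`fit_quality_mask`.  ``init`` is ``"loglinear"`` (default) or
    ``"fixed"`` (S0 from the first echo, T mid-bounds).
    """
    if series.n_echoes < 3:
        raise KneeVBRError("need at least 3 echoes for a 2-parameter fit")
    t_min, t_max = bounds
    if not (0 < t_min < t_max):
        raise KneeVBRError(f"invalid bounds {bounds}")
    mask = _default_mask(series) if mask is None else np.asarray(mask, dtype=bool)
    if not mask.any():
        raise KneeVBRError("empty fitting mask")

    te = np.asarray(series.echo_times_ms)
    signals = series.data[mask]
    finite = np.all(np.isfinite(signals), axis=1)

    if init == "loglinear":
        ll = loglinear_fit(series, mask)
        t0 = ll.time_ms[mask]
        s00 = ll.s0[mask]
    elif init == "fixed":
        t0 = np.full(signals.shape[0], np.nan)
        s00 = np.full(signals.shape[0], np.nan)
    else:
        raise KneeVBRError(f"unknown init {init!r}")
    fallback_t = np.sqrt(t_min * t_max)
    t0 = np.where(np.isfinite(t0) & (t0 > 0), np.clip(t0, t_min / 10, t_max * 10),
                  fallback_t)
    s0_guess = np.maximum(signals[:, 0], np.max(np.abs(signals), axis=1))
    s00 = np.where(np.isfinite(s00) & (s00 > 0), s00, np.maximum(s0_guess, _LOG_EPS))

    safe = np.where(finite[:, None], signals, 0.0)
    s0_hat, t_hat, conv = _lm_exponential(safe, te, s00, t0, max_iter=max_iter)
    model = s0_hat[:, None] * np.exp(-te[None, :] / t_hat[:, None])
    r2 = _r_squared(safe, model)
    flat = np.sum((safe - safe.mean(axis=1, keepdims=True)) ** 2, axis=1) <= 0
    conv = conv & finite & ~flat

    out = _empty_map(series, mask, method="levenberg-marquardt", bounds=bounds)
    out.time_ms[mask] = np.where(finite, t_hat, np.nan)
    out.s0[mask] = np.where(finite, s0_hat, np.nan)
    out.r_squared[mask] = np.where(finite, r2, np.nan)
    convmap = np.zeros(series.grid_shape, dtype=bool)
    convmap[mask] = conv
    out.converged = convmap
    out.meta["n_fitted"] = int(mask.sum())
    out.meta["n_converged"] = int(conv.sum())
    return out


def fit_quality_mask(
    rmap: RelaxationMap,
    min_r_squared: float = 0.0,
    bounds: tuple[float, float] | None = None,
) -> np.ndarray:
    """Voxels that converged, meet the r^2 floor and lie strictly inside bounds."""
    if bounds is None:
        bounds = rmap.meta.get("bounds", DEFAULT_BOUNDS_MS)
    t_min, t_max = bounds
    tol = 1e-9 * t_max  # estimates numerically *at* a bound count as outside
    with np.errstate(invalid="ignore"):
        ok = (
            rmap.mask
            & rmap.converged
            & np.isfinite(rmap.time_ms)
            & (rmap.r_squared >= min_r_squared)
            & (rmap.time_ms - t_min > tol)
            & (t_max - rmap.time_ms > tol)
        )
    return ok
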