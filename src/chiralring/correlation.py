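"""Temporal and spatiotemporal correlation analysis.

Estimators follow the standard stationary-window conventions: deviations
``delta x = x - <x>`` are taken from the window mean (no detrending), the
1D temporal estimator uses the biased ``1/n`` normalization so that the
normalized autocorrelation is exactly 1 at zero lag, and the 2D estimator
averages over all valid ``(theta, t)`` pairs with the angular shift
periodic on the ring (clockwise-positive ``delta theta``).

A traveling wave appears as a tilted ridge in the spatiotemporal
autocorrelation; :func:`wave_speed` extracts its slope (rad per unit time)
by locating the peak angular offset at each time lag (with parabolic
sub-bin refinement) and fitting a line through the origin.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .errors import DegenerateSeriesError, LagRangeError, NoRidgeError
from .params import ModelParameters

__all__ = [
    "CorrelationResult",
    "SweepResult",
    "EnsembleProfile",
    "temporal_crosscorr",
    "spatiotemporal_corr",
    "integrated_corr",
    "wave_speed",
    "cv_statistics",
    "ensemble_aggregate",
    "parameter_sweep",
    "first_positive_peak",
]


@dataclass
class CorrelationResult:
    """Lag grid(s) with correlation values and the normalizing scales."""

    dt_lags: np.ndarray
    values: np.ndarray                    # (n_dt,) or (n_dtheta, n_dt)
    sigma_x: float
    sigma_y: float
    normalized: bool
    dtheta_lags: np.ndarray | None = None

    def to_frame(self, name: str = "C") -> pd.DataFrame:
        if self.values.ndim == 1:
            return pd.DataFrame({"dt": self.dt_lags, "value": self.values, "name": name})
        th, dt = np.meshgrid(self.dtheta_lags, self.dt_lags, indexing="ij")
        return pd.DataFrame(
            {
                "dtheta": th.ravel(),
                "dt": dt.ravel(),
                "value": self.values.ravel(),
                "name": name,
            }
        )


def temporal_crosscorr(
    x: np.ndarray,
    y: np.ndarray,
    max_lag: float,
    dt_sample: float,
    normalized: bool = True,
) -> CorrelationResult:
    """``C_xy(dt) = <delta x(t) delta y(t + dt)>`` on an even lag grid.

    A positive lag means ``x`` precedes ``y``. The autocorrelation is the
    ``x is y`` case. ``max_lag`` is in time units; the series must share
    the sampling cadence ``dt_sample``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1D series")
    n = x.size
    m = int(round(max_lag / dt_sample))
    if m >= n:
        raise ValueError("max_lag must be shorter than the series")
    dx = x - x.mean()
    dy = y - y.mean()
    sx = x.std()
    sy = y.std()
    if sx == 0.0 or sy == 0.0:
        raise DegenerateSeriesError("zero variance in correlation input")
    vals = np.empty(2 * m + 1)
    for j, k in enumerate(range(-m, m + 1)):
        if k >= 0:
            s = float(np.dot(dx[: n - k], dy[k:]))
        else:
            s = float(np.dot(dx[-k:], dy[: n + k]))
        vals[j] = s / n
    if normalized:
        vals /= sx * sy
    lags = np.arange(-m, m + 1) * dt_sample
    return CorrelationResult(
        dt_lags=lags, values=vals, sigma_x=sx, sigma_y=sy, normalized=normalized
    )


def spatiotemporal_corr(
    field: np.ndarray,
    max_dt: float,
    dt_sample: float,
    field_y: np.ndarray | None = None,
    n_dtheta: int | None = None,
    normalized: bool = True,
) -> CorrelationResult:
    """``C(dtheta, dt)`` of a local field on the (time, angular-bin) grid.

    ``field`` has shape ``(T, n_bins)``; the angular shift wraps around the
    ring (clockwise-positive). Missing bins (NaN) are handled by pairwise
    deletion; each lag averages over its valid pairs. For the cross-variant
    pass ``field_y`` (``C(dtheta,dt) = <dx(theta,t) dy(theta+dtheta,t+dt)>``),
    normalized by ``sigma_x sigma_y`` instead of the field variance.
    """
    f = np.asarray(field, dtype=float).T  # (n_bins, T)
    g = f if field_y is None else np.asarray(field_y, dtype=float).T
    if g.shape != f.shape:
        raise ValueError("fields must share the (time, bin) grid")
    nb, nt = f.shape
    m = int(round(max_dt / dt_sample))
    if m >= nt:
        raise ValueError("max_dt must be shorter than the window")
    if n_dtheta is None:
        n_dtheta = nb // 2
    dx = f - np.nanmean(f)
    dy = g - np.nanmean(g)
    sx = float(np.sqrt(np.nanmean(dx * dx)))
    sy = float(np.sqrt(np.nanmean(dy * dy)))
    if sx == 0.0 or sy == 0.0:
        raise DegenerateSeriesError("zero variance in field")
    has_nan = bool(np.isnan(dx).any() or np.isnan(dy).any())

    j_lags = np.arange(-n_dtheta, n_dtheta + 1)
    k_lags = np.arange(-m, m + 1)
    vals = np.full((j_lags.size, k_lags.size), np.nan)
    for ji, j in enumerate(j_lags):
        # dy(theta + j) aligned with dx(theta): roll backwards by j
        dyj = np.roll(dy, -j, axis=0)
        for ki, k in enumerate(k_lags):
            if k >= 0:
                a, b = dx[:, : nt - k], dyj[:, k:]
            else:
                a, b = dx[:, -k:], dyj[:, : nt + k]
            if has_nan:
                prod = a * b
                cnt = np.count_nonzero(~np.isnan(prod))
                if cnt == 0:
                    continue
                vals[ji, ki] = np.nansum(prod) / cnt
            else:
                vals[ji, ki] = np.einsum("ij,ij->", a, b) / a.size
    if normalized:
        vals /= sx * sy
    binw = 2.0 * np.pi / nb
    return CorrelationResult(
        dt_lags=k_lags * dt_sample,
        dtheta_lags=j_lags * binw,
        values=vals,
        sigma_x=sx,
        sigma_y=sy,
        normalized=normalized,
    )


def integrated_corr(
    result: CorrelationResult, t_lo: float = 1.0, t_hi: float = 5.0
) -> np.ndarray:
    """Trapezoidal integral of ``C(dtheta, dt)`` over ``dt`` in [t_lo, t_hi]."""
    if t_lo >= t_hi:
        raise LagRangeError("t_lo must be < t_hi")
    lags = result.dt_lags
    if t_lo < lags.min() - 1e-12 or t_hi > lags.max() + 1e-12:
        raise LagRangeError(
            f"lag grid [{lags.min():g}, {lags.max():g}] does not cover "
            f"[{t_lo:g}, {t_hi:g}]"
        )
    sel = (lags >= t_lo - 1e-12) & (lags <= t_hi + 1e-12)
    return np.trapezoid(result.values[:, sel], lags[sel], axis=1)


def wave_speed(
    result: CorrelationResult,
    dt_range: tuple[float, float] = (0.2, 1.0),
    min_corr: float = 0.15,
    min_contrast: float = 0.05,
) -> tuple[float, float]:
    """Slope of the correlation ridge, rad per unit time, with its SE.

    For each time lag in ``dt_range`` the angular offset of maximum
    correlation is located (parabolic sub-bin refinement, periodic in
    ``dtheta``); the points ``(dt, dtheta_peak)`` are fit by least squares
    through the origin. Raises :class:`NoRidgeError` when fewer than three
    lags show a usable peak (weak or flat correlation).
    """
    if result.dtheta_lags is None:
        raise ValueError("wave_speed needs a 2D spatiotemporal correlation")
    lags = result.dt_lags
    th = result.dtheta_lags
    binw = th[1] - th[0]
    sel = np.nonzero((lags >= dt_range[0] - 1e-12) & (lags <= dt_range[1] + 1e-12))[0]
    sel = sel[np.argsort(lags[sel])]
    # follow the ridge outward from (0, 0): at each lag search only near the
    # previous peak, so periodic correlation copies are not mistaken for it
    window = max(0.8, 4.0 * binw)
    prev = 0.0
    pts_t, pts_th = [], []
    for ki in sel:
        col = result.values[:, ki]
        if np.isnan(col).all():
            continue
        if np.nanmax(col) - np.nanmin(col) < min_contrast:
            continue  # flat in dtheta: no spatial structure at this lag
        dist = np.abs(np.mod(th - prev + np.pi, 2.0 * np.pi) - np.pi)
        near = dist <= window
        if not near.any() or np.isnan(col[near]).all():
            continue
        cand = np.where(near, col, -np.inf)
        cand = np.where(np.isnan(cand), -np.inf, cand)
        i = int(np.argmax(cand))
        if col[i] < min_corr:
            continue
        im, ip = (i - 1) % len(col), (i + 1) % len(col)
        c0, cm, cp = col[i], col[im], col[ip]
        denom = cm - 2.0 * c0 + cp
        frac = 0.0 if denom == 0.0 or np.isnan(denom) else 0.5 * (cm - cp) / denom
        frac = float(np.clip(frac, -0.5, 0.5))
        pts_t.append(lags[ki])
        pts_th.append(th[i] + frac * binw)
        prev = th[i] + frac * binw
    if len(pts_t) < 3:
        raise NoRidgeError(
            f"only {len(pts_t)} usable ridge points in dt range {dt_range}"
        )
    tt = np.asarray(pts_t)
    thth = np.asarray(pts_th)
    denom = float(np.dot(tt, tt))
    slope = float(np.dot(tt, thth)) / denom
    resid = thth - slope * tt
    dof = max(len(tt) - 1, 1)
    se = float(np.sqrt(np.dot(resid, resid) / dof / denom))
    return slope, se


def cv_statistics(x: np.ndarray, axis_time: int = 0) -> float:
    """Coefficient of variation ``sigma / mean`` of a series or local field.

    For a 2D field the CV is computed per angular bin over time and then
    averaged over bins (NaN bins ignored).
    """
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        mu = x.mean()
        if abs(mu) < 1e-300:
            raise DegenerateSeriesError("CV undefined for zero-mean series")
        return float(x.std() / mu)
    mu = np.nanmean(x, axis=axis_time)
    sd = np.nanstd(x, axis=axis_time)
    if np.all(np.abs(mu) < 1e-300):
        raise DegenerateSeriesError("CV undefined: all bins have zero mean")
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(np.abs(mu) > 0.0, sd / mu, np.nan)
    return float(np.nanmean(cv))


@dataclass
class EnsembleProfile:
    """Pointwise ensemble mean with a normal-approximation 95% CI."""

    mean: np.ndarray
    ci_half: np.ndarray
    n: int
    grid: np.ndarray | None = None

    @property
    def ci_low(self) -> np.ndarray:
        return self.mean - self.ci_half

    @property
    def ci_high(self) -> np.ndarray:
        return self.mean + self.ci_half


def ensemble_aggregate(
    profiles, grid: np.ndarray | None = None
) -> EnsembleProfile:
    """Mean profile over seeds with ``mean +- 1.96 SE`` confidence band."""
    arr = np.asarray(list(profiles), dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2:
        raise ValueError("need >= 2 profiles on identical grids")
    if grid is not None and len(grid) != arr.shape[1]:
        raise ValueError("profile length does not match the lag grid")
    n = arr.shape[0]
    mean = arr.mean(axis=0)
    se = arr.std(axis=0, ddof=1) / np.sqrt(n)
    return EnsembleProfile(mean=mean, ci_half=1.96 * se, n=n, grid=grid)


def first_positive_peak(
    lags: np.ndarray,
    values: np.ndarray,
    min_lag: float = 0.3,
    prominence: float = 0.05,
) -> tuple[float, float]:
    """First local maximum of a correlation curve at positive lag.

    Peaks are required to have the given prominence (on the scale of the
    normalized correlation) and to lie beyond ``min_lag``; the returned
    location is refined parabolically. Raises :class:`NoRidgeError` when no
    peak qualifies (aperiodic signal).
    """
    lags = np.asarray(lags, dtype=float)
    values = np.asarray(values, dtype=float)
    scale = np.nanmax(np.abs(values))
    if not np.isfinite(scale) or scale == 0.0:
        raise NoRidgeError("flat correlation: no peak")
    idx, _ = find_peaks(values, prominence=prominence * scale)
    idx = [i for i in idx if lags[i] > min_lag]
    if not idx:
        raise NoRidgeError(f"no correlation peak beyond lag {min_lag}")
    i = idx[0]
    c0, cm, cp = values[i], values[i - 1], values[i + 1]
    denom = cm - 2.0 * c0 + cp
    frac = 0.0 if denom == 0.0 else float(np.clip(0.5 * (cm - cp) / denom, -0.5, 0.5))
    h = lags[1] - lags[0]
    return float(lags[i] + frac * h), float(c0)


# ---------------------------------------------------------------------------
# parameter sweeps
# ---------------------------------------------------------------------------

@dataclass
class SweepResult:
    """Per-parameter-value time-averaged observables with dispersion."""

    parameter: str
    records: list[dict] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.records)


def _window_stats(result, t_lo: float, t_hi: float) -> dict:
    obs = result.observables.window(t_lo, t_hi)
    return {
        "v_mean": float(obs.v_global.mean()),
        "v_std": float(obs.v_global.std()),
        "n_t1_mean": float(obs.n_t1.mean()),
        "s_mean": float(obs.s_mean.mean()),
        "c_mean": float(np.nanmean(obs.c_chirality)),
    }


def parameter_sweep(
    params: ModelParameters,
    parameter: str,
    values,
    mode: str = "independent",
    seed: int = 0,
    t_end: float = 40.0,
    window: tuple[float, float] | None = None,
    record_every: float = 0.1,
) -> SweepResult:
    """Time-averaged observables across a parameter scan.

    ``independent`` mode runs every value from a freshly generated tissue;
    ``hysteresis`` runs the sorted values in increasing then decreasing
    order, warm-starting each run from the previous final state, which
    exposes the subcritical (bistable) branch structure of the
    rotating/non-rotating transition.
    """
    from .dynamics import run_simulation

    values = list(values)
    if not values:
        raise ValueError("empty parameter value list")
    if mode not in ("independent", "hysteresis"):
        raise ValueError(f"unknown sweep mode {mode!r}")
    if window is None:
        window = (t_end / 2.0, t_end)
    sweep = SweepResult(parameter=parameter)

    if mode == "independent":
        for i, val in enumerate(values):
            p = params.replace(**{parameter: val})
            res = run_simulation(p, t_end, seed=seed + i, record_every=record_every)
            rec = {"value": val, "branch": "independent", **_window_stats(res, *window)}
            sweep.records.append(rec)
        return sweep

    if sorted(values) != values:
        raise ValueError("hysteresis mode requires sorted values")
    for branch, ordered in (("increasing", values), ("decreasing", values[::-1])):
        state = None
        for val in ordered:
            p = params.replace(**{parameter: val})
            res = run_simulation(
                p, t_end, seed=seed, record_every=record_every, initial_state=state
            )
            state = res.final_state
            rec = {"value": val, "branch": branch, **_window_stats(res, *window)}
            sweep.records.append(rec)
    return sweep
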