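"""Per-cell, global, and locally binned observables of a trajectory.

Four quantities summarize the collective dynamics:

* ``v`` — cell angular velocity ``d psi / dt`` about the origin, computed
  from the area centroid of each cell, clockwise-positive;
* ``s`` — elliptical shape anisotropy, half the eigenvalue difference of
  the area-normalized second-moment tensor of the cell polygon;
* ``n_T1`` — number of T1 transitions per unit time (centered sliding
  window);
* ``c`` — bond chirality ``N_cl/N_ccl - N_ccl/N_cl`` comparing counts of
  clockwise- vs counter-clockwise-tilted junctions.

Local fields ``v(theta, t)`` and ``n_T1(theta, t)`` bin cells and T1 events
into angular sectors of the ring by their clockwise angular position.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateSeriesError, GeometryError, TrackingError
from .mesh import TissueState, local_bond_angles

__all__ = [
    "ObservableSeries",
    "cell_angular_velocity",
    "shape_anisotropy",
    "bond_chirality",
    "t1_rate",
    "local_fields",
    "zscore",
    "compute_observables",
]


@dataclass
class ObservableSeries:
    """Time-sampled global quantities and locally binned fields."""

    times: np.ndarray        # (T,)
    v_global: np.ndarray     # (T,) rad per unit time, clockwise-positive
    n_t1: np.ndarray         # (T,) events per unit time
    s_mean: np.ndarray       # (T,) dimensionless anisotropy
    c_chirality: np.ndarray  # (T,)
    v_local: np.ndarray      # (T, n_bins), NaN where a bin is empty
    n_t1_local: np.ndarray   # (T, n_bins)
    bin_edges: np.ndarray    # (n_bins + 1,) partition of [0, 2 pi)

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.times,
                "v_global": self.v_global,
                "n_t1": self.n_t1,
                "s_mean": self.s_mean,
                "c_chirality": self.c_chirality,
            }
        )

    def local_frame(self) -> pd.DataFrame:
        t_idx, b_idx = np.meshgrid(
            np.arange(len(self.times)), np.arange(self.v_local.shape[1]), indexing="ij"
        )
        centers = self.bin_centers
        return pd.DataFrame(
            {
                "time": self.times[t_idx.ravel()],
                "bin_index": b_idx.ravel(),
                "theta_center_rad": centers[b_idx.ravel()],
                "v_local": self.v_local.ravel(),
                "n_t1_local": self.n_t1_local.ravel(),
            }
        )

    def to_csv(self, global_path, local_path=None) -> None:
        self.to_frame().to_csv(global_path, index=False)
        if local_path is not None:
            self.local_frame().to_csv(local_path, index=False)

    @classmethod
    def from_csv(cls, global_path, local_path) -> "ObservableSeries":
        g = pd.read_csv(global_path)
        loc = pd.read_csv(local_path)
        times = g["time"].to_numpy()
        n_bins = int(loc["bin_index"].max()) + 1
        piv_v = loc.pivot(index="time", columns="bin_index", values="v_local")
        piv_n = loc.pivot(index="time", columns="bin_index", values="n_t1_local")
        edges = np.linspace(0.0, 2.0 * np.pi, n_bins + 1)
        return cls(
            times=times,
            v_global=g["v_global"].to_numpy(),
            n_t1=g["n_t1"].to_numpy(),
            s_mean=g["s_mean"].to_numpy(),
            c_chirality=g["c_chirality"].to_numpy(),
            v_local=piv_v.to_numpy(),
            n_t1_local=piv_n.to_numpy(),
            bin_edges=edges,
        )

    def window(self, t_lo: float, t_hi: float) -> "ObservableSeries":
        """Restrict all series to the closed time window [t_lo, t_hi]."""
        sel = (self.times >= t_lo - 1e-12) & (self.times <= t_hi + 1e-12)
        return ObservableSeries(
            times=self.times[sel],
            v_global=self.v_global[sel],
            n_t1=self.n_t1[sel],
            s_mean=self.s_mean[sel],
            c_chirality=self.c_chirality[sel],
            v_local=self.v_local[sel],
            n_t1_local=self.n_t1_local[sel],
            bin_edges=self.bin_edges,
        )


def cell_angular_velocity(psi: np.ndarray, times: np.ndarray) -> np.ndarray:
    """Angular velocity of each cell from its angular-position track.

    ``psi`` is a ``(T, N)`` array of clockwise angular positions sampled at
    ``times``. The track is unwrapped along time (assumes ``|d psi| < pi``
    per sample) and differentiated with central differences (one-sided at
    the ends).
    """
    psi = np.asarray(psi, dtype=float)
    times = np.asarray(times, dtype=float)
    if psi.ndim == 1:
        psi = psi[:, None]
    if psi.shape[0] != times.shape[0]:
        raise TrackingError("psi and times have mismatched lengths")
    if psi.shape[0] < 2:
        raise TrackingError("need at least 2 snapshots to differentiate")
    if np.isnan(psi).any():
        raise TrackingError("cell lost from trajectory (NaN in psi)")
    unwrapped = np.unwrap(psi, axis=0)
    return np.gradient(unwrapped, times, axis=0)


def shape_anisotropy(state: TissueState, cid: int) -> float:
    """Half the eigenvalue difference of the cell's second-moment tensor.

    The tensor is the covariance of the uniform distribution over the
    polygon (second area moments about the centroid, divided by the area),
    so the result is invariant under rotation and zero for any shape whose
    second-moment tensor is isotropic (e.g. regular polygons).
    """
    loop = state.cells[cid]
    if len(loop) < 3:
        raise GeometryError(f"cell {cid} has fewer than 3 vertices")
    pts = state.pos[np.asarray(loop)]
    x, y = pts[:, 0], pts[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cr = x * yn - xn * y
    a = 0.5 * cr.sum()
    if a <= 0.0:
        raise GeometryError(f"cell {cid} has non-positive area")
    cx = np.sum((x + xn) * cr) / (6.0 * a)
    cy = np.sum((y + yn) * cr) / (6.0 * a)
    sxx = np.sum(cr * (x * x + x * xn + xn * xn)) / 12.0
    syy = np.sum(cr * (y * y + y * yn + yn * yn)) / 12.0
    sxy = np.sum(cr * (x * yn + 2.0 * x * y + 2.0 * xn * yn + xn * y)) / 24.0
    mxx = sxx / a - cx * cx
    myy = syy / a - cy * cy
    mxy = sxy / a - cx * cy
    return float(np.sqrt(0.25 * (mxx - myy) ** 2 + mxy * mxy))


def bond_chirality(state: TissueState) -> float:
    """``N_cl/N_ccl - N_ccl/N_cl`` over all junctions.

    Junction tilt is measured clockwise from the local outward radius (the
    same reference as the chiral tension): angles strictly between 0 and
    90 degrees count toward ``N_cl``, strictly between 90 and 180 toward
    ``N_ccl``, and exact boundary angles count in neither.
    """
    ang = local_bond_angles(state)
    n_cl = int(np.count_nonzero((ang > 0.0) & (ang < 90.0)))
    n_ccl = int(np.count_nonzero((ang > 90.0) & (ang < 180.0)))
    if n_cl == 0 or n_ccl == 0:
        raise DegenerateSeriesError(
            f"bond chirality undefined: N_cl={n_cl}, N_ccl={n_ccl}"
        )
    return n_cl / n_ccl - n_ccl / n_cl


def t1_rate(
    event_times: np.ndarray, times: np.ndarray, window: float = 1.0
) -> np.ndarray:
    """Events per unit time in a centered sliding window of width ``window``."""
    if window <= 0.0:
        raise ValueError("window must be > 0")
    ev = np.sort(np.asarray(event_times, dtype=float))
    times = np.asarray(times, dtype=float)
    lo = np.searchsorted(ev, times - 0.5 * window, side="left")
    hi = np.searchsorted(ev, times + 0.5 * window, side="left")
    return (hi - lo) / window


def local_fields(
    psi: np.ndarray,
    v_cells: np.ndarray,
    times: np.ndarray,
    event_times: np.ndarray,
    event_theta: np.ndarray,
    n_bins: int = 60,
    window: float = 1.0,
):
    """Locally binned velocity and T1-rate fields over the ring.

    Cells are assigned to ``n_bins`` equal angular sectors by the clockwise
    angular position of their centroid at each sample time; ``v_local`` is
    the mean per-cell angular velocity in each sector (NaN when empty) and
    ``n_t1_local`` counts logged events per sector per unit time using the
    same centered window as :func:`t1_rate`.

    Returns ``(v_local, n_t1_local, bin_edges)``.
    """
    if n_bins < 4:
        raise ValueError("n_bins must be >= 4")
    edges = np.linspace(0.0, 2.0 * np.pi, n_bins + 1)
    psi_mod = np.mod(psi, 2.0 * np.pi)
    bins = np.clip((psi_mod / (2.0 * np.pi / n_bins)).astype(int), 0, n_bins - 1)
    n_t = len(times)
    v_local = np.full((n_t, n_bins), np.nan)
    for it in range(n_t):
        idx = bins[it]
        sums = np.bincount(idx, weights=v_cells[it], minlength=n_bins)
        cnts = np.bincount(idx, minlength=n_bins)
        nz = cnts > 0
        v_local[it, nz] = sums[nz] / cnts[nz]

    ev_t = np.asarray(event_times, dtype=float)
    ev_b = np.clip(
        (np.mod(event_theta, 2.0 * np.pi) / (2.0 * np.pi / n_bins)).astype(int),
        0,
        n_bins - 1,
    )
    n_t1_local = np.zeros((n_t, n_bins))
    for b in range(n_bins):
        sel = ev_t[ev_b == b]
        if sel.size:
            n_t1_local[:, b] = t1_rate(sel, times, window)
    return v_local, n_t1_local, edges


def zscore(x: np.ndarray) -> np.ndarray:
    """Standardize a series to mean 0 and unit population variance."""
    x = np.asarray(x, dtype=float)
    mu = x.mean()
    sigma = x.std()
    if sigma == 0.0 or not np.isfinite(sigma):
        raise DegenerateSeriesError("cannot z-score a constant series")
    return (x - mu) / sigma


def compute_observables(result, n_bins: int = 60, window: float = 1.0) -> ObservableSeries:
    """Derive the full :class:`ObservableSeries` from a simulation result."""
    times = result.times
    if len(times) >= 2:
        v_cells = cell_angular_velocity(result.psi, times)
    else:
        v_cells = np.zeros_like(result.psi)
    v_global = v_cells.mean(axis=1)
    n_t1 = t1_rate(result.t1_times, times, window)
    v_local, n_t1_local, edges = local_fields(
        result.psi, v_cells, times, result.t1_times, result.t1_theta, n_bins, window
    )
    return ObservableSeries(
        times=times,
        v_global=v_global,
        n_t1=n_t1,
        s_mean=result.s_cells.mean(axis=1),
        c_chirality=result.c_series,
        v_local=v_local,
        n_t1_local=n_t1_local,
        bin_edges=edges,
    )
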