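"""Shared fixtures: small handcrafted meshes and a cached default tissue."""

from __future__ import annotations

import numpy as np
import pytest

from chiralring import ModelParameters
from chiralring.mesh import TissueState, build_annulus_tissue


def make_pinwheel(d: float = 0.2) -> TissueState:
    """Four quadrilateral cells around a central vertical bond of length d.

    The central bond (vertices 6-7) is shared by the left (0) and right (1)
    cells; the bottom (2) and top (3) cells each touch it at one endpoint,
    so a T1 on it is the textbook neighbour exchange.
    """
    pos = np.array(
        [
            [-1.0, -1.0], [1.0, -1.0], [1.0, 1.0], [-1.0, 1.0],
            [0.0, -1.0], [0.0, 1.0],
            [0.0, -d / 2.0], [0.0, d / 2.0],
        ]
    )
    cells = [
        [0, 6, 7, 3],   # left
        [1, 2, 7, 6],   # right
        [0, 4, 1, 6],   # bottom
        [2, 5, 3, 7],   # top
    ]
    edges = set()
    for loop in cells:
        for a, b in zip(loop, loop[1:] + loop[:1]):
            edges.add((min(a, b), max(a, b)))
    bond_v = np.array(sorted(edges))
    n_b = len(bond_v)
    return TissueState(
        pos,
        np.ones(len(pos)),
        np.zeros(len(pos), dtype=np.int8),
        bond_v,
        np.zeros(n_b),
        np.zeros(n_b),
        cells,
    )


def make_single_cell(pts: np.ndarray) -> TissueState:
    """A lone polygonal cell (used for geometry and energy oracles)."""
    n = len(pts)
    cells = [list(range(n))]
    bond_v = np.array(sorted((i, (i + 1) % n) for i in range(n)))
    bond_v = np.sort(bond_v, axis=1)
    bond_v = np.unique(bond_v, axis=0)
    n_b = len(bond_v)
    return TissueState(
        np.asarray(pts, dtype=float),
        np.ones(n),
        np.zeros(n, dtype=np.int8),
        bond_v,
        np.zeros(n_b),
        np.zeros(n_b),
        cells,
    )


def regular_polygon(n: int, circumradius: float = 1.0, phase: float = 0.0) -> np.ndarray:
    ang = phase + 2.0 * np.pi * np.arange(n) / n
    return np.column_stack([circumradius * np.cos(ang), circumradius * np.sin(ang)])


@pytest.fixture(scope="session")
def default_params() -> ModelParameters:
    return ModelParameters()


@pytest.fixture(scope="session")
def annulus(default_params) -> TissueState:
    """One freshly generated 450-cell annulus, shared read-only."""
    return build_annulus_tissue(default_params, seed=11)


@pytest.fixture()
def pinwheel() -> TissueState:
    return make_pinwheel()


# ---------------------------------------------------------------------------
# full-scale simulation fixtures, shared between the acceptance tests and the
# run-level invariant tests (each is computed once per session)
# ---------------------------------------------------------------------------

STATIC_SEEDS = (101, 102, 103)
KP5_SEEDS = (201, 202, 203)
FLUCT_SEEDS = (301, 302, 303)
ENSEMBLE_SEEDS = tuple(range(1600, 1616))

STATIC_WINDOW = (20.0, 60.0)
ENSEMBLE_WINDOW = (12.5, 25.0)


def _run(params, t_end, seed):
    from chiralring.dynamics import run_simulation

    return run_simulation(params, t_end=t_end, seed=seed)


@pytest.fixture(scope="session")
def static_runs():
    """Three seeds of the reference condition: K_p=7.5, static tension, t=60."""
    p = ModelParameters(K_p=7.5)
    return [_run(p, 60.0, s) for s in STATIC_SEEDS]


@pytest.fixture(scope="session")
def kp5_runs():
    p = ModelParameters(K_p=5.0)
    return [_run(p, 60.0, s) for s in KP5_SEEDS]


@pytest.fixture(scope="session")
def fluct_runs():
    p = ModelParameters(K_p=7.5, fluctuation=True)
    return [_run(p, 60.0, s) for s in FLUCT_SEEDS]


@pytest.fixture(scope="session")
def ensemble_profiles(fluct_runs):
    """Integrated T1-T1 correlation profiles over 16 fluctuating-tension seeds.

    The three long reference runs contribute their early window; the
    remaining seeds are fresh short runs with independent quenched
    fluctuation parameters.
    """
    import numpy as np

    from chiralring.correlation import integrated_corr, spatiotemporal_corr

    p = ModelParameters(K_p=7.5, fluctuation=True)
    profiles = []
    grid = None

    def add(res):
        nonlocal grid
        w = res.observables.window(*ENSEMBLE_WINDOW)
        field = np.where(np.isnan(w.n_t1_local), 0.0, w.n_t1_local)
        corr = spatiotemporal_corr(field, max_dt=5.0, dt_sample=0.1)
        profiles.append(integrated_corr(corr, 1.0, 5.0))
        grid = corr.dtheta_lags

    for res in fluct_runs:
        add(res)
    for s in ENSEMBLE_SEEDS[: 16 - len(fluct_runs)]:
        add(_run(p, ENSEMBLE_WINDOW[1], s))
    return np.asarray(profiles), grid
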