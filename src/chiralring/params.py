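"""Model parameters of the annular vertex model.

All quantities are in model units: lengths are measured in units of the
outer wall radius and tensions in units of the maximum chiral tension, so
``R_out = 1`` and ``gamma_c = 1`` by default. The preferred cell area is
the annulus area divided by the cell number, ``A_0 = pi(R_out^2 - R_in^2)/N``,
and the preferred perimeter is that of the equal-area circle,
``L_0 = 2 sqrt(pi A_0)``.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass

from .errors import ParameterError

__all__ = ["ModelParameters"]


@dataclass(frozen=True)
class ModelParameters:
    """Constants of the energy, the chiral tension and the integrator.

    Parameters
    ----------
    K_a : float
        Area-elasticity coefficient (hydrostatic pressure strength).
    K_p : float
        Perimeter-elasticity coefficient (cortical tension strength).
    gamma_c : float
        Maximum bond line tension of the chiral term.
    theta_0 : float
        Chirality angle in degrees, measured clockwise from the AP axis
        (the +y axis of the simulation frame). Tension is maximal on
        bonds tilted by ``theta_0``.
    epsilon : float
        Bond length below which a T1 transition is triggered.
    dt : float
        Euler time increment. The default (2e-4) sits a factor ~1.4 below
        the explicit-stability limit of the stiffest elastic mode for the
        default parameter set; larger values make the integrator diverge
        regardless of the starting configuration.
    N : int
        Number of cells; conserved for the whole run.
    R_out, R_in : float
        Outer and inner confining wall radii.
    k_out, k_in : float
        Radial wall spring coefficients.
    eta_bulk, eta_out, eta_in : float
        Friction coefficients for bulk / outer-wall / inner-wall vertices.
    fluctuation : bool
        If True, the chiral tension is additionally modulated per bond by
        ``cos^2(2 pi f t + delta)`` with quenched random ``f``, ``delta``.
    A_0, L_0 : float or None
        Preferred area / perimeter. ``None`` (default) derives them from
        the geometry as described in the module docstring.
    t1_refractory : int
        Number of steps after a T1 during which the flipped bond may not
        flip again.
    """

    K_a: float = 10.0
    K_p: float = 7.5
    gamma_c: float = 1.0
    theta_0: float = 45.0
    epsilon: float = 0.005
    dt: float = 2e-4
    N: int = 450
    R_out: float = 1.0
    R_in: float = 0.5
    k_out: float = 100.0
    k_in: float = 100.0
    eta_bulk: float = 1.0
    eta_out: float = 100.0
    eta_in: float = 10.0
    fluctuation: bool = False
    A_0: float | None = None
    L_0: float | None = None
    t1_refractory: int = 50

    def __post_init__(self) -> None:
        if self.N < 3:
            raise ParameterError(f"N must be >= 3, got {self.N}")
        if not (0.0 < self.R_in < self.R_out):
            raise ParameterError(
                f"need 0 < R_in < R_out, got R_in={self.R_in}, R_out={self.R_out}"
            )
        if self.dt <= 0.0:
            raise ParameterError(f"dt must be > 0, got {self.dt}")
        if self.epsilon <= 0.0:
            raise ParameterError(f"epsilon must be > 0, got {self.epsilon}")
        for name in ("K_a", "K_p", "gamma_c", "k_out", "k_in"):
            if getattr(self, name) < 0.0:
                raise ParameterError(f"{name} must be >= 0")
        for name in ("eta_bulk", "eta_out", "eta_in"):
            if getattr(self, name) <= 0.0:
                raise ParameterError(f"{name} must be > 0")
        if self.A_0 is not None and self.A_0 <= 0.0:
            raise ParameterError("A_0 must be > 0")
        if self.L_0 is not None and self.L_0 <= 0.0:
            raise ParameterError("L_0 must be > 0")
        if self.t1_refractory < 0:
            raise ParameterError("t1_refractory must be >= 0")

    @property
    def a0(self) -> float:
        """Preferred cell area (derived from the annulus if not set)."""
        if self.A_0 is not None:
            return self.A_0
        return math.pi * (self.R_out**2 - self.R_in**2) / self.N

    @property
    def l0(self) -> float:
        """Preferred cell perimeter (circle of area ``a0`` if not set)."""
        if self.L_0 is not None:
            return self.L_0
        return 2.0 * math.sqrt(math.pi * self.a0)

    @property
    def theta_0_rad(self) -> float:
        return math.radians(self.theta_0)

    def replace(self, **changes) -> "ModelParameters":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def field_names(cls) -> tuple[str, ...]:
        return tuple(f.name for f in dataclasses.fields(cls))

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParameters":
        known = set(cls.field_names())
        unknown = sorted(set(d) - known)
        if unknown:
            raise ParameterError(f"unknown parameter keys: {unknown}")
        return cls(**d)
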