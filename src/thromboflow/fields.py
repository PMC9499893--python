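"""Core data types: structured grid, frozen flow field, species state,
model parameters and region masks.

All fields live at cell centers of a uniform rectangular grid and are stored
as 2D arrays of shape ``(ny, nx)`` indexed ``[j, i]`` with x rightward and y
upward.  The flat cell index is ``j * nx + i``, i.e. the C-order ravel of the
2D array.  Units are strictly SI (m, s, Pa, mol, m^-3).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, NamedTuple

import numpy as np

from .errors import ValidationError

__all__ = [
    "StructuredGrid2D",
    "FlowField",
    "SpeciesState",
    "ModelParameters",
    "RegionMask",
    "uniform_state",
    "check_divergence",
    "DivergenceCheck",
]

#: Default blood density (kg m^-3) at a hematocrit of 44%.
BLOOD_DENSITY = 1056.4

#: Default dynamic viscosity (Pa s) used when no per-cell field is supplied.
BLOOD_VISCOSITY = 3.5e-3


@dataclass(frozen=True)
class StructuredGrid2D:
    """Uniform, cell-centered rectangular grid.

    Parameters
    ----------
    nx, ny : int
        Number of cells along x and y; at least 3 each so that interior
        central differences exist.
    dx, dy : float
        Cell sizes in meters.
    origin : tuple of float
        Coordinates of the lower-left *corner* of the domain (m).
    """

    nx: int
    ny: int
    dx: float
    dy: float
    origin: tuple = (0.0, 0.0)

    def __post_init__(self):
        if self.nx < 3 or self.ny < 3:
            raise ValidationError(f"grid must be at least 3x3, got {self.nx}x{self.ny}")
        if self.dx <= 0 or self.dy <= 0:
            raise ValidationError(f"cell sizes must be positive, got dx={self.dx}, dy={self.dy}")

    @property
    def shape(self):
        """Array shape ``(ny, nx)`` of cell-centered fields."""
        return (self.ny, self.nx)

    @property
    def n_cells(self) -> int:
        return self.nx * self.ny

    @property
    def cell_volume(self) -> float:
        """Cell volume per unit depth (m^3 / m = m^2), strictly positive."""
        return self.dx * self.dy

    @property
    def length(self) -> float:
        return self.nx * self.dx

    @property
    def height(self) -> float:
        return self.ny * self.dy

    @property
    def x_centers(self) -> np.ndarray:
        """x coordinates of cell centers, shape ``(nx,)``."""
        return self.origin[0] + (np.arange(self.nx) + 0.5) * self.dx

    @property
    def y_centers(self) -> np.ndarray:
        """y coordinates of cell centers, shape ``(ny,)``."""
        return self.origin[1] + (np.arange(self.ny) + 0.5) * self.dy

    def meshgrid(self):
        """Cell-center coordinate arrays ``(X, Y)`` of shape ``(ny, nx)``."""
        return np.meshgrid(self.x_centers, self.y_centers)

    def flat_index(self, i, j):
        """Map cell index (i, j) to the flat index ``j*nx + i``."""
        i = np.asarray(i)
        j = np.asarray(j)
        if np.any((i < 0) | (i >= self.nx) | (j < 0) | (j >= self.ny)):
            raise ValidationError("cell index out of range")
        return j * self.nx + i

    def check_field(self, arr: np.ndarray, name: str = "field") -> np.ndarray:
        """Validate that ``arr`` is congruent with the grid; returns it as float."""
        arr = np.asarray(arr, dtype=float)
        if arr.shape != self.shape:
            raise ValidationError(
                f"{name} has shape {arr.shape}, expected {self.shape} for this grid"
            )
        return arr


@dataclass
class FlowField:
    """Frozen carrier flow: per-cell velocity, viscosity and turbulence fields.

    ``mu_t`` (eddy viscosity, Pa s) and ``k`` (turbulent kinetic energy,
    m^2 s^-2) default to zero, i.e. a purely viscous stress evaluation.
    The velocity field is held fixed while species are transported on it.
    """

    u: np.ndarray
    v: np.ndarray
    mu: np.ndarray
    mu_t: np.ndarray = None
    k: np.ndarray = None
    rho: float = BLOOD_DENSITY

    def __post_init__(self):
        self.u = np.asarray(self.u, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        self.mu = np.asarray(self.mu, dtype=float)
        if self.mu_t is None:
            self.mu_t = np.zeros_like(self.u)
        else:
            self.mu_t = np.asarray(self.mu_t, dtype=float)
        if self.k is None:
            self.k = np.zeros_like(self.u)
        else:
            self.k = np.asarray(self.k, dtype=float)
        if self.rho <= 0:
            raise ValidationError(f"density must be positive, got {self.rho}")
        if np.any(self.mu <= 0):
            raise ValidationError("dynamic viscosity must be positive everywhere")
        if np.any(self.mu_t < 0):
            raise ValidationError("eddy viscosity must be non-negative")
        if np.any(self.k < 0):
            raise ValidationError("turbulent kinetic energy must be non-negative")

    def validate(self, grid: StructuredGrid2D) -> "FlowField":
        for name in ("u", "v", "mu", "mu_t", "k"):
            grid.check_field(getattr(self, name), name)
        return self

    def copy(self) -> "FlowField":
        return FlowField(
            u=self.u.copy(), v=self.v.copy(), mu=self.mu.copy(),
            mu_t=self.mu_t.copy(), k=self.k.copy(), rho=self.rho,
        )


@dataclass
class SpeciesState:
    """Per-cell concentrations of the three transported species.

    ``phi_a`` and ``phi_n`` are activated / non-activated platelet number
    concentrations (m^-3); ``adp`` is the ADP molar concentration
    (mol m^-3).  The activated fraction ``phi_f = phi_a / (phi_a + phi_n)``
    must stay in [0, 1] wherever platelets are present.
    """

    phi_a: np.ndarray
    phi_n: np.ndarray
    adp: np.ndarray

    def __post_init__(self):
        self.phi_a = np.asarray(self.phi_a, dtype=float)
        self.phi_n = np.asarray(self.phi_n, dtype=float)
        self.adp = np.asarray(self.adp, dtype=float)

    def validate(self, grid: StructuredGrid2D = None) -> "SpeciesState":
        if grid is not None:
            for name in ("phi_a", "phi_n", "adp"):
                grid.check_field(getattr(self, name), name)
        if np.any(self.phi_a < 0) or np.any(self.phi_n < 0) or np.any(self.adp < 0):
            raise ValidationError("species concentrations must be non-negative")
        return self

    @property
    def total_platelets(self) -> np.ndarray:
        return self.phi_a + self.phi_n

    def phi_f(self) -> np.ndarray:
        """Activated fraction; 0 where no platelets are present."""
        total = self.total_platelets
        out = np.zeros_like(self.phi_a)
        np.divide(self.phi_a, total, out=out, where=total > 0)
        return out

    def copy(self) -> "SpeciesState":
        return SpeciesState(self.phi_a.copy(), self.phi_n.copy(), self.adp.copy())


@dataclass(frozen=True)
class ModelParameters:
    """Baseline model constants and solver controls.

    The species / kinetics defaults are the published baseline parameter set
    of the activation model: platelet diffusivities ``D_a``, ``D_n``
    (1.58e-11 m^2 s^-1), an effectively advection-only ADP diffusivity
    ``D_ADP`` (1e-20 m^2 s^-1), the ADP release per activation ``R_ADP``
    (3e-17 mol), the chemical threshold ``ADP_t`` (2e-3 mol m^-3) with
    characteristic time ``t_ADP`` (1 s), the shear power-law constants
    ``C``, ``alpha``, ``beta`` (calibrated for tau in Pa, rates in s^-1),
    and a background platelet pool split into 25e12 m^-3 activated and
    475e12 m^-3 non-activated.
    """

    # kinetics / transport constants
    D_a: float = 1.58e-11
    D_n: float = 1.58e-11
    D_ADP: float = 1e-20
    R_ADP: float = 3e-17
    ADP_t: float = 2e-3
    t_ADP: float = 1.0
    C: float = 1.4854e-7
    alpha: float = 1.4854
    beta: float = 1.4401
    phi_a0: float = 25e12
    phi_b0: float = 475e12
    # stress evaluation mode
    use_reynolds_stress: bool = False
    # solver controls
    dt: float = 1.0
    stabilization_tol: float = 1e-6
    consecutive_steps: int = 5
    max_steps: int = 500
    substep_max_frac: float = 0.1
    max_substeps: int = 100
    phi_f_tol: float = 1e-9
    adp_inlet: float = 0.0
    negativity_tol: float = 1e-6

    def __post_init__(self):
        positive = (
            "D_a", "D_n", "D_ADP", "R_ADP", "ADP_t", "t_ADP",
            "C", "alpha", "beta", "dt",
        )
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValidationError(f"parameter {name} must be positive, got {getattr(self, name)}")
        if self.phi_a0 < 0 or self.phi_b0 < 0 or self.phi_a0 + self.phi_b0 <= 0:
            raise ValidationError("initial platelet concentrations must be non-negative with positive total")
        if not (0 < self.substep_max_frac <= 1):
            raise ValidationError("substep_max_frac must lie in (0, 1]")
        if self.max_substeps < 1 or self.max_steps < 1 or self.consecutive_steps < 1:
            raise ValidationError("iteration counts must be at least 1")

    @property
    def total_platelets0(self) -> float:
        """Total background platelet concentration (m^-3)."""
        return self.phi_a0 + self.phi_b0

    def with_(self, **kwargs) -> "ModelParameters":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


@dataclass
class RegionMask:
    """Per-cell integer region labels with human-readable names.

    Label 0 means "unassigned"; every non-zero label that occurs must have a
    name and a non-empty cell set.
    """

    labels: np.ndarray
    names: Dict[int, str] = field(default_factory=dict)

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        if np.any(self.labels < 0):
            raise ValidationError("region ids must be non-negative")
        present = set(np.unique(self.labels)) - {0}
        missing = present - set(self.names)
        if missing:
            raise ValidationError(f"region ids without names: {sorted(missing)}")
        for rid in self.names:
            if rid <= 0:
                raise ValidationError(f"named region ids must be positive, got {rid}")
            if not np.any(self.labels == rid):
                raise ValidationError(f"region {rid} ({self.names[rid]}) has no cells")

    @property
    def region_ids(self):
        return sorted(self.names)

    def mask(self, rid: int) -> np.ndarray:
        return self.labels == rid

    def volumes(self, grid: StructuredGrid2D) -> Dict[int, float]:
        """Region volumes per unit depth; strictly positive for named regions."""
        return {rid: float(np.count_nonzero(self.mask(rid))) * grid.cell_volume
                for rid in self.region_ids}


class DivergenceCheck(NamedTuple):
    """Result of :func:`check_divergence`."""

    max_divergence: float  # s^-1
    threshold: float       # s^-1
    passed: bool


def check_divergence(grid: StructuredGrid2D, flow: FlowField, tol: float = 1e-10) -> DivergenceCheck:
    """Maximum absolute central-difference divergence over interior cells.

    Species conservation presupposes a divergence-free carrier field, so the
    check guards every synthetic or imported flow before transport.  The
    pass/fail threshold is ``tol * max(|u|, |v|) / min(dx, dy)``, i.e. a
    dimensionless tolerance scaled to the velocity-gradient magnitude the
    field could plausibly carry.
    """
    flow.validate(grid)
    u, v = flow.u, flow.v
    div = (u[1:-1, 2:] - u[1:-1, :-2]) / (2.0 * grid.dx) \
        + (v[2:, 1:-1] - v[:-2, 1:-1]) / (2.0 * grid.dy)
    max_div = float(np.max(np.abs(div))) if div.size else 0.0
    vmax = max(float(np.max(np.abs(u))), float(np.max(np.abs(v))))
    threshold = tol * vmax / min(grid.dx, grid.dy)
    return DivergenceCheck(max_div, threshold, max_div <= threshold)


def uniform_state(grid: StructuredGrid2D, params: ModelParameters) -> SpeciesState:
    """Species field initialized uniformly at the background values.

    Mirrors initializing the transport stage from a converged steady flow:
    platelets at the background split, no free ADP.
    """
    return SpeciesState(
        phi_a=np.full(grid.shape, params.phi_a0),
        phi_n=np.full(grid.shape, params.phi_b0),
        adp=np.zeros(grid.shape),
    )
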