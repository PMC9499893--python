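"""Velocity gradients, stress tensors and the scalar shear stress.

Mechanical platelet activation is driven by a single frame-invariant scalar
built from the stress tensor,

    tau = (1/sqrt(3)) * sqrt( sxx^2 + syy^2 + szz^2
                              - sxx*syy - sxx*szz - syy*szz
                              + 3*(sxy^2 + sxz^2 + syz^2) ),

which equals ``sqrt(3 J2)`` with ``J2`` the second invariant of the
deviatoric part — isotropic contributions (such as the turbulent-kinetic-
energy term of the Boussinesq closure) cannot change it.

Two stress evaluations are provided: the purely viscous tensor
``mu * (du_i/dx_j + du_j/dx_i)`` and the total tensor augmenting it with the
Boussinesq Reynolds-stress closure
``(mu + mu_t) * (du_i/dx_j + du_j/dx_i) - (2/3) rho k delta_ij``.
The 2D fields are embedded in the 3D formulas with ``w = 0`` and all
z-derivatives zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fields import FlowField, StructuredGrid2D

__all__ = [
    "VelocityGradients",
    "StressTensorField",
    "velocity_gradients",
    "viscous_stress",
    "total_stress",
    "scalar_shear_stress",
    "scalar_stress_field",
]


@dataclass
class VelocityGradients:
    """Cell-centered velocity gradients (s^-1); z-derivatives are zero."""

    dudx: np.ndarray
    dudy: np.ndarray
    dvdx: np.ndarray
    dvdy: np.ndarray


@dataclass
class StressTensorField:
    """Symmetric stress tensor per cell (Pa); six stored components."""

    sxx: np.ndarray
    syy: np.ndarray
    szz: np.ndarray
    sxy: np.ndarray
    sxz: np.ndarray
    syz: np.ndarray

    @classmethod
    def zeros(cls, shape):
        return cls(*(np.zeros(shape) for _ in range(6)))


def velocity_gradients(grid: StructuredGrid2D, flow: FlowField) -> VelocityGradients:
    """Second-order central differences on interior cells, first-order
    one-sided at boundaries."""
    flow.validate(grid)
    dudy, dudx = np.gradient(flow.u, grid.dy, grid.dx, edge_order=1)
    dvdy, dvdx = np.gradient(flow.v, grid.dy, grid.dx, edge_order=1)
    return VelocityGradients(dudx=dudx, dudy=dudy, dvdx=dvdx, dvdy=dvdy)


def viscous_stress(gradients: VelocityGradients, mu: np.ndarray) -> StressTensorField:
    """Viscous stress ``sigma_ij = mu (du_i/dx_j + du_j/dx_i)`` per cell."""
    mu = np.asarray(mu, dtype=float)
    zero = np.zeros_like(gradients.dudx)
    return StressTensorField(
        sxx=2.0 * mu * gradients.dudx,
        syy=2.0 * mu * gradients.dvdy,
        szz=zero.copy(),
        sxy=mu * (gradients.dudy + gradients.dvdx),
        sxz=zero.copy(),
        syz=zero.copy(),
    )


def total_stress(gradients: VelocityGradients, mu, mu_t, rho: float, k) -> StressTensorField:
    """Total stress: viscous plus Boussinesq Reynolds part.

    ``sigma_ij = (mu + mu_t)(du_i/dx_j + du_j/dx_i) - (2/3) rho k delta_ij``.
    """
    mu_eff = np.asarray(mu, dtype=float) + np.asarray(mu_t, dtype=float)
    iso = (2.0 / 3.0) * rho * np.asarray(k, dtype=float)
    zero = np.zeros_like(gradients.dudx)
    return StressTensorField(
        sxx=2.0 * mu_eff * gradients.dudx - iso,
        syy=2.0 * mu_eff * gradients.dvdy - iso,
        szz=np.zeros_like(gradients.dudx) - iso,
        sxy=mu_eff * (gradients.dudy + gradients.dvdx),
        sxz=zero.copy(),
        syz=zero.copy(),
    )


def scalar_shear_stress(tensor: StressTensorField) -> np.ndarray:
    """Scalar shear stress tau (Pa), non-negative.

    The radicand is floored at zero before the square root; negative values
    can only arise from floating-point cancellation.
    """
    sxx, syy, szz = tensor.sxx, tensor.syy, tensor.szz
    radicand = (
        sxx**2 + syy**2 + szz**2
        - sxx * syy - sxx * szz - syy * szz
        + 3.0 * (tensor.sxy**2 + tensor.sxz**2 + tensor.syz**2)
    )
    return np.sqrt(np.clip(radicand, 0.0, None) / 3.0)


def scalar_stress_field(grid: StructuredGrid2D, flow: FlowField,
                        use_reynolds_stress: bool = False) -> np.ndarray:
    """Per-cell tau from a flow field, viscous-only or Reynolds-augmented."""
    grads = velocity_gradients(grid, flow)
    if use_reynolds_stress:
        tensor = total_stress(grads, flow.mu, flow.mu_t, flow.rho, flow.k)
    else:
        tensor = viscous_stress(grads, flow.mu)
    return scalar_shear_stress(tensor)
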