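"""Platelet-activation kinetics: mechanical and chemical rates, reaction
source terms and a well-mixed (0D) reference integrator.

Activation converts non-activated platelets (phi_n) into activated ones
(phi_a) and releases ADP.  Two cues contribute:

* mechanical — a shear power law in the scalar shear stress tau and the
  activated fraction phi_f = phi_a / (phi_a + phi_n):

      A_M(phi_f, tau) = (1 - phi_f) * C**(1/beta) * beta
                        * phi_f**((beta-1)/beta) * tau**(alpha/beta)

  with constants calibrated for tau in Pa and A_M in s^-1;

* chemical — a threshold switch on the ADP concentration:

      A_C(ADP) = ADP / (ADP_t * t_ADP)   if ADP >= ADP_t, else 0.

The combined volumetric sources are

      S_a  =  A_C * phi_n + A_M * (phi_a + phi_n)  =  -S_n,
      S_adp = R_ADP * S_a,

so activation conserves total platelets exactly and ties the ADP release
stoichiometrically to the number of activations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ModelCollapseError, ParameterDomainError, ValidationError
from .fields import ModelParameters, SpeciesState

__all__ = [
    "SourceTerms",
    "mechanical_activation_rate",
    "chemical_activation_rate",
    "reaction_sources",
    "advance_reactions",
    "integrate_wellmixed",
    "WellMixedTrajectory",
]


@dataclass
class SourceTerms:
    """Reaction source rates with the mechanical/chemical decomposition.

    ``S_n = -S_a`` and ``S_adp = R_ADP * S_a`` hold exactly;
    ``S_a = A_M_part + A_C_part`` with both parts non-negative.
    """

    S_a: np.ndarray       # m^-3 s^-1
    S_n: np.ndarray       # m^-3 s^-1
    S_adp: np.ndarray     # mol m^-3 s^-1
    A_M_part: np.ndarray  # m^-3 s^-1
    A_C_part: np.ndarray  # m^-3 s^-1


def _activated_fraction(phi_a, phi_n, tol: float):
    """phi_f clamped to [0, 1] within ``tol``; beyond that the state is invalid.

    Cells with no platelets at all get phi_f = 0 (they produce no sources);
    the count of such cells is returned for diagnostics.
    """
    total = phi_a + phi_n
    empty = total <= 0
    phi_f = np.zeros_like(total, dtype=float)
    np.divide(phi_a, total, out=phi_f, where=~empty)
    if np.any(phi_f < -tol) or np.any(phi_f > 1 + tol):
        worst = float(np.max(np.abs(phi_f - np.clip(phi_f, 0.0, 1.0))))
        raise ModelCollapseError(
            f"activated fraction left [0, 1] by {worst:.3e} (tolerance {tol:.1e})"
        )
    return np.clip(phi_f, 0.0, 1.0), int(np.count_nonzero(empty))


def mechanical_activation_rate(phi_a, phi_n, tau, params: ModelParameters):
    """Shear power-law activation rate A_M (s^-1).

    Zero when tau = 0, when phi_f = 0 (requires ``(beta-1)/beta > 0`` for the
    power law to be regular there) and when phi_f = 1 (no platelets left to
    activate).
    """
    phi_a = np.asarray(phi_a, dtype=float)
    phi_n = np.asarray(phi_n, dtype=float)
    tau = np.asarray(tau, dtype=float)
    if np.any(tau < 0):
        raise ValidationError("scalar shear stress must be non-negative")
    phi_f, _ = _activated_fraction(phi_a, phi_n, params.phi_f_tol)
    exp_f = (params.beta - 1.0) / params.beta
    if exp_f <= 0 and np.any(phi_f == 0):
        raise ParameterDomainError(
            f"power law singular at phi_f = 0 for beta = {params.beta} ((beta-1)/beta <= 0)"
        )
    prefactor = params.C ** (1.0 / params.beta) * params.beta
    return (1.0 - phi_f) * prefactor * phi_f**exp_f * tau ** (params.alpha / params.beta)


def chemical_activation_rate(adp, params: ModelParameters):
    """Threshold-based chemical activation rate A_C (s^-1).

    ``A_C = ADP / (ADP_t * t_ADP)`` once ADP reaches the threshold ``ADP_t``,
    zero below it — a switch-like response that jumps to ``1/t_ADP`` at the
    threshold.
    """
    adp = np.asarray(adp, dtype=float)
    if np.any(adp < 0):
        raise ValidationError("ADP concentration must be non-negative")
    return np.where(adp >= params.ADP_t, adp / (params.ADP_t * params.t_ADP), 0.0)


def reaction_sources(state: SpeciesState, tau, params: ModelParameters) -> SourceTerms:
    """Source terms of the three species equations at the given state."""
    A_M = mechanical_activation_rate(state.phi_a, state.phi_n, tau, params)
    A_C = chemical_activation_rate(state.adp, params)
    A_C_part = A_C * state.phi_n
    A_M_part = A_M * (state.phi_a + state.phi_n)
    S_a = A_M_part + A_C_part
    return SourceTerms(S_a=S_a, S_n=-S_a, S_adp=params.R_ADP * S_a,
                       A_M_part=A_M_part, A_C_part=A_C_part)


def advance_reactions(state: SpeciesState, tau, params: ModelParameters, window: float):
    """Advance the reaction ODEs explicitly over one time window.

    Sub-steps are sized so that no species changes by more than
    ``params.substep_max_frac`` of its current value per sub-step, up to a
    budget of ``params.max_substeps`` sub-steps per window.  If the budget is
    exhausted the remainder of the window is taken in a single uncapped
    step; sources too stiff for the budget then drive the activated fraction
    out of [0, 1], which raises :class:`ModelCollapseError` — the physical
    failure mode of an explicit source treatment rather than a silently
    wrong answer.

    Returns ``(new_state, am_integral, ac_integral)`` where the integrals
    are the per-cell time-integrated mechanical and chemical contributions
    to S_a over the window (m^-3).
    """
    if window <= 0:
        raise ValidationError(f"reaction window must be positive, got {window}")
    phi_a = np.array(state.phi_a, dtype=float)
    phi_n = np.array(state.phi_n, dtype=float)
    adp = np.array(state.adp, dtype=float)
    tau = np.asarray(tau, dtype=float)
    am_int = np.zeros_like(phi_a)
    ac_int = np.zeros_like(phi_a)

    t = 0.0
    eps = 1e-12 * window
    for _ in range(params.max_substeps):
        if t >= window - eps:
            break
        src = reaction_sources(SpeciesState(phi_a, phi_n, adp), tau, params)
        # stiffest relative rate over all cells and species (s^-1); ADP is
        # measured against max(adp, ADP_t/2) so that its growth is resolved
        # where it feeds back into the chemical rate but harmless growth far
        # below the threshold does not throttle the step
        with np.errstate(divide="ignore", invalid="ignore"):
            rel = np.maximum(
                np.where(phi_n > 0, src.S_a / phi_n, 0.0),
                np.where(phi_a > 0, src.S_a / phi_a, 0.0),
            )
            rel = np.maximum(rel, src.S_adp / np.maximum(adp, 0.5 * params.ADP_t))
        max_rel = float(np.max(rel)) if rel.size else 0.0
        if max_rel <= 0:
            dt_sub = window - t
        else:
            dt_sub = min(window - t, params.substep_max_frac / max_rel)
        phi_a += dt_sub * src.S_a
        phi_n += dt_sub * src.S_n
        adp += dt_sub * src.S_adp
        am_int += dt_sub * src.A_M_part
        ac_int += dt_sub * src.A_C_part
        t += dt_sub
    if t < window - eps:
        # sub-step budget exhausted: take the remainder in one uncapped step
        src = reaction_sources(SpeciesState(phi_a, phi_n, adp), tau, params)
        dt_sub = window - t
        phi_a += dt_sub * src.S_a
        phi_n += dt_sub * src.S_n
        adp += dt_sub * src.S_adp
        am_int += dt_sub * src.A_M_part
        ac_int += dt_sub * src.A_C_part
    # validity check (raises ModelCollapseError on violation)
    _activated_fraction(phi_a, phi_n, params.phi_f_tol)
    phi_a = np.clip(phi_a, 0.0, None)
    phi_n = np.clip(phi_n, 0.0, None)
    adp = np.clip(adp, 0.0, None)
    return SpeciesState(phi_a, phi_n, adp), am_int, ac_int


@dataclass
class WellMixedTrajectory:
    """Time series of a 0D (transport-free) integration."""

    t: np.ndarray
    phi_a: np.ndarray
    phi_n: np.ndarray
    adp: np.ndarray

    def final_state(self) -> SpeciesState:
        return SpeciesState(np.array(self.phi_a[-1]), np.array(self.phi_n[-1]),
                            np.array(self.adp[-1]))


def integrate_wellmixed(state0: SpeciesState, tau: float, params: ModelParameters,
                        t_end: float, dt: float) -> WellMixedTrajectory:
    """Integrate the reaction system with transport removed (well-mixed cell).

    Serves as the stoichiometry testbed and as a reference for the spatial
    solver: d(phi_a)/dt = S_a, d(phi_n)/dt = S_n, d(ADP)/dt = S_adp at
    constant tau.  States are recorded every ``dt``; within each window the
    sub-step limiter of :func:`advance_reactions` applies.
    """
    if dt <= 0:
        raise ValidationError(f"dt must be positive, got {dt}")
    if t_end < dt:
        raise ValidationError(f"t_end must be at least dt, got t_end={t_end}, dt={dt}")
    state = SpeciesState(np.atleast_1d(np.asarray(state0.phi_a, dtype=float)).copy(),
                         np.atleast_1d(np.asarray(state0.phi_n, dtype=float)).copy(),
                         np.atleast_1d(np.asarray(state0.adp, dtype=float)).copy())
    state.validate()
    n_steps = int(round(t_end / dt))
    ts = [0.0]
    pa = [float(state.phi_a[0])]
    pn = [float(state.phi_n[0])]
    ad = [float(state.adp[0])]
    for n in range(n_steps):
        state, _, _ = advance_reactions(state, tau, params, dt)
        ts.append((n + 1) * dt)
        pa.append(float(state.phi_a[0]))
        pn.append(float(state.phi_n[0]))
        ad.append(float(state.adp[0]))
    return WellMixedTrajectory(np.array(ts), np.array(pa), np.array(pn), np.array(ad))
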