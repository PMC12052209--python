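"""Deterministic rate laws of the two-gene inhibition cascade.

Species order everywhere is ``(m1, p1, m2, p2)``: mRNA and protein of the
inhibiting gene (GFP), then of the inhibited gene (RFP).

Production under finite machinery is modeled with partition-function
denominators ``1 + sum_j demand_j / capacity_j``; the basal and induced
transcription terms share one denominator, matching the closed-form steady
states ``<m_i> = (km0_i + km_i R_i) / (dm_i (1 + sum_j R_j/Jm_j))``.
"""

from __future__ import annotations

import numpy as np

from .params import CircuitParams, ConcentrationState, ResourceMode

__all__ = [
    "regulatory_input",
    "transcription_denominators",
    "translation_denominators",
    "ode_rhs",
    "steady_state_closed_form",
    "count_gain_fluxes",
    "count_loss_fluxes",
]


def regulatory_input(params: CircuitParams, p1: float, gene: int) -> float:
    """Transcriptional activity R_gene.

    Gene 1 is driven only by its inducer: ``R1 = I1``.  Gene 2 is driven by
    its inducer and repressed by GFP protein through an inhibitory Hill
    function: ``R2 = I2 * Kg^n / (p1^n + Kg^n)``.
    """
    p1 = float(p1)
    if np.isnan(p1) or p1 < 0:
        raise ValueError(f"p1 must be a non-negative number, got {p1}")
    if gene == 1:
        return params.I1
    if gene == 2:
        kgn = params.Kg ** params.n
        return params.I2 * kgn / (p1 ** params.n + kgn)
    raise ValueError(f"gene must be 1 or 2, got {gene}")


def _hill(params: CircuitParams, p1):
    """Vectorized inhibitory Hill factor Kg^n / (p1^n + Kg^n)."""
    kgn = params.Kg ** params.n
    return kgn / (np.asarray(p1, dtype=float) ** params.n + kgn)


def transcription_denominators(params: CircuitParams, mode: ResourceMode, R1, R2):
    """Partition-function denominators of the two transcription rates."""
    mode = ResourceMode.coerce(mode)
    if mode is ResourceMode.UNLIMITED:
        one = np.ones_like(np.asarray(R2, dtype=float))
        return one, one
    if mode is ResourceMode.SHARED:
        den = 1.0 + R1 / params.Jm1 + R2 / params.Jm2
        return den, den
    return 1.0 + R1 / params.Jm1, 1.0 + R2 / params.Jm2


def translation_denominators(params: CircuitParams, mode: ResourceMode, m1, m2):
    """Partition-function denominators of the two translation rates."""
    mode = ResourceMode.coerce(mode)
    if mode is ResourceMode.UNLIMITED:
        one = np.ones_like(np.asarray(m1, dtype=float) * np.asarray(m2, dtype=float))
        return one, one
    if mode is ResourceMode.SHARED:
        den = 1.0 + m1 / params.Jp1 + m2 / params.Jp2
        return den, den
    return 1.0 + m1 / params.Jp1, 1.0 + m2 / params.Jp2


def ode_rhs(state, params: CircuitParams, mode: ResourceMode) -> np.ndarray:
    """Time derivatives (dm1, dp1, dm2, dp2) at a concentration state.

    ``state`` may be a :class:`ConcentrationState` or any length-4 array-like.
    NaN entries are rejected; tiny negative excursions (as produced by stiff
    ODE steppers) are tolerated.
    """
    mode = ResourceMode.coerce(mode)
    if isinstance(state, ConcentrationState):
        state = state.to_array()
    x = np.asarray(state, dtype=float)
    if x.shape != (4,):
        raise ValueError(f"state must have 4 entries, got shape {x.shape}")
    if np.any(np.isnan(x)):
        raise ValueError("NaN in state")
    m1, p1, m2, p2 = x
    R1 = params.I1
    R2 = params.I2 * _hill(params, max(p1, 0.0))
    den_m1, den_m2 = transcription_denominators(params, mode, R1, R2)
    den_p1, den_p2 = translation_denominators(params, mode, m1, m2)
    return np.array(
        [
            (params.km01 + params.km1 * R1) / den_m1 - params.dm1 * m1,
            params.kp1 * m1 / den_p1 - params.dp1 * p1,
            (params.km02 + params.km2 * R2) / den_m2 - params.dm2 * m2,
            params.kp2 * m2 / den_p2 - params.dp2 * p2,
        ]
    )


def steady_state_closed_form(
    params: CircuitParams, mode: ResourceMode
) -> ConcentrationState:
    """Closed-form steady state for the uncoupled (unlimited/orthogonal) regimes.

    Gene 1 is self-contained, so its means follow directly; gene 2's means
    then follow by substituting R2(p1).  The shared regime couples the genes
    through the partition functions and has no closed form — use
    :func:`rcnoise.bifurcation.find_steady_states` instead.
    """
    mode = ResourceMode.coerce(mode)
    if mode is ResourceMode.SHARED:
        raise ValueError(
            "no closed-form steady state for shared resources; "
            "use rcnoise.bifurcation.find_steady_states"
        )
    R1 = params.I1
    if mode is ResourceMode.UNLIMITED:
        m1 = (params.km01 + params.km1 * R1) / params.dm1
        p1 = params.kp1 * m1 / params.dp1
        R2 = params.I2 * _hill(params, p1)
        m2 = (params.km02 + params.km2 * R2) / params.dm2
        p2 = params.kp2 * m2 / params.dp2
    else:  # ORTHOGONAL: self-saturation only, still explicit
        m1 = (params.km01 + params.km1 * R1) / (
            params.dm1 * (1.0 + R1 / params.Jm1)
        )
        p1 = params.kp1 * m1 / (params.dp1 * (1.0 + m1 / params.Jp1))
        R2 = params.I2 * _hill(params, p1)
        m2 = (params.km02 + params.km2 * R2) / (
            params.dm2 * (1.0 + R2 / params.Jm2)
        )
        p2 = params.kp2 * m2 / (params.dp2 * (1.0 + m2 / params.Jp2))
    return ConcentrationState(float(m1), float(p1), float(m2), float(p2))


def count_gain_fluxes(
    counts, params: CircuitParams, mode: ResourceMode
) -> np.ndarray:
    """Production fluxes (molecules/time) at a count state (M1, P1, M2, P2).

    These are the concentration-space production rates evaluated at
    ``X / Omega`` and multiplied by ``Omega`` — the system-size convention
    under which the stochastic model reduces to the deterministic one.
    """
    mode = ResourceMode.coerce(mode)
    X = np.asarray(counts, dtype=float)
    om = params.Omega
    m1, p1, m2 = X[0] / om, X[1] / om, X[2] / om
    R1 = params.I1
    R2 = params.I2 * _hill(params, p1)
    den_m1, den_m2 = transcription_denominators(params, mode, R1, R2)
    den_p1, den_p2 = translation_denominators(params, mode, m1, m2)
    return np.array(
        [
            om * (params.km01 + params.km1 * R1) / den_m1,
            om * params.kp1 * m1 / den_p1,
            om * (params.km02 + params.km2 * R2) / den_m2,
            om * params.kp2 * m2 / den_p2,
        ]
    )


def count_loss_fluxes(counts, params: CircuitParams) -> np.ndarray:
    """First-order loss fluxes d_i * X_i (molecules/time)."""
    X = np.asarray(counts, dtype=float)
    rates = np.array([params.dm1, params.dp1, params.dm2, params.dp2])
    return rates * X
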