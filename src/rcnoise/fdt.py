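"""Analytical stationary noise from the normalized fluctuation-dissipation
relation, and its cascade decomposition into source-attributed components.

Conventions
-----------
Species indices 1..4 are (m1, p1, m2, p2).  Lifetimes are tau_i = 1/d_i.
The susceptibility H_ij is the logarithmic derivative of the loss/gain flux
ratio of species i with respect to species j at the stationary means; the
normalized drift matrix is A_ij = -H_ij / tau_i (diagonal -1/tau_i), and
the stationary normalized covariance eta solves

    A eta + eta A^T + D = 0,    D_ii = 2 / (tau_i <N_i>).

The diffusion reading D_ii = 2/(tau_i <N_i>) is forced by the Poisson limit
eta_11 = 1/<M1> for an isolated birth-death species.

The closed-form decomposition below is the exact recursive solution of that
Lyapunov equation for the lower-triangular cascade; components therefore
sum to the Lyapunov diagonal to machine precision.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.linalg import solve_lyapunov

from .model import count_gain_fluxes, count_loss_fluxes, steady_state_closed_form
from .params import CircuitParams, ResourceMode

__all__ = [
    "SusceptibilityMatrix",
    "FDTMatrices",
    "NoiseDecomposition",
    "stationary_means",
    "susceptibilities",
    "fdt_matrices",
    "lyapunov_noise",
    "decompose_noise",
    "noise_curves",
]

_ANALYTIC_MODES = (ResourceMode.UNLIMITED, ResourceMode.ORTHOGONAL)


@dataclass(frozen=True)
class SusceptibilityMatrix:
    H: np.ndarray  # 4x4
    tau: np.ndarray  # lifetimes (tau1..tau4)
    means: np.ndarray  # stationary molecule counts (M1, P1, M2, P2)


@dataclass(frozen=True)
class FDTMatrices:
    A: np.ndarray  # normalized drift, A_ij = -H_ij / tau_i
    D: np.ndarray  # diagonal diffusion, D_ii = 2/(tau_i <N_i>)


@dataclass(frozen=True)
class NoiseDecomposition:
    """Total eta^2 per species plus named propagated components.

    Component keys use the arrow convention, e.g. ``"p2<-m2<-p1"`` for noise
    originating in p1 and reaching p2 through m2.
    """

    totals: dict[str, float]
    components: dict[str, dict[str, float]]

    def total(self, species: str) -> float:
        return self.totals[species]


def stationary_means(
    params: CircuitParams, mode: ResourceMode, means: Optional[np.ndarray] = None
) -> np.ndarray:
    """Omega-scaled stationary counts; closed form unless supplied."""
    if means is not None:
        return np.asarray(means, dtype=float)
    mode = ResourceMode.coerce(mode)
    if mode in _ANALYTIC_MODES:
        ss = steady_state_closed_form(params, mode)
    else:
        from .bifurcation import find_steady_states

        stable = [p for p in find_steady_states(params, mode) if p.stable]
        if len(stable) != 1:
            raise ValueError(
                "shared-mode means are ambiguous (not exactly one stable state); "
                "pass `means` explicitly"
            )
        ss = stable[0].state
    return ss.to_array() * params.Omega


def susceptibilities(
    params: CircuitParams,
    mode: ResourceMode,
    means: Optional[np.ndarray] = None,
) -> SusceptibilityMatrix:
    """H matrix, lifetimes, and stationary counts.

    Off-diagonal entries are central log-space finite differences of
    ln(J_i^- / J_i^+) in ln(X_j) (relative step 1e-6).  Diagonals are exactly
    1 in the unlimited and orthogonal regimes (the gain flux of a species
    never depends on that species itself), and are likewise computed
    numerically for any other case.
    """
    mode = ResourceMode.coerce(mode)
    N = stationary_means(params, mode, means)
    if np.any(N <= 0):
        raise ValueError("zero stationary mean count: log-derivative undefined")
    tau = 1.0 / np.array([params.dm1, params.dp1, params.dm2, params.dp2])

    def log_ratio(X: np.ndarray) -> np.ndarray:
        return np.log(count_loss_fluxes(X, params) / count_gain_fluxes(X, params, mode))

    if mode in _ANALYTIC_MODES:
        H = _analytic_H(params, mode, N)
    else:
        H = np.zeros((4, 4))
        rel = 1e-6
        for j in range(4):
            Xp, Xm = N.copy(), N.copy()
            Xp[j] = N[j] * (1.0 + rel)
            Xm[j] = N[j] * (1.0 - rel)
            dlnx = np.log(Xp[j]) - np.log(Xm[j])
            H[:, j] = (log_ratio(Xp) - log_ratio(Xm)) / dlnx
    return SusceptibilityMatrix(H=H, tau=tau, means=N)


def _analytic_H(params: CircuitParams, mode: ResourceMode, N: np.ndarray) -> np.ndarray:
    """Exact susceptibilities for the uncoupled (cascade-patterned) regimes.

    Diagonals are 1 (no gain flux depends on its own species).  Translation
    couplings are -1, damped by the self-saturation factor 1/(1 + m_i/Jp_i)
    in the orthogonal case.  H32 follows from the log-derivative of the
    Hill-driven transcription gain of gene 2.
    """
    om = params.Omega
    m1, p1, m2 = N[0] / om, N[1] / om, N[2] / om
    orth = mode is ResourceMode.ORTHOGONAL
    H = np.eye(4)
    H[1, 0] = -1.0 / (1.0 + m1 / params.Jp1) if orth else -1.0
    H[3, 2] = -1.0 / (1.0 + m2 / params.Jp2) if orth else -1.0
    kgn = params.Kg ** params.n
    hill_p = p1 ** params.n / (p1 ** params.n + kgn)  # d ln R2 / d ln p1 = -n*hill_p
    R2 = params.I2 * kgn / (p1 ** params.n + kgn)
    h32 = params.n * hill_p * params.km2 * R2 / (params.km02 + params.km2 * R2)
    if orth:
        h32 -= params.n * hill_p * R2 / (params.Jm2 + R2)
    H[2, 1] = h32
    return H


def fdt_matrices(
    params: CircuitParams,
    mode: ResourceMode,
    means: Optional[np.ndarray] = None,
) -> FDTMatrices:
    sus = susceptibilities(params, mode, means)
    A = -sus.H / sus.tau[:, None]
    D = np.diag(2.0 / (sus.tau * sus.means))
    return FDTMatrices(A=A, D=D)


def lyapunov_noise(
    params: CircuitParams,
    mode: ResourceMode,
    means: Optional[np.ndarray] = None,
    allow_shared_lna: bool = False,
) -> np.ndarray:
    """Stationary normalized covariance; diagonal = total eta^2 per species.

    Exact (within the normalized-FDT framework) for the unlimited and
    orthogonal regimes.  For shared resources there is no tractable
    analytical solution; pass ``allow_shared_lna=True`` to evaluate the same
    machinery as a linear-noise approximation, clearly labeled as such.
    """
    mode = ResourceMode.coerce(mode)
    if mode is ResourceMode.SHARED and not allow_shared_lna:
        raise ValueError(
            "no analytical shared-mode solution; set allow_shared_lna=True for "
            "a linear-noise approximation, or use SSA statistics"
        )
    mats = fdt_matrices(params, mode, means)
    eig = np.linalg.eigvals(mats.A)
    if np.any(eig.real >= 0):
        raise ValueError("drift matrix is not Hurwitz: unstable stationary point")
    eta = solve_lyapunov(mats.A, -mats.D)
    return 0.5 * (eta + eta.T)


def decompose_noise(
    params: CircuitParams,
    mode: ResourceMode,
    means: Optional[np.ndarray] = None,
) -> NoiseDecomposition:
    """Closed-form source decomposition of every species' stationary noise.

    Writing a_i = 1/tau_i, the recursion down the cascade gives (with
    T_down(i) = H^2 * a_i/(a_{i-1}+a_i) the time-averaging transfer factor):

      eta2(m1) = 1/M1
      eta2(p1) = 1/P1 + (1/M1) H21^2 a2/(a1+a2)
      eta2(m2) = 1/M2 + [eta_p1<-p1 + eta_p1<-m1 (1 + a2/(a1+a3))]
                  * H32^2 a3/(a2+a3)       (split by source)
      eta2(p2) = 1/P2 + eta_m2<-m2 T + eta_m2<-p1 (1 + a3/(a2+a4)) T
                  + eta_m2<-p1<-m1 (1 + a3/(a2+a4)
                      (1 + a2/(a1+a2+a3) * (a2+a3)/(a1+a4))) T,
                  T = H43^2 a4/(a3+a4)

    These are the exact recursive solutions of the cascade Lyapunov
    equation, so components sum to :func:`lyapunov_noise` diagonals to
    machine precision.
    """
    mode = ResourceMode.coerce(mode)
    if mode is ResourceMode.SHARED:
        raise ValueError(
            "the cascade decomposition holds only for unlimited/orthogonal "
            "resources; shared-mode noise is estimated from SSA trajectories"
        )
    sus = susceptibilities(params, mode, means)
    M1, P1, M2, P2 = sus.means
    a1, a2, a3, a4 = 1.0 / sus.tau
    H21, H32, H43 = sus.H[1, 0], sus.H[2, 1], sus.H[3, 2]

    eta_p1_p1 = 1.0 / P1
    eta_p1_m1 = (1.0 / M1) * H21**2 * a2 / (a1 + a2)

    T23 = H32**2 * a3 / (a2 + a3)
    eta_m2_m2 = 1.0 / M2
    eta_m2_p1 = eta_p1_p1 * T23
    eta_m2_p1_m1 = eta_p1_m1 * (1.0 + a2 / (a1 + a3)) * T23

    T34 = H43**2 * a4 / (a3 + a4)
    eta_p2_p2 = 1.0 / P2
    eta_p2_m2 = eta_m2_m2 * T34
    eta_p2_m2_p1 = eta_m2_p1 * (1.0 + a3 / (a2 + a4)) * T34
    eta_p2_m2_p1_m1 = (
        eta_m2_p1_m1
        * (1.0 + (a3 / (a2 + a4)) * (1.0 + (a2 / (a1 + a2 + a3)) * (a2 + a3) / (a1 + a4)))
        * T34
    )

    components = {
        "m1": {"m1<-m1": 1.0 / M1},
        "p1": {"p1<-p1": eta_p1_p1, "p1<-m1": eta_p1_m1},
        "m2": {
            "m2<-m2": eta_m2_m2,
            "m2<-p1": eta_m2_p1,
            "m2<-p1<-m1": eta_m2_p1_m1,
        },
        "p2": {
            "p2<-p2": eta_p2_p2,
            "p2<-m2": eta_p2_m2,
            "p2<-m2<-p1": eta_p2_m2_p1,
            "p2<-m2<-p1<-m1": eta_p2_m2_p1_m1,
        },
    }
    totals = {sp: float(sum(terms.values())) for sp, terms in components.items()}
    return NoiseDecomposition(totals=totals, components=components)


def noise_curves(
    params: CircuitParams,
    mode: ResourceMode,
    doses: np.ndarray,
    dose_parameter: str = "I1",
) -> pd.DataFrame:
    """Tidy table of analytic noise components over a dose grid.

    Columns: dose parameter, species, component ('total' plus each named
    term), eta2.
    """
    rows = []
    for dose in np.asarray(doses, dtype=float):
        p = params.replace(**{dose_parameter: float(dose)})
        dec = decompose_noise(p, mode)
        for sp, terms in dec.components.items():
            rows.append(
                {dose_parameter: dose, "species": sp, "component": "total",
                 "eta2": dec.totals[sp]}
            )
            for name, val in terms.items():
                rows.append(
                    {dose_parameter: dose, "species": sp, "component": name,
                     "eta2": float(val)}
                )
    return pd.DataFrame(rows)
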