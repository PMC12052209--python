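"""Exact Gillespie simulation of the 8-reaction cascade in molecule counts.

Propensities are the deterministic production/loss fluxes evaluated at
concentrations ``X/Omega`` and multiplied by ``Omega`` (standard system-size
convention), so ensemble means track the ODE solution in the macroscopic
limit.  The direct method is used: exponential waiting times at the total
propensity, channel chosen proportionally.

The inner loop is compiled with numba; trajectories are sampled on a
regular grid (default dt = 0.1 lifetimes) to bound memory.  A given
(params, mode, seed, t_end, init) tuple reproduces bit-exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from numba import njit
from scipy.integrate import solve_ivp

from .model import count_gain_fluxes, count_loss_fluxes, ode_rhs
from .params import CircuitParams, CountState, ResourceMode

__all__ = [
    "ReactionChannel",
    "Trajectory",
    "build_propensities",
    "gillespie_run",
    "clamped_mean_run",
    "dose_sweep",
    "spawn_seed",
]

SPECIES = ("M1", "P1", "M2", "P2")

#: state-change vectors, channel order: (m1+, m1-, p1+, p1-, m2+, m2-, p2+, p2-)
STOICHIOMETRY = np.array(
    [
        [1, 0, 0, 0],
        [-1, 0, 0, 0],
        [0, 1, 0, 0],
        [0, -1, 0, 0],
        [0, 0, 1, 0],
        [0, 0, -1, 0],
        [0, 0, 0, 1],
        [0, 0, 0, -1],
    ],
    dtype=np.int64,
)

CHANNEL_LABELS = (
    "m1_birth", "m1_death", "p1_birth", "p1_death",
    "m2_birth", "m2_death", "p2_birth", "p2_death",
)


@dataclass(frozen=True)
class ReactionChannel:
    label: str
    change: np.ndarray
    propensity: Callable[[np.ndarray], float]


def build_propensities(
    params: CircuitParams,
    mode: ResourceMode,
    clamp: Optional[tuple[float, float]] = None,
) -> list[ReactionChannel]:
    """The 8 reaction channels as inspectable python callables.

    ``clamp = (M1_mean, M2_mean)``: inside gene i's translation partition
    function the *opposing* mRNA count is replaced by its clamped mean while
    every other occurrence stays live.  Only meaningful under shared
    resources.
    """
    mode = ResourceMode.coerce(mode)
    if clamp is not None and mode is not ResourceMode.SHARED:
        raise ValueError("clamping applies to the shared-resource mode only")

    def _check(X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if np.any(X < 0):
            raise ValueError("negative molecule count")
        return X

    def gain(i: int) -> Callable[[np.ndarray], float]:
        if clamp is None:
            return lambda X, i=i: float(count_gain_fluxes(_check(X), params, mode)[i])

        cM1, cM2 = clamp

        def g(X: np.ndarray, i=i) -> float:
            X = _check(X)
            if i == 1:  # gene-1 translation: clamp opposing mRNA M2
                Xc = X.copy()
                Xc[2] = cM2
                return float(count_gain_fluxes(Xc, params, mode)[i])
            if i == 3:  # gene-2 translation: clamp opposing mRNA M1
                Xc = X.copy()
                Xc[0] = cM1
                return float(count_gain_fluxes(Xc, params, mode)[i])
            return float(count_gain_fluxes(X, params, mode)[i])

        return g

    def loss(i: int) -> Callable[[np.ndarray], float]:
        return lambda X, i=i: float(count_loss_fluxes(_check(X), params)[i])

    channels = []
    for i in range(4):
        channels.append(
            ReactionChannel(CHANNEL_LABELS[2 * i], STOICHIOMETRY[2 * i], gain(i))
        )
        channels.append(
            ReactionChannel(CHANNEL_LABELS[2 * i + 1], STOICHIOMETRY[2 * i + 1], loss(i))
        )
    return channels


# ---------------------------------------------------------------------------
# compiled kernel

# theta layout matches params.PARAM_NAMES:
# 0 km01, 1 km1, 2 kp1, 3 dm1, 4 dp1, 5 I1, 6 Jm1, 7 Jp1,
# 8 km02, 9 km2, 10 kp2, 11 dm2, 12 dp2, 13 I2, 14 Jm2, 15 Jp2,
# 16 n, 17 Kg, 18 Omega


@njit(cache=True)
def _propensities(theta, mode, clampM1, clampM2, M1, P1, M2, P2, a):
    om = theta[18]
    R1 = theta[5]
    kgn = theta[17] ** theta[16]
    p1c = P1 / om
    R2 = theta[13] * kgn / (p1c ** theta[16] + kgn)
    if mode == 0:  # unlimited
        den_m1 = 1.0
        den_m2 = 1.0
        den_p1 = 1.0
        den_p2 = 1.0
    elif mode == 1:  # shared
        den_m1 = 1.0 + R1 / theta[6] + R2 / theta[14]
        den_m2 = den_m1
        m1c = M1 / om
        m2c = M2 / om
        if clampM1 >= 0.0:
            den_p1 = 1.0 + m1c / theta[7] + (clampM2 / om) / theta[15]
            den_p2 = 1.0 + (clampM1 / om) / theta[7] + m2c / theta[15]
        else:
            den = 1.0 + m1c / theta[7] + m2c / theta[15]
            den_p1 = den
            den_p2 = den
    else:  # orthogonal
        den_m1 = 1.0 + R1 / theta[6]
        den_m2 = 1.0 + R2 / theta[14]
        den_p1 = 1.0 + (M1 / om) / theta[7]
        den_p2 = 1.0 + (M2 / om) / theta[15]
    a[0] = om * (theta[0] + theta[1] * R1) / den_m1
    a[1] = theta[3] * M1
    a[2] = theta[2] * M1 / den_p1
    a[3] = theta[4] * P1
    a[4] = om * (theta[8] + theta[9] * R2) / den_m2
    a[5] = theta[11] * M2
    a[6] = theta[10] * M2 / den_p2
    a[7] = theta[12] * P2


@njit(cache=True)
def _ssa_core(theta, mode, clampM1, clampM2, x0, t_end, dt, seed):
    np.random.seed(seed)
    n_samples = int(np.floor(t_end / dt)) + 1
    out = np.zeros((n_samples, 4), dtype=np.int64)
    M1, P1, M2, P2 = x0[0], x0[1], x0[2], x0[3]
    out[0, 0], out[0, 1], out[0, 2], out[0, 3] = M1, P1, M2, P2
    a = np.zeros(8)
    t = 0.0
    isamp = 0
    while True:
        _propensities(theta, mode, clampM1, clampM2, M1, P1, M2, P2, a)
        atot = a[0] + a[1] + a[2] + a[3] + a[4] + a[5] + a[6] + a[7]
        if atot <= 0.0:
            break  # absorbing state: hold counts to t_end
        t_next = t - np.log(np.random.random()) / atot
        while isamp + 1 < n_samples and (isamp + 1) * dt <= t_next:
            isamp += 1
            out[isamp, 0], out[isamp, 1] = M1, P1
            out[isamp, 2], out[isamp, 3] = M2, P2
        if t_next >= t_end:
            t = t_end
            break
        t = t_next
        r = np.random.random() * atot
        acc = 0.0
        ch = 7
        for k in range(8):
            acc += a[k]
            if r < acc:
                ch = k
                break
        if ch == 0:
            M1 += 1
        elif ch == 1:
            M1 -= 1
        elif ch == 2:
            P1 += 1
        elif ch == 3:
            P1 -= 1
        elif ch == 4:
            M2 += 1
        elif ch == 5:
            M2 -= 1
        elif ch == 6:
            P2 += 1
        else:
            P2 -= 1
    while isamp + 1 < n_samples:
        isamp += 1
        out[isamp, 0], out[isamp, 1] = M1, P1
        out[isamp, 2], out[isamp, 3] = M2, P2
    return out


# ---------------------------------------------------------------------------
# trajectory container


@dataclass
class Trajectory:
    """Regularly-sampled SSA output with full provenance."""

    t: np.ndarray
    counts: np.ndarray  # (n_samples, 4) int64, columns = SPECIES
    params: CircuitParams
    mode: ResourceMode
    seed: int
    clamp: Optional[tuple[float, float]] = None
    burn_in_frac: float = 0.2

    def species(self, name: str) -> np.ndarray:
        return self.counts[:, SPECIES.index(name)]

    @property
    def burn_in_time(self) -> float:
        return self.burn_in_frac * float(self.t[-1])

    def stationary(self) -> np.ndarray:
        """Post-burn-in slice of the count series."""
        if self.t.size == 0:
            return self.counts
        return self.counts[self.t >= self.burn_in_time]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, columns=list(SPECIES))
        df.insert(0, "t", self.t)
        return df

    def to_csv(self, path) -> None:
        """Write t,M1,P1,M2,P2 CSV plus a JSON provenance sidecar."""
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        sidecar = {
            "params": self.params.to_dict(),
            "mode": self.mode.value,
            "seed": int(self.seed),
            "clamp": None if self.clamp is None else list(self.clamp),
            "burn_in_frac": self.burn_in_frac,
        }
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(sidecar, indent=2) + "\n"
        )


# ---------------------------------------------------------------------------
# drivers


def _default_init(params: CircuitParams, mode: ResourceMode) -> np.ndarray:
    """Attractor reached from the empty state, rounded to integer counts.

    Well-defined in both the monostable and bistable regimes (in the latter
    it selects the branch continuously connected to the empty state).
    """
    sol = solve_ivp(
        lambda t, x: ode_rhs(x, params, mode),
        (0.0, 200.0),
        np.zeros(4),
        method="LSODA",
        rtol=1e-8,
        atol=1e-10,
    )
    conc = sol.y[:, -1]
    return np.maximum(np.round(conc * params.Omega), 0).astype(np.int64)


def gillespie_run(
    params: CircuitParams,
    mode: ResourceMode,
    t_end: float,
    seed: int,
    init: Optional[CountState | Sequence[int]] = None,
    dt_sample: float = 0.1,
    clamp: Optional[tuple[float, float]] = None,
    burn_in_frac: float = 0.2,
) -> Trajectory:
    """Exact SSA run sampled on a regular grid.

    ``init`` defaults to the deterministic attractor reached from the empty
    state (rounded to counts).  ``clamp=(M1_mean, M2_mean)`` replaces the
    opposing mRNA inside each gene's translation partition by a fixed mean
    (shared mode only).
    """
    mode = ResourceMode.coerce(mode)
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    if clamp is not None and mode is not ResourceMode.SHARED:
        raise ValueError("clamping applies to the shared-resource mode only")
    if init is None:
        x0 = _default_init(params, mode)
    elif isinstance(init, CountState):
        x0 = init.to_array()
    else:
        x0 = np.asarray(init, dtype=np.int64)
        if x0.shape != (4,) or np.any(x0 < 0):
            raise ValueError("init must be 4 non-negative integer counts")
    cM1, cM2 = (-1.0, -1.0) if clamp is None else (float(clamp[0]), float(clamp[1]))
    counts = _ssa_core(
        params.theta(), mode.code, cM1, cM2, x0,
        float(t_end), float(dt_sample), np.uint32(seed & 0xFFFFFFFF),
    )
    t = np.arange(counts.shape[0]) * dt_sample
    return Trajectory(
        t=t, counts=counts, params=params, mode=mode, seed=int(seed),
        clamp=clamp, burn_in_frac=burn_in_frac,
    )


def clamped_mean_run(
    params: CircuitParams,
    t_end: float,
    seed: int,
    reference: str = "deterministic",
    branch: Optional[str] = None,
    dt_sample: float = 0.1,
    burn_in_frac: float = 0.2,
) -> Trajectory:
    """Shared-mode run with the opposing mRNAs fixed at reference means.

    This keeps the level of resource competition but removes the noise fed
    into each gene by the other gene's mRNA fluctuations.

    reference='deterministic': clamp at the shared-model steady state; in
    the bistable regime the caller must name ``branch`` ('gfp_high' or
    'gfp_low').  reference='empirical': clamp at the time-averaged counts of
    an unclamped burn-in run (same seed schedule, one spawn).
    """
    mode = ResourceMode.SHARED
    if reference == "deterministic":
        from .bifurcation import find_steady_states

        stable = [p for p in find_steady_states(params, mode) if p.stable]
        if len(stable) > 1:
            if branch is None:
                raise ValueError(
                    "bistable parameters: name the clamping branch "
                    "('gfp_high' or 'gfp_low')"
                )
            stable.sort(key=lambda p: p.p1)
            pt = stable[-1] if branch == "gfp_high" else stable[0]
        else:
            pt = stable[0]
        clamp = (params.Omega * pt.state.m1, params.Omega * pt.state.m2)
    elif reference == "empirical":
        ref = gillespie_run(
            params, mode, t_end=max(0.2 * t_end, 200.0),
            seed=spawn_seed(seed, 0, 0, salt=1),
            dt_sample=dt_sample, burn_in_frac=burn_in_frac,
        )
        stat = ref.stationary()
        clamp = (float(stat[:, 0].mean()), float(stat[:, 2].mean()))
    else:
        raise ValueError("reference must be 'deterministic' or 'empirical'")
    return gillespie_run(
        params, mode, t_end, seed, dt_sample=dt_sample,
        clamp=clamp, burn_in_frac=burn_in_frac,
    )


def spawn_seed(master_seed: int, dose_index: int, rep: int, salt: int = 0) -> int:
    """Deterministic per-task seed from a master seed and task coordinates."""
    ss = np.random.SeedSequence(entropy=int(master_seed),
                                spawn_key=(int(salt), int(dose_index), int(rep)))
    return int(ss.generate_state(1, dtype=np.uint32)[0])


def dose_sweep(
    params: CircuitParams,
    mode: ResourceMode,
    doses: Sequence[float],
    reps: int,
    t_end: float,
    master_seed: int,
    dose_parameter: str = "I1",
    clamped: bool = False,
    clamp_reference: str = "empirical",
    dt_sample: float = 0.1,
    burn_in_frac: float = 0.2,
) -> list[list[Trajectory]]:
    """Replicated SSA runs over a dose grid; returns trajectories[dose][rep].

    Seeds are spawned deterministically from ``master_seed`` and the
    (dose index, replicate) coordinates, so any subset reproduces exactly.
    With ``clamped=True`` each dose uses :func:`clamped_mean_run`.
    """
    mode = ResourceMode.coerce(mode)
    out: list[list[Trajectory]] = []
    for i, dose in enumerate(doses):
        p = params.replace(**{dose_parameter: float(dose)})
        runs = []
        for r in range(reps):
            seed = spawn_seed(master_seed, i, r)
            if clamped:
                runs.append(
                    clamped_mean_run(
                        p, t_end, seed, reference=clamp_reference,
                        dt_sample=dt_sample, burn_in_frac=burn_in_frac,
                    )
                )
            else:
                runs.append(
                    gillespie_run(
                        p, mode, t_end, seed,
                        dt_sample=dt_sample, burn_in_frac=burn_in_frac,
                    )
                )
        out.append(runs)
    return out
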