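"""Steady-state, bifurcation, nullcline, and sensitivity analysis.

The cascade's fixed points reduce exactly to the roots of a scalar equation
in p1: at steady state both mRNA concentrations are explicit functions of
p1 (through R2), so the protein balance of gene 1 closes on itself.  All
steady-state finding below brackets sign changes of that residual on a
dense p1 grid and polishes them with Brent's method, which is robust for
this 4-dimensional but effectively one-dimensional root structure.

Saddle-node (SN) points are localized by bisection on the steady-state
count, not by arclength continuation — the system is cheap enough that the
grid-scan approach is both simpler and more robust.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .model import (
    ode_rhs,
    regulatory_input,
    steady_state_closed_form,
    transcription_denominators,
    translation_denominators,
)
from .params import PARAM_NAMES, CircuitParams, ConcentrationState, ResourceMode

__all__ = [
    "SteadyStatePoint",
    "BifurcationDiagram",
    "SensitivityReport",
    "find_steady_states",
    "jacobian",
    "bifurcation_1d",
    "bifurcation_2d",
    "sensitivity_sn",
    "nullclines",
]

#: relative distance below which two fixed points are considered identical
_DEDUP_RTOL = 1e-5


@dataclass(frozen=True)
class SteadyStatePoint:
    state: ConcentrationState
    eigenvalues: np.ndarray
    stable: bool

    @property
    def p1(self) -> float:
        return self.state.p1


@dataclass
class BifurcationDiagram:
    """One-parameter bifurcation scan with saddle-node points.

    ``points[k]`` holds all steady states found at ``grid[k]``;
    ``branch_ids[k]`` gives a continuity label per steady state obtained by
    nearest-neighbor matching (in p1) between consecutive grid values.
    """

    swept_parameter: str
    grid: np.ndarray
    points: list[list[SteadyStatePoint]]
    branch_ids: list[list[int]]
    sn_points: list[tuple[float, ConcentrationState]] = field(default_factory=list)

    @property
    def bistable_window(self) -> Optional[tuple[float, float]]:
        if len(self.sn_points) < 2:
            return None
        vals = sorted(v for v, _ in self.sn_points)
        return vals[0], vals[-1]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for val, pts, ids in zip(self.grid, self.points, self.branch_ids):
            for pt, bid in zip(pts, ids):
                s = pt.state
                rows.append(
                    {
                        self.swept_parameter: val,
                        "branch": bid,
                        "m1": s.m1,
                        "p1": s.p1,
                        "m2": s.m2,
                        "p2": s.p2,
                        "stable": pt.stable,
                    }
                )
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def sn_to_json(self, path) -> None:
        payload = [
            {
                "parameter": self.swept_parameter,
                "value": v,
                "state": {"m1": s.m1, "p1": s.p1, "m2": s.m2, "p2": s.p2},
            }
            for v, s in self.sn_points
        ]
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")


@dataclass
class SensitivityReport:
    """Percent SN shifts under +/-delta perturbation of each parameter.

    ``entries[param][sign]`` is ``(dSN1_pct, dSN2_pct)`` or ``None`` when the
    perturbation destroys bistability.  ``sign`` is "+" or "-".
    """

    delta: float
    baseline_sn: tuple[float, float]
    entries: dict[str, dict[str, Optional[tuple[float, float]]]]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for param, signs in self.entries.items():
            for sign, shift in signs.items():
                rows.append(
                    {
                        "parameter": param,
                        "direction": sign,
                        "dSN1_pct": None if shift is None else shift[0],
                        "dSN2_pct": None if shift is None else shift[1],
                        "bistable": shift is not None,
                    }
                )
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# scalar reduction


def _p1_residual(p1, params: CircuitParams, mode: ResourceMode):
    """f(p1) whose roots are the fixed points; vectorized over p1."""
    p1 = np.asarray(p1, dtype=float)
    R1 = params.I1
    kgn = params.Kg ** params.n
    R2 = params.I2 * kgn / (p1 ** params.n + kgn)
    den_m1, den_m2 = transcription_denominators(params, mode, R1, R2)
    m1 = (params.km01 + params.km1 * R1) / (params.dm1 * den_m1)
    m2 = (params.km02 + params.km2 * R2) / (params.dm2 * den_m2)
    den_p1, _ = translation_denominators(params, mode, m1, m2)
    return params.kp1 * m1 / (params.dp1 * den_p1) - p1


def _state_from_p1(p1: float, params: CircuitParams, mode: ResourceMode):
    R1 = params.I1
    R2 = regulatory_input(params, max(p1, 0.0), 2)
    den_m1, den_m2 = transcription_denominators(params, mode, R1, R2)
    m1 = (params.km01 + params.km1 * R1) / (params.dm1 * den_m1)
    m2 = (params.km02 + params.km2 * R2) / (params.dm2 * den_m2)
    _, den_p2 = translation_denominators(params, mode, m1, m2)
    p2 = params.kp2 * m2 / (params.dp2 * den_p2)
    return ConcentrationState(float(m1), max(float(p1), 0.0), float(m2), float(p2))


def _p1_upper_bound(params: CircuitParams) -> float:
    m1_max = (params.km01 + params.km1 * params.I1) / params.dm1
    return 1.05 * params.kp1 * m1_max / params.dp1 + 1.0


def _root_p1_values(
    params: CircuitParams, mode: ResourceMode, grid_size: int = 2000
) -> list[float]:
    hi = _p1_upper_bound(params)
    grid = np.linspace(0.0, hi, grid_size)
    vals = _p1_residual(grid, params, mode)
    roots: list[float] = []
    for i in range(len(grid) - 1):
        a, b = vals[i], vals[i + 1]
        if a == 0.0:
            roots.append(float(grid[i]))
        elif a * b < 0:
            roots.append(
                float(
                    brentq(
                        lambda x: float(_p1_residual(x, params, mode)),
                        grid[i],
                        grid[i + 1],
                        xtol=1e-12,
                        rtol=1e-14,
                    )
                )
            )
    if vals[-1] == 0.0:
        roots.append(float(grid[-1]))
    # dedupe (tangencies can double-count)
    out: list[float] = []
    for r in sorted(roots):
        if not out or abs(r - out[-1]) > _DEDUP_RTOL * max(1.0, abs(r)):
            out.append(r)
    return out


def _count_roots(
    params: CircuitParams, mode: ResourceMode, grid_size: int = 2000
) -> int:
    """Fast root count via sign changes only (no polishing)."""
    hi = _p1_upper_bound(params)
    grid = np.linspace(0.0, hi, grid_size)
    vals = _p1_residual(grid, params, mode)
    return int(np.sum(vals[:-1] * vals[1:] < 0) + np.sum(vals == 0.0))


# ---------------------------------------------------------------------------
# fixed points with stability


def jacobian(
    state, params: CircuitParams, mode: ResourceMode, rel_step: float = 1e-6
) -> np.ndarray:
    """Central finite-difference Jacobian of :func:`ode_rhs`."""
    if isinstance(state, ConcentrationState):
        state = state.to_array()
    x = np.asarray(state, dtype=float)
    J = np.empty((4, 4))
    for j in range(4):
        h = rel_step * max(abs(x[j]), 1e-3)
        xp, xm = x.copy(), x.copy()
        xp[j] += h
        xm[j] -= h
        J[:, j] = (ode_rhs(xp, params, mode) - ode_rhs(xm, params, mode)) / (2 * h)
    return J


def find_steady_states(
    params: CircuitParams,
    mode: ResourceMode,
    grid_size: int = 2000,
) -> list[SteadyStatePoint]:
    """All fixed points in the physical region, with stability flags.

    Returns an empty list (with a warning) only if no root brackets — a sign
    of pathological parameters, since production at p1=0 is positive.
    """
    mode = ResourceMode.coerce(mode)
    roots = _root_p1_values(params, mode, grid_size)
    points: list[SteadyStatePoint] = []
    for r in roots:
        st = _state_from_p1(r, params, mode)
        eig = np.linalg.eigvals(jacobian(st, params, mode))
        points.append(
            SteadyStatePoint(state=st, eigenvalues=eig, stable=bool(np.all(eig.real < 0)))
        )
    if not points:
        import warnings

        warnings.warn("no steady state converged; parameters may be pathological")
    return sorted(points, key=lambda p: p.p1)


# ---------------------------------------------------------------------------
# 1D bifurcation


def _with_param(params: CircuitParams, name: str, value: float) -> CircuitParams:
    if name == "1/Jp2":
        if value <= 0:
            raise ValueError("1/Jp2 must be > 0 to map back to Jp2")
        return params.replace(Jp2=1.0 / value)
    if name not in PARAM_NAMES:
        raise ValueError(f"unknown parameter {name!r}")
    return params.replace(**{name: value})


def _refine_sn(
    params: CircuitParams,
    mode: ResourceMode,
    name: str,
    inside: float,
    outside: float,
    tol: float = 1e-3,
    grid_size: int = 2000,
) -> tuple[float, ConcentrationState]:
    """Bisect between a bistable and a monostable parameter value.

    Returns the SN parameter value and the (approximate) merging state:
    the midpoint of the closest stable/unstable root pair on the bistable side.
    """
    n_inside = _count_roots(_with_param(params, name, inside), mode, grid_size)
    while abs(inside - outside) > tol:
        mid = 0.5 * (inside + outside)
        if _count_roots(_with_param(params, name, mid), mode, grid_size) == n_inside:
            inside = mid
        else:
            outside = mid
    p_in = _with_param(params, name, inside)
    roots = _root_p1_values(p_in, mode, grid_size)
    # merging pair = the two closest roots
    if len(roots) >= 2:
        gaps = np.diff(roots)
        k = int(np.argmin(gaps))
        p1_sn = 0.5 * (roots[k] + roots[k + 1])
    else:
        p1_sn = roots[0]
    return 0.5 * (inside + outside), _state_from_p1(p1_sn, p_in, mode)


def bifurcation_1d(
    params: CircuitParams,
    mode: ResourceMode,
    parameter: str,
    lo: float,
    hi: float,
    resolution: int = 400,
    sn_tol: float = 1e-3,
    grid_size: int = 2000,
) -> BifurcationDiagram:
    """Scan ``parameter`` over [lo, hi]; locate branches and SN points."""
    mode = ResourceMode.coerce(mode)
    if not lo < hi:
        raise ValueError("require lo < hi")
    _with_param(params, parameter, hi)  # validates the name early
    grid = np.linspace(lo, hi, resolution)
    points: list[list[SteadyStatePoint]] = []
    counts: list[int] = []
    for v in grid:
        try:
            pts = find_steady_states(_with_param(params, parameter, v), mode, grid_size)
        except ValueError as err:  # positivity violated at this grid value
            raise ValueError(
                f"{parameter}={v} outside positivity constraints: {err}"
            ) from err
        points.append(pts)
        counts.append(len(pts))

    # branch continuity by nearest-neighbor matching on p1
    branch_ids: list[list[int]] = []
    next_id = 0
    prev: list[tuple[int, float]] = []
    for pts in points:
        ids: list[int] = []
        used: set[int] = set()
        for pt in pts:
            best = None
            for k, (bid, p1v) in enumerate(prev):
                if k in used:
                    continue
                d = abs(pt.p1 - p1v)
                if best is None or d < best[1]:
                    best = (k, d, bid)
            if best is not None and best[1] < 0.35 * max(1.0, pt.p1):
                used.add(best[0])
                ids.append(best[2])
            else:
                ids.append(next_id)
                next_id += 1
        branch_ids.append(ids)
        prev = list(zip(ids, [pt.p1 for pt in pts]))

    sn_points: list[tuple[float, ConcentrationState]] = []
    for i in range(len(grid) - 1):
        if counts[i] != counts[i + 1]:
            if counts[i] > counts[i + 1]:
                inside, outside = grid[i], grid[i + 1]
            else:
                inside, outside = grid[i + 1], grid[i]
            sn_points.append(
                _refine_sn(params, mode, parameter, inside, outside, sn_tol, grid_size)
            )
    sn_points.sort(key=lambda t: t[0])
    return BifurcationDiagram(
        swept_parameter=parameter,
        grid=grid,
        points=points,
        branch_ids=branch_ids,
        sn_points=sn_points,
    )


# ---------------------------------------------------------------------------
# 2D bifurcation


def bifurcation_2d(
    params: CircuitParams,
    mode: ResourceMode,
    p_x: tuple[float, float] | None = None,
    p_y: tuple[float, float] | None = None,
    x_name: str = "I1",
    y_name: str = "1/Jp2",
    resolution_x: int = 200,
    resolution_y: int = 21,
    sn_tol: float = 1e-3,
    grid_size: int = 1500,
) -> dict:
    """SN curves in the (x, y) parameter plane plus the cusp in y.

    For each y-grid value a 1D scan in x records 0 or 2 SN points.  The cusp
    is the y value below which the SN pair disappears, refined by bisection.
    ``y_name='1/Jp2'`` sweeps the reciprocal translational capacity of gene 2.
    """
    mode = ResourceMode.coerce(mode)
    x_lo, x_hi = p_x if p_x is not None else (0.0, 2.0)
    y_lo, y_hi = p_y if p_y is not None else (0.0, 1.0)
    y_grid = np.linspace(y_lo, y_hi, resolution_y)
    if y_name == "1/Jp2" and y_grid[0] <= 0:
        y_grid[0] = min(1e-6, 0.5 * (y_grid[1] if resolution_y > 1 else 1e-6))

    rows = []
    for y in y_grid:
        base = _with_param(params, y_name, y)
        diag = bifurcation_1d(
            base, mode, x_name, x_lo, x_hi,
            resolution=resolution_x, sn_tol=sn_tol, grid_size=grid_size,
        )
        sns = [v for v, _ in diag.sn_points]
        rows.append({"y": float(y), "sn": sns})

    def _has_bistability(y: float) -> bool:
        base = _with_param(params, y_name, y)
        x_grid = np.linspace(x_lo, x_hi, resolution_x)
        return any(
            _count_roots(_with_param(base, x_name, x), mode, grid_size) == 3
            for x in x_grid
        )

    cusp = None
    flags = [len(r["sn"]) >= 2 for r in rows]
    for i in range(len(y_grid) - 1):
        if flags[i] != flags[i + 1]:
            lo_y, hi_y = y_grid[i], y_grid[i + 1]
            for _ in range(20):
                mid = 0.5 * (lo_y + hi_y)
                if _has_bistability(mid) == flags[i]:
                    lo_y = mid
                else:
                    hi_y = mid
            cusp = 0.5 * (lo_y + hi_y)
            break
    return {
        "x_name": x_name,
        "y_name": y_name,
        "rows": rows,
        "cusp": cusp,
    }


# ---------------------------------------------------------------------------
# sensitivity of SN locations


def sensitivity_sn(
    params: CircuitParams,
    mode: ResourceMode,
    delta: float = 0.20,
    sweep: tuple[str, float, float] = ("I1", 0.0, 2.0),
    parameters: Optional[Sequence[str]] = None,
    resolution: int = 150,
    grid_size: int = 1500,
) -> SensitivityReport:
    """Percent change of both SN locations under +/-delta per-parameter tweaks.

    The swept dose itself and Omega (a pure unit conversion) are excluded.
    Loss of bistability under a perturbation is recorded as ``None``.
    """
    mode = ResourceMode.coerce(mode)
    sweep_name, lo, hi = sweep
    if parameters is None:
        parameters = [p for p in PARAM_NAMES if p not in (sweep_name, "Omega")]

    def _sn_pair(p: CircuitParams) -> Optional[tuple[float, float]]:
        diag = bifurcation_1d(
            p, mode, sweep_name, lo, hi, resolution=resolution, grid_size=grid_size
        )
        if len(diag.sn_points) < 2:
            return None
        vals = sorted(v for v, _ in diag.sn_points)
        return vals[0], vals[-1]

    base = _sn_pair(params)
    if base is None:
        raise ValueError("baseline parameters are not bistable over the sweep range")

    entries: dict[str, dict[str, Optional[tuple[float, float]]]] = {}
    for name in parameters:
        entries[name] = {}
        for sign, fac in (("+", 1.0 + delta), ("-", 1.0 - delta)):
            pert = _sn_pair(params.replace(**{name: getattr(params, name) * fac}))
            if pert is None:
                entries[name][sign] = None
            else:
                entries[name][sign] = (
                    100.0 * (pert[0] - base[0]) / base[0],
                    100.0 * (pert[1] - base[1]) / base[1],
                )
    return SensitivityReport(delta=delta, baseline_sn=base, entries=entries)


# ---------------------------------------------------------------------------
# nullclines in the reduced (p1, m2) plane


def nullclines(
    params: CircuitParams,
    mode: ResourceMode = ResourceMode.SHARED,
    p1_grid: Optional[np.ndarray] = None,
) -> dict:
    """Reduced-plane nullclines and their intersections (= fixed points).

    The reduction holds m1 at its quasi-steady value m1*(p1).  Curve A is
    dp1/dt = 0 solved for m2; curve B is dm2/dt = 0, i.e. m2 = m2*(p1).
    Intersections are mapped back to full states (p2 via dp2/dt = 0).
    """
    mode = ResourceMode.coerce(mode)
    if mode is not ResourceMode.SHARED:
        raise ValueError("nullcline reduction targets the shared-resource system")
    if p1_grid is None:
        p1_grid = np.linspace(1e-3, _p1_upper_bound(params), 800)
    p1 = np.asarray(p1_grid, dtype=float)
    kgn = params.Kg ** params.n
    R1 = params.I1
    R2 = params.I2 * kgn / (p1 ** params.n + kgn)
    den_m = 1.0 + R1 / params.Jm1 + R2 / params.Jm2
    m1 = (params.km01 + params.km1 * R1) / (params.dm1 * den_m)
    # curve A: kp1*m1/(1 + m1/Jp1 + m2/Jp2) = dp1*p1  =>  m2
    m2_A = params.Jp2 * (
        params.kp1 * m1 / (params.dp1 * p1) - 1.0 - m1 / params.Jp1
    )
    # curve B: quasi-steady RFP mRNA
    m2_B = (params.km02 + params.km2 * R2) / (params.dm2 * den_m)

    diff = m2_A - m2_B
    intersections = []
    for i in range(len(p1) - 1):
        if diff[i] * diff[i + 1] < 0:
            f = lambda x: float(
                _p1_residual(x, params, mode)
            )  # same roots as the reduced intersection
            r = brentq(f, p1[i], p1[i + 1], xtol=1e-12)
            intersections.append(_state_from_p1(r, params, mode))
    return {
        "p1": p1,
        "m2_dp1dt0": m2_A,
        "m2_dm2dt0": m2_B,
        "intersections": intersections,
    }
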