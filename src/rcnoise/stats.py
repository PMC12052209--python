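"""Stationary statistics of SSA trajectories.

Noise is the squared coefficient of variation eta^2 = var/mean^2 of the
post-burn-in molecule counts.  Mode detection works on a smoothed count
histogram; switching statistics use hysteresis thresholding around the
anti-mode so that within-mode fluctuations are not counted as switches.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .ssa import SPECIES, Trajectory

__all__ = [
    "StationarySummary",
    "ModeSummary",
    "SwitchingSummary",
    "stationary_summary",
    "detect_modes",
    "switching_stats",
    "noise_dose_curves",
    "refine_peak",
]


@dataclass(frozen=True)
class StationarySummary:
    """Per-species mean, variance and eta^2 over the stationary segment."""

    mean: dict[str, float]
    variance: dict[str, float]
    eta2: dict[str, Optional[float]]  # None when the mean is zero
    burn_in_time: float
    n_samples: int
    ess: dict[str, float]  # autocorrelation-based effective sample size


@dataclass(frozen=True)
class ModeSummary:
    species: str
    modes: list[float]  # count values at local maxima, ascending
    modality: str  # 'unimodal' | 'bimodal'
    anti_mode: Optional[float]  # separating minimum, when bimodal


@dataclass(frozen=True)
class SwitchingSummary:
    n_switches: int
    dwell_times: dict[str, list[float]]  # per state: 'low', 'high'
    time_fraction: dict[str, float]


def _ess(x: np.ndarray) -> float:
    """Effective sample size from the integrated autocorrelation time."""
    n = len(x)
    x = x - x.mean()
    v = float(np.dot(x, x)) / n
    if v == 0:
        return float(n)
    tau = 1.0
    for lag in range(1, min(n // 2, 2000)):
        rho = float(np.dot(x[:-lag], x[lag:])) / ((n - lag) * v)
        if rho < 0.05:
            break
        tau += 2.0 * rho
    return n / tau


def stationary_summary(traj: Trajectory, burn_in: Optional[float] = None) -> StationarySummary:
    """Moments of the post-burn-in samples (grid sampling => time-weighted)."""
    t_burn = traj.burn_in_time if burn_in is None else float(burn_in)
    if t_burn >= traj.t[-1]:
        raise ValueError("burn-in exceeds trajectory length")
    seg = traj.counts[traj.t >= t_burn]
    mean, variance, eta2, ess = {}, {}, {}, {}
    for k, sp in enumerate(SPECIES):
        x = seg[:, k].astype(float)
        mu = float(x.mean())
        s2 = float(x.var())
        mean[sp] = mu
        variance[sp] = s2
        eta2[sp] = (s2 / mu**2) if mu > 0 else None
        ess[sp] = _ess(x)
    return StationarySummary(
        mean=mean, variance=variance, eta2=eta2,
        burn_in_time=t_burn, n_samples=seg.shape[0], ess=ess,
    )


def detect_modes(
    traj: Trajectory,
    species: str,
    bins: Optional[int] = None,
    prominence_frac: float = 0.05,
    smooth_window: int = 5,
    valley_ratio: float = 0.8,
) -> ModeSummary:
    """Local modes of the stationary count distribution.

    Histogram bin width defaults to Freedman-Diaconis with a floor of one
    count; the histogram is smoothed with a centered moving average before
    peak picking.  Peaks need relative prominence >= ``prominence_frac`` of
    the global maximum; adjacent peaks whose separating valley stays above
    ``valley_ratio`` of the lower peak are merged (sampling wiggles on one
    broad mode are not distinct modes).  More than two surviving peaks keep
    the two highest.
    """
    x = traj.stationary()[:, SPECIES.index(species)].astype(float)
    if x.size == 0:
        raise ValueError("empty stationary segment")
    lo, hi = x.min(), x.max()
    if bins is None:
        iqr = np.subtract(*np.percentile(x, [75, 25]))
        width = max(2.0 * iqr / x.size ** (1 / 3), 1.0)
        bins = max(int(np.ceil((hi - lo + 1) / width)), 1)
    edges = np.linspace(lo - 0.5, hi + 0.5, bins + 1)
    hist, _ = np.histogram(x, bins=edges)
    kernel = np.ones(smooth_window) / smooth_window
    smooth = np.convolve(hist.astype(float), kernel, mode="same")
    centers = 0.5 * (edges[:-1] + edges[1:])

    # zero-pad so maxima at the histogram boundary count as peaks too
    padded = np.concatenate([[0.0], smooth, [0.0]])
    peaks, _ = find_peaks(padded, prominence=prominence_frac * smooth.max())
    peaks = peaks - 1
    if len(peaks) == 0:
        peaks = np.array([int(np.argmax(smooth))])
    # merge peaks separated only by shallow valleys
    peaks = list(peaks)
    while len(peaks) > 1:
        ratios = []
        for a, b in zip(peaks[:-1], peaks[1:]):
            valley = smooth[a : b + 1].min()
            ratios.append(valley / min(smooth[a], smooth[b]))
        k = int(np.argmax(ratios))
        if ratios[k] >= valley_ratio:
            drop = k if smooth[peaks[k]] < smooth[peaks[k + 1]] else k + 1
            peaks.pop(drop)
        else:
            break
    if len(peaks) > 2:
        peaks = sorted(sorted(peaks, key=lambda p: -smooth[p])[:2])
    modes = sorted(float(centers[p]) for p in peaks)
    if len(modes) == 2:
        i0, i1 = np.searchsorted(centers, modes[0]), np.searchsorted(centers, modes[1])
        anti_idx = i0 + int(np.argmin(smooth[i0 : i1 + 1]))
        return ModeSummary(species, modes, "bimodal", float(centers[anti_idx]))
    return ModeSummary(species, modes, "unimodal", None)


def switching_stats(
    traj: Trajectory,
    modes: ModeSummary,
    hysteresis_frac: float = 0.25,
) -> SwitchingSummary:
    """Switch counts and dwell times via hysteresis thresholding.

    The band spans +/- ``hysteresis_frac`` of the inter-mode distance around
    the anti-mode; a switch is registered only when the signal crosses from
    one threshold to the opposite one.  Time inside the band accrues to the
    current state, so dwell times partition the stationary duration.
    """
    if modes.modality != "bimodal" or modes.anti_mode is None:
        raise ValueError("switching statistics require a bimodal classification")
    x = traj.stationary()[:, SPECIES.index(modes.species)].astype(float)
    dt = float(traj.t[1] - traj.t[0]) if len(traj.t) > 1 else 1.0
    gap = modes.modes[1] - modes.modes[0]
    lo_thr = modes.anti_mode - hysteresis_frac * gap
    hi_thr = modes.anti_mode + hysteresis_frac * gap

    state = "high" if x[0] >= modes.anti_mode else "low"
    dwell: dict[str, list[float]] = {"low": [], "high": []}
    current = 0.0
    n_switches = 0
    for v in x:
        if state == "low" and v >= hi_thr:
            dwell["low"].append(current)
            current = 0.0
            state = "high"
            n_switches += 1
        elif state == "high" and v <= lo_thr:
            dwell["high"].append(current)
            current = 0.0
            state = "low"
            n_switches += 1
        current += dt
    dwell[state].append(current)
    total = sum(sum(v) for v in dwell.values())
    frac = {s: (sum(v) / total if total > 0 else 0.0) for s, v in dwell.items()}
    return SwitchingSummary(n_switches=n_switches, dwell_times=dwell, time_fraction=frac)


def refine_peak(doses: np.ndarray, values: np.ndarray, interior: bool = True) -> float:
    """Peak dose by parabolic interpolation through the argmax and neighbors.

    With ``interior=True`` (default) the peak is the highest *local* maximum
    strictly inside the grid, ignoring boundary values — low-dose boundary
    points can dominate eta^2 simply because counts are small there.
    """
    doses = np.asarray(doses, dtype=float)
    values = np.asarray(values, dtype=float)
    if interior:
        pks, _ = find_peaks(values)
        k = int(pks[np.argmax(values[pks])]) if len(pks) else int(np.argmax(values))
    else:
        k = int(np.argmax(values))
    if k == 0 or k == len(values) - 1:
        return float(doses[k])
    x0, x1, x2 = doses[k - 1 : k + 2]
    y0, y1, y2 = values[k - 1 : k + 2]
    denom = y0 - 2 * y1 + y2
    if denom == 0:
        return float(x1)
    h = x1 - x0
    return float(x1 + 0.5 * h * (y0 - y2) / denom)


def noise_dose_curves(
    sweep: Sequence[Sequence[Trajectory]],
    doses: Sequence[float],
    dose_parameter: str = "I1",
) -> pd.DataFrame:
    """Mean and eta^2 per dose, pooled over replicates.

    Samples from all replicates at a dose are pooled (equal grid weighting),
    so switching variability across replicates is captured in the variance.
    Returns a tidy frame with columns (dose, species, mean, eta2, n_reps).
    """
    rows = []
    for dose, runs in zip(doses, sweep):
        pooled = np.concatenate([r.stationary() for r in runs], axis=0)
        for k, sp in enumerate(SPECIES):
            x = pooled[:, k].astype(float)
            mu = float(x.mean())
            s2 = float(x.var())
            rows.append(
                {
                    dose_parameter: float(dose),
                    "species": sp,
                    "mean": mu,
                    "eta2": s2 / mu**2 if mu > 0 else np.nan,
                    "n_reps": len(runs),
                }
            )
    return pd.DataFrame(rows)
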