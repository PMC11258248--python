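"""Population kinetics of the surface-hopping ensembles.

State populations on a time grid, the sequential kinetic model
(upper states → S1 → S0 with a bi-exponential S1 decay), weighted-average
lifetimes, lifetime ratios and eV↔nm conversion.

The sequential model: the pooled upper-state population decays as
exp(−t/τ₂); S1, fed by that decay, follows the Bateman-type closed form

    P₁(t) = Σᵢ wᵢ · τᵢ/(τᵢ − τ₂) · (e^{−t/τᵢ} − e^{−t/τ₂}),   Σᵢ wᵢ = 1,

with two decay channels τ₁ (fast, weight w) and τ₁′ (slow). The
weighted-average lifetime is τ₁^avg = w·τ₁ + (1−w)·τ₁′.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .constants import EV_NM

__all__ = [
    "PopulationCurves", "KineticFitResult", "populations_from_ensemble",
    "sequential_s1", "fit_sequential_kinetics", "weighted_average_lifetime",
    "lifetime_ratio", "ev_nm_convert", "FitError",
]


class FitError(RuntimeError):
    pass


@dataclass
class PopulationCurves:
    """Fraction of trajectories on each state over a common time grid."""

    times: np.ndarray          # fs
    populations: np.ndarray    # (n_states, n_times), rows sum to 1
    n_trajectories: int
    label: str = ""

    def __post_init__(self):
        sums = self.populations.sum(axis=0)
        if np.any(np.abs(sums - 1.0) > 1e-9):
            raise ValueError("state populations must sum to 1 at every time")
        if np.any((self.populations < -1e-12) | (self.populations > 1 + 1e-12)):
            raise ValueError("populations must lie in [0, 1]")

    def upper_pool(self) -> np.ndarray:
        """Summed population of every state above S1 (the τ₂ pool)."""
        return self.populations[2:].sum(axis=0)

    @property
    def s1(self) -> np.ndarray:
        return self.populations[1]


@dataclass
class KineticFitResult:
    tau2: float                # fs
    tau1: float                # ps
    tau1_prime: float          # ps
    weight_fast: float
    tau1_avg: float            # ps
    residual_norm: float = 0.0
    stderr: dict = field(default_factory=dict)
    flags: list = field(default_factory=list)

    def __post_init__(self):
        expected = weighted_average_lifetime(
            self.weight_fast, self.tau1, self.tau1_prime, digits=None)
        if abs(self.tau1_avg - expected) > 1e-9 * max(1.0, abs(expected)):
            raise ValueError("tau1_avg inconsistent with its components")


def populations_from_ensemble(trajectories, grid, n_states: int | None = None
                              ) -> PopulationCurves:
    """P_k(t) = fraction of trajectories whose active state is k at t.

    Each trajectory needs ``times`` and ``active`` arrays spanning the grid;
    the active state at a grid point is the last recorded value at or
    before it.
    """
    trajectories = list(trajectories)
    if not trajectories:
        raise ValueError("empty ensemble")
    grid = np.asarray(grid, dtype=float)
    if n_states is None:
        n_states = max(int(np.max(t.active)) for t in trajectories) + 1
        n_states = max(n_states, 2)
    counts = np.zeros((n_states, grid.size))
    for traj in trajectories:
        tt = np.asarray(traj.times, dtype=float)
        if grid[0] < tt[0] - 1e-9 or grid[-1] > tt[-1] + 1e-9:
            raise ValueError("trajectory does not span the requested grid")
        idx = np.searchsorted(tt, grid + 1e-9) - 1
        idx = np.clip(idx, 0, tt.size - 1)
        states = np.asarray(traj.active, dtype=int)[idx]
        counts[states, np.arange(grid.size)] += 1
    return PopulationCurves(times=grid,
                            populations=counts / len(trajectories),
                            n_trajectories=len(trajectories))


def sequential_s1(t, tau2, tau1, tau1_prime, weight_fast):
    """Closed-form S1 population of the sequential model (t and τ₂ in fs,
    τ₁ and τ₁′ in ps). Handles the τᵢ → τ₂ degenerate limit analytically."""
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    for w, tau_ps in ((weight_fast, tau1), (1.0 - weight_fast, tau1_prime)):
        tau = tau_ps * 1000.0  # fs
        if abs(tau - tau2) < 1e-9 * max(tau, tau2):
            # lim τ→τ₂ of τ/(τ−τ₂)(e^{−t/τ} − e^{−t/τ₂}) = (t/τ₂) e^{−t/τ₂}
            out = out + w * (t / tau2) * np.exp(-t / tau2)
        else:
            out = out + w * tau / (tau - tau2) * (
                np.exp(-t / tau) - np.exp(-t / tau2))
    return out


def delayed_biexponential_s1(t, t0, tau1, tau1_prime, weight_fast):
    """Alternative S1 model: an independent bi-exponential switched on at
    delay t0 (fs); provided for comparison with the sequential-feed form."""
    t = np.asarray(t, dtype=float)
    tt = np.clip(t - t0, 0.0, None)
    return (weight_fast * np.exp(-tt / (tau1 * 1000.0))
            + (1 - weight_fast) * np.exp(-tt / (tau1_prime * 1000.0)))


def fit_sequential_kinetics(curves: PopulationCurves,
                            p0=(100.0, 1.0, 20.0, 0.3),
                            model: str = "sequential") -> KineticFitResult:
    """Joint nonlinear least-squares fit of the upper-state and S1 curves.

    The pooled upper-state population is fit to exp(−t/τ₂) and S1 to the
    sequential-feed closed form, sharing τ₂, with unit weights on the
    grid. Initial guesses (τ₂ fs, τ₁ ps, τ₁′ ps, w) default to
    (100, 1, 20, 0.3). ``model="delayed"`` fits the independent delayed
    bi-exponential instead (τ₂ from the upper pool only).
    """
    t = curves.times
    upper = curves.upper_pool()
    s1 = curves.s1
    if np.all(upper == 0) and np.all(s1 == 0):
        raise FitError("curves carry no excited-state population")

    if model == "sequential":
        y = np.concatenate([upper, s1])

        def f(tt, tau2, tau1, tau1p, w):
            return np.concatenate([
                np.exp(-tt[: t.size] / tau2),
                sequential_s1(tt[t.size:], tau2, tau1, tau1p, w)])

        xdata = np.concatenate([t, t])
    elif model == "delayed":
        y = s1

        def f(tt, tau2, tau1, tau1p, w):
            return delayed_biexponential_s1(tt, tau2, tau1, tau1p, w)

        xdata = t
    else:
        raise ValueError("model must be 'sequential' or 'delayed'")

    bounds = ([1e-3, 1e-4, 1e-4, 0.0], [1e6, 1e4, 1e4, 1.0])
    try:
        popt, pcov = curve_fit(f, xdata, y, p0=list(p0), bounds=bounds,
                               maxfev=20000)
    except RuntimeError as exc:
        raise FitError(f"kinetic fit did not converge: {exc}") from exc
    tau2, tau1, tau1p, w = (float(v) for v in popt)
    if tau1 > tau1p:  # report the fast channel first
        tau1, tau1p = tau1p, tau1
        w = 1.0 - w
    resid = f(xdata, *popt) - y
    perr = np.sqrt(np.abs(np.diag(pcov)))
    flags = []
    if w > 0.99 or w < 0.01 or abs(tau1p - tau1) < 1e-3 * tau1p:
        flags.append("tau1_prime_unidentifiable")
    if not np.all(np.isfinite(perr)):
        flags.append("covariance_singular")
    return KineticFitResult(
        tau2=tau2, tau1=tau1, tau1_prime=tau1p, weight_fast=w,
        tau1_avg=weighted_average_lifetime(w, tau1, tau1p, digits=None),
        residual_norm=float(np.linalg.norm(resid)),
        stderr={"tau2": float(perr[0]), "tau1": float(perr[1]),
                "tau1_prime": float(perr[2]), "weight_fast": float(perr[3])},
        flags=flags)


def weighted_average_lifetime(weight_fast: float, tau1: float,
                              tau1_prime: float, digits: int | None = 1
                              ) -> float:
    """τ₁^avg = w·τ₁ + (1−w)·τ₁′ (ps), reported to one decimal by default."""
    if not 0.0 <= weight_fast <= 1.0:
        raise ValueError("weight must lie in [0, 1]")
    if tau1 <= 0 or tau1_prime <= 0:
        raise ValueError("lifetimes must be positive")
    avg = weight_fast * tau1 + (1.0 - weight_fast) * tau1_prime
    return float(avg) if digits is None else round(float(avg), digits)


def lifetime_ratio(numerator: float, denominator: float) -> float:
    """Plain lifetime quotient, rounded to two decimals."""
    if denominator <= 0:
        raise ValueError("denominator lifetime must be positive")
    return round(numerator / denominator, 2)


def ev_nm_convert(value: float) -> float:
    """Convert photon energy (eV) to wavelength (nm) or back; self-inverse."""
    if value <= 0:
        raise ValueError("energy/wavelength must be positive")
    return EV_NM / value
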