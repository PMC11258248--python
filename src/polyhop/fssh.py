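"""Fewest-switches surface hopping with locally diabatic electronic propagation.

Nuclei follow velocity-Verlet dynamics on one adiabatic surface of a
:class:`~polyhop.models.ModelHamiltonian`; the electronic amplitudes are
integrated in a locally diabatic representation built from the overlap
matrix between adiabatic eigenvectors at successive geometries, which
avoids explicit nonadiabatic coupling vectors. Stochastic surface switches
follow Tully's fewest-switches prescription, with isotropic velocity
rescaling at hops and either an overlap-based (frozen-Gaussian) or an
energy-based decoherence correction.

Units: eV / Å / fs / amu throughout (see :mod:`polyhop.constants`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .constants import AMU_A2_FS2_TO_EV, HBAR_EV_FS
from .models import (ModelHamiltonian, evaluate_surfaces,
                     lowdin_orthonormalize, fix_eigenvector_phases)

__all__ = [
    "SHSettings", "TrajectoryRecord", "HopEvent", "InitialCondition",
    "electronic_step", "hop_probabilities", "apply_hop",
    "decoherence_correct", "sample_initial_conditions",
    "propagate_trajectory", "run_ensemble", "PropagationError",
]


class PropagationError(RuntimeError):
    pass


@dataclass
class SHSettings:
    """Numerical settings of one surface-hopping run.

    ``decoherence_params`` defaults: frozen-Gaussian width 6 amu^1/2·Å and
    collapse threshold 1e-3 for the overlap scheme; energy constant
    0.1 Hartree (2.72114 eV) for the energy-based scheme.
    """

    nuclear_timestep: float = 0.1           # fs
    electronic_substeps: int = 100
    total_time: float = 100.0               # fs
    decoherence_scheme: str = "overlap"     # overlap | energy_based | none
    decoherence_params: dict = field(default_factory=dict)
    frustrated_hop_policy: str = "ignore"   # ignore | reverse
    rng_seed: int = 0
    temperature: float = 300.0              # K (initial sampling only)
    energy_tolerance: float = 1e-3          # eV drift allowed between hops
    record_stride: int = 1

    def __post_init__(self):
        if self.nuclear_timestep <= 0:
            raise ValueError("nuclear_timestep must be > 0")
        if self.electronic_substeps < 1:
            raise ValueError("electronic_substeps must be >= 1")
        n = self.total_time / self.nuclear_timestep
        if abs(n - round(n)) > 1e-9:
            raise ValueError("total_time must be a multiple of nuclear_timestep")
        if self.decoherence_scheme not in ("overlap", "energy_based", "none"):
            raise ValueError(
                f"unknown decoherence scheme {self.decoherence_scheme!r}")
        if self.frustrated_hop_policy not in ("ignore", "reverse"):
            raise ValueError(
                f"unknown frustrated-hop policy {self.frustrated_hop_policy!r}")
        defaults = {"gaussian_width": 6.0, "collapse_threshold": 1e-3,
                    "energy_constant": 2.72114}
        self.decoherence_params = {**defaults, **self.decoherence_params}

    @property
    def n_steps(self) -> int:
        return int(round(self.total_time / self.nuclear_timestep))


@dataclass
class HopEvent:
    """One accepted surface switch."""

    time: float                       # fs
    from_state: int
    to_state: int
    geometry_descriptors: dict = field(default_factory=dict)
    energy_gap_before: float = 0.0    # eV, E_to − E_from just before the hop

    def __post_init__(self):
        if self.from_state == self.to_state:
            raise ValueError("hop must change the active state")


@dataclass
class TrajectoryRecord:
    """Time-ordered frames of one surface-hopping run."""

    times: np.ndarray                 # (nf,) fs
    coords: np.ndarray                # (nf, n_dof)
    velocities: np.ndarray            # (nf, n_dof)
    active: np.ndarray                # (nf,) int
    energies: np.ndarray              # (nf, n_states) eV
    coeffs: np.ndarray                # (nf, n_states) complex
    dipoles_ground: np.ndarray | None = None   # (nf, n_states) |μ(S0→k)|
    dipoles_s1: np.ndarray | None = None       # (nf, n_states) |μ(S1→k)|
    hops: list = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return self.times.size

    @property
    def n_states(self) -> int:
        return self.energies.shape[1]

    @property
    def esa_gaps(self) -> np.ndarray:
        """Per-frame S1→Sn gaps (eV) for every state above S1."""
        return self.energies[:, 2:] - self.energies[:, 1:2]

    @property
    def esa_weights(self) -> np.ndarray:
        """Per-frame |μ(S1→Sn)|² weights matching :attr:`esa_gaps`."""
        if self.dipoles_s1 is None:
            return np.ones_like(self.esa_gaps)
        return np.abs(self.dipoles_s1[:, 2:]) ** 2

    def validate(self, norm_tol: float = 1e-6) -> None:
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("frame times must be strictly increasing")
        if self.active.min() < 0 or self.active.max() >= self.n_states:
            raise ValueError("active state index out of range")
        norms = np.sum(np.abs(self.coeffs) ** 2, axis=1)
        if np.any(np.abs(norms - 1.0) > norm_tol):
            raise ValueError("electronic coefficient norm deviates from 1")


@dataclass
class InitialCondition:
    coords: np.ndarray
    velocities: np.ndarray
    state: int
    coeffs: np.ndarray | None = None


# ---------------------------------------------------------------------------
# electronic propagation
# ---------------------------------------------------------------------------

def _ordered_product(u_stack: np.ndarray) -> np.ndarray:
    """Time-ordered product U_{m-1}·…·U_0 of stacked matrices (tree-reduced)."""
    while u_stack.shape[0] > 1:
        m = u_stack.shape[0]
        even = u_stack[: m - m % 2]
        paired = np.matmul(even[1::2], even[0::2])
        if m % 2:
            u_stack = np.concatenate([paired, u_stack[-1:]])
        else:
            u_stack = paired
    return u_stack[0]


def electronic_step(coeffs, overlap, energies_t, energies_tdt, dt,
                    substeps: int = 100, unitarity_tol: float = 1e-8):
    """Propagate electronic amplitudes across one nuclear step.

    The adiabatic basis at time t defines the local diabatic basis; the
    diabatic Hamiltonian interpolates linearly from diag(E(t)) to
    T·diag(E(t+dt))·Tᵀ where ``overlap`` T is the (Löwdin-orthogonalized)
    matrix of eigenvector overlaps. Each substep applies the exact
    exponential of the midpoint Hamiltonian; the step propagator in the
    adiabatic bases is P = Tᵀ·U_{m-1}·…·U_0.

    Returns ``(new_coeffs, flux)``. ``flux[j, k] = Re[c_j*(t+dt) P_jk c_k(t)]``
    decomposes the new populations into source-state contributions
    (rows sum to the new populations: Σ_k flux[j, k] = |c_j(t+dt)|²);
    its active-state column feeds the fewest-switches hop probabilities.
    """
    c = np.asarray(coeffs, dtype=complex)
    t_mat = lowdin_orthonormalize(np.asarray(overlap, dtype=float))
    h0 = np.diag(np.asarray(energies_t, dtype=float))
    h1 = t_mat @ np.diag(np.asarray(energies_tdt, dtype=float)) @ t_mat.T
    delta = dt / substeps
    # midpoint Hamiltonians of each substep, stacked
    frac = (np.arange(substeps) + 0.5) / substeps
    h_stack = h0[None] + frac[:, None, None] * (h1 - h0)[None]
    if c.size == 2:
        # closed-form exponential of a real-symmetric 2×2 (Pauli form)
        ebar = 0.5 * (h_stack[:, 0, 0] + h_stack[:, 1, 1])
        dz = 0.5 * (h_stack[:, 0, 0] - h_stack[:, 1, 1])
        dx = h_stack[:, 0, 1]
        r = np.sqrt(dz * dz + dx * dx)
        arg = r * delta / HBAR_EV_FS
        sinc = np.where(r > 1e-300, np.sin(arg) / np.maximum(r, 1e-300),
                        delta / HBAR_EV_FS)
        phase = np.exp(-1j * ebar * delta / HBAR_EV_FS)
        cosr = np.cos(arg)
        u_stack = np.empty_like(h_stack, dtype=complex)
        u_stack[:, 0, 0] = phase * (cosr - 1j * sinc * dz)
        u_stack[:, 1, 1] = phase * (cosr + 1j * sinc * dz)
        u_stack[:, 0, 1] = u_stack[:, 1, 0] = phase * (-1j * sinc * dx)
    else:
        evals, evecs = np.linalg.eigh(h_stack)
        phases = np.exp(-1j * evals * delta / HBAR_EV_FS)
        u_stack = np.einsum("sij,sj,skj->sik", evecs, phases, evecs.conj())
    propagator = t_mat.T @ _ordered_product(u_stack)
    new_coeffs = propagator @ c
    norm = float(np.sum(np.abs(new_coeffs) ** 2))
    if abs(norm - 1.0) > unitarity_tol and abs(np.sum(np.abs(c) ** 2) - 1) < 1e-9:
        raise PropagationError(
            f"non-unitary electronic propagation (norm {norm:.12f})")
    flux = np.real(np.conj(new_coeffs)[:, None] * propagator * c[None, :])
    return new_coeffs, flux


def hop_probabilities(active: int, coeffs, flux, dt=None) -> np.ndarray:
    """Fewest-switches hop probabilities out of ``active`` for one step.

    Locally diabatic prescription: the net active-population loss over the
    step, (1 − ρ_aa(t+dt)/ρ_aa(t)), is attributed to target states in
    proportion to their (positive) entries in the active column of the
    population-transfer matrix ``flux`` returned by
    :func:`electronic_step`. Each probability lies in [0, 1], the vector
    sums to ≤ 1, and it vanishes when no population leaves the active
    state.
    """
    coeffs = np.asarray(coeffs, dtype=complex)
    n = coeffs.size
    pop_a = float(np.abs(coeffs[active]) ** 2)
    if pop_a <= np.finfo(float).eps:
        warnings.warn("active-state population at machine epsilon; "
                      "hop probabilities set to zero", RuntimeWarning)
        return np.zeros(n)
    flux = np.asarray(flux, dtype=float)
    pop_a_new = float(flux[active].sum())  # = |c_a(t+dt)|²
    loss = 1.0 - pop_a_new / pop_a
    if loss <= 0.0:
        return np.zeros(n)
    denom = pop_a - flux[active, active]
    if denom <= 0.0:
        return np.zeros(n)
    g = loss * np.maximum(flux[:, active], 0.0) / denom
    g[active] = 0.0
    g = np.clip(g, 0.0, 1.0)
    total = g.sum()
    if total > 1.0:
        g /= total
    return g


def apply_hop(coords, velocities, active, target, energies, masses,
              policy: str = "ignore"):
    """Attempt a hop ``active → target`` with isotropic velocity rescaling.

    Returns ``(velocities, new_active, frustrated)``. Total (kinetic +
    potential) energy is conserved at an accepted hop; an uphill hop
    without sufficient kinetic energy is frustrated (state unchanged,
    velocities kept or reversed per ``policy``) and never produces NaN.
    """
    if target == active:
        raise ValueError("hop target equals the active state")
    velocities = np.asarray(velocities, dtype=float)
    masses = np.asarray(masses, dtype=float)
    gap = float(energies[target] - energies[active])  # eV
    ke = 0.5 * float(np.sum(masses * velocities ** 2)) * AMU_A2_FS2_TO_EV
    if ke <= gap or ke <= 0.0:
        if policy == "reverse":
            return -velocities, active, True
        return velocities, active, True
    factor = np.sqrt(1.0 - gap / ke)
    return velocities * factor, target, False


def decoherence_correct(coeffs, active: int, scheme: str, params: dict,
                        context: dict) -> np.ndarray:
    """Apply the configured decoherence correction to the amplitudes.

    ``context`` carries per-step information: ``dt`` (fs), ``gaps``
    (E_k − E_active, eV), ``kinetic_energy`` (eV) for the energy-based
    scheme, and ``overlaps`` (per-state frozen-Gaussian overlap with the
    active wavepacket) for the overlap scheme. The returned vector is
    renormalized to unit norm, with the removed population transferred to
    the active amplitude.
    """
    c = np.asarray(coeffs, dtype=complex).copy()
    n = c.size
    if scheme == "none":
        return c
    if scheme == "energy_based":
        dt = context["dt"]
        gaps = np.abs(np.asarray(context["gaps"], dtype=float))
        ekin = max(float(context["kinetic_energy"]), 1e-12)
        cconst = params.get("energy_constant", 2.72114)
        for k in range(n):
            if k == active or gaps[k] == 0.0:
                continue
            tau = HBAR_EV_FS / gaps[k] * (1.0 + cconst / ekin)
            c[k] *= np.exp(-dt / tau)
    elif scheme == "overlap":
        thr = params.get("collapse_threshold", 1e-3)
        overlaps = np.asarray(context["overlaps"], dtype=float)
        for k in range(n):
            if k != active and overlaps[k] < thr:
                c[k] = 0.0
    else:
        raise ValueError(f"unknown decoherence scheme {scheme!r}")
    others = np.sum(np.abs(c) ** 2) - np.abs(c[active]) ** 2
    if np.abs(c[active]) < 1e-12:
        c[active] = np.sqrt(max(1.0 - others, 0.0))
    else:
        c[active] *= np.sqrt(max(1.0 - others, 0.0)) / np.abs(c[active])
    return c


def sample_initial_conditions(frames_coords, frames_velocities, dipoles,
                              n: int, seed: int, energies=None,
                              excitation_window=None) -> list[InitialCondition]:
    """Draw initial excited states according to the transition dipoles.

    Frames (ground-ensemble phase-space points) are drawn uniformly with
    replacement; for each frame the starting state k ≥ 1 is drawn with
    probability ∝ |μ(S0→k)|², optionally restricted to states whose
    vertical energy lies inside ``excitation_window = (emin, emax)``.
    """
    coords = np.atleast_2d(np.asarray(frames_coords, dtype=float))
    vels = np.atleast_2d(np.asarray(frames_velocities, dtype=float))
    mu = np.atleast_2d(np.asarray(dipoles, dtype=float))
    rng = np.random.default_rng(seed)
    weights = np.abs(mu) ** 2
    weights[:, 0] = 0.0  # never "excite" into the ground state
    if excitation_window is not None:
        if energies is None:
            raise ValueError("excitation_window requires per-frame energies")
        emin, emax = excitation_window
        e = np.atleast_2d(np.asarray(energies, dtype=float))
        weights = np.where((e >= emin) & (e <= emax), weights, 0.0)
    if not np.any(weights > 0):
        raise ValueError("all transition dipoles vanish (or none inside the "
                         "excitation window); cannot sample initial states")
    out = []
    n_frames = coords.shape[0]
    for _ in range(n):
        while True:
            f = int(rng.integers(n_frames))
            w = weights[f]
            if w.sum() > 0:
                break
        state = int(rng.choice(w.size, p=w / w.sum()))
        out.append(InitialCondition(coords[f].copy(), vels[f].copy(), state))
    return out


# ---------------------------------------------------------------------------
# trajectory propagation
# ---------------------------------------------------------------------------

def propagate_trajectory(initial: InitialCondition, model: ModelHamiltonian,
                         settings: SHSettings,
                         rng: np.random.Generator | None = None
                         ) -> tuple[TrajectoryRecord, list[HopEvent]]:
    """Run one fewest-switches trajectory; returns the record and its hops."""
    if not (0 <= initial.state < model.n_states):
        raise ValueError("initial state index out of range")
    rng = rng if rng is not None else np.random.default_rng(settings.rng_seed)
    dt = settings.nuclear_timestep
    masses = model.masses
    q = np.asarray(initial.coords, dtype=float).copy()
    v = np.asarray(initial.velocities, dtype=float).copy()
    active = int(initial.state)
    c = (np.asarray(initial.coeffs, dtype=complex).copy()
         if initial.coeffs is not None
         else np.eye(model.n_states, dtype=complex)[active])

    surf = evaluate_surfaces(q, model)
    if not np.all(np.isfinite(surf.energies)):
        raise PropagationError("non-finite initial energies")
    u_prev = surf.eigenvectors

    n_steps = settings.n_steps
    stride = max(int(settings.record_stride), 1)
    rec_idx = list(range(0, n_steps + 1, stride))
    if rec_idx[-1] != n_steps:
        rec_idx.append(n_steps)
    nf = len(rec_idx)
    rec_pos = {s: i for i, s in enumerate(rec_idx)}
    times = np.empty(nf)
    coords_arr = np.empty((nf, model.n_dof))
    vel_arr = np.empty((nf, model.n_dof))
    act_arr = np.empty(nf, dtype=np.int16)
    e_arr = np.empty((nf, model.n_states))
    c_arr = np.empty((nf, model.n_states), dtype=complex)
    has_dip = model.dipole_matrix(q) is not None
    dip0 = np.empty((nf, model.n_states)) if has_dip else None
    dip1 = np.empty((nf, model.n_states)) if has_dip else None

    def record(step, t):
        i = rec_pos.get(step)
        if i is None:
            return
        times[i] = t
        coords_arr[i] = q
        vel_arr[i] = v
        act_arr[i] = active
        e_arr[i] = surf.energies
        c_arr[i] = c
        if has_dip:
            mu = model.dipole_matrix(q)
            dip0[i] = mu[0]
            dip1[i] = mu[1]

    hops: list[HopEvent] = []
    n_frustrated = 0
    ke = 0.5 * float(np.sum(masses * v ** 2)) * AMU_A2_FS2_TO_EV
    e_ref = ke + surf.energies[active]
    # overlap-decoherence auxiliary displacements per state
    aux_dx = np.zeros((model.n_states, model.n_dof))
    aux_dv = np.zeros((model.n_states, model.n_dof))
    sigma = settings.decoherence_params["gaussian_width"]  # amu^1/2·Å

    record(0, 0.0)
    for step in range(1, n_steps + 1):
        t = step * dt
        accel = -surf.gradients[active] / (masses * AMU_A2_FS2_TO_EV)
        if not np.all(np.isfinite(accel)):
            raise PropagationError(f"non-finite forces at step {step}")
        v_half = v + 0.5 * accel * dt
        q = q + v_half * dt
        new_surf = evaluate_surfaces(q, model)
        # eigenvector continuity along the trajectory overrides static phases
        o_raw = u_prev.T @ new_surf.eigenvectors
        signs = np.sign(np.diag(o_raw))
        signs[signs == 0] = 1.0
        u_new = new_surf.eigenvectors * signs
        o_raw = o_raw * signs
        new_surf = new_surf._replace(eigenvectors=u_new)
        accel_new = -new_surf.gradients[active] / (masses * AMU_A2_FS2_TO_EV)
        v = v_half + 0.5 * accel_new * dt

        c_start = c
        c, flux = electronic_step(c, o_raw, surf.energies, new_surf.energies,
                                  dt, settings.electronic_substeps)
        g = hop_probabilities(active, c_start, flux)
        xi = rng.random()
        target = -1
        cum = 0.0
        for k in range(model.n_states):
            cum += g[k]
            if xi < cum:
                target = k
                break
        ke = 0.5 * float(np.sum(masses * v ** 2)) * AMU_A2_FS2_TO_EV
        if target >= 0:
            gap_before = float(new_surf.energies[target]
                               - new_surf.energies[active])
            v_new, new_active, frustrated = apply_hop(
                q, v, active, target, new_surf.energies, masses,
                settings.frustrated_hop_policy)
            if frustrated:
                n_frustrated += 1
                v = v_new
            else:
                hops.append(HopEvent(time=t, from_state=active,
                                     to_state=target,
                                     energy_gap_before=gap_before))
                v = v_new
                active = new_active
                ke = 0.5 * float(np.sum(masses * v ** 2)) * AMU_A2_FS2_TO_EV
                e_ref = ke + new_surf.energies[active]
                aux_dx[:] = 0.0
                aux_dv[:] = 0.0

        # decoherence
        if settings.decoherence_scheme == "overlap":
            pops = np.abs(c) ** 2
            live = pops > 1e-10
            f_act = -new_surf.gradients[active]
            for k in range(model.n_states):
                if k == active or not live[k]:
                    aux_dx[k] = 0.0
                    aux_dv[k] = 0.0
                    continue
                aux_dv[k] += (-new_surf.gradients[k] - f_act) / \
                    (masses * AMU_A2_FS2_TO_EV) * dt
                aux_dx[k] += aux_dv[k] * dt
            u2 = np.sum(masses * aux_dx ** 2, axis=1)  # mass-weighted Ų·amu
            overlaps = np.exp(-u2 / (4.0 * sigma ** 2))
            collapsed = (overlaps < settings.decoherence_params
                         ["collapse_threshold"])
            c = decoherence_correct(c, active, "overlap",
                                    settings.decoherence_params,
                                    {"overlaps": overlaps})
            aux_dx[collapsed] = 0.0
            aux_dv[collapsed] = 0.0
        elif settings.decoherence_scheme == "energy_based":
            c = decoherence_correct(
                c, active, "energy_based", settings.decoherence_params,
                {"dt": dt, "gaps": new_surf.energies
                 - new_surf.energies[active], "kinetic_energy": ke})

        e_tot = ke + new_surf.energies[active]
        if abs(e_tot - e_ref) > settings.energy_tolerance:
            raise PropagationError(
                f"energy drift {e_tot - e_ref:+.3e} eV beyond tolerance at "
                f"step {step} (t = {t:.2f} fs)")
        surf = new_surf
        u_prev = u_new
        record(step, t)

    rec = TrajectoryRecord(
        times=times, coords=coords_arr, velocities=vel_arr,
        active=act_arr, energies=e_arr, coeffs=c_arr,
        dipoles_ground=dip0, dipoles_s1=dip1, hops=hops,
        metadata={"model": model.name, "seed": settings.rng_seed,
                  "n_frustrated_hops": n_frustrated,
                  "settings": {"nuclear_timestep": dt,
                               "electronic_substeps": settings.electronic_substeps,
                               "total_time": settings.total_time,
                               "decoherence_scheme": settings.decoherence_scheme,
                               "frustrated_hop_policy":
                                   settings.frustrated_hop_policy}})
    return rec, hops


def run_ensemble(initials: Sequence[InitialCondition],
                 model: ModelHamiltonian, settings: SHSettings,
                 base_seed: int | None = None) -> list[TrajectoryRecord]:
    """Propagate an ensemble; trajectory i uses an independent RNG stream
    seeded ``base_seed + i`` (reproducible and order-independent)."""
    base = settings.rng_seed if base_seed is None else base_seed
    records = []
    for i, init in enumerate(initials):
        rng = np.random.default_rng(base + i)
        rec, _ = propagate_trajectory(init, model, settings, rng=rng)
        rec.metadata["seed"] = base + i
        rec.metadata["trajectory_index"] = i
        records.append(rec)
    return records
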