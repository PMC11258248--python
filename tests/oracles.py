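"""Independent reference implementations used as test oracles.

Everything here is deliberately written from first principles (dense
matrix exponentials, direct summations, grid wavepacket propagation)
and stays independent of the polyhop code paths it checks.
"""

import numpy as np
from scipy.linalg import expm

HBAR = 0.6582119569          # eV·fs
AMU_CONV = 103.642697        # amu·Å²/fs² in eV


def expm_propagate(coeffs, overlap, e_t, e_tdt, dt, substeps=8000):
    """Brute-force locally diabatic propagation with dense expm factors."""
    w, s, vt = np.linalg.svd(np.asarray(overlap, float))
    t = w @ vt
    h0 = np.diag(np.asarray(e_t, float))
    h1 = t @ np.diag(np.asarray(e_tdt, float)) @ t.T
    c = np.asarray(coeffs, complex).copy()
    d = dt / substeps
    for k in range(substeps):
        hk = h0 + ((k + 0.5) / substeps) * (h1 - h0)
        c = expm(-1j * hk * d / HBAR) @ c
    return t.T @ c


def finite_difference_gradients(model, coords, h=1e-5):
    """Central finite differences of the adiabatic energies."""
    coords = np.asarray(coords, float)
    grads = np.zeros((model.n_states, coords.size))
    for q in range(coords.size):
        dq = np.zeros_like(coords)
        dq[q] = h
        ep = np.linalg.eigvalsh(model.diabatic_matrix(coords + dq))
        em = np.linalg.eigvalsh(model.diabatic_matrix(coords - dq))
        grads[:, q] = (ep - em) / (2 * h)
    return grads


def two_state_mixing_angle(v):
    """Adiabatic mixing angle of a real symmetric 2×2 diabatic matrix."""
    return 0.5 * np.arctan2(2.0 * v[0, 1], v[0, 0] - v[1, 1])


def dihedral_atan2(p0, p1, p2, p3):
    """Signed torsion via the cross-product/atan2 construction, degrees."""
    b1, b2, b3 = p1 - p0, p2 - p1, p3 - p2
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    ang = np.degrees(np.arctan2(np.dot(m1, n2), np.dot(n1, n2)))
    return ang + 360.0 if ang <= -180.0 else ang


def bla_direct(coords, singles, doubles):
    """Direct arithmetic over the bond lists."""
    def mean_len(bonds):
        return np.mean([np.linalg.norm(coords[i] - coords[j])
                        for i, j in bonds])
    return mean_len(singles) - mean_len(doubles)


def accumulate_esa_loops(trajectories, grid, sigma, active_state=1):
    """Plain double-loop re-accumulation of the ESA spectrum."""
    intensity = np.zeros_like(grid)
    n_frames = 0
    for traj in trajectories:
        active = np.asarray(traj.active)
        gaps = np.asarray(traj.esa_gaps, float)
        weights = np.asarray(traj.esa_weights, float)
        for f in range(active.size):
            if active[f] != active_state:
                continue
            n_frames += 1
            for g, w in zip(np.atleast_1d(gaps[f]),
                            np.atleast_1d(weights[f])):
                intensity += w * np.exp(
                    -0.5 * ((grid - g) / sigma) ** 2) / (
                    sigma * np.sqrt(2 * np.pi))
    return intensity, n_frames


def coulomb_sum_direct(pos_a, q_a, pos_b, q_b):
    """Element-by-element Coulomb sum in cm⁻¹."""
    bohr = 0.529177211
    hartree_cm = 219474.6314
    total = 0.0
    for i in range(len(q_a)):
        for j in range(len(q_b)):
            r = np.linalg.norm(pos_a[i] - pos_b[j]) / bohr
            total += q_a[i] * q_b[j] / r
    return total * hartree_cm


def basin_switches_bruteforce(series, dwell):
    """Brute-force cis/trans basin tracking with a dwell requirement."""
    series = np.asarray(series, float)
    basin = ["trans" if abs(v) > 90.0 else "cis" for v in series]
    events = []
    cur = basin[0]
    i = 1
    while i < len(basin):
        if basin[i] != cur:
            j = i
            while j < len(basin) and basin[j] == basin[i]:
                j += 1
            if j - i >= dwell:
                events.append((i, cur, basin[i]))
                cur = basin[i]
            i = j
        else:
            i += 1
    return events


def split_operator_transmission(model, x0, v0, sigma_x, t_total, dt,
                                xmin=-60.0, xmax=60.0, nx=8192, x_cut=5.0):
    """Numerically converged two-state wavepacket scattering reference.

    Split-operator (Strang) propagation of the diabatic spinor wavefunction
    on a fine grid; the initial Gaussian sits on the lower adiabatic
    surface at ``x0`` with mean velocity ``v0`` and position spread
    ``sigma_x``. Returns (T_lower, T_upper, R_lower, R_upper): adiabatic
    populations beyond/before ``x_cut`` at the final time.
    """
    m = model.masses[0]
    x = np.linspace(xmin, xmax, nx, endpoint=False)
    dx = x[1] - x[0]
    k = 2 * np.pi * np.fft.fftfreq(nx, dx)
    kin = np.exp(-1j * (HBAR ** 2 / (2 * m * AMU_CONV)) * k ** 2 * dt / HBAR)
    v = np.array([model.diabatic_matrix([xi]) for xi in x])

    def pauli_exp(vmat, tau):
        ebar = 0.5 * (vmat[:, 0, 0] + vmat[:, 1, 1])
        dz = 0.5 * (vmat[:, 0, 0] - vmat[:, 1, 1])
        dxy = vmat[:, 0, 1]
        r = np.sqrt(dz * dz + dxy * dxy)
        arg = r * tau / HBAR
        sinc = np.where(r > 1e-300, np.sin(arg) / np.maximum(r, 1e-300),
                        tau / HBAR)
        ph = np.exp(-1j * ebar * tau / HBAR)
        u = np.empty((vmat.shape[0], 2, 2), complex)
        u[:, 0, 0] = ph * (np.cos(arg) - 1j * sinc * dz)
        u[:, 1, 1] = ph * (np.cos(arg) + 1j * sinc * dz)
        u[:, 0, 1] = u[:, 1, 0] = ph * (-1j * sinc * dxy)
        return u

    u_half = pauli_exp(v, dt / 2)
    _, evecs = np.linalg.eigh(v)
    g = (2 * np.pi * sigma_x ** 2) ** (-0.25) * np.exp(
        -(x - x0) ** 2 / (4 * sigma_x ** 2)
        + 1j * m * AMU_CONV * v0 * x / HBAR)
    psi = evecs[:, :, 0] * g[:, None]
    psi /= np.sqrt((np.abs(psi) ** 2).sum() * dx)
    for _ in range(int(round(t_total / dt))):
        psi = np.einsum("xij,xj->xi", u_half, psi)
        psi = np.fft.ifft(kin[:, None] * np.fft.fft(psi, axis=0), axis=0)
        psi = np.einsum("xij,xj->xi", u_half, psi)
    phi = np.einsum("xji,xj->xi", evecs, psi)
    dens = np.abs(phi) ** 2 * dx
    mask = x > x_cut
    return (dens[mask, 0].sum(), dens[mask, 1].sum(),
            dens[~mask, 0].sum(), dens[~mask, 1].sum())
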