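"""Coulomb couplings between chromophore transition densities.

Transition densities are represented as atomic transition charges (the
TrEsp picture): the electronic coupling between two chromophores is the
charge–charge Coulomb sum, evaluated in atomic units and reported in
cm⁻¹. A point-dipole formula over the derived transition dipoles serves
as a far-field cross-check. Donor–acceptor energy-gap statistics quantify
how often excitation-energy transfer (EET) from a chlorophyll Qy donor to
the carotenoid S1 acceptor is energetically downhill.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .constants import BOHR_ANG, HARTREE_CM

__all__ = ["ChromophoreTransition", "GapSample", "coulomb_coupling",
           "point_dipole_coupling", "eet_favorability",
           "read_transition_charges", "write_transition_charges"]


@dataclass
class ChromophoreTransition:
    """Atomic transition charges representing one chromophore's transition
    density (positions in Å, charges in e)."""

    positions: np.ndarray       # (n, 3) Å
    charges: np.ndarray         # (n,) e; sums ≈ 0 for a transition density
    label: str = ""
    atoms: list = field(default_factory=list)

    def __post_init__(self):
        self.positions = np.atleast_2d(np.asarray(self.positions, float))
        self.charges = np.atleast_1d(np.asarray(self.charges, float))
        if self.positions.shape != (self.charges.size, 3):
            raise ValueError("positions and charges lengths disagree")

    @property
    def dipole(self) -> np.ndarray:
        """Derived transition dipole Σ qᵢ rᵢ (e·Å)."""
        return self.charges @ self.positions

    @property
    def center(self) -> np.ndarray:
        """|q|-weighted centroid (Å)."""
        w = np.abs(self.charges)
        if w.sum() == 0:
            return self.positions.mean(axis=0)
        return (w @ self.positions) / w.sum()

    @property
    def radius(self) -> float:
        """Extent of the charge cloud: max distance from the centroid (Å)."""
        return float(np.linalg.norm(self.positions - self.center,
                                    axis=1).max())


def coulomb_coupling(a: ChromophoreTransition, b: ChromophoreTransition,
                     screening: float = 1.0, min_distance: float = 0.1
                     ) -> float:
    """TrEsp Coulomb coupling V = s·Σᵢⱼ qᵢqⱼ/rᵢⱼ in cm⁻¹.

    Distances enter in bohr so the sum is in Hartree, converted with
    1 Hartree = 219474.6314 cm⁻¹. Symmetric under argument swap; an
    optional scalar ``screening`` stands in for a dielectric factor.
    Raises if any inter-chromophore atom pair is closer than
    ``min_distance`` Å (overlapping charge clouds).
    """
    r = cdist(a.positions, b.positions)
    if r.min() < min_distance:
        i, j = np.unravel_index(np.argmin(r), r.shape)
        raise ValueError(
            f"atoms {i} of {a.label or 'a'} and {j} of {b.label or 'b'} are "
            f"{r.min():.3f} Å apart (< {min_distance} Å)")
    v_hartree = float(np.sum(np.outer(a.charges, b.charges) / (r / BOHR_ANG)))
    return screening * v_hartree * HARTREE_CM


def point_dipole_coupling(a: ChromophoreTransition, b: ChromophoreTransition,
                          screening: float = 1.0,
                          separation_factor: float = 3.0) -> float:
    """Ideal-dipole coupling from the derived dipoles and centers, cm⁻¹.

    V = s·(μ_a·μ_b − 3(μ_a·R̂)(μ_b·R̂))/R³ in atomic units. Refuses when the
    center separation is below ``separation_factor`` times either charge
    cloud's radius — the multipole expansion is meaningless for
    overlapping clouds; use :func:`coulomb_coupling` instead.
    """
    rvec = b.center - a.center
    dist = float(np.linalg.norm(rvec))
    min_sep = separation_factor * max(a.radius, b.radius)
    if dist < min_sep:
        raise ValueError(
            f"center separation {dist:.2f} Å below {min_sep:.2f} Å "
            f"({separation_factor}× the larger cloud radius); the "
            "point-dipole form is invalid here — use coulomb_coupling")
    rhat = rvec / dist
    mu_a = a.dipole / BOHR_ANG   # e·bohr
    mu_b = b.dipole / BOHR_ANG
    r_bohr = dist / BOHR_ANG
    kappa_term = mu_a @ mu_b - 3.0 * (mu_a @ rhat) * (mu_b @ rhat)
    return screening * kappa_term / r_bohr ** 3 * HARTREE_CM


@dataclass
class GapSample:
    """Paired per-frame vertical excitation energies (eV) of a donor
    (chlorophyll Qy) and an acceptor (carotenoid S1)."""

    donor_energies: np.ndarray
    acceptor_energies: np.ndarray
    donor_label: str = "Qy"
    acceptor_label: str = "S1"
    set_label: str = ""
    conformer: str = ""

    def __post_init__(self):
        self.donor_energies = np.atleast_1d(
            np.asarray(self.donor_energies, float))
        self.acceptor_energies = np.atleast_1d(
            np.asarray(self.acceptor_energies, float))
        if self.donor_energies.size != self.acceptor_energies.size:
            raise ValueError("donor/acceptor samples must be paired")
        if self.donor_energies.size == 0:
            raise ValueError("empty gap sample")
        if np.any(self.donor_energies <= 0) or np.any(
                self.acceptor_energies <= 0):
            raise ValueError("excitation energies must be positive")


def eet_favorability(samples, bins: int = 60):
    """Fraction of frames where the acceptor S1 lies below the donor Qy.

    ``samples``: one GapSample or an iterable. Returns a DataFrame with one
    row per sample: the favorable fraction and energy histograms (shared
    bin edges per row) for both distributions.
    """
    if isinstance(samples, GapSample):
        samples = [samples]
    samples = list(samples)
    if not samples:
        raise ValueError("no gap samples given")
    rows = []
    for s in samples:
        frac = float(np.mean(s.acceptor_energies < s.donor_energies))
        lo = min(s.donor_energies.min(), s.acceptor_energies.min())
        hi = max(s.donor_energies.max(), s.acceptor_energies.max())
        edges = np.linspace(lo, hi + 1e-12, bins + 1)
        rows.append({
            "set": s.set_label, "conformer": s.conformer,
            "donor": s.donor_label, "acceptor": s.acceptor_label,
            "n_frames": s.donor_energies.size,
            "favorable_fraction": frac,
            "bin_edges": edges,
            "donor_hist": np.histogram(s.donor_energies, edges)[0],
            "acceptor_hist": np.histogram(s.acceptor_energies, edges)[0]})
    return pd.DataFrame(rows)


def read_transition_charges(path, label: str = "") -> ChromophoreTransition:
    """Read a chromophore file: CSV with columns atom, x, y, z, q."""
    df = pd.read_csv(path)
    required = {"atom", "x", "y", "z", "q"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}")
    return ChromophoreTransition(
        positions=df[["x", "y", "z"]].to_numpy(float),
        charges=df["q"].to_numpy(float),
        label=label or str(path), atoms=list(df["atom"]))


def write_transition_charges(chromo: ChromophoreTransition, path) -> None:
    atoms = chromo.atoms or ["C"] * chromo.charges.size
    pd.DataFrame({
        "atom": atoms,
        "x": chromo.positions[:, 0], "y": chromo.positions[:, 1],
        "z": chromo.positions[:, 2], "q": chromo.charges,
    }).to_csv(path, index=False)
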