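"""Analytic multi-state model Hamiltonians for nonadiabatic dynamics.

Provides diabatic model potentials (one-dimensional two-state scattering
models for engine validation, plus a reduced-dimensional carotenoid
surrogate along bond-length-alternation and torsion coordinates), their
adiabatic surfaces/gradients via exact diagonalization, and overlap
matrices between adiabatic eigenvectors at successive geometries — the
input of locally diabatic electronic propagation.

Adiabatic quantities follow a deterministic phase convention: each
eigenvector is flipped so that its largest-magnitude component is
positive, making repeated evaluations bitwise reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from typing import NamedTuple

import numpy as np
import yaml

MODEL_FORMAT_ID = "polyhop-model/1"


class EvaluationError(RuntimeError):
    """Model potential could not be evaluated at the given coordinates."""


class SurfaceEval(NamedTuple):
    """Adiabatic energies (eV, ascending), gradients (eV/Å per state) and
    phase-fixed eigenvector columns at one geometry."""

    energies: np.ndarray      # (n_states,)
    gradients: np.ndarray     # (n_states, n_dof)
    eigenvectors: np.ndarray  # (n_states, n_states), columns are states


def fix_eigenvector_phases(vecs: np.ndarray) -> np.ndarray:
    """Flip eigenvector columns so the largest-|component| entry is positive."""
    idx = np.argmax(np.abs(vecs), axis=0)
    signs = np.sign(vecs[idx, np.arange(vecs.shape[1])])
    signs[signs == 0] = 1.0
    return vecs * signs


class ModelHamiltonian:
    """Base class: a diabatic potential matrix over ``n_dof`` coordinates.

    Subclasses implement :meth:`diabatic_matrix` (and ideally the analytic
    :meth:`diabatic_gradient`; a central finite difference is the fallback).
    ``masses`` are per-dof inertias in amu (amu·Å² for angular coordinates).
    """

    name = "base"

    def __init__(self, n_states: int, masses, labels=None):
        self.n_states = int(n_states)
        self.masses = np.atleast_1d(np.asarray(masses, dtype=float))
        self.n_dof = self.masses.size
        self.labels = list(labels) if labels is not None else [
            f"S{i}" for i in range(self.n_states)
        ]
        if len(self.labels) != self.n_states:
            raise ValueError("labels length must equal n_states")

    # -- to be implemented by subclasses -------------------------------
    def diabatic_matrix(self, coords: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def diabatic_gradient(self, coords: np.ndarray, h: float = 1e-6) -> np.ndarray:
        """d V / d q, shape (n_dof, n_states, n_states); central differences."""
        coords = np.asarray(coords, dtype=float)
        out = np.empty((self.n_dof, self.n_states, self.n_states))
        for i in range(self.n_dof):
            dq = np.zeros(self.n_dof)
            dq[i] = h
            out[i] = (self.diabatic_matrix(coords + dq)
                      - self.diabatic_matrix(coords - dq)) / (2 * h)
        return out

    def dipole_matrix(self, coords: np.ndarray) -> np.ndarray | None:
        """Transition-dipole magnitudes between adiabatic states (a.u.),
        or None if the model defines none."""
        return None

    # -- config round-trip ---------------------------------------------
    def to_config(self) -> dict:
        raise NotImplementedError

    def _check_coords(self, coords):
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (self.n_dof,):
            raise ValueError(
                f"expected {self.n_dof} coordinates, got shape {coords.shape}")
        if not np.all(np.isfinite(coords)):
            bad = int(np.flatnonzero(~np.isfinite(coords))[0])
            raise EvaluationError(f"non-finite value in coordinate {bad}")
        return coords


def evaluate_surfaces(coords, model: ModelHamiltonian) -> SurfaceEval:
    """Adiabatic energies (ascending), Hellmann–Feynman gradients and
    phase-fixed eigenvectors of ``model`` at ``coords``."""
    coords = model._check_coords(coords)
    v = model.diabatic_matrix(coords)
    if not np.all(np.isfinite(v)):
        bad = int(np.argwhere(~np.isfinite(v))[0][0])
        raise EvaluationError(
            f"non-finite potential at coords={coords.tolist()} (row {bad})")
    v = 0.5 * (v + v.T)
    energies, vecs = np.linalg.eigh(v)
    vecs = fix_eigenvector_phases(vecs)
    dv = model.diabatic_gradient(coords)
    # Hellmann–Feynman: dE_i/dq = <i| dV/dq |i>
    gradients = np.einsum("ki,qkl,li->iq", vecs, dv, vecs)
    return SurfaceEval(energies, gradients, vecs)


def state_overlap_matrix(coords_t, coords_tdt, model: ModelHamiltonian) -> np.ndarray:
    """Overlap matrix ``O[i, j] = <i(t)|j(t+dt)>`` between adiabatic
    eigenvectors at two geometries, with columns sign-fixed so the
    diagonal is non-negative (diagonal-dominant phase convention)."""
    u_t = evaluate_surfaces(coords_t, model).eigenvectors
    u_dt = evaluate_surfaces(coords_tdt, model).eigenvectors
    o = u_t.T @ u_dt
    signs = np.sign(np.diag(o))
    signs[signs == 0] = 1.0
    return o * signs


def lowdin_orthonormalize(o: np.ndarray, svd_floor: float = 1e-8) -> np.ndarray:
    """Nearest orthogonal matrix to ``o`` (Löwdin, via SVD).

    Warns and proceeds with the renormalized factors if the overlap step is
    so large that the matrix is (near-)singular.
    """
    w, s, vt = np.linalg.svd(o)
    if s.min() < svd_floor:
        warnings.warn(
            f"near-singular state overlap (smallest singular value {s.min():.2e}); "
            "renormalizing — consider a smaller nuclear timestep",
            RuntimeWarning, stacklevel=2)
    return w @ vt


# ---------------------------------------------------------------------------
# concrete models
# ---------------------------------------------------------------------------

class AvoidedCrossing1D(ModelHamiltonian):
    """One-dimensional two-state single avoided crossing (scattering model).

    V11 = A(1 − e^{−Bx}) for x ≥ 0, −A(1 − e^{Bx}) for x < 0;
    V22 = −V11; V12 = C e^{−Dx²}.  Units: eV, Å, amu.
    """

    name = "avoided_crossing_1d"

    def __init__(self, a=0.27211, b=3.0236, c=0.13606, d=3.5711, mass=1.0972):
        super().__init__(2, [mass], labels=["lower", "upper"])
        self.a, self.b, self.c, self.d = float(a), float(b), float(c), float(d)

    def diabatic_matrix(self, coords):
        x = float(np.asarray(coords).reshape(-1)[0])
        v11 = self.a * (1 - np.exp(-self.b * x)) if x >= 0 \
            else -self.a * (1 - np.exp(self.b * x))
        v12 = self.c * np.exp(-self.d * x * x)
        return np.array([[v11, v12], [v12, -v11]])

    def diabatic_gradient(self, coords, h=None):
        x = float(np.asarray(coords).reshape(-1)[0])
        dv11 = self.a * self.b * np.exp(-self.b * abs(x))
        dv12 = -2 * self.d * x * self.c * np.exp(-self.d * x * x)
        return np.array([[[dv11, dv12], [dv12, -dv11]]])

    def to_config(self):
        return {"format": MODEL_FORMAT_ID, "model": self.name,
                "parameters": {"a": self.a, "b": self.b, "c": self.c,
                               "d": self.d, "mass": float(self.masses[0])}}


class HarmonicModel(ModelHamiltonian):
    """Uncoupled (or constantly coupled) displaced harmonic diabats.

    Diagonal i: offset_i + Σ_q ½ k_i (q − center_iq)²; constant off-diagonal
    ``coupling`` everywhere. Useful for conservation and no-hop tests.
    """

    name = "harmonic"

    def __init__(self, offsets, curvatures, centers, masses, coupling=0.0,
                 labels=None):
        offsets = np.atleast_1d(np.asarray(offsets, dtype=float))
        super().__init__(offsets.size, masses, labels=labels)
        self.offsets = offsets
        self.curvatures = np.broadcast_to(
            np.asarray(curvatures, dtype=float),
            (self.n_states, self.n_dof)).copy()
        self.centers = np.broadcast_to(
            np.asarray(centers, dtype=float),
            (self.n_states, self.n_dof)).copy()
        self.coupling = float(coupling)

    def diabatic_matrix(self, coords):
        coords = np.asarray(coords, dtype=float)
        diag = self.offsets + 0.5 * np.sum(
            self.curvatures * (coords - self.centers) ** 2, axis=1)
        v = np.full((self.n_states, self.n_states), self.coupling)
        np.fill_diagonal(v, diag)
        return v

    def diabatic_gradient(self, coords, h=None):
        coords = np.asarray(coords, dtype=float)
        out = np.zeros((self.n_dof, self.n_states, self.n_states))
        grad = self.curvatures * (coords - self.centers)  # (n_states, n_dof)
        for q in range(self.n_dof):
            np.fill_diagonal(out[q], grad[:, q])
        return out

    def to_config(self):
        return {"format": MODEL_FORMAT_ID, "model": self.name,
                "parameters": {
                    "offsets": self.offsets.tolist(),
                    "curvatures": self.curvatures.tolist(),
                    "centers": self.centers.tolist(),
                    "masses": self.masses.tolist(),
                    "coupling": self.coupling,
                    "labels": self.labels}}


@dataclass
class CarotenoidSurrogateSpec:
    """Parameters of the reduced carotenoid model (BLA + lumenal torsion).

    The ground state has a positive BLA minimum (alternating bonds) while S1
    has its minimum near zero BLA; the S0–S1 diabatic coupling switches on as
    BLA goes negative (inverted alternation) and as the lumenal torsion
    departs from planarity — the two internal-conversion channels of
    carotenoid photophysics. ``conformer`` selects the torsional baseline:
    the s-cis rotamer sits slightly strained off-planar with a stiffer
    torsion, the s-trans one is planar but torsionally softer.
    """

    n_states: int = 3
    state_offsets: tuple = (0.0, 2.05, 2.35)        # eV
    bla_minima: tuple = (0.06, -0.005, 0.10)        # Å
    bla_curvatures: tuple = (80.0, 60.0, 40.0)      # eV/Å²
    torsion_curvatures: tuple = (15.0, 4.0, 10.0)   # eV/rad²
    bla_mass: float = 10.0                          # amu
    torsion_inertia: float = 50.0                   # amu·Å²
    coupling_s1s0_amp: float = 0.10                 # eV
    coupling_bla_center: float = -0.03              # Å
    coupling_bla_width: float = 0.012               # Å
    coupling_torsion_amp: float = 0.05              # eV
    coupling_s2s1: float = 0.03                     # eV
    coupling_s2s0: float = 0.01                     # eV
    conformer: str = "s-trans"
    conformer_offset: float = 0.25                  # rad, s-cis torsional baseline
    dipoles_from_ground: tuple = (0.05, 2.0)        # |μ(S0→S1)|, |μ(S0→S2)| a.u.
    dipole_s1_sn: float = 1.0                       # |μ(S1→Sn)| a.u.

    def __post_init__(self):
        if self.conformer not in ("s-trans", "s-cis"):
            raise ValueError("conformer must be 's-trans' or 's-cis'")
        if self.bla_minima[0] <= 0:
            raise ValueError("ground-state BLA minimum must be positive")
        if abs(self.bla_minima[1]) > 0.02:
            raise ValueError("S1 BLA minimum must be near zero")
        if self.n_states < 3:
            raise ValueError("surrogate needs at least S0, S1, S2")


class CarotenoidSurrogate(ModelHamiltonian):
    """Reduced 3+-state carotenoid model on (BLA x [Å], torsion φ [rad]).

    Diagonal diabats are displaced harmonic wells; the S0–S1 coupling is a
    logistic switch in BLA (grows below zero) plus a sin²φ torsional term,
    so the S0–S1 adiabatic gap closes both for inverted bond alternation
    and for out-of-plane backbone distortion.
    """

    name = "carotenoid_surrogate"

    def __init__(self, spec: CarotenoidSurrogateSpec | None = None):
        self.spec = spec or CarotenoidSurrogateSpec()
        s = self.spec
        ns = s.n_states
        labels = [f"S{i}" for i in range(ns)]
        super().__init__(ns, [s.bla_mass, s.torsion_inertia], labels=labels)
        self._phi0 = 0.0 if s.conformer == "s-trans" else s.conformer_offset
        # states above S2 (if any) stack upward with S2-like shape
        self._offsets = np.array(
            list(s.state_offsets) + [s.state_offsets[-1] + 0.3 * (i + 1)
                                     for i in range(ns - 3)])
        self._kx = np.array(
            list(s.bla_curvatures) + [s.bla_curvatures[-1]] * (ns - 3))
        self._x0 = np.array(
            list(s.bla_minima) + [s.bla_minima[-1]] * (ns - 3))
        kphi = list(s.torsion_curvatures) + [s.torsion_curvatures[-1]] * (ns - 3)
        self._kphi = np.array(kphi)
        if s.conformer == "s-cis":
            self._kphi = self._kphi * 1.8  # stiffer: narrow distributions

    def diabatic_matrix(self, coords):
        x, phi = float(coords[0]), float(coords[1])
        s = self.spec
        diag = (self._offsets + 0.5 * self._kx * (x - self._x0) ** 2
                + 0.5 * self._kphi * (phi - self._phi0) ** 2)
        v = np.zeros((self.n_states, self.n_states))
        np.fill_diagonal(v, diag)
        c01 = (s.coupling_s1s0_amp
               / (1.0 + np.exp((x - s.coupling_bla_center) / s.coupling_bla_width))
               + s.coupling_torsion_amp * np.sin(phi - self._phi0) ** 2)
        v[0, 1] = v[1, 0] = c01
        v[1, 2] = v[2, 1] = s.coupling_s2s1
        v[0, 2] = v[2, 0] = s.coupling_s2s0
        return v

    def diabatic_gradient(self, coords, h=None):
        x, phi = float(coords[0]), float(coords[1])
        s = self.spec
        out = np.zeros((2, self.n_states, self.n_states))
        np.fill_diagonal(out[0], self._kx * (x - self._x0))
        np.fill_diagonal(out[1], self._kphi * (phi - self._phi0))
        z = np.exp((x - s.coupling_bla_center) / s.coupling_bla_width)
        dc_dx = -s.coupling_s1s0_amp * z / (s.coupling_bla_width * (1 + z) ** 2)
        dc_dphi = s.coupling_torsion_amp * np.sin(2 * (phi - self._phi0))
        out[0, 0, 1] = out[0, 1, 0] = dc_dx
        out[1, 0, 1] = out[1, 1, 0] = dc_dphi
        return out

    def dipole_matrix(self, coords):
        s = self.spec
        mu = np.zeros((self.n_states, self.n_states))
        mu[0, 1] = mu[1, 0] = s.dipoles_from_ground[0]
        mu[0, 2] = mu[2, 0] = s.dipoles_from_ground[1]
        for k in range(2, self.n_states):
            mu[1, k] = mu[k, 1] = s.dipole_s1_sn
        return mu

    def to_config(self):
        return {"format": MODEL_FORMAT_ID, "model": self.name,
                "parameters": asdict(self.spec)}


_MODEL_REGISTRY = {
    AvoidedCrossing1D.name: lambda p: AvoidedCrossing1D(**p),
    HarmonicModel.name: lambda p: HarmonicModel(**p),
    CarotenoidSurrogate.name:
        lambda p: CarotenoidSurrogate(CarotenoidSurrogateSpec(
            **{k: tuple(v) if isinstance(v, list) else v for k, v in p.items()})),
}


def model_from_config(cfg: dict) -> ModelHamiltonian:
    if cfg.get("format") != MODEL_FORMAT_ID:
        raise ValueError(f"unrecognized model format id: {cfg.get('format')!r}")
    name = cfg.get("model")
    if name not in _MODEL_REGISTRY:
        raise ValueError(f"unknown model form {name!r}; "
                         f"known: {sorted(_MODEL_REGISTRY)}")
    return _MODEL_REGISTRY[name](cfg.get("parameters", {}))


def load_model(path) -> ModelHamiltonian:
    """Load a model Hamiltonian from a YAML config file."""
    with open(path) as fh:
        return model_from_config(yaml.safe_load(fh))


def save_model(model: ModelHamiltonian, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(model.to_config(), fh, sort_keys=False)
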