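"""Synthetic surface-hopping ensembles with prescribed statistics.

Generates mock trajectory ensembles — hop-time sequences from a
sequential kinetic model, mean-reverting (Ornstein–Uhlenbeck) geometry
descriptor series with state- and conformer-dependent targets, vertical
energy samples, ESA gap series and transition-charge sets — carrying the
statistical structure the analysis stack assumes, so every pipeline stage
is testable without quantum-chemistry trajectories.

The default :class:`EnsembleSpec` encodes the study conditions this
package analyzes: two conformational sets (A: 396 trajectories, all
s-cis; B: 386, half s-trans), a 15 ps production window, τ₂ ≈ 150 fs
upper-state decay and conformer-dependent bi-exponential S1 decay, wide
s-trans versus narrow s-cis S1 energy distributions around chlorophyll
Qy energies near 2 eV.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import null_space
from scipy.signal import lfilter

from .couplings import ChromophoreTransition, GapSample
from .kinetics import weighted_average_lifetime

__all__ = [
    "ConformerKinetics", "DescriptorDistributions", "EnergyModel",
    "EnsembleSpec", "SyntheticTrajectory", "SyntheticEnsemble",
    "generate_ensemble", "generate_transition_charges", "SpecError",
]

UPPER, S1, S0 = 2, 1, 0


class SpecError(ValueError):
    pass


@dataclass
class ConformerKinetics:
    """Sequential-model parameters of one conformer population."""

    tau2_fs: float
    tau1_ps: float
    tau1_prime_ps: float
    weight_fast: float

    @property
    def tau1_avg_ps(self) -> float:
        return weighted_average_lifetime(
            self.weight_fast, self.tau1_ps, self.tau1_prime_ps, digits=None)


@dataclass
class DescriptorDistributions:
    """Stationary targets of the OU descriptor series, per conformer.

    Angles in degrees, BLA in Å. The s-trans rotamer sits at ds2 ≈ 180°
    with ds1 ≈ 80° and broader BLA / larger backbone twist; the s-cis at
    ds2 ≈ 0°, ds1 ≈ −50°, narrower distributions.
    """

    ds2_center: dict = field(default_factory=lambda: {
        "s-trans": 180.0, "s-cis": 0.0})
    ds2_sigma: dict = field(default_factory=lambda: {
        "s-trans": 8.0, "s-cis": 8.0})
    ds1_center: dict = field(default_factory=lambda: {
        "s-trans": 80.0, "s-cis": -50.0})
    ds1_sigma: dict = field(default_factory=lambda: {
        "s-trans": 15.0, "s-cis": 12.0})
    bla_mean_ground: float = 0.10
    bla_mean_s1: float = 0.0
    bla_sigma: dict = field(default_factory=lambda: {
        "s-trans": 0.020, "s-cis": 0.012})
    # per-dd twist spread (deg) about planarity; lumenal side loosens on S1
    dd_sigma_lumenal: dict = field(default_factory=lambda: {
        "s-trans": 13.0, "s-cis": 10.0})
    dd_sigma_stromal: dict = field(default_factory=lambda: {
        "s-trans": 10.0, "s-cis": 8.0})
    dd_s1_lumenal_factor: float = 1.6
    correlation_time_fs: float = 100.0


@dataclass
class EnergyModel:
    """Vertical-energy statistics: narrow chlorophyll Qy near 2 eV; S1 of
    the s-trans conformer extremely wide (reaching below Qy), s-cis
    narrow and safely above."""

    qy_mean: float = 2.0
    qy_sigma: float = 0.04
    s1_mean: dict = field(default_factory=lambda: {
        "s-trans": 2.2, "s-cis": 2.35})
    s1_sigma: dict = field(default_factory=lambda: {
        "s-trans": 0.60, "s-cis": 0.12})
    esa_gap_mean: dict = field(default_factory=lambda: {
        "s-trans": 2.30, "s-cis": 2.24})
    esa_gap_sigma: float = 0.10
    esa_correlation_time_fs: float = 200.0


@dataclass
class EnsembleSpec:
    """Full specification of a synthetic trajectory ensemble."""

    n_per_set: dict = field(default_factory=lambda: {"A": 396, "B": 386})
    conformer_fractions: dict = field(default_factory=lambda: {
        "A": {"s-cis": 1.0}, "B": {"s-trans": 0.5, "s-cis": 0.5}})
    kinetics: dict = field(default_factory=lambda: {
        "A": {"s-cis": ConformerKinetics(135.0, 1.0, 21.2, 0.201)},
        "B": {"s-cis": ConformerKinetics(162.0, 1.2, 25.0, 0.222),
              "s-trans": ConformerKinetics(141.0, 1.1, 16.7, 0.590)}})
    total_time: float = 15000.0     # fs
    frame_dt: float = 10.0          # fs
    descriptors: DescriptorDistributions = field(
        default_factory=DescriptorDistributions)
    energies: EnergyModel = field(default_factory=EnergyModel)
    # fraction of fast-channel S1→S0 hops decaying through inverted BLA
    # (the remainder through lumenal distortion); free parameter
    bla_channel_fraction: float = 0.67
    seed: int = 2024
    include_descriptor_series: bool = True
    keep_dihedral_series: bool = False

    def validate(self) -> None:
        problems = []
        for s, n in self.n_per_set.items():
            if n < 0:
                problems.append(f"n_per_set[{s}] must be non-negative")
            fr = self.conformer_fractions.get(s)
            if fr is None:
                problems.append(f"conformer_fractions missing set {s}")
                continue
            if abs(sum(fr.values()) - 1.0) > 1e-9:
                problems.append(f"conformer_fractions[{s}] must sum to 1")
            for conf in fr:
                if conf not in self.kinetics.get(s, {}):
                    problems.append(f"kinetics missing ({s}, {conf})")
        for s, by_conf in self.kinetics.items():
            for conf, k in by_conf.items():
                if min(k.tau2_fs, k.tau1_ps, k.tau1_prime_ps) <= 0:
                    problems.append(f"kinetics[{s}][{conf}]: lifetimes > 0")
                if not 0 <= k.weight_fast <= 1:
                    problems.append(f"kinetics[{s}][{conf}]: weight in [0,1]")
        if self.frame_dt <= 0 or self.total_time <= 0:
            problems.append("frame_dt and total_time must be positive")
        if not 0 <= self.bla_channel_fraction <= 1:
            problems.append("bla_channel_fraction must lie in [0, 1]")
        if problems:
            raise SpecError("invalid ensemble spec: " + "; ".join(problems))


@dataclass
class SyntheticTrajectory:
    """Lightweight analysis-grade record of one mock trajectory."""

    times: np.ndarray
    active: np.ndarray              # int8: 2 upper pool, 1 S1, 0 S0
    set_label: str
    conformer: str
    index: int
    t_upper_decay: float            # fs, upper→S1 hop time
    t_s1_decay: float | None        # fs, S1→S0 hop time (None = survivor)
    series: dict = field(default_factory=dict)   # descriptor name -> array
    s1_energy: np.ndarray | None = None          # per-frame vertical S1 (eV)
    _esa_gap: np.ndarray | None = None

    @property
    def esa_gaps(self) -> np.ndarray:
        return self._esa_gap.reshape(-1, 1)

    @property
    def esa_weights(self) -> np.ndarray:
        return np.ones_like(self.esa_gaps)


@dataclass
class SyntheticEnsemble:
    trajectories: list
    hop_table: pd.DataFrame
    spec: EnsembleSpec

    def __len__(self):
        return len(self.trajectories)

    def subset(self, set_label=None, conformer=None) -> "SyntheticEnsemble":
        sel = [t for t in self.trajectories
               if (set_label is None or t.set_label == set_label)
               and (conformer is None or t.conformer == conformer)]
        ht = self.hop_table
        if set_label is not None and len(ht):
            ht = ht[ht["set"] == set_label]
        if conformer is not None and len(ht):
            ht = ht[ht["conformer"] == conformer]
        return SyntheticEnsemble(sel, ht.reset_index(drop=True), self.spec)

    def gap_samples(self, n_ground_frames: int = 50) -> list:
        """One GapSample per (set, conformer): early-window (thermal-ground)
        S1 energies paired with fresh Qy draws."""
        rng = np.random.default_rng(self.spec.seed + 977)
        out = []
        groups: dict = {}
        for t in self.trajectories:
            if t.s1_energy is None:
                continue
            groups.setdefault((t.set_label, t.conformer), []).append(
                t.s1_energy[:n_ground_frames])
        em = self.spec.energies
        for (s, conf), chunks in sorted(groups.items()):
            acc = np.concatenate(chunks)
            donor = rng.normal(em.qy_mean, em.qy_sigma, acc.size)
            out.append(GapSample(donor_energies=donor,
                                 acceptor_energies=acc,
                                 set_label=s, conformer=conf))
        return out


def _ou_series(rng, n, dt, mean, sigma, tau_c, x0=None):
    """Exact-discretization Ornstein–Uhlenbeck series (stationary target).

    The deviation from the mean is an AR(1) process, evaluated with a
    linear filter rather than a Python loop.
    """
    decay = np.exp(-dt / tau_c)
    innov = sigma * np.sqrt(1.0 - decay ** 2)
    start = (rng.normal(mean, sigma) if x0 is None else x0) - mean
    drive = np.concatenate([[start], innov * rng.normal(0.0, 1.0, n - 1)])
    dev = lfilter([1.0], [1.0, -decay], drive)
    return mean + dev


def _ou_series_piecewise(rng, times, dt, means, sigma, tau_c):
    """OU series whose target mean is a per-frame array (state-dependent):
    x_k = μ_k + (x_{k-1} − μ_k)·e^{−dt/τ} + innovation."""
    n = times.size
    decay = np.exp(-dt / tau_c)
    innov = sigma * np.sqrt(1.0 - decay ** 2)
    start = rng.normal(means[0], sigma) - means[0]
    drive = np.concatenate(
        [[start], decay * (means[:-1] - means[1:])
         + innov * rng.normal(0.0, 1.0, n - 1)])
    dev = lfilter([1.0], [1.0, -decay], drive)
    return means + dev


def _hop_descriptors(rng, spec, conformer, channel):
    """(bla, d_lum) at an S1→S0 hop for a given decay channel."""
    if channel == "bla":
        bla = -0.022 - abs(rng.normal(0.01, 0.008))
        d_lum = min(abs(rng.normal(0.05, 0.02)), 0.095)
    elif channel == "distortion":
        d_lum = 0.105 + abs(rng.normal(0.04, 0.03))
        bla = max(rng.normal(0.0, 0.01), -0.019)
    else:  # slow channel: unconstrained, planar-ish near-zero BLA
        bla = rng.normal(-0.005, 0.010)
        d_lum = abs(rng.normal(0.05, 0.03))
    return float(bla), float(d_lum)


def _distortion_from_sigma(rng, n, sigma_deg, n_dihedrals, tau_c, dt,
                           keep=False, scale=None):
    """D-index series from ``n_dihedrals`` OU twist series about planarity.

    ``scale`` optionally widens the twists per frame (e.g. after the S1
    onset). Returns (d_series, dihedral_series or None); dihedrals are
    reported around 180° (trans basin).
    """
    twists = np.empty((n_dihedrals, n))
    for i in range(n_dihedrals):
        twists[i] = _ou_series(rng, n, dt, 0.0, sigma_deg, tau_c)
    if scale is not None:
        twists = twists * np.asarray(scale)[None, :]
    d = np.mean(1.0 - np.abs(np.cos(np.radians(twists))), axis=0)
    dihedrals = 180.0 - twists if keep else None
    return d, dihedrals


def generate_ensemble(spec: EnsembleSpec | None = None) -> SyntheticEnsemble:
    """Generate the mock ensemble described by ``spec`` (reproducible).

    Per trajectory: the upper→S1 hop time is Exp(τ₂); the S1 residence is
    drawn from the bi-exponential mixture w·Exp(τ₁) + (1−w)·Exp(τ₁′),
    truncated at the production window (survivors end on S1). Fast-channel
    hops get hop-frame descriptors in the inverted-BLA channel
    (BLA < −0.02 Å) or the lumenal-distortion channel (D_Lum > 0.10) per
    ``spec.bla_channel_fraction``; descriptor series are OU processes with
    state-dependent means (BLA relaxing toward 0 on S1).
    """
    spec = spec or EnsembleSpec()
    spec.validate()
    des, em = spec.descriptors, spec.energies
    times = np.arange(0.0, spec.total_time + 0.5 * spec.frame_dt,
                      spec.frame_dt)
    nf = times.size
    n_total = sum(spec.n_per_set.values())
    seeds = np.random.SeedSequence(spec.seed).spawn(n_total)
    hop_rows = []
    trajectories = []
    idx = 0
    for set_label in sorted(spec.n_per_set):
        n_set = spec.n_per_set[set_label]
        fracs = spec.conformer_fractions[set_label]
        confs = sorted(fracs)
        counts = {c: int(round(fracs[c] * n_set)) for c in confs}
        # rounding leftovers go to the first conformer
        counts[confs[0]] += n_set - sum(counts.values())
        for conf in confs:
            kin = spec.kinetics[set_label][conf]
            for _ in range(counts[conf]):
                rng = np.random.default_rng(seeds[idx])
                t21 = rng.exponential(kin.tau2_fs)
                fast = rng.random() < kin.weight_fast
                tau = (kin.tau1_ps if fast else kin.tau1_prime_ps) * 1000.0
                dwell = rng.exponential(tau)
                t10 = t21 + dwell
                active = np.full(nf, UPPER, dtype=np.int8)
                active[times >= t21] = S1
                t_s1 = None
                if t10 <= spec.total_time:
                    active[times >= t10] = S0
                    t_s1 = float(t10)
                    if fast:
                        channel = ("bla" if rng.random()
                                   < spec.bla_channel_fraction
                                   else "distortion")
                    else:
                        channel = "slow"
                    bla_h, dlum_h = _hop_descriptors(rng, spec, conf, channel)
                    ds2_h = rng.normal(des.ds2_center[conf],
                                       des.ds2_sigma[conf])
                    hop_rows.append({
                        "trajectory": idx, "set": set_label,
                        "conformer": conf, "time": float(t10),
                        "from_state": 1, "to_state": 0,
                        "bla": bla_h, "d_lum": dlum_h,
                        "ds2": float(ds2_h), "channel": channel})
                hop_rows.append({
                    "trajectory": idx, "set": set_label, "conformer": conf,
                    "time": float(min(t21, spec.total_time)),
                    "from_state": 2, "to_state": 1,
                    "bla": np.nan, "d_lum": np.nan, "ds2": np.nan,
                    "channel": ""})

                series = {}
                s1_energy = None
                esa = None
                if spec.include_descriptor_series:
                    on_s1 = active == S1
                    bla_means = np.where(on_s1, des.bla_mean_s1,
                                         des.bla_mean_ground)
                    series["bla"] = _ou_series_piecewise(
                        rng, times, spec.frame_dt, bla_means,
                        des.bla_sigma[conf],
                        des.correlation_time_fs).astype(np.float32)
                    series["ds1"] = _ou_series(
                        rng, nf, spec.frame_dt, des.ds1_center[conf],
                        des.ds1_sigma[conf],
                        des.correlation_time_fs).astype(np.float32)
                    series["ds2"] = _ou_series(
                        rng, nf, spec.frame_dt, des.ds2_center[conf],
                        des.ds2_sigma[conf],
                        des.correlation_time_fs).astype(np.float32)
                    # lumenal side loosens once S1 is populated
                    lum_scale = np.where(times >= t21,
                                         des.dd_s1_lumenal_factor, 1.0)
                    d_lum, dd_lum = _distortion_from_sigma(
                        rng, nf, des.dd_sigma_lumenal[conf], 4,
                        des.correlation_time_fs, spec.frame_dt,
                        keep=spec.keep_dihedral_series, scale=lum_scale)
                    d_str, dd_str = _distortion_from_sigma(
                        rng, nf, des.dd_sigma_stromal[conf], 5,
                        des.correlation_time_fs, spec.frame_dt,
                        keep=spec.keep_dihedral_series)
                    series["d_lum"] = d_lum.astype(np.float32)
                    series["d_strom"] = d_str.astype(np.float32)
                    if spec.keep_dihedral_series:
                        for i in range(4):
                            series[f"dd{i + 1}"] = dd_lum[i].astype(np.float32)
                        for i in range(5):
                            series[f"dd{i + 5}"] = dd_str[i].astype(np.float32)
                    s1_energy = _ou_series(
                        rng, nf, spec.frame_dt, em.s1_mean[conf],
                        em.s1_sigma[conf],
                        em.esa_correlation_time_fs).astype(np.float32)
                    esa = _ou_series(
                        rng, nf, spec.frame_dt, em.esa_gap_mean[conf],
                        em.esa_gap_sigma,
                        em.esa_correlation_time_fs).astype(np.float32)

                trajectories.append(SyntheticTrajectory(
                    times=times, active=active, set_label=set_label,
                    conformer=conf, index=idx,
                    t_upper_decay=float(t21), t_s1_decay=t_s1,
                    series=series, s1_energy=s1_energy, _esa_gap=esa))
                idx += 1
    hop_table = pd.DataFrame(
        hop_rows, columns=["trajectory", "set", "conformer", "time",
                           "from_state", "to_state", "bla", "d_lum", "ds2",
                           "channel"])
    return SyntheticEnsemble(trajectories=trajectories, hop_table=hop_table,
                             spec=spec)


def generate_transition_charges(n_atoms: int, dipole_target, seed: int = 0,
                                positions=None, noise_scale: float = 0.02,
                                label: str = "synthetic"
                                ) -> ChromophoreTransition:
    """Random atomic transition charges with zero net charge and an exact
    target dipole (e·Å).

    Positions default to a jittered chain with ~1.4 Å spacing. The minimum
    norm charge vector satisfying Σq = 0 and Σ q·r = target is perturbed
    inside the constraint null space for realism. Raises when the target
    is unreachable for the given geometry (e.g. a dipole off-axis for a
    two-atom chromophore).
    """
    if n_atoms < 2:
        raise ValueError("need at least two atoms")
    rng = np.random.default_rng(seed)
    target = np.asarray(dipole_target, dtype=float).reshape(3)
    if positions is None:
        positions = np.zeros((n_atoms, 3))
        positions[:, 0] = 1.4 * np.arange(n_atoms)
        positions += rng.normal(0.0, 0.1, positions.shape)
    else:
        positions = np.asarray(positions, dtype=float)
    a = np.vstack([np.ones(n_atoms), positions.T])   # (4, n)
    b = np.concatenate([[0.0], target])
    q0, *_ = np.linalg.lstsq(a, b, rcond=None)
    if np.linalg.norm(a @ q0 - b) > 1e-8 * max(1.0, np.linalg.norm(b)):
        raise ValueError(
            "dipole target unreachable for the given geometry "
            f"(residual {np.linalg.norm(a @ q0 - b):.2e})")
    ns = null_space(a)
    if ns.size:
        q0 = q0 + ns @ rng.normal(0.0, noise_scale, ns.shape[1])
    return ChromophoreTransition(positions=positions, charges=q0, label=label)
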