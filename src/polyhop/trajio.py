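"""File formats: XYZ trajectories with tabular sidecars, topology and
model configs, hop tables and run manifests.

The XYZ dialect is standard (atom-count line, then a comment line carrying
``t= <fs>``, then element + three floats per atom). Reduced-coordinate
model trajectories are written as pseudo-atoms ``X0, X1, …`` with the
coordinate value in the x column. The per-frame sidecar is a versioned CSV
with time, active state, adiabatic energies, coefficient magnitude/phase,
velocities and transition-dipole magnitudes. Numeric fields are printed
with 12 significant digits, so write→read round-trips are exact at that
precision.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _pkg_version
from .fssh import TrajectoryRecord
from .geometry import ConjugationTopology

SIDECAR_FORMAT_ID = "polyhop-sidecar/1"
TOPOLOGY_FORMAT_ID = "polyhop-topology/1"
MANIFEST_FORMAT_ID = "polyhop-manifest/1"
FLOAT_FMT = "%.12g"


class ParseError(ValueError):
    def __init__(self, message, path=None, line=None):
        loc = f"{path}:{line}: " if path is not None else ""
        super().__init__(f"{loc}{message}")
        self.line = line


def write_trajectory(record: TrajectoryRecord, xyz_path, sidecar_path) -> None:
    """Write geometry frames (XYZ) plus the per-frame tabular sidecar."""
    coords = np.asarray(record.coords)
    reduced = coords.ndim == 2
    with open(xyz_path, "w") as fh:
        for f in range(record.n_frames):
            if reduced:
                n_at = coords.shape[1]
                fh.write(f"{n_at}\nt= {FLOAT_FMT % record.times[f]}\n")
                for i in range(n_at):
                    fh.write(f"X{i} {FLOAT_FMT % coords[f, i]} 0 0\n")
            else:
                n_at = coords.shape[1]
                fh.write(f"{n_at}\nt= {FLOAT_FMT % record.times[f]}\n")
                for i in range(n_at):
                    x, y, z = coords[f, i]
                    fh.write(f"C {FLOAT_FMT % x} {FLOAT_FMT % y} "
                             f"{FLOAT_FMT % z}\n")
    ns = record.n_states
    data = {"time": record.times, "active": record.active}
    for k in range(ns):
        data[f"e{k}"] = record.energies[:, k]
    for k in range(ns):
        data[f"c{k}_mag"] = np.abs(record.coeffs[:, k])
        data[f"c{k}_phase"] = np.angle(record.coeffs[:, k])
    if reduced:
        for q in range(coords.shape[1]):
            data[f"v{q}"] = record.velocities[:, q]
    if record.dipoles_ground is not None:
        for k in range(ns):
            data[f"mu0_{k}"] = record.dipoles_ground[:, k]
    if record.dipoles_s1 is not None:
        for k in range(ns):
            data[f"mu1_{k}"] = record.dipoles_s1[:, k]
    df = pd.DataFrame(data)
    with open(sidecar_path, "w") as fh:
        fh.write(f"# {SIDECAR_FORMAT_ID}\n")
        df.to_csv(fh, index=False, float_format=FLOAT_FMT)


def _read_xyz(path):
    frames, times = [], []
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n_at = int(lines[i].strip())
        except ValueError:
            raise ParseError(f"expected atom count, got {lines[i]!r}",
                             path, i + 1)
        if i + 1 >= len(lines) or "t=" not in lines[i + 1]:
            raise ParseError("comment line must carry 't= <fs>'", path, i + 2)
        times.append(float(lines[i + 1].split("t=")[1].split()[0]))
        block = []
        for j in range(n_at):
            k = i + 2 + j
            if k >= len(lines):
                raise ParseError("truncated frame", path, k + 1)
            parts = lines[k].split()
            if len(parts) < 4:
                raise ParseError(f"malformed atom line {lines[k]!r}",
                                 path, k + 1)
            block.append((parts[0], float(parts[1]), float(parts[2]),
                          float(parts[3])))
        frames.append(block)
        i += 2 + n_at
    return frames, np.asarray(times)


def read_trajectory(xyz_path, sidecar_path) -> TrajectoryRecord:
    """Read a trajectory written by :func:`write_trajectory`."""
    frames, times = _read_xyz(xyz_path)
    with open(sidecar_path) as fh:
        header = fh.readline()
        if SIDECAR_FORMAT_ID not in header:
            raise ParseError(f"missing sidecar format id {SIDECAR_FORMAT_ID}",
                             sidecar_path, 1)
        df = pd.read_csv(fh)
    if len(df) != len(frames):
        raise ParseError(
            f"XYZ has {len(frames)} frames but sidecar has {len(df)} rows",
            sidecar_path, len(df) + 2)
    reduced = all(a[0].startswith("X") for a in frames[0])
    if reduced:
        coords = np.array([[a[1] for a in fr] for fr in frames])
    else:
        coords = np.array([[(a[1], a[2], a[3]) for a in fr] for fr in frames])
    ns = sum(1 for c in df.columns if c.startswith("e"))
    energies = df[[f"e{k}" for k in range(ns)]].to_numpy()
    coeffs = np.array([
        df[f"c{k}_mag"].to_numpy() * np.exp(1j * df[f"c{k}_phase"].to_numpy())
        for k in range(ns)]).T
    vel_cols = [c for c in df.columns if c.startswith("v")]
    velocities = (df[vel_cols].to_numpy() if vel_cols
                  else np.zeros_like(coords))
    dip0 = dip1 = None
    if f"mu0_{0}" in df.columns:
        dip0 = df[[f"mu0_{k}" for k in range(ns)]].to_numpy()
    if f"mu1_{0}" in df.columns:
        dip1 = df[[f"mu1_{k}" for k in range(ns)]].to_numpy()
    return TrajectoryRecord(
        times=df["time"].to_numpy(), coords=coords, velocities=velocities,
        active=df["active"].to_numpy(dtype=int), energies=energies,
        coeffs=coeffs, dipoles_ground=dip0, dipoles_s1=dip1,
        metadata={"source": str(xyz_path)})


def write_hop_table(hops, path) -> None:
    """Hop table as CSV; accepts a DataFrame or HopEvent iterables."""
    if not isinstance(hops, pd.DataFrame):
        rows = []
        for h in hops:
            row = {"time": h.time, "from_state": h.from_state,
                   "to_state": h.to_state,
                   "energy_gap_before": h.energy_gap_before}
            row.update(h.geometry_descriptors)
            rows.append(row)
        hops = pd.DataFrame(rows)
    hops.to_csv(path, index=False, float_format=FLOAT_FMT)


def topology_to_yaml(topology: ConjugationTopology, path) -> None:
    doc = {"format": TOPOLOGY_FORMAT_ID,
           "n_atoms": topology.n_atoms,
           "single_bonds": [list(b) for b in topology.single_bonds],
           "double_bonds": [list(b) for b in topology.double_bonds],
           "dihedrals_s": {k: list(v) for k, v in topology.dihedrals_s.items()},
           "dihedrals_d": {k: list(v) for k, v in topology.dihedrals_d.items()},
           "lumenal": list(topology.lumenal),
           "stromal": list(topology.stromal)}
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def topology_from_yaml(path) -> ConjugationTopology:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if doc.get("format") != TOPOLOGY_FORMAT_ID:
        raise ParseError(f"unrecognized topology format {doc.get('format')!r}",
                         path, 1)
    return ConjugationTopology(
        single_bonds=[tuple(b) for b in doc["single_bonds"]],
        double_bonds=[tuple(b) for b in doc["double_bonds"]],
        dihedrals_s={k: tuple(v) for k, v in doc["dihedrals_s"].items()},
        dihedrals_d={k: tuple(v) for k, v in doc["dihedrals_d"].items()},
        lumenal=doc.get("lumenal", []), stromal=doc.get("stromal", []),
        n_atoms=doc.get("n_atoms", 0))


def write_manifest(path, config: dict, seeds=None) -> None:
    """Run manifest: verbatim config echo + seeds + code version.

    Deliberately carries no timestamps so identical runs produce identical
    artifacts byte for byte.
    """
    doc = {"format": MANIFEST_FORMAT_ID, "polyhop_version": _pkg_version,
           "seeds": seeds if seeds is not None else [],
           "config": config}
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
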