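"""Geometry descriptors of a conjugated chain.

Bond-length alternation (BLA), named backbone dihedrals (ds1–ds9 around
single C−C bonds, dd1–dd9 around double C=C bonds), bounded distortion
indices D / D_Lum / D_Strom quantifying deviation from planarity,
conformer classification from ds2, hop-channel characterization and
photoisomerization detection. The conjugation topology (which bonds are
which, and the lumenal/stromal partition of the C=C dihedrals) is always
explicit input; nothing is perceived from chemistry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ConjugationTopology", "GeometryDescriptors", "DihedralError",
    "compute_bla", "compute_dihedral", "distortion_index",
    "distortion_index_geometry", "classify_conformer", "describe_frame",
    "characterize_hops", "detect_photoisomerization",
    "lutein_like_topology", "build_chain",
]

BLA_CHANNEL_THRESHOLD = -0.02   # Å; hops below count as BLA-driven
DLUM_CHANNEL_THRESHOLD = 0.10   # lumenal distortion marking the twist channel


class DihedralError(ValueError):
    """Torsion undefined (collinear atoms)."""


@dataclass
class ConjugationTopology:
    """Bond lists and named dihedral quartets of the conjugated backbone.

    ``dihedrals_d`` names dd1…ddN (around C=C bonds) ordered from the
    lumenal to the stromal end; ``lumenal`` / ``stromal`` partition those
    names into the two halves of the chain.
    """

    single_bonds: list      # ordered (i, j) atom-index pairs
    double_bonds: list
    dihedrals_s: dict       # name -> (i, j, k, l)
    dihedrals_d: dict
    lumenal: list = field(default_factory=list)   # subset of dihedrals_d keys
    stromal: list = field(default_factory=list)
    n_atoms: int = 0

    def __post_init__(self):
        names = set(self.dihedrals_d)
        if set(self.lumenal) & set(self.stromal):
            raise ValueError("lumenal and stromal dihedral sets overlap")
        if set(self.lumenal) | set(self.stromal) != names:
            raise ValueError("lumenal + stromal must exhaust the C=C dihedrals")
        if self.n_atoms:
            for pair in list(self.single_bonds) + list(self.double_bonds):
                if max(pair) >= self.n_atoms or min(pair) < 0:
                    raise ValueError(f"bond {pair} out of atom range")
            for quart in list(self.dihedrals_s.values()) + \
                    list(self.dihedrals_d.values()):
                if max(quart) >= self.n_atoms or min(quart) < 0:
                    raise ValueError(f"dihedral {quart} out of atom range")


@dataclass
class GeometryDescriptors:
    """Descriptor set of one frame."""

    bla: float                  # Å
    ds: dict                    # name -> degrees in (−180, 180]
    dd: dict
    d_total: float              # D over all C=C dihedrals, in [0, 1]
    d_lum: float
    d_strom: float
    conformer: str              # "s-trans" | "s-cis"


def _bond_lengths(coords: np.ndarray, bonds) -> np.ndarray:
    bonds = np.asarray(bonds, dtype=int)
    return np.linalg.norm(coords[bonds[:, 0]] - coords[bonds[:, 1]], axis=1)


def compute_bla(coords, topology: ConjugationTopology) -> float:
    """Mean single-bond length minus mean double-bond length (Å).

    Positive for an alternating ground-state chain; collapses toward (and
    below) zero when the alternation inverts in the excited state.
    """
    if not topology.single_bonds or not topology.double_bonds:
        raise ValueError("topology must list both single and double bonds")
    coords = np.asarray(coords, dtype=float)
    singles = _bond_lengths(coords, topology.single_bonds)
    doubles = _bond_lengths(coords, topology.double_bonds)
    return float(singles.mean() - doubles.mean())


def compute_dihedral(coords, quartet) -> float:
    """Signed IUPAC torsion of four atoms, degrees in (−180, 180].

    Planar-trans arrangements give 180°, planar-cis 0°. Raises
    :class:`DihedralError` when three consecutive atoms are collinear.
    """
    i, j, k, l = quartet
    if len({i, j, k, l}) != 4:
        raise ValueError("dihedral needs four distinct atoms")
    coords = np.asarray(coords, dtype=float)
    p0, p1, p2, p3 = coords[i], coords[j], coords[k], coords[l]
    b1, b2, b3 = p1 - p0, p2 - p1, p3 - p2
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    tol = 1e-10 * max(np.linalg.norm(b1) * np.linalg.norm(b2), 1e-30)
    if np.linalg.norm(n1) < tol or np.linalg.norm(n2) < tol:
        raise DihedralError(f"collinear atoms in dihedral {quartet}")
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    angle = np.degrees(np.arctan2(np.dot(m1, n2), np.dot(n1, n2)))
    if angle <= -180.0 + 1e-12:
        angle += 360.0
    return float(angle)


def distortion_index(angles_deg) -> float:
    """Bounded planarity deviation D = mean(1 − |cos θ|) over a dihedral set.

    Zero iff every angle is exactly planar (0° or 180°), 1 when all are
    twisted to 90°; a value of 0.10 corresponds to a ~26° mean twist.
    """
    angles = np.atleast_1d(np.asarray(angles_deg, dtype=float))
    if angles.size == 0:
        raise ValueError("empty dihedral set")
    return float(np.mean(1.0 - np.abs(np.cos(np.radians(angles)))))


def distortion_index_geometry(coords, topology: ConjugationTopology,
                              which: str = "all") -> float:
    """D index computed from a geometry over ``which`` ∈ {all, lumenal, stromal}."""
    if which == "all":
        names = list(topology.dihedrals_d)
    elif which == "lumenal":
        names = topology.lumenal
    elif which == "stromal":
        names = topology.stromal
    else:
        raise ValueError("which must be 'all', 'lumenal' or 'stromal'")
    if not names:
        raise ValueError("empty dihedral set")
    angles = [compute_dihedral(coords, topology.dihedrals_d[n]) for n in names]
    return distortion_index(angles)


def classify_conformer(ds2_deg: float) -> str:
    """s-trans for |ds2| ≥ 90° (tie-break at exactly 90° → s-trans),
    s-cis for |ds2| < 90°."""
    if not -180.0 < ds2_deg <= 180.0 + 1e-9:
        raise ValueError("ds2 must lie in (−180, 180] degrees")
    return "s-trans" if abs(ds2_deg) >= 90.0 else "s-cis"


def describe_frame(coords, topology: ConjugationTopology) -> GeometryDescriptors:
    """All descriptors of one geometry frame."""
    ds = {n: compute_dihedral(coords, q) for n, q in topology.dihedrals_s.items()}
    dd = {n: compute_dihedral(coords, q) for n, q in topology.dihedrals_d.items()}
    d_all = distortion_index([dd[n] for n in topology.dihedrals_d])
    d_lum = distortion_index([dd[n] for n in topology.lumenal])
    d_strom = distortion_index([dd[n] for n in topology.stromal])
    return GeometryDescriptors(
        bla=compute_bla(coords, topology), ds=ds, dd=dd,
        d_total=d_all, d_lum=d_lum, d_strom=d_strom,
        conformer=classify_conformer(ds.get("ds2", 180.0)))


# ---------------------------------------------------------------------------
# hop-channel characterization
# ---------------------------------------------------------------------------

def characterize_hops(hops, time_cutoff: float = 2000.0,
                      bla_threshold: float = BLA_CHANNEL_THRESHOLD,
                      dlum_threshold: float = DLUM_CHANNEL_THRESHOLD,
                      from_state: int = 1, to_state: int = 0):
    """Annotate S1→S0 hops with decay-channel flags and summarize counts.

    ``hops``: DataFrame with columns ``time`` (fs), ``from_state``,
    ``to_state``, ``bla`` (Å), ``d_lum`` and optionally ``conformer``; or an
    iterable of HopEvent-like objects whose ``geometry_descriptors`` carry
    ``bla``/``d_lum``. Channels: ``bla_channel`` = BLA below the threshold;
    ``distortion_channel`` = D_Lum above its threshold at non-negative-ish
    BLA (the two channels are disjoint by construction). The summary counts
    each channel's hops and the fraction occurring before ``time_cutoff``.

    Returns ``(table, summary)``; an ensemble without hops yields an empty
    table and zero counts.
    """
    if not isinstance(hops, pd.DataFrame):
        rows = []
        for h in hops:
            row = {"time": h.time, "from_state": h.from_state,
                   "to_state": h.to_state}
            row.update(h.geometry_descriptors)
            rows.append(row)
        hops = pd.DataFrame(
            rows, columns=["time", "from_state", "to_state", "bla", "d_lum",
                           "conformer"])
    df = hops.copy()
    if len(df):
        df = df[(df["from_state"] == from_state)
                & (df["to_state"] == to_state)].copy()
    if not len(df):
        empty = pd.DataFrame(columns=list(hops.columns)
                             + ["bla_channel", "distortion_channel"])
        return empty, {"n_hops": 0, "groups": {}}

    df["bla_channel"] = df["bla"] < bla_threshold
    df["distortion_channel"] = ((df["d_lum"] > dlum_threshold)
                                & (df["bla"] >= bla_threshold))

    def _summarize(sub):
        out = {"n_hops": int(len(sub))}
        for ch in ("bla_channel", "distortion_channel"):
            sel = sub[sub[ch]]
            n = int(len(sel))
            n_within = int((sel["time"] < time_cutoff).sum())
            pct = round(100.0 * n_within / n) if n else 0
            out[ch] = {"n": n, "n_within_cutoff": n_within,
                       "pct_within_cutoff": pct}
        return out

    summary = _summarize(df)
    summary["groups"] = {}
    if "conformer" in df.columns and df["conformer"].notna().any():
        for name, sub in df.groupby("conformer"):
            summary["groups"][name] = _summarize(sub)
    return df, summary


def detect_photoisomerization(dd_series, dwell_frames: int = 50):
    """Detect cis↔trans isomerization events around C=C bonds.

    ``dd_series``: mapping name → per-frame dihedral series (degrees), or a
    single 1-D series. An event is recorded when a series crosses 90° and
    settles in the opposite planar basin (|θ| > 90 ↔ trans, < 90 ↔ cis)
    for at least ``dwell_frames`` consecutive frames. Returns a list of
    ``(name, frame_index, from_basin, to_basin)``.
    """
    if isinstance(dd_series, dict):
        items = dd_series.items()
    else:
        items = [("dd", dd_series)]
    events = []
    for name, series in items:
        series = np.asarray(series, dtype=float)
        basins = np.where(np.abs(series) > 90.0, "trans", "cis")
        cur = basins[0]
        i = 1
        n = basins.size
        while i < n:
            if basins[i] != cur:
                j = i
                while j < n and basins[j] == basins[i]:
                    j += 1
                if j - i >= dwell_frames:
                    events.append((name, i, cur, basins[i]))
                    cur = basins[i]
                i = j
            else:
                i += 1
    return events


# ---------------------------------------------------------------------------
# synthetic chain construction (fixtures and demos)
# ---------------------------------------------------------------------------

def lutein_like_topology() -> ConjugationTopology:
    """A 22-atom conjugated chain with 9 named single-bond (ds) and 9
    double-bond (dd) dihedrals ordered lumenal → stromal, dd1–dd4 lumenal."""
    n_atoms = 22
    singles = [(k, k + 1) for k in range(1, 20, 2)]   # 10 singles
    doubles = [(k, k + 1) for k in range(2, 19, 2)]   # 9 doubles
    ds = {f"ds{m + 1}": (k - 1, k, k + 1, k + 2)
          for m, k in enumerate(range(1, 18, 2))}
    dd = {f"dd{m + 1}": (k - 1, k, k + 1, k + 2)
          for m, k in enumerate(range(2, 19, 2))}
    return ConjugationTopology(
        single_bonds=singles[:9], double_bonds=doubles,
        dihedrals_s=ds, dihedrals_d=dd,
        lumenal=[f"dd{i}" for i in range(1, 5)],
        stromal=[f"dd{i}" for i in range(5, 10)],
        n_atoms=n_atoms)


def build_chain(bond_lengths, torsions_deg, bond_angle_deg: float = 120.0
                ) -> np.ndarray:
    """Cartesian coordinates of a chain from internal coordinates (NeRF).

    ``bond_lengths``: n−1 values; ``torsions_deg``: n−3 values where
    ``torsions_deg[i]`` is the dihedral of atoms (i, i+1, i+2, i+3), i.e.
    the torsion about bond (i+1, i+2). All bond angles are equal.
    """
    lengths = np.asarray(bond_lengths, dtype=float)
    torsions = np.radians(np.asarray(torsions_deg, dtype=float))
    n = lengths.size + 1
    if torsions.size != n - 3:
        raise ValueError("need n-3 torsions for n atoms")
    theta = np.radians(bond_angle_deg)
    coords = np.zeros((n, 3))
    coords[1] = [lengths[0], 0.0, 0.0]
    coords[2] = coords[1] + lengths[1] * np.array(
        [-np.cos(theta), np.sin(theta), 0.0])
    for i in range(3, n):
        a, b, c = coords[i - 3], coords[i - 2], coords[i - 1]
        r = lengths[i - 1]
        phi = torsions[i - 3]
        bc = c - b
        bc /= np.linalg.norm(bc)
        ab = b - a
        nvec = np.cross(ab, bc)
        nvec /= np.linalg.norm(nvec)
        mvec = np.cross(nvec, bc)
        d_local = np.array([-r * np.cos(theta),
                            r * np.sin(theta) * np.cos(phi),
                            -r * np.sin(theta) * np.sin(phi)])
        coords[i] = c + d_local[0] * bc + d_local[1] * mvec + d_local[2] * nvec
    return coords
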