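"""Physical constants and unit conversions.

Internal unit system: energy in eV, length in Å, time in fs, mass in amu.
Torsion-like degrees of freedom carry an inertia in amu·Å² with the
coordinate in radians, so the same kinetic-energy conversion applies.
"""

#: Reduced Planck constant, eV·fs.
HBAR_EV_FS = 0.6582119569

#: 1 amu·Å²/fs² expressed in eV (kinetic-energy conversion).
AMU_A2_FS2_TO_EV = 103.642697

#: 1 Hartree in cm⁻¹.
HARTREE_CM = 219474.6314

#: 1 bohr in Å.
BOHR_ANG = 0.529177211

#: hc in eV·nm, for energy↔wavelength conversion.
EV_NM = 1239.8419
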