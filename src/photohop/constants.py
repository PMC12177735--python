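"""Unit conversion constants (CODATA 2018).

Internal unit system is atomic units throughout: energies in hartree,
lengths in bohr, masses in electron masses, hbar = 1, and time in atomic
time units.  All I/O happens in the conventional spectroscopy units
(angstrom, eV, fs, cm^-1, amu); conversions go through this table only.
"""

# length
BOHR_TO_ANGSTROM = 0.529177210903
ANGSTROM_TO_BOHR = 1.0 / BOHR_TO_ANGSTROM

# energy
HARTREE_TO_EV = 27.211386245988
EV_TO_HARTREE = 1.0 / HARTREE_TO_EV
HARTREE_TO_WAVENUMBER = 219474.6313632
WAVENUMBER_TO_HARTREE = 1.0 / HARTREE_TO_WAVENUMBER

# mass
AMU_TO_AU = 1822.888486209

# time
AU_TIME_TO_FS = 2.4188843265857e-2
FS_TO_AU_TIME = 1.0 / AU_TIME_TO_FS

# hbar in atomic units
HBAR = 1.0

# element masses in amu (most abundant isotope composition averages)
ATOMIC_MASSES = {
    "H": 1.00782503207,
    "C": 12.0,
    "N": 14.0030740048,
    "O": 15.99491461956,
    "X": 1.0,  # generic model particle; mass usually overridden
}
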