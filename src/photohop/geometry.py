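"""Core value types: nuclear geometries and per-geometry electronic data."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import AMU_TO_AU, ATOMIC_MASSES, ANGSTROM_TO_BOHR, BOHR_TO_ANGSTROM


@dataclass(frozen=True)
class Geometry:
    """A molecular geometry.

    Coordinates are stored internally in bohr; masses in amu.  Use
    :meth:`from_angstrom` / :attr:`coords_angstrom` at the I/O boundary.
    """

    atom_labels: tuple[str, ...]
    coords: np.ndarray  # (n_atoms, 3), bohr
    masses: np.ndarray  # (n_atoms,), amu

    def __post_init__(self):
        coords = np.asarray(self.coords, dtype=float)
        masses = np.asarray(self.masses, dtype=float)
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "masses", masses)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValueError(f"coords must be (n, 3), got {coords.shape}")
        if len(self.atom_labels) != coords.shape[0]:
            raise ValueError("label count does not match coordinate rows")
        if masses.shape != (coords.shape[0],):
            raise ValueError("mass count does not match coordinate rows")
        if not np.all(np.isfinite(coords)):
            raise ValueError("non-finite coordinates")
        if np.any(masses <= 0):
            raise ValueError("masses must be positive")

    @classmethod
    def from_angstrom(cls, atom_labels, coords_angstrom, masses=None) -> "Geometry":
        labels = tuple(atom_labels)
        if masses is None:
            masses = np.array([ATOMIC_MASSES[s] for s in labels])
        return cls(labels, np.asarray(coords_angstrom, float) * ANGSTROM_TO_BOHR,
                   np.asarray(masses, float))

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]

    @property
    def coords_angstrom(self) -> np.ndarray:
        return self.coords * BOHR_TO_ANGSTROM

    @property
    def masses_au(self) -> np.ndarray:
        """Masses in electron-mass atomic units."""
        return self.masses * AMU_TO_AU

    def distance(self, i: int, j: int) -> float:
        """Interatomic distance in bohr."""
        return float(np.linalg.norm(self.coords[i] - self.coords[j]))

    def with_coords(self, coords: np.ndarray) -> "Geometry":
        return Geometry(self.atom_labels, coords, self.masses)


@dataclass(frozen=True)
class SurfacePoint:
    """Electronic-structure data at one geometry.

    energies: per-state electronic energies, hartree, in the provider's
        fixed state order (e.g. S0, S1, T1, T2).
    gradients: per-state Cartesian derivatives, hartree/bohr,
        shape (n_states, n_atoms, 3).
    soc_norms: nonnegative spin-orbit-coupling norms, cm^-1, keyed by the
        designated singlet-triplet pair labels, e.g. ("S1", "T1").
    """

    energies: np.ndarray
    gradients: np.ndarray
    soc_norms: dict[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self):
        e = np.asarray(self.energies, float)
        g = np.asarray(self.gradients, float)
        object.__setattr__(self, "energies", e)
        object.__setattr__(self, "gradients", g)
        if not np.all(np.isfinite(e)):
            raise ValueError("non-finite energies")
        if g.ndim != 3 or g.shape[0] != e.shape[0] or g.shape[2] != 3:
            raise ValueError(f"gradients must be (n_states, n_atoms, 3), got {g.shape}")
        for pair, v in self.soc_norms.items():
            if v < 0:
                raise ValueError(f"negative SOC norm for {pair}")


def kinetic_energy(velocities: np.ndarray, masses_au: np.ndarray) -> float:
    """Kinetic energy in hartree; velocities in bohr / a.u. time."""
    v = np.asarray(velocities, float)
    return float(0.5 * np.sum(masses_au[:, None] * v * v))
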