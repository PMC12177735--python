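"""Zero-point Wigner sampling and pathway interpolation.

Initial conditions for trajectory launch are drawn from the Wigner
distribution of the harmonic vibrational ground state: for each retained
normal mode of (mass-weighted) frequency omega, the mass-weighted
coordinate and momentum are independent Gaussians

    Q ~ N(0, hbar / (2 omega)),      P ~ N(0, hbar omega / 2),

so the mean sampled energy per mode is the zero-point energy hbar*omega/2.
Sampling is performed at 0 K (no thermal excitation).  Randomness uses a
counter-based generator (Philox) with an explicit substream per draw, so
ensembles are reproducible independent of execution order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np

from .constants import WAVENUMBER_TO_HARTREE
from .errors import SamplingError, ShapeError
from .geometry import Geometry


@dataclass(frozen=True)
class NormalModeSet:
    """Harmonic normal modes at a reference geometry.

    frequencies: harmonic wavenumbers, cm^-1 (negative = imaginary).
    mode_vectors: (n_modes, n_atoms, 3) mass-weighted orthonormal vectors.
    reference_geometry: the expansion point.
    retained_mask: True for modes sampled by Wigner sampling; modes with
        |frequency| below the translational/rotational cutoff are excluded.
    """

    frequencies: np.ndarray
    mode_vectors: np.ndarray
    reference_geometry: Geometry
    retained_mask: np.ndarray

    def __post_init__(self):
        L = np.asarray(self.mode_vectors, float)
        n_modes = L.shape[0]
        flat = L.reshape(n_modes, -1)
        gram = flat @ flat.T
        if not np.allclose(gram, np.eye(n_modes), atol=1e-8):
            raise ValueError("mode vectors are not orthonormal (tol 1e-8)")

    @property
    def retained_frequencies(self) -> np.ndarray:
        return self.frequencies[self.retained_mask]

    @property
    def n_retained(self) -> int:
        return int(np.count_nonzero(self.retained_mask))


@dataclass(frozen=True)
class InitialCondition:
    """One sampled phase-space point (positions in bohr, velocities in a.u.)."""

    geometry: Geometry
    velocities: np.ndarray
    seed_record: dict

    def __post_init__(self):
        v = np.asarray(self.velocities, float)
        object.__setattr__(self, "velocities", v)
        if v.shape != self.geometry.coords.shape:
            raise ShapeError("velocity shape does not match coordinates")


class ProvenancedGeometry(NamedTuple):
    geometry: Geometry
    provenance: str


def _substream(seed: int, index: int) -> np.random.Generator:
    """Independent Philox substream for draw `index` under master `seed`."""
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(int(index),))
    return np.random.Generator(np.random.Philox(ss))


def sample_wigner(
    modes: NormalModeSet,
    n: int,
    seed: int,
    remove_rotation: bool = False,
) -> list[InitialCondition]:
    """Draw `n` initial conditions from the ground-state Wigner function.

    Total linear momentum is removed from every sample.  Angular momentum
    is only projected out when `remove_rotation` is set (off by default,
    since rotation removal changes the sampled kinetic energies).
    """
    if n < 0:
        raise ValueError("n must be nonnegative")
    freqs = modes.retained_frequencies
    if np.any(freqs <= 0):
        raise SamplingError("retained modes contain imaginary/zero frequencies")

    ref = modes.reference_geometry
    masses_au = ref.masses_au
    sqrt_m = np.sqrt(masses_au)[:, None]
    L = modes.mode_vectors[modes.retained_mask]  # (m, n_atoms, 3)
    omega = freqs * WAVENUMBER_TO_HARTREE  # a.u.

    sigma_q = np.sqrt(1.0 / (2.0 * omega))
    sigma_p = np.sqrt(omega / 2.0)

    out = []
    for i in range(n):
        rng = _substream(seed, i)
        q = rng.normal(0.0, sigma_q)
        p = rng.normal(0.0, sigma_p)
        dx = np.tensordot(q, L, axes=(0, 0)) / sqrt_m
        vel = np.tensordot(p, L, axes=(0, 0)) / sqrt_m
        # remove center-of-mass velocity
        total_m = masses_au.sum()
        vcom = (masses_au[:, None] * vel).sum(axis=0) / total_m
        vel = vel - vcom
        coords = ref.coords + dx
        if remove_rotation:
            vel = _remove_angular_momentum(coords, vel, masses_au)
        out.append(
            InitialCondition(
                geometry=ref.with_coords(coords),
                velocities=vel,
                seed_record={"seed": int(seed), "index": i},
            )
        )
    return out


def _remove_angular_momentum(coords, vel, masses_au):
    com = (masses_au[:, None] * coords).sum(axis=0) / masses_au.sum()
    r = coords - com
    Ltot = np.sum(masses_au[:, None] * np.cross(r, vel), axis=0)
    inertia = np.zeros((3, 3))
    for ri, m in zip(r, masses_au):
        inertia += m * (np.dot(ri, ri) * np.eye(3) - np.outer(ri, ri))
    omega = np.linalg.lstsq(inertia, Ltot, rcond=None)[0]
    return vel - np.cross(np.tile(omega, (r.shape[0], 1)), r)


def linear_interpolate_path(start: Geometry, end: Geometry, n_points: int) -> list[Geometry]:
    """Cartesian linear interpolation between two geometries, inclusive.

    A lightweight stand-in for internal-coordinate (geodesic) interpolation,
    adequate for assembling fixture pathways on analytic surfaces.
    """
    if start.atom_labels != end.atom_labels or start.coords.shape != end.coords.shape:
        raise ShapeError("start/end geometries have different atoms")
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    ts = np.linspace(0.0, 1.0, n_points)
    return [
        start.with_coords((1.0 - t) * start.coords + t * end.coords) for t in ts
    ]


def build_training_geometries(
    modes: NormalModeSet,
    paths: Sequence[tuple[Geometry, Geometry]],
    n_wigner: int,
    n_path: int,
    seed: int,
    dedupe_tol: float = 1e-8,
) -> list[ProvenancedGeometry]:
    """Assemble the initial training-set geometries.

    Union of `n_wigner` Wigner samples about the reference and `n_path`
    linearly interpolated structures per (start, end) path, deduplicated by
    coordinate identity (max-abs difference below `dedupe_tol`, bohr).
    """
    labeled: list[ProvenancedGeometry] = []
    for ic in sample_wigner(modes, n_wigner, seed):
        labeled.append(ProvenancedGeometry(ic.geometry, "wigner"))
    for ipath, (a, b) in enumerate(paths):
        for g in linear_interpolate_path(a, b, n_path):
            labeled.append(ProvenancedGeometry(g, f"path{ipath}"))

    unique: list[ProvenancedGeometry] = []
    for item in labeled:
        dup = any(
            item.geometry.coords.shape == u.geometry.coords.shape
            and np.max(np.abs(item.geometry.coords - u.geometry.coords)) < dedupe_tol
            for u in unique
        )
        if not dup:
            unique.append(item)
    return unique
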