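"""Inverse-distance-matrix descriptor.

The feature vector is the flattened upper triangle of the inverse
interatomic-distance matrix (1/bohr) in fixed atom order, which makes
predictions exactly invariant under rigid rotations and translations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..errors import DegenerateGeometryError, ShapeError
from ..geometry import Geometry

DISTANCE_FLOOR_BOHR = 0.2


@dataclass(frozen=True)
class Descriptor:
    values: np.ndarray  # (n_pairs,), 1/bohr


def pair_list(n_atoms: int) -> list[tuple[int, int]]:
    return [(a, b) for a in range(n_atoms) for b in range(a + 1, n_atoms)]


def featurize(geom: Geometry) -> Descriptor:
    """Inverse distances 1/||r_a - r_b|| for all pairs a < b."""
    n = geom.n_atoms
    if n < 2:
        raise ShapeError("descriptor needs at least 2 atoms")
    diff = geom.coords[:, None, :] - geom.coords[None, :, :]
    dist = np.linalg.norm(diff, axis=-1)
    iu = np.triu_indices(n, k=1)
    d = dist[iu]
    if np.any(d < DISTANCE_FLOOR_BOHR):
        raise DegenerateGeometryError(
            f"atoms closer than {DISTANCE_FLOOR_BOHR} bohr"
        )
    return Descriptor(values=1.0 / d)


def featurize_with_jacobian(geom: Geometry) -> tuple[np.ndarray, np.ndarray]:
    """Features plus d(features)/d(Cartesian coords), shape (n_pairs, 3*n)."""
    n = geom.n_atoms
    feats = featurize(geom).values
    pairs = pair_list(n)
    J = np.zeros((len(pairs), n, 3))
    for p, (a, b) in enumerate(pairs):
        rab = geom.coords[a] - geom.coords[b]
        r = np.linalg.norm(rab)
        g = -rab / r**3  # d(1/r)/d x_a
        J[p, a] = g
        J[p, b] = -g
    return feats, J.reshape(len(pairs), 3 * n)
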