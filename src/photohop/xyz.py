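"""Multi-frame XYZ reading and writing.

Format (documented; no external dependency needed for so simple a format):
line 1 of each frame is the atom count, line 2 a comment carrying
whitespace-separated key=value metadata pairs (preserved verbatim), then
one `label x y z` line per atom with coordinates in angstrom printed to 10
decimal places.  Frames repeat back to back.
"""

from __future__ import annotations

import numpy as np

from .errors import ParseError
from .geometry import Geometry

PRINT_DECIMALS = 10


def write_xyz(path, frames) -> None:
    """Write (Geometry, metadata-dict) pairs as multi-frame XYZ."""
    lines = []
    for geom, meta in frames:
        lines.append(str(geom.n_atoms))
        lines.append(" ".join(f"{k}={v}" for k, v in meta.items()))
        for lbl, xyz in zip(geom.atom_labels, geom.coords_angstrom):
            lines.append(
                f"{lbl} "
                + " ".join(f"{c:.{PRINT_DECIMALS}f}" for c in xyz)
            )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def _parse_meta(comment: str) -> dict[str, str]:
    meta = {}
    for tok in comment.split():
        if "=" in tok:
            k, v = tok.split("=", 1)
            meta[k] = v
    return meta


def read_xyz(path, masses=None) -> list[tuple[Geometry, dict[str, str]]]:
    """Read a multi-frame XYZ file into (Geometry, metadata) pairs.

    Malformed frame headers or truncated frames raise ParseError carrying
    the 1-based line number.
    """
    with open(path) as fh:
        lines = fh.read().splitlines()
    frames = []
    i = 0
    n_lines = len(lines)
    while i < n_lines:
        if not lines[i].strip():
            i += 1
            continue
        header_line = i + 1
        try:
            n_atoms = int(lines[i].strip())
        except ValueError:
            raise ParseError(
                f"expected an atom count, got {lines[i]!r}", line=header_line
            )
        if n_atoms <= 0:
            raise ParseError("atom count must be positive", line=header_line)
        if i + 1 >= n_lines:
            raise ParseError("missing comment line", line=header_line + 1)
        meta = _parse_meta(lines[i + 1])
        if i + 2 + n_atoms > n_lines:
            raise ParseError(
                f"frame starting here declares {n_atoms} atoms but the file "
                "ends early",
                line=header_line,
            )
        labels, coords = [], []
        for a in range(n_atoms):
            ln = i + 2 + a
            parts = lines[ln].split()
            if len(parts) != 4:
                raise ParseError(
                    f"expected 'label x y z', got {lines[ln]!r}", line=ln + 1
                )
            labels.append(parts[0])
            try:
                coords.append([float(x) for x in parts[1:]])
            except ValueError:
                raise ParseError(
                    f"non-numeric coordinate in {lines[ln]!r}", line=ln + 1
                )
        frames.append(
            (Geometry.from_angstrom(labels, np.array(coords), masses), meta)
        )
        i += 2 + n_atoms
    return frames
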