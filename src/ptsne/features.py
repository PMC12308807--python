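"""Featurization of molecular conformations and the tool's text formats.

Two descriptor families cover the typical peptide workflow: all pairwise
distances among a selection of (heavy) atoms, and sin/cos pairs of backbone
torsion angles.  Both are invariant under rigid rotation and translation of
the conformation, which is what makes them usable as embedding inputs.

File formats are deliberately plain: whitespace-delimited numeric matrices
with ``#`` comments, and the standard multi-frame XYZ dialect
(atom-count line, comment line, then ``element x y z`` rows).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ConformationSet",
    "read_matrix",
    "write_matrix",
    "read_xyz",
    "write_xyz",
    "heavy_atom_indices",
    "distance_features",
    "dihedral_angle",
    "sincos_features",
]


@dataclass
class ConformationSet:
    """A stack of conformations of one molecule.

    coords has shape (n_frames, n_atoms, 3); atom_labels holds one
    element/name string per atom.
    """

    coords: np.ndarray
    atom_labels: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError(
                f"coords must have shape (frames, atoms, 3), got {self.coords.shape}"
            )
        if self.coords.shape[1] < 2:
            raise ValueError("need at least 2 atoms")
        if not np.isfinite(self.coords).all():
            raise ValueError("non-finite coordinates")
        if not self.atom_labels:
            self.atom_labels = ["X"] * self.coords.shape[1]
        if len(self.atom_labels) != self.coords.shape[1]:
            raise ValueError("atom_labels length does not match atom count")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]


# ---------------------------------------------------------------------------
# text matrix I/O


def read_matrix(path, columns=None) -> np.ndarray:
    """Read a whitespace-delimited numeric matrix, ``#`` lines skipped.

    Parameters
    ----------
    path : str or Path
    columns : sequence of int, optional
        Column indices to keep, in the stated order.  ``None`` keeps all.

    Raises
    ------
    ValueError
        On ragged rows or non-numeric tokens (the line number is reported),
        or an empty column selection.
    """
    if columns is not None:
        columns = list(columns)
        if len(columns) == 0:
            raise ValueError("empty column selection")
    rows = []
    width = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            tokens = stripped.split()
            try:
                values = [float(t) for t in tokens]
            except ValueError as exc:
                raise ValueError(f"{path}: non-numeric token on line {lineno}") from exc
            if width is None:
                width = len(values)
            elif len(values) != width:
                raise ValueError(
                    f"{path}: line {lineno} has {len(values)} columns, "
                    f"expected {width}"
                )
            rows.append(values)
    if not rows:
        raise ValueError(f"{path}: no data rows")
    X = np.asarray(rows, dtype=float)
    if columns is not None:
        if max(columns) >= X.shape[1] or min(columns) < 0:
            raise ValueError(
                f"column selection {columns} out of range for {X.shape[1]} columns"
            )
        X = X[:, columns]
    return X


def write_matrix(path, X, header: list[str] | None = None) -> None:
    """Write a matrix as TSV with an optional ``#``-prefixed column header."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    with open(path, "w") as fh:
        if header:
            fh.write("# " + "\t".join(header) + "\n")
        for row in X:
            fh.write("\t".join(format(v, ".10g") for v in row) + "\n")


# ---------------------------------------------------------------------------
# XYZ I/O


def read_xyz(path) -> ConformationSet:
    """Read a (multi-frame) XYZ file.

    Every frame must carry the same atom count; violations are reported
    with the offending frame index.
    """
    frames = []
    labels: list[str] = []
    with open(path) as fh:
        lines = fh.readlines()
    pos = 0
    frame_no = 0
    n_lines = len(lines)
    while pos < n_lines:
        if not lines[pos].strip():
            pos += 1
            continue
        try:
            n_atoms = int(lines[pos].strip())
        except ValueError:
            raise ValueError(
                f"{path}: malformed atom-count line {pos + 1} "
                f"({lines[pos].strip()!r})"
            ) from None
        if pos + 1 + n_atoms >= n_lines + 1:
            raise ValueError(f"{path}: truncated frame {frame_no}")
        block = lines[pos + 2: pos + 2 + n_atoms]
        if len(block) < n_atoms:
            raise ValueError(f"{path}: truncated frame {frame_no}")
        coords = np.empty((n_atoms, 3))
        frame_labels = []
        for a, line in enumerate(block):
            parts = line.split()
            if len(parts) < 4:
                raise ValueError(
                    f"{path}: bad atom line in frame {frame_no}, atom {a}"
                )
            frame_labels.append(parts[0])
            try:
                coords[a] = [float(p) for p in parts[1:4]]
            except ValueError:
                raise ValueError(
                    f"{path}: non-numeric coordinate in frame {frame_no}, atom {a}"
                ) from None
        if frames and n_atoms != frames[0].shape[0]:
            raise ValueError(
                f"{path}: frame {frame_no} has {n_atoms} atoms, "
                f"frame 0 has {frames[0].shape[0]}"
            )
        if not labels:
            labels = frame_labels
        frames.append(coords)
        pos += 2 + n_atoms
        frame_no += 1
    if not frames:
        raise ValueError(f"{path}: no frames found")
    return ConformationSet(np.stack(frames), labels)


def write_xyz(path, conf: ConformationSet, comment: str = "") -> None:
    """Write a ConformationSet in multi-frame XYZ format."""
    with open(path, "w") as fh:
        for f in range(conf.n_frames):
            fh.write(f"{conf.n_atoms}\n{comment}\n")
            for label, (x, y, z) in zip(conf.atom_labels, conf.coords[f]):
                fh.write(f"{label} {x:.10g} {y:.10g} {z:.10g}\n")


# ---------------------------------------------------------------------------
# descriptors


def heavy_atom_indices(conf: ConformationSet) -> list[int]:
    """Indices of atoms whose element label is not hydrogen."""
    return [
        i
        for i, lab in enumerate(conf.atom_labels)
        if lab.strip()[:1].upper() != "H"
    ]


def distance_features(conf: ConformationSet, selection=None) -> np.ndarray:
    """Pairwise distances among selected atoms, one row per frame.

    Pairs are ordered lexicographically by selection order (i < j), giving
    ``s * (s - 1) / 2`` features for ``s`` selected atoms; ten heavy atoms
    yield the 45 inter-heavy-atom distances of a dipeptide descriptor set.
    """
    if selection is None:
        selection = heavy_atom_indices(conf)
    sel = list(selection)
    if len(sel) != len(set(sel)):
        raise ValueError("selection contains duplicates")
    if len(sel) < 2:
        raise ValueError("need at least 2 selected atoms")
    if max(sel) >= conf.n_atoms or min(sel) < 0:
        raise ValueError(f"selection out of range for {conf.n_atoms} atoms")
    xyz = conf.coords[:, sel, :]
    ii, jj = np.triu_indices(len(sel), k=1)
    diff = xyz[:, ii, :] - xyz[:, jj, :]
    return np.sqrt((diff**2).sum(axis=2))


def dihedral_angle(conf: ConformationSet, quad) -> np.ndarray:
    """Signed torsion angle about the b–c bond, in degrees, range (-180, 180].

    ``quad`` is the four atom indices (a, b, c, d).  Uses the standard
    atan2 construction from the two plane normals, with the IUPAC sign
    convention (cis = 0, trans = 180).  Frames where the three bond vectors
    degenerate (zero length or exact collinearity) yield NaN.
    """
    a, b, c, d = (int(i) for i in quad)
    if len({a, b, c, d}) != 4:
        raise ValueError(f"dihedral indices must be distinct, got {(a, b, c, d)}")
    if max(a, b, c, d) >= conf.n_atoms or min(a, b, c, d) < 0:
        raise ValueError(f"dihedral indices out of range for {conf.n_atoms} atoms")
    p = conf.coords
    b1 = p[:, b] - p[:, a]
    b2 = p[:, c] - p[:, b]
    b3 = p[:, d] - p[:, c]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2n = np.linalg.norm(b2, axis=1)
    y = np.einsum("ij,ij->i", np.cross(n1, n2), b2) / np.where(b2n > 0, b2n, 1.0)
    x = np.einsum("ij,ij->i", n1, n2)
    bad = (np.linalg.norm(n1, axis=1) == 0) | (np.linalg.norm(n2, axis=1) == 0)
    ang = np.degrees(np.arctan2(y, x))
    # atan2 returns (-180, 180]; fold the -180 representative onto +180
    ang[ang <= -180.0] = 180.0
    ang[bad] = np.nan
    return ang


def sincos_features(angles, degrees: bool = True) -> np.ndarray:
    """Interleaved (sin, cos) columns for each input angle column.

    ``k`` angle columns yield ``2k`` features; three (phi, psi) torsion
    pairs give the 12-feature sin/cos descriptor of a tetrapeptide.  Every
    (sin, cos) pair lies on the unit circle by construction.
    """
    A = np.atleast_2d(np.asarray(angles, dtype=float))
    if A.ndim != 2:
        raise ValueError(f"angles must be 1-D or 2-D, got shape {A.shape}")
    if A.shape[0] == 1 and np.asarray(angles).ndim == 1:
        A = A.T
    if not np.isfinite(A).all():
        raise ValueError("non-finite angle values")
    rad = np.radians(A) if degrees else A
    out = np.empty((A.shape[0], 2 * A.shape[1]))
    out[:, 0::2] = np.sin(rad)
    out[:, 1::2] = np.cos(rad)
    return out
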