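"""Lattice representation and geometry bookkeeping for the Cellular Potts model.

A configuration is a 2D integer label image: pixel value 0 is the medium
(the perigonadal environment), positive values are cell ids. Each cell id
maps to a :class:`CellKind` (PGC or SGP). Geometry — per-cell volume
(pixel count), perimeter (boundary edge count) and per-interface shared edge
counts — is measured on the 4-neighbour pixel graph; pixels outside the
grid are treated as medium (fixed-medium boundary condition).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

MEDIUM_ID = 0


class CellKind(enum.IntEnum):
    """Cell classes. MEDIUM is the reserved background (label id 0)."""

    MEDIUM = 0
    PGC = 1
    SGP = 2


class BoundaryCondition(enum.Enum):
    FIXED_MEDIUM = "fixed-medium"


@dataclass(frozen=True)
class CellLabel:
    """A cell identity: a positive integer id plus its kind."""

    id: int
    kind: CellKind

    def __post_init__(self) -> None:
        if self.kind is CellKind.MEDIUM and self.id != MEDIUM_ID:
            raise ValueError("MEDIUM must carry the reserved id 0")
        if self.kind is not CellKind.MEDIUM and self.id <= 0:
            raise ValueError("cell ids must be positive")


@dataclass
class LatticeState:
    """A full lattice configuration.

    Parameters
    ----------
    labels
        ``(height, width)`` integer array; 0 is medium, ``1..n`` are cells.
    kinds
        1D array mapping label id -> :class:`CellKind` value; ``kinds[0]``
        must be MEDIUM.
    """

    labels: np.ndarray
    kinds: np.ndarray
    boundary_condition: BoundaryCondition = BoundaryCondition.FIXED_MEDIUM

    def __post_init__(self) -> None:
        self.labels = np.ascontiguousarray(self.labels, dtype=np.int32)
        self.kinds = np.ascontiguousarray(self.kinds, dtype=np.int8)
        if self.labels.ndim != 2:
            raise ValueError("labels must be a 2D array")
        if self.kinds[MEDIUM_ID] != CellKind.MEDIUM:
            raise ValueError("kinds[0] must be MEDIUM")
        if self.labels.max(initial=0) >= len(self.kinds):
            raise ValueError("label id exceeds kinds table")
        if (self.kinds[1:] == CellKind.MEDIUM).any():
            raise ValueError("only id 0 may be MEDIUM")

    @property
    def dims(self) -> tuple[int, int]:
        return self.labels.shape  # (height, width)

    @property
    def n_labels(self) -> int:
        """Number of label slots including medium."""
        return len(self.kinds)

    def cell_ids(self, kind: CellKind | None = None) -> np.ndarray:
        ids = np.arange(1, self.n_labels)
        if kind is None:
            return ids
        return ids[self.kinds[1:] == kind]

    def copy(self) -> "LatticeState":
        return LatticeState(
            self.labels.copy(), self.kinds.copy(), self.boundary_condition
        )


@dataclass
class CellGeometry:
    """Exact integer geometry of a configuration.

    ``volumes[i]`` is the pixel count of label ``i``; ``perimeters[i]`` its
    boundary length in lattice-edge units; ``interfaces[i, j]`` the number of
    4-neighbour pixel edges shared by labels ``i`` and ``j`` (symmetric).
    The perimeter of every label equals the sum of its interface lengths.
    """

    volumes: np.ndarray
    perimeters: np.ndarray
    interfaces: np.ndarray

    @property
    def interface_lengths(self) -> dict[tuple[int, int], int]:
        """Sparse ``{(i, j): length}`` view of the interface matrix, i < j."""
        out: dict[tuple[int, int], int] = {}
        n = self.interfaces.shape[0]
        for i in range(n):
            for j in range(i + 1, n):
                if self.interfaces[i, j]:
                    out[(i, j)] = int(self.interfaces[i, j])
        return out

    def copy(self) -> "CellGeometry":
        return CellGeometry(
            self.volumes.copy(), self.perimeters.copy(), self.interfaces.copy()
        )

    def check_consistency(self) -> None:
        if not np.array_equal(self.interfaces, self.interfaces.T):
            raise AssertionError("interface matrix must be symmetric")
        if not np.array_equal(self.perimeters, self.interfaces.sum(axis=1)):
            raise AssertionError("perimeter must equal summed interface lengths")
        if (self.volumes < 0).any() or (self.interfaces < 0).any():
            raise AssertionError("geometry quantities must be nonnegative")


def compute_geometry(state: LatticeState) -> CellGeometry:
    """Measure volumes, perimeters and interface lengths by edge enumeration.

    Every horizontal and vertical pixel-edge pair is visited once; border
    pixels additionally contribute an edge against the virtual medium
    outside the grid.
    """
    labels = state.labels
    n = state.n_labels
    volumes = np.bincount(labels.ravel(), minlength=n).astype(np.int64)
    interfaces = np.zeros((n, n), dtype=np.int64)

    def _accumulate(a: np.ndarray, b: np.ndarray) -> None:
        m = a != b
        if m.any():
            np.add.at(interfaces, (a[m], b[m]), 1)
            np.add.at(interfaces, (b[m], a[m]), 1)

    _accumulate(labels[:, :-1].ravel(), labels[:, 1:].ravel())
    _accumulate(labels[:-1, :].ravel(), labels[1:, :].ravel())
    # fixed-medium boundary: edges against the virtual medium frame
    for border in (labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1]):
        nz = border[border != MEDIUM_ID].astype(np.intp)
        if nz.size:
            np.add.at(interfaces, (nz, MEDIUM_ID), 1)
            np.add.at(interfaces, (MEDIUM_ID, nz), 1)

    perimeters = interfaces.sum(axis=1)
    return CellGeometry(volumes, perimeters, interfaces)
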