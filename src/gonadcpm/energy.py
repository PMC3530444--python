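"""The three-term Cellular Potts potential and its incremental differences.

The total energy of a configuration is

    U = sum_cells (K_i/2)(V_i - V_i0)^2          (volume elasticity)
      + sum_interfaces E_j * l_j                 (linear interfacial energy)
      + sum_cells (C_i/2) * L_i^2                (quadratic cortical tension)

where V_i and L_i are the volume and peripheral length of cell i and l_j is
the shared edge length of interface j. The medium carries no volume or
perimeter terms and enters only through cell–medium ("out") interfacial
coefficients. Negative E favours longer contact (adhesion); positive E
favours contraction (tension).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .lattice import MEDIUM_ID, CellGeometry, CellKind, LatticeState, compute_geometry

KindPair = tuple[CellKind, CellKind]


class ConfigurationError(ValueError):
    """Raised when energy parameters are incomplete or inconsistent."""


def pair_key(a: CellKind, b: CellKind) -> KindPair:
    """Canonical unordered kind pair."""
    a, b = CellKind(a), CellKind(b)
    return (a, b) if a <= b else (b, a)


@dataclass
class EnergyParameters:
    """All coefficients of the potential, in absolute (lattice) units.

    ``K``, ``V0``, ``C`` map non-medium kinds to the elastic coefficient,
    favoured volume (pixels) and quadratic perimeter coefficient. ``E`` maps
    unordered kind pairs — (PGC, PGC), (PGC, SGP), (SGP, SGP) and the
    cell–medium pairs standing for the "out" coefficients — to linear
    interfacial coefficients. ``beta`` is the inverse temperature of the
    Metropolis dynamics.
    """

    K: Mapping[CellKind, float]
    V0: Mapping[CellKind, float]
    C: Mapping[CellKind, float]
    E: Mapping[KindPair, float]
    beta: float

    def __post_init__(self) -> None:
        self.E = {pair_key(*k): float(v) for k, v in self.E.items()}
        if self.beta <= 0:
            raise ConfigurationError("beta must be positive")
        for kind in (CellKind.PGC, CellKind.SGP):
            if kind in self.V0 and self.V0[kind] <= 0:
                raise ConfigurationError(f"V0[{kind.name}] must be positive")
            if kind in self.K and self.K[kind] < 0:
                raise ConfigurationError(f"K[{kind.name}] must be nonnegative")
        if CellKind.MEDIUM in self.K or CellKind.MEDIUM in self.V0:
            raise ConfigurationError("the medium has no volume terms")

    def kind_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Dense per-kind arrays (K3, V03, C3, E33); missing E entries are NaN."""
        K3 = np.zeros(3)
        V03 = np.zeros(3)
        C3 = np.zeros(3)
        for kind in (CellKind.PGC, CellKind.SGP):
            K3[kind] = self.K.get(kind, 0.0)
            V03[kind] = self.V0.get(kind, 0.0)
            C3[kind] = self.C.get(kind, 0.0)
        E33 = np.full((3, 3), np.nan)
        E33[MEDIUM_ID, MEDIUM_ID] = 0.0  # medium-medium: never an interface
        for (a, b), v in self.E.items():
            E33[a, b] = v
            E33[b, a] = v
        return K3, V03, C3, E33

    def require_pairs(self, kinds_present: set[CellKind]) -> None:
        """Fail if any interface class that can occur has no E entry."""
        cells = sorted(k for k in kinds_present if k is not CellKind.MEDIUM)
        needed: list[KindPair] = []
        for i, a in enumerate(cells):
            needed.append(pair_key(a, CellKind.MEDIUM))
            for b in cells[i:]:
                needed.append(pair_key(a, b))
        missing = [p for p in needed if p not in self.E]
        if missing:
            names = ", ".join(f"({a.name}, {b.name})" for a, b in missing)
            raise ConfigurationError(f"missing interfacial coefficient(s): {names}")


def total_energy(
    state: LatticeState,
    params: EnergyParameters,
    geometry: CellGeometry | None = None,
) -> float:
    """Total potential energy of a configuration.

    Each unordered interface is counted exactly once; the medium contributes
    no volume or perimeter terms.
    """
    if geometry is None:
        geometry = compute_geometry(state)
    K3, V03, C3, E33 = params.kind_arrays()
    kinds = state.kinds.astype(np.intp)

    u = 0.0
    cell_ids = np.arange(1, state.n_labels)
    kv = kinds[cell_ids]
    dv = geometry.volumes[cell_ids] - V03[kv]
    u += float(np.sum(0.5 * K3[kv] * dv * dv))
    L = geometry.perimeters[cell_ids].astype(float)
    u += float(np.sum(0.5 * C3[kv] * L * L))

    iu, ju = np.triu_indices(state.n_labels, k=1)
    lengths = geometry.interfaces[iu, ju]
    occ = lengths > 0
    if occ.any():
        coeffs = E33[kinds[iu[occ]], kinds[ju[occ]]]
        if np.isnan(coeffs).any():
            bad = np.flatnonzero(np.isnan(coeffs))[0]
            a = CellKind(int(kinds[iu[occ][bad]]))
            b = CellKind(int(kinds[ju[occ][bad]]))
            raise ConfigurationError(
                f"missing interfacial coefficient for occurring pair ({a.name}, {b.name})"
            )
        u += float(np.sum(coeffs * lengths[occ]))
    return u


NEIGHBOURS4 = ((-1, 0), (1, 0), (0, -1), (0, 1))


def _neighbour_labels(labels: np.ndarray, r: int, c: int) -> list[int]:
    h, w = labels.shape
    out = []
    for dr, dc in NEIGHBOURS4:
        rr, cc = r + dr, c + dc
        if 0 <= rr < h and 0 <= cc < w:
            out.append(int(labels[rr, cc]))
        else:
            out.append(MEDIUM_ID)  # outside the grid is medium
    return out


def delta_energy(
    state: LatticeState,
    geometry: CellGeometry,
    pixel: tuple[int, int],
    new_label: int,
    params: EnergyParameters,
) -> float:
    """Energy change of flipping ``pixel`` to ``new_label``.

    Computed from the local 4-neighbourhood only; exactly equals
    ``total_energy(after) - total_energy(before)``. The proposed label must
    be carried by one of the pixel's 4- or 8-neighbours (or be the current
    label, in which case the flip is a no-op with zero energy change).
    """
    r, c = pixel
    a = int(state.labels[r, c])
    b = int(new_label)
    if b == a:
        return 0.0
    h, w = state.labels.shape
    adjacent = set()
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr == 0 and dc == 0:
                continue
            rr, cc = r + dr, c + dc
            if 0 <= rr < h and 0 <= cc < w:
                adjacent.add(int(state.labels[rr, cc]))
            else:
                adjacent.add(MEDIUM_ID)
    if b not in adjacent:
        raise ValueError(f"proposed label {b} is not adjacent to pixel {pixel}")

    K3, V03, C3, E33 = params.kind_arrays()
    kinds = state.kinds
    ka, kb = int(kinds[a]), int(kinds[b])

    dla = 0
    dlb = 0
    du_lin = 0.0
    for ln in _neighbour_labels(state.labels, r, c):
        kn = int(kinds[ln])
        if ln == a:
            du_lin += E33[ka, kb]  # interior a-edge becomes an (a, b) interface
            dla += 1
            dlb += 1
        elif ln == b:
            du_lin -= E33[ka, kb]  # (a, b) interface edge becomes interior to b
            dla -= 1
            dlb -= 1
        else:
            du_lin += E33[kb, kn] - E33[ka, kn]
            dla -= 1
            dlb += 1
    if np.isnan(du_lin):
        raise ConfigurationError("missing interfacial coefficient for occurring pair")

    du = du_lin
    if ka != CellKind.MEDIUM:
        va = float(geometry.volumes[a])
        du += K3[ka] * (0.5 - (va - V03[ka]))
        la = float(geometry.perimeters[a])
        du += 0.5 * C3[ka] * ((la + dla) ** 2 - la * la)
    if kb != CellKind.MEDIUM:
        vb = float(geometry.volumes[b])
        du += K3[kb] * ((vb - V03[kb]) + 0.5)
        lb = float(geometry.perimeters[b])
        du += 0.5 * C3[kb] * ((lb + dlb) ** 2 - lb * lb)
    return float(du)


def apply_flip(
    state: LatticeState, geometry: CellGeometry, pixel: tuple[int, int], new_label: int
) -> None:
    """Apply a flip in place, updating geometry incrementally."""
    r, c = pixel
    a = int(state.labels[r, c])
    b = int(new_label)
    if a == b:
        return
    for ln in _neighbour_labels(state.labels, r, c):
        if ln == a:
            geometry.interfaces[a, b] += 1
            geometry.interfaces[b, a] += 1
            geometry.perimeters[a] += 1
            geometry.perimeters[b] += 1
        elif ln == b:
            geometry.interfaces[a, b] -= 1
            geometry.interfaces[b, a] -= 1
            geometry.perimeters[a] -= 1
            geometry.perimeters[b] -= 1
        else:
            geometry.interfaces[a, ln] -= 1
            geometry.interfaces[ln, a] -= 1
            geometry.interfaces[b, ln] += 1
            geometry.interfaces[ln, b] += 1
            geometry.perimeters[a] -= 1
            geometry.perimeters[b] += 1
    geometry.volumes[a] -= 1
    geometry.volumes[b] += 1
    state.labels[r, c] = b
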