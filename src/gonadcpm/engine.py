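"""Metropolis Monte Carlo driver for the Cellular Potts model.

One Monte Carlo step (MCS) is lattice-size (height x width) flip attempts;
each attempt picks a uniformly random boundary pixel, proposes the label of
a uniformly chosen differing neighbour, and accepts with probability 1 when
the energy change is non-positive and exp(-beta * dU) otherwise. Repeated
MCS trace the temporal relaxation of the tissue.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import _kernels
from .energy import EnergyParameters, total_energy
from .lattice import CellGeometry, CellKind, LatticeState, compute_geometry
from .morphometrics import union_circularity


def metropolis_accept(
    delta_u: float, beta: float, rng: np.random.Generator
) -> bool:
    """Metropolis rule: always accept dU <= 0; else with prob exp(-beta dU)."""
    if beta <= 0:
        raise ValueError("beta must be positive")
    if delta_u <= 0.0:
        return True
    return bool(rng.random() < np.exp(-beta * delta_u))


def mcs_step(
    state: LatticeState,
    geometry: CellGeometry,
    params: EnergyParameters,
    rng: np.random.Generator,
    n_mcs: int = 1,
    proposal_connectivity: int = 4,
) -> int:
    """Advance ``n_mcs`` Monte Carlo steps in place; return accepted flips.

    ``proposal_connectivity`` (4 or 8) widens only the proposal pool;
    geometry and energies always use 4-neighbour edge counting.
    """
    if proposal_connectivity not in (4, 8):
        raise ValueError("proposal connectivity must be 4 or 8")
    kinds_present = {CellKind(int(k)) for k in np.unique(state.kinds[state.labels])}
    params.require_pairs(kinds_present)
    K3, V03, C3, E33 = params.kind_arrays()
    E33 = np.nan_to_num(E33, nan=0.0)  # unreachable pairs after validation
    padded = np.pad(state.labels, 1)  # fixed-medium frame
    accepted = _kernels.run_mcs(
        padded,
        state.kinds.astype(np.int8),
        geometry.volumes,
        geometry.perimeters,
        geometry.interfaces,
        K3,
        V03,
        C3,
        E33,
        float(params.beta),
        int(n_mcs),
        rng,
        proposal_connectivity == 8,
    )
    state.labels[...] = padded[1:-1, 1:-1]
    if accepted < 0:
        warnings.warn("lattice has a single label: MCS is a no-op", stacklevel=2)
        return 0
    return int(accepted)


@dataclass
class SimulationTrace:
    """Recorded time course of one simulation run."""

    mcs: list[int]
    energies: list[float]
    circularities: list[float]
    volume_series: list[np.ndarray]  # per-record copy of per-label volumes
    snapshots: list[tuple[int, np.ndarray]]
    extinctions: list[tuple[int, int]]  # (mcs, cell_id) volume hit zero
    accepted: list[int]
    seed: int | None
    params: EnergyParameters
    final_state: LatticeState | None = None
    final_geometry: CellGeometry | None = None

    def windowed_circularity(self, window: tuple[int, int]) -> float:
        """Mean circularity over snapshots with window[0] <= MCS <= window[1]."""
        lo, hi = window
        vals = [c for m, c in zip(self.mcs, self.circularities) if lo <= m <= hi]
        if not vals:
            raise ValueError("no recorded points inside the window")
        return float(np.mean(vals))

    def windowed_volumes(self, window: tuple[int, int]) -> np.ndarray:
        """Time-averaged per-label volumes over the recorded window."""
        lo, hi = window
        vols = [v for m, v in zip(self.mcs, self.volume_series) if lo <= m <= hi]
        if not vols:
            raise ValueError("no recorded points inside the window")
        return np.mean(vols, axis=0)


def run_simulation(
    initial: LatticeState,
    params: EnergyParameters,
    n_mcs: int,
    record_every: int = 20,
    seed: int | None = 0,
    rng: np.random.Generator | None = None,
    keep_snapshots: bool = False,
    snapshot_every: int | None = None,
    proposal_connectivity: int = 4,
) -> SimulationTrace:
    """Run the Metropolis dynamics, recording energy and gonad circularity.

    Records at MCS 0, every ``record_every`` MCS, and at the end. Snapshots
    (label-image copies) are stored at ``snapshot_every`` (default: the
    record interval) when ``keep_snapshots`` is set; the first and last
    states are always kept. Cells whose volume reaches zero are logged as
    extinction events.
    """
    if n_mcs < 0:
        raise ValueError("n_mcs must be nonnegative")
    if rng is None:
        rng = np.random.default_rng(seed)
    state = initial.copy()
    geometry = compute_geometry(state)
    if snapshot_every is None:
        snapshot_every = record_every

    trace = SimulationTrace([], [], [], [], [], [], [], seed, params)
    alive = geometry.volumes[1:] > 0

    def _record(mcs_index: int, accepted: int) -> None:
        trace.mcs.append(mcs_index)
        trace.energies.append(total_energy(state, params, geometry))
        trace.circularities.append(union_circularity(state.labels))
        trace.volume_series.append(geometry.volumes.copy())
        trace.accepted.append(accepted)
        if keep_snapshots and (
            mcs_index % snapshot_every == 0 or mcs_index == n_mcs
        ):
            trace.snapshots.append((mcs_index, state.labels.copy()))

    _record(0, 0)
    if not trace.snapshots:
        trace.snapshots.append((0, state.labels.copy()))

    done = 0
    while done < n_mcs:
        chunk = min(record_every, n_mcs - done)
        accepted = mcs_step(
            state, geometry, params, rng, n_mcs=chunk,
            proposal_connectivity=proposal_connectivity,
        )
        done += chunk
        now_alive = geometry.volumes[1:] > 0
        for cid in np.flatnonzero(alive & ~now_alive):
            trace.extinctions.append((done, int(cid) + 1))
        alive = now_alive
        _record(done, accepted)

    if trace.snapshots[-1][0] != done:
        trace.snapshots.append((done, state.labels.copy()))
    trace.final_state = state
    trace.final_geometry = geometry
    return trace
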