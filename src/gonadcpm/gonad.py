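"""The embryonic-gonad system: 7 PGCs and 14 SGPs under compaction.

Builds absolute energy coefficients from the published dimensionless ones,
constructs the elongated initial primordium, and sweeps the two free
interfacial coefficients — the SGP–SGP tension/adhesion balance
(``e_sgp_sgp``; DE-cadherin enrichment at SGP–SGP boundaries lowers it) and
the SGP–medium tension (``e_sgp_out``) — to map compaction as a phase
diagram of time-averaged gonad circularity.

Dimensionless interfacial coefficients are converted to lattice units as
``E = e * K_G * V_G0**1.5`` and perimeter coefficients as
``C = c * K_G * V_G0``; the inverse temperature multiplies energies of that
magnitude, so reduced-scale runs (``scale`` < 1, favoured volumes x scale^2)
rescale beta by ``scale**-3`` to leave the dimensionless products — and
hence the acceptance statistics — unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .energy import ConfigurationError, EnergyParameters, pair_key
from .engine import SimulationTrace, run_simulation
from .lattice import CellKind, LatticeState
from .morphometrics import union_circularity

MARGIN = 10  # minimum medium margin around the initial cluster, px


@dataclass
class GonadModelConfig:
    """Full parameterisation of a gonad-compaction run.

    ``e_sgp_sgp`` and ``e_sgp_out`` are the dimensionless phase-diagram
    axes; the remaining coefficients are the published constants. ``scale``
    shrinks all lengths linearly (favoured volumes by scale^2) for
    reduced-lattice runs. ``dims`` (height, width) may be None to derive a
    lattice that fits the cluster, its rounded end state, and the margins.
    """

    n_pgc: int = 7
    n_sgp: int = 14
    e_sgp_sgp: float = -0.01
    e_sgp_out: float = 0.16
    k_g: float = 80.0
    v_g0: float = 1600.0
    k_s: float = 200.0
    v_s0: float = 400.0
    c_g: float = 6.8e-3
    c_s: float = 7.4e-3
    e_pgc_pgc: float = 4.0e-2
    e_pgc_sgp: float = -2.0e-2
    e_pgc_out: float = 2.2e-1
    beta: float = 1.2e-5
    initial_aspect_ratio: float = 3.0
    dims: tuple[int, int] | None = None
    scale: float = 1.0
    dimensionless: bool = True  # interpret e_* as dimensionless coefficients
    sgp_energy_unit: str = "pgc"  # "pgc": K_G*V_G0^1.5 units; "sgp": K_S*V_S0^1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pgc < 1 or self.n_sgp < 1:
            raise ConfigurationError("n_pgc and n_sgp must be >= 1")
        if self.initial_aspect_ratio < 1:
            raise ConfigurationError("initial_aspect_ratio must be >= 1")
        if not 0 < self.scale <= 1:
            raise ConfigurationError("scale must be in (0, 1]")

    @property
    def v_g0_eff(self) -> float:
        return round(self.v_g0 * self.scale**2)

    @property
    def v_s0_eff(self) -> float:
        return round(self.v_s0 * self.scale**2)

    @property
    def beta_eff(self) -> float:
        return self.beta / self.scale**3

    @property
    def cluster_area(self) -> float:
        return self.n_pgc * self.v_g0_eff + self.n_sgp * self.v_s0_eff


def build_parameters(config: GonadModelConfig) -> EnergyParameters:
    """Absolute-valued :class:`EnergyParameters` from the dimensionless ones.

    With defaults: E_PGC-out = 0.22 * 80 * 1600**1.5 = 1,126,400 and
    C_S = 7.4e-3 * 128,000 = 947.2.
    """
    vg = config.v_g0_eff
    vs = config.v_s0_eff
    unit_c = config.k_g * vg
    unit_e = config.k_g * vg**1.5
    # The SGP-SGP and SGP-out coefficients are the swept axes and are quoted
    # without an explicit unit. "pgc" (default) reads them in the same
    # K_G * V_G0^{3/2} unit as the PGC coefficients; "sgp" reads them in the
    # SGPs' own elastic unit K_S * V_S0^{3/2}, which places the gonad surface
    # in a thermally active regime (see docs/methods.md).
    if config.sgp_energy_unit == "sgp":
        unit_e_sgp = config.k_s * vs**1.5
    elif config.sgp_energy_unit == "pgc":
        unit_e_sgp = unit_e
    else:
        raise ConfigurationError("sgp_energy_unit must be 'sgp' or 'pgc'")
    if not config.dimensionless:
        unit_c = unit_e = unit_e_sgp = 1.0
    G, S, M = CellKind.PGC, CellKind.SGP, CellKind.MEDIUM
    return EnergyParameters(
        K={G: config.k_g, S: config.k_s},
        V0={G: vg, S: vs},
        C={G: config.c_g * unit_c, S: config.c_s * unit_c},
        E={
            pair_key(G, G): config.e_pgc_pgc * unit_e,
            pair_key(G, S): config.e_pgc_sgp * unit_e,
            pair_key(S, S): config.e_sgp_sgp * unit_e_sgp,
            pair_key(G, M): config.e_pgc_out * unit_e,
            pair_key(S, M): config.e_sgp_out * unit_e_sgp,
        },
        beta=config.beta_eff,
    )


def _cluster_profile(aspect_ratio: float, length: float, x: np.ndarray) -> np.ndarray:
    """Normalised half-height of the primordium band at positions ``x``.

    The band is a superellipse-capped rod with shallow waists at the thirds
    (the three parasegment SGP clusters that merged to form the primordium);
    waist depth and cap sharpness fade to a disc as aspect ratio -> 1.
    """
    u = 2.0 * x / length  # [-1, 1]
    p = 2.0 * aspect_ratio
    m = 0.35 * (aspect_ratio - 1.0) / 2.0
    x01 = (u + 1.0) / 2.0
    sigma = 1.0 / 18.0
    bumps = np.exp(-(((x01 - 1 / 3) / sigma) ** 2)) + np.exp(
        -(((x01 - 2 / 3) / sigma) ** 2)
    )
    with np.errstate(invalid="ignore"):
        f = np.where(
            np.abs(u) < 1.0, np.sqrt(np.clip(1.0 - np.abs(u) ** p, 0.0, 1.0)), -1.0
        )
    return np.where(f >= 0.0, f * (1.0 - m * bumps), -1.0)


def _cluster_geometry(config: GonadModelConfig) -> tuple[float, float]:
    """(length, max half-height) of the initial cluster, in pixels."""
    ar = config.initial_aspect_ratio
    u = np.linspace(-1.0, 1.0, 4001)
    f0 = np.clip(_cluster_profile(ar, 2.0, u), 0.0, None)  # length 2 -> x == u
    area0 = np.trapezoid(2.0 * f0, u)  # area of the unit-half-height band
    # A = (L/2) * b * area0 and L = 2 * ar * b
    b = float(np.sqrt(config.cluster_area / (ar * area0)))
    return 2.0 * ar * b, b


def minimum_dims(config: GonadModelConfig) -> tuple[int, int]:
    """Smallest (height, width) lattice for the cluster plus margins,
    long axis horizontal."""
    length, half_h = _cluster_geometry(config)
    # the compacted (disc) end state only has to fit; the 10 px medium
    # margin applies to the initial cluster
    disc_diam = 2.0 * np.sqrt(config.cluster_area / np.pi)
    height = int(np.ceil(max(2 * half_h + 2 * MARGIN, disc_diam + 4)))
    width = int(np.ceil(max(length + 2 * MARGIN, disc_diam + 4)))
    return height, width


def initial_configuration(config: GonadModelConfig) -> LatticeState:
    """The elongated starting primordium.

    PGCs form a central row spanning the cluster; SGPs tile the bands above
    and below it. Cells are contiguous column-major chunks of exactly equal
    pixel counts per band, so every cell starts within a few percent of its
    favoured volume (well inside the +-10% construction tolerance).
    """
    min_h, min_w = minimum_dims(config)
    if config.dims is None:
        dims = (min_h, min_w)
    else:
        dims = tuple(config.dims)
        if max(dims) < max(min_h, min_w) or min(dims) < min(min_h, min_w):
            raise ConfigurationError(
                f"lattice {dims} too small; minimum dims are "
                f"({min_h}, {min_w}) (either orientation)"
            )
    h, w = dims
    transpose = False
    if (w >= h) != (min_w >= min_h):
        transpose = True  # orient the cluster along the longer lattice axis
        h, w = w, h

    length, half_h = _cluster_geometry(config)
    yy, xx = np.mgrid[0:h, 0:w]
    fx = _cluster_profile(config.initial_aspect_ratio, length, xx - w / 2.0) * half_h
    cluster = np.abs(yy - h / 2.0) <= fx
    if not cluster.any():
        raise ConfigurationError("degenerate cluster: no pixels")

    # split cluster rows into three bands with pixel counts proportional to
    # the favoured band areas (top SGPs / PGC row / bottom SGPs)
    n_top = config.n_sgp // 2
    n_bot = config.n_sgp - n_top
    area = int(cluster.sum())
    targets = np.array(
        [
            n_top * config.v_s0_eff,
            config.n_pgc * config.v_g0_eff,
            n_bot * config.v_s0_eff,
        ],
        dtype=float,
    )
    targets *= area / targets.sum()
    # pixel-level band split in row-major order: band sizes are exact, so
    # per-cell volumes land within ~1 px of the favoured values
    pix_all = np.argwhere(cluster)
    pix_all = pix_all[np.lexsort((pix_all[:, 1], pix_all[:, 0]))]  # row-major
    n1 = int(round(targets[0]))
    n2 = n1 + int(round(targets[1]))

    labels = np.zeros((h, w), dtype=np.int32)
    pgc_ids = np.arange(1, config.n_pgc + 1)
    sgp_ids = np.arange(config.n_pgc + 1, config.n_pgc + config.n_sgp + 1)
    bands = [
        (pix_all[:n1], sgp_ids[:n_top]),
        (pix_all[n1:n2], pgc_ids),
        (pix_all[n2:], sgp_ids[n_top:]),
    ]
    for pix, ids in bands:
        if len(pix) < len(ids):
            raise ConfigurationError("cluster band too small for its cells")
        pix = pix[np.lexsort((pix[:, 0], pix[:, 1]))]  # column-major chunks
        chunks = np.array_split(np.arange(len(pix)), len(ids))
        for cid, idx in zip(ids, chunks):
            labels[pix[idx, 0], pix[idx, 1]] = cid

    kinds = np.zeros(config.n_pgc + config.n_sgp + 1, dtype=np.int8)
    kinds[pgc_ids] = CellKind.PGC
    kinds[sgp_ids] = CellKind.SGP
    if transpose:
        labels = np.ascontiguousarray(labels.T)
    return LatticeState(labels, kinds)


def gonad_circularity(labels_or_state, method: str = "contour",
                      return_split: bool = False):
    """Circularity 4*pi*A/P^2 of the PGC+SGP union (largest component)."""
    labels = getattr(labels_or_state, "labels", labels_or_state)
    return union_circularity(labels, method=method, return_split=return_split)


def run_gonad_simulation(
    config: GonadModelConfig,
    n_mcs: int,
    record_every: int = 20,
    seed: int | None = None,
    keep_snapshots: bool = False,
    snapshot_every: int | None = None,
) -> SimulationTrace:
    """Convenience wrapper: build parameters + initial state and simulate."""
    params = build_parameters(config)
    state = initial_configuration(config)
    return run_simulation(
        state,
        params,
        n_mcs=n_mcs,
        record_every=record_every,
        seed=config.seed if seed is None else seed,
        keep_snapshots=keep_snapshots,
        snapshot_every=snapshot_every,
    )


@dataclass
class PhaseDiagram:
    """Windowed mean gonad circularity over an (e_sgp_sgp, e_sgp_out) grid."""

    e_sgp_sgp_values: np.ndarray
    e_sgp_out_values: np.ndarray
    mean_circularity: np.ndarray  # shape (len(sgp_sgp), len(sgp_out))
    trials: pd.DataFrame
    n_trials: int
    mcs_window: tuple[int, int]

    def mean_at(self, e_sgp_sgp: float, e_sgp_out: float) -> float:
        i = int(np.argmin(np.abs(self.e_sgp_sgp_values - e_sgp_sgp)))
        j = int(np.argmin(np.abs(self.e_sgp_out_values - e_sgp_out)))
        return float(self.mean_circularity[i, j])


def phase_sweep(
    base_config: GonadModelConfig,
    e_sgp_sgp_values: Sequence[float],
    e_sgp_out_values: Sequence[float],
    n_trials: int = 10,
    n_mcs: int = 20_000,
    mcs_window: tuple[int, int] = (12_000, 20_000),
    record_every: int = 20,
    seed: int = 0,
) -> PhaseDiagram:
    """Phase diagram of compaction vs the two free interfacial coefficients.

    For each grid point, ``n_trials`` seeded runs (seed + trial index, the
    same seeds across grid points, so comparisons are paired) record the
    arithmetic-mean gonad circularity over snapshots inside ``mcs_window``.
    """
    lo, hi = mcs_window
    if not (0 <= lo < hi <= n_mcs):
        raise ConfigurationError("mcs_window must satisfy 0 <= start < end <= n_mcs")
    ss_vals = np.asarray(e_sgp_sgp_values, dtype=float)
    so_vals = np.asarray(e_sgp_out_values, dtype=float)
    mean_map = np.zeros((len(ss_vals), len(so_vals)))
    rows = []
    for i, ess in enumerate(ss_vals):
        for j, eso in enumerate(so_vals):
            config = replace(base_config, e_sgp_sgp=float(ess), e_sgp_out=float(eso))
            vals = []
            for trial in range(n_trials):
                trial_seed = seed + trial
                trace = run_gonad_simulation(
                    config, n_mcs=n_mcs, record_every=record_every, seed=trial_seed
                )
                wc = trace.windowed_circularity(mcs_window)
                final_geo = trace.final_geometry
                surviving = int(np.sum(final_geo.volumes[1:] > 0))
                _, split = union_circularity(
                    trace.final_state.labels, return_split=True
                )
                vals.append(wc)
                rows.append(
                    {
                        "e_sgp_sgp": float(ess),
                        "e_sgp_out": float(eso),
                        "trial": trial,
                        "seed": trial_seed,
                        "mean_circularity": wc,
                        "final_circularity": trace.circularities[-1],
                        "surviving_cells": surviving,
                        "split_final": bool(split),
                        "n_extinctions": len(trace.extinctions),
                    }
                )
            mean_map[i, j] = float(np.mean(vals))
    trials = pd.DataFrame(rows)
    return PhaseDiagram(ss_vals, so_vals, mean_map, trials, n_trials, mcs_window)


# The published parameterisations. "paper" is the full-scale system with the
# Movie S4 interfacial coefficients and the published averaging window;
# "-reduced" presets shrink lengths by 0.375 onto a 120x72 lattice.
PRESETS: dict[str, dict] = {
    "paper": dict(
        config=dict(e_sgp_sgp=-0.01, e_sgp_out=0.16),
        n_mcs=20_000,
        record_every=20,
        mcs_window=(12_000, 20_000),
    ),
    "movie-s4": dict(
        config=dict(e_sgp_sgp=-0.01, e_sgp_out=0.16),
        n_mcs=20_000,
        record_every=20,
        mcs_window=(12_000, 20_000),
    ),
    "movie-s5": dict(
        config=dict(e_sgp_sgp=0.0, e_sgp_out=0.16),
        n_mcs=20_000,
        record_every=20,
        mcs_window=(12_000, 20_000),
    ),
    "movie-s4-reduced": dict(
        config=dict(e_sgp_sgp=-0.01, e_sgp_out=0.16, scale=0.375, dims=(72, 120)),
        n_mcs=8_000,
        record_every=20,
        mcs_window=(5_000, 8_000),
    ),
    "movie-s5-reduced": dict(
        config=dict(e_sgp_sgp=0.0, e_sgp_out=0.16, scale=0.375, dims=(72, 120)),
        n_mcs=8_000,
        record_every=20,
        mcs_window=(5_000, 8_000),
    ),
}


def preset_config(name: str, **overrides) -> tuple[GonadModelConfig, dict]:
    """A named preset as (config, run_kwargs)."""
    if name not in PRESETS:
        raise ConfigurationError(
            f"unknown preset {name!r}; choose from {sorted(PRESETS)}"
        )
    spec = PRESETS[name]
    cfg = GonadModelConfig(**{**spec["config"], **overrides})
    run_kwargs = {k: v for k, v in spec.items() if k != "config"}
    return cfg, run_kwargs
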