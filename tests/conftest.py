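import numpy as np
import pytest

from gonadcpm import CellKind, EnergyParameters, LatticeState, pair_key

G, S, M = CellKind.PGC, CellKind.SGP, CellKind.MEDIUM


def brute_force_geometry(state: LatticeState):
    """Independent oracle: explicit loop over every horizontal/vertical
    pixel-edge pair, with out-of-grid neighbours read as medium."""
    labels = state.labels
    h, w = labels.shape
    n = state.n_labels
    volumes = np.zeros(n, dtype=np.int64)
    interfaces = np.zeros((n, n), dtype=np.int64)
    for r in range(h):
        for c in range(w):
            volumes[labels[r, c]] += 1
    for r in range(h):
        for c in range(w):
            a = labels[r, c]
            # right and down interior edges; all four border edges vs medium
            for dr, dc in ((0, 1), (1, 0)):
                rr, cc = r + dr, c + dc
                if rr < h and cc < w:
                    b = labels[rr, cc]
                    if a != b:
                        interfaces[a, b] += 1
                        interfaces[b, a] += 1
            for rr, cc in ((r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1)):
                if not (0 <= rr < h and 0 <= cc < w) and a != 0:
                    interfaces[a, 0] += 1
                    interfaces[0, a] += 1
    return volumes, interfaces.sum(axis=1), interfaces


def random_state(rng: np.random.Generator, shape=(30, 30), n_cells=4,
                 kinds_seq=None) -> LatticeState:
    """A random multi-cell label field (nearest-seed blobs in medium)."""
    h, w = shape
    seeds = rng.integers(2, [h - 2, w - 2], size=(n_cells, 2))
    yy, xx = np.mgrid[0:h, 0:w]
    d2 = (yy[..., None] - seeds[:, 0]) ** 2 + (xx[..., None] - seeds[:, 1]) ** 2
    nearest = np.argmin(d2, axis=2).astype(np.int32)
    labels = np.where(d2.min(axis=2) < (min(h, w) / 3) ** 2, nearest + 1, 0)
    if kinds_seq is None:
        kinds_seq = [G if i % 2 == 0 else S for i in range(n_cells)]
    kinds = np.array([M] + list(kinds_seq), dtype=np.int8)
    return LatticeState(labels.astype(np.int32), kinds)


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture
def small_params():
    """Complete parameter set with O(1) coefficients for unit tests."""
    return EnergyParameters(
        K={G: 2.0, S: 5.0},
        V0={G: 40.0, S: 10.0},
        C={G: 0.3, S: 0.4},
        E={
            pair_key(G, G): 1.5,
            pair_key(G, S): -0.7,
            pair_key(S, S): -0.2,
            pair_key(G, M): 3.0,
            pair_key(S, M): 2.0,
        },
        beta=0.05,
    )
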