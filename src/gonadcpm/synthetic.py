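"""Synthetic stained-gonad sections with known ground truth.

Emulates the 2D confocal sections the morphometric statistics are computed
on: an elliptical gonad of germ cells (central) and somatic cells
(peripheral) tessellated by nearest-seed partition, plus a matching
membrane-stain intensity image whose outer-surface vs cell–cell boundary
enrichment, blur and noise are controlled. Everything is deterministic
given the spec and seed, so estimator recovery can be tested without any
microscopy data.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .lattice import CellKind, LatticeState
from .morphometrics import (
    Region,
    cell_circularity,
    cell_orientation,
    membrane_intensity_ratio,
    sgp_membrane_classes,
    union_circularity,
)


@dataclass
class SyntheticGonadSpec:
    """Controls for one synthetic gonad section.

    Intensity levels are arbitrary units; ``psf_sigma`` is the Gaussian
    blur width in pixels and ``noise_sd`` the additive Gaussian noise scale.
    ``gonad_area`` (pixels) is conserved across aspect ratios so a
    compaction series only changes shape.
    """

    n_sgp: int = 14
    n_pgc: int = 7
    aspect_ratio: float = 3.0
    dims: tuple[int, int] = (160, 240)
    gonad_area: float = 12_000.0
    inner_level: float = 100.0
    outer_level: float = 200.0
    background: float = 10.0
    psf_sigma: float = 1.0
    noise_sd: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.aspect_ratio < 1:
            raise ValueError("aspect_ratio must be >= 1")
        if min(self.inner_level, self.outer_level, self.background) < 0:
            raise ValueError("intensity levels must be nonnegative")
        if self.n_sgp < 1 or self.n_pgc < 0:
            raise ValueError("need at least one SGP")
        a = np.sqrt(self.gonad_area * self.aspect_ratio / np.pi)
        b = a / self.aspect_ratio
        if 2 * a > self.dims[1] - 4 or 2 * b > self.dims[0] - 4:
            raise ValueError(
                f"dims {self.dims} too small for a {self.aspect_ratio}:1 "
                f"ellipse of area {self.gonad_area}"
            )

    @property
    def true_ratio(self) -> float:
        return self.outer_level / self.inner_level


@dataclass
class SyntheticTruth:
    """Generator ground truth for recovery tests."""

    cells: pd.DataFrame  # cell_id, kind, seed_x, seed_y, area, circularity,
    #                      orientation_deg, region
    true_ratio: float
    semi_axes: tuple[float, float]
    ap_axis: tuple[float, float]
    union_circularity: float


def _normalized_seeds(
    n_pgc: int, n_sgp: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Seed layout in the unit disc: germ cells fill the centre (sunflower
    pattern, so their tessellation cells stay roundish), somatic cells sit
    on a peripheral ring."""
    if n_pgc > 0:
        golden = np.pi * (3.0 - np.sqrt(5.0))
        i = np.arange(n_pgc)
        radius = 0.45 * np.sqrt((i + 0.5) / n_pgc)
        theta = i * golden
        pgc = np.column_stack([radius * np.cos(theta), radius * np.sin(theta)])
        pgc += rng.normal(0.0, 0.02, pgc.shape)
    else:
        pgc = np.zeros((0, 2))
    theta = 2 * np.pi * np.arange(n_sgp) / n_sgp
    theta = theta + rng.normal(0.0, 0.35 / n_sgp, n_sgp)
    radius = 0.78 + rng.normal(0.0, 0.03, n_sgp)
    sgp = np.column_stack([radius * np.cos(theta), radius * np.sin(theta)])
    return pgc, sgp


def _labels_for_ratio(
    spec: SyntheticGonadSpec,
    aspect_ratio: float,
    pgc_n: np.ndarray,
    sgp_n: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, tuple[float, float]]:
    h, w = spec.dims
    a = np.sqrt(spec.gonad_area * aspect_ratio / np.pi)
    b = a / aspect_ratio
    seeds = np.vstack([pgc_n, sgp_n]) * np.array([a, b])  # anisotropic scale
    yy, xx = np.mgrid[0:h, 0:w]
    x = xx - w / 2.0
    y = yy - h / 2.0
    inside = (x / a) ** 2 + (y / b) ** 2 <= 1.0
    pix = np.argwhere(inside)
    pts = np.column_stack([pix[:, 1] - w / 2.0, pix[:, 0] - h / 2.0])
    d2 = ((pts[:, None, :] - seeds[None, :, :]) ** 2).sum(axis=2)
    nearest = np.argmin(d2, axis=1)
    labels = np.zeros((h, w), dtype=np.int32)
    labels[pix[:, 0], pix[:, 1]] = nearest + 1
    n_cells = len(seeds)
    kinds = np.zeros(n_cells + 1, dtype=np.int8)
    kinds[1 : len(pgc_n) + 1] = CellKind.PGC
    kinds[len(pgc_n) + 1 :] = CellKind.SGP
    return labels, kinds, (a, b)


def _truth_table(
    spec: SyntheticGonadSpec,
    labels: np.ndarray,
    kinds: np.ndarray,
    seeds_px: np.ndarray,
    semi_axes: tuple[float, float],
) -> SyntheticTruth:
    a, _ = semi_axes
    rows = []
    xs = seeds_px[:, 0]
    for cid in range(1, len(kinds)):
        mask = labels == cid
        area = int(mask.sum())
        circ = cell_circularity(mask) if area else np.nan
        ang = cell_orientation(mask) if area else None
        f = (xs[cid - 1] + a) / (2 * a)  # position along the AP extent
        region = (
            Region.ANTERIOR if f <= 1 / 3 else Region.MIDDLE if f <= 2 / 3
            else Region.POSTERIOR
        )
        rows.append(
            {
                "cell_id": cid,
                "kind": CellKind(int(kinds[cid])).name,
                "seed_x": float(seeds_px[cid - 1, 0]),
                "seed_y": float(seeds_px[cid - 1, 1]),
                "area": area,
                "circularity": circ,
                "orientation_deg": np.nan if ang is None else ang,
                "region": region.value,
            }
        )
    return SyntheticTruth(
        cells=pd.DataFrame(rows),
        true_ratio=spec.true_ratio,
        semi_axes=semi_axes,
        ap_axis=(1.0, 0.0),
        union_circularity=union_circularity(labels),
    )


def generate_gonad_labels(
    spec: SyntheticGonadSpec,
) -> tuple[LatticeState, SyntheticTruth]:
    """A label image of the gonad plus its ground-truth table.

    Seeds the germ cells centrally and the somatic cells peripherally
    inside an ellipse of the requested aspect ratio, then assigns each
    ellipse pixel to its nearest seed (a Voronoi tessellation clipped to
    the gonad outline). Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng([spec.seed, 0])
    pgc_n, sgp_n = _normalized_seeds(spec.n_pgc, spec.n_sgp, rng)
    labels, kinds, semi = _labels_for_ratio(spec, spec.aspect_ratio, pgc_n, sgp_n)
    seeds_px = np.vstack([pgc_n, sgp_n]) * np.array(semi)
    truth = _truth_table(spec, labels, kinds, seeds_px, semi)
    return LatticeState(labels, kinds), truth


def generate_membrane_image(
    labels: np.ndarray | LatticeState,
    spec: SyntheticGonadSpec,
    kinds: np.ndarray | None = None,
) -> np.ndarray:
    """Membrane-stain intensity image matching a label image.

    SGP–SGP boundary pixels carry ``inner_level``, SGP–medium boundary
    pixels ``outer_level``, everything else the background. The outer
    membrane signal also covers the medium-side pixel layer, so both
    membrane classes are two pixels wide (an SGP–SGP boundary is painted
    from both adjoining cells) and the Gaussian PSF erodes them
    symmetrically. Blur and seeded Gaussian noise are applied last.
    """
    if isinstance(labels, LatticeState):
        kinds = labels.kinds
        labels = labels.labels
    if kinds is None:
        raise ValueError("kinds required when labels is a plain array")
    outer, inner = sgp_membrane_classes(labels, kinds)
    # medium pixels flanking the outer membrane (membrane signal straddles
    # the cell outline)
    pad = np.pad(outer, 1)
    halo = (
        pad[:-2, 1:-1] | pad[2:, 1:-1] | pad[1:-1, :-2] | pad[1:-1, 2:]
    ) & (labels == 0)
    # membrane signal rides on top of the uniform background, so the
    # background-subtracted class means recover the levels exactly
    image = np.full(labels.shape, spec.background, dtype=float)
    image[inner] = spec.background + spec.inner_level
    image[outer | halo] = spec.background + spec.outer_level
    if spec.psf_sigma > 0:
        image = ndimage.gaussian_filter(image, spec.psf_sigma)
    if spec.noise_sd > 0:
        rng = np.random.default_rng([spec.seed, 1])
        image = image + rng.normal(0.0, spec.noise_sd, image.shape)
    return image


def generate_compaction_series(
    spec: SyntheticGonadSpec, aspect_ratios: Sequence[float]
) -> list[tuple[LatticeState, SyntheticTruth]]:
    """Label images emulating progressive compaction.

    One image per aspect ratio with a matched (identical) seed layout in
    normalised coordinates, so the series differs only by the anisotropic
    stretch; the gonad-union circularity strictly increases as the aspect
    ratio decreases.
    """
    ratios = list(aspect_ratios)
    if not ratios:
        raise ValueError("aspect_ratios must be nonempty")
    if any(r < 1 for r in ratios):
        raise ValueError("aspect ratios must be >= 1")
    out = []
    for ar in ratios:
        item_spec = replace(spec, aspect_ratio=float(ar))
        out.append(generate_gonad_labels(item_spec))
    return out


def measured_ratio(
    spec: SyntheticGonadSpec,
) -> tuple[float, float]:
    """(true, recovered) membrane intensity ratio for one synthetic gonad.

    The known background level is subtracted during measurement (as a
    quantitative-imaging pipeline would after estimating it from off-tissue
    pixels) and membrane vertices, where the PSF mixes the two classes, are
    excluded.
    """
    state, _ = generate_gonad_labels(spec)
    image = generate_membrane_image(state, spec)
    rec = membrane_intensity_ratio(
        image, state.labels, state.kinds,
        background=spec.background, junction_exclusion_px=2,
    )
    if rec.ratio is None:
        raise ValueError("ratio undefined for this spec")
    return spec.true_ratio, rec.ratio
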