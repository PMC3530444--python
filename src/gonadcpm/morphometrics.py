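"""Cell-shape and staining-intensity statistics.

Implements the image-quantification readouts used to describe gonad
compaction: per-cell circularity ``4*pi*area/perimeter**2``, the acute angle
between a cell's longest axis and the gonad's anterior–posterior (AP) axis,
an anterior/middle/posterior partition along that axis, and the
outer-membrane vs SGP–SGP-boundary staining intensity ratio used to
quantify DE-cadherin relocalisation. All operations work on 2D label /
intensity images (a single confocal section, or a simulation snapshot).
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from skimage import measure

from .lattice import MEDIUM_ID, CellKind

DEGENERATE_AREA = 10  # px; smaller regions are flagged
_ANISOTROPY_MIN = 1.05  # eigenvalue ratio below which orientation is undefined


class Region(enum.Enum):
    ANTERIOR = "anterior"
    MIDDLE = "middle"
    POSTERIOR = "posterior"


@dataclass
class MorphometricRecord:
    cell_id: int
    circularity: float
    orientation_deg: float | None
    region: Region


@dataclass
class IntensityRatioRecord:
    """Mean membrane signal facing the medium (outer) vs SGP–SGP boundaries
    (inner), and their ratio. ``ratio`` is None when no inner boundary
    exists (e.g. a single SGP)."""

    outer_mean: float
    inner_mean: float
    ratio: float | None
    n_outer: int
    n_inner: int


def circularity(area: float, perimeter: float) -> float:
    """``4*pi*area/perimeter**2`` for continuous measurements.

    1.0 for a perfect circle; an elongated shape approaches 0.
    """
    if perimeter <= 0:
        raise ValueError("perimeter must be positive")
    return 4.0 * np.pi * area / perimeter**2


def mask_perimeter(mask: np.ndarray, method: str = "contour") -> float:
    """Perimeter of a binary mask.

    ``contour``
        Length of the smoothed marching-squares contour polygon (5-vertex
        circular moving average). Sub-pixel; nearly unbiased for smooth
        shapes, where raw lattice edge counts overestimate by up to 4/pi.
    ``edge``
        Exact count of exposed 4-neighbour pixel edges (lattice units).
    ``crofton``
        skimage's 4-direction Crofton estimate.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    if method == "edge":
        padded = np.pad(mask, 1)
        return float(
            np.sum(padded[1:, :] != padded[:-1, :])
            + np.sum(padded[:, 1:] != padded[:, :-1])
        )
    if method == "crofton":
        return float(measure.perimeter_crofton(mask, directions=4))
    if method != "contour":
        raise ValueError(f"unknown perimeter method {method!r}")

    padded = np.pad(mask.astype(float), 1)
    contours = measure.find_contours(padded, 0.5)
    best = 0.0
    win = 5
    for contour in contours:
        pts = contour[:-1]  # closed polygon: last vertex repeats the first
        n = len(pts)
        if n < 3:
            continue
        if n <= win:
            closed = np.vstack([pts, pts[:1]])
            length = float(np.sum(np.linalg.norm(np.diff(closed, axis=0), axis=1)))
            best = max(best, length)
            continue
        kernel = np.ones(win) / win
        smoothed = np.empty_like(pts)
        half = win // 2
        for d in range(2):
            wrapped = np.concatenate([pts[-half:, d], pts[:, d], pts[:half, d]])
            smoothed[:, d] = np.convolve(wrapped, kernel, mode="valid")
        closed = np.vstack([smoothed, smoothed[:1]])
        length = float(np.sum(np.linalg.norm(np.diff(closed, axis=0), axis=1)))
        best = max(best, length)
    return best


def cell_circularity(mask: np.ndarray, method: str = "contour") -> float:
    """Circularity of one cell region, clipped to 1.0.

    Regions below 10 px are measurable but flagged degenerate via a warning.
    """
    mask = np.asarray(mask, dtype=bool)
    area = int(mask.sum())
    if area == 0:
        raise ValueError("empty cell region")
    if area < DEGENERATE_AREA:
        warnings.warn(
            f"region of {area} px is below the {DEGENERATE_AREA} px "
            "degeneracy threshold; circularity is unreliable",
            stacklevel=2,
        )
    value = circularity(area, mask_perimeter(mask, method=method))
    return min(value, 1.0)


def union_circularity(
    labels: np.ndarray,
    method: str = "contour",
    return_split: bool = False,
):
    """Circularity of the union of all non-medium pixels (the gonad).

    If the union has several connected components the largest one is
    measured and a split flag is raised.
    """
    mask = np.asarray(labels) != MEDIUM_ID
    if not mask.any():
        raise ValueError("empty gonad")
    comp, n_comp = ndimage.label(mask)  # 4-connectivity (default structure)
    if n_comp > 1:
        sizes = ndimage.sum_labels(mask, comp, index=np.arange(1, n_comp + 1))
        mask = comp == (1 + int(np.argmax(sizes)))
    value = cell_circularity(mask, method=method)
    if return_split:
        return value, n_comp > 1
    return value


def _unit(vec: Sequence[float]) -> np.ndarray:
    v = np.asarray(vec, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("AP axis must be a nonzero vector")
    return v / n


def cell_orientation(
    mask: np.ndarray, ap_axis: Sequence[float] = (1.0, 0.0)
) -> float | None:
    """Acute angle (degrees, [0, 90]) between the cell's longest axis and
    the AP axis.

    The longest axis is the principal eigenvector of the second central
    moments of the pixel set. ``ap_axis`` is an (x, y) = (column, row)
    direction. Near-isotropic regions (principal eigenvalue ratio < 1.05)
    have no meaningful long axis and yield ``None``.
    """
    mask = np.asarray(mask, dtype=bool)
    coords = np.argwhere(mask)  # (row, col)
    if coords.shape[0] == 0:
        raise ValueError("empty cell region")
    xy = coords[:, ::-1].astype(float)  # (x=col, y=row)
    centred = xy - xy.mean(axis=0)
    cov = centred.T @ centred / len(xy)
    evals, evecs = np.linalg.eigh(cov)
    lam_minor, lam_major = evals
    if lam_major <= 0:
        return None
    if lam_minor > 0 and lam_major / lam_minor < _ANISOTROPY_MIN:
        return None
    major = evecs[:, 1]
    u = _unit(ap_axis)
    cosang = abs(float(np.dot(major, u)))
    return float(np.degrees(np.arccos(np.clip(cosang, 0.0, 1.0))))


def partition_regions(
    labels: np.ndarray,
    ap_axis: Sequence[float] = (1.0, 0.0),
) -> dict[int, Region]:
    """Assign each cell to anterior / middle / posterior thirds.

    Cell centroids are projected onto ``ap_axis`` (pointing anterior to
    posterior) and the projected extent of the gonad union is split into
    three equal-length bins; boundary values fall into the lower-index bin.
    A degenerate (zero-extent) projection assigns everything to MIDDLE.
    """
    labels = np.asarray(labels)
    ids = np.unique(labels)
    ids = ids[ids != MEDIUM_ID]
    if ids.size == 0:
        raise ValueError("empty gonad")
    u = _unit(ap_axis)

    rows, cols = np.nonzero(labels != MEDIUM_ID)
    proj_all = cols * u[0] + rows * u[1]
    lo, hi = float(proj_all.min()), float(proj_all.max())
    extent = hi - lo
    order = [Region.ANTERIOR, Region.MIDDLE, Region.POSTERIOR]

    out: dict[int, Region] = {}
    for cid in ids:
        rr, cc = np.nonzero(labels == cid)
        p = float(cc.mean() * u[0] + rr.mean() * u[1])
        if extent == 0:
            out[int(cid)] = Region.MIDDLE
            continue
        f = (p - lo) / extent
        if f <= 1.0 / 3.0:
            out[int(cid)] = order[0]
        elif f <= 2.0 / 3.0:
            out[int(cid)] = order[1]
        else:
            out[int(cid)] = order[2]
    return out


def sgp_membrane_classes(
    labels: np.ndarray, kinds: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Classify SGP membrane pixels into outer and inner masks.

    A membrane pixel is an SGP pixel with a differing 4-neighbour (pixels
    outside the image read as medium). Pixels touching the medium are OUTER;
    otherwise pixels touching a different SGP are INNER. SGP–PGC boundary
    pixels belong to neither class.
    """
    labels = np.asarray(labels)
    kinds = np.asarray(kinds)
    pad = np.pad(labels, 1, constant_values=MEDIUM_ID)
    shifts = (pad[:-2, 1:-1], pad[2:, 1:-1], pad[1:-1, :-2], pad[1:-1, 2:])
    is_sgp = kinds[labels] == CellKind.SGP
    touches_medium = np.zeros_like(is_sgp)
    touches_other_sgp = np.zeros_like(is_sgp)
    for nb in shifts:
        differing = nb != labels
        touches_medium |= differing & (nb == MEDIUM_ID)
        touches_other_sgp |= differing & (kinds[nb] == CellKind.SGP)
    outer = is_sgp & touches_medium
    inner = is_sgp & touches_other_sgp & ~touches_medium
    return outer, inner


def membrane_intensity_ratio(
    intensity: np.ndarray,
    labels: np.ndarray,
    kinds: np.ndarray,
    background: float | None = None,
    junction_exclusion_px: int = 0,
) -> IntensityRatioRecord:
    """Outer-membrane / inner-boundary mean intensity ratio of the SGPs.

    Pools pixels over the whole gonad section. When a ``background`` level
    is supplied it is subtracted from both class means before the ratio is
    formed (an additive camera/stain floor biases the raw ratio toward 1).
    ``junction_exclusion_px`` drops pixels within that (8-connected)
    distance of both classes — the vertices where outer and inner membranes
    meet, where a finite PSF mixes the two signals. The ratio is undefined
    (None) when there is no SGP–SGP boundary.
    """
    intensity = np.asarray(intensity, dtype=float)
    if intensity.shape != np.asarray(labels).shape:
        raise ValueError("intensity and label images must share dimensions")
    outer, inner = sgp_membrane_classes(labels, kinds)
    if junction_exclusion_px > 0:
        struct = ndimage.generate_binary_structure(2, 2)
        near_outer = ndimage.binary_dilation(
            outer, struct, iterations=junction_exclusion_px
        )
        near_inner = ndimage.binary_dilation(
            inner, struct, iterations=junction_exclusion_px
        )
        junction = near_outer & near_inner
        if (outer & ~junction).any() and (inner & ~junction).any():
            outer &= ~junction
            inner &= ~junction
    n_outer, n_inner = int(outer.sum()), int(inner.sum())
    bg = 0.0 if background is None else float(background)
    outer_mean = float(intensity[outer].mean() - bg) if n_outer else float("nan")
    inner_mean = float(intensity[inner].mean() - bg) if n_inner else float("nan")
    if n_inner == 0 or inner_mean == 0:
        warnings.warn("no SGP-SGP boundary pixels: intensity ratio undefined",
                      stacklevel=2)
        ratio = None
    else:
        ratio = outer_mean / inner_mean
    return IntensityRatioRecord(outer_mean, inner_mean, ratio, n_outer, n_inner)


def measure_labels(
    labels: np.ndarray,
    kinds: np.ndarray | None = None,
    ap_axis: Sequence[float] | None = None,
    method: str = "contour",
) -> pd.DataFrame:
    """Per-cell morphometric table for a label image.

    When ``ap_axis`` is omitted it is fitted as the principal axis of the
    gonad union mask. Returns one row per non-medium label with area,
    circularity, orientation (NaN when undefined) and AP region.
    """
    labels = np.asarray(labels)
    if ap_axis is None:
        ap_axis = principal_axis(labels != MEDIUM_ID)
    regions = partition_regions(labels, ap_axis)
    rows = []
    for cid in sorted(regions):
        mask = labels == cid
        ang = cell_orientation(mask, ap_axis)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            circ = cell_circularity(mask, method=method)
        rows.append(
            {
                "cell_id": cid,
                "kind": CellKind(int(kinds[cid])).name if kinds is not None else "",
                "area": int(mask.sum()),
                "circularity": circ,
                "orientation_deg": np.nan if ang is None else ang,
                "region": regions[cid].value,
            }
        )
    return pd.DataFrame(rows)


def principal_axis(mask: np.ndarray) -> np.ndarray:
    """Principal (longest) axis of a mask as an (x, y) unit vector."""
    coords = np.argwhere(np.asarray(mask, dtype=bool))
    if coords.shape[0] == 0:
        raise ValueError("empty mask")
    xy = coords[:, ::-1].astype(float)
    centred = xy - xy.mean(axis=0)
    cov = centred.T @ centred / len(xy)
    _, evecs = np.linalg.eigh(cov)
    axis = evecs[:, 1]
    if axis[0] < 0 or (axis[0] == 0 and axis[1] < 0):
        axis = -axis
    return axis


def summarize_groups(
    groups: Mapping[str, Sequence[float]],
    contrasts: Sequence[tuple[str, str]] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-group mean and standard error plus Welch two-sample p-values.

    ``contrasts`` defaults to all unordered group pairs. The unequal-variance
    (Welch) t-test is used for each contrast.
    """
    if any(len(v) == 0 for v in groups.values()):
        raise ValueError("empty group")
    summary = pd.DataFrame(
        [
            {
                "group": name,
                "n": len(vals),
                "mean": float(np.mean(vals)),
                "se": float(stats.sem(vals)) if len(vals) > 1 else float("nan"),
            }
            for name, vals in groups.items()
        ]
    )
    names = list(groups)
    if contrasts is None:
        contrasts = [(a, b) for i, a in enumerate(names) for b in names[i + 1 :]]
    comp_rows = []
    for a, b in contrasts:
        res = stats.ttest_ind(groups[a], groups[b], equal_var=False)
        comp_rows.append(
            {"group_a": a, "group_b": b,
             "t": float(res.statistic), "p_value": float(res.pvalue)}
        )
    return summary, pd.DataFrame(comp_rows)
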