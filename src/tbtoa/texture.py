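"""Fractal trabecular-bone-texture (TBT) descriptors from knee radiographs.

The texture of subchondral trabecular bone on a plain radiograph behaves, over
a limited range of scales, like a fractional Brownian surface: the mean squared
intensity increment between pixels a distance ``d`` apart grows as a power law

    V(d) = E[(I(x + d*e) - I(x))^2]  ~  C * d^(2H),

where ``H`` is the Hurst exponent of the texture and ``e`` a unit direction.
The quadratic-variation (VAR) estimator regresses ``log V`` on ``log d`` and
reads off ``H`` as half the slope; the fractal dimension of the intensity
surface is ``FD = 3 - H``.

A knee is described by a patchwork of 16 rectangular regions of interest (ROIs)
tiling the tibial subchondral band. For each ROI the estimator is evaluated in
two increment directions -- horizontal (HF, along image rows) and vertical
(VF, along columns) -- and over two physical scale bands -- "micro"
(lags below ~0.4 mm, the scale of individual trabeculae) and "milli"
(lags of ~0.6-1.2 mm, the scale of the trabecular network) -- yielding
16 x 2 x 2 = 64 descriptors per image.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .exceptions import (
    BandError,
    DegenerateTextureError,
    LagError,
    ParameterError,
    SizeError,
    StructuralError,
)

__all__ = [
    "TextureImage",
    "ROILayout",
    "ScaleBands",
    "Variogram",
    "TBTVector",
    "BANDS",
    "DIRECTIONS",
    "COMPARTMENTS",
    "build_roi_layout",
    "directional_variogram",
    "fit_fractal",
    "extract_tbt",
    "delta_tbt",
    "subset_by_compartment",
    "estimate_hurst",
    "descriptor_names",
]

BANDS = ("micro", "milli")
DIRECTIONS = ("HF", "VF")
COMPARTMENTS = ("medial", "central", "lateral")

#: Default compartment tag per column of the 2x8 ROI grid: the medial plateau
#: spans columns 0-2, the central (inter-spinous) region columns 3-4, and the
#: lateral plateau columns 5-7.
DEFAULT_COMPARTMENT_COLS: dict[int, str] = {
    0: "medial", 1: "medial", 2: "medial",
    3: "central", 4: "central",
    5: "lateral", 6: "lateral", 7: "lateral",
}


@dataclass(frozen=True)
class TextureImage:
    """A 2D grayscale intensity field with physical pixel spacing.

    Parameters
    ----------
    pixels : ndarray of shape (rows, cols)
        Non-negative intensities (float or integer).
    pixel_spacing_mm : float
        Physical size of one pixel in millimetres.
    """

    pixels: np.ndarray
    pixel_spacing_mm: float

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2 or px.shape[0] < 16 or px.shape[1] < 16:
            raise SizeError(f"image must be at least 16x16 pixels, got {px.shape}")
        if not np.all(np.isfinite(px)) or np.any(px < 0):
            raise ParameterError("pixel intensities must be finite and non-negative")
        if not self.pixel_spacing_mm > 0:
            raise ParameterError("pixel_spacing_mm must be positive")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class ROILayout:
    """An ordered patchwork of 16 axis-aligned ROIs with compartment tags.

    Each ROI is a half-open pixel rectangle ``(row, col, height, width)``.
    """

    rois: tuple[tuple[int, int, int, int], ...]
    compartments: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.rois) != 16:
            raise StructuralError(f"layout must have exactly 16 ROIs, got {len(self.rois)}")
        if len(self.compartments) != 16:
            raise StructuralError("one compartment tag per ROI is required")
        for tag in self.compartments:
            if tag not in COMPARTMENTS:
                raise ParameterError(f"unknown compartment tag {tag!r}")
        for tag in COMPARTMENTS:
            if tag not in self.compartments:
                raise StructuralError(f"compartment {tag!r} is unused")
        for i, (r, c, h, w) in enumerate(self.rois):
            if h < 16 or w < 16:
                raise SizeError(f"ROI {i} is {h}x{w}; ROIs must be at least 16 px per side")
        # pairwise non-overlap
        for (i, a), (j, b) in itertools.combinations(enumerate(self.rois), 2):
            if _rects_overlap(a, b):
                raise StructuralError(f"ROIs {i} and {j} overlap")

    def roi_ids(self, compartment: str) -> list[int]:
        """Indices of the ROIs tagged with *compartment* ('all' for every ROI)."""
        if compartment == "all":
            return list(range(16))
        if compartment not in COMPARTMENTS:
            raise ParameterError(f"unknown compartment {compartment!r}")
        return [i for i, tag in enumerate(self.compartments) if tag == compartment]


def _rects_overlap(a: tuple[int, int, int, int], b: tuple[int, int, int, int]) -> bool:
    ar, ac, ah, aw = a
    br, bc, bh, bw = b
    return ar < br + bh and br < ar + ah and ac < bc + bw and bc < ac + aw


@dataclass(frozen=True)
class ScaleBands:
    """Physical scale bands (mm) delimiting the micro and milli regimes.

    The empirical variograms of subchondral texture show a break around
    0.5 mm; lags at or below ``micro_max_mm`` probe individual trabeculae
    while lags in ``[milli_min_mm, milli_max_mm]`` probe the network scale.
    """

    micro_max_mm: float = 0.400
    milli_min_mm: float = 0.600
    milli_max_mm: float = 1.200
    cutoff_mm: float = 0.500  # informational: the observed regime break

    def __post_init__(self) -> None:
        if not (0 < self.micro_max_mm < self.cutoff_mm < self.milli_min_mm < self.milli_max_mm):
            raise ParameterError(
                "bands must satisfy 0 < micro_max < cutoff < milli_min < milli_max"
            )

    def band_mask(self, lags_mm: np.ndarray, band: str) -> np.ndarray:
        """Boolean mask of the lags falling in *band* (boundaries included)."""
        lags_mm = np.asarray(lags_mm, dtype=float)
        if band == "micro":
            return lags_mm <= self.micro_max_mm
        if band == "milli":
            return (lags_mm >= self.milli_min_mm) & (lags_mm <= self.milli_max_mm)
        raise ParameterError(f"unknown band {band!r}")


@dataclass(frozen=True)
class Variogram:
    """Directional empirical variogram of one ROI."""

    direction: str
    lags_px: np.ndarray
    lags_mm: np.ndarray
    v: np.ndarray
    n_pairs: np.ndarray

    def __post_init__(self) -> None:
        if self.direction not in DIRECTIONS:
            raise ParameterError(f"direction must be one of {DIRECTIONS}")
        if not (len(self.lags_px) == len(self.lags_mm) == len(self.v) == len(self.n_pairs)):
            raise StructuralError("variogram fields must have equal length")
        if np.any(np.asarray(self.v) < 0) or np.any(np.asarray(self.n_pairs) < 1):
            raise StructuralError("v must be >= 0 and n_pairs >= 1 elementwise")


@dataclass(frozen=True)
class TBTVector:
    """The 64 fractal descriptors of one knee image.

    ``index`` maps each entry to its ``(roi_id, band, direction)`` triple in
    lexicographic order (roi 0..15, band micro/milli, direction HF/VF).
    ``descriptor_kind`` is ``"H"`` (Hurst exponent) or ``"FD"``
    (surface fractal dimension, ``FD = 3 - H``).
    """

    values: np.ndarray
    index: tuple[tuple[int, str, str], ...]
    descriptor_kind: str = "H"

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.shape != (len(self.index),):
            raise StructuralError("values and index lengths differ")
        if self.descriptor_kind not in ("H", "FD"):
            raise ParameterError("descriptor_kind must be 'H' or 'FD'")
        if len(set(self.index)) != len(self.index):
            raise StructuralError("descriptor index has duplicate entries")
        object.__setattr__(self, "values", vals)

    def __len__(self) -> int:
        return len(self.values)

    def names(self, prefix: str = "tbt") -> list[str]:
        return [f"{prefix}_r{r:02d}_{b}_{d}" for r, b, d in self.index]


def full_index() -> tuple[tuple[int, str, str], ...]:
    """The canonical 64-entry descriptor index: (roi, band, direction)."""
    return tuple(
        (roi, band, direction)
        for roi in range(16)
        for band in BANDS
        for direction in DIRECTIONS
    )


def descriptor_names(prefix: str = "tbt") -> list[str]:
    """Canonical descriptor column names, e.g. ``tbt_r00_micro_HF``."""
    return [f"{prefix}_r{r:02d}_{b}_{d}" for r, b, d in full_index()]


def build_roi_layout(
    tibia_bbox: tuple[int, int, int, int],
    rows: int = 2,
    cols: int = 8,
    compartment_cols: dict[int, str] | None = None,
) -> ROILayout:
    """Tile a tibial bounding box with a ``rows x cols`` grid of 16 ROIs.

    Parameters
    ----------
    tibia_bbox : (row, col, height, width)
        Half-open pixel rectangle delimiting the subchondral band.
    rows, cols : int
        Grid shape; must multiply to 16. The default 2x8 grid follows the
        patchwork covering the whole subchondral zone, two ROI rows deep.
    compartment_cols : dict, optional
        Column index -> compartment tag. Defaults to columns 0-2 medial,
        3-4 central, 5-7 lateral.
    """
    if rows * cols != 16:
        raise StructuralError(f"rows*cols must equal 16, got {rows}x{cols}")
    if compartment_cols is None:
        if cols != 8:
            raise ParameterError("compartment_cols is required when cols != 8")
        compartment_cols = DEFAULT_COMPARTMENT_COLS
    missing = [c for c in range(cols) if c not in compartment_cols]
    if missing:
        raise ParameterError(f"compartment_cols lacks entries for columns {missing}")

    r0, c0, height, width = tibia_bbox
    if height < 16 * rows or width < 16 * cols:
        raise SizeError(
            f"bbox {height}x{width} cannot host a {rows}x{cols} grid of >=16 px ROIs"
        )
    row_edges = np.linspace(0, height, rows + 1).astype(int)
    col_edges = np.linspace(0, width, cols + 1).astype(int)
    rois = []
    tags = []
    for i in range(rows):
        for j in range(cols):
            rois.append((
                r0 + int(row_edges[i]),
                c0 + int(col_edges[j]),
                int(row_edges[i + 1] - row_edges[i]),
                int(col_edges[j + 1] - col_edges[j]),
            ))
            tags.append(compartment_cols[j])
    return ROILayout(rois=tuple(rois), compartments=tuple(tags))


def directional_variogram(
    image: TextureImage,
    roi: tuple[int, int, int, int],
    direction: str,
    max_lag_px: int,
) -> Variogram:
    """Quadratic variations of one ROI along rows (HF) or columns (VF).

    For each lag ``d`` in ``1..max_lag_px`` the statistic is the mean squared
    increment ``V(d) = mean[(I(x + d*e) - I(x))^2]`` over every pixel pair in
    the ROI separated by ``d`` pixels along the unit direction ``e`` --
    ``e = (0, 1)`` for HF (increments along a row), ``e = (1, 0)`` for VF.
    Pair counts are exact; a constant ROI yields an all-zero variogram, which
    is legal here and flagged only at fitting time.
    """
    if direction not in DIRECTIONS:
        raise ParameterError(f"direction must be one of {DIRECTIONS}")
    r, c, h, w = roi
    if r < 0 or c < 0 or r + h > image.shape[0] or c + w > image.shape[1]:
        raise StructuralError(f"ROI {roi} does not fit in image of shape {image.shape}")
    patch = image.pixels[r : r + h, c : c + w]
    extent = w if direction == "HF" else h
    if not 1 <= max_lag_px < extent:
        raise LagError(
            f"max_lag_px must be in [1, {extent - 1}] for a {h}x{w} ROI ({direction})"
        )
    lags = np.arange(1, max_lag_px + 1)
    v = np.empty(max_lag_px)
    n_pairs = np.empty(max_lag_px, dtype=int)
    for k, d in enumerate(lags):
        if direction == "HF":
            diff = patch[:, d:] - patch[:, :-d]
        else:
            diff = patch[d:, :] - patch[:-d, :]
        v[k] = np.mean(diff * diff)
        n_pairs[k] = diff.size
    return Variogram(
        direction=direction,
        lags_px=lags,
        lags_mm=lags * image.pixel_spacing_mm,
        v=v,
        n_pairs=n_pairs,
    )


def fit_fractal(
    variogram: Variogram,
    band: str,
    bands: ScaleBands = ScaleBands(),
    kind: str = "H",
    weight_by_pairs: bool = False,
) -> float:
    """Estimate the Hurst exponent from a variogram restricted to one band.

    Ordinary least squares of ``log V`` on ``log lag_mm`` over the lags whose
    physical length falls inside the band (boundaries included); the Hurst
    estimate is half the slope, and ``FD = 3 - H`` when ``kind='FD'``. Exact
    on exact power laws. ``weight_by_pairs`` switches to pair-count-weighted
    least squares.

    The estimate is returned unclipped: pathological ROIs may yield values
    outside (0, 1), which downstream standardisation absorbs.
    """
    if kind not in ("H", "FD"):
        raise ParameterError("kind must be 'H' or 'FD'")
    mask = bands.band_mask(variogram.lags_mm, band)
    if int(mask.sum()) < 2:
        raise BandError(
            f"band {band!r} contains {int(mask.sum())} lag(s); at least 2 are required"
        )
    v = np.asarray(variogram.v)[mask]
    if np.any(v == 0):
        raise DegenerateTextureError(f"zero variogram value inside band {band!r}")
    x = np.log(np.asarray(variogram.lags_mm)[mask])
    y = np.log(v)
    w = np.asarray(variogram.n_pairs)[mask].astype(float) if weight_by_pairs else None
    slope = np.polyfit(x, y, 1, w=w)[0]
    hurst = slope / 2.0
    return 3.0 - hurst if kind == "FD" else hurst


def _max_lag_for(bands: ScaleBands, spacing_mm: float) -> int:
    return int(np.floor(bands.milli_max_mm / spacing_mm))


def extract_tbt(
    image: TextureImage,
    layout: ROILayout,
    bands: ScaleBands = ScaleBands(),
    kind: str = "H",
) -> TBTVector:
    """Compute the 64 TBT descriptors of one knee image.

    Per ROI, the directional variogram is evaluated up to the largest lag in
    the milli band, then fitted separately in the micro and milli bands for
    the HF and VF directions. Values are ordered lexicographically by
    ``(roi, band, direction)``. Per-ROI failures are re-raised with the ROI
    index attached.
    """
    max_lag = _max_lag_for(bands, image.pixel_spacing_mm)
    values = []
    index = []
    for roi_id, roi in enumerate(layout.rois):
        fits: dict[tuple[str, str], float] = {}
        for direction in DIRECTIONS:
            try:
                vg = directional_variogram(image, roi, direction, max_lag)
                for band in BANDS:
                    fits[band, direction] = fit_fractal(vg, band, bands, kind=kind)
            except (LagError, BandError, DegenerateTextureError) as exc:
                raise type(exc)(f"ROI {roi_id} ({direction}): {exc}") from exc
        for band in BANDS:
            for direction in DIRECTIONS:
                values.append(fits[band, direction])
                index.append((roi_id, band, direction))
    return TBTVector(values=np.array(values), index=tuple(index), descriptor_kind=kind)


def delta_tbt(v0: TBTVector, v24: TBTVector) -> TBTVector:
    """Longitudinal descriptor change, ``delta = v24 - v0`` componentwise."""
    if v0.index != v24.index or v0.descriptor_kind != v24.descriptor_kind:
        raise StructuralError("TBT vectors have mismatching index structures")
    return TBTVector(
        values=v24.values - v0.values,
        index=v0.index,
        descriptor_kind=v0.descriptor_kind,
    )


def subset_by_compartment(v: TBTVector, layout: ROILayout, compartment: str) -> TBTVector:
    """Restrict a descriptor vector to the ROIs of one tibial compartment.

    ``compartment`` is ``'medial'``, ``'central'``, ``'lateral'`` or ``'all'``;
    the result keeps the 4 descriptors of each selected ROI in order.
    """
    keep = set(layout.roi_ids(compartment))
    sel = [i for i, (roi, _, _) in enumerate(v.index) if roi in keep]
    return TBTVector(
        values=v.values[sel],
        index=tuple(v.index[i] for i in sel),
        descriptor_kind=v.descriptor_kind,
    )


def estimate_hurst(
    image: TextureImage,
    band: str = "micro",
    direction: str = "HF",
    bands: ScaleBands = ScaleBands(),
) -> float:
    """Whole-image Hurst estimate: single-ROI variogram fit in one band."""
    roi = (0, 0, image.shape[0], image.shape[1])
    vg = directional_variogram(image, roi, direction, _max_lag_for(bands, image.pixel_spacing_mm))
    return fit_fractal(vg, band, bands)
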