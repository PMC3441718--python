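"""Polar cluster quantification and localization classification.

Rod-shaped gliding bacteria such as *Myxococcus xanthus* localize motility
regulators (MglA, MglB, RomR) in clusters at the cell poles.  A cell's
localization pattern is scored from a single fluorescence channel by
integrating the signal over each pole region, subtracting the integrated
signal of an equal-area cytoplasmic reference region (background
correction), and classifying the ratio of the two corrected pole
intensities:

* ratio ≤ 2.0                -> bipolar symmetric
* 2.1 ≤ ratio ≤ 10.0         -> bipolar asymmetric
* ratio ≥ 10.1               -> unipolar

The ratio is always taken as max/min, rounded to one decimal before the
rules are applied (the printed boundaries are one-decimal values; rounding
closes the raw-ratio gaps (2.0, 2.1) and (10.0, 10.1) so every ratio maps
to exactly one class).  A cell with no pole above the cluster-presence
floor is scored diffuse; a cell with exactly one pole above the floor is
unipolar regardless of ratio.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from enum import Enum
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Pattern",
    "CellImage",
    "PolarMeasurement",
    "PatternSummary",
    "measure_polar_intensity",
    "classify_localization",
    "summarize_patterns",
    "round_ratio",
]


class Pattern(str, Enum):
    """Localization classes of a polar fluorescence signal."""

    UNIPOLAR = "unipolar"
    BIPOLAR_ASYMMETRIC = "bipolar_asymmetric"
    BIPOLAR_SYMMETRIC = "bipolar_symmetric"
    DIFFUSE = "diffuse"


def _as_pixel_array(pixels) -> np.ndarray:
    arr = np.asarray(pixels, dtype=np.intp)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("pixel region must be an (n, 2) array of row/col coordinates")
    return arr


@dataclass
class CellImage:
    """Single-channel intensity image with cell mask and measurement regions.

    ``pole_regions`` are two disjoint pixel sets (``(n, 2)`` integer arrays of
    0-based row/col coordinates); ``cyto_region`` is a cytoplasmic reference
    region with the same pixel count as each pole region, so background
    correction needs no area scaling.
    """

    intensity: np.ndarray
    cell_mask: np.ndarray
    pole_regions: tuple[np.ndarray, np.ndarray]
    cyto_region: np.ndarray
    cell_id: str = "cell"

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity)
        self.cell_mask = np.asarray(self.cell_mask, dtype=bool)
        self.pole_regions = (
            _as_pixel_array(self.pole_regions[0]),
            _as_pixel_array(self.pole_regions[1]),
        )
        self.cyto_region = _as_pixel_array(self.cyto_region)

    def validate(self) -> None:
        """Check the region invariants; raise ValueError on violation."""
        if self.intensity.shape != self.cell_mask.shape:
            raise ValueError("intensity and cell_mask shapes differ")
        n0, n1, nc = (
            len(self.pole_regions[0]),
            len(self.pole_regions[1]),
            len(self.cyto_region),
        )
        if not (n0 == n1 == nc):
            raise ValueError(
                f"region pixel counts differ: pole_1={n0}, pole_2={n1}, "
                f"cytoplasm={nc}; background correction requires equal areas"
            )
        for name, region in (
            ("pole_1", self.pole_regions[0]),
            ("pole_2", self.pole_regions[1]),
            ("cytoplasm", self.cyto_region),
        ):
            if len(region) == 0:
                raise ValueError(f"region {name} is empty")
            if not self.cell_mask[region[:, 0], region[:, 1]].all():
                raise ValueError(f"region {name} extends outside the cell mask")
        set0 = set(map(tuple, self.pole_regions[0]))
        set1 = set(map(tuple, self.pole_regions[1]))
        if set0 & set1:
            raise ValueError("pole regions overlap")


@dataclass
class PolarMeasurement:
    """Background-corrected pole intensities and the class they imply.

    ``corrected_I`` may be negative after background subtraction.  ``ratio``
    is max/min of the corrected intensities, defined only when both poles
    carry signal above the presence floor.
    """

    corrected_I: tuple[float, float]
    ratio: float | None = None
    pattern: Pattern | None = None
    cell_id: str = "cell"


@dataclass
class PatternSummary:
    """Counts and percentages of localization patterns across cells."""

    counts: dict[Pattern, int]
    percentages: dict[Pattern, float]
    n_cells: int


def _region_sum(intensity: np.ndarray, region: np.ndarray) -> float:
    return float(intensity[region[:, 0], region[:, 1]].sum(dtype=np.float64))


def measure_polar_intensity(img: CellImage) -> PolarMeasurement:
    """Integrate each pole region and subtract the cytoplasmic reference.

    corrected_I[i] = sum(intensity over pole_region_i)
                     - sum(intensity over cyto_region)

    Pure function of the pixel values: exact in integer photon units.
    """
    img.validate()
    cyto = _region_sum(img.intensity, img.cyto_region)
    corrected = tuple(
        _region_sum(img.intensity, pole) - cyto for pole in img.pole_regions
    )
    return PolarMeasurement(corrected_I=corrected, cell_id=img.cell_id)


def round_ratio(r: float) -> float:
    """Round a ratio to one decimal, half away from zero.

    Works on the value's shortest decimal representation so that e.g.
    505/100 = 5.05 rounds to 5.1 even though the nearest binary double is
    fractionally below 5.05.
    """
    return float(Decimal(repr(float(r))).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def classify_localization(
    corrected_I: Sequence[float], presence_floor: float = 0.0
) -> Pattern:
    """Assign a localization class from two corrected pole intensities.

    A pole carries a cluster when its corrected intensity exceeds
    ``presence_floor`` (default 0; set to k·sigma of the cytoplasmic noise
    for noisy data).  Neither pole above the floor -> diffuse; exactly one
    -> unipolar; both -> the ratio max/min is rounded to one decimal and
    mapped to bipolar symmetric (≤2.0), bipolar asymmetric (2.1–10.0) or
    unipolar (≥10.1).
    """
    a, b = float(corrected_I[0]), float(corrected_I[1])
    if math.isnan(a) or math.isnan(b) or math.isinf(a) or math.isinf(b):
        raise ValueError(f"corrected intensities must be finite, got ({a}, {b})")
    if presence_floor < 0:
        raise ValueError("presence_floor must be >= 0")
    present = (a > presence_floor, b > presence_floor)
    if not any(present):
        return Pattern.DIFFUSE
    if present.count(True) == 1:
        return Pattern.UNIPOLAR
    r = round_ratio(max(a, b) / min(a, b))
    if r <= 2.0:
        return Pattern.BIPOLAR_SYMMETRIC
    if r <= 10.0:
        return Pattern.BIPOLAR_ASYMMETRIC
    return Pattern.UNIPOLAR


def classify_measurement(
    m: PolarMeasurement, presence_floor: float = 0.0
) -> PolarMeasurement:
    """Return a copy of ``m`` with ratio and pattern filled in."""
    a, b = m.corrected_I
    pattern = classify_localization((a, b), presence_floor)
    ratio = None
    if min(a, b) > presence_floor:
        ratio = round_ratio(max(a, b) / min(a, b))
    return PolarMeasurement(
        corrected_I=m.corrected_I, ratio=ratio, pattern=pattern, cell_id=m.cell_id
    )


def summarize_patterns(
    measurements: Iterable[PolarMeasurement | Pattern],
) -> PatternSummary:
    """Tabulate pattern counts and percentages over a set of cells.

    Accepts classified measurements or bare patterns.  Percentages are
    100·count/n and sum to 100 up to float rounding.
    """
    patterns: list[Pattern] = []
    for m in measurements:
        if isinstance(m, Pattern):
            patterns.append(m)
        else:
            if m.pattern is None:
                raise ValueError(
                    f"measurement for {m.cell_id!r} has no pattern; classify first"
                )
            patterns.append(m.pattern)
    if not patterns:
        raise ValueError("summarize_patterns requires at least one measurement")
    n = len(patterns)
    counts = Counter(patterns)
    full_counts = {p: counts.get(p, 0) for p in Pattern}
    percentages = {p: 100.0 * c / n for p, c in full_counts.items()}
    return PatternSummary(counts=full_counts, percentages=percentages, n_cells=n)
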