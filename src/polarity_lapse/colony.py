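"""Colony-expansion quantification for agar motility assays.

Motility of gliding bacteria is scored on agar plates as the increase in
colony diameter over 24 h.  Each colony's diameter is measured at two
positions (here: two chords through the mask centroid at fixed angles,
default orthogonal) and averaged; expansion is diameter(24 h) minus
diameter(0 h), reported across replicate colonies (typically three per
strain) as mean ± sample standard deviation in mm.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

logger = logging.getLogger(__name__)

__all__ = ["ColonyOutline", "colony_diameter", "colony_expansion"]


@dataclass
class ColonyOutline:
    """Binary colony mask plus the physical pixel size in mm/pixel."""

    mask: np.ndarray
    pixel_size: float
    colony_id: str = "colony"

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if not self.mask.any():
            raise ValueError(f"colony mask {self.colony_id!r} is empty")
        _, n_components = ndimage.label(self.mask)
        if n_components != 1:
            raise ValueError(
                f"colony mask {self.colony_id!r} has {n_components} connected "
                "components; expected a single colony"
            )


def _chord_length(mask: np.ndarray, centroid: tuple[float, float], angle_rad: float,
                  step: float = 0.25) -> float:
    """Length in pixels of the chord through the centroid at the given angle.

    Walks from the centroid in both directions in sub-pixel steps using
    nearest-pixel membership, stopping at the first exit from the mask
    (adequate for convex colony outlines).
    """
    h, w = mask.shape
    drow = -math.sin(angle_rad)  # angle measured in image x/y convention
    dcol = math.cos(angle_rad)

    def extent(sign: float) -> float:
        t = 0.0
        while True:
            t_next = t + step
            r = int(round(centroid[0] + sign * t_next * drow))
            c = int(round(centroid[1] + sign * t_next * dcol))
            if r < 0 or r >= h or c < 0 or c >= w or not mask[r, c]:
                return t
            t = t_next

    return extent(+1.0) + extent(-1.0)


def colony_diameter(
    outline: ColonyOutline, angles_deg: tuple[float, float] = (0.0, 90.0)
) -> float:
    """Colony diameter in mm: mean of two chords through the centroid.

    The two measurement angles default to 0° and 90° (orthogonal chords), a
    reproducible stand-in for measuring the plate "at two positions".
    """
    centroid = ndimage.center_of_mass(outline.mask)
    chords = [
        _chord_length(outline.mask, centroid, math.radians(a)) for a in angles_deg
    ]
    return float(np.mean(chords)) * outline.pixel_size


def colony_expansion(
    replicates: list[tuple[ColonyOutline, ColonyOutline]],
    angles_deg: tuple[float, float] = (0.0, 90.0),
) -> dict:
    """Mean ± sample SD of colony-diameter increase across replicates.

    ``replicates`` pairs the 0-h and 24-h outline of each colony.  Negative
    increases (shrinkage) are allowed but logged.  With a single replicate
    the SD is undefined and reported as 0 with a warning.
    """
    if not replicates:
        raise ValueError("colony_expansion requires at least one replicate pair")
    increases = []
    for t0, t24 in replicates:
        if not math.isclose(t0.pixel_size, t24.pixel_size):
            raise ValueError(
                f"pixel sizes differ within pair {t0.colony_id!r}: "
                f"{t0.pixel_size} vs {t24.pixel_size}"
            )
        delta = colony_diameter(t24, angles_deg) - colony_diameter(t0, angles_deg)
        if delta < 0:
            logger.warning("colony %s shrank by %.3f mm", t0.colony_id, -delta)
        increases.append(delta)
    increases = np.asarray(increases)
    if len(increases) == 1:
        warnings.warn("single replicate: sample SD undefined, reported as 0")
        sd = 0.0
    else:
        sd = float(increases.std(ddof=1))
    return {
        "mean_mm": float(increases.mean()),
        "sd_mm": sd,
        "n": len(increases),
        "increases_mm": increases.tolist(),
    }
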