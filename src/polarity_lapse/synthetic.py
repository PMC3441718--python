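"""Synthetic inputs with known ground truth for every pipeline stage.

Generates (i) rod-shaped cells with planted polar clusters over a uniform
cytoplasmic background, (ii) time-lapse trajectories with reversals planted
as a Poisson-type process on the frame grid, (iii) protein alignments drawn
column-wise from specified residue profiles, and (iv) genome × marker
presence/absence tables with planted co-occurrence pattern counts.

Cells are axis-aligned capsules (rectangle plus semicircular caps) — the
simplest shape with unambiguous poles.  Pole measurement regions are discs
centred on the cap tips, clipped to the mask; the cytoplasmic reference
region is a disc of identical pixel count at mid-cell, so background
correction needs no area scaling.  Photon counts are integers before noise;
Poisson noise is applied pixel-wise.

All generators are deterministic: same spec + same seed gives byte-identical
output.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .polarity import CellImage, PolarMeasurement, classify_measurement
from .reversals import Trajectory
from .seq_features import AMINO_ACIDS, CooccurrenceTable

__all__ = [
    "ImageSpec",
    "TrackSpec",
    "AlignmentSpec",
    "PatternSpec",
    "DEFAULT_MARKERS",
    "FIG2_LIKE_PATTERN_COUNTS",
    "generate_cell_image",
    "generate_trajectories",
    "generate_alignment",
    "generate_presence_absence",
    "conserved_region_profiles",
]

DEFAULT_MARKERS = ("MglA", "MglB", "RomR-REC", "RomR-C", "Frz", "Glt", "T4P")

# Default planted pattern counts, engineered to reproduce the headline
# co-occurrence structure of the marker set: 60 genomes with MglA and MglB,
# 26 of those with an intact RomR (REC + C), 10 of those with a Frz system,
# 5 genomes with a partial RomR and no MglA/MglB, 70 MglA and 31 RomR
# genomes in total.  Marker order follows DEFAULT_MARKERS.
FIG2_LIKE_PATTERN_COUNTS: dict[str, int] = {
    "1111111": 10,  # full polarity + reversal + both motility machineries
    "1111011": 16,  # MglA/MglB/RomR without Frz
    "1100001": 34,  # MglA/MglB only, T4P
    "1000001": 10,  # MglA only, T4P
    "0010000": 5,   # partial RomR (REC only), no MglA/MglB
    "0000001": 20,  # T4P only
}


@dataclass
class ImageSpec:
    """Parameters of one synthetic cell image.

    pole_intensities are the planted corrected integrated intensities in
    photons (what a downstream measurement should recover exactly in the
    noiseless case).  cyto_level is the uniform cytoplasmic background in
    photons/pixel.  noise_model is "none", "poisson", or "gaussian" (with
    gaussian_sigma).
    """

    image_size: tuple[int, int] = (64, 96)
    cell_length: float = 70.0
    cell_width: float = 14.0
    cyto_level: int = 100
    pole_intensities: tuple[int, int] = (500, 100)
    pole_region_radius: float = 5.0
    noise_model: str = "none"
    gaussian_sigma: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        h, w = self.image_size
        if self.cell_length + 4 > w or self.cell_width + 4 > h:
            raise ValueError("cell does not fit inside the image with a 2-pixel margin")
        if any(p < 0 for p in self.pole_intensities):
            raise ValueError("pole_intensities must be >= 0")
        if self.cyto_level < 0:
            raise ValueError("cyto_level must be >= 0")
        if self.cell_width <= 2 or self.cell_length <= self.cell_width:
            raise ValueError("need cell_length > cell_width > 2")
        if self.pole_region_radius <= 0:
            raise ValueError("pole_region_radius must be positive")
        if self.noise_model not in ("none", "poisson", "gaussian"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")


@dataclass
class TrackSpec:
    """Parameters of a synthetic time-lapse tracking experiment.

    reversal_rate is the expected number of reversals per observation
    window (Poisson mean λ).  Defaults match a standard 15-min window at
    30-s frames with 50 cells.
    """

    duration_min: float = 15.0
    frame_interval_s: float = 30.0
    reversal_rate: float = 4.0
    speed: float = 3.0
    positional_noise_sd: float = 0.2
    pause_fraction: float = 0.0
    n_cells: int = 50
    seed: int = 0

    @property
    def n_intervals(self) -> int:
        n = self.duration_min * 60.0 / self.frame_interval_s
        if abs(n - round(n)) > 1e-9:
            raise ValueError(
                f"duration ({self.duration_min} min) is not an integer number "
                f"of {self.frame_interval_s}-s intervals"
            )
        return int(round(n))

    def validate(self) -> None:
        _ = self.n_intervals
        if self.reversal_rate < 0:
            raise ValueError("reversal_rate must be >= 0")
        if not 0 <= self.pause_fraction <= 1:
            raise ValueError("pause_fraction must be in [0, 1]")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.speed < 0 or self.positional_noise_sd < 0:
            raise ValueError("speed and positional_noise_sd must be >= 0")
        n_boundaries = self.n_intervals - 1
        if self.reversal_rate > n_boundaries:
            raise ValueError(
                f"reversal_rate {self.reversal_rate} exceeds the "
                f"{n_boundaries} observable direction changes in the window"
            )
        if self.reversal_rate > n_boundaries / 2:
            warnings.warn(
                "mean inter-reversal time below 2 frames: reversals are "
                "undetectable at this sampling rate",
                stacklevel=2,
            )


@dataclass
class AlignmentSpec:
    """Column-profile model of an aligned protein family."""

    n_sequences: int
    column_profiles: np.ndarray  # (n_columns, 20), rows on the simplex
    seed: int = 0

    def __post_init__(self) -> None:
        self.column_profiles = np.asarray(self.column_profiles, dtype=float)

    @property
    def n_columns(self) -> int:
        return self.column_profiles.shape[0]

    def validate(self) -> None:
        if self.n_sequences < 1:
            raise ValueError("n_sequences must be >= 1")
        if self.column_profiles.ndim != 2 or self.column_profiles.shape[1] != len(
            AMINO_ACIDS
        ):
            raise ValueError("column_profiles must be (n_columns, 20)")
        if np.any(self.column_profiles < 0):
            raise ValueError("profile frequencies must be >= 0")
        sums = self.column_profiles.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("each column profile must sum to 1 (±1e-9)")


@dataclass
class PatternSpec:
    """Planted co-occurrence pattern counts for a marker set."""

    markers: tuple[str, ...] = DEFAULT_MARKERS
    pattern_counts: dict[str, int] = field(
        default_factory=lambda: dict(FIG2_LIKE_PATTERN_COUNTS)
    )
    seed: int = 0

    def validate(self) -> None:
        if len(set(self.markers)) != len(self.markers):
            raise ValueError("duplicate marker names")
        for pattern, count in self.pattern_counts.items():
            if len(pattern) != len(self.markers) or set(pattern) - {"0", "1"}:
                raise ValueError(
                    f"pattern {pattern!r} must be a bit-string with one bit "
                    f"per marker ({len(self.markers)} markers)"
                )
            if count < 1:
                raise ValueError(f"pattern {pattern!r} has count {count} < 1")


# ---------------------------------------------------------------------------
# cell images


def _capsule_geometry(spec: ImageSpec):
    h, w = spec.image_size
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    radius = spec.cell_width / 2.0
    half_axis = spec.cell_length / 2.0 - radius  # rectangle half-length
    tips = ((cy, cx - spec.cell_length / 2.0), (cy, cx + spec.cell_length / 2.0))
    return cy, cx, radius, half_axis, tips


def _capsule_mask(spec: ImageSpec) -> np.ndarray:
    h, w = spec.image_size
    cy, cx, radius, half_axis, _ = _capsule_geometry(spec)
    rows, cols = np.mgrid[0:h, 0:w]
    # distance to the central segment along x
    dx = np.clip(np.abs(cols - cx) - half_axis, 0, None)
    dy = rows - cy
    return dx**2 + dy**2 <= radius**2


def _disc_region(
    mask: np.ndarray, center: tuple[float, float], radius: float, n_pixels: int | None
) -> np.ndarray:
    """Mask pixels within radius of center, nearest first; optionally truncated."""
    rows, cols = np.nonzero(mask)
    d2 = (rows - center[0]) ** 2 + (cols - center[1]) ** 2
    inside = d2 <= radius**2
    order = np.lexsort((cols[inside], rows[inside], d2[inside]))
    region = np.stack([rows[inside][order], cols[inside][order]], axis=1)
    if n_pixels is not None:
        region = region[:n_pixels]
    return region


def generate_cell_image(spec: ImageSpec) -> tuple[CellImage, PolarMeasurement]:
    """One synthetic cell plus the ground-truth polar measurement.

    Before noise, the integrated intensity over each pole region equals the
    planted corrected value plus cyto_level × region area, so background
    subtraction against the equal-area cytoplasmic disc recovers the planted
    pair exactly in the noiseless case.  Ground truth records the planted
    corrected intensities and the localization class they imply.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    mask = _capsule_mask(spec)
    cy, cx, _, _, tips = _capsule_geometry(spec)

    pole_a = _disc_region(mask, tips[0], spec.pole_region_radius, None)
    pole_b = _disc_region(mask, tips[1], spec.pole_region_radius, None)
    n_pix = min(len(pole_a), len(pole_b))
    if n_pix == 0:
        raise ValueError("pole regions fall outside the cell mask")
    pole_a, pole_b = pole_a[:n_pix], pole_b[:n_pix]
    if set(map(tuple, pole_a)) & set(map(tuple, pole_b)):
        raise ValueError("pole regions overlap; cell too short for this radius")
    cyto = _disc_region(mask, (cy, cx), max(spec.image_size), n_pix)
    for pole in (pole_a, pole_b):
        if set(map(tuple, pole)) & set(map(tuple, cyto)):
            raise ValueError("cytoplasmic region overlaps a pole region")

    image = np.zeros(spec.image_size, dtype=np.int64)
    image[mask] = spec.cyto_level
    for pole, planted in zip((pole_a, pole_b), spec.pole_intensities):
        planted = int(planted)
        base, extra = divmod(planted, n_pix)
        image[pole[:, 0], pole[:, 1]] += base
        image[pole[:extra, 0], pole[:extra, 1]] += 1

    noisy = image.astype(float)
    if spec.noise_model == "poisson":
        noisy = rng.poisson(image).astype(float)
    elif spec.noise_model == "gaussian":
        noisy = image + rng.normal(0.0, spec.gaussian_sigma, size=image.shape)

    cell = CellImage(
        intensity=noisy,
        cell_mask=mask,
        pole_regions=(pole_a, pole_b),
        cyto_region=cyto,
        cell_id=f"synthetic-{spec.seed}",
    )
    truth = classify_measurement(
        PolarMeasurement(
            corrected_I=tuple(float(p) for p in spec.pole_intensities),
            cell_id=cell.cell_id,
        )
    )
    return cell, truth


# ---------------------------------------------------------------------------
# trajectories


def generate_trajectories(spec: TrackSpec) -> list[Trajectory]:
    """Synthetic single-cell tracks with planted reversal events.

    Each cell moves along a fixed random axis at ``speed`` pixels/frame.
    A reversal is an observable change of direction between consecutive
    steps, so events are planted on the frame grid at the n−1 interior
    frame boundaries, each independently with probability λ/(n−1): the
    planted count per track is Binomial(n−1, λ/(n−1)) with mean exactly λ,
    and every planted event produces a sign change of the noiseless
    displacement series.  The recorded event frame is the first frame at
    which the cell sits displaced in the new direction.  Positional noise
    is i.i.d. Gaussian per frame.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n_int = spec.n_intervals
    p_event = spec.reversal_rate / (n_int - 1) if n_int > 1 else 0.0
    tracks: list[Trajectory] = []
    for ci in range(spec.n_cells):
        theta = rng.uniform(0, 2 * math.pi)
        axis = np.array([math.cos(theta), math.sin(theta)])
        start = rng.uniform(100.0, 900.0, size=2)
        direction = rng.choice([-1.0, 1.0])
        # events[i] flips the direction between step i and step i+1
        events = rng.random(n_int - 1) < p_event
        paused = (
            rng.random(n_int) < spec.pause_fraction
            if spec.pause_fraction > 0
            else np.zeros(n_int, dtype=bool)
        )
        positions = np.empty((n_int + 1, 2))
        positions[0] = start
        event_frames = []
        for i in range(n_int):
            if i > 0 and events[i - 1]:
                direction = -direction
                event_frames.append(i + 1)
            step = 0.0 if paused[i] else direction * spec.speed
            positions[i + 1] = positions[i] + step * axis
        if spec.positional_noise_sd > 0:
            positions = positions + rng.normal(
                0.0, spec.positional_noise_sd, size=positions.shape
            )
        tracks.append(
            Trajectory(
                cell_id=f"cell{ci:04d}",
                positions=positions,
                axis_angle=np.full(n_int + 1, theta),
                frame_interval_s=spec.frame_interval_s,
                true_reversal_frames=np.asarray(event_frames),
            )
        )
    return tracks


# ---------------------------------------------------------------------------
# alignments


def generate_alignment(spec: AlignmentSpec) -> list[SeqRecord]:
    """Sample an aligned sequence set column-wise from the profiles."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    alphabet = np.array(list(AMINO_ACIDS))
    columns = np.empty((spec.n_columns, spec.n_sequences), dtype="U1")
    for j in range(spec.n_columns):
        columns[j] = rng.choice(alphabet, size=spec.n_sequences, p=spec.column_profiles[j])
    return [
        SeqRecord(Seq("".join(columns[:, i])), id=f"seq{i:05d}", description="")
        for i in range(spec.n_sequences)
    ]


def conserved_region_profiles(
    n_columns: int = 20,
    invariant: dict[int, str] | None = None,
    enriched: dict[int, tuple[str, float]] | None = None,
    background_concentration: float = 5.0,
    seed: int = 0,
) -> np.ndarray:
    """Column profiles for a conserved protein region.

    Emulates a conserved C-terminal domain: ``invariant`` columns are point
    masses on one residue (e.g. the invariant Trp and Pro of a conserved
    output domain), ``enriched`` columns put the stated weight on one
    residue (e.g. 0.6 on Glu) with the rest spread over the alphabet, and
    the remaining columns are Dirichlet draws around uniform.
    """
    if invariant is None:
        invariant = {n_columns // 5: "W", (3 * n_columns) // 5: "P"}
    if enriched is None:
        enriched = {
            (2 * n_columns) // 5: ("E", 0.6),
            (4 * n_columns) // 5: ("E", 0.6),
        }
    for col in list(invariant) + list(enriched):
        if not 0 <= col < n_columns:
            raise ValueError(f"column index {col} outside 0..{n_columns - 1}")
    overlap = set(invariant) & set(enriched)
    if overlap:
        raise ValueError(f"columns {sorted(overlap)} are both invariant and enriched")
    rng = np.random.default_rng(seed)
    n_aa = len(AMINO_ACIDS)
    profiles = rng.dirichlet(np.full(n_aa, background_concentration), size=n_columns)
    for col, residue in invariant.items():
        profiles[col] = 0.0
        profiles[col][AMINO_ACIDS.index(residue)] = 1.0
    for col, (residue, weight) in enriched.items():
        rest = rng.dirichlet(np.full(n_aa - 1, background_concentration))
        row = np.insert(rest * (1 - weight), AMINO_ACIDS.index(residue), weight)
        profiles[col] = row
    return profiles


# ---------------------------------------------------------------------------
# presence/absence tables


def generate_presence_absence(spec: PatternSpec) -> CooccurrenceTable:
    """Genome × marker table with exactly the planted pattern counts.

    Rows (genomes) are shuffled by the seed; genome ids are synthetic.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    rows = []
    for pattern, count in sorted(spec.pattern_counts.items()):
        bits = [bit == "1" for bit in pattern]
        rows.extend([bits] * count)
    n = len(rows)
    ids = [f"genome{i:05d}" for i in range(n)]
    order = rng.permutation(n)
    data = pd.DataFrame(
        [rows[i] for i in order],
        index=[ids[i] for i in order],
        columns=list(spec.markers),
    )
    return CooccurrenceTable(data)
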