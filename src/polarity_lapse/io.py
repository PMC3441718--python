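"""Readers and writers for the pipeline's on-disk formats.

Conventions: images are single-channel 16-bit TIFF; measurement regions are
CSV of 0-based row/col pixel coordinates (or a label TIFF with pole 1 = 1,
pole 2 = 2, cytoplasm = 3); tracks are CSV with 0-based frames; domain-hit
tables are TSV with 1-based inclusive residue coordinates (the common
domain-table convention, stated in the header comment of each file);
alignments are aligned FASTA.  CSV dialect: comma, UTF-8, ``.`` decimal,
mandatory header row.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from Bio import SeqIO

from . import __version__
from .polarity import CellImage, PatternSummary, PolarMeasurement
from .reversals import ReversalSummary, Trajectory
from .seq_features import CooccurrenceTable, DomainHit

REGION_LABELS = {"pole_1": 1, "pole_2": 2, "cytoplasm": 3}


# --- images and regions ----------------------------------------------------


def write_image_tiff(path, image: np.ndarray) -> None:
    arr = np.asarray(image)
    clipped = np.clip(np.rint(arr), 0, np.iinfo(np.uint16).max).astype(np.uint16)
    tifffile.imwrite(str(path), clipped)


def read_image_tiff(path) -> np.ndarray:
    return tifffile.imread(str(path))


def write_regions_csv(path, cell: CellImage) -> None:
    rows = []
    for name, region in (
        ("pole_1", cell.pole_regions[0]),
        ("pole_2", cell.pole_regions[1]),
        ("cytoplasm", cell.cyto_region),
    ):
        for r, c in region:
            rows.append({"region": name, "row": int(r), "col": int(c)})
    pd.DataFrame(rows).to_csv(path, index=False)


def write_regions_label_tiff(path, cell: CellImage) -> None:
    labels = np.zeros(cell.cell_mask.shape, dtype=np.uint16)
    for name, region in (
        ("pole_1", cell.pole_regions[0]),
        ("pole_2", cell.pole_regions[1]),
        ("cytoplasm", cell.cyto_region),
    ):
        labels[region[:, 0], region[:, 1]] = REGION_LABELS[name]
    tifffile.imwrite(str(path), labels)


def _regions_from_frame(df: pd.DataFrame) -> dict[str, np.ndarray]:
    regions = {}
    for name in REGION_LABELS:
        sub = df[df["region"] == name]
        if sub.empty:
            raise ValueError(f"region {name!r} missing from region table")
        regions[name] = sub[["row", "col"]].to_numpy(dtype=np.intp)
    return regions


def read_cell_image(image_path, regions_path, cell_id: str = "cell") -> CellImage:
    """Assemble a CellImage from an intensity TIFF and a region CSV/TIFF.

    The cell mask is taken as the union of all labelled regions plus every
    nonzero-labelled pixel when a label TIFF is given; with a region CSV the
    mask is the union of the three regions (sufficient for measurement,
    which only touches region pixels).
    """
    intensity = read_image_tiff(image_path)
    regions_path = Path(regions_path)
    if regions_path.suffix.lower() in (".tif", ".tiff"):
        labels = tifffile.imread(str(regions_path))
        regions = {
            name: np.stack(np.nonzero(labels == lab), axis=1)
            for name, lab in REGION_LABELS.items()
        }
    else:
        regions = _regions_from_frame(pd.read_csv(regions_path))
    mask = np.zeros(intensity.shape, dtype=bool)
    for region in regions.values():
        mask[region[:, 0], region[:, 1]] = True
    return CellImage(
        intensity=intensity,
        cell_mask=mask,
        pole_regions=(regions["pole_1"], regions["pole_2"]),
        cyto_region=regions["cytoplasm"],
        cell_id=cell_id,
    )


# --- tracks ----------------------------------------------------------------


def write_tracks_csv(path, tracks: list[Trajectory]) -> None:
    frames = []
    for traj in tracks:
        for i, (pos, angle) in enumerate(zip(traj.positions, traj.axis_angle)):
            frames.append(
                {
                    "frame": i,
                    "cell_id": traj.cell_id,
                    "x": pos[0],
                    "y": pos[1],
                    "axis_angle_rad": angle,
                }
            )
    pd.DataFrame(frames, columns=["frame", "cell_id", "x", "y", "axis_angle_rad"]).to_csv(
        path, index=False
    )


def read_tracks_csv(path, frame_interval_s: float = 30.0) -> list[Trajectory]:
    df = pd.read_csv(path)
    required = {"frame", "cell_id", "x", "y", "axis_angle_rad"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"track file {path} lacks columns: {sorted(missing)}")
    tracks = []
    for cell_id, sub in df.groupby("cell_id", sort=True):
        sub = sub.sort_values("frame")
        tracks.append(
            Trajectory(
                cell_id=str(cell_id),
                positions=sub[["x", "y"]].to_numpy(),
                axis_angle=sub["axis_angle_rad"].to_numpy(),
                frame_interval_s=frame_interval_s,
            )
        )
    return tracks


# --- sequences and tables --------------------------------------------------


def write_fasta(path, records) -> None:
    SeqIO.write(records, str(path), "fasta")


def read_alignment_fasta(path) -> list[str]:
    seqs = [str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")]
    if not seqs:
        raise ValueError(f"no sequences in {path}")
    return seqs


DOMAIN_HEADER_COMMENT = "# coordinates: 1-based inclusive residue positions\n"


def write_domain_hits_tsv(path, hits: list[DomainHit]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(DOMAIN_HEADER_COMMENT)
        pd.DataFrame(
            [
                {
                    "protein": h.protein,
                    "domain": h.domain,
                    "start": h.start,
                    "end": h.end,
                    "score": h.score,
                }
                for h in hits
            ]
        ).to_csv(fh, sep="\t", index=False)


def read_domain_hits_tsv(path) -> list[DomainHit]:
    df = pd.read_csv(path, sep="\t", comment="#")
    return [
        DomainHit(
            protein=str(r.protein),
            domain=str(r.domain),
            start=int(r.start),
            end=int(r.end),
            score=float(r.score),
        )
        for r in df.itertuples()
    ]


def write_presence_absence_tsv(path, table: CooccurrenceTable) -> None:
    out = table.data.astype(int)
    out.index.name = "genome"
    out.to_csv(path, sep="\t")


def read_presence_absence_tsv(path) -> CooccurrenceTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    bad = ~df.isin([0, 1]).all()
    if bad.any():
        raise ValueError(
            f"non-binary values in markers: {list(df.columns[bad])}"
        )
    return CooccurrenceTable(df.astype(bool))


# --- result tables and metadata -------------------------------------------


def write_measurements_csv(path, measurements: list[PolarMeasurement]) -> None:
    pd.DataFrame(
        [
            {
                "cell_id": m.cell_id,
                "I_pole1": m.corrected_I[0],
                "I_pole2": m.corrected_I[1],
                "ratio": m.ratio if m.ratio is not None else "",
                "pattern": m.pattern.value if m.pattern is not None else "",
            }
            for m in measurements
        ]
    ).to_csv(path, index=False)


def pattern_summary_dict(summary: PatternSummary) -> dict:
    return {
        "n": summary.n_cells,
        "patterns": {
            p.value: {"count": summary.counts[p], "percent": summary.percentages[p]}
            for p in summary.counts
        },
    }


def reversal_summary_dict(summary: ReversalSummary) -> dict:
    return {
        "n_cells": summary.n_cells,
        "mean": summary.mean,
        "p10": summary.p10,
        "p25": summary.p25,
        "p75": summary.p75,
        "p90": summary.p90,
        "outliers": summary.outliers.tolist(),
        "percentile_definition": "linear interpolation between order statistics",
    }


def file_digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_metadata(path, command: str, parameters: dict, inputs: list | None = None,
                   seed: int | None = None) -> None:
    """Provenance JSON: version, seed, parameters and input digests."""
    meta = {
        "tool": "polarity-lapse",
        "version": __version__,
        "command": command,
        "seed": seed,
        "parameters": parameters,
        "inputs": [
            {"path": str(p), "sha256": file_digest(p)} for p in (inputs or [])
        ],
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
        fh.write("\n")
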