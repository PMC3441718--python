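"""Sequence-level tabulations: logos, linker composition, domain
architectures, and genome co-occurrence patterns.

Four small analyses commonly run downstream of homology searches:

* per-column information content of a protein alignment (WebLogo-style
  sequence logo data: R = log2(20) − (H + e_n), letter height = f_a·R);
* amino-acid composition of a sequence set pooled by physicochemical
  class (hydrophobic / polar uncharged / acidic / basic / special by
  default);
* resolution of overlapping domain hits into a final architecture by
  greedily keeping the highest-scoring model;
* collapsing a genome × marker presence/absence matrix into co-occurrence
  patterns with counts, plus conditional queries ("of the genomes with
  MglA and MglB, how many also encode RomR?").
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AMINO_ACIDS",
    "DEFAULT_CLASS_MAP",
    "AlignmentColumnProfile",
    "CompositionProfile",
    "DomainHit",
    "CooccurrenceTable",
    "column_information",
    "alignment_logo",
    "composition_by_class",
    "resolve_architecture",
    "tabulate_cooccurrence",
    "query_cooccurrence",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP_CHARS = frozenset("-.")

# Physicochemical grouping used for linker-composition profiles.  The field
# has no single canonical partition; this five-class map is a common one and
# can be overridden with any residue -> class mapping.
DEFAULT_CLASS_MAP: dict[str, str] = {
    **{aa: "hydrophobic" for aa in "AVLIMFWYC"},
    **{aa: "polar_uncharged" for aa in "STNQ"},
    **{aa: "acidic" for aa in "DE"},
    **{aa: "basic" for aa in "KRH"},
    **{aa: "special" for aa in "GP"},
}


@dataclass
class AlignmentColumnProfile:
    """One alignment column: residue frequencies and information content.

    ``n`` counts non-gap residues only.  ``information`` is R in bits,
    0 ≤ R ≤ log2(20); ``letter_heights`` (f_a·R) sum to R.
    """

    frequencies: dict[str, float]
    n: int
    information: float
    letter_heights: dict[str, float]
    position: int = 0


@dataclass
class CompositionProfile:
    """Pooled residue fractions per physicochemical class."""

    class_fractions: dict[str, float]
    n_residues: int
    label: str = ""


@dataclass(frozen=True)
class DomainHit:
    """One domain model hit; start/end are 1-based inclusive residue coords."""

    protein: str
    domain: str
    start: int
    end: int
    score: float

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"{self.protein}/{self.domain}: start {self.start} > end {self.end}"
            )
        if not math.isfinite(self.score):
            raise ValueError(f"{self.protein}/{self.domain}: non-finite score")

    def overlaps(self, other: "DomainHit") -> bool:
        return self.start <= other.end and other.start <= self.end


class CooccurrenceTable:
    """Boolean genome × marker matrix with a fixed marker order."""

    def __init__(self, data: pd.DataFrame):
        if data.index.has_duplicates:
            raise ValueError("genome ids must be unique")
        if data.columns.has_duplicates:
            raise ValueError("marker names must be unique")
        self.data = data.astype(bool)

    @property
    def markers(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_genomes(self) -> int:
        return len(self.data)

    def pattern_strings(self) -> pd.Series:
        """Per-genome presence/absence bit-string in marker order."""
        if self.n_genomes == 0:
            return pd.Series(dtype=str)
        return self.data.astype(int).astype(str).agg("".join, axis=1)


def column_information(
    column: Iterable[str], correct_small_sample: bool = True,
    ambiguous_as_gap: bool = False,
) -> AlignmentColumnProfile:
    """Information content of one alignment column.

    R = log2(20) − (H + e_n) with H the Shannon entropy of the observed
    residue frequencies and e_n = (20−1)/(2·ln2·n) the small-sample
    correction (omitted when ``correct_small_sample`` is False).  Gaps are
    excluded from n.  Ambiguity codes (B, J, Z, X) are rejected unless
    ``ambiguous_as_gap``.  R is clamped at 0 (the correction can push small
    noisy columns negative).
    """
    counts: dict[str, int] = {}
    n = 0
    for i, raw in enumerate(column):
        residue = raw.upper()
        if residue in GAP_CHARS:
            continue
        if residue not in AMINO_ACIDS:
            if ambiguous_as_gap and residue in "BJZX*":
                continue
            raise ValueError(
                f"unknown residue {residue!r} at column entry {i}; "
                "pass ambiguous_as_gap=True to drop ambiguity codes"
            )
        counts[residue] = counts.get(residue, 0) + 1
        n += 1
    if n == 0:
        raise ValueError("all-gap column: information content undefined")
    freqs = {aa: c / n for aa, c in counts.items()}
    entropy = -sum(f * math.log2(f) for f in freqs.values())
    e_n = (len(AMINO_ACIDS) - 1) / (2 * math.log(2) * n) if correct_small_sample else 0.0
    information = max(0.0, math.log2(len(AMINO_ACIDS)) - (entropy + e_n))
    heights = {aa: f * information for aa, f in freqs.items()}
    return AlignmentColumnProfile(
        frequencies=freqs, n=n, information=information, letter_heights=heights
    )


def alignment_logo(
    sequences: Sequence[str], correct_small_sample: bool = True,
    ambiguous_as_gap: bool = False,
) -> pd.DataFrame:
    """Logo table for an aligned sequence set: one row per column.

    Columns: position (1-based), n, R_bits, then per-residue letter heights.
    All-gap columns are flagged (R NaN) and carry zero heights.
    """
    lengths = {len(s) for s in sequences}
    if len(lengths) != 1:
        raise ValueError(f"sequences are not aligned: lengths {sorted(lengths)}")
    (width,) = lengths
    rows = []
    for j in range(width):
        col = [s[j] for s in sequences]
        try:
            prof = column_information(col, correct_small_sample, ambiguous_as_gap)
            row = {"position": j + 1, "n": prof.n, "R_bits": prof.information}
            row.update({aa: prof.letter_heights.get(aa, 0.0) for aa in AMINO_ACIDS})
        except ValueError:
            row = {"position": j + 1, "n": 0, "R_bits": float("nan")}
            row.update({aa: 0.0 for aa in AMINO_ACIDS})
        rows.append(row)
    return pd.DataFrame(rows)


def composition_by_class(
    sequences: Iterable[str],
    class_map: Mapping[str, str] = DEFAULT_CLASS_MAP,
    label: str = "",
) -> CompositionProfile:
    """Pooled amino-acid composition by physicochemical class.

    Residues from all sequences are pooled; gaps are skipped; a residue
    outside the class map raises with its sequence and position.
    """
    counts: dict[str, int] = {}
    total = 0
    any_seq = False
    for si, seq in enumerate(sequences):
        any_seq = True
        for pi, raw in enumerate(seq):
            residue = raw.upper()
            if residue in GAP_CHARS:
                continue
            if residue not in class_map:
                raise ValueError(
                    f"residue {residue!r} at sequence {si}, position {pi + 1} "
                    "is not in the class map"
                )
            cls = class_map[residue]
            counts[cls] = counts.get(cls, 0) + 1
            total += 1
    if not any_seq or total == 0:
        raise ValueError("no residues to profile")
    fractions = {cls: c / total for cls, c in counts.items()}
    return CompositionProfile(class_fractions=fractions, n_residues=total, label=label)


def resolve_architecture(hits: Sequence[DomainHit]) -> list[DomainHit]:
    """Resolve overlapping domain hits into the final architecture.

    Greedy by score: repeatedly accept the highest-scoring remaining hit and
    discard every hit sharing at least one residue with an accepted one.
    Score ties break by earlier start, then lexicographic domain name, so
    the result is deterministic.  Output is sorted by start coordinate.
    """
    proteins = {h.protein for h in hits}
    if len(proteins) > 1:
        raise ValueError(f"hits span multiple proteins: {sorted(proteins)}")
    ordered = sorted(hits, key=lambda h: (-h.score, h.start, h.domain))
    accepted: list[DomainHit] = []
    for hit in ordered:
        if not any(hit.overlaps(a) for a in accepted):
            accepted.append(hit)
    return sorted(accepted, key=lambda h: h.start)


def tabulate_cooccurrence(table: CooccurrenceTable) -> list[tuple[str, int]]:
    """Collapse the genome × marker matrix to (pattern, count) rows.

    Patterns are presence/absence bit-strings in the table's marker order,
    sorted by count descending, ties by bit-string descending.
    """
    patterns = table.pattern_strings()
    if patterns.empty:
        return []
    counts = patterns.value_counts()
    return sorted(
        counts.items(), key=lambda kv: (-kv[1], tuple(-int(b) for b in kv[0]))
    )


def query_cooccurrence(
    table: CooccurrenceTable, require: Sequence[str], also: str | None = None
) -> tuple[int, int | None]:
    """Count genomes with all ``require`` markers, and those also with ``also``.

    With an empty ``require`` set, the first count is the total number of
    genomes.  Returns (n_require, n_also); n_also is None when ``also`` is
    not given.
    """
    for marker in list(require) + ([also] if also else []):
        if marker not in table.data.columns:
            raise ValueError(f"unknown marker {marker!r}")
    sel = pd.Series(True, index=table.data.index)
    for marker in require:
        sel &= table.data[marker]
    n_req = int(sel.sum())
    n_also = int((sel & table.data[also]).sum()) if also else None
    return n_req, n_also
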