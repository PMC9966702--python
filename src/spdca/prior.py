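"""Protein topology annotations and the structural prior masks.

GPCRs are segmented into topology domains (N-terminal, seven
transmembrane helices, intra/extracellular loops, C-terminal).
Coevolutionary signal in transmembrane segments is unreliable — they are
highly conserved, so apparent couplings there are mostly noise — and the
structure prior therefore localizes the convolution to non-TM segments by
default: each protein gets a per-column weight in [0, 1] that multiplies
the evolutionary score matrix before the Gaussian kernel is applied.

Segment tables follow the UniProt topology style: one row per segment
with a label (e.g. "ECL2"), a category, and a 1-based inclusive residue
range.  Hand-copied UniProt topology sections parse directly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

CATEGORIES = ("N-terminal", "C-terminal", "TM", "ICL", "ECL", "other")

#: default prior: everything except transmembrane segments
DEFAULT_INCLUDED = frozenset({"N-terminal", "C-terminal", "ICL", "ECL"})

_CATEGORY_SYNONYMS = {
    "n-terminal": "N-terminal", "nter": "N-terminal", "n-ter": "N-terminal",
    "nterm": "N-terminal", "n": "N-terminal",
    "c-terminal": "C-terminal", "cter": "C-terminal", "c-ter": "C-terminal",
    "cterm": "C-terminal", "c": "C-terminal",
    "tm": "TM", "transmembrane": "TM", "helical": "TM",
    "icl": "ICL", "intracellular": "ICL", "cytoplasmic": "ICL",
    "ecl": "ECL", "extracellular": "ECL",
    "other": "other",
}


class TopologyError(ValueError):
    """Inconsistent segment table."""


def normalize_category(raw: str) -> str:
    key = str(raw).strip().lower()
    if key in _CATEGORY_SYNONYMS:
        return _CATEGORY_SYNONYMS[key]
    raise TopologyError(f"unknown topology category {raw!r}; expected one of {CATEGORIES}")


@dataclass(frozen=True)
class Segment:
    label: str
    category: str   # one of CATEGORIES
    start: int      # 1-based
    end: int        # inclusive


@dataclass
class DomainMap:
    """Non-overlapping topology segments covering a protein of given length.

    Columns not covered by any input segment belong to auto-inserted
    filler segments of category "other".
    """

    protein: str
    segments: list[Segment]
    length: int

    def segment_at(self, pos: int) -> Segment:
        """The segment containing 1-based position ``pos``."""
        if not 1 <= pos <= self.length:
            raise IndexError(f"position {pos} outside protein of length {self.length}")
        for seg in self.segments:
            if seg.start <= pos <= seg.end:
                return seg
        raise AssertionError("segments do not cover the protein")  # pragma: no cover

    def category_vector(self) -> np.ndarray:
        out = np.empty(self.length, dtype=object)
        for seg in self.segments:
            out[seg.start - 1 : seg.end] = seg.category
        return out


def parse_topology(
    table: pd.DataFrame | str | Path, protein: str = "", length: int | None = None
) -> DomainMap:
    """Validate a segment table into a :class:`DomainMap`.

    ``table`` is a TSV path or DataFrame with columns
    (label, category, start, end).  Overlapping segments raise an error
    naming both; gaps between segments are auto-labeled "other".  The
    protein length defaults to the largest segment end.
    """
    if not isinstance(table, pd.DataFrame):
        path = Path(table)
        table = pd.read_csv(path, sep="\t", comment="#")
        protein = protein or path.stem
    required = {"label", "category", "start", "end"}
    if not required.issubset(table.columns):
        raise TopologyError(f"segment table must have columns {sorted(required)}")

    segs = []
    for _, row in table.iterrows():
        start, end = int(row["start"]), int(row["end"])
        if end < start:
            raise TopologyError(f"segment {row['label']!r}: end {end} < start {start}")
        if start < 1:
            raise TopologyError(f"segment {row['label']!r}: start {start} < 1")
        segs.append(Segment(str(row["label"]), normalize_category(row["category"]), start, end))
    segs.sort(key=lambda s: s.start)
    for prev, cur in zip(segs, segs[1:]):
        if cur.start <= prev.end:
            raise TopologyError(
                f"segments {prev.label!r} ({prev.start}-{prev.end}) and "
                f"{cur.label!r} ({cur.start}-{cur.end}) overlap"
            )
    if length is None:
        length = max((s.end for s in segs), default=0)
    if segs and segs[-1].end > length:
        raise TopologyError(
            f"segment {segs[-1].label!r} ends at {segs[-1].end} beyond length {length}"
        )

    # fill uncovered stretches with "other"
    full: list[Segment] = []
    cursor = 1
    for seg in segs:
        if seg.start > cursor:
            full.append(Segment("other", "other", cursor, seg.start - 1))
        full.append(seg)
        cursor = seg.end + 1
    if cursor <= length:
        full.append(Segment("other", "other", cursor, length))
    return DomainMap(protein=protein, segments=full, length=length)


def write_topology(dm: DomainMap, path: str | Path) -> None:
    pd.DataFrame(
        [
            {"label": s.label, "category": s.category, "start": s.start, "end": s.end}
            for s in dm.segments
        ]
    ).to_csv(path, sep="\t", index=False)


@dataclass
class PriorMask:
    """Per-column weights in [0, 1] localizing the convolution."""

    weights: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.min(initial=0.0) < 0.0 or self.weights.max(initial=0.0) > 1.0:
            raise ValueError("prior mask weights must lie in [0, 1]")

    @classmethod
    def ones(cls, length: int) -> "PriorMask":
        return cls(np.ones(length), provenance="uninformative")


def build_prior_mask(
    dm: DomainMap, included_categories: frozenset | set = DEFAULT_INCLUDED
) -> PriorMask:
    """Binary mask: 1 on columns in included categories, 0 elsewhere.

    The default excludes only TM segments, where coevolutionary methods
    perform poorly due to high conservation.
    """
    included = {normalize_category(c) for c in included_categories}
    weights = np.zeros(dm.length)
    for seg in dm.segments:
        if seg.category in included:
            weights[seg.start - 1 : seg.end] = 1.0
    if included and weights.sum() == 0:
        warnings.warn(
            f"prior mask for {dm.protein or 'protein'} is all zeros; "
            "the convolved map will vanish", stacklevel=2,
        )
    if not included:
        warnings.warn("empty category set: all-zeros mask", stacklevel=2)
    return PriorMask(weights, provenance=f"categories={sorted(included)}")


def write_mask(mask: PriorMask, path: str | Path) -> None:
    pd.DataFrame(
        {"position": np.arange(1, mask.weights.size + 1), "weight": mask.weights}
    ).to_csv(path, sep="\t", index=False)


def read_mask(path: str | Path) -> PriorMask:
    df = pd.read_csv(path, sep="\t")
    return PriorMask(df["weight"].to_numpy(), provenance=str(path))


def packaged_topology(receptor: str) -> DomainMap:
    """Load one of the packaged GPCR topology fixtures (e.g. "A2aR", "D2R")."""
    from importlib.resources import files

    path = files("spdca.data.topologies").joinpath(f"{receptor}.tsv")
    if not path.is_file():
        raise FileNotFoundError(f"no packaged topology for {receptor!r}")
    import io

    df = pd.read_csv(io.StringIO(path.read_text()), sep="\t", comment="#")
    return parse_topology(df, protein=receptor)
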