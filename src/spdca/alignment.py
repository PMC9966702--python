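"""Reading, filtering and species-wise pairing of ortholog alignments.

Inter-protein coevolution needs a *concatenated* multiple sequence
alignment (cMSA): for every species present in the ortholog alignments of
both proteins, the two aligned sequences are joined end to end.  This
module provides the plumbing around that step — FASTA parsing, the
identity-band ortholog filter (sequences too close to the reference carry
no evolutionary signal, sequences too far are unreliable orthologs),
best-isoform selection, and the concatenation itself.

Coordinates are 1-based and ranges inclusive throughout the package,
matching the "R291-S412" style of residue-range notation.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: 20 amino acids followed by the gap symbol; the gap is a bona fide
#: Potts state downstream (common plmDCA practice).
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY-"

GAP = "-"


class AlignmentError(ValueError):
    """Malformed or inconsistent alignment input."""


@dataclass
class Alignment:
    """An aligned set of ortholog sequences for one protein.

    ``rows`` is an (n_sequences, length) array of single-character symbols
    restricted to :data:`AA_ALPHABET`; unknown symbols are mapped to the
    gap at parse time and counted in ``n_unknown_mapped``.
    """

    rows: np.ndarray
    species_ids: list[str]
    name: str = ""
    n_unknown_mapped: int = 0

    @property
    def n_rows(self) -> int:
        return self.rows.shape[0]

    @property
    def length(self) -> int:
        return self.rows.shape[1]

    def sequence(self, i: int) -> str:
        return "".join(self.rows[i])

    def __post_init__(self) -> None:
        self.rows = np.asarray(self.rows, dtype="U1")
        if self.rows.ndim != 2:
            raise AlignmentError("alignment rows must form a 2-D matrix")
        if len(self.species_ids) != self.rows.shape[0]:
            raise AlignmentError(
                f"{len(self.species_ids)} species ids for {self.rows.shape[0]} rows"
            )


@dataclass
class PairedAlignment:
    """Species-matched concatenation of two protein alignments.

    Each row is the protein-A row followed by the protein-B row for one
    species; ``len_a`` and ``len_b`` record the block boundary so the
    inter-protein part of any downstream score matrix can be recovered.
    """

    rows: np.ndarray
    species_ids: list[str]
    len_a: int
    len_b: int
    name_a: str = ""
    name_b: str = ""
    n_dropped_a: int = 0
    n_dropped_b: int = 0

    @property
    def n_rows(self) -> int:
        return self.rows.shape[0]

    @property
    def length(self) -> int:
        return self.rows.shape[1]

    def __post_init__(self) -> None:
        self.rows = np.asarray(self.rows, dtype="U1")
        if self.rows.ndim != 2 or self.rows.shape[1] != self.len_a + self.len_b:
            raise AlignmentError("paired rows must have length len_a + len_b")

    def block_a(self) -> Alignment:
        return Alignment(self.rows[:, : self.len_a], list(self.species_ids), self.name_a)

    def block_b(self) -> Alignment:
        return Alignment(self.rows[:, self.len_a :], list(self.species_ids), self.name_b)


def _clean_symbols(seq: str) -> tuple[np.ndarray, int]:
    """Uppercase, map '.' to '-' and unknown symbols to gap; count the latter."""
    arr = np.array(list(seq.upper().replace(".", GAP)), dtype="U1")
    known = np.isin(arr, list(AA_ALPHABET))
    n_unknown = int((~known).sum())
    arr[~known] = GAP
    return arr, n_unknown


def read_alignment(
    path: str | Path,
    name: str = "",
    species_regex: str | None = None,
) -> Alignment:
    """Read an aligned FASTA file into an :class:`Alignment`.

    The species id is the first whitespace-delimited token of the header
    by default; ``species_regex`` (first capture group) overrides that for
    other header dialects.

    Raises :class:`AlignmentError` on an empty file or ragged rows (the
    error names the offending record).
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise AlignmentError(f"{path}: no FASTA records found")

    pattern = re.compile(species_regex) if species_regex else None
    rows, species = [], []
    n_unknown = 0
    length = None
    for k, rec in enumerate(records, start=1):
        arr, n = _clean_symbols(str(rec.seq))
        if length is None:
            length = arr.size
        elif arr.size != length:
            raise AlignmentError(
                f"{path}: record {k} ({rec.id!r}) has length {arr.size}, "
                f"expected {length}"
            )
        if pattern is not None:
            m = pattern.search(rec.description)
            if not m:
                raise AlignmentError(
                    f"{path}: species regex matched nothing in header {rec.description!r}"
                )
            species.append(m.group(1))
        else:
            species.append(rec.id.split()[0])
        rows.append(arr)
        n_unknown += n
    return Alignment(np.vstack(rows), species, name or path.stem, n_unknown)


def write_alignment(aln: Alignment, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(aln.sequence(i)), id=sp, description="")
        for i, sp in enumerate(aln.species_ids)
    ]
    SeqIO.write(records, str(path), "fasta")


def fractional_identity(row: np.ndarray, reference: np.ndarray) -> float:
    """Identity over columns where neither sequence is gapped; NaN if none."""
    both = (row != GAP) & (reference != GAP)
    n = int(both.sum())
    if n == 0:
        return float("nan")
    return float((row[both] == reference[both]).sum() / n)


def _as_row(reference: str | np.ndarray, length: int) -> np.ndarray:
    ref = np.array(list(reference), dtype="U1") if isinstance(reference, str) else np.asarray(reference, dtype="U1")
    if ref.size != length:
        raise AlignmentError(
            f"reference length {ref.size} does not match alignment length {length}; "
            "the reference must be given on alignment coordinates"
        )
    return ref


def filter_by_similarity(
    aln: Alignment,
    reference: str | np.ndarray,
    min_frac: float = 0.70,
    max_frac: float = 0.90,
) -> Alignment:
    """Keep rows whose identity to ``reference`` lies in [min_frac, max_frac].

    The identity band removes near-duplicates of the reference (no
    divergence signal) and distant or spurious orthologs.  All-gap rows
    (undefined identity) are dropped with a warning.  An empty result is
    returned (with a warning), not raised.
    """
    if not (0.0 <= min_frac <= max_frac <= 1.0):
        raise ValueError(f"invalid identity bounds [{min_frac}, {max_frac}]")
    ref = _as_row(reference, aln.length)
    ids = np.array([fractional_identity(r, ref) for r in aln.rows])
    undefined = np.isnan(ids)
    if undefined.any():
        warnings.warn(
            f"{int(undefined.sum())} row(s) share no ungapped column with the "
            "reference; dropped", stacklevel=2,
        )
    keep = ~undefined & (ids >= min_frac) & (ids <= max_frac)
    if not keep.any():
        warnings.warn(
            f"identity filter [{min_frac}, {max_frac}] removed every row of "
            f"{aln.name or 'alignment'}", stacklevel=2,
        )
        return Alignment(np.empty((0, aln.length), dtype="U1"), [], aln.name)
    return Alignment(
        aln.rows[keep],
        [sp for sp, k in zip(aln.species_ids, keep) if k],
        aln.name,
        aln.n_unknown_mapped,
    )


def select_best_isoform(aln: Alignment, reference: str | np.ndarray) -> Alignment:
    """Keep, per species, the single row most identical to ``reference``.

    Ties are broken by first occurrence in the file.  Rows with undefined
    identity compare as -inf (kept only if the species has nothing else).
    """
    ref = _as_row(reference, aln.length)
    best: dict[str, tuple[float, int]] = {}
    order: list[str] = []
    for i, sp in enumerate(aln.species_ids):
        ident = fractional_identity(aln.rows[i], ref)
        score = float("-inf") if np.isnan(ident) else ident
        if sp not in best:
            best[sp] = (score, i)
            order.append(sp)
        elif score > best[sp][0]:
            best[sp] = (score, i)
    idx = [best[sp][1] for sp in order]
    return Alignment(aln.rows[idx], order, aln.name, aln.n_unknown_mapped)


def concatenate_by_species(a: Alignment, b: Alignment) -> PairedAlignment:
    """Join two alignments species-by-species into a paired alignment.

    Only species present in both inputs are kept, in protein-A row order;
    species unique to one side are counted in ``n_dropped_a/b``.  Requires
    unique species ids in each input (run :func:`select_best_isoform`
    first if needed).
    """
    for aln in (a, b):
        if len(set(aln.species_ids)) != aln.n_rows:
            raise AlignmentError(
                f"duplicate species ids in {aln.name or 'alignment'}; "
                "select one isoform per species first"
            )
    index_b = {sp: i for i, sp in enumerate(b.species_ids)}
    shared = [sp for sp in a.species_ids if sp in index_b]
    if not shared:
        raise AlignmentError(
            f"no species shared between {a.name or 'A'} and {b.name or 'B'}"
        )
    rows = np.hstack(
        [
            a.rows[[a.species_ids.index(sp) for sp in shared]],
            b.rows[[index_b[sp] for sp in shared]],
        ]
    )
    return PairedAlignment(
        rows,
        shared,
        len_a=a.length,
        len_b=b.length,
        name_a=a.name,
        name_b=b.name,
        n_dropped_a=a.n_rows - len(shared),
        n_dropped_b=b.n_rows - len(shared),
    )


def write_paired(pa: PairedAlignment, fasta_path: str | Path) -> None:
    """Write a paired alignment as FASTA plus a `.meta.tsv` sidecar.

    The sidecar records ``len_a``/``len_b`` (the block boundary cannot be
    recovered from the FASTA alone) and the species list.
    """
    fasta_path = Path(fasta_path)
    records = [
        SeqRecord(Seq("".join(pa.rows[i])), id=sp, description="")
        for i, sp in enumerate(pa.species_ids)
    ]
    SeqIO.write(records, str(fasta_path), "fasta")
    meta = fasta_path.with_suffix(fasta_path.suffix + ".meta.tsv")
    with open(meta, "w") as fh:
        fh.write(f"len_a\t{pa.len_a}\n")
        fh.write(f"len_b\t{pa.len_b}\n")
        fh.write(f"name_a\t{pa.name_a}\n")
        fh.write(f"name_b\t{pa.name_b}\n")
        for sp in pa.species_ids:
            fh.write(f"species\t{sp}\n")


def read_paired(fasta_path: str | Path) -> PairedAlignment:
    """Read a paired alignment written by :func:`write_paired`."""
    fasta_path = Path(fasta_path)
    meta_path = fasta_path.with_suffix(fasta_path.suffix + ".meta.tsv")
    if not meta_path.exists():
        raise AlignmentError(f"missing sidecar metadata file {meta_path}")
    meta: dict[str, str] = {}
    for line in meta_path.read_text().splitlines():
        key, _, val = line.partition("\t")
        if key != "species":
            meta[key] = val
    aln = read_alignment(fasta_path)
    return PairedAlignment(
        aln.rows,
        aln.species_ids,
        len_a=int(meta["len_a"]),
        len_b=int(meta["len_b"]),
        name_a=meta.get("name_a", ""),
        name_b=meta.get("name_b", ""),
    )
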