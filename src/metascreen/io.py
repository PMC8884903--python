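"""Readers, writers and FASTQ quantification for pooled CRISPR screen data.

The on-disk dialects are deliberately pinned so that every artifact
round-trips byte-identically:

* library CSV with header ``sgrna_id,spacer,gene``;
* sample sheet TSV with header
  ``sample_id\tcompartment\torgan\tsubject_id\tweek``;
* count matrix TSV whose first column is ``sgrna_id`` and whose remaining
  columns are sample ids, with integer cells.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

COMPARTMENTS: tuple[str, ...] = (
    "preimplant",
    "primary",
    "recurrent",
    "blood",
    "metastasis",
)
ORGANS: tuple[str, ...] = ("lung", "liver", "spleen", "brain", "kidney")

_SPACER_ALPHABET = frozenset("ACGT")


@dataclass(frozen=True)
class LibraryDesign:
    """sgRNA library: unique guide ids, fixed-length spacers, gene symbols.

    The gene map defines the resolution of every downstream call: a gene is
    only observable through the guides that target it.
    """

    frame: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        f = self.frame
        required = ["sgrna_id", "spacer", "gene"]
        missing = [c for c in required if c not in f.columns]
        if missing:
            raise ValueError(f"library is missing columns: {missing}")
        dup = f["sgrna_id"][f["sgrna_id"].duplicated()]
        if len(dup):
            raise ValueError(f"duplicate sgrna_id: {dup.iloc[0]!r}")
        lengths = f["spacer"].str.len().unique()
        if len(f) and len(lengths) != 1:
            raise ValueError(
                f"spacers must share one length, found lengths {sorted(lengths)}"
            )
        for row_number, spacer in enumerate(f["spacer"], start=1):
            if not _SPACER_ALPHABET.issuperset(spacer):
                raise ValueError(
                    f"non-ACGT spacer at row {row_number}: {spacer!r}"
                )
        if len(f) == 0:
            raise ValueError("library is empty")
        object.__setattr__(self, "frame", f.reset_index(drop=True))

    @property
    def sgrna_ids(self) -> pd.Index:
        return pd.Index(self.frame["sgrna_id"])

    @property
    def genes(self) -> pd.Index:
        return pd.Index(pd.unique(self.frame["gene"]))

    @property
    def spacer_length(self) -> int:
        return int(self.frame["spacer"].str.len().iloc[0])

    def sgrnas_per_gene(self) -> pd.Series:
        """Number of guides targeting each gene (the library's ``s``)."""
        return self.frame.groupby("gene", sort=False).size()

    def gene_of(self) -> pd.Series:
        """sgrna_id -> gene symbol mapping as a Series."""
        return self.frame.set_index("sgrna_id")["gene"]

    def __len__(self) -> int:
        return len(self.frame)


@dataclass(frozen=True)
class SampleSheet:
    """Sample annotations: compartment class, organ (metastases only), mouse, week."""

    frame: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        f = self.frame
        required = ["sample_id", "compartment", "organ", "subject_id", "week"]
        missing = [c for c in required if c not in f.columns]
        if missing:
            raise ValueError(f"sample sheet is missing columns: {missing}")
        dup = f["sample_id"][f["sample_id"].duplicated()]
        if len(dup):
            raise ValueError(f"duplicate sample_id: {dup.iloc[0]!r}")
        bad = set(f["compartment"]) - set(COMPARTMENTS)
        if bad:
            raise ValueError(f"unknown compartment(s): {sorted(bad)}")
        organ = f["organ"].fillna("")
        is_met = f["compartment"] == "metastasis"
        missing_organ = f.loc[is_met & (organ == ""), "sample_id"]
        if len(missing_organ):
            raise ValueError(
                f"metastasis sample without organ: {missing_organ.iloc[0]!r}"
            )
        stray = f.loc[~is_met & (organ != ""), "sample_id"]
        if len(stray):
            raise ValueError(
                f"organ set on non-metastasis sample: {stray.iloc[0]!r}"
            )
        bad_organ = set(organ[is_met]) - set(ORGANS)
        if bad_organ:
            raise ValueError(f"unknown organ(s): {sorted(bad_organ)}")
        if (f["week"].astype(int) < 0).any():
            raise ValueError("week must be a nonnegative integer")
        f = f.assign(organ=organ, week=f["week"].astype(int)).reset_index(drop=True)
        object.__setattr__(self, "frame", f)

    @property
    def sample_ids(self) -> pd.Index:
        return pd.Index(self.frame["sample_id"])

    def samples_in(self, compartment: str, organ: str | None = None) -> list[str]:
        f = self.frame
        mask = f["compartment"] == compartment
        if organ is not None:
            mask &= f["organ"] == organ
        return f.loc[mask, "sample_id"].tolist()

    def compartments_present(self) -> list[str]:
        present = set(self.frame["compartment"])
        return [c for c in COMPARTMENTS if c in present]

    def organs_present(self) -> list[str]:
        met = self.frame[self.frame["compartment"] == "metastasis"]
        present = set(met["organ"])
        return [o for o in ORGANS if o in present]

    def __len__(self) -> int:
        return len(self.frame)


# ---------------------------------------------------------------------------
# readers / writers


def read_library(path: str | Path) -> LibraryDesign:
    frame = pd.read_csv(path, dtype=str)
    return LibraryDesign(frame)


def write_library(lib: LibraryDesign, path: str | Path) -> None:
    lib.frame.to_csv(path, index=False)


def read_sample_sheet(path: str | Path) -> SampleSheet:
    frame = pd.read_csv(
        path, sep="\t", dtype={"sample_id": str, "compartment": str,
                               "organ": str, "subject_id": str, "week": int},
        keep_default_na=False,
    )
    return SampleSheet(frame)


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    sheet.frame.to_csv(path, sep="\t", index=False)


def read_counts(
    path: str | Path,
    lib: LibraryDesign | None = None,
    sheet: SampleSheet | None = None,
) -> pd.DataFrame:
    """Read an sgRNA x sample count matrix (TSV, first column ``sgrna_id``).

    If a library or sample sheet is given, row/column labels must be subsets
    of the corresponding design.
    """
    counts = pd.read_csv(path, sep="\t", index_col="sgrna_id")
    validate_counts(counts, lib=lib, sheet=sheet)
    return counts


def validate_counts(
    counts: pd.DataFrame,
    lib: LibraryDesign | None = None,
    sheet: SampleSheet | None = None,
) -> None:
    if counts.index.has_duplicates:
        raise ValueError("duplicate sgrna_id rows in count matrix")
    if counts.columns.has_duplicates:
        raise ValueError("duplicate sample columns in count matrix")
    if not all(np.issubdtype(dt, np.integer) for dt in counts.dtypes):
        raise ValueError("count matrix cells must be integers")
    if (counts.to_numpy() < 0).any():
        raise ValueError("negative counts are not allowed")
    if lib is not None:
        stray = counts.index.difference(lib.sgrna_ids)
        if len(stray):
            raise ValueError(f"count rows not in library: {list(stray[:3])}")
    if sheet is not None:
        stray = counts.columns.difference(sheet.sample_ids)
        if len(stray):
            raise ValueError(f"count columns not in sample sheet: {list(stray[:3])}")


def write_counts(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t", index_label="sgrna_id")


# ---------------------------------------------------------------------------
# FASTQ quantification


def _open_maybe_gzip(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _iter_fastq(path: str | Path) -> Iterator[str]:
    """Yield read sequences; re-raise parse errors with the record index."""
    index = 0
    with _open_maybe_gzip(path) as handle:
        it = FastqGeneralIterator(handle)
        while True:
            try:
                _title, seq, _qual = next(it)
            except StopIteration:
                return
            except ValueError as exc:
                raise ValueError(f"unreadable FASTQ record {index}: {exc}") from exc
            yield seq
            index += 1


def _hamming1_neighbors(spacer: str) -> Iterator[str]:
    for i, base in enumerate(spacer):
        for alt in "ACGT":
            if alt != base:
                yield spacer[:i] + alt + spacer[i + 1 :]


_AMBIGUOUS = object()


def build_spacer_index(lib: LibraryDesign, max_mismatch: int):
    """Exact and (optionally) Hamming-1 lookup tables for spacer assignment.

    A key claimed by two or more guides maps to an ambiguity sentinel: reads
    landing there are never assigned.
    """
    exact: dict[str, object] = {}
    for sgrna_id, spacer in zip(lib.frame["sgrna_id"], lib.frame["spacer"]):
        exact[spacer] = _AMBIGUOUS if spacer in exact else sgrna_id
    near: dict[str, object] = {}
    if max_mismatch == 1:
        for sgrna_id, spacer in zip(lib.frame["sgrna_id"], lib.frame["spacer"]):
            for variant in _hamming1_neighbors(spacer):
                if variant in near and near[variant] != sgrna_id:
                    near[variant] = _AMBIGUOUS
                else:
                    near.setdefault(variant, sgrna_id)
    return exact, near


def quantify_sequences(
    seqs: Sequence[str] | Iterator[str],
    lib: LibraryDesign,
    offset: int = 0,
    max_mismatch: int = 0,
) -> tuple[pd.Series, int]:
    """Count spacer occurrences in an iterable of read sequences.

    Each read contributes to at most one guide: the exact match of the L-mer
    at ``offset``, else — when ``max_mismatch=1`` — the unique guide at
    Hamming distance 1. Reads matching zero or several guides, and reads too
    short to carry the L-mer, are tallied as unassigned.
    """
    if max_mismatch not in (0, 1):
        raise ValueError("max_mismatch must be 0 or 1")
    if offset < 0:
        raise ValueError("offset must be nonnegative")
    L = lib.spacer_length
    exact, near = build_spacer_index(lib, max_mismatch)
    counts: dict[str, int] = dict.fromkeys(lib.frame["sgrna_id"], 0)
    unassigned = 0
    end = offset + L
    for seq in seqs:
        if len(seq) < end:
            unassigned += 1
            continue
        kmer = seq[offset:end].upper()
        hit = exact.get(kmer)
        if hit is None and max_mismatch == 1:
            hit = near.get(kmer)
        if hit is None or hit is _AMBIGUOUS:
            unassigned += 1
        else:
            counts[hit] += 1
    return pd.Series(counts, name="count"), unassigned


def quantify_fastq(
    fastq: str | Path,
    lib: LibraryDesign,
    offset: int = 0,
    max_mismatch: int = 0,
) -> tuple[pd.Series, int]:
    """Quantify one sample's FASTQ into a per-sgRNA count column.

    Returns ``(counts, unassigned)`` with
    ``counts.sum() + unassigned == number of reads``.
    """
    return quantify_sequences(_iter_fastq(fastq), lib, offset, max_mismatch)


def write_fastq(seqs: Sequence[str], path: str | Path, prefix: str = "read") -> None:
    """Write plain 4-line FASTQ records with uniform dummy qualities."""
    with open(path, "w") as out:
        for i, seq in enumerate(seqs):
            out.write(f"@{prefix}{i}\n{seq}\n+\n{'I' * len(seq)}\n")
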