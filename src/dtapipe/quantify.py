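"""Count-matrix container, library bookkeeping, and RPKM normalization.

The raw input of the pipeline is a gene x library table of unambiguous
tag counts for the seven-library abscission time-course design
(untreated controls CK0..CK3 and ethephon-treated ETH1..ETH3), together
with per-gene transcript lengths.  This module validates and houses that
table, computes the per-library read-accounting statistics (totals,
mapped and unique-match reads with their percentages), and normalizes
counts to RPKM (reads per kilobase of transcript per million assigned
reads).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .formatting import percentage

#: The seven pooled-replicate libraries of the abscission time course.
DEFAULT_LIBRARIES: tuple[str, ...] = (
    "CK0", "CK1", "CK2", "CK3", "ETH1", "ETH2", "ETH3",
)

GENE_COLUMN = "gene_id"
LENGTH_COLUMN = "length_bp"


class CountMatrixError(ValueError):
    """Raised when a count table violates the container invariants."""


@dataclass(frozen=True)
class CountMatrix:
    """Gene x library unambiguous tag counts plus gene lengths.

    Parameters
    ----------
    counts
        Integer DataFrame indexed by gene id, one column per library.
    lengths
        Transcript length in bp per gene, same index as ``counts``.
    """

    counts: pd.DataFrame
    lengths: pd.Series

    def __post_init__(self) -> None:
        counts, lengths = self.counts, self.lengths
        if counts.index.has_duplicates:
            dupes = counts.index[counts.index.duplicated()].unique().tolist()
            raise CountMatrixError(f"duplicate gene ids: {dupes[:5]}")
        if counts.shape[0] == 0 or counts.shape[1] == 0:
            raise CountMatrixError("count matrix must have >= 1 gene and >= 1 library")
        values = counts.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise CountMatrixError("counts must be numeric")
        if np.any(~np.isfinite(values)):
            raise CountMatrixError("counts contain missing or non-finite values")
        if np.any(values != np.floor(values)):
            raise CountMatrixError("counts must be integers")
        if np.any(values < 0):
            raise CountMatrixError("counts must be non-negative")
        if not lengths.index.equals(counts.index):
            raise CountMatrixError("lengths index must match the gene universe")
        if np.any(lengths.to_numpy() < 1):
            raise CountMatrixError("gene lengths must be >= 1 bp")
        object.__setattr__(self, "counts", counts.astype(np.int64))
        object.__setattr__(self, "lengths", lengths.astype(np.int64))

    # -- accessors ---------------------------------------------------------
    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def libraries(self) -> tuple[str, ...]:
        return tuple(self.counts.columns)

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    def totals(self) -> pd.Series:
        """Per-library total assigned counts (the RPKM denominators N)."""
        return self.counts.sum(axis=0)

    def require_libraries(self, labels: Iterable[str]) -> None:
        missing = [lab for lab in labels if lab not in self.counts.columns]
        if missing:
            raise CountMatrixError(f"missing libraries: {missing}")

    def expressed_genes(self) -> pd.Index:
        """Genes with >= 1 assigned read in >= 1 library.

        Used as the enrichment background universe: unexpressed genes
        cannot be responsive and would inflate N.
        """
        return self.counts.index[self.counts.sum(axis=1) > 0]

    # -- IO ----------------------------------------------------------------
    @classmethod
    def from_frame(cls, frame: pd.DataFrame,
                   libraries: Sequence[str] | None = None) -> "CountMatrix":
        """Build from a flat table with gene_id / length_bp / library columns."""
        if GENE_COLUMN not in frame.columns or LENGTH_COLUMN not in frame.columns:
            raise CountMatrixError(
                f"table must have '{GENE_COLUMN}' and '{LENGTH_COLUMN}' columns")
        labels = tuple(libraries) if libraries is not None else DEFAULT_LIBRARIES
        missing = [lab for lab in labels if lab not in frame.columns]
        if missing:
            raise CountMatrixError(f"missing library columns: {missing}")
        indexed = frame.set_index(GENE_COLUMN)
        return cls(counts=indexed[list(labels)], lengths=indexed[LENGTH_COLUMN])

    @classmethod
    def from_tsv(cls, path: str | Path,
                 libraries: Sequence[str] | None = None) -> "CountMatrix":
        try:
            frame = pd.read_csv(path, sep="\t")
        except Exception as exc:  # pragma: no cover - pandas message passthrough
            raise CountMatrixError(f"malformed count TSV {path}: {exc}") from exc
        return cls.from_frame(frame, libraries=libraries)

    def to_tsv(self, path: str | Path) -> None:
        out = self.counts.copy()
        out.insert(0, LENGTH_COLUMN, self.lengths)
        out.index.name = GENE_COLUMN
        out.to_csv(path, sep="\t")


def load_counts(path: str | Path,
                libraries: Sequence[str] | None = None) -> CountMatrix:
    """Load and validate a count TSV (gene_id, length_bp, one column per library)."""
    return CountMatrix.from_tsv(path, libraries=libraries)


# ---------------------------------------------------------------------------
# Library bookkeeping (read-accounting statistics)
# ---------------------------------------------------------------------------

ACCOUNTING_COLUMNS = ("total_reads", "mapped_reads", "unique_match_reads")


class LibraryStatsError(ValueError):
    """Raised for inconsistent read-accounting integers."""


def library_stats(accounting: pd.DataFrame | Mapping[str, Sequence[int]],
                  ) -> pd.DataFrame:
    """Compute mapped/unique percentages from per-library read accounting.

    ``accounting`` has one row per library (index = library label) and
    integer columns ``total_reads``, ``mapped_reads``,
    ``unique_match_reads``.  Percentages are 100 x numerator/denominator
    rounded half-up to two decimals, matching how sequencing summary
    tables are conventionally printed.
    """
    frame = pd.DataFrame(accounting).copy()
    missing = [c for c in ACCOUNTING_COLUMNS if c not in frame.columns]
    if missing:
        raise LibraryStatsError(f"missing accounting columns: {missing}")
    for col in ACCOUNTING_COLUMNS:
        values = frame[col].to_numpy()
        if np.any(values < 0) or np.any(values != np.floor(values)):
            raise LibraryStatsError(f"{col} must be non-negative integers")
    if (frame["total_reads"] == 0).any():
        raise LibraryStatsError("total_reads == 0 leaves rates undefined")
    if (frame["mapped_reads"] > frame["total_reads"]).any():
        raise LibraryStatsError("mapped_reads may not exceed total_reads")
    if (frame["unique_match_reads"] > frame["mapped_reads"]).any():
        raise LibraryStatsError("unique_match_reads may not exceed mapped_reads")
    frame["mapped_pct"] = [
        percentage(m, t) for m, t in zip(frame["mapped_reads"], frame["total_reads"])
    ]
    frame["unique_pct"] = [
        percentage(u, t) for u, t in
        zip(frame["unique_match_reads"], frame["total_reads"])
    ]
    return frame


# ---------------------------------------------------------------------------
# RPKM normalization
# ---------------------------------------------------------------------------


class NormalizationError(ValueError):
    """Raised when a library has no assigned reads to normalize against."""


@dataclass(frozen=True)
class ExpressionMatrix:
    """Per-gene, per-library RPKM with the library denominators used.

    RPKM_gl = 1e9 * C_gl / (N_l * L_g) where N_l is the library's total
    gene-assigned unambiguous count and L_g the transcript length in bp.
    """

    rpkm: pd.DataFrame
    denominators: pd.Series = field(repr=False)

    def to_tsv(self, path: str | Path) -> None:
        out = self.rpkm.copy()
        out.index.name = GENE_COLUMN
        out.to_csv(path, sep="\t")


def compute_rpkm(counts: CountMatrix) -> ExpressionMatrix:
    """Normalize assigned tag counts to RPKM."""
    totals = counts.totals()
    empty = totals[totals == 0]
    if len(empty):
        raise NormalizationError(
            f"libraries with zero assigned reads: {list(empty.index)}")
    lengths = counts.lengths.to_numpy()[:, None].astype(float)
    rpkm = 1e9 * counts.counts.to_numpy(dtype=float) / (
        totals.to_numpy(dtype=float)[None, :] * lengths)
    frame = pd.DataFrame(rpkm, index=counts.gene_ids, columns=counts.libraries)
    return ExpressionMatrix(rpkm=frame, denominators=totals)
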