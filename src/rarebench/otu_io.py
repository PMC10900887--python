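"""Count-table containers and readers/writers for mothur ``.shared`` and TSV matrices.

The universal currency of the package is the :class:`OtuTable`: an integer
matrix of sequence counts with one row per sample and one column per OTU.
Normalizations that produce real-valued entries (relative abundances, CSS
scaling, CLR values) return an :class:`AbundanceTable` tagged with the
transformation that produced it, so downstream code can validate the row
constraints that each transformation guarantees.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "OtuTable",
    "AbundanceTable",
    "DistanceMatrix",
    "OtuTableError",
    "read_shared",
    "write_shared",
    "read_counts_tsv",
    "write_counts_tsv",
]


class OtuTableError(ValueError):
    """Raised when a count table or one of its serializations is malformed."""


def _check_ids(ids: tuple[str, ...], what: str) -> None:
    if len(set(ids)) != len(ids):
        dupes = sorted({x for x in ids if ids.count(x) > 1})
        raise OtuTableError(f"duplicate {what}: {dupes[:5]}")


@dataclass(frozen=True)
class OtuTable:
    """Samples × OTUs matrix of nonnegative integer sequence counts.

    Row sums are the per-sample sequencing depths (``N`` in the diversity
    formulas); they are always derived from ``counts``, never stored.
    """

    sample_ids: tuple[str, ...]
    otu_ids: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise OtuTableError("counts must be a 2-D matrix")
        if not np.issubdtype(counts.dtype, np.integer):
            if np.issubdtype(counts.dtype, np.floating) and np.all(
                counts == np.floor(counts)
            ):
                counts = counts.astype(np.int64)
            else:
                raise OtuTableError("counts must be integral")
        if counts.size and counts.min() < 0:
            raise OtuTableError("counts must be nonnegative")
        if counts.shape != (len(self.sample_ids), len(self.otu_ids)):
            raise OtuTableError(
                f"counts shape {counts.shape} does not match "
                f"{len(self.sample_ids)} samples × {len(self.otu_ids)} OTUs"
            )
        if counts.size == 0:
            raise OtuTableError("empty table")
        _check_ids(tuple(self.sample_ids), "sample ids")
        _check_ids(tuple(self.otu_ids), "OTU ids")
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))
        object.__setattr__(self, "otu_ids", tuple(self.otu_ids))
        object.__setattr__(self, "counts", np.ascontiguousarray(counts, dtype=np.int64))

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_otus(self) -> int:
        return len(self.otu_ids)

    @property
    def depths(self) -> np.ndarray:
        """Per-sample sequencing depths (row sums)."""
        return self.counts.sum(axis=1)

    def sample(self, sample_id: str) -> np.ndarray:
        return self.counts[self.sample_ids.index(sample_id)]

    def select_samples(self, keep: np.ndarray | list) -> "OtuTable":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return OtuTable(
            tuple(self.sample_ids[i] for i in keep),
            self.otu_ids,
            self.counts[keep],
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=list(self.sample_ids), columns=list(self.otu_ids)
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, OtuTable):
            return NotImplemented
        return (
            self.sample_ids == other.sample_ids
            and self.otu_ids == other.otu_ids
            and np.array_equal(self.counts, other.counts)
        )


_VALID_TAGS = ("relabund", "clr", "css")


@dataclass(frozen=True)
class AbundanceTable:
    """Real-valued samples × OTUs matrix plus the transformation that made it.

    Tags and their row invariants:

    - ``relabund``: rows sum to 1 (zero-depth rows are disallowed),
    - ``clr``: rows sum to 0 (the CLR identity),
    - ``css``: nonnegative scaled counts, no row constraint.
    """

    sample_ids: tuple[str, ...]
    otu_ids: tuple[str, ...]
    values: np.ndarray
    tag: str

    def __post_init__(self) -> None:
        values = np.ascontiguousarray(self.values, dtype=np.float64)
        if values.shape != (len(self.sample_ids), len(self.otu_ids)):
            raise OtuTableError("values shape does not match ids")
        if self.tag not in _VALID_TAGS:
            raise OtuTableError(f"unknown tag {self.tag!r}; expected one of {_VALID_TAGS}")
        rows = values.sum(axis=1)
        if self.tag == "relabund" and not np.allclose(rows, 1.0, atol=1e-9):
            raise OtuTableError("relative-abundance rows must sum to 1")
        if self.tag == "clr" and not np.allclose(rows, 0.0, atol=1e-9):
            raise OtuTableError("CLR rows must sum to 0")
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))
        object.__setattr__(self, "otu_ids", tuple(self.otu_ids))
        object.__setattr__(self, "values", values)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric, zero-diagonal, nonnegative matrix of pairwise dissimilarities."""

    sample_ids: tuple[str, ...]
    values: np.ndarray
    metric: str = ""

    def __post_init__(self) -> None:
        values = np.ascontiguousarray(self.values, dtype=np.float64)
        n = len(self.sample_ids)
        if values.shape != (n, n):
            raise OtuTableError("distance matrix must be square over sample_ids")
        if not np.allclose(values, values.T, atol=1e-12):
            raise OtuTableError("distance matrix must be symmetric")
        if np.any(np.diag(values) != 0.0):
            raise OtuTableError("distance matrix diagonal must be exactly zero")
        if values.size and values.min() < 0:
            raise OtuTableError("distances must be nonnegative")
        if self.metric in ("jaccard", "braycurtis") and values.size and values.max() > 1 + 1e-12:
            raise OtuTableError(f"{self.metric} distances must be ≤ 1")
        # enforce exact symmetry so downstream sums are order-independent
        values = (values + values.T) / 2.0
        np.fill_diagonal(values, 0.0)
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))
        object.__setattr__(self, "values", values)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def condensed(self) -> np.ndarray:
        """Upper-triangle entries in scipy's condensed order."""
        iu = np.triu_indices(self.n_samples, k=1)
        return self.values[iu]


_INT_RE = re.compile(r"^[+]?\d+$")


def _parse_int_cell(cell: str, row: str, col: str) -> int:
    if not _INT_RE.match(cell.strip()):
        raise OtuTableError(
            f"non-integer count {cell!r} at sample {row!r}, OTU {col!r}"
        )
    return int(cell)


def _warn_zero_depth(table: OtuTable) -> None:
    zero = [s for s, d in zip(table.sample_ids, table.depths) if d == 0]
    if zero:
        warnings.warn(
            f"samples with zero depth: {zero[:5]}"
            + (" ..." if len(zero) > 5 else "")
            + "; downstream operations that divide by depth will reject them",
            UserWarning,
            stacklevel=3,
        )


def read_shared(path) -> OtuTable:
    """Read a mothur ``.shared`` file (``label  Group  numOtus  <otu...>``).

    Any single distance ``label`` is accepted; ``numOtus`` must agree with the
    number of OTU columns in every row.
    """
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 4 or header[:3] != ["label", "Group", "numOtus"]:
            raise OtuTableError(
                f"{path}: not a .shared file (header must start with "
                "'label\\tGroup\\tnumOtus')"
            )
        otu_ids = tuple(header[3:])
        samples: list[str] = []
        rows: list[list[int]] = []
        labels: set[str] = set()
        for line in fh:
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 3 + len(otu_ids):
                raise OtuTableError(
                    f"{path}: row for {fields[1] if len(fields) > 1 else '?'} has "
                    f"{len(fields) - 3} OTU columns, expected {len(otu_ids)}"
                )
            label, group, num_otus = fields[0], fields[1], fields[2]
            labels.add(label)
            if _parse_int_cell(num_otus, group, "numOtus") != len(otu_ids):
                raise OtuTableError(
                    f"{path}: numOtus={num_otus} disagrees with "
                    f"{len(otu_ids)} OTU columns (sample {group!r})"
                )
            if group in samples:
                raise OtuTableError(f"{path}: duplicate Group {group!r}")
            samples.append(group)
            rows.append([_parse_int_cell(c, group, o) for c, o in zip(fields[3:], otu_ids)])
    if len(labels) > 1:
        raise OtuTableError(f"{path}: multiple distance labels {sorted(labels)}")
    if not rows:
        raise OtuTableError(f"{path}: no sample rows")
    table = OtuTable(tuple(samples), otu_ids, np.array(rows, dtype=np.int64))
    _warn_zero_depth(table)
    return table


def write_shared(table: OtuTable, path, label: str = "0.03") -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(["label", "Group", "numOtus", *table.otu_ids]) + "\n")
        for sid, row in zip(table.sample_ids, table.counts):
            fh.write(
                "\t".join([label, sid, str(table.n_otus), *map(str, row)]) + "\n"
            )


def read_counts_tsv(path) -> OtuTable:
    """Read a plain TSV count matrix: header of OTU ids, first column sample ids."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    if df.empty:
        raise OtuTableError(f"{path}: empty table")
    counts = np.empty(df.shape, dtype=np.int64)
    for j, col in enumerate(df.columns):
        for i, (sid, cell) in enumerate(zip(df.index, df[col])):
            counts[i, j] = _parse_int_cell(cell, str(sid), str(col))
    table = OtuTable(tuple(map(str, df.index)), tuple(map(str, df.columns)), counts)
    _warn_zero_depth(table)
    return table


def write_counts_tsv(table: OtuTable, path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(["sample", *table.otu_ids]) + "\n")
        for sid, row in zip(table.sample_ids, table.counts):
            fh.write("\t".join([sid, *map(str, row)]) + "\n")


def write_distance_tsv(dm: DistanceMatrix, path) -> None:
    """Square TSV with a leading sample column."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(["sample", *dm.sample_ids]) + "\n")
        for sid, row in zip(dm.sample_ids, dm.values):
            fh.write("\t".join([sid, *(f"{v:.10g}" for v in row)]) + "\n")


def write_distance_phylip(dm: DistanceMatrix, path) -> None:
    """Lower-triangle PHYLIP-style distance file."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"{dm.n_samples}\n")
        for i, sid in enumerate(dm.sample_ids):
            cells = [f"{dm.values[i, j]:.10g}" for j in range(i)]
            fh.write("\t".join([sid, *cells]).rstrip("\t") + "\n")
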