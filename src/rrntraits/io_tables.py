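"""Tabular input handling: OTU count tables, taxonomy maps, rarefaction,
relative abundance.

The central container is :class:`OtuTable`, a non-negative integer count
matrix (OTUs in rows, samples in columns) with optional per-sample metadata
(time in days, replicate label, habitat/regime group). Tables are plain
UTF-8 TSV on disk; the first column is ``otu_id`` and the header row holds
sample ids. Orientation is fixed as OTUs-in-rows — a transposed input is
never guessed, only honoured on an explicit flag, because silent
transposition is a classic corruption source.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "OtuTable",
    "RelAbundanceTable",
    "ParseError",
    "ValidationError",
    "read_otu_table",
    "write_otu_table",
    "read_sample_metadata",
    "read_taxonomy",
    "normalize_genus",
    "UNASSIGNED",
    "rarefy",
    "relative_abundance",
]

UNASSIGNED = "unassigned"

META_COLUMNS = ("time_days", "replicate", "group")


class ParseError(ValueError):
    """A file could not be parsed into a valid table."""


class ValidationError(ValueError):
    """Parsed data violates a container invariant."""


@dataclass
class OtuTable:
    """OTU-by-sample count matrix with per-sample metadata.

    Parameters
    ----------
    counts
        DataFrame of non-negative integers, index = OTU ids,
        columns = sample ids.
    sample_meta
        DataFrame indexed by sample id with (a subset of) the columns
        ``time_days``, ``replicate``, ``group``. Missing entries are NaN.
    """

    counts: pd.DataFrame
    sample_meta: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            dup = self.counts.index[self.counts.index.duplicated()][0]
            raise ValidationError(f"duplicate OTU id: {dup!r}")
        if self.counts.columns.has_duplicates:
            dup = self.counts.columns[self.counts.columns.duplicated()][0]
            raise ValidationError(f"duplicate sample id: {dup!r}")
        arr = self.counts.to_numpy()
        if arr.size and not np.issubdtype(arr.dtype, np.number):
            raise ValidationError("counts must be numeric")
        if arr.size:
            if np.any(arr < 0):
                raise ValidationError("negative count encountered")
            if not np.allclose(arr, np.round(arr)):
                raise ValidationError("non-integer count encountered")
        self.counts = self.counts.astype(np.int64)
        if self.sample_meta is None:
            self.sample_meta = pd.DataFrame(
                index=self.counts.columns, columns=list(META_COLUMNS), dtype=object
            )
        else:
            meta = self.sample_meta.reindex(self.counts.columns)
            for col in META_COLUMNS:
                if col not in meta.columns:
                    meta[col] = np.nan
            self.sample_meta = meta

    @property
    def otu_ids(self) -> list:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list:
        return list(self.counts.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def column_sums(self) -> pd.Series:
        return self.counts.sum(axis=0)


@dataclass
class RelAbundanceTable:
    """Proportions with the same axes as the source :class:`OtuTable`.

    Each sample column sums to 1 (within 1e-9), or to 0 for an all-zero
    sample, in which case the sample id appears in ``zero_samples``. A
    ``partial`` table holds subset rows of whole-sample proportions and is
    exempt from the sum-to-1 check (columns sum to at most 1).
    """

    props: pd.DataFrame
    zero_samples: tuple = ()
    partial: bool = False

    def __post_init__(self) -> None:
        sums = self.props.sum(axis=0)
        zero = set(self.zero_samples)
        for sid, s in sums.items():
            if sid in zero:
                if abs(s) > 1e-9:
                    raise ValidationError(f"flagged zero sample {sid!r} is non-zero")
            elif self.partial:
                if s > 1.0 + 1e-9:
                    raise ValidationError(f"sample {sid!r} subset proportions exceed 1")
            elif abs(s - 1.0) > 1e-9:
                raise ValidationError(f"sample {sid!r} proportions sum to {s}, not 1")


def read_otu_table(
    path,
    format: str = "tsv",
    metadata_path=None,
    transposed: bool = False,
) -> OtuTable:
    """Read a TSV OTU table (first column ``otu_id``, header = sample ids).

    ``transposed=True`` declares the file is samples-in-rows; it is never
    auto-detected. An optional sidecar metadata TSV maps sample id to
    time_days / replicate / group.
    """
    if format != "tsv":
        raise ValueError(f"unsupported format {format!r}")
    try:
        with open(path, "r", encoding="utf-8") as fh:
            header = fh.readline()
            if not header.strip():
                raise ParseError("no data rows")
            columns = header.rstrip("\n").split("\t")
            rows = [line.rstrip("\n").split("\t") for line in fh if line.strip()]
    except OSError as exc:
        raise ParseError(f"cannot read {path}: {exc}") from exc
    if not rows:
        raise ParseError("no data rows")
    sample_ids = columns[1:]
    seen: set = set()
    for sid in sample_ids:
        if sid in seen:
            raise ParseError(f"duplicate sample id in header: {sid!r}")
        seen.add(sid)
    otu_ids = []
    seen = set()
    data = []
    for row in rows:
        oid = row[0]
        if oid in seen:
            raise ParseError(f"duplicate OTU id in row: {oid!r}")
        seen.add(oid)
        otu_ids.append(oid)
        if len(row) != len(columns):
            raise ParseError(f"row {oid!r} has {len(row) - 1} cells, expected {len(sample_ids)}")
        vals = []
        for sid, cell in zip(sample_ids, row[1:]):
            try:
                v = float(cell)
            except ValueError as exc:
                raise ParseError(f"non-numeric count {cell!r} at ({oid}, {sid})") from exc
            if v < 0:
                raise ValidationError(f"negative count at ({oid}, {sid})")
            if v != int(v):
                raise ValidationError(f"non-integer count at ({oid}, {sid})")
            vals.append(int(v))
        data.append(vals)
    counts = pd.DataFrame(data, index=otu_ids, columns=sample_ids, dtype=np.int64)
    if transposed:
        counts = counts.T
    meta = read_sample_metadata(metadata_path) if metadata_path is not None else None
    return OtuTable(counts, meta)


def write_otu_table(table: OtuTable, path) -> None:
    df = table.counts.copy()
    df.index.name = "otu_id"
    df.to_csv(path, sep="\t")


def read_sample_metadata(path) -> pd.DataFrame:
    """Read a sample metadata TSV: sample_id, time_days, replicate, group."""
    meta = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in meta.columns:
        raise ParseError("metadata file lacks a sample_id column")
    meta = meta.set_index("sample_id")
    if "time_days" in meta.columns:
        meta["time_days"] = pd.to_numeric(meta["time_days"], errors="coerce")
    return meta


def normalize_genus(name) -> str:
    """Trim and case-normalize a genus string; empty/missing -> sentinel."""
    if name is None or (isinstance(name, float) and np.isnan(name)):
        return UNASSIGNED
    s = str(name).strip().casefold()
    return s if s else UNASSIGNED


def read_taxonomy(path) -> dict:
    """Read OTU -> genus TSV (columns otu_id, genus) into a normalized map."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "otu_id" not in df.columns or "genus" not in df.columns:
        raise ParseError("taxonomy file needs columns otu_id and genus")
    if df["otu_id"].duplicated().any():
        dup = df.loc[df["otu_id"].duplicated(), "otu_id"].iloc[0]
        raise ParseError(f"duplicate otu_id in taxonomy: {dup!r}")
    return {oid: normalize_genus(g) for oid, g in zip(df["otu_id"], df["genus"])}


def rarefy(table: OtuTable, depth: int, seed: int) -> OtuTable:
    """Subsample every sample to exactly ``depth`` reads without replacement.

    Each sample is an independent multivariate-hypergeometric draw from the
    multiset of reads implied by its counts. Samples whose total is below
    ``depth`` are dropped with a warning — padding would fabricate reads.
    Deterministic given ``seed``.
    """
    if depth <= 0:
        raise ValueError("rarefaction depth must be a positive integer")
    rng = np.random.default_rng(seed)
    sums = table.column_sums()
    keep = [sid for sid in table.sample_ids if sums[sid] >= depth]
    dropped = [sid for sid in table.sample_ids if sums[sid] < depth]
    if dropped:
        warnings.warn(
            f"dropping {len(dropped)} sample(s) below depth {depth}: {dropped}",
            UserWarning,
            stacklevel=2,
        )
    out = {}
    for sid in keep:
        col = table.counts[sid].to_numpy()
        if sums[sid] == depth:
            out[sid] = col.copy()
        else:
            out[sid] = rng.multivariate_hypergeometric(col, depth)
    counts = pd.DataFrame(out, index=table.counts.index, dtype=np.int64)
    if not keep:
        counts = pd.DataFrame(index=table.counts.index, dtype=np.int64)
    return OtuTable(counts, table.sample_meta.loc[keep] if keep else None)


def relative_abundance(
    table: OtuTable,
    subset=None,
    renormalize: bool = False,
) -> RelAbundanceTable:
    """Convert counts to proportions, optionally over an OTU subset.

    With ``renormalize`` the denominator is the subset's own column total,
    so the returned columns sum to 1 over the subset; without it the
    whole-sample total is used and subset columns may sum to less than 1
    (only full-table calls then satisfy the sum-to-1 invariant; subset
    calls return the subset rows of the full-table proportions).
    """
    counts = table.counts
    if subset is not None:
        subset_ids = [oid for oid in counts.index if oid in set(subset)]
        if not subset_ids:
            raise ValueError("empty subset intersection")
        sub = counts.loc[subset_ids]
    else:
        sub = counts
    denom = sub.sum(axis=0) if (renormalize or subset is None) else counts.sum(axis=0)
    zero = tuple(sid for sid in sub.columns if denom[sid] == 0)
    safe = denom.replace(0, 1)
    props = sub.div(safe, axis=1).astype(float)
    partial = subset is not None and not renormalize
    return RelAbundanceTable(props, zero, partial=partial)
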