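"""Data model, TSV/BIOM readers and writers, and cross-table validation.

The universal currency is the :class:`CountTable` — a samples x ASVs
integer matrix — together with a :class:`SampleFrame` holding the nested
sampling design (plot > point > core > aggregate/bulk) and per-sample
environment measurements, and a :class:`TaxonomyTable` mapping ASVs to
ranked lineages.

On disk everything is tab-separated UTF-8 text.  The canonical count-table
orientation is ASVs as rows and samples as columns (the common amplicon
convention); the reader accepts both orientations via a flag.  Missing
environment measurements are kept as missing (NaN), never imputed as zero:
downstream analyses silently drop samples lacking the variable they need,
which mirrors how field datasets with incomplete chemistry are analysed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

SAMPLE_TYPES = ("aggregate", "bulk")
DEPTH_LAYERS = ("top", "deep")

#: environment columns recognised in a sample metadata table, in canonical order
ENV_COLUMNS = (
    "C_pct",
    "N_pct",
    "CN_ratio",
    "d13C_permil",
    "d15N_permil",
    "SWC",
    "gene_copies",
)

_REQUIRED_SAMPLE_COLUMNS = (
    "sample_id",
    "sample_type",
    "depth_layer",
    "plot_id",
    "point_id",
    "core_id",
    "x",
    "y",
)


class DataError(ValueError):
    """Raised when an input table violates the data contract."""


@dataclass(frozen=True)
class CountTable:
    """Integer ASV abundance matrix, samples x ASVs.

    Parameters
    ----------
    sample_ids : sequence of str
        Unique sample identifiers (row labels).
    asv_ids : sequence of str
        Unique ASV identifiers (column labels).
    counts : ndarray of int, shape (n_samples, n_asvs)
        Nonnegative read counts.
    """

    sample_ids: tuple
    asv_ids: tuple
    counts: np.ndarray = field(repr=False)

    def __post_init__(self):
        sample_ids = tuple(str(s) for s in self.sample_ids)
        asv_ids = tuple(str(a) for a in self.asv_ids)
        object.__setattr__(self, "sample_ids", sample_ids)
        object.__setattr__(self, "asv_ids", asv_ids)
        if len(set(sample_ids)) != len(sample_ids):
            raise DataError("duplicate sample identifiers")
        if len(set(asv_ids)) != len(asv_ids):
            raise DataError("duplicate ASV identifiers")
        counts = np.asarray(self.counts)
        if counts.ndim != 2 or counts.shape != (len(sample_ids), len(asv_ids)):
            raise DataError(
                f"counts shape {counts.shape} does not match "
                f"({len(sample_ids)}, {len(asv_ids)})"
            )
        if counts.size == 0:
            raise DataError("empty count table")
        if not np.issubdtype(counts.dtype, np.integer):
            rounded = np.rint(counts)
            bad = ~np.isclose(counts.astype(float), rounded, atol=1e-9)
            if bad.any():
                i, j = np.argwhere(bad)[0]
                raise DataError(
                    f"non-integer count {counts[i, j]!r} at sample "
                    f"{sample_ids[i]!r}, ASV {asv_ids[j]!r}"
                )
            counts = rounded.astype(np.int64)
        else:
            counts = counts.astype(np.int64)
        if (counts < 0).any():
            i, j = np.argwhere(counts < 0)[0]
            raise DataError(
                f"negative count at sample {sample_ids[i]!r}, ASV {asv_ids[j]!r}"
            )
        counts = counts.copy()
        counts.setflags(write=False)
        object.__setattr__(self, "counts", counts)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_asvs(self) -> int:
        return len(self.asv_ids)

    def to_frame(self) -> pd.DataFrame:
        """Samples x ASVs DataFrame view of the counts."""
        return pd.DataFrame(
            np.asarray(self.counts), index=list(self.sample_ids),
            columns=list(self.asv_ids),
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CountTable":
        return cls(tuple(map(str, df.index)), tuple(map(str, df.columns)),
                   df.to_numpy())

    def totals(self) -> np.ndarray:
        """Per-sample read totals."""
        return np.asarray(self.counts).sum(axis=1)

    def subset_samples(self, ids: Iterable[str]) -> "CountTable":
        ids = [str(i) for i in ids]
        pos = {s: k for k, s in enumerate(self.sample_ids)}
        missing = [i for i in ids if i not in pos]
        if missing:
            raise DataError(f"unknown sample identifiers: {missing}")
        rows = [pos[i] for i in ids]
        return CountTable(tuple(ids), self.asv_ids,
                          np.asarray(self.counts)[rows])

    def presence(self) -> np.ndarray:
        """Boolean samples x ASVs presence matrix (count > 0)."""
        return np.asarray(self.counts) > 0


@dataclass(frozen=True)
class SampleFrame:
    """Per-sample design, coordinates (metres), and environment measurements.

    Wraps a DataFrame indexed by sample_id with the design columns
    (sample_type, depth_layer, plot_id, point_id, core_id, x, y) and the
    canonical environment columns (NaN where not measured).
    """

    data: pd.DataFrame

    def __post_init__(self):
        df = self.data
        if df.index.name != "sample_id":
            raise DataError("SampleFrame index must be named 'sample_id'")
        if df.index.has_duplicates:
            dup = df.index[df.index.duplicated()].tolist()
            raise DataError(f"duplicate sample identifiers: {dup}")
        for col in _REQUIRED_SAMPLE_COLUMNS[1:]:
            if col not in df.columns:
                raise DataError(f"missing required column {col!r}")
        bad_type = set(df["sample_type"]) - set(SAMPLE_TYPES)
        if bad_type:
            raise DataError(f"unknown sample_type values: {sorted(bad_type)}")
        bad_depth = set(df["depth_layer"]) - set(DEPTH_LAYERS)
        if bad_depth:
            raise DataError(f"unknown depth_layer values: {sorted(bad_depth)}")
        if not np.isfinite(df[["x", "y"]].to_numpy(dtype=float)).all():
            raise DataError("non-finite coordinates")
        # hierarchy must nest: core -> point -> plot, each child under one parent
        for child, parent in (("core_id", "point_id"), ("point_id", "plot_id")):
            n_parents = df.groupby(child, observed=True)[parent].nunique()
            bad = n_parents[n_parents > 1]
            if len(bad):
                raise DataError(
                    f"{child} {bad.index[0]!r} nested under multiple {parent}s"
                )
        df = df.copy()
        for col in ENV_COLUMNS:
            if col not in df.columns:
                df[col] = np.nan
            df[col] = pd.to_numeric(df[col], errors="raise")
        # C:N consistency where all three are present
        m = df[["C_pct", "N_pct", "CN_ratio"]].notna().all(axis=1)
        if m.any():
            c = df.loc[m, "C_pct"].to_numpy(float)
            n = df.loc[m, "N_pct"].to_numpy(float)
            cn = df.loc[m, "CN_ratio"].to_numpy(float)
            with np.errstate(divide="ignore", invalid="ignore"):
                rel = np.abs(cn - c / n) / np.maximum(np.abs(cn), 1e-300)
            if np.any(rel > 1e-6):
                sid = df.index[m][int(np.argmax(rel > 1e-6))]
                raise DataError(f"CN_ratio inconsistent with C/N for {sid!r}")
        for col in ("C_pct", "N_pct", "SWC", "gene_copies"):
            if (df[col].dropna() < 0).any():
                raise DataError(f"negative values in {col}")
        object.__setattr__(self, "data", df)

    @property
    def sample_ids(self) -> list:
        return list(self.data.index)

    def subset(self, ids: Iterable[str]) -> "SampleFrame":
        return SampleFrame(self.data.loc[list(ids)])

    def aggregates(self) -> pd.DataFrame:
        return self.data[self.data["sample_type"] == "aggregate"]

    def bulks(self) -> pd.DataFrame:
        return self.data[self.data["sample_type"] == "bulk"]

    def coords(self, ids: Sequence[str] | None = None) -> np.ndarray:
        df = self.data if ids is None else self.data.loc[list(ids)]
        return df[["x", "y"]].to_numpy(dtype=float)


@dataclass(frozen=True)
class TaxonomyTable:
    """ASV -> ranked lineage; ``phylum`` is the rank the top-taxa statistic uses."""

    data: pd.DataFrame

    RANKS = ("domain", "phylum", "class", "order", "family", "genus")

    def __post_init__(self):
        df = self.data
        if df.index.name != "asv_id":
            raise DataError("TaxonomyTable index must be named 'asv_id'")
        if df.index.has_duplicates:
            raise DataError("duplicate asv_id in taxonomy table")
        if "phylum" not in df.columns:
            raise DataError("taxonomy table must have a 'phylum' column")
        df = df.copy()
        df["phylum"] = df["phylum"].fillna("unclassified").replace("", "unclassified")
        object.__setattr__(self, "data", df)

    def phylum_of(self, asv_ids: Sequence[str]) -> np.ndarray:
        """Phylum per ASV; unknown ASVs map to ``"unclassified"``."""
        s = self.data["phylum"].reindex(list(asv_ids)).fillna("unclassified")
        return s.to_numpy(dtype=object)


@dataclass(frozen=True)
class ValidatedDataset:
    """Cross-referenced counts + design + taxonomy, ready for analysis."""

    counts: CountTable
    samples: SampleFrame
    taxonomy: TaxonomyTable


def read_count_table(path, orientation: str = "asvs-as-rows") -> CountTable:
    """Read a TSV count table.

    Parameters
    ----------
    path : str or Path
        Tab-separated file with an identifier header row and first column.
    orientation : {"asvs-as-rows", "samples-as-rows"}
        How the file is laid out; the returned table is always samples x ASVs.
    """
    if orientation not in ("asvs-as-rows", "samples-as-rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.empty:
        raise DataError(f"empty count table: {path}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any():
        r, c = np.argwhere(numeric.isna().to_numpy())[0]
        raise DataError(
            f"non-numeric cell {df.iat[r, c]!r} at row {df.index[r]!r}, "
            f"column {df.columns[c]!r}"
        )
    frac = numeric.to_numpy(dtype=float)
    if not np.allclose(frac, np.rint(frac), atol=1e-9):
        r, c = np.argwhere(~np.isclose(frac, np.rint(frac), atol=1e-9))[0]
        raise DataError(
            f"non-integer count {df.iat[r, c]!r} at row {df.index[r]!r}, "
            f"column {df.columns[c]!r}"
        )
    if orientation == "asvs-as-rows":
        numeric = numeric.T
    return CountTable(tuple(map(str, numeric.index)),
                      tuple(map(str, numeric.columns)),
                      numeric.to_numpy())


def write_count_table(table: CountTable, path) -> None:
    """Write in canonical orientation (ASVs as rows), identifiers sorted."""
    df = table.to_frame().T
    df = df.sort_index(axis=0).sort_index(axis=1)
    df.index.name = "asv_id"
    df.to_csv(path, sep="\t")


def read_sample_frame(path) -> SampleFrame:
    """Read sample metadata TSV into a typed :class:`SampleFrame`."""
    df = pd.read_csv(path, sep="\t", dtype={c: str for c in _REQUIRED_SAMPLE_COLUMNS[:6]})
    missing = [c for c in _REQUIRED_SAMPLE_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"sample table missing columns: {missing}")
    df = df.set_index("sample_id")
    df["x"] = pd.to_numeric(df["x"])
    df["y"] = pd.to_numeric(df["y"])
    return SampleFrame(df)


def write_sample_frame(frame: SampleFrame, path) -> None:
    df = frame.data.sort_index()
    cols = list(_REQUIRED_SAMPLE_COLUMNS[1:]) + [c for c in ENV_COLUMNS if c in df.columns]
    df[cols].to_csv(path, sep="\t")


def read_taxonomy_table(path) -> TaxonomyTable:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "asv_id" not in df.columns:
        raise DataError("taxonomy table must have an 'asv_id' column")
    if df["asv_id"].duplicated().any():
        dup = df.loc[df["asv_id"].duplicated(), "asv_id"].tolist()
        raise DataError(f"duplicate asv_id in taxonomy table: {dup}")
    return TaxonomyTable(df.set_index("asv_id"))


def write_taxonomy_table(tax: TaxonomyTable, path) -> None:
    tax.data.sort_index().to_csv(path, sep="\t")


def read_biom_count_table(path) -> CountTable:
    """Minimal BIOM 2.1 (HDF5) reader for the standard CSR observation matrix.

    BIOM stores observations (ASVs) x samples; the result is transposed to
    the in-memory samples x ASVs convention.
    """
    import h5py
    from scipy import sparse

    with h5py.File(path, "r") as f:
        asv_ids = [x.decode() if isinstance(x, bytes) else str(x)
                   for x in f["observation/ids"][:]]
        sample_ids = [x.decode() if isinstance(x, bytes) else str(x)
                      for x in f["sample/ids"][:]]
        g = f["observation/matrix"]
        mat = sparse.csr_matrix(
            (g["data"][:], g["indices"][:], g["indptr"][:]),
            shape=(len(asv_ids), len(sample_ids)),
        )
    dense = np.asarray(mat.todense())
    return CountTable(tuple(sample_ids), tuple(asv_ids), dense.T)


def validate_dataset(counts: CountTable, samples: SampleFrame,
                     taxonomy: TaxonomyTable) -> ValidatedDataset:
    """Cross-reference the three tables.

    Samples present in the counts but absent from the metadata are an error
    (they cannot be analysed); ASVs lacking a taxonomy row are retained with
    phylum ``"unclassified"`` and a warning.
    """
    known = set(samples.sample_ids)
    unknown = [s for s in counts.sample_ids if s not in known]
    if len(unknown) == len(counts.sample_ids):
        raise DataError("no overlap between count table and sample metadata")
    if unknown:
        raise DataError(f"count-table samples missing from metadata: {unknown}")
    tax = taxonomy.data
    missing_tax = [a for a in counts.asv_ids if a not in tax.index]
    if missing_tax:
        warnings.warn(
            f"{len(missing_tax)} ASV(s) lack taxonomy; assigned phylum "
            f"'unclassified'", stacklevel=2,
        )
        extra = pd.DataFrame({"phylum": "unclassified"},
                             index=pd.Index(missing_tax, name="asv_id"))
        tax = pd.concat([tax, extra])
        taxonomy = TaxonomyTable(tax)
    meta = samples.subset(counts.sample_ids).data
    for depth in DEPTH_LAYERS:
        sub = meta[meta["depth_layer"] == depth]
        if len(sub) and not set(SAMPLE_TYPES) <= set(sub["sample_type"]):
            raise DataError(
                f"depth layer {depth!r} lacks one of the sample types"
            )
    return ValidatedDataset(counts, samples, taxonomy)
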