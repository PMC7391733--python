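"""Count tables, sample metadata, and regional species pools.

The data model mirrors how 16S amplicon studies are organised: an ASV-by-sample
integer count matrix (:class:`AbundanceTable`), one metadata record per sample
(:class:`SampleRecord`), and the two bound together as a :class:`Cohort`.
Regional species pools (the metacommunity abundance estimate the neutral model
conditions on) are built by pooling samples.

Supported on-disk formats: tab-separated count matrices (taxa as rows, samples
as columns), BIOM 2.1 (HDF5), and a plain CSV metadata table.
"""

from __future__ import annotations

import csv
import math
import os
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AbundanceTable",
    "SampleRecord",
    "Cohort",
    "SourcePool",
    "TableError",
    "MetadataError",
    "read_counts",
    "write_counts",
    "read_metadata",
    "write_metadata",
    "subset",
    "build_source_pool",
    "occurrence_frequency",
    "ROLES",
    "BODY_SITES",
    "VILLAGE_TYPES",
]

ROLES = frozenset({"infant", "mother", "other_adult"})
BODY_SITES = frozenset({"stool", "tongue"})
VILLAGE_TYPES = frozenset({"proximal_river", "distal_river", "forest"})

#: infants in the supported cohorts are at most 3 years old
MAX_INFANT_AGE_MONTHS = 37.0


class TableError(ValueError):
    """Raised for malformed or inconsistent count tables."""


class MetadataError(ValueError):
    """Raised for malformed sample metadata."""


def _find_duplicates(items: Sequence[str]) -> list[str]:
    seen: set[str] = set()
    dups: list[str] = []
    for it in items:
        if it in seen and it not in dups:
            dups.append(it)
        seen.add(it)
    return dups


@dataclass(frozen=True)
class AbundanceTable:
    """Taxa x samples nonnegative integer read-count matrix.

    Parameters
    ----------
    taxon_ids : sequence of str
        Unique row identifiers (ASV/OTU ids).
    sample_ids : sequence of str
        Unique column identifiers.
    counts : ndarray of shape (n_taxa, n_samples)
        Nonnegative integer read counts. Every sample (column) must have a
        positive total depth; all-zero samples are rejected at construction.
    """

    taxon_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "taxon_ids", tuple(str(t) for t in self.taxon_ids))
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        arr = np.asarray(self.counts)
        if arr.ndim != 2:
            raise TableError(f"counts must be 2-D (taxa x samples), got ndim={arr.ndim}")
        if arr.shape != (len(self.taxon_ids), len(self.sample_ids)):
            raise TableError(
                f"counts shape {arr.shape} does not match "
                f"{len(self.taxon_ids)} taxa x {len(self.sample_ids)} samples"
            )
        if arr.size == 0:
            raise TableError("table must contain at least one taxon and one sample")
        for kind, ids in (("taxon", self.taxon_ids), ("sample", self.sample_ids)):
            dups = _find_duplicates(ids)
            if dups:
                raise TableError(f"duplicate {kind} id(s): {', '.join(dups)}")
        if not np.issubdtype(arr.dtype, np.integer):
            flo = np.asarray(arr, dtype=float)
            if np.isnan(flo).any():
                i, j = np.argwhere(np.isnan(flo))[0]
                raise TableError(
                    f"NaN count at taxon {self.taxon_ids[i]!r}, sample {self.sample_ids[j]!r}"
                )
            if not np.all(flo == np.floor(flo)):
                i, j = np.argwhere(flo != np.floor(flo))[0]
                raise TableError(
                    f"non-integer count {flo[i, j]!r} at taxon "
                    f"{self.taxon_ids[i]!r}, sample {self.sample_ids[j]!r}"
                )
            arr = flo.astype(np.int64)
        else:
            arr = arr.astype(np.int64)
        if (arr < 0).any():
            i, j = np.argwhere(arr < 0)[0]
            raise TableError(
                f"negative count {arr[i, j]} at taxon "
                f"{self.taxon_ids[i]!r}, sample {self.sample_ids[j]!r}"
            )
        depths = arr.sum(axis=0)
        if (depths == 0).any():
            j = int(np.argmin(depths))
            raise TableError(f"sample {self.sample_ids[j]!r} has zero total count")
        arr.setflags(write=False)
        object.__setattr__(self, "counts", arr)

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def depths(self) -> np.ndarray:
        """Per-sample read depth (column sums)."""
        return self.counts.sum(axis=0)

    def proportions(self) -> np.ndarray:
        """Per-sample relative abundances (columns sum to 1)."""
        return self.counts / self.depths()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=list(self.taxon_ids), columns=list(self.sample_ids)
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "AbundanceTable":
        return cls(tuple(map(str, frame.index)), tuple(map(str, frame.columns)), frame.to_numpy())

    def select_samples(self, sample_ids: Sequence[str]) -> "AbundanceTable":
        """Restrict to the given samples (taxa retained, even if all-zero)."""
        index = {s: j for j, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in index]
        if missing:
            raise TableError(f"unknown sample id(s): {', '.join(missing)}")
        cols = [index[s] for s in sample_ids]
        return AbundanceTable(self.taxon_ids, tuple(sample_ids), self.counts[:, cols])

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise TableError(f"unknown sample id: {sample_id!r}") from None


@dataclass(frozen=True)
class SampleRecord:
    """Per-sample covariates driving subsetting and partitioning."""

    sample_id: str
    subject_id: str
    role: str
    body_site: str
    age_months: float
    country: str
    dyad_id: str | None = None
    village: str | None = None
    village_type: str | None = None

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise MetadataError(
                f"sample {self.sample_id!r}: unknown role {self.role!r}; "
                f"allowed: {', '.join(sorted(ROLES))}"
            )
        if self.body_site not in BODY_SITES:
            raise MetadataError(
                f"sample {self.sample_id!r}: unknown body_site {self.body_site!r}; "
                f"allowed: {', '.join(sorted(BODY_SITES))}"
            )
        if self.village_type is not None and self.village_type not in VILLAGE_TYPES:
            raise MetadataError(
                f"sample {self.sample_id!r}: unknown village_type {self.village_type!r}; "
                f"allowed: {', '.join(sorted(VILLAGE_TYPES))}"
            )
        age = float(self.age_months)
        if not math.isfinite(age) or age < 0:
            raise MetadataError(
                f"sample {self.sample_id!r}: age_months must be finite and >= 0, got {self.age_months!r}"
            )
        if self.role == "infant" and age >= MAX_INFANT_AGE_MONTHS:
            raise MetadataError(
                f"sample {self.sample_id!r}: infant age_months must be < "
                f"{MAX_INFANT_AGE_MONTHS}, got {age}"
            )
        object.__setattr__(self, "age_months", age)

    @property
    def is_adult(self) -> bool:
        return self.role in ("mother", "other_adult")


@dataclass(frozen=True)
class Cohort:
    """An :class:`AbundanceTable` joined with one :class:`SampleRecord` per sample."""

    table: AbundanceTable
    records: tuple[SampleRecord, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "records", tuple(self.records))
        rec_ids = [r.sample_id for r in self.records]
        dups = _find_duplicates(rec_ids)
        if dups:
            raise MetadataError(f"duplicate sample_id(s) in metadata: {', '.join(dups)}")
        tab = set(self.table.sample_ids)
        rec = set(rec_ids)
        if tab != rec:
            missing = sorted(tab - rec)
            extra = sorted(rec - tab)
            parts = []
            if missing:
                parts.append(f"samples without metadata: {', '.join(missing)}")
            if extra:
                parts.append(f"metadata without samples: {', '.join(extra)}")
            raise MetadataError("; ".join(parts))

    @property
    def n_samples(self) -> int:
        return self.table.n_samples

    def record(self, sample_id: str) -> SampleRecord:
        return self._by_id[sample_id]

    @property
    def _by_id(self) -> dict[str, SampleRecord]:
        return {r.sample_id: r for r in self.records}

    def records_aligned(self) -> list[SampleRecord]:
        """Records in table column order."""
        by_id = self._by_id
        return [by_id[s] for s in self.table.sample_ids]

    def subjects(self) -> dict[str, list[str]]:
        """Mapping subject_id -> sample ids (in table column order)."""
        out: dict[str, list[str]] = {}
        for rec in self.records_aligned():
            out.setdefault(rec.subject_id, []).append(rec.sample_id)
        return out

    def metadata_frame(self) -> pd.DataFrame:
        rows = [
            {
                "sample_id": r.sample_id,
                "subject_id": r.subject_id,
                "dyad_id": r.dyad_id,
                "role": r.role,
                "body_site": r.body_site,
                "age_months": r.age_months,
                "village": r.village,
                "village_type": r.village_type,
                "country": r.country,
            }
            for r in self.records_aligned()
        ]
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class SourcePool:
    """Regional species pool: relative abundances over a cohort's taxa.

    ``p`` sums to one; taxa never observed in the pooled samples get ``p = 0``
    and are excluded from model fitting downstream.
    """

    taxon_ids: tuple[str, ...]
    p: np.ndarray
    n_samples_pooled: int
    pooling_rule: str

    def __post_init__(self) -> None:
        p = np.asarray(self.p, dtype=float)
        if p.ndim != 1 or p.shape[0] != len(self.taxon_ids):
            raise TableError("pool length must equal the number of taxa")
        if (p < 0).any() or not np.isfinite(p).all():
            raise TableError("pool proportions must be finite and >= 0")
        if abs(p.sum() - 1.0) > 1e-9:
            raise TableError(f"pool proportions must sum to 1, got {p.sum()!r}")
        p.setflags(write=False)
        object.__setattr__(self, "p", p)
        object.__setattr__(self, "taxon_ids", tuple(self.taxon_ids))


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

_BIOM_URL = "http://biom-format.org"


def _infer_format(path: str, fmt: str | None) -> str:
    if fmt is not None:
        if fmt not in ("tsv", "biom"):
            raise TableError(f"unknown count-table format {fmt!r}; allowed: tsv, biom")
        return fmt
    return "biom" if os.path.splitext(path)[1].lower() == ".biom" else "tsv"


def read_counts(path: str, format: str | None = None) -> AbundanceTable:
    """Read a count table from TSV (taxa rows, samples columns) or BIOM 2.1."""
    fmt = _infer_format(path, format)
    if fmt == "biom":
        return _read_biom(path)
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise TableError(f"{path}: empty file") from None
        sample_ids = [h.strip() for h in header[1:]]
        taxon_ids: list[str] = []
        rows: list[list[str]] = []
        for line in reader:
            if not line:
                continue
            taxon_ids.append(line[0].strip())
            if len(line) - 1 != len(sample_ids):
                raise TableError(
                    f"{path}: row {line[0]!r} has {len(line) - 1} cells, "
                    f"expected {len(sample_ids)}"
                )
            rows.append(line[1:])
    counts = np.empty((len(taxon_ids), len(sample_ids)), dtype=np.int64)
    for i, row in enumerate(rows):
        for j, cell in enumerate(row):
            try:
                value = float(cell)
            except ValueError:
                raise TableError(
                    f"{path}: non-numeric count {cell!r} at taxon "
                    f"{taxon_ids[i]!r}, sample {sample_ids[j]!r}"
                ) from None
            if math.isnan(value):
                raise TableError(
                    f"{path}: NaN count at taxon {taxon_ids[i]!r}, sample {sample_ids[j]!r}"
                )
            if value != math.floor(value):
                raise TableError(
                    f"{path}: non-integer count {cell!r} at taxon "
                    f"{taxon_ids[i]!r}, sample {sample_ids[j]!r}"
                )
            counts[i, j] = int(value)
    return AbundanceTable(tuple(taxon_ids), tuple(sample_ids), counts)


def write_counts(table: AbundanceTable, path: str, format: str | None = None) -> None:
    """Write a count table as TSV or BIOM 2.1 (inferred from the extension)."""
    fmt = _infer_format(path, format)
    if fmt == "biom":
        _write_biom(table, path)
        return
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["taxon_id", *table.sample_ids])
        for i, taxon in enumerate(table.taxon_ids):
            writer.writerow([taxon, *table.counts[i].tolist()])


def _read_biom(path: str) -> AbundanceTable:
    import h5py
    from scipy import sparse

    with h5py.File(path, "r") as fh:
        taxon_ids = [t.decode() if isinstance(t, bytes) else str(t) for t in fh["observation/ids"][:]]
        sample_ids = [s.decode() if isinstance(s, bytes) else str(s) for s in fh["sample/ids"][:]]
        data = fh["observation/matrix/data"][:]
        indices = fh["observation/matrix/indices"][:]
        indptr = fh["observation/matrix/indptr"][:]
    mat = sparse.csr_matrix(
        (data, indices, indptr), shape=(len(taxon_ids), len(sample_ids))
    ).toarray()
    return AbundanceTable(tuple(taxon_ids), tuple(sample_ids), mat)


def _write_biom(table: AbundanceTable, path: str) -> None:
    import h5py
    from scipy import sparse

    csr = sparse.csr_matrix(table.counts)
    csc = csr.tocsc()
    ids = np.array([t.encode() for t in table.taxon_ids])
    sids = np.array([s.encode() for s in table.sample_ids])
    with h5py.File(path, "w") as fh:
        fh.attrs["id"] = "No Table ID"
        fh.attrs["type"] = "OTU table"
        fh.attrs["format-url"] = _BIOM_URL
        fh.attrs["format-version"] = np.array([2, 1], dtype=np.int64)
        fh.attrs["generated-by"] = "ncmkit"
        fh.attrs["creation-date"] = "1970-01-01T00:00:00"
        fh.attrs["shape"] = np.array(table.counts.shape, dtype=np.int64)
        fh.attrs["nnz"] = int(csr.nnz)
        obs = fh.create_group("observation")
        obs.create_dataset("ids", data=ids)
        om = obs.create_group("matrix")
        om.create_dataset("data", data=csr.data.astype(np.float64))
        om.create_dataset("indices", data=csr.indices.astype(np.int64))
        om.create_dataset("indptr", data=csr.indptr.astype(np.int64))
        obs.create_group("metadata")
        obs.create_group("group-metadata")
        smp = fh.create_group("sample")
        smp.create_dataset("ids", data=sids)
        sm = smp.create_group("matrix")
        sm.create_dataset("data", data=csc.data.astype(np.float64))
        sm.create_dataset("indices", data=csc.indices.astype(np.int64))
        sm.create_dataset("indptr", data=csc.indptr.astype(np.int64))
        smp.create_group("metadata")
        smp.create_group("group-metadata")


_REQUIRED_META = ("sample_id", "subject_id", "role", "body_site", "age_months", "country")
_OPTIONAL_META = ("dyad_id", "village", "village_type")


def read_metadata(path: str) -> list[SampleRecord]:
    """Read sample metadata from CSV; one :class:`SampleRecord` per row."""
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise MetadataError(f"{path}: empty metadata file")
        missing = [c for c in _REQUIRED_META if c not in reader.fieldnames]
        if missing:
            raise MetadataError(f"{path}: missing required column(s): {', '.join(missing)}")
        records: list[SampleRecord] = []
        for lineno, row in enumerate(reader, start=2):
            def opt(key: str) -> str | None:
                val = row.get(key)
                return val.strip() if val is not None and val.strip() != "" else None

            try:
                age = float(row["age_months"])
            except (TypeError, ValueError):
                raise MetadataError(
                    f"{path}:{lineno}: age_months must be numeric, got {row.get('age_months')!r}"
                ) from None
            records.append(
                SampleRecord(
                    sample_id=row["sample_id"].strip(),
                    subject_id=row["subject_id"].strip(),
                    role=row["role"].strip(),
                    body_site=row["body_site"].strip(),
                    age_months=age,
                    country=row["country"].strip(),
                    dyad_id=opt("dyad_id"),
                    village=opt("village"),
                    village_type=opt("village_type"),
                )
            )
    dups = _find_duplicates([r.sample_id for r in records])
    if dups:
        raise MetadataError(f"{path}: duplicate sample_id(s): {', '.join(dups)}")
    return records


def write_metadata(records: Iterable[SampleRecord], path: str) -> None:
    cols = list(_REQUIRED_META) + list(_OPTIONAL_META)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(cols)
        for r in records:
            writer.writerow(
                [
                    r.sample_id,
                    r.subject_id,
                    r.role,
                    r.body_site,
                    r.age_months,
                    r.country,
                    r.dyad_id or "",
                    r.village or "",
                    r.village_type or "",
                ]
            )


# ---------------------------------------------------------------------------
# cohort operations
# ---------------------------------------------------------------------------

def subset(cohort: Cohort, predicate: Callable[[SampleRecord], bool]) -> Cohort:
    """Jointly restrict table columns and metadata to samples matching ``predicate``.

    All-zero taxon rows are retained (dropping taxa is a separate concern).
    Raises :class:`MetadataError` if no sample matches.
    """
    keep = [r for r in cohort.records_aligned() if predicate(r)]
    if not keep:
        raise MetadataError("subset predicate matched no samples")
    table = cohort.table.select_samples([r.sample_id for r in keep])
    return Cohort(table, tuple(keep))


def build_source_pool(cohort: Cohort, pooling_rule: str = "pooled_counts") -> SourcePool:
    """Estimate the regional species pool from a cohort's samples.

    ``pooled_counts`` (default) sums the read counts of every sample and
    normalises the total; ``mean_of_proportions`` averages per-sample relative
    abundances. Both return proportions over the cohort's full taxon list.
    """
    counts = cohort.table.counts
    if pooling_rule == "pooled_counts":
        pooled = counts.sum(axis=1).astype(float)
        total = pooled.sum()
        if total == 0:
            raise TableError("cannot build a source pool from an all-zero table")
        p = pooled / total
    elif pooling_rule == "mean_of_proportions":
        p = cohort.table.proportions().mean(axis=1)
        p = p / p.sum()
    else:
        raise TableError(
            f"unknown pooling_rule {pooling_rule!r}; "
            "allowed: pooled_counts, mean_of_proportions"
        )
    return SourcePool(cohort.table.taxon_ids, p, cohort.n_samples, pooling_rule)


def occurrence_frequency(cohort: Cohort, min_reads_detect: int = 1) -> np.ndarray:
    """Per-taxon fraction of samples with at least ``min_reads_detect`` reads."""
    if min_reads_detect < 1:
        raise TableError(f"min_reads_detect must be >= 1, got {min_reads_detect}")
    return (cohort.table.counts >= min_reads_detect).mean(axis=1)
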