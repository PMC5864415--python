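"""Domain types and readers/writers for feature tables and sample metadata.

A :class:`FeatureTable` is a dense non-negative integer matrix of feature
(sOTU/taxon) counts, features as rows and samples as columns, optionally
annotated with a semicolon-delimited taxonomic lineage per feature.  The
canonical interchange format is TSV (features as rows, first column the
feature id, optional trailing ``taxonomy`` column); the BIOM format is
supported in both its v1 JSON and v2.1 HDF5 dialects.

Sample metadata is a QIIME-style tab-separated mapping file.  The required
columns are ``sample_id`` (``#SampleID`` is accepted as an alias) and
``control_class``; ``input_cells``, ``target_spec``, ``plate`` and ``well``
are optional.  ``control_class`` must be one of the six tokens in
:data:`CONTROL_CLASSES`; translating whatever convention a study used into
these tokens is the caller's job.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import FrozenSet, Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .errors import (
    DuplicateIdError,
    MissingInputCellsError,
    NegativeCountError,
    NonIntegerCountError,
    TableFormatError,
    UnknownControlClassError,
    UnknownSampleError,
)

CONTROL_CLASSES = frozenset(
    {
        "extraction_positive",
        "pcr_positive",
        "extraction_negative",
        "pcr_negative",
        "blank",
        "sample",
    }
)

POSITIVE_CLASSES = frozenset({"extraction_positive", "pcr_positive"})
NEGATIVE_CLASSES = frozenset({"extraction_negative", "pcr_negative", "blank"})

#: A target specification: either a lineage substring (matched
#: case-insensitively against taxonomy strings) or an explicit set of
#: feature identifiers.
TargetSpec = Union[str, FrozenSet[str]]

TAXONOMY_COLUMN = "taxonomy"


def _check_unique(ids: Sequence[str], what: str) -> None:
    if len(set(ids)) != len(ids):
        seen: set[str] = set()
        dupes = sorted({i for i in ids if i in seen or seen.add(i)})  # type: ignore[func-returns-value]
        raise DuplicateIdError(f"duplicate {what} identifiers: {dupes[:5]}")


@dataclass(eq=False)
class FeatureTable:
    """Counts of features per sample.

    Parameters
    ----------
    feature_ids, sample_ids:
        Ordered unique identifiers for the rows and columns of ``counts``.
    counts:
        Non-negative integer matrix of shape ``(n_features, n_samples)``.
    taxonomy:
        Optional mapping from feature id to a semicolon-delimited lineage
        string; may cover any subset of ``feature_ids``.
    """

    feature_ids: tuple
    sample_ids: tuple
    counts: np.ndarray
    taxonomy: Optional[Mapping[str, str]] = None

    def __post_init__(self) -> None:
        self.feature_ids = tuple(str(f) for f in self.feature_ids)
        self.sample_ids = tuple(str(s) for s in self.sample_ids)
        _check_unique(self.feature_ids, "feature")
        _check_unique(self.sample_ids, "sample")
        counts = np.asarray(self.counts)
        if counts.size == 0:
            counts = counts.reshape(len(self.feature_ids), len(self.sample_ids))
        if counts.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise TableFormatError(
                f"counts shape {counts.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        if not np.issubdtype(counts.dtype, np.integer):
            as_float = np.asarray(counts, dtype=float)
            if not np.all(np.isfinite(as_float)) or np.any(as_float != np.floor(as_float)):
                raise NonIntegerCountError("counts must be exact integers")
            counts = as_float.astype(np.int64)
        if counts.size and counts.min() < 0:
            raise NegativeCountError("counts must be non-negative")
        self.counts = np.ascontiguousarray(counts, dtype=np.int64)
        if self.taxonomy is not None:
            unknown = set(self.taxonomy) - set(self.feature_ids)
            if unknown:
                raise TableFormatError(
                    f"taxonomy given for unknown features: {sorted(unknown)[:5]}"
                )
            self.taxonomy = dict(self.taxonomy)

    # -- container protocol ------------------------------------------------

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise UnknownSampleError(sample_id) from None

    def sample_counts(self, sample_id: str) -> np.ndarray:
        return self.counts[:, self.sample_index(sample_id)]

    def depths(self) -> pd.Series:
        """Per-sample read depth (column sums)."""
        return pd.Series(
            self.counts.sum(axis=0), index=list(self.sample_ids), name="depth"
        )

    def select_samples(self, sample_ids: Iterable[str]) -> "FeatureTable":
        """Subset to the given samples, preserving this table's order."""
        keep = set(sample_ids)
        missing = keep - set(self.sample_ids)
        if missing:
            raise UnknownSampleError(sorted(missing)[0])
        idx = [i for i, s in enumerate(self.sample_ids) if s in keep]
        return FeatureTable(
            feature_ids=self.feature_ids,
            sample_ids=tuple(self.sample_ids[i] for i in idx),
            counts=self.counts[:, idx],
            taxonomy=self.taxonomy,
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FeatureTable):
            return NotImplemented
        return (
            self.feature_ids == other.feature_ids
            and self.sample_ids == other.sample_ids
            and np.array_equal(self.counts, other.counts)
            and (self.taxonomy or {}) == (other.taxonomy or {})
        )


@dataclass(frozen=True)
class SampleRecord:
    """Per-sample metadata: control class and, for positives, the known input.

    ``input_cells`` is the number of spiked cells for extraction controls and
    genome copies for PCR controls; it must be present exactly for positive
    control classes.  ``target_spec`` names the expected organism of a
    positive control, as a lineage substring or explicit feature-id set.
    """

    sample_id: str
    control_class: str
    input_cells: Optional[float] = None
    target_spec: Optional[TargetSpec] = None
    plate: Optional[str] = None
    well: Optional[str] = None

    def __post_init__(self) -> None:
        if self.control_class not in CONTROL_CLASSES:
            raise UnknownControlClassError(
                f"{self.sample_id!r}: unknown control_class "
                f"{self.control_class!r}; expected one of {sorted(CONTROL_CLASSES)}"
            )
        is_positive = self.control_class in POSITIVE_CLASSES
        if is_positive and self.input_cells is None:
            raise MissingInputCellsError(
                f"positive control {self.sample_id!r} lacks input_cells"
            )
        if not is_positive and self.input_cells is not None:
            raise MissingInputCellsError(
                f"{self.sample_id!r} is not a positive control but has input_cells"
            )
        if self.input_cells is not None and self.input_cells < 0:
            raise MissingInputCellsError(
                f"{self.sample_id!r}: input_cells must be non-negative"
            )


@dataclass
class StudyDesign:
    """The set of :class:`SampleRecord` of one study, keyed by sample id."""

    records: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for sid, rec in self.records.items():
            if sid != rec.sample_id:
                raise DuplicateIdError(f"record key {sid!r} != sample_id {rec.sample_id!r}")

    @property
    def titration_levels(self) -> tuple:
        """Sorted distinct input_cells values among positive controls."""
        levels = {
            r.input_cells
            for r in self.records.values()
            if r.control_class in POSITIVE_CLASSES and r.input_cells is not None
        }
        return tuple(sorted(levels))

    def sample_ids_of_class(self, classes: Union[str, Iterable[str]]) -> tuple:
        if isinstance(classes, str):
            classes = {classes}
        classes = set(classes)
        return tuple(
            sid for sid, r in self.records.items() if r.control_class in classes
        )

    def __getitem__(self, sample_id: str) -> SampleRecord:
        return self.records[sample_id]

    def __contains__(self, sample_id: str) -> bool:
        return sample_id in self.records

    def __len__(self) -> int:
        return len(self.records)


# ---------------------------------------------------------------------------
# Feature-table I/O
# ---------------------------------------------------------------------------

def read_feature_table(path, format: str = "tsv") -> FeatureTable:
    """Read a feature table from ``path``.

    ``format='tsv'`` expects features as rows, samples as columns, the
    first column holding feature ids and an optional final ``taxonomy``
    column.  ``format='biom'`` auto-detects the v1 (JSON) and v2.1 (HDF5)
    dialects.
    """
    path = Path(path)
    if format == "tsv":
        return _read_tsv(path)
    if format == "biom":
        from ._biom import read_biom

        return read_biom(path)
    raise TableFormatError(f"unknown feature-table format {format!r}")


def write_feature_table(table: FeatureTable, path, format: str = "tsv") -> None:
    """Write ``table`` to ``path``; output is bit-stable for a fixed table."""
    path = Path(path)
    if format == "tsv":
        _write_tsv(table, path)
    elif format == "biom":
        from ._biom import write_biom

        write_biom(table, path, dialect="json")
    elif format == "biom-hdf5":
        from ._biom import write_biom

        write_biom(table, path, dialect="hdf5")
    else:
        raise TableFormatError(f"unknown feature-table format {format!r}")


def _read_tsv(path: Path) -> FeatureTable:
    # pandas silently de-duplicates repeated header names; check them raw
    with open(path) as fh:
        header_line = fh.readline().rstrip("\n")
    if header_line.strip():
        _check_unique(header_line.split("\t"), "header")
    try:
        df = pd.read_csv(
            path, sep="\t", header=0, dtype=str, comment=None, skip_blank_lines=True
        )
    except pd.errors.EmptyDataError:
        raise TableFormatError(f"{path}: empty file, no header") from None
    if df.shape[1] < 1:
        raise TableFormatError(f"{path}: header has no columns")
    columns = list(df.columns)
    has_taxonomy = len(columns) > 1 and columns[-1].lower() == TAXONOMY_COLUMN
    sample_cols = columns[1 : -1 if has_taxonomy else len(columns)]
    _check_unique(sample_cols, "sample")
    feature_ids = [str(v) for v in df.iloc[:, 0]]
    _check_unique(feature_ids, "feature")

    counts = np.zeros((len(feature_ids), len(sample_cols)), dtype=np.int64)
    for j, col in enumerate(sample_cols):
        for i, raw in enumerate(df[col]):
            counts[i, j] = _parse_count(raw, path, feature_ids[i], col)
    taxonomy = None
    if has_taxonomy:
        taxonomy = {
            fid: str(tax)
            for fid, tax in zip(feature_ids, df.iloc[:, -1])
            if not (isinstance(tax, float) and math.isnan(tax))
        }
    return FeatureTable(
        feature_ids=tuple(feature_ids),
        sample_ids=tuple(sample_cols),
        counts=counts,
        taxonomy=taxonomy,
    )


def _parse_count(raw, path: Path, feature: str, sample: str):
    try:
        value = float(raw)
    except (TypeError, ValueError):
        raise NonIntegerCountError(
            f"{path}: non-numeric count {raw!r} at ({feature}, {sample})"
        ) from None
    if not math.isfinite(value) or value != math.floor(value):
        raise NonIntegerCountError(
            f"{path}: fractional count {raw!r} at ({feature}, {sample}); "
            "counts are exact integers and are not rounded"
        )
    if value < 0:
        raise NegativeCountError(
            f"{path}: negative count {raw!r} at ({feature}, {sample})"
        )
    return int(value)


def _write_tsv(table: FeatureTable, path: Path) -> None:
    with open(path, "w", newline="") as fh:
        header = ["#OTU ID", *table.sample_ids]
        if table.taxonomy is not None:
            header.append(TAXONOMY_COLUMN)
        fh.write("\t".join(header) + "\n")
        for i, fid in enumerate(table.feature_ids):
            row = [fid, *(str(int(c)) for c in table.counts[i])]
            if table.taxonomy is not None:
                row.append(table.taxonomy.get(fid, ""))
            fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# Sample-map I/O
# ---------------------------------------------------------------------------

_SAMPLE_ID_ALIASES = ("sample_id", "#SampleID", "#sampleid", "sampleid")


def parse_target_spec(raw: Optional[str]) -> Optional[TargetSpec]:
    """Parse a metadata target specification.

    Values prefixed ``ids:`` are comma-separated explicit feature ids;
    anything else is a lineage substring.
    """
    if raw is None:
        return None
    raw = raw.strip()
    if not raw:
        return None
    if raw.startswith("ids:"):
        ids = [t.strip() for t in raw[4:].split(",") if t.strip()]
        return frozenset(ids)
    return raw


def format_target_spec(spec: Optional[TargetSpec]) -> str:
    if spec is None:
        return ""
    if isinstance(spec, str):
        return spec
    return "ids:" + ",".join(sorted(spec))


def read_metadata(path) -> StudyDesign:
    """Read a QIIME-style tab-separated sample map into a :class:`StudyDesign`."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", header=0, dtype=str)
    except pd.errors.EmptyDataError:
        raise TableFormatError(f"{path}: empty metadata file") from None
    cols = {c.lower(): c for c in df.columns}
    id_col = None
    for alias in _SAMPLE_ID_ALIASES:
        if alias.lower() in cols:
            id_col = cols[alias.lower()]
            break
    if id_col is None:
        raise TableFormatError(
            f"{path}: no sample_id column (accepted aliases: {_SAMPLE_ID_ALIASES})"
        )
    if "control_class" not in cols:
        raise TableFormatError(f"{path}: missing required column control_class")

    def _get(row, name):
        col = cols.get(name)
        if col is None:
            return None
        value = row[col]
        if isinstance(value, float) and math.isnan(value):
            return None
        value = str(value).strip()
        return value or None

    records = {}
    for _, row in df.iterrows():
        sid = str(row[id_col]).strip()
        cells_raw = _get(row, "input_cells")
        rec = SampleRecord(
            sample_id=sid,
            control_class=str(row[cols["control_class"]]).strip(),
            input_cells=float(cells_raw) if cells_raw is not None else None,
            target_spec=parse_target_spec(_get(row, "target_spec")),
            plate=_get(row, "plate"),
            well=_get(row, "well"),
        )
        if sid in records:
            raise DuplicateIdError(f"{path}: duplicate sample_id {sid!r}")
        records[sid] = rec
    return StudyDesign(records=records)


def write_metadata(design: StudyDesign, path) -> None:
    """Write a :class:`StudyDesign` as a tab-separated sample map."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        fh.write("sample_id\tcontrol_class\tinput_cells\ttarget_spec\tplate\twell\n")
        for sid, rec in design.records.items():
            cells = "" if rec.input_cells is None else _fmt_cells(rec.input_cells)
            fh.write(
                "\t".join(
                    [
                        sid,
                        rec.control_class,
                        cells,
                        format_target_spec(rec.target_spec),
                        rec.plate or "",
                        rec.well or "",
                    ]
                )
                + "\n"
            )


def _fmt_cells(value: float) -> str:
    return str(int(value)) if float(value).is_integer() else repr(float(value))
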