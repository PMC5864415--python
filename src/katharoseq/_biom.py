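"""Minimal BIOM feature-table I/O (v1 JSON and v2.1 HDF5 dialects).

Implements just enough of the Biological Observation Matrix format to
exchange count tables with the wider ecosystem: sparse and dense v1 JSON
matrices, and the CSR-by-observation layout of v2.1 HDF5 files.  Taxonomy
is read from observation metadata (either a ``taxonomy`` list of ranks or a
single lineage string) and written back as a semicolon-delimited lineage.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .errors import TableFormatError

_HDF5_MAGIC = b"\x89HDF\r\n\x1a\n"
_V1_FORMAT = "Biological Observation Matrix 1.0.0"
_FORMAT_URL = "http://biom-format.org"
# fixed timestamp keeps written files bit-stable for identical tables
_EPOCH = "1970-01-01T00:00:00"


def read_biom(path):
    path = Path(path)
    with open(path, "rb") as fh:
        magic = fh.read(8)
    if magic == _HDF5_MAGIC:
        return _read_hdf5(path)
    return _read_json(path)


def write_biom(table, path, dialect: str = "json") -> None:
    if dialect == "json":
        _write_json(table, Path(path))
    elif dialect == "hdf5":
        _write_hdf5(table, Path(path))
    else:
        raise TableFormatError(f"unknown BIOM dialect {dialect!r}")


# ---------------------------------------------------------------------------
# v1 JSON
# ---------------------------------------------------------------------------

def _lineage_from_metadata(metadata) -> str | None:
    if not metadata:
        return None
    tax = metadata.get("taxonomy")
    if tax is None:
        return None
    if isinstance(tax, str):
        return tax
    return "; ".join(str(t) for t in tax)


def _read_json(path: Path):
    from .data_model import FeatureTable

    try:
        with open(path) as fh:
            doc = json.load(fh)
    except (json.JSONDecodeError, UnicodeDecodeError) as exc:
        raise TableFormatError(f"{path}: not a BIOM file ({exc})") from None
    try:
        shape = tuple(doc["shape"])
        rows, cols = doc["rows"], doc["columns"]
        matrix_type = doc["matrix_type"]
        data = doc["data"]
    except KeyError as exc:
        raise TableFormatError(f"{path}: BIOM JSON missing key {exc}") from None
    if len(rows) != shape[0] or len(cols) != shape[1]:
        raise TableFormatError(f"{path}: BIOM shape {shape} disagrees with row/column lists")
    counts = np.zeros(shape, dtype=np.int64)
    if matrix_type == "sparse":
        for i, j, v in data:
            counts[int(i), int(j)] = v
    elif matrix_type == "dense":
        counts[:] = np.asarray(data)
    else:
        raise TableFormatError(f"{path}: unknown matrix_type {matrix_type!r}")
    taxonomy = {}
    for row in rows:
        lineage = _lineage_from_metadata(row.get("metadata"))
        if lineage is not None:
            taxonomy[str(row["id"])] = lineage
    return FeatureTable(
        feature_ids=tuple(str(r["id"]) for r in rows),
        sample_ids=tuple(str(c["id"]) for c in cols),
        counts=counts,
        taxonomy=taxonomy or None,
    )


def _write_json(table, path: Path) -> None:
    rows = []
    for fid in table.feature_ids:
        metadata = None
        if table.taxonomy is not None and fid in table.taxonomy:
            # stored as the verbatim lineage string; rank lists written by
            # other tools are still accepted on read
            metadata = {"taxonomy": table.taxonomy[fid]}
        rows.append({"id": fid, "metadata": metadata})
    nz = np.nonzero(table.counts)
    data = [
        [int(i), int(j), int(table.counts[i, j])] for i, j in zip(*nz)
    ]
    doc = {
        "id": None,
        "format": _V1_FORMAT,
        "format_url": _FORMAT_URL,
        "type": "OTU table",
        "generated_by": "katharoseq",
        "date": _EPOCH,
        "matrix_type": "sparse",
        "matrix_element_type": "int",
        "shape": [table.n_features, table.n_samples],
        "rows": rows,
        "columns": [{"id": sid, "metadata": None} for sid in table.sample_ids],
        "data": data,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, separators=(",", ":"), sort_keys=False)


# ---------------------------------------------------------------------------
# v2.1 HDF5
# ---------------------------------------------------------------------------

def _decode(value) -> str:
    return value.decode() if isinstance(value, bytes) else str(value)


def _read_hdf5(path: Path):
    from .data_model import FeatureTable
    from scipy import sparse

    with h5py.File(path, "r") as fh:
        try:
            obs_ids = [_decode(v) for v in fh["observation/ids"][()]]
            sample_ids = [_decode(v) for v in fh["sample/ids"][()]]
            grp = fh["observation/matrix"]
            matrix = sparse.csr_matrix(
                (grp["data"][()], grp["indices"][()], grp["indptr"][()]),
                shape=(len(obs_ids), len(sample_ids)),
            )
        except KeyError as exc:
            raise TableFormatError(f"{path}: BIOM HDF5 missing {exc}") from None
        taxonomy = None
        if "observation/metadata/taxonomy" in fh:
            ds = fh["observation/metadata/taxonomy"]
            raw = ds[()]
            taxonomy = {}
            for fid, entry in zip(obs_ids, raw):
                if isinstance(entry, np.ndarray):
                    lineage = "; ".join(_decode(t) for t in entry)
                else:
                    lineage = _decode(entry)
                taxonomy[fid] = lineage
    counts = np.asarray(matrix.todense())
    return FeatureTable(
        feature_ids=tuple(obs_ids),
        sample_ids=tuple(sample_ids),
        counts=counts,
        taxonomy=taxonomy,
    )


def _write_hdf5(table, path: Path) -> None:
    from scipy import sparse

    csr = sparse.csr_matrix(table.counts)
    csc = csr.tocsc()
    str_t = h5py.string_dtype()
    with h5py.File(path, "w") as fh:
        fh.attrs["id"] = "No Table ID"
        fh.attrs["type"] = "OTU table"
        fh.attrs["format-url"] = _FORMAT_URL
        fh.attrs["format-version"] = np.array([2, 1], dtype=np.int64)
        fh.attrs["generated-by"] = "katharoseq"
        fh.attrs["creation-date"] = _EPOCH
        fh.attrs["shape"] = np.array(
            [table.n_features, table.n_samples], dtype=np.int64
        )
        fh.attrs["nnz"] = int(csr.nnz)
        fh.create_dataset(
            "observation/ids", data=np.array(table.feature_ids, dtype=str_t)
        )
        fh.create_dataset("observation/matrix/data", data=csr.data.astype(np.float64))
        fh.create_dataset("observation/matrix/indices", data=csr.indices.astype(np.int64))
        fh.create_dataset("observation/matrix/indptr", data=csr.indptr.astype(np.int64))
        fh.create_group("observation/group-metadata")
        fh.create_dataset("sample/ids", data=np.array(table.sample_ids, dtype=str_t))
        fh.create_dataset("sample/matrix/data", data=csc.data.astype(np.float64))
        fh.create_dataset("sample/matrix/indices", data=csc.indices.astype(np.int64))
        fh.create_dataset("sample/matrix/indptr", data=csc.indptr.astype(np.int64))
        fh.create_group("sample/metadata")
        fh.create_group("sample/group-metadata")
        if table.taxonomy is not None:
            lineages = np.array(
                [table.taxonomy.get(fid, "") for fid in table.feature_ids],
                dtype=str_t,
            )
            fh.create_dataset("observation/metadata/taxonomy", data=lineages)
        else:
            fh.create_group("observation/metadata")
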