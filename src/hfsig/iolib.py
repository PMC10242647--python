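"""Validated container types and readers/writers for every on-disk format
the pipeline touches.

Formats supported:

* expression matrices as TSV (genes in rows, first column = gene ids,
  header row = sample/cell ids) or MatrixMarket MTX with ``genes.txt`` /
  ``barcodes.txt`` sidecars,
* gene-set collections as GMT,
* sample / cell metadata as TSV,
* result objects as versioned JSON reports.

Parsers reject malformed input rather than coercing it; error messages carry
the offending identifier or line number.  Gene identifiers are opaque,
case-sensitive strings — no alias resolution is attempted.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

REPORT_SCHEMA_VERSION = "1"

__all__ = [
    "FormatError",
    "ValidationError",
    "ExpressionMatrix",
    "GeneSet",
    "GeneSetCollection",
    "BulkCohort",
    "CellCohort",
    "read_matrix",
    "read_matrix_tsv",
    "write_matrix_tsv",
    "read_matrix_mtx",
    "write_matrix_mtx",
    "read_gmt",
    "write_gmt",
    "read_metadata_tsv",
    "write_metadata_tsv",
    "read_bulk_cohort",
    "write_bulk_cohort",
    "write_report",
    "sha256_file",
]


class FormatError(ValueError):
    """A file does not conform to its declared format."""


class ValidationError(ValueError):
    """Parsed content violates a container invariant."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    dups: list[str] = []
    for i in ids:
        if i in seen:
            dups.append(i)
        seen.add(i)
    if dups:
        raise ValidationError(f"duplicate {what}: {sorted(set(dups))}")


@dataclass
class ExpressionMatrix:
    """A genes x columns expression matrix.

    ``layer`` is ``"counts"`` for raw (non-negative) values and ``"lognorm"``
    for log-normalized values.
    """

    gene_ids: list[str]
    column_ids: list[str]
    values: np.ndarray
    layer: str = "counts"

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.column_ids = [str(c) for c in self.column_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.layer not in ("counts", "lognorm"):
            raise ValidationError(f"unknown layer tag {self.layer!r}")
        _check_unique(self.gene_ids, "gene ids")
        _check_unique(self.column_ids, "column ids")
        if self.values.shape != (len(self.gene_ids), len(self.column_ids)):
            raise ValidationError(
                f"value shape {self.values.shape} inconsistent with "
                f"{len(self.gene_ids)} genes x {len(self.column_ids)} columns"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("matrix contains non-finite values")
        if self.layer == "counts" and np.any(self.values < 0):
            raise ValidationError("counts layer contains negative values")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_columns(self) -> int:
        return len(self.column_ids)

    def gene_index(self, genes: Sequence[str]) -> np.ndarray:
        lut = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in lut]
        if missing:
            raise ValidationError(f"genes not in matrix: {missing[:10]}")
        return np.array([lut[g] for g in genes], dtype=int)

    def column_index(self, columns: Sequence[str]) -> np.ndarray:
        lut = {c: i for i, c in enumerate(self.column_ids)}
        missing = [c for c in columns if c not in lut]
        if missing:
            raise ValidationError(f"columns not in matrix: {missing[:10]}")
        return np.array([lut[c] for c in columns], dtype=int)

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        idx = self.gene_index(genes)
        return ExpressionMatrix(list(genes), list(self.column_ids), self.values[idx, :], self.layer)

    def subset_columns(self, columns: Sequence[str]) -> "ExpressionMatrix":
        idx = self.column_index(columns)
        return ExpressionMatrix(list(self.gene_ids), list(columns), self.values[:, idx], self.layer)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.column_ids)


@dataclass(frozen=True)
class GeneSet:
    name: str
    category: str
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValidationError(f"gene set {self.name!r} has no members")


@dataclass
class GeneSetCollection:
    """Named gene sets with category labels (GOBP/KEGG/Hallmark/Reactome-style)."""

    sets: dict[str, GeneSet] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, gs in self.sets.items():
            if name != gs.name:
                raise ValidationError(f"key {name!r} != set name {gs.name!r}")

    def add(self, gs: GeneSet) -> None:
        if gs.name in self.sets:
            raise ValidationError(f"duplicate gene set name {gs.name!r}")
        self.sets[gs.name] = gs

    def names(self) -> list[str]:
        return list(self.sets)

    def categories(self) -> list[str]:
        out: list[str] = []
        for gs in self.sets.values():
            if gs.category not in out:
                out.append(gs.category)
        return out

    def subset_by_category(self, category: str) -> "GeneSetCollection":
        return GeneSetCollection(
            {n: g for n, g in self.sets.items() if g.category == category}
        )

    def all_genes(self) -> set[str]:
        out: set[str] = set()
        for gs in self.sets.values():
            out.update(gs.members)
        return out

    def __len__(self) -> int:
        return len(self.sets)

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def __getitem__(self, name: str) -> GeneSet:
        return self.sets[name]


@dataclass
class BulkCohort:
    """A genes x samples matrix plus binary class labels.

    ``labels`` maps every matrix column to ``"positive"`` or ``"negative"``.
    """

    matrix: ExpressionMatrix
    labels: pd.Series

    def __post_init__(self) -> None:
        self.labels = pd.Series(self.labels)
        missing = [c for c in self.matrix.column_ids if c not in self.labels.index]
        if missing:
            raise ValidationError(f"samples without class label: {missing[:10]}")
        bad = sorted(set(self.labels) - {"positive", "negative"})
        if bad:
            raise ValidationError(f"class labels must be positive/negative, got {bad}")
        self.labels = self.labels.loc[self.matrix.column_ids]

    @property
    def y(self) -> np.ndarray:
        """Boolean vector aligned to matrix columns; True = positive class."""
        return (self.labels.to_numpy() == "positive")


@dataclass
class CellCohort:
    """A genes x cells matrix plus per-cell metadata.

    ``obs`` is indexed by cell id with columns cell_type, subcluster,
    condition, donor.
    """

    matrix: ExpressionMatrix
    obs: pd.DataFrame

    REQUIRED = ("cell_type", "subcluster", "condition", "donor")

    def __post_init__(self) -> None:
        for col in self.REQUIRED:
            if col not in self.obs.columns:
                raise ValidationError(f"cell metadata missing column {col!r}")
        missing = [c for c in self.matrix.column_ids if c not in self.obs.index]
        if missing:
            raise ValidationError(f"cells without metadata: {missing[:10]}")
        self.obs = self.obs.loc[self.matrix.column_ids]

    def cluster_labels(self) -> pd.Series:
        return self.obs["cell_type"].astype(str) + "_" + self.obs["subcluster"].astype(str)


# ---------------------------------------------------------------------------
# matrix IO


def read_matrix_tsv(path: str | Path, layer: str = "counts") -> ExpressionMatrix:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
        if not header:
            raise FormatError(f"{path}: empty file")
        columns = header.rstrip("\n").split("\t")[1:]
        n_fields = len(columns) + 1
        gene_ids: list[str] = []
        rows: list[list[float]] = []
        for lineno, line in enumerate(fh, start=2):
            fields = line.rstrip("\n").split("\t")
            if line.strip() == "":
                continue
            if len(fields) != n_fields:
                raise FormatError(
                    f"{path}: line {lineno}: expected {n_fields} fields, got {len(fields)}"
                )
            gene_ids.append(fields[0])
            try:
                rows.append([float(v) for v in fields[1:]])
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from exc
    dup = pd.Index(gene_ids)[pd.Index(gene_ids).duplicated()]
    if len(dup):
        raise FormatError(f"{path}: duplicate gene ids: {sorted(set(dup))}")
    values = np.array(rows, dtype=float) if rows else np.zeros((0, len(columns)))
    return ExpressionMatrix(gene_ids, columns, values, layer)


def write_matrix_tsv(m: ExpressionMatrix, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("gene\t" + "\t".join(m.column_ids) + "\n")
        for g, row in zip(m.gene_ids, m.values):
            fh.write(g + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


def read_matrix_mtx(
    mtx_path: str | Path,
    genes_path: str | Path | None = None,
    barcodes_path: str | Path | None = None,
    layer: str = "counts",
) -> ExpressionMatrix:
    mtx_path = Path(mtx_path)
    genes_path = Path(genes_path) if genes_path else mtx_path.parent / "genes.txt"
    barcodes_path = Path(barcodes_path) if barcodes_path else mtx_path.parent / "barcodes.txt"
    mat = scipy.io.mmread(str(mtx_path))
    if scipy.sparse.issparse(mat):
        mat = mat.toarray()
    gene_ids = [ln.strip() for ln in open(genes_path) if ln.strip()]
    column_ids = [ln.strip() for ln in open(barcodes_path) if ln.strip()]
    if mat.shape != (len(gene_ids), len(column_ids)):
        raise FormatError(
            f"{mtx_path}: shape {mat.shape} does not match sidecars "
            f"({len(gene_ids)} genes, {len(column_ids)} barcodes)"
        )
    return ExpressionMatrix(gene_ids, column_ids, np.asarray(mat, dtype=float), layer)


def write_matrix_mtx(m: ExpressionMatrix, mtx_path: str | Path) -> None:
    mtx_path = Path(mtx_path)
    scipy.io.mmwrite(str(mtx_path), scipy.sparse.coo_matrix(m.values))
    with open(mtx_path.parent / "genes.txt", "w") as fh:
        fh.write("\n".join(m.gene_ids) + "\n")
    with open(mtx_path.parent / "barcodes.txt", "w") as fh:
        fh.write("\n".join(m.column_ids) + "\n")


def read_matrix(path: str | Path, fmt: str = "tsv", layer: str = "counts") -> ExpressionMatrix:
    if fmt == "tsv":
        return read_matrix_tsv(path, layer=layer)
    if fmt == "mtx":
        return read_matrix_mtx(path, layer=layer)
    raise ValueError(f"unknown matrix format {fmt!r}")


# ---------------------------------------------------------------------------
# GMT


def read_gmt(path: str | Path, category: str = "default") -> GeneSetCollection:
    """Read a GMT file: one set per line, ``name<TAB>description<TAB>members...``.

    The description field is used as the set category when it is non-empty.
    """
    path = Path(path)
    coll = GeneSetCollection()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.strip() == "":
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}: line {lineno}: expected >= 3 tab-separated fields, got {len(fields)}"
                )
            name, desc, members = fields[0], fields[1], tuple(f for f in fields[2:] if f)
            if not members:
                raise FormatError(f"{path}: line {lineno}: gene set {name!r} has no members")
            if name in coll:
                raise FormatError(f"{path}: line {lineno}: duplicate set name {name!r}")
            coll.add(GeneSet(name, desc if desc else category, members))
    return coll


def write_gmt(coll: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for gs in coll.sets.values():
            fh.write(gs.name + "\t" + gs.category + "\t" + "\t".join(gs.members) + "\n")


# ---------------------------------------------------------------------------
# metadata


def read_metadata_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "id" not in df.columns:
        raise FormatError(f"{path}: metadata must have an 'id' column")
    if df["id"].duplicated().any():
        dups = sorted(df.loc[df["id"].duplicated(), "id"].unique())
        raise FormatError(f"{path}: duplicate ids: {dups}")
    return df.set_index("id")


def write_metadata_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label="id")


def read_bulk_cohort(matrix_path: str | Path, labels_path: str | Path,
                     layer: str = "lognorm") -> BulkCohort:
    m = read_matrix_tsv(matrix_path, layer=layer)
    meta = read_metadata_tsv(labels_path)
    if "class_label" not in meta.columns:
        raise FormatError(f"{labels_path}: metadata must have a 'class_label' column")
    return BulkCohort(m, meta["class_label"])


def write_bulk_cohort(cohort: BulkCohort, matrix_path: str | Path,
                      labels_path: str | Path) -> None:
    write_matrix_tsv(cohort.matrix, matrix_path)
    write_metadata_tsv(cohort.labels.rename("class_label").to_frame(), labels_path)


# ---------------------------------------------------------------------------
# JSON reports


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _jsonable(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.bool_):
        return bool(obj)
    if isinstance(obj, pd.Series):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, pd.DataFrame):
        return _jsonable(obj.to_dict(orient="list"))
    if isinstance(obj, Path):
        return str(obj)
    return obj


def write_report(obj, path: str | Path, *, kind: str | None = None,
                 extra: Mapping | None = None) -> None:
    """Serialize a result object as a versioned, byte-stable JSON report."""
    payload = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "kind": kind if kind is not None else type(obj).__name__,
        "result": _jsonable(obj),
    }
    if extra:
        payload.update(_jsonable(dict(extra)))
    path = Path(path)
    try:
        with open(path, "w") as fh:
            json.dump(payload, fh, sort_keys=True, indent=2)
            fh.write("\n")
    except OSError as exc:
        raise IOError(f"cannot write report to {path}: {exc}") from exc


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()
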