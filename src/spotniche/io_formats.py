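"""Readers and writers for the on-disk artifacts the pipeline touches.

Supported formats: MatrixMarket coordinate-integer bundles (matrix.mtx +
features.tsv + barcodes.tsv), spaceranger-style ``tissue_positions.csv``
(with or without header), GMT gene-set files and plain TSV result tables.
Gene identity is the symbol string, case-sensitive; no alias resolution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

logger = logging.getLogger(__name__)

POSITIONS_COLUMNS = [
    "barcode",
    "in_tissue",
    "array_row",
    "array_col",
    "pxl_row_in_fullres",
    "pxl_col_in_fullres",
]


class FormatError(ValueError):
    """A file violates the contract of its declared format."""


@dataclass
class SpotTable:
    """Spot identities with hex-array and full-resolution pixel coordinates.

    ``array_row``/``array_col`` are 0-based offsets on the hex lattice with
    the even-parity convention: every spot satisfies (row + col) % 2 == 0.
    ``pixel_x`` maps to ``pxl_col_in_fullres`` and ``pixel_y`` to
    ``pxl_row_in_fullres`` (image convention).
    """

    frame: pd.DataFrame  # columns: spot_id, array_row, array_col, pixel_x, pixel_y, in_tissue

    def __post_init__(self) -> None:
        f = self.frame
        required = ["spot_id", "array_row", "array_col", "pixel_x", "pixel_y", "in_tissue"]
        missing = [c for c in required if c not in f.columns]
        if missing:
            raise FormatError(f"SpotTable missing columns: {missing}")
        if f["spot_id"].duplicated().any():
            dup = f.loc[f["spot_id"].duplicated(), "spot_id"].iloc[0]
            raise FormatError(f"duplicate spot barcode: {dup!r}")
        parity = (f["array_row"].to_numpy() + f["array_col"].to_numpy()) % 2
        if (parity != 0).any():
            bad = f.loc[parity != 0, "spot_id"].iloc[0]
            raise FormatError(f"odd (row+col) parity for barcode {bad!r}")
        coords = f[["array_row", "array_col"]].apply(tuple, axis=1)
        if coords.duplicated().any():
            raise FormatError("two spots share the same (array_row, array_col)")
        self.frame = f.reset_index(drop=True)

    @property
    def spot_ids(self) -> list[str]:
        return self.frame["spot_id"].tolist()

    def __len__(self) -> int:
        return len(self.frame)


@dataclass
class CountMatrix:
    """Gene x spot raw UMI counts, stored sparse (CSR)."""

    gene_ids: list[str]
    spot_ids: list[str]
    counts: sp.csr_matrix

    def __post_init__(self) -> None:
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise FormatError("gene_ids are not unique")
        if len(set(self.spot_ids)) != len(self.spot_ids):
            raise FormatError("spot_ids are not unique")
        self.counts = sp.csr_matrix(self.counts)
        if self.counts.shape != (len(self.gene_ids), len(self.spot_ids)):
            raise FormatError(
                f"count matrix shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.spot_ids)} spots"
            )
        data = self.counts.data
        if data.size and (data < 0).any():
            raise FormatError("negative counts")
        if data.size and not np.allclose(data, np.round(data)):
            raise FormatError("non-integer counts")

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def gene_index(self, gene: str) -> int:
        try:
            return self.gene_ids.index(gene)
        except ValueError:
            raise KeyError(gene) from None

    def gene_counts(self, gene: str) -> np.ndarray:
        """Dense count vector across spots for one gene."""
        return np.asarray(self.counts[self.gene_index(gene)].todense()).ravel()

    def dense(self) -> np.ndarray:
        return np.asarray(self.counts.todense())


@dataclass
class GeneSetCollection:
    """Named gene sets (signatures), e.g. parsed from a GMT file."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise FormatError(f"gene set {name!r} is empty")
            if len(set(genes)) != len(genes):
                raise FormatError(f"gene set {name!r} has duplicate members")

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def names(self) -> list[str]:
        return list(self.sets)


def _dedupe_symbols(symbols: list[str]) -> list[str]:
    """Disambiguate duplicate symbols in file order: second copy gets '.1', third '.2', ..."""
    seen: dict[str, int] = {}
    out = []
    for s in symbols:
        n = seen.get(s, 0)
        out.append(s if n == 0 else f"{s}.{n}")
        seen[s] = n + 1
    return out


def read_mtx_bundle(matrix_path, features_path, barcodes_path) -> CountMatrix:
    """Read a MatrixMarket coordinate matrix with its feature and barcode sidecars.

    Features files may carry extra tab-separated columns (10x style id/symbol/type);
    the symbol column (second if present, else first) is used.
    """
    mat = scipy.io.mmread(str(matrix_path))
    mat = sp.coo_matrix(mat)
    if mat.data.size and not np.allclose(mat.data, np.round(mat.data)):
        raise FormatError(f"{matrix_path}: matrix contains non-integer values")

    def _read_lines(path):
        with open(path, encoding="utf-8") as fh:
            return [ln.rstrip("\n") for ln in fh if ln.strip()]

    feat_lines = _read_lines(features_path)
    symbols = []
    for ln in feat_lines:
        parts = ln.split("\t")
        symbols.append(parts[1] if len(parts) >= 2 else parts[0])
    barcodes = [ln.split("\t")[0] for ln in _read_lines(barcodes_path)]
    if mat.shape != (len(symbols), len(barcodes)):
        raise FormatError(
            f"dimension mismatch: {matrix_path} declares {mat.shape}, but "
            f"{features_path} has {len(symbols)} rows and {barcodes_path} has {len(barcodes)} rows"
        )
    return CountMatrix(_dedupe_symbols(symbols), barcodes, mat.tocsr())


def write_mtx_bundle(cm: CountMatrix, matrix_path, features_path, barcodes_path) -> None:
    scipy.io.mmwrite(str(matrix_path), sp.coo_matrix(cm.counts), field="integer")
    with open(features_path, "w", encoding="utf-8") as fh:
        for g in cm.gene_ids:
            fh.write(f"{g}\t{g}\tGene Expression\n")
    with open(barcodes_path, "w", encoding="utf-8") as fh:
        for b in cm.spot_ids:
            fh.write(b + "\n")


def read_positions(path) -> SpotTable:
    """Read a tissue_positions.csv table; the header row is optional.

    Expected columns in order: barcode, in_tissue, array_row, array_col,
    pxl_row_in_fullres, pxl_col_in_fullres. Out-of-tissue spots are retained
    and flagged via ``in_tissue``.
    """
    with open(path, encoding="utf-8") as fh:
        first = fh.readline()
    has_header = first.split(",")[0].strip().lower() in {"barcode", "spot_id"}
    df = pd.read_csv(
        path,
        header=0 if has_header else None,
        names=POSITIONS_COLUMNS,
    )
    frame = pd.DataFrame(
        {
            "spot_id": df["barcode"].astype(str),
            "array_row": df["array_row"].astype(int),
            "array_col": df["array_col"].astype(int),
            "pixel_x": df["pxl_col_in_fullres"].astype(float),
            "pixel_y": df["pxl_row_in_fullres"].astype(float),
            "in_tissue": df["in_tissue"].astype(int).astype(bool),
        }
    )
    return SpotTable(frame)


def write_positions(spot_table: SpotTable, path) -> None:
    f = spot_table.frame
    out = pd.DataFrame(
        {
            "barcode": f["spot_id"],
            "in_tissue": f["in_tissue"].astype(int),
            "array_row": f["array_row"],
            "array_col": f["array_col"],
            "pxl_row_in_fullres": f["pixel_y"],
            "pxl_col_in_fullres": f["pixel_x"],
        }
    )
    out.to_csv(path, index=False, lineterminator="\n")


def read_gmt(path) -> GeneSetCollection:
    """Parse a GMT file: name <tab> description <tab> gene1 <tab> gene2 ...

    Duplicate genes within a set are dropped keeping first occurrence; the
    number dropped is logged.
    """
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}: line {lineno} has fewer than 3 fields")
            name, desc, genes = parts[0], parts[1], parts[2:]
            genes = [g for g in genes if g]
            deduped = list(dict.fromkeys(genes))
            n_dup = len(genes) - len(deduped)
            if n_dup:
                logger.info("gene set %s: %d duplicate gene(s) dropped", name, n_dup)
            if name in sets:
                raise FormatError(f"{path}: duplicate set name {name!r} at line {lineno}")
            sets[name] = deduped
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, genes in collection.sets.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *genes]) + "\n")


def _format_value(v) -> str:
    if v is None or (isinstance(v, float) and np.isnan(v)):
        return ""
    if isinstance(v, (bool, np.bool_)):
        return "True" if v else "False"
    if isinstance(v, (int, np.integer)):
        return str(int(v))
    if isinstance(v, (float, np.floating)):
        return f"{float(v):.6g}"
    return str(v)


def write_table(records, path, columns=None) -> None:
    """Write records (sequence of mappings or a DataFrame) as a UTF-8 TSV.

    Floats are rendered with 6 significant digits; the column order is the
    schema order of the first record (or the explicit ``columns``, required
    when the record list is empty). All records must share one schema.
    """
    if isinstance(records, pd.DataFrame):
        columns = list(records.columns)
        rows = records.to_dict(orient="records")
    else:
        rows = list(records)
        if columns is None:
            columns = list(rows[0].keys()) if rows else []
        else:
            columns = list(columns)
        for i, r in enumerate(rows):
            if list(r.keys()) != columns:
                raise FormatError(
                    f"record {i} schema {list(r.keys())} differs from {columns}"
                )
    if not columns:
        raise FormatError("cannot write a table with no columns")
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(columns) + "\n")
        for r in rows:
            fh.write("\t".join(_format_value(r[c]) for c in columns) + "\n")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
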