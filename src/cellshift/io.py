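"""Readers and writers for the standard single-cell exchange formats.

Handles the 10x-style MatrixMarket triplet layout (``matrix.mtx`` +
``features.tsv`` + ``barcodes.tsv``, optionally gzipped), delimited
cell-annotation tables, and GMT gene-set files.  This module performs no
computation beyond validation.
"""

from __future__ import annotations

import gzip
import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .errors import FormatError, IntegrityError, ValidationError

CONDITIONS = ("case", "control")

_ANNOTATION_COLUMNS = {
    "barcode": ("barcode", "cell", "cell_id"),
    "sample_id": ("sample_id", "sample"),
    "condition": ("condition", "group"),
    "cluster": ("cluster", "cell_type", "celltype", "cluster_id"),
}


@dataclass
class CountMatrix:
    """Sparse genes x cells UMI count matrix with identifiers.

    Attributes
    ----------
    values
        ``scipy.sparse`` matrix of shape (n_genes, n_cells) holding
        non-negative integer counts.
    gene_ids
        Unique gene identifiers, one per row.
    gene_symbols
        Gene symbols, one per row; may repeat (defaults to ``gene_ids``).
    barcodes
        Unique cell barcodes, one per column.
    """

    values: sp.spmatrix
    gene_ids: list[str]
    barcodes: list[str]
    gene_symbols: list[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.gene_symbols is None:
            self.gene_symbols = list(self.gene_ids)
        self.values = sp.csc_matrix(self.values)
        self.validate()

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def validate(self) -> None:
        n_genes, n_cells = self.values.shape
        if len(self.gene_ids) != n_genes:
            raise IntegrityError(
                f"{len(self.gene_ids)} gene ids for {n_genes} matrix rows"
            )
        if len(self.gene_symbols) != n_genes:
            raise IntegrityError(
                f"{len(self.gene_symbols)} gene symbols for {n_genes} rows"
            )
        if len(self.barcodes) != n_cells:
            raise IntegrityError(
                f"{len(self.barcodes)} barcodes for {n_cells} matrix columns"
            )
        if len(set(self.gene_ids)) != n_genes:
            raise IntegrityError("gene ids are not unique")
        if len(set(self.barcodes)) != n_cells:
            raise IntegrityError("barcodes are not unique")
        data = self.values.data
        if data.size:
            if data.min() < 0:
                raise ValidationError("counts must be non-negative")
            if not np.allclose(data, np.round(data)):
                raise ValidationError("counts must be integers")

    def subset(self, gene_mask=None, cell_mask=None) -> "CountMatrix":
        """Return a new matrix restricted to boolean/index masks, order kept."""
        gm = np.arange(self.n_genes) if gene_mask is None else np.asarray(gene_mask)
        cm = np.arange(self.n_cells) if cell_mask is None else np.asarray(cell_mask)
        if gm.dtype == bool:
            gm = np.flatnonzero(gm)
        if cm.dtype == bool:
            cm = np.flatnonzero(cm)
        return CountMatrix(
            values=self.values[gm][:, cm],
            gene_ids=[self.gene_ids[i] for i in gm],
            gene_symbols=[self.gene_symbols[i] for i in gm],
            barcodes=[self.barcodes[i] for i in cm],
        )


def _find_file(directory: Path, stems: Sequence[str]) -> Path:
    for stem in stems:
        for suffix in ("", ".gz"):
            p = directory / (stem + suffix)
            if p.exists():
                return p
    raise FormatError(
        f"none of {list(stems)} (plain or .gz) found in {directory}"
    )


def _open_text(path: Path):
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _read_lines(path: Path) -> list[str]:
    with _open_text(path) as fh:
        return [line.rstrip("\n").rstrip("\r") for line in fh if line.strip()]


def read_counts_mtx(directory: str | Path) -> CountMatrix:
    """Read a 10x-style triplet directory into a :class:`CountMatrix`.

    Accepts ``matrix.mtx[.gz]`` plus ``features.tsv[.gz]`` (or the older
    ``genes.tsv``) and ``barcodes.tsv[.gz]``.  The features file may carry
    1, 2, or 3 tab-separated columns (id / id+symbol / id+symbol+type).
    """
    directory = Path(directory)
    if not directory.is_dir():
        raise FormatError(f"not a directory: {directory}")
    mtx_path = _find_file(directory, ["matrix.mtx"])
    feat_path = _find_file(directory, ["features.tsv", "genes.tsv"])
    bc_path = _find_file(directory, ["barcodes.tsv"])

    with _open_text(mtx_path) as fh:
        try:
            mat = scipy.io.mmread(fh)
        except Exception as exc:  # scipy raises ValueError on bad headers
            raise FormatError(f"cannot parse {mtx_path}: {exc}") from exc
    mat = sp.csc_matrix(mat)

    feat_rows = [line.split("\t") for line in _read_lines(feat_path)]
    gene_ids = [r[0] for r in feat_rows]
    gene_symbols = [r[1] if len(r) > 1 else r[0] for r in feat_rows]
    barcodes = _read_lines(bc_path)

    if len(gene_ids) != mat.shape[0]:
        raise IntegrityError(
            f"{feat_path.name} lists {len(gene_ids)} features but matrix "
            f"header declares {mat.shape[0]} rows"
        )
    if len(barcodes) != mat.shape[1]:
        raise IntegrityError(
            f"{bc_path.name} lists {len(barcodes)} barcodes but matrix "
            f"header declares {mat.shape[1]} columns"
        )
    return CountMatrix(mat, gene_ids, barcodes, gene_symbols)


def write_counts_mtx(m: CountMatrix, directory: str | Path, gzipped: bool = False) -> None:
    """Write ``m`` as a triplet directory; round-trips exactly through
    :func:`read_counts_mtx`."""
    m.validate()
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    suffix = ".gz" if gzipped else ""

    buf = _io.BytesIO()
    scipy.io.mmwrite(buf, sp.coo_matrix(m.values).astype(np.int64), field="integer")
    mtx_bytes = buf.getvalue()
    feat_bytes = "".join(
        f"{gid}\t{sym}\tGene Expression\n"
        for gid, sym in zip(m.gene_ids, m.gene_symbols)
    ).encode()
    bc_bytes = "".join(f"{bc}\n" for bc in m.barcodes).encode()

    for name, payload in (
        ("matrix.mtx", mtx_bytes),
        ("features.tsv", feat_bytes),
        ("barcodes.tsv", bc_bytes),
    ):
        path = directory / (name + suffix)
        opener = gzip.open if gzipped else open
        with opener(path, "wb") as fh:
            fh.write(payload)


def read_cell_annotation(path: str | Path) -> pd.DataFrame:
    """Read a per-cell annotation table (TSV or CSV by sniffing).

    Returns a DataFrame with columns ``barcode``, ``sample_id``,
    ``condition`` (restricted to ``case``/``control``), and ``cluster``.
    Unrecognised extra columns are dropped.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"annotation file not found: {path}")
    df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    return validate_cell_annotation(df)


def validate_cell_annotation(df: pd.DataFrame) -> pd.DataFrame:
    """Normalise column names and enforce annotation invariants."""
    rename = {}
    lower = {c.lower(): c for c in df.columns}
    for canonical, aliases in _ANNOTATION_COLUMNS.items():
        for alias in aliases:
            if alias in lower:
                rename[lower[alias]] = canonical
                break
        else:
            raise FormatError(
                f"annotation is missing a {canonical!r} column "
                f"(accepted names: {aliases})"
            )
    out = df.rename(columns=rename)[list(_ANNOTATION_COLUMNS)].copy()
    dupes = out["barcode"][out["barcode"].duplicated()]
    if len(dupes):
        raise IntegrityError(f"duplicate barcodes in annotation: {sorted(set(dupes))[:5]}")
    bad = sorted(set(out["condition"]) - set(CONDITIONS))
    if bad:
        raise ValidationError(
            f"condition must be one of {CONDITIONS}; found {bad}"
        )
    return out.reset_index(drop=True)


def write_cell_annotation(df: pd.DataFrame, path: str | Path) -> None:
    validate_cell_annotation(df).to_csv(path, sep="\t", index=False)


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Parse a GMT file into ``{set name: [gene symbols]}``.

    The description field (second column) is discarded; genes repeated
    within a set are deduplicated with order preserved.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"GMT file not found: {path}")
    sets: dict[str, list[str]] = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path.name}:{lineno}: GMT lines need >= 3 tab-separated "
                    f"fields, got {len(fields)}"
                )
            name = fields[0]
            if name in sets:
                raise IntegrityError(f"{path.name}:{lineno}: duplicate set name {name!r}")
            genes = list(dict.fromkeys(g for g in fields[2:] if g))
            if not genes:
                raise FormatError(f"{path.name}:{lineno}: set {name!r} has no genes")
            sets[name] = genes
    return sets
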