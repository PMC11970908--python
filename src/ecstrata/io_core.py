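"""On-disk formats and core in-memory containers.

The package exchanges data in the CellRanger-style Matrix Market triplet
(``matrix.mtx`` + ``features.tsv`` + ``barcodes.tsv``), plain delimited
tables with a header line, and simple one-set-per-line gene-set files.
MTX indices are 1-based on disk (Matrix Market standard) and 0-based in
memory.  No science lives here.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .errors import ConsistencyError, FormatError, SchemaError, ValidationError

logger = logging.getLogger("ecstrata")
if not logger.handlers:  # stderr logging with per-stage counters
    _h = logging.StreamHandler()
    _h.setFormatter(logging.Formatter("[%(name)s] %(levelname)s: %(message)s"))
    logger.addHandler(_h)
    logger.setLevel(logging.INFO)

#: Symbol prefix marking mitochondrial genes (case-insensitive).  The mouse
#: mitochondrial genome contributes genes named mt-Nd1, mt-Co1, ...;
#: configurable because annotation sources differ.
DEFAULT_MITO_PREFIX = "mt-"

REGIONS = ("duodenum", "jejunum", "proximal_colon", "distal_colon", "other")
REPORTER_STATES = ("positive", "negative", "unknown")


@dataclass
class CountMatrix:
    """Genes × cells sparse UMI count matrix with identifiers.

    ``values`` is a CSR matrix of non-negative integers; ``mito_flags``
    marks genes of mitochondrial origin (used by the QC mito-fraction
    filter).
    """

    values: sp.csr_matrix
    gene_ids: list[str]
    cell_ids: list[str]
    mito_flags: np.ndarray

    def __post_init__(self) -> None:
        self.values = sp.csr_matrix(self.values)
        self.mito_flags = np.asarray(self.mito_flags, dtype=bool)
        n_genes, n_cells = self.values.shape
        if len(self.gene_ids) != n_genes:
            raise ConsistencyError(
                f"{len(self.gene_ids)} gene ids for {n_genes} matrix rows"
            )
        if len(self.cell_ids) != n_cells:
            raise ConsistencyError(
                f"{len(self.cell_ids)} cell ids for {n_cells} matrix columns"
            )
        if len(set(self.gene_ids)) != n_genes:
            raise ConsistencyError("duplicate gene identifiers")
        if len(set(self.cell_ids)) != n_cells:
            raise ConsistencyError("duplicate cell identifiers")
        if self.mito_flags.shape != (n_genes,):
            raise ConsistencyError("mito_flags length must equal gene count")
        if self.values.nnz and self.values.data.min() < 0:
            raise ValidationError("UMI counts must be non-negative")
        if self.values.nnz and np.any(self.values.data != np.round(self.values.data)):
            raise ValidationError("UMI counts must be integral")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def gene_index(self, gene: str) -> int:
        try:
            return self.gene_ids.index(gene)
        except ValueError:
            raise ValidationError(f"gene {gene!r} not in matrix") from None


@dataclass
class LogMatrix:
    """Normalized expression, log2(count / size_factor + 1).

    Entries are ≥ 0 and an entry is zero iff the raw count was zero.
    ``size_factors`` records provenance.
    """

    values: sp.csr_matrix
    gene_ids: list[str]
    cell_ids: list[str]
    size_factors: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = sp.csr_matrix(self.values)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def dense(self) -> np.ndarray:
        return np.asarray(self.values.todense())

    def gene_index(self, gene: str) -> int:
        try:
            return self.gene_ids.index(gene)
        except ValueError:
            raise ValidationError(f"gene {gene!r} not in matrix") from None


@dataclass(frozen=True)
class GeneSet:
    """A named, non-empty set of gene identifiers."""

    name: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "genes", frozenset(self.genes))
        if not self.genes:
            raise ValidationError(f"gene set {self.name!r} is empty")


def _sniff_delimiter(first_line: str) -> str:
    return "\t" if "\t" in first_line else ","


def read_count_matrix(
    mtx_path: str | Path,
    features_path: str | Path,
    barcodes_path: str | Path,
    mito_prefix: str = DEFAULT_MITO_PREFIX,
) -> CountMatrix:
    """Read a CellRanger-style MTX triplet.

    The features file may carry one column (symbol) or several
    (id, symbol, ...); the first column becomes the gene identifier and
    the second, when present, the symbol used for the mitochondrial
    prefix test.
    """
    mtx_path = Path(mtx_path)
    try:
        mat = scipy.io.mmread(str(mtx_path))
    except Exception as exc:  # noqa: BLE001 - scipy raises bare ValueError
        raise FormatError(f"malformed MTX file {mtx_path}: {exc}") from exc
    mat = sp.csr_matrix(mat)

    features = _read_id_table(features_path)
    barcodes = _read_id_table(barcodes_path)
    if len(features) != mat.shape[0]:
        raise ConsistencyError(
            f"features file has {len(features)} rows but MTX declares "
            f"{mat.shape[0]} genes"
        )
    if len(barcodes) != mat.shape[1]:
        raise ConsistencyError(
            f"barcodes file has {len(barcodes)} rows but MTX declares "
            f"{mat.shape[1]} cells"
        )
    gene_ids = [row[0] for row in features]
    symbols = [row[1] if len(row) > 1 else row[0] for row in features]
    cell_ids = [row[0] for row in barcodes]
    prefix = mito_prefix.lower()
    mito = np.array([s.lower().startswith(prefix) for s in symbols], dtype=bool)
    cm = CountMatrix(mat, gene_ids, cell_ids, mito)
    logger.info(
        "read_count_matrix: %d genes x %d cells (%d mito genes) from %s",
        cm.n_genes, cm.n_cells, int(mito.sum()), mtx_path,
    )
    return cm


def _read_id_table(path: str | Path) -> list[list[str]]:
    rows: list[list[str]] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            rows.append(line.split("\t") if "\t" in line else line.split(","))
    return rows


def write_count_matrix(cm: CountMatrix, out_dir: str | Path) -> None:
    """Write the MTX triplet; inverse of :func:`read_count_matrix`."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(str(out / "matrix.mtx"), sp.coo_matrix(cm.values), field="integer")
    with open(out / "features.tsv", "w") as fh:
        for g in cm.gene_ids:
            fh.write(f"{g}\n")
    with open(out / "barcodes.tsv", "w") as fh:
        for c in cm.cell_ids:
            fh.write(f"{c}\n")
    logger.info("write_count_matrix: %d genes x %d cells -> %s",
                cm.n_genes, cm.n_cells, out)


def read_table(
    path: str | Path,
    required: dict[str, type] | None = None,
) -> pd.DataFrame:
    """Read a delimited table with a header line.

    ``required`` maps column names to types (``str``, ``int``, ``float``);
    missing required columns raise :class:`SchemaError`, unparseable
    numeric cells raise :class:`SchemaError`.  Extra columns are kept.
    Delimiter (tab vs comma) is auto-detected from the header line.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    delim = _sniff_delimiter(first)
    df = pd.read_csv(path, sep=delim, dtype=str)
    required = required or {}
    for col, typ in required.items():
        if col not in df.columns:
            raise SchemaError(f"table {path} is missing required column {col!r}")
        if typ in (int, float):
            try:
                df[col] = df[col].astype(typ)
            except (TypeError, ValueError) as exc:
                raise SchemaError(
                    f"column {col!r} of {path} has unparseable numeric cells: {exc}"
                ) from exc
    return df


def read_cell_meta(path: str | Path) -> pd.DataFrame:
    """Read per-cell metadata (cell_id, region, optional reporter)."""
    df = read_table(path, required={"cell_id": str, "region": str})
    bad = set(df["region"]) - set(REGIONS)
    if bad:
        raise SchemaError(f"unknown region labels: {sorted(bad)}")
    if "reporter" in df.columns:
        bad = set(df["reporter"]) - set(REPORTER_STATES)
        if bad:
            raise SchemaError(f"unknown reporter labels: {sorted(bad)}")
    if df["cell_id"].duplicated().any():
        raise ConsistencyError("duplicate cell_id rows in cell metadata")
    return df


def read_gene_sets(path: str | Path) -> list[GeneSet]:
    """Read gene sets, one per line: name followed by gene symbols.

    Tokens may be separated by tabs, spaces or commas.  Duplicate genes
    within a set are collapsed with a warning; an empty set is an error.
    """
    sets: list[GeneSet] = []
    names: set[str] = set()
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            tokens = [t for t in line.replace(",", " ").split() if t]
            if not tokens:
                continue
            name, genes = tokens[0], tokens[1:]
            if not genes:
                raise ValidationError(f"gene set {name!r} (line {ln}) has no genes")
            if name in names:
                raise ConsistencyError(f"duplicate gene set name {name!r}")
            if len(set(genes)) != len(genes):
                logger.warning("gene set %r: duplicate genes collapsed", name)
            names.add(name)
            sets.append(GeneSet(name, frozenset(genes)))
    return sets


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, quoting=csv.QUOTE_MINIMAL)


def read_config(path: str | Path) -> dict:
    """Read a TOML/YAML-style key-value configuration file."""
    import yaml

    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if cfg is None:
        return {}
    if not isinstance(cfg, dict):
        raise FormatError(f"config {path} must be a key-value mapping")
    return cfg
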