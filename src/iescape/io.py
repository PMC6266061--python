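"""Expression-matrix and gene-set I/O.

The pipeline operates on normalized, log2-scale expression matrices
(genes x samples) keyed by unique HUGO symbols.  This module reads and
writes the two plain-text matrix formats used in microarray work (GCT 1.2
and headered TSV), parses GMT gene-set files, and collapses probe-level
matrices to one row per gene symbol.

Matrix writers emit UTF-8 with LF line endings at full float precision, so
read -> write -> read round-trips are value-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger("iescape")

__all__ = [
    "ExpressionMatrix",
    "GeneSet",
    "ExpressionFormatError",
    "read_expression",
    "write_expression",
    "read_gmt",
    "write_gmt",
    "collapse_probes",
    "IEGS33_STARTER",
    "TCELL_ACTIVATION_STARTER",
    "builtin_gene_sets",
]


class ExpressionFormatError(ValueError):
    """Malformed GCT/TSV/GMT content, with enough context to locate it."""


# ---------------------------------------------------------------------------
# Domain containers
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Log2-scale expression values for unique genes across unique samples.

    Thin validated wrapper around a pandas DataFrame whose index holds gene
    symbols and whose columns hold sample identifiers.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if not isinstance(df, pd.DataFrame):
            raise TypeError("ExpressionMatrix.data must be a DataFrame")
        if df.shape[0] < 2 or df.shape[1] < 1:
            raise ValueError(
                f"expression matrix needs >=2 genes and >=1 sample, got {df.shape}"
            )
        if df.index.duplicated().any():
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene symbols: {dups[:5]}")
        if df.columns.duplicated().any():
            dups = df.columns[df.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups[:5]}")
        values = df.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValueError("expression values must be numeric")
        if not np.isfinite(values).all():
            bad = np.argwhere(~np.isfinite(values))[0]
            raise ValueError(
                f"non-finite value at gene {df.index[bad[0]]!r}, "
                f"sample {df.columns[bad[1]]!r}"
            )
        self.data = df.astype(float)

    @property
    def gene_symbols(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def subset_samples(self, sample_ids: Iterable[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.loc[:, list(sample_ids)])


@dataclass(frozen=True)
class GeneSet:
    """A named collection of gene symbols (order-free, duplicates collapsed)."""

    name: str
    genes: frozenset[str] = field(default_factory=frozenset)
    description: str = ""

    def __post_init__(self) -> None:
        genes = frozenset(g.strip() for g in self.genes if g.strip())
        if not genes:
            raise ValueError(f"gene set {self.name!r} is empty")
        object.__setattr__(self, "genes", genes)

    def __len__(self) -> int:
        return len(self.genes)

    def intersect(self, symbols: Iterable[str]) -> frozenset[str]:
        return self.genes & set(symbols)


# ---------------------------------------------------------------------------
# Built-in gene sets
# ---------------------------------------------------------------------------

#: Immune-escape genes named in the source signature's description: immune
#: checkpoints, their ligands, immunosuppressive enzymes, cytokines and
#: chemokines.  This is a starter list — exact reproduction of published
#: scores requires the full 33-gene GMT supplied by the user.
IEGS33_STARTER: tuple[str, ...] = (
    "CTLA4", "PDCD1", "LAG3", "HAVCR2", "CD80", "CD86", "CD274", "PDCD1LG2",
    "LGALS9", "IDO1", "ARG1", "ENTPD1", "IL10", "HGF", "GDF15", "CCL22",
    "ICOS", "CCL2", "SOCS3", "IL6ST", "LAIR1", "CSF1", "IDO2", "KIR2DL1",
    "VEGFA", "TIMP1", "IL23A", "PVR", "MSR1", "JAK2",
)

#: T-cell activation genes named in the source description (starter list;
#: the full 44-gene MSigDB-derived set must be supplied for exact scores).
TCELL_ACTIVATION_STARTER: tuple[str, ...] = ("IL2", "CD28", "ZAP70", "LCK")


def builtin_gene_sets() -> dict[str, GeneSet]:
    """Starter IEGS33 and T-cell-activation gene sets shipped with the package."""
    return {
        "IEGS33": GeneSet(
            "IEGS33", frozenset(IEGS33_STARTER),
            "immune-escape signature (starter list)",
        ),
        "TCELL_ACTIVATION": GeneSet(
            "TCELL_ACTIVATION", frozenset(TCELL_ACTIVATION_STARTER),
            "T-cell activation signature (starter list)",
        ),
    }


# ---------------------------------------------------------------------------
# Matrix readers / writers
# ---------------------------------------------------------------------------


def _handle_duplicates(
    df: pd.DataFrame, collapse: Literal["error", "max_mean", "mean"]
) -> pd.DataFrame:
    if not df.index.duplicated().any():
        return df
    dups = df.index[df.index.duplicated()].unique().tolist()
    if collapse == "error":
        raise ValueError(
            f"duplicate gene symbols {dups[:5]} (pass collapse='max_mean' or "
            "'mean' to collapse them)"
        )
    n_before = df.shape[0]
    if collapse == "mean":
        df = df.groupby(level=0, sort=False).mean()
    elif collapse == "max_mean":
        means = df.mean(axis=1).to_numpy()
        best_pos: dict[str, int] = {}
        for pos, (sym, m) in enumerate(zip(df.index, means)):
            if sym not in best_pos or m > means[best_pos[sym]]:
                best_pos[sym] = pos
        df = df.iloc[sorted(best_pos.values())]
    else:  # pragma: no cover - guarded by Literal
        raise ValueError(f"unknown collapse method {collapse!r}")
    logger.info("collapsed %d duplicate rows to %d genes", n_before, df.shape[0])
    return df


def read_expression(
    path: str | Path,
    fmt: Literal["gct", "tsv"] | None = None,
    collapse: Literal["error", "max_mean", "mean"] = "error",
) -> ExpressionMatrix:
    """Read a genes x samples matrix from GCT 1.2 or headered TSV.

    Parameters
    ----------
    path
        Input file.  Format is inferred from the suffix unless ``fmt`` given.
    fmt
        ``"gct"`` (GCT 1.2: ``#1.2`` header, dims line, Name/Description
        columns) or ``"tsv"`` (gene column + sample header row).
    collapse
        What to do with duplicate gene rows: reject (default), keep the
        probe with the highest row mean, or average them.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt is None:
        fmt = "gct" if path.suffix.lower() == ".gct" else "tsv"
    if fmt == "gct":
        df = _read_gct(path)
    elif fmt == "tsv":
        df = _read_tsv(path)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    df = _handle_duplicates(df, collapse)
    return ExpressionMatrix(df)


def _parse_cell(token: str, row: int, col: int, path: Path) -> float:
    try:
        return float(token)
    except ValueError:
        raise ExpressionFormatError(
            f"{path}: non-numeric value {token!r} at data row {row}, column {col}"
        ) from None


def _read_gct(path: Path) -> pd.DataFrame:
    with open(path, encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    if len(lines) < 3 or not lines[0].startswith("#1.2"):
        raise ExpressionFormatError(f"{path}: missing GCT 1.2 '#1.2' header line")
    dims = lines[1].split("\t")
    try:
        n_genes, n_samples = int(dims[0]), int(dims[1])
    except (ValueError, IndexError):
        raise ExpressionFormatError(
            f"{path}: malformed GCT dims line {lines[1]!r}"
        ) from None
    header = lines[2].split("\t")
    if len(header) < 3 or header[0] != "Name" or header[1] != "Description":
        raise ExpressionFormatError(
            f"{path}: GCT column header must start with Name\\tDescription"
        )
    sample_ids = header[2:]
    if len(sample_ids) != n_samples:
        raise ExpressionFormatError(
            f"{path}: declared {n_samples} samples but header has {len(sample_ids)}"
        )
    data_lines = [ln for ln in lines[3:] if ln.strip()]
    if len(data_lines) != n_genes:
        raise ExpressionFormatError(
            f"{path}: declared {n_genes} data rows but found {len(data_lines)}"
        )
    genes: list[str] = []
    rows: list[list[float]] = []
    for i, ln in enumerate(data_lines, start=1):
        parts = ln.split("\t")
        if len(parts) != 2 + n_samples:
            raise ExpressionFormatError(
                f"{path}: data row {i} has {len(parts) - 2} values, "
                f"expected {n_samples}"
            )
        genes.append(parts[0].strip())
        rows.append([_parse_cell(v, i, j + 1, path) for j, v in enumerate(parts[2:])])
    return pd.DataFrame(rows, index=genes, columns=sample_ids)


def _read_tsv(path: Path) -> pd.DataFrame:
    with open(path, encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if len(lines) < 2:
        raise ExpressionFormatError(f"{path}: TSV needs a header row and data rows")
    header = lines[0].split("\t")
    sample_ids = header[1:]
    if not sample_ids:
        raise ExpressionFormatError(f"{path}: TSV header has no sample columns")
    genes: list[str] = []
    rows: list[list[float]] = []
    for i, ln in enumerate(lines[1:], start=1):
        parts = ln.split("\t")
        if len(parts) != len(header):
            raise ExpressionFormatError(
                f"{path}: row {i} has {len(parts)} fields, expected {len(header)}"
            )
        genes.append(parts[0].strip())
        rows.append([_parse_cell(v, i, j + 1, path) for j, v in enumerate(parts[1:])])
    return pd.DataFrame(rows, index=genes, columns=sample_ids)


def write_expression(
    matrix: ExpressionMatrix, path: str | Path, fmt: Literal["gct", "tsv"] | None = None
) -> Path:
    """Write a matrix as GCT 1.2 or TSV (UTF-8, LF, full float precision)."""
    path = Path(path)
    if fmt is None:
        fmt = "gct" if path.suffix.lower() == ".gct" else "tsv"
    df = matrix.data
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        if fmt == "gct":
            fh.write("#1.2\n")
            fh.write(f"{df.shape[0]}\t{df.shape[1]}\n")
            fh.write("Name\tDescription\t" + "\t".join(df.columns) + "\n")
            for gene, row in zip(df.index, df.to_numpy()):
                fh.write(gene + "\tna\t"
                         + "\t".join(repr(float(v)) for v in row) + "\n")
        elif fmt == "tsv":
            fh.write("gene\t" + "\t".join(df.columns) + "\n")
            for gene, row in zip(df.index, df.to_numpy()):
                fh.write(gene + "\t"
                         + "\t".join(repr(float(v)) for v in row) + "\n")
        else:
            raise ValueError(f"unknown format {fmt!r}")
    return path


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Parse a GMT file: one gene set per tab-separated line
    (name, description, gene symbols...)."""
    path = Path(path)
    sets: list[GeneSet] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, ln in enumerate(fh, start=1):
            ln = ln.rstrip("\n").rstrip("\r")
            if not ln.strip():
                continue
            parts = ln.split("\t")
            if len(parts) < 3:
                raise ExpressionFormatError(
                    f"{path}: line {lineno} has {len(parts)} fields, "
                    "GMT needs name, description and >=1 gene"
                )
            name, desc = parts[0], parts[1]
            genes = [g.strip() for g in parts[2:] if g.strip()]
            if len(set(genes)) < len(genes):
                logger.warning(
                    "gene set %s (line %d): %d duplicate symbols collapsed",
                    name, lineno, len(genes) - len(set(genes)),
                )
            sets.append(GeneSet(name, frozenset(genes), desc))
    if not sets:
        logger.warning("GMT file %s contains no gene sets", path)
    return sets


def write_gmt(gene_sets: Iterable[GeneSet], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for gs in gene_sets:
            fh.write(
                "\t".join([gs.name, gs.description or "na", *sorted(gs.genes)]) + "\n"
            )
    return path


# ---------------------------------------------------------------------------
# Probe collapsing
# ---------------------------------------------------------------------------


def collapse_probes(
    probe_matrix: ExpressionMatrix,
    mapping: Mapping[str, str],
    method: Literal["max_mean", "mean"] = "max_mean",
) -> ExpressionMatrix:
    """Collapse a probe-level matrix to one row per gene symbol.

    ``max_mean`` keeps, per gene, the probe with the highest mean across
    samples (the single most informative probe); ``mean`` averages all
    probes of a gene.  Probes absent from ``mapping`` are dropped and
    counted in the log.  Symbols are matched case-sensitively after
    whitespace trimming; alias resolution is the caller's responsibility.
    """
    if not mapping:
        raise ValueError("empty probe mapping")
    clean = {str(k).strip(): str(v).strip() for k, v in mapping.items() if str(v).strip()}
    df = probe_matrix.data
    mapped_mask = df.index.to_series().isin(clean)
    n_unmapped = int((~mapped_mask).sum())
    if n_unmapped == len(df):
        raise ValueError("no probe in the matrix has a mapping entry")
    if n_unmapped:
        logger.info("dropping %d unmapped probes", n_unmapped)
    df = df.loc[mapped_mask.to_numpy()]
    symbols = [clean[p] for p in df.index]
    df = df.set_axis(symbols, axis=0)
    df = _handle_duplicates(df, collapse=method)
    return ExpressionMatrix(df)
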