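"""Reading, writing and preprocessing of expression matrices and gene sets.

Expression data enter the pipeline as delimited text (genes × samples by
default), optionally at probe level with a separate probe→gene annotation.
Probe-level matrices are collapsed to gene level by averaging all probes
mapped to each gene; linear-scale matrices are brought to log2 scale with a
configurable pseudocount. Gene sets are read from GMT files.

Gene symbols are upper-cased on load so that matrices and gene sets from
sources with inconsistent casing match.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Roles a gene set can play in the analysis.
GENE_SET_ROLES = (
    "epithelial",
    "mesenchymal",
    "pemt",
    "hallmark_pathway",
    "target_set",
    "signature",
)


class ParseError(ValueError):
    """Raised when an input file violates the expected layout."""


@dataclass
class ExpressionMatrix:
    """A genes × samples expression table.

    ``data`` is a DataFrame with unique gene (or probe) identifiers on the
    index and unique sample identifiers on the columns. Values are expected
    to be on log2 scale once preprocessing is complete; ``metadata`` carries
    free-form provenance (dataset id, platform, ``log_scale`` flag, ...).
    """

    data: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dupes = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ParseError(f"duplicate gene/probe identifiers: {dupes[:5]}")
        if self.data.columns.has_duplicates:
            dupes = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ParseError(f"duplicate sample identifiers: {dupes[:5]}")
        if (self.data.index.astype(str) == "").any():
            raise ParseError("empty gene identifier in matrix index")

    @property
    def gene_ids(self) -> list[str]:
        return self.data.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.data.columns.tolist()

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()


@dataclass(frozen=True)
class ProbeAnnotation:
    """One probe→gene mapping row; an empty symbol marks an unmapped probe."""

    probe_id: str
    gene_symbol: str


@dataclass(frozen=True)
class GeneSet:
    """A named gene list with a role tag (epithelial, pathway, ...)."""

    name: str
    genes: frozenset[str]
    role: str = "signature"

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("gene set needs a non-empty name")
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")
        if self.role not in GENE_SET_ROLES:
            raise ValueError(f"unknown gene-set role {self.role!r}")

    def __len__(self) -> int:
        return len(self.genes)

    def intersect(self, universe: Iterable[str]) -> frozenset[str]:
        return self.genes & set(universe)


@dataclass
class GeneSetCollection:
    """Mapping of unique names to :class:`GeneSet` objects."""

    sets: dict[str, GeneSet] = field(default_factory=dict)

    def __getitem__(self, name: str) -> GeneSet:
        return self.sets[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def __iter__(self):
        return iter(self.sets.values())

    def __len__(self) -> int:
        return len(self.sets)

    def add(self, gene_set: GeneSet) -> None:
        if gene_set.name in self.sets:
            raise ValueError(f"duplicate gene-set name {gene_set.name!r}")
        self.sets[gene_set.name] = gene_set

    @property
    def names(self) -> list[str]:
        return list(self.sets)


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_expression(
    path: str | Path,
    *,
    transpose: bool = False,
    metadata: Mapping | None = None,
) -> ExpressionMatrix:
    """Read a delimited expression matrix (genes in rows unless ``transpose``).

    The first row must be a header of sample ids, the first column gene or
    probe ids. Duplicate sample ids and non-numeric cells are rejected.
    Genes with any missing value are dropped with a logged count.
    """
    path = Path(path)
    sep = _sep_for(path)
    with open(path, newline="") as fh:
        header = next(csv.reader(fh, delimiter=sep), None)
    if header is None or len(header) < 2:
        raise ParseError(f"{path}: header row with at least one sample id required")
    sample_ids = header[1:]
    seen: set[str] = set()
    for sid in sample_ids:
        if sid in seen:
            raise ParseError(f"{path}: duplicate sample id {sid!r} in header")
        seen.add(sid)

    df = pd.read_csv(path, sep=sep, index_col=0)
    df.columns = sample_ids
    non_numeric = df.columns[[not pd.api.types.is_numeric_dtype(df[c]) for c in df.columns]]
    if len(non_numeric):
        bad_col = non_numeric[0]
        coerced = pd.to_numeric(df[bad_col], errors="coerce")
        bad_rows = df.index[coerced.isna() & df[bad_col].notna()].tolist()
        raise ParseError(
            f"{path}: non-numeric value in column {bad_col!r}"
            + (f", row {bad_rows[0]!r}" if bad_rows else "")
        )
    df.index = df.index.astype(str).str.upper()
    df.index.name = "gene"
    if transpose:
        df = df.T
        df.index = df.index.astype(str).str.upper()
    n_missing = int(df.isna().any(axis=1).sum())
    if n_missing:
        logger.warning("%s: dropped %d genes with missing values", path.name, n_missing)
        df = df.dropna(axis=0)
    meta = dict(metadata or {})
    meta.setdefault("source", str(path))
    meta["n_dropped_missing"] = n_missing
    return ExpressionMatrix(df.astype(float), meta)


def write_expression(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Write a matrix as delimited text (sep inferred from the extension)."""
    path = Path(path)
    matrix.data.to_csv(path, sep=_sep_for(path), float_format="%.10g")


def read_probe_annotation(path: str | Path) -> list[ProbeAnnotation]:
    """Read a two-column (probe_id, gene_symbol) TSV; header optional."""
    path = Path(path)
    rows: list[ProbeAnnotation] = []
    with open(path, newline="") as fh:
        for i, parts in enumerate(csv.reader(fh, delimiter="\t")):
            if not parts or (i == 0 and parts[0].lower() in {"probe_id", "probe"}):
                continue
            if len(parts) < 2:
                raise ParseError(f"{path}: line {i + 1}: expected 2 columns")
            rows.append(ProbeAnnotation(parts[0], parts[1].upper()))
    return rows


def collapse_probes(
    probe_matrix: ExpressionMatrix,
    annotation: Iterable[ProbeAnnotation],
) -> ExpressionMatrix:
    """Collapse a probe-level matrix to gene level by per-gene averaging.

    Each gene's value in a sample is the arithmetic mean over all probes
    mapped to it. A probe annotated to several genes contributes to each of
    them; probes without a mapping (or absent from the annotation) are
    dropped. The returned metadata records how many probes were dropped.
    """
    pairs = pd.DataFrame(
        [(a.probe_id, a.gene_symbol) for a in annotation if a.gene_symbol],
        columns=["probe_id", "gene_symbol"],
    )
    if len(pairs):
        pairs = pairs[pairs["probe_id"].isin(probe_matrix.data.index)]
    if not len(pairs):
        raise ValueError("no probe in the matrix maps to a gene")
    mapped = probe_matrix.data.loc[pairs["probe_id"]]
    mapped.index = pd.Index(pairs["gene_symbol"], name="gene")
    collapsed = mapped.groupby(level=0, sort=True).mean()
    n_dropped = probe_matrix.n_genes - probe_matrix.data.index.isin(pairs["probe_id"]).sum()
    if n_dropped:
        logger.info("collapse_probes: dropped %d unmapped probes", n_dropped)
    meta = dict(probe_matrix.metadata)
    meta["n_probes_in"] = probe_matrix.n_genes
    meta["n_probes_dropped"] = int(n_dropped)
    meta["n_genes_out"] = collapsed.shape[0]
    return ExpressionMatrix(collapsed, meta)


def log2_normalize(matrix: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """Replace every value x by log2(x + pseudocount).

    Refuses matrices already flagged as log scale and any negative input.
    """
    if matrix.metadata.get("log_scale"):
        raise ValueError("matrix is already on log2 scale")
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    vals = matrix.values
    if (vals < 0).any():
        raise ValueError("negative values: input must be on linear scale")
    out = pd.DataFrame(
        np.log2(vals + pseudocount), index=matrix.data.index, columns=matrix.data.columns
    )
    meta = dict(matrix.metadata)
    meta["log_scale"] = True
    meta["pseudocount"] = pseudocount
    return ExpressionMatrix(out, meta)


def read_gmt(path: str | Path, role: str = "signature") -> GeneSetCollection:
    """Read a GMT file (name TAB description TAB gene TAB gene ...).

    Duplicate genes within a line are deduplicated with a logged warning;
    lines with fewer than three fields are rejected.
    """
    path = Path(path)
    coll = GeneSetCollection()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}: line {lineno}: GMT lines need >= 3 fields")
            name = parts[0]
            genes = [g.strip().upper() for g in parts[2:] if g.strip()]
            unique = frozenset(genes)
            if len(unique) < len(genes):
                logger.warning(
                    "%s: line %d (%s): %d duplicate genes removed",
                    path.name, lineno, name, len(genes) - len(unique),
                )
            coll.add(GeneSet(name=name, genes=unique, role=role))
    return coll


def write_gmt(collection: GeneSetCollection | Iterable[GeneSet], path: str | Path) -> None:
    """Write gene sets as GMT, one line per set, genes sorted for stability."""
    with open(path, "w") as fh:
        for gs in collection:
            fh.write("\t".join([gs.name, gs.role, *sorted(gs.genes)]) + "\n")
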