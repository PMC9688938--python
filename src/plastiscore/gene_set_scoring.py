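"""Single-sample gene-set scoring.

Three families of scorers operate on a log2 expression matrix:

* :func:`ssgsea_score` — single-sample GSEA. Genes are ranked per sample;
  the running sum gains weight proportional to ``rank ** weight_exponent``
  at in-set genes (weights normalised to sum to one over the set) and loses
  ``1 / (N - |S|)`` at out-of-set genes. The raw score is the *integral* of
  the running sum over all gene positions, not its maximum deviation. Under
  range normalisation, all samples' raw scores are divided by the cohort's
  (max − min), giving the normalised enrichment score (NES). NES values are
  therefore cohort-relative.
* :func:`aucell_score` — rank-AUC activity for single cells: the area under
  the gene-set recovery curve within the top ``top_fraction`` of the
  ranking, scaled so a top-packed set scores 1.
* :func:`target_activity_score` / :func:`fao_score` — activity proxies from
  curated downstream target genes (AMPK, HIF-1α) and from fatty-acid
  oxidation enzyme genes, as per-sample means of z-scored expression
  (optionally PCA-based or with per-gene weights).

All scorers are rank- or z-based, so they are invariant to strictly
increasing per-sample transforms (ssGSEA/AUCell) or per-gene affine
rescaling (activity scores).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from plastiscore.data_io import ExpressionMatrix, GeneSet

logger = logging.getLogger(__name__)


@dataclass
class ScoreTable:
    """Samples × metrics table of signature scores.

    ``data`` holds one row per sample, one column per metric; metric names
    are unique and every cell is finite. ``metric_info`` records per-metric
    provenance (scoring method, gene-set coverage, parameters).
    """

    data: pd.DataFrame
    metric_info: dict[str, dict] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.data.columns.has_duplicates:
            raise ValueError("metric names must be unique")
        if not np.isfinite(self.data.to_numpy(dtype=float)).all():
            raise ValueError("score table contains non-finite values")

    @property
    def sample_ids(self) -> list[str]:
        return self.data.index.tolist()

    @property
    def metric_names(self) -> list[str]:
        return self.data.columns.tolist()

    def add_metric(self, name: str, values: pd.Series, info: dict | None = None) -> None:
        if name in self.data.columns:
            raise ValueError(f"metric {name!r} already present")
        self.data[name] = values.reindex(self.data.index)
        if self.data[name].isna().any():
            raise ValueError(f"metric {name!r} missing values for some samples")
        if info:
            self.metric_info[name] = info

    @classmethod
    def from_columns(cls, columns: dict[str, pd.Series]) -> "ScoreTable":
        return cls(pd.DataFrame(columns))

    def to_tsv(self, path: str | Path) -> None:
        self.data.to_csv(path, sep="\t", index_label="sample_id", float_format="%.10g")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "ScoreTable":
        return cls(pd.read_csv(path, sep="\t", index_col=0))


@dataclass
class SsgseaParams:
    """Parameters for single-sample GSEA.

    ``weight_exponent`` (α ≥ 0) controls how strongly top ranks are
    emphasised; 0.75 is the de-facto default of the ssGSEA tool family.
    ``normalization='range'`` divides raw scores by the cohort max − min.
    ``min_coverage`` is the minimum fraction of a gene set that must be
    present in the matrix before scoring is attempted.
    """

    weight_exponent: float = 0.75
    normalization: str = "range"  # {"range", "none"}
    min_coverage: float = 0.5

    def __post_init__(self) -> None:
        if self.weight_exponent < 0:
            raise ValueError("weight_exponent must be >= 0")
        if self.normalization not in {"range", "none"}:
            raise ValueError("normalization must be 'range' or 'none'")


def resolve_set_genes(
    matrix: ExpressionMatrix, gene_set: GeneSet, min_coverage: float = 0.5
) -> list[str]:
    """Intersect a gene set with the matrix universe, enforcing coverage.

    Missing genes are dropped with a warning; coverage below
    ``min_coverage`` (fraction of the set found) raises.
    """
    present = sorted(gene_set.intersect(matrix.gene_ids))
    if not present:
        raise ValueError(f"gene set {gene_set.name!r}: no genes present in matrix")
    coverage = len(present) / len(gene_set)
    if coverage < min_coverage:
        raise ValueError(
            f"gene set {gene_set.name!r}: coverage {coverage:.2f} below "
            f"minimum {min_coverage:.2f} ({len(present)}/{len(gene_set)} genes)"
        )
    if len(present) < len(gene_set):
        logger.warning(
            "gene set %s: %d/%d genes absent from matrix, dropped",
            gene_set.name, len(gene_set) - len(present), len(gene_set),
        )
    return present


def _ssgsea_raw_sample(values: np.ndarray, in_set: np.ndarray, alpha: float) -> float:
    """Integral running-sum ssGSEA score for one sample.

    ``values``: expression vector; ``in_set``: boolean membership mask.
    Genes are walked in descending expression order; rank weights use
    average ranks so tied genes share a weight.
    """
    n = values.size
    m = int(in_set.sum())
    if m == n:
        raise ValueError("gene set equals the whole universe; decrement undefined")
    # average rank, highest expression -> rank N
    ranks = rankdata(values, method="average")
    order = np.argsort(-values, kind="stable")
    mask = in_set[order]
    weights = np.where(mask, ranks[order] ** alpha, 0.0)
    total_w = weights.sum()
    steps = np.where(mask, weights / total_w, -1.0 / (n - m))
    return float(np.cumsum(steps).sum())


def ssgsea_score(
    matrix: ExpressionMatrix,
    gene_set: GeneSet,
    params: SsgseaParams | None = None,
) -> pd.Series:
    """Per-sample ssGSEA scores for one gene set.

    Returns a Series indexed by sample id. Under range normalisation the
    values are NES (cohort-relative); with ``normalization='none'`` the raw
    integral scores are returned.
    """
    params = params or SsgseaParams()
    present = resolve_set_genes(matrix, gene_set, params.min_coverage)
    in_set = matrix.data.index.isin(present)
    vals = matrix.values
    raw = np.array(
        [
            _ssgsea_raw_sample(vals[:, j], in_set, params.weight_exponent)
            for j in range(matrix.n_samples)
        ]
    )
    if params.normalization == "range":
        span = raw.max() - raw.min()
        if span == 0:
            raise ValueError(
                f"gene set {gene_set.name!r}: all samples score identically; "
                "range normalisation undefined"
            )
        raw = raw / span
    return pd.Series(raw, index=matrix.data.columns, name=f"NES:{gene_set.name}")


def aucell_score(
    matrix: ExpressionMatrix,
    gene_set: GeneSet,
    top_fraction: float = 0.05,
    min_coverage: float = 0.5,
) -> pd.Series:
    """Rank-AUC gene-set activity per cell (AUCell-style).

    For each cell the genes are ranked by expression (descending; ties
    broken deterministically by gene symbol). The recovery curve counts set
    genes among the top ``k`` ranks for k = 1..⌈top_fraction·N⌉; the score
    is its area normalised by the maximal achievable area, so a set packed
    at the very top scores 1 and a set entirely outside the window scores 0.
    """
    if not (0 < top_fraction <= 1):
        raise ValueError("top_fraction must lie in (0, 1]")
    present = resolve_set_genes(matrix, gene_set, min_coverage)
    n = matrix.n_genes
    k_max = math.ceil(top_fraction * n)
    in_set = matrix.data.index.isin(present)
    # deterministic tie-break: sort by (-expression, gene symbol)
    sym_order = np.argsort(matrix.data.index.to_numpy())
    sym_rank = np.empty(n, dtype=int)
    sym_rank[sym_order] = np.arange(n)
    max_area = sum(min(k, len(present)) for k in range(1, k_max + 1))
    scores = np.empty(matrix.n_samples)
    vals = matrix.values
    for j in range(matrix.n_samples):
        order = np.lexsort((sym_rank, -vals[:, j]))
        hits = np.cumsum(in_set[order][:k_max])
        scores[j] = hits.sum() / max_area
    return pd.Series(scores, index=matrix.data.columns, name=f"AUC:{gene_set.name}")


def _zscore_submatrix(matrix: ExpressionMatrix, genes: list[str], set_name: str) -> pd.DataFrame:
    sub = matrix.data.loc[genes]
    sd = sub.std(axis=1, ddof=1)
    flat = sd == 0
    if flat.all():
        raise ValueError(f"gene set {set_name!r}: all genes constant across samples")
    if flat.any():
        logger.warning(
            "gene set %s: dropped %d zero-variance genes", set_name, int(flat.sum())
        )
        sub, sd = sub.loc[~flat], sd[~flat]
    return sub.sub(sub.mean(axis=1), axis=0).div(sd, axis=0)


def target_activity_score(
    matrix: ExpressionMatrix,
    target_set: GeneSet,
    method: str = "mean_z",
    min_coverage: float = 0.5,
) -> pd.Series:
    """Pathway/TF activity from downstream target genes (AMPK, HIF-1α...).

    ``mean_z``: per-sample mean of the targets' z-scored expression.
    ``first_pc``: sample projections on the first principal axis of the
    target submatrix, sign-oriented to correlate positively with mean_z.
    """
    if method not in {"mean_z", "first_pc"}:
        raise ValueError("method must be 'mean_z' or 'first_pc'")
    present = resolve_set_genes(matrix, target_set, min_coverage)
    if len(present) < 2:
        raise ValueError(f"gene set {target_set.name!r}: need >= 2 targets present")
    z = _zscore_submatrix(matrix, present, target_set.name)
    mean_z = z.mean(axis=0)
    if method == "mean_z":
        out = mean_z
    else:
        centered = z.to_numpy() - z.to_numpy().mean(axis=1, keepdims=True)
        _, _, vt = np.linalg.svd(centered.T, full_matrices=False)
        proj = centered.T @ vt[0]
        if np.corrcoef(proj, mean_z.to_numpy())[0, 1] < 0:
            proj = -proj
        out = pd.Series(proj, index=z.columns)
    return out.rename(f"{target_set.name}_activity")


def load_weights(path: str | Path) -> dict[str, float]:
    """Read per-gene weights from a two-column (gene, weight) TSV."""
    df = pd.read_csv(path, sep="\t", header=None, names=["gene", "weight"], comment="#")
    return {str(g).upper(): float(w) for g, w in zip(df["gene"], df["weight"])}


def fao_score(
    matrix: ExpressionMatrix,
    fao_genes: GeneSet,
    weights: dict[str, float] | None = None,
    min_coverage: float = 0.5,
) -> pd.Series:
    """Fatty-acid-oxidation score: weighted sum of z-scored enzyme genes.

    Default weights are uniform 1/|S|; a user-supplied weight table (e.g.
    the published enzyme-specific coefficients) overrides them. Weights for
    genes absent from the matrix are ignored with a warning.
    """
    present = resolve_set_genes(matrix, fao_genes, min_coverage)
    if len(present) < 2:
        raise ValueError("need >= 2 FAO genes present")
    z = _zscore_submatrix(matrix, present, fao_genes.name)
    kept = z.index.tolist()
    if weights is None:
        w = pd.Series(1.0 / len(fao_genes), index=kept)
    else:
        missing = set(weights) - set(kept)
        if missing:
            logger.warning("fao_score: weights for absent genes ignored: %s", sorted(missing))
        w = pd.Series({g: weights.get(g, 0.0) for g in kept})
    return z.mul(w, axis=0).sum(axis=0).rename(f"{fao_genes.name}_score")
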