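"""EMT quantification: 76GS, signed KS, and Epi/Mes/pEMT enrichment scores.

Four complementary metrics place each sample on the epithelial–mesenchymal
spectrum:

* **76GS** — a weighted sum over a 76-gene signature, each gene weighted by
  its Pearson correlation with CDH1 (E-cadherin) across the cohort and
  mean-centred per gene, so the cohort mean score is 0. Higher = more
  epithelial.
* **KS** — the signed two-sample Kolmogorov–Smirnov statistic comparing the
  per-sample expression distributions of an epithelial and a mesenchymal
  gene list. Scores lie in [−1, 1]; positive means the mesenchymal genes
  sit higher in the sample's expression distribution.
* **Epi / Mes / pEMT** — ssGSEA NES on the KS epithelial list, the KS
  mesenchymal list, and a partial-EMT signature respectively. A hybrid
  epithelial/mesenchymal sample scores intermediate on KS but high on pEMT.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import ks_2samp

from plastiscore.data_io import ExpressionMatrix, GeneSet
from plastiscore.gene_set_scoring import (
    ScoreTable,
    SsgseaParams,
    resolve_set_genes,
    ssgsea_score,
)

logger = logging.getLogger(__name__)

ANCHOR_GENE = "CDH1"


@dataclass
class EmtGeneLists:
    """The gene lists backing the four EMT metrics."""

    gs76: GeneSet
    ks_epithelial: GeneSet
    ks_mesenchymal: GeneSet
    pemt: GeneSet

    def __post_init__(self) -> None:
        overlap = self.ks_epithelial.genes & self.ks_mesenchymal.genes
        if overlap:
            raise ValueError(
                f"epithelial and mesenchymal lists overlap: {sorted(overlap)[:5]}"
            )

    @classmethod
    def from_collection(cls, coll) -> "EmtGeneLists":
        """Build from a GMT collection with sets GS76, KS_EPI, KS_MES, PEMT."""
        try:
            return cls(
                gs76=coll["GS76"],
                ks_epithelial=coll["KS_EPI"],
                ks_mesenchymal=coll["KS_MES"],
                pemt=coll["PEMT"],
            )
        except KeyError as e:
            raise KeyError(
                "EMT GMT must contain sets named GS76, KS_EPI, KS_MES, PEMT"
            ) from e


def score_76gs(
    matrix: ExpressionMatrix,
    gs76: GeneSet,
    weight_method: str = "pearson",
    min_coverage: float = 0.5,
) -> pd.Series:
    """CDH1-correlation-weighted 76-gene EMT score (higher = epithelial).

    Each listed gene g gets weight w_g = corr(x_g, x_CDH1) across samples;
    the per-sample score is Σ_g w_g · (x_g − mean_g). Mean-centring per gene
    makes the score platform-offset free and zero-mean over the cohort.
    Zero-variance genes carry no information and are dropped.
    """
    if weight_method not in {"pearson", "spearman"}:
        raise ValueError("weight_method must be 'pearson' or 'spearman'")
    if ANCHOR_GENE not in matrix.data.index:
        raise ValueError(f"{ANCHOR_GENE} absent from matrix; 76GS weights undefined")
    if matrix.n_samples < 2:
        raise ValueError("76GS needs >= 2 samples to estimate weights")
    present = resolve_set_genes(matrix, gs76, min_coverage)
    sub = matrix.data.loc[present]
    sd = sub.std(axis=1, ddof=1)
    if (sd == 0).all():
        raise ValueError("all signature genes constant across samples")
    if (sd == 0).any():
        logger.warning("76GS: dropped %d zero-variance genes", int((sd == 0).sum()))
        sub = sub.loc[sd > 0]
    anchor = matrix.data.loc[ANCHOR_GENE]
    if anchor.std(ddof=1) == 0:
        raise ValueError(f"{ANCHOR_GENE} constant across samples; weights undefined")
    if weight_method == "spearman":
        sub_w, anchor_w = sub.rank(axis=1), anchor.rank()
    else:
        sub_w, anchor_w = sub, anchor
    weights = sub_w.T.corrwith(anchor_w)
    centered = sub.sub(sub.mean(axis=1), axis=0)
    return centered.mul(weights, axis=0).sum(axis=0).rename("76GS")


def _signed_ks_sample(e_vals: np.ndarray, m_vals: np.ndarray) -> tuple[float, float]:
    """Signed KS statistic for one sample; positive = mesenchymal higher.

    D+ = sup(CDF_E − CDF_M) grows when mesenchymal values dominate (their
    CDF lags); D− = sup(CDF_M − CDF_E) grows when epithelial values
    dominate. The score is +D+ or −D− by whichever is larger; its magnitude
    is the two-sample KS statistic. Returns (score, two-sided p-value).
    """
    grid = np.sort(np.concatenate([e_vals, m_vals]))
    cdf_e = np.searchsorted(np.sort(e_vals), grid, side="right") / e_vals.size
    cdf_m = np.searchsorted(np.sort(m_vals), grid, side="right") / m_vals.size
    diff = cdf_e - cdf_m
    d_plus = float(diff.max())
    d_minus = float(-diff.min())
    if abs(d_plus - d_minus) < 1e-9:
        logger.info("KS: D+ and D- tie within 1e-9; sign taken from D+ >= D-")
    score = d_plus if d_plus >= d_minus else -d_minus
    p = float(ks_2samp(e_vals, m_vals).pvalue)
    return score, p


def score_ks(
    matrix: ExpressionMatrix,
    epithelial: GeneSet,
    mesenchymal: GeneSet,
    min_coverage: float = 0.5,
) -> pd.DataFrame:
    """Per-sample signed KS EMT score and two-sided KS test p-value.

    Returns a DataFrame with columns ``KS`` (in [−1, 1], positive =
    mesenchymal) and ``KS_pvalue``.
    """
    e_genes = resolve_set_genes(matrix, epithelial, min_coverage)
    m_genes = resolve_set_genes(matrix, mesenchymal, min_coverage)
    if set(e_genes) & set(m_genes):
        raise ValueError("epithelial and mesenchymal lists overlap in matrix")
    e_block = matrix.data.loc[e_genes].to_numpy()
    m_block = matrix.data.loc[m_genes].to_numpy()
    rows = [
        _signed_ks_sample(e_block[:, j], m_block[:, j]) for j in range(matrix.n_samples)
    ]
    return pd.DataFrame(rows, index=matrix.data.columns, columns=["KS", "KS_pvalue"])


def score_epi_mes_pemt(
    matrix: ExpressionMatrix,
    lists: EmtGeneLists,
    params: SsgseaParams | None = None,
) -> pd.DataFrame:
    """ssGSEA NES on the epithelial, mesenchymal and partial-EMT lists.

    Columns: ``Epi``, ``Mes``, ``pEMT``.
    """
    params = params or SsgseaParams()
    return pd.DataFrame(
        {
            "Epi": ssgsea_score(matrix, lists.ks_epithelial, params),
            "Mes": ssgsea_score(matrix, lists.ks_mesenchymal, params),
            "pEMT": ssgsea_score(matrix, lists.pemt, params),
        }
    )


def emt_score_table(
    matrix: ExpressionMatrix,
    lists: EmtGeneLists,
    params: SsgseaParams | None = None,
) -> ScoreTable:
    """All EMT metrics for a matrix: 76GS, KS (+p), Epi, Mes, pEMT."""
    params = params or SsgseaParams()
    df = score_epi_mes_pemt(matrix, lists, params)
    df.insert(0, "76GS", score_76gs(matrix, lists.gs76))
    ks = score_ks(matrix, lists.ks_epithelial, lists.ks_mesenchymal)
    df.insert(1, "KS", ks["KS"])
    df["KS_pvalue"] = ks["KS_pvalue"]
    return ScoreTable(df)
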