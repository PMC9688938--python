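"""Pan-dataset correlation meta-analysis.

For each dataset, pairs of signature scores (e.g. PD-L1 activity vs. the
mesenchymal NES) are correlated per sample; across datasets the resulting
(ρ, p) records are aggregated volcano-style — a dataset counts as
significant when |ρ| > 0.3 and p < 0.05 (strict inequalities) — and
summarised as positive/negative counts. Datasets significant in *two*
pairwise comparisons are cross-tabulated into sign quadrants. A long-form
checkpoint-gene × hallmark-pathway Spearman table backs the heatmap view,
flagging cells with p > 0.05 as not significant ('X').

Raw p-values drive every headline count (no multiple-testing correction,
matching the published procedure); a Benjamini–Hochberg column is emitted
alongside for transparency.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from plastiscore.gene_set_scoring import ScoreTable

logger = logging.getLogger(__name__)

#: smallest reportable p-value; keeps p strictly positive
P_FLOOR = float(np.finfo(float).tiny)

DEFAULT_R_THRESHOLD = 0.3
DEFAULT_P_THRESHOLD = 0.05


@dataclass(frozen=True)
class CorrelationRecord:
    """One dataset's correlation between two score metrics."""

    dataset_id: str
    metric_x: str
    metric_y: str
    rho: float
    p_value: float
    n_samples: int
    method: str = "spearman"

    @property
    def is_defined(self) -> bool:
        return np.isfinite(self.rho)


@dataclass
class VolcanoSummary:
    """Counts of significant positive/negative correlations across datasets."""

    metric_x: str
    metric_y: str
    n_total: int
    n_significant: int
    n_positive: int
    n_negative: int
    r_threshold: float = DEFAULT_R_THRESHOLD
    p_threshold: float = DEFAULT_P_THRESHOLD

    def __post_init__(self) -> None:
        assert self.n_positive + self.n_negative == self.n_significant <= self.n_total

    @property
    def positive_fraction(self) -> float:
        """Fraction of significant datasets with a positive correlation."""
        if self.n_significant == 0:
            return float("nan")
        return self.n_positive / self.n_significant


@dataclass
class QuadrantSummary:
    """Sign-quadrant counts for datasets significant in both of two pairs."""

    pair_x: tuple[str, str]
    pair_y: tuple[str, str]
    counts: dict[str, int] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def correlate_pair(
    scores: ScoreTable,
    metric_x: str,
    metric_y: str,
    method: str = "spearman",
    dataset_id: str = "",
) -> CorrelationRecord:
    """Correlate two score columns across samples (Spearman by default).

    A constant metric yields a record with ρ = NaN, excluded downstream.
    """
    if method not in {"spearman", "pearson"}:
        raise ValueError("method must be 'spearman' or 'pearson'")
    for m in (metric_x, metric_y):
        if m not in scores.data.columns:
            raise KeyError(f"metric {m!r} not in score table")
    pair = scores.data[[metric_x, metric_y]].dropna()
    n = len(pair)
    if n < 3:
        raise ValueError(f"need >= 3 paired samples, got {n}")
    x, y = pair[metric_x].to_numpy(), pair[metric_y].to_numpy()
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        logger.warning(
            "dataset %s: constant metric in pair (%s, %s); rho undefined",
            dataset_id, metric_x, metric_y,
        )
        return CorrelationRecord(dataset_id, metric_x, metric_y, float("nan"), 1.0, n, method)
    if method == "spearman":
        rho, p = stats.spearmanr(x, y)
    else:
        rho, p = stats.pearsonr(x, y)
    p = max(float(p), P_FLOOR)
    return CorrelationRecord(dataset_id, metric_x, metric_y, float(rho), p, n, method)


def _is_significant(rec: CorrelationRecord, r_threshold: float, p_threshold: float) -> bool:
    return rec.is_defined and abs(rec.rho) > r_threshold and rec.p_value < p_threshold


def records_to_frame(records: list[CorrelationRecord]) -> pd.DataFrame:
    """Long-form view of correlation records (one row per dataset)."""
    return pd.DataFrame(
        {
            "dataset_id": [r.dataset_id for r in records],
            "metric_x": [r.metric_x for r in records],
            "metric_y": [r.metric_y for r in records],
            "rho": [r.rho for r in records],
            "p_value": [r.p_value for r in records],
            "n_samples": [r.n_samples for r in records],
        }
    )


def volcano_classify(
    records: list[CorrelationRecord],
    r_threshold: float = DEFAULT_R_THRESHOLD,
    p_threshold: float = DEFAULT_P_THRESHOLD,
) -> tuple[VolcanoSummary, pd.DataFrame]:
    """Classify per-dataset correlations as significant positive/negative.

    Returns the summary and a per-record classification table (with a BH
    q-value column emitted for reference, unused in the counts). Records
    with undefined ρ are excluded from ``n_total`` with a logged reason.
    """
    if not records:
        raise ValueError("no correlation records supplied")
    pairs = {(r.metric_x, r.metric_y) for r in records}
    if len(pairs) > 1:
        raise ValueError(f"records mix metric pairs: {sorted(pairs)}")
    defined = [r for r in records if r.is_defined]
    n_dropped = len(records) - len(defined)
    if n_dropped:
        logger.warning("volcano_classify: %d records with undefined rho excluded", n_dropped)
    table = records_to_frame(defined)
    table["significant"] = [
        _is_significant(r, r_threshold, p_threshold) for r in defined
    ]
    table["direction"] = np.where(table["rho"] > 0, "positive", "negative")
    table["q_value"] = (
        stats.false_discovery_control(table["p_value"].to_numpy())
        if len(table)
        else np.array([])
    )
    sig = table[table["significant"]]
    (mx, my), = pairs
    summary = VolcanoSummary(
        metric_x=mx,
        metric_y=my,
        n_total=len(defined),
        n_significant=len(sig),
        n_positive=int((sig["rho"] > 0).sum()),
        n_negative=int((sig["rho"] < 0).sum()),
        r_threshold=r_threshold,
        p_threshold=p_threshold,
    )
    return summary, table


def quadrant_count(
    records_x: list[CorrelationRecord],
    records_y: list[CorrelationRecord],
    r_threshold: float = DEFAULT_R_THRESHOLD,
    p_threshold: float = DEFAULT_P_THRESHOLD,
) -> QuadrantSummary:
    """Cross-tabulate datasets significant in both metric pairs by sign.

    Quadrant keys are '++', '+-', '-+', '--' for (sign ρ_x, sign ρ_y).
    """
    def _index(records: list[CorrelationRecord]) -> dict[str, CorrelationRecord]:
        out: dict[str, CorrelationRecord] = {}
        for r in records:
            if r.dataset_id in out:
                raise ValueError(f"dataset {r.dataset_id!r} duplicated within one pair")
            out[r.dataset_id] = r
        return out

    by_x, by_y = _index(records_x), _index(records_y)
    counts = {"++": 0, "+-": 0, "-+": 0, "--": 0}
    for ds in by_x.keys() & by_y.keys():
        rx, ry = by_x[ds], by_y[ds]
        if _is_significant(rx, r_threshold, p_threshold) and _is_significant(
            ry, r_threshold, p_threshold
        ):
            key = ("+" if rx.rho > 0 else "-") + ("+" if ry.rho > 0 else "-")
            counts[key] += 1
    pair_x = (records_x[0].metric_x, records_x[0].metric_y) if records_x else ("", "")
    pair_y = (records_y[0].metric_x, records_y[0].metric_y) if records_y else ("", "")
    return QuadrantSummary(pair_x=pair_x, pair_y=pair_y, counts=counts)


def checkpoint_hallmark_table(
    scores: ScoreTable,
    checkpoint_genes: list[str],
    hallmark_metrics: list[str],
    p_threshold: float = 0.05,
) -> pd.DataFrame:
    """Checkpoint-gene expression × hallmark-score Spearman table.

    Long-form rows (gene, metric, rho, p_value, q_value, significant);
    significance at p ≤ p_threshold — cells above it correspond to the 'X'
    marks on the published-style heatmap. Checkpoint genes are looked up as
    ``EXPR:<gene>`` columns, falling back to the bare gene name; missing
    genes yield all-NaN rows with a warning.
    """
    for m in hallmark_metrics:
        if m not in scores.data.columns:
            raise KeyError(f"hallmark metric {m!r} not in score table")
    rows = []
    for gene in checkpoint_genes:
        col = f"EXPR:{gene}" if f"EXPR:{gene}" in scores.data.columns else gene
        if col not in scores.data.columns:
            logger.warning("checkpoint gene %s absent from score table", gene)
            for m in hallmark_metrics:
                rows.append((gene, m, np.nan, np.nan, False))
            continue
        for m in hallmark_metrics:
            rec = correlate_pair(scores, col, m, method="spearman")
            rows.append((gene, m, rec.rho, rec.p_value, rec.p_value <= p_threshold))
    out = pd.DataFrame(
        rows, columns=["gene", "metric", "rho", "p_value", "significant"]
    )
    valid = out["p_value"].notna()
    out["q_value"] = np.nan
    if valid.any():
        out.loc[valid, "q_value"] = stats.false_discovery_control(
            out.loc[valid, "p_value"].to_numpy()
        )
    return out
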