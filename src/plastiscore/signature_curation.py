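"""PD-L1 activity-signature curation by pan-cancer co-expression.

A gene joins the signature when it is robustly co-expressed with an anchor
gene (CD274/PD-L1 by default) across a compendium of cancer-type cohorts:
Spearman ρ > ``rho_min`` and p < ``p_max`` with the anchor in at least
``min_cohorts`` cohorts. The anchor itself is excluded by default so that
downstream signature-vs-anchor correlations are not circular.

Per-cohort Spearman statistics are computed for all genes at once (rank
transform + vectorised Pearson), with p-values from the large-sample
t-approximation — the same approximation scipy uses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special
from scipy.stats import rankdata

from plastiscore.data_io import ExpressionMatrix, GeneSet

logger = logging.getLogger(__name__)


@dataclass
class PanCancerCompendium:
    """Named cancer-type cohorts, each an expression matrix."""

    cohorts: dict[str, ExpressionMatrix] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.cohorts) < 2:
            raise ValueError("compendium needs >= 2 cohorts")

    def __len__(self) -> int:
        return len(self.cohorts)

    def __iter__(self):
        return iter(self.cohorts.items())


@dataclass
class CurationParams:
    """Thresholds for signature membership.

    Defaults mirror the published rule: ρ > 0.5, p < 0.01, in at least 15
    cohorts of the compendium.
    """

    rho_min: float = 0.5
    p_max: float = 0.01
    min_cohorts: int = 15
    anchor_gene: str = "CD274"
    include_anchor: bool = False
    min_samples: int = 4

    def __post_init__(self) -> None:
        if not 0 < self.rho_min < 1:
            raise ValueError("rho_min must lie in (0, 1)")
        if not 0 < self.p_max < 1:
            raise ValueError("p_max must lie in (0, 1)")
        if self.min_cohorts < 1:
            raise ValueError("min_cohorts must be >= 1")


def spearman_vs_anchor(matrix: ExpressionMatrix, anchor_gene: str) -> pd.DataFrame:
    """Spearman ρ and two-sided p of every gene against the anchor gene.

    Returns a DataFrame indexed by gene with columns ``rho`` and ``p``.
    Constant genes get ρ = NaN (they never qualify).
    """
    if anchor_gene not in matrix.data.index:
        raise ValueError(f"anchor gene {anchor_gene!r} absent from cohort")
    vals = matrix.values
    n = matrix.n_samples
    anchor = vals[matrix.data.index.get_loc(anchor_gene)]
    if np.unique(anchor).size == 1:
        raise ValueError(f"anchor gene {anchor_gene!r} constant in cohort")
    ranks = np.apply_along_axis(rankdata, 1, vals)
    a_rank = rankdata(anchor)
    ranks_c = ranks - ranks.mean(axis=1, keepdims=True)
    a_c = a_rank - a_rank.mean()
    denom = np.sqrt((ranks_c**2).sum(axis=1) * (a_c**2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = np.where(denom > 0, ranks_c @ a_c / denom, np.nan)
        rho = np.clip(rho, -1.0, 1.0)
        t = rho * np.sqrt((n - 2) / np.maximum(1.0 - rho**2, 1e-300))
    p = special.stdtr(n - 2, -np.abs(t)) * 2
    p = np.where(np.abs(rho) >= 1.0, 0.0, p)
    return pd.DataFrame({"rho": rho, "p": p}, index=matrix.data.index)


def curate_signature(
    compendium: PanCancerCompendium,
    params: CurationParams | None = None,
) -> GeneSet:
    """Genes co-expressed with the anchor in enough cohorts.

    A gene qualifies in a cohort iff ρ > rho_min and p < p_max (strict);
    the returned set contains genes qualifying in ≥ min_cohorts cohorts.
    Cohorts with fewer than ``min_samples`` samples are excluded with a
    warning (their p-values are unstable).
    """
    params = params or CurationParams()
    counts: pd.Series | None = None
    n_used = 0
    for name, cohort in compendium:
        if cohort.n_samples < params.min_samples:
            logger.warning(
                "cohort %s excluded: only %d samples", name, cohort.n_samples
            )
            continue
        stats = spearman_vs_anchor(cohort, params.anchor_gene)
        qual = ((stats["rho"] > params.rho_min) & (stats["p"] < params.p_max)).astype(int)
        counts = qual if counts is None else counts.add(qual, fill_value=0)
        n_used += 1
    if counts is None:
        raise ValueError("all cohorts excluded; cannot curate signature")
    if params.min_cohorts > n_used:
        logger.warning(
            "min_cohorts=%d exceeds usable cohorts (%d); signature will be empty-prone",
            params.min_cohorts, n_used,
        )
    selected = set(counts.index[counts >= params.min_cohorts])
    if not params.include_anchor:
        selected.discard(params.anchor_gene)
    if not selected:
        raise ValueError("no gene met the curation thresholds")
    return GeneSet(name=f"{params.anchor_gene}_SIGNATURE", genes=frozenset(selected), role="signature")
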