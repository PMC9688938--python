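"""Survival stratification by joint PD-L1/glycolysis status.

Samples are median-split on a PD-L1 metric (signature NES or CD274
expression) and a glycolysis metric into P+G+ (high on both) and P+G−
(high PD-L1, low glycolysis); ties go to "low". The two groups are compared
with Kaplan–Meier curves, the log-rank test, and a single-binary-covariate
Cox proportional-hazards fit (Efron tie handling) reporting HR, 95% CI,
log2(HR) and the Wald p-value. log2HR > 0 means the first group (P+G+) has
an increased mortality risk.

Estimation is delegated to `lifelines`; complete separation (monotone
likelihood) is caught and reported as a flagged infinite-HR result rather
than a crash.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test

from plastiscore.gene_set_scoring import ScoreTable

logger = logging.getLogger(__name__)

P_HIGH_G_HIGH = "P+G+"
P_HIGH_G_LOW = "P+G-"
OTHER = "other"


@dataclass
class SurvivalCohort:
    """Time-to-event records: index sample_id, columns time and event.

    ``event`` is 1 for an observed death, 0 for censoring; times are
    non-negative and in consistent (pass-through) units.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = {"time", "event"} - set(self.data.columns)
        if missing:
            raise ValueError(f"survival table missing columns: {sorted(missing)}")
        if self.data["time"].isna().any():
            raise ValueError("missing survival times")
        if (self.data["time"] < 0).any():
            raise ValueError("negative survival times")
        if not self.data["event"].isin([0, 1]).all():
            raise ValueError("event must be 0 (censored) or 1 (death)")

    @property
    def sample_ids(self) -> list[str]:
        return self.data.index.tolist()


@dataclass
class GroupAssignment:
    """Sample → {P+G+, P+G-, other} labels plus the thresholds used."""

    labels: pd.Series
    split_rule: dict[str, float] = field(default_factory=dict)

    def samples_in(self, label: str) -> list[str]:
        return self.labels.index[self.labels == label].tolist()


@dataclass
class CoxResult:
    """Two-group Cox fit: HR with 95% CI, log2HR, Wald p, group sizes."""

    hazard_ratio: float
    ci_low: float
    ci_high: float
    log2_hr: float
    p_value: float
    n_per_group: dict[str, int]
    converged: bool = True

    def __post_init__(self) -> None:
        if self.converged and not (
            self.ci_low <= self.hazard_ratio <= self.ci_high
        ):
            raise ValueError("CI must bracket the hazard ratio")


def read_clinical(path: str | Path) -> SurvivalCohort:
    """Read a clinical TSV with columns sample_id, os_time, os_event."""
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "os_time", "os_event"}
    if not required <= set(df.columns):
        raise ValueError(f"clinical table needs columns {sorted(required)}")
    df = df.set_index("sample_id").rename(columns={"os_time": "time", "os_event": "event"})
    return SurvivalCohort(df[["time", "event"]])


def median_split(
    scores: ScoreTable,
    pdl1_metric: str,
    glycolysis_metric: str,
    tie: str = "low",
) -> GroupAssignment:
    """Median-split both metrics; label P+G+, P+G− and other.

    "High" means strictly above the cohort median when ``tie='low'`` (the
    default: ties at the median fall in the low group) or at-or-above the
    median when ``tie='high'``. Thresholds are recorded in the result.
    """
    for m in (pdl1_metric, glycolysis_metric):
        if m not in scores.data.columns:
            raise KeyError(f"metric {m!r} not in score table")
        if scores.data[m].nunique() == 1:
            raise ValueError(f"metric {m!r} constant; median split degenerate")
    if len(scores.data) < 4:
        raise ValueError("median split needs >= 4 samples")
    if tie not in {"low", "high"}:
        raise ValueError("tie must be 'low' or 'high'")
    p, g = scores.data[pdl1_metric], scores.data[glycolysis_metric]
    p_med, g_med = float(p.median()), float(g.median())
    if tie == "low":
        p_high, g_high = p > p_med, g > g_med
    else:
        p_high, g_high = p >= p_med, g >= g_med
    labels = pd.Series(OTHER, index=scores.data.index, name="group")
    labels[p_high & g_high] = P_HIGH_G_HIGH
    labels[p_high & ~g_high] = P_HIGH_G_LOW
    return GroupAssignment(
        labels=labels,
        split_rule={pdl1_metric: p_med, glycolysis_metric: g_med, "tie": tie},
    )


def _two_group_frame(
    cohort: SurvivalCohort,
    groups: GroupAssignment,
    labels: tuple[str, str],
) -> pd.DataFrame:
    common = cohort.data.index.intersection(groups.labels.index)
    df = cohort.data.loc[common].copy()
    df["group"] = groups.labels.loc[common]
    df = df[df["group"].isin(labels)]
    for lab in labels:
        if (df["group"] == lab).sum() == 0:
            raise ValueError(f"group {lab!r} has zero samples")
    return df


@dataclass
class KaplanMeierResult:
    """Per-group KM survival curves plus the two-group log-rank test."""

    curves: dict[str, pd.DataFrame]  # columns: time, survival
    logrank_statistic: float
    logrank_p: float
    n_per_group: dict[str, int]


def kaplan_meier(
    cohort: SurvivalCohort,
    groups: GroupAssignment,
    labels: tuple[str, str] = (P_HIGH_G_HIGH, P_HIGH_G_LOW),
) -> KaplanMeierResult:
    """Product-limit survival per group and the two-group log-rank test."""
    df = _two_group_frame(cohort, groups, labels)
    if df["event"].sum() == 0:
        raise ValueError("no events observed; log-rank test undefined")
    curves: dict[str, pd.DataFrame] = {}
    for lab in labels:
        sub = df[df["group"] == lab]
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], sub["event"], label=lab)
        sf = kmf.survival_function_
        curves[lab] = pd.DataFrame(
            {"time": sf.index.to_numpy(), "survival": sf[lab].to_numpy()}
        )
    a, b = (df[df["group"] == lab] for lab in labels)
    res = logrank_test(a["time"], b["time"], a["event"], b["event"])
    return KaplanMeierResult(
        curves=curves,
        logrank_statistic=float(res.test_statistic),
        logrank_p=float(res.p_value),
        n_per_group={lab: int((df["group"] == lab).sum()) for lab in labels},
    )


def cox_hr(
    cohort: SurvivalCohort,
    groups: GroupAssignment,
    labels: tuple[str, str] = (P_HIGH_G_HIGH, P_HIGH_G_LOW),
) -> CoxResult:
    """Single binary-covariate Cox PH fit: hazard of labels[0] vs labels[1].

    Efron approximation for tied event times. Monotone likelihood /
    complete separation yields a flagged result with an infinite HR.
    """
    df = _two_group_frame(cohort, groups, labels)
    for lab in labels:
        if df.loc[df["group"] == lab, "event"].sum() == 0:
            logger.warning("group %s has zero events; fit may be unstable", lab)
    n_per_group = {lab: int((df["group"] == lab).sum()) for lab in labels}
    fit_df = pd.DataFrame(
        {
            "time": df["time"],
            "event": df["event"],
            "exposed": (df["group"] == labels[0]).astype(float),
        }
    )
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(fit_df, duration_col="time", event_col="event")
    except ConvergenceError:
        logger.warning("Cox fit did not converge (monotone likelihood?)")
        sign = 1.0 if df.loc[df["group"] == labels[0], "time"].mean() < df.loc[
            df["group"] == labels[1], "time"
        ].mean() else -1.0
        hr = float("inf") if sign > 0 else 0.0
        return CoxResult(hr, 0.0, float("inf"), sign * float("inf"), 1.0,
                         n_per_group, converged=False)
    beta = float(cph.params_["exposed"])
    se = float(cph.standard_errors_["exposed"])
    hr = float(np.exp(beta))
    # near-separation fits can push the CI bound past float range; the
    # resulting inf bound is a faithful report, not an error
    with np.errstate(over="ignore"):
        ci_low = float(np.exp(beta - 1.959963984540054 * se))
        ci_high = float(np.exp(beta + 1.959963984540054 * se))
    return CoxResult(
        hazard_ratio=hr,
        ci_low=ci_low,
        ci_high=ci_high,
        log2_hr=float(beta / np.log(2)),
        p_value=float(cph.summary.loc["exposed", "p"]),
        n_per_group=n_per_group,
    )


def hazard_by_gene(
    cohort: SurvivalCohort,
    scores: ScoreTable,
    gene_metric: str,
    tie: str = "low",
) -> CoxResult:
    """Median-split a single metric into high/low and fit the Cox HR.

    Reports the hazard of the high-expression group relative to low; used
    row-wise to build forest tables across cancer types.
    """
    if gene_metric not in scores.data.columns:
        raise KeyError(f"metric {gene_metric!r} not in score table")
    col = scores.data[gene_metric]
    if col.nunique() == 1:
        raise ValueError(f"metric {gene_metric!r} constant; median split degenerate")
    med = float(col.median())
    high = col > med if tie == "low" else col >= med
    labels = pd.Series("low", index=col.index, name="group")
    labels[high] = "high"
    groups = GroupAssignment(labels=labels, split_rule={gene_metric: med, "tie": tie})
    return cox_hr(cohort, groups, labels=("high", "low"))
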