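"""End-to-end orchestration: score → meta-analyse → survive, from one config.

A :class:`RunConfig` (typically loaded from YAML) lists the expression
datasets, the gene-set GMT, which metrics to compute, which metric pairs to
meta-analyse, and optional survival settings. :func:`run_all` executes the
stages in order, writes every table as TSV, and emits a machine-readable
JSON report with per-stage row counts, structured warnings and SHA-256
hashes of all outputs, so repeated runs can be compared hash-for-hash.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from plastiscore import data_io
from plastiscore.data_io import ExpressionMatrix
from plastiscore.emt_scoring import EmtGeneLists, emt_score_table
from plastiscore.gene_set_scoring import ScoreTable, SsgseaParams, ssgsea_score
from plastiscore.meta_analysis import (
    correlate_pair,
    quadrant_count,
    records_to_frame,
    volcano_classify,
)
from plastiscore.survival import cox_hr, kaplan_meier, median_split, read_clinical

logger = logging.getLogger(__name__)

#: metrics handled by the EMT panel rather than plain ssGSEA
EMT_METRICS = {"76GS", "KS", "Epi", "Mes", "pEMT"}


class _WarningCollector(logging.Handler):
    """Collects package log records as structured dicts for the run report."""

    def __init__(self) -> None:
        super().__init__(level=logging.WARNING)
        self.records: list[dict] = []

    def emit(self, record: logging.LogRecord) -> None:
        self.records.append(
            {"logger": record.name, "level": record.levelname, "message": record.getMessage()}
        )


@dataclass
class RunConfig:
    """Declarative description of a full pipeline run."""

    datasets: list[dict]  # each: {id, path, transpose?}
    gene_sets: str  # GMT path; may include GS76/KS_EPI/KS_MES/PEMT
    metrics: list[str]  # EMT panel names and/or gene-set names for ssGSEA
    expression_genes: list[str] = field(default_factory=list)  # emitted as EXPR:<gene>
    pairs: list[tuple[str, str]] = field(default_factory=list)
    quadrants: list[tuple[list[str], list[str]]] = field(default_factory=list)
    r_threshold: float = 0.3
    p_threshold: float = 0.05
    correlation_method: str = "spearman"
    ssgsea: SsgseaParams = field(default_factory=SsgseaParams)
    survival: dict | None = None  # {clinical, pdl1_metric, glycolysis_metric, dataset}
    out_dir: str = "plastiscore_out"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        ss = raw.pop("ssgsea", None)
        cfg = cls(**raw)
        if ss:
            cfg.ssgsea = SsgseaParams(**ss)
        cfg.pairs = [tuple(p) for p in cfg.pairs]
        cfg.quadrants = [(list(a), list(b)) for a, b in cfg.quadrants]
        return cfg

    def validate(self) -> None:
        for ds in self.datasets:
            if not Path(ds["path"]).exists():
                raise FileNotFoundError(f"dataset {ds.get('id')}: missing {ds['path']}")
        if not Path(self.gene_sets).exists():
            raise FileNotFoundError(f"gene-set GMT missing: {self.gene_sets}")
        if self.survival and not Path(self.survival["clinical"]).exists():
            raise FileNotFoundError(f"clinical table missing: {self.survival['clinical']}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def score_dataset(
    matrix: ExpressionMatrix,
    collection: data_io.GeneSetCollection,
    metrics: list[str],
    expression_genes: list[str],
    params: SsgseaParams,
) -> ScoreTable:
    """Compute the requested metric columns for one dataset."""
    cols: dict[str, pd.Series] = {}
    if EMT_METRICS & set(metrics):
        emt = emt_score_table(matrix, EmtGeneLists.from_collection(collection), params)
        for m in metrics:
            if m in EMT_METRICS:
                cols[m] = emt.data[m]
    for m in metrics:
        if m in EMT_METRICS:
            continue
        if m not in collection:
            raise KeyError(f"metric {m!r}: no such gene set in the GMT")
        cols[f"NES:{m}"] = ssgsea_score(matrix, collection[m], params)
    for gene in expression_genes:
        g = gene.upper()
        if g not in matrix.data.index:
            logger.warning("expression gene %s absent from matrix", g)
            continue
        cols[f"EXPR:{g}"] = matrix.data.loc[g]
    return ScoreTable(pd.DataFrame(cols))


def run_all(config: RunConfig) -> dict:
    """Execute the configured pipeline and return the run report."""
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    collector = _WarningCollector()
    pkg_logger = logging.getLogger("plastiscore")
    pkg_logger.addHandler(collector)
    report: dict = {"stages": {}, "outputs": {}, "warnings": collector.records,
                    "seed": config.seed}
    try:
        collection = data_io.read_gmt(config.gene_sets)
        score_tables: dict[str, ScoreTable] = {}
        stage = "scoring"
        for ds in config.datasets:
            ds_id = ds["id"]
            try:
                matrix = data_io.read_expression(
                    ds["path"], transpose=bool(ds.get("transpose", False))
                )
                score_tables[ds_id] = score_dataset(
                    matrix, collection, config.metrics, config.expression_genes,
                    config.ssgsea,
                )
            except Exception as e:
                raise RuntimeError(f"stage {stage}: dataset {ds_id}: {e}") from e
            path = out_dir / f"scores_{ds_id}.tsv"
            score_tables[ds_id].to_tsv(path)
            report["outputs"][path.name] = _sha256(path)
        report["stages"]["scoring"] = {
            "n_datasets": len(score_tables),
            "n_samples": {k: len(v.data) for k, v in score_tables.items()},
        }

        stage = "meta_analysis"
        records_by_pair = {}
        for mx, my in config.pairs:
            recs = []
            for ds_id, table in score_tables.items():
                try:
                    recs.append(
                        correlate_pair(table, mx, my, config.correlation_method, ds_id)
                    )
                except Exception as e:
                    raise RuntimeError(f"stage {stage}: dataset {ds_id}: {e}") from e
            records_by_pair[(mx, my)] = recs
            summary, table = volcano_classify(recs, config.r_threshold, config.p_threshold)
            slug = f"{mx}_vs_{my}".replace(":", "").replace("/", "-")
            rec_path = out_dir / f"records_{slug}.tsv"
            table.to_csv(rec_path, sep="\t", index=False, float_format="%.10g")
            report["outputs"][rec_path.name] = _sha256(rec_path)
            report["stages"].setdefault("meta_analysis", {})[f"{mx} vs {my}"] = {
                "n_total": summary.n_total,
                "n_significant": summary.n_significant,
                "n_positive": summary.n_positive,
                "n_negative": summary.n_negative,
            }
        for pair_x, pair_y in config.quadrants:
            qx, qy = tuple(pair_x), tuple(pair_y)
            qs = quadrant_count(
                records_by_pair[qx], records_by_pair[qy],
                config.r_threshold, config.p_threshold,
            )
            key = f"({qx[0]},{qx[1]}) x ({qy[0]},{qy[1]})"
            report["stages"].setdefault("quadrants", {})[key] = qs.counts

        if config.survival:
            stage = "survival"
            sv = config.survival
            cohort = read_clinical(sv["clinical"])
            table = score_tables[sv["dataset"]]
            try:
                groups = median_split(table, sv["pdl1_metric"], sv["glycolysis_metric"])
                km = kaplan_meier(cohort, groups)
                cox = cox_hr(cohort, groups)
            except Exception as e:
                raise RuntimeError(f"stage {stage}: dataset {sv['dataset']}: {e}") from e
            km_path = out_dir / "km_curves.tsv"
            pd.concat(
                [c.assign(group=lab) for lab, c in km.curves.items()]
            ).to_csv(km_path, sep="\t", index=False, float_format="%.10g")
            report["outputs"][km_path.name] = _sha256(km_path)
            report["stages"]["survival"] = {
                "logrank_p": km.logrank_p,
                "hazard_ratio": cox.hazard_ratio,
                "log2_hr": cox.log2_hr,
                "ci": [cox.ci_low, cox.ci_high],
                "cox_p": cox.p_value,
                "n_per_group": cox.n_per_group,
            }
    finally:
        pkg_logger.removeHandler(collector)

    report_path = out_dir / "run_report.json"
    with open(report_path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
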