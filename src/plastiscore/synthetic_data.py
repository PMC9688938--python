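"""Synthetic expression, compendium, time-course and survival generators.

The generators plant the statistical structure that the analysis stages
assume, so the whole pipeline is testable without downloading any cohort:

* Per sample, a vector of latent signature activities (epithelial,
  mesenchymal, partial-EMT, PD-L1, glycolysis, HIF-1α, OXPHOS) is drawn
  from a multivariate normal whose correlation matrix ("coupling") plants
  the pairwise associations of interest — by default PD-L1 couples
  positively to the mesenchymal, partial-EMT, glycolysis and HIF-1α
  programs and negatively to OXPHOS, while being uncorrelated with the
  epithelial program.
* Samples belong to epithelial / hybrid / mesenchymal populations that
  shift the E/M latents; hybrid samples carry simultaneous partial E and M
  activity plus an elevated partial-EMT latent.
* Member genes of each signature read out their latent linearly
  (``baseline + effect_size · latent + N(0, noise_sd)`` on log2 scale);
  CDH1 is tied to the epithelial latent so 76GS weights are recoverable.
* Compendium cohorts plant anchor-correlated genes in an exact number of
  cohorts (for signature-curation recovery tests); survival cohorts draw
  exponential event times with a proportional-hazards group multiplier and
  uniform independent censoring calibrated to a target censoring fraction.

Every generator is a pure function of its config and seed: the same seed
reproduces byte-identical outputs. A truth table accompanies each dataset
recording the planted latents and labels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from plastiscore.data_io import ExpressionMatrix, GeneSet, GeneSetCollection
from plastiscore.signature_curation import PanCancerCompendium
from plastiscore.survival import P_HIGH_G_HIGH, GroupAssignment, SurvivalCohort

logger = logging.getLogger(__name__)

#: order of the latent signature activities
LATENT_NAMES = ("epi", "mes", "pemt", "pdl1", "glycolysis", "hif1a", "oxphos")

#: which gene sets are generated and which latent each reads out
SET_LATENTS = {
    "KS_EPI": "epi",
    "KS_MES": "mes",
    "PEMT": "pemt",
    "PDL1": "pdl1",
    "GLYCOLYSIS": "glycolysis",
    "HIF1A_TARGETS": "hif1a",
    "AMPK_TARGETS": "glycolysis",  # AMPK activity tracks the energy-stress axis
    "OXPHOS": "oxphos",
    "FAO": "oxphos",  # fatty-acid oxidation feeds OXPHOS
}

SET_ROLES = {
    "KS_EPI": "epithelial",
    "KS_MES": "mesenchymal",
    "PEMT": "pemt",
    "PDL1": "signature",
    "GLYCOLYSIS": "hallmark_pathway",
    "HIF1A_TARGETS": "target_set",
    "AMPK_TARGETS": "target_set",
    "OXPHOS": "hallmark_pathway",
    "FAO": "target_set",
}

DEFAULT_SET_SIZES = {
    "KS_EPI": 25,
    "KS_MES": 25,
    "PEMT": 30,
    "PDL1": 30,
    "GLYCOLYSIS": 30,
    "HIF1A_TARGETS": 23,
    "AMPK_TARGETS": 33,
    "OXPHOS": 30,
    "FAO": 14,
}

#: population mean shifts (in latent SD units) for (epi, mes, pemt)
POPULATION_SHIFTS = {
    "epithelial": {"epi": 1.0, "mes": -1.0, "pemt": 0.0},
    "hybrid": {"epi": 0.5, "mes": 0.5, "pemt": 1.0},
    "mesenchymal": {"epi": -1.0, "mes": 1.0, "pemt": 0.0},
}


def default_coupling() -> pd.DataFrame:
    """Default latent correlation matrix, mirroring the planted sign
    structure: PD-L1 +Mes, +pEMT, +glycolysis, +HIF-1α, −OXPHOS; Epi ⊥ PD-L1.
    """
    c = pd.DataFrame(np.eye(len(LATENT_NAMES)), index=LATENT_NAMES, columns=LATENT_NAMES)

    def put(a: str, b: str, v: float) -> None:
        c.loc[a, b] = c.loc[b, a] = v

    put("epi", "mes", -0.5)
    put("mes", "pemt", 0.4)
    put("pdl1", "mes", 0.5)
    put("pdl1", "pemt", 0.5)
    put("pdl1", "glycolysis", 0.5)
    put("pdl1", "hif1a", 0.5)
    put("pdl1", "oxphos", -0.4)
    put("glycolysis", "hif1a", 0.5)
    put("glycolysis", "oxphos", -0.3)
    put("hif1a", "oxphos", -0.3)
    return c


def _nearest_psd(c: np.ndarray) -> np.ndarray:
    w, v = np.linalg.eigh(c)
    w = np.clip(w, 1e-10, None)
    fixed = v @ np.diag(w) @ v.T
    d = np.sqrt(np.diag(fixed))
    return fixed / np.outer(d, d)


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic generators.

    ``effect_size`` is the loading of a member gene on its latent (in noise
    SD units on log2 scale); ``population_fractions`` are the epithelial /
    hybrid / mesenchymal mixture weights; ``coupling`` is the latent
    correlation matrix (defaults to :func:`default_coupling`);
    ``hazard_multiplier`` is the P+G+ : P+G− hazard ratio used by
    :func:`generate_survival`.
    """

    seed: int = 0
    n_genes: int = 2000
    n_samples: int = 100
    set_sizes: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_SET_SIZES))
    n_gs76: int = 76
    population_fractions: tuple[float, float, float] = (0.4, 0.2, 0.4)
    effect_size: float = 2.0
    coupling: pd.DataFrame | None = None
    baseline_mean: float = 8.0
    baseline_sd: float = 1.0
    noise_sd: float = 1.0
    hazard_multiplier: float = 2.0
    baseline_hazard: float = 0.01
    censoring_fraction: float = 0.2

    def __post_init__(self) -> None:
        if abs(sum(self.population_fractions) - 1.0) > 1e-9:
            raise ValueError("population fractions must sum to 1")
        if self.coupling is None:
            self.coupling = default_coupling()
        c = self.coupling.loc[list(LATENT_NAMES), list(LATENT_NAMES)].to_numpy()
        if not np.allclose(c, c.T):
            raise ValueError("coupling matrix must be symmetric")
        eigmin = float(np.linalg.eigvalsh(c).min())
        if eigmin < -1e-10:
            near = _nearest_psd(c)
            raise ValueError(
                "coupling matrix is not positive semi-definite "
                f"(min eigenvalue {eigmin:.3g}); nearest PSD correlation:\n{near}"
            )

    def with_coupling(self, a: str, b: str, value: float) -> "SyntheticConfig":
        """Copy of the config with one coupling entry replaced."""
        c = self.coupling.copy()
        c.loc[a, b] = c.loc[b, a] = value
        return replace(self, coupling=c)


def _gene_universe(config: SyntheticConfig) -> tuple[list[str], GeneSetCollection, dict[str, list[str]]]:
    """Allocate gene symbols to signature sets and background.

    The 76-gene EMT list is composed of CDH1, a block of epithelial-latent
    genes and a block of mesenchymal-latent genes, so its CDH1-correlation
    weights have both signs, as in the real signature.
    """
    members: dict[str, list[str]] = {}
    for name, size in config.set_sizes.items():
        members[name] = [f"{name}_G{i:03d}" for i in range(size)]
    # 76GS: CDH1 + extra epi-tied genes + extra mes-tied genes
    n_extra = config.n_gs76 - 1
    n_epi_extra = (n_extra + 1) // 2
    n_mes_extra = n_extra - n_epi_extra
    gs76_epi = ["CDH1"] + [f"GS76E_G{i:03d}" for i in range(n_epi_extra)]
    gs76_mes = [f"GS76M_G{i:03d}" for i in range(n_mes_extra)]
    members["_GS76_EPI"] = gs76_epi
    members["_GS76_MES"] = gs76_mes
    # CD274 (PD-L1 itself) reads out the pdl1 latent but stays out of the
    # curated PDL1 signature set, mirroring anchor exclusion in curation
    members["_CD274"] = ["CD274"]
    named = [g for genes in members.values() for g in genes]
    n_background = config.n_genes - len(named)
    if n_background < 0:
        raise ValueError("n_genes too small for the requested set sizes")
    background = [f"BG_G{i:04d}" for i in range(n_background)]
    universe = named + background

    coll = GeneSetCollection()
    for name in config.set_sizes:
        coll.add(GeneSet(name=name, genes=frozenset(members[name]), role=SET_ROLES[name]))
    coll.add(GeneSet(name="GS76", genes=frozenset(gs76_epi + gs76_mes), role="signature"))
    return universe, coll, members


def _draw_latents(
    rng: np.random.Generator, config: SyntheticConfig, n: int
) -> tuple[pd.DataFrame, np.ndarray]:
    """Latent activities (n × latents) plus population labels."""
    c = config.coupling.loc[list(LATENT_NAMES), list(LATENT_NAMES)].to_numpy()
    z = rng.multivariate_normal(np.zeros(len(LATENT_NAMES)), c, size=n, method="eigh")
    latents = pd.DataFrame(z, columns=LATENT_NAMES)
    pops = rng.choice(
        ["epithelial", "hybrid", "mesenchymal"], size=n, p=config.population_fractions
    )
    for pop, shifts in POPULATION_SHIFTS.items():
        mask = pops == pop
        for lat, delta in shifts.items():
            latents.loc[mask, lat] += delta
    return latents, pops


def generate_bulk_dataset(
    config: SyntheticConfig,
    dataset_id: str = "SYNTH",
) -> tuple[ExpressionMatrix, GeneSetCollection, pd.DataFrame]:
    """One bulk cohort with planted E/hybrid/M populations and couplings.

    Returns the log2-scale expression matrix, the gene-set collection
    (including the 76-gene list as ``GS76``) and a truth table with one row
    per sample (population label and every latent activity).
    """
    rng = np.random.default_rng(config.seed)
    universe, coll, members = _gene_universe(config)
    latents, pops = _draw_latents(rng, config, config.n_samples)
    n_genes, n_samples = len(universe), config.n_samples

    baseline = rng.normal(config.baseline_mean, config.baseline_sd, size=n_genes)
    x = np.tile(baseline[:, None], (1, n_samples))
    gene_index = {g: i for i, g in enumerate(universe)}

    def add_effect(genes: list[str], latent: str) -> None:
        idx = [gene_index[g] for g in genes]
        x[idx, :] += config.effect_size * latents[latent].to_numpy()[None, :]

    for name, latent in SET_LATENTS.items():
        add_effect(members[name], latent)
    add_effect(members["_GS76_EPI"], "epi")
    add_effect(members["_GS76_MES"], "mes")
    add_effect(members["_CD274"], "pdl1")
    x += rng.normal(0.0, config.noise_sd, size=x.shape)

    sample_ids = [f"{dataset_id}_S{i:04d}" for i in range(n_samples)]
    matrix = ExpressionMatrix(
        pd.DataFrame(x, index=pd.Index(universe, name="gene"), columns=sample_ids),
        metadata={"dataset_id": dataset_id, "log_scale": True, "seed": config.seed},
    )
    truth = latents.copy()
    truth.insert(0, "population", pops)
    truth.index = pd.Index(sample_ids, name="sample_id")
    return matrix, coll, truth


def generate_compendium(
    config: SyntheticConfig,
    n_cohorts: int = 27,
    planted_genes: int = 40,
    planted_cohort_count: int = 20,
    rho_true: float = 0.7,
    anchor_gene: str = "CD274",
) -> tuple[PanCancerCompendium, frozenset[str]]:
    """Pan-cancer compendium for signature-curation recovery tests.

    Planted genes read out the anchor with Pearson loading ``rho_true`` in
    exactly ``planted_cohort_count`` cohorts (the first ones, per cohort
    order) and are independent noise elsewhere; all remaining genes are
    independent noise everywhere. Returns the compendium and the truth set.
    """
    if planted_cohort_count > n_cohorts:
        raise ValueError("planted_cohort_count cannot exceed n_cohorts")
    rng = np.random.default_rng(config.seed)
    planted = [f"PLANT_G{i:03d}" for i in range(planted_genes)]
    n_null = config.n_genes - planted_genes - 1
    if n_null < 0:
        raise ValueError("n_genes too small for planted_genes")
    null_genes = [f"NULL_G{i:04d}" for i in range(n_null)]
    genes = [anchor_gene] + planted + null_genes
    lam = np.sqrt(1.0 - rho_true**2)
    cohorts: dict[str, ExpressionMatrix] = {}
    for c in range(n_cohorts):
        anchor = rng.normal(size=config.n_samples)
        x = rng.normal(size=(len(genes), config.n_samples))
        x[0] = anchor
        if c < planted_cohort_count:
            x[1 : 1 + planted_genes] = (
                rho_true * anchor[None, :] + lam * x[1 : 1 + planted_genes]
            )
        mat = pd.DataFrame(
            config.baseline_mean + x,
            index=pd.Index(genes, name="gene"),
            columns=[f"C{c:02d}_S{i:03d}" for i in range(config.n_samples)],
        )
        cohorts[f"COHORT_{c:02d}"] = ExpressionMatrix(
            mat, metadata={"dataset_id": f"COHORT_{c:02d}", "log_scale": True}
        )
    return PanCancerCompendium(cohorts), frozenset(planted)


def generate_timecourse(
    config: SyntheticConfig,
    n_timepoints: int = 4,
    cells_per_timepoint: int = 100,
    emt_step: float = 0.75,
) -> tuple[list[ExpressionMatrix], GeneSetCollection, pd.DataFrame]:
    """EMT-induction time course: one cell matrix per timepoint.

    The mesenchymal latent mean advances by ``emt_step`` per timepoint
    while the epithelial mean recedes, emulating induction; all other
    latents co-vary with the E/M axes via the coupling matrix. Suitable for
    rank-AUC (AUCell-style) scoring.
    """
    if cells_per_timepoint < 1:
        raise ValueError("cells_per_timepoint must be >= 1")
    if n_timepoints < 1:
        raise ValueError("n_timepoints must be >= 1")
    universe, coll, members = _gene_universe(config)
    rng = np.random.default_rng(config.seed)
    gene_index = {g: i for i, g in enumerate(universe)}
    baseline = rng.normal(config.baseline_mean, config.baseline_sd, size=len(universe))
    matrices: list[ExpressionMatrix] = []
    truth_rows = []
    c = config.coupling.loc[list(LATENT_NAMES), list(LATENT_NAMES)].to_numpy()
    for t in range(n_timepoints):
        z = rng.multivariate_normal(
            np.zeros(len(LATENT_NAMES)), c, size=cells_per_timepoint, method="eigh"
        )
        latents = pd.DataFrame(z, columns=LATENT_NAMES)
        latents["mes"] += emt_step * t
        latents["epi"] -= emt_step * t
        latents["pemt"] += emt_step * t * 0.5
        x = np.tile(baseline[:, None], (1, cells_per_timepoint))
        for name, latent in SET_LATENTS.items():
            idx = [gene_index[g] for g in members[name]]
            x[idx, :] += config.effect_size * latents[latent].to_numpy()[None, :]
        for key, latent in (("_GS76_EPI", "epi"), ("_GS76_MES", "mes"), ("_CD274", "pdl1")):
            idx = [gene_index[g] for g in members[key]]
            x[idx, :] += config.effect_size * latents[latent].to_numpy()[None, :]
        x += rng.normal(0.0, config.noise_sd, size=x.shape)
        cells = [f"T{t}_C{i:04d}" for i in range(cells_per_timepoint)]
        matrices.append(
            ExpressionMatrix(
                pd.DataFrame(x, index=pd.Index(universe, name="gene"), columns=cells),
                metadata={"dataset_id": f"TIMEPOINT_{t}", "timepoint": t, "log_scale": True},
            )
        )
        block = latents.copy()
        block.insert(0, "timepoint", t)
        block.index = pd.Index(cells, name="cell_id")
        truth_rows.append(block)
    return matrices, coll, pd.concat(truth_rows)


def _calibrate_uniform_censoring(lam: float, target: float) -> float:
    """Upper bound b of U(0, b) censoring giving P(censored) ≈ target.

    For T ~ Exp(lam) and C ~ U(0, b), P(C < T) = (1 − exp(−lam·b))/(lam·b),
    which decreases from 1 (b → 0) towards 0; solved by bisection.
    """
    if not (0 < target < 1):
        raise ValueError("target censoring fraction must be in (0, 1)")

    def frac(b: float) -> float:
        return (1.0 - np.exp(-lam * b)) / (lam * b)

    lo, hi = 1e-9 / lam, 1.0 / lam
    while frac(hi) > target:
        hi *= 2.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if frac(mid) > target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def generate_survival(
    config: SyntheticConfig,
    groups: GroupAssignment,
) -> SurvivalCohort:
    """Exponential event times under proportional hazards between groups.

    Samples labelled P+G+ get hazard ``baseline_hazard · hazard_multiplier``;
    everyone else the baseline hazard. Censoring is independent uniform,
    calibrated to the configured censoring fraction (0 disables censoring).
    """
    rng = np.random.default_rng(config.seed)
    samples = groups.labels.index
    hazards = np.where(
        groups.labels.to_numpy() == P_HIGH_G_HIGH,
        config.baseline_hazard * config.hazard_multiplier,
        config.baseline_hazard,
    )
    event_times = rng.exponential(1.0 / hazards)
    if config.censoring_fraction <= 0:
        times, events = event_times, np.ones(len(samples), dtype=int)
    else:
        times = event_times.copy()
        events = np.ones(len(samples), dtype=int)
        for lam in np.unique(hazards):
            mask = hazards == lam
            b = _calibrate_uniform_censoring(lam, config.censoring_fraction)
            censor = rng.uniform(0.0, b, size=int(mask.sum()))
            censored = censor < event_times[mask]
            t = np.where(censored, censor, event_times[mask])
            times[mask] = t
            events[mask] = (~censored).astype(int)
    df = pd.DataFrame({"time": times, "event": events}, index=samples)
    df.index.name = "sample_id"
    return SurvivalCohort(df)
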