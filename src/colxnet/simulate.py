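"""Synthetic cohorts with the statistical structure the pipeline assumes.

The expression generator is a single-latent-factor-per-module model: genes of
module m follow ``x_gs = lambda_g * z_{m,s} + eps_gs`` with loadings drawn
uniformly from a configured range, module factors ``z`` standard normal (or a
two-Gaussian mixture for the anchor module, which downstream produces a
bimodal %G.A.M.E. distribution), and Gaussian noise. Background genes are pure
noise. This is the simplest model producing the block-correlation structure a
weighted co-expression analysis assumes, and it supplies an interpretable true
eigengene per module.

Survival times are exponential with hazard
``baseline_rate * exp(beta_signal*z_anchor + beta_age*(age-60) + beta_stage*stage)``
and independent uniform censoring. Cell-type count data are negative binomial
with planted fold-change markers; bulk mixtures are noisy convex combinations
of cell-type mean profiles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .io import ClinicalTable, ExpressionMatrix, Unit

__all__ = [
    "SimConfig",
    "SurvivalConfig",
    "CellTypeConfig",
    "SimTruth",
    "simulate_cohort",
    "simulate_celltype_counts",
    "simulate_mixtures",
]

DEFAULT_CELLTYPE_NAMES = ("NCSC", "OA_MSC", "OAC", "BMSC")


@dataclass
class SurvivalConfig:
    """Hazard model for simulated event times.

    ``beta_signal`` is the log-hazard per SD of the anchor-module factor
    (default ln 2, i.e. hazard ratio 2 per SD); ``beta_age`` per year of age
    (default 0.03, ~+3% risk/year); ``beta_stage`` for stage 3-4 vs 1-2.
    Censoring times are uniform on (0, censor_horizon].
    """

    baseline_rate: float = 0.02
    beta_signal: float = math.log(2.0)
    beta_age: float = 0.03
    beta_stage: float = 1.0
    censor_horizon: float = 120.0


@dataclass
class CellTypeConfig:
    """Negative-binomial cell-type count model with planted markers."""

    k_types: int = 4
    n_reps: int = 3
    nb_dispersion: float = 0.05
    marker_fold: float = 16.0
    markers_per_type: int = 40

    def __post_init__(self) -> None:
        if self.n_reps < 2:
            raise ValueError("n_reps must be >= 2")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if self.marker_fold < 4:
            raise ValueError("marker_fold must be >= 4 (four-fold marker rule)")


@dataclass
class SimConfig:
    n_genes: int = 1200
    n_samples: int = 300
    module_sizes: tuple[int, ...] = (60, 50, 40)
    loading_range: tuple[float, float] = (0.6, 0.9)
    noise_sd: float = 1.0
    anchor_gene_id: str = "COL10A1"
    anchor_module_index: int = 0
    # (delta between component means, weight of the upper component); None = unimodal
    factor_mixture: tuple[float, float] | None = None
    survival: SurvivalConfig = field(default_factory=SurvivalConfig)
    celltypes: CellTypeConfig = field(default_factory=CellTypeConfig)
    male_fraction: float = 0.5
    stage34_fraction: float = 0.3
    cohort_label: str = "synthetic"
    seed: int = 0
    # redraw samples (factors, noise, clinical) under the same gene-level
    # structure (loadings, names); None = same stream as seed. Lets a second
    # config act as an independent replicate cohort of the same "biology".
    sample_seed: int | None = None

    def __post_init__(self) -> None:
        if sum(self.module_sizes) > self.n_genes:
            raise ValueError("sum(module_sizes) exceeds n_genes")
        lo, hi = self.loading_range
        if not (0 <= lo <= hi <= 1):
            raise ValueError("loading_range must lie in [0, 1] with low <= high")
        if not (0 <= self.anchor_module_index < len(self.module_sizes)):
            raise ValueError(
                f"anchor_module_index {self.anchor_module_index} out of range "
                f"for {len(self.module_sizes)} modules"
            )
        if isinstance(self.survival, dict):
            self.survival = SurvivalConfig(**self.survival)
        if isinstance(self.celltypes, dict):
            self.celltypes = CellTypeConfig(**self.celltypes)
        self.module_sizes = tuple(int(m) for m in self.module_sizes)

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SimTruth:
    """Ground truth retained from a simulation for downstream recovery tests."""

    module_labels: dict[str, int] = field(default_factory=dict)
    factors: np.ndarray | None = None          # modules x samples
    loadings: dict[str, float] = field(default_factory=dict)
    survival_coefficients: dict[str, float] = field(default_factory=dict)
    marker_sets: dict[str, list[str]] = field(default_factory=dict)
    mixture_fractions: np.ndarray | None = None  # samples x cell types
    celltype_names: list[str] = field(default_factory=list)

    def anchor_factor(self, anchor_module_index: int) -> np.ndarray:
        if self.factors is None:
            raise ValueError("no factors recorded")
        return self.factors[anchor_module_index]


def _gene_names(n_genes: int) -> list[str]:
    width = max(4, len(str(n_genes)))
    return [f"G{i:0{width}d}" for i in range(1, n_genes + 1)]


def simulate_cohort(config: SimConfig,
                    rng: np.random.Generator | None = None
                    ) -> tuple[ExpressionMatrix, ClinicalTable, SimTruth]:
    """Generate an expression cohort, clinical table and ground truth.

    The anchor gene replaces the first gene of module ``anchor_module_index``.
    Deterministic for a fixed config seed.
    """
    if rng is not None:
        rng_struct = rng_samp = rng
    else:
        rng_struct = np.random.default_rng([config.seed, 0])
        samp = config.seed if config.sample_seed is None else config.sample_seed
        rng_samp = np.random.default_rng([samp, 1])
    n_g, n_s = config.n_genes, config.n_samples
    genes = _gene_names(n_g)

    # module factors: one latent factor per module; anchor module optionally bimodal
    n_mod = len(config.module_sizes)
    factors = rng_samp.standard_normal((n_mod, n_s))
    if config.factor_mixture is not None:
        delta, weight = config.factor_mixture
        comp = rng_samp.random(n_s) < weight
        z = rng_samp.standard_normal(n_s) + np.where(comp, delta / 2.0, -delta / 2.0)
        factors[config.anchor_module_index] = (z - z.mean()) / z.std()

    labels = np.zeros(n_g, dtype=int)
    lo, hi = config.loading_range
    lam = np.zeros(n_g)
    X = rng_samp.standard_normal((n_g, n_s)) * config.noise_sd
    start = 0
    for m, size in enumerate(config.module_sizes):
        sl = slice(start, start + size)
        labels[sl] = m + 1
        lam[sl] = rng_struct.uniform(lo, hi, size) if hi > lo else lo
        X[sl, :] += lam[sl, None] * factors[m][None, :]
        start += size
    # anchor gene is a member of the anchor module
    anchor_row = sum(config.module_sizes[: config.anchor_module_index])
    genes[anchor_row] = config.anchor_gene_id

    # clinical covariates
    age = np.clip(rng_samp.normal(60, 10, n_s), 18, 90)
    gender = np.where(rng_samp.random(n_s) < config.male_fraction, "male", "female")
    stage34 = rng_samp.random(n_s) < config.stage34_fraction

    sv = config.survival
    z_anchor = factors[config.anchor_module_index]
    log_hazard = (sv.beta_signal * z_anchor + sv.beta_age * (age - 60.0)
                  + sv.beta_stage * stage34.astype(float))
    hazard = sv.baseline_rate * np.exp(log_hazard)
    t_event = rng_samp.exponential(1.0 / hazard)
    t_censor = rng_samp.uniform(0, sv.censor_horizon, n_s)
    time = np.minimum(t_event, t_censor)
    event = (t_event <= t_censor).astype(int)

    samples = [f"S{j:04d}" for j in range(1, n_s + 1)]
    clin = ClinicalTable(pd.DataFrame({
        "sample_id": samples,
        "age": age,
        "gender": gender,
        "stage_binary": np.where(stage34, "3-4", "1-2"),
        "os_time": time,
        "os_event": event,
        "dfi_time": time,
        "dfi_event": event,
    }))
    expr = ExpressionMatrix(genes, samples, X, unit=Unit.LOG2,
                            cohort_label=config.cohort_label)
    truth = SimTruth(
        module_labels=dict(zip(genes, labels.tolist())),
        factors=factors,
        loadings=dict(zip(genes, lam.tolist())),
        survival_coefficients={
            "signal": sv.beta_signal, "age": sv.beta_age, "stage": sv.beta_stage,
        },
    )
    return expr, clin, truth


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    # NB parameterized by mean/dispersion: var = mu + dispersion*mu^2
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def simulate_celltype_counts(config: SimConfig,
                             rng: np.random.Generator | None = None
                             ) -> tuple[ExpressionMatrix, list[str], SimTruth]:
    """Negative-binomial counts for replicated cell types with planted markers.

    Each planted marker's mean is ``marker_fold`` times higher in its own type
    than in every other type. The anchor gene is planted as a marker of the
    last type (BMSC under the default four-type naming). Returns the count
    matrix, per-sample type labels, and the truth marker sets.
    """
    ct = config.celltypes
    if ct.k_types < 2:
        raise ValueError("k_types must be >= 2")
    rng = rng if rng is not None else config.rng()
    k, reps = ct.k_types, ct.n_reps
    names = (list(DEFAULT_CELLTYPE_NAMES) if k == len(DEFAULT_CELLTYPE_NAMES)
             else [f"T{t+1}" for t in range(k)])
    n_g = config.n_genes
    genes = _gene_names(n_g)
    n_markers = ct.markers_per_type * k
    if n_markers > n_g:
        raise ValueError("markers_per_type * k_types exceeds n_genes")

    # per-gene baseline means, log-uniform over a bulk-RNA-like range
    base = np.exp(rng.uniform(np.log(20), np.log(200), n_g))
    mean_matrix = np.tile(base[:, None], (1, k))
    marker_sets: dict[str, list[str]] = {name: [] for name in names}
    gi = 0
    for t in range(k):
        for _ in range(ct.markers_per_type):
            mean_matrix[gi, :] = base[gi]
            mean_matrix[gi, t] = base[gi] * ct.marker_fold
            marker_sets[names[t]].append(genes[gi])
            gi += 1
    # anchor gene as a marker of the last (BMSC-like) type
    if ct.markers_per_type > 0:
        anchor_row = (k - 1) * ct.markers_per_type
        genes[anchor_row] = config.anchor_gene_id
        marker_sets[names[k - 1]][0] = config.anchor_gene_id

    labels = [name for name in names for _ in range(reps)]
    samples = [f"{name}_rep{r}" for name in names for r in range(1, reps + 1)]
    means = np.repeat(mean_matrix, reps, axis=1)
    counts = _nb_draw(rng, means, ct.nb_dispersion).astype(float)
    expr = ExpressionMatrix(genes, samples, counts, unit=Unit.COUNTS,
                            cohort_label=f"{config.cohort_label}_celltypes")
    truth = SimTruth(marker_sets=marker_sets, celltype_names=names)
    return expr, labels, truth


def simulate_mixtures(profiles: ExpressionMatrix, fractions: np.ndarray,
                      noise_sd: float = 0.0,
                      rng: np.random.Generator | None = None,
                      seed: int | None = None) -> ExpressionMatrix:
    """Bulk samples as noisy convex combinations of cell-type profiles.

    ``profiles`` is genes x cell types; ``fractions`` is samples x cell types
    with non-negative entries. Sample j equals ``profiles @ fractions[j] +
    Gaussian(0, noise_sd)``.
    """
    fractions = np.asarray(fractions, dtype=float)
    if fractions.ndim != 2 or fractions.shape[1] != profiles.n_samples:
        raise ValueError("fractions must be (n_samples, n_cell_types)")
    if np.any(fractions < 0):
        raise ValueError("mixture fractions must be non-negative")
    rng = rng if rng is not None else np.random.default_rng(seed)
    bulk = profiles.values @ fractions.T
    if noise_sd > 0:
        bulk = bulk + rng.normal(0, noise_sd, bulk.shape)
    samples = [f"MIX{j:04d}" for j in range(1, fractions.shape[0] + 1)]
    return ExpressionMatrix(list(profiles.gene_ids), samples, bulk,
                            unit=profiles.unit, cohort_label="mixtures")
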