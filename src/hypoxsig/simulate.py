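"""Synthetic secretome, microdissected-tissue and survival-cohort generators.

Each generator reproduces the statistical structure the downstream analysis
assumes and returns, alongside the data, a :class:`PlantedTruth` naming the
planted effects so recovery can be checked against a known answer.

* Secretomes: log2 intensity = per-protein baseline + a global basal-vs-
  luminal shift + a planted hypoxia effect (responsive proteins, hypoxia
  samples of the responsive subtype only) + Gaussian noise. Cells then go
  missing with probability ``logistic((midpoint - intensity) * slope)``, so
  low-abundance proteins drop out more often (missing-not-at-random), which
  is what downshifted-normal imputation is built for.
* Tissue: paired epithelium/stroma samples per patient; stroma-exclusive
  planted proteins carry the subtype effect only in stroma, shared planted
  proteins carry it in both compartments.
* Cohort: gene expression is Gaussian; the death hazard is exponential with
  rate baseline * exp(beta*z + gamma*treat + delta*z*treat) where z is the
  standardized signature score, and follow-up is administratively censored.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .types import CohortData, IntensityMatrix, SampleDesign, SUBTYPES

__all__ = [
    "SecretomeSimConfig",
    "TissueSimConfig",
    "CohortSimConfig",
    "PlantedTruth",
    "simulate_secretome",
    "simulate_tissue",
    "simulate_cohort",
]


@dataclass(frozen=True)
class PlantedTruth:
    """Ground truth of a simulated dataset: which ids carry which planted
    effect, and (for cohorts) the true log-hazard coefficients."""

    planted: dict[str, tuple[str, ...]] = field(default_factory=dict)
    effect_sizes: dict[str, float] = field(default_factory=dict)
    beta: float | None = None
    gamma: float | None = None
    delta: float | None = None


@dataclass(frozen=True)
class SecretomeSimConfig:
    """Conditioned-media experiment: 2 subtypes x 2 oxygen conditions.

    Defaults emulate a scaled-down discovery secretome: several hundred
    quantified proteins, 6 replicate runs per (subtype, oxygen) group, a
    strong planted hypoxia response (2 log2 units) in mostly
    subtype-private protein sets, and intensity-dependent dropout.
    """

    n_proteins: int = 800
    replicates: int = 6
    baseline_mean: float = 25.0      # log2 intensity
    baseline_sd: float = 2.0
    subtype_effect: float = 1.0      # basal minus luminal baseline, log2
    n_hypoxia_luminal: int = 60
    n_hypoxia_basal: int = 20
    n_hypoxia_shared: int = 5        # overlap counted inside both sets
    hypoxia_effect: float = 2.0      # log2, > 0
    noise_sd: float = 0.5
    miss_midpoint: float | None = 20.0   # None disables missingness
    miss_slope: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates < 2:
            raise ValueError("need >= 2 replicates per group for a t-test")
        for name in ("n_proteins", "n_hypoxia_luminal", "n_hypoxia_basal",
                     "n_hypoxia_shared"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_hypoxia_shared > min(self.n_hypoxia_luminal, self.n_hypoxia_basal):
            raise ValueError("shared planted count exceeds a subtype's planted count")
        total = self.n_hypoxia_luminal + self.n_hypoxia_basal - self.n_hypoxia_shared
        if total > self.n_proteins:
            raise ValueError("planted proteins exceed n_proteins")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.hypoxia_effect <= 0:
            raise ValueError("hypoxia_effect must be > 0")


def _protein_ids(n: int) -> list[str]:
    width = len(str(max(n, 1)))
    return [f"P{i:0{width}d}" for i in range(1, n + 1)]


def _apply_missingness(values: np.ndarray, midpoint: float | None, slope: float,
                       rng: np.random.Generator) -> np.ndarray:
    if midpoint is None:
        return values
    p_miss = expit((midpoint - values) * slope)
    mask = rng.random(values.shape) < p_miss
    out = values.copy()
    out[mask] = np.nan
    return out


def simulate_secretome(config: SecretomeSimConfig) -> tuple[IntensityMatrix, SampleDesign, PlantedTruth]:
    rng = np.random.default_rng(config.seed)
    ids = _protein_ids(config.n_proteins)

    n_lum, n_bas, n_sh = (config.n_hypoxia_luminal, config.n_hypoxia_basal,
                          config.n_hypoxia_shared)
    planted_lum = tuple(ids[:n_lum])
    start = n_lum - n_sh
    planted_bas = tuple(ids[start:start + n_bas])

    samples, rows = [], []
    for subtype in SUBTYPES:
        for oxygen in ("normoxia", "hypoxia"):
            for rep in range(1, config.replicates + 1):
                samples.append(f"{subtype[:3]}_{oxygen[:3]}_{rep}")
                rows.append((subtype, oxygen, rep))
    design = SampleDesign(pd.DataFrame(rows, index=samples,
                                       columns=["subtype", "oxygen", "replicate"]))

    baseline = rng.normal(config.baseline_mean, config.baseline_sd, config.n_proteins)
    values = np.empty((config.n_proteins, len(samples)))
    lum_idx = np.isin(ids, planted_lum)
    bas_idx = np.isin(ids, planted_bas)
    for j, (subtype, oxygen, _rep) in enumerate(rows):
        col = baseline.copy()
        if subtype == "basal":
            col += config.subtype_effect
        if oxygen == "hypoxia":
            responsive = lum_idx if subtype == "luminal" else bas_idx
            col = col + responsive * config.hypoxia_effect
        values[:, j] = col + rng.normal(0.0, config.noise_sd, config.n_proteins)

    values = _apply_missingness(values, config.miss_midpoint, config.miss_slope, rng)
    matrix = IntensityMatrix(pd.DataFrame(values, index=ids, columns=samples))
    truth = PlantedTruth(
        planted={"hypoxia_luminal": planted_lum, "hypoxia_basal": planted_bas},
        effect_sizes={"hypoxia_luminal": config.hypoxia_effect,
                      "hypoxia_basal": config.hypoxia_effect},
    )
    return matrix, design, truth


@dataclass(frozen=True)
class TissueSimConfig:
    """Microdissected tumor proteome: paired epithelium/stroma per patient.

    Stroma-exclusive planted proteins differ between subtypes only in the
    stromal compartment; shared planted proteins differ in both. The two
    planted sets are disjoint.
    """

    n_proteins: int = 800
    patients_per_subtype: int = 12
    n_stroma_exclusive: int = 40
    stroma_effect: float = 2.0       # basal minus luminal, log2, stroma only
    n_shared: int = 20
    shared_effect: float = 2.0       # basal minus luminal, both compartments
    baseline_mean: float = 25.0
    baseline_sd: float = 2.0
    noise_sd: float = 0.5
    miss_midpoint: float | None = 20.0
    miss_slope: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.patients_per_subtype < 3:
            raise ValueError("need >= 3 patients per subtype")
        if self.n_stroma_exclusive < 0 or self.n_shared < 0:
            raise ValueError("planted counts must be >= 0")
        if self.n_stroma_exclusive + self.n_shared > self.n_proteins:
            raise ValueError("planted proteins exceed n_proteins")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")


def simulate_tissue(config: TissueSimConfig) -> tuple[IntensityMatrix, SampleDesign, PlantedTruth]:
    rng = np.random.default_rng(config.seed)
    ids = _protein_ids(config.n_proteins)
    stroma_excl = tuple(ids[:config.n_stroma_exclusive])
    shared = tuple(ids[config.n_stroma_exclusive:
                       config.n_stroma_exclusive + config.n_shared])

    samples, rows = [], []
    pat = 0
    for subtype in SUBTYPES:
        for _ in range(config.patients_per_subtype):
            pat += 1
            pid = f"pat{pat:03d}"
            for compartment in ("epithelium", "stroma"):
                samples.append(f"{pid}_{compartment[:3]}")
                rows.append((subtype, compartment, pid))
    design = SampleDesign(pd.DataFrame(rows, index=samples,
                                       columns=["subtype", "compartment", "patient_id"]))

    baseline = rng.normal(config.baseline_mean, config.baseline_sd, config.n_proteins)
    se_idx = np.isin(ids, stroma_excl)
    sh_idx = np.isin(ids, shared)
    values = np.empty((config.n_proteins, len(samples)))
    for j, (subtype, compartment, _pid) in enumerate(rows):
        col = baseline.copy()
        if subtype == "basal":
            col = col + sh_idx * config.shared_effect
            if compartment == "stroma":
                col = col + se_idx * config.stroma_effect
        values[:, j] = col + rng.normal(0.0, config.noise_sd, config.n_proteins)

    values = _apply_missingness(values, config.miss_midpoint, config.miss_slope, rng)
    matrix = IntensityMatrix(pd.DataFrame(values, index=ids, columns=samples))
    truth = PlantedTruth(
        planted={"stroma_exclusive": stroma_excl, "shared_compartment": shared},
        effect_sizes={"stroma_exclusive": config.stroma_effect,
                      "shared_compartment": config.shared_effect},
    )
    return matrix, design, truth


@dataclass(frozen=True)
class CohortSimConfig:
    """Expression cohort with hazard tied to the signature score.

    The death hazard is ``baseline_hazard * exp(beta*z + gamma*treat +
    delta*z*treat)`` with z the standardized (mean 0, sd 1) signature score,
    so ``beta`` is a log hazard ratio per score standard deviation
    regardless of signature size. Clinical covariates (tumor size class,
    grade, node status, subtype, treatment flags) are drawn independently of
    the hazard unless they enter through the treatment terms.
    """

    n_genes: int = 500
    n_patients: int = 500
    signature: tuple[str, ...] | None = None   # default: first 33 gene ids
    gene_mean: float = 8.0           # log2 expression, population location
    gene_mean_sd: float = 1.0        # spread of per-gene means
    gene_sd: float = 1.0             # within-gene, across-patient sd
    beta: float = float(np.log(2.0))
    baseline_hazard: float = 0.003   # events per month
    treatment_prob: float = 0.5
    gamma: float = 0.0               # treatment main effect, log-hazard
    delta: float = 0.0               # score x treatment interaction
    censor_time: float = 240.0       # administrative censoring, months
    p_basal: float = 0.14
    seed: int = 0

    def __post_init__(self) -> None:
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be > 0")
        if not 0 < self.treatment_prob < 1:
            raise ValueError("treatment_prob must be in (0, 1)")
        if self.censor_time <= 0:
            raise ValueError("censor_time must be > 0")
        if self.n_patients < 4 or self.n_genes < 1:
            raise ValueError("need n_patients >= 4 and n_genes >= 1")


def _gene_ids(n: int) -> list[str]:
    width = len(str(max(n, 1)))
    return [f"G{i:0{width}d}" for i in range(1, n + 1)]


def simulate_cohort(config: CohortSimConfig) -> tuple[CohortData, PlantedTruth]:
    rng = np.random.default_rng(config.seed)
    genes = _gene_ids(config.n_genes)
    signature = tuple(config.signature) if config.signature is not None \
        else tuple(genes[:min(33, config.n_genes)])
    absent = set(signature) - set(genes)
    if absent:
        raise ValueError(f"signature gene(s) absent from simulated pool: {sorted(absent)}")

    patients = [f"MB{i:04d}" for i in range(1, config.n_patients + 1)]
    mu = rng.normal(config.gene_mean, config.gene_mean_sd, config.n_genes)
    expr = mu[:, None] + rng.normal(0.0, config.gene_sd,
                                    (config.n_genes, config.n_patients))
    expression = pd.DataFrame(expr, index=genes, columns=patients)

    sig_rows = expression.loc[list(signature)]
    score = sig_rows.sub(sig_rows.mean(axis=1), axis=0).sum(axis=0).to_numpy()
    z = (score - score.mean()) / score.std()

    treat = (rng.random(config.n_patients) < config.treatment_prob).astype(int)
    rate = config.baseline_hazard * np.exp(
        config.beta * z + config.gamma * treat + config.delta * z * treat)
    event_time = rng.exponential(1.0 / rate)
    time = np.minimum(event_time, config.censor_time)
    event = (event_time <= config.censor_time).astype(int)

    clinical = pd.DataFrame(
        {
            "tumor_size_class": (rng.random(config.n_patients) < 0.5).astype(int),
            "grade_class": (rng.random(config.n_patients) < 0.5).astype(int),
            "node_status": (rng.random(config.n_patients) < 0.45).astype(int),
            "subtype_basal": (rng.random(config.n_patients) < config.p_basal).astype(int),
            "endocrine": (rng.random(config.n_patients) < 0.5).astype(int),
            "chemo": (rng.random(config.n_patients) < 0.25).astype(int),
            "radiotherapy": treat,
        },
        index=patients,
    )
    survival = pd.DataFrame({"time": time, "event": event}, index=patients)
    cohort = CohortData(expression, clinical, survival)
    truth = PlantedTruth(
        planted={"signature": signature},
        effect_sizes={},
        beta=config.beta, gamma=config.gamma, delta=config.delta,
    )
    return cohort, truth
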