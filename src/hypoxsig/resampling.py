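"""Permutation uniqueness test and greedy leave-one-out signature
reduction.

The strength of a gene set in a cohort is the log-rank chi-square of
signature-high (upper score quartile, Q4) versus the rest (Q1-Q3); the
chi-square and its p value rank sets identically at 1 df.

* The permutation test compares a candidate signature against sets of the
  same size drawn uniformly without replacement from a pool (conventionally
  the union of the two source sets the candidate was intersected from); the
  empirical p uses the add-one rule so it is never zero.
* The greedy reduction repeatedly drops the member whose removal gives the
  lowest log-rank p for the remaining set, down to a single member,
  recording the full signature as step 0 so the best step can never be
  worse than the starting set. The procedure is deterministic: ties on p
  prefer the larger chi-square, then removal of the lexicographically
  smallest gene.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .signature import ScoringConfig, score_signature, stratify_quartiles
from .survival import logrank_test
from .types import CohortData, SignatureSet

logger = logging.getLogger("hypoxsig")

__all__ = [
    "PermutationConfig",
    "PermutationResult",
    "ReductionStep",
    "ReductionTrajectory",
    "signature_strength",
    "permutation_uniqueness",
    "greedy_reduce",
]


def signature_strength(cohort: CohortData, sig: SignatureSet,
                       cfg: ScoringConfig | None = None) -> tuple[float, float]:
    """Score the signature, cut at quartiles and log-rank Q4 vs Q1-Q3;
    returns (chi_square, two-sided p)."""
    sv = stratify_quartiles(score_signature(cohort, sig, cfg))
    res = logrank_test(cohort.survival["time"], cohort.survival["event"],
                       sv.high.to_numpy())
    return res.chi_square, res.p_value


class _StrengthEngine:
    """Precomputed mean-centered expression for fast repeated strength
    evaluation of row subsets of a fixed cohort."""

    def __init__(self, cohort: CohortData, genes: list[str]):
        rows = cohort.expression.loc[genes]
        self.centered = rows.sub(rows.mean(axis=1), axis=0).to_numpy(float)
        self.gene_index = {g: i for i, g in enumerate(genes)}
        self.time = cohort.survival["time"].to_numpy(float)
        self.event = cohort.survival["event"].to_numpy(int)

    def strength(self, row_idx: np.ndarray) -> tuple[float, float]:
        scores = self.centered[row_idx].sum(axis=0)
        q75 = np.quantile(scores, 0.75)
        high = scores > q75          # boundary ties go to the lower group
        if not high.any() or high.all():
            raise ValueError("degenerate quartile split (all scores identical?)")
        res = logrank_test(self.time, self.event, high)
        return res.chi_square, res.p_value


@dataclass(frozen=True)
class PermutationConfig:
    """pool — the selection universe the null draws from (the candidate
    need not be a member); statistic is the Q4-vs-rest log-rank
    chi-square."""

    pool: SignatureSet
    n_permutations: int = 10_000
    statistic: str = "logrank_chi_square"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if self.statistic != "logrank_chi_square":
            raise ValueError("only the 'logrank_chi_square' statistic is supported")


@dataclass(frozen=True)
class PermutationResult:
    observed_statistic: float
    observed_p: float
    null_statistics: np.ndarray
    empirical_p: float


def permutation_uniqueness(cohort: CohortData, candidate: SignatureSet,
                           cfg: PermutationConfig) -> PermutationResult:
    """Empirical p of the candidate's strength against same-size random
    draws from the pool: p = (1 + #{null >= observed}) / (B + 1)."""
    pool_present = [g for g in cfg.pool.members if g in cohort.expression.index]
    n_absent = len(cfg.pool.members) - len(pool_present)
    if n_absent:
        logger.warning("dropping %d pool gene(s) absent from the cohort", n_absent)
    k = len(candidate.members)
    if len(pool_present) < k:
        raise ValueError(
            f"pool ({len(pool_present)} scoreable genes) smaller than "
            f"candidate ({k})"
        )
    observed_chi2, observed_p = signature_strength(cohort, candidate)

    engine = _StrengthEngine(cohort, pool_present)
    rng = np.random.default_rng(cfg.seed)
    null = np.empty(cfg.n_permutations)
    n_pool = len(pool_present)
    for b in range(cfg.n_permutations):
        idx = rng.choice(n_pool, size=k, replace=False)
        null[b], _ = engine.strength(idx)
    empirical_p = (1.0 + float(np.sum(null >= observed_chi2))) / (cfg.n_permutations + 1.0)
    return PermutationResult(observed_statistic=observed_chi2,
                             observed_p=observed_p,
                             null_statistics=null,
                             empirical_p=empirical_p)


@dataclass(frozen=True)
class ReductionStep:
    members: tuple[str, ...]
    removed: str | None          # gene removed to reach this step (None at step 0)
    chi_square: float
    p_value: float


@dataclass(frozen=True)
class ReductionTrajectory:
    """Strict subset chain from the full signature (step 0) down to one
    member; ``best_step`` indexes the minimum log-rank p (ties keep the
    larger set)."""

    steps: list[ReductionStep] = field(default_factory=list)
    best_step: int = 0

    @property
    def best(self) -> ReductionStep:
        return self.steps[self.best_step]


def greedy_reduce(cohort: CohortData, sig: SignatureSet,
                  cfg: ScoringConfig | None = None) -> ReductionTrajectory:
    """Backward elimination on log-rank p: at each step evaluate every
    leave-one-out subset and keep the one with the lowest p, until a single
    member remains. Deterministic (no randomness; documented tie rule)."""
    if len(sig.members) < 2:
        raise ValueError("signature must have >= 2 members to reduce")
    missing = [g for g in sig.members if g not in cohort.expression.index]
    if missing:
        raise ValueError(f"signature gene(s) absent from cohort: {missing}")

    engine = _StrengthEngine(cohort, list(sig.members))
    current = list(sig.members)

    def idx_of(members: list[str]) -> np.ndarray:
        return np.array([engine.gene_index[g] for g in members], dtype=int)

    chi2, p = engine.strength(idx_of(current))
    steps = [ReductionStep(tuple(current), None, chi2, p)]
    while len(current) > 1:
        best = None
        for gene in current:
            subset = [g for g in current if g != gene]
            try:
                chi2, p = engine.strength(idx_of(subset))
            except ValueError as exc:
                raise ValueError(f"subset without {gene!r} unscoreable: {exc}") from exc
            key = (p, -chi2, gene)
            if best is None or key < best[0]:
                best = (key, gene, subset, chi2, p)
        _, gene, subset, chi2, p = best
        steps.append(ReductionStep(tuple(subset), gene, chi2, p))
        current = subset

    best_step = 0
    for i, step in enumerate(steps):
        if step.p_value < steps[best_step].p_value:
            best_step = i
    return ReductionTrajectory(steps=steps, best_step=best_step)


def trajectory_table(traj: ReductionTrajectory) -> pd.DataFrame:
    """Flat view of a reduction trajectory for writing to TSV."""
    return pd.DataFrame(
        {
            "step": range(len(traj.steps)),
            "size": [len(s.members) for s in traj.steps],
            "removed": [s.removed or "" for s in traj.steps],
            "chi_square": [s.chi_square for s in traj.steps],
            "p_value": [s.p_value for s in traj.steps],
        }
    )
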