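"""Signature derivation, probe collapsing, scoring and quartile
stratification.

The signature is the intersection of two derived protein sets:

* the hypoxome — proteins significantly increased under hypoxia (raw
  p < alpha and positive log2 fold change) within either subtype, with the
  per-subtype sets unioned;
* the stroma-exclusive set — proteins that separate the subtypes in the
  stromal compartment but not in matched tumor epithelium (any
  epithelium-significant protein is subtracted regardless of direction).

Scoring centers each signature gene on its cohort-wide mean and sums the
centered values per patient; patients are then cut at the score quartiles,
with the upper quartile (Q4) the signature-high group.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import CohortData, SignatureSet

logger = logging.getLogger("hypoxsig")

__all__ = [
    "ScoringConfig",
    "ScoreVector",
    "collapse_probes_max",
    "derive_hypoxome",
    "derive_stroma_exclusive",
    "intersect_signature",
    "score_signature",
    "stratify_quartiles",
]

QUARTILE_LABELS = ("Q1", "Q2", "Q3", "Q4")


@dataclass(frozen=True)
class ScoringConfig:
    """missing_gene_policy: "drop_warn" drops signature genes absent from
    the cohort with a logged warning; "error" refuses to score."""

    missing_gene_policy: str = "drop_warn"

    def __post_init__(self) -> None:
        if self.missing_gene_policy not in ("drop_warn", "error"):
            raise ValueError("missing_gene_policy must be 'drop_warn' or 'error'")


@dataclass(frozen=True)
class ScoreVector:
    """Per-patient signature scores, optionally with quartile labels.

    ``high`` marks Q4 membership. When no gene was dropped the scores sum
    to zero (each gene is mean-centered across patients)."""

    scores: pd.Series
    genes_used: tuple[str, ...]
    genes_dropped: tuple[str, ...] = ()
    quartile: pd.Series | None = None
    high: pd.Series | None = None


def collapse_probes_max(expression: pd.DataFrame, probe_map: pd.Series) -> pd.DataFrame:
    """Collapse a probes-x-samples grid to genes-x-samples by taking, per
    gene and sample, the maximum over that gene's probes ("max probe").
    Probes without a map entry are dropped (count logged)."""
    probe_map = pd.Series(probe_map)
    if probe_map.empty:
        raise ValueError("probe map is empty")
    mapped = expression.index.intersection(probe_map.index)
    n_unmapped = expression.shape[0] - len(mapped)
    if len(mapped) == 0:
        raise ValueError("no probe in the expression grid has a map entry")
    if n_unmapped:
        logger.info("dropping %d unmapped probe(s)", n_unmapped)
    sub = expression.loc[mapped]
    genes = probe_map.loc[mapped]
    return sub.groupby(genes.values).max()


def _significant(table: pd.DataFrame, alpha: float,
                 positive_only: bool) -> set[str]:
    mask = table["p_value"] < alpha
    if positive_only:
        mask &= table["log2fc"] > 0
    return set(table.index[mask])


def derive_hypoxome(diff_lum: pd.DataFrame, diff_bas: pd.DataFrame,
                    alpha: float = 0.05,
                    ) -> tuple[SignatureSet, SignatureSet, SignatureSet]:
    """Hypoxia-increased proteins per subtype (p < alpha and log2fc > 0 on
    the normoxia-vs-hypoxia contrast) and their union, each
    lexicographically sorted."""
    set_lum = _significant(diff_lum, alpha, positive_only=True)
    set_bas = _significant(diff_bas, alpha, positive_only=True)
    if not (set(diff_lum.index) & set(diff_bas.index)):
        logger.warning("differential tables share no proteins; union still formed")
    union = sorted(set_lum | set_bas)
    return (
        SignatureSet("hypoxome_luminal", tuple(sorted(set_lum))),
        SignatureSet("hypoxome_basal", tuple(sorted(set_bas))),
        SignatureSet("hypoxome", tuple(union)),
    )


def derive_stroma_exclusive(diff_stroma: pd.DataFrame, diff_epi: pd.DataFrame,
                            alpha: float = 0.05) -> SignatureSet:
    """Proteins separating the subtypes in stroma (p < alpha, either
    direction) minus those also separating them in epithelium."""
    sig_stroma = _significant(diff_stroma, alpha, positive_only=False)
    sig_epi = _significant(diff_epi, alpha, positive_only=False)
    if diff_stroma.equals(diff_epi):
        logger.warning("identical stroma and epithelium tables; result is empty")
    members = sorted(sig_stroma - sig_epi)
    return SignatureSet("stroma_exclusive", tuple(members))


def intersect_signature(hypoxome: SignatureSet, stroma_exclusive: SignatureSet,
                        name: str = "derived_signature") -> SignatureSet:
    """Sorted intersection of the two derived sets — the stromal hypoxia
    signature. An empty intersection is returned (with a warning), not
    raised."""
    members = sorted(set(hypoxome.members) & set(stroma_exclusive.members))
    if not members:
        logger.warning("signature intersection is empty")
    return SignatureSet(name, tuple(members))


def score_signature(cohort: CohortData, sig: SignatureSet,
                    cfg: ScoringConfig | None = None) -> ScoreVector:
    """Per patient, sum the cohort-mean-centered expression of the
    signature genes present in the cohort."""
    cfg = cfg or ScoringConfig()
    present = [g for g in sig.members if g in cohort.expression.index]
    dropped = tuple(g for g in sig.members if g not in cohort.expression.index)
    if dropped:
        if cfg.missing_gene_policy == "error":
            raise ValueError(f"signature gene(s) absent from cohort: {list(dropped)}")
        logger.warning("dropping %d signature gene(s) absent from cohort: %s",
                       len(dropped), list(dropped))
    if not present:
        raise ValueError("no signature gene present in the cohort expression grid")
    rows = cohort.expression.loc[present]
    centered = rows.sub(rows.mean(axis=1), axis=0)
    scores = centered.sum(axis=0)
    scores.name = sig.name
    return ScoreVector(scores=scores, genes_used=tuple(present),
                       genes_dropped=dropped)


def stratify_quartiles(sv: ScoreVector) -> ScoreVector:
    """Label patients Q1-Q4 at the 25th/50th/75th score percentiles
    (linear-interpolation quantiles); scores exactly on a boundary go to
    the lower group, so Q4 (the signature-high group) is conservative."""
    scores = sv.scores
    if len(scores) < 4:
        raise ValueError(f"need >= 4 patients to stratify, got {len(scores)}")
    values = scores.to_numpy(float)
    if np.all(values == values[0]):
        raise ValueError("all scores identical; no stratification possible")
    q25, q50, q75 = np.quantile(values, [0.25, 0.5, 0.75])
    labels = np.select(
        [values <= q25, values <= q50, values <= q75],
        ["Q1", "Q2", "Q3"],
        default="Q4",
    )
    quartile = pd.Series(labels, index=scores.index, name="quartile")
    high = pd.Series(labels == "Q4", index=scores.index, name="high")
    return ScoreVector(scores=scores, genes_used=sv.genes_used,
                       genes_dropped=sv.genes_dropped,
                       quartile=quartile, high=high)
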