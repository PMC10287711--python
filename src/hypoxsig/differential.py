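"""Valid-value filtering, downshifted-normal imputation and two-sample
t-tests on intensity matrices, plus the marker-based microdissection
purity estimate.

The processing chain mirrors the conventional label-free workflow: keep
proteins quantified in at least half the samples of a group, replace the
remaining missing values with draws from a normal distribution shifted
below the observed column distribution (width 0.3 x sd, downshift
1.8 x sd — the standard parameters for missing-not-at-random dropout),
then compare groups with an equal-variance two-sided Student's t test at
alpha 0.05 on raw p values.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .types import Contrast, IntensityMatrix, SampleDesign

logger = logging.getLogger("hypoxsig")

__all__ = [
    "ImputationParams",
    "DifferentialConfig",
    "filter_valid_values",
    "impute_downshifted",
    "differential_test",
    "estimate_marker_purity",
]


@dataclass(frozen=True)
class ImputationParams:
    """width — multiplier on the per-column sd for the imputation spread;
    downshift — how many observed sds below the observed column mean the
    imputation distribution is centered."""

    width: float = 0.3
    downshift: float = 1.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("width must be > 0")
        if self.downshift < 0:
            raise ValueError("downshift must be >= 0")


@dataclass(frozen=True)
class DifferentialConfig:
    """filter_mode "any_group" retains a protein quantified in at least
    ``min_valid_fraction`` of samples of >= 1 group (the cited software's
    retention convention); "all_groups" requires it in every group. Both
    are exposed because the removal rule can be read either way.
    ``welch`` switches to the unequal-variance test; the equal-variance
    Student's t is the default. ``add_bh`` appends a Benjamini-Hochberg
    q-value column as an annotation only — the derivation path thresholds
    raw p values."""

    alpha: float = 0.05
    min_valid_fraction: float = 0.5
    filter_mode: str = "any_group"
    apply_filter: bool = True
    apply_imputation: bool = True
    welch: bool = False
    add_bh: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 < self.min_valid_fraction <= 1:
            raise ValueError("min_valid_fraction must be in (0, 1]")
        if self.filter_mode not in ("any_group", "all_groups"):
            raise ValueError("filter_mode must be 'any_group' or 'all_groups'")


def filter_valid_values(m: IntensityMatrix, design: SampleDesign,
                        contrast: Contrast,
                        cfg: DifferentialConfig | None = None) -> IntensityMatrix:
    """Drop proteins with too few quantified values; never alters a value."""
    cfg = cfg or DifferentialConfig()
    g1, g2 = contrast.groups(design)
    fracs = []
    for grp in (g1, g2):
        sub = m.data.loc[:, grp]
        fracs.append(sub.notna().sum(axis=1) / len(grp))
    frac = pd.concat(fracs, axis=1)
    ok_per_group = frac >= cfg.min_valid_fraction
    keep = ok_per_group.any(axis=1) if cfg.filter_mode == "any_group" \
        else ok_per_group.all(axis=1)
    dropped = int((~keep).sum())
    if dropped:
        logger.info("valid-value filter removed %d of %d proteins",
                    dropped, m.data.shape[0])
    return IntensityMatrix(m.data.loc[keep])


def impute_downshifted(m: IntensityMatrix,
                       params: ImputationParams | None = None) -> IntensityMatrix:
    """Replace missing entries column-wise with draws from
    Normal(mean_obs - downshift*sd_obs, (width*sd_obs)^2), computed from the
    observed values of that column. Observed entries are never changed."""
    params = params or ImputationParams()
    if m.n_missing == 0:
        return m
    rng = np.random.default_rng(params.seed)
    out = m.data.copy()
    for col in out.columns:
        column = out[col]
        missing = column.isna()
        if not missing.any():
            continue
        observed = column.dropna()
        if len(observed) < 2:
            raise ValueError(
                f"column {col!r} has {len(observed)} observed value(s); "
                "need >= 2 to impute"
            )
        mean, sd = observed.mean(), observed.std(ddof=1)
        draws = rng.normal(mean - params.downshift * sd, params.width * sd,
                           int(missing.sum()))
        out.loc[missing, col] = draws
    return IntensityMatrix(out)


def differential_test(m: IntensityMatrix, design: SampleDesign,
                      contrast: Contrast,
                      cfg: DifferentialConfig | None = None,
                      imp: ImputationParams | None = None) -> pd.DataFrame:
    """Two-sample t test per protein between the two contrast groups.

    Returns a table indexed by protein id with columns mean_g1, mean_g2,
    log2fc (= mean_g2 - mean_g1), linear_fold (= 2**log2fc), t_stat,
    p_value, n_valid_g1, n_valid_g2. The t statistic is signed as
    (mean_g1 - mean_g2) / se, so a protein higher in group 2 has t < 0 and
    log2fc > 0. Filtering and imputation are applied first when enabled.
    """
    cfg = cfg or DifferentialConfig()
    imp = imp or ImputationParams()
    g1, g2 = contrast.groups(design)
    work = m.subset_samples(g1 + g2)
    if cfg.apply_filter:
        work = filter_valid_values(work, design, contrast, cfg)
    if cfg.apply_imputation:
        work = impute_downshifted(work, imp)

    a = work.data.loc[:, g1].to_numpy(float)
    b = work.data.loc[:, g2].to_numpy(float)
    n1 = np.sum(~np.isnan(a), axis=1)
    n2 = np.sum(~np.isnan(b), axis=1)
    if np.all(n1 < 2) or np.all(n2 < 2):
        raise ValueError("fewer than 2 valid samples per group after processing")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        m1 = np.nanmean(a, axis=1)
        m2 = np.nanmean(b, axis=1)
        v1 = np.nanvar(a, axis=1, ddof=1)
        v2 = np.nanvar(b, axis=1, ddof=1)

    if cfg.welch:
        se2 = v1 / n1 + v2 / n2
        df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    else:
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        se2 = sp2 * (1.0 / n1 + 1.0 / n2)
        df = (n1 + n2 - 2).astype(float)

    diff = m1 - m2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / np.sqrt(se2)
        p = 2.0 * stats.t.sf(np.abs(t), df)

    zero_var = se2 == 0
    if np.any(zero_var):
        equal = zero_var & (diff == 0)
        unequal = zero_var & (diff != 0)
        t[equal], p[equal] = 0.0, 1.0
        if np.any(unequal):
            warnings.warn(
                f"{int(unequal.sum())} protein(s) have zero pooled variance with "
                "unequal means; p set to the smallest positive float",
                RuntimeWarning, stacklevel=2,
            )
            t[unequal] = np.where(diff[unequal] > 0, np.inf, -np.inf)
            p[unequal] = np.nextafter(0.0, 1.0)

    too_few = (n1 < 2) | (n2 < 2)
    t[too_few] = np.nan
    p[too_few] = np.nan

    table = pd.DataFrame(
        {
            "mean_g1": m1, "mean_g2": m2,
            "log2fc": m2 - m1, "linear_fold": 2.0 ** (m2 - m1),
            "t_stat": t, "p_value": p,
            "n_valid_g1": n1, "n_valid_g2": n2,
        },
        index=work.data.index,
    )
    if cfg.add_bh:
        valid = table["p_value"].notna()
        q = np.full(len(table), np.nan)
        q[valid.to_numpy()] = stats.false_discovery_control(
            table.loc[valid, "p_value"].to_numpy(), method="bh")
        table["q_value"] = q
    return table


def estimate_marker_purity(epith: IntensityMatrix, stroma: IntensityMatrix,
                           marker_id: str, pairing: dict[str, tuple[str, str]],
                           input_scale: str = "log2",
                           ) -> tuple[float, float, pd.Series]:
    """Estimate epithelial contamination of microdissected stroma from an
    epithelium-specific marker (e.g. cytokeratin-8).

    ``pairing`` maps patient id -> (epithelium sample id, stroma sample id).
    Per patient, ratio = linear-scale stroma intensity / epithelium
    intensity of the marker, and contamination percent = 100 * ratio; a
    62-fold epithelium excess thus gives 100/62 = 1.6%. Returns (mean
    percent, median percent, per-patient percents). Pairs where the marker
    is unquantified are dropped with a warning; a zero epithelium intensity
    is an error.
    """
    if input_scale not in ("log2", "linear"):
        raise ValueError("input_scale must be 'log2' or 'linear'")
    if marker_id not in epith.data.index or marker_id not in stroma.data.index:
        raise ValueError(f"marker {marker_id!r} absent from a matrix")
    percents = {}
    for patient, (e_samp, s_samp) in pairing.items():
        e_val = epith.data.at[marker_id, e_samp]
        s_val = stroma.data.at[marker_id, s_samp]
        if np.isnan(e_val) or np.isnan(s_val):
            warnings.warn(f"marker missing for patient {patient!r}; pair dropped",
                          RuntimeWarning, stacklevel=2)
            continue
        if input_scale == "log2":
            e_lin, s_lin = 2.0 ** e_val, 2.0 ** s_val
        else:
            e_lin, s_lin = float(e_val), float(s_val)
        if e_lin == 0:
            raise ValueError(f"zero epithelium marker intensity for patient {patient!r}")
        percents[patient] = 100.0 * s_lin / e_lin
    if not percents:
        raise ValueError("no complete patient pair with the marker quantified")
    series = pd.Series(percents, name=f"{marker_id}_percent")
    return float(series.mean()), float(series.median()), series
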