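"""Core data containers for the stromal-hypoxia signature pipeline.

The pipeline operates on four kinds of objects:

* :class:`IntensityMatrix` — log2 protein abundances (proteins x samples)
  with explicit missing values, the unit every proteomics stage consumes;
* :class:`SampleDesign` — per-sample factor labels (subtype, oxygen,
  compartment, patient) that define the groups of a differential contrast;
* :class:`CohortData` — a gene-expression cohort with clinical covariates
  and a survival outcome, used for scoring and survival modelling;
* :class:`SignatureSet` — an ordered set of gene/protein identifiers, the
  object that is derived, scored, permuted and reduced.

All tabular fields are pandas objects; ``NaN`` is the single missing state
in an :class:`IntensityMatrix` and is distinct from zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SUBTYPES = ("luminal", "basal")
OXYGEN_LEVELS = ("normoxia", "hypoxia")
COMPARTMENTS = ("epithelium", "stroma")

#: factor columns a SampleDesign may carry
DESIGN_FACTORS = ("subtype", "oxygen", "compartment", "patient_id", "replicate")


def _check_unique(values, what: str) -> None:
    idx = pd.Index(values)
    if idx.has_duplicates:
        dups = sorted(idx[idx.duplicated()].unique().tolist())
        raise ValueError(f"duplicate {what}: {dups}")


@dataclass(frozen=True)
class IntensityMatrix:
    """Log2 protein intensities, proteins as rows, samples as columns.

    Missing values are ``NaN``; they mark proteins not quantified in a run
    (missing-not-at-random at low abundance), never an abundance of zero.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if not isinstance(self.data, pd.DataFrame):
            raise TypeError("IntensityMatrix.data must be a pandas DataFrame")
        _check_unique(self.data.index, "protein id(s)")
        _check_unique(self.data.columns, "sample id(s)")
        object.__setattr__(self, "data", self.data.astype(float))

    @property
    def protein_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_missing(self) -> int:
        return int(self.data.isna().sum().sum())

    def subset_samples(self, sample_ids) -> "IntensityMatrix":
        return IntensityMatrix(self.data.loc[:, list(sample_ids)])


@dataclass(frozen=True)
class SampleDesign:
    """Per-sample factor labels; index = sample id.

    Recognised factor columns: ``subtype`` (luminal/basal), ``oxygen``
    (normoxia/hypoxia, secretome experiments), ``compartment``
    (epithelium/stroma, microdissected tissue), ``patient_id`` and
    ``replicate``. Optional factors may be absent or NaN; a factor used by
    a requested contrast must be non-missing for every sample in it.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if not isinstance(self.table, pd.DataFrame):
            raise TypeError("SampleDesign.table must be a pandas DataFrame")
        _check_unique(self.table.index, "sample id(s) in design")
        if "subtype" in self.table.columns:
            bad = set(self.table["subtype"].dropna()) - set(SUBTYPES)
            if bad:
                raise ValueError(f"unknown subtype level(s): {sorted(bad)}")
        if "oxygen" in self.table.columns:
            bad = set(self.table["oxygen"].dropna()) - set(OXYGEN_LEVELS)
            if bad:
                raise ValueError(f"unknown oxygen level(s): {sorted(bad)}")
        if "compartment" in self.table.columns:
            bad = set(self.table["compartment"].dropna()) - set(COMPARTMENTS)
            if bad:
                raise ValueError(f"unknown compartment level(s): {sorted(bad)}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    def samples_where(self, **levels) -> list[str]:
        """Sample ids whose factors equal the given levels, e.g.
        ``samples_where(subtype="luminal", oxygen="hypoxia")``."""
        mask = pd.Series(True, index=self.table.index)
        for factor, level in levels.items():
            if factor not in self.table.columns:
                raise KeyError(f"design has no factor {factor!r}")
            mask &= self.table[factor] == level
        return list(self.table.index[mask])


@dataclass(frozen=True)
class Contrast:
    """A two-group comparison: ``factor`` with levels ``(group1, group2)``,
    optionally restricted to samples where ``within`` holds
    (e.g. hypoxia vs normoxia within subtype=luminal)."""

    factor: str
    levels: tuple[str, str]
    within: dict[str, str] = field(default_factory=dict)

    def groups(self, design: SampleDesign) -> tuple[list[str], list[str]]:
        g1 = design.samples_where(**{self.factor: self.levels[0]}, **self.within)
        g2 = design.samples_where(**{self.factor: self.levels[1]}, **self.within)
        if not g1 or not g2:
            raise ValueError(
                f"empty group in contrast {self.factor}={self.levels} within {self.within}"
            )
        if self.factor in design.table.columns:
            scope = design.samples_where(**self.within) if self.within else design.sample_ids
            missing = design.table.loc[scope, self.factor].isna()
            if missing.any():
                raise ValueError(
                    f"factor {self.factor!r} missing for sample(s) "
                    f"{list(missing.index[missing])}"
                )
        return g1, g2


@dataclass(frozen=True)
class SignatureSet:
    """An ordered, duplicate-free list of gene/protein identifiers."""

    name: str
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        members = tuple(str(m) for m in self.members)
        _check_unique(members, f"member(s) in signature {self.name!r}")
        object.__setattr__(self, "members", members)

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, item) -> bool:
        return item in self.members

    def sorted(self, name: str | None = None) -> "SignatureSet":
        return SignatureSet(name or self.name, tuple(sorted(self.members)))


@dataclass(frozen=True)
class CohortData:
    """An expression cohort: genes x patients expression (complete after
    probe collapse), per-patient clinical covariates, and survival outcome
    (``time`` in months > 0; ``event`` 1 = death from disease, 0 = censored,
    including deaths from other causes)."""

    expression: pd.DataFrame
    clinical: pd.DataFrame
    survival: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.expression.index, "gene id(s)")
        _check_unique(self.expression.columns, "patient id(s)")
        patients = pd.Index(self.expression.columns)
        for name, tab in (("clinical", self.clinical), ("survival", self.survival)):
            if not patients.equals(pd.Index(tab.index)):
                raise ValueError(
                    f"{name} table patients do not match expression columns"
                )
        if self.expression.isna().any().any():
            raise ValueError("expression contains missing values after collapse")
        for col in ("time", "event"):
            if col not in self.survival.columns:
                raise ValueError(f"survival table lacks column {col!r}")
        time = self.survival["time"].to_numpy(float)
        if not np.all(np.isfinite(time)) or np.any(time <= 0):
            raise ValueError("survival time must be finite and strictly positive")
        ev = set(self.survival["event"].unique().tolist())
        if not ev <= {0, 1}:
            raise ValueError(f"event must be 0/1, got {sorted(ev)}")

    @property
    def patient_ids(self) -> list[str]:
        return list(self.expression.columns)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.expression.index)

    @property
    def n_events(self) -> int:
        return int(self.survival["event"].sum())
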