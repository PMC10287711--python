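"""Readers and writers for the pipeline's on-disk formats.

One unambiguous dialect everywhere: tab-separated tables, decimal point
".", missing written as "NA". On read, the tokens "NA" and "" as well as
unparseable numeric cells become missing. Identifiers are matched exactly
and case-sensitively. Gene sets travel as standard GMT
(name <tab> description <tab> member...).
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .types import CohortData, IntensityMatrix, SampleDesign, SignatureSet

logger = logging.getLogger("hypoxsig")

NA_TOKEN = "NA"


def setup_logging(verbose: bool = False) -> None:
    """Log to standard error; -v raises the level to DEBUG."""
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.handlers[:] = [handler]
    logger.setLevel(logging.DEBUG if verbose else logging.INFO)


# ---------------------------------------------------------------------------
# intensity matrix + design


def _read_table(path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep="\t",
        index_col=0,
        dtype=str,
        na_values=[NA_TOKEN, ""],
        keep_default_na=False,
    )
    df.index = df.index.astype(str)
    df.index.name = None
    df.columns.name = None
    return df


def read_intensity_matrix(path) -> IntensityMatrix:
    """Read a proteins-x-samples TSV; first column = protein id, header =
    sample ids. Unparseable cells become missing."""
    raw = _read_table(path)
    if raw.index.has_duplicates:
        dups = sorted(raw.index[raw.index.duplicated()].unique().tolist())
        raise ValueError(f"duplicate protein id(s) in {path}: {dups}")
    if raw.columns.has_duplicates:
        dups = sorted(raw.columns[raw.columns.duplicated()].unique().tolist())
        raise ValueError(f"duplicate sample id(s) in {path}: {dups}")
    values = raw.apply(pd.to_numeric, errors="coerce")
    return IntensityMatrix(values)


def read_sample_design(path) -> SampleDesign:
    table = _read_table(path)
    if table.index.has_duplicates:
        dups = sorted(table.index[table.index.duplicated()].unique().tolist())
        raise ValueError(f"duplicate sample id(s) in design {path}: {dups}")
    return SampleDesign(table)


def read_intensity_bundle(matrix_path, design_path) -> tuple[IntensityMatrix, SampleDesign]:
    """Read a matrix TSV and its sample-design TSV as a consistent pair."""
    m = read_intensity_matrix(matrix_path)
    design = read_sample_design(design_path)
    extra = set(design.sample_ids) - set(m.sample_ids)
    if extra:
        raise ValueError(f"design sample(s) absent from matrix: {sorted(extra)}")
    missing = set(m.sample_ids) - set(design.sample_ids)
    if missing:
        raise ValueError(f"matrix sample(s) absent from design: {sorted(missing)}")
    # align design row order to the matrix columns
    design = SampleDesign(design.table.loc[m.sample_ids])
    return m, design


def write_intensity_matrix(m: IntensityMatrix, path) -> None:
    m.data.to_csv(path, sep="\t", na_rep=NA_TOKEN, index_label="protein_id")


def write_sample_design(design: SampleDesign, path) -> None:
    design.table.to_csv(path, sep="\t", na_rep=NA_TOKEN, index_label="sample_id")


def write_intensity_bundle(m: IntensityMatrix, design: SampleDesign,
                           matrix_path, design_path) -> None:
    write_intensity_matrix(m, matrix_path)
    write_sample_design(design, design_path)


# ---------------------------------------------------------------------------
# GMT gene sets


def read_gmt(path) -> list[SignatureSet]:
    """One SignatureSet per line: name, description, members... Member order
    is preserved; duplicate members on a line are an error."""
    sets: list[SignatureSet] = []
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}: line {lineno} has {len(fields)} field(s); "
                    "expected name, description and at least one member"
                )
            name, _desc, *members = fields
            members = [m for m in members if m != ""]
            if not members:
                raise ValueError(f"{path}: line {lineno} has no members")
            sets.append(SignatureSet(name, tuple(members)))
    return sets


def write_gmt(sets: list[SignatureSet], path, description: str = "na") -> None:
    """Write standard GMT; round-trips bit-exactly with :func:`read_gmt`."""
    for s in sets:
        if len(s.members) == 0:
            raise ValueError(f"signature {s.name!r} has no members; cannot write GMT")
    with open(path, "wt", encoding="utf-8") as fh:
        for s in sets:
            fh.write("\t".join([s.name, description, *s.members]) + "\n")


# ---------------------------------------------------------------------------
# cohort bundle + config


@dataclass(frozen=True)
class CohortConfig:
    """Declares which clinical columns play which role (no column guessing).

    ``time_column``/``event_column`` locate the survival outcome in the
    clinical table; ``covariate_columns`` are prognostic adjusters;
    ``treatment_columns`` are 0/1 treatment flags (endocrine, chemo,
    radiotherapy)."""

    time_column: str = "time"
    event_column: str = "event"
    covariate_columns: tuple[str, ...] = ()
    treatment_columns: tuple[str, ...] = ()

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        with open(path, "rt", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        cohort = raw.get("cohort", raw)
        return cls(
            time_column=cohort.get("time_column", "time"),
            event_column=cohort.get("event_column", "event"),
            covariate_columns=tuple(cohort.get("covariate_columns", ())),
            treatment_columns=tuple(cohort.get("treatment_columns", ())),
        )


def read_probe_map(path) -> pd.Series:
    """Two-column TSV probe -> gene; returns a Series indexed by probe."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"probe map {path} needs two columns (probe, gene)")
    s = pd.Series(df.iloc[:, 1].values, index=df.iloc[:, 0].values)
    if s.index.has_duplicates:
        dups = sorted(s.index[s.index.duplicated()].unique().tolist())
        raise ValueError(f"duplicate probe id(s) in map: {dups}")
    return s


def read_cohort(expression_path, clinical_path, config: CohortConfig) -> CohortData:
    """Assemble a CohortData from an expression TSV (genes x patients) and a
    clinical TSV whose survival columns are named by ``config``."""
    expr = _read_table(expression_path).apply(pd.to_numeric, errors="coerce")
    clin = _read_table(clinical_path)
    for col in (config.time_column, config.event_column):
        if col not in clin.columns:
            raise ValueError(f"clinical table lacks declared column {col!r}")
    surv = pd.DataFrame(
        {
            "time": pd.to_numeric(clin[config.time_column]),
            "event": pd.to_numeric(clin[config.event_column]).astype(int),
        },
        index=clin.index,
    )
    clinical = clin.drop(columns=[config.time_column, config.event_column])
    for col in (*config.covariate_columns, *config.treatment_columns):
        if col not in clinical.columns:
            raise ValueError(f"clinical table lacks declared column {col!r}")
        clinical[col] = pd.to_numeric(clinical[col])
    clinical = clinical.loc[expr.columns]
    surv = surv.loc[expr.columns]
    return CohortData(expr, clinical, surv)


def write_cohort(cohort: CohortData, expression_path, clinical_path) -> None:
    cohort.expression.to_csv(expression_path, sep="\t", na_rep=NA_TOKEN,
                             index_label="gene_id")
    joined = cohort.clinical.join(cohort.survival)
    joined.to_csv(clinical_path, sep="\t", na_rep=NA_TOKEN, index_label="patient_id")
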