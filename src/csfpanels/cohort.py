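"""Cohort data model, file I/O, configuration, and run manifests.

The universal input of every analysis stage is a :class:`CohortTable`: one
row per subject carrying demographics (age at lumbar puncture, gender, APOE
genotype, Clinical Dementia Rating) and one column per analyte
concentration, plus a sidecar of per-analyte units and lower detection
limits (LDL).

CSV dialect (documented contract): comma-separated, UTF-8, "." decimal.
An empty cell or ``NA`` is a missing value; a cell of the form ``<x``
(e.g. ``<2.5``) is a below-detection-limit measurement and is stored as
missing with the ``below_ldl`` flag set.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("csfpanels")

#: demographic columns every cohort file must carry, in order
DEMOGRAPHIC_COLUMNS = ("subject_id", "age_at_lp", "gender", "apoe", "cdr")

#: CDR levels the model understands (0 = normal, 0.5 = very mild, 1 = mild)
ALLOWED_CDR = (0.0, 0.5, 1.0)


class SchemaError(ValueError):
    """A required column is absent or malformed."""


class IntegrityError(ValueError):
    """File contents violate a cross-file or uniqueness constraint."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class CohortTable:
    """Subjects x analytes concentration matrix plus demographics.

    Attributes
    ----------
    demographics : pd.DataFrame
        Indexed by subject_id; columns ``age_at_lp`` (years), ``gender``
        ("female"/"male"), ``apoe`` (genotype string, e.g. "e3e4"),
        ``cdr`` (0, 0.5 or 1).
    values : pd.DataFrame
        Concentrations, indexed by subject_id, one column per analyte.
        NaN marks a missing cell (including below-LDL cells until they are
        imputed).
    below_ldl : pd.DataFrame
        Boolean mask, same shape as ``values``: True where the assay
        reported the value as below its lower detection limit.
    analyte_meta : pd.DataFrame
        Indexed by analyte name; columns ``unit`` and ``ldl`` (>0).
    """

    demographics: pd.DataFrame
    values: pd.DataFrame
    below_ldl: pd.DataFrame
    analyte_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    # -- invariants --------------------------------------------------------
    def validate(self) -> None:
        if not self.demographics.index.is_unique:
            dup = self.demographics.index[self.demographics.index.duplicated()][0]
            raise IntegrityError(f"duplicate subject_id {dup!r}")
        bad_cdr = set(self.demographics["cdr"]) - set(ALLOWED_CDR)
        if bad_cdr:
            raise IntegrityError(f"cdr values outside {ALLOWED_CDR}: {sorted(bad_cdr)}")
        if list(self.values.columns) != list(self.analyte_meta.index):
            missing = set(self.values.columns).symmetric_difference(self.analyte_meta.index)
            raise IntegrityError(f"analyte columns and metadata disagree on: {sorted(missing)}")
        if (self.analyte_meta["ldl"] <= 0).any():
            bad = self.analyte_meta.index[self.analyte_meta["ldl"] <= 0][0]
            raise IntegrityError(f"LDL must be positive; analyte {bad!r} violates this")
        if self.below_ldl.shape != self.values.shape:
            raise IntegrityError("below_ldl mask shape differs from values")

    # -- derived views -----------------------------------------------------
    @property
    def n_subjects(self) -> int:
        return len(self.demographics)

    @property
    def n_analytes(self) -> int:
        return self.values.shape[1]

    @property
    def analytes(self) -> list[str]:
        return list(self.values.columns)

    def female_indicator(self) -> pd.Series:
        """Binary covariate: 1 for female, 0 for male."""
        return (self.demographics["gender"] == "female").astype(float)

    def e4_carrier(self) -> pd.Series:
        """APOE epsilon-4 positivity: any e4 allele in the genotype string."""
        return self.demographics["apoe"].str.contains("4").astype(float)

    def impaired(self) -> pd.Series:
        """Binary group label: 1 for CDR > 0 (very mild/mild dementia), 0 for CDR 0."""
        return (self.demographics["cdr"] > 0).astype(int)

    def subset_subjects(self, ids) -> "CohortTable":
        ids = list(ids)
        return CohortTable(
            demographics=self.demographics.loc[ids].copy(),
            values=self.values.loc[ids].copy(),
            below_ldl=self.below_ldl.loc[ids].copy(),
            analyte_meta=self.analyte_meta.copy(),
        )

    def subset_analytes(self, names) -> "CohortTable":
        names = list(names)
        return CohortTable(
            demographics=self.demographics.copy(),
            values=self.values[names].copy(),
            below_ldl=self.below_ldl[names].copy(),
            analyte_meta=self.analyte_meta.loc[names].copy(),
        )

    def copy(self) -> "CohortTable":
        return CohortTable(
            demographics=self.demographics.copy(),
            values=self.values.copy(),
            below_ldl=self.below_ldl.copy(),
            analyte_meta=self.analyte_meta.copy(),
        )


@dataclass
class FollowUpRecord:
    """Time from baseline lumbar puncture to CDR conversion or censoring."""

    subject_id: str
    time_to_event: float  # years
    event: bool  # True = converted to CDR>0, False = censored

    def __post_init__(self) -> None:
        if not self.time_to_event > 0:
            raise IntegrityError(
                f"time_to_event must be positive (subject {self.subject_id})"
            )


@dataclass
class RunConfig:
    """All tunable thresholds of the pipeline, collected in one place.

    Defaults are the constants the workflow is defined with: the 10%
    measurability threshold, the 5-SD outlier rule, 100 bootstrap
    iterations, 200 train/test splits at an 80% training fraction,
    sensitivity read at 80% specificity, Cox screening at p<0.15 with
    multivariate retention at p<0.05, and a Bonferroni family of 128 tests.
    """

    missing_threshold: float = 0.10
    outlier_z: float = 5.0
    knn_k: int = 5
    bootstrap_B: int = 100
    n_splits: int = 200
    train_frac: float = 0.80
    specificity_target: float = 0.80
    screen_alpha: float = 0.15
    retention_alpha: float = 0.05
    bonferroni_alpha: float = 0.05
    bonferroni_n: int = 128
    corr_threshold: float = 0.40
    seed: int = 0
    out_dir: str = "results"

    def __post_init__(self) -> None:
        for name in ("missing_threshold", "train_frac", "specificity_target",
                     "screen_alpha", "retention_alpha", "bonferroni_alpha"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0,1), got {v}")
        if self.bootstrap_B < 1:
            raise ValueError("bootstrap_B must be >= 1")
        if self.bonferroni_n < 1:
            raise ValueError("bonferroni_n must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise SchemaError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def _parse_cell(raw: Any) -> tuple[float, bool, bool]:
    """Parse one concentration cell -> (value, below_ldl, unparseable)."""
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return np.nan, False, False
    s = str(raw).strip()
    if s == "" or s.upper() in {"NA", "NAN"}:
        return np.nan, False, False
    if s.startswith("<"):
        return np.nan, True, False
    try:
        return float(s), False, False
    except ValueError:
        return np.nan, False, True


def read_ldl(path: str | Path) -> pd.DataFrame:
    """Read the LDL sidecar: columns analyte, unit, ldl."""
    meta = pd.read_csv(path, dtype={"analyte": str, "unit": str})
    for col in ("analyte", "unit", "ldl"):
        if col not in meta.columns:
            raise SchemaError(f"LDL table missing required column {col!r}")
    if not meta["analyte"].is_unique:
        raise IntegrityError("duplicate analyte in LDL table")
    return meta.set_index("analyte")


def read_cohort(path: str | Path, ldl_path: str | Path) -> CohortTable:
    """Read a wide cohort CSV plus its LDL sidecar into a CohortTable.

    Unparseable concentration cells are recorded as missing; the count is
    logged. A missing demographic column raises :class:`SchemaError`; a
    duplicate subject id or an analyte absent from the LDL table raises
    :class:`IntegrityError`.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in DEMOGRAPHIC_COLUMNS:
        if col not in raw.columns:
            raise SchemaError(f"cohort file missing required column {col!r}")
    analyte_cols = [c for c in raw.columns if c not in DEMOGRAPHIC_COLUMNS]
    meta = read_ldl(ldl_path)
    absent = [a for a in analyte_cols if a not in meta.index]
    if absent:
        raise IntegrityError(f"LDL table lacks analytes: {absent}")

    demo = pd.DataFrame(
        {
            "age_at_lp": pd.to_numeric(raw["age_at_lp"]).to_numpy(),
            "gender": raw["gender"].str.strip().str.lower().to_numpy(),
            "apoe": raw["apoe"].str.strip().to_numpy(),
            "cdr": pd.to_numeric(raw["cdr"]).to_numpy(),
        },
        index=pd.Index(raw["subject_id"].str.strip().to_numpy(), name="subject_id"),
    )
    bad_gender = set(demo["gender"]) - {"female", "male"}
    if bad_gender:
        raise SchemaError(f"unrecognized gender values: {sorted(bad_gender)}")

    n = len(raw)
    values = np.full((n, len(analyte_cols)), np.nan)
    mask = np.zeros((n, len(analyte_cols)), dtype=bool)
    n_unparseable = 0
    for j, col in enumerate(analyte_cols):
        for i, cell in enumerate(raw[col]):
            v, below, bad = _parse_cell(cell)
            values[i, j] = v
            mask[i, j] = below
            n_unparseable += bad
    if n_unparseable:
        logger.warning("recorded %d unparseable concentration cells as missing",
                       n_unparseable)

    return CohortTable(
        demographics=demo,
        values=pd.DataFrame(values, index=demo.index, columns=analyte_cols),
        below_ldl=pd.DataFrame(mask, index=demo.index, columns=analyte_cols),
        analyte_meta=meta.loc[analyte_cols],
    )


def write_cohort(table: CohortTable, path: str | Path, ldl_path: str | Path) -> None:
    """Write a CohortTable back to the wide CSV + LDL sidecar dialect.

    Below-LDL cells are emitted as ``<LDL`` so the censoring survives a
    round trip; missing cells are emitted empty.
    """
    out = table.demographics.reset_index().copy()
    out["cdr"] = out["cdr"].map(lambda c: f"{c:g}")
    for name in table.analytes:
        ldl = table.analyte_meta.loc[name, "ldl"]
        col = []
        for v, below in zip(table.values[name], table.below_ldl[name]):
            if below:
                col.append(f"<{ldl:g}")
            elif np.isnan(v):
                col.append("")
            else:
                col.append(repr(float(v)))
        out[name] = col
    out.to_csv(path, index=False)
    table.analyte_meta.reset_index().to_csv(ldl_path, index=False)


def read_followup(path: str | Path) -> list[FollowUpRecord]:
    """Read follow-up CSV: columns subject_id, time_to_event, event."""
    raw = pd.read_csv(path, dtype={"subject_id": str})
    for col in ("subject_id", "time_to_event", "event"):
        if col not in raw.columns:
            raise SchemaError(f"follow-up file missing required column {col!r}")
    records = []
    for _, row in raw.iterrows():
        ev = str(row["event"]).strip().lower()
        if ev not in {"converted", "censored"}:
            raise SchemaError(f"event must be converted/censored, got {ev!r}")
        records.append(FollowUpRecord(row["subject_id"],
                                      float(row["time_to_event"]),
                                      ev == "converted"))
    return records


def write_followup(records: list[FollowUpRecord], path: str | Path) -> None:
    pd.DataFrame(
        {
            "subject_id": [r.subject_id for r in records],
            "time_to_event": [r.time_to_event for r in records],
            "event": ["converted" if r.event else "censored" for r in records],
        }
    ).to_csv(path, index=False)


def write_report(stage_results: Mapping[str, pd.DataFrame],
                 out_dir: str | Path,
                 config: RunConfig | None = None) -> dict[str, Path]:
    """Write stage result tables as CSV plus a JSON run manifest.

    ``stage_results`` maps a table name (e.g. "screen", "panels", "ml",
    "cox") to a DataFrame; each becomes ``<name>.csv`` under ``out_dir``.
    The manifest records the configuration (seed included) so a run can be
    reproduced; it carries no timestamps, so equal config and seed yield
    byte-identical output.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    for name, df in stage_results.items():
        p = out_dir / f"{name}.csv"
        df.to_csv(p, index=False)
        written[name] = p
    manifest = {
        "tables": sorted(stage_results),
        "config": config.to_dict() if config is not None else None,
        "seed": config.seed if config is not None else None,
    }
    mpath = out_dir / "manifest.json"
    with open(mpath, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    written["manifest"] = mpath
    return written
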