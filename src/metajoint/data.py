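"""Shared data model for multi-study joint longitudinal / time-to-event datasets.

A *study* couples a long-format table of repeated continuous measurements
(one row per subject per visit) with a one-row-per-subject survival table
(follow-up time and event indicator).  Every other module consumes these
containers rather than raw files, so validation lives here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

LONG_COLUMNS = ("subject_id", "time", "outcome")
SURV_COLUMNS = ("subject_id", "surv_time", "event")


class FormatError(ValueError):
    """A file is missing required columns or otherwise malformed."""


class ValidationError(ValueError):
    """A dataset violates a structural invariant."""


@dataclass
class StudyData:
    """One study's individual participant data.

    Parameters
    ----------
    study_id : str
        Opaque study label; no ordering semantics.
    longitudinal : pandas.DataFrame
        Columns ``subject_id``, ``time``, ``outcome`` plus any covariate
        columns (e.g. ``treat``).  One row per measurement occasion.
    survival : pandas.DataFrame
        Columns ``subject_id``, ``surv_time``, ``event`` plus covariates.
        Exactly one row per subject; ``event`` is 1 for an observed event
        and 0 for censoring.

    Invariants (enforced by :meth:`validate`): every longitudinal subject
    has a survival row; measurement times are finite, non-negative and
    strictly before the subject's survival time; (subject, time) pairs are
    unique; events are coded 0/1.
    """

    study_id: str
    longitudinal: pd.DataFrame
    survival: pd.DataFrame

    def __post_init__(self) -> None:
        self.study_id = str(self.study_id)
        self.validate()

    # -- validation ---------------------------------------------------
    def validate(self) -> "StudyData":
        long, surv = self.longitudinal, self.survival
        for col in LONG_COLUMNS:
            if col not in long.columns:
                raise FormatError(f"longitudinal table missing column {col!r}")
        for col in SURV_COLUMNS:
            if col not in surv.columns:
                raise FormatError(f"survival table missing column {col!r}")
        if surv["subject_id"].duplicated().any():
            raise ValidationError("survival table must have one row per subject")
        ev = surv["event"].to_numpy()
        if not np.isin(ev, (0, 1)).all():
            raise ValidationError("event indicator must be 0 or 1")
        if (surv["surv_time"].to_numpy() <= 0).any():
            raise ValidationError("survival times must be positive")
        t = long["time"].to_numpy(dtype=float)
        if not np.isfinite(t).all() or (t < 0).any():
            raise ValidationError("measurement times must be finite and >= 0")
        missing = set(long["subject_id"]) - set(surv["subject_id"])
        if missing:
            raise ValidationError(
                f"subjects in longitudinal but not survival: {sorted(map(str, missing))[:5]}"
            )
        if long.duplicated(subset=["subject_id", "time"]).any():
            raise ValidationError("duplicate (subject_id, time) measurement")
        # strict 'measurement before event time' rule
        st = surv.set_index("subject_id")["surv_time"]
        viol = t >= st.loc[long["subject_id"]].to_numpy(dtype=float)
        if viol.any():
            raise ValidationError(
                f"{int(viol.sum())} longitudinal rows at or after the survival time"
            )
        return self

    @property
    def n_subjects(self) -> int:
        return len(self.survival)

    @property
    def n_events(self) -> int:
        return int(self.survival["event"].sum())

    @property
    def n_measurements(self) -> int:
        return len(self.longitudinal)

    def covariate_names(self) -> list[str]:
        return [c for c in self.survival.columns if c not in SURV_COLUMNS]


@dataclass
class MetaDataset:
    """A collection of studies entering one two-stage meta-analysis."""

    studies: list[StudyData] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [s.study_id for s in self.studies]
        if len(set(ids)) != len(ids):
            raise ValidationError("study_ids must be unique")

    def __len__(self) -> int:
        return len(self.studies)

    def __iter__(self):
        return iter(self.studies)

    def __getitem__(self, i):
        return self.studies[i]


DEFAULT_COLUMN_MAP = {
    "subject_id": "subject_id",
    "time": "time",
    "outcome": "outcome",
    "surv_time": "surv_time",
    "event": "event",
}


def read_study(
    longitudinal_path: str | Path,
    survival_path: str | Path,
    column_map: Mapping[str, str] | None = None,
    study_id: str | None = None,
) -> StudyData:
    """Read one study from two CSV files.

    ``column_map`` maps canonical names (``subject_id``, ``time``,
    ``outcome``, ``surv_time``, ``event``) to the column names used in the
    files.  Longitudinal rows with a missing outcome are dropped, as are
    rows whose measurement time is at or after the subject's survival time
    (strictly-before rule); the number of dropped rows is logged.
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    cmap.update(column_map or {})
    long = pd.read_csv(longitudinal_path)
    surv = pd.read_csv(survival_path)
    for canon in ("subject_id", "time", "outcome"):
        if cmap[canon] not in long.columns:
            raise FormatError(
                f"longitudinal file missing column {cmap[canon]!r} (for {canon})"
            )
    for canon in ("subject_id", "surv_time", "event"):
        if cmap[canon] not in surv.columns:
            raise FormatError(
                f"survival file missing column {cmap[canon]!r} (for {canon})"
            )
    long = long.rename(columns={v: k for k, v in cmap.items() if v in long.columns})
    surv = surv.rename(columns={v: k for k, v in cmap.items() if v in surv.columns})

    n0 = len(long)
    long = long.dropna(subset=["outcome"])
    n_na = n0 - len(long)
    if n_na:
        logger.warning("dropped %d longitudinal rows with missing outcome", n_na)

    missing = set(long["subject_id"]) - set(surv["subject_id"])
    if missing:
        raise ValidationError(
            f"subjects in longitudinal but not survival: {sorted(map(str, missing))[:5]}"
        )
    st = surv.set_index("subject_id")["surv_time"]
    keep = long["time"].to_numpy(dtype=float) < st.loc[
        long["subject_id"]
    ].to_numpy(dtype=float)
    n_drop = int((~keep).sum())
    if n_drop:
        logger.warning(
            "dropped %d longitudinal rows at or after the survival time", n_drop
        )
    long = long.loc[keep].reset_index(drop=True)
    sid = study_id if study_id is not None else Path(longitudinal_path).stem
    return StudyData(sid, long, surv.reset_index(drop=True))


def write_study(
    study: StudyData,
    longitudinal_path: str | Path,
    survival_path: str | Path,
) -> tuple[Path, Path]:
    """Write a study back to the two-CSV interchange format."""
    lp, sp = Path(longitudinal_path), Path(survival_path)
    study.longitudinal.to_csv(lp, index=False)
    study.survival.to_csv(sp, index=False)
    return lp, sp


def write_meta_dataset(dataset: MetaDataset, out_dir: str | Path) -> list[Path]:
    """Write each study as ``<study_id>_longitudinal.csv`` / ``<study_id>_survival.csv``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: list[Path] = []
    for s in dataset:
        paths.extend(
            write_study(
                s,
                out / f"{s.study_id}_longitudinal.csv",
                out / f"{s.study_id}_survival.csv",
            )
        )
    return paths


def summarize_study(study: StudyData) -> dict:
    """Subject, event and measurement counts, as printed in study tables."""
    return {
        "study_id": study.study_id,
        "n_subjects": study.n_subjects,
        "n_events": study.n_events,
        "n_measurements": study.n_measurements,
    }
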