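"""Cohort containers and tidy tabular I/O.

A cohort is a conversion-aligned two-group longitudinal design: per subject a
group label (HD / control), covariates, and irregular visit times in years
relative to motor conversion (t = 0); per visit 55 regional volumes expressed
as % of the cohort mean volume at diagnosis, plus optional TMS / SDMT scores
rescaled to [0, 100].

On disk a cohort is two tab-separated tables:

``subjects.tsv``
    one row per subject: id, group, cag, gender, age, tiv, site
    (cag empty for controls)
``visits.tsv``
    one row per subject-visit: id, time_years, the 55 region columns in the
    documented order of :data:`hdprog.regions.REGION_COLUMNS`, tms, sdmt
    (behavior columns empty when not measured)
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .regions import BEHAVIOR_CHANNELS, N_REGIONS, REGION_COLUMNS

SUBJECT_COLUMNS = ["id", "group", "cag", "gender", "age", "tiv", "site"]
VISIT_COLUMNS = ["id", "time_years"] + REGION_COLUMNS + BEHAVIOR_CHANNELS


class CohortValidationError(ValueError):
    """Raised when cohort tables violate the documented schema."""


@dataclass
class Subject:
    id: str
    group: str  # "HD" or "control"
    cag: int | None
    gender: str  # "F" or "M"
    age_at_alignment: float
    tiv: float
    site: str
    visit_times: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def __post_init__(self):
        if self.group not in ("HD", "control"):
            raise CohortValidationError(
                f"subject {self.id}: group must be HD or control, got {self.group!r}")
        t = np.asarray(self.visit_times, float)
        if len(t) and np.any(np.diff(t) <= 0):
            raise CohortValidationError(
                f"subject {self.id}: visit_times must be strictly increasing")
        self.visit_times = t


@dataclass
class RegionalTimeSeries:
    """Observed volumes (and optional behavior) for one subject."""

    subject_id: str
    times: np.ndarray
    volumes: np.ndarray  # [visit x 55], % of cohort mean at diagnosis
    behavior: np.ndarray | None = None  # [visit x 2], rescaled to [0, 100]

    def __post_init__(self):
        self.times = np.asarray(self.times, float)
        self.volumes = np.asarray(self.volumes, float)
        if self.volumes.ndim != 2 or self.volumes.shape != (len(self.times), N_REGIONS):
            raise CohortValidationError(
                f"subject {self.subject_id}: volumes must be "
                f"[{len(self.times)} x {N_REGIONS}]")
        if np.any(np.diff(self.times) <= 0):
            raise CohortValidationError(
                f"subject {self.subject_id}: times must be strictly increasing")
        bad = np.argwhere(~(self.volumes > 0))
        if len(bad):
            r, c = bad[0]
            raise CohortValidationError(
                f"subject {self.subject_id}: non-positive volume in region "
                f"{REGION_COLUMNS[c]!r} at visit row {r}")
        if self.behavior is not None:
            self.behavior = np.asarray(self.behavior, float)
            if self.behavior.shape != (len(self.times), len(BEHAVIOR_CHANNELS)):
                raise CohortValidationError(
                    f"subject {self.subject_id}: behavior must be "
                    f"[{len(self.times)} x {len(BEHAVIOR_CHANNELS)}]")
            finite = self.behavior[np.isfinite(self.behavior)]
            if len(finite) and (finite.min() < 0 or finite.max() > 100):
                raise CohortValidationError(
                    f"subject {self.subject_id}: behavior outside [0, 100]")


Cohort = tuple[list[Subject], list[RegionalTimeSeries]]


def write_cohort(subjects: list[Subject], series: list[RegionalTimeSeries],
                 subjects_path, visits_path) -> None:
    """Write the two tidy TSV tables with the fixed documented column order."""
    srows = [
        {"id": s.id, "group": s.group,
         "cag": "" if s.cag is None else int(s.cag),
         "gender": s.gender, "age": s.age_at_alignment,
         "tiv": s.tiv, "site": s.site}
        for s in subjects
    ]
    pd.DataFrame(srows, columns=SUBJECT_COLUMNS).to_csv(
        subjects_path, sep="\t", index=False, float_format="%.17g")

    vrows = []
    for ts in series:
        for i, t in enumerate(ts.times):
            row = {"id": ts.subject_id, "time_years": t}
            row.update(dict(zip(REGION_COLUMNS, ts.volumes[i])))
            for j, ch in enumerate(BEHAVIOR_CHANNELS):
                val = np.nan if ts.behavior is None else ts.behavior[i, j]
                row[ch] = "" if not np.isfinite(val) else val
            vrows.append(row)
    pd.DataFrame(vrows, columns=VISIT_COLUMNS).to_csv(
        visits_path, sep="\t", index=False, float_format="%.17g")


def read_cohort(subjects_path, visits_path) -> Cohort:
    """Read and hard-validate a cohort written by :func:`write_cohort`.

    Irregular (non-annual) visit spacing is accepted; times must only be
    strictly increasing per subject.
    """
    subjects_path, visits_path = Path(subjects_path), Path(visits_path)
    sdf = pd.read_csv(subjects_path, sep="\t", dtype={"id": str},
                      float_precision="round_trip")
    vdf = pd.read_csv(visits_path, sep="\t", dtype={"id": str},
                      float_precision="round_trip")

    for col in SUBJECT_COLUMNS:
        if col not in sdf.columns:
            raise CohortValidationError(f"subjects table missing column {col!r}")
    for col in VISIT_COLUMNS:
        if col not in vdf.columns:
            raise CohortValidationError(f"visits table missing column {col!r}")

    dup = vdf.duplicated(subset=["id", "time_years"])
    if dup.any():
        row = vdf[dup].iloc[0]
        raise CohortValidationError(
            f"duplicate subject-visit row: id={row['id']} t={row['time_years']}")

    subjects = []
    series = []
    for _, r in sdf.iterrows():
        sv = vdf[vdf["id"] == r["id"]].sort_values("time_years")
        times = sv["time_years"].to_numpy(float)
        cag = None if pd.isna(r["cag"]) else int(r["cag"])
        subjects.append(Subject(
            id=r["id"], group=r["group"], cag=cag, gender=r["gender"],
            age_at_alignment=float(r["age"]), tiv=float(r["tiv"]),
            site=str(r["site"]), visit_times=times))
        beh = sv[BEHAVIOR_CHANNELS].to_numpy(float)
        if np.all(~np.isfinite(beh)):
            beh = None
        series.append(RegionalTimeSeries(
            subject_id=r["id"], times=times,
            volumes=sv[REGION_COLUMNS].to_numpy(float), behavior=beh))
    return subjects, series


def hd_indices(subjects: list[Subject]) -> list[int]:
    return [i for i, s in enumerate(subjects) if s.group == "HD"]


def control_indices(subjects: list[Subject]) -> list[int]:
    return [i for i, s in enumerate(subjects) if s.group == "control"]
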