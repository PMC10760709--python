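"""Cohort dataset container and CSV readers/writers.

A cohort is two tables.  The subject table mirrors the study-style subject
description (anthropometrics, amputation level BK/AK, affected side, daily
hours on legs, years since amputation).  The trial table holds timed walking
trials of two kinds: straight rest-to-rest bouts (distance, duration) and
circle trials (radius, lap count, prosthesis-in/out direction, total
duration).  Average speeds are derived on load — ``D/T`` for straight bouts
and ``laps * 2*pi*R / T`` for circles — and stored in a ``speed_m_s``
column.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SUBJECT_COLUMNS",
    "TRIAL_COLUMNS",
    "LEVEL_TO_GROUP",
    "CohortDataset",
    "derive_speeds",
    "read_dataset",
]

SUBJECT_COLUMNS = [
    "subject_id",
    "age_yr",
    "mass_kg",
    "height_m",
    "leg_length_prosthesis_m",
    "leg_length_intact_m",
    "level",
    "affected_side",
    "sex",
    "hours_on_legs_per_day",
    "years_since_amputation",
]

TRIAL_COLUMNS = [
    "subject_id",
    "task",
    "trial_index",
    "distance_m",
    "radius_m",
    "laps",
    "direction",
    "duration_s",
]

#: amputation level code in the subject table -> coefficient group label
LEVEL_TO_GROUP = {"BK": "below_knee", "AK": "above_knee"}

_VALID_TASKS = {"straight", "circle"}
_VALID_DIRECTIONS = {"prosthesis_in", "prosthesis_out"}


def derive_speeds(trials: pd.DataFrame) -> pd.DataFrame:
    """Return a copy of the trial table with the ``speed_m_s`` column derived
    from distance/radius, laps and duration."""
    trials = trials.copy()
    straight = trials["task"] == "straight"
    speed = np.where(
        straight,
        trials["distance_m"] / trials["duration_s"],
        trials["laps"] * 2.0 * np.pi * trials["radius_m"] / trials["duration_s"],
    )
    trials["speed_m_s"] = speed
    return trials


@dataclass
class CohortDataset:
    """Subject table + trial table for one (real or synthetic) cohort.

    ``provenance`` records where the data came from: ``{"kind": "synthetic",
    "config": {...}}`` or ``{"kind": "real", "source": path}``.
    """

    subjects: pd.DataFrame
    trials: pd.DataFrame
    provenance: dict = field(default_factory=lambda: {"kind": "unknown"})

    def __post_init__(self) -> None:
        if "speed_m_s" not in self.trials.columns:
            self.trials = derive_speeds(self.trials)
        self.validate()

    # -- validation ---------------------------------------------------------
    def validate(self) -> None:
        errors: list[str] = []
        subs = self.subjects
        trials = self.trials
        missing_sub = [c for c in SUBJECT_COLUMNS if c not in subs.columns]
        missing_tr = [c for c in TRIAL_COLUMNS if c not in trials.columns]
        if missing_sub:
            errors.append(f"subject table missing columns: {missing_sub}")
        if missing_tr:
            errors.append(f"trial table missing columns: {missing_tr}")
        if errors:
            raise ValueError("; ".join(errors))

        bad_level = subs.loc[~subs["level"].isin(LEVEL_TO_GROUP), "subject_id"]
        if len(bad_level):
            errors.append(
                f"unknown amputation level code for subjects {list(bad_level)} "
                f"(expected one of {sorted(LEVEL_TO_GROUP)})"
            )
        known = set(subs["subject_id"])
        orphans = trials.loc[~trials["subject_id"].isin(known), "subject_id"]
        if len(orphans):
            errors.append(
                f"trials reference unknown subject ids: {sorted(set(orphans))}"
            )
        dur = pd.to_numeric(trials["duration_s"], errors="coerce")
        bad_dur = trials.index[~(dur > 0)]
        if len(bad_dur):
            errors.append(
                f"non-numeric or non-positive duration in trial rows {list(bad_dur)}"
            )
        bad_task = trials.index[~trials["task"].isin(_VALID_TASKS)]
        if len(bad_task):
            errors.append(f"unknown task in trial rows {list(bad_task)}")
        circ = trials[trials["task"] == "circle"]
        bad_dir = circ.index[~circ["direction"].isin(_VALID_DIRECTIONS)]
        if len(bad_dir):
            errors.append(f"unknown circle direction in trial rows {list(bad_dir)}")
        key_cols = ["subject_id", "task", "distance_m", "radius_m", "direction",
                    "trial_index"]
        dupes = trials.duplicated(subset=key_cols)
        if dupes.any():
            errors.append(
                f"duplicate trial keys in rows {list(trials.index[dupes])}"
            )
        if errors:
            raise ValueError("; ".join(errors))

    # -- accessors ----------------------------------------------------------
    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def group_of(self) -> pd.Series:
        """Map subject_id -> coefficient group label."""
        return self.subjects.set_index("subject_id")["level"].map(LEVEL_TO_GROUP)

    def subjects_in_group(self, group: str) -> list:
        """Subject ids whose amputation level maps to ``group``
        (``"above_knee"`` / ``"below_knee"``)."""
        g = self.group_of()
        return list(g.index[g == group])

    def trials_for_group(self, group: str) -> pd.DataFrame:
        """Trial rows (with derived speeds) for one amputation group."""
        ids = set(self.subjects_in_group(group))
        return self.trials[self.trials["subject_id"].isin(ids)].copy()

    # -- i/o ----------------------------------------------------------------
    def write(self, subjects_path, trials_path, config_path=None) -> None:
        """Write the two CSV tables (12 significant digits) and, optionally,
        a JSON sidecar with the provenance/generating configuration."""
        self.subjects.to_csv(subjects_path, index=False, float_format="%.12g")
        self.trials[TRIAL_COLUMNS].to_csv(
            trials_path, index=False, float_format="%.12g"
        )
        if config_path is not None:
            Path(config_path).write_text(json.dumps(self.provenance, indent=2))

    def equals(self, other: "CohortDataset", rtol: float = 1e-9) -> bool:
        """Field-wise equality of the two tables within floating tolerance."""
        try:
            pd.testing.assert_frame_equal(
                self.subjects.reset_index(drop=True),
                other.subjects.reset_index(drop=True),
                rtol=rtol,
                check_dtype=False,
            )
            pd.testing.assert_frame_equal(
                self.trials[TRIAL_COLUMNS + ["speed_m_s"]].reset_index(drop=True),
                other.trials[TRIAL_COLUMNS + ["speed_m_s"]].reset_index(drop=True),
                rtol=rtol,
                check_dtype=False,
            )
        except AssertionError:
            return False
        return True


def read_dataset(
    subjects_path,
    trials_path,
    column_map: dict[str, str] | None = None,
    circle_durations: str = "total",
) -> CohortDataset:
    """Load a cohort from two CSV files.

    Parameters
    ----------
    column_map :
        Optional adapter mapping from the file's column names to the
        canonical schema, for ingesting externally deposited tables.
    circle_durations :
        ``"total"`` if circle rows hold the whole multi-lap duration
        (canonical), ``"per_lap"`` if they hold a single-lap average, in
        which case durations are multiplied by the lap count on load.
    """
    subjects = pd.read_csv(subjects_path)
    trials = pd.read_csv(trials_path)
    if column_map:
        subjects = subjects.rename(columns=column_map)
        trials = trials.rename(columns=column_map)
    if circle_durations not in ("total", "per_lap"):
        raise ValueError("circle_durations must be 'total' or 'per_lap'")
    if circle_durations == "per_lap":
        circ = trials["task"] == "circle"
        trials.loc[circ, "duration_s"] = (
            trials.loc[circ, "duration_s"] * trials.loc[circ, "laps"]
        )
    return CohortDataset(
        subjects=subjects,
        trials=trials,
        provenance={"kind": "real", "source": str(subjects_path)},
    )
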