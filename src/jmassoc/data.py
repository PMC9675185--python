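"""Trial dataset container: paired longitudinal and survival tables.

longitudinal: one row per CD4 measurement (subject_id, time_months, sqrt_cd4).
survival:     one row per subject (subject_id, time_months, event, arm, age,
              gender), event in {0,1}, arm 1 = combined integrated therapy,
              gender 1 = women.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataError

__all__ = ["TrialDataset", "SubjectCovariates"]

LONG_COLS = ["subject_id", "time_months", "sqrt_cd4"]
SURV_COLS = ["subject_id", "time_months", "event", "arm", "age", "gender"]


@dataclass(frozen=True)
class SubjectCovariates:
    """Baseline covariates entering the survival sub-model linear predictor."""

    arm: int
    age: float
    gender: int

    def __post_init__(self) -> None:
        if self.arm not in (0, 1) or self.gender not in (0, 1):
            raise DataError("arm and gender must be 0/1")
        if not self.age > 0:
            raise DataError("age must be positive")

    def as_array(self) -> np.ndarray:
        return np.array([self.arm, self.age, self.gender], dtype=float)


@dataclass
class TrialDataset:
    longitudinal: pd.DataFrame
    survival: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    # -- invariants ---------------------------------------------------------
    def validate(self) -> None:
        for cols, df, name in ((LONG_COLS, self.longitudinal, "longitudinal"),
                               (SURV_COLS, self.survival, "survival")):
            missing = [c for c in cols if c not in df.columns]
            if missing:
                raise DataError(f"{name} table missing columns {missing}")
        surv = self.survival
        if surv["subject_id"].duplicated().any():
            dup = surv.loc[surv["subject_id"].duplicated(), "subject_id"].tolist()
            raise DataError(f"duplicate survival rows for subjects {dup}")
        if (surv["time_months"] < 0).any():
            raise DataError("negative survival times")
        if not set(surv["event"].unique()) <= {0, 1}:
            raise DataError("event indicator must be 0/1")
        long = self.longitudinal
        if not np.isfinite(long["sqrt_cd4"].to_numpy(dtype=float)).all():
            raise DataError("non-finite longitudinal measurements")
        ids_long = set(long["subject_id"])
        ids_surv = set(surv["subject_id"])
        if ids_long - ids_surv:
            raise DataError(f"longitudinal-only subjects: {sorted(ids_long - ids_surv)[:5]}")
        if ids_surv - ids_long:
            raise DataError(f"subjects with no measurements: {sorted(ids_surv - ids_long)[:5]}")
        tmap = surv.set_index("subject_id")["time_months"]
        late = long[long["time_months"].to_numpy() > tmap.loc[long["subject_id"]].to_numpy() + 1e-9]
        if len(late):
            raise DataError(
                f"measurements after the event/censoring time for subjects "
                f"{sorted(set(late['subject_id']))[:5]}")

    # -- views --------------------------------------------------------------
    @property
    def subject_ids(self) -> np.ndarray:
        return self.survival["subject_id"].to_numpy()

    @property
    def n_subjects(self) -> int:
        return len(self.survival)

    @property
    def t_max(self) -> float:
        """Largest observed event/censoring time (months)."""
        if "t_max" in self.meta:
            return float(self.meta["t_max"])
        return float(self.survival["time_months"].max())

    def covariates(self, sid) -> SubjectCovariates:
        row = self.survival.set_index("subject_id").loc[sid]
        return SubjectCovariates(int(row["arm"]), float(row["age"]), int(row["gender"]))

    def covariate_matrix(self) -> np.ndarray:
        """n x 3 array of (arm, age, gender) in survival-table order."""
        return self.survival[["arm", "age", "gender"]].to_numpy(dtype=float)

    # -- IO -----------------------------------------------------------------
    def to_csv(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.longitudinal.to_csv(outdir / "long.csv", index=False)
        self.survival.to_csv(outdir / "surv.csv", index=False)

    @classmethod
    def from_csv(cls, path, raw_cd4: bool = False) -> "TrialDataset":
        path = Path(path)
        long = pd.read_csv(path / "long.csv")
        surv = pd.read_csv(path / "surv.csv")
        if raw_cd4:
            if "cd4" in long.columns:
                long = long.rename(columns={"cd4": "sqrt_cd4"})
            long["sqrt_cd4"] = np.sqrt(long["sqrt_cd4"].to_numpy(dtype=float))
        return cls(long, surv)
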