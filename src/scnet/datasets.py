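"""Container for subjects x regions cortical-thickness tables.

A :class:`ThicknessDataset` holds the per-subject regional mean thickness
matrix (mm) together with the covariates the analysis removes before
network construction (age, IQ and mean overall cortical thickness) and an
optional dimensional symptom score (ADHD index).  The on-disk format is a
tidy CSV: one row per subject with columns ``subject_id, group, age, iq,
adhd_index`` followed by one column per region.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

META_COLUMNS = ["subject_id", "group", "age", "iq", "adhd_index"]


class DataValidationError(ValueError):
    """Structural problem in an input table (missing values, bad groups...)."""


@dataclass
class ThicknessDataset:
    """Subjects x regions thickness matrix with covariates and group labels.

    Parameters
    ----------
    subject_ids : sequence of str
    group : sequence of str
        Two-level group label per subject (e.g. ``"case"`` / ``"control"``).
    thickness : ndarray, shape (n_subjects, n_regions)
        Regional mean cortical thickness in mm; strictly positive.
    age : ndarray, years.
    iq : ndarray, dimensionless.
    region_names : sequence of str, unique, one per column.
    adhd_index : ndarray or None
        Optional symptom severity score.
    mean_thickness : ndarray or None
        Mean overall cortical thickness covariate; computed as the
        unweighted row mean across regions when not supplied.
    case_label : str or None
        Which group level is the clinical/case group.  Defaults to the
        first label in sorted order.
    """

    subject_ids: list[str]
    group: np.ndarray
    thickness: np.ndarray
    age: np.ndarray
    iq: np.ndarray
    region_names: list[str]
    adhd_index: np.ndarray | None = None
    mean_thickness: np.ndarray | None = None
    case_label: str | None = field(default=None)

    def __post_init__(self) -> None:
        self.group = np.asarray(self.group, dtype=object)
        self.thickness = np.asarray(self.thickness, dtype=float)
        self.age = np.asarray(self.age, dtype=float)
        self.iq = np.asarray(self.iq, dtype=float)
        self.subject_ids = list(self.subject_ids)
        self.region_names = list(self.region_names)
        if self.adhd_index is not None:
            self.adhd_index = np.asarray(self.adhd_index, dtype=float)
        self._validate()
        if self.mean_thickness is None:
            self.mean_thickness = self.thickness.mean(axis=1)
        else:
            self.mean_thickness = np.asarray(self.mean_thickness, dtype=float)
        if self.case_label is None:
            self.case_label = self.group_levels[0]
        elif self.case_label not in self.group_levels:
            raise DataValidationError(
                f"case_label {self.case_label!r} not among group levels {self.group_levels}"
            )

    def _validate(self) -> None:
        n, p = self.thickness.shape
        if len(self.subject_ids) != n:
            raise DataValidationError("subject_ids length does not match thickness rows")
        if len(self.region_names) != p:
            raise DataValidationError("region_names length does not match thickness columns")
        if len(set(self.region_names)) != p:
            raise DataValidationError("region_names are not unique")
        if not np.all(np.isfinite(self.thickness)):
            raise DataValidationError("thickness contains missing or non-finite values")
        if np.any(self.thickness <= 0):
            raise DataValidationError("thickness values must be strictly positive (mm)")
        if len(self.group_levels) != 2:
            raise DataValidationError(
                f"exactly two group levels required, found {self.group_levels}"
            )
        for name, arr in [("age", self.age), ("iq", self.iq)]:
            if arr.shape != (n,):
                raise DataValidationError(f"covariate {name!r} has wrong length")

    # ------------------------------------------------------------------
    @property
    def n_subjects(self) -> int:
        return self.thickness.shape[0]

    @property
    def n_regions(self) -> int:
        return self.thickness.shape[1]

    @property
    def group_levels(self) -> list[str]:
        return sorted(set(self.group))

    @property
    def control_label(self) -> str:
        levels = self.group_levels
        return levels[1] if levels[0] == self.case_label else levels[0]

    def group_mask(self, label: str) -> np.ndarray:
        return self.group == label

    # ------------------------------------------------------------------
    def to_dataframe(self) -> pd.DataFrame:
        """Tidy table: metadata columns followed by one column per region."""
        df = pd.DataFrame(
            {
                "subject_id": self.subject_ids,
                "group": self.group,
                "age": self.age,
                "iq": self.iq,
                "adhd_index": (
                    self.adhd_index if self.adhd_index is not None else np.nan
                ),
            }
        )
        thick = pd.DataFrame(self.thickness, columns=self.region_names)
        return pd.concat([df, thick], axis=1)

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, case_label: str | None = None
    ) -> "ThicknessDataset":
        missing = [c for c in ("subject_id", "group", "age", "iq") if c not in df]
        if missing:
            raise DataValidationError(f"missing required columns: {missing}")
        regions = [c for c in df.columns if c not in META_COLUMNS]
        adhd = None
        if "adhd_index" in df and df["adhd_index"].notna().any():
            adhd = df["adhd_index"].to_numpy(dtype=float)
        return cls(
            subject_ids=[str(s) for s in df["subject_id"]],
            group=df["group"].to_numpy(dtype=object),
            thickness=df[regions].to_numpy(dtype=float),
            age=df["age"].to_numpy(dtype=float),
            iq=df["iq"].to_numpy(dtype=float),
            region_names=regions,
            adhd_index=adhd,
            case_label=case_label,
        )

    def to_csv(self, path) -> None:
        # %.17g guarantees float round-trip through the text format
        self.to_dataframe().to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def read_csv(cls, path, case_label: str | None = None) -> "ThicknessDataset":
        df = pd.read_csv(path, float_precision="round_trip")
        return cls.from_dataframe(df, case_label=case_label)
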