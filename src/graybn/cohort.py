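"""Cohort tables: reading, validation, demographics.

A cohort table holds one row per subject with a group label, sex, age, and
one mean gray-matter volume per region of interest (ROI).  The default ROI
set is the eight core default-mode-network regions (posterior cingulate,
medial prefrontal, bilateral hippocampus, inferior parietal and inferior
temporal cortices).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RoiSpec",
    "DEFAULT_ROIS",
    "DEFAULT_ROI_NAMES",
    "CohortTable",
    "read_cohort",
    "write_cohort",
    "summarize_demographics",
    "sex_ratio_chi_square",
]

REQUIRED_COLUMNS = ("subject_id", "group", "sex", "age")


@dataclass(frozen=True)
class RoiSpec:
    """One region of interest: display name, short code, and the integer
    label value(s) identifying it inside an atlas label image."""

    name: str
    abbreviation: str
    atlas_labels: tuple[int, ...]

    def __post_init__(self):
        object.__setattr__(self, "atlas_labels", tuple(int(v) for v in self.atlas_labels))
        if len(self.atlas_labels) == 0:
            raise ValueError(f"ROI {self.abbreviation!r}: at least one atlas label required")
        if any(v < 0 for v in self.atlas_labels):
            raise ValueError(f"ROI {self.abbreviation!r}: atlas labels must be >= 0")


#: The eight core DMN regions.  Atlas label values are placeholders bound to
#: whatever label image the masks come from; override via a ROI config.
DEFAULT_ROIS: tuple[RoiSpec, ...] = (
    RoiSpec("Posterior cingulate cortex", "PCC", (1,)),
    RoiSpec("Medial prefrontal cortex", "mPFC", (2,)),
    RoiSpec("Left hippocampus", "lHP", (3,)),
    RoiSpec("Right hippocampus", "rHP", (4,)),
    RoiSpec("Left inferior parietal cortex", "lIPC", (5,)),
    RoiSpec("Right inferior parietal cortex", "rIPC", (6,)),
    RoiSpec("Left inferior temporal cortex", "lITC", (7,)),
    RoiSpec("Right inferior temporal cortex", "rITC", (8,)),
)

DEFAULT_ROI_NAMES: tuple[str, ...] = tuple(r.abbreviation for r in DEFAULT_ROIS)

_abbrs = [r.abbreviation for r in DEFAULT_ROIS]
assert len(set(_abbrs)) == len(_abbrs)


class CohortTable:
    """Validated subjects-by-variables table.

    Wraps a DataFrame with columns ``subject_id, group, sex, age`` plus one
    numeric column per ROI; extra columns (e.g. MMSE/CDR) pass through
    untouched.  Row order is preserved.
    """

    def __init__(self, df: pd.DataFrame, roi_names: Sequence[str] | None = None):
        roi_names = tuple(roi_names) if roi_names is not None else DEFAULT_ROI_NAMES
        missing = [c for c in (*REQUIRED_COLUMNS, *roi_names) if c not in df.columns]
        if missing:
            raise ValueError(f"missing column(s): {missing}")
        df = df.reset_index(drop=True).copy()
        df["subject_id"] = df["subject_id"].astype(str)
        dup = df["subject_id"][df["subject_id"].duplicated()]
        if len(dup):
            raise ValueError(f"duplicate subject_id(s): {sorted(set(dup))}")
        for col in roi_names:
            vals = pd.to_numeric(df[col], errors="coerce")
            bad = df.loc[vals.isna() | ~np.isfinite(vals), "subject_id"]
            if len(bad):
                raise ValueError(
                    f"non-numeric or non-finite volume in column {col!r} "
                    f"for subject(s) {list(bad)}"
                )
            df[col] = vals.astype(float)
        df["age"] = pd.to_numeric(df["age"], errors="coerce")
        self.df = df
        self.roi_names = roi_names

    # -- accessors ---------------------------------------------------------

    def __len__(self) -> int:
        return len(self.df)

    @property
    def subject_ids(self) -> list[str]:
        return list(self.df["subject_id"])

    @property
    def groups(self) -> list[str]:
        """Distinct group labels in order of first appearance."""
        return list(dict.fromkeys(self.df["group"]))

    @property
    def volumes(self) -> np.ndarray:
        """(n, d) matrix of ROI volumes in ``roi_names`` order."""
        return self.df[list(self.roi_names)].to_numpy(dtype=float)

    def group_volumes(self, label: str) -> np.ndarray:
        sub = self.df[self.df["group"] == label]
        if len(sub) == 0:
            raise ValueError(f"no subjects in group {label!r}")
        return sub[list(self.roi_names)].to_numpy(dtype=float)

    def require_two_groups(self) -> tuple[str, str]:
        g = self.groups
        if len(g) != 2:
            raise ValueError(f"expected exactly two group labels, found {g}")
        return g[0], g[1]

    def drop_subject(self, subject_id: str) -> "CohortTable":
        sub = self.df[self.df["subject_id"] != subject_id]
        return CohortTable(sub, self.roi_names)

    def __eq__(self, other) -> bool:
        """Field-for-field equality, volumes compared at 1e-9 (float
        formatting tolerance for CSV round trips)."""
        if not (
            isinstance(other, CohortTable)
            and self.roi_names == other.roi_names
            and self.df.shape == other.df.shape
            and all(self.df.columns == other.df.columns)
        ):
            return False
        meta = [c for c in self.df.columns if c not in self.roi_names]
        return self.df[meta].equals(other.df[meta]) and np.allclose(
            self.volumes, other.volumes, rtol=0, atol=1e-9
        )


def read_cohort(path, roi_names: Sequence[str] | None = None) -> CohortTable:
    """Read and validate a cohort CSV (comma-separated, UTF-8, header row,
    '.' decimal).  Lines starting with '#' are ignored."""
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    return CohortTable(df, roi_names)


def write_cohort(table: CohortTable, path) -> None:
    """Write the cohort as CSV; ``read_cohort`` round-trips it exactly up to
    float formatting (full repr precision is used)."""
    table.df.to_csv(path, index=False, float_format=lambda v: format(v, ".17g"))


def summarize_demographics(table: CohortTable) -> pd.DataFrame:
    """Per-group n, female/male counts, and age mean +/- sample sd.

    The age sd uses the n-1 denominator; a single-subject group reports
    NaN sd (undefined by convention).
    """
    rows = {}
    for g in table.groups:
        sub = table.df[table.df["group"] == g]
        if len(sub) == 0:
            raise ValueError(f"empty group {g!r}")
        sex = sub["sex"].astype(str).str.upper().str[0]
        rows[g] = {
            "n": len(sub),
            "n_female": int((sex == "F").sum()),
            "n_male": int((sex == "M").sum()),
            "age_mean": float(sub["age"].mean()),
            "age_sd": float(sub["age"].std(ddof=1)),
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def sex_ratio_chi_square(counts) -> tuple[float, float]:
    """Pearson chi-square (df=1, no continuity correction) on a 2x2
    group-by-sex contingency table.

    Returns ``(statistic, p_value)``.  Raises if any margin is zero (the
    expected counts would be undefined) or any cell is negative.
    """
    c = np.asarray(counts, dtype=float)
    if c.shape != (2, 2):
        raise ValueError("counts must be a 2x2 table")
    if np.any(c < 0):
        raise ValueError("counts must be non-negative")
    if np.any(c.sum(axis=0) <= 0) or np.any(c.sum(axis=1) <= 0):
        raise ValueError("zero margin: expected counts undefined")
    res = stats.chi2_contingency(c, correction=False)
    return float(res.statistic), float(res.pvalue)
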