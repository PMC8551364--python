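"""Cohort metadata: sample → subject/group/arm/timepoint plus clinical indices.

The cohort design mirrors a two-arm longitudinal treatment study: healthy
controls (HC) sampled once at baseline, patients (RA) sampled at ordered
timepoints M0/M1/M3/M6 under one of two treatment arms (HQT or LEF, both on
top of methotrexate).  Clinical indices (ESR, CRP, RF, anti-CCP, AST,
DAS28-CRP and the joint/function scores) may be missing; missing cells stay
missing (NaN) and are never imputed to zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

GROUPS = ("HC", "RA")
ARMS = ("HQT", "LEF", "none")
TIMEPOINTS = ("M0", "M1", "M3", "M6")
#: months elapsed since baseline for each sampling visit
TIMEPOINT_MONTHS = {"M0": 0.0, "M1": 1.0, "M3": 3.0, "M6": 6.0}

#: clinical indices carried by the metadata table (units in docs/methods.md)
CLINICAL_INDICES = (
    "ESR", "CRP", "RF", "anti_CCP", "AST",
    "DAS28_CRP", "JSS", "JTS", "MS", "VAS_P", "VAS_D", "HAQ",
)

REQUIRED_COLUMNS = ("sample_id", "subject_id", "group", "arm", "timepoint")


class MetadataError(ValueError):
    """Raised for malformed or inconsistent cohort metadata."""


@dataclass
class Cohort:
    """Validated per-sample metadata table.

    ``df`` has one row per sample, indexed by sample_id, with subject_id,
    group, arm, timepoint and one column per clinical index.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df
        for col in REQUIRED_COLUMNS[1:]:
            if col not in df.columns:
                raise MetadataError(f"missing required column {col!r}")
        if df.index.has_duplicates:
            raise MetadataError("duplicate sample ids")
        for col, allowed in (("group", GROUPS), ("arm", ARMS), ("timepoint", TIMEPOINTS)):
            bad = set(df[col].unique()) - set(allowed)
            if bad:
                raise MetadataError(f"unknown {col} token(s): {sorted(bad)}")
        pairs = df[["subject_id", "timepoint"]]
        if pairs.duplicated().any():
            dup = pairs[pairs.duplicated()].iloc[0]
            raise MetadataError(
                f"duplicated (subject, timepoint) pair: ({dup['subject_id']}, {dup['timepoint']})"
            )
        hc = df[df["group"] == "HC"]
        if not (hc["arm"] == "none").all():
            raise MetadataError("HC samples must have arm='none'")
        if not (hc["timepoint"] == "M0").all():
            raise MetadataError("HC samples must be baseline (M0) only")
        for col in CLINICAL_INDICES:
            if col not in df.columns:
                df[col] = np.nan

    @property
    def sample_ids(self) -> list[str]:
        return list(self.df.index)

    def samples(self, group: str | None = None, arm: str | None = None,
                timepoint: str | None = None) -> list[str]:
        """Sample ids matching the given strata (None = no constraint)."""
        mask = pd.Series(True, index=self.df.index)
        if group is not None:
            mask &= self.df["group"] == group
        if arm is not None:
            mask &= self.df["arm"] == arm
        if timepoint is not None:
            mask &= self.df["timepoint"] == timepoint
        return list(self.df.index[mask])

    def baseline_samples(self) -> list[str]:
        """All baseline (M0) samples: the HC + untreated-RA comparison set."""
        return self.samples(timepoint="M0")

    def index_values(self, index: str, sample_ids=None) -> pd.Series:
        if index not in CLINICAL_INDICES:
            raise MetadataError(f"unknown clinical index {index!r}")
        s = self.df[index]
        if sample_ids is not None:
            s = s.loc[list(sample_ids)]
        return s

    def counts(self) -> pd.DataFrame:
        """Sample counts per (group, arm, timepoint), for validation summaries."""
        return (self.df.groupby(["group", "arm", "timepoint"], observed=True)
                .size().rename("n_samples").reset_index())
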