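"""Core tabular containers shared across the pipeline stages.

All containers are thin, validated wrappers around pandas objects. Probes/assays
are rows; lanes/samples are columns, matching the on-disk TSV dialect.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

PROBE_CLASSES = frozenset(
    {"endogenous", "positive_control", "negative_control", "spike_in"}
)

ASSAY_ROLES = frozenset({"target", "spike_in", "endogenous_reference"})

DIAGNOSES = frozenset({"AD", "MCI", "NC"})


class ValidationError(ValueError):
    """Raised when an input table violates a container invariant."""


@dataclass
class CountMatrix:
    """nCounter-style digital counts.

    Parameters
    ----------
    counts
        Non-negative counts, probes as rows, lanes as columns. Each lane is one
        cartridge position (one replicate of one sample).
    probe_class
        One of ``endogenous``, ``positive_control``, ``negative_control``,
        ``spike_in`` per probe.
    lanes
        Lane metadata indexed by lane id, with columns ``sample_id`` and
        ``replicate``. Triplicate lanes of a sample share ``sample_id``.
    """

    counts: pd.DataFrame
    probe_class: pd.Series
    lanes: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.counts.index.is_unique:
            dupes = self.counts.index[self.counts.index.duplicated()].unique()
            raise ValidationError(f"duplicate probe names: {list(dupes)}")
        if (self.counts.to_numpy() < 0).any():
            raise ValidationError("counts must be non-negative")
        unknown = set(self.probe_class.unique()) - PROBE_CLASSES
        if unknown:
            raise ValidationError(f"unknown probe_class token(s): {sorted(unknown)}")
        if not self.probe_class.index.equals(self.counts.index):
            self.probe_class = self.probe_class.reindex(self.counts.index)
            if self.probe_class.isna().any():
                missing = self.probe_class.index[self.probe_class.isna()]
                raise ValidationError(f"probes without probe_class: {list(missing)}")
        if not set(self.counts.columns) <= set(self.lanes.index):
            missing = sorted(set(self.counts.columns) - set(self.lanes.index))
            raise ValidationError(f"lanes without metadata: {missing}")
        self.lanes = self.lanes.loc[list(self.counts.columns)]

    @property
    def probes(self) -> pd.Index:
        return self.counts.index

    @property
    def lane_ids(self) -> pd.Index:
        return self.counts.columns

    def probes_of_class(self, cls: str) -> pd.Index:
        return self.counts.index[self.probe_class == cls]

    def copy(self) -> "CountMatrix":
        return CountMatrix(
            self.counts.copy(), self.probe_class.copy(), self.lanes.copy()
        )

    def sample_means(self, values: pd.DataFrame | None = None) -> pd.DataFrame:
        """Average replicate lanes into one column per sample."""
        values = self.counts if values is None else values
        return values.T.groupby(self.lanes["sample_id"]).mean().T


@dataclass
class CtMatrix:
    """TaqMan threshold-cycle values, assays as rows, samples as columns.

    Missing Ct (non-amplification) is NaN. ``assay_role`` flags the exogenous
    spike-in and the candidate endogenous reference assays.
    """

    ct: pd.DataFrame
    assay_role: pd.Series

    def __post_init__(self) -> None:
        if not self.ct.index.is_unique:
            raise ValidationError("duplicate assay names")
        vals = self.ct.to_numpy(dtype=float)
        finite = np.isfinite(vals)
        if (vals[finite] <= 0).any():
            raise ValidationError("non-missing Ct values must be finite and > 0")
        if np.isinf(vals).any():
            raise ValidationError("Ct values must be finite or NaN")
        unknown = set(self.assay_role.unique()) - ASSAY_ROLES
        if unknown:
            raise ValidationError(f"unknown assay role token(s): {sorted(unknown)}")
        if not self.assay_role.index.equals(self.ct.index):
            self.assay_role = self.assay_role.reindex(self.ct.index)
            if self.assay_role.isna().any():
                raise ValidationError("every assay needs a role flag")
        if not (self.assay_role == "spike_in").any():
            raise ValidationError("at least one spike-in reference assay is required")

    @property
    def assays(self) -> pd.Index:
        return self.ct.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.ct.columns

    def assays_of_role(self, role: str) -> pd.Index:
        return self.ct.index[self.assay_role == role]


@dataclass
class SampleSheet:
    """Sample metadata: id, cohort (1|2) and diagnosis (AD|MCI|NC)."""

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        required = {"sample_id", "cohort", "diagnosis"}
        if not required <= set(self.table.columns):
            raise ValidationError(f"sample sheet needs columns {sorted(required)}")
        if self.table["sample_id"].duplicated().any():
            dupes = self.table.loc[self.table["sample_id"].duplicated(), "sample_id"]
            raise ValidationError(f"duplicate sample ids: {list(dupes)}")
        bad = set(self.table["diagnosis"].unique()) - DIAGNOSES
        if bad:
            raise ValidationError(f"unknown diagnosis token(s): {sorted(bad)}")
        bad_cohort = set(self.table["cohort"].astype(int).unique()) - {1, 2}
        if bad_cohort:
            raise ValidationError(f"unknown cohort label(s): {sorted(bad_cohort)}")
        self.table = self.table.reset_index(drop=True)
        self.table["cohort"] = self.table["cohort"].astype(int)

    @property
    def sample_ids(self) -> pd.Index:
        return pd.Index(self.table["sample_id"])

    def subset(self, cohort: int | None = None, diagnoses=None) -> "SampleSheet":
        t = self.table
        if cohort is not None:
            t = t[t["cohort"] == cohort]
        if diagnoses is not None:
            t = t[t["diagnosis"].isin(set(diagnoses))]
        return SampleSheet(t.copy())

    def diagnosis_of(self, sample_ids) -> pd.Series:
        mapping = self.table.set_index("sample_id")["diagnosis"]
        missing = [s for s in sample_ids if s not in mapping.index]
        if missing:
            raise ValidationError(f"samples absent from sheet: {missing}")
        return mapping.loc[list(sample_ids)]

    def __len__(self) -> int:
        return len(self.table)
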