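"""Domain types, tabular IO and the paired-difference transforms.

The analysis operates on two cohort designs:

* a *repeated time point* cohort, where every subject contributes a
  baseline and a repeated (later, closer to diagnosis) sample.  Per
  subject the progression pattern is ``X_progress = X_repeated -
  X_baseline``, and per matched pair the disease-progression difference
  is ``d = X_progress(case) - X_progress(control)``;
* a *single time point* cohort, where each pair contributes one sample
  per subject and the case-control difference is ``d = X_case -
  X_control``.

Each matched pair carries two time coordinates, both in years: ``ttd``,
the time from collection of the case's repeated (or single) sample to
diagnosis, and ``tbs``, the time between the baseline and the repeated
sample.  These two coordinates span the plane the scan engine explores.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from smartscan.errors import MetadataError, PairingError, SchemaError

META_COLUMNS = (
    "sample_id",
    "subject_id",
    "pair_id",
    "group",
    "timepoint",
    "sampling_time",
    "diagnosis_time",
)

_GROUPS = {"case", "control"}
_TIMEPOINTS = {"baseline", "repeated", "single"}


@dataclass
class SampleTable:
    """A metabolite intensity matrix with per-sample metadata.

    Parameters
    ----------
    values : pandas.DataFrame
        Rows = samples (index: sample id), columns = variables.  Positive
        intensities in arbitrary units; missing values are rejected.
    meta : pandas.DataFrame
        One row per sample (same index), with columns ``subject_id``,
        ``pair_id``, ``group`` (case/control), ``timepoint``
        (baseline/repeated/single), ``sampling_time`` (years, float) and
        ``diagnosis_time`` (years; NaN for controls).
    """

    values: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    @property
    def variable_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return len(self.values)

    def validate(self) -> None:
        """Check all structural invariants; raise on the first violation."""
        cols = pd.Index(self.values.columns)
        if cols.has_duplicates:
            dupes = cols[cols.duplicated()].unique().tolist()
            raise SchemaError(f"duplicated variable names: {dupes}")
        missing_cols = [c for c in META_COLUMNS if c != "sample_id" and c not in self.meta.columns]
        if missing_cols:
            raise SchemaError(f"metadata missing required column(s): {missing_cols}")
        if not self.values.index.equals(self.meta.index):
            raise SchemaError("values and metadata rows do not match by sample id")
        if self.values.isna().any().any():
            bad = self.values.columns[self.values.isna().any()].tolist()
            raise SchemaError(f"missing values in variables {bad}; only complete variables are analyzed")
        bad_group = set(self.meta["group"]) - _GROUPS
        if bad_group:
            raise SchemaError(f"unknown group label(s): {sorted(bad_group)}")
        bad_tp = set(self.meta["timepoint"]) - _TIMEPOINTS
        if bad_tp:
            raise SchemaError(f"unknown timepoint label(s): {sorted(bad_tp)}")
        # each pair: exactly one case subject and one control subject
        for pair_id, grp in self.meta.groupby("pair_id"):
            roles = grp.groupby("subject_id")["group"].agg(lambda s: s.iloc[0])
            n_case = int((roles == "case").sum())
            n_ctrl = int((roles == "control").sum())
            if n_case != 1 or n_ctrl != 1:
                raise PairingError(
                    f"pair {pair_id!r} must have exactly one case and one control subject "
                    f"(found {n_case} case, {n_ctrl} control)"
                )

    def write(self, values_path: str | Path, meta_path: str | Path, sep: str = "\t") -> None:
        """Write the two-file representation (values matrix + metadata)."""
        self.values.to_csv(values_path, sep=sep, index_label="sample_id")
        self.meta.to_csv(meta_path, sep=sep, index_label="sample_id")


@dataclass
class PairedObservation:
    """One matched case-control pair reduced to a difference vector.

    ``d`` holds one entry per variable; ``tbs`` is None for single
    time point cohorts.
    """

    pair_id: str
    ttd: float
    tbs: float | None
    d: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        if not self.ttd > 0:
            raise MetadataError(f"pair {self.pair_id!r}: time to diagnosis must be > 0, got {self.ttd}")
        if self.tbs is not None and not self.tbs > 0:
            raise MetadataError(f"pair {self.pair_id!r}: time between samples must be > 0, got {self.tbs}")


@dataclass
class PairedCohort:
    """A set of paired difference observations sharing a variable order."""

    observations: list[PairedObservation]
    variable_ids: list[str]

    def __post_init__(self) -> None:
        p = len(self.variable_ids)
        for obs in self.observations:
            if obs.d.shape != (p,):
                raise SchemaError(
                    f"pair {obs.pair_id!r}: difference vector has {obs.d.shape[0]} entries, expected {p}"
                )

    def __len__(self) -> int:
        return len(self.observations)

    @property
    def pair_ids(self) -> list[str]:
        return [o.pair_id for o in self.observations]

    @property
    def d_matrix(self) -> np.ndarray:
        """Pairs-by-variables difference matrix."""
        return np.vstack([o.d for o in self.observations])

    @property
    def ttd(self) -> np.ndarray:
        return np.array([o.ttd for o in self.observations])

    @property
    def tbs(self) -> np.ndarray:
        return np.array([np.nan if o.tbs is None else o.tbs for o in self.observations])

    @property
    def coords(self) -> np.ndarray:
        """(n, 2) array of (ttd, tbs) scan coordinates."""
        return np.column_stack([self.ttd, self.tbs])

    def subset(self, pair_ids: Sequence[str]) -> "PairedCohort":
        wanted = set(pair_ids)
        obs = [o for o in self.observations if o.pair_id in wanted]
        return PairedCohort(observations=obs, variable_ids=self.variable_ids)

    def to_frame(self) -> pd.DataFrame:
        """Difference matrix as a DataFrame with ttd/tbs columns prepended."""
        df = pd.DataFrame(self.d_matrix, index=self.pair_ids, columns=self.variable_ids)
        df.insert(0, "tbs", self.tbs)
        df.insert(0, "ttd", self.ttd)
        df.index.name = "pair_id"
        return df


def _detect_sep(path: str | Path) -> str:
    with open(path) as fh:
        first = fh.readline()
    return "\t" if "\t" in first else ","


def load_cohort(values_path: str | Path, meta_path: str | Path) -> SampleTable:
    """Read the two-file cohort representation.

    The values file holds the numeric matrix (first column = sample id,
    header = variable ids); the metadata file holds the sample
    annotations.  TSV is the default; comma-delimited files are detected
    from the header line.
    """
    values = pd.read_csv(values_path, sep=_detect_sep(values_path), index_col=0)
    meta = pd.read_csv(meta_path, sep=_detect_sep(meta_path), index_col=0)
    missing = [c for c in META_COLUMNS if c != "sample_id" and c not in meta.columns]
    if missing:
        raise SchemaError(f"metadata file missing required column(s): {missing}")
    meta = meta.loc[:, [c for c in META_COLUMNS if c != "sample_id"]]
    meta["sampling_time"] = pd.to_numeric(meta["sampling_time"], errors="raise").astype(float)
    meta["diagnosis_time"] = pd.to_numeric(meta["diagnosis_time"], errors="coerce").astype(float)
    if not values.index.equals(meta.index):
        if set(values.index) == set(meta.index):
            meta = meta.loc[values.index]
        else:
            raise SchemaError("sample ids differ between values and metadata files")
    return SampleTable(values=values, meta=meta)


def progression(table: SampleTable) -> pd.DataFrame:
    """Per-subject progression: repeated minus baseline intensity.

    Returns a subjects-by-variables DataFrame.  Every subject must have
    exactly one baseline and one repeated sample.
    """
    rows: dict[str, np.ndarray] = {}
    for subject_id, grp in table.meta.groupby("subject_id", sort=False):
        tp = grp["timepoint"]
        base = grp.index[tp == "baseline"]
        rep = grp.index[tp == "repeated"]
        if len(base) != 1 or len(rep) != 1:
            raise PairingError(
                f"subject {subject_id!r} needs exactly one baseline and one repeated sample "
                f"(found {len(base)} baseline, {len(rep)} repeated)"
            )
        rows[subject_id] = table.values.loc[rep[0]].to_numpy() - table.values.loc[base[0]].to_numpy()
    out = pd.DataFrame.from_dict(rows, orient="index", columns=table.variable_ids)
    out.index.name = "subject_id"
    return out


def _pair_members(table: SampleTable, pair_id: str) -> tuple[str, str]:
    """Return (case_subject, control_subject) for a pair."""
    grp = table.meta[table.meta["pair_id"] == pair_id]
    case = grp.loc[grp["group"] == "case", "subject_id"].unique()
    ctrl = grp.loc[grp["group"] == "control", "subject_id"].unique()
    if len(case) != 1 or len(ctrl) != 1:
        raise PairingError(f"pair {pair_id!r} does not have exactly one case and one control subject")
    return str(case[0]), str(ctrl[0])


def disease_progress(table: SampleTable) -> PairedCohort:
    """Case-minus-control progression differences with scan coordinates.

    For each matched pair, ``d = progression(case) - progression(control)``.
    ``ttd`` is anchored to the case's repeated sample (time from its
    collection to diagnosis) and ``tbs`` is the case's baseline-to-repeated
    interval.
    """
    prog = progression(table)
    observations = []
    for pair_id in table.meta["pair_id"].unique():
        case_subj, ctrl_subj = _pair_members(table, pair_id)
        d = prog.loc[case_subj].to_numpy() - prog.loc[ctrl_subj].to_numpy()
        case_meta = table.meta[(table.meta["subject_id"] == case_subj)]
        rep = case_meta[case_meta["timepoint"] == "repeated"].iloc[0]
        base = case_meta[case_meta["timepoint"] == "baseline"].iloc[0]
        if pd.isna(rep["diagnosis_time"]):
            raise MetadataError(f"case subject {case_subj!r} (pair {pair_id!r}) lacks diagnosis_time")
        ttd = float(rep["diagnosis_time"]) - float(rep["sampling_time"])
        tbs = float(rep["sampling_time"]) - float(base["sampling_time"])
        observations.append(PairedObservation(pair_id=str(pair_id), ttd=ttd, tbs=tbs, d=d))
    return PairedCohort(observations=observations, variable_ids=table.variable_ids)


def case_control_difference(table: SampleTable) -> PairedCohort:
    """Case minus control differences for a single time point cohort."""
    observations = []
    for pair_id in table.meta["pair_id"].unique():
        case_subj, ctrl_subj = _pair_members(table, pair_id)
        sub = table.meta[table.meta["pair_id"] == pair_id]
        case_rows = sub.index[sub["subject_id"] == case_subj]
        ctrl_rows = sub.index[sub["subject_id"] == ctrl_subj]
        if len(case_rows) != 1 or len(ctrl_rows) != 1:
            raise PairingError(
                f"pair {pair_id!r}: single time point cohort needs one sample per subject"
            )
        d = table.values.loc[case_rows[0]].to_numpy() - table.values.loc[ctrl_rows[0]].to_numpy()
        case_meta = table.meta.loc[case_rows[0]]
        if pd.isna(case_meta["diagnosis_time"]):
            raise MetadataError(f"case subject {case_subj!r} (pair {pair_id!r}) lacks diagnosis_time")
        ttd = float(case_meta["diagnosis_time"]) - float(case_meta["sampling_time"])
        observations.append(PairedObservation(pair_id=str(pair_id), ttd=ttd, tbs=None, d=d))
    return PairedCohort(observations=observations, variable_ids=table.variable_ids)
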