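"""Long-format longitudinal height data: reading, validation, filtering.

One row per measurement: subject id, sex, decimal age (years), height (cm).
``LongitudinalDataset`` is the exchange object between every pipeline
stage; it guarantees per-subject age ordering, unique (subject, age)
pairs and a single sex per subject.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "AGE_RANGE",
    "HEIGHT_RANGE",
    "AgeSegmentation",
    "DatasetSummary",
    "LongitudinalDataset",
    "DEFAULT_SEGMENT_BOUNDARIES",
    "ValidationIssue",
    "ValidationReport",
    "filter_age_segments",
    "read_long_table",
    "summarize_dataset",
    "write_long_table",
]

AGE_RANGE = (0.0, 25.0)       # [lo, hi) decimal years
HEIGHT_RANGE = (50.0, 230.0)  # (lo, hi) cm

#: Five pubertal age segments used for the cohort inclusion rule:
#: 7 to <8.8, 8.8 to <10.6, 10.6 to <12.4, 12.4 to <14.2, 14.2 to <16 years.
DEFAULT_SEGMENT_BOUNDARIES = (7.0, 8.8, 10.6, 12.4, 14.2, 16.0)

_SEX_ALIASES = {
    "m": "male", "male": "male", "boy": "male", "b": "male", "1": "male",
    "f": "female", "female": "female", "girl": "female", "g": "female", "2": "female",
}

_COLUMNS = ("subject_id", "sex", "age", "height")


@dataclass(frozen=True)
class ValidationIssue:
    row: int            # 1-based data row number (header excluded)
    subject_id: str
    message: str

    def __str__(self) -> str:
        return f"row {self.row}\tsubject {self.subject_id or '?'}\t{self.message}"


@dataclass
class ValidationReport:
    """Machine-readable record of rows rejected (or repaired) during reading."""

    issues: list[ValidationIssue] = field(default_factory=list)

    def add(self, row: int, subject_id: str, message: str) -> None:
        self.issues.append(ValidationIssue(row, subject_id, message))

    def __len__(self) -> int:
        return len(self.issues)

    def to_text(self) -> str:
        return "\n".join(str(i) for i in self.issues)


@dataclass(frozen=True)
class AgeSegmentation:
    """Ordered boundaries defining half-open age intervals [b_k, b_{k+1})."""

    boundaries: tuple[float, ...] = DEFAULT_SEGMENT_BOUNDARIES

    def __post_init__(self):
        b = tuple(float(x) for x in self.boundaries)
        if len(b) < 2:
            raise ValueError("need at least two boundaries")
        if any(y <= x for x, y in zip(b, b[1:])):
            raise ValueError("boundaries must be strictly increasing")
        object.__setattr__(self, "boundaries", b)

    @property
    def intervals(self) -> list[tuple[float, float]]:
        b = self.boundaries
        return list(zip(b[:-1], b[1:]))

    def segment_of(self, age: float) -> int | None:
        """Index of the half-open interval containing ``age``, else None."""
        b = self.boundaries
        if age < b[0] or age >= b[-1]:
            return None
        return int(np.searchsorted(b, age, side="right") - 1)


class LongitudinalDataset:
    """Validated long-format height measurements.

    Wraps a DataFrame with columns ``subject_id`` (str), ``sex``
    ({'male','female'}), ``age`` (years), ``height`` (cm), sorted by
    subject then age, with unique (subject, age) pairs.
    """

    def __init__(self, df: pd.DataFrame, provenance: str = ""):
        missing = [c for c in _COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"missing columns: {missing}")
        df = df.loc[:, list(_COLUMNS)].copy()
        df["subject_id"] = df["subject_id"].astype(str)
        df["sex"] = df["sex"].astype(str)
        df["age"] = df["age"].astype(float)
        df["height"] = df["height"].astype(float)
        bad_sex = ~df["sex"].isin(["male", "female"])
        if bad_sex.any():
            raise ValueError(f"invalid sex values: {sorted(df.loc[bad_sex, 'sex'].unique())}")
        if df.duplicated(["subject_id", "age"]).any():
            raise ValueError("duplicate (subject_id, age) pairs")
        nsex = df.groupby("subject_id")["sex"].nunique()
        if (nsex > 1).any():
            raise ValueError(f"subjects with conflicting sex: {list(nsex[nsex > 1].index)}")
        self._df = df.sort_values(["subject_id", "age"], kind="mergesort").reset_index(drop=True)
        self.provenance = provenance

    # -- accessors ----------------------------------------------------
    @property
    def df(self) -> pd.DataFrame:
        return self._df.copy()

    @property
    def n_subjects(self) -> int:
        return self._df["subject_id"].nunique()

    @property
    def n_measurements(self) -> int:
        return len(self._df)

    @property
    def subject_ids(self) -> list[str]:
        return list(dict.fromkeys(self._df["subject_id"]))

    def subject(self, subject_id: str) -> pd.DataFrame:
        return self._df[self._df["subject_id"] == str(subject_id)].copy()

    def subset(self, subject_ids) -> "LongitudinalDataset":
        keep = set(map(str, subject_ids))
        return LongitudinalDataset(
            self._df[self._df["subject_id"].isin(keep)], provenance=self.provenance
        )

    def __eq__(self, other) -> bool:
        return isinstance(other, LongitudinalDataset) and self._df.equals(other._df)

    def __repr__(self) -> str:
        return (
            f"LongitudinalDataset({self.n_subjects} subjects, "
            f"{self.n_measurements} measurements)"
        )


def read_long_table(
    path, column_map: dict | None = None
) -> tuple[LongitudinalDataset, ValidationReport]:
    """Read a comma-separated long-format table with per-row validation.

    ``column_map`` maps canonical names (subject_id, sex, age, height) to
    the file's column names.  Rows violating measurement invariants are
    rejected and recorded in the returned :class:`ValidationReport`;
    reading fails only if a mapped column is absent or no valid row
    remains.
    """
    colmap = dict(zip(_COLUMNS, _COLUMNS))
    if column_map:
        colmap.update({k: v for k, v in column_map.items() if k in _COLUMNS})

    raw = pd.read_csv(path, dtype=str, skipinitialspace=True)
    missing = [v for v in colmap.values() if v not in raw.columns]
    if missing:
        raise ValueError(f"missing column(s) in {path}: {missing}")

    report = ValidationReport()
    rows = []
    sex_of: dict[str, str] = {}
    seen: set[tuple[str, float]] = set()
    for idx, rec in enumerate(raw.itertuples(index=False), start=1):
        rec = dict(zip(raw.columns, rec))
        sid = str(rec[colmap["subject_id"]]).strip() if pd.notna(rec[colmap["subject_id"]]) else ""
        if not sid:
            report.add(idx, "", "empty subject id")
            continue
        sex_raw = str(rec[colmap["sex"]]).strip().lower() if pd.notna(rec[colmap["sex"]]) else ""
        sex = _SEX_ALIASES.get(sex_raw)
        if sex is None:
            report.add(idx, sid, f"unrecognized sex {sex_raw!r}")
            continue
        try:
            age = float(rec[colmap["age"]])
            height = float(rec[colmap["height"]])
        except (TypeError, ValueError):
            report.add(idx, sid, "unparseable age or height")
            continue
        if not (AGE_RANGE[0] <= age < AGE_RANGE[1]):
            report.add(idx, sid, f"age {age} outside [{AGE_RANGE[0]}, {AGE_RANGE[1]})")
            continue
        if not (HEIGHT_RANGE[0] < height < HEIGHT_RANGE[1]):
            report.add(idx, sid, f"height {height} outside ({HEIGHT_RANGE[0]}, {HEIGHT_RANGE[1]})")
            continue
        if sid in sex_of and sex_of[sid] != sex:
            report.add(idx, sid, f"sex {sex!r} conflicts with earlier {sex_of[sid]!r}; row dropped")
            continue
        if (sid, age) in seen:
            report.add(idx, sid, f"duplicate (subject, age={age}); first occurrence kept")
            continue
        sex_of[sid] = sex
        seen.add((sid, age))
        rows.append((sid, sex, age, height))

    if not rows:
        raise ValueError(f"no valid rows in {path} ({len(report)} rejected)")
    df = pd.DataFrame(rows, columns=list(_COLUMNS))
    name = getattr(path, "name", str(path)) if not isinstance(path, io.IOBase) else "<stream>"
    return LongitudinalDataset(df, provenance=f"read from {name}"), report


def write_long_table(data: LongitudinalDataset, path, column_map: dict | None = None) -> None:
    """Write the dataset as a UTF-8 comma-separated table with a header row."""
    df = data.df
    if column_map:
        df = df.rename(columns={k: v for k, v in column_map.items() if k in _COLUMNS})
    df.to_csv(path, index=False)


def filter_age_segments(data: LongitudinalDataset, seg: AgeSegmentation | None = None) -> LongitudinalDataset:
    """Keep subjects having at least one measurement in every age segment.

    All measurements of retained subjects are kept, including any outside
    the segmentation span.  Idempotent; never invents rows.
    """
    seg = seg or AgeSegmentation()
    df = data._df
    if df.empty:
        return LongitudinalDataset(df, provenance=data.provenance)
    b = np.asarray(seg.boundaries)
    k = len(b) - 1
    in_span = (df["age"].values >= b[0]) & (df["age"].values < b[-1])
    seg_idx = np.searchsorted(b, df["age"].values, side="right") - 1
    cover = (
        pd.DataFrame({"subject_id": df["subject_id"].values[in_span], "seg": seg_idx[in_span]})
        .groupby("subject_id")["seg"]
        .nunique()
    )
    keep = cover[cover == k].index
    out = df[df["subject_id"].isin(keep)]
    return LongitudinalDataset(out, provenance=data.provenance)


@dataclass(frozen=True)
class DatasetSummary:
    n_subjects: int
    n_measurements: int
    n_subjects_by_sex: dict
    n_measurements_by_sex: dict
    mean_measurements_per_subject: float  # NaN when the dataset is empty

    def __str__(self) -> str:
        mean = (
            "NA"
            if np.isnan(self.mean_measurements_per_subject)
            else f"{self.mean_measurements_per_subject:.1f}"
        )
        return (
            f"{self.n_subjects} subjects, {self.n_measurements} measurements "
            f"(boys {self.n_subjects_by_sex.get('male', 0)}, "
            f"girls {self.n_subjects_by_sex.get('female', 0)}); "
            f"mean {mean} measurements/subject"
        )


def summarize_dataset(data: LongitudinalDataset) -> DatasetSummary:
    df = data._df
    n_subj = data.n_subjects
    mean = float("nan") if n_subj == 0 else len(df) / n_subj
    return DatasetSummary(
        n_subjects=n_subj,
        n_measurements=len(df),
        n_subjects_by_sex=df.groupby("sex")["subject_id"].nunique().to_dict(),
        n_measurements_by_sex=df.groupby("sex").size().to_dict(),
        mean_measurements_per_subject=mean if n_subj == 0 else round(mean, 1),
    )
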