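"""Domain types, cohort I/O, design encoding and descriptive summaries.

A cohort is a flat table of subject-level survival records: follow-up time
in months, an integer event code (0 = right-censored, 1..K = cause of
death), and the prognostic covariates used throughout the package — sex,
age at diagnosis (years), body mass index (kg/m²) and AJCC tumour stage
(I–IV).  Two causes of death are the default (1 = colorectal cancer,
2 = other causes) but every operation is generic in K.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

SEX_LEVELS = ("man", "woman")
STAGE_LEVELS = ("I", "II", "III", "IV")

#: Column order of the regression design row.  Reference subject: man, stage I.
DESIGN_COLUMNS = (
    "intercept",
    "bmi",
    "age",
    "sex_woman",
    "stage_II",
    "stage_III",
    "stage_IV",
)

#: Default CSV column roles; a column map overrides source header names.
DEFAULT_COLUMNS = ("time", "event", "sex", "age", "bmi", "stage")


class CohortParseError(ValueError):
    """Raised when a cohort file or row violates the record invariants."""


@dataclass(frozen=True)
class SubjectRecord:
    """One subject's follow-up time, observed event cause and covariates.

    Parameters
    ----------
    time : float
        Follow-up time in months; strictly positive and finite.
    event : int
        0 if right-censored, otherwise the cause index (1..K).
    sex : str
        ``"man"`` or ``"woman"``.
    age : float
        Age at diagnosis, years.
    bmi : float
        Body mass index, kg/m²; strictly positive.
    stage : str
        AJCC stage, one of ``"I"``, ``"II"``, ``"III"``, ``"IV"``.
    """

    time: float
    event: int
    sex: str
    age: float
    bmi: float
    stage: str

    def __post_init__(self) -> None:
        if not (np.isfinite(self.time) and self.time > 0):
            raise CohortParseError(f"time must be positive and finite, got {self.time}")
        if int(self.event) != self.event or self.event < 0:
            raise CohortParseError(f"event must be a nonnegative integer, got {self.event}")
        if self.sex not in SEX_LEVELS:
            raise CohortParseError(f"sex must be one of {SEX_LEVELS}, got {self.sex!r}")
        if self.stage not in STAGE_LEVELS:
            raise CohortParseError(f"stage must be one of {STAGE_LEVELS}, got {self.stage!r}")
        if not (np.isfinite(self.bmi) and self.bmi > 0):
            raise CohortParseError(f"bmi must be positive, got {self.bmi}")
        if not np.isfinite(self.age):
            raise CohortParseError(f"age must be finite, got {self.age}")


@dataclass
class Dataset:
    """An ordered cohort of :class:`SubjectRecord` with a declared cause count K."""

    records: list[SubjectRecord]
    n_causes: int = 2

    def __post_init__(self) -> None:
        if self.n_causes < 1:
            raise ValueError("n_causes must be >= 1")
        for i, r in enumerate(self.records):
            if r.event > self.n_causes:
                raise ValueError(
                    f"record {i}: event code {r.event} exceeds n_causes={self.n_causes}"
                )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def times(self) -> np.ndarray:
        return np.array([r.time for r in self.records], dtype=float)

    @property
    def events(self) -> np.ndarray:
        return np.array([r.event for r in self.records], dtype=int)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.times,
                "event": self.events,
                "sex": [r.sex for r in self.records],
                "age": [r.age for r in self.records],
                "bmi": [r.bmi for r in self.records],
                "stage": [r.stage for r in self.records],
            }
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, n_causes: int | None = None) -> "Dataset":
        records = []
        for i, row in enumerate(df.itertuples(index=False)):
            try:
                records.append(
                    SubjectRecord(
                        time=float(row.time),
                        event=_parse_event(row.event),
                        sex=str(row.sex),
                        age=float(row.age),
                        bmi=float(row.bmi),
                        stage=str(row.stage),
                    )
                )
            except (CohortParseError, ValueError, TypeError) as exc:
                raise CohortParseError(f"row {i}: {exc}") from exc
        if not records:
            raise CohortParseError("empty dataset")
        if n_causes is None:
            n_causes = max((r.event for r in records), default=0) or 1
        return cls(records=records, n_causes=n_causes)


def _parse_event(value) -> int:
    f = float(value)
    if f != int(f):
        raise CohortParseError(f"event code must be an integer, got {value!r}")
    return int(f)


def read_cohort(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    delimiter: str = ",",
    n_causes: int | None = None,
) -> Dataset:
    """Read a cohort CSV into a :class:`Dataset`.

    ``column_map`` maps roles (``time``, ``event``, ``sex``, ``age``, ``bmi``,
    ``stage``) to source header names; by default the roles are the headers.
    K is inferred as the maximum event code unless ``n_causes`` is given.
    Missing values and invariant violations are rejected with the offending
    row number — no imputation is attempted.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=delimiter, dtype={"stage": str, "sex": str})
    mapping = {role: role for role in DEFAULT_COLUMNS}
    if column_map:
        mapping.update(column_map)
    missing = [src for src in mapping.values() if src not in df.columns]
    if missing:
        raise CohortParseError(f"missing required column(s): {', '.join(missing)}")
    df = df.rename(columns={src: role for role, src in mapping.items()})
    df = df[list(DEFAULT_COLUMNS)]
    if df.isna().any().any():
        bad = int(df.index[df.isna().any(axis=1)][0])
        raise CohortParseError(f"row {bad}: missing value")
    if len(df) == 0:
        raise CohortParseError("empty dataset")
    return Dataset.from_dataframe(df, n_causes=n_causes)


def write_cohort(dataset: Dataset, path: str | Path, delimiter: str = ",") -> None:
    """Write a cohort back to CSV in the dialect :func:`read_cohort` reads."""
    dataset.to_dataframe().to_csv(path, sep=delimiter, index=False)


def encode_design(record: SubjectRecord) -> np.ndarray:
    """Encode one record as the 7-column design row.

    Order: intercept, bmi, age, sex_woman, stage_II, stage_III, stage_IV.
    Age and BMI enter untransformed so coefficients are per-year and
    per-kg/m²; reference levels are man and stage I.
    """
    row = np.zeros(len(DESIGN_COLUMNS))
    row[0] = 1.0
    row[1] = record.bmi
    row[2] = record.age
    row[3] = 1.0 if record.sex == "woman" else 0.0
    if record.stage != "I":
        row[3 + STAGE_LEVELS.index(record.stage)] = 1.0
    return row


def design_matrix(dataset: Dataset) -> np.ndarray:
    """Stack :func:`encode_design` over the cohort, shape (n, 7)."""
    return np.array([encode_design(r) for r in dataset.records])


def summarize(dataset: Dataset) -> dict:
    """Cohort descriptives: category counts/percentages with per-category
    cause-specific death counts, mean/sd of continuous covariates, and
    mean/sd/median/quartiles of follow-up time.

    Subgroup "mean survival" is the naive mean of observed (possibly
    censored) follow-up times, labelled as such.  Percentages are reported
    to full precision; renderers round to one decimal.
    """
    if len(dataset) == 0:
        raise ValueError("empty dataset")
    df = dataset.to_dataframe()
    n = len(df)
    K = dataset.n_causes

    def _group_block(level_values: Sequence[str], column: str) -> dict:
        block = {}
        for level in level_values:
            sub = df[df[column] == level]
            entry = {
                "n": int(len(sub)),
                "pct": 100.0 * len(sub) / n,
                "deaths_by_cause": {
                    j: int((sub["event"] == j).sum()) for j in range(1, K + 1)
                },
                "mean_observed_time": float(sub["time"].mean()) if len(sub) else float("nan"),
                "se_observed_time": (
                    float(sub["time"].std(ddof=1) / np.sqrt(len(sub)))
                    if len(sub) > 1
                    else float("nan")
                ),
            }
            block[level] = entry
        return block

    deaths = {j: int((df["event"] == j).sum()) for j in range(1, K + 1)}
    summary = {
        "n": n,
        "n_causes": K,
        "deaths_by_cause": deaths,
        "death_pct_by_cause": {j: 100.0 * deaths[j] / n for j in deaths},
        "censored": int((df["event"] == 0).sum()),
        "censored_pct": 100.0 * (df["event"] == 0).sum() / n,
        "by_sex": _group_block(SEX_LEVELS, "sex"),
        "by_stage": _group_block(STAGE_LEVELS, "stage"),
        "age": {"mean": float(df["age"].mean()), "sd": float(df["age"].std(ddof=1))},
        "bmi": {"mean": float(df["bmi"].mean()), "sd": float(df["bmi"].std(ddof=1))},
        "followup_months": {
            "mean": float(df["time"].mean()),
            "sd": float(df["time"].std(ddof=1)),
            "median": float(df["time"].median()),
            "p25": float(df["time"].quantile(0.25)),
            "p75": float(df["time"].quantile(0.75)),
        },
    }
    return summary


def summary_to_json(summary: dict) -> str:
    return json.dumps(summary, indent=2)


def summary_to_tsv(summary: dict) -> str:
    """Render the summary as a descriptive-table TSV (one decimal for
    percentages, two for means)."""
    K = summary["n_causes"]
    death_cols = "\t".join(f"deaths cause {j}" for j in range(1, K + 1))
    lines = [f"Covariate\tNumber (%)\t{death_cols}\tMean observed time (se)"]

    def _fmt(entry: dict) -> str:
        deaths = "\t".join(str(entry["deaths_by_cause"][j]) for j in range(1, K + 1))
        return (
            f"{entry['n']}({entry['pct']:.1f})\t{deaths}\t"
            f"{entry['mean_observed_time']:.2f}({entry['se_observed_time']:.2f})"
        )

    lines.append("Sex")
    for level in SEX_LEVELS:
        lines.append(f"{level.capitalize()}\t{_fmt(summary['by_sex'][level])}")
    lines.append("Stage")
    for level in STAGE_LEVELS:
        lines.append(f"Stage {level}\t{_fmt(summary['by_stage'][level])}")
    return "\n".join(lines) + "\n"
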