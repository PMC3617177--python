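"""Long-format experience-sampling (ESM) data: reading, validation, lagging.

ESM studies signal participants several times per day ("beeps") and collect
momentary self-reports on a fixed set of items. The dynamic models in this
package regress each beep on the immediately preceding beep of the *same*
day, so the central data-preparation step is turning the long table into a
lagged design while respecting day boundaries (no overnight lags) and
missingness (no bridging of skipped beeps, casewise deletion of partially
answered pairs).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ESMSchema",
    "ESMDataset",
    "LaggedDesign",
    "ReductionReport",
    "IntervalStats",
    "ESMValidationError",
    "read_esm_csv",
    "build_lagged_design",
    "interval_stats",
]

#: canonical column names used internally
PERSON, DAY, BEEP, TIME, PERIOD = "person", "day", "beep", "time", "period"
THERAPY, NEUROTICISM = "therapy", "neuroticism"


class ESMValidationError(ValueError):
    """Raised when an ESM table violates its declared schema."""


@dataclass
class ESMSchema:
    """Column mapping and scale declaration for a long-format ESM file.

    Parameters
    ----------
    variables
        Names of the J observed items (columns in the file).
    scale
        Inclusive (low, high) bounds of the response scale, e.g. ``(1, 7)``
        for a 7-point Likert scale or ``(0, 100)`` for a visual-analogue one.
    person, day, beep
        Column names for the person id, day index (>= 1) and within-day beep
        index (>= 1).
    time
        Optional column with clock time in decimal hours.
    period
        Optional 0/1 column separating baseline from post-baseline blocks;
        absent means a single period coded 0.
    therapy, neuroticism
        Optional person-level covariate columns (treatment indicator and
        neuroticism sum score).
    """

    variables: list[str]
    scale: tuple[float, float]
    person: str = PERSON
    day: str = DAY
    beep: str = BEEP
    time: str | None = None
    period: str | None = None
    therapy: str | None = None
    neuroticism: str | None = None
    na_values: Sequence[str] = ("", "NA", "NaN", "nan", ".", "-999")

    def __post_init__(self) -> None:
        if len(self.variables) < 1:
            raise ESMValidationError("schema must declare at least one variable")
        lo, hi = self.scale
        if not lo < hi:
            raise ESMValidationError(f"scale bounds must satisfy low < high, got {self.scale}")
        self.scale = (float(lo), float(hi))

    @classmethod
    def from_file(cls, path: str | Path) -> "ESMSchema":
        """Load a schema from a YAML or JSON config file."""
        path = Path(path)
        text = path.read_text()
        raw = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        raw["scale"] = tuple(raw["scale"])
        return cls(**raw)


@dataclass
class ESMDataset:
    """Validated long-format ESM observations.

    ``data`` uses canonical columns: person, day, beep, [time], period,
    the J variables, and optional person-level covariates therapy /
    neuroticism. One row per *answered* beep; item-level missingness is
    allowed (NaN), skipped beeps are simply absent rows.
    """

    data: pd.DataFrame
    variables: list[str]
    scale: tuple[float, float]

    def __post_init__(self) -> None:
        self.validate()

    # -- validation ---------------------------------------------------
    def validate(self) -> None:
        df = self.data
        required = [PERSON, DAY, BEEP, PERIOD] + list(self.variables)
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ESMValidationError(f"missing canonical columns: {missing}")
        dup = df.duplicated(subset=[PERSON, DAY, BEEP])
        if dup.any():
            rows = df.loc[dup, [PERSON, DAY, BEEP]].head(5).to_dict("records")
            raise ESMValidationError(
                f"duplicate (person, day, beep) triples, e.g. {rows}"
            )
        for col in (DAY, BEEP):
            if (df[col] < 1).any():
                bad = df.index[df[col] < 1][0]
                raise ESMValidationError(f"{col} index < 1 at row {bad}")
        lo, hi = self.scale
        vals = df[list(self.variables)]
        out = (vals < lo) | (vals > hi)
        if out.any().any():
            r = np.where(out.to_numpy())[0][0]
            row = df.iloc[r]
            badvar = out.columns[out.iloc[r].to_numpy()][0]
            raise ESMValidationError(
                f"value {row[badvar]!r} of '{badvar}' outside scale [{lo}, {hi}] "
                f"at row {df.index[r]} (person={row[PERSON]}, day={row[DAY]}, "
                f"beep={row[BEEP]})"
            )
        if not df[PERIOD].isin([0, 1]).all():
            raise ESMValidationError("period column must be 0 (baseline) or 1 (post)")
        # beep strictly increasing within person-day follows from uniqueness
        # once sorted; enforce sorted order for downstream code
        self.data = df.sort_values([PERSON, DAY, BEEP], kind="mergesort").reset_index(
            drop=True
        )

    # -- convenience --------------------------------------------------
    @property
    def persons(self) -> np.ndarray:
        return self.data[PERSON].unique()

    @property
    def n_variables(self) -> int:
        return len(self.variables)

    def counts(self) -> pd.DataFrame:
        """Answered-beep counts per person and period."""
        return (
            self.data.groupby([PERSON, PERIOD], observed=True)
            .size()
            .rename("n_answered")
            .reset_index()
        )

    def covariates(self) -> pd.DataFrame:
        """One row per person with any level-2 covariates present."""
        cols = [c for c in (THERAPY, NEUROTICISM) if c in self.data.columns]
        return self.data.groupby(PERSON, observed=True)[cols].first() if cols else (
            pd.DataFrame(index=pd.Index(self.persons, name=PERSON))
        )


def read_esm_csv(path: str | Path, schema: ESMSchema) -> ESMDataset:
    """Read and validate a delimited ESM file against ``schema``.

    Blanks and the schema's sentinel strings are coerced to missing. Raises
    :class:`ESMValidationError` for duplicate (person, day, beep) triples or
    out-of-scale values, naming the offending row.
    """
    path = Path(path)
    sep = "\t" if path.suffix in (".tsv", ".txt") else ","
    raw = pd.read_csv(path, sep=sep, na_values=list(schema.na_values), comment="#",
                      float_precision="round_trip")
    rename = {schema.person: PERSON, schema.day: DAY, schema.beep: BEEP}
    if schema.time:
        rename[schema.time] = TIME
    if schema.period:
        rename[schema.period] = PERIOD
    if schema.therapy:
        rename[schema.therapy] = THERAPY
    if schema.neuroticism:
        rename[schema.neuroticism] = NEUROTICISM
    missing = [c for c in rename if c not in raw.columns] + [
        v for v in schema.variables if v not in raw.columns
    ]
    if missing:
        raise ESMValidationError(f"file {path} lacks columns {missing}")
    df = raw.rename(columns=rename)
    if PERIOD not in df.columns:
        df[PERIOD] = 0
    keep = [PERSON, DAY, BEEP] + [c for c in (TIME, PERIOD, THERAPY, NEUROTICISM) if c in df.columns]
    df = df[keep + list(schema.variables)].copy()
    for col in (DAY, BEEP):
        df[col] = df[col].astype(int)
    for v in schema.variables:
        df[v] = pd.to_numeric(df[v], errors="coerce")
    return ESMDataset(df, list(schema.variables), schema.scale)


# ---------------------------------------------------------------------------
# Lagging


@dataclass
class ReductionReport:
    """Accounting of how lagging + day-boundary rules shrink the data."""

    n_answered_beeps: int
    n_complete_beeps: int
    n_lagged_rows: int
    mean_reports_per_person_period: float  #: answered beeps, before lagging
    mean_usable_per_person_period: float  #: lagged rows, after
    casewise_dropped: int  #: adjacent pairs lost to item-level missingness
    table: pd.DataFrame = field(repr=False)  #: per person x period counts


@dataclass
class LaggedDesign:
    """Response rows paired with the same-day previous-beep predictor vector.

    ``data`` columns: person, day, beep (of the response), period, optional
    covariates, ``y_<var>`` responses at t and ``lag_<var>`` predictors at
    t-1. Every row has complete response and predictor vectors.
    """

    data: pd.DataFrame
    variables: list[str]
    report: ReductionReport | None = None
    lag: int = 1

    @property
    def response_columns(self) -> list[str]:
        return [f"y_{v}" for v in self.variables]

    @property
    def predictor_columns(self) -> list[str]:
        return [f"lag_{v}" for v in self.variables]

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, variables: list[str], lag: int = 1) -> "LaggedDesign":
        return cls(pd.read_csv(path, comment="#", float_precision="round_trip"),
                   list(variables), None, lag)


def build_lagged_design(
    esm: ESMDataset, lag: int = 1, center_predictors: bool = False
) -> LaggedDesign:
    """Pair each beep t (t >= 2) with beep t-1 of the same person-day.

    A response row is usable only when the beep with index exactly one lower
    was answered on the same day and both beeps are complete on all J
    variables (casewise deletion). Gaps are never bridged and days never
    lagged across (the first beep of a day is only ever a predictor), so a
    night never separates a pair.

    Predictors are raw scores by default; ``center_predictors`` subtracts
    each person's own mean (over their answered beeps) from the lagged
    columns, moving between-person level differences out of the lag
    coefficients and into the intercepts.
    """
    if lag != 1:
        raise ValueError(
            "build_lagged_design handles the primary lag-1 model; higher "
            "orders are built by diagnostics.lag_order_comparison"
        )
    df = esm.data
    variables = esm.variables
    complete = df[variables].notna().all(axis=1)
    comp = df[complete]

    meta_cols = [PERSON, DAY, BEEP, PERIOD] + [
        c for c in (TIME, THERAPY, NEUROTICISM) if c in df.columns
    ]
    resp = comp[meta_cols + variables].rename(columns={v: f"y_{v}" for v in variables})
    pred = comp[[PERSON, DAY, BEEP] + variables].rename(
        columns={v: f"lag_{v}" for v in variables}
    )
    pred = pred.assign(**{BEEP: pred[BEEP] + 1})  # aligns beep t-1 under key t
    merged = resp.merge(pred, on=[PERSON, DAY, BEEP], how="inner")

    # pairs of *answered* adjacent beeps, ignoring item completeness, to
    # report how many pairs casewise deletion removed
    keys = pd.MultiIndex.from_frame(df[[PERSON, DAY, BEEP]])
    prev_keys = pd.MultiIndex.from_arrays([df[PERSON], df[DAY], df[BEEP] + 1])
    answered_pairs = int(prev_keys.isin(keys).sum())

    if merged.empty:
        raise ESMValidationError(
            "no usable lagged rows: every answered beep lacks a complete "
            "same-day predecessor. The model needs runs of >= 2 consecutive "
            "answered beeps within a day."
        )

    per_pp_answered = df.groupby([PERSON, PERIOD], observed=True).size()
    per_pp_usable = (
        merged.groupby([PERSON, PERIOD], observed=True)
        .size()
        .reindex(per_pp_answered.index, fill_value=0)
    )
    table = pd.concat(
        {"n_answered": per_pp_answered, "n_usable": per_pp_usable}, axis=1
    ).fillna(0).astype(int).reset_index()
    if center_predictors:
        person_means = df.groupby(PERSON, observed=True)[variables].mean()
        for v in variables:
            merged[f"lag_{v}"] = merged[f"lag_{v}"] - merged[PERSON].map(person_means[v])
    report = ReductionReport(
        n_answered_beeps=int(len(df)),
        n_complete_beeps=int(complete.sum()),
        n_lagged_rows=int(len(merged)),
        mean_reports_per_person_period=float(per_pp_answered.mean()),
        mean_usable_per_person_period=float(per_pp_usable.mean()),
        casewise_dropped=answered_pairs - int(len(merged)),
        table=table,
    )
    return LaggedDesign(merged.reset_index(drop=True), list(variables), report)


# ---------------------------------------------------------------------------
# Measurement-interval statistics


@dataclass
class IntervalStats:
    """Mean/SD (sample SD, ddof=1) of hours between adjacent answered beeps."""

    available: bool
    mean_hours: float | None = None
    sd_hours: float | None = None
    n_pairs: int = 0
    message: str = ""


def interval_stats(esm: ESMDataset) -> IntervalStats:
    """Spacing of the measurement pairs the lag-1 model actually uses.

    Computed over within-day pairs of answered beeps with adjacent beep
    indices; gaps across skipped beeps and across the night are excluded,
    mirroring the lagging rule. SD is the sample standard deviation.
    """
    if TIME not in esm.data.columns:
        return IntervalStats(False, message="no clock-time column in this dataset")
    df = esm.data
    t = df[TIME]
    same_pair = (
        (df[PERSON] == df[PERSON].shift())
        & (df[DAY] == df[DAY].shift())
        & (df[BEEP] == df[BEEP].shift() + 1)
    )
    gaps = (t - t.shift())[same_pair].dropna().to_numpy()
    if gaps.size == 0:
        return IntervalStats(False, message="no adjacent answered pairs with clock time")
    sd = float(np.std(gaps, ddof=1)) if gaps.size > 1 else 0.0
    return IntervalStats(True, float(np.mean(gaps)), sd, int(gaps.size))
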