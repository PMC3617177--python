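"""Model-assumption checks for the multilevel VAR(1).

Three assumptions get dedicated diagnostics: (weak) stationarity of each
person x variable x period series (KPSS test, stationarity as the null),
absence of an overall trend (summed-BIC comparison against a model with a
person-specific linear trend in the beep number), and the adequacy of lag
order one (summed-BIC comparison of order 1..max_order fits on a common
row set, with lag-1 coefficient stability across orders).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.tsa.stattools import kpss as _sm_kpss
from statsmodels.tools.sm_exceptions import InterpolationWarning

from .data import BEEP, DAY, PERIOD, PERSON, ESMDataset, LaggedDesign
from .model import RandomSpec, fit_mixed_equation

__all__ = [
    "KPSSResult",
    "StationarityReport",
    "TrendComparison",
    "LagOrderComparison",
    "kpss_test",
    "proportion_stationary",
    "bic_trend_comparison",
    "lag_order_comparison",
]


@dataclass
class KPSSResult:
    """Level-stationarity KPSS test; p-values interpolated from the
    standard critical-value table and clamped to [0.01, 0.10]."""

    statistic: float
    pvalue: float
    nlags: int
    n: int

    def stationary(self, alpha: float = 0.05) -> bool:
        return self.pvalue >= alpha


def _schwert_lag(n: int) -> int:
    # short truncation lag: floor(4 * (T/100)^(1/4))
    return int(np.floor(4.0 * (n / 100.0) ** 0.25))


def kpss_test(series, nlags: int | None = None) -> KPSSResult:
    """KPSS test of level stationarity for one series.

    Missing values are dropped; a constant series has statistic 0 and is
    reported stationary. The long-run variance uses a short Schwert-style
    bandwidth by default.
    """
    x = np.asarray(pd.Series(series).dropna(), dtype=float)
    n = len(x)
    if n < 10:
        raise ValueError(f"series too short for KPSS ({n} < 10 points)")
    if np.ptp(x) == 0.0:
        return KPSSResult(0.0, 0.10, 0, n)
    lags = _schwert_lag(n) if nlags is None else int(nlags)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", InterpolationWarning)
        stat, p, used, _crit = _sm_kpss(x, regression="c", nlags=lags)
    return KPSSResult(float(stat), float(np.clip(p, 0.01, 0.10)), int(used), n)


@dataclass
class StationarityReport:
    """Share of person x variable x period series judged stationary."""

    fraction_stationary: float
    n_tested: int
    n_stationary: int
    n_too_short: int
    min_length: int
    alpha: float
    table: pd.DataFrame = field(repr=False)  #: one row per tested series


def proportion_stationary(
    esm: ESMDataset, alpha: float = 0.05, min_length: int = 10
) -> StationarityReport:
    """Run the KPSS test on every person x variable x period series.

    Series shorter than ``min_length`` after dropping missing values are
    excluded from the fraction and counted separately.
    """
    rows = []
    n_short = 0
    df = esm.data.sort_values([PERSON, PERIOD, DAY, BEEP], kind="mergesort")
    for (person, period), block in df.groupby([PERSON, PERIOD], observed=True):
        for v in esm.variables:
            x = block[v].dropna()
            if len(x) < min_length:
                n_short += 1
                continue
            r = kpss_test(x)
            rows.append(
                {
                    "person": person,
                    "period": period,
                    "variable": v,
                    "n": r.n,
                    "statistic": r.statistic,
                    "pvalue": r.pvalue,
                    "stationary": r.stationary(alpha),
                }
            )
    table = pd.DataFrame(rows)
    n_tested = len(table)
    n_stat = int(table["stationary"].sum()) if n_tested else 0
    return StationarityReport(
        fraction_stationary=n_stat / n_tested if n_tested else float("nan"),
        n_tested=n_tested, n_stationary=n_stat, n_too_short=n_short,
        min_length=min_length, alpha=alpha, table=table,
    )


# ---------------------------------------------------------------------------
# Trend BIC comparison


@dataclass
class TrendComparison:
    """Summed BICs of the baseline model vs one with a person-specific
    linear trend in the beep number (lower BIC preferred)."""

    bic_no_trend: float
    bic_trend: float
    per_equation: pd.DataFrame
    failures: list[str]

    @property
    def preferred(self) -> str:
        return "no-trend" if self.bic_no_trend <= self.bic_trend else "trend"


def bic_trend_comparison(
    design: LaggedDesign, random_spec: RandomSpec | None = None, reml: bool = True
) -> TrendComparison:
    """Compare the baseline fit against a deterministic-trend alternative.

    The trend model adds the beep number as a fixed predictor with a
    person-specific random slope, per equation. BICs are summed over
    equations; both models use the identical row set by construction.
    Equations where the trend model fails are omitted from both sums and
    flagged.
    """
    spec = random_spec or RandomSpec()
    df = design.data
    X = pd.DataFrame({"intercept": np.ones(len(df))}, index=df.index)
    for c in design.predictor_columns:
        X[c] = df[c].to_numpy(dtype=float)
    Xt = X.copy()
    Xt["beep_number"] = df[BEEP].to_numpy(dtype=float)
    if spec.structure == "none":
        trend_re = None
    else:
        # baseline random structure plus a person-specific trend slope
        base_re = Xt[["intercept"]] if spec.structure == "intercept" else X
        trend_re = pd.concat([base_re, Xt[["beep_number"]]], axis=1)
    rows, failures = [], []
    for v in design.variables:
        y = df[f"y_{v}"].to_numpy(dtype=float)
        base = fit_mixed_equation(y, X, df[PERSON], spec.structure, reml, v)
        try:
            trend = fit_mixed_equation(
                y, Xt, df[PERSON], spec.structure, reml, v, exog_re=trend_re,
            )
        except Exception as exc:  # noqa: BLE001
            failures.append(v)
            warnings.warn(f"trend model failed for {v!r}: {exc}")
            continue
        rows.append(
            {"variable": v, "bic_no_trend": base.bic, "bic_trend": trend.bic,
             "n_obs": base.n_obs}
        )
    per_eq = pd.DataFrame(rows)
    if per_eq.empty:
        raise RuntimeError("trend comparison failed for every equation")
    assert per_eq["n_obs"].nunique() == 1, "BIC compared across differing row sets"
    return TrendComparison(
        float(per_eq["bic_no_trend"].sum()), float(per_eq["bic_trend"].sum()),
        per_eq, failures,
    )


# ---------------------------------------------------------------------------
# Lag-order comparison


def _multi_lag_frame(esm: ESMDataset, order: int) -> pd.DataFrame:
    """Rows whose previous ``order`` same-day beeps are all answered and
    complete; predictors lag1_<v> .. lag<order>_<v>."""
    df = esm.data
    complete = df[esm.variables].notna().all(axis=1)
    comp = df[complete]
    out = comp[[PERSON, DAY, BEEP, PERIOD] + esm.variables].rename(
        columns={v: f"y_{v}" for v in esm.variables}
    )
    for s in range(1, order + 1):
        pred = comp[[PERSON, DAY, BEEP] + esm.variables].rename(
            columns={v: f"lag{s}_{v}" for v in esm.variables}
        )
        pred = pred.assign(**{BEEP: pred[BEEP] + s})
        out = out.merge(pred, on=[PERSON, DAY, BEEP], how="inner")
    return out.reset_index(drop=True)


@dataclass
class LagOrderComparison:
    """Summed BIC per fitted order on a common row set, plus the lag-1
    coefficient matrices (and their SEs) per order for stability checks."""

    orders: list[int]
    bic: dict[int, float]
    lag1_coefs: dict[int, np.ndarray]
    lag1_se: dict[int, np.ndarray]
    n_obs: int

    @property
    def preferred_order(self) -> int:
        return min(self.bic, key=self.bic.get)

    def max_lag1_shift(self) -> float:
        """Largest |difference| in lag-1 coefficients between any two orders,
        in units of the order-1 standard error."""
        base = self.lag1_coefs[1]
        se = self.lag1_se[1]
        shifts = [
            np.max(np.abs(self.lag1_coefs[o] - base) / np.where(se > 0, se, np.inf))
            for o in self.orders if o != 1
        ]
        return float(max(shifts)) if shifts else 0.0


def lag_order_comparison(
    esm: ESMDataset,
    max_order: int = 3,
    random_spec: RandomSpec | None = None,
    reml: bool = True,
    min_rows: int = 50,
) -> LagOrderComparison:
    """Fit VAR models of order 1..max_order on a common row set.

    The common rows are those usable at ``max_order`` (each response needs
    its previous ``max_order`` same-day beeps answered), so summed BICs are
    comparable. Random effects attach to the intercept and the lag-1
    slopes only; higher-lag coefficients are fixed.
    """
    if max_order < 1:
        raise ValueError("max_order must be >= 1")
    spec = random_spec or RandomSpec()
    frame = _multi_lag_frame(esm, max_order)
    if len(frame) < min_rows:
        raise ValueError(
            f"only {len(frame)} rows usable at order {max_order} "
            f"(need >= {min_rows}); try a lower max_order"
        )
    J = len(esm.variables)
    bics: dict[int, float] = {}
    coefs: dict[int, np.ndarray] = {}
    ses: dict[int, np.ndarray] = {}
    for order in range(1, max_order + 1):
        X = pd.DataFrame({"intercept": np.ones(len(frame))}, index=frame.index)
        for s in range(1, order + 1):
            for v in esm.variables:
                X[f"lag{s}_{v}"] = frame[f"lag{s}_{v}"].to_numpy(dtype=float)
        if spec.structure == "none":
            exog_re = None
        elif spec.structure == "intercept":
            exog_re = X[["intercept"]]
        else:
            # random effects on intercept + lag-1 slopes only; higher-lag
            # coefficients stay fixed
            exog_re = X[["intercept"] + [f"lag1_{v}" for v in esm.variables]]
        total = 0.0
        c1 = np.empty((J, J))
        s1 = np.empty((J, J))
        for j, v in enumerate(esm.variables):
            y = frame[f"y_{v}"].to_numpy(dtype=float)
            fit = fit_mixed_equation(
                y, X, frame[PERSON], spec.structure, reml, v, exog_re=exog_re
            )
            total += fit.bic
            c1[j] = [fit.coef(f"lag1_{w}") for w in esm.variables]
            s1[j] = [fit.se[fit.coef_names.index(f"lag1_{w}")] for w in esm.variables]
        bics[order] = total
        coefs[order] = c1
        ses[order] = s1
    return LagOrderComparison(list(bics), bics, coefs, ses, len(frame))
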