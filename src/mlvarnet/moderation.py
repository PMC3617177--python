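"""Level-2 moderators of the dynamic network.

Two extensions of the baseline multilevel VAR(1):

* a *local* therapy analysis — each lag coefficient gains a post-baseline
  change term and a post x therapy x lagged-predictor three-way interaction,
  with person-specific intercept deviations estimated separately pre and
  post while slope deviations are shared across periods (persons who
  deviate from the average dynamics at baseline are assumed to keep doing
  so afterwards);
* a *global* neuroticism analysis — an ordinal 0/1/2 group score (from
  quartile or questionnaire-defined cuts) interacts linearly with the
  baseline lag coefficients only, producing one network per group,
  Phi(g) = Gamma + g * N.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import NEUROTICISM, PERIOD, PERSON, THERAPY, LaggedDesign
from .model import RandomSpec, UnivariateFit, bh_fdr, fit_mixed_equation

__all__ = [
    "GroupAssignment",
    "TherapyModelFit",
    "TherapyEffectTest",
    "NeuroticismModelFit",
    "assign_neuroticism_groups",
    "fit_therapy_model",
    "test_therapy_effects",
    "fit_neuroticism_model",
    "build_neuroticism_design",
]

#: questionnaire-defined group boundaries (low < b1 <= mid <= b2 < high)
NAMED_BOUNDARIES = {
    "neo-ffi": ((34.5, 45.5), (12.0, 60.0)),  # sum scores 12-34 / 35-45 / 46-60
    "tipi": ((2.25, 4.75), (1.0, 7.0)),  # sum scores 1-2 / 2.5-4.5 / 5-7
}


@dataclass
class GroupAssignment:
    """Ordinal neuroticism groups (0 low, 1 mid, 2 high) with provenance."""

    groups: pd.Series
    boundaries: tuple[float, float]
    source: str  #: "empirical-quartiles" | scale name | "explicit"
    counts: dict[int, int]
    degenerate: bool = False


def assign_neuroticism_groups(
    scores,
    boundaries: tuple[float, float] | None = None,
    scale: str | None = None,
) -> GroupAssignment:
    """Split neuroticism sum scores into low/mid/high groups (0/1/2).

    With a named ``scale`` ("neo-ffi" or "tipi") the questionnaire's fixed
    quartile-based cut points are used and out-of-range scores are errors;
    with explicit ``boundaries`` those two cut points apply; otherwise the
    empirical first and third quartile of the scores are used. A score s
    maps to 0 when s < b1, to 2 when s > b2, else to 1. Degenerate
    quartiles (all scores equal) put everyone in the mid group with a
    warning.
    """
    s = pd.Series(scores, dtype=float)
    if s.isna().any():
        raise ValueError("neuroticism scores contain missing values")
    degenerate = False
    if scale is not None:
        if scale not in NAMED_BOUNDARIES:
            raise ValueError(f"unknown scale {scale!r}; known: {sorted(NAMED_BOUNDARIES)}")
        (b1, b2), (lo, hi) = NAMED_BOUNDARIES[scale]
        bad = s[(s < lo) | (s > hi)]
        if len(bad):
            raise ValueError(
                f"score(s) {bad.tolist()[:5]} outside the {scale} range [{lo}, {hi}]"
            )
        source = scale
    elif boundaries is not None:
        b1, b2 = map(float, boundaries)
        source = "explicit"
    else:
        b1, b2 = (float(np.percentile(s, 25)), float(np.percentile(s, 75)))
        source = "empirical-quartiles"
        if b1 == b2:
            degenerate = True
            warnings.warn(
                "degenerate quartiles (all scores nearly equal); "
                "assigning everyone to the mid group"
            )
    if degenerate:
        g = pd.Series(1, index=s.index, dtype=int)
    else:
        g = ((s >= b1).astype(int) + (s > b2).astype(int)).astype(int)
    counts = {k: int((g == k).sum()) for k in (0, 1, 2)}
    return GroupAssignment(g, (b1, b2), source, counts, degenerate)


# ---------------------------------------------------------------------------
# Therapy: local network analysis


@dataclass
class TherapyModelFit:
    """Per-equation moderated fits and the assembled period/arm matrices.

    Phi_B is the baseline network, Phi_C = Phi_B + post-change matrix the
    post-baseline control network, Phi_T = Phi_C + interaction matrix the
    post-baseline therapy network (assembly identities, not re-fits).
    """

    variables: list[str]
    fits: list[UnivariateFit]
    Phi_B: np.ndarray
    post_change: np.ndarray
    interaction: np.ndarray
    interaction_pvalues: np.ndarray
    Phi_C: np.ndarray = field(init=False)
    Phi_T: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.Phi_C = self.Phi_B + self.post_change
        self.Phi_T = self.Phi_C + self.interaction


def _check_cells(data: pd.DataFrame) -> None:
    for period in (0, 1):
        for arm in (0, 1):
            n = int(((data[PERIOD] == period) & (data[THERAPY] == arm)).sum())
            if n == 0:
                raise ValueError(
                    f"empty design cell: period={period}, therapy={arm} has no rows"
                )


def fit_therapy_model(
    design: LaggedDesign,
    random_spec: RandomSpec | None = None,
    reml: bool = True,
) -> TherapyModelFit:
    """Fit the therapy-moderated multilevel VAR(1) on both periods.

    Fixed structure per equation: baseline intercept and lag coefficients,
    post-baseline changes for controls, and post x therapy x predictor
    three-way interactions (plus the matching intercept terms). Random
    structure: separate pre/post intercept deviations and shared slope
    deviations, unstructured covariance by default.
    """
    df = design.data
    if THERAPY not in df.columns:
        raise ValueError("design lacks a therapy covariate")
    if df[PERIOD].nunique() < 2:
        raise ValueError("therapy model needs both baseline and post-baseline rows")
    if df[THERAPY].nunique() < 2:
        raise ValueError(
            "therapy indicator has no variation (all "
            f"{int(df[THERAPY].iloc[0])}); the therapy interaction matrix is inestimable"
        )
    _check_cells(df)
    spec = random_spec or RandomSpec()
    post = df[PERIOD].to_numpy(dtype=float)
    ther = df[THERAPY].to_numpy(dtype=float)
    X = pd.DataFrame(index=df.index)
    X["intercept"] = 1.0
    X["post"] = post
    X["post:therapy"] = post * ther
    for v in design.variables:
        X[f"lag_{v}"] = df[f"lag_{v}"].to_numpy(dtype=float)
    for v in design.variables:
        X[f"post:lag_{v}"] = post * df[f"lag_{v}"].to_numpy(dtype=float)
    for v in design.variables:
        X[f"post:therapy:lag_{v}"] = post * ther * df[f"lag_{v}"].to_numpy(dtype=float)
    re_df = pd.DataFrame(index=df.index)
    re_df["pre_intercept"] = 1.0 - post
    re_df["post_intercept"] = post
    for v in design.variables:
        re_df[f"lag_{v}"] = X[f"lag_{v}"]

    fits = []
    for v in design.variables:
        y = df[f"y_{v}"].to_numpy(dtype=float)
        if spec.structure == "none":
            fit = fit_mixed_equation(y, X, df[PERSON], "none", reml, v)
        else:
            fit = fit_mixed_equation(
                y, X, df[PERSON], spec.structure, reml, v, exog_re=re_df
            )
        fits.append(fit)
    lag_names = [f"lag_{v}" for v in design.variables]
    Phi_B = np.array([[f.coef(c) for c in lag_names] for f in fits])
    delta = np.array([[f.coef(f"post:{c}") for c in lag_names] for f in fits])
    tau = np.array([[f.coef(f"post:therapy:{c}") for c in lag_names] for f in fits])
    tau_p = np.array([[f.coef_p(f"post:therapy:{c}") for c in lag_names] for f in fits])
    return TherapyModelFit(list(design.variables), fits, Phi_B, delta, tau, tau_p)


@dataclass
class TherapyEffectTest:
    """FDR-controlled test of the J*J three-way therapy interactions."""

    variables: list[str]
    pvalues: np.ndarray
    fdr_mask: np.ndarray
    raw_mask: np.ndarray
    q: float

    @property
    def n_significant(self) -> int:
        return int(self.fdr_mask.sum())


def test_therapy_effects(fit: TherapyModelFit, q: float = 0.05) -> TherapyEffectTest:
    """Benjamini-Hochberg mask over the three-way interaction p-values,
    with the raw-alpha mask alongside for sensitivity."""
    p = fit.interaction_pvalues
    return TherapyEffectTest(fit.variables, p, bh_fdr(p, q), p < q, q)


# ---------------------------------------------------------------------------
# Neuroticism: moderated model feeding the global (centrality) analysis


@dataclass
class NeuroticismModelFit:
    """Fits with an ordinal neuroticism score moderating the baseline links.

    Gamma holds the baseline lag coefficients (the g=0 network), nu the
    per-group-step interaction coefficients; phi_group(g) = Gamma + g * nu.
    """

    variables: list[str]
    fits: list[UnivariateFit]
    Gamma: np.ndarray
    nu: np.ndarray
    nu_pvalues: np.ndarray
    baseline_only: bool

    def phi_group(self, g: int) -> np.ndarray:
        if g not in (0, 1, 2):
            raise ValueError("group must be 0, 1 or 2")
        return self.Gamma + g * self.nu


def build_neuroticism_design(
    design: LaggedDesign,
    groups: pd.Series,
    baseline_only: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.Series]:
    """Shared fixed/random/response design for the neuroticism models.

    Returns (X, re_df, Y, persons). ``groups`` maps person id to 0/1/2.
    With both periods included, period main effects and period x lag terms
    absorb post-baseline change while the neuroticism interaction attaches
    to the baseline lag coefficients only; ``baseline_only`` restricts to
    period-0 rows instead.
    """
    df = design.data
    missing = set(df[PERSON].unique()) - set(groups.index)
    if missing:
        raise ValueError(f"no neuroticism group for persons {sorted(missing)[:5]}")
    g = df[PERSON].map(groups).to_numpy(dtype=float)
    present = set(int(x) for x in np.unique(g))
    absent = {0, 1, 2} - present
    if absent:
        raise ValueError(f"neuroticism group(s) {sorted(absent)} absent from the design")
    if baseline_only:
        keep = df[PERIOD] == 0
        df = df[keep]
        g = g[keep.to_numpy()]
        if df.empty:
            raise ValueError("no baseline rows in the design")
    X = pd.DataFrame(index=df.index)
    X["intercept"] = 1.0
    both = not baseline_only and df[PERIOD].nunique() > 1
    post = df[PERIOD].to_numpy(dtype=float)
    if both:
        X["post"] = post
    X["neuroticism"] = g
    for v in design.variables:
        X[f"lag_{v}"] = df[f"lag_{v}"].to_numpy(dtype=float)
    if both:
        for v in design.variables:
            X[f"post:lag_{v}"] = post * X[f"lag_{v}"]
    for v in design.variables:
        X[f"neuroticism:lag_{v}"] = g * X[f"lag_{v}"]
    re_df = pd.DataFrame(index=df.index)
    if both:
        re_df["pre_intercept"] = 1.0 - post
        re_df["post_intercept"] = post
    else:
        re_df["intercept"] = 1.0
    for v in design.variables:
        re_df[f"lag_{v}"] = X[f"lag_{v}"]
    Y = df[[f"y_{v}" for v in design.variables]]
    return X, re_df, Y, df[PERSON]


def fit_neuroticism_model(
    design: LaggedDesign,
    groups: pd.Series | GroupAssignment,
    baseline_only: bool = False,
    random_spec: RandomSpec | None = None,
    reml: bool = True,
) -> NeuroticismModelFit:
    """Fit the neuroticism-moderated multilevel VAR(1).

    The ordinal group score (0/1/2) enters linearly: each lag coefficient
    gains a per-group-step shift, and a main-effect term shifts the
    intercept. All three groups must be present.
    """
    if isinstance(groups, GroupAssignment):
        groups = groups.groups
    spec = random_spec or RandomSpec()
    X, re_df, Y, persons = build_neuroticism_design(design, groups, baseline_only)
    fits = []
    for v in design.variables:
        y = Y[f"y_{v}"].to_numpy(dtype=float)
        if spec.structure == "none":
            fit = fit_mixed_equation(y, X, persons, "none", reml, v)
        else:
            fit = fit_mixed_equation(
                y, X, persons, spec.structure, reml, v, exog_re=re_df
            )
        fits.append(fit)
    lag_names = [f"lag_{v}" for v in design.variables]
    Gamma = np.array([[f.coef(c) for c in lag_names] for f in fits])
    nu = np.array([[f.coef(f"neuroticism:{c}") for c in lag_names] for f in fits])
    nu_p = np.array([[f.coef_p(f"neuroticism:{c}") for c in lag_names] for f in fits])
    return NeuroticismModelFit(list(design.variables), fits, Gamma, nu, nu_p, baseline_only)
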