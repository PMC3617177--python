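"""Multilevel VAR(1) estimation by stacked univariate linear mixed models.

Each of the J variables at beep t is regressed on all J variables at beep
t-1 within the same day. Every regression coefficient decomposes into a
population-average (fixed) part and a person-specific (random) deviation
drawn from a zero-mean multivariate normal with, by default, an
unstructured within-equation covariance. Fitting the J equations
separately and re-indexing the fixed effects into the J x J transition
matrix Phi is an instance of pseudo-likelihood estimation: the full joint
multivariate mixed model is never formed, and cross-equation random-effect
covariances are not identified. Innovation (residual) correlations across
equations are recovered indirectly from the stacked per-row residuals.

Phi[j, k] is the effect of variable k at t-1 on variable j at t, i.e. the
edge k -> j when Phi is read as an adjacency matrix.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.regression.linear_model import OLS
from statsmodels.regression.mixed_linear_model import MixedLM, MixedLMParams
from statsmodels.stats.multitest import multipletests

from .data import PERSON, LaggedDesign
from .graph import NetworkGraph

__all__ = [
    "RandomSpec",
    "UnivariateFit",
    "MLVARModel",
    "fit_univariate",
    "fit_mlvar",
    "residual_correlations",
    "bh_fdr",
    "population_network",
    "random_sd_network",
    "individual_network",
]


@dataclass(frozen=True)
class RandomSpec:
    """Which coefficients receive person-specific random deviations.

    structure:
      - "unstructured": random intercept + all slopes, free covariance
        (the primary model; matches a full lme4-style random-slopes fit)
      - "diagonal": same terms, independent random effects
      - "intercept": random intercept only
      - "none": ordinary least squares (single-person / fixed-only fits)
    """

    structure: str = "unstructured"

    def __post_init__(self) -> None:
        if self.structure not in ("unstructured", "diagonal", "intercept", "none"):
            raise ValueError(f"unknown random-effect structure {self.structure!r}")


@dataclass
class UnivariateFit:
    """One equation of the stacked model: variable ``response`` at t on all
    variables at t-1, with person-specific coefficient deviations."""

    response: str
    coef_names: list[str]
    gamma: np.ndarray  #: fixed coefficients, intercept first
    se: np.ndarray
    tvalues: np.ndarray
    pvalues: np.ndarray  #: Wald, standard-normal reference
    re_names: list[str]
    Omega: np.ndarray  #: random-effect covariance over re_names (possibly empty)
    sigma2: float  #: residual (innovation) variance
    blups: pd.DataFrame  #: per-person predicted deviations, persons x re_names
    residuals: np.ndarray  #: conditional residuals, aligned with design rows
    fitted: np.ndarray
    llf: float
    bic: float  #: -2 llf + k log(n), k = fixed + free covariance + residual
    n_obs: int
    n_persons: int
    converged: bool
    simplified: bool  #: True when covariance was simplified to diagonal to converge
    structure: str

    def coef(self, name: str) -> float:
        return float(self.gamma[self.coef_names.index(name)])

    def coef_p(self, name: str) -> float:
        return float(self.pvalues[self.coef_names.index(name)])

    def re_sd(self, name: str) -> float:
        """SD of the random deviation on coefficient ``name`` (0 if fixed-only)."""
        if name not in self.re_names:
            return 0.0
        i = self.re_names.index(name)
        return float(np.sqrt(max(self.Omega[i, i], 0.0)))

    def blup(self, person, name: str) -> float:
        if name not in self.re_names:
            return 0.0
        return float(self.blups.loc[person, name])


def _n_cov_params(structure: str, k_re: int) -> int:
    if structure == "unstructured":
        return k_re * (k_re + 1) // 2
    if structure == "diagonal":
        return k_re
    if structure == "intercept":
        return 1
    return 0


def fit_mixed_equation(
    y: np.ndarray,
    X: pd.DataFrame,
    groups: pd.Series,
    structure: str = "unstructured",
    reml: bool = True,
    response: str = "y",
    exog_re: pd.DataFrame | None = None,
) -> UnivariateFit:
    """REML-fit one mixed equation, with a convergence-retry ladder.

    ``X`` is the fixed-effect design (named columns); ``exog_re`` the
    random-effect design, defaulting to ``X`` itself (or its first column
    for structure "intercept"). Non-convergence is retried with
    alternative optimizers and perturbed restarts; as a last resort an
    unstructured covariance is simplified to diagonal and the result
    flagged ``simplified``.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    coef_names = list(X.columns)
    k_fe = len(coef_names)
    persons = pd.unique(groups)

    if structure == "none":
        res = OLS(y, np.asarray(X)).fit()
        p = 2 * stats.norm.sf(np.abs(res.tvalues))
        k = k_fe + 1
        return UnivariateFit(
            response=response, coef_names=coef_names,
            gamma=np.asarray(res.params), se=np.asarray(res.bse),
            tvalues=np.asarray(res.tvalues), pvalues=p,
            re_names=[], Omega=np.zeros((0, 0)), sigma2=float(res.mse_resid),
            blups=pd.DataFrame(0.0, index=pd.Index(persons, name=PERSON), columns=[]),
            residuals=np.asarray(res.resid), fitted=np.asarray(res.fittedvalues),
            llf=float(res.llf), bic=float(-2 * res.llf + k * np.log(n)),
            n_obs=n, n_persons=len(persons), converged=True, simplified=False,
            structure="none",
        )

    if len(persons) < 2:
        raise ValueError(
            "random effects need at least 2 persons; refit with "
            "RandomSpec(structure='none') for a single-person series"
        )

    if exog_re is None:
        exog_re = X[[coef_names[0]]] if structure == "intercept" else X
    re_names = list(exog_re.columns)
    k_re = len(re_names)

    def _free(struct):
        if struct == "diagonal":
            return MixedLMParams.from_components(
                fe_params=np.ones(k_fe), cov_re=np.eye(k_re)
            )
        return None

    def _attempt(struct):
        model = MixedLM(y, X, groups=groups, exog_re=exog_re)
        best = None
        rng = np.random.default_rng(0)
        # perturbed lbfgs restarts are far cheaper than the derivative-free
        # fallbacks and usually rescue boundary cases, so they come first
        plans = (
            [("lbfgs", False)]
            + [("lbfgs", True)] * 3
            + [("bfgs", False), ("powell", True), ("powell", False)]
        )
        for method, warm in plans:
            kwargs = {}
            if warm:
                if best is None:
                    continue
                kwargs["start_params"] = best.params * (
                    1.0 + 0.05 * rng.standard_normal(best.params.shape)
                )
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    res = model.fit(
                        reml=reml, method=method, maxiter=500, free=_free(struct), **kwargs
                    )
            except (np.linalg.LinAlgError, ValueError):
                continue
            usable = np.isfinite(res.params).all() and np.isfinite(res.llf)
            if usable and (best is None or res.llf > best.llf):
                best = res
            if res.converged and usable:
                return res, True
        return best, False

    res, ok = _attempt(structure)
    simplified = False
    if not ok and structure == "unstructured":
        res, ok = _attempt("diagonal")
        if ok:
            simplified = True
            structure = "diagonal"
    if res is None:
        raise RuntimeError(f"mixed model for {response!r} failed in every attempt")

    fe = np.asarray(res.fe_params, dtype=float)
    se = np.asarray(res.bse_fe, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        tv = np.where(se > 0, fe / se, 0.0)
    p = 2 * stats.norm.sf(np.abs(tv))
    omega = np.asarray(res.cov_re, dtype=float)
    blups = pd.DataFrame(
        {pid: re_vec for pid, re_vec in res.random_effects.items()}
    ).T
    blups.columns = re_names
    blups.index.name = PERSON
    blups = blups.reindex(pd.Index(persons, name=PERSON)).fillna(0.0)
    k = k_fe + _n_cov_params(structure, k_re) + 1
    return UnivariateFit(
        response=response, coef_names=coef_names, gamma=fe, se=se, tvalues=tv,
        pvalues=p, re_names=re_names, Omega=omega, sigma2=float(res.scale),
        blups=blups, residuals=np.asarray(res.resid, dtype=float),
        fitted=np.asarray(res.fittedvalues, dtype=float),
        llf=float(res.llf), bic=float(-2 * res.llf + k * np.log(n)),
        n_obs=n, n_persons=len(persons), converged=bool(ok),
        simplified=simplified, structure=structure,
    )


def _design_matrix(design: LaggedDesign) -> pd.DataFrame:
    X = pd.DataFrame({"intercept": np.ones(len(design.data))}, index=design.data.index)
    for c in design.predictor_columns:
        X[c] = design.data[c].to_numpy(dtype=float)
    return X


def fit_univariate(
    design: LaggedDesign,
    response: int | str,
    random_spec: RandomSpec | None = None,
    reml: bool = True,
) -> UnivariateFit:
    """Fit one equation of the multilevel VAR(1).

    ``response`` is a variable name or index. The default specification
    gives the intercept and all J lag coefficients person-specific random
    deviations with an unstructured covariance.
    """
    if design.data.empty:
        raise ValueError("empty lagged design")
    spec = random_spec or RandomSpec()
    name = design.variables[response] if isinstance(response, int) else response
    if name not in design.variables:
        raise KeyError(f"unknown response {name!r}; variables: {design.variables}")
    X = _design_matrix(design)
    y = design.data[f"y_{name}"].to_numpy(dtype=float)
    return fit_mixed_equation(
        y, X, design.data[PERSON], spec.structure, reml, response=name
    )


@dataclass
class MLVARModel:
    """J univariate mixed fits stacked into population-level matrices.

    Assembly is re-indexing only: Phi[j, k] is exactly the fixed lag-k
    coefficient of equation j. Sd holds the random-effect SDs of the slope
    coefficients, pvalues the Wald p-values of the lag coefficients
    (intercepts excluded), resid_corr the indirectly estimated innovation
    correlation matrix.
    """

    variables: list[str]
    fits: list[UnivariateFit | None]
    errors: dict[str, str]
    Phi: np.ndarray
    intercepts: np.ndarray
    Sd: np.ndarray
    pvalues: np.ndarray
    se: np.ndarray
    resid_corr: np.ndarray | None
    persons: np.ndarray

    @property
    def n_variables(self) -> int:
        return len(self.variables)

    @property
    def valid(self) -> bool:
        return not self.errors

    @property
    def any_simplified(self) -> bool:
        return any(f is not None and f.simplified for f in self.fits)

    def require_valid(self, what: str) -> None:
        if self.errors:
            raise RuntimeError(
                f"{what} needs all equations fitted; failed: {sorted(self.errors)}"
            )

    def total_bic(self) -> float:
        self.require_valid("total BIC")
        return float(sum(f.bic for f in self.fits))

    def summary_dict(self) -> dict:
        out = {
            "variables": self.variables,
            "orientation": "Phi[j,k] is the edge k->j (k at t-1 predicts j at t)",
            "Phi": self.Phi.tolist(),
            "intercepts": self.intercepts.tolist(),
            "random_effect_sd": self.Sd.tolist(),
            "pvalues": self.pvalues.tolist(),
            "se": self.se.tolist(),
            "residual_correlations": None if self.resid_corr is None else self.resid_corr.tolist(),
            "equations": {},
            "errors": self.errors,
        }
        for f in self.fits:
            if f is None:
                continue
            out["equations"][f.response] = {
                "coef_names": f.coef_names,
                "gamma": f.gamma.tolist(),
                "se": f.se.tolist(),
                "pvalues": f.pvalues.tolist(),
                "Omega": f.Omega.tolist(),
                "sigma2": f.sigma2,
                "llf": f.llf,
                "bic": f.bic,
                "n_obs": f.n_obs,
                "converged": f.converged,
                "simplified": f.simplified,
                "structure": f.structure,
            }
        return out

    def to_json(self, path: str | Path, metadata: dict | None = None) -> Path:
        path = Path(path)
        payload = dict(metadata or {})
        payload.update(self.summary_dict())
        path.write_text(json.dumps(payload, indent=1))
        return path


def fit_mlvar(
    design: LaggedDesign,
    random_spec: RandomSpec | None = None,
    reml: bool = True,
    compute_residual_corr: bool = True,
) -> MLVARModel:
    """Fit all J equations and assemble the multilevel VAR(1) model.

    Equations that fail outright are recorded in ``errors`` (their Phi rows
    become NaN) and downstream network constructors refuse the partial
    model; everything else proceeds per equation.
    """
    J = len(design.variables)
    if J < 2:
        raise ValueError("multilevel VAR needs at least 2 variables")
    spec = random_spec or RandomSpec()
    fits: list[UnivariateFit | None] = []
    errors: dict[str, str] = {}
    for v in design.variables:
        try:
            fits.append(fit_univariate(design, v, spec, reml))
        except Exception as exc:  # noqa: BLE001 - partial models are a contract
            fits.append(None)
            errors[v] = str(exc)
    Phi = np.full((J, J), np.nan)
    Sd = np.full((J, J), np.nan)
    pv = np.full((J, J), np.nan)
    se = np.full((J, J), np.nan)
    icpt = np.full(J, np.nan)
    for j, f in enumerate(fits):
        if f is None:
            continue
        Phi[j] = f.gamma[1:]
        se[j] = f.se[1:]
        pv[j] = f.pvalues[1:]
        icpt[j] = f.gamma[0]
        Sd[j] = [f.re_sd(c) for c in f.coef_names[1:]]
    model = MLVARModel(
        variables=list(design.variables), fits=fits, errors=errors,
        Phi=Phi, intercepts=icpt, Sd=Sd, pvalues=pv, se=se,
        resid_corr=None, persons=design.data[PERSON].unique(),
    )
    if compute_residual_corr and not errors:
        model.resid_corr = residual_correlations(model)
    return model


def residual_correlations(model: MLVARModel) -> np.ndarray:
    """Innovation correlations, estimated indirectly from stacked residuals.

    The pseudo-likelihood fit never models the J equations jointly, so the
    contemporaneous innovation correlations are recovered as the Pearson
    correlations of the per-row conditional residuals. Requires all
    equations to have been fitted on the identical row set (guaranteed by
    casewise deletion during lagging).
    """
    model.require_valid("residual correlations")
    ns = {f.n_obs for f in model.fits}
    if len(ns) != 1:
        raise ValueError(
            f"equations fitted on different row counts {sorted(ns)}; "
            "residual vectors cannot be aligned (lagging bug?)"
        )
    R = np.column_stack([f.residuals for f in model.fits])
    corr = np.corrcoef(R, rowvar=False)
    np.fill_diagonal(corr, 1.0)
    return corr


def bh_fdr(pvalues, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection mask at FDR level ``q``.

    NaN p-values are excluded from the family (and never rejected); the
    returned boolean array has the input's shape.
    """
    p = np.asarray(pvalues, dtype=float)
    if np.nanmin(p, initial=0.0) < 0 or np.nanmax(p, initial=0.0) > 1:
        raise ValueError("p-values must lie in [0, 1]")
    flat = p.ravel()
    ok = np.isfinite(flat)
    out = np.zeros(flat.shape, dtype=bool)
    if ok.sum():
        out[ok] = multipletests(flat[ok], alpha=q, method="fdr_bh")[0]
    return out.reshape(p.shape)


def population_network(
    model: MLVARModel, alpha: float = 0.05, use_fdr: bool = False
) -> NetworkGraph:
    """Population-average network: fixed-effect matrix Phi with a
    significance mask over the J*J lag coefficients (intercepts excluded),
    either raw Wald alpha or BH-FDR at level ``alpha``."""
    model.require_valid("population network")
    mask = bh_fdr(model.pvalues, q=alpha) if use_fdr else (model.pvalues < alpha)
    return NetworkGraph(
        list(model.variables), model.Phi.copy(), mask, "fixed",
        model.pvalues.copy(),
        meta={"alpha": alpha, "fdr": use_fdr},
    )


def random_sd_network(model: MLVARModel, cutoff: float = 0.1) -> NetworkGraph:
    """Individual-differences network: random-effect SD per link, masked at
    ``cutoff`` (SDs above the cutoff mark links with large heterogeneity)."""
    model.require_valid("random-SD network")
    meta = {"cutoff": cutoff}
    if model.any_simplified:
        meta["simplified_covariance"] = [
            f.response for f in model.fits if f is not None and f.simplified
        ]
    return NetworkGraph(
        list(model.variables), model.Sd.copy(), model.Sd > cutoff, "sd", meta=meta
    )


def individual_network(model: MLVARModel, person_id) -> NetworkGraph:
    """Person-specific network Phi_p = Phi + B_p, where B_p collects the
    person's predicted (BLUP) slope deviations. No significance mask."""
    model.require_valid("individual network")
    known = list(model.persons)
    if person_id not in known:
        shown = known[:10] + (["..."] if len(known) > 10 else [])
        raise KeyError(f"unknown person {person_id!r}; known ids: {shown}")
    J = model.n_variables
    B = np.zeros((J, J))
    for j, f in enumerate(model.fits):
        B[j] = [f.blup(person_id, c) for c in f.coef_names[1:]]
    return NetworkGraph(
        list(model.variables), model.Phi + B, None, "individual",
        meta={"person": person_id},
    )
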