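"""Hierarchical VAR(1) generator for synthetic experience-sampling data.

The generator mirrors the estimation model: each person owns a transition
matrix Phi_p = Gamma + (person-specific deviations) and intercept vector,
with deviations drawn per equation from a zero-mean multivariate normal.
Within a day, beeps follow y_t = mu_p + Phi_p y_{t-1} + eps_t with
multivariate-normal innovations; the first beep of every day restarts from
the person's stationary distribution (day-boundary reset), and beeps are
deleted independently at a fixed missingness rate. Optional moderator
machinery adds a post-period matrix for treated persons (therapy) and a
per-group-step matrix tied to an ordinal neuroticism score.

Default parameter values emulate the shape of a clinical ESM study:
~100 persons, 6 days x 10 beeps per period on a 1-7 Likert-type scale,
self-loops around 0.2 with person SD 0.1, and a missingness rate that
reproduces roughly 49 answered of 60 scheduled beeps per period.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import linalg as sla

from .data import BEEP, DAY, NEUROTICISM, PERIOD, PERSON, THERAPY, TIME, ESMDataset, build_lagged_design

__all__ = [
    "SimulationConfig",
    "PersonParams",
    "RecoveryReport",
    "draw_person_parameters",
    "simulate_esm",
    "recovery_experiment",
    "default_gamma",
    "default_sigma",
    "default_omega",
]

DEFAULT_VARIABLES = ["cheerful", "event", "worry", "fearful", "sad", "relaxed"]
#: indices of positively vs negatively valenced items in DEFAULT_VARIABLES
_POS = (0, 1, 5)
_NEG = (2, 3, 4)


def default_gamma(J: int = 6) -> np.ndarray:
    """Population transition matrix: positive self-loops ~0.2, mild
    excitatory links within a valence cluster, mild inhibitory links
    across clusters (only defined with this structure for J = 6)."""
    if J != 6:
        g = np.full((J, J), 0.03)
        np.fill_diagonal(g, 0.2)
        return g
    g = np.zeros((6, 6))
    np.fill_diagonal(g, 0.2)
    for j in _POS:
        for k in _POS:
            if j != k:
                g[j, k] = 0.06
    for j in _NEG:
        for k in _NEG:
            if j != k:
                g[j, k] = 0.06
    for j in _POS:
        for k in _NEG:
            g[j, k] = -0.05
            g[k, j] = -0.05
    g[4, 2] = 0.10  # worry feeds sadness
    g[3, 2] = 0.08  # worry feeds fear
    return g


def default_sigma(J: int = 6, var: float = 0.8) -> np.ndarray:
    """Innovation covariance with positive within-valence and negative
    cross-valence contemporaneous correlation."""
    corr = np.eye(J)
    if J == 6:
        for grp in (_POS, _NEG):
            for j in grp:
                for k in grp:
                    if j != k:
                        corr[j, k] = 0.3
        for j in _POS:
            for k in _NEG:
                corr[j, k] = corr[k, j] = -0.15
    return var * corr


def default_omega(J: int = 6, intercept_sd: float = 0.3,
                  own_sd: float = 0.1, cross_sd: float = 0.05) -> list[np.ndarray]:
    """Per-equation diagonal random-effect covariances: intercept SD 0.3,
    own-lag (self-loop) SD 0.1, cross-lag SD 0.05."""
    out = []
    for j in range(J):
        sds = np.full(J + 1, cross_sd)
        sds[0] = intercept_sd
        sds[j + 1] = own_sd
        out.append(np.diag(sds**2))
    return out


@dataclass
class SimulationConfig:
    """Generative parameters for a synthetic ESM study.

    ``n_days`` is days per period; with ``n_periods=2`` the second block is
    the post-baseline period (therapy effects, if any, apply there to
    treated persons). ``gamma`` is the population transition matrix,
    ``omega`` the per-equation (J+1)x(J+1) random-effect covariances
    (intercept first), ``sigma`` the innovation covariance.
    """

    variables: Sequence[str] = tuple(DEFAULT_VARIABLES)
    n_persons: int = 100
    n_days: int = 6
    n_beeps: int = 10
    n_periods: int = 1
    gamma: np.ndarray | None = None
    intercepts: np.ndarray | None = None
    omega: Sequence[np.ndarray] | None = None
    sigma: np.ndarray | None = None
    missing_rate: float = 0.18
    therapy_effect: np.ndarray | None = None
    treated_fraction: float = 63 / 129
    neuro_effect: np.ndarray | None = None
    neuro_mean: float = 40.7
    neuro_sd: float = 7.4
    neuro_bounds: tuple[float, float] = (12.0, 60.0)
    neuro_boundaries: tuple[float, float] = (34.5, 45.5)
    scale: tuple[float, float] = (1.0, 7.0)
    stationary_means: np.ndarray | None = None
    quantize: bool = False
    #: correlation between random deviations of *different* equations
    #: (robustness-study option; the estimator cannot identify it, so the
    #: default generator keeps equations independent)
    cross_equation_corr: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        self.variables = list(self.variables)
        J = len(self.variables)
        if self.gamma is None:
            self.gamma = default_gamma(J)
        self.gamma = np.asarray(self.gamma, dtype=float)
        if self.gamma.shape != (J, J):
            raise ValueError(f"gamma must be {J}x{J}")
        if self.sigma is None:
            self.sigma = default_sigma(J)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if self.omega is None:
            self.omega = default_omega(J)
        self.omega = [np.asarray(o, dtype=float) for o in self.omega]
        if len(self.omega) == 1 and J > 1:
            self.omega = [self.omega[0]] * J
        if self.stationary_means is None:
            # mid-scale means: positives high, negatives low on the Likert scale
            lo, hi = self.scale
            span = hi - lo
            m = np.full(J, lo + 0.5 * span)
            if self.variables == DEFAULT_VARIABLES:
                m[list(_POS)] = lo + 0.58 * span
                m[list(_NEG)] = lo + 0.25 * span
            self.stationary_means = m
        self.stationary_means = np.asarray(self.stationary_means, dtype=float)
        if self.intercepts is None:
            self.intercepts = (np.eye(J) - self.gamma) @ self.stationary_means
        self.intercepts = np.asarray(self.intercepts, dtype=float)
        self.validate()

    def validate(self) -> None:
        J = len(self.variables)
        rho = float(np.max(np.abs(np.linalg.eigvals(self.gamma))))
        if rho >= 1.0:
            raise ValueError(f"spectral radius of gamma is {rho:.3f} >= 1")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        for name, m in [("sigma", self.sigma)] + [
            (f"omega[{j}]", o) for j, o in enumerate(self.omega)
        ]:
            m = np.asarray(m)
            want = (J, J) if name == "sigma" else (J + 1, J + 1)
            if m.shape != want:
                raise ValueError(f"{name} must have shape {want}, got {m.shape}")
            if not np.allclose(m, m.T):
                raise ValueError(f"{name} must be symmetric")
            if np.min(np.linalg.eigvalsh(m)) < -1e-10:
                raise ValueError(f"{name} must be positive semi-definite")
        if not -1.0 < self.cross_equation_corr < 1.0:
            raise ValueError("cross_equation_corr must lie in (-1, 1)")
        if self.cross_equation_corr:
            if np.min(np.linalg.eigvalsh(self.joint_omega())) < -1e-10:
                raise ValueError(
                    "cross_equation_corr makes the joint deviation covariance indefinite"
                )

    @property
    def n_variables(self) -> int:
        return len(self.variables)

    def joint_omega(self) -> np.ndarray:
        """Covariance of all J*(J+1) stacked deviations: the per-equation
        blocks on the diagonal, and ``cross_equation_corr`` scaled by the
        marginal SDs between entries of different equations."""
        J = self.n_variables
        k = J + 1
        C = np.zeros((J * k, J * k))
        sds = np.concatenate([np.sqrt(np.diag(o)) for o in self.omega])
        for j in range(J):
            C[j * k:(j + 1) * k, j * k:(j + 1) * k] = self.omega[j]
        if self.cross_equation_corr:
            cross = self.cross_equation_corr * np.outer(sds, sds)
            for j in range(J):
                for i in range(J):
                    if i != j:
                        C[j * k:(j + 1) * k, i * k:(i + 1) * k] = cross[
                            j * k:(j + 1) * k, i * k:(i + 1) * k
                        ]
        return C

    #: SD of the random slope deviation on link (j, k), for recovery reports
    def slope_sd_matrix(self) -> np.ndarray:
        J = self.n_variables
        return np.array(
            [[np.sqrt(self.omega[j][k + 1, k + 1]) for k in range(J)] for j in range(J)]
        )


@dataclass
class PersonParams:
    """Per-person generative parameters (baseline period)."""

    intercepts: np.ndarray  #: (P, J)
    phi: np.ndarray  #: (P, J, J), includes neuroticism-group shifts
    n_redraws: int
    n_shrunk: int


def _psd_factor(m: np.ndarray) -> np.ndarray:
    """Square root factor of a PSD matrix (eigen-based; tolerates singular)."""
    vals, vecs = np.linalg.eigh(m)
    vals = np.clip(vals, 0.0, None)
    return vecs * np.sqrt(vals)


def draw_person_parameters(
    config: SimulationConfig,
    rng: np.random.Generator,
    neuro_groups: np.ndarray | None = None,
) -> PersonParams:
    """Draw person-specific intercepts and transition matrices.

    Deviations are drawn independently across equations by default
    (matching what the pseudo-likelihood fit can identify);
    ``cross_equation_corr`` switches to a joint draw for robustness
    studies. Persons whose matrix has spectral radius >= 0.98 are redrawn
    up to 100 times, then their deviations are shrunk toward the
    population matrix until stable.
    """
    J, P = config.n_variables, config.n_persons
    if config.cross_equation_corr:
        joint_factor = _psd_factor(config.joint_omega())
        factors = None
    else:
        joint_factor = None
        factors = [_psd_factor(o) for o in config.omega]
    target = np.asarray(config.gamma)
    base_shift = np.zeros((P, J, J))
    if config.neuro_effect is not None and neuro_groups is not None:
        base_shift = neuro_groups[:, None, None] * np.asarray(config.neuro_effect)
    phi = np.empty((P, J, J))
    icpt = np.empty((P, J))
    n_redraws = n_shrunk = 0
    for p in range(P):
        for _attempt in range(100):
            if joint_factor is not None:
                dev = (joint_factor @ rng.standard_normal(J * (J + 1))).reshape(J, J + 1)
            else:
                dev = np.empty((J, J + 1))
                for j in range(J):
                    dev[j] = factors[j] @ rng.standard_normal(J + 1)
            cand = target + base_shift[p] + dev[:, 1:]
            if np.max(np.abs(np.linalg.eigvals(cand))) < 0.98:
                break
            n_redraws += 1
        else:
            # shrink the last draw's deviations toward the population matrix
            for _ in range(60):
                dev *= 0.5
                cand = target + base_shift[p] + dev[:, 1:]
                n_shrunk += 1
                if np.max(np.abs(np.linalg.eigvals(cand))) < 0.98:
                    break
            else:
                raise RuntimeError(
                    "persistent nonstationary person draws; the population "
                    "matrix (plus moderator shifts) itself appears unstable"
                )
        phi[p] = cand
        icpt[p] = config.intercepts + dev[:, 0]
    return PersonParams(icpt, phi, n_redraws, n_shrunk)


def _stationary_start(mu: np.ndarray, phi: np.ndarray, sigma: np.ndarray,
                      rng: np.random.Generator) -> np.ndarray:
    """One draw from the within-day stationary distribution; falls back to a
    50-step burn-in from the mean when the Lyapunov solve misbehaves."""
    J = len(mu)
    mean = np.linalg.solve(np.eye(J) - phi, mu)
    try:
        cov = sla.solve_discrete_lyapunov(phi, sigma)
        cov = (cov + cov.T) / 2
        return mean + _psd_factor(cov) @ rng.standard_normal(J)
    except (np.linalg.LinAlgError, ValueError):
        f = _psd_factor(sigma)
        y = mean.copy()
        for _ in range(50):
            y = mu + phi @ y + f @ rng.standard_normal(J)
        return y


def simulate_esm(config: SimulationConfig) -> ESMDataset:
    """Generate a synthetic ESM dataset from the hierarchical VAR(1) model.

    Day numbering runs across periods (period q covers days
    q*n_days+1 .. (q+1)*n_days). Clock times place beep b in the b-th
    90-minute block starting 07:30, uniformly within the block.
    """
    rng = np.random.default_rng(config.seed)
    J, P = config.n_variables, config.n_persons
    therapy = (rng.random(P) < config.treated_fraction).astype(int)
    neuro = np.clip(
        np.round(rng.normal(config.neuro_mean, config.neuro_sd, size=P)),
        *config.neuro_bounds,
    )
    b1, b2 = config.neuro_boundaries
    groups = (neuro >= b1).astype(int) + (neuro > b2).astype(int)
    params = draw_person_parameters(
        config, rng, neuro_groups=groups if config.neuro_effect is not None else None
    )
    sig_factor = _psd_factor(config.sigma)
    records = []
    person_ids = np.arange(1, P + 1)
    for p in range(P):
        for q in range(config.n_periods):
            phi = params.phi[p]
            if q >= 1 and config.therapy_effect is not None and therapy[p]:
                phi = phi + np.asarray(config.therapy_effect)
            mu = params.intercepts[p]
            for d in range(1, config.n_days + 1):
                day = q * config.n_days + d
                y = _stationary_start(mu, phi, config.sigma, rng)
                for b in range(1, config.n_beeps + 1):
                    if b > 1:
                        y = mu + phi @ y + sig_factor @ rng.standard_normal(J)
                    if rng.random() < config.missing_rate:
                        continue
                    vals = y
                    if config.quantize:
                        vals = np.clip(np.round(y), *config.scale)
                    records.append(
                        (person_ids[p], day, b,
                         7.5 + 1.5 * (b - 1) + rng.uniform(0.0, 1.5),
                         q, therapy[p], neuro[p], *vals)
                    )
    df = pd.DataFrame(
        records,
        columns=[PERSON, DAY, BEEP, TIME, PERIOD, THERAPY, NEUROTICISM, *config.variables],
    )
    scale = config.scale
    if not config.quantize:
        # continuous draws can exceed the nominal response scale; declare
        # bounds wide enough to hold the realized values
        lo = min(scale[0], float(df[config.variables].min().min()) - 1e-9)
        hi = max(scale[1], float(df[config.variables].max().max()) + 1e-9)
        scale = (lo, hi)
    return ESMDataset(df, list(config.variables), scale)


# ---------------------------------------------------------------------------
# Parameter-recovery harness


@dataclass
class RecoveryReport:
    """Monte-Carlo recovery of generator parameters by the stacked fit."""

    config: SimulationConfig
    n_reps: int
    n_failures: int
    gamma_true: np.ndarray
    gamma_mean: np.ndarray  #: element-wise mean of Phi-hat across replicates
    gamma_bias: np.ndarray
    gamma_rmse: np.ndarray
    sd_true: np.ndarray
    sd_mean: np.ndarray
    resid_corr_true: np.ndarray
    resid_corr_mean: np.ndarray
    seeds: list[int]

    @property
    def mean_abs_bias(self) -> float:
        return float(np.mean(np.abs(self.gamma_bias)))

    def table(self) -> pd.DataFrame:
        J = len(self.config.variables)
        rows = []
        for j in range(J):
            for k in range(J):
                rows.append(
                    {
                        "response": self.config.variables[j],
                        "predictor": self.config.variables[k],
                        "true": self.gamma_true[j, k],
                        "mean_estimate": self.gamma_mean[j, k],
                        "bias": self.gamma_bias[j, k],
                        "rmse": self.gamma_rmse[j, k],
                        "sd_true": self.sd_true[j, k],
                        "sd_mean_estimate": self.sd_mean[j, k],
                    }
                )
        return pd.DataFrame(rows)


def recovery_experiment(
    config: SimulationConfig,
    n_reps: int = 20,
    fit_spec=None,
    seed: int | None = None,
) -> RecoveryReport:
    """Simulate-and-refit ``n_reps`` times; report bias and RMSE.

    Each replicate simulates a dataset, builds the lagged design and runs
    the stacked mixed-model fit (unstructured within-equation covariance by
    default, the same specification as the primary model). Replicates whose
    fit fails are counted, not fatal.
    """
    from .model import RandomSpec, fit_mlvar  # local import avoids cycle

    spec = fit_spec or RandomSpec()
    master = np.random.default_rng(config.seed if seed is None else seed)
    seeds = [int(master.integers(2**31)) for _ in range(n_reps)]
    phis, sds, rcorrs = [], [], []
    n_fail = 0
    for s in seeds:
        data = simulate_esm(replace(config, seed=s))
        design = build_lagged_design(data)
        model = fit_mlvar(design, spec)
        if model.errors:
            n_fail += 1
            continue
        phis.append(model.Phi)
        sds.append(model.Sd)
        rcorrs.append(model.resid_corr)
    if not phis:
        raise RuntimeError("every recovery replicate failed")
    phis = np.array(phis)
    gamma_mean = phis.mean(axis=0)
    gamma_true = np.asarray(config.gamma)
    d = np.asarray(config.sigma).diagonal()
    with np.errstate(invalid="ignore", divide="ignore"):
        rc_true = config.sigma / np.sqrt(np.outer(d, d))
    rc_true = np.where(np.isfinite(rc_true), rc_true, 0.0)
    np.fill_diagonal(rc_true, 1.0)
    return RecoveryReport(
        config=config, n_reps=n_reps, n_failures=n_fail,
        gamma_true=gamma_true, gamma_mean=gamma_mean,
        gamma_bias=gamma_mean - gamma_true,
        gamma_rmse=np.sqrt(((phis - gamma_true) ** 2).mean(axis=0)),
        sd_true=config.slope_sd_matrix(), sd_mean=np.array(sds).mean(axis=0),
        resid_corr_true=rc_true, resid_corr_mean=np.array(rcorrs).mean(axis=0),
        seeds=seeds,
    )
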