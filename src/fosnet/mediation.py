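"""Bayesian path/mediation analysis of the DG excitatory/inhibitory microcircuit.

The model is a fully observed recursive linear-Gaussian path system over the
four microcircuit variables (PV_H exogenous; MC, PV_GL, GC endogenous):

* model 1 (with indirect paths)::

      MC    ~ a1 * PV_H
      PV_GL ~ a2 * MC
      GC    ~ b1 * MC + b2 * PV_GL + b3 * PV_H

  with the two theoretical indirect paths MC -> PV_GL -> GC (``a2 * b2``) and
  PV_H -> MC -> GC (``a1 * b1``) and their totals derived per posterior draw;

* model 2 (direct effects only): the single GC regression.

Because the system is recursive and fully observed, the likelihood factorizes
into independent regressions; the joint posterior is sampled by a blocked
Gibbs scheme — the coefficient vector of each equation has a conjugate normal
conditional under its normal(0, sd) prior, and the residual scale (half-normal
prior) is updated with a univariate slice step on log sigma.  Four chains with
over-dispersed starts are run by default (1,000 warmup, 5,000 retained each,
the release settings); reduced settings are accepted everywhere.

Reported effects are standardized per draw by the predictor/outcome standard
deviations of the data as fitted (inputs are centered and scaled within group
by default, so standardized betas are the natural output scale).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Sequence

import arviz as az
import numpy as np
import pandas as pd

__all__ = [
    "PathModelSpec",
    "PosteriorDraws",
    "EffectSummary",
    "fit_path_model",
    "fit_restricted_model",
    "rhat",
    "posterior_predictive_p",
    "information_criteria",
    "derived_effects",
    "multigroup_fit_compare",
    "group_difference",
    "r_squared_gc",
]

logger = logging.getLogger(__name__)

MODEL1_EQUATIONS: tuple[tuple[str, tuple[str, ...]], ...] = (
    ("MC", ("PV_H",)),
    ("PV_GL", ("MC",)),
    ("GC", ("MC", "PV_GL", "PV_H")),
)
MODEL2_EQUATIONS: tuple[tuple[str, tuple[str, ...]], ...] = (
    ("GC", ("MC", "PV_GL", "PV_H")),
)

#: Canonical short names for the microcircuit paths.
PATH_NAMES: dict[tuple[str, str], str] = {
    ("MC", "PV_H"): "a1",
    ("PV_GL", "MC"): "a2",
    ("GC", "MC"): "b1",
    ("GC", "PV_GL"): "b2",
    ("GC", "PV_H"): "b3",
}


def _coef_name(outcome: str, predictor: str) -> str:
    return PATH_NAMES.get((outcome, predictor), f"{outcome}~{predictor}")


@dataclass(frozen=True)
class PathModelSpec:
    """Which path system to fit, and its priors.

    Coefficients get normal(0, ``coef_prior_sd``) priors; residual scales get
    half-normal(``resid_prior_scale``) priors.  Both are recorded in output
    metadata so results are self-describing.
    """

    model_id: str = "model1_with_indirect"
    coef_prior_sd: float = 10.0
    resid_prior_scale: float = 10.0
    constrain_equal_across_groups: bool = False
    equations: tuple[tuple[str, tuple[str, ...]], ...] | None = None

    def __post_init__(self) -> None:
        if self.model_id not in ("model1_with_indirect", "model2_direct_only"):
            if self.equations is None:
                raise ValueError(f"unknown model_id {self.model_id!r}")
        if self.coef_prior_sd <= 0 or self.resid_prior_scale <= 0:
            raise ValueError("prior scales must be positive")
        eqs = self.resolved_equations
        seen: set[str] = set()
        for outcome, predictors in eqs:
            if any(p == outcome for p in predictors):
                raise ValueError(f"{outcome} cannot predict itself")
            if outcome in seen:
                raise ValueError(f"duplicate equation for {outcome}")
            for p in predictors:
                if p in seen:
                    continue
            seen.add(outcome)
        # the equation list must be a valid topological order (recursive system)
        defined: set[str] = set()
        outcomes = {o for o, _ in eqs}
        for outcome, predictors in eqs:
            for p in predictors:
                if p in outcomes and p not in defined:
                    raise ValueError(
                        "equations must be listed in causal order "
                        f"({p} is used before it is modeled)"
                    )
            defined.add(outcome)

    @property
    def resolved_equations(self) -> tuple[tuple[str, tuple[str, ...]], ...]:
        if self.equations is not None:
            return self.equations
        if self.model_id == "model1_with_indirect":
            return MODEL1_EQUATIONS
        return MODEL2_EQUATIONS

    @property
    def variables(self) -> list[str]:
        seen: list[str] = []
        for outcome, predictors in self.resolved_equations:
            for v in (*predictors, outcome):
                if v not in seen:
                    seen.append(v)
        return seen


@dataclass
class PosteriorDraws:
    """MCMC draws of every path coefficient and residual scale.

    ``params`` maps parameter name to a (chains, draws) array.  ``data``
    holds the data exactly as fitted (after centering/scaling), which the
    diagnostic and effect operations reuse.
    """

    params: dict[str, np.ndarray]
    spec: PathModelSpec
    data: pd.DataFrame
    seed: int
    chains: int
    warmup: int
    draws: int
    scale_info: dict[str, tuple[float, float]] = field(default_factory=dict)
    group: str | None = None

    def stacked(self, name: str) -> np.ndarray:
        return self.params[name].reshape(-1)

    def to_arviz(self, log_likelihood: np.ndarray | None = None) -> az.InferenceData:
        kwargs = {}
        if log_likelihood is not None:
            kwargs["log_likelihood"] = {"obs": log_likelihood}
        return az.from_dict(posterior=self.params, **kwargs)

    @property
    def coefficient_names(self) -> list[str]:
        return [
            _coef_name(outcome, p)
            for outcome, predictors in self.spec.resolved_equations
            for p in predictors
        ]


class InformationCriteria(NamedTuple):
    dic: float
    waic: float
    looic: float


@dataclass
class EffectSummary:
    """Standardized direct/indirect/total effects with 95% credible intervals.

    ``draws`` maps each effect name to its standardized posterior draws
    (flattened over chains); indirect-effect draws are the exact per-draw
    products of their component-path draws.
    """

    table: pd.DataFrame
    draws: dict[str, np.ndarray]
    r_squared_gc: float


# ---------------------------------------------------------------------------
# sampler internals

def _slice_log_sigma(
    u: float, n: int, ssr: float, prior_scale: float, rng: np.random.Generator,
    width: float = 1.0, max_steps: int = 50,
) -> float:
    """One slice-sampling update of log(sigma) for a Gaussian regression.

    Target: sigma^-n exp(-ssr / (2 sigma^2)) * HalfNormal(sigma | prior_scale),
    with the log-transform Jacobian.
    """
    def logf(v: float) -> float:
        s2 = np.exp(2.0 * v)
        return -(n - 1) * v - 0.5 * ssr / s2 - 0.5 * s2 / prior_scale**2

    level = logf(u) - rng.exponential()
    left = u - width * rng.uniform()
    right = left + width
    for _ in range(max_steps):
        if logf(left) <= level:
            break
        left -= width
    for _ in range(max_steps):
        if logf(right) <= level:
            break
        right += width
    while True:
        prop = rng.uniform(left, right)
        if logf(prop) > level:
            return prop
        if prop < u:
            left = prop
        else:
            right = prop


def _gibbs_regression(
    y: np.ndarray,
    x: np.ndarray,
    coef_prior_sd: float,
    resid_prior_scale: float,
    chains: int,
    warmup: int,
    draws: int,
    seeds: Sequence[np.random.SeedSequence],
) -> tuple[np.ndarray, np.ndarray]:
    """Sample one regression; returns betas (chains, draws, p) and sigmas."""
    n, p = x.shape
    xtx = x.T @ x
    xty = x.T @ y
    yty = float(y @ y)
    prior_prec = np.eye(p) / coef_prior_sd**2
    betas = np.empty((chains, draws, p))
    sigmas = np.empty((chains, draws))
    for c in range(chains):
        rng = np.random.default_rng(seeds[c])
        beta = rng.normal(0.0, 0.5, size=p)  # over-dispersed starts
        log_sigma = rng.normal(0.0, 0.5)
        for it in range(warmup + draws):
            sigma2 = np.exp(2.0 * log_sigma)
            prec = xtx / sigma2 + prior_prec
            chol = np.linalg.cholesky(prec)
            mean = np.linalg.solve(prec, xty / sigma2)
            z = rng.standard_normal(p)
            beta = mean + np.linalg.solve(chol.T, z)
            ssr = yty - 2.0 * beta @ xty + beta @ xtx @ beta
            log_sigma = _slice_log_sigma(log_sigma, n, ssr, resid_prior_scale, rng)
            if it >= warmup:
                betas[c, it - warmup] = beta
                sigmas[c, it - warmup] = np.exp(log_sigma)
    if not (np.isfinite(betas).all() and np.isfinite(sigmas).all()):
        raise RuntimeError("sampler produced non-finite draws")
    return betas, sigmas


def _prepare_data(
    data: pd.DataFrame, spec: PathModelSpec, standardize: bool
) -> tuple[pd.DataFrame, dict[str, tuple[float, float]]]:
    variables = spec.variables
    missing = [v for v in variables if v not in data.columns]
    if missing:
        raise ValueError(f"data lacks required columns: {missing}")
    sub = data[variables].astype(float)
    if not np.isfinite(sub.to_numpy()).all():
        raise ValueError("data contains missing or non-finite values")
    if len(sub) < 4:
        raise ValueError("at least 4 animals are required")
    scale_info = {}
    out = sub.copy()
    for v in variables:
        mu = float(sub[v].mean())
        sd = float(sub[v].std(ddof=1))
        if standardize and sd == 0:
            raise ValueError(f"variable {v!r} is constant; cannot standardize")
        scale_info[v] = (mu, sd)
        out[v] = (sub[v] - mu) / (sd if standardize else 1.0)
    return out, scale_info


def fit_path_model(
    data: pd.DataFrame,
    spec: PathModelSpec | None = None,
    chains: int = 4,
    warmup: int = 1000,
    draws: int = 5000,
    seed: int = 0,
    standardize: bool = True,
) -> PosteriorDraws:
    """Sample the joint posterior of the path system on one group's data.

    Input variables are centered (and, by default, scaled) before fitting, so
    no intercepts are needed and coefficients are on the standardized scale.
    Deterministic under a fixed seed.
    """
    spec = spec or PathModelSpec()
    fitted, scale_info = _prepare_data(data, spec, standardize)
    root = np.random.SeedSequence(seed)
    params: dict[str, np.ndarray] = {}
    for eq_index, (outcome, predictors) in enumerate(spec.resolved_equations):
        eq_seeds = np.random.SeedSequence([seed, eq_index]).spawn(chains)
        y = fitted[outcome].to_numpy()
        x = fitted[list(predictors)].to_numpy()
        betas, sigmas = _gibbs_regression(
            y, x, spec.coef_prior_sd, spec.resid_prior_scale,
            chains, warmup, draws, eq_seeds,
        )
        for k, predictor in enumerate(predictors):
            params[_coef_name(outcome, predictor)] = betas[:, :, k]
        params[f"sigma_{outcome}"] = sigmas
    return PosteriorDraws(
        params=params, spec=spec, data=fitted, seed=seed, chains=chains,
        warmup=warmup, draws=draws, scale_info=scale_info,
    )


def fit_restricted_model(
    data_by_group: Mapping[str, pd.DataFrame],
    spec: PathModelSpec | None = None,
    chains: int = 4,
    warmup: int = 1000,
    draws: int = 5000,
    seed: int = 0,
    standardize: bool = True,
) -> dict:
    """Multigroup fit with coefficients shared and residual scales free.

    Returns a dict with the shared-coefficient draws, per-group residual-scale
    draws (``sigma_<outcome>[<group>]``), and the per-group fitted data.
    """
    spec = spec or PathModelSpec(constrain_equal_across_groups=True)
    groups = list(data_by_group)
    fitted, scales = {}, {}
    for g in groups:
        fitted[g], scales[g] = _prepare_data(data_by_group[g], spec, standardize)
    params: dict[str, np.ndarray] = {}
    for eq_index, (outcome, predictors) in enumerate(spec.resolved_equations):
        p = len(predictors)
        mats = {
            g: (
                fitted[g][outcome].to_numpy(),
                fitted[g][list(predictors)].to_numpy(),
            )
            for g in groups
        }
        moments = {
            g: (x.T @ x, x.T @ y, float(y @ y), len(y)) for g, (y, x) in mats.items()
        }
        prior_prec = np.eye(p) / spec.coef_prior_sd**2
        betas = np.empty((chains, draws, p))
        sigmas = {g: np.empty((chains, draws)) for g in groups}
        eq_seeds = np.random.SeedSequence([seed, 100 + eq_index]).spawn(chains)
        for c in range(chains):
            rng = np.random.default_rng(eq_seeds[c])
            beta = rng.normal(0.0, 0.5, size=p)
            log_sig = {g: rng.normal(0.0, 0.5) for g in groups}
            for it in range(warmup + draws):
                prec = prior_prec.copy()
                rhs = np.zeros(p)
                for g in groups:
                    xtx, xty, _, _ = moments[g]
                    s2 = np.exp(2.0 * log_sig[g])
                    prec += xtx / s2
                    rhs += xty / s2
                chol = np.linalg.cholesky(prec)
                mean = np.linalg.solve(prec, rhs)
                beta = mean + np.linalg.solve(chol.T, rng.standard_normal(p))
                for g in groups:
                    xtx, xty, yty, n_g = moments[g]
                    ssr = yty - 2.0 * beta @ xty + beta @ xtx @ beta
                    log_sig[g] = _slice_log_sigma(
                        log_sig[g], n_g, ssr, spec.resid_prior_scale, rng
                    )
                if it >= warmup:
                    betas[c, it - warmup] = beta
                    for g in groups:
                        sigmas[g][c, it - warmup] = np.exp(log_sig[g])
        for k, predictor in enumerate(predictors):
            params[_coef_name(outcome, predictor)] = betas[:, :, k]
        for g in groups:
            params[f"sigma_{outcome}[{g}]"] = sigmas[g]
    return {
        "params": params, "spec": spec, "data": fitted, "seed": seed,
        "chains": chains, "warmup": warmup, "draws": draws, "scales": scales,
    }


# ---------------------------------------------------------------------------
# diagnostics

def rhat(posterior: PosteriorDraws) -> dict[str, float]:
    """Split-chain potential scale reduction factor per parameter."""
    if posterior.chains < 2:
        raise ValueError("R-hat requires at least 2 chains")
    flat = {k: v for k, v in posterior.params.items()}
    for name, arr in flat.items():
        if np.allclose(arr.var(axis=1), 0.0):
            logger.warning("zero within-chain variance for %s; R-hat undefined", name)
    result = az.rhat(az.from_dict(posterior=flat))
    return {name: float(result[name].values) for name in flat}


def pointwise_loglik(posterior: PosteriorDraws) -> np.ndarray:
    """Per-observation log likelihood of the whole system, (chains, draws, n)."""
    data = posterior.data
    n = len(data)
    total = np.zeros((posterior.chains, posterior.draws, n))
    for outcome, predictors in posterior.spec.resolved_equations:
        y = data[outcome].to_numpy()
        x = data[list(predictors)].to_numpy()
        beta = np.stack(
            [posterior.params[_coef_name(outcome, p)] for p in predictors], axis=-1
        )  # (chains, draws, p)
        sigma = posterior.params[f"sigma_{outcome}"]  # (chains, draws)
        mu = np.einsum("cdp,np->cdn", beta, x)
        resid = y[None, None, :] - mu
        total += (
            -0.5 * np.log(2.0 * np.pi)
            - np.log(sigma)[:, :, None]
            - 0.5 * (resid / sigma[:, :, None]) ** 2
        )
    return total


def _deviance_at_posterior_mean(posterior: PosteriorDraws) -> float:
    data = posterior.data
    total = 0.0
    n = len(data)
    for outcome, predictors in posterior.spec.resolved_equations:
        y = data[outcome].to_numpy()
        x = data[list(predictors)].to_numpy()
        beta = np.array(
            [posterior.params[_coef_name(outcome, p)].mean() for p in predictors]
        )
        sigma = float(posterior.params[f"sigma_{outcome}"].mean())
        resid = y - x @ beta
        total += (
            -0.5 * n * np.log(2.0 * np.pi)
            - n * np.log(sigma)
            - 0.5 * float((resid / sigma) @ (resid / sigma))
        )
    return -2.0 * total


def dic(posterior: PosteriorDraws) -> float:
    """Deviance information criterion: mean deviance plus p_D."""
    ll = pointwise_loglik(posterior).sum(axis=-1)
    mean_deviance = float((-2.0 * ll).mean())
    p_d = mean_deviance - _deviance_at_posterior_mean(posterior)
    return mean_deviance + p_d


def information_criteria(
    posterior: PosteriorDraws, data: pd.DataFrame | None = None,
    spec: PathModelSpec | None = None,
) -> InformationCriteria:
    """DIC, WAIC and LOOIC (deviance scale) for the fitted system.

    WAIC and LOOIC come from the pointwise log predictive density (arviz);
    unstable importance weights are reported as a warning with the count of
    flagged observations.
    """
    ll = pointwise_loglik(posterior)
    idata = posterior.to_arviz(log_likelihood=ll)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        waic_res = az.waic(idata, scale="deviance")
        loo_res = az.loo(idata, scale="deviance")
    k = np.asarray(loo_res.pareto_k)
    n_bad = int((k > 0.7).sum())
    if n_bad:
        warnings.warn(
            f"unstable importance weights for {n_bad} observation(s); "
            "LOOIC may be optimistic"
        )
    return InformationCriteria(
        dic=float(dic(posterior)),
        waic=float(waic_res.elpd_waic),
        looic=float(loo_res.elpd_loo),
    )


def posterior_predictive_p(
    posterior: PosteriorDraws,
    data: pd.DataFrame | None = None,
    spec: PathModelSpec | None = None,
    max_draws: int = 1000,
    seed: int = 0,
) -> float:
    """Moment-based posterior predictive p-value; near 0.5 indicates good fit.

    Discrepancy per draw: the maximum-likelihood covariance discrepancy
    ``log|Sigma| - log|S| + tr(S Sigma^-1) - p`` between a sample covariance
    ``S`` and the draw's model-implied covariance, evaluated for the observed
    data and for a same-size replicate simulated from the draw.  PPP is the
    fraction of draws where the replicate discrepancy is at least the observed
    one.
    """
    data = posterior.data if data is None else data
    spec = spec or posterior.spec
    variables = spec.variables
    outcomes = [o for o, _ in spec.resolved_equations]
    exo = [v for v in variables if v not in outcomes]
    order = exo + outcomes
    idx = {v: i for i, v in enumerate(order)}
    x_obs = data[order].to_numpy()
    n, k = x_obs.shape
    s_obs = np.cov(x_obs, rowvar=False)
    s_exo = np.atleast_2d(np.cov(data[exo].to_numpy(), rowvar=False)) if exo else None

    coef_draws = {
        (outcome, p): posterior.stacked(_coef_name(outcome, p))
        for outcome, predictors in spec.resolved_equations
        for p in predictors
    }
    sigma_draws = {o: posterior.stacked(f"sigma_{o}") for o in outcomes}
    total = next(iter(sigma_draws.values())).size
    rng = np.random.default_rng(seed)
    take = (
        rng.choice(total, size=max_draws, replace=False)
        if total > max_draws else np.arange(total)
    )
    exceed = 0
    chol_exo = np.linalg.cholesky(s_exo) if exo else None
    sign_obs, logdet_obs = np.linalg.slogdet(s_obs)
    if sign_obs <= 0:
        raise ValueError("observed covariance matrix is singular")
    for d in take:
        b = np.zeros((k, k))
        psi = np.zeros((k, k))
        if exo:
            psi[: len(exo), : len(exo)] = s_exo
        for outcome, predictors in spec.resolved_equations:
            for p in predictors:
                b[idx[outcome], idx[p]] = coef_draws[(outcome, p)][d]
            psi[idx[outcome], idx[outcome]] = sigma_draws[outcome][d] ** 2
        a = np.linalg.inv(np.eye(k) - b)
        sigma_implied = a @ psi @ a.T
        sigma_inv = np.linalg.inv(sigma_implied)
        _, logdet_implied = np.linalg.slogdet(sigma_implied)

        def discrepancy(s: np.ndarray, logdet_s: float) -> float:
            return float(logdet_implied - logdet_s + np.trace(s @ sigma_inv) - k)

        f_obs = discrepancy(s_obs, logdet_obs)
        rep = np.zeros((n, k))
        if exo:
            rep[:, : len(exo)] = rng.standard_normal((n, len(exo))) @ chol_exo.T
        for outcome, predictors in spec.resolved_equations:
            mu = sum(
                coef_draws[(outcome, p)][d] * rep[:, idx[p]] for p in predictors
            )
            rep[:, idx[outcome]] = mu + rng.normal(
                0.0, sigma_draws[outcome][d], size=n
            )
        s_rep = np.cov(rep, rowvar=False)
        sign_rep, logdet_rep = np.linalg.slogdet(s_rep)
        f_rep = discrepancy(s_rep, logdet_rep)
        exceed += f_rep >= f_obs
    return float(exceed / len(take))


# ---------------------------------------------------------------------------
# derived effects and comparisons

def _std_coef_draws(posterior: PosteriorDraws) -> dict[str, np.ndarray]:
    """Coefficient draws standardized by sd(predictor)/sd(outcome) of the
    as-fitted data (exactly the raw draws when the fit standardized inputs)."""
    data = posterior.data
    sds = data.std(ddof=1)
    out = {}
    for outcome, predictors in posterior.spec.resolved_equations:
        for p in predictors:
            name = _coef_name(outcome, p)
            out[name] = posterior.stacked(name) * float(sds[p]) / float(sds[outcome])
    return out


def _summarize(draws: np.ndarray) -> tuple[float, float, float, bool]:
    lo, hi = np.percentile(draws, [2.5, 97.5])
    return float(draws.mean()), float(lo), float(hi), bool(lo > 0 or hi < 0)


def derived_effects(
    posterior: PosteriorDraws, data: pd.DataFrame | None = None
) -> EffectSummary:
    """Standardized direct, indirect and total effects with 95% CrIs.

    Indirect effects are per-draw products of their component paths:
    ``MC -> PV_GL -> GC = a2 * b2`` and ``PV_H -> MC -> GC = a1 * b1``.
    Totals: ``MC -> GC = b1 + a2*b2``; ``PV_H -> GC = b3 + a1*b1``.  The
    three-path chain ``PV_H -> MC -> PV_GL -> GC = a1*a2*b2`` is reported
    separately and folded into neither total.
    """
    if posterior.spec.model_id != "model1_with_indirect":
        raise ValueError("derived effects require the model with indirect paths")
    std = _std_coef_draws(posterior)
    a1, a2 = std["a1"], std["a2"]
    b1, b2, b3 = std["b1"], std["b2"], std["b3"]
    effects = {
        "direct PV_H->MC": a1,
        "direct MC->PV_GL": a2,
        "direct MC->GC": b1,
        "direct PV_GL->GC": b2,
        "direct PV_H->GC": b3,
        "indirect MC->PV_GL->GC": a2 * b2,
        "indirect PV_H->MC->GC": a1 * b1,
        "three-path PV_H->MC->PV_GL->GC": a1 * a2 * b2,
        "total MC->GC": b1 + a2 * b2,
        "total PV_H->GC": b3 + a1 * b1,
    }
    rows = []
    for name, draw in effects.items():
        mean, lo, hi, sig = _summarize(draw)
        rows.append((name, mean, lo, hi, sig))
    table = pd.DataFrame(
        rows, columns=["effect", "beta", "ci_low", "ci_high", "significant"]
    )
    return EffectSummary(
        table=table,
        draws={**effects, **{f"component {k}": v for k, v in std.items()}},
        r_squared_gc=r_squared_gc(posterior),
    )


def r_squared_gc(posterior: PosteriorDraws, data: pd.DataFrame | None = None) -> float:
    """Posterior-mean Bayesian R^2 of the granule-cell equation."""
    eqs = dict(posterior.spec.resolved_equations)
    if "GC" not in eqs:
        raise ValueError("model has no GC equation")
    predictors = list(eqs["GC"])
    data = posterior.data if data is None else data
    x = data[predictors].to_numpy()
    beta = np.stack(
        [posterior.params[_coef_name("GC", p)] for p in predictors], axis=-1
    )
    sigma = posterior.params["sigma_GC"]
    mu = np.einsum("cdp,np->cdn", beta, x)
    fit_var = mu.var(axis=-1, ddof=1)
    r2 = fit_var / (fit_var + sigma**2)
    return float(r2.mean())


def multigroup_fit_compare(
    data_by_group: Mapping[str, pd.DataFrame],
    spec: PathModelSpec | None = None,
    chains: int = 4,
    warmup: int = 1000,
    draws: int = 5000,
    seed: int = 0,
) -> dict:
    """Free (per-group) versus restricted (shared-coefficient) multigroup fit.

    Both are fitted; the preferred model is the one with the lower total DIC
    (free DIC sums the per-group fits; the restricted fit shares coefficients
    but keeps group-specific residual scales).
    """
    if len(data_by_group) < 2:
        raise ValueError("multigroup comparison needs at least two groups")
    spec = spec or PathModelSpec()
    free_fits: dict[str, PosteriorDraws] = {}
    dic_free = 0.0
    for g_index, (group, data) in enumerate(data_by_group.items()):
        try:
            fit = fit_path_model(
                data, spec, chains=chains, warmup=warmup, draws=draws,
                seed=seed + 1000 * (g_index + 1),
            )
        except Exception as err:  # noqa: BLE001 - re-raise with group context
            raise RuntimeError(f"fit failed for group {group!r}: {err}") from err
        fit.group = group
        free_fits[group] = fit
        dic_free += dic(fit)
    restricted = fit_restricted_model(
        data_by_group, spec, chains=chains, warmup=warmup, draws=draws, seed=seed
    )
    dic_restricted = _dic_restricted(restricted)
    return {
        "free": free_fits,
        "restricted": restricted,
        "dic_free": float(dic_free),
        "dic_restricted": float(dic_restricted),
        "preferred": "free" if dic_free < dic_restricted else "restricted",
    }


def _dic_restricted(restricted: dict) -> float:
    params = restricted["params"]
    spec: PathModelSpec = restricted["spec"]
    groups = list(restricted["data"])
    deviance_draws = None
    deviance_at_mean = 0.0
    for outcome, predictors in spec.resolved_equations:
        beta = np.stack(
            [params[_coef_name(outcome, p)] for p in predictors], axis=-1
        )
        beta_mean = beta.mean(axis=(0, 1))
        for g in groups:
            data = restricted["data"][g]
            y = data[outcome].to_numpy()
            x = data[list(predictors)].to_numpy()
            sigma = params[f"sigma_{outcome}[{g}]"]
            mu = np.einsum("cdp,np->cdn", beta, x)
            ll = (
                -0.5 * np.log(2.0 * np.pi)
                - np.log(sigma)[:, :, None]
                - 0.5 * ((y[None, None, :] - mu) / sigma[:, :, None]) ** 2
            ).sum(axis=-1)
            deviance_draws = -2.0 * ll if deviance_draws is None else deviance_draws - 2.0 * ll
            resid = y - x @ beta_mean
            sig_mean = float(sigma.mean())
            deviance_at_mean += -2.0 * (
                -0.5 * len(y) * np.log(2.0 * np.pi)
                - len(y) * np.log(sig_mean)
                - 0.5 * float((resid / sig_mean) @ (resid / sig_mean))
            )
    mean_dev = float(deviance_draws.mean())
    return mean_dev + (mean_dev - deviance_at_mean)


def group_difference(
    posterior_a: PosteriorDraws,
    posterior_b: PosteriorDraws,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-parameter posterior of the between-group difference (A minus B).

    Standardized coefficient draws from the two fits are subsampled (without
    replacement, seeded) to a common length and differenced pairwise; a
    parameter is flagged when the 95% CrI of the difference excludes zero or a
    sign probability exceeds 0.95.
    """
    std_a = _std_coef_draws(posterior_a)
    std_b = _std_coef_draws(posterior_b)
    shared = [k for k in std_a if k in std_b]
    if not shared:
        raise ValueError("the two posteriors share no parameters")
    rng = np.random.default_rng(seed)
    rows = []
    for name in shared:
        da, db = std_a[name], std_b[name]
        m = min(da.size, db.size)
        if da.size > m:
            da = da[rng.choice(da.size, size=m, replace=False)]
        if db.size > m:
            db = db[rng.choice(db.size, size=m, replace=False)]
        diff = da - db
        mean, lo, hi, ci_sig = _summarize(diff)
        p_pos = float((diff > 0).mean())
        p_neg = float((diff < 0).mean())
        rows.append(
            (name, mean, lo, hi, p_pos, p_neg, ci_sig or max(p_pos, p_neg) > 0.95)
        )
    return pd.DataFrame(
        rows,
        columns=["parameter", "diff_mean", "ci_low", "ci_high", "p_gt_0", "p_lt_0", "flagged"],
    )
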