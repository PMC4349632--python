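"""Hierarchical (Type-II ML / empirical Bayes) model fitting.

Subject-level parameters are treated as draws from independent Gaussian
group distributions in unconstrained space.  Fitting alternates an
E-step — per-subject MAP estimates with a Laplace (Gaussian) posterior
approximation around each mode — with an M-step that moment-matches the
group mean and variance to the approximate posteriors, i.e. the
standard Expectation-Maximization scheme for random-effects model
fitting.  Models are compared with the integrated Bayesian Information
Criterion

    iBIC = -2 * sum_i log p(D_i | group prior)  +  k * log(N),

where the per-subject marginal likelihoods are Laplace-approximated
integrals over the group prior, k counts group hyperparameters (a mean
and a variance per parameter) and N is the total number of free choices
pooled over subjects.  Goodness of fit is summarized by the Cox-Snell
pseudo-r-squared against a per-subject intercept-only baseline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .models import ChoiceArrays, ModelSpec, choice_arrays, get_model, nll_and_grad

VARIANCE_FLOOR = 1e-6
EM_TOL = 1e-4
EM_MAX_ITER = 100
N_RESTARTS = 5


@dataclass
class GroupPrior:
    """Independent Gaussian prior per parameter, unconstrained space."""

    param_names: tuple[str, ...]
    mean: np.ndarray
    var: np.ndarray

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.var = np.maximum(np.asarray(self.var, dtype=float), VARIANCE_FLOOR)

    def copy(self) -> "GroupPrior":
        return GroupPrior(self.param_names, self.mean.copy(), self.var.copy())


#: Generic starting point in unconstrained space: tau = 1, intercept at
#: the middle token value, weights at 0.5; broad initial group variance.
_INIT_MEAN = {"tau": 0.0, "c_int": 5.0, "w": 0.0, "w3": 0.0, "w5": 0.0, "w7": 0.0}
_INIT_VAR = 6.25


def default_prior(spec: ModelSpec) -> GroupPrior:
    mean = np.array([_INIT_MEAN[name] for name in spec.param_names])
    return GroupPrior(spec.param_names, mean, np.full(spec.n_params, _INIT_VAR))


@dataclass
class SubjectFit:
    """MAP estimate for one subject under a given group prior."""

    x_map: np.ndarray  # unconstrained MAP
    params: dict[str, float]  # native-space MAP
    hessian: np.ndarray  # of the negative log posterior at the mode
    posterior_cov: np.ndarray
    log_marginal: float  # Laplace-approximated log p(D_i | prior)
    nll: float  # data NLL at the MAP
    converged: bool
    n_choices: int


@dataclass
class FitResult:
    """Output of one hierarchical model fit."""

    model_id: str
    prior: GroupPrior
    subjects: dict[int, SubjectFit]
    log_marginal_total: float
    ibic: float
    n_total_choices: int
    n_iterations: int
    converged: bool
    objective_trace: list[float] = field(default_factory=list)
    variance_floor_hit: bool = False

    def map_table(self) -> pd.DataFrame:
        rows = []
        for sid, sf in sorted(self.subjects.items()):
            row = {"subject_id": sid, "nll": sf.nll, "n_choices": sf.n_choices}
            row.update(sf.params)
            rows.append(row)
        return pd.DataFrame(rows)

    def to_json(self) -> str:
        spec = get_model(self.model_id)
        payload = {
            "model_id": self.model_id,
            "group_prior": {
                "param_names": list(self.prior.param_names),
                "mean_unconstrained": self.prior.mean.tolist(),
                "var_unconstrained": self.prior.var.tolist(),
                "mean_native": spec.to_native(self.prior.mean),
            },
            "ibic": self.ibic,
            "log_marginal_total": self.log_marginal_total,
            "n_total_choices": self.n_total_choices,
            "n_iterations": self.n_iterations,
            "converged": self.converged,
            "variance_floor_hit": self.variance_floor_hit,
            "subjects": {
                str(sid): {
                    "params": sf.params,
                    "x_map": sf.x_map.tolist(),
                    "nll": sf.nll,
                    "log_marginal": sf.log_marginal,
                    "converged": sf.converged,
                    "n_choices": sf.n_choices,
                }
                for sid, sf in sorted(self.subjects.items())
            },
        }
        return json.dumps(payload, indent=1)


# -- penalized objective ----------------------------------------------


def _penalized_nll_and_grad(
    spec: ModelSpec, x: np.ndarray, data: ChoiceArrays, prior: GroupPrior
) -> tuple[float, np.ndarray]:
    f, g = nll_and_grad(spec, x, data)
    dev = x - prior.mean
    f += float(np.sum(dev**2 / (2.0 * prior.var)))
    f += float(0.5 * np.sum(np.log(2.0 * np.pi * prior.var)))
    g = g + dev / prior.var
    return f, g


def _fd_hessian(fun_grad, x: np.ndarray, h: float = 1e-4) -> np.ndarray:
    """Central finite differences of the gradient."""
    d = x.size
    H = np.empty((d, d))
    for i in range(d):
        e = np.zeros(d)
        e[i] = h
        _, gp = fun_grad(x + e)
        _, gm = fun_grad(x - e)
        H[i] = (gp - gm) / (2.0 * h)
    return 0.5 * (H + H.T)


def fit_subject_map(
    spec: ModelSpec,
    data: ChoiceArrays,
    prior: GroupPrior,
    *,
    n_restarts: int = N_RESTARTS,
    rng: np.random.Generator | None = None,
    x_warm: np.ndarray | None = None,
) -> SubjectFit:
    """MAP estimate (unconstrained space) with Laplace curvature.

    Multi-start: the prior mean, ``n_restarts - 1`` seeded draws from
    the prior, and optionally a warm start; the best optimum is kept.
    """
    if data.n < 1:
        raise ValueError("subject has no free choices")
    rng = rng or np.random.default_rng(0)

    def fun_grad(x):
        return _penalized_nll_and_grad(spec, x, data, prior)

    starts = [prior.mean.copy()]
    if x_warm is not None:
        starts.append(np.asarray(x_warm, dtype=float))
    sd = np.sqrt(prior.var)
    for _ in range(max(n_restarts - 1, 0)):
        starts.append(rng.normal(prior.mean, sd))

    best = None
    any_converged = False
    for x0 in starts:
        res = optimize.minimize(
            fun_grad, np.clip(x0, *np.array(spec.bounds()).T), jac=True,
            method="L-BFGS-B", bounds=spec.bounds(),
            options={"maxiter": 500},
        )
        any_converged = any_converged or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res

    H = _fd_hessian(fun_grad, best.x)
    # Guard against a non-PD curvature from a flat or kinked optimum.
    eigvals, eigvecs = np.linalg.eigh(H)
    eigvals = np.maximum(eigvals, 1e-8)
    H_pd = eigvecs @ np.diag(eigvals) @ eigvecs.T
    cov = eigvecs @ np.diag(1.0 / eigvals) @ eigvecs.T

    d = spec.n_params
    # log p(D) ~ -penalized_nll(x_map) + d/2 log(2pi) - 1/2 log det H
    log_marginal = float(
        -best.fun + 0.5 * d * np.log(2.0 * np.pi) - 0.5 * np.sum(np.log(eigvals))
    )
    from .models import nll as data_nll  # native-space data NLL at the mode

    params = spec.to_native(best.x)
    return SubjectFit(
        x_map=best.x,
        params=params,
        hessian=H_pd,
        posterior_cov=cov,
        log_marginal=log_marginal,
        nll=data_nll(spec, params, data),
        converged=any_converged,
        n_choices=data.n,
    )


# -- EM ----------------------------------------------------------------


def prepare_subjects(df: pd.DataFrame, solver=None) -> dict[int, ChoiceArrays]:
    """Split a group log into per-subject choice arrays (sorted ids)."""
    return {
        int(sid): choice_arrays(sub, solver)
        for sid, sub in df.groupby("subject_id", sort=True)
    }


def em_fit(
    spec_or_id,
    data,
    *,
    seed: int = 0,
    tol: float = EM_TOL,
    max_iter: int = EM_MAX_ITER,
    n_restarts: int = N_RESTARTS,
    verbose: bool = False,
) -> FitResult:
    """Hierarchical EM fit of one model to a group dataset.

    ``data`` is a long-format DataFrame or a dict subject_id ->
    :class:`ChoiceArrays`.  Deterministic given ``seed``.  Restarts are
    used in full on the first iteration; later E-steps warm-start from
    the previous MAP (plus the prior-mean start).
    """
    spec = get_model(spec_or_id) if isinstance(spec_or_id, str) else spec_or_id
    subjects = prepare_subjects(data) if isinstance(data, pd.DataFrame) else dict(data)
    if len(subjects) < 2:
        raise ValueError("hierarchical fitting requires at least 2 subjects")
    ids = sorted(subjects)

    prior = default_prior(spec)
    fits: dict[int, SubjectFit] = {}
    trace: list[float] = []
    converged = False
    n_iter = 0
    floor_hit = False

    for n_iter in range(1, max_iter + 1):
        # E-step: per-subject MAP + Laplace posterior under current prior.
        new_fits = {}
        for j, sid in enumerate(ids):
            rng = np.random.default_rng(
                np.random.SeedSequence([seed, n_iter, j])
            )
            warm = fits[sid].x_map if sid in fits else None
            restarts = n_restarts if n_iter == 1 else 1
            new_fits[sid] = fit_subject_map(
                spec, subjects[sid], prior,
                n_restarts=restarts, rng=rng, x_warm=warm,
            )
        fits = new_fits
        trace.append(sum(sf.log_marginal for sf in fits.values()))

        # M-step: moment-match group mean and variance.
        X = np.stack([fits[sid].x_map for sid in ids])
        V = np.stack([np.diag(fits[sid].posterior_cov) for sid in ids])
        new_mean = X.mean(axis=0)
        new_var = (X**2 + V).mean(axis=0) - new_mean**2
        floor_hit = floor_hit or bool(np.any(new_var < VARIANCE_FLOOR))
        new_var = np.maximum(new_var, VARIANCE_FLOOR)

        delta = max(
            np.max(np.abs(new_mean - prior.mean)), np.max(np.abs(new_var - prior.var))
        )
        prior = GroupPrior(spec.param_names, new_mean, new_var)
        if verbose:
            print(f"  EM iter {n_iter}: objective={trace[-1]:.3f} delta={delta:.2e}")
        if delta < tol:
            converged = True
            break

    # Final E-step under the converged prior so marginals match it.
    for j, sid in enumerate(ids):
        rng = np.random.default_rng(np.random.SeedSequence([seed, max_iter + 1, j]))
        fits[sid] = fit_subject_map(
            spec, subjects[sid], prior, n_restarts=1, rng=rng,
            x_warm=fits[sid].x_map,
        )
    total = sum(sf.log_marginal for sf in fits.values())
    n_total = sum(sf.n_choices for sf in fits.values())
    result = FitResult(
        model_id=spec.model_id,
        prior=prior,
        subjects=fits,
        log_marginal_total=total,
        ibic=ibic_value(total, spec.n_params, n_total),
        n_total_choices=n_total,
        n_iterations=n_iter,
        converged=converged,
        objective_trace=trace,
        variance_floor_hit=floor_hit,
    )
    return result


def ibic_value(log_marginal_total: float, n_params: int, n_total_choices: int) -> float:
    """iBIC = -2 * integrated group log-likelihood + k log N with
    k = 2 hyperparameters (mean, variance) per model parameter."""
    if not np.isfinite(log_marginal_total):
        raise ValueError("non-finite integrated likelihood")
    if n_total_choices <= 0:
        raise ValueError("n_total_choices must be positive")
    k = 2 * n_params
    return float(-2.0 * log_marginal_total + k * np.log(n_total_choices))


def ibic(fit: FitResult, n_total_choices: int | None = None) -> float:
    n = fit.n_total_choices if n_total_choices is None else n_total_choices
    return ibic_value(fit.log_marginal_total, get_model(fit.model_id).n_params, n)


# -- goodness of fit ----------------------------------------------------


def pseudo_r2(ll_model: float, ll_baseline: float, n_choices: int) -> float:
    """Cox-Snell pseudo-r-squared: 1 - exp(2 (ll0 - ll1) / n)."""
    if n_choices <= 0:
        raise ValueError("n_choices must be positive")
    return float(1.0 - np.exp(2.0 * (ll_baseline - ll_model) / n_choices))


def baseline_loglik(data: ChoiceArrays) -> float:
    """Intercept-only baseline: constant accept probability fit by ML
    (the empirical accept rate)."""
    n = data.n
    k = float(data.y.sum())
    p = k / n
    ll = 0.0
    if k > 0:
        ll += k * np.log(p)
    if k < n:
        ll += (n - k) * np.log(1.0 - p)
    return float(ll)


def subject_pseudo_r2(fit: FitResult, subjects: dict[int, ChoiceArrays]) -> pd.Series:
    vals = {}
    for sid, sf in fit.subjects.items():
        ll0 = baseline_loglik(subjects[sid])
        vals[sid] = pseudo_r2(-sf.nll, ll0, sf.n_choices)
    return pd.Series(vals, name="pseudo_r2").sort_index()


def _bootstrap_ci(
    values: np.ndarray, rng: np.random.Generator, n_boot: int = 2000
) -> tuple[float, float]:
    n = values.size
    idx = rng.integers(0, n, size=(n_boot, n))
    means = values[idx].mean(axis=1)
    lo, hi = np.percentile(means, [2.5, 97.5])
    return float(lo), float(hi)


def compare_models(
    data,
    model_ids=("immediate", "optimal", "trade1", "trade3"),
    *,
    seed: int = 0,
    verbose: bool = False,
    **em_kwargs,
) -> tuple[pd.DataFrame, dict[str, FitResult]]:
    """Fit each model to the same group data and rank by iBIC.

    Returns the comparison table (ascending iBIC) and the fits.  The
    pseudo-r-squared column is the across-subject mean with a 95%
    bootstrap confidence interval.
    """
    subjects = prepare_subjects(data) if isinstance(data, pd.DataFrame) else dict(data)
    rows = []
    fits: dict[str, FitResult] = {}
    for model_id in model_ids:
        if verbose:
            print(f"fitting {model_id} ...")
        fit = em_fit(model_id, subjects, seed=seed, verbose=verbose, **em_kwargs)
        fits[model_id] = fit
        r2 = subject_pseudo_r2(fit, subjects).to_numpy()
        lo, hi = _bootstrap_ci(r2, np.random.default_rng(seed + 1))
        rows.append(
            {
                "model": model_id,
                "k": get_model(model_id).n_params,
                "log_marginal": fit.log_marginal_total,
                "iBIC": fit.ibic,
                "pseudo_r2_mean": float(r2.mean()),
                "pseudo_r2_ci_low": lo,
                "pseudo_r2_ci_high": hi,
            }
        )
    table = pd.DataFrame(rows).sort_values("iBIC", ignore_index=True)
    return table, fits


def param_quartiles(fit: FitResult) -> pd.DataFrame:
    """25th/50th/75th percentile of native-space MAP estimates across
    subjects, one column per parameter."""
    table = fit.map_table().drop(columns=["subject_id", "nll", "n_choices"])
    q = table.quantile([0.25, 0.5, 0.75])
    q.index = ["p25", "median", "p75"]
    return q
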