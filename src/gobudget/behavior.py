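"""Descriptive and regression analyses of choice behavior.

Three analyses characterize how acceptance depends on within-trial
state: (i) an acceptance grid — P(go) at every (offer index, rejections
so far, offer value) permutation under the uniform contingency, the
summary in which the impulsive over-acceptance of 7-token offers is
visible; (ii) the decorrelated-offer subset — free choices at offer
indexes 2-3 while m = 0, where immediate and long-term value are
maximally decoupled; (iii) per-subject logistic regression of go/nogo
on immediate (IR) and long-term (EV) value jointly, with the group
assessed by one-sample t-tests on the betas.

The regression uses iteratively reweighted least squares.  A robust
variant down-weights high-residual observations with a Tukey bisquare
weight on Pearson residuals (default on); the plain-IRLS path is the
textbook logistic ML fit and is available for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import annotate_states
from .models import choice_arrays

MIN_CELL_COUNT = 15
BISQUARE_C = 4.685
#: Coefficient magnitude beyond which a logistic fit on token-scale
#: regressors is treated as (quasi-)separated: |beta| = 50 over a
#: regressor range of ~4 tokens implies odds ratios beyond exp(200),
#: i.e. numerically deterministic choice.
SEPARATION_BETA_LIMIT = 50.0


def acceptance_grid(df: pd.DataFrame, min_count: int = MIN_CELL_COUNT) -> pd.DataFrame:
    """Pooled acceptance probability per (offer_index, n_rejected,
    offer_value) cell, uniform-contingency (m=0) free choices only.

    Returns a long table with columns offer_index, n_rejected,
    offer_value, p_accept, n_obs, included; ``included`` is False where
    fewer than ``min_count`` observations fall in the cell.
    """
    df = annotate_states(df)
    free = df[(df["forced"] == 0) & (df["m_at_offer"] == 0)]
    if free.empty:
        return pd.DataFrame(
            columns=[
                "offer_index", "n_rejected", "offer_value",
                "p_accept", "n_obs", "included",
            ]
        )
    grouped = free.groupby(
        ["offer_index", "n_rejected_before", "offer_value"], sort=True
    )["action"]
    out = grouped.agg(
        n_obs="size", p_accept=lambda a: float((a == "go").mean())
    ).reset_index()
    out = out.rename(columns={"n_rejected_before": "n_rejected"})
    out["included"] = out["n_obs"] >= min_count
    return out[
        ["offer_index", "n_rejected", "offer_value", "p_accept", "n_obs", "included"]
    ]


def select_decorrelated_offers(df: pd.DataFrame) -> pd.DataFrame:
    """Free choices at offer indexes 2-3 with the uniform contingency
    still in force — the states where IR and EV are most decoupled."""
    df = annotate_states(df)
    mask = (
        (df["forced"] == 0)
        & (df["m_at_offer"] == 0)
        & df["offer_index"].isin([2, 3])
    )
    return df[mask]


class SeparationError(RuntimeError):
    """Perfect separation: the ML estimate diverges."""


@dataclass
class LogisticFit:
    terms: tuple[str, ...]
    beta: np.ndarray
    se: np.ndarray
    converged: bool
    n_obs: int


def logistic_irls(
    X: np.ndarray,
    y: np.ndarray,
    *,
    robust: bool = True,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Logistic regression by iteratively reweighted least squares.

    With ``robust=True`` each IRLS weight is multiplied by a Tukey
    bisquare weight of the Pearson residual, down-weighting
    high-leverage/outlying observations.  Returns (beta, se, converged);
    raises :class:`SeparationError` when the fit diverges (complete
    separation) and ``ValueError`` on a rank-deficient design.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, d = X.shape
    if np.linalg.matrix_rank(X) < d:
        raise ValueError("design matrix is rank deficient (constant regressor?)")
    beta = np.zeros(d)
    converged = False
    XtWX = None
    for _ in range(max_iter):
        eta = X @ beta
        p = 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))
        var = np.maximum(p * (1.0 - p), 1e-10)
        w = var.copy()
        if robust:
            r_pearson = (y - p) / np.sqrt(var)
            u = np.abs(r_pearson) / BISQUARE_C
            w_rob = np.where(u < 1.0, (1.0 - u**2) ** 2, 0.0)
            w *= w_rob
        z = eta + (y - p) / var
        XtW = X.T * w
        XtWX = XtW @ X
        try:
            new_beta = np.linalg.solve(XtWX, XtW @ z)
        except np.linalg.LinAlgError as exc:
            raise SeparationError("IRLS normal equations singular") from exc
        step = np.max(np.abs(new_beta - beta))
        beta = new_beta
        if not np.all(np.isfinite(beta)) or np.max(np.abs(beta)) > 1e4:
            raise SeparationError("coefficients diverged (complete separation?)")
        if step < tol:
            converged = True
            break
    if np.max(np.abs(beta)) > SEPARATION_BETA_LIMIT:
        raise SeparationError(
            "quasi-separation: coefficient magnitude exceeds "
            f"{SEPARATION_BETA_LIMIT} (numerically deterministic choice)"
        )
    se = np.sqrt(np.diag(np.linalg.inv(XtWX)))
    return beta, se, converged


def robust_logistic(
    subject_df: pd.DataFrame,
    *,
    robust: bool = True,
    standardize: bool = False,
) -> LogisticFit:
    """Per-subject regression of go/nogo on IR and EV jointly.

    EV is joined from the optimal solver at each free-choice state.  Set
    ``standardize=True`` to z-score the regressors (betas are reported
    raw by default).
    """
    data = choice_arrays(subject_df)
    if data.y.min() == data.y.max():
        raise SeparationError("subject has only one response type")
    ir = data.IR.astype(float)
    ev = data.EV.astype(float)
    if np.ptp(ir) == 0 or np.ptp(ev) == 0:
        raise ValueError("a regressor is constant within the subset")
    if standardize:
        ir = (ir - ir.mean()) / ir.std()
        ev = (ev - ev.mean()) / ev.std()
    X = np.column_stack([np.ones_like(ir), ir, ev])
    beta, se, converged = logistic_irls(X, data.y, robust=robust)
    return LogisticFit(
        terms=("intercept", "IR", "EV"),
        beta=beta,
        se=se,
        converged=converged,
        n_obs=data.n,
    )


def subject_betas(
    df: pd.DataFrame,
    *,
    robust: bool = True,
    decorrelated_only: bool = False,
    standardize: bool = False,
) -> pd.DataFrame:
    """Fit the IR+EV regression per subject; separated subjects are
    flagged (``ok=False``) and excluded from downstream group tests."""
    if decorrelated_only:
        df = select_decorrelated_offers(df)
    rows = []
    for sid, sub in df.groupby("subject_id", sort=True):
        row = {"subject_id": sid, "ok": True, "note": ""}
        try:
            fit = robust_logistic(sub, robust=robust, standardize=standardize)
            row.update(dict(zip(fit.terms, fit.beta)))
            row.update({f"se_{t}": s for t, s in zip(fit.terms, fit.se)})
        except (SeparationError, ValueError) as exc:
            row["ok"] = False
            row["note"] = str(exc)
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class GroupTest:
    term: str
    mean: float
    t: float
    df: int
    p: float
    n: int


def group_ttest(betas: pd.DataFrame, terms=("IR", "EV")) -> list[GroupTest]:
    """One-sample t-test of each beta against zero across subjects."""
    ok = betas[betas["ok"]] if "ok" in betas else betas
    if len(ok) < 2:
        raise ValueError("group test requires at least 2 subjects with valid fits")
    out = []
    for term in terms:
        vals = ok[term].to_numpy(dtype=float)
        if np.allclose(vals, vals[0]):
            raise ValueError(f"degenerate zero-variance betas for {term}")
        t, p = stats.ttest_1samp(vals, 0.0)
        out.append(
            GroupTest(
                term=term, mean=float(vals.mean()), t=float(t),
                df=len(vals) - 1, p=float(p), n=len(vals),
            )
        )
    return out


def group_report(tests: list[GroupTest]) -> str:
    lines = ["One-sample t-tests on per-subject regression betas (vs 0):"]
    for gt in tests:
        lines.append(
            f"  {gt.term}: mean b = {gt.mean:.3f}, t({gt.df}) = {gt.t:.2f}, "
            f"p = {gt.p:.3g} (n = {gt.n})"
        )
    return "\n".join(lines)
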