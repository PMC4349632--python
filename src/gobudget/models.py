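"""Candidate observation models mapping decision values to choice.

Four models turn an offer into a probability of a go response through a
sigmoid P(go) = 1 / (1 + exp(-tau * V_A)):

- ``immediate``: V_A = IR - c_int; only the face value matters.
- ``optimal``:   V_A = EV, the long-term value from the belief-state
  solver.
- ``trade1``:    V_A = w * EV + (1 - w) * (IR - c_int); one weight
  trades long-term against immediate value.
- ``trade3``:    as trade1 but with a separate weight w3/w5/w7 for each
  face value.

Parameters live in two spaces: the native space with domain constraints
(tau > 0, weights in [0, 1]) and an unconstrained space used for
optimization and group-level Gaussians (log for tau, logit for weights,
identity for the intercept).  The intercept symbol is ``c_int``
throughout, whether it plays the immediate model's or the trade models'
intercept role.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .solver import OptimalSolver, default_solver
from .task import TOKEN_VALUES

P_FLOOR = 1e-12
_LOG_P_FLOOR = np.log(P_FLOOR)

# -- parameter transforms ---------------------------------------------


def _logit(p):
    p = np.asarray(p, dtype=float)
    return np.log(p) - np.log1p(-p)


def _sigmoid(x):
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


TRANSFORMS = {
    "log": (np.log, np.exp),  # positive parameters (tau)
    "logit": (_logit, _sigmoid),  # unit-interval parameters (weights)
    "identity": (lambda x: np.asarray(x, dtype=float),) * 2,
}

#: Optimization box per transform, unconstrained space.  Wide enough to
#: be inert for any data-supported optimum while keeping exp/logistic
#: arithmetic finite.
TRANSFORM_BOUNDS = {
    "log": (-15.0, 15.0),
    "logit": (-30.0, 30.0),
    "identity": (-100.0, 100.0),
}


@dataclass(frozen=True)
class ModelSpec:
    """One candidate model: ordered parameter names and their transforms."""

    model_id: str
    param_names: tuple[str, ...]
    transforms: tuple[str, ...]

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    def to_unconstrained(self, native: dict[str, float]) -> np.ndarray:
        return np.array(
            [
                TRANSFORMS[t][0](native[name])
                for name, t in zip(self.param_names, self.transforms)
            ],
            dtype=float,
        )

    def bounds(self) -> list[tuple[float, float]]:
        return [TRANSFORM_BOUNDS[t] for t in self.transforms]

    def to_native(self, x: np.ndarray) -> dict[str, float]:
        return {
            name: float(TRANSFORMS[t][1](xi))
            for name, t, xi in zip(self.param_names, self.transforms, x)
        }


MODELS: dict[str, ModelSpec] = {
    "immediate": ModelSpec("immediate", ("tau", "c_int"), ("log", "identity")),
    "optimal": ModelSpec("optimal", ("tau",), ("log",)),
    "trade1": ModelSpec(
        "trade1", ("tau", "c_int", "w"), ("log", "identity", "logit")
    ),
    "trade3": ModelSpec(
        "trade3",
        ("tau", "c_int", "w3", "w5", "w7"),
        ("log", "identity", "logit", "logit", "logit"),
    ),
}

MODEL_IDS = tuple(MODELS)


def get_model(model_id: str) -> ModelSpec:
    try:
        return MODELS[model_id]
    except KeyError:
        raise ValueError(
            f"unknown model {model_id!r}; expected one of {MODEL_IDS}"
        ) from None


# -- choice probability ------------------------------------------------


def p_accept(V_A, tau):
    """Softmax (sigmoid) acceptance probability 1 / (1 + exp(-tau * V_A))."""
    if np.any(np.asarray(tau) < 0):
        raise ValueError("temperature tau must be nonnegative")
    return _sigmoid(np.asarray(tau, dtype=float) * np.asarray(V_A, dtype=float))


def decision_value(spec: ModelSpec, params: dict[str, float], IR, EV):
    """V_A for each offer under ``spec``.  ``IR`` and ``EV`` broadcast."""
    IR = np.asarray(IR, dtype=float)
    EV = np.asarray(EV, dtype=float)
    if spec.model_id == "immediate":
        return IR - params["c_int"]
    if spec.model_id == "optimal":
        return EV
    if spec.model_id == "trade1":
        w = params["w"]
        return w * EV + (1.0 - w) * (IR - params["c_int"])
    if spec.model_id == "trade3":
        w = np.choose(
            _value_index(IR), [params["w3"], params["w5"], params["w7"]]
        )
        return w * EV + (1.0 - w) * (IR - params["c_int"])
    raise ValueError(f"unknown model {spec.model_id!r}")


def _value_index(IR) -> np.ndarray:
    idx = np.searchsorted(TOKEN_VALUES, np.asarray(IR))
    return idx


# -- choice data --------------------------------------------------------


@dataclass
class ChoiceArrays:
    """Free-choice records of one subject as flat arrays for likelihoods."""

    y: np.ndarray  # 1 = go, 0 = nogo
    IR: np.ndarray  # face values
    EV: np.ndarray  # long-term values joined from the solver
    value_idx: np.ndarray  # 0/1/2 for IR = 3/5/7

    @property
    def n(self) -> int:
        return self.y.size


def choice_arrays(
    df: pd.DataFrame, solver: OptimalSolver | None = None
) -> ChoiceArrays:
    """Extract free choices from a long-format log and join EV per state.

    ``df`` must carry offer_index, offer_value, m_at_offer, action and
    forced columns plus per-trial grouping columns (subject_id, session,
    trial) from which within-trial accept counts are reconstructed.
    Forced records are dropped: they carry no choice information.
    """
    from .io import annotate_states  # local import to avoid a cycle

    df = annotate_states(df)
    free = df[df["forced"] == 0]
    if free.empty:
        raise ValueError("no free-choice records in the data")
    solver = solver or default_solver()
    table = solver.ev_table()
    keys = zip(
        free["offer_index"].to_numpy() - 1,
        free["n_accepted_before"].to_numpy(),
        free["m_at_offer"].to_numpy(),
        free["offer_value"].to_numpy(),
    )
    ev = np.array([table[k] for k in keys], dtype=float)
    y = (free["action"] == "go").to_numpy(dtype=float)
    IR = free["offer_value"].to_numpy(dtype=float)
    return ChoiceArrays(y=y, IR=IR, EV=ev, value_idx=_value_index(IR))


# -- likelihood ---------------------------------------------------------


def nll(spec: ModelSpec, params: dict[str, float], data) -> float:
    """Negative log-likelihood of the free choices under native params.

    ``data`` is a :class:`ChoiceArrays` or a long-format DataFrame (the
    latter is converted, excluding forced records).  Per-choice
    probabilities are floored at 1e-12.
    """
    if isinstance(data, pd.DataFrame):
        data = choice_arrays(data)
    v = decision_value(spec, params, data.IR, data.EV)
    p_go = p_accept(v, params["tau"])
    p_obs = np.where(data.y > 0.5, p_go, 1.0 - p_go)
    return float(-np.sum(np.log(np.maximum(p_obs, P_FLOOR))))


def nll_and_grad(
    spec: ModelSpec, x: np.ndarray, data: ChoiceArrays
) -> tuple[float, np.ndarray]:
    """NLL and its gradient in unconstrained parameter space.

    With z = tau * V_A and p = sigmoid(z), dNLL/dz = p - y per choice;
    tau in log space contributes dz = z, the intercept contributes
    dz = -tau * (1 - w) (with w = 0 for the immediate model), and a
    logit-space weight contributes dz = tau * (EV - IR + c_int) * w(1 - w).
    """
    params = spec.to_native(x)
    tau = params["tau"]
    v = decision_value(spec, params, data.IR, data.EV)
    z = tau * v
    # log-lik per obs: y*z - log(1 + e^z); stable via logaddexp
    ll = np.sum(data.y * z - np.logaddexp(0.0, z))
    p = _sigmoid(z)
    resid = p - data.y  # dNLL/dz
    grad = np.empty(spec.n_params)
    grad[0] = float(resid @ z)  # d z / d log(tau) = z
    if spec.model_id == "immediate":
        grad[1] = float(resid.sum()) * -tau
    elif spec.model_id == "trade1":
        w = params["w"]
        grad[1] = float(resid @ np.full_like(z, -tau * (1.0 - w)))
        dv_dw = data.EV - (data.IR - params["c_int"])
        grad[2] = float(resid @ (tau * dv_dw)) * w * (1.0 - w)
    elif spec.model_id == "trade3":
        ws = np.array([params["w3"], params["w5"], params["w7"]])
        w_obs = ws[data.value_idx]
        grad[1] = float(resid @ (-tau * (1.0 - w_obs)))
        dv_dw = data.EV - (data.IR - params["c_int"])
        for j, name in enumerate(("w3", "w5", "w7")):
            mask = data.value_idx == j
            wj = params[name]
            grad[2 + j] = float(
                resid[mask] @ (tau * dv_dw[mask])
            ) * wj * (1.0 - wj)
    # 'optimal' has only tau
    return float(-ll), grad


def nll_report(
    specs_params: dict[str, dict[str, float]], df: pd.DataFrame
) -> pd.DataFrame:
    """Per-subject, per-model NLL table (subject, model, nll, n_choices)."""
    rows = []
    for subject_id, sub in df.groupby("subject_id", sort=True):
        data = choice_arrays(sub)
        for model_id, params in specs_params.items():
            rows.append(
                {
                    "subject": subject_id,
                    "model": model_id,
                    "nll": nll(get_model(model_id), params, data),
                    "n_choices": data.n,
                }
            )
    return pd.DataFrame(rows)
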