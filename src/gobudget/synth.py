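"""Synthetic group datasets with the task's exact generative structure.

The study design this emulates: 23 subjects, three 36-trial sessions
(108 trials each), 7-9 offers per trial with a 4-6 accept budget drawn
uniformly and independently, offer values from the contingency
distributions, and choices sampled from one of the four candidate
models with subject-level parameters drawn from a group distribution.

Group parameter draws are Gaussian in the unconstrained (transformed)
space so that every draw respects the native domain; native mean/sd
settings are mapped through the transforms by the delta method, with
weights clipped away from the unit-interval boundary before the logit.
Sessions are statistically identical; the session column exists for
schema fidelity only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import task
from .io import LOG_COLUMNS
from .models import ModelSpec, TRANSFORMS, decision_value, get_model, p_accept
from .solver import OptimalSolver, default_solver

#: Native-space (mean, sd) of the group distribution for each generating
#: model.  The trade3 values follow the reference group medians and
#: quartile-implied spreads for that model (w5 is set just inside the
#: unit interval because the group logit-Gaussian cannot center on 1.0);
#: the other models use plausible group settings producing the same mix
#: of stochastic and value-driven choice.
DEFAULT_GROUP_PARAMS: dict[str, dict[str, tuple[float, float]]] = {
    "trade3": {
        "tau": (2.833, 1.35),
        "c_int": (5.891, 0.95),
        "w3": (0.834, 0.081),
        "w5": (0.95, 0.10),
        "w7": (0.264, 0.205),
    },
    "trade1": {
        "tau": (2.833, 1.35),
        "c_int": (5.891, 0.95),
        "w": (0.60, 0.20),
    },
    "optimal": {"tau": (2.0, 0.8)},
    "immediate": {"tau": (1.0, 0.4), "c_int": (5.0, 1.0)},
}

#: Weights are clipped to this interval before the logit transform.
WEIGHT_CLIP = (0.025, 0.975)
#: Cap on the unconstrained-space sd produced by the delta method (the
#: derivative of the logit blows up near the boundary).
MAX_UNCONSTRAINED_SD = 2.5


@dataclass
class GroupDesign:
    """Design of one synthetic group dataset."""

    n_subjects: int = 23
    n_sessions: int = 3
    trials_per_session: int = 36
    model_id: str = "trade3"
    group_params: dict[str, tuple[float, float]] | None = None
    seed: int = 0
    m_monotone: bool = False

    @property
    def n_trials(self) -> int:
        return self.n_sessions * self.trials_per_session

    def resolved_group_params(self) -> dict[str, tuple[float, float]]:
        params = dict(DEFAULT_GROUP_PARAMS[self.model_id])
        if self.group_params:
            params.update(self.group_params)
        return params


def unconstrained_group_moments(
    spec: ModelSpec, native: dict[str, tuple[float, float]]
) -> tuple[np.ndarray, np.ndarray]:
    """Map native (mean, sd) settings to unconstrained (mu, sd) per
    parameter via the delta method."""
    mus, sds = [], []
    for name, transform in zip(spec.param_names, spec.transforms):
        mean, sd = native[name]
        if transform == "logit":
            mean = float(np.clip(mean, *WEIGHT_CLIP))
            deriv = 1.0 / (mean * (1.0 - mean))
        elif transform == "log":
            deriv = 1.0 / mean
        else:
            deriv = 1.0
        mus.append(float(TRANSFORMS[transform][0](mean)))
        sds.append(min(sd * deriv, MAX_UNCONSTRAINED_SD))
    return np.array(mus), np.array(sds)


def draw_subject_params(
    spec: ModelSpec,
    native_settings: dict[str, tuple[float, float]],
    rng: np.random.Generator,
) -> dict[str, float]:
    mu, sd = unconstrained_group_moments(spec, native_settings)
    x = rng.normal(mu, sd)
    return spec.to_native(x)


def model_policy(
    spec: ModelSpec,
    params: dict[str, float],
    rng: np.random.Generator,
    solver: OptimalSolver | None = None,
):
    """A ``policy(state, offer_value) -> action`` sampling from the model."""
    table = (solver or default_solver()).ev_table()

    def policy(state: task.TrialState, value: int) -> str:
        ev = table[(state.offer_index - 1, state.n_accepted, state.m, value)]
        v_a = float(decision_value(spec, params, value, ev))
        p = float(p_accept(v_a, params["tau"]))
        return "go" if rng.random() < p else "nogo"

    return policy


def _subject_rng(design: GroupDesign, subject_index: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([int(design.seed), int(subject_index)])
    )


def generate_subject(
    design: GroupDesign, subject_index: int
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Simulate one subject: returns their long-format log and the true
    generating parameters.  Reproducible from (design.seed, subject_index)."""
    spec = get_model(design.model_id)
    rng = _subject_rng(design, subject_index)
    params = draw_subject_params(spec, design.resolved_group_params(), rng)
    policy = model_policy(spec, params, rng)
    rows = []
    trial_no = 0
    for session in range(1, design.n_sessions + 1):
        for _ in range(design.trials_per_session):
            trial_no += 1
            config = task.draw_trial_config(rng)
            log = task.simulate_trial(
                config, policy, rng, m_monotone=design.m_monotone
            )
            for rec in log.records:
                rows.append(
                    (
                        subject_index,
                        session,
                        trial_no,
                        rec.offer_index,
                        rec.offer_value,
                        rec.m_at_offer,
                        rec.action,
                        int(rec.forced),
                        config.n_offers,
                        config.budget,
                    )
                )
    df = pd.DataFrame(rows, columns=LOG_COLUMNS)
    return df, params


def generate_group(design: GroupDesign) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the whole group.

    Returns the concatenated choice log and a truth table with one row
    per (subject_id, parameter, true_value).
    """
    logs, truth_rows = [], []
    for subject in range(1, design.n_subjects + 1):
        df, params = generate_subject(design, subject)
        logs.append(df)
        truth_rows.extend(
            {"subject_id": subject, "parameter": k, "true_value": v}
            for k, v in params.items()
        )
    return (
        pd.concat(logs, ignore_index=True),
        pd.DataFrame(truth_rows, columns=["subject_id", "parameter", "true_value"]),
    )


def truth_wide(truth: pd.DataFrame) -> pd.DataFrame:
    """Pivot the truth table to one row per subject."""
    return truth.pivot(index="subject_id", columns="parameter", values="true_value")
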