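"""Generative model of the sequential-offer go/nogo task.

Each trial presents 7-9 token offers (values 3, 5 or 7) one at a time.
The player may accept ("go") at most `budget` (4-6) of them; once the
budget is spent the remaining responses are forced nogos.  Offer values
are drawn from one of three contingency distributions indexed by
``m``: the trial starts uniform (m=0) and degrades when a 5-token
(m=1) or 7-token (m=2) offer is accepted after the first offer and
before three offers have been rejected.  Payout is the sum of accepted
offer values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

TOKEN_VALUES: tuple[int, int, int] = (3, 5, 7)

#: Contingency distributions over token values (3, 5, 7).  m=0 is the
#: uniform trial-onset state; m=1 and m=2 are the penalty states entered
#: by accepting a 5- or 7-token offer early in a trial.
OFFER_DISTRIBUTIONS: dict[int, tuple[float, float, float]] = {
    0: (1.0 / 3.0, 1.0 / 3.0, 1.0 / 3.0),
    1: (0.50, 0.25, 0.25),
    2: (0.90, 0.05, 0.05),
}

N_OFFERS_RANGE = (7, 8, 9)
BUDGET_RANGE = (4, 5, 6)

#: Number of prior rejections at or beyond which the contingency locks.
REJECTION_LOCK = 3

Action = Literal["go", "nogo"]


def offer_probs(m: int) -> tuple[float, float, float]:
    """Probability triple over token values (3, 5, 7) for contingency ``m``."""
    try:
        return OFFER_DISTRIBUTIONS[m]
    except KeyError:
        raise ValueError(f"contingency index must be 0, 1 or 2, got {m!r}") from None


def update_m(
    m: int,
    action: Action,
    offer_value: int,
    offer_index: int,
    n_rejected: int,
    *,
    m_monotone: bool = False,
) -> int:
    """Contingency index after responding to one offer.

    ``m`` is unchanged on a nogo, on a 3-token offer, on the first offer,
    or once three or more offers have previously been rejected.  Otherwise
    accepting a 5-token offer sets m=1 and accepting a 7-token offer sets
    m=2 (the most-recent-choice rule, so a later accepted 5 can relax m
    from 2 back to 1 unless ``m_monotone`` forbids improvement).

    Parameters
    ----------
    offer_index : int
        1-based position of the offer within the trial.
    n_rejected : int
        Offers rejected before this one (whole-trial count).
    """
    if m not in OFFER_DISTRIBUTIONS:
        raise ValueError(f"contingency index must be 0, 1 or 2, got {m!r}")
    if action != "go" or offer_value == 3:
        return m
    if offer_index == 1 or n_rejected >= REJECTION_LOCK:
        return m
    new_m = 1 if offer_value == 5 else 2
    if m_monotone:
        return max(m, new_m)
    return new_m


@dataclass(frozen=True)
class TrialConfig:
    """Offer count and accept budget for one trial."""

    n_offers: int
    budget: int

    def __post_init__(self) -> None:
        if not (7 <= self.n_offers <= 9):
            raise ValueError(f"n_offers must be in 7..9, got {self.n_offers}")
        if not (4 <= self.budget <= 6):
            raise ValueError(f"budget must be in 4..6, got {self.budget}")


def draw_trial_config(rng: np.random.Generator) -> TrialConfig:
    """Draw offer count and budget uniformly and independently."""
    return TrialConfig(
        n_offers=int(rng.choice(N_OFFERS_RANGE)),
        budget=int(rng.choice(BUDGET_RANGE)),
    )


def sample_offer(m: int, rng: np.random.Generator) -> int:
    """Draw one token value from the contingency-``m`` distribution."""
    return int(rng.choice(TOKEN_VALUES, p=offer_probs(m)))


@dataclass(frozen=True)
class OfferRecord:
    offer_index: int
    offer_value: int
    m_at_offer: int
    action: Action
    forced: bool


@dataclass
class TrialState:
    """Mutable within-trial state at an offer presentation."""

    config: TrialConfig
    offer_index: int = 1
    n_accepted: int = 0
    n_rejected: int = 0
    m: int = 0
    current_offer_value: int | None = None
    m_monotone: bool = False

    @property
    def budget_exhausted(self) -> bool:
        return self.n_accepted >= self.config.budget

    @property
    def done(self) -> bool:
        return self.offer_index > self.config.n_offers

    def step(self, action: Action) -> OfferRecord:
        """Respond to the current offer; returns the record written.

        A go attempted after the budget is exhausted is coerced to a
        forced nogo.  Counters and the contingency index are advanced and
        ``offer_index`` incremented.
        """
        if self.done:
            raise RuntimeError("trial is complete; cannot step past the final offer")
        if self.current_offer_value is None:
            raise RuntimeError("no offer presented; set current_offer_value first")
        value = self.current_offer_value
        forced = False
        if self.budget_exhausted:
            forced = True
            action = "nogo"
        record = OfferRecord(self.offer_index, value, self.m, action, forced)
        self.m = update_m(
            self.m, action, value, self.offer_index, self.n_rejected,
            m_monotone=self.m_monotone,
        )
        if action == "go":
            self.n_accepted += 1
        else:
            self.n_rejected += 1
        self.offer_index += 1
        self.current_offer_value = None
        return record


@dataclass
class TrialLog:
    """Complete record of one trial."""

    config: TrialConfig
    records: list[OfferRecord] = field(default_factory=list)

    @property
    def total_tokens(self) -> int:
        return trial_payout(self)

    def validate(self) -> None:
        """Raise ``ValueError`` on any violated trial invariant."""
        if len(self.records) != self.config.n_offers:
            raise ValueError(
                f"trial has {len(self.records)} records, expected {self.config.n_offers}"
            )
        n_go = sum(r.action == "go" for r in self.records)
        if n_go > self.config.budget:
            raise ValueError(f"{n_go} accepts exceed budget {self.config.budget}")
        n_acc = n_rej = 0
        m = 0
        seen_forced = False
        for i, rec in enumerate(self.records, start=1):
            if rec.offer_index != i:
                raise ValueError(f"record {i} has offer_index {rec.offer_index}")
            if rec.offer_value not in TOKEN_VALUES:
                raise ValueError(f"offer value {rec.offer_value} not in {TOKEN_VALUES}")
            if rec.m_at_offer != m:
                raise ValueError(
                    f"record {i}: m_at_offer {rec.m_at_offer} inconsistent with "
                    f"update rules (expected {m})"
                )
            exhausted = n_acc >= self.config.budget
            if rec.forced != exhausted:
                raise ValueError(f"record {i}: forced flag should be {exhausted}")
            if rec.forced and rec.action != "nogo":
                raise ValueError(f"record {i}: forced record must be nogo")
            if seen_forced and not rec.forced:
                raise ValueError("forced records must form a suffix")
            seen_forced = seen_forced or rec.forced
            m = update_m(m, rec.action, rec.offer_value, i, n_rej)
            if rec.action == "go":
                n_acc += 1
            else:
                n_rej += 1


def trial_payout(log: TrialLog) -> int:
    """Total tokens won: sum of accepted offer values."""
    if len(log.records) != log.config.n_offers:
        raise ValueError("incomplete trial log")
    n_go = sum(r.action == "go" for r in log.records)
    if n_go > log.config.budget:
        raise ValueError(f"{n_go} accepts exceed budget {log.config.budget}")
    return sum(r.offer_value for r in log.records if r.action == "go")


def simulate_trial(
    config: TrialConfig,
    policy,
    rng: np.random.Generator,
    *,
    m_monotone: bool = False,
) -> TrialLog:
    """Play one trial, asking ``policy(state, offer_value) -> action`` at
    each free choice.  Forced nogos after budget exhaustion bypass the
    policy."""
    state = TrialState(config, m_monotone=m_monotone)
    records: list[OfferRecord] = []
    while not state.done:
        state.current_offer_value = sample_offer(state.m, rng)
        if state.budget_exhausted:
            action: Action = "nogo"
        else:
            action = policy(state, state.current_offer_value)
        records.append(state.step(action))
    return TrialLog(config, records)
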