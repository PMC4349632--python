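"""Optimal belief-state agent for the budgeted offer task.

The agent never observes the trial's true offer count or budget, only
their generating ranges, so its state is a pair of belief distributions:
``O`` over the number of offers remaining (initially uniform on 7..9)
and ``A`` over accepts remaining (uniform on 4..6), plus the contingency
index ``m`` and the rejection count that gates contingency updates.
Responding to an offer shifts the relevant belief left by one and
renormalizes, so both beliefs are deterministic functions of the number
of offers seen and accepts used; those counts are therefore the
canonical memoization key.

The state value is the expectation over the forthcoming offer value
``r`` of the better of rejecting (continue with probability P(o>1)) and
accepting (bank ``r``, continue with probability P(o>1)P(a>1), with the
contingency updated for accepting ``r``).  The recursion bottoms out
when either continuation probability is zero.  The decision quantity is
``EV = V_AF + IR - V_R``: the face value plus the future value of
accepting minus the value of rejecting.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property

import pandas as pd

from .task import (
    BUDGET_RANGE,
    N_OFFERS_RANGE,
    REJECTION_LOCK,
    TOKEN_VALUES,
    offer_probs,
    update_m,
)


@dataclass(frozen=True)
class CountBelief:
    """Discrete belief over a nonnegative remaining-count variable."""

    support: tuple[int, ...]
    probs: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.support) != len(self.probs) or not self.support:
            raise ValueError("support and probs must be nonempty and matched")
        if any(p < 0 for p in self.probs):
            raise ValueError("belief weights must be nonnegative")
        if abs(sum(self.probs) - 1.0) > 1e-12:
            raise ValueError("belief weights must sum to 1")
        if any(b <= a for a, b in zip(self.support, self.support[1:])):
            raise ValueError("support must be strictly increasing")


def uniform_belief(lo: int, hi: int) -> CountBelief:
    n = hi - lo + 1
    return CountBelief(tuple(range(lo, hi + 1)), (1.0 / n,) * n)


def shift(belief: CountBelief) -> CountBelief:
    """Belief after the count decrements: P'(c) = P(c+1) / sum P(c+1).

    Undefined when all mass sits at 1 (nothing can remain), which marks
    a terminal state.
    """
    pairs = [(c - 1, p) for c, p in zip(belief.support, belief.probs) if c - 1 >= 1]
    total = sum(p for _, p in pairs)
    if total <= 0:
        raise ValueError("shift undefined: all belief mass at count 1 (terminal)")
    return CountBelief(
        tuple(c for c, _ in pairs), tuple(p / total for _, p in pairs)
    )


def shifted(base: CountBelief, times: int) -> CountBelief:
    b = base
    for _ in range(times):
        b = shift(b)
    return b


def p_continue(belief: CountBelief) -> float:
    """P(count > 1): probability the process survives this response."""
    return sum(p for c, p in zip(belief.support, belief.probs) if c > 1)


_O0 = uniform_belief(min(N_OFFERS_RANGE), max(N_OFFERS_RANGE))  # uniform on 7..9
_A0 = uniform_belief(min(BUDGET_RANGE), max(BUDGET_RANGE))  # uniform on 4..6

# Offers seen beyond which the O belief collapses to {1}; likewise the
# maximum accepts after which A collapses (no further accept successor).
MAX_OFFERS_SEEN = max(N_OFFERS_RANGE) - 1  # 8
MAX_ACCEPTS = max(BUDGET_RANGE) - 1  # 5


@dataclass(frozen=True)
class BeliefState:
    """Agent state at an offer presentation.

    ``offers_seen`` offers have already been responded to (so the current
    offer has 1-based index ``offers_seen + 1``), ``n_accepted`` of them
    with a go.  Beliefs O and A are derived by shifting the onset
    uniforms, so the triple (offers_seen, n_accepted, m) identifies the
    state.
    """

    offers_seen: int
    n_accepted: int
    m: int

    def __post_init__(self) -> None:
        if not (0 <= self.offers_seen <= MAX_OFFERS_SEEN):
            raise ValueError(f"offers_seen out of range: {self.offers_seen}")
        if not (0 <= self.n_accepted <= min(self.offers_seen, MAX_ACCEPTS)):
            raise ValueError(
                f"n_accepted {self.n_accepted} invalid for offers_seen {self.offers_seen}"
            )
        if self.m not in (0, 1, 2):
            raise ValueError(f"invalid contingency index {self.m}")

    @property
    def offer_index(self) -> int:
        return self.offers_seen + 1

    @property
    def n_rejected(self) -> int:
        return self.offers_seen - self.n_accepted

    @property
    def n_rejected_capped(self) -> int:
        return min(self.n_rejected, REJECTION_LOCK)

    @property
    def is_first_offer(self) -> bool:
        return self.offers_seen == 0

    @cached_property
    def O(self) -> CountBelief:
        return shifted(_O0, self.offers_seen)

    @cached_property
    def A(self) -> CountBelief:
        return shifted(_A0, self.n_accepted)

    def key(self) -> tuple[int, int, int]:
        return (self.offers_seen, self.n_accepted, self.m)


def initial_beliefs() -> BeliefState:
    """Trial-onset state: O uniform on 7..9, A uniform on 4..6, m=0."""
    return BeliefState(0, 0, 0)


class OptimalSolver:
    """Memoized dynamic-programming solver over belief states.

    Parameters
    ----------
    m_monotone : bool
        Forbid contingency improvement (an accepted 5 at m=2 keeps m=2)
        instead of the literal most-recent-choice rule.
    contingency_updates : bool
        When False, accepting never changes ``m`` — the no-penalty limit
        in which greedy acceptance is optimal.  Used for sanity checks.
    """

    def __init__(self, *, m_monotone: bool = False, contingency_updates: bool = True):
        self.m_monotone = m_monotone
        self.contingency_updates = contingency_updates
        self._sv_cache: dict[tuple[int, int, int], float] = {}

    # -- contingency bookkeeping -------------------------------------

    def _m_after_accept(self, state: BeliefState, r: int) -> int:
        if not self.contingency_updates:
            return state.m
        return update_m(
            state.m, "go", r, state.offer_index, state.n_rejected,
            m_monotone=self.m_monotone,
        )

    # -- values -------------------------------------------------------

    def state_value(self, state: BeliefState) -> float:
        """Expected further tokens from this state under optimal play (SV)."""
        key = state.key()
        cached = self._sv_cache.get(key)
        if cached is not None:
            return cached
        po = p_continue(state.O)
        pa = p_continue(state.A)
        probs = offer_probs(state.m)
        sv = 0.0
        for r, pr in zip(TOKEN_VALUES, probs):
            v_rej = 0.0
            if po > 0.0:
                nxt = BeliefState(state.offers_seen + 1, state.n_accepted, state.m)
                v_rej = po * self.state_value(nxt)
            v_acc = float(r)
            if po > 0.0 and pa > 0.0:
                nxt = BeliefState(
                    state.offers_seen + 1,
                    state.n_accepted + 1,
                    self._m_after_accept(state, r),
                )
                v_acc += po * pa * self.state_value(nxt)
            sv += pr * max(v_rej, v_acc)
        self._sv_cache[key] = sv
        return sv

    def value_reject(self, state: BeliefState) -> float:
        """V_R: expected tokens from rejecting the current offer."""
        po = p_continue(state.O)
        if po <= 0.0:
            return 0.0
        nxt = BeliefState(state.offers_seen + 1, state.n_accepted, state.m)
        return po * self.state_value(nxt)

    def value_accept_future(self, state: BeliefState, r: int) -> float:
        """V_AF: expected future tokens (beyond the face value) from accepting
        a value-``r`` offer."""
        po = p_continue(state.O)
        pa = p_continue(state.A)
        if po <= 0.0 or pa <= 0.0:
            return 0.0
        nxt = BeliefState(
            state.offers_seen + 1, state.n_accepted + 1, self._m_after_accept(state, r)
        )
        return po * pa * self.state_value(nxt)

    def ev(self, state: BeliefState, IR: int) -> float:
        """Long-term value of accepting: EV = V_AF + IR - V_R."""
        if IR not in TOKEN_VALUES:
            raise ValueError(f"offer value must be one of {TOKEN_VALUES}, got {IR}")
        return self.value_accept_future(state, IR) + IR - self.value_reject(state)

    # -- enumeration and tables ---------------------------------------

    def reachable_states(self) -> list[BeliefState]:
        """All belief states reachable from trial onset, BFS order."""
        start = initial_beliefs()
        seen = {start.key()}
        order = [start]
        frontier = [start]
        while frontier:
            nxt_frontier = []
            for s in frontier:
                if p_continue(s.O) <= 0.0:
                    continue
                succs = [BeliefState(s.offers_seen + 1, s.n_accepted, s.m)]
                if p_continue(s.A) > 0.0:
                    for r in TOKEN_VALUES:
                        succs.append(
                            BeliefState(
                                s.offers_seen + 1,
                                s.n_accepted + 1,
                                self._m_after_accept(s, r),
                            )
                        )
                for ns in succs:
                    if ns.key() not in seen:
                        seen.add(ns.key())
                        order.append(ns)
                        nxt_frontier.append(ns)
            frontier = nxt_frontier
        return order

    def ev_table(self) -> dict[tuple[int, int, int, int], float]:
        """EV for every reachable (offers_seen, n_accepted, m) state and
        offer value, keyed ``(offers_seen, n_accepted, m, IR)``."""
        table: dict[tuple[int, int, int, int], float] = {}
        for s in self.reachable_states():
            for r in TOKEN_VALUES:
                table[s.key() + (r,)] = self.ev(s, r)
        return table

    def policy_table(self) -> pd.DataFrame:
        """Optimal action and value decomposition at every reachable state
        and offer value.  Accept iff EV >= 0 (ties broken toward accept)."""
        rows = []
        for s in self.reachable_states():
            vr = self.value_reject(s)
            for r in TOKEN_VALUES:
                vaf = self.value_accept_future(s, r)
                ev = vaf + r - vr
                rows.append(
                    {
                        "offers_seen": s.offers_seen,
                        "n_accepted": s.n_accepted,
                        "n_rejected": s.n_rejected,
                        "m": s.m,
                        "is_first_offer": s.is_first_offer,
                        "IR": r,
                        "V_R": vr,
                        "V_AF": vaf,
                        "EV": ev,
                        "action": "go" if ev >= 0.0 else "nogo",
                    }
                )
        return pd.DataFrame(rows)


def brute_force_sv(
    state: BeliefState, *, m_monotone: bool = False, contingency_updates: bool = True
) -> float:
    """Exhaustive, cache-free evaluation of the state value.

    Same recursion as :meth:`OptimalSolver.state_value` but with no
    memoization: an independent tree search used as a verification
    oracle.  Cost grows as ~6^(remaining horizon), so only sensible for
    the task's <= 9-offer horizon.  Runs on raw counts with precomputed
    continuation probabilities to keep the full-tree search tractable.
    """
    # P(o>1) after s offers seen / P(a>1) after k accepts, from shifting
    # the onset uniforms.
    po_by_seen = [
        p_continue(shifted(_O0, s)) for s in range(MAX_OFFERS_SEEN + 1)
    ]
    pa_by_accepted = [
        p_continue(shifted(_A0, k)) for k in range(MAX_ACCEPTS + 1)
    ]
    dists = {m: offer_probs(m) for m in (0, 1, 2)}

    def recurse(s: int, k: int, m: int) -> float:
        po = po_by_seen[s]
        pa = pa_by_accepted[k]
        sv = 0.0
        for r, pr in zip(TOKEN_VALUES, dists[m]):
            v_rej = po * recurse(s + 1, k, m) if po > 0.0 else 0.0
            v_acc = float(r)
            if po > 0.0 and pa > 0.0:
                if contingency_updates:
                    m2 = update_m(m, "go", r, s + 1, s - k, m_monotone=m_monotone)
                else:
                    m2 = m
                v_acc += po * pa * recurse(s + 1, k + 1, m2)
            sv += pr * max(v_rej, v_acc)
        return sv

    return recurse(state.offers_seen, state.n_accepted, state.m)


_default_solver: OptimalSolver | None = None


def default_solver() -> OptimalSolver:
    """Shared literal-rule solver instance (caches persist across calls)."""
    global _default_solver
    if _default_solver is None:
        _default_solver = OptimalSolver()
    return _default_solver


def state_value(state: BeliefState) -> float:
    return default_solver().state_value(state)


def value_reject(state: BeliefState) -> float:
    return default_solver().value_reject(state)


def value_accept_future(state: BeliefState, r: int) -> float:
    return default_solver().value_accept_future(state, r)


def ev(state: BeliefState, IR: int) -> float:
    return default_solver().ev(state, IR)
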