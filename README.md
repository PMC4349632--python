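# gobudget

Modeling self-control in a budgeted sequential-offer task: when is it
worth refusing the biggest reward on the table?

`gobudget` implements the computational core of a go/nogo foraging
paradigm in which a player receives 7–9 sequential token offers (worth
3, 5 or 7) per trial but may accept only 4–6 of them, and where
accepting a high-value offer early degrades the distribution of all
future offers. Accepting a 5 shifts the offer distribution from
uniform to {0.50, 0.25, 0.25} (over 3, 5, 7 tokens), accepting a 7
shifts it to {0.90, 0.05, 0.05}; the shift applies only after the
first offer and before three offers have been rejected. The design
dissociates **immediate value** (IR, the face value) from **long-term
value** (EV, the full consequence of accepting), because for early
7-token offers EV is negative while IR is maximal.

The package provides:

- **task engine** — the generative trial model: contingency-dependent
  offer sampling, action-driven contingency updates, budget
  enforcement, payout (`gobudget.task`);
- **optimal agent** — belief-state dynamic programming over the
  player's uncertainty about offers and accepts remaining, with
  EV = V_AF + IR − V_R at every reachable state and an exhaustive
  brute-force oracle (`gobudget.solver`);
- **choice models** — four softmax observation models (immediate,
  optimal, one-weight and three-weight trade-off) with analytic
  likelihood gradients (`gobudget.models`);
- **hierarchical fitting** — random-effects EM with Laplace-
  approximated subject posteriors, iBIC model comparison and
  Cox–Snell pseudo-r² (`gobudget.fit`);
- **synthetic data** — a generator reproducing the study design (23
  subjects × 108 trials) with choices from any candidate model
  (`gobudget.synth`);
- **behavioral analyses** — state-wise acceptance grids, the
  decorrelated offer subset, and robust logistic regression of choice
  on IR and EV (`gobudget.behavior`);
- **recovery studies** — parameter and model-selection recovery at
  design scale (`gobudget.recovery`).

The trade-off models define the headline quantity: a weight
w ∈ [0, 1] per offer (or per face value) in

V_A = w·EV + (1 − w)·(IR − c),

where w near 0 means choice is driven by immediate value (impulsive)
and w near 1 by long-term value (controlled).

See `docs/methods.md` for the model equations, fitting details and
known limitations.

## Worked example

```python
from gobudget.solver import BeliefState, default_solver
from gobudget.synth import GroupDesign, generate_group
from gobudget.fit import compare_models

solver = default_solver()
state = BeliefState(offers_seen=1, n_accepted=1, m=0)  # 2nd offer, none rejected
for r in (3, 5, 7):
    print(f"EV({r}) = {solver.ev(state, r):+.3f}")

df, truth = generate_group(GroupDesign(seed=2026))     # 23 subjects x 108 trials
table, fits = compare_models(df, seed=2026)
print(table[["model", "k", "iBIC"]].round(1).to_string(index=False))
```

prints

```
EV(3) = -0.776
EV(5) = +0.855
EV(7) = -0.359
    model  k    iBIC
   trade3  5  9725.6
   trade1  3 11074.4
  optimal  1 14585.3
immediate  2 21161.9
```

The EV lines are the task's signature: at the second offer with the
uniform distribution still in force, a 5-token offer is worth
accepting but a 7-token offer is not — its face value is outweighed by
the damage to future offers. The iBIC table (smaller is better) shows
the three-weight trade-off model correctly winning on data that were
generated from it, ahead of its one-weight nesting and of the pure
long-term (optimal) and pure face-value (immediate) accounts.

The same pipeline is available from the shell:

```bash
gobudget simulate --seed 2026 --out-dir out/sim
gobudget solve    --out-dir out/policy
gobudget compare  --data out/sim/choices.csv --seed 2026 --out-dir out/cmp
gobudget analyze  --data out/sim/choices.csv --out-dir out/analysis
gobudget recover  --kind models --seed 2026 --out-dir out/recovery
gobudget validate --data out/sim/choices.csv
```

The numbered scripts under `analysis/` run the full study pipeline in
order (simulate → solve → describe → fit/compare → recovery) and write
their tables under `results/`.

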