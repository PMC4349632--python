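"""Parameter recovery of the three-weight trade-off model.

Ten generate-and-refit replicates at design scale (23 x 108).  For
each replicate the recovered native-space group means are compared
with the replicate's empirical truth, and per-subject estimates are
correlated with the generating values — the package's evidence that
individual trade-off weights are identifiable from this task.
"""

from pathlib import Path

from gobudget.recovery import parameter_recovery

SEED = 2026
OUT = Path(__file__).resolve().parent.parent / "results" / "recovery"


def main() -> None:
    res = parameter_recovery(n_replicates=10, seed=SEED)
    OUT.mkdir(parents=True, exist_ok=True)
    res.per_rep.to_csv(OUT / "parameter_recovery.csv", index=False)
    res.pairs.to_csv(OUT / "parameter_recovery_pairs.csv", index=False)

    print("per-replicate group-mean errors and truth-estimate correlations:")
    cols = [c for c in res.per_rep.columns if c.startswith(("err_w", "corr_w"))]
    print(res.per_rep[["rep"] + cols].round(3).to_string(index=False))
    for w in ("w3", "w5", "w7"):
        print(f"{w}: max |group-mean error| = "
              f"{res.per_rep[f'err_{w}'].abs().max():.3f}, "
              f"pooled per-subject correlation = {res.pooled_corr(w):.3f}")


if __name__ == "__main__":
    main()
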