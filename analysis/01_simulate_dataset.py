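"""Simulate the study-scale synthetic dataset.

23 subjects x 108 trials (three 36-trial sessions), choices from the
three-weight trade-off model with group parameters at the reference
medians.  Writes the choice log and the generating-parameter truth
table used by the downstream fitting and analysis scripts.
"""

from pathlib import Path

from gobudget.io import validate_log, write_log_csv
from gobudget.synth import GroupDesign, generate_group, truth_wide

SEED = 2026
OUT = Path(__file__).resolve().parent.parent / "results" / "dataset"


def main() -> None:
    design = GroupDesign(seed=SEED)
    df, truth = generate_group(design)
    errors = validate_log(df)
    assert not errors, errors

    OUT.mkdir(parents=True, exist_ok=True)
    write_log_csv(df, OUT / "choices.csv")
    truth.to_csv(OUT / "truth_params.csv", index=False)

    tw = truth_wide(truth)
    n_free = int((df.forced == 0).sum())
    print(f"simulated {design.n_subjects} subjects x {design.n_trials} trials "
          f"({len(df)} offers, {n_free} free choices) with seed {SEED}")
    print("true group parameter means (native space):")
    print(tw.mean().round(3).to_string())
    print(f"wrote {OUT / 'choices.csv'} and truth_params.csv")


if __name__ == "__main__":
    main()
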