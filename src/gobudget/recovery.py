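"""Parameter- and model-recovery studies on synthetic groups.

Recovery simulations are the package's check that the fitting machinery
can be trusted at the study's design scale (23 subjects x 108 trials):
parameters estimated from data generated with known settings should
track the truth, and iBIC should prefer the model that actually
generated the data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fit import compare_models, em_fit, prepare_subjects
from .models import MODEL_IDS, get_model
from .synth import GroupDesign, generate_group, truth_wide


@dataclass
class ParamRecoveryResult:
    per_rep: pd.DataFrame  # one row per replicate: group-mean errors, corr
    pairs: pd.DataFrame  # (rep, subject_id, parameter, true, estimated)

    def pooled_corr(self, parameter: str) -> float:
        sub = self.pairs[self.pairs["parameter"] == parameter]
        return float(np.corrcoef(sub["true"], sub["estimated"])[0, 1])

    def mean_abs_group_error(self, parameter: str) -> float:
        return float(self.per_rep[f"err_{parameter}"].abs().mean())


def parameter_recovery(
    n_replicates: int = 10,
    seed: int = 0,
    model_id: str = "trade3",
    n_subjects: int = 23,
    n_trials: int = 108,
) -> ParamRecoveryResult:
    """Generate-and-refit replicates of one model at design scale.

    Group-mean error per parameter is the recovered native-space mean
    of the MAP estimates minus the empirical mean of the replicate's
    true per-subject parameters.
    """
    spec = get_model(model_id)
    rep_rows, pair_rows = [], []
    for rep in range(n_replicates):
        rep_seed = seed * 1000 + rep
        design = GroupDesign(
            n_subjects=n_subjects,
            n_sessions=3 if n_trials % 3 == 0 else 1,
            trials_per_session=n_trials // (3 if n_trials % 3 == 0 else 1),
            model_id=model_id,
            seed=rep_seed,
        )
        df, truth = generate_group(design)
        tw = truth_wide(truth)
        result = em_fit(spec, df, seed=rep_seed)
        est = result.map_table().set_index("subject_id")
        row = {"rep": rep, "seed": rep_seed}
        for name in spec.param_names:
            row[f"err_{name}"] = float(
                est[name].mean() - tw[name].loc[est.index].mean()
            )
            row[f"corr_{name}"] = float(
                np.corrcoef(tw[name].loc[est.index], est[name])[0, 1]
            )
            for sid in est.index:
                pair_rows.append(
                    {
                        "rep": rep,
                        "subject_id": sid,
                        "parameter": name,
                        "true": float(tw[name].loc[sid]),
                        "estimated": float(est[name].loc[sid]),
                    }
                )
        rep_rows.append(row)
    return ParamRecoveryResult(pd.DataFrame(rep_rows), pd.DataFrame(pair_rows))


def model_recovery(
    n_replicates: int = 5,
    seed: int = 0,
    generators=MODEL_IDS,
    n_subjects: int = 23,
    n_trials: int = 108,
) -> pd.DataFrame:
    """Generate from each model, fit all four, record the iBIC winner.

    Returns one row per (generator, replicate) with the winner and the
    iBIC margin to the runner-up.
    """
    rows = []
    for generator in generators:
        for rep in range(n_replicates):
            rep_seed = seed * 1000 + 100 * MODEL_IDS.index(generator) + rep
            design = GroupDesign(
                n_subjects=n_subjects,
                n_sessions=3 if n_trials % 3 == 0 else 1,
                trials_per_session=n_trials // (3 if n_trials % 3 == 0 else 1),
                model_id=generator,
                seed=rep_seed,
            )
            df, _ = generate_group(design)
            subjects = prepare_subjects(df)
            table, _ = compare_models(subjects, seed=rep_seed)
            winner = table["model"].iloc[0]
            rows.append(
                {
                    "generator": generator,
                    "rep": rep,
                    "seed": rep_seed,
                    "winner": winner,
                    "correct": winner == generator,
                    "ibic_margin": float(table["iBIC"].iloc[1] - table["iBIC"].iloc[0]),
                }
            )
    return pd.DataFrame(rows)
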