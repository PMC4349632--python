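"""Reading, writing and validation of long-format choice logs.

One row per offer with columns: subject_id, session, trial,
offer_index, offer_value, m_at_offer, action ("go"/"nogo"), forced
(0/1), n_offers, budget.  CSV is the primary format; a JSON mirror
(records orientation, identical field names) is provided.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .task import TOKEN_VALUES, update_m

LOG_COLUMNS = [
    "subject_id",
    "session",
    "trial",
    "offer_index",
    "offer_value",
    "m_at_offer",
    "action",
    "forced",
    "n_offers",
    "budget",
]

TRIAL_KEYS = ["subject_id", "session", "trial"]


def write_log_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, columns=LOG_COLUMNS)


def read_log_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in LOG_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"choice log is missing columns: {missing}")
    return df


def write_log_json(df: pd.DataFrame, path) -> None:
    records = df[LOG_COLUMNS].to_dict(orient="records")
    Path(path).write_text(json.dumps(records, indent=1))


def read_log_json(path) -> pd.DataFrame:
    records = json.loads(Path(path).read_text())
    df = pd.DataFrame.from_records(records)
    missing = [c for c in LOG_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"choice log is missing columns: {missing}")
    return df


def annotate_states(df: pd.DataFrame) -> pd.DataFrame:
    """Add per-offer state columns derived from within-trial history:
    ``n_accepted_before`` and ``n_rejected_before`` (counts prior to the
    current offer).  Rows are sorted by trial and offer index.

    Idempotent: frames already carrying the history columns (e.g. a
    filtered subset of an annotated frame, whose rows no longer form
    complete trials) are returned with their counts untouched.
    """
    if {"n_accepted_before", "n_rejected_before"} <= set(df.columns):
        return df
    df = df.sort_values(TRIAL_KEYS + ["offer_index"], kind="stable").reset_index(
        drop=True
    )
    is_go = (df["action"] == "go").astype(int)
    grouped = is_go.groupby([df[k] for k in TRIAL_KEYS], sort=False)
    df = df.copy()
    df["n_accepted_before"] = grouped.cumsum() - is_go
    df["n_rejected_before"] = (
        df["offer_index"] - 1 - df["n_accepted_before"]
    )
    return df


def validate_log(df: pd.DataFrame) -> list[str]:
    """Check every trial invariant; returns a list of error messages
    (empty when the log is valid)."""
    errors: list[str] = []
    missing = [c for c in LOG_COLUMNS if c not in df.columns]
    if missing:
        return [f"missing columns: {missing}"]
    bad_value = ~df["offer_value"].isin(TOKEN_VALUES)
    if bad_value.any():
        errors.append(
            f"rows {df.index[bad_value].tolist()[:5]}: offer_value not in {TOKEN_VALUES}"
        )
    bad_action = ~df["action"].isin(["go", "nogo"])
    if bad_action.any():
        errors.append(f"rows {df.index[bad_action].tolist()[:5]}: action not go/nogo")
    if errors:
        return errors

    for keys, trial in df.groupby(TRIAL_KEYS, sort=False):
        label = f"trial {keys}"
        trial = trial.sort_values("offer_index")
        n_offers = int(trial["n_offers"].iloc[0])
        budget = int(trial["budget"].iloc[0])
        if not (7 <= n_offers <= 9 and 4 <= budget <= 6):
            errors.append(f"{label}: n_offers={n_offers}, budget={budget} out of range")
            continue
        if list(trial["offer_index"]) != list(range(1, n_offers + 1)):
            errors.append(f"{label}: offer_index not contiguous 1..{n_offers}")
            continue
        n_go = int((trial["action"] == "go").sum())
        if n_go > budget:
            errors.append(
                f"{label}: {n_go} accepts exceed budget {budget} "
                f"(rows {trial.index.tolist()})"
            )
        m = 0
        n_acc = n_rej = 0
        seen_forced = False
        for row in trial.itertuples():
            i = int(row.offer_index)
            if int(row.m_at_offer) != m:
                errors.append(
                    f"{label} offer {i}: m_at_offer={row.m_at_offer}, expected {m}"
                )
                break
            exhausted = n_acc >= budget
            if bool(row.forced) != exhausted:
                errors.append(f"{label} offer {i}: forced flag should be {exhausted}")
                break
            if row.forced and row.action != "nogo":
                errors.append(f"{label} offer {i}: forced record must be nogo")
                break
            if seen_forced and not row.forced:
                errors.append(f"{label} offer {i}: forced records must form a suffix")
                break
            seen_forced = seen_forced or bool(row.forced)
            m = update_m(m, row.action, int(row.offer_value), i, n_rej)
            if row.action == "go":
                n_acc += 1
            else:
                n_rej += 1
    return errors
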