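"""Coding of per-trial questionnaire answers into behavioral indicators.

After each 60 s excerpt, listeners answered two questions:

* "Do you know this music?"  — Yes / No / Not sure        -> Familiarity
* "How much did your mind wander?" — 0-25 / 25-50 / 50-75 / 75-100 (% of
  time)                                                    -> Mind Wandering

plus the design itself supplies a Repetition indicator (first vs second
presentation of each excerpt).  Coding rules:

* Familiarity is High iff the answer to the *first* presentation of the
  stimulus was Yes; No and Not sure collapse to Low.  Only the
  first-presentation answer is used (the second is contaminated by the
  repetition itself) and the code propagates to all epochs of both
  presentations of that (subject, stimulus).
* Mind Wandering is a participant-level split: each answer bin maps to its
  midpoint (12.5, 37.5, 62.5, 87.5), the subject mean is compared to the
  grand mean of subject means, and subjects strictly above it are High.
  A subject exactly at the grand mean codes Low (deterministic tie rule).
* Repetition: presentation 1 -> First, presentation 2 -> Second.

All operations are idempotent on an already-coded table.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "FAMILIARITY_ANSWERS",
    "MW_BINS",
    "MW_MIDPOINTS",
    "code_familiarity",
    "code_mind_wandering",
    "code_repetition",
    "code_indicators",
    "familiarity_agreement",
]

FAMILIARITY_ANSWERS = ("Yes", "No", "NotSure")
MW_BINS = ("0-25%", "25-50%", "50-75%", "75-100%")
MW_MIDPOINTS = {"0-25%": 12.5, "25-50%": 37.5, "50-75%": 62.5, "75-100%": 87.5}


def _validate_answers(records: pd.DataFrame) -> None:
    bad = set(records["familiarity_answer"].astype(str)) - set(FAMILIARITY_ANSWERS)
    if bad:
        raise ValueError(f"unknown familiarity answers: {sorted(bad)}")


def code_familiarity(records: pd.DataFrame) -> pd.DataFrame:
    """Add ``coded_familiarity`` from first-presentation answers.

    Raises if any (subject, stimulus) lacks a presentation-1 answer;
    missing answers are never imputed.
    """
    _validate_answers(records)
    out = records.copy()
    first = records[records["presentation"] == 1]
    key = ["subject_id", "stimulus_id"]
    answers = first.drop_duplicates(subset=key).set_index(key)["familiarity_answer"]
    pairs = out[key].drop_duplicates()
    missing = [
        tuple(row)
        for row in pairs.itertuples(index=False)
        if tuple(row) not in answers.index
    ]
    if missing:
        raise ValueError(f"missing presentation-1 familiarity answer for {missing[:5]}")
    mapped = answers.map(lambda a: "High" if str(a) == "Yes" else "Low")
    out["coded_familiarity"] = pd.MultiIndex.from_frame(out[key]).map(mapped)
    return out


def code_mind_wandering(records: pd.DataFrame) -> pd.DataFrame:
    """Add the participant-level ``coded_mw_group`` split.

    Bin midpoints -> subject mean over all trials -> grand mean of subject
    means -> High iff subject mean strictly exceeds the grand mean.
    """
    bad = set(records["mw_answer_bin"].astype(str)) - set(MW_BINS)
    if bad:
        raise ValueError(f"unknown mind-wandering bins: {sorted(bad)}")
    out = records.copy()
    mid = out["mw_answer_bin"].astype(str).map(MW_MIDPOINTS)
    subject_mean = mid.groupby(out["subject_id"]).mean()
    grand_mean = subject_mean.mean()
    codes = subject_mean.map(lambda m: "High" if m > grand_mean else "Low")
    out["coded_mw_group"] = out["subject_id"].map(codes)
    return out


def code_repetition(records: pd.DataFrame) -> pd.DataFrame:
    """Add ``coded_repetition``: First for presentation 1, Second for 2."""
    pres = records["presentation"].astype(int)
    if not pres.isin([1, 2]).all():
        raise ValueError("presentation must be 1 or 2")
    out = records.copy()
    out["coded_repetition"] = np.where(pres == 1, "First", "Second")
    return out


def code_indicators(records: pd.DataFrame) -> pd.DataFrame:
    """Apply all three coding rules; idempotent and deterministic."""
    return code_repetition(code_mind_wandering(code_familiarity(records)))


def familiarity_agreement(records: pd.DataFrame, designed_labels: dict) -> dict:
    """Agreement between answers and designed stimulus categories.

    ``designed_labels`` maps stimulus_id -> "familiar" / "unfamiliar".
    Over first presentations only, returns

    * ``p_familiar_given_familiar``:  P(answer Yes | designed familiar)
    * ``p_unfamiliar_given_unfamiliar``: P(answer No or Not sure | designed
      unfamiliar)
    """
    first = records[records["presentation"] == 1].drop_duplicates(
        subset=["subject_id", "stimulus_id"]
    )
    designed = first["stimulus_id"].map(designed_labels)
    ans = first["familiarity_answer"].astype(str)
    fam_mask = designed == "familiar"
    unfam_mask = designed == "unfamiliar"
    out = {}
    out["p_familiar_given_familiar"] = (
        float((ans[fam_mask] == "Yes").mean()) if fam_mask.any() else np.nan
    )
    out["p_unfamiliar_given_unfamiliar"] = (
        float((ans[unfam_mask] != "Yes").mean()) if unfam_mask.any() else np.nan
    )
    return out
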