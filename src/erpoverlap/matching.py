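"""Trial-group construction for separating N400 and P3-latency effects.

Two designs are provided. *Competition groups* pit the two effects against
each other: group 1 holds speeded-condition trials with low association
strength (expected: large N400) but short P3 latency, group 2 high-AS trials
with long P3 latency; groups 3 and 4 are the same subject/word-pair
combinations taken from the delayed condition, where no decision-locked P3
overlaps the N400. *Fixed-latency groups* instead select low-AS and high-AS
trials whose RT and estimated P3 latency both sit near a fixed target (0.65 s,
late enough that the P3 no longer overlaps the 400-500 ms N400 window) and
match them 1:1 within subject, so the N400 contrast can be read without
P3-latency confounds.

The scoring function is the L1 discrepancy
``score = |rt - rt_target| + |p3 - p3_target|`` (seconds, equal weights).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import stats as stats_mod
from .erp import mean_amplitude

__all__ = [
    "ScoringTargets",
    "score",
    "build_competition_groups",
    "build_fixed_latency_groups",
    "contrast_groups",
]


@dataclass(frozen=True)
class ScoringTargets:
    """Target RT and P3 latency (seconds) for the trial-scoring function."""

    rt_target: float = 0.65
    p3_target: float = 0.65

    def __post_init__(self):
        if self.rt_target <= 0 or self.p3_target <= 0:
            raise ValueError("scoring targets must be positive")


def score(trial_rt, trial_p3, targets=ScoringTargets()):
    """L1 trial score: |rt - rt_target| + |p3 - p3_target| (seconds).

    Zero iff both quantities match their targets exactly; symmetric in the two
    discrepancy terms. Accepts scalars or arrays.
    """
    rt = np.asarray(trial_rt, dtype=float)
    p3 = np.asarray(trial_p3, dtype=float)
    out = np.abs(rt - targets.rt_target) + np.abs(p3 - targets.p3_target)
    return float(out) if out.ndim == 0 else out


def _require_columns(df, cols, name):
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{name} lacks columns {missing}")


def build_competition_groups(speeded_trials, delayed_trials, *,
                             as_low_max=1, as_high_min=18,
                             p3_short_max=0.5, p3_long_min=0.6, seed=0):
    """Construct the four N400-vs-P3 competition groups.

    ``speeded_trials`` must carry ``p3_latency_s`` (estimated single-trial P3
    latency). Group 1: speeded, AS <= ``as_low_max`` and latency <=
    ``p3_short_max``; group 2: speeded, AS >= ``as_high_min`` and latency >=
    ``p3_long_min``. Only subject/word-pair combinations available (not
    rejected) in *both* conditions are eligible, so the delayed mirrors
    (groups 3 and 4) always exist; sizes of groups 1 and 2 are then equalised
    by seeded random discard. Returns a DataFrame with columns ``group`` (1-4),
    ``subject_id``, ``pair_id``, ``trial_id``.
    """
    _require_columns(speeded_trials,
                     ["trial_id", "subject_id", "pair_id", "as_score",
                      "p3_latency_s"], "speeded_trials")
    _require_columns(delayed_trials,
                     ["trial_id", "subject_id", "pair_id"], "delayed_trials")
    rng = np.random.default_rng(seed)

    key = ["subject_id", "pair_id"]
    delayed_lut = delayed_trials.set_index(key)["trial_id"]
    if not delayed_lut.index.is_unique:
        raise ValueError("delayed_trials has duplicate subject/pair combinations")
    sp = speeded_trials.merge(
        delayed_lut.rename("delayed_trial_id").reset_index(), on=key, how="inner")

    sel1 = sp[(sp["as_score"] <= as_low_max)
              & (sp["p3_latency_s"] <= p3_short_max)]
    sel2 = sp[(sp["as_score"] >= as_high_min)
              & (sp["p3_latency_s"] >= p3_long_min)]
    for label, sel in (("low-AS/short-latency", sel1), ("high-AS/long-latency", sel2)):
        if sel.empty:
            raise ValueError(f"competition selection emptied by the {label} criterion")

    n = min(len(sel1), len(sel2))
    out = []
    for g, sel in ((1, sel1), (2, sel2)):
        sel = sel.sort_values("trial_id").reset_index(drop=True)
        keep = np.sort(rng.choice(len(sel), size=n, replace=False))
        sel = sel.iloc[keep]
        out.append(pd.DataFrame({
            "group": g, "subject_id": sel["subject_id"].to_numpy(),
            "pair_id": sel["pair_id"].to_numpy(),
            "trial_id": sel["trial_id"].to_numpy()}))
        out.append(pd.DataFrame({
            "group": g + 2, "subject_id": sel["subject_id"].to_numpy(),
            "pair_id": sel["pair_id"].to_numpy(),
            "trial_id": sel["delayed_trial_id"].to_numpy()}))
    result = pd.concat(out, ignore_index=True).sort_values(
        ["group", "trial_id"], kind="stable").reset_index(drop=True)
    return result


def build_fixed_latency_groups(speeded_trials, *, as_low_max=1, as_high_min=18,
                               n_per_subject=75, targets=ScoringTargets()):
    """Select latency/RT-matched low-AS and high-AS groups per subject.

    For each subject the low-AS group holds the ``n_per_subject`` trials with
    AS <= ``as_low_max`` scoring lowest against the fixed targets. Then, in
    ascending order of that anchor score, each selected trial is matched
    greedily (1:1, without replacement) to the not-yet-taken high-AS trial
    (AS >= ``as_high_min``) minimising the score with the targets set to the
    anchor trial's own RT and latency. Ties break toward the lower trial_id.

    Returns a DataFrame with columns ``group`` ("lowAS"/"highAS"),
    ``subject_id``, ``pair_id``, ``trial_id``, ``partner_trial_id``, ``score``
    (anchor score for lowAS rows, pairing score for highAS rows).
    """
    _require_columns(speeded_trials,
                     ["trial_id", "subject_id", "pair_id", "as_score", "rt_s",
                      "p3_latency_s"], "speeded_trials")
    trials = speeded_trials.dropna(subset=["rt_s", "p3_latency_s"])
    rows = []
    shortfalls = []
    for subject, sub in trials.groupby("subject_id", sort=True):
        low = sub[sub["as_score"] <= as_low_max].copy()
        high = sub[sub["as_score"] >= as_high_min].copy()
        if len(low) < n_per_subject or len(high) < n_per_subject:
            shortfalls.append((subject, len(low), len(high)))
            continue
        low["anchor_score"] = score(low["rt_s"].to_numpy(),
                                    low["p3_latency_s"].to_numpy(), targets)
        low = low.sort_values(["anchor_score", "trial_id"],
                              kind="stable").head(n_per_subject)

        high = high.sort_values("trial_id").reset_index(drop=True)
        h_rt = high["rt_s"].to_numpy()
        h_p3 = high["p3_latency_s"].to_numpy()
        taken = np.zeros(len(high), dtype=bool)
        for _, anchor in low.iterrows():
            pair_scores = (np.abs(h_rt - anchor["rt_s"])
                           + np.abs(h_p3 - anchor["p3_latency_s"]))
            pair_scores = np.where(taken, np.inf, pair_scores)
            j = int(np.argmin(pair_scores))    # first minimum = lowest trial_id
            taken[j] = True
            partner = high.iloc[j]
            rows.append(("lowAS", subject, anchor["pair_id"],
                         anchor["trial_id"], partner["trial_id"],
                         anchor["anchor_score"]))
            rows.append(("highAS", subject, partner["pair_id"],
                         partner["trial_id"], anchor["trial_id"],
                         float(pair_scores[j])))
    if shortfalls:
        detail = "; ".join(
            f"subject {s}: {nl} low-AS / {nh} high-AS eligible (need "
            f"{n_per_subject})" for s, nl, nh in shortfalls)
        raise ValueError(f"insufficient eligible trials: {detail}")
    return pd.DataFrame(rows, columns=[
        "group", "subject_id", "pair_id", "trial_id", "partner_trial_id",
        "score"])


def contrast_groups(epochs, assignment, *, group_a, group_b, channel="Pz",
                    window=(0.4, 0.5)):
    """Contrast the mean voltage of two trial groups at one channel.

    Per-trial window means (``channel``, ``window``) are fed to
    :func:`stats.fit_lme` with +/-1 group coding as the fixed effect
    (``group_a`` coded +1, ``group_b`` coded -1). Returns a dict with the
    per-group means, their difference (a - b) and the mixed-model result.
    """
    sub_a = assignment[assignment["group"] == group_a]
    sub_b = assignment[assignment["group"] == group_b]
    if sub_a.empty or sub_b.empty:
        raise ValueError(f"empty group in contrast ({group_a!r} vs {group_b!r})")
    amps = mean_amplitude(epochs, channel, window)
    amp_by_trial = pd.Series(amps, index=epochs.metadata["trial_id"].to_numpy())

    frames = []
    for coding, sub in ((1.0, sub_a), (-1.0, sub_b)):
        missing = ~sub["trial_id"].isin(amp_by_trial.index)
        if missing.any():
            raise ValueError(
                f"{int(missing.sum())} group trials missing from the epochs")
        frames.append(pd.DataFrame({
            "amplitude": amp_by_trial.loc[sub["trial_id"]].to_numpy(),
            "coding": coding,
            "subject_id": sub["subject_id"].to_numpy(),
            "pair_id": sub["pair_id"].to_numpy(),
        }))
    table = pd.concat(frames, ignore_index=True)
    mean_a = float(frames[0]["amplitude"].mean())
    mean_b = float(frames[1]["amplitude"].mean())
    lme = stats_mod.fit_lme(table, stats_mod.LmeSpec(
        dependent="amplitude", fixed="coding"))
    return {
        "mean_a": mean_a,
        "mean_b": mean_b,
        "difference": mean_a - mean_b,
        "lme": lme,
        "n_per_group": (len(sub_a), len(sub_b)),
    }
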