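"""Attention-bias scoring of trial-level dot-probe reaction times.

On each trial an emotional face and a neutral face appear left and right of
fixation, then a probe replaces one of them.  Faster responses when the
probe appears at the emotional face's location indicate attention captured
by that face.  With R/L the probe position and e the emotional-face
position, the per-condition bias score is

    bias = 1/2 * [(RpLe - RpRe) + (LpRe - LpLe)]

where each term is a mean RT over the trials of that cell (RpLe: probe
right, emotional face left, and so on).  The score equals the mean
incongruent-RT minus the mean congruent-RT; positive values mean attention
toward the emotional face, negative values attentional avoidance.

Trial hygiene (incorrect responses, implausibly fast or slow RTs, optional
per-subject SD clipping) is configurable; the defaults are conventional
dot-probe choices, not prescriptions of any particular study.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

CONDITIONS = ("NH", "NS", "NA", "NF")  # neutral-happy, -sad, -anger, -fear
_CELLS = ("RpLe", "RpRe", "LpRe", "LpLe")

REQUIRED_COLUMNS = ("subject_id", "condition", "face_side", "probe_side", "rt_ms", "correct")


def _validate_trials(trials: pd.DataFrame) -> pd.DataFrame:
    missing = set(REQUIRED_COLUMNS) - set(trials.columns)
    if missing:
        raise ValueError(f"trial table missing columns: {sorted(missing)}")
    bad_sides = set(trials["face_side"]).union(trials["probe_side"]) - {"L", "R"}
    if bad_sides:
        raise ValueError(f"sides must be 'L' or 'R', found {sorted(bad_sides)}")
    if (trials["rt_ms"] <= 0).any():
        raise ValueError("all reaction times must be positive")
    return trials


def filter_trials(
    trials: pd.DataFrame,
    rt_min_ms: float = 200.0,
    rt_max_ms: float = 1500.0,
    sd_clip: float | None = None,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Remove incorrect and out-of-range trials.

    Order of rules: drop incorrect responses, drop RTs outside
    ``[rt_min_ms, rt_max_ms]``, then optionally drop trials beyond
    ``sd_clip`` standard deviations of each subject's remaining RT
    distribution.  Returns the filtered table and per-rule removal counts.
    """
    if rt_min_ms <= 0 or rt_max_ms <= rt_min_ms:
        raise ValueError("need 0 < rt_min_ms < rt_max_ms")
    trials = _validate_trials(trials)
    report = {"n_input": len(trials)}
    kept = trials[trials["correct"].astype(bool)]
    report["removed_incorrect"] = len(trials) - len(kept)
    in_range = kept[(kept["rt_ms"] >= rt_min_ms) & (kept["rt_ms"] <= rt_max_ms)]
    report["removed_rt_range"] = len(kept) - len(in_range)
    if sd_clip is not None:
        if sd_clip <= 0:
            raise ValueError("sd_clip must be positive")
        stats = in_range.groupby("subject_id")["rt_ms"].agg(["mean", "std"])
        stats["std"] = stats["std"].fillna(0.0)
        mu = in_range["subject_id"].map(stats["mean"])
        sd = in_range["subject_id"].map(stats["std"])
        ok = (in_range["rt_ms"] - mu).abs() <= sd_clip * sd
        report["removed_sd_clip"] = int((~ok).sum())
        in_range = in_range[ok]
    else:
        report["removed_sd_clip"] = 0
    report["n_kept"] = len(in_range)
    return in_range.reset_index(drop=True), report


def _cell_of(trials: pd.DataFrame) -> pd.Series:
    # cell label: probe side then emotional-face side, e.g. probe right +
    # emotional face left -> RpLe
    return trials["probe_side"].astype(str) + "p" + trials["face_side"].astype(str) + "e"


def bias_score(
    trials: pd.DataFrame, emotion: str, cell_stat: str = "mean"
) -> pd.DataFrame:
    """Per-subject bias score for one emotion condition.

    Expects filtered trials.  A subject's score is emitted only when all
    four probe-by-face cells contain at least one trial; otherwise the row
    is flagged missing with the reason recorded.

    Returns a frame with columns ``subject_id, condition, bias_ms,
    n_RpLe, n_RpRe, n_LpRe, n_LpLe, valid, reason``.
    """
    if cell_stat not in ("mean", "median"):
        raise ValueError("cell_stat must be 'mean' or 'median'")
    trials = _validate_trials(trials)
    sub = trials[trials["condition"] == emotion].copy()
    sub["cell"] = _cell_of(sub)
    agg = sub.groupby(["subject_id", "cell"])["rt_ms"].agg(cell_stat).unstack("cell")
    counts = sub.groupby(["subject_id", "cell"]).size().unstack("cell").fillna(0).astype(int)
    rows = []
    for subject in trials["subject_id"].unique():
        cell_ns = {c: int(counts.loc[subject, c]) if subject in counts.index and c in counts.columns else 0 for c in _CELLS}
        empty = [c for c in _CELLS if cell_ns[c] == 0]
        if empty:
            rows.append((subject, emotion, np.nan, *cell_ns.values(), False, f"empty cells: {','.join(empty)}"))
            continue
        g = agg.loc[subject]
        score = 0.5 * ((g["RpLe"] - g["RpRe"]) + (g["LpRe"] - g["LpLe"]))
        rows.append((subject, emotion, float(score), *cell_ns.values(), True, ""))
    return pd.DataFrame(
        rows,
        columns=["subject_id", "condition", "bias_ms", *[f"n_{c}" for c in _CELLS], "valid", "reason"],
    )


def score_cohort(
    trials: pd.DataFrame,
    emotions: Sequence[str] = CONDITIONS,
    cell_stat: str = "mean",
) -> pd.DataFrame:
    """Tidy bias-score table: one row per subject and emotion condition."""
    return pd.concat(
        [bias_score(trials, e, cell_stat) for e in emotions], ignore_index=True
    )


def scores_wide(scores: pd.DataFrame) -> pd.DataFrame:
    """Pivot tidy scores to a subject-by-condition frame of bias values."""
    return scores.pivot(index="subject_id", columns="condition", values="bias_ms")


class DotProbeScorer(TransformerMixin, BaseEstimator):
    """Transformer from raw trial tables to subject-by-condition bias scores.

    Applies the trial filter, scores each requested emotion condition, and
    returns the wide per-subject frame.  Filter removal counts from the most
    recent ``transform`` are kept in ``filter_report_``.
    """

    def __init__(
        self,
        emotions: Sequence[str] = CONDITIONS,
        rt_min_ms: float = 200.0,
        rt_max_ms: float = 1500.0,
        sd_clip: float | None = None,
        cell_stat: str = "mean",
    ):
        self.emotions = emotions
        self.rt_min_ms = rt_min_ms
        self.rt_max_ms = rt_max_ms
        self.sd_clip = sd_clip
        self.cell_stat = cell_stat

    def fit(self, X: pd.DataFrame, y=None) -> "DotProbeScorer":
        _validate_trials(X)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        filtered, self.filter_report_ = filter_trials(
            X, self.rt_min_ms, self.rt_max_ms, self.sd_clip
        )
        self.scores_ = score_cohort(filtered, self.emotions, self.cell_stat)
        return scores_wide(self.scores_)
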