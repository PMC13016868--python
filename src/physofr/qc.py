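"""Functional outlier screening via Fraiman-Muniz curve depth.

A trial's curve depth within one channel's collection is the time-average
of the pointwise univariate depth ``1 - |1/2 - F_t(x_i(t))|`` where ``F_t``
is the empirical CDF over the n curves at time t.  The least central 1% of
curves per channel are flagged; a trial flagged in any channel is removed
entirely, and participants left with too few trials for any odorant are
discarded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import TrialEpochSet


def fm_depth(curves: np.ndarray) -> np.ndarray:
    """Fraiman-Muniz depth of each row of an (n, T) curve matrix.

    Values lie in (0, 1]; a single curve has depth 0.5 (its own empirical
    CDF is 1 everywhere).
    """
    curves = np.asarray(curves, dtype=float)
    if curves.ndim != 2:
        raise ValueError("curves must be a 2-D (n, T) matrix on a common grid")
    if curves.shape[0] < 1:
        raise ValueError("need at least one curve")
    if not np.isfinite(curves).all():
        raise ValueError("curves contain non-finite values")
    n = curves.shape[0]
    # F_t(x_i(t)) = #{j : x_j(t) <= x_i(t)} / n, computed per time point
    order = np.argsort(curves, axis=0, kind="stable")
    ranks = np.empty_like(curves)
    # count of values <= x, with ties sharing the maximal count
    srt = np.take_along_axis(curves, order, axis=0)
    for t in range(curves.shape[1]):
        counts = np.searchsorted(srt[:, t], curves[:, t], side="right")
        ranks[:, t] = counts
    F = ranks / n
    return (1.0 - np.abs(0.5 - F)).mean(axis=1)


@dataclass
class DepthResult:
    """Per-(trial, channel) depth scores, ranks, and outlier flags."""

    table: pd.DataFrame  # columns: trial_index, channel, depth, rank, outlier
    fraction: float

    def flagged_trials(self) -> np.ndarray:
        """Indices of trials flagged in at least one channel (whole-trial rule)."""
        t = self.table
        return np.unique(t.loc[t["outlier"], "trial_index"].to_numpy())


def depth_by_channel(epochs: TrialEpochSet) -> pd.DataFrame:
    """Depth of every trial curve, computed within each channel separately."""
    rows = []
    for ci, c in enumerate(epochs.channels):
        d = fm_depth(epochs.data[:, ci, :])
        rank = np.argsort(np.argsort(d, kind="stable"), kind="stable")
        rows.append(pd.DataFrame({
            "trial_index": np.arange(len(d)), "channel": c,
            "depth": d, "rank": rank, "outlier": False,
        }))
    return pd.concat(rows, ignore_index=True)


def flag_outliers(depths: pd.DataFrame, fraction: float = 0.01) -> DepthResult:
    """Flag the ``floor(fraction * n)`` lowest-depth curves per channel.

    Ties are broken by stable trial order, so reruns flag identical trials.
    """
    if not (0 <= fraction < 1):
        raise ValueError("fraction must be in [0, 1)")
    out = depths.copy()
    out["outlier"] = False
    for c, grp in out.groupby("channel", sort=False):
        k = int(np.floor(fraction * len(grp)))
        if k > 0:
            idx = grp.sort_values(["depth", "trial_index"], kind="stable").index[:k]
            out.loc[idx, "outlier"] = True
    return DepthResult(table=out, fraction=fraction)


@dataclass
class ExclusionReport:
    removed_trials: pd.DataFrame
    removed_participants: list

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"kind": "trial", "participant_id": r["participant_id"],
             "trial": r["trial"], "reason": "low functional depth"}
            for _, r in self.removed_trials.iterrows()
        ]
        rows += [
            {"kind": "participant", "participant_id": p, "trial": -1,
             "reason": reason}
            for p, reason in self.removed_participants
        ]
        return pd.DataFrame(rows, columns=["kind", "participant_id", "trial", "reason"])


def apply_exclusions(epochs: TrialEpochSet, ratings: pd.DataFrame,
                     depth_result: DepthResult, min_trials: int = 8):
    """Remove flagged trials, then participants below the per-odor retention rule.

    A participant is discarded when, after outlier removal, fewer than
    ``min_trials`` trials remain for any odorant.  Returns
    ``(epochs, ratings, report)``.
    """
    flagged = depth_result.flagged_trials()
    keep = np.ones(len(epochs.trials), dtype=bool)
    keep[flagged] = False
    removed_trials = epochs.trials.loc[~keep].copy()

    kept_epochs = epochs.select(keep)
    key = ["participant_id", "trial"]
    kept_keys = kept_epochs.trials[key]
    kept_ratings = ratings.merge(kept_keys, on=key)

    removed_participants = []
    if min_trials > 0:
        counts = kept_epochs.trials.groupby(["participant_id", "odor"]).size()
        for pid in kept_epochs.trials["participant_id"].unique():
            per_odor = counts.loc[pid]
            if per_odor.min() < min_trials or len(per_odor) < len(epochs.trials["odor"].unique()):
                removed_participants.append(
                    (pid, f"fewer than {min_trials} retained trials for an odorant"))
        bad = {p for p, _ in removed_participants}
        if bad:
            mask = ~kept_epochs.trials["participant_id"].isin(bad).to_numpy()
            kept_epochs = kept_epochs.select(mask)
            kept_ratings = kept_ratings[~kept_ratings["participant_id"].isin(bad)].reset_index(drop=True)

    if len(kept_epochs.trials) == 0:
        raise ValueError("all trials excluded: empty survivor set")
    return kept_epochs, kept_ratings.reset_index(drop=True), ExclusionReport(
        removed_trials=removed_trials, removed_participants=removed_participants)
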