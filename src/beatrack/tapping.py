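"""Finger-tapping variability: cleaning rules, MAD, and group comparison.

Tapping consistency is quantified as the (unscaled) median absolute
deviation of the inter-tap intervals per trial, a robust dispersion measure
in raw milliseconds. Cleaning follows fixed rules: the first taps (before
981 ms, i.e. the first two beats) are dropped so the participant has heard
two beats; intervals faster than 50 ms (involuntary double-presses) or
slower than 3000 ms (idling) are removed; trials with fewer than the
required minimum of surviving intervals are excluded (6 in the 16-tap
design, 15 in the 32-tap design); and within each participant and
condition, trials containing an interval more than three standard
deviations above the pooled mean are excluded, as are participants whose
condition-mean MAD is more than three standard deviations above the group
mean. The tonal-vs-atonal contrast is a one-tailed Wilcoxon signed-rank
test on per-participant condition means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .synth import TappingTrial

__all__ = [
    "CleaningRules",
    "TappingSummary",
    "EXCLUDED",
    "expected_taps",
    "clean_trial",
    "trial_mad",
    "outlier_filter",
    "group_compare",
    "summarize",
]


class _Excluded:
    """Sentinel: the trial did not survive cleaning."""

    def __repr__(self) -> str:
        return "EXCLUDED"

    def __bool__(self) -> bool:
        return False


EXCLUDED = _Excluded()

_NOTE_FRACTION = {"whole": 1, "half": 2, "quarter": 4, "eighth": 8, "sixteenth": 16}


@dataclass(frozen=True)
class CleaningRules:
    """Thresholds of the tap-cleaning pipeline (times in the stated units)."""

    min_tap_time: float = 0.981  # s; drops the first two taps of a 652-ms beat
    min_interval: float = 50.0  # ms
    max_interval: float = 3000.0  # ms
    min_intervals: int = 6  # required surviving intervals (15 for 32-tap trials)
    trial_sd_k: float = 3.0
    participant_sd_k: float = 3.0

    def __post_init__(self) -> None:
        if self.min_interval >= self.max_interval:
            raise ValueError("min_interval must be < max_interval")


#: Rule presets: the 16-tap main design and the 32-tap replication design.
RULES_MAIN = CleaningRules(min_intervals=6)
RULES_REPLICATION = CleaningRules(min_intervals=15)


@dataclass
class TappingSummary:
    """Per-trial MADs and retention bookkeeping for one participant/condition."""

    participant: str
    condition: str
    trial_mads: list[float]
    n_retained: int
    n_excluded: int
    expected_intervals: int

    @property
    def mean_mad(self) -> float:
        return float(np.mean(self.trial_mads)) if self.trial_mads else float("nan")


def expected_taps(
    n_bars: int, meter: tuple[int, int] = (4, 4), beat_unit: str = "eighth", tempo: float = 46.0
) -> int:
    """Number of beat-unit events in ``n_bars`` (e.g. 2 bars of 4/4 at the
    eighth-note beat -> 16 taps)."""
    beats, unit = meter
    frac = _NOTE_FRACTION[beat_unit]
    if frac % unit:
        raise ValueError(f"beat unit {beat_unit!r} does not divide the {beats}/{unit} bar")
    return int(n_bars * beats * (frac // unit))


def clean_trial(
    trial: TappingTrial, rules: CleaningRules = RULES_MAIN, expected: int = 16
):
    """Surviving inter-tap intervals (ms) of one trial, or EXCLUDED.

    Taps before ``min_tap_time`` are dropped; intervals between consecutive
    remaining taps outside [min_interval, max_interval] are removed
    (intervals spanning a removed interior interval are not re-bridged); the
    trial is excluded if fewer than ``rules.min_intervals`` intervals
    survive.
    """
    taps = np.asarray(trial.tap_times, dtype=float)
    taps = taps[taps >= rules.min_tap_time]
    intervals = np.diff(taps) * 1000.0
    intervals = intervals[(intervals >= rules.min_interval) & (intervals <= rules.max_interval)]
    if intervals.size < rules.min_intervals:
        return EXCLUDED
    return intervals


def trial_mad(intervals: np.ndarray) -> float:
    """Median absolute deviation of intervals (ms), unscaled."""
    intervals = np.asarray(intervals, dtype=float)
    if intervals.size < 2:
        raise ValueError("need at least 2 intervals for a MAD")
    return float(np.median(np.abs(intervals - np.median(intervals))))


def outlier_filter(
    trials: pd.DataFrame, rules: CleaningRules = RULES_MAIN
) -> tuple[pd.DataFrame, list[str]]:
    """Drop outlier trials, then outlier participants.

    ``trials`` needs columns participant, condition, trial, intervals (array
    of ms) and mad. A trial is excluded if any of its intervals exceeds the
    participant x condition pooled mean by ``trial_sd_k`` standard
    deviations; a participant is excluded if any condition-mean MAD exceeds
    the group mean by ``participant_sd_k`` standard deviations. Returns the
    retained trials and the excluded participant labels.
    """
    keep_rows = []
    for (_, _), grp in trials.groupby(["participant", "condition"], sort=False):
        pooled = np.concatenate([np.asarray(iv, float) for iv in grp["intervals"]])
        bound = pooled.mean() + rules.trial_sd_k * pooled.std(ddof=0)
        for idx, row in grp.iterrows():
            if np.all(np.asarray(row["intervals"], float) <= bound + 1e-12):
                keep_rows.append(idx)
    kept = trials.loc[sorted(keep_rows)]

    excluded_participants: list[str] = []
    cond_means = kept.groupby(["participant", "condition"])["mad"].mean().reset_index()
    for cond, grp in cond_means.groupby("condition"):
        bound = grp["mad"].mean() + rules.participant_sd_k * grp["mad"].std(ddof=0)
        if grp["mad"].std(ddof=0) == 0:
            continue
        excluded_participants += list(grp.loc[grp["mad"] > bound, "participant"])
    excluded_participants = sorted(set(excluded_participants))
    kept = kept[~kept["participant"].isin(excluded_participants)]
    return kept.reset_index(drop=True), excluded_participants


def summarize(
    trials: list[TappingTrial], rules: CleaningRules = RULES_MAIN, expected: int = 16
) -> tuple[pd.DataFrame, list[str]]:
    """Clean a batch of trials and apply the outlier filters.

    Returns a per-trial DataFrame (participant, condition, trial, intervals,
    mad) of retained trials plus the list of excluded participants.
    """
    rows = []
    for i, tr in enumerate(trials):
        intervals = clean_trial(tr, rules, expected)
        if intervals is EXCLUDED:
            continue
        rows.append(
            {
                "participant": tr.participant,
                "condition": tr.condition,
                "trial": i,
                "intervals": intervals,
                "mad": trial_mad(intervals),
            }
        )
    frame = pd.DataFrame(rows)
    if frame.empty:
        return frame, []
    return outlier_filter(frame, rules)


def group_compare(
    mean_mads: pd.DataFrame, conditions: tuple[str, str] = ("tonal", "atonal")
) -> dict:
    """One-tailed Wilcoxon signed-rank test of condition mean MADs.

    ``mean_mads`` needs columns participant, condition, mean_mad with both
    conditions present per participant. Tests the directed hypothesis that
    the second condition (atonal) is more variable than the first. Exact
    enumeration for n <= 12, normal approximation (Z) otherwise; zero
    differences are excluded per the standard rule.
    """
    a_name, b_name = conditions
    wide = mean_mads.pivot(index="participant", columns="condition", values="mean_mad")
    if not {a_name, b_name} <= set(wide.columns) or wide[[a_name, b_name]].isna().any().any():
        raise ValueError("participants must be paired across both conditions")
    a = wide[a_name].to_numpy()
    b = wide[b_name].to_numpy()
    n = a.size
    if n < 5:
        raise ValueError(f"refusing to test n={n} < 5 paired participants")

    diff = a - b  # negative when the second condition is more variable
    nz = diff[diff != 0]
    if nz.size == 0:
        return {
            "Z": 0.0,
            "p_one_tailed": 0.5,
            "mean_difference": 0.0,
            "percent_direction": 0.0,
            "n": n,
        }
    method = "exact" if nz.size <= 12 else "approx"
    res = sstats.wilcoxon(a, b, alternative="less", zero_method="wilcox", method=method)
    # signed normal-approximation Z of the W+ statistic (reported alongside
    # the exact p for small n)
    m = nz.size
    ranks = sstats.rankdata(np.abs(nz))
    w_plus = ranks[nz > 0].sum()
    mu = m * (m + 1) / 4.0
    sigma = np.sqrt(m * (m + 1) * (2 * m + 1) / 24.0)
    z = (w_plus - mu) / sigma if sigma > 0 else 0.0
    return {
        "Z": float(z),
        "p_one_tailed": float(res.pvalue),
        "mean_difference": float(np.mean(b - a)),
        "percent_direction": float(100.0 * np.mean(b > a)),
        "n": n,
    }
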