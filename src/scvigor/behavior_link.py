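"""Neuron-to-behavior coupling indices and cross-neuron correlations.

Each unit's influence on the upcoming saccade is summarized by two
Pearson correlations over trials: firing rate in the 80-160 ms
post-target window versus reaction time (RT index) and versus peak
velocity (PV index).  Trials with fewer than 5 spikes in the window are
dropped, and a unit needs at least 15 surviving trials for an index to
be defined.  Across units of a subtype, the value index is then
correlated with the RT and PV indices — neurons whose firing
discriminates object value more strongly also predict saccade vigor
more strongly (negative value-RT, positive value-PV relation).
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import TooFewTrialsError, UndefinedCorrelationError

MIN_SPIKES_PER_TRIAL = 5
MIN_VALID_TRIALS = 15
ALPHA = 0.05

OVERLAP_CATEGORIES = (
    "reward_only", "rt_only", "pv_only",
    "reward_rt", "reward_pv", "rt_pv", "all_three", "none",
)


def rate_behavior_correlation(
    rates: np.ndarray,
    behavior: np.ndarray,
    counts: np.ndarray | None = None,
    min_spikes: int = MIN_SPIKES_PER_TRIAL,
    min_trials: int = MIN_VALID_TRIALS,
) -> tuple[float, float, int]:
    """Pearson correlation between per-trial firing rate and behavior.

    ``counts`` are the per-trial spike counts used for the >=
    ``min_spikes`` inclusion rule; when omitted they are assumed equal
    to the rates scaled to an 80 ms window.  Returns ``(r, p, n)``.
    """
    rates = np.asarray(rates, dtype=float)
    behavior = np.asarray(behavior, dtype=float)
    if counts is None:
        counts = rates * 0.08
    counts = np.asarray(counts, dtype=float)
    keep = counts >= min_spikes
    r_kept, b_kept = rates[keep], behavior[keep]
    n = int(keep.sum())
    if n < min_trials:
        raise TooFewTrialsError(
            f"only {n} trials with >= {min_spikes} spikes (need {min_trials})")
    if np.ptp(r_kept) == 0 or np.ptp(b_kept) == 0:
        raise UndefinedCorrelationError("constant rates or behavior")
    r, p = stats.pearsonr(r_kept, b_kept)
    return float(r), float(p), n


def build_index_table(unit_rows: list[dict]) -> pd.DataFrame:
    """Assemble the per-unit index table from precomputed row dicts.

    Each row must carry ``unit_id`` and ``subtype``; index fields
    (value_index, auroc, rt_index, pv_index with their p-values and
    ``n_valid_trials``) may be missing, in which case the corresponding
    significance flag is False and the missing index is NaN with a
    reason.  Significance flags are (re)derived from the p-values at
    alpha = 0.05.
    """
    cols = ["unit_id", "subtype", "value_index", "auroc", "value_p",
            "rt_index", "rt_p", "pv_index", "pv_p", "n_valid_trials",
            "index_missing_reason"]
    df = pd.DataFrame(unit_rows)
    for c in cols:
        if c not in df.columns:
            df[c] = np.nan
    df["index_missing_reason"] = df["index_missing_reason"].fillna("none")
    df["sig_reward"] = df["value_p"] < ALPHA
    df["sig_rt"] = df["rt_p"] < ALPHA
    df["sig_pv"] = df["pv_p"] < ALPHA
    return df[cols + ["sig_reward", "sig_rt", "sig_pv"]]


def index_correlation(
    table: pd.DataFrame,
    subtype: str,
    x: str = "value_index",
    y: str = "rt_index",
) -> tuple[float, float, int, float, float]:
    """Cross-neuron Pearson correlation between two indices of a subtype.

    Returns ``(r, p, n, slope, intercept)`` with the best-fit line for
    plotting; units with either index undefined are dropped.
    """
    sub = table[table["subtype"] == subtype]
    xv = sub[x].to_numpy(dtype=float)
    yv = sub[y].to_numpy(dtype=float)
    ok = np.isfinite(xv) & np.isfinite(yv)
    xv, yv = xv[ok], yv[ok]
    if xv.size < 3:
        raise TooFewTrialsError(f"need >= 3 {subtype} units with both indices")
    r, p = stats.pearsonr(xv, yv)
    slope, intercept = np.polyfit(xv, yv, 1)
    return float(r), float(p), int(xv.size), float(slope), float(intercept)


def modulation_overlap(table: pd.DataFrame) -> pd.DataFrame:
    """Counts of reward/RT/PV-modulated units per subtype (Venn cells).

    The eight categories partition each subtype's units exactly.
    """
    rows = []
    for subtype, sub in table.groupby("subtype"):
        rw = sub["sig_reward"].fillna(False).to_numpy(dtype=bool)
        rt = sub["sig_rt"].fillna(False).to_numpy(dtype=bool)
        pv = sub["sig_pv"].fillna(False).to_numpy(dtype=bool)
        counts = {
            "reward_only": int(np.sum(rw & ~rt & ~pv)),
            "rt_only": int(np.sum(~rw & rt & ~pv)),
            "pv_only": int(np.sum(~rw & ~rt & pv)),
            "reward_rt": int(np.sum(rw & rt & ~pv)),
            "reward_pv": int(np.sum(rw & ~rt & pv)),
            "rt_pv": int(np.sum(~rw & rt & pv)),
            "all_three": int(np.sum(rw & rt & pv)),
            "none": int(np.sum(~rw & ~rt & ~pv)),
        }
        counts["subtype"] = subtype
        counts["total"] = len(sub)
        rows.append(counts)
    return pd.DataFrame(rows, columns=["subtype", *OVERLAP_CATEGORIES, "total"])
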