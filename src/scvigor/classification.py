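"""Functional classification of SC units from window-rate contrasts.

Units are classified into visual, visuomotor, motor and tonic subtypes
from per-trial firing rates in five canonical windows: baseline (-200 to
0 ms) , phasic #1 (0-80 ms) and phasic #2 (80-160 ms) aligned on target
onset, and pre-saccadic (-100 to -50 ms) and peri-saccadic (-50 to
+20 ms) aligned on saccade onset.  A Kruskal-Wallis omnibus test across
the five windows screens for any task response; the subtype criteria are
then evaluated with directional rank-sum comparisons at the same alpha.

Because the visual criteria are a subset of the visuomotor criteria, a
unit meeting both is visuomotor iff its pre- vs. peri-saccadic contrast
is significant.  The excitatory criteria are evaluated before the tonic
(suppression) criterion: rank tests on short, low-count windows have a
small shape bias toward "reduction" even at equal means, and a unit with
a genuine phasic increase should never fall into the suppressed class.
The motor and tonic gates are mutually exclusive in practice because
motor requires phasic1 < phasic2 while suppression sets phasic1 >
phasic2.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ScvigorError
from .spike_tools import WindowSpec

ALPHA = 0.05

CLASS_WINDOWS = {
    "baseline": WindowSpec("baseline", -200.0, 0.0, "target_on"),
    "phasic1": WindowSpec("phasic1", 0.0, 80.0, "target_on"),
    "phasic2": WindowSpec("phasic2", 80.0, 160.0, "target_on"),
    "presacc": WindowSpec("presacc", -100.0, -50.0, "saccade_on"),
    "perisacc": WindowSpec("perisacc", -50.0, 20.0, "saccade_on"),
}

SUBTYPES = ("visual", "visuomotor", "motor", "tonic")
_REQUIRED = ("baseline", "phasic1", "phasic2", "presacc", "perisacc")


@dataclass
class ClassLabel:
    """Subtype assignment with the statistics that produced it."""

    unit_id: str
    subtype: str                      # visual|visuomotor|motor|tonic|unclassified
    exclusion_reason: str = "none"    # none|too_few_trials_or_spikes|no_task_response|criteria_not_met
    pvalues: dict = field(default_factory=dict)


def _rank_p(x: np.ndarray, y: np.ndarray, alternative: str) -> float:
    """Rank-sum p-value; degenerate inputs count as no evidence (p=1)."""
    if x.size == 0 or y.size == 0:
        return 1.0
    if np.ptp(np.concatenate([x, y])) == 0:
        return 1.0
    return float(stats.mannwhitneyu(x, y, alternative=alternative).pvalue)


def classify_unit(rates: dict[str, np.ndarray], alpha: float = ALPHA,
                  unit_id: str = "") -> ClassLabel:
    """Assign a functional subtype from the five canonical window rates.

    ``rates`` maps window names (baseline, phasic1, phasic2, presacc,
    perisacc) to per-trial firing rates.  The decision sequence is:

    1. Kruskal-Wallis omnibus across all five windows; p >= alpha means
       no task response and the unit stays unclassified.
    2. Tonic: phasic1 or phasic2 significantly *below* baseline.
    3. Visual/visuomotor: phasic1 and phasic2 significantly above
       baseline; visuomotor additionally shows a pre- vs. peri-saccadic
       difference, otherwise visual.
    4. Motor: pre- vs. peri-saccadic difference and phasic1
       significantly below phasic2.
    """
    missing = [w for w in _REQUIRED if w not in rates]
    if missing:
        raise ScvigorError(f"missing window rates: {missing}")
    arrays = {w: np.asarray(rates[w], dtype=float) for w in _REQUIRED}

    samples = [arrays[w] for w in _REQUIRED]
    if np.ptp(np.concatenate(samples)) == 0:
        omnibus_p = 1.0
    else:
        omnibus_p = float(stats.kruskal(*samples).pvalue)

    p = {
        "omnibus": omnibus_p,
        "phasic1_gt_base": _rank_p(arrays["phasic1"], arrays["baseline"], "greater"),
        "phasic2_gt_base": _rank_p(arrays["phasic2"], arrays["baseline"], "greater"),
        "phasic1_lt_base": _rank_p(arrays["phasic1"], arrays["baseline"], "less"),
        "phasic2_lt_base": _rank_p(arrays["phasic2"], arrays["baseline"], "less"),
        "pre_vs_peri": _rank_p(arrays["presacc"], arrays["perisacc"], "two-sided"),
        "phasic1_lt_phasic2": _rank_p(arrays["phasic1"], arrays["phasic2"], "less"),
    }

    if omnibus_p >= alpha:
        return ClassLabel(unit_id, "unclassified", "no_task_response", p)
    if p["phasic1_gt_base"] < alpha and p["phasic2_gt_base"] < alpha:
        if p["pre_vs_peri"] < alpha:
            return ClassLabel(unit_id, "visuomotor", "none", p)
        return ClassLabel(unit_id, "visual", "none", p)
    if p["pre_vs_peri"] < alpha and p["phasic1_lt_phasic2"] < alpha:
        return ClassLabel(unit_id, "motor", "none", p)
    if p["phasic1_lt_base"] < alpha or p["phasic2_lt_base"] < alpha:
        return ClassLabel(unit_id, "tonic", "none", p)
    return ClassLabel(unit_id, "unclassified", "criteria_not_met", p)


def classify_session(
    unit_rates: dict[str, dict[str, np.ndarray] | None],
    alpha: float = ALPHA,
) -> pd.DataFrame:
    """Classify every unit of a session and account for every exclusion.

    ``unit_rates`` maps unit_id to its five window-rate arrays, or to
    ``None`` for units that failed the inclusion filter.  Every unit
    appears exactly once in the returned table; subtype counts plus
    exclusion counts sum to the total.
    """
    rows = []
    for unit_id, rates in unit_rates.items():
        if rates is None:
            rows.append({"unit_id": unit_id, "subtype": "unclassified",
                         "exclusion_reason": "too_few_trials_or_spikes"})
            continue
        label = classify_unit(rates, alpha=alpha, unit_id=unit_id)
        row = {"unit_id": unit_id, "subtype": label.subtype,
               "exclusion_reason": label.exclusion_reason}
        row.update({f"p_{k}": v for k, v in label.pvalues.items()})
        rows.append(row)
    cols = ["unit_id", "subtype", "exclusion_reason"]
    return pd.DataFrame(rows, columns=cols + sorted(
        {c for r in rows for c in r} - set(cols)))
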