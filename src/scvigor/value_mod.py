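"""Per-unit reward (value) modulation statistics.

Good-object versus bad-object firing is quantified three ways:

* a paired Wilcoxon signed-rank comparison of per-trial rates in the
  80-240 ms post-target window (sign of the modulation);
* the value index — mean good minus mean bad rate in 80-160 ms;
* the AUROC of good versus bad rates in 80-160 ms, a threshold-free
  discriminability measure on a 0-1 scale, with a label-permutation
  test for significance.

Internally AUROC treats good as the positive class (values above 0.5 =
positive modulation).  The published convention is the mirror image
(values below 0.5 denote positively modulated cells); reporting layers
can emit ``1 - auroc`` under that convention.

The modulation-onset latency is the first time the good-minus-bad SDF
difference exceeds a baseline-derived threshold (baseline mean + 3 SD)
continuously for 20 ms.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import ScvigorError

BASELINE_WINDOW = (-300.0, 0.0)  # ms, for the onset threshold
ONSET_SEARCH = (80.0, 250.0)     # ms, where a modulation onset may be declared
PERSISTENCE_MS = 20
VALUE_WINDOW = (80.0, 240.0)     # ms, signed-rank comparison
INDEX_WINDOW = (80.0, 160.0)     # ms, value index and AUROC


@dataclass
class ModulationResult:
    unit_id: str
    value_index: float      # spikes/s, mean good - mean bad (80-160 ms)
    auroc: float            # internal convention: >0.5 = good > bad
    auroc_p: float
    signed_rank_p: float
    sign: str               # positive | negative | none
    onset_ms: float | None


def _pair(good: np.ndarray, bad: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Trial-level pairing: evenly subsample the longer condition."""
    n = min(good.size, bad.size)
    if good.size > n:
        good = good[np.round(np.linspace(0, good.size - 1, n)).astype(int)]
    if bad.size > n:
        bad = bad[np.round(np.linspace(0, bad.size - 1, n)).astype(int)]
    return good, bad


def value_comparison(
    good_rates: np.ndarray,
    bad_rates: np.ndarray,
    good_index_rates: np.ndarray | None = None,
    bad_index_rates: np.ndarray | None = None,
    alpha: float = 0.05,
) -> tuple[float, str, float]:
    """Signed-rank comparison of good vs. bad rates; returns (p, sign, index).

    The comparison is paired at the trial level: the longer condition is
    deterministically subsampled (evenly spaced in trial order) to match
    the shorter one, then a Wilcoxon signed-rank test is applied to the
    pairwise differences.  The value index is the difference of means of
    the ``*_index_rates`` arrays (80-160 ms rates) when given, otherwise
    of the comparison arrays themselves.
    """
    good = np.asarray(good_rates, dtype=float)
    bad = np.asarray(bad_rates, dtype=float)
    if good.size < 5 or bad.size < 5:
        raise ScvigorError("need at least 5 trials per condition")
    gi = good if good_index_rates is None else np.asarray(good_index_rates, float)
    bi = bad if bad_index_rates is None else np.asarray(bad_index_rates, float)
    index = float(gi.mean() - bi.mean())

    g, b = _pair(good, bad)
    diffs = g - b
    if np.all(diffs == 0):
        return 1.0, "none", index
    p = float(stats.wilcoxon(g, b).pvalue)
    if p < alpha:
        sign = "positive" if np.median(diffs) > 0 or (np.median(diffs) == 0 and index > 0) else "negative"
    else:
        sign = "none"
    return p, sign, index


def auroc(good_rates: np.ndarray, bad_rates: np.ndarray) -> float:
    """P(random good rate > random bad rate), ties counted half.

    Equals the rank-sum statistic U divided by n_good * n_bad, i.e. the
    area under the ROC curve with good as the positive class.
    """
    good = np.asarray(good_rates, dtype=float)
    bad = np.asarray(bad_rates, dtype=float)
    if good.size == 0 or bad.size == 0:
        raise ScvigorError("auroc needs non-empty samples")
    ranks = stats.rankdata(np.concatenate([good, bad]))
    u = ranks[:good.size].sum() - good.size * (good.size + 1) / 2.0
    return float(u / (good.size * bad.size))


def auroc_significance(
    good_rates: np.ndarray,
    bad_rates: np.ndarray,
    n_perm: int = 1000,
    rng: np.random.Generator | None = None,
) -> float:
    """Two-sided permutation p for |AUROC - 0.5| under label shuffling."""
    good = np.asarray(good_rates, dtype=float)
    bad = np.asarray(bad_rates, dtype=float)
    if good.size + bad.size < 8:
        raise ScvigorError("need a combined n of at least 8")
    if rng is None:
        rng = np.random.default_rng(0)
    observed = abs(auroc(good, bad) - 0.5)
    pooled = np.concatenate([good, bad])
    n_g, n_b = good.size, bad.size
    # all permutations at once: random keys -> argsort = uniform shuffles
    idx = np.argsort(rng.random((n_perm, pooled.size)), axis=1)
    ranks = stats.rankdata(pooled[idx], axis=1)
    u = ranks[:, :n_g].sum(axis=1) - n_g * (n_g + 1) / 2.0
    stat = np.abs(u / (n_g * n_b) - 0.5)
    count = int(np.count_nonzero(stat >= observed - 1e-12))
    return (count + 1) / (n_perm + 1)


def modulation_onset(
    t: np.ndarray,
    sdf_good: np.ndarray,
    sdf_bad: np.ndarray,
    baseline_window: tuple[float, float] = BASELINE_WINDOW,
    persistence_ms: int = PERSISTENCE_MS,
    sign: str = "positive",
    search_window: tuple[float, float] = ONSET_SEARCH,
) -> float | None:
    """Latency at which the good-bad SDF difference becomes significant.

    The difference d(t) = SDF_good - SDF_bad (or its negative for
    ``sign='negative'``) is compared against a threshold equal to its
    baseline-period mean plus three baseline SDs; the onset is the first
    time inside ``search_window`` where d stays at or above the
    threshold for ``persistence_ms`` consecutive milliseconds.  Returns
    ``None`` when the criterion is never met (including the degenerate
    zero-variance, zero-difference case).

    The default search window is 80-250 ms post-target.  Reward
    information reaches the colliculus through value pathways no earlier
    than ~80 ms — the early visual transient is value-agnostic — and
    that transient is also the highest-rate epoch, where a baseline-
    derived threshold under-covers the rate-scaled sampling noise of the
    difference trace.  Beyond ~250 ms the difference picks up
    movement-locked lobes (the two conditions have different
    reaction-time distributions), which are saccade-timing effects
    rather than value signals.
    """
    t = np.asarray(t, dtype=float)
    d = np.asarray(sdf_good, dtype=float) - np.asarray(sdf_bad, dtype=float)
    if sign == "negative":
        d = -d
    base = (t >= baseline_window[0]) & (t < baseline_window[1])
    if not base.any():
        raise ScvigorError("baseline window outside the SDF span")
    mu = d[base].mean()
    sd = d[base].std(ddof=1) if np.count_nonzero(base) > 1 else 0.0
    search = (t >= search_window[0]) & (t <= search_window[1])
    if sd == 0.0 and np.all(d[search] <= mu):
        return None
    threshold = mu + 3.0 * sd
    # with a degenerate (zero-variance) baseline only a strict exceedance counts
    above = ((d >= threshold) if sd > 0 else (d > threshold)) & search
    run = 0
    for i in range(above.size):
        run = run + 1 if above[i] else 0
        if run >= persistence_ms:
            return float(t[i - persistence_ms + 1])
    return None
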