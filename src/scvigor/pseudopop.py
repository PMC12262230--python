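"""Pseudo-population bootstrap of event-aligned spike-density functions.

The population response on a hypothetical trial of a given reaction-time
(RT) tertile is simulated by pooling one single-trial SDF of that
tertile from each of ``n_pool`` randomly chosen units (with
replacement).  ``n_pseudo_trials`` such pseudo-trials are averaged; the
peak (or, for tonic units, trough) time and rate of the average trace
are extracted in each response epoch.  Repeating the whole procedure
``n_repeats`` times yields bootstrap distributions whose means and
2.5/97.5 percentiles summarize the population timing:

* early visual epoch (E_VIS, 30-80 ms post-target),
* late visual epoch (L_VIS, 80-130 ms post-target),
* pre-saccadic epoch (PRE_SAC, beyond 130 ms target-aligned, and
  -40 to 0 ms saccade-aligned).

Target-locked components produce tertile-invariant peak times when
aligned on target onset; saccade-locked components produce
tertile-invariant peaks only when aligned on saccade onset — the logic
that dissociates visual from motor processing stages.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ScvigorError, TooFewTrialsError

QUANTILE_LABELS = ("short", "medium", "long")

TARGET_SPAN = (-300.0, 400.0)
SACCADE_SPAN = (-300.0, 200.0)

E_VIS = (30.0, 80.0)
L_VIS = (80.0, 130.0)
PRE_SAC_START = 130.0
PRE_SAC_SACC = (-40.0, 0.0)


@dataclass(frozen=True)
class QuantileSplit:
    """RT-tertile labels per trial plus the boundary RTs."""

    labels: np.ndarray        # str per trial: short|medium|long
    boundaries: tuple[float, float]

    def mask(self, label: str) -> np.ndarray:
        return self.labels == label


@dataclass(frozen=True)
class BootstrapConfig:
    n_pool: int = 25            # units pooled per pseudo-trial
    n_pseudo_trials: int = 25   # pseudo-trials per tertile (10-35 admissible)
    n_repeats: int = 10000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pool < 1 or self.n_repeats < 1 or self.n_pseudo_trials < 1:
            raise ConfigurationError("bootstrap sizes must be at least 1")


@dataclass
class UnitTraces:
    """Per-unit single-trial SDFs for both alignments, with behavior."""

    unit_id: str
    subtype: str
    t_target: np.ndarray
    sdf_target: np.ndarray    # (n_trials, n_time)
    t_saccade: np.ndarray
    sdf_saccade: np.ndarray
    rt_ms: np.ndarray
    conditions: np.ndarray


def split_quantiles(rts: np.ndarray) -> QuantileSplit:
    """Partition trials into RT tertiles (short / medium / long).

    Trials are sorted by RT with stable tie-breaking in original order;
    group sizes differ by at most one, with earlier tertiles taking the
    remainder.
    """
    rts = np.asarray(rts, dtype=float)
    n = rts.size
    if n < 3:
        raise TooFewTrialsError("need at least 3 trials to form tertiles")
    order = np.argsort(rts, kind="stable")
    base, rem = divmod(n, 3)
    sizes = [base + (1 if i < rem else 0) for i in range(3)]
    labels = np.empty(n, dtype=object)
    start = 0
    cut = []
    for label, size in zip(QUANTILE_LABELS, sizes):
        idx = order[start:start + size]
        labels[idx] = label
        cut.append(start + size)
        start += size
    b1 = float(rts[order[cut[0] - 1]])
    b2 = float(rts[order[cut[1] - 1]])
    return QuantileSplit(labels=labels.astype(str), boundaries=(b1, b2))


def simulate_pseudo_trial(
    units: list[UnitTraces],
    quantile: str,
    splits: list[QuantileSplit],
    n_pool: int,
    rng: np.random.Generator,
    alignment: str = "target",
) -> np.ndarray:
    """One pooled pseudo-trial trace: mean of ``n_pool`` single-trial SDFs.

    ``n_pool`` units are chosen uniformly with replacement; from each, a
    single trial of the requested RT tertile is chosen uniformly.
    """
    mats = [u.sdf_target if alignment == "target" else u.sdf_saccade for u in units]
    pools = [np.nonzero(s.mask(quantile))[0] for s in splits]
    if all(p.size == 0 for p in pools):
        raise ScvigorError(f"no unit has trials in tertile {quantile!r}")
    picks = rng.integers(0, len(units), size=n_pool)
    rows = np.empty((n_pool, mats[0].shape[1]))
    for j, u in enumerate(picks):
        pool = pools[u]
        if pool.size == 0:  # resample a unit that covers this tertile
            u = int(rng.choice([k for k in range(len(units)) if pools[k].size]))
            pool = pools[u]
        rows[j] = mats[u][rng.choice(pool)]
    return rows.mean(axis=0)


def epoch_extremum(
    t: np.ndarray,
    trace: np.ndarray,
    window: tuple[float, float],
    kind: str = "peak",
) -> tuple[float, float]:
    """Time and rate of the extremum of ``trace`` within ``window``.

    ``kind`` is ``'peak'`` (argmax) or ``'trough'`` (argmin); the first
    occurrence wins on exact ties.
    """
    mask = (t >= window[0]) & (t <= window[1])
    if not mask.any():
        raise ConfigurationError("epoch lies outside the trace span")
    seg = trace[mask]
    i = int(np.argmax(seg)) if kind == "peak" else int(np.argmin(seg))
    return float(t[mask][i]), float(seg[i])


def bootstrap_population(
    units: list[UnitTraces],
    config: BootstrapConfig,
    conditions: tuple[str, ...] | None = None,
    extremum_kind: str | None = None,
) -> pd.DataFrame:
    """Full bootstrap for one subtype population.

    Per repeat and RT tertile, ``n_pseudo_trials`` pooled traces are
    averaged and the per-epoch extremum (peak, or trough for tonic
    populations) is extracted from the average, for both target and
    saccade alignments.  The summary reports the mean and the 2.5/97.5
    percentile interval of the extremum time and rate over repeats.

    ``conditions`` restricts pooling to trials of the given condition(s)
    and produces one summary block per condition (value-conditioned
    bootstrap); by default all trials are pooled.
    """
    if not units:
        raise ScvigorError("bootstrap needs at least one unit")
    subtypes = {u.subtype for u in units}
    if extremum_kind is None:
        extremum_kind = "trough" if subtypes == {"tonic"} else "peak"

    rng = np.random.default_rng(config.seed)
    splits = [split_quantiles(u.rt_ms) for u in units]
    rows = []
    cond_list: list[str | None] = list(conditions) if conditions else [None]
    for cond in cond_list:
        rows.extend(_bootstrap_one(units, splits, config, rng, cond, extremum_kind))
    return pd.DataFrame(rows)


def _bootstrap_one(units, splits, config, rng, cond, extremum_kind):
    t_t = units[0].t_target
    t_s = units[0].t_saccade
    all_rts = np.concatenate([u.rt_ms for u in units])
    all_labels = np.concatenate([s.labels for s in splits])

    # per (unit, tertile) trial index pools, restricted to the condition
    pools_t: dict[str, list[np.ndarray]] = {}
    for q in QUANTILE_LABELS:
        per_unit = []
        for u, s in zip(units, splits):
            mask = s.mask(q)
            if cond is not None:
                mask = mask & (u.conditions == cond)
            per_unit.append(np.nonzero(mask)[0])
        if all(p.size == 0 for p in per_unit):
            raise ScvigorError(f"tertile {q!r} empty for condition {cond!r}")
        pools_t[q] = per_unit

    n_draw = config.n_pool * config.n_pseudo_trials
    covered = {q: np.array([k for k, p in enumerate(pools_t[q]) if p.size])
               for q in QUANTILE_LABELS}

    long_med = float(np.median(all_rts[all_labels == "long"]))
    epochs_target = {"E_VIS": E_VIS, "L_VIS": L_VIS,
                     "PRE_SAC": (PRE_SAC_START, PRE_SAC_START + long_med)}

    results: dict[tuple, list] = {}
    for rep in range(config.n_repeats):
        for q in QUANTILE_LABELS:
            ok_units = covered[q]
            picks = ok_units[rng.integers(0, ok_units.size, size=n_draw)]
            rnd = rng.random(n_draw)
            for alignment, mats, t_grid in (
                ("target", [u.sdf_target for u in units], t_t),
                ("saccade", [u.sdf_saccade for u in units], t_s),
            ):
                trace = np.zeros(t_grid.size)
                for u_idx in np.unique(picks):
                    sel = picks == u_idx
                    pool = pools_t[q][u_idx]
                    tr_idx = pool[(rnd[sel] * pool.size).astype(int)]
                    trace += mats[u_idx][tr_idx].sum(axis=0)
                trace /= n_draw
                eps = (epochs_target if alignment == "target"
                       else {"PRE_SAC": PRE_SAC_SACC})
                for name, win in eps.items():
                    tm, rate = epoch_extremum(t_grid, trace, win, extremum_kind)
                    results.setdefault((q, name, alignment), []).append((tm, rate))

    rows = []
    for (q, name, alignment), vals in results.items():
        arr = np.asarray(vals)
        tm, rate = arr[:, 0], arr[:, 1]
        rows.append({
            "condition": cond if cond is not None else "all",
            "quantile": q, "epoch": name, "alignment": alignment,
            "extremum": extremum_kind,
            "time_mean": float(tm.mean()),
            "time_lo": float(np.percentile(tm, 2.5)),
            "time_hi": float(np.percentile(tm, 97.5)),
            "rate_mean": float(rate.mean()),
            "rate_lo": float(np.percentile(rate, 2.5)),
            "rate_hi": float(np.percentile(rate, 97.5)),
            "n_repeats": config.n_repeats,
        })
    return rows
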