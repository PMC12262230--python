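"""Session-level orchestration: from raw bundles to per-stage tables.

These helpers wire the low-level operations together for one or more
sessions: saccade detection per trial, unit inclusion and window rates,
classification input assembly, per-unit modulation statistics, the
pseudo-population trace containers, and the behavior-link index rows.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from . import behavior_link, classification, kinematics, spike_tools, value_mod
from .errors import TooFewTrialsError, UndefinedCorrelationError
from .pseudopop import SACCADE_SPAN, TARGET_SPAN, UnitTraces
from .spike_tools import WindowSpec
from .synth import SessionBundle


def analyze_saccades(bundle: SessionBundle) -> pd.DataFrame:
    """Detect and score the trial saccade of every trial.

    Returns one row per trial with RT, peak velocity, amplitude,
    saccade onset on the session clock, and validity flags; trials with
    no admissible saccade are marked invalid with reason
    ``no_response``.
    """
    trace = kinematics.EyeTrace(bundle.eye_t, bundle.eye_x, bundle.eye_y)
    events = kinematics.detect_saccades(trace)
    rows = []
    for tr in bundle.trials:
        ev = kinematics.trial_saccade(events, tr.target_on_ms)
        if ev is None:
            rows.append({"trial_id": tr.trial_id, "condition": tr.condition,
                         "object_id": tr.object_id, "valid": False,
                         "reject_reason": "no_response",
                         "rt_ms": np.nan, "pv_deg_s": np.nan,
                         "amplitude_deg": np.nan, "saccade_on_ms": np.nan,
                         "target_on_ms": tr.target_on_ms})
            continue
        ev = kinematics.saccade_metrics(ev, trace, tr.target_on_ms,
                                        (tr.target_x_deg, tr.target_y_deg))
        rows.append({"trial_id": tr.trial_id, "condition": tr.condition,
                     "object_id": tr.object_id, "valid": bool(ev.valid),
                     "reject_reason": ev.reject_reason,
                     "rt_ms": ev.rt_ms, "pv_deg_s": ev.pv_deg_s,
                     "amplitude_deg": ev.amplitude_deg,
                     "saccade_on_ms": ev.onset_ms,
                     "target_on_ms": tr.target_on_ms})
    return pd.DataFrame(rows)


def _valid(saccades: pd.DataFrame) -> pd.DataFrame:
    return saccades[saccades["valid"]].reset_index(drop=True)


def unit_rasters(
    bundle: SessionBundle,
    saccades: pd.DataFrame,
) -> dict[str, dict[str, spike_tools.AlignedRaster]]:
    """Target- and saccade-aligned rasters per unit, valid trials only."""
    val = _valid(saccades)
    target_ms = val["target_on_ms"].to_numpy()
    sacc_ms = val["saccade_on_ms"].to_numpy()
    conds = val["condition"].to_numpy()
    ids = val["trial_id"].to_numpy()
    out = {}
    for unit in bundle.units:
        out[unit.unit_id] = {
            "target_on": spike_tools.align_spikes(
                unit.spike_ms, target_ms, conds, ids, unit.unit_id, "target_on"),
            "saccade_on": spike_tools.align_spikes(
                unit.spike_ms, sacc_ms, conds, ids, unit.unit_id, "saccade_on"),
        }
    return out


def classification_inputs(
    rasters: dict[str, dict[str, spike_tools.AlignedRaster]],
) -> dict[str, dict[str, np.ndarray] | None]:
    """Window rates for classification; None for units failing inclusion."""
    out: dict[str, dict[str, np.ndarray] | None] = {}
    for unit_id, pair in rasters.items():
        passed, _reason = spike_tools.inclusion_filter(pair["target_on"])
        if not passed:
            out[unit_id] = None
            continue
        rates = {}
        for name, win in classification.CLASS_WINDOWS.items():
            raster = pair[win.event]
            rates[name] = spike_tools.window_rate(raster, win)
        out[unit_id] = rates
    return out


def classify(bundle: SessionBundle, saccades: pd.DataFrame,
             alpha: float = classification.ALPHA) -> pd.DataFrame:
    rasters = unit_rasters(bundle, saccades)
    return classification.classify_session(classification_inputs(rasters),
                                           alpha=alpha)


def modulation_table(
    bundle: SessionBundle,
    saccades: pd.DataFrame,
    classes: pd.DataFrame,
    n_perm: int = 1000,
    seed: int = 0,
    figure_convention: bool = False,
) -> pd.DataFrame:
    """Per-unit value-modulation statistics for classified units.

    ``figure_convention=True`` reports ``1 - AUROC`` (the published
    plotting convention, where values below 0.5 denote positive
    modulation); the internal convention has good as the positive class.
    """
    rasters = unit_rasters(bundle, saccades)
    classified = classes[classes["subtype"] != "unclassified"]
    win_cmp = WindowSpec("value_cmp", *value_mod.VALUE_WINDOW, "target_on")
    win_idx = WindowSpec("value_idx", *value_mod.INDEX_WINDOW, "target_on")
    rng = np.random.default_rng(seed)
    rows = []
    for _, crow in classified.iterrows():
        unit_id = crow["unit_id"]
        raster = rasters[unit_id]["target_on"]
        good = raster.conditions == "good"
        r_cmp = spike_tools.window_rate(raster, win_cmp)
        r_idx = spike_tools.window_rate(raster, win_idx)
        p, sign, index = value_mod.value_comparison(
            r_cmp[good], r_cmp[~good], r_idx[good], r_idx[~good])
        a = value_mod.auroc(r_idx[good], r_idx[~good])
        ap = value_mod.auroc_significance(r_idx[good], r_idx[~good],
                                          n_perm=n_perm, rng=rng)
        sdf_pair = spike_tools.sdf(raster, span=TARGET_SPAN)
        onset = value_mod.modulation_onset(
            sdf_pair.t, sdf_pair.mean(good), sdf_pair.mean(~good),
            sign="negative" if sign == "negative" else "positive")
        rows.append({"unit_id": unit_id, "subtype": crow["subtype"],
                     "value_index": index, "signed_rank_p": p, "sign": sign,
                     "auroc": 1.0 - a if figure_convention else a,
                     "auroc_p": ap,
                     "onset_ms": onset if onset is not None else np.nan})
    return pd.DataFrame(rows, columns=["unit_id", "subtype", "value_index",
                                       "signed_rank_p", "sign", "auroc",
                                       "auroc_p", "onset_ms"])


def unit_traces(
    bundle: SessionBundle,
    saccades: pd.DataFrame,
    classes: pd.DataFrame,
    subtype: str,
    rasters: dict | None = None,
) -> list[UnitTraces]:
    """Single-trial SDF containers for the bootstrap, one per unit."""
    if rasters is None:
        rasters = unit_rasters(bundle, saccades)
    val = _valid(saccades)
    rts = val["rt_ms"].to_numpy()
    conds = val["condition"].to_numpy()
    keep = classes[(classes["subtype"] == subtype)]["unit_id"]
    out = []
    for unit_id in keep:
        pair = rasters[unit_id]
        sdf_t = spike_tools.sdf(pair["target_on"], span=TARGET_SPAN)
        sdf_s = spike_tools.sdf(pair["saccade_on"], span=SACCADE_SPAN)
        out.append(UnitTraces(unit_id=unit_id, subtype=subtype,
                              t_target=sdf_t.t, sdf_target=sdf_t.values,
                              t_saccade=sdf_s.t, sdf_saccade=sdf_s.values,
                              rt_ms=rts, conditions=conds))
    return out


def index_rows(
    bundle: SessionBundle,
    saccades: pd.DataFrame,
    classes: pd.DataFrame,
    modulation: pd.DataFrame,
) -> list[dict]:
    """Behavior-link rows (value/RT/PV indices) for one session's units."""
    rasters = unit_rasters(bundle, saccades)
    val = _valid(saccades)
    rt = val["rt_ms"].to_numpy()
    pv = val["pv_deg_s"].to_numpy()
    win_idx = WindowSpec("value_idx", *value_mod.INDEX_WINDOW, "target_on")
    mod = modulation.set_index("unit_id")
    rows = []
    for unit_id in mod.index:
        raster = rasters[unit_id]["target_on"]
        rates = spike_tools.window_rate(raster, win_idx)
        counts = spike_tools.window_counts(raster, win_idx)
        row = {"unit_id": unit_id, "subtype": mod.loc[unit_id, "subtype"],
               "value_index": mod.loc[unit_id, "value_index"],
               "auroc": mod.loc[unit_id, "auroc"],
               "value_p": mod.loc[unit_id, "signed_rank_p"]}
        try:
            r_rt, p_rt, n = behavior_link.rate_behavior_correlation(rates, rt, counts)
            r_pv, p_pv, _ = behavior_link.rate_behavior_correlation(rates, pv, counts)
            row.update({"rt_index": r_rt, "rt_p": p_rt,
                        "pv_index": r_pv, "pv_p": p_pv, "n_valid_trials": n})
        except TooFewTrialsError:
            row["index_missing_reason"] = "too_few_trials"
        except UndefinedCorrelationError:
            row["index_missing_reason"] = "undefined_correlation"
        rows.append(row)
    return rows
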