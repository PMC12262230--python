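"""Event alignment, spike-density estimation and window firing rates.

Spike-density functions (SDFs) use Gaussian kernels with a 10 ms
bandwidth, interpreted as the kernel SD.  Each spike contributes a
unit-mass Gaussian, so the integral of a trial's SDF over the analysis
span equals its interior spike count.  Internally the SDF is computed on
a span padded by six kernel SDs and cropped, so no kernel mass is lost
at the reported boundaries.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ScvigorError, TooFewTrialsError

DEFAULT_BANDWIDTH_MS = 10.0
ANALYSIS_SPAN = (-300.0, 400.0)  # ms around target onset, unit-inclusion window
MIN_TRIALS_PER_CONDITION = 5
MIN_SPIKES = 20  # strictly more than this many spikes required

EVENT_NAMES = ("fixation_on", "target_on", "saccade_on")


@dataclass(frozen=True)
class WindowSpec:
    """A named analysis window relative to an alignment event."""

    name: str
    start: float  # ms
    end: float    # ms
    event: str = "target_on"

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ScvigorError(f"window {self.name}: start must precede end")
        if self.event not in EVENT_NAMES:
            raise ScvigorError(f"window {self.name}: unknown event {self.event!r}")


@dataclass
class AlignedRaster:
    """Per-trial spike times relative to one alignment event.

    ``trials`` holds one array of relative spike times (ms) per retained
    trial, in original trial order; ``conditions`` the matching labels.
    """

    unit_id: str
    event: str
    trials: list[np.ndarray]
    conditions: np.ndarray
    trial_ids: np.ndarray

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def subset(self, mask: np.ndarray) -> "AlignedRaster":
        idx = np.nonzero(mask)[0]
        return AlignedRaster(self.unit_id, self.event,
                             [self.trials[i] for i in idx],
                             self.conditions[idx], self.trial_ids[idx])


@dataclass
class SDFMatrix:
    """Trials x time spike-density estimate on a 1 ms grid (spikes/s)."""

    t: np.ndarray        # ms, relative to the alignment event
    values: np.ndarray   # (n_trials, n_time)
    bandwidth_ms: float

    def trial_integral(self) -> np.ndarray:
        """Integral of each trial's SDF over the span, in spikes."""
        return self.values.sum(axis=1) / 1000.0

    def mean(self, mask: np.ndarray | None = None) -> np.ndarray:
        vals = self.values if mask is None else self.values[mask]
        return vals.mean(axis=0) if len(vals) else np.zeros_like(self.t)


def align_spikes(
    spike_ms: np.ndarray,
    event_ms: np.ndarray,
    conditions: np.ndarray,
    trial_ids: np.ndarray | None = None,
    unit_id: str = "",
    event: str = "target_on",
    window: tuple[float, float] = (-600.0, 800.0),
) -> AlignedRaster:
    """Align a unit's session spike times on one event per trial.

    ``event_ms`` gives the alignment time of each retained trial on the
    session clock; spikes within ``window`` of it become relative times.
    """
    if event not in EVENT_NAMES:
        raise ScvigorError(f"unknown event name {event!r}")
    spike_ms = np.asarray(spike_ms, dtype=float)
    event_ms = np.asarray(event_ms, dtype=float)
    if trial_ids is None:
        trial_ids = np.arange(event_ms.size)
    rows = []
    for ev in event_ms:
        lo = np.searchsorted(spike_ms, ev + window[0])
        hi = np.searchsorted(spike_ms, ev + window[1])
        rows.append(spike_ms[lo:hi] - ev)
    return AlignedRaster(unit_id=unit_id, event=event, trials=rows,
                         conditions=np.asarray(conditions),
                         trial_ids=np.asarray(trial_ids))


def sdf(
    raster: AlignedRaster,
    bandwidth_ms: float = DEFAULT_BANDWIDTH_MS,
    span: tuple[float, float] = ANALYSIS_SPAN,
) -> SDFMatrix:
    """Gaussian-kernel spike-density function per trial, in spikes/s.

    Each spike contributes a Gaussian of SD ``bandwidth_ms`` and unit
    mass; kernels are evaluated out to six SDs on a span padded by the
    same amount, then cropped to ``span``.
    """
    if bandwidth_ms <= 0:
        raise ScvigorError("bandwidth must be positive")
    pad = int(np.ceil(6.0 * bandwidth_ms))
    t0 = span[0] - pad
    grid = np.arange(t0, span[1] + pad + 1.0, 1.0)
    n_t = grid.size
    values = np.zeros((raster.n_trials, n_t))
    taps = np.arange(-pad, pad + 1, dtype=float)
    norm = 1000.0 / (bandwidth_ms * np.sqrt(2.0 * np.pi))
    for i, spikes in enumerate(raster.trials):
        if spikes.size == 0:
            continue
        centers = np.round(spikes).astype(int)
        frac = spikes - centers
        cols = (centers - int(t0))[:, None] + taps[None, :].astype(int)
        kern = norm * np.exp(-0.5 * ((taps[None, :] - frac[:, None]) / bandwidth_ms) ** 2)
        inside = (cols >= 0) & (cols < n_t)
        np.add.at(values[i], cols[inside], kern[inside])
    keep = (grid >= span[0]) & (grid <= span[1])
    return SDFMatrix(t=grid[keep], values=values[:, keep], bandwidth_ms=bandwidth_ms)


def window_rate(raster: AlignedRaster, window: WindowSpec) -> np.ndarray:
    """Per-trial firing rate (spikes/s) as count in [start, end) / duration."""
    if raster.n_trials == 0:
        raise TooFewTrialsError("window_rate on an empty trial set")
    dur_s = (window.end - window.start) / 1000.0
    counts = np.array([np.count_nonzero((tr >= window.start) & (tr < window.end))
                       for tr in raster.trials], dtype=float)
    return counts / dur_s


def window_counts(raster: AlignedRaster, window: WindowSpec) -> np.ndarray:
    """Per-trial spike counts in [start, end)."""
    return np.array([np.count_nonzero((tr >= window.start) & (tr < window.end))
                     for tr in raster.trials], dtype=int)


def inclusion_filter(
    raster: AlignedRaster,
    span: tuple[float, float] = ANALYSIS_SPAN,
    min_trials: int = MIN_TRIALS_PER_CONDITION,
    min_spikes: int = MIN_SPIKES,
) -> tuple[bool, str]:
    """Unit-inclusion rule: enough valid trials and enough spikes.

    A unit passes if it has at least ``min_trials`` valid trials in each
    task condition and fired strictly more than ``min_spikes`` spikes in
    the analysis span across all valid trials.
    """
    conditions = np.asarray(raster.conditions)
    for cond in np.unique(conditions) if conditions.size else []:
        if np.count_nonzero(conditions == cond) < min_trials:
            return False, "too_few_trials"
    if conditions.size == 0 or np.unique(conditions).size < 2:
        return False, "too_few_trials"
    total = sum(int(np.count_nonzero((tr >= span[0]) & (tr < span[1])))
                for tr in raster.trials)
    if total <= min_spikes:
        return False, "too_few_spikes"
    return True, "none"
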