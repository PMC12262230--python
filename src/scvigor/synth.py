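"""Synthetic superior-colliculus recording sessions.

Generates session bundles — trial event tables, per-unit spike trains and
a 1 kHz eye trace — with the statistical structure the downstream
analyses assume: condition-dependent reaction-time distributions, a
saturating main-sequence amplitude/peak-velocity relation, four
functional unit subtypes (visual, visuomotor, motor, tonic) built from
firing-rate templates, a value gain on the late-visual and pre-saccadic
rate components of high-value ("good") trials, and a shared per-trial
latent gain that couples firing rates to reaction time and peak
velocity.  Ground-truth labels and parameters are emitted alongside so
that recovery tests can score every downstream stage.

The template shapes (Gaussian transients, bump-plateau late component,
saccade-locked burst, ramp-and-recover suppression) are modeling choices
of this package, not measurements; the ground truth records them as
such.
"""
from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace

import numpy as np
from scipy.stats import truncnorm

from .errors import ConfigurationError, ScvigorError

SUBTYPES = ("visual", "visuomotor", "motor", "tonic")

#: spikes/s added per deg/s of... (none: module-level constants below are ms)
_LATE_END_LAG = 50.0    # late component holds until saccade onset + this lag
_LATE_DECAY_MS = 60.0   # and then decays with this Gaussian SD
_TONIC_RECOVERY_MS = 25.0


@dataclass(frozen=True)
class RateTemplate:
    """Additive firing-rate components of one unit subtype.

    All times are ms relative to target onset except ``motor_peak_lead``
    and ``tonic_trough_lead`` which are ms *before* saccade onset.  The
    late and motor components (and the tonic suppression) are the
    value-sensitive parts of the response.
    """

    baseline: float = 15.0            # spikes/s
    visual_gain: float = 0.0          # spikes/s, target-locked transient
    visual_peak_latency: float = 42.0  # ms post-target
    visual_width: float = 12.0        # ms (Gaussian SD)
    late_gain: float = 0.0            # spikes/s, late visual component
    late_peak_latency: float = 106.0  # ms post-target
    late_width: float = 18.0          # ms (Gaussian SD of the rising bump)
    late_plateau: float = 0.85        # sustained fraction of the late peak
    motor_gain: float = 0.0           # spikes/s, saccade-locked burst
    motor_peak_lead: float = 11.0     # ms before saccade onset
    motor_width: float = 10.0         # ms (Gaussian SD)
    tonic_suppression: float = 0.0    # spikes/s removed at the trough
    tonic_onset_latency: float = 50.0  # ms post-target, suppression onset
    tonic_trough_lead: float = 33.0   # ms before saccade onset

    def __post_init__(self) -> None:
        if self.baseline < 0:
            raise ConfigurationError("baseline rate must be non-negative")
        for name in ("visual_width", "late_width", "motor_width"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")


def default_templates() -> dict[str, RateTemplate]:
    """Subtype templates with the timing structure of SC responses.

    Component latencies follow the recorded population: visual transient
    peaking 42 ms post-target, late visual component peaking ~106 ms,
    pre-saccadic burst peaking 11 ms before saccade onset, and tonic
    suppression from a 22 spikes/s baseline to ~12 spikes/s troughing
    33 ms before the saccade.
    """
    return {
        "visual": RateTemplate(baseline=17, visual_gain=35, late_gain=10,
                               late_plateau=0.80),
        "visuomotor": RateTemplate(baseline=15, visual_gain=40, late_gain=28,
                                   late_plateau=0.92, motor_gain=50),
        "motor": RateTemplate(baseline=15, visual_gain=0, late_gain=20,
                              late_peak_latency=110, late_width=12,
                              motor_gain=55),
        "tonic": RateTemplate(baseline=22, tonic_suppression=10),
    }


@dataclass(frozen=True)
class GeneratorParams:
    """All knobs of the synthetic-session generator.

    Behavioral defaults mirror the recorded task: good-object reaction
    times 186 +/- 25 ms vs. bad 211 +/- 36 ms, peak velocities near
    740 vs. 700 deg/s, target eccentricities of 4-25 deg, and 56 good /
    43 bad completed trials per session.
    """

    rt_mean_good: float = 186.0
    rt_sd_good: float = 25.0
    rt_mean_bad: float = 211.0
    rt_sd_bad: float = 36.0
    rt_floor: float = 140.0          # ms, truncation of the RT distributions
    amp_range: tuple[float, float] = (4.0, 25.0)   # deg, session eccentricity
    main_seq_vmax: float = 620.0     # deg/s, main-sequence saturation
    main_seq_const: float = 9.0      # deg, main-sequence length constant
    pv_good_bonus: float = 0.05      # fractional PV increase on good trials
    amp_jitter_frac: float = 0.03    # trial-to-trial motor noise on amplitude
    pv_noise_frac: float = 0.03      # multiplicative PV noise
    pv_latent_coupling: float = 0.08  # PV sensitivity to the latent gain
    eye_noise_sd: float = 0.01       # deg, positional tracker noise
    n_units_per_subtype: int = 5
    subtype_templates: dict[str, RateTemplate] = field(default_factory=default_templates)
    value_gain: float = 3.0          # multiplier on late/motor components, good trials
    value_onset: float = 95.0        # ms post-target at which the gain engages
    value_ramp_ms: float = 8.0       # rise time of the value-gain engagement
    trial_gain_cv: float = 0.15      # per-trial whole-unit rate variability (CV)
    latent_sd: float = 0.5           # SD of the shared per-trial gain g ~ N(1, sd)
    rate_rt_coupling: float = 0.8    # RT shift = -coupling * (g-1) * rt_sd
    unit_coupling_range: tuple[float, float] = (0.25, 1.75)  # per-unit susceptibility
    n_trials_good: int = 56
    n_trials_bad: int = 43
    seed: int = 0
    fixation_ms: float = 300.0
    hold_ms: float = 500.0
    iti_ms: float = 400.0

    def __post_init__(self) -> None:
        if self.rt_sd_good <= 0 or self.rt_sd_bad <= 0:
            raise ConfigurationError("RT standard deviations must be positive")
        if self.rt_floor <= 0:
            raise ConfigurationError("rt_floor must be positive")
        if not self.amp_range[0] < self.amp_range[1]:
            raise ConfigurationError("amp_range must satisfy min < max")
        if self.n_trials_good <= 0 or self.n_trials_bad <= 0:
            raise ConfigurationError("trial counts must be positive")
        if self.n_units_per_subtype <= 0:
            raise ConfigurationError("unit counts must be positive")
        if self.value_gain <= 0:
            raise ConfigurationError("value_gain must be positive")
        missing = [s for s in SUBTYPES if s not in self.subtype_templates]
        if missing:
            raise ConfigurationError(f"missing templates for subtypes: {missing}")


@dataclass
class TrialRecord:
    trial_id: int
    condition: str          # good | bad
    object_id: int          # 0..3 good, 4..7 bad
    fix_on_ms: float
    target_on_ms: float
    target_x_deg: float
    target_y_deg: float
    outcome: str = "completed"


@dataclass
class UnitRecord:
    unit_id: str
    channel: int
    spike_ms: np.ndarray


@dataclass
class UnitTruth:
    unit_id: str
    subtype: str
    modulation_sign: int    # +1, -1 (tonic only) or 0
    coupling: float         # per-unit susceptibility c_u
    value_gain_eff: float   # 1 + c_u * (value_gain - 1)


@dataclass
class SessionBundle:
    """One synthetic recording session plus (synthetic-only) ground truth."""

    manifest: dict
    trials: list[TrialRecord]
    units: list[UnitRecord]
    eye_t: np.ndarray
    eye_x: np.ndarray
    eye_y: np.ndarray
    truth: dict | None = None


# ---------------------------------------------------------------------------
# behavior

def main_sequence_pv(amplitude: float | np.ndarray, params: GeneratorParams) -> np.ndarray:
    """Saturating main-sequence peak velocity for a given amplitude."""
    return params.main_seq_vmax * (1.0 - np.exp(-np.asarray(amplitude) / params.main_seq_const))


def _draw_rt(params: GeneratorParams, condition: str, rng: np.random.Generator,
             size: int) -> np.ndarray:
    mean = params.rt_mean_good if condition == "good" else params.rt_mean_bad
    sd = params.rt_sd_good if condition == "good" else params.rt_sd_bad
    a = (params.rt_floor - mean) / sd
    return truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=size, random_state=rng)


def minimum_jerk(amplitude: float, duration_ms: float, t_ms: np.ndarray) -> np.ndarray:
    """Minimum-jerk displacement profile (deg) at times ``t_ms`` from onset."""
    tau = np.clip(t_ms / duration_ms, 0.0, 1.0)
    return amplitude * (10 * tau**3 - 15 * tau**4 + 6 * tau**5)


def threshold_crossing_lag(pv: float, duration_ms: float,
                           threshold: float = 30.0) -> float:
    """Time from minimum-jerk movement start to the speed-threshold crossing.

    Saccade onset is operationally defined as the 30 deg/s crossing, so
    the generator places movements such that this crossing — not the
    start of the (asymptotically slow) minimum-jerk ramp — occurs at the
    nominal reaction time.  For minimum jerk, v(tau) = PV * 16 tau^2
    (1-tau)^2, giving tau0 = (1 - sqrt(1 - sqrt(thr/PV))) / 2.
    """
    ratio = min(threshold / pv, 1.0)
    tau0 = 0.5 * (1.0 - np.sqrt(max(1.0 - np.sqrt(ratio), 0.0)))
    return float(tau0 * duration_ms)


def sample_behavior(
    params: GeneratorParams,
    condition: str,
    rng: np.random.Generator,
    target_amp: float | None = None,
    latent: float = 1.0,
) -> tuple[float, float, float, np.ndarray]:
    """Draw one trial's kinematics and a noise-free eye-displacement segment.

    Returns ``(rt_ms, amplitude_deg, pv_deg_s, segment)`` where
    ``segment`` is the displacement from fixation sampled at 1 kHz over
    ``fixation + rt + saccade + hold``.  The peak velocity follows the
    main sequence, gains a small bonus on good trials, and co-fluctuates
    with the shared latent gain; the minimum-jerk duration is set so that
    the segment's analytic peak velocity equals the drawn PV.
    """
    if condition not in ("good", "bad"):
        raise ConfigurationError(f"unknown condition {condition!r}")
    rt = float(_draw_rt(params, condition, rng, 1)[0])
    if target_amp is None:
        target_amp = float(rng.uniform(*params.amp_range))
    amplitude = float(target_amp * (1.0 + params.amp_jitter_frac * rng.standard_normal()))
    amplitude = max(amplitude, 0.5)
    pv = float(main_sequence_pv(amplitude, params))
    if condition == "good":
        pv *= 1.0 + params.pv_good_bonus
    pv *= 1.0 + params.pv_latent_coupling * (latent - 1.0)
    pv *= 1.0 + params.pv_noise_frac * rng.standard_normal()
    pv = max(pv, 50.0)
    duration = 1.875 * amplitude / pv * 1000.0  # peak of min-jerk = 1.875 A / D
    n = int(np.ceil(params.fixation_ms + rt + duration + params.hold_ms))
    t = np.arange(n, dtype=float)
    onset = params.fixation_ms + rt - threshold_crossing_lag(pv, duration)
    segment = minimum_jerk(amplitude, duration, t - onset)
    return rt, amplitude, pv, segment


# ---------------------------------------------------------------------------
# firing rates

def _smoothstep(x: np.ndarray) -> np.ndarray:
    """C1 ramp from 0 to 1 on x in [0, 1]."""
    x = np.clip(x, 0.0, 1.0)
    return x * x * (3.0 - 2.0 * x)


def rate_function(
    template: RateTemplate,
    condition: str,
    rt: float,
    params: GeneratorParams,
    *,
    value_gain: float | None = None,
    latent: float = 1.0,
    modulation_sign: int = 1,
    span: tuple[float, float] = (-500.0, 500.0),
) -> tuple[np.ndarray, np.ndarray]:
    """Trial firing-rate profile lambda(t) on a 1 ms grid.

    ``span`` is relative to target onset, with the upper bound taken
    relative to saccade onset (i.e. the grid runs from ``span[0]`` to
    ``rt + span[1]``).  Returns ``(t_ms, rate)`` with rate in spikes/s,
    clipped at zero.  On good trials the late and motor components (or
    the tonic suppression) are scaled by the value gain after it engages
    at ``params.value_onset``; the same components are multiplied by the
    shared latent gain.
    """
    if rt <= 0:
        raise ConfigurationError("rt must be positive")
    if condition not in ("good", "bad"):
        raise ConfigurationError(f"unknown condition {condition!r}")
    vg = params.value_gain if value_gain is None else value_gain
    t = np.arange(span[0], rt + span[1], 1.0)
    lam = np.full(t.shape, float(template.baseline))

    # value engagement: smooth step at value_onset, good trials only
    if condition == "good" and vg != 1.0:
        vfac = 1.0 + (vg - 1.0) * _smoothstep((t - params.value_onset) / params.value_ramp_ms + 0.5)
    else:
        vfac = np.ones_like(t)

    if template.visual_gain:
        lam += template.visual_gain * np.exp(
            -0.5 * ((t - template.visual_peak_latency) / template.visual_width) ** 2)

    if template.late_gain:
        tp = template.late_peak_latency
        bump = np.exp(-0.5 * ((t - tp) / template.late_width) ** 2)
        shape = np.where(t < tp, bump,
                         template.late_plateau + (1 - template.late_plateau) * bump)
        # hold until shortly after the saccade, then decay
        t_end = rt + _LATE_END_LAG
        shape = shape * np.where(t < t_end, 1.0,
                                 np.exp(-0.5 * ((t - t_end) / _LATE_DECAY_MS) ** 2))
        lam += template.late_gain * shape * vfac

    if template.motor_gain:
        center = rt - template.motor_peak_lead
        lam += (template.motor_gain * latent
                * np.exp(-0.5 * ((t - center) / template.motor_width) ** 2)
                * (1.0 + (vg - 1.0) * (condition == "good")))

    if template.tonic_suppression:
        trough = rt - template.tonic_trough_lead
        rise = _smoothstep((t - template.tonic_onset_latency)
                           / max(trough - template.tonic_onset_latency, 1.0))
        shape = np.where(t < trough, rise,
                         np.exp(-0.5 * ((t - trough) / _TONIC_RECOVERY_MS) ** 2))
        depth = template.tonic_suppression
        if condition == "good" and vg != 1.0:
            # sign +1: less suppression for good (positive value modulation)
            step = 1.0 + (vg - 1.0) * _smoothstep((t - params.value_onset) / params.value_ramp_ms + 0.5)
            depth = depth * np.where(modulation_sign > 0, 1.0 / step, step)
        lam -= depth * shape

    return t, np.clip(lam, 0.0, None)


def sample_spike_train(
    t_ms: np.ndarray,
    rate: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Inhomogeneous-Poisson spike times by thinning against the rate envelope.

    ``rate`` (spikes/s) is interpreted as piecewise-constant on the 1 ms
    grid ``t_ms``.  Candidate events are drawn homogeneously at the
    envelope rate and accepted with probability lambda(t)/lambda_max,
    which is exact for bounded rates.  Returns strictly increasing times.
    """
    rate = np.asarray(rate, dtype=float)
    if rate.size != t_ms.size:
        raise ScvigorError("rate and time grid must have equal length")
    if not np.all(np.isfinite(rate)) or rate.min() < 0:
        raise ScvigorError("rate must be finite and non-negative")
    lam_max = float(rate.max())
    if lam_max == 0.0:
        return np.empty(0)
    t0, t1 = float(t_ms[0]), float(t_ms[-1]) + 1.0
    n = rng.poisson(lam_max * (t1 - t0) / 1000.0)
    if n == 0:
        return np.empty(0)
    cand = np.sort(rng.uniform(t0, t1, size=n))
    idx = np.minimum(((cand - t0)).astype(int), rate.size - 1)
    keep = rng.uniform(0.0, lam_max, size=n) < rate[idx]
    return np.unique(cand[keep])


# ---------------------------------------------------------------------------
# session assembly

def generate_session(params: GeneratorParams) -> SessionBundle:
    """Generate one complete synthetic session, deterministically from the seed."""
    rng = np.random.default_rng(params.seed)
    n_good, n_bad = params.n_trials_good, params.n_trials_bad
    n_trials = n_good + n_bad

    conditions = np.array(["good"] * n_good + ["bad"] * n_bad)
    rng.shuffle(conditions)
    object_ids = np.where(conditions == "good",
                          rng.integers(0, 4, n_trials),
                          rng.integers(4, 8, n_trials))

    # session geometry: one target eccentricity (the units' shared RF)
    ecc = float(rng.uniform(*params.amp_range))
    angle = float(rng.uniform(0.0, 2.0 * np.pi))
    direction = np.array([np.cos(angle), np.sin(angle)])
    target_pos = ecc * direction

    latents = 1.0 + params.latent_sd * rng.standard_normal(n_trials)

    # per-trial behavior
    trials: list[TrialRecord] = []
    rts = np.empty(n_trials)
    pvs = np.empty(n_trials)
    amps = np.empty(n_trials)
    durs = np.empty(n_trials)
    for i in range(n_trials):
        rt, amp, pv, _ = sample_behavior(params, conditions[i], rng,
                                         target_amp=ecc, latent=latents[i])
        rt_sd = params.rt_sd_good if conditions[i] == "good" else params.rt_sd_bad
        rt = max(rt - params.rate_rt_coupling * (latents[i] - 1.0) * rt_sd,
                 params.rt_floor)
        rts[i], amps[i], pvs[i] = rt, amp, pv
        durs[i] = 1.875 * amp / pv * 1000.0

    # session timeline
    fix_on = np.empty(n_trials)
    target_on = np.empty(n_trials)
    clock = 500.0
    for i in range(n_trials):
        fix_on[i] = clock
        target_on[i] = clock + params.fixation_ms
        ret_dur = 1.875 * amps[i] / float(main_sequence_pv(amps[i], params)) * 1000.0
        clock = (target_on[i] + rts[i] + durs[i] + params.hold_ms
                 + 100.0 + ret_dur + params.iti_ms)

    session_len = int(np.ceil(clock + 500.0))
    eye_t = np.arange(session_len, dtype=float)
    eye_x = np.zeros(session_len)
    eye_y = np.zeros(session_len)
    for i in range(n_trials):
        # the drawn RT is the 30 deg/s crossing; movement starts slightly earlier
        onset = target_on[i] + rts[i] - threshold_crossing_lag(pvs[i], durs[i])
        i0 = int(np.floor(onset))
        i1 = int(np.ceil(onset + durs[i] + params.hold_ms + 100.0))
        seg_t = eye_t[i0:i1] - onset
        disp = minimum_jerk(amps[i], durs[i], seg_t)
        frac = disp / amps[i]
        eye_x[i0:i1] = frac * amps[i] * direction[0]
        eye_y[i0:i1] = frac * amps[i] * direction[1]
        # hold at landing until the return movement
        land_x = amps[i] * direction[0]
        land_y = amps[i] * direction[1]
        r0 = i1
        ret_pv = float(main_sequence_pv(amps[i], params))
        ret_dur = 1.875 * amps[i] / ret_pv * 1000.0
        r1 = min(int(np.ceil(r0 + ret_dur)), session_len)
        ret_t = eye_t[r0:r1] - eye_t[r0]
        back = 1.0 - minimum_jerk(1.0, ret_dur, ret_t)
        eye_x[r0:r1] = back * land_x
        eye_y[r0:r1] = back * land_y
        trials.append(TrialRecord(
            trial_id=i, condition=str(conditions[i]), object_id=int(object_ids[i]),
            fix_on_ms=fix_on[i], target_on_ms=target_on[i],
            target_x_deg=float(target_pos[0]), target_y_deg=float(target_pos[1]),
        ))
    if params.eye_noise_sd > 0:
        eye_x += rng.normal(0.0, params.eye_noise_sd, session_len)
        eye_y += rng.normal(0.0, params.eye_noise_sd, session_len)

    # units
    units: list[UnitRecord] = []
    truths: list[UnitTruth] = []
    c_lo, c_hi = params.unit_coupling_range
    channel = 0
    for subtype in SUBTYPES:
        template = params.subtype_templates[subtype]
        for k in range(params.n_units_per_subtype):
            unit_id = f"{subtype}_{k:02d}"
            coupling = float(rng.uniform(c_lo, c_hi))
            vg_eff = 1.0 + coupling * (params.value_gain - 1.0)
            if subtype == "tonic":
                sign = 1 if k < (params.n_units_per_subtype + 1) // 2 else -1
            else:
                sign = int(np.sign(params.value_gain - 1.0))
            spikes: list[np.ndarray] = []
            if params.trial_gain_cv > 0:
                # per-trial whole-unit excitability (super-Poisson variability)
                sig2 = np.log1p(params.trial_gain_cv ** 2)
                trial_gain = rng.lognormal(-sig2 / 2.0, np.sqrt(sig2), n_trials)
            else:
                trial_gain = np.ones(n_trials)
            for i in range(n_trials):
                g_eff = 1.0 + coupling * (latents[i] - 1.0)
                t_rel, lam = rate_function(
                    template, str(conditions[i]), float(rts[i]), params,
                    value_gain=vg_eff, latent=g_eff, modulation_sign=sign)
                st = sample_spike_train(t_rel, lam * trial_gain[i], rng)
                spikes.append(st + target_on[i])
            all_spikes = np.concatenate(spikes) if spikes else np.empty(0)
            units.append(UnitRecord(unit_id=unit_id, channel=channel,
                                    spike_ms=np.sort(all_spikes)))
            truths.append(UnitTruth(unit_id=unit_id, subtype=subtype,
                                    modulation_sign=sign, coupling=coupling,
                                    value_gain_eff=vg_eff))
            channel += 1

    manifest = {
        "session_id": f"synth-{params.seed:06d}",
        "subject": "SYN",
        "sampling_rate_hz": 1000,
        "n_trials": n_trials,
        "target_eccentricity_deg": round(ecc, 4),
    }
    truth = {
        "note": ("synthetic session; rate-template shapes are generator "
                 "constructs, not measurements"),
        "units": [asdict(t) for t in truths],
        "rt_ms": [round(float(v), 4) for v in rts],
        "pv_deg_s": [round(float(v), 4) for v in pvs],
        "amplitude_deg": [round(float(v), 4) for v in amps],
        "latent_gain": [round(float(v), 6) for v in latents],
        "params": _params_to_jsonable(params),
    }
    return SessionBundle(manifest=manifest, trials=trials, units=units,
                         eye_t=eye_t, eye_x=eye_x, eye_y=eye_y, truth=truth)


def _params_to_jsonable(params: GeneratorParams) -> dict:
    d = asdict(params)
    d["subtype_templates"] = {k: asdict(v) for k, v in params.subtype_templates.items()}
    return d


def params_from_dict(d: dict) -> GeneratorParams:
    """Inverse of the ``params`` entry written to truth.json."""
    d = dict(d)
    if "subtype_templates" in d:
        d["subtype_templates"] = {k: RateTemplate(**v)
                                  for k, v in d["subtype_templates"].items()}
    if "amp_range" in d:
        d["amp_range"] = tuple(d["amp_range"])
    if "unit_coupling_range" in d:
        d["unit_coupling_range"] = tuple(d["unit_coupling_range"])
    return GeneratorParams(**d)
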