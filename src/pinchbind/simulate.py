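"""Synthetic prime-probe pinch sessions with a controllable binding effect.

The generator emulates a tone/pinch prime-probe experiment: on every trial the
participant pinches a force sensor (the prime), hears an effect tone, and —
except on catch trials — responds to a second tone (the probe) with another
pinch.  The second tone either repeats the first (congruent) or changes
(incongruent).  The planted "binding" mechanism is a linear retrieval model:
the probe pinch reproduces a fraction λ of the prime pinch's trial-level
deviation from the participant's mean, with λ depending on congruency.  The
congruent-incongruent λ difference is the ground-truth effect that the
downstream similarity analysis must recover; λ_congruent = λ_incongruent is
the null regime used for type-I-error calibration.

Probe deviations receive complementary noise sqrt(1-λ²)·within_sd so that the
marginal trial-level spread is the same in prime and probe and the expected
trial-level prime-probe correlation equals λ exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError, InvalidParameterError
from .force import ForceTrace, PinchEvent

TONE_LOW = "low"
TONE_HIGH = "high"
TONE_NONE = "none"


@dataclass
class DesignSpec:
    """Block/trial structure and timing of one experimental design."""

    n_blocks: int
    trials_per_block: int
    n_congruent_per_block: int
    n_incongruent_per_block: int
    n_catch_per_block: int
    soa_ms: float = 600.0              # prime-effect tone onset -> probe tone onset
    response_window_ms: float = 1200.0
    tone_low_hz: float = 440.0
    tone_high_hz: float = 1175.0
    tone_duration_ms: float = 300.0
    go_signal: bool = False            # prime cued by an auditory go signal
    probe_effect_tone: bool = False    # probe pinch elicits its own effect tone
    effect_delay_ms: float = 6.0       # constant hardware lag action -> tone

    def __post_init__(self) -> None:
        counts = (self.n_congruent_per_block, self.n_incongruent_per_block,
                  self.n_catch_per_block)
        if any(c < 0 for c in counts) or self.n_blocks <= 0 or self.trials_per_block <= 0:
            raise ConfigurationError("block/trial counts must be positive")
        if sum(counts) != self.trials_per_block:
            raise ConfigurationError(
                "congruent + incongruent + catch must equal trials_per_block")
        if self.soa_ms <= 0 or self.response_window_ms <= 0:
            raise ConfigurationError("soa_ms and response_window_ms must be positive")

    @property
    def n_trials(self) -> int:
        return self.n_blocks * self.trials_per_block

    @property
    def catch_fraction(self) -> float:
        return self.n_catch_per_block / self.trials_per_block


#: Named design presets.  "exp1": self-initiated prime, sparse catch trials.
#: "exp2": go-signal prime, 50% catch trials, probe effect tone, shorter tones.
DESIGN_PRESETS = {
    "exp1": dict(n_blocks=7, trials_per_block=30, n_congruent_per_block=12,
                 n_incongruent_per_block=12, n_catch_per_block=6,
                 soa_ms=600.0, response_window_ms=1200.0,
                 tone_low_hz=440.0, tone_high_hz=1175.0, tone_duration_ms=300.0,
                 go_signal=False, probe_effect_tone=False, effect_delay_ms=6.0),
    "exp2": dict(n_blocks=9, trials_per_block=40, n_congruent_per_block=10,
                 n_incongruent_per_block=10, n_catch_per_block=20,
                 soa_ms=600.0, response_window_ms=1200.0,
                 tone_low_hz=440.0, tone_high_hz=1175.0, tone_duration_ms=150.0,
                 go_signal=True, probe_effect_tone=True, effect_delay_ms=6.0),
}


def design_preset(name: str) -> DesignSpec:
    try:
        return DesignSpec(**DESIGN_PRESETS[name])
    except KeyError:
        raise ConfigurationError(f"unknown design preset {name!r}") from None


@dataclass
class PopulationSpec:
    """Participant-population parameters of the generative model.

    Defaults emulate a young-adult cohort pinching an FSR: participant mean
    peak forces of a few newton with substantial between-participant spread,
    pinch durations around 300 ms (well under the 600 ms screening cap), a
    mild congruency RT advantage, and small additive sensor noise that never
    reaches the 0.32 N detection threshold on its own.
    """

    n_participants: int = 19
    mean_peak_N: float = 3.6
    sd_peak_N: float = 1.5              # between-participant SD of mean peak
    mean_duration_ms: float = 300.0
    sd_duration_ms: float = 60.0        # between-participant SD of mean duration
    within_sd_peak_N: float = 1.1       # trial-level SD of peak
    within_sd_duration_ms: float = 45.0  # trial-level SD of duration
    lambda_congruent: float = 0.65      # retrieval strength = expected prime-probe r
    lambda_incongruent: float = 0.55
    probe_boost_peak_N: float = 1.2     # probe pinches are systematically harder
    probe_boost_auc_frac: float = 0.0   # extra multiplicative probe AUC boost
    rt_location_ms: float = 332.0       # mean probe RT on incongruent trials
    rt_scale: float = 0.32              # lognormal shape (unitless)
    rt_congruency_advantage_ms: float = 16.0
    sensor_noise_sd_N: float = 0.02
    miss_rate: float = 0.019
    false_alarm_rate: float = 0.008
    restart_rate: float = 0.075         # per-attempt probability of a too-early pinch
    catch_error_rate: float = 0.061     # probability of pinching on a catch trial
    seed: int = 0

    def __post_init__(self) -> None:
        for lam in (self.lambda_congruent, self.lambda_incongruent):
            if not 0.0 <= lam <= 1.0:
                raise ConfigurationError("retrieval strengths must lie in [0, 1]")
        sds = (self.sd_peak_N, self.sd_duration_ms, self.within_sd_peak_N,
               self.within_sd_duration_ms, self.sensor_noise_sd_N)
        if any(s < 0 for s in sds):
            raise ConfigurationError("all SDs must be non-negative")
        probs = (self.miss_rate, self.false_alarm_rate, self.restart_rate,
                 self.catch_error_rate)
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ConfigurationError("rates must be probabilities in [0, 1]")

    @property
    def is_null(self) -> bool:
        """True in the no-binding regime (congruent and incongruent exchangeable)."""
        return self.lambda_congruent == self.lambda_incongruent


@dataclass
class TrialRecord:
    """One prime-probe trial with ground-truth events and outcome."""

    participant_id: str
    block_index: int
    trial_index: int
    condition: str                     # congruent | incongruent | catch
    prime_tone: str
    probe_tone: str
    prime_stim_onset_ms: Optional[float]   # go-signal onset (go-signal designs only)
    probe_stim_onset_ms: Optional[float]   # second-tone onset (None on catch trials)
    prime_event: Optional[PinchEvent]
    probe_event: Optional[PinchEvent]
    prime_rt_ms: Optional[float]
    probe_rt_ms: Optional[float]
    outcome: str                       # ok | miss | false_alarm | catch_correct | catch_error
    n_restarts: int = 0


def make_pulse(peak_N: float, duration_ms: float,
               sample_rate_hz: float = 1000.0) -> ForceTrace:
    """Idealized brief pinch: a raised-sine-squared force pulse.

    F(t) = peak · sin²(π t / duration) on t ∈ [0, duration], zero outside.
    The shape has closed forms for everything detection and feature
    extraction measure: full-pulse integral peak·duration/2, and threshold
    crossings at t = (duration/π)·asin(sqrt(threshold/peak)).
    """
    if peak_N <= 0 or duration_ms <= 0 or sample_rate_hz <= 0:
        raise InvalidParameterError("make_pulse arguments must be positive")
    n = int(round(duration_ms * sample_rate_hz / 1000.0)) + 1
    t = np.arange(n) * (1000.0 / sample_rate_hz)
    samples = peak_N * np.sin(np.pi * np.minimum(t, duration_ms) / duration_ms) ** 2
    samples[samples < 0] = 0.0
    return ForceTrace(samples=samples, sample_rate_hz=sample_rate_hz,
                      t0_ms=0.0, channel="force_N")


def pulse_threshold_crossing_ms(peak_N: float, duration_ms: float,
                                threshold_N: float) -> float:
    """Analytic time at which the sin² pulse first exceeds ``threshold_N``."""
    if not 0 < threshold_N < peak_N:
        raise InvalidParameterError("threshold must lie strictly inside (0, peak)")
    return (duration_ms / math.pi) * math.asin(math.sqrt(threshold_N / peak_N))


def pulse_partial_auc_Nms(peak_N: float, duration_ms: float,
                          t1_ms: float, t2_ms: float) -> float:
    """Closed-form ∫ peak·sin²(πt/D) dt over [t1, t2] (N·ms)."""
    def antideriv(t: float) -> float:
        return peak_N * (t / 2.0 - (duration_ms / (4.0 * math.pi))
                         * math.sin(2.0 * math.pi * t / duration_ms))
    return antideriv(t2_ms) - antideriv(t1_ms)


def encode_voltage(trace: ForceTrace, a: float, b: float,
                   floor_N: float = 1e-4) -> ForceTrace:
    """Encode a force trace as raw FSR voltage, V = ln(max(F, floor)/a)/b.

    Exact inverse of :func:`pinchbind.force.voltage_to_force` above the
    representable force floor; samples below the floor clip to the baseline
    voltage ln(floor/a)/b.
    """
    if a <= 0:
        raise InvalidParameterError("gain a must be positive")
    if b == 0:
        raise InvalidParameterError("exponent b must be nonzero")
    if not np.all(np.isfinite(trace.samples)):
        raise DataError("trace contains non-finite samples")
    if np.any(trace.samples < 0):
        raise DataError("force samples must be non-negative")
    from dataclasses import replace
    volts = np.log(np.maximum(trace.samples, floor_N) / a) / b
    return replace(trace, samples=volts, channel="voltage")


def _schedule_block(design: DesignSpec, rng: np.random.Generator) -> list[str]:
    """Pseudo-random condition order; the first two trials are never catch."""
    n_non_catch = design.trials_per_block - design.n_catch_per_block
    if design.n_catch_per_block > 0 and n_non_catch < 2:
        raise ConfigurationError(
            "catch count leaves fewer than two non-catch trials; the "
            "first-two-trials constraint cannot be satisfied")
    conditions = (["congruent"] * design.n_congruent_per_block
                  + ["incongruent"] * design.n_incongruent_per_block
                  + ["catch"] * design.n_catch_per_block)
    while True:
        order = list(rng.permutation(conditions))
        if "catch" not in order[:2]:
            return order


def participant_rng(seed: int, participant_index: int) -> np.random.Generator:
    """Independent, reproducible per-participant stream from one root seed."""
    return np.random.default_rng(np.random.SeedSequence((seed, participant_index)))


def _draw_rt(rng: np.random.Generator, pop: PopulationSpec, congruent: bool) -> float:
    """Lognormal RT with mean rt_location (minus the congruency advantage)."""
    mean = pop.rt_location_ms - (pop.rt_congruency_advantage_ms if congruent else 0.0)
    s = pop.rt_scale
    return mean * math.exp(s * rng.standard_normal() - 0.5 * s * s)


def generate_session(design: DesignSpec, pop: PopulationSpec,
                     participant_id: str, participant_index: int = 0,
                     render_traces: bool = True,
                     ) -> tuple[list[TrialRecord], dict]:
    """Simulate one participant's full session.

    Returns the trial records (ground truth features embedded as PinchEvents)
    and, when ``render_traces`` is set, a dict mapping ``(trial_index, part)``
    to a noisy force trace from which detection must re-derive the features.
    """
    rng = participant_rng(pop.seed, participant_index)

    mu_peak = max(1.0, pop.mean_peak_N + pop.sd_peak_N * rng.standard_normal())
    mu_dur = max(120.0, pop.mean_duration_ms
                 + pop.sd_duration_ms * rng.standard_normal())

    records: list[TrialRecord] = []
    traces: dict = {}
    trial_index = 0
    for block in range(design.n_blocks):
        for condition in _schedule_block(design, rng):
            rec, trial_traces = _generate_trial(
                design, pop, rng, participant_id, block, trial_index,
                condition, mu_peak, mu_dur, render_traces)
            records.append(rec)
            traces.update(trial_traces)
            trial_index += 1
    return records, traces


def _clip_feature(x: float, lo: float) -> float:
    return lo if x < lo else x


def _generate_trial(design: DesignSpec, pop: PopulationSpec,
                    rng: np.random.Generator, participant_id: str,
                    block: int, trial_index: int, condition: str,
                    mu_peak: float, mu_dur: float, render_traces: bool):
    prime_tone = TONE_LOW if rng.random() < 0.5 else TONE_HIGH
    if condition == "congruent":
        probe_tone = prime_tone
    elif condition == "incongruent":
        probe_tone = TONE_HIGH if prime_tone == TONE_LOW else TONE_LOW
    else:
        probe_tone = TONE_NONE

    n_restarts = 0
    while rng.random() < pop.restart_rate:
        n_restarts += 1

    # Prime pinch: trial-level deviation around the participant mean.
    dev_peak = pop.within_sd_peak_N * rng.standard_normal()
    dev_dur = pop.within_sd_duration_ms * rng.standard_normal()
    prime_peak = _clip_feature(mu_peak + dev_peak, 0.5)
    prime_dur = _clip_feature(mu_dur + dev_dur, 60.0)

    # Trial clock: 0 = go-signal onset (go-signal designs) or start of the
    # prime recording window (self-initiated designs).
    if design.go_signal:
        prime_stim_onset: Optional[float] = 0.0
        prime_rt: Optional[float] = _draw_rt(rng, pop, congruent=False)
        prime_onset = prime_rt
    else:
        prime_stim_onset = None
        prime_rt = None
        prime_onset = 2000.0 + float(rng.exponential(400.0))

    prime_event = PinchEvent(
        onset_ms=prime_onset, offset_ms=prime_onset + prime_dur,
        duration_ms=prime_dur, peak_force_N=prime_peak,
        auc_Nms=prime_peak * prime_dur / 2.0, rt_ms=prime_rt)

    prime_tone_onset = prime_onset + design.effect_delay_ms
    probe_stim_onset = (None if condition == "catch"
                        else prime_tone_onset + design.soa_ms)

    # Probe pinch via the retrieval model.
    lam = (pop.lambda_congruent if condition == "congruent"
           else pop.lambda_incongruent)
    resid = math.sqrt(max(0.0, 1.0 - lam * lam))
    probe_peak = _clip_feature(
        mu_peak + lam * dev_peak + resid * pop.within_sd_peak_N * rng.standard_normal()
        + pop.probe_boost_peak_N, 0.5)
    probe_dur = _clip_feature(
        (mu_dur + lam * dev_dur
         + resid * pop.within_sd_duration_ms * rng.standard_normal())
        * (1.0 + pop.probe_boost_auc_frac), 60.0)

    probe_event: Optional[PinchEvent] = None
    probe_rt: Optional[float] = None
    if condition == "catch":
        if rng.random() < pop.catch_error_rate:
            outcome = "catch_error"
            onset = prime_tone_onset + float(rng.uniform(300.0, 1500.0))
            probe_event = PinchEvent(
                onset_ms=onset, offset_ms=onset + probe_dur,
                duration_ms=probe_dur, peak_force_N=probe_peak,
                auc_Nms=probe_peak * probe_dur / 2.0)
        else:
            outcome = "catch_correct"
    else:
        u = rng.random()
        if u < pop.miss_rate:
            outcome = "miss"
        elif u < pop.miss_rate + pop.false_alarm_rate:
            outcome = "false_alarm"
            onset = float(rng.uniform(prime_tone_onset, probe_stim_onset))
            probe_event = PinchEvent(
                onset_ms=onset, offset_ms=onset + probe_dur,
                duration_ms=probe_dur, peak_force_N=probe_peak,
                auc_Nms=probe_peak * probe_dur / 2.0)
        else:
            outcome = "ok"
            probe_rt = _draw_rt(rng, pop, congruent=(condition == "congruent"))
            onset = probe_stim_onset + probe_rt
            probe_event = PinchEvent(
                onset_ms=onset, offset_ms=onset + probe_dur,
                duration_ms=probe_dur, peak_force_N=probe_peak,
                auc_Nms=probe_peak * probe_dur / 2.0, rt_ms=probe_rt)

    record = TrialRecord(
        participant_id=participant_id, block_index=block,
        trial_index=trial_index, condition=condition,
        prime_tone=prime_tone, probe_tone=probe_tone,
        prime_stim_onset_ms=prime_stim_onset,
        probe_stim_onset_ms=probe_stim_onset,
        prime_event=prime_event, probe_event=probe_event,
        prime_rt_ms=prime_rt, probe_rt_ms=probe_rt,
        outcome=outcome, n_restarts=n_restarts)

    traces: dict = {}
    if render_traces:
        traces[(trial_index, "prime")] = _render_part(
            rng, pop, prime_event, participant_id, trial_index, "prime")
        if probe_event is not None:
            traces[(trial_index, "probe")] = _render_part(
                rng, pop, probe_event, participant_id, trial_index, "probe")
    return record, traces


#: Rest padding around each rendered pinch; generous relative to the 10 ms
#: persistence requirement so edge effects cannot occur in synthetic windows.
_PAD_BEFORE_MS = 150.0
_PAD_AFTER_MS = 250.0


def _render_part(rng: np.random.Generator, pop: PopulationSpec,
                 event: PinchEvent, participant_id: str, trial_index: int,
                 part: str, sample_rate_hz: float = 1000.0) -> ForceTrace:
    """Render one pinch as a padded, noisy force trace (non-negative)."""
    pulse = make_pulse(event.peak_force_N, event.duration_ms, sample_rate_hz)
    dt = 1000.0 / sample_rate_hz
    n_before = int(round(_PAD_BEFORE_MS / dt))
    n_after = int(round(_PAD_AFTER_MS / dt))
    samples = np.concatenate([np.zeros(n_before), pulse.samples, np.zeros(n_after)])
    if pop.sensor_noise_sd_N > 0:
        samples = samples + pop.sensor_noise_sd_N * rng.standard_normal(samples.size)
    samples = np.clip(samples, 0.0, None)
    return ForceTrace(samples=samples, sample_rate_hz=sample_rate_hz,
                      t0_ms=event.onset_ms - n_before * dt, channel="force_N",
                      participant_id=participant_id, trial_index=trial_index,
                      part=part)


def trials_to_frame(records: list[TrialRecord]) -> pd.DataFrame:
    """Long-format trial table (one row per trial, event features flattened)."""
    rows = []
    for r in records:
        row = {
            "participant_id": r.participant_id, "block_index": r.block_index,
            "trial_index": r.trial_index, "condition": r.condition,
            "prime_tone": r.prime_tone, "probe_tone": r.probe_tone,
            "prime_stim_onset_ms": r.prime_stim_onset_ms,
            "probe_stim_onset_ms": r.probe_stim_onset_ms,
            "prime_rt_ms": r.prime_rt_ms, "probe_rt_ms": r.probe_rt_ms,
            "outcome": r.outcome, "n_restarts": r.n_restarts,
        }
        for part, ev in (("prime", r.prime_event), ("probe", r.probe_event)):
            if ev is None:
                row.update({f"{part}_onset_ms": np.nan, f"{part}_offset_ms": np.nan,
                            f"{part}_duration_ms": np.nan, f"{part}_peak_N": np.nan,
                            f"{part}_auc_Nms": np.nan})
            else:
                row.update({f"{part}_onset_ms": ev.onset_ms,
                            f"{part}_offset_ms": ev.offset_ms,
                            f"{part}_duration_ms": ev.duration_ms,
                            f"{part}_peak_N": ev.peak_force_N,
                            f"{part}_auc_Nms": ev.auc_Nms})
        rows.append(row)
    return pd.DataFrame(rows)
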