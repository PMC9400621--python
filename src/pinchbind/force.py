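"""Force-signal processing: voltage calibration, pinch detection, feature extraction.

A pinch on a force-sensing resistor (FSR) shows up as a transient bump in the
force trace.  Onset is the first sample strictly above a fixed force threshold
(default 0.32 N) that is preceded by a sufficiently long run of at-or-below
threshold samples (default 10 ms); offset is the first subsequent at-or-below
sample followed by an equally long sub-threshold run.  Trace boundaries count
as satisfied history/future, so events that begin or end at the edge of the
recorded window are still detected.  From the detected bounds we derive the
pinch duration, the peak force, the temporal integral of force (AUC, N·ms) and
— given a stimulus onset — the reaction time.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .errors import DataError, InvalidParameterError, UsageError

#: Default calibration constants of the exponential voltage->force transform
#: F = a * exp(b * V).  The hardware constants are device-specific; these
#: defaults are recorded with every analysis that uses them.
DEFAULT_TRANSFORM_A = 0.05  # N, force at V = 0
DEFAULT_TRANSFORM_B = 1.5   # per volt


@dataclass
class ForceTrace:
    """Uniformly sampled force (or encoded voltage) signal for one trial part."""

    samples: np.ndarray
    sample_rate_hz: float = 1000.0
    t0_ms: float = 0.0
    channel: str = "force_N"          # "force_N" | "voltage"
    participant_id: Optional[str] = None
    trial_index: Optional[int] = None
    part: Optional[str] = None        # "prime" | "probe"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sample_rate_hz <= 0:
            raise InvalidParameterError("sample_rate_hz must be positive")
        if self.samples.size == 0:
            raise DataError("trace must contain at least one sample")
        if not np.all(np.isfinite(self.samples)):
            raise DataError("trace contains non-finite samples")
        if self.channel == "force_N" and np.any(self.samples < 0):
            raise DataError("force traces must be non-negative")

    @property
    def dt_ms(self) -> float:
        return 1000.0 / self.sample_rate_hz

    @property
    def times_ms(self) -> np.ndarray:
        return self.t0_ms + np.arange(self.samples.size) * self.dt_ms


@dataclass
class PinchEvent:
    """One detected pinch: bounds plus derived features."""

    onset_ms: float
    offset_ms: float
    duration_ms: float
    peak_force_N: float = np.nan
    auc_Nms: float = np.nan
    rt_ms: Optional[float] = None
    negative_rt: bool = False
    n_extra_events: int = 0


@dataclass
class DetectionParams:
    """Threshold/persistence rule parameters for pinch detection."""

    threshold_N: float = 0.32
    persistence_ms: float = 10.0
    transform_a: float = DEFAULT_TRANSFORM_A
    transform_b: float = DEFAULT_TRANSFORM_B
    # "exceeded" = strictly above threshold; "under" = at or below.  Flip to
    # include threshold-equal samples in the event instead.
    strict_above: bool = True

    def __post_init__(self) -> None:
        if self.threshold_N <= 0:
            raise InvalidParameterError("threshold_N must be positive")
        if self.persistence_ms < 0:
            raise InvalidParameterError("persistence_ms must be non-negative")


def voltage_to_force(trace: ForceTrace, a: float = DEFAULT_TRANSFORM_A,
                     b: float = DEFAULT_TRANSFORM_B) -> ForceTrace:
    """Apply the exponential FSR calibration F = a * exp(b * V) sample-wise."""
    if trace.channel != "voltage":
        raise UsageError(f"expected a voltage trace, got channel={trace.channel!r}")
    if a <= 0:
        raise InvalidParameterError("gain a must be positive")
    if b == 0:
        raise InvalidParameterError("exponent b must be nonzero")
    return replace(trace, samples=a * np.exp(b * trace.samples), channel="force_N")


def identity_filter(trace: ForceTrace) -> ForceTrace:
    """Hook for an acquisition-matching low-pass filter; the default is a no-op.

    Synthetic traces are band-limited by construction, so no additional
    filtering is applied.  Real recordings that were not already low-pass
    filtered online can swap in a concrete filter here.
    """
    return trace


def _runs(above: np.ndarray) -> list[tuple[int, int, bool]]:
    """Run-length encode a boolean array as (start, end, value) with end exclusive."""
    change = np.flatnonzero(above[1:] != above[:-1]) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [above.size]))
    return [(int(s), int(e), bool(above[s])) for s, e in zip(starts, ends)]


def detect_pinch(trace: ForceTrace, params: DetectionParams | None = None,
                 ) -> Optional[PinchEvent]:
    """Detect the first qualifying pinch in a force trace.

    Returns ``None`` when no crossing qualifies (a valid result, not an
    error).  Short sub-threshold dips that do not satisfy the persistence
    requirement are absorbed into a single merged event.  Additional
    qualifying events after the first are counted in ``n_extra_events``.
    """
    params = params or DetectionParams()
    if trace.channel != "force_N":
        raise UsageError("detect_pinch requires a force-channel trace")
    p = int(round(params.persistence_ms * trace.sample_rate_hz / 1000.0))
    x = trace.samples
    above = x > params.threshold_N if params.strict_above else x >= params.threshold_N
    if not above.any():
        return None

    runs = _runs(above)
    events: list[tuple[int, int]] = []  # (onset index, offset index or -1)
    onset_i: Optional[int] = None
    history_ok = True  # trace start counts as satisfied history
    for k, (s, e, is_above) in enumerate(runs):
        if is_above:
            if onset_i is None and history_ok:
                onset_i = s
        else:
            history_ok = (e - s >= p) or (s == 0) or (e == x.size)
            if onset_i is not None and ((e - s >= p) or (e == x.size)):
                events.append((onset_i, s))
                onset_i = None
    # a trace that ends above threshold has no qualifying offset sample
    if not events:
        return None
    onset_i, offset_i = events[0]
    onset_ms = trace.t0_ms + onset_i * trace.dt_ms
    offset_ms = trace.t0_ms + offset_i * trace.dt_ms
    return PinchEvent(onset_ms=onset_ms, offset_ms=offset_ms,
                      duration_ms=offset_ms - onset_ms,
                      n_extra_events=len(events) - 1)


def compute_features(trace: ForceTrace, event: PinchEvent,
                     stimulus_onset_ms: Optional[float] = None) -> PinchEvent:
    """Fill peak force, AUC and (optionally) RT for a detected event.

    Peak is the maximum force over [onset, offset]; AUC is the trapezoid
    integral of the raw force over the same window, in N·ms.  A stimulus
    onset later than the pinch onset yields a negative RT which is returned
    and flagged rather than dropped.
    """
    if trace.channel != "force_N":
        raise UsageError("compute_features requires a force-channel trace")
    i_on = int(round((event.onset_ms - trace.t0_ms) / trace.dt_ms))
    i_off = int(round((event.offset_ms - trace.t0_ms) / trace.dt_ms))
    if i_on < 0 or i_off >= trace.samples.size or i_on > i_off:
        raise DataError("event lies outside the trace extent")
    seg = trace.samples[i_on:i_off + 1]
    peak = float(seg.max())
    auc = float(np.trapezoid(seg, dx=trace.dt_ms))
    rt: Optional[float] = None
    negative = False
    if stimulus_onset_ms is not None:
        rt = event.onset_ms - stimulus_onset_ms
        negative = rt < 0
    return replace(event, peak_force_N=peak, auc_Nms=auc, rt_ms=rt,
                   negative_rt=negative)


def extract_features(traces: dict, trials: pd.DataFrame,
                     params: DetectionParams | None = None) -> pd.DataFrame:
    """Run detection + feature extraction over a session's trace collection.

    ``traces`` maps ``(trial_index, part)`` to a ForceTrace (voltage traces
    are calibrated first with the params' transform constants); ``trials`` is
    the long-format trial table and supplies per-part stimulus onsets.
    Returns one row per (participant, trial, part) with all PinchEvent fields;
    parts with no detected pinch get NaN features.
    """
    params = params or DetectionParams()
    trial_info = trials.set_index("trial_index")
    rows = []
    for (trial_index, part), trace in sorted(traces.items()):
        if trace.channel == "voltage":
            trace = voltage_to_force(trace, params.transform_a, params.transform_b)
        trace = identity_filter(trace)
        info = trial_info.loc[trial_index]
        stim_col = "prime_stim_onset_ms" if part == "prime" else "probe_stim_onset_ms"
        stim = info.get(stim_col)
        stim = None if stim is None or pd.isna(stim) else float(stim)
        event = detect_pinch(trace, params)
        row = {
            "participant_id": trace.participant_id,
            "trial_index": trial_index,
            "part": part,
            "condition": info["condition"],
            "block_index": info.get("block_index"),
            "stimulus_onset_ms": stim,
        }
        if event is not None:
            event = compute_features(trace, event, stimulus_onset_ms=stim)
            row.update(onset_ms=event.onset_ms, offset_ms=event.offset_ms,
                       duration_ms=event.duration_ms,
                       peak_N=event.peak_force_N, auc_Nms=event.auc_Nms,
                       rt_ms=event.rt_ms, negative_rt=event.negative_rt,
                       n_extra_events=event.n_extra_events)
        else:
            row.update(onset_ms=np.nan, offset_ms=np.nan, duration_ms=np.nan,
                       peak_N=np.nan, auc_Nms=np.nan, rt_ms=np.nan,
                       negative_rt=False, n_extra_events=0)
        rows.append(row)
    return pd.DataFrame(rows)
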