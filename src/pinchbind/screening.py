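"""Trial-outcome classification and the multi-stage outlier-rejection cascade.

Screening operates on the wide per-trial feature table (one row per trial,
``prime_*`` / ``probe_*`` feature columns) and applies, in a fixed documented
order:

1. RT floor — probe (and, for go-signal designs, prime) RTs faster than
   100 ms are anticipations;
2. RT ceiling — either participant×condition mean + 2.5 SD, or an absolute
   3 s cap followed by a z > 2.5 cut (both computed over the trials still
   eligible at that stage, single pass);
3. prime pinch-duration cap — durations ≥ 600 ms (inclusive) overlap the
   probe stimulus;
4. probe pinch-duration cap — same rule on the probe pinch;
5. per-DV z rejection — |z| > 2.5 on the analysed dependent variable,
   computed per participant × condition separately for the prime and probe
   values; this stage is re-run per analysis, so different DVs see different
   survivor sets.

Catch trials are never screened; they pass through untouched for error-rate
reporting.  Only trials classified ``ok`` are eligible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError

MODE_MEAN_SD = "mean_plus_2.5sd"
MODE_ABS_THEN_Z = "absolute_3000ms_then_z2.5"


@dataclass
class ScreeningRules:
    rt_floor_ms: float = 100.0
    rt_ceiling_mode: str = MODE_MEAN_SD
    rt_ceiling_sd: float = 2.5
    rt_ceiling_abs_ms: float = 3000.0
    rt_ceiling_z: float = 2.5
    duration_cap_ms: float = 600.0
    dv_z_cutoff: float = 2.5
    check_prime_rt: bool = False      # go-signal designs also screen prime RT
    group_by_condition: bool = True   # stats per participant×condition vs per participant

    def __post_init__(self) -> None:
        if min(self.rt_floor_ms, self.rt_ceiling_sd, self.rt_ceiling_abs_ms,
               self.rt_ceiling_z, self.duration_cap_ms, self.dv_z_cutoff) <= 0:
            raise ConfigurationError("all screening thresholds must be positive")
        if self.rt_ceiling_mode not in (MODE_MEAN_SD, MODE_ABS_THEN_Z):
            raise ConfigurationError(
                f"unknown rt_ceiling_mode {self.rt_ceiling_mode!r}")


SCREENING_PRESETS = {
    "exp1": ScreeningRules(rt_ceiling_mode=MODE_MEAN_SD, check_prime_rt=False),
    "exp2": ScreeningRules(rt_ceiling_mode=MODE_ABS_THEN_Z, check_prime_rt=True),
}


def screening_preset(name: str) -> ScreeningRules:
    try:
        rules = SCREENING_PRESETS[name]
    except KeyError:
        raise ConfigurationError(f"unknown screening preset {name!r}") from None
    return ScreeningRules(**vars(rules))


@dataclass
class ScreeningReport:
    """Ordered per-rule rejection log plus per-condition survivor counts."""

    rule_log: list = field(default_factory=list)  # [{rule, n_rejected, fraction}]
    n_eligible: int = 0
    n_remaining: int = 0
    n_remaining_by_condition: dict = field(default_factory=dict)

    def add(self, rule: str, n_rejected: int, n_at_stage: int) -> None:
        frac = 0.0 if n_at_stage == 0 else n_rejected / n_at_stage
        self.rule_log.append({"rule": rule, "n_rejected": int(n_rejected),
                              "fraction_of_eligible": frac})
    def to_dict(self) -> dict:
        return {"n_eligible": self.n_eligible, "n_remaining": self.n_remaining,
                "n_remaining_by_condition": self.n_remaining_by_condition,
                "rules": self.rule_log}


def classify_outcomes(trials: pd.DataFrame, soa_ms: float = 600.0,
                      response_window_ms: float = 1200.0) -> pd.DataFrame:
    """Assign trial outcomes from events and stimulus timing.

    Non-catch trials: a probe pinch inside the SOA interval (before the
    second tone) is a false alarm; no probe pinch, or one later than the
    response window, is a miss; otherwise ok.  Catch trials: any probe-part
    pinch is a catch error, none is a correct rejection.
    """
    trials = trials.copy()
    if trials["prime_onset_ms"].isna().any():
        bad = trials.loc[trials["prime_onset_ms"].isna(), "trial_index"].tolist()
        raise DataError(f"missing prime event on non-restart trials {bad}")
    catch = (trials["condition"] == "catch").to_numpy()
    has_probe = trials["probe_onset_ms"].notna().to_numpy()
    onset = trials["probe_onset_ms"].to_numpy(dtype=float)
    stim = trials["probe_stim_onset_ms"].to_numpy(dtype=float)
    trials["outcome"] = np.select(
        [catch & has_probe,
         catch,
         ~has_probe,
         onset < stim,
         onset > stim + response_window_ms],
        ["catch_error", "catch_correct", "miss", "false_alarm", "miss"],
        default="ok")
    return trials


def _group_keys(rules: ScreeningRules) -> list[str]:
    keys = ["participant_id"]
    if rules.group_by_condition:
        keys.append("condition")
    return keys


def _z_mask(values: pd.Series, groups: pd.DataFrame, keys: list[str],
            cutoff: float, rule: str) -> pd.Series:
    """|z| > cutoff mask within groups; cells with <2 values are skipped."""
    mask = pd.Series(False, index=values.index)
    for _, idx in groups.groupby(keys, observed=True).groups.items():
        v = values.loc[idx].dropna()
        if len(v) < 2:
            warnings.warn(f"{rule}: cell with <2 trials skipped (SD undefined)",
                          stacklevel=2)
            continue
        sd = v.std(ddof=1)
        if sd == 0:
            continue
        z = (v - v.mean()) / sd
        mask.loc[v.index[np.abs(z) > cutoff]] = True
    return mask


def screen(trials: pd.DataFrame, rules: ScreeningRules,
           dv: Optional[str] = None) -> tuple[pd.DataFrame, ScreeningReport]:
    """Apply the rejection cascade; returns (surviving ok-trials, report).

    ``dv`` names the dependent variable (e.g. ``auc_Nms``) for the final
    per-DV z stage, applied to the ``prime_<dv>`` and ``probe_<dv>`` columns;
    pass ``None`` to skip that stage (e.g. for the RT analysis, where the
    ceiling rules already constrain RT).
    """
    if "outcome" not in trials.columns:
        raise DataError("trials must be outcome-classified before screening")
    keys = _group_keys(rules)
    report = ScreeningReport()
    eligible = trials[trials["outcome"] == "ok"].copy()
    report.n_eligible = len(eligible)

    def apply_stage(rule: str, mask: pd.Series) -> None:
        nonlocal eligible
        report.add(rule, int(mask.sum()), len(eligible))
        eligible = eligible[~mask]

    # 1. RT floor
    fast = eligible["probe_rt_ms"] < rules.rt_floor_ms
    if rules.check_prime_rt and "prime_rt_ms" in eligible.columns:
        fast = fast | (eligible["prime_rt_ms"] < rules.rt_floor_ms)
    apply_stage("rt_floor", fast)

    # 2. RT ceiling
    if rules.rt_ceiling_mode == MODE_MEAN_SD:
        ceil_mask = pd.Series(False, index=eligible.index)
        for _, idx in eligible.groupby(keys, observed=True).groups.items():
            v = eligible.loc[idx, "probe_rt_ms"]
            if len(v) < 2:
                warnings.warn("rt_ceiling: cell with <2 trials skipped",
                              stacklevel=1)
                continue
            ceil_mask.loc[idx] = v > v.mean() + rules.rt_ceiling_sd * v.std(ddof=1)
        apply_stage("rt_ceiling_mean_sd", ceil_mask)
    else:
        apply_stage("rt_ceiling_absolute",
                    eligible["probe_rt_ms"] > rules.rt_ceiling_abs_ms)
        apply_stage("rt_ceiling_z",
                    _z_mask(eligible["probe_rt_ms"], eligible, keys,
                            rules.rt_ceiling_z, "rt_ceiling_z"))

    # 3./4. pinch-duration caps (inclusive: durations equal to the cap reject)
    apply_stage("prime_duration_cap",
                eligible["prime_duration_ms"] >= rules.duration_cap_ms)
    apply_stage("probe_duration_cap",
                eligible["probe_duration_ms"] >= rules.duration_cap_ms)

    # 5. per-DV z rejection, prime and probe values separately
    if dv is not None:
        mask = (_z_mask(eligible[f"prime_{dv}"], eligible, keys,
                        rules.dv_z_cutoff, f"dv_z[{dv}]")
                | _z_mask(eligible[f"probe_{dv}"], eligible, keys,
                          rules.dv_z_cutoff, f"dv_z[{dv}]"))
        apply_stage(f"dv_z_{dv}", mask)

    report.n_remaining = len(eligible)
    report.n_remaining_by_condition = (
        eligible.groupby("condition", observed=True).size().to_dict())
    return eligible, report
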