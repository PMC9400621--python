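"""Independent brute-force oracles used by the test suite.

Deliberately naive re-implementations — sample-by-sample scans, textbook
formulas, alternative integral representations — kept separate from the
package code paths they check.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import integrate
from scipy.special import gammaln


def brute_force_detect(samples, dt_ms, threshold, persistence_ms):
    """Sample-by-sample scan for the first qualifying pinch.

    Returns (onset_index, offset_index) or None.  Trace start/end count as
    satisfied persistence history/future.
    """
    n = len(samples)
    p = int(round(persistence_ms / dt_ms))

    def below_run_before(i):
        # length of the consecutive at-or-below run ending right before i
        k = 0
        j = i - 1
        while j >= 0 and samples[j] <= threshold:
            k += 1
            j -= 1
        return k, (j < 0)  # run length, reached trace start

    def below_run_from(i):
        k = 0
        j = i
        while j < n and samples[j] <= threshold:
            k += 1
            j += 1
        return k, (j >= n)  # run length, reached trace end

    onset = None
    for i in range(n):
        if samples[i] > threshold:
            run, hit_start = below_run_before(i)
            if run >= p or hit_start:
                onset = i
                break
    if onset is None:
        return None
    for i in range(onset + 1, n):
        if samples[i] <= threshold:
            run, hit_end = below_run_from(i)
            if run >= p or hit_end:
                return onset, i
    return None  # never terminated below threshold


def pearson_by_hand(x, y):
    """Textbook Pearson correlation from raw sums."""
    n = len(x)
    sx, sy = sum(x), sum(y)
    sxx = sum(v * v for v in x)
    syy = sum(v * v for v in y)
    sxy = sum(a * b for a, b in zip(x, y))
    num = n * sxy - sx * sy
    den = math.sqrt((n * sxx - sx * sx) * (n * syy - sy * sy))
    return num / den


def jzs_bf10_g_integral(t, n, scale=0.707):
    """JZS Bayes factor via the Zellner-Siow g-prior mixture representation.

    Integrates over g with an InverseGamma(1/2, scale^2/2) mixing density
    instead of over the effect size under the Cauchy prior — an algebraically
    different route to the same Bayes factor.
    """
    nu = n - 1

    def log_invgamma_pdf(g):
        a, b = 0.5, scale * scale / 2.0
        return a * math.log(b) - gammaln(a) - (a + 1) * math.log(g) - b / g

    def integrand(g):
        log_lik = (-0.5 * math.log(1.0 + n * g)
                   - ((nu + 1) / 2.0)
                   * math.log(1.0 + t * t / ((1.0 + n * g) * nu)))
        return math.exp(log_lik + log_invgamma_pdf(g))

    num, _ = integrate.quad(integrand, 0, np.inf, epsrel=1e-10, limit=400)
    den = (1.0 + t * t / nu) ** (-(nu + 1) / 2.0)
    return num / den


def cascade_oracle(trials: pd.DataFrame, dv: str, *, rt_floor=100.0,
                   ceiling_mode="mean_plus_2.5sd", duration_cap=600.0,
                   z_cut=2.5, check_prime_rt=False,
                   order=("floor", "ceiling", "prime_cap", "probe_cap", "z"),
                   ) -> set:
    """Independent re-implementation of the screening cascade.

    Applies each rule in ``order`` with explicit row loops and returns the
    set of surviving trial indices (ok-outcome trials only).
    """
    alive = {i for i in trials.index if trials.loc[i, "outcome"] == "ok"}

    def cells():
        out = {}
        for i in alive:
            key = (trials.loc[i, "participant_id"], trials.loc[i, "condition"])
            out.setdefault(key, []).append(i)
        return out

    for rule in order:
        if rule == "floor":
            doomed = set()
            for i in alive:
                if trials.loc[i, "probe_rt_ms"] < rt_floor:
                    doomed.add(i)
                if check_prime_rt and trials.loc[i, "prime_rt_ms"] < rt_floor:
                    doomed.add(i)
            alive -= doomed
        elif rule == "ceiling":
            if ceiling_mode == "mean_plus_2.5sd":
                doomed = set()
                for key, idx in cells().items():
                    rts = [trials.loc[i, "probe_rt_ms"] for i in idx]
                    if len(rts) < 2:
                        continue
                    mu = np.mean(rts)
                    sd = np.std(rts, ddof=1)
                    for i in idx:
                        if trials.loc[i, "probe_rt_ms"] > mu + 2.5 * sd:
                            doomed.add(i)
                alive -= doomed
            else:
                alive -= {i for i in alive
                          if trials.loc[i, "probe_rt_ms"] > 3000.0}
                doomed = set()
                for key, idx in cells().items():
                    rts = [trials.loc[i, "probe_rt_ms"] for i in idx]
                    if len(rts) < 2:
                        continue
                    mu, sd = np.mean(rts), np.std(rts, ddof=1)
                    if sd == 0:
                        continue
                    for i in idx:
                        if abs((trials.loc[i, "probe_rt_ms"] - mu) / sd) > z_cut:
                            doomed.add(i)
                alive -= doomed
        elif rule == "prime_cap":
            alive -= {i for i in alive
                      if trials.loc[i, "prime_duration_ms"] >= duration_cap}
        elif rule == "probe_cap":
            alive -= {i for i in alive
                      if trials.loc[i, "probe_duration_ms"] >= duration_cap}
        elif rule == "z":
            doomed = set()
            for part in ("prime", "probe"):
                col = f"{part}_{dv}"
                for key, idx in cells().items():
                    vals = [trials.loc[i, col] for i in idx]
                    if len(vals) < 2:
                        continue
                    mu, sd = np.mean(vals), np.std(vals, ddof=1)
                    if sd == 0:
                        continue
                    for i in idx:
                        if abs((trials.loc[i, col] - mu) / sd) > z_cut:
                            doomed.add(i)
            alive -= doomed
        else:
            raise ValueError(rule)
    return alive
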