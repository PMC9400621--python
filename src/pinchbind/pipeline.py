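"""Pipeline orchestration: simulate -> process -> screen -> analyze, plus
parameter-recovery / type-I-error calibration experiments.

``run_analysis`` produces, per dependent variable, the three comparison
families of the similarity analysis (Fisher-Z correlation contrast, mean
absolute difference contrast, probe RT contrast) plus the prime-vs-probe
forcefulness comparison; two bundles can be combined into the pooled analysis
and the 2 (experiment) × 2 (part) mixed ANOVA.  ``recover`` sweeps retrieval
strengths and reports rejection rates of the congruency test, with the null
row (λ_congruent = λ_incongruent) always included so nominal type-I error is
visible next to power.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import io as pio
from .errors import ConfigurationError, DataError
from .force import DetectionParams, extract_features
from .screening import ScreeningRules, classify_outcomes, screen, screening_preset
from .simulate import (DesignSpec, PopulationSpec, design_preset,
                       generate_session, trials_to_frame)
from .stats import (TestResult, dz_confint, mixed_anova_2x2, paired_t,
                    prime_probe_summary)

log = logging.getLogger("pinchbind")

#: The dependent variables of the similarity analysis, as trial-table column
#: suffixes (prime_<dv> / probe_<dv>).
DEFAULT_DVS = ("auc_Nms", "peak_N", "duration_ms")


@dataclass
class AnalysisConfig:
    design: Union[str, DesignSpec] = "exp1"
    population: PopulationSpec = field(default_factory=PopulationSpec)
    n_participants: int = 19
    detection: DetectionParams = field(default_factory=DetectionParams)
    screening: Union[str, ScreeningRules, None] = None  # None -> match design preset
    dvs: Sequence[str] = DEFAULT_DVS
    alpha: float = 0.05
    alpha_duration: float = 0.025   # Bonferroni .05/2 for the two duration tests
    seed: int = 0
    out_dir: Optional[str] = None
    reps: int = 200
    use_traces: bool = True         # False: analyze ground-truth features directly

    def resolved_design(self) -> DesignSpec:
        return design_preset(self.design) if isinstance(self.design, str) else self.design

    def resolved_screening(self) -> ScreeningRules:
        s = self.screening
        if s is None:
            s = self.design if isinstance(self.design, str) else "exp1"
        return screening_preset(s) if isinstance(s, str) else s


def simulate_cohort(config: AnalysisConfig) -> tuple[pd.DataFrame, dict]:
    """Simulate all participants; returns (trial frame, traces keyed by
    (participant_id, trial_index, part))."""
    design = config.resolved_design()
    pop = replace(config.population, seed=config.seed)
    frames = []
    traces: dict = {}
    for i in range(config.n_participants):
        pid = f"p{i + 1:02d}"
        records, ptraces = generate_session(
            design, pop, pid, participant_index=i,
            render_traces=config.use_traces)
        frames.append(trials_to_frame(records))
        for (trial_index, part), trace in ptraces.items():
            traces[(pid, trial_index, part)] = trace
    return pd.concat(frames, ignore_index=True), traces


def features_to_trial_table(features: pd.DataFrame,
                            trials: pd.DataFrame) -> pd.DataFrame:
    """Widen the long (participant, trial, part) feature table to one row per
    trial with ``prime_*`` / ``probe_*`` columns, carrying trial metadata."""
    meta_cols = ["participant_id", "trial_index", "block_index", "condition",
                 "prime_stim_onset_ms", "probe_stim_onset_ms"]
    meta = trials[meta_cols].drop_duplicates(["participant_id", "trial_index"])
    feat_cols = ["onset_ms", "offset_ms", "duration_ms", "peak_N", "auc_Nms",
                 "rt_ms"]
    wide = features.pivot(index=["participant_id", "trial_index"],
                          columns="part", values=feat_cols)
    wide.columns = [f"{part}_{col}" for col, part in wide.columns]
    wide = wide.reset_index()
    out = meta.merge(wide, on=["participant_id", "trial_index"], how="left")
    for col in [f"{p}_{c}" for p in ("prime", "probe") for c in feat_cols]:
        if col not in out.columns:
            out[col] = np.nan
    return out


def process_cohort(config: AnalysisConfig, trials: pd.DataFrame,
                   traces: dict) -> pd.DataFrame:
    """Detection + feature extraction over all rendered traces."""
    tables = []
    for pid, sub in trials.groupby("participant_id", observed=True):
        ptraces = {(t, part): trace for (p, t, part), trace in traces.items()
                   if p == pid}
        feats = extract_features(ptraces, sub, config.detection)
        feats["participant_id"] = pid
        tables.append(feats)
    features = pd.concat(tables, ignore_index=True)
    return features_to_trial_table(features, trials)


def ground_truth_trial_table(trials: pd.DataFrame) -> pd.DataFrame:
    """Trial table taken directly from the generator's ground-truth features
    (no trace rendering / detection); used by the fast recovery paths."""
    return trials.copy()


def _corr_test(summaries: pd.DataFrame, label: str, alpha: float) -> Optional[TestResult]:
    piv = summaries.pivot(index="participant_id", columns="condition",
                          values="z_r")
    if not {"congruent", "incongruent"}.issubset(piv.columns):
        return None
    piv = piv.replace([np.inf, -np.inf], np.nan).dropna()
    if len(piv) < 2:
        return None
    return paired_t(piv["congruent"], piv["incongruent"], label=label)


def _diff_test(summaries: pd.DataFrame, label: str) -> Optional[TestResult]:
    piv = summaries.pivot(index="participant_id", columns="condition",
                          values="mean_abs_diff").dropna()
    if not {"congruent", "incongruent"}.issubset(piv.columns) or len(piv) < 2:
        return None
    return paired_t(piv["congruent"], piv["incongruent"], label=label)


def _rt_test(survivors: pd.DataFrame, label: str = "rt") -> Optional[TestResult]:
    cell_means = (survivors.groupby(["participant_id", "condition"],
                                    observed=True)["probe_rt_ms"]
                  .mean().unstack("condition").dropna())
    if not {"congruent", "incongruent"}.issubset(cell_means.columns):
        return None
    return paired_t(cell_means["congruent"], cell_means["incongruent"],
                    label=label)


def _part_means(survivors: pd.DataFrame, dv: str) -> pd.DataFrame:
    """Per-participant mean prime and probe values, pooled across conditions."""
    g = survivors.groupby("participant_id", observed=True)
    return pd.DataFrame({"prime": g[f"prime_{dv}"].mean(),
                         "probe": g[f"probe_{dv}"].mean()}).dropna()


def run_analysis(config: AnalysisConfig,
                 trial_table: Optional[pd.DataFrame] = None) -> dict:
    """Run the full pipeline and return the report bundle.

    With no ``trial_table``, a cohort is simulated under ``config``; a
    user-supplied wide trial table (e.g. from real recordings) is analyzed
    unchanged.  The bundle holds per-DV screening reports, participant-level
    summaries, the test families, and the intermediate tables needed for
    pooled analyses.  When ``config.out_dir`` is set, ``tests.json``,
    ``summaries.csv``, ``screening_report.json`` and a text report are
    written there.
    """
    design = config.resolved_design()
    rules = config.resolved_screening()
    if trial_table is None:
        trials, traces = simulate_cohort(config)
        log.info("simulated %d trials, %d traces", len(trials), len(traces))
        if config.use_traces:
            trial_table = process_cohort(config, trials, traces)
        else:
            trial_table = ground_truth_trial_table(trials)
    trial_table = classify_outcomes(
        trial_table, soa_ms=design.soa_ms,
        response_window_ms=design.response_window_ms)

    tests: dict[str, TestResult] = {}
    screening_reports: dict[str, dict] = {}
    summaries_frames = []
    part_means: dict[str, pd.DataFrame] = {}

    def add(res: Optional[TestResult]) -> None:
        if res is not None:
            tests[res.label] = res

    for dv in config.dvs:
        survivors, report = screen(trial_table, rules, dv=dv)
        screening_reports[dv] = report.to_dict()
        log.info("screening[%s]: %d of %d eligible trials remain", dv,
                 report.n_remaining, report.n_eligible)
        summaries = prime_probe_summary(survivors, dv)
        summaries_frames.append(summaries)
        short = dv.split("_")[0]  # auc | peak | duration
        alpha = config.alpha_duration if short == "duration" else config.alpha
        add(_corr_test(summaries, f"{short}_corr", alpha))
        add(_diff_test(summaries, f"{short}_diff"))
        if short in ("auc", "peak"):
            pm = _part_means(survivors, dv)
            part_means[dv] = pm
            if len(pm) >= 2:
                add(paired_t(pm["prime"], pm["probe"],
                             label=f"{short}_prime_vs_probe"))

    rt_survivors, rt_report = screen(trial_table, rules, dv=None)
    screening_reports["rt"] = rt_report.to_dict()
    add(_rt_test(rt_survivors))

    outcome_counts = trial_table["outcome"].value_counts().to_dict()
    bundle = {
        "tests": {k: v.to_dict() for k, v in tests.items()},
        "screening": screening_reports,
        "outcome_counts": outcome_counts,
        "summaries": pd.concat(summaries_frames, ignore_index=True),
        "part_means": part_means,
        "n_participants": int(trial_table["participant_id"].nunique()),
        "alpha": config.alpha,
        "alpha_duration": config.alpha_duration,
        "seed": config.seed,
    }
    if config.out_dir:
        _write_bundle(Path(config.out_dir), bundle)
    return bundle


def _write_bundle(out: Path, bundle: dict) -> None:
    out.mkdir(parents=True, exist_ok=True)
    pio.write_json(out / "tests.json", bundle["tests"])
    pio.write_json(out / "screening_report.json", bundle["screening"])
    bundle["summaries"].to_csv(out / "summaries.csv", index=False)
    lines = [f"participants: {bundle['n_participants']}",
             f"trial outcomes: {bundle['outcome_counts']}", ""]
    for label, t in sorted(bundle["tests"].items()):
        lines.append(
            f"{label:22s} t({t['df']}) = {t['t']:+.2f}, p = {t['p']:.3f}, "
            f"dz = {t['dz']:.2f}, BF10 = {t['bf10']:.3f}")
    (out / "report.txt").write_text("\n".join(lines) + "\n")


def pooled_analysis(bundle1: dict, bundle2: dict,
                    dvs: Sequence[str] = DEFAULT_DVS) -> dict:
    """Combine two experiments: pooled test families plus the 2×2 mixed ANOVA.

    Participant-level summaries are concatenated across experiments despite
    the differing designs (heterogeneity warned); the ANOVA crosses
    experiment (between) with trial part (within) on mean forcefulness.
    """
    warnings.warn("pooled analysis concatenates participant-level summaries "
                  "from two designs; interpret between-experiment effects "
                  "with the design differences in mind")
    tests: dict[str, dict] = {}
    summaries = pd.concat(
        [b["summaries"].assign(experiment=i + 1) for i, b in
         enumerate((bundle1, bundle2))], ignore_index=True)
    # participant ids may collide across experiments
    summaries["participant_id"] = (summaries["experiment"].astype(str) + ":"
                                   + summaries["participant_id"].astype(str))
    for dv in dvs:
        short = dv.split("_")[0]
        sub = summaries[summaries["dv"] == dv]
        res = _corr_test(sub, f"pooled_{short}_corr", alpha=0.05)
        if res is not None:
            tests[res.label] = res.to_dict()
        res = _diff_test(sub, f"pooled_{short}_diff")
        if res is not None:
            tests[res.label] = res.to_dict()

    anova: dict[str, list] = {}
    for dv in ("auc_Nms", "peak_N"):
        rows = []
        for i, b in enumerate((bundle1, bundle2)):
            pm = b["part_means"].get(dv)
            if pm is None:
                continue
            for pid, row in pm.iterrows():
                for part in ("prime", "probe"):
                    rows.append({"participant_id": f"e{i + 1}:{pid}",
                                 "group": f"exp{i + 1}", "part": part,
                                 "value": row[part]})
        if rows:
            anova[dv] = [a.to_dict() for a in
                         mixed_anova_2x2(pd.DataFrame(rows))]
    return {"tests": tests, "anova": anova}


def effect_size_table(tests: dict, conf: float = 0.95) -> pd.DataFrame:
    """Signed dz point estimates with noncentral-t confidence intervals.

    One row per test family in the bundle's ``tests`` mapping; the CI inverts
    the noncentral-t distribution at the observed t and is symmetric about 0
    when t = 0.
    """
    rows = []
    for label, t in sorted(tests.items()):
        lo, hi = dz_confint(t["t"], t["n"], conf)
        rows.append({"analysis": label, "n": t["n"], "t": t["t"],
                     "dz": t["t"] / math.sqrt(t["n"]),
                     "dz_abs": t["dz"], "ci_low": lo, "ci_high": hi})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Recovery / calibration experiments
# ---------------------------------------------------------------------------

def _corr_rejections_vectorized(lambda_c: float, lambda_i: float,
                                n_participants: int, trials_per_condition: int,
                                reps: int, rng: np.random.Generator,
                                alpha: float = 0.05,
                                ) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized feature-level simulation of the duration-correlation test.

    Draws trial-level prime deviations and λ-coupled probe deviations
    straight from the generative model (participant means cancel out of the
    within-participant correlation), computes the per-participant Fisher-Z
    correlations and the paired t across participants for each replicate.
    Returns (two-sided p-values, dz) arrays of length ``reps``.
    """
    P, T = n_participants, trials_per_condition
    z = {}
    for cond, lam in (("c", lambda_c), ("i", lambda_i)):
        prime = rng.standard_normal((reps, P, T))
        resid = math.sqrt(max(0.0, 1.0 - lam * lam))
        probe = lam * prime + resid * rng.standard_normal((reps, P, T))
        px = prime - prime.mean(axis=2, keepdims=True)
        py = probe - probe.mean(axis=2, keepdims=True)
        r = (px * py).sum(axis=2) / np.sqrt(
            (px ** 2).sum(axis=2) * (py ** 2).sum(axis=2))
        z[cond] = np.arctanh(np.clip(r, -1 + 1e-12, 1 - 1e-12))
    d = z["c"] - z["i"]                       # (reps, P)
    tstat = d.mean(axis=1) / (d.std(axis=1, ddof=1) / math.sqrt(P))
    pvals = 2.0 * sps.t.sf(np.abs(tstat), P - 1)
    return pvals, np.abs(tstat) / math.sqrt(P)


@dataclass
class RecoveryCell:
    lambda_c: float
    lambda_i: float
    n_participants: int
    reps: int
    rejection_rate: float
    mc_se: float
    mean_dz: float
    seed: int


def recover(grid: Sequence[tuple[float, float]], reps: int, seed: int,
            n_participants: int = 19,
            design: Union[str, DesignSpec] = "exp1",
            population: Optional[PopulationSpec] = None,
            alpha: float = 0.05, level: str = "features",
            use_traces: bool = False) -> pd.DataFrame:
    """Rejection-rate table of the duration-correlation congruency test over
    a (λ_congruent, λ_incongruent) grid; a null row (λ_c = λ_i) is always
    included.

    ``level="features"`` draws trial features directly from the generative
    model (vectorized; trace rendering and detection — which recover the
    features deterministically — are exercised elsewhere); ``level="pipeline"``
    runs the full per-replicate pipeline and is meant for small ``reps``.
    """
    if not grid:
        raise ConfigurationError("recovery grid must be non-empty")
    if reps < 1:
        raise ConfigurationError("reps must be >= 1")
    grid = list(grid)
    if not any(lc == li for lc, li in grid):
        base = population.lambda_incongruent if population else 0.55
        grid.append((base, base))
    design_spec = design_preset(design) if isinstance(design, str) else design
    T = design_spec.n_congruent_per_block * design_spec.n_blocks
    pop = population or PopulationSpec()

    rows = []
    for cell_idx, (lc, li) in enumerate(grid):
        cell_seed = seed + 1000 * cell_idx
        if level == "features":
            rng = np.random.default_rng(np.random.SeedSequence((seed, cell_idx)))
            pvals, dzs = _corr_rejections_vectorized(
                lc, li, n_participants, T, reps, rng, alpha)
        elif level == "pipeline":
            pvals_l, dz_l = [], []
            for rep in range(reps):
                cfg = AnalysisConfig(
                    design=design_spec,
                    population=replace(pop, lambda_congruent=lc,
                                       lambda_incongruent=li),
                    n_participants=n_participants,
                    seed=cell_seed + rep, use_traces=use_traces,
                    dvs=("duration_ms",))
                bundle = run_analysis(cfg)
                res = bundle["tests"].get("duration_corr")
                if res is None:
                    continue
                pvals_l.append(res["p"])
                dz_l.append(res["dz"])
            pvals, dzs = np.asarray(pvals_l), np.asarray(dz_l)
        else:
            raise ConfigurationError(f"unknown recovery level {level!r}")
        rate = float(np.mean(pvals < alpha)) if pvals.size else np.nan
        se = (math.sqrt(rate * (1.0 - rate) / pvals.size)
              if pvals.size > 1 else np.nan)
        rows.append(RecoveryCell(
            lambda_c=lc, lambda_i=li, n_participants=n_participants,
            reps=int(pvals.size), rejection_rate=rate, mc_se=se,
            mean_dz=float(np.mean(dzs)) if dzs.size else np.nan,
            seed=cell_seed).__dict__)
    return pd.DataFrame(rows)
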