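"""End-to-end study pipeline: detection -> behavior -> spectra -> Granger -> stats.

Orchestrates the full analysis over a cohort of sessions (each rat runs a
baseline and a testing session under no-infusion, saline and muscimol),
applying the study's subject-inclusion rules: rats whose two LFP channels
were digitized at different rates are dropped from all LFP analyses, and
rats contributing fewer than two trials of a VTE class are reported as
missing for that class.  Control values collapse all sessions except
muscimol testing.  Every excluded subject carries a machine-readable
reason code in the run report.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior as bhv
from . import granger as gc
from . import lfp as sp
from . import stats as st
from .behavior import Condition, Epoch, TrialRecord
from .defaults import FREQ_GRID, MIN_TRIALS_PER_CLASS
from .synthetic import SyntheticSession
from .trajectory import IdPhiParams

__all__ = [
    "AnalysisParams",
    "RunReport",
    "detect_all",
    "collapse_controls",
    "analyze_cohort",
    "run_study",
]

CONTROL = "control"
MUSCIMOL_TESTING = "muscimol_testing"


@dataclass(frozen=True)
class AnalysisParams:
    """Pipeline-wide knobs, all defaulted to the study conventions."""

    idphi: IdPhiParams = field(default_factory=IdPhiParams)
    vte_threshold: float = 0.0
    zln_pooling: str = "study"           # study | rat | session
    clipping_threshold: float = 0.01
    min_trials_per_class: int = MIN_TRIALS_PER_CLASS
    #: LFP window starts this many seconds before choice-region entry (the
    #: choice-point box includes data immediately preceding entry)
    lfp_prepad_s: float = 0.33
    #: coherence segment length; 1 s keeps the estimator's resolution
    #: bandwidth identical across conditions with unequal trial counts
    coherence_segment_s: float = 1.0
    max_lag: int = 20
    #: samples per series used during BIC order selection (bounds runtime;
    #: the final fit always uses the full series)
    order_sel_samples: int = 6000
    control_pooling: str = "trials"      # trials | session_means


@dataclass
class RunReport:
    n_sessions: int = 0
    n_trials: int = 0
    stage_counts: dict = field(default_factory=dict)
    exclusions: list[dict] = field(default_factory=list)
    outputs: list[str] = field(default_factory=list)

    def exclude(self, rat: str, scope: str, code: str, detail: str = "") -> None:
        self.exclusions.append(
            {"rat_id": rat, "scope": scope, "reason_code": code, "detail": detail}
        )

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, default=str)


def _group_of(condition: Condition, epoch: Epoch) -> str:
    if condition == Condition.MUSCIMOL and epoch == Epoch.TESTING:
        return MUSCIMOL_TESTING
    return CONTROL


def detect_all(sessions: list[SyntheticSession], params: AnalysisParams) -> pd.DataFrame:
    """Run VTE detection on every session; one row per trial.

    With the default study-wide pooling, ln(IdPhi) is z-scored over every
    trial of every session at once (the distribution whose ballistic bulk
    tapers at 0).  Per-session pooling is available but mislabels about
    half the trials of a session that happens to contain no genuine
    deliberative pass, since the threshold is relative.
    """
    from .trajectory import classify_vte, extract_passes

    extracted = []
    for s in sessions:
        passes, sweeps = extract_passes(s.position, s.geometry, params.idphi,
                                        expected_trials=len(s.truth))
        extracted.append((s, passes, sweeps))

    if params.zln_pooling == "study":
        pools = {None: [(s, p, sw) for s, p, sw in extracted]}
    elif params.zln_pooling == "rat":
        pools = {}
        for s, p, sw in extracted:
            pools.setdefault(s.rat_id, []).append((s, p, sw))
    elif params.zln_pooling == "session":
        pools = {i: [item] for i, item in enumerate(extracted)}
    else:
        raise ValueError(f"unknown zln_pooling {params.zln_pooling!r}")

    labels_by_session: dict[int, list] = {}
    for group in pools.values():
        idphi = np.concatenate([[p.idphi for p in passes] for _, passes, _ in group])
        hs = np.concatenate([sw for _, _, sw in group]).astype(bool)
        qc = [p.qc_flags for _, passes, _ in group for p in passes]
        labels = classify_vte(idphi, head_sweep=hs,
                              threshold=params.vte_threshold, qc_flags=qc)
        offset = 0
        for s, passes, _ in group:
            labels_by_session[id(s)] = labels[offset : offset + len(passes)]
            offset += len(passes)

    rows = []
    for s, passes, _sweeps in extracted:
        labels = labels_by_session[id(s)]
        correct = bhv.score_alternation([p.exit_arm for p in passes])
        for p, lab, ok in zip(passes, labels, correct):
            rows.append({
                "rat_id": s.rat_id, "condition": s.condition.value,
                "epoch": s.epoch.value, "group": _group_of(s.condition, s.epoch),
                "trial_index": p.trial_index, "arm": p.exit_arm,
                "correct": bool(ok), "idphi": p.idphi,
                "zln_idphi": lab.zln_idphi, "is_vte_idphi": lab.is_vte_idphi,
                "is_head_sweep": lab.is_head_sweep, "is_vte": lab.is_vte,
                "time_spent": p.time_spent,
                "pass_start_s": float(p.timestamps[0]),
                "pass_end_s": float(p.timestamps[-1]),
                "qc_flags": ";".join(sorted(lab.qc_flags)),
            })
    return pd.DataFrame(rows)


def behavior_tables(trials: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Session summaries and per-rat condition contrasts.

    Returns (per-session summary, per-rat contrast table).  Contrasts:
    perseveration and turn-bias differences (testing - baseline, in raw
    percentage points: control sessions can have zero perseveration, so
    the normalized score is not always defined) per condition, and the
    normalized difference of VTE / non-VTE overlap with perseverative
    error sequences between muscimol testing and pooled controls.
    """
    summaries = []
    for (rat, cond, epoch), g in trials.groupby(["rat_id", "condition", "epoch"]):
        g = g.sort_values("trial_index")
        recs = [TrialRecord(int(r.trial_index), r.arm, bool(r.correct), bool(r.is_vte),
                            Epoch(epoch), Condition(cond))
                for r in g.itertuples()]
        summ = bhv.summarize_session(recs)
        summaries.append({
            "rat_id": rat, "condition": cond, "epoch": epoch,
            "pct_correct": summ.pct_correct_overall,
            "pct_correct_vte": summ.pct_correct_vte,
            "pct_correct_nonvte": summ.pct_correct_nonvte,
            "perseveration": summ.perseveration_score,
            "turn_bias": summ.turn_bias,
            "n_trials": summ.n_trials, "n_vte": summ.n_vte,
        })
    summary = pd.DataFrame(summaries)

    contrasts = []
    for rat, g in summary.groupby("rat_id"):
        row: dict = {"rat_id": rat}
        for cond in ("no_infusion", "saline", "muscimol"):
            base = g[(g.condition == cond) & (g.epoch == "baseline")]
            test = g[(g.condition == cond) & (g.epoch == "testing")]
            if len(base) == 1 and len(test) == 1:
                row[f"persev_diff_{cond}"] = float(test.perseveration.iloc[0]
                                                   - base.perseveration.iloc[0])
                row[f"turnbias_diff_{cond}"] = float(test.turn_bias.iloc[0]
                                                     - base.turn_bias.iloc[0])
        # VTE overlap with perseverative error sequences, muscimol vs controls
        rat_trials = trials[trials.rat_id == rat]
        overlap = {}
        for group in (CONTROL, MUSCIMOL_TESTING):
            sub = rat_trials[rat_trials.group == group].sort_values(
                ["condition", "epoch", "trial_index"])
            per_session = []
            for (_c, _e), sess in sub.groupby(["condition", "epoch"]):
                recs = [TrialRecord(int(r.trial_index), r.arm, bool(r.correct),
                                    bool(r.is_vte)) for r in sess.itertuples()]
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    per_session.append(bhv.vte_error_overlap(recs))
            vals = [o["vte"] for o in per_session if o["vte"] is not None]
            overlap[group] = float(np.mean(vals)) if vals else None
        if overlap[CONTROL] is not None and overlap[MUSCIMOL_TESTING] is not None:
            total = overlap[MUSCIMOL_TESTING] + overlap[CONTROL]
            if total > 0:
                row["vte_overlap_normdiff"] = bhv.norm_diff(
                    overlap[MUSCIMOL_TESTING], overlap[CONTROL])
        contrasts.append(row)
    return summary, pd.DataFrame(contrasts)


def collapse_controls(
    values: pd.DataFrame,
    value_col: str,
    mode: str = "trials",
) -> pd.Series:
    """Pool all non-(muscimol, testing) rows into one control value per rat.

    ``mode='trials'`` pools rows (trials) directly; ``'session_means'``
    first averages within each session, then across sessions.
    """
    ctl = values[values.apply(
        lambda r: _group_of(Condition(r.condition), Epoch(r.epoch)) == CONTROL, axis=1)]
    if ctl.empty:
        raise ValueError("no control data present")
    if mode == "trials":
        return ctl.groupby("rat_id")[value_col].mean()
    if mode == "session_means":
        per_sess = ctl.groupby(["rat_id", "condition", "epoch"])[value_col].mean()
        return per_sess.groupby("rat_id").mean()
    raise ValueError(f"unknown pooling mode {mode!r}")


def _segment_sets(
    session: SyntheticSession, session_trials: pd.DataFrame, params: AnalysisParams
) -> sp.LfpSegmentSet:
    """Cut choice-point LFP windows for one session and screen clipping."""
    fs = session.lfp_rate
    segments: dict[int, dict[str, np.ndarray]] = {}
    is_vte: dict[int, bool] = {}
    for r in session_trials.itertuples():
        a = max(int((r.pass_start_s - params.lfp_prepad_s) * fs), 0)
        b = int(np.ceil(r.pass_end_s * fs))
        segments[int(r.trial_index)] = {
            "mPFC": session.lfp_mpfc[a:b], "dHPC": session.lfp_hpc[a:b],
        }
        is_vte[int(r.trial_index)] = bool(r.is_vte)
    segset = sp.LfpSegmentSet(sampling_rate=fs, segments=segments, is_vte=is_vte)
    return sp.exclude_clipped_trials(segset, threshold=params.clipping_threshold)


def lfp_stage(
    sessions: list[SyntheticSession],
    trials: pd.DataFrame,
    params: AnalysisParams,
    report: RunReport,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Coherence and Granger estimates per rat, group and VTE class.

    Rats with mismatched channel sampling rates are excluded from all LFP
    analyses; rat/group/class cells with fewer than the minimum retained
    trials are missing.  Returns (theta summary table, coherence spectra
    table).
    """
    bad_rate_rats = {s.rat_id for s in sessions if s.lfp_rate != s.lfp_rate_hpc}
    for rat in sorted(bad_rate_rats):
        report.exclude(rat, "lfp", "mismatched_sampling_rates")

    # gather retained per-trial segments grouped by rat/group/class
    store: dict[tuple[str, str, bool], list[dict[str, np.ndarray]]] = {}
    time_spent: dict[tuple[str, str, bool], list[float]] = {}
    rates: dict[str, float] = {}
    for s in sessions:
        if s.rat_id in bad_rate_rats:
            continue
        rates[s.rat_id] = s.lfp_rate
        st_mask = (
            (trials.rat_id == s.rat_id)
            & (trials.condition == s.condition.value)
            & (trials.epoch == s.epoch.value)
        )
        sess_trials = trials[st_mask]
        segset = _segment_sets(s, sess_trials, params)
        group = _group_of(s.condition, s.epoch)
        for t in segset.trial_ids():
            key = (s.rat_id, group, segset.is_vte[t])
            store.setdefault(key, []).append(segset.segments[t])
            ts = sess_trials[sess_trials.trial_index == t].time_spent.iloc[0]
            time_spent.setdefault(key, []).append(float(ts))

    theta_rows = []
    spectra_rows = []
    for (rat, group, vte), segs in sorted(store.items(), key=lambda kv: kv[0][:2]):
        if len(segs) < params.min_trials_per_class:
            report.exclude(rat, f"lfp_{group}_{'vte' if vte else 'nonvte'}",
                           "insufficient_trials", f"{len(segs)} trials")
            continue
        fs = rates[rat]
        x = np.concatenate([d["mPFC"] for d in segs])
        y = np.concatenate([d["dHPC"] for d in segs])
        coh = sp.coherence(x, y, fs, grid=FREQ_GRID,
                           segment_seconds=params.coherence_segment_s)
        coh_n = sp.normalize_over_frequencies(coh)
        theta_coh = sp.theta_band_mean(coh_n)
        theta_power = {}
        for region, sig in (("mpfc", x), ("hpc", y)):
            try:
                ps = sp.power_spectrum(sig, fs)
                grid_ps = sp.SpectralResult(
                    FREQ_GRID, np.interp(FREQ_GRID, ps.frequencies, ps.values),
                    kind="log_power")
                theta_power[region] = sp.theta_band_mean(grid_ps)
            except ValueError:
                theta_power[region] = np.nan

        order = _select_order_bounded(x, y, params)
        fit = gc.fit_var(x, y, order, sampling_rate=fs)
        spec = gc.spectral_gc(fit, grid=FREQ_GRID, sampling_rate=fs)
        gx = float(np.mean(spec.gc_x_to_y[_theta_idx()]))
        gy = float(np.mean(spec.gc_y_to_x[_theta_idx()]))

        theta_rows.append({
            "rat_id": rat, "group": group, "class": "vte" if vte else "nonvte",
            "theta_coherence_norm": theta_coh,
            "theta_logpower_mpfc": theta_power["mpfc"],
            "theta_logpower_hpc": theta_power["hpc"],
            "gc_mpfc_to_hpc": gx, "gc_hpc_to_mpfc": gy,
            "order_used": order,
            "mean_time_spent": float(np.mean(time_spent[(rat, group, vte)])),
            "n_trials": len(segs),
        })
        for f, c, cn in zip(coh.frequencies, coh.values, coh_n.values):
            spectra_rows.append({
                "rat_id": rat, "group": group,
                "class": "vte" if vte else "nonvte",
                "frequency": float(f), "coherence": float(c),
                "coherence_norm": float(cn),
            })
    return pd.DataFrame(theta_rows), pd.DataFrame(spectra_rows)


def _theta_idx() -> np.ndarray:
    from .defaults import theta_mask

    return theta_mask(FREQ_GRID)


def _select_order_bounded(x: np.ndarray, y: np.ndarray, params: AnalysisParams) -> int:
    n = min(len(x), params.order_sel_samples)
    max_lag = min(params.max_lag, (n - 2) // 10)
    if max_lag < 1:
        return 1
    sel = gc.select_order([(x[:n], y[:n])], max_lag=max_lag)
    return sel.global_order


def stats_stage(
    contrasts: pd.DataFrame, theta: pd.DataFrame, report: RunReport
) -> pd.DataFrame:
    """The study's statistical battery over the pipeline tables."""
    rows = []

    def add(analysis: str, **kw) -> None:
        rows.append({"analysis": analysis, **kw})

    # perseveration / turn-bias differences across the three conditions
    for metric in ("persev_diff", "turnbias_diff"):
        cols = [f"{metric}_{c}" for c in ("no_infusion", "saline", "muscimol")]
        if all(c in contrasts.columns for c in cols):
            mat = contrasts[cols].to_numpy(dtype=float)
            try:
                res = st.rm_anova_oneway(mat)
                add(f"{metric}_rm_anova", statistic=res.f_stat, df1=res.df_effect,
                    df2=res.df_error, p_raw=res.p_raw, p_corrected=res.p_gg,
                    epsilon=res.gg_epsilon, n=res.n_subjects)
            except ValueError as err:
                report.exclude("-", f"stats_{metric}", "anova_failed", str(err))
            for cond in ("no_infusion", "saline", "muscimol"):
                vals = contrasts[f"{metric}_{cond}"].dropna().to_numpy(dtype=float)
                if len(vals) >= 2 and vals.std(ddof=1) > 0:
                    t = st.t_tests(vals, mode="one_sample", comparisons=3)
                    add(f"{metric}_{cond}_vs0", statistic=t.t_stat, df1=t.df,
                        p_raw=t.p_raw, p_corrected=t.p_bonferroni,
                        ci_low=t.ci_low, ci_high=t.ci_high, effect=t.cohen_d, n=t.n)

    # VTE overlap normalized difference vs 0
    if "vte_overlap_normdiff" in contrasts.columns:
        vals = contrasts["vte_overlap_normdiff"].dropna().to_numpy(dtype=float)
        if len(vals) >= 2 and vals.std(ddof=1) > 0:
            t = st.t_tests(vals, mode="one_sample", comparisons=2)
            add("vte_overlap_normdiff_vs0", statistic=t.t_stat, df1=t.df,
                p_raw=t.p_raw, p_corrected=t.p_bonferroni,
                ci_low=t.ci_low, ci_high=t.ci_high, effect=t.cohen_d, n=t.n)

    # theta coherence: paired t per class, two comparisons -> alpha 0.025
    for cls in ("vte", "nonvte"):
        sub = theta[theta["class"] == cls].pivot_table(
            index="rat_id", columns="group", values="theta_coherence_norm")
        if {CONTROL, MUSCIMOL_TESTING} <= set(sub.columns):
            paired = sub.dropna()
            if len(paired) >= 2:
                t = st.t_tests(paired[CONTROL].to_numpy(),
                               paired[MUSCIMOL_TESTING].to_numpy(),
                               mode="paired", comparisons=2)
                add(f"theta_coherence_{cls}_paired", statistic=t.t_stat, df1=t.df,
                    p_raw=t.p_raw, p_corrected=t.p_bonferroni,
                    ci_low=t.ci_low, ci_high=t.ci_high, effect=t.cohen_d, n=t.n)

    # Granger normalized difference scores vs 0, per direction and class
    for cls in ("vte", "nonvte"):
        for col, direction in (("gc_mpfc_to_hpc", "mpfc_to_hpc"),
                               ("gc_hpc_to_mpfc", "hpc_to_mpfc")):
            sub = theta[theta["class"] == cls].pivot_table(
                index="rat_id", columns="group", values=col).dropna()
            if {CONTROL, MUSCIMOL_TESTING} <= set(sub.columns) and len(sub) >= 2:
                scores = np.array([
                    bhv.norm_diff(m, c) for m, c in
                    zip(sub[MUSCIMOL_TESTING], sub[CONTROL])
                    if m + c > 0
                ])
                if len(scores) >= 2 and scores.std(ddof=1) > 0:
                    t = st.t_tests(scores, mode="one_sample", comparisons=3)
                    add(f"granger_{direction}_{cls}_normdiff_vs0",
                        statistic=t.t_stat, df1=t.df, p_raw=t.p_raw,
                        p_corrected=t.p_bonferroni, ci_low=t.ci_low,
                        ci_high=t.ci_high, effect=t.cohen_d, n=t.n,
                        mean_score=float(scores.mean()))

    # time spent vs theta coherence during VTEs
    vte = theta[theta["class"] == "vte"]
    for label, sub in (("all", vte),
                       ("muscimol", vte[vte.group == MUSCIMOL_TESTING]),
                       ("control", vte[vte.group == CONTROL])):
        if len(sub) >= 3:
            for log_flag, suffix in ((False, ""), (True, "_logtime")):
                try:
                    r, p = st.pearson_r(sub["mean_time_spent"].to_numpy(),
                                        sub["theta_coherence_norm"].to_numpy(),
                                        log_x=log_flag)
                    add(f"timespent_coherence_{label}{suffix}", statistic=r,
                        p_raw=p, n=len(sub))
                except ValueError:
                    pass
    return pd.DataFrame(rows)


def analyze_cohort(
    sessions: list[SyntheticSession],
    params: AnalysisParams | None = None,
    out_dir: str | Path | None = None,
) -> dict:
    """Run every stage over in-memory sessions; optionally write the tables.

    Returns a dict with keys ``trials``, ``summary``, ``contrasts``,
    ``theta``, ``spectra``, ``stats`` (DataFrames) and ``report``.
    """
    params = params or AnalysisParams()
    report = RunReport(n_sessions=len(sessions))

    # rats contributing < 2 VTE trials overall are dropped from VTE analyses
    trials = detect_all(sessions, params)
    report.n_trials = len(trials)
    report.stage_counts["detect"] = len(trials)

    vte_counts = trials[trials.is_vte].groupby("rat_id").size()
    sparse = [r for r in trials.rat_id.unique()
              if vte_counts.get(r, 0) < params.min_trials_per_class]
    for rat in sparse:
        report.exclude(rat, "vte_analyses", "insufficient_vte_trials",
                       f"{int(vte_counts.get(rat, 0))} VTE trials")

    summary, contrasts = behavior_tables(trials)
    report.stage_counts["behavior_sessions"] = len(summary)

    # sparse-VTE rats stay in the LFP stage: their VTE cells fall below the
    # per-cell trial minimum on their own, while their non-VTE data is kept
    theta, spectra = lfp_stage(sessions, trials, params, report)
    report.stage_counts["lfp_cells"] = len(theta)

    stats_table = stats_stage(contrasts, theta, report)
    report.stage_counts["stats_rows"] = len(stats_table)

    out = {"trials": trials, "summary": summary, "contrasts": contrasts,
           "theta": theta, "spectra": spectra, "stats": stats_table,
           "report": report}
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for name in ("trials", "summary", "contrasts", "theta", "spectra", "stats"):
            path = out_dir / f"{name}.tsv"
            out[name].to_csv(path, sep="\t", index=False)
            report.outputs.append(str(path))
        with open(out_dir / "run_report.json", "w") as fh:
            fh.write(report.to_json())
        report.outputs.append(str(out_dir / "run_report.json"))
    return out


def run_study(config: dict, out_dir: str | Path) -> dict:
    """Execute the full study from a configuration mapping.

    ``config`` either names a cohort directory to load
    (``{"cohort_dir": ...}``) or asks for simulation
    (``{"simulate": {"n_rats": 7, "seed": 1, ...}}``).  Analysis
    parameters may be overridden under ``"analysis"``.
    """
    from .io import load_cohort
    from .synthetic import simulate_cohort

    if "cohort_dir" in config:
        sessions = load_cohort(config["cohort_dir"])
    elif "simulate" in config:
        sessions = simulate_cohort(**config["simulate"])
    else:
        raise ValueError("config must provide 'cohort_dir' or 'simulate'")
    akw = config.get("analysis", {})
    idphi = IdPhiParams(**akw.pop("idphi", {}))
    params = AnalysisParams(idphi=idphi, **akw)
    return analyze_cohort(sessions, params, out_dir=out_dir)
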