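"""Tidy metric tables and figure-style reports over analyzed trials.

``metrics_frame`` flattens per-game analyzer outputs into one long
DataFrame (one row per scored unit: item, attempt, shape, trial or mode),
which downstream feeds the speed-accuracy group report, the per-mode
bimanual summary table, and the plots.
"""

from __future__ import annotations

import warnings

import matplotlib
import numpy as np
import pandas as pd

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from . import bimanual, fine_motor, whole_limb  # noqa: E402
from .data_model import TrialRecord, validate_trial  # noqa: E402
from .errors import GamekinError, SchemaError  # noqa: E402
from .summary_stats import speed_accuracy_report  # noqa: E402

_BASE_COLS = ["trial_id", "game", "hand", "age_years", "unit",
              "completion_s", "error"]


def trial_metrics_rows(trial: TrialRecord) -> list[dict]:
    """Score one trial with its game's analyzer; one dict per scored unit."""
    base = {"trial_id": trial.trial_id, "game": trial.game,
            "hand": trial.hand, "age_years": trial.age_years}
    rows: list[dict] = []
    if trial.game == "market":
        for m in whole_limb.analyze_market(trial):
            rows.append({**base, "unit": m.item_id,
                         "completion_s": m.completion_s, "error": m.rmse_mm,
                         "rmse_mm": m.rmse_mm, "placed_ok": m.placed_ok})
    elif trial.game == "race":
        for m in whole_limb.analyze_race(trial):
            rows.append({**base, "unit": m.attempt_id,
                         "completion_s": m.completion_s, "error": m.rmse_mm,
                         "rmse_mm": m.rmse_mm,
                         "shortcut_error": m.shortcut_error,
                         "n_segments": m.segmentation.n_segments})
    elif trial.game == "filling":
        for m in fine_motor.analyze_filling(trial):
            rows.append({**base, "unit": m.shape_id,
                         "completion_s": m.completion_s,
                         "error": m.outside_pct,
                         "inside_pct": m.inside_pct,
                         "outside_pct": m.outside_pct,
                         "coverage_pct": m.coverage_pct})
    elif trial.game == "message":
        m = fine_motor.score_message(trial)
        dur = max(trial.duration_s, 1e-9)
        rows.append({**base, "unit": "trial",
                     "completion_s": trial.duration_s,
                     "error": m.errors_total / dur,
                     "taps_total": m.taps_total,
                     "errors_total": m.errors_total,
                     "tap_rate": m.taps_total / dur,
                     "chars_revealed": m.chars_revealed,
                     "displacements": m.displacements,
                     "fixed_path_len_mm": m.fixed_path_len_mm})
    elif trial.game == "round":
        s = bimanual.coordination_summary(trial)
        rows.append({**base, "unit": s.mode, "mode": s.mode,
                     "completion_s": trial.duration_s,
                     "error": s.phase_mean_deg,
                     "phase_mean_deg": s.phase_mean_deg,
                     "phase_sd_deg": s.phase_sd_deg,
                     "phase_ci_lo": s.phase_ci95[0],
                     "phase_ci_hi": s.phase_ci95[1],
                     "omega_right_mean": s.omega_right.mean,
                     "omega_right_sd": s.omega_right.sd,
                     "omega_left_mean": s.omega_left.mean,
                     "omega_left_sd": s.omega_left.sd,
                     "omega_diff_mean": s.omega_diff.mean,
                     "omega_diff_sd": s.omega_diff.sd,
                     "travel_left_m": s.travel_m["left"],
                     "travel_right_m": s.travel_m["right"]})
    else:
        raise SchemaError(f"unknown game {trial.game!r}")
    return rows


def metrics_frame(trials: list[TrialRecord],
                  skip_invalid: bool = True) -> tuple[pd.DataFrame, list[str]]:
    """Validate + analyze trials; returns (long metrics table, issue log)."""
    rows, issues = [], []
    for trial in trials:
        report = validate_trial(trial)
        if not report.ok:
            issues.extend(f"{trial.trial_id}: {c}: {m}" for c, m in report.issues)
            if skip_invalid:
                continue
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                rows.extend(trial_metrics_rows(trial))
        except GamekinError as exc:
            issues.append(f"{trial.trial_id}: analyzer failed: {exc}")
    df = pd.DataFrame(rows, columns=None if rows else _BASE_COLS)
    return df, issues


def group_report(df: pd.DataFrame) -> pd.DataFrame:
    """Speed-accuracy and age-trend correlations per game."""
    parts = []
    if len(df):
        parts.append(speed_accuracy_report(df, group_by="game"))
        if df["age_years"].notna().any():
            parts.append(speed_accuracy_report(
                df[df["age_years"].notna()], group_by="age"))
    return pd.concat(parts, ignore_index=True) if parts else pd.DataFrame()


_MODE_ORDER = ["in_phase_congruent", "in_phase_mirrored",
               "antiphase_congruent", "antiphase_mirrored"]


def bimanual_mode_table(df: pd.DataFrame) -> pd.DataFrame:
    """Per-mode phase/speed synchronization summary (one row per mode)."""
    sub = df[df["game"] == "round"]
    rows = []
    for mode in _MODE_ORDER:
        m = sub[sub["mode"] == mode]
        if not len(m):
            continue
        rows.append({
            "mode": mode,
            "phase_sd_deg": m["phase_sd_deg"].mean(),
            "phase_mean_deg": m["phase_mean_deg"].mean(),
            "omega_right_sd": m["omega_right_sd"].mean(),
            "omega_right_mean": m["omega_right_mean"].mean(),
            "omega_left_sd": m["omega_left_sd"].mean(),
            "omega_left_mean": m["omega_left_mean"].mean(),
            "omega_diff_sd": m["omega_diff_sd"].mean(),
            "omega_diff_mean": m["omega_diff_mean"].mean(),
            "travel_left_m": m["travel_left_m"].mean(),
            "travel_right_m": m["travel_right_m"].mean(),
            "n_trials": len(m),
        })
    return pd.DataFrame(rows)


def plot_speed_accuracy(df: pd.DataFrame, out_path) -> None:
    """Scatter of completion time vs error per game, with exponential fit."""
    from .summary_stats import PairedSample, fit_exponential

    games = [g for g in df["game"].unique()
             if df[df["game"] == g]["error"].notna().sum() >= 3]
    fig, axes = plt.subplots(1, max(len(games), 1),
                             figsize=(4 * max(len(games), 1), 3.5),
                             squeeze=False)
    for ax, game in zip(axes[0], games):
        sub = df[df["game"] == game].dropna(subset=["completion_s", "error"])
        x, y = sub["completion_s"].to_numpy(), sub["error"].to_numpy()
        ax.scatter(x, y, s=18, alpha=0.7)
        if len(x) >= 3 and np.all(y > 0) and np.std(x) > 0:
            fit = fit_exponential(PairedSample(x, y))
            xx = np.linspace(x.min(), x.max(), 100)
            ax.plot(xx, fit.a * np.exp(fit.b * xx), "r-", lw=1.5)
        ax.set_xlabel("completion time (s)")
        ax.set_ylabel("error")
        ax.set_title(game)
    fig.tight_layout()
    fig.savefig(out_path, dpi=110)
    plt.close(fig)


def plot_phase_by_mode(df: pd.DataFrame, out_path) -> None:
    """Bar plot of mean |phase difference| per bimanual mode."""
    table = bimanual_mode_table(df)
    fig, ax = plt.subplots(figsize=(5, 3.5))
    if len(table):
        ax.bar(table["mode"], table["phase_mean_deg"],
               yerr=table["phase_sd_deg"], capsize=3)
        ax.set_ylabel("|phase difference| (deg)")
        ax.tick_params(axis="x", rotation=30)
    fig.tight_layout()
    fig.savefig(out_path, dpi=110)
    plt.close(fig)
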