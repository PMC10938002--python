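"""Per-trial scalar features and condition averages from processed traces.

Conventions: windows are half-open ``[start, end)`` on the down-sampled
grid; peak constriction is the signed minimum of the corrected trace (more
negative = stronger constriction); the pre-test level is the mean of the
bins just before test onset.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .preprocess import TRIAL_LABELS

PEAK_WINDOW = (0.3, 1.3)  # s after test onset
PRETEST_WINDOW = (-0.2, 0.0)  # s before test onset


def _window_mask(t_rel: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    lo, hi = window
    return (t_rel >= lo - 1e-9) & (t_rel < hi - 1e-9)


def peak_constriction(trace: pd.DataFrame) -> float:
    """Minimum corrected value over valid bins in the peak window (NaN if none)."""
    m = _window_mask(trace["t_rel"].to_numpy(float), PEAK_WINDOW)
    vals = trace["z"].to_numpy(float)[m]
    vals = vals[np.isfinite(vals)]
    return float(np.min(vals)) if vals.size else float("nan")


def pretest_pupil(trace: pd.DataFrame) -> float:
    """Mean corrected value over valid bins in the pre-test window (NaN if none)."""
    m = _window_mask(trace["t_rel"].to_numpy(float), PRETEST_WINDOW)
    vals = trace["z"].to_numpy(float)[m]
    vals = vals[np.isfinite(vals)]
    return float(np.mean(vals)) if vals.size else float("nan")


def luminance_label(experiment: np.ndarray, numerosity: np.ndarray) -> np.ndarray:
    """Realized-luminance grouping: one level per numerosity in experiment 2
    (where diameter jitter perturbs total area), a single level otherwise."""
    experiment = np.asarray(experiment)
    numerosity = np.asarray(numerosity)
    return np.where(
        experiment == 2, np.char.add("exp2-N", numerosity.astype(str)), "exp1"
    )


def extract_features(trials: pd.DataFrame) -> pd.DataFrame:
    """One row of features per processed trial (test-aligned traces only)."""
    test = trials[trials["align"] == "test"]
    rows = []
    for labels, trace in test.groupby(TRIAL_LABELS, sort=False):
        t_rel = trace["t_rel"].to_numpy(float)
        z = trace["z"].to_numpy(float)
        peak_m = _window_mask(t_rel, PEAK_WINDOW) & np.isfinite(z)
        row = dict(zip(TRIAL_LABELS, labels))
        row["peak_constriction"] = float(z[peak_m].min()) if peak_m.any() else np.nan
        pre_m = _window_mask(t_rel, PRETEST_WINDOW) & np.isfinite(z)
        row["pretest_pupil"] = float(z[pre_m].mean()) if pre_m.any() else np.nan
        row["n_valid_bins_in_peak_window"] = int(peak_m.sum())
        rows.append(row)
    out = pd.DataFrame(rows)
    if not out.empty:
        out["luminance"] = luminance_label(out["experiment"], out["numerosity"])
    return out


def condition_average_traces(
    trials: pd.DataFrame, align: str = "test", by_numerosity: bool = True
) -> pd.DataFrame:
    """Mean trace per condition (x numerosity), with SEM across participants.

    Trials are first averaged within participant, then across participants,
    so the SEM reflects between-participant variability; missing bins are
    skipped at every level.
    """
    sel = trials[trials["align"] == align]
    keys = ["condition"] + (["numerosity"] if by_numerosity else [])
    per_p = (
        sel.groupby(keys + ["participant_id", "t_idx", "t_rel"], sort=True)["z"]
        .mean()
        .reset_index()
    )
    agg = per_p.groupby(keys + ["t_idx", "t_rel"], sort=True)["z"].agg(
        ["mean", "sem", "count"]
    )
    return agg.reset_index().rename(
        columns={"mean": "z_mean", "sem": "z_sem", "count": "n_participants"}
    )


def condition_peaks(avg_traces: pd.DataFrame) -> pd.DataFrame:
    """Window peak of each condition(-x-numerosity) average trace."""
    keys = [c for c in ("condition", "numerosity") if c in avg_traces.columns]
    rows = []
    for labels, grp in avg_traces.groupby(keys, sort=True):
        m = _window_mask(grp["t_rel"].to_numpy(float), PEAK_WINDOW)
        vals = grp["z_mean"].to_numpy(float)[m]
        vals = vals[np.isfinite(vals)]
        labels = labels if isinstance(labels, tuple) else (labels,)
        rows.append(
            dict(zip(keys, labels), peak=float(np.min(vals)) if vals.size else np.nan)
        )
    return pd.DataFrame(rows)


def adaptation_effect_pupil(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-participant pupil adaptation effect.

    Test-locked traces are averaged across numerosities within each
    condition; the effect is the window peak after adapt-high minus after
    adapt-low (positive = weaker constriction after adapt-high).
    Participants missing a condition are dropped.
    """
    test = trials[trials["align"] == "test"]
    rows = []
    for pid, grp in test.groupby("participant_id", sort=True):
        peaks = {}
        for condition, sub in grp.groupby("condition"):
            mean_trace = (
                sub.groupby(["t_idx", "t_rel"], sort=True)["z"].mean().reset_index()
            )
            m = _window_mask(mean_trace["t_rel"].to_numpy(float), PEAK_WINDOW)
            vals = mean_trace["z"].to_numpy(float)[m]
            vals = vals[np.isfinite(vals)]
            if vals.size:
                peaks[condition] = float(np.min(vals))
        if {"high", "low"} <= set(peaks):
            rows.append(
                {
                    "participant_id": pid,
                    "pupil_effect": peaks["high"] - peaks["low"],
                }
            )
    return pd.DataFrame(rows)


def adaptation_effect_behavior(
    estimates: pd.DataFrame, numerosity: int = 40
) -> pd.DataFrame:
    """Per-participant behavioural adaptation effect at the highest test
    numerosity: mean estimate after adapt-low minus after adapt-high
    (positive = stronger underestimation after adapt-high)."""
    sel = estimates[estimates["numerosity"] == numerosity]
    rows = []
    for pid, grp in sel.groupby("participant_id", sort=True):
        means = grp.groupby("condition")["estimate"].mean()
        if {"high", "low"} <= set(means.index):
            rows.append(
                {
                    "participant_id": pid,
                    "behavior_effect": float(means["low"] - means["high"]),
                }
            )
    return pd.DataFrame(rows)
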