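"""Cleaning of raw pupil sample streams into event-locked, normalized traces.

Stage order is fixed: sample-level artifact flagging -> saccade-based trial
exclusion -> down-sampling to a coarse grid -> per-participant z-scoring ->
per-trial baseline correction.  Flagged samples are excluded (never
interpolated) and can therefore never contribute to a bin mean, a z
statistic or a baseline median.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .simulate import RawSession

TRIAL_LABELS = ["participant_id", "experiment", "session", "condition", "trial", "numerosity"]

# Event-locked segment extents on the down-sampled grid (seconds rel. onset).
TEST_SEGMENT = (-0.7, 2.5)
ADAPTER_SEGMENT = (-0.5, 3.0)


class DegenerateInputError(ValueError):
    """Input has no variance / too few valid points for normalization."""


@dataclass(frozen=True)
class CleaningParams:
    """Artifact thresholds and resampling parameters."""

    min_pupil_mm: float = 1.0
    max_rate_mm_per_s: float = 25.0
    saccade_amp_deg: float = 1.0
    saccade_min_run: int = 3
    blink_margin_s: float = 0.1
    out_rate_hz: int = 20
    baseline_halfwidth_s: float = 0.2

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            if getattr(self, f.name) <= 0:
                raise ValueError(f"{f.name} must be positive")

    def replace(self, **changes) -> "CleaningParams":
        return dataclasses.replace(self, **changes)


def _runs(flag: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) index runs where ``flag`` is True."""
    if flag.size == 0:
        return []
    d = np.diff(flag.astype(np.int8))
    starts = list(np.where(d == 1)[0] + 1)
    stops = list(np.where(d == -1)[0] + 1)
    if flag[0]:
        starts.insert(0, 0)
    if flag[-1]:
        stops.append(flag.size)
    return list(zip(starts, stops))


def flag_invalid_samples(
    samples: pd.DataFrame, params: CleaningParams = CleaningParams()
) -> tuple[np.ndarray, np.ndarray]:
    """Validity mask plus merged artifact intervals for one sample stream.

    A sample is invalid when its pupil is below the plausibility floor
    (blinks/dropouts, dilated by ``blink_margin_s`` on each side to cover
    corrupted blink edges) or when the absolute pupil rate of change between
    adjacent surviving samples exceeds ``max_rate_mm_per_s`` (both samples of
    the offending pair are flagged).

    Returns ``(mask, intervals)`` with ``mask`` True for valid samples and
    ``intervals`` an ``(m, 2)`` array of merged [start, stop) times.
    """
    t = samples["t_s"].to_numpy(dtype=float)
    p = samples["pupil_mm"].to_numpy(dtype=float)
    n = len(t)
    if n == 0:
        return np.zeros(0, dtype=bool), np.zeros((0, 2))

    low = p < params.min_pupil_mm
    bad = low.copy()
    if n > 1:
        dt_med = float(np.median(np.diff(t)))
        margin = int(round(params.blink_margin_s / dt_med)) if dt_med > 0 else 0
        for start, stop in _runs(low):
            bad[max(0, start - margin) : min(n, stop + margin)] = True

        keep_idx = np.where(~bad)[0]
        if keep_idx.size > 1:
            dp = np.abs(np.diff(p[keep_idx]))
            dt = np.diff(t[keep_idx])
            fast = np.zeros(keep_idx.size - 1, dtype=bool)
            pos = dt > 0
            fast[pos] = dp[pos] / dt[pos] > params.max_rate_mm_per_s
            bad[keep_idx[:-1][fast]] = True
            bad[keep_idx[1:][fast]] = True

    step = float(np.median(np.diff(t))) if n > 1 else 0.0
    intervals = np.array(
        [(t[a], t[b - 1] + step) for a, b in _runs(bad)], dtype=float
    ).reshape(-1, 2)
    return ~bad, intervals


def trial_epochs(events: pd.DataFrame) -> pd.DataFrame:
    """Per-trial [topup_start, trial_end) epochs from an event log."""
    ev = events[events["trial"] > 0]
    wide = ev.pivot_table(index="trial", columns="event", values="t_s")
    for name in ("topup_start", "trial_end", "test_on"):
        if name not in wide.columns:
            raise ValueError(f"event log lacks {name!r} events")
    out = wide[["topup_start", "test_on", "trial_end"]].reset_index()
    return out.sort_values("trial").reset_index(drop=True)


def exclude_saccade_trials(
    samples: pd.DataFrame,
    events: pd.DataFrame,
    params: CleaningParams = CleaningParams(),
) -> pd.DataFrame:
    """Keep/drop decision per trial based on gaze excursions.

    A trial is dropped when gaze strays more than ``saccade_amp_deg`` from
    the trial's median fixation for at least ``saccade_min_run`` consecutive
    samples anywhere inside the trial epoch.
    """
    if "gaze_x_deg" not in samples.columns or "gaze_y_deg" not in samples.columns:
        raise ValueError("samples lack gaze channels")
    t = samples["t_s"].to_numpy(dtype=float)
    gx = samples["gaze_x_deg"].to_numpy(dtype=float)
    gy = samples["gaze_y_deg"].to_numpy(dtype=float)
    rows = []
    for _, ep in trial_epochs(events).iterrows():
        sel = (t >= ep["topup_start"]) & (t < ep["trial_end"])
        x, y = gx[sel], gy[sel]
        if x.size == 0:
            rows.append((int(ep["trial"]), False, "no_samples", np.nan))
            continue
        dist = np.hypot(x - np.median(x), y - np.median(y))
        over = dist > params.saccade_amp_deg
        has_saccade = any(
            stop - start >= params.saccade_min_run for start, stop in _runs(over)
        )
        rows.append(
            (
                int(ep["trial"]),
                not has_saccade,
                "saccade" if has_saccade else "",
                float(dist.max()),
            )
        )
    return pd.DataFrame(rows, columns=["trial", "keep", "reason", "max_excursion_deg"])


def downsample(
    samples: pd.DataFrame,
    mask: np.ndarray,
    out_rate_hz: int = 20,
) -> pd.DataFrame:
    """Average valid samples into fixed bins anchored at t = 0.

    Bin ``k`` covers ``[k/out_rate, (k+1)/out_rate)`` and is reported at its
    left edge; bins without any valid sample are NaN.
    """
    t = samples["t_s"].to_numpy(dtype=float)
    p = samples["pupil_mm"].to_numpy(dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if t.size == 0:
        return pd.DataFrame({"bin": [], "t_s": [], "pupil": []})
    k = np.floor(t * out_rate_hz + 1e-6).astype(np.int64)
    n_bins = int(k.max()) + 1
    counts = np.bincount(k[mask], minlength=n_bins)
    sums = np.bincount(k[mask], weights=p[mask], minlength=n_bins)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    bins = np.arange(n_bins)
    return pd.DataFrame({"bin": bins, "t_s": bins / out_rate_hz, "pupil": means})


def zscore_participant(values: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Centre by the median and scale by the sample SD of all valid values."""
    values = np.asarray(values, dtype=float)
    valid = values[np.isfinite(values)]
    if valid.size < 2:
        raise DegenerateInputError("need at least 2 valid points to z-score")
    med = float(np.median(valid))
    sd = float(np.std(valid, ddof=1))
    if sd == 0:
        raise DegenerateInputError("zero variance: cannot z-score")
    return (values - med) / sd, med, sd


def baseline_correct(
    t_rel: np.ndarray,
    values: np.ndarray,
    halfwidth_s: float = 0.2,
) -> np.ndarray:
    """Subtract the median of valid bins within ``[-halfwidth, +halfwidth)``
    of the locked event (``t_rel == 0``)."""
    t_rel = np.asarray(t_rel, dtype=float)
    values = np.asarray(values, dtype=float)
    in_win = (t_rel >= -halfwidth_s - 1e-9) & (t_rel < halfwidth_s - 1e-9)
    window = values[in_win]
    window = window[np.isfinite(window)]
    if window.size == 0:
        raise DegenerateInputError("no valid bins in the baseline window")
    return values - float(np.median(window))


@dataclass
class ProcessedParticipant:
    """All processed trials of one participant plus bookkeeping."""

    trials: pd.DataFrame  # long: labels + align + t_rel + z
    exclusions: pd.DataFrame  # one row per trial: kept flag + reason
    z_median: float
    z_sd: float


def process_participant(
    sessions: Sequence[RawSession],
    params: CleaningParams = CleaningParams(),
) -> ProcessedParticipant:
    """Run the full cleaning chain over all sessions of one participant."""
    per_session = []
    for sess in sessions:
        mask, _ = flag_invalid_samples(sess.samples, params)
        keep = exclude_saccade_trials(sess.samples, sess.events, params)
        binned = downsample(sess.samples, mask, params.out_rate_hz)
        per_session.append((sess, keep, binned))

    # z statistics over every retained-trial bin of the participant
    pooled = []
    for sess, keep, binned in per_session:
        epochs = trial_epochs(sess.events).merge(keep[["trial", "keep"]], on="trial")
        tb = binned["t_s"].to_numpy()
        in_kept = np.zeros(len(binned), dtype=bool)
        for _, ep in epochs[epochs["keep"]].iterrows():
            in_kept |= (tb >= ep["topup_start"] - 1e-9) & (tb < ep["trial_end"] - 1e-9)
        pooled.append(binned["pupil"].to_numpy()[in_kept])
    _, med, sd = zscore_participant(np.concatenate(pooled))

    out_rate = params.out_rate_hz
    trial_rows, excl_rows = [], []
    for sess, keep, binned in per_session:
        z = (binned["pupil"].to_numpy() - med) / sd
        labels_by_trial = sess.design.set_index("trial")
        epochs = trial_epochs(sess.events).merge(keep, on="trial")
        for _, ep in epochs.iterrows():
            trial = int(ep["trial"])
            labels = labels_by_trial.loc[trial]
            base = {
                "participant_id": labels["participant_id"],
                "experiment": int(labels["experiment"]),
                "session": int(labels["session"]),
                "condition": labels["condition"],
                "trial": trial,
                "numerosity": int(labels["numerosity"]),
            }
            if not ep["keep"]:
                excl_rows.append({**base, "kept": False, "reason": ep["reason"]})
                continue
            segments = {}
            failed = None
            for align, onset, (lo, hi) in (
                ("test", ep["test_on"], TEST_SEGMENT),
                ("adapter", ep["topup_start"], ADAPTER_SEGMENT),
            ):
                onset_bin = int(round(onset * out_rate))
                b0, b1 = onset_bin + int(round(lo * out_rate)), onset_bin + int(
                    round(hi * out_rate)
                )
                b0, b1 = max(0, b0), min(len(z), b1)
                rel = np.arange(b0, b1) - onset_bin
                t_rel = rel / out_rate
                try:
                    corrected = baseline_correct(
                        t_rel, z[b0:b1], params.baseline_halfwidth_s
                    )
                except DegenerateInputError:
                    failed = align
                    break
                segments[align] = (rel, t_rel, corrected)
            if failed == "test":
                excl_rows.append({**base, "kept": False, "reason": "empty_baseline_test"})
                continue
            for align, (rel, t_rel, corrected) in segments.items():
                for k, tr, v in zip(rel, t_rel, corrected):
                    trial_rows.append(
                        {**base, "align": align, "t_idx": int(k), "t_rel": tr, "z": v}
                    )
            reason = "empty_baseline_adapter" if failed == "adapter" else ""
            excl_rows.append({**base, "kept": True, "reason": reason})

    trials = pd.DataFrame(trial_rows)
    exclusions = pd.DataFrame(excl_rows)
    return ProcessedParticipant(
        trials=trials, exclusions=exclusions, z_median=med, z_sd=sd
    )
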