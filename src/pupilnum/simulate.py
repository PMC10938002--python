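"""Synthetic eye-tracker sessions and verbal numerosity estimates.

The generator mirrors the structure the downstream analysis assumes: a
per-participant baseline pupil diameter, slow drift, an event-locked
constriction impulse at every luminance onset whose amplitude grows with the
logarithm of the *perceived* numerosity, an adaptation condition that scales
perceived numerosity down after the high-numerosity adapter, plus blinks,
velocity spikes and occasional saccades.  Verbal estimates apply the same
perceived-numerosity scaling with multiplicative lognormal noise.

Timing of a session (500 Hz sampling): 60 s of initial adaptation, then each
trial runs top-up adapter 2 s -> blank 0.5 s -> test 0.5 s -> 2.5 s
inter-trial interval (5.5 s per trial).

All randomness flows through seeds derived deterministically from
``(base seed, participant id, purpose)`` so the same participant keeps the
same latent parameters across sessions and across the pupillometric and
psychophysical experiments.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .stimuli import DESIGN_COLUMNS, TEST_NUMEROSITIES

EVENT_NAMES = (
    "adapt_start",
    "topup_start",
    "blank_start",
    "test_on",
    "test_off",
    "trial_end",
)

INITIAL_ADAPT_S = 60.0
TOPUP_S = 2.0
BLANK_S = 0.5
TEST_S = 0.5
ITI_S = 2.5
TRIAL_S = TOPUP_S + BLANK_S + TEST_S + ITI_S  # 5.5 s

ADAPTER_NUMEROSITY = {"high": 160, "low": 10}


def stable_seed(*parts) -> int:
    """Deterministic 64-bit seed from arbitrary labelled parts."""
    digest = hashlib.sha256("|".join(str(p) for p in parts).encode()).digest()
    return int.from_bytes(digest[:8], "little")


@dataclass(frozen=True)
class SimParams:
    """Generative parameters of the synthetic cohort."""

    n_participants: int = 22
    baseline_pupil_mm: float = 5.0
    baseline_sd_mm: float = 0.5
    drift_amplitude_mm: float = 0.10
    drift_timescale_s: float = 20.0
    response_gain_g0: float = 0.10  # mm, constriction at ln(N)=0
    response_gain_g1: float = 0.04  # mm per ln(perceived N)
    response_latency_s: float = 0.3
    kernel_shape: float = 3.0
    kernel_tau_s: float = 0.4
    adapter_gain: float = 1.0  # scales adapter/top-up kernels (0 disables)
    k_high: float = 0.75
    k_low: float = 1.0
    sigma_k: float = 0.08  # SD of the per-participant high-condition factor
    estimate_noise_cv: float = 0.15
    noise_sd_mm: float = 0.004
    blink_rate_hz: float = 0.05
    spike_rate_hz: float = 0.01
    saccade_trial_prob: float = 0.055
    gaze_noise_sd_deg: float = 0.05
    sample_rate_hz: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if self.response_latency_s < 0.3:
            raise ValueError("response_latency_s must be >= 0.3 s")
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")
        if not self.k_high <= self.k_low:
            raise ValueError("need k_high <= k_low")

    def replace(self, **changes) -> "SimParams":
        return dataclasses.replace(self, **changes)


@dataclass
class RawSession:
    """One participant-session: sample stream, event log, design and truth."""

    samples: pd.DataFrame  # t_s, pupil_mm, gaze_x_deg, gaze_y_deg, valid_flag
    events: pd.DataFrame  # trial, event, t_s
    design: pd.DataFrame  # rows of the session design
    truth: dict  # participant factors, per-trial amplitudes, artifact intervals


def perceived_numerosity(n: float, k: float) -> float:
    """Perceived numerosity after adaptation: physical ``n`` times factor ``k``."""
    if n <= 0:
        raise ValueError("numerosity must be positive")
    return n * k


def draw_participant_truth(
    participant_id, params: SimParams, seed: int | None = None
) -> dict:
    """Latent per-participant factors, reproducible across sessions.

    The adaptation susceptibility ``u`` multiplies the *depth* of adaptation
    (1 - k_high), so with no adaptation programmed (k_high == k_low) there is
    no spurious between-condition variability; ``u`` also drives the
    behavioural effect, coupling the two modalities.
    """
    base = params.seed if seed is None else seed
    rng = np.random.default_rng(stable_seed(base, participant_id, "truth"))
    baseline = rng.normal(params.baseline_pupil_mm, params.baseline_sd_mm)
    depth = 1.0 - params.k_high
    sigma_rel = params.sigma_k / depth if depth > 0 else 0.0
    u = max(0.0, rng.normal(1.0, sigma_rel))
    k_high = 1.0 - depth * u
    k_low = 1.0 - (1.0 - params.k_low) * u
    return {
        "participant_id": participant_id,
        "baseline_mm": float(baseline),
        "k_high": float(k_high),
        "k_low": float(k_low),
        "u": float(u),
    }


def pupil_kernel(
    t: np.ndarray | float,
    latency: float = 0.3,
    shape: float = 3.0,
    tau: float = 0.4,
) -> np.ndarray | float:
    """Unit-amplitude constriction impulse: 0 before ``latency``, then a
    single negative lobe (gamma-density shaped) peaking at
    ``latency + (shape-1)*tau`` and relaxing back to 0."""
    t = np.asarray(t, dtype=float)
    s = t - latency
    out = np.zeros_like(s)
    pos = s > 0
    s_peak = (shape - 1.0) * tau
    peak_val = s_peak ** (shape - 1.0) * np.exp(-s_peak / tau)
    out[pos] = -(s[pos] ** (shape - 1.0) * np.exp(-s[pos] / tau)) / peak_val
    return out if out.ndim else float(out)


def _response_amplitude_mm(perceived_n: float, params: SimParams) -> float:
    return params.response_gain_g0 + params.response_gain_g1 * np.log(perceived_n)


def _ou_drift(n: int, dt: float, amplitude: float, timescale: float,
              rng: np.random.Generator) -> np.ndarray:
    """Stationary AR(1) (discretised Ornstein-Uhlenbeck) drift."""
    if amplitude <= 0:
        return np.zeros(n)
    phi = np.exp(-dt / timescale)
    innov_sd = amplitude * np.sqrt(1.0 - phi**2)
    e = rng.normal(0.0, innov_sd, size=n)
    e[0] = rng.normal(0.0, amplitude)
    return lfilter([1.0], [1.0, -phi], e)


def session_events(design_rows: pd.DataFrame) -> pd.DataFrame:
    """Event log for one session on the canonical trial clock."""
    trials = design_rows["trial"].to_numpy()
    rows = [(0, "adapt_start", 0.0)]
    for j, trial in enumerate(trials):
        t0 = INITIAL_ADAPT_S + j * TRIAL_S
        rows.extend(
            [
                (trial, "topup_start", t0),
                (trial, "blank_start", t0 + TOPUP_S),
                (trial, "test_on", t0 + TOPUP_S + BLANK_S),
                (trial, "test_off", t0 + TOPUP_S + BLANK_S + TEST_S),
                (trial, "trial_end", t0 + TRIAL_S),
            ]
        )
    return pd.DataFrame(rows, columns=["trial", "event", "t_s"])


def simulate_session(
    design_rows: pd.DataFrame,
    params: SimParams,
    seed: int,
    truth: Mapping | None = None,
) -> RawSession:
    """Simulate the raw 500 Hz sample stream of one participant-session."""
    design_rows = design_rows.reset_index(drop=True)
    if design_rows.empty:
        raise ValueError("design_rows is empty")
    for col in DESIGN_COLUMNS:
        if col not in design_rows.columns:
            raise ValueError(f"design is missing column {col!r}")
    pids = design_rows["participant_id"].unique()
    sessions = design_rows["session"].unique()
    conditions = design_rows["condition"].unique()
    if len(pids) != 1 or len(sessions) != 1 or len(conditions) != 1:
        raise ValueError("design_rows must cover exactly one participant-session")
    pid, condition = pids[0], conditions[0]
    if truth is None:
        truth = draw_participant_truth(pid, params)

    rng = np.random.default_rng(stable_seed(seed, pid, sessions[0], "session"))
    fs = params.sample_rate_hz
    dt = 1.0 / fs
    n_trials = len(design_rows)
    duration = INITIAL_ADAPT_S + n_trials * TRIAL_S
    n = int(round(duration * fs))
    t = np.arange(n) * dt

    pupil = np.full(n, truth["baseline_mm"])
    pupil += _ou_drift(n, dt, params.drift_amplitude_mm, params.drift_timescale_s, rng)

    # event-locked constriction kernels; support truncated at 5 s (< 5.3 s,
    # the gap to the next trial's baseline window) so trials do not overlap
    support = np.arange(int(round(5.0 * fs))) * dt
    kern = pupil_kernel(
        support, params.response_latency_s, params.kernel_shape, params.kernel_tau_s
    )

    def add_kernel(onset_s: float, amplitude_mm: float) -> None:
        i0 = int(round(onset_s * fs))
        seg = kern[: max(0, min(len(kern), n - i0))]
        pupil[i0 : i0 + len(seg)] += amplitude_mm * seg

    adapter_n = ADAPTER_NUMEROSITY[condition]
    adapter_amp = params.adapter_gain * _response_amplitude_mm(adapter_n, params)
    if params.adapter_gain > 0:
        add_kernel(0.0, adapter_amp)

    k_cond = truth["k_high"] if condition == "high" else truth["k_low"]
    trial_truth = []
    events = session_events(design_rows)
    for j, row in design_rows.iterrows():
        t0 = INITIAL_ADAPT_S + j * TRIAL_S
        if params.adapter_gain > 0:
            add_kernel(t0, adapter_amp)
        perceived = perceived_numerosity(row["numerosity"], k_cond)
        amp = _response_amplitude_mm(perceived, params)
        add_kernel(t0 + TOPUP_S + BLANK_S, amp)
        trial_truth.append(
            {
                "trial": int(row["trial"]),
                "numerosity": int(row["numerosity"]),
                "perceived_numerosity": float(perceived),
                "amplitude_mm": float(amp),
            }
        )

    if params.noise_sd_mm > 0:
        pupil += rng.normal(0.0, params.noise_sd_mm, size=n)

    # gaze: small jitter around fixation
    gaze_x = rng.normal(0.0, params.gaze_noise_sd_deg, size=n)
    gaze_y = rng.normal(0.0, params.gaze_noise_sd_deg, size=n)

    valid = np.ones(n, dtype=np.int8)
    blink_intervals: list[tuple[float, float]] = []
    if params.blink_rate_hz > 0:
        n_blinks = rng.poisson(params.blink_rate_hz * duration)
        ramp = int(round(0.02 * fs))  # 20 ms steep edges
        for t_b in np.sort(rng.uniform(0.0, duration - 0.5, size=n_blinks)):
            dur = rng.uniform(0.1, 0.3)
            i0, i1 = int(round(t_b * fs)), int(round((t_b + dur) * fs))
            lo, hi = max(0, i0 - ramp), min(n, i1 + ramp)
            core = slice(max(0, i0), min(n, i1))
            down = slice(lo, max(0, i0))
            up = slice(min(n, i1), hi)
            floor = 0.1
            pupil[core] = floor
            if down.stop > down.start:
                w = np.linspace(1.0, 0.0, down.stop - down.start, endpoint=False)
                pupil[down] = floor + (pupil[down] - floor) * w
            if up.stop > up.start:
                w = np.linspace(0.0, 1.0, up.stop - up.start, endpoint=False)
                pupil[up] = floor + (pupil[up] - floor) * w
            valid[core] = 0
            blink_intervals.append((lo * dt, hi * dt))

    spike_samples: list[int] = []
    if params.spike_rate_hz > 0:
        n_spikes = rng.poisson(params.spike_rate_hz * duration)
        idx = rng.integers(1, n - 1, size=n_spikes)
        for i in np.sort(idx):
            pupil[i] += rng.choice([-1.0, 1.0]) * rng.uniform(0.3, 0.6)
            spike_samples.append(int(i))

    saccade_trials: list[int] = []
    if params.saccade_trial_prob > 0:
        for j, row in design_rows.iterrows():
            if rng.uniform() < params.saccade_trial_prob:
                t0 = INITIAL_ADAPT_S + j * TRIAL_S
                onset = t0 + rng.uniform(0.2, TRIAL_S - 0.5)
                dur = rng.uniform(0.1, 0.2)
                i0, i1 = int(round(onset * fs)), int(round((onset + dur) * fs))
                angle = rng.uniform(0.0, 2.0 * np.pi)
                ampl = rng.uniform(1.5, 3.0)
                gaze_x[i0:i1] += ampl * np.cos(angle)
                gaze_y[i0:i1] += ampl * np.sin(angle)
                saccade_trials.append(int(row["trial"]))

    samples = pd.DataFrame(
        {
            "t_s": t,
            "pupil_mm": pupil,
            "gaze_x_deg": gaze_x,
            "gaze_y_deg": gaze_y,
            "valid_flag": valid,
        }
    )
    truth_out = dict(truth)
    truth_out.update(
        {
            "session": int(sessions[0]),
            "condition": condition,
            "trials": trial_truth,
            "blink_intervals": blink_intervals,
            "spike_samples": spike_samples,
            "saccade_trials": saccade_trials,
            "adapter_amplitude_mm": float(adapter_amp),
        }
    )
    return RawSession(samples=samples, events=events, design=design_rows, truth=truth_out)


def simulate_participant(
    design: pd.DataFrame, params: SimParams, seed: int
) -> list[RawSession]:
    """Simulate all sessions of one participant with shared latent factors."""
    pids = design["participant_id"].unique()
    if len(pids) != 1:
        raise ValueError("design must cover exactly one participant")
    truth = draw_participant_truth(pids[0], params, seed=seed)
    sessions = []
    for _, rows in design.groupby("session", sort=True):
        sessions.append(simulate_session(rows, params, seed=seed, truth=truth))
    return sessions


def simulate_estimates(
    design: pd.DataFrame, params: SimParams, seed: int | None = None
) -> pd.DataFrame:
    """Verbal numerosity estimates for every design row.

    estimate = perceived numerosity x lognormal noise with unit mean and
    coefficient of variation ``estimate_noise_cv``.
    """
    base = params.seed if seed is None else seed
    out = []
    for pid, rows in design.groupby("participant_id", sort=False):
        truth = draw_participant_truth(pid, params, seed=base)
        rng = np.random.default_rng(stable_seed(base, pid, "estimates"))
        k = {"high": truth["k_high"], "low": truth["k_low"]}
        cv = params.estimate_noise_cv
        sigma = np.sqrt(np.log1p(cv**2))
        for _, row in rows.iterrows():
            perceived = perceived_numerosity(row["numerosity"], k[row["condition"]])
            noise = np.exp(rng.normal(-(sigma**2) / 2.0, sigma)) if cv > 0 else 1.0
            out.append(
                {
                    "participant_id": pid,
                    "experiment": row["experiment"],
                    "session": row["session"],
                    "condition": row["condition"],
                    "numerosity": row["numerosity"],
                    "trial": row["trial"],
                    "estimate": float(perceived * noise),
                }
            )
    return pd.DataFrame(out)


def simulate_cohort_features(
    n_participants: int,
    params: SimParams,
    seed: int,
    reps_per_cell: int = 9,
    experiments: Sequence[int] = (1, 2),
    feature_noise_sd: float = 0.05,
    pretest_noise_sd: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Feature-level cohort generator for simulation batteries.

    Evaluates the same generative model as the trace simulator directly at
    the feature level (per-trial peak constriction, pre-test pupil and
    verbal estimate), skipping the 500 Hz stream — orders of magnitude
    faster, for power / type-I / coupling studies that need hundreds of
    cohorts.  Pre-test pupil carries the residual adapter-kernel tail at
    test onset, so it differs between conditions as in the trace model.
    """
    rng = np.random.default_rng(stable_seed(seed, "cohort-features"))
    tail = -float(
        pupil_kernel(
            np.array([TOPUP_S + BLANK_S]),
            params.response_latency_s,
            params.kernel_shape,
            params.kernel_tau_s,
        )[0]
    )  # positive fraction of the adapter amplitude still present at test onset
    sigma_est = np.sqrt(np.log1p(params.estimate_noise_cv**2))
    feat_rows, est_rows = [], []
    for i in range(n_participants):
        pid = f"P{i + 1:02d}"
        truth = draw_participant_truth(pid, params, seed=seed)
        b = rng.normal(0.0, 0.3)  # participant offset in the feature scale
        b_pre = rng.normal(0.0, 0.3)
        experiment = experiments[i % len(experiments)]
        k = {"high": truth["k_high"], "low": truth["k_low"]}
        for condition in ("high", "low"):
            adapter_amp = params.adapter_gain * _response_amplitude_mm(
                ADAPTER_NUMEROSITY[condition], params
            )
            for numerosity in TEST_NUMEROSITIES:
                perceived = perceived_numerosity(numerosity, k[condition])
                amp = _response_amplitude_mm(perceived, params)
                for rep in range(reps_per_cell):
                    feat_rows.append(
                        {
                            "participant_id": pid,
                            "experiment": experiment,
                            "condition": condition,
                            "numerosity": numerosity,
                            "trial": rep + 1,
                            "peak_constriction": b
                            - amp
                            + rng.normal(0.0, feature_noise_sd),
                            "pretest_pupil": b_pre
                            - tail * adapter_amp
                            + rng.normal(0.0, pretest_noise_sd),
                        }
                    )
                    noise = (
                        np.exp(rng.normal(-(sigma_est**2) / 2.0, sigma_est))
                        if params.estimate_noise_cv > 0
                        else 1.0
                    )
                    est_rows.append(
                        {
                            "participant_id": pid,
                            "experiment": experiment,
                            "condition": condition,
                            "numerosity": numerosity,
                            "trial": rep + 1,
                            "estimate": float(perceived * noise),
                        }
                    )
    features = pd.DataFrame(feat_rows)
    features["luminance"] = np.where(
        features["experiment"] == 2,
        "exp2-N" + features["numerosity"].astype(str),
        "exp1",
    )
    return features, pd.DataFrame(est_rows)


def write_session(session: RawSession, directory, prefix: str) -> None:
    """Write one session's samples/events/truth as text files."""
    import json
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    session.samples.to_csv(directory / f"{prefix}_samples.tsv", sep="\t", index=False)
    session.events.to_csv(directory / f"{prefix}_events.tsv", sep="\t", index=False)
    (directory / f"{prefix}_truth.json").write_text(json.dumps(session.truth, indent=1))
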