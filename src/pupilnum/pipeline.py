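"""End-to-end orchestration: simulate -> preprocess -> features -> stats.

A run is fully determined by a :class:`RunConfig`; every stage draws its
randomness from seeds derived by hashing (master seed, stage, participant),
so identical configs give identical outputs.  The manifest records seeds,
per-stage attrition and SHA-256 hashes of all written tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, features as feat, stats as st, stimuli as stim
from .preprocess import CleaningParams, process_participant
from .simulate import SimParams, simulate_estimates, simulate_participant, stable_seed

log = logging.getLogger("pupilnum")


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one full synthetic-cohort run."""

    n_participants_exp1: int = 12
    n_participants_exp2: int = 10
    reps_per_numerosity_per_session: int = 18
    master_seed: int = 0
    out_dir: str = "run_output"
    sim: SimParams = field(default_factory=SimParams)
    cleaning: CleaningParams = field(default_factory=CleaningParams)
    save_raw: bool = False
    make_figures: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = SimParams(**raw.pop("sim", {}))
        cleaning = CleaningParams(**raw.pop("cleaning", {}))
        return cls(sim=sim, cleaning=cleaning, **raw)

    def participants(self) -> pd.DataFrame:
        rows = [(f"E1P{i + 1:02d}", 1) for i in range(self.n_participants_exp1)]
        rows += [(f"E2P{i + 1:02d}", 2) for i in range(self.n_participants_exp2)]
        return pd.DataFrame(rows, columns=["participant_id", "experiment"])


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def _example_stimuli(out: Path, seed: int) -> dict:
    """Render one example array per role, widening the field when the
    published geometry cannot contain the requested dot area."""
    spec = stim.StimulusSpec()
    info = {}
    jobs = [("adapter-high", "high", None), ("adapter-low", "low", None)] + [
        (f"test-N{n}", None, n) for n in spec.test_numerosities
    ]
    for name, condition, n in jobs:
        if condition is not None:
            count = spec.adapter_high_n if condition == "high" else spec.adapter_low_n
            diam = stim.equal_area_diameter(count, spec.adapter_total_area)
            diameters = np.full(count, diam)
        else:
            diameters = np.full(n, stim.equal_area_diameter(n, spec.test_total_area))
        field_d = spec.field_diameter
        widened = False
        try:
            stim.sample_positions(
                len(diameters), diameters, field_d, spec.min_gap,
                spec.fixation_radius, seed=stable_seed(seed, name), max_restarts=1,
                max_tries=2000,
            )
        except stim.PackingInfeasibleError:
            field_d = stim.feasible_field_diameter(diameters, spec.min_gap)
            widened = True
        if condition is not None:
            arr = stim.make_adapter(
                condition, spec, seed=stable_seed(seed, name), field_diameter=field_d
            )
        else:
            arr = stim.make_test(
                n, 1, spec, seed=stable_seed(seed, name), field_diameter=field_d
            )
        (out / f"{name}.json").write_text(arr.to_json())
        img = stim.render(arr, pixels_per_degree=20, field_diameter=field_d)
        stim.save_render_png(img, out / f"{name}.png")
        info[name] = {
            "numerosity": int(arr.numerosity),
            "total_area_deg2": stim.total_area(arr),
            "field_diameter_deg": field_d,
            "field_widened": widened,
        }
        if widened:
            log.warning(
                "%s: published field (%.1f deg) cannot contain %.1f deg^2 of "
                "dots; rendered in a %.1f-deg field",
                name, spec.field_diameter, stim.total_area(arr), field_d,
            )
    return info


def _figures(out: Path, trials: pd.DataFrame, peaks: pd.DataFrame,
             estimates: pd.DataFrame, corr: st.CorrelationResult | None) -> list[str]:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    written = []
    colors = {"high": "crimson", "low": "steelblue"}

    # condition-average traces, adapter- and test-locked
    fig, axes = plt.subplots(1, 2, figsize=(10, 4), sharey=True)
    for ax, align, title in (
        (axes[0], "adapter", "adapter-locked"),
        (axes[1], "test", "test-locked"),
    ):
        avg = feat.condition_average_traces(trials, align=align, by_numerosity=False)
        for condition, grp in avg.groupby("condition"):
            ax.plot(grp["t_rel"], grp["z_mean"], color=colors[condition],
                    label=f"adapt-{condition}")
            ax.fill_between(grp["t_rel"], grp["z_mean"] - grp["z_sem"],
                            grp["z_mean"] + grp["z_sem"], alpha=0.3,
                            color=colors[condition])
        ax.axvline(0.0, ls="--", c="gray")
        ax.set_xlabel("time from onset (s)")
        ax.set_title(title)
    axes[0].set_ylabel("pupil (z, baseline-corrected)")
    axes[1].legend()
    fig.tight_layout()
    p = out / "traces_by_condition.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    written.append(p.name)

    fig, ax = plt.subplots(figsize=(5, 4))
    for condition, grp in peaks.groupby("condition"):
        grp = grp.sort_values("numerosity")
        ax.plot(grp["numerosity"], grp["peak"], "o-", color=colors[condition],
                label=f"adapt-{condition}")
    ax.set_xscale("log")
    ax.set_xticks(list(stim.TEST_NUMEROSITIES))
    ax.get_xaxis().set_major_formatter(matplotlib.ticker.ScalarFormatter())
    ax.set_xlabel("test numerosity")
    ax.set_ylabel("peak constriction (z)")
    ax.legend()
    fig.tight_layout()
    p = out / "peak_by_numerosity.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    written.append(p.name)

    fig, ax = plt.subplots(figsize=(5, 4))
    means = estimates.groupby(["condition", "numerosity"])["estimate"].mean().reset_index()
    for condition, grp in means.groupby("condition"):
        grp = grp.sort_values("numerosity")
        ax.plot(grp["numerosity"], grp["estimate"], "o-", color=colors[condition],
                label=f"adapt-{condition}")
    ax.plot([10, 40], [10, 40], ":", c="gray", label="veridical")
    ax.set_xlabel("physical numerosity")
    ax.set_ylabel("mean estimate")
    ax.legend()
    fig.tight_layout()
    p = out / "estimates_by_numerosity.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    written.append(p.name)

    if corr is not None:
        fig, ax = plt.subplots(figsize=(4.5, 4))
        ax.scatter(corr.pairs["behavior_effect"], corr.pairs["pupil_effect"], c="k")
        ax.set_xlabel("estimate difference at N=40 (low - high)")
        ax.set_ylabel("peak-constriction difference (high - low)")
        ax.set_title(f"r = {corr.r:.2f}, p = {corr.p_value:.3f}, n = {corr.n}")
        fig.tight_layout()
        p = out / "pupil_behavior_correlation.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        written.append(p.name)
    return written


def run_all(config: RunConfig) -> dict:
    """Execute the full pipeline; returns (and writes) the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "master_seed": config.master_seed,
        "config": {
            "n_participants_exp1": config.n_participants_exp1,
            "n_participants_exp2": config.n_participants_exp2,
            "reps_per_numerosity_per_session": config.reps_per_numerosity_per_session,
            "sim": dataclasses.asdict(config.sim),
            "cleaning": dataclasses.asdict(config.cleaning),
        },
        "stages": {},
    }
    stage = "stimuli"
    try:
        stim_dir = out / "stimuli"
        stim_dir.mkdir(exist_ok=True)
        manifest["stages"][stage] = _example_stimuli(
            stim_dir, stable_seed(config.master_seed, stage)
        )

        stage = "design"
        participants = config.participants()
        designs = []
        for experiment, grp in participants.groupby("experiment"):
            designs.append(
                stim.build_design(
                    grp["participant_id"].tolist(),
                    config.reps_per_numerosity_per_session,
                    seed=stable_seed(config.master_seed, stage, experiment),
                    experiment=int(experiment),
                )
            )
        design = pd.concat(designs, ignore_index=True)
        _write_tsv(design, out / "design.tsv")
        manifest["stages"][stage] = {
            "n_participants": len(participants),
            "trials_per_participant": int(
                design.groupby("participant_id").size().iloc[0]
            ),
        }

        stage = "simulate+preprocess"
        # one cohort seed for both modalities so that each participant's
        # latent factors (adaptation strength, baseline) are shared between
        # the pupillometric and psychophysical simulations
        cohort_seed = stable_seed(config.master_seed, "cohort")
        all_trials, all_excl, attrition = [], [], {}
        for pid, pdesign in design.groupby("participant_id", sort=False):
            sessions = simulate_participant(pdesign, config.sim, seed=cohort_seed)
            if config.save_raw:
                from .simulate import write_session

                for sess in sessions:
                    write_session(
                        sess, out / "raw", f"{pid}_S{sess.truth['session']}"
                    )
            processed = process_participant(sessions, config.cleaning)
            all_trials.append(processed.trials)
            all_excl.append(processed.exclusions)
            kept = int(processed.exclusions["kept"].sum())
            attrition[str(pid)] = {
                "trials_in": len(processed.exclusions),
                "trials_kept": kept,
                "trials_excluded": len(processed.exclusions) - kept,
            }
            log.info("processed %s: %s", pid, attrition[str(pid)])
        trials = pd.concat(all_trials, ignore_index=True)
        exclusions = pd.concat(all_excl, ignore_index=True)
        _write_tsv(trials, out / "processed_trials.tsv")
        _write_tsv(exclusions, out / "exclusion_log.tsv")
        manifest["stages"][stage] = {"per_participant": attrition}

        stage = "estimates"
        estimates = simulate_estimates(design, config.sim, seed=cohort_seed)
        _write_tsv(estimates, out / "estimates.tsv")

        stage = "features"
        features = feat.extract_features(trials)
        _write_tsv(features, out / "features.tsv")
        avg = feat.condition_average_traces(trials)
        _write_tsv(avg, out / "condition_average_traces.tsv")
        peaks = feat.condition_peaks(avg)
        _write_tsv(peaks, out / "condition_peaks.tsv")
        manifest["stages"][stage] = {
            "n_trials_featured": int(features["peak_constriction"].notna().sum()),
            "n_trials_missing_peak": int(features["peak_constriction"].isna().sum()),
        }

        stage = "stats"
        pupil_model = st.fit_pupil_model(features)
        (out / "pupil_model.json").write_text(pupil_model.to_json())
        behavior_model = st.fit_behavior_model(estimates)
        (out / "behavior_model.json").write_text(behavior_model.to_json())
        pupil_eff = feat.adaptation_effect_pupil(trials)
        behav_eff = feat.adaptation_effect_behavior(estimates)
        corr = None
        try:
            corr = st.correlate_effects(pupil_eff, behav_eff)
            (out / "correlation.json").write_text(json.dumps(corr.to_dict(), indent=1))
            _write_tsv(corr.pairs, out / "correlation_pairs.tsv")
        except st.UndefinedCorrelationError as err:
            manifest["stages"].setdefault(stage, {})["correlation_skipped"] = str(err)
        manifest["stages"].setdefault(stage, {}).update(
            {
                "pupil_model_n_obs": pupil_model.n_obs,
                "behavior_model_n_obs": behavior_model.n_obs,
            }
        )

        if config.make_figures:
            stage = "figures"
            manifest["stages"][stage] = _figures(out, trials, peaks, estimates, corr)
    except Exception as err:  # noqa: BLE001 - stage context for the caller
        manifest["failed_stage"] = stage
        manifest["error"] = str(err)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {err}") from err

    manifest["outputs"] = {
        p.name: _sha256(p) for p in sorted(out.glob("*.tsv")) + sorted(out.glob("*.json"))
        if p.name != "manifest.json"
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
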