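"""Orchestration of the full synthetic study over the condition grid.

The study crosses 3 tasks x 2 systems x 4 apodization levels (24 conditions)
with a roster of synthetic observers standing in for subjects.  For each
observer x condition the pipeline runs staircase training, a testing block at
the trained threshold (repeating once if PC exceeds the 90% retraining rule),
performance summaries, classification images (standard and unapodized), and
their spectra, features and sampling efficiencies.  Everything is seeded
deterministically per (observer, condition) from the master seed, so a rerun
reproduces the same CSV metrics byte for byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .classification_images import (
    classification_image_from_testing,
    classification_spectrum,
    sampling_efficiency,
    smooth,
    spectral_features,
)
from .imaging_chain import (
    APOD_LEVELS,
    SYSTEM1,
    SYSTEM2,
    ApodizationSpec,
    Condition,
    SystemSpec,
    pixel_sd_analytic,
    resolution_10pct,
)
from .observer_models import (
    ObserverSpec,
    io_template,
    lowfreq_attenuated_template,
    rescaled_template,
)
from .phantom_tasks import TASK_IDS
from .psychophysics import (
    make_analytic_responder,
    make_stimulus_responder,
    run_staircase,
    run_testing_block,
    session_endpoints,
    summarize_performance,
)

log = logging.getLogger("ctdiscrim")

__all__ = [
    "ObserverRecipe",
    "StudyConfig",
    "default_roster",
    "run_study",
    "report_tables",
    "analytic_system_table",
]

#: suprathreshold staircase starting points per task (theta units differ)
DEFAULT_THETA0 = {"T1": 1.0, "T2": 1.0, "T3": 1.5}


@dataclass(frozen=True)
class ObserverRecipe:
    """How to build a synthetic observer for a given condition.

    ``kind`` is one of ``'io'`` (Ideal-Observer template), ``'rescaled'``
    (spatially rescaled IO template; ``scale < 1`` = undersized) or
    ``'lowfreq_attenuated'`` (IO template with low frequencies suppressed
    below ``f_knee`` cyc/mm).  ``internal_noise_sd`` adds decision noise in
    response-SD units; for an 'io' observer the resulting efficiency is
    ``1 / (1 + internal_noise_sd^2)``.
    """

    label: str
    kind: str = "io"
    internal_noise_sd: float = 0.0
    scale: float = 1.0
    f_knee: float = 0.05

    def build(self, condition: Condition, theta: float) -> ObserverSpec:
        mu_t, mu_a = condition.mean_images(theta)
        t = io_template(mu_t, mu_a, condition.noise, condition.apod, condition.display)
        if self.kind == "rescaled":
            t = rescaled_template(t, self.scale)
        elif self.kind == "lowfreq_attenuated":
            t = lowfreq_attenuated_template(t, self.f_knee)
        elif self.kind != "io":
            raise ValueError(f"unknown observer kind {self.kind!r}")
        return ObserverSpec(t, self.internal_noise_sd, self.label)


def default_roster() -> list[ObserverRecipe]:
    """Six synthetic subjects spanning target efficiencies ~0.10-0.40.

    Three are Ideal-Observer templates degraded only by internal noise
    (efficiency 1/(1+kappa^2) = 0.40, 0.25, 0.10); two use undersized
    templates, and one attenuates low frequencies, emulating the mis-tuning
    patterns seen in human classification images.
    """
    return [
        ObserverRecipe("obs-io40", "io", internal_noise_sd=float(np.sqrt(1 / 0.40 - 1))),
        ObserverRecipe("obs-io25", "io", internal_noise_sd=float(np.sqrt(1 / 0.25 - 1))),
        ObserverRecipe("obs-io10", "io", internal_noise_sd=float(np.sqrt(1 / 0.10 - 1))),
        ObserverRecipe("obs-small80", "rescaled", internal_noise_sd=1.0, scale=0.8),
        ObserverRecipe("obs-small65", "rescaled", internal_noise_sd=1.2, scale=0.65),
        ObserverRecipe("obs-hp", "lowfreq_attenuated", internal_noise_sd=1.0, f_knee=0.08),
    ]


@dataclass
class StudyConfig:
    """Configuration of a full synthetic study run."""

    tasks: list[str] = field(default_factory=lambda: list(TASK_IDS))
    systems: list[str] = field(default_factory=lambda: ["S1", "S2"])
    apod_levels: list[str] = field(default_factory=lambda: list(APOD_LEVELS))
    roster: list[ObserverRecipe] = field(default_factory=default_roster)
    n_staircase_runs: int = 6
    trials_per_run: int = 80
    n_trials: int = 2000
    target_sd: float = 166.5
    master_seed: int = 20230414
    responder: str = "stimulus"  # 'stimulus' renders images; 'analytic' is fast
    outdir: str = "study_output"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        raw = yaml.safe_load(Path(path).read_text())
        roster = [ObserverRecipe(**r) for r in raw.pop("roster", [])]
        cfg = cls(**{k: v for k, v in raw.items() if k != "roster"})
        if roster:
            cfg.roster = roster
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    def conditions(self) -> list[Condition]:
        systems = {"S1": SYSTEM1, "S2": SYSTEM2}
        return [
            Condition.create(t, systems[s], a, self.target_sd)
            for t in self.tasks
            for s in self.systems
            for a in self.apod_levels
        ]


def _subject_seed(master: int, cond_label: str, obs_label: str) -> np.random.SeedSequence:
    key = f"{cond_label}/{obs_label}".encode()
    return np.random.SeedSequence([master, int.from_bytes(key[:8].ljust(8, b"\0"), "big") % 2**31])


def run_condition(
    cfg: StudyConfig, condition: Condition, recipe: ObserverRecipe
) -> dict:
    """Train, test and analyze one observer in one condition."""
    ss = _subject_seed(cfg.master_seed, condition.label, recipe.label)
    rng_train, rng_test, rng_retest = [np.random.default_rng(s) for s in ss.spawn(3)]
    theta0 = DEFAULT_THETA0[condition.task_id]

    def responder_for(theta: float):
        obs = recipe.build(condition, theta)
        if cfg.responder == "analytic":
            return make_analytic_responder(obs, condition)
        return make_stimulus_responder(obs, condition)

    # the observer template tracks theta through training: rebuild per trial
    # is wasteful, so train with the template built at theta0 and refine once
    staircase = run_staircase(
        responder_for(theta0),
        theta0,
        rng_train,
        n_runs=cfg.n_staircase_runs,
        trials_per_run=cfg.trials_per_run,
    )
    theta = staircase.threshold
    obs = recipe.build(condition, theta)
    testing = run_testing_block(obs, condition, theta, rng_test, n_trials=cfg.n_trials)
    if testing.flagged_retrain:
        log.info("%s/%s PC=%.3f > 0.90: repeating training+testing", condition.label, recipe.label, testing.pc)
        staircase = run_staircase(
            responder_for(theta),
            theta0,
            rng_retest,
            n_runs=cfg.n_staircase_runs,
            trials_per_run=cfg.trials_per_run,
        )
        theta = staircase.threshold
        obs = recipe.build(condition, theta)
        testing = run_testing_block(obs, condition, theta, rng_retest, n_trials=cfg.n_trials)

    perf = summarize_performance(condition, obs, testing)
    endpoints = session_endpoints(condition, obs, staircase, testing)

    result = {"performance": perf, "endpoints": endpoints, "theta": theta}
    for unapod in (False, True):
        ci = smooth(classification_image_from_testing(testing, unapodized=unapod))
        feats = spectral_features(ci)
        result["ci_unapod" if unapod else "ci"] = ci
        result["features_unapod" if unapod else "features"] = feats
        if not unapod:
            result["sampling_efficiency"] = sampling_efficiency(ci, condition, theta)
            result["spectrum"] = classification_spectrum(ci)
        else:
            result["spectrum_unapod"] = classification_spectrum(ci)
    return result


def run_study(cfg: StudyConfig) -> Path:
    """Run the configured study and write the artifact tree; returns outdir."""
    import h5py

    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(out / "config.yaml")
    perf_rows, feat_rows, endpoint_frames = [], [], []
    for condition in cfg.conditions():
        cdir = out / condition.label
        cdir.mkdir(exist_ok=True)
        for recipe in cfg.roster:
            try:
                res = run_condition(cfg, condition, recipe)
            except Exception:  # pragma: no cover - diagnostic path
                log.exception("condition %s observer %s failed", condition.label, recipe.label)
                continue
            perf_rows.append(
                res["performance"].to_dict() | {"sampling_efficiency": res["sampling_efficiency"]}
            )
            for variant in ("", "_unapod"):
                f = res["features" + variant]
                feat_rows.append(
                    {
                        "task": condition.task_id,
                        "system": condition.system.name,
                        "apod": condition.apod.level,
                        "observer": recipe.label,
                        "variant": "unapodized" if variant else "apodized",
                        "IP": f.integrated_power,
                        "MF": f.mean_frequency,
                    }
                )
            endpoint_frames.append(res["endpoints"])
            with h5py.File(cdir / f"{recipe.label}.h5", "w") as h5:
                h5.attrs.update(
                    {
                        "task": condition.task_id,
                        "system": condition.system.name,
                        "apod": condition.apod.level,
                        "observer": recipe.label,
                        "theta": res["theta"],
                    }
                )
                h5.create_dataset("classification_image", data=res["ci"].image)
                h5.create_dataset("classification_image_unapod", data=res["ci_unapod"].image)
            spec_df = pd.DataFrame(
                {
                    "f_cyc_per_mm": res["spectrum"].freq,
                    "apodized": res["spectrum"].values,
                    "unapodized": res["spectrum_unapod"].values,
                }
            )
            spec_df.to_csv(cdir / f"{recipe.label}_spectrum.csv", index=False)
        log.info("finished condition %s", condition.label)
    pd.DataFrame(perf_rows).to_csv(out / "performance.csv", index=False)
    pd.DataFrame(feat_rows).to_csv(out / "features.csv", index=False)
    if endpoint_frames:
        pd.concat(endpoint_frames, ignore_index=True).to_csv(out / "endpoints.csv", index=False)
    analytic_system_table().to_csv(out / "system_table.csv", index=False)
    report_tables(out)
    return out


def analytic_system_table(target_sd: float = 166.5) -> pd.DataFrame:
    """Analytic resolution (10%-of-max) and pixel SD per system x apodization."""
    from .imaging_chain import NoiseModel, calibrate_noise_scale

    noise = calibrate_noise_scale(NoiseModel(), target_sd)
    rows = []
    for sysspec in (SYSTEM1, SYSTEM2):
        for level in APOD_LEVELS:
            apod = ApodizationSpec.for_level(level, sysspec)
            rows.append(
                {
                    "system": sysspec.name,
                    "apod": level,
                    "resolution_cyc_per_mm": round(resolution_10pct(sysspec, apod), 4),
                    "pixel_sd_hu": round(pixel_sd_analytic(noise, apod), 2),
                }
            )
    return pd.DataFrame(rows)


def report_tables(outdir: str | Path) -> list[Path]:
    """Regenerate summary figures/tables from the logged CSVs alone."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(outdir)
    made = []
    perf_path = out / "performance.csv"
    if perf_path.exists():
        perf = pd.read_csv(perf_path)
        fig, ax = plt.subplots(figsize=(5, 5))
        by_cond = perf.groupby("condition")[["efficiency", "sampling_efficiency"]].mean()
        ax.scatter(by_cond["sampling_efficiency"], by_cond["efficiency"])
        lim = max(1.0, by_cond.to_numpy().max() * 1.05)
        ax.plot([0, lim], [0, lim], "k--", lw=0.8)
        ax.set_xlabel("sampling efficiency")
        ax.set_ylabel("observer efficiency")
        fig.tight_layout()
        p = out / "efficiency_scatter.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        made.append(p)
    feat_path = out / "features.csv"
    if feat_path.exists():
        feats = pd.read_csv(feat_path)
        fig, axes = plt.subplots(1, 2, figsize=(9, 4), sharex=True)
        for ax, col in zip(axes, ("IP", "MF")):
            for (variant, task), df in feats.groupby(["variant", "task"]):
                m = df.groupby("apod")[col].mean()
                ax.plot(m.index, m.values, marker="o", label=f"{task} {variant}")
            ax.set_xlabel("apodization level")
            ax.set_ylabel(col)
        axes[0].legend(fontsize=7)
        fig.tight_layout()
        p = out / "feature_trends.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        made.append(p)
    summary = {"tables": [str(p.name) for p in made]}
    (out / "report.json").write_text(json.dumps(summary, indent=2))
    return made
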