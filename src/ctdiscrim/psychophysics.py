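"""The 2AFC experiment engine: staircase training, testing, and endpoints.

Training uses a 3-down-1-up staircase on the task parameter: three correct
answers in a row shrink it by 15%, any error grows it by 15%.  The asymptotic
convergence point of this rule is the parameter where the probability of
three consecutive correct answers is 1/2, i.e. per-trial PC = 0.5^(1/3) ~
0.794 — "approximately 80% correct".  Six staircase runs are performed per
condition; the threshold is the geometric mean of the reversal values pooled
over the last five runs (geometric because the steps are multiplicative).

Testing runs a long block of fresh 2AFC trials (2000 in the full study) at
the trained threshold.  Endpoints per condition are proportion correct,
detectability ``d = sqrt(2) * Phi^-1(PC)``, threshold contrast energy and its
PC-corrected form, and efficiency against the Ideal Observer.  Per-session
tables (5 staircase-run log-energies, 10 x 200-trial log-efficiencies) are
emitted for external mixed-model analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .gridspec import PIXEL_AREA_MM2
from .imaging_chain import Condition, StimulusPair
from .observer_models import (
    ObserverSpec,
    decide_2afc,
    effective_snr,
    io_template,
    response_sd,
    template_snr,
)

__all__ = [
    "StaircaseRun",
    "StaircaseResult",
    "TrialRecord",
    "TestingResult",
    "PerformanceSummary",
    "run_staircase",
    "run_testing_block",
    "contrast_energy",
    "detectability",
    "corrected_threshold_energy",
    "efficiency",
    "condition_io_snr",
    "make_analytic_responder",
    "make_stimulus_responder",
    "summarize_performance",
    "session_endpoints",
]

#: targeted proportion correct of the 3-down-1-up rule, 0.5**(1/3)
STAIRCASE_TARGET_PC = 0.5 ** (1.0 / 3.0)


@dataclass
class StaircaseRun:
    thetas: list[float] = field(default_factory=list)
    outcomes: list[int] = field(default_factory=list)
    reversals: list[float] = field(default_factory=list)

    @property
    def flagged(self) -> bool:
        """True when the run produced too few reversals to be informative."""
        return len(self.reversals) < 2


@dataclass
class StaircaseResult:
    threshold: float
    runs: list[StaircaseRun]
    discard_reversals: int = 2

    def _kept(self, run: StaircaseRun) -> list[float]:
        return run.reversals[self.discard_reversals :]

    @property
    def run_thresholds(self) -> list[float]:
        """Per-run geometric-mean reversal theta for the pooled (last) runs."""
        return [
            float(np.exp(np.mean(np.log(self._kept(r)))))
            for r in self.runs_used
            if self._kept(r)
        ]

    @property
    def runs_used(self) -> list[StaircaseRun]:
        return self.runs[1:] if len(self.runs) > 1 else self.runs


def run_staircase(
    respond: Callable[[float, np.random.Generator], int],
    theta0: float,
    rng: np.random.Generator,
    n_runs: int = 6,
    trials_per_run: int = 80,
    step: float = 0.15,
    n_down: int = 3,
    pool_last: int = 5,
    discard_reversals: int = 2,
) -> StaircaseResult:
    """Run a 3-down-1-up staircase and estimate the ~79%-correct threshold.

    ``respond(theta, rng)`` plays one trial and returns 1 (correct) or 0.
    Each run restarts from the suprathreshold ``theta0``.  The threshold is
    the geometric mean of reversal values pooled over the last ``pool_last``
    runs, discarding the first ``discard_reversals`` reversals of each run
    (the transient of the descent from the suprathreshold start, which
    otherwise biases the estimate toward easy values).
    """
    if theta0 <= 0:
        raise ValueError("initial theta must be positive")
    runs: list[StaircaseRun] = []
    for _ in range(n_runs):
        run = StaircaseRun()
        theta = float(theta0)
        streak = 0
        last_dir = 0  # +1 theta increasing, -1 decreasing
        for _ in range(trials_per_run):
            out = int(respond(theta, rng))
            run.thetas.append(theta)
            run.outcomes.append(out)
            direction = 0
            if out:
                streak += 1
                if streak >= n_down:
                    direction = -1
                    streak = 0
            else:
                streak = 0
                direction = +1
            if direction:
                if last_dir and direction != last_dir:
                    run.reversals.append(theta)
                last_dir = direction
                theta *= (1.0 - step) if direction < 0 else (1.0 + step)
        runs.append(run)
    pooled = [th for r in runs[-pool_last:] for th in r.reversals[discard_reversals:]]
    if not pooled:
        # degenerate runs (too few reversals) are flagged; fall back to the
        # final theta of each pooled run so the engine still returns a value
        pooled = [r.thetas[-1] for r in runs[-pool_last:]]
    threshold = float(np.exp(np.mean(np.log(pooled))))
    return StaircaseResult(threshold=threshold, runs=runs, discard_reversals=discard_reversals)


@dataclass
class TrialRecord:
    """One completed 2AFC trial, with optional retained noise fields."""

    index: int
    outcome: int
    theta: float
    seed: object = None
    noise_diff: np.ndarray | None = None  # n+ - n- (apodized, spatial)
    noise_diff_unapod: np.ndarray | None = None


class ClassificationAccumulator:
    """Streaming sums for classification images over a testing block.

    The score-weighted field average requires sums of ``(n+ - n-)`` and of
    ``outcome * (n+ - n-)`` in the frequency domain; storing only these two
    accumulators (for the apodized and the matched unapodized fields) keeps
    memory constant over arbitrarily long blocks.
    """

    def __init__(self, shape=(128, 128)):
        self.n = 0
        self.sum_field = np.zeros(shape, dtype=complex)
        self.sum_scored = np.zeros(shape, dtype=complex)
        self.sum_field_unapod = np.zeros(shape, dtype=complex)
        self.sum_scored_unapod = np.zeros(shape, dtype=complex)

    def add(self, outcome: int, pair: StimulusPair) -> None:
        d = np.fft.fft2(pair.noise_target - pair.noise_alternative)
        du = np.fft.fft2(pair.noise_target_unapod - pair.noise_alternative_unapod)
        self.sum_field += d
        self.sum_field_unapod += du
        if outcome:
            self.sum_scored += d
            self.sum_scored_unapod += du
        self.n += 1


@dataclass
class TestingResult:
    pc: float
    outcomes: np.ndarray
    theta: float
    flagged_retrain: bool
    records: list[TrialRecord] | None = None
    accumulator: ClassificationAccumulator | None = None
    condition: Condition | None = None
    observer: ObserverSpec | None = None


def run_testing_block(
    obs: ObserverSpec,
    condition: Condition,
    theta: float,
    rng: np.random.Generator,
    n_trials: int = 2000,
    collect: str = "accumulate",
    retrain_pc: float = 0.90,
) -> TestingResult:
    """Run a block of fresh 2AFC trials at a fixed task parameter.

    ``collect`` controls what is retained for classification-image analysis:
    ``'accumulate'`` (streaming sums; constant memory), ``'records'`` (per-
    trial noise-field differences) or ``'none'``.  Conditions whose observed
    PC exceeds ``retrain_pc`` are flagged for re-training per the repeat rule.
    """
    if collect not in ("accumulate", "records", "none"):
        raise ValueError("collect must be 'accumulate', 'records' or 'none'")
    resp_sd = response_sd(obs.template, condition.noise, condition.apod, condition.display)
    outcomes = np.zeros(n_trials, dtype=np.int8)
    acc = ClassificationAccumulator() if collect == "accumulate" else None
    records: list[TrialRecord] | None = [] if collect == "records" else None
    for j in range(n_trials):
        pair = condition.render_trial(theta, rng)
        out = decide_2afc(obs, pair, rng, resp_sd=resp_sd)
        outcomes[j] = out
        if acc is not None:
            acc.add(out, pair)
        if records is not None:
            records.append(
                TrialRecord(
                    index=j,
                    outcome=out,
                    theta=float(theta),
                    noise_diff=(pair.noise_target - pair.noise_alternative).astype(np.float32),
                    noise_diff_unapod=(
                        pair.noise_target_unapod - pair.noise_alternative_unapod
                    ).astype(np.float32),
                )
            )
    pc = float(outcomes.mean())
    return TestingResult(
        pc=pc,
        outcomes=outcomes,
        theta=float(theta),
        flagged_retrain=pc > retrain_pc,
        records=records,
        accumulator=acc,
        condition=condition,
        observer=obs,
    )


def contrast_energy(mu_target: np.ndarray, mu_alternative: np.ndarray) -> float:
    """Pixel area times summed squared mean difference, HU^2 mm^2."""
    d = np.asarray(mu_target, float) - np.asarray(mu_alternative, float)
    return float(PIXEL_AREA_MM2 * (d**2).sum())


def detectability(pc: float) -> float:
    """2AFC detectability index ``d = sqrt(2) * Phi^-1(PC)``."""
    if not 0.0 < pc < 1.0:
        raise ValueError("PC must lie strictly between 0 and 1")
    return float(np.sqrt(2.0) * norm.ppf(pc))


def corrected_threshold_energy(e_c: float, pc_observed: float, pc_target: float = 0.80) -> float:
    """Rescale threshold energy from the observed PC to the target PC."""
    d_t = detectability(pc_target)
    d_o = detectability(pc_observed)
    return float(e_c * (d_t / d_o) ** 2)


def efficiency(pc_observed: float, snr_io: float) -> float:
    """Squared ratio of observed detectability to Ideal-Observer SNR."""
    if snr_io <= 0:
        raise ValueError("snr_io must be positive")
    return float((detectability(pc_observed) / snr_io) ** 2)


def condition_io_snr(condition: Condition, theta: float) -> float:
    """SNR of the Ideal Observer at the tested task parameter."""
    mu_t, mu_a = condition.mean_images(theta)
    w_io = io_template(mu_t, mu_a, condition.noise, condition.apod, condition.display)
    return template_snr(w_io, mu_t, mu_a, condition.noise, condition.apod, condition.display)


def make_analytic_responder(
    obs: ObserverSpec, condition: Condition
) -> Callable[[float, np.random.Generator], int]:
    """Bernoulli responder using the closed-form 2AFC psychometric function.

    For a linear observer in Gaussian noise, PC(theta) =
    Phi(SNR_eff(theta)/sqrt(2)); SNR values are cached per theta, since
    staircase thetas revisit a multiplicative lattice.
    """
    cache: dict[float, float] = {}

    def respond(theta: float, rng: np.random.Generator) -> int:
        key = float(theta)
        if key not in cache:
            cache[key] = effective_snr(obs, condition, key)
        pc = norm.cdf(cache[key] / np.sqrt(2.0))
        return int(rng.random() < pc)

    return respond


def make_stimulus_responder(
    obs: ObserverSpec, condition: Condition
) -> Callable[[float, np.random.Generator], int]:
    """Responder that renders full image stimuli and applies the observer."""
    resp_sd = response_sd(obs.template, condition.noise, condition.apod, condition.display)

    def respond(theta: float, rng: np.random.Generator) -> int:
        pair = condition.render_trial(theta, rng)
        return decide_2afc(obs, pair, rng, resp_sd=resp_sd)

    return respond


@dataclass
class PerformanceSummary:
    condition_label: str
    observer_label: str
    theta: float
    pc: float
    d: float
    e_c: float
    e_c_corrected: float
    snr_io: float
    eta: float

    def to_dict(self) -> dict:
        return {
            "condition": self.condition_label,
            "observer": self.observer_label,
            "theta": self.theta,
            "pc": self.pc,
            "d": self.d,
            "contrast_energy": self.e_c,
            "contrast_energy_corrected": self.e_c_corrected,
            "snr_io": self.snr_io,
            "efficiency": self.eta,
        }


def summarize_performance(
    condition: Condition, obs: ObserverSpec, testing: TestingResult
) -> PerformanceSummary:
    """Collapse a testing block into the standard performance endpoints."""
    mu_t, mu_a = condition.mean_images(testing.theta)
    e_c = contrast_energy(mu_t, mu_a)
    snr_io = condition_io_snr(condition, testing.theta)
    return PerformanceSummary(
        condition_label=condition.label,
        observer_label=obs.label,
        theta=testing.theta,
        pc=testing.pc,
        d=detectability(testing.pc),
        e_c=e_c,
        e_c_corrected=corrected_threshold_energy(e_c, testing.pc),
        snr_io=snr_io,
        eta=efficiency(testing.pc, snr_io),
    )


def session_endpoints(
    condition: Condition,
    obs: ObserverSpec,
    staircase: StaircaseResult,
    testing: TestingResult,
    session_trials: int = 200,
) -> pd.DataFrame:
    """Per-session endpoint table for external mixed-model analysis.

    Emits one log-threshold-energy row per pooled staircase run and one
    log-efficiency row per block of ``session_trials`` consecutive testing
    trials (10 sessions for a 2000-trial block).
    """
    rows = []
    for s, th in enumerate(staircase.run_thresholds):
        mu_t, mu_a = condition.mean_images(th)
        rows.append(
            {
                "condition": condition.label,
                "observer": obs.label,
                "endpoint": "log_threshold_energy",
                "session": s,
                "value": float(np.log(contrast_energy(mu_t, mu_a))),
            }
        )
    snr_io = condition_io_snr(condition, testing.theta)
    n_sessions = len(testing.outcomes) // session_trials
    for s in range(n_sessions):
        pc = float(testing.outcomes[s * session_trials : (s + 1) * session_trials].mean())
        pc = min(max(pc, 0.5 / session_trials), 1.0 - 0.5 / session_trials)
        rows.append(
            {
                "condition": condition.label,
                "observer": obs.label,
                "endpoint": "log_efficiency",
                "session": s,
                "value": float(np.log(efficiency(pc, snr_io))),
            }
        )
    return pd.DataFrame(rows)
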