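"""Trial loop, curricula execution, criterion tracking and greedy evaluation.

A trial runs the three learning phases: relax the network on the encoded
stimulus, sample an action from the softmax over the motor potentials,
propagate the accessory activity from the winner, compute the
reward-prediction error and apply the three-factor weight update.
Training is considered successful when the greedy policy (argmax motor
potential, evaluated on each training trial's converged potentials) is
correct on a configurable number of consecutive stimulus presentations
(default 400).
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.ndimage as ndi

from . import architectures, learning, tasks
from .dynamics import relax_to_fixed_point
from .params import ModelParams
from .weights import WeightSet

logger = logging.getLogger(__name__)


@dataclass
class TrainConfig:
    """Everything a training run needs besides the architecture itself."""

    task: str = "tracing"
    eta: float = 0.02
    tau: float = 0.15
    reward: float = 0.8
    criterion_window: int = 400
    stop_on_criterion: bool = True
    trial_cap: int = 300_000
    phase_cap: int = 50_000
    seed: int = 0
    accessory_method: str = "solve"

    def validate(self, prm: ModelParams) -> None:
        if self.task not in ("contour", "tracing"):
            raise ValueError(f"task must be 'contour' or 'tracing', got {self.task!r}")
        if self.tau <= 0:
            raise ValueError(f"tau must be > 0, got {self.tau}")
        if self.eta < 0:
            raise ValueError(f"eta must be >= 0, got {self.eta}")
        if not 0 < self.reward < prm.beta:
            raise ValueError(
                f"reward must lie in (0, beta={prm.beta}), got {self.reward}"
            )
        if self.criterion_window < 1:
            raise ValueError("criterion_window must be >= 1")


@dataclass
class TrialLog:
    """Append-only per-trial records of a training run."""

    records: list = field(default_factory=list)

    def append(self, **kw) -> None:
        self.records.append(kw)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame.from_records(self.records)

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class TrainResult:
    weights: WeightSet
    log: pd.DataFrame
    reached_criterion: bool
    trials_used: int
    spec: architectures.ArchitectureSpec


def trial_rng(master_seed: int, trial: int, stream: str) -> np.random.Generator:
    """Deterministic per-trial generator derived from the master seed.

    Replaying (seed, trial index, stream) regenerates the identical
    stimulus or action draw.
    """
    ss = np.random.SeedSequence(
        entropy=master_seed,
        spawn_key=(zlib.crc32(stream.encode("utf8")) & 0x7FFFFFFF, trial),
    )
    return np.random.default_rng(ss)


def run_trial(
    weights: WeightSet,
    spec: architectures.ArchitectureSpec,
    stimulus,
    prm: ModelParams,
    config: TrainConfig,
    rng: np.random.Generator,
    learn: bool = True,
):
    """Run one trial (phases 1-3) and update the weights in place.

    Returns ``(outcome, record)`` where ``record`` is a dict of the
    per-trial log fields.  On non-convergence the learning update is
    skipped and the trial flagged.
    """
    I_inp = tasks.encode_stimulus(stimulus, spec)
    state = relax_to_fixed_point(weights, I_inp, prm)
    motor = spec.layer_slice("motor")
    motor_p = state.p[motor]
    outcome = learning.select_action_softmax(motor_p, config.tau, rng)
    greedy = int(np.argmax(motor_p))
    outcome.reward = tasks.reward_for(stimulus, outcome.chosen, config.reward)
    outcome.rpe = learning.reward_prediction_error(
        outcome.reward, motor_p[outcome.chosen]
    )
    updated = False
    if learn and state.converged and config.eta > 0 and outcome.rpe != 0.0:
        adj = learning.linearize_at_fixed_point(state, weights, prm)
        accessory = learning.propagate_accessory(
            adj, motor.start + outcome.chosen, prm, method=config.accessory_method
        )
        learning.apply_weight_update(
            weights, state, accessory, outcome.rpe, config.eta, I_inp, prm
        )
        updated = True
    if isinstance(stimulus, tasks.ContourStimulus):
        length = stimulus.contour_length
    else:
        length = max(len(stimulus.target_path), 1)
    record = dict(
        length=length,
        chosen=outcome.chosen,
        correct=stimulus.correct_action,
        greedy_correct=bool(greedy == stimulus.correct_action),
        reward=outcome.reward,
        rpe=outcome.rpe,
        steps=state.steps_used,
        converged=bool(state.converged),
        updated=updated,
    )
    return outcome, record


def train(
    config: TrainConfig,
    prm: ModelParams | None = None,
    spec: architectures.ArchitectureSpec | None = None,
    weights: WeightSet | None = None,
    curriculum: tasks.Curriculum | None = None,
) -> TrainResult:
    """Execute a curriculum and then the full task until the criterion.

    The consecutive-greedy-correct criterion is tracked only in the final
    (full-task) phase and resets on any greedy-incorrect or non-converged
    trial.  Stops at ``trial_cap`` if the criterion is not reached.
    """
    prm = prm or ModelParams()
    config.validate(prm)
    if spec is None:
        spec = (
            architectures.build_contour_network()
            if config.task == "contour"
            else architectures.build_tracing_network()
        )
    if weights is None:
        weights = architectures.init_weights(
            spec, np.random.default_rng(np.random.SeedSequence(config.seed))
        )
    if curriculum is None:
        curriculum = (
            tasks.contour_curriculum()
            if config.task == "contour"
            else tasks.tracing_curriculum()
        )
    grid = spec.meta["grid"]
    log = TrialLog()
    trial = 0
    streak = 0
    reached = False
    final_phase = len(curriculum.phases) - 1

    for phase_idx, phase in enumerate(curriculum.phases):
        is_final = phase_idx == final_phase
        phase_trials = 0
        window: list[bool] = []
        while trial < config.trial_cap:
            stim_rng = trial_rng(config.seed, trial, "stimulus")
            act_rng = trial_rng(config.seed, trial, "action")
            stimulus = tasks.draw_stimulus(
                config.task, phase.stimulus_params, stim_rng, grid
            )
            _, record = run_trial(weights, spec, stimulus, prm, config, act_rng)
            record.update(trial=trial, phase=phase.name)
            log.append(**record)
            trial += 1
            phase_trials += 1
            ok = record["greedy_correct"] and record["converged"]
            if is_final:
                streak = streak + 1 if ok else 0
                if streak >= config.criterion_window:
                    reached = True
                    if config.stop_on_criterion:
                        break
            else:
                window.append(ok)
                if phase.n_trials is not None:
                    if phase_trials >= phase.n_trials:
                        break
                elif phase.advance_window is not None:
                    if len(window) >= phase.advance_window and (
                        np.mean(window[-phase.advance_window:])
                        >= phase.advance_threshold
                    ):
                        break
                if phase_trials >= config.phase_cap:
                    logger.warning(
                        "phase %s hit the per-phase cap (%d trials) without "
                        "meeting its advancement rule",
                        phase.name,
                        config.phase_cap,
                    )
                    break
        if reached or trial >= config.trial_cap:
            break

    return TrainResult(
        weights=weights,
        log=log.to_frame(),
        reached_criterion=reached,
        trials_used=trial,
        spec=spec,
    )


def evaluate_greedy(
    weights: WeightSet,
    spec: architectures.ArchitectureSpec,
    prm: ModelParams,
    stimulus_params: dict,
    n_stimuli: int,
    rng: np.random.Generator,
    task: str | None = None,
) -> float:
    """Fraction of fresh stimuli answered correctly by the greedy policy.

    No learning takes place; the choice is the argmax motor potential at
    the converged state.
    """
    task = task or spec.task
    motor = spec.layer_slice("motor")
    grid = spec.meta["grid"]
    correct = 0
    for _ in range(n_stimuli):
        stimulus = tasks.draw_stimulus(task, stimulus_params, rng, grid)
        I_inp = tasks.encode_stimulus(stimulus, spec)
        state = relax_to_fixed_point(weights, I_inp, prm)
        if int(np.argmax(state.p[motor])) == stimulus.correct_action:
            correct += 1
    return correct / n_stimuli


def smooth_learning_curve(series: np.ndarray, sigma: float = 100.0) -> np.ndarray:
    """Gaussian smoothing of a per-trial indicator (or any) series."""
    if sigma <= 0:
        raise ValueError(f"sigma must be > 0, got {sigma}")
    return ndi.gaussian_filter1d(np.asarray(series, dtype=float), sigma, mode="nearest")
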