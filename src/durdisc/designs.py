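"""Experimental designs: constant-stimuli trial sequences and weighted up-down staircases."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np

from . import models
from .models import IRMObserver, IRMState, Observer, perceive

__all__ = [
    "ORDERS",
    "TrialSpec",
    "ResponseRecord",
    "ConstantStimuliDesign",
    "StaircaseConfig",
    "StaircaseRun",
    "c_grid",
    "build_design",
    "run_constant_stimuli",
    "staircase_step",
    "run_staircase",
    "staircase_dl",
]

ORDERS = ("sc", "cs")
STIMULUS_TYPES = ("filled", "empty")

#: preset comparison grids keyed by the standard duration (ms)
_C_GRID_PRESETS = {
    80.0: tuple(np.arange(20.0, 141.0, 15.0)),
    500.0: tuple(np.arange(300.0, 701.0, 50.0)),
}


@dataclass(frozen=True)
class TrialSpec:
    """One two-interval trial: which durations are shown, in which order."""

    standard: float
    comparison: float
    order: str  # 'sc' = standard first, 'cs' = comparison first
    isi: float = 900.0
    stimulus_type: str = "filled"
    block: int = 0
    trial_in_block: int = 0

    def __post_init__(self) -> None:
        if self.order not in ORDERS:
            raise ValueError(f"order must be one of {ORDERS}, got {self.order!r}")

    @property
    def first_duration(self) -> float:
        return self.standard if self.order == "sc" else self.comparison

    @property
    def second_duration(self) -> float:
        return self.comparison if self.order == "sc" else self.standard


@dataclass(frozen=True)
class ResponseRecord:
    """A trial plus the binary judgment (and, optionally, the latent draws)."""

    trial: TrialSpec
    response_c_longer: bool
    x1: Optional[float] = None
    x2: Optional[float] = None
    reference: Optional[float] = None
    observer_id: int = 0
    experiment: str = ""


@dataclass(frozen=True)
class ConstantStimuliDesign:
    """Method-of-constant-stimuli session layout.

    Trial types are all (comparison level, order) pairs; each type appears
    ``reps_per_block`` times per block, shuffled within block.
    """

    standard: float
    c_levels: Tuple[float, ...]
    reps_per_block: int = 2
    n_blocks: int = 20
    isi: float = 900.0
    stimulus_type: str = "filled"
    seed: int = 0

    def __post_init__(self) -> None:
        levels = np.asarray(self.c_levels, dtype=float)
        if levels.size < 2:
            raise ValueError("need at least two comparison levels")
        if not np.allclose(levels + levels[::-1], 2.0 * self.standard):
            raise ValueError("c_levels must be symmetric around the standard")

    @property
    def trials_per_block(self) -> int:
        return len(self.c_levels) * 2 * self.reps_per_block

    @property
    def n_trials(self) -> int:
        return self.trials_per_block * self.n_blocks


def c_grid(standard: float) -> Tuple[float, ...]:
    """Preset comparison grids: 9 levels symmetric around the 80 or 500 ms standard."""
    try:
        return _C_GRID_PRESETS[float(standard)]
    except KeyError:
        raise ValueError(
            f"no preset comparison grid for standard={standard}; pass an explicit grid"
        ) from None


def build_design(
    design: ConstantStimuliDesign, rng: Optional[np.random.Generator] = None
) -> List[TrialSpec]:
    """Materialize the shuffled trial list for a whole session.

    The output is a permutation of the deterministic type-by-repetition
    multiset: the seed (or the given generator) changes order only.
    """
    if rng is None:
        rng = np.random.default_rng(design.seed)
    types = [(c, order) for order in ORDERS for c in design.c_levels]
    trials: List[TrialSpec] = []
    for block in range(design.n_blocks):
        block_types = types * design.reps_per_block
        perm = rng.permutation(len(block_types))
        for slot, idx in enumerate(perm):
            c, order = block_types[idx]
            trials.append(
                TrialSpec(
                    standard=design.standard,
                    comparison=float(c),
                    order=order,
                    isi=design.isi,
                    stimulus_type=design.stimulus_type,
                    block=block,
                    trial_in_block=slot,
                )
            )
    return trials


def run_constant_stimuli(
    trials: Sequence[TrialSpec],
    observer: Observer,
    rng: np.random.Generator,
    state: Optional[IRMState] = None,
    keep_latents: bool = True,
    observer_id: int = 0,
    experiment: str = "",
) -> List[ResponseRecord]:
    """Simulate an observer through a trial sequence, in presentation order.

    For an IRM observer the internal reference is carried across all trials
    (and blocks) of the sequence; calling this separately per regime realizes
    the between-regime reset.
    """
    if not trials:
        raise ValueError("empty trial sequence")
    d1 = np.array([t.first_duration for t in trials])
    d2 = np.array([t.second_duration for t in trials])
    if (
        isinstance(observer, IRMObserver)
        and state is None
        and observer.i0_policy == "standard_mean"
    ):
        state = IRMState(reference=trials[0].standard, trial_index=0)
    batch = models.respond_batch(observer, d1, d2, rng, state=state)
    is_cs = np.array([t.order == "cs" for t in trials])
    c_longer = np.where(is_cs, batch.first_judged_longer, ~batch.first_judged_longer)
    ref = batch.reference
    return [
        ResponseRecord(
            trial=t,
            response_c_longer=bool(c_longer[i]),
            x1=float(batch.x1[i]) if keep_latents else None,
            x2=float(batch.x2[i]) if keep_latents else None,
            reference=float(ref[i]) if (keep_latents and ref is not None) else None,
            observer_id=observer_id,
            experiment=experiment,
        )
        for i, t in enumerate(trials)
    ]


@dataclass(frozen=True)
class StaircaseConfig:
    """Weighted up-down staircase settings.

    After "c judged longer" the comparison moves down by ``step_down``,
    otherwise up by ``step_up``; zero drift at P("c longer") = target_p
    requires ``step_up / step_down = target_p / (1 - target_p)``.
    """

    target_p: float
    step_down: float
    step_up: float
    start_c: float
    n_trials: int = 60
    floor: float = 0.0
    ceiling: Optional[float] = None
    forbid_crossing_standard: bool = False
    estimator: str = "last_k_mean"
    k: int = 20

    def __post_init__(self) -> None:
        if not 0.0 < self.target_p < 1.0:
            raise ValueError("target_p must lie in (0, 1)")
        if self.step_down <= 0 or self.step_up <= 0:
            raise ValueError("step sizes must be positive")
        if self.floor > self.start_c:
            raise ValueError("floor must not exceed start_c")
        if self.estimator not in ("reversal_mean", "last_k_mean"):
            raise ValueError(f"unknown estimator {self.estimator!r}")
        if self.estimator == "last_k_mean" and self.n_trials < self.k:
            raise ValueError("n_trials must be >= k for last_k_mean")

    @classmethod
    def weighted_up_down(
        cls, target_p: float, base_step: float, start_c: float, **kwargs
    ) -> "StaircaseConfig":
        """Build a config with the zero-drift step ratio for ``target_p``.

        The smaller of the two steps equals ``base_step``: for an upper run
        (target .75) step_up = 3 * base_step, for a lower run (target .25)
        step_down = 3 * base_step.
        """
        ratio = target_p / (1.0 - target_p)
        if ratio >= 1.0:
            step_down, step_up = base_step, base_step * ratio
        else:
            step_down, step_up = base_step / ratio, base_step
        return cls(
            target_p=target_p,
            step_down=step_down,
            step_up=step_up,
            start_c=start_c,
            **kwargs,
        )


def staircase_step(
    current_c: float,
    response_c_longer: bool,
    config: StaircaseConfig,
    standard: Optional[float] = None,
) -> float:
    """Next comparison value after one response, honouring floor/ceiling/crossing.

    With ``forbid_crossing_standard`` the run must stay strictly on its
    starting side of the standard: a move that would land on or beyond the
    standard is rejected and the comparison stays put.
    """
    nxt = (
        current_c - config.step_down
        if response_c_longer
        else current_c + config.step_up
    )
    nxt = max(nxt, config.floor)
    if config.ceiling is not None:
        nxt = min(nxt, config.ceiling)
    if config.forbid_crossing_standard and standard is not None:
        below = config.start_c < standard
        if (below and nxt >= standard) or (not below and nxt <= standard):
            nxt = current_c
    return nxt


@dataclass(frozen=True)
class StaircaseRun:
    """A completed staircase: the presented track, responses, and the estimate."""

    config: StaircaseConfig
    order: str
    standard: float
    c_sequence: np.ndarray
    responses: np.ndarray
    reversals: Tuple[int, ...]
    estimate: float
    valid: bool
    final_state: Optional[IRMState] = None


def run_staircase(
    config: StaircaseConfig,
    observer: Observer,
    standard: float,
    rng: np.random.Generator,
    order: str = "sc",
    isi: float = 900.0,
    state: Optional[IRMState] = None,
) -> StaircaseRun:
    """Run one adaptive track against an observer.

    Pass ``state`` (and reuse ``run.final_state``) to carry the IRM reference
    across the blocked runs of a session — this persistence is what makes the
    blocked staircase dialect bias-prone.
    """
    if order not in ORDERS:
        raise ValueError(f"order must be one of {ORDERS}")
    if (
        isinstance(observer, IRMObserver)
        and state is None
        and observer.i0_policy == "standard_mean"
    ):
        state = IRMState(reference=standard, trial_index=0)
    c = float(config.start_c)
    cs: List[float] = []
    resp: List[bool] = []
    for _ in range(config.n_trials):
        d1, d2 = (standard, c) if order == "sc" else (c, standard)
        _, _, outcome, state = models.respond_trial(observer, d1, d2, rng, state=state)
        c_longer = (
            outcome.first_judged_longer
            if order == "cs"
            else not outcome.first_judged_longer
        )
        cs.append(c)
        resp.append(bool(c_longer))
        c = staircase_step(c, c_longer, config, standard=standard)
    c_seq = np.asarray(cs)
    responses = np.asarray(resp)
    # intended movement flips sign exactly when the response changes
    reversals = tuple(
        int(i) for i in range(1, len(resp)) if resp[i] != resp[i - 1]
    )
    if config.estimator == "reversal_mean":
        if reversals:
            estimate, valid = float(c_seq[list(reversals)].mean()), True
        else:
            estimate, valid = float("nan"), False
    else:
        estimate, valid = float(c_seq[-config.k :].mean()), True
    return StaircaseRun(
        config=config,
        order=order,
        standard=standard,
        c_sequence=c_seq,
        responses=responses,
        reversals=reversals,
        estimate=estimate,
        valid=valid,
        final_state=state if isinstance(observer, IRMObserver) else None,
    )


def run_staircase_set(
    configs: Sequence[Tuple[StaircaseConfig, str]],
    observer: Observer,
    standard: float,
    rng: np.random.Generator,
    interleave: bool = False,
    state: Optional[IRMState] = None,
) -> List[StaircaseRun]:
    """Run several staircases in one session, sharing the IRM reference.

    ``configs`` pairs each staircase with its stimulus order.  Blocked mode
    (default) runs them one after another; interleaved mode draws the next
    track at random trial by trial, which prevents the internal reference from
    adapting to any single track's local comparison level.
    """
    if not interleave:
        runs = []
        for config, order in configs:
            run = run_staircase(
                config, observer, standard, rng, order=order, state=state
            )
            state = run.final_state
            runs.append(run)
        return runs

    if (
        isinstance(observer, IRMObserver)
        and state is None
        and observer.i0_policy == "standard_mean"
    ):
        state = IRMState(reference=standard, trial_index=0)
    current = [float(cfg.start_c) for cfg, _ in configs]
    seqs: List[List[float]] = [[] for _ in configs]
    resps: List[List[bool]] = [[] for _ in configs]
    schedule = np.repeat(
        np.arange(len(configs)), [cfg.n_trials for cfg, _ in configs]
    )
    rng.shuffle(schedule)
    for idx in schedule:
        config, order = configs[idx]
        c = current[idx]
        d1, d2 = (standard, c) if order == "sc" else (c, standard)
        _, _, outcome, state = models.respond_trial(observer, d1, d2, rng, state=state)
        c_longer = (
            outcome.first_judged_longer
            if order == "cs"
            else not outcome.first_judged_longer
        )
        seqs[idx].append(c)
        resps[idx].append(bool(c_longer))
        current[idx] = staircase_step(c, c_longer, config, standard=standard)
    runs = []
    for i, (config, order) in enumerate(configs):
        c_seq = np.asarray(seqs[i])
        resp = resps[i]
        reversals = tuple(
            int(j) for j in range(1, len(resp)) if resp[j] != resp[j - 1]
        )
        if config.estimator == "reversal_mean":
            if reversals:
                estimate, valid = float(c_seq[list(reversals)].mean()), True
            else:
                estimate, valid = float("nan"), False
        else:
            estimate, valid = float(c_seq[-config.k :].mean()), True
        runs.append(
            StaircaseRun(
                config=config,
                order=order,
                standard=standard,
                c_sequence=c_seq,
                responses=np.asarray(resp),
                reversals=reversals,
                estimate=estimate,
                valid=valid,
                final_state=state if isinstance(observer, IRMObserver) else None,
            )
        )
    return runs


def staircase_dl(upper: StaircaseRun, lower: StaircaseRun) -> float:
    """DL estimate (c_hat_.75 - c_hat_.25) / 2; may be negative for degenerate runs."""
    if not (upper.valid and lower.valid):
        raise ValueError("both runs must carry valid estimates")
    return (upper.estimate - lower.estimate) / 2.0
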