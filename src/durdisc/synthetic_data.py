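"""Synthetic study cohorts and the two headline simulation studies.

``simulate_cohort`` emulates one full experiment (n observers, two duration
regimes, constant stimuli, Spearman-Kärber estimation, ANOVA battery).
``bias_study`` pits the bias-prone blocked staircase dialect against the
method of constant stimuli on the same generative observers.  ``recover_g``
grid-searches the internal-reference weight from trial records.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
from scipy import signal, stats

from . import designs, estimation, inference, models
from .designs import ConstantStimuliDesign, ResponseRecord, StaircaseConfig
from .estimation import PsychometricTable, SKEstimate, TypeBEffect
from .models import DifferenceObserver, IRMObserver, NoiseSpec, SWMObserver

__all__ = [
    "ParamDist",
    "CohortConfig",
    "ObserverResult",
    "ScenarioResult",
    "BiasStudyResult",
    "RecoveryResult",
    "EXPERIMENT_PRESETS",
    "simulate_cohort",
    "bias_study",
    "recover_g",
    "flat_function_filter",
    "make_observer",
]

#: experiment label -> (ISI ms, stimulus type); ISI and type are labels only
EXPERIMENT_PRESETS: Dict[str, Tuple[float, str]] = {
    "E1": (900.0, "filled"),
    "E2": (900.0, "empty"),
    "E3": (200.0, "filled"),
    "E4": (200.0, "empty"),
}

MODELS = ("difference", "irm", "swm")


@dataclass(frozen=True)
class ParamDist:
    """Truncated-normal distribution for an observer parameter."""

    mean: float
    sd: float = 0.0
    low: float = -math.inf
    high: float = math.inf

    def draw(self, rng: np.random.Generator) -> float:
        if self.sd == 0.0:
            return float(np.clip(self.mean, self.low, self.high))
        for _ in range(1000):
            x = rng.normal(self.mean, self.sd)
            if self.low <= x <= self.high:
                return float(x)
        return float(np.clip(rng.normal(self.mean, self.sd), self.low, self.high))


ParamLike = Union[float, ParamDist]

_DEFAULT_PARAMS: Dict[str, Dict[str, ParamLike]] = {
    "difference": {"gamma": 0.0, "sigma0": 10.0, "weber": 0.1},
    "irm": {"g": 0.4, "gamma": 0.0, "sigma0": 10.0, "weber": 0.1},
    "swm": {"s1": 1.0, "s2": 1.0, "gamma": 0.0, "sigma0": 10.0, "weber": 0.1},
}


def _draw_params(
    model: str, params: Mapping[str, ParamLike], rng: np.random.Generator
) -> Dict[str, float]:
    merged: Dict[str, ParamLike] = dict(_DEFAULT_PARAMS[model])
    merged.update(params)
    out = {}
    for name, value in merged.items():
        out[name] = value.draw(rng) if isinstance(value, ParamDist) else float(value)
    return out


def make_observer(model: str, params: Mapping[str, float], standard: float):
    """Instantiate an observer from drawn parameter values.

    For the SWM the reference levels default to the regime's standard.
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}; expected one of {MODELS}")
    noise = NoiseSpec(sigma0=params["sigma0"], weber=params["weber"])
    if model == "difference":
        return DifferenceObserver(gamma=params["gamma"], noise=noise)
    if model == "irm":
        return IRMObserver(
            g=params["g"],
            gamma=params["gamma"],
            noise=noise,
            i0_policy=params.get("i0_policy", "first_sensation"),
        )
    if model == "swm":
        return SWMObserver(
            s1=params["s1"],
            s2=params["s2"],
            r1=params.get("r1", standard),
            r2=params.get("r2", standard),
            gamma=params["gamma"],
            noise=noise,
        )
    raise ValueError(f"unknown model {model!r}; expected one of {MODELS}")


@dataclass(frozen=True)
class CohortConfig:
    """One synthetic experiment: observers, model, regimes, and labels."""

    n_observers: int = 40
    model: str = "irm"
    params: Mapping[str, ParamLike] = field(default_factory=dict)
    experiment: str = "E1"
    regimes: Tuple[float, ...] = (80.0, 500.0)
    reps_per_block: int = 2
    n_blocks: int = 20
    flat_threshold: float = 0.25
    keep_records: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_observers < 2:
            raise ValueError("need at least two observers")
        if self.model not in MODELS:
            raise ValueError(f"unknown model {self.model!r}")
        if self.experiment not in EXPERIMENT_PRESETS:
            raise ValueError(f"unknown experiment preset {self.experiment!r}")


@dataclass(frozen=True)
class RegimeResult:
    standard: float
    table: PsychometricTable
    est_sc: SKEstimate
    est_cs: SKEstimate
    type_b: TypeBEffect


@dataclass(frozen=True)
class ObserverResult:
    observer_id: int
    params: Dict[str, float]
    part_order: Tuple[float, ...]  # regime presentation order (counterbalanced)
    regimes: Dict[float, RegimeResult]
    excluded: bool = False
    exclusion_reason: str = ""
    records: Tuple[ResponseRecord, ...] = ()


@dataclass(frozen=True)
class ScenarioResult:
    config: CohortConfig
    observers: List[ObserverResult]
    replaced: List[ObserverResult]
    anovas: Dict[float, Dict[str, object]]

    def mean_delta_dl(self, standard: float) -> float:
        return float(
            np.mean([o.regimes[standard].type_b.delta_dl for o in self.observers])
        )

    def mean_delta_wf(self, standard: float) -> float:
        return float(
            np.mean([o.regimes[standard].type_b.delta_wf for o in self.observers])
        )


def _condition_ranges(obs_regimes: Mapping[float, RegimeResult]) -> List[float]:
    """Monotonized response range per (regime, order) condition."""
    out = []
    for rr in obs_regimes.values():
        for order in designs.ORDERS:
            p = estimation.monotonize(
                rr.table.proportions(order), rr.table.n_trials[order]
            )
            out.append(float(p.max() - p.min()))
    return out


def flat_function_filter(
    tables_by_observer: Mapping[int, Sequence[Tuple[PsychometricTable, str]]],
    threshold: float = 0.25,
) -> Dict[int, bool]:
    """Flag observers whose response range stays below ``threshold`` everywhere.

    Each observer maps to (table, order) conditions; the flag is True
    (excluded) only when every condition is flat.  ``threshold = 0`` excludes
    nobody.
    """
    flags = {}
    for obs_id, conditions in tables_by_observer.items():
        ranges = []
        for table, order in conditions:
            p = estimation.monotonize(
                table.proportions(order), table.n_trials[order]
            )
            ranges.append(float(p.max() - p.min()))
        flags[obs_id] = bool(ranges) and all(r < threshold for r in ranges)
    return flags


def _simulate_observer(
    config: CohortConfig,
    observer_id: int,
    params: Dict[str, float],
    part_order: Tuple[float, ...],
    rng: np.random.Generator,
) -> ObserverResult:
    isi, stimulus_type = EXPERIMENT_PRESETS[config.experiment]
    per_regime: Dict[float, RegimeResult] = {}
    kept: List[ResponseRecord] = []
    for standard in part_order:
        observer = make_observer(config.model, params, standard)
        design = ConstantStimuliDesign(
            standard=standard,
            c_levels=designs.c_grid(standard),
            reps_per_block=config.reps_per_block,
            n_blocks=config.n_blocks,
            isi=isi,
            stimulus_type=stimulus_type,
        )
        trials = designs.build_design(design, rng)
        # fresh state per regime: the reference resets when the standard changes
        records = designs.run_constant_stimuli(
            trials, observer, rng, keep_latents=False, observer_id=observer_id,
            experiment=config.experiment,
        )
        table = estimation.aggregate(records)
        if config.keep_records:
            kept.extend(records)
        lo, hi = estimation.default_anchors(standard, table.c_levels)
        est_sc = estimation.spearman_karber(table, lo, hi, "sc")
        est_cs = estimation.spearman_karber(table, lo, hi, "cs")
        per_regime[standard] = RegimeResult(
            standard=standard,
            table=table,
            est_sc=est_sc,
            est_cs=est_cs,
            type_b=estimation.type_b(est_sc, est_cs),
        )
    return ObserverResult(
        observer_id=observer_id,
        params=params,
        part_order=part_order,
        regimes=per_regime,
        records=tuple(kept),
    )


def simulate_cohort(config: CohortConfig) -> ScenarioResult:
    """Simulate a full cohort; flat observers are replaced by fresh draws.

    Fully deterministic given the config (including its seed).
    """
    rng = np.random.default_rng(config.seed)
    observers: List[ObserverResult] = []
    replaced: List[ObserverResult] = []
    next_id = 0
    max_draws = config.n_observers * 20
    while len(observers) < config.n_observers:
        if next_id >= max_draws:
            raise RuntimeError(
                "too many flat observers; check parameters or flat_threshold"
            )
        params = _draw_params(config.model, config.params, rng)
        part_order = (
            config.regimes if next_id % 2 == 0 else tuple(reversed(config.regimes))
        )
        obs = _simulate_observer(config, next_id, params, part_order, rng)
        next_id += 1
        if config.flat_threshold > 0 and all(
            r < config.flat_threshold for r in _condition_ranges(obs.regimes)
        ):
            replaced.append(
                replace(obs, excluded=True, exclusion_reason="flat psychometric function")
            )
            continue
        observers.append(obs)

    anovas: Dict[float, Dict[str, object]] = {}
    for standard in config.regimes:
        tables = [o.regimes[standard].table for o in observers]
        n_levels = len(tables[0].c_levels)
        props = np.empty((len(observers), n_levels, 2))
        for i, t in enumerate(tables):
            props[i, :, 0] = t.proportions("sc")
            props[i, :, 1] = t.proportions("cs")
        dls = np.array(
            [
                [o.regimes[standard].type_b.dl_sc, o.regimes[standard].type_b.dl_cs]
                for o in observers
            ]
        )
        anovas[standard] = {
            "two_way": inference.rm_anova_2way(props),
            "one_way": inference.rm_anova_1way(dls),
        }
    return ScenarioResult(
        config=config, observers=observers, replaced=replaced, anovas=anovas
    )


@dataclass(frozen=True)
class BiasStudyResult:
    """Paired Type B estimates: blocked staircase dialect vs. constant stimuli."""

    staircase_type_b: np.ndarray
    constant_stimuli_type_b: np.ndarray
    staircase_dls: np.ndarray  # columns: dl_sc, dl_cs
    interleaved: bool

    @property
    def mean_staircase(self) -> float:
        return float(self.staircase_type_b.mean())

    @property
    def mean_constant_stimuli(self) -> float:
        return float(self.constant_stimuli_type_b.mean())


def bias_study(
    n_observers: int = 200,
    model: str = "irm",
    g: float = 0.5,
    gamma: float = 0.0,
    noise: NoiseSpec = NoiseSpec(sigma0=2.0, weber=0.6),
    standard: float = 50.0,
    base_step: Optional[float] = None,
    n_trials_per_run: int = 60,
    floor: float = 0.0,
    forbid_crossing_standard: bool = True,
    estimator: str = "last_k_mean",
    k: int = 20,
    interleave: bool = False,
    c_step_fraction: float = 0.2,
    seed: int = 0,
) -> BiasStudyResult:
    """Apply both measurement procedures to the same generative observers.

    Per observer: four weighted up-down staircases (orders sc/cs x targets
    .25/.75) sharing one session (blocked by default), then a fresh 720-trial
    constant-stimuli session analyzed with Spearman-Kärber.  The defaults
    realize the bias-prone dialect: very short standard, floor at 0 ms,
    prohibition of crossing the standard, blocked runs, last-20 estimation.
    """
    rng = np.random.default_rng(seed)
    base = base_step if base_step is not None else 0.1 * standard
    step = c_step_fraction * standard
    grid = tuple(standard + step * np.arange(-4, 5))
    design = ConstantStimuliDesign(standard=standard, c_levels=grid)
    anchors = estimation.default_anchors(standard, np.asarray(grid))
    run_specs = []
    for target in (0.25, 0.75):
        for order in designs.ORDERS:
            start = standard - 4 * base if target == 0.25 else standard + 4 * base
            cfg = StaircaseConfig.weighted_up_down(
                target,
                base,
                start,
                n_trials=n_trials_per_run,
                floor=floor,
                forbid_crossing_standard=forbid_crossing_standard,
                estimator=estimator,
                k=k,
            )
            run_specs.append((cfg, order))

    params = {"g": g, "gamma": gamma, "sigma0": noise.sigma0, "weber": noise.weber,
              "s1": 1.0, "s2": 1.0}
    tb_stair, tb_cs, dl_pairs = [], [], []
    for _ in range(n_observers):
        observer = make_observer(model, params, standard)
        runs = designs.run_staircase_set(
            run_specs, observer, standard, rng, interleave=interleave
        )
        by_key = {(spec[0].target_p, spec[1]): run for spec, run in zip(run_specs, runs)}
        dl_sc = designs.staircase_dl(by_key[(0.75, "sc")], by_key[(0.25, "sc")])
        dl_cs = designs.staircase_dl(by_key[(0.75, "cs")], by_key[(0.25, "cs")])
        tb_stair.append(dl_sc - dl_cs)
        dl_pairs.append((dl_sc, dl_cs))

        observer = make_observer(model, params, standard)  # fresh state
        trials = designs.build_design(design, rng)
        records = designs.run_constant_stimuli(
            trials, observer, rng, keep_latents=False
        )
        table = estimation.aggregate(records)
        est_sc = estimation.spearman_karber(table, *anchors, "sc")
        est_cs = estimation.spearman_karber(table, *anchors, "cs")
        tb_cs.append(est_sc.dl - est_cs.dl)
    return BiasStudyResult(
        staircase_type_b=np.asarray(tb_stair),
        constant_stimuli_type_b=np.asarray(tb_cs),
        staircase_dls=np.asarray(dl_pairs),
        interleaved=interleave,
    )


@dataclass(frozen=True)
class RecoveryResult:
    g: float
    gamma: float
    sigma0: float
    log_likelihood: float
    g_grid_step: float
    identifiable: bool = True


def _session_loglik(
    records: Sequence[ResponseRecord],
    g: float,
    gamma: float,
    sigma0: float,
    weber: float,
    i0_policy: str,
) -> float:
    """Composite log-likelihood from per-trial marginal response probabilities.

    The reference is linear-Gaussian in the latent sensations, so its marginal
    mean and variance follow first-order recursions evaluated as filters; the
    cross-trial response correlation is ignored (composite likelihood).
    """
    d1 = np.array([r.trial.first_duration for r in records])
    d2 = np.array([r.trial.second_duration for r in records])
    is_cs = np.array([r.trial.order == "cs" for r in records])
    resp = np.array([r.response_c_longer for r in records])
    s1sq = (sigma0 + weber * d1) ** 2
    s2sq = (sigma0 + weber * d2) ** 2
    if i0_policy == "standard_mean":
        standard = records[0].trial.standard
        zi_mu, zi_var = g * standard, 0.0
    else:  # first trial's reference is exactly the first sensation
        zi_mu = g * d1[0]
        zi_var = g * (2.0 - g) * s1sq[0]
    mu, _ = signal.lfilter([1.0 - g], [1.0, -g], d1, zi=[zi_mu])
    var, _ = signal.lfilter([(1.0 - g) ** 2], [1.0, -(g**2)], s1sq, zi=[zi_var])
    sd_d = np.sqrt(var + s2sq)
    p_first = stats.norm.sf((gamma - (mu - d2)) / sd_d)
    p_c = np.where(is_cs, p_first, 1.0 - p_first)
    p_obs = np.where(resp, p_c, 1.0 - p_c)
    return float(np.sum(np.log(np.clip(p_obs, 1e-12, 1.0))))


def recover_g(
    records: Union[Sequence[ResponseRecord], Sequence[Sequence[ResponseRecord]]],
    g_grid: Sequence[float],
    gamma_grid: Sequence[float] = (0.0,),
    sigma0_grid: Sequence[float] = (10.0,),
    weber: float = 0.0,
    i0_policy: str = "first_sensation",
) -> RecoveryResult:
    """Grid-search maximum composite likelihood for IRM parameters.

    ``records`` is one session or a sequence of sessions (the reference
    recursion restarts at each session boundary).  The grid resolution bounds
    the precision of the estimates.
    """
    if not records:
        raise ValueError("no records")
    sessions: List[Sequence[ResponseRecord]]
    if isinstance(records[0], ResponseRecord):
        sessions = [records]  # type: ignore[list-item]
    else:
        sessions = list(records)  # type: ignore[arg-type]
    responses = [r.response_c_longer for sess in sessions for r in sess]
    g_grid = sorted(float(v) for v in g_grid)
    g_step = min(np.diff(g_grid)) if len(g_grid) > 1 else 0.0
    if len(set(responses)) < 2:
        return RecoveryResult(
            g=float("nan"), gamma=float("nan"), sigma0=float("nan"),
            log_likelihood=float("-inf"), g_grid_step=float(g_step),
            identifiable=False,
        )
    best = None
    for g in g_grid:
        if not 0.0 <= g < 1.0:
            raise ValueError("g grid values must lie in [0, 1)")
        for gamma in gamma_grid:
            for sigma0 in sigma0_grid:
                ll = sum(
                    _session_loglik(sess, g, gamma, sigma0, weber, i0_policy)
                    for sess in sessions
                )
                if best is None or ll > best[0]:
                    best = (ll, g, gamma, sigma0)
    ll, g, gamma, sigma0 = best
    return RecoveryResult(
        g=g, gamma=gamma, sigma0=sigma0, log_likelihood=ll,
        g_grid_step=float(g_step),
    )
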