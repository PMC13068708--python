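"""Trial-by-trial generative observer models for two-interval duration comparison.

Three decision processes are implemented, all operating on noisy latent
sensations of the two presented durations:

* :class:`DifferenceObserver` — compares the two sensations directly.
* :class:`IRMObserver` — compares the second sensation against an internal
  reference that is updated each trial as a weighted mix of the running
  reference and the first sensation (weight ``g``).
* :class:`SWMObserver` — weights each sensation against its own fixed
  reference level before taking the difference (weights ``s1``, ``s2``).

All observers judge the *first* stimulus longer iff the decision variable
exceeds the criterion ``gamma``; ties go to the second stimulus.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Union

import numpy as np
from scipy import signal, stats

__all__ = [
    "NoiseSpec",
    "DifferenceObserver",
    "IRMObserver",
    "SWMObserver",
    "IRMState",
    "DecisionOutcome",
    "BatchResponse",
    "perceive",
    "irm_update",
    "irm_decide",
    "swm_decide",
    "difference_decide",
    "difference_psychometric",
    "respond_trial",
    "respond_batch",
]

I0_POLICIES = ("first_sensation", "standard_mean")


@dataclass(frozen=True)
class NoiseSpec:
    """Sensory noise law: sensation SD for duration ``d`` is ``sigma0 + weber * d``."""

    sigma0: float = 10.0
    weber: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma0 < 0 or self.weber < 0:
            raise ValueError("sigma0 and weber must be non-negative")

    def sigma(self, duration):
        """Sensation SD at a physical duration (array-friendly, non-decreasing)."""
        return self.sigma0 + self.weber * np.asarray(duration, dtype=float)


@dataclass(frozen=True)
class DifferenceObserver:
    """Classic Thurstonian difference model: D = X1 - X2 compared against gamma."""

    gamma: float = 0.0
    noise: NoiseSpec = field(default_factory=NoiseSpec)


@dataclass(frozen=True)
class IRMObserver:
    """Internal-reference observer.

    The reference on trial ``n`` is ``I_n = g * I_{n-1} + (1 - g) * X1_n`` and the
    decision variable is ``D_n = I_n - X2_n``.  ``i0_policy`` controls the
    reference before any trial has been seen: ``first_sensation`` starts the
    recursion at the first trial's first sensation (no history), while
    ``standard_mean`` starts at the standard duration of the current regime.
    """

    g: float
    gamma: float = 0.0
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    i0_policy: str = "first_sensation"

    def __post_init__(self) -> None:
        if not 0.0 <= self.g < 1.0:
            raise ValueError(f"g must lie in [0, 1), got {self.g}")
        if self.i0_policy not in I0_POLICIES:
            raise ValueError(f"unknown i0_policy {self.i0_policy!r}")


@dataclass(frozen=True)
class SWMObserver:
    """Sensation-weighting observer.

    D = [s1*X1 + (1-s1)*r1] - [s2*X2 + (1-s2)*r2].  A weight below 1 draws the
    effective magnitude toward its reference level (assimilation), above 1
    pushes it away (contrast).
    """

    s1: float = 1.0
    s2: float = 1.0
    r1: float = 0.0
    r2: float = 0.0
    gamma: float = 0.0
    noise: NoiseSpec = field(default_factory=NoiseSpec)

    def __post_init__(self) -> None:
        if not (np.isfinite(self.s1) and np.isfinite(self.s2)):
            raise ValueError("s1 and s2 must be finite")
        if self.s1 < 0 or self.s2 < 0:
            raise ValueError("s1 and s2 must be non-negative")


Observer = Union[DifferenceObserver, IRMObserver, SWMObserver]


@dataclass(frozen=True)
class IRMState:
    """Running internal reference; updated exactly once per trial."""

    reference: float
    trial_index: int = 0


@dataclass(frozen=True)
class DecisionOutcome:
    """Realized decision variable and the resulting binary judgment."""

    d_value: float
    first_judged_longer: bool


def perceive(duration, noise: NoiseSpec, rng: np.random.Generator):
    """Draw a latent sensation: normal with mean ``duration`` and SD ``noise.sigma``.

    Accepts scalars or arrays.  Draws are not truncated at zero; negative
    values are legitimate latent magnitudes.
    """
    d = np.asarray(duration, dtype=float)
    if np.any(d < 0):
        raise ValueError("durations must be non-negative")
    out = rng.normal(d, noise.sigma(d))
    return float(out) if np.isscalar(duration) else out


def irm_update(state: IRMState, x1: float, g: float) -> IRMState:
    """Advance the internal reference by one trial using the first sensation."""
    if not 0.0 <= g < 1.0:
        raise ValueError(f"g must lie in [0, 1), got {g}")
    return IRMState(
        reference=g * state.reference + (1.0 - g) * x1,
        trial_index=state.trial_index + 1,
    )


def irm_decide(state: IRMState, x2: float, gamma: float) -> DecisionOutcome:
    """D = reference - x2; first judged longer iff D > gamma (ties -> second)."""
    d = state.reference - x2
    return DecisionOutcome(d_value=d, first_judged_longer=bool(d > gamma))


def swm_decide(x1: float, x2: float, obs: SWMObserver) -> DecisionOutcome:
    e1 = obs.s1 * x1 + (1.0 - obs.s1) * obs.r1
    e2 = obs.s2 * x2 + (1.0 - obs.s2) * obs.r2
    d = e1 - e2
    return DecisionOutcome(d_value=d, first_judged_longer=bool(d > obs.gamma))


def difference_decide(x1: float, x2: float, gamma: float = 0.0) -> DecisionOutcome:
    d = x1 - x2
    return DecisionOutcome(d_value=d, first_judged_longer=bool(d > gamma))


def difference_psychometric(
    standard: float, comparison: float, order: str, obs: DifferenceObserver
) -> float:
    """Closed-form P("comparison judged longer") for the difference observer.

    For order ``sc`` (standard first) this is Phi((c - s + gamma) / sigma_tot),
    for ``cs`` the sign of gamma flips; the two functions differ in location by
    ``2 * gamma`` but share their shape.  With zero total noise a step function
    (honouring the tie rule) is returned.
    """
    if order not in ("sc", "cs"):
        raise ValueError(f"order must be 'sc' or 'cs', got {order!r}")
    s, c, g = float(standard), float(comparison), obs.gamma
    sig = float(np.hypot(obs.noise.sigma(s), obs.noise.sigma(c)))
    if order == "sc":
        # c is second: "c longer" iff D = X1(s) - X2(c) <= gamma
        loc = c - s + g
        if sig == 0.0:
            return 1.0 if loc >= 0.0 else 0.0
    else:
        # c is first: "c longer" iff D = X1(c) - X2(s) > gamma
        loc = c - s - g
        if sig == 0.0:
            return 1.0 if loc > 0.0 else 0.0
    return float(stats.norm.cdf(loc / sig))


def respond_trial(
    observer: Observer,
    first_duration: float,
    second_duration: float,
    rng: np.random.Generator,
    state: Optional[IRMState] = None,
):
    """Simulate one trial; returns ``(x1, x2, outcome, new_state)``.

    ``state`` is only meaningful for :class:`IRMObserver`; pass the state
    returned from the previous call to carry the reference across trials.
    """
    x1 = perceive(first_duration, observer.noise, rng)
    x2 = perceive(second_duration, observer.noise, rng)
    if isinstance(observer, IRMObserver):
        if state is None:
            # no history yet: the first update makes I_1 = x1 exactly
            state = IRMState(reference=x1, trial_index=0)
        state = irm_update(state, x1, observer.g)
        outcome = irm_decide(state, x2, observer.gamma)
        return x1, x2, outcome, state
    if isinstance(observer, SWMObserver):
        return x1, x2, swm_decide(x1, x2, observer), None
    return x1, x2, difference_decide(x1, x2, observer.gamma), None


@dataclass(frozen=True)
class BatchResponse:
    """Vectorized simulation output for a sequence of trials."""

    first_judged_longer: np.ndarray
    d_values: np.ndarray
    x1: np.ndarray
    x2: np.ndarray
    reference: Optional[np.ndarray]
    state: Optional[IRMState]


def respond_batch(
    observer: Observer,
    first_durations,
    second_durations,
    rng: np.random.Generator,
    state: Optional[IRMState] = None,
) -> BatchResponse:
    """Simulate a whole trial sequence at once.

    Equivalent to repeated :func:`respond_trial` calls except that all first
    sensations are drawn before all second sensations (a different consumption
    of the random stream, not a different distribution).  The IRM reference
    recursion is evaluated as a first-order linear filter.
    """
    d1 = np.asarray(first_durations, dtype=float)
    d2 = np.asarray(second_durations, dtype=float)
    if d1.shape != d2.shape or d1.ndim != 1 or d1.size == 0:
        raise ValueError("first/second durations must be equal-length 1-D arrays")
    x1 = perceive(d1, observer.noise, rng)
    x2 = perceive(d2, observer.noise, rng)

    if isinstance(observer, IRMObserver):
        g = observer.g
        if state is None:
            if observer.i0_policy == "standard_mean":
                raise ValueError(
                    "standard_mean policy requires an explicit initial IRMState"
                )
            zi = np.array([g * x1[0]])
            n0 = 0
        else:
            zi = np.array([g * state.reference])
            n0 = state.trial_index
        ref, _ = signal.lfilter([1.0 - g], [1.0, -g], x1, zi=zi)
        d = ref - x2
        new_state = IRMState(reference=float(ref[-1]), trial_index=n0 + d1.size)
        return BatchResponse(d > observer.gamma, d, x1, x2, ref, new_state)

    if isinstance(observer, SWMObserver):
        e1 = observer.s1 * x1 + (1.0 - observer.s1) * observer.r1
        e2 = observer.s2 * x2 + (1.0 - observer.s2) * observer.r2
        d = e1 - e2
        return BatchResponse(d > observer.gamma, d, x1, x2, None, None)

    d = x1 - x2
    return BatchResponse(d > observer.gamma, d, x1, x2, None, None)
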