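"""Psychometric tables and Spearman-Kärber PSE/DL/WF estimation.

The Spearman-Kärber estimator treats the (monotonized, anchor-extended)
response proportions as a CDF sampled at the comparison levels and computes
the moments of the implied piecewise-uniform distribution; the DL is the
0.75 standard-normal quantile times the estimated SD.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .designs import ORDERS, ResponseRecord

__all__ = [
    "Z75",
    "PsychometricTable",
    "SKEstimate",
    "TypeBEffect",
    "aggregate",
    "monotonize",
    "spearman_karber",
    "dl_from_quartiles",
    "type_b",
    "default_anchors",
]

#: exact multiplier relating DL to the psychometric SD (0.6745 to 4 decimals)
Z75 = float(stats.norm.ppf(0.75))

#: anchor presets: c values where the response probability is assumed 0 and 1
_ANCHOR_PRESETS: Dict[float, Tuple[float, float]] = {
    80.0: (0.0, 160.0),
    500.0: (200.0, 800.0),
}


@dataclass(frozen=True)
class PsychometricTable:
    """Per (order, comparison level) counts of "c judged longer"."""

    standard: float
    c_levels: np.ndarray
    n_trials: Dict[str, np.ndarray]
    n_c_longer: Dict[str, np.ndarray]
    isi: Optional[float] = None
    stimulus_type: Optional[str] = None

    def proportions(self, order: str) -> np.ndarray:
        return self.n_c_longer[order] / self.n_trials[order]


def aggregate(records: Sequence[ResponseRecord]) -> PsychometricTable:
    """Tally "c judged longer" counts by (order, comparison level).

    All records must come from a single regime (one standard duration).
    """
    if not records:
        raise ValueError("no records to aggregate")
    standards = {r.trial.standard for r in records}
    if len(standards) > 1:
        raise ValueError(f"records mix regimes with standards {sorted(standards)}")
    standard = standards.pop()
    c_levels = np.array(sorted({r.trial.comparison for r in records}))
    index = {c: i for i, c in enumerate(c_levels)}
    n_trials = {o: np.zeros(len(c_levels), dtype=int) for o in ORDERS}
    n_longer = {o: np.zeros(len(c_levels), dtype=int) for o in ORDERS}
    for r in records:
        i = index[r.trial.comparison]
        n_trials[r.trial.order][i] += 1
        n_longer[r.trial.order][i] += int(r.response_c_longer)
    for o in ORDERS:
        if np.any(n_trials[o] == 0):
            raise ValueError(f"order {o!r} has comparison levels without trials")
    first = records[0].trial
    return PsychometricTable(
        standard=standard,
        c_levels=c_levels,
        n_trials=n_trials,
        n_c_longer=n_longer,
        isi=first.isi,
        stimulus_type=first.stimulus_type,
    )


def monotonize(proportions, weights=None) -> np.ndarray:
    """Weighted pool-adjacent-violators fit: the closest non-decreasing sequence.

    Within each pooled block the output equals the weight-weighted mean of the
    inputs; the operation is idempotent and conserves the overall weighted mean.
    """
    p = np.asarray(proportions, dtype=float)
    w = np.ones_like(p) if weights is None else np.asarray(weights, dtype=float)
    if p.shape != w.shape or p.ndim != 1:
        raise ValueError("proportions and weights must be equal-length 1-D arrays")
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    # blocks of (weight sum, weighted mean, run length)
    blocks: List[List[float]] = []
    for pi, wi in zip(p, w):
        blocks.append([wi, pi, 1])
        while len(blocks) >= 2 and blocks[-2][1] > blocks[-1][1] + 1e-15:
            w2, m2, n2 = blocks.pop()
            w1, m1, n1 = blocks.pop()
            wt = w1 + w2
            blocks.append([wt, (w1 * m1 + w2 * m2) / wt, n1 + n2])
    out = np.empty_like(p)
    i = 0
    for _, mean, length in blocks:
        out[i : i + length] = mean
        i += length
    return out


@dataclass(frozen=True)
class SKEstimate:
    """Spearman-Kärber summary of one psychometric function."""

    pse: float
    sd: float
    dl: float
    wf: float
    anchor_low: float
    anchor_high: float
    standard: float
    order: str
    valid: bool = True  # False for flat functions (sd == 0)


def default_anchors(
    standard: float, c_levels: Optional[np.ndarray] = None
) -> Tuple[float, float]:
    """Anchor presets for the 80/500 ms regimes; one grid step beyond otherwise."""
    key = float(standard)
    if key in _ANCHOR_PRESETS:
        lo, hi = _ANCHOR_PRESETS[key]
        if c_levels is None or (lo < np.min(c_levels) and hi > np.max(c_levels)):
            return lo, hi
    if c_levels is None:
        raise ValueError(f"no anchor preset for standard={standard}")
    levels = np.sort(np.asarray(c_levels, dtype=float))
    step = float(np.min(np.diff(levels)))
    return (max(0.0, levels[0] - step), levels[-1] + step)


def spearman_karber(
    table: PsychometricTable,
    anchor_low: float,
    anchor_high: float,
    order: str,
) -> SKEstimate:
    """Distribution-free PSE/SD/DL/WF for one stimulus order.

    Proportions are monotonized (trial counts as weights), extended with p=0 at
    ``anchor_low`` and p=1 at ``anchor_high``, and each probability increment
    is spread uniformly over its comparison interval:

    * mean: sum of dp * (c_k + c_{k+1}) / 2
    * second moment: sum of dp * (c_k^2 + c_k*c_{k+1} + c_{k+1}^2) / 3
    """
    if order not in ORDERS:
        raise ValueError(f"order must be one of {ORDERS}")
    c = np.asarray(table.c_levels, dtype=float)
    if not (anchor_low < c[0] and anchor_high > c[-1]):
        raise ValueError("anchors must strictly bracket the comparison grid")
    p = monotonize(table.proportions(order), table.n_trials[order])
    cc = np.concatenate([[anchor_low], c, [anchor_high]])
    pp = np.clip(np.concatenate([[0.0], p, [1.0]]), 0.0, 1.0)
    dp = np.diff(pp)
    pse = float(np.sum(dp * (cc[:-1] + cc[1:]) / 2.0))
    m2 = float(np.sum(dp * (cc[:-1] ** 2 + cc[:-1] * cc[1:] + cc[1:] ** 2) / 3.0))
    var = max(m2 - pse**2, 0.0)
    sd = float(np.sqrt(var))
    dl = Z75 * sd
    return SKEstimate(
        pse=pse,
        sd=sd,
        dl=dl,
        wf=dl / table.standard,
        anchor_low=anchor_low,
        anchor_high=anchor_high,
        standard=table.standard,
        order=order,
        valid=sd > 0.0,
    )


def dl_from_quartiles(psychometric, proportions=None, bracket=None) -> float:
    """Half the interquartile range of a monotone psychometric function.

    ``psychometric`` is either a monotone callable c -> p (inverted by
    bisection over ``bracket``; a discontinuous step maps both quartiles to
    the jump, giving 0) or an array of comparison levels paired with sampled
    ``proportions`` (quartiles located by linear interpolation between grid
    points).  Returns NaN when .25 or .75 is not bracketed (flat function).
    """
    if callable(psychometric):
        if bracket is None:
            raise ValueError("bracket=(lo, hi) is required for a callable")
        lo, hi = float(bracket[0]), float(bracket[1])
        if not (psychometric(lo) <= 0.25 and psychometric(hi) >= 0.75):
            return float("nan")

        def quantile_fn(q: float) -> float:
            a, b = lo, hi
            for _ in range(200):
                mid = 0.5 * (a + b)
                if psychometric(mid) >= q:
                    b = mid
                else:
                    a = mid
            return 0.5 * (a + b)

        return (quantile_fn(0.75) - quantile_fn(0.25)) / 2.0

    c = np.asarray(psychometric, dtype=float)
    p = np.asarray(proportions, dtype=float)
    if c.shape != p.shape or c.ndim != 1 or c.size < 2:
        raise ValueError("need matching 1-D arrays of at least two points")
    if np.any(np.diff(p) < -1e-12):
        raise ValueError("proportions must be non-decreasing; monotonize first")
    if not (p[0] <= 0.25 <= p[-1] and p[0] <= 0.75 <= p[-1]):
        return float("nan")

    def quantile(q: float) -> float:
        # first interval [i, i+1] whose proportions bracket q
        i = int(np.searchsorted(p, q, side="left"))
        if i == 0:
            return float(c[0])
        lo, hi = p[i - 1], p[i]
        if hi == lo:
            return float(c[i])
        return float(c[i - 1] + (q - lo) / (hi - lo) * (c[i] - c[i - 1]))

    return (quantile(0.75) - quantile(0.25)) / 2.0


@dataclass(frozen=True)
class TypeBEffect:
    """Order difference in sensitivity: negative means sharper when s leads."""

    dl_sc: float
    dl_cs: float
    delta_dl: float
    wf_sc: float
    wf_cs: float
    delta_wf: float


def type_b(est_sc: SKEstimate, est_cs: SKEstimate) -> TypeBEffect:
    """Type B effect DL_sc - DL_cs (and its Weber-fraction analogue)."""
    if est_sc.standard != est_cs.standard:
        raise ValueError("estimates come from different regimes")
    return TypeBEffect(
        dl_sc=est_sc.dl,
        dl_cs=est_cs.dl,
        delta_dl=est_sc.dl - est_cs.dl,
        wf_sc=est_sc.wf,
        wf_cs=est_cs.wf,
        delta_wf=est_sc.wf - est_cs.wf,
    )
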