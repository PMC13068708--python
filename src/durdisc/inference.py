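"""Repeated-measures / mixed ANOVAs with sphericity handling, and power analysis.

All ANOVAs assume complete balanced designs (the simulated experiments always
are) and are computed from explicit sums-of-squares decompositions so they can
be verified against hand calculations.  Greenhouse-Geisser correction is
applied to a within-subject effect when its Mauchly test is significant
("auto" gate), or always/never on request.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional

import numpy as np
from scipy import stats

__all__ = [
    "AnovaResult",
    "PowerSpec",
    "rm_anova_1way",
    "rm_anova_2way",
    "mixed_anova_3way",
    "power_rm",
    "gg_epsilon",
    "mauchly",
]


@dataclass(frozen=True)
class AnovaResult:
    effect: str
    f_value: float
    df_num: float
    df_den: float
    p_value: float
    partial_eta_sq: float
    epsilon_gg: float = 1.0
    mauchly_w: Optional[float] = None
    mauchly_p: Optional[float] = None
    gg_applied: bool = False
    ss_effect: float = 0.0
    ss_error: float = 0.0


def _orthonormal_contrasts(k: int) -> np.ndarray:
    """Orthonormal basis (k x (k-1)) of the contrast space (normalized Helmert)."""
    h = np.zeros((k, k - 1))
    for j in range(1, k):
        h[:j, j - 1] = 1.0
        h[j, j - 1] = -float(j)
        h[:, j - 1] /= np.linalg.norm(h[:, j - 1])
    return h


def gg_epsilon(scores: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from n x q orthonormal contrast scores."""
    s = np.cov(scores, rowvar=False)
    s = np.atleast_2d(s)
    q = s.shape[0]
    eig = np.linalg.eigvalsh(s)
    eig = np.clip(eig, 0.0, None)
    denom = q * float(np.sum(eig**2))
    if denom <= 0.0:
        return 1.0
    return float(np.sum(eig) ** 2 / denom)


def mauchly(scores: np.ndarray):
    """Mauchly sphericity test on n x q orthonormal contrast scores.

    Returns ``(W, chi2, df, p)``; degenerate cases (q < 2 or too few subjects
    for a full-rank covariance) return W = 1 with p = NaN.
    """
    n, q = scores.shape
    if q < 2 or n <= q:
        return 1.0, 0.0, 0, float("nan")
    s = np.cov(scores, rowvar=False)
    eig = np.linalg.eigvalsh(s)
    if np.any(eig <= 0):
        return 0.0, float("inf"), q * (q + 1) // 2 - 1, 0.0
    w = float(np.prod(eig) / (np.mean(eig) ** q))
    d = 1.0 - (2.0 * q**2 + q + 2.0) / (6.0 * q * (n - 1))
    chi2 = -(n - 1) * d * np.log(w)
    df = q * (q + 1) // 2 - 1
    return w, float(chi2), df, float(stats.chi2.sf(chi2, df))


def _f_and_p(ss_eff, df_eff, ss_err, df_err, eps, gg_applied):
    ms_eff = ss_eff / df_eff
    ms_err = ss_err / df_err
    if ss_eff <= 1e-12 and ss_err <= 1e-12:
        return 0.0, 1.0
    f = ms_eff / ms_err if ms_err > 0 else np.inf
    d1, d2 = (df_eff * eps, df_err * eps) if gg_applied else (df_eff, df_err)
    return float(f), float(stats.f.sf(f, d1, d2))


def _partial_eta(ss_eff: float, ss_err: float) -> float:
    tot = ss_eff + ss_err
    return float(ss_eff / tot) if tot > 0 else 0.0


def _within_result(name, scores, ss_eff, df_eff, ss_err, df_err, alpha, gg_mode):
    """Assemble one within-subject effect with its sphericity handling."""
    q = scores.shape[1]
    if q >= 2:
        w, _, _, p_mauchly = mauchly(scores)
        eps = gg_epsilon(scores)
    else:
        w, p_mauchly, eps = None, None, 1.0
    if gg_mode == "always":
        gg = q >= 2
    elif gg_mode == "never":
        gg = False
    else:  # auto: only when Mauchly indicates a violation
        gg = bool(
            q >= 2 and p_mauchly is not None and not np.isnan(p_mauchly) and p_mauchly < alpha
        )
    f, p = _f_and_p(ss_eff, df_eff, ss_err, df_err, eps, gg)
    return AnovaResult(
        effect=name,
        f_value=f,
        df_num=df_eff * eps if gg else df_eff,
        df_den=df_err * eps if gg else df_err,
        p_value=p,
        partial_eta_sq=_partial_eta(ss_eff, ss_err),
        epsilon_gg=eps,
        mauchly_w=w,
        mauchly_p=p_mauchly,
        gg_applied=gg,
        ss_effect=float(ss_eff),
        ss_error=float(ss_err),
    )


def rm_anova_1way(y: np.ndarray, effect: str = "order") -> AnovaResult:
    """Paired two-level repeated-measures ANOVA; F equals the squared paired t."""
    y = np.asarray(y, dtype=float)
    if y.ndim != 2 or y.shape[1] != 2:
        raise ValueError("y must be an n x 2 array")
    n = y.shape[0]
    if n < 2:
        raise ValueError("need at least two subjects")
    grand = y.mean()
    cond = y.mean(axis=0)
    subj = y.mean(axis=1)
    ss_eff = n * float(np.sum((cond - grand) ** 2))
    ss_err = float(np.sum((y - cond[None, :] - subj[:, None] + grand) ** 2))
    f, p = _f_and_p(ss_eff, 1, ss_err, n - 1, 1.0, False)
    return AnovaResult(
        effect=effect,
        f_value=f,
        df_num=1,
        df_den=n - 1,
        p_value=p,
        partial_eta_sq=_partial_eta(ss_eff, ss_err),
        ss_effect=ss_eff,
        ss_error=ss_err,
    )


def rm_anova_2way(
    y: np.ndarray,
    factor_a: str = "c",
    factor_b: str = "order",
    alpha_sphericity: float = 0.05,
    gg: str = "auto",
) -> List[AnovaResult]:
    """Two-way fully-within ANOVA on an (n_subjects, a, b) cell-mean array.

    Returns results for the two main effects and the interaction, each tested
    against its own subject-interaction error stratum.
    """
    y = np.asarray(y, dtype=float)
    if y.ndim != 3:
        raise ValueError("y must be (subjects, a_levels, b_levels)")
    if not np.all(np.isfinite(y)):
        raise ValueError("missing cells are not supported")
    n, a, b = y.shape
    if n < 2:
        raise ValueError("need at least two subjects")
    grand = y.mean()
    am = y.mean(axis=(0, 2))
    bm = y.mean(axis=(0, 1))
    abm = y.mean(axis=0)
    sa = y.mean(axis=2)
    sb = y.mean(axis=1)
    sm = y.mean(axis=(1, 2))

    ss_a = n * b * float(np.sum((am - grand) ** 2))
    ss_b = n * a * float(np.sum((bm - grand) ** 2))
    ss_ab = n * float(np.sum((abm - am[:, None] - bm[None, :] + grand) ** 2))
    ss_as = b * float(np.sum((sa - am[None, :] - sm[:, None] + grand) ** 2))
    ss_bs = a * float(np.sum((sb - bm[None, :] - sm[:, None] + grand) ** 2))
    resid = (
        y
        - abm[None, :, :]
        - sa[:, :, None]
        - sb[:, None, :]
        + am[None, :, None]
        + bm[None, None, :]
        + sm[:, None, None]
        - grand
    )
    ss_abs = float(np.sum(resid**2))

    ca = _orthonormal_contrasts(a)
    cb = _orthonormal_contrasts(b)
    scores_a = sa @ ca
    scores_b = sb @ cb
    scores_ab = y.reshape(n, a * b) @ np.kron(ca, cb)

    return [
        _within_result(
            factor_a, scores_a, ss_a, a - 1, ss_as, (a - 1) * (n - 1),
            alpha_sphericity, gg,
        ),
        _within_result(
            factor_b, scores_b, ss_b, b - 1, ss_bs, (b - 1) * (n - 1),
            alpha_sphericity, gg,
        ),
        _within_result(
            f"{factor_a} x {factor_b}", scores_ab, ss_ab, (a - 1) * (b - 1),
            ss_abs, (a - 1) * (b - 1) * (n - 1), alpha_sphericity, gg,
        ),
    ]


def mixed_anova_3way(
    y: np.ndarray,
    between1: np.ndarray,
    between2: np.ndarray,
    within: str = "duration",
    b1: str = "isi",
    b2: str = "stimulus_type",
) -> List[AnovaResult]:
    """Mixed 2x2x2 ANOVA: one two-level within factor, two two-level between factors.

    ``y`` is (n_subjects, 2) with one column per within level; ``between1`` and
    ``between2`` give each subject's group labels.  Between effects are tested
    against subjects-within-groups, within effects against its interaction
    with subjects-within-groups.
    """
    y = np.asarray(y, dtype=float)
    g1 = np.asarray(between1)
    g2 = np.asarray(between2)
    if y.ndim != 2 or y.shape[1] != 2:
        raise ValueError("y must be (subjects, 2)")
    if g1.shape != (y.shape[0],) or g2.shape != (y.shape[0],):
        raise ValueError("between labels must match the number of subjects")
    l1, l2 = np.unique(g1), np.unique(g2)
    if len(l1) != 2 or len(l2) != 2:
        raise ValueError("both between factors must have exactly two levels")
    counts = {
        (a_, b_): int(np.sum((g1 == a_) & (g2 == b_))) for a_ in l1 for b_ in l2
    }
    if min(counts.values()) == 0:
        raise ValueError("empty between-subject cell")
    if len(set(counts.values())) != 1:
        raise ValueError("unbalanced between-subject cells are not supported")
    n_cell = counts[(l1[0], l2[0])]
    n = y.shape[0]
    w = 2  # within levels

    grand = y.mean()
    subj = y.mean(axis=1)

    def m(mask=None, col=None):
        block = y if mask is None else y[mask]
        return block.mean() if col is None else block[:, col].mean()

    # between-subject strata (on subject means, weighted by w observations each)
    ss_b1 = sum(
        w * 2 * n_cell * (subj[g1 == a_].mean() - grand) ** 2 for a_ in l1
    )
    ss_b2 = sum(
        w * 2 * n_cell * (subj[g2 == b_].mean() - grand) ** 2 for b_ in l2
    )
    ss_b1b2 = 0.0
    for a_ in l1:
        for b_ in l2:
            dev = (
                subj[(g1 == a_) & (g2 == b_)].mean()
                - subj[g1 == a_].mean()
                - subj[g2 == b_].mean()
                + grand
            )
            ss_b1b2 += w * n_cell * dev**2
    ss_err_between = 0.0
    for a_ in l1:
        for b_ in l2:
            mask = (g1 == a_) & (g2 == b_)
            ss_err_between += w * float(
                np.sum((subj[mask] - subj[mask].mean()) ** 2)
            )

    # within strata
    wm = y.mean(axis=0)
    ss_w = n * float(np.sum((wm - grand) ** 2))
    ss_wb1 = 0.0
    for a_ in l1:
        for k in range(w):
            dev = m(g1 == a_, k) - subj[g1 == a_].mean() - wm[k] + grand
            ss_wb1 += 2 * n_cell * dev**2
    ss_wb2 = 0.0
    for b_ in l2:
        for k in range(w):
            dev = m(g2 == b_, k) - subj[g2 == b_].mean() - wm[k] + grand
            ss_wb2 += 2 * n_cell * dev**2
    ss_wb1b2 = 0.0
    for a_ in l1:
        for b_ in l2:
            mask = (g1 == a_) & (g2 == b_)
            for k in range(w):
                dev = (
                    m(mask, k)
                    - m(g1 == a_, k)
                    - m(g2 == b_, k)
                    + wm[k]
                    - subj[mask].mean()
                    + subj[g1 == a_].mean()
                    + subj[g2 == b_].mean()
                    - grand
                )
                ss_wb1b2 += n_cell * dev**2
    ss_err_within = 0.0
    for a_ in l1:
        for b_ in l2:
            mask = (g1 == a_) & (g2 == b_)
            cell = y[mask]
            cell_w = cell.mean(axis=0)
            resid = (
                cell
                - cell_w[None, :]
                - subj[mask][:, None]
                + cell.mean()
            )
            ss_err_within += float(np.sum(resid**2))

    df_between_err = n - 4
    df_within_err = n - 4

    def result(name, ss_eff, df_eff, ss_err, df_err):
        f, p = _f_and_p(ss_eff, df_eff, ss_err, df_err, 1.0, False)
        return AnovaResult(
            effect=name,
            f_value=f,
            df_num=df_eff,
            df_den=df_err,
            p_value=p,
            partial_eta_sq=_partial_eta(ss_eff, ss_err),
            ss_effect=float(ss_eff),
            ss_error=float(ss_err),
        )

    return [
        result(b1, ss_b1, 1, ss_err_between, df_between_err),
        result(b2, ss_b2, 1, ss_err_between, df_between_err),
        result(f"{b1} x {b2}", ss_b1b2, 1, ss_err_between, df_between_err),
        result(within, ss_w, 1, ss_err_within, df_within_err),
        result(f"{within} x {b1}", ss_wb1, 1, ss_err_within, df_within_err),
        result(f"{within} x {b2}", ss_wb2, 1, ss_err_within, df_within_err),
        result(
            f"{within} x {b1} x {b2}", ss_wb1b2, 1, ss_err_within, df_within_err
        ),
    ]


@dataclass(frozen=True)
class PowerSpec:
    """Inputs for the repeated-measures power computation (within-factor convention)."""

    eta_p_sq: float
    n: int
    alpha: float = 0.05
    rm_correlation: float = 0.5
    levels: int = 2

    def __post_init__(self) -> None:
        if not 0.0 < self.eta_p_sq < 1.0:
            raise ValueError("eta_p_sq must lie in (0, 1)")
        if not -1.0 < self.rm_correlation < 1.0:
            raise ValueError("rm_correlation must lie in (-1, 1)")
        if self.n < 2:
            raise ValueError("n must be at least 2")


def power_rm(spec: PowerSpec) -> float:
    """Power of the two-level within-subject F test.

    Effect size f = sqrt(eta_p_sq / (1 - eta_p_sq)); noncentrality
    lambda = n * f^2 * levels / (1 - rho); power is the upper tail of the
    noncentral F(1, n-1) beyond the central critical value.
    """
    if spec.levels != 2:
        raise ValueError("only two within-factor levels are supported")
    f2 = spec.eta_p_sq / (1.0 - spec.eta_p_sq)
    lam = spec.n * f2 * spec.levels / (1.0 - spec.rm_correlation)
    df1, df2 = 1, spec.n - 1
    f_crit = stats.f.ppf(1.0 - spec.alpha, df1, df2)
    return float(stats.ncf.sf(f_crit, df1, df2, lam))
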