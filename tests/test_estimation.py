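import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate, stats

from durdisc import designs, estimation
from durdisc.estimation import (
    Z75,
    PsychometricTable,
    aggregate,
    default_anchors,
    dl_from_quartiles,
    monotonize,
    spearman_karber,
    type_b,
)
from durdisc.models import DifferenceObserver, NoiseSpec


def make_table(c_levels, p, n=1000, standard=80.0):
    counts = np.round(np.asarray(p) * n).astype(int)
    return PsychometricTable(
        standard=standard,
        c_levels=np.asarray(c_levels, dtype=float),
        n_trials={"sc": np.full(len(c_levels), n), "cs": np.full(len(c_levels), n)},
        n_c_longer={"sc": counts, "cs": counts},
    )


class TestAggregate:
    def test_paper_preset_cell_counts(self, short_design, rng):
        trials = designs.build_design(short_design)
        records = designs.run_constant_stimuli(
            trials, DifferenceObserver(noise=NoiseSpec(10, 0)), rng
        )
        table = aggregate(records)
        for order in ("sc", "cs"):
            assert np.all(table.n_trials[order] == 40)  # 2 reps x 20 blocks
        assert len(table.c_levels) == 9

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            aggregate([])

    def test_mixed_regimes_rejected(self, rng):
        t1 = designs.TrialSpec(standard=80.0, comparison=80.0, order="sc")
        t2 = designs.TrialSpec(standard=500.0, comparison=500.0, order="sc")
        recs = [
            designs.ResponseRecord(trial=t, response_c_longer=True) for t in (t1, t2)
        ]
        with pytest.raises(ValueError):
            aggregate(recs)

    def test_order_partition_preserves_totals(self, short_design, rng):
        trials = designs.build_design(short_design)
        records = designs.run_constant_stimuli(
            trials, DifferenceObserver(noise=NoiseSpec(10, 0)), rng
        )
        table = aggregate(records)
        swapped = [
            designs.ResponseRecord(
                trial=designs.TrialSpec(
                    standard=r.trial.standard,
                    comparison=r.trial.comparison,
                    order="cs" if r.trial.order == "sc" else "sc",
                    block=r.trial.block,
                    trial_in_block=r.trial.trial_in_block,
                ),
                response_c_longer=r.response_c_longer,
            )
            for r in records
        ]
        table2 = aggregate(swapped)
        total = table.n_c_longer["sc"] + table.n_c_longer["cs"]
        total2 = table2.n_c_longer["sc"] + table2.n_c_longer["cs"]
        assert np.array_equal(total, total2)


def brute_force_isotonic(p, w):
    """Minimize weighted squared error over all contiguous-block partitions."""
    n = len(p)
    best, best_err = None, np.inf
    for cuts in itertools.product([0, 1], repeat=n - 1):
        bounds = [0] + [i + 1 for i, c in enumerate(cuts) if c] + [n]
        fitted = np.empty(n)
        for a, b in zip(bounds[:-1], bounds[1:]):
            fitted[a:b] = np.average(p[a:b], weights=w[a:b])
        if np.all(np.diff(fitted) >= -1e-12):
            err = np.sum(w * (p - fitted) ** 2)
            if err < best_err - 1e-12:
                best, best_err = fitted, err
    return best


class TestMonotonize:
    def test_frozen_example(self):
        out = monotonize([0.0, 0.2, 0.1, 0.9])
        assert np.allclose(out, [0.0, 0.15, 0.15, 0.9])

    def test_already_monotone_unchanged(self):
        p = [0.1, 0.1, 0.4, 0.9]
        assert np.allclose(monotonize(p), p)

    def test_weighted_pooling(self):
        out = monotonize([0.4, 0.0], [1, 3])
        assert np.allclose(out, [0.1, 0.1])

    def test_matches_brute_force(self, rng):
        for _ in range(50):
            n = rng.integers(2, 7)
            p = rng.uniform(0, 1, n)
            w = rng.integers(1, 10, n).astype(float)
            assert np.allclose(monotonize(p, w), brute_force_isotonic(p, w))

    def test_matches_sklearn(self, rng):
        from sklearn.isotonic import IsotonicRegression

        for _ in range(20):
            n = rng.integers(2, 12)
            p = rng.uniform(0, 1, n)
            w = rng.uniform(0.5, 10, n)
            ref = IsotonicRegression().fit_transform(np.arange(n), p, sample_weight=w)
            assert np.allclose(monotonize(p, w), ref)

    @given(
        st.lists(st.floats(0, 1), min_size=1, max_size=12),
        st.integers(0, 2**31),
    )
    def test_properties(self, p, seed):
        w = np.random.default_rng(seed).uniform(0.5, 5, len(p))
        out = monotonize(p, w)
        assert np.all(np.diff(out) >= -1e-12)  # non-decreasing
        assert np.allclose(monotonize(out, w), out)  # idempotent
        assert np.average(out, weights=w) == pytest.approx(
            np.average(p, weights=w)
        )  # mass conserving


class TestSpearmanKarber:
    def test_dl_constant(self):
        assert round(Z75, 4) == 0.6745

    def test_step_data_uniform_moments(self):
        # all mass on (65, 80): mean 72.5, sd 15/sqrt(12)
        c = np.arange(20.0, 141.0, 15.0)
        p = (c >= 80.0).astype(float)
        est = spearman_karber(make_table(c, p), 0.0, 160.0, "sc")
        assert est.pse == pytest.approx(72.5)
        assert est.sd == pytest.approx(15.0 / np.sqrt(12.0))
        assert est.dl == pytest.approx(Z75 * 15.0 / np.sqrt(12.0))
        assert est.wf == pytest.approx(est.dl / 80.0)

    def test_linear_data_uniform_on_anchors(self):
        c = np.arange(20.0, 141.0, 15.0)
        est = spearman_karber(make_table(c, c / 160.0, n=160), 0.0, 160.0, "sc")
        assert est.pse == pytest.approx(80.0)
        assert est.sd == pytest.approx(160.0 / np.sqrt(12.0))

    def test_shift_equivariance(self):
        c = np.arange(20.0, 141.0, 15.0)
        p = np.clip((c - 50.0) / 60.0, 0, 1)
        a = spearman_karber(make_table(c, p, n=60), 0.0, 160.0, "sc")
        b = spearman_karber(
            make_table(c + 25.0, p, n=60), 25.0, 185.0, "sc"
        )
        assert b.pse == pytest.approx(a.pse + 25.0)
        assert b.sd == pytest.approx(a.sd)

    def test_scale_equivariance(self):
        c = np.arange(20.0, 141.0, 15.0)
        p = np.clip((c - 50.0) / 60.0, 0, 1)
        a = spearman_karber(make_table(c, p, n=60), 0.0, 160.0, "sc")
        b = spearman_karber(
            make_table(3 * c, p, n=60, standard=240.0), 0.0, 480.0, "sc"
        )
        assert b.pse == pytest.approx(3 * a.pse)
        assert b.sd == pytest.approx(3 * a.sd)
        assert b.dl == pytest.approx(3 * a.dl)

    def test_moments_match_numerical_integration(self, rng):
        # oracle: integrate the implied piecewise-uniform density directly
        c = np.arange(20.0, 141.0, 15.0)
        p = np.sort(rng.uniform(0, 1, len(c)))
        est = spearman_karber(make_table(c, p, n=10**6), 0.0, 160.0, "sc")
        cc = np.concatenate([[0.0], c, [160.0]])
        pp = np.concatenate([[0.0], monotonize(p), [1.0]])

        def density(x):
            i = np.searchsorted(cc, x, side="right") - 1
            i = np.clip(i, 0, len(cc) - 2)
            return (pp[i + 1] - pp[i]) / (cc[i + 1] - cc[i])

        mean, _ = integrate.quad(lambda x: x * density(x), 0, 160, limit=400)
        m2, _ = integrate.quad(lambda x: x**2 * density(x), 0, 160, limit=400)
        assert est.pse == pytest.approx(mean, rel=1e-4)
        assert est.sd == pytest.approx(np.sqrt(m2 - mean**2), rel=1e-3)

    def test_consistency_on_normal_data(self, rng):
        # n = 1e4 per level: recover the generating mean within 1 ms, SD within 5%
        c = np.arange(20.0, 141.0, 15.0)
        n = 10_000
        sigma = 22.0  # large enough that grid discretization inflates SD < 5%
        true_p = stats.norm.cdf((c - 80.0) / sigma)
        counts = rng.binomial(n, true_p)
        table = PsychometricTable(
            standard=80.0,
            c_levels=c,
            n_trials={"sc": np.full(9, n), "cs": np.full(9, n)},
            n_c_longer={"sc": counts, "cs": counts},
        )
        est = spearman_karber(table, 0.0, 160.0, "sc")
        assert abs(est.pse - 80.0) < 1.0
        assert abs(est.sd - sigma) / sigma < 0.05

    def test_non_bracketing_anchors_rejected(self):
        c = np.arange(20.0, 141.0, 15.0)
        with pytest.raises(ValueError):
            spearman_karber(make_table(c, c / 160.0), 20.0, 160.0, "sc")
        with pytest.raises(ValueError):
            spearman_karber(make_table(c, c / 160.0), 0.0, 140.0, "sc")

    def test_flat_function_flagged(self):
        c = np.arange(20.0, 141.0, 15.0)
        est = spearman_karber(make_table(c, np.full(9, 0.5)), 0.0, 160.0, "sc")
        assert est.sd > 0  # anchors spread the mass; function is not flat-flagged
        # a genuinely degenerate table: all mass in one interval of width zero
        # is impossible with strict anchors, so validity tracks sd > 0
        assert est.valid


class TestDefaultAnchors:
    def test_presets(self):
        assert default_anchors(80.0) == (0.0, 160.0)
        assert default_anchors(500.0) == (200.0, 800.0)

    def test_grid_step_rule(self):
        grid = np.array([10.0, 20, 30, 40, 50, 60, 70, 80, 90])
        assert default_anchors(50.0, grid) == (0.0, 100.0)

    def test_preset_overridden_when_not_bracketing(self):
        grid = 500.0 + 100.0 * np.arange(-4, 5)
        assert default_anchors(500.0, grid) == (0.0, 1000.0)


class TestDlFromQuartiles:
    def test_normal_cdf_gives_z75_sigma(self):
        sigma = 12.0
        c = np.linspace(20, 140, 601)
        p = stats.norm.cdf((c - 80.0) / sigma)
        assert dl_from_quartiles(c, p) == pytest.approx(Z75 * sigma, rel=1e-3)

    def test_logistic_cdf_gives_b_ln3(self):
        b = 10.0
        c = np.linspace(0, 160, 801)
        p = stats.logistic.cdf(c, loc=80.0, scale=b)
        assert dl_from_quartiles(c, p) == pytest.approx(b * np.log(3.0), rel=1e-3)

    def test_step_function_gives_zero(self):
        step = lambda c: 1.0 if c >= 80.0 else 0.0
        assert dl_from_quartiles(step, bracket=(0.0, 160.0)) == pytest.approx(
            0.0, abs=1e-6
        )

    def test_callable_normal_cdf(self):
        fn = lambda c: stats.norm.cdf((c - 80.0) / 12.0)
        assert dl_from_quartiles(fn, bracket=(0.0, 160.0)) == pytest.approx(
            Z75 * 12.0, abs=1e-6
        )

    def test_sampled_step_matches_uniform_segment_rule(self):
        # sampled at grid points, the jump interval is read as a uniform ramp
        c = np.arange(20.0, 141.0, 15.0)
        p = (c >= 80.0).astype(float)
        assert dl_from_quartiles(c, p) == pytest.approx(0.5 * 15.0 / 2.0)

    def test_unbracketed_quartile_flagged(self):
        c = np.arange(20.0, 141.0, 15.0)
        assert np.isnan(dl_from_quartiles(c, np.full(9, 0.5)))

    def test_agrees_with_spearman_karber_on_smooth_data(self):
        c = np.arange(5.0, 156.0, 5.0)
        p = stats.norm.cdf((c - 80.0) / 15.0)
        table = make_table(c, p, n=10**6)
        sk = spearman_karber(table, 0.0, 160.0, "sc")
        dq = dl_from_quartiles(c, p)
        assert abs(sk.dl - dq) / dq < 0.05


class TestTypeB:
    def test_negative_effect(self):
        a = spearman_karber(
            make_table(np.arange(20.0, 141.0, 15.0), np.arange(9) / 8.0, n=8),
            0.0, 160.0, "sc",
        )
        assert type_b(a, a).delta_dl == 0.0

    def test_sign_and_wf(self):
        est = lambda dl, order: estimation.SKEstimate(
            pse=500.0, sd=dl / Z75, dl=dl, wf=dl / 500.0,
            anchor_low=200.0, anchor_high=800.0, standard=500.0, order=order,
        )
        tb = type_b(est(50.0, "sc"), est(60.0, "cs"))
        assert tb.delta_dl == pytest.approx(-10.0)
        assert tb.delta_wf == pytest.approx(-0.02)

    def test_mixed_regimes_rejected(self):
        a = estimation.SKEstimate(80, 10, 6.7, 0.08, 0, 160, 80.0, "sc")
        b = estimation.SKEstimate(500, 50, 33, 0.067, 200, 800, 500.0, "cs")
        with pytest.raises(ValueError):
            type_b(a, b)
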