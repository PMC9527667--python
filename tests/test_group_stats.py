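"""Bootstrap differences, permutation nulls, p-values, effect sizes,
windowed summaries and the mixed ANOVA."""

import numpy as np
import pytest

from seiznet import group_stats as gs
from seiznet.graph_metrics import MetricSeries


def panel(values, condition="focal", times=None):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    t = np.arange(values.shape[1]) * 0.25 if times is None else times
    return gs.MetricPanel(condition=condition, values=values, times_min=t)


class TestBootstrapDifference:
    def test_identical_constant_panels(self):
        p = panel([[2.0, 2.0, 2.0]])
        res = gs.bootstrap_difference(p, p, n_boot=100, seed=0)
        assert np.all(res.diff == 0.0)
        assert np.all(res.ci_low == 0.0) and np.all(res.ci_high == 0.0)

    def test_constant_panels_exact_difference(self):
        pa = panel(np.full((4, 5), 3.0))
        pb = panel(np.full((7, 5), 1.0), condition="bilateral")
        res = gs.bootstrap_difference(pa, pb, n_boot=50, seed=1)
        assert np.allclose(res.diff, 2.0)

    def test_ci_covers_zero_under_null(self, rng):
        """Percentile CIs from segment-level resampling should cover the
        true (zero) difference at roughly nominal rate."""
        covered = total = 0
        for _ in range(200):
            pa = panel(rng.standard_normal((20, 10)))
            pb = panel(rng.standard_normal((20, 10)), condition="bilateral")
            res = gs.bootstrap_difference(pa, pb, n_boot=500, seed=rng)
            covered += int(((res.ci_low <= 0) & (0 <= res.ci_high)).sum())
            total += 10
        assert covered / total >= 0.90

    def test_empty_panel_rejected(self):
        pa = panel([[1.0]])
        pb = gs.MetricPanel("focal", np.empty((0, 1)), np.array([0.0]))
        with pytest.raises(ValueError):
            gs.bootstrap_difference(pa, pb)

    def test_mean_of_difference_matches_group_means(self, rng):
        """Effect-size route (i): the bootstrap difference mean estimates
        mean(A) - mean(B)."""
        pa = panel(rng.normal(1.0, 1.0, (40, 3)))
        pb = panel(rng.normal(0.0, 1.0, (40, 3)), condition="bilateral")
        res = gs.bootstrap_difference(pa, pb, n_boot=4000, seed=2)
        truth = pa.values.mean(axis=0) - pb.values.mean(axis=0)
        mc_se = 2.0 / np.sqrt(40) / np.sqrt(4000) * 4  # generous MC margin
        assert np.allclose(res.mean, truth, atol=5 * mc_se + 0.02)


class TestPermutationNull:
    def test_null_centred_at_zero(self, rng):
        pa = panel(rng.standard_normal((15, 4)))
        pb = panel(rng.standard_normal((10, 4)), condition="bilateral")
        null = gs.permutation_null(pa, pb, n_perm=4000, seed=3)
        se = null.std(axis=0) / np.sqrt(null.shape[0])
        assert np.all(np.abs(null.mean(axis=0)) < 3 * se + 1e-3)

    def test_group_sizes_preserved(self):
        """With panels of ones and zeros every permuted difference must be
        attainable from a (3, 2) split, proving the split sizes."""
        pa = panel(np.ones((3, 1)))
        pb = panel(np.zeros((2, 1)), condition="bilateral")
        null = gs.permutation_null(pa, pb, n_perm=500, seed=4).ravel()
        # k ones assigned to group A (k in 1..3): diff = k/3 - (3-k)/2
        attainable = {k / 3 - (3 - k) / 2 for k in (1, 2, 3)}
        assert {round(v, 10) for v in null} <= {round(v, 10) for v in attainable}

    def test_single_iteration_reproducible(self):
        pa = panel(np.arange(8.0).reshape(4, 2))
        pb = panel(np.arange(6.0).reshape(3, 2), condition="bilateral")
        a = gs.permutation_null(pa, pb, n_perm=1, seed=9)
        b = gs.permutation_null(pa, pb, n_perm=1, seed=9)
        assert np.array_equal(a, b)


class TestPValue:
    def test_floor_at_one_over_b(self):
        diff = np.abs(np.random.default_rng(0).standard_normal((10_000, 1))) + 0.1
        assert gs.p_value(diff)[0] == pytest.approx(1e-4)
        null = np.random.default_rng(1).standard_normal((10_000, 1)) * 0.01
        assert gs.p_value(diff, null)[0] == pytest.approx(1e-4)

    def test_symmetric_distribution_not_significant(self, rng):
        diff = rng.standard_normal((5000, 1))
        assert gs.p_value(diff)[0] > 0.5

    def test_half_mass_below_zero_caps_at_one(self):
        diff = np.concatenate([np.ones(500), -np.ones(500)])[:, None]
        assert gs.p_value(diff)[0] == 1.0


class TestCohensD:
    def test_identical_panels_zero(self):
        boot = np.full((100, 3), 1.5)
        d, d_iter = gs.cohens_d(boot, boot.copy())
        assert np.all(d == 0.0) and np.all(d_iter == 0.0)

    def test_bootstrapped_d_grows_with_n(self, rng):
        """d on bootstrapped *mean* distributions scales like sqrt(n): it
        measures separation of group-mean estimates, not of segments."""
        ds = []
        for n in (50, 200):
            pa = panel(rng.normal(1.0, 1.0, (n, 1)))
            pb = panel(rng.normal(0.0, 1.0, (n, 1)), condition="bilateral")
            res = gs.bootstrap_difference(pa, pb, n_boot=2000, seed=5)
            d, _ = gs.cohens_d(res.boot_a, res.boot_b)
            ds.append(abs(d[0]))
        assert ds[0] > 1.0
        assert ds[1] > ds[0]


class TestSignificantIntervals:
    times = np.arange(-900, 570, 15) / 60.0  # standard 98-window axis

    def test_no_significance_empty(self):
        assert gs.significant_intervals(np.ones(98), self.times) == []

    def test_single_run_maps_to_interval(self):
        times = np.arange(-15.0, 10.0, 0.25)  # axis containing a 9.75 start
        p = np.ones(len(times))
        p[(times >= 2.25) & (times <= 9.75)] = 0.01
        assert gs.significant_intervals(p, times) == [(2.25, 10.0)]

    def test_two_runs_sorted_disjoint(self):
        p = np.ones(98)
        p[10:13] = 0.001
        p[50:52] = 0.001
        out = gs.significant_intervals(p, self.times)
        assert len(out) == 2
        assert out[0][1] <= out[1][0]


def metric_series(values, segment_id="s0", condition="focal"):
    values = np.asarray(values, dtype=float)
    times = np.arange(-900, -900 + 15 * len(values), 15) / 60.0
    return MetricSeries(segment_id, condition, "density", values, times)


class TestWindowAverages:
    def test_constant_series(self):
        ws = gs.window_averages(metric_series(np.full(98, 0.3)))
        assert all(v == pytest.approx(0.3) for v in ws.means.values())

    def test_monotone_series_gives_increasing_windows(self):
        ws = gs.window_averages(metric_series(np.arange(98.0)))
        vals = [ws.means[w] for w in gs.WINDOW_NAMES]
        assert all(a < b for a, b in zip(vals, vals[1:]))

    def test_window_at_onset_is_ictal(self):
        values = np.zeros(98)
        times = np.arange(-900, 570, 15) / 60.0
        values[np.flatnonzero(times == 0.0)[0]] = 98.0
        ws = gs.window_averages(MetricSeries("s", "focal", "density", values, times))
        assert ws.means["ictal"] > 0
        assert ws.means["preictal_3"] == 0.0


class TestRmAnova:
    def summaries(self, data):
        """data: condition -> (n_segments, 5) array."""
        out = []
        for cond, arr in data.items():
            for i, row in enumerate(arr):
                out.append(
                    gs.WindowedSummary(
                        f"{cond}-{i}", cond, "density",
                        dict(zip(gs.WINDOW_NAMES, map(float, row))),
                    )
                )
        return out

    def test_identical_values_give_zero_f(self):
        data = {
            "focal": np.full((5, 5), 1.0),
            "bilateral": np.full((5, 5), 1.0),
        }
        anova, _ = gs.rm_anova(self.summaries(data))
        assert np.allclose(anova["F"], 0.0)
        assert np.allclose(anova["p_unc"], 1.0)

    def test_condition_shift_detected_without_interaction(self, rng):
        base = rng.standard_normal((20, 5))
        data = {"focal": base, "bilateral": rng.standard_normal((20, 5)) + 5.0}
        anova, _ = gs.rm_anova(self.summaries(data))
        row = anova.set_index("Source")
        assert row.loc["condition", "p_unc"] < 0.01
        assert row.loc["Interaction", "p_unc"] > 0.01

    def test_window_effect_detected_without_condition_effect(self, rng):
        trend = np.linspace(0, 5, 5)
        data = {
            "focal": rng.standard_normal((20, 5)) + trend,
            "bilateral": rng.standard_normal((20, 5)) + trend,
        }
        anova, posthoc = gs.rm_anova(self.summaries(data))
        row = anova.set_index("Source")
        assert row.loc["window", "p_unc"] < 0.01
        assert row.loc["condition", "p_unc"] > 0.01
        # post hoc paired t-tests include the extreme window pair per condition
        extreme = posthoc[
            (posthoc["window_a"] == "preictal_1") & (posthoc["window_b"] == "postictal")
        ]
        assert (extreme["p"] < 0.01).all()

    def test_small_condition_rejected(self):
        data = {"focal": np.ones((1, 5)), "bilateral": np.ones((3, 5))}
        with pytest.raises(ValueError, match="fewer than 2"):
            gs.rm_anova(self.summaries(data))


class TestComparePanels:
    def test_reproducible_and_detects_shift(self, rng):
        pa = panel(rng.normal(1.0, 0.5, (18, 6)), condition="bilateral")
        pb = panel(rng.normal(0.0, 0.5, (49, 6)), condition="focal")
        c1 = gs.compare_panels(pa, pb, metric="density", n_boot=1000, seed=7)
        c2 = gs.compare_panels(pa, pb, metric="density", n_boot=1000, seed=7)
        assert np.array_equal(c1.p, c2.p)
        assert np.array_equal(c1.ci_low, c2.ci_low)
        assert np.array_equal(c1.d, c2.d)
        assert np.all(c1.p < 0.05)
        assert c1.d_min is not None and c1.d_min > 0
        assert c1.d_min_ci[0] <= c1.d_min_ci[1]
        assert c1.significant_intervals  # at least one interval
        # CI ordering invariant
        assert np.all(c1.ci_low <= c1.mean_diff) and np.all(c1.mean_diff <= c1.ci_high)

    def test_no_effect_no_dmin(self):
        pa = panel(np.zeros((5, 3)), condition="bilateral")
        pb = panel(np.zeros((6, 3)), condition="focal")
        comp = gs.compare_panels(pa, pb, n_boot=200, seed=8)
        assert comp.d_min is None
        assert comp.significant_intervals == []
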