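import itertools
import math

import numpy as np
import pytest
from scipy import stats as sps

from steptrack.analysis import (
    InsufficientDataError,
    SUMMARY_STATS,
    _mannwhitney,
    age_split_comparison,
    daywise_correlation,
    improvement_step_comparison,
    phase_summary,
    prepost_summary_correlation,
    steps_vs_ecog,
)
from steptrack.cohort import StepSeries
from steptrack.msas import MsasResponse, default_catalog
from steptrack.synthgen import gen_cohort, scenario
from steptrack.util import Absent

CATALOG = default_catalog()


def pre_series(pid, values, start=-7):
    return StepSeries(pid, {d: v for d, v in zip(range(start, 0), values)})


class TestPhaseSummary:
    def test_three_full_days(self):
        s = phase_summary(pre_series("P1", [2000, 4000, 6000]), "pre")
        assert (s.mean, s.median, s.max, s.min) == (4000, 4000, 6000, 2000)
        assert s.n_days_used == 3

    def test_single_day_degenerate(self):
        s = phase_summary(pre_series("P1", [5000]), "pre")
        assert (s.mean, s.median, s.max, s.min) == (5000, 5000, 5000, 5000)

    def test_partial_days_excluded(self):
        series = pre_series("P1", [2000, 100, 50, 4000, 0, 6000])
        s = phase_summary(series, "pre")
        # oracle: recompute excluding <=100-step days
        vals = [v for v in series.records.values() if v is not None and v > 100]
        assert s.mean == pytest.approx(sum(vals) / len(vals))
        assert s.n_days_used == 3
        assert s.min == 2000

    def test_no_full_days_absent(self):
        result = phase_summary(pre_series("P1", [100, 50]), "pre")
        assert isinstance(result, Absent)

    def test_order_invariant(self):
        s = phase_summary(pre_series("P1", [9000, 200, 3000]), "pre")
        assert s.min <= s.median <= s.max


def both_phase_series(pid, pre_vals, post_vals):
    records = {d: v for d, v in zip(range(-7, 0), pre_vals)}
    records.update({d: v for d, v in zip(range(1, 15), post_vals)})
    return StepSeries(pid, records)


class TestPrepostCorrelation:
    def test_identical_phases_diagonal_one(self, make_cohort):
        spec = {}
        vals = [[2000, 3000, 4500], [5000, 2500, 7000], [1500, 9000, 3000], [4000, 4400, 2000]]
        for i, v in enumerate(vals):
            spec[f"P{i}"] = {
                **{d: x for d, x in zip((-3, -2, -1), v)},
                **{d: x for d, x in zip((1, 2, 3), v)},
            }
        matrix = prepost_summary_correlation(make_cohort(spec))
        for stat in SUMMARY_STATS:
            assert matrix[(stat, stat)].estimate == pytest.approx(1.0)

    def test_matches_direct_formula_oracle(self, make_cohort):
        rng = np.random.default_rng(5)
        spec = {}
        for i in range(5):
            spec[f"P{i}"] = dict(
                both_phase_series(
                    f"P{i}",
                    rng.integers(200, 12000, 7).tolist(),
                    rng.integers(200, 12000, 14).tolist(),
                ).records
            )
        cohort = make_cohort(spec)
        matrix = prepost_summary_correlation(cohort)

        def stat_of(values, name):
            if name == "mean":
                return sum(values) / len(values)
            if name == "median":
                return float(np.median(values))
            return float(max(values) if name == "max" else min(values))

        for i, j in itertools.product(SUMMARY_STATS, repeat=2):
            xs, ys = [], []
            for pid, records in spec.items():
                post_vals = [v for d, v in records.items() if 1 <= d <= 14 and v > 100]
                pre_vals = [v for d, v in records.items() if -7 <= d <= -1 and v > 100]
                xs.append(stat_of(post_vals, i))
                ys.append(stat_of(pre_vals, j))
            n = len(xs)
            mx, my = sum(xs) / n, sum(ys) / n
            cov = sum((a - mx) * (b - my) for a, b in zip(xs, ys))
            r = cov / math.sqrt(
                sum((a - mx) ** 2 for a in xs) * sum((b - my) ** 2 for b in ys)
            )
            assert matrix[(i, j)].estimate == pytest.approx(r, abs=1e-12)
            t = r * math.sqrt((n - 2) / (1 - r * r))
            assert matrix[(i, j)].p_value == pytest.approx(
                2 * sps.t.sf(abs(t), n - 2), rel=1e-9
            )

    def test_patient_without_post_excluded(self, make_cohort):
        rng = np.random.default_rng(9)
        spec = {
            f"P{i}": dict(
                both_phase_series(
                    f"P{i}", rng.integers(200, 9000, 7).tolist(), rng.integers(200, 9000, 14).tolist()
                ).records
            )
            for i in range(4)
        }
        spec["NOPOST"] = {d: 5000 for d in range(-7, 0)}
        matrix = prepost_summary_correlation(make_cohort(spec))
        assert matrix[("mean", "mean")].n == 4

    def test_too_few_patients(self, make_cohort):
        spec = {"P1": {-1: 500, 1: 700}, "P2": {-1: 900, 1: 400}}
        with pytest.raises(InsufficientDataError):
            prepost_summary_correlation(make_cohort(spec))


class TestDaywiseCorrelation:
    def test_constant_cohort_zero_variance_flagged(self, make_cohort):
        spec = {f"P{i}": {d: 5000 for d in range(-7, 15) if d != 0} for i in range(4)}
        result = daywise_correlation(make_cohort(spec), "pre", "mean")
        for day in range(-7, 0):
            assert isinstance(result[day], Absent)
            assert result[day].reason == "zero variance"

    def test_day_with_two_patients_absent(self, make_cohort):
        rng = np.random.default_rng(2)
        spec = {
            f"P{i}": dict(
                both_phase_series(
                    f"P{i}", rng.integers(200, 9000, 7).tolist(), rng.integers(200, 9000, 14).tolist()
                ).records
            )
            for i in range(4)
        }
        for pid in ("P0", "P1"):  # day -7 recorded for only 2 patients
            del spec[pid][-7]
        result = daywise_correlation(make_cohort(spec), "pre", "mean")
        assert isinstance(result[-7], Absent)
        assert result[-7].reason == "n<3"
        assert not isinstance(result[-6], Absent)

    def test_strong_patient_effect_gives_positive_correlations(self):
        config = scenario(
            "null",
            seed=8,
            n_patients=60,
            between_patient_sd=0.7,
            nb_dispersion=50.0,
        )
        cohort = gen_cohort(config)
        for phase in ("pre", "post"):
            result = daywise_correlation(cohort, phase, "mean")
            for day, res in result.items():
                assert not isinstance(res, Absent)
                assert res.estimate > 0

    def test_unknown_statistic(self, make_cohort):
        with pytest.raises(ValueError):
            daywise_correlation(make_cohort({}), "pre", "variance")


def enumerate_mwu_p(x, y):
    """Exact two-sided Mann-Whitney p by full enumeration of rank arrangements."""
    pooled = sorted(x + y)
    ranks = {v: i + 1 for i, v in enumerate(pooled)}  # no ties by construction
    n1, n2 = len(x), len(y)

    def u_stat(rank_sum):
        return rank_sum - n1 * (n1 + 1) / 2

    observed = u_stat(sum(ranks[v] for v in x))
    us = [
        u_stat(sum(combo))
        for combo in itertools.combinations(range(1, n1 + n2 + 1), n1)
    ]
    total = len(us)
    p_le = sum(u <= observed for u in us) / total
    p_ge = sum(u >= observed for u in us) / total
    return min(1.0, 2 * min(p_le, p_ge))


class TestGroupComparisons:
    def test_exact_mwu_separated_groups(self, make_cohort):
        spec = {}
        for i, v in enumerate([1, 2, 3]):
            spec[f"A{i}"] = ({-1: v * 1000}, {"ecog": 0})
        for i, v in enumerate([101, 102, 103]):
            spec[f"B{i}"] = ({-1: v * 1000}, {"ecog": 1})
        result = steps_vs_ecog(make_cohort(spec), "pre")
        # full enumeration over C(6,3)=20 arrangements gives two-sided p = 2/20
        assert result.comparison.p_value == pytest.approx(0.1)
        assert result.comparison.test == "mannwhitneyu"

    def test_identical_groups_zero_effect_size(self, make_cohort):
        spec = {}
        for i, v in enumerate([1000, 2000, 3000]):
            spec[f"A{i}"] = ({-1: v}, {"ecog": 0})
            spec[f"B{i}"] = ({-1: v}, {"ecog": 1})
        result = steps_vs_ecog(make_cohort(spec), "pre")
        assert result.comparison.effect_size == pytest.approx(0.0)

    def test_single_group_correlation_absent(self, make_cohort):
        spec = {f"P{i}": ({-1: 1000 + i}, {"ecog": 1}) for i in range(4)}
        result = steps_vs_ecog(make_cohort(spec), "pre")
        assert isinstance(result.correlation, Absent)
        assert result.comparison.p_value is None

    def test_spearman_direction(self, make_cohort):
        spec = {}
        for i in range(6):
            ecog = 0 if i < 3 else 1
            steps = 8000 - 3000 * ecog + 17 * i
            spec[f"P{i}"] = ({-1: steps}, {"ecog": ecog})
        result = steps_vs_ecog(make_cohort(spec), "pre")
        assert result.correlation.statistic == "spearman"
        assert result.correlation.estimate < 0

    @pytest.mark.parametrize("sizes", [(2, 3), (3, 3), (4, 5), (5, 5), (2, 5)])
    def test_mwu_matches_full_enumeration(self, sizes):
        rng = np.random.default_rng(sum(sizes))
        for _ in range(10):
            pool = rng.permutation(1000)[: sum(sizes)].astype(float)
            x = list(pool[: sizes[0]])
            y = list(pool[sizes[0]:])
            _, p = _mannwhitney(x, y)
            assert p == pytest.approx(enumerate_mwu_p(x, y), abs=1e-12)


def improvement_cohort(make_cohort):
    """2 improved patients at 6000 steps/day, 2 non-improved at 4000."""
    spec, pre_resp, post_resp = {}, {}, {}
    for pid, steps, improved in (
        ("I1", 6000, True),
        ("I2", 6000, True),
        ("N1", 4000, False),
        ("N2", 4000, False),
    ):
        records = {d: steps for d in range(-7, 15) if d != 0}
        spec[pid] = records
        pre_items = {item: 2 for item in CATALOG.all_items}
        post_items = {item: (1 if improved else 2) for item in CATALOG.all_items}
        pre_resp[pid] = MsasResponse(pid, pre_items)
        post_resp[pid] = MsasResponse(pid, post_items)
    return make_cohort(spec, msas_pre=pre_resp, msas_post=post_resp)


class TestImprovementSplit:
    def test_hand_cohort_group_means(self, make_cohort):
        cohort = improvement_cohort(make_cohort)
        for subscale in ("gdi", "tmsas", "phys", "psych"):
            split = improvement_step_comparison(cohort, subscale)
            assert split["improved"].n == 2
            assert split["improved"].pre_mean_steps == pytest.approx(6000)
            assert split["improved"].post_mean_steps == pytest.approx(6000)
            assert split["not_improved"].pre_mean_steps == pytest.approx(4000)

    def test_all_improved_single_row(self, make_cohort):
        cohort = improvement_cohort(make_cohort)
        # make everyone improve
        for pid in cohort.patient_ids:
            cohort.msas_post[pid] = MsasResponse(
                pid, {item: 0 for item in CATALOG.all_items}
            )
        split = improvement_step_comparison(cohort, "gdi")
        assert split["improved"].n == 4
        assert isinstance(split["not_improved"], Absent)

    def test_negative_coupling_generator(self):
        cohort = gen_cohort(scenario("reference", seed=17, n_patients=150))
        split = improvement_step_comparison(cohort, "tmsas")
        assert split["improved"].pre_mean_steps > split["not_improved"].pre_mean_steps
        assert split["improved"].post_mean_steps > split["not_improved"].post_mean_steps

    def test_unknown_subscale(self, make_cohort):
        with pytest.raises(ValueError):
            improvement_step_comparison(improvement_cohort(make_cohort), "bogus")


class TestAgeSplit:
    def test_hand_cohort_medians(self, make_cohort):
        spec = {
            "Y1": ({-1: 6000, -2: 6000}, {"age": 45}),
            "Y2": ({-1: 5600, -2: 5600}, {"age": 59}),
            "O1": ({-1: 4700, -2: 4700}, {"age": 60}),
            "O2": ({-1: 4800, -2: 4800}, {"age": 75}),
        }
        result = age_split_comparison(make_cohort(spec), "pre", threshold=60)
        assert result.younger.median == pytest.approx(5800)
        assert result.older.median == pytest.approx(4750)
        assert isinstance(result.p_value, float)

    def test_all_same_side_absent(self, make_cohort):
        spec = {f"P{i}": ({-1: 5000}, {"age": 70 + i}) for i in range(3)}
        result = age_split_comparison(make_cohort(spec), "pre", threshold=60)
        assert isinstance(result.younger, Absent)
        assert isinstance(result.p_value, Absent)

    def test_zero_threshold_boundary(self, make_cohort):
        spec = {f"P{i}": ({-1: 5000 + i}, {"age": 50 + i}) for i in range(3)}
        result = age_split_comparison(make_cohort(spec), "pre", threshold=0)
        assert isinstance(result.younger, Absent)
        assert result.older.n == 3
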