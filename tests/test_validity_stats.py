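"""Nonparametric statistics: Kruskal-Wallis, Dunn-Holm, categorical
thresholds, relevance synthesis, quantiles, and power simulation.

The Dunn/Kruskal-Wallis oracle used here is an independent brute-force
implementation (explicit rank computation via argsort, manual tie
correction, manual Holm step-down) kept deliberately separate from the
package code path."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as hst
from scipy import stats as sps

from vestigait import validity_stats as vs
from vestigait.trial_io import SubjectMeta, load_reference_cohort


# --- independent oracle -----------------------------------------------------

def oracle_ranks(pooled):
    order = np.argsort(pooled, kind="stable")
    ranks = np.empty(len(pooled))
    i = 0
    srt = pooled[order]
    while i < len(srt):
        j = i
        while j < len(srt) and srt[j] == srt[i]:
            j += 1
        ranks[order[i:j]] = 0.5 * (i + 1 + j)  # average rank of the tie run
        i = j
    return ranks


def oracle_kw(groups):
    pooled = np.concatenate(groups)
    n = len(pooled)
    ranks = oracle_ranks(pooled)
    h = 0.0
    start = 0
    for g in groups:
        r = ranks[start : start + len(g)]
        h += len(g) * (r.mean() - (n + 1) / 2) ** 2
        start += len(g)
    h *= 12.0 / (n * (n + 1))
    # tie correction
    _, counts = np.unique(pooled, return_counts=True)
    c = 1.0 - np.sum(counts**3 - counts) / (n**3 - n)
    h = h / c if c > 0 else 0.0
    return h, sps.chi2.sf(h, len(groups) - 1)


def oracle_holm(pvals):
    m = len(pvals)
    order = np.argsort(pvals)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * pvals[idx])
        adj[idx] = min(running, 1.0)
    return adj


def oracle_dunn(groups_dict, pairs):
    names = list(groups_dict)
    pooled = np.concatenate([groups_dict[g] for g in names])
    n = len(pooled)
    ranks = oracle_ranks(pooled)
    mean_rank, start = {}, 0
    for g in names:
        k = len(groups_dict[g])
        mean_rank[g] = ranks[start : start + k].mean()
        start += k
    _, counts = np.unique(pooled, return_counts=True)
    tie = np.sum(counts**3 - counts) / (12.0 * (n - 1))
    raw = []
    for pair in pairs:
        a, b = pair.split("-")
        se = np.sqrt((n * (n + 1) / 12.0 - tie)
                     * (1 / len(groups_dict[a]) + 1 / len(groups_dict[b])))
        z = (mean_rank[a] - mean_rank[b]) / se
        raw.append(2 * sps.norm.sf(abs(z)))
    return dict(zip(pairs, oracle_holm(np.array(raw))))


class TestKruskalWallis:
    def test_hand_rank_example(self):
        # three separated triples: H = 12/(9*10) * (3*9 + 0 + 3*9) = 7.2
        h, p = vs.kruskal_wallis([1, 2, 3], [4, 5, 6], [7, 8, 9])
        assert h == pytest.approx(7.2, abs=1e-12)
        assert p == pytest.approx(sps.chi2.sf(7.2, 2), abs=1e-12)

    def test_identical_groups_no_evidence(self):
        h, p = vs.kruskal_wallis([1.0, 1.0], [1.0, 1.0], [1.0, 1.0])
        assert h == 0.0 and p == 1.0

    def test_group_label_permutation_invariance(self):
        rng = np.random.default_rng(2)
        a, b, c = rng.normal(size=(3, 8))
        h1, _ = vs.kruskal_wallis(a, b, c)
        h2, _ = vs.kruskal_wallis(c, a, b)
        assert h1 == pytest.approx(h2, rel=1e-12)

    def test_undersized_group_missing(self):
        h, p = vs.kruskal_wallis([1.0], [1, 2, 3], [4, 5, 6])
        assert np.isnan(h) and np.isnan(p)


class TestDunnHolm:
    def test_matches_independent_oracle_on_random_fixtures(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            groups = {g: rng.normal(rng.uniform(-1, 1), 1.0,
                                    rng.integers(5, 12))
                      for g in ("BV", "UV", "HS")}
            got = vs.dunn_holm(groups)
            want = oracle_dunn(groups, vs.PAIRS)
            for pair in vs.PAIRS:
                assert got[pair] == pytest.approx(want[pair], abs=1e-10)

    def test_kw_oracle_on_random_fixtures_with_ties(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            gs = [np.round(rng.normal(size=rng.integers(5, 12)), 1)
                  for _ in range(3)]
            h1, p1 = vs.kruskal_wallis(*gs)
            h2, p2 = oracle_kw(gs)
            assert h1 == pytest.approx(h2, abs=1e-10)
            assert p1 == pytest.approx(p2, abs=1e-10)

    def test_identical_groups_all_adjusted_one(self):
        groups = {g: np.ones(6) for g in ("BV", "UV", "HS")}
        adj = vs.dunn_holm(groups)
        assert all(p == 1.0 for p in adj.values())

    def test_contract_requires_significant_kw(self):
        groups = {g: np.arange(5.0) for g in ("BV", "UV", "HS")}
        with pytest.raises(ValueError, match="Kruskal-Wallis"):
            vs.dunn_holm(groups, kw_p=0.2)

    @given(hst.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_holm_never_decreases_and_preserves_order(self, seed):
        rng = np.random.default_rng(seed)
        groups = {g: rng.normal(rng.uniform(-0.5, 0.5), 1.0, 8)
                  for g in ("BV", "UV", "HS")}
        adj = vs.dunn_holm(groups)
        raw = {}
        pooled = np.concatenate(list(groups.values()))
        want = oracle_dunn(groups, vs.PAIRS)
        for pair in vs.PAIRS:
            assert 0.0 <= adj[pair] <= 1.0
            assert adj[pair] == pytest.approx(want[pair], abs=1e-10)


class TestShapiroScreen:
    def test_normal_quantiles_pass(self):
        q = sps.norm.ppf((np.arange(10) + 0.5) / 10)
        rep = vs.shapiro_screen({"HS": q})
        assert rep["p"].iloc[0] > 0.05

    def test_bimodal_sample_fails(self):
        x = np.r_[np.full(5, -5.0), np.full(5, 5.0)] + \
            0.01 * np.arange(10)
        rep = vs.shapiro_screen({"BV": x})
        assert rep["p"].iloc[0] < 0.05

    def test_small_and_constant_groups_flagged(self):
        rep = vs.shapiro_screen({"a": [1.0, 2.0], "b": np.ones(8)})
        assert "n < 3" in rep["note"].iloc[0]
        assert "constant" in rep["note"].iloc[1]


class TestCategorize:
    @pytest.mark.parametrize("p,expected", [
        (0.0005, "excellent"), (0.001, "excellent"), (0.005, "good"),
        (0.03, "moderate"), (0.07, "fair"), (0.1, "poor"), (0.5, "poor")])
    def test_discriminant_thresholds(self, p, expected):
        assert vs.categorize(p, "discriminant") == expected

    @pytest.mark.parametrize("r,expected", [
        (0.85, "excellent"), (0.61, "good"), (-0.81, "excellent"),
        (0.5, "moderate"), (0.3, "fair"), (0.2, "poor"), (0.05, "poor")])
    def test_correlation_thresholds(self, r, expected):
        assert vs.categorize(r, "correlation") == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            vs.categorize(1.5, "discriminant")
        with pytest.raises(ValueError):
            vs.categorize(1.2, "correlation")


class TestRelevanceRule:
    def _matrix(self, kw_p, r, applicability):
        cell = vs.ComparisonCell("comfortable_gait", "Walking_speed",
                                 1.0, kw_p, {"BV": 10, "UV": 10, "HS": 10})
        if kw_p <= 0.05:
            cell.dunn_p = {"BV-HS": kw_p, "UV-HS": 0.5, "BV-UV": 0.5}
        corr = [vs.ConvergentCell("comfortable_gait", "Walking_speed",
                                  "BV", r, 10)]
        app = dict(vs.DEFAULT_APPLICABILITY)
        app["Walking_speed"] = applicability
        return vs.synthesize_relevance([cell], corr, app)

    def test_moderate_good_excellent_is_relevant(self):
        out = self._matrix(kw_p=0.03, r=0.7, applicability="excellent")
        assert out["tier"].iloc[0] == "relevant"

    def test_weak_applicability_is_interesting(self):
        out = self._matrix(kw_p=0.03, r=0.5, applicability="poor")
        assert out["tier"].iloc[0] == "interesting"

    def test_poor_discrimination_is_not_relevant(self):
        out = self._matrix(kw_p=0.5, r=0.9, applicability="excellent")
        assert out["tier"].iloc[0] == "not-relevant"

    def test_missing_applicability_entry_raises(self):
        cell = vs.ComparisonCell("t", "Mystery", 1.0, 0.5, {})
        with pytest.raises(KeyError, match="Mystery"):
            vs.synthesize_relevance([cell], [], vs.DEFAULT_APPLICABILITY)


class TestConvergentCorrelations:
    def _table(self, values_by_subject, task="comfortable_gait",
               param="Walking_speed", group="BV"):
        rows = [(sid, group, task, param, v)
                for sid, v in values_by_subject.items()]
        return pd.DataFrame(rows, columns=["subject", "group", "task",
                                           "parameter", "value"])

    def test_perfect_linear_relation(self):
        cohort = [SubjectMeta(f"B{i}", "BV", "both", dhi=2.0 * i + 1)
                  for i in range(5)]
        table = self._table({f"B{i}": float(i) for i in range(5)})
        cells = vs.convergent_correlations(table, cohort)
        assert cells[0].r == pytest.approx(1.0, abs=1e-12)

    def test_hand_covariance_example(self):
        cohort = [SubjectMeta(f"B{i}", "BV", "both", dhi=y)
                  for i, y in enumerate([1, 3, 2, 4])]
        table = self._table({f"B{i}": float(x)
                             for i, x in enumerate([1, 2, 3, 4])})
        cells = vs.convergent_correlations(table, cohort)
        assert cells[0].r == pytest.approx(0.8, abs=1e-12)

    def test_missing_dhi_excluded_pairwise(self):
        cohort = load_reference_cohort()
        bv = [s for s in cohort if s.group == "BV"]
        table = self._table({s.subject_id: float(i)
                             for i, s in enumerate(bv)})
        cells = vs.convergent_correlations(table, cohort)
        assert cells[0].n == 9  # one BV participant has no DHI

    def test_zero_variance_gives_no_cell(self):
        cohort = [SubjectMeta(f"B{i}", "BV", "both", dhi=10.0 + i)
                  for i in range(5)]
        table = self._table({f"B{i}": 1.0 for i in range(5)})
        assert vs.convergent_correlations(table, cohort) == []


class TestMedianIqr:
    def test_singleton(self):
        assert vs.median_iqr([5.0]) == (5.0, 5.0, 5.0)

    def test_missing_dropped(self):
        med, q1, q3 = vs.median_iqr([1.0, None, np.nan, 3.0])
        assert med == 2.0

    def test_empty_missing(self):
        assert all(np.isnan(v) for v in vs.median_iqr([]))


class TestPowerSimulation:
    def test_null_calibrates_to_alpha(self):
        specs = [(0.0, 1.0, 10)] * 3
        power = vs.simulate_kw_power(specs, alpha=0.05, n_sim=4000, seed=0)
        se = np.sqrt(0.05 * 0.95 / 4000)
        assert power == pytest.approx(0.05, abs=3 * se + 0.005)

    def test_huge_separation_saturates(self):
        specs = [(0.0, 1.0, 10), (10.0, 1.0, 10), (20.0, 1.0, 10)]
        power = vs.simulate_kw_power(specs, n_sim=500, seed=1)
        assert power == 1.0

    def test_invalid_sd_rejected(self):
        with pytest.raises(ValueError):
            vs.simulate_kw_power([(0.0, 0.0, 10)] * 3)

    def test_matches_per_cohort_scipy_loop(self):
        specs = [(1.09, 0.22, 10), (1.05, 0.17, 10), (1.29, 0.09, 10)]
        # the vectorized rank path must agree with a direct per-cohort loop
        rng = np.random.default_rng(5)
        n_sim = 300
        hits = 0
        for _ in range(n_sim):
            gs = [rng.normal(m, s, n) for m, s, n in specs]
            hits += sps.kruskal(*gs)[1] <= 0.05
        loop = hits / n_sim
        vec = vs.simulate_kw_power(specs, n_sim=4000, seed=5)
        se = np.sqrt(loop * (1 - loop) / n_sim)
        assert vec == pytest.approx(loop, abs=4 * se)


class TestDiscriminantGrid:
    def _long_table(self, rng, n_tasks=3, effect=0.0):
        rows = []
        for t in range(n_tasks):
            for g, shift in (("BV", effect), ("UV", effect / 2), ("HS", 0.0)):
                for i in range(10):
                    rows.append((f"{g}{i}", g, f"task{t}", "P",
                                 rng.normal(shift, 1.0)))
        return pd.DataFrame(rows, columns=["subject", "group", "task",
                                           "parameter", "value"])

    def test_absent_parameter_marked_not_relevant(self):
        rng = np.random.default_rng(0)
        table = self._long_table(rng)
        grid = vs.build_discriminant_grid(table, all_parameters=["P", "Q"])
        q_cells = [c for c in grid if c.parameter == "Q"]
        assert q_cells and all(c.not_relevant for c in q_cells)

    def test_strong_effect_detected(self):
        rng = np.random.default_rng(1)
        table = self._long_table(rng, effect=3.0)
        grid = vs.build_discriminant_grid(table)
        for c in grid:
            assert c.kw_p <= 0.05 and c.dunn_p is not None
            assert c.dunn_p["BV-HS"] <= 0.05

    def test_dunn_only_when_significant(self):
        rng = np.random.default_rng(2)
        table = self._long_table(rng, n_tasks=30, effect=0.0)
        grid = vs.build_discriminant_grid(table)
        for c in grid:
            assert (c.dunn_p is not None) == (c.kw_p <= 0.05)

    def test_type_one_error_calibrated(self):
        """Cell-wise Kruskal-Wallis rejection rate under exchangeable
        groups stays near the nominal 5% over >= 2000 cells."""
        rng = np.random.default_rng(10)
        rows = []
        for t in range(70):
            for p in range(30):
                for g in ("BV", "UV", "HS"):
                    for i in range(10):
                        rows.append((f"{g}{i}", g, f"t{t}", f"p{p}",
                                     rng.normal()))
        table = pd.DataFrame(rows, columns=["subject", "group", "task",
                                            "parameter", "value"])
        grid = vs.build_discriminant_grid(table)
        assert len(grid) == 2100
        rate = np.mean([c.kw_p <= 0.05 for c in grid])
        assert 0.03 <= rate <= 0.07
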