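"""Rank tests against enumeration oracles; Bonferroni; cascade behavior."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from striodens.stats import (
    ComparisonPlan,
    bonferroni,
    comparisons_table,
    kruskal_wallis,
    mann_whitney_u,
    run_cascade,
)


def exact_mw_p_by_enumeration(a, b):
    """Two-sided exact Mann-Whitney p by complete enumeration of the rank
    assignments (no ties).  Independent of the implementation under test."""
    n1, n2 = len(a), len(b)
    pooled = np.concatenate([a, b])
    ranks = pooled.argsort().argsort() + 1
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    mu = n1 * n2 / 2
    stat_obs = abs(u_obs - mu)
    total = 0
    extreme = 0
    all_ranks = np.arange(1, n1 + n2 + 1)
    for combo in itertools.combinations(range(n1 + n2), n1):
        u = all_ranks[list(combo)].sum() - n1 * (n1 + 1) / 2
        total += 1
        if abs(u - mu) >= stat_obs - 1e-9:
            extreme += 1
    return extreme / total


class TestKruskalWallis:
    def test_three_even_groups(self):
        h, p = kruskal_wallis([[1, 2, 3], [4, 5, 6], [7, 8, 9]])
        assert h == pytest.approx(7.2)

    def test_identical_groups_have_zero_h(self):
        h, _ = kruskal_wallis([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
        assert h == pytest.approx(0.0)

    def test_constant_data(self):
        assert kruskal_wallis([[5.0, 5.0], [5.0, 5.0]]) == (0.0, 1.0)

    def test_invariant_to_within_group_ordering(self):
        rng = np.random.default_rng(0)
        groups = [rng.normal(size=5).tolist() for _ in range(3)]
        h1, _ = kruskal_wallis(groups)
        shuffled = [sorted(g, reverse=True) for g in groups]
        h2, _ = kruskal_wallis(shuffled)
        assert h1 == pytest.approx(h2)

    def test_two_group_p_ranking_matches_mann_whitney(self):
        """With 2 groups, Kruskal-Wallis orders datasets by p exactly as the
        Mann-Whitney test does (no ties)."""
        rng = np.random.default_rng(1)
        results = []
        for _ in range(20):
            a = rng.normal(size=6)
            b = rng.normal(loc=rng.uniform(0, 2), size=6)
            _, kw_p = kruskal_wallis([a, b])
            _, mw_p, _ = mann_whitney_u(a, b, mode="exact")
            results.append((kw_p, mw_p))
        for (k1, m1), (k2, m2) in itertools.combinations(results, 2):
            if not math.isclose(m1, m2):
                assert (k1 < k2) == (m1 < m2)


class TestMannWhitney:
    def test_small_sample_exact_p(self):
        u, p, mode = mann_whitney_u([1, 2], [3, 4])
        assert u == 0
        assert p == pytest.approx(1 / 3)
        assert mode == "exact"

    def test_identical_samples(self):
        _, p, _ = mann_whitney_u([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == 1.0

    def test_constant_samples_zero_variance_guard(self):
        _, p, mode = mann_whitney_u([4.0, 4.0, 4.0], [4.0, 4.0, 4.0])
        assert p == 1.0
        assert mode.startswith("normal")

    def test_exact_mode_refuses_ties(self):
        _, _, mode = mann_whitney_u([1.0, 2.0, 2.0], [2.0, 3.0], mode="exact")
        assert mode == "normal+ties-fallback"

    @pytest.mark.parametrize("seed", range(10))
    def test_exact_equals_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n1, n2 = rng.integers(2, 9, size=2)
        a = rng.normal(size=n1)
        b = rng.normal(loc=rng.uniform(-1, 1), size=n2)
        _, p, mode = mann_whitney_u(a, b, mode="exact")
        assert mode == "exact"
        assert p == pytest.approx(exact_mw_p_by_enumeration(a, b), abs=1e-12)


class TestBonferroni:
    def test_arithmetic_and_cap(self):
        assert bonferroni([0.004], m=10) == [pytest.approx(0.04)]
        assert bonferroni([0.2], m=10) == [1.0]

    def test_boundary_not_significant_under_strict_rule(self):
        adjusted = bonferroni([0.005], m=10)[0]
        assert adjusted == pytest.approx(0.05)
        assert not (adjusted < 0.05)  # strict < at alpha

    def test_family_size_validation(self):
        with pytest.raises(ValueError):
            bonferroni([0.1, 0.2], m=1)
        with pytest.raises(ValueError):
            bonferroni([0.1], m=0)

    @settings(max_examples=50, derandomize=True)
    @given(
        st.lists(st.floats(0, 1), min_size=1, max_size=6),
        st.integers(6, 30),
        st.integers(0, 20),
    )
    def test_monotone_in_p_and_m(self, ps, m, extra):
        adj = bonferroni(ps, m=m)
        assert all(a <= b for a, b in zip(sorted(adj), bonferroni(sorted(ps), m=m)))
        bigger = bonferroni(ps, m=m + extra)
        assert all(a <= b for a, b in zip(adj, bigger))


def _metric_cohort(rng, effect=0.0, n_animals=4, metric="strio_intensity"):
    """Metrics-style table: one value per hemisphere, genotype effect on one
    metric in the DL sector only."""
    rows = []
    for genotype in ("WT", "MUT"):
        for i in range(n_animals):
            intercept = rng.normal(0, 1)
            for hemi in ("left", "right"):
                for sector in ("whole", "DM", "DL", "VM", "VL"):
                    value = rng.normal(10, 0.5) + intercept
                    if genotype == "MUT" and sector == "DL":
                        value += effect
                    rows.append(
                        {
                            "level": "rostral",
                            "age": 3,
                            "sector": sector,
                            "genotype": genotype,
                            "animal_id": f"{genotype}{i}",
                            metric: value,
                            "matrix_intensity": rng.normal(5, 0.5) + intercept,
                        }
                    )
    return pd.DataFrame(rows)


class TestCascade:
    def test_programmed_effect_flagged_and_null_metric_not(self):
        rng = np.random.default_rng(5)
        table = _metric_cohort(rng, effect=8.0)
        plan = ComparisonPlan(metrics=("strio_intensity", "matrix_intensity"))
        out = comparisons_table(run_cascade(table, plan))
        dl_strio = out[(out["sector"] == "DL") & (out["metric"] == "strio_intensity")]
        dl_matrix = out[(out["sector"] == "DL") & (out["metric"] == "matrix_intensity")]
        assert bool(dl_strio["significant"].iloc[0])
        assert not bool(dl_matrix["significant"].iloc[0])
        assert (out["family_m"] == 10).all()

    def test_missing_group_skipped(self):
        rng = np.random.default_rng(6)
        table = _metric_cohort(rng)
        table = table[table["genotype"] == "WT"]
        assert run_cascade(table, ComparisonPlan(metrics=("strio_intensity",))) == []

    def test_audit_fields_present(self):
        rng = np.random.default_rng(7)
        table = _metric_cohort(rng)
        comps = run_cascade(table, ComparisonPlan(metrics=("strio_intensity",)))
        for c in comps:
            assert c.group_n == [8, 8]
            assert c.family_m >= len(c.raw_p)
            assert all(m in ("exact", "normal", "normal+ties-fallback") for m in c.modes)
            for raw, adj in zip(c.raw_p, c.adjusted_p):
                assert adj == pytest.approx(min(1.0, raw * c.family_m))

    def test_monotone_power_in_effect_size(self):
        """Doubling the programmed effect never lowers the mean number of
        flagged comparisons (200 replicate metric cohorts)."""
        flags = {}
        for effect in (1.5, 3.0):
            rng = np.random.default_rng(11)
            counts = []
            for _ in range(200):
                table = _metric_cohort(rng, effect=effect)
                out = comparisons_table(
                    run_cascade(table, ComparisonPlan(metrics=("strio_intensity",)))
                )
                counts.append(int(out["significant"].sum()))
            flags[effect] = np.mean(counts)
        assert flags[3.0] >= flags[1.5]


class TestHolm:
    def test_step_down_adjustment(self):
        from striodens.stats import holm

        # ordered p: 0.01, 0.02, 0.04 with m=3 -> 0.03, 0.04, 0.04
        assert holm([0.02, 0.01, 0.04], m=3) == [
            pytest.approx(0.04),
            pytest.approx(0.03),
            pytest.approx(0.04),
        ]

    def test_never_exceeds_bonferroni(self):
        from striodens.stats import holm

        rng = np.random.default_rng(0)
        ps = rng.uniform(0, 1, size=8).tolist()
        for h, b in zip(holm(ps, m=10), bonferroni(ps, m=10)):
            assert h <= b + 1e-12

    def test_cascade_flag_selects_holm(self):
        rng = np.random.default_rng(5)
        table = _metric_cohort(rng, effect=8.0)
        plan = ComparisonPlan(metrics=("strio_intensity",), correction="holm")
        out = comparisons_table(run_cascade(table, plan))
        assert (out["adjusted_p"] <= 1.0).all()
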