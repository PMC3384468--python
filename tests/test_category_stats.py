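"""Rank-sum machinery, the hierarchy verdict, ΔGC3 and correlations."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from gc3kog.composition import GeneRecord
from gc3kog.category_stats import (
    category_hierarchy_test,
    delta_gc3,
    gc_correlations,
    mann_whitney,
)


def brute_force_mw(x, y, alternative="two-sided"):
    """Exhaustive-enumeration oracle for the exact Mann-Whitney p-value."""
    x, y = list(x), list(y)
    pooled = x + y
    n, m = len(x), len(y)
    u_obs = sum(xi > yj for xi in x for yj in y)
    us = []
    for idx in itertools.combinations(range(n + m), n):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(n + m) if i not in idx]
        us.append(sum(a > b for a in xs for b in ys))
    us = np.array(us)
    total = len(us)
    if alternative == "greater":
        p = (us >= u_obs).sum() / total
    else:
        p = min(1.0, 2 * min((us <= u_obs).sum(), (us >= u_obs).sum()) / total)
    return u_obs, p


class TestMannWhitney:
    def test_separated_triplets(self):
        u, p = mann_whitney([1, 2, 3], [4, 5, 6])
        assert u == 0 and p == pytest.approx(0.1)

    def test_identical_samples_p_one(self):
        _, p = mann_whitney([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == pytest.approx(1.0)

    def test_empty_sample_errors(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])

    def test_u_statistics_sum_to_nm(self, rng):
        x = rng.normal(size=23)
        y = rng.normal(size=17)
        ux, _ = mann_whitney(x, y)
        uy, _ = mann_whitney(y, x)
        assert ux + uy == pytest.approx(23 * 17)

    @given(
        st.integers(1, 7),
        st.integers(1, 7),
        st.randoms(use_true_random=False),
    )
    def test_exact_branch_matches_enumeration(self, n, m, random):
        vals = random.sample(range(1000), n + m)
        x, y = [float(v) for v in vals[:n]], [float(v) for v in vals[n:]]
        u, p = mann_whitney(x, y)
        u_oracle, p_oracle = brute_force_mw(x, y)
        assert u == u_oracle
        assert p == pytest.approx(p_oracle, abs=1e-12)

    def test_type_one_error_rate_under_null(self, rng):
        reps, n, alpha = 1000, 2000, 0.05
        rejections = 0
        for _ in range(reps):
            x = rng.normal(0.58, 0.16, n)
            y = rng.normal(0.58, 0.16, n)
            _, p = mann_whitney(x, y)
            rejections += p < alpha
        ci = 2.576 * np.sqrt(alpha * (1 - alpha) / reps)
        assert abs(rejections / reps - alpha) < ci


def make_records(means, n, rng, sd=0.15):
    recs = []
    for cat, mu in means.items():
        vals = np.clip(rng.normal(mu, sd, n), 0, 1)
        recs += [
            GeneRecord(f"{cat}{i}", "sp", 0.5, float(v), 100, category=cat)
            for i, v in enumerate(vals)
        ]
    return recs


class TestHierarchy:
    def test_missing_category_errors(self, rng):
        recs = make_records({"BLUE": 0.5, "BLACK": 0.5}, 10, rng)
        with pytest.raises(ValueError, match="RED"):
            category_hierarchy_test(recs)

    def test_planted_hierarchy_gives_pattern(self, rng):
        recs = make_records({"BLUE": 0.50, "BLACK": 0.58, "RED": 0.66}, 800, rng)
        comparisons, verdict = category_hierarchy_test(recs)
        assert verdict == "PATTERN"
        assert all(c.p_two_sided < 0.05 for c in comparisons)
        assert {c.direction for c in comparisons} == {"RED", "BLACK"}

    def test_red_only_shift_gives_partial(self, rng):
        # the monotreme/marsupial-like structure: Red exceeds both,
        # Black and Blue indistinguishable
        recs = make_records({"BLUE": 0.58, "BLACK": 0.58, "RED": 0.60}, 2000, rng)
        _, verdict = category_hierarchy_test(recs)
        assert verdict == "PARTIAL"

    def test_exchangeable_categories_give_none(self, rng):
        recs = make_records({"BLUE": 0.58, "BLACK": 0.58, "RED": 0.58}, 1500, rng)
        _, verdict = category_hierarchy_test(recs)
        assert verdict == "NONE"

    def test_invariant_to_order_and_shift(self, rng):
        recs = make_records({"BLUE": 0.45, "BLACK": 0.50, "RED": 0.55}, 300, rng, sd=0.05)
        comp1, v1 = category_hierarchy_test(recs)
        shuffled = list(recs)
        rng.shuffle(shuffled)
        shifted = [
            GeneRecord(r.id, r.species, r.gc, min(1.0, r.gc3 + 0.1), r.n_codons,
                       category=r.category)
            for r in shuffled
        ]
        comp2, v2 = category_hierarchy_test(shifted)
        assert v1 == v2
        assert [(c.pair, c.statistic, c.p_two_sided) for c in comp1] == [
            (c.pair, c.statistic, c.p_two_sided) for c in comp2
        ]


def _genomes(rng, n=300, shift=None):
    ref = make_records({"BLUE": 0.55, "BLACK": 0.58, "RED": 0.61}, n, rng, sd=0.1)
    shift = shift or {}
    tgt = [
        GeneRecord("t_" + r.id, "tgt", r.gc,
                   float(np.clip(r.gc3 - shift.get(r.category, 0.0), 0, 1)),
                   r.n_codons, category=r.category)
        for r in ref
    ]
    pairs = [(r.id, "t_" + r.id) for r in ref]
    return ref, tgt, pairs


class TestDeltaGc3:
    def test_identical_genomes_degenerate(self, rng):
        ref, tgt, pairs = _genomes(rng)
        res = delta_gc3(pairs, ref, tgt)
        assert res.degenerate
        assert all(d.delta_gc3 == 0 for d in res.deltas)
        assert res.tests == []

    def test_antisymmetric_orientation(self, rng):
        ref, tgt, pairs = _genomes(rng, shift={"RED": 0.1, "BLACK": 0.05, "BLUE": 0.02})
        fwd = delta_gc3(pairs, ref, tgt)
        rev = delta_gc3([(t, r) for r, t in pairs], tgt, ref)
        assert np.allclose(
            [d.delta_gc3 for d in fwd.deltas], [-d.delta_gc3 for d in rev.deltas]
        )

    def test_planted_red_increment_detected(self, rng):
        ref, tgt, pairs = _genomes(
            rng, n=500, shift={"RED": 0.10, "BLACK": 0.05, "BLUE": 0.05}
        )
        res = delta_gc3(pairs, ref, tgt)
        per = res.per_category.set_index("category")
        assert per.loc["RED", "mean_delta"] == pytest.approx(0.10, abs=0.02)
        tested = {c.pair: c for c in res.tests}
        assert tested[("RED", "BLACK")].p_two_sided < 0.05
        assert tested[("RED", "BLACK")].direction == "RED"

    def test_unknown_gene_errors(self, rng):
        ref, tgt, _ = _genomes(rng, n=5)
        with pytest.raises(KeyError):
            delta_gc3([("nope", tgt[0].id)], ref, tgt)


class TestCorrelations:
    def test_perfect_linear(self):
        df = pd.DataFrame({"gc3": [0.1, 0.2, 0.3, 0.4], "intron_gc": [0.2, 0.4, 0.6, 0.8]})
        out = gc_correlations(df)
        assert out.loc[0, "pearson_r"] == pytest.approx(1.0)

    def test_monotone_nonlinear_spearman_exceeds_pearson(self, rng):
        x = rng.uniform(0, 1, 500)
        df = pd.DataFrame({"x": x, "y": np.exp(8 * x)})
        out = gc_correlations(df)
        assert out.loc[0, "spearman_rho"] > out.loc[0, "pearson_r"]
        assert out.loc[0, "spearman_rho"] == pytest.approx(1.0)

    def test_independent_columns_near_zero(self, rng):
        df = pd.DataFrame({"x": rng.normal(size=1000), "y": rng.normal(size=1000)})
        out = gc_correlations(df)
        assert abs(out.loc[0, "pearson_r"]) < 0.1

    def test_too_few_rows_errors(self):
        with pytest.raises(ValueError):
            gc_correlations(pd.DataFrame({"x": [1.0, 2.0], "y": [1.0, 2.0]}))

    def test_incomplete_rows_dropped(self):
        df = pd.DataFrame(
            {"x": [1.0, 2.0, 3.0, 4.0, np.nan], "y": [2.0, 4.0, 6.0, 8.0, 1.0]}
        )
        out = gc_correlations(df)
        assert out.loc[0, "n"] == 4
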