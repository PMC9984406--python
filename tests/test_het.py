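"""Rank-based HET statistics against exhaustive enumeration oracles.

The oracles below recompute each statistic from its definition (explicit
threshold scans, pair counting) and each exact p value by enumerating every
arrangement of group labels over the pooled observed values; they share no
code with the dynamic-programming implementations they check.
"""

import itertools
import math
from fractions import Fraction

import numpy as np
import pytest
from scipy import stats

from lsvkit.het import (
    STATISTICS,
    _TOL,
    het_test,
    infoscore,
    mann_whitney,
    tnom,
    welch_t,
)
from lsvkit.psi import ExperimentLsvCoverage, experiment_psi


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def oracle_two_u(x, y):
    return sum(2 * (a > b) + (a == b) for a in x for b in y)


def oracle_tnom_stat(x, y):
    """Scan every threshold between distinct pooled values, both orientations."""
    vals = sorted(set(x) | set(y))
    cuts = [min(vals) - 1] + [
        (a + b) / 2 for a, b in zip(vals, vals[1:])
    ] + [max(vals) + 1]
    best = len(x) + len(y)
    for t in cuts:
        left_x = sum(1 for v in x if v < t)
        left_y = sum(1 for v in y if v < t)
        m1 = left_y + (len(x) - left_x)   # x below, y above
        m2 = left_x + (len(y) - left_y)   # y below, x above
        best = min(best, m1, m2)
    return best


def oracle_info_stat(x, y):
    vals = sorted(set(x) | set(y))
    n1, n2 = len(x), len(y)
    n = n1 + n2

    def h(p):
        return 0.0 if p <= 0 or p >= 1 else -p * math.log2(p) - (1 - p) * math.log2(1 - p)

    best = 0.0
    for t in [(a + b) / 2 for a, b in zip(vals, vals[1:])]:
        lx = sum(1 for v in x if v < t)
        ly = sum(1 for v in y if v < t)
        left, right = lx + ly, n - lx - ly
        cond = 0.0
        if left:
            cond += left / n * h(lx / left)
        if right:
            cond += right / n * h((n1 - lx) / right)
        best = max(best, h(n1 / n) - cond)
    return best


def enumerate_labelings(pooled, n1):
    for idx in itertools.combinations(range(len(pooled)), n1):
        sel = set(idx)
        x = [pooled[i] for i in range(len(pooled)) if i in sel]
        y = [pooled[i] for i in range(len(pooled)) if i not in sel]
        yield x, y


def oracle_mwu_p(x, y):
    pooled = list(x) + list(y)
    n1, n2 = len(x), len(y)
    dev = abs(oracle_two_u(x, y) - n1 * n2)
    hits = sum(
        1 for xs, ys in enumerate_labelings(pooled, n1)
        if abs(oracle_two_u(xs, ys) - n1 * n2) >= dev
    )
    return float(Fraction(hits, math.comb(n1 + n2, n1)))


def oracle_tnom_p(x, y):
    pooled = list(x) + list(y)
    obs = oracle_tnom_stat(x, y)
    hits = sum(
        1 for xs, ys in enumerate_labelings(pooled, len(x))
        if oracle_tnom_stat(xs, ys) <= obs
    )
    return float(Fraction(hits, math.comb(len(pooled), len(x))))


def oracle_info_p(x, y):
    pooled = list(x) + list(y)
    obs = oracle_info_stat(x, y)
    if obs <= _TOL:
        return 1.0
    hits = sum(
        1 for xs, ys in enumerate_labelings(pooled, len(x))
        if oracle_info_stat(xs, ys) >= obs - _TOL
    )
    return float(Fraction(hits, math.comb(len(pooled), len(x))))


# ---------------------------------------------------------------------------
# Welch
# ---------------------------------------------------------------------------

class TestWelch:
    def test_identical_constant_groups(self):
        assert welch_t([0.5] * 3, [0.5] * 4) == 1.0

    def test_separated_groups_significant_and_match_formula(self):
        x, y = [0.1, 0.2, 0.3], [0.7, 0.8, 0.9]
        p = welch_t(x, y)
        # textbook Welch-Satterthwaite computation
        vx, vy = np.var(x, ddof=1), np.var(y, ddof=1)
        t = (np.mean(x) - np.mean(y)) / math.sqrt(vx / 3 + vy / 3)
        df = (vx / 3 + vy / 3) ** 2 / (
            (vx / 3) ** 2 / 2 + (vy / 3) ** 2 / 2
        )
        expect = 2 * stats.t.sf(abs(t), df)
        assert p == pytest.approx(expect, rel=1e-9)
        assert p < 0.05

    def test_symmetric_in_group_order(self, rng):
        x, y = rng.uniform(size=5), rng.uniform(size=7)
        assert welch_t(x, y) == pytest.approx(welch_t(y, x))

    def test_constant_groups_with_different_means(self):
        assert welch_t([0.2] * 3, [0.8] * 3) == 0.0


# ---------------------------------------------------------------------------
# Mann-Whitney
# ---------------------------------------------------------------------------

class TestMannWhitney:
    def test_fully_separated_small(self):
        assert mann_whitney([1, 2], [3, 4]) == pytest.approx(2 / 6)

    def test_all_tied_gives_one(self):
        assert mann_whitney([5.0] * 3, [5.0] * 4) == 1.0

    @pytest.mark.parametrize("n1,n2", [(1, 3), (2, 2), (3, 4), (5, 3), (6, 6)])
    def test_exact_matches_enumeration_continuous(self, n1, n2, rng):
        x = list(rng.uniform(size=n1))
        y = list(rng.uniform(size=n2))
        assert mann_whitney(x, y) == oracle_mwu_p(x, y)

    @pytest.mark.parametrize("n1,n2", [(2, 3), (4, 4), (5, 4)])
    def test_exact_matches_enumeration_with_ties(self, n1, n2, rng):
        x = list(rng.integers(0, 3, size=n1).astype(float))
        y = list(rng.integers(0, 3, size=n2).astype(float))
        assert mann_whitney(x, y) == oracle_mwu_p(x, y)

    def test_asymptotic_close_to_permutation(self, rng):
        x = rng.normal(0.0, 1.0, size=35)
        y = rng.normal(0.5, 1.0, size=35)
        p = mann_whitney(x, y)  # n = 70 -> asymptotic branch
        # permutation oracle on the U statistic
        pooled = np.concatenate([x, y])
        ranks = stats.rankdata(pooled)
        obs = ranks[:35].sum()
        perms = np.array([
            rng.permutation(ranks)[:35].sum() for _ in range(100_000)
        ])
        mu = ranks.sum() * 35 / 70
        p_perm = np.mean(np.abs(perms - mu) >= abs(obs - mu) - 1e-9)
        assert abs(p - p_perm) < 0.01


# ---------------------------------------------------------------------------
# TNOM
# ---------------------------------------------------------------------------

class TestTnom:
    def test_perfect_separation(self):
        stat, p = tnom([0.1, 0.2], [0.7, 0.8])
        assert stat == 0
        assert p == pytest.approx(2 / 6)

    def test_interleaved(self):
        stat, _ = tnom([1, 3], [2, 4])
        assert stat == oracle_tnom_stat([1, 3], [2, 4]) == 1

    def test_identical_constants(self):
        stat, p = tnom([2.0, 2.0], [2.0, 2.0, 2.0])
        assert stat == 2 and p == 1.0

    @pytest.mark.parametrize("n1,n2", [(1, 4), (2, 3), (3, 3), (4, 5), (6, 5)])
    def test_matches_enumeration(self, n1, n2, rng):
        for vals in (rng.uniform(size=n1 + n2),
                     rng.integers(0, 3, size=n1 + n2).astype(float)):
            x, y = list(vals[:n1]), list(vals[n1:])
            stat, p = tnom(x, y)
            assert stat == oracle_tnom_stat(x, y)
            assert p == oracle_tnom_p(x, y)


# ---------------------------------------------------------------------------
# InfoScore
# ---------------------------------------------------------------------------

class TestInfoScore:
    def test_perfect_balanced_split_is_one_bit(self):
        stat, p = infoscore([0.1, 0.2], [0.7, 0.8])
        assert stat == pytest.approx(1.0)
        assert p == pytest.approx(2 / 6)

    def test_indistinguishable_values(self):
        stat, p = infoscore([3.0, 3.0], [3.0, 3.0, 3.0])
        assert stat == 0.0 and p == 1.0

    @pytest.mark.parametrize("n1,n2", [(1, 4), (2, 3), (3, 3), (4, 5), (6, 5)])
    def test_matches_enumeration(self, n1, n2, rng):
        for vals in (rng.uniform(size=n1 + n2),
                     rng.integers(0, 3, size=n1 + n2).astype(float)):
            x, y = list(vals[:n1]), list(vals[n1:])
            stat, p = infoscore(x, y)
            assert stat == pytest.approx(oracle_info_stat(x, y), abs=1e-12)
            assert p == oracle_info_p(x, y)


# ---------------------------------------------------------------------------
# invariances
# ---------------------------------------------------------------------------

class TestInvariances:
    @pytest.mark.parametrize("name", ["mannwhitney", "tnom", "infoscore"])
    def test_rank_tests_invariant_to_monotone_transform(self, name, rng):
        x, y = list(rng.uniform(size=5)), list(rng.uniform(size=6))
        f = STATISTICS[name]
        tx = [math.exp(3 * v) for v in x]
        ty = [math.exp(3 * v) for v in y]
        assert f(x, y) == pytest.approx(f(tx, ty))

    @pytest.mark.parametrize("name", list(STATISTICS))
    def test_two_sided_symmetry(self, name, rng):
        x, y = list(rng.uniform(size=4)), list(rng.uniform(size=6))
        f = STATISTICS[name]
        assert f(x, y) == pytest.approx(f(y, x))


# ---------------------------------------------------------------------------
# het_test driver
# ---------------------------------------------------------------------------

def point_mass_posterior(psi, lsv_id="l", bins=40):
    reads = np.array([psi, 1 - psi]) * 1e4
    boots = np.tile(reads[:, None], (1, 3))
    exp = ExperimentLsvCoverage("e", reads, np.full(2, 10.0), boots)
    return experiment_psi(exp, lsv_id, [("J", 0, 1), ("J", 1, 2)], bins=bins)


def degenerate_posterior(psi, bins=40):
    """A true point mass: all density in the bin containing psi."""
    from lsvkit.psi import PsiPosterior, psi_bins

    centers = psi_bins(bins)
    j = int(np.argmin(np.abs(centers - psi)))
    density = np.zeros((2, bins))
    density[0, j] = 1.0
    density[1, bins - 1 - j] = 1.0
    means = np.array([centers[j], 1 - centers[j]])
    a = np.full((3, 2), 1.0)
    return PsiPosterior("l", [("J", 0, 1), ("J", 1, 2)], a, a, density, means)


class TestHetDriver:
    def test_point_mass_posteriors_make_quantile_equal_mean(self):
        g1 = [degenerate_posterior(p) for p in (0.18, 0.2, 0.22)]
        g2 = [degenerate_posterior(p) for p in (0.7, 0.75, 0.8)]
        res = het_test(g1, g2, n_rep=12, seed=3)
        for s in res.p_quantile:
            assert res.p_quantile[s][0] == pytest.approx(res.p_mean[s][0])

    def test_medians_and_difference(self):
        g1 = [point_mass_posterior(p) for p in (0.2, 0.3, 0.4)]
        g2 = [point_mass_posterior(p) for p in (0.6, 0.7, 0.8)]
        res = het_test(g1, g2, n_rep=0, seed=0)
        assert res.medians[0][0] == pytest.approx(0.3, abs=0.02)
        assert res.medians[1][0] == pytest.approx(0.7, abs=0.02)
        assert res.dmedian[0] == pytest.approx(0.4, abs=0.03)

    def test_unquantifiable_experiments_dropped(self):
        g1 = [None, point_mass_posterior(0.4), point_mass_posterior(0.5)]
        g2 = [point_mass_posterior(0.5), None, point_mass_posterior(0.6)]
        res = het_test(g1, g2, n_rep=0, seed=0)
        assert res is not None

    def test_empty_group_skips_lsv(self):
        assert het_test([None], [point_mass_posterior(0.5)], n_rep=0) is None

    def test_deterministic_given_seed(self):
        g1 = [point_mass_posterior(p) for p in (0.2, 0.4, 0.5)]
        g2 = [point_mass_posterior(p) for p in (0.5, 0.6, 0.8)]
        a = het_test(g1, g2, n_rep=10, seed=11)
        b = het_test(g1, g2, n_rep=10, seed=11)
        for s in a.p_quantile:
            assert np.array_equal(a.p_quantile[s], b.p_quantile[s])
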