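import numpy as np
import pytest

from avistability.stability import (
    ExtinctionCurve,
    active_extinction_curve,
    curve_auc,
    curve_half_life,
    functional_vulnerability,
    passive_extinction_curve,
)
from avistability.tpd import assemblage_tpd
from oracles import make_toy_tpd, oracle_active_curve, oracle_spearman


def _curve(points):
    return ExtinctionCurve("t", "general_traits", "active", np.asarray(points, float), 1)


def _disjoint_assemblage(n, support=4):
    members = [
        (make_toy_tpd(f"s{i}", {j: 1.0 for j in range(i * support, (i + 1) * support)}), 1.0)
        for i in range(n)
    ]
    return assemblage_tpd("A", members)


def _identical_assemblage(n):
    cells = {0: 0.3, 1: 0.3, 2: 0.4}
    return assemblage_tpd("A", [(make_toy_tpd(f"s{i}", cells), 1.0) for i in range(n)])


class TestVulnerability:
    def test_perfect_anticorrelation_gives_plus_one(self):
        red = {"a": 3.0, "b": 2.0, "c": 1.0, "d": 0.5}
        sens = {"a": 0.1, "b": 0.5, "c": 0.9, "d": 1.5}
        assert functional_vulnerability(red, sens) == pytest.approx(1.0)

    def test_perfect_correlation_gives_minus_one(self):
        red = {"a": 1.0, "b": 2.0, "c": 3.0}
        sens = {"a": 0.1, "b": 0.2, "c": 0.4}
        assert functional_vulnerability(red, sens) == pytest.approx(-1.0)

    def test_ties_match_average_rank_spearman_oracle(self):
        red = {"a": 1.0, "b": 1.0, "c": 3.0, "d": 2.0, "e": 5.0}
        sens = {"a": 0.5, "b": 0.2, "c": 0.2, "d": 0.9, "e": 0.1}
        got = functional_vulnerability(red, sens)
        exp = -oracle_spearman(
            np.array([sens[k] for k in red]), np.array([red[k] for k in red])
        )
        assert got == pytest.approx(exp, abs=1e-12)

    def test_constant_vector_flagged_not_raised(self):
        with pytest.warns(UserWarning, match="constant"):
            v = functional_vulnerability({"a": 1.0, "b": 1.0, "c": 1.0}, {"a": 1, "b": 2, "c": 3})
        assert np.isnan(v)

    def test_too_few_species_raises(self):
        with pytest.raises(ValueError):
            functional_vulnerability({"a": 1.0, "b": 2.0}, {"a": 1.0, "b": 2.0})


class TestActiveCurve:
    def test_identical_tpds_hold_fd_until_last_removal(self):
        atpd = _identical_assemblage(5)
        scores = {f"s{i}": float(i) for i in range(5)}
        c = active_extinction_curve(atpd, scores)
        np.testing.assert_allclose(c.points[:-1, 1], 1.0)
        assert c.points[-1, 1] == 0.0

    def test_disjoint_equal_supports_decline_linearly(self):
        n = 6
        atpd = _disjoint_assemblage(n)
        scores = {f"s{i}": float(i) for i in range(n)}
        c = active_extinction_curve(atpd, scores)
        np.testing.assert_allclose(c.points[:, 1], (n - np.arange(n + 1)) / n, atol=1e-12)

    def test_matches_prefix_removal_oracle(self, rng):
        """5-species toy with stated scores equals recompute-by-definition."""
        members = [
            (make_toy_tpd(f"s{i}", {int(c): 1.0 for c in rng.choice(30, 6, replace=False)}),
             float(rng.random() + 0.5))
            for i in range(5)
        ]
        atpd = assemblage_tpd("A", members)
        scores = {f"s{i}": [3.0, 1.0, 5.0, 2.0, 4.0][i] for i in range(5)}
        c = active_extinction_curve(atpd, scores)
        order = sorted(scores, key=scores.get, reverse=True)
        np.testing.assert_allclose(c.points[:, 1], oracle_active_curve(atpd, order, 30), atol=1e-12)

    def test_curve_endpoints_standardised(self, rng):
        atpd = _disjoint_assemblage(4)
        c = active_extinction_curve(atpd, {f"s{i}": float(i) for i in range(4)})
        assert tuple(c.points[0]) == (0.0, 1.0)
        assert tuple(c.points[-1]) == (1.0, 0.0)
        assert (np.diff(c.points[:, 1]) <= 1e-12).all()

    def test_tie_breaking_averages_over_replicates(self):
        # two tied species: one unique, one redundant with the third
        members = [
            (make_toy_tpd("u", {0: 1.0, 1: 1.0}), 1.0),
            (make_toy_tpd("r1", {10: 1.0, 11: 1.0}), 1.0),
            (make_toy_tpd("r2", {10: 1.0, 11: 1.0}), 1.0),
        ]
        atpd = assemblage_tpd("A", members)
        scores = {"u": 1.0, "r1": 1.0, "r2": 0.0}  # u and r1 tied at the top
        c = active_extinction_curve(atpd, scores, n_tiebreak_reps=400, rng_seed=5)
        assert c.replicates == 400
        # first removal is u or r1 with equal probability: mean rel_fd = 0.5*(0.5 + 1.0)
        assert c.points[1, 1] == pytest.approx(0.75, abs=0.05)


class TestPassiveCurve:
    def test_time_to_first_removal_matches_geometric_law(self):
        """Two species with removal probs (0.9, 0.1): mean wait = 1/(1-0.1*0.9)."""
        atpd = _disjoint_assemblage(2)
        scores = {"s0": 2.0, "s1": 1.0}
        c = passive_extinction_curve(
            atpd, scores, n_reps=10_000, rng_seed=3, keep_replicates=True,
            prob_fn=lambda s: np.where(s > 1.5, 0.9, 0.1),
        )
        waits = []
        for pts in c.replicate_points:
            drop = np.nonzero(pts[:, 1] < 1.0)[0][0]
            waits.append(pts[drop, 0])
        expected = 1.0 / (1.0 - 0.1 * 0.9)
        assert np.mean(waits) == pytest.approx(expected, abs=0.02)

    def test_at_most_two_removals_per_step(self):
        atpd = _disjoint_assemblage(8, support=2)
        scores = {f"s{i}": 10.0 for i in range(8)}
        c = passive_extinction_curve(
            atpd, scores, n_reps=50, rng_seed=1, keep_replicates=True,
            prob_fn=lambda s: np.full(len(s), 0.99),
        )
        for pts in c.replicate_points:
            drops = -np.diff(pts[:, 1]) * 8 * 2  # cells lost per step / cells per sp.
            removed_per_step = -np.diff(pts[:, 1]) / (1.0 / 8)
            assert (removed_per_step <= 2 + 1e-9).all()

    def test_sharp_probabilities_approach_active_order(self):
        """Near-deterministic removal probabilities reproduce the active curve."""
        atpd = _disjoint_assemblage(4)
        scores = {f"s{i}": float(i) for i in range(4)}
        active = active_extinction_curve(atpd, scores)
        passive = passive_extinction_curve(
            atpd, scores, n_reps=200, rng_seed=2,
            max_removals_per_step=1,
            prob_fn=lambda s: np.where(s == s.max(), 0.9999, 1e-6),
        )
        # compare on the shared lattice of removal fractions
        interp = np.interp(active.points[:, 0], passive.points[:, 0], passive.points[:, 1])
        np.testing.assert_allclose(interp, active.points[:, 1], atol=0.05)

    def test_mean_curve_standardised_and_monotone(self):
        atpd = _disjoint_assemblage(5)
        scores = {f"s{i}": float(i % 3) for i in range(5)}
        c = passive_extinction_curve(atpd, scores, n_reps=30, rng_seed=0)
        assert c.points[0, 1] == 1.0 and c.points[-1, 1] == 0.0
        assert (np.diff(c.points[:, 1]) <= 1e-9).all()


class TestCurveSummaries:
    @pytest.mark.parametrize(
        "points,expected",
        [
            ([(0, 1), (0.25, 1), (0.5, 1), (0.75, 1), (1, 0)], 0.875),
            ([(0, 1), (1, 0)], 0.5),
            ([(0, 1), (0.25, 0), (0.5, 0), (0.75, 0), (1, 0)], 0.125),
        ],
    )
    def test_auc_trapezoid_arithmetic(self, points, expected):
        assert curve_auc(_curve(points)) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize(
        "points,expected",
        [
            ([(0, 1), (1, 0)], 0.5),
            ([(0, 1), (0.75, 1), (1, 0)], 0.875),
            ([(0, 1), (0.5, 1), (1, 1)], 1.0),  # fully redundant: never reaches 0.5
        ],
    )
    def test_half_life(self, points, expected):
        assert curve_half_life(_curve(points)) == pytest.approx(expected, abs=1e-12)

    def test_dominance_monotonicity(self, rng):
        """Pointwise-dominating curves have larger AUC and half-life."""
        x = np.linspace(0, 1, 21)
        for _ in range(10):
            ya = np.sort(rng.random(21))[::-1]
            ya[0], ya[-1] = 1.0, 0.0
            yb = np.clip(ya - rng.random(21) * 0.3, 0, 1)
            yb = np.minimum.accumulate(yb)
            yb[0], yb[-1] = min(1.0, ya[0]), 0.0
            yb = np.minimum(yb, ya)
            a, b = _curve(np.column_stack([x, ya])), _curve(np.column_stack([x, yb]))
            assert curve_auc(a) >= curve_auc(b) - 1e-12
            assert curve_half_life(a) >= curve_half_life(b) - 1e-12


class TestVulnerabilityRecovery:
    def test_unique_sensitive_species_yield_positive_vulnerability(self):
        """Sign flips with the sensitivity of the functionally unique species."""
        from avistability.diversity import all_species_redundancy_contributions

        members = [
            (make_toy_tpd("u1", {100: 1.0, 101: 1.0}), 1.0),
            (make_toy_tpd("u2", {200: 1.0, 201: 1.0}), 1.0),
            (make_toy_tpd("r1", {0: 1.0, 1: 1.0}), 1.0),
            (make_toy_tpd("r2", {0: 1.0, 1: 1.0}), 1.0),
            (make_toy_tpd("r3", {0: 1.0, 1: 1.0}), 1.0),
        ]
        atpd = assemblage_tpd("A", members)
        contribs = all_species_redundancy_contributions(atpd)
        sens_hi_unique = {"u1": 2.0, "u2": 1.5, "r1": -1.0, "r2": -0.5, "r3": -2.0}
        sens_lo_unique = {"u1": -2.0, "u2": -1.5, "r1": 1.0, "r2": 0.5, "r3": 2.0}
        assert functional_vulnerability(contribs, sens_hi_unique) > 0
        assert functional_vulnerability(contribs, sens_lo_unique) < 0
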