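"""Necessity / sufficiency metrics and counterfactual-frequency attribution."""

import numpy as np
import pytest

from necsuff import (
    AttributionResult,
    ContractError,
    DiverseCF,
    ExhaustiveGenerator,
    PermuteAttack,
    cf_frequency_attribution,
    necessity,
    necsuff_report,
    sufficiency,
)

from .conftest import (
    LinearThresholdModel,
    brute_force_necessity,
    brute_force_sufficiency,
    step_model,
)

EX = ExhaustiveGenerator()


def _pool(seed=0, n=40, d=3, loc=0.0):
    return np.random.default_rng(seed).normal(loc, 1.0, (n, d))


def _dpool(seed=0, n=16, d=3):
    # binary-valued pool so exhaustive enumeration stays tiny
    return np.random.default_rng(seed).integers(0, 2, (n, d)).astype(float)


class TestFrequencyAttribution:
    def test_single_cause_model_concentrates_on_x0(self):
        pool = _pool(0, loc=0.5)
        rows = _pool(1, n=8, loc=-0.5)
        freq = cf_frequency_attribution(
            step_model(0), rows, PermuteAttack(), seed=0,
            reference_pool=pool, budget=800,
        )
        assert freq.fractions[0] == pytest.approx(1.0)
        assert np.all(freq.fractions[1:] == 0.0)
        assert np.all(freq.fractions <= 1.0)
        assert freq.n_counterfactuals == 8

    def test_or_style_model_uses_either_single_feature(self):
        """Flip reachable via either feature; proximity keeps edits singletons."""
        model = LinearThresholdModel([1.0, 1.0, 0.0], b=-0.5)
        pool = np.random.default_rng(2).uniform(-2, 2, (40, 3))
        rows = np.random.default_rng(3).uniform(-1.0, -0.7, (10, 3))
        counts = np.zeros(3)
        for i, row in enumerate(rows):
            f = cf_frequency_attribution(
                model, row[None, :], PermuteAttack(), seed=i,
                reference_pool=pool, budget=1500,
            )
            assert f.n_counterfactuals == 1
            sizes = [np.count_nonzero(f.counts)]
            assert sizes == [1]  # a single changed feature per counterfactual
            counts += f.counts
        assert counts[0] > 0 and counts[1] > 0
        assert counts[2] == 0

    def test_failed_instances_reported_not_counted(self):
        const = lambda X: np.full(np.atleast_2d(X).shape[0], 0.8)
        freq = cf_frequency_attribution(
            const, _pool(4, n=5), PermuteAttack(), seed=0,
            reference_pool=_pool(5), budget=300,
        )
        assert freq.n_no_counterfactual == 5
        assert freq.n_counterfactuals == 0
        assert np.all(freq.fractions == 0.0)

    def test_empty_evaluation_set_rejected(self):
        with pytest.raises(ContractError):
            cf_frequency_attribution(
                step_model(), np.empty((0, 2)), PermuteAttack(),
                reference_pool=_pool(0, d=2),
            )


class TestNecessity:
    def test_ignored_feature_has_zero_necessity(self):
        val = necessity(step_model(0), _pool(0), [2], EX, n_cf=2, seed=0,
                        reference_pool=_pool(1))
        assert val == 0.0

    def test_single_cause_threshold_full_necessity(self):
        pool = _pool(2, loc=0.0)
        rows = _pool(3, n=10)
        val = necessity(step_model(0), rows, [0], EX, n_cf=1, seed=0,
                        reference_pool=pool)
        assert val == 1.0

    def test_unknown_target_rejected(self):
        with pytest.raises(ContractError):
            necessity(step_model(0), _pool(0), [9], EX, reference_pool=_pool(1))

    @pytest.mark.parametrize("n_cf", [1, 2, 4])
    def test_lookup_table_model_matches_enumeration(self, n_cf):
        """4-binary-feature model: exact match vs brute-force enumeration."""
        rng = np.random.default_rng(42)
        table = rng.integers(0, 2, size=(2,) * 4).astype(float)

        def model(X):
            X = np.atleast_2d(X).astype(int)
            return table[X[:, 0], X[:, 1], X[:, 2], X[:, 3]]

        pool = rng.integers(0, 2, size=(20, 4)).astype(float)
        rows = rng.integers(0, 2, size=(6, 4)).astype(float)
        for target in ([0], [1, 3]):
            expected = brute_force_necessity(model, rows, target, n_cf,
                                             levels=(0.0, 1.0))
            got = necessity(model, rows, target, EX, n_cf=n_cf, seed=0,
                            reference_pool=pool)
            assert got == pytest.approx(expected)


class TestSufficiency:
    def test_constant_model_zero(self):
        const = lambda X: np.full(np.atleast_2d(X).shape[0], 0.8)
        assert sufficiency(const, _pool(0), [0], EX, n_cf=2, seed=0,
                           reference_pool=_pool(1)) == 0.0

    def test_single_cause_sufficiency_equals_unconstrained_fraction(self):
        """Freezing the only cause blocks every flip, so term B vanishes."""
        pool = _pool(2)
        rows = _pool(3, n=10)
        suff = sufficiency(step_model(0), rows, [0], EX, n_cf=1, seed=0,
                           reference_pool=pool)
        # term A: every instance flips through x0 when all features are free
        assert suff == 1.0

    def test_ignored_feature_near_zero_over_seeds(self):
        model = step_model(0)
        pool = _pool(4)
        rows = _pool(5, n=6)
        vals = [
            sufficiency(model, rows, [2], DiverseCF(), n_cf=2, seed=s,
                        reference_pool=pool, budget=600)
            for s in range(10)
        ]
        assert abs(np.mean(vals)) < 0.05

    def test_matches_brute_force_on_binary_space(self):
        rng = np.random.default_rng(9)
        model = LinearThresholdModel(rng.normal(0, 1, 3), b=0.2)
        pool = rng.integers(0, 2, size=(15, 3)).astype(float)
        rows = rng.integers(0, 2, size=(5, 3)).astype(float)
        for target in ([0], [2]):
            expected = brute_force_sufficiency(model, rows, target, 2,
                                               levels=(0.0, 1.0))
            got = sufficiency(model, rows, target, EX, n_cf=2, seed=0,
                              reference_pool=pool)
            assert got == pytest.approx(expected)

    def test_prose_variant_flag(self):
        pool = _pool(2)
        rows = _pool(3, n=6)
        prose = sufficiency(step_model(0), rows, [0], EX, n_cf=1, seed=0,
                            reference_pool=pool, prose_variant=True)
        assert prose == 1.0  # 1 - term B with the only cause frozen


def _ranking(d, order=None):
    vals = np.linspace(1.0, 0.1, d)
    if order is not None:
        v = np.zeros(d)
        v[list(order)] = vals[: len(order)]
        vals = v
    return AttributionResult(values=vals, method="shapley", scope="global")


class TestReport:
    def test_target_count_is_k_plus_two_per_generator(self):
        model = step_model(0)
        pool = _dpool(0, d=4)
        rows = _pool(1, n=4, d=4)
        report = necsuff_report(
            model, rows, _ranking(4), k=2,
            generators={"exhaustive": EX}, seed=0,
            reference_pool=pool, budgets=(1, 2), budget=400,
        )
        assert len(report.entries) == 2 + 2  # 2 singles + combined + complement
        names = {t for (_, t) in report.entries}
        assert "top_k_combined" in names and "complement" in names

    def test_all_necessity_values_in_unit_interval(self):
        model = LinearThresholdModel([1.0, -1.0, 0.5], b=0.0)
        report = necsuff_report(
            model, _dpool(2, n=4), _ranking(3), k=1,
            generators={"exhaustive": EX}, seed=0,
            reference_pool=_dpool(3), budgets=(1, 2), budget=400,
        )
        for vals in report.entries.values():
            for v in vals["necessity"].values():
                assert 0.0 <= v <= 1.0
            for v in vals["sufficiency"].values():
                assert v >= 0.0

    def test_combined_necessity_at_least_max_single(self):
        """A feature-set mask can reach every flip its subsets can."""
        model = LinearThresholdModel([1.0, 1.0, 0.0], b=-0.5)
        pool = np.random.default_rng(5).integers(0, 2, (16, 3)).astype(float)
        rows = np.random.default_rng(6).integers(0, 2, (5, 3)).astype(float)
        report = necsuff_report(
            model, rows, _ranking(3, order=[0, 1]), k=2,
            generators={"exhaustive": EX}, seed=0,
            reference_pool=pool, budgets=(1, 2, 4), budget=1000,
        )
        singles = [
            report.entries[("exhaustive", t)]["necessity"]["mean"]
            for (_, t) in report.entries
            if t.startswith("top") and t != "top_k_combined"
        ]
        combined = report.entries[("exhaustive", "top_k_combined")]["necessity"]["mean"]
        assert combined >= max(singles)

    def test_budget_average_reported(self):
        report = necsuff_report(
            step_model(0), _dpool(7, n=3), _ranking(3), k=1,
            generators={"exhaustive": EX}, seed=0,
            reference_pool=_dpool(8), budgets=(1, 2, 4, 8), budget=400,
        )
        for vals in report.entries.values():
            assert set(vals["necessity"]) == {1, 2, 4, 8, "mean"}
            assert vals["necessity"]["mean"] == pytest.approx(
                np.mean([vals["necessity"][b] for b in (1, 2, 4, 8)])
            )

    def test_k_exceeding_feature_count_rejected(self):
        with pytest.raises(ContractError):
            necsuff_report(step_model(0), _pool(0), _ranking(3), k=9,
                           generators={"exhaustive": EX}, reference_pool=_pool(1))

    def test_non_global_ranking_rejected(self):
        local = AttributionResult(values=np.ones(3), method="shapley",
                                  scope="instance")
        with pytest.raises(ContractError):
            necsuff_report(step_model(0), _pool(0), local, k=1,
                           generators={"exhaustive": EX}, reference_pool=_pool(1))
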