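import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ddnetmap import (
    ChoiceProfile,
    ChoiceSimSpec,
    DiscountModel,
    MCQItem,
    ParameterError,
    QCThresholds,
    candidate_grid,
    consistency_at_k,
    default_item_bank,
    estimate_k,
    gen_mcq_responses,
    implied_k,
    qc_flags,
    score_cohort,
)
from ddnetmap.mcq import MISSING


ITEMS = default_item_bank()
GRID = candidate_grid(ITEMS)


class TestImpliedK:
    def test_worked_examples(self):
        assert implied_k(MCQItem("i", 50, 100, 50)) == pytest.approx(0.02)
        assert implied_k(MCQItem("i", 99, 100, 1)) == pytest.approx(1 / 99)
        # k scales inversely with delay
        assert implied_k(MCQItem("i", 50, 100, 25)) == pytest.approx(0.04)

    def test_invalid_items_rejected(self):
        with pytest.raises(ParameterError):
            MCQItem("i", 100, 50, 10)  # delayed must exceed immediate
        with pytest.raises(ParameterError):
            MCQItem("i", 50, 100, 0)


class TestConsistency:
    def test_extreme_profiles(self):
        n = len(ITEMS)
        all_delayed = ChoiceProfile("p", [1] * n)
        all_imm = ChoiceProfile("p", [0] * n)
        k_lo = GRID[0]
        k_hi = GRID[-1]
        assert consistency_at_k(all_delayed, ITEMS, k_lo) == 1.0
        assert consistency_at_k(all_imm, ITEMS, k_hi) == 1.0
        assert consistency_at_k(all_delayed, ITEMS, k_hi) == 0.0

    def test_boundary_tie_counts_consistent(self):
        item = MCQItem("i", 50, 100, 50)  # implied k = 0.02 exactly
        for choice in (0, 1):
            prof = ChoiceProfile("p", [choice])
            assert consistency_at_k(prof, [item], 0.02) == 1.0

    def test_missing_excluded_from_denominator(self):
        items = [MCQItem("1", 50, 100, 50), MCQItem("2", 50, 100, 25)]
        prof = ChoiceProfile("p", [1, MISSING])
        # at k below both implied: predicted delayed for the answered item
        assert consistency_at_k(prof, items, 0.001) == 1.0

    def test_all_missing_rejected(self):
        prof = ChoiceProfile("p", [MISSING] * len(ITEMS))
        with pytest.raises(ParameterError):
            consistency_at_k(prof, ITEMS, 0.02)


def brute_force_best_k(profile, items, grid):
    """Independent oracle: full-grid consistency maximization."""
    cons = [consistency_at_k(profile, items, k) for k in grid]
    best = max(cons)
    plateau = [k for k, c in zip(grid, cons) if c == best]
    return np.exp(np.mean(np.log(plateau)))


class TestEstimateK:
    def test_on_grid_noiseless_recovery_matches_oracle(self):
        true_k = GRID[np.argmin(np.abs(GRID - 0.05))]  # on-grid rate near 0.05
        prof = gen_mcq_responses(ChoiceSimSpec(np.log10(true_k), 0.0, ITEMS))
        res = estimate_k(prof, ITEMS, GRID)
        oracle = brute_force_best_k(prof, ITEMS, GRID)
        assert res.k_overall == pytest.approx(oracle, rel=1e-12)
        spacing = np.max(np.diff(np.log10(GRID)))
        assert abs(res.log10_k - np.log10(true_k)) <= spacing / 2
        # the bin plateaus contain the truth
        for k_bin in res.k_by_bin.values():
            assert GRID[0] <= k_bin <= GRID[-1]

    def test_all_delayed_floors_estimate(self):
        prof = ChoiceProfile("p", [1] * len(ITEMS))
        res = estimate_k(prof, ITEMS, GRID)
        assert res.k_overall == GRID[0]
        assert "floor_estimate" in res.qc_reasons

    def test_all_immediate_ceils_estimate(self):
        prof = ChoiceProfile("p", [0] * len(ITEMS))
        res = estimate_k(prof, ITEMS, GRID)
        assert res.k_overall == GRID[-1]
        assert "ceiling_estimate" in res.qc_reasons

    def test_item_order_invariance(self):
        prof = gen_mcq_responses(ChoiceSimSpec(-1.5, 0.0, ITEMS))
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(ITEMS))
        prof_p = ChoiceProfile("p", [prof.choices[i] for i in perm])
        items_p = [ITEMS[i] for i in perm]
        a = estimate_k(prof, ITEMS, GRID)
        b = estimate_k(prof_p, items_p, GRID)
        assert a.k_overall == pytest.approx(b.k_overall, rel=1e-12)
        assert a.k_by_bin == pytest.approx(b.k_by_bin)

    def test_empty_grid_rejected(self):
        prof = ChoiceProfile("p", [1] * len(ITEMS))
        with pytest.raises(ParameterError):
            estimate_k(prof, ITEMS, np.array([]))

    def test_log10_is_exact_transform(self):
        prof = gen_mcq_responses(ChoiceSimSpec(-2.0, 0.0, ITEMS))
        res = estimate_k(prof, ITEMS, GRID)
        assert 10 ** res.log10_k == pytest.approx(res.k_overall, rel=1e-12)

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(st.floats(min_value=-3.7, max_value=-0.65))
    def test_noiseless_chooser_fully_consistent_at_estimate(self, log10k):
        """A temperature-0 chooser is 100% consistent at its own estimate."""
        prof = gen_mcq_responses(ChoiceSimSpec(log10k, 0.0, ITEMS))
        res = estimate_k(prof, ITEMS, GRID)
        assert res.consistency == 1.0


class TestMonotonicity:
    def test_khat_monotone_in_true_k(self):
        prev = -np.inf
        for t in GRID:
            prof = gen_mcq_responses(ChoiceSimSpec(np.log10(t), 0.0, ITEMS))
            k_hat = estimate_k(prof, ITEMS, GRID).k_overall
            assert k_hat >= prev - 1e-15
            prev = k_hat


class TestQC:
    def _result(self, prof):
        return estimate_k(prof, ITEMS, GRID)

    def test_clean_profile_passes(self):
        prof = gen_mcq_responses(ChoiceSimSpec(-1.5, 0.0, ITEMS))
        res = self._result(prof)
        ok, reasons = qc_flags(prof, res)
        assert ok and not reasons

    def test_low_concordance_fails(self):
        # anti-hyperbolic responder: delayed exactly when a rational
        # discounter would go immediate
        rng = np.random.default_rng(1)
        prof = gen_mcq_responses(ChoiceSimSpec(-1.5, 0.0, ITEMS))
        flipped = ChoiceProfile("p", [1 - c for c in prof.choices])
        res = self._result(flipped)
        if res.consistency < 0.75:
            ok, reasons = qc_flags(flipped, res)
            assert not ok and "low_concordance" in reasons
        else:  # extreme flip may still fit some k; force a noisy profile
            noisy = ChoiceProfile("p", list(rng.integers(0, 2, len(ITEMS))))
            res = self._result(noisy)
            assume_low = res.consistency < 0.75
            assert assume_low

    def test_uniform_response_flagged(self):
        prof = ChoiceProfile("p", [1] * len(ITEMS))
        res = self._result(prof)
        ok, reasons = qc_flags(prof, res)
        assert not ok and "uniform_response" in reasons

    def test_missing_over_threshold_fails(self):
        choices = [1] * len(ITEMS)
        choices[0] = MISSING
        choices[3] = 0
        prof = ChoiceProfile("p", choices)
        res = self._result(prof)
        ok, reasons = qc_flags(prof, res, QCThresholds(max_missing=0))
        assert not ok and "excess_missing" in reasons
        ok2, _ = qc_flags(prof, res, QCThresholds(max_missing=2, min_consistency=0.5))
        assert ok2


class TestCohort:
    def test_score_cohort_shapes_and_exclusions(self):
        from ddnetmap import gen_cohort
        mat = gen_cohort([-3.0, -2.0, -1.0], noise_temperature=0.0, rng_seed=0)
        # append a uniform responder
        row = {"participant_id": "uniform"}
        row.update({c: 1 for c in mat.columns if c != "participant_id"})
        mat = pd.concat([mat, pd.DataFrame([row])], ignore_index=True)
        out = score_cohort(mat, ITEMS)
        assert len(out) == 4
        assert list(out.columns[:1]) == ["participant_id"]
        assert {"k_small", "k_medium", "k_large"} <= set(out.columns)
        assert out.loc[3, "qc_pass"] == False  # noqa: E712
        assert "uniform_response" in out.loc[3, "qc_reasons"]
        # noiseless rows pass and are ordered in k
        ks = out.loc[:2, "k_overall"].to_numpy()
        assert np.all(np.diff(ks) > 0)

    def test_malformed_matrix_errors(self):
        from ddnetmap import FormatError
        bad = pd.DataFrame({"participant_id": ["p1"], "item_1": [2]})
        with pytest.raises(FormatError):
            score_cohort(bad, ITEMS[:1])

    def test_model_results_summary(self):
        from ddnetmap import gen_cohort
        mat = gen_cohort(np.linspace(-3.2, -1.0, 8), noise_temperature=1.0,
                         rng_seed=4)
        res = DiscountModel(mat).fit()
        text = res.summary()
        assert "participants: 8" in text
        assert res.table["log10_k"].between(-4.0, -0.5).all()
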