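import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import studentized_range

from miprot.diffexp import (
    DEResult,
    anova_terms_matrix,
    anova_two_way,
    bh_adjust,
    call_de,
    pool_geometric,
    srange_sf,
    tukey_from_cells,
    tukey_hsd,
)
from miprot.errors import UserInputError
from miprot.impute import build_ensemble
from miprot.synthetic import GeneratorConfig, simulate

TOY_VALUES = [1.0, 3.0, 2.0, 4.0, 5.0, 7.0, 6.0, 8.0]
TOY_A = ["a1"] * 4 + ["a2"] * 4
TOY_B = ["b1", "b1", "b2", "b2"] * 2


def hand_balanced_two_way(values, a, b):
    """Independent oracle: textbook sums-of-squares decomposition for a
    balanced layout, computed cell by cell from first principles."""
    values = np.asarray(values, float)
    grand = values.mean()
    levels_a = sorted(set(a))
    levels_b = sorted(set(b))
    a = np.asarray(a)
    b = np.asarray(b)
    n_per_cell = len(values) / (len(levels_a) * len(levels_b))
    ss_a = sum(
        (values[a == la].mean() - grand) ** 2 * (a == la).sum() for la in levels_a
    )
    ss_b = sum(
        (values[b == lb].mean() - grand) ** 2 * (b == lb).sum() for lb in levels_b
    )
    ss_cells = sum(
        (values[(a == la) & (b == lb)].mean() - grand) ** 2 * n_per_cell
        for la in levels_a
        for lb in levels_b
    )
    ss_ab = ss_cells - ss_a - ss_b
    ss_err = sum(
        ((values[(a == la) & (b == lb)] - values[(a == la) & (b == lb)].mean()) ** 2).sum()
        for la in levels_a
        for lb in levels_b
    )
    return ss_a, ss_b, ss_ab, ss_err


class TestAnovaToy:
    def test_hand_decomposition_oracle(self):
        ss_a, ss_b, ss_ab, ss_err = hand_balanced_two_way(TOY_VALUES, TOY_A, TOY_B)
        assert (ss_a, ss_b, ss_ab, ss_err) == (32.0, 2.0, 0.0, 8.0)

    def test_printed_toy_f_and_p(self):
        res = anova_two_way(TOY_VALUES, factor_a=TOY_A, factor_b=TOY_B)
        assert res.F["treatment"] == pytest.approx(16.0)
        assert res.F["time"] == pytest.approx(1.0)
        assert res.F["interaction"] == pytest.approx(0.0, abs=1e-10)
        assert res.p_treatment == pytest.approx(0.0161, abs=2e-4)
        assert res.p_time == pytest.approx(0.374, abs=1e-3)
        assert res.p_interaction == pytest.approx(1.0)
        assert res.df == {"treatment": 1, "time": 1, "interaction": 1, "error": 4}

    def test_matches_hand_oracle_on_random_balanced(self):
        rng = np.random.default_rng(0)
        a = ["x"] * 6 + ["y"] * 6
        b = ["p", "p", "q", "q", "r", "r"] * 2
        values = rng.normal(size=12)
        ss_a, ss_b, ss_ab, ss_err = hand_balanced_two_way(values, a, b)
        res = anova_two_way(values, factor_a=a, factor_b=b)
        assert res.ss["treatment"] == pytest.approx(ss_a)
        assert res.ss["time"] == pytest.approx(ss_b)
        assert res.ss["interaction"] == pytest.approx(ss_ab, abs=1e-9)
        assert res.ss["error"] == pytest.approx(ss_err)

    def test_within_cell_permutation_invariance(self):
        shuffled = [3.0, 1.0, 4.0, 2.0, 7.0, 5.0, 8.0, 6.0]
        a = anova_two_way(TOY_VALUES, factor_a=TOY_A, factor_b=TOY_B)
        b = anova_two_way(shuffled, factor_a=TOY_A, factor_b=TOY_B)
        assert a.p_treatment == pytest.approx(b.p_treatment)
        assert a.p_interaction == pytest.approx(b.p_interaction)

    def test_location_invariance(self):
        base = anova_two_way(TOY_VALUES, factor_a=TOY_A, factor_b=TOY_B)
        moved = anova_two_way(
            [v + 100.0 for v in TOY_VALUES], factor_a=TOY_A, factor_b=TOY_B
        )
        for term in ("treatment", "time", "interaction"):
            assert base.F[term] == pytest.approx(moved.F[term], abs=1e-8)


class TestAnovaDesign:
    def test_balanced_identity_total_ss(self, design30):
        rng = np.random.default_rng(1)
        y = rng.normal(size=(design30.n_samples, 50))
        res = anova_terms_matrix(y, design30)
        total = ((y - y.mean(axis=0)) ** 2).sum(axis=0)
        decomposed = (
            res["ss"]["treatment"] + res["ss"]["time"]
            + res["ss"]["interaction"] + res["ss"]["error"]
        )
        np.testing.assert_allclose(decomposed, total, rtol=1e-10)

    def test_type_ii_matches_statsmodels_on_unbalanced(self, design28):
        sm = pytest.importorskip("statsmodels.api")
        from statsmodels.formula.api import ols
        from statsmodels.stats.anova import anova_lm

        rng = np.random.default_rng(2)
        values = rng.normal(size=design28.n_samples)
        res = anova_two_way(values, design28)
        df = design28.table.assign(y=values)
        fit = ols("y ~ C(group) * C(timepoint)", data=df).fit()
        tab = anova_lm(fit, typ=2)
        assert res.ss["treatment"] == pytest.approx(tab.loc["C(group)", "sum_sq"])
        assert res.ss["time"] == pytest.approx(tab.loc["C(timepoint)", "sum_sq"])
        assert res.ss["interaction"] == pytest.approx(
            tab.loc["C(group):C(timepoint)", "sum_sq"]
        )
        assert res.p_interaction == pytest.approx(
            tab.loc["C(group):C(timepoint)", "PR(>F)"]
        )

    def test_incomplete_values_rejected(self, design28):
        values = np.full(design28.n_samples, 1.0)
        values[3] = np.nan
        with pytest.raises(UserInputError, match="complete"):
            anova_two_way(values, design28)

    def test_single_sample_cell_rejected(self):
        from miprot.synthetic import generate_design

        design = generate_design(3, ["NEVKP1_BL", "NEVKP2_BL"])
        rng = np.random.default_rng(3)
        with pytest.raises(UserInputError, match=">=2 samples per cell"):
            anova_two_way(rng.normal(size=design.n_samples), design)

    def test_zero_residual_variance(self, design28):
        # constant within cells, different across groups: p 0 for the
        # affected terms, 1 where the effect SS is zero
        t = design28.table
        values = np.where(t["group"] == "NEVKP", 1.0, 2.0)
        with pytest.warns(UserWarning, match="zero residual variance"):
            res = anova_two_way(values, design28)
        assert res.p_treatment == 0.0
        assert res.p_time == 1.0


class TestTukey:
    def test_hand_computed_q_statistic(self):
        # cells {1,2},{1,2},{5,6}: pooled MSE = 0.5, extreme-pair mean
        # difference 4.0, SE = sqrt(0.5/2 * (1/2 + 1/2)) = 0.5 => q = 8.0
        results = tukey_from_cells([np.array([1.0, 2.0]), np.array([1.0, 2.0]), np.array([5.0, 6.0])])
        extreme = results[1]
        assert extreme.q_statistic == pytest.approx(8.0)
        expected_p = float(studentized_range.sf(8.0, 3, 3))
        assert extreme.adjusted_p == pytest.approx(expected_p, rel=1e-6)

    def test_identical_cells_contrast(self):
        results = tukey_from_cells([np.array([1.0, 2.0, 3.0]), np.array([1.0, 2.0, 3.0])])
        (c,) = results
        assert c.mean_difference == 0.0
        assert c.adjusted_p == pytest.approx(1.0)

    def test_adjusted_p_monotone_in_q(self):
        qs = np.linspace(0.1, 12, 30)
        ps = srange_sf(qs, 6, 22)
        assert (np.diff(ps) < 0).all()

    def test_fifteen_design_contrasts(self, design28):
        rng = np.random.default_rng(4)
        results = tukey_hsd(rng.normal(size=design28.n_samples), design28)
        assert len(results) == 15
        pairs = {tuple(sorted(map(str, r.cell_pair))) for r in results}
        assert len(pairs) == 15

    def test_fast_interpolant_matches_exact(self):
        qs = np.concatenate([np.linspace(0.05, 15, 40), [20.0, 30.0]])
        exact = srange_sf(qs, 6, 22)
        fast = srange_sf(qs, 6, 22, fast=True)
        np.testing.assert_allclose(fast, exact, rtol=5e-3, atol=1e-12)

    def test_tukey_kramer_matches_scipy_on_balanced_oneway(self):
        # one-way layout: scipy's tukey_hsd is an independent implementation
        from scipy.stats import tukey_hsd as scipy_tukey

        rng = np.random.default_rng(5)
        cells = [rng.normal(i, 1, 6) for i in range(3)]
        ours = tukey_from_cells(cells)
        ref = scipy_tukey(*cells)
        for c in ours:
            i, j = c.cell_pair
            assert c.adjusted_p == pytest.approx(ref.pvalue[i, j], abs=1e-6)


class TestBH:
    def test_printed_example(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_hand_stepup_oracle(self):
        p = np.array([0.005, 0.04, 0.02, 0.9])
        m = 4
        order = np.argsort(p)
        staged = p[order] * m / np.arange(1, 5)
        expected_sorted = np.minimum.accumulate(staged[::-1])[::-1]
        expected = np.empty(4)
        expected[order] = expected_sorted
        np.testing.assert_allclose(bh_adjust(p), expected)

    def test_constant_and_single(self):
        np.testing.assert_allclose(bh_adjust([0.3, 0.3, 0.3]), [0.3, 0.3, 0.3])
        np.testing.assert_allclose(bh_adjust([0.07]), [0.07])

    def test_out_of_range_rejected(self):
        with pytest.raises(UserInputError):
            bh_adjust([0.5, 1.5])

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=50))
    @settings(max_examples=200, deadline=None)
    def test_never_below_raw_and_permutation_invariant(self, p):
        p = np.asarray(p)
        q = bh_adjust(p)
        assert (q >= p - 1e-12).all()
        assert (q <= 1.0).all()
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(p))
        q_perm = bh_adjust(p[perm])
        np.testing.assert_allclose(q_perm, q[perm])


class TestPooling:
    def test_constant(self):
        assert pool_geometric([0.05, 0.05, 0.05]) == pytest.approx(0.05)

    def test_closed_form(self):
        assert pool_geometric([1e-2, 1e-4]) == pytest.approx(1e-3)

    def test_empty_rejected(self):
        with pytest.raises(UserInputError):
            pool_geometric([])

    def test_zero_floored_with_warning(self):
        with pytest.warns(UserWarning, match="floored"):
            out = pool_geometric([0.0, 1.0])
        assert out > 0

    @given(st.lists(st.floats(min_value=1e-12, max_value=1), min_size=1, max_size=30))
    @settings(max_examples=200, deadline=None)
    def test_between_min_and_max(self, p):
        pooled = pool_geometric(p)
        assert min(p) - 1e-15 <= pooled <= max(p) + 1e-15


def _sim_ensemble(seed, n_proteins=150, de_fraction=0.1, n_replicates=10, **kw):
    cfg = GeneratorConfig(
        n_proteins=n_proteins, de_fraction=de_fraction, effect_size_log2=2.0,
        missing_target_fraction=0.15, noise_sd=0.5, seed=seed,
        contaminant_count=0, reverse_count=0,
        pep_violation_fraction=0.0, single_peptide_fraction=0.0, **kw,
    )
    sim = simulate(cfg)
    ens = build_ensemble(sim.matrix, n_replicates=n_replicates, master_seed=seed + 1000)
    return sim, ens


class TestCallDe:
    def test_planted_effects_recovered(self):
        sim, ens = _sim_ensemble(seed=0)
        de = call_de(ens)
        true_de = set(sim.truth.de_protein_ids)
        called = set(de.significant_ids)
        recovered = called & true_de
        assert len(recovered) >= 0.8 * len(true_de)
        sub = de.table.loc[sorted(recovered)]
        assert (sub["timepoint_of_significance"] == "POD3").all()
        assert (sub["direction"] == "NEVKP").all()

    def test_null_dataset_near_zero_calls(self):
        _, ens = _sim_ensemble(seed=1, de_fraction=0.0)
        de = call_de(ens)
        assert len(de.significant_ids) <= 2

    def test_significance_implies_annotation(self):
        _, ens = _sim_ensemble(seed=2)
        de = call_de(ens)
        sig = de.table[de.table["significant"]]
        assert (sig["timepoint_of_significance"] != "").all()
        assert (sig["direction"] != "").all()
        assert (sig["q_interaction"] < de.alpha).all()

    def test_main_effects_mode(self):
        _, ens = _sim_ensemble(seed=3)
        de = call_de(ens, de_term="main_effects")
        sig = de.table[de.table["significant"]]
        assert ((sig["q_treatment"] < 0.05) & (sig["q_time"] < 0.05)).all()

    def test_pooled_q_in_unit_interval(self):
        _, ens = _sim_ensemble(seed=4, n_proteins=60, n_replicates=5)
        de = call_de(ens)
        for col in ("q_treatment", "q_time", "q_interaction"):
            assert de.table[col].between(0, 1).all()

    def test_pooling_stability_r300_vs_r150(self):
        # ensemble convergence: pooled q at R=300 and R=150 agree within
        # 10% relative for proteins with q < 0.2
        sim, ens = _sim_ensemble(seed=5, n_proteins=80, n_replicates=300)
        de_full = call_de(ens)
        from miprot.impute import ImputedEnsemble

        half = ImputedEnsemble(
            ens.replicates[:150], ens.replicate_seeds[:150], ens.source, ens.fits
        )
        de_half = call_de(half)
        t = de_full.table["q_interaction"]
        small = (t < 0.2) & (t > 1e-6)  # relative scale meaningless below the floor
        assert small.any()
        a = de_full.table.loc[small, "q_interaction"]
        b = de_half.table.loc[small, "q_interaction"]
        assert ((a - b).abs() / a).max() < 0.10
        # extremely small q agree on the log scale
        tiny = t <= 1e-6
        if tiny.any():
            la = np.log(de_full.table.loc[tiny, "q_interaction"])
            lb = np.log(de_half.table.loc[tiny, "q_interaction"])
            assert (la - lb).abs().max() < 0.2

    def test_invalid_alpha(self):
        _, ens = _sim_ensemble(seed=6, n_proteins=40, n_replicates=3)
        with pytest.raises(UserInputError):
            call_de(ens, alpha=1.5)

    def test_result_round_trip(self, tmp_path):
        _, ens = _sim_ensemble(seed=7, n_proteins=40, n_replicates=3)
        de = call_de(ens)
        de.to_tsv(tmp_path / "de.tsv")
        loaded = pd.read_csv(tmp_path / "de.tsv", sep="\t", index_col="protein_id")
        assert list(loaded.index) == list(de.table.index)
        np.testing.assert_allclose(loaded["q_interaction"], de.table["q_interaction"])
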