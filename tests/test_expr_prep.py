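"""Expression preprocessing: normalization, condition filters, replicate
averaging, duplicate detection, sparse pruning, and subsetting."""

import math

import numpy as np
import pandas as pd
import pytest

from growthcub.expr_prep import (
    average_replicates,
    detect_duplicate_profiles,
    drop_duplicate_profiles,
    drop_gene_set,
    filter_conditions,
    load_expression,
    neutral_subsets,
    normalize_abundances,
    prune_to_sparse,
)
from conftest import make_matrix


class TestNormalize:
    def test_ln_flavor_uniform_column(self):
        raw = pd.DataFrame({"c1": [1.0, 1.0]})
        out, n_zero = normalize_abundances(raw, "six_plus_ln_frac")
        assert n_zero == 0
        assert np.allclose(out["c1"], 6 + math.log(0.5))
        assert out.iloc[0, 0] == pytest.approx(5.3069, abs=1e-4)

    def test_log10_flavor_uniform_column(self):
        raw = pd.DataFrame({"c1": [1.0, 1.0]})
        out, _ = normalize_abundances(raw, "six_plus_log10_frac")
        assert np.allclose(out["c1"], 6 + math.log10(0.5))
        assert out.iloc[0, 0] == pytest.approx(5.6990, abs=1e-4)

    def test_zero_replacement_before_transform_with_recomputed_total(self):
        raw = pd.DataFrame({"c1": [0.0, 1.0, 3.0]})
        out, n_zero = normalize_abundances(raw, "six_plus_log10_frac")
        assert n_zero == 1
        # zeros -> global min nonzero (1); totals recomputed: [1,1,3]/5
        assert out["c1"].tolist() == pytest.approx(
            [6 + math.log10(0.2), 6 + math.log10(0.2), 6 + math.log10(0.6)]
        )
        assert out.iloc[0, 0] == pytest.approx(5.3010, abs=1e-4)
        assert out.iloc[2, 0] == pytest.approx(5.7782, abs=1e-4)

    def test_zero_replacement_uses_global_matrix_minimum(self):
        raw = pd.DataFrame({"c1": [0.0, 10.0], "c2": [0.5, 10.0]})
        out, _ = normalize_abundances(raw, "six_plus_ln_frac")
        # global min nonzero is 0.5 (from c2), not anything column-local
        assert out.iloc[0, 0] == pytest.approx(6 + math.log(0.5 / 10.5))

    def test_zero_policy_error(self):
        raw = pd.DataFrame({"c1": [0.0, 1.0]})
        with pytest.raises(ValueError, match="zero entries"):
            normalize_abundances(raw, "six_plus_ln_frac", zero_policy="error")

    def test_fraction_conservation_property(self):
        rng = np.random.default_rng(3)
        raw = pd.DataFrame(rng.gamma(2.0, 5.0, size=(40, 6)))
        out, _ = normalize_abundances(raw, "six_plus_ln_frac")
        fracs = np.exp(out.to_numpy() - 6.0)
        assert np.allclose(fracs.sum(axis=0), 1.0, atol=1e-12)


class TestFilterConditions:
    def test_growth_rate_filters(self):
        m = make_matrix(np.ones((2, 3)), [0.5, 0.0, np.nan])
        kept, report = filter_conditions(m)
        assert kept.n_columns == 1
        assert report == {"missing_growth": 1, "zero_growth": 1, "low_alignment": 0}

    def test_alignment_threshold_boundary(self):
        m = make_matrix(np.ones((2, 2)), [0.5, 0.5], alignment_score=[85.0, 79.0])
        kept, report = filter_conditions(m)
        assert kept.n_columns == 1 and report["low_alignment"] == 1

    def test_constructed_fixture_counts(self):
        growth = [0.5] * 7 + [0.0, 0.0] + [0.5]
        align = [100.0] * 9 + [50.0]
        m = make_matrix(np.ones((3, 10)), growth, alignment_score=align)
        kept, report = filter_conditions(m)
        assert kept.n_columns == 7
        assert report == {"missing_growth": 0, "zero_growth": 2, "low_alignment": 1}

    def test_all_removed_errors(self):
        m = make_matrix(np.ones((2, 1)), [0.0])
        with pytest.raises(ValueError, match="all conditions removed"):
            filter_conditions(m)


class TestAverageReplicates:
    def test_identical_replicates_idempotent(self):
        vals = np.array([[2.0, 2.0], [5.0, 5.0]])
        m = make_matrix(vals, [0.5, 0.5], condition_ids=["c", "c"])
        out = average_replicates(m)
        assert out.n_columns == 1
        assert np.allclose(out.values["c"], [2.0, 5.0])

    def test_arithmetic_means_of_values_and_growth(self):
        m = make_matrix(np.array([[2.0, 4.0]]), [0.5, 0.7], condition_ids=["c", "c"])
        out = average_replicates(m)
        assert out.values.iloc[0, 0] == pytest.approx(3.0)
        assert out.meta.loc["c", "growth_rate"] == pytest.approx(0.6)

    def test_flags_merge_by_or_and_counts(self):
        m = make_matrix(
            np.arange(12.0).reshape(2, 6),
            [0.1] * 6,
            condition_ids=["a", "a", "b", "b", "c", "c"],
            is_ale=[True, False, False, False, False, False],
        )
        out = average_replicates(m)
        assert out.n_columns == 3
        assert bool(out.meta.loc["a", "is_ale"]) is True
        assert bool(out.meta.loc["b", "is_ale"]) is False

    def test_grand_mean_conserved_with_equal_replicate_counts(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=(10, 6))
        m = make_matrix(vals, [0.2] * 6, condition_ids=["a", "a", "b", "b", "c", "c"])
        out = average_replicates(m)
        assert out.values.to_numpy().mean() == pytest.approx(vals.mean(), abs=1e-12)


class TestDuplicates:
    def test_identical_columns_reported(self):
        vals = np.array([[1.0, 1.0], [2.0, 2.0], [5.0, 5.0]])
        m = make_matrix(vals, [0.1, 0.2])
        pairs, constant = detect_duplicate_profiles(m)
        assert pairs == [("e1", "e2")] and constant == []

    def test_monotone_transform_is_duplicate_under_spearman(self):
        m = make_matrix(np.array([[1.0, 10.0], [2.0, 20.0], [3.0, 30.0]]), [0.1, 0.2])
        pairs, _ = detect_duplicate_profiles(m)
        assert pairs == [("e1", "e2")]

    def test_constant_column_reported_separately(self):
        m = make_matrix(np.array([[1.0, 7.0], [2.0, 7.0], [3.0, 7.0]]), [0.1, 0.2])
        pairs, constant = detect_duplicate_profiles(m)
        assert pairs == [] and constant == ["e2"]

    def test_injected_pair_found_and_both_members_dropped(self):
        from growthcub import simulate

        m, truth = simulate.gen_expression(n_genes=50, seed=4, n_duplicate_pairs=1)
        # with one replicate per condition, the injected condition pair maps
        # to exactly one experiment-column pair
        expected = sorted(f"{c}_r1" for c in truth.duplicate_pairs[0])
        pairs, _ = detect_duplicate_profiles(m)
        assert [sorted(p) for p in pairs] == [expected]
        dropped_m, dropped = drop_duplicate_profiles(m)
        assert sorted(dropped) == expected
        assert dropped_m.n_columns == m.n_columns - 2


class TestPruneToSparse:
    def test_noop_when_target_equals_count(self):
        m = make_matrix(np.random.default_rng(0).normal(size=(5, 4)), [0.1] * 4)
        out, log = prune_to_sparse(m, 4, seed=0)
        assert log == [] and list(out.values.columns) == list(m.values.columns)

    def test_identical_pair_is_pruned_first(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=5)
        vals = np.column_stack([base, base, rng.normal(size=5)])
        m = make_matrix(vals, [0.1] * 3)
        out, log = prune_to_sparse(m, 2, seed=0)
        assert log[0]["pair"] == ["e1", "e2"]
        assert log[0]["removed"] in ("e1", "e2")

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(2)
        m = make_matrix(rng.normal(size=(20, 10)), [0.1] * 10)
        out1, log1 = prune_to_sparse(m, 5, seed=42)
        out2, log2 = prune_to_sparse(m, 5, seed=42)
        assert log1 == log2
        assert out1.values.equals(out2.values)

    def test_surviving_max_correlation_does_not_increase(self):
        rng = np.random.default_rng(5)
        m = make_matrix(rng.normal(size=(30, 8)), [0.1] * 8)

        def max_offdiag(mat):
            ranks = mat.values.rank(axis=0).to_numpy()
            r = np.corrcoef(ranks, rowvar=False)
            np.fill_diagonal(r, -np.inf)
            return r.max()

        before = max_offdiag(m)
        out, _ = prune_to_sparse(m, 4, seed=7)
        assert max_offdiag(out) <= before + 1e-12


class TestSubsets:
    def test_no_flags_identity(self):
        m = make_matrix(np.ones((2, 3)), [0.1] * 3)
        non_ale, wt = neutral_subsets(m)
        assert non_ale.n_columns == 3 and wt.n_columns == 3

    def test_flag_logic(self):
        m = make_matrix(
            np.ones((2, 4)),
            [0.1] * 4,
            is_ale=[True, True, False, False],
            is_mutant_or_ko=[False, False, True, False],
        )
        non_ale, wt = neutral_subsets(m)
        assert non_ale.n_columns == 2 and wt.n_columns == 1

    def test_compendium_like_ratios(self):
        # 103 conditions -> 48 non-ALE -> 28 wild-type, as in a real
        # growth-annotated compendium's bookkeeping
        n = 103
        is_ale = [i < 55 for i in range(n)]
        is_mut = [55 <= i < 75 for i in range(n)]
        m = make_matrix(np.ones((2, n)), [0.1] * n, is_ale=is_ale, is_mutant_or_ko=is_mut)
        non_ale, wt = neutral_subsets(m)
        assert non_ale.n_columns == 48 and wt.n_columns == 28


class TestDropGeneSet:
    def test_empty_set_identity(self):
        m = make_matrix(np.ones((10, 2)), [0.1, 0.2])
        out, report = drop_gene_set(m, set())
        assert out.n_genes == 10 and report == {"removed": 0, "absent": 0}

    def test_present_and_absent_ids(self):
        m = make_matrix(np.ones((10, 2)), [0.1, 0.2])
        out, report = drop_gene_set(m, {"g1", "g2", "nope"})
        assert out.n_genes == 8
        assert report == {"removed": 2, "absent": 1}


def test_tsv_roundtrip(tmp_path):
    m = make_matrix(np.random.default_rng(0).normal(size=(4, 3)), [0.1, 0.2, 0.3])
    m.write(tmp_path / "e.tsv", tmp_path / "m.tsv")
    back = load_expression(tmp_path / "e.tsv", tmp_path / "m.tsv")
    assert np.allclose(back.values.to_numpy(), m.values.to_numpy())
    assert list(back.meta["condition_id"]) == list(m.meta["condition_id"])
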