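"""Spectral-count normalization, Spearman correlation with exact small-n
p-values, spot-volume normalization and the pooled t-test."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rcspipe.quant_stats import (
    CountMatrix,
    SpotVolumeTable,
    correlate_with_reference,
    normalize_counts,
    normalize_spot_volumes,
    spearman,
    spot_t_test,
)
from rcspipe.synthetic_data import generate_counts, SyntheticTruth


def matrix_from(columns, proteins=None):
    values = pd.DataFrame(
        np.asarray(columns, dtype=float).T,
        index=proteins or [f"P{i}" for i in range(len(columns[0]))],
        columns=[f"S{j}" for j in range(len(columns))],
    )
    return CountMatrix(values=values)


class TestNormalizeCounts:
    def test_equal_split_log2(self):
        out = normalize_counts(matrix_from([[2, 2]]), pseudocount=0)
        assert out.values["S0"].tolist() == pytest.approx([-1.0, -1.0])

    def test_direct_arithmetic(self):
        out = normalize_counts(matrix_from([[1, 3]]), pseudocount=0)
        assert out.values["S0"].tolist() == pytest.approx(
            [-2.0, math.log2(0.75)]
        )

    def test_fractions_sum_to_one_without_pseudocount(self):
        out = normalize_counts(matrix_from([[3, 9, 1], [4, 4, 8]]), pseudocount=0)
        sums = (2.0 ** out.values).sum(axis=0)
        assert sums.tolist() == pytest.approx([1.0, 1.0], abs=1e-9)

    def test_zero_count_without_pseudocount_instructs_use(self):
        with pytest.raises(ValueError, match="pseudocount"):
            normalize_counts(matrix_from([[0, 5]]), pseudocount=0)

    def test_zero_counts_fine_with_pseudocount(self):
        out = normalize_counts(matrix_from([[0, 5]]), pseudocount=0.5)
        assert np.isfinite(out.values.values).all()

    def test_double_normalization_refused(self):
        out = normalize_counts(matrix_from([[1, 2]]))
        with pytest.raises(ValueError):
            normalize_counts(out)


class TestSpearman:
    def test_hand_computed_rank_value(self):
        rho, _ = spearman([1, 2, 3, 4, 5], [2, 1, 4, 3, 5])
        assert rho == pytest.approx(1 - 6 * 4 / (5 * 24))  # 0.8

    def test_monotone_transform_gives_one(self):
        x = [0.2, 1.5, 3.0, 7.2, 9.9, 12.0]
        rho, p = spearman(x, np.exp(x))
        assert rho == pytest.approx(1.0)
        assert p == pytest.approx(2 / math.factorial(6))

    def test_antitone_gives_minus_one(self):
        x = [1.0, 2.0, 5.0, 9.0]
        rho, _ = spearman(x, [-v**3 for v in x])
        assert rho == pytest.approx(-1.0)

    @pytest.mark.parametrize("n", [4, 5, 6, 7])
    def test_exact_p_matches_all_permutations_oracle(self, n):
        rng = np.random.default_rng(n)
        x = rng.permutation(n) + 1.0
        y = rng.permutation(n) + 1.0
        rho_obs, p = spearman(x, y)
        # independent oracle: correlate against every permutation of y
        rhos = []
        for perm in itertools.permutations(range(n)):
            yy = y[list(perm)]
            rhos.append(np.corrcoef(stats.rankdata(x), stats.rankdata(yy))[0, 1])
        oracle_p = np.mean(np.abs(rhos) >= abs(rho_obs) - 1e-12)
        assert p == pytest.approx(oracle_p, abs=1e-12)

    def test_tied_data_equals_rank_pearson(self):
        x = [1, 2, 2, 3, 4, 4, 4, 5, 6, 7, 8, 8]
        y = [2, 1, 3, 3, 5, 4, 6, 5, 7, 9, 8, 8]
        rho, _ = spearman(x, y)
        expected = np.corrcoef(stats.rankdata(x), stats.rankdata(y))[0, 1]
        assert rho == pytest.approx(expected)
        # cross-check against the reference implementation
        assert rho == pytest.approx(stats.spearmanr(x, y).statistic)

    def test_large_n_uses_t_approximation(self):
        rng = np.random.default_rng(42)
        x = rng.normal(size=30)
        y = 0.5 * x + rng.normal(size=30)
        rho, p = spearman(x, y)
        t = rho * math.sqrt((30 - 2) / (1 - rho**2))
        assert p == pytest.approx(2 * stats.t.sf(abs(t), df=28))

    def test_missing_pairs_dropped(self):
        x = [1, 2, np.nan, 4, 5, 6]
        y = [1, 2, 3, np.nan, 5, 6]
        rho, _ = spearman(x, y)
        assert rho == pytest.approx(1.0)

    def test_constant_vector_flagged_not_raised(self):
        rho, p = spearman([1, 1, 1, 1], [1, 2, 3, 4])
        assert math.isnan(rho) and math.isnan(p)

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            spearman([1, 2], [3, 4])


class TestCorrelateWithReference:
    def normalized(self, rows, proteins):
        raw = matrix_from(np.asarray(rows).T.tolist(), proteins=proteins)
        return normalize_counts(raw, pseudocount=0.5)

    def test_identical_row_gives_rho_one(self):
        matrix = self.normalized(
            [[5, 8, 2, 9, 4, 7], [5, 8, 2, 9, 4, 7], [9, 1, 7, 3, 8, 2]],
            ["REF", "SAME", "OTHER"],
        )
        records = correlate_with_reference(matrix, "REF", ["SAME", "OTHER"])
        assert records[0].protein_b == "SAME"
        assert records[0].rho == pytest.approx(1.0)
        assert records[0].n_used == 6

    def test_missing_protein_named_in_error(self):
        matrix = self.normalized([[1, 2, 3, 4]], ["REF"])
        with pytest.raises(KeyError, match="GHOST"):
            correlate_with_reference(matrix, "REF", ["GHOST"])

    def test_planted_correlation_recovered_within_sampling_error(self, tmp_path):
        truth = SyntheticTruth(rng_seed=7)
        truth.planted_correlations = [("REFP", "CORR", 0.6), ("REFP", "INDEP", 0.0)]
        generate_counts(tmp_path / "c.tsv", truth=truth, n_samples=95, rng_seed=7)
        matrix = normalize_counts(CountMatrix.read_tsv(tmp_path / "c.tsv"))
        records = {
            r.protein_b: r
            for r in correlate_with_reference(matrix, "REFP", ["CORR", "INDEP"])
        }
        assert records["CORR"].rho == pytest.approx(0.6, abs=0.15)
        assert abs(records["INDEP"].rho) < 0.3

    def test_raw_matrix_refused(self):
        raw = matrix_from([[1, 2], [3, 4]], proteins=["A", "B"])
        with pytest.raises(ValueError):
            correlate_with_reference(raw, "A", ["B"])


def spot_table(rows, background):
    data = pd.DataFrame(rows, columns=["spot", "gel", "group", "volume", "valid"])
    return SpotVolumeTable(data=data, background=background)


class TestNormalizeSpotVolumes:
    def test_proportions_of_valid_total(self):
        table = spot_table(
            [("s1", "g1", "a", 10.0, True), ("s2", "g1", "a", 30.0, True)],
            {"g1": 0.0},
        )
        out = normalize_spot_volumes(table)
        assert out.data.volume.tolist() == pytest.approx([0.25, 0.75])

    def test_background_subtracted_before_totals(self):
        table = spot_table(
            [("s1", "g1", "a", 12.0, True), ("s2", "g1", "a", 32.0, True)],
            {"g1": 2.0},
        )
        out = normalize_spot_volumes(table)
        assert out.data.volume.tolist() == pytest.approx([0.25, 0.75])

    def test_invalid_spot_excluded_from_denominator(self):
        table = spot_table(
            [
                ("s1", "g1", "a", 10.0, True),
                ("s2", "g1", "a", 30.0, True),
                ("s3", "g1", "a", 1000.0, False),
            ],
            {"g1": 0.0},
        )
        out = normalize_spot_volumes(table)
        assert out.data.volume.tolist()[:2] == pytest.approx([0.25, 0.75])
        assert np.isnan(out.data.volume.tolist()[2])

    def test_subtraction_floors_at_zero(self):
        table = spot_table(
            [("s1", "g1", "a", 5.0, True), ("s2", "g1", "a", 25.0, True)],
            {"g1": 10.0},
        )
        out = normalize_spot_volumes(table)
        assert out.data.volume.tolist() == pytest.approx([0.0, 1.0])

    def test_all_zero_gel_raises_naming_gel(self):
        table = spot_table(
            [("s1", "g1", "a", 1.0, True), ("s1", "g2", "a", 9.0, True)],
            {"g1": 5.0, "g2": 0.0},
        )
        with pytest.raises(ValueError, match="g1"):
            normalize_spot_volumes(table)

    def test_per_gel_valid_volumes_sum_to_one(self):
        rng = np.random.default_rng(0)
        rows = [
            (f"s{i}", gel, gel[0], float(rng.uniform(10, 100)), i % 7 != 0)
            for gel in ("a1", "a2", "b1", "b2")
            for i in range(20)
        ]
        out = normalize_spot_volumes(spot_table(rows, {g: 1.0 for g in ("a1", "a2", "b1", "b2")}))
        sums = out.data.dropna().groupby("gel").volume.sum()
        assert sums.tolist() == pytest.approx([1.0] * 4)


def triplicate_table(values_a, values_b, spot="s1"):
    rows = []
    for i, v in enumerate(values_a, 1):
        rows.append((spot, f"ctrl_{i}", "ctrl", float(v), True))
    for i, v in enumerate(values_b, 1):
        rows.append((spot, f"mod_{i}", "mod", float(v), True))
    table = spot_table(rows, {f"{g}_{i}": 0.0 for g in ("ctrl", "mod") for i in (1, 2, 3)})
    table.state = "normalized"
    return table


class TestSpotTTest:
    def test_identical_groups_null_identity(self):
        out = spot_t_test(triplicate_table([1, 2, 3], [1, 2, 3]))
        assert out.t.iloc[0] == pytest.approx(0.0)
        assert out.p_value.iloc[0] == pytest.approx(1.0)

    def test_closed_form_pooled_t(self):
        out = spot_t_test(triplicate_table([1, 2, 3], [4, 5, 6]))
        assert abs(out.t.iloc[0]) == pytest.approx(3 / math.sqrt(2 / 3), rel=1e-9)
        assert out.p_value.iloc[0] == pytest.approx(0.021312, abs=1e-4)
        assert bool(out.significant.iloc[0])

    def test_symmetric_under_group_exchange(self):
        a, b = [1.0, 2.5, 2.0], [3.0, 4.5, 5.0]
        forward = spot_t_test(triplicate_table(a, b))
        # swap the group labels
        swapped = spot_t_test(triplicate_table(b, a))
        assert forward.t.iloc[0] == pytest.approx(-swapped.t.iloc[0])
        assert forward.p_value.iloc[0] == pytest.approx(swapped.p_value.iloc[0])

    def test_untestable_spot_flagged(self):
        rows = [
            ("s1", "ctrl_1", "ctrl", 1.0, True),
            ("s1", "ctrl_2", "ctrl", 2.0, True),
            ("s1", "mod_1", "mod", 3.0, True),
        ]
        table = spot_table(rows, {"ctrl_1": 0, "ctrl_2": 0, "mod_1": 0})
        table.state = "normalized"
        out = spot_t_test(table)
        assert not bool(out.testable.iloc[0])
        assert not bool(out.significant.iloc[0])
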