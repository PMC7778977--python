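"""Rank computation, cross-platform normalization and expression scores."""

import numpy as np
import pytest

from exatlas.calls import AssayCall, DataType, EstLibrary, HIGH, LOW, PRESENT
from exatlas.ontology import Condition
from exatlas.ranks import (
    ChipRanking,
    LibraryRanking,
    RankInputs,
    affy_condition_rank,
    affy_normalize_chip_rank,
    chip_type_global_max,
    compute_global_ranks,
    dense_rank,
    est_condition_rank,
    expression_score,
    fractional_rank,
    global_mean_rank,
    insitu_condition_rank,
    normalize_affy_chips,
    normalize_datatype_rank,
    rnaseq_condition_rank,
    weighted_mean_rank,
)

COND = Condition("UBERON:0001264", "UBERON:0000066")


class TestRankingPrimitives:
    def test_fractional_strict_ordering(self):
        ranks, distinct = fractional_rank({"g1": 3.0, "g2": 1.0, "g3": 2.0})
        assert ranks == {"g1": 1, "g2": 3, "g3": 2}
        assert distinct == 3

    def test_fractional_ties_get_mean_position(self):
        ranks, distinct = fractional_rank({"g1": 5.0, "g2": 5.0, "g3": 1.0})
        assert ranks == {"g1": 1.5, "g2": 1.5, "g3": 3}
        assert distinct == 2

    @pytest.mark.parametrize("seed", range(5))
    def test_fractional_matches_sort_oracle(self, seed):
        rng = np.random.default_rng(seed)
        values = {f"g{i}": float(v) for i, v in enumerate(rng.integers(0, 8, 30))}
        ranks, distinct = fractional_rank(values)
        assert sum(ranks.values()) == pytest.approx(30 * 31 / 2)
        # brute-force oracle: rank = mean of the 1-based positions of the
        # value in the descending sort
        desc = sorted(values.values(), reverse=True)
        for g, v in values.items():
            positions = [i + 1 for i, x in enumerate(desc) if x == v]
            assert ranks[g] == pytest.approx(sum(positions) / len(positions))
        assert distinct == len(set(ranks.values()))

    def test_dense_basic_and_all_equal(self):
        assert dense_rank({"a": 9.0, "b": 9.0, "c": 4.0}) == {"a": 1, "b": 1, "c": 2}
        assert dense_rank({"a": 2.0, "b": 2.0}) == {"a": 1, "b": 1}

    @pytest.mark.parametrize("seed", range(5))
    def test_dense_max_equals_distinct_count(self, seed):
        rng = np.random.default_rng(seed)
        values = {f"g{i}": float(v) for i, v in enumerate(rng.integers(0, 10, 40))}
        ranks = dense_rank(values)
        assert max(ranks.values()) == len(set(values.values()))
        assert sorted(set(ranks.values())) == list(range(1, max(ranks.values()) + 1))

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            fractional_rank({})
        with pytest.raises(ValueError):
            dense_rank({})

    def test_rank_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(9)
        values = {f"g{i}": float(v) for i, v in enumerate(rng.exponential(2, 25))}
        transformed = {g: np.log1p(v) * 3 + 1 for g, v in values.items()}
        assert fractional_rank(values) == fractional_rank(transformed)


class TestRnaSeqConditionRank:
    def _lib(self, gene_rank, distinct, aid="l1"):
        return LibraryRanking(aid, COND, gene_rank, distinct)

    def test_single_library_passthrough(self):
        assert rnaseq_condition_rank([self._lib({"g": 4.0}, 17)], "g") == 4.0

    def test_weighted_mean_hand_value(self):
        libs = [self._lib({"g": 2.0}, 10), self._lib({"g": 4.0}, 30, aid="l2")]
        assert rnaseq_condition_rank(libs, "g") == pytest.approx(3.5)

    def test_equal_weights_reduce_to_mean(self):
        libs = [self._lib({"g": 2.0}, 20), self._lib({"g": 4.0}, 20, aid="l2")]
        assert rnaseq_condition_rank(libs, "g") == pytest.approx(3.0)

    def test_gene_absent_from_all_libraries(self):
        assert rnaseq_condition_rank([self._lib({"g": 1.0}, 5)], "other") is None

    @pytest.mark.parametrize("seed", range(5))
    def test_weighted_mean_within_rank_range(self, seed):
        rng = np.random.default_rng(seed)
        pairs = [(float(rng.uniform(1, 50)), float(rng.integers(1, 100))) for _ in range(6)]
        m = weighted_mean_rank(pairs)
        ranks = [r for r, _ in pairs]
        assert min(ranks) <= m <= max(ranks)


class TestAffyNormalization:
    def _chip(self, ranks, distinct, chip_type, aid):
        return ChipRanking(aid, COND, ranks, distinct, chip_type=chip_type)

    def test_single_chip_type_factor_is_one(self):
        chip = self._chip({"g": 10.0}, 5, "A", "c1")
        affy_normalize_chip_rank(chip, {"A": 100.0}, cond_max=100.0)
        assert chip.norm_frac_rank == {"g": 10.0}

    def test_smaller_chip_type_scaled_up(self):
        chip = self._chip({"g": 10.0}, 5, "A", "c1")
        affy_normalize_chip_rank(chip, {"A": 100.0, "B": 200.0}, cond_max=200.0)
        assert chip.norm_frac_rank == {"g": 15.0}

    def test_max_chip_type_unscaled(self):
        chip = self._chip({"g": 10.0}, 5, "B", "c1")
        affy_normalize_chip_rank(chip, {"A": 100.0, "B": 200.0}, cond_max=200.0)
        assert chip.norm_frac_rank == {"g": 10.0}

    def test_condition_max_uses_only_represented_types(self):
        # type C (global max 400) is absent from this condition: condMax=200
        chips = [
            self._chip({f"g{i}": float(i + 1) for i in range(100)}, 100, "A", "c1"),
            self._chip({f"g{i}": float(i + 1) for i in range(200)}, 200, "B", "c2"),
        ]
        other_cond = Condition("UBERON:0000016", "UBERON:0000066")
        big = ChipRanking("c3", other_cond, {f"g{i}": float(i + 1) for i in range(400)}, 400, chip_type="C")
        normalize_affy_chips(chips + [big])
        assert chips[0].norm_frac_rank["g9"] == pytest.approx(10.0 * (1 + 200 / 100) / 2)

    def test_weighted_mean_hand_value(self):
        c1 = self._chip({}, 50, "A", "c1")
        c1.norm_frac_rank = {"g": 15.0}
        c2 = self._chip({}, 150, "A", "c2")
        c2.norm_frac_rank = {"g": 10.0}
        assert affy_condition_rank([c1, c2], "g") == pytest.approx(11.25)

    def test_zero_type_max_rejected(self):
        chip = self._chip({"g": 1.0}, 1, "A", "c1")
        with pytest.raises(ValueError):
            affy_normalize_chip_rank(chip, {"A": 0.0}, cond_max=0.0)

    def test_global_max_per_type(self):
        chips = [
            self._chip({"g1": 1.0, "g2": 2.0}, 2, "A", "c1"),
            self._chip({"g1": 1.0, "g2": 2.0, "g3": 3.0}, 3, "A", "c2"),
            self._chip({"g1": 1.0}, 1, "B", "c3"),
        ]
        assert chip_type_global_max(chips) == {"A": 3.0, "B": 1.0}


class TestDenseRankDataTypes:
    def test_insitu_weighted_evidence(self):
        def spot(gene, n_high, n_low):
            calls = []
            for i in range(n_high):
                calls.append(AssayCall(gene, COND, PRESENT, HIGH, DataType.INSITU, "e", f"{gene}h{i}"))
            for i in range(n_low):
                calls.append(AssayCall(gene, COND, PRESENT, LOW, DataType.INSITU, "e", f"{gene}l{i}"))
            return calls

        calls = spot("g1", 2, 0) + spot("g2", 0, 3) + spot("g3", 1, 2)
        ranks, cond_max = insitu_condition_rank(calls)
        # evidence scores 2.0, 1.5, 2.0 -> dense ranks 1, 2, 1
        assert ranks == {"g1": 1, "g2": 2, "g3": 1}
        assert cond_max == 2

    def test_insitu_more_spots_rank_better(self):
        calls = [
            AssayCall("g1", COND, PRESENT, HIGH, DataType.INSITU, "e", f"a{i}") for i in range(3)
        ] + [AssayCall("g2", COND, PRESENT, HIGH, DataType.INSITU, "e", "b0")]
        ranks, _ = insitu_condition_rank(calls)
        assert ranks["g1"] < ranks["g2"]

    def test_insitu_absent_spots_ignored(self):
        calls = [
            AssayCall("g1", COND, PRESENT, HIGH, DataType.INSITU, "e", "a"),
            AssayCall("g2", COND, "absent", HIGH, DataType.INSITU, "e", "b"),
        ]
        ranks, cond_max = insitu_condition_rank(calls)
        assert ranks == {"g1": 1} and cond_max == 1

    def test_est_totals_summed_across_libraries(self):
        libs = [
            EstLibrary("l1", COND, {"g1": 5, "g2": 6}),
            EstLibrary("l2", COND, {"g1": 2}),
        ]
        ranks, cond_max = est_condition_rank(libs)
        assert ranks == {"g1": 1, "g2": 2} and cond_max == 2
        assert est_condition_rank(list(reversed(libs)))[0] == ranks

    def test_single_gene_rank_one(self):
        ranks, cond_max = est_condition_rank([EstLibrary("l", COND, {"g": 3})])
        assert ranks == {"g": 1} and cond_max == 1


class TestNormalizationAndScore:
    def test_factor_one_when_condition_max_is_species_max(self):
        assert normalize_datatype_rank(7.0, 40.0, 40.0) == 7.0

    def test_insitu_style_small_max_scaled(self):
        assert normalize_datatype_rank(1.0, 5.0, 40000.0) == pytest.approx(4000.5)

    def test_linear_in_rank(self):
        a = normalize_datatype_rank(3.0, 10.0, 100.0)
        assert normalize_datatype_rank(6.0, 10.0, 100.0) == pytest.approx(2 * a)

    def test_zero_condition_max_rejected(self):
        with pytest.raises(ValueError):
            normalize_datatype_rank(1.0, 0.0, 10.0)

    def test_global_mean_hand_value(self):
        assert global_mean_rank([(40.0, 3.5), (200.0, 11.25)]) == pytest.approx(9.958333333333334)

    def test_single_data_type_collapse(self):
        assert global_mean_rank([(40.0, 3.5)]) == 3.5

    def test_weights_commute_across_data_types(self):
        pairs = [(40.0, 3.5), (200.0, 11.25), (5.0, 4000.5)]
        assert global_mean_rank(pairs) == pytest.approx(global_mean_rank(list(reversed(pairs))))

    def test_all_weights_zero_rejected(self):
        with pytest.raises(ValueError):
            global_mean_rank([(0.0, 3.0)])

    def test_score_boundaries_and_midpoint(self):
        assert expression_score(1.0, 50.0) == pytest.approx(100.0)
        assert expression_score(50.0, 50.0) == pytest.approx(100.0 / 50.0)
        assert expression_score(5.0, 10.0) == pytest.approx(60.0)

    def test_score_strictly_decreasing_affine(self):
        smax = 123.0
        scores = [expression_score(r, smax) for r in np.linspace(1, smax, 20)]
        assert all(a > b for a, b in zip(scores, scores[1:]))
        # affine: second differences vanish
        d2 = np.diff(scores, 2)
        assert np.allclose(d2, 0)

    def test_rank_outside_range_rejected(self):
        with pytest.raises(ValueError):
            expression_score(0.5, 10.0)
        with pytest.raises(ValueError):
            expression_score(11.0, 10.0)


class TestFullRankPipeline:
    def test_single_library_collapse(self):
        """With one RNA-seq library and nothing else, every gene's global
        rank equals its normalized fractional rank."""
        rng = np.random.default_rng(21)
        values = {f"g{i}": float(v) for i, v in enumerate(rng.permutation(50))}
        lr = LibraryRanking.from_values("l1", COND, values)
        inputs = RankInputs(rnaseq={COND: [lr]})
        out = compute_global_ranks(inputs)
        assert len(out) == 50
        species_max = max(lr.frac_rank.values())
        for g in out:
            expected = normalize_datatype_rank(lr.frac_rank[g.gene], species_max, species_max)
            assert g.mean_norm_rank == pytest.approx(expected)
            assert g.expression_score == pytest.approx(expression_score(expected, species_max))

    def test_mixed_data_types_use_stated_weights(self):
        lr = LibraryRanking.from_values("l1", COND, {"g1": 10.0, "g2": 5.0, "g3": 1.0})
        est = EstLibrary("e1", COND, {"g1": 9, "g2": 3})
        inputs = RankInputs(rnaseq={COND: [lr]}, est={COND: [est]})
        out = {g.gene: g for g in compute_global_ranks(inputs)}
        assert out["g1"].weight_rnaseq == 3.0  # distinct rank count
        assert out["g1"].weight_est == 2.0  # max dense rank in condition
        assert out["g3"].weight_est == 0.0  # no EST data for g3
        assert out["g3"].mean_norm_rank == pytest.approx(out["g3"].norm_rank_rnaseq)
        # hand evaluation for g1: species max = 3 (rna-seq frac ranks 1..3)
        b = normalize_datatype_rank(1.0, 3.0, 3.0)
        h = normalize_datatype_rank(1.0, 2.0, 3.0)
        assert out["g1"].mean_norm_rank == pytest.approx((3 * b + 2 * h) / 5)
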