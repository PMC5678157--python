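from __future__ import annotations

import math

import numpy as np
import pytest

from pathtriad.enrichment import (
    EnrichmentResult,
    GseaConfig,
    RankedList,
    _es_from_positions,
    enrichment_score,
    normalize_and_fdr,
    permutation_null,
    rank_proteins,
    run_gsea,
)
from pathtriad.profile_io import GeneSetCollection
from conftest import profile_from
from helpers import brute_force_es, brute_force_running_sum, exhaustive_null_es, exhaustive_p


def ranked_from(metrics: list[float]) -> RankedList:
    """Ranked list over symbols A, B, C, ... with the given (sorted) metrics."""
    symbols = tuple(chr(ord("A") + i) for i in range(len(metrics)))
    return RankedList(symbols=symbols, metrics=np.asarray(metrics, dtype=float))


def random_instance(rng, n_max=12):
    n = int(rng.integers(3, n_max + 1))
    metrics = np.sort(rng.normal(0, 1.5, n))[::-1]
    k = int(rng.integers(1, n))
    members_idx = rng.choice(n, size=k, replace=False)
    ranked = ranked_from(metrics.tolist())
    members = {ranked.symbols[i] for i in members_idx}
    p = float(rng.choice([0.0, 1.0, 2.0]))
    return ranked, members, p


class TestRankProteins:
    def test_descending_by_ratio(self):
        profile = profile_from("p", A=1.0, B=-1.0, C=2.0)
        assert rank_proteins(profile).symbols == ("C", "A", "B")

    def test_ties_broken_lexicographically(self):
        profile = profile_from("p", ZZZ=0.5, AAA=0.5, MMM=0.5)
        assert rank_proteins(profile).symbols == ("AAA", "MMM", "ZZZ")

    def test_input_record_order_is_irrelevant(self):
        rng = np.random.default_rng(3)
        items = [(f"G{i}", float(v)) for i, v in enumerate(rng.normal(0, 1, 40))]
        from pathtriad.profile_io import ProteinRatioProfile

        reference = None
        for _ in range(5):
            rng.shuffle(items)
            profile = ProteinRatioProfile.from_pairs("p", items)
            ranked = rank_proteins(profile)
            if reference is None:
                reference = ranked.symbols
            assert ranked.symbols == reference


class TestEnrichmentScore:
    def test_members_at_top_give_es_one(self):
        ranked = ranked_from([3.0, 2.0, 1.0, -1.0, -2.0])
        score = enrichment_score(ranked, {"A", "B"}, p=1.0)
        assert score.es == pytest.approx(1.0)
        assert set(score.leading_edge) == {"A", "B"}

    def test_hand_enumerated_running_sum(self):
        ranked = ranked_from([3.0, 2.0, 1.0, -1.0, -2.0])
        score = enrichment_score(ranked, {"A", "C"}, p=1.0)
        expected = brute_force_running_sum(
            [3.0, 2.0, 1.0, -1.0, -2.0], [True, False, True, False, False], 1.0
        )
        assert score.running_sum.tolist() == expected
        assert score.es == max(expected)

    def test_matches_bruteforce_oracle_exactly(self):
        rng = np.random.default_rng(11)
        for _ in range(300):
            ranked, members, p = random_instance(rng)
            hit = [s in members for s in ranked.symbols]
            es, _ = brute_force_es(ranked.metrics.tolist(), hit, p)
            assert enrichment_score(ranked, members, p).es == es

    def test_running_sum_ends_at_zero(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            ranked, members, p = random_instance(rng, n_max=30)
            score = enrichment_score(ranked, members, p)
            assert score.running_sum[-1] == pytest.approx(0.0, abs=1e-12)
            assert -1.0 - 1e-12 <= score.es <= 1.0 + 1e-12

    def test_mirror_symmetry_for_unweighted_statistic(self):
        metrics = [2.5, 1.2, 0.4, -0.3, -1.1, -2.0]
        ranked = ranked_from(metrics)
        mirrored = ranked_from([-m for m in reversed(metrics)])
        members = {"B", "C"}
        mirrored_members = {
            mirrored.symbols[len(metrics) - 1 - ranked.symbols.index(s)]
            for s in members
        }
        left = enrichment_score(ranked, members, p=0.0)
        right = enrichment_score(mirrored, mirrored_members, p=0.0)
        assert left.es == pytest.approx(-right.es)

    def test_leading_edge_rederivable_from_running_sum(self):
        rng = np.random.default_rng(13)
        for _ in range(100):
            ranked, members, p = random_instance(rng, n_max=20)
            score = enrichment_score(ranked, members, p)
            if score.es > 0:
                expected = [
                    s for s in ranked.symbols[: score.peak_index + 1] if s in members
                ]
            else:
                expected = [
                    s for s in ranked.symbols[score.peak_index:] if s in members
                ]
            assert list(score.leading_edge) == expected

    def test_degenerate_memberships_rejected(self):
        ranked = ranked_from([1.0, 0.5, -0.5])
        with pytest.raises(ValueError):
            enrichment_score(ranked, {"X", "Y"}, 1.0)
        with pytest.raises(ValueError):
            enrichment_score(ranked, {"A", "B", "C"}, 1.0)

    def test_all_zero_metrics_fall_back_to_unweighted_increments(self):
        ranked = ranked_from([0.0, 0.0, 0.0, 0.0])
        score = enrichment_score(ranked, {"A", "C"}, p=1.0)
        expected = brute_force_running_sum(
            [0.0] * 4, [True, False, True, False], 0.0
        )
        assert score.running_sum.tolist() == expected


class TestPermutationNull:
    def test_same_seed_reproduces_sample(self):
        ranked = ranked_from(np.linspace(3, -3, 40).tolist())
        cfg = GseaConfig(min_size=1, n_perm=100, rng_seed=9)
        a = permutation_null(ranked, 5, cfg, stream_key="X")
        b = permutation_null(ranked, 5, cfg, stream_key="X")
        assert np.array_equal(a, b)
        c = permutation_null(ranked, 5, cfg, stream_key="Y")
        assert not np.array_equal(a, c)

    def test_requested_number_of_permutations(self):
        ranked = ranked_from(np.linspace(2, -2, 25).tolist())
        cfg = GseaConfig(min_size=1, n_perm=357)
        assert len(permutation_null(ranked, 4, cfg)) == 357

    def test_exhaustive_mode_enumerates_all_subsets(self):
        metrics = [2.0, 1.0, 0.5, -0.5, -1.5]
        ranked = ranked_from(metrics)
        cfg = GseaConfig(min_size=1, exhaustive=True)
        null = permutation_null(ranked, 2, cfg)
        assert len(null) == math.comb(5, 2)
        expected = exhaustive_null_es(metrics, 2, 1.0)
        assert sorted(null.tolist()) == pytest.approx(sorted(expected))

    def test_set_size_must_be_below_universe(self):
        ranked = ranked_from([1.0, -1.0])
        with pytest.raises(ValueError):
            permutation_null(ranked, 2, GseaConfig(min_size=1))

    def test_vectorized_scorer_agrees_with_single_set_scorer(self):
        rng = np.random.default_rng(21)
        metrics = np.sort(rng.normal(0, 1.5, 60))[::-1]
        ranked = ranked_from(metrics.tolist())
        for k in (3, 10, 25):
            subsets = np.sort(
                np.array([rng.choice(60, k, replace=False) for _ in range(40)]), axis=1
            )
            weights = np.abs(metrics) ** 1.0
            vec = _es_from_positions(subsets, weights, 60)
            for row, es in zip(subsets, vec):
                members = {ranked.symbols[i] for i in row}
                assert es == pytest.approx(
                    enrichment_score(ranked, members, 1.0).es, abs=1e-12
                )


class TestNormalizeAndFdr:
    def test_nes_is_one_when_es_equals_null_mean_magnitude(self):
        r = EnrichmentResult(pathway="P", mapped_n=5, tested=True, es=0.5)
        nulls = {"P": np.array([0.25, 0.75, -0.4, -0.6])}
        normalize_and_fdr([r], nulls)
        assert r.nes == pytest.approx(1.0)
        assert r.p_nominal == pytest.approx(0.5)  # one of two positive nulls >= 0.5

    def test_observed_beyond_every_null_flagged_below_resolution(self):
        r = EnrichmentResult(pathway="P", mapped_n=5, tested=True, es=0.99)
        nulls = {"P": np.concatenate([np.full(500, 0.3), np.full(500, -0.3)])}
        normalize_and_fdr([r], nulls)
        assert r.p_nominal == 0.0
        assert r.p_below_resolution

    def test_missing_null_sample_is_error(self):
        r = EnrichmentResult(pathway="P", mapped_n=5, tested=True, es=0.5)
        with pytest.raises(ValueError, match="null sample"):
            normalize_and_fdr([r], {})


class TestRunGsea:
    def test_pathway_below_min_size_reported_untested_with_count(self):
        profile = profile_from("p", **{f"G{i}": float(i) for i in range(40)})
        sets = GeneSetCollection(
            sets={
                "SMALL": frozenset(f"G{i}" for i in range(19)),
                "OK": frozenset(f"G{i}" for i in range(20, 40)),
            },
            source="t",
        )
        cfg = GseaConfig(min_size=20, max_size=200, n_perm=50)
        results = {r.pathway: r for r in run_gsea(profile, sets, cfg)}
        assert not results["SMALL"].tested
        assert results["SMALL"].mapped_n == 19
        assert results["SMALL"].es is None
        assert results["OK"].tested

    def test_members_absent_from_profile_do_not_count(self):
        profile = profile_from("p", **{f"G{i}": float(i) for i in range(30)})
        sets = GeneSetCollection(
            sets={"S": frozenset({f"G{i}" for i in range(25)} | {"MISSING1", "MISSING2"})},
            source="t",
        )
        cfg = GseaConfig(min_size=20, n_perm=50)
        (result,) = run_gsea(profile, sets, cfg)
        assert result.mapped_n == 25

    def test_planted_up_shifted_set_recovered_significant(self):
        rng = np.random.default_rng(17)
        n = 300
        values = rng.normal(0, 0.5, n)
        values[:30] += 1.5
        profile = profile_from("p", **{f"G{i:03d}": float(v) for i, v in enumerate(values)})
        sets = {"PLANTED": frozenset(f"G{i:03d}" for i in range(30))}
        for k in range(8):
            members = rng.choice(n, 30, replace=False)
            sets[f"NULL{k}"] = frozenset(f"G{i:03d}" for i in members)
        results = {
            r.pathway: r
            for r in run_gsea(
                profile,
                GeneSetCollection(sets=sets, source="t"),
                GseaConfig(n_perm=500, rng_seed=5),
            )
        }
        assert results["PLANTED"].significant
        assert results["PLANTED"].direction == "UP"

    def test_all_zero_profile_yields_no_significant_pathway(self):
        profile = profile_from("p", **{f"G{i}": 0.0 for i in range(60)})
        sets = GeneSetCollection(
            sets={f"S{k}": frozenset(f"G{i}" for i in range(k, k + 25)) for k in range(4)},
            source="t",
        )
        results = run_gsea(profile, sets, GseaConfig(min_size=20, n_perm=200))
        assert not any(r.significant for r in results)

    def test_results_independent_of_set_evaluation_order(self):
        profile = profile_from("p", **{f"G{i}": float(np.sin(i)) for i in range(60)})
        base = {f"S{k}": frozenset(f"G{i}" for i in range(k, k + 25)) for k in range(5)}
        cfg = GseaConfig(min_size=20, n_perm=100, rng_seed=2)
        forward = run_gsea(profile, GeneSetCollection(sets=dict(base), source="t"), cfg)
        reordered = dict(reversed(list(base.items())))
        backward = run_gsea(profile, GeneSetCollection(sets=reordered, source="t"), cfg)
        assert [(r.pathway, r.es, r.p_nominal, r.fdr) for r in forward] == [
            (r.pathway, r.es, r.p_nominal, r.fdr) for r in backward
        ]


class TestExactSmallUniverse:
    def test_nominal_p_matches_exhaustive_enumeration(self):
        """On a <=8 protein universe the engine's permutation p equals the
        exact p over all same-size subsets."""
        rng = np.random.default_rng(29)
        for _ in range(20):
            n = int(rng.integers(5, 9))
            metrics = np.sort(rng.normal(0, 1.2, n))[::-1].tolist()
            k = int(rng.integers(2, n - 1))
            ranked = ranked_from(metrics)
            members = set(rng.choice(list(ranked.symbols), k, replace=False).tolist())
            cfg = GseaConfig(min_size=1, max_size=8, exhaustive=True)
            sets = GeneSetCollection(sets={"S": frozenset(members)}, source="t")
            profile = profile_from("p", **dict(zip(ranked.symbols, metrics)))
            (result,) = run_gsea(profile, sets, cfg)
            null = exhaustive_null_es(metrics, k, 1.0)
            es, _ = brute_force_es(metrics, [s in members for s in ranked.symbols], 1.0)
            assert result.p_nominal == pytest.approx(exhaustive_p(null, es), abs=1e-12)
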