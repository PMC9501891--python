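"""Running-sum enrichment, permutation null, NES/p and run_gsea plumbing."""

import numpy as np
import pandas as pd
import pytest

from immunosig.errors import (
    ConfigError,
    DegenerateSetError,
    EmptyCollectionError,
    EmptySetError,
    MetricError,
)
from immunosig.gsea import (
    GeneSetCollection,
    RankedList,
    enrichment_score,
    nes_and_p,
    permutation_null,
    rank_genes,
    read_gmt,
    run_gsea,
    write_gmt,
)
from immunosig.matrix import CohortAnnotation, NormalizedMatrix


def ranked_from(metrics, genes=None):
    n = len(metrics)
    genes = genes or [f"g{i:02d}" for i in range(n)]
    order = np.lexsort((np.asarray(genes, dtype=object), -np.asarray(metrics, float)))
    return RankedList(
        genes=np.asarray(genes, dtype=object)[order],
        metric=np.asarray(metrics, dtype=float)[order],
    )


def brute_force_es(genes, metrics, gene_set, p=1.0):
    """Independent oracle: literal walk of the ranked list."""
    n = len(genes)
    in_set = [g in gene_set for g in genes]
    n_h = sum(in_set)
    n_r = sum(abs(m) ** p for g, m, h in zip(genes, metrics, in_set) if h)
    running, best, s = [], 0.0, 0.0
    for g, m, h in zip(genes, metrics, in_set):
        s += (abs(m) ** p) / n_r if h else -1.0 / (n - n_h)
        running.append(s)
        if abs(s) > abs(best):
            best = s
    return best


def make_values_annotation(x, responders, genes=None, samples=None):
    x = np.asarray(x, dtype=float)
    genes = genes or [f"g{i:02d}" for i in range(x.shape[0])]
    samples = samples or [f"S{j}" for j in range(x.shape[1])]
    values = NormalizedMatrix(
        values=pd.DataFrame(x, index=genes, columns=samples),
        scale_factors=pd.Series(1.0, index=samples),
        pseudocount=1.0,
    )
    resp = ["responder" if s in responders else "non_responder" for s in samples]
    ann = CohortAnnotation(
        pd.DataFrame({"sample_id": samples, "response": resp,
                      "pfs_months": 1.0, "event": 1})
    )
    return values, ann


class TestRankGenes:
    def test_signal_to_noise_hand_value(self):
        values, ann = make_values_annotation(
            [[1, 3, 0, 2]], responders=["S0", "S1"], genes=["g"]
        )
        r = rank_genes(values, ann)
        assert r.metric[0] == pytest.approx(1.0 / (2 * np.sqrt(2)))

    def test_identical_groups_give_zero(self):
        values, ann = make_values_annotation(
            [[5, 6, 5, 6]], responders=["S0", "S1"], genes=["g"]
        )
        assert rank_genes(values, ann).metric[0] == 0.0

    def test_variance_floor_for_constant_group(self):
        # responder values constant at 10 -> sd floored at 0.2*10 = 2
        values, ann = make_values_annotation(
            [[10, 10, 4, 6]], responders=["S0", "S1"], genes=["g"]
        )
        r = rank_genes(values, ann)
        sd_b = np.std([4, 6], ddof=1)
        expected = (10 - 5) / (2.0 + max(sd_b, 0.2 * 5, 0.2))
        assert r.metric[0] == pytest.approx(expected)

    def test_small_group_suggests_fallback_metric(self):
        values, ann = make_values_annotation(
            [[1, 2, 3]], responders=["S0"], genes=["g"]
        )
        with pytest.raises(MetricError, match="difference_of_means"):
            rank_genes(values, ann)
        r = rank_genes(values, ann, metric="difference_of_means")
        assert r.metric[0] == pytest.approx(1 - 2.5)

    def test_ties_broken_lexicographically(self):
        values, ann = make_values_annotation(
            np.zeros((3, 4)), responders=["S0", "S1"], genes=["b", "a", "c"]
        )
        assert rank_genes(values, ann).genes.tolist() == ["a", "b", "c"]


class TestEnrichmentScore:
    def test_top_two_reach_plus_one(self):
        r = ranked_from(list(range(10, 0, -1)))
        es, _, le = enrichment_score(r, {r.genes[0], r.genes[1]})
        assert es == pytest.approx(1.0)
        assert set(le) == {r.genes[0], r.genes[1]}

    def test_bottom_two_reach_minus_one(self):
        r = ranked_from(list(range(10, 0, -1)))
        es, _, le = enrichment_score(r, {r.genes[-1], r.genes[-2]})
        assert es == pytest.approx(-1.0)
        assert set(le) == {r.genes[-1], r.genes[-2]}

    def test_hand_computed_running_sum(self):
        # metrics (5,4,3,2,1), set = ranks 1 and 3 -> peak 5/8 - 1/3 + 3/8 = 2/3
        r = ranked_from([5, 4, 3, 2, 1])
        es, running, le = enrichment_score(r, {r.genes[0], r.genes[2]})
        assert es == pytest.approx(2 / 3)
        assert running[2] == pytest.approx(2 / 3)
        assert le == [r.genes[0], r.genes[2]]

    def test_empty_intersection_rejected(self):
        r = ranked_from([3, 2, 1])
        with pytest.raises(EmptySetError):
            enrichment_score(r, {"missing"})

    def test_whole_panel_set_rejected(self):
        r = ranked_from([3, 2, 1])
        with pytest.raises(EmptySetError):
            enrichment_score(r, set(r.genes))

    def test_all_zero_in_set_metrics_degenerate(self):
        r = ranked_from([1.0, 0.0, 0.0, -1.0])
        zero_genes = set(r.genes[np.asarray(r.metric) == 0.0])
        with pytest.raises(DegenerateSetError):
            enrichment_score(r, zero_genes)

    def test_reversal_antisymmetry(self):
        """ES of a set equals -ES on the reversed ranking with negated metric."""
        rng = np.random.default_rng(4)
        for _ in range(50):
            n = rng.integers(5, 15)
            metrics = rng.normal(size=n)
            metrics += 1e-6 * np.arange(n)  # avoid exact ties
            genes = [f"g{i:02d}" for i in range(n)]
            r = ranked_from(metrics, genes)
            size = rng.integers(1, n - 1)
            members = set(rng.choice(genes, size=size, replace=False))
            es, _, _ = enrichment_score(r, members)
            rev = RankedList(genes=r.genes[::-1].copy(), metric=-r.metric[::-1].copy())
            es_rev, _, _ = enrichment_score(rev, members)
            assert es == pytest.approx(-es_rev)

    def test_matches_brute_force_walk(self):
        rng = np.random.default_rng(123)
        for _ in range(200):
            n = rng.integers(4, 21)
            metrics = rng.normal(size=n) * rng.choice([0.5, 2.0])
            genes = [f"g{i:02d}" for i in range(n)]
            r = ranked_from(metrics, genes)
            size = rng.integers(1, min(6, n - 1) + 1)
            members = set(rng.choice(genes, size=size, replace=False))
            if np.all(np.abs(r.metric[np.isin(r.genes, list(members))]) == 0):
                continue
            es, _, _ = enrichment_score(r, members)
            ref = brute_force_es(r.genes, r.metric, members)
            assert es == pytest.approx(ref, abs=1e-12)
            assert -1.0 <= es <= 1.0


class TestPermutationNull:
    def test_seeded_determinism(self):
        rng = np.random.default_rng(0)
        values, ann = make_values_annotation(
            rng.normal(size=(30, 10)), responders=[f"S{j}" for j in range(5)]
        )
        gene_set = values.gene_ids[:5]
        a = permutation_null(values, ann, gene_set, 200, seed=7)
        b = permutation_null(values, ann, gene_set, 200, seed=7)
        assert (a == b).all()

    def test_small_n_perm_rejected(self):
        values, ann = make_values_annotation(
            np.zeros((5, 4)), responders=["S0", "S1"]
        )
        with pytest.raises(ConfigError):
            permutation_null(values, ann, values.gene_ids[:2], 50)

    def test_null_mean_near_zero_for_symmetric_weight_profile(self):
        """Random-set null ES is symmetric about zero when the ranking's
        weight profile is reversal-symmetric (a palindromic |metric|);
        with an asymmetric profile the weighted statistic need not be."""
        from immunosig.gsea import _es_batch

        half = np.linspace(2.0, 0.1, 20)
        w = np.concatenate([half, half[::-1]])  # palindromic weights
        rng = np.random.default_rng(3)
        n, h, B = w.size, 6, 1000
        keys = rng.random((B, n))
        positions = np.argpartition(keys, h - 1, axis=1)[:, :h]
        positions.sort(axis=1)
        nulls = _es_batch(w, positions, n)
        se = nulls.std(ddof=1) / np.sqrt(B)
        assert abs(nulls.mean()) < 3 * se

    def test_gene_set_nulls_match_scalar_path(self):
        """The vectorized null ES agrees with the per-draw scalar computation."""
        rng = np.random.default_rng(5)
        values, ann = make_values_annotation(
            rng.normal(size=(25, 8)), responders=[f"S{j}" for j in range(4)]
        )
        ranked = rank_genes(values, ann)
        nulls = permutation_null(values, ann, values.gene_ids[:5], 100, seed=11)
        check_rng = np.random.default_rng(11)
        keys = check_rng.random((100, len(ranked)))
        positions = np.argpartition(keys, 4, axis=1)[:, :5]
        for i in range(100):
            members = set(ranked.genes[positions[i]])
            es, _, _ = enrichment_score(ranked, members)
            # sign may flip only on exact peak/trough magnitude ties
            assert abs(nulls[i]) == pytest.approx(abs(es), abs=1e-12)

    def test_near_whole_panel_null_finite(self):
        rng = np.random.default_rng(6)
        values, ann = make_values_annotation(
            rng.normal(size=(10, 8)), responders=[f"S{j}" for j in range(4)]
        )
        nulls = permutation_null(values, ann, values.gene_ids[:-1], 100, seed=2)
        assert np.isfinite(nulls).all()

    def test_phenotype_mode_runs_and_is_seeded(self):
        rng = np.random.default_rng(8)
        values, ann = make_values_annotation(
            rng.normal(size=(20, 10)), responders=[f"S{j}" for j in range(5)]
        )
        a = permutation_null(values, ann, values.gene_ids[:4], 100,
                             mode="phenotype", seed=1)
        b = permutation_null(values, ann, values.gene_ids[:4], 100,
                             mode="phenotype", seed=1)
        assert (a == b).all() and np.isfinite(a).all()


class TestNesAndP:
    def test_ratio_normalization(self):
        nes, _ = nes_and_p(0.5, [0.25, 0.25, 0.25])
        assert nes == pytest.approx(2.0)

    def test_counting_with_observed_at_the_null_max(self):
        rng = np.random.default_rng(0)
        nulls = rng.uniform(0.01, 0.5, size=999)
        es = nulls.max()
        _, p = nes_and_p(es, nulls)
        assert p == pytest.approx(2 / 1000)

    def test_zero_es_degenerate(self):
        assert nes_and_p(0.0, [0.1, -0.2]) == (0.0, 1.0)

    def test_empty_null_rejected(self):
        with pytest.raises(ValueError):
            nes_and_p(0.5, [])

    def test_sign_stratification(self):
        nulls = np.array([0.5, 0.5, -0.1, -0.1, -0.1, -0.1])
        nes, p = nes_and_p(-0.2, nulls)
        assert nes == pytest.approx(-2.0)
        assert p == pytest.approx(1 / 5)


class TestRunGsea:
    def test_whole_panel_only_collection_rejected(self):
        rng = np.random.default_rng(0)
        values, ann = make_values_annotation(
            rng.normal(size=(8, 6)), responders=["S0", "S1", "S2"]
        )
        coll = GeneSetCollection({"ALL": list(values.gene_ids)})
        with pytest.raises(EmptyCollectionError):
            run_gsea(values, ann, coll, n_perm=100)

    def test_small_sets_discarded(self):
        rng = np.random.default_rng(1)
        values, ann = make_values_annotation(
            rng.normal(size=(20, 6)), responders=["S0", "S1", "S2"]
        )
        coll = GeneSetCollection({
            "TINY": values.gene_ids[:2],
            "OK": values.gene_ids[:5],
        })
        results = run_gsea(values, ann, coll, n_perm=100, seed=0)
        assert [r.name for r in results] == ["OK"]

    def test_results_sorted_and_flagged(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(60, 20))
        x[:8, :10] += 2.5  # strong planted set in responders
        values, ann = make_values_annotation(
            x, responders=[f"S{j}" for j in range(10)]
        )
        coll = GeneSetCollection({
            "PLANTED": values.gene_ids[:8],
            **{f"NULL{i}": list(np.random.default_rng(i).choice(
                values.gene_ids[8:], size=8, replace=False)) for i in range(5)},
        })
        results = run_gsea(values, ann, coll, n_perm=500, seed=3)
        assert results[0].name == "PLANTED"
        assert results[0].significant and results[0].q < 0.1
        ps = [r.p for r in results]
        assert ps == sorted(ps)
        for r in results:
            assert -1 <= r.es <= 1
            if r.es != 0:
                assert np.sign(r.nes) == np.sign(r.es)
            assert set(r.leading_edge) <= set(r.members)


def test_gmt_round_trip(tmp_path):
    coll = GeneSetCollection({"A_SET": ["g1", "g2"], "B_SET": ["g3", "g2", "g4"]},
                             source="test")
    p = tmp_path / "sets.gmt"
    write_gmt(coll, p)
    back = read_gmt(p, source="test")
    assert back.sets == coll.sets
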