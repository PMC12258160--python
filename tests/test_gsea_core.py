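"""Enrichment engine: hand-computed walks, exhaustive subset oracle,
fgsea cross-check, null-sampler consistency, NES/p-value definitions, BH."""

import itertools
import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sgsea.cox_rank import RankedList
from sgsea.gsea_core import (
    bh_adjust,
    enrichment_score,
    nes_and_pvalue,
    run_enrichment,
    sample_null_es,
)
from sgsea.io_formats import GeneSetCollection

from conftest import oracle_es, oracle_running_sum


def _ranked(stats, genes=None):
    stats = np.asarray(stats, dtype=float)
    genes = genes or [f"g{i + 1}" for i in range(len(stats))]
    return RankedList(genes=genes, stats=stats, mode="preranked")


class TestEnrichmentScore:
    def test_top_singleton_walk_and_leading_edge(self, tiny_ranked):
        res = enrichment_score(tiny_ranked, {"g1"})
        np.testing.assert_allclose(res.running_sum, [1.0, 0.5, 0.0])
        assert res.es == pytest.approx(1.0)
        assert res.leading_edge == ["g1"]

    def test_bottom_singleton_walk_and_leading_edge(self, tiny_ranked):
        res = enrichment_score(tiny_ranked, {"g3"})
        np.testing.assert_allclose(res.running_sum, [-0.5, -1.0, 0.0])
        assert res.es == pytest.approx(-1.0)
        assert res.leading_edge == ["g3"]

    def test_negating_and_reversing_flips_es(self):
        rng = np.random.default_rng(0)
        stats = np.sort(rng.normal(size=40))[::-1]
        genes = [f"g{i}" for i in range(40)]
        ranked = _ranked(stats, genes)
        flipped = _ranked(-stats[::-1], genes[::-1])
        for seed in range(5):
            members = set(np.random.default_rng(seed).choice(genes, 7, replace=False))
            a = enrichment_score(ranked, members).es
            b = enrichment_score(flipped, members).es
            assert a == pytest.approx(-b, abs=1e-12)

    def test_empty_and_full_intersections_error(self, tiny_ranked):
        with pytest.raises(ValueError, match="intersect"):
            enrichment_score(tiny_ranked, {"absent"})
        with pytest.raises(ValueError, match="whole"):
            enrichment_score(tiny_ranked, {"g1", "g2", "g3"})

    def test_exhaustive_subsets_match_loop_oracle(self):
        """Every proper subset of an 8-gene universe: the vectorized walk must
        equal the explicit-iteration prefix-extremum oracle."""
        rng = np.random.default_rng(5)
        stats = np.sort(rng.normal(scale=2, size=8))[::-1]
        genes = [f"g{i}" for i in range(8)]
        ranked = _ranked(stats, genes)
        for bits in range(1, 2 ** 8 - 1):
            member = [(bits >> i) & 1 == 1 for i in range(8)]
            res = enrichment_score(ranked, {g for g, m in zip(genes, member) if m})
            np.testing.assert_allclose(res.running_sum, oracle_running_sum(stats, member),
                                       atol=1e-12)
            assert res.es == pytest.approx(oracle_es(stats, member), abs=1e-12)

    def test_matches_fgsea_reference_implementation(self):
        """ES values must agree with fgsea::calcGseaStat on random sets."""
        assert shutil.which("Rscript"), "Rscript required for the fgsea cross-check"
        rng = np.random.default_rng(7)
        n = 50
        stats = np.sort(rng.normal(size=n))[::-1]
        genes = [f"g{i}" for i in range(n)]
        ranked = _ranked(stats, genes)
        sets = [sorted(rng.choice(n, size=s, replace=False).tolist())
                for s in (3, 5, 8, 12, 20, 30) for _ in range(3)]
        ours = [enrichment_score(ranked, [genes[i] for i in idx]).es for idx in sets]
        rsets = ",".join("c(%s)" % ",".join(str(i + 1) for i in idx) for idx in sets)
        script = (
            "suppressMessages(library(fgsea));"
            f"stats <- c({','.join(repr(float(v)) for v in stats)});"
            f"sets <- list({rsets});"
            "res <- sapply(sets, function(s) calcGseaStat(stats, selectedStats=s,"
            " gseaParam=1, scoreType='std'));"
            "cat(paste(res, collapse=','))"
        )
        out = subprocess.run(["Rscript", "-e", script], capture_output=True,
                             text=True, check=True)
        theirs = np.array([float(v) for v in out.stdout.strip().split(",")])
        np.testing.assert_allclose(ours, theirs, atol=1e-10)

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(st.data())
    def test_es_bounded_and_walk_closes_at_zero(self, data):
        n = data.draw(st.integers(4, 30))
        stats = data.draw(st.lists(
            st.floats(min_value=-50, max_value=50, allow_nan=False),
            min_size=n, max_size=n,
        ))
        stats = np.sort(np.asarray(stats))[::-1]
        size = data.draw(st.integers(1, n - 1))
        genes = [f"g{i}" for i in range(n)]
        members = set(data.draw(st.permutations(genes))[:size])
        res = enrichment_score(_ranked(stats, genes), members)
        assert -1.0 <= res.es <= 1.0
        assert abs(res.running_sum[-1]) < 1e-12
        assert set(res.leading_edge) <= members


class TestNullSampler:
    def test_deterministic_under_seed(self, tiny_ranked):
        rng = np.random.default_rng(1)
        stats = np.sort(rng.normal(size=60))[::-1]
        ranked = _ranked(stats)
        a = sample_null_es(ranked, 10, 500, seed=42)
        b = sample_null_es(ranked, 10, 500, seed=42)
        np.testing.assert_array_equal(a, b)

    def test_analytic_candidates_equal_full_walk(self):
        """The hit-position shortcut must reproduce the full running-sum ES
        on the identical random draws."""
        rng = np.random.default_rng(1)
        n, s = 40, 8
        stats = np.sort(rng.normal(size=n))[::-1]
        genes = [f"g{i}" for i in range(n)]
        ranked = _ranked(stats, genes)
        null = sample_null_es(ranked, s, 300, seed=3)
        keys = np.random.default_rng(3).random((300, n))
        pos = np.argpartition(keys, s - 1, axis=1)[:, :s]
        direct = np.array([
            enrichment_score(ranked, [genes[i] for i in row]).es for row in pos
        ])
        np.testing.assert_allclose(null, direct, atol=1e-12)

    def test_half_universe_null_mean_near_zero_on_symmetric_stats(self):
        stats = np.concatenate([np.arange(30, 0, -1), -np.arange(1, 31)]).astype(float)
        ranked = _ranked(stats)
        null = sample_null_es(ranked, 30, 2000, seed=0)
        se = null.std(ddof=1) / np.sqrt(len(null))
        assert abs(null.mean()) < 3 * se

    def test_full_universe_size_rejected(self, tiny_ranked):
        with pytest.raises(ValueError, match="set_size"):
            sample_null_es(tiny_ranked, 3, 200, seed=0)

    def test_low_permutation_count_warns(self, tiny_ranked):
        ranked = _ranked(np.arange(20, 0, -1, dtype=float))
        with pytest.warns(UserWarning, match="nperm"):
            sample_null_es(ranked, 4, 50, seed=0)


class TestNesAndPvalue:
    def test_nes_is_es_over_same_sign_null_mean(self):
        null = np.array([0.25, 0.25, 0.25, -0.9, -0.1])
        nes, _ = nes_and_pvalue(0.5, null)
        assert nes == pytest.approx(2.0)

    def test_es_beyond_every_null_gives_add_one_floor(self):
        null = np.concatenate([np.linspace(0.01, 0.5, 99), [-0.3]])
        _, pval = nes_and_pvalue(0.9, null)
        assert pval == pytest.approx(1 / 100)

    def test_es_tied_with_null_counts_as_extreme(self):
        null = np.array([0.5, 0.3, 0.1, -0.2])
        _, pval = nes_and_pvalue(0.5, null)
        assert pval >= 2 / (1 + 3)

    def test_inflating_es_never_raises_pvalue(self):
        rng = np.random.default_rng(2)
        null = rng.normal(scale=0.3, size=500)
        pvals = [nes_and_pvalue(es, null)[1] for es in (0.1, 0.3, 0.5, 0.8)]
        assert pvals == sorted(pvals, reverse=True)


class TestBhAdjust:
    def test_single_pvalue_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.03]), [0.03])

    def test_stepup_hand_example(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_all_ones_stay_ones(self):
        np.testing.assert_allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)


class TestRunEnrichment:
    def _setup(self, seed=0, n=200):
        rng = np.random.default_rng(seed)
        stats = np.sort(rng.normal(size=n))[::-1]
        genes = [f"g{i}" for i in range(n)]
        ranked = _ranked(stats, genes)
        coll = GeneSetCollection()
        coll.add("top", genes[:15], "loaded at the top")
        for i in range(6):
            coll.add(f"rand{i}", rng.choice(genes, size=12, replace=False), "")
        coll.add("tiny", genes[:2], "below min_size")
        return ranked, coll

    def test_output_schema_and_size_filter(self):
        ranked, coll = self._setup()
        res = run_enrichment(ranked, coll, min_size=3, nperm=200, nperm_max=200, seed=1)
        for col in ["pathway", "pval", "padj", "log2err", "ES", "NES", "size", "leadingEdge"]:
            assert col in res.columns
        assert "tiny" not in set(res["pathway"])
        assert (res["padj"] >= res["pval"] - 1e-12).all()
        assert ((res["pval"] > 0) & (res["pval"] <= 1)).all()
        assert np.all(np.sign(res["NES"]) == np.sign(res["ES"]))

    def test_loaded_set_beats_random_sets(self):
        ranked, coll = self._setup()
        res = run_enrichment(ranked, coll, nperm=500, nperm_max=5000, seed=1)
        res = res.set_index("pathway")
        assert res.loc["top", "pval"] == res["pval"].min()
        assert res.loc["top", "NES"] > 0

    def test_bit_identical_under_same_seed(self):
        ranked, coll = self._setup()
        a = run_enrichment(ranked, coll, nperm=300, seed=9)
        b = run_enrichment(ranked, coll, nperm=300, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_adaptive_escalation_resolves_small_pvalues(self):
        ranked, coll = self._setup()
        low = run_enrichment(ranked, coll, nperm=200, nperm_max=200, seed=2)
        high = run_enrichment(ranked, coll, nperm=200, nperm_max=20000, seed=2)
        floor_low = low.set_index("pathway").loc["top", "pval"]
        floor_high = high.set_index("pathway").loc["top", "pval"]
        assert floor_high < floor_low
        assert high.set_index("pathway").loc["top", "nperm"] > 200

    def test_everything_filtered_is_an_error(self):
        ranked, coll = self._setup()
        with pytest.raises(ValueError, match="size filter"):
            run_enrichment(ranked, coll, min_size=100, nperm=100)
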