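"""Cox partial-likelihood fits: oracle equivalence, model invariances,
tie handling, external cross-checks, and the hazard-ratio ranking."""

import numpy as np
import pandas as pd
import pytest

from sgsea.cox_rank import RankedList, fit_cox_gene, rank_by_lhr, rank_genes
from sgsea.io_formats import SurvivalTable
from sgsea.preprocess import NormalizedMatrix, logcpm_voom
from sgsea.synth import simulate_survival_dataset

from conftest import oracle_cox_grid


def _surv(time, status):
    ids = [f"s{i}" for i in range(len(time))]
    return SurvivalTable(pd.DataFrame({"time": time, "status": status}, index=ids))


class TestFitCoxGene:
    def test_constant_expression_is_non_informative(self):
        sv = _surv([1, 2, 3, 4], [1, 1, 0, 1])
        fit = fit_cox_gene(np.full(4, 2.5), sv)
        assert fit.beta == 0.0
        assert not fit.converged
        assert fit.flag == "non-informative"

    def test_zero_events_is_an_error(self):
        sv = _surv([1, 2, 3], [0, 0, 0])
        with pytest.raises(ValueError, match="events"):
            fit_cox_gene(np.array([1.0, 2.0, 3.0]), sv)

    def test_newton_raphson_matches_grid_search_oracle(self):
        """All-event 8-sample data with distinct times: the NR maximizer must
        agree with exhaustive maximization of a hand-coded partial likelihood."""
        rng = np.random.default_rng(100)
        for _ in range(5):
            x = rng.normal(size=8)
            t = rng.exponential(size=8)
            fit = fit_cox_gene(x, _surv(t, np.ones(8, dtype=int)))
            assert fit.converged
            assert abs(fit.beta - oracle_cox_grid(x, t)) <= 2e-3

    def test_scaling_covariate_halves_beta_and_shift_leaves_it(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=40)
        t = rng.exponential(scale=np.exp(-0.7 * x))
        sv = _surv(t, np.ones(40, dtype=int))
        base = fit_cox_gene(x, sv)
        assert fit_cox_gene(2 * x, sv).beta == pytest.approx(base.beta / 2, abs=1e-10)
        assert fit_cox_gene(x + 5.3, sv).beta == pytest.approx(base.beta, abs=1e-10)

    def test_efron_equals_breslow_without_tied_event_times(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=60)
        t = rng.exponential(scale=np.exp(-0.4 * x))
        status = (rng.random(60) < 0.7).astype(int)
        sv = _surv(t, status)
        e = fit_cox_gene(x, sv, ties="efron")
        b = fit_cox_gene(x, sv, ties="breslow")
        assert e.beta == pytest.approx(b.beta, abs=1e-8)

    def test_matches_lifelines_with_ties_and_censoring(self):
        lifelines = pytest.importorskip("lifelines")
        rng = np.random.default_rng(1)
        n = 150
        x = rng.normal(size=n)
        t = np.round(rng.exponential(scale=np.exp(-0.5 * x)), 2) + 0.01
        status = (rng.random(n) < 0.7).astype(int)
        fit = fit_cox_gene(x, _surv(t, status))
        cph = lifelines.CoxPHFitter().fit(
            pd.DataFrame({"time": t, "status": status, "x": x}), "time", "status"
        )
        assert fit.beta == pytest.approx(cph.params_["x"], abs=1e-4)
        assert fit.se == pytest.approx(cph.standard_errors_["x"], abs=1e-4)

    def test_covariate_adjustment_matches_lifelines(self):
        lifelines = pytest.importorskip("lifelines")
        rng = np.random.default_rng(2)
        n = 120
        x = rng.normal(size=n)
        age = rng.normal(60, 8, size=n)
        t = rng.exponential(scale=np.exp(-0.5 * x - 0.02 * age))
        status = (rng.random(n) < 0.8).astype(int)
        sv = SurvivalTable(
            pd.DataFrame({"time": t, "status": status, "age": age},
                         index=[f"s{i}" for i in range(n)]),
            covariate_names=("age",),
        )
        fit = fit_cox_gene(x, sv, covariates=["age"])
        cph = lifelines.CoxPHFitter().fit(
            pd.DataFrame({"time": t, "status": status, "x": x, "age": age}),
            "time", "status",
        )
        assert fit.beta == pytest.approx(cph.params_["x"], abs=1e-4)

    def test_separated_data_is_flagged_not_clipped_into_the_fit(self):
        # expression order identical to death order: monotone likelihood
        x = np.arange(8, dtype=float)
        t = np.arange(1, 9, dtype=float)[::-1]
        fit = fit_cox_gene(x, _surv(t, np.ones(8, dtype=int)))
        assert not fit.converged


class TestRankedList:
    def test_ties_break_lexicographically(self):
        rl = rank_genes(["zz", "aa", "mm"], [1.0, 1.0, 2.0], mode="lhr")
        assert rl.genes == ["mm", "aa", "zz"]

    def test_duplicate_genes_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            RankedList(genes=["a", "a"], stats=np.array([1.0, 0.5]))


class TestRankByLhr:
    def _norm(self, values, genes, samples):
        return NormalizedMatrix(values=pd.DataFrame(values, index=genes, columns=samples))

    def test_signal_gene_reaches_the_top_of_the_ranking(self):
        hits = 0
        for seed in range(5):
            counts, surv, _, truth = simulate_survival_dataset(
                n_samples=300, n_genes=150, n_pathways=5, pathway_size=1,
                effect_beta=1.0, censor_target=0.3, n_planted=1, seed=seed,
            )
            norm = logcpm_voom(counts)
            ranked = rank_by_lhr(norm, surv)
            signal = truth.beta_true[truth.beta_true != 0].index[0]
            hits += ranked.genes.index(signal) < 2  # top ~1% of 150 genes
        assert hits >= 4

    def test_negated_effect_sends_the_signal_gene_to_the_bottom(self):
        counts, surv, _, truth = simulate_survival_dataset(
            n_samples=300, n_genes=150, n_pathways=5, pathway_size=1,
            effect_beta=-1.0, censor_target=0.3, n_planted=1, seed=0,
        )
        ranked = rank_by_lhr(logcpm_voom(counts), surv)
        signal = truth.beta_true[truth.beta_true != 0].index[0]
        assert ranked.genes.index(signal) >= len(ranked) - 2

    def test_gene_order_permutation_leaves_ranking_unchanged(self):
        counts, surv, _, _ = simulate_survival_dataset(
            n_samples=80, n_genes=60, n_pathways=3, pathway_size=5,
            effect_beta=0.5, censor_target=0.3, seed=3,
        )
        norm = logcpm_voom(counts)
        perm = np.random.default_rng(0).permutation(norm.values.shape[0])
        shuffled = NormalizedMatrix(values=norm.values.iloc[perm])
        a = rank_by_lhr(norm, surv)
        b = rank_by_lhr(shuffled, surv)
        assert a.genes == b.genes
        np.testing.assert_array_equal(a.stats, b.stats)

    def test_too_few_usable_genes_is_an_error(self):
        sv = _surv([1, 2, 3, 4], [1, 1, 1, 0])
        norm = self._norm(np.ones((3, 4)), ["g1", "g2", "g3"], sv.sample_ids)
        with pytest.raises(ValueError, match="fewer than 2"):
            rank_by_lhr(norm, sv)
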