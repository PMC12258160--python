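"""Meta-analyses: the outcome-permutation FDR audit and the SGSEA-vs-GSEA
significant-pathway comparison.

The audit breaks the expression-outcome association by jointly shuffling
each sample's (time, status) pair across samples — jointly, because
shuffling time and status independently would fabricate censoring patterns
that never occurred — then reruns the survival enrichment pipeline and
records, per pathway, how often the adjusted p-value falls below alpha.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cox_rank import rank_by_lhr
from .gsea_core import run_enrichment
from .io_formats import CountsTable, GeneSetCollection, SurvivalTable, align_counts_survival
from .preprocess import filter_low_expression, logcpm_voom

logger = logging.getLogger(__name__)


@dataclass
class FdrAuditResult:
    """Per-pathway estimated false-call rate under outcome permutation."""

    per_pathway: pd.Series
    average: float
    B: int
    alpha: float


@dataclass
class VennPartition:
    """Counts of pathways significant in both, one, or neither analysis."""

    both: int
    only_a: int
    only_b: int
    neither: int
    total: int

    def __post_init__(self) -> None:
        if self.both + self.only_a + self.only_b + self.neither != self.total:
            raise ValueError("Venn partition counts do not sum to the shared total")


def permutation_fdr_audit(
    counts: CountsTable,
    surv: SurvivalTable,
    collection: GeneSetCollection,
    B: int = 100,
    alpha: float = 0.15,
    seed: int = 0,
    min_mean: float = 0.1,
    covariates=None,
    ties: str = "efron",
    min_size: int = 3,
    max_size: int = 500,
    nperm: int = 1000,
    nperm_max: int = 10_000,
    exponent: float = 1.0,
) -> FdrAuditResult:
    """Estimate per-pathway FDR by rerunning SGSEA on permuted outcomes.

    Filtering and normalization do not depend on the outcome and are done
    once; each of the ``B`` replicates redoes the Cox ranking and the
    enrichment (with its own shared same-size null cache).
    """
    if B < 10:
        warnings.warn(f"B={B} permutations give unstable FDR estimates", stacklevel=2)
    counts, surv = align_counts_survival(counts, surv)
    filtered = filter_low_expression(counts, min_mean=min_mean)
    norm = logcpm_voom(filtered)

    rng = np.random.default_rng(seed)
    n = len(surv.sample_ids)
    hits: dict[str, int] = {}
    tested: dict[str, int] = {}
    for b in range(B):
        perm = rng.permutation(n)
        data = surv.data.copy()
        data[["time", "status"]] = surv.data[["time", "status"]].to_numpy()[perm]
        surv_b = SurvivalTable(data, covariate_names=surv.covariate_names)
        ranked = rank_by_lhr(norm, surv_b, covariates=covariates, ties=ties)
        res = run_enrichment(
            ranked, collection, min_size=min_size, max_size=max_size,
            nperm=nperm, nperm_max=nperm_max,
            seed=int(rng.integers(2**31)), alpha=alpha, exponent=exponent,
        )
        for name, padj in zip(res["pathway"], res["padj"]):
            tested[name] = tested.get(name, 0) + 1
            if padj < alpha:
                hits[name] = hits.get(name, 0) + 1
        logger.debug("audit replicate %d/%d done", b + 1, B)

    per = pd.Series(
        {name: hits.get(name, 0) / tested[name] for name in tested}, name="fdr"
    ).sort_index()
    return FdrAuditResult(per_pathway=per, average=float(per.mean()), B=B, alpha=alpha)


def compare_significant(
    res_a: pd.DataFrame, res_b: pd.DataFrame, alpha: float = 0.15
) -> VennPartition:
    """Partition the shared pathways by significance in each analysis."""
    a = res_a.set_index("pathway")["padj"] if "pathway" in res_a.columns else res_a["padj"]
    b = res_b.set_index("pathway")["padj"] if "pathway" in res_b.columns else res_b["padj"]
    shared = sorted(set(a.index) & set(b.index))
    if not shared:
        raise ValueError("the two result tables share no pathway names")
    dropped = (len(a) - len(shared)) + (len(b) - len(shared))
    if dropped:
        logger.info("comparison restricted to %d shared pathways (%d dropped)",
                    len(shared), dropped)
    sig_a = a.loc[shared] < alpha
    sig_b = b.loc[shared] < alpha
    return VennPartition(
        both=int((sig_a & sig_b).sum()),
        only_a=int((sig_a & ~sig_b).sum()),
        only_b=int((~sig_a & sig_b).sum()),
        neither=int((~sig_a & ~sig_b).sum()),
        total=len(shared),
    )
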