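"""Per-gene Cox proportional-hazards fits and the log-hazard-ratio ranking.

The model for gene *i* is h(t, x_i) = h0(t) * exp(beta * x_i): beta is the
log hazard ratio per unit of normalized expression, with the baseline hazard
h0 profiled out by the partial likelihood. One fit per gene produces the
ranking statistic of the survival mode; genes whose fits do not converge
(quasi-separation, no information) are excluded from the ranking rather
than clipped, so that pathological betas cannot dominate the extremes of
the ranked list.

The partial likelihood is maximized by Newton-Raphson with step-halving,
with the Efron tie correction by default (Breslow available). The engine
precomputes the time ordering and tie structure once per dataset so that
thousands of per-gene fits only pay for cumulative sums.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io_formats import SurvivalTable
from .preprocess import NormalizedMatrix

logger = logging.getLogger(__name__)

SEPARATION_BETA = 15.0  # |beta| beyond this is treated as quasi-separation


@dataclass
class CoxFit:
    """Result of a single Cox partial-likelihood fit.

    ``beta`` is the log hazard ratio for the gene column (the first design
    column); ``se``/``z``/``p`` are the Wald quantities, ``loglik`` the
    maximized partial log-likelihood.
    """

    beta: float
    se: float
    z: float
    p: float
    loglik: float
    converged: bool
    n_events: int
    flag: str | None = None


@dataclass
class RankedList:
    """Genes in descending order of a ranking statistic.

    ``mode`` tags the statistic: ``"lhr"`` (Cox log hazard ratio), ``"lfc"``
    (NB log2 fold change) or ``"preranked"``. Ties are broken
    lexicographically by gene id, so the ordering is deterministic.
    """

    genes: list[str]
    stats: np.ndarray
    mode: str = "lhr"
    n_excluded: int = 0

    def __post_init__(self) -> None:
        self.stats = np.asarray(self.stats, dtype=float)
        if len(self.genes) != len(self.stats):
            raise ValueError("genes and stats length mismatch")
        if len(self.genes) != len(set(self.genes)):
            raise ValueError("ranked list contains duplicate gene ids")
        if not np.all(np.isfinite(self.stats)):
            raise ValueError("ranking statistics must be finite")

    def __len__(self) -> int:
        return len(self.genes)

    def to_series(self) -> pd.Series:
        return pd.Series(self.stats, index=self.genes, name=self.mode)


def rank_genes(gene_ids, stats, mode: str, n_excluded: int = 0) -> RankedList:
    """Sort genes by statistic descending, ties broken by gene id."""
    gene_ids = np.asarray(list(gene_ids), dtype=object)
    stats = np.asarray(stats, dtype=float)
    order = np.lexsort((gene_ids, -stats))
    return RankedList(
        genes=list(gene_ids[order]), stats=stats[order], mode=mode, n_excluded=n_excluded
    )


class CoxEngine:
    """Shared per-dataset precomputation for many per-gene Cox fits."""

    def __init__(self, time, status, ties: str = "efron"):
        time = np.asarray(time, dtype=float)
        status = np.asarray(status, dtype=int)
        if time.shape != status.shape or time.ndim != 1:
            raise ValueError("time and status must be 1-D arrays of equal length")
        if status.sum() == 0:
            raise ValueError("no events in the survival data; the partial likelihood is empty")
        if ties not in ("efron", "breslow"):
            raise ValueError(f"unknown tie method {ties!r}")
        self.ties = ties
        self.n = len(time)
        self.n_events = int(status.sum())

        order = np.argsort(time, kind="stable")
        self.order = order
        t = time[order]
        e = status[order]
        self.event_mask = e == 1

        # tie groups over the time-sorted array
        first = np.r_[True, t[1:] != t[:-1]]
        group_id = np.cumsum(first) - 1
        group_start = np.flatnonzero(first)

        ev_pos = np.flatnonzero(e == 1)
        ev_group = group_id[ev_pos]
        self.ev_pos = ev_pos
        self.ev_risk_start = group_start[ev_group]  # risk set = suffix from here

        # within-group event index l (0-based) and group event count d
        seg_first = np.r_[True, ev_group[1:] != ev_group[:-1]]
        self.seg_starts = np.flatnonzero(seg_first)
        seg_id = np.cumsum(seg_first) - 1
        self.seg_id = seg_id
        seg_sizes = np.bincount(seg_id)
        self.ev_d = seg_sizes[seg_id].astype(float)
        self.ev_l = np.arange(len(ev_pos)) - self.seg_starts[seg_id]
        if ties == "efron":
            self.ev_r = self.ev_l / self.ev_d
        else:
            self.ev_r = np.zeros(len(ev_pos))

    def _quantities(self, X: np.ndarray, beta: np.ndarray):
        """Partial log-likelihood, score and observed information at beta."""
        eta = X @ beta
        eta = np.clip(eta, -500.0, 500.0)
        w = np.exp(eta)
        k = X.shape[1]

        rc0 = np.cumsum(w[::-1])[::-1]
        wX = w[:, None] * X
        rc1 = np.cumsum(wX[::-1], axis=0)[::-1]
        wXX = wX[:, :, None] * X[:, None, :]
        rc2 = np.cumsum(wXX[::-1], axis=0)[::-1]

        R0 = rc0[self.ev_risk_start]
        R1 = rc1[self.ev_risk_start]
        R2 = rc2[self.ev_risk_start]

        tie0 = np.add.reduceat(w[self.ev_pos], self.seg_starts)[self.seg_id]
        tie1 = np.add.reduceat(wX[self.ev_pos], self.seg_starts, axis=0)[self.seg_id]
        tie2 = np.add.reduceat(wXX[self.ev_pos], self.seg_starts, axis=0)[self.seg_id]

        r = self.ev_r
        S0 = R0 - r * tie0
        S1 = R1 - r[:, None] * tie1
        S2 = R2 - r[:, None, None] * tie2

        ll = float(eta[self.ev_pos].sum() - np.log(S0).sum())
        M = S1 / S0[:, None]
        U = X[self.ev_pos].sum(axis=0) - M.sum(axis=0)
        info = (S2 / S0[:, None, None]).sum(axis=0) - np.einsum("ek,el->kl", M, M)
        return ll, U, info.reshape(k, k)

    def fit(self, X: np.ndarray, max_iter: int = 25, tol: float = 1e-9):
        """Newton-Raphson with step-halving; X is n x k in original sample order."""
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        Xs = X[self.order]
        Xs = Xs - Xs.mean(axis=0)  # centering: invariant beta, stabler exp()
        k = Xs.shape[1]
        beta = np.zeros(k)
        ll, U, info = self._quantities(Xs, beta)
        converged = False
        flag = None
        for _ in range(max_iter):
            try:
                direction = np.linalg.solve(info, U)
            except np.linalg.LinAlgError:
                flag = "singular-information"
                break
            step = 1.0
            for _ in range(20):
                candidate = beta + step * direction
                ll_new, U_new, info_new = self._quantities(Xs, candidate)
                if ll_new >= ll - 1e-12:
                    break
                step /= 2.0
            beta, U, info = candidate, U_new, info_new
            if abs(beta[0]) > SEPARATION_BETA:
                flag = "separation"
                break
            if abs(ll_new - ll) < tol * (abs(ll) + tol):
                ll = ll_new
                converged = True
                break
            ll = ll_new
        se = np.full(k, np.nan)
        if flag != "singular-information":
            try:
                cov = np.linalg.inv(info)
                d = np.diag(cov)
                se = np.sqrt(np.where(d > 0, d, np.nan))
            except np.linalg.LinAlgError:
                pass
        return beta, se, ll, converged and flag is None, flag


def fit_cox_gene(
    expr,
    surv: SurvivalTable,
    covariates=None,
    ties: str = "efron",
    max_iter: int = 25,
    tol: float = 1e-9,
) -> CoxFit:
    """Fit the single-gene Cox model, optionally with shared covariates.

    ``expr`` is per-sample normalized expression aligned to ``surv`` (a
    Series indexed by sample id, or an array in the survival table's sample
    order). ``covariates`` may be a DataFrame or a list of covariate column
    names present in the survival table.
    """
    if isinstance(expr, pd.Series):
        expr = expr.reindex(surv.sample_ids).to_numpy(dtype=float)
    else:
        expr = np.asarray(expr, dtype=float)
    if len(expr) != len(surv.sample_ids):
        raise ValueError("expression vector does not align with the survival samples")
    engine = CoxEngine(surv.time, surv.status, ties=ties)
    cov = _covariate_matrix(surv, covariates)
    return _fit_one(engine, expr, cov, max_iter=max_iter, tol=tol)


def _covariate_matrix(surv: SurvivalTable, covariates) -> np.ndarray | None:
    if covariates is None:
        return None
    if isinstance(covariates, pd.DataFrame):
        return covariates.reindex(surv.sample_ids).to_numpy(dtype=float)
    return surv.covariates(list(covariates)).to_numpy(dtype=float)


def _fit_one(engine: CoxEngine, expr: np.ndarray, cov: np.ndarray | None,
             max_iter: int = 25, tol: float = 1e-9) -> CoxFit:
    if np.ptp(expr) == 0.0:
        return CoxFit(
            beta=0.0, se=np.nan, z=np.nan, p=1.0, loglik=np.nan,
            converged=False, n_events=engine.n_events, flag="non-informative",
        )
    X = expr[:, None] if cov is None else np.column_stack([expr, cov])
    beta, se, ll, converged, flag = engine.fit(X, max_iter=max_iter, tol=tol)
    b0, s0 = float(beta[0]), float(se[0])
    z = b0 / s0 if converged and np.isfinite(s0) and s0 > 0 else np.nan
    p = float(np.clip(2.0 * sps.norm.sf(abs(z)), 1e-300, 1.0)) if np.isfinite(z) else 1.0
    return CoxFit(
        beta=b0, se=s0, z=z, p=p, loglik=ll,
        converged=converged, n_events=engine.n_events, flag=flag,
    )


def fit_cox_all_genes(
    norm: NormalizedMatrix,
    surv: SurvivalTable,
    covariates=None,
    ties: str = "efron",
    max_iter: int = 25,
    tol: float = 1e-9,
) -> pd.DataFrame:
    """One Cox fit per gene; returns beta/se/z/p/converged/flag per gene."""
    samples = [s for s in norm.sample_ids if s in set(surv.sample_ids)]
    if len(samples) < 2:
        raise ValueError("normalized matrix and survival table share fewer than 2 samples")
    values = norm.values[samples].to_numpy(dtype=float)
    sub = SurvivalTable(
        surv.data.loc[samples], covariate_names=surv.covariate_names, n_removed=surv.n_removed
    )
    engine = CoxEngine(sub.time, sub.status, ties=ties)
    cov = _covariate_matrix(sub, covariates)
    rows = []
    for g, x in zip(norm.gene_ids, values):
        fit = _fit_one(engine, x, cov, max_iter=max_iter, tol=tol)
        rows.append((g, fit.beta, fit.se, fit.z, fit.p, fit.converged, fit.flag))
    return pd.DataFrame(
        rows, columns=["gene", "beta", "se", "z", "p", "converged", "flag"]
    ).set_index("gene")


def rank_by_lhr(
    norm: NormalizedMatrix,
    surv: SurvivalTable,
    covariates=None,
    ties: str = "efron",
    max_iter: int = 25,
    tol: float = 1e-9,
) -> RankedList:
    """Rank genes by Cox log hazard ratio, descending.

    Non-converged or non-informative fits are excluded and counted; the
    excluded fraction is logged and recorded on the result.
    """
    fits = fit_cox_all_genes(
        norm, surv, covariates=covariates, ties=ties, max_iter=max_iter, tol=tol
    )
    usable = fits[fits["converged"]]
    n_excluded = len(fits) - len(usable)
    if len(usable) < 2:
        raise ValueError(f"fewer than 2 genes with converged Cox fits ({len(usable)})")
    if n_excluded:
        logger.info(
            "excluded %d of %d genes from the ranking (%.2f%% non-converged/non-informative)",
            n_excluded, len(fits), 100.0 * n_excluded / len(fits),
        )
    return rank_genes(usable.index, usable["beta"].to_numpy(), mode="lhr", n_excluded=n_excluded)
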