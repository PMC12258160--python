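"""Negative-binomial GLM log2 fold changes for the case-control GSEA mode.

A plain NB2 Wald GLM: per-gene dispersion estimated by method of moments on
size-factor-normalized counts and refined by maximum likelihood, then a
log-link GLM with design intercept + condition (optionally + pair
indicators) and log size factors as offsets. No dispersion-trend or LFC
shrinkage is applied — the fold change is an input statistic for
enrichment, not an effect-size estimate to be reported on its own.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, special

from .cox_rank import RankedList, rank_genes
from .io_formats import CountsTable
from .preprocess import median_ratio_size_factors

logger = logging.getLogger(__name__)

DISPERSION_FLOOR = 1e-8
LN2 = np.log(2.0)


@dataclass
class LfcFit:
    """Per-gene NB GLM result: log2 fold change of condition B vs A."""

    log2fc: float
    se: float
    wald_p: float
    dispersion: float
    basemean: float
    flag: str | None = None


def _condition_arrays(condition) -> tuple[np.ndarray, list]:
    cond = pd.Series(condition)
    levels = sorted(cond.unique())
    if len(levels) != 2:
        raise ValueError(f"exactly two condition labels required, got {levels}")
    return (cond == levels[1]).to_numpy(dtype=float), levels


def _nb_nll(log_alpha: float, y: np.ndarray, mu: np.ndarray) -> float:
    alpha = np.exp(log_alpha)
    r = 1.0 / alpha
    return -float(
        np.sum(
            special.gammaln(y + r) - special.gammaln(r) - special.gammaln(y + 1)
            + r * np.log(r / (r + mu)) + y * np.log(mu / (r + mu))
        )
    )


def estimate_dispersion(
    counts: CountsTable,
    size_factors: pd.Series | None = None,
    condition=None,
) -> pd.Series:
    """Per-gene NB dispersion: moments estimate, refined by per-gene MLE.

    Counts are normalized by size factor; the moments estimate
    max(0, (s^2 - m) / m^2) pools residual variance within condition, then
    the NB likelihood is maximized in the dispersion with the group means
    held at their normalized sample means. Floored at 1e-8.
    """
    if size_factors is None:
        size_factors = median_ratio_size_factors(counts)
    sf = size_factors.reindex(counts.sample_ids).to_numpy(dtype=float)
    c = counts.counts.to_numpy(dtype=float)
    z = c / sf

    if condition is None:
        groups = np.zeros(counts.n_samples, dtype=int)
    else:
        groups, _ = _condition_arrays(condition)
        groups = groups.astype(int)
    n = counts.n_samples
    n_groups = len(np.unique(groups))
    group_means = np.stack([
        z[:, groups == g].mean(axis=1) for g in np.unique(groups)
    ], axis=1)
    fitted = group_means[:, groups]
    resid_ss = ((z - fitted) ** 2).sum(axis=1)
    s2 = resid_ss / max(n - n_groups, 1)
    mbar = z.mean(axis=1)

    with np.errstate(divide="ignore", invalid="ignore"):
        alpha_mom = np.where(mbar > 0, (s2 - mbar) / mbar ** 2, 0.0)
    alpha_mom = np.clip(alpha_mom, DISPERSION_FLOOR, 100.0)

    out = np.empty(counts.n_genes)
    for i in range(counts.n_genes):
        if mbar[i] <= 0 or s2[i] <= 0:
            out[i] = DISPERSION_FLOOR
            continue
        mu = np.maximum(fitted[i] * sf, 1e-8)
        y = c[i]
        lo, hi = np.log(DISPERSION_FLOOR), np.log(100.0)
        x0 = float(np.clip(np.log(alpha_mom[i]), lo, hi))
        res = optimize.minimize_scalar(
            _nb_nll, args=(y, mu), bounds=(lo, hi), method="bounded",
            options={"xatol": 1e-4},
        )
        cand = float(res.x)
        # keep whichever of {MLE solution, moments start} has higher likelihood
        if _nb_nll(x0, y, mu) < _nb_nll(cand, y, mu):
            cand = x0
        out[i] = np.exp(cand)
    return pd.Series(np.maximum(out, DISPERSION_FLOOR), index=counts.gene_ids, name="dispersion")


def nb_wald_lfc(
    counts: CountsTable,
    condition,
    size_factors: pd.Series | None = None,
    dispersions: pd.Series | None = None,
    pairs=None,
) -> pd.DataFrame:
    """Per-gene NB Wald GLM log2 fold change (second condition level vs first).

    Design: intercept + condition indicator (+ pair indicators when
    ``pairs`` labels a paired layout), offset log size factors. A gene that
    is all-zero in one condition gets a 0.5 pseudo-mean fold change and is
    flagged instead of fitted.
    """
    if size_factors is None:
        size_factors = median_ratio_size_factors(counts)
    sf = size_factors.reindex(counts.sample_ids).to_numpy(dtype=float)
    cond, levels = _condition_arrays(condition)
    if dispersions is None:
        dispersions = estimate_dispersion(counts, size_factors, condition)
    disp = dispersions.reindex(counts.gene_ids).to_numpy(dtype=float)

    design = [np.ones(counts.n_samples), cond]
    if pairs is not None:
        pair_dummies = pd.get_dummies(pd.Series(pairs), drop_first=True).to_numpy(dtype=float)
        design.extend(pair_dummies.T)
    X = np.column_stack(design)
    offset = np.log(sf)

    c = counts.counts.to_numpy(dtype=float)
    z = c / sf
    rows = []
    for i, gene in enumerate(counts.gene_ids):
        y = c[i]
        basemean = float(z[i].mean())
        mean_a = z[i][cond == 0].mean()
        mean_b = z[i][cond == 1].mean()
        if mean_a == 0.0 or mean_b == 0.0:
            lfc = float(np.log2(max(mean_b, 0.5) / max(mean_a, 0.5)))
            rows.append((gene, lfc, np.nan, np.nan, disp[i], basemean, "zero-group"))
            continue
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fam = sm.families.NegativeBinomial(alpha=max(disp[i], DISPERSION_FLOOR))
                fit = sm.GLM(y, X, family=fam, offset=offset).fit()
            lfc = float(fit.params[1] / LN2)
            se = float(fit.bse[1] / LN2)
            p = float(np.clip(fit.pvalues[1], 1e-300, 1.0))
            flag = None
        except Exception as exc:  # non-convergence on a degenerate gene
            lfc, se, p, flag = np.nan, np.nan, np.nan, f"fit-failed:{type(exc).__name__}"
        rows.append((gene, lfc, se, p, disp[i], basemean, flag))
    df = pd.DataFrame(
        rows, columns=["gene", "log2fc", "se", "wald_p", "dispersion", "basemean", "flag"]
    ).set_index("gene")
    df.attrs["levels"] = levels
    return df


def rank_by_lfc(
    counts: CountsTable,
    condition,
    size_factors: pd.Series | None = None,
    dispersions: pd.Series | None = None,
    pairs=None,
) -> RankedList:
    """Rank genes by NB log2 fold change, descending (ties by gene id)."""
    fits = nb_wald_lfc(counts, condition, size_factors, dispersions, pairs=pairs)
    usable = fits[np.isfinite(fits["log2fc"])]
    n_excluded = len(fits) - len(usable)
    if len(usable) < 2:
        raise ValueError("fewer than 2 genes with a finite log2 fold change")
    if n_excluded:
        logger.info("excluded %d genes with undefined fold change", n_excluded)
    return rank_genes(
        usable.index, usable["log2fc"].to_numpy(), mode="lfc", n_excluded=n_excluded
    )
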