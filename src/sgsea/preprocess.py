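"""Count filtering and normalization ahead of Cox ranking or NB modeling.

Two normalization routes coexist, mirroring the two analysis modes:

* the survival route works on log2-CPM values with a fitted mean-variance
  trend (the voom recipe), because the Cox model wants an approximately
  continuous, homoscedastic covariate;
* the case-control route leaves counts raw and hands median-of-ratios size
  factors to the negative-binomial GLM, which models normalization inside
  the likelihood.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .io_formats import CountsTable

logger = logging.getLogger(__name__)


@dataclass
class NormalizedMatrix:
    """log2-CPM values plus (optional) voom precision weights.

    ``values`` and ``weights`` share the shape and labels of the filtered
    counts matrix. The weights are computed for parity with the published
    recipe but the Cox stage does not consume them by default.
    """

    values: pd.DataFrame
    weights: pd.DataFrame | None = None
    recipe: dict = field(default_factory=dict)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


def filter_low_expression(counts: CountsTable, min_mean: float = 0.1) -> CountsTable:
    """Drop genes averaging fewer than ``min_mean`` reads per sample.

    The default 0.1 encodes "less than 1 read per 10 samples on average";
    the rule is a strict less-than, so a gene sitting exactly on the
    threshold is kept. Idempotent, and monotone in ``min_mean``.
    """
    means = counts.counts.mean(axis=1)
    keep = means.to_numpy() >= min_mean
    n_removed = int((~keep).sum())
    if keep.sum() == 0:
        raise ValueError(f"filtering at min_mean={min_mean} removed every gene")
    if n_removed:
        logger.info("low-expression filter removed %d of %d genes", n_removed, counts.n_genes)
    return CountsTable(counts.counts.loc[keep])


def logcpm(counts: np.ndarray | pd.DataFrame) -> np.ndarray:
    """log2( (count + 0.5) / (library size + 1) * 1e6 ), per observation."""
    c = np.asarray(counts, dtype=float)
    lib = c.sum(axis=0)
    return np.log2((c + 0.5) / (lib + 1.0) * 1e6)


def logcpm_voom(counts: CountsTable, span: float = 0.5) -> NormalizedMatrix:
    """voom-style normalization: log2-CPM plus mean-variance precision weights.

    The trend is a lowess fit (span 0.5) of the square-root residual
    standard deviation on the average log2-count; each observation's weight
    is the inverse fourth power of the trend prediction at its fitted
    log2-count. With no design beyond an intercept the residual SD is the
    per-gene SD of the log2-CPM values.
    """
    c = counts.counts.to_numpy(dtype=float)
    lib = c.sum(axis=0)
    if np.any(lib <= 0):
        bad = counts.sample_ids[int(np.argmax(lib <= 0))]
        raise ValueError(f"sample {bad!r} has zero library size")
    y = np.log2((c + 0.5) / (lib + 1.0) * 1e6)

    # mean log2-count and sqrt residual SD per gene (intercept-only design)
    mean_lib_term = np.mean(np.log2(lib + 1.0))
    sx = y.mean(axis=1) + mean_lib_term - np.log2(1e6)
    sd = y.std(axis=1, ddof=1)
    sy = np.sqrt(sd)

    informative = sd > 0  # genes with <2 distinct values carry no variance signal
    if informative.sum() >= 10:
        fit = lowess(sy[informative], sx[informative], frac=span, return_sorted=True)
        tx, ty = fit[:, 0], fit[:, 1]
    else:  # degenerate tiny input: flat trend at the mean
        tx = np.array([sx.min(), sx.max()])
        ty = np.full(2, max(sy[informative].mean() if informative.any() else 1.0, 1e-6))

    # fitted log2-count per observation, trend interpolated with boundary clamp
    lam = y + np.log2(lib + 1.0)[None, :] - np.log2(1e6)
    pred = np.interp(lam, tx, ty)
    pred = np.maximum(pred, 1e-6)
    w = pred ** -4

    values = pd.DataFrame(y, index=counts.counts.index, columns=counts.counts.columns)
    weights = pd.DataFrame(w, index=counts.counts.index, columns=counts.counts.columns)
    recipe = {"method": "voom-logcpm", "span": span, "prior_count": 0.5, "lib_offset": 1.0}
    return NormalizedMatrix(values=values, weights=weights, recipe=recipe)


def median_ratio_size_factors(counts: CountsTable) -> pd.Series:
    """Median-of-ratios size factors for NB count models.

    For every gene positive in all samples, form count / geometric mean of
    that gene across samples; a sample's factor is the median of its ratios.
    """
    c = counts.counts.to_numpy(dtype=float)
    all_positive = (c > 0).all(axis=1)
    if not all_positive.any():
        raise ValueError(
            "no gene has nonzero counts in every sample; filter low-expression genes first"
        )
    logc = np.log(c[all_positive])
    log_geomean = logc.mean(axis=1, keepdims=True)
    factors = np.exp(np.median(logc - log_geomean, axis=0))
    return pd.Series(factors, index=counts.counts.columns, name="size_factor")
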