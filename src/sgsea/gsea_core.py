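"""Weighted running-sum enrichment with a gene-sampling permutation null.

The enrichment score (ES) walks the ranked list: members of the gene set
("hits") add |statistic|^exponent normalized by the in-set total, and
non-members subtract 1/(N - N_hits); the ES is the walk value of maximal
absolute deviation from zero, so both cumulative distributions end at zero
and ES lies in [-1, 1]. Significance is calibrated by drawing random gene
sets of the same size from the ranked universe (the preranked null — the
ranking already encodes the phenotype, so genes, not phenotypes, are
permuted), normalizing ES by the mean same-sign null magnitude (NES) and
computing an add-one permutation p-value. Small p-values are resolved by
adaptively escalating the permutation count; Benjamini-Hochberg adjustment
runs across all tested pathways.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .cox_rank import RankedList
from .io_formats import GeneSetCollection

logger = logging.getLogger(__name__)

_CHUNK_ROWS = 50_000  # null-permutation batches, bounds memory at ~N*chunk floats


@dataclass
class ESResult:
    """Enrichment score with its full running sum and leading edge."""

    es: float
    running_sum: np.ndarray
    peak_index: int
    leading_edge: list[str]
    hit_indices: np.ndarray


def _hit_mask(ranked: RankedList, gene_set) -> np.ndarray:
    members = set(gene_set.genes) if hasattr(gene_set, "genes") else set(gene_set)
    mask = np.fromiter((g in members for g in ranked.genes), dtype=bool, count=len(ranked))
    return mask


def enrichment_score(ranked: RankedList, gene_set, exponent: float = 1.0) -> ESResult:
    """Running-sum enrichment score of one gene set against a ranked list.

    A tie between equal-magnitude positive and negative extrema resolves to
    the positive one. The leading edge contains the hits at or before the
    positive peak (ES > 0), or at or after the negative trough (ES < 0),
    ordered from the relevant extreme of the list inward.
    """
    n = len(ranked)
    hits = _hit_mask(ranked, gene_set)
    n_hits = int(hits.sum())
    if n_hits == 0:
        raise ValueError("gene set does not intersect the ranked universe")
    if n_hits == n:
        raise ValueError("gene set covers the whole ranked universe; miss increment undefined")

    w = np.abs(ranked.stats) ** exponent
    hit_total = w[hits].sum()
    inc = np.empty(n)
    if hit_total > 0:
        inc[hits] = w[hits] / hit_total
    else:  # all in-set statistics are zero: fall back to equal hit weights
        inc[hits] = 1.0 / n_hits
    inc[~hits] = -1.0 / (n - n_hits)
    running = np.cumsum(inc)

    imax = int(np.argmax(running))
    imin = int(np.argmin(running))
    # >= with tolerance: an exact-magnitude tie resolves to the positive peak
    if running[imax] >= -running[imin] - 1e-12:
        es, peak = float(running[imax]), imax
    else:
        es, peak = float(running[imin]), imin
    es = float(np.clip(es, -1.0, 1.0))  # guard one-ULP float excursions

    hit_idx = np.flatnonzero(hits)
    genes = np.asarray(ranked.genes, dtype=object)
    if es > 0:
        le = list(genes[hit_idx[hit_idx <= peak]])
    elif es < 0:
        le = list(genes[hit_idx[hit_idx >= peak]][::-1])  # bottom-most first
    else:
        le = []
    return ESResult(
        es=es, running_sum=running, peak_index=peak, leading_edge=le, hit_indices=hit_idx
    )


def _null_es_from_positions(w: np.ndarray, positions: np.ndarray, n: int) -> np.ndarray:
    """ES for many random gene sets given sorted hit positions (m x s).

    The walk's positive extremum sits at a hit and its negative extremum
    just before a hit (or at the final value, zero), so only the 2s
    candidate values per permutation need evaluating.
    """
    m, s = positions.shape
    wh = w[positions]
    cw = np.cumsum(wh, axis=1)
    tot = cw[:, -1:]
    zero_tot = tot == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(zero_tot, 0.0, wh / np.where(zero_tot, 1.0, tot))
        cfrac = np.where(zero_tot, 0.0, cw / np.where(zero_tot, 1.0, tot))
    if zero_tot.any():  # all-zero statistics in the drawn set: equal weights
        k_over_s = np.arange(1, s + 1) / s
        cfrac = np.where(zero_tot, k_over_s[None, :], cfrac)
        frac = np.where(zero_tot, 1.0 / s, frac)
    k = np.arange(1, s + 1)
    miss = (positions + 1 - k) / (n - s)
    after = cfrac - miss
    before = after - frac
    maxes = np.maximum(after.max(axis=1), 0.0)
    mins = np.minimum(before.min(axis=1), 0.0)
    return np.clip(np.where(maxes >= -mins - 1e-12, maxes, mins), -1.0, 1.0)


def sample_null_es(
    ranked: RankedList,
    set_size: int,
    nperm: int,
    seed,
    exponent: float = 1.0,
) -> np.ndarray:
    """ES of ``nperm`` uniformly drawn size-``set_size`` gene sets.

    Reproducible under ``seed`` (an int or a numpy Generator); the same
    sample is intended to be shared by all same-size pathways within a run.
    """
    n = len(ranked)
    if not 0 < set_size < n:
        raise ValueError(f"set_size must be in (0, {n}); got {set_size}")
    if nperm < 100:
        warnings.warn(f"nperm={nperm} is very low; p-values will be unstable", stacklevel=2)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    w = np.abs(ranked.stats) ** exponent
    out = np.empty(nperm)
    for start in range(0, nperm, _CHUNK_ROWS):
        m = min(_CHUNK_ROWS, nperm - start)
        keys = rng.random((m, n))
        positions = np.argpartition(keys, set_size - 1, axis=1)[:, :set_size]
        positions.sort(axis=1)
        out[start:start + m] = _null_es_from_positions(w, positions, n)
    return out


def nes_and_pvalue(es: float, null_sample: np.ndarray) -> tuple[float, float]:
    """Normalize ES by the mean same-sign null magnitude; add-one p-value.

    If the null sample contains no value of the ES's sign, falls back to the
    magnitude of the whole null sample (one-sided fallback) with a warning.
    """
    null = np.asarray(null_sample, dtype=float)
    if es == 0.0:
        return 0.0, 1.0
    same = null[null > 0] if es > 0 else null[null < 0]
    if same.size == 0:
        warnings.warn(
            "null sample has no ES of the observed sign; using |null| as fallback",
            stacklevel=2,
        )
        same = null
    mean_mag = float(np.mean(np.abs(same)))
    nes = es / mean_mag if mean_mag > 0 else 0.0
    pval = (1.0 + int(np.sum(np.abs(same) >= abs(es)))) / (1.0 + same.size)
    return float(nes), float(pval)


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def _log2err(pval: float, nperm: int) -> float:
    """Monte-Carlo standard error of log2(p-hat) from the permutation count.

    Not comparable to split-sampling error estimates from other tools; NA
    (nan) when the p-value is at the resolution floor.
    """
    if pval * nperm < 1.5:  # p at the add-one floor: SE formula degenerates
        return float("nan")
    se_p = np.sqrt(pval * (1.0 - pval) / nperm)
    return float(se_p / (pval * np.log(2.0)))


def run_enrichment(
    ranked: RankedList,
    collection: GeneSetCollection,
    min_size: int = 3,
    max_size: int = 500,
    nperm: int = 1000,
    nperm_max: int = 1_000_000,
    seed: int = 0,
    alpha: float = 0.15,
    exponent: float = 1.0,
) -> pd.DataFrame:
    """Test every gene set in ``collection`` against ``ranked``.

    Null ES draws are shared across same-size pathways; pathways whose
    p-value hits the resolution limit (pval < 10/nperm) are re-evaluated at
    10x the permutations, up to ``nperm_max``, so small p-values are
    resolved without paying the maximal cost everywhere. Returns the
    per-pathway table (pathway, pval, padj, log2err, ES, NES, size,
    leadingEdge, plus significance at ``alpha`` and permutations used).
    """
    universe = set(ranked.genes)
    tested: list[tuple[str, ESResult, int]] = []
    sizes_seen: list[int] = []
    for gs in collection:
        size = len(gs.genes & universe)
        sizes_seen.append(size)
        if size < min_size or size > max_size or size == 0 or size == len(ranked):
            continue
        tested.append((gs.name, enrichment_score(ranked, gs, exponent=exponent), size))
    if not tested:
        dist = pd.Series(sizes_seen).describe().to_dict() if sizes_seen else {}
        raise ValueError(
            f"no pathway passed the size filter [{min_size}, {max_size}]; "
            f"intersection-size distribution: {dist}"
        )

    results: dict[str, dict] = {}
    active = list(range(len(tested)))
    level = int(nperm)
    level_idx = 0
    while active:
        null_cache: dict[int, np.ndarray] = {}
        for i in active:
            name, esr, size = tested[i]
            if size not in null_cache:
                rng = np.random.default_rng([int(seed), size, level_idx])
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    null_cache[size] = sample_null_es(
                        ranked, size, level, rng, exponent=exponent
                    )
            nes, pval = nes_and_pvalue(esr.es, null_cache[size])
            results[name] = {
                "pathway": name,
                "pval": pval,
                "log2err": _log2err(pval, level),
                "ES": esr.es,
                "NES": nes,
                "size": size,
                "leadingEdge": esr.leading_edge,
                "nperm": level,
            }
        next_level = level * 10
        if next_level > nperm_max:
            break
        active = [
            i for i in active
            if results[tested[i][0]]["pval"] < 10.0 / results[tested[i][0]]["nperm"]
        ]
        level = next_level
        level_idx += 1

    table = pd.DataFrame([results[name] for name, _, _ in tested])
    table["padj"] = bh_adjust(table["pval"].to_numpy())
    table["significant"] = table["padj"] < alpha
    cols = ["pathway", "pval", "padj", "log2err", "ES", "NES", "size",
            "leadingEdge", "significant", "nperm"]
    return table[cols]
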