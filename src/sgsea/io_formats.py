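"""Readers and writers for the delimited formats the pipeline touches.

Counts matrices, per-sample survival metadata, GMT gene-set collections,
ranked-list exports (CSV / RNK) and enrichment result tables. All readers
accept comma- or tab-delimited text; gene and sample identifiers are treated
as opaque, case-sensitive strings (renaming only ever happens through an
explicit :class:`IdMap`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ENRICHMENT_COLUMNS = ["pathway", "pval", "padj", "log2err", "ES", "NES", "size", "leadingEdge"]
LEADING_EDGE_SEP = ";"

_STATUS_RECODE = {
    "0": 0, "1": 1,
    "false": 0, "true": 1,
    "alive": 0, "dead": 1,
}


class FormatError(ValueError):
    """A file violated the structural contract of its format."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class CountsTable:
    """Gene x sample matrix of non-negative read counts.

    ``counts`` is a DataFrame with gene identifiers as the index and sample
    identifiers as the columns, regardless of the orientation of the file it
    was read from.
    """

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.counts
        _check_unique(df.index, "gene")
        _check_unique(df.columns, "sample")
        if df.shape[1] < 2:
            raise FormatError("a counts table needs at least 2 samples")
        values = df.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise FormatError("counts matrix contains non-numeric entries")
        bad = ~np.isfinite(values) | (values < 0)
        if bad.any():
            g, s = np.argwhere(bad)[0]
            raise FormatError(
                f"negative or non-finite count at gene {df.index[g]!r}, sample {df.columns[s]!r}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]


@dataclass
class SurvivalTable:
    """Per-sample censored survival outcome with optional numeric covariates.

    ``data`` is indexed by sample id and holds ``time`` (positive, one unit
    throughout), ``status`` (1 = event, 0 = censored) and any covariate
    columns. ``n_removed`` records how many input rows were dropped for
    invalid time or missing status.
    """

    data: pd.DataFrame
    covariate_names: tuple[str, ...] = ()
    n_removed: int = 0

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "sample")
        for col in ("time", "status"):
            if col not in self.data.columns:
                raise FormatError(f"survival table lacks required column {col!r}")
        time = self.data["time"].to_numpy(dtype=float)
        if not np.all(np.isfinite(time) & (time > 0)):
            raise FormatError("survival times must be finite and > 0")
        status = self.data["status"].to_numpy()
        if not np.isin(status, (0, 1)).all():
            raise FormatError("status must be coded 0 (censored) / 1 (event)")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def time(self) -> np.ndarray:
        return self.data["time"].to_numpy(dtype=float)

    @property
    def status(self) -> np.ndarray:
        return self.data["status"].to_numpy(dtype=int)

    def covariates(self, names: tuple[str, ...] | list[str] | None = None) -> pd.DataFrame:
        names = tuple(names) if names is not None else self.covariate_names
        missing = [n for n in names if n not in self.data.columns]
        if missing:
            raise KeyError(f"covariate columns not present: {missing}")
        return self.data[list(names)].astype(float)


@dataclass(frozen=True)
class GeneSet:
    name: str
    description: str
    genes: frozenset[str]


@dataclass
class GeneSetCollection:
    """Named gene sets with GMT semantics (membership is a set)."""

    sets: dict[str, GeneSet] = field(default_factory=dict)

    def __iter__(self):
        return iter(self.sets.values())

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> GeneSet:
        return self.sets[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def add(self, name: str, genes, description: str = "") -> None:
        if name in self.sets:
            raise FormatError(f"duplicate gene set name {name!r}")
        genes = frozenset(map(str, genes))
        if not genes:
            raise FormatError(f"gene set {name!r} has no members")
        self.sets[name] = GeneSet(name, description, genes)

    @property
    def names(self) -> list[str]:
        return list(self.sets)


@dataclass
class IdMap:
    """One-way gene identifier mapping (e.g., Entrez -> HUGO symbol)."""

    mapping: dict[str, str]

    def apply(self, counts: CountsTable) -> tuple[CountsTable, int]:
        """Rename gene ids; unmapped genes are dropped and counted."""
        keep = [g for g in counts.gene_ids if g in self.mapping]
        n_dropped = counts.n_genes - len(keep)
        if n_dropped:
            logger.info("id mapping dropped %d unmapped genes", n_dropped)
        df = counts.counts.loc[keep].rename(index=self.mapping)
        if df.index.duplicated().any():
            dups = sorted(set(df.index[df.index.duplicated()]))
            raise FormatError(f"id mapping produced duplicate gene ids: {dups[:10]}")
        return CountsTable(df), n_dropped


def _check_unique(index, what: str) -> None:
    if index.duplicated().any():
        dups = sorted(set(index[index.duplicated()]))
        raise FormatError(f"duplicate {what} identifiers: {dups[:10]}")


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------

def _read_delimited(path, delimiter: str | None) -> pd.DataFrame:
    sep = delimiter if delimiter is not None else None  # None -> sniff , / tab
    return pd.read_csv(path, sep=sep, index_col=0, engine="python")


def read_counts(
    path,
    orientation: str = "auto",
    delimiter: str | None = None,
    sample_ids=None,
) -> CountsTable:
    """Read a counts matrix and return it in canonical gene x sample form.

    Parameters
    ----------
    orientation
        ``"genes_in_rows"``, ``"samples_in_rows"`` or ``"auto"``. Auto
        detection prefers the axis whose labels overlap ``sample_ids`` (take
        them from the survival table); an overlap tie is an error asking for
        an explicit orientation — silent transposition is the classic failure
        mode for this format.
    """
    df = _read_delimited(path, delimiter)
    raw = df.apply(pd.to_numeric, errors="coerce")
    bad = raw.isna() & df.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise FormatError(
            f"non-numeric count at row {df.index[r]!r}, column {df.columns[c]!r}"
        )
    if raw.isna().to_numpy().any():
        r, c = np.argwhere(raw.isna().to_numpy())[0]
        raise FormatError(f"missing count at row {df.index[r]!r}, column {df.columns[c]!r}")

    if orientation == "auto":
        if sample_ids is None:
            raise ValueError("orientation='auto' needs the survival table's sample_ids")
        ids = set(map(str, sample_ids))
        rows = len(ids.intersection(map(str, raw.index)))
        cols = len(ids.intersection(map(str, raw.columns)))
        if rows == cols:
            raise FormatError(
                "cannot auto-detect orientation: sample-id overlap is "
                f"{rows} on rows and {cols} on columns; pass orientation explicitly"
            )
        orientation = "samples_in_rows" if rows > cols else "genes_in_rows"
        logger.info("auto-detected orientation: %s", orientation)
    if orientation == "samples_in_rows":
        raw = raw.T
    elif orientation != "genes_in_rows":
        raise ValueError(f"unknown orientation {orientation!r}")
    raw.index = raw.index.map(str)
    raw.columns = raw.columns.map(str)
    return CountsTable(raw)


def write_counts(counts: CountsTable, path, delimiter: str = ",") -> None:
    counts.counts.to_csv(path, sep=delimiter)


# ---------------------------------------------------------------------------
# survival
# ---------------------------------------------------------------------------

def _recode_status(values: pd.Series) -> np.ndarray:
    out = np.empty(len(values), dtype=float)
    for i, v in enumerate(values):
        if pd.isna(v):
            out[i] = np.nan
            continue
        if isinstance(v, (bool, np.bool_)):
            out[i] = int(v)
            continue
        key = str(v).strip().lower()
        if key.endswith(".0"):
            key = key[:-2]
        if key in _STATUS_RECODE:
            out[i] = _STATUS_RECODE[key]
        else:
            raise FormatError(
                f"unrecognized survival status {v!r}; accepted codings are 0/1, "
                "TRUE/FALSE and alive/dead"
            )
    return out


def read_survival(
    path,
    time_col: str = "time",
    status_col: str = "status",
    covariate_cols=(),
    delimiter: str | None = None,
) -> SurvivalTable:
    """Read per-sample survival metadata, dropping invalid rows.

    Rows with time <= 0 (invalid data input), missing time or missing status
    are removed and counted; a status value outside the accepted codings is
    an error rather than a removal.
    """
    df = _read_delimited(path, delimiter)
    for col in (time_col, status_col, *covariate_cols):
        if col not in df.columns:
            raise FormatError(f"survival file lacks column {col!r}")
    time = pd.to_numeric(df[time_col], errors="coerce")
    status = _recode_status(df[status_col])
    keep = time.notna().to_numpy() & (time.to_numpy(dtype=float) > 0) & ~np.isnan(status)
    n_removed = int((~keep).sum())
    if n_removed:
        logger.info("removed %d samples with invalid time or missing status", n_removed)
    out = pd.DataFrame(
        {"time": time.to_numpy(dtype=float)[keep], "status": status[keep].astype(int)},
        index=df.index[keep].map(str),
    )
    for col in covariate_cols:
        vals = pd.to_numeric(df[col], errors="coerce").to_numpy(dtype=float)[keep]
        if np.isnan(vals).any():
            raise FormatError(f"covariate column {col!r} has missing/non-numeric entries")
        out[col] = vals
    return SurvivalTable(out, covariate_names=tuple(covariate_cols), n_removed=n_removed)


def write_survival(surv: SurvivalTable, path, delimiter: str = ",") -> None:
    surv.data.to_csv(path, sep=delimiter, index_label="sample")


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------

def read_gmt(path) -> GeneSetCollection:
    """Parse a GMT file: name <tab> description <tab> member genes."""
    collection = GeneSetCollection()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}: line {lineno} has fewer than 3 tab-separated fields")
            name, description, *genes = fields
            genes = [g for g in genes if g]
            if not genes:
                raise FormatError(f"{path}: line {lineno}: gene set {name!r} has no members")
            collection.add(name, genes, description)
    return collection


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for gs in collection:
            members = "\t".join(sorted(gs.genes))
            fh.write(f"{gs.name}\t{gs.description}\t{members}\n")


# ---------------------------------------------------------------------------
# id map
# ---------------------------------------------------------------------------

def read_id_map(path, delimiter: str | None = "\t") -> IdMap:
    """Two-column from_id -> to_id table (TSV by default, header optional)."""
    df = pd.read_csv(path, sep=delimiter, header=None, dtype=str, engine="python")
    if df.shape[1] < 2:
        raise FormatError("id map needs two columns: from_id, to_id")
    # tolerate a header line such as "entrez\tsymbol"
    mapping = dict(zip(df.iloc[:, 0], df.iloc[:, 1]))
    return IdMap(mapping)


# ---------------------------------------------------------------------------
# ranked lists
# ---------------------------------------------------------------------------

def write_ranked_list(ranked, path, dialect: str = "csv") -> None:
    """Export a ranked gene list, CSV (header) or RNK (tab, no header)."""
    if len(ranked.genes) == 0:
        raise ValueError("refusing to write an empty ranked list")
    df = pd.DataFrame({"gene": ranked.genes, "statistic": np.asarray(ranked.stats, dtype=float)})
    if dialect == "csv":
        df.to_csv(path, index=False, float_format="%.12g")
    elif dialect == "rnk":
        df.to_csv(path, sep="\t", index=False, header=False, float_format="%.12g")
    else:
        raise ValueError(f"unknown ranked-list dialect {dialect!r}")


def read_ranked_list(path, dialect: str = "auto", mode: str = "preranked"):
    """Read a ranked list written by :func:`write_ranked_list` (or externally)."""
    from .cox_rank import RankedList  # local import to avoid a cycle

    path = Path(path)
    if dialect == "auto":
        dialect = "rnk" if path.suffix.lower() == ".rnk" else "csv"
    if dialect == "csv":
        df = pd.read_csv(path)
        genes, stats = df.iloc[:, 0], df.iloc[:, 1]
    elif dialect == "rnk":
        df = pd.read_csv(path, sep="\t", header=None)
        genes, stats = df.iloc[:, 0], df.iloc[:, 1]
    else:
        raise ValueError(f"unknown ranked-list dialect {dialect!r}")
    return RankedList(genes=list(map(str, genes)), stats=stats.to_numpy(dtype=float), mode=mode)


# ---------------------------------------------------------------------------
# enrichment tables
# ---------------------------------------------------------------------------

def write_enrichment_table(results: pd.DataFrame, path) -> None:
    """Write the per-pathway enrichment table.

    Columns, in order: pathway, pval, padj, log2err, ES, NES, size,
    leadingEdge — with the leading edge serialized as a single
    ``;``-delimited cell.
    """
    out = results.copy()
    for col in ENRICHMENT_COLUMNS:
        if col not in out.columns:
            raise ValueError(f"enrichment table lacks column {col!r}")
    out["leadingEdge"] = [
        LEADING_EDGE_SEP.join(le) if isinstance(le, (list, tuple)) else str(le)
        for le in out["leadingEdge"]
    ]
    out[ENRICHMENT_COLUMNS].to_csv(path, index=False, float_format="%.12g")


def read_enrichment_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in ENRICHMENT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"enrichment table lacks columns {missing}")
    df["leadingEdge"] = [
        [] if pd.isna(le) or le == "" else str(le).split(LEADING_EDGE_SEP)
        for le in df["leadingEdge"]
    ]
    return df


# ---------------------------------------------------------------------------
# alignment
# ---------------------------------------------------------------------------

def align_counts_survival(
    counts: CountsTable, surv: SurvivalTable
) -> tuple[CountsTable, SurvivalTable]:
    """Intersect and co-order samples between a counts and a survival table.

    Samples are placed in sorted order so the result is independent of the
    input row order of either file.
    """
    shared = sorted(set(counts.sample_ids) & set(surv.sample_ids))
    n_c, n_s = counts.n_samples, len(surv.sample_ids)
    if len(shared) < 2:
        raise ValueError(
            f"counts and survival share only {len(shared)} sample ids "
            f"({n_c} in counts, {n_s} in survival)"
        )
    dropped = (n_c - len(shared)) + (n_s - len(shared))
    if dropped:
        logger.info(
            "sample intersection kept %d samples (dropped %d counts-only, %d survival-only)",
            len(shared), n_c - len(shared), n_s - len(shared),
        )
    counts2 = CountsTable(counts.counts[shared])
    surv2 = SurvivalTable(
        surv.data.loc[shared], covariate_names=surv.covariate_names, n_removed=surv.n_removed
    )
    return counts2, surv2
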