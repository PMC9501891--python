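"""Expression-matrix container, cohort annotation and housekeeping normalization.

Targeted expression panels (NanoString nCounter and similar) report
nonnegative transcript counts for a few hundred genes, a subset of which are
housekeeping genes assumed stable across samples.  Normalization follows the
instrument's documented convention: each sample is rescaled so that the
geometric mean of its housekeeping counts equals the cohort average, then
values are log2-transformed with a pseudocount.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import AnnotationError, FormatError, MissingGeneError

RESPONDER = "responder"
NON_RESPONDER = "non_responder"

__all__ = [
    "ExpressionMatrix",
    "NormalizedMatrix",
    "CohortAnnotation",
    "read_expression_matrix",
    "read_housekeeping_list",
    "read_cohort_annotation",
    "geometric_mean",
    "housekeeping_normalize",
]


@dataclass
class ExpressionMatrix:
    """Gene x sample nonnegative counts with a housekeeping-gene subset.

    Parameters
    ----------
    counts
        DataFrame indexed by gene symbol with one column per sample.
    housekeeping
        Genes used to derive per-sample normalization factors; must be a
        subset of the index.
    """

    counts: pd.DataFrame
    housekeeping: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        idx = pd.Index([str(g).strip() for g in self.counts.index], name="gene")
        cols = pd.Index([str(s).strip() for s in self.counts.columns])
        if idx.duplicated().any():
            dup = idx[idx.duplicated()].unique().tolist()
            raise FormatError(f"duplicate gene identifiers: {dup}")
        if cols.duplicated().any():
            dup = cols[cols.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample identifiers: {dup}")
        values = self.counts.to_numpy(dtype=float)
        if not np.isfinite(values).all():
            raise ValueError("counts must be finite")
        if (values < 0).any():
            raise ValueError("counts must be nonnegative")
        self.counts = pd.DataFrame(values, index=idx, columns=cols)
        self.housekeeping = [str(g).strip() for g in self.housekeeping]
        missing = set(self.housekeeping) - set(idx)
        if missing:
            raise MissingGeneError(missing, "housekeeping genes absent from matrix")

    @property
    def gene_ids(self) -> list[str]:
        return self.counts.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.counts.columns.tolist()

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def to_tsv(self, path, housekeeping_path=None) -> None:
        out = self.counts.copy()
        out.index.name = "gene"
        out.to_csv(path, sep="\t")
        if housekeeping_path is not None:
            with open(housekeeping_path, "w") as fh:
                for g in self.housekeeping:
                    fh.write(g + "\n")


@dataclass
class NormalizedMatrix:
    """log2-scale expression after housekeeping normalization."""

    values: pd.DataFrame
    scale_factors: pd.Series
    pseudocount: float
    housekeeping: list[str] = field(default_factory=list)

    @property
    def gene_ids(self) -> list[str]:
        return self.values.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.values.columns.tolist()

    def to_tsv(self, path) -> None:
        out = self.values.copy()
        out.index.name = "gene"
        out.to_csv(path, sep="\t", float_format="%.10g")


_VALID_RESPONSES = {RESPONDER, NON_RESPONDER}


@dataclass
class CohortAnnotation:
    """Per-sample response label and right-censored progression-free survival.

    Responders are patients with any tumor regression from baseline
    (best_change_pct < 0); a best change of exactly 0 is treated as
    non-responder.  ``event`` is 1 when progression was observed, 0 when the
    PFS time is censored.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table.copy()
        if "sample_id" in t.columns:
            t = t.set_index("sample_id")
        t.index = pd.Index([str(s).strip() for s in t.index], name="sample_id")
        if t.index.duplicated().any():
            raise FormatError("duplicate sample identifiers in annotation")
        has_resp = "response" in t.columns and t["response"].notna().any()
        has_change = "best_change_pct" in t.columns and t["best_change_pct"].notna().any()
        if not has_resp and not has_change:
            raise AnnotationError("need response or best_change_pct")
        if "best_change_pct" not in t.columns:
            t["best_change_pct"] = np.nan
        t["best_change_pct"] = pd.to_numeric(t["best_change_pct"], errors="coerce")
        if "response" not in t.columns:
            t["response"] = None
        derived = np.where(t["best_change_pct"] < 0, RESPONDER, NON_RESPONDER)
        resp = t["response"].where(t["response"].notna(), pd.Series(derived, index=t.index))
        resp = resp.where(t["best_change_pct"].notna() | t["response"].notna())
        if resp.isna().any():
            bad = t.index[resp.isna()].tolist()
            raise AnnotationError(f"samples without response or best_change_pct: {bad}")
        bad = set(resp) - _VALID_RESPONSES
        if bad:
            raise ValueError(f"invalid response labels: {sorted(bad)}")
        # explicit labels must agree with the RECIST-style best change
        both = t["response"].notna() & t["best_change_pct"].notna()
        neg = both & (t["best_change_pct"] < 0) & (t["response"] != RESPONDER)
        pos = both & (t["best_change_pct"] > 0) & (t["response"] != NON_RESPONDER)
        if neg.any() or pos.any():
            bad = t.index[neg | pos].tolist()
            raise AnnotationError(f"response inconsistent with best_change_pct: {bad}")
        t["response"] = resp
        if "pfs_months" in t.columns:
            t["pfs_months"] = pd.to_numeric(t["pfs_months"])
            if (t["pfs_months"].dropna() < 0).any():
                raise ValueError("pfs_months must be nonnegative")
        if "event" in t.columns:
            ev = t["event"].dropna()
            if not set(pd.to_numeric(ev)).issubset({0, 1}):
                raise ValueError("event must be 0 or 1")
            t["event"] = pd.to_numeric(t["event"]).astype("Int64")
        self.table = t

    @property
    def sample_ids(self) -> list[str]:
        return self.table.index.tolist()

    @property
    def response(self) -> pd.Series:
        return self.table["response"]

    def responders(self) -> list[str]:
        return self.table.index[self.table["response"] == RESPONDER].tolist()

    def non_responders(self) -> list[str]:
        return self.table.index[self.table["response"] == NON_RESPONDER].tolist()

    def survival_arrays(self, samples: Sequence[str] | None = None):
        t = self.table if samples is None else self.table.loc[list(samples)]
        return (
            t["pfs_months"].to_numpy(dtype=float),
            t["event"].to_numpy(dtype=int),
        )

    def subset(self, samples: Sequence[str]) -> "CohortAnnotation":
        return CohortAnnotation(self.table.loc[list(samples)].reset_index())

    def to_csv(self, path) -> None:
        self.table.reset_index().to_csv(path, index=False)


def read_housekeeping_list(path) -> list[str]:
    """Read a one-gene-per-line housekeeping list (blank lines ignored)."""
    with open(path) as fh:
        genes = [line.strip() for line in fh if line.strip()]
    return genes


def read_expression_matrix(path, housekeeping_path=None) -> ExpressionMatrix:
    """Read a gene x sample count TSV (first column ``gene``).

    Duplicate gene or sample identifiers raise :class:`FormatError`;
    housekeeping genes absent from the matrix raise
    :class:`MissingGeneError`.  Input gene order is preserved.
    """
    with open(path) as fh:
        header = next(csv.reader(fh, delimiter="\t"))
    samples = [c.strip() for c in header[1:]]
    if len(set(samples)) != len(samples):
        raise FormatError("duplicate sample identifiers in header")
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.columns = samples
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise FormatError(f"non-numeric expression values: {exc}") from exc
    hk = read_housekeeping_list(housekeeping_path) if housekeeping_path else []
    return ExpressionMatrix(df, housekeeping=hk)


def read_cohort_annotation(path) -> CohortAnnotation:
    """Read the cohort annotation CSV (sample_id, response, best_change_pct,
    pfs_months, event)."""
    df = pd.read_csv(path)
    if "sample_id" not in df.columns:
        raise FormatError("annotation CSV must have a sample_id column")
    return CohortAnnotation(df)


def geometric_mean(values: Iterable[float]) -> float:
    """exp(mean(log(values))) for strictly positive values."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("geometric mean of empty sequence")
    if (arr <= 0).any() or not np.isfinite(arr).all():
        raise ValueError("geometric mean requires strictly positive values")
    return float(np.exp(np.mean(np.log(arr))))


def housekeeping_normalize(m: ExpressionMatrix, pseudocount: float = 1.0) -> NormalizedMatrix:
    """Scale each sample so housekeeping geometric means match the cohort
    average, then log2-transform.

    Per sample j, ``g_j = geomean(housekeeping counts + pseudocount)`` and
    ``scale_j = mean_j(g_j) / g_j``; normalized values are
    ``log2(scale_j * (count + pseudocount))``.  After scaling (before log2)
    the housekeeping geometric mean is identical across samples.
    """
    if not m.housekeeping:
        raise MissingGeneError([], "housekeeping list is empty")
    if not pseudocount > 0:
        raise ValueError("pseudocount must be positive")
    hk = m.counts.loc[m.housekeeping].to_numpy(dtype=float) + pseudocount
    g = np.exp(np.mean(np.log(hk), axis=0))
    scale = g.mean() / g
    shifted = m.counts.to_numpy(dtype=float) + pseudocount
    values = np.log2(shifted * scale[np.newaxis, :])
    return NormalizedMatrix(
        values=pd.DataFrame(values, index=m.counts.index, columns=m.counts.columns),
        scale_factors=pd.Series(scale, index=m.counts.columns, name="scale_factor"),
        pseudocount=float(pseudocount),
        housekeeping=list(m.housekeeping),
    )
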