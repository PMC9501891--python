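"""Core-gene signature derivation, scoring and stratification.

The signature is built from the top enriched pathways: a core gene is one
appearing in at least ``min_pathways`` (default 2) of the top-k pathways'
gene lists — by default their leading edges, i.e. the genes actually driving
enrichment.  The per-sample signature score is the arithmetic mean of the
core genes' log2 expression, and cohorts are dichotomized at the median
score (strictly above -> high).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .errors import (
    DichotomizationError,
    EmptySignatureError,
    MissingGeneError,
    SelectionError,
)
from .gsea import EnrichmentResult
from .matrix import NormalizedMatrix

__all__ = [
    "SignatureModel",
    "ScoreVector",
    "select_top_pathways",
    "derive_core_genes",
    "signature_score",
    "score_samples",
    "dichotomize",
    "load_reference_signature",
    "read_signature",
]


@dataclass
class SignatureModel:
    """An ordered core-gene list with pathway provenance.

    ``provenance`` maps each core gene to the set of contributing top
    pathways; it may be empty for externally supplied (file-loaded)
    signatures whose derivation is not on record.
    """

    core_genes: list[str]
    provenance: dict[str, set[str]] = field(default_factory=dict)
    top_pathways: list[tuple[str, float]] = field(default_factory=list)
    score_basis: str = "leading_edge"

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for g in self.core_genes:
                prov = ";".join(sorted(self.provenance.get(g, ())))
                fh.write(f"{g}\t{prov}\n" if prov else f"{g}\n")


@dataclass
class ScoreVector:
    """Per-sample signature scores with a high/low split."""

    scores: pd.Series
    cutoff: float
    strata: pd.Series  # "high" / "low" per sample

    def high_samples(self) -> list[str]:
        return self.strata.index[self.strata == "high"].tolist()

    def low_samples(self) -> list[str]:
        return self.strata.index[self.strata == "low"].tolist()

    def to_csv(self, path) -> None:
        out = pd.DataFrame({"score": self.scores, "stratum": self.strata})
        out.index.name = "sample_id"
        out.to_csv(path)


def select_top_pathways(results: list[EnrichmentResult], k: int) -> list[str]:
    """The k pathways with smallest nominal p (ties: larger |NES|, then name)."""
    if len(results) < k:
        raise SelectionError(f"need >= {k} enrichment results, got {len(results)}")

    def key(r: EnrichmentResult):
        a = abs(r.nes) if np.isfinite(r.nes) else 0.0
        return (r.p, -a, r.name)

    return [r.name for r in sorted(results, key=key)[:k]]


def derive_core_genes(
    top_results: list[EnrichmentResult],
    basis: str = "leading_edge",
    min_pathways: int = 2,
) -> SignatureModel:
    """Core genes = genes in >= ``min_pathways`` of the top pathways' lists.

    ``basis`` chooses the pathway gene lists: ``leading_edge`` (default,
    the genes driving each pathway's enrichment) or ``full_set`` (all
    panel members).  Ordering is deterministic: contributing-pathway count
    descending, then gene id.  Raises :class:`EmptySignatureError` when no
    gene repeats — callers may retry with ``full_set``.
    """
    if min_pathways < 2:
        raise ValueError("min_pathways must be >= 2")
    if basis not in {"leading_edge", "full_set"}:
        raise ValueError(f"unknown basis {basis!r}")
    provenance: dict[str, set[str]] = {}
    for r in sorted(top_results, key=lambda r: r.name):
        genes = r.leading_edge if basis == "leading_edge" else r.members
        for g in genes:
            provenance.setdefault(g, set()).add(r.name)
    core = {g: s for g, s in provenance.items() if len(s) >= min_pathways}
    if not core:
        raise EmptySignatureError(
            f"no gene appears in >= {min_pathways} of the top pathways "
            f"(basis={basis})"
        )
    ordered = sorted(core, key=lambda g: (-len(core[g]), g))
    return SignatureModel(
        core_genes=ordered,
        provenance=core,
        top_pathways=[(r.name, r.p) for r in top_results],
        score_basis=basis,
    )


def signature_score(values: NormalizedMatrix, model: SignatureModel, sample: str) -> float:
    """Mean log2 expression of the core genes for one sample.

    A missing core gene is an error — the signature is fixed, never
    silently reduced.
    """
    missing = set(model.core_genes) - set(values.values.index)
    if missing:
        raise MissingGeneError(missing, "signature genes absent from matrix")
    return float(values.values.loc[model.core_genes, sample].mean())


def score_samples(values: NormalizedMatrix, model: SignatureModel) -> pd.Series:
    """Signature score for every sample in the matrix."""
    missing = set(model.core_genes) - set(values.values.index)
    if missing:
        raise MissingGeneError(missing, "signature genes absent from matrix")
    s = values.values.loc[model.core_genes].mean(axis=0)
    s.name = "score"
    return s


def dichotomize(scores: pd.Series, method: str = "median", cutoff: float | None = None) -> ScoreVector:
    """Split samples into high (> cutoff) and low (<= cutoff) strata.

    ``median`` uses the cohort median; ``fixed`` uses the supplied cutoff
    (which must lie inside the observed score range).  Both strata must be
    nonempty.
    """
    s = scores.astype(float)
    if s.size < 2:
        raise DichotomizationError("need >= 2 samples to dichotomize")
    if s.nunique() == 1:
        raise DichotomizationError("all scores identical")
    if method == "median":
        cut = float(s.median())
    elif method == "fixed":
        if cutoff is None:
            raise ValueError("fixed method requires a cutoff")
        if not (s.min() <= cutoff <= s.max()):
            raise DichotomizationError("fixed cutoff outside the observed score range")
        cut = float(cutoff)
    else:
        raise ValueError(f"unknown method {method!r}")
    strata = pd.Series(np.where(s > cut, "high", "low"), index=s.index, name="stratum")
    if (strata == "high").sum() == 0 or (strata == "low").sum() == 0:
        raise DichotomizationError("dichotomization produced an empty stratum")
    return ScoreVector(scores=s, cutoff=cut, strata=strata)


def read_signature(path) -> SignatureModel:
    """Read a gene<TAB>provenance signature TSV (provenance optional)."""
    genes: list[str] = []
    provenance: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            g = parts[0].strip()
            genes.append(g)
            if len(parts) > 1 and parts[1].strip():
                provenance[g] = set(parts[1].split(";"))
    if not genes:
        raise EmptySignatureError("signature file lists no genes")
    return SignatureModel(core_genes=genes, provenance=provenance)


def load_reference_signature() -> SignatureModel:
    """The frozen six-gene immune-related signature
    (PSMB10, PSMB9, LAG3, CCL5, IFI35, SH2D1A) for scoring new cohorts."""
    ref = resources.files("immunosig.data").joinpath("sixgene_signature.tsv")
    with resources.as_file(ref) as path:
        return read_signature(path)
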