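"""Marker-gene immune cell-type scores and responder comparison.

Each cell type's score for a sample is the arithmetic mean of the log2
expression of its marker genes present on the panel (absent markers are
dropped with a warning).  Scores are compared between responders and
non-responders with the two-sided Wilcoxon rank-sum test at raw p < 0.05
(no multiple-testing correction across cell types, matching common
targeted-panel practice for a dozen predefined cell types).
"""

from __future__ import annotations

import logging
from importlib import resources

import pandas as pd

from .errors import AnnotationError, FormatError, MissingGeneError
from .matrix import RESPONDER, CohortAnnotation, NormalizedMatrix
from .stats import wilcoxon_rank_sum

logger = logging.getLogger(__name__)

__all__ = [
    "read_markers",
    "default_markers",
    "cell_type_score",
    "score_cell_types",
    "compare_cell_scores",
]


def read_markers(path) -> dict[str, list[str]]:
    """Read a cell_type<TAB>gene marker table into {cell_type: [genes]}."""
    markers: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(f"expected cell_type<TAB>gene, got {line!r}")
            markers.setdefault(parts[0], []).append(parts[1])
    for name, genes in markers.items():
        if not genes:
            raise FormatError(f"cell type {name!r} has no markers")
    return markers


def default_markers() -> dict[str, list[str]]:
    """The packaged 12-cell-type marker list (replaceable via ``read_markers``).

    Marker genes follow the established tumor-immune marker-gene convention
    for targeted expression panels; edit or supply your own TSV to match a
    specific panel's annotation.
    """
    ref = resources.files("immunosig.data").joinpath("default_markers.tsv")
    with resources.as_file(ref) as path:
        return read_markers(path)


def cell_type_score(values: NormalizedMatrix, markers, sample: str) -> float:
    """Arithmetic mean of a sample's log2 values over the present markers."""
    present = [g for g in markers if g in values.values.index]
    absent = [g for g in markers if g not in values.values.index]
    if absent:
        logger.warning("markers absent from panel, dropped: %s", ", ".join(absent))
    if not present:
        raise MissingGeneError(markers, "no marker present in matrix")
    return float(values.values.loc[present, sample].mean())


def score_cell_types(values: NormalizedMatrix, markers: dict[str, list[str]]) -> pd.DataFrame:
    """Cell type x sample score matrix (mean log2 of present markers).

    Cell types with no marker on the panel are skipped with a warning; an
    entirely unscorable marker collection is an error.
    """
    panel = set(values.gene_ids)
    rows = {}
    for cell_type, genes in markers.items():
        present = [g for g in genes if g in panel]
        absent = [g for g in genes if g not in panel]
        if absent:
            logger.warning(
                "%s: markers absent from panel, dropped: %s",
                cell_type, ", ".join(absent),
            )
        if not present:
            logger.warning("%s: no marker on panel, cell type skipped", cell_type)
            continue
        rows[cell_type] = values.values.loc[present].mean(axis=0)
    if not rows:
        raise MissingGeneError(
            [g for genes in markers.values() for g in genes],
            "no cell type has any marker on the panel",
        )
    out = pd.DataFrame(rows).T
    out.index.name = "cell_type"
    return out


def compare_cell_scores(
    scores: pd.DataFrame,
    annotation: CohortAnnotation,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Wilcoxon rank-sum comparison of each cell type between phenotypes.

    Returns the score matrix augmented with W, two-sided p and a
    significance flag at raw p < ``alpha``.
    """
    samples = scores.columns.tolist()
    missing = set(samples) - set(annotation.sample_ids)
    if missing:
        raise AnnotationError(f"scored samples without annotation: {sorted(missing)}")
    resp = annotation.table.loc[samples, "response"]
    a_cols = [s for s in samples if resp[s] == RESPONDER]
    b_cols = [s for s in samples if resp[s] != RESPONDER]
    if not a_cols or not b_cols:
        raise AnnotationError("both responder and non-responder samples required")
    stats = []
    for cell_type in scores.index:
        w, p = wilcoxon_rank_sum(
            scores.loc[cell_type, a_cols], scores.loc[cell_type, b_cols]
        )
        stats.append((w, p, p < alpha))
    out = scores.copy()
    out[["W", "p", "significant"]] = pd.DataFrame(
        stats, index=scores.index, columns=["W", "p", "significant"]
    )
    return out
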