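"""Model/Results interface for signature discovery and validation.

:class:`SignatureDiscovery` is the fitted-model entry point: construct it
from an expression matrix, cohort annotation and gene-set collection, call
:meth:`~SignatureDiscovery.fit`, and receive a
:class:`SignatureDiscoveryResults` holding the normalized matrix, immune
cell-type scores, the enrichment table, the derived core-gene signature,
per-sample scores with the high/low split, and the high-vs-low survival
comparison.  :meth:`SignatureDiscoveryResults.apply` scores an independent
validation cohort with the frozen signature and reports its survival
split, responder discrimination (ROC/AUC with DeLong CI) and score
comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import immune, roc, signature as sig, survival as surv
from .errors import EmptySignatureError
from .gsea import (
    EnrichmentResult,
    GeneSetCollection,
    enrichment_table,
    read_gmt,
    run_gsea,
)
from .matrix import (
    NON_RESPONDER,
    RESPONDER,
    CohortAnnotation,
    ExpressionMatrix,
    NormalizedMatrix,
    housekeeping_normalize,
    read_cohort_annotation,
    read_expression_matrix,
)
from .stats import wilcoxon_rank_sum

__all__ = ["SignatureDiscovery", "SignatureDiscoveryResults", "SignatureValidationResults"]


@dataclass
class SignatureValidationResults:
    """Frozen-signature scoring of an independent cohort."""

    scores: sig.ScoreVector
    survival: surv.SurvivalComparison | None = None
    roc: roc.ROCResult | None = None
    score_test: tuple[float, float] | None = None  # Wilcoxon (W, p) resp vs non-resp

    def summary(self) -> str:
        lines = ["Signature validation", "=" * 44]
        lines.append(f"samples scored:        {self.scores.scores.size}")
        lines.append(f"score cutoff:          {self.scores.cutoff:.4g}")
        if self.score_test is not None:
            lines.append(
                f"responder vs non-responder score: Wilcoxon p = {self.score_test[1]:.4g}"
            )
        if self.roc is not None:
            ci = self.roc.ci or (np.nan, np.nan)
            lines.append(
                f"response AUC:          {self.roc.auc:.3f} "
                f"(95% CI {ci[0]:.3f}-{ci[1]:.3f})"
            )
        if self.survival is not None:
            s = self.survival
            lines.append(
                "median PFS high/low:   "
                f"{s.median_text('high')} / {s.median_text('low')} months"
            )
            lines.append(
                f"log-rank:              chi2 = {s.chi_square:.3f}, p = {s.p:.4g}"
            )
            if s.hr_note:
                lines.append(f"hazard ratio:          {s.hr_note}")
            else:
                lines.append(
                    f"HR (high vs low):      {s.hr:.3f} "
                    f"(95% CI {s.hr_ci[0]:.3f}-{s.hr_ci[1]:.3f})"
                )
        return "\n".join(lines)


@dataclass
class SignatureDiscoveryResults:
    """Everything the derivation cohort yields, plus apply() for new cohorts."""

    model: "SignatureDiscovery"
    normalized: NormalizedMatrix
    cell_scores: pd.DataFrame
    enrichment: list[EnrichmentResult]
    top_pathways: list[str]
    signature: sig.SignatureModel
    scores: sig.ScoreVector
    survival: surv.SurvivalComparison
    roc: roc.ROCResult | None = None
    score_test: tuple[float, float] | None = None
    seed: int | None = None
    basis_used: str = "leading_edge"

    @property
    def enrichment_table(self) -> pd.DataFrame:
        return enrichment_table(self.enrichment)

    def apply(
        self,
        expression: ExpressionMatrix,
        annotation: CohortAnnotation | None = None,
        renormalize: bool = True,
        pseudocount: float | None = None,
    ) -> SignatureValidationResults:
        """Score an independent cohort with the frozen derived signature.

        The validation cohort is normalized with its own housekeeping
        factors (``renormalize=True``, the default); the signature itself is
        never modified.
        """
        pc = self.normalized.pseudocount if pseudocount is None else pseudocount
        values = (
            housekeeping_normalize(expression, pseudocount=pc)
            if renormalize
            else NormalizedMatrix(
                values=np.log2(expression.counts + pc),
                scale_factors=pd.Series(1.0, index=expression.counts.columns),
                pseudocount=pc,
                housekeeping=list(expression.housekeeping),
            )
        )
        return apply_signature(self.signature, values, annotation,
                               method=self.model.dichotomize_method)

    def summary(self) -> str:
        lines = ["Immune-related signature discovery", "=" * 44]
        lines.append(
            f"cohort:                {self.normalized.values.shape[1]} samples, "
            f"{self.normalized.values.shape[0]} genes"
        )
        lines.append("top pathways (nominal p):")
        by_name = {r.name: r for r in self.enrichment}
        for name in self.top_pathways:
            r = by_name[name]
            lines.append(f"  {name}: p = {r.p:.4g}, NES = {r.nes:.3f}, q = {r.q:.3g}")
        lines.append(
            f"core genes ({len(self.signature.core_genes)}, basis "
            f"{self.basis_used}): {', '.join(self.signature.core_genes)}"
        )
        if self.score_test is not None:
            lines.append(
                f"responder vs non-responder score: Wilcoxon p = {self.score_test[1]:.4g}"
            )
        if self.roc is not None:
            ci = self.roc.ci or (np.nan, np.nan)
            lines.append(
                f"response AUC:          {self.roc.auc:.3f} "
                f"(95% CI {ci[0]:.3f}-{ci[1]:.3f})"
            )
        s = self.survival
        lines.append(
            "median PFS high/low:   "
            f"{s.median_text('high')} / {s.median_text('low')} months"
        )
        lines.append(f"log-rank:              chi2 = {s.chi_square:.3f}, p = {s.p:.4g}")
        if s.hr_note:
            lines.append(f"hazard ratio:          {s.hr_note}")
        else:
            lines.append(
                f"HR (high vs low):      {s.hr:.3f} "
                f"(95% CI {s.hr_ci[0]:.3f}-{s.hr_ci[1]:.3f})"
            )
        return "\n".join(lines)


def _score_and_outcomes(
    values: NormalizedMatrix,
    model: sig.SignatureModel,
    annotation: CohortAnnotation | None,
    method: str = "median",
):
    scores = sig.score_samples(values, model)
    vector = sig.dichotomize(scores, method=method)
    survival_cmp = roc_res = score_test = None
    if annotation is not None:
        samples = scores.index.tolist()
        ann = annotation.table.loc[samples]
        if {"pfs_months", "event"}.issubset(ann.columns) and ann["pfs_months"].notna().all():
            t, e = ann["pfs_months"].to_numpy(float), ann["event"].to_numpy(int)
            survival_cmp = surv.compare_survival(
                t, e, vector.strata.to_numpy(), reference="low", comparison="high"
            )
        resp = ann["response"]
        a = scores[resp == RESPONDER]
        b = scores[resp == NON_RESPONDER]
        if a.size and b.size:
            score_test = wilcoxon_rank_sum(a, b)
            labels = (resp == RESPONDER).astype(int).to_numpy()
            roc_res = roc.roc_with_ci(scores.to_numpy(), labels)
    return vector, survival_cmp, roc_res, score_test


def apply_signature(
    model: sig.SignatureModel,
    values: NormalizedMatrix,
    annotation: CohortAnnotation | None = None,
    method: str = "median",
) -> SignatureValidationResults:
    """Score a normalized cohort with a frozen signature and, when outcome
    annotation is available, compare PFS between score strata and measure
    responder discrimination."""
    vector, survival_cmp, roc_res, score_test = _score_and_outcomes(
        values, model, annotation, method=method
    )
    return SignatureValidationResults(
        scores=vector, survival=survival_cmp, roc=roc_res, score_test=score_test
    )


class SignatureDiscovery:
    """Derive an immune-related core-gene signature from a panel cohort.

    Parameters
    ----------
    expression
        Raw panel counts with housekeeping genes.
    annotation
        Response labels and right-censored PFS per sample.
    gene_sets
        Pathway collection (GMT-style) to test for phenotype enrichment.
    markers
        Cell-type marker lists; defaults to the packaged 12-type list.
    pseudocount, metric, permutation_mode, n_permutations, weight_exponent,
    min_set_size, q_threshold
        Normalization and enrichment settings (GSEA-convention defaults;
        gene-set permutation suits small cohorts).
    top_k, min_pathways, basis
        Signature rule: core genes appear in >= ``min_pathways`` of the
        ``top_k`` pathways' ``basis`` gene lists; when the leading-edge
        basis yields no core gene and ``fallback_full_set`` is on, the
        full-set basis is retried.
    dichotomize_method
        High/low split of signature scores (default cohort median).
    """

    def __init__(
        self,
        expression: ExpressionMatrix,
        annotation: CohortAnnotation,
        gene_sets: GeneSetCollection,
        markers: dict[str, list[str]] | None = None,
        *,
        pseudocount: float = 1.0,
        metric: str = "signal_to_noise",
        permutation_mode: str = "gene_set",
        n_permutations: int = 1000,
        weight_exponent: float = 1.0,
        min_set_size: int = 3,
        q_threshold: float = 0.1,
        top_k: int = 3,
        min_pathways: int = 2,
        basis: str = "leading_edge",
        fallback_full_set: bool = True,
        dichotomize_method: str = "median",
    ) -> None:
        missing = set(expression.sample_ids) - set(annotation.sample_ids)
        if missing:
            raise ValueError(f"expression samples without annotation: {sorted(missing)}")
        self.expression = expression
        self.annotation = annotation
        self.gene_sets = gene_sets
        self.markers = markers if markers is not None else immune.default_markers()
        self.pseudocount = pseudocount
        self.metric = metric
        self.permutation_mode = permutation_mode
        self.n_permutations = n_permutations
        self.weight_exponent = weight_exponent
        self.min_set_size = min_set_size
        self.q_threshold = q_threshold
        self.top_k = top_k
        self.min_pathways = min_pathways
        self.basis = basis
        self.fallback_full_set = fallback_full_set
        self.dichotomize_method = dichotomize_method

    @classmethod
    def from_files(
        cls,
        expression_path,
        housekeeping_path,
        annotation_path,
        gmt_path,
        markers_path=None,
        **kwargs,
    ) -> "SignatureDiscovery":
        expr = read_expression_matrix(expression_path, housekeeping_path)
        ann = read_cohort_annotation(annotation_path)
        sets = read_gmt(gmt_path)
        markers = immune.read_markers(markers_path) if markers_path else None
        return cls(expr, ann, sets, markers=markers, **kwargs)

    def fit(self, seed=None) -> SignatureDiscoveryResults:
        """Run normalization, cell scores, enrichment, signature derivation
        and outcome comparison; returns the results object."""
        normalized = housekeeping_normalize(self.expression, self.pseudocount)
        cell_scores = immune.compare_cell_scores(
            immune.score_cell_types(normalized, self.markers), self.annotation
        )
        results = run_gsea(
            normalized,
            self.annotation,
            self.gene_sets,
            n_perm=self.n_permutations,
            mode=self.permutation_mode,
            metric=self.metric,
            weight_exponent=self.weight_exponent,
            min_size=self.min_set_size,
            q_threshold=self.q_threshold,
            seed=seed,
        )
        top_names = sig.select_top_pathways(results, self.top_k)
        top_results = [r for r in results if r.name in top_names]
        basis_used = self.basis
        try:
            model = sig.derive_core_genes(
                top_results, basis=self.basis, min_pathways=self.min_pathways
            )
        except EmptySignatureError:
            if not (self.fallback_full_set and self.basis == "leading_edge"):
                raise
            basis_used = "full_set"
            model = sig.derive_core_genes(
                top_results, basis="full_set", min_pathways=self.min_pathways
            )
        vector, survival_cmp, roc_res, score_test = _score_and_outcomes(
            normalized, model, self.annotation, method=self.dichotomize_method
        )
        if survival_cmp is None:
            raise ValueError("derivation cohort requires pfs_months and event")
        return SignatureDiscoveryResults(
            model=self,
            normalized=normalized,
            cell_scores=cell_scores,
            enrichment=results,
            top_pathways=top_names,
            signature=model,
            scores=vector,
            survival=survival_cmp,
            roc=roc_res,
            score_test=score_test,
            seed=seed,
            basis_used=basis_used,
        )
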