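"""End-to-end orchestration with file outputs and a reproducibility manifest.

``run_pipeline`` drives the Model/Results objects over on-disk inputs and
writes every stage product (normalized matrix, cell scores, enrichment
table, signature, scores, survival and ROC summaries) plus a JSON manifest
recording input checksums, the seed and the package version.  Two modes:
``derive`` builds the signature from the cohort; ``apply`` scores a cohort
with a frozen signature file (or the packaged six-gene signature).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .errors import ConfigError
from .matrix import housekeeping_normalize, read_cohort_annotation, read_expression_matrix
from .model import SignatureDiscovery, apply_signature
from .roc import ROCResult
from .signature import load_reference_signature, read_signature
from .survival import SurvivalComparison

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Paths and settings for one pipeline run (YAML/JSON-serializable)."""

    expression: str
    housekeeping: str
    annotation: str
    outdir: str
    gene_sets: str | None = None
    markers: str | None = None
    variants: str | None = None
    signature: str | None = None  # apply mode: frozen signature TSV (default packaged)
    mode: str = "derive"
    pseudocount: float = 1.0
    metric: str = "signal_to_noise"
    permutation_mode: str = "gene_set"
    n_permutations: int = 1000
    weight_exponent: float = 1.0
    min_set_size: int = 3
    q_threshold: float = 0.1
    top_k: int = 3
    min_pathways: int = 2
    basis: str = "leading_edge"
    dichotomize_method: str = "median"
    panel_mb: float | None = None
    seed: int = 0

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        text = Path(path).read_text()
        if str(path).endswith((".yaml", ".yml")):
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        return cls(**data)

    def validate(self) -> None:
        if self.mode not in {"derive", "apply"}:
            raise ConfigError(f"unknown mode {self.mode!r}")
        if self.mode == "derive" and not self.gene_sets:
            raise ConfigError("derive mode requires a gene-set GMT")
        for label in ("expression", "housekeeping", "annotation"):
            p = getattr(self, label)
            if not p or not Path(p).exists():
                raise ConfigError(f"{label} path does not exist: {p!r}")
        for label in ("gene_sets", "markers", "variants", "signature"):
            p = getattr(self, label)
            if p and not Path(p).exists():
                raise ConfigError(f"{label} path does not exist: {p!r}")


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_survival(cmp_: SurvivalComparison, outdir: Path, prefix: str) -> list[str]:
    files = []
    rows = []
    for label, curve in cmp_.curves.items():
        rows.append(
            pd.DataFrame(
                {
                    "stratum": label,
                    "time": curve.times,
                    "survival": curve.survival,
                    "at_risk": curve.at_risk,
                    "events": curve.n_events,
                }
            )
        )
    path = outdir / f"{prefix}_km.csv"
    pd.concat(rows, ignore_index=True).to_csv(path, index=False) if rows else None
    files.append(path.name)
    summary = {
        "median_" + lab: cmp_.medians[lab] for lab in cmp_.curves
    } | {
        "chi_square": cmp_.chi_square,
        "logrank_p": cmp_.p,
        "hr": cmp_.hr,
        "hr_ci_low": cmp_.hr_ci[0],
        "hr_ci_high": cmp_.hr_ci[1],
        "hr_p": cmp_.hr_p,
        "hr_note": cmp_.hr_note,
    }
    spath = outdir / f"{prefix}_summary.csv"
    pd.DataFrame([summary]).to_csv(spath, index=False)
    files.append(spath.name)
    return files


def _write_roc(res: ROCResult, outdir: Path, prefix: str) -> list[str]:
    path = outdir / f"{prefix}_roc.csv"
    res.to_frame().to_csv(path, index=False)
    ci = res.ci or (np.nan, np.nan)
    spath = outdir / f"{prefix}_roc_summary.csv"
    pd.DataFrame(
        [{"auc": res.auc, "ci_low": ci[0], "ci_high": ci[1],
          "ci_degenerate": res.ci_degenerate}]
    ).to_csv(spath, index=False)
    return [path.name, spath.name]


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run the configured analysis and return the manifest dictionary.

    Stage failures are re-raised with the stage name; outputs written before
    the failure are kept and the manifest records the failed stage.
    """
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "mode": cfg.mode,
        "seed": cfg.seed,
        "config": dataclasses.asdict(cfg),
        "inputs": {},
        "outputs": [],
        "failed_stage": None,
    }
    for label in ("expression", "housekeeping", "annotation", "gene_sets",
                  "markers", "variants", "signature"):
        p = getattr(cfg, label)
        if p:
            manifest["inputs"][label] = {"path": str(p), "sha256": _sha256(p)}

    stage = "read_inputs"
    try:
        t0 = time.time()
        expression = read_expression_matrix(cfg.expression, cfg.housekeeping)
        annotation = read_cohort_annotation(cfg.annotation)
        logger.info("stage %s done in %.2fs", stage, time.time() - t0)

        if cfg.mode == "derive":
            stage = "derive"
            t0 = time.time()
            model = SignatureDiscovery.from_files(
                cfg.expression, cfg.housekeeping, cfg.annotation, cfg.gene_sets,
                markers_path=cfg.markers,
                pseudocount=cfg.pseudocount,
                metric=cfg.metric,
                permutation_mode=cfg.permutation_mode,
                n_permutations=cfg.n_permutations,
                weight_exponent=cfg.weight_exponent,
                min_set_size=cfg.min_set_size,
                q_threshold=cfg.q_threshold,
                top_k=cfg.top_k,
                min_pathways=cfg.min_pathways,
                basis=cfg.basis,
                dichotomize_method=cfg.dichotomize_method,
            )
            res = model.fit(seed=cfg.seed)
            logger.info("stage %s done in %.2fs", stage, time.time() - t0)

            stage = "write_outputs"
            res.normalized.to_tsv(outdir / "normalized.tsv")
            manifest["outputs"].append("normalized.tsv")
            res.cell_scores.to_csv(outdir / "cell_scores.csv")
            manifest["outputs"].append("cell_scores.csv")
            res.enrichment_table.to_csv(outdir / "enrichment.csv", index=False)
            manifest["outputs"].append("enrichment.csv")
            res.signature.to_tsv(outdir / "signature.tsv")
            manifest["outputs"].append("signature.tsv")
            res.scores.to_csv(outdir / "scores.csv")
            manifest["outputs"].append("scores.csv")
            manifest["outputs"] += _write_survival(res.survival, outdir, "survival")
            if res.roc is not None:
                manifest["outputs"] += _write_roc(res.roc, outdir, "response")
            (outdir / "summary.txt").write_text(res.summary() + "\n")
            manifest["outputs"].append("summary.txt")
        else:
            stage = "apply"
            t0 = time.time()
            model = (
                read_signature(cfg.signature) if cfg.signature
                else load_reference_signature()
            )
            values = housekeeping_normalize(expression, cfg.pseudocount)
            res = apply_signature(model, values, annotation,
                                  method=cfg.dichotomize_method)
            logger.info("stage %s done in %.2fs", stage, time.time() - t0)

            stage = "write_outputs"
            values.to_tsv(outdir / "normalized.tsv")
            manifest["outputs"].append("normalized.tsv")
            res.scores.to_csv(outdir / "scores.csv")
            manifest["outputs"].append("scores.csv")
            if res.survival is not None:
                manifest["outputs"] += _write_survival(res.survival, outdir, "survival")
            if res.roc is not None:
                manifest["outputs"] += _write_roc(res.roc, outdir, "response")
            (outdir / "summary.txt").write_text(res.summary() + "\n")
            manifest["outputs"].append("summary.txt")

        if cfg.variants:
            stage = "tmb"
            from .tmb import compute_tmb, read_variant_table

            if not cfg.panel_mb:
                raise ConfigError("variants supplied but panel_mb missing")
            variants = read_variant_table(cfg.variants)
            tmb = compute_tmb(variants, cfg.panel_mb, samples=annotation.sample_ids)
            tmb.to_csv(outdir / "tmb.csv", index=False)
            manifest["outputs"].append("tmb.csv")
    except Exception as exc:
        manifest["failed_stage"] = stage
        _write_manifest(manifest, outdir)
        exc.stage = stage  # annotate for callers; original error type preserved
        logger.error("stage %s failed: %s", stage, exc)
        raise

    _write_manifest(manifest, outdir)
    return manifest


def _write_manifest(manifest: dict, outdir: Path) -> None:
    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        raise TypeError(type(o))

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=default)
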