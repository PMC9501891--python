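"""Synthetic targeted-panel cohorts with planted expression and outcome truth.

Emulates a ~289-gene tumor-immune NanoString-style cohort: negative-binomial
counts around log-normal per-gene baselines, a housekeeping subset with no
group effect, responder/non-responder labels, planted log2 fold changes in
chosen genes (responders vs non-responders), and right-censored
progression-free survival whose exponential hazard depends on a latent
signature score.  The generator is fully seeded: the same config reproduces
the same cohort byte for byte.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .errors import ConfigError
from .gsea import GeneSetCollection
from .matrix import NON_RESPONDER, RESPONDER, CohortAnnotation, ExpressionMatrix

__all__ = [
    "SynthConfig",
    "SynthCohort",
    "generate_cohort",
    "generate_variant_table",
    "make_signature_scenario",
    "DEFAULT_CORE_GENES",
]

#: Core-gene names used by :func:`make_signature_scenario`; chosen to match
#: the six-gene reference signature so apply-mode runs work out of the box.
DEFAULT_CORE_GENES = ("PSMB10", "PSMB9", "LAG3", "CCL5", "IFI35", "SH2D1A")


@dataclass
class SynthConfig:
    """Study conditions for one synthetic cohort.

    Defaults mirror the pilot-study setting this generator emulates: a
    289-gene panel with ~10 housekeeping genes, 12 samples with 8 of 12
    responders, overdispersed counts, and a protective association between
    the latent signature score and the progression hazard.
    """

    n_genes: int = 289
    n_housekeeping: int = 10
    n_samples: int = 12
    prop_responders: float = 8 / 12
    #: gene id -> planted log2 fold change (responders vs non-responders)
    planted_genes: dict[str, float] = field(default_factory=dict)
    baseline_log_mean: float = 6.0   # log2 scale; ~64 counts
    baseline_log_sd: float = 1.5     # spread of per-gene log2 baselines
    dispersion: float = 10.0         # negative-binomial size parameter
    hazard_base: float = 0.1         # events / month at average latent score
    hazard_log_hr_per_score: float = -0.7  # log HR per SD of latent score
    censor_rate: float = 0.2
    seed: int = 0
    gene_prefix: str = "IRG"
    hk_prefix: str = "HK"
    #: name filler genes after the packaged immune marker genes first, so
    #: synthetic panels carry cell-type markers like the real assay
    include_marker_genes: bool = True

    def validate(self) -> None:
        if self.n_genes < 2 or self.n_housekeeping < 1:
            raise ConfigError("need >= 2 genes and >= 1 housekeeping gene")
        if self.n_housekeeping >= self.n_genes:
            raise ConfigError("housekeeping genes must be a strict subset of the panel")
        if self.n_samples < 2:
            raise ConfigError("need >= 2 samples")
        if not 0 < self.prop_responders < 1:
            raise ConfigError("prop_responders must be in (0, 1)")
        if self.dispersion <= 0:
            raise ConfigError("dispersion must be positive")
        if self.hazard_base <= 0:
            raise ConfigError("hazard_base must be positive")
        if not 0 <= self.censor_rate < 1:
            raise ConfigError("censor_rate must be in [0, 1)")
        if len(self.planted_genes) > self.n_genes - self.n_housekeeping:
            raise ConfigError("more planted genes than non-housekeeping slots")
        for g in self.planted_genes:
            if str(g).startswith(self.hk_prefix):
                raise ConfigError("housekeeping genes may not be planted")

    def gene_ids(self) -> tuple[list[str], list[str]]:
        """(all gene ids, housekeeping ids); planted genes come first."""
        planted = list(self.planted_genes)
        n_filler = self.n_genes - self.n_housekeeping - len(planted)
        filler: list[str] = []
        if self.include_marker_genes:
            from .immune import default_markers

            seen = set(planted)
            for genes in default_markers().values():
                for g in genes:
                    if g not in seen:
                        seen.add(g)
                        filler.append(g)
            filler = filler[:n_filler]
        filler += [
            f"{self.gene_prefix}{i:04d}" for i in range(1, n_filler - len(filler) + 1)
        ]
        hk = [f"{self.hk_prefix}{i:02d}" for i in range(1, self.n_housekeeping + 1)]
        return planted + filler + hk, hk


@dataclass
class SynthCohort:
    expression: ExpressionMatrix
    annotation: CohortAnnotation
    config: SynthConfig
    latent_scores: pd.Series  # standardized per-sample latent signature score

    def write(self, outdir) -> None:
        from pathlib import Path

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.expression.to_tsv(out / "expression.tsv", out / "housekeeping.txt")
        self.annotation.to_csv(out / "annotation.csv")
        import json

        with open(out / "config.json", "w") as fh:
            json.dump(dataclasses.asdict(self.config), fh, indent=2)


def _censor_horizon(hazards: np.ndarray, censor_rate: float) -> float:
    """T_max such that mean_j P(U(0,T) < Exp(hazard_j)) equals censor_rate."""

    def mean_censor_prob(t):
        lt = hazards * t
        return float(np.mean((1 - np.exp(-lt)) / lt)) - censor_rate

    return brentq(mean_censor_prob, 1e-9, 1e9, xtol=1e-10, rtol=1e-12)


def generate_cohort(cfg: SynthConfig) -> SynthCohort:
    """Draw one seeded synthetic cohort from the configured conditions."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    genes, hk = cfg.gene_ids()
    n_g, n_s = len(genes), cfg.n_samples

    n_resp = int(round(cfg.prop_responders * n_s))
    n_resp = min(max(n_resp, 1), n_s - 1)
    responder = np.zeros(n_s, dtype=bool)
    responder[:n_resp] = True
    samples = [f"S{i:03d}" for i in range(1, n_s + 1)]

    base_log2 = rng.normal(cfg.baseline_log_mean, cfg.baseline_log_sd, size=n_g)
    log2fc = np.array([cfg.planted_genes.get(g, 0.0) for g in genes])
    # gene x sample log2 mean; the planted shift applies only to responders
    mean_log2 = base_log2[:, None] + log2fc[:, None] * responder[None, :]
    mu = 2.0 ** mean_log2
    p = cfg.dispersion / (cfg.dispersion + mu)
    counts = rng.negative_binomial(cfg.dispersion, p).astype(float)

    expr = ExpressionMatrix(
        pd.DataFrame(counts, index=genes, columns=samples), housekeeping=hk
    )

    # latent score: per-sample mean of planted genes' true log2 means,
    # standardized across the cohort (all-zero when nothing is planted)
    if cfg.planted_genes:
        planted_idx = [genes.index(g) for g in cfg.planted_genes]
        latent = mean_log2[planted_idx, :].mean(axis=0)
    else:
        latent = np.zeros(n_s)
    sd = latent.std()
    z = (latent - latent.mean()) / sd if sd > 0 else np.zeros(n_s)

    hazards = cfg.hazard_base * np.exp(cfg.hazard_log_hr_per_score * z)
    event_time = rng.exponential(1.0 / hazards)
    if cfg.censor_rate > 0:
        t_max = _censor_horizon(hazards, cfg.censor_rate)
        censor_time = rng.uniform(0, t_max, size=n_s)
    else:
        censor_time = np.full(n_s, np.inf)
    pfs = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(int)

    best_change = np.where(
        responder, rng.uniform(-80, -5, size=n_s), rng.uniform(5, 80, size=n_s)
    )
    ann = CohortAnnotation(
        pd.DataFrame(
            {
                "sample_id": samples,
                "response": np.where(responder, RESPONDER, NON_RESPONDER),
                "best_change_pct": np.round(best_change, 1),
                "pfs_months": np.round(pfs, 4),
                "event": event,
            }
        )
    )
    return SynthCohort(
        expression=expr,
        annotation=ann,
        config=cfg,
        latent_scores=pd.Series(z, index=samples, name="latent_score"),
    )


_VARIANT_CLASSES = (
    "missense", "nonsense", "splice_site", "inframe", "frameshift",
    "synonymous", "intronic",
)
_VARIANT_GENES = (
    "TP53", "KRAS", "IDH1", "FGFR2", "BAP1", "ARID1A", "SMAD4",
    "CDKN2A", "PTEN", "PIK3CA",
)


def generate_variant_table(n_samples: int, rates: dict[str, float], seed=None) -> pd.DataFrame:
    """Poisson per-sample per-class variant counts, one row per variant.

    ``rates`` maps effect classes to expected counts per sample; unknown
    classes or negative rates are errors.
    """
    unknown = set(rates) - set(_VARIANT_CLASSES)
    if unknown:
        raise ValueError(f"unknown effect classes: {sorted(unknown)}")
    if any(v < 0 for v in rates.values()):
        raise ValueError("rates must be nonnegative")
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(1, n_samples + 1):
        sid = f"S{i:03d}"
        for cls in _VARIANT_CLASSES:
            lam = rates.get(cls, 0.0)
            for _ in range(rng.poisson(lam)):
                rows.append(
                    {
                        "sample_id": sid,
                        "gene": rng.choice(_VARIANT_GENES),
                        "effect_class": cls,
                    }
                )
    return pd.DataFrame(rows, columns=["sample_id", "gene", "effect_class"])


def make_signature_scenario(
    n_samples: int = 30,
    log2fc: float = 2.0,
    core_genes=DEFAULT_CORE_GENES,
    n_pathways: int = 3,
    pathway_size: int = 15,
    n_background_sets: int = 20,
    background_size: int = 15,
    seed: int = 0,
    **cfg_overrides,
) -> tuple[SynthConfig, GeneSetCollection]:
    """A derivation scenario: planted core genes shared by planted pathways.

    The core genes carry ``log2fc`` in responders and belong to every one of
    the ``n_pathways`` planted pathway sets (hence to >= 2 of them); pathway
    filler genes are disjoint null genes, so only core genes can recur
    across pathways.  Background sets are random null-gene sets.  Returns
    the cohort config and the matching gene-set collection.
    """
    core = list(core_genes)
    cfg = SynthConfig(
        n_samples=n_samples,
        prop_responders=0.5,
        planted_genes={g: log2fc for g in core},
        seed=seed,
        **cfg_overrides,
    )
    cfg.validate()
    genes, hk = cfg.gene_ids()
    null_genes = [g for g in genes if g not in cfg.planted_genes and g not in hk]
    rng = np.random.default_rng(seed + 1)
    n_filler = pathway_size - len(core)
    if n_filler < 0:
        raise ConfigError("pathway_size smaller than the core gene count")
    needed = n_pathways * n_filler
    if needed > len(null_genes):
        raise ConfigError("not enough null genes for disjoint pathway fillers")
    shuffled = list(rng.permutation(null_genes))
    sets: dict[str, list[str]] = {}
    pathway_names = [
        "GOBP_RESPONSE_TO_BIOTIC_STIMULUS",
        "GOBP_REGULATION_OF_INNATE_IMMUNE_RESPONSE",
        "GOBP_T_CELL_MIGRATION",
    ]
    for i in range(n_pathways):
        name = pathway_names[i] if i < len(pathway_names) else f"PLANTED_PATHWAY_{i + 1}"
        filler = shuffled[i * n_filler : (i + 1) * n_filler]
        sets[name] = core + filler
    for j in range(n_background_sets):
        members = list(rng.choice(null_genes, size=background_size, replace=False))
        sets[f"NULL_SET_{j + 1:02d}"] = members
    return cfg, GeneSetCollection(sets, source="synthetic")
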