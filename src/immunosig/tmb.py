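"""Tumor mutational burden from classified somatic variants.

TMB counts nonsynonymous somatic mutations — missense, nonsense,
splice-site, inframe and frameshift — per sample and reports them per
megabase of sequenced panel territory.  Effect prediction is upstream of
this module: variants arrive already classified (TSV, or a VCF carrying a
SnpEff/VEP-style annotation field).
"""

from __future__ import annotations

import pandas as pd

from .errors import FormatError, VocabularyError

NONSYNONYMOUS = frozenset({"missense", "nonsense", "splice_site", "inframe", "frameshift"})
EFFECT_CLASSES = NONSYNONYMOUS | frozenset({"synonymous", "intronic", "other"})

#: SnpEff/VEP consequence terms mapped into the closed effect vocabulary.
_ANN_TERMS = {
    "missense_variant": "missense",
    "stop_gained": "nonsense",
    "stop_lost": "nonsense",
    "start_lost": "nonsense",
    "splice_acceptor_variant": "splice_site",
    "splice_donor_variant": "splice_site",
    "inframe_insertion": "inframe",
    "inframe_deletion": "inframe",
    "disruptive_inframe_insertion": "inframe",
    "disruptive_inframe_deletion": "inframe",
    "frameshift_variant": "frameshift",
    "synonymous_variant": "synonymous",
    "stop_retained_variant": "synonymous",
    "intron_variant": "intronic",
}

__all__ = [
    "NONSYNONYMOUS",
    "EFFECT_CLASSES",
    "is_nonsynonymous",
    "compute_tmb",
    "read_variant_table",
    "variants_from_vcf",
]


def is_nonsynonymous(effect_class: str) -> bool:
    """True for the functional classes counted into TMB."""
    if effect_class not in EFFECT_CLASSES:
        raise VocabularyError(
            f"unknown effect class {effect_class!r}; expected one of "
            f"{sorted(EFFECT_CLASSES)}"
        )
    return effect_class in NONSYNONYMOUS


def read_variant_table(path) -> pd.DataFrame:
    """Read a sample_id<TAB>gene<TAB>effect_class variant TSV."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "gene", "effect_class"}
    if not required.issubset(df.columns):
        raise FormatError(f"variant table needs columns {sorted(required)}")
    return df


def variants_from_vcf(path, sample_id: str, ann_field: str = "ANN") -> pd.DataFrame:
    """Thin adapter: one-sample VCF with a pre-annotated effect field.

    Reads the first annotation entry of each record's ``ANN``/``CSQ``-style
    INFO field (pipe-separated; consequence term second, gene fourth) and
    maps the consequence term into the closed effect vocabulary
    (unrecognized terms become ``other``).
    """
    from cyvcf2 import VCF

    rows = []
    for rec in VCF(str(path)):
        raw = rec.INFO.get(ann_field)
        if raw is None:
            continue
        first = str(raw).split(",")[0].split("|")
        term = first[1] if len(first) > 1 else ""
        gene = first[3] if len(first) > 3 else ""
        effect = next(
            (_ANN_TERMS[t] for t in term.split("&") if t in _ANN_TERMS), "other"
        )
        rows.append({"sample_id": sample_id, "gene": gene, "effect_class": effect})
    return pd.DataFrame(rows, columns=["sample_id", "gene", "effect_class"])


def compute_tmb(variants: pd.DataFrame, panel_mb: float, samples=None) -> pd.DataFrame:
    """Per-sample nonsynonymous count and TMB (mutations/Mb).

    ``samples`` optionally lists every cohort sample so that samples with
    zero variants are reported with TMB 0.
    """
    if not panel_mb > 0:
        raise ValueError("panel_mb must be positive")
    if variants.empty:
        counts = pd.Series(dtype=int)
    else:
        nonsyn = variants["effect_class"].map(is_nonsynonymous)
        counts = variants.loc[nonsyn.astype(bool), "sample_id"].value_counts()
    index = pd.Index(
        list(samples) if samples is not None else counts.index, name="sample_id"
    )
    counts = counts.reindex(index, fill_value=0).astype(int)
    out = pd.DataFrame(
        {"nonsyn_count": counts, "tmb_per_mb": counts / panel_mb}
    ).reset_index()
    return out
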