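"""Variant/CNV qualification rules and the five collapsing-model presets.

A collapsing model decides which observations make a sample a carrier
of a gene. Five presets are provided:

==================== =========== ========= =========== ====
name                 inheritance impact    MAF cutoff  CNVs
==================== =========== ========= =========== ====
dominant_stringent   dominant    stringent < 0.001     no
dominant_relaxed     dominant    relaxed   < 0.001     no
recessive_stringent  recessive   stringent < 0.01      no
recessive_relaxed    recessive   relaxed   < 0.01      no
recessive_cnv        recessive   stringent < 0.01      yes
==================== =========== ========= =========== ====

The stringent impact set is protein-truncating / canonical splice-site
consequences; relaxed additionally admits missense variants with CADD
>= 20. Recessive models count only homozygous or hemizygous calls.
MAF comparisons are strict (<); CADD and CNV quality thresholds are
inclusive (>=). A missing MAF passes MAF filters (ultra-rare variants
present as absent from population databases); a missing CADD fails the
missense rule.

Homozygous-deletion CNVs qualify when copy number is 0, the call
log-likelihood is >= 15, the sample's reference-cohort correlation is
>= 0.9 (exomes) or >= 0.55 (genomes), the call does not overlap a CNV
polymorphism region, and its in-house deletion frequency is missing or
<= 1%.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Iterable, Sequence

import yaml

from .cohort_io import CnvCall, SmallVariant

__all__ = [
    "ModelSpec",
    "QualifiedCall",
    "STRINGENT_CONSEQUENCES",
    "model_presets",
    "preset",
    "qualify_small_variant",
    "qualify_cnv",
    "models_to_yaml",
    "models_from_yaml",
]

# Protein-truncating and canonical splice-site consequence terms
# (Sequence Ontology names); start_lost/stop_lost inclusion is a
# configurable package choice.
STRINGENT_CONSEQUENCES = frozenset(
    {
        "stop_gained",
        "frameshift_variant",
        "splice_donor_variant",
        "splice_acceptor_variant",
        "stop_lost",
        "start_lost",
    }
)

_CONSEQUENCE_ALIASES = {
    "frameshift": "frameshift_variant",
    "splice_donor": "splice_donor_variant",
    "splice_acceptor": "splice_acceptor_variant",
    "missense": "missense_variant",
}

_MISSENSE = frozenset({"missense_variant"})


def normalize_consequence(consequence: str) -> str:
    c = consequence.strip().lower()
    return _CONSEQUENCE_ALIASES.get(c, c)


@dataclass(frozen=True)
class ModelSpec:
    """One collapsing scheme."""

    name: str
    inheritance: str  # dominant | recessive
    impact_set: str  # stringent | relaxed
    maf_cutoff: float
    genotype_required: str  # any | hom_or_hemi
    include_cnv: bool = False
    cnv_gate_min_cases: int = 2
    cadd_min: float = 20.0
    stringent_consequences: frozenset[str] = STRINGENT_CONSEQUENCES

    def __post_init__(self) -> None:
        if self.inheritance not in {"dominant", "recessive"}:
            raise ValueError(f"unknown inheritance {self.inheritance!r}")
        if self.impact_set not in {"stringent", "relaxed"}:
            raise ValueError(f"unknown impact set {self.impact_set!r}")
        if self.genotype_required not in {"any", "hom_or_hemi"}:
            raise ValueError(
                f"unknown genotype requirement {self.genotype_required!r}"
            )
        if self.inheritance == "dominant" and self.genotype_required != "any":
            raise ValueError("dominant models must accept any genotype")
        if (
            self.inheritance == "recessive"
            and self.genotype_required != "hom_or_hemi"
        ):
            raise ValueError("recessive models count hom/hemi calls only")
        if self.include_cnv and not (
            self.inheritance == "recessive" and self.impact_set == "stringent"
        ):
            raise ValueError(
                "CNV evidence extends only the recessive stringent model"
            )
        if not (0.0 < self.maf_cutoff <= 1.0):
            raise ValueError(f"MAF cutoff {self.maf_cutoff} outside (0, 1]")
        object.__setattr__(
            self,
            "stringent_consequences",
            frozenset(
                normalize_consequence(c) for c in self.stringent_consequences
            ),
        )


@dataclass(frozen=True)
class QualifiedCall:
    """One (sample, gene) carrier contribution under one model."""

    sample_id: str
    gene: str
    source: str  # small_variant | cnv
    model_name: str


def model_presets() -> list[ModelSpec]:
    """The five preset collapsing schemes, in fixed order."""
    return [
        ModelSpec(
            name="dominant_stringent",
            inheritance="dominant",
            impact_set="stringent",
            maf_cutoff=0.001,
            genotype_required="any",
        ),
        ModelSpec(
            name="dominant_relaxed",
            inheritance="dominant",
            impact_set="relaxed",
            maf_cutoff=0.001,
            genotype_required="any",
        ),
        ModelSpec(
            name="recessive_stringent",
            inheritance="recessive",
            impact_set="stringent",
            maf_cutoff=0.01,
            genotype_required="hom_or_hemi",
        ),
        ModelSpec(
            name="recessive_relaxed",
            inheritance="recessive",
            impact_set="relaxed",
            maf_cutoff=0.01,
            genotype_required="hom_or_hemi",
        ),
        ModelSpec(
            name="recessive_cnv",
            inheritance="recessive",
            impact_set="stringent",
            maf_cutoff=0.01,
            genotype_required="hom_or_hemi",
            include_cnv=True,
        ),
    ]


def preset(name: str) -> ModelSpec:
    for m in model_presets():
        if m.name == name:
            return m
    raise KeyError(f"unknown model preset {name!r}")


def qualify_small_variant(v: SmallVariant, m: ModelSpec) -> bool:
    """Pure predicate: does this call qualify under this model?"""
    if not v.quality_pass:
        return False
    consequence = normalize_consequence(v.consequence)
    if consequence in m.stringent_consequences:
        pass
    elif (
        m.impact_set == "relaxed"
        and consequence in _MISSENSE
        and v.cadd is not None
        and v.cadd >= m.cadd_min
    ):
        pass
    else:
        return False
    if v.maf is not None and not (v.maf < m.maf_cutoff):
        return False
    if m.genotype_required == "hom_or_hemi" and v.genotype not in (
        "hom",
        "hemi",
    ):
        return False
    return True


def qualify_cnv(
    c: CnvCall,
    min_log_likelihood: float = 15.0,
    min_correlation_es: float = 0.9,
    min_correlation_gs: float = 0.55,
    max_inhouse_maf: float = 0.01,
) -> bool:
    """Pure predicate for high-quality homozygous deletions."""
    if c.copy_number != 0:
        return False
    if c.log_likelihood < min_log_likelihood:
        return False
    min_corr = min_correlation_es if c.assay == "ES" else min_correlation_gs
    if c.reference_correlation < min_corr:
        return False
    if c.polymorphism_overlap:
        return False
    if c.inhouse_maf is not None and c.inhouse_maf > max_inhouse_maf:
        return False
    return True


# ---------------------------------------------------------------------------
# YAML round-trip so users can define custom models


def models_to_yaml(models: Sequence[ModelSpec]) -> str:
    payload = []
    for m in models:
        d = asdict(m)
        d["stringent_consequences"] = sorted(m.stringent_consequences)
        payload.append(d)
    return yaml.safe_dump(payload, sort_keys=False)


def models_from_yaml(text: str) -> list[ModelSpec]:
    payload = yaml.safe_load(text)
    if not isinstance(payload, list):
        raise ValueError("model YAML must be a list of model mappings")
    out = []
    for d in payload:
        d = dict(d)
        if "stringent_consequences" in d:
            d["stringent_consequences"] = frozenset(
                d["stringent_consequences"]
            )
        out.append(ModelSpec(**d))
    return out
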