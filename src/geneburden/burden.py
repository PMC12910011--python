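"""Per-gene collapsing burden tests with CNV evidence gating.

For each gene and collapsing model, samples are collapsed to a binary
carrier status (at least one qualifying small variant; optionally a
qualifying homozygous-deletion CNV, admitted only for genes already
impacted by qualifying small variants in at least ``cnv_gate_min_cases``
cases). Carrier counts against case/control status form a 2x2 table
tested with the two-sided Fisher exact test; the minimum P across a
configured set of models is the gene's reported statistic, compared to
a Bonferroni-corrected genome-wide threshold (alpha / n genes tested)
plus a fixed suggestive threshold.

The two-sided P value is the sum over all tables with the observed
margins whose hypergeometric probability is at most that of the
observed table (with a tiny relative tolerance for floating-point
ties) — the standard definition implemented by scipy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort_io import CnvCall, SampleRecord, SmallVariant
from .qualification import ModelSpec, qualify_cnv, qualify_small_variant

__all__ = [
    "NoTestableGenesError",
    "ContingencyTable",
    "GeneBurdenResult",
    "ScanSummary",
    "gene_contingency",
    "fisher_exact_two_sided",
    "corrected_thresholds",
    "run_burden_scan",
    "export_manhattan_table",
    "results_frame",
    "DEFAULT_AGGREGATION",
]

class NoTestableGenesError(ValueError):
    """No gene carries a stringent qualifying small variant in cases,
    so the multiple-testing denominator is undefined."""


# Fixed tie-break / aggregation order for min-P across models
DEFAULT_AGGREGATION = (
    "dominant_stringent",
    "recessive_stringent",
    "recessive_cnv",
)


@dataclass(frozen=True)
class ContingencyTable:
    """Carrier counts: a/b case carriers/non-carriers, c/d controls."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")

    @property
    def n_cases(self) -> int:
        return self.a + self.b

    @property
    def n_controls(self) -> int:
        return self.c + self.d


@dataclass(frozen=True)
class ModelResult:
    case_carriers: int
    control_carriers: int
    p_value: float


@dataclass
class GeneBurdenResult:
    gene: str
    chrom: str
    pos: int
    per_model: dict[str, ModelResult]
    min_p: float
    best_model: str
    tested: bool
    significant: bool = False
    suggestive: bool = False


@dataclass(frozen=True)
class ScanSummary:
    n_genes_tested: int
    alpha: float
    bonferroni_threshold: float
    sidak_threshold: float
    suggestive_threshold: float = 0.0025


def fisher_exact_two_sided(t: ContingencyTable) -> float:
    """Two-sided Fisher exact P for a carrier-count table.

    All-zero tables (and tables with a zero carrier margin) return 1 by
    convention. The result is clamped into (0, 1].
    """
    if t.a + t.b + t.c + t.d == 0:
        return 1.0
    p = stats.fisher_exact([[t.a, t.b], [t.c, t.d]], alternative="two-sided")[1]
    p = float(p)
    tiny = np.finfo(float).tiny
    return min(1.0, max(p, tiny))


def corrected_thresholds(alpha: float, n_genes: int) -> tuple[float, float]:
    """Bonferroni (alpha/n) and Sidak (1 - (1-alpha)^(1/n)) per-gene
    thresholds for family-wise error alpha over n genes."""
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must be in (0, 1)")
    bonferroni = alpha / n_genes
    sidak = -math.expm1(math.log1p(-alpha) / n_genes)
    return bonferroni, sidak


def gene_contingency(
    gene: str,
    sv_calls: Iterable[SmallVariant],
    cnv_calls: Iterable[CnvCall],
    samples: Sequence[SampleRecord],
    model: ModelSpec,
) -> ContingencyTable:
    """Collapse qualified calls for one gene into a 2x2 carrier table.

    ``sv_calls`` and ``cnv_calls`` must already have passed
    qualification for this model; they may span multiple genes (calls
    for other genes are ignored). CNV carriers are admitted only when
    the model includes CNVs *and* at least ``model.cnv_gate_min_cases``
    case samples carry qualifying small variants in the gene.
    """
    group_of = {s.sample_id: s.group for s in samples}
    sv_carriers: set[str] = set()
    for v in sv_calls:
        if v.gene != gene:
            continue
        if v.sample_id not in group_of:
            raise KeyError(
                f"sample {v.sample_id!r} has calls but is not in the manifest"
            )
        sv_carriers.add(v.sample_id)

    carriers = set(sv_carriers)
    if model.include_cnv:
        sv_case_carriers = sum(
            1 for s in sv_carriers if group_of[s] == "case"
        )
        if sv_case_carriers >= model.cnv_gate_min_cases:
            for c in cnv_calls:
                if gene not in c.genes:
                    continue
                if c.sample_id not in group_of:
                    raise KeyError(
                        f"sample {c.sample_id!r} has calls but is not in "
                        "the manifest"
                    )
                carriers.add(c.sample_id)

    n_cases = sum(1 for s in samples if s.group == "case")
    n_controls = len(samples) - n_cases
    a = sum(1 for s in carriers if group_of[s] == "case")
    c = len(carriers) - a
    return ContingencyTable(a=a, b=n_cases - a, c=c, d=n_controls - c)


def _chrom_key(chrom: str) -> tuple[int, str]:
    c = chrom[3:] if chrom.lower().startswith("chr") else chrom
    if c.isdigit():
        return (int(c), "")
    order = {"X": 23, "Y": 24, "MT": 25, "M": 25}
    return (order.get(c, 26), c)


def run_burden_scan(
    samples: Sequence[SampleRecord],
    variants: Sequence[SmallVariant],
    cnvs: Sequence[CnvCall] = (),
    models: Sequence[ModelSpec] | None = None,
    aggregation_models: Sequence[str] | None = None,
    alpha: float = 0.05,
    suggestive_threshold: float = 0.0025,
) -> tuple[list[GeneBurdenResult], ScanSummary]:
    """Scan every gene with qualifying small variants across models.

    ``aggregation_models`` names the models over which the per-gene
    minimum P is taken (default: dominant stringent, recessive
    stringent, recessive+CNV — restricted to models actually scanned),
    with ties broken by that order. The multiple-testing denominator is
    the number of genes with at least one small variant among *cases*
    qualifying under a stringent model of the run.
    """
    from .qualification import model_presets

    if models is None:
        models = model_presets()
    if not samples:
        raise ValueError("empty cohort")
    n_cases = sum(1 for s in samples if s.group == "case")
    if n_cases == 0 or n_cases == len(samples):
        raise ValueError("cohort must contain both cases and controls")
    model_names = [m.name for m in models]
    if aggregation_models is None:
        aggregation = [n for n in DEFAULT_AGGREGATION if n in model_names]
        if not aggregation:
            aggregation = list(model_names)
    else:
        unknown = set(aggregation_models) - set(model_names)
        if unknown:
            raise ValueError(
                "aggregation models not scanned: " + ", ".join(sorted(unknown))
            )
        aggregation = [n for n in model_names if n in set(aggregation_models)]

    group_of = {s.sample_id: s.group for s in samples}

    # qualification pass, per model
    qualified_sv: dict[str, list[SmallVariant]] = {}
    for m in models:
        qualified_sv[m.name] = [
            v for v in variants if qualify_small_variant(v, m)
        ]
    qualified_cnv = [c for c in cnvs if qualify_cnv(c)]

    genes: dict[str, tuple[tuple[int, str], int]] = {}
    for vs in qualified_sv.values():
        for v in vs:
            key = (_chrom_key(v.chrom), v.pos)
            if v.gene not in genes or key < genes[v.gene]:
                genes[v.gene] = key
    gene_chrom: dict[str, tuple[str, int]] = {}
    for vs in qualified_sv.values():
        for v in vs:
            cur = gene_chrom.get(v.gene)
            if cur is None or (_chrom_key(v.chrom), v.pos) < (
                _chrom_key(cur[0]),
                cur[1],
            ):
                gene_chrom[v.gene] = (v.chrom, v.pos)

    # genome-wide denominator: genes hit by stringent qualifying
    # variants among cases
    tested_genes: set[str] = set()
    for m in models:
        if m.impact_set != "stringent":
            continue
        for v in qualified_sv[m.name]:
            if group_of.get(v.sample_id) == "case":
                tested_genes.add(v.gene)
    n_genes_tested = len(tested_genes)
    if n_genes_tested == 0:
        raise NoTestableGenesError(
            "no genes with stringent qualifying variants among cases"
        )
    bonferroni, sidak = corrected_thresholds(alpha, n_genes_tested)
    summary = ScanSummary(
        n_genes_tested=n_genes_tested,
        alpha=alpha,
        bonferroni_threshold=bonferroni,
        sidak_threshold=sidak,
        suggestive_threshold=suggestive_threshold,
    )

    results: list[GeneBurdenResult] = []
    for gene in genes:
        per_model: dict[str, ModelResult] = {}
        for m in models:
            table = gene_contingency(
                gene, qualified_sv[m.name], qualified_cnv, samples, m
            )
            per_model[m.name] = ModelResult(
                case_carriers=table.a,
                control_carriers=table.c,
                p_value=fisher_exact_two_sided(table),
            )
        min_p = min(per_model[n].p_value for n in aggregation)
        best_model = next(
            n for n in aggregation if per_model[n].p_value == min_p
        )
        chrom, pos = gene_chrom[gene]
        results.append(
            GeneBurdenResult(
                gene=gene,
                chrom=chrom,
                pos=pos,
                per_model=per_model,
                min_p=min_p,
                best_model=best_model,
                tested=gene in tested_genes,
                significant=min_p < bonferroni,
                suggestive=min_p < suggestive_threshold,
            )
        )
    results.sort(key=lambda r: (_chrom_key(r.chrom), r.pos, r.gene))
    return results, summary


def results_frame(
    results: Sequence[GeneBurdenResult], summary: ScanSummary
) -> pd.DataFrame:
    """results.tsv layout: per-model carrier counts and P, then min_p,
    best_model and threshold flags."""
    model_names: list[str] = []
    for r in results:
        for n in r.per_model:
            if n not in model_names:
                model_names.append(n)
    rows = []
    for r in results:
        row: dict[str, object] = {
            "gene": r.gene,
            "chrom": r.chrom,
            "pos": r.pos,
        }
        for n in model_names:
            mr = r.per_model.get(n)
            row[f"{n}_case_carriers"] = mr.case_carriers if mr else 0
            row[f"{n}_control_carriers"] = mr.control_carriers if mr else 0
            row[f"{n}_p"] = mr.p_value if mr else 1.0
        row["min_p"] = r.min_p
        row["best_model"] = r.best_model
        row["tested"] = r.tested
        row["significant"] = r.significant
        row["suggestive"] = r.suggestive
        rows.append(row)
    return pd.DataFrame(rows)


def export_manhattan_table(
    results: Sequence[GeneBurdenResult], summary: ScanSummary
) -> pd.DataFrame:
    """Manhattan-plot input: gene, position, -log10(min P), flags."""
    if not results:
        raise ValueError("no results to export")
    tiny = np.finfo(float).tiny
    rows = [
        {
            "gene": r.gene,
            "chrom": r.chrom,
            "pos": r.pos,
            "minus_log10_min_p": -math.log10(max(r.min_p, tiny)),
            "significant": r.min_p < summary.bonferroni_threshold,
            "suggestive": r.min_p < summary.suggestive_threshold,
        }
        for r in results
    ]
    return pd.DataFrame(rows)
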