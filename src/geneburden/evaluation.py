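"""Cohort-level summaries and operating-characteristic experiments.

Covers three things: diagnostic-yield summaries (and Fisher comparisons
between testing strategies), the 17-column clinical feature matrix that
feeds a penalised yield predictor (HPO mean specificity, HPO count,
seven movement-disorder subgroup indicators, gender, seven age bins),
and Monte-Carlo estimation of the burden scan's type-I error and power
on simulated cohorts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from decimal import Decimal, ROUND_HALF_UP
from typing import Mapping, Sequence

import math

import numpy as np
import pandas as pd

from .burden import (
    ContingencyTable,
    NoTestableGenesError,
    fisher_exact_two_sided,
    run_burden_scan,
)
from .cohort_io import SampleRecord
from .ontology import AnnotationSet, TermStat, mean_specificity
from .qualification import ModelSpec
from .synthetic_cohort import SimConfig, simulate_cohort

logger = logging.getLogger(__name__)

__all__ = [
    "YieldSummary",
    "diagnostic_yield",
    "compare_yields",
    "FEATURE_COLUMNS",
    "AGE_BINS",
    "build_feature_matrix",
    "OperatingCharacteristics",
    "estimate_operating_characteristics",
]


@dataclass(frozen=True)
class YieldSummary:
    label: str
    n_total: int
    n_solved: int
    percent: float


def diagnostic_yield(
    n_solved: int, n_total: int, label: str = "", decimals: int = 1
) -> YieldSummary:
    """Solved fraction as a percentage, rounded half-away-from-zero."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not (0 <= n_solved <= n_total):
        raise ValueError("n_solved must be in [0, n_total]")
    pct = Decimal(100 * n_solved) / Decimal(n_total)
    q = Decimal(1).scaleb(-decimals)
    percent = float(pct.quantize(q, rounding=ROUND_HALF_UP))
    return YieldSummary(
        label=label, n_total=n_total, n_solved=n_solved, percent=percent
    )


def compare_yields(
    a_solved: int, a_total: int, b_solved: int, b_total: int
) -> float:
    """Two-sided Fisher exact comparison of two solved/total yields."""
    t = ContingencyTable(
        a=a_solved, b=a_total - a_solved, c=b_solved, d=b_total - b_solved
    )
    return fisher_exact_two_sided(t)


# ---------------------------------------------------------------------------
# Feature matrix

AGE_BINS: tuple[tuple[float, float], ...] = (
    (0, 5),
    (5, 20),
    (20, 30),
    (30, 40),
    (40, 50),
    (50, 60),
    (60, 100),
)

_SUBGROUP_ORDER = (
    "ataxia",
    "spasticity",
    "dystonia",
    "ataxia/dystonia",
    "ataxia/spasticity",
    "dystonia/spasticity",
    "ataxia/dystonia/spasticity",
)

FEATURE_COLUMNS: tuple[str, ...] = (
    ("hpo_mean", "hpo_count")
    + tuple(f"subgroup_{s.replace('/', '_')}" for s in _SUBGROUP_ORDER)
    + ("gender",)
    + tuple(f"age_{int(lo)}_{int(hi)}" for lo, hi in AGE_BINS)
)


def _age_bin_index(age: float) -> int | None:
    """Half-open bins [lo, hi); the last bin is closed at 100."""
    for i, (lo, hi) in enumerate(AGE_BINS):
        last = i == len(AGE_BINS) - 1
        if lo <= age < hi or (last and age == hi):
            return i
    return None


def build_feature_matrix(
    samples: Sequence[SampleRecord],
    term_stats: Mapping[str, TermStat],
    gender_coding: str = "male",
) -> pd.DataFrame:
    """The 17-feature clinical matrix, one row per sample.

    hpo_mean is the mean relative height of the sample's terms; the
    subgroup and age-bin indicator blocks are one-hot. ``gender_coding``
    selects which sex codes as 1. Samples without terms get hpo_mean 0
    and without a usable age get all age bins 0 (both logged).
    """
    if gender_coding not in {"male", "female"}:
        raise ValueError("gender_coding must be 'male' or 'female'")
    rows = []
    n_no_terms = n_no_age = 0
    for s in samples:
        missing = [t for t in s.hpo_terms if t not in term_stats]
        if missing:
            raise KeyError(
                f"sample {s.sample_id}: no term statistics for "
                + ", ".join(sorted(missing))
            )
        if s.hpo_terms:
            aset = AnnotationSet(s.sample_id, frozenset(s.hpo_terms))
            hpo_mean = mean_specificity(aset, term_stats)
        else:
            hpo_mean = 0.0
            n_no_terms += 1
        row: dict[str, object] = {
            "sample_id": s.sample_id,
            "hpo_mean": hpo_mean,
            "hpo_count": len(set(s.hpo_terms)),
        }
        for sg in _SUBGROUP_ORDER:
            row[f"subgroup_{sg.replace('/', '_')}"] = int(s.subgroup == sg)
        row["gender"] = int(s.sex == gender_coding)
        bin_idx = (
            None
            if s.age_at_testing is None
            else _age_bin_index(s.age_at_testing)
        )
        if bin_idx is None:
            n_no_age += 1
        for i, (lo, hi) in enumerate(AGE_BINS):
            row[f"age_{int(lo)}_{int(hi)}"] = int(bin_idx == i)
        rows.append(row)
    if n_no_terms:
        logger.warning(
            "build_feature_matrix: %d sample(s) without HPO terms", n_no_terms
        )
    if n_no_age:
        logger.warning(
            "build_feature_matrix: %d sample(s) without usable age", n_no_age
        )
    df = pd.DataFrame(rows).set_index("sample_id")
    return df[list(FEATURE_COLUMNS)]


# ---------------------------------------------------------------------------
# Operating characteristics on simulated cohorts


@dataclass(frozen=True)
class OperatingCharacteristics:
    alpha: float
    n_replicates: int
    n_null_gene_tests: int
    type1_rate: float
    type1_se: float
    power: dict[str, float]
    power_se: dict[str, float]


def estimate_operating_characteristics(
    sim_config: SimConfig,
    n_replicates: int,
    alpha: float = 0.05,
    models: Sequence[ModelSpec] | None = None,
    aggregation_models: Sequence[str] | None = None,
) -> OperatingCharacteristics:
    """Monte-Carlo type-I error and power of the burden scan.

    Per replicate a cohort is simulated with a seed derived from the
    config seed, scanned, and: the type-I rate is the fraction of (null
    gene, replicate) pairs whose min P is <= alpha (genes absent from
    the results count as P = 1); power per planted gene is the fraction
    of replicates in which it clears the scan's Bonferroni threshold.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    seeds = [
        int(s.generate_state(1)[0] % (2**31))
        for s in np.random.SeedSequence(sim_config.seed).spawn(n_replicates)
    ]
    n_null_hits = 0
    n_null_tests = 0
    planted_names = [p.gene for p in sim_config.planted_genes]
    hits = {g: 0 for g in planted_names}
    for r in range(n_replicates):
        cfg = replace(sim_config, seed=seeds[r])
        cohort = simulate_cohort(cfg)
        try:
            results, summary = run_burden_scan(
                cohort.samples,
                cohort.variants,
                cohort.cnvs,
                models=models,
                aggregation_models=aggregation_models,
                alpha=alpha,
            )
        except NoTestableGenesError:
            # nothing qualifies in this replicate: every gene counts as
            # P = 1 (no false positives, no power)
            n_null_tests += len(cohort.truth.null_gene_mafs)
            continue
        by_gene = {res.gene: res for res in results}
        null_genes = set(cohort.truth.null_gene_mafs)
        n_null_tests += len(null_genes)
        for g in null_genes:
            res = by_gene.get(g)
            if res is not None and res.min_p <= alpha:
                n_null_hits += 1
        for g in planted_names:
            res = by_gene.get(g)
            if res is not None and res.min_p < summary.bonferroni_threshold:
                hits[g] += 1
    type1 = n_null_hits / n_null_tests if n_null_tests else 0.0
    type1_se = (
        math.sqrt(type1 * (1 - type1) / n_null_tests) if n_null_tests else 0.0
    )
    power = {g: hits[g] / n_replicates for g in planted_names}
    power_se = {
        g: math.sqrt(power[g] * (1 - power[g]) / n_replicates)
        for g in planted_names
    }
    return OperatingCharacteristics(
        alpha=alpha,
        n_replicates=n_replicates,
        n_null_gene_tests=n_null_tests,
        type1_rate=type1,
        type1_se=type1_se,
        power=power,
        power_se=power_se,
    )
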