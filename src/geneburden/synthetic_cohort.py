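"""Seeded synthetic cohorts with the structure the burden scan assumes.

The generator emulates a case-control sequencing cohort: null genes
whose rare-variant carrier frequencies are identical in cases and
controls (Hardy-Weinberg genotype draws on autosomes; on chrX males are
hemizygous carriers with probability equal to the allele frequency),
one or more planted risk genes carrying ultra-rare loss-of-function
variants (the archetype: X-linked PTVs, hemizygous in males, absent
from population databases), noisy CNV calls with quality metrics, and
phenotype-ontology annotation sets of tunable specificity.

Defaults mirror the study cohort the scan is designed for: 2287 cases
and 10,845 controls. Planted genes support two modes — ``fraction``
(binomial carrier draws per group) and ``exact`` (a fixed number of
carriers assigned per group), the latter for reproducing worked
examples such as 7 case carriers vs 0 control carriers.

Everything is driven by one mandatory seed; per-table substreams are
spawned from it so, e.g., changing CNV noise does not perturb the
variant draws. Identical configs produce byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .cohort_io import (
    CnvCall,
    SampleRecord,
    SmallVariant,
    write_cnv_table,
    write_sample_manifest,
    write_variant_table,
)
from .ontology import OntologyGraph

__all__ = [
    "PlantedGeneSpec",
    "CnvNoiseConfig",
    "HpoConfig",
    "SimConfig",
    "SimTruth",
    "Cohort",
    "simulate_cohort",
    "simulate_hpo_annotations",
    "balanced_ontology",
    "sim_config_from_dict",
    "sim_config_to_dict",
]

_SUBGROUPS = (
    "ataxia",
    "spasticity",
    "dystonia",
    "ataxia/dystonia",
    "ataxia/spasticity",
    "dystonia/spasticity",
    "ataxia/dystonia/spasticity",
)


@dataclass(frozen=True)
class PlantedGeneSpec:
    """A risk gene with group-specific carrier rates.

    mode='fraction': carriers per group are Binomial(n_group, fraction).
    mode='exact': exactly case_carriers / control_carriers samples are
    assigned (error if they exceed the eligible group size).
    """

    gene: str
    chromosome: str = "X"  # 'X' or an autosome name like '5'
    mode: str = "fraction"
    case_carrier_fraction: float = 0.0
    control_carrier_fraction: float = 0.0
    case_carriers: int = 0
    control_carriers: int = 0
    consequence: str = "stop_gained"
    maf: float | None = None  # planted PTVs default to missing MAF

    def __post_init__(self) -> None:
        if self.mode not in {"fraction", "exact"}:
            raise ValueError(f"unknown planting mode {self.mode!r}")
        for f in (self.case_carrier_fraction, self.control_carrier_fraction):
            if not (0.0 <= f <= 1.0):
                raise ValueError(f"carrier fraction {f} outside [0, 1]")


@dataclass(frozen=True)
class CnvNoiseConfig:
    rate_per_sample: float = 0.02
    homozygous_fraction: float = 0.5  # copy number 0 vs 1
    log_likelihood_mean: float = 12.0  # exponential mean
    correlation_low: float = 0.3
    correlation_high: float = 1.0
    polymorphism_fraction: float = 0.2
    inhouse_maf_missing_fraction: float = 0.5


@dataclass(frozen=True)
class HpoConfig:
    terms_per_patient: float = 6.0
    fixed_terms: bool = False  # True: exactly terms_per_patient terms
    specificity_bias: float = 0.7  # walk-continuation probability


@dataclass(frozen=True)
class SimConfig:
    seed: int
    n_cases: int = 2287
    n_controls: int = 10845
    n_genes: int = 50
    male_fraction: float = 0.5
    x_gene_fraction: float = 0.05
    variants_per_gene: float = 3.0
    maf_low: float = 1e-5
    maf_high: float = 0.05
    ptv_fraction: float = 0.3
    cadd_mean: float = 20.0
    cadd_sd: float = 8.0
    es_fraction: float = 0.85
    planted_genes: tuple[PlantedGeneSpec, ...] = ()
    cnv: CnvNoiseConfig = field(default_factory=CnvNoiseConfig)
    hpo: HpoConfig = field(default_factory=HpoConfig)

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for n in (self.n_cases, self.n_controls, self.n_genes):
            if n < 0:
                raise ValueError("counts must be non-negative")
        for f in (self.male_fraction, self.ptv_fraction, self.es_fraction):
            if not (0.0 <= f <= 1.0):
                raise ValueError(f"fraction {f} outside [0, 1]")
        if not (0.0 < self.maf_low <= self.maf_high <= 0.05):
            raise ValueError("MAF range must satisfy 0 < low <= high <= 0.05")


@dataclass
class SimTruth:
    """Ground truth consistent with the emitted tables."""

    planted: dict[str, dict[str, list[str]]]
    null_gene_mafs: dict[str, list[float]]

    def to_json(self) -> str:
        return json.dumps(
            {"planted": self.planted, "null_gene_mafs": self.null_gene_mafs},
            indent=2,
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "SimTruth":
        d = json.loads(text)
        return cls(planted=d["planted"], null_gene_mafs=d["null_gene_mafs"])


@dataclass
class Cohort:
    samples: list[SampleRecord]
    variants: list[SmallVariant]
    cnvs: list[CnvCall]
    truth: SimTruth

    def write(self, outdir: str | Path, header_lines: Sequence[str] = ()) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_sample_manifest(self.samples, outdir / "samples.tsv", header_lines)
        write_variant_table(self.variants, outdir / "variants.tsv", header_lines)
        write_cnv_table(self.cnvs, outdir / "cnvs.tsv", header_lines)
        (outdir / "truth.json").write_text(self.truth.to_json() + "\n")


def _substreams(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def simulate_cohort(config: SimConfig) -> Cohort:
    """Generate samples, small variants, CNV calls and ground truth."""
    rng_samples, rng_variants, rng_planted, rng_cnv = _substreams(
        config.seed, 4
    )

    # --- samples -----------------------------------------------------------
    n_total = config.n_cases + config.n_controls
    ids = [f"case{i + 1:05d}" for i in range(config.n_cases)] + [
        f"ctrl{i + 1:05d}" for i in range(config.n_controls)
    ]
    male = rng_samples.random(n_total) < config.male_fraction
    ages = np.round(rng_samples.uniform(5.0, 80.0, n_total), 1)
    es = rng_samples.random(n_total) < config.es_fraction
    subgroup_idx = rng_samples.integers(0, len(_SUBGROUPS), n_total)
    samples = [
        SampleRecord(
            sample_id=ids[i],
            sex="male" if male[i] else "female",
            group="case" if i < config.n_cases else "control",
            assay="ES" if es[i] else "GS",
            age_at_testing=float(ages[i]),
            subgroup=_SUBGROUPS[subgroup_idx[i]] if i < config.n_cases else None,
        )
        for i in range(n_total)
    ]

    # --- null genes --------------------------------------------------------
    planted_names = {p.gene for p in config.planted_genes}
    n_x = int(round(config.n_genes * config.x_gene_fraction))
    gene_chrom: dict[str, str] = {}
    positions: dict[str, int] = {}
    for g in range(config.n_genes):
        name = f"G{g + 1:04d}"
        if name in planted_names:
            raise ValueError(f"planted gene name {name} collides with a null gene")
        chrom = "X" if g < n_x else str((g - n_x) % 22 + 1)
        gene_chrom[name] = chrom
        positions[name] = 1_000_000 + g * 100_000

    variants: list[SmallVariant] = []
    null_gene_mafs: dict[str, list[float]] = {}
    male_arr = male
    for name, chrom in gene_chrom.items():
        nv = max(1, int(rng_variants.poisson(config.variants_per_gene)))
        mafs = np.exp(
            rng_variants.uniform(
                np.log(config.maf_low), np.log(config.maf_high), nv
            )
        )
        null_gene_mafs[name] = [float(m) for m in mafs]
        for j in range(nv):
            p = float(mafs[j])
            pos = positions[name] + j * 10
            is_ptv = rng_variants.random() < config.ptv_fraction
            consequence = (
                "stop_gained" if is_ptv else "missense_variant"
            )
            impact = "high" if is_ptv else "moderate"
            cadd = float(
                np.clip(
                    rng_variants.normal(config.cadd_mean, config.cadd_sd),
                    0.0,
                    60.0,
                )
            )
            u = rng_variants.random(n_total)
            if chrom == "X":
                p_hom = p * p
                p_het = 2.0 * p * (1.0 - p)
                genotype = np.full(n_total, "", dtype=object)
                genotype[male_arr & (u < p)] = "hemi"
                fem = ~male_arr
                genotype[fem & (u < p_hom)] = "hom"
                genotype[fem & (u >= p_hom) & (u < p_hom + p_het)] = "het"
            else:
                p_hom = p * p
                p_het = 2.0 * p * (1.0 - p)
                genotype = np.full(n_total, "", dtype=object)
                genotype[u < p_hom] = "hom"
                genotype[(u >= p_hom) & (u < p_hom + p_het)] = "het"
            (carrier_idx,) = np.nonzero(genotype != "")
            for i in carrier_idx:
                variants.append(
                    SmallVariant(
                        sample_id=ids[i],
                        chrom=chrom,
                        pos=pos,
                        ref="A",
                        alt="T",
                        gene=name,
                        genotype=str(genotype[i]),
                        consequence=consequence,
                        impact=impact,
                        cadd=round(cadd, 2),
                        maf=round(p, 8),
                        quality_pass=True,
                    )
                )

    # --- planted genes -----------------------------------------------------
    planted_truth: dict[str, dict[str, list[str]]] = {}
    case_ids = np.asarray(ids[: config.n_cases])
    ctrl_ids = np.asarray(ids[config.n_cases :])
    case_male = male_arr[: config.n_cases]
    ctrl_male = male_arr[config.n_cases :]
    for k, spec in enumerate(config.planted_genes):
        on_x = spec.chromosome.upper() in {"X", "CHRX"}
        chrom = "X" if on_x else spec.chromosome
        pos = 150_000_000 + k * 100_000
        elig_case = case_ids[case_male] if on_x else case_ids
        elig_ctrl = ctrl_ids[ctrl_male] if on_x else ctrl_ids
        if spec.mode == "exact":
            if spec.case_carriers > elig_case.size or (
                spec.control_carriers > elig_ctrl.size
            ):
                raise ValueError(
                    f"planted gene {spec.gene}: requested carriers exceed "
                    "eligible group size"
                )
            chosen_case = rng_planted.choice(
                elig_case, size=spec.case_carriers, replace=False
            )
            chosen_ctrl = rng_planted.choice(
                elig_ctrl, size=spec.control_carriers, replace=False
            )
        else:
            chosen_case = elig_case[
                rng_planted.random(elig_case.size) < spec.case_carrier_fraction
            ]
            chosen_ctrl = elig_ctrl[
                rng_planted.random(elig_ctrl.size)
                < spec.control_carrier_fraction
            ]
        planted_truth[spec.gene] = {
            "case_carriers": sorted(str(s) for s in chosen_case),
            "control_carriers": sorted(str(s) for s in chosen_ctrl),
        }
        sex_of = dict(zip(ids, male_arr))
        for sid in list(chosen_case) + list(chosen_ctrl):
            sid = str(sid)
            genotype = "hemi" if on_x and sex_of[sid] else "het"
            if on_x and not sex_of[sid]:
                genotype = "hom"  # female carriers counted recessively
            variants.append(
                SmallVariant(
                    sample_id=sid,
                    chrom=chrom,
                    pos=pos,
                    ref="C",
                    alt="T",
                    gene=spec.gene,
                    genotype=genotype,
                    consequence=spec.consequence,
                    impact="high",
                    cadd=None,
                    maf=spec.maf,
                    quality_pass=True,
                )
            )

    # --- CNV noise ---------------------------------------------------------
    cnvs: list[CnvCall] = []
    cfg = config.cnv
    n_cnvs = int(rng_cnv.poisson(cfg.rate_per_sample * n_total))
    all_genes = list(gene_chrom) + [p.gene for p in config.planted_genes]
    gene_chrom_all = dict(gene_chrom)
    for k, spec in enumerate(config.planted_genes):
        gene_chrom_all[spec.gene] = (
            "X" if spec.chromosome.upper() in {"X", "CHRX"} else spec.chromosome
        )
        positions[spec.gene] = 150_000_000 + k * 100_000
    assay_of = {s.sample_id: s.assay for s in samples}
    for _ in range(n_cnvs):
        sid = ids[int(rng_cnv.integers(0, n_total))]
        gene = all_genes[int(rng_cnv.integers(0, len(all_genes)))]
        start = positions[gene] - 500
        end = positions[gene] + 500
        cn = 0 if rng_cnv.random() < cfg.homozygous_fraction else 1
        ll = float(rng_cnv.exponential(cfg.log_likelihood_mean))
        corr = float(
            rng_cnv.uniform(cfg.correlation_low, cfg.correlation_high)
        )
        poly = bool(rng_cnv.random() < cfg.polymorphism_fraction)
        if rng_cnv.random() < cfg.inhouse_maf_missing_fraction:
            maf = None
        else:
            maf = float(np.exp(rng_cnv.uniform(np.log(1e-4), np.log(0.05))))
        cnvs.append(
            CnvCall(
                sample_id=sid,
                chrom=gene_chrom_all[gene],
                start=start,
                end=end,
                genes=(gene,),
                copy_number=cn,
                log_likelihood=round(ll, 2),
                reference_correlation=round(corr, 3),
                assay=assay_of[sid],
                polymorphism_overlap=poly,
                inhouse_maf=None if maf is None else round(maf, 6),
            )
        )

    truth = SimTruth(planted=planted_truth, null_gene_mafs=null_gene_mafs)
    return Cohort(samples=samples, variants=variants, cnvs=cnvs, truth=truth)


def simulate_hpo_annotations(
    config: HpoConfig,
    graph: OntologyGraph,
    sample_ids: Sequence[str],
    seed: int,
) -> dict[str, tuple[str, ...]]:
    """Sample per-patient term sets by biased random walks from the root.

    Each term is drawn by descending one mandatory step from the root
    (phenotype annotations are never the root itself) and then
    continuing downward with probability ``specificity_bias`` while
    children exist. Higher bias yields stochastically deeper — more
    specific — terms.
    """
    if len(graph) == 0:
        raise ValueError("empty ontology")
    if not graph.children[graph.root]:
        raise ValueError("root has no children; nothing to annotate with")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    out: dict[str, tuple[str, ...]] = {}
    for sid in sample_ids:
        if config.fixed_terms:
            k = int(config.terms_per_patient)
        else:
            k = max(1, int(rng.poisson(config.terms_per_patient)))
        terms: set[str] = set()
        for _ in range(k):
            node = graph.root
            kids = sorted(graph.children[node])
            node = kids[int(rng.integers(0, len(kids)))]
            while True:
                kids = sorted(graph.children[node])
                if not kids or rng.random() >= config.specificity_bias:
                    break
                node = kids[int(rng.integers(0, len(kids)))]
            terms.add(node)
        out[sid] = tuple(sorted(terms))
    return out


def balanced_ontology(
    depth: int = 4, branching: int = 3, prefix: str = "T"
) -> OntologyGraph:
    """A deterministic balanced-tree toy ontology for simulations and
    examples (``branching**depth`` leaves; ids encode the path)."""
    parents: dict[str, set[str]] = {f"{prefix}:root": set()}
    frontier = [f"{prefix}:root"]
    for _ in range(depth):
        nxt = []
        for node in frontier:
            for b in range(branching):
                child = f"{node}.{b}"
                parents[child] = {node}
                nxt.append(child)
        frontier = nxt
    return OntologyGraph(parents)


# ---------------------------------------------------------------------------
# YAML-friendly config round-trip


def sim_config_to_dict(config: SimConfig) -> dict:
    d = asdict(config)
    d["planted_genes"] = [asdict(p) for p in config.planted_genes]
    return d


def sim_config_from_dict(d: Mapping) -> SimConfig:
    d = dict(d)
    if "planted_genes" in d:
        d["planted_genes"] = tuple(
            p if isinstance(p, PlantedGeneSpec) else PlantedGeneSpec(**p)
            for p in d["planted_genes"]
        )
    if "cnv" in d and not isinstance(d["cnv"], CnvNoiseConfig):
        d["cnv"] = CnvNoiseConfig(**d["cnv"])
    if "hpo" in d and not isinstance(d["hpo"], HpoConfig):
        d["hpo"] = HpoConfig(**d["hpo"])
    return SimConfig(**d)
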