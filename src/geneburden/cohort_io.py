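"""Readers and writers for all cohort artifacts.

Canonical exchange format is TSV (sample manifest, annotated
small-variant table, CNV call table) plus BED3 for the cross-assay
region mask; a minimal single-sample VCF ingestion path is provided as
a convenience for already-annotated VCFs. Coordinates follow the usual
conventions: variants are 1-based (VCF), intervals 0-based half-open
(BED).

Missing-value policy: an absent population MAF means "absent from the
population databases", i.e. likely ultra-rare, and therefore *passes*
MAF filters downstream; an absent CADD score *fails* the deleterious
missense rule. Readers consequently parse empty cells as missing, never
as zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SchemaError",
    "RowError",
    "SampleRecord",
    "SmallVariant",
    "CnvCall",
    "RegionMask",
    "SEXES",
    "GROUPS",
    "ASSAYS",
    "SUBGROUPS",
    "PAR_GRCH38",
    "read_sample_manifest",
    "write_sample_manifest",
    "read_variant_table",
    "write_variant_table",
    "read_cnv_table",
    "write_cnv_table",
    "read_region_bed",
    "apply_region_mask",
    "ingest_vcf",
    "is_x_nonpar",
]


class SchemaError(ValueError):
    """Input file is missing a required column."""


class RowError(ValueError):
    """A row violates a field constraint (message carries the row number)."""


SEXES = frozenset({"male", "female", "unknown"})
GROUPS = frozenset({"case", "control"})
ASSAYS = frozenset({"ES", "GS"})
SUBGROUPS = frozenset(
    {
        "ataxia",
        "spasticity",
        "dystonia",
        "ataxia/dystonia",
        "ataxia/spasticity",
        "dystonia/spasticity",
        "ataxia/dystonia/spasticity",
    }
)
GENOTYPES = frozenset({"het", "hom", "hemi"})
IMPACTS = frozenset({"high", "moderate", "low", "modifier"})

# GRCh38 pseudoautosomal regions on chrX, 1-based inclusive
PAR_GRCH38: tuple[tuple[int, int], ...] = (
    (10_001, 2_781_479),
    (155_701_383, 156_030_895),
)

_HEMI_CONTIGS = frozenset({"X", "Y", "chrX", "chrY", "MT", "chrM", "chrMT"})


def _norm_chrom(chrom: str) -> str:
    return chrom[3:] if chrom.lower().startswith("chr") else chrom


def is_x_nonpar(
    chrom: str, pos: int, par: Sequence[tuple[int, int]] = PAR_GRCH38
) -> bool:
    """True for a 1-based position on chrX outside the pseudoautosomal
    regions (default coordinates: GRCh38)."""
    if _norm_chrom(chrom) != "X":
        return False
    return not any(lo <= pos <= hi for lo, hi in par)


@dataclass(frozen=True)
class SampleRecord:
    sample_id: str
    sex: str
    group: str
    assay: str
    hpo_terms: tuple[str, ...] = ()
    age_at_testing: float | None = None
    subgroup: str | None = None

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise RowError(f"sample {self.sample_id}: unknown sex {self.sex!r}")
        if self.group not in GROUPS:
            raise RowError(
                f"sample {self.sample_id}: unknown group {self.group!r}"
            )
        if self.assay not in ASSAYS:
            raise RowError(
                f"sample {self.sample_id}: unknown assay {self.assay!r}"
            )
        if self.subgroup is not None and self.subgroup not in SUBGROUPS:
            raise RowError(
                f"sample {self.sample_id}: unknown subgroup {self.subgroup!r}"
            )


@dataclass(frozen=True)
class SmallVariant:
    sample_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    genotype: str
    consequence: str
    impact: str
    cadd: float | None = None
    maf: float | None = None
    quality_pass: bool = True

    def __post_init__(self) -> None:
        if self.genotype not in GENOTYPES:
            raise RowError(f"unknown genotype {self.genotype!r}")
        if self.impact not in IMPACTS:
            raise RowError(f"unknown impact {self.impact!r}")
        if self.maf is not None and not (0.0 <= self.maf <= 1.0):
            raise RowError(f"MAF {self.maf} outside [0, 1]")
        if self.genotype == "hemi" and self.chrom not in _HEMI_CONTIGS:
            raise RowError(
                f"hemizygous genotype on non-hemizygous contig {self.chrom}"
            )
        if self.pos < 1:
            raise RowError(f"position {self.pos} is not 1-based")


@dataclass(frozen=True)
class CnvCall:
    sample_id: str
    chrom: str
    start: int  # 0-based half-open
    end: int
    genes: tuple[str, ...]
    copy_number: int
    log_likelihood: float
    reference_correlation: float
    assay: str
    polymorphism_overlap: bool = False
    inhouse_maf: float | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise RowError(
                f"CNV interval start {self.start} >= end {self.end}"
            )
        if self.copy_number < 0:
            raise RowError(f"negative copy number {self.copy_number}")
        if not (-1.0 <= self.reference_correlation <= 1.0):
            raise RowError(
                f"reference correlation {self.reference_correlation} "
                "outside [-1, 1]"
            )
        if self.assay not in ASSAYS:
            raise RowError(f"unknown assay {self.assay!r}")


class RegionMask:
    """Per-chromosome merged, sorted 0-based half-open intervals."""

    def __init__(
        self, intervals: Mapping[str, Iterable[tuple[int, int]]] | None = None
    ) -> None:
        self.intervals: dict[str, np.ndarray] = {}
        for chrom, ivs in (intervals or {}).items():
            merged = self._merge(list(ivs))
            if merged.size:
                self.intervals[_norm_chrom(chrom)] = merged

    @staticmethod
    def _merge(ivs: list[tuple[int, int]]) -> np.ndarray:
        for start, end in ivs:
            if start >= end:
                raise RowError(f"interval start {start} >= end {end}")
        ivs = sorted(ivs)
        merged: list[list[int]] = []
        for start, end in ivs:
            if merged and start <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], end)
            else:
                merged.append([start, end])
        return np.asarray(merged, dtype=np.int64).reshape(-1, 2)

    def __bool__(self) -> bool:
        return bool(self.intervals)

    def contains(self, chrom: str, pos0: int) -> bool:
        """Membership of a 0-based position."""
        ivs = self.intervals.get(_norm_chrom(chrom))
        if ivs is None:
            return False
        i = np.searchsorted(ivs[:, 0], pos0, side="right") - 1
        return i >= 0 and pos0 < ivs[i, 1]

    def total_length(self) -> int:
        return int(
            sum((ivs[:, 1] - ivs[:, 0]).sum() for ivs in self.intervals.values())
        )


# ---------------------------------------------------------------------------
# TSV readers / writers

SAMPLE_COLUMNS = [
    "sample_id",
    "sex",
    "group",
    "assay",
    "age_at_testing",
    "subgroup",
    "hpo_terms",
]
VARIANT_COLUMNS = [
    "sample_id",
    "chrom",
    "pos",
    "ref",
    "alt",
    "gene",
    "genotype",
    "consequence",
    "impact",
    "cadd",
    "maf",
    "quality_pass",
]
CNV_COLUMNS = [
    "sample_id",
    "chrom",
    "start",
    "end",
    "genes",
    "copy_number",
    "log_likelihood",
    "reference_correlation",
    "assay",
    "polymorphism_overlap",
    "inhouse_maf",
]


def _read_tsv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", dtype=str, keep_default_na=False, comment="#"
    )
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path}: missing required column(s): {', '.join(missing)}"
        )
    return df


def _opt_float(value: str, what: str, row: int) -> float | None:
    if value == "":
        return None
    try:
        return float(value)
    except ValueError:
        raise RowError(f"row {row}: bad {what} value {value!r}") from None


def _bool(value: str, what: str, row: int) -> bool:
    v = value.strip().lower()
    if v in {"true", "1", "yes"}:
        return True
    if v in {"false", "0", "no", ""}:
        return False
    raise RowError(f"row {row}: bad {what} value {value!r}")


def read_sample_manifest(path: str | Path) -> list[SampleRecord]:
    """Read samples.tsv. Vocabularies are case-insensitive; HPO terms
    are ';'-separated; duplicate sample ids are rejected."""
    df = _read_tsv(path, SAMPLE_COLUMNS[:4])
    records: list[SampleRecord] = []
    seen: set[str] = set()
    for i, row in enumerate(df.itertuples(index=False), start=2):
        d = row._asdict()
        sid = d["sample_id"]
        if sid in seen:
            raise RowError(f"row {i}: duplicate sample_id {sid!r}")
        seen.add(sid)
        terms = tuple(
            t for t in d.get("hpo_terms", "").split(";") if t.strip()
        )
        subgroup = d.get("subgroup", "").strip().lower() or None
        try:
            records.append(
                SampleRecord(
                    sample_id=sid,
                    sex=d["sex"].strip().lower(),
                    group=d["group"].strip().lower(),
                    assay=d["assay"].strip().upper(),
                    hpo_terms=terms,
                    age_at_testing=_opt_float(
                        d.get("age_at_testing", ""), "age_at_testing", i
                    ),
                    subgroup=subgroup,
                )
            )
        except RowError as exc:
            raise RowError(f"row {i}: {exc}") from None
    return records


def write_sample_manifest(
    records: Sequence[SampleRecord],
    path: str | Path,
    header_lines: Sequence[str] = (),
) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("\t".join(SAMPLE_COLUMNS) + "\n")
        for r in records:
            age = "" if r.age_at_testing is None else _fmt_num(r.age_at_testing)
            fh.write(
                "\t".join(
                    [
                        r.sample_id,
                        r.sex,
                        r.group,
                        r.assay,
                        age,
                        r.subgroup or "",
                        ";".join(r.hpo_terms),
                    ]
                )
                + "\n"
            )


def _fmt_num(x: float) -> str:
    """Round-trip-safe numeric formatting (ints stay integral)."""
    if x == int(x) and abs(x) < 1e15:
        return str(int(x))
    return repr(float(x))


def read_variant_table(
    path: str | Path, samples: Sequence[SampleRecord] | None = None
) -> list[SmallVariant]:
    """Read variants.tsv; empty cadd/maf cells parse as missing.

    If ``samples`` is given, hemizygous calls are additionally checked
    to belong to male samples.
    """
    df = _read_tsv(path, VARIANT_COLUMNS)
    sex_of = {s.sample_id: s.sex for s in samples or ()}
    out: list[SmallVariant] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        d = row._asdict()
        try:
            v = SmallVariant(
                sample_id=d["sample_id"],
                chrom=d["chrom"],
                pos=int(d["pos"]),
                ref=d["ref"],
                alt=d["alt"],
                gene=d["gene"],
                genotype=d["genotype"].strip().lower(),
                consequence=d["consequence"].strip().lower(),
                impact=d["impact"].strip().lower(),
                cadd=_opt_float(d["cadd"], "cadd", i),
                maf=_opt_float(d["maf"], "maf", i),
                quality_pass=_bool(d["quality_pass"], "quality_pass", i),
            )
        except (RowError, ValueError) as exc:
            raise RowError(f"row {i}: {exc}") from None
        if (
            v.genotype == "hemi"
            and sex_of
            and sex_of.get(v.sample_id) == "female"
        ):
            raise RowError(
                f"row {i}: hemizygous call for female sample {v.sample_id}"
            )
        out.append(v)
    return out


def write_variant_table(
    variants: Sequence[SmallVariant],
    path: str | Path,
    header_lines: Sequence[str] = (),
) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("\t".join(VARIANT_COLUMNS) + "\n")
        for v in variants:
            fh.write(
                "\t".join(
                    [
                        v.sample_id,
                        v.chrom,
                        str(v.pos),
                        v.ref,
                        v.alt,
                        v.gene,
                        v.genotype,
                        v.consequence,
                        v.impact,
                        "" if v.cadd is None else _fmt_num(v.cadd),
                        "" if v.maf is None else _fmt_num(v.maf),
                        "true" if v.quality_pass else "false",
                    ]
                )
                + "\n"
            )


def read_cnv_table(path: str | Path) -> list[CnvCall]:
    df = _read_tsv(path, CNV_COLUMNS)
    out: list[CnvCall] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        d = row._asdict()
        try:
            out.append(
                CnvCall(
                    sample_id=d["sample_id"],
                    chrom=d["chrom"],
                    start=int(d["start"]),
                    end=int(d["end"]),
                    genes=tuple(
                        g for g in d["genes"].split(";") if g.strip()
                    ),
                    copy_number=int(d["copy_number"]),
                    log_likelihood=float(d["log_likelihood"]),
                    reference_correlation=float(d["reference_correlation"]),
                    assay=d["assay"].strip().upper(),
                    polymorphism_overlap=_bool(
                        d["polymorphism_overlap"], "polymorphism_overlap", i
                    ),
                    inhouse_maf=_opt_float(
                        d["inhouse_maf"], "inhouse_maf", i
                    ),
                )
            )
        except (RowError, ValueError) as exc:
            raise RowError(f"row {i}: {exc}") from None
    return out


def write_cnv_table(
    cnvs: Sequence[CnvCall],
    path: str | Path,
    header_lines: Sequence[str] = (),
) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("\t".join(CNV_COLUMNS) + "\n")
        for c in cnvs:
            fh.write(
                "\t".join(
                    [
                        c.sample_id,
                        c.chrom,
                        str(c.start),
                        str(c.end),
                        ";".join(c.genes),
                        str(c.copy_number),
                        _fmt_num(c.log_likelihood),
                        _fmt_num(c.reference_correlation),
                        c.assay,
                        "true" if c.polymorphism_overlap else "false",
                        ""
                        if c.inhouse_maf is None
                        else _fmt_num(c.inhouse_maf),
                    ]
                )
                + "\n"
            )


def read_region_bed(path: str | Path) -> RegionMask:
    """Read a BED3+ file into a merged, sorted region mask. An empty
    file yields an empty (disabled) mask."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for i, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise RowError(f"row {i}: BED line has <3 columns")
            chrom, start_s, end_s = fields[0], fields[1], fields[2]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise RowError(
                    f"row {i}: non-integer BED coordinates"
                ) from None
            if start >= end:
                raise RowError(f"row {i}: start {start} >= end {end}")
            by_chrom.setdefault(chrom, []).append((start, end))
    return RegionMask(by_chrom)


def apply_region_mask(
    variants: Sequence[SmallVariant], mask: RegionMask
) -> list[SmallVariant]:
    """Keep variants whose 0-based position (pos - 1) falls inside the
    mask. An empty mask keeps everything. Order-preserving."""
    if not mask:
        return list(variants)
    return [v for v in variants if mask.contains(v.chrom, v.pos - 1)]


# ---------------------------------------------------------------------------
# VCF ingestion

DEFAULT_ANNOTATION_KEYS = {
    "gene": "GENE",
    "consequence": "CSQ_CONSEQUENCE",
    "impact": "IMPACT",
    "cadd": "CADD",
    "maf": "GNOMAD_AF",
}


def _info_per_alt(value, alt_index: int, n_alt: int):
    """INFO values of Number=A arrive as tuples (numeric) or a single
    comma-joined string; pick the entry for the given alt, otherwise
    return the scalar unchanged."""
    if isinstance(value, (tuple, list)):
        return value[alt_index] if alt_index < len(value) else None
    if isinstance(value, str) and n_alt > 1:
        parts = value.split(",")
        if len(parts) == n_alt:
            return parts[alt_index]
    return value


def ingest_vcf(
    path: str | Path,
    sample_id: str,
    annotation_keys: Mapping[str, str] | None = None,
    sex: str = "unknown",
    par: Sequence[tuple[int, int]] = PAR_GRCH38,
) -> list[SmallVariant]:
    """Ingest a single-sample, already-annotated VCF.

    GT 0/1 maps to het, 1/1 to hom; a haploid GT, or a male hom call on
    chrX outside the pseudoautosomal regions, maps to hemi. Multiallelic
    records are split per alt. Records without a usable GT are skipped
    (counted in the log).
    """
    from cyvcf2 import VCF

    keys = dict(DEFAULT_ANNOTATION_KEYS)
    keys.update(annotation_keys or {})
    unknown = set(keys) - set(DEFAULT_ANNOTATION_KEYS)
    if unknown:
        raise SchemaError(
            f"unknown annotation key role(s): {', '.join(sorted(unknown))}"
        )

    vcf = VCF(str(path))
    out: list[SmallVariant] = []
    n_skipped = 0
    for record in vcf:
        gts = record.genotypes
        if not gts:
            n_skipped += 1
            continue
        alleles = [a for a in gts[0][:-1] if a is not None and a >= 0]
        if not alleles:
            n_skipped += 1
            continue
        haploid = len(alleles) == 1
        for alt_index, alt in enumerate(record.ALT):
            count = sum(1 for a in alleles if a == alt_index + 1)
            if count == 0:
                continue
            if haploid:
                genotype = "hemi"
            elif count >= 2:
                genotype = "hom"
            else:
                genotype = "het"
            if (
                genotype == "hom"
                and sex == "male"
                and is_x_nonpar(record.CHROM, record.POS, par)
            ):
                genotype = "hemi"

            def info(role: str):
                return _info_per_alt(
                    record.INFO.get(keys[role]), alt_index, len(record.ALT)
                )

            cadd = info("cadd")
            maf = info("maf")
            quality_pass = record.FILTER is None  # PASS or '.'
            out.append(
                SmallVariant(
                    sample_id=sample_id,
                    chrom=record.CHROM,
                    pos=record.POS,
                    ref=record.REF,
                    alt=alt,
                    gene=str(info("gene") or ""),
                    genotype=genotype,
                    consequence=str(info("consequence") or "").lower(),
                    impact=str(info("impact") or "modifier").lower(),
                    cadd=None if cadd is None else float(cadd),
                    maf=None if maf is None else float(maf),
                    quality_pass=quality_pass,
                )
            )
    if n_skipped:
        logger.warning(
            "ingest_vcf: skipped %d record(s) without usable GT", n_skipped
        )
    return out
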