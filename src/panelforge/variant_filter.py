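"""GATK-style hard-filter cascade and master-site-set construction.

Variants are classified as SNP / indel / mixed and judged against the
standard hard-filter thresholds (strict inequalities):

    SNPs:   QD < 2.0, MQ < 40.0, FS > 60.0, SOR > 3.0,
            MQRankSum < -12.5, ReadPosRankSum < -8.0
    INDELs: QD < 2.0, ReadPosRankSum < -20.0, InbreedingCoeff < -0.8,
            FS > 200.0, SOR > 10.0

A record fails iff any *present* annotation violates its clause; absent
annotations pass by default (the usual missing-annotation behaviour, switch
with ``missing_policy="fail"``).  Boundary values are non-violating.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF, Writer

from .panel_io import chrom_sort_key

__all__ = [
    "VariantRecord",
    "FilterVerdict",
    "FilterConfig",
    "SNP_THRESHOLDS",
    "INDEL_THRESHOLDS",
    "classify_variant",
    "hard_filter_snp",
    "hard_filter_indel",
    "filter_vcf",
    "merge_site_lists",
]

# (operator, cutoff): the record FAILS when  value <op> cutoff  holds.
SNP_THRESHOLDS: dict[str, tuple[str, float]] = {
    "QD": ("<", 2.0),
    "MQ": ("<", 40.0),
    "FS": (">", 60.0),
    "SOR": (">", 3.0),
    "MQRankSum": ("<", -12.5),
    "ReadPosRankSum": ("<", -8.0),
}
INDEL_THRESHOLDS: dict[str, tuple[str, float]] = {
    "QD": ("<", 2.0),
    "ReadPosRankSum": ("<", -20.0),
    "InbreedingCoeff": ("<", -0.8),
    "FS": (">", 200.0),
    "SOR": (">", 10.0),
}


@dataclass
class VariantRecord:
    """One VCF site: coordinates, alleles, INFO annotations, genotypes."""

    chrom: str
    pos: int
    ref: str
    alts: tuple[str, ...]
    annotations: dict[str, float] = field(default_factory=dict)
    genotypes: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if not self.ref or not self.alts or any(not a for a in self.alts):
            raise ValueError("ref and alts must be non-empty")
        if any(a == self.ref for a in self.alts):
            raise ValueError("alt allele equals ref")


@dataclass(frozen=True)
class FilterVerdict:
    passed: bool
    reasons: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        assert self.passed == (len(self.reasons) == 0)


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds and policies for :func:`filter_vcf`.

    ``mixed_policy``: "exclude" (default; mixed SNP/indel records are routed
    to neither output and counted separately) or "fail".
    ``missing_policy``: "pass" (absent annotations do not violate) or "fail".
    """

    snp_thresholds: dict[str, tuple[str, float]] = field(default_factory=lambda: dict(SNP_THRESHOLDS))
    indel_thresholds: dict[str, tuple[str, float]] = field(default_factory=lambda: dict(INDEL_THRESHOLDS))
    mixed_policy: str = "exclude"
    missing_policy: str = "pass"

    def __post_init__(self) -> None:
        if self.mixed_policy not in ("exclude", "fail"):
            raise ValueError(f"unknown mixed_policy {self.mixed_policy!r}")
        if self.missing_policy not in ("pass", "fail"):
            raise ValueError(f"unknown missing_policy {self.missing_policy!r}")


def classify_variant(record: VariantRecord) -> str:
    """snp iff ref and every alt are single bases; indel iff every ref/alt
    pair has differing lengths; mixed otherwise."""
    if len(record.ref) == 1 and all(len(a) == 1 for a in record.alts):
        return "snp"
    if all(len(a) != len(record.ref) for a in record.alts):
        return "indel"
    return "mixed"


def _apply_thresholds(
    record: VariantRecord,
    thresholds: dict[str, tuple[str, float]],
    missing_policy: str = "pass",
) -> FilterVerdict:
    reasons = []
    for key, (op, cutoff) in thresholds.items():
        value = record.annotations.get(key)
        if value is None:
            if missing_policy == "fail":
                reasons.append(key)
            continue
        try:
            value = float(value)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"non-numeric annotation value for {key!r}: {value!r}") from exc
        if np.isnan(value):
            if missing_policy == "fail":
                reasons.append(key)
            continue
        violated = value < cutoff if op == "<" else value > cutoff
        if violated:
            reasons.append(key)
    return FilterVerdict(passed=not reasons, reasons=tuple(reasons))


def hard_filter_snp(record: VariantRecord, config: FilterConfig | None = None) -> FilterVerdict:
    cfg = config or FilterConfig()
    return _apply_thresholds(record, cfg.snp_thresholds, cfg.missing_policy)


def hard_filter_indel(record: VariantRecord, config: FilterConfig | None = None) -> FilterVerdict:
    cfg = config or FilterConfig()
    return _apply_thresholds(record, cfg.indel_thresholds, cfg.missing_policy)


_ANNOTATION_KEYS = ("QD", "MQ", "FS", "SOR", "MQRankSum", "ReadPosRankSum", "InbreedingCoeff")


def _record_from_cyvcf2(variant) -> VariantRecord:
    ann = {}
    for key in _ANNOTATION_KEYS:
        val = variant.INFO.get(key)
        if val is not None:
            ann[key] = float(val)
    return VariantRecord(
        chrom=variant.CHROM,
        pos=variant.POS,
        ref=variant.REF,
        alts=tuple(variant.ALT),
        annotations=ann,
    )


def filter_vcf(
    in_vcf: str | Path,
    out_prefix: str | Path,
    config: FilterConfig | None = None,
) -> dict:
    """Route every record of ``in_vcf`` to <prefix>.pass.vcf or
    <prefix>.fail.vcf (mixed records excluded by default) and return a
    report with counts by class and by violated threshold.

    The partition property |pass| + |fail| + |mixed_excluded| = |input|
    holds for every run.
    """
    cfg = config or FilterConfig()
    out_prefix = str(out_prefix)
    vcf = VCF(str(in_vcf))
    pass_writer = Writer(out_prefix + ".pass.vcf", vcf)
    fail_writer = Writer(out_prefix + ".fail.vcf", vcf)

    counts = {
        "input": 0,
        "snp": {"pass": 0, "fail": 0},
        "indel": {"pass": 0, "fail": 0},
        "mixed": {"excluded": 0, "fail": 0},
        "fail_reasons": {},
    }
    multiallelic_snps = 0
    for variant in vcf:
        counts["input"] += 1
        rec = _record_from_cyvcf2(variant)
        klass = classify_variant(rec)
        if klass == "mixed":
            if cfg.mixed_policy == "exclude":
                counts["mixed"]["excluded"] += 1
                continue
            fail_writer.write_record(variant)
            counts["mixed"]["fail"] += 1
            continue
        if klass == "snp" and len(rec.alts) > 1:
            multiallelic_snps += 1
        verdict = (
            hard_filter_snp(rec, cfg) if klass == "snp" else hard_filter_indel(rec, cfg)
        )
        if verdict.passed:
            pass_writer.write_record(variant)
            counts[klass]["pass"] += 1
        else:
            fail_writer.write_record(variant)
            counts[klass]["fail"] += 1
            for r in verdict.reasons:
                counts["fail_reasons"][r] = counts["fail_reasons"].get(r, 0) + 1
    pass_writer.close()
    fail_writer.close()
    vcf.close()

    counts["multiallelic_snps_flagged"] = multiallelic_snps
    counts["pass_total"] = counts["snp"]["pass"] + counts["indel"]["pass"]
    counts["fail_total"] = (
        counts["snp"]["fail"] + counts["indel"]["fail"] + counts["mixed"]["fail"]
    )
    report_path = out_prefix + ".filter_report.json"
    Path(report_path).write_text(json.dumps(counts, indent=2))
    return counts


def merge_site_lists(vcf_paths: list[str | Path]) -> pd.DataFrame:
    """Positional union of sites from several VCFs, genotypes dropped.

    Keyed by (chrom, pos, ref, alt); duplicates collapse; the output is
    sorted by natural chromosome order then position.  Conflicting REF
    alleles at an identical (chrom, pos) indicate the inputs were not called
    against the same reference and raise a ValueError.
    """
    if not vcf_paths:
        raise ValueError("need at least one VCF")
    seen: set[tuple[str, int, str, str]] = set()
    ref_at: dict[tuple[str, int], str] = {}
    rows = []
    for path in vcf_paths:
        vcf = VCF(str(path))
        for variant in vcf:
            key_pos = (variant.CHROM, variant.POS)
            prior = ref_at.get(key_pos)
            if prior is not None and prior != variant.REF:
                raise ValueError(
                    f"conflicting REF alleles at {variant.CHROM}:{variant.POS} "
                    f"({prior!r} vs {variant.REF!r})"
                )
            ref_at[key_pos] = variant.REF
            for alt in variant.ALT:
                key = (variant.CHROM, variant.POS, variant.REF, alt)
                if key not in seen:
                    seen.add(key)
                    rows.append(key)
        vcf.close()
    df = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])
    if df.empty:
        return df
    df["_ck"] = df["chrom"].map(chrom_sort_key)
    df = df.sort_values(["_ck", "pos", "ref", "alt"]).drop(columns="_ck").reset_index(drop=True)
    return df


def write_sites_vcf(sites: pd.DataFrame, path: str | Path) -> None:
    """Sites-only VCF 4.2 (no genotype columns) from a merged site list."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=panelforge-sites\n")
        for chrom in sites["chrom"].drop_duplicates():
            end = int(sites.loc[sites["chrom"] == chrom, "pos"].max()) + 100
            fh.write(f"##contig=<ID={chrom},length={end}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for row in sites.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.pos}\t.\t{row.ref}\t{row.alt}\t.\t.\t.\n")
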