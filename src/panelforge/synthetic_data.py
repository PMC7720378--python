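"""Synthetic inputs for capture-panel design pipelines.

Everything downstream of this module (hard filtering, AIM selection, array
QC, probe design) consumes standard file formats — annotated VCFs, FASTA
references, delimited array-QC exports.  This module fabricates all of them
with *known* truth: multi-population diploid genotypes under the
Balding–Nichols model with a specified FST, GATK-style INFO annotations with
violations planted strictly inside the failing region of each threshold,
reference genomes with planted repeat families and near-homologous decoy
loci, and array sample/SNP tables with planted QC failures.  Every
generator returns a truth manifest so that downstream filter tests can
assert exact survivor counts rather than approximate ones.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "PopulationModel",
    "GenotypePanel",
    "GenomeSpec",
    "DecoySpec",
    "simulate_populations",
    "write_vcf",
    "write_populations_file",
    "simulate_reference",
    "write_fasta",
    "simulate_array_tables",
    "SNP_PASSING_RANGES",
    "SNP_FAILING_RANGES",
    "INDEL_PASSING_RANGES",
    "INDEL_FAILING_RANGES",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


# --------------------------------------------------------------------------
# population genotypes (Balding–Nichols)
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PopulationModel:
    """Generating parameters for a multi-population diploid cohort.

    ``fst`` is the Balding–Nichols differentiation parameter F: each
    population's allele frequency at a locus is drawn from
    ``Beta(p(1-F)/F, (1-p)(1-F)/F)`` around the ancestral frequency ``p``,
    so the expected pairwise FST between any two populations is F.
    """

    n_pops: int = 2
    n_per_pop: int = 50
    fst: float = 0.05
    anc_freq_range: tuple[float, float] = (0.1, 0.9)
    n_snps_per_chrom: int = 1000
    chrom_names: tuple[str, ...] = ("chr1",)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.fst < 1.0):
            raise ValueError(f"fst must be in [0, 1), got {self.fst}")
        if self.n_per_pop < 2:
            raise ValueError(f"n_per_pop must be >= 2, got {self.n_per_pop}")
        if self.n_pops < 1:
            raise ValueError("n_pops must be >= 1")
        lo, hi = self.anc_freq_range
        if not (0.0 < lo < hi < 1.0):
            raise ValueError(
                f"anc_freq_range must be strictly inside (0, 1), got {self.anc_freq_range}"
            )
        if self.n_snps_per_chrom < 1:
            raise ValueError("n_snps_per_chrom must be >= 1")
        if len(self.chrom_names) < 1:
            raise ValueError("need at least one chromosome")


@dataclass
class GenotypePanel:
    """A complete (no missing data) diploid genotype matrix with locus metadata.

    ``genotypes`` holds alternate-allele dosages (0/1/2), shape
    ``(n_samples, n_loci)``.  ``pop_labels`` aligns with rows, the locus
    arrays with columns.  ``pop_freq`` (populations x loci) stores the true
    per-population allele frequencies the genotypes were drawn from.
    """

    genotypes: np.ndarray
    sample_ids: list[str]
    pop_labels: list[str]
    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    anc_freq: np.ndarray
    pop_freq: np.ndarray

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_loci(self) -> int:
        return self.genotypes.shape[1]


def simulate_populations(model: PopulationModel) -> GenotypePanel:
    """Draw a diploid cohort under the Balding–Nichols model.

    For each locus an ancestral frequency p is drawn uniformly from
    ``model.anc_freq_range``; each population's frequency comes from the
    Beta distribution parameterized by (p, F); genotypes are Binomial(2, .).
    F = 0 bypasses the Beta draw entirely (every population frequency equals
    p exactly), avoiding the 0/0 in the Beta parameters.
    """
    rng = np.random.default_rng(model.seed)
    n_loci = model.n_snps_per_chrom * len(model.chrom_names)
    lo, hi = model.anc_freq_range
    p = rng.uniform(lo, hi, size=n_loci)

    F = model.fst
    if F == 0.0:
        pop_freq = np.tile(p, (model.n_pops, 1))
    else:
        scale = (1.0 - F) / F
        pop_freq = rng.beta(p * scale, (1.0 - p) * scale, size=(model.n_pops, n_loci))

    genotypes = np.empty((model.n_pops * model.n_per_pop, n_loci), dtype=np.int8)
    pop_labels: list[str] = []
    sample_ids: list[str] = []
    for k in range(model.n_pops):
        rows = slice(k * model.n_per_pop, (k + 1) * model.n_per_pop)
        genotypes[rows] = rng.binomial(2, pop_freq[k], size=(model.n_per_pop, n_loci))
        pop_labels += [f"pop{k + 1}"] * model.n_per_pop
        sample_ids += [f"pop{k + 1}_s{i + 1}" for i in range(model.n_per_pop)]

    chrom = np.repeat(np.asarray(model.chrom_names, dtype=object), model.n_snps_per_chrom)
    pos = np.tile(np.arange(1, model.n_snps_per_chrom + 1, dtype=np.int64) * 10, len(model.chrom_names))
    ref_idx = rng.integers(0, 4, size=n_loci)
    alt_idx = (ref_idx + rng.integers(1, 4, size=n_loci)) % 4
    ref = np.array([chr(_BASES[i]) for i in ref_idx], dtype=object)
    alt = np.array([chr(_BASES[i]) for i in alt_idx], dtype=object)

    return GenotypePanel(
        genotypes=genotypes,
        sample_ids=sample_ids,
        pop_labels=pop_labels,
        chrom=chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        anc_freq=p,
        pop_freq=pop_freq,
    )


# --------------------------------------------------------------------------
# annotated VCF output with planted hard-filter violations
# --------------------------------------------------------------------------

# Passing draws sit comfortably inside the passing region of each GATK-style
# hard-filter clause; failing draws sit strictly inside the failing region,
# never on the boundary, so expected survivor counts are unambiguous.
SNP_PASSING_RANGES: dict[str, tuple[float, float]] = {
    "QD": (10.0, 30.0),
    "MQ": (50.0, 60.0),
    "FS": (0.0, 30.0),
    "SOR": (0.5, 2.0),
    "MQRankSum": (-2.0, 2.0),
    "ReadPosRankSum": (-2.0, 2.0),
    "InbreedingCoeff": (-0.2, 0.2),
}
SNP_FAILING_RANGES: dict[str, tuple[float, float]] = {
    "QD": (0.0, 1.9),
    "MQ": (10.0, 39.0),
    "FS": (70.0, 200.0),
    "SOR": (3.5, 8.0),
    "MQRankSum": (-20.0, -13.0),
    "ReadPosRankSum": (-15.0, -8.5),
}
INDEL_PASSING_RANGES = SNP_PASSING_RANGES
INDEL_FAILING_RANGES: dict[str, tuple[float, float]] = {
    "QD": (0.0, 1.9),
    "ReadPosRankSum": (-30.0, -20.5),
    "InbreedingCoeff": (-1.0, -0.85),
    "FS": (210.0, 400.0),
    "SOR": (10.5, 15.0),
}

_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1"}


def write_populations_file(panel: GenotypePanel, path: str | Path) -> None:
    """Two-column delimited map of sample id to population label."""
    with open(path, "w") as fh:
        for sid, lab in zip(panel.sample_ids, panel.pop_labels):
            fh.write(f"{sid}\t{lab}\n")


def write_vcf(
    panel: GenotypePanel,
    out_vcf: str | Path,
    *,
    snp_violations: dict[str, float] | None = None,
    indel_fraction: float = 0.0,
    indel_violations: dict[str, float] | None = None,
    seed: int = 0,
    manifest_path: str | Path | None = None,
) -> dict:
    """Write the panel as an annotated VCF 4.2 and return a truth manifest.

    ``snp_violations`` / ``indel_violations`` map an INFO key to the fraction
    of records of that class planted in the key's failing region; fractions
    must lie in [0, 1] and the planted sets are disjoint across keys, so the
    expected survivor count is exactly ``n_class - sum(planted)``.
    ``indel_fraction`` converts that fraction of records into 1-bp deletions.
    """
    snp_violations = dict(snp_violations or {})
    indel_violations = dict(indel_violations or {})
    for frac in [*snp_violations.values(), *indel_violations.values(), indel_fraction]:
        if not (0.0 <= frac <= 1.0):
            raise ValueError(f"fractions must be in [0, 1], got {frac}")
    for key in (*snp_violations, *indel_violations):
        if key not in SNP_PASSING_RANGES:
            raise ValueError(f"unknown annotation key {key!r}")

    rng = np.random.default_rng(seed)
    n = panel.n_loci
    n_indel = int(round(indel_fraction * n))
    is_indel = np.zeros(n, dtype=bool)
    if n_indel:
        is_indel[rng.choice(n, size=n_indel, replace=False)] = True
    snp_idx = np.flatnonzero(~is_indel)
    indel_idx = np.flatnonzero(is_indel)

    def plant(idx_pool: np.ndarray, violations: dict[str, float],
              failing: dict[str, tuple[float, float]]) -> dict[str, np.ndarray]:
        counts = {k: int(round(f * len(idx_pool))) for k, f in violations.items()}
        total = sum(counts.values())
        if total > len(idx_pool):
            raise ValueError("planted violation counts exceed the number of records")
        shuffled = rng.permutation(idx_pool)
        out, start = {}, 0
        for k, c in counts.items():
            if k not in failing:
                raise ValueError(f"{k!r} has no failing region for this variant class")
            out[k] = np.sort(shuffled[start:start + c])
            start += c
        return out

    snp_planted = plant(snp_idx, snp_violations, SNP_FAILING_RANGES)
    indel_planted = plant(indel_idx, indel_violations, INDEL_FAILING_RANGES)

    # annotation values: passing everywhere, then overwrite planted records
    ann = {
        k: rng.uniform(lo, hi, size=n)
        for k, (lo, hi) in SNP_PASSING_RANGES.items()
    }
    for k, idx in snp_planted.items():
        lo, hi = SNP_FAILING_RANGES[k]
        ann[k][idx] = rng.uniform(lo, hi, size=len(idx))
    for k, idx in indel_planted.items():
        lo, hi = INDEL_FAILING_RANGES[k]
        ann[k][idx] = rng.uniform(lo, hi, size=len(idx))

    chrom_lengths: dict[str, int] = {}
    for c, p in zip(panel.chrom, panel.pos):
        chrom_lengths[c] = max(chrom_lengths.get(c, 0), int(p) + 100)

    ann_keys = list(SNP_PASSING_RANGES)
    with open(out_vcf, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=panelforge-synthetic\n")
        for c, ln in chrom_lengths.items():
            fh.write(f"##contig=<ID={c},length={ln}>\n")
        for k in ann_keys:
            fh.write(f'##INFO=<ID={k},Number=1,Type=Float,Description="{k} annotation">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(panel.sample_ids) + "\n"
        )
        for j in range(n):
            ref, alt = panel.ref[j], panel.alt[j]
            if is_indel[j]:
                ref, alt = ref + "T", ref  # 1-bp deletion
            info = ";".join(f"{k}={ann[k][j]:.4f}" for k in ann_keys)
            gts = "\t".join(_GT_STRINGS[int(g)] for g in panel.genotypes[:, j])
            fh.write(
                f"{panel.chrom[j]}\t{panel.pos[j]}\t.\t{ref}\t{alt}\t100\t.\t{info}\tGT\t{gts}\n"
            )

    manifest = {
        "n_records": n,
        "n_snp": int(len(snp_idx)),
        "n_indel": int(len(indel_idx)),
        "planted_snp_violations": {k: len(v) for k, v in snp_planted.items()},
        "planted_indel_violations": {k: len(v) for k, v in indel_planted.items()},
        "expected_snp_pass": int(len(snp_idx) - sum(len(v) for v in snp_planted.values())),
        "expected_indel_pass": int(len(indel_idx) - sum(len(v) for v in indel_planted.values())),
        "violating_records": {
            "snp": {k: [int(i) for i in v] for k, v in snp_planted.items()},
            "indel": {k: [int(i) for i in v] for k, v in indel_planted.items()},
        },
    }
    if manifest_path is not None:
        Path(manifest_path).write_text(json.dumps(manifest, indent=2))
    return manifest


# --------------------------------------------------------------------------
# reference genome with planted repeats and decoys
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class DecoySpec:
    """Copy ``source`` (chrom, start, end; 0-based half-open) to each
    destination (chrom, pos) with exactly ``mismatches`` substitutions per
    copy — a near-homologous decoy for testing near-match counting."""

    source: tuple[str, int, int]
    destinations: tuple[tuple[str, int], ...]
    mismatches: int = 0


@dataclass(frozen=True)
class GenomeSpec:
    chrom_lengths: dict[str, int] = field(default_factory=lambda: {"chr1": 100_000})
    repeat_motif: str | None = None
    repeat_copies: int = 0
    repeat_positions: tuple[tuple[str, int], ...] | None = None
    decoys: tuple[DecoySpec, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        for chrom, ln in self.chrom_lengths.items():
            if ln < 1:
                raise ValueError(f"chromosome {chrom} has non-positive length")
        if self.repeat_copies and not self.repeat_motif:
            raise ValueError("repeat_copies > 0 requires a repeat_motif")
        for d in self.decoys:
            c, s, e = d.source
            if not (0 <= s < e <= self.chrom_lengths[c]):
                raise ValueError(f"decoy source {d.source} outside chromosome bounds")
            if d.mismatches > e - s:
                raise ValueError("mismatch count exceeds copy length")
            for dc, dp in d.destinations:
                if not (0 <= dp and dp + (e - s) <= self.chrom_lengths[dc]):
                    raise ValueError(f"decoy destination ({dc}, {dp}) outside chromosome bounds")


def _random_sequence(rng: np.random.Generator, length: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=length)]


def simulate_reference(spec: GenomeSpec) -> tuple[dict[str, str], dict]:
    """Random-background genome with planted repeat copies and decoys.

    Returns (sequences, manifest).  Repeat copies make the motif's 15-mers
    overrepresented by construction; decoys give exact, known near-match
    counts.  Overlapping placements are rejected so each planted feature is
    attributable to exactly one truth-manifest entry.
    """
    rng = np.random.default_rng(spec.seed)
    seqs = {c: _random_sequence(rng, ln) for c, ln in spec.chrom_lengths.items()}

    placed: list[tuple[str, int, int]] = []

    def claim(chrom: str, start: int, end: int) -> None:
        if not (0 <= start < end <= spec.chrom_lengths[chrom]):
            raise ValueError(f"placement ({chrom}, {start}, {end}) outside chromosome bounds")
        for c, s, e in placed:
            if c == chrom and start < e and s < end:
                raise ValueError(f"overlapping placements at ({chrom}, {start}, {end})")
        placed.append((chrom, start, end))

    repeat_positions: list[tuple[str, int]] = []
    if spec.repeat_copies:
        motif = np.frombuffer(spec.repeat_motif.upper().encode(), dtype=np.uint8)
        if spec.repeat_positions is not None:
            positions = list(spec.repeat_positions)
            if len(positions) != spec.repeat_copies:
                raise ValueError("repeat_positions length must equal repeat_copies")
        else:
            positions = _auto_place(rng, spec.chrom_lengths, len(motif), spec.repeat_copies)
        for chrom, pos in positions:
            claim(chrom, pos, pos + len(motif))
            seqs[chrom][pos:pos + len(motif)] = motif
            repeat_positions.append((chrom, int(pos)))

    decoy_manifest = []
    for d in spec.decoys:
        sc, ss, se = d.source
        claim(sc, ss, se)
    for d in spec.decoys:
        sc, ss, se = d.source
        src = seqs[sc][ss:se].copy()
        copies = []
        for dc, dp in d.destinations:
            claim(dc, dp, dp + len(src))
            copy = src.copy()
            if d.mismatches:
                sites = rng.choice(len(src), size=d.mismatches, replace=False)
                for t in sites:
                    choices = _BASES[_BASES != copy[t]]
                    copy[t] = rng.choice(choices)
            seqs[dc][dp:dp + len(src)] = copy
            copies.append({"chrom": dc, "pos": int(dp), "mismatches": int(d.mismatches)})
        decoy_manifest.append({
            "source": {"chrom": sc, "start": int(ss), "end": int(se)},
            "copies": copies,
        })

    manifest = {
        "chrom_lengths": dict(spec.chrom_lengths),
        "repeat_motif": spec.repeat_motif,
        "repeat_positions": [[c, p] for c, p in repeat_positions],
        "decoys": decoy_manifest,
        "seed": spec.seed,
    }
    return {c: s.tobytes().decode() for c, s in seqs.items()}, manifest


def _auto_place(
    rng: np.random.Generator,
    chrom_lengths: dict[str, int],
    width: int,
    n: int,
) -> list[tuple[str, int]]:
    """Deterministic non-overlapping placements, round-robin over chromosomes."""
    out: list[tuple[str, int]] = []
    taken: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_lengths}
    chroms = list(chrom_lengths)
    attempts = 0
    while len(out) < n:
        attempts += 1
        if attempts > 100 * n:
            raise ValueError("could not place repeats without overlap; genome too small")
        c = chroms[len(out) % len(chroms)]
        if chrom_lengths[c] < width:
            raise ValueError(f"chromosome {c} shorter than the repeat motif")
        pos = int(rng.integers(0, chrom_lengths[c] - width + 1))
        if all(not (pos < e and s < pos + width) for s, e in taken[c]):
            taken[c].append((pos, pos + width))
            out.append((c, pos))
    return out


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 60) -> None:
    """FASTA with fixed line wrapping (faidx-compatible)."""
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# --------------------------------------------------------------------------
# microarray QC tables with planted failures
# --------------------------------------------------------------------------

_SNP_FAILURE_CLASSES = ("cluster_sep", "nocall", "ab_r_mean", "low_maf")


def simulate_array_tables(
    n_samples: int,
    n_snps: int,
    planted_failures: dict[str, int] | None = None,
    seed: int = 0,
    chrom: str = "chr1",
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Emulate genotyping-platform QC exports with planted failures.

    ``planted_failures`` counts per class: ``sample_outlier`` (samples whose
    (call rate, P10) point falls far from the majority cluster),
    ``cluster_sep`` (< 0.3), ``nocall`` (> 10 % missing calls over retained
    samples), ``ab_r_mean`` (< 0.12) and ``low_maf`` (MAF <= 0.01).  SNP
    failure classes are planted on disjoint records so expected survivor
    counts are exact.  Genotype calls for outlier samples are valid, so
    dropping those samples only shrinks the denominator; planted no-call and
    MAF values are constructed over the retained samples.
    """
    planted = dict(planted_failures or {})
    unknown = set(planted) - {*_SNP_FAILURE_CLASSES, "sample_outlier"}
    if unknown:
        raise ValueError(f"unknown failure classes: {sorted(unknown)}")
    n_out = planted.get("sample_outlier", 0)
    snp_fail_total = sum(planted.get(k, 0) for k in _SNP_FAILURE_CLASSES)
    if snp_fail_total > n_snps:
        raise ValueError("planted SNP failure counts exceed n_snps")
    if n_out > n_samples:
        raise ValueError("planted outlier count exceeds n_samples")

    rng = np.random.default_rng(seed)
    sample_ids = [f"S{i + 1:03d}" for i in range(n_samples)]
    outlier_idx = np.sort(rng.choice(n_samples, size=n_out, replace=False)) if n_out else np.array([], dtype=int)
    is_outlier = np.zeros(n_samples, dtype=bool)
    is_outlier[outlier_idx] = True

    call_rate = rng.uniform(0.975, 0.998, size=n_samples)
    p10 = rng.normal(9000.0, 250.0, size=n_samples)
    call_rate[is_outlier] = rng.uniform(0.50, 0.70, size=n_out)
    p10[is_outlier] = rng.uniform(2000.0, 3000.0, size=n_out)
    samples = pd.DataFrame({"sample_id": sample_ids, "call_rate": call_rate, "p10": p10})

    n_retained = n_samples - n_out
    if n_retained < 2:
        raise ValueError("need at least 2 non-outlier samples")

    # disjoint SNP failure assignment
    order = rng.permutation(n_snps)
    cursor = 0
    fail_idx: dict[str, np.ndarray] = {}
    for k in _SNP_FAILURE_CLASSES:
        c = planted.get(k, 0)
        fail_idx[k] = np.sort(order[cursor:cursor + c])
        cursor += c

    cluster_sep = rng.uniform(0.5, 0.95, size=n_snps)
    cluster_sep[fail_idx["cluster_sep"]] = rng.uniform(0.05, 0.25, size=len(fail_idx["cluster_sep"]))
    ab_r_mean = rng.uniform(0.3, 1.2, size=n_snps)
    ab_r_mean[fail_idx["ab_r_mean"]] = rng.uniform(0.01, 0.10, size=len(fail_idx["ab_r_mean"]))

    # no-call counts over *retained* samples: passing SNPs get <= 10 %,
    # planted ones strictly > 10 % (the threshold is "more than 10 %")
    max_pass_nc = int(np.floor(0.10 * n_retained))
    min_fail_nc = max_pass_nc + 1
    if min_fail_nc > n_retained and len(fail_idx["nocall"]):
        raise ValueError("too few retained samples to plant a no-call failure")
    nocall_counts = rng.integers(0, max_pass_nc + 1, size=n_snps)
    nocall_counts[fail_idx["nocall"]] = rng.integers(min_fail_nc, n_retained + 1, size=len(fail_idx["nocall"]))

    # genotype calls: allele-B frequency comfortably polymorphic for passing
    # SNPs (realized MAF re-drawn until > 0.01 over retained samples);
    # low-MAF SNPs planted with at most one B allele among retained samples
    low_maf = np.zeros(n_snps, dtype=bool)
    low_maf[fail_idx["low_maf"]] = True
    retained_rows = np.flatnonzero(~is_outlier)
    calls = np.empty((n_samples, n_snps), dtype=object)
    for j in range(n_snps):
        nc = nocall_counts[j]
        nc_rows = rng.choice(retained_rows, size=nc, replace=False) if nc else np.array([], dtype=int)
        callable_rows = np.setdiff1d(retained_rows, nc_rows)
        if low_maf[j]:
            # strictly inside the failing region: MAF <= 0.01 over callable
            # retained samples (for small cohorts that means monomorphic)
            max_b = int(np.floor(0.01 * 2 * len(callable_rows)))
            dos = np.zeros(n_samples, dtype=int)
            n_b = int(rng.integers(0, max_b + 1))
            if n_b:
                for row in rng.choice(callable_rows, size=n_b, replace=False):
                    dos[row] = 1
        else:
            q = rng.uniform(0.15, 0.85)
            # enforce a realized MAF > 0.01 only where the MAF filter will
            # actually be reached (SNPs planted to fail earlier stages are
            # excluded regardless of their allele frequencies)
            must_pass_maf = all(j not in fail_idx[k] for k in _SNP_FAILURE_CLASSES)
            for _ in range(100):
                dos = rng.binomial(2, q, size=n_samples)
                b = dos[callable_rows].sum()
                tot = 2 * len(callable_rows)
                if not must_pass_maf or (tot and min(b, tot - b) / tot > 0.01):
                    break
            else:  # pragma: no cover - practically unreachable
                raise RuntimeError("failed to realize a polymorphic SNP")
        col = np.array(["AA", "AB", "BB"], dtype=object)[dos]
        col[nc_rows] = "NC"
        calls[:, j] = col

    snps = pd.DataFrame({
        "snp_id": [f"snp{j + 1:05d}" for j in range(n_snps)],
        "chrom": chrom,
        "pos": np.arange(1, n_snps + 1) * 25,
        "cluster_sep": cluster_sep,
        "ab_r_mean": ab_r_mean,
        "biallelic": True,
    })
    for i, sid in enumerate(sample_ids):
        snps[f"gt_{sid}"] = calls[i, :]

    n_snp_survivors = n_snps - snp_fail_total
    manifest = {
        "n_samples": n_samples,
        "n_snps": n_snps,
        "planted_outlier_samples": [sample_ids[i] for i in outlier_idx],
        "expected_retained_samples": n_retained,
        "planted_snp_failures": {k: int(len(v)) for k, v in fail_idx.items()},
        "failing_snp_ids": {k: [f"snp{j + 1:05d}" for j in v] for k, v in fail_idx.items()},
        "expected_snp_survivors": int(n_snp_survivors),
    }
    return samples, snps, manifest


def save_manifest(manifest: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2))
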