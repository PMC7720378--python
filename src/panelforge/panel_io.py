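"""Interval plumbing, panel summarization and sequencing-cost accounting.

Coordinate conventions: BED-style 0-based half-open intervals everywhere
externally; VCF-style 1-based positions at the variant-record level. The
single conversion point is :func:`snp_pos_to_interval`.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "chrom_sort_key",
    "snp_pos_to_interval",
    "read_bed",
    "write_bed",
    "merge_intervals",
    "panel_size",
    "intersect_with_exons",
    "summarize_panel",
    "CostModel",
    "cost_per_sample",
    "max_multiplex",
]

_CHROM_RE = re.compile(r"^(chr)?(\d+)([A-Za-z]*)$")


def chrom_sort_key(label: str) -> tuple:
    """Natural chromosome ordering: chr1 < chr2A < chr2B < ... < chr22 <
    chrX < chrY < chrM < chrUn < anything else (lexicographic within tier)."""
    m = _CHROM_RE.match(label)
    if m:
        return (0, int(m.group(2)), m.group(3))
    stripped = label[3:] if label.lower().startswith("chr") else label
    special = {"X": 0, "Y": 1, "M": 2, "MT": 2, "Un": 3}
    if stripped in special:
        return (1, special[stripped], "")
    return (2, 0, label)


def snp_pos_to_interval(pos: int) -> tuple[int, int]:
    """1-based SNP position -> 0-based half-open singleton interval."""
    if pos < 1:
        raise ValueError(f"1-based position must be >= 1, got {pos}")
    return pos - 1, pos


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read a BED3+ file into a DataFrame (chrom, start, end[, name])."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    n = df.shape[1]
    names = ["chrom", "start", "end"] + [f"col{i}" for i in range(3, n)]
    if n >= 4:
        names[3] = "name"
    df.columns = names
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    return df


def write_bed(df: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in ["chrom", "start", "end", "name"] if c in df.columns]
    df[cols].to_csv(path, sep="\t", header=False, index=False)


def merge_intervals(df: pd.DataFrame, merge_adjacent: bool = True) -> pd.DataFrame:
    """Union of BED intervals; adjacent (touching) intervals merge by default."""
    if df.empty:
        return df.loc[:, ["chrom", "start", "end"]].copy()
    out = []
    for chrom, grp in df.groupby("chrom", sort=False):
        ivals = grp[["start", "end"]].to_numpy(dtype=np.int64)
        ivals = ivals[np.lexsort((ivals[:, 1], ivals[:, 0]))]
        cur_s, cur_e = ivals[0]
        for s, e in ivals[1:]:
            touches = s <= cur_e if merge_adjacent else s < cur_e
            if touches:
                cur_e = max(cur_e, e)
            else:
                out.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        out.append((chrom, cur_s, cur_e))
    merged = pd.DataFrame(out, columns=["chrom", "start", "end"])
    merged["_ck"] = merged["chrom"].map(chrom_sort_key)
    return merged.sort_values(["_ck", "start"]).drop(columns="_ck").reset_index(drop=True)


def panel_size(intervals: pd.DataFrame) -> int:
    """Total bp spanned by the union of the intervals (merged before summing)."""
    merged = merge_intervals(intervals)
    if merged.empty:
        return 0
    return int((merged["end"] - merged["start"]).sum())


def intersect_with_exons(snp_sites: pd.DataFrame, exon_intervals: pd.DataFrame) -> np.ndarray:
    """Per-site boolean: does the SNP (1-based ``pos``) fall in any exon?

    Exact half-open semantics: the SNP occupies [pos-1, pos), so it is
    inside an exon [s, e) iff s <= pos-1 < e.  Unsorted exon input is
    auto-sorted with a warning.
    """
    flags = np.zeros(len(snp_sites), dtype=bool)
    if exon_intervals.empty or snp_sites.empty:
        return flags
    ex = exon_intervals
    sorted_ok = all(
        (grp["start"].is_monotonic_increasing) for _, grp in ex.groupby("chrom", sort=False)
    )
    if not sorted_ok:
        warnings.warn("exon intervals unsorted; sorting", stacklevel=2)
    merged = merge_intervals(ex, merge_adjacent=False)
    for chrom, grp in merged.groupby("chrom", sort=False):
        mask = (snp_sites["chrom"] == chrom).to_numpy()
        if not mask.any():
            continue
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        p0 = snp_sites.loc[mask, "pos"].to_numpy(dtype=np.int64) - 1  # 0-based
        idx = np.searchsorted(starts, p0, side="right") - 1
        ok = (idx >= 0) & (p0 < ends[np.clip(idx, 0, None)])
        flags[mask] = ok
    return flags


def summarize_panel(
    sites: pd.DataFrame,
    exon_flags: np.ndarray,
    probe_status: np.ndarray,
) -> pd.DataFrame:
    """Per-chromosome panel distribution with a totals row.

    Columns: n_loci, n_in_exons, n_with_probes, n_in_exons_with_probes.
    ``probe_status`` is a per-site boolean (probe successfully designed).
    The totals row always equals the column sums (asserted).
    """
    if len(exon_flags) != len(sites) or len(probe_status) != len(sites):
        raise ValueError("exon_flags and probe_status must align with sites")
    df = sites[["chrom"]].copy()
    df["in_exon"] = np.asarray(exon_flags, dtype=bool)
    df["has_probe"] = np.asarray(probe_status, dtype=bool)
    if df.empty:
        summary = pd.DataFrame(
            columns=["n_loci", "n_in_exons", "n_with_probes", "n_in_exons_with_probes"]
        )
    else:
        g = df.groupby("chrom", sort=False)
        summary = pd.DataFrame({
            "n_loci": g.size(),
            "n_in_exons": g["in_exon"].sum().astype(int),
            "n_with_probes": g["has_probe"].sum().astype(int),
            "n_in_exons_with_probes": g.apply(
                lambda x: int((x["in_exon"] & x["has_probe"]).sum()), include_groups=False
            ),
        })
        summary = summary.loc[sorted(summary.index, key=chrom_sort_key)]
    totals = summary.sum(axis=0).astype(int) if not summary.empty else pd.Series(
        0, index=["n_loci", "n_in_exons", "n_with_probes", "n_in_exons_with_probes"]
    )
    summary.loc["Total"] = totals
    body = summary.drop(index="Total")
    assert (summary.loc["Total"] == body.sum(axis=0)).all() or body.empty
    return summary.astype(int)


@dataclass(frozen=True)
class CostModel:
    """Sequencing-economics inputs for multiplexing capacity.

    lane_cost in currency units; lane_yield_bp total sequenced bases per
    lane; panel_size_bp merged target span; coverage_target fold coverage;
    efficiency the on-target fraction in (0, 1].
    """

    lane_cost: float
    n_samples: int
    lane_yield_bp: int
    panel_size_bp: int
    coverage_target: float
    efficiency: float

    def __post_init__(self) -> None:
        for name in ("lane_cost", "n_samples", "lane_yield_bp", "panel_size_bp", "coverage_target"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0.0 < self.efficiency <= 1.0):
            raise ValueError("efficiency must be in (0, 1]")


def cost_per_sample(lane_cost: float, n_samples: int) -> float:
    """Lane cost split per sample, rounded to cents (integer-cent arithmetic)."""
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    cents = round(lane_cost * 100.0 / n_samples)
    return cents / 100.0


def max_multiplex(model: CostModel) -> int:
    """Samples per lane at the requested coverage:
    floor(lane_yield * efficiency / (panel_size * coverage))."""
    denom = model.panel_size_bp * model.coverage_target
    if denom <= 0:
        raise ValueError("panel_size_bp * coverage_target must be positive")
    return int(model.lane_yield_bp * model.efficiency // denom)
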