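"""Hybrid-capture probe tiling and uniqueness filtering.

Probes of 50–100 nt are tiled over each target (default 75 nt every 25 nt;
single-base SNP targets get one centered probe).  Two uniqueness filters
follow, mirroring standard capture-design practice:

1. *Overrepresented k-mer filter* — any probe containing a canonical 15-mer
   whose genome-wide count exceeds a cutoff (default: mean + 5 sd of the
   observed counts, minimum 10) is removed, to avoid baits hybridizing to
   repeat families.
2. *Near-match filter* — probes are screened against the reference with an
   ungapped seed-style scan: a non-target site counts as a potential match
   when some 30-nt subsequence of the probe aligns with at least 90 %
   identity (>= 27/30 bases).  Hits on the same strand within one
   probe-length merge into a single site, and hits overlapping the probe's
   own source locus are excluded.  Probes with 21 or more such sites
   ("fewer than 21" are kept) are rejected.

Kept probes targeting isolated SNPs — SNP-class targets overlapping no
exon or gene target — are doubled in concentration to balance capture
yields against the larger exon targets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "Target",
    "Probe",
    "KmerIndex",
    "ProbeDesignConfig",
    "tile_probes",
    "build_kmer_index",
    "filter_overrepresented",
    "count_near_matches",
    "select_unique_probes",
    "assign_concentration",
    "design_panel",
]

_CODE = np.full(256, 255, dtype=np.uint8)
for i, b in enumerate(b"ACGT"):
    _CODE[b] = i
    _CODE[ord(chr(b).lower())] = i

TARGET_CLASSES = ("snp", "exon", "gene", "other")


@dataclass(frozen=True)
class Target:
    """A genomic interval to capture (0-based half-open)."""

    chrom: str
    start: int
    end: int
    klass: str = "other"
    id: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.klass not in TARGET_CLASSES:
            raise ValueError(f"unknown target class {self.klass!r}")


@dataclass
class Probe:
    """A candidate capture oligo with design status."""

    chrom: str
    start: int
    end: int
    sequence: str
    target_id: str
    concentration: float = 1.0
    status: str = "kept"
    reject_reason: str | None = None
    near_matches: int | None = None

    def __post_init__(self) -> None:
        if not (50 <= len(self.sequence) <= 100):
            raise ValueError(f"probe length {len(self.sequence)} outside [50, 100]")
        if len(self.sequence) != self.end - self.start:
            raise ValueError("sequence length must equal end - start")
        if self.status == "kept" and self.reject_reason is not None:
            raise ValueError("kept probes cannot carry a reject reason")

    def reject(self, reason: str) -> None:
        self.status = "rejected"
        self.reject_reason = reason


def _encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.upper().encode(), dtype=np.uint8)]


def _revcomp_codes(codes: np.ndarray) -> np.ndarray:
    out = codes[::-1].copy()
    acgt = out < 4
    out[acgt] = 3 - out[acgt]
    return out


# --------------------------------------------------------------------------
# tiling
# --------------------------------------------------------------------------

def tile_probes(
    target: Target,
    reference: dict[str, str],
    probe_len: int = 75,
    step: int = 25,
) -> list[Probe]:
    """Overlapping probes covering every base of ``target`` at least once.

    Successive probes are offset by ``step``; probes running past a contig
    end are shifted back inside (never shortened below the 50 nt floor).
    Single-base targets get one probe centered on the base.
    """
    if not (50 <= probe_len <= 100):
        raise ValueError(f"probe_len must be in [50, 100], got {probe_len}")
    if not (1 <= step <= probe_len):
        raise ValueError(f"step must be in [1, probe_len], got {step}")
    if target.chrom not in reference:
        raise ValueError(f"chromosome {target.chrom!r} absent from reference")
    chrom_len = len(reference[target.chrom])
    if target.end > chrom_len:
        raise ValueError(f"target {target.id!r} extends past the contig end")
    if chrom_len < probe_len:
        raise ValueError(
            f"contig {target.chrom!r} shorter than probe_len; no legal probe for {target.id!r}"
        )

    if target.end - target.start == 1:
        starts = [target.start - probe_len // 2]
    else:
        starts = list(range(target.start, target.end, step))
    clipped = sorted({min(max(s, 0), chrom_len - probe_len) for s in starts})

    seq = reference[target.chrom]
    probes = []
    for s in clipped:
        probes.append(Probe(
            chrom=target.chrom,
            start=s,
            end=s + probe_len,
            sequence=seq[s:s + probe_len].upper(),
            target_id=target.id,
        ))
    return probes


# --------------------------------------------------------------------------
# k-mer index and overrepresentation filter
# --------------------------------------------------------------------------

@dataclass
class KmerIndex:
    """Canonical k-mer counts over a reference, with an overrepresentation
    cutoff (a k-mer is overrepresented when count > cutoff)."""

    k: int
    counts: dict[int, int]
    overrep_cutoff: int

    def count_of(self, kmer: str) -> int:
        codes = _encode(kmer)
        if len(codes) != self.k or (codes > 3).any():
            return 0
        return self.counts.get(int(_canonical_codes(codes[None, :], self.k)[0]), 0)


def _kmer_codes(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """(positions, canonical codes) of all valid (ACGT-only) k-mer windows."""
    n = len(codes)
    if n < k:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    n_win = n - k + 1
    valid_base = codes < 4
    ok = np.ones(n_win, dtype=bool)
    cs = np.concatenate(([0], np.cumsum(~valid_base)))
    ok = (cs[k:] - cs[:-k]) == 0
    windows = np.lib.stride_tricks.sliding_window_view(codes, k)[ok].astype(np.int64)
    if windows.size == 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    return np.flatnonzero(ok), _canonical_codes(windows, k)


def _canonical_codes(windows: np.ndarray, k: int) -> np.ndarray:
    """Lexicographic min of each window's 2-bit code and its reverse
    complement, so both strands collapse to one key."""
    weights_f = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    weights_r = 4 ** np.arange(k, dtype=np.int64)
    fwd = windows @ weights_f
    rev = (3 - windows) @ weights_r
    return np.minimum(fwd, rev)


def build_kmer_index(
    reference: dict[str, str],
    k: int = 15,
    overrep_cutoff: int | None = None,
) -> KmerIndex:
    """Count canonical k-mers over all contigs (windows containing non-ACGT
    bases are skipped).

    The default cutoff is max(10, mean + 5 sd) of the observed counts; an
    explicit ``overrep_cutoff`` overrides the policy.
    """
    if k != 15:
        import warnings

        warnings.warn(f"k={k} differs from the standard 15-mer screen", stacklevel=2)
    all_codes: dict[int, int] = {}
    for seq in reference.values():
        _, canon = _kmer_codes(_encode(seq), k)
        if canon.size == 0:
            continue
        uniq, cnt = np.unique(canon, return_counts=True)
        for u, c in zip(uniq.tolist(), cnt.tolist()):
            all_codes[u] = all_codes.get(u, 0) + c
    if overrep_cutoff is None:
        if all_codes:
            vals = np.fromiter(all_codes.values(), dtype=float)
            overrep_cutoff = max(10, int(math.ceil(vals.mean() + 5.0 * vals.std())))
        else:
            overrep_cutoff = 10
    if overrep_cutoff < 2:
        raise ValueError("overrep_cutoff must be >= 2")
    return KmerIndex(k=k, counts=all_codes, overrep_cutoff=overrep_cutoff)


def filter_overrepresented(probes: list[Probe], index: KmerIndex) -> list[Probe]:
    """Reject probes containing any overrepresented k-mer (count > cutoff).

    Probes with non-ACGT bases are rejected with reason ``ambiguous_base``.
    Already-rejected probes pass through untouched.  Order-independent.
    """
    for probe in probes:
        if probe.status != "kept":
            continue
        codes = _encode(probe.sequence)
        if (codes > 3).any():
            probe.reject("ambiguous_base")
            continue
        _, canon = _kmer_codes(codes, index.k)
        if any(index.counts.get(int(c), 0) > index.overrep_cutoff for c in canon):
            probe.reject("overrepresented_kmer")
    return probes


# --------------------------------------------------------------------------
# near-match counting (ungapped, windowed identity)
# --------------------------------------------------------------------------

def _window_hit_positions(
    probe_codes: np.ndarray,
    seq_codes: np.ndarray,
    window: int,
    min_match: int,
) -> np.ndarray:
    """Genome start positions (of the window) where some ``window``-length
    subsequence of the probe matches with >= min_match identical bases,
    ungapped.  Exhaustive over all alignment offsets, vectorized."""
    L = len(probe_codes)
    G = len(seq_codes)
    if G < window:
        return np.empty(0, dtype=np.int64)
    pad = L
    spad = np.full(G + 2 * pad, 254, dtype=np.uint8)  # sentinel never matches
    spad[pad:pad + G] = seq_codes
    A = len(spad) - L + 1
    eq = np.empty((L, A), dtype=np.uint8)
    for u in range(L):
        eq[u] = spad[u:u + A] == probe_codes[u]
    cs = np.zeros((L + 1, A), dtype=np.int16)
    np.cumsum(eq, axis=0, out=cs[1:])
    hits_i, hits_a = np.nonzero(cs[window:] - cs[:-window] >= min_match)
    pos = hits_a + hits_i - pad
    pos = pos[(pos >= 0) & (pos <= G - window)]
    return np.unique(pos)


def _merge_sites(positions: np.ndarray, merge_dist: int) -> int:
    if positions.size == 0:
        return 0
    positions = np.sort(positions)
    return int(1 + (np.diff(positions) > merge_dist).sum())


def count_near_matches(
    probe: Probe,
    reference: dict[str, str],
    identity: float = 0.90,
    window: int = 30,
) -> int:
    """Distinct non-target genomic sites (both strands) at which some
    ``window``-nt subsequence of the probe aligns ungapped with at least
    ceil(identity * window) matching bases.

    Hits overlapping the probe's own source interval are excluded; hits
    within one probe-length of each other on the same strand merge into one
    site.
    """
    if window > len(probe.sequence):
        raise ValueError("window exceeds probe length")
    p_fwd = _encode(probe.sequence)
    if (p_fwd > 3).any():
        raise ValueError("probe sequence must be ACGT-only")
    min_match = math.ceil(identity * window)
    p_rev = _revcomp_codes(p_fwd)
    probe_len = len(probe.sequence)

    total = 0
    for chrom, seq in reference.items():
        seq_codes = _encode(seq)
        for strand_codes in (p_fwd, p_rev):
            pos = _window_hit_positions(strand_codes, seq_codes, window, min_match)
            if chrom == probe.chrom and pos.size:
                overlap = (pos < probe.end) & (pos + window > probe.start)
                pos = pos[~overlap]
            total += _merge_sites(pos, probe_len)
    return total


def select_unique_probes(
    probes: list[Probe],
    reference: dict[str, str],
    max_matches: int = 21,
    identity: float = 0.90,
    window: int = 30,
) -> list[Probe]:
    """Keep probes with strictly fewer than ``max_matches`` non-target
    near-match sites; reject the rest with reason ``too_many_near_matches``."""
    for probe in probes:
        if probe.status != "kept":
            continue
        n = count_near_matches(probe, reference, identity=identity, window=window)
        probe.near_matches = n
        if n >= max_matches:
            probe.reject("too_many_near_matches")
    return probes


# --------------------------------------------------------------------------
# concentration and full pipeline
# --------------------------------------------------------------------------

def assign_concentration(probes: list[Probe], targets: list[Target]) -> list[Probe]:
    """Double the concentration of kept probes on isolated SNP targets.

    A probe qualifies when its target is SNP-class and the probe interval
    overlaps no exon or gene target; everything else stays at 1.0.
    """
    by_id = {t.id: t for t in targets}
    exonic = [t for t in targets if t.klass in ("exon", "gene")]
    for probe in probes:
        if probe.status != "kept":
            continue
        target = by_id.get(probe.target_id)
        if target is None or target.klass != "snp":
            probe.concentration = 1.0
            continue
        overlaps = any(
            t.chrom == probe.chrom and probe.start < t.end and t.start < probe.end
            for t in exonic
        )
        probe.concentration = 1.0 if overlaps else 2.0
    return probes


@dataclass(frozen=True)
class ProbeDesignConfig:
    probe_len: int = 75
    step: int = 25
    k: int = 15
    overrep_cutoff: int | None = None
    identity: float = 0.90
    window: int = 30
    max_matches: int = 21


def design_panel(
    targets: list[Target],
    reference: dict[str, str],
    config: ProbeDesignConfig | None = None,
) -> tuple[list[Probe], dict]:
    """Full probe-design pipeline: tile, k-mer filter, near-match filter,
    concentration assignment; plus a per-target coverage report.

    The report lists, per target: probes tiled/kept, rejects by reason, the
    fraction of target bases covered by kept probes, and the uncovered
    sub-intervals.  Deterministic for fixed inputs.
    """
    cfg = config or ProbeDesignConfig()
    probes: list[Probe] = []
    target_errors: dict[str, str] = {}
    for t in targets:
        try:
            probes.extend(tile_probes(t, reference, cfg.probe_len, cfg.step))
        except ValueError as exc:
            target_errors[t.id] = str(exc)

    index = build_kmer_index(reference, k=cfg.k, overrep_cutoff=cfg.overrep_cutoff)
    filter_overrepresented(probes, index)
    select_unique_probes(
        probes, reference, max_matches=cfg.max_matches,
        identity=cfg.identity, window=cfg.window,
    )
    assign_concentration(probes, targets)

    report: dict = {
        "config": {
            "probe_len": cfg.probe_len, "step": cfg.step, "k": cfg.k,
            "overrep_cutoff": index.overrep_cutoff,
            "identity": cfg.identity, "window": cfg.window,
            "max_matches": cfg.max_matches,
        },
        "n_targets": len(targets),
        "n_probes": len(probes),
        "n_kept": sum(p.status == "kept" for p in probes),
        "rejects_by_reason": {},
        "target_errors": target_errors,
        "per_target": {},
    }
    for p in probes:
        if p.status == "rejected":
            report["rejects_by_reason"][p.reject_reason] = (
                report["rejects_by_reason"].get(p.reject_reason, 0) + 1
            )

    for t in targets:
        if t.id in target_errors:
            report["per_target"][t.id] = {"error": target_errors[t.id]}
            continue
        own = [p for p in probes if p.target_id == t.id]
        kept = [p for p in own if p.status == "kept"]
        covered = np.zeros(t.end - t.start, dtype=bool)
        for p in kept:
            s = max(p.start, t.start) - t.start
            e = min(p.end, t.end) - t.start
            if e > s:
                covered[s:e] = True
        uncovered = _bool_runs(~covered, offset=t.start)
        report["per_target"][t.id] = {
            "n_probes": len(own),
            "n_kept": len(kept),
            "rejects": {
                r: sum(p.reject_reason == r for p in own if p.status == "rejected")
                for r in {p.reject_reason for p in own if p.status == "rejected"}
            },
            "covered_fraction": float(covered.mean()),
            "uncovered": uncovered,
        }
    return probes, report


def _bool_runs(mask: np.ndarray, offset: int = 0) -> list[list[int]]:
    """Maximal runs of True in ``mask`` as [start, end) intervals."""
    if not mask.any():
        return []
    padded = np.concatenate(([False], mask, [False]))
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    return [[int(s + offset), int(e + offset)] for s, e in zip(starts, ends)]


def probes_to_table(probes: list[Probe]):
    """Delimited-table view (pandas) of a probe list."""
    import pandas as pd

    return pd.DataFrame([
        {
            "probe_id": f"{p.target_id}|{p.chrom}:{p.start}-{p.end}",
            "chrom": p.chrom, "start": p.start, "end": p.end,
            "target_id": p.target_id, "concentration": p.concentration,
            "status": p.status, "reject_reason": p.reject_reason or "",
            "near_matches": -1 if p.near_matches is None else p.near_matches,
            "sequence": p.sequence,
        }
        for p in probes
    ])
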