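"""Probe tiling, k-mer overrepresentation screen, near-match counting
(against an exhaustive sliding-window oracle) and the design pipeline."""

from __future__ import annotations

import math
import random

import numpy as np
import pytest

from panelforge import probe_design as pdg
from panelforge import synthetic_data as sd

_COMP = str.maketrans("ACGT", "TGCA")


def _revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


# --------------------------------------------------------------------------
# exhaustive oracle: plain-Python scan of every probe window against every
# genome position on both strands, then the same site-merging semantics
# --------------------------------------------------------------------------

def near_match_oracle(probe: pdg.Probe, reference: dict[str, str],
                      identity: float = 0.90, window: int = 30) -> int:
    min_match = math.ceil(identity * window)
    pseq = probe.sequence
    total = 0
    for chrom, seq in reference.items():
        for strand_seq in (pseq, _revcomp(pseq)):
            hits = set()
            for i in range(len(pseq) - window + 1):
                sub = strand_seq[i:i + window]
                for j in range(len(seq) - window + 1):
                    matches = sum(a == b for a, b in zip(sub, seq[j:j + window]))
                    if matches >= min_match:
                        hits.add(j)
            if chrom == probe.chrom:
                hits = {j for j in hits
                        if not (j < probe.end and j + window > probe.start)}
            sites = 0
            prev = None
            for j in sorted(hits):
                if prev is None or j - prev > len(pseq):
                    sites += 1
                prev = j
            total += sites
    return total


class TestTileProbes:
    def test_snp_target_centered_probe(self, clean_genome):
        seqs, _ = clean_genome
        t = pdg.Target("chr1", 500, 501, klass="snp", id="s1")
        probes = pdg.tile_probes(t, seqs, probe_len=75)
        assert len(probes) == 1
        assert 500 - probes[0].start == 37  # SNP at the center offset
        assert probes[0].sequence == seqs["chr1"][probes[0].start:probes[0].end]

    def test_exon_fully_covered_with_step_offsets(self, clean_genome):
        seqs, _ = clean_genome
        t = pdg.Target("chr1", 1000, 1300, klass="exon", id="e1")
        probes = pdg.tile_probes(t, seqs, probe_len=75, step=25)
        starts = [p.start for p in probes]
        assert all(b - a == 25 for a, b in zip(starts, starts[1:]))
        covered = np.zeros(300, dtype=bool)
        for p in probes:
            covered[max(p.start, 1000) - 1000:min(p.end, 1300) - 1000] = True
        assert covered.all()

    def test_contig_end_shifting(self, clean_genome):
        seqs, _ = clean_genome
        L = len(seqs["chr1"])
        t = pdg.Target("chr1", L - 10, L, klass="other", id="edge")
        probes = pdg.tile_probes(t, seqs)
        assert all(p.end <= L for p in probes)
        assert all(len(p.sequence) == 75 for p in probes)

    def test_illegal_probe_len_rejected(self, clean_genome):
        seqs, _ = clean_genome
        t = pdg.Target("chr1", 100, 200)
        with pytest.raises(ValueError):
            pdg.tile_probes(t, seqs, probe_len=40)
        with pytest.raises(ValueError):
            pdg.tile_probes(t, seqs, probe_len=101)

    def test_contig_too_short_rejected(self):
        t = pdg.Target("tiny", 0, 10)
        with pytest.raises(ValueError, match="shorter than probe_len"):
            pdg.tile_probes(t, {"tiny": "ACGT" * 10})


class TestKmerIndex:
    def test_unique_sequence_counts_all_one(self):
        # 45 distinct bases with no repeated 15-mer
        rng = random.Random(4)
        seq = "".join(rng.choice("ACGT") for _ in range(45))
        index = pdg.build_kmer_index({"c": seq}, overrep_cutoff=10)
        assert all(v == 1 for v in index.counts.values()) or max(index.counts.values()) <= 2
        assert len(index.counts) <= 31

    def test_planted_motif_flagged_overrepresented(self):
        motif = "TTGACCATGGCAAGTCCAT"
        spec = sd.GenomeSpec(chrom_lengths={"chr1": 100_000},
                             repeat_motif=motif, repeat_copies=500, seed=6)
        seqs, _ = sd.simulate_reference(spec)
        index = pdg.build_kmer_index(seqs)
        for i in range(len(motif) - 14):
            assert index.count_of(motif[i:i + 15]) > index.overrep_cutoff

    def test_canonicalization_merges_strands(self):
        kmer = "ACGTACGTACGTACG"
        seq = "TTTTT" + kmer + "TTTTT" + _revcomp(kmer) + "TTTTT"
        index = pdg.build_kmer_index({"c": seq}, overrep_cutoff=10)
        assert index.count_of(kmer) >= 2
        assert index.count_of(kmer) == index.count_of(_revcomp(kmer))

    def test_non_acgt_windows_skipped(self):
        seq = "ACGTACGTACGTACGT" + "N" + "ACGTACGTACGTACGT"
        index = pdg.build_kmer_index({"c": seq}, overrep_cutoff=10)
        total_windows = sum(index.counts.values())
        assert total_windows == 4  # 2 valid windows per N-free block


class TestFilterOverrepresented:
    def _probe(self, seq, chrom="chr1", start=0):
        return pdg.Probe(chrom=chrom, start=start, end=start + len(seq),
                         sequence=seq, target_id="t")

    def test_unique_probe_kept_repeat_probe_rejected(self):
        motif = "GATTACAGGATCCGGATTACA"
        spec = sd.GenomeSpec(chrom_lengths={"chr1": 80_000},
                             repeat_motif=motif, repeat_copies=300, seed=8)
        seqs, manifest = sd.simulate_reference(spec)
        index = pdg.build_kmer_index(seqs)
        rc, rpos = manifest["repeat_positions"][0]
        over = self._probe(seqs[rc][rpos - 20:rpos + 55], chrom=rc, start=rpos - 20)
        # find a clean region away from all planted repeats
        clean_start = next(
            s for s in range(0, 70_000, 997)
            if all(abs(s - p) > 200 for _, p in manifest["repeat_positions"])
        )
        clean = self._probe(seqs["chr1"][clean_start:clean_start + 75], start=clean_start)
        pdg.filter_overrepresented([over, clean], index)
        assert over.status == "rejected" and over.reject_reason == "overrepresented_kmer"
        assert clean.status == "kept"

    def test_ambiguous_base_rejected(self):
        index = pdg.KmerIndex(k=15, counts={}, overrep_cutoff=10)
        p = self._probe("ACGTN" + "ACGT" * 18)
        pdg.filter_overrepresented([p], index)
        assert p.reject_reason == "ambiguous_base"

    def test_infinite_cutoff_keeps_everything(self):
        spec = sd.GenomeSpec(chrom_lengths={"chr1": 10_000},
                             repeat_motif="ACCGGTTACCGGTTA", repeat_copies=50, seed=9)
        seqs, _ = sd.simulate_reference(spec)
        index = pdg.build_kmer_index(seqs, overrep_cutoff=10**9)
        probes = pdg.tile_probes(pdg.Target("chr1", 100, 400), seqs)
        pdg.filter_overrepresented(probes, index)
        assert all(p.status == "kept" for p in probes)

    def test_kept_probes_have_no_overrepresented_kmers(self):
        """Invariant: every kept probe has zero overrepresented 15-mers."""
        spec = sd.GenomeSpec(chrom_lengths={"chr1": 40_000},
                             repeat_motif="CCATTGCAGGACCATT", repeat_copies=200, seed=10)
        seqs, _ = sd.simulate_reference(spec)
        index = pdg.build_kmer_index(seqs)
        probes = []
        for s in range(0, 5000, 500):
            probes.extend(pdg.tile_probes(pdg.Target("chr1", s, s + 100, id=f"t{s}"), seqs))
        pdg.filter_overrepresented(probes, index)
        for p in probes:
            if p.status == "kept":
                assert all(
                    index.count_of(p.sequence[i:i + 15]) <= index.overrep_cutoff
                    for i in range(len(p.sequence) - 14)
                )


@pytest.fixture(scope="module")
def decoy_genome():
    """5 kb genome with a probe-source 30-mer copied to 4 distant sites at
    <= 3 mismatches; small enough for the exhaustive oracle."""
    dests = tuple(("chr1", 2000 + 300 * i) for i in range(4))
    spec = sd.GenomeSpec(
        chrom_lengths={"chr1": 5000},
        decoys=(sd.DecoySpec(("chr1", 500, 530), dests, mismatches=3),),
        seed=40,
    )
    seqs, manifest = sd.simulate_reference(spec)
    probe = pdg.Probe(chrom="chr1", start=480, end=555,
                      sequence=seqs["chr1"][480:555], target_id="src")
    return seqs, manifest, probe


class TestCountNearMatches:
    def test_unique_probe_counts_zero(self, clean_genome):
        seqs, _ = clean_genome
        small = {"chr1": seqs["chr1"][:4000]}
        probe = pdg.Probe("chr1", 100, 175, small["chr1"][100:175], "t")
        assert pdg.count_near_matches(probe, small) == 0

    def test_planted_decoys_counted_exactly(self, decoy_genome):
        seqs, manifest, probe = decoy_genome
        assert pdg.count_near_matches(probe, seqs) == 4

    def test_matches_exhaustive_oracle(self, decoy_genome):
        seqs, _, probe = decoy_genome
        assert pdg.count_near_matches(probe, seqs) == near_match_oracle(probe, seqs)

    def test_oracle_equivalence_on_random_probes(self, rng):
        """Production counter equals the exhaustive oracle for arbitrary
        probes against a small genome, including reverse-strand hits."""
        spec = sd.GenomeSpec(chrom_lengths={"chr1": 1500, "chr2": 800}, seed=41)
        seqs, _ = sd.simulate_reference(spec)
        # plant one reverse-complement copy across chromosomes
        src = seqs["chr1"][200:230]
        seqs["chr2"] = seqs["chr2"][:400] + _revcomp(src) + seqs["chr2"][430:]
        for start in (150, 200, 700):
            probe = pdg.Probe("chr1", start, start + 60,
                              seqs["chr1"][start:start + 60], "t")
            assert pdg.count_near_matches(probe, seqs) == near_match_oracle(probe, seqs)

    def test_four_mismatches_per_window_not_counted(self):
        """Copies below 27/30 identity in every window are invisible."""
        rng = random.Random(42)
        bg = "".join(rng.choice("ACGT") for _ in range(3000))
        src = bg[500:530]
        # plant a copy with 4 substitutions spread across the 30-mer
        copy = list(src)
        for t in (3, 11, 19, 27):
            copy[t] = {"A": "C", "C": "A", "G": "T", "T": "G"}[copy[t]]
        seq = bg[:2000] + "".join(copy) + bg[2030:]
        seqs = {"chr1": seq}
        probe = pdg.Probe("chr1", 490, 550, seq[490:550], "t")
        n = pdg.count_near_matches(probe, seqs)
        assert n == near_match_oracle(probe, seqs)
        assert n == 0

    def test_window_longer_than_probe_errors(self, clean_genome):
        seqs, _ = clean_genome
        probe = pdg.Probe("chr1", 0, 50, seqs["chr1"][:50], "t")
        with pytest.raises(ValueError, match="window"):
            pdg.count_near_matches(probe, seqs, window=60)


class TestSelectUniqueProbes:
    def test_boundary_at_max_matches(self, decoy_genome):
        seqs, _, probe = decoy_genome
        p20 = pdg.Probe(probe.chrom, probe.start, probe.end, probe.sequence, "t")
        pdg.select_unique_probes([p20], seqs, max_matches=5)
        assert p20.status == "kept" and p20.near_matches == 4
        p21 = pdg.Probe(probe.chrom, probe.start, probe.end, probe.sequence, "t")
        pdg.select_unique_probes([p21], seqs, max_matches=4)
        assert p21.status == "rejected"
        assert p21.reject_reason == "too_many_near_matches"

    def test_filter_order_independence(self, decoy_genome, rng):
        """Statuses are a pure per-probe function; shuffling the probe list
        leaves every status unchanged."""
        seqs, _, _ = decoy_genome
        probes = pdg.tile_probes(pdg.Target("chr1", 400, 700, id="t"), seqs)
        index = pdg.build_kmer_index(seqs, overrep_cutoff=10)

        def run(order):
            ps = [pdg.Probe(p.chrom, p.start, p.end, p.sequence, p.target_id)
                  for p in order]
            pdg.filter_overrepresented(ps, index)
            pdg.select_unique_probes(ps, seqs, max_matches=2)
            return {(p.start, p.end): (p.status, p.reject_reason) for p in ps}

        shuffled = list(probes)
        rng.shuffle(shuffled)
        assert run(probes) == run(shuffled)


class TestAssignConcentration:
    def _fixture(self, clean_genome):
        seqs, _ = clean_genome
        targets = [
            pdg.Target("chr1", 10_000, 10_001, klass="snp", id="snp_iso"),
            pdg.Target("chr1", 20_000, 20_300, klass="exon", id="exon1"),
            pdg.Target("chr1", 20_100, 20_101, klass="snp", id="snp_in_exon"),
        ]
        probes = []
        for t in targets:
            probes.extend(pdg.tile_probes(t, seqs))
        return targets, probes

    def test_isolated_snp_doubled(self, clean_genome):
        targets, probes = self._fixture(clean_genome)
        pdg.assign_concentration(probes, targets)
        by_target = {}
        for p in probes:
            by_target.setdefault(p.target_id, set()).add(p.concentration)
        assert by_target["snp_iso"] == {2.0}
        assert by_target["exon1"] == {1.0}
        assert by_target["snp_in_exon"] == {1.0}  # overlaps the exon: not isolated


class TestDesignPanel:
    def test_clean_genome_full_coverage_no_rejects(self, clean_genome):
        seqs, _ = clean_genome
        targets = [
            pdg.Target("chr1", 1000 * (i + 1), 1000 * (i + 1) + (1 if i % 2 else 200),
                       klass="snp" if i % 2 else "exon", id=f"t{i}")
            for i in range(10)
        ]
        probes, report = pdg.design_panel(targets, seqs)
        assert report["n_kept"] == report["n_probes"]
        assert report["rejects_by_reason"] == {}
        for tid, info in report["per_target"].items():
            assert info["covered_fraction"] == 1.0
            assert info["uncovered"] == []

    def test_repeat_under_exon_partially_uncovered(self):
        """An exon sitting on a planted repeat loses its probes there; the
        uncovered extent brackets the repeat."""
        motif = "ACCGGTAGGCATCCGGTAAGCCTA"  # 24 nt
        positions = tuple(("chr1", 30_000 + 200 * i) for i in range(299)) + (("chr1", 10_100),)
        spec = sd.GenomeSpec(chrom_lengths={"chr1": 95_000}, repeat_motif=motif,
                             repeat_copies=300, repeat_positions=positions, seed=44)
        seqs, _ = sd.simulate_reference(spec)
        exon = pdg.Target("chr1", 10_000, 10_250, klass="exon", id="ex")
        cfg = pdg.ProbeDesignConfig(max_matches=10**9)  # isolate the k-mer filter
        probes, report = pdg.design_panel([exon], seqs, cfg)
        info = report["per_target"]["ex"]
        assert info["covered_fraction"] < 1.0
        assert info["uncovered"]
        unc_start = info["uncovered"][0][0]
        unc_end = info["uncovered"][-1][1]
        # uncovered region brackets the repeat within one probe length
        assert 10_100 - 75 <= unc_start <= 10_100 + len(motif)
        assert 10_100 - len(motif) <= unc_end <= 10_100 + len(motif) + 75

    def test_coverage_soundness(self, clean_genome):
        """A target base is uncovered iff no kept probe overlaps it."""
        seqs, _ = clean_genome
        t = pdg.Target("chr1", 3000, 3400, klass="gene", id="g")
        probes, report = pdg.design_panel([t], seqs)
        kept = [p for p in probes if p.status == "kept"]
        for base in range(3000, 3400, 7):
            covered = any(p.start <= base < p.end for p in kept)
            in_uncovered = any(s <= base < e for s, e in report["per_target"]["g"]["uncovered"])
            assert covered != in_uncovered

    def test_deterministic_rerun(self, clean_genome):
        seqs, _ = clean_genome
        targets = [pdg.Target("chr1", 5000, 5200, klass="exon", id="e")]
        _, r1 = pdg.design_panel(targets, seqs)
        _, r2 = pdg.design_panel(targets, seqs)
        assert r1 == r2

    def test_kept_probe_invariants(self, clean_genome):
        seqs, _ = clean_genome
        targets = [pdg.Target("chr1", 100, 101, klass="snp", id="s"),
                   pdg.Target("chr1", 8000, 8150, klass="exon", id="e")]
        probes, _ = pdg.design_panel(targets, seqs)
        for p in probes:
            assert 50 <= len(p.sequence) <= 100
            if p.status == "kept":
                assert p.reject_reason is None
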