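"""Tile capture probes over SNP and exon targets and filter for uniqueness.

The reference carries a planted repeat family (300 copies) and a decoy
locus copied to 25 near-identical sites; probes touching either should be
rejected, everything else kept.
"""

from panelforge import probe_design as pdg
from panelforge import synthetic_data as sd

decoy_dests = tuple(("chr1", 60_000 + 500 * i) for i in range(25))
spec = sd.GenomeSpec(
    chrom_lengths={"chr1": 100_000},
    repeat_motif="ACGGTTCAGGCATCCGGTAAGC", repeat_copies=300,
    repeat_positions=tuple(("chr1", 20_000 + 120 * i) for i in range(300)),
    decoys=(sd.DecoySpec(("chr1", 10_000, 10_030), decoy_dests, mismatches=2),),
    seed=6,
)
seqs, manifest = sd.simulate_reference(spec)

targets = [
    pdg.Target("chr1", 5_000, 5_001, klass="snp", id="clean_snp"),
    pdg.Target("chr1", 10_000, 10_001, klass="snp", id="decoy_snp"),
    pdg.Target("chr1", 20_011, 20_012, klass="snp", id="repeat_snp"),
    pdg.Target("chr1", 80_000, 80_300, klass="exon", id="exon1"),
]
probes, report = pdg.design_panel(targets, seqs)

print(f"probes tiled: {report['n_probes']}, kept: {report['n_kept']}")
print(f"rejections: {report['rejects_by_reason']}")
for p in probes:
    if p.target_id.endswith("_snp"):
        print(f"  {p.target_id}: {p.status:8s} reason={p.reject_reason} "
              f"near_matches={p.near_matches} conc={p.concentration}")
# The clean SNP probe survives at 2x concentration (isolated SNP); the
# decoy-locus probe fails the near-match screen (>= 21 sites at 90 %
# identity over 30-mers) and the repeat-locus probe fails the 15-mer screen.
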