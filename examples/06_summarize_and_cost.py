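"""Summarize a panel per chromosome and estimate sequencing economics.

Uses a small synthetic panel for the distribution table, then the published
lane figures for the cost arithmetic: a $1812 MiSeq v2 lane shared by 16
samples, and a $2819 HiSeq 4000 lane shared by 192.
"""

import numpy as np
import pandas as pd

from panelforge import panel_io as pio

sites = pd.DataFrame({
    "chrom": ["chr1"] * 6 + ["chr2A"] * 4 + ["chrX"] * 2,
    "pos": [100, 200, 300, 400, 500, 600, 100, 200, 300, 400, 100, 200],
})
exons = pd.DataFrame({"chrom": ["chr1", "chr2A"], "start": [250, 0], "end": [450, 150]})
exon_flags = pio.intersect_with_exons(sites, exons)
probe_status = np.array([True] * 10 + [False] * 2)

summary = pio.summarize_panel(sites, exon_flags, probe_status)
print(summary, "\n")

panel_bp = pio.panel_size(pd.DataFrame({
    "chrom": ["chr1", "chr1", "chr2A"],
    "start": [0, 9_000_000, 0], "end": [10_000_000, 17_045_000, 851_000],
}))
print(f"merged panel span: {panel_bp / 1e6:.3f} Mb")
print(f"cost/sample, 16-plex MiSeq lane:   ${pio.cost_per_sample(1812, 16):.2f}")
print(f"cost/sample, 192-plex HiSeq lane:  ${pio.cost_per_sample(2819, 192):.2f}")

model = pio.CostModel(lane_cost=1812, n_samples=16, lane_yield_bp=7_500_000_000,
                      panel_size_bp=panel_bp, coverage_target=45, efficiency=0.9)
print(f"samples/lane at 45x coverage:      {pio.max_multiplex(model)}")
# Overlapping intervals merge before the span is summed; per-sample cost is
# the lane cost split across the multiplexed samples, in integer cents.
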