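"""Estimate a haploid genome size two ways from simulated sequencing depth.

Builds a k-mer frequency histogram and a per-contig coverage table for a
1 Mb genome sequenced at ~40x, then applies both estimators: the k-mer
peak formula GS = N / (C * p) averaged over the standard k range, and the
Lander-Waterman formula GS = L * N / C with the half-sample modal coverage.
"""

from nucleotype.genomesize import (
    DEFAULT_K_LIST,
    analyze_kmer_histogram,
    coverage_mode,
    lander_waterman_gs,
    multi_k_average,
)
from nucleotype.simulate import sim_coverage_table, sim_kmer_histogram

GS_TRUE = 1_000_000

per_k = {}
for i, k in enumerate(DEFAULT_K_LIST):
    hist = sim_kmer_histogram(GS_TRUE, depth_mean=40.0, k=k, seed=100 + i)
    est = analyze_kmer_histogram(hist)
    per_k[k] = est.gs_bp
    print(f"k={k}: peak depth {est.peak_depth:.0f}, error cutoff {est.cutoff}, "
          f"GS = {est.gs_bp / 1e6:.3f} Mb")

gs_kmer = multi_k_average(per_k)
print(f"\nmulti-k average: {gs_kmer / 1e6:.3f} Mb")

table, n_reads = sim_coverage_table(GS_TRUE, n_contigs=300, depth_mean=35.0,
                                    read_length=150, seed=7)
mode = coverage_mode(table)
gs_cov = lander_waterman_gs(150, n_reads, mode)
print(f"coverage method: modal coverage {mode:.1f}x, GS = {gs_cov / 1e6:.3f} Mb")

print(f"\nTruth is {GS_TRUE / 1e6:.1f} Mb; both estimates should sit within "
      "a few percent, and their difference shows the cross-method spread.")
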