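"""Partition long reads into haplotype-specific sets.

Reads are assigned via their marker overlaps: >= 500 bp aligned to a marker,
largest overlap wins, collapsed markers randomize among their groups.
"""

from polygamete import (SimConfig, bin_reads, build_pap_matrix, group_contigs,
                        simulate_gametes, simulate_genome, simulate_reads)
from polygamete.simulate import simulate_marker_counts, true_markers

cfg = SimConfig(n_chromosomes=2, chrom_length_bp=1_000_000, n_gametes=400,
                seed=4)
genome = simulate_genome(cfg)
gametes = simulate_gametes(genome)
markers = true_markers(genome)
pap = build_pap_matrix(simulate_marker_counts(genome, gametes, markers),
                       markers, min_informative=20)
grouping = group_contigs(pap)

records, read_truth = simulate_reads(genome, n_reads=10_000)
table, summary = bin_reads(records, markers, grouping, seed=4)

frac = summary.attrs["assigned_fraction"]
print(f"{len(table)} reads, assigned fraction: {100 * frac:.2f}%")
per_group = summary[summary["group_id"] >= 0]
print(f"reads per group: min {per_group['n_reads'].min()}, "
      f"max {per_group['n_reads'].max()} over {len(per_group)} groups")
# With 8 haplotype groups (2 chromosomes x 4) and uniform read sampling,
# each group receives ~1/8 of the reads; reads from collapsed (IBD) regions
# are split randomly among the groups sharing the region.
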