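"""Simulate a small labeled tetraploid genome and its pollen gametes.

Builds two 600-kb chromosomes with four haplotypes each, half of the genome
inside identical-by-descent (IBD) blocks, then draws 300 diploid gametes and
their low-coverage marker read counts.
"""

from collections import Counter

from polygamete import SimConfig, simulate_gametes, simulate_genome
from polygamete.simulate import simulate_marker_counts, true_markers

cfg = SimConfig(n_chromosomes=2, chrom_length_bp=600_000, n_gametes=300, seed=1)
genome = simulate_genome(cfg)
gametes = simulate_gametes(genome)

print(f"contigs: {len(genome.contigs)}")
print(f"realized IBD fraction: {genome.ibd_fraction_realized():.3f} "
      f"(target {cfg.ibd_fraction})")
classes = Counter(c.copy_number for c in genome.contigs)
for k in sorted(classes):
    name = {1: "haplotigs", 2: "diplotigs", 3: "triplotigs",
            4: "tetraplotigs"}[k]
    print(f"  {name}: {classes[k]}")

markers = true_markers(genome)
counts = simulate_marker_counts(genome, gametes, markers)
mat = counts.drop(columns="marker_id").to_numpy()
print(f"markers: {len(markers)}, gametes: {len(gametes)}")
print(f"mean reads per marker per gamete: {mat.mean():.1f}")
# Each gamete carries 2 of the 4 haplotypes, so a haplotig marker is covered
# in about half of the gametes; that presence/absence signal is what the
# linkage clustering runs on.
hap = mat[markers["copy_class"].to_numpy() == 1] > 0
print(f"haplotig marker presence rate across gametes: {hap.mean():.3f} "
      "(expected ~0.5)")
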