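# Methods

This note documents the models, parameter choices and numerical conventions
behind `polygamete`, and what the bundled simulator does and does not
emulate.

## Phasing model

The method treats each ~50-kb contig interval ("coverage marker") as a
dominant genetic marker scored across a panel of diploid gametes.  Its core
assumptions are:

- **Random bivalent pairing.**  At tetraploid meiosis the four homologs pair
  two-and-two; all three pairings are equally likely, so a gamete carries
  each unordered haplotype pair with probability 1/6 and each single
  haplotype with probability 1/2.  Under this model the carrier indicators
  of two homologous haplotypes at one locus have correlation −1/3, which is
  why the homology threshold of −0.25 separates homologs (−1/3) from
  independent chromosomes (≈ 0) with a wide margin given a few hundred
  gametes.
- **Locally rare recombination.**  Crossovers decay PAP correlation along a
  chromosome roughly as exp(−2·c·d/L) for mean crossovers c per bivalent at
  marker distance d on a chromosome of length L.  The linkage threshold of
  0.55 therefore requires markers bridging any collapsed (unanchored) region
  to sit within a modest genetic distance of each other.  Real genomes meet
  this because large IBD blocks are pericentromeric, where recombination is
  suppressed; the simulator meets it by construction (see below).
- **Depth separability.**  Somatic depth peaks at H·k for k collapsed
  haplotypes must be resolvable; with Poisson-like noise (sd ≈ sqrt(H·k))
  and H ≈ 113 the class boundaries at H·(i+½) misclassify well under 1% of
  10-kb windows.

## Key parameters

| parameter | default | meaning |
|---|---|---|
| `H` (`somatic_depth_per_haplotype`) | 113× | per-haplotype somatic depth; sets the copy-class bounds H·(i+½) |
| `theta_link` | 0.55 | minimum end-marker PAP correlation for a linkage edge |
| `theta_hom` | −0.25 | maximum marker correlation marking two groups homologous |
| `min_haplotig_bp` | 100 kb | haplotigs below this are rescued, not clustered |
| `min_overlap_bp` | 500 bp | read-to-marker overlap floor for binning |
| `min_informative` | 50 | markers with raw count > 7·N/10⁶ a gamete needs for a stable m_r; lower it for panels with few markers |
| `window_bp` / `marker_bp` | 10 kb / 50 kb | depth window and coverage-marker sizes |
| `k` | 21 | k-mer size for trio evaluation |
| `n_gametes` / `gamete_coverage` | 717 / 0.18× | gamete panel emulated by the simulator |
| `crossovers_per_bivalent_mean` | 1.0 | Poisson mean crossovers per bivalent; a typical plant value, exposed because the emulated study does not report a per-chromosome rate |
| `ibd_fraction` | 0.5 | genome fraction inside IBD blocks |
| `double_reduction_rate` | 0.0 | probability both gamete chromatids derive from one bivalent |

## The simulator

`synthetic` genomes are built per chromosome as alternating unique segments
and IBD blocks, window-aligned:

- **IBD blocks** hit the target fraction exactly (to window resolution).
  Block lengths are jittered around `ibd_block_mean_bp` within [0.5, 1.5]×
  the mean, and blocks are separated by at least `ibd_min_gap_bp` (default
  100 kb) of unique sequence.  The spacing guarantees that every haplotype
  retains clusterable ≥100-kb haplotigs between collapsed regions and that
  marker pairs flanking a block stay within the genetic distance the 0.55
  threshold tolerates — the role pericentromeric recombination suppression
  plays in real genomes, which the uniform-crossover simulator does not
  model.  Sharing multiplicity defaults to 80% two-way and 20% three-way
  blocks; four-way blocks default to zero weight because a contig collapsed
  across all four haplotypes carries no linkage signal and can never be
  grouped (a structural limitation of the method, exercisable via
  `ibd_share_weights`).
- **Sequences** (optional, for the k-mer path): haplotypes mutate from a
  random ancestral sequence; IBD members share one mutation lineage and are
  bit-identical inside blocks.  The per-lineage substitution rate is solved
  from 2μ − (4/3)μ² = r so the realized pairwise SNP density in divergent
  regions equals the configured r (default 1/60) in expectation despite
  same-site collisions.
- **Meiosis**: uniform choice among the three bivalent pairings, one
  recombinant chromatid per bivalent with Poisson crossovers at uniform
  positions; optional double reduction takes both chromatids from one
  bivalent.
- **Gamete read counts** at a marker are Poisson with rate
  (coverage/read_length) × (bp of the marker covered by mosaics whose source
  haplotype belongs to the marker's contig).  The fractional-coverage form
  means a crossover inside a marker contributes proportionally rather than
  all-or-nothing.
- **Somatic window depths** are Normal(H·k, sqrt(H·k)) truncated at 0.
- **Long reads** are sampled uniformly over the four haplotypes and reported
  as contig alignment records, split at contig junctions.

What the simulator does **not** emulate: read-level sequencing errors and
mapping ambiguity, organellar contamination, chimeric contigs, repeat-driven
coverage inflation (replotigs arise only through depth noise), non-uniform
crossover landscapes, and segregation distortion.  Passing tests on the
simulator therefore demonstrates the statistical machinery — depth
classification, genotyping, linkage clustering, binning, evaluation — under
the stated meiosis and noise model, not robustness to alignment artifacts in
real data.

## Numerical conventions and tie-breaks

- **Rounding** is half-up everywhere the method rounds (class bounds:
  169.5 → 170; genotypes: floor(x + 0.5)), then genotypes are clipped into
  the class domain.  Round-then-clip is used, not clip-then-round.
- **Marker chunking**: runs of same-class windows are cut into `marker_bp`
  pieces; a trailing remainder at least half a window long stands as its own
  shorter marker, smaller contig-end stubs are absorbed into the previous
  piece.  A 70-kb run therefore yields a 50-kb and a 20-kb marker.
- **Zero-variance PAPs** (all tetraplotig markers, fixated patterns) return
  NaN correlations and never contribute edges, homology calls or rescue
  scores.  The bitwise-AND score is the exception: it masks the collapsed
  PAP by a candidate group's carriers and checks variance of the *masked*
  vector, so a saturated diplotig pattern (every gamete a carrier) is still
  scorable.
- **AND-score binarization** is class-dependent: diplotig genotypes binarize
  at ≥ 1; triplotig genotypes at ≥ 2, because their domain {1,2} never drops
  to 0 — the ≥ 2 indicator equals "does not carry the missing homolog" and
  is the informative signal.  Correlations and AND scores are clamped to
  [−1, 1] and AND scores are quantized to 9 decimals before ranking so that
  float noise cannot reorder exact ties.
- **Ties** (argmax rescue targets, top-k AND scores, equal read overlaps)
  break deterministically toward the lowest group id / earliest
  (contig, start), and are flagged in the output.
- **Clustering determinism**: vertices, components and groups are processed
  in canonical (sorted) order, so results are independent of input row
  order; conflict-driven splitting removes the minimum-weight edge of any
  component whose members' end markers correlate below `theta_hom`, repeating
  until no conflict remains.
- **Read-binning randomness** derives a per-read generator from
  blake2b(read_id) XOR seed, making single-read assignment reproducible in
  isolation and the whole binning independent of record order.
- **Degenerate inputs**: gametes with no aligned reads, an all-dropped
  gamete panel, unknown contigs in alignment records, overlapping depth
  windows and invalid configurations raise errors rather than propagate
  NaNs.

## Design choices

- Graph clustering is thresholded connected components plus conflict-driven
  edge removal — the simplest procedure consistent with the two thresholds;
  no community detection is layered on top, so group counts are not biased
  toward an expected number (an `expected_groups` option only emits a
  diagnostic).
- The homology test runs over all (subsampled, default cap 30 per group)
  markers of each group rather than only end markers, which maximizes the
  chance of catching a same-locus homolog pair; the cap bounds the O(G²·m²)
  correlation work.
- Contig copy class is the bp-majority class of its markers, making the
  pipeline robust to isolated misclassified windows inside a contig.
- A contig whose markers are all four-copy is left unassigned unless a
  non-tetraplotig marker ties it to a chromosome, in which case it joins all
  four groups of that chromosome.
- Parental k-mer sets use canonical (strand-collapsed) k-mers; coverage
  windows (defaults 6–12 / 5–11) apply only when parents are given as reads
  with multiplicities — truth sequences count every k-mer once.
- Counts-mode evaluation restricts to markers whose contig haplotypes are
  parent-pure, mirroring the uninformativeness of k-mers shared between
  parents.

## Problem sizes

The test suite and the acceptance script exercise the full method on
simulations of 12 chromosomes × 1 Mb with 700 gametes (about 820 markers and
a dozen seconds per replicate), ten seeded replicates for the recovery
statistics, and 100,000 15-kb reads for the binning rate; smaller 1–3
chromosome simulations back the unit and property tests.  These sizes were
chosen so the whole distribution checks run in minutes while every group,
chromosome and threshold of the full-scale design (48 groups, 12
chromosomes) is still exercised.

## Known limitations

- Groups are sets of contigs; ordering/orienting contigs within a group
  (scaffolding) is out of scope.
- The simulator's IBD placement is uniform along the chromosome (a flagless
  simplification); pericentromeric enrichment and recombination suppression
  are not modeled, which is precisely why the default block sizes are kept
  small relative to the chromosome.
- Depth computation from BAMs, SNP calling in gametes, genotype imputation
  and organelle filtering are upstream of this package's inputs.
- With very few gametes the −0.25 homology threshold can fire on sampling
  noise between unrelated groups (the 6-gamete worked example already shows
  a −1/3 correlation between non-complementary patterns); the method is
  designed for panels of hundreds of gametes.
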