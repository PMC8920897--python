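"""Simulator ground-truth properties: IBD structure, meiosis, read counts."""

from itertools import combinations

import numpy as np
import pytest

from polygamete.simulate import (BIVALENT_PAIRINGS, ConfigError, SimConfig,
                                 simulate_gametes, simulate_genome,
                                 simulate_marker_counts,
                                 simulate_window_depths, true_markers)


def test_config_validation():
    with pytest.raises(ConfigError):
        SimConfig(ibd_fraction=1.5)
    with pytest.raises(ConfigError):
        SimConfig(marker_bp=55_000)  # not a multiple of the window
    with pytest.raises(ConfigError):
        SimConfig(n_haplotypes=2)
    with pytest.raises(ConfigError):
        SimConfig(ibd_fraction=1.0, ibd_block_mean_bp=2_000_000,
                  chrom_length_bp=1_000_000)


def test_no_ibd_means_only_haplotigs():
    cfg = SimConfig(n_chromosomes=3, chrom_length_bp=200_000, ibd_fraction=0.0,
                    seed=1)
    genome = simulate_genome(cfg)
    assert all(c.copy_number == 1 for c in genome.contigs)
    assert len(genome.contigs) == 4 * cfg.n_chromosomes


def test_realized_ibd_fraction_near_target(small_genome):
    target = small_genome.config.ibd_fraction
    assert abs(small_genome.ibd_fraction_realized() - target) <= 0.1 * target


def test_contig_tiling_covers_each_haplotype_exactly_once(small_genome):
    cfg = small_genome.config
    for chrom in range(cfg.n_chromosomes):
        for h in range(4):
            ivs = sorted((c.start, c.end) for c in small_genome.contigs
                         if c.chrom == chrom and h in c.haplotypes)
            assert ivs[0][0] == 0 and ivs[-1][1] == cfg.chrom_length_bp
            assert all(a[1] == b[0] for a, b in zip(ivs, ivs[1:]))


def test_ibd_members_share_identical_sequence():
    cfg = SimConfig(n_chromosomes=1, chrom_length_bp=300_000, sequences=True,
                    seed=5)
    genome = simulate_genome(cfg)
    assert genome.ibd_blocks
    for b in genome.ibd_blocks:
        seqs = [genome.sequences[(b.chrom, h)][b.start:b.end]
                for h in sorted(b.haplotypes)]
        for s in seqs[1:]:
            assert np.array_equal(seqs[0], s)


def test_pairwise_divergence_matches_target_rate():
    """Non-IBD haplotype pairs differ at ~1 SNP per 60 bp (binomial tolerance)."""
    cfg = SimConfig(n_chromosomes=1, chrom_length_bp=500_000, ibd_fraction=0.0,
                    sequences=True, seed=9)
    genome = simulate_genome(cfg)
    L = cfg.chrom_length_bp
    rates = []
    for a, b in combinations(range(4), 2):
        diff = (genome.sequences[(0, a)] != genome.sequences[(0, b)]).sum()
        rates.append(diff / L)
    target = cfg.snp_rate_divergent
    sigma = np.sqrt(target / L)  # binomial sd of the rate estimate
    for r in rates:
        assert abs(r - target) < 5 * sigma


def test_seeded_determinism():
    cfg = SimConfig(n_chromosomes=2, chrom_length_bp=200_000, n_gametes=40,
                    seed=42)
    g1, g2 = simulate_genome(cfg), simulate_genome(cfg)
    assert g1.contig_table().equals(g2.contig_table())
    gam1 = simulate_gametes(g1)
    gam2 = simulate_gametes(g2)
    assert all(a.mosaics == b.mosaics for a, b in zip(gam1, gam2))
    c1 = simulate_marker_counts(g1, gam1)
    c2 = simulate_marker_counts(g2, gam2)
    assert c1.equals(c2)


def test_gametes_without_recombination_carry_two_intact_haplotypes():
    cfg = SimConfig(n_chromosomes=2, chrom_length_bp=200_000, n_gametes=60,
                    crossovers_per_bivalent_mean=0.0, seed=3)
    genome = simulate_genome(cfg)
    for g in simulate_gametes(genome):
        for chrom in range(cfg.n_chromosomes):
            m1, m2 = g.mosaics[chrom]
            assert len(m1) == 1 and len(m2) == 1
            assert m1[0][2] != m2[0][2]  # two distinct haplotypes


def test_haplotype_pairs_equifrequent():
    """Each unordered haplotype pair occurs in ~1/6 of gametes.

    Oracle by enumeration: 3 pairings x (2 x 2) chromatid choices yield each
    of the 6 unordered pairs in exactly 2 of the 12 outcomes.
    """
    outcomes = []
    for pairing in BIVALENT_PAIRINGS:
        for i in range(2):
            for j in range(2):
                outcomes.append(frozenset((pairing[0][i], pairing[1][j])))
    from collections import Counter
    enum = Counter(outcomes)
    assert all(v == 2 for v in enum.values()) and len(enum) == 6

    cfg = SimConfig(n_chromosomes=1, chrom_length_bp=100_000, n_gametes=3000,
                    crossovers_per_bivalent_mean=0.0, seed=8)
    genome = simulate_genome(cfg)
    counts = Counter()
    for g in simulate_gametes(genome):
        m1, m2 = g.mosaics[0]
        counts[frozenset((m1[0][2], m2[0][2]))] += 1
    for pair in enum:
        freq = counts[pair] / cfg.n_gametes
        assert abs(freq - 1 / 6) < 4 * np.sqrt((1 / 6) * (5 / 6) / cfg.n_gametes)


def test_mean_crossovers_matches_poisson_mean():
    cfg = SimConfig(n_chromosomes=1, chrom_length_bp=1_000_000, n_gametes=800,
                    crossovers_per_bivalent_mean=1.5, seed=2)
    genome = simulate_genome(cfg)
    gametes = simulate_gametes(genome)
    n_co = [len(g.crossovers[0]) for g in gametes]
    mean_per_mosaic = np.mean(n_co) / 2
    assert abs(mean_per_mosaic - 1.5) < 0.15


def test_double_reduction_draws_both_mosaics_from_one_bivalent():
    cfg = SimConfig(n_chromosomes=1, chrom_length_bp=100_000, n_gametes=400,
                    crossovers_per_bivalent_mean=0.0, double_reduction_rate=1.0,
                    seed=4)
    genome = simulate_genome(cfg)
    for g in simulate_gametes(genome):
        m1, m2 = g.mosaics[0]
        pair = {m1[0][2], m2[0][2]}
        assert any(pair <= set(biv) for p in BIVALENT_PAIRINGS for biv in p)


def test_marker_counts_zero_without_carrier_and_double_for_tetraplotig():
    cfg = SimConfig(n_chromosomes=1, chrom_length_bp=400_000, ibd_fraction=0.5,
                    ibd_share_weights=(0.0, 0.0, 1.0), n_gametes=50,
                    crossovers_per_bivalent_mean=0.0, seed=6)
    genome = simulate_genome(cfg)
    gametes = simulate_gametes(genome)
    markers = true_markers(genome)
    rate = cfg.gamete_coverage / cfg.read_length_bp

    # a gamete carrying neither haplotype of a haplotig marker gets count 0
    counts = simulate_marker_counts(genome, gametes, markers)
    mat = counts[[g.gamete_id for g in gametes]].to_numpy()
    hap_rows = np.flatnonzero(markers["copy_class"].to_numpy() == 1)
    checked = 0
    for r in hap_rows:
        contig = genome.contig(markers["contig_id"].iat[r])
        for gi, g in enumerate(gametes):
            carried = {m[0][2] for m in g.mosaics[0]}
            if not (carried & contig.haplotypes):
                assert mat[r, gi] == 0
                checked += 1
    assert checked > 0

    # tetraplotig markers: both mosaics always overlap -> rate for c = 2
    tet_rows = np.flatnonzero(markers["copy_class"].to_numpy() == 4)
    assert len(tet_rows) > 0
    lam2 = 2 * rate * markers["W"].to_numpy()[tet_rows]
    observed = mat[tet_rows].mean(axis=1)
    assert np.allclose(observed, lam2, rtol=0.25)


def test_gamete_coverage_marginal(small_genome, small_gametes, small_counts):
    """Realized per-gamete coverage tracks the configured 0.18x within 5%."""
    cfg = small_genome.config
    markers = true_markers(small_genome)
    mat = small_counts[[g.gamete_id for g in small_gametes]].to_numpy()
    # expected carried bp per gamete: two mosaics x chromosomes x length
    carried_bp = 2 * cfg.n_chromosomes * cfg.chrom_length_bp
    realized = mat.sum(axis=0).mean() * cfg.read_length_bp / carried_bp
    assert abs(realized - cfg.gamete_coverage) < 0.05 * cfg.gamete_coverage


def test_somatic_depth_means_scale_with_copy_number(small_genome):
    depths = simulate_window_depths(small_genome)
    H = small_genome.config.somatic_depth_per_haplotype
    by_contig = {c.contig_id: c.copy_number for c in small_genome.contigs}
    depths = depths.assign(k=[by_contig[c] for c in depths["contig_id"]])
    for k, grp in depths.groupby("k"):
        if len(grp) < 10:
            continue
        assert abs(grp["depth"].mean() - H * k) < 4 * np.sqrt(H * k / len(grp))
    two = depths[depths["k"] == 2]
    if len(two):
        assert abs(two["depth"].mean() - 226.0) < 5.0


def test_presence_matrix_has_four_patterns_without_recombination():
    """With no crossovers and no IBD, marker presence columns are OR-pairs of
    exactly four per-haplotype patterns per chromosome."""
    cfg = SimConfig(n_chromosomes=2, chrom_length_bp=300_000, ibd_fraction=0.0,
                    crossovers_per_bivalent_mean=0.0, n_gametes=150,
                    gamete_coverage=18.0, seed=13)
    genome = simulate_genome(cfg)
    gametes = simulate_gametes(genome)
    markers = true_markers(genome)
    counts = simulate_marker_counts(genome, gametes, markers)
    mat = counts[[g.gamete_id for g in gametes]].to_numpy() > 0
    for chrom in range(cfg.n_chromosomes):
        rows = [i for i in range(len(markers))
                if genome.contig(markers["contig_id"].iat[i]).chrom == chrom]
        patterns = {tuple(mat[i]) for i in rows}
        assert len(patterns) == 4
        stacked = np.array(sorted(patterns))
        assert (stacked.sum(axis=0) == 2).all()  # every gamete carries 2 haps
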