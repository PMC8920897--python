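"""Linkage-graph clustering, homology detection, rescue and multi-copy rules."""

import itertools

import numpy as np
import pytest

from conftest import pap_from_strings
from polygamete.cluster import (assign_multicopy_contig, build_linkage_graph,
                                cluster_graph, detect_homologous_groups,
                                group_contigs, grouping_accuracy,
                                rescue_small_haplotigs, _binarize)
from polygamete.pap import build_pap_matrix
from polygamete.simulate import (SimConfig, simulate_gametes, simulate_genome,
                                 simulate_marker_counts, true_markers)


class TestWorkedExample:
    """The six-contig toy: A=F='111000', B=D='000111', E='101010', C='111111'."""

    PATTERNS = {"A": "111000", "B": "000111", "C": "111111",
                "D": "000111", "E": "101010", "F": "111000"}

    def _pap(self):
        return pap_from_strings(self.PATTERNS, {"C": 2})

    def test_haplotig_clusters(self):
        pap = self._pap()
        G = build_linkage_graph(pap)
        assert G.has_edge("A", "F") and G.has_edge("B", "D")
        assert not G.has_edge("A", "E")  # cor = 1/3, below the 0.55 threshold
        groups = cluster_graph(G, pap)
        assert groups == [["A", "F"], ["B", "D"], ["E"]]

    def test_diplotig_extends_two_clusters(self):
        pap = self._pap()
        result = group_contigs(pap)
        members = [set(g) for g in result.groups]
        assert {"A", "C", "F"} in members
        assert {"B", "C", "D"} in members
        assert {"E"} in members
        assert result.group_of_contig["C"] == [0, 1]

    def test_complementary_groups_are_homologous(self):
        pap = self._pap()
        groups = cluster_graph(build_linkage_graph(pap), pap)
        chrom_map, warnings = detect_homologous_groups(groups, pap)
        # cor(A, B) = -1 and cor(E, B) = -1/3, both below -0.25: all three
        # groups are homologous haplotypes of one chromosome
        assert chrom_map[0] == chrom_map[1] == chrom_map[2]
        assert warnings  # the chromosome has 3 groups, not the expected 4


class TestAndRuleIdentity:
    def test_exhaustive_disjoint_sums_at_six_gametes(self):
        """If Z = X + Y with disjoint carriers, binarize(Z) & X == X and the
        assignment recovers exactly X's and Y's groups."""
        n_checked = 0
        for bits_x in range(64):
            x = np.array([(bits_x >> i) & 1 for i in range(6)], dtype=np.int8)
            if x.std() == 0:
                continue
            free = [i for i in range(6) if x[i] == 0]
            for r in range(1, 2 ** len(free)):
                y = np.zeros(6, dtype=np.int8)
                for j, i in enumerate(free):
                    y[i] = (r >> j) & 1
                if y.std() == 0:
                    continue
                z = x + y
                zb = _binarize(z[None, :], 2)[0]
                assert np.array_equal(zb & x, x)
                assert np.array_equal(zb & y, y)
                chosen, scores, _ = assign_multicopy_contig(
                    z[None, :], 2, [x[None, :], y[None, :]])
                assert chosen == [0, 1]
                assert scores[0] == pytest.approx(1.0)
                n_checked += 1
        # sum over nonconstant x of (2^zeros(x) - 1) nonzero disjoint y
        assert n_checked == 602

    def test_degenerate_diplotig_flags_tie_or_partial(self):
        # Z == X: no gamete exposes the second haplotype
        x = np.array([1, 1, 0, 0, 1, 0], dtype=np.int8)
        w = np.array([0, 1, 1, 0, 0, 1], dtype=np.int8)
        chosen, scores, flags = assign_multicopy_contig(
            x[None, :], 2, [x[None, :], w[None, :]])
        assert chosen[0] == 0 and scores[0] == pytest.approx(1.0)
        assert len(chosen) == 2  # second-best group still returned

    def test_triplotig_scores_exclude_missing_homolog(self):
        """A triplotig's genotype is 2 minus the missing homolog's carrier, so
        the class-3 binarization must expose that signal."""
        rng = np.random.default_rng(0)
        pairs = list(itertools.combinations(range(4), 2))
        draws = rng.integers(0, 6, 400)
        carriers = np.zeros((4, 400), dtype=np.int8)
        for g, d in enumerate(draws):
            for h in pairs[d]:
                carriers[h, g] = 1
        z = np.int8(2) - carriers[3]  # collapses haplotypes {0,1,2}
        chosen, _, _ = assign_multicopy_contig(
            z[None, :], 3, [carriers[h][None, :] for h in range(4)])
        assert sorted(chosen) == [0, 1, 2]


class TestSimulatedGrouping:
    def _pap(self, cfg):
        genome = simulate_genome(cfg)
        gametes = simulate_gametes(genome)
        markers = true_markers(genome)
        counts = simulate_marker_counts(genome, gametes, markers)
        return genome, build_pap_matrix(counts, markers, min_informative=10)

    def test_single_chromosome_recovers_four_groups(self):
        cfg = SimConfig(n_chromosomes=1, chrom_length_bp=1_000_000,
                        n_gametes=400, seed=31)
        genome, pap = self._pap(cfg)
        result = group_contigs(pap)
        assert result.n_groups == 4
        assert result.n_chromosomes == 1

    def test_exact_recovery_without_recombination_noise_or_ibd(self):
        cfg = SimConfig(n_chromosomes=2, chrom_length_bp=600_000,
                        ibd_fraction=0.0, crossovers_per_bivalent_mean=0.0,
                        n_gametes=200, gamete_coverage=18.0, seed=32)
        genome, pap = self._pap(cfg)
        result = group_contigs(pap)
        truth = {c.contig_id: c.haplotypes for c in genome.contigs}
        # each group is exactly the contig set of one haplotype
        expected = {}
        for cid, haps in truth.items():
            expected.setdefault((genome.contig(cid).chrom, min(haps)),
                                set()).add(cid)
        got = {frozenset(g) for g in result.groups}
        assert got == {frozenset(v) for v in expected.values()}
        purity, accuracy = grouping_accuracy(result, pap, truth)
        assert (purity["purity"] == 1.0).all()
        assert accuracy == 1.0

    def test_grouping_accuracy_with_ibd_and_recombination(self, small_pipeline):
        _, result, _ = small_pipeline
        assert result.metrics["grouping_accuracy"] >= 0.996
        assert result.metrics["n_groups"] == 12
        assert result.metrics["n_chromosomes"] == 3

    def test_rescue_assigns_short_haplotigs_to_true_group(self):
        cfg = SimConfig(n_chromosomes=1, chrom_length_bp=800_000,
                        ibd_fraction=0.4, ibd_block_mean_bp=80_000,
                        n_gametes=400, seed=33)
        genome, pap = self._pap(cfg)
        groups = cluster_graph(build_linkage_graph(pap), pap)
        rescued = rescue_small_haplotigs(groups, pap)
        truth = {c.contig_id: c.haplotypes for c in genome.contigs}
        group_hap = []
        for members in groups:
            haps = {min(truth[cid]) for cid in members}
            assert len(haps) == 1
            group_hap.append(haps.pop())
        assert rescued, "expected at least one sub-100kb haplotig"
        correct = sum(group_hap[g] in truth[cid]
                      for cid, (g, _, _) in rescued.items())
        assert correct / len(rescued) >= 0.99

    def test_collapsed_contigs_get_all_true_groups(self, small_pipeline):
        cfg, result, out = small_pipeline
        assert result.metrics["grouping_accuracy"] >= 0.95


class TestDeterminism:
    def test_clustering_invariant_to_marker_order(self):
        cfg = SimConfig(n_chromosomes=2, chrom_length_bp=600_000,
                        n_gametes=250, seed=41)
        genome = simulate_genome(cfg)
        gametes = simulate_gametes(genome)
        markers = true_markers(genome)
        counts = simulate_marker_counts(genome, gametes, markers)
        pap1 = build_pap_matrix(counts, markers, min_informative=10)
        rng = np.random.default_rng(1)
        perm = rng.permutation(len(markers))
        markers_sh = markers.iloc[perm].reset_index(drop=True)
        counts_sh = counts.iloc[perm].reset_index(drop=True)
        pap2 = build_pap_matrix(counts_sh, markers_sh, min_informative=10)
        r1 = group_contigs(pap1)
        r2 = group_contigs(pap2)
        assert [sorted(g) for g in r1.groups] == [sorted(g) for g in r2.groups]
        assert r1.chromosome_of_group == r2.chromosome_of_group

    def test_chromosome_count_never_exceeds_group_count(self, small_pipeline):
        _, result, _ = small_pipeline
        g = result.grouping
        assert g.n_chromosomes <= g.n_groups


class TestEdgeCases:
    def test_empty_graph_empty_grouping(self):
        pap = pap_from_strings({"A": "1100"}, {}, contig_bp=50_000)
        G = build_linkage_graph(pap)  # 50 kb contig: below the vertex floor
        assert len(G) == 0
        assert cluster_graph(G, pap) == []

    def test_two_disjoint_cliques_give_two_groups(self):
        pap = pap_from_strings(
            {"A": "111000", "B": "111000", "C": "111000",
             "X": "000111", "Y": "000111", "Z": "000111"}, {})
        groups = cluster_graph(build_linkage_graph(pap), pap)
        assert [set(g) for g in groups] == [{"A", "B", "C"}, {"X", "Y", "Z"}]

    def test_rescue_tie_breaks_to_lowest_group_and_flags(self):
        pap = pap_from_strings(
            {"A": "111000", "B": "000111", "s": "111000"}, {},
            contig_bp=120_000)
        pap.markers.loc[pap.markers["contig_id"] == "s",
                        ["end", "W"]] = 60_000
        groups = [["A"], ["B"]]
        # make both groups equally correlated with s by duplicating pattern
        pap.genotypes[1] = pap.genotypes[0]
        rescued = rescue_small_haplotigs(groups, pap)
        g, conf, flags = rescued["s"]
        assert g == 0 and conf == pytest.approx(1.0)
        assert "tie" in flags
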