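"""Linkage clustering of contigs into haplotype groups from PAP correlations.

Haplotig markers from the same haplotype are co-inherited across gametes and
their PAPs correlate strongly; markers from homologous haplotypes of the same
chromosome anticorrelate (a diploid gamete carrying one homolog is less
likely to carry another), and markers from different chromosomes segregate
independently.  The grouping therefore proceeds in four steps:

1. a linkage graph over haplotigs >= 100 kb, connecting pairs whose best
   end-marker PAP correlation exceeds 0.55; connected components (after
   removing edges that merge anticorrelated, i.e. homologous, vertices) are
   the haplotype groups;
2. groups whose markers reach correlations below -0.25 are homologous —
   their transitive closure defines the chromosomes (expected: 4 groups per
   chromosome);
3. haplotigs shorter than 100 kb join the group of their single most
   correlated marker;
4. collapsed contigs (diplotigs/triplotigs) are assigned to the k groups
   maximizing cor(Z & X, X), the bitwise-AND test: if Z merges haplotypes X
   and Y then masking Z by X's carriers reproduces X.  Pure tetraplotig
   contigs carry no linkage information and stay unassigned unless a
   non-tetraplotig marker ties them to a chromosome.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .depth import REP_CLASS
from .pap import PAPMatrix, correlation_matrix

__all__ = [
    "DEFAULT_THETA_LINK",
    "DEFAULT_THETA_HOM",
    "DEFAULT_MIN_HAPLOTIG_BP",
    "GroupingResult",
    "build_linkage_graph",
    "cluster_graph",
    "detect_homologous_groups",
    "rescue_small_haplotigs",
    "assign_multicopy_contig",
    "group_contigs",
    "grouping_accuracy",
]

DEFAULT_THETA_LINK = 0.55
DEFAULT_THETA_HOM = -0.25
DEFAULT_MIN_HAPLOTIG_BP = 100_000

#: genotype threshold that binarizes a PAP into a carrier indicator, per class.
#: For collapsed classes the informative indicator is "all copies of the
#: marker's haplotype set are present": g >= 1 for diplotigs, g >= 2 for
#: triplotigs (whose genotypes never drop to 0).
_BINARIZE_AT = {1: 1, 2: 1, 3: 2}


@dataclass
class _ContigInfo:
    contig_id: str
    length: int
    majority_class: int
    marker_idx: list[int]          # all non-REP marker rows of this contig
    class_idx: list[int]           # rows of majority-class markers


@dataclass
class GroupingResult:
    """Marker/contig -> group assignments and group -> chromosome map."""

    groups: list[list[str]]                       # member contigs per group
    group_of_contig: dict[str, list[int]]
    chromosome_of_group: dict[int, int]
    confidence: dict[str, float] = field(default_factory=dict)
    flags: dict[str, list[str]] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    @property
    def n_chromosomes(self) -> int:
        return len(set(self.chromosome_of_group.values()))

    def groups_of_chromosome(self, chrom: int) -> list[int]:
        return sorted(g for g, c in self.chromosome_of_group.items() if c == chrom)

    def to_frame(self, pap: PAPMatrix) -> pd.DataFrame:
        rows = []
        m = pap.markers
        for i in range(len(m)):
            cid = m["contig_id"].iat[i]
            for g in self.group_of_contig.get(cid, []):
                rows.append((m["marker_id"].iat[i], cid, int(m["start"].iat[i]),
                             int(m["end"].iat[i]), int(m["copy_class"].iat[i]),
                             g, self.chromosome_of_group.get(g, -1),
                             self.confidence.get(cid, float("nan")),
                             ";".join(self.flags.get(cid, []))))
        return pd.DataFrame(rows, columns=[
            "marker_id", "contig_id", "start", "end", "copy_class", "group_id",
            "chromosome_id", "confidence", "flags"])


def _contig_infos(pap: PAPMatrix,
                  contig_lengths: dict[str, int] | None = None) -> list[_ContigInfo]:
    m = pap.markers
    infos = []
    for cid, grp in m.groupby("contig_id", sort=True):
        grp = grp.sort_values("start")
        idx = [i for i in grp.index if grp.loc[i, "copy_class"] != REP_CLASS]
        if not idx:
            continue
        length = (contig_lengths or {}).get(cid, int(grp["end"].max()))
        bp_per_class = grp.groupby("copy_class")["W"].sum()
        bp_per_class = bp_per_class[bp_per_class.index != REP_CLASS]
        majority = int(bp_per_class.idxmax())
        cls_idx = [i for i in idx if m["copy_class"].iat[i] == majority]
        infos.append(_ContigInfo(cid, length, majority, idx, cls_idx))
    return infos


def _end_markers(info: _ContigInfo, pap: PAPMatrix) -> list[int]:
    """First and last usable (non-constant) majority-class marker rows."""
    zv = pap.zero_variance
    usable = [i for i in info.class_idx if not zv[i]]
    if not usable:
        return []
    return sorted({usable[0], usable[-1]})


def build_linkage_graph(pap: PAPMatrix,
                        theta_link: float = DEFAULT_THETA_LINK,
                        min_haplotig_bp: int = DEFAULT_MIN_HAPLOTIG_BP,
                        contig_lengths: dict[str, int] | None = None) -> nx.Graph:
    """Thresholded linkage graph over long haplotigs.

    Vertices are haplotig contigs of at least ``min_haplotig_bp``; an edge
    connects two vertices if the highest correlation between the PAPs of
    their end markers exceeds ``theta_link``.
    """
    infos = _contig_infos(pap, contig_lengths)
    vertices = [c for c in infos
                if c.majority_class == 1 and c.length >= min_haplotig_bp]
    G = nx.Graph()
    ends: dict[str, list[int]] = {}
    for c in vertices:
        em = _end_markers(c, pap)
        if not em:
            continue
        ends[c.contig_id] = em
        G.add_node(c.contig_id, length=c.length, end_markers=em)
    ids = sorted(ends)
    all_rows = sorted({i for em in ends.values() for i in em})
    pos = {r: j for j, r in enumerate(all_rows)}
    corr = correlation_matrix(pap.genotypes[all_rows])
    for a, b in itertools.combinations(ids, 2):
        vals = [corr[pos[i], pos[j]] for i in ends[a] for j in ends[b]]
        vals = [v for v in vals if np.isfinite(v)]
        if not vals:
            continue
        w = max(vals)
        if w > theta_link:
            G.add_edge(a, b, weight=w)
    return G


def _component_conflict(comp: list[str], G: nx.Graph, pap: PAPMatrix,
                        theta_hom: float) -> bool:
    rows = sorted({i for n in comp for i in G.nodes[n]["end_markers"]})
    if len(rows) < 2:
        return False
    corr = correlation_matrix(pap.genotypes[rows])
    low = np.nanmin(corr) if np.isfinite(corr).any() else np.nan
    return np.isfinite(low) and low < theta_hom


def cluster_graph(G: nx.Graph, pap: PAPMatrix,
                  theta_hom: float = DEFAULT_THETA_HOM) -> list[list[str]]:
    """Connected components, split while any component joins homologous vertices.

    A component containing an end-marker pair correlated below ``theta_hom``
    has merged different haplotypes; its minimum-weight edge is removed and
    the check repeats.  Groups are returned canonically ordered (by smallest
    member id) so the result is independent of input order.
    """
    H = G.copy()
    while True:
        conflict_found = False
        for comp in nx.connected_components(H):
            comp = sorted(comp)
            if len(comp) < 2:
                continue
            if _component_conflict(comp, H, pap, theta_hom):
                edges = sorted(H.subgraph(comp).edges(data="weight"),
                               key=lambda e: (e[2], e[0], e[1]))
                u, v, _ = edges[0]
                H.remove_edge(u, v)
                conflict_found = True
                break
        if not conflict_found:
            break
    groups = [sorted(c) for c in nx.connected_components(H)]
    groups.sort(key=lambda g: g[0])
    return groups


def _group_marker_pool(groups: list[list[str]], infos: dict[str, _ContigInfo],
                       pap: PAPMatrix, cap: int) -> list[list[int]]:
    zv = pap.zero_variance
    pools = []
    for members in groups:
        rows = [i for cid in members for i in infos[cid].class_idx if not zv[i]]
        if len(rows) > cap:
            sel = np.linspace(0, len(rows) - 1, cap).astype(int)
            rows = [rows[j] for j in sel]
        pools.append(rows)
    return pools


def detect_homologous_groups(groups: list[list[str]], pap: PAPMatrix,
                             theta_hom: float = DEFAULT_THETA_HOM,
                             max_markers_per_group: int = 30,
                             contig_lengths: dict[str, int] | None = None
                             ) -> tuple[dict[int, int], list[str]]:
    """Chromosome map: transitive closure of the negative-correlation relation.

    Two groups are homologous if the lowest correlation between any pair of
    their markers falls below ``theta_hom`` (marker pools are subsampled to
    ``max_markers_per_group`` evenly spaced markers per group for speed).
    """
    infos = {c.contig_id: c for c in _contig_infos(pap, contig_lengths)}
    pools = _group_marker_pool(groups, infos, pap, max_markers_per_group)
    all_rows = sorted({i for p in pools for i in p})
    pos = {r: j for j, r in enumerate(all_rows)}
    corr = correlation_matrix(pap.genotypes[all_rows]) if all_rows else np.empty((0, 0))
    Gh = nx.Graph()
    Gh.add_nodes_from(range(len(groups)))
    for a, b in itertools.combinations(range(len(groups)), 2):
        if not pools[a] or not pools[b]:
            continue
        block = corr[np.ix_([pos[i] for i in pools[a]],
                            [pos[j] for j in pools[b]])]
        if np.isfinite(block).any() and np.nanmin(block) < theta_hom:
            Gh.add_edge(a, b)
    comps = [sorted(c) for c in nx.connected_components(Gh)]
    comps.sort(key=lambda c: c[0])
    chromosome_of_group = {}
    warnings = []
    for chrom, comp in enumerate(comps):
        for g in comp:
            chromosome_of_group[g] = chrom
        if len(comp) != 4:
            warnings.append(
                f"chromosome {chrom} has {len(comp)} groups (expected 4)")
    return chromosome_of_group, warnings


def rescue_small_haplotigs(groups: list[list[str]], pap: PAPMatrix,
                           min_haplotig_bp: int = DEFAULT_MIN_HAPLOTIG_BP,
                           contig_lengths: dict[str, int] | None = None
                           ) -> dict[str, tuple[int, float, list[str]]]:
    """Assign each short, ungrouped haplotig to its argmax-correlation group.

    Returns contig -> (group_id, confidence, flags); ties break toward the
    lowest group id and are flagged.  Contigs whose correlations are all
    undefined stay unassigned.
    """
    infos = {c.contig_id: c for c in _contig_infos(pap, contig_lengths)}
    grouped = {cid for g in groups for cid in g}
    zv = pap.zero_variance
    pool_rows, pool_group = [], []
    for gi, members in enumerate(groups):
        for cid in members:
            for i in infos[cid].class_idx:
                if not zv[i]:
                    pool_rows.append(i)
                    pool_group.append(gi)
    out: dict[str, tuple[int, float, list[str]]] = {}
    if not pool_rows:
        return out
    pool = np.asarray(pool_rows)
    pool_group = np.asarray(pool_group)
    for cid in sorted(infos):
        c = infos[cid]
        if c.majority_class != 1 or cid in grouped or c.length >= min_haplotig_bp:
            continue
        rows = [i for i in c.class_idx if not zv[i]]
        if not rows:
            continue
        sub = correlation_matrix(pap.genotypes[sorted(set(rows) | set(pool))])
        order = sorted(set(rows) | set(pool))
        pos = {r: j for j, r in enumerate(order)}
        block = sub[np.ix_([pos[i] for i in rows], [pos[i] for i in pool])]
        if not np.isfinite(block).any():
            continue
        best_per_group: dict[int, float] = {}
        col_best = np.nanmax(block, axis=0)
        for g, v in zip(pool_group, col_best):
            if np.isfinite(v) and v > best_per_group.get(int(g), -np.inf):
                best_per_group[int(g)] = float(v)
        top = max(best_per_group.values())
        winners = sorted(g for g, v in best_per_group.items() if v >= top - 1e-12)
        flags = ["rescued"] + (["tie"] if len(winners) > 1 else [])
        out[cid] = (winners[0], top, flags)
    return out


def _binarize(geno: np.ndarray, copy_class: int) -> np.ndarray:
    return (geno >= _BINARIZE_AT[copy_class]).astype(np.int8)


def assign_multicopy_contig(z_rows: np.ndarray, copy_class: int,
                            pools: list[np.ndarray]) -> tuple[list[int], list[float], list[str]]:
    """Top-k groups for one collapsed contig by the bitwise-AND correlation test.

    ``z_rows``: genotype rows of the contig's collapsed-class markers;
    ``pools``: per group, binarized carrier indicators of representative
    markers.  Score of a group is max over (z, x) pairs of cor(z_b & x, x)
    with z_b the class-appropriate carrier binarization of z.  Returns the
    ``copy_class`` best groups (ties broken toward lower ids, flagged).
    """
    k = copy_class
    zb = _binarize(z_rows, copy_class)
    scores = np.full(len(pools), -np.inf)
    for gi, xb in enumerate(pools):
        if xb.size == 0:
            continue
        best = -np.inf
        for x in xb:
            sx = x.std()
            if sx == 0:
                continue
            v = zb & x
            sv = v.std(axis=1)
            ok = sv > 0
            if not ok.any():
                continue
            vc = v[ok] - v[ok].mean(axis=1, keepdims=True)
            xc = x - x.mean()
            num = vc @ xc
            den = np.sqrt((vc * vc).sum(axis=1)) * np.sqrt((xc * xc).sum())
            best = max(best, float(np.clip(np.max(num / den), -1.0, 1.0)))
        scores[gi] = best
    # quantize so float noise cannot reorder exact ties; ties then break by id
    quant = np.where(np.isfinite(scores), np.round(scores, 9), -np.inf)
    order = sorted(range(len(pools)), key=lambda g: (-quant[g], g))
    chosen = [g for g in order[:k] if np.isfinite(scores[g])]
    flags = []
    if len(chosen) < k:
        flags.append("partial")
    if len(order) > k and np.isfinite(scores[order[k - 1]]) and \
            quant[order[k - 1]] == quant[order[k]]:
        flags.append("tie")
    return chosen, [float(scores[g]) for g in chosen], flags


def group_contigs(pap: PAPMatrix,
                  theta_link: float = DEFAULT_THETA_LINK,
                  theta_hom: float = DEFAULT_THETA_HOM,
                  min_haplotig_bp: int = DEFAULT_MIN_HAPLOTIG_BP,
                  max_markers_per_group: int = 30,
                  rep_pool_cap: int = 20,
                  contig_lengths: dict[str, int] | None = None,
                  expected_groups: int | None = None) -> GroupingResult:
    """Run the full grouping: graph, clustering, homology, rescue, multi-copy."""
    infos = {c.contig_id: c for c in _contig_infos(pap, contig_lengths)}
    G = build_linkage_graph(pap, theta_link, min_haplotig_bp, contig_lengths)
    groups = cluster_graph(G, pap, theta_hom)
    chrom_map, warnings = detect_homologous_groups(
        groups, pap, theta_hom, max_markers_per_group, contig_lengths)
    if expected_groups is not None and len(groups) != expected_groups:
        warnings.append(f"found {len(groups)} groups, expected {expected_groups}")

    result = GroupingResult(groups=[list(g) for g in groups],
                            group_of_contig={}, chromosome_of_group=chrom_map,
                            warnings=warnings)
    for gi, members in enumerate(groups):
        for cid in members:
            result.group_of_contig[cid] = [gi]
            result.confidence[cid] = 1.0

    rescued = rescue_small_haplotigs(groups, pap, min_haplotig_bp, contig_lengths)
    for cid, (gi, conf, flags) in rescued.items():
        result.group_of_contig[cid] = [gi]
        result.groups[gi].append(cid)
        result.confidence[cid] = conf
        result.flags[cid] = flags

    pools = _group_marker_pool(groups, infos, pap, rep_pool_cap)
    bin_pools = [
        _binarize(pap.genotypes[rows], 1) if rows else np.empty((0, 0), np.int8)
        for rows in pools
    ]
    zv = pap.zero_variance
    for cid in sorted(infos):
        c = infos[cid]
        if c.majority_class not in (2, 3, 4) or cid in result.group_of_contig:
            continue
        if c.majority_class == 4:
            anchor = [i for i in c.marker_idx
                      if pap.markers["copy_class"].iat[i] != 4 and not zv[i]]
            if not anchor:
                result.flags[cid] = ["tetraplotig_unlinked"]
                continue
            rescue_one = _nearest_group(pap, anchor, pools)
            if rescue_one is None:
                result.flags[cid] = ["tetraplotig_unlinked"]
                continue
            chrom = chrom_map.get(rescue_one)
            chosen = [g for g, ch in chrom_map.items() if ch == chrom]
            chosen.sort()
            result.group_of_contig[cid] = chosen
            result.flags[cid] = ["tetraplotig_by_chromosome"] + (
                ["partial"] if len(chosen) < 4 else [])
            for g in chosen:
                result.groups[g].append(cid)
            continue
        # constant PAPs are fine here: the AND test masks them by each group's
        # carriers and checks variance of the masked vector instead
        rows = c.class_idx
        chosen, scores, flags = assign_multicopy_contig(
            pap.genotypes[rows], c.majority_class, bin_pools)
        result.group_of_contig[cid] = chosen
        result.confidence[cid] = scores[0] if scores else float("nan")
        if flags:
            result.flags[cid] = flags
        for g in chosen:
            result.groups[g].append(cid)
    for g in result.groups:
        g.sort()
    return result


def _nearest_group(pap: PAPMatrix, rows: list[int],
                   pools: list[list[int]]) -> int | None:
    pool_rows = [i for p in pools for i in p]
    pool_group = [gi for gi, p in enumerate(pools) for _ in p]
    if not pool_rows:
        return None
    order = sorted(set(rows) | set(pool_rows))
    pos = {r: j for j, r in enumerate(order)}
    corr = correlation_matrix(pap.genotypes[order])
    block = corr[np.ix_([pos[i] for i in rows], [pos[i] for i in pool_rows])]
    if not np.isfinite(block).any():
        return None
    col_best = np.nanmax(block, axis=0)
    best_g, best_v = None, -np.inf
    for g, v in zip(pool_group, col_best):
        if np.isfinite(v) and v > best_v:
            best_g, best_v = g, v
    return best_g


# ---------------------------------------------------------------------------
# truth-based evaluation (simulation only)


def grouping_accuracy(result: GroupingResult, pap: PAPMatrix,
                      truth_haplotypes: dict[str, frozenset[int]]
                      ) -> tuple[pd.DataFrame, float]:
    """Per-group purity and overall marker-assignment accuracy against truth.

    ``truth_haplotypes`` maps contig ids to their true haplotype sets (the
    simulator's contig table).  A marker-to-group assignment is correct if the
    group's dominant true haplotype is one of the marker's contig haplotypes.
    Purity is the majority-haplotype bp fraction over a group's haplotig
    members.  Overall accuracy weighs assignments by marker bp.
    """
    m = pap.markers
    group_hap: dict[int, int] = {}
    purity_rows = []
    for gi, members in enumerate(result.groups):
        bp: dict[int, float] = {}
        for cid in members:
            haps = truth_haplotypes.get(cid)
            if haps is None:
                raise ValueError(f"contig {cid} missing from truth")
            if len(haps) != 1:
                continue
            length = float(m.loc[m["contig_id"] == cid, "W"].sum())
            h = next(iter(haps))
            bp[h] = bp.get(h, 0.0) + length
        if not bp:
            continue
        total = sum(bp.values())
        h_major = max(sorted(bp), key=lambda h: bp[h])
        group_hap[gi] = h_major
        purity_rows.append((gi, h_major, bp[h_major] / total, total))
    purity = pd.DataFrame(purity_rows,
                          columns=["group_id", "haplotype", "purity", "bp"])

    correct_bp = 0.0
    total_bp = 0.0
    for i in range(len(m)):
        cid = m["contig_id"].iat[i]
        w = float(m["W"].iat[i])
        for g in result.group_of_contig.get(cid, []):
            total_bp += w
            if group_hap.get(g) in truth_haplotypes[cid]:
                correct_bp += w
    accuracy = correct_bp / total_bp if total_bp else float("nan")
    return purity, accuracy
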