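"""Synthetic autotetraploid genome, diploid-gamete and read-count simulator.

Every downstream stage (depth typing, PAP genotyping, linkage clustering,
read binning, phasing evaluation) can be exercised end to end on the output
of this module, with full ground truth attached.

The model emulates a highly heterozygous autotetraploid such as cultivated
potato: four haplotypes per chromosome, ~1 SNP per 60 bp between non-related
haplotype pairs, and roughly half of the genome lying in identical-by-descent
(IBD) blocks introduced by recent inbreeding, which collapse during contig
assembly.  Meiosis produces diploid gametes (e.g. pollen): the four homologs
pair two-and-two into bivalents (three pairings, equiprobable), each bivalent
recombines and contributes one chromatid.  Gametes are then "sequenced" at
very low coverage (default 0.18x) by Poisson-sampling read counts per
coverage marker.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SimConfig",
    "Contig",
    "IBDBlock",
    "TruthGenome",
    "GameteGenome",
    "simulate_genome",
    "simulate_gametes",
    "simulate_window_depths",
    "simulate_marker_counts",
    "simulate_reads",
    "true_markers",
    "contig_sequence",
    "haplotype_records",
]

#: the three ways four homologs can pair into two bivalents
BIVALENT_PAIRINGS = (
    ((0, 1), (2, 3)),
    ((0, 2), (1, 3)),
    ((0, 3), (1, 2)),
)

#: parent of origin per haplotype index: 0,1 maternal ('A'), 2,3 paternal ('B')
PARENT_OF_HAPLOTYPE = ("A", "A", "B", "B")

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


class ConfigError(ValueError):
    """Raised for inconsistent simulation parameters."""


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated tetraploid + gamete-sequencing experiment.

    Defaults follow the study conditions this simulator emulates: per-haplotype
    somatic depth H = 113x, 717 pollen genomes at 0.18x each, ~1 SNP per 60 bp
    in divergent regions and ~50% of the genome inside IBD blocks.
    """

    n_chromosomes: int = 12
    chrom_length_bp: int = 1_000_000
    n_haplotypes: int = 4
    snp_rate_divergent: float = 1.0 / 60.0
    ibd_fraction: float = 0.5
    ibd_block_mean_bp: int = 100_000
    ibd_min_gap_bp: int = 100_000
    ibd_share_weights: tuple[float, float, float] = (0.8, 0.2, 0.0)  # 2-,3-,4-way
    n_gametes: int = 717
    gamete_coverage: float = 0.18
    somatic_depth_per_haplotype: float = 113.0
    crossovers_per_bivalent_mean: float = 1.0
    double_reduction_rate: float = 0.0
    window_bp: int = 10_000
    marker_bp: int = 50_000
    read_length_bp: int = 150
    sequences: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_haplotypes != 4:
            raise ConfigError("the meiosis model requires exactly 4 haplotypes")
        if not 0.0 <= self.ibd_fraction <= 1.0:
            raise ConfigError("ibd_fraction must lie in [0, 1]")
        for name in ("n_chromosomes", "chrom_length_bp", "ibd_block_mean_bp",
                     "n_gametes", "window_bp", "marker_bp", "read_length_bp"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.marker_bp % self.window_bp != 0:
            raise ConfigError("marker_bp must be a multiple of window_bp")
        if self.ibd_fraction >= 1.0 and self.ibd_block_mean_bp > self.chrom_length_bp:
            raise ConfigError("ibd_fraction ~1 with blocks larger than a chromosome")
        if abs(sum(self.ibd_share_weights) - 1.0) > 1e-9:
            raise ConfigError("ibd_share_weights must sum to 1")


@dataclass(frozen=True)
class Contig:
    """A contig of the emulated initial assembly, in chromosome coordinates.

    ``haplotypes`` is the set of haplotype indices collapsed into this contig:
    a singleton for a haplotig, 2/3/4 members for collapsed contigs over IBD
    blocks.  Coordinates are 0-based half-open on the source chromosome.
    """

    contig_id: str
    chrom: int
    start: int
    end: int
    haplotypes: frozenset[int]

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def copy_number(self) -> int:
        return len(self.haplotypes)


@dataclass(frozen=True)
class IBDBlock:
    chrom: int
    start: int
    end: int
    haplotypes: frozenset[int]


@dataclass
class TruthGenome:
    """Fully labeled synthetic tetraploid genome."""

    config: SimConfig
    contigs: list[Contig]
    ibd_blocks: list[IBDBlock]
    #: (chrom, haplotype) -> uint8 base codes; empty in counts-only mode
    sequences: dict[tuple[int, int], np.ndarray] = field(default_factory=dict)

    def contig(self, contig_id: str) -> Contig:
        return self._by_id[contig_id]

    @property
    def _by_id(self) -> dict[str, Contig]:
        cache = getattr(self, "_by_id_cache", None)
        if cache is None:
            cache = {c.contig_id: c for c in self.contigs}
            object.__setattr__(self, "_by_id_cache", cache)
        return cache

    def ibd_fraction_realized(self) -> float:
        ibd = sum(b.end - b.start for b in self.ibd_blocks)
        return ibd / (self.config.n_chromosomes * self.config.chrom_length_bp)

    def contig_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "contig_id": [c.contig_id for c in self.contigs],
                "chrom": [c.chrom for c in self.contigs],
                "start": [c.start for c in self.contigs],
                "end": [c.end for c in self.contigs],
                "haplotypes": [",".join(map(str, sorted(c.haplotypes)))
                                for c in self.contigs],
            }
        )


@dataclass
class GameteGenome:
    """The two recombinant haplotype mosaics carried by one diploid gamete.

    ``mosaics[c]`` holds the two mosaics of chromosome ``c``; each mosaic is a
    list of ``(start, end, source_haplotype)`` tiles covering the chromosome.
    """

    gamete_id: str
    mosaics: list[tuple[list[tuple[int, int, int]], list[tuple[int, int, int]]]]
    crossovers: list[list[int]]

    def carries(self, chrom: int, pos: int) -> set[int]:
        """Haplotype indices present at a position (2, or 1 under double reduction)."""
        out = set()
        for mosaic in self.mosaics[chrom]:
            for s, e, h in mosaic:
                if s <= pos < e:
                    out.add(h)
                    break
        return out


# ---------------------------------------------------------------------------
# genome


def _round_window(x: float, window: int) -> int:
    return int(round(x / window)) * window


def _place_ibd_blocks(cfg: SimConfig, rng: np.random.Generator) -> list[tuple[int, int]]:
    """Window-aligned IBD intervals on one chromosome hitting the target fraction.

    Block lengths ~ Uniform(0.5m, 1.5m); blocks are separated by at least
    ``ibd_min_gap_bp`` of unique sequence so that every haplotype keeps
    anchorable unique segments between collapsed regions.
    """
    L, w = cfg.chrom_length_bp, cfg.window_bp
    target = _round_window(cfg.ibd_fraction * L, w)
    if target <= 0:
        return []
    gap_total = L - target
    max_blocks = max(1, 1 + gap_total // max(cfg.ibd_min_gap_bp, w))
    n = int(min(max(1, round(target / cfg.ibd_block_mean_bp)), max_blocks))
    # equal window-unit shares, then random pairwise transfers bounded to keep
    # every block within [0.5, 1.5] x its base size
    total_units = target // w
    base = total_units // n
    units = np.full(n, base, dtype=np.int64)
    units[rng.permutation(n)[: total_units - base * n]] += 1
    lo, hi = max(1, base // 2), base + base // 2
    for _ in range(4 * n):
        i, j = rng.integers(0, n, 2)
        if i == j:
            continue
        amount = int(rng.integers(0, max(base // 4, 1) + 1))
        if units[i] - amount >= lo and units[j] + amount <= hi:
            units[i] -= amount
            units[j] += amount
    lengths = [int(u) * w for u in units]
    interior = (n - 1) * cfg.ibd_min_gap_bp
    extra_units = (gap_total - interior) // w
    shares = rng.multinomial(extra_units, np.full(n + 1, 1.0 / (n + 1)))
    blocks = []
    pos = int(shares[0]) * w
    for i, length in enumerate(lengths):
        blocks.append((pos, pos + length))
        pos += length
        if i < n - 1:
            pos += cfg.ibd_min_gap_bp + int(shares[i + 1]) * w
    return blocks


def _mutation_rate(pairwise_rate: float) -> float:
    """Per-lineage substitution probability giving the requested pairwise SNP rate.

    Two lineages mutating independently at rate mu differ at a site with
    probability 2*mu*(1-mu) + (2/3)*mu**2; solve that for mu.
    """
    r = pairwise_rate
    if r <= 0:
        return 0.0
    return (3.0 / 8.0) * (2.0 - math.sqrt(4.0 - 16.0 * r / 3.0))


def simulate_genome(config: SimConfig, rng: np.random.Generator | None = None) -> TruthGenome:
    """Generate the labeled tetraploid genome: IBD blocks, contig tiling, sequences.

    Contigs tile every haplotype of every chromosome exactly once: one collapsed
    contig per maximal IBD block (emitted once for its member haplotypes) and
    haplotigs covering everything else.
    """
    cfg = config
    if rng is None:
        rng = np.random.default_rng([cfg.seed, 0])
    sizes = np.array([2, 3, 4])
    weights = np.asarray(cfg.ibd_share_weights, dtype=float)
    contigs: list[Contig] = []
    blocks_all: list[IBDBlock] = []
    sequences: dict[tuple[int, int], np.ndarray] = {}
    mu = _mutation_rate(cfg.snp_rate_divergent)
    for chrom in range(cfg.n_chromosomes):
        intervals = _place_ibd_blocks(cfg, rng)
        blocks = []
        for j, (s, e) in enumerate(intervals):
            k = int(rng.choice(sizes, p=weights))
            members = frozenset(int(h) for h in rng.choice(4, size=k, replace=False))
            blocks.append(IBDBlock(chrom, s, e, members))
        blocks_all.extend(blocks)
        # collapsed contig per block
        for j, b in enumerate(blocks):
            contigs.append(
                Contig(f"chr{chrom:02d}_col{j:02d}", chrom, b.start, b.end, b.haplotypes)
            )
        # haplotigs: per haplotype, maximal runs between its member blocks
        for h in range(4):
            cuts = sorted((b.start, b.end) for b in blocks if h in b.haplotypes)
            pos, idx = 0, 0
            for s, e in cuts:
                if s > pos:
                    contigs.append(
                        Contig(f"chr{chrom:02d}_h{h}_{idx:02d}", chrom, pos, s,
                               frozenset([h]))
                    )
                    idx += 1
                pos = e
            if pos < cfg.chrom_length_bp:
                contigs.append(
                    Contig(f"chr{chrom:02d}_h{h}_{idx:02d}", chrom, pos,
                           cfg.chrom_length_bp, frozenset([h]))
                )
        if cfg.sequences:
            ancestral = rng.integers(0, 4, cfg.chrom_length_bp, dtype=np.uint8)
            haps = [ancestral.copy() for _ in range(4)]
            segments = _segments_with_lineages(blocks, cfg.chrom_length_bp)
            for (s, e, lineages) in segments:
                for lineage in lineages:
                    n_mut = rng.binomial(e - s, mu)
                    if n_mut == 0:
                        continue
                    pos_m = rng.choice(e - s, size=n_mut, replace=False) + s
                    off = rng.integers(1, 4, n_mut, dtype=np.uint8)
                    new = (ancestral[pos_m] + off) % 4
                    for h in lineage:
                        haps[h][pos_m] = new
            for h in range(4):
                sequences[(chrom, h)] = haps[h]
    contigs.sort(key=lambda c: (c.chrom, c.start, c.contig_id))
    return TruthGenome(config=cfg, contigs=contigs, ibd_blocks=blocks_all,
                       sequences=sequences)


def _segments_with_lineages(blocks: list[IBDBlock], L: int):
    """Tile [0, L) into segments, each with its mutation lineages.

    Inside an IBD block the member haplotypes form one lineage (identical
    sequence); everywhere else all four haplotypes mutate independently.
    """
    out = []
    pos = 0
    for b in sorted(blocks, key=lambda b: b.start):
        if b.start > pos:
            out.append((pos, b.start, [[0], [1], [2], [3]]))
        members = sorted(b.haplotypes)
        lineages = [members] + [[h] for h in range(4) if h not in b.haplotypes]
        out.append((b.start, b.end, lineages))
        pos = b.end
    if pos < L:
        out.append((pos, L, [[0], [1], [2], [3]]))
    return out


# ---------------------------------------------------------------------------
# meiosis


def _chromatid(bivalent: tuple[int, int], L: int, co_mean: float,
               rng: np.random.Generator) -> tuple[list[tuple[int, int, int]], list[int]]:
    n_co = int(rng.poisson(co_mean))
    positions = sorted(int(p) for p in rng.integers(1, L, size=n_co))
    positions = sorted(set(positions))
    current = int(rng.integers(0, 2))
    tiles = []
    pos = 0
    for p in positions:
        tiles.append((pos, p, bivalent[current]))
        current = 1 - current
        pos = p
    tiles.append((pos, L, bivalent[current]))
    # merge adjacent tiles from the same source (possible after duplicate draws)
    merged = [tiles[0]]
    for s, e, h in tiles[1:]:
        ps, pe, ph = merged[-1]
        if h == ph:
            merged[-1] = (ps, e, h)
        else:
            merged.append((s, e, h))
    return merged, positions


def simulate_gametes(genome: TruthGenome, config: SimConfig | None = None,
                     rng: np.random.Generator | None = None) -> list[GameteGenome]:
    """Diploid gametes: random bivalent pairing, one recombinant chromatid each.

    Per chromosome the four homologs are partitioned uniformly into two
    bivalents (three pairings equiprobable); each bivalent contributes one
    chromatid carrying Poisson-many crossovers at uniform positions.  With
    probability ``double_reduction_rate`` both chromatids come from a single
    bivalent instead.
    """
    cfg = config or genome.config
    if rng is None:
        rng = np.random.default_rng([cfg.seed, 1])
    L = cfg.chrom_length_bp
    gametes = []
    for g in range(cfg.n_gametes):
        mosaics = []
        crossovers = []
        for _ in range(cfg.n_chromosomes):
            pairing = BIVALENT_PAIRINGS[int(rng.integers(0, 3))]
            if cfg.double_reduction_rate > 0 and rng.random() < cfg.double_reduction_rate:
                biv = pairing[int(rng.integers(0, 2))]
                pair = (biv, biv)
            else:
                pair = pairing
            m1, co1 = _chromatid(pair[0], L, cfg.crossovers_per_bivalent_mean, rng)
            m2, co2 = _chromatid(pair[1], L, cfg.crossovers_per_bivalent_mean, rng)
            mosaics.append((m1, m2))
            crossovers.append(sorted(co1 + co2))
        gametes.append(GameteGenome(f"g{g:04d}", mosaics, crossovers))
    return gametes


# ---------------------------------------------------------------------------
# marker tiling, somatic depths, gamete read counts


def chunk_length(length: int, marker_bp: int, min_tail_bp: int) -> list[tuple[int, int]]:
    """Cut ``[0, length)`` into marker-sized chunks.

    Full ``marker_bp`` pieces are emitted; a trailing remainder shorter than
    ``min_tail_bp`` is merged into the previous chunk, otherwise it stands as
    its own (shorter) marker.
    """
    if length <= marker_bp:
        return [(0, length)]
    bounds = list(range(0, length, marker_bp))
    chunks = [(s, min(s + marker_bp, length)) for s in bounds]
    tail = chunks[-1]
    if tail[1] - tail[0] < min_tail_bp and len(chunks) > 1:
        prev = chunks[-2]
        chunks = chunks[:-2] + [(prev[0], tail[1])]
    return chunks


def true_markers(genome: TruthGenome, marker_bp: int | None = None,
                 window_bp: int | None = None) -> pd.DataFrame:
    """Noise-free coverage-marker tiling straight from the contig truth.

    Mirrors what depth typing recovers from somatic depths when classification
    is perfect.  Copy class equals the number of collapsed haplotypes.
    """
    cfg = genome.config
    marker_bp = marker_bp or cfg.marker_bp
    window_bp = window_bp or cfg.window_bp
    rows = []
    for c in genome.contigs:
        for s, e in chunk_length(c.length, marker_bp, window_bp // 2):
            rows.append((c.contig_id, s, e, c.copy_number, e - s))
    df = pd.DataFrame(rows, columns=["contig_id", "start", "end", "copy_class", "W"])
    df.insert(0, "marker_id", [f"{r.contig_id}:{r.start}-{r.end}"
                               for r in df.itertuples()])
    return df


def simulate_window_depths(genome: TruthGenome,
                           rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Somatic per-window sequencing depths over the contig tiling.

    Depth of a window in a contig collapsing k haplotypes ~ Normal(H*k,
    sqrt(H*k)), truncated at 0 — a Poisson-like noise model producing the
    well-separated depth peaks that copy classification relies on.
    """
    cfg = genome.config
    if rng is None:
        rng = np.random.default_rng([cfg.seed, 3])
    H = cfg.somatic_depth_per_haplotype
    recs = []
    for c in genome.contigs:
        starts = np.arange(0, c.length, cfg.window_bp)
        ends = np.minimum(starts + cfg.window_bp, c.length)
        mean = H * c.copy_number
        depth = rng.normal(mean, math.sqrt(mean), size=len(starts))
        np.maximum(depth, 0.0, out=depth)
        for s, e, d in zip(starts, ends, depth):
            recs.append((c.contig_id, int(s), int(e), float(d)))
    return pd.DataFrame(recs, columns=["contig_id", "start", "end", "depth"])


def simulate_marker_counts(genome: TruthGenome, gametes: list[GameteGenome],
                           markers: pd.DataFrame | None = None,
                           rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Per-marker x per-gamete Poisson read counts.

    The rate for marker m in gamete g is ``coverage/read_length`` reads per bp
    times the number of bp of m's interval covered by mosaics whose source
    haplotype is collapsed in m's contig (so a fully double-covered marker has
    twice the rate of a single-copy one).

    ``markers`` may be any marker table over the truth contigs (for instance
    the one recovered by depth typing); defaults to the noise-free tiling.
    """
    cfg = genome.config
    if rng is None:
        rng = np.random.default_rng([cfg.seed, 2])
    if markers is None:
        markers = true_markers(genome)
    rate_per_bp = cfg.gamete_coverage / cfg.read_length_bp
    n_mark, n_gam = len(markers), len(gametes)
    counts = np.zeros((n_mark, n_gam), dtype=np.int64)

    contig_of = genome._by_id
    by_chrom: dict[int, dict] = {}
    marker_contigs = markers["contig_id"].to_numpy()
    mstart_rel = markers["start"].to_numpy()
    mend_rel = markers["end"].to_numpy()
    for i in range(n_mark):
        c = contig_of[marker_contigs[i]]
        d = by_chrom.setdefault(c.chrom, {"idx": [], "gs": [], "ge": [], "haps": []})
        d["idx"].append(i)
        d["gs"].append(c.start + mstart_rel[i])
        d["ge"].append(c.start + mend_rel[i])
        d["haps"].append(c.haplotypes)
    for chrom, d in by_chrom.items():
        d["idx"] = np.asarray(d["idx"])
        d["gs"] = np.asarray(d["gs"], dtype=np.int64)
        d["ge"] = np.asarray(d["ge"], dtype=np.int64)
        d["has"] = [np.array([h in haps for haps in d["haps"]]) for h in range(4)]

    for gi, gam in enumerate(gametes):
        for chrom, d in by_chrom.items():
            cov = np.zeros(len(d["idx"]))
            for mosaic in gam.mosaics[chrom]:
                for s, e, h in mosaic:
                    ov = np.minimum(d["ge"], e) - np.maximum(d["gs"], s)
                    np.clip(ov, 0, None, out=ov)
                    cov += ov * d["has"][h]
            lam = rate_per_bp * cov
            counts[d["idx"], gi] = rng.poisson(lam)
    out = pd.DataFrame(counts, columns=[g.gamete_id for g in gametes])
    out.insert(0, "marker_id", markers["marker_id"].to_numpy())
    return out


# ---------------------------------------------------------------------------
# long reads


def simulate_reads(genome: TruthGenome, n_reads: int, read_length_bp: int = 15_000,
                   rng: np.random.Generator | None = None
                   ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Uniform long reads over the four haplotypes, as contig alignment records.

    Returns ``(records, truth)``: records with one row per read-contig
    alignment piece (reads spanning contig junctions split into pieces), and a
    truth table mapping each read to its source haplotype.
    """
    cfg = genome.config
    if rng is None:
        rng = np.random.default_rng([cfg.seed, 4])
    L = cfg.chrom_length_bp
    # (chrom, hap) -> sorted contig intervals covering that haplotype
    tracks: dict[tuple[int, int], list[Contig]] = {}
    for c in genome.contigs:
        for h in c.haplotypes:
            tracks.setdefault((c.chrom, h), []).append(c)
    for key in tracks:
        tracks[key].sort(key=lambda c: c.start)

    haps = rng.integers(0, 4, n_reads)
    chroms = rng.integers(0, cfg.n_chromosomes, n_reads)
    span = min(read_length_bp, L)
    starts = rng.integers(0, L - span + 1, n_reads)
    rec_rows, truth_rows = [], []
    for i in range(n_reads):
        rid = f"r{i:06d}"
        h, chrom, s = int(haps[i]), int(chroms[i]), int(starts[i])
        e = s + span
        truth_rows.append((rid, chrom, h, s))
        for c in tracks[(chrom, h)]:
            if c.end <= s:
                continue
            if c.start >= e:
                break
            ps, pe = max(s, c.start), min(e, c.end)
            rec_rows.append((rid, c.contig_id, ps - c.start, pe - c.start, pe - ps))
    records = pd.DataFrame(
        rec_rows, columns=["read_id", "contig_id", "contig_start", "contig_end",
                           "aligned_bp"]
    )
    truth = pd.DataFrame(truth_rows, columns=["read_id", "chrom", "haplotype", "start"])
    return records, truth


# ---------------------------------------------------------------------------
# sequence export


def contig_sequence(genome: TruthGenome, contig_id: str) -> np.ndarray:
    """Base codes of a contig (identical across its collapsed haplotypes)."""
    c = genome.contig(contig_id)
    if not genome.sequences:
        raise ValueError("genome was simulated in counts-only mode")
    h = min(c.haplotypes)
    return genome.sequences[(c.chrom, h)][c.start:c.end]


def codes_to_str(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode("ascii")


def haplotype_records(genome: TruthGenome):
    """Yield ``(name, sequence_string)`` per haplotype-chromosome (FASTA order)."""
    for (chrom, h), codes in sorted(genome.sequences.items()):
        yield f"chr{chrom}_hap{h}", codes_to_str(codes)


def gamete_truth_table(gametes: list[GameteGenome]) -> pd.DataFrame:
    rows = []
    for g in gametes:
        for chrom, pair in enumerate(g.mosaics):
            for m_idx, mosaic in enumerate(pair):
                for s, e, h in mosaic:
                    rows.append((g.gamete_id, chrom, m_idx, s, e, h))
    return pd.DataFrame(
        rows, columns=["gamete_id", "chrom", "mosaic", "start", "end", "haplotype"]
    )
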