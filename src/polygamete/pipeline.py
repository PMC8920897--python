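"""End-to-end orchestration: simulate -> type-depth -> build-paps -> cluster
-> bin-reads -> evaluate, with per-stage TSV artifacts and JSON manifests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__, io
from .binning import DEFAULT_MIN_OVERLAP_BP, bin_reads
from .cluster import (DEFAULT_MIN_HAPLOTIG_BP, DEFAULT_THETA_HOM,
                      DEFAULT_THETA_LINK, GroupingResult, group_contigs,
                      grouping_accuracy)
from .depth import classify_windows, merge_to_markers
from .evaluate import (DEFAULT_K, extract_parent_kmers, precision,
                       precision_from_labels, reports_frame, score_haplotype)
from .pap import build_pap_matrix
from .simulate import (PARENT_OF_HAPLOTYPE, SimConfig, TruthGenome,
                       codes_to_str, contig_sequence, gamete_truth_table,
                       haplotype_records, simulate_gametes,
                       simulate_marker_counts, simulate_reads,
                       simulate_window_depths, simulate_genome)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "marker_parent_labels"]


@dataclass
class PipelineConfig:
    """Knobs of the full phasing pipeline (simulated or file-driven)."""

    outdir: Path
    seed: int = 0
    sim: SimConfig | None = None            # simulate stage; None = real-data mode
    depths_path: Path | None = None         # real-data inputs
    counts_path: Path | None = None
    alignments_path: Path | None = None
    H: float = 113.0
    theta_link: float = DEFAULT_THETA_LINK
    theta_hom: float = DEFAULT_THETA_HOM
    min_haplotig_bp: int = DEFAULT_MIN_HAPLOTIG_BP
    min_overlap_bp: int = DEFAULT_MIN_OVERLAP_BP
    min_informative: int = 50
    k: int = DEFAULT_K
    n_reads: int = 20_000
    read_length_bp: int = 15_000
    run_binning: bool = True
    run_evaluation: bool = True


@dataclass
class PipelineResult:
    grouping: GroupingResult
    stages: list[str]
    metrics: dict = field(default_factory=dict)


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()[:16]


def _manifest(outdir: Path, stage: str, params: dict, inputs: list[Path],
              outputs: list[Path]) -> None:
    mdir = Path(outdir) / "manifests"
    mdir.mkdir(parents=True, exist_ok=True)
    payload = {
        "stage": stage,
        "version": __version__,
        "params": {k: (str(v) if isinstance(v, Path) else v)
                   for k, v in params.items()},
        "inputs": {str(p): _digest(p) for p in inputs},
        "outputs": {str(p): _digest(p) for p in outputs},
    }
    (mdir / f"{stage}.json").write_text(json.dumps(payload, indent=2, default=str))


def marker_parent_labels(markers: pd.DataFrame, grouping: GroupingResult,
                         genome: TruthGenome) -> pd.DataFrame:
    """Parent-labeled marker-to-group assignments (counts-mode evaluation input).

    Only markers whose contig's haplotype set is parent-pure (all maternal or
    all paternal) are diagnostic; collapsed contigs spanning both parents are
    excluded, mirroring how k-mers shared by the parents are uninformative.
    """
    rows = []
    for r in markers.itertuples():
        contig = genome.contig(r.contig_id)
        parents = {PARENT_OF_HAPLOTYPE[h] for h in contig.haplotypes}
        if len(parents) != 1:
            continue
        parent = next(iter(parents))
        for g in grouping.group_of_contig.get(r.contig_id, []):
            rows.append((r.marker_id, g, parent))
    return pd.DataFrame(rows, columns=["marker_id", "group_id", "parent"])


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute all configured stages; every stage writes its TSV + manifest."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    stages: list[str] = []
    metrics: dict = {}
    genome = gametes = None

    if config.sim is not None:
        cfg = dataclasses.replace(config.sim, seed=config.seed)
        genome = simulate_genome(cfg)
        gametes = simulate_gametes(genome)
        depths = simulate_window_depths(genome)
        io.write_tsv(genome.contig_table(), out / "contig_truth.tsv")
        io.write_tsv(gamete_truth_table(gametes), out / "gamete_truth.tsv")
        io.write_window_depths(depths, out / "window_depths.tsv")
        if cfg.sequences:
            io.write_fasta(haplotype_records(genome), out / "haplotypes.fasta")
        _manifest(out, "simulate", dataclasses.asdict(cfg), [],
                  [out / "contig_truth.tsv", out / "window_depths.tsv"])
        stages.append("simulate")
        H = cfg.somatic_depth_per_haplotype
    else:
        if config.depths_path is None:
            raise FileNotFoundError(
                "type-depth stage: no window-depth input and simulation disabled")
        depths = io.read_window_depths(config.depths_path)
        H = config.H

    classified = classify_windows(depths, H)
    markers = merge_to_markers(classified)
    io.write_markers(markers, out / "markers.tsv")
    _manifest(out, "type_depth", {"H": H}, [out / "window_depths.tsv"]
              if config.sim is not None else [config.depths_path],
              [out / "markers.tsv"])
    stages.append("type_depth")

    if config.sim is not None:
        counts = simulate_marker_counts(genome, gametes, markers)
        io.write_counts(counts, out / "counts.tsv")
    else:
        if config.counts_path is None:
            raise FileNotFoundError("build-paps stage: no counts input")
        counts = io.read_counts(config.counts_path)

    pap = build_pap_matrix(counts, markers,
                           min_informative=config.min_informative)
    io.write_tsv(pap.to_frame(), out / "paps.tsv")
    io.write_tsv(pap.normalizers, out / "normalizers.tsv")
    _manifest(out, "build_paps", {"min_informative": config.min_informative},
              [out / "markers.tsv"], [out / "paps.tsv"])
    stages.append("build_paps")
    metrics["n_markers"] = len(pap.markers)
    metrics["n_gametes_used"] = len(pap.gamete_ids)
    metrics["dropped_gametes"] = len(pap.dropped_gametes)

    grouping = group_contigs(pap, config.theta_link, config.theta_hom,
                             config.min_haplotig_bp)
    io.write_grouping(grouping.to_frame(pap), out / "grouping.tsv")
    _manifest(out, "cluster",
              {"theta_link": config.theta_link, "theta_hom": config.theta_hom,
               "min_haplotig_bp": config.min_haplotig_bp},
              [out / "paps.tsv"], [out / "grouping.tsv"])
    stages.append("cluster")
    metrics["n_groups"] = grouping.n_groups
    metrics["n_chromosomes"] = grouping.n_chromosomes
    metrics["grouping_warnings"] = list(grouping.warnings)

    if config.run_binning:
        if config.sim is not None:
            records, read_truth = simulate_reads(
                genome, config.n_reads, config.read_length_bp)
            io.write_alignments(records, out / "read_alignments.tsv")
            io.write_tsv(read_truth, out / "read_truth.tsv")
        else:
            if config.alignments_path is None:
                raise FileNotFoundError("bin-reads stage: no alignment input")
            records = io.read_alignments(config.alignments_path)
        table, summary = bin_reads(records, markers, grouping,
                                   seed=config.seed,
                                   min_overlap_bp=config.min_overlap_bp)
        io.write_tsv(table, out / "read_bins.tsv")
        io.write_tsv(summary, out / "read_bins_summary.tsv")
        _manifest(out, "bin_reads",
                  {"min_overlap_bp": config.min_overlap_bp, "seed": config.seed},
                  [out / "grouping.tsv"], [out / "read_bins.tsv"])
        stages.append("bin_reads")
        metrics["read_assigned_fraction"] = summary.attrs["assigned_fraction"]

    if config.run_evaluation and config.sim is not None:
        truth_haps = {c.contig_id: c.haplotypes for c in genome.contigs}
        purity, accuracy = grouping_accuracy(grouping, pap, truth_haps)
        labels = marker_parent_labels(pap.markers, grouping, genome)
        reports, prec = precision_from_labels(labels)
        io.write_tsv(reports_frame(reports), out / "phasing_report.tsv")
        metrics["grouping_accuracy"] = accuracy
        metrics["phasing_precision"] = prec
        if genome.sequences:
            metrics["kmer_precision"] = _kmer_precision(genome, grouping,
                                                        config.k)
        _manifest(out, "evaluate", {"k": config.k},
                  [out / "grouping.tsv"], [out / "phasing_report.tsv"])
        stages.append("evaluate")

    (out / "metrics.json").write_text(json.dumps(metrics, indent=2, default=str))
    return PipelineResult(grouping=grouping, stages=stages, metrics=metrics)


def _kmer_precision(genome: TruthGenome, grouping: GroupingResult,
                    k: int) -> float:
    """Sequence-mode precision: parent k-mer sets vs per-group pseudo-assemblies."""
    cfg = genome.config
    parent_a = [codes_to_str(genome.sequences[(c, h)])
                for c in range(cfg.n_chromosomes) for h in (0, 1)]
    parent_b = [codes_to_str(genome.sequences[(c, h)])
                for c in range(cfg.n_chromosomes) for h in (2, 3)]
    sets = extract_parent_kmers(parent_a, parent_b, k)
    reports = []
    for gi, members in enumerate(grouping.groups):
        seqs = [codes_to_str(contig_sequence(genome, cid)) for cid in members]
        if seqs:
            reports.append(score_haplotype(seqs, sets, name=f"group{gi}"))
    return precision(reports)
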